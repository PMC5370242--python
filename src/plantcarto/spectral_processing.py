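"""MS/MS peak filtering and cosine spectral similarity.

Two filters precede all similarity scoring: removal of peaks within a
+/-17 Da window of the precursor, and a window filter keeping a peak only
when it ranks among the 6 most intense within any 50 Da window centered on
itself. Similarity is the (modified) cosine: square-root-transformed
intensities, fragment pairs matched one-to-one by maximum total weight,
with an optional precursor-shifted pairing that links structural analogs.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import LevelError
from .models import Spectrum

#: candidate-pair count above which the matcher falls back from the exact
#: assignment solver to greedy descending-weight selection
EXACT_ASSIGNMENT_LIMIT = 32


def _require_ms2(s: Spectrum, op: str) -> None:
    if s.ms_level != 2 or s.precursor_mz is None:
        raise LevelError(f"{op} needs an MS2 spectrum with a precursor")


def filter_precursor_window(s: Spectrum, half_window_da: float = 17.0
                            ) -> Spectrum:
    """Remove all peaks within ``half_window_da`` of the precursor m/z
    (boundary inclusive); flags the result."""
    _require_ms2(s, "filter_precursor_window")
    keep = np.abs(s.mz - s.precursor_mz) > half_window_da
    out = s.copy(mz=s.mz[keep], intensity=s.intensity[keep])
    out.precursor_window_applied = True
    return out


def filter_window_top_n(s: Spectrum, top_n: int = 6,
                        window_da: float = 50.0) -> Spectrum:
    """Keep a peak iff it ranks within the ``top_n`` by intensity among all
    peaks in the ``window_da`` window centered on itself.

    Ranking ties break toward lower m/z. Idempotent: a retained peak can
    only lose neighbors, never gain them.
    """
    mz, inten = s.mz, s.intensity
    n = mz.size
    if n <= top_n:
        out = s.copy()
        out.window_topn_applied = True
        return out
    half = window_da / 2.0
    # rank peaks by (-intensity, mz); a peak survives if fewer than top_n
    # better-ranked peaks fall inside its window
    order = np.lexsort((mz, -inten))
    rank = np.empty(n, dtype=np.int64)
    rank[order] = np.arange(n)
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = np.searchsorted(mz, mz[i] - half)
        hi = np.searchsorted(mz, mz[i] + half, side="right")
        better = np.count_nonzero(rank[lo:hi] < rank[i])
        keep[i] = better < top_n
    out = s.copy(mz=mz[keep], intensity=inten[keep])
    out.window_topn_applied = True
    return out


def filter_spectrum(s: Spectrum, precursor_half_window_da: float = 17.0,
                    top_n: int = 6, window_da: float = 50.0) -> Spectrum:
    """Standard pre-networking filter chain: precursor window then
    top-N-per-window."""
    return filter_window_top_n(
        filter_precursor_window(s, precursor_half_window_da),
        top_n=top_n, window_da=window_da)


def _candidate_pairs(mz_a, mz_b, frag_tol_da, delta):
    """(i, j) fragment index pairs within tolerance, direct and (when delta
    is not None) precursor-shifted; deduplicated."""
    pairs = set()
    for shift in ([0.0] if delta is None else [0.0, delta]):
        j_lo = np.searchsorted(mz_b, mz_a - shift - frag_tol_da)
        j_hi = np.searchsorted(mz_b, mz_a - shift + frag_tol_da,
                               side="right")
        for i, (lo, hi) in enumerate(zip(j_lo, j_hi)):
            for j in range(lo, hi):
                pairs.add((i, j))
    return sorted(pairs)


def _match_pairs_exact(pairs, weights):
    """Maximum-total-weight one-to-one subset of candidate pairs via the
    rectangular assignment solver (non-candidates weigh zero)."""
    rows = sorted({i for i, _ in pairs})
    cols = sorted({j for _, j in pairs})
    ri = {r: k for k, r in enumerate(rows)}
    ci = {c: k for k, c in enumerate(cols)}
    w = np.zeros((len(rows), len(cols)))
    for (i, j), wt in zip(pairs, weights):
        w[ri[i], ci[j]] = wt
    r_idx, c_idx = linear_sum_assignment(w, maximize=True)
    chosen = []
    pair_w = dict(zip(pairs, weights))
    for r, c in zip(r_idx, c_idx):
        p = (rows[r], cols[c])
        if p in pair_w and pair_w[p] > 0:
            chosen.append((p, pair_w[p]))
    return chosen


def _match_pairs_greedy(pairs, weights):
    order = sorted(range(len(pairs)),
                   key=lambda k: (-weights[k], pairs[k]))
    used_a, used_b = set(), set()
    chosen = []
    for k in order:
        i, j = pairs[k]
        if i in used_a or j in used_b or weights[k] <= 0:
            continue
        used_a.add(i)
        used_b.add(j)
        chosen.append(((i, j), weights[k]))
    return chosen


def cosine_score(a: Spectrum, b: Spectrum, frag_tol_da: float = 0.02,
                 shifted: bool = False,
                 transform: str = "sqrt") -> tuple[float, int]:
    """(Modified) cosine similarity between two MS2 spectra.

    Intensities are square-root transformed (``transform='identity'``
    disables this). Candidate fragment pairs lie within ``frag_tol_da``
    directly, plus — when ``shifted`` — offset by the precursor mass
    difference. The score is the maximum-weight one-to-one matching weight
    sum over the product of the two spectral norms; exact assignment up to
    ``EXACT_ASSIGNMENT_LIMIT`` candidate pairs, greedy beyond.

    Returns ``(cosine in [0, 1], n_matched)``.
    """
    _require_ms2(a, "cosine_score")
    _require_ms2(b, "cosine_score")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    if transform == "sqrt":
        ia = np.sqrt(a.intensity)
        ib = np.sqrt(b.intensity)
    elif transform == "identity":
        ia = a.intensity.astype(np.float64)
        ib = b.intensity.astype(np.float64)
    else:
        raise ValueError(f"unknown intensity transform '{transform}'")
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    if norm == 0:
        return 0.0, 0
    delta = (a.precursor_mz - b.precursor_mz) if shifted else None
    if delta is not None and abs(delta) <= frag_tol_da:
        delta = None  # shifted pairing collapses onto the direct one
    pairs = _candidate_pairs(a.mz, b.mz, frag_tol_da, delta)
    if not pairs:
        return 0.0, 0
    weights = [float(ia[i] * ib[j]) for i, j in pairs]
    if len(pairs) <= EXACT_ASSIGNMENT_LIMIT:
        chosen = _match_pairs_exact(pairs, weights)
    else:
        chosen = _match_pairs_greedy(pairs, weights)
    score = sum(w for _, w in chosen) / norm
    return min(float(score), 1.0), len(chosen)


def brute_force_cosine(a: Spectrum, b: Spectrum, frag_tol_da: float = 0.02,
                       shifted: bool = False,
                       transform: str = "sqrt") -> tuple[float, int]:
    """Exhaustive-enumeration reference matcher (test oracle).

    Enumerates every one-to-one subset of candidate pairs and returns the
    best score; exponential, only usable on toy spectra.
    """
    _require_ms2(a, "brute_force_cosine")
    _require_ms2(b, "brute_force_cosine")
    if a.n_peaks == 0 or b.n_peaks == 0:
        return 0.0, 0
    ia = np.sqrt(a.intensity) if transform == "sqrt" else a.intensity
    ib = np.sqrt(b.intensity) if transform == "sqrt" else b.intensity
    norm = float(np.linalg.norm(ia) * np.linalg.norm(ib))
    if norm == 0:
        return 0.0, 0
    delta = (a.precursor_mz - b.precursor_mz) if shifted else None
    if delta is not None and abs(delta) <= frag_tol_da:
        delta = None
    pairs = _candidate_pairs(a.mz, b.mz, frag_tol_da, delta)
    pairs = [p for p in pairs if ia[p[0]] * ib[p[1]] > 0]
    best = (0.0, 0)

    def recurse(idx, used_a, used_b, total, count):
        nonlocal best
        if total > best[0] or (total == best[0] and count > best[1]):
            best = (total, count)
        for k in range(idx, len(pairs)):
            i, j = pairs[k]
            if i in used_a or j in used_b:
                continue
            recurse(k + 1, used_a | {i}, used_b | {j},
                    total + float(ia[i] * ib[j]), count + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return min(best[0] / norm, 1.0), best[1]
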