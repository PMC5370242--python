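# Methods

This note documents the models and procedures implemented in
`plantcarto`, the defaults and why they hold, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pipeline model

The package treats a whole-plant spatial metabolomics study as five
stages over files: MS1 feature finding, MS/MS molecular networking,
spectral-library annotation, presence/absence statistics, and 3D ion-map
export. All retention times are normalized to seconds on read (mzML
minute-valued scan times are converted), and every stage is a pure
function of its input files and the configuration, so composed
subcommands and the single `run` entry point produce byte-identical
artifacts.

### Feature finding

* **Mass detection.** Centroids with intensity ≥ `noise_threshold`
  (2.0×10⁶) are kept. Profile spectra are centroided at local maxima with
  a 3-point parabolic fit in m/z. The threshold is applied to the
  centroided intensity; whether a vendor threshold refers to profile or
  centroid height is instrument lore, and the centroided reading is the
  reproducible one.
* **Chromatogram building.** Centroids chain scan-to-scan to the nearest
  open trace whose running intensity-weighted center lies within
  `mz_tol_ppm` (10 ppm), one centroid per trace per scan, assigned
  best-ppm-first. Chains spanning < 0.3 s are noise and dropped. Traces
  stay open across temporal gaps; deconvolution later splits at gaps
  wider than 5× the median scan spacing, so a metabolite that stops
  eluting and a later isobar do not merge into one peak.
* **Deconvolution.** Baseline cutoff: contiguous segments above
  `baseline` (1.0×10⁴) become peaks; segments wider than 120 s are split
  recursively at their deepest interior minimum (the exact splitting rule
  of the historical implementations is undocumented; deepest-minimum
  recursion is this package's choice — it is deterministic and
  idempotent). Area is the trapezoidal integral of the segment in
  intensity·seconds; a pure Gaussian of height h and width σ integrates
  to h·σ·√(2π) within 2% at the default 2 Hz sampling, which the test
  suite asserts. Peaks near the detection threshold lose tail area to
  truncation (the trace only exists where centroids passed the mass
  detector); this mirrors real threshold-limited data and is why
  recovery criteria are presence-based, not area-based.
* **Isotope removal.** Partners at +k·1.003355/z Da (k ≤ 3, z ≤
  `max_charge`) within 10 ppm / 10 s and not exceeding the parent's area
  are removed; the lowest-m/z chain member survives. No averagine
  intensity model is applied — the source workflow states only that
  isotope peaks were removed.
* **Alignment.** Samples in lexicographic id order; each feature joins
  the open row minimizing (Δppm/tol)² + (Δrt/tol)² against the row's
  running area-weighted consensus, ties to the lower row index, one
  feature per sample per row (the loser of a collision starts a new
  row). This makes alignment independent of scan order within runs and
  of dictionary iteration order. No retention-time warping is applied;
  the workflow being modeled aligns with fixed tolerances only.

### Spectral processing and networking

* Filters: peaks within ±17 Da of the precursor are removed (boundary
  inclusive); then a peak survives only if it ranks in the top 6 by
  intensity within the 50 Da window centered on itself (ties toward
  lower m/z). Centering windows on peaks rather than fixed bins avoids
  bin-boundary artifacts; both filters are idempotent.
* Cosine: intensities are square-root transformed (configurable to
  identity). Candidate fragment pairs lie within 0.02 Da directly, plus
  — for the modified cosine — within 0.02 Da of the precursor mass
  difference. The matcher solves the exact maximum-weight one-to-one
  assignment (rectangular Hungarian) for up to 32 candidate pairs and
  falls back to greedy descending weight above that; the test suite
  enforces equality with exhaustive enumeration on small spectra. The
  modified cosine is used for network edges (it links analogs differing
  by one modification), the plain cosine for clustering and library
  search (which target identical molecules).
* Clustering: a single deterministic greedy pass over spectra sorted by
  (precursor m/z, sample, scan); a spectrum joins the first cluster
  within 0.02 Da precursor whose consensus it matches at cosine ≥ 0.7,
  else seeds a new cluster. Consensus peaks are intensity-weighted mean
  m/z with summed intensities, merged at 0.02 Da, and re-filtered with
  the top-6/50 Da rule after each merge (re-filtering after merge is
  unspecified upstream; re-applying keeps the density invariant).
  Clusters with fewer than 2 members are discarded. The iterative
  multi-round sweep of the original clustering tool is deliberately
  simplified to one pass: the properties that matter downstream
  (determinism, cluster recovery) are tested directly.
* Edges require modified cosine ≥ 0.7 and ≥ 4 matched peaks
  ("more than 4" is read as the inclusive ≥ 4 convention of the
  workflow's parameter; the literal ≥ 5 reading is a config switch),
  then mutual top-10 pruning: an edge survives only if it ranks in both
  endpoints' top 10 by cosine. Blank subtraction removes nodes with
  *any* member scan from a blank sample (conservative; an
  exclusive-membership mode is provided, since the source text does not
  fix which was used).
* Library search reports the best-cosine record within 0.02 Da
  precursor, cosine ≥ 0.7, ≥ 4 matched peaks, |precursor error| ≤ 20
  ppm.

### Statistics and mapping

* TIC normalization divides each sample column by its total area.
  Binarization (area > 0) is unaffected by it, so TIC-normalize →
  Jaccard equals Jaccard alone; both steps are implemented faithfully
  and the no-op is asserted as an invariant rather than "fixed" by
  substituting a different metric.
* PCoA: Gower double centering of −½d², symmetric eigendecomposition,
  axes = eigenvectors × √eigenvalue for positive eigenvalues only;
  negative eigenvalues are reported and uncorrected (no
  Cailliez/Lingoes). Sign convention: each axis's largest-magnitude
  coordinate is positive, making output stable across eigensolver
  backends. The implementation is cross-checked against scikit-bio in
  the tests, never delegated to it.
* Venn counts bucket each feature (or MS/MS node) by the exact set of
  tissue groups where it is present; regions sum to the union count.
* The 'ili table holds one row per non-blank sample (name, X, Y, Z,
  radius, then one column per feature labelled `mz_<4dp>_rt_<1dp>s`),
  raw areas by default because 'ili applies its own linear color
  scaling at render time. Coordinates are validated against the mesh
  bounding box expanded by one spot radius and are assumed to be in
  mesh model units. Missing cells are written as 0 (the viewer maps
  numeric columns), numbers at full `repr` precision, RFC-4180 quoting,
  LF endings — rewriting the same table is byte-identical.

## Synthetic world

`make_study(seed)` states the default world: 2 plants × 4 tissues
(stem, leaf, flower, fruit) × 6 spots on procedural ellipsoid-union
meshes, a shared 60-metabolite panel of which 10% (6, including the
internal standard) occur in all tissues, ~20% in tissue pairs and the
rest in exactly one tissue; two 3-member analog families (common
fragment template, constant +14.0157 Da precursor ladder, half the
fragments shifted); one fruit marker exclusive to each plant; and two
blank runs. Peak heights are log-uniform 10⁷–10⁸ (internal standard
fixed at 5×10⁷), elution σ uniform 1–4 s on a 600 s gradient sampled at
2 Hz, +1 isotopes at an m/z-scaled ratio, multiplicative log-normal
intensity noise of width 1/SNR (default SNR 100), spot-to-spot
biological variation log-normal with 20% CV, and top-5 DDA with
exclusion after 3 selections released after 20 s.

Idealizations a green test does **not** speak to: background/solvent
ions are planted in blank runs only (so that the all-tissue Venn region
equals the stated core exactly — real solvent background appears in
every injection and must be handled by the blank filters); metabolite
m/z values are separated by ≥ 3.2 Da, so the aligner is never stressed
by near-isobars; there is no retention-time drift between runs, no
adducts, no in-source fragmentation, and no isotope fine structure.
Recovery and localization results on this world demonstrate correctness
of the machinery, not performance on crowded real chromatograms.

## Degenerate inputs and tie-breaks

Empty spectra score (0, 0); two empty presence sets are at Jaccard
distance 0; an all-zero sample column raises a degenerate-sample error
naming the sample; runs with zero MS1 scans are rejected on read; MS2
scans without a precursor are format errors. All orderings that affect
output (alignment candidates, edge ranking, cluster seeds, library
ties) have explicit deterministic tie-breaks, and all generator
randomness flows from one integer seed through named child streams.

## Known limitations

Single-pass clustering can, in principle, split a compound across nodes
when early members are atypical (real studies show the same redundancy).
The greedy matcher above 32 candidate pairs is an approximation — with
top-6/50 Da filtered spectra the exact solver handles practically all
pairs. Vendor raw formats, mzTab, gap-filling, adduct grouping, RT
warping, negative-eigenvalue corrections and interactive rendering are
out of scope.
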