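import numpy as np
import pytest

from plantcarto import pipeline, synth_data
from plantcarto.config import PipelineConfig
from plantcarto.models import Spectrum


def make_spectrum(mz, intensity, precursor=None, level=2, rt=0.0,
                  scan_id="s1", sample_id="sample"):
    return Spectrum(scan_id=scan_id, ms_level=level, rt_seconds=rt,
                    mz=np.asarray(mz, dtype=float),
                    intensity=np.asarray(intensity, dtype=float),
                    precursor_mz=precursor, sample_id=sample_id)


def random_ms2(rng, n_peaks=None, precursor=None):
    n = int(n_peaks if n_peaks is not None else rng.integers(1, 9))
    mz = np.sort(rng.uniform(50.0, 450.0, size=n))
    intensity = rng.uniform(1.0, 100.0, size=n)
    prec = float(precursor if precursor is not None
                 else rng.uniform(460.0, 500.0))
    return make_spectrum(mz, intensity, precursor=prec)


@pytest.fixture(scope="session")
def small_study():
    """Reduced synthetic study shared by unit tests (fast)."""
    return synth_data.make_study(7, spots_per_tissue=2, n_metabolites=24)


@pytest.fixture(scope="session")
def small_runs(small_study):
    return synth_data.render_runs(small_study.truth)


@pytest.fixture(scope="session")
def e2e(tmp_path_factory):
    """Default-scale synthetic study pushed through the full pipeline once;
    shared by the end-to-end and acceptance tests."""
    root = tmp_path_factory.mktemp("e2e")
    cfg = PipelineConfig(input_dir=str(root / "in"),
                         output_dir=str(root / "out"), seed=1,
                         library_path=str(root / "in" / "library.mgf"))
    pipeline.stage_simulate(cfg)
    manifest = pipeline.run_pipeline(cfg)
    truth = synth_data.GroundTruth.load_json(root / "in" / "truth.json")
    return {"cfg": cfg, "root": root, "manifest": manifest, "truth": truth,
            "report": synth_data.truth_report(truth)}
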