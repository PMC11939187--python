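import numpy as np
import pytest

from serumml import synth
from serumml.peaks import FeatureMatrix
from serumml.pipeline import build_feature_matrix
from serumml.screening import differential_test, volcano_filter

ACCEPTANCE_SEED = 20230269


def make_matrix(values, labels, feature_mzs=None, sample_ids=None,
                missing=None) -> FeatureMatrix:
    """Hand-built feature matrix for unit tests (shifted to non-negative,
    preserving all orderings, since the container stores relative areas)."""
    values = np.asarray(values, float)
    if values.min() < 0:
        values = values - values.min()
    n, d = values.shape
    return FeatureMatrix(
        feature_mzs=np.asarray(feature_mzs if feature_mzs is not None
                               else 1000.0 + 100.0 * np.arange(d), float),
        values=values,
        sample_ids=list(sample_ids) if sample_ids is not None
        else [f"s{i}" for i in range(n)],
        labels=np.asarray(labels, dtype=str),
        missing=missing,
        imputed=True,
    )


@pytest.fixture(scope="session")
def paper_cohort():
    """Full default cohort run once: feature matrix, truth and volcano calls."""
    cfg = synth.paper_default_config(seed=ACCEPTANCE_SEED)
    spectra, labels, truth = synth.generate_cohort(cfg)
    fm = build_feature_matrix(spectra)
    dt = differential_test(fm)
    up, down = volcano_filter(dt)
    return {"fm": fm, "truth": truth, "table": dt, "up": up, "down": down,
            "config": cfg}


@pytest.fixture(scope="session")
def small_cohort():
    """Small planted-signal cohort for fast end-to-end checks."""
    cfg = synth.SynthConfig(n_cancer=25, n_healthy=25, replicates_per_sample=3,
                            n_peaks=40, n_up=5, n_down=7, seed=11)
    spectra, labels, truth = synth.generate_cohort(cfg)
    fm = build_feature_matrix(spectra)
    return {"spectra": spectra, "labels": labels, "truth": truth, "fm": fm,
            "config": cfg}
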