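import numpy as np
import pytest

from micnet.io import ExpressionMatrix
from micnet.simulate import Marker, Module, SyntheticSpec, generate


@pytest.fixture(scope="session")
def marker_cohort():
    """Balanced cohort with strong planted markers (delta/sigma = 3)."""
    spec = SyntheticSpec(
        n_tumor=100, n_normal=100, p_mirna=30, p_protein=12,
        noise_sd=1.0, zero_rate=0.0, seed=42,
    )
    spec.planted_markers = [Marker(f, 3.0) for f in spec.mirna_names()[:4]] + [
        Marker(f, 3.0) for f in spec.protein_names()[:3]
    ]
    mirna, protein, truth = generate(spec)
    return mirna, protein, truth


@pytest.fixture(scope="session")
def module_cohort():
    """Cohort with a normal-only cross-layer module around one miRNA hub."""
    spec = SyntheticSpec(
        n_tumor=150, n_normal=100, p_mirna=10, p_protein=5,
        noise_sd=1.0, zero_rate=0.0, seed=7,
    )
    spec.planted_modules = [
        Module(("mir-001", "prot-001", "prot-002", "prot-003"), "normal", 3.0)
    ]
    mirna, protein, truth = generate(spec)
    return mirna, protein, truth


def toy_matrix(values, layer="miRNA", condition=None, samples=None, features=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = samples or [f"TCGA-AA-{i:04d}-01A" for i in range(1, n + 1)]
    condition = condition or ["tumor"] * n
    features = features or [f"f{j}" for j in range(1, p + 1)]
    return ExpressionMatrix(layer, samples, features, values, condition)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(mean=2.0, size=(6, 4))
    return toy_matrix(vals, condition=["tumor"] * 3 + ["normal"] * 3)
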