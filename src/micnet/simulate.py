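"""Synthetic two-layer expression cohorts with planted ground truth.

The generator emulates a paired tumor/normal cohort measured on two
molecular layers (miRNA and protein), written in the same CSV dialects the
loaders accept. It plants exactly the two kinds of signal the analysis
pipeline is built to detect:

* **markers** — features whose log-expression mean shifts between tumor
  and normal samples (fuel for the feature selectors);
* **modules** — feature blocks, optionally spanning both layers, that
  share a latent factor in one condition only, creating condition-specific
  co-expression edges (fuel for the MIC network stage and node scoring).

Log-expression for sample *i*, feature *j* is

    log v_ij = baseline_j + delta_j * 1[tumor_i] + sum_m lambda_m z_im + eps_ij

with ``z_im ~ N(0,1)`` shared per patient within a module's active
condition and ``eps_ij ~ N(0, noise_sd^2)``; expression is ``exp`` of
that. A configurable fraction of non-planted features is contaminated
with exact zeros to exercise the zero-noise filter. Class imbalance
defaults to roughly 10:1 tumor:normal, the regime of paired TCGA-style
breast-cancer cohorts, so minority up-sampling is exercised by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import NORMAL, TUMOR, ExpressionMatrix, write_mirna_table, write_protein_table

__all__ = ["Marker", "Module", "SyntheticSpec", "GroundTruth", "generate", "write_fixtures", "default_spec"]


@dataclass(frozen=True)
class Marker:
    """A feature with mean log-expression shift ``delta`` in tumor samples."""

    feature: str
    delta: float = 2.0


@dataclass(frozen=True)
class Module:
    """A correlated block active in one condition only.

    ``features`` may mix miRNA and protein names, in which case the module
    plants cross-layer dependence; ``loading`` is the latent-factor weight
    shared by all members.
    """

    features: tuple[str, ...]
    condition: str = NORMAL
    loading: float = 3.0

    def __post_init__(self):
        if self.condition not in (TUMOR, NORMAL):
            raise ValueError(f"module condition must be tumor/normal, got {self.condition!r}")
        if self.loading <= 0:
            raise ValueError("module loading must be positive")


@dataclass
class SyntheticSpec:
    """Cohort layout and planted structure for one synthetic dataset."""

    n_tumor: int = 300
    n_normal: int = 30
    p_mirna: int = 60
    p_protein: int = 25
    planted_markers: list[Marker] = field(default_factory=list)
    planted_modules: list[Module] = field(default_factory=list)
    noise_sd: float = 1.0
    zero_rate: float = 0.0
    baseline: float = 5.0
    seed: int = 0

    def mirna_names(self) -> list[str]:
        return [f"mir-{i + 1:03d}" for i in range(self.p_mirna)]

    def protein_names(self) -> list[str]:
        return [f"prot-{i + 1:03d}" for i in range(self.p_protein)]

    def validate(self) -> None:
        if self.n_tumor < 1 or self.n_normal < 1:
            raise ValueError("need at least one sample per condition")
        if not (0 <= self.zero_rate < 1):
            raise ValueError("zero_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        declared = set(self.mirna_names()) | set(self.protein_names())
        for mk in self.planted_markers:
            if mk.feature not in declared:
                raise ValueError(f"planted marker {mk.feature!r} not in declared features")
        for mod in self.planted_modules:
            unknown = set(mod.features) - declared
            if unknown:
                raise ValueError(f"module features not declared: {sorted(unknown)}")
            per_layer = [f for f in mod.features if f.startswith("mir-")]
            if len(per_layer) > self.p_mirna or len(mod.features) - len(per_layer) > self.p_protein:
                raise ValueError("module larger than its layer")


@dataclass
class GroundTruth:
    """What was planted, and which edges the network stage should recover."""

    markers: dict[str, float]
    modules: list[Module]

    def marker_names(self, layer: str | None = None) -> list[str]:
        names = sorted(self.markers)
        if layer == "miRNA":
            return [f for f in names if f.startswith("mir-")]
        if layer == "protein":
            return [f for f in names if f.startswith("prot-")]
        return names

    def expected_edges(self, condition: str) -> set[frozenset]:
        """All within-module pairs (intra- and cross-layer) active in ``condition``."""
        edges: set[frozenset] = set()
        for mod in self.modules:
            if mod.condition != condition:
                continue
            feats = list(mod.features)
            for i in range(len(feats)):
                for j in range(i + 1, len(feats)):
                    edges.add(frozenset((feats[i], feats[j])))
        return edges

    def to_frame(self) -> pd.DataFrame:
        rows = [("marker", f, str(d)) for f, d in sorted(self.markers.items())]
        for m_idx, mod in enumerate(self.modules):
            for f in mod.features:
                rows.append((f"module-{m_idx + 1}-{mod.condition}", f, str(mod.loading)))
        return pd.DataFrame(rows, columns=["role", "entity", "value"])


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Draw one paired two-layer cohort from ``spec``.

    Both layers cover the same patients: every patient contributes a tumor
    sample and the first ``n_normal`` patients additionally contribute a
    paracancerous normal sample, mimicking matched solid-tissue-normal
    controls. Identical seeds give identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_patients = spec.n_tumor
    patients = [f"TCGA-SY-{i + 1:04d}" for i in range(n_patients)]
    samples = [(p, TUMOR) for p in patients] + [(p, NORMAL) for p in patients[: spec.n_normal]]

    mirna_feats = spec.mirna_names()
    prot_feats = spec.protein_names()
    markers = {mk.feature: mk.delta for mk in spec.planted_markers}

    # latent module factors, one value per sample, zero outside the active condition
    factors = []
    for mod in spec.planted_modules:
        z = rng.normal(size=len(samples))
        active = np.array([c == mod.condition for _, c in samples], dtype=float)
        factors.append(z * active)

    def layer_values(feats: list[str]) -> np.ndarray:
        n, p = len(samples), len(feats)
        log_v = spec.baseline + rng.normal(scale=spec.noise_sd, size=(n, p))
        tumor_ind = np.array([c == TUMOR for _, c in samples], dtype=float)
        for j, f in enumerate(feats):
            if f in markers:
                log_v[:, j] += markers[f] * tumor_ind
            for mod, z in zip(spec.planted_modules, factors):
                if f in mod.features:
                    log_v[:, j] += mod.loading * z
        return np.exp(log_v)

    vals_mirna = layer_values(mirna_feats)
    vals_prot = layer_values(prot_feats)

    planted = set(markers) | {f for mod in spec.planted_modules for f in mod.features}
    _contaminate_zeros(vals_mirna, mirna_feats, planted, spec.zero_rate, rng)
    _contaminate_zeros(vals_prot, prot_feats, planted, spec.zero_rate, rng)

    sample_ids = [f"{p}-01A" if c == TUMOR else f"{p}-11A" for p, c in samples]
    condition = [c for _, c in samples]
    mirna = ExpressionMatrix("miRNA", sample_ids, mirna_feats, vals_mirna, condition)
    protein = ExpressionMatrix("protein", list(sample_ids), prot_feats, vals_prot, list(condition))
    return mirna, protein, GroundTruth(markers, list(spec.planted_modules))


def _contaminate_zeros(values, feats, planted, zero_rate, rng) -> None:
    """Zero out scattered entries of ~zero_rate of the non-planted features."""
    candidates = [j for j, f in enumerate(feats) if f not in planted]
    n_contam = int(round(zero_rate * len(feats)))
    n_contam = min(n_contam, len(candidates))
    if n_contam == 0:
        return
    chosen = rng.choice(candidates, size=n_contam, replace=False)
    n = values.shape[0]
    for j in chosen:
        hits = rng.integers(1, max(2, n // 10))
        rows = rng.choice(n, size=hits, replace=False)
        values[rows, j] = 0.0


def write_fixtures(mirna: ExpressionMatrix, protein: ExpressionMatrix, out_dir,
                   truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write a generated cohort in both on-disk dialects (plus ground truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna": out / "mirna_expression.csv",
        "protein": out / "protein_expression.csv",
    }
    write_mirna_table(mirna, paths["mirna"])
    write_protein_table(protein, paths["protein"])
    if truth is not None:
        paths["truth"] = out / "ground_truth.csv"
        truth.to_frame().to_csv(paths["truth"], index=False)
    return paths


def default_spec(seed: int = 0) -> SyntheticSpec:
    """The package's reference cohort: paired two-layer data at ~10:1 imbalance.

    Plants six miRNA and four protein markers (delta = 2 log-units against
    unit noise), one normal-specific miRNA module, one normal-specific
    cross-layer module, and one weaker tumor-specific miRNA module, so the
    normal-tissue networks are denser than the tumor networks — the regime
    the scoring stage is designed for. A quarter of the non-planted
    features carry zero contamination for the noise filter.
    """
    spec = SyntheticSpec(seed=seed)
    mir = spec.mirna_names()
    prot = spec.protein_names()
    # module members also get a milder marginal shift: differentially
    # co-expressed molecules in real cohorts are usually differentially
    # expressed too, and it keeps them in the selectors' candidate pool
    spec.planted_markers = (
        [Marker(f, 2.0) for f in mir[:6]]
        + [Marker(f, 2.0) for f in prot[:4]]
        + [Marker(f, 1.0) for f in mir[6:20]]
        + [Marker(f, 1.0) for f in prot[4:7]]
    )
    spec.planted_modules = [
        Module(tuple(mir[6:12]), NORMAL, 3.0),
        Module(tuple(mir[12:16] + prot[4:7]), NORMAL, 3.0),
        Module(tuple(mir[16:20]), TUMOR, 2.0),
    ]
    spec.zero_rate = 0.25
    return spec
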