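"""Synthetic FC cohorts with known class structure.

Real FC matrices are sample Pearson correlations of regional time series, so
the generator works the same way: each class has a population correlation
matrix; each subject gets a jittered copy of their class matrix (projected
back to a valid correlation matrix), T latent Gaussian time points are drawn
from it, and the subject's FC is the sample correlation of those draws.
Sampling noise therefore scales as ~(1-r^2)/sqrt(T), exactly as in real
resting-state FC, which keeps the thresholding and classification behaviour
downstream realistic.

Class differences are planted on a chosen fraction of edges as a shift
``effect_size`` (delta-r) in population correlation.  With ``effect_size=0``
the classes are exchangeable: phenotype distributions are class-independent
by default, so nothing separates the classes and downstream classifiers
should sit at chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .data_model import Cohort, FCMatrix, Phenotype

logger = logging.getLogger(__name__)

__all__ = ["SimSpec", "PhenotypeModel", "GroundTruth", "generate_cohort",
           "worked_example_cohort", "nearest_correlation"]


class ParameterError(ValueError):
    """An infeasible simulation parameter (e.g. correlations leaving (-1,1))."""


@dataclass
class PhenotypeModel:
    """Per-class phenotype distributions.

    ``age_mean``/``age_sd`` may be scalars (shared across classes) or one
    value per class; ages are truncated to [5, 90] by resampling.  ``p_male``
    is the Bernoulli probability of sex M.  ``site_levels`` draws a site
    uniformly when given.  Defaults are class-independent so that a zero
    effect size yields a true null cohort.
    """

    age_mean: float | Sequence[float] = 30.0
    age_sd: float | Sequence[float] = 10.0
    p_male: float | Sequence[float] = 0.5
    site_levels: Optional[Sequence[str]] = None

    def _per_class(self, value, c: int) -> float:
        if np.isscalar(value):
            return float(value)
        return float(value[c])

    def sample(self, rng: np.random.Generator, class_index: int,
               subject_id: str, label: str) -> Phenotype:
        mean = self._per_class(self.age_mean, class_index)
        sd = self._per_class(self.age_sd, class_index)
        age = rng.normal(mean, sd)
        while not (5.0 <= age <= 90.0):
            age = rng.normal(mean, sd)
        sex = "M" if rng.random() < self._per_class(self.p_male, class_index) else "F"
        site = None
        if self.site_levels is not None:
            site = str(self.site_levels[rng.integers(len(self.site_levels))])
        return Phenotype(subject_id=subject_id, age_years=float(round(age, 2)),
                         sex=sex, label=label, site=site)


@dataclass
class SimSpec:
    """Parameters of a simulated FC cohort.

    Defaults describe the standard study conditions used throughout the
    package's tests and examples: N=20 regions, two balanced classes of 50,
    T=150 time points, a 30%-density positive backbone at correlation ~0.3,
    an effect of delta-r=0.4 planted on 5% of edges, and mild subject-level
    jitter (sd 0.05) on the latent covariance.
    """

    n_regions: int = 20
    n_per_class: Sequence[int] = (50, 50)
    n_timepoints: int = 150
    base_density: float = 0.3
    base_strength: float = 0.3
    effect_edges: float = 0.05
    effect_size: float = 0.4
    noise_sd: float = 0.05
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    label_names: Optional[Sequence[str]] = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 30:
            raise ParameterError("n_timepoints must be >= 30 for stable correlations")
        if self.n_regions < 2:
            raise ParameterError("need at least 2 regions")
        if len(self.n_per_class) < 2:
            raise ParameterError("need at least 2 classes")
        if not (0.0 <= self.base_density <= 1.0):
            raise ParameterError("base_density must be in [0, 1]")
        if not (0.0 <= self.effect_edges <= 1.0):
            raise ParameterError("effect_edges must be in [0, 1]")

    def labels(self) -> list[str]:
        if self.label_names is not None:
            if len(self.label_names) != len(self.n_per_class):
                raise ParameterError("label_names length must match n_per_class")
            return list(self.label_names)
        if len(self.n_per_class) == 2:
            return ["control", "patient"]
        return ["control"] + [f"patient_{i}" for i in range(1, len(self.n_per_class))]


@dataclass
class GroundTruth:
    """What was planted: per-class population matrices and the effect edges."""

    population_matrices: list[np.ndarray]
    effect_edge_index: np.ndarray  # (n_effect, 2) upper-triangle (i, j) pairs
    backbone_edge_index: np.ndarray
    spec: SimSpec


def nearest_correlation(m: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix into a valid correlation matrix.

    Eigenvalues are clipped at ``eig_floor``, then the matrix is rescaled to
    unit diagonal.  Off-diagonal magnitudes are finally clipped fractionally
    below 1 so sample correlation is always defined.
    """
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    if w.min() < eig_floor:
        w = np.clip(w, eig_floor, None)
        m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    np.fill_diagonal(m, 1.0)
    off = ~np.eye(m.shape[0], dtype=bool)
    m[off] = np.clip(m[off], -0.999, 0.999)
    return 0.5 * (m + m.T)


def _population_matrices(spec: SimSpec, rng: np.random.Generator
                         ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    n = spec.n_regions
    iu = np.triu_indices(n, k=1)
    n_edges = iu[0].size

    # positive backbone: base_density of edges at base_strength, rest near 0
    n_backbone = int(round(spec.base_density * n_edges))
    order = rng.permutation(n_edges)
    backbone = order[:n_backbone]
    base_vals = rng.normal(0.0, 0.03, size=n_edges)
    base_vals[backbone] = spec.base_strength + rng.normal(0.0, 0.05, size=n_backbone)

    base = np.eye(n)
    base[iu] = base_vals
    base = base + np.triu(base, k=1).T

    # planted effects: delta-r added for each non-reference class on its own
    # random subset of edges, sign chosen to keep correlations inside (-1,1)
    n_effect = max(1, int(round(spec.effect_edges * n_edges))) if spec.effect_size != 0 else 0
    populations = []
    effect_rows: list[np.ndarray] = []
    for c in range(len(spec.n_per_class)):
        mat = base.copy()
        if c > 0 and n_effect > 0:
            chosen = rng.choice(n_edges, size=n_effect, replace=False)
            effect_rows.append(np.column_stack([iu[0][chosen], iu[1][chosen]]))
            for e in chosen:
                i, j = iu[0][e], iu[1][e]
                shifted = mat[i, j] + spec.effect_size
                if abs(shifted) >= 1.0:
                    shifted = mat[i, j] - spec.effect_size
                if abs(shifted) >= 1.0:
                    raise ParameterError(
                        f"effect_size {spec.effect_size} pushes correlation at "
                        f"({i},{j}) outside (-1, 1)")
                mat[i, j] = mat[j, i] = shifted
        populations.append(nearest_correlation(mat))
    effect_index = (np.vstack(effect_rows) if effect_rows
                    else np.empty((0, 2), dtype=int))
    backbone_index = np.column_stack([iu[0][backbone], iu[1][backbone]])
    return populations, effect_index, backbone_index


def generate_cohort(spec: SimSpec) -> tuple[Cohort, GroundTruth]:
    """Simulate a cohort of sample-correlation FC matrices.

    Deterministic given ``spec.seed``: the same spec yields a bit-identical
    cohort.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    populations, effect_index, backbone_index = _population_matrices(spec, rng)
    labels = spec.labels()
    region_ids = [f"region_{i:03d}" for i in range(spec.n_regions)]

    subjects = []
    sid = 0
    for c, n_c in enumerate(spec.n_per_class):
        for _ in range(n_c):
            subject_id = f"sub-{sid:04d}"
            sid += 1
            # subject-level jitter on the latent covariance, then PSD repair
            jitter = rng.normal(0.0, spec.noise_sd, size=(spec.n_regions,) * 2)
            subj_cov = populations[c] + 0.5 * (jitter + jitter.T)
            np.fill_diagonal(subj_cov, 1.0)
            subj_cov = nearest_correlation(subj_cov)
            chol = np.linalg.cholesky(subj_cov + 1e-10 * np.eye(spec.n_regions))
            ts = rng.standard_normal((spec.n_timepoints, spec.n_regions)) @ chol.T
            fc_values = np.corrcoef(ts, rowvar=False)
            fc_values = np.clip(0.5 * (fc_values + fc_values.T), -1.0, 1.0)
            np.fill_diagonal(fc_values, 1.0)
            fc = FCMatrix(values=fc_values, region_ids=region_ids)
            phen = spec.phenotype_model.sample(rng, c, subject_id, labels[c])
            subjects.append((fc, phen))

    cohort = Cohort(subjects=subjects, label_names=labels,
                    provenance=f"synthetic:fcnets seed={spec.seed}")
    truth = GroundTruth(population_matrices=populations,
                        effect_edge_index=effect_index,
                        backbone_edge_index=backbone_index, spec=spec)
    logger.info("generated synthetic cohort: %d subjects, N=%d, classes=%s",
                cohort.n_subjects, spec.n_regions, list(spec.n_per_class))
    return cohort, truth


WORKED_EXAMPLE_SEED = 20240


def worked_example_cohort() -> Cohort:
    """The repository's canonical fixture: N=20, two balanced classes of 40.

    Fixed seed; calling twice returns identical cohorts.
    """
    spec = SimSpec(n_regions=20, n_per_class=(40, 40), seed=WORKED_EXAMPLE_SEED)
    cohort, _ = generate_cohort(spec)
    return cohort
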