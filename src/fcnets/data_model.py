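"""Domain types and on-disk formats for functional-connectivity cohorts.

A *functional connectivity* (FC) matrix is the symmetric N x N matrix of
Pearson correlations between the activity time series of N brain regions.
A cohort bundles one FC matrix per subject with a phenotype row (age, sex,
optional imaging site, diagnostic label).  Cohorts live on disk as a small
YAML manifest referencing a phenotype CSV and one matrix file per subject,
stored either as ``.npy`` (bit-exact) or delimited text (human-readable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1
SEX_LEVELS = ("F", "M")  # frozen one-hot order

__all__ = [
    "FCMatrix", "Phenotype", "Cohort", "ValidationError", "StructuralError",
    "encode_phenotype", "load_cohort", "save_cohort",
]


class ValidationError(ValueError):
    """A matrix or phenotype violates a domain invariant."""


class StructuralError(ValueError):
    """Subjects within a cohort are mutually inconsistent (e.g. N mismatch)."""


@dataclass
class FCMatrix:
    """One subject's symmetric N x N correlation matrix.

    ``unit_diagonal`` is True for real FC (correlation of a region with
    itself); generator-produced matrices set it False because the embedding
    inner product yields tanh(||x_i||^2) on the diagonal.
    """

    values: np.ndarray
    region_ids: list[str] = field(default_factory=list)
    unit_diagonal: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.region_ids:
            self.region_ids = [f"region_{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def validate(self, subject_id: str = "?", tol: float = 1e-6) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"subject {subject_id}: matrix is not square: {v.shape}")
        if len(self.region_ids) != v.shape[0]:
            raise ValidationError(
                f"subject {subject_id}: {len(self.region_ids)} region ids for "
                f"{v.shape[0]} rows")
        asym = float(np.max(np.abs(v - v.T))) if v.size else 0.0
        if asym > tol:
            raise ValidationError(
                f"subject {subject_id}: asymmetric matrix (max |A - A^T| = {asym:.3g})")
        hi = float(np.max(np.abs(v)))
        if hi > 1.0 + tol:
            raise ValidationError(
                f"subject {subject_id}: correlation out of [-1, 1] "
                f"(max |value| = {hi:.3g})")
        if self.unit_diagonal:
            dev = float(np.max(np.abs(np.diag(v) - 1.0)))
            if dev > tol:
                raise ValidationError(
                    f"subject {subject_id}: diagonal deviates from 1 by {dev:.3g}")


@dataclass
class Phenotype:
    """Non-imaging covariates for one subject."""

    subject_id: str
    age_years: float
    sex: str
    label: str
    site: Optional[str] = None

    def validate(self) -> None:
        if not (0.0 <= self.age_years <= 120.0):
            raise ValidationError(
                f"subject {self.subject_id}: age {self.age_years} outside [0, 120]")
        if self.sex not in SEX_LEVELS:
            raise ValidationError(
                f"subject {self.subject_id}: sex {self.sex!r} not in {SEX_LEVELS}")
        if pd.isna(self.label) or self.label == "":
            raise ValidationError(f"subject {self.subject_id}: missing label")


@dataclass
class Cohort:
    """An ordered set of (FCMatrix, Phenotype) pairs sharing a region list."""

    subjects: list[tuple[FCMatrix, Phenotype]]
    label_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.subjects:
            n = self.subjects[0][0].n_regions
            for fc, phen in self.subjects:
                if fc.n_regions != n:
                    raise StructuralError(
                        f"subject {phen.subject_id}: N={fc.n_regions} differs from "
                        f"cohort N={n}")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_regions(self) -> int:
        if not self.subjects:
            raise StructuralError("empty cohort has no region count")
        return self.subjects[0][0].n_regions

    @property
    def region_ids(self) -> list[str]:
        return self.subjects[0][0].region_ids

    @property
    def has_site(self) -> bool:
        return any(p.site is not None for _, p in self.subjects)

    @property
    def site_levels(self) -> Optional[list[str]]:
        """Observed site levels in lexicographic (frozen one-hot) order."""
        if not self.has_site:
            return None
        return sorted({p.site for _, p in self.subjects if p.site is not None})

    def matrices(self) -> np.ndarray:
        """Stacked (n_subjects, N, N) array of FC values."""
        return np.stack([fc.values for fc, _ in self.subjects])

    def labels(self) -> np.ndarray:
        """Integer class index per subject, following ``label_names`` order."""
        index = {name: i for i, name in enumerate(self.label_names)}
        return np.array([index[p.label] for _, p in self.subjects], dtype=np.intp)

    def phenotype_matrix(self, site_levels: Optional[Sequence[str]] = None) -> np.ndarray:
        """Stacked phenotype encodings (n_subjects, p)."""
        if site_levels is None:
            site_levels = self.site_levels
        return np.stack([
            encode_phenotype(p, site_levels).vector for _, p in self.subjects
        ])

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort(
            subjects=[self.subjects[i] for i in indices],
            label_names=list(self.label_names),
            provenance=self.provenance,
        )

    def validate(self) -> None:
        if len({p.label for _, p in self.subjects}) < 2:
            raise StructuralError("cohort has fewer than 2 distinct labels")
        for fc, phen in self.subjects:
            fc.validate(subject_id=phen.subject_id)
            phen.validate()
            if phen.label not in self.label_names:
                raise ValidationError(
                    f"subject {phen.subject_id}: label {phen.label!r} not in "
                    f"{self.label_names}")


@dataclass
class PhenotypeEncoding:
    """Bounded [0, 1] covariate vector: [age/100] ++ one-hot sex ++ one-hot site."""

    vector: np.ndarray


def encode_phenotype(p: Phenotype,
                     site_levels: Optional[Sequence[str]] = None) -> PhenotypeEncoding:
    """Encode a phenotype as the bounded vector used by both classifiers.

    Age is normalised by 100 (clamped at 1.0 for ages above 100 with a
    warning); sex and site are one-hot with frozen level order (F/M;
    lexicographic sites recorded in the manifest).  When ``site_levels`` is
    None the site block is omitted.
    """
    age = p.age_years / 100.0
    if age > 1.0:
        warnings.warn(
            f"subject {p.subject_id}: age {p.age_years} > 100, clamping encoding to 1.0")
        age = 1.0
    if age < 0.0:
        raise ValidationError(f"subject {p.subject_id}: negative age")
    parts = [np.array([age])]
    sex_vec = np.zeros(len(SEX_LEVELS))
    sex_vec[SEX_LEVELS.index(p.sex)] = 1.0
    parts.append(sex_vec)
    if site_levels is not None:
        site_vec = np.zeros(len(site_levels))
        if p.site not in site_levels:
            raise ValidationError(
                f"subject {p.subject_id}: unknown site {p.site!r}, "
                f"levels are {list(site_levels)}")
        site_vec[list(site_levels).index(p.site)] = 1.0
        parts.append(site_vec)
    return PhenotypeEncoding(vector=np.concatenate(parts))


# ---------------------------------------------------------------------------
# on-disk format


def save_cohort(cohort: Cohort, out_dir: str | Path,
                matrix_format: str = "npy") -> Path:
    """Write a cohort to ``out_dir``; returns the manifest path.

    ``matrix_format``: "npy" (bit-exact round trip) or "tsv" (delimited text,
    round trips to ~1e-16 via 17 significant digits).
    """
    if cohort.n_subjects == 0:
        raise ValueError("refusing to save an empty cohort")
    if matrix_format not in ("npy", "tsv"):
        raise ValueError(f"unknown matrix format {matrix_format!r}")
    out_dir = Path(out_dir)
    mat_dir = out_dir / "matrices"
    mat_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for fc, phen in cohort.subjects:
        fname = f"{phen.subject_id}.{matrix_format}"
        path = mat_dir / fname
        if matrix_format == "npy":
            np.save(path, fc.values)
        else:
            np.savetxt(path, fc.values, delimiter="\t", fmt="%.17g")
        rows.append({
            "subject_id": phen.subject_id,
            "age": phen.age_years,
            "sex": phen.sex,
            "site": phen.site if phen.site is not None else "",
            "label": phen.label,
            "matrix_file": f"matrices/{fname}",
        })
    pheno = pd.DataFrame(rows)
    if not cohort.has_site:
        pheno = pheno.drop(columns=["site"])
    csv_path = out_dir / "phenotypes.csv"
    pheno.to_csv(csv_path, index=False)

    manifest = {
        "format_version": MANIFEST_VERSION,
        "n_regions": cohort.n_regions,
        "region_ids": list(cohort.region_ids),
        "label_names": list(cohort.label_names),
        "site_levels": cohort.site_levels,
        "matrix_format": matrix_format,
        "phenotype_csv": "phenotypes.csv",
        "provenance": cohort.provenance,
        # generator-produced matrices have tanh(||x_i||^2) diagonals, not 1
        "unit_diagonal": all(fc.unit_diagonal for fc, _ in cohort.subjects),
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    logger.info("saved cohort with %d subjects to %s", cohort.n_subjects, out_dir)
    return manifest_path


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Load and validate a cohort from its manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("format_version") != MANIFEST_VERSION:
        raise ValueError(
            f"unsupported manifest version {manifest.get('format_version')!r}")
    root = manifest_path.parent
    pheno = pd.read_csv(root / manifest["phenotype_csv"], dtype={"subject_id": str})
    required = {"subject_id", "age", "sex", "label", "matrix_file"}
    missing_cols = required - set(pheno.columns)
    if missing_cols:
        raise ValueError(f"phenotype CSV missing columns: {sorted(missing_cols)}")
    if pheno[sorted(required - {"matrix_file"})].isna().any().any():
        bad = pheno[pheno[sorted(required - {"matrix_file"})].isna().any(axis=1)]
        raise ValidationError(
            "missing phenotype values for subjects: "
            + ", ".join(bad["subject_id"].astype(str)))

    region_ids = list(manifest["region_ids"])
    n_regions = int(manifest["n_regions"])
    subjects: list[tuple[FCMatrix, Phenotype]] = []
    for row in pheno.itertuples(index=False):
        mpath = root / row.matrix_file
        if not mpath.exists():
            raise FileNotFoundError(
                f"matrix file for subject {row.subject_id} not found: {mpath}")
        if manifest["matrix_format"] == "npy":
            values = np.load(mpath)
        else:
            values = np.loadtxt(mpath, delimiter="\t", ndmin=2)
        site = getattr(row, "site", None)
        if site is not None and (pd.isna(site) or site == ""):
            site = None
        if values.ndim != 2 or values.shape != (n_regions, n_regions):
            raise StructuralError(
                f"subject {row.subject_id}: matrix has shape {values.shape}, "
                f"manifest says N={n_regions}")
        fc = FCMatrix(values=values, region_ids=region_ids,
                      unit_diagonal=bool(manifest.get("unit_diagonal", True)))
        phen = Phenotype(subject_id=str(row.subject_id), age_years=float(row.age),
                         sex=str(row.sex), label=str(row.label), site=site)
        fc.validate(subject_id=phen.subject_id)
        phen.validate()
        subjects.append((fc, phen))

    cohort = Cohort(subjects=subjects, label_names=list(manifest["label_names"]),
                    provenance=manifest.get("provenance", ""))
    cohort.validate()
    return cohort
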