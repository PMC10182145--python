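"""In-memory containers shared across the pipeline.

The genotype side of the analysis travels as a :class:`GenotypeMatrix`
(subjects x variants dosage matrix with a missingness mask and per-variant
metadata); the phenotype side is a plain pandas DataFrame (the "cohort
table") holding one row per subject with clinical covariates and the
right-censored outcome columns ``time`` (months, > 0) and ``event`` (0/1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns every cohort table with outcomes must carry.
OUTCOME_COLUMNS = ("time", "event")

VARIANT_META_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class GenotypeMatrix:
    """Subjects x variants dosage matrix with missingness.

    Parameters
    ----------
    subject_ids : array of str
        Unique subject identifiers, one per row of ``dosage``.
    variants : pandas.DataFrame
        Per-variant metadata with columns ``variant_id``, ``chrom``,
        ``pos`` (1-based), ``ref``, ``alt`` and optionally ``info_score``
        (imputation quality in [0, 1]).
    dosage : ndarray, shape (n_subjects, n_variants)
        Effect-allele (ALT) dosage in [0, 2]; ``nan`` marks missing calls.
    """

    subject_ids: np.ndarray
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValidationError("dosage must be 2-D (subjects x variants)")
        if self.dosage.shape != (len(self.subject_ids), len(self.variants)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.variants)} variants"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("subject ids must be unique")
        vid = self.variants["variant_id"]
        if vid.duplicated().any():
            raise ValidationError("variant ids must be unique")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if np.any(bad):
            raise ValidationError("dosages must lie in [0, 2] where not missing")
        pos = self.variants["pos"].to_numpy()
        for _, grp in self.variants.groupby("chrom", sort=False):
            p = grp["pos"].to_numpy()
            if np.any(np.diff(p) < 0):
                raise ValidationError("positions must be non-decreasing within chromosome")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return np.isnan(self.dosage)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def effect_allele_freq(self) -> np.ndarray:
        """Per-variant ALT allele frequency on non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor allele frequency: folded ALT frequency, min(p, 1-p)."""
        p = self.effect_allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask.mean(axis=0)

    def select_variants(self, index) -> "GenotypeMatrix":
        """Subset by variant positional index (bool mask or int array)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            subject_ids=self.subject_ids,
            variants=self.variants.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index],
        )

    def select_subjects(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            subject_ids=self.subject_ids[index],
            variants=self.variants.copy(),
            dosage=self.dosage[index, :],
        )

    def dosage_for(self, variant_id: str) -> np.ndarray:
        """Dosage column for one variant id."""
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if len(idx) == 0:
            raise KeyError(f"unknown variant id: {variant_id}")
        return self.dosage[:, idx[0]]


def check_cohort(cohort: pd.DataFrame, require_outcome: bool = True) -> pd.DataFrame:
    """Validate a cohort table; returns it unchanged.

    Requires unique ``subject_id``; with outcomes, ``time`` > 0 and
    ``event`` in {0, 1}.
    """
    if "subject_id" not in cohort.columns:
        raise ValidationError("cohort table must have a subject_id column")
    if cohort["subject_id"].duplicated().any():
        raise ValidationError("subject ids must be unique")
    if require_outcome:
        for col in OUTCOME_COLUMNS:
            if col not in cohort.columns:
                raise ValidationError(f"cohort table missing outcome column {col!r}")
        if len(cohort) and not (cohort["time"] > 0).all():
            raise ValidationError("time must be strictly positive")
        if len(cohort) and not cohort["event"].isin([0, 1]).all():
            raise ValidationError("event must be 0 or 1")
    return cohort


def align_subjects(g: GenotypeMatrix, cohort: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Align genotype rows and cohort rows on subject id (inner join, cohort order)."""
    ids = cohort["subject_id"].to_numpy()
    lookup = {s: i for i, s in enumerate(g.subject_ids)}
    keep = [s in lookup for s in ids]
    cohort = cohort.loc[keep].reset_index(drop=True)
    rows = np.array([lookup[s] for s in cohort["subject_id"]], dtype=int)
    return g.select_subjects(rows), cohort
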