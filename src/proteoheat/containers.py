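"""Core in-memory containers shared by every pipeline stage.

The central object is :class:`IntensityMatrix`: a proteins x samples table of
log2 (or raw) abundances with an explicit boolean detection mask.  DIA-MS
matrices carry substantial, intensity-dependent missingness, and several
downstream analyses (detection-frequency classification in particular) must
operate on the *original* detection pattern even after missing cells have been
imputed — hence the mask is stored separately from the values and survives
imputation untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_SCALES = ("raw", "log2", "log2-normalized", "imputed")


class ValidationError(ValueError):
    """Raised when an input table violates a structural contract."""


@dataclass
class IntensityMatrix:
    """Proteins x samples abundance matrix with an explicit detection mask.

    Parameters
    ----------
    values : pandas.DataFrame
        Abundances, indexed by protein id with sample ids as columns.
        Missing cells are NaN unless ``scale_flag == "imputed"``.
    mask : pandas.DataFrame
        Boolean, same shape: True where the protein was detected (observed)
        in that sample.  For imputed matrices this is the *pre-imputation*
        mask; imputed values never count as detections.
    scale_flag : str
        One of ``raw``, ``log2``, ``log2-normalized``, ``imputed``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    scale_flag: str = "raw"

    def __post_init__(self) -> None:
        if self.scale_flag not in VALID_SCALES:
            raise ValidationError(
                f"scale_flag must be one of {VALID_SCALES}, got {self.scale_flag!r}"
            )
        if self.values.shape != self.mask.shape:
            raise ValidationError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(
            self.mask.columns
        ):
            raise ValidationError("values and mask must share index and columns")
        for axis, name in ((self.values.index, "protein"), (self.values.columns, "sample")):
            dup = axis[axis.duplicated()].unique()
            if len(dup):
                raise ValidationError(f"duplicate {name} id(s): {list(dup)[:5]}")
        if self.scale_flag == "imputed":
            if self.values.isna().any().any():
                raise ValidationError("imputed matrix must have zero missing cells")
        else:
            # NaN pattern and mask must agree on non-imputed matrices
            if not (self.values.isna().to_numpy() == ~self.mask.to_numpy()).all():
                raise ValidationError("NaN pattern of values disagrees with mask")

    # -- convenience accessors -------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def missing_fraction(self) -> float:
        """Overall fraction of non-detected cells (from the mask)."""
        return float((~self.mask.to_numpy()).mean())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(self.values.copy(), self.mask.copy(), self.scale_flag)

    @classmethod
    def from_values(cls, values: pd.DataFrame, scale_flag: str = "raw") -> "IntensityMatrix":
        """Build a matrix whose mask is simply the non-NaN pattern."""
        return cls(values, values.notna(), scale_flag)


@dataclass
class SampleDesign:
    """Per-sample experimental factors for the factorial stress design.

    The reference design is 2 tolerance classes x 2 genotypes per class x
    2 sampling days x 3 biological replicates = 24 samples, with day modelled
    as a factor (baseline day 0 vs stress day 6).
    """

    table: pd.DataFrame  # index: sample id; columns: genotype, tolerance_class, day, replicate
    REQUIRED = ("genotype", "tolerance_class", "day", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"design table missing column(s): {missing}")
        dup = self.table.index[self.table.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate sample id(s) in design: {list(dup)[:5]}")
        bad = set(self.table["tolerance_class"]) - {"tolerant", "sensitive"}
        if bad:
            raise ValidationError(f"unknown tolerance_class value(s): {sorted(bad)}")
        cells = self.table.groupby(["genotype", "day"], observed=True).size()
        if (cells < 1).any():
            raise ValidationError("every (genotype, day) cell needs >= 1 replicate")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def classes(self) -> list:
        return sorted(self.table["tolerance_class"].unique())

    @property
    def genotypes(self) -> list:
        return sorted(self.table["genotype"].unique())

    @property
    def days(self) -> list:
        return sorted(self.table["day"].unique())

    def check_matches(self, matrix: IntensityMatrix) -> None:
        """Every matrix sample id must appear exactly once in the design."""
        missing = matrix.sample_ids.difference(self.table.index)
        if len(missing):
            raise ValidationError(f"matrix sample(s) absent from design: {list(missing)[:5]}")

    def samples_in(self, *, tolerance_class=None, genotype=None, day=None) -> pd.Index:
        """Sample ids matching the given factor levels (None = any)."""
        sel = pd.Series(True, index=self.table.index)
        if tolerance_class is not None:
            sel &= self.table["tolerance_class"] == tolerance_class
        if genotype is not None:
            sel &= self.table["genotype"] == genotype
        if day is not None:
            sel &= self.table["day"] == day
        return self.table.index[sel]


@dataclass
class AnnotationSets:
    """Pathway id -> (name, frozenset of member protein ids)."""

    names: dict = field(default_factory=dict)
    members: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValidationError(f"pathway {pid!r} has an empty member list")
            self.members[pid] = frozenset(mem)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def universe(self) -> frozenset:
        """Union of all annotated protein ids."""
        out: set = set()
        for mem in self.members.values():
            out |= mem
        return frozenset(out)


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
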