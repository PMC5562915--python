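"""Core in-memory containers shared across the pipeline.

The pipeline moves four kinds of objects between stages: gene-by-tissue
expression matrices (FPKM), a secretory-pathway annotation (gene ->
functional module / subsystem / gene family), per-protein PTM site counts,
and the result records of the downstream statistics (category calls,
Grubbs outlier calls, disulfide-load estimates, regressions).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

DETECTION_FPKM = 1.0  # FPKM > 1 means "detected" in a tissue
FOLD_THRESHOLD = 5.0  # inclusive fold threshold of the enrichment rules


class SecpathError(Exception):
    """Base class for all package errors."""


class FormatError(SecpathError):
    """A file violated the expected external format."""


class ValidationError(SecpathError):
    """An in-memory object violated a domain invariant."""


class PlanError(SecpathError):
    """A simulation plan is internally infeasible."""


@dataclass
class ExpressionMatrix:
    """Nonnegative FPKM values over genes x tissues for one dataset.

    ``values`` is a pandas DataFrame indexed by gene symbol with one
    column per tissue. Gene symbols and tissue names are unique.
    """

    dataset_id: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene symbols: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValidationError("duplicate tissue names")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite FPKM at gene {v.index[bad[0]]!r}, "
                f"tissue {v.columns[bad[1]]!r}"
            )
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative FPKM at gene {v.index[bad[0]]!r}, "
                f"tissue {v.columns[bad[1]]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.dataset_id, self.values.loc[present].copy())

    def log10p(self) -> pd.DataFrame:
        """log10(FPKM + 1), the default transform for correlation work."""
        return np.log10(self.values + 1.0)


@dataclass
class PathwayAnnotation:
    """Secretory-pathway annotation: gene -> module, subsystem, family.

    ``table`` is indexed by gene with columns ``module``, ``subsystem``,
    ``family`` (``"none"`` for genes outside any family), optional
    ``secretory_client`` (bool) and ``complex_count`` (nullable int).
    Families of size 1 are rejected at load time (the member is kept
    with family ``"none"``), so every surviving family has >= 2 members.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("a gene appears more than once in the annotation")
        for col in ("module", "subsystem", "family"):
            if col not in self.table.columns:
                raise ValidationError(f"annotation is missing column {col!r}")
        sizes = self.table["family"][self.table["family"] != "none"].value_counts()
        singletons = sizes[sizes < 2]
        if len(singletons):
            raise ValidationError(
                f"singleton families present: {list(singletons.index)[:5]}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def families(self, min_size: int = 2) -> dict[str, list[str]]:
        """Family name -> member genes, restricted to families >= min_size."""
        fams: dict[str, list[str]] = {}
        grouped = self.table[self.table["family"] != "none"].groupby("family")
        for name, sub in grouped:
            if len(sub) >= min_size:
                fams[str(name)] = list(sub.index)
        return fams

    def subsystem_of(self, gene: str) -> Optional[str]:
        if gene in self.table.index:
            return str(self.table.loc[gene, "subsystem"])
        return None

    def family_of(self, gene: str) -> Optional[str]:
        if gene in self.table.index:
            return str(self.table.loc[gene, "family"])
        return None


@dataclass
class PTMRecord:
    """Per-protein secretory feature counts extracted from UniProt-style GFF."""

    protein: str
    n_glyc_sites: int = 0
    o_glyc_sites: int = 0
    disulfide_sites: int = 0
    gpi_sites: int = 0
    tm_domains: int = 0
    has_signal_peptide: bool = False
    secretomep_score: Optional[float] = None
    localization: Optional[str] = None
    unannotated: bool = False  # protein seen in expression but absent from GFF

    def __post_init__(self) -> None:
        for name in ("n_glyc_sites", "o_glyc_sites", "disulfide_sites",
                     "gpi_sites", "tm_domains"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a nonnegative integer, got {v!r}")


@dataclass
class CategoryCall:
    """One gene's tissue-specificity category and the witnessing evidence."""

    gene: str
    category: str  # NotDetected | TissueEnriched | GroupEnriched |
    #                TissueEnhanced | ExpressedInAll | Mixed
    witness_tissues: tuple[str, ...] = ()
    witness_fold: Optional[float] = None


@dataclass
class GrubbsResult:
    """Grubbs outlier statistic G = max|x - mean| / s for one sample."""

    G: float
    n: int
    argmax_index: int
    direction: str  # "above" | "below"
    p: Optional[float] = None


@dataclass
class ExtremeCall:
    """A family member flagged as a Grubbs outlier in one tissue."""

    gene: str
    family: str
    tissue: str
    G: float
    p: float
    fold_change: float
    dataset_id: str
    validated: bool = False
    subsystem: Optional[str] = None
    direction: str = "above"


@dataclass
class DSLoad:
    """Per-tissue disulfide enrichment estimator DS_e = log10(sum fpkm_i * ds_i)."""

    tissue: str
    ds_e: float
    n_genes: int
    undefined: bool = False


@dataclass
class LoadAssociation:
    """OLS association of one enzyme gene's FPKM with DS_e across tissues."""

    gene: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    slope_ci: tuple[float, float]
    n_tissues: int


@dataclass
class SecretomeSet:
    """The secretome analysis set after the signal-peptide filters.

    ``genes`` is the conventional (signal-peptide-bearing) analysis set.
    ``unconventional`` are proteins without a signal peptide but with a
    SecretomeP-style score > 0.6; they are tracked but excluded from the
    disulfide-load computation.
    """

    genes: set[str]
    unconventional: set[str] = field(default_factory=set)
    localization: dict[str, str] = field(default_factory=dict)


def calls_to_frame(calls: list) -> pd.DataFrame:
    """Flatten a list of result dataclasses into a DataFrame."""
    if not calls:
        return pd.DataFrame()
    return pd.DataFrame([dataclasses.asdict(c) for c in calls])
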