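"""Cross-tissue correlation structure of a gene set's expression.

Tissue-by-tissue Pearson correlation of log10(FPKM+1) expression
profiles, average-linkage hierarchical clustering on 1 - rho with a
2-group split, a permutation test asking whether a designated tissue
group correlates unusually weakly with the rest for a given gene set,
and per-gene-family correlation profiles against a reference tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .types import ExpressionMatrix, PathwayAnnotation, ValidationError

logger = logging.getLogger(__name__)

MIN_FAMILY_SIZE_CORR = 3  # Pearson over 2 members is always +/-1


@dataclass
class TissueCorrelationMatrix:
    """Symmetric tissue x tissue Pearson matrix for one gene set."""

    rho: pd.DataFrame
    gene_set_id: str

    @property
    def tissues(self) -> list[str]:
        return list(self.rho.index)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for t1, t2 in combinations(self.tissues, 2):
            rows.append((t1, t2, self.rho.loc[t1, t2], self.gene_set_id))
        return pd.DataFrame(rows, columns=["tissue1", "tissue2", "rho", "gene_set_id"])


@dataclass
class ClusteringResult:
    """Dendrogram of tissues plus the flat 2-group split."""

    linkage: np.ndarray
    tissues: list[str]
    leaf_order: list[str]
    groups: dict[str, int]  # tissue -> 1 or 2
    degenerate: bool = False
    newick: str = ""

    def group_members(self, label: int) -> set[str]:
        return {t for t, g in self.groups.items() if g == label}


@dataclass
class FamilyCorrelationProfile:
    family: str
    tissue_pair: tuple[str, str]
    rho: float


def _profiles(m: ExpressionMatrix, genes, log_transform: bool) -> pd.DataFrame:
    if genes is None:
        sub = m.values
    else:
        present = [g for g in genes if g in m.values.index]
        sub = m.values.loc[present]
    if sub.shape[0] < 2:
        raise ValidationError(
            f"need >= 2 usable genes, found {sub.shape[0]}"
        )
    return np.log10(sub + 1.0) if log_transform else sub


def cross_tissue_correlation(
    m: ExpressionMatrix,
    genes: Optional[Sequence[str]] = None,
    log_transform: bool = True,
    gene_set_id: str = "gene_set",
) -> TissueCorrelationMatrix:
    """Pearson correlation between tissues over a gene set's profiles.

    Computed on log10(FPKM+1) by default. A tissue with zero variance
    across the gene set yields missing entries for its pairs (logged).
    """
    sub = _profiles(m, genes, log_transform)
    rho = sub.corr(method="pearson")  # zero-variance columns -> NaN
    zero_var = sub.std(axis=0) == 0
    if zero_var.any():
        logger.warning(
            "zero expression variance in tissues %s; correlations missing",
            list(sub.columns[zero_var]),
        )
    np.fill_diagonal(rho.values, 1.0)
    return TissueCorrelationMatrix(rho=rho, gene_set_id=gene_set_id)


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"


def cluster_tissues(c: TissueCorrelationMatrix, k: int = 2) -> ClusteringResult:
    """Average-linkage clustering of tissues on distance 1 - rho.

    Returns the dendrogram (linkage matrix + Newick), the leaf order,
    and the flat split into ``k`` groups (default 2, the split used for
    the low-correlation tissue analysis). Missing correlations raise an
    error instructing imputation or a gene-set change.
    """
    rho = c.rho
    if rho.isna().to_numpy().any():
        raise ValidationError(
            "correlation matrix has missing entries; impute (e.g. by the "
            "matrix minimum) or choose a gene set without zero-variance tissues"
        )
    d = 1.0 - rho.to_numpy()
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    Z = hierarchy.linkage(squareform(d, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    degenerate = bool(np.allclose(d, 0.0))
    if degenerate:
        logger.warning("all tissues perfectly correlated; split is arbitrary")
    tree = hierarchy.to_tree(Z)
    newick = _to_newick(tree, c.tissues) + ";"
    return ClusteringResult(
        linkage=Z,
        tissues=c.tissues,
        leaf_order=[c.tissues[i] for i in leaves],
        groups={t: int(g) for t, g in zip(c.tissues, flat)},
        degenerate=degenerate,
        newick=newick,
    )


def low_group_permutation_test(
    m: ExpressionMatrix,
    genes: Sequence[str],
    group: Sequence[str],
    n_perm: int = 999,
    seed: Optional[int] = None,
    log_transform: bool = True,
) -> tuple[float, float]:
    """Is the group's between-group correlation unusually low for this gene set?

    Statistic: the median Pearson rho over all (in-group, out-group)
    tissue pairs, computed on the gene set. Null: the same statistic for
    gene sets of equal size redrawn uniformly (without replacement) from
    all genes in the matrix. One-sided toward low correlation with the
    add-one rule: p = (1 + #{null <= observed}) / (1 + n_perm).
    """
    group = list(dict.fromkeys(group))
    tissues = m.tissues
    unknown = set(group) - set(tissues)
    if unknown:
        raise ValidationError(f"unknown tissues in group: {sorted(unknown)}")
    if not group or len(group) >= len(tissues):
        raise ValidationError("group must be a proper nonempty subset of tissues")
    if n_perm < 100:
        logger.warning("n_perm=%d is low; p-value resolution is coarse", n_perm)

    rng = np.random.default_rng(seed)
    full = np.log10(m.values.to_numpy() + 1.0) if log_transform else m.values.to_numpy()
    gene_index = {g: i for i, g in enumerate(m.genes)}
    target = [gene_index[g] for g in genes if g in gene_index]
    if len(target) < 2:
        raise ValidationError("need >= 2 usable genes in the target set")

    in_idx = np.array([tissues.index(t) for t in group])
    out_idx = np.array([i for i in range(len(tissues)) if i not in set(in_idx)])

    def stat(rows: np.ndarray) -> float:
        x = full[rows]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(x, rowvar=False)
        return float(np.nanmedian(r[np.ix_(in_idx, out_idx)]))

    observed = stat(np.array(target))
    n_genes_total = full.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        rows = rng.choice(n_genes_total, size=len(target), replace=False)
        null[i] = stat(rows)
    p = (1.0 + np.sum(null <= observed)) / (1.0 + n_perm)
    return observed, float(p)


def family_correlation_profiles(
    m: ExpressionMatrix,
    ann: PathwayAnnotation,
    reference_tissue: Optional[str] = None,
    log_transform: bool = True,
) -> list[FamilyCorrelationProfile]:
    """Per-family Pearson correlation between tissue pairs.

    For each family of >= 3 members, correlate the members' expression
    values between tissue pairs — all pairs, or the reference tissue
    against every other. Families below the size floor are skipped with
    a log entry (Pearson over two points is always +/- 1).
    """
    if reference_tissue is not None and reference_tissue not in m.tissues:
        raise ValidationError(f"unknown reference tissue {reference_tissue!r}")
    out: list[FamilyCorrelationProfile] = []
    for family, members in sorted(ann.families(min_size=2).items()):
        present = [g for g in members if g in m.values.index]
        if len(present) < MIN_FAMILY_SIZE_CORR:
            logger.info("family %s has %d usable members (<%d); skipped",
                        family, len(present), MIN_FAMILY_SIZE_CORR)
            continue
        sub = m.values.loc[present]
        if log_transform:
            sub = np.log10(sub + 1.0)
        if reference_tissue is not None:
            pairs = [(reference_tissue, t) for t in m.tissues if t != reference_tissue]
        else:
            pairs = list(combinations(m.tissues, 2))
        for t1, t2 in pairs:
            a, b = sub[t1].to_numpy(), sub[t2].to_numpy()
            if a.std() == 0 or b.std() == 0:
                rho = np.nan
            else:
                rho = float(np.corrcoef(a, b)[0, 1])
            out.append(FamilyCorrelationProfile(family, (t1, t2), rho))
    return out


def profiles_table(profiles: list[FamilyCorrelationProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": [p.family for p in profiles],
            "tissue1": [p.tissue_pair[0] for p in profiles],
            "tissue2": [p.tissue_pair[1] for p in profiles],
            "rho": [p.rho for p in profiles],
        }
    )
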