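"""Family-wise extreme-gene detection via the Grubbs outlier test.

Within each gene family the total expression can vary between tissues,
so each member gene is summarised by its *family share* per tissue,
s_{g,t} = fpkm_{g,t} / sum over the family of fpkm in t, which cancels
family-total and library-size variation. The Grubbs statistic

    G = max_i |x_i - mean(x)| / s        (s with n-1 denominator)

is computed on each gene's share vector across tissues; the two-sided
p-value follows the classical t-distribution relation

    t^2 = n (n-2) G^2 / ((n-1)^2 - n G^2),   p = min(1, 2 n P(T_{n-2} >= t)).

Calls with p < alpha whose maximal deviation lies above the mean are
emitted as (gene, tissue) extreme calls; a second, independent dataset
validates a call when the identical pair recurs there.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    ExpressionMatrix,
    ExtremeCall,
    GrubbsResult,
    PathwayAnnotation,
    ValidationError,
)

logger = logging.getLogger(__name__)

_P_FLOOR = np.finfo(float).tiny


def grubbs_bound(n: int) -> float:
    """The attainable maximum of G for a sample of size n: (n-1)/sqrt(n)."""
    return (n - 1) / np.sqrt(n)


def grubbs_statistic(x) -> GrubbsResult:
    """G = max|x - mean| / s with the argmax position and direction.

    Requires n >= 3 and positive sample standard deviation. Ties in the
    maximal absolute deviation break toward the lowest index (logged).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError(f"Grubbs test needs n >= 3, got n={x.size}")
    if np.isnan(x).any():
        raise ValidationError("sample contains NaN")
    n = len(x)
    s = x.std(ddof=1)
    if s == 0:
        raise ValidationError("degenerate sample: zero standard deviation")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    if (dev == dev[idx]).sum() > 1:
        logger.info("tied maximal deviations; keeping lowest index %d", idx)
    G = float(dev[idx] / s)
    direction = "above" if x[idx] >= x.mean() else "below"
    return GrubbsResult(G=G, n=n, argmax_index=idx, direction=direction)


def grubbs_pvalue(G: float, n: int) -> float:
    """Two-sided Grubbs p-value via the t-distribution inversion.

    Clamped to (tiny, 1]: G at or beyond the attainable bound
    (n-1)/sqrt(n) maps to the numerical floor, G = 0 to 1.
    """
    if n < 3:
        raise ValidationError(f"Grubbs test needs n >= 3, got n={n}")
    if G < 0:
        raise ValidationError("G must be nonnegative")
    if G == 0.0:
        return 1.0
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:  # at or beyond the attainable bound
        return _P_FLOOR
    t = np.sqrt(n * (n - 2) * G * G / denom)
    p = 2.0 * n * stats.t.sf(t, df=n - 2)
    return float(min(1.0, max(p, _P_FLOOR)))


def grubbs_test(x) -> GrubbsResult:
    """Statistic and p-value in one call."""
    res = grubbs_statistic(x)
    res.p = grubbs_pvalue(res.G, res.n)
    return res


def family_share(m: ExpressionMatrix, family_genes: Sequence[str]) -> pd.DataFrame:
    """Per-tissue expression share of each family member.

    Columns (tissues) with zero family total get missing shares,
    logged. Shares sum to 1 in every tissue with a positive total.
    """
    present = [g for g in family_genes if g in m.values.index]
    sub = m.values.loc[present]
    totals = sub.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.info("family share undefined in %d tissues (zero total)",
                    int(zero.sum()))
    shares = sub.div(totals.where(~zero), axis=1)
    return shares


def _fold_change(m: ExpressionMatrix, gene: str, tissue: str) -> float:
    row = m.values.loc[gene]
    others = row.drop(tissue)
    med = float(others.median())
    val = float(row[tissue])
    if med == 0.0:
        return np.inf if val > 0 else np.nan
    return val / med


def detect_extreme_genes(
    m: ExpressionMatrix,
    ann: PathwayAnnotation,
    alpha: float = 0.05,
    iterate: bool = False,
    max_depth: int = 2,
    min_family_size: int = 3,
    bh_correct: bool = False,
    input_mode: str = "share",
) -> tuple[list[ExtremeCall], list[ExtremeCall]]:
    """Scan every gene family for per-tissue expression outliers.

    Returns ``(above_calls, below_calls)``: only above-mean outliers are
    extreme calls proper (expression spikes); below-mean outliers are
    reported separately. ``input_mode`` selects the vector handed to the
    Grubbs test: family shares (default), raw FPKM or log10(FPKM+1).

    With ``iterate``, each called tissue is masked and the gene retested
    up to ``max_depth`` calls. ``bh_correct`` applies Benjamini-Hochberg
    across all tested genes before the alpha filter (off by default:
    the procedure filters on raw p < alpha).
    """
    if input_mode not in {"share", "fpkm", "log"}:
        raise ValidationError(f"unknown input_mode {input_mode!r}")
    tested: list[tuple] = []  # (gene, family, tissue, G, p, direction)

    for family, members in sorted(ann.families(min_size=min_family_size).items()):
        present = [g for g in members if g in m.values.index]
        if len(present) < min_family_size:
            continue
        if input_mode == "share":
            vectors = family_share(m, present)
        elif input_mode == "fpkm":
            vectors = m.values.loc[present]
        else:
            vectors = np.log10(m.values.loc[present] + 1.0)
        for gene in present:
            vec = vectors.loc[gene].dropna()
            masked = vec
            for _depth in range(max_depth if iterate else 1):
                if len(masked) < 3 or masked.std(ddof=1) == 0:
                    if len(masked) >= 3:
                        logger.info("degenerate share vector for %s; skipped", gene)
                    break
                res = grubbs_test(masked.to_numpy())
                tissue = str(masked.index[res.argmax_index])
                tested.append((gene, family, tissue, res.G, res.p, res.direction))
                if res.p >= alpha:
                    break
                masked = masked.drop(tissue)

    if not tested:
        return [], []

    pvals = np.array([t[4] for t in tested])
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        p_adj = pvals

    above, below = [], []
    for (gene, family, tissue, G, p, direction), padj in zip(tested, p_adj):
        if padj >= alpha:
            continue
        call = ExtremeCall(
            gene=gene,
            family=family,
            tissue=tissue,
            G=float(G),
            p=float(padj),
            fold_change=_fold_change(m, gene, tissue),
            dataset_id=m.dataset_id,
            subsystem=ann.subsystem_of(gene),
            direction=direction,
        )
        (above if direction == "above" else below).append(call)
    return above, below


def _norm_tissue(t: str, alias: Optional[dict] = None) -> str:
    t = t.strip().casefold()
    if alias:
        t = alias.get(t, t)
    return t


def consensus(
    calls_primary: list[ExtremeCall],
    calls_validation: list[ExtremeCall],
    alias_map: Optional[dict[str, str]] = None,
    tissues_primary: Optional[Sequence[str]] = None,
    tissues_validation: Optional[Sequence[str]] = None,
) -> list[ExtremeCall]:
    """Flag primary calls replicated as the same (gene, tissue) pair.

    Tissue names are harmonised by exact case-insensitive match plus an
    optional alias map. If the two datasets' tissue vocabularies are
    supplied and share no tissue after harmonisation, that is an error
    suggesting an alias map (disjoint *call* sets are fine: nothing
    validates). Unvalidated calls are retained, flagged.
    """
    alias = {
        _norm_tissue(k): _norm_tissue(v) for k, v in (alias_map or {}).items()
    }
    if tissues_primary is not None and tissues_validation is not None:
        v1 = {_norm_tissue(t, alias) for t in tissues_primary}
        v2 = {_norm_tissue(t, alias) for t in tissues_validation}
        if v1 and v2 and not (v1 & v2):
            raise ValidationError(
                "tissue vocabularies of the two datasets are disjoint; "
                "supply a tissue alias map"
            )
    validated_pairs = {
        (c.gene, _norm_tissue(c.tissue, alias)) for c in calls_validation
    }
    out = []
    for c in calls_primary:
        pair = (c.gene, _norm_tissue(c.tissue, alias))
        out.append(
            ExtremeCall(
                **{**c.__dict__, "validated": pair in validated_pairs}
            )
        )
    return out


def build_network(calls: list[ExtremeCall], ann: PathwayAnnotation) -> nx.Graph:
    """Bipartite tissue--gene network of extreme calls.

    Gene nodes carry family and subsystem; edges carry G, p, fold change
    and the validation flag. Empty input yields an empty network with a
    warning.
    """
    net = nx.Graph()
    if not calls:
        logger.warning("building network from zero extreme calls")
        return net
    for c in calls:
        net.add_node(c.tissue, kind="tissue", bipartite=0)
        net.add_node(
            c.gene,
            kind="gene",
            bipartite=1,
            family=c.family,
            subsystem=c.subsystem or (ann.subsystem_of(c.gene) or "unknown"),
        )
        net.add_edge(
            c.gene,
            c.tissue,
            G=float(c.G),
            p=float(c.p),
            fold_change=float(c.fold_change) if np.isfinite(c.fold_change) else -1.0,
            validated=bool(c.validated),
        )
    return net


def subsystem_tissue_table(calls: list[ExtremeCall]) -> pd.DataFrame:
    """Frequency of extreme genes per subsystem x tissue."""
    if not calls:
        return pd.DataFrame()
    df = pd.DataFrame(
        {"subsystem": [c.subsystem for c in calls],
         "tissue": [c.tissue for c in calls]}
    )
    return df.groupby(["subsystem", "tissue"]).size().unstack(fill_value=0)


def extreme_calls_table(calls: list[ExtremeCall]) -> pd.DataFrame:
    """Extreme calls as the output TSV layout."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "family": [c.family for c in calls],
            "subsystem": [c.subsystem for c in calls],
            "tissue": [c.tissue for c in calls],
            "G": [c.G for c in calls],
            "p": [c.p for c in calls],
            "fold_change": [c.fold_change for c in calls],
            "dataset": [c.dataset_id for c in calls],
            "validated": [c.validated for c in calls],
        }
    )
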