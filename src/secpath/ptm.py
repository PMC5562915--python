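"""Secretome definition, disulfide-load estimation and enzyme association.

The secretome analysis set comprises proteins with an N-terminal signal
peptide (conventional secretion); proteins without one but with an
unconventional-secretion score > 0.6 are tracked separately and
excluded from the load computation. Per tissue, the disulfide
processing demand is summarised by the enrichment estimator

    DS_e(t) = log10( sum_i fpkm_{i,t} * ds_i )

over the secretome genes i, where ds_i counts the protein's annotated
disulfide bonds. Linear association between a processing enzyme's FPKM
and DS_e across tissues is tested by ordinary least squares with the
Pearson correlation t-test.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    DSLoad,
    ExpressionMatrix,
    LoadAssociation,
    PTMRecord,
    SecretomeSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

UNCONVENTIONAL_SCORE_CUTOFF = 0.6
TISSUE_SPECIFIC_CATEGORIES = frozenset(
    {"TissueEnriched", "GroupEnriched", "TissueEnhanced", "Mixed"}
)


def define_secretome(
    ptm: dict[str, PTMRecord],
    categories: Optional[dict[str, str]] = None,
    restrict_to: Optional[Iterable[str]] = None,
) -> SecretomeSet:
    """Build the secretome analysis set from PTM records.

    Conventional members carry a signal peptide and form the analysis
    set. Proteins without one but with secretomep_score > 0.6 are
    recorded as unconventional and excluded; proteins with neither are
    dropped. With ``categories`` (gene -> category) and ``restrict_to``,
    the analysis set is limited to those categories (e.g. the
    tissue-specific ones).
    """
    conventional, unconventional = set(), set()
    localization = {}
    for name, rec in ptm.items():
        if rec.localization:
            localization[name] = rec.localization
        if rec.has_signal_peptide:
            conventional.add(name)
        elif rec.secretomep_score is not None and \
                rec.secretomep_score > UNCONVENTIONAL_SCORE_CUTOFF:
            unconventional.add(name)
    if restrict_to is not None:
        if categories is None:
            raise ValidationError("category restriction requires a category table")
        wanted = set(restrict_to)
        conventional = {
            g for g in conventional if categories.get(g) in wanted
        }
    if not conventional:
        raise ValidationError("secretome analysis set is empty")
    return SecretomeSet(
        genes=conventional,
        unconventional=unconventional,
        localization=localization,
    )


def disulfide_enrichment(
    m: ExpressionMatrix,
    sec: SecretomeSet,
    ptm: dict[str, PTMRecord],
) -> list[DSLoad]:
    """DS_e = log10(sum fpkm_i * ds_i) for every tissue.

    Secretome genes absent from the PTM records contribute ds = 0
    (flagged upstream, not dropped). A tissue whose weighted sum is 0
    gets an undefined load, excluded from downstream regressions.
    """
    genes = sorted(sec.genes & set(m.genes))
    if not genes:
        raise ValidationError("no secretome genes present in the expression matrix")
    ds = np.array([
        ptm[g].disulfide_sites if g in ptm else 0 for g in genes
    ], dtype=float)
    sub = m.values.loc[genes]
    totals = sub.mul(ds, axis=0).sum(axis=0)
    out = []
    for tissue, total in totals.items():
        if total > 0:
            out.append(DSLoad(tissue=str(tissue), ds_e=float(np.log10(total)),
                              n_genes=len(genes)))
        else:
            out.append(DSLoad(tissue=str(tissue), ds_e=float("nan"),
                              n_genes=len(genes), undefined=True))
    return out


def associate_family_with_load(
    m: ExpressionMatrix,
    family: Sequence[str],
    loads: list[DSLoad],
) -> list[LoadAssociation]:
    """OLS of each enzyme gene's FPKM on DS_e across tissues.

    Reports slope with 95% CI, Pearson r and its two-sided p-value.
    Needs >= 3 tissues with defined loads; a constant DS_e across
    tissues is a degenerate regression and raises.
    """
    defined = [l for l in loads if not l.undefined and l.tissue in m.tissues]
    if len(defined) < 3:
        raise ValidationError(
            f"need >= 3 tissues with defined loads, got {len(defined)}"
        )
    x = np.array([l.ds_e for l in defined])
    if np.ptp(x) == 0:
        raise ValidationError("DS_e constant across tissues: degenerate regression")
    tissues = [l.tissue for l in defined]
    out = []
    for gene in family:
        if gene not in m.values.index:
            logger.info("enzyme gene %s absent from matrix; skipped", gene)
            continue
        y = m.values.loc[gene, tissues].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        tcrit = stats.t.ppf(0.975, df=len(x) - 2)
        out.append(
            LoadAssociation(
                gene=gene,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                pearson_r=float(fit.rvalue),
                p_value=float(max(fit.pvalue, np.finfo(float).tiny)),
                slope_ci=(
                    float(fit.slope - tcrit * fit.stderr),
                    float(fit.slope + tcrit * fit.stderr),
                ),
                n_tissues=len(x),
            )
        )
    return out


def ptm_annotation_matrix(
    sec: SecretomeSet,
    ptm: dict[str, PTMRecord],
) -> pd.DataFrame:
    """Per-gene PTM site counts with low/medium/high tercile bins.

    Counts of N-glycosylation, O-glycosylation, disulfide and
    GPI-anchor sites per secretome gene. Each count column is
    discretised against the terciles of its *nonzero* values: zeros
    bin as ``none``, then ``low``/``medium``/``high``. Feeds the
    clustered-heatmap annotation bars.
    """
    genes = sorted(sec.genes)
    counts = pd.DataFrame(
        {
            "n_glyc": [ptm[g].n_glyc_sites if g in ptm else 0 for g in genes],
            "o_glyc": [ptm[g].o_glyc_sites if g in ptm else 0 for g in genes],
            "disulfide": [ptm[g].disulfide_sites if g in ptm else 0 for g in genes],
            "gpi": [ptm[g].gpi_sites if g in ptm else 0 for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    for col in list(counts.columns):
        counts[f"{col}_bin"] = tercile_bins(counts[col])
    return counts


def tercile_bins(column: pd.Series) -> pd.Series:
    """Discretise counts: zero -> none; nonzero by terciles -> low/medium/high."""
    vals = column.to_numpy(dtype=float)
    bins = pd.Series("none", index=column.index, dtype=object)
    nz = vals[vals > 0]
    if nz.size == 0:
        return bins
    q1, q2 = np.quantile(nz, [1 / 3, 2 / 3])
    labels = np.where(vals <= q1, "low", np.where(vals <= q2, "medium", "high"))
    bins[vals > 0] = labels[vals > 0]
    return bins


def loads_table(loads: list[DSLoad]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": [l.tissue for l in loads],
            "ds_e": [l.ds_e for l in loads],
            "n_genes": [l.n_genes for l in loads],
            "undefined": [l.undefined for l in loads],
        }
    )


def associations_table(assocs: list[LoadAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [a.gene for a in assocs],
            "slope": [a.slope for a in assocs],
            "intercept": [a.intercept for a in assocs],
            "pearson_r": [a.pearson_r for a in assocs],
            "p_value": [a.p_value for a in assocs],
            "slope_ci_low": [a.slope_ci[0] for a in assocs],
            "slope_ci_high": [a.slope_ci[1] for a in assocs],
            "n_tissues": [a.n_tissues for a in assocs],
        }
    )
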