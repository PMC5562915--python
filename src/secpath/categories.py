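"""Six-rule tissue-specificity classification of expression profiles.

Every gene falls into exactly one of six categories derived from its
FPKM profile across tissues (detection threshold FPKM > 1, fold
threshold 5, inclusive):

* ``NotDetected``     — FPKM < 1 in every tissue.
* ``TissueEnriched``  — a unique top tissue at >= 5x the FPKM of every
  other tissue.
* ``GroupEnriched``   — a group of 2–7 tissues whose mean FPKM is
  >= 5x the maximum of all remaining tissues.
* ``TissueEnhanced``  — a top tissue at >= 5x the mean FPKM of all
  tissues (itself included).
* ``ExpressedInAll``  — FPKM > 1 in every tissue.
* ``Mixed``           — everything else detected in at least one tissue.

Rules are evaluated specificity-first (NotDetected, TissueEnriched,
GroupEnriched, TissueEnhanced, ExpressedInAll, Mixed), so enrichment
categories dominate: a gene both ubiquitous and 5-fold spiked in one
tissue is enhanced, not expressed-in-all. Group-enriched groups are
prefixes of the descending-FPKM ordering (sizes 2–7).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    CategoryCall,
    DETECTION_FPKM,
    ExpressionMatrix,
    FOLD_THRESHOLD,
    ValidationError,
)

CATEGORIES = (
    "NotDetected",
    "TissueEnriched",
    "GroupEnriched",
    "TissueEnhanced",
    "ExpressedInAll",
    "Mixed",
)

_MAX_GROUP = 7


def _fold(numer: float, denom: float) -> float:
    if denom == 0.0:
        return np.inf if numer > 0 else np.nan
    with np.errstate(over="ignore"):
        return numer / denom


def classify_gene(x, tissues=None, gene: str = "") -> CategoryCall:
    """Classify one FPKM vector into its tissue-specificity category."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValidationError("need an FPKM vector over at least 2 tissues")
    if np.isnan(x).any():
        raise ValidationError("FPKM vector contains NaN")
    if (x < 0).any():
        raise ValidationError("FPKM vector contains negative values")
    if tissues is None:
        tissues = [f"t{i}" for i in range(len(x))]
    tissues = list(tissues)

    # rule 1: not detected anywhere
    if (x < DETECTION_FPKM).all():
        return CategoryCall(gene, "NotDetected")

    order = np.argsort(-x, kind="stable")
    top = order[0]
    rest_max = x[order[1:]].max()

    # rule 2: tissue enriched — unique top >= 5x every other tissue
    unique_top = (x == x[top]).sum() == 1
    if unique_top:
        fold = _fold(x[top], rest_max)
        if fold >= FOLD_THRESHOLD:
            return CategoryCall(gene, "TissueEnriched", (tissues[top],), float(fold))

    # rule 3: group enriched — descending prefix of 2..7 tissues, mean
    # >= 5x max of the remaining tissues
    n = len(x)
    for k in range(2, min(_MAX_GROUP, n - 1) + 1):
        grp = order[:k]
        out = order[k:]
        fold = _fold(x[grp].mean(), x[out].max())
        if fold >= FOLD_THRESHOLD:
            return CategoryCall(
                gene, "GroupEnriched", tuple(tissues[i] for i in grp), float(fold)
            )

    # rule 5 before rule 4: tissue enhanced — top >= 5x mean of all
    fold = _fold(x[top], x.mean())
    if fold >= FOLD_THRESHOLD:
        return CategoryCall(gene, "TissueEnhanced", (tissues[top],), float(fold))

    # rule 4: expressed in all tissues
    if (x > DETECTION_FPKM).all():
        return CategoryCall(gene, "ExpressedInAll")

    # rule 6: the remainder, detected somewhere but not everywhere
    return CategoryCall(gene, "Mixed")


def classify_all(m: ExpressionMatrix, genes=None):
    """Classify every (or a subset of) gene in a matrix.

    Returns ``(calls, counts)`` where ``counts`` is a Series over all
    six categories (zeros included) summing to the number of genes.
    """
    if genes is None:
        sub = m.values
    else:
        present = [g for g in genes if g in m.values.index]
        sub = m.values.loc[present]
    tissues = list(sub.columns)
    calls = [
        classify_gene(row.to_numpy(), tissues, gene=str(g))
        for g, row in sub.iterrows()
    ]
    counts = pd.Series(
        {c: 0 for c in CATEGORIES}, dtype=int, name="n_genes"
    )
    for call in calls:
        counts[call.category] += 1
    return calls, counts


def calls_table(calls) -> pd.DataFrame:
    """Category calls as the output TSV layout."""
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "category": [c.category for c in calls],
            "witness_tissues": [";".join(c.witness_tissues) for c in calls],
            "witness_fold": [c.witness_fold for c in calls],
        }
    )
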