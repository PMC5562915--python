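"""Readers and writers for every external artifact of the pipeline.

Formats: gene-by-tissue FPKM matrices as TSV, the pathway-annotation
table as TSV, per-protein PTM features as UniProt-dialect GFF (column 1
is the protein accession, column 3 the feature type, column 9 a
``Note=`` attribute), and the tissue--gene network as SIF or GraphML.
"""

from __future__ import annotations

import logging
import urllib.parse
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    ExpressionMatrix,
    FormatError,
    PathwayAnnotation,
    PTMRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

# UniProt feature-type vocabulary we extract, normalised to lower case.
_SIGNAL_TYPES = {"signal peptide", "signal"}
_DISULFIDE_TYPES = {"disulfide bond", "disulfide"}
_GLYC_TYPES = {"glycosylation", "glycosylation site", "carbohyd"}
_GPI_TYPES = {"lipidation", "gpi-anchor", "gpi-anchor amidated site"}
_TM_TYPES = {"transmembrane", "transmembrane region", "transmem"}


def load_expression(path, dataset_id: str) -> ExpressionMatrix:
    """Read a TSV FPKM matrix (header: gene<TAB>tissue1...tissueN).

    Duplicate gene rows collapse by per-tissue maximum with a logged
    warning. Negative or non-numeric cells raise :class:`FormatError`
    naming the offending row and column.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise FormatError(f"{path}: empty expression file")

    num = raw.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} at gene "
            f"{raw.index[r]!r}, tissue {raw.columns[c]!r}"
        )
    if num.isna().to_numpy().any():
        r, c = np.argwhere(num.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {raw.index[r]!r}, "
            f"tissue {raw.columns[c]!r}"
        )
    if (num.to_numpy() < 0).any():
        r, c = np.argwhere(num.to_numpy() < 0)[0]
        raise FormatError(
            f"{path}: negative FPKM {num.iat[r, c]} at gene "
            f"{num.index[r]!r}, tissue {num.columns[c]!r}"
        )

    if num.index.has_duplicates:
        dupes = num.index[num.index.duplicated()].unique().tolist()
        logger.warning(
            "%s: %d duplicated gene rows collapsed by max FPKM: %s",
            path, len(dupes), dupes[:10],
        )
        num = num.groupby(level=0, sort=False).max()
    num.index = num.index.astype(str)
    num.index.name = "gene"
    return ExpressionMatrix(dataset_id=dataset_id, values=num.astype(float))


def write_expression(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def load_pathway_annotation(path, subsystem_vocabulary: Optional[Iterable[str]] = None
                            ) -> PathwayAnnotation:
    """Read the gene -> module/subsystem/family annotation TSV.

    Singleton families are demoted to ``"none"`` (the gene is kept) with
    a logged message. If a controlled subsystem vocabulary is supplied,
    unknown subsystem labels raise :class:`ValidationError`.
    """
    path = Path(path)
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene", "module", "subsystem", "family"}
    missing = required - set(tab.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    tab = tab.set_index("gene")
    tab["family"] = tab["family"].fillna("none").replace("", "none")

    if subsystem_vocabulary is not None:
        vocab = set(subsystem_vocabulary)
        unknown = set(tab["subsystem"]) - vocab
        if unknown:
            raise ValidationError(
                f"{path}: unknown subsystem labels {sorted(unknown)[:5]}"
            )

    sizes = tab["family"][tab["family"] != "none"].value_counts()
    singles = sizes[sizes == 1].index.tolist()
    if singles:
        logger.info("%s: %d singleton families demoted to 'none': %s",
                    path, len(singles), singles[:10])
        tab.loc[tab["family"].isin(singles), "family"] = "none"

    if "secretory_client" in tab.columns:
        tab["secretory_client"] = (
            tab["secretory_client"].str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            ).astype("boolean")
        )
    if "complex_count" in tab.columns:
        tab["complex_count"] = pd.to_numeric(
            tab["complex_count"], errors="coerce"
        ).astype("Int64")
    return PathwayAnnotation(table=tab)


def packaged_pathway_annotation() -> PathwayAnnotation:
    """The packaged synthetic secretory-pathway annotation fixture.

    A synthetic stand-in for the published component table, built to the
    printed marginals: 575 genes over 4 functional modules, 13
    subsystems and 30 gene families (family sizes 4-44, 347 genes in
    families). Gene symbols are synthetic.
    """
    ref = resources.files("secpath.data") / "pathway_annotation_synthetic.tsv"
    with resources.as_file(ref) as p:
        return load_pathway_annotation(p)


def _note_text(attributes: str) -> str:
    for part in attributes.split(";"):
        key, _, val = part.partition("=")
        if key.strip().lower() == "note":
            return urllib.parse.unquote(val)
    return ""


def parse_uniprot_gff(path, extra_annotations=None) -> dict[str, PTMRecord]:
    """Count the secretory PTM features of a UniProt-dialect GFF file.

    One ``Disulfide bond`` feature line counts one disulfide site (one
    bond, not two half-cystines). N- vs O-glycosylation is distinguished
    by the feature's ``Note=`` text. Malformed lines are skipped with a
    counted warning; a file with zero parsable features raises
    :class:`FormatError`.

    ``extra_annotations`` optionally points to a sidecar TSV (columns
    ``protein``, ``secretomep_score``, ``localization``) merged into the
    records — the GFF dialect itself has no field for either.
    """
    path = Path(path)
    counts: dict[str, dict] = {}
    n_features = 0
    n_malformed = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                n_malformed += 1
                continue
            acc, _, ftype = cols[0], cols[1], cols[2].strip().lower()
            note = _note_text(cols[8]).lower()
            rec = counts.setdefault(
                acc,
                dict(n_glyc=0, o_glyc=0, ds=0, gpi=0, tm=0, sp=False),
            )
            if ftype in _SIGNAL_TYPES:
                rec["sp"] = True
            elif ftype in _DISULFIDE_TYPES:
                rec["ds"] += 1
            elif ftype in _GLYC_TYPES:
                if "o-linked" in note:
                    rec["o_glyc"] += 1
                else:  # UniProt notes default to N-linked carbohydrate
                    rec["n_glyc"] += 1
            elif ftype in _GPI_TYPES:
                if ftype.startswith("gpi") or "gpi" in note:
                    rec["gpi"] += 1
            elif ftype in _TM_TYPES:
                rec["tm"] += 1
            else:
                continue  # feature type outside the extracted seven
            n_features += 1
    if n_malformed:
        logger.warning("%s: skipped %d malformed GFF lines", path, n_malformed)
    if n_features == 0:
        raise FormatError(f"{path}: no parsable PTM features")

    records = {
        acc: PTMRecord(
            protein=acc,
            n_glyc_sites=c["n_glyc"],
            o_glyc_sites=c["o_glyc"],
            disulfide_sites=c["ds"],
            gpi_sites=c["gpi"],
            tm_domains=c["tm"],
            has_signal_peptide=c["sp"],
        )
        for acc, c in counts.items()
    }

    if extra_annotations is not None:
        side = pd.read_csv(extra_annotations, sep="\t", dtype=str)
        if "protein" not in side.columns:
            raise FormatError("sidecar annotation needs a 'protein' column")
        for _, row in side.iterrows():
            rec = records.get(str(row["protein"]))
            if rec is None:
                continue
            score = row.get("secretomep_score")
            if score is not None and not pd.isna(score):
                rec.secretomep_score = float(score)
            loc = row.get("localization")
            if loc is not None and not pd.isna(loc):
                rec.localization = str(loc)
    return records


def placeholder_ptm_record(protein: str) -> PTMRecord:
    """Record for a protein absent from the GFF: all counts 0, flagged."""
    return PTMRecord(protein=protein, unannotated=True)


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Export the bipartite tissue--gene network as SIF or GraphML.

    SIF lines read ``gene<TAB>extreme_in<TAB>tissue``. A GraphML round
    trip reproduces every node and edge attribute.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt not in {"sif", "graphml"}:
        raise ValueError(f"unsupported network format {format!r}")
    if net.number_of_nodes() == 0:
        logger.warning("%s: writing empty network", path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(net.edges()):
                gene, tissue = (u, v) if net.nodes[u].get("kind") == "gene" else (v, u)
                fh.write(f"{gene}\textreme_in\t{tissue}\n")
    else:
        out = nx.Graph()
        for node, attrs in net.nodes(data=True):
            out.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
        for u, v, attrs in net.edges(data=True):
            out.add_edge(u, v, **{k: v for k, v in attrs.items() if v is not None})
        nx.write_graphml(out, path)


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
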