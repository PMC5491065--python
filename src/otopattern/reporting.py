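"""Result tables: per-group probe/gene counts, top-N gene rankings, and
transcription-factor subsetting by GO annotation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ValidationError
from .io import AnnotationTable
from .patterns import GROUP_LABEL_ORDER

logger = logging.getLogger(__name__)

GO_TRANSCRIPTION = "GO:0006351"


@dataclass
class GroupReport:
    group_label: str
    probe_count: int
    gene_count: int
    top_genes: pd.DataFrame = field(repr=False)
    tf_genes: pd.DataFrame = field(repr=False)


def group_counts(
    assignments: pd.DataFrame,
    gene_tables: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-group probe (and optionally gene) counts plus totals.

    Asserts the partition identity: the six probe counts sum exactly to
    the number of significant, assignable probes.  The returned frame is
    the Venn-count summary — one mutually exclusive count per group.
    """
    assigned = assignments[
        assignments["significant"] & assignments["assignable"]
    ]
    counts = assigned["group"].value_counts()
    labels = [l for l in GROUP_LABEL_ORDER if l in counts.index] + [
        l for l in counts.index if l not in GROUP_LABEL_ORDER
    ]
    labels = labels or list(GROUP_LABEL_ORDER)
    probe_counts = counts.reindex(labels, fill_value=0).astype(int)
    if probe_counts.sum() != len(assigned):
        raise ValidationError(
            "group probe counts do not partition the assigned probes"
        )
    out = pd.DataFrame({"probe_count": probe_counts})
    if gene_tables is not None:
        out["gene_count"] = [
            len(gene_tables.get(lbl, ())) for lbl in out.index
        ]
    out.loc["total"] = out.sum()
    out.index.name = "group"
    return out


def top_genes(gene_table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """The ``n`` genes with the largest log2 fold change, descending; ties
    broken by gene-symbol lexicographic order."""
    if n <= 0:
        raise ValidationError("n must be positive")
    ranked = gene_table.sort_values(
        ["log2_fc", "gene_symbol"], ascending=[False, True], kind="stable"
    )
    return ranked.head(n).reset_index(drop=True)


def subset_transcription_factors(
    gene_table: pd.DataFrame,
    annotation: AnnotationTable,
    go_id: str = GO_TRANSCRIPTION,
    tf_catalogue: set[str] | None = None,
) -> pd.DataFrame:
    """Genes of a group table annotated with ``go_id`` (default the
    DNA-templated-transcription term), optionally refined by intersection
    with a user-supplied transcription-factor catalogue."""
    tf_genes = annotation.genes_with_go(go_id)
    if not tf_genes:
        logger.warning("GO id %s absent from the entire annotation", go_id)
        return gene_table.iloc[0:0].reset_index(drop=True)
    keep = gene_table["gene_symbol"].isin(tf_genes)
    if tf_catalogue is not None:
        keep &= gene_table["gene_symbol"].isin(tf_catalogue)
    return gene_table[keep].reset_index(drop=True)


def build_group_reports(
    assignments: pd.DataFrame,
    gene_tables: dict[str, pd.DataFrame],
    annotation: AnnotationTable,
    n_top: int = 10,
    go_id: str = GO_TRANSCRIPTION,
    tf_catalogue: set[str] | None = None,
) -> list[GroupReport]:
    """One :class:`GroupReport` per group label, in report order."""
    counts = group_counts(assignments, gene_tables)
    reports = []
    for label in counts.index:
        if label == "total":
            continue
        table = gene_tables.get(label, pd.DataFrame(
            columns=["gene_symbol", "probe_id", "q", "log2_fc"]))
        reports.append(
            GroupReport(
                group_label=label,
                probe_count=int(counts.loc[label, "probe_count"]),
                gene_count=len(table),
                top_genes=top_genes(table, n_top) if len(table) else table,
                tf_genes=subset_transcription_factors(
                    table, annotation, go_id=go_id, tf_catalogue=tf_catalogue
                ),
            )
        )
    return reports
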