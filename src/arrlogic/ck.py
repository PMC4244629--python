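"""Overlap of exogenous-cytokinin DEGs with the mutant regulatory structure.

Genes responding to exogenous CK treatment in wild type are classified
against their behaviour in the TF deletion mutants: a gene up-regulated by
CK and down-regulated in the mutants ("up_dw") behaves as a direct positive
target of the duplicated activators, and its group suffix (G1–G5, else
"Others") records which part of the regulatory structure carries it —
e.g. "up_dwG2" genes are redundantly regulated by two of the three TFs.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = ("up_up", "up_dw", "dw_up", "dw_dw", "ck_only")


def _mutant_direction(gene: str,
                      cluster_table: pd.DataFrame,
                      mutant_calls: pd.DataFrame) -> str | None:
    """U/D/none for one gene; None signals an excluded tie."""
    if gene in cluster_table.index:
        row = cluster_table.loc[gene]
        if isinstance(row, pd.DataFrame):
            raise ValueError(f"gene {gene!r} has multiple cluster rows")
        if row["cluster"] > 0:
            return str(row["direction"])
    if gene in mutant_calls.index:
        calls = mutant_calls.loc[gene]
        n_up = int((calls == "U").sum())
        n_down = int((calls == "D").sum())
        if n_up == 0 and n_down == 0:
            return "none"
        if n_up == n_down:
            return None  # direction tie: excluded, caller logs
        return "U" if n_up > n_down else "D"
    return "none"


def classify_ck_overlap(ck_table: pd.DataFrame,
                        cluster_table: pd.DataFrame,
                        mutant_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CK-vs-mutant classification.

    ``ck_table`` is the CK-comparison statistic table (only rows with call
    U or D are classified); ``cluster_table`` carries cluster, direction,
    group and selected flags from the logic stage; ``mutant_calls`` is the
    genes × 7 U/D/N pattern frame, used for the direction of genes that are
    mutant DEGs but failed logic mapping.  Genes whose unmapped mutant
    calls tie between U and D are excluded and logged.  The ``focus``
    column flags the up-in-CK/down-in-mutants view (the expected direction
    for targets of positive regulators) without filtering anything.
    """
    degs = ck_table[ck_table["call"].isin(["U", "D"])]
    rows = {}
    excluded: list[str] = []
    for gene, row in degs.iterrows():
        ck_call = str(row["call"])
        mut = _mutant_direction(gene, cluster_table, mutant_calls)
        if mut is None:
            excluded.append(gene)
            continue
        if mut == "none":
            cls = "ck_only"
            suffix = ""
        else:
            cls = f"{'up' if ck_call == 'U' else 'dw'}_" \
                  f"{'up' if mut == 'U' else 'dw'}"
            suffix = "Others"
            if gene in cluster_table.index:
                crow = cluster_table.loc[gene]
                if bool(crow.get("selected", False)) \
                        and str(crow.get("group", "none")) != "none":
                    suffix = str(crow["group"])
        cluster = 0
        if gene in cluster_table.index:
            cluster = int(cluster_table.loc[gene, "cluster"])
        rows[gene] = (ck_call, mut, cls, suffix, f"{cls}{suffix}",
                      cluster, cls == "up_dw")
    if excluded:
        logger.warning("excluded %d CK DEGs with tied unmapped mutant "
                       "direction: %s", len(excluded), excluded[:10])
    out = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["ck_call", "mutant_direction", "class", "group_suffix",
                 "label", "cluster", "focus"]).rename_axis("gene_id")
    out.attrs["excluded_ties"] = excluded
    return out


def summarize_overlap(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Counts per (class, group suffix) with per-cluster breakdowns.

    Rows with ``cluster`` 0 aggregate a whole (class, suffix) cell; the
    cluster-level rows within each cell sum to it, so e.g. the up_dwG2
    total equals the sum of its per-cluster counts.
    """
    rows = []
    for (cls, suffix), sub in per_gene.groupby(["class", "group_suffix"]):
        rows.append({"class": cls, "group_suffix": suffix, "cluster": 0,
                     "count": int(len(sub))})
        for cluster, csub in sub[sub["cluster"] > 0].groupby("cluster"):
            rows.append({"class": cls, "group_suffix": suffix,
                         "cluster": int(cluster), "count": int(len(csub))})
    return pd.DataFrame(rows,
                        columns=["class", "group_suffix", "cluster", "count"])


def class_counts(per_gene: pd.DataFrame) -> dict[str, int]:
    """Total genes per class; sums to the number of classified CK DEGs."""
    counts = per_gene["class"].value_counts()
    return {c: int(counts.get(c, 0)) for c in CLASSES}
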