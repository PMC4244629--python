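"""Count aggregation for run reports.

The headline numbers of a run are simple aggregates: per-comparison and
per-category DEG counts split by direction, cluster sizes, and significant
node counts.  Totals are always the sum of their up and down components
(a gene called in both directions across a category's comparisons is
counted once in each component).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

SINGLE = ("arr1", "arr10", "arr12")
DOUBLE = ("arr1/10", "arr1/12", "arr10/12")
TRIPLE = ("arr1/10/12",)

CATEGORIES: dict[str, tuple[str, ...]] = {
    "single": SINGLE,
    "double": DOUBLE,
    "triple": TRIPLE,
}


def directional_counts(call_tables: Mapping[str, pd.DataFrame],
                       comparisons: Sequence[str]) -> dict[str, int]:
    """Distinct up/down genes over a set of comparisons, plus their sum."""
    up: set = set()
    down: set = set()
    for label in comparisons:
        t = call_tables[label]
        up |= set(t.index[t["call"] == "U"])
        down |= set(t.index[t["call"] == "D"])
    return {"up": len(up), "down": len(down), "total": len(up) + len(down)}


def deg_count_summary(call_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-comparison and per-category DEG counts (up + down = total)."""
    rows = []
    for label, t in call_tables.items():
        c = directional_counts(call_tables, [label])
        rows.append({"scope": label, **c})
    for cat, labels in CATEGORIES.items():
        if all(lab in call_tables for lab in labels):
            rows.append({"scope": cat,
                         **directional_counts(call_tables, labels)})
    return pd.DataFrame(rows).set_index("scope")


def directional_node_counts(flags: pd.Series,
                            directions: pd.Series) -> dict[str, int]:
    """Significant nodes split by regulation direction.

    ``flags``: boolean significance per node; ``directions``: U/D per gene
    (e.g. the mapped cluster direction).  Nodes without a direction are
    dropped; the total is up + down.
    """
    sig = flags[flags].index
    d = directions.reindex(sig).dropna()
    up = int((d == "U").sum())
    down = int((d == "D").sum())
    return {"up": up, "down": down, "total": up + down}


def cluster_size_table(cluster_table: pd.DataFrame) -> pd.DataFrame:
    """Cluster sizes by direction, with selection flags echoed."""
    mapped = cluster_table[cluster_table["cluster"] > 0]
    rows = []
    for (cluster, direction), sub in mapped.groupby(["cluster", "direction"]):
        rows.append({"cluster": int(cluster), "direction": direction,
                     "size": int(len(sub)),
                     "selected": bool(sub["selected"].iloc[0]),
                     "group": sub["group"].iloc[0]})
    return pd.DataFrame(rows, columns=["cluster", "direction", "size",
                                       "selected", "group"])
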