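"""Gene-set over-representation: one-tailed Fisher test with EASE variant.

For a query of n genes from a universe of N, a term with K members and k of
them in the query has p = P(X ≥ k) under the hypergeometric distribution.
The EASE variant recomputes with k−1 (floor 0) — the conservative score a
widely used annotation server reports — and is always ≥ the plain Fisher p.
A Benjamini–Hochberg column is attached for transparency; the pass flag uses
the raw p at the requested threshold (default 0.1).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_upper_tail(overlap: int, universe: int, term_size: int,
                         query_size: int) -> float:
    """P(X ≥ overlap) for X ~ Hypergeom(universe, term_size, query_size)."""
    if overlap <= 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe, term_size, query_size))


def fisher_enrichment(query: Iterable[str],
                      annotation: Mapping[str, Iterable[str]],
                      universe: Iterable[str],
                      variant: str = "fisher",
                      threshold: float = 0.1) -> pd.DataFrame:
    """Per-term over-representation of a query gene list.

    Both the plain Fisher p and the EASE score are always computed;
    ``variant`` chooses which one drives the pass flag and the sort.
    The universe defaults in callers to all genes on the platform, not the
    DEG list.  Results are sorted by the governing p, ties by term.
    """
    if variant not in ("fisher", "ease"):
        raise ValueError(f"unknown variant {variant!r}")
    uni = set(universe)
    q = set(query)
    if not uni:
        raise ValueError("empty universe")
    if not q:
        raise ValueError("empty query")
    stray = q - uni
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    rows = []
    for term, genes in annotation.items():
        members = set(genes) & uni
        k = len(members & q)
        p = hypergeom_upper_tail(k, len(uni), len(members), len(q))
        ease = hypergeom_upper_tail(max(k - 1, 0), len(uni), len(members),
                                    len(q))
        rows.append({"term": term, "overlap": k, "query_size": len(q),
                     "term_size": len(members), "universe_size": len(uni),
                     "p": p, "ease_p": ease})
    out = pd.DataFrame(rows, columns=["term", "overlap", "query_size",
                                      "term_size", "universe_size",
                                      "p", "ease_p"])
    if out.empty:
        out["bh_q"] = np.nan
        out["passes"] = pd.Series(dtype=bool)
        return out.set_index("term")
    governing = out["ease_p"] if variant == "ease" else out["p"]
    out["bh_q"] = multipletests(governing, method="fdr_bh")[1]
    out["passes"] = governing < threshold
    out = out.assign(_g=governing).sort_values(["_g", "term"]).drop(columns="_g")
    return out.set_index("term")
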