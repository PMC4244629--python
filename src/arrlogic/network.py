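"""Empirical-null node significance and membership tabulations.

Hub-like molecules are nodes whose degree sits in the upper tail of the
network-wide degree distribution (empirical p < 0.05); the same machinery
applies to local clustering coefficients.  The default "exact" mode uses the
upper-tail ECDF over all nodes; a sampled mode (draws with replacement,
seeded) mirrors the approximate procedure of estimating that null from
100,000 random draws.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

ALPHA_DEFAULT = 0.05


def _check_simple(graph: nx.Graph) -> None:
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if any(u == v for u, v in nx.selfloop_edges(graph)):
        raise ValueError("self-loops are not allowed")


def clustering_coefficients(graph: nx.Graph) -> pd.Series:
    """Local clustering coefficient c = 2e/(k(k−1)); c = 0 for degree < 2."""
    _check_simple(graph)
    cc = nx.clustering(graph)
    return pd.Series(cc, name="clustering_coefficient").sort_index()


def node_significance(graph: nx.Graph,
                      statistic: str = "degree",
                      mode: str = "exact",
                      n_samples: int = 100_000,
                      seed: int | None = None,
                      alpha: float = ALPHA_DEFAULT,
                      restrict_to: Iterable[str] | None = None) -> pd.DataFrame:
    """Upper-tail empirical p-value of a node statistic for every node.

    ``exact``: p = #{nodes with statistic ≥ observed} / n over all nodes
    (the observed node counts itself, so p is never 0).  ``sampled``:
    the null is ``n_samples`` draws with replacement from the node
    statistics and p = (1 + #{draws ≥ observed}) / (1 + n_samples).
    ``restrict_to`` limits the reported rows (e.g. to DEGs) while the null
    still uses every node.  Nodes absent from the network get no row.
    """
    _check_simple(graph)
    if statistic == "degree":
        values = pd.Series(dict(graph.degree()), name="degree")
    elif statistic == "clustering_coefficient":
        values = clustering_coefficients(graph)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    values = values.sort_index()
    pool = np.sort(values.to_numpy(dtype=float))
    n = pool.size
    obs = values.to_numpy(dtype=float)
    if mode == "exact":
        p = (n - np.searchsorted(pool, obs, side="left")) / n
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        draws = np.sort(rng.choice(pool, size=n_samples, replace=True))
        count = n_samples - np.searchsorted(draws, obs, side="left")
        p = (1.0 + count) / (1.0 + n_samples)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame({
        statistic: values,
        "p": p,
        "significant": p < alpha,
    }).rename_axis("node")
    if restrict_to is not None:
        keep = out.index.intersection(list(restrict_to))
        out = out.loc[keep]
    return out


def node_stats(graph: nx.Graph,
               mode: str = "exact",
               n_samples: int = 100_000,
               seed: int | None = None,
               alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Combined per-node table: degree, clustering coefficient, both
    empirical p-values and the hub / high-clustering flags."""
    ss = np.random.SeedSequence(seed).spawn(2)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss]
    deg = node_significance(graph, "degree", mode, n_samples, seeds[0], alpha)
    cc = node_significance(graph, "clustering_coefficient", mode, n_samples,
                           seeds[1], alpha)
    return pd.DataFrame({
        "degree": deg["degree"],
        "clustering_coefficient": cc["clustering_coefficient"],
        "p_degree": deg["p"],
        "p_cc": cc["p"],
        "hub": deg["significant"],
        "high_cc": cc["significant"],
    }).rename_axis("node")


def group_fraction_table(classes: pd.Series,
                         target_sets: Mapping[str, object]) -> pd.DataFrame:
    """Membership counts and fractions of gene classes within target sets.

    ``classes`` maps gene → class label (e.g. group or cluster).  Each
    target set is either a plain gene collection or a DataFrame with
    ``gene_id`` and ``layer`` columns (layer-stratified rows are then
    emitted in addition to the whole-set rows).  The fraction is the count
    divided by the *set* size, with the percent rounded to one decimal as
    conventionally reported; an empty set yields a flagged row with an
    undefined fraction.
    """
    classes = classes.dropna()
    rows = []

    def _emit(set_name: str, layer: str, members: set[str]) -> None:
        size = len(members)
        in_set = classes[classes.index.isin(members)]
        if size == 0:
            rows.append({"set": set_name, "layer": layer, "class": "none",
                         "count": 0, "set_size": 0,
                         "fraction": np.nan, "percent": np.nan,
                         "undefined": True})
            return
        for cls, sub in in_set.groupby(in_set):
            frac = len(sub) / size
            rows.append({"set": set_name, "layer": layer, "class": str(cls),
                         "count": int(len(sub)), "set_size": size,
                         "fraction": frac,
                         "percent": round(100.0 * frac, 1),
                         "undefined": False})

    for name, target in target_sets.items():
        if isinstance(target, pd.DataFrame):
            members = set(target["gene_id"])
            _emit(name, "all", members)
            for layer, sub in target.groupby("layer"):
                _emit(name, str(layer), set(sub["gene_id"]))
        else:
            _emit(name, "all", set(target))
    return pd.DataFrame(
        rows, columns=["set", "layer", "class", "count", "set_size",
                       "fraction", "percent", "undefined"])


def membership_fraction(count: int, set_size: int) -> float:
    """One membership fraction as a one-decimal percent (report convention)."""
    if set_size <= 0:
        raise ValueError("set size must be positive")
    return round(100.0 * count / set_size, 1)
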