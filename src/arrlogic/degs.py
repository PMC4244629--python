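"""Integrative differential-expression statistic with permutation nulls.

For each gene and comparison two statistics are computed on the log2 scale:
a pooled-variance Student's t (T) and the log2-median-ratio
(M = median(test) − median(ref)).  Their empirical null distributions are
built by relabeling the comparison's samples into the two groups in every
non-identity balanced way (exhaustive when feasible, seeded sampling
otherwise) and pooling the recomputed statistics across genes.  One-sided
empirical p-values with an add-one pseudocount are combined with Stouffer's
method, and a gene is called differentially expressed when the combined
p-value passes alpha AND |M| exceeds the per-comparison fold-change cutoff,
the 95th percentile of the null |M| distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

_P_CLAMP = 1e-15


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-group comparison: test samples versus reference samples."""

    label: str
    test_ids: tuple[str, ...]
    ref_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.test_ids) < 2 or len(self.ref_ids) < 2:
            raise ValueError(f"{self.label}: each group needs >= 2 samples")
        if set(self.test_ids) & set(self.ref_ids):
            raise ValueError(f"{self.label}: groups overlap")


@dataclass
class NullDistributions:
    """Pooled permutation nulls for one comparison."""

    t_values: np.ndarray
    m_values: np.ndarray
    n_permutations: int
    scheme: str

    def __post_init__(self) -> None:
        if self.t_values.size == 0 or self.m_values.size == 0:
            raise ValueError("empty null distribution")


def compute_gene_stats(values_test: np.ndarray,
                       values_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-variance t and log2-median-ratio, vectorized over genes.

    Inputs are genes × replicates arrays (1-D inputs are treated as a single
    gene).  Zero pooled variance yields t = 0 when the group means agree and
    ±inf otherwise.
    """
    a = np.atleast_2d(np.asarray(values_test, dtype=float))
    b = np.atleast_2d(np.asarray(values_ref, dtype=float))
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite expression values")
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    sp2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) \
        / (n1 + n2 - 2)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        degenerate = sp2 == 0
        t = np.where(degenerate & (diff == 0), 0.0, t)
        t = np.where(degenerate & (diff != 0), np.sign(diff) * np.inf, t)
    m = np.median(a, axis=1) - np.median(b, axis=1)
    if np.ndim(values_test) == 1:
        return float(t[0]), float(m[0])
    return t, m


def _balanced_assignments(n_pool: int, n_test: int) -> list[tuple[int, ...]]:
    """All choices of test-group indices from the pooled samples."""
    return list(itertools.combinations(range(n_pool), n_test))


def build_permutation_null(matrix: pd.DataFrame,
                           spec: ComparisonSpec,
                           max_perms: int = 1000,
                           seed: int | None = None) -> NullDistributions:
    """Pool T and M over all (or sampled) non-identity relabelings.

    Samples of the comparison are pooled and re-split into groups of the
    original sizes; the identity split is excluded.  With a 2v2 design this
    enumerates the C(4,2)−1 = 5 non-identity assignments exhaustively;
    larger designs fall back to seeded sampling without the identity once
    the count exceeds ``max_perms``.  Statistics are pooled across genes
    into one common null per statistic.
    """
    cols = list(spec.test_ids) + list(spec.ref_ids)
    values = matrix[cols].to_numpy(dtype=float)
    n_test = len(spec.test_ids)
    assignments = _balanced_assignments(len(cols), n_test)
    identity = tuple(range(n_test))
    assignments = [a for a in assignments if a != identity]
    if len(assignments) < 2:
        raise ValueError("fewer than 2 distinct permutations available")
    if len(assignments) > max_perms:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(assignments), size=max_perms, replace=False)
        assignments = [assignments[i] for i in sorted(idx)]
        scheme = f"sampled {max_perms} balanced relabelings"
    else:
        scheme = f"exhaustive {len(assignments)} balanced relabelings"
    t_all, m_all = [], []
    all_idx = set(range(len(cols)))
    for a in assignments:
        ref_idx = sorted(all_idx - set(a))
        t, m = compute_gene_stats(values[:, list(a)], values[:, ref_idx])
        t_all.append(t)
        m_all.append(m)
    return NullDistributions(
        t_values=np.concatenate(t_all),
        m_values=np.concatenate(m_all),
        n_permutations=len(assignments),
        scheme=scheme,
    )


def empirical_pvalue(observed, null_values: np.ndarray,
                     side: str = "auto"):
    """One-sided empirical p with add-one pseudocount.

    For a positive observation p = (1 + #{null ≥ obs}) / (1 + N), mirrored
    for a negative one; ``side`` may force ``greater`` or ``less``.  The
    pseudocount keeps p within [1/(N+1), 1] so a permutation p-value is
    never exactly zero.
    """
    null_sorted = np.sort(np.asarray(null_values, dtype=float))
    n = null_sorted.size
    if n == 0:
        raise ValueError("empty null distribution")
    obs = np.atleast_1d(np.asarray(observed, dtype=float))
    if side == "auto":
        upper = obs >= 0
    elif side == "greater":
        upper = np.ones(obs.shape, dtype=bool)
    elif side == "less":
        upper = np.zeros(obs.shape, dtype=bool)
    else:
        raise ValueError(f"unknown side {side!r}")
    ge = n - np.searchsorted(null_sorted, obs, side="left")
    le = np.searchsorted(null_sorted, obs, side="right")
    count = np.where(upper, ge, le)
    p = (1.0 + count) / (1.0 + n)
    return float(p[0]) if np.ndim(observed) == 0 else p


def stouffer_combine(p_t, p_m):
    """Stouffer combination of two one-sided p-values.

    z_i = Φ⁻¹(1 − p_i), z_c = (z_t + z_m)/√2, p = 1 − Φ(z_c).  Inputs are
    clamped to [1e-15, 1 − 1e-15] so infinite z-scores cannot arise.
    """
    pt = np.clip(np.asarray(p_t, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    pm = np.clip(np.asarray(p_m, dtype=float), _P_CLAMP, 1 - _P_CLAMP)
    z = (sps.norm.isf(pt) + sps.norm.isf(pm)) / np.sqrt(2.0)
    p = sps.norm.sf(z)
    return float(p) if np.ndim(p_t) == 0 else p


def call_degs(t_stat: pd.Series,
              log2_median_ratio: pd.Series,
              null: NullDistributions,
              alpha: float = 0.05,
              fc_quantile: float = 0.95) -> pd.DataFrame:
    """Dual-gate DEG calls for one comparison.

    The fold-change cutoff is the ``fc_quantile`` quantile (linear
    interpolation) of the null |M| distribution — data-derived per
    comparison, never a fixed constant.  A gene is U or D when the combined
    p-value is ≤ alpha AND |M| ≥ that cutoff, with direction = sign(M);
    otherwise N.  A BH-adjusted column of the combined p is attached for
    transparency but plays no part in the calls.
    """
    t = t_stat.to_numpy(dtype=float)
    m = log2_median_ratio.to_numpy(dtype=float)
    p_t = empirical_pvalue(t, null.t_values)
    p_m = empirical_pvalue(m, null.m_values)
    p_c = stouffer_combine(p_t, p_m)
    fc_cutoff = float(np.quantile(np.abs(null.m_values), fc_quantile))
    passes = (p_c <= alpha) & (np.abs(m) >= fc_cutoff) & (m != 0)
    call = np.where(passes, np.where(m > 0, "U", "D"), "N")
    bh = multipletests(p_c, method="fdr_bh")[1]
    return pd.DataFrame({
        "t_stat": t,
        "log2_median_ratio": m,
        "p_t": p_t,
        "p_m": p_m,
        "p_combined": p_c,
        "bh_q": bh,
        "fc_cutoff": fc_cutoff,
        "call": call,
    }, index=t_stat.index).rename_axis("gene_id")


def run_comparison(matrix: pd.DataFrame,
                   spec: ComparisonSpec,
                   alpha: float = 0.05,
                   fc_quantile: float = 0.95,
                   max_perms: int = 1000,
                   seed: int | None = None) -> pd.DataFrame:
    """Full per-gene statistic table for one comparison."""
    t, m = compute_gene_stats(matrix[list(spec.test_ids)].to_numpy(),
                              matrix[list(spec.ref_ids)].to_numpy())
    null = build_permutation_null(matrix, spec, max_perms=max_perms, seed=seed)
    return call_degs(pd.Series(t, index=matrix.index),
                     pd.Series(m, index=matrix.index),
                     null, alpha=alpha, fc_quantile=fc_quantile)


def run_comparisons(matrix: pd.DataFrame,
                    specs: Sequence[ComparisonSpec],
                    alpha: float = 0.05,
                    fc_quantile: float = 0.95,
                    max_perms: int = 1000,
                    seed: int | None = None) -> dict[str, pd.DataFrame]:
    """Run a batch of comparisons with per-comparison child seeds."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(specs))
    out: dict[str, pd.DataFrame] = {}
    for spec, child in zip(specs, children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        out[spec.label] = run_comparison(
            matrix, spec, alpha=alpha, fc_quantile=fc_quantile,
            max_perms=max_perms, seed=child_seed)
    return out


def deg_summary(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down/total DEG counts per comparison."""
    rows = []
    for label, t in tables.items():
        up = int((t["call"] == "U").sum())
        down = int((t["call"] == "D").sum())
        rows.append({"comparison": label, "up": up, "down": down,
                     "total": up + down})
    return pd.DataFrame(rows).set_index("comparison")
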