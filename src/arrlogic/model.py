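"""Model/Results surface tying the pipeline stages together.

:class:`KnockoutLogicModel` is built from an :class:`ExpressionStudy`
(optionally straight from files or a simulation config); ``fit()`` runs
quantile normalization, probe collapsing, the permutation DEG statistic for
the seven mutant-vs-WT comparisons (plus the CK comparison when those
samples exist), pattern encoding and logic mapping, and returns a
:class:`KnockoutLogicResults` carrying every intermediate table, the
per-comparison fold-change cutoffs, and a ``summary()`` in the style of a
statistical results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import ck as ck_mod
from . import degs, io, logic, report


class KnockoutLogicModel:
    """Boolean regulatory-logic model of a combinatorial knockout study."""

    def __init__(self, study: io.ExpressionStudy,
                 normalize: bool = True,
                 collapse: bool = True):
        self.study = study
        self.normalize = normalize
        self.collapse = collapse

    @classmethod
    def from_files(cls, matrix_path, sheet_path, **kwargs
                   ) -> "KnockoutLogicModel":
        return cls(io.read_expression_study(matrix_path, sheet_path), **kwargs)

    @classmethod
    def from_simulation(cls, config=None, seed: int | None = None, **kwargs):
        """Build from a synthetic study; returns (model, truth table)."""
        from .simulate import SimConfig, generate_expression_study
        if config is None:
            config = SimConfig(seed=0 if seed is None else seed)
        elif seed is not None:
            from dataclasses import replace
            config = replace(config, seed=seed)
        study, truth = generate_expression_study(config)
        return cls(study, **kwargs), truth

    def fit(self,
            alpha: float = 0.05,
            fc_quantile: float = 0.95,
            max_perms: int = 1000,
            mode: str = "closure",
            percentile: float = 50.0,
            n_catalogue: int = 15,
            seed: int | None = None) -> "KnockoutLogicResults":
        """Run normalize → DEG statistics → logic inference.

        ``alpha`` and ``fc_quantile`` gate the dual-threshold DEG calls;
        ``mode`` ("closure" or "strict") and ``percentile`` control pattern
        mapping and major-cluster selection; ``n_catalogue`` (15 or 18)
        bounds the reported structure catalogue.  One seed fans out to
        per-comparison child seeds so each comparison is independently
        reproducible.
        """
        matrix = self.study.matrix
        if self.normalize:
            matrix = io.quantile_normalize(matrix)
        if self.collapse and matrix.index.has_duplicates:
            matrix = io.collapse_probes(matrix)
        specs = io.mutant_comparisons(self.study)
        ck_spec = io.ck_comparison(self.study)
        all_specs = specs + ([ck_spec] if ck_spec else [])
        tables = degs.run_comparisons(
            matrix, all_specs, alpha=alpha, fc_quantile=fc_quantile,
            max_perms=max_perms, seed=seed)
        mutant_tables = {s.label: tables[s.label] for s in specs}
        ck_table = tables.get(ck_spec.label) if ck_spec else None
        patterns = logic.encode_patterns(mutant_tables)
        assignments = logic.assign_clusters(patterns, mode=mode,
                                            n_catalogue=n_catalogue)
        cluster_table = logic.cluster_select_group(assignments,
                                                   percentile=percentile)
        return KnockoutLogicResults(
            model=self,
            params={"alpha": alpha, "fc_quantile": fc_quantile,
                    "max_perms": max_perms, "mode": mode,
                    "percentile": percentile, "n_catalogue": n_catalogue,
                    "seed": seed},
            matrix=matrix,
            deg_tables=mutant_tables,
            ck_table=ck_table,
            patterns=patterns,
            cluster_table=cluster_table,
        )


@dataclass
class KnockoutLogicResults:
    """Fitted tables and diagnostics of a knockout-logic analysis."""

    model: KnockoutLogicModel
    params: dict
    matrix: pd.DataFrame
    deg_tables: Mapping[str, pd.DataFrame]
    ck_table: pd.DataFrame | None
    patterns: pd.DataFrame
    cluster_table: pd.DataFrame
    _ck_overlap: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def fc_cutoffs(self) -> pd.Series:
        """Per-comparison 95th-percentile |log2-median-ratio| cutoffs."""
        vals = {lab: float(t["fc_cutoff"].iloc[0])
                for lab, t in self.deg_tables.items()}
        if self.ck_table is not None:
            vals["WT+CK"] = float(self.ck_table["fc_cutoff"].iloc[0])
        return pd.Series(vals, name="fc_cutoff")

    @property
    def deg_counts(self) -> pd.DataFrame:
        return report.deg_count_summary(self.deg_tables)

    @property
    def cluster_sizes(self) -> pd.DataFrame:
        return report.cluster_size_table(self.cluster_table)

    @property
    def mapped_structures(self) -> list[int]:
        """Distinct cluster indices present among mapped genes."""
        mapped = self.cluster_table[self.cluster_table["cluster"] > 0]
        return sorted(mapped["cluster"].unique().tolist())

    def ck_overlap(self) -> pd.DataFrame:
        """CK-vs-mutant classification (requires the CK comparison)."""
        if self.ck_table is None:
            raise ValueError("study has no CK/mock wild-type samples")
        if self._ck_overlap is None:
            self._ck_overlap = ck_mod.classify_ck_overlap(
                self.ck_table, self.cluster_table, self.patterns)
        return self._ck_overlap

    def recovery_against(self, truth: pd.DataFrame) -> dict:
        """Structure/direction recovery versus a planted ground truth.

        ``truth`` is the simulator's table (cluster>0 rows are planted).
        Returns the fraction of planted genes mapped to their planted
        cluster and direction, plus the raw counts.
        """
        planted = truth[truth["cluster"] > 0]
        got = self.cluster_table.reindex(planted.index)
        ok = ((got["cluster"] == planted["cluster"])
              & (got["direction"] == planted["direction"])).fillna(False)
        return {"n_planted": int(len(planted)),
                "n_recovered": int(ok.sum()),
                "recovery": float(ok.mean()) if len(planted) else float("nan")}

    def summary(self) -> str:
        """Human-readable results summary."""
        lines = []
        w = 62
        lines.append("Knockout Boolean-Logic Results".center(w))
        lines.append("=" * w)
        p = self.params
        lines.append(f"Genes: {self.matrix.shape[0]:>6}    "
                     f"Samples: {self.matrix.shape[1]:>4}    "
                     f"alpha: {p['alpha']}  fc_q: {p['fc_quantile']}")
        lines.append(f"Mapping mode: {p['mode']}    "
                     f"selection percentile: {p['percentile']}    "
                     f"seed: {p['seed']}")
        lines.append("-" * w)
        lines.append(f"{'comparison':<14}{'up':>7}{'down':>7}{'total':>8}"
                     f"{'fc_cutoff':>12}")
        cuts = self.fc_cutoffs
        for lab, t in self.deg_tables.items():
            up = int((t["call"] == "U").sum())
            dn = int((t["call"] == "D").sum())
            lines.append(f"{lab:<14}{up:>7}{dn:>7}{up + dn:>8}"
                         f"{cuts[lab]:>12.3f}")
        if self.ck_table is not None:
            t = self.ck_table
            up = int((t["call"] == "U").sum())
            dn = int((t["call"] == "D").sum())
            lines.append(f"{'WT+CK':<14}{up:>7}{dn:>7}{up + dn:>8}"
                         f"{cuts['WT+CK']:>12.3f}")
        lines.append("-" * w)
        mapped = self.cluster_table[self.cluster_table["cluster"] > 0]
        unmapped = self.cluster_table[self.cluster_table["cluster"] == 0]
        lines.append(f"Patterned genes: {len(self.cluster_table):>6}   "
                     f"mapped: {len(mapped):>6}   unmapped: {len(unmapped):>5}")
        n_selected = len(mapped.loc[mapped["selected"], "cluster"].unique())
        lines.append(f"Distinct structures: {len(self.mapped_structures)}   "
                     f"clusters selected: {n_selected}")
        sizes = self.cluster_sizes
        if not sizes.empty:
            lines.append(f"{'cluster':<9}{'dir':>4}{'size':>7}{'sel':>5}"
                         f"{'group':>7}")
            for _, r in sizes.sort_values(["cluster", "direction"]).iterrows():
                lines.append(f"C{r['cluster']:<8}{r['direction']:>4}"
                             f"{r['size']:>7}{str(bool(r['selected'])):>6}"
                             f"{r['group']:>7}")
        lines.append("=" * w)
        return "\n".join(lines)
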