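"""Expression-study containers, TSV/GEO readers, quantile normalization.

The unit of all comparisons is an :class:`ExpressionStudy`: a genes × samples
log2-intensity matrix together with a sample sheet giving each column's
genotype, treatment and replicate index.  The design under study has ten
conditions — wild type and the seven deletion-mutant combinations of the
ARR1/10/12 transcription factors, untreated, plus mock- and
cytokinin-treated wild type — with two or more replicates each.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .degs import ComparisonSpec
from .logic import COMPARISON_LABELS

GENOTYPES: tuple[str, ...] = ("WT",) + COMPARISON_LABELS
TREATMENTS: tuple[str, ...] = ("none", "mock", "CK")
SHEET_COLUMNS: tuple[str, ...] = ("genotype", "treatment", "replicate")


@dataclass
class ExpressionStudy:
    """Log2 expression matrix plus per-sample metadata.

    ``matrix``: genes × samples DataFrame of log2 intensities (duplicate
    gene IDs are legal — probes collapse to genes later).  ``samples``:
    DataFrame indexed by sample ID with columns genotype, treatment,
    replicate, covering every matrix column exactly once.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.validate_on_init:
            self.validate()

    def validate(self) -> None:
        if self.matrix.shape[0] == 0 or self.matrix.shape[1] == 0:
            raise ValueError("empty expression matrix")
        missing_cols = [c for c in SHEET_COLUMNS
                        if c not in self.samples.columns]
        if missing_cols:
            raise ValueError(f"sample sheet lacks columns {missing_cols}")
        mat_ids = list(self.matrix.columns)
        sheet_ids = set(self.samples.index)
        absent = [s for s in mat_ids if s not in sheet_ids]
        if absent:
            raise ValueError(f"samples missing from sheet: {absent}")
        if len(set(mat_ids)) != len(mat_ids):
            raise ValueError("duplicate sample IDs in matrix")
        extra = sheet_ids - set(mat_ids)
        if extra:
            raise ValueError(f"sheet rows without matrix column: {sorted(extra)}")
        bad_g = set(self.samples["genotype"]) - set(GENOTYPES)
        if bad_g:
            raise ValueError(f"unknown genotype labels: {sorted(bad_g)}")
        bad_t = set(self.samples["treatment"]) - set(TREATMENTS)
        if bad_t:
            raise ValueError(f"unknown treatment labels: {sorted(bad_t)}")
        body = self.matrix.to_numpy()
        if not np.issubdtype(body.dtype, np.number):
            raise ValueError("non-numeric cells in expression matrix")

    def sample_ids(self, genotype: str, treatment: str = "none") -> list[str]:
        sel = self.samples[(self.samples["genotype"] == genotype)
                           & (self.samples["treatment"] == treatment)]
        return list(sel.index)

    def drop_missing(self) -> "ExpressionStudy":
        """Row-drop policy for missing values (opt-in)."""
        return ExpressionStudy(self.matrix.dropna(axis=0), self.samples)


def read_expression_study(matrix_path, sheet_path,
                          allow_missing: bool = False) -> ExpressionStudy:
    """Read a TSV matrix (gene rows, sample columns) and its sample sheet."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if matrix.empty:
        raise ValueError(f"empty expression matrix: {matrix_path}")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"non-numeric cells in {matrix_path}: {err}") from err
    if not allow_missing and matrix.isna().any().any():
        raise ValueError(
            f"missing values in {matrix_path}; pass allow_missing=True "
            "and apply drop_missing() to opt into the row-drop policy")
    sheet = pd.read_csv(sheet_path, sep="\t", index_col=0, dtype=str)
    if "replicate" in sheet.columns:
        sheet["replicate"] = sheet["replicate"].astype(int)
    return ExpressionStudy(matrix, sheet)


def write_expression_study(study: ExpressionStudy,
                           matrix_path, sheet_path) -> None:
    study.matrix.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    study.samples.rename_axis("sample_id").to_csv(sheet_path, sep="\t")


def read_geo_series_matrix(path) -> pd.DataFrame:
    """Matrix section of a plain-text GEO Series Matrix file.

    Only the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` is parsed (tab-separated, ID_REF first
    column); metadata lines are ignored.
    """
    lines = []
    with open(path) as fh:
        inside = False
        for line in fh:
            key = line.strip().lower()
            if key == "!series_matrix_table_begin":
                inside = True
                continue
            if key == "!series_matrix_table_end":
                break
            if inside:
                lines.append(line)
    if not lines:
        raise ValueError(f"no series-matrix table found in {path}")
    df = pd.read_csv(_stdio.StringIO("".join(lines)), sep="\t", index_col=0)
    df.columns = [c.strip('"') for c in df.columns]
    df.index = [str(i).strip('"') for i in df.index]
    return df.astype(float)


def quantile_normalize(data):
    """Quantile normalization of a matrix or study (columns = samples).

    Every column is mapped onto the common reference distribution given by
    the row means of the column-sorted matrix, so all columns end up with
    identical sorted values while each column's rank order is preserved.
    Ties within a column receive the mean of the reference quantiles they
    span (average-rank dialect), so an all-constant column maps to the mean
    of the whole reference rather than erroring.
    """
    if isinstance(data, ExpressionStudy):
        return ExpressionStudy(quantile_normalize(data.matrix), data.samples)
    df = data
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    x = df.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values; apply a missing-value policy first")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col_sorted = x[order, j]
        # each tie group takes the mean of the reference slots it occupies
        assigned = pd.Series(reference).groupby(col_sorted).transform("mean")
        out[order, j] = assigned.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def collapse_probes(matrix: pd.DataFrame,
                    probe_to_gene: pd.Series | None = None) -> pd.DataFrame:
    """Collapse probe rows to genes by the per-gene median.

    With ``probe_to_gene`` given, probe IDs are first mapped to gene IDs
    (probes absent from the map are dropped); otherwise duplicate index
    labels are treated as probes of one gene.  The median is invariant to
    probe order.
    """
    m = matrix
    if probe_to_gene is not None:
        keep = m.index.intersection(probe_to_gene.index)
        m = m.loc[keep]
        m = m.set_axis(probe_to_gene.loc[keep].to_numpy(), axis=0)
    return m.groupby(level=0, sort=True).median()


def mutant_comparisons(study: ExpressionStudy) -> list[ComparisonSpec]:
    """The seven untreated mutant-vs-WT comparison specs, canonical order."""
    ref = tuple(study.sample_ids("WT", "none"))
    specs = []
    for genotype in COMPARISON_LABELS:
        test = tuple(study.sample_ids(genotype, "none"))
        specs.append(ComparisonSpec(label=genotype, test_ids=test,
                                    ref_ids=ref))
    return specs


def ck_comparison(study: ExpressionStudy) -> ComparisonSpec | None:
    """CK-treated vs mock-treated wild type, if those samples exist."""
    test = tuple(study.sample_ids("WT", "CK"))
    mock = tuple(study.sample_ids("WT", "mock"))
    if len(test) < 2 or len(mock) < 2:
        return None
    return ComparisonSpec(label="WT+CK", test_ids=test, ref_ids=mock)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT annotation file → {term: gene set} (description field ignored)."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = {g for g in parts[2:] if g}
    return out


def write_gmt(annotation: dict[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for term, genes in annotation.items():
            fh.write("\t".join([term, term] + sorted(genes)) + "\n")


def read_edge_list(path) -> "pd.DataFrame":
    """Two-column undirected edge list TSV (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"edge list {path} needs >= 2 columns")
    return df.iloc[:, :2].set_axis(["source", "target"], axis=1)


def write_edge_list(graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\n")
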