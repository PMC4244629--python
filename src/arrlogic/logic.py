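"""Monotone Boolean regulatory-structure inference from knockout patterns.

A target gene of a duplicated transcription-factor family is modelled by a
monotone Boolean function f over TF *presence*: the gene keeps its wild-type
expression level while f is satisfied and shifts once f fails.  In canonical
form f is the antichain of its minimal sufficient TF subsets (minimal DNF):
``1∨12`` means either ARR1 or ARR12 alone suffices, ``1∧10∧12`` means all
three are required.  A deletion genotype S switches the gene off exactly when
S intersects every minimal sufficient subset (the monotone hitting-set
criterion), which yields a predicted set of changed comparisons for each
structure.  Inference inverts this map: a gene's U/D/N call pattern over the
seven mutant-vs-WT comparisons is matched against the predicted changed sets
of all candidate structures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The three duplicated type-B ARR transcription factors.
TFS: tuple[int, ...] = (1, 10, 12)

#: Canonical comparison order: singles, doubles, triple.
DELETION_SETS: tuple[frozenset[int], ...] = (
    frozenset({1}),
    frozenset({10}),
    frozenset({12}),
    frozenset({1, 10}),
    frozenset({1, 12}),
    frozenset({10, 12}),
    frozenset({1, 10, 12}),
)

COMPARISON_LABELS: tuple[str, ...] = (
    "arr1",
    "arr10",
    "arr12",
    "arr1/10",
    "arr1/12",
    "arr10/12",
    "arr1/10/12",
)

#: Fixed cluster numbering for the 15 structures reported for this family,
#: plus the three x∧(y∨z) forms (16-18) that complete the candidate space.
_CLUSTER_ORDER: tuple[frozenset[frozenset[int]], ...] = (
    frozenset({frozenset({1})}),                                      # C1
    frozenset({frozenset({10})}),                                     # C2
    frozenset({frozenset({12})}),                                     # C3
    frozenset({frozenset({1, 10})}),                                  # C4
    frozenset({frozenset({1}), frozenset({10})}),                     # C5
    frozenset({frozenset({1, 12})}),                                  # C6
    frozenset({frozenset({1}), frozenset({12})}),                     # C7
    frozenset({frozenset({10, 12})}),                                 # C8
    frozenset({frozenset({10}), frozenset({12})}),                    # C9
    frozenset({frozenset({1, 10, 12})}),                              # C10
    frozenset({frozenset({1, 10}), frozenset({1, 12}),
               frozenset({10, 12})}),                                 # C11
    frozenset({frozenset({1}), frozenset({10, 12})}),                 # C12
    frozenset({frozenset({10}), frozenset({1, 12})}),                 # C13
    frozenset({frozenset({12}), frozenset({1, 10})}),                 # C14
    frozenset({frozenset({1}), frozenset({10}), frozenset({12})}),    # C15
    frozenset({frozenset({1, 10}), frozenset({1, 12})}),              # C16: 1∧(10∨12)
    frozenset({frozenset({1, 10}), frozenset({10, 12})}),             # C17: 10∧(1∨12)
    frozenset({frozenset({1, 12}), frozenset({10, 12})}),             # C18: 12∧(1∨10)
)

#: Group assignment over selected clusters: unique-TF, pairwise-OR,
#: triple-AND, triple-OR, mixed AND/OR.
DEFAULT_GROUP_MAP: Mapping[int, str] = {
    1: "G1", 2: "G1", 3: "G1",
    5: "G2", 7: "G2", 9: "G2",
    10: "G3",
    15: "G4",
    11: "G5", 12: "G5",
}

AND = "∧"
OR = "∨"


def _label_antichain(terms: frozenset[frozenset[int]]) -> str:
    """Human-readable label, e.g. ``1∨(10∧12)`` or ``1∧(10∨12)``."""
    sorted_terms = sorted(terms, key=lambda t: (len(t), tuple(sorted(t))))
    if len(sorted_terms) == 1:
        return AND.join(str(x) for x in sorted(sorted_terms[0]))
    # Factor a shared conjunct when the residuals are singletons: the three
    # x∧(y∨z) structures read better factored than as raw DNF.
    common = frozenset.intersection(*sorted_terms)
    residuals = [t - common for t in sorted_terms]
    if common and all(len(r) == 1 for r in residuals):
        head = AND.join(str(x) for x in sorted(common))
        tail = OR.join(str(next(iter(r))) for r in
                       sorted(residuals, key=lambda r: tuple(sorted(r))))
        return f"{head}{AND}({tail})"
    parts = []
    for t in sorted_terms:
        s = AND.join(str(x) for x in sorted(t))
        parts.append(f"({s})" if len(t) > 1 else s)
    return OR.join(parts)


@dataclass(frozen=True)
class LogicStructure:
    """A non-constant monotone Boolean function in antichain form.

    ``terms`` is the family of minimal sufficient TF subsets; the function is
    satisfied by a set P of present TFs iff some term is contained in P.
    """

    terms: frozenset[frozenset[int]]
    label: str = field(compare=False, default="")
    cluster: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if not self.terms or any(len(t) == 0 for t in self.terms):
            raise ValueError("antichain must consist of nonempty subsets")
        for a, b in itertools.permutations(self.terms, 2):
            if a < b:
                raise ValueError(f"not an antichain: {set(a)} ⊂ {set(b)}")
        if not self.label:
            object.__setattr__(self, "label", _label_antichain(self.terms))

    def satisfied(self, present: Iterable[int]) -> bool:
        p = frozenset(present)
        return any(t <= p for t in self.terms)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def enumerate_structures(n_tfs: int = 3,
                         tfs: Sequence[int] = TFS) -> list[LogicStructure]:
    """All non-constant monotone Boolean functions over ``n_tfs`` regulators.

    Enumerated as antichains of nonempty TF subsets (the minimal DNF of a
    monotone function is exactly such an antichain, and every such antichain
    arises).  For 3 TFs there are 18 — the Dedekind count 20 minus the two
    constants.  The first 15 carry the fixed cluster numbering; the three
    x∧(y∨z) forms are numbered 16-18.
    """
    if n_tfs < 1:
        raise ValueError("n_tfs must be >= 1")
    if n_tfs > 4:
        raise ValueError("enumeration beyond 4 regulators is not supported")
    universe = tuple(tfs[:n_tfs])
    subsets = [frozenset(c)
               for r in range(1, n_tfs + 1)
               for c in itertools.combinations(universe, r)]
    out: list[LogicStructure] = []
    for r in range(1, len(subsets) + 1):
        for family in itertools.combinations(subsets, r):
            if any(a < b or b < a
                   for a, b in itertools.combinations(family, 2)):
                continue
            out.append(LogicStructure(frozenset(family)))
    if tuple(universe) == TFS:
        index = {s: i + 1 for i, s in enumerate(_CLUSTER_ORDER)}
        out = [LogicStructure(s.terms, s.label, index[s.terms]) for s in out]
        out.sort(key=lambda s: s.cluster)
    return out


def predict_changed_set(structure: LogicStructure,
                        tfs: Sequence[int] = TFS) -> frozenset[frozenset[int]]:
    """Deletion sets that switch the structure off.

    A deletion set S leaves no minimal sufficient subset intact exactly when
    S intersects every term, so the predicted changed comparisons are the
    hitting sets of the antichain.
    """
    out = set()
    for r in range(1, len(tfs) + 1):
        for c in itertools.combinations(tfs, r):
            s = frozenset(c)
            if all(s & t for t in structure.terms):
                out.add(s)
    return frozenset(out)


def changed_comparison_indices(structure: LogicStructure) -> frozenset[int]:
    """Indices (0-6, canonical order) of comparisons predicted to change."""
    changed = predict_changed_set(structure)
    return frozenset(i for i, s in enumerate(DELETION_SETS) if s in changed)


def superset_closure(
        deletion_sets: Iterable[frozenset[int]],
        tfs: Sequence[int] = TFS) -> frozenset[frozenset[int]]:
    """Close a family of deletion sets upward under superset.

    Monotonicity of the planted logic implies that if deleting S changes a
    gene, deleting any S' ⊇ S changes it too; closure imputes calls missed
    in the implied comparisons.
    """
    base = frozenset(frozenset(s) for s in deletion_sets)
    out = set()
    for r in range(1, len(tfs) + 1):
        for c in itertools.combinations(tfs, r):
            s = frozenset(c)
            if any(b <= s for b in base):
                out.add(s)
    return frozenset(out)


class _Catalogue:
    """Lazy lookup tables from predicted changed sets back to structures."""

    def __init__(self) -> None:
        self.structures = enumerate_structures(3)
        self.by_changed_set = {predict_changed_set(s): s
                               for s in self.structures}
        self.by_cluster = {s.cluster: s for s in self.structures}
        self.by_label = {s.label: s for s in self.structures}


_CATALOGUE: _Catalogue | None = None


def catalogue() -> _Catalogue:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = _Catalogue()
    return _CATALOGUE


def encode_patterns(call_tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """U/D/N pattern vectors over the seven comparisons.

    ``call_tables`` maps each comparison label to a per-gene table holding a
    ``call`` column (U/D/N).  All seven comparisons must be present and share
    one gene universe.  Returns a genes × 7 DataFrame of symbols; the
    all-N rows are retained (downstream mapping excludes them).
    """
    missing = [lab for lab in COMPARISON_LABELS if lab not in call_tables]
    if missing:
        raise ValueError(f"missing comparisons: {missing}")
    cols = {}
    genes = None
    for lab in COMPARISON_LABELS:
        t = call_tables[lab]
        calls = t["call"] if "call" in t else t.iloc[:, 0]
        if genes is None:
            genes = calls.index
        elif not genes.equals(calls.index):
            raise ValueError(f"gene universe of {lab!r} differs")
        bad = set(calls.unique()) - {"U", "D", "N"}
        if bad:
            raise ValueError(f"invalid call symbols in {lab!r}: {bad}")
        cols[lab] = calls
    return pd.DataFrame(cols, index=genes)[list(COMPARISON_LABELS)]


def map_pattern_to_structure(
        pattern: Sequence[str],
        mode: str = "closure") -> tuple[LogicStructure, str] | None:
    """Map one 7-symbol U/D/N pattern to a (structure, direction) pair.

    Patterns whose changed entries mix U and D are inconsistent with a single
    monotone structure and return ``None`` (unmapped), as do patterns with no
    matching structure.  In ``closure`` mode (default) the observed changed
    set is first closed upward under superset — treating a missed call in an
    implied comparison as a false negative — before the exact match; in
    ``strict`` mode the observed set must match a predicted set verbatim.
    """
    if mode not in ("strict", "closure"):
        raise ValueError(f"unknown mode {mode!r}")
    pattern = list(pattern)
    if len(pattern) != len(DELETION_SETS):
        raise ValueError("pattern must have 7 entries")
    symbols = {p for p in pattern if p != "N"}
    if not symbols:
        raise ValueError("all-N pattern has no structure; exclude upstream")
    if len(symbols) > 1:
        return None
    direction = symbols.pop()
    observed = frozenset(DELETION_SETS[i]
                         for i, p in enumerate(pattern) if p != "N")
    if mode == "closure":
        observed = superset_closure(observed)
    structure = catalogue().by_changed_set.get(observed)
    if structure is None:
        return None
    return structure, direction


def assign_clusters(patterns: pd.DataFrame,
                    mode: str = "closure",
                    n_catalogue: int = 15) -> pd.DataFrame:
    """Per-gene cluster assignment from pattern vectors.

    Returns a DataFrame indexed by gene with columns ``cluster`` (0 for
    unmapped), ``label`` and ``direction``; genes with all-N patterns are
    dropped (they are not DEGs anywhere).  ``n_catalogue`` bounds the
    reported structure catalogue: with the default 15 — the structures the
    reference knockout analysis exhibits — a pattern implying one of the
    three x∧(y∨z) forms is reported unmapped; ``n_catalogue=18`` reports
    the complete monotone family.
    """
    if n_catalogue not in (15, 18):
        raise ValueError("n_catalogue must be 15 or 18")
    rows = {}
    for gene, row in patterns.iterrows():
        vec = row.tolist()
        if all(v == "N" for v in vec):
            continue
        hit = map_pattern_to_structure(vec, mode=mode)
        if hit is None or hit[0].cluster > n_catalogue:
            rows[gene] = (0, "unmapped", "".join(sorted({v for v in vec
                                                         if v != "N"})))
        else:
            s, d = hit
            rows[gene] = (s.cluster, s.label, d)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["cluster", "label", "direction"]
    ).rename_axis("gene_id")


def cluster_select_group(assignments: pd.DataFrame,
                         percentile: float = 50.0,
                         group_map: Mapping[int, str] = DEFAULT_GROUP_MAP,
                         n_catalogue: int = 15) -> pd.DataFrame:
    """Flag major clusters and assign groups.

    Independently for up- and down-regulated genes the per-cluster sizes over
    the ``n_catalogue`` numbered structures are collected (absent structures
    count as size 0) and a cluster is *selected* when its size strictly
    exceeds the requested percentile (linear interpolation) of those sizes.
    Genes in unselected or unmapped clusters keep their cluster but get
    group ``none``.
    """
    out = assignments.copy()
    out["selected"] = False
    out["group"] = "none"
    for direction in ("U", "D"):
        sub = out[(out["direction"] == direction) & (out["cluster"] > 0)
                  & (out["cluster"] <= n_catalogue)]
        sizes = np.zeros(n_catalogue)
        counts = sub["cluster"].value_counts()
        for c, n in counts.items():
            sizes[c - 1] = n
        threshold = float(np.percentile(sizes, percentile))
        chosen = {c + 1 for c in range(n_catalogue) if sizes[c] > threshold}
        mask = out.index.isin(sub.index) & out["cluster"].isin(chosen)
        out.loc[mask, "selected"] = True
        for cluster in chosen:
            g = group_map.get(cluster)
            if g is not None:
                out.loc[mask & (out["cluster"] == cluster), "group"] = g
    return out


def structure_catalogue_frame() -> pd.DataFrame:
    """The 18-structure catalogue as a tidy table (for JSON/TSV export)."""
    rows = []
    for s in catalogue().structures:
        changed = predict_changed_set(s)
        rows.append({
            "cluster": s.cluster,
            "label": s.label,
            "antichain": sorted(sorted(t) for t in s.terms),
            "changed_comparisons": [COMPARISON_LABELS[i] for i, d in
                                    enumerate(DELETION_SETS) if d in changed],
        })
    return pd.DataFrame(rows).set_index("cluster")
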