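"""Synthetic expression studies with planted Boolean regulatory structures.

The generator emulates the combinatorial-knockout design the inference
pipeline is built for: ten conditions — wild type and the seven deletion
mutant combinations of three duplicated transcription factors, untreated,
plus mock- and cytokinin-treated wild type — with two biological replicates
each by default.  Each planted target gene carries a monotone Boolean
structure over TF presence; in a genotype whose deletion set switches the
structure off, an *activated* target drops by ``effect_delta`` log2 units
below its baseline and a *repressed* target rises by the same amount.
Replicate noise is i.i.d. Gaussian on the log2 scale.  Companion generators
produce interaction networks, annotation sets and hormone-layer gene lists
so downstream stages are testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionStudy, GENOTYPES
from .logic import LogicStructure, catalogue

#: genotype label → deleted TF set
DELETION_MAP: dict[str, frozenset[int]] = {
    "WT": frozenset(),
    "arr1": frozenset({1}),
    "arr10": frozenset({10}),
    "arr12": frozenset({12}),
    "arr1/10": frozenset({1, 10}),
    "arr1/12": frozenset({1, 12}),
    "arr10/12": frozenset({10, 12}),
    "arr1/10/12": frozenset({1, 10, 12}),
}

#: (genotype, treatment) pairs defining the ten simulated conditions.
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    [(g, "none") for g in GENOTYPES] + [("WT", "mock"), ("WT", "CK")]
)


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    All expression quantities are in log2 units.  ``genes_per_structure``
    planted genes are drawn for each of the 15 catalogue structures
    (optionally all 18); a ``fraction_repressed`` share of them rise rather
    than fall when their logic fails.  ``ck_effect_delta`` is added to the
    designated CK-responsive subset in CK-treated wild type only.
    """

    n_background_genes: int = 5000
    genes_per_structure: int = 40
    effect_delta: float = 2.0
    noise_sd: float = 0.25
    baseline_mu: float = 8.0
    baseline_sd: float = 1.5
    n_replicates: int = 2
    fraction_repressed: float = 0.4
    ck_effect_delta: float = 2.0
    ck_fraction_planted: float = 0.3
    n_ck_background: int = 200
    n_structures: int = 15
    probes_per_gene: int = 1
    probe_offset_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_background_genes < 0 or self.genes_per_structure < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_background_genes + self.genes_per_structure <= 0:
            raise ValueError("study must contain at least one gene")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.fraction_repressed <= 1.0:
            raise ValueError("fraction_repressed must lie in [0, 1]")
        if not 0.0 <= self.ck_fraction_planted <= 1.0:
            raise ValueError("ck_fraction_planted must lie in [0, 1]")
        if self.n_structures not in (15, 18):
            raise ValueError("n_structures must be 15 or 18")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be >= 1")


@dataclass(frozen=True)
class PlantedGene:
    """Ground truth for one simulated gene.

    Background genes carry no structure; planted genes shift by the study's
    effect size whenever their structure is unsatisfied in a genotype.
    """

    gene_id: str
    structure: LogicStructure | None
    direction: str  # "activated" (drops when logic fails) or "repressed"
    baseline: float
    ck_responsive: bool = False

    def __post_init__(self) -> None:
        if self.direction not in ("activated", "repressed", "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.structure is None and self.direction != "none":
            raise ValueError("background genes have no direction")


def expected_expression(gene: PlantedGene, genotype: str, treatment: str,
                        config: SimConfig) -> float:
    """Noise-free expectation of one gene in one condition."""
    if genotype not in DELETION_MAP:
        raise ValueError(f"unknown genotype {genotype!r}")
    value = gene.baseline
    if gene.structure is not None:
        present = frozenset({1, 10, 12}) - DELETION_MAP[genotype]
        if not gene.structure.satisfied(present):
            sign = -1.0 if gene.direction == "activated" else 1.0
            value += sign * config.effect_delta
    if gene.ck_responsive and treatment == "CK":
        value += config.ck_effect_delta
    return value


def generate_planted_genes(config: SimConfig,
                           rng: np.random.Generator) -> list[PlantedGene]:
    """Draw the ground-truth gene list implied by a configuration."""
    structures = [s for s in catalogue().structures
                  if s.cluster <= config.n_structures]
    genes: list[PlantedGene] = []
    for s in structures:
        n_rep = int(round(config.genes_per_structure
                          * config.fraction_repressed))
        for i in range(config.genes_per_structure):
            direction = "repressed" if i < n_rep else "activated"
            genes.append(PlantedGene(
                gene_id=f"P{s.cluster:02d}{'U' if direction == 'repressed' else 'D'}_{i:04d}",
                structure=s,
                direction=direction,
                baseline=float(rng.normal(config.baseline_mu,
                                          config.baseline_sd)),
                ck_responsive=bool(rng.random() < config.ck_fraction_planted),
            ))
    n_ck_bg = min(config.n_ck_background, config.n_background_genes)
    ck_bg = set(rng.choice(config.n_background_genes, size=n_ck_bg,
                           replace=False)) if n_ck_bg else set()
    for i in range(config.n_background_genes):
        genes.append(PlantedGene(
            gene_id=f"B{i:05d}",
            structure=None,
            direction="none",
            baseline=float(rng.normal(config.baseline_mu, config.baseline_sd)),
            ck_responsive=i in ck_bg,
        ))
    return genes


def truth_frame(genes: Sequence[PlantedGene]) -> pd.DataFrame:
    """Ground truth as a tidy table (TSV-writable)."""
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id,
            "cluster": g.structure.cluster if g.structure else 0,
            "structure": g.structure.label if g.structure else "background",
            "direction": {"activated": "D", "repressed": "U",
                          "none": "N"}[g.direction],
            "ck_responsive": g.ck_responsive,
            "baseline": g.baseline,
        })
    return pd.DataFrame(rows).set_index("gene_id")


def generate_expression_study(
        config: SimConfig,
        truth: Sequence[PlantedGene] | None = None,
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Simulate one study; returns the study and its ground-truth table.

    Column order is condition-major (the ten conditions in canonical order,
    replicates within).  With ``probes_per_gene > 1`` the matrix has one row
    per probe under a duplicated gene index, each probe offset by a fixed
    Gaussian shift, to exercise probe-to-gene collapsing.
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth = generate_planted_genes(config, rng)
    sample_rows = []
    for genotype, treatment in CONDITIONS:
        for r in range(1, config.n_replicates + 1):
            tag = {"none": "", "mock": "_mock", "CK": "_CK"}[treatment]
            sid = f"{genotype.replace('/', '_')}{tag}_r{r}"
            sample_rows.append((sid, genotype, treatment, r))
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "genotype", "treatment",
                              "replicate"]).set_index("sample_id")
    n_samples = len(samples)
    expected = np.empty((len(truth), n_samples))
    for i, gene in enumerate(truth):
        for j, (_, row) in enumerate(samples.iterrows()):
            expected[i, j] = expected_expression(
                gene, row["genotype"], row["treatment"], config)
    gene_ids = [g.gene_id for g in truth]
    if config.probes_per_gene > 1:
        k = config.probes_per_gene
        offsets = rng.normal(0.0, config.probe_offset_sd,
                             size=len(truth) * k)
        expected = np.repeat(expected, k, axis=0) + offsets[:, None]
        gene_ids = [g for g in gene_ids for _ in range(k)]
    noise = rng.normal(0.0, config.noise_sd, size=expected.shape)
    matrix = pd.DataFrame(expected + noise, index=gene_ids,
                          columns=samples.index)
    return ExpressionStudy(matrix, samples), truth_frame(truth)


def generate_ppi_network(n_nodes: int, attach_m: int,
                         seed: int | None = None,
                         node_prefix: str = "N") -> nx.Graph:
    """Connected scale-free-ish interaction network (preferential attachment).

    Barabási–Albert growth yields a simple connected graph with a
    heavy-tailed degree distribution, standing in for a curated
    protein-protein interactome.
    """
    if attach_m < 1 or n_nodes <= attach_m:
        raise ValueError("need n_nodes > attach_m >= 1")
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    return nx.relabel_nodes(g, {i: f"{node_prefix}{i:05d}" for i in g.nodes})


def generate_annotation_sets(
        genes: Sequence[str],
        n_terms: int,
        size_range: tuple[int, int] = (10, 100),
        planted_enrichment: Sequence[tuple[str, Sequence[str]]] = (),
        seed: int | None = None) -> dict[str, set[str]]:
    """Random annotation terms over a gene universe, plus planted terms.

    Each of ``n_terms`` random terms draws a uniform size from
    ``size_range`` and samples genes without replacement.  Planted
    (term, subset) pairs are included verbatim so enrichment recovery can
    be asserted against a known answer.
    """
    genes = list(genes)
    lo, hi = size_range
    if hi > len(genes):
        raise ValueError("size_range exceeds the gene universe")
    if lo < 1 or lo > hi:
        raise ValueError("invalid size_range")
    rng = np.random.default_rng(seed)
    out: dict[str, set[str]] = {}
    for term, subset in planted_enrichment:
        extra = set(subset) - set(genes)
        if extra:
            raise ValueError(f"planted genes outside universe: {sorted(extra)}")
        out[term] = set(subset)
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        out[f"TERM{i:04d}"] = set(members)
    return out


HORMONES: tuple[str, ...] = ("CK", "ABA", "ET", "JA", "Aux", "GA", "BL")
LAYERS: tuple[str, ...] = ("upstream", "intermediate", "downstream")


def generate_hormone_layers(genes: Sequence[str],
                            genes_per_hormone: int = 60,
                            hormones: Sequence[str] = HORMONES,
                            seed: int | None = None) -> pd.DataFrame:
    """Hormone-signaling gene lists with upstream/intermediate/downstream
    layer labels, drawn from the gene universe (hormone lists may overlap
    each other but each gene appears once per hormone)."""
    genes = list(genes)
    if genes_per_hormone > len(genes):
        raise ValueError("genes_per_hormone exceeds the gene universe")
    rng = np.random.default_rng(seed)
    rows = []
    for h in hormones:
        members = rng.choice(genes, size=genes_per_hormone, replace=False)
        # downstream-heavy split, as signaling cascades fan out
        layer_p = (0.15, 0.35, 0.5)
        layers = rng.choice(LAYERS, size=genes_per_hormone, p=layer_p)
        for g, layer in zip(members, layers):
            rows.append({"hormone": h, "gene_id": str(g), "layer": layer})
    return pd.DataFrame(rows)


def default_config(**overrides) -> SimConfig:
    """The study-design defaults, with keyword overrides."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()
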