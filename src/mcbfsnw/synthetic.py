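"""Synthetic labeled expression matrices and interaction networks.

The expression generator emulates a microarray-style study: continuous
Gaussian values, a handful of genes carrying class-specific mean shifts, the
rest pure noise. The graph generator plants a single high-degree hub in a
sparse background so centrality methods have a known answer. Both are pure
functions of their scenario (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .data_io import ExpressionDataset, InteractionNetwork

__all__ = [
    "ExpressionScenario",
    "GraphScenario",
    "simulate_expression",
    "simulate_graph",
]


@dataclass
class ExpressionScenario:
    """Study conditions for a simulated expression dataset.

    Defaults describe a small two-class cohort: 60 samples, 500 genes of
    which 20 are informative, class means separated by 2 noise SDs.
    ``effect_size`` is the adjacent-class mean difference in noise-SD units.
    """

    n_samples: int = 60
    n_genes: int = 500
    n_informative: int = 20
    n_classes: int = 2
    effect_size: float = 2.0
    noise_sd: float = 1.0
    class_proportions: Sequence[float] | None = None
    distribution: str = "normal"  # or "lognormal" for RNA-seq-like tails
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_classes < 2:
            raise ValueError("need >= 2 classes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.class_proportions is not None:
            props = np.asarray(self.class_proportions, dtype=float)
            if len(props) != self.n_classes or np.any(props <= 0) or not np.isclose(
                props.sum(), 1.0
            ):
                raise ValueError("class_proportions must be a positive simplex "
                                 "vector of length n_classes")
        if self.distribution not in ("normal", "lognormal"):
            raise ValueError("distribution must be 'normal' or 'lognormal'")


@dataclass
class GraphScenario:
    """Conditions for a simulated interaction network."""

    n_nodes: int = 100
    model: str = "planted_hub"
    hub_degree: int = 20
    base_prob: float = 0.02
    seed: int = 7

    def __post_init__(self) -> None:
        if self.model not in ("planted_hub", "preferential_attachment",
                              "erdos_renyi"):
            raise ValueError(f"unknown graph model {self.model!r}")
        if self.model == "planted_hub" and not 1 <= self.hub_degree < self.n_nodes:
            raise ValueError("hub_degree must be in [1, n_nodes)")
        if not 0.0 <= self.base_prob <= 1.0:
            raise ValueError("base_prob must be in [0, 1]")


def _class_sizes(scn: ExpressionScenario) -> list[int]:
    """Deterministic largest-remainder apportionment of samples to classes."""
    props = (
        np.full(scn.n_classes, 1.0 / scn.n_classes)
        if scn.class_proportions is None
        else np.asarray(scn.class_proportions, dtype=float)
    )
    raw = props * scn.n_samples
    sizes = np.floor(raw).astype(int)
    rem = scn.n_samples - sizes.sum()
    order = np.argsort(-(raw - sizes), kind="stable")
    for i in order[:rem]:
        sizes[i] += 1
    if np.any(sizes < 1):
        raise ValueError("every class needs at least one sample")
    return [int(x) for x in sizes]


def simulate_expression(
    scn: ExpressionScenario,
) -> tuple[ExpressionDataset, list[str]]:
    """Generate a labeled matrix with planted informative genes.

    Noise genes are N(0, noise_sd) in every class. Each informative gene gets
    a class-specific mean offset effect_size * noise_sd * (i - (c-1)/2), so
    adjacent classes differ by effect_size noise SDs. Returns the dataset and
    the informative gene ids (the planted ground truth).
    """
    rng = np.random.default_rng(scn.seed)
    sizes = _class_sizes(scn)
    class_of = np.repeat(np.arange(scn.n_classes), sizes)
    values = rng.normal(0.0, scn.noise_sd, size=(scn.n_samples, scn.n_genes))
    informative = np.sort(
        rng.choice(scn.n_genes, size=scn.n_informative, replace=False)
    )
    offsets = scn.effect_size * scn.noise_sd * (
        class_of - (scn.n_classes - 1) / 2.0
    )
    values[:, informative] += offsets[:, None]
    if scn.distribution == "lognormal":
        values = np.exp(values)
    width = len(str(scn.n_genes))
    gene_ids = [f"G{i+1:0{width}d}" for i in range(scn.n_genes)]
    sample_ids = [f"S{j+1:03d}" for j in range(scn.n_samples)]
    labels = [f"class{int(i)}" for i in class_of]
    data = ExpressionDataset(values, sample_ids, gene_ids, labels)
    return data, [gene_ids[i] for i in informative]


def simulate_graph(scn: GraphScenario) -> tuple[InteractionNetwork, list[str]]:
    """Generate an interaction network; for the planted-hub model the hub id
    is returned as ground truth.

    planted_hub: Erdos-Renyi background at ``base_prob`` plus one node wired
    to ``hub_degree`` distinct others. preferential_attachment and
    erdos_renyi are plain background models (no ground truth).
    """
    rng = np.random.default_rng(scn.seed)
    width = len(str(scn.n_nodes))
    names = [f"N{i:0{width}d}" for i in range(scn.n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    truth: list[str] = []
    if scn.model == "preferential_attachment":
        base = nx.barabasi_albert_graph(
            scn.n_nodes, max(1, int(round(scn.base_prob * scn.n_nodes))),
            seed=int(rng.integers(2**31)),
        )
        g.add_edges_from((names[a], names[b]) for a, b in base.edges)
        return InteractionNetwork(g), truth

    n = scn.n_nodes
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < scn.base_prob
    g.add_edges_from(
        (names[a], names[b]) for a, b in zip(iu[0][mask], iu[1][mask])
    )
    if scn.model == "planted_hub":
        hub = int(rng.integers(n))
        others = [i for i in range(n) if i != hub]
        targets = rng.choice(len(others), size=scn.hub_degree, replace=False)
        g.add_edges_from((names[hub], names[others[t]]) for t in targets)
        truth = [names[hub]]
    return InteractionNetwork(g), truth
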