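"""Synthetic benchmark generator: truth networks, dynamics, noisy priors.

The generator produces inputs with the statistical structure the
inference method assumes, at desk scale and with no downloads:

* **Truth network** — an undirected preferential-attachment
  (Barabasi-Albert) graph, mimicking the scale-free topology reported
  for biological interaction networks (few highly-connected hubs, many
  low-degree genes). Each gene is assigned up to ``regulator_cap`` of
  its neighbors as regulators and a randomly drawn deterministic
  ternary update rule over its regulators' states.

* **Ternary dynamics** — a random ternary initial state; at every step
  each gene's next value is its rule applied to its regulators' current
  values, replaced with probability ``noise`` by a uniform ternary
  draw. This yields a quantized genes x time-points matrix whose lag-1
  structure is exactly what the penalized-entropy criterion measures.

* **Corrupted prior** — the truth with each edge deleted independently
  at the false-negative rate and spurious non-edges inserted so that
  the expected number added equals ``prior_fp_rate x |truth edges|``,
  modelling prior-knowledge sources that are both incomplete and
  contaminated (e.g. high-throughput two-hybrid screens).

Every generator is a pure function of (spec, seed): the same spec gives
bit-identical output across runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionMatrix, Network

__all__ = ["SyntheticSpec", "GeneRules", "generate_truth", "simulate_dynamics", "corrupt_prior"]

_LEVELS = (-1, 0, 1)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    ``noise`` is the per-gene per-step probability that the rule output
    is replaced by a uniform ternary draw; ``attach_edges`` is the
    preferential-attachment growth parameter (edges added per new node).
    """

    n_genes: int = 30
    n_timepoints: int = 40
    attach_edges: int = 2
    noise: float = 0.05
    prior_fp_rate: float = 0.0
    prior_fn_rate: float = 0.0
    seed: int = 0
    regulator_cap: int = 3

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("need at least 3 genes")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 time points")
        for name in ("noise", "prior_fp_rate", "prior_fn_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def gene_name(self, i: int) -> str:
        width = len(str(self.n_genes - 1))
        return f"g{i:0{width}d}"


@dataclass(frozen=True)
class GeneRules:
    """Per-gene regulators and deterministic ternary update tables."""

    regulators: dict[str, tuple[str, ...]]
    tables: dict[str, dict[tuple[int, ...], int]]

    def update(self, gene: str, state: dict[str, int]) -> int:
        regs = self.regulators[gene]
        return self.tables[gene][tuple(state[r] for r in regs)]


def generate_truth(spec: SyntheticSpec) -> tuple[Network, GeneRules]:
    """Scale-free truth network plus a ternary update rule per gene."""
    rng = np.random.default_rng(spec.seed)
    m = min(spec.attach_edges, spec.n_genes - 1)
    g = nx.barabasi_albert_graph(spec.n_genes, m, seed=int(rng.integers(2**31)))
    names = {i: spec.gene_name(i) for i in g.nodes}
    edges = [(names[a], names[b]) for a, b in g.edges]
    net = Network.build(edges, genes=names.values())

    regulators: dict[str, tuple[str, ...]] = {}
    tables: dict[str, dict[tuple[int, ...], int]] = {}
    for i in sorted(g.nodes):
        gene = names[i]
        nbrs = sorted(names[j] for j in g.neighbors(i))
        if len(nbrs) > spec.regulator_cap:
            idx = rng.choice(len(nbrs), size=spec.regulator_cap, replace=False)
            nbrs = [nbrs[j] for j in sorted(idx)]
        regulators[gene] = tuple(nbrs)
        table = {
            state: int(rng.choice(_LEVELS))
            for state in itertools.product(_LEVELS, repeat=len(nbrs))
        }
        tables[gene] = table
    return net, GeneRules(regulators, tables)


def simulate_dynamics(rules: GeneRules, spec: SyntheticSpec) -> ExpressionMatrix:
    """Run the ternary dynamics and return a quantized expression matrix."""
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(rules.regulators)
    state = {g: int(rng.choice(_LEVELS)) for g in genes}
    series = {g: [state[g]] for g in genes}
    for _ in range(1, spec.n_timepoints):
        nxt: dict[str, int] = {}
        for g in genes:
            value = rules.update(g, state)
            if spec.noise > 0 and rng.random() < spec.noise:
                value = int(rng.choice(_LEVELS))
            nxt[g] = value
        state = nxt
        for g in genes:
            series[g].append(state[g])
    values = np.asarray([series[g] for g in genes], dtype=int)
    return ExpressionMatrix(genes, values, quantized=True)


def corrupt_prior(truth: Network, spec: SyntheticSpec) -> Network:
    """Prior network: truth minus random deletions plus random insertions.

    Each truth edge survives with probability 1 - ``prior_fn_rate``;
    each non-edge is inserted independently with a probability chosen so
    the expected number of insertions is ``prior_fp_rate x |edges|``.
    """
    rng = np.random.default_rng(spec.seed + 2)
    kept = [e for e in sorted(truth.edges) if rng.random() >= spec.prior_fn_rate]
    genes = sorted(truth.genes)
    non_edges = [
        (a, b)
        for a, b in itertools.combinations(genes, 2)
        if (a, b) not in truth.edges
    ]
    added: list[tuple[str, str]] = []
    if spec.prior_fp_rate > 0 and non_edges:
        p = min(1.0, spec.prior_fp_rate * truth.n_edges / len(non_edges))
        added = [e for e in non_edges if rng.random() < p]
    return Network.build(kept + added, genes=truth.genes)
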