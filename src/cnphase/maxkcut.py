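"""Constrained Max-k-Cut: randomized greedy solver and brute-force oracle.

The problem: partition the haplotype vertices into k sets maximizing the
total soft-edge weight across different sets (the cut), under the constraint
that every hard edge lies on the cut.  Max-k-Cut is NP-hard; the randomized
greedy below attains a (k-2)/(k-1) approximation ratio for k > 2 and is run
with independent random restarts, keeping the best cut.

Cluster indices are 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cnphase.graph_model import CNVGraph
from cnphase.rngutil import SeedLike, as_seedseq

BRUTE_FORCE_VERTEX_LIMIT = 12


@dataclass
class Partition:
    """A feasible k-partition of the graph's vertices with its cut value."""

    k: int
    assignment: np.ndarray  # vertex -> cluster in {0..k-1}
    cut_value: int

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int64)
        if self.assignment.min(initial=0) < 0 or (
            self.assignment.size and self.assignment.max() >= self.k
        ):
            raise ValueError("cluster labels out of range")

    def copy(self) -> "Partition":
        return Partition(self.k, self.assignment.copy(), self.cut_value)


def cut_weight(graph: CNVGraph, assignment: np.ndarray) -> int:
    """Total soft weight across clusters for a complete assignment."""
    a = np.asarray(assignment)
    if a.shape[0] != graph.n_vertices:
        raise ValueError("assignment length mismatch")
    if (a < 0).any():
        raise ValueError("all vertices must be assigned")
    diff = a[:, None] != a[None, :]
    return int((graph.soft_weights * diff).sum()) // 2


def _check_feasible(graph: CNVGraph, assignment: np.ndarray) -> None:
    for u, v in graph.hard_edges:
        if assignment[u] == assignment[v]:
            raise AssertionError(f"hard edge ({u},{v}) not on the cut")


def _greedy_once(graph: CNVGraph, k: int, rng: np.random.Generator) -> np.ndarray:
    n = graph.n_vertices
    soft = graph.soft_weights
    hard_partner = {}
    for u, v in graph.hard_edges:
        hard_partner[u] = v
        hard_partner[v] = u
    assignment = np.full(n, -1, dtype=np.int64)
    # (1) k random distinct vertices seed the k clusters
    seeds = rng.choice(n, size=k, replace=False)
    for c, v in enumerate(seeds):
        assignment[v] = c
    # weight from each vertex to each cluster's current members
    to_cluster = np.zeros((n, k), dtype=np.int64)
    for c, v in enumerate(seeds):
        to_cluster[:, c] += soft[:, v]
    placed_total = soft[:, seeds].sum(axis=1)
    # (2) place remaining vertices in random order, maximizing the cut
    order = np.setdiff1d(np.arange(n), seeds)
    rng.shuffle(order)
    for v in order:
        gains = placed_total[v] - to_cluster[v]
        partner = hard_partner.get(v)
        if partner is not None and assignment[partner] >= 0:
            gains = gains.copy()
            gains[assignment[partner]] = np.iinfo(np.int64).min
        # ties take the lowest cluster index: zero-distance vertices (shared
        # haplotypes) then aggregate instead of scattering; randomization
        # still enters through the seeds and the placement order
        c = int(np.argmax(gains))
        assignment[v] = c
        to_cluster[:, c] += soft[:, v]
        placed_total += soft[:, v]
    return assignment


def greedy_constrained_maxkcut(
    graph: CNVGraph, k: int, restarts: int = 10, seed: SeedLike = None
) -> Partition:
    """Best-of-``restarts`` randomized greedy constrained Max-k-Cut.

    Each restart draws fresh initial vertices and vertex order (and tie
    breaks) from its own substream of ``seed``, so the result is
    reproducible and independent of restart order; ties on the final cut
    value keep the lowest restart index.
    """
    n = graph.n_vertices
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds vertex count {n}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    streams = as_seedseq(seed).spawn(restarts)
    best_assignment = None
    best_cut = -1
    for ss in streams:
        rng = np.random.default_rng(ss)
        assignment = _greedy_once(graph, k, rng)
        c = cut_weight(graph, assignment)
        if c > best_cut:
            best_cut = c
            best_assignment = assignment
    _check_feasible(graph, best_assignment)
    return Partition(k=k, assignment=best_assignment, cut_value=best_cut)


def brute_force_maxkcut(graph: CNVGraph, k: int) -> Partition:
    """Exact optimum by enumerating k-labelings (test oracle; n <= 12).

    The first vertex is pinned to cluster 0 (cluster labels are
    exchangeable) and empty clusters are allowed; neither changes the
    optimal cut value.
    """
    n = graph.n_vertices
    if n > BRUTE_FORCE_VERTEX_LIMIT:
        raise ValueError(f"brute force refused for n={n} > {BRUTE_FORCE_VERTEX_LIMIT}")
    if k < 2 or k > n:
        raise ValueError("k out of range")
    m = k ** (n - 1)
    # mixed-radix enumeration of labels for vertices 1..n-1
    codes = np.arange(m)
    labels = np.zeros((m, n), dtype=np.int64)
    for v in range(1, n):
        labels[:, v] = (codes // k ** (v - 1)) % k
    feasible = np.ones(m, dtype=bool)
    for u, v in graph.hard_edges:
        feasible &= labels[:, u] != labels[:, v]
    if not feasible.any():  # cannot occur: hard edges are vertex-disjoint, k >= 2
        raise RuntimeError("no feasible labeling")
    labels = labels[feasible]
    cuts = np.zeros(labels.shape[0], dtype=np.int64)
    soft = graph.soft_weights
    for u in range(n):
        for v in range(u + 1, n):
            if soft[u, v]:
                cuts += soft[u, v] * (labels[:, u] != labels[:, v])
    best = int(np.argmax(cuts))
    return Partition(k=k, assignment=labels[best], cut_value=int(cuts[best]))
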