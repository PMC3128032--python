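"""Weighted haplotype graph with hard and soft edges.

Every haplotype occurrence (two per individual) becomes a vertex; edge
weights are pairwise hamming distances, so identical haplotypes from
different individuals appear as multiple vertices at zero distance.  An
individual with an odd total copy number must carry two *different*
chromosome-specific copies, so the edge between that individual's two
vertices is *hard*: it must lie on the cut.  Hard-edge weight is excluded
from the soft cut objective — hard edges act purely as constraints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple, Union

import numpy as np

from cnphase.hapio import CNVRecord, LocalHaplotypeSet

HapLike = Union[str, np.ndarray]


def hamming(h1: HapLike, h2: HapLike) -> int:
    """Number of differing positions between two equal-length haplotypes."""
    a = np.frombuffer(h1.encode(), dtype=np.uint8) if isinstance(h1, str) else np.asarray(h1)
    b = np.frombuffer(h2.encode(), dtype=np.uint8) if isinstance(h2, str) else np.asarray(h2)
    if a.shape != b.shape:
        raise ValueError(f"haplotype length mismatch: {a.shape} vs {b.shape}")
    return int(np.count_nonzero(a != b))


@dataclass
class CNVGraph:
    """Dense weighted graph over haplotype vertices for one CNV.

    ``weights`` holds all pairwise hamming distances; ``soft_weights`` is the
    same matrix with hard-edge entries zeroed, and is what the cut objective
    scores.  Vertex ``2i`` / ``2i + 1`` are the two haplotypes of the i-th
    included individual.
    """

    cnv_id: str
    sample_ids: List[str]  # individuals included (non-missing totals)
    totals: Dict[str, int]
    weights: np.ndarray
    hard_edges: Set[Tuple[int, int]]  # (u, v) with u < v, v = u + 1

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.int64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if w.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("vertex count must be 2 x individuals")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-weights must be zero")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        for u, v in self.hard_edges:
            if v != u + 1 or u % 2 != 0:
                raise ValueError("hard edges only join one individual's two vertices")
        self.weights = w
        soft = w.copy()
        for u, v in self.hard_edges:
            soft[u, v] = soft[v, u] = 0
        self.soft_weights = soft

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]

    @property
    def total_soft_weight(self) -> int:
        """W: sum of soft-edge weights over unordered pairs."""
        return int(self.soft_weights.sum()) // 2

    def partner(self, v: int) -> int:
        """The other haplotype vertex of v's individual."""
        return v ^ 1

    def individual_of(self, v: int) -> int:
        return v // 2

    def dump_edges(self, path: str) -> None:
        """Debug dump as an edge-list TSV: u, v, weight, hard|soft."""
        with open(path, "w") as fh:
            fh.write("u\tv\tweight\tkind\n")
            n = self.n_vertices
            for u in range(n):
                for v in range(u + 1, n):
                    kind = "hard" if (u, v) in self.hard_edges else "soft"
                    fh.write(f"{u}\t{v}\t{self.weights[u, v]}\t{kind}\n")


def build_graph(local: LocalHaplotypeSet, cnv: Optional[CNVRecord] = None,
                totals: Optional[Dict[str, int]] = None) -> CNVGraph:
    """Build the hard/soft-edge graph from local haplotypes and totals.

    Individuals whose total is missing are excluded from the graph (and from
    this CNV only).  Totals may be given either via ``cnv`` or directly as a
    mapping.
    """
    if totals is None:
        if cnv is None:
            raise ValueError("either cnv or totals must be provided")
        totals = {s: t for s, t in cnv.totals.items() if t is not None}
    included = [s for s in local.sample_ids if s in totals]
    if not included:
        raise ValueError(f"{local.cnv_id}: no individual with a non-missing total")
    idx = [local.sample_ids.index(s) for s in included]
    rows = np.concatenate([[2 * i, 2 * i + 1] for i in idx])
    H = local.haplotypes[rows].astype(np.int16)
    weights = (H[:, None, :] != H[None, :, :]).sum(axis=2).astype(np.int64)
    hard = {
        (2 * j, 2 * j + 1)
        for j, s in enumerate(included)
        if totals[s] % 2 == 1
    }
    return CNVGraph(
        cnv_id=local.cnv_id,
        sample_ids=included,
        totals={s: int(totals[s]) for s in included},
        weights=weights,
        hard_edges=hard,
    )
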