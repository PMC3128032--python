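"""Shared builders for random test instances."""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pytest

from cnphase.csp import Constraint, ConstraintSet
from cnphase.graph_model import CNVGraph


def make_graph(
    weights: np.ndarray, odd: List[bool], cnv_id: str = "test"
) -> CNVGraph:
    """CNVGraph from an upper-triangular weight spec and per-individual parity."""
    w = np.asarray(weights, dtype=np.int64)
    w = np.triu(w, 1)
    w = w + w.T
    n_ind = w.shape[0] // 2
    assert len(odd) == n_ind
    hard = {(2 * i, 2 * i + 1) for i in range(n_ind) if odd[i]}
    totals = {f"s{i}": (3 if odd[i] else 2) for i in range(n_ind)}
    return CNVGraph(
        cnv_id=cnv_id,
        sample_ids=[f"s{i}" for i in range(n_ind)],
        totals=totals,
        weights=w,
        hard_edges=hard,
    )


def random_graph(rng: np.random.Generator, max_individuals: int = 4) -> CNVGraph:
    """Random small graph: integer weights 0-5, random odd-total individuals."""
    n_ind = int(rng.integers(2, max_individuals + 1))
    n = 2 * n_ind
    w = rng.integers(0, 6, size=(n, n))
    odd = list(rng.random(n_ind) < 0.5)
    return make_graph(w, odd)


def random_constraint_set(rng: np.random.Generator) -> ConstraintSet:
    """Random small constraint set within the brute-force oracle limits."""
    n = int(rng.integers(2, 7))
    c_max = int(rng.integers(1, 6))
    if max(c_max, n - 1) + 1 > 9:
        c_max = min(c_max, 8)
    m = int(rng.integers(1, 8))
    counts: Dict[Tuple[int, int, int], int] = {}
    for _ in range(m):
        a, b = sorted(rng.integers(0, n, size=2))
        t = int(rng.integers(0, c_max + 1))
        counts[(int(a), int(b), t)] = counts.get((int(a), int(b), t), 0) + int(
            rng.integers(1, 4)
        )
    return ConstraintSet(
        n=n,
        constraints=[Constraint(a, b, t, m_) for (a, b, t), m_ in counts.items()],
        c_max=c_max,
    )


def planted_constraint_set(
    rng: np.random.Generator,
) -> Tuple[ConstraintSet, List[int]]:
    """Constraint set generated from a hidden injective assignment.

    All constraints are consistent with the planted values and form a
    connected chain, so propagation from a correct seed satisfies every
    constraint without conflict.
    """
    n = int(rng.integers(2, 6))
    values = list(rng.permutation(n))  # distinct values in 0..n-1
    c_max = max(values[i] + values[j] for i in range(n) for j in range(n) if i != j)
    counts: Dict[Tuple[int, int, int], int] = {}
    order = list(rng.permutation(n))
    for prev, cur in zip(order, order[1:]):  # spanning chain: connected
        a, b = sorted((prev, cur))
        t = values[a] + values[b]
        counts[(a, b, t)] = counts.get((a, b, t), 0) + int(rng.integers(1, 3))
    for _ in range(int(rng.integers(0, 4))):  # consistent extras
        i, j = rng.choice(n, size=2, replace=False)
        a, b = sorted((int(i), int(j)))
        t = values[a] + values[b]
        counts[(a, b, t)] = counts.get((a, b, t), 0) + 1
    cs = ConstraintSet(
        n=n,
        constraints=[Constraint(a, b, t, m) for (a, b, t), m in counts.items()],
        c_max=c_max,
    )
    return cs, values


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
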