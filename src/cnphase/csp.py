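"""Unique Max-2-CSP: constraint construction, greedy solution-table solver, oracle.

After clustering, every individual contributes one two-variable sum
constraint X_a + X_b = Total(i), where X_a, X_b are the clusters holding
their two haplotypes (a = b when both land in one cluster).  Identical
(a, b, T) constraints are collapsed with a multiplicity.  The Unique
Max-2-CSP asks for pairwise-distinct integers from the domain
D = {0, ..., d} maximizing the satisfied multiplicity; it is NP-hard, and
is solved here by seeding every (variable, value) pair, propagating through
one-assigned constraints with a majority-type rule, and greedily unioning
the best rows of the resulting solution table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cnphase.maxkcut import Partition
from cnphase.rngutil import SeedLike, as_seedseq

BRUTE_FORCE_VAR_LIMIT = 6
BRUTE_FORCE_DOMAIN_LIMIT = 9


@dataclass(frozen=True)
class Constraint:
    a: int  # variable indices, 0-based, a <= b
    b: int
    total: int
    multiplicity: int

    def satisfied_by(self, values: Sequence[int]) -> bool:
        va, vb = values[self.a], values[self.b]
        return va >= 0 and vb >= 0 and va + vb == self.total


@dataclass
class ConstraintSet:
    """Collapsed two-variable sum constraints over n cluster variables.

    The domain is D = {0, ..., d} with d = max(c_max, n - 1): copy numbers
    cannot exceed the largest observed total, but at least n distinct values
    must exist for an injective assignment to be possible.  Values above
    c_max can only be forced by that floor and are flagged downstream.
    """

    n: int
    constraints: List[Constraint]
    c_max: int

    def __post_init__(self) -> None:
        for c in self.constraints:
            if not (0 <= c.a <= c.b < self.n):
                raise ValueError("constraint variable out of range")
            if c.total < 0 or c.multiplicity < 1:
                raise ValueError("invalid constraint")

    @property
    def d(self) -> int:
        return max(self.c_max, self.n - 1)

    @property
    def total_multiplicity(self) -> int:
        return sum(c.multiplicity for c in self.constraints)


@dataclass
class Assignment:
    """Integer values per cluster variable; -1 marks an unassigned variable."""

    values: List[int]
    satisfied_count: int
    flagged_high: List[int] = field(default_factory=list)  # values above c_max

    def __post_init__(self) -> None:
        assigned = [v for v in self.values if v >= 0]
        if len(assigned) != len(set(assigned)):
            raise ValueError("assigned values must be pairwise distinct")


def build_constraints(
    partition: Partition, totals: Sequence[int]
) -> ConstraintSet:
    """One constraint per individual from the partition's cluster labels.

    ``totals[i]`` is the total copy number of the individual whose
    haplotypes are vertices 2i and 2i + 1.
    """
    n_ind = len(totals)
    if partition.assignment.shape[0] != 2 * n_ind:
        raise ValueError("partition must cover both haplotypes of each individual")
    counts: Dict[Tuple[int, int, int], int] = {}
    for i, t in enumerate(totals):
        a = int(partition.assignment[2 * i])
        b = int(partition.assignment[2 * i + 1])
        if a > b:
            a, b = b, a
        counts[(a, b, int(t))] = counts.get((a, b, int(t)), 0) + 1
    constraints = [
        Constraint(a, b, t, m) for (a, b, t), m in sorted(counts.items())
    ]
    c_max = max(int(t) for t in totals)
    return ConstraintSet(n=partition.k, constraints=constraints, c_max=c_max)


def count_satisfied(cs: ConstraintSet, values: Sequence[int]) -> int:
    """Multiplicity-weighted count of satisfied constraints; -1 satisfies none."""
    return sum(c.multiplicity for c in cs.constraints if c.satisfied_by(values))


def _propagate(
    cs: ConstraintSet, seed_var: int, seed_val: int, rng: np.random.Generator
) -> List[int]:
    """One randomized propagation round from X_seed_var = seed_val.

    Repeatedly picks (uniformly) a constraint with exactly one assigned
    variable; the unknown gets T1 - known where T1 is the majority total
    among all constraint types on that variable pair (ties broken at
    random).  A propagated value outside D or colliding with a used value
    blocks that variable for the round (conflict), recorded as -1.
    """
    n, d = cs.n, cs.d
    values = [-1] * n
    blocked = [False] * n
    values[seed_var] = seed_val
    used = {seed_val}
    # group constraint types by unordered variable pair
    by_pair: Dict[Tuple[int, int], List[Constraint]] = {}
    for c in cs.constraints:
        by_pair.setdefault((c.a, c.b), []).append(c)
    while True:
        open_pairs = []
        for (a, b), group in by_pair.items():
            if a == b:
                continue
            known_a, known_b = values[a] >= 0, values[b] >= 0
            if known_a == known_b:
                continue
            unknown = b if known_a else a
            if not blocked[unknown]:
                open_pairs.append((a, b, unknown))
        if not open_pairs:
            break
        a, b, unknown = open_pairs[rng.integers(len(open_pairs))]
        group = by_pair[(a, b)]
        max_mult = max(c.multiplicity for c in group)
        majority = [c for c in group if c.multiplicity == max_mult]
        chosen = majority[rng.integers(len(majority))] if len(majority) > 1 else majority[0]
        known_val = values[a] if values[a] >= 0 else values[b]
        val = chosen.total - known_val
        if val < 0 or val > d or val in used:
            blocked[unknown] = True
        else:
            values[unknown] = val
            used.add(val)
    return values


def solve_unique_max2csp(
    cs: ConstraintSet, restarts: int = 10, seed: SeedLike = None
) -> Assignment:
    """Solution-table greedy heuristic for Unique Max-2-CSP.

    For every (variable i, value c) with 0 <= c <= c_max, seed X_i = c and
    propagate; the best of ``restarts`` randomized rounds becomes row (i, c)
    of the solution table.  Rows are then unioned greedily by descending
    satisfied count (ties: more assigned variables, then lowest row index),
    never overwriting earlier assignments and keeping values distinct;
    variables never reached stay -1.
    """
    if cs.n == 0 or not cs.constraints:
        return Assignment(values=[-1] * cs.n, satisfied_count=0)
    streams = as_seedseq(seed).spawn(cs.n * (cs.c_max + 1))
    table: List[Tuple[int, int, List[int]]] = []  # (satisfied, n_assigned, values)
    for i in range(cs.n):
        for c in range(cs.c_max + 1):
            rng = np.random.default_rng(streams[i * (cs.c_max + 1) + c])
            best_vals: List[int] = [-1] * cs.n
            best_count = -1
            best_assigned = -1
            for _ in range(restarts):
                vals = _propagate(cs, i, c, rng)
                cnt = count_satisfied(cs, vals)
                na = sum(v >= 0 for v in vals)
                if cnt > best_count or (cnt == best_count and na > best_assigned):
                    best_vals, best_count, best_assigned = vals, cnt, na
            table.append((best_count, best_assigned, best_vals))
    order = sorted(
        range(len(table)),
        key=lambda r: (-table[r][0], -table[r][1], r),
    )
    union = [-1] * cs.n
    used: set[int] = set()
    current = 0
    for r in order:
        _, _, vals = table[r]
        candidate = list(union)
        cand_used = set(used)
        for v in range(cs.n):
            if candidate[v] < 0 and vals[v] >= 0 and vals[v] not in cand_used:
                candidate[v] = vals[v]
                cand_used.add(vals[v])
        new_count = count_satisfied(cs, candidate)
        if new_count > current:
            union, used, current = candidate, cand_used, new_count
    flagged = [v for v in union if v > cs.c_max]
    return Assignment(values=union, satisfied_count=current, flagged_high=flagged)


def brute_force_max2csp(cs: ConstraintSet) -> Assignment:
    """Exact optimum over all injective assignments (test oracle).

    Enforced limits: n <= 6 variables, |D| <= 9 values.
    """
    if cs.n > BRUTE_FORCE_VAR_LIMIT:
        raise ValueError(f"brute force refused for n={cs.n} > {BRUTE_FORCE_VAR_LIMIT}")
    if cs.d + 1 > BRUTE_FORCE_DOMAIN_LIMIT:
        raise ValueError(
            f"brute force refused for |D|={cs.d + 1} > {BRUTE_FORCE_DOMAIN_LIMIT}"
        )
    if not cs.constraints:
        return Assignment(values=[-1] * cs.n, satisfied_count=0)
    best_vals: Optional[Tuple[int, ...]] = None
    best_count = -1
    for perm in itertools.permutations(range(cs.d + 1), cs.n):
        cnt = count_satisfied(cs, perm)
        if cnt > best_count:
            best_count = cnt
            best_vals = perm
    assert best_vals is not None
    flagged = [v for v in best_vals if v > cs.c_max]
    return Assignment(
        values=list(best_vals), satisfied_count=best_count, flagged_high=flagged
    )
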