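"""Per-CNV inference: k-loop over clustering + assignment, then adjustment.

For each CNV the clustering (constrained Max-k-Cut) and the copy-number
assignment (Unique Max-2-CSP) are run for every k from 2 up to the maximum
possible number of distinct chromosome-specific copy numbers; the k with the
most satisfied individuals wins (ties: smaller k, then larger cut).  The
individuals still violating their constraint are then re-clustered by the
randomized adjustment loop: their two haplotypes are moved into the pair of
valued clusters that satisfies the total while maximizing the cut.  Cluster
values are frozen during adjustment; an individual for which no pair of
assigned cluster values sums to its total is flagged unresolved (-1, -1).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from cnphase.csp import (
    Assignment,
    build_constraints,
    count_satisfied,
    solve_unique_max2csp,
)
from cnphase.graph_model import CNVGraph, build_graph
from cnphase.hapio import (
    CNVRecord,
    EmptyWindowError,
    HaplotypePanel,
    LocalHaplotypeSet,
    select_window,
)
from cnphase.maxkcut import Partition, cut_weight, greedy_constrained_maxkcut
from cnphase.rngutil import SeedLike, as_seedseq

logger = logging.getLogger(__name__)

DEFAULT_MIN_SNPS = 10
DEFAULT_RESTARTS = 10


@dataclass
class DiplotypeCallSet:
    """Inferred unordered copy-number pairs for one CNV."""

    cnv_id: str
    sample_ids: List[str]
    pairs: Dict[str, Tuple[int, int]]  # (-1, -1) marks unresolved
    totals: Dict[str, int]
    satisfied: Dict[str, bool]
    chosen_k: int
    n_satisfied: int
    cluster_labels: Optional[np.ndarray] = None  # per haplotype vertex
    cluster_values: Optional[List[int]] = None

    def hap_copy_labels(self) -> Optional[List[int]]:
        """Chromosome-specific copy number per haplotype vertex, or None."""
        if self.cluster_labels is None or self.cluster_values is None:
            return None
        return [self.cluster_values[c] for c in self.cluster_labels]


def max_clusters(totals: Sequence[int]) -> int:
    """Maximum number of clusters to try: c_max + 1 distinct copy numbers.

    With observed totals up to c_max, chromosome-specific copies range over
    0..c_max, so at most c_max + 1 clusters are meaningful; the count is
    additionally capped by the number of haplotype vertices (two per
    individual).
    """
    totals = list(totals)
    if not totals:
        raise ValueError("totals must be non-empty")
    return min(max(totals) + 1, 2 * len(totals))


def _individual_satisfied(
    assignment_values: Sequence[int], labels: np.ndarray, i: int, total: int
) -> bool:
    va = assignment_values[labels[2 * i]]
    vb = assignment_values[labels[2 * i + 1]]
    return va >= 0 and vb >= 0 and va + vb == total


def adjust(
    graph: CNVGraph,
    partition: Partition,
    assignment: Assignment,
    restarts: int = DEFAULT_RESTARTS,
    seed: SeedLike = None,
) -> Tuple[Partition, Dict[str, Tuple[int, int]]]:
    """Re-cluster constraint-violating individuals, maximizing the cut.

    For each unsatisfied individual every ordered pair of valued clusters
    whose values sum to the individual's total is evaluated; the placement
    with the largest resulting cut wins (ties broken at random).  The whole
    pass runs ``restarts`` times with random individual order, keeping the
    final partition with the best cut.  Cluster values are never changed.
    """
    values = assignment.values
    valued = [c for c, v in enumerate(values) if v >= 0]
    totals = [graph.totals[s] for s in graph.sample_ids]
    n_ind = len(totals)
    base = partition.assignment
    unsat = [
        i
        for i in range(n_ind)
        if not _individual_satisfied(values, base, i, totals[i])
    ]
    # feasible (ordered) cluster pairs per total, shared across passes
    options_by_total: Dict[int, List[Tuple[int, int]]] = {}
    for t in {totals[i] for i in unsat}:
        options_by_total[t] = [
            (p, q) for p in valued for q in valued if values[p] + values[q] == t
        ]
    if not unsat:
        return partition.copy(), _calls_from(graph, base, values, set())
    best_labels = None
    best_cut = -1
    best_flagged: set[int] = set()
    for ss in as_seedseq(seed).spawn(restarts):
        rng = np.random.default_rng(ss)
        labels = base.copy()
        flagged: set[int] = set()
        for i in rng.permutation(unsat):
            opts = options_by_total[totals[i]]
            if not opts:
                flagged.add(int(i))
                logger.debug(
                    "%s %s: no cluster-value pair sums to %d; unresolved",
                    graph.cnv_id,
                    graph.sample_ids[i],
                    totals[i],
                )
                continue
            cuts = np.empty(len(opts), dtype=np.int64)
            for j, (p, q) in enumerate(opts):
                labels[2 * i], labels[2 * i + 1] = p, q
                cuts[j] = cut_weight(graph, labels)
            ties = np.flatnonzero(cuts == cuts.max())
            j = int(ties[rng.integers(len(ties))]) if len(ties) > 1 else int(ties[0])
            labels[2 * i], labels[2 * i + 1] = opts[j]
        c = cut_weight(graph, labels)
        if c > best_cut:
            best_cut = c
            best_labels = labels
            best_flagged = flagged
    if best_flagged:
        logger.warning(
            "%s: %d individual(s) unresolved (no cluster-value pair matches total)",
            graph.cnv_id,
            len(best_flagged),
        )
    adjusted = Partition(k=partition.k, assignment=best_labels, cut_value=best_cut)
    return adjusted, _calls_from(graph, best_labels, values, best_flagged)


def _calls_from(
    graph: CNVGraph,
    labels: np.ndarray,
    values: Sequence[int],
    flagged: set[int],
) -> Dict[str, Tuple[int, int]]:
    calls: Dict[str, Tuple[int, int]] = {}
    for i, sid in enumerate(graph.sample_ids):
        if i in flagged:
            calls[sid] = (-1, -1)
            continue
        va, vb = values[labels[2 * i]], values[labels[2 * i + 1]]
        if va < 0 or vb < 0:
            calls[sid] = (-1, -1)
        else:
            calls[sid] = (int(va), int(vb))
    return calls


def infer_cnv(
    local: LocalHaplotypeSet,
    cnv: Optional[CNVRecord] = None,
    totals: Optional[Dict[str, int]] = None,
    restarts: int = DEFAULT_RESTARTS,
    seed: SeedLike = None,
) -> DiplotypeCallSet:
    """Infer chromosome-specific copy-number pairs at one CNV.

    Runs the clustering + assignment pipeline for every k in 2..k_max,
    selects the k with the most satisfied individuals (ties: smaller k,
    then larger cut), then adjusts the violators.  Deterministic given
    ``seed``.
    """
    graph = build_graph(local, cnv=cnv, totals=totals)
    ind_totals = [graph.totals[s] for s in graph.sample_ids]
    k_hi = max(2, max_clusters(ind_totals))
    k_hi = min(k_hi, graph.n_vertices)
    master = as_seedseq(seed)
    k_values = list(range(2, k_hi + 1))
    streams = master.spawn(2 * len(k_values) + 1)
    best = None  # (satisfied, -k, cut, partition, assignment)
    for j, k in enumerate(k_values):
        part = greedy_constrained_maxkcut(
            graph, k, restarts=restarts, seed=streams[2 * j]
        )
        cs = build_constraints(part, ind_totals)
        asg = solve_unique_max2csp(cs, restarts=restarts, seed=streams[2 * j + 1])
        key = (asg.satisfied_count, -k, part.cut_value)
        if best is None or key > best[0]:
            best = (key, part, asg)
    _, part, asg = best
    adjusted, calls = adjust(graph, part, asg, restarts=restarts, seed=streams[-1])
    satisfied = {
        sid: calls[sid][0] >= 0
        and calls[sid][0] + calls[sid][1] == graph.totals[sid]
        for sid in graph.sample_ids
    }
    return DiplotypeCallSet(
        cnv_id=local.cnv_id,
        sample_ids=list(graph.sample_ids),
        pairs=calls,
        totals=dict(graph.totals),
        satisfied=satisfied,
        chosen_k=part.k,
        n_satisfied=sum(satisfied.values()),
        cluster_labels=adjusted.assignment,
        cluster_values=list(asg.values),
    )


def phase_all(
    panel: HaplotypePanel,
    cnv_records: Sequence[CNVRecord],
    extension_factor: float = 1.0,
    min_snps: int = DEFAULT_MIN_SNPS,
    restarts: int = DEFAULT_RESTARTS,
    seed: SeedLike = None,
) -> Tuple[List[DiplotypeCallSet], List[Dict[str, object]]]:
    """Run the whole pipeline over a CNV table.

    Each CNV is processed independently with a seed substream derived from
    the master seed and the CNV id, so results do not depend on processing
    order.  Returns the call sets and a per-CNV summary (chosen k,
    satisfaction, or the skip reason).
    """
    base = as_seedseq(seed)
    streams = [
        np.random.SeedSequence(
            entropy=base.entropy, spawn_key=(zlib.crc32(rec.cnv_id.encode()),)
        )
        for rec in cnv_records
    ]
    calls: List[DiplotypeCallSet] = []
    summary: List[Dict[str, object]] = []
    for rec, ss in zip(cnv_records, streams):
        row: Dict[str, object] = {"cnv_id": rec.cnv_id, "status": "ok"}
        try:
            local = select_window(panel, rec, extension_factor=extension_factor)
        except EmptyWindowError:
            row["status"] = "skipped: empty window"
            summary.append(row)
            continue
        except ValueError as exc:
            row["status"] = f"skipped: {exc}"
            summary.append(row)
            continue
        if local.n_snps < min_snps:
            row["status"] = f"skipped: <{min_snps} SNPs"
            row["n_snps"] = local.n_snps
            logger.info("%s skipped: %d < %d SNPs", rec.cnv_id, local.n_snps, min_snps)
            summary.append(row)
            continue
        if not rec.called_samples():
            row["status"] = "skipped: no totals"
            summary.append(row)
            continue
        cs = infer_cnv(local, cnv=rec, restarts=restarts, seed=ss)
        calls.append(cs)
        row.update(
            n_snps=local.n_snps,
            chosen_k=cs.chosen_k,
            n_individuals=len(cs.sample_ids),
            n_satisfied=cs.n_satisfied,
            n_unresolved=sum(p == (-1, -1) for p in cs.pairs.values()),
        )
        summary.append(row)
    return calls, summary
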