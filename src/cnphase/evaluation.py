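"""Scoring of inferred diplotype calls: accuracy, miscalls, Mendelian checks,
population distributions, and SNP-copy linkage (r-squared).

All comparisons are over *unordered* pairs: the method can infer which two
chromosome-specific copy numbers an individual carries, but not which
physical chromosome carries which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from cnphase.hapio import LocalHaplotypeSet, Pedigree

if TYPE_CHECKING:  # pragma: no cover
    from cnphase.phaser import DiplotypeCallSet
    from cnphase.simulator import SimTruth

Pair = Tuple[int, int]


@dataclass
class EvalReport:
    """Summary of one evaluation run."""

    accuracy: Optional[float] = None
    miscall_rate_0_2: Optional[float] = None
    mendelian_rates: Dict[str, float] = field(default_factory=dict)
    haploid_freqs: Dict[int, float] = field(default_factory=dict)
    diplotype_freqs: Dict[Pair, float] = field(default_factory=dict)
    mean_r2: Dict[str, float] = field(default_factory=dict)


def _norm(pair: Pair) -> Pair:
    return tuple(sorted(pair))


def accuracy(calls: "DiplotypeCallSet", truth: "SimTruth") -> float:
    """Fraction of individuals whose unordered call equals the truth pair.

    Unresolved calls (-1, -1) count as incorrect.
    """
    if set(calls.pairs) != set(truth.pairs):
        raise ValueError("calls and truth cover different individuals")
    total = len(truth.pairs)
    correct = sum(
        _norm(calls.pairs[s]) == _norm(truth.pairs[s]) for s in truth.pairs
    )
    return correct / total


def miscall_rate_oneone(calls: "DiplotypeCallSet", truth: "SimTruth") -> float:
    """Fraction of truly-1/1 individuals called as the 0/2 configuration."""
    for s, p in truth.pairs.items():
        if _norm(p) != (1, 1):
            raise ValueError(f"{s}: truth {p} is not 1/1; wrong experiment")
    n = len(truth.pairs)
    miscalled = sum(_norm(calls.pairs[s]) == (0, 2) for s in truth.pairs)
    return miscalled / n


def mendelian_rate(
    calls: "DiplotypeCallSet", pedigree: Pedigree
) -> Tuple[float, int]:
    """Mendelian consistent rate among fully-called trios at one CNV.

    A trio is consistent when the child's unordered pair can be formed by
    taking one copy-number value from the father's pair and one from the
    mother's.  Trios with a missing or unresolved member are excluded; the
    second return value counts them.
    """
    consistent = 0
    called = 0
    excluded = 0
    for child, father, mother in pedigree.trios:
        members = (child, father, mother)
        if any(m not in calls.pairs or calls.pairs[m][0] < 0 for m in members):
            excluded += 1
            continue
        called += 1
        c = _norm(calls.pairs[child])
        f, m = calls.pairs[father], calls.pairs[mother]
        ok = any(_norm((fi, mj)) == c for fi in f for mj in m)
        consistent += ok
    if called == 0:
        raise ValueError("no fully-called trio")
    return consistent / called, excluded


def distributions(
    calls: Sequence["DiplotypeCallSet"],
) -> Tuple[Dict[int, float], Dict[Pair, float]]:
    """Haploid and diplotype-configuration frequency tables over all calls.

    The haploid table pools both chromosome slots; unresolved calls are
    skipped.  Each table is normalized to sum to 1.
    """
    hap: Dict[int, int] = {}
    dip: Dict[Pair, int] = {}
    for cs in calls:
        for pair in cs.pairs.values():
            if pair[0] < 0 or pair[1] < 0:
                continue
            key = _norm(pair)
            dip[key] = dip.get(key, 0) + 1
            for v in pair:
                hap[v] = hap.get(v, 0) + 1
    if not dip:
        raise ValueError("no resolved calls")
    nh = sum(hap.values())
    nd = sum(dip.values())
    return (
        {k: v / nh for k, v in sorted(hap.items())},
        {k: v / nd for k, v in sorted(dip.items())},
    )


def cnv_snp_r2(
    haplotypes: Union[LocalHaplotypeSet, np.ndarray],
    hap_copy_labels: Sequence[int],
) -> Optional[float]:
    """Mean squared correlation between SNP alleles and the copy allele.

    Per SNP, the squared Pearson correlation between the 0/1 SNP allele and
    an indicator of the most frequent non-1 copy allele, over haplotype
    rows; monomorphic SNPs are skipped.  Returns None when undefined (all
    haplotypes carry copy 1, or no polymorphic SNP).
    """
    H = haplotypes.haplotypes if isinstance(haplotypes, LocalHaplotypeSet) else haplotypes
    H = np.asarray(H)
    labels = np.asarray(hap_copy_labels)
    if labels.shape[0] != H.shape[0]:
        raise ValueError("one copy label per haplotype row is required")
    non_one = labels[labels != 1]
    if non_one.size == 0:
        return None
    values, counts = np.unique(non_one, return_counts=True)
    focal = int(values[np.argmax(counts)])
    y = (labels == focal).astype(float)
    if y.std() == 0:
        return None
    r2s: List[float] = []
    for j in range(H.shape[1]):
        x = H[:, j].astype(float)
        if x.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2s.append(float(r * r))
    if not r2s:
        return None
    return float(np.mean(r2s))
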