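"""Synthetic panels: HWE diplotypes, LD-tagged haplotypes, X-pairing, trios.

The generator emulates the study conditions under which background-haplotype
inference is meaningful: each chromosome-specific copy-number allele carries
its own *tag* haplotype (maximally separated binary strings, pairwise
hamming distance about half the SNP count, built from Hadamard codes), LD is
decayed by flipping each SNP allele independently with a given probability,
and diplotype configurations are drawn to match Hardy-Weinberg counts
exactly (complete mode) or perturbed one diplotype at a time until the
chi-square P-value first drops below a target (default 0.98).

Defaults: 16 individuals, haploid copy-allele frequencies {1: 0.75, 0: 0.25},
16 SNPs, no flipping (perfect LD, mean r-squared 1.0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import hadamard
from scipy.stats import chi2

from cnphase.evaluation import cnv_snp_r2
from cnphase.hapio import CNVRecord, HaplotypePanel, LocalHaplotypeSet, Pedigree
from cnphase.rngutil import SeedLike, as_seedseq

logger = logging.getLogger(__name__)

Pair = Tuple[int, int]


@dataclass
class SimConfig:
    """Study conditions for one simulated CNV panel."""

    n_individuals: int = 16
    copy_freqs: Dict[int, float] = field(default_factory=lambda: {1: 0.75, 0: 0.25})
    n_snps: int = 16
    ld_flip_fraction: float = 0.0
    hwe_mode: str = "complete"  # or "perturbed"
    target_hwe_p: float = 0.98
    seed: SeedLike = None
    cnv_id: str = "sim_cnv"
    chrom: str = "1"
    cnv_start: int = 10000
    cnv_end: int = 12000

    def __post_init__(self) -> None:
        total = sum(self.copy_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"copy-allele frequencies sum to {total}, not 1")
        if not 0.0 <= self.ld_flip_fraction <= 1.0:
            raise ValueError("ld_flip_fraction must be in [0, 1]")
        if self.hwe_mode not in ("complete", "perturbed"):
            raise ValueError(f"unknown hwe_mode {self.hwe_mode!r}")
        if any(c < 0 for c in self.copy_freqs):
            raise ValueError("copy-number alleles must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted beside every simulated panel."""

    pairs: Dict[str, Pair]  # unordered true diplotype per individual
    hap_copy_labels: List[int]  # true copy allele per haplotype row
    achieved_hwe_p: float
    achieved_mean_r2: float


def tag_haplotypes(n_alleles: int, n_snps: int) -> np.ndarray:
    """Distinct tag haplotypes, pairwise separated by about n_snps / 2.

    Rows of a Hadamard matrix (order: smallest power of two >= n_alleles)
    are tiled/truncated to n_snps columns; distinct rows differ in exactly
    half of each full block.
    """
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    order = 1
    while order < max(2, n_alleles):
        order *= 2
    H = hadamard(order)
    reps = -(-n_snps // order)  # ceil
    tiled = np.tile(H, (1, reps))[:, :n_snps]
    return (tiled < 0).astype(np.uint8)[:n_alleles]


def hwe_expected_counts(freqs: Dict[int, float], n: int) -> Dict[Pair, float]:
    """Expected HWE diplotype counts (unordered pairs) for n individuals."""
    alleles = sorted(freqs)
    out: Dict[Pair, float] = {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            p = freqs[a] * freqs[b] * (1 if a == b else 2)
            out[(a, b)] = n * p
    return out


def _round_counts(expected: Dict[Pair, float], n: int) -> Dict[Pair, int]:
    """Largest-remainder rounding to integer counts summing to n."""
    floors = {k: int(np.floor(v)) for k, v in expected.items()}
    deficit = n - sum(floors.values())
    remainders = sorted(
        expected, key=lambda k: (-(expected[k] - floors[k]), k)
    )
    for k in remainders[:deficit]:
        floors[k] += 1
    return floors


def hwe_chisq_p(counts: Dict[Pair, int]) -> float:
    """Chi-square goodness-of-fit P of diplotype counts against HWE.

    Allele frequencies are estimated from the counts themselves;
    df = g(g-1)/2 for g observed alleles.  Monomorphic data give P = 1.
    """
    n = sum(counts.values())
    if n == 0:
        return 1.0
    allele_counts: Dict[int, int] = {}
    for (a, b), c in counts.items():
        allele_counts[a] = allele_counts.get(a, 0) + c
        allele_counts[b] = allele_counts.get(b, 0) + c
    alleles = sorted(a for a, c in allele_counts.items() if c > 0)
    g = len(alleles)
    if g <= 1:
        return 1.0
    freqs = {a: allele_counts[a] / (2 * n) for a in alleles}
    expected = hwe_expected_counts(freqs, n)
    stat = 0.0
    for pair, e in expected.items():
        if e > 0:
            o = counts.get(pair, 0)
            stat += (o - e) ** 2 / e
    df = g * (g - 1) // 2
    return float(chi2.sf(stat, df))


def _perturb_counts(
    counts: Dict[Pair, int],
    configs: List[Pair],
    target_p: float,
    rng: np.random.Generator,
) -> Dict[Pair, int]:
    """Move single diplotypes until the HWE P first drops to <= target.

    Each step evaluates every single-individual reassignment and applies the
    one that lowers P the least (greedy smallest perturbation); ties broken
    at random.
    """
    counts = dict(counts)
    p = hwe_chisq_p(counts)
    guard = 0
    while p > target_p and guard < 10 * sum(counts.values()):
        guard += 1
        candidates: List[Tuple[float, Pair, Pair]] = []
        for src in configs:
            if counts.get(src, 0) == 0:
                continue
            for dst in configs:
                if dst == src:
                    continue
                trial = dict(counts)
                trial[src] -= 1
                trial[dst] = trial.get(dst, 0) + 1
                q = hwe_chisq_p(trial)
                if q < p:
                    candidates.append((q, src, dst))
        if not candidates:
            break
        best_q = max(q for q, _, _ in candidates)
        ties = [c for c in candidates if c[0] == best_q]
        q, src, dst = ties[rng.integers(len(ties))]
        counts[src] -= 1
        counts[dst] = counts.get(dst, 0) + 1
        p = q
    return counts


def _positions(cfg_start: int, cfg_end: int, n_snps: int) -> np.ndarray:
    """SNPs evenly spread over the one-fold extension window of the CNV."""
    length = cfg_end - cfg_start
    lo, hi = cfg_start - length, cfg_end + length
    return (lo + (np.arange(n_snps) + 0.5) * (hi - lo) / n_snps).astype(np.int64)


def _assemble(
    cfg: SimConfig,
    pairs: List[Pair],
    rng: np.random.Generator,
    achieved_p: float,
) -> Tuple[HaplotypePanel, CNVRecord, SimTruth]:
    alleles = sorted({a for p in pairs for a in p})
    tag_of = dict(zip(alleles, tag_haplotypes(len(alleles), cfg.n_snps)))
    sample_ids = [f"s{i:02d}" for i in range(len(pairs))]
    rows = []
    labels: List[int] = []
    for a, b in pairs:
        # order within the individual is arbitrary; shuffle the slot
        order = (a, b) if rng.integers(2) == 0 else (b, a)
        for allele in order:
            hap = tag_of[allele].copy()
            if cfg.ld_flip_fraction > 0:
                flips = rng.random(cfg.n_snps) < cfg.ld_flip_fraction
                hap = hap ^ flips.astype(np.uint8)
            rows.append(hap)
            labels.append(allele)
    matrix = np.vstack(rows)
    panel = HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=[f"snp{j:03d}" for j in range(cfg.n_snps)],
        snp_positions=_positions(cfg.cnv_start, cfg.cnv_end, cfg.n_snps),
        alleles=matrix,
        chrom=cfg.chrom,
    )
    totals = {s: int(a + b) for s, (a, b) in zip(sample_ids, pairs)}
    record = CNVRecord(cfg.cnv_id, cfg.chrom, cfg.cnv_start, cfg.cnv_end, dict(totals))
    r2 = cnv_snp_r2(matrix, labels)
    truth = SimTruth(
        pairs={s: tuple(sorted(p)) for s, p in zip(sample_ids, pairs)},
        hap_copy_labels=labels,
        achieved_hwe_p=achieved_p,
        achieved_mean_r2=float("nan") if r2 is None else r2,
    )
    return panel, record, truth


def simulate_panel(cfg: SimConfig) -> Tuple[HaplotypePanel, CNVRecord, SimTruth]:
    """Simulate one CNV panel under the configured HWE mode and LD level."""
    rng = np.random.default_rng(as_seedseq(cfg.seed))
    expected = hwe_expected_counts(cfg.copy_freqs, cfg.n_individuals)
    counts = _round_counts(expected, cfg.n_individuals)
    configs = sorted(expected)
    if cfg.hwe_mode == "perturbed":
        counts = _perturb_counts(counts, configs, cfg.target_hwe_p, rng)
    achieved_p = hwe_chisq_p(counts)
    if cfg.hwe_mode == "complete" and achieved_p < 1.0 - 1e-9:
        logger.info(
            "exact HWE counts infeasible for n=%d; achieved P=%.4f",
            cfg.n_individuals,
            achieved_p,
        )
    pairs: List[Pair] = []
    for pair in configs:
        pairs.extend([pair] * counts.get(pair, 0))
    perm = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in perm]
    return _assemble(cfg, pairs, rng, achieved_p)


def simulate_x_pairs(
    haploid_calls: Sequence[Tuple[Sequence[int], int]],
    cfg: Optional[SimConfig] = None,
    seed: SeedLike = None,
) -> Tuple[HaplotypePanel, CNVRecord, SimTruth]:
    """Random disjoint pairing of haploid (haplotype, copy) records.

    Emulates building diploid totals from male X chromosomes, where the
    measured total *is* the chromosome-specific copy number.  An odd record
    count drops the last shuffled record with a warning.
    """
    if len(haploid_calls) < 2:
        raise ValueError("need at least two haploid records to pair")
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(as_seedseq(seed if seed is not None else cfg.seed))
    order = rng.permutation(len(haploid_calls))
    if len(order) % 2 == 1:
        logger.warning("odd number of haploid records; dropping one")
        order = order[:-1]
    sample_ids = [f"s{i:02d}" for i in range(len(order) // 2)]
    rows: List[np.ndarray] = []
    labels: List[int] = []
    pairs: Dict[str, Pair] = {}
    totals: Dict[str, Optional[int]] = {}
    for j, sid in enumerate(sample_ids):
        (h1, c1) = haploid_calls[order[2 * j]]
        (h2, c2) = haploid_calls[order[2 * j + 1]]
        rows.extend([np.asarray(h1, dtype=np.uint8), np.asarray(h2, dtype=np.uint8)])
        labels.extend([int(c1), int(c2)])
        pairs[sid] = tuple(sorted((int(c1), int(c2))))
        totals[sid] = int(c1) + int(c2)
    matrix = np.vstack(rows)
    n_snps = matrix.shape[1]
    panel = HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=[f"snp{j:03d}" for j in range(n_snps)],
        snp_positions=_positions(cfg.cnv_start, cfg.cnv_end, n_snps),
        alleles=matrix,
        chrom=cfg.chrom,
    )
    record = CNVRecord(cfg.cnv_id, cfg.chrom, cfg.cnv_start, cfg.cnv_end, totals)
    r2 = cnv_snp_r2(matrix, labels)
    truth = SimTruth(
        pairs=pairs,
        hap_copy_labels=labels,
        achieved_hwe_p=hwe_chisq_p(
            _pairs_to_counts(list(pairs.values()))
        ),
        achieved_mean_r2=float("nan") if r2 is None else r2,
    )
    return panel, record, truth


def _pairs_to_counts(pairs: Sequence[Pair]) -> Dict[Pair, int]:
    out: Dict[Pair, int] = {}
    for p in pairs:
        key = tuple(sorted(p))
        out[key] = out.get(key, 0) + 1
    return out


def simulate_oneone_panel(
    n_individuals: int = 16,
    frac_noninformative: float = 0.0,
    n_snps: int = 16,
    seed: SeedLike = None,
) -> Tuple[HaplotypePanel, CNVRecord, SimTruth]:
    """A no-CNV panel: every individual truly 1/1, total copy number 2.

    All haplotype rows start as the copy-1 tag haplotype; then
    ``round(frac_noninformative * 2n)`` rows, chosen uniformly, are replaced
    with uniform-random strings that carry no LD information.  Used to
    measure how often 1/1 is miscalled as 0/2.
    """
    if not 0.0 <= frac_noninformative <= 1.0:
        raise ValueError("frac_noninformative must be in [0, 1]")
    cfg = SimConfig(n_individuals=n_individuals, n_snps=n_snps, seed=seed)
    rng = np.random.default_rng(as_seedseq(seed))
    tag = tag_haplotypes(2, n_snps)[1]
    matrix = np.tile(tag, (2 * n_individuals, 1)).astype(np.uint8)
    n_replace = int(round(frac_noninformative * 2 * n_individuals))
    if n_replace:
        which = rng.choice(2 * n_individuals, size=n_replace, replace=False)
        matrix[which] = rng.integers(0, 2, size=(n_replace, n_snps), dtype=np.uint8)
    sample_ids = [f"s{i:02d}" for i in range(n_individuals)]
    panel = HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=[f"snp{j:03d}" for j in range(n_snps)],
        snp_positions=_positions(cfg.cnv_start, cfg.cnv_end, n_snps),
        alleles=matrix,
        chrom=cfg.chrom,
    )
    totals: Dict[str, Optional[int]] = {s: 2 for s in sample_ids}
    record = CNVRecord(cfg.cnv_id, cfg.chrom, cfg.cnv_start, cfg.cnv_end, totals)
    labels = [1] * (2 * n_individuals)
    truth = SimTruth(
        pairs={s: (1, 1) for s in sample_ids},
        hap_copy_labels=labels,
        achieved_hwe_p=1.0,
        achieved_mean_r2=float("nan"),  # single copy allele: r2 undefined
    )
    return panel, record, truth


def simulate_trios(
    n_trios: int, cfg: Optional[SimConfig] = None
) -> Tuple[HaplotypePanel, CNVRecord, SimTruth, Pedigree]:
    """Trios with faithful inheritance: each child receives one
    (haplotype, copy) unit from each parent, chosen uniformly.

    Parents are drawn exactly as in :func:`simulate_panel`; children copy
    the parent's realized haplotype rows, so LD noise is inherited too.
    """
    cfg = cfg or SimConfig()
    if n_trios == 0:
        empty = Pedigree([])
        panel = HaplotypePanel([], [f"snp{j:03d}" for j in range(cfg.n_snps)],
                               _positions(cfg.cnv_start, cfg.cnv_end, cfg.n_snps),
                               np.zeros((0, cfg.n_snps), dtype=np.uint8), cfg.chrom)
        record = CNVRecord(cfg.cnv_id, cfg.chrom, cfg.cnv_start, cfg.cnv_end, {})
        return panel, record, SimTruth({}, [], 1.0, float("nan")), empty
    parent_cfg = SimConfig(
        n_individuals=2 * n_trios,
        copy_freqs=dict(cfg.copy_freqs),
        n_snps=cfg.n_snps,
        ld_flip_fraction=cfg.ld_flip_fraction,
        hwe_mode=cfg.hwe_mode,
        target_hwe_p=cfg.target_hwe_p,
        seed=cfg.seed,
        cnv_id=cfg.cnv_id,
        chrom=cfg.chrom,
        cnv_start=cfg.cnv_start,
        cnv_end=cfg.cnv_end,
    )
    p_panel, _, p_truth = simulate_panel(parent_cfg)
    rng = np.random.default_rng(as_seedseq(cfg.seed).spawn(1)[0])
    sample_ids: List[str] = []
    rows: List[np.ndarray] = []
    labels: List[int] = []
    pairs: Dict[str, Pair] = {}
    trios: List[Tuple[str, str, str]] = []
    for t in range(n_trios):
        father, mother, child = f"f{t:02d}", f"m{t:02d}", f"c{t:02d}"
        trios.append((child, father, mother))
        child_rows = []
        child_labels = []
        for parent_idx, pid in ((2 * t, father), (2 * t + 1, mother)):
            for slot in (0, 1):
                rows.append(p_panel.alleles[2 * parent_idx + slot])
                labels.append(p_truth.hap_copy_labels[2 * parent_idx + slot])
            sample_ids.append(pid)
            pairs[pid] = p_truth.pairs[f"s{parent_idx:02d}"]
            transmit = int(rng.integers(2))
            child_rows.append(p_panel.alleles[2 * parent_idx + transmit])
            child_labels.append(p_truth.hap_copy_labels[2 * parent_idx + transmit])
        sample_ids.append(child)
        rows.extend(child_rows)
        labels.extend(child_labels)
        pairs[child] = tuple(sorted(child_labels))
    matrix = np.vstack(rows)
    panel = HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=list(p_panel.snp_ids),
        snp_positions=p_panel.snp_positions,
        alleles=matrix,
        chrom=cfg.chrom,
    )
    totals: Dict[str, Optional[int]] = {s: int(sum(pairs[s])) for s in sample_ids}
    record = CNVRecord(cfg.cnv_id, cfg.chrom, cfg.cnv_start, cfg.cnv_end, totals)
    r2 = cnv_snp_r2(matrix, labels)
    truth = SimTruth(
        pairs=pairs,
        hap_copy_labels=labels,
        achieved_hwe_p=p_truth.achieved_hwe_p,
        achieved_mean_r2=float("nan") if r2 is None else r2,
    )
    return panel, record, truth, Pedigree(trios)


def write_truth(truth: SimTruth, path: str) -> None:
    """Write the truth table beside a simulated panel."""
    with open(path, "w") as fh:
        fh.write(
            f"#achieved_hwe_p={truth.achieved_hwe_p!r}\t"
            f"achieved_mean_r2={truth.achieved_mean_r2!r}\n"
        )
        fh.write("sample_id\tcopy_a\tcopy_b\n")
        for sid in sorted(truth.pairs):
            a, b = truth.pairs[sid]
            fh.write(f"{sid}\t{a}\t{b}\n")


def read_truth(path: str) -> SimTruth:
    """Read a truth table written by :func:`write_truth`.

    Haplotype-level copy labels are not serialized; the returned truth
    carries the per-individual pairs and the recorded summary statistics.
    """
    pairs: Dict[str, Pair] = {}
    achieved_p = float("nan")
    achieved_r2 = float("nan")
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    key, _, value = token.partition("=")
                    if key == "achieved_hwe_p":
                        achieved_p = float(value)
                    elif key == "achieved_mean_r2":
                        achieved_r2 = float(value)
                continue
            parts = line.split("\t")
            if not line or parts[0] == "sample_id":
                continue
            pairs[parts[0]] = (int(parts[1]), int(parts[2]))
    return SimTruth(
        pairs=pairs,
        hap_copy_labels=[],
        achieved_hwe_p=achieved_p,
        achieved_mean_r2=achieved_r2,
    )


def panel_to_local(panel: HaplotypePanel, record: CNVRecord) -> LocalHaplotypeSet:
    """Whole simulated panel as a LocalHaplotypeSet (all SNPs in window)."""
    return LocalHaplotypeSet(
        cnv_id=record.cnv_id,
        sample_ids=list(panel.sample_ids),
        haplotypes=panel.alleles,
        window=(int(panel.snp_positions[0]), int(panel.snp_positions[-1]) + 1),
        snp_ids=list(panel.snp_ids),
    )
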