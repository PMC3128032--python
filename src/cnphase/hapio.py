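"""Input/output for phased haplotypes, CNV total copy numbers, pedigrees and calls.

Two haplotype input formats are supported:

* a plain whitespace-delimited *hap-matrix* dialect: an optional ``chrom``
  line, a ``sample_ids`` header line, then one line per SNP containing the
  SNP id, its base-pair position and one allele symbol per haplotype column
  (two adjacent columns per sample: haplotype A then haplotype B);
* standard VCF with phased genotypes (``|`` separator), read with cyvcf2;
  unphased or multiallelic records are skipped with a logged count.

Alleles are recoded per SNP to 0 (major) / 1 (minor); hamming distances are
unaffected by the coding.  CNV coordinates are BED-style 0-based half-open;
VCF positions are converted from 1-based.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Dict, List, Optional, Sequence, Tuple

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from cnphase.phaser import DiplotypeCallSet

logger = logging.getLogger(__name__)

MISSING = "."


class ParseError(ValueError):
    """Malformed input file (message carries the offending line number)."""


class EmptyWindowError(ValueError):
    """No SNP falls inside the selected window around a CNV."""


@dataclass
class HaplotypePanel:
    """Phased biallelic SNP haplotypes for a set of samples.

    ``alleles`` has ``2 * n_samples`` rows: rows ``2i`` and ``2i + 1`` are
    haplotypes A and B of sample ``i``.
    """

    sample_ids: List[str]
    snp_ids: List[str]
    snp_positions: np.ndarray
    alleles: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.snp_positions = np.asarray(self.snp_positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.alleles.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"allele matrix has {self.alleles.shape[0]} rows, "
                f"expected 2 x {len(self.sample_ids)} samples"
            )
        if self.alleles.shape[1] != len(self.snp_ids):
            raise ValueError("allele matrix width does not match SNP count")
        if len(self.snp_ids) != len(self.snp_positions):
            raise ValueError("snp_ids and snp_positions length mismatch")
        if len(self.snp_positions) > 1 and not np.all(np.diff(self.snp_positions) > 0):
            raise ValueError("SNP positions must be strictly increasing")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("alleles must be recoded to 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_rows(self, sample_id: str) -> Tuple[np.ndarray, np.ndarray]:
        i = self.sample_ids.index(sample_id)
        return self.alleles[2 * i], self.alleles[2 * i + 1]


@dataclass
class CNVRecord:
    """One CNV locus with per-sample total copy numbers.

    Coordinates are 0-based half-open.  ``totals`` maps sample id to a
    non-negative integer total copy number, or ``None`` when missing; a
    missing total excludes that sample from this CNV only.
    """

    cnv_id: str
    chrom: str
    start: int
    end: int
    totals: Dict[str, Optional[int]]

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.cnv_id}: end must exceed start")
        for sid, t in self.totals.items():
            if t is not None and t < 0:
                raise ValueError(f"{self.cnv_id}: negative total for {sid}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def called_samples(self) -> List[str]:
        return [s for s, t in self.totals.items() if t is not None]


@dataclass
class LocalHaplotypeSet:
    """Per-CNV haplotype pairs restricted to the selected SNP window."""

    cnv_id: str
    sample_ids: List[str]
    haplotypes: np.ndarray  # (2 * n_samples, n_snps) of 0/1
    window: Tuple[int, int]
    snp_ids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype matrix must have two rows per sample")
        if self.n_snps < 1:
            raise ValueError("a local haplotype set needs at least one SNP")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def strings(self, sample_id: str) -> Tuple[str, str]:
        i = self.sample_ids.index(sample_id)
        a, b = self.haplotypes[2 * i], self.haplotypes[2 * i + 1]
        return "".join(map(str, a)), "".join(map(str, b))


@dataclass
class Pedigree:
    """Parent-offspring trios: (child_id, father_id, mother_id)."""

    trios: List[Tuple[str, str, str]]

    def __post_init__(self) -> None:
        for child, father, mother in self.trios:
            if child in (father, mother):
                raise ValueError(f"{child} cannot be its own parent")

    def validate_against(self, sample_ids: Sequence[str]) -> None:
        known = set(sample_ids)
        for trio in self.trios:
            for sid in trio:
                if sid not in known:
                    raise ValueError(f"pedigree id {sid!r} not among samples")


def _recode_biallelic(columns: List[List[str]], snp_ids: List[str]) -> np.ndarray:
    """Recode raw allele symbols to 0 (major) / 1 (minor), column-wise."""
    n_hap = len(columns[0])
    out = np.zeros((n_hap, len(columns)), dtype=np.uint8)
    for j, col in enumerate(columns):
        symbols = sorted(set(col))
        if len(symbols) > 2:
            raise ParseError(f"SNP {snp_ids[j]} has >2 allele symbols: {symbols}")
        if len(symbols) == 1:
            continue  # monomorphic: all zeros
        counts = {s: col.count(s) for s in symbols}
        # major symbol -> 0; count ties broken toward the smaller symbol
        major = max(symbols, key=lambda s: (counts[s], s != min(symbols)))
        out[:, j] = [0 if a == major else 1 for a in col]
    return out


def _read_hap_matrix(path: str) -> HaplotypePanel:
    chrom = "1"
    sample_ids: Optional[List[str]] = None
    snp_ids: List[str] = []
    positions: List[int] = []
    columns: List[List[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "chrom":
                if len(parts) != 2:
                    raise ParseError(f"line {lineno}: malformed chrom line")
                chrom = parts[1]
                continue
            if parts[0] == "sample_ids":
                sample_ids = parts[1:]
                if not sample_ids:
                    raise ParseError(f"line {lineno}: no sample ids")
                continue
            if sample_ids is None:
                raise ParseError(f"line {lineno}: missing sample_ids header")
            if len(parts) != 2 + 2 * len(sample_ids):
                raise ParseError(
                    f"line {lineno}: expected {2 + 2 * len(sample_ids)} fields, "
                    f"got {len(parts)}"
                )
            snp_ids.append(parts[0])
            try:
                positions.append(int(parts[1]))
            except ValueError as exc:
                raise ParseError(f"line {lineno}: bad position {parts[1]!r}") from exc
            columns.append(parts[2:])
    if sample_ids is None or not snp_ids:
        raise ParseError(f"{path}: empty haplotype file")
    alleles = _recode_biallelic(columns, snp_ids)
    return HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        snp_positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        chrom=chrom,
    )


def _read_vcf(path: str) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ParseError(f"{path}: VCF has no samples")
    snp_ids: List[str] = []
    positions: List[int] = []
    rows: List[np.ndarray] = []
    chrom: Optional[str] = None
    skipped = 0
    for var in vcf:
        gts = np.asarray(var.genotypes)  # (n_samples, 3): a, b, phased flag
        if len(var.ALT) != 1 or not np.all(gts[:, 2]) or gts[:, :2].min() < 0:
            skipped += 1
            continue
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            skipped += 1
            continue
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        positions.append(var.POS)  # 1-based in VCF; kept as-is, windows use bp spans
        rows.append(gts[:, :2].reshape(-1).astype(np.uint8))
    if skipped:
        logger.info("skipped %d unphased/multiallelic/off-chrom VCF records", skipped)
    if not snp_ids:
        raise ParseError(f"{path}: no usable phased biallelic records")
    alleles = np.column_stack(rows)
    return HaplotypePanel(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        snp_positions=np.array(positions, dtype=np.int64) - 1,  # to 0-based
        alleles=alleles,
        chrom=chrom or "1",
    )


def read_haplotypes(path: str, format: str = "hap-matrix") -> HaplotypePanel:
    """Read a phased haplotype panel from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"hap-matrix"`` (plain-text dialect) or ``"vcf"``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format in ("hap-matrix", "hapmatrix"):
        return _read_hap_matrix(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown haplotype format {format!r}")


def write_haplotypes(panel: HaplotypePanel, path: str) -> None:
    """Write a panel in the hap-matrix dialect (inverse of read_haplotypes)."""
    with open(path, "w") as fh:
        fh.write(f"chrom {panel.chrom}\n")
        fh.write("sample_ids " + " ".join(panel.sample_ids) + "\n")
        for j, (sid, pos) in enumerate(zip(panel.snp_ids, panel.snp_positions)):
            row = " ".join(str(a) for a in panel.alleles[:, j])
            fh.write(f"{sid} {pos} {row}\n")


def read_cnv_table(path: str) -> List[CNVRecord]:
    """Read the CNV totals table: ``cnv_id chrom start end <sample...>`` TSV."""
    records: List[CNVRecord] = []
    with open(path) as fh:
        header: Optional[List[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if header is None:
                if parts[:4] != ["cnv_id", "chrom", "start", "end"]:
                    raise ParseError(
                        f"line {lineno}: header must start with "
                        "'cnv_id chrom start end'"
                    )
                header = parts[4:]
                if not header:
                    raise ParseError(f"line {lineno}: no sample columns")
                continue
            if len(parts) != 4 + len(header):
                raise ParseError(f"line {lineno}: expected {4 + len(header)} fields")
            totals: Dict[str, Optional[int]] = {}
            for sid, cell in zip(header, parts[4:]):
                if cell == MISSING:
                    totals[sid] = None
                    continue
                try:
                    value = int(cell)
                except ValueError as exc:
                    raise ParseError(
                        f"line {lineno}: non-integer total {cell!r} for {sid}"
                    ) from exc
                totals[sid] = value
            try:
                records.append(
                    CNVRecord(parts[0], parts[1], int(parts[2]), int(parts[3]), totals)
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    if header is None:
        raise ParseError(f"{path}: empty CNV table")
    return records


def write_cnv_table(records: Sequence[CNVRecord], path: str) -> None:
    samples = list(records[0].totals) if records else []
    with open(path, "w") as fh:
        fh.write("\t".join(["cnv_id", "chrom", "start", "end"] + samples) + "\n")
        for rec in records:
            cells = [
                MISSING if rec.totals[s] is None else str(rec.totals[s])
                for s in samples
            ]
            fh.write(
                "\t".join([rec.cnv_id, rec.chrom, str(rec.start), str(rec.end)] + cells)
                + "\n"
            )


def read_pedigree(path: str) -> Pedigree:
    """Read a trio pedigree TSV: ``child father mother`` per line."""
    trios: List[Tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.split()[0] == "child":
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"line {lineno}: expected 'child father mother'")
            trios.append((parts[0], parts[1], parts[2]))
    return Pedigree(trios)


def select_window(
    panel: HaplotypePanel,
    cnv: CNVRecord,
    extension_factor: float = 1.0,
) -> LocalHaplotypeSet:
    """Select SNPs within ``extension_factor`` CNV-lengths of the CNV.

    With L = end - start the window is [start - f*L, end + f*L), so the
    default f = 1.0 spans three CNV lengths centred on the CNV.  Raises
    :class:`EmptyWindowError` when no SNP falls inside; the caller may widen
    the factor or skip the CNV.
    """
    if extension_factor < 0:
        raise ValueError("extension_factor must be >= 0")
    if panel.chrom != cnv.chrom:
        raise ValueError(
            f"panel chromosome {panel.chrom!r} != CNV chromosome {cnv.chrom!r}"
        )
    span = cnv.length * extension_factor
    lo = int(np.floor(cnv.start - span))
    hi = int(np.ceil(cnv.end + span))
    mask = (panel.snp_positions >= lo) & (panel.snp_positions < hi)
    if not mask.any():
        raise EmptyWindowError(
            f"{cnv.cnv_id}: no SNPs in window [{lo}, {hi}) at f={extension_factor}"
        )
    return LocalHaplotypeSet(
        cnv_id=cnv.cnv_id,
        sample_ids=list(panel.sample_ids),
        haplotypes=panel.alleles[:, mask],
        window=(lo, hi),
        snp_ids=[s for s, m in zip(panel.snp_ids, mask) if m],
    )


_CALL_COLUMNS = ["cnv_id", "sample_id", "copy_hapA", "copy_hapB", "total", "satisfied", "k"]


def write_calls(calls: Sequence["DiplotypeCallSet"], path: str) -> None:
    """Write diplotype calls as TSV; unassigned copies (-1) serialize as NA."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CALL_COLUMNS) + "\n")
        for cs in calls:
            for sid in cs.sample_ids:
                a, b = cs.pairs[sid]
                total = cs.totals[sid]
                if a < 0 or b < 0:
                    logger.warning(
                        "%s %s: unresolved call serialized as NA", cs.cnv_id, sid
                    )
                fields = [
                    cs.cnv_id,
                    sid,
                    "NA" if a < 0 else str(a),
                    "NA" if b < 0 else str(b),
                    str(total),
                    "true" if cs.satisfied[sid] else "false",
                    str(cs.chosen_k),
                ]
                fh.write("\t".join(fields) + "\n")


def read_calls(path: str) -> List["DiplotypeCallSet"]:
    """Read a calls TSV back into DiplotypeCallSet objects (round-trip)."""
    from cnphase.phaser import DiplotypeCallSet

    groups: Dict[str, DiplotypeCallSet] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header != _CALL_COLUMNS:
            raise ParseError(f"{path}: unexpected calls header {header}")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_CALL_COLUMNS):
                raise ParseError(f"line {lineno}: expected {len(_CALL_COLUMNS)} fields")
            cnv_id, sid, a, b, total, sat, k = parts
            if cnv_id not in groups:
                groups[cnv_id] = DiplotypeCallSet(
                    cnv_id=cnv_id,
                    sample_ids=[],
                    pairs={},
                    totals={},
                    satisfied={},
                    chosen_k=int(k),
                    n_satisfied=0,
                )
            cs = groups[cnv_id]
            cs.sample_ids.append(sid)
            cs.pairs[sid] = (
                -1 if a == "NA" else int(a),
                -1 if b == "NA" else int(b),
            )
            cs.totals[sid] = int(total)
            cs.satisfied[sid] = sat == "true"
            cs.n_satisfied += sat == "true"
    return list(groups.values())
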