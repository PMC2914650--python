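"""Evolutionary rates: miRNA sequence divergence and protein dN ingestion.

miRNA evolutionary rate is measured as sequence divergence against an outgroup
(human vs. rhesus macaque in the original data): the proportion of substituted
columns among aligned (both-ungapped) columns of a pairwise genome alignment
that fall inside the miRNA's genomic interval.  Columns where either sequence
carries a gap are excluded from both the numerator and the denominator.  No
multiple-hit correction is applied by default (primate distances are small); a
Jukes–Cantor switch is available.

Protein evolutionary rate (dN, nonsynonymous substitutions per site) is an
input, read from a 2-column TSV.

Coordinates are 0-based half-open internally; AXT input (1-based inclusive)
is converted at the boundary, BED is native.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("mirnetevo")

GAP = "-"


class RateValidationError(ValueError):
    pass


class AlignmentParseError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentBlock:
    """One pairwise alignment block, reference coordinates on the plus strand."""

    ref_chrom: str
    ref_start: int  # 0-based start on the reference
    ref_aln: str  # reference sequence, may contain gaps
    query_aln: str  # query (outgroup) sequence, same aligned length

    def __post_init__(self) -> None:
        if len(self.ref_aln) != len(self.query_aln):
            raise AlignmentParseError(
                f"aligned lengths differ: {len(self.ref_aln)} vs "
                f"{len(self.query_aln)} ({self.ref_chrom}:{self.ref_start})"
            )
        if self.ref_start < 0:
            raise AlignmentParseError("ref_start must be >= 0")

    @property
    def ref_span(self) -> int:
        """Ungapped reference length = bases covered on ref_chrom."""
        return len(self.ref_aln) - self.ref_aln.count(GAP)

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


@dataclass(frozen=True)
class GenomicInterval:
    id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RateValidationError(
                f"{self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise RateValidationError(f"{self.id}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RateTable:
    """Mapping node id → non-negative evolutionary rate."""

    rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.rates.items():
            if not math.isfinite(v) or v < 0:
                raise RateValidationError(f"rate for {k!r} must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.rates)

    def __contains__(self, key: str) -> bool:
        return key in self.rates

    def __getitem__(self, key: str) -> float:
        return self.rates[key]

    def get(self, key: str, default=None):
        return self.rates.get(key, default)

    def items(self):
        return self.rates.items()


@dataclass(frozen=True)
class DivergenceRecord:
    """Divergence for one interval plus coverage QC.

    ``status`` is "ok", "no_alignment" (no aligned column overlaps the
    interval) or "low_coverage" (aligned fraction below the threshold); the
    rate is None unless status is "ok".
    """

    id: str
    rate: float | None
    n_substitutions: int
    n_aligned_sites: int
    aligned_fraction: float
    status: str


def mirna_divergence(
    blocks: Iterable[AlignmentBlock],
    interval: GenomicInterval,
    min_aligned_fraction: float = 0.5,
    jukes_cantor: bool = False,
) -> DivergenceRecord:
    """Sequence divergence of one miRNA interval from alignment blocks.

    Walks alignment columns whose reference coordinate falls in the interval;
    a column counts as an aligned site when both bases are ungapped and as a
    substitution when additionally the bases differ case-insensitively.  Where
    blocks overlap on the reference, the first block covering a position wins
    (best-in-genome pairwise alignments are normally non-overlapping).

    The count is strand-symmetric, so minus-strand intervals need no special
    handling: complementing both sequences preserves every match/mismatch.
    """
    n_subs = 0
    n_sites = 0
    covered: set[int] = set()
    warned_overlap = False
    for block in blocks:
        if block.ref_chrom != interval.chrom:
            continue
        if block.ref_end <= interval.start or block.ref_start >= interval.end:
            continue
        pos = block.ref_start
        for ref_c, qry_c in zip(block.ref_aln, block.query_aln):
            if ref_c == GAP:
                continue  # insertion in the query: no reference coordinate
            if interval.start <= pos < interval.end and qry_c != GAP:
                if pos in covered:
                    if not warned_overlap:
                        logger.warning(
                            "overlapping alignment blocks at %s:%d; first wins",
                            interval.chrom,
                            pos,
                        )
                        warned_overlap = True
                else:
                    covered.add(pos)
                    n_sites += 1
                    if ref_c.upper() != qry_c.upper():
                        n_subs += 1
            pos += 1
    frac = n_sites / len(interval)
    if n_sites == 0:
        return DivergenceRecord(interval.id, None, 0, 0, 0.0, "no_alignment")
    rate = n_subs / n_sites
    if jukes_cantor:
        arg = 1.0 - 4.0 * rate / 3.0
        rate = -0.75 * math.log(arg) if arg > 0 else math.inf
    if frac < min_aligned_fraction:
        return DivergenceRecord(interval.id, None, n_subs, n_sites, frac, "low_coverage")
    return DivergenceRecord(interval.id, rate, n_subs, n_sites, frac, "ok")


def divergence_table(
    blocks: Iterable[AlignmentBlock],
    intervals: Iterable[GenomicInterval],
    min_aligned_fraction: float = 0.5,
    jukes_cantor: bool = False,
) -> tuple[RateTable, pd.DataFrame]:
    """Divergence for every interval; excluded intervals appear only in QC.

    Returns the rate table (status "ok" only) and a QC frame with one row per
    interval: id, status, aligned_fraction, n_substitutions, n_aligned_sites.
    """
    blocks = list(blocks)
    records = [
        mirna_divergence(blocks, iv, min_aligned_fraction, jukes_cantor)
        for iv in intervals
    ]
    rates = {r.id: r.rate for r in records if r.status == "ok"}
    n_skipped = len(records) - len(rates)
    if n_skipped:
        logger.info("divergence: %d of %d intervals excluded", n_skipped, len(records))
    qc = pd.DataFrame(
        [
            (r.id, r.status, r.aligned_fraction, r.n_substitutions, r.n_aligned_sites)
            for r in records
        ],
        columns=["id", "status", "aligned_fraction", "n_subs", "n_sites"],
    )
    return RateTable(rates), qc


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_axt(path) -> list[AlignmentBlock]:
    """Read AXT pairwise alignment blocks.

    AXT headers are ``index refChrom refStart refEnd queryChrom qStart qEnd
    strand score`` with 1-based inclusive coordinates; converted to 0-based
    half-open on read.
    """
    blocks: list[AlignmentBlock] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].strip() or lines[i].startswith("#"):
            i += 1
            continue
        header = lines[i].split()
        if len(header) < 9:
            raise AlignmentParseError(f"{path}:{i + 1}: malformed AXT header")
        if i + 2 >= len(lines):
            raise AlignmentParseError(f"{path}:{i + 1}: truncated AXT block")
        ref_chrom, ref_start = header[1], int(header[2]) - 1
        block = AlignmentBlock(
            ref_chrom=ref_chrom,
            ref_start=ref_start,
            ref_aln=lines[i + 1].strip(),
            query_aln=lines[i + 2].strip(),
        )
        declared_end = int(header[3])
        if block.ref_end != declared_end:
            raise AlignmentParseError(
                f"{path}:{i + 1}: header span {ref_start + 1}-{declared_end} does "
                f"not match ungapped reference length {block.ref_span}"
            )
        blocks.append(block)
        i += 3
    return blocks


def write_axt(blocks: Iterable[AlignmentBlock], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for idx, b in enumerate(blocks):
            qlen = len(b.query_aln) - b.query_aln.count(GAP)
            fh.write(
                f"{idx} {b.ref_chrom} {b.ref_start + 1} {b.ref_end} "
                f"q_{b.ref_chrom} 1 {max(qlen, 1)} + 0\n"
            )
            fh.write(b.ref_aln + "\n")
            fh.write(b.query_aln + "\n\n")


def read_bed(path) -> list[GenomicInterval]:
    """Read miRNA coordinates from BED (>= 4 columns; strand from column 6)."""
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise RateValidationError(
                    f"{path}:{lineno}: BED needs chrom, start, end, name"
                )
            name = f[3]
            if name in seen:
                raise RateValidationError(f"{path}:{lineno}: duplicate name {name!r}")
            seen.add(name)
            strand = f[5] if len(f) >= 6 else "+"
            intervals.append(
                GenomicInterval(
                    id=name, chrom=f[0], start=int(f[1]), end=int(f[2]), strand=strand
                )
            )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


def load_rate_table(path) -> RateTable:
    """Read a 2-column TSV (id, rate); duplicate ids and bad rates are errors."""
    rates: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 2:
                raise RateValidationError(
                    f"{path}:{lineno}: expected 2 tab-separated fields"
                )
            if lineno == 1 and f[0] == "id":
                continue  # optional header
            key = f[0].strip()
            try:
                value = float(f[1])
            except ValueError as exc:
                raise RateValidationError(
                    f"{path}:{lineno}: non-numeric rate {f[1]!r}"
                ) from exc
            if key in rates:
                raise RateValidationError(f"{path}:{lineno}: duplicate id {key!r}")
            if not math.isfinite(value) or value < 0:
                raise RateValidationError(
                    f"{path}:{lineno}: rate must be finite and >= 0, got {value}"
                )
            rates[key] = value
    return RateTable(rates)


def write_rate_table(table: RateTable | Mapping[str, float], path) -> None:
    rates = table.rates if isinstance(table, RateTable) else dict(table)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "rate"])
        for key in sorted(rates):
            w.writerow([key, repr(float(rates[key]))])
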