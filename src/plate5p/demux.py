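"""Well-barcode / UMI extraction from Read2 and read-pair demultiplexing.

Read2 layout is positional: bases [0,8) are the well barcode, [8,13) the
UMI, and whatever remains is the observed part of the TATA spacer (a 16-cycle
read only sees its first bases). Barcodes are corrected against the plate
whitelist with a radius of one substitution — unambiguous because the
whitelist guarantees a minimum pairwise Hamming distance of 3. Pairs whose
barcode resolves to a negative-control well are counted separately and
excluded from downstream cells; every input pair lands in exactly one report
category.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .reference import BarcodeWhitelist, PlateLayout

DEFAULT_BARCODE_LEN = 8
DEFAULT_UMI_LEN = 5
#: reject a pair when the mean Phred over barcode+UMI bases falls below this
DEFAULT_MIN_MEAN_PHRED = 20.0


class DemuxError(ValueError):
    pass


class Read2TooShort(DemuxError):
    pass


@dataclass(frozen=True)
class TaggedRead:
    cell_id: str  # "<plate_id>:<well_id>"
    umi: str
    sequence: str
    qualities: str


@dataclass
class DemuxReport:
    total: int = 0
    assigned: int = 0
    unassigned: int = 0
    short_read2: int = 0
    negative_control: int = 0
    #: subset of `unassigned` rejected on Read2 base quality
    low_quality: int = 0

    def check_partition(self) -> bool:
        return (
            self.assigned + self.unassigned + self.short_read2 + self.negative_control
            == self.total
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for k in ("total", "assigned", "unassigned", "short_read2",
                      "negative_control", "low_quality"):
                fh.write(f"{k}\t{getattr(self, k)}\n")


def parse_read2(
    read2: str,
    barcode_length: int = DEFAULT_BARCODE_LEN,
    umi_length: int = DEFAULT_UMI_LEN,
) -> tuple[str, str, str]:
    """Split Read2 into (barcode, umi, observed spacer) by position."""
    if len(read2) < barcode_length + umi_length:
        raise Read2TooShort(f"read2 of length {len(read2)} too short")
    return (
        read2[:barcode_length],
        read2[barcode_length : barcode_length + umi_length],
        read2[barcode_length + umi_length :],
    )


class BarcodeCorrector:
    """Exact + unique Hamming-1 barcode correction against a whitelist."""

    def __init__(self, whitelist: BarcodeWhitelist):
        self.exact: dict[str, str] = {b: w for w, b in whitelist.entries}
        if len(self.exact) != len(whitelist):
            raise DemuxError("whitelist contains duplicate barcodes")
        self.neighbors: dict[str, str | None] = {}
        for well, bc in whitelist.entries:
            for i in range(len(bc)):
                for sub in "ACGTN":
                    if sub == bc[i]:
                        continue
                    mut = bc[:i] + sub + bc[i + 1 :]
                    if mut in self.exact:
                        continue
                    if mut in self.neighbors and self.neighbors[mut] != well:
                        self.neighbors[mut] = None  # ambiguous
                    else:
                        self.neighbors[mut] = well

    def correct(self, barcode: str) -> str | None:
        well = self.exact.get(barcode)
        if well is not None:
            return well
        return self.neighbors.get(barcode)


def correct_barcode(barcode: str, whitelist: BarcodeWhitelist) -> str | None:
    """Exact match, else the unique well at Hamming distance 1, else None."""
    return BarcodeCorrector(whitelist).correct(barcode)


def _mean_phred(qual: str) -> float:
    if not qual:
        return 0.0
    return sum(ord(q) - 33 for q in qual) / len(qual)


def _fastq_reader(source) -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, sequence, qualities) from a path or an iterable."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            while True:
                head = fh.readline()
                if not head:
                    return
                seq = fh.readline().strip()
                fh.readline()
                qual = fh.readline().strip()
                yield head.strip()[1:].split()[0], seq, qual
    else:
        for rec in source:
            if hasattr(rec, "read_id"):
                yield rec.read_id, rec.sequence, rec.qualities
            else:
                yield rec


def demultiplex(
    read1_source,
    read2_source,
    layout: PlateLayout,
    barcode_length: int = DEFAULT_BARCODE_LEN,
    umi_length: int = DEFAULT_UMI_LEN,
    min_mean_phred: float = DEFAULT_MIN_MEAN_PHRED,
    strict_spacer: bool = False,
    expected_spacer: str = "TATA",
) -> tuple[dict[str, list[TaggedRead]], DemuxReport]:
    """Demultiplex a synchronized FASTQ pair into per-cell tagged Read1 sets.

    Sources may be file paths (plain or gzipped FASTQ) or iterables of
    FastqRecord / (id, seq, qual) tuples. Raises on record-id mismatch
    between the two mates. With ``strict_spacer`` the observed spacer prefix
    must match the expected spacer ("TAT" within a 16-cycle read).
    """
    corrector = BarcodeCorrector(layout.whitelist)
    report = DemuxReport()
    cells: dict[str, list[TaggedRead]] = {}
    spacer_seen = len(expected_spacer)

    r2_iter = _fastq_reader(read2_source)
    for rid1, seq1, qual1 in _fastq_reader(read1_source):
        try:
            rid2, seq2, qual2 = next(r2_iter)
        except StopIteration:
            raise DemuxError("read2 file exhausted before read1") from None
        if rid1 != rid2:
            raise DemuxError(f"desynchronized FASTQ pair: {rid1!r} vs {rid2!r}")
        report.total += 1
        try:
            barcode, umi, spacer = parse_read2(seq2, barcode_length, umi_length)
        except Read2TooShort:
            report.short_read2 += 1
            continue
        if _mean_phred(qual2[: barcode_length + umi_length]) < min_mean_phred:
            report.unassigned += 1
            report.low_quality += 1
            continue
        if strict_spacer:
            expect = expected_spacer[: len(spacer)]
            if spacer[: len(expect)] != expect:
                report.unassigned += 1
                continue
        well = corrector.correct(barcode)
        if well is None:
            report.unassigned += 1
            continue
        if well in layout.negative_control_wells:
            report.negative_control += 1
            continue
        report.assigned += 1
        cell_id = f"{layout.plate_id}:{well}"
        cells.setdefault(cell_id, []).append(TaggedRead(cell_id, umi, seq1, qual1))
    try:
        next(r2_iter)
    except StopIteration:
        pass
    else:
        raise DemuxError("read1 file exhausted before read2")
    return cells, report


def write_tagged_fastq(path: str | Path, reads: Iterable[TaggedRead]) -> None:
    """Write one cell's tagged reads; tags live in the header comment."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, r in enumerate(reads):
            fh.write(
                f"@{r.cell_id.replace(':', '.')}.{i:08d} CB:{r.cell_id} UB:{r.umi}\n"
                f"{r.sequence}\n+\n{r.qualities}\n"
            )


def read_tagged_fastq(path: str | Path) -> list[TaggedRead]:
    out: list[TaggedRead] = []
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            head = fh.readline()
            if not head:
                break
            seq = fh.readline().strip()
            fh.readline()
            qual = fh.readline().strip()
            tags = dict(
                f.split(":", 1) for f in head.strip().split()[1:] if ":" in f
            )
            out.append(TaggedRead(tags["CB"], tags["UB"], seq, qual))
    return out
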