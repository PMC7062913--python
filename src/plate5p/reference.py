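"""Domain types, reference loading and bundled fixtures.

Plate-based 5'-end scRNA-seq quantifies transcripts against a transcript-set
reference (one or more transcripts per gene), a table of 92 synthetic
polyadenylated spike-in RNAs of known concentration, a 96-entry well-barcode
whitelist, and — for antigen-receptor reconstruction — a germline database of
V/D/J/C segments with CDR3 anchor annotations.

All coordinates are 0-based half-open; sequences are stored 5'->3' sense.

The bundled fixtures are synthetic and generated deterministically from a
fixed seed: real spike-in concentrations and germline repertoires are vendor
/ curated data, but every computation downstream is agnostic to the actual
sequences, so a seeded toy set keeps the package self-contained.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

AVOGADRO = 6.02214076e23
#: average molar mass of one ssRNA nucleotide, g/mol
RNA_NT_MW = 340.0
DALTON_G = 1.0 / AVOGADRO

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: seed fixing every bundled fixture
_FIXTURE_SEED = 20_200_303

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {}


def _build_codon_table() -> None:
    from Bio.Seq import Seq

    for a in "ACGT":
        for b in "ACGT":
            for c in "ACGT":
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate())


_build_codon_table()


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string codon-wise; trailing partial codon ignored."""
    return "".join(
        _CODON_TABLE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3)
    )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ReferenceError(f"empty sequence for {self.transcript_id}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ReferenceError(
                f"transcript {self.transcript_id}: invalid characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SpikeInSpecies:
    species_id: str
    sequence: str
    #: attomoles per microliter in the stock mix
    stock_concentration: float

    def __post_init__(self) -> None:
        if self.stock_concentration < 0:
            raise ReferenceError(
                f"spike-in {self.species_id}: negative concentration"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


def expected_molecules(
    stock_concentration: float, dilution_factor: float, well_volume: float
) -> float:
    """Expected molecule count delivered to one well.

    Parameters are the stock concentration (attomol/ul), the dilution factor
    applied to the stock (dimensionless, >= 1) and the well volume (ul).
    """
    if stock_concentration < 0 or well_volume < 0:
        raise ValueError("concentration and volume must be non-negative")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    return stock_concentration * 1e-18 * AVOGADRO * well_volume / dilution_factor


@dataclass(frozen=True)
class BarcodeWhitelist:
    """Ordered well -> 8-base barcode table for one plate design."""

    entries: tuple[tuple[str, str], ...]

    @property
    def wells(self) -> tuple[str, ...]:
        return tuple(w for w, _ in self.entries)

    @property
    def barcodes(self) -> tuple[str, ...]:
        return tuple(b for _, b in self.entries)

    def barcode_of(self, well: str) -> str:
        return dict(self.entries)[well]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class WhitelistReport:
    n_entries: int
    min_pairwise_hamming: int | None
    duplicates: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return (
            self.n_entries == 96
            and not self.duplicates
            and self.min_pairwise_hamming is not None
            and self.min_pairwise_hamming >= 3
        )


def validate_whitelist(whitelist: BarcodeWhitelist) -> WhitelistReport:
    """Report count, duplicates and minimum pairwise Hamming distance.

    Passes iff 96 entries, no duplicate barcodes, and min distance >= 3
    (the margin that makes single-mismatch correction unambiguous).
    """
    barcodes = whitelist.barcodes
    seen: dict[str, int] = {}
    dups = []
    for b in barcodes:
        seen[b] = seen.get(b, 0) + 1
    dups = tuple(b for b, n in seen.items() if n > 1)
    min_d = None
    for i in range(len(barcodes)):
        for j in range(i + 1, len(barcodes)):
            d = hamming(barcodes[i], barcodes[j])
            if min_d is None or d < min_d:
                min_d = d
    return WhitelistReport(len(barcodes), min_d, dups)


ROWS = "ABCDEFGH"
COLUMNS = tuple(range(1, 13))
ALL_WELLS = tuple(f"{r}{c}" for r in ROWS for c in COLUMNS)
DEFAULT_NEGATIVE_CONTROLS = frozenset({"H1", "H12"})


@dataclass(frozen=True)
class PlateLayout:
    """One 96-well plate: whitelist plus the empty negative-control wells."""

    plate_id: str
    whitelist: BarcodeWhitelist
    negative_control_wells: frozenset[str] = DEFAULT_NEGATIVE_CONTROLS

    def __post_init__(self) -> None:
        unknown = self.negative_control_wells - set(self.whitelist.wells)
        if unknown:
            raise ReferenceError(
                f"negative-control wells not on plate: {sorted(unknown)}"
            )

    @property
    def cell_wells(self) -> tuple[str, ...]:
        return tuple(
            w for w in self.whitelist.wells if w not in self.negative_control_wells
        )


SUPPORTED_LOCI = ("IGH", "IGK", "IGL", "TRA", "TRB")
#: loci whose rearrangement includes a D segment
D_LOCI = frozenset({"IGH", "TRB"})
SEGMENT_CLASSES = ("V", "D", "J", "C")


@dataclass(frozen=True)
class GermlineSegment:
    segment_id: str
    segment_class: str
    locus: str
    sequence: str
    #: 0-based start of the conserved anchor codon (Cys for V, Trp/Phe for J)
    cdr3_anchor: int | None = None
    reading_frame_offset: int = 0
    isotype: str | None = None

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise ReferenceError(f"bad segment class {self.segment_class!r}")
        if self.locus not in SUPPORTED_LOCI:
            raise ReferenceError(f"unsupported locus {self.locus!r}")
        if self.segment_class in ("V", "J"):
            a = self.cdr3_anchor
            if a is None or not (0 <= a <= len(self.sequence) - 3):
                raise ReferenceError(
                    f"{self.segment_id}: V/J segments need an in-sequence cdr3_anchor"
                )
            aa = translate(self.sequence[a : a + 3])
            expected = "C" if self.segment_class == "V" else "WF"
            if aa not in expected:
                raise ReferenceError(
                    f"{self.segment_id}: anchor codon translates to {aa!r},"
                    f" expected one of {expected!r}"
                )

    @property
    def gene(self) -> str:
        """Gene-level name (allele suffix ``*NN`` stripped)."""
        return strip_allele(self.segment_id)


def strip_allele(segment_id: str) -> str:
    return re.sub(r"\*\d+$", "", segment_id)


@dataclass
class GermlineDatabase:
    segments: tuple[GermlineSegment, ...]
    _index: dict[tuple[str, str], list[GermlineSegment]] = field(
        init=False, repr=False
    )

    def __post_init__(self) -> None:
        self._index = {}
        seen = set()
        for s in self.segments:
            if s.segment_id in seen:
                raise ReferenceError(f"duplicate segment id {s.segment_id}")
            seen.add(s.segment_id)
            self._index.setdefault((s.locus, s.segment_class), []).append(s)

    def get(self, locus: str, segment_class: str) -> list[GermlineSegment]:
        return list(self._index.get((locus, segment_class), []))

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(sorted({s.locus for s in self.segments}))

    def validate(self) -> None:
        """Check per-locus completeness (>=2 V, >=2 J, >=1 C; D for IGH/TRB)."""
        for locus in self.loci:
            if len(self.get(locus, "V")) < 2 or len(self.get(locus, "J")) < 2:
                raise ReferenceError(f"{locus}: needs >=2 V and >=2 J segments")
            cs = self.get(locus, "C")
            if not cs:
                raise ReferenceError(f"{locus}: needs >=1 C segment")
            if any(c.isotype is None for c in cs):
                raise ReferenceError(f"{locus}: C segments must carry an isotype")
            if locus == "IGH" and not self.get(locus, "D"):
                raise ReferenceError("IGH: needs >=1 D segment")


# ---------------------------------------------------------------------------
# FASTA / TSV I/O
# ---------------------------------------------------------------------------

_GERMLINE_KEYS = {"class", "locus"}


def _parse_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse FASTA into (id, description, sequence); errors name the line."""
    path = Path(path)
    records: list[tuple[str, str, str]] = []
    header: str | None = None
    desc = ""
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, desc, "".join(chunks)))
                fields = line[1:].split(None, 1)
                if not fields:
                    raise ReferenceError(f"{path}:{lineno}: empty FASTA header")
                header = fields[0]
                desc = fields[1] if len(fields) > 1 else ""
                chunks = []
            else:
                if header is None:
                    raise ReferenceError(
                        f"{path}:{lineno}: sequence data before first '>' header"
                    )
                chunks.append(line.upper())
    if header is not None:
        records.append((header, desc, "".join(chunks)))
    return records


def load_fasta_reference(path: str | Path, kind: str):
    """Load a FASTA reference of the given kind.

    kind="transcriptome" -> list[TranscriptRecord]; gene id taken from a
    ``gene=...`` key in the description, else the transcript id itself.
    kind="spikein" -> list[SpikeInSpecies] with concentration from a
    ``conc=...`` key (attomol/ul, default 0).
    kind="germline" -> GermlineDatabase; headers must carry the key=value
    dialect ``class=V locus=IGH anchor=270 frame=0 [isotype=IGHM]``.
    """
    if kind not in ("transcriptome", "spikein", "germline"):
        raise ValueError(f"unknown reference kind {kind!r}")
    records = _parse_fasta(path)
    ids = [r[0] for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ReferenceError(f"{path}: duplicate record ids {sorted(dup)}")

    def kv(desc: str) -> dict[str, str]:
        return dict(f.split("=", 1) for f in desc.split() if "=" in f)

    if kind == "transcriptome":
        return [
            TranscriptRecord(rid, kv(desc).get("gene", rid), seq)
            for rid, desc, seq in records
        ]
    if kind == "spikein":
        return [
            SpikeInSpecies(rid, seq, float(kv(desc).get("conc", 0.0)))
            for rid, desc, seq in records
        ]
    segments = []
    for rid, desc, seq in records:
        meta = kv(desc)
        missing = _GERMLINE_KEYS - set(meta)
        if missing:
            raise ReferenceError(
                f"{path}: germline header {rid!r} missing keys {sorted(missing)}"
            )
        segments.append(
            GermlineSegment(
                segment_id=rid,
                segment_class=meta["class"],
                locus=meta["locus"],
                sequence=seq,
                cdr3_anchor=int(meta["anchor"]) if "anchor" in meta else None,
                reading_frame_offset=int(meta.get("frame", 0)),
                isotype=meta.get("isotype"),
            )
        )
    db = GermlineDatabase(tuple(segments))
    db.validate()
    return db


def write_fasta(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, description, sequence) triples as FASTA, 80-column wrapped."""
    with open(path, "w") as fh:
        for rid, desc, seq in records:
            head = f">{rid} {desc}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def transcriptome_to_fasta(path: str | Path, transcripts: Sequence[TranscriptRecord]):
    write_fasta(path, [(t.transcript_id, f"gene={t.gene_id}", t.sequence) for t in transcripts])


def spikeins_to_fasta(path: str | Path, species: Sequence[SpikeInSpecies]) -> None:
    write_fasta(
        path,
        [(s.species_id, f"conc={s.stock_concentration:.8g}", s.sequence) for s in species],
    )


def germline_to_fasta(path: str | Path, db: GermlineDatabase) -> None:
    rows = []
    for s in db.segments:
        desc = f"class={s.segment_class} locus={s.locus}"
        if s.cdr3_anchor is not None:
            desc += f" anchor={s.cdr3_anchor}"
        desc += f" frame={s.reading_frame_offset}"
        if s.isotype:
            desc += f" isotype={s.isotype}"
        rows.append((s.segment_id, desc, s.sequence))
    write_fasta(path, rows)


def load_whitelist_tsv(path: str | Path) -> BarcodeWhitelist:
    entries = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReferenceError(f"{path}:{lineno}: expected 2 columns")
            entries.append((parts[0], parts[1]))
    return BarcodeWhitelist(tuple(entries))


def whitelist_to_tsv(path: str | Path, whitelist: BarcodeWhitelist) -> None:
    with open(path, "w") as fh:
        for well, bc in whitelist.entries:
            fh.write(f"{well}\t{bc}\n")


def load_spikein_table_tsv(path: str | Path) -> dict[str, float]:
    """species_id -> stock concentration (attomol/ul)."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ReferenceError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = float(parts[1])
    return out


# ---------------------------------------------------------------------------
# bundled fixtures (deterministic, synthetic)
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons avoiding stop codons."""
    out = []
    while len(out) < n:
        codon = _random_seq(rng, 3)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


def bundled_whitelist() -> BarcodeWhitelist:
    """96 synthetic 8-base barcodes with min pairwise Hamming distance >= 3.

    Real plate designs select barcodes empirically (avoiding TSO concatemer
    artifacts); the fixture instead guarantees the geometric property the
    demultiplexer relies on for unambiguous 1-mismatch correction.
    """
    rng = np.random.default_rng(_FIXTURE_SEED)
    chosen: list[str] = []
    while len(chosen) < 96:
        cand = _random_seq(rng, 8)
        if all(hamming(cand, b) >= 3 for b in chosen):
            chosen.append(cand)
    return BarcodeWhitelist(tuple(zip(ALL_WELLS, chosen)))


#: default per-well spike mass targeted by the bundled mix (picograms)
SPIKE_MASS_PG = 0.025
DEFAULT_DILUTION_FACTOR = 2_000_000.0
DEFAULT_WELL_VOLUME_UL = 2.0


def bundled_spikeins(n_species: int = 92) -> list[SpikeInSpecies]:
    """Synthetic 92-species spike-in mix.

    Lengths 250-2000 nt with a 30-nt poly(A) tail; stock concentrations
    log-uniform over 5 orders of magnitude, rescaled so that at the default
    dilution (1:2,000,000 into a 2-ul well) the mix delivers ~0.025 pg RNA
    per well.
    """
    rng = np.random.default_rng(_FIXTURE_SEED + 1)
    lengths = rng.integers(250, 2001, size=n_species)
    raw_conc = 10.0 ** rng.uniform(-2.0, 3.0, size=n_species)
    # per-well mass at unit scale, in grams
    molecules = raw_conc * 1e-18 * AVOGADRO * DEFAULT_WELL_VOLUME_UL / DEFAULT_DILUTION_FACTOR
    mass_g = float(np.sum(molecules * lengths * RNA_NT_MW * DALTON_G))
    scale = (SPIKE_MASS_PG * 1e-12) / mass_g
    species = []
    for i in range(n_species):
        body = _random_seq(rng, int(lengths[i]) - 30)
        species.append(
            SpikeInSpecies(
                species_id=f"SPIKE-{i + 1:05d}",
                sequence=body + "A" * 30,
                stock_concentration=float(raw_conc[i] * scale),
            )
        )
    return species


def bundled_transcriptome(n_genes: int = 30) -> list[TranscriptRecord]:
    """Toy transcript set: one transcript per gene, lengths 900-2400 nt
    (typical mRNA scale, comfortably longer than the 100-850 bp inserts)."""
    rng = np.random.default_rng(_FIXTURE_SEED + 2)
    lengths = rng.integers(900, 2401, size=n_genes)
    return [
        TranscriptRecord(
            transcript_id=f"TX{i + 1:04d}",
            gene_id=f"GENE{i + 1:04d}",
            sequence=_random_seq(rng, int(lengths[i])),
        )
        for i in range(n_genes)
    ]


def _make_v(rng, segment_id, locus) -> GermlineSegment:
    # 90 framework codons, conserved Cys anchor codon, 2 codons of CDR3 overhang
    seq = _random_codons(rng, 90) + "TGT" + _random_codons(rng, 2)
    return GermlineSegment(segment_id, "V", locus, seq, cdr3_anchor=270)


def _make_j(rng, segment_id, locus) -> GermlineSegment:
    anchor = "TGG" if locus in ("IGH", "TRB") else "TTC"
    seq = _random_codons(rng, 3) + anchor + _random_codons(rng, 10)
    return GermlineSegment(segment_id, "J", locus, seq, cdr3_anchor=9)


def _make_c(rng, segment_id, locus) -> GermlineSegment:
    return GermlineSegment(
        segment_id, "C", locus, _random_codons(rng, 90), isotype=segment_id
    )


def _make_d(rng, segment_id, locus) -> GermlineSegment:
    return GermlineSegment(segment_id, "D", locus, _random_seq(rng, int(rng.integers(16, 23))))


def _mutate_allele(rng, seg: GermlineSegment, new_id: str, n_subs: int = 2) -> GermlineSegment:
    """Derive a near-identical allele, avoiding anchor and stop creation."""
    seq = list(seg.sequence)
    forbidden = set()
    if seg.cdr3_anchor is not None:
        forbidden = set(range(seg.cdr3_anchor, seg.cdr3_anchor + 3))
    done = 0
    while done < n_subs:
        pos = int(rng.integers(0, len(seq)))
        if pos in forbidden:
            continue
        old = seq[pos]
        new = rng.choice([b for b in "ACGT" if b != old])
        codon_start = pos - (pos % 3)
        trial = seq.copy()
        trial[pos] = new
        if "".join(trial[codon_start : codon_start + 3]) in STOP_CODONS:
            continue
        seq = trial
        done += 1
    return GermlineSegment(
        new_id, seg.segment_class, seg.locus, "".join(seq),
        cdr3_anchor=seg.cdr3_anchor,
        reading_frame_offset=seg.reading_frame_offset,
        isotype=seg.isotype,
    )


def bundled_germline() -> GermlineDatabase:
    """Toy germline database for IGH/IGK/IGL/TRA/TRB.

    V segments are 93 codons ending 9 nt after the conserved Cys codon
    (anchor=270); J segments carry 9 nt of junction-side sequence before the
    conserved Trp/Phe codon (anchor=9) and 30 nt after it; C segments are 90
    stop-free codons labelled with their isotype. One V and one J gene per
    receptor family carry a second near-identical allele so gene-level
    (allele-stripped) logic is exercised.
    """
    rng = np.random.default_rng(_FIXTURE_SEED + 3)
    segs: list[GermlineSegment] = []

    plan = {
        "IGH": (["IGHV1-1*01", "IGHV2-5*01", "IGHV3-23*01"],
                ["IGHD3-10*01", "IGHD2-2*01"],
                ["IGHJ4*01", "IGHJ6*01"],
                ["IGHM", "IGHD", "IGHG1", "IGHA1"]),
        "IGK": (["IGKV1-5*01", "IGKV3-20*01", "IGKV4-1*01"], [],
                ["IGKJ1*01", "IGKJ2*01"], ["IGKC"]),
        "IGL": (["IGLV1-40*01", "IGLV2-14*01"], [],
                ["IGLJ2*01", "IGLJ3*01"], ["IGLC2"]),
        "TRA": (["TRAV1-2*01", "TRAV12-1*01"], [],
                ["TRAJ33*01", "TRAJ12*01"], ["TRAC"]),
        "TRB": (["TRBV5-1*01", "TRBV20-1*01"], ["TRBD1*01"],
                ["TRBJ2-1*01", "TRBJ1-5*01"], ["TRBC1"]),
    }
    for locus, (vs, ds, js, cs) in plan.items():
        for vid in vs:
            segs.append(_make_v(rng, vid, locus))
        for did in ds:
            segs.append(_make_d(rng, did, locus))
        for jid in js:
            segs.append(_make_j(rng, jid, locus))
        for cid in cs:
            segs.append(_make_c(rng, cid, locus))
    by_id = {s.segment_id: s for s in segs}
    segs.append(_mutate_allele(rng, by_id["IGHV3-23*01"], "IGHV3-23*02"))
    segs.append(_mutate_allele(rng, by_id["IGHJ4*01"], "IGHJ4*02"))
    db = GermlineDatabase(tuple(segs))
    db.validate()
    return db


def bundled_layout(plate_id: str = "P1") -> PlateLayout:
    return PlateLayout(plate_id, bundled_whitelist())
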