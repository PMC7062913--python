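"""Ground-truthed read simulator for plate-based 5'-end scRNA-seq.

Read anatomy being emulated (one molecule -> one or more read pairs):

* Read1 (default 67 nt) covers the 5' end of the cDNA insert *from its 3'
  end*, i.e. it is the reverse complement of the 3'-terminal bases of a
  fragment that always starts at the transcript's 5' terminus. Insert sizes
  are uniform over 100-850 bp (clipped to transcript length), which biases
  coverage toward the 5' half of gene bodies.
* Read2 (default 16 nt) reads the template-switch oligo: an 8-bp
  well-specific barcode, a 5-bp UMI, then a TATA spacer of which only the
  first bases fit within the read length.

Each molecule receives a UMI drawn uniformly from the 4^5 = 1,024 space
(collisions are possible and intentional: the counting oracle is
collision-aware), is emitted with a shifted-Poisson number of PCR copies,
and every emitted copy receives independent per-base substitution errors.
Spike-in molecules are drawn Poisson(expected molecules per well) in every
cell-containing well; negative-control wells (H1/H12 by default) emit
nothing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import (
    D_LOCI,
    GermlineDatabase,
    GermlineSegment,
    PlateLayout,
    SpikeInSpecies,
    STOP_CODONS,
    TranscriptRecord,
    expected_molecules,
    revcomp,
    translate,
)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_plates: int = 1
    cells_per_plate: int = 94
    genes: int | None = None  # None = use full reference
    mean_molecules_per_cell: int = 2000
    expression_dispersion: float = 1.0
    spikein_dilution_factor: float = 2_000_000.0
    well_volume_ul: float = 2.0
    #: optional cap on emitted read pairs per cell (None = emit all copies)
    reads_per_cell_target: int | None = None
    pcr_duplication_mean: float = 20.0
    seq_error_rate: float = 1e-3
    insert_size_min: int = 100
    insert_size_max: int = 850
    read1_length: int = 67
    read2_length: int = 16
    umi_length: int = 5
    barcode_length: int = 8
    spacer: str = "TATA"
    receptor_mode: str = "none"  # none | BCR | TCR
    shm_rate: float = 0.01
    receptor_molecules_heavy: int = 50
    receptor_molecules_light: int = 100

    def __post_init__(self) -> None:
        if self.read2_length < self.barcode_length + self.umi_length:
            raise SimulationError("read2 too short for barcode + UMI")
        if self.insert_size_min > self.insert_size_max:
            raise SimulationError("insert size range inverted")
        if not (0 <= self.seq_error_rate <= 1 and 0 <= self.shm_rate <= 1):
            raise SimulationError("probabilities must lie in [0, 1]")
        if self.pcr_duplication_mean < 1:
            raise SimulationError("pcr_duplication_mean must be >= 1")
        if self.cells_per_plate > 94:
            raise SimulationError("at most 94 cells per plate (2 control wells)")
        if self.receptor_mode not in ("none", "BCR", "TCR"):
            raise SimulationError(f"unknown receptor_mode {self.receptor_mode!r}")


@dataclass
class RearrangementTruth:
    cell_id: str
    locus: str
    v_id: str
    d_id: str | None
    j_id: str
    c_id: str
    junction_nt: str  # CDR3, anchor-codon inclusive, after SHM
    contig_nt: str
    shm_positions: tuple[int, ...]
    productive: bool
    isotype: str


@dataclass
class GroundTruth:
    """Truth channel: the molecule table plus per-cell receptor records."""

    molecules: pd.DataFrame  # plate_id, well_id, cell_id, gene_id, umi, copies_emitted
    receptors: list[RearrangementTruth]
    cell_wells: dict[str, tuple[str, str]]  # cell_id -> (plate_id, well_id)

    def umi_counts(self) -> pd.DataFrame:
        """Collision-aware truth counts: distinct (gene, UMI) per cell.

        Only molecules with at least one emitted copy are countable.
        """
        m = self.molecules[self.molecules["copies_emitted"] > 0]
        return (
            m.drop_duplicates(["cell_id", "gene_id", "umi"])
            .groupby(["cell_id", "gene_id"])
            .size()
            .rename("molecules")
            .reset_index()
        )


@dataclass
class FastqRecord:
    read_id: str
    sequence: str
    qualities: str


@dataclass
class SimulatedPlate:
    plate_id: str
    read1: list[FastqRecord]
    read2: list[FastqRecord]
    truth: GroundTruth

    def write(self, outdir: str | Path, gzipped: bool = True) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        suffix = ".fastq.gz" if gzipped else ".fastq"
        p1 = outdir / f"{self.plate_id}_R1{suffix}"
        p2 = outdir / f"{self.plate_id}_R2{suffix}"
        write_fastq(p1, self.read1)
        write_fastq(p2, self.read2)
        self.truth.molecules.to_csv(
            outdir / f"{self.plate_id}_truth_molecules.tsv", sep="\t", index=False
        )
        pd.DataFrame([vars(r) for r in self.truth.receptors]).to_csv(
            outdir / f"{self.plate_id}_truth_receptors.tsv", sep="\t", index=False
        )
        return p1, p2


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in records:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.qualities}\n")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in (b"A", b"C", b"G", b"T") if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# V(D)J rearrangement simulation
# ---------------------------------------------------------------------------


def simulate_rearrangement(
    db: GermlineDatabase,
    locus: str,
    rng: np.random.Generator,
    shm_rate: float = 0.0,
    productive: bool = True,
    cell_id: str = "",
    max_tries: int = 200,
) -> tuple[str, RearrangementTruth]:
    """Simulate one rearranged receptor transcript for a locus.

    Contig = V (3' exonuclease trim 0-5 nt) + N additions (0-8 nt)
    [+ trimmed D + N additions for IGH/TRB] + J (5' trim 0-5 nt) + full C.
    For productive chains the junction is padded so the J anchor shares the
    V reading frame, and any draw creating a stop codon (including via SHM)
    is redrawn. SHM substitutions land uniformly over the V(D)J region only.
    """
    vs = db.get(locus, "V")
    js = db.get(locus, "J")
    cs = db.get(locus, "C")
    if not (vs and js and cs):
        raise SimulationError(f"locus {locus!r} absent or incomplete in germline db")
    ds = db.get(locus, "D") if locus in D_LOCI else []

    v = vs[int(rng.integers(len(vs)))]
    j = js[int(rng.integers(len(js)))]
    c = cs[int(rng.integers(len(cs)))]
    d = ds[int(rng.integers(len(ds)))] if ds else None

    for _ in range(max_tries):
        t_v = int(rng.integers(0, 6))
        v_part = v.sequence[: len(v.sequence) - t_v]
        n1 = _random_dna(rng, int(rng.integers(0, 9)))
        d_part = ""
        n2 = ""
        if d is not None:
            # keep >= 8 nt of D so the annotator's ungapped D rule can fire
            budget = len(d.sequence) - 8
            t5 = int(rng.integers(0, min(5, budget) + 1))
            t3 = int(rng.integers(0, min(5, budget - t5) + 1))
            d_part = d.sequence[t5 : len(d.sequence) - t3]
            n2 = _random_dna(rng, int(rng.integers(0, 9)))
        t_j = int(rng.integers(0, 6))
        j_part = j.sequence[t_j:]

        pos_v_anchor = v.cdr3_anchor  # V prefix is never trimmed
        pos_j_anchor = (
            len(v_part) + len(n1) + len(d_part) + len(n2) + (j.cdr3_anchor - t_j)
        )
        delta = (pos_j_anchor - pos_v_anchor) % 3
        if productive and delta:
            pad = _random_dna(rng, 3 - delta)
            n1 += pad
            pos_j_anchor += 3 - delta
        elif not productive and delta == 0:
            n1 += _random_dna(rng, 1)
            pos_j_anchor += 1

        contig = v_part + n1 + d_part + n2 + j_part + c.sequence
        c_start = len(contig) - len(c.sequence)

        # SHM over the V(D)J region only
        shm_positions: list[int] = []
        if shm_rate > 0:
            arr = list(contig)
            hits = np.nonzero(rng.random(c_start) < shm_rate)[0]
            for i in hits:
                arr[i] = str(rng.choice([b for b in "ACGT" if b != arr[i]]))
                shm_positions.append(int(i))
            contig = "".join(arr)

        if productive:
            orf = contig[: len(contig) - (len(contig) % 3)]
            if "*" in translate(orf):
                continue
        junction = contig[pos_v_anchor : pos_j_anchor + 3]
        truth = RearrangementTruth(
            cell_id=cell_id,
            locus=locus,
            v_id=v.segment_id,
            d_id=d.segment_id if d is not None else None,
            j_id=j.segment_id,
            c_id=c.segment_id,
            junction_nt=junction,
            contig_nt=contig,
            shm_positions=tuple(shm_positions),
            productive=productive,
            isotype=c.isotype or c.segment_id,
        )
        return contig, truth
    raise SimulationError(
        f"could not draw a stop-free rearrangement for {locus} in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# plate simulation
# ---------------------------------------------------------------------------


_LIGHT_CHOICES = {"BCR": ("IGK", "IGL"), "TCR": ("TRA",)}
_HEAVY_LOCUS = {"BCR": "IGH", "TCR": "TRB"}


def simulate_plate(
    config: SimulationConfig,
    transcripts: Sequence[TranscriptRecord],
    spikeins: Sequence[SpikeInSpecies],
    layout: PlateLayout,
    germline: GermlineDatabase | None = None,
    rng: np.random.Generator | None = None,
) -> SimulatedPlate:
    """Simulate one plate; deterministic given config.seed (or a passed rng)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.receptor_mode != "none" and germline is None:
        raise SimulationError("receptor simulation requires a germline database")

    txs = list(transcripts)
    if config.genes is not None:
        txs = txs[: config.genes]
    if not txs:
        raise SimulationError("empty transcript reference")

    expected = {
        s.species_id: expected_molecules(
            s.stock_concentration, config.spikein_dilution_factor, config.well_volume_ul
        )
        for s in spikeins
    }
    spike_seq = {s.species_id: s.sequence for s in spikeins}

    cell_wells = layout.cell_wells[: config.cells_per_plate]
    mol_rows: list[tuple] = []
    receptors: list[RearrangementTruth] = []
    cell_map: dict[str, tuple[str, str]] = {}
    read1: list[FastqRecord] = []
    read2: list[FastqRecord] = []
    counter = 0

    gene_ids = [t.gene_id for t in txs]
    tx_seqs = [t.sequence for t in txs]

    for well in cell_wells:
        cell_id = f"{layout.plate_id}:{well}"
        cell_map[cell_id] = (layout.plate_id, well)
        barcode = layout.whitelist.barcode_of(well)

        # endogenous molecules: log-normal per-gene abundance, Poisson counts
        abund = rng.lognormal(0.0, config.expression_dispersion, size=len(txs))
        lam = config.mean_molecules_per_cell * abund / abund.sum()
        n_mols = rng.poisson(lam)

        molecules: list[tuple[str, str]] = []  # (gene_id, sequence)
        for g in range(len(txs)):
            molecules.extend([(gene_ids[g], tx_seqs[g])] * int(n_mols[g]))

        # spike-ins: identical expectation in every cell-containing well
        for sid, exp in expected.items():
            k = int(rng.poisson(exp))
            molecules.extend([(sid, spike_seq[sid])] * k)

        # receptor transcripts
        if config.receptor_mode != "none":
            heavy = _HEAVY_LOCUS[config.receptor_mode]
            lights = _LIGHT_CHOICES[config.receptor_mode]
            light = lights[int(rng.integers(len(lights)))]
            for locus, n_rec in (
                (heavy, config.receptor_molecules_heavy),
                (light, config.receptor_molecules_light),
            ):
                contig, truth = simulate_rearrangement(
                    germline, locus, rng, shm_rate=config.shm_rate, cell_id=cell_id
                )
                receptors.append(truth)
                molecules.extend([(f"{locus}:{cell_id}", contig)] * n_rec)

        # emit reads per molecule
        cell_reads: list[tuple[str, str, str, str]] = []  # (gene, umi, r1, r2)
        cell_mols: list[list] = []
        for gene_id, seq in molecules:
            umi = _random_dna(rng, config.umi_length)
            copies = 1 + int(rng.poisson(config.pcr_duplication_mean - 1.0))
            row = [layout.plate_id, well, cell_id, gene_id, umi, copies]
            cell_mols.append(row)
            for _ in range(copies):
                f = int(rng.integers(config.insert_size_min, config.insert_size_max + 1))
                f = min(f, len(seq))
                frag = seq[:f]
                r1 = revcomp(frag[max(0, f - config.read1_length) :])
                tso = barcode + umi + config.spacer
                r2 = tso[: config.read2_length].ljust(config.read2_length, "T")
                r1 = _apply_errors(rng, r1, config.seq_error_rate)
                r2 = _apply_errors(rng, r2, config.seq_error_rate)
                cell_reads.append((gene_id, umi, r1, r2))

        if (
            config.reads_per_cell_target is not None
            and len(cell_reads) > config.reads_per_cell_target
        ):
            keep = rng.choice(
                len(cell_reads), size=config.reads_per_cell_target, replace=False
            )
            keep_set = set(int(i) for i in keep)
            # recount emitted copies after downsampling
            kept_reads = [cell_reads[i] for i in sorted(keep_set)]
            emitted: dict[tuple[str, str], int] = {}
            for gene_id, umi, _, _ in kept_reads:
                emitted[(gene_id, umi)] = emitted.get((gene_id, umi), 0) + 1
            # copies per molecule row are approximate once molecules share a
            # (gene, umi) key; distribute the kept copies over those rows
            remaining = dict(emitted)
            for row in cell_mols:
                key = (row[3], row[4])
                take = min(row[5], remaining.get(key, 0))
                row[5] = take
                if key in remaining:
                    remaining[key] -= take
            cell_reads = kept_reads

        mol_rows.extend(tuple(r) for r in cell_mols)
        for gene_id, umi, r1, r2 in cell_reads:
            rid = f"{layout.plate_id}.{counter:09d}"
            counter += 1
            read1.append(FastqRecord(rid, r1, "I" * len(r1)))
            read2.append(FastqRecord(rid, r2, "I" * len(r2)))

    molecules_df = pd.DataFrame(
        mol_rows,
        columns=["plate_id", "well_id", "cell_id", "gene_id", "umi", "copies_emitted"],
    )
    truth = GroundTruth(molecules_df, receptors, cell_map)
    return SimulatedPlate(layout.plate_id, read1, read2, truth)
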