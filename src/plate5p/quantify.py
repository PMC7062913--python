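"""Strand-aware k-mer pseudoalignment, UMI collapsing, and matrix assembly.

Read1 is antisense (it reads the 5' fragment from its 3' end), so every read
is reverse-complemented before k-mer lookup against the sense transcript +
spike-in index. A read votes for each gene one of its k-mers belongs to; it
is assigned to the unique gene with the maximal vote count provided that
count reaches ``min_hits``, ties are ambiguous, and anything below the
threshold is unmapped. This deliberately substitutes splice-aware genome
alignment: the reference here is transcript-level, so gene-assignment
semantics are equivalent at desk scale.

Molecules are counted per (gene, UMI). The default "directional" collapse
merges a UMI b into a neighbour a when Hamming(a, b) == 1 and
count(a) >= 2*count(b) - 1 — the standard adjacency rule for absorbing
satellite UMIs created by sequencing errors on PCR copies. "exact" mode
(distinct pairs) is kept as the collision-aware oracle mode.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demux import TaggedRead
from .reference import SpikeInSpecies, TranscriptRecord, revcomp

DEFAULT_K = 21
DEFAULT_MIN_HITS = 3

UNMAPPED = "unmapped"
AMBIGUOUS = "ambiguous"


class QuantifyError(ValueError):
    pass


@dataclass
class KmerIndex:
    k: int
    genes: tuple[str, ...]
    #: k-mer -> tuple of gene indices (shared k-mers keep multi-gene sets)
    table: dict[str, tuple[int, ...]]

    def lookup(self, kmer: str) -> tuple[int, ...]:
        return self.table.get(kmer, ())


def build_index(
    transcripts: Sequence[TranscriptRecord],
    spikeins: Sequence[SpikeInSpecies] = (),
    k: int = DEFAULT_K,
) -> KmerIndex:
    """Index sense k-mers of transcriptome + spike-ins to gene-id sets."""
    if k % 2 == 0:
        raise QuantifyError("k must be odd")
    sources: list[tuple[str, str, str]] = [
        (t.transcript_id, t.gene_id, t.sequence) for t in transcripts
    ] + [(s.species_id, s.species_id, s.sequence) for s in spikeins]
    for sid, _, seq in sources:
        if len(seq) < k:
            raise QuantifyError(f"k={k} exceeds length of sequence {sid!r}")
    genes: list[str] = []
    gene_idx: dict[str, int] = {}
    tmp: dict[str, set[int]] = defaultdict(set)
    for _, gene, seq in sources:
        gi = gene_idx.setdefault(gene, len(gene_idx))
        if gi == len(genes):
            genes.append(gene)
        for i in range(len(seq) - k + 1):
            tmp[seq[i : i + k]].add(gi)
    table = {kmer: tuple(sorted(gs)) for kmer, gs in tmp.items()}
    return KmerIndex(k=k, genes=tuple(genes), table=table)


def assign_read(
    sequence: str, index: KmerIndex, min_hits: int = DEFAULT_MIN_HITS
) -> str:
    """Assign one antisense read to a gene id, AMBIGUOUS, or UNMAPPED."""
    sense = revcomp(sequence)
    k = index.k
    votes: Counter[int] = Counter()
    for i in range(len(sense) - k + 1):
        for gi in index.lookup(sense[i : i + k]):
            votes[gi] += 1
    if not votes:
        return UNMAPPED
    ranked = votes.most_common()
    best_gene, best = ranked[0]
    if best < min_hits:
        return UNMAPPED
    if len(ranked) > 1 and ranked[1][1] == best:
        return AMBIGUOUS
    return index.genes[best_gene]


def _directional_clusters(counts: Mapping[str, int]) -> int:
    """Number of molecule clusters under the directional adjacency rule."""
    order = sorted(counts, key=lambda u: (-counts[u], u))
    visited: set[str] = set()
    n_clusters = 0
    for seed in order:
        if seed in visited:
            continue
        n_clusters += 1
        stack = [seed]
        visited.add(seed)
        while stack:
            a = stack.pop()
            ca = counts[a]
            for i in range(len(a)):
                for sub in "ACGT":
                    if sub == a[i]:
                        continue
                    b = a[:i] + sub + a[i + 1 :]
                    if b in counts and b not in visited and ca >= 2 * counts[b] - 1:
                        visited.add(b)
                        stack.append(b)
    return n_clusters


@dataclass
class CellCounts:
    cell_id: str
    counts: dict[str, int]
    n_reads: int = 0
    n_unmapped: int = 0
    n_ambiguous: int = 0
    n_bad_umi: int = 0


def count_umis(
    assignments: Iterable[tuple[str, str]],
    collapse_mode: str = "directional",
    umi_length: int = 5,
) -> tuple[dict[str, int], int]:
    """Collapse (gene_id, umi) read assignments into per-gene molecule counts.

    Returns (counts, n_dropped) where n_dropped counts reads whose UMI had
    the wrong length.
    """
    if collapse_mode not in ("exact", "directional"):
        raise QuantifyError(f"unknown collapse mode {collapse_mode!r}")
    per_gene: dict[str, Counter[str]] = defaultdict(Counter)
    dropped = 0
    for gene, umi in assignments:
        if len(umi) != umi_length:
            dropped += 1
            continue
        per_gene[gene][umi] += 1
    counts: dict[str, int] = {}
    for gene, umis in per_gene.items():
        if collapse_mode == "exact":
            counts[gene] = len(umis)
        else:
            counts[gene] = _directional_clusters(umis)
    return counts, dropped


def count_cell(
    cell_id: str,
    reads: Iterable[TaggedRead],
    index: KmerIndex,
    min_hits: int = DEFAULT_MIN_HITS,
    collapse_mode: str = "directional",
    umi_length: int = 5,
) -> CellCounts:
    """Pseudoalign and UMI-collapse all reads of one cell."""
    assignments: list[tuple[str, str]] = []
    n_reads = n_unmapped = n_ambiguous = 0
    for r in reads:
        n_reads += 1
        gene = assign_read(r.sequence, index, min_hits)
        if gene == UNMAPPED:
            n_unmapped += 1
        elif gene == AMBIGUOUS:
            n_ambiguous += 1
        else:
            assignments.append((gene, r.umi))
    counts, dropped = count_umis(assignments, collapse_mode, umi_length)
    return CellCounts(cell_id, counts, n_reads, n_unmapped, n_ambiguous, dropped)


@dataclass
class CountMatrix:
    """Gene-by-cell molecule count matrix with per-cell metadata."""

    matrix: pd.DataFrame  # genes x cells, int
    metadata: pd.DataFrame  # index: cell_id; plate_id, well_id, totals

    @classmethod
    def from_cells(
        cls,
        cells: Sequence[CellCounts],
        gene_universe: Sequence[str],
        plate_of: Mapping[str, tuple[str, str]] | None = None,
    ) -> "CountMatrix":
        genes = list(gene_universe)
        mat = pd.DataFrame(
            0, index=genes, columns=[c.cell_id for c in cells], dtype=np.int64
        )
        for c in cells:
            for gene, n in c.counts.items():
                if gene in mat.index:
                    mat.loc[gene, c.cell_id] = n
        meta = pd.DataFrame(index=mat.columns)
        if plate_of:
            meta["plate_id"] = [plate_of.get(c, ("", ""))[0] for c in meta.index]
            meta["well_id"] = [plate_of.get(c, ("", ""))[1] for c in meta.index]
        else:
            meta["plate_id"] = [c.split(":")[0] for c in meta.index]
            meta["well_id"] = [c.split(":")[-1] for c in meta.index]
        meta["total_umis"] = mat.sum(axis=0).astype(int)
        meta["genes_detected"] = (mat > 0).sum(axis=0).astype(int)
        return cls(mat, meta)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def cells(self) -> list[str]:
        return list(self.matrix.columns)

    def validate(self) -> None:
        if (self.matrix.values < 0).any():
            raise QuantifyError("negative counts")
        if not (self.metadata["total_umis"].values == self.matrix.sum(axis=0).values).all():
            raise QuantifyError("metadata totals disagree with column sums")
        if not (
            self.metadata["genes_detected"].values == (self.matrix > 0).sum(axis=0).values
        ).all():
            raise QuantifyError("metadata genes_detected disagrees with matrix")

    def write_mtx(self, outdir: str | Path) -> None:
        """cellranger-style triplet: matrix.mtx + genes.tsv + cells.tsv."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), csr_matrix(self.matrix.values))
        with open(outdir / "genes.tsv", "w") as fh:
            fh.write("\n".join(self.genes) + "\n")
        with open(outdir / "cells.tsv", "w") as fh:
            fh.write("\n".join(self.cells) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        self.matrix.to_csv(path, sep="\t")


def merge_plates(matrices: Sequence[CountMatrix]) -> CountMatrix:
    """Column-wise merge of per-plate matrices with deterministic ordering."""
    if not matrices:
        raise QuantifyError("nothing to merge")
    gene_sets = [tuple(m.genes) for m in matrices]
    base = set(gene_sets[0])
    for gs in gene_sets[1:]:
        if set(gs) != base:
            diff = sorted(base.symmetric_difference(gs))
            raise QuantifyError(f"gene universe mismatch: {diff}")
    all_cells = [c for m in matrices for c in m.cells]
    if len(set(all_cells)) != len(all_cells):
        dups = sorted({c for c in all_cells if all_cells.count(c) > 1})
        raise QuantifyError(f"duplicate cell ids across plates: {dups}")
    mat = pd.concat([m.matrix.loc[gene_sets[0], :] for m in matrices], axis=1)
    meta = pd.concat([m.metadata for m in matrices], axis=0)

    def well_key(well: str) -> tuple[str, int]:
        return (well[0], int(well[1:]))

    order = sorted(
        mat.columns,
        key=lambda c: (meta.loc[c, "plate_id"], well_key(meta.loc[c, "well_id"])),
    )
    return CountMatrix(mat.loc[:, order], meta.loc[order, :])
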