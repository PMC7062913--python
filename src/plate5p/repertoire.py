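"""Per-cell antigen-receptor reconstruction from 5'-end reads.

The stages mirror how repertoire recovery works when the sequencing reads
span the whole variable region and a large part of the constant region:

1. de novo assembly of each cell's Read1 set (reverse-complemented to sense)
   with a small de Bruijn assembler;
2. V(D)J annotation of every contig by local affine-gap alignment against a
   germline segment database, with CDR3 extracted between the conserved
   Cys (V) and Trp/Phe (J) anchor codons, anchor-inclusive;
3. a constant-region check: contigs whose C segment is absent or out of
   frame with the V(D)J open reading frame are discarded;
4. merging of contigs that represent the same rearrangement (same V, J and
   CDR3), keeping the largest;
5. expression-based chain selection: the cell's own reads are pseudoaligned
   back onto the candidate contigs and the best-supported productive contig
   wins each locus;
6. clonotype assignment on gene-level (allele-stripped) V/J calls, and
   V-region mutation load relative to germline.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .demux import TaggedRead
from .reference import (
    D_LOCI,
    GermlineDatabase,
    GermlineSegment,
    revcomp,
    strip_allele,
    translate,
)

DEFAULT_K_ASSEMBLY = 31
DEFAULT_MIN_KMER_COV = 2
DEFAULT_MIN_CONTIG_LENGTH = 150
DEFAULT_MIN_SCORE = 60
DEFAULT_MIN_C_SCORE = 40
#: C alignment must start within this many nt of the J segment end
C_MAX_GAP = 10
#: minimum ungapped D match length inside the junction
D_MIN_MATCH = 8


class RepertoireError(ValueError):
    pass


# ---------------------------------------------------------------------------
# de novo assembly
# ---------------------------------------------------------------------------


@dataclass
class Contig:
    cell_id: str
    contig_id: str
    sequence: str
    read_support: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)


def _kmer_counts(seqs: Iterable[str], k: int) -> Counter:
    counts: Counter[str] = Counter()
    for s in seqs:
        for i in range(len(s) - k + 1):
            km = s[i : i + k]
            if "N" not in km:
                counts[km] += 1
    return counts


def _unitigs(kmers: set[str], k: int) -> list[str]:
    """Maximal unambiguous paths in the k-mer de Bruijn graph."""

    def succs(km: str) -> list[str]:
        return [km[1:] + b for b in "ACGT" if km[1:] + b in kmers]

    def preds(km: str) -> list[str]:
        return [b + km[:-1] for b in "ACGT" if b + km[:-1] in kmers]

    visited: set[str] = set()
    out: list[str] = []
    starts = [
        km
        for km in kmers
        if len(preds(km)) != 1 or len(succs(preds(km)[0])) > 1
    ]
    for start in starts:
        if start in visited:
            continue
        path = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = succs(cur)
            if len(nxt) != 1:
                break
            nn = nxt[0]
            if len(preds(nn)) != 1 or nn in visited:
                break
            path.append(nn)
            visited.add(nn)
            cur = nn
        out.append(path[0] + "".join(p[-1] for p in path[1:]))
    # isolated cycles never reach a start node; harvest whatever remains
    for km in kmers:
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            nxt = succs(cur)
            if len(nxt) != 1 or nxt[0] in visited:
                break
            path.append(nxt[0])
            visited.add(nxt[0])
            cur = nxt[0]
        out.append(path[0] + "".join(p[-1] for p in path[1:]))
    return out


def _prune_tips(kmers: set[str], k: int) -> set[str]:
    """Drop dead-end unitigs shorter than 2k that hang off a branch."""

    def has_pred(km: str) -> bool:
        return any(b + km[:-1] in kmers for b in "ACGT")

    def has_succ(km: str) -> bool:
        return any(km[1:] + b in kmers for b in "ACGT")

    doomed: set[str] = set()
    for unitig in _unitigs(kmers, k):
        if len(unitig) >= 2 * k:
            continue
        first = unitig[:k]
        last = unitig[-k:]
        left_dead = not any(
            b + first[:-1] in kmers and b + first[:-1] not in _path_kmers(unitig, k)
            for b in "ACGT"
        )
        right_dead = not any(
            last[1:] + b in kmers and last[1:] + b not in _path_kmers(unitig, k)
            for b in "ACGT"
        )
        # a tip dangles on exactly one side
        if left_dead != right_dead:
            doomed |= _path_kmers(unitig, k)
    return kmers - doomed


def _path_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def assemble_contigs(
    reads: Sequence[TaggedRead] | Sequence[str],
    cell_id: str = "",
    k_assembly: int = DEFAULT_K_ASSEMBLY,
    min_kmer_cov: int = DEFAULT_MIN_KMER_COV,
    min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH,
) -> list[Contig]:
    """Assemble one cell's antisense reads into sense contigs.

    Reads are reverse-complemented, k-mers below the coverage floor are
    dropped (this removes most sequencing-error k-mers), short dead-end tips
    are pruned, and maximal unambiguous paths at least
    ``min_contig_length`` long are emitted. Read support is a fast
    shared-k-mer vote recomputed properly at chain selection.
    """
    if k_assembly % 2 == 0:
        raise RepertoireError("k_assembly must be odd")
    seqs = [r.sequence if isinstance(r, TaggedRead) else r for r in reads]
    sense = [revcomp(s) for s in seqs]
    counts = _kmer_counts(sense, k_assembly)
    kmers = {km for km, n in counts.items() if n >= min_kmer_cov}
    if not kmers:
        return []
    kmers = _prune_tips(kmers, k_assembly)
    contigs_seq = [
        u for u in _unitigs(kmers, k_assembly) if len(u) >= min_contig_length
    ]
    contigs_seq.sort(key=lambda s: (-len(s), s))
    contigs = [
        Contig(cell_id, f"{cell_id or 'cell'}_contig{i + 1}", seq)
        for i, seq in enumerate(contigs_seq)
    ]
    if contigs:
        # quick support: each read votes for the contig sharing most k-mers
        owner: dict[str, int] = {}
        for ci, c in enumerate(contigs):
            for km in _path_kmers(c.sequence, k_assembly):
                owner.setdefault(km, ci)
        for s in sense:
            votes: Counter[int] = Counter()
            for i in range(len(s) - k_assembly + 1):
                ci = owner.get(s[i : i + k_assembly])
                if ci is not None:
                    votes[ci] += 1
            if votes:
                contigs[votes.most_common(1)[0][0]].read_support += 1
    return contigs


# ---------------------------------------------------------------------------
# V(D)J annotation
# ---------------------------------------------------------------------------


@dataclass
class VdjAnnotation:
    locus: str
    v_call: str
    j_call: str
    d_call: str | None = None
    c_call: str | None = None
    isotype: str | None = None
    v_identity: float = 0.0  # percent of aligned V columns matching germline
    cdr3_nt: str = ""
    cdr3_aa: str = ""
    frame_ok: bool = False
    stop_free: bool = False
    productive: bool = False
    # contig coordinates (0-based) of the anchors and segment bounds
    v_anchor_pos: int = -1
    j_anchor_pos: int = -1
    j_end_pos: int = -1
    sense_sequence: str = ""


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class _LocalHit:
    score: float
    t_blocks: tuple[tuple[int, int], ...]  # contig blocks
    q_blocks: tuple[tuple[int, int], ...]  # germline blocks
    matches: int
    columns: int

    @property
    def t_start(self) -> int:
        return self.t_blocks[0][0]

    @property
    def t_end(self) -> int:
        return self.t_blocks[-1][1]

    @property
    def q_start(self) -> int:
        return self.q_blocks[0][0]

    @property
    def q_end(self) -> int:
        return self.q_blocks[-1][1]

    def map_q_to_t(self, q: int) -> int:
        """Contig coordinate of germline position q (extrapolated off-ends)."""
        for (ts, te), (qs, qe) in zip(self.t_blocks, self.q_blocks):
            if qs <= q < qe:
                return ts + (q - qs)
        if q < self.q_start:
            return self.t_start - (self.q_start - q)
        return self.t_end + (q - self.q_end)


def _align(contig: str, segment: str) -> _LocalHit | None:
    if not contig or not segment:
        return None
    alignments = _ALIGNER.align(contig, segment)
    try:
        aln = alignments[0]
    except IndexError:
        return None
    t_blocks, q_blocks = aln.aligned
    t_blocks = tuple((int(a), int(b)) for a, b in t_blocks)
    q_blocks = tuple((int(a), int(b)) for a, b in q_blocks)
    matches = columns = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for x, y in zip(contig[ts:te], segment[qs:qe]):
            columns += 1
            if x == y:
                matches += 1
    return _LocalHit(float(aln.score), t_blocks, q_blocks, matches, columns)


def _shares_kmer(contig: str, segments: Iterable[GermlineSegment], k: int = 15,
                 min_shared: int = 2) -> bool:
    """Cheap prescreen: does the contig share exact k-mers with any segment?"""
    contig_kmers = _path_kmers(contig, k) | _path_kmers(revcomp(contig), k)
    for seg in segments:
        shared = 0
        for i in range(len(seg.sequence) - k + 1):
            if seg.sequence[i : i + k] in contig_kmers:
                shared += 1
                if shared >= min_shared:
                    return True
    return False


def _longest_common_substring(a: str, b: str) -> int:
    if not a or not b:
        return 0
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def annotate_vdj(
    contig: Contig | str,
    db: GermlineDatabase,
    min_score: float = DEFAULT_MIN_SCORE,
    prescreen: bool = True,
) -> VdjAnnotation | None:
    """Annotate a contig with V/J calls, CDR3 and productivity flags.

    Both orientations are tried; the orientation and locus of the best V
    alignment win. Returns None when the best V or J alignment score stays
    below ``min_score`` (non-receptor contigs).
    """
    seq = contig.sequence if isinstance(contig, Contig) else contig
    if prescreen and not _shares_kmer(
        seq, [s for s in db.segments if s.segment_class in ("V", "J")]
    ):
        return None

    best: tuple[float, str, GermlineSegment, _LocalHit, str] | None = None
    for oriented in (seq, revcomp(seq)):
        for locus in db.loci:
            for v in db.get(locus, "V"):
                hit = _align(oriented, v.sequence)
                if hit and (best is None or hit.score > best[0]):
                    best = (hit.score, locus, v, hit, oriented)
    if best is None or best[0] < min_score:
        return None
    _, locus, v, v_hit, sense = best

    j_best: tuple[GermlineSegment, _LocalHit] | None = None
    for j in db.get(locus, "J"):
        hit = _align(sense, j.sequence)
        if hit and (j_best is None or hit.score > j_best[1].score):
            j_best = (j, hit)
    if j_best is None or j_best[1].score < min_score:
        return None
    j, j_hit = j_best

    v_anchor = v_hit.map_q_to_t(v.cdr3_anchor)
    j_anchor = j_hit.map_q_to_t(j.cdr3_anchor)
    j_end = j_hit.map_q_to_t(len(j.sequence) - 1) + 1
    if j_anchor <= v_anchor:
        return None

    cdr3_nt = sense[v_anchor : j_anchor + 3]
    frame_ok = len(cdr3_nt) % 3 == 0
    cdr3_aa = translate(cdr3_nt) if frame_ok else ""

    orf_start = v_hit.t_start + ((v_anchor - v_hit.t_start) % 3)
    orf = sense[orf_start : min(j_end, len(sense))]
    stop_free = "*" not in translate(orf[: len(orf) - (len(orf) % 3)])

    d_call = None
    if locus in D_LOCI:
        junction = sense[v_anchor + 3 : j_anchor]
        d_top = (0, None)
        for d in db.get(locus, "D"):
            lcs = _longest_common_substring(junction, d.sequence)
            if lcs > d_top[0]:
                d_top = (lcs, d.segment_id)
        if d_top[0] >= D_MIN_MATCH:
            d_call = d_top[1]

    v_identity = 100.0 * v_hit.matches / v_hit.columns if v_hit.columns else 0.0
    return VdjAnnotation(
        locus=locus,
        v_call=v.segment_id,
        j_call=j.segment_id,
        d_call=d_call,
        v_identity=v_identity,
        cdr3_nt=cdr3_nt,
        cdr3_aa=cdr3_aa,
        frame_ok=frame_ok,
        stop_free=stop_free,
        productive=False,  # finalized by the constant-region check
        v_anchor_pos=v_anchor,
        j_anchor_pos=j_anchor,
        j_end_pos=j_end,
        sense_sequence=sense,
    )


def check_constant_region(
    annotation: VdjAnnotation,
    db: GermlineDatabase,
    min_c_score: float = DEFAULT_MIN_C_SCORE,
    max_gap: int = C_MAX_GAP,
) -> tuple[VdjAnnotation | None, str | None]:
    """Require an in-frame constant region 3' of J; else discard.

    Returns (annotation, None) on success (c_call/isotype/productive set) or
    (None, reason) with reason in {"no_constant_region", "c_out_of_frame"}.
    """
    sense = annotation.sense_sequence
    best: tuple[GermlineSegment, _LocalHit] | None = None
    for c in db.get(annotation.locus, "C"):
        hit = _align(sense, c.sequence)
        if hit and (best is None or hit.score > best[1].score):
            best = (c, hit)
    if best is None or best[1].score < min_c_score:
        return None, "no_constant_region"
    c, hit = best
    c_start = hit.t_start - hit.q_start  # extrapolated contig coord of C base 0
    if abs(c_start - annotation.j_end_pos) > max_gap:
        return None, "no_constant_region"
    contig_frame = (c_start - annotation.v_anchor_pos) % 3
    germline_frame = (0 - c.reading_frame_offset) % 3
    if contig_frame != germline_frame:
        return None, "c_out_of_frame"
    out = replace(
        annotation,
        c_call=c.segment_id,
        isotype=c.isotype or c.segment_id,
    )
    out.productive = out.frame_ok and out.stop_free and out.c_call is not None
    return out, None


# ---------------------------------------------------------------------------
# merging, selection, recovery, clonotypes
# ---------------------------------------------------------------------------


def merge_same_rearrangement(
    candidates: Sequence[tuple[Contig, VdjAnnotation]],
) -> list[tuple[Contig, VdjAnnotation]]:
    """Collapse contigs with identical (V, J, CDR3) to the largest one.

    Ties break on higher read support, then lexicographic contig id; the
    kept contig's support is the sum over merged members.
    """
    groups: dict[tuple[str, str, str], list[tuple[Contig, VdjAnnotation]]] = (
        defaultdict(list)
    )
    for contig, ann in candidates:
        groups[(ann.v_call, ann.j_call, ann.cdr3_nt)].append((contig, ann))
    out = []
    for members in groups.values():
        members.sort(key=lambda m: (-m[0].length, -m[0].read_support, m[0].contig_id))
        keep_contig, keep_ann = members[0]
        total = sum(m[0].read_support for m in members)
        out.append((replace(keep_contig, read_support=total), keep_ann))
    out.sort(key=lambda m: m[0].contig_id)
    return out


def _pseudo_support(
    contigs: Sequence[Contig], reads: Sequence[TaggedRead], k: int = 21
) -> dict[str, int]:
    """Reads-on-contigs support with the same voting semantics as counting."""
    kmer_map: dict[str, set[int]] = defaultdict(set)
    for ci, c in enumerate(contigs):
        for km in _path_kmers(c.sequence, k):
            kmer_map[km].add(ci)
    support = {c.contig_id: 0 for c in contigs}
    for r in reads:
        sense = revcomp(r.sequence)
        votes: Counter[int] = Counter()
        for i in range(len(sense) - k + 1):
            for ci in kmer_map.get(sense[i : i + k], ()):
                votes[ci] += 1
        if not votes:
            continue
        ranked = votes.most_common()
        if ranked[0][1] < 3:
            continue
        if len(ranked) > 1 and ranked[1][1] == ranked[0][1]:
            continue
        support[contigs[ranked[0][0]].contig_id] += 1
    return support


def select_chain(
    candidates: Sequence[tuple[Contig, VdjAnnotation]],
    cell_reads: Sequence[TaggedRead],
    k: int = 21,
) -> tuple[Contig, VdjAnnotation] | None:
    """Pick the highest-expressed productive contig of one locus.

    Support is recomputed by pseudoaligning the cell's reads onto the
    candidate contigs; ties go to the longer contig.
    """
    productive = [(c, a) for c, a in candidates if a.productive]
    if not productive:
        return None
    support = _pseudo_support([c for c, _ in productive], cell_reads, k)
    ranked = sorted(
        productive,
        key=lambda m: (-support[m[0].contig_id], -m[0].length, m[0].contig_id),
    )
    keep_contig, keep_ann = ranked[0]
    return replace(keep_contig, read_support=support[keep_contig.contig_id]), keep_ann


_HEAVY = {"BCR": ("IGH",), "TCR": ("TRB",)}
_LIGHT = {"BCR": ("IGK", "IGL"), "TCR": ("TRA",)}
_CLASSES = {
    "BCR": ("paired", "heavy_only", "light_only", "none"),
    "TCR": ("paired", "beta_only", "alpha_only", "none"),
}


@dataclass
class CellRepertoire:
    cell_id: str
    chains: dict[str, tuple[Contig, VdjAnnotation]] = field(default_factory=dict)
    recovery_class: str = "none"
    discards: list[tuple[str, str]] = field(default_factory=list)  # (contig_id, reason)


def classify_recovery(cell: CellRepertoire, mode: str = "BCR") -> str:
    heavy = any(l in cell.chains for l in _HEAVY[mode])
    light = any(l in cell.chains for l in _LIGHT[mode])
    names = _CLASSES[mode]
    if heavy and light:
        return names[0]
    if heavy:
        return names[1]
    if light:
        return names[2]
    return names[3]


def recovery_fractions(
    cells: Sequence[CellRepertoire], mode: str = "BCR"
) -> dict[str, float]:
    """Cohort pie fractions over all analyzed cells (sums to 1)."""
    names = _CLASSES[mode]
    n = len(cells)
    if n == 0:
        return {name: 0.0 for name in names}
    counts = Counter(classify_recovery(c, mode) for c in cells)
    return {name: counts.get(name, 0) / n for name in names}


def reconstruct_cell(
    cell_id: str,
    reads: Sequence[TaggedRead],
    db: GermlineDatabase,
    mode: str = "BCR",
    k_assembly: int = DEFAULT_K_ASSEMBLY,
    min_kmer_cov: int = DEFAULT_MIN_KMER_COV,
    min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH,
    min_score: float = DEFAULT_MIN_SCORE,
) -> CellRepertoire:
    """Full per-cell pipeline: assemble, annotate, filter, merge, select."""
    cell = CellRepertoire(cell_id)
    contigs = assemble_contigs(
        reads, cell_id, k_assembly, min_kmer_cov, min_contig_length
    )
    per_locus: dict[str, list[tuple[Contig, VdjAnnotation]]] = defaultdict(list)
    for contig in contigs:
        ann = annotate_vdj(contig, db, min_score)
        if ann is None:
            continue
        ann, reason = check_constant_region(ann, db)
        if ann is None:
            cell.discards.append((contig.contig_id, reason))
            continue
        if not ann.productive:
            cell.discards.append((contig.contig_id, "nonproductive"))
            continue
        per_locus[ann.locus].append((contig, ann))
    for locus, cands in per_locus.items():
        merged = merge_same_rearrangement(cands)
        selected = select_chain(merged, reads)
        if selected is not None:
            cell.chains[locus] = selected
    cell.recovery_class = classify_recovery(cell, mode)
    return cell


@dataclass(frozen=True)
class Clonotype:
    clonotype_id: str
    v_gene: str
    j_gene: str
    member_cell_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_cell_ids)


def assign_clonotypes(
    annotations: Mapping[str, VdjAnnotation], locus: str
) -> list[Clonotype]:
    """Partition cells carrying the locus by gene-level (V, J) identity.

    Allele suffixes (``*NN``) are stripped; clonotype ids are stable,
    ordered by decreasing size then lexicographic (V, J) key.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    for cell_id, ann in annotations.items():
        if ann.locus != locus:
            continue
        groups[(strip_allele(ann.v_call), strip_allele(ann.j_call))].append(cell_id)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [
        Clonotype(f"CT{i + 1:04d}", v, j, tuple(sorted(cells)))
        for i, ((v, j), cells) in enumerate(ordered)
    ]


def mutation_frequency(annotation: VdjAnnotation) -> float | None:
    """Percent mismatched aligned V columns (gaps excluded) = 100 - identity."""
    if not annotation.v_call:
        return None
    return 100.0 - annotation.v_identity


def repertoire_to_tsv(path: str | Path, cells: Sequence[CellRepertoire]) -> None:
    """AIRR-inspired TSV, one row per selected chain."""
    cols = [
        "cell_id", "locus", "v_call", "d_call", "j_call", "c_call",
        "productive", "cdr3_nt", "cdr3_aa", "v_identity_pct",
        "mutation_freq_pct", "read_support", "contig_length", "sequence",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for cell in cells:
            for locus in sorted(cell.chains):
                contig, ann = cell.chains[locus]
                row = [
                    cell.cell_id, locus, ann.v_call, ann.d_call or "",
                    ann.j_call, ann.c_call or "", str(ann.productive),
                    ann.cdr3_nt, ann.cdr3_aa, f"{ann.v_identity:.3f}",
                    f"{100.0 - ann.v_identity:.3f}", str(contig.read_support),
                    str(contig.length), ann.sense_sequence,
                ]
                fh.write("\t".join(row) + "\n")


def discards_to_tsv(path: str | Path, cells: Sequence[CellRepertoire]) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tcontig_id\treason\n")
        for cell in cells:
            for contig_id, reason in cell.discards:
                fh.write(f"{cell.cell_id}\t{contig_id}\t{reason}\n")
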