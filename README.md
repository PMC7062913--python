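# plate5p

Plate-based 5′-end single-cell RNA-seq resolves, for each FACS-sorted B or T
cell in a 96-well plate, both its transcriptome and the rearranged sequence of
its antigen receptor (BCR or TCR). The trick is in the read anatomy: a
template-switch oligo puts an 8-bp well barcode, a 5-bp UMI and a TATA spacer
on the cDNA 5′ end; Read2 (16 cycles) reads that tag, while Read1 (67 cycles)
reads the gene insert *from its 3′ end*, so reads tile the 5′ half of each
mRNA in antisense orientation. Because immunoglobulin and TCR variable
regions sit at the mRNA 5′ end, the same reads that quantify gene expression
also cover the whole V(D)J rearrangement and a large part of the constant
region — enough to reconstruct paired heavy/light (or β/α) chains per cell.

`plate5p` implements the complete computational side of such an experiment,
plus a ground-truthed simulator so every stage is testable without any
external dataset:

* **simulate** — paired FASTQ with the exact read anatomy above: 100–850 bp
  inserts, per-well barcodes, UMIs drawn from the 4⁵ = 1,024 space, ERCC-like
  spike-ins dosed by concentration/dilution (default 1:2,000,000 into 2 µl,
  ≈ 0.025 pg/well), V(D)J rearrangements with junctional trimming,
  N-additions and somatic hypermutation, PCR duplication, sequencing error,
  and empty negative-control wells (H1, H12). A molecule-level truth channel
  records everything.
* **demux** — positional barcode/UMI extraction from Read2, unambiguous
  1-mismatch barcode correction (the bundled whitelist guarantees pairwise
  Hamming distance ≥ 3), quality filtering, per-cell grouping.
* **quantify** — strand-aware k-mer pseudoalignment of Read1 against a
  transcript + spike-in reference, UMI collapse (directional adjacency rule
  `count(a) ≥ 2·count(b) − 1`, or exact distinct-pair mode), and
  multi-plate gene-by-cell matrix assembly (MatrixMarket and TSV output).
* **repertoire** — per-cell de Bruijn assembly of Read1, V(D)J annotation by
  local affine-gap alignment against a germline database, CDR3 between the
  conserved Cys and Trp/Phe anchors, in-frame constant-region requirement,
  merging of same-rearrangement contigs (largest kept), expression-based
  chain selection by pseudoaligning the cell's own reads back onto its
  contigs, gene-level V–J clonotypes, and V-region mutation frequency.
* **qc** — spike-in accuracy (Pearson r of log₁₀(UMI+1) vs
  log₁₀(molecules+1) over detected species), a five-parameter logistic
  detection curve `y = p_min + (p_max − p_min)/(1 + (m_ref/m)^h)^s` whose
  50% crossing is the EC50 molecular sensitivity, gene-body coverage
  profiles, hard 250-gene + 3-MAD cell filters, log-normalization to 10,000
  counts per cell, and the arcsinh transform for index-sort fluorescence.

## Worked example

```python
import plate5p as p
from plate5p.simulate import SimulationConfig, simulate_plate

cfg = SimulationConfig(
    seed=42, cells_per_plate=8, mean_molecules_per_cell=1000,
    spikein_dilution_factor=8.6e8,      # ~100 spike molecules/well
    pcr_duplication_mean=4.0, seq_error_rate=1e-3,
    receptor_mode="BCR", shm_rate=0.01,
)
layout = p.bundled_layout()
plate = simulate_plate(cfg, p.bundled_transcriptome(), p.bundled_spikeins(),
                       layout, p.bundled_germline())
cells, report = p.demultiplex(plate.read1, plate.read2, layout)

index = p.build_index(p.bundled_transcriptome(), p.bundled_spikeins())
genes = [t.gene_id for t in p.bundled_transcriptome()] + \
        [s.species_id for s in p.bundled_spikeins()]
counted = [p.count_cell(cid, reads, index) for cid, reads in sorted(cells.items())]
matrix = p.CountMatrix.from_cells(counted, genes)

reps = [p.reconstruct_cell(cid, reads, p.bundled_germline(), "BCR")
        for cid, reads in sorted(cells.items())]
```

prints (assembled from the objects above):

```
simulated 39466 read pairs for 8 cells
demux: 39463/39466 assigned (3 unassigned, 0 in control wells)
matrix: 122 genes x 8 cells, median 871 molecules/cell
mean spike-in accuracy r = 0.877, mean spike-in content = 11.5%
BCR recovery: {'paired': 0.88, 'heavy_only': 0.0, 'light_only': 0.12, 'none': 0.0}
cell P1:A1: IGH IGHV3-23*01 / IGHD2-2*01 / IGHJ6*01, isotype IGHG1, CDR3 CSSGLEGLLQTIITYW, mutation load 0.42%
```

Read this as: at a 10⁻³ per-base error rate essentially every read pair is
still assignable to its well (barcode correction radius 1 against a
distance-≥3 whitelist); the per-cell Pearson accuracy of ~0.88 reflects pure
Poisson sampling of ~100 spike molecules over 92 species; 7 of 8 cells
yield a paired heavy+light receptor while one recovers only its
(higher-expressed) light chain; and the reconstructed heavy chain of cell
A1 matches its simulated germline calls with a 0.42% V-region mutation load
(simulated SHM was 1%, so individual cells scatter around that).

The same pipeline is scriptable from the shell:

```bash
plate5p simulate --config config.yaml --seed 7 --out sim/
plate5p demux --r1 sim/P1_R1.fastq.gz --r2 sim/P1_R2.fastq.gz \
              --whitelist sim/whitelist.tsv --out demuxed/
plate5p count --cells-dir demuxed/ --transcriptome sim/transcriptome.fasta \
              --spikeins sim/spikeins.fasta --out counts/
plate5p repertoire --cells-dir demuxed/ --germline sim/germline.fasta --out rep/
plate5p qc --matrix counts/matrix.tsv --spikeins sim/spikeins.fasta --out qc/
# or everything at once, with a reproducibility manifest:
plate5p run-all --config config.yaml --seed 7 --out run/
```

## Reference formats

FASTA for transcripts (`>TX0001 gene=GENE0001`), spike-ins
(`>SPIKE-00001 conc=<attomol/ul>`) and germline segments
(`>IGHV3-23*01 class=V locus=IGH anchor=270 frame=0`, with `isotype=` on
constant segments); two-column TSV for the well→barcode whitelist; matrix
output as MatrixMarket triplet or dense TSV; repertoire output as an
AIRR-inspired TSV, one row per selected chain.
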