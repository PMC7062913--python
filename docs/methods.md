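# Methods

## The measurement being modelled

One 96-well plate holds up to 94 single cells (wells H1 and H12 stay empty
as contamination sentinels). Reverse transcription appends a
template-switch oligo to each cDNA 5′ end carrying an 8-bp well barcode, a
5-bp UMI and a TATA spacer. After pooling and tagmentation, sequencing
produces a synchronized pair per fragment: Read2 (16 nt) covers barcode +
UMI + the first bases of the spacer; Read1 (67 nt) reads the insert from
its 3′ end, i.e. it is the reverse complement of the 3′-terminal bases of a
fragment anchored at the transcript 5′ terminus. Insert sizes of 100–850 bp
therefore translate into antisense reads tiling roughly the first 33–850
bases of each mRNA — which is also why complete V(D)J regions of antigen
receptor transcripts are recoverable from the same data.

## Simulator

The generator is a first-class module, not a test helper. Per cell it draws
per-gene abundances log-normal(0, σ) (σ = `expression_dispersion`, default
1), molecule counts Poisson with mean `mean_molecules_per_cell · aᵍ/Σa`,
one UMI per molecule uniform over 4⁵, a shifted-Poisson number of PCR
copies per molecule (`copies = 1 + Poisson(mean − 1)`), and independent
per-base substitution errors per emitted copy — so UMI errors occur and
exercise the directional collapse. Spike-in molecules are Poisson with mean
`conc · 10⁻¹⁸ · N_A · V / D` per species, identical in every cell-containing
well; negative-control wells emit nothing. Fragment length is uniform on
[100, 850] clipped to the transcript length; Read1 is the reverse complement
of the fragment's last 67 bases (the whole fragment when shorter — no
adapter read-through is invented). Base qualities are constant `I`;
quality modelling is out of scope.

Receptor transcripts are built per cell as V (3′-trimmed 0–5 nt) +
N-additions (0–8 nt) [+ trimmed D + N for IGH/TRB] + J (5′-trimmed 0–5 nt) +
the full constant segment. For productive chains the junction is padded so
the J anchor shares the V reading frame and draws creating stop codons
(including via SHM) are redrawn; D trims are bounded so ≥ 8 nt of D
survive, keeping the annotator's D rule decidable. SHM substitutes bases
uniformly over the V(D)J region only; the truth record stores the
post-mutation contig and its anchor-inclusive CDR3, since that is what a
correct reconstruction should return. Heavy/light molecule counts default
to 50/100, reflecting the roughly two-fold higher light-chain expression
seen in B cells — which is also why light-only is the dominant failure
mode when recovery is incomplete.

`reads_per_cell_target` is an optional cap: when set, each cell's emitted
copies are downsampled to it and the truth `copies_emitted` is recounted.
The default (None) emits every copy, which is what the conservation oracle
needs.

What the simulator does **not** emulate: indel sequencing errors, barcode
hopping, ambient RNA, doublets, transcript-length-dependent capture bias,
or any capture-efficiency loss (every molecule present yields at least one
read). Passing tests therefore demonstrate correctness of the pipeline's
logic under the stated noise model, not real-data sensitivity figures —
molecular detection limits on real data are dominated by capture
efficiency, which is deliberately outside this model.

## Bundled references

All fixtures are synthetic and regenerated deterministically from a fixed
internal seed. The 96-barcode whitelist is sampled greedily under a
minimum pairwise Hamming distance of 3, the geometric property that makes
1-mismatch correction unambiguous. The 92 spike-in species have lengths
250–2,000 nt (30-nt poly(A) tail) and stock concentrations log-uniform
over five orders of magnitude, rescaled so the default dosing (1:2,000,000
into 2 µl) delivers 0.025 pg of RNA — ≈ 4.3 × 10⁴ molecules — per well.
The toy transcriptome holds 30 genes of 900–2,400 nt, comfortably longer
than the insert range so coverage profiles show the protocol's 5′ bias
rather than short-transcript clipping. The germline database covers
IGH/IGK/IGL/TRA/TRB with V segments ending 9 nt after the conserved Cys
codon, J segments carrying 9 nt of junction-side sequence before the
conserved Trp/Phe codon, isotype-labelled constant segments, and one
near-identical second allele per receptor family so gene-level
(allele-stripped) logic is genuinely exercised. Real vendor concentration
tables and curated germline repertoires could be dropped in through the
documented FASTA/TSV loaders; all downstream mathematics is agnostic to
the actual sequences.

## Pipeline parameters

| parameter | default | rationale |
|---|---|---|
| barcode correction radius | 1 substitution | unambiguous given whitelist distance ≥ 3; indels not corrected |
| Read2 quality floor | mean Phred ≥ 20 over barcode+UMI | "low-quality" needs an operational cut; exposed in config |
| pseudoalignment k | 21 | < read length 67 with margin; one error still leaves ≥ 23 clean k-mers |
| min k-mer hits per read | 3 | rejects spurious single-k-mer matches |
| UMI collapse | directional, radius 1 | per-copy errors create satellite UMIs; `count(a) ≥ 2·count(b) − 1` is the standard adjacency criterion; exact mode kept as the collision-aware oracle |
| assembly k | 31 | longer than repeats in desk-scale references, < read length |
| min k-mer coverage | 2 | removes almost all error k-mers at ~10⁻³ error |
| min contig length | 150 nt | below any plausible V(D)J+C fragment of interest |
| alignment scores | match 2 / mismatch −2 / open −4 / extend −1, local | standard nucleotide scoring; V/J acceptance at score ≥ 60, C at ≥ 40 |
| C placement | start within 10 nt of J end, in frame | "in-frame constant region" made operational |
| D call | ungapped match ≥ 8 nt inside junction | short D segments cannot support scored alignment |
| hard gene floor | 250 genes | per-cell quality floor for genome-scale references (scaled when the gene universe is tiny) |
| MAD filter | 3 MADs, consistency constant 1.4826 | makes the MAD comparable to an SD; statistics computed after the hard floor so dead cells cannot drag the median |
| normalization | ln(1 + 10⁴·count/total), spike-ins excluded | spike content must not deflate biological expression |

UMI collapse radius, HTSeq-like assignment mode, per-plate vs per-sample
MAD statistics and the quality floor are configuration knobs because the
underlying conventions vary between pipelines; defaults are stated above.

## Numerical choices

The 5PL detection curve `y = p_min + (p_max − p_min)/(1 + (m_ref/m)^h)^s`
is evaluated in log space (no overflow at extreme molecule ratios) and fit
by bounded least squares from `p_min=0, p_max=100, h=s=1`, `m_ref` at the
species nearest 50% detection. EC50 is defined operationally as the 50%
crossing of the fitted curve, found by bisection in log-molecules over the
observed range; if detection never crosses 50% the fit is returned with
the EC50 flagged unreliable rather than extrapolated. In the symmetric
limit (s = 1, full asymptotes) EC50 equals `m_ref` exactly.

Accuracy requires ≥ 3 detected species (two points always give |r| = 1)
and non-degenerate variance. Ties in contig merging break on read support
then contig id; ties in chain selection break on contig length; clonotype
ids order by size then lexicographic (V, J). All coordinates are 0-based
half-open, sequences 5′→3′ sense; Read1 is reverse-complemented exactly
once, at entry to quantification or assembly.

Annotation maps germline anchor positions through the local alignment and
extrapolates linearly off alignment ends — exact whenever indels are
absent, which holds under the simulator's substitution-only error model.
Mutation frequency is 100 − V identity, i.e. mismatched aligned V columns
over aligned V columns with gap columns excluded; J and junction
mismatches are deliberately not counted (the V region is the
alignment-stable denominator). Local alignment clips terminal mismatches,
which biases the estimate down by a few percent of its value at 2% SHM —
visible but well inside the ±0.5 percentage-point acceptance band.

## Problem sizes

Desk-scale test conditions, chosen once: conservation runs use 16 cells ×
2,000 molecules with duplication mean 4 and zero sequencing error;
repertoire recovery uses 100 B cells (two plates of 50) at SHM 1%, error
10⁻³, 50 heavy / 100 light receptor molecules, 200 background molecules
over 20 genes; sensitivity recovery uses 30 species × 480 wells × 100
replicates; filter-oracle agreement uses 200 random tables of 3–30 cells.
Test configurations raise the spike dilution so spike molecules are a few
percent of cell content (the design target for spike-in mass); the
package default stays at the protocol's 1:2,000,000.

## Known limitations

Allele-level segment calls are not claimed — near-identical alleles are
resolved arbitrarily and all comparisons are gene-level, matching the
clonotype definition. Multiple productive rearrangements in one locus are
resolved by expression, never flagged as doublets. The pseudoaligner is
transcript-level by design: splice-aware genome alignment, multi-mapping
EM, and intronic/antisense categories are out of scope, as are variable
gene selection, embeddings and marker testing downstream of the
normalized matrix.
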