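"""Assembly, V(D)J annotation, chain selection and clonotypes."""

import numpy as np
import pytest

import plate5p as p
from plate5p.reference import revcomp, strip_allele
from plate5p.repertoire import Contig, VdjAnnotation


def tiled_reads(seq, read_len=67, step=20):
    """Antisense reads tiling a sense sequence end to end, twice over
    (coverage >= 2 everywhere so the k-mer coverage floor keeps them)."""
    out = []
    for start in range(0, len(seq) - read_len + 1, step):
        out.append(revcomp(seq[start : start + read_len]))
    out.append(revcomp(seq[-read_len:]))
    return out * 2


class TestAssembly:
    def test_tiled_sequence_reassembles_exactly(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 400))
        contigs = p.assemble_contigs(tiled_reads(seq), "c")
        assert len(contigs) == 1
        assert contigs[0].sequence == seq

    def test_no_reads_empty(self):
        assert p.assemble_contigs([], "c") == []

    def test_two_disjoint_sources_two_contigs(self):
        rng = np.random.default_rng(1)
        s1 = "".join(rng.choice(list("ACGT"), 350))
        s2 = "".join(rng.choice(list("ACGT"), 300))
        contigs = p.assemble_contigs(tiled_reads(s1) + tiled_reads(s2), "c")
        assert sorted(c.sequence for c in contigs) == sorted([s1, s2])

    def test_singleton_error_kmers_filtered(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 400))
        reads = tiled_reads(seq)
        corrupt = list(reads[0])
        corrupt[30] = "A" if corrupt[30] != "A" else "C"
        contigs = p.assemble_contigs(reads + ["".join(corrupt)], "c")
        assert [c.sequence for c in contigs] == [seq]

    def test_read_support_assigned(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400))
        reads = tiled_reads(seq)
        contigs = p.assemble_contigs(reads, "c")
        assert contigs[0].read_support == len(reads)


def _simulated_candidate(germline, seed=0, locus="IGH", shm=0.0):
    rng = np.random.default_rng(seed)
    contig_nt, truth = p.simulate_rearrangement(germline, locus, rng, shm_rate=shm)
    return Contig("cell", f"cell_contig{seed}", contig_nt), truth


class TestAnnotate:
    def test_simulated_contig_fully_recovered(self, germline):
        for seed, locus in [(0, "IGH"), (1, "IGK"), (2, "TRB"), (3, "IGL")]:
            contig, truth = _simulated_candidate(germline, seed, locus)
            ann = p.annotate_vdj(contig, germline)
            assert ann is not None
            assert ann.locus == locus
            assert strip_allele(ann.v_call) == strip_allele(truth.v_id)
            assert strip_allele(ann.j_call) == strip_allele(truth.j_id)
            assert ann.cdr3_nt == truth.junction_nt
            assert ann.frame_ok and ann.stop_free

    def test_reverse_orientation_handled(self, germline):
        contig, truth = _simulated_candidate(germline, 4)
        flipped = Contig("cell", "cell_contig", revcomp(contig.sequence))
        ann = p.annotate_vdj(flipped, germline)
        assert ann is not None and ann.cdr3_nt == truth.junction_nt

    def test_d_called_for_heavy_chain(self, germline):
        hits = 0
        for seed in range(6):
            contig, truth = _simulated_candidate(germline, seed, "IGH")
            ann = p.annotate_vdj(contig, germline)
            if ann.d_call is not None:
                hits += 1
                assert strip_allele(ann.d_call) == strip_allele(truth.d_id)
        assert hits >= 4  # >=8 nt of D survive by construction

    def test_junction_insertion_breaks_frame(self, germline):
        contig, truth = _simulated_candidate(germline, 5)
        seq = contig.sequence
        pos = seq.index(truth.junction_nt) + 4
        broken = Contig("cell", "cell_contig", seq[:pos] + "G" + seq[pos:])
        ann = p.annotate_vdj(broken, germline)
        assert ann is not None
        assert not ann.frame_ok
        ann2, reason = p.check_constant_region(ann, germline)
        assert ann2 is None and reason == "c_out_of_frame"

    def test_random_transcript_not_annotated(self, germline, transcriptome):
        for t in transcriptome[:3]:
            assert p.annotate_vdj(t.sequence[:500], germline) is None

    def test_shuffled_receptor_not_annotated(self, germline):
        contig, _ = _simulated_candidate(germline, 6)
        rng = np.random.default_rng(6)
        shuffled = "".join(rng.permutation(list(contig.sequence)))
        assert p.annotate_vdj(shuffled, germline, prescreen=False) is None


class TestConstantRegion:
    def test_full_contig_isotype_called(self, germline):
        for seed in range(4):
            contig, truth = _simulated_candidate(germline, seed)
            ann = p.annotate_vdj(contig, germline)
            ann, reason = p.check_constant_region(ann, germline)
            assert reason is None
            assert ann.c_call == truth.c_id
            assert ann.isotype == truth.isotype
            assert ann.productive

    def test_truncated_before_c_discarded(self, germline):
        contig, truth = _simulated_candidate(germline, 7)
        c = next(s for s in germline.segments if s.segment_id == truth.c_id)
        cut = Contig("cell", "x", contig.sequence[: len(contig.sequence) - len(c.sequence)])
        ann = p.annotate_vdj(cut, germline)
        assert ann is not None
        ann2, reason = p.check_constant_region(ann, germline)
        assert ann2 is None and reason == "no_constant_region"

    def test_frame_shifted_c_discarded(self, germline):
        contig, truth = _simulated_candidate(germline, 8)
        c = next(s for s in germline.segments if s.segment_id == truth.c_id)
        c_start = len(contig.sequence) - len(c.sequence)
        shifted = Contig(
            "cell", "x",
            contig.sequence[:c_start] + "G" + contig.sequence[c_start:],
        )
        ann = p.annotate_vdj(shifted, germline)
        ann2, reason = p.check_constant_region(ann, germline)
        assert ann2 is None and reason == "c_out_of_frame"


def _ann(v="IGHV1-1*01", j="IGHJ4*01", cdr3="TGTAAATGG", locus="IGH"):
    a = VdjAnnotation(locus=locus, v_call=v, j_call=j, cdr3_nt=cdr3)
    a.productive = True
    return a


class TestMergeAndSelect:
    def test_largest_kept_support_summed(self):
        cands = [
            (Contig("c", "c_contig1", "A" * 500, read_support=10), _ann()),
            (Contig("c", "c_contig2", "A" * 620, read_support=5), _ann()),
            (Contig("c", "c_contig3", "A" * 300, read_support=1), _ann()),
        ]
        merged = p.merge_same_rearrangement(cands)
        assert len(merged) == 1
        assert merged[0][0].length == 620
        assert merged[0][0].read_support == 16

    def test_distinct_cdr3_kept_separate(self):
        cands = [
            (Contig("c", "c_contig1", "A" * 500), _ann(cdr3="TGTAAATGG")),
            (Contig("c", "c_contig2", "A" * 400), _ann(cdr3="TGTCCCTGG")),
        ]
        assert len(p.merge_same_rearrangement(cands)) == 2

    def test_support_conserved_per_group(self):
        cands = [
            (Contig("c", f"c_contig{i}", "A" * (300 + i), read_support=i), _ann())
            for i in range(1, 5)
        ]
        merged = p.merge_same_rearrangement(cands)
        assert merged[0][0].read_support == sum(range(1, 5))

    def test_select_highest_expression(self, germline):
        c1, t1 = _simulated_candidate(germline, 10, "IGH")
        c2, t2 = _simulated_candidate(germline, 11, "IGH")
        reads = [
            p.TaggedRead("c", "AAAAA", revcomp(c1.sequence[i : i + 67]), "I" * 67)
            for i in range(0, 400, 10)
        ] + [
            p.TaggedRead("c", "AAAAA", revcomp(c2.sequence[i : i + 67]), "I" * 67)
            for i in range(0, 100, 10)
        ]
        a1 = p.annotate_vdj(c1, germline)
        a1, _ = p.check_constant_region(a1, germline)
        a2 = p.annotate_vdj(c2, germline)
        a2, _ = p.check_constant_region(a2, germline)
        selected = p.select_chain([(c1, a1), (c2, a2)], reads)
        assert selected is not None
        assert selected[1].cdr3_nt == a1.cdr3_nt
        assert selected[0].read_support > 0

    def test_select_single_candidate(self, germline):
        c1, _ = _simulated_candidate(germline, 12)
        a1 = p.annotate_vdj(c1, germline)
        a1, _ = p.check_constant_region(a1, germline)
        assert p.select_chain([(c1, a1)], []) is not None

    def test_select_no_productive(self):
        a = _ann()
        a.productive = False
        assert p.select_chain([(Contig("c", "x", "A" * 200), a)], []) is None


class TestRecoveryAndClonotypes:
    def test_recovery_classes(self):
        cell = p.CellRepertoire("c")
        cell.chains = {"IGH": None, "IGK": None}
        assert p.classify_recovery(cell, "BCR") == "paired"
        cell.chains = {"IGK": None}
        assert p.classify_recovery(cell, "BCR") == "light_only"
        cell.chains = {"IGH": None}
        assert p.classify_recovery(cell, "BCR") == "heavy_only"
        cell.chains = {}
        assert p.classify_recovery(cell, "BCR") == "none"
        cell.chains = {"TRB": None}
        assert p.classify_recovery(cell, "TCR") == "beta_only"

    def test_fractions_sum_to_one(self):
        cells = []
        for chains in ({"IGH": 1, "IGL": 1}, {"IGK": 1}, {}, {"IGH": 1}):
            c = p.CellRepertoire("c%d" % len(cells))
            c.chains = dict(chains)
            cells.append(c)
        fracs = p.recovery_fractions(cells, "BCR")
        assert sum(fracs.values()) == pytest.approx(1.0)
        assert fracs["paired"] == 0.25

    def test_allele_stripping_groups_clonotypes(self):
        anns = {
            "c1": _ann(v="IGHV3-23*01", j="IGHJ4*02"),
            "c2": _ann(v="IGHV3-23*02", j="IGHJ4*01"),
            "c3": _ann(v="IGHV3-23*01", j="IGHJ6*01"),
        }
        cts = p.assign_clonotypes(anns, "IGH")
        assert len(cts) == 2
        assert cts[0].size == 2 and set(cts[0].member_cell_ids) == {"c1", "c2"}

    def test_clonotypes_partition_eligible_cells(self):
        rng = np.random.default_rng(0)
        vs = ["IGHV1-1*01", "IGHV2-5*01", "IGHV3-23*01"]
        js = ["IGHJ4*01", "IGHJ6*01"]
        anns = {
            f"c{i}": _ann(v=str(rng.choice(vs)), j=str(rng.choice(js)))
            for i in range(30)
        }
        cts = p.assign_clonotypes(anns, "IGH")
        members = [c for ct in cts for c in ct.member_cell_ids]
        assert sorted(members) == sorted(anns)
        for ct in cts:
            assert all(
                (strip_allele(anns[c].v_call), strip_allele(anns[c].j_call))
                == (ct.v_gene, ct.j_gene)
                for ct_c in [ct] for c in ct.member_cell_ids
            )

    def test_expanded_clone_among_singletons(self):
        anns = {f"s{i}": _ann(v=f"IGHV{i}*01", j="IGHJ4*01") for i in range(10)}
        anns["e1"] = _ann(v="IGHV3-23*01", j="IGHJ6*01")
        anns["e2"] = _ann(v="IGHV3-23*02", j="IGHJ6*01")
        sizes = sorted(ct.size for ct in p.assign_clonotypes(anns, "IGH"))
        assert sizes == [1] * 10 + [2]


class TestMutationFrequency:
    def test_germline_identical_zero(self, germline):
        contig, _ = _simulated_candidate(germline, 13, shm=0.0)
        ann = p.annotate_vdj(contig, germline)
        assert p.mutation_frequency(ann) == pytest.approx(0.0, abs=1e-9)

    def test_arithmetic(self):
        ann = _ann()
        ann.v_identity = 98.0  # 4 mismatches / 200 aligned columns
        assert p.mutation_frequency(ann) == pytest.approx(2.0)

    def test_monotone_in_shm(self, germline):
        freqs = []
        for shm in (0.0, 0.02, 0.06):
            vals = []
            for seed in range(20, 26):
                contig, _ = _simulated_candidate(germline, seed, shm=shm)
                ann = p.annotate_vdj(contig, germline)
                vals.append(p.mutation_frequency(ann))
            freqs.append(np.mean(vals))
        assert freqs[0] < freqs[1] < freqs[2]


class TestEndToEndCell:
    def test_light_recovery_not_hurt_by_fewer_heavy(self, germline, transcriptome):
        """Halving heavy molecules must not increase heavy recovery."""
        from plate5p.simulate import SimulationConfig, simulate_plate
        import plate5p as pp

        results = {}
        for heavy in (50, 12):
            cfg = SimulationConfig(
                seed=99, cells_per_plate=4, mean_molecules_per_cell=100, genes=10,
                spikein_dilution_factor=2e12, pcr_duplication_mean=2.0,
                seq_error_rate=1e-3, receptor_mode="BCR", shm_rate=0.01,
                receptor_molecules_heavy=heavy, receptor_molecules_light=100,
            )
            plate = simulate_plate(cfg, transcriptome, pp.bundled_spikeins(),
                                   pp.bundled_layout(), germline)
            cells, _ = pp.demultiplex(plate.read1, plate.read2, pp.bundled_layout())
            n_heavy = 0
            for cid, reads in sorted(cells.items()):
                rep = pp.reconstruct_cell(cid, reads, germline, "BCR")
                n_heavy += "IGH" in rep.chains
            results[heavy] = n_heavy
        assert results[12] <= results[50]
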