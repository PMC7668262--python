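import numpy as np
import pytest

from alusirna import (
    SimConfig,
    SimRefParams,
    align_ungapped,
    apply_alu_knockdown,
    classify_utr_alus,
    make_hairpin,
    make_synthetic_references,
    map_dicing_products,
    preprocess_reads,
    revcomp,
    run_cascade,
    screen_single_alu_genes,
    simulate_dicer_products,
    simulate_library,
)
from alusirna.profiling import DICING_ADAPTOR_3P, DICING_ADAPTOR_5P
from alusirna.simulate import SIM_CLASSES


class TestMakeSyntheticReferences:
    def test_same_seed_is_byte_identical(self):
        a = make_synthetic_references(3)
        b = make_synthetic_references(3)
        assert a.genome.seq == b.genome.seq
        assert [(s.id, s.seq) for rs in a.ref_sets for s in rs.sequences] == [
            (s.id, s.seq) for rs in b.ref_sets for s in rs.sequences
        ]
        assert a.repeats == b.repeats

    def test_gene_configurations_recovered_by_screen(self, refs):
        statuses = classify_utr_alus(refs.genes, refs.repeats)
        antisense = screen_single_alu_genes(statuses, "antisense", 4.5)
        sense = screen_single_alu_genes(statuses, "sense", 4.5)
        truth_anti = sorted(
            g for g, k in refs.gene_truth.items() if k == "single_antisense"
        )
        truth_sense = sorted(
            g for g, k in refs.gene_truth.items() if k == "single_sense"
        )
        assert antisense == truth_anti and sense == truth_sense

    def test_zero_mutation_copies_match_consensus(self):
        p = SimRefParams(genome_mutation_rate=0.0)
        refs = make_synthetic_references(9, p)
        cons = {c.id: c.seq for c in refs.alu_consensi}
        for rep in refs.repeats:
            embedded = refs.genome.seq[rep.start : rep.end]
            if rep.strand == "-":
                embedded = revcomp(embedded)
            assert embedded == cons[rep.subfamily]

    def test_small_rna_sets_share_no_19mer_with_alu(self, refs):
        alu19 = set()
        for c in refs.alu_consensi:
            for s in (c.seq, revcomp(c.seq)):
                alu19 |= {s[i : i + 19] for i in range(len(s) - 18)}
        for cat in ("rRNA", "tRNA", "miRNA", "snoRNA", "transcript"):
            for seq in refs.reference_set(cat).sequences:
                kmers = {seq.seq[i : i + 19] for i in range(len(seq.seq) - 18)}
                assert kmers.isdisjoint(alu19)

    def test_cross_contamination_plants_shared_21mer(self):
        refs = make_synthetic_references(9, SimRefParams(cross_contaminate=True))
        shared = refs.alu_consensi[0].seq[100:121]
        assert shared in refs.reference_set("rRNA").sequences[0].seq


class TestSimulateDicerProducts:
    @pytest.fixture()
    def hairpin(self, refs):
        return make_hairpin(
            "hp", refs.alu_consensi[0], refs.alu_consensi[1], loop_len=70, seed=1
        )

    def test_fragments_map_back_with_zero_mismatches(self, hairpin, refs):
        from alusirna import NamedSequence

        ref = NamedSequence("hp", hairpin.full_seq)
        frags = simulate_dicer_products(hairpin, 200, seed=2)
        for seq, strand, start in frags:
            hits = align_ungapped(seq, ref, 0)
            assert any(h.strand == strand and h.start == start for h in hits)
            assert 21 <= len(seq) <= 24

    def test_fragments_confined_to_arms(self, hairpin):
        (l0, l1), (r0, r1) = hairpin.arms
        for seq, _, start in simulate_dicer_products(hairpin, 500, seed=3):
            end = start + len(seq)
            assert (l0 <= start and end <= l1) or (r0 <= start and end <= r1)

    def test_zero_fragments(self, hairpin):
        assert simulate_dicer_products(hairpin, 0, seed=4) == []

    def test_pure_plus_strand_ratio_gives_no_minus_coverage(self):
        # Unrelated arms so placements are unambiguous (sibling-subfamily
        # arms can cross-map between stems).
        from alusirna import NamedSequence, SmallRead

        rng = np.random.default_rng(6)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        left = NamedSequence("L", rng.choice(bases, size=300).tobytes().decode())
        right = NamedSequence("R", rng.choice(bases, size=300).tobytes().decode())
        hairpin = make_hairpin("hp2", left, right, loop_len=70, seed=6)
        frags = simulate_dicer_products(hairpin, 300, seed=5, minus_fraction=0.0)
        reads = [
            SmallRead(f"d{i}", DICING_ADAPTOR_5P + seq + DICING_ADAPTOR_3P)
            for i, (seq, _, _) in enumerate(frags)
        ]
        cov = map_dicing_products(reads, hairpin)
        assert cov.minus.sum() == 0 and cov.n_mapped == 300

    def test_short_arm_rejected(self, refs):
        from alusirna import NamedSequence

        tiny = NamedSequence("t", "ACGT" * 5)
        hp = make_hairpin("h", tiny, tiny, loop_len=30, seed=1)
        with pytest.raises(ValueError):
            simulate_dicer_products(hp, 10, seed=1)


class TestSimulateLibrary:
    def test_same_config_is_byte_identical(self, refs):
        cfg = SimConfig(seed=21, n_reads=300)
        r1, t1 = simulate_library(cfg, refs)
        r2, t2 = simulate_library(cfg, refs)
        assert [(a.id, a.seq) for a in r1] == [(b.id, b.seq) for b in r2]
        assert t1.per_read.equals(t2.per_read)

    def test_truth_covers_every_read_once(self, refs):
        reads, truth = simulate_library(SimConfig(seed=22, n_reads=500), refs)
        assert list(truth.per_read["read_id"]) == [r.id for r in reads]
        assert sum(truth.class_counts.values()) == len(reads)

    def test_adaptor_appended_to_every_read(self, refs):
        cfg = SimConfig(seed=23, n_reads=200)
        reads, truth = simulate_library(cfg, refs)
        for read, ins_len in zip(reads, truth.per_read["insert_len"]):
            expected_adaptor = cfg.adaptor[: cfg.machine_read_len - ins_len]
            assert read.seq[ins_len:] == expected_adaptor

    def test_class_counts_concentrate_around_mix(self, refs):
        n = 20_000
        cfg = SimConfig(seed=24, n_reads=n)
        _, truth = simulate_library(cfg, refs)
        for cls, p in zip(SIM_CLASSES, cfg.probabilities()):
            se = np.sqrt(n * p * (1 - p))
            assert abs(truth.class_counts[cls] - n * p) <= 4 * se + 1

    def test_background_only_mix_is_mostly_unassigned(self, refs):
        mix = {c: 0.0 for c in SIM_CLASSES}
        mix["random_background"] = 1.0
        cfg = SimConfig(seed=25, n_reads=2000, class_mix=mix)
        reads, _ = simulate_library(cfg, refs)
        passed, _ = preprocess_reads(reads, cfg.adaptor)
        summary = run_cascade(passed, refs.ref_sets)
        off_target = summary.total_input - summary.counts["unaligned"] - summary.counts["genome"]
        assert off_target / summary.total_input <= 0.01

    def test_cascade_recovers_true_labels(self, refs):
        cfg = SimConfig(seed=26, n_reads=20_000)
        reads, truth = simulate_library(cfg, refs)
        passed, _ = preprocess_reads(reads, cfg.adaptor)
        summary = run_cascade(passed, refs.ref_sets)
        expected = {
            "miRNA": "miRNA",
            "rRNA_frag": "rRNA",
            "tRNA_frag": "tRNA",
            "alu_sirna_sense": "repeat",
            "alu_sirna_antisense": "repeat",
        }
        truth_by_id = dict(
            zip(truth.per_read["read_id"], truth.per_read["true_class"])
        )
        agree = total = 0
        for a in summary.assignments:
            cls = truth_by_id[a.read_id]
            if cls == "random_background":
                continue
            total += a.mult
            if a.category == expected[cls]:
                agree += a.mult
        assert agree == total  # error-free inserts: exact recovery
        # Alu strand truth carried through to the hits.
        strand_truth = dict(zip(truth.per_read["read_id"], truth.per_read["strand"]))
        for a in summary.assignments:
            if truth_by_id[a.read_id].startswith("alu_sirna"):
                assert a.hit.strand == strand_truth[a.read_id]

    def test_sequencing_errors_still_recovered_within_tolerance(self, refs):
        # At 1% per-base error, even a 35 nt insert stays within the
        # 2-mismatch budget >99% of the time, so sourced reads recover
        # their true category at >=99% overall.
        cfg = SimConfig(seed=27, n_reads=5000, mutation_rate=0.01)
        reads, truth = simulate_library(cfg, refs)
        passed, _ = preprocess_reads(reads, cfg.adaptor)
        summary = run_cascade(passed, refs.ref_sets)
        expected = {
            "miRNA": "miRNA",
            "rRNA_frag": "rRNA",
            "tRNA_frag": "tRNA",
            "alu_sirna_sense": "repeat",
            "alu_sirna_antisense": "repeat",
            "random_background": None,
        }
        truth_by_id = dict(
            zip(truth.per_read["read_id"], truth.per_read["true_class"])
        )
        agree = total = 0
        for a in summary.assignments:
            want = expected[truth_by_id[a.read_id]]
            if want is None:
                continue
            total += a.mult
            agree += a.mult * (a.category == want)
        assert agree / total >= 0.99


class TestKnockdownThinning:
    def test_non_alu_reads_identical_and_alu_thinned(self, refs):
        cfg = SimConfig(seed=28, n_reads=30_000)
        reads, truth = simulate_library(cfg, refs)
        treated, t_truth = apply_alu_knockdown(reads, truth, 0.5, seed=28)
        n_alu = sum(
            v for k, v in truth.class_counts.items() if k.startswith("alu_sirna")
        )
        n_alu_t = sum(
            v for k, v in t_truth.class_counts.items() if k.startswith("alu_sirna")
        )
        assert n_alu_t < n_alu
        non_alu = {
            r.id for r in reads
        } - set(truth.per_read.loc[
            truth.per_read["true_class"].str.startswith("alu_sirna"), "read_id"
        ])
        assert non_alu == {
            r.id
            for r in treated
            if not t_truth.per_read.set_index("read_id")["true_class"][r.id].startswith("alu")
        }

    def test_scale_one_is_identity(self, refs):
        cfg = SimConfig(seed=29, n_reads=2000)
        reads, truth = simulate_library(cfg, refs)
        treated, _ = apply_alu_knockdown(reads, truth, 1.0, seed=29)
        assert [r.id for r in treated] == [r.id for r in reads]


class TestSimConfigValidation:
    def test_mix_must_sum_to_one(self):
        mix = {c: 0.0 for c in SIM_CLASSES}
        mix["miRNA"] = 0.5
        with pytest.raises(ValueError):
            SimConfig(seed=1, class_mix=mix)

    def test_alu_scale_reweights_probabilities(self):
        cfg = SimConfig(seed=1, alu_scale=0.5)
        p = cfg.probabilities()
        base = SimConfig(seed=1).probabilities()
        i = SIM_CLASSES.index("alu_sirna_sense")
        assert p[i] < base[i]
        assert p.sum() == pytest.approx(1.0)
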