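import numpy as np
import pytest
from scipy import stats

from placeprof.formats import parse_newick_numbered
from placeprof.place import build_model
from placeprof.recruit import translate
from placeprof.refpkg import ModelSpec
from placeprof.synth import (
    CommunitySpec,
    GeneContent,
    GenomeSpec,
    ReadSimParams,
    generate_metagenome_reads,
    make_benchmark_scenario,
    reverse_translate,
    simulate_alignment_on_tree,
    synth_refpkg,
)


@pytest.fixture(scope="module")
def model():
    return build_model(ModelSpec(alpha=1.0, k=4))


class TestSimulateAlignment:
    def test_zero_branch_lengths_copy_root_everywhere(self, model):
        t = parse_newick_numbered("((A:0.0,B:0.0):0.0,C:0.0);")
        leaves = simulate_alignment_on_tree(t, model, 50, seed=3)
        assert leaves["A"] == leaves["B"] == leaves["C"]

    def test_same_seed_reproduces_leaves(self, model):
        t = parse_newick_numbered("((A:0.2,B:0.1):0.1,C:0.3);")
        a = simulate_alignment_on_tree(t, model, 80, seed=5)
        b = simulate_alignment_on_tree(t, model, 80, seed=5)
        assert a == b
        c = simulate_alignment_on_tree(t, model, 80, seed=6)
        assert a != c

    def test_long_branch_composition_approaches_stationary(self, model):
        t = parse_newick_numbered("(A:10000.0,B:10000.0);")
        leaves = simulate_alignment_on_tree(t, model, 10000, seed=7)
        from placeprof.matrices import AA_ORDER

        counts = np.array([leaves["A"].count(a) for a in AA_ORDER])
        # chi-square goodness of fit against the stationary distribution
        chi2 = ((counts - 10000 * model.pi) ** 2 / (10000 * model.pi)).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=19)


class TestReverseTranslate:
    def test_met_codon_unique(self):
        assert reverse_translate("MA", seed=1)[:3] == "ATG"

    def test_round_trip_translation(self):
        rng = np.random.default_rng(8)
        from placeprof.matrices import AA_ORDER

        for _ in range(10):
            aa = "".join(rng.choice(list(AA_ORDER), 30))
            assert translate(reverse_translate(aa, seed=int(rng.integers(100)))) == aa

    def test_fixed_seed_fixed_codons(self):
        assert reverse_translate("MKVLW", seed=4) == reverse_translate(
            "MKVLW", seed=4
        )


def _community(refpkgs, carrier_copies=2):
    gene_rp = refpkgs["nirK"]
    leaf = sorted(gene_rp.ingroup_ids)[0]
    rpob_leaf = sorted(refpkgs["rpoB"].ingroup_ids)[0]
    return CommunitySpec(
        [
            GenomeSpec(
                "g0",
                1.0,
                [
                    GeneContent("rpoB", rpob_leaf, 1),
                    GeneContent("nirK", leaf, carrier_copies),
                ],
            )
        ]
    )


@pytest.fixture(scope="module")
def refpkgs():
    return {"rpoB": synth_refpkg("rpoB", 21), "nirK": synth_refpkg("nirK", 22)}


class TestGenerateReads:
    def test_copy_number_doubles_expected_gene_reads(self, refpkgs):
        spec = _community(refpkgs, carrier_copies=2)
        params = ReadSimParams(n_pairs=1500, seed=9)
        _r1, _r2, truth = generate_metagenome_reads(spec, refpkgs, params)
        n_gene = int((truth["gene"] == "nirK").sum())
        # genes have equal length so gene pairs ~ Binomial(n, 2/3)
        lo, hi = stats.binom.interval(0.95, 1500, 2.0 / 3.0)
        assert lo <= n_gene <= hi

    def test_zero_error_reads_are_substrings_of_source(self, refpkgs):
        spec = _community(refpkgs, carrier_copies=1)
        params = ReadSimParams(n_pairs=40, seed=10, error_rate=0.0)
        from placeprof.synth import realize_gene_sequences
        from placeprof.recruit import reverse_complement

        seqs = realize_gene_sequences(spec, refpkgs, seed=10)
        r1, r2, truth = generate_metagenome_reads(
            spec, refpkgs, params, gene_sequences=seqs
        )
        for rec1, rec2, (_, row) in zip(r1, r2, truth.iterrows()):
            dna = seqs[(row["genome"], row["gene"])]
            assert rec1.seq in dna
            assert reverse_complement(rec2.seq) in dna

    def test_fixed_seed_gives_identical_fastq_bytes(self, refpkgs, tmp_path):
        from placeprof.formats import write_fastq

        spec = _community(refpkgs)
        params = ReadSimParams(n_pairs=30, seed=11)
        out = []
        for name in ("a", "b"):
            r1, _r2, _t = generate_metagenome_reads(spec, refpkgs, params)
            p = tmp_path / f"{name}.fastq"
            write_fastq(r1, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_truth_table_conserves_every_pair(self, refpkgs):
        spec = _community(refpkgs)
        params = ReadSimParams(n_pairs=25, seed=12)
        r1, r2, truth = generate_metagenome_reads(spec, refpkgs, params)
        assert len(truth) == 25
        assert truth["read_id"].is_unique
        assert [r.id for r in r1] == truth["read_id"].tolist()
        assert [r.id for r in r2] == truth["read_id"].tolist()

    def test_rpob_missing_rejected(self, refpkgs):
        spec = CommunitySpec(
            [GenomeSpec("g0", 1.0, [GeneContent("nirK", "x", 1)])]
        )
        with pytest.raises(ValueError, match="rpoB"):
            generate_metagenome_reads(spec, refpkgs, ReadSimParams(n_pairs=5))

    def test_abundances_must_sum_to_one(self, refpkgs):
        leaf = sorted(refpkgs["rpoB"].ingroup_ids)[0]
        spec = CommunitySpec(
            [GenomeSpec("g0", 0.7, [GeneContent("rpoB", leaf, 1)])]
        )
        with pytest.raises(ValueError, match="sum"):
            generate_metagenome_reads(spec, refpkgs, ReadSimParams(n_pairs=5))


class TestScenarios:
    def test_basic_truth_fraction(self, basic_scenario):
        assert basic_scenario.truth_percent["nirK"] == 20.0
        _meta, spec = basic_scenario.samples[0]
        carriers = [
            g for g in spec.genomes if any(gc.gene == "nirK" for gc in g.genes)
        ]
        assert len(carriers) == 4 and len(spec.genomes) == 20

    def test_multicopy_uncorrected_is_twice_corrected(self):
        sc = make_benchmark_scenario("multicopy", seed=3, n_pairs=10)
        assert sc.copy_numbers[("narG", "SAR11")] == 2.0
        _meta, spec = sc.samples[0]
        for g in spec.genomes:
            for gc in g.genes:
                if gc.gene == "narG":
                    assert gc.copies == 2

    def test_outgroup_stress_marks_contaminants(self):
        sc = make_benchmark_scenario("outgroup_stress", seed=3, n_pairs=400)
        meta, spec = sc.samples[0]
        r1, _r2, truth = generate_metagenome_reads(
            spec, sc.refpkgs, sc.params, meta.sample_id
        )
        og = truth[truth["is_outgroup"]]
        assert len(og) > 0
        assert (og["clade"] == "outgroup").all()
        gene_reads = truth[truth["gene"] == "narG"]
        frac = len(og) / len(gene_reads)
        assert 0.03 < frac < 0.25  # targets 10%

    def test_particle_scenario_enriches_clade_two(self):
        sc = make_benchmark_scenario("particle_vs_free", seed=3)
        (meta_p, spec_p), (meta_f, spec_f) = sc.samples
        assert meta_p.fraction == "particle_gt30um"
        ab_p = {g.genome_id: g.abundance for g in spec_p.genomes}
        ab_f = {g.genome_id: g.abundance for g in spec_f.genomes}
        # 5x relative weight, diluted by renormalization over the community
        assert ab_p["g02"] / ab_f["g02"] > 2.5
        assert ab_p["g05"] < ab_f["g05"]

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            make_benchmark_scenario("nope")

    def test_depth_profile_has_six_depths(self):
        sc = make_benchmark_scenario("depth_profile", seed=3)
        depths = [m.depth for m, _s in sc.samples]
        assert depths == sorted(depths) and len(depths) == 6
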