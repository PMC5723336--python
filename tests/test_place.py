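import math

import numpy as np
import pytest

from oracles import enumeration_site_likelihood, gamma_rates_quadrature
from placeprof.formats import SeqRecord, parse_newick_numbered
from placeprof.matrices import AA_INDEX, encode_aa
from placeprof.place import (
    AlignedQuery,
    GAP_CODE,
    PlacementEngine,
    UNK_CODE,
    align_read_to_profile,
    build_model,
    combine_pair_in_alignment,
    discrete_gamma_rates,
    epa_place,
    substitution_probability,
    tree_log_likelihood,
)
from placeprof.recruit import RecruitedRead
from placeprof.refpkg import ModelSpec, build_refpkg


@pytest.fixture(scope="module", params=["LG", "WAG", "JTT"])
def model(request):
    return build_model(ModelSpec(request.param, alpha=0.7, k=3))


class TestModel:
    def test_rate_matrix_rows_sum_to_zero(self, model):
        assert np.abs(model.Q.sum(axis=1)).max() < 1e-12

    def test_reversibility(self, model):
        flux = model.pi[:, None] * model.Q
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_unit_expected_substitution_rate(self, model):
        assert -np.dot(model.pi, np.diag(model.Q)) == pytest.approx(1.0)

    def test_large_alpha_collapses_rate_variation(self):
        # gamma sd is 1/sqrt(alpha), so category means approach 1 as
        # alpha grows (at 1e7, all four means are within 1e-3 of 1)
        m = build_model(ModelSpec(alpha=1e7, k=4))
        assert np.abs(m.rates - 1.0).max() < 1e-3

    def test_single_category_is_rate_one(self):
        m = build_model(ModelSpec(k=1))
        assert m.rates.tolist() == [1.0]

    def test_unknown_matrix_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_model(ModelSpec(matrix="NOPE"))

    def test_empirical_frequencies_follow_alignment(self):
        aln = [SeqRecord("a", "AAAA"), SeqRecord("b", "AAAR")]
        m = build_model(ModelSpec(frequencies="empirical"), aln)
        assert m.pi[AA_INDEX["A"]] > 0.2
        assert abs(m.pi.sum() - 1) < 1e-12


class TestTransitionProbability:
    def test_zero_time_is_identity(self, model):
        P = substitution_probability(model, 0.0, 0)
        assert np.abs(P - np.eye(20)).max() < 1e-12

    def test_rows_sum_to_one(self, model):
        for t in (0.01, 0.5, 3.0):
            P = substitution_probability(model, t, 1)
            assert np.abs(P.sum(axis=1) - 1).max() < 1e-10

    def test_small_time_series_expansion(self, model):
        t = 1e-6
        r = float(model.rates[0])
        P = substitution_probability(model, t, 0)
        approx = np.eye(20) + model.Q * r * t
        assert np.abs(P - approx).max() < 10 * t * t

    def test_long_time_reaches_stationarity(self, model):
        P = substitution_probability(model, 1e4, 0)
        assert np.abs(P - model.pi[None, :]).max() < 1e-6

    def test_stationary_distribution_fixed_point(self, model):
        P = substitution_probability(model, 0.7, 2)
        assert np.abs(model.pi @ P - model.pi).max() < 1e-12

    def test_negative_time_rejected(self, model):
        with pytest.raises(ValueError):
            model.transition(-0.1)


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha,k", [(0.2, 4), (0.5, 4), (1.0, 8), (5.0, 2)])
    def test_mean_rate_is_one(self, alpha, k):
        r = discrete_gamma_rates(alpha, k)
        assert abs(r.mean() - 1.0) < 1e-8

    def test_matches_quadrature_oracle(self):
        r = discrete_gamma_rates(0.5, 4)
        oracle = gamma_rates_quadrature(0.5, 4)
        assert np.abs(r - oracle).max() < 1e-4
        assert np.all(np.diff(r) > 0)

    def test_single_category(self):
        assert discrete_gamma_rates(2.3, 1).tolist() == [1.0]


class TestTreeLogLikelihood:
    def test_zero_branch_two_leaf_identity(self):
        m = build_model(ModelSpec(k=1))
        t = parse_newick_numbered("(A:0.0,B:0.0);")
        ll = tree_log_likelihood(t, m, {"A": "A", "B": "A"})
        assert ll == pytest.approx(math.log(m.pi[AA_INDEX["A"]]), rel=1e-12)

    def test_matches_enumeration_oracle_three_leaves(self):
        m = build_model(ModelSpec(alpha=0.7, k=3))
        t = parse_newick_numbered("((A:0.12,B:0.3):0.07,C:0.25);")
        rows = {"A": "MK", "B": "MR", "C": "AK"}
        # node ids: A=0,B=1,AB=2,C=3,root=4
        parent = {0: 2, 1: 2, 2: 4, 3: 4}
        lengths = {v: float(t.lengths[v]) for v in parent}
        children = {2: [0, 1], 4: [2, 3], 0: [], 1: [], 3: []}
        expected = 0.0
        for s in range(2):
            leaf_states = {
                0: AA_INDEX[rows["A"][s]],
                1: AA_INDEX[rows["B"][s]],
                3: AA_INDEX[rows["C"][s]],
            }
            expected += math.log(
                enumeration_site_likelihood(parent, lengths, children, 4,
                                            leaf_states, m)
            )
        got = tree_log_likelihood(t, m, rows)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_gaps_are_missing_data(self):
        m = build_model(ModelSpec(k=2))
        t = parse_newick_numbered("((A:0.1,B:0.2):0.05,C:0.3);")
        full = tree_log_likelihood(t, m, {"A": "M", "B": "-", "C": "M"})
        reduced = tree_log_likelihood(
            parse_newick_numbered("(A:0.15,C:0.3);"), m, {"A": "M", "C": "M"}
        )
        assert full == pytest.approx(reduced, rel=1e-10)

    def test_rerooting_invariance(self):
        m = build_model(ModelSpec(alpha=0.9, k=4))
        rows = {"A": "MKVL", "B": "MRVI", "C": "AKVL"}
        t1 = parse_newick_numbered("((A:0.12,B:0.3):0.07,C:0.25);")
        t2 = parse_newick_numbered("((B:0.3,C:0.32):0.06,A:0.06);")
        l1 = tree_log_likelihood(t1, m, rows)
        l2 = tree_log_likelihood(t2, m, rows)
        assert l1 == pytest.approx(l2, rel=1e-8)

    def test_missing_leaf_row_rejected(self):
        m = build_model(ModelSpec(k=1))
        t = parse_newick_numbered("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="no sequence row"):
            tree_log_likelihood(t, m, {"A": "M"})


def _recruited(aa, read_id="r", mate="1"):
    return RecruitedRead(read_id, mate, 1, aa, (0, 3 * len(aa)), 100.0,
                         1e-30, "ref")


class TestProfileAlignment:
    def test_reference_slice_aligns_to_its_columns(self, four_taxon_refpkg):
        row = four_taxon_refpkg.row("A")
        q = align_read_to_profile(_recruited(row[5:35]), four_taxon_refpkg)
        covered = np.nonzero(q.coverage_mask)[0]
        assert covered.tolist() == list(range(5, 35))
        assert "".join(
            "ARNDCQEGHILKMFPSTWYV"[c] for c in q.codes[5:35]
        ) == row[5:35]

    def test_all_x_read_aligned_but_uninformative(self, four_taxon_refpkg):
        q = align_read_to_profile(_recruited("X" * 35), four_taxon_refpkg)
        assert q.n_informative == 0

    def test_deletion_relative_to_reference_leaves_gap_column(
        self, four_taxon_refpkg
    ):
        row = four_taxon_refpkg.row("A")
        deleted = row[5:20] + row[21:36]  # drop column 20
        q = align_read_to_profile(_recruited(deleted), four_taxon_refpkg)
        covered = set(np.nonzero(q.coverage_mask)[0].tolist())
        assert 20 not in covered
        assert covered == set(range(5, 36)) - {20}


class TestCombinePair:
    def _q(self, codes):
        return AlignedQuery("r/1", np.asarray(codes, dtype=np.int64))

    def test_disjoint_coverage_unions(self):
        a = self._q([0, 1, GAP_CODE, GAP_CODE])
        b = AlignedQuery("r/2", np.array([GAP_CODE, GAP_CODE, 2, 3]))
        c = combine_pair_in_alignment(a, b)
        assert c.codes.tolist() == [0, 1, 2, 3]
        assert c.query_id == "r"

    def test_agreement_kept_disagreement_masked(self):
        a = self._q([0, 1, 2])
        b = AlignedQuery("r/2", np.array([0, 5, GAP_CODE]))
        c = combine_pair_in_alignment(a, b)
        assert c.codes.tolist() == [0, UNK_CODE, 2]

    def test_column_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_pair_in_alignment(
                self._q([0, 1]), AlignedQuery("r/2", np.array([0, 1, 2]))
            )


class TestPlacement:
    def test_leaf_identical_query_places_on_its_pendant_edge(
        self, four_taxon_refpkg
    ):
        rp = four_taxon_refpkg
        q = AlignedQuery("q", encode_aa(rp.row("A")))
        engine = PlacementEngine(rp, min_aa=10)
        pl = engine.place(q)
        assert pl.best_edge == rp.tree.pendant_edge("A")
        assert pl.best_pendant <= 1e-3

    def test_lwr_sums_to_one_and_rows_sorted(self, four_taxon_refpkg):
        rp = four_taxon_refpkg
        q = AlignedQuery("q", encode_aa(rp.row("C")))
        pl = PlacementEngine(rp, min_aa=10).place(q)
        lwrs = [r[2] for r in pl.rows]
        assert abs(sum(lwrs) - 1.0) < 1e-6
        assert lwrs == sorted(lwrs, reverse=True)
        assert all(1e-8 <= r[3] <= 2.0 for r in pl.rows)

    def test_symmetric_query_splits_lwr_equally(self):
        # A and B identical except one site; query covers only shared sites
        base = "MKVLAEQWRTYHDS" * 3
        aln = [
            SeqRecord("A", base),
            SeqRecord("B", base[:-1] + "G"),
            SeqRecord("C", "".join(reversed(base))),
            SeqRecord("D", base[::2] + base[::2]),
        ]
        tree = parse_newick_numbered("((A:0.2,B:0.2):0.1,(C:0.25,D:0.2):0.1);")
        rp = build_refpkg("sym", aln, tree, {}, set(), ModelSpec(k=2))
        codes = encode_aa(base)
        codes[-1] = GAP_CODE  # exclude the A/B-discriminating site
        pl = PlacementEngine(rp, min_aa=10).place(AlignedQuery("q", codes))
        lwr = {r[0]: r[2] for r in pl.rows}
        ea, eb = rp.tree.pendant_edge("A"), rp.tree.pendant_edge("B")
        assert lwr[ea] == pytest.approx(lwr[eb], abs=1e-6)

    def test_deterministic_output(self, four_taxon_refpkg):
        rp = four_taxon_refpkg
        codes = encode_aa(rp.row("B"))
        p1 = epa_place(AlignedQuery("q", codes.copy()), rp)
        p2 = epa_place(AlignedQuery("q", codes.copy()), rp)
        assert p1.rows == p2.rows

    def test_short_query_refused(self, four_taxon_refpkg):
        codes = np.full(40, GAP_CODE, dtype=np.int64)
        codes[:5] = encode_aa(four_taxon_refpkg.row("A")[:5])
        q = AlignedQuery("q", codes)
        with pytest.raises(ValueError, match="covers"):
            PlacementEngine(four_taxon_refpkg, min_aa=33).place(q)

    def test_more_consistent_columns_keep_best_edge(self, four_taxon_refpkg):
        rp = four_taxon_refpkg
        engine = PlacementEngine(rp, min_aa=10)
        codes = np.full(40, GAP_CODE, dtype=np.int64)
        full = encode_aa(rp.row("A"))
        codes[:20] = full[:20]
        e1 = engine.place(AlignedQuery("q", codes.copy())).best_edge
        codes[20:] = full[20:]
        e2 = engine.place(AlignedQuery("q", codes)).best_edge
        assert e1 == rp.tree.pendant_edge("A")
        assert e2 == rp.tree.pendant_edge("A")
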