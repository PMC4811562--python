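"""Design construction: pair coding, D-error, Fedorov exchange, blocking."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import choicemix as cm
from choicemix.attributes import AttributeError_
from choicemix.design import (DesignError, _block_criterion, _orient_rows,
                              profile_model_matrix)


def two_binary_attrs():
    return [
        cm.AttributeSpec("a", "categorical", ("lo", "hi"), reference_level="lo"),
        cm.AttributeSpec("b", "continuous", (0, 1)),
    ]


class TestCodeChoicePair:
    def test_identical_profiles_give_zero_vector(self, attrs):
        p = {"access": "allowed", "cattle": 40, "cons": "half",
             "cult": "5acres", "smlstk": 80, "wage": 0}
        delta = cm.code_choice_pair(cm.ChoicePair(p, dict(p)), attrs)
        assert np.all(delta == 0)

    def test_printed_example_card(self, attrs, table1_pair):
        # apply the documented coding (scales 100 / 200 / 10,000) to the
        # printed example: expect access 0, cattle -0.6, cons150 -1,
        # cons75 +1, cult +1, smlstk 0, wage 0
        delta = cm.code_choice_pair(table1_pair, attrs)
        expected = {"access": 0.0, "cattle": -0.6, "cons150": -1.0,
                    "cons75": 1.0, "cult": 1.0, "smlstk": 0.0, "wage": 0.0}
        cols = cm.coded_columns(attrs)
        assert cols == list(expected)
        np.testing.assert_allclose(delta, [expected[c] for c in cols])

    def test_swap_negates(self, attrs, candidates):
        rng = np.random.default_rng(0)
        for k in rng.choice(len(candidates), 25, replace=False):
            pair = candidates[int(k)]
            d1 = cm.code_choice_pair(pair, attrs)
            d2 = cm.code_choice_pair(pair.swapped(), attrs)
            np.testing.assert_allclose(d1, -d2)

    def test_unknown_attribute_names_offender(self, attrs):
        bad = {"access": "allowed", "cattle": 40, "cons": "half",
               "cult": "none", "smlstk": 80, "wage": 0, "bogus": 1}
        with pytest.raises(AttributeError_, match="bogus"):
            cm.code_choice_pair(cm.ChoicePair(bad, bad), attrs)

    def test_illegal_level_names_attribute(self, attrs):
        bad = {"access": "allowed", "cattle": 55, "cons": "half",
               "cult": "none", "smlstk": 80, "wage": 0}
        with pytest.raises(AttributeError_, match="cattle"):
            cm.code_choice_pair(cm.ChoicePair(bad, bad), attrs)


class TestCandidateSet:
    def test_standard_experiment_counts(self, candidates):
        assert candidates.n_profiles == 2 * 3 * 3 * 2 * 3 * 3 == 324
        assert len(candidates) == 324 * 323 // 2 == 52326

    def test_two_binary_attributes(self):
        cands = cm.build_candidate_set(two_binary_attrs())
        assert cands.n_profiles == 4
        assert len(cands) == 6

    def test_no_self_pairs(self, candidates):
        rng = np.random.default_rng(1)
        for k in rng.choice(len(candidates), 50, replace=False):
            pair = candidates[int(k)]
            assert pair.option1 != pair.option2
            assert np.any(pair.delta != 0)

    def test_single_level_attribute_rejected(self):
        with pytest.raises(AttributeError_):
            cm.AttributeSpec("x", "continuous", (1,))


class TestDError:
    def test_orthonormal_rows(self):
        X = np.vstack([np.eye(3)] * 3)  # X'X/9 = I/3 -> det 1/27, ^(-1/3) = 3
        assert cm.d_error(np.sqrt(3) * X) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        X = np.array([[1, 0], [0, 1], [1, 1], [1, -1]], dtype=float)
        assert cm.d_error(X) == pytest.approx(4 / 3)

    def test_singular_gives_infinity(self):
        X = np.ones((4, 2))
        assert cm.d_error(X) == math.inf

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_permutation_and_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        base = cm.d_error(X)
        perm = rng.permutation(8)
        signs = rng.choice([-1.0, 1.0], size=(8, 1))
        assert cm.d_error(signs * X[perm]) == pytest.approx(base, rel=1e-9)


class TestFedorovSelect:
    def test_matches_exhaustive_on_tiny_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(5):
            C = rng.normal(size=(8, 2))
            best = min(cm.d_error(C[list(combo)])
                       for combo in itertools.combinations(range(8), 4))
            des = cm.federov_select(C, 4, restarts=30, seed=trial)
            assert des.d_error == pytest.approx(best, rel=1e-12)

    def test_exchange_matches_exhaustive_beyond_cutoff(self):
        # 18 choose 5 = 8568 subsets: exercised by the exchange, not the
        # exact path; must still find the exhaustive optimum
        rng = np.random.default_rng(4)
        C = rng.normal(size=(18, 3))
        best = min(cm.d_error(C[list(combo)])
                   for combo in itertools.combinations(range(18), 5))
        des = cm.federov_select(C, 5, restarts=60, seed=0)
        assert des.d_error == pytest.approx(best, rel=1e-12)

    def test_output_size_and_distinctness(self, candidates):
        des = cm.federov_select(candidates, 16, restarts=3, seed=0)
        assert des.n_runs == 16
        idx = des.meta["indices"]
        assert len(set(idx)) == 16

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(5)
        C = rng.normal(size=(120, 4))
        d1 = cm.federov_select(C, 8, restarts=2, seed=9).d_error
        d2 = cm.federov_select(C, 8, restarts=10, seed=9).d_error
        assert d2 <= d1 + 1e-12

    def test_reproducible(self, candidates):
        a = cm.federov_select(candidates, 16, restarts=2, seed=11)
        b = cm.federov_select(candidates, 16, restarts=2, seed=11)
        assert a.meta["indices"] == b.meta["indices"]

    def test_infeasible_sizes_error(self):
        C = np.eye(3)
        with pytest.raises(DesignError):
            cm.federov_select(C, 5, seed=0)       # more runs than candidates
        with pytest.raises(DesignError):
            cm.federov_select(C, 2, seed=0)       # fewer runs than columns

    def test_beats_random_subsets(self, candidates, design):
        rng = np.random.default_rng(6)
        random_best = min(
            cm.d_error(candidates.deltas[rng.choice(len(candidates), 16,
                                                    replace=False)])
            for _ in range(1000))
        assert design.d_error <= random_best

    def test_intercept_estimable_after_orientation(self, design):
        A = np.column_stack([np.ones(design.n_runs), design.X])
        assert np.linalg.matrix_rank(A) == A.shape[1]

    def test_orientation_preserves_d_error(self, candidates):
        des = cm.federov_select(candidates, 16, restarts=3, seed=2)
        assert cm.d_error(des.X) == pytest.approx(des.d_error, rel=1e-12)
        signs = _orient_rows(des.X)
        assert np.all(np.abs(signs) == 1)


class TestBlockDesign:
    def test_paper_shape_two_blocks_of_eight(self, design):
        members = design.block_members()
        assert sorted(members) == [1, 2]
        assert all(len(v) == 8 for v in members.values())

    def test_toy_matches_exhaustive_partitions(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 2))
        des = cm.ChoiceDesign(attrs=[], pairs=[None] * 4, X=X,
                              d_error=cm.d_error(X))
        blocked = cm.block_design(des, 2, seed=0)
        # brute force over the 3 distinct partitions into two pairs
        parts = [([0, 1], [2, 3]), ([0, 2], [1, 3]), ([0, 3], [1, 2])]
        best = -math.inf
        for b1, b2 in parts:
            assign = np.empty(4, dtype=int)
            assign[b1], assign[b2] = 0, 1
            best = max(best, _block_criterion(X, assign, 2))
        assert blocked.meta["block_criterion"] == pytest.approx(best, rel=1e-12)

    def test_blocking_keeps_pairs_and_d_error(self, candidates):
        des = cm.federov_select(candidates, 16, restarts=2, seed=3)
        blocked = cm.block_design(des, 2, seed=1)
        assert blocked.meta["indices"] == des.meta["indices"]
        assert blocked.d_error == des.d_error
        np.testing.assert_array_equal(blocked.X, des.X)

    def test_unequal_block_sizes(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(5, 2))
        des = cm.ChoiceDesign(attrs=[], pairs=[None] * 5, X=X,
                              d_error=cm.d_error(X))
        blocked = cm.block_design(des, 2, block_sizes=[2, 3], seed=0)
        sizes = np.bincount(blocked.blocks)[1:]
        assert sorted(sizes.tolist()) == [2, 3]

    def test_too_many_blocks_error(self, design):
        with pytest.raises(DesignError):
            cm.block_design(design, 17)


class TestReferenceCriterion:
    def test_profile_matrix_shape(self, attrs):
        F = profile_model_matrix(attrs)
        assert F.shape == (324, 11)     # intercept + sum(levels - 1)
        assert np.all(F[:, 0] == 1)

    def test_search_is_reproducible(self, attrs):
        a = cm.reference_profile_criterion(attrs, restarts=5, seed=1)
        b = cm.reference_profile_criterion(attrs, restarts=5, seed=1)
        assert a["D"] == b["D"]
        assert 0 < a["D"] < 1


class TestAttributeConfig:
    def test_yaml_roundtrip_preserves_coding(self, attrs, tmp_path):
        from choicemix.attributes import dump_attributes
        path = tmp_path / "attrs.yaml"
        dump_attributes(attrs, path)
        back = cm.load_attributes(path)
        assert cm.coded_columns(back) == cm.coded_columns(attrs)
        p = {"access": "allowed", "cattle": 100, "cons": "half",
             "cult": "none", "smlstk": 200, "wage": 6000}
        q = {"access": "prohibited", "cattle": 0, "cons": "full",
             "cult": "5acres", "smlstk": 0, "wage": 0}
        np.testing.assert_allclose(
            cm.code_choice_pair(cm.ChoicePair(p, q), back),
            cm.code_choice_pair(cm.ChoicePair(p, q), attrs))


class TestDesignIO:
    def test_roundtrip(self, design, tmp_path):
        path = tmp_path / "design.csv"
        cm.write_design(design, path)
        back = cm.read_design(path, design.attrs)
        np.testing.assert_allclose(back.X, design.X)
        np.testing.assert_array_equal(back.blocks, design.blocks)
        assert back.d_error == pytest.approx(design.d_error)
        assert [p.option1 for p in back.pairs] == [p.option1 for p in design.pairs]
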