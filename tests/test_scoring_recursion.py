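import json

import numpy as np
import pytest

from epp.errors import ValidationError
from epp.output import tree_to_dict
from epp.scoring_recursion import (EPPConfig, analyze_pair, apply_balance,
                                   epp_recurse, score_boundary, stitch_chains)
from epp.synthetic import make_fixture
from oracles import gaussian_bump_density


class TestApplyBalance:
    def test_even_split_is_identity(self):
        assert apply_balance(10.0, 0.5) == 10.0

    def test_lopsided_split_penalized(self):
        assert apply_balance(10.0, 0.1) == pytest.approx(10.0 / 0.36)

    def test_symmetric_in_p(self):
        assert apply_balance(7.0, 0.2) == pytest.approx(apply_balance(7.0, 0.8))

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_fraction_rejected(self, p):
        with pytest.raises(ValidationError):
            apply_balance(1.0, p)


class TestScoreBoundary:
    def test_zero_density_boundary_scores_zero(self):
        d = np.zeros((129, 129))
        chain = np.column_stack([np.arange(129), np.full(129, 64)])
        assert score_boundary([chain], d, 1000, 0.01) == 0.0

    def test_linear_in_n(self):
        rng = np.random.default_rng(0)
        d = rng.random((129, 129))
        chain = np.column_stack([np.arange(129), np.full(129, 64)])
        s1 = score_boundary([chain], d, 1000, 0.01)
        s2 = score_boundary([chain], d, 2000, 0.01)
        assert s2 == pytest.approx(2 * s1)

    def test_deep_valley_beats_shallow_valley(self):
        # three bumps in a row, the left gap much wider than the right one
        d = gaussian_bump_density([(0.15, 0.5), (0.6, 0.5), (0.8, 0.5)],
                                  [0.05, 0.05, 0.05], [1, 1, 1])
        col_deep = int(round(0.375 * 128))   # between bumps 1 and 2
        col_shallow = int(round(0.7 * 128))  # between bumps 2 and 3
        rows = np.arange(129)
        deep = score_boundary(
            [np.column_stack([rows, np.full(129, col_deep)])], d, 1000, 0.01)
        shallow = score_boundary(
            [np.column_stack([rows, np.full(129, col_shallow)])], d, 1000, 0.01)
        # independent line-integral oracle on the analytic density
        xs = np.linspace(0, 1, 129)
        oracle = [1000 * 0.02 * np.trapezoid(d[:, c], xs)
                  for c in (col_deep, col_shallow)]
        assert deep == pytest.approx(oracle[0], rel=1e-9)
        assert shallow == pytest.approx(oracle[1], rel=1e-9)
        assert deep < shallow


class TestAnalyzePair:
    def test_single_blob_no_separation(self):
        ev, _ = make_fixture("one_blob", n=10_000, seed=0)
        assert analyze_pair(ev, (0, 1), EPPConfig()) is None

    def test_two_blobs_valley_candidate(self):
        ev, _ = make_fixture("two_blobs", n=10_000, seed=0)
        res = analyze_pair(ev, (0, 1), EPPConfig())
        assert res is not None
        assert res.P == pytest.approx(0.5, abs=0.05)
        assert not res.widened
        # boundary runs along the x = 0.5 valley
        cols = np.concatenate([c[:, 1] for c in res.chains])
        assert np.abs(cols.mean() / 256 - 0.5) < 0.05

    def test_many_spikes_requires_widening(self):
        ev, _ = make_fixture("many_spikes", n=20_000, seed=0)
        res = analyze_pair(ev, (0, 1), EPPConfig())
        assert res is not None
        assert res.widened and res.W > 0.01

    def test_tiny_population_returns_none(self):
        ev, _ = make_fixture("one_blob", n=8, seed=0)
        assert analyze_pair(ev, (0, 1), EPPConfig()) is None


class TestEppRecurse:
    def test_two_blobs_recovered_pure(self, two_blobs_small):
        ev, labels = two_blobs_small
        tree = epp_recurse(ev, EPPConfig())
        leaves = tree.leaves()
        assert len(leaves) == 2
        assign = tree.leaf_of_events()
        for leaf in leaves:
            comp = labels[leaf.indices]
            assert (np.bincount(comp).max() / len(comp)) >= 0.99
        # partition invariant
        assert sorted(np.concatenate([l.indices for l in leaves])) \
            == list(range(ev.n))
        assert np.bincount(assign)[1:].sum() == ev.n

    def test_single_gaussian_single_leaf(self):
        ev, _ = make_fixture("one_blob", n=10_000, seed=2)
        tree = epp_recurse(ev, EPPConfig())
        assert len(tree.leaves()) == 1
        assert tree.root.is_leaf

    def test_root_split_uses_only_separating_pair(self):
        # dims 1 and 3 are bimodal; dim 2 is N(0.5, 0.05^2) and disqualified
        ev, _ = make_fixture("pair13_only", n=10_000, seed=3)
        tree = epp_recurse(ev, EPPConfig())
        assert tree.root.dims == (0, 2)

    def test_mode_contrast_on_tiny_satellite(self):
        ev, labels = make_fixture("tiny_plus_overlap", seed=4)
        p_first = {}
        sep_tree = None
        for mode in ("best_separation", "best_balance"):
            tree = epp_recurse(ev, EPPConfig(mode=mode))
            p = tree.root.P
            p_first[mode] = min(p, 1 - p)
            if mode == "best_separation":
                sep_tree = tree
        assert p_first["best_balance"] >= p_first["best_separation"] - 1e-12
        # best separation's first split isolates the 2% satellite
        small = min((sep_tree.root.in_child, sep_tree.root.out_child),
                    key=lambda c: c.n)
        assert (labels[small.indices] == 2).mean() > 0.95

    def test_deterministic_tree(self, two_blobs_small):
        ev, _ = two_blobs_small
        a = tree_to_dict(epp_recurse(ev, EPPConfig()))
        b = tree_to_dict(epp_recurse(ev, EPPConfig()))
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_min_events_rel_stops_recursion(self, two_blobs_small):
        # default: the split happens but the small children become leaves;
        # strict variant: a split producing an under-sized child is refused
        ev, _ = two_blobs_small
        tree = epp_recurse(ev, EPPConfig(min_events_rel=0.9))
        assert len(tree.leaves()) == 2
        assert all(l.is_leaf for l in (tree.root.in_child, tree.root.out_child))
        strict = epp_recurse(ev, EPPConfig(min_events_rel=0.9,
                                           min_stop_strict=True))
        assert len(strict.leaves()) == 1

    def test_depth_bounded_by_leaves(self):
        ev, _ = make_fixture("triangle_blobs", n=12_000, seed=5)
        tree = epp_recurse(ev, EPPConfig())
        leaves = tree.leaves()

        def depth(node):
            if node.is_leaf:
                return 0
            return 1 + max(depth(node.in_child), depth(node.out_child))

        assert depth(tree.root) <= len(leaves) - 1

    def test_leaf_labels_annotate_split_markers(self, two_blobs_small):
        ev, _ = two_blobs_small
        tree = epp_recurse(ev, EPPConfig())
        labels = {l.label for l in tree.leaves()}
        assert labels == {"D1+", "D1-"}

    def test_single_dimension_rejected(self):
        ev, _ = make_fixture("one_blob", n=100, seed=0)
        ev.phenotyping_mask[1] = False
        with pytest.raises(ValidationError):
            epp_recurse(ev, EPPConfig())


def test_stitch_chains_joins_end_to_end():
    a = np.array([[0, 0], [0, 1], [0, 2]])
    b = np.array([[0, 4], [0, 3]])   # reversed continuation
    poly = stitch_chains([a, b])
    assert poly.shape == (5, 2)
    assert np.abs(np.diff(poly[:, 1])).max() == 1
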