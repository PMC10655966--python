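"""Unit tests for the ranked-genealogy F/W/R encoding."""

import numpy as np
import pytest

import msprime

from popdann.genealogy import (
    EncodingError,
    Genealogy,
    GenealogyError,
    branch_span_count,
    decode_F,
    encode_genealogy,
    enumerate_ranked_shapes,
    extract_focal_genealogy,
    genealogy_from_newick,
    genealogy_from_shape,
    nearest_segregating_site,
    random_genealogy,
    ranked_shape_of,
)


class TestWorkedExamples:
    def test_two_leaf_tree(self):
        g = Genealogy(
            n=2,
            node_times=np.array([0.0, 0.0, 2.5]),
            parent=np.array([2, 2, -1]),
            derived_leaves=frozenset({0}),
        )
        e = encode_genealogy(g)
        assert e.F.tolist() == [[2]]
        assert e.W.tolist() == [[2.5]]
        assert e.R.tolist() == [[1]]

    def test_caterpillar_mutation_on_outer_leaf(self, caterpillar3):
        from dataclasses import replace

        g = replace(caterpillar3, derived_leaves=frozenset({2}))
        e = encode_genealogy(g)
        assert e.F.tolist() == [[2, 0], [1, 3]]
        assert e.W.tolist() == [[2.0, 0.0], [3.0, 1.0]]
        assert e.R.tolist() == [[1, 0], [1, 1]]

    def test_caterpillar_mutation_on_cherry_stem(self, caterpillar3):
        from dataclasses import replace

        g = replace(caterpillar3, derived_leaves=frozenset({0, 1}))
        e = encode_genealogy(g)
        # two derived leaf branches cover the youngest window; the stem
        # covers the most ancient; no derived branch covers [0, TMRCA]
        assert e.R.tolist() == [[1, 0], [0, 2]]
        assert np.all(e.R <= e.F)

    def test_128_taxa_yield_127_cubed_channels(self, rng):
        g = random_genealogy(128, rng)
        e = encode_genealogy(g)
        assert e.stacked().shape == (127, 127, 3)


class TestInvariants:
    @pytest.mark.parametrize("trial", range(5))
    def test_random_trees_satisfy_encoding_invariants(self, rng, trial):
        n = int(rng.integers(2, 65))
        g = random_genealogy(n, rng)
        e = encode_genealogy(g)
        m = n - 1
        # diagonal: window k from the top contains k+1 branches
        assert np.array_equal(np.diag(e.F), np.arange(2, n + 1))
        # strict lower-triangularity above the diagonal
        assert np.all(np.triu(e.F, 1) == 0)
        assert np.all(np.triu(e.W, 1) == 0)
        # column/row monotonicity of F
        for j in range(m):
            col = e.F[j:, j]
            assert np.all(np.diff(col) <= 0)
        for i in range(m):
            row = e.F[i, : i + 1]
            assert np.all(np.diff(row) >= 0)
        # telescoping of W and TMRCA recovery
        diag = np.diag(e.W)
        for i in range(m):
            for j in range(i + 1):
                assert e.W[i, j] == pytest.approx(diag[j : i + 1].sum(), rel=1e-9)
        assert diag.sum() == pytest.approx(g.tmrca)
        # coalescent times recoverable from the reversed W diagonal
        recovered = np.cumsum(diag[::-1])
        assert np.allclose(recovered, g.coalescent_times(), rtol=1e-9)
        # dominance
        assert np.all(e.R >= 0) and np.all(e.R <= e.F)

    def test_oracle_equivalence_of_F_and_R(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 33))
            g = random_genealogy(n, rng)
            e = encode_genealogy(g)
            t = np.concatenate([[0.0], g.coalescent_times()])
            for i in range(1, n):
                for j in range(1, i + 1):
                    lo, hi = t[n - 1 - i], t[n - j]
                    assert e.F[i - 1, j - 1] == branch_span_count(g, lo, hi)
                    assert e.R[i - 1, j - 1] == branch_span_count(
                        g, lo, hi, derived_only=True
                    )


class TestBranchSpanCount:
    def test_degenerate_window_at_present_counts_all_leaves(self, rng):
        g = random_genealogy(12, rng)
        assert branch_span_count(g, 0.0, 0.0) == 12

    def test_caterpillar_full_window_spanned_only_by_outer_leaf(self, caterpillar3):
        assert branch_span_count(caterpillar3, 0.0, 3.0) == 1

    def test_window_outside_tmrca_rejected(self, caterpillar3):
        with pytest.raises(ValueError):
            branch_span_count(caterpillar3, 0.0, 10.0)
        with pytest.raises(ValueError):
            branch_span_count(caterpillar3, -1.0, 2.0)


class TestBijectivity:
    @pytest.mark.parametrize("n,count", [(2, 1), (3, 1), (4, 2), (5, 5), (6, 16)])
    def test_ranked_shape_enumeration_counts(self, n, count):
        assert len(enumerate_ranked_shapes(n)) == count

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_encode_decode_identity_over_all_ranked_shapes(self, n):
        seen = {}
        for shape in enumerate_ranked_shapes(n):
            g = genealogy_from_shape(shape)
            F = encode_genealogy(g, require_derived=False).F
            assert decode_F(F) == shape  # decode . encode = id
            key = F.tobytes()
            assert key not in seen, "two ranked shapes share an F matrix"
            seen[key] = shape
            # encode . decode = id: rebuild from the decoded shape
            g2 = genealogy_from_shape(decode_F(F))
            assert np.array_equal(encode_genealogy(g2, require_derived=False).F, F)

    def test_decode_rejects_invalid_diagonal(self):
        with pytest.raises(EncodingError):
            decode_F(np.array([[3]]))

    def test_decode_rejects_unrealizable_matrix(self):
        # valid diagonal but impossible off-diagonal count
        F = np.array([[2, 0], [3, 3]])
        with pytest.raises(EncodingError):
            decode_F(F)


class TestValidation:
    def test_non_ultrametric_rejected(self):
        with pytest.raises(GenealogyError):
            Genealogy(
                n=2,
                node_times=np.array([0.0, 1.0, 2.0]),
                parent=np.array([2, 2, -1]),
            )

    def test_nonbinary_rejected(self):
        # node 4 with three children
        with pytest.raises(GenealogyError):
            Genealogy(
                n=3,
                node_times=np.array([0.0, 0.0, 0.0, 1.0, 2.0]),
                parent=np.array([4, 4, 4, 4, -1]),
            )

    def test_derived_leaves_must_be_proper_subset(self, caterpillar3):
        from dataclasses import replace

        with pytest.raises(GenealogyError):
            replace(caterpillar3, derived_leaves=frozenset({0, 1, 2}))
        with pytest.raises(GenealogyError):
            replace(caterpillar3, derived_leaves=frozenset())

    def test_non_clade_derived_set_raises_naming_leaves(self):
        g = Genealogy(
            n=4,
            node_times=np.array([0, 0, 0, 0, 1.0, 2.0, 3.0]),
            parent=np.array([4, 4, 5, 6, 5, 6, -1]),
            derived_leaves=frozenset({0, 2}),  # not monophyletic
        )
        with pytest.raises(EncodingError, match="not a clade"):
            encode_genealogy(g)

    def test_tie_resolution_produces_strict_ranking(self):
        g = Genealogy(
            n=3,
            node_times=np.array([0.0, 0.0, 0.0, 1.0, 1.0 + 1e-15]),
            parent=np.array([3, 3, 4, 4, -1]),
        ).resolve_ties()
        times = g.coalescent_times()
        assert times[1] > times[0]


@pytest.fixture(scope="module")
def ts():
    ts = msprime.sim_ancestry(
        samples=8,
        sequence_length=100_000,
        recombination_rate=1e-8,
        population_size=10_000,
        random_seed=7,
    )
    return msprime.sim_mutations(ts, rate=1e-8, random_seed=7)


class TestTreeSequenceBridge:

    def test_marginal_tree_matches_interval_lookup(self, ts):
        g = extract_focal_genealogy(ts, 50_000.0, focal_site_required=False)
        tree = ts.at(50_000.0)
        assert tree.interval.left <= 50_000.0 < tree.interval.right
        assert g.n == ts.num_samples
        assert g.tmrca == pytest.approx(
            max(tree.time(u) for u in tree.nodes()), rel=1e-9
        )

    def test_single_tree_sequence_any_position(self):
        ts = msprime.sim_ancestry(
            samples=4, sequence_length=1_000, population_size=1_000, random_seed=3
        )
        g0 = extract_focal_genealogy(ts, 0.0, focal_site_required=False)
        g1 = extract_focal_genealogy(ts, 999.0, focal_site_required=False)
        assert np.array_equal(g0.parent, g1.parent)

    def test_focal_site_derived_leaves(self, ts):
        site = nearest_segregating_site(ts, 50_000.0)
        g = extract_focal_genealogy(ts, site.position)
        assert g.derived_leaves is not None
        assert 0 < len(g.derived_leaves) < g.n
        e = encode_genealogy(g)
        assert e.R.max() > 0

    def test_position_out_of_range_rejected(self, ts):
        with pytest.raises(ValueError):
            extract_focal_genealogy(ts, 1e9)

    def test_missing_focal_site_raises_when_required(self, ts):
        # pick a position with no site
        positions = {s.position for s in ts.sites()}
        pos = next(x for x in np.arange(1.5, 1e5) if x not in positions)
        with pytest.raises(ValueError):
            extract_focal_genealogy(ts, pos, focal_site_required=True)


class TestNewick:
    def test_round_trip_encoding(self, caterpillar3):
        nwk = "((a:1.0,b:1.0):2.0,c:3.0);"
        g = genealogy_from_newick(nwk)
        e = encode_genealogy(g, require_derived=False)
        expected = encode_genealogy(caterpillar3, require_derived=False)
        assert np.array_equal(e.F, expected.F)
        assert np.allclose(e.W, expected.W)

    def test_non_ultrametric_newick_rejected(self):
        with pytest.raises(GenealogyError):
            genealogy_from_newick("((a:1.0,b:2.0):2.0,c:3.0);")


def test_ranked_shape_of_inverts_genealogy_from_shape(rng):
    for shape in enumerate_ranked_shapes(6):
        assert ranked_shape_of(genealogy_from_shape(shape)) == shape
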