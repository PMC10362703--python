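import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rlcausal import (Dataset, annotate_and_prune, iie_strength, normalize,
                      spacing_entropy)
from rlcausal.strength import STRENGTH_CAP


class TestSpacingEntropy:
    def test_two_point_unit_spacing_is_exactly_one(self):
        # psi(2) - psi(1) = 1 by the digamma recurrence, log(1) = 0
        assert spacing_entropy([0.0, 1.0]).value == pytest.approx(1.0, abs=1e-12)

    def test_two_point_spacing_e_is_exactly_two(self):
        assert spacing_entropy([0.0, np.e]).value == pytest.approx(2.0, abs=1e-12)

    def test_uniform_near_zero_entropy(self):
        draws = np.random.default_rng(0).random(5000)
        assert abs(spacing_entropy(draws).value) < 0.05

    def test_normal_near_half_log_2pie(self):
        draws = np.random.default_rng(1).normal(size=5000)
        truth = 0.5 * np.log(2 * np.pi * np.e)
        assert abs(spacing_entropy(draws).value - truth) < 0.05

    @settings(max_examples=30, deadline=None)
    @given(a=st.floats(0.01, 50.0), b=st.floats(-20.0, 20.0),
           seed=st.integers(0, 2**20))
    def test_affine_equivariance(self, a, b, seed):
        x = np.random.default_rng(seed).normal(size=60)
        base = spacing_entropy(x).value
        shifted = spacing_entropy(a * x + b).value
        assert shifted == pytest.approx(base + np.log(a), rel=1e-9, abs=1e-9)

    def test_consistency_improves_with_sample_size(self):
        rng = np.random.default_rng(3)
        truth = 0.5 * np.log(2 * np.pi * np.e)
        errors = {}
        for n in (100, 5000):
            errs = [abs(spacing_entropy(rng.normal(size=n)).value - truth)
                    for _ in range(50)]
            errors[n] = np.mean(errs)
        assert errors[5000] < errors[100]

    def test_tie_policies(self):
        x = [0.0, 1.0, 1.0, 3.0]
        dropped = spacing_entropy(x, "drop")
        assert dropped.zero_spacings == 1
        # drop: psi(4) - psi(1) + (log 1 + log 2)/2
        from scipy.special import digamma
        expected = digamma(4) - digamma(1) + np.log(2) / 2
        assert dropped.value == pytest.approx(expected, abs=1e-12)
        eps = spacing_entropy(x, "epsilon")
        assert eps.value < dropped.value  # the floored log(1e-12) drags it down

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            spacing_entropy([2.0, 2.0, 2.0])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            spacing_entropy([1.0])


class TestIieStrength:
    def test_entropy_gap_two_gives_half(self):
        # columns engineered to entropies s and s + 2 via exact affine scaling
        x = np.random.default_rng(0).normal(size=500)
        assert iie_strength(x, np.exp(2.0) * x) == pytest.approx(0.5, rel=1e-9)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=200), rng.random(200)
        assert iie_strength(a, b) == iie_strength(b, a)

    def test_equal_entropy_capped(self, rng):
        a = rng.normal(size=300)
        assert iie_strength(a, a) == STRENGTH_CAP

    def test_raw_strength_scale_dependent_normalized_invariant(self, rng):
        a = rng.normal(size=400)
        b = rng.random(400) * 3 + 1
        raw = iie_strength(a, b)
        scaled = iie_strength(a, 10.0 * b)
        assert raw != pytest.approx(scaled, rel=1e-3)

        def unit(v):
            return (v - v.min()) / (v.max() - v.min())
        assert iie_strength(unit(a), unit(b)) == pytest.approx(
            iie_strength(unit(a), unit(10.0 * b)), rel=1e-9)


class TestAnnotateAndPrune:
    @pytest.fixture
    def data(self, rng):
        # distinct marginal shapes -> distinct entropies
        cols = np.column_stack([
            rng.random(400),
            rng.normal(size=400),
            rng.exponential(size=400),
            rng.beta(0.3, 0.3, size=400),
        ])
        return normalize(Dataset(cols))

    def test_kept_edges_match_independent_strengths(self, data):
        graph = np.ones((4, 4), np.int8)
        np.fill_diagonal(graph, 0)
        out = annotate_and_prune(graph, data, threshold=0.5)
        kept = {(s, t): w for s, t, w in out.edges}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                t = iie_strength(data.values[:, i], data.values[:, j])
                key = (data.columns[i], data.columns[j])
                if t >= 0.5:
                    assert kept[key] == pytest.approx(t, rel=1e-12)
                else:
                    assert key not in kept

    def test_boundary_strength_kept_next_float_removed(self, data):
        graph = np.ones((4, 4), np.int8)
        np.fill_diagonal(graph, 0)
        annotated = annotate_and_prune(graph, data, threshold=0.0)
        strengths = sorted(w for _, _, w in annotated.edges)
        pivot = strengths[len(strengths) // 2]
        at = annotate_and_prune(graph, data, threshold=pivot)
        above = annotate_and_prune(graph, data, threshold=np.nextafter(pivot, np.inf))
        kept_at = {(s, t) for s, t, _ in at.edges}
        kept_above = {(s, t) for s, t, _ in above.edges}
        boundary = {(s, t) for s, t, w in annotated.edges if w == pivot}
        assert boundary and boundary <= kept_at
        assert kept_above == kept_at - boundary

    def test_threshold_monotonicity(self, data):
        graph = np.ones((4, 4), np.int8)
        np.fill_diagonal(graph, 0)
        lo = annotate_and_prune(graph, data, threshold=0.5)
        hi = annotate_and_prune(graph, data, threshold=2.0)
        assert {(s, t) for s, t, _ in hi.edges} <= {(s, t) for s, t, _ in lo.edges}

    def test_empty_graph_stays_empty(self, data):
        out = annotate_and_prune(np.zeros((4, 4), np.int8), data)
        assert out.edges == ()

    def test_pruned_edges_subset_of_input_graph(self, data, rng):
        graph = (rng.random((4, 4)) < 0.5).astype(np.int8)
        np.fill_diagonal(graph, 0)
        out = annotate_and_prune(graph, data)
        index = {v: k for k, v in enumerate(out.variables)}
        for s, t, _ in out.edges:
            assert graph[index[s], index[t]] == 1
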