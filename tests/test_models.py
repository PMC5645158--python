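"""Model log-weights and exact distributions against enumeration oracles."""

import itertools

import numpy as np
import pytest

from popmaxent import (
    PairwiseModel,
    exact_distribution,
    inhibited_log_weight,
    pairwise_log_weight,
    reduced_distribution,
    relative_entropy,
    truncated_distribution,
)
from conftest import random_pairwise


class TestPairwiseLogWeight:
    def test_zero_state_gives_zero(self, make_model):
        model = make_model(5)
        assert pairwise_log_weight(np.zeros(5), model) == 0.0

    def test_two_unit_substitution(self):
        model = PairwiseModel(h=np.array([1.0, -1.0]),
                              J=np.array([[0.0, 0.5], [0.5, 0.0]]))
        assert pairwise_log_weight(np.array([1, 1]), model) == pytest.approx(0.5)

    def test_non_binary_rejected(self, make_model):
        with pytest.raises(ValueError):
            pairwise_log_weight(np.array([0, 2, 0, 0, 0]), make_model(5))

    def test_enumeration_matches_direct_formula(self, make_model):
        """Normalised exp(log-weights) equals brute-force probabilities."""
        model = make_model(10)
        dist = exact_distribution(model)
        # independent brute force over itertools product
        weights = []
        for s in itertools.product((0, 1), repeat=10):
            s = np.array(s, dtype=float)
            w = model.h @ s
            for i in range(10):
                for j in range(i + 1, 10):
                    w += model.J[i, j] * s[i] * s[j]
            weights.append(np.exp(w))
        probs = np.array(weights) / np.sum(weights)
        # state_table enumerates with unit i as bit i of the index
        order = [sum(b << i for i, b in enumerate(s))
                 for s in itertools.product((0, 1), repeat=10)]
        assert np.allclose(dist.p[order], probs, atol=1e-12)


class TestInhibited:
    def test_ji_zero_recovers_pairwise(self, make_model, rng):
        base = make_model(6)
        model = PairwiseModel.with_theta(base.h, base.J, 0.0, 0.5)
        for _ in range(10):
            s = (rng.random(6) < 0.5).astype(int)
            assert inhibited_log_weight(s, model) == pytest.approx(
                pairwise_log_weight(s, base))

    def test_below_threshold_term_vanishes(self, make_model):
        base = make_model(6)
        model = PairwiseModel.with_theta(base.h, base.J, -7.0, 0.5)
        s = np.array([1, 1, 0, 0, 0, 0])  # sbar = 1/3 < theta
        assert inhibited_log_weight(s, model) == pytest.approx(
            pairwise_log_weight(s, base))

    def test_strong_inhibition_converges_to_truncation(self, make_model):
        base = make_model(8)
        tvs = []
        for J_I in (-5.0, -10.0, -20.0, -40.0, -50.0):
            model = PairwiseModel.with_theta(base.h, base.J, J_I, 0.5)
            tv = 0.5 * np.abs(
                exact_distribution(model).p
                - truncated_distribution(model, 0.5).p
            ).sum()
            tvs.append(tv)
        assert all(a > b for a, b in zip(tvs, tvs[1:]))  # monotone in J_I
        assert tvs[-1] < 1e-6

    def test_inhibition_only_removes_weight_above_threshold(self, make_model):
        base = make_model(6)
        model = PairwiseModel.with_theta(base.h, base.J, -3.0, 0.5)
        p_pair = exact_distribution(base).p
        p_inh = exact_distribution(model).p
        from popmaxent.models import state_table

        S = state_table(6).sum(axis=1)
        below = S < 3
        # relative weight of below-threshold states can only grow
        assert p_inh[below].sum() >= p_pair[below].sum() - 1e-12


class TestExactDistribution:
    def test_uniform_when_no_parameters(self):
        model = PairwiseModel(h=np.zeros(5), J=np.zeros((5, 5)))
        dist = exact_distribution(model)
        assert np.allclose(dist.p, 2.0 ** -5)
        assert np.allclose(dist.E_s, 0.5)
        iu = np.triu_indices(5, 1)
        assert np.allclose(dist.E_ss[iu], 0.25)

    def test_single_unit_logistic(self):
        a = 0.7
        model = PairwiseModel(h=np.array([a]), J=np.zeros((1, 1)))
        dist = exact_distribution(model)
        assert dist.p[1] == pytest.approx(1 / (1 + np.exp(-a)))

    def test_expectations_consistent_with_table(self, make_model):
        model = make_model(6)
        dist = exact_distribution(model)
        from popmaxent.models import state_table

        states = state_table(6).astype(float)
        assert np.allclose(dist.E_s, dist.p @ states, atol=1e-14)
        E2 = np.einsum("s,si,sj->ij", dist.p, states, states)
        iu = np.triu_indices(6, 1)
        assert np.allclose(dist.E_ss[iu], E2[iu], atol=1e-14)

    def test_cap_enforced(self):
        model = PairwiseModel(h=np.zeros(25), J=np.zeros((25, 25)))
        with pytest.raises(ValueError, match="cap"):
            exact_distribution(model)


class TestReducedDistribution:
    def test_zero_parameters_give_binomial(self):
        model = reduced_distribution(10, 0.0, 0.0)
        from math import comb

        expected = np.array([comb(10, s) for s in range(11)]) / 2 ** 10
        assert np.allclose(model.pmf, expected, atol=1e-14)
        assert model.E_sbar == pytest.approx(0.5)

    def test_printed_multipliers_give_two_discrete_maxima(self):
        """At N=159 the data-constrained reduced model has two pmf peaks."""
        from popmaxent import find_modes

        model = reduced_distribution(159, -3.259, 0.03859)
        modes, ratio = find_modes(model)
        assert len(modes) == 2
        assert ratio is not None and ratio > 1

    @pytest.mark.parametrize("n,h,J", [(5, -1.3, 0.2), (7, 0.4, -0.1)])
    def test_aggregates_homogeneous_pairwise_model(self, n, h, J):
        model = PairwiseModel.homogeneous(n, h, J)
        dist = exact_distribution(model)
        from popmaxent.models import state_table

        S = state_table(n).sum(axis=1)
        aggregated = np.array([dist.p[S == s].sum() for s in range(n + 1)])
        assert np.allclose(aggregated, reduced_distribution(n, h, J).pmf,
                           atol=1e-12)

    def test_pmf_normalised(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 400))
            model = reduced_distribution(
                n, rng.normal(0, 3), rng.normal(0, 0.1))
            assert abs(model.pmf.sum() - 1) < 1e-12


class TestTruncated:
    def test_theta_one_is_plain_pairwise(self, make_model):
        model = make_model(6)
        assert np.allclose(truncated_distribution(model, 1.0).p,
                           exact_distribution(model).p, atol=1e-14)

    def test_theta_zero_is_point_mass_on_silence(self, make_model):
        p = truncated_distribution(make_model(6), 0.0).p
        assert p[0] == pytest.approx(1.0)
        assert p[1:].sum() == pytest.approx(0.0, abs=1e-300)


class TestRelativeEntropy:
    def test_identical_distributions_give_zero(self, rng):
        p = rng.random(11)
        p /= p.sum()
        assert relative_entropy(p, p) == pytest.approx(0.0, abs=1e-14)

    def test_reduced_uniform_vs_binomial_reference(self):
        model = reduced_distribution(12, 0.0, 0.0)
        from math import comb

        ref = np.array([comb(12, s) for s in range(13)]) / 2 ** 12
        assert relative_entropy(model.pmf, ref) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_summation(self, rng):
        p = rng.random(11)
        p /= p.sum()
        q = rng.random(11)
        q /= q.sum()
        direct = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
        assert relative_entropy(p, q) == pytest.approx(direct, abs=1e-12)
        assert relative_entropy(p, q) >= 0

    def test_support_violation_raises(self):
        p = np.array([0.5, 0.5, 0.0])
        q = np.array([1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            relative_entropy(p, q)


def test_model_json_round_trip(tmp_path, make_model):
    model = make_model(5)
    inhibited = PairwiseModel.with_theta(model.h, model.J, -24.7, 0.4)
    path = tmp_path / "model.json"
    inhibited.to_json(path)
    back = PairwiseModel.from_json(path)
    assert np.allclose(back.h, inhibited.h)
    assert np.allclose(back.J, inhibited.J)
    assert back.J_I == inhibited.J_I and back.Theta == inhibited.Theta
    # lower-triangle input is symmetrised on load
    import json

    obj = json.loads(path.read_text())
    obj["J"] = np.tril(inhibited.J).tolist()
    path.write_text(json.dumps(obj))
    tri = PairwiseModel.from_json(path)
    assert np.allclose(tri.J, inhibited.J)
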