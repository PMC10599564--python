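import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from conftest import brute_force_logits
from splicepotts.alphabet import PAIRS
from splicepotts.marginals import estimate_marginals
from splicepotts.model import (
    PottsModel,
    active_couplings,
    energies,
    energy,
    fit_maxent,
    model_marginals,
    partition_function,
    probability_grid,
    sample_sequences,
    sequence_probability,
    zero_sum_gauge,
)
from splicepotts.synth import make_random_potts


class TestEnergy:
    def test_zero_model_all_zero(self, zero_model):
        assert energy(zero_model, "CAGGTAAGT") == 0.0
        assert energy(zero_model, "AAAAAAAAA") == 0.0

    def test_single_field_term(self, zero_model):
        zero_model.h[3, 2] = 2.0  # +1 position, letter G
        assert energy(zero_model, "CAGGTAAGT") == pytest.approx(-2.0)

    def test_matches_brute_force_summation(self, random_model):
        rng = np.random.default_rng(1)
        codes = rng.integers(0, 4, size=(50, 9))
        seqs = ["".join("ACGT"[c] for c in row) for row in codes]
        e = energies(random_model, seqs)
        for seq, got in zip(seqs, e):
            s = [int("ACGT".index(c)) for c in seq]
            expected = -sum(random_model.h[i, s[i]] for i in range(9))
            for p, (i, j) in enumerate(PAIRS):
                expected -= random_model.J[p, s[i] * 4 + s[j]]
            assert got == pytest.approx(expected, abs=1e-12)


class TestPartitionFunction:
    def test_zero_model_closed_form(self, zero_model):
        assert partition_function(zero_model) == pytest.approx(9 * np.log(4), abs=1e-10)

    def test_fields_only_factorizes(self):
        rng = np.random.default_rng(5)
        h = rng.normal(0, 1, (9, 4))
        model = PottsModel(h, np.zeros((36, 16)))
        expected = sum(logsumexp(h[i]) for i in range(9))
        assert partition_function(model) == pytest.approx(expected, abs=1e-10)

    def test_random_sparse_model_matches_enumeration(self, random_model):
        flat = brute_force_logits(random_model.h, random_model.J)
        assert partition_function(random_model) == pytest.approx(
            logsumexp(flat), abs=1e-9
        )


class TestSequenceProbability:
    def test_uniform_for_zero_model(self, zero_model):
        assert sequence_probability(zero_model, "CAGGTAAGT") == pytest.approx(1 / 4**9)

    def test_fields_only_equals_independent_product(self):
        rng = np.random.default_rng(8)
        f = rng.dirichlet(np.ones(4) * 5, size=9)
        model = PottsModel(np.log(f), np.zeros((36, 16)))
        seq = "CAGGTAAGT"
        prod = np.prod([f[i, "ACGT".index(c)] for i, c in enumerate(seq)])
        assert sequence_probability(model, seq) == pytest.approx(prod, rel=1e-9)

    def test_probabilities_normalize(self, random_model):
        assert probability_grid(random_model).sum() == pytest.approx(1.0, abs=1e-9)


class TestModelMarginals:
    def test_zero_model_uniform(self, zero_model):
        mm = model_marginals(zero_model)
        assert np.allclose(mm.f1, 0.25, atol=1e-12)
        assert np.allclose(mm.f2, 0.0625, atol=1e-12)

    def test_fields_only_independence(self):
        rng = np.random.default_rng(9)
        model = PottsModel(rng.normal(0, 0.8, (9, 4)), np.zeros((36, 16)))
        mm = model_marginals(model)
        for p, (i, j) in enumerate(PAIRS):
            assert np.allclose(
                mm.f2[p], np.outer(mm.f1[i], mm.f1[j]).ravel(), atol=1e-12
            )

    def test_agrees_with_empirical_sampling(self, random_model):
        n = 200000
        mm = model_marginals(random_model)
        emp = estimate_marginals(sample_sequences(random_model, n, seed=77), 0.0)
        sigma1 = np.sqrt(mm.f1 * (1 - mm.f1) / n)
        sigma2 = np.sqrt(mm.f2 * (1 - mm.f2) / n)
        assert np.all(np.abs(emp.f1 - mm.f1) <= 4 * sigma1 + 1e-9)
        assert np.all(np.abs(emp.f2 - mm.f2) <= 4 * sigma2 + 1e-9)


class TestSampling:
    def test_same_seed_identical(self, random_model):
        a = sample_sequences(random_model, 500, seed=3)
        b = sample_sequences(random_model, 500, seed=3)
        assert a.sequences == b.sequences

    def test_fields_only_frequencies_near_softmax(self):
        rng = np.random.default_rng(4)
        h = rng.normal(0, 1, (9, 4))
        model = PottsModel(h, np.zeros((36, 16)))
        n = 50000
        emp = estimate_marginals(sample_sequences(model, n, seed=6), 0.0)
        soft = np.exp(h) / np.exp(h).sum(axis=1, keepdims=True)
        sigma = np.sqrt(soft * (1 - soft) / n)
        assert np.all(np.abs(emp.f1 - soft) <= 4 * sigma + 1e-9)


class TestGauge:
    @given(st.floats(-2.0, 2.0), st.integers(0, 8))
    @settings(max_examples=20, deadline=None)
    def test_constant_field_shift_leaves_probabilities_unchanged(self, c, pos):
        model = make_random_potts(seed=99, n_couplings=6)
        shifted = PottsModel(model.h.copy(), model.J.copy())
        shifted.h[pos] += c
        assert energy(shifted, "CAGGTAAGT") == pytest.approx(
            energy(model, "CAGGTAAGT") - c, abs=1e-9
        )
        np.testing.assert_allclose(
            probability_grid(shifted), probability_grid(model), atol=1e-12
        )

    def test_zero_sum_gauge_rows(self, random_model):
        g = zero_sum_gauge(random_model)
        assert np.allclose(g.h.sum(axis=1), 0.0, atol=1e-10)


class TestActiveCouplings:
    def test_zero_model_empty(self, zero_model):
        assert active_couplings(zero_model) == []

    def test_count_and_sorting(self, random_model):
        acts = active_couplings(random_model)
        assert len(acts) == int(np.count_nonzero(random_model.J))
        mags = [abs(c.value) for c in acts]
        assert mags == sorted(mags, reverse=True)

    def test_notation(self):
        J = np.zeros((36, 16))
        J[PAIRS.index((2, 8)), 4 * 2 + 3] = -0.8  # -1G with +6T
        acts = active_couplings(PottsModel(np.zeros((9, 4)), J))
        assert acts[0].label == "-1G:+6T"


class TestFit:
    def test_large_gamma_full_shrinkage(self, random_model):
        target = model_marginals(random_model)
        fit = fit_maxent(target, 1.0, max_iter=200)
        assert not fit.J.any()
        assert np.abs(model_marginals(fit).f1 - target.f1).max() < 1e-5

    def test_moment_matching_at_gamma_zero(self, random_model):
        ens = sample_sequences(random_model, 20000, seed=12)
        target = estimate_marginals(ens, pseudocount=1.0)
        fit = fit_maxent(target, 0.0, max_iter=2000)
        mm = model_marginals(fit)
        assert np.abs(mm.f2 - target.f2).max() <= 1e-4
        assert fit.fit_metadata["converged"]

    def test_parameter_recovery_at_moderate_gamma(self):
        truth = make_random_potts(31, n_couplings=5, field_scale=0.25, coupling_scale=0.6)
        fit = fit_maxent(model_marginals(truth), 0.005, max_iter=2000)
        planted = np.flatnonzero(truth.J.ravel())
        recovered = fit.J.ravel()[planted]
        assert np.all(recovered != 0)
        r = np.corrcoef(recovered, truth.J.ravel()[planted])[0, 1]
        assert r >= 0.9

    def test_objective_monotone_across_accepted_steps(self, random_model):
        ens = sample_sequences(random_model, 5000, seed=8)
        target = estimate_marginals(ens, pseudocount=1.0)
        fit = fit_maxent(target, 0.02, max_iter=60, trace=True)
        tr = fit.fit_metadata["objective_trace"]
        assert all(b <= a + 1e-12 for a, b in zip(tr, tr[1:]))

    def test_zero_target_entries_error_mentions_pseudocount(self, tiny_ensemble):
        target = estimate_marginals(tiny_ensemble, pseudocount=0.0)
        with pytest.raises(ValueError, match="pseudocount"):
            fit_maxent(target, 0.0)

    def test_refit_of_sampled_model_reproduces_marginals(self):
        # fit/resample closure: samples of a fitted model match its marginals
        truth = make_random_potts(17, n_couplings=4, field_scale=0.3, coupling_scale=0.5)
        ens = sample_sequences(truth, 50000, seed=2)
        fit = fit_maxent(estimate_marginals(ens, 1.0), 0.01, max_iter=1000)
        mm = model_marginals(fit)
        n = 200000
        emp = estimate_marginals(sample_sequences(fit, n, seed=3), 0.0)
        sigma = np.sqrt(mm.f2 * (1 - mm.f2) / n)
        assert np.all(np.abs(emp.f2 - mm.f2) <= 4 * sigma + 1e-9)


def test_serialization_round_trip(tmp_path, random_model):
    path = tmp_path / "m.json"
    fitted = zero_sum_gauge(random_model)
    fitted.save(path)
    back = PottsModel.load(path)
    np.testing.assert_allclose(back.h, fitted.h, atol=0)
    np.testing.assert_allclose(back.J, fitted.J, atol=0)
    assert back.gauge_tag == fitted.gauge_tag


def test_ensemble_scoring_rejects_ambiguous_sequences(zero_model):
    with pytest.raises(ValueError, match="non-ACGT"):
        energies(zero_model, ["CAGGTANGT"])
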