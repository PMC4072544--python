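"""Extended pairwise ML codon model: rate matrix, likelihood, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncrates.mlmodel import (
    MLParameters,
    build_rate_matrix,
    estimate_codon_frequencies,
    fit_ml,
    fit_standard_omega,
    pair_counts,
    pair_log_likelihood,
    transition_matrix,
)
from ncrates.simulate import (
    SimulationSpec,
    simulate_codon_pair,
    uniform_codon_frequencies,
)

from conftest import aln_from_codons


@pytest.fixture(scope="module")
def pi():
    return uniform_codon_frequencies()


class TestCodonFrequencies:
    def test_one_of_each_codon_is_uniform(self, code):
        pi = estimate_codon_frequencies(["".join(code.sense_codons)], pseudocount=0.5)
        assert np.allclose(pi.pi, 1 / 61)

    def test_pseudocount_only_is_uniform(self):
        pi = estimate_codon_frequencies([], pseudocount=0.5)
        assert np.allclose(pi.pi, 1 / 61)

    def test_pooling_equals_concatenation(self):
        a, b = "ATGGCTAAA", "GCTGCTTTT"
        pooled = estimate_codon_frequencies([a, b])
        concat = estimate_codon_frequencies([a + b])
        assert np.allclose(pooled.pi, concat.pi)

    def test_stop_mass_in_table_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            estimate_codon_frequencies({"ATG": 5.0, "TAA": 1.0})


params_strategy = st.builds(
    MLParameters,
    t=st.floats(0.05, 2.0),
    kappa=st.floats(0.2, 10.0),
    gamma=st.floats(0.05, 3.0),
    lam=st.floats(0.05, 4.0),
)


class TestRateMatrix:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(params=params_strategy)
    def test_q_invariants_for_random_parameters(self, params):
        pi = uniform_codon_frequencies()
        Q = build_rate_matrix(params, pi)
        assert np.allclose(Q.q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance
        flux = pi.pi[:, None] * Q.q
        assert np.allclose(flux, flux.T, atol=1e-12)
        # unit expected substitution rate
        assert -float(np.dot(pi.pi, np.diag(Q.q))) == pytest.approx(1.0)

    def test_multi_position_changes_have_zero_rate(self, pi):
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=2, gamma=0.5, lam=0.5), pi)
        codons = Q.codons
        for i, ci in enumerate(codons[:10]):
            for j, cj in enumerate(codons):
                if sum(a != b for a, b in zip(ci, cj)) > 1:
                    assert Q.q[i, j] == 0.0

    def test_neutral_parameters_treat_all_changes_identically(self, pi):
        # gamma = lam = 1 with uniform pi: every single-nt transversion gets
        # the same rate, every transition kappa times that, synonymous or not
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=3.0, gamma=1.0, lam=1.0), pi)
        idx = {c: k for k, c in enumerate(Q.codons)}
        transversion_rate = Q.q[idx["TTT"], idx["TTG"]]  # F->L transversion
        transition_rate = Q.q[idx["TTT"], idx["TTC"]]  # F->F transition
        assert transition_rate == pytest.approx(3.0 * transversion_rate)
        # nonsynonymous entries coincide with synonymous ones
        assert Q.q[idx["TTT"], idx["GTT"]] == pytest.approx(transversion_rate)  # F->V
        assert Q.q[idx["ATG"], idx["ACG"]] == pytest.approx(transition_rate)  # M->T

    def test_vanishing_lambda_silences_nonconservative_changes(self, pi, cls):
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=2, gamma=0.5, lam=1e-12), pi)
        idx = {c: k for k, c in enumerate(Q.codons)}
        # GTT (V) -> GCT (A) is non-conservative
        assert Q.q[idx["GTT"], idx["GCT"]] == pytest.approx(0.0, abs=1e-12)
        # GTT (V) -> ATT (I) is conservative and must stay positive
        assert Q.q[idx["GTT"], idx["ATT"]] > 0


class TestTransitionMatrix:
    def test_zero_time_is_identity(self, pi):
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=2, gamma=0.5, lam=0.5), pi)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61), atol=1e-12)

    def test_rows_are_probability_distributions(self, pi):
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=2, gamma=0.5, lam=0.5), pi)
        P = transition_matrix(Q, 0.7)
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_chapman_kolmogorov(self, pi):
        Q = build_rate_matrix(MLParameters(t=0.3, kappa=2.5, gamma=0.4, lam=0.6), pi)
        P1, P2 = transition_matrix(Q, 0.2), transition_matrix(Q, 0.5)
        assert np.allclose(P1 @ P2, transition_matrix(Q, 0.7), atol=1e-8)


class TestLikelihood:
    def test_identical_codon_at_tiny_time_approaches_log_pi(self, pi):
        n = np.zeros((61, 61), dtype=int)
        i = pi.codons.index("ATG")
        n[i, i] = 1
        ll = pair_log_likelihood(
            n, MLParameters(t=1e-9, kappa=2, gamma=0.5, lam=0.5), pi
        )
        assert ll == pytest.approx(math.log(pi.pi[i]), abs=1e-6)

    def test_invariant_to_swapping_the_sequences(self, pi, cls, code):
        params = MLParameters(t=0.4, kappa=2.0, gamma=0.3, lam=0.5)
        aln = simulate_codon_pair(SimulationSpec(length=200, params=params, seed=5))
        n = pair_counts(aln, code=code)
        ll = pair_log_likelihood(n, params, pi, cls=cls, code=code)
        ll_t = pair_log_likelihood(n.T, params, pi, cls=cls, code=code)
        assert ll == pytest.approx(ll_t, abs=1e-8)

    def test_true_parameters_beat_perturbed_ones_on_large_sample(self, pi, cls, code):
        params = MLParameters(t=0.3, kappa=2.0, gamma=0.3, lam=0.5)
        aln = simulate_codon_pair(SimulationSpec(length=4000, params=params, seed=17))
        n = pair_counts(aln, code=code)
        ll_true = pair_log_likelihood(n, params, pi, cls=cls, code=code)
        for field, value in (("t", 0.3), ("kappa", 2.0), ("gamma", 0.3), ("lam", 0.5)):
            for factor in (0.8, 1.2):
                perturbed = MLParameters(**{
                    "t": 0.3, "kappa": 2.0, "gamma": 0.3, "lam": 0.5,
                    field: value * factor,
                })
                assert ll_true >= pair_log_likelihood(
                    n, perturbed, pi, cls=cls, code=code
                )


class TestFitting:
    def test_identical_sequences_drive_t_to_lower_bound(self, cls, code):
        aln = aln_from_codons(["ATG", "GCT", "AAA"] * 10, ["ATG", "GCT", "AAA"] * 10)
        fit = fit_ml(aln, cls=cls, code=code, n_starts=1)
        assert fit.params.t < 1e-5
        assert "t_at_lower_bound" in fit.notes

    def test_single_pair_parameter_recovery(self, cls, code):
        truth = MLParameters(t=0.3, kappa=2.0, gamma=0.3, lam=0.5)
        aln = simulate_codon_pair(SimulationSpec(length=2000, params=truth, seed=23))
        fit = fit_ml(aln, cls=cls, code=code, n_starts=2, seed=1)
        assert fit.converged
        assert fit.params.t == pytest.approx(truth.t, rel=0.2)
        assert fit.params.kappa == pytest.approx(truth.kappa, rel=0.25)
        assert fit.params.lam == pytest.approx(truth.lam, rel=0.3)

    def test_standard_omega_fit_recovers_gamma_when_lambda_is_one(self, cls, code):
        truth = MLParameters(t=0.3, kappa=2.0, gamma=0.4, lam=1.0)
        aln = simulate_codon_pair(SimulationSpec(length=2000, params=truth, seed=31))
        fit = fit_standard_omega(aln, code=code, n_starts=2, seed=1)
        assert fit.omega == pytest.approx(0.4, rel=0.25)

    def test_purely_synonymous_divergence_flags_omega_floor(self, code):
        # Leu codons CTT/CTC/CTA/CTG: synonymous changes only
        aln = aln_from_codons(["CTT", "CTA", "CTC"] * 15, ["CTC", "CTG", "CTT"] * 15)
        fit = fit_standard_omega(aln, code=code, n_starts=1)
        assert fit.omega <= 1e-3
        assert any("lower_bound" in note for note in fit.notes)

    def test_extended_model_nests_standard_model(self, cls, code):
        # the 4-parameter model's maximum must dominate the lam=1 submodel's
        truth = MLParameters(t=0.35, kappa=1.8, gamma=0.4, lam=0.4)
        aln = simulate_codon_pair(SimulationSpec(length=400, params=truth, seed=41))
        full = fit_ml(aln, cls=cls, code=code, n_starts=2, seed=2)
        reduced = fit_standard_omega(aln, code=code, n_starts=2, seed=2)
        assert full.loglik >= reduced.loglik - 1e-6

    def test_lambda_estimate_insensitive_to_gamma(self, cls, code):
        # orthogonality: shifting gamma at fixed lam barely moves median lam-hat
        medians = []
        for gamma in (0.1, 0.3, 1.0):
            truth = MLParameters(t=0.3, kappa=2.0, gamma=gamma, lam=0.5)
            lams = []
            for rep in range(8):
                aln = simulate_codon_pair(
                    SimulationSpec(length=800, params=truth, seed=1000 + rep)
                )
                lams.append(fit_ml(aln, cls=cls, code=code, n_starts=1).params.lam)
            medians.append(float(np.median(lams)))
        spread = (max(medians) - min(medians)) / 0.5
        assert spread < 0.25
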