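"""Unit tests for the variational GO-activity model."""

import numpy as np
import pytest
from scipy.special import digamma

from gobayes.exact import exact_log_marginal
from gobayes.model import (
    GOActivityModel,
    decide,
    evidence_from_posterior,
    expected_fdr,
    free_energy,
    identify,
    init_state,
    vb_fit,
    vb_sweep,
)
from gobayes.types import ModelData, PriorSpec, TermPosterior, VariationalState

from conftest import random_small_instance


class TestEvidenceConversion:
    @pytest.mark.parametrize(
        "post1, prior1, expected",
        [
            (0.8, 0.5, (0.4, 1.6)),
            (0.5, 0.5, (1.0, 1.0)),
            (0.2, 0.4, (4.0 / 3.0, 0.5)),
        ],
    )
    def test_bayes_ratio(self, post1, prior1, expected):
        ev = evidence_from_posterior(post1, prior1, clip=1e-12)
        assert ev.lik0 == pytest.approx(expected[0])
        assert ev.lik1 == pytest.approx(expected[1])

    def test_boundary_is_clipped(self):
        ev = evidence_from_posterior(1.0, 0.5, clip=1e-12)
        assert ev.lik0 == pytest.approx(2e-12, rel=1e-6)
        assert ev.lik1 == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("prior1", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_prior_rejected(self, prior1):
        with pytest.raises(ValueError, match="prior"):
            evidence_from_posterior(0.5, prior1)

    def test_scale_invariance_of_posteriors(self):
        """Multiplying a gene's likelihood pair by c > 0 leaves qG alone.

        Compared over a fixed number of sweeps: the update map itself is
        scale-invariant (the constant only shifts the bound), while the
        stopping rule measures the shifted bound.
        """
        from gobayes.model import init_state

        probs = {"T1": [0.9, 0.3, 0.6], "T2": [0.2, 0.8]}

        def run(extra_log):
            model = GOActivityModel.from_probabilities(probs)
            model.data.log_lik = model.data.log_lik + extra_log
            state = init_state(model.data, model.priors, np.random.default_rng(5))
            for _ in range(100):
                vb_sweep(state, model.data, model.priors)
            return state.qG

        ref = run(0.0)
        for c in (1e-6, 3.7, 1e6):
            np.testing.assert_allclose(run(np.log(c)), ref, atol=1e-10)


class TestSweep:
    def test_sweep_matches_handcoded_update_formulas(self):
        """One sweep equals an independent transcription of the four
        coordinate updates for a 1-term, 2-gene instance with 9:1 evidence."""
        priors = PriorSpec.uniform()
        model = GOActivityModel.from_probabilities({"T": [0.9, 0.1]})
        data = model.data
        state = init_state(data, priors, rng=None)  # qG = 0.5, Betas at prior
        qG0 = state.qG.copy()
        lik = np.exp(data.log_lik)

        # independent transcription: E[ln x] = psi(a) - psi(a+b)
        def eln(c):
            return digamma(c) - digamma(c.sum())

        elnPi = np.array([eln(priors.delta_Pi[0]), eln(priors.delta_Pi[1])])
        w = np.array(
            [
                lik[s, 1]
                * np.exp(qG0[0] * elnPi[1, 1] + (1 - qG0[0]) * elnPi[0, 1])
                for s in range(2)
            ]
        )
        v = np.array(
            [
                lik[s, 0]
                * np.exp(qG0[0] * elnPi[1, 0] + (1 - qG0[0]) * elnPi[0, 0])
                for s in range(2)
            ]
        )
        qI_exp = w / (w + v)
        elnP = eln(priors.delta_P)
        a = elnP[1] + np.sum(qI_exp * elnPi[1, 1] + (1 - qI_exp) * elnPi[1, 0])
        b = elnP[0] + np.sum(qI_exp * elnPi[0, 1] + (1 - qI_exp) * elnPi[0, 0])
        qG_exp = np.exp(a) / (np.exp(a) + np.exp(b))
        qP_exp = priors.delta_P + np.array([1 - qG_exp, qG_exp])
        qPi_exp = priors.delta_Pi.copy()
        for l, wgt in ((0, 1 - qG_exp), (1, qG_exp)):
            qPi_exp[l] += np.array(
                [np.sum(wgt * (1 - qI_exp)), np.sum(wgt * qI_exp)]
            )

        vb_sweep(state, data, priors)
        np.testing.assert_allclose(state.qI, qI_exp, rtol=1e-12)
        np.testing.assert_allclose(state.qG, [qG_exp], rtol=1e-12)
        np.testing.assert_allclose(state.qP, qP_exp, rtol=1e-12)
        np.testing.assert_allclose(state.qPi, qPi_exp, rtol=1e-12)

    def test_beta_counts_accumulate_expected_occupancies(self):
        """After a sweep, Q(P) holds prior counts plus summed qG; with two
        terms saturated at qG = (1, 0) that is Beta(2, 2)."""
        priors = PriorSpec.uniform()
        model = GOActivityModel.from_probabilities(
            {"up": [0.999] * 4, "down": [0.001] * 4}
        )
        rng = np.random.default_rng(0)
        state = init_state(model.data, priors, rng)
        for _ in range(50):
            vb_sweep(state, model.data, priors)
        assert state.qG.max() > 0.999 and state.qG.min() < 0.001
        np.testing.assert_allclose(state.qP, [2.0, 2.0], atol=1e-3)
        expected = priors.delta_P + np.array(
            [model.data.n_terms - state.qG.sum(), state.qG.sum()]
        )
        np.testing.assert_allclose(state.qP, expected, rtol=1e-12)

    def test_factors_stay_normalised_and_bounded(self):
        rng = np.random.default_rng(3)
        model, priors = random_small_instance(rng)
        state = init_state(model.data, priors, rng)
        for _ in range(10):
            vb_sweep(state, model.data, priors)
            assert np.all((state.qG >= 0) & (state.qG <= 1))
            assert np.all((state.qI >= 0) & (state.qI <= 1))
            assert np.all(state.qP >= priors.delta_P - 1e-12)
            assert np.all(state.qPi >= priors.delta_Pi - 1e-12)


class TestFreeEnergy:
    def test_empty_model_has_zero_free_energy(self):
        data = ModelData([], np.array([], dtype=np.intp), [], np.zeros((0, 2)))
        priors = PriorSpec.uniform()
        assert free_energy(init_state(data, priors), data, priors) == pytest.approx(0.0)

    def test_trace_is_nondecreasing(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            model, priors = random_small_instance(rng)
            _, state = vb_fit(model.data, priors, n_restarts=2, seed=7)
            tr = np.asarray(state.free_energy_trace)
            drops = np.diff(tr) / np.maximum(1.0, np.abs(tr[:-1]))
            assert drops.min() >= -1e-8

    def test_bounded_by_exact_log_marginal(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            model, priors = random_small_instance(rng)
            _, state = vb_fit(model.data, priors, n_restarts=3, seed=3)
            assert state.free_energy_trace[-1] <= exact_log_marginal(
                model.data, priors
            ) + 1e-9


class TestIdentify:
    def _state(self, qPi):
        return VariationalState(
            qP=np.array([2.0, 3.0]),
            qPi=np.asarray(qPi, dtype=float),
            qG=np.array([0.9, 0.2]),
            qI=np.array([0.5]),
        )

    def test_correct_labeling_unchanged(self):
        # E[Pi_11] = 0.9, E[Pi_01] = 0.2
        state = self._state([[8.0, 2.0], [1.0, 9.0]])
        identify(state)
        assert state.identified
        np.testing.assert_allclose(state.qG, [0.9, 0.2])
        np.testing.assert_allclose(state.qP, [2.0, 3.0])

    def test_swapped_labeling_flipped(self):
        # E[Pi_11] = 0.2, E[Pi_01] = 0.9
        state = self._state([[1.0, 9.0], [8.0, 2.0]])
        identify(state)
        np.testing.assert_allclose(state.qG, [0.1, 0.8])
        np.testing.assert_allclose(state.qPi, [[8.0, 2.0], [1.0, 9.0]])
        np.testing.assert_allclose(state.qP, [3.0, 2.0])

    def test_tie_warns_and_keeps_labeling(self):
        state = self._state([[5.0, 5.0], [2.0, 2.0]])
        with pytest.warns(RuntimeWarning, match="tie"):
            identify(state)
        np.testing.assert_allclose(state.qG, [0.9, 0.2])


class TestFit:
    def test_saturated_evidence_activates_all_terms(self):
        model = GOActivityModel.from_probabilities(
            {f"T{k}": [0.999] * 5 for k in range(3)}
        )
        posteriors, _ = vb_fit(model.data, model.priors, n_restarts=5, seed=0)
        assert all(p.prob_active > 0.99 for p in posteriors)

    def test_gene_order_within_term_is_irrelevant(self):
        """Slot order is an artifact of storage, not part of the model."""
        rng = np.random.default_rng(21)
        model, priors = random_small_instance(rng)
        data = model.data
        perm = np.concatenate(
            [
                rng.permutation(np.flatnonzero(data.slot_term == k))
                for k in range(data.n_terms)
            ]
        )
        permuted = ModelData(
            data.term_ids,
            data.slot_term[perm],
            [data.slot_gene[i] for i in perm],
            data.log_lik[perm],
        )
        p1, _ = vb_fit(data, priors, n_restarts=3, seed=9)
        p2, _ = vb_fit(permuted, priors, n_restarts=3, seed=9)
        np.testing.assert_allclose(
            [p.prob_active for p in p1],
            [p.prob_active for p in p2],
            atol=1e-10,
        )

    def test_label_flip_is_an_equivalent_fixed_point(self):
        """With symmetric priors, the mirrored solution has the same bound
        and is itself (numerically) stationary."""
        priors = PriorSpec.uniform()
        model = GOActivityModel.from_probabilities(
            {"up": [0.95] * 4, "down": [0.05] * 4}
        )
        _, state = vb_fit(model.data, priors, n_restarts=3, seed=2)
        flipped = state.copy()
        flipped.qG = 1.0 - flipped.qG
        flipped.qPi = flipped.qPi[::-1].copy()
        flipped.qP = flipped.qP[::-1].copy()
        flipped.qI = flipped.qI.copy()
        f0 = free_energy(state, model.data, priors)
        f1 = free_energy(flipped, model.data, priors)
        assert f1 == pytest.approx(f0, rel=1e-9)
        before = flipped.qG.copy()
        vb_sweep(flipped, model.data, priors)
        np.testing.assert_allclose(flipped.qG, before, atol=1e-6)

    def test_nonconvergence_warns_but_returns(self):
        model = GOActivityModel.from_probabilities({"T": [0.7, 0.2, 0.9]})
        with pytest.warns(RuntimeWarning, match="converged"):
            posteriors, state = vb_fit(
                model.data, model.priors, n_restarts=2, max_iter=1, seed=0
            )
        assert len(posteriors) == 1
        assert not state.converged


class TestDecisions:
    def _posteriors(self, probs):
        return [
            TermPosterior(f"T{i}", p, 3, "inactive")
            for i, p in enumerate(probs)
        ]

    @pytest.mark.parametrize(
        "probs, threshold, n_active",
        [
            ((0.51,), 0.5, 1),
            ((0.50,), 0.5, 0),  # strictly-greater rule
            ((1.0, 0.996, 0.99), 0.995, 2),
        ],
    )
    def test_strict_threshold_rule(self, probs, threshold, n_active):
        out = decide(self._posteriors(probs), threshold)
        assert sum(p.decision == "active" for p in out) == n_active

    def test_expected_fdr_examples(self):
        post = self._posteriors((1.0, 1.0, 0.9, 0.8))
        assert expected_fdr(post, 0.5) == pytest.approx(0.075)
        assert expected_fdr(self._posteriors((1.0, 1.0)), 0.5) == 0.0

    def test_expected_fdr_matches_direct_summation(self):
        rng = np.random.default_rng(17)
        probs = rng.uniform(0.6, 1.0, size=1000)
        post = self._posteriors(probs)
        assert expected_fdr(post, 0.5) == pytest.approx(np.mean(1.0 - probs))

    def test_expected_fdr_empty_selection_errors(self):
        with pytest.raises(ValueError, match="no term selected"):
            expected_fdr(self._posteriors((0.1, 0.2)), 0.5)


class TestResultsObject:
    def test_frame_sorted_and_summary_prints(self, four_term_model):
        res = four_term_model.fit(n_restarts=4, seed=0)
        df = res.frame()
        assert list(df.columns) == ["term_id", "prob_active", "n_genes", "decision"]
        assert (df["prob_active"].diff().dropna() <= 1e-12).all()
        text = res.summary()
        assert "restarts" in text and "active" in text

    def test_dropped_terms_warn(self, four_term):
        from gobayes.model import evidence_from_posterior
        from gobayes.types import TermAnnotation

        evidence = {
            g: evidence_from_posterior(p, gene_id=g)
            for g, p in four_term.gene_probs.items()
        }
        terms = list(four_term.terms) + [TermAnnotation("GO:GHOST", ["nope"])]
        with pytest.warns(RuntimeWarning, match="no observed gene"):
            model = GOActivityModel(terms, evidence)
        assert model.dropped_terms == ["GO:GHOST"]
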