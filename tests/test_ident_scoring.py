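import numpy as np
import pytest
from scipy.stats import norm

from specuniq import (
    MixtureParams,
    PipelineConfig,
    PsmRecord,
    filter_and_rollup,
    fit_score_mixture,
    local_fdr_binned,
    posterior,
    qvalues_from_decoys,
)


def _psm(score, decoy=False, sample="A1", pep="PEPTIDEK", ppm=1.0, post=None, sid=None):
    return PsmRecord(
        sample_id=sample,
        spectrum_id=sid or f"s{abs(hash((score, decoy, pep, sample))) % 10**8}",
        peptide_seq=pep,
        charge=2,
        score=float(score),
        is_decoy=decoy,
        mass_error_ppm=ppm,
        posterior=post,
    )


class TestFitScoreMixture:
    def test_recovers_generating_parameters(self):
        """Generate-and-refit: a 50/50 N(4,1)+N(0,1) draw is recovered."""
        rng = np.random.default_rng(0)
        correct = rng.normal(4, 1, 500)
        incorrect = rng.normal(0, 1, 500)
        scores = np.r_[correct, incorrect]
        # half of the incorrect population is decoy-labelled (same null)
        decoys = np.r_[np.zeros(500, bool), np.arange(500) % 2 == 0]
        params = fit_score_mixture(scores, decoys)
        assert 0.45 <= params.pi_correct <= 0.55
        assert abs(params.mu_correct - 4.0) <= 0.15

    def test_separated_clusters_saturate_posteriors(self):
        rng = np.random.default_rng(0)
        lo = rng.normal(-10, 0.5, 100)
        hi = rng.normal(10, 0.5, 100)
        params = fit_score_mixture(np.r_[lo, hi], np.r_[np.ones(100, bool), np.zeros(100, bool)])
        assert np.all(posterior(hi, params) > 0.999)

    def test_mostly_null_data_gives_small_pi(self):
        rng = np.random.default_rng(3)
        decoys = rng.normal(0, 1, 995)
        targets = rng.normal(0, 1, 5)
        params = fit_score_mixture(
            np.r_[decoys, targets], np.r_[np.ones(995, bool), np.zeros(5, bool)]
        )
        assert params.pi_correct <= 0.1

    def test_loglik_trace_non_decreasing(self):
        rng = np.random.default_rng(11)
        scores = np.r_[rng.normal(4, 1, 300), rng.normal(0, 1, 300)]
        decoys = np.r_[np.zeros(300, bool), np.ones(300, bool)]
        trace = np.array(fit_score_mixture(scores, decoys).loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)

    @pytest.mark.parametrize(
        "scores, decoys, match",
        [
            (np.ones(60), np.r_[np.ones(10, bool), np.zeros(50, bool)], "degenerate"),
            (np.arange(10.0), np.ones(10, bool), "≥50 scores"),
            (np.arange(60.0), np.zeros(60, bool), "≥5 decoys"),
        ],
    )
    def test_input_validation(self, scores, decoys, match):
        with pytest.raises(ValueError, match=match):
            fit_score_mixture(scores, decoys)


class TestPosterior:
    def test_closed_form_density_arithmetic(self):
        """p(1) for pi=0.5, N(2,1) vs N(0,1) by direct density evaluation."""
        params = MixtureParams(0.5, 2.0, 1.0, 0.0, 1.0)
        f1, f0 = norm.pdf(1, 2, 1), norm.pdf(1, 0, 1)
        assert posterior(1.0, params) == pytest.approx(
            0.5 * f1 / (0.5 * f1 + 0.5 * f0), abs=1e-12
        )
        # x=1 is the equal-density midpoint, so this is also 0.5
        assert posterior(1.0, params) == pytest.approx(0.5, abs=1e-12)

    def test_limit_is_one_for_high_scores(self):
        params = MixtureParams(0.5, 2.0, 1.0, 0.0, 1.0)
        assert posterior(50.0, params) == pytest.approx(1.0, abs=1e-12)

    def test_equal_sigma_map_is_monotone(self):
        params = MixtureParams(0.3, 3.0, 1.2, 0.0, 1.2)
        x = np.linspace(-10, 10, 400)
        assert np.all(np.diff(posterior(x, params)) >= 0)

    def test_unequal_sigma_clamped_to_monotone_envelope(self):
        # wide null: raw posterior would fall again at extreme scores
        params = MixtureParams(0.5, 3.0, 1.0, 0.0, 3.0)
        x = np.linspace(-20, 30, 1000)
        p = posterior(x, params)
        assert np.all(np.diff(p) >= -1e-12)
        assert np.all((p >= 0) & (p <= 1))


class TestQvalues:
    def test_hand_enumerated_example(self):
        """Targets 5,4,3 above a single decoy at 2: all targets get q=0."""
        psms = [_psm(5), _psm(4), _psm(3), _psm(2, decoy=True)]
        q = qvalues_from_decoys(psms)
        assert list(q[:3]) == [0.0, 0.0, 0.0]
        # a target weaker than the decoy inherits FDR ≥ 1/4
        psms.append(_psm(1))
        q = qvalues_from_decoys(psms)
        assert q[4] >= 0.25

    def test_no_decoys_gives_zero_q(self):
        q = qvalues_from_decoys([_psm(3), _psm(2), _psm(1)])
        assert np.all(q == 0)

    def test_tied_scores_share_one_q(self):
        psms = [_psm(2.0), _psm(2.0, decoy=True), _psm(2.0), _psm(2.0, decoy=True)]
        q = qvalues_from_decoys(psms)
        assert len(set(q)) == 1

    def test_q_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(5)
        psms = [
            _psm(s, decoy=bool(d))
            for s, d in zip(rng.normal(2, 2, 400), rng.integers(0, 2, 400))
        ]
        q = qvalues_from_decoys(psms)
        scores = np.array([p.score for p in psms])
        order = np.argsort(-scores)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_zero_targets_is_an_error(self):
        with pytest.raises(ValueError, match="no target"):
            qvalues_from_decoys([_psm(1, decoy=True)])


class TestLocalFdr:
    def test_uniformly_mixed_decoys_match_count_ratio(self):
        """With decoys interleaved everywhere, lfdr ≈ D/T in every bin."""
        rng = np.random.default_rng(9)
        n = 4000
        psms = [
            _psm(s, decoy=bool(i % 4 == 0))
            for i, s in enumerate(rng.normal(0, 1, n))
        ]
        lfdr = local_fdr_binned(psms, n_bins=10)
        assert np.all(np.abs(lfdr - 1 / 3) < 0.15)  # D/T = 1000/3000

    def test_clean_top_bin_gets_zero(self):
        # decoys only at low scores; the top of the ranking is clean
        psms = [_psm(10 + i * 0.01, sid=f"t{i}") for i in range(100)]
        psms += [_psm(-10 + i * 0.01, decoy=True, sid=f"d{i}") for i in range(50)]
        psms += [_psm(-10 + i * 0.01 + 0.005, sid=f"u{i}") for i in range(50)]
        lfdr = local_fdr_binned(psms, n_bins=4)
        top = max(psms, key=lambda p: p.score)
        assert lfdr[psms.index(top)] == 0.0

    def test_non_increasing_in_score_and_bounded(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.normal(4, 1, 800), rng.normal(0, 1, 800)]
        decoys = np.r_[np.zeros(800, bool), np.arange(800) % 2 == 0]
        psms = [_psm(s, decoy=bool(d), sid=f"x{i}")
                for i, (s, d) in enumerate(zip(scores, decoys))]
        lfdr = local_fdr_binned(psms, n_bins=16)
        order = np.argsort([p.score for p in psms])
        assert np.all(np.diff(lfdr[order]) <= 1e-12)
        assert np.all((lfdr >= 0) & (lfdr <= 1))

    def test_count_weighted_mean_matches_global_fdr(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.normal(4, 1, 1000), rng.normal(0, 1, 1000)]
        decoys = np.r_[np.zeros(1000, bool), np.arange(1000) % 2 == 0]
        psms = [_psm(s, decoy=bool(d), sid=f"y{i}")
                for i, (s, d) in enumerate(zip(scores, decoys))]
        lfdr = local_fdr_binned(psms, n_bins=20)
        d_total = sum(p.is_decoy for p in psms)
        t_total = len(psms) - d_total
        # summing lfdr over targets estimates the number of false targets
        target_mean = np.mean([f for p, f in zip(psms, lfdr) if not p.is_decoy])
        assert target_mean == pytest.approx(d_total / t_total, rel=0.2)


class TestFilterAndRollup:
    CONFIG = PipelineConfig(seed=0)

    def test_counts_surviving_spectra_per_peptide(self):
        psms = [
            _psm(0, post=0.99, sid="a"),
            _psm(0, post=0.97, sid="b"),
            _psm(0, post=0.50, sid="c"),
            _psm(5, decoy=True, sid="d"),
        ]
        (pep,) = filter_and_rollup(psms, None, self.CONFIG)
        assert pep.spectral_count == 2
        assert pep.best_posterior == 0.99

    def test_mass_error_beyond_tolerance_dropped(self):
        psms = [_psm(0, post=0.99, ppm=12.0), _psm(5, decoy=True)]
        assert filter_and_rollup(psms, None, self.CONFIG) == []

    def test_decoy_with_high_posterior_dropped(self):
        psms = [_psm(9, decoy=True, post=0.99)]
        assert filter_and_rollup(psms, None, self.CONFIG) == []
        psms.append(_psm(9, post=0.99, pep="ACDEFK"))
        peps = filter_and_rollup(psms, None, self.CONFIG)
        assert [p.peptide_seq for p in peps] == ["ACDEFK"]
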