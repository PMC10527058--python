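"""Peptide-level scoring: mixture posteriors, decoy q-values, local FDR.

Search-engine discriminant scores are modelled as a two-component Gaussian
mixture

    f(x) = pi * N(x; mu1, sigma1^2) + (1 - pi) * N(x; mu0, sigma0^2)

where the first component describes correct identifications and the second
incorrect ones.  The parameters are fitted by EM; the posterior probability
that a PSM with score x is correct is

    p(x) = pi f1(x) / (pi f1(x) + (1 - pi) f0(x)).

Decoy matches provide a second, assumption-free error estimate: global
q-values by target-decoy competition and a binned local FDR smoothed by
isotonic regression.  Finally :func:`filter_and_rollup` applies the PSM
acceptance rules (posterior > threshold, |mass error| within tolerance,
decoys dropped) and rolls surviving spectra up to per-sample peptides with
spectral counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.isotonic import IsotonicRegression

from .formats_io import PipelineConfig, PsmRecord

_SIGMA_FLOOR = 1e-3
_EM_TOL = 1e-8
_EM_MAX_ITER = 500


@dataclass
class MixtureParams:
    """Fitted two-Gaussian score mixture (correct vs incorrect)."""

    pi_correct: float
    mu_correct: float
    sigma_correct: float
    mu_incorrect: float
    sigma_incorrect: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.sigma_correct <= 0 or self.sigma_incorrect <= 0:
            raise ValueError("mixture sigmas must be positive")
        if not (0.0 < self.pi_correct < 1.0):
            raise ValueError("pi_correct must lie in (0, 1)")


@dataclass(frozen=True)
class ScoredPeptide:
    """Per-(sample, peptide) evidence after PSM filtering."""

    sample_id: str
    peptide_seq: str
    best_posterior: float
    spectral_count: int
    qvalue: float = 0.0
    local_fdr: float = 0.0


def fit_score_mixture(
    scores: Sequence[float], decoy_flags: Sequence[bool]
) -> MixtureParams:
    """Fit the correct/incorrect score mixture by EM.

    Initialisation uses the decoys for the incorrect component and the top
    decile of target scores for the correct one.  Non-convergence within the
    iteration budget sets ``converged=False`` rather than raising.
    """
    x = np.asarray(scores, dtype=float)
    decoy = np.asarray(decoy_flags, dtype=bool)
    if x.size != decoy.size:
        raise ValueError("scores and decoy_flags must have equal length")
    if x.size < 50:
        raise ValueError(f"need ≥50 scores to fit the mixture, got {x.size}")
    if decoy.sum() < 5:
        raise ValueError(f"need ≥5 decoys to initialise, got {int(decoy.sum())}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: all scores equal")

    targets = x[~decoy]
    mu0 = float(np.mean(x[decoy]))
    s0 = max(float(np.std(x[decoy])), _SIGMA_FLOOR)
    top = targets[targets >= np.quantile(targets, 0.9)] if targets.size else x
    mu1 = float(np.mean(top))
    s1 = max(float(np.std(top)), _SIGMA_FLOOR)
    pi = 0.5

    trace: list[float] = []
    converged = False
    for _ in range(_EM_MAX_ITER):
        # E step
        log_f1 = norm.logpdf(x, mu1, s1) + np.log(pi)
        log_f0 = norm.logpdf(x, mu0, s0) + np.log1p(-pi)
        log_norm = np.logaddexp(log_f1, log_f0)
        resp = np.exp(log_f1 - log_norm)
        loglik = float(np.sum(log_norm))
        if trace and abs(loglik - trace[-1]) < _EM_TOL:
            trace.append(loglik)
            converged = True
            break
        trace.append(loglik)
        # M step
        w1 = resp.sum()
        w0 = x.size - w1
        pi = float(np.clip(w1 / x.size, 1e-6, 1 - 1e-6))
        mu1 = float(np.sum(resp * x) / max(w1, 1e-12))
        mu0 = float(np.sum((1 - resp) * x) / max(w0, 1e-12))
        s1 = max(float(np.sqrt(np.sum(resp * (x - mu1) ** 2) / max(w1, 1e-12))),
                 _SIGMA_FLOOR)
        s0 = max(float(np.sqrt(np.sum((1 - resp) * (x - mu0) ** 2) / max(w0, 1e-12))),
                 _SIGMA_FLOOR)

    if mu1 < mu0:  # relabel so the correct component sits on top
        mu1, mu0 = mu0, mu1
        s1, s0 = s0, s1
        pi = 1.0 - pi
    return MixtureParams(
        pi_correct=pi,
        mu_correct=mu1,
        sigma_correct=s1,
        mu_incorrect=mu0,
        sigma_incorrect=s0,
        loglik_trace=trace,
        converged=converged,
    )


def posterior(score, params: MixtureParams):
    """Posterior probability of correctness for one score (vectorised).

    With equal component variances the map is monotone increasing in score.
    With unequal variances the raw posterior is non-monotone (the wider
    component dominates in one tail); the returned value is clamped to the
    monotone non-decreasing envelope by holding it flat beyond the vertex of
    the quadratic log-odds, so a better score never gets a lower posterior.
    """
    x = np.asarray(score, dtype=float)
    pi, mu1, s1, mu0, s0 = (
        params.pi_correct,
        params.mu_correct,
        params.sigma_correct,
        params.mu_incorrect,
        params.sigma_incorrect,
    )
    if not np.isclose(s1, s0):
        # log-odds is quadratic: a x^2 + ...; vertex where d/dx = 0
        a = 0.5 * (1.0 / s0**2 - 1.0 / s1**2)
        b = mu1 / s1**2 - mu0 / s0**2
        vertex = -b / (2.0 * a)
        if a > 0:  # opens upward: decreasing left of vertex -> hold flat
            x = np.maximum(x, vertex)
        else:  # opens downward: decreasing right of vertex -> hold flat
            x = np.minimum(x, vertex)
    log_f1 = norm.logpdf(x, mu1, s1) + np.log(pi)
    log_f0 = norm.logpdf(x, mu0, s0) + np.log1p(-pi)
    p = np.exp(log_f1 - np.logaddexp(log_f1, log_f0))
    return float(p) if np.isscalar(score) else p


def qvalues_from_decoys(
    psms: Sequence[PsmRecord], decoy_ratio: float = 1.0
) -> np.ndarray:
    """Target-decoy q-values, aligned with the input order.

    Sorting by score descending, FDR(t) = decoy_ratio * D(t) / max(T(t), 1)
    over cumulative decoy/target counts; q is the running minimum taken from
    the weakest score upward.  Tied scores share one q.
    """
    scores = np.array([p.score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    if (~decoy).sum() == 0:
        raise ValueError("no target PSMs")
    order = np.argsort(-scores, kind="stable")
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    fdr = decoy_ratio * d_cum / np.maximum(t_cum, 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    # ties share the q of the last (most permissive) member of the tie block
    sorted_scores = scores[order]
    for start in np.flatnonzero(np.r_[True, np.diff(sorted_scores) != 0]):
        stop = start
        while stop + 1 < q.size and sorted_scores[stop + 1] == sorted_scores[start]:
            stop += 1
        q[start : stop + 1] = q[stop]
    out = np.empty_like(q)
    out[order] = q
    return out


def local_fdr_binned(
    psms: Sequence[PsmRecord], n_bins: int = 20, decoy_ratio: float = 1.0
) -> np.ndarray:
    """Binned decoy-based local FDR, isotonic in score, aligned with input.

    PSMs are split into ``n_bins`` equal-count score bins; the raw bin
    estimate decoy_ratio * D_bin / max(T_bin, 1) is made non-increasing in
    score by isotonic regression (bin-count weighted) and clipped to [0, 1].
    """
    scores = np.array([p.score for p in psms], dtype=float)
    decoy = np.array([p.is_decoy for p in psms], dtype=bool)
    if scores.size < n_bins * 5:
        raise ValueError(f"need ≥{n_bins * 5} PSMs for {n_bins} bins")
    order = np.argsort(scores, kind="stable")  # ascending
    bin_of_sorted = np.minimum(
        (np.arange(scores.size) * n_bins) // scores.size, n_bins - 1
    )
    bin_idx = np.empty(scores.size, dtype=int)
    bin_idx[order] = bin_of_sorted
    raw = np.zeros(n_bins)
    weight = np.zeros(n_bins)
    for b in range(n_bins):
        mask = bin_idx == b
        d = decoy[mask].sum()
        t = mask.sum() - d
        raw[b] = decoy_ratio * d / max(t, 1)
        weight[b] = mask.sum()
    iso = IsotonicRegression(increasing=False)  # lfdr falls as score rises
    smoothed = np.clip(iso.fit_transform(np.arange(n_bins), raw, sample_weight=weight), 0.0, 1.0)
    return smoothed[bin_idx]


def filter_and_rollup(
    psms: Sequence[PsmRecord],
    params: MixtureParams | None,
    config: PipelineConfig,
) -> list[ScoredPeptide]:
    """Apply the PSM acceptance rules and roll up to per-sample peptides.

    Decoys are dropped; PSMs with |mass error| beyond the tolerance or a
    posterior below the acceptance probability are dropped; each surviving
    (sample, peptide) pair becomes one :class:`ScoredPeptide` carrying the
    best posterior and the count of accepted spectra.

    Precomputed posteriors on the records take precedence; scores are pushed
    through ``params`` only where the posterior is missing.
    """
    targets = [p for p in psms if not p.is_decoy]
    if targets:
        q_all = qvalues_from_decoys(psms, config.decoy_ratio)
        q_by_id = {id(p): q for p, q in zip(psms, q_all)}
    else:
        q_by_id = {}
    lfdr_by_id: dict[int, float] = {}
    if len(psms) >= 100:  # enough PSMs for 20 equal-count bins
        lfdr_all = local_fdr_binned(psms, 20, config.decoy_ratio)
        lfdr_by_id = {id(p): f for p, f in zip(psms, lfdr_all)}
    best: dict[tuple[str, str], ScoredPeptide] = {}
    for psm in targets:
        if abs(psm.mass_error_ppm) > config.max_mass_error_ppm:
            continue
        post = psm.posterior
        if post is None:
            if params is None:
                raise ValueError(
                    f"PSM {psm.spectrum_id} has no posterior and no mixture "
                    "parameters were supplied"
                )
            post = float(posterior(psm.score, params))
        if post < config.peptide_prob_min:
            continue
        key = (psm.sample_id, psm.peptide_seq)
        q = float(q_by_id.get(id(psm), 0.0))
        lf = float(lfdr_by_id.get(id(psm), 0.0))
        prev = best.get(key)
        if prev is None:
            best[key] = ScoredPeptide(
                sample_id=psm.sample_id,
                peptide_seq=psm.peptide_seq,
                best_posterior=post,
                spectral_count=1,
                qvalue=q,
                local_fdr=lf,
            )
        else:
            best[key] = ScoredPeptide(
                sample_id=psm.sample_id,
                peptide_seq=psm.peptide_seq,
                best_posterior=max(prev.best_posterior, post),
                spectral_count=prev.spectral_count + 1,
                qvalue=min(prev.qvalue, q),
                local_fdr=min(prev.local_fdr, lf),
            )
    return sorted(best.values(), key=lambda s: (s.sample_id, s.peptide_seq))
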