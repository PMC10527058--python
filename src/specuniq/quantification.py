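"""Spectral-count quantitation.

Counts are normalised across samples (total-count scaling), screened for
quality outliers by regressing log10 SD on log10 mean across proteins and
flagging |standardised residual| > 3, and converted to cancer/control fold
changes with explicit infinite-fold semantics: a protein absent from every
control sample but present in cancer has an infinite fold change, which is
tracked separately from the finite ≥ 1.7-fold up-regulated set.  A
per-protein significance gate (two-factor linear model on log counts, or
Welch's t as a simpler alternative) marks proteins whose group difference
is statistically supported at the configured alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import PipelineConfig, SampleMeta

INFINITE = math.inf


@dataclass
class QuantRecord:
    gene_symbol: str
    mean_atrophic: float
    sd_atrophic: float
    mean_cancer: float
    sd_cancer: float
    log_mean: float
    log_sd: float
    fold_change: float  # math.inf encodes the infinite-fold case
    outlier: bool = False
    upregulated: bool = False
    p_gate: float = float("nan")
    gate_flagged: bool = False  # zero-variance fallback used


def normalize_counts(counts: pd.DataFrame, method: str = "total_count") -> pd.DataFrame:
    """Scale each sample to the grand mean library size (or pass through)."""
    if method == "none":
        return counts.astype(float)
    if method != "total_count":
        raise ValueError(f"unknown normalization method {method!r}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        zero = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero total counts: {zero}")
    return counts * (totals.mean() / totals)


def _group_samples(meta: list[SampleMeta]) -> tuple[list[str], list[str]]:
    atrophic = [m.sample_id for m in meta if m.group == "atrophic"]
    cancer = [m.sample_id for m in meta if m.group == "cancer"]
    return atrophic, cancer


def quant_table(
    counts: pd.DataFrame, meta: list[SampleMeta], config: PipelineConfig
) -> pd.DataFrame:
    """Per-protein summary statistics on normalised counts.

    Columns: group means/SDs (no pseudocount), and log10 mean/SD across all
    samples with the pseudocount (used by the outlier screen).
    """
    atrophic, cancer = _group_samples(meta)
    eps = config.pseudocount
    out = pd.DataFrame(index=counts.index)
    out["mean_atrophic"] = counts[atrophic].mean(axis=1)
    out["sd_atrophic"] = counts[atrophic].std(axis=1, ddof=1)
    out["mean_cancer"] = counts[cancer].mean(axis=1)
    out["sd_cancer"] = counts[cancer].std(axis=1, ddof=1)
    m = counts.mean(axis=1)
    s = counts.std(axis=1, ddof=1)
    out["log_mean"] = np.log10(m + eps)
    out["log_sd"] = np.log10(s + eps)
    return out


def exclude_outliers(records: pd.DataFrame, config: PipelineConfig) -> pd.Series:
    """Flag proteins off the log SD vs log mean trend.

    Ordinary least squares of log10(SD + eps) on log10(mean + eps) across
    proteins; a protein is an outlier iff its |standardised residual|
    exceeds ``config.outlier_sd``.  The alternative ``global`` mode flags
    proteins whose log mean lies more than ``outlier_sd`` SDs from the
    across-protein average.  With fewer than 10 proteins the screen is
    skipped with a warning and nothing is flagged.
    """
    if len(records) < 10:
        warnings.warn("fewer than 10 proteins: outlier screen skipped")
        return pd.Series(False, index=records.index)
    x = records["log_mean"].to_numpy()
    if config.outlier_mode == "global":
        z = (x - x.mean()) / max(x.std(ddof=1), 1e-12)
        return pd.Series(np.abs(z) > config.outlier_sd, index=records.index)
    y = records["log_sd"].to_numpy()
    if np.ptp(x) < 1e-12:  # all means identical: no trend to regress on
        return pd.Series(False, index=records.index)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    scale = resid.std(ddof=2)
    if scale < 1e-12:
        return pd.Series(False, index=records.index)
    return pd.Series(np.abs(resid / scale) > config.outlier_sd, index=records.index)


def fold_changes(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Cancer/control fold changes with infinite-fold handling.

    FC = mean_cancer / mean_atrophic when the control mean is positive;
    infinite when only the cancer mean is positive; proteins absent from
    both groups are excluded (NaN fold change).  ``upregulated`` marks a
    finite FC at or above the threshold — infinite-fold proteins are the
    presence/absence signal and are not counted among the finite
    up-regulated set.
    """
    out = records.copy()
    ma = out["mean_atrophic"].to_numpy(dtype=float)
    mc = out["mean_cancer"].to_numpy(dtype=float)
    fc = np.full(len(out), np.nan)
    finite = ma > 0
    fc[finite] = mc[finite] / ma[finite]
    fc[(ma == 0) & (mc > 0)] = INFINITE
    out["fold_change"] = fc
    out["upregulated"] = np.isfinite(fc) & (fc >= config.fold_change_min)
    return out


def significance_gate(
    counts: pd.DataFrame,
    meta: list[SampleMeta],
    config: PipelineConfig,
    method: str | None = None,
) -> pd.DataFrame:
    """Per-protein p-value for the cancer/control difference on log counts.

    ``two_way_anova`` fits log10(count + eps) on a disease-status factor and
    an orthogonal subtype contrast (0 for control, -1 endometrioid, +1
    serous) and returns the status-effect p; ``welch_log`` runs Welch's
    t-test on the log counts.  Residual (or group) variances are floored at
    eps^2 so all-zero proteins yield a defined, non-significant p; such rows
    are flagged.  The gate passes iff p < ``config.enrichment_alpha``.
    """
    method = method or config.gate_method
    eps = config.pseudocount
    sample_ids = [m.sample_id for m in meta]
    y_all = np.log10(counts[sample_ids].to_numpy(dtype=float) + eps)
    status = np.array([1.0 if m.group == "cancer" else 0.0 for m in meta])
    contrast = np.array(
        [{"none": 0.0, "type1": -1.0, "type2": 1.0}[m.subtype] for m in meta]
    )
    n = len(meta)
    ps = np.ones(len(counts))
    flagged = np.zeros(len(counts), dtype=bool)
    if method == "two_way_anova":
        X = np.column_stack([np.ones(n), status, contrast])
        dof = n - X.shape[1]
        XtX_inv = np.linalg.inv(X.T @ X)
        hat = XtX_inv @ X.T
        for i, y in enumerate(y_all):
            beta = hat @ y
            resid = y - X @ beta
            s2 = float(resid @ resid) / dof
            if s2 <= 0.0:  # degenerate row: fall back to the pseudocount scale
                s2 = eps**2
                flagged[i] = True
            se = math.sqrt(s2 * XtX_inv[1, 1])
            t = beta[1] / se
            ps[i] = 2.0 * stats.t.sf(abs(t), dof)
    elif method == "welch_log":
        a_idx = [i for i, m in enumerate(meta) if m.group == "atrophic"]
        c_idx = [i for i, m in enumerate(meta) if m.group == "cancer"]
        for i, y in enumerate(y_all):
            ya, yc = y[a_idx], y[c_idx]
            va, vc = ya.var(ddof=1), yc.var(ddof=1)
            if va == 0.0 and vc == 0.0:
                if np.isclose(ya.mean(), yc.mean()):
                    ps[i] = 1.0
                    flagged[i] = True
                    continue
                va = vc = eps**2
                flagged[i] = True
            t, df, p = welch_from_moments(
                ya.mean(), va, len(ya), yc.mean(), vc, len(yc)
            )
            ps[i] = p
    else:
        raise ValueError(f"unknown gate method {method!r}")
    return pd.DataFrame(
        {
            "p_gate": ps,
            "gate_pass": ps < config.enrichment_alpha,
            "gate_flagged": flagged,
        },
        index=counts.index,
    )


def welch_from_moments(m1, v1, n1, m2, v2, n2) -> tuple[float, float, float]:
    """Welch t statistic, Welch–Satterthwaite df and two-tailed p.

    The p-value is evaluated through the regularised incomplete beta
    function, P(|T| > t) = I_{df/(df + t^2)}(df/2, 1/2).
    """
    from scipy.special import betainc

    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return 0.0, float(n1 + n2 - 2), 1.0
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return float(t), float(df), min(max(p, 0.0), 1.0)


def quantify(
    counts: pd.DataFrame, meta: list[SampleMeta], config: PipelineConfig
) -> pd.DataFrame:
    """Full quantitation: normalise, summarise, screen, fold-change, gate."""
    normed = normalize_counts(counts, config.normalization)
    table = quant_table(normed, meta, config)
    table["outlier"] = exclude_outliers(table, config)
    table = fold_changes(table, config)
    gate = significance_gate(normed, meta, config)
    return table.join(gate)
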