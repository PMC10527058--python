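"""Patient-characteristics statistics: group summaries and Welch's t-test.

The two study arms are small (four patients each) and their dispersions
differ, so the default two-sample comparison is the unequal-variance
(Welch) t-test with Welch–Satterthwaite degrees of freedom; the pooled
Student form is available by flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import betainc

from .formats_io import SampleMeta


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    mean: float
    sd: float  # sample SD (n-1); 0 with degenerate=True when n == 1
    degenerate: bool = False


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def _values(meta: Sequence[SampleMeta], field: str, group: str) -> np.ndarray:
    if field not in ("age", "bmi"):
        raise ValueError(f"unknown field {field!r}")
    vals = []
    for m in meta:
        if m.group != group:
            continue
        v = getattr(m, field)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"sample {m.sample_id}: missing {field}")
        vals.append(float(v))
    return np.asarray(vals)


def summarize(meta: Sequence[SampleMeta], field: str) -> dict[str, GroupSummary]:
    """Per-group mean and sample SD of a patient characteristic."""
    out: dict[str, GroupSummary] = {}
    for group in ("atrophic", "cancer"):
        x = _values(meta, field, group)
        if x.size == 0:
            raise ValueError(f"no samples in group {group}")
        if x.size == 1:
            out[group] = GroupSummary(group, 1, float(x[0]), 0.0, degenerate=True)
        else:
            out[group] = GroupSummary(
                group, int(x.size), float(x.mean()), float(x.std(ddof=1))
            )
    return out


def welch_t(
    meta: Sequence[SampleMeta], field: str, pooled: bool = False
) -> WelchResult:
    """Two-tailed two-sample t-test between the study arms.

    Welch by default; ``pooled=True`` gives the classic equal-variance
    Student form.  The p-value comes from the regularised incomplete beta
    function: P(|T| > t) = I_{df/(df + t^2)}(df/2, 1/2).
    """
    x = _values(meta, field, "atrophic")
    y = _values(meta, field, "cancer")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("need ≥2 samples per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if np.isclose(x.mean(), y.mean()):
            return WelchResult(0.0, float(n1 + n2 - 2), 1.0)
        return WelchResult(math.inf, float(n1 + n2 - 2), 0.0)
    if pooled:
        df = float(n1 + n2 - 2)
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        se = math.sqrt(se2)
    t = (x.mean() - y.mean()) / se
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return WelchResult(float(t), float(df), min(max(p, 0.0), 1.0))
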