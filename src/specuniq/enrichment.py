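"""Annotation-set over-representation and the network membership report.

Given a query set of gene symbols (e.g. the cancer-only proteins), each
annotation term is tested for over-representation with the one-sided
hypergeometric tail

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the term size within the universe, n the
query size and k the overlap.  P-values are adjusted across terms by
Benjamini–Hochberg.  :func:`network_table` renders the per-term membership
report with subtype superscripts (1 = endometrioid-only, 2 = serous-only,
B = both), listing proteins covered by no term under an ``unmapped`` row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .formats_io import AnnotationSet


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query ∩ term
    K: int  # term ∩ universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    q_value: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def hypergeom_enrich(
    query: set[str],
    sets: Sequence[AnnotationSet],
    universe: set[str],
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation, BH-adjusted, sorted by p.

    Query symbols outside the universe are trimmed with a warning; term
    members are intersected with the universe before counting.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query symbol(s) outside the universe were trimmed"
        )
    q = query & universe
    N, n = len(universe), len(q)
    raw: list[tuple[AnnotationSet, int, int, float]] = []
    for s in sets:
        members = s.members & universe
        K = len(members)
        k = len(q & members)
        # survival function at k-1 is the inclusive upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        raw.append((s, k, K, min(p, 1.0)))
    qvals = bh_adjust([r[3] for r in raw])
    results = [
        EnrichmentResult(s.term_id, s.term_name, k, K, n, N, p, float(qv))
        for (s, k, K, p), qv in zip(raw, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def network_table(
    proteins: Sequence[str],
    subtype_of: Mapping[str, str],
    sets: Sequence[AnnotationSet],
) -> list[tuple[str, str]]:
    """Per-term membership rows with subtype superscript marks.

    Returns ``(term_name, rendered members)`` rows, one per annotation term
    that intersects ``proteins``, each member rendered as ``SYMBOL ^mark``
    with mark 1 (endometrioid-only), 2 (serous-only) or B (both).  Proteins
    in no term are gathered under a final ``unmapped`` row.
    """
    marks = {"type1_only": "1", "type2_only": "2", "both": "B"}

    def render(symbol: str) -> str:
        mark = marks.get(subtype_of.get(symbol, "both"), "B")
        return f"{symbol} ^{mark}"

    rows: list[tuple[str, str]] = []
    mapped: set[str] = set()
    for s in sets:
        members = sorted(set(proteins) & s.members)
        if members:
            mapped.update(members)
            rows.append((s.term_name, "; ".join(render(m) for m in members)))
    unmapped = sorted(set(proteins) - mapped)
    if unmapped:
        rows.append(("unmapped", "; ".join(render(m) for m in unmapped)))
    return rows
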