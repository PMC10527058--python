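"""Presence/absence partitioning and novelty categorisation.

The core of the analysis is deliberately simple: instead of asking "how
much more of protein X does the tumour make?", each protein is called
present or absent per study arm from its per-sample acceptance flags (the
all-or-nothing reading), giving a three-way partition — control-only,
cancer-only, and common to both.  Cancer-only entries are deduplicated to
one accession per gene symbol, attributed to the histological subtype(s)
whose samples carry them (endometrioid = type 1, serous = type 2), and
screened against curated knowledge lists so that only symbols never linked
to this cancer — or to any cancer — remain as novel candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .formats_io import KnowledgeBase, PipelineConfig, SampleMeta

SET_ATROPHIC_ONLY = "atrophic_only"
SET_CANCER_ONLY = "cancer_only"
SET_COMMON = "common"

CAT_KNOWN_EC = "known_ec"
CAT_KNOWN_OTHER = "known_other_cancer"
CAT_NOVEL_LIT = "novel_with_literature"
CAT_NOVEL_NOLIT = "novel_no_literature"


@dataclass
class PartitionResult:
    atrophic_only: frozenset[str]
    cancer_only: frozenset[str]
    common: frozenset[str]
    duplicates_removed: list[tuple[str, list[str]]] = field(default_factory=list)
    subtype_of: dict[str, str] = field(default_factory=dict)
    category_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = (self.atrophic_only, self.cancer_only, self.common)
        total = len(self.atrophic_only | self.cancer_only | self.common)
        if sum(len(s) for s in sets) != total:
            raise ValueError("partition sets must be pairwise disjoint")

    @property
    def n_present(self) -> int:
        """Symbols present in at least one arm (the bookkeeping total)."""
        return len(self.atrophic_only) + len(self.cancer_only) + len(self.common)


def presence_call(
    accepted_row: Mapping[str, bool] | pd.Series,
    group_samples: Sequence[str],
    config: PipelineConfig,
) -> bool:
    """Present in a group iff accepted in ≥ presence_min_samples of it."""
    if not group_samples:
        raise ValueError("unknown or empty sample group")
    hits = sum(bool(accepted_row[s]) for s in group_samples)
    return hits >= config.presence_min_samples


def venn_partition(
    accepted: pd.DataFrame,
    meta: Sequence[SampleMeta],
    config: PipelineConfig,
    symbol_of: Mapping[str, str] | None = None,
) -> PartitionResult:
    """Three-way presence partition at the gene-symbol level.

    ``accepted`` has one row per protein group and one boolean column per
    sample.  Rows sharing a gene symbol are OR-combined before the calls, so
    the three sets are disjoint by construction.  Symbols present in neither
    arm are dropped.
    """
    atrophic = [m.sample_id for m in meta if m.group == "atrophic"]
    cancer = [m.sample_id for m in meta if m.group == "cancer"]
    symbol_of = symbol_of or {k: k for k in accepted.index}
    by_symbol = accepted.groupby(
        accepted.index.map(lambda k: symbol_of.get(k, k))
    ).any()
    a_only, c_only, common = set(), set(), set()
    for symbol, row in by_symbol.iterrows():
        in_a = presence_call(row, atrophic, config)
        in_c = presence_call(row, cancer, config)
        if in_a and in_c:
            common.add(symbol)
        elif in_a:
            a_only.add(symbol)
        elif in_c:
            c_only.add(symbol)
    return PartitionResult(
        atrophic_only=frozenset(a_only),
        cancer_only=frozenset(c_only),
        common=frozenset(common),
    )


def deduplicate(
    entries: Sequence[tuple[str, str, int]],
) -> tuple[set[str], list[tuple[str, list[str]]]]:
    """Collapse accession-level entries to one per gene symbol.

    ``entries`` are (accession, gene_symbol, total_spectra).  The keeper is
    the accession with the most total spectra, ties broken lexicographically;
    dropped accessions are logged per symbol.
    """
    by_symbol: dict[str, list[tuple[str, int]]] = {}
    for acc, sym, spectra in entries:
        by_symbol.setdefault(sym, []).append((acc, spectra))
    kept: set[str] = set()
    log: list[tuple[str, list[str]]] = []
    for sym in sorted(by_symbol):
        ranked = sorted(by_symbol[sym], key=lambda t: (-t[1], t[0]))
        kept.add(sym)
        dropped = [acc for acc, _ in ranked[1:]]
        if dropped:
            log.append((sym, dropped))
    return kept, log


def subtype_attribution(
    accepted: pd.DataFrame,
    meta: Sequence[SampleMeta],
    symbols: Sequence[str],
    config: PipelineConfig,
    symbol_of: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Attribute cancer-associated symbols to type 1 / type 2 / both.

    A symbol is ``type1_only`` when present (per presence_min_samples) in
    the endometrioid samples and absent from the serous ones; ``type2_only``
    symmetrically; ``both`` otherwise (including presence in both subtypes).
    """
    t1 = [m.sample_id for m in meta if m.subtype == "type1"]
    t2 = [m.sample_id for m in meta if m.subtype == "type2"]
    symbol_of = symbol_of or {k: k for k in accepted.index}
    by_symbol = accepted.groupby(
        accepted.index.map(lambda k: symbol_of.get(k, k))
    ).any()
    out: dict[str, str] = {}
    for symbol in symbols:
        if symbol not in by_symbol.index:
            continue
        row = by_symbol.loc[symbol]
        in_t1 = presence_call(row, t1, config)
        in_t2 = presence_call(row, t2, config)
        if in_t1 and not in_t2:
            out[symbol] = "type1_only"
        elif in_t2 and not in_t1:
            out[symbol] = "type2_only"
        else:
            out[symbol] = "both"
    return out


def categorize_novelty(
    cancer_only: Sequence[str] | frozenset[str], kb: KnowledgeBase
) -> dict[str, str]:
    """Sequential-elimination categories for cancer-only symbols.

    Precedence: already reported in this cancer > reported in another cancer
    > unreported but with functional literature > no literature at all.
    Only the last two are novel candidates.
    """
    out: dict[str, str] = {}
    for symbol in cancer_only:
        if symbol in kb.known_ec:
            out[symbol] = CAT_KNOWN_EC
        elif symbol in kb.known_other_cancer:
            out[symbol] = CAT_KNOWN_OTHER
        elif symbol in kb.has_literature:
            out[symbol] = CAT_NOVEL_LIT
        else:
            out[symbol] = CAT_NOVEL_NOLIT
    return out


def partition_and_categorize(
    accepted: pd.DataFrame,
    counts: pd.DataFrame,
    meta: Sequence[SampleMeta],
    kb: KnowledgeBase,
    config: PipelineConfig,
    symbol_of: Mapping[str, str] | None = None,
) -> PartitionResult:
    """Run the full partition stage: venn, dedup, subtype, novelty."""
    result = venn_partition(accepted, meta, config, symbol_of)
    symbol_of = symbol_of or {k: k for k in accepted.index}
    entries = [
        (key, symbol_of.get(key, key), int(counts.loc[key].sum()))
        for key in accepted.index
        if symbol_of.get(key, key) in result.cancer_only
    ]
    deduped, log = deduplicate(entries)
    assert deduped == set(result.cancer_only)
    cancer_assoc = sorted(result.cancer_only | result.common)
    subtype = subtype_attribution(accepted, meta, cancer_assoc, config, symbol_of)
    categories = categorize_novelty(result.cancer_only, kb)
    return PartitionResult(
        atrophic_only=result.atrophic_only,
        cancer_only=result.cancer_only,
        common=result.common,
        duplicates_removed=log,
        subtype_of=subtype,
        category_of=categories,
    )
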