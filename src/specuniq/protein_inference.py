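"""Protein inference: peptide mapping, probabilities, parsimony grouping.

Accepted peptides are mapped onto the protein database by exact substring
search with isoleucine/leucine treated as equivalent (they are isobaric and
indistinguishable by MS/MS).  Protein-level probability combines distinct
peptide posteriors with a noisy-OR product, P = 1 - prod(1 - p_i).  Shared
peptides are resolved by the principles of parsimony:

1. proteins with identical accepted-peptide sets merge into one
   indistinguishable group;
2. proteins whose peptide set is a strict subset of another's are subsumed;
3. remaining proteins enter a greedy minimal set cover, ties broken by
   (more distinct peptides, more total spectra, lexicographic accession),
   and every peptide's spectra are credited to the single covering group
   that claimed it first — counts stay integral and nothing is counted
   twice;
4. clusters are the connected components of the peptide-sharing graph.

A group is accepted in a sample only when its protein probability meets the
threshold AND it has the minimum number of distinct peptides there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import PipelineConfig, ProteinSeq
from .ident_scoring import ScoredPeptide


def _il_collapse(seq: str) -> str:
    return seq.replace("L", "I")


@dataclass
class PeptideProteinMap:
    """Bidirectional peptide ↔ protein (target accession) mapping."""

    peptide_to_proteins: dict[str, frozenset[str]]
    protein_to_peptides: dict[str, frozenset[str]]
    orphans: frozenset[str]  # accepted peptides matching no target protein

    def __post_init__(self) -> None:
        for pep, accs in self.peptide_to_proteins.items():
            for acc in accs:
                assert pep in self.protein_to_peptides[acc]


@dataclass
class ProteinGroup:
    group_id: str
    representative_accession: str
    member_accessions: frozenset[str]
    gene_symbol: str
    peptides: frozenset[str]  # peptides credited to this group
    peptides_per_sample: dict[str, frozenset[str]] = field(default_factory=dict)
    counts_per_sample: dict[str, int] = field(default_factory=dict)
    protein_prob_per_sample: dict[str, float] = field(default_factory=dict)
    accepted_per_sample: dict[str, bool] = field(default_factory=dict)
    cluster_id: int = 0


def map_peptides(
    peptides: Iterable[ScoredPeptide] | Iterable[str],
    db: Sequence[ProteinSeq],
) -> PeptideProteinMap:
    """Map peptide sequences to every target protein containing them.

    Matching is exact substring with I/L equivalence.  Peptides matching
    only decoy entries are discarded; peptides matching nothing are
    collected in the ``orphans`` set (reported, not fatal).
    """
    if not db:
        raise ValueError("empty protein database")
    pep_seqs = sorted(
        {p.peptide_seq if isinstance(p, ScoredPeptide) else p for p in peptides}
    )
    targets = [p for p in db if not p.is_decoy]
    collapsed = [(p, _il_collapse(p.sequence)) for p in targets]
    pep_to_prot: dict[str, set[str]] = {}
    orphans: set[str] = set()
    for pep in pep_seqs:
        needle = _il_collapse(pep)
        hits = {p.accession for p, seq in collapsed if needle in seq}
        if hits:
            pep_to_prot[pep] = hits
        else:
            orphans.add(pep)
    prot_to_pep: dict[str, set[str]] = {}
    for pep, accs in pep_to_prot.items():
        for acc in accs:
            prot_to_pep.setdefault(acc, set()).add(pep)
    return PeptideProteinMap(
        peptide_to_proteins={k: frozenset(v) for k, v in pep_to_prot.items()},
        protein_to_peptides={k: frozenset(v) for k, v in prot_to_pep.items()},
        orphans=frozenset(orphans),
    )


def protein_probability(peptide_posteriors: Sequence[float]) -> float:
    """Noisy-OR protein probability over distinct-peptide posteriors."""
    if len(peptide_posteriors) == 0:
        return 0.0
    p = np.asarray(peptide_posteriors, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("peptide posteriors must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def _greedy_cover(
    peptide_sets: Mapping[str, frozenset[str]],
    spectra_totals: Mapping[str, int],
) -> tuple[list[str], dict[str, str]]:
    """Greedy minimal set cover; returns (chosen accessions, peptide→owner)."""
    uncovered: set[str] = set().union(*peptide_sets.values())
    chosen: list[str] = []
    owner: dict[str, str] = {}
    remaining = dict(peptide_sets)
    while uncovered:
        best_acc = min(
            remaining,
            key=lambda a: (
                -len(remaining[a] & uncovered),
                -len(remaining[a]),
                -spectra_totals.get(a, 0),
                a,
            ),
        )
        gain = remaining[best_acc] & uncovered
        if not gain:
            break
        for pep in gain:
            owner[pep] = best_acc
        uncovered -= gain
        chosen.append(best_acc)
        del remaining[best_acc]
    return chosen, owner


def parsimony_groups(
    pmap: PeptideProteinMap,
    peptides: Sequence[ScoredPeptide],
    db: Sequence[ProteinSeq],
    config: PipelineConfig,
) -> list[ProteinGroup]:
    """Resolve shared peptides into parsimony protein groups.

    See the module docstring for the four rules.  Per-sample acceptance
    (probability AND two-peptide rule) is filled in on each group.
    """
    symbol_of = {p.accession: p.gene_symbol for p in db}
    by_pep: dict[str, list[ScoredPeptide]] = {}
    for sp in peptides:
        if sp.peptide_seq in pmap.peptide_to_proteins:
            by_pep.setdefault(sp.peptide_seq, []).append(sp)

    pep_total_spectra = {
        pep: sum(sp.spectral_count for sp in sps) for pep, sps in by_pep.items()
    }
    prot_spectra = {
        acc: sum(pep_total_spectra.get(p, 0) for p in peps)
        for acc, peps in pmap.protein_to_peptides.items()
    }

    # rule 1: merge indistinguishable proteins (identical peptide sets)
    members_by_set: dict[frozenset[str], list[str]] = {}
    for acc, peps in pmap.protein_to_peptides.items():
        members_by_set.setdefault(peps, []).append(acc)
    reps: dict[str, frozenset[str]] = {}  # representative -> peptide set
    members_of: dict[str, frozenset[str]] = {}
    for peps, accs in members_by_set.items():
        rep = min(accs)
        reps[rep] = peps
        members_of[rep] = frozenset(accs)

    # rule 2: drop strict subsets (subsumed proteins)
    rep_list = sorted(reps)
    subsumed = {
        r
        for r in rep_list
        if any(reps[r] < reps[o] for o in rep_list if o != r)
    }
    survivors = {r: reps[r] for r in rep_list if r not in subsumed}

    # rule 3: greedy cover assigns each peptide to one owning group
    chosen, owner = _greedy_cover(survivors, prot_spectra)

    # rule 4: clusters = connected components of the peptide-sharing graph
    cluster_of = _cluster_components(survivors)

    groups: list[ProteinGroup] = []
    samples = sorted({sp.sample_id for sp in peptides})
    for i, rep in enumerate(sorted(chosen)):
        owned = frozenset(p for p, a in owner.items() if a == rep)
        peps_per_sample: dict[str, frozenset[str]] = {}
        counts: dict[str, int] = {}
        probs: dict[str, float] = {}
        accepted: dict[str, bool] = {}
        for s in samples:
            sps = [sp for pep in owned for sp in by_pep.get(pep, [])
                   if sp.sample_id == s]
            peps_here = frozenset(sp.peptide_seq for sp in sps)
            peps_per_sample[s] = peps_here
            counts[s] = sum(sp.spectral_count for sp in sps)
            probs[s] = protein_probability([sp.best_posterior for sp in sps])
            accepted[s] = (
                probs[s] >= config.protein_prob_min
                and len(peps_here) >= config.min_peptides
            )
        groups.append(
            ProteinGroup(
                group_id=f"G{i + 1:05d}",
                representative_accession=rep,
                member_accessions=members_of[rep],
                gene_symbol=symbol_of.get(rep, rep),
                peptides=owned,
                peptides_per_sample=peps_per_sample,
                counts_per_sample=counts,
                protein_prob_per_sample=probs,
                accepted_per_sample=accepted,
                cluster_id=cluster_of[rep],
            )
        )
    return groups


def _cluster_components(peptide_sets: Mapping[str, frozenset[str]]) -> dict[str, int]:
    """Connected components of the protein–peptide sharing graph."""
    parent = {acc: acc for acc in peptide_sets}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    by_pep: dict[str, str] = {}
    for acc in sorted(peptide_sets):
        for pep in peptide_sets[acc]:
            if pep in by_pep:
                ra, rb = find(acc), find(by_pep[pep])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
            else:
                by_pep[pep] = acc
    roots = sorted({find(a) for a in peptide_sets})
    root_id = {r: i + 1 for i, r in enumerate(roots)}
    return {a: root_id[find(a)] for a in peptide_sets}


def accepted_matrix(
    groups: Sequence[ProteinGroup], samples: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Presence/count matrices keyed by gene symbol.

    Returns ``(accepted, counts, symbol_of)`` where the DataFrames have one
    row per group (indexed by gene symbol, disambiguated with the
    representative accession when a symbol recurs) and one column per
    sample, and ``symbol_of`` maps each row key back to its gene symbol.
    """
    if not groups:
        empty = pd.DataFrame(columns=list(samples))
        return empty.astype(bool), empty.astype(float), {}
    index = [g.gene_symbol for g in groups]
    if len(set(index)) < len(index):  # disambiguate duplicated symbols
        index = [
            f"{g.gene_symbol}|{g.representative_accession}" for g in groups
        ]
    symbol_of = {key: g.gene_symbol for key, g in zip(index, groups)}
    accepted = pd.DataFrame(
        [[g.accepted_per_sample.get(s, False) for s in samples] for g in groups],
        index=index,
        columns=list(samples),
        dtype=bool,
    )
    counts = pd.DataFrame(
        [[g.counts_per_sample.get(s, 0) for s in samples] for g in groups],
        index=index,
        columns=list(samples),
        dtype=float,
    )
    return accepted, counts, symbol_of
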