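"""End-to-end orchestration: score → infer → quantify → partition → enrich.

:func:`run_pipeline` is the in-memory entry point used by the tests and the
simulator-driven acceptance run; :func:`run_all` is the file-based wrapper
behind ``specuniq run`` that reads every input format, writes the per-stage
TSVs and the run manifest, and fails loudly on any stage error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import (
    cohort_stats,
    enrichment as enrichment_mod,
    ident_scoring,
    partition_novelty,
    protein_inference,
    quantification,
)
from .formats_io import (
    AnnotationSet,
    KnowledgeBase,
    PipelineConfig,
    ProteinSeq,
    PsmRecord,
    SampleMeta,
    read_fasta,
    read_gmt,
    read_psm_table,
    read_sample_sheet,
)


@dataclass
class PipelineResult:
    """All in-memory stage outputs of one run."""

    mixture: ident_scoring.MixtureParams | None
    peptides: list[ident_scoring.ScoredPeptide]
    groups: list[protein_inference.ProteinGroup]
    accepted: pd.DataFrame
    counts: pd.DataFrame
    symbol_of: dict[str, str]
    quant: pd.DataFrame
    partition: partition_novelty.PartitionResult
    enrichment: list[enrichment_mod.EnrichmentResult]
    network: list[tuple[str, str]]
    qvalues: np.ndarray | None
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    psms: Sequence[PsmRecord],
    fasta: Sequence[ProteinSeq],
    samples: Sequence[SampleMeta],
    kb: KnowledgeBase,
    annotations: Sequence[AnnotationSet] | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every stage on in-memory inputs and return all stage outputs."""
    manifest: dict = {"config": dataclasses.asdict(config), "counts": {}}
    counts_log = manifest["counts"]
    counts_log["n_psms"] = len(psms)
    counts_log["n_decoy_psms"] = sum(p.is_decoy for p in psms)

    # --- scoring ------------------------------------------------------------
    needs_fit = any(p.posterior is None and not p.is_decoy for p in psms)
    mixture = None
    if needs_fit:
        mixture = ident_scoring.fit_score_mixture(
            [p.score for p in psms], [p.is_decoy for p in psms]
        )
    qvalues = ident_scoring.qvalues_from_decoys(psms, config.decoy_ratio)
    peptides = ident_scoring.filter_and_rollup(psms, mixture, config)
    counts_log["n_peptides_accepted"] = len({p.peptide_seq for p in peptides})
    counts_log["n_spectra_accepted"] = int(
        sum(p.spectral_count for p in peptides)
    )

    # --- inference ----------------------------------------------------------
    pmap = protein_inference.map_peptides(peptides, fasta)
    groups = protein_inference.parsimony_groups(pmap, peptides, fasta, config)
    sample_ids = [m.sample_id for m in samples]
    accepted, counts, symbol_of = protein_inference.accepted_matrix(
        groups, sample_ids
    )
    counts_log["n_protein_groups"] = len(groups)
    counts_log["n_orphan_peptides"] = len(pmap.orphans)

    # --- quantification (gene-symbol level) ----------------------------------
    counts_sym = counts.groupby(counts.index.map(symbol_of.get)).sum()
    quant = quantification.quantify(counts_sym, list(samples), config)
    counts_log["n_upregulated"] = int(quant["upregulated"].sum())
    counts_log["n_infinite_fold"] = int(np.isinf(quant["fold_change"]).sum())
    counts_log["n_outliers"] = int(quant["outlier"].sum())

    # --- partition & novelty --------------------------------------------------
    partition = partition_novelty.partition_and_categorize(
        accepted, counts, list(samples), kb, config, symbol_of
    )
    counts_log["n_atrophic_only"] = len(partition.atrophic_only)
    counts_log["n_cancer_only"] = len(partition.cancer_only)
    counts_log["n_common"] = len(partition.common)
    novel = [
        s
        for s, c in partition.category_of.items()
        if c in (partition_novelty.CAT_NOVEL_LIT, partition_novelty.CAT_NOVEL_NOLIT)
    ]
    counts_log["n_novel"] = len(novel)
    counts_log["n_novel_with_literature"] = sum(
        partition.category_of[s] == partition_novelty.CAT_NOVEL_LIT for s in novel
    )
    # bookkeeping identity: disjoint sets sum to the symbols present anywhere
    assert partition.n_present == (
        counts_log["n_atrophic_only"]
        + counts_log["n_cancer_only"]
        + counts_log["n_common"]
    )

    # --- enrichment -----------------------------------------------------------
    enrich_results: list[enrichment_mod.EnrichmentResult] = []
    network: list[tuple[str, str]] = []
    if annotations:
        universe = set(
            partition.atrophic_only | partition.cancer_only | partition.common
        )
        enrich_results = enrichment_mod.hypergeom_enrich(
            set(partition.cancer_only), list(annotations), universe
        )
        network = enrichment_mod.network_table(
            sorted(partition.cancer_only), partition.subtype_of, list(annotations)
        )
    else:
        manifest["warnings"] = ["no annotation sets supplied; enrichment skipped"]

    return PipelineResult(
        mixture=mixture,
        peptides=peptides,
        groups=groups,
        accepted=accepted,
        counts=counts,
        symbol_of=symbol_of,
        quant=quant,
        partition=partition,
        enrichment=enrich_results,
        network=network,
        qvalues=qvalues,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# file-based runner
# ---------------------------------------------------------------------------


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_outputs(result: PipelineResult, outdir) -> dict[str, str]:
    """Write every stage table under ``outdir``; returns name → path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    pep_df = pd.DataFrame(
        [dataclasses.asdict(p) for p in result.peptides]
    )
    paths["scored_peptides"] = str(outdir / "scored_peptides.tsv")
    pep_df.to_csv(paths["scored_peptides"], sep="\t", index=False)

    rows = []
    for g in result.groups:
        rows.append(
            {
                "group_id": g.group_id,
                "representative": g.representative_accession,
                "members": ";".join(sorted(g.member_accessions)),
                "gene_symbol": g.gene_symbol,
                "cluster_id": g.cluster_id,
                **{f"count_{s}": c for s, c in g.counts_per_sample.items()},
                **{
                    f"prob_{s}": round(p, 6)
                    for s, p in g.protein_prob_per_sample.items()
                },
                **{f"accepted_{s}": a for s, a in g.accepted_per_sample.items()},
            }
        )
    paths["groups"] = str(outdir / "groups.tsv")
    pd.DataFrame(rows).to_csv(paths["groups"], sep="\t", index=False)

    paths["quant"] = str(outdir / "quant.tsv")
    result.quant.rename_axis("gene_symbol").to_csv(paths["quant"], sep="\t")

    part = result.partition
    part_rows = []
    for name, symbols in (
        ("atrophic_only", part.atrophic_only),
        ("cancer_only", part.cancer_only),
        ("common", part.common),
    ):
        for sym in sorted(symbols):
            part_rows.append(
                {
                    "symbol": sym,
                    "set": name,
                    "subtype": part.subtype_of.get(sym, ""),
                    "category": part.category_of.get(sym, ""),
                    "fold_change": (
                        result.quant.loc[sym, "fold_change"]
                        if sym in result.quant.index
                        else float("nan")
                    ),
                    "upregulated": bool(
                        result.quant.loc[sym, "upregulated"]
                    )
                    if sym in result.quant.index
                    else False,
                }
            )
    paths["partition"] = str(outdir / "partition.tsv")
    pd.DataFrame(part_rows).to_csv(paths["partition"], sep="\t", index=False)

    paths["enrichment"] = str(outdir / "enrichment.tsv")
    pd.DataFrame(
        [dataclasses.asdict(r) for r in result.enrichment]
    ).to_csv(paths["enrichment"], sep="\t", index=False)

    paths["network"] = str(outdir / "network.tsv")
    pd.DataFrame(result.network, columns=["term", "members"]).to_csv(
        paths["network"], sep="\t", index=False
    )
    return paths


def run_all(
    config: PipelineConfig,
    psm_paths: Sequence[str],
    fasta_path: str,
    sample_sheet_path: str,
    kb_ec_path: str,
    kb_other_path: str,
    kb_lit_path: str,
    gmt_path: str | None,
    outdir: str,
) -> dict:
    """File-based end-to-end run; writes all stage TSVs plus manifest.json."""
    t0 = time.time()
    psms: list[PsmRecord] = []
    for p in psm_paths:
        psms.extend(read_psm_table(p))
    fasta = read_fasta(fasta_path, decoy_prefix=config.decoy_prefix)
    samples = read_sample_sheet(sample_sheet_path)
    kb = KnowledgeBase.from_files(kb_ec_path, kb_other_path, kb_lit_path)
    annotations = read_gmt(gmt_path) if gmt_path else None

    result = run_pipeline(psms, fasta, samples, kb, annotations, config)
    paths = write_outputs(result, outdir)

    manifest = result.manifest
    manifest["inputs"] = {
        str(p): _digest(p)
        for p in [*psm_paths, fasta_path, sample_sheet_path]
        + ([gmt_path] if gmt_path else [])
    }
    manifest["outputs"] = paths
    manifest["cohort"] = {}
    for fld in ("age", "bmi"):
        summ = cohort_stats.summarize(samples, fld)
        welch = cohort_stats.welch_t(samples, fld)
        manifest["cohort"][fld] = {
            "mean_atrophic": summ["atrophic"].mean,
            "mean_cancer": summ["cancer"].mean,
            "p": welch.p,
        }
    manifest["elapsed_s"] = round(time.time() - t0, 3)
    for name, p in paths.items():
        assert Path(p).exists(), f"missing output {name}"
    manifest_path = Path(outdir) / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
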