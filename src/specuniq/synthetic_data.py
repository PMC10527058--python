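"""Synthetic PSM cohort generator with planted ground truth.

Emulates the data structure of a 4-control vs 4-cancer (2 endometrioid +
2 serous) spectral-counting study so every pipeline stage can be exercised
and scored offline.  Proteins are planted in known classes:

* ``common_eq``   — present in both arms at equal abundance;
* ``common_up``   — present in both arms, up-regulated ``true_fold``-fold
  in cancer;
* ``cancer_only`` / ``atrophic_only`` — the all-or-nothing signal;
* ``type1_only`` / ``type2_only``     — confined to one cancer subtype;
* paralog families — protein pairs sharing peptides, to exercise parsimony.

Per-protein abundance a_p ~ logNormal(0, 0.5); per (protein, sample) the
spectral count is Poisson(depth * a_p * fold) with fold encoding the class,
allocated multinomially over the protein's peptides.  Every emitted
spectrum becomes a correct PSM (score ~ N(4, 1), mass error ~ N(0, 3) ppm);
incorrect PSMs are added at ``incorrect_psm_rate`` per correct PSM, half
matched to target peptides and half to decoys (score ~ N(0, 1), mass error
~ Uniform(-20, 20) ppm), giving the 1:1 target-decoy structure the error
estimation assumes.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .formats_io import (
    AnnotationSet,
    KnowledgeBase,
    ProteinSeq,
    PsmRecord,
    SampleMeta,
    write_fasta,
    write_gene_list,
    write_gmt,
    write_psm_table,
    write_sample_sheet,
)

CLASSES = (
    "common_eq",
    "common_up",
    "cancer_only",
    "atrophic_only",
    "type1_only",
    "type2_only",
)

# sample ids and Table-1-style covariates for the 4 + (2 + 2) design
_ATROPHIC = [("A1", 55, 19), ("A2", 65, 22), ("A3", 63, 26), ("A4", 57, 24)]
_TYPE1 = [("E1", 88, 24), ("E2", 74, 42)]
_TYPE2 = [("S1", 61, 38), ("S2", 61, 40)]

_RESIDUES = "ACDEFGHMNPQSTVWY"  # internal residues; K/R close the peptide


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort."""

    n_common_eq: int = 30
    n_common_up: int = 20
    n_cancer_only: int = 20
    n_atrophic_only: int = 15
    n_type1_only: int = 8
    n_type2_only: int = 8
    n_paralog_families: int = 3
    true_fold: float = 3.0
    depth: float = 30.0  # expected spectra per present protein per sample
    lambda_pep: float = 3.0  # peptides per protein = 2 + Poisson(lambda_pep)
    shared_peptide_rate: float = 0.05
    incorrect_psm_rate: float = 0.15
    mu_correct: float = 4.0
    sigma_correct: float = 1.0
    mu_incorrect: float = 0.0
    sigma_incorrect: float = 1.0
    mass_error_sd_correct: float = 3.0
    mass_error_range_incorrect: float = 20.0
    abundance_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = (
            self.n_common_eq,
            self.n_common_up,
            self.n_cancer_only,
            self.n_atrophic_only,
            self.n_type1_only,
            self.n_type2_only,
        )
        if any(s < 0 for s in sizes):
            raise ValueError("class sizes must be non-negative")
        if sum(sizes) + self.n_paralog_families == 0:
            raise ValueError("at least one protein class must be non-empty")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.true_fold <= 1:
            raise ValueError("true_fold must exceed 1")


@dataclass
class TruthBundle:
    """Planted ground truth for recovery scoring."""

    class_of: dict[str, str]  # gene symbol -> class
    fold_of: dict[str, float]  # gene symbol -> true cancer/control fold
    peptide_to_protein: dict[str, str]  # peptide -> generating accession
    psm_correct: dict[str, bool]  # spectrum id -> correct / incorrect
    category_of: dict[str, str] = field(default_factory=dict)

    def expected_sets(self) -> dict[str, set[str]]:
        """Expected presence/absence partition implied by the classes."""
        a_only = {s for s, c in self.class_of.items() if c == "atrophic_only"}
        c_only = {
            s
            for s, c in self.class_of.items()
            if c in ("cancer_only", "type1_only", "type2_only")
        }
        common = {
            s for s, c in self.class_of.items() if c in ("common_eq", "common_up")
        }
        return {"atrophic_only": a_only, "cancer_only": c_only, "common": common}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthBundle":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimOutput:
    psms: list[PsmRecord]
    fasta: list[ProteinSeq]  # targets + 1:1 reversed decoys
    samples: list[SampleMeta]
    truth: TruthBundle
    knowledge: KnowledgeBase
    annotations: list[AnnotationSet]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            write_psm_table(
                [p for p in self.psms if p.sample_id == s.sample_id],
                outdir / f"psms_{s.sample_id}.tsv",
            )
        write_fasta(self.fasta, outdir / "database.fasta")
        write_sample_sheet(self.samples, outdir / "samples.tsv")
        self.truth.to_json(outdir / "truth.json")
        write_gene_list(self.knowledge.known_ec, outdir / "kb_known_ec.txt")
        write_gene_list(
            self.knowledge.known_other_cancer, outdir / "kb_known_other.txt"
        )
        write_gene_list(self.knowledge.has_literature, outdir / "kb_literature.txt")
        write_gmt(self.annotations, outdir / "annotations.gmt")


def _sample_sheet() -> list[SampleMeta]:
    meta = [
        SampleMeta(sid, "atrophic", "none", age, bmi) for sid, age, bmi in _ATROPHIC
    ]
    meta += [SampleMeta(sid, "cancer", "type1", age, bmi) for sid, age, bmi in _TYPE1]
    meta += [SampleMeta(sid, "cancer", "type2", age, bmi) for sid, age, bmi in _TYPE2]
    return meta


def _new_peptide(rng: np.random.Generator, seen: set[str]) -> str:
    while True:
        length = int(rng.integers(7, 15))
        body = "".join(rng.choice(list(_RESIDUES), size=length))
        pep = body + str(rng.choice(["K", "R"]))
        if pep not in seen:
            seen.add(pep)
            return pep


def _fold_vector(cls: str, true_fold: float, meta: Sequence[SampleMeta]) -> np.ndarray:
    out = np.zeros(len(meta))
    for i, m in enumerate(meta):
        if cls == "common_eq":
            out[i] = 1.0
        elif cls == "common_up":
            out[i] = true_fold if m.group == "cancer" else 1.0
        elif cls == "cancer_only":
            out[i] = 1.0 if m.group == "cancer" else 0.0
        elif cls == "atrophic_only":
            out[i] = 1.0 if m.group == "atrophic" else 0.0
        elif cls == "type1_only":
            out[i] = 1.0 if m.subtype == "type1" else 0.0
        elif cls == "type2_only":
            out[i] = 1.0 if m.subtype == "type2" else 0.0
        else:
            raise ValueError(f"unknown class {cls}")
    return out


def generate(config: SimConfig) -> SimOutput:
    """Generate the full synthetic cohort (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    meta = _sample_sheet()
    seen_peptides: set[str] = set()

    # --- plant the proteome -------------------------------------------------
    proteins: list[dict] = []  # accession, symbol, class, peptides
    counters = {
        "common_eq": ("CEQ", config.n_common_eq),
        "common_up": ("CUP", config.n_common_up),
        "cancer_only": ("CON", config.n_cancer_only),
        "atrophic_only": ("AON", config.n_atrophic_only),
        "type1_only": ("T1O", config.n_type1_only),
        "type2_only": ("T2O", config.n_type2_only),
    }
    acc_i = 0
    for cls, (prefix, size) in counters.items():
        for j in range(size):
            acc_i += 1
            npep = 2 + int(rng.poisson(config.lambda_pep))
            peps = [_new_peptide(rng, seen_peptides) for _ in range(npep)]
            proteins.append(
                dict(
                    accession=f"SP{acc_i:05d}",
                    symbol=f"{prefix}{j + 1:04d}",
                    cls=cls,
                    peptides=peps,
                )
            )
    # paralog families: pairs of common-class proteins sharing peptides
    for f in range(config.n_paralog_families):
        npep = 2 + int(rng.poisson(config.lambda_pep))
        base = [_new_peptide(rng, seen_peptides) for _ in range(npep)]
        n_shared = max(1, round(config.shared_peptide_rate * npep))
        for tag in ("A", "B"):
            acc_i += 1
            own = [_new_peptide(rng, seen_peptides) for _ in range(max(2, npep - n_shared))]
            proteins.append(
                dict(
                    accession=f"SP{acc_i:05d}",
                    symbol=f"PAR{f + 1:03d}{tag}",
                    cls="common_eq",
                    peptides=base[:n_shared] + own,
                )
            )

    fasta: list[ProteinSeq] = []
    pep_owner: dict[str, str] = {}
    for p in proteins:
        seq = "".join(p["peptides"])
        fasta.append(ProteinSeq(p["accession"], p["symbol"], seq, is_decoy=False))
        for pep in p["peptides"]:
            pep_owner.setdefault(pep, p["accession"])
    fasta += [
        ProteinSeq(
            f"DECOY_{p.accession}",
            f"DECOY_{p.gene_symbol}",
            p.sequence[::-1],
            is_decoy=True,
        )
        for p in list(fasta)
    ]

    # --- spectral counts and PSMs -------------------------------------------
    abundance = {
        p["accession"]: float(rng.lognormal(0.0, config.abundance_sigma))
        for p in proteins
    }
    target_peptides = sorted(pep_owner)
    psms: list[PsmRecord] = []
    psm_correct: dict[str, bool] = {}
    spec_i = 0
    for si, m in enumerate(meta):
        n_correct_sample = 0
        for p in proteins:
            lam = (
                config.depth
                * abundance[p["accession"]]
                * _fold_vector(p["cls"], config.true_fold, meta)[si]
            )
            c = int(rng.poisson(lam)) if lam > 0 else 0
            if c == 0:
                continue
            alloc = rng.multinomial(c, np.full(len(p["peptides"]), 1 / len(p["peptides"])))
            for pep, k in zip(p["peptides"], alloc):
                for _ in range(int(k)):
                    spec_i += 1
                    sid = f"spec{spec_i:07d}"
                    psms.append(
                        PsmRecord(
                            sample_id=m.sample_id,
                            spectrum_id=sid,
                            peptide_seq=pep,
                            charge=int(rng.integers(2, 4)),
                            score=float(
                                rng.normal(config.mu_correct, config.sigma_correct)
                            ),
                            is_decoy=False,
                            mass_error_ppm=float(
                                rng.normal(0.0, config.mass_error_sd_correct)
                            ),
                        )
                    )
                    psm_correct[sid] = True
                    n_correct_sample += 1
        n_bad = int(rng.poisson(config.incorrect_psm_rate * n_correct_sample))
        for b in range(n_bad):
            spec_i += 1
            sid = f"spec{spec_i:07d}"
            is_decoy = bool(b % 2)  # alternate: 1:1 incorrect targets vs decoys
            pep = str(rng.choice(target_peptides))
            if is_decoy:
                pep = pep[::-1][:-1] + pep[-1]  # reversed, tryptic terminus kept
            psms.append(
                PsmRecord(
                    sample_id=m.sample_id,
                    spectrum_id=sid,
                    peptide_seq=pep,
                    charge=int(rng.integers(2, 4)),
                    score=float(
                        rng.normal(config.mu_incorrect, config.sigma_incorrect)
                    ),
                    is_decoy=is_decoy,
                    mass_error_ppm=float(
                        rng.uniform(
                            -config.mass_error_range_incorrect,
                            config.mass_error_range_incorrect,
                        )
                    ),
                )
            )
            psm_correct[sid] = False

    # --- truth, knowledge lists, annotation sets ----------------------------
    class_of = {p["symbol"]: p["cls"] for p in proteins}
    fold_of = {
        p["symbol"]: (config.true_fold if p["cls"] == "common_up" else 1.0)
        for p in proteins
    }
    truth = TruthBundle(
        class_of=class_of,
        fold_of=fold_of,
        peptide_to_protein=pep_owner,
        psm_correct=psm_correct,
    )

    cancer_only_syms = sorted(truth.expected_sets()["cancer_only"])
    categories = ("known_ec", "known_other_cancer", "novel_with_literature",
                  "novel_no_literature")
    kb_ec, kb_other, kb_lit = set(), set(), set()
    for i, sym in enumerate(cancer_only_syms):
        cat = categories[i % 4]
        truth.category_of[sym] = cat
        if cat == "known_ec":
            kb_ec.add(sym)
        elif cat == "known_other_cancer":
            kb_other.add(sym)
        elif cat == "novel_with_literature":
            kb_lit.add(sym)
    kb = KnowledgeBase(frozenset(kb_ec), frozenset(kb_other), frozenset(kb_lit))

    universe = sorted(class_of)
    annotations: list[AnnotationSet] = []
    if cancer_only_syms:
        annotations.append(
            AnnotationSet(
                "SYN0001",
                "cancer_enriched_process",
                frozenset(
                    rng.choice(
                        cancer_only_syms,
                        size=max(2, int(0.8 * len(cancer_only_syms))),
                        replace=False,
                    )
                ),
            )
        )
    for t in range(2, 6):
        members = rng.choice(
            universe, size=min(len(universe), max(3, len(universe) // 6)),
            replace=False,
        )
        annotations.append(
            AnnotationSet(f"SYN{t:04d}", f"background_process_{t}", frozenset(members))
        )

    return SimOutput(
        psms=psms,
        fasta=fasta,
        samples=meta,
        truth=truth,
        knowledge=kb,
        annotations=annotations,
    )


def evaluate_recovery(
    truth: TruthBundle,
    partition=None,
    quant=None,
    psms: Sequence[PsmRecord] | None = None,
    qvalues: Sequence[float] | None = None,
    q_cut: float = 0.05,
) -> dict:
    """Score pipeline outputs against the planted truth.

    Returns a JSON-serialisable dict with per-set Jaccard indices (when a
    partition is given), the realised PSM-level FDR among targets accepted
    at ``q_cut`` (when PSMs and q-values are given), and the relative
    fold-change errors of the planted up-regulated proteins (when a quant
    table is given).
    """
    metrics: dict = {}
    if partition is not None:
        expected = truth.expected_sets()
        observed = {
            "atrophic_only": set(partition.atrophic_only),
            "cancer_only": set(partition.cancer_only),
            "common": set(partition.common),
        }
        if not (
            set().union(*observed.values()) & set().union(*expected.values())
        ):
            raise ValueError("pipeline output and truth share no symbols")
        metrics["jaccard"] = {
            name: (
                len(observed[name] & expected[name])
                / max(len(observed[name] | expected[name]), 1)
            )
            for name in expected
        }
    if psms is not None and qvalues is not None:
        accepted = [
            p
            for p, q in zip(psms, qvalues)
            if not p.is_decoy and q <= q_cut
        ]
        if accepted:
            n_false = sum(
                not truth.psm_correct.get(p.spectrum_id, False) for p in accepted
            )
            metrics["realized_fdr"] = n_false / len(accepted)
            metrics["n_accepted_psms"] = len(accepted)
    if quant is not None:
        errors = []
        for sym, true_fold in truth.fold_of.items():
            if truth.class_of.get(sym) != "common_up" or sym not in quant.index:
                continue
            fc = quant.loc[sym, "fold_change"]
            if np.isfinite(fc):
                errors.append(abs(fc - true_fold) / true_fold)
        if errors:
            metrics["fold_change_median_rel_error"] = float(np.median(errors))
            metrics["n_fold_change_proteins"] = len(errors)
    return metrics
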