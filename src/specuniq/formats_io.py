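"""Readers, writers and the run configuration.

All external formats consumed or produced by the pipeline live here:
tab-delimited PSM tables, FASTA protein databases, GMT annotation sets,
plain-text gene lists, the sample sheet, and the JSON config.  No science
happens in this module — every function either moves bytes into the domain
types below or moves them back out, validating invariants on the way.

The PSM table is a flat TSV with a named header (columns in any order):

    sample_id  spectrum_id  peptide_seq  charge  score  is_decoy
    mass_error_ppm  [posterior]

``is_decoy`` accepts 0/1, true/false (any case).  ``posterior`` is optional
per row (empty cell) and per file (column absent).
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: default accession prefix marking reversed/shuffled database entries
DECOY_PREFIX = "DECOY_"


class FormatError(ValueError):
    """Malformed input file (missing column, bad row, broken invariant)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PsmRecord:
    """One scored spectrum→peptide match."""

    sample_id: str
    spectrum_id: str
    peptide_seq: str
    charge: int
    score: float
    is_decoy: bool
    mass_error_ppm: float
    posterior: float | None = None

    def __post_init__(self) -> None:
        if not self.peptide_seq:
            raise FormatError("peptide_seq must be non-empty")
        bad = set(self.peptide_seq) - AMINO_ACIDS
        if bad:
            raise FormatError(
                f"peptide {self.peptide_seq!r} contains non-amino-acid "
                f"characters {sorted(bad)}"
            )
        if self.charge <= 0:
            raise FormatError(f"charge must be positive, got {self.charge}")
        if self.posterior is not None and not (0.0 <= self.posterior <= 1.0):
            raise FormatError(
                f"posterior {self.posterior} outside [0, 1] "
                f"(spectrum {self.spectrum_id})"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One row of the sample sheet."""

    sample_id: str
    group: str  # atrophic | cancer
    subtype: str  # none | type1 | type2
    age: float
    bmi: float

    def __post_init__(self) -> None:
        if self.group not in ("atrophic", "cancer"):
            raise FormatError(f"unknown group {self.group!r}")
        if self.subtype not in ("none", "type1", "type2"):
            raise FormatError(f"unknown subtype {self.subtype!r}")
        if (self.subtype == "none") != (self.group == "atrophic"):
            raise FormatError(
                f"sample {self.sample_id}: subtype must be 'none' iff group "
                f"is 'atrophic' (got group={self.group}, subtype={self.subtype})"
            )


@dataclass(frozen=True)
class ProteinSeq:
    """One database entry; decoys carry the configured accession prefix."""

    accession: str
    gene_symbol: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.accession}")


@dataclass(frozen=True)
class AnnotationSet:
    """One GMT gene set."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"annotation set {self.term_id} has no members")


@dataclass(frozen=True)
class KnowledgeBase:
    """Curated symbol lists used for novelty categorisation.

    ``known_ec``: proteins already reported in endometrial cancer;
    ``known_other_cancer``: reported in other cancers but not EC;
    ``has_literature``: any published functional literature at all.
    """

    known_ec: frozenset[str]
    known_other_cancer: frozenset[str]
    has_literature: frozenset[str]

    @classmethod
    def from_files(cls, ec_path, other_path, lit_path) -> "KnowledgeBase":
        return cls(
            known_ec=frozenset(read_gene_list(ec_path)),
            known_other_cancer=frozenset(read_gene_list(other_path)),
            has_literature=frozenset(read_gene_list(lit_path)),
        )


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place.

    Defaults are the acceptance rules of the study design: peptide and
    protein posterior probability > 0.95, at least two distinct peptides
    per protein per sample, precursor mass error within 10 ppm,
    up-regulation at a fold change of at least 1.7, outlier exclusion at
    three standardised residual SDs, and a p < 0.01 significance gate.
    """

    peptide_prob_min: float = 0.95
    protein_prob_min: float = 0.95
    min_peptides: int = 2
    max_mass_error_ppm: float = 10.0
    fold_change_min: float = 1.7
    outlier_sd: float = 3.0
    presence_min_samples: int = 1
    enrichment_alpha: float = 0.01
    decoy_ratio: float = 1.0
    pseudocount: float = 0.5
    seed: int = 0
    decoy_prefix: str = DECOY_PREFIX
    normalization: str = "none"  # none | total_count
    outlier_mode: str = "residual"  # residual | global
    gate_method: str = "two_way_anova"  # two_way_anova | welch_log

    def __post_init__(self) -> None:
        for name in (
            "peptide_prob_min",
            "protein_prob_min",
            "max_mass_error_ppm",
            "fold_change_min",
            "outlier_sd",
            "enrichment_alpha",
            "decoy_ratio",
            "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("peptide_prob_min", "protein_prob_min", "enrichment_alpha"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.min_peptides < 1 or self.presence_min_samples < 1:
            raise ValueError("min_peptides and presence_min_samples must be ≥ 1")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

_PSM_REQUIRED = (
    "sample_id",
    "spectrum_id",
    "peptide_seq",
    "charge",
    "score",
    "is_decoy",
    "mass_error_ppm",
)

_TRUE_STRINGS = {"1", "true", "t", "yes"}
_FALSE_STRINGS = {"0", "false", "f", "no", ""}


def _parse_bool(value, line_no: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise FormatError(f"line {line_no}: cannot parse boolean {value!r}")


def read_psm_table(path) -> list[PsmRecord]:
    """Read a tab-delimited PSM table into :class:`PsmRecord` objects.

    Column order is irrelevant; the header must name every required column.
    A missing ``posterior`` column (or empty cells in it) yields ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PSM_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    has_posterior = "posterior" in df.columns
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        try:
            score = float(row["score"])
            charge = int(row["charge"])
            ppm = float(row["mass_error_ppm"])
        except ValueError as exc:
            raise FormatError(f"{path}: line {i}: {exc}") from exc
        posterior = None
        if has_posterior and str(row["posterior"]).strip() != "":
            posterior = float(row["posterior"])
        records.append(
            PsmRecord(
                sample_id=row["sample_id"],
                spectrum_id=row["spectrum_id"],
                peptide_seq=row["peptide_seq"].upper(),
                charge=charge,
                score=score,
                is_decoy=_parse_bool(row["is_decoy"], i)
                or row["spectrum_id"].startswith(DECOY_PREFIX),
                mass_error_ppm=ppm,
                posterior=posterior,
            )
        )
    return records


def write_psm_table(records: Iterable[PsmRecord], path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=list(_PSM_REQUIRED) + ["posterior"])
    df["is_decoy"] = df["is_decoy"].astype(int)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_DEFAULT_SYMBOL_RE = re.compile(r"^(?P<acc>[^|\s]+)(?:\|(?P<sym>[^\s|]+))?")


def read_fasta(path, *, decoy_prefix: str = DECOY_PREFIX,
               symbol_regex: re.Pattern | str | None = None) -> list[ProteinSeq]:
    """Read a protein FASTA whose headers follow ``accession|symbol desc``.

    Headers without a gene symbol fall back to the accession.  Decoy status
    is taken from the accession prefix.  Duplicate accessions are an error.
    """
    pattern = re.compile(symbol_regex) if isinstance(symbol_regex, str) else (
        symbol_regex or _DEFAULT_SYMBOL_RE
    )
    proteins: list[ProteinSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.description)
        if m is None:
            raise FormatError(f"{path}: unparseable header {rec.description!r}")
        acc = m.group("acc")
        sym = m.groupdict().get("sym") or acc
        if acc in seen:
            raise FormatError(f"{path}: duplicate accession {acc}")
        seen.add(acc)
        seq = str(rec.seq).upper()
        proteins.append(
            ProteinSeq(
                accession=acc,
                gene_symbol=sym.upper(),
                sequence=seq,
                is_decoy=acc.startswith(decoy_prefix),
            )
        )
    return proteins


def write_fasta(proteins: Iterable[ProteinSeq], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.accession}|{p.gene_symbol}",
                  description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GMT, gene lists, sample sheet
# ---------------------------------------------------------------------------


def read_gmt(path) -> list[AnnotationSet]:
    sets: list[AnnotationSet] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {i}: GMT rows need ≥3 fields")
        members = frozenset(f.strip().upper() for f in fields[2:] if f.strip())
        sets.append(AnnotationSet(fields[0], fields[1], members))
    return sets


def write_gmt(sets: Iterable[AnnotationSet], path) -> None:
    lines = [
        "\t".join([s.term_id, s.term_name, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> set[str]:
    """One symbol per line; '#' starts a comment; upper-cased, deduplicated."""
    symbols: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if token:
            symbols.add(token.upper())
    return symbols


def write_gene_list(symbols: Iterable[str], path) -> None:
    Path(path).write_text("\n".join(sorted(set(symbols))) + "\n")


def read_sample_sheet(path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "group", "subtype", "age", "bmi"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dupes}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            group=row.group,
            subtype=row.subtype,
            age=float(row.age),
            bmi=float(row.bmi),
        )
        for row in df.itertuples(index=False)
    ]


def write_sample_sheet(meta: Sequence[SampleMeta], path) -> None:
    pd.DataFrame([dataclasses.asdict(m) for m in meta]).to_csv(
        path, sep="\t", index=False
    )
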