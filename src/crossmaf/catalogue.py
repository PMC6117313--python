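"""Curated disease-variant catalogues.

A catalogue is a tab-separated table of variants curated by a locus-specific
database (the motivating case is the ARVC/D Genetic Variants Database for the
five desmosomal genes PKP2, DSP, DSG2, DSC2 and JUP), each labelled
``pathogenic`` or ``unknown``.  This module reads and validates such tables,
deduplicates on (gene, cDNA HGVS), and produces Table-style per-gene counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CatalogueVariant",
    "GeneMeta",
    "GenomicKey",
    "CatalogueWarning",
    "DEFAULT_VOCAB",
    "ARVC_GENE_META",
    "read_catalogue",
    "write_catalogue",
    "summarize_catalogue",
    "read_gene_meta",
]


class CatalogueWarning(UserWarning):
    """Non-fatal irregularity while reading a catalogue (dropped or merged rows)."""


#: Case-insensitive classification vocabulary.  The source databases use two
#: classes; "uncertain"/"VUS" are synonyms for unknown.  Labels outside the
#: map are dropped with a counted warning.
DEFAULT_VOCAB: dict[str, str] = {
    "pathogenic": "pathogenic",
    "unknown": "unknown",
    "uncertain": "unknown",
    "vus": "unknown",
}

REQUIRED_COLUMNS = ("gene", "transcript", "cdna_hgvs", "classification")
KEY_COLUMNS = ("contig", "position", "ref", "alt", "build")


@dataclass(frozen=True)
class GenomicKey:
    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    build: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("empty allele in genomic key")
        if self.ref == self.alt:
            raise ValueError("ref == alt in genomic key")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass
class CatalogueVariant:
    """One curated disease-variant record."""

    gene: str
    transcript: str
    cdna_hgvs: str
    classification: str  # "pathogenic" | "unknown"
    protein_hgvs: str | None = None
    genomic_key: GenomicKey | None = None
    predictions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.classification not in ("pathogenic", "unknown"):
            raise ValueError(
                f"classification must be pathogenic/unknown, got {self.classification!r}"
            )

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.cdna_hgvs}"


@dataclass(frozen=True)
class GeneMeta:
    """Per-gene metadata: canonical transcript, protein length, inheritance.

    ``inheritance`` drives the prevalence-stage exclusion rule: variants in a
    recessive-inheritance gene only contribute to a dominant-model genotype
    prevalence if a homozygote was observed.
    """

    gene: str
    transcript: str
    amino_acid_count: int
    inheritance: str  # "dominant" | "recessive" | "both"
    interval: tuple[str, int, int] | None = None  # contig, start, end (1-based incl.)

    def __post_init__(self) -> None:
        if self.amino_acid_count <= 0:
            raise ValueError(f"amino_acid_count must be positive for {self.gene}")
        if self.inheritance not in ("dominant", "recessive", "both"):
            raise ValueError(f"bad inheritance {self.inheritance!r} for {self.gene}")


#: Default metadata for the five major ARVC desmosomal genes.  Protein lengths
#: follow the canonical transcripts; JUP variants cause the recessive form
#: (Naxos disease), the others are dominant in the classical presentation.
ARVC_GENE_META: dict[str, GeneMeta] = {
    "DSC2": GeneMeta("DSC2", "ENST00000280904.10", 901, "dominant"),
    "DSG2": GeneMeta("DSG2", "ENST00000261590.12", 1118, "dominant"),
    "DSP": GeneMeta("DSP", "ENST00000379802.7", 2871, "dominant"),
    "JUP": GeneMeta("JUP", "ENST00000393931.7", 745, "recessive"),
    "PKP2": GeneMeta("PKP2", "ENST00000070846.10", 837, "dominant"),
}

_PREDICTION_PREFIX = "pred_"


def read_catalogue(
    path: str | Path,
    vocab_map: Mapping[str, str] = DEFAULT_VOCAB,
    column_map: Mapping[str, str] | None = None,
) -> list[CatalogueVariant]:
    """Read a catalogue TSV into validated, deduplicated records.

    ``column_map`` maps the file's header names onto the canonical names
    (gene, transcript, cdna_hgvs, protein_hgvs, classification, contig,
    position, ref, alt, build, pred_<tool>).  Classification labels are
    matched case-insensitively against ``vocab_map``; rows with labels
    outside it are dropped with a counted warning.  Duplicate
    (gene, cdna_hgvs) rows keep the first occurrence, with a warning.
    Unparseable genomic keys are kept as records without a key.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"catalogue is missing required column {col!r}")

    vocab = {k.lower(): v for k, v in vocab_map.items()}
    pred_cols = [c for c in df.columns if c.startswith(_PREDICTION_PREFIX)]

    records: list[CatalogueVariant] = []
    seen: set[tuple[str, str]] = set()
    n_dropped = 0
    n_dupes = 0
    for _, row in df.iterrows():
        label = str(row["classification"]).strip().lower()
        if label not in vocab:
            n_dropped += 1
            continue
        gene = str(row["gene"]).strip()
        cdna = str(row["cdna_hgvs"]).strip()
        if (gene, cdna) in seen:
            n_dupes += 1
            continue
        seen.add((gene, cdna))
        key = _parse_genomic_key(row)
        predictions = {
            c[len(_PREDICTION_PREFIX):]: str(row[c]).strip()
            for c in pred_cols
            if str(row[c]).strip()
        }
        protein = str(row.get("protein_hgvs", "")).strip() or None
        records.append(
            CatalogueVariant(
                gene=gene,
                transcript=str(row["transcript"]).strip(),
                cdna_hgvs=cdna,
                classification=vocab[label],
                protein_hgvs=protein,
                genomic_key=key,
                predictions=predictions,
            )
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} row(s) with classification outside the vocabulary",
            CatalogueWarning,
            stacklevel=2,
        )
    if n_dupes:
        warnings.warn(
            f"collapsed {n_dupes} duplicate (gene, cdna_hgvs) row(s), keeping the first",
            CatalogueWarning,
            stacklevel=2,
        )
    return records


def _parse_genomic_key(row: pd.Series) -> GenomicKey | None:
    vals = {c: str(row.get(c, "")).strip() for c in KEY_COLUMNS}
    if not any(vals[c] for c in ("contig", "position", "ref", "alt")):
        return None
    try:
        return GenomicKey(
            contig=vals["contig"],
            position=int(vals["position"]),
            ref=vals["ref"].upper(),
            alt=vals["alt"].upper(),
            build=vals["build"],
        )
    except (ValueError, TypeError):
        warnings.warn(
            f"unparseable genomic key for {vals}; record kept without one",
            CatalogueWarning,
            stacklevel=3,
        )
        return None


def write_catalogue(records: Iterable[CatalogueVariant], path: str | Path) -> None:
    """Write records as a normalized catalogue TSV (stable column order)."""
    records = list(records)
    tools = sorted({t for r in records for t in r.predictions})
    rows = []
    for r in records:
        row = {
            "gene": r.gene,
            "transcript": r.transcript,
            "cdna_hgvs": r.cdna_hgvs,
            "protein_hgvs": r.protein_hgvs or "",
            "classification": r.classification,
            "contig": r.genomic_key.contig if r.genomic_key else "",
            "position": r.genomic_key.position if r.genomic_key else "",
            "ref": r.genomic_key.ref if r.genomic_key else "",
            "alt": r.genomic_key.alt if r.genomic_key else "",
            "build": r.genomic_key.build if r.genomic_key else "",
        }
        for t in tools:
            row[_PREDICTION_PREFIX + t] = r.predictions.get(t, "")
        rows.append(row)
    cols = ["gene", "transcript", "cdna_hgvs", "protein_hgvs", "classification",
            "contig", "position", "ref", "alt", "build"] + [_PREDICTION_PREFIX + t for t in tools]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def summarize_catalogue(records: Sequence[CatalogueVariant]) -> pd.DataFrame:
    """Per-gene pathogenic/unknown counts, one row per gene plus TOTAL.

    The counts partition the catalogue: column sums over genes equal the
    totals row, and the totals sum to ``len(records)``.
    """
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        g = counts.setdefault(r.gene, {"pathogenic": 0, "unknown": 0})
        g[r.classification] += 1
    rows = [
        {"gene": gene, "n_pathogenic": c["pathogenic"], "n_unknown": c["unknown"]}
        for gene, c in sorted(counts.items())
    ]
    rows.append({
        "gene": "TOTAL",
        "n_pathogenic": sum(r["n_pathogenic"] for r in rows),
        "n_unknown": sum(r["n_unknown"] for r in rows),
    })
    return pd.DataFrame(rows, columns=["gene", "n_pathogenic", "n_unknown"])


def read_gene_meta(path: str | Path) -> dict[str, GeneMeta]:
    """Read gene metadata from TSV (gene, transcript, amino_acid_count,
    inheritance, and optionally contig/start/end for the gene interval)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    for col in ("gene", "transcript", "amino_acid_count", "inheritance"):
        if col not in df.columns:
            raise ValueError(f"gene meta is missing required column {col!r}")
    meta: dict[str, GeneMeta] = {}
    for _, row in df.iterrows():
        interval = None
        if str(row.get("contig", "")).strip():
            interval = (str(row["contig"]), int(row["start"]), int(row["end"]))
        gene = str(row["gene"]).strip()
        if gene in meta:
            raise ValueError(f"duplicate gene meta entry for {gene}")
        meta[gene] = GeneMeta(
            gene=gene,
            transcript=str(row["transcript"]).strip(),
            amino_acid_count=int(row["amino_acid_count"]),
            inheritance=str(row["inheritance"]).strip().lower(),
            interval=interval,
        )
    return meta


def write_gene_meta(meta: Mapping[str, GeneMeta], path: str | Path) -> None:
    rows = []
    for g in sorted(meta):
        m = meta[g]
        contig, start, end = m.interval if m.interval else ("", "", "")
        rows.append({
            "gene": m.gene, "transcript": m.transcript,
            "amino_acid_count": m.amino_acid_count, "inheritance": m.inheritance,
            "contig": contig, "start": start, "end": end,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
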