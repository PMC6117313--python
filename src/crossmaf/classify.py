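"""Frequency classification of catalogued variants.

Each catalogue variant is matched to at most one frequency-store record and
classed rare/common under two rules:

* the **global rule** — the pooled, cohort-wide MAF against the threshold;
* the **popmax rule** — "common in at least one ancestry group": the maximum
  per-population MAF against the threshold.

The threshold comparison is inclusive (MAF >= t is common), the default t is
0.001 (the dominant-disease discovery cut-off), with 0.0001 as the stringent
alternative.  Crossing the catalogue label with the popmax verdict gives the
four-way class: pathogenic_rare, pathogenic_common, unknown_rare,
unknown_common.  Variants absent from the store are "not_observed", which is
kept distinct from "rare": absence of evidence of commonness is not evidence
the variant was ever genotyped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalogue import CatalogueVariant, GenomicKey
from .frequencies import (
    DEFAULT_POPULATIONS,
    FrequencyRecord,
    PopCounts,
    maf,
    normalize_variant,
    popmax_maf,
)

__all__ = [
    "DEFAULT_THRESHOLD",
    "STRINGENT_THRESHOLD",
    "ClassifiedVariant",
    "validate_threshold",
    "match_variants",
    "classify_variant",
    "classify_all",
    "per_population_tally",
    "count_common",
    "percent_common",
    "write_classified_tsv",
    "read_classified_tsv",
]

DEFAULT_THRESHOLD = 0.001
STRINGENT_THRESHOLD = 0.0001

RARE, COMMON, NOT_OBSERVED = "rare", "common", "not_observed"


def validate_threshold(t: float) -> float:
    if not (0.0 < t < 0.5):
        raise ValueError(f"MAF threshold must lie in (0, 0.5), got {t}")
    return float(t)


@dataclass
class ClassifiedVariant:
    """A catalogue variant with its frequency evidence and rule verdicts."""

    catalogue: CatalogueVariant
    matched: bool
    per_population_maf: dict[str, float | None] = field(default_factory=dict)
    global_maf: float | None = None
    class_global: str = NOT_OBSERVED
    class_popmax: str = NOT_OBSERVED
    popmax_population: str | None = None
    four_way: str | None = None
    total_ac: int = 0
    max_nhom: int = 0

    def __post_init__(self) -> None:
        if self.matched == (self.class_popmax == NOT_OBSERVED):
            raise ValueError("matched flag inconsistent with class_popmax")
        if self.matched == (self.four_way is None):
            raise ValueError("matched flag inconsistent with four_way")

    @property
    def gene(self) -> str:
        return self.catalogue.gene

    @property
    def classification(self) -> str:
        return self.catalogue.classification

    def reclassified(self, t: float) -> "ClassifiedVariant":
        """The same evidence re-judged at a different threshold."""
        if not self.matched:
            return self
        return _judge(self, validate_threshold(t))


def _judge(cv: ClassifiedVariant, t: float) -> ClassifiedVariant:
    defined = [f for f in cv.per_population_maf.values() if f is not None]
    pop_best = max(defined) if defined else None
    class_popmax = COMMON if (pop_best is not None and pop_best >= t) else RARE
    class_global = COMMON if (cv.global_maf is not None and cv.global_maf >= t) else RARE
    return replace(
        cv,
        class_global=class_global,
        class_popmax=class_popmax,
        four_way=f"{cv.catalogue.classification}_{class_popmax}",
    )


def _store_index(
    records: Iterable[FrequencyRecord],
) -> tuple[dict[tuple, FrequencyRecord], dict[tuple[str, str], FrequencyRecord]]:
    by_key: dict[tuple, FrequencyRecord] = {}
    by_name: dict[tuple[str, str], FrequencyRecord] = {}
    for rec in records:
        rec = rec.normalized()
        by_key.setdefault(rec.key, rec)
        if rec.gene and rec.cdna_hgvs:
            by_name.setdefault((rec.gene, rec.cdna_hgvs), rec)
    return by_key, by_name


def match_variants(
    catalogue: Sequence[CatalogueVariant],
    store: Iterable[FrequencyRecord],
    filter_policy: str = "pass",
) -> list[tuple[CatalogueVariant, FrequencyRecord | None]]:
    """Join catalogue variants to store records.

    The join key is the normalized genomic key when the catalogue carries
    one, otherwise the exact (gene, cdna_hgvs) pair against store
    annotations.  Each catalogue variant matches at most one record; a
    variant whose two join routes resolve to distinct records is a hard
    error (ambiguous catalogue).  ``filter_policy`` is "pass" (default:
    only PASS store records are matchable) or "all".
    """
    if filter_policy not in ("pass", "all"):
        raise ValueError(f"filter_policy must be 'pass' or 'all', got {filter_policy!r}")
    usable = (
        r for r in store if filter_policy == "all" or r.filter_status == "pass"
    )
    by_key, by_name = _store_index(usable)
    out: list[tuple[CatalogueVariant, FrequencyRecord | None]] = []
    for var in catalogue:
        hits: list[FrequencyRecord] = []
        if var.genomic_key is not None:
            k = var.genomic_key
            norm = normalize_variant(k.contig, k.position, k.ref, k.alt)
            rec = by_key.get(norm)
            if rec is not None:
                hits.append(rec)
        named = by_name.get((var.gene, var.cdna_hgvs))
        if named is not None and all(named.key != h.key for h in hits):
            if hits:
                raise ValueError(
                    f"ambiguous catalogue entry {var.label}: genomic key and "
                    f"(gene, cdna_hgvs) resolve to distinct store records"
                )
            if var.genomic_key is None:
                hits.append(named)
        out.append((var, hits[0] if hits else None))
    return out


def classify_variant(
    pair: tuple[CatalogueVariant, FrequencyRecord | None],
    t: float = DEFAULT_THRESHOLD,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
) -> ClassifiedVariant:
    """Classify one matched pair at threshold ``t`` over population set ``pops``."""
    t = validate_threshold(t)
    var, rec = pair
    if rec is None:
        return ClassifiedVariant(catalogue=var, matched=False)
    per_pop = rec.maf_by_population(pops)
    _, best_pop = popmax_maf(rec, pops)
    cv = ClassifiedVariant(
        catalogue=var,
        matched=True,
        per_population_maf=per_pop,
        global_maf=maf(
            sum(rec.per_population.get(p, PopCounts()).ac for p in pops),
            sum(rec.per_population.get(p, PopCounts()).an for p in pops),
        ),
        class_global=RARE,  # provisional; _judge overwrites
        class_popmax=RARE,
        popmax_population=best_pop,
        four_way=f"{var.classification}_{RARE}",
        total_ac=sum(rec.per_population.get(p, PopCounts()).ac for p in pops),
        max_nhom=max((rec.per_population.get(p, PopCounts()).nhom for p in pops), default=0),
    )
    return _judge(cv, t)


def classify_all(
    catalogue: Sequence[CatalogueVariant],
    store: Iterable[FrequencyRecord],
    t: float = DEFAULT_THRESHOLD,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
    filter_policy: str = "pass",
) -> list[ClassifiedVariant]:
    """match_variants + classify_variant over a whole catalogue.

    Output order follows the catalogue and the verdicts are independent of
    store iteration order.
    """
    pairs = match_variants(catalogue, store, filter_policy=filter_policy)
    return [classify_variant(p, t, pops) for p in pairs]


def per_population_tally(
    classified: Sequence[ClassifiedVariant],
    t: float = DEFAULT_THRESHOLD,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
) -> pd.DataFrame:
    """Per-population rare/common counts by catalogue class.

    For each population independently, matched variants with a defined MAF in
    that population are counted common (MAF >= t) or rare; undefined MAFs are
    omitted.  The "ALL" pseudo-population judges the pooled MAF.  Rows are
    populations; columns are pathogenic_common / pathogenic_rare /
    unknown_common / unknown_rare.
    """
    t = validate_threshold(t)
    cols = ["pathogenic_common", "pathogenic_rare", "unknown_common", "unknown_rare"]
    tally = pd.DataFrame(0, index=list(pops) + ["ALL"], columns=cols)
    for cv in classified:
        if not cv.matched:
            continue
        for pop in pops:
            f = cv.per_population_maf.get(pop)
            if f is None:
                continue
            verdict = COMMON if f >= t else RARE
            tally.loc[pop, f"{cv.classification}_{verdict}"] += 1
        if cv.global_maf is not None:
            verdict = COMMON if cv.global_maf >= t else RARE
            tally.loc["ALL", f"{cv.classification}_{verdict}"] += 1
    tally.index.name = "population"
    return tally


def count_common(
    classified: Sequence[ClassifiedVariant],
    rule: str = "popmax",
    classification: str = "pathogenic",
) -> tuple[int, int, float | None]:
    """(n common, n considered, percent) for one rule and catalogue class.

    n considered counts the matched variants of the requested classification;
    percent is 100*n_common/n_considered to one decimal, or None when
    nothing was considered.
    """
    if rule not in ("global", "popmax"):
        raise ValueError(f"rule must be 'global' or 'popmax', got {rule!r}")
    considered = [
        cv for cv in classified if cv.matched and cv.classification == classification
    ]
    attr = "class_global" if rule == "global" else "class_popmax"
    n_common = sum(1 for cv in considered if getattr(cv, attr) == COMMON)
    return n_common, len(considered), percent_common(n_common, len(considered))


def percent_common(n_common: int, n_considered: int) -> float | None:
    """100*n_common/n_considered rounded to one decimal; None when empty."""
    if n_considered == 0:
        return None
    return round(100.0 * n_common / n_considered, 1)


_POP_MAF_PREFIX = "maf_"


def write_classified_tsv(
    classified: Sequence[ClassifiedVariant],
    path: str | Path,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
    params: Mapping[str, object] | None = None,
) -> None:
    """Flatten classified variants to TSV (one row per variant).

    A leading ``#`` comment line records the run parameters.
    """
    rows = []
    for cv in classified:
        var = cv.catalogue
        row: dict[str, object] = {
            "gene": var.gene,
            "transcript": var.transcript,
            "cdna_hgvs": var.cdna_hgvs,
            "protein_hgvs": var.protein_hgvs or "",
            "classification": var.classification,
            "matched": int(cv.matched),
        }
        for pop in pops:
            f = cv.per_population_maf.get(pop)
            row[_POP_MAF_PREFIX + pop] = "" if f is None else repr(f)
        row.update({
            "maf_global": "" if cv.global_maf is None else repr(cv.global_maf),
            "class_global": cv.class_global,
            "class_popmax": cv.class_popmax,
            "popmax_population": cv.popmax_population or "",
            "four_way": cv.four_way or "",
            "total_ac": cv.total_ac,
            "max_nhom": cv.max_nhom,
        })
        for tool, label in sorted(var.predictions.items()):
            row["pred_" + tool] = label
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        if params:
            kv = " ".join(f"{k}={v}" for k, v in params.items())
            fh.write(f"# crossmaf classified variants {kv}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_classified_tsv(path: str | Path) -> list[ClassifiedVariant]:
    """Read back the output of write_classified_tsv."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    pops = [c[len(_POP_MAF_PREFIX):] for c in df.columns
            if c.startswith(_POP_MAF_PREFIX) and c != "maf_global"]
    out: list[ClassifiedVariant] = []
    for _, row in df.iterrows():
        preds = {
            c[len("pred_"):]: row[c] for c in df.columns
            if c.startswith("pred_") and str(row[c]).strip()
        }
        var = CatalogueVariant(
            gene=row["gene"], transcript=row["transcript"],
            cdna_hgvs=row["cdna_hgvs"],
            classification=row["classification"],
            protein_hgvs=row["protein_hgvs"] or None,
            predictions=preds,
        )
        matched = bool(int(row["matched"]))
        if not matched:
            out.append(ClassifiedVariant(catalogue=var, matched=False))
            continue
        per_pop = {
            p: (float(row[_POP_MAF_PREFIX + p]) if str(row[_POP_MAF_PREFIX + p]) else None)
            for p in pops
        }
        out.append(ClassifiedVariant(
            catalogue=var,
            matched=True,
            per_population_maf=per_pop,
            global_maf=float(row["maf_global"]) if str(row["maf_global"]) else None,
            class_global=row["class_global"],
            class_popmax=row["class_popmax"],
            popmax_population=row["popmax_population"] or None,
            four_way=row["four_way"],
            total_ac=int(row["total_ac"]),
            max_nhom=int(row["max_nhom"]),
        ))
    return out
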