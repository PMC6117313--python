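"""gnomAD-style population frequency stores.

A frequency store holds, per biallelic site, the allele count (AC), allele
number (AN) and alternate-homozygote count (nhomalt) for each ancestry group
of a large sequencing cohort.  This module reads such stores from VCF (INFO
keys like ``AC_afr``/``AN_afr``/``nhomalt_afr``) or from a long-format table,
normalizes variants to their minimal left-anchored representation, and exposes
per-population and pooled minor allele frequencies (MAF).

The eight default ancestry groups mirror gnomAD v2: African (AFR), Ashkenazi
Jewish (AJ), East Asian (EA), Non-Finnish European (EUR), Finnish (FIN),
Latino (LAT), South Asian (SA) and Other (OTH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "DEFAULT_POPULATIONS",
    "PopCounts",
    "FrequencyRecord",
    "FrequencyStoreWarning",
    "maf",
    "popmax_maf",
    "normalize_variant",
    "read_frequency_vcf",
    "read_frequency_table",
    "write_frequency_table",
    "write_frequency_vcf",
]

#: Fixed population-code order; ties in popmax are broken by this order.
DEFAULT_POPULATIONS: tuple[str, ...] = (
    "AFR", "AJ", "EA", "EUR", "FIN", "LAT", "SA", "OTH",
)

#: INFO-key templates for the gnomAD v2 dialect (population code lower-cased).
DEFAULT_INFO_TEMPLATE: tuple[str, str, str] = ("AC_{}", "AN_{}", "nhomalt_{}")

_VALID_BASES = frozenset("ACGTN")


class FrequencyStoreWarning(UserWarning):
    """Non-fatal irregularity while reading a frequency store."""


@dataclass(frozen=True)
class PopCounts:
    """Allele bookkeeping for one population at one site.

    ac
        copies of the alternate allele observed.
    an
        total called chromosomes (2 x called genotypes).
    nhom
        individuals homozygous for the alternate allele.
    """

    ac: int = 0
    an: int = 0
    nhom: int = 0

    def __post_init__(self) -> None:
        if self.ac < 0 or self.an < 0 or self.nhom < 0:
            raise ValueError(f"negative allele counts: {self}")
        if self.ac > self.an:
            raise ValueError(f"ac > an: {self}")
        if 2 * self.nhom > self.ac:
            raise ValueError(f"2*nhom > ac: {self}")


@dataclass
class FrequencyRecord:
    """One normalized biallelic site with per-population AC/AN/nhomalt.

    Pooled (cohort-wide) counts are always derived by summing over
    populations, never stored independently.  ``gene`` and ``cdna_hgvs`` are
    optional annotations used only for string-join matching when a catalogue
    lacks genomic coordinates.
    """

    contig: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    filter_status: str = "pass"  # "pass" | "fail"
    per_population: dict[str, PopCounts] = field(default_factory=dict)
    gene: str | None = None
    cdna_hgvs: str | None = None

    def __post_init__(self) -> None:
        if self.filter_status not in ("pass", "fail"):
            raise ValueError(f"filter_status must be pass/fail, got {self.filter_status!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def global_ac(self) -> int:
        return sum(c.ac for c in self.per_population.values())

    @property
    def global_an(self) -> int:
        return sum(c.an for c in self.per_population.values())

    @property
    def max_nhom(self) -> int:
        return max((c.nhom for c in self.per_population.values()), default=0)

    def maf_global(self) -> float | None:
        return maf(self.global_ac, self.global_an)

    def maf_by_population(self, pops: Sequence[str] | None = None) -> dict[str, float | None]:
        pops = tuple(pops) if pops is not None else tuple(self.per_population)
        out: dict[str, float | None] = {}
        for p in pops:
            c = self.per_population.get(p, PopCounts())
            out[p] = maf(c.ac, c.an)
        return out

    def normalized(self) -> "FrequencyRecord":
        contig, pos, ref, alt = normalize_variant(self.contig, self.position, self.ref, self.alt)
        if (contig, pos, ref, alt) == self.key:
            return self
        return FrequencyRecord(contig, pos, ref, alt, self.filter_status,
                               dict(self.per_population), self.gene, self.cdna_hgvs)


def maf(ac: int, an: int) -> float | None:
    """Minor allele frequency from an allele count and allele number.

    The alternate-allele frequency ac/an is folded to the rarer allele,
    ``min(f, 1 - f)``, so the result lies in [0, 0.5].  ``an == 0`` means no
    genotypes were called: the frequency is undefined (``None``), which never
    exceeds any threshold downstream.
    """
    if ac < 0 or an < 0:
        raise ValueError(f"negative counts: ac={ac}, an={an}")
    if ac > an:
        raise ValueError(f"ac ({ac}) exceeds an ({an})")
    if an == 0:
        return None
    f = ac / an
    return min(f, 1.0 - f)


def popmax_maf(
    record: FrequencyRecord, pops: Sequence[str] = DEFAULT_POPULATIONS
) -> tuple[float | None, str | None]:
    """Maximum per-population MAF and the population attaining it.

    Undefined population MAFs (an = 0) are skipped.  If every population is
    undefined, returns ``(None, None)``.  Ties are broken by the fixed
    population order of ``pops``.
    """
    if not pops:
        raise ValueError("empty population set")
    best: float | None = None
    best_pop: str | None = None
    for p in pops:
        c = record.per_population.get(p, PopCounts())
        f = maf(c.ac, c.an)
        if f is None:
            continue
        if best is None or f > best:
            best, best_pop = f, p
    return best, best_pop


def normalize_variant(
    contig: str, position: int, ref: str, alt: str
) -> tuple[str, int, str, str]:
    """Canonical minimal representation of a biallelic variant.

    Shared trailing bases are trimmed first, then shared leading bases (with
    the position advanced), each while both alleles keep at least one base —
    so indels retain a single left-anchor base.  Trimming the suffix before
    the prefix yields the left-most (left-aligned) of the fully trimmed
    forms.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}): not a variant")
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    for allele in (ref, alt):
        if not set(allele) <= _VALID_BASES:
            raise ValueError(f"allele {allele!r} contains non-ACGTN characters")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return (contig, position, ref, alt)


def _info_get(site: "pysam.VariantRecord", key: str) -> object | None:
    # pysam raises "Invalid header" for keys the header does not declare
    try:
        return site.info.get(key)
    except (KeyError, ValueError):
        return None


def _split_info_value(value: object, n_alts: int) -> list[int]:
    """INFO value (scalar or per-alt tuple) -> one integer per alt allele."""
    if value is None:
        return [0] * n_alts
    if isinstance(value, (tuple, list)):
        vals = [0 if v is None else int(v) for v in value]
        if len(vals) == n_alts:
            return vals
        if len(vals) == 1:
            return vals * n_alts
        raise ValueError(f"INFO arity {len(vals)} != number of alts {n_alts}")
    return [int(value)] * n_alts


def read_frequency_vcf(
    path: str | Path,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
    info_template: tuple[str, str, str] = DEFAULT_INFO_TEMPLATE,
    lowercase_pop: bool = True,
) -> Iterator[FrequencyRecord]:
    """Stream normalized FrequencyRecords from a VCF.

    Multiallelic sites are split into one record per alternate allele, with
    Number=A INFO fields apportioned by alt index; AN-type fields are shared
    across the split alts.  A missing INFO key for a population yields
    (0, 0, 0) for that population with a once-per-key warning.  Records with
    ac > an or negative values are rejected with a warning.
    """
    ac_t, an_t, nh_t = info_template
    warned_keys: set[str] = set()
    with pysam.VariantFile(str(path)) as vcf:
        for site in vcf:
            n_alts = len(site.alts or ())
            if n_alts == 0:
                continue
            filt = set(site.filter.keys())
            status = "pass" if (not filt or filt == {"PASS"}) else "fail"
            gene = _info_get(site, "GENE")
            cdna = _info_get(site, "CDNA")
            per_alt_counts: list[dict[str, tuple[int, int, int]]] = [
                {} for _ in range(n_alts)
            ]
            for pop in pops:
                code = pop.lower() if lowercase_pop else pop
                triple = []
                for template in (ac_t, an_t, nh_t):
                    k = template.format(code)
                    value = _info_get(site, k)
                    if value is not None:
                        triple.append(_split_info_value(value, n_alts))
                    else:
                        if k not in warned_keys:
                            warned_keys.add(k)
                            warnings.warn(
                                f"INFO key {k!r} absent; population {pop} set to (0,0,0)",
                                FrequencyStoreWarning,
                                stacklevel=2,
                            )
                        triple.append([0] * n_alts)
                for i in range(n_alts):
                    per_alt_counts[i][pop] = (triple[0][i], triple[1][i], triple[2][i])
            for i, alt in enumerate(site.alts):
                try:
                    per_pop = {
                        p: PopCounts(*per_alt_counts[i][p]) for p in pops
                    }
                except ValueError as exc:
                    warnings.warn(
                        f"rejected {site.chrom}:{site.pos} {site.ref}>{alt}: {exc}",
                        FrequencyStoreWarning,
                        stacklevel=2,
                    )
                    continue
                rec = FrequencyRecord(
                    site.chrom, site.pos, site.ref, str(alt),
                    filter_status=status, per_population=per_pop,
                    gene=str(gene) if gene is not None else None,
                    cdna_hgvs=str(cdna) if cdna is not None else None,
                )
                yield rec.normalized()


TABLE_COLUMNS = ("contig", "position", "ref", "alt", "filter", "pop", "ac", "an", "nhom")


def read_frequency_table(path: str | Path) -> Iterator[FrequencyRecord]:
    """Stream FrequencyRecords from a long-format TSV (one row per
    variant x population; columns contig, position, ref, alt, filter, pop,
    ac, an, nhom, optionally gene and cdna_hgvs).

    Rows are grouped by variant key into one record per key.  Conflicting
    duplicate (key, pop) rows are a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str},
                     comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"frequency table missing column(s): {', '.join(missing)}")
    if df.empty:
        return
    dup = df.duplicated(subset=["contig", "position", "ref", "alt", "pop"], keep=False)
    if dup.any():
        conflicting = df[dup].drop_duplicates(
            subset=["contig", "position", "ref", "alt", "pop", "ac", "an", "nhom"]
        )
        if conflicting.duplicated(subset=["contig", "position", "ref", "alt", "pop"]).any():
            raise ValueError("conflicting duplicate (variant, population) rows in frequency table")
        df = df.drop_duplicates(subset=["contig", "position", "ref", "alt", "pop"])
    keys = ["contig", "position", "ref", "alt"]
    for (contig, position, ref, alt), grp in df.groupby(keys, sort=True):
        per_pop = {
            str(row["pop"]): PopCounts(int(row["ac"]), int(row["an"]), int(row["nhom"]))
            for _, row in grp.iterrows()
        }
        status = "pass" if str(grp.iloc[0]["filter"]).upper() == "PASS" else "fail"
        gene = grp.iloc[0].get("gene")
        cdna = grp.iloc[0].get("cdna_hgvs")
        rec = FrequencyRecord(
            str(contig), int(position), str(ref), str(alt),
            filter_status=status, per_population=per_pop,
            gene=None if pd.isna(gene) else str(gene) if gene is not None else None,
            cdna_hgvs=None if pd.isna(cdna) else str(cdna) if cdna is not None else None,
        )
        yield rec.normalized()


def write_frequency_table(records: Iterable[FrequencyRecord], path: str | Path) -> None:
    """Write records as the long-format TSV read back by read_frequency_table."""
    rows = []
    for rec in records:
        for pop, c in rec.per_population.items():
            rows.append({
                "contig": rec.contig, "position": rec.position,
                "ref": rec.ref, "alt": rec.alt,
                "filter": "PASS" if rec.filter_status == "pass" else "FAIL",
                "pop": pop, "ac": c.ac, "an": c.an, "nhom": c.nhom,
                "gene": rec.gene or "", "cdna_hgvs": rec.cdna_hgvs or "",
            })
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS) + ["gene", "cdna_hgvs"]).to_csv(
        path, sep="\t", index=False
    )


def write_frequency_vcf(
    records: Sequence[FrequencyRecord],
    path: str | Path,
    pops: Sequence[str] = DEFAULT_POPULATIONS,
    contig_lengths: Mapping[str, int] | None = None,
    info_template: tuple[str, str, str] = DEFAULT_INFO_TEMPLATE,
) -> None:
    """Write records as an uncompressed VCF in the gnomAD v2 INFO dialect."""
    header = pysam.VariantHeader()
    header.filters.add("FAIL", None, None, "Failed site-level quality")
    contigs = contig_lengths or {}
    seen = {r.contig for r in records}
    max_pos: dict[str, int] = {}
    for r in records:
        max_pos[r.contig] = max(max_pos.get(r.contig, 0), r.position + len(r.ref))
    for contig in sorted(seen):
        header.contigs.add(contig, length=contigs.get(contig, max_pos[contig] + 1000))
    ac_t, an_t, nh_t = info_template
    for pop in pops:
        code = pop.lower()
        header.info.add(ac_t.format(code), "A", "Integer", f"Alternate allele count, {pop}")
        header.info.add(an_t.format(code), "1", "Integer", f"Allele number, {pop}")
        header.info.add(nh_t.format(code), "A", "Integer", f"Homozygote count, {pop}")
    header.info.add("GENE", "1", "String", "Gene symbol annotation")
    header.info.add("CDNA", "1", "String", "HGVS cDNA annotation")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in sorted(records, key=lambda r: (r.contig, r.position, r.ref, r.alt)):
            site = out.new_record(
                contig=rec.contig, start=rec.position - 1,
                alleles=(rec.ref, rec.alt),
            )
            if rec.filter_status == "pass":
                site.filter.add("PASS")
            else:
                site.filter.add("FAIL")
            for pop in pops:
                c = rec.per_population.get(pop, PopCounts())
                code = pop.lower()
                site.info[ac_t.format(code)] = (c.ac,)
                site.info[an_t.format(code)] = c.an
                site.info[nh_t.format(code)] = (c.nhom,)
            if rec.gene:
                site.info["GENE"] = rec.gene
            if rec.cdna_hgvs:
                site.info["CDNA"] = rec.cdna_hgvs
            out.write(site)
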