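"""Shared fixtures: synthetic catalogues, stores and demo cohorts.

All fixture data is generated programmatically; the only bundled numbers are
the per-gene reference tallies shipped inside the package.
"""

from __future__ import annotations

import pytest

from crossmaf.catalogue import CatalogueVariant, GenomicKey, write_catalogue
from crossmaf.frequencies import DEFAULT_POPULATIONS, FrequencyRecord, PopCounts
from crossmaf.reference import GENE_COUNTS
from crossmaf.synthetic import default_demo_spec, generate_store


def make_record(
    per_pop: dict[str, tuple[int, int, int]],
    contig: str = "chr1",
    position: int = 100,
    ref: str = "A",
    alt: str = "G",
    filter_status: str = "pass",
    gene: str | None = None,
    cdna: str | None = None,
) -> FrequencyRecord:
    """FrequencyRecord from {pop: (ac, an, nhom)}; unlisted pops get (0,0,0)."""
    counts = {p: PopCounts(*per_pop.get(p, (0, 0, 0))) for p in DEFAULT_POPULATIONS}
    return FrequencyRecord(contig, position, ref, alt, filter_status=filter_status,
                           per_population=counts, gene=gene, cdna_hgvs=cdna)


def make_variant(
    gene: str = "PKP2",
    cdna: str = "c.100A>G",
    classification: str = "pathogenic",
    key: tuple | None = ("chr1", 100, "A", "G"),
    predictions: dict[str, str] | None = None,
) -> CatalogueVariant:
    gk = GenomicKey(*key) if key else None
    return CatalogueVariant(gene=gene, transcript=f"NM_{gene}", cdna_hgvs=cdna,
                            classification=classification, genomic_key=gk,
                            predictions=predictions or {})


@pytest.fixture(scope="session")
def demo_data():
    """The built-in demonstration cohort, generated once per session."""
    return generate_store(default_demo_spec(seed=7))


@pytest.fixture()
def reconstructed_catalogue_records() -> list[CatalogueVariant]:
    """A synthetic stand-in for the external five-gene ARVC catalogue.

    Variant identities are invented; only the per-gene pathogenic/unknown
    marginals match the bundled reference tallies (364 + 266 in total).
    """
    records = []
    for gene, c in GENE_COUNTS.items():
        for i in range(c.n_pathogenic):
            records.append(make_variant(gene, f"c.{i + 1}A>G", "pathogenic", key=None))
        for i in range(c.n_unknown):
            records.append(make_variant(gene, f"c.{i + 1}del", "unknown", key=None))
    return records


@pytest.fixture()
def reconstructed_catalogue_tsv(tmp_path, reconstructed_catalogue_records):
    path = tmp_path / "catalogue.tsv"
    write_catalogue(reconstructed_catalogue_records, path)
    return path
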