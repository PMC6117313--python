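"""Frequency-store parsing, variant normalization, MAF and popmax."""

import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_record

from crossmaf.frequencies import (
    DEFAULT_POPULATIONS,
    FrequencyRecord,
    FrequencyStoreWarning,
    PopCounts,
    maf,
    normalize_variant,
    popmax_maf,
    read_frequency_table,
    read_frequency_vcf,
    write_frequency_table,
    write_frequency_vcf,
)

# --- normalization -----------------------------------------------------------


def oracle_minimal_form(position, ref, alt):
    """Independent oracle: enumerate every order of single-base affix trims.

    A trim removes a shared leading base (advancing the position) or a shared
    trailing base, while both alleles keep >= 1 base afterwards.  Among all
    fully trimmed forms reachable in any order, the canonical one is the
    left-most (minimum position — the left-anchored representation), with the
    shortest alleles as tie-break.
    """
    seen = set()
    frontier = {(position, ref, alt)}
    terminal = set()
    while frontier:
        state = frontier.pop()
        if state in seen:
            continue
        seen.add(state)
        pos, r, a = state
        moves = []
        if len(r) > 1 and len(a) > 1 and r[-1] == a[-1]:
            moves.append((pos, r[:-1], a[:-1]))
        if len(r) > 1 and len(a) > 1 and r[0] == a[0]:
            moves.append((pos + 1, r[1:], a[1:]))
        if not moves:
            terminal.add(state)
        frontier.update(moves)
    return min(terminal, key=lambda s: (s[0], len(s[1]), len(s[2])))


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        (("chr1", 100, "AT", "AG"), ("chr1", 101, "T", "G")),     # prefix trim
        (("chr1", 100, "C", "T"), ("chr1", 100, "C", "T")),       # minimal SNV
        (("chr1", 100, "CA", "TA"), ("chr1", 100, "C", "T")),     # suffix trim
        (("chr1", 98, "GCATT", "GCAT"), ("chr1", 100, "AT", "A")),  # anchored del
        (("chr1", 100, "A", "AGG"), ("chr1", 100, "A", "AGG")),   # anchored ins
    ])
    def test_known_forms(self, raw, expected):
        assert normalize_variant(*raw) == expected

    @pytest.mark.parametrize("padded", [
        # the same deletion (AT>A) written with redundant flanking bases
        (98, "GCATT", "GCAT"),
        (97, "TGCATTGC", "TGCATGC"),
        (95, "ACGTGATGCA", "ACGTGAGCA"),
    ])
    def test_padded_deletion_matches_oracle_and_minimal_key(self, padded):
        pos, ref, alt = padded
        got = normalize_variant("chr1", pos, ref, alt)
        assert got == ("chr1",) + oracle_minimal_form(pos, ref, alt)
        assert got == ("chr1", 100, "AT", "A")

    @given(
        pos=st.integers(1, 1000),
        core_ref=st.text("ACGT", min_size=1, max_size=4),
        core_alt=st.text("ACGT", min_size=1, max_size=4),
        left=st.text("ACGT", max_size=3),
        right=st.text("ACGT", max_size=3),
    )
    @settings(max_examples=300, derandomize=True)
    def test_padding_invariance_matches_oracle(self, pos, core_ref, core_alt, left, right):
        """Adding shared flanks never changes the normalized key, and the
        greedy suffix-then-prefix trim agrees with the exhaustive oracle."""
        if core_ref == core_alt:
            return
        ref, alt = left + core_ref + right, left + core_alt + right
        got = normalize_variant("c", pos, ref, alt)
        assert got == ("c",) + oracle_minimal_form(pos, ref, alt)
        # idempotence: normalizing the output is the identity
        assert normalize_variant(*got) == got

    def test_ref_equal_alt_rejected(self):
        with pytest.raises(ValueError, match="not a variant"):
            normalize_variant("chr1", 100, "AC", "AC")

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant("chr1", 100, "", "A")


# --- MAF and popmax ----------------------------------------------------------


class TestMaf:
    @pytest.mark.parametrize("ac,an,expected", [
        (0, 10000, 0.0),
        (10, 10000, 0.001),
        (19998, 20000, 0.0001),  # folded to the minor allele
        (5, 10, 0.5),
    ])
    def test_values(self, ac, an, expected):
        assert maf(ac, an) == pytest.approx(expected)

    def test_an_zero_is_undefined(self):
        assert maf(0, 0) is None

    def test_ac_above_an_rejected(self):
        with pytest.raises(ValueError):
            maf(11, 10)

    @given(an=st.integers(1, 10**6), ac=st.integers(0, 10**6))
    @settings(max_examples=200, derandomize=True)
    def test_folded_range(self, an, ac):
        if ac > an:
            ac = ac % (an + 1)
        f = maf(ac, an)
        assert 0.0 <= f <= 0.5


@st.composite
def random_record(draw, max_f=0.5):
    """A record whose alternate allele is the minor allele in every population."""
    per_pop = {}
    for p in DEFAULT_POPULATIONS:
        an = draw(st.sampled_from([0, 200, 2000, 20000, 150000]))
        ac = draw(st.integers(0, int(an * max_f))) if an else 0
        per_pop[p] = (ac, an, 0)
    return make_record(per_pop)


class TestPopmax:
    def test_max_and_argmax(self):
        rec = make_record({"EUR": (10, 20000, 0), "FIN": (40, 20000, 0)})
        f, pop = popmax_maf(rec)
        assert (f, pop) == (pytest.approx(0.002), "FIN")

    def test_all_undefined(self):
        rec = make_record({})
        assert popmax_maf(rec) == (None, None)

    def test_empty_population_set_rejected(self):
        with pytest.raises(ValueError):
            popmax_maf(make_record({}), pops=())

    def test_ties_break_by_population_order(self):
        rec = make_record({"FIN": (20, 20000, 0), "AFR": (20, 20000, 0)})
        assert popmax_maf(rec)[1] == "AFR"  # AFR precedes FIN in the fixed order

    @given(rec=random_record())
    @settings(max_examples=200, derandomize=True)
    def test_matches_bruteforce_enumeration(self, rec):
        per_pop = {p: maf(c.ac, c.an) for p, c in rec.per_population.items()}
        defined = {p: f for p, f in per_pop.items() if f is not None}
        got_f, got_p = popmax_maf(rec)
        if not defined:
            assert (got_f, got_p) == (None, None)
        else:
            assert got_f == max(defined.values())
            assert defined[got_p] == got_f

    @given(rec=random_record())
    @settings(max_examples=200, derandomize=True)
    def test_pooled_never_exceeds_popmax(self, rec):
        """Weighted-mean <= max, in the minor-alternate-allele regime."""
        pooled = rec.maf_global()
        best, _ = popmax_maf(rec)
        if pooled is not None:
            assert best is not None
            assert pooled <= best + 1e-12


# --- VCF and table I/O -------------------------------------------------------


def write_vcf_text(path, body, pops=("afr", "fin")):
    lines = ["##fileformat=VCFv4.2", '##FILTER=<ID=RF,Description="random forest">']
    for p in pops:
        lines += [
            f'##INFO=<ID=AC_{p},Number=A,Type=Integer,Description="">',
            f'##INFO=<ID=AN_{p},Number=1,Type=Integer,Description="">',
            f'##INFO=<ID=nhomalt_{p},Number=A,Type=Integer,Description="">',
        ]
    lines += ['##contig=<ID=chr1,length=100000>',
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    path.write_text("\n".join(lines + body) + "\n")
    return path


class TestReadVcf:
    def test_multiallelic_site_splits(self, tmp_path):
        body = [
            "chr1\t100\t.\tA\tG\t.\tPASS\tAC_afr=1;AN_afr=100;nhomalt_afr=0;AC_fin=2;AN_fin=200;nhomalt_fin=0",
            "chr1\t200\t.\tC\tT,G\t.\tPASS\tAC_afr=3,4;AN_afr=100;nhomalt_afr=0,0;AC_fin=0,0;AN_fin=200;nhomalt_fin=0,0",
        ]
        path = write_vcf_text(tmp_path / "s.vcf", body)
        recs = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        assert len(recs) == 3
        t_rec = next(r for r in recs if r.alt == "T")
        assert t_rec.per_population["AFR"] == PopCounts(3, 100, 0)
        g_rec = next(r for r in recs if r.alt == "G" and r.position == 200)
        assert g_rec.per_population["AFR"] == PopCounts(4, 100, 0)
        # AN is shared across the split alts
        assert t_rec.global_an == g_rec.global_an == 300

    def test_non_pass_filter_maps_to_fail(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG\t.\tRF\tAC_afr=1;AN_afr=100;nhomalt_afr=0;AC_fin=0;AN_fin=0;nhomalt_fin=0"]
        path = write_vcf_text(tmp_path / "s.vcf", body)
        (rec,) = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        assert rec.filter_status == "fail"

    def test_missing_population_key_gives_zeros_with_warning(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG\t.\tPASS\tAC_fin=100;AN_fin=20000;nhomalt_fin=0"]
        path = write_vcf_text(tmp_path / "s.vcf", body, pops=("fin",))
        with pytest.warns(FrequencyStoreWarning) as caught:
            (rec,) = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        assert rec.per_population["FIN"] == PopCounts(100, 20000, 0)
        assert rec.per_population["AFR"] == PopCounts(0, 0, 0)
        # one warning per absent key, once each
        messages = sorted(str(w.message).split("'")[1] for w in caught)
        assert messages == ["AC_afr", "AN_afr", "nhomalt_afr"]

    def test_ac_above_an_record_rejected_with_warning(self, tmp_path):
        body = ["chr1\t100\t.\tA\tG\t.\tPASS\tAC_afr=500;AN_afr=100;nhomalt_afr=0;AC_fin=0;AN_fin=0;nhomalt_fin=0"]
        path = write_vcf_text(tmp_path / "s.vcf", body)
        with pytest.warns(FrequencyStoreWarning, match="rejected"):
            recs = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        assert recs == []

    def test_emitted_records_are_normalized_and_stable(self, tmp_path):
        body = ["chr1\t100\t.\tAT\tAG\t.\tPASS\tAC_afr=1;AN_afr=100;nhomalt_afr=0;AC_fin=0;AN_fin=0;nhomalt_fin=0"]
        path = write_vcf_text(tmp_path / "s.vcf", body)
        (rec,) = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        assert rec.key == ("chr1", 101, "T", "G")
        assert rec.normalized() is rec


class TestReadTable:
    def test_eight_rows_collapse_to_one_record(self, tmp_path):
        p = tmp_path / "t.tsv"
        header = "contig\tposition\tref\talt\tfilter\tpop\tac\tan\tnhom\n"
        rows = "".join(
            f"chr1\t100\tA\tG\tPASS\t{pop}\t1\t100\t0\n" for pop in DEFAULT_POPULATIONS
        )
        p.write_text(header + rows)
        (rec,) = list(read_frequency_table(p))
        assert len(rec.per_population) == 8
        assert rec.global_ac == 8

    def test_empty_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("contig\tposition\tref\talt\tfilter\tpop\tac\tan\tnhom\n")
        assert list(read_frequency_table(p)) == []

    def test_conflicting_duplicate_rows_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "contig\tposition\tref\talt\tfilter\tpop\tac\tan\tnhom\n"
            "chr1\t100\tA\tG\tPASS\tAFR\t1\t100\t0\n"
            "chr1\t100\tA\tG\tPASS\tAFR\t2\t100\t0\n"
        )
        with pytest.raises(ValueError, match="conflicting"):
            list(read_frequency_table(p))

    def test_missing_column_error(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("contig\tposition\tref\talt\tpop\tac\tan\tnhom\nchr1\t1\tA\tG\tAFR\t0\t0\t0\n")
        with pytest.raises(ValueError, match="filter"):
            list(read_frequency_table(p))


class TestWriteReadRoundTrip:
    def test_vcf_and_table_routes_agree(self, tmp_path, demo_data):
        records = demo_data.records
        vcf_path = tmp_path / "store.vcf"
        tsv_path = tmp_path / "store.tsv"
        pops = list(demo_data.spec.populations)
        write_frequency_vcf(records, vcf_path, pops=pops)
        write_frequency_table(records, tsv_path)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from_vcf = {r.key: r.per_population for r in read_frequency_vcf(vcf_path, pops=pops)}
        from_tsv = {r.key: r.per_population for r in read_frequency_table(tsv_path)}
        assert from_vcf == from_tsv
        assert len(from_vcf) == len(records)

    def test_an_mass_preserved_by_split_and_roundtrip(self, tmp_path):
        body = ["chr1\t200\t.\tC\tT,G\t.\tPASS\tAC_afr=3,4;AN_afr=100;nhomalt_afr=0,0;AC_fin=1,0;AN_fin=200;nhomalt_fin=0,0"]
        path = write_vcf_text(tmp_path / "s.vcf", body)
        recs = list(read_frequency_vcf(path, pops=("AFR", "FIN")))
        for rec in recs:  # every emitted alt keeps the site AN per population
            assert rec.per_population["AFR"].an == 100
            assert rec.per_population["FIN"].an == 200
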