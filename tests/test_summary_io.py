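"""Data model, file round trips, harmonization and proxy lookup."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pqtlmr.exceptions import EmptyInputError, MissingLdError, SummaryFormatError
from pqtlmr.summary_io import (
    DropSignal,
    LdMatrix,
    RegionStats,
    VariantKey,
    find_proxy,
    harmonize_pair,
    read_ld_matrix,
    read_region_stats,
    write_ld_matrix,
    write_region_stats,
)

from conftest import make_record, make_variant


HEADER = (
    "chromosome\tbase_pair_location\trsid\teffect_allele\tother_allele\t"
    "effect_allele_frequency\tbeta\tstandard_error\tp_value\tn\n"
)


def _write(tmp_path, rows, header=HEADER, name="stats.tsv"):
    path = tmp_path / name
    path.write_text(header + "".join(rows))
    return path


class TestRegionIO:
    def test_well_formed_file_round_trips(self, tmp_path):
        rows = [
            f"1\t{100 + i}\trs{i}\tA\tG\t0.3\t0.1\t0.02\t1e-6\t10000\n" for i in range(3)
        ]
        stats = read_region_stats(_write(tmp_path, rows), "prot")
        assert len(stats) == 3
        assert stats.trait_id == "prot"
        out = tmp_path / "out.tsv"
        write_region_stats(stats, out)
        again = read_region_stats(out, "prot")
        assert again.records == stats.records

    def test_invalid_rows_dropped_not_fatal(self, tmp_path):
        rows = [
            "1\t100\trs0\tA\tG\t0.3\t0.1\t0.02\t1e-6\t10000\n",
            "1\t101\trs1\tA\tG\t0.3\t0.1\t0\t1e-6\t10000\n",  # se = 0
            "1\t102\trs2\tA\tG\t0.3\t0.1\t0.02\t1e-6\t10000\n",
        ]
        stats = read_region_stats(_write(tmp_path, rows), "prot")
        assert stats.rsids == ["rs0", "rs2"]

    def test_missing_column_names_the_column(self, tmp_path):
        header = HEADER.replace("\tbeta", "")
        rows = ["1\t100\trs0\tA\tG\t0.3\t0.02\t1e-6\t10000\n"]
        with pytest.raises(SummaryFormatError, match="beta"):
            read_region_stats(_write(tmp_path, rows, header=header), "prot")

    def test_empty_file_raises(self, tmp_path):
        with pytest.raises(EmptyInputError):
            read_region_stats(_write(tmp_path, []), "prot")

    def test_trait_type_preserved_through_round_trip(self, tmp_path):
        rec = make_record(
            trait_type="case_control", n=20_000, n_case=8_000, n_control=12_000
        )
        stats = RegionStats(records=[rec])
        path = tmp_path / "cc.tsv"
        write_region_stats(stats, path)
        again = read_region_stats(path, rec.trait_id)
        assert again.records[0].trait_type == "case_control"
        assert again.records[0].n_case == 8_000

    def test_precision_at_least_ten_significant_digits(self, tmp_path):
        rec = make_record(beta=0.123456789012345, se=1.23456789012e-3)
        path = tmp_path / "prec.tsv"
        write_region_stats(RegionStats(records=[rec]), path)
        again = read_region_stats(path, rec.trait_id).records[0]
        assert again.beta == pytest.approx(rec.beta, rel=1e-10)
        assert again.se == pytest.approx(rec.se, rel=1e-10)


class TestLdIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(4, 4))
        r = np.corrcoef(a)
        variants = [make_variant(rsid=f"rs{i}", pos=100 + i) for i in range(4)]
        ld = LdMatrix(variants=variants, r=r, build_label="GRCh38")
        write_ld_matrix(ld, tmp_path / "m.txt", tmp_path / "v.tsv", tmp_path / "meta.json")
        again = read_ld_matrix(tmp_path / "m.txt", tmp_path / "v.tsv", tmp_path / "meta.json")
        assert np.allclose(again.r, r)
        assert again.build_label == "GRCh38"
        assert [v.rsid for v in again.variants] == [v.rsid for v in variants]

    def test_invariants_enforced(self):
        variants = [make_variant(rsid=f"rs{i}", pos=100 + i) for i in range(2)]
        with pytest.raises(ValueError):
            LdMatrix(variants=variants, r=np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            LdMatrix(variants=variants, r=np.array([[2.0, 0.5], [0.5, 1.0]]))


class TestHarmonize:
    def test_flipped_effect_allele_negates_beta(self):
        exp = make_record(ea="A", oa="G", beta=0.3)
        out = make_record(ea="G", oa="A", beta=0.2, eaf=0.7, trait_id="cancer")
        _, h = harmonize_pair(exp, out)
        assert h.beta == pytest.approx(-0.2)
        assert h.eaf == pytest.approx(0.3)
        assert h.variant.effect_allele == "A"
        assert h.variant.other_allele == "G"

    def test_opposite_strand_complemented(self):
        exp = make_record(ea="A", oa="G", beta=0.3, eaf=0.3)
        out = make_record(ea="T", oa="C", beta=0.2, eaf=0.3, trait_id="cancer")
        _, h = harmonize_pair(exp, out)
        assert h.beta == pytest.approx(0.2)
        assert h.variant.effect_allele == "A"

    def test_opposite_strand_and_flip(self):
        exp = make_record(ea="A", oa="G", beta=0.3, eaf=0.3)
        out = make_record(ea="C", oa="T", beta=0.2, eaf=0.7, trait_id="cancer")
        _, h = harmonize_pair(exp, out)
        assert h.beta == pytest.approx(-0.2)
        assert h.eaf == pytest.approx(0.3)

    def test_palindrome_at_half_frequency_dropped(self):
        exp = make_record(ea="A", oa="T", eaf=0.5)
        out = make_record(ea="A", oa="T", eaf=0.5, trait_id="cancer")
        result = harmonize_pair(exp, out)
        assert isinstance(result, DropSignal)
        assert result.reason == "ambiguous-palindrome"

    def test_palindrome_with_high_maf_dropped(self):
        exp = make_record(ea="C", oa="G", eaf=0.45)
        out = make_record(ea="C", oa="G", eaf=0.44, trait_id="cancer")
        assert isinstance(harmonize_pair(exp, out), DropSignal)

    def test_palindrome_with_low_maf_retained(self):
        exp = make_record(ea="A", oa="T", eaf=0.1)
        out = make_record(ea="T", oa="A", eaf=0.9, beta=0.2, trait_id="cancer")
        _, h = harmonize_pair(exp, out)
        assert h.beta == pytest.approx(-0.2)
        assert h.eaf == pytest.approx(0.1)

    def test_irreconcilable_alleles_drop(self):
        exp = make_record(ea="A", oa="G")
        out = make_record(ea="A", oa="C", trait_id="cancer")
        result = harmonize_pair(exp, out)
        assert isinstance(result, DropSignal)
        assert result.reason == "incompatible-alleles"

    @settings(derandomize=True, max_examples=50)
    @given(
        beta=st.floats(-1, 1, allow_nan=False),
        eaf=st.floats(0.05, 0.95),
        flip=st.booleans(),
    )
    def test_idempotent(self, beta, eaf, flip):
        exp = make_record(ea="A", oa="G", beta=0.3, eaf=0.3)
        if flip:
            out = make_record(ea="G", oa="A", beta=beta, eaf=eaf, trait_id="cancer")
        else:
            out = make_record(ea="A", oa="G", beta=beta, eaf=eaf, trait_id="cancer")
        first = harmonize_pair(exp, out)
        assert not isinstance(first, DropSignal)
        second = harmonize_pair(*first)
        assert second[1] == first[1]


class TestFindProxy:
    def _panel(self, r01):
        variants = [make_variant(rsid=f"rs{i}", pos=100 + i) for i in range(3)]
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        return variants, LdMatrix(variants=variants, r=r)

    def test_threshold_pass(self):
        variants, ld = self._panel(np.sqrt(0.85))
        region = RegionStats(records=[make_record(rsid="rs1", pos=101, trait_id="cancer")])
        rec, sign = find_proxy(variants[0], region, ld, min_r2=0.8)
        assert rec.variant.rsid == "rs1"
        assert sign == 1

    def test_threshold_fail_returns_none(self):
        variants, ld = self._panel(np.sqrt(0.5))
        region = RegionStats(records=[make_record(rsid="rs1", pos=101, trait_id="cancer")])
        assert find_proxy(variants[0], region, ld, min_r2=0.8) is None

    def test_negative_r_propagates_sign(self):
        variants, ld = self._panel(-0.95)
        region = RegionStats(records=[make_record(rsid="rs1", pos=101, trait_id="cancer")])
        rec, sign = find_proxy(variants[0], region, ld, min_r2=0.8)
        assert sign == -1

    def test_missing_target_raises(self):
        variants, ld = self._panel(0.9)
        region = RegionStats(records=[make_record(rsid="rs1", pos=101, trait_id="cancer")])
        stranger = make_variant(rsid="rs99", pos=999)
        with pytest.raises(MissingLdError):
            find_proxy(stranger, region, ld)


def test_variant_invariants():
    with pytest.raises(ValueError):
        VariantKey("1", 100, "rs1", "A", "A")
    with pytest.raises(ValueError):
        VariantKey("1", 0, "rs1", "A", "G")
    v = VariantKey("1", 100, "rs1", "a", "g")
    assert v.effect_allele == "A" and v.other_allele == "G"
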