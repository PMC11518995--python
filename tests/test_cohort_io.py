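"""Cohort containers, VCF/TSV round trips and copy-number lookup."""

import numpy as np
import pandas as pd
import pytest

from embryophylo.cohort import (
    CohortError,
    CohortTable,
    CopyNumberProfile,
    SampleMeta,
    VariantSite,
    cn_at,
)
from embryophylo.io import (
    ParseError,
    read_cohort,
    read_copy_number,
    write_cohort,
    write_copy_number,
)

from conftest import make_site


class TestVariantSite:
    def test_class_inference(self):
        assert make_site(ref="A", alt="T").variant_class == "SNV"
        assert make_site(ref="AT", alt="GC").variant_class == "DNV"
        assert make_site(ref="A", alt="AT").variant_class == "insertion"
        assert make_site(ref="AT", alt="A").variant_class == "deletion"

    def test_duplication_accepted_as_insertion_shape(self):
        v = make_site(ref="A", alt="ATTTGCATTTGCA", vclass="duplication")
        assert v.variant_class == "duplication"

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pos=0),
            dict(ref="A", alt="A"),
            dict(ref="A", alt="AT", vclass="SNV"),
            dict(ref="AT", alt="A", vclass="duplication"),
        ],
    )
    def test_invalid_sites_rejected(self, kwargs):
        with pytest.raises(CohortError):
            make_site(**{"chrom": "1", "pos": 5, **kwargs})


def _toy_table(n_samples=6, n_sites=15):
    rng = np.random.default_rng(0)
    sites = [make_site(chrom=str(1 + i % 3), pos=10 * i + 7) for i in range(n_sites - 2)]
    sites.append(make_site(chrom="4", pos=99, ref="CT", alt="TA", vclass="DNV"))
    sites.append(make_site(chrom="4", pos=200, ref="G",
                           alt="G" + "ACGTACGTACGT", vclass="duplication"))
    roles = ["tumour", "tumour", "tumour", "tumour", "normal_kidney", "blood"]
    samples = [SampleMeta(f"S{j}", roles[j % len(roles)]) for j in range(n_samples)]
    depth = rng.integers(10, 200, size=(n_sites, n_samples))
    alt = rng.binomial(depth, 0.4)
    return CohortTable(sites, samples, alt, depth)


class TestRoundTrip:
    @pytest.mark.parametrize("fmt", ["tsv", "vcf"])
    def test_write_read_identity(self, fmt, tmp_path):
        table = _toy_table().sorted()
        path = tmp_path / f"cohort.{fmt}"
        write_cohort(table, path, fmt)
        back = read_cohort([path], fmt, table.samples)
        assert back.equals(table)

    @pytest.mark.parametrize("fmt", ["tsv", "vcf"])
    def test_empty_table_round_trip(self, fmt, tmp_path):
        samples = [SampleMeta("T1", "tumour")]
        table = CohortTable([], samples, np.zeros((0, 1)), np.zeros((0, 1)))
        path = tmp_path / f"empty.{fmt}"
        write_cohort(table, path, fmt)
        back = read_cohort([path], fmt, samples)
        assert back.n_sites == 0 and back.sample_ids == ["T1"]

    def test_non_snv_records_preserved(self, tmp_path):
        table = _toy_table().sorted()
        path = tmp_path / "c.vcf"
        write_cohort(table, path, "vcf")
        back = read_cohort([path], "vcf", table.samples)
        classes = {s.variant_class for s in back.sites}
        assert {"DNV", "duplication"} <= classes


class TestUnionSemantics:
    def test_union_of_overlapping_vcfs(self, tmp_path):
        """Two single-sample files sharing 1 of 3 records union to 5 sites;
        a sample missing a site gets depth 0 (no coverage)."""
        s1 = [make_site(pos=p) for p in (10, 20, 30)]
        s2 = [make_site(pos=p) for p in (30, 40, 50)]
        m1 = [SampleMeta("A", "tumour")]
        m2 = [SampleMeta("B", "tumour")]
        t1 = CohortTable(s1, m1, [[5], [6], [7]], [[50], [60], [70]])
        t2 = CohortTable(s2, m2, [[1], [2], [3]], [[10], [20], [30]])
        write_cohort(t1, tmp_path / "a.vcf", "vcf")
        write_cohort(t2, tmp_path / "b.vcf", "vcf")
        merged = read_cohort(
            [tmp_path / "a.vcf", tmp_path / "b.vcf"], "vcf", m1 + m2
        )
        assert merged.n_sites == 5
        assert [s.pos for s in merged.sites] == [10, 20, 30, 40, 50]
        i = [s.pos for s in merged.sites].index(40)
        j = merged.sample_index("A")
        assert merged.depth[i, j] == 0 and merged.alt[i, j] == 0
        assert np.isnan(merged.vaf()[i, j])

    def test_empty_file_list(self):
        table = read_cohort([], "tsv", [SampleMeta("A", "tumour")])
        assert table.n_sites == 0

    def test_duplicate_sample_id_rejected(self):
        with pytest.raises(CohortError):
            read_cohort([], "tsv", [SampleMeta("A", "tumour"),
                                    SampleMeta("A", "blood")])

    def test_site_order_deterministic(self, tmp_path):
        table = _toy_table()
        shuffled = table.subset_sites(
            np.random.default_rng(5).permutation(table.n_sites)
        )
        write_cohort(table, tmp_path / "a.tsv", "tsv")
        write_cohort(shuffled, tmp_path / "b.tsv", "tsv")
        a = read_cohort([tmp_path / "a.tsv"], "tsv", table.samples)
        b = read_cohort([tmp_path / "b.tsv"], "tsv", table.samples)
        assert a.equals(b)

    def test_malformed_tsv_names_file_and_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\tref\talt\tS.alt\tS.depth\n1\t-5\tA\tT\t1\t2\n")
        with pytest.raises(ParseError, match="bad.tsv.*line"):
            read_cohort([path], "tsv", [SampleMeta("S", "tumour")])


class TestCopyNumber:
    def test_bed_dialect_conversion(self, tmp_path):
        path = tmp_path / "cn.tsv"
        pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [1000],
             "total_cn": [1], "minor_cn": [0]}
        ).to_csv(path, sep="\t", index=False)
        prof = read_copy_number(path, purity=0.9)
        assert prof.segments == [("1", 1, 1000, 1, 0)]
        assert prof.cn_at("1", 1) == (1, 0)
        assert prof.cn_at("1", 1000) == (1, 0)
        assert prof.cn_at("1", 1001) == (2, 1)

    def test_round_trip(self, tmp_path):
        prof = CopyNumberProfile("T", 0.8, [("2", 11, 500, 3, 1)])
        write_copy_number(prof, tmp_path / "cn.tsv")
        back = read_copy_number(tmp_path / "cn.tsv", purity=0.8, sample_id="T")
        assert back.segments == prof.segments

    def test_overlap_rejected(self):
        with pytest.raises(CohortError, match="overlap"):
            CopyNumberProfile("T", 1.0, [("1", 1, 100, 2, 1), ("1", 50, 200, 2, 1)])

    def test_total_less_than_minor_rejected(self):
        with pytest.raises(CohortError):
            CopyNumberProfile("T", 1.0, [("1", 1, 100, 1, 2)])

    def test_order_invariance(self):
        segs = [("1", 101, 200, 1, 0), ("1", 1, 100, 2, 0), ("2", 1, 50, 3, 1)]
        a = CopyNumberProfile("T", 1.0, segs)
        b = CopyNumberProfile("T", 1.0, list(reversed(segs)))
        for chrom, pos in [("1", 1), ("1", 100), ("1", 101), ("1", 150),
                           ("2", 25), ("2", 51), ("3", 7)]:
            assert a.cn_at(chrom, pos) == b.cn_at(chrom, pos)

    def test_lookup_is_total(self):
        """cn_at returns the diploid default everywhere outside segments."""
        prof = CopyNumberProfile("T", 1.0, [("1", 100, 200, 1, 0)])
        assert cn_at(prof, "1", 99) == (2, 1)
        assert cn_at(prof, "1", 100) == (1, 0)   # start boundary inclusive
        assert cn_at(prof, "1", 200) == (1, 0)   # end boundary inclusive
        assert cn_at(prof, "1", 201) == (2, 1)
        assert cn_at(prof, "X", 5) == (2, 1)     # uncovered chromosome


class TestCohortTable:
    def test_count_consistency_enforced(self):
        samples = [SampleMeta("A", "tumour")]
        with pytest.raises(CohortError):
            CohortTable([make_site()], samples, [[5]], [[4]])  # alt > depth

    def test_vaf_nan_only_at_zero_depth(self):
        samples = [SampleMeta("A", "tumour"), SampleMeta("B", "blood")]
        t = CohortTable([make_site()], samples, [[3, 0]], [[10, 0]])
        v = t.vaf()
        assert v[0, 0] == 0.3 and np.isnan(v[0, 1])
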