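"""Site/panel/report I-O: parsing rules, validation, round trips."""

import numpy as np
import pandas as pd
import pytest

from snp_ploidy import (SNPPanel, SNPSite, read_site_table, read_vcf_sites,
                        sites_to_frame, write_report, write_site_table)
from snp_ploidy.classifier import IntervalCounts, PloidyCall, fit_parabola
from snp_ploidy.sites import SiteFormatError, iter_sites
from snp_ploidy.upd import UPDCall


class TestSNPSite:
    def test_valid_site_and_total_depth(self):
        s = SNPSite("chr1", 12345, "A", "G", 7, 8, 0.31)
        assert s.total_depth == 15

    @pytest.mark.parametrize("kwargs", [
        dict(ref="AA", alt="G"),           # not a single base
        dict(ref="N", alt="G"),            # outside ACGT
        dict(ref="A", alt="A"),            # identical alleles
        dict(ref_depth=-3),                # negative depth
        dict(pos=0),                       # 1-based coordinates
        dict(panel_af=1.5),                # AF outside [0,1]
    ])
    def test_invalid_sites_rejected(self, kwargs):
        base = dict(chrom="chr1", pos=100, ref="A", alt="G",
                    ref_depth=5, alt_depth=5, panel_af=0.2)
        base.update(kwargs)
        with pytest.raises(SiteFormatError):
            SNPSite(**base)


class TestReadVCF:
    def test_field_mapping(self, tiny_vcf):
        df, stats = read_vcf_sites(tiny_vcf, "S1")
        first = df.iloc[0]
        assert (first.chrom, first.pos, first.ref, first.alt) == ("chr1", 12345, "A", "G")
        assert (first.ref_depth, first.alt_depth) == (7, 8)

    def test_skip_counters(self, tiny_vcf):
        df, stats = read_vcf_sites(tiny_vcf, "S1")
        assert stats.n_multiallelic == 1
        assert stats.n_indel == 1
        assert stats.n_no_allelic_depth == 1
        assert stats.n_kept == len(df) == 3

    def test_zero_depth_site_retained(self, tiny_vcf):
        df, _ = read_vcf_sites(tiny_vcf, "S1")
        z = df[(df.chrom == "chr2") & (df.pos == 100)]
        assert len(z) == 1 and z.iloc[0].ref_depth == 0 and z.iloc[0].alt_depth == 0

    def test_per_sample_depths_differ(self, tiny_vcf):
        df1, _ = read_vcf_sites(tiny_vcf, "S1")
        df2, _ = read_vcf_sites(tiny_vcf, "S2")
        assert df1.iloc[0].alt_depth == 8 and df2.iloc[0].alt_depth == 0

    def test_unknown_sample_raises(self, tiny_vcf):
        with pytest.raises(KeyError, match="NOPE"):
            read_vcf_sites(tiny_vcf, "NOPE")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_vcf_sites(tmp_path / "absent.vcf", "S1")


class TestSiteTable:
    def test_parse_line(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom\tpos\tref\talt\tref_depth\talt_depth\tpanel_af\n"
                     "chr2\t100\tC\tT\t12\t11\t0.31\n")
        df = read_site_table(p)
        assert len(df) == 1
        assert df.iloc[0].panel_af == pytest.approx(0.31)

    def test_empty_table_and_missing_af(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom\tpos\tref\talt\tref_depth\talt_depth\tpanel_af\n")
        assert len(read_site_table(p)) == 0
        p.write_text("chrom\tpos\tref\talt\tref_depth\talt_depth\tpanel_af\n"
                     "chr1\t5\tA\tG\t3\t4\t\n")
        df = read_site_table(p)
        assert np.isnan(df.iloc[0].panel_af)

    def test_bad_header_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("pos\tchrom\tref\talt\tref_depth\talt_depth\tpanel_af\n")
        with pytest.raises(SiteFormatError, match="header"):
            read_site_table(p)

    @pytest.mark.parametrize("depth", ["-3", "x", "2.5"])
    def test_bad_depth_names_line(self, tmp_path, depth):
        p = tmp_path / "s.tsv"
        p.write_text("chrom\tpos\tref\talt\tref_depth\talt_depth\tpanel_af\n"
                     "chr1\t5\tA\tG\t3\t4\t0.2\n"
                     f"chr1\t9\tA\tG\t{depth}\t4\t0.2\n")
        with pytest.raises(SiteFormatError, match="line 3"):
            read_site_table(p)

    def test_round_trip_preserves_order_and_values(self, tmp_path):
        sites = [SNPSite("chr2", 100, "C", "T", 12, 11, 0.31),
                 SNPSite("chr1", 7, "A", "G", 0, 25, None),
                 SNPSite("chr1", 3, "G", "C", 4, 4, 0.05)]
        df = sites_to_frame(sites)
        p = tmp_path / "rt.tsv"
        write_site_table(df, p)
        back = read_site_table(p)
        pd.testing.assert_frame_equal(df, back)
        assert [s.pos for s in iter_sites(back)] == [100, 7, 3]


class TestPanel:
    def test_duplicate_positions_rejected(self):
        sites = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [5, 5],
                              "ref": ["A", "A"], "alt": ["G", "C"],
                              "af": [0.1, 0.2]})
        with pytest.raises(SiteFormatError, match="unique"):
            SNPPanel(sites=sites)

    def test_gap_beyond_chromosome_rejected(self, toy_panel):
        with pytest.raises(SiteFormatError, match="gap"):
            SNPPanel(sites=toy_panel.sites,
                     chrom_sizes={"chr1": 1000},
                     gaps={"chr1": [(500, 2000)]})


class TestWriteReport:
    def _call(self):
        counts = IntervalCounts(10, 20, 10, 2000)
        fit = fit_parabola(counts)
        return PloidyCall(sample_id="S1", verdict="diploid", ratio=1.0,
                          fit=fit, z=0.5, counts=counts, flags={"low_sites"})

    def test_report_contains_statistics(self, tmp_path):
        write_report(self._call(), [], tmp_path)
        text = (tmp_path / "report.yaml").read_text()
        for key in ("verdict", "ratio_statistic", "parabola", "z_score",
                    "n_candidate_sites", "flags"):
            assert key in text

    def test_deterministic_serialisation(self, tmp_path):
        upd = [UPDCall("chr1", 0, 5_000_000, "segmental", 5, 1.0)]
        write_report(self._call(), upd, tmp_path / "a")
        write_report(self._call(), upd, tmp_path / "b")
        assert ((tmp_path / "a" / "report.yaml").read_bytes()
                == (tmp_path / "b" / "report.yaml").read_bytes())
        assert ((tmp_path / "a" / "upd.bed").read_bytes()
                == (tmp_path / "b" / "upd.bed").read_bytes())

    def test_empty_upd_list_gives_header_only_bed(self, tmp_path):
        write_report(self._call(), [], tmp_path)
        lines = (tmp_path / "upd.bed").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("#")
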