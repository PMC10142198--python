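"""Region quantification, comparator calls and genomic-context annotation."""

import numpy as np
import pandas as pd
import pytest

from phumr import (
    GeneModel,
    GenomicInterval,
    RefUMR,
    annotate_cgi_context,
    assign_gene_context,
    classify_umr,
    conservation_mean,
    gcimp_call,
    missed_fraction,
    region_mean_delta,
)
from phumr.annotate import read_bedgraph, read_wig
from phumr.methylome import MethylationMatrix


def _matrix(positions, normal, tumor, chrom="chr1"):
    normal = np.asarray(normal, dtype=float)
    tumor = np.asarray(tumor, dtype=float)
    sites = pd.DataFrame({"chrom": chrom, "pos": np.asarray(positions)})
    return MethylationMatrix(
        sites=sites,
        levels=np.hstack([normal, tumor]),
        sample_ids=[f"s{i}" for i in range(normal.shape[1] + tumor.shape[1])],
        cohorts=np.array(["normal"] * normal.shape[1] + ["tumor"] * tumor.shape[1]),
    )


class TestRegionQuantification:
    def test_simple_means(self):
        m = _matrix([10, 20], [[0.2], [0.4]], [[0.6], [0.8]])
        q = region_mean_delta(m, GenomicInterval("chr1", 0, 100))
        assert q.mean_normal == pytest.approx(0.3)
        assert q.mean_tumor == pytest.approx(0.7)
        assert q.delta_region == pytest.approx(0.4)

    def test_identical_cohorts_zero_delta(self):
        levels = [[0.1], [0.5], [0.9]]
        m = _matrix([10, 20, 30], levels, levels)
        q = region_mean_delta(m, GenomicInterval("chr1", 0, 100))
        assert q.delta_region == pytest.approx(0.0)

    def test_masked_mean_oracle(self):
        rng = np.random.default_rng(6)
        normal = rng.uniform(size=(20, 4))
        tumor = rng.uniform(size=(20, 3))
        normal[rng.uniform(size=normal.shape) < 0.3] = np.nan
        m = _matrix(np.arange(20) * 10, normal, tumor)
        iv = GenomicInterval("chr1", 35, 125)  # CpGs at 40..120
        q = region_mean_delta(m, iv)
        rows = slice(4, 13)
        assert q.mean_normal == pytest.approx(np.nanmean(normal[rows]))
        assert q.mean_tumor == pytest.approx(np.nanmean(tumor[rows]))

    def test_region_without_cpgs_is_masked(self):
        m = _matrix([10], [[0.1]], [[0.9]])
        q = region_mean_delta(m, GenomicInterval("chr1", 500, 600))
        assert np.isnan(q.mean_normal) and np.isnan(q.mean_tumor)


class TestGcimpCall:
    def _cohorts(self, n_cpg, normal_mean, tumor_mean, n=6):
        jitter = np.linspace(-0.02, 0.02, n)
        normal = np.tile(normal_mean + jitter, (n_cpg, 1))
        tumor = np.tile(tumor_mean + jitter, (n_cpg, 1))
        return normal, tumor

    def test_clear_shift_is_called(self):
        normal, tumor = self._cohorts(8, 0.05, 0.30)
        m = _matrix(np.arange(8) * 10, normal, tumor)
        calls = gcimp_call(m, [GenomicInterval("chr1", 0, 100)])
        assert calls["gcimp"].iloc[0]
        assert calls["delta"].iloc[0] == pytest.approx(0.25)

    def test_small_shift_fails_effect_gate(self):
        normal, tumor = self._cohorts(8, 0.05, 0.20)
        m = _matrix(np.arange(8) * 10, normal, tumor)
        calls = gcimp_call(m, [GenomicInterval("chr1", 0, 100)])
        assert calls["delta"].iloc[0] == pytest.approx(0.15)
        assert not calls["gcimp"].iloc[0]

    def test_partial_erosion_missed_by_cgi_mean_but_caught_as_phumr(self):
        """30% of CpGs eroded at +0.5: CGI delta 0.15 < 0.2, yet phUMR called."""
        n_cpg = 20
        positions = np.arange(n_cpg) * 10
        eroded = np.zeros(n_cpg, dtype=bool)
        eroded[:6] = True  # 30%
        jitter = np.linspace(-0.02, 0.02, 6)
        normal = np.tile(0.05 + jitter, (n_cpg, 1))
        tumor = np.tile(0.05 + jitter, (n_cpg, 1)) + np.where(eroded, 0.5, 0.0)[:, None]
        m = _matrix(positions, normal, tumor)
        cgi = GenomicInterval("chr1", 0, 200)
        calls = gcimp_call(m, [cgi])
        assert calls["delta"].iloc[0] == pytest.approx(0.15)
        assert not calls["gcimp"].iloc[0]

        refumr = RefUMR(interval=cgi, n_cpg=n_cpg, support=1.0)
        deltas = np.where(eroded, 0.5, 0.0)
        c = classify_umr(refumr, positions, deltas, eroded)
        assert c.umr_class == "phUMR"
        assert c.mean_delta_whole == pytest.approx(0.15)
        assert c.mean_delta_hyper == pytest.approx(0.5)
        assert missed_fraction([c]) == 1.0


class TestMissedFraction:
    def _phumr(self, whole, hyper):
        n = 20
        pos = np.arange(n) * 10
        flags = np.zeros(n, dtype=bool)
        flags[:6] = True
        c = classify_umr(
            RefUMR(GenomicInterval("chr1", 0, 200), n, 1.0),
            pos,
            np.where(flags, hyper, (whole * n - 6 * hyper) / (n - 6)),
            flags,
        )
        assert c.umr_class == "phUMR"
        assert c.mean_delta_whole == pytest.approx(whole)
        return c

    def test_diluted_phumr_is_missed(self):
        assert missed_fraction([self._phumr(0.12, 0.45)]) == 1.0

    def test_strong_phumr_is_not_missed(self):
        assert missed_fraction([self._phumr(0.35, 0.8)]) == 0.0

    def test_counts_match_direct_enumeration(self):
        classified = [self._phumr(w, h) for w, h in
                      [(0.12, 0.45), (0.35, 0.8), (0.05, 0.3), (0.19, 0.5), (0.25, 0.6)]]
        assert missed_fraction(classified) == pytest.approx(3 / 5)

    def test_no_phumrs_rejected(self):
        with pytest.raises(ValueError, match="no phUMRs"):
            missed_fraction([])


def _context_oracle(interval, cgis):
    """Per-base nearest-CGI distance oracle for shore/shelf labels."""
    best = "open_sea"
    rank = {"open_sea": 0, "shelf": 1, "shore": 2, "CGI": 3}
    for b in range(interval.start, interval.end):
        d = None
        for c in cgis:
            if c.chrom != interval.chrom:
                continue
            if c.start <= b < c.end:
                dist = 0
            elif b < c.start:
                dist = c.start - b
            else:
                dist = b - c.end + 1
            d = dist if d is None else min(d, dist)
        if d is None:
            label = "open_sea"
        elif d == 0:
            label = "CGI"
        elif d <= 2000:
            label = "shore"
        elif d <= 4000:
            label = "shelf"
        else:
            label = "open_sea"
        if rank[label] > rank[best]:
            best = label
    return best


class TestCgiContext:
    CGIS = [GenomicInterval("chr1", 10_000, 11_000), GenomicInterval("chr1", 30_000, 30_500)]

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (10_200, 10_400, "CGI"),
            (11_900, 12_100, "shore"),  # ~1 kb beyond the edge
            (13_800, 14_100, "shelf"),  # ~3 kb beyond
            (20_500, 21_000, "open_sea"),  # ~10 kb away
            (9_500, 10_050, "CGI"),  # straddles CGI and shore: CGI wins
            (8_500, 8_600, "shore"),  # upstream flank counts too
        ],
    )
    def test_band_examples(self, start, end, expected):
        assert annotate_cgi_context(GenomicInterval("chr1", start, end), self.CGIS) == expected

    def test_matches_per_base_distance_oracle(self):
        rng = np.random.default_rng(8)
        cgis = []
        cursor = 0
        for _ in range(6):
            cursor += int(rng.integers(3_000, 15_000))
            cgis.append(GenomicInterval("chr1", cursor, cursor + int(rng.integers(200, 2_000))))
            cursor = cgis[-1].end
        for _ in range(100):
            start = int(rng.integers(0, cursor + 10_000))
            query = GenomicInterval("chr1", start, start + int(rng.integers(50, 1_500)))
            assert annotate_cgi_context(query, cgis) == _context_oracle(query, cgis)

    def test_label_is_a_single_partition(self):
        labels = {"CGI", "shore", "shelf", "open_sea"}
        q = GenomicInterval("chr1", 11_500, 11_600)
        assert annotate_cgi_context(q, self.CGIS) in labels


class TestGeneContext:
    GENES = [
        GeneModel("GENE_F", "chr1", "+", tss=50_000, tes=60_000),
        GeneModel("GENE_R", "chr1", "-", tss=90_000, tes=80_000),
    ]

    def test_upstream_window_is_promoter(self):
        hits = assign_gene_context(GenomicInterval("chr1", 48_900, 49_200), self.GENES)
        assert hits == [("GENE_F", "promoter")]

    def test_minus_strand_promoter_is_upstream_of_high_coordinate_tss(self):
        hits = assign_gene_context(GenomicInterval("chr1", 90_500, 91_000), self.GENES)
        assert hits == [("GENE_R", "promoter")]

    def test_intronic_interval_is_gene_body(self):
        hits = assign_gene_context(GenomicInterval("chr1", 55_000, 55_200), self.GENES)
        assert hits == [("GENE_F", "gene_body")]

    def test_interval_beyond_tes_is_unassigned(self):
        assert assign_gene_context(GenomicInterval("chr1", 65_000, 65_500), self.GENES) == []

    def test_two_overlapping_windows_yield_two_assignments(self):
        genes = self.GENES + [GeneModel("GENE_F2", "chr1", "+", tss=54_000, tes=70_000)]
        hits = assign_gene_context(GenomicInterval("chr1", 53_500, 54_500), genes)
        assert sorted(h[0] for h in hits) == ["GENE_F", "GENE_F2"]


class TestConservation:
    def test_constant_track(self):
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1000], "value": [0.5]})
        assert conservation_mean(GenomicInterval("chr1", 100, 200), track) == pytest.approx(0.5)

    def test_half_and_half(self):
        track = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 50], "end": [50, 100], "value": [0.0, 1.0]}
        )
        assert conservation_mean(GenomicInterval("chr1", 0, 100), track) == pytest.approx(0.5)

    def test_uncovered_interval_is_masked(self):
        track = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "value": [1.0]})
        assert np.isnan(conservation_mean(GenomicInterval("chr1", 0, 100), track))

    def test_sparse_track_matches_per_base_oracle(self):
        rng = np.random.default_rng(10)
        rows = []
        cursor = 0
        for _ in range(30):
            cursor += int(rng.integers(1, 50))
            end = cursor + int(rng.integers(1, 40))
            rows.append(("chr1", cursor, end, float(rng.uniform())))
            cursor = end
        track = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
        base_scores = np.full(cursor + 100, np.nan)
        for _, s, e, v in rows:
            base_scores[s:e] = v
        for _ in range(20):
            start = int(rng.integers(0, cursor))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(10, 200)))
            expected = base_scores[iv.start : iv.end]
            expected = expected[np.isfinite(expected)]
            got = conservation_mean(iv, track)
            if len(expected) == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected.mean())


class TestTrackParsers:
    def test_bedgraph(self, tmp_path):
        path = tmp_path / "t.bedgraph"
        path.write_text("chr1\t0\t10\t0.5\nchr1\t10\t20\t1.0\n")
        df = read_bedgraph(path)
        assert df["value"].tolist() == [0.5, 1.0]

    def test_fixed_step_wig(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text("fixedStep chrom=chr1 start=11 step=2 span=2\n0.1\n0.2\n")
        df = read_wig(path)
        # wig is 1-based: start=11 -> 0-based 10
        assert df[["start", "end"]].to_numpy().tolist() == [[10, 12], [12, 14]]

    def test_variable_step_wig(self, tmp_path):
        path = tmp_path / "t.wig"
        path.write_text("variableStep chrom=chr1 span=3\n101 0.7\n")
        df = read_wig(path)
        assert df.iloc[0]["start"] == 100 and df.iloc[0]["end"] == 103
        assert df.iloc[0]["value"] == pytest.approx(0.7)
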