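"""Contig classification, SNP projection and density summaries."""

import numpy as np
import pandas as pd
import pytest

from rrlsnp import comparative_overlay as co
from rrlsnp import synthetic_data as sd


def hit_row(q="c1", s="chr1", sstart=1001, send=1400, evalue=1e-80, bits=700.0):
    return {
        "qseqid": q, "sseqid": s, "pident": 92.0, "length": 400, "mismatch": 32,
        "gapopen": 0, "qstart": 1, "qend": 400, "sstart": sstart, "send": send,
        "evalue": evalue, "bitscore": bits,
    }


def as_hits(rows):
    return co.parse_hits(pd.DataFrame(rows))


class TestParseHits:
    def test_subthreshold_dropped(self):
        hits = as_hits([hit_row(evalue=1e-40)])
        assert hits.empty

    def test_minus_strand_normalized(self):
        hits = as_hits([hit_row(sstart=500, send=401)])
        row = hits.iloc[0]
        assert row["strand"] == "-"
        assert (row["s_lo"], row["s_hi"]) == (400, 500)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert co.parse_hits(str(p)).empty

    def test_file_round_trip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        pd.DataFrame([hit_row(), hit_row(s="chr2")]).to_csv(
            p, sep="\t", header=False, index=False
        )
        hits = co.parse_hits(str(p))
        assert list(hits["sseqid"]) == ["chr1", "chr2"]


class TestCountPositions:
    @pytest.mark.parametrize(
        "intervals,expected",
        [
            ([(100, 500), (300, 700)], 1),  # overlapping HSPs merge
            ([(100, 500), (1_000_100, 1_000_500)], 2),
            ([(0, 10), (20, 30), (40, 50), (60, 70)], 4),
            ([(0, 10), (10, 20)], 2),  # touching is not overlapping
        ],
    )
    def test_merging(self, intervals, expected):
        assert co.count_positions(intervals) == expected


class TestClassify:
    def test_single_hit_unique(self):
        pl = co.classify_contig("c1", as_hits([hit_row()]))
        assert pl.status == "unique"
        assert pl.chromosome == "chr1" and pl.n_positions == 1
        assert pl.interval == (1000, 1400)

    def test_one_chrom_plus_chrun_informative(self):
        rows = [hit_row(), hit_row(sstart=2_000_001, send=2_000_400),
                hit_row(s="chrUn.004", sstart=5001, send=5400)]
        pl = co.classify_contig("c1", as_hits(rows))
        assert pl.status == "informative_multi"
        assert pl.has_chrun_partner

    def test_two_chromosomes_uninformative(self):
        pl = co.classify_contig("c1", as_hits([hit_row(), hit_row(s="chr2")]))
        assert pl.status == "uninformative"

    def test_four_positions_uninformative(self):
        rows = [hit_row(sstart=1 + i * 1_000_000, send=400 + i * 1_000_000)
                for i in range(4)]
        assert co.classify_contig("c1", as_hits(rows)).status == "uninformative"

    def test_no_hits(self):
        assert co.classify_contig("c1", None).status == "no_hit"

    def test_partition_and_truth_roundtrip(self, bovine_like_chromosomes):
        plans = sd.random_hit_plans(500, bovine_like_chromosomes, seed=9)
        hits, truth = sd.simulate_surrogate_hits(plans, bovine_like_chromosomes)
        placements = co.classify_all(
            co.parse_hits(hits), all_contigs=[p.contig_id for p in plans]
        )
        # exact agreement with the generator's independently derived truth
        for row in truth.itertuples():
            assert placements[row.contig_id].status == row.status
        # the four statuses partition the contig set
        statuses = pd.Series([p.status for p in placements.values()]).value_counts()
        assert statuses.sum() == len(plans)


class TestProjection:
    def plus_placement(self):
        return co.classify_contig("c1", as_hits([hit_row()]))

    def minus_placement(self):
        return co.classify_contig("c1", as_hits([hit_row(sstart=1400, send=1001)]))

    def test_plus_strand_arithmetic(self):
        pl = self.plus_placement()
        # q_lo=0, s_lo=1000: offset 50 lands at chromosome position 1050 (0-based)
        assert co.project_snp(pl, 50) == 1050

    def test_minus_strand_mirrors(self):
        pl = self.minus_placement()
        assert co.project_snp(pl, 0) == 1399
        assert co.project_snp(pl, 50) == 1349

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_round_trip_both_strands(self, strand):
        pl = self.plus_placement() if strand == "+" else self.minus_placement()
        for off in (0, 1, 57, 399):
            cpos = co.project_snp(pl, off)
            assert co.reverse_project_snp(pl, cpos) == off

    def test_offset_outside_alignment_unprojected(self):
        pl = self.plus_placement()
        assert co.project_snp(pl, 400) is None
        snps = pd.DataFrame({"contig_id": ["c1"], "pos": [400]})
        out = co.project_snps(snps, {"c1": pl})
        assert out.iloc[0]["status"] == "outside_alignment"

    def test_snp_on_unplaced_contig_carried(self):
        snps = pd.DataFrame({"contig_id": ["cX"], "pos": [10]})
        out = co.project_snps(snps, {"cX": co.ContigPlacement("cX", "no_hit")})
        assert out.iloc[0]["status"] == "no_hit"


class TestSummaries:
    def test_single_chromosome_density(self):
        sizes = pd.DataFrame({"name": ["chr1"], "length": [10_000_000]})
        placements = {
            f"c{i}": co.ContigPlacement(
                f"c{i}", "unique", "chr1", "+", (i * 1000, i * 1000 + 400), (0, 400), 1
            )
            for i in range(100)
        }
        table, mean, sd_ = co.summarize(placements, None, sizes)
        assert table.iloc[0]["density_kb_per_hit"] == pytest.approx(100.0)
        assert mean == pytest.approx(100.0)

    def test_mean_and_sample_sd(self):
        sizes = pd.DataFrame({"name": ["chr1", "chr2"],
                              "length": [4_000_000, 5_000_000]})
        placements = {}
        for i in range(100):  # chr1: 40 kb/hit
            placements[f"a{i}"] = co.ContigPlacement(
                f"a{i}", "unique", "chr1", "+", (i * 100, i * 100 + 50), (0, 50), 1)
        for i in range(100):  # chr2: 50 kb/hit
            placements[f"b{i}"] = co.ContigPlacement(
                f"b{i}", "unique", "chr2", "+", (i * 100, i * 100 + 50), (0, 50), 1)
        _, mean, sd_ = co.summarize(placements, None, sizes)
        assert mean == pytest.approx(45.0)
        assert sd_ == pytest.approx(7.0710678, rel=1e-6)  # sample SD

    def test_density_additivity(self):
        sizes = pd.DataFrame({"name": ["chr1", "chr2"],
                              "length": [4_000_000, 5_000_000]})
        def make(n_per):
            pls = {}
            for c, chrom in enumerate(["chr1", "chr2"]):
                for i in range(n_per):
                    pls[f"{chrom}_{c}_{i}"] = co.ContigPlacement(
                        f"{chrom}_{c}_{i}", "unique", chrom, "+",
                        (i * 100, i * 100 + 50), (0, 50), 1)
            return pls
        t1, _, _ = co.summarize(make(10), None, sizes)
        t2, _, _ = co.summarize(make(20), None, sizes)
        assert (t2["density_kb_per_hit"] * 2 == t1["density_kb_per_hit"]).all()

    def test_zero_hit_chromosome_excluded_from_mean(self):
        sizes = pd.DataFrame({"name": ["chr1", "chr2"], "length": [10_000_000] * 2})
        placements = {"c0": co.ContigPlacement("c0", "unique", "chr1", "+",
                                               (0, 400), (0, 400), 1)}
        table, mean, _ = co.summarize(placements, None, sizes)
        assert np.isnan(table.iloc[1]["density_kb_per_hit"])
        assert mean == pytest.approx(10_000.0)

    def test_unknown_chromosome_raises(self):
        sizes = pd.DataFrame({"name": ["chr1"], "length": [10_000_000]})
        placements = {"c0": co.ContigPlacement("c0", "unique", "chr9", "+",
                                               (0, 400), (0, 400), 1)}
        with pytest.raises(KeyError):
            co.summarize(placements, None, sizes)


class TestHotspots:
    def make_snps(self, positions, chrom="chr28", contig="c1"):
        return pd.DataFrame(
            {
                "contig_id": contig, "pos": range(len(positions)),
                "status": "projected", "chrom": chrom,
                "chrom_start": positions,
                "chrom_end": [p + 1 for p in positions],
            }
        )

    def test_dense_cluster_found(self):
        rng = np.random.default_rng(1)
        snps = self.make_snps(sorted(rng.integers(11_350_000, 11_390_000, 424)))
        hot = co.find_snp_hotspots(snps, window=50_000, min_snps=100)
        assert len(hot) == 1
        assert hot.iloc[0]["n_snps"] == 424

    def test_uniform_background_has_no_hotspots(self):
        snps = self.make_snps(list(range(0, 40_000_000, 1_000_000)))
        hot = co.find_snp_hotspots(snps, window=1_000_000, min_snps=100)
        assert hot.empty

    def test_separated_clusters_stay_distinct(self):
        a = list(range(1_000_000, 1_004_000, 20))
        b = list(range(9_000_000, 9_004_000, 20))
        hot = co.find_snp_hotspots(self.make_snps(a + b), window=50_000,
                                   min_snps=100)
        assert len(hot) == 2
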