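"""NQS filtering, pileup calling, flags, stratification and VCF round-trip."""

import numpy as np
import pytest

from rrlsnp import snp_caller as sc
from rrlsnp import synthetic_data as sd

CFG = sc.CallerConfig()


def make_read(bases, quals=None, start=0, contig="c", read_length=None,
              aligned=None, matches=None, insertions=()):
    quals = quals if quals is not None else [30] * len(bases)
    n_aligned = aligned if aligned is not None else sum(b != "-" for b in bases)
    return sc.AlignedRead(
        read_id="r", contig_id=contig, start=start, bases=bases, quals=quals,
        read_length=read_length or n_aligned,
        aligned_length=n_aligned,
        matches=matches if matches is not None else n_aligned,
        insertions=frozenset(insertions),
    )


class TestFilterAlignment:
    @pytest.mark.parametrize(
        "read_length,aligned,matches,accept",
        [
            (200, 200, 180, True),  # identity exactly 0.90: boundary inclusive
            (200, 179, 179, False),  # aligned fraction 0.895
            (236, 236, 236, True),  # perfect read
            (200, 180, 161, False),  # identity 0.894
        ],
    )
    def test_thresholds(self, read_length, aligned, matches, accept):
        read = make_read("A" * aligned, read_length=read_length,
                         aligned=aligned, matches=matches)
        assert sc.filter_alignment(read, CFG) is accept

    def test_zero_length_read_rejected(self):
        read = make_read("A", read_length=0, aligned=0, matches=0)
        read.read_length = 0
        assert sc.filter_alignment(read, CFG) is False


class TestNQS:
    def test_clean_window_passes(self):
        read = make_read("A" * 21, [20] * 21)
        assert sc.nqs_pass(read, "A" * 21, 10, CFG)

    def test_central_quality_threshold(self):
        quals = [40] * 21
        quals[10] = 19
        read = make_read("A" * 21, quals)
        assert not sc.nqs_pass(read, "A" * 21, 10, CFG)

    def test_window_mean_quality(self):
        # window [10,10,10,10,10,20,10,10,10,10,10]: mean 10.9 < 15
        quals = [10] * 11
        quals[5] = 20
        read = make_read("A" * 11, quals)
        assert not sc.nqs_pass(read, "A" * 11, 5, CFG)

    def test_window_discrepancy_budget_excludes_central(self):
        ref = "A" * 11
        read2 = make_read("AACCAAAAAAA", [30] * 11)  # 2 flanking mismatches: ok
        assert sc.nqs_pass(read2, ref, 5, CFG)
        read3 = make_read("AACCAAAACAA", [30] * 11)  # 3 flanking mismatches
        assert not sc.nqs_pass(read3, ref, 5, CFG)
        readc = make_read("AACCAGAAAAA", [30] * 11)  # central mismatch not counted
        assert sc.nqs_pass(readc, ref, 5, CFG)

    def test_gap_run_counts_once(self):
        ref = "A" * 15
        read = make_read("AAA---AAAAAAAAA", [30, 30, 30, -1, -1, -1] + [30] * 9)
        assert sc.nqs_pass(read, ref, 8, CFG)  # one gap run within window

    def test_mask_agrees_with_scalar_on_noisy_reads(self, pool_truth,
                                                    pool_fragments, tmp_path):
        model = sd.ReadModel(substitution_rate=0.02, homopolymer_indel_rate=0.002,
                             seed=31)
        reads = sd.simulate_reads(pool_truth, pool_fragments, model, 2)
        sam = tmp_path / "noisy.sam"
        sd.write_sam(reads, pool_truth.references, str(sam))
        chrom, ref = next(iter(pool_truth.references.items()))
        aligned = sc.read_sam(str(sam), {chrom: ref})
        rng = np.random.default_rng(0)
        for i in rng.choice(len(aligned), 40, replace=False):
            read = aligned[i]
            mask = sc.nqs_mask(read, ref, CFG)
            for off in range(len(read.bases)):
                assert bool(mask[off]) == sc.nqs_pass(read, ref, read.start + off, CFG)


class TestPileupAndCalling:
    def test_filtered_depth_counts_only_nqs_passing(self):
        ref = "A" * 30
        good = [make_read("A" * 30) for _ in range(3)]
        cols = sc.build_pileup(good, "c", ref, CFG)
        assert all(c.filtered_depth == 3 and c.raw_depth == 3 for c in cols)
        bad = make_read("A" * 30, [30] * 15 + [10] + [30] * 14)  # fails NQS at 15
        cols = sc.build_pileup(good + [bad], "c", ref, CFG)
        col15 = next(c for c in cols if c.pos == 15)
        assert col15.raw_depth == 4 and col15.filtered_depth == 3

    @pytest.mark.parametrize(
        "counts,expect_call,expect_maf",
        [
            ({"A": 2, "G": 1}, True, 1 / 3),  # 33% >= 10%
            ({"A": 97, "G": 2}, False, None),  # 2% < 10% and count 2 < 3
            ({"A": 100, "G": 3}, True, 3 / 103),  # count rule despite 2.9%
        ],
    )
    def test_support_rule_examples(self, counts, expect_call, expect_maf):
        col = sc.PileupColumn("c", 5, {b: (n, []) for b, n in counts.items()},
                              sum(counts.values()))
        calls = sc.call_snps([col], CFG)
        assert bool(calls) is expect_call
        if expect_call:
            assert calls[0].maf == pytest.approx(expect_maf)
            assert calls[0].allele_cardinality == 2

    def test_coverage_bounds(self):
        low = sc.PileupColumn("c", 1, {"A": (1, []), "G": (1, [])}, 2)
        high = sc.PileupColumn("c", 2, {"A": (800, []), "G": (300, [])}, 1100)
        assert sc.call_snps([low, high], CFG) == []

    def test_min_coverage_monotonicity(self, pool_truth, errorfree_reads, tmp_path):
        sam = tmp_path / "t.sam"
        sd.write_sam(errorfree_reads, pool_truth.references, str(sam))
        chrom, ref = next(iter(pool_truth.references.items()))
        aligned = sc.read_sam(str(sam), {chrom: ref})
        previous = None
        for min_cov in (3, 5, 8, 12):
            cfg = sc.CallerConfig(min_coverage=min_cov)
            calls = sc.call_snps(sc.build_pileup(aligned, chrom, ref, cfg), cfg)
            if previous is not None:
                assert len(calls) <= previous
            previous = len(calls)


class TestFlags:
    def test_homopolymer_adjacent_run_flagged(self):
        assert sc.flag_homopolymer_proximity("AAAACGT", 5)
        assert not sc.flag_homopolymer_proximity("ACACACACACACACACAC", 9)

    def test_distant_run_not_flagged(self):
        seq = "AAAA" + "ACGT" * 5 + "C" + "ACGT" * 5
        assert not sc.flag_homopolymer_proximity(seq, 24)

    @pytest.mark.parametrize(
        "positions,window,expected",
        [
            ((100, 105), 11, [True, True]),
            ((100, 112), 11, [False, False]),
            ((100,), 11, [False]),
        ],
    )
    def test_clustered_flags(self, positions, window, expected):
        calls = [
            sc.SNPCall("c", p, "A", ["G"], {"A": 3, "G": 3}, 6, 3, 0.5, 2)
            for p in positions
        ]
        sc.flag_clustered(calls, cluster_window=window)
        assert [c.clustered for c in calls] == expected


class TestStratify:
    def test_strata_totals_and_overcap(self):
        calls = [
            sc.SNPCall("c", i, "A", ["G"], {}, cov, mac, mac / cov, 2)
            for i, (cov, mac) in enumerate(
                [(3, 1), (3, 1), (4, 2), (5, 2), (6, 1), (9, 1), (151, 1)]
            )
        ]
        table = sc.stratify(calls, coverage_cap=150)
        by = {(r["coverage"], r["minor_allele_count"]): r["n_calls"]
              for _, r in table.iterrows()}
        assert by[(3, 1)] == 2 and by[(4, 2)] == 1 and by[(5, 2)] == 1
        assert by[("other", "")] == 1  # 9X/1 is in-cap but outside the six classes
        assert by[("over_cap", "")] == 1
        assert table["n_calls"].sum() == len(calls)


@pytest.fixture(scope="module")
def accepted_and_called(pool_truth, errorfree_reads, tmp_path_factory):
    sam = tmp_path_factory.mktemp("sam") / "reads.sam"
    sd.write_sam(errorfree_reads, pool_truth.references, str(sam))
    chrom, ref = next(iter(pool_truth.references.items()))
    aligned = sc.read_sam(str(sam), {chrom: ref})
    accepted = [r for r in aligned if sc.filter_alignment(r, CFG)]
    pile = sc.build_pileup(accepted, chrom, ref, CFG)
    return accepted, sc.call_snps(pile, CFG)


@pytest.fixture(scope="module")
def called(accepted_and_called):
    return accepted_and_called[1]


class TestOnSyntheticPool:
    def test_perfect_recall_and_precision_errorfree(self, pool_truth,
                                                    accepted_and_called):
        accepted, calls = accepted_and_called
        chrom, ref = next(iter(pool_truth.references.items()))
        planted = {v.pos for v in pool_truth.variants}
        called_pos = {c.pos for c in calls}
        assert called_pos <= planted  # precision 1: no unplanted position called
        # independent scalar recount of NQS-passing depth and alt support
        by_pos = {v.pos: v for v in pool_truth.variants}
        depth = {p: 0 for p in planted}
        alt = {p: 0 for p in planted}
        for read in accepted:
            for pos in range(read.start, read.end):
                v = by_pos.get(pos)
                if v is None or read.bases[pos - read.start] == "-":
                    continue
                if sc.nqs_pass(read, ref, pos, CFG):
                    depth[pos] += 1
                    if read.bases[pos - read.start] == v.alt:
                        alt[pos] += 1
        expected = {
            p for p in planted
            if depth[p] >= 3 and 0 < alt[p] < depth[p]
            and (alt[p] >= 3 or alt[p] / depth[p] >= 0.10)
        }
        assert expected <= called_pos  # recall 1 where the support rule is met

    def test_maf_estimates_track_pool_frequencies(self, pool_truth, called):
        truth_by_pos = {v.pos: v for v in pool_truth.variants}
        errors, ses = [], []
        for c in called:
            v = truth_by_pos[c.pos]
            est_alt = c.counts.get(v.alt, 0) / c.coverage
            errors.append(abs(est_alt - v.frequency))
            ses.append(np.sqrt(v.frequency * (1 - v.frequency) / c.coverage))
        assert len(errors) > 40
        assert np.mean(errors) <= 2 * np.mean(ses)

    def test_vcf_round_trip(self, pool_truth, called, tmp_path):
        chrom, ref = next(iter(pool_truth.references.items()))
        for c in called:
            c.homopolymer_proximal = sc.flag_homopolymer_proximity(ref, c.pos)
        sc.flag_clustered(called)
        path = tmp_path / "calls.vcf"
        sc.write_vcf(called, {chrom: ref}, str(path))
        back = sc.read_vcf(str(path))
        assert len(back) == len(called)
        for a, b in zip(sorted(called, key=lambda c: c.pos), back):
            assert (a.contig_id, a.pos, a.ref_allele, a.alt_alleles) == (
                b.contig_id, b.pos, b.ref_allele, b.alt_alleles
            )
            assert a.coverage == b.coverage
            assert a.minor_allele_count == b.minor_allele_count
            assert a.maf == pytest.approx(b.maf)
            assert a.homopolymer_proximal == b.homopolymer_proximal
            assert a.clustered == b.clustered
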