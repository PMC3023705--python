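"""Pooled SNP calling under the Neighborhood Quality Standard (NQS).

A base may support a variant only if it is itself confidently called
(central Phred >= 20) and sits in a clean neighborhood: an 11-bp window whose
mean quality is >= 15 and which contains at most 2 gap/mismatch discrepancies
versus the contig consensus (the candidate base itself excluded).  Columns of
NQS-passing bases are then screened with a minimum depth of 3, a maximum of
1000, and an allele-support rule of >= 10% frequency OR >= 3 reads.

Alignment-level gating mirrors strict reference-assembly read matching:
aligned fraction >= 0.90 of read length and identity >= 0.90 of the aligned
length.  MAF is estimated from pooled read counts (minor count / filtered
depth); no per-individual genotypes exist at the pool level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "CallerConfig",
    "AlignedRead",
    "PileupColumn",
    "SNPCall",
    "read_sam",
    "filter_alignment",
    "nqs_pass",
    "build_pileup",
    "call_snps",
    "flag_homopolymer_proximity",
    "flag_clustered",
    "stratify",
    "write_vcf",
    "read_vcf",
    "TABLE_CLASSES",
]

_BASE_ORDER = {"A": 0, "C": 1, "G": 2, "T": 3}

# (coverage, minor allele count) strata used for validation bookkeeping
TABLE_CLASSES = [(3, 1), (4, 1), (4, 2), (5, 1), (5, 2), (6, 1)]


@dataclass(frozen=True)
class CallerConfig:
    min_central_quality: int = 20
    min_average_quality: float = 15.0
    window: int = 11
    max_gap_mismatch_in_window: int = 2
    min_coverage: int = 3
    max_coverage: int = 1000
    min_variant_frequency: float = 0.10
    min_variant_count: int = 3
    min_read_length_fraction: float = 0.90
    min_identity: float = 0.90
    nqs_enabled: bool = True  # False = ablation: every aligned base counts

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if min(self.min_central_quality, self.min_coverage) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class AlignedRead:
    """A read projected onto contig coordinates.

    ``bases``/``quals`` run over contig positions [start, start+len(bases));
    a deletion in the read is '-' with quality -1.  ``insertions`` holds the
    contig offsets (relative to ``start``) that are followed by an inserted
    run in the read.
    """

    read_id: str
    contig_id: str
    start: int
    bases: str
    quals: list
    read_length: int
    aligned_length: int  # query bases aligned (M columns)
    matches: int  # aligned bases equal to the contig consensus
    insertions: frozenset = frozenset()

    @property
    def end(self) -> int:
        return self.start + len(self.bases)

    def covers(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_sam(path: str, contigs: dict) -> list:
    """Load alignments from SAM into contig-space AlignedReads.

    ``contigs`` maps contig id -> consensus sequence.  Unmapped reads are
    skipped.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.reference_name not in contigs:
                continue
            reads.append(_from_segment(seg, contigs[seg.reference_name]))
    return reads


def _from_segment(seg: "pysam.AlignedSegment", contig_seq: str) -> AlignedRead:
    qseq = seg.query_sequence
    qual = seg.query_qualities
    start = seg.reference_start
    bases: list[str] = []
    quals: list[int] = []
    insertions: set[int] = set()
    matches = 0
    aligned = 0
    qpos = 0
    rpos = start
    for op, n in seg.cigartuples:
        if op == 0 or op == 7 or op == 8:  # M/=/X
            for k in range(n):
                b = qseq[qpos + k].upper()
                bases.append(b)
                quals.append(int(qual[qpos + k]) if qual is not None else 30)
                if b == contig_seq[rpos + k].upper():
                    matches += 1
            aligned += n
            qpos += n
            rpos += n
        elif op == 1:  # insertion in read
            insertions.add(rpos - start)
            qpos += n
        elif op == 2 or op == 3:  # deletion / skip
            bases.extend("-" * n)
            quals.extend([-1] * n)
            rpos += n
        elif op == 4:  # soft clip
            qpos += n
        # hard clips / pads consume nothing tracked here
    return AlignedRead(
        read_id=seg.query_name,
        contig_id=seg.reference_name,
        start=start,
        bases="".join(bases),
        quals=quals,
        read_length=seg.query_length or len(qseq),
        aligned_length=aligned,
        matches=matches,
        insertions=frozenset(insertions),
    )


def filter_alignment(read: AlignedRead, cfg: CallerConfig) -> bool:
    """Strict read-matching gate: aligned fraction and identity both >= 0.90."""
    if read.read_length == 0:
        return False
    if read.aligned_length / read.read_length < cfg.min_read_length_fraction:
        return False
    return read.matches / read.aligned_length >= cfg.min_identity


def nqs_pass(
    read: AlignedRead, contig_seq: str, contig_position: int, cfg: CallerConfig
) -> bool:
    """Neighborhood Quality Standard at one contig position of one read.

    The window is centered on the position and truncated at read ends; the
    mean is taken over available read bases.  Discrepancies are mismatches vs
    the contig consensus plus gap events (a deletion run or insertion counts
    once), with the central base excluded from the discrepancy count.
    """
    if not read.covers(contig_position):
        raise ValueError("position not covered by read")
    off = contig_position - read.start
    if read.bases[off] == "-":
        return False
    if not cfg.nqs_enabled:  # ablation: every aligned base counts
        return True
    if read.quals[off] < cfg.min_central_quality:
        return False
    half = cfg.window // 2
    lo = max(0, off - half)
    hi = min(len(read.bases), off + half + 1)
    window_quals = [q for q in read.quals[lo:hi] if q >= 0]
    if np.mean(window_quals) < cfg.min_average_quality:
        return False
    disc = 0
    in_gap = False
    for k in range(lo, hi):
        b = read.bases[k]
        if b == "-":
            if not in_gap:
                disc += 1
                in_gap = True
            continue
        in_gap = False
        if k != off and b != contig_seq[read.start + k].upper():
            disc += 1
    disc += sum(1 for i in read.insertions if lo <= i < hi)
    return disc <= cfg.max_gap_mismatch_in_window


def _window_sum(x: np.ndarray, half: int) -> np.ndarray:
    """Sliding sum over [i-half, i+half] truncated at the array ends."""
    c = np.concatenate(([0], np.cumsum(x)))
    n = len(x)
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    return c[hi] - c[lo]


def nqs_mask(read: AlignedRead, contig_seq: str, cfg: CallerConfig) -> np.ndarray:
    """Vectorized NQS verdict for every contig position a read spans.

    Semantically identical to calling :func:`nqs_pass` position by position
    (asserted by the test suite); used by :func:`build_pileup` for speed.
    """
    b = np.frombuffer(read.bases.encode(), dtype=np.uint8)
    q = np.asarray(read.quals, dtype=np.int32)
    n = len(b)
    is_del = b == ord("-")
    if not cfg.nqs_enabled:  # ablation: every aligned base counts
        return ~is_del
    ok = ~is_del & (q >= cfg.min_central_quality)
    half = cfg.window // 2
    ref = np.frombuffer(
        contig_seq[read.start : read.end].upper().encode(), dtype=np.uint8
    )
    # mean window quality over read bases present (deletions excluded)
    qv = np.where(is_del, 0, q)
    cnt = _window_sum((~is_del).astype(np.int64), half)
    qsum = _window_sum(qv.astype(np.int64), half)
    with np.errstate(invalid="ignore"):
        ok &= np.where(cnt > 0, qsum >= cfg.min_average_quality * cnt, False)
    # discrepancies: mismatches (central excluded), deletion runs counted once
    # per run in-window, insertion events
    mism = (~is_del) & (b != ref)
    disc = _window_sum(mism.astype(np.int64), half) - mism.astype(np.int64)
    run_start = is_del & np.concatenate(([True], ~is_del[:-1]))
    disc += _window_sum(run_start.astype(np.int64), half)
    # a deletion run entering the window from the left counts once: window
    # start i-half > 0 lands mid-run when both (i-half) and (i-half-1) are dels
    spill = np.zeros(n, dtype=np.int64)
    if n > half + 1:
        idx = np.arange(half + 1, n)
        spill[idx] = (is_del[idx - half] & is_del[idx - half - 1]).astype(np.int64)
    disc += spill
    if read.insertions:
        ins = np.zeros(n, dtype=np.int64)
        for i in read.insertions:
            if 0 <= i < n:
                ins[i] = 1
        disc += _window_sum(ins, half)
    ok &= disc <= cfg.max_gap_mismatch_in_window
    return ok


@dataclass
class PileupColumn:
    contig_id: str
    pos: int
    alleles: dict  # base -> (count, list of quals) over NQS-passing bases
    raw_depth: int

    @property
    def filtered_depth(self) -> int:
        return sum(c for c, _ in self.alleles.values())


_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_ORDER.items():
    _CODE[ord(_b)] = _i


def build_pileup(
    reads: Sequence[AlignedRead],
    contig_id: str,
    contig_seq: str,
    cfg: CallerConfig,
    collect_quals: bool = False,
) -> list:
    """Per-position allele tallies over NQS-passing bases of accepted reads.

    Raw depth counts every aligned base of the accepted reads; allele tallies
    keep only NQS-passing bases.  Per-allele quality lists are gathered only
    when ``collect_quals`` is set (they are not needed for calling).
    """
    L = len(contig_seq)
    counts = np.zeros((4, L), dtype=np.int64)
    raw = np.zeros(L, dtype=np.int64)
    quals: dict | None = {} if collect_quals else None
    for read in reads:
        if read.contig_id != contig_id:
            continue
        if read.end > L:
            raise ValueError("alignment extends beyond contig")
        b = np.frombuffer(read.bases.encode(), dtype=np.uint8)
        codes = _CODE[b]
        present = codes >= 0
        pos = read.start + np.nonzero(present)[0]
        np.add.at(raw, pos, 1)
        passing = nqs_mask(read, contig_seq, cfg) & present
        ppos = read.start + np.nonzero(passing)[0]
        np.add.at(counts, (codes[passing], ppos), 1)
        if collect_quals:
            for p in np.nonzero(passing)[0]:
                key = (read.start + int(p), read.bases[p])
                quals.setdefault(key, []).append(read.quals[p])
    columns = []
    for p in np.nonzero(raw > 0)[0]:
        alleles = {}
        for base, i in _BASE_ORDER.items():
            c = int(counts[i, p])
            if c:
                qlist = quals.get((int(p), base), []) if collect_quals else []
                alleles[base] = (c, qlist)
        columns.append(PileupColumn(contig_id, int(p), alleles, int(raw[p])))
    return columns


@dataclass
class SNPCall:
    contig_id: str
    pos: int  # 0-based
    ref_allele: str
    alt_alleles: list
    counts: dict  # allele -> NQS-passing count
    coverage: int  # filtered depth
    minor_allele_count: int
    maf: float
    allele_cardinality: int
    homopolymer_proximal: bool = False
    clustered: bool = False


def call_snps(pileup: Sequence[PileupColumn], cfg: CallerConfig) -> list:
    """Screen pileup columns for variants under the depth and support rules.

    The consensus allele is the majority allele of the filtered column (ties
    broken A<C<G<T); a non-consensus allele qualifies when its frequency is
    >= ``min_variant_frequency`` or its count >= ``min_variant_count``.
    """
    calls: list[SNPCall] = []
    for col in pileup:
        depth = col.filtered_depth
        if not cfg.min_coverage <= depth <= cfg.max_coverage:
            continue
        counts = {b: c for b, (c, _) in col.alleles.items()}
        consensus = max(counts, key=lambda b: (counts[b], -_BASE_ORDER[b]))
        alts = [
            b
            for b in sorted(counts, key=_BASE_ORDER.get)
            if b != consensus
            and (counts[b] / depth >= cfg.min_variant_frequency
                 or counts[b] >= cfg.min_variant_count)
        ]
        if not alts:
            continue
        ranked = sorted(counts.values(), reverse=True)
        minor = ranked[1]
        calls.append(
            SNPCall(
                contig_id=col.contig_id,
                pos=col.pos,
                ref_allele=consensus,
                alt_alleles=alts,
                counts=counts,
                coverage=depth,
                minor_allele_count=minor,
                maf=minor / depth,
                allele_cardinality=1 + len(alts),
            )
        )
    return calls


def flag_homopolymer_proximity(
    contig_seq: str, pos: int, min_run: int = 4, proximity: int = 5
) -> bool:
    """True when a homopolymer run (>= min_run) lies within +/- proximity bp.

    Such contexts inflate pyrosequencing error and are excluded from
    validation candidates.
    """
    if not 0 <= pos < len(contig_seq):
        raise ValueError("position outside contig")
    lo, hi = pos - proximity, pos + proximity
    i = 0
    n = len(contig_seq)
    while i < n:
        j = i
        while j < n and contig_seq[j] == contig_seq[i]:
            j += 1
        if j - i >= min_run and i <= hi and j - 1 >= lo:
            return True
        i = j
    return False


def flag_clustered(calls: Sequence[SNPCall], cluster_window: int = 11) -> None:
    """Mark calls with another call within ``cluster_window`` bp on the contig."""
    by_contig: dict[str, list[SNPCall]] = {}
    for c in calls:
        by_contig.setdefault(c.contig_id, []).append(c)
    for group in by_contig.values():
        group.sort(key=lambda c: c.pos)
        for i, c in enumerate(group):
            near = (
                (i > 0 and c.pos - group[i - 1].pos <= cluster_window)
                or (i + 1 < len(group) and group[i + 1].pos - c.pos <= cluster_window)
            )
            c.clustered = near


def stratify(calls: Sequence[SNPCall], coverage_cap: int = 150) -> pd.DataFrame:
    """Tally calls into (coverage, minor allele count) validation strata.

    Rows follow the canonical low-coverage classes (3X/1 ... 6X/1) plus an
    ``other`` bucket for in-cap calls outside them and an ``over_cap`` bucket
    for coverage above the cap.
    """
    tallies = {cls: 0 for cls in TABLE_CLASSES}
    other = over = 0
    for c in calls:
        if c.coverage > coverage_cap:
            over += 1
        elif (c.coverage, c.minor_allele_count) in tallies:
            tallies[(c.coverage, c.minor_allele_count)] += 1
        else:
            other += 1
    rows = [
        {"coverage": cov, "minor_allele_count": mac, "n_calls": n}
        for (cov, mac), n in tallies.items()
    ]
    rows.append({"coverage": "other", "minor_allele_count": "", "n_calls": other})
    rows.append({"coverage": "over_cap", "minor_allele_count": "", "n_calls": over})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(calls: Sequence[SNPCall], contigs: dict, path: str) -> None:
    """Write calls as VCF (1-based positions; flags in FILTER, stats in INFO)."""
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="NQS-filtered depth">')
    header.add_line('##INFO=<ID=AC,Number=.,Type=Integer,Description="Per-allele read counts, ref first">')
    header.add_line('##INFO=<ID=MAF,Number=1,Type=Float,Description="Pooled minor allele frequency">')
    header.add_line('##FILTER=<ID=HOMOPOLYMER,Description="Within or near a homopolymer run">')
    header.add_line('##FILTER=<ID=CLUSTERED,Description="Another putative SNP within the analysis window">')
    for name, seq in contigs.items():
        header.add_line(f"##contig=<ID={name},length={len(seq)}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.contig_id, c.pos)):
            rec = out.new_record(
                contig=c.contig_id,
                start=c.pos,
                stop=c.pos + 1,
                alleles=[c.ref_allele, *c.alt_alleles],
            )
            rec.info["DP"] = c.coverage
            rec.info["AC"] = [c.counts[a] for a in (c.ref_allele, *c.alt_alleles)]
            rec.info["MAF"] = round(c.maf, 6)
            if c.homopolymer_proximal:
                rec.filter.add("HOMOPOLYMER")
            if c.clustered:
                rec.filter.add("CLUSTERED")
            if not c.homopolymer_proximal and not c.clustered:
                rec.filter.add("PASS")
            out.write(rec)


def read_vcf(path: str) -> list:
    calls: list[SNPCall] = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            alleles = list(rec.alleles)
            ac = list(rec.info["AC"])
            counts = dict(zip(alleles, ac))
            depth = int(rec.info["DP"])
            ranked = sorted(counts.values(), reverse=True)
            filters = set(rec.filter.keys())
            calls.append(
                SNPCall(
                    contig_id=rec.contig,
                    pos=rec.start,
                    ref_allele=alleles[0],
                    alt_alleles=alleles[1:],
                    counts=counts,
                    coverage=depth,
                    minor_allele_count=ranked[1],
                    maf=ranked[1] / depth,
                    allele_cardinality=len(alleles),
                    homopolymer_proximal="HOMOPOLYMER" in filters,
                    clustered="CLUSTERED" in filters,
                )
            )
    return calls
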