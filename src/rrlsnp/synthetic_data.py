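"""Synthetic pooled-population sequencing data with known truth.

Emulates the study design that motivates the pipeline: equimolar pooled DNA
from a small panel of diploid individuals (default 16), digested into
size-selected restriction fragments and pyrosequenced with long single-end
reads (~236 bp mean) carrying substitution and homopolymer-indel errors.
Every output (FASTA reference, haplotypes, FASTQ reads, truth SAM, BLAST
outfmt-6 hit tables) comes with machine-readable truth so each downstream
stage can be validated in isolation.

All coordinates are 0-based half-open internally; SAM/BLAST conventions are
applied only when writing those formats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .rrl_digest import Fragment

__all__ = [
    "PopulationModel",
    "random_genome",
    "Variant",
    "TruthSet",
    "ReadModel",
    "SimulatedRead",
    "simulate_population",
    "simulate_reads",
    "write_fastq",
    "write_sam",
    "write_fasta",
    "HitSpec",
    "ContigHitPlan",
    "simulate_surrogate_hits",
    "random_hit_plans",
]

_BASES = np.array(list("ACGT"))
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(
    rng: np.random.Generator, length: int, gc_content: float = 0.5
) -> str:
    """I.i.d. random nucleotide sequence at the given GC content."""
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    return bytes(rng.choice(_BASE_BYTES, size=length, p=probs)).decode()


@dataclass(frozen=True)
class PopulationModel:
    """Pooled-population model: panel size, ploidy and planted-SNP regime.

    ``maf_distribution`` is a named tuple-style spec: ``("uniform", lo, hi)``
    or ``("point", p)``; sampled minor allele frequencies must fall in
    (0, 0.5].  The default uniform(0.05, 0.5) has mean 0.275, close to the
    pool-level averages observed in reduced-representation deer data
    (0.282 nuclear RRL, 0.274 pooled).
    """

    n_individuals: int = 16
    ploidy: int = 2
    snp_density: float = 1.0  # variants per kb
    maf_distribution: tuple = ("uniform", 0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.snp_density < 0:
            raise ValueError("snp_density must be >= 0")

    @property
    def n_haplotypes(self) -> int:
        return self.n_individuals * self.ploidy

    def sample_maf(self, rng: np.random.Generator) -> float:
        kind = self.maf_distribution[0]
        if kind == "uniform":
            lo, hi = self.maf_distribution[1:3]
            if not 0 < lo <= hi <= 0.5:
                raise ValueError("uniform MAF bounds must satisfy 0 < lo <= hi <= 0.5")
            return float(rng.uniform(lo, hi))
        if kind == "point":
            p = float(self.maf_distribution[1])
            if not 0 < p <= 0.5:
                raise ValueError("point MAF must be in (0, 0.5]")
            return p
        raise ValueError(f"unknown MAF distribution {kind!r}")


@dataclass(frozen=True)
class Variant:
    """A planted diallelic variant with its realized pool frequency."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    frequency: float  # realized alt-allele frequency in the pool
    carriers: frozenset  # haplotype indices carrying the alt allele


@dataclass
class TruthSet:
    """Reference sequence(s) plus the planted variants defining all haplotypes."""

    references: dict  # chrom -> sequence string
    variants: list  # list[Variant]
    n_haplotypes: int

    def __post_init__(self) -> None:
        seen = set()
        for v in self.variants:
            if v.chrom not in self.references:
                raise ValueError(f"variant on unknown sequence {v.chrom}")
            ref = self.references[v.chrom]
            if not 0 <= v.pos < len(ref):
                raise ValueError("variant position outside its sequence")
            if ref[v.pos] != v.ref:
                raise ValueError("ref allele does not match reference base")
            if (v.chrom, v.pos) in seen:
                raise ValueError("two variants share a position")
            seen.add((v.chrom, v.pos))

    def variants_on(self, chrom: str) -> list:
        return [v for v in self.variants if v.chrom == chrom]

    def _index(self, chrom: str):
        # sorted position index per chromosome, built lazily
        cache = getattr(self, "_idx_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_idx_cache", cache)
        if chrom not in cache:
            vs = sorted(self.variants_on(chrom), key=lambda v: v.pos)
            cache[chrom] = (np.array([v.pos for v in vs], dtype=np.int64), vs)
        return cache[chrom]

    def haplotype_base(self, hap: int, chrom: str, pos: int) -> str:
        for v in self.variants:
            if v.chrom == chrom and v.pos == pos:
                return v.alt if hap in v.carriers else v.ref
        return self.references[chrom][pos]

    def haplotype_slice(self, hap: int, chrom: str, start: int, end: int) -> str:
        """Sequence of haplotype ``hap`` over [start, end) of ``chrom``."""
        positions, vs = self._index(chrom)
        lo = int(np.searchsorted(positions, start, side="left"))
        hi = int(np.searchsorted(positions, end, side="left"))
        if lo == hi:
            return self.references[chrom][start:end]
        seq = list(self.references[chrom][start:end])
        for v in vs[lo:hi]:
            if hap in v.carriers:
                seq[v.pos - start] = v.alt
        return "".join(seq)


def simulate_population(
    model: PopulationModel, genome_length: int, gc_content: float = 0.42
) -> TruthSet:
    """Random reference plus planted diallelic SNPs at the model's density.

    Per variant the pool allele count is drawn binomial(H, MAF) over the
    H = ploidy x n_individuals haplotypes; count-zero draws are discarded
    (the allele is absent from the pool, hence undiscoverable).  The stored
    truth frequency is the realized count / H.
    """
    if genome_length < 1000:
        raise ValueError("genome_length must be >= 1 kb")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    rng = np.random.default_rng(model.seed)
    ref = random_genome(rng, genome_length, gc_content)
    chrom = "ref1"

    n_target = int(round(model.snp_density * genome_length / 1000.0))
    n_target = min(n_target, genome_length)
    variants: list[Variant] = []
    if n_target > 0:
        positions = np.sort(rng.choice(genome_length, size=n_target, replace=False))
        H = model.n_haplotypes
        for pos in positions:
            ref_base = ref[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            maf = model.sample_maf(rng)
            count = int(rng.binomial(H, maf))
            if count == 0:
                continue
            carriers = frozenset(int(i) for i in rng.choice(H, size=count, replace=False))
            variants.append(
                Variant(chrom, int(pos), ref_base, alt, count / H, carriers)
            )
    return TruthSet({chrom: ref}, variants, model.n_haplotypes)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass(frozen=True)
class ReadModel:
    """Long-single-end read model with 454-style error structure.

    Substitution errors are i.i.d. per base; homopolymer indels occur per
    run of length L >= 3 with probability ``homopolymer_indel_rate * (L - 2)``
    capped at 0.5 (one inserted or deleted base, equiprobable).  Qualities
    are Phred+33; ``quality_profile`` maps fractional read position in [0,1]
    to a mean Phred score.
    """

    mean_read_length: int = 236
    length_sd: float = 40.0
    substitution_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    quality_profile: Callable[[float], float] | None = None
    quality_sd: float = 3.0
    min_read_length: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_read_length <= 0:
            raise ValueError("mean_read_length must be positive")
        for r in (self.substitution_rate, self.homopolymer_indel_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def mean_quality(self, frac: float) -> float:
        if self.quality_profile is not None:
            return self.quality_profile(frac)
        return 33.0 - 8.0 * frac  # mild 5'->3' decay typical of pyrosequencing


@dataclass
class SimulatedRead:
    """One read plus its truth alignment against the un-mutated reference."""

    name: str
    sequence: str
    qualities: list  # list[int], Phred
    chrom: str
    ref_start: int  # 0-based on the reference sequence
    cigar: list  # list[(op, length)] with op in {"M", "I", "D"}
    haplotype: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in "MD")


def _homopolymer_runs(seq: str, min_len: int = 3) -> list:
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j))
        i = j
    return runs


def _apply_errors(
    seq: str, model: ReadModel, rng: np.random.Generator
) -> tuple[str, list, set]:
    """Mutate a haplotype-derived read.

    Returns ``(sequence, cigar vs source, error positions)``; error positions
    (in final read coordinates, approximate across indels) receive degraded
    base qualities, mirroring the quality/miscall correlation of real base
    calling.
    """
    ops: list[tuple[str, int]] = [("M", len(seq))]
    out = list(seq)
    err_pos: set[int] = set()
    # homopolymer indels first (runs detected on the source sequence), applied
    # right-to-left so earlier coordinates stay valid
    if model.homopolymer_indel_rate > 0:
        for start, end in reversed(_homopolymer_runs(seq)):
            L = end - start
            p = min(model.homopolymer_indel_rate * (L - 2), 0.5)
            if rng.random() >= p:
                continue
            if rng.random() < 0.5:  # insertion: lengthen the run by one
                out.insert(start, seq[start])
                ops = _splice_cigar(ops, start, "I")
                err_pos.add(start)
            else:  # deletion
                del out[start]
                ops = _splice_cigar(ops, start, "D")
    # substitutions on the final sequence
    if model.substitution_rate > 0:
        hits = np.nonzero(rng.random(len(out)) < model.substitution_rate)[0]
        for i in hits:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
            err_pos.add(int(i))
    return "".join(out), _merge_ops(ops), err_pos


def _splice_cigar(ops: list, ref_pos: int, kind: str) -> list:
    """Insert a 1-bp I or D event at source coordinate ``ref_pos``."""
    new: list[tuple[str, int]] = []
    consumed = 0
    done = False
    for op, n in ops:
        spans_ref = op in ("M", "D")
        if not done and spans_ref and consumed <= ref_pos < consumed + n:
            left = ref_pos - consumed
            if left:
                new.append((op, left))
            if kind == "I":
                new.append(("I", 1))
                new.append((op, n - left))
            else:  # deletion consumes one source base
                new.append(("D", 1))
                if n - left - 1:
                    new.append((op, n - left - 1))
            done = True
        else:
            new.append((op, n))
        if spans_ref:
            consumed += n
    return new


def _merge_ops(ops: list) -> list:
    merged: list[list] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1][1] += n
        else:
            merged.append([op, n])
    return [(op, n) for op, n in merged]


def simulate_reads(
    truth: TruthSet,
    fragments: Sequence[Fragment],
    model: ReadModel,
    target_depth: float,
) -> list:
    """Sample reads from haplotype copies of ``fragments`` to a target depth.

    Fragments are drawn with probability proportional to their length and the
    haplotype uniformly from the pool (equimolar individuals); reads start
    uniformly within the fragment.  Fragments shorter than the sampled read
    length yield one full-fragment read.  Emission stops once total bases
    reach ``target_depth`` x total fragment length.
    """
    if not fragments:
        raise ValueError("fragments must be non-empty")
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    rng = np.random.default_rng(model.seed)
    lengths = np.array([len(f) for f in fragments], dtype=float)
    cum = np.cumsum(lengths / lengths.sum())
    target_bp = target_depth * lengths.sum()

    reads: list[SimulatedRead] = []
    emitted = 0
    idx = 0
    while emitted < target_bp:
        frag = fragments[int(np.searchsorted(cum, rng.random()))]
        hap = int(rng.integers(truth.n_haplotypes))
        L = int(round(rng.normal(model.mean_read_length, model.length_sd)))
        L = max(L, model.min_read_length)
        if L >= len(frag):
            start_in_frag, L = 0, len(frag)
        else:
            start_in_frag = int(rng.integers(0, len(frag) - L + 1))
        ref_start = frag.start + start_in_frag
        hap_seq = truth.haplotype_slice(hap, frag.source_id, ref_start, ref_start + L)
        seq, cigar, err_pos = _apply_errors(hap_seq, model, rng)
        n = len(seq)
        fracs = np.arange(n) / max(n - 1, 1)
        means = np.array([model.mean_quality(f) for f in fracs]) \
            if model.quality_profile is not None else 33.0 - 8.0 * fracs
        q = np.clip(np.rint(rng.normal(means, model.quality_sd)), 2, 40)
        if err_pos:
            err_idx = [i for i in err_pos if i < n]
            # miscalled bases carry degraded confidence, as in real base calling
            q[err_idx] = np.clip(np.rint(rng.normal(10.0, 3.0, size=len(err_idx))), 2, 25)
        quals = q.astype(int).tolist()
        reads.append(
            SimulatedRead(
                name=f"read{idx:07d}",
                sequence=seq,
                qualities=quals,
                chrom=frag.source_id,
                ref_start=ref_start,
                cigar=cigar,
                haplotype=hap,
            )
        )
        emitted += len(seq)
        idx += 1
    return reads


def write_fasta(references: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: Iterable[SimulatedRead], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.qualities) + "\n")


def write_sam(reads: Sequence[SimulatedRead], references: dict, path: str) -> None:
    """Truth alignments as soft-clip-free SAM against the reference sequences."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in references.items()],
    }
    names = list(references)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.sequence
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.qualities)
            )
            a.reference_id = names.index(r.chrom)
            a.reference_start = r.ref_start
            a.mapping_quality = 60
            a.cigarstring = "".join(f"{n}{op}" for op, n in r.cigar)
            a.flag = 0
            out.write(a)


# ---------------------------------------------------------------------------
# Surrogate-genome BLAST hit simulation


@dataclass(frozen=True)
class HitSpec:
    """One intended alignment of a contig onto a surrogate chromosome."""

    subject: str
    sstart: int  # 1-based inclusive, leftmost subject coordinate
    length: int
    strand: str = "+"
    evalue: float = 1e-80
    identity: float = 92.0


@dataclass
class ContigHitPlan:
    """Planned hit multiplicity for one contig, plus its intended status.

    ``truth_status`` is derived from the plan's design parameters (named
    chromosomes, chrUn partners, position counts, e-value threshold), not
    from the emitted rows, so it is an independent oracle for the overlay
    classifier.
    """

    contig_id: str
    contig_length: int
    hits: list  # list[HitSpec]
    truth_status: str = ""


def _plan_truth_status(
    hits: Sequence[HitSpec], evalue_threshold: float = 1e-50,
    chrun_prefix: str = "chrun",
) -> str:
    live = [h for h in hits if h.evalue <= evalue_threshold]
    if not live:
        return "no_hit"
    named = sorted({h.subject for h in live if not h.subject.lower().startswith(chrun_prefix)})
    unknown = sorted({h.subject for h in live if h.subject.lower().startswith(chrun_prefix)})
    def npos(subj):
        return len([h for h in live if h.subject == subj])
    if len(named) >= 2 or len(unknown) >= 2:
        return "uninformative"
    if len(named) == 1 and not unknown:
        n = npos(named[0])
        if n == 1:
            return "unique"
        return "informative_multi" if n <= 3 else "uninformative"
    if len(named) == 1 and len(unknown) == 1:
        ok = npos(named[0]) <= 3 and npos(unknown[0]) <= 3
        return "informative_multi" if ok else "uninformative"
    # chrUn only: a single discrete unplaced scaffold still anchors the contig
    n = npos(unknown[0])
    return "informative_multi" if n <= 3 else "uninformative"


def simulate_surrogate_hits(
    plans: Sequence[ContigHitPlan],
    chromosome_lengths: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Realize hit plans as BLAST outfmt-6 rows plus a truth-status table.

    ``chromosome_lengths`` needs columns ``name`` and ``length``.  Plans whose
    intended hits are pairwise non-overlapping on the subject guarantee the
    planned multiplicity equals the merged-position count.  Raises if any
    alignment would extend past its chromosome end.
    """
    sizes = dict(zip(chromosome_lengths["name"], chromosome_lengths["length"]))
    rows = []
    truth_rows = []
    for plan in plans:
        status = plan.truth_status or _plan_truth_status(plan.hits)
        truth_rows.append({"contig_id": plan.contig_id, "status": status})
        for h in plan.hits:
            if h.subject not in sizes:
                raise ValueError(f"unknown chromosome {h.subject}")
            send = h.sstart + h.length - 1
            if send > sizes[h.subject] or h.sstart < 1:
                raise ValueError(
                    f"alignment past end of {h.subject}: {h.sstart}-{send}"
                )
            aln_len = min(h.length, plan.contig_length)
            mism = int(round(aln_len * (1 - h.identity / 100.0)))
            sstart, send_out = (h.sstart, h.sstart + aln_len - 1)
            if h.strand == "-":
                sstart, send_out = send_out, sstart
            rows.append(
                {
                    "qseqid": plan.contig_id,
                    "sseqid": h.subject,
                    "pident": h.identity,
                    "length": aln_len,
                    "mismatch": mism,
                    "gapopen": 0,
                    "qstart": 1,
                    "qend": aln_len,
                    "sstart": sstart,
                    "send": send_out,
                    "evalue": h.evalue,
                    "bitscore": round(2 * aln_len * h.identity / 100.0, 1),
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def random_hit_plans(
    n_contigs: int,
    chromosome_lengths: pd.DataFrame,
    seed: int = 0,
    contig_length: int = 400,
) -> list:
    """Randomized classifier fixtures covering the full rule space.

    Mixes single unique hits, multi-position hits (2-5 positions), chrUn
    partners, multi-chromosome cases, sub-threshold e-values and minus-strand
    placements; intended hits never overlap on a subject so planned and
    merged position counts coincide.
    """
    rng = np.random.default_rng(seed)
    named = [n for n in chromosome_lengths["name"] if not n.lower().startswith("chrun")]
    unknown = [n for n in chromosome_lengths["name"] if n.lower().startswith("chrun")]
    sizes = dict(zip(chromosome_lengths["name"], chromosome_lengths["length"]))
    plans = []
    for i in range(n_contigs):
        cid = f"contig{i:05d}"
        kind = rng.choice(
            ["unique", "multi", "chrun_partner", "multichrom", "overmulti",
             "subthreshold", "none", "chrun_only"],
            p=[0.35, 0.15, 0.15, 0.1, 0.08, 0.07, 0.05, 0.05],
        )
        def spots(subj, k):
            # k disjoint placements on one subject
            span = sizes[subj]
            starts = sorted(rng.choice(span // 1000 - 1, size=k, replace=False))
            return [
                HitSpec(
                    subj, int(s) * 1000 + 1, contig_length,
                    strand=str(rng.choice(["+", "-"])),
                    evalue=10.0 ** -float(rng.integers(55, 120)),
                )
                for s in starts
            ]
        hits: list[HitSpec] = []
        if kind == "unique":
            hits = spots(str(rng.choice(named)), 1)
        elif kind == "multi":
            hits = spots(str(rng.choice(named)), int(rng.integers(2, 4)))
        elif kind == "chrun_partner":
            hits = spots(str(rng.choice(named)), int(rng.integers(1, 4)))
            hits += spots(str(rng.choice(unknown)), int(rng.integers(1, 4)))
        elif kind == "multichrom":
            a, b = rng.choice(named, size=2, replace=False)
            hits = spots(str(a), 1) + spots(str(b), 1)
        elif kind == "overmulti":
            hits = spots(str(rng.choice(named)), int(rng.integers(4, 6)))
        elif kind == "subthreshold":
            h = spots(str(rng.choice(named)), 1)[0]
            hits = [dataclasses.replace(h, evalue=1e-40)]
        elif kind == "chrun_only":
            hits = spots(str(rng.choice(unknown)), int(rng.integers(1, 3)))
        plans.append(ContigHitPlan(cid, contig_length, hits))
    return plans
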