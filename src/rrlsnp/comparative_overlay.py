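"""Comparative contig overlay onto a divergent surrogate genome.

For a species without a draft assembly, de novo contigs can be anchored on a
related genome through blastn hits and used to estimate the genomic
distribution and density of both contigs and the SNPs they carry.  A contig's
hit pattern is "informative" when it is confined to a single chromosome with
at most three distinct chromosomal positions, optionally accompanied by one
unplaced (chrUn) scaffold with at most three positions; everything else is
ambiguous.  Contigs with exactly one position on one named chromosome anchor
uniquely and can be projected, SNP by SNP, into chromosome coordinates.

Input is standard BLAST tabular output (``-outfmt 6``); projections are
emitted as BED intervals (0-based half-open).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BLAST6_COLUMNS",
    "ContigPlacement",
    "parse_hits",
    "count_positions",
    "classify_contig",
    "classify_all",
    "project_snp",
    "reverse_project_snp",
    "project_snps",
    "summarize",
    "find_snp_hotspots",
]

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_EVALUE = 1e-50
CHRUN_PATTERN = re.compile(r"^chrun", re.IGNORECASE)


@dataclass
class ContigPlacement:
    """Classified hit status of one contig, with coordinates when unique."""

    contig_id: str
    status: str  # unique | informative_multi | uninformative | no_hit
    chromosome: str | None = None
    strand: str | None = None
    interval: tuple | None = None  # 0-based half-open on the chromosome
    query_interval: tuple | None = None  # 0-based half-open on the contig
    n_positions: int = 0
    has_chrun_partner: bool = False


def parse_hits(
    path_or_df, evalue_threshold: float = DEFAULT_EVALUE
) -> pd.DataFrame:
    """Read outfmt-6 rows, drop sub-threshold e-values, normalize strand.

    Adds 0-based half-open columns ``s_lo``/``s_hi`` (ascending regardless of
    strand), ``q_lo``/``q_hi``, and ``strand``.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(
            path_or_df, sep="\t", names=BLAST6_COLUMNS, header=None, comment="#"
        )
        if df.shape[1] != len(BLAST6_COLUMNS):
            raise ValueError("malformed BLAST tabular input")
    bad = df[BLAST6_COLUMNS].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"malformed row at line {int(np.nonzero(bad.values)[0][0]) + 1}")
    df = df[df["evalue"] <= evalue_threshold].copy()
    minus = df["sstart"] > df["send"]
    df["strand"] = np.where(minus, "-", "+")
    df["s_lo"] = np.where(minus, df["send"], df["sstart"]) - 1
    df["s_hi"] = np.where(minus, df["sstart"], df["send"])
    df["q_lo"] = df["qstart"] - 1
    df["q_hi"] = df["qend"]
    return df.reset_index(drop=True)


def count_positions(
    intervals: Sequence[tuple], merge_gap: int = 0
) -> int:
    """Number of distinct chromosomal positions among subject intervals.

    Intervals (0-based half-open, strand-normalized) that overlap by at least
    one base (or lie within ``merge_gap``) belong to one position; split HSPs
    therefore collapse.
    """
    if not len(intervals):
        return 0
    ivs = sorted(intervals)
    n = 1
    _, cur_hi = ivs[0]
    for lo, hi in ivs[1:]:
        if lo >= cur_hi + merge_gap:
            n += 1
            cur_hi = hi
        else:
            cur_hi = max(cur_hi, hi)
    return n


def _is_chrun(name: str, pattern: re.Pattern = CHRUN_PATTERN) -> bool:
    return bool(pattern.search(str(name)))


def classify_contig(
    contig_id: str, hits: pd.DataFrame, chrun_pattern: re.Pattern = CHRUN_PATTERN,
    merge_gap: int = 0,
) -> ContigPlacement:
    """Apply the informative-hit rules to one contig's e-value-filtered hits.

    unique: one merged position on one named chromosome, no other subject.
    informative_multi: one named chromosome with <= 3 positions, alone or with
    exactly one chrUn scaffold (<= 3 positions); a single chrUn scaffold with
    <= 3 positions also anchors informatively but never uniquely.
    Everything else (>= 2 named chromosomes, >= 2 chrUn scaffolds, > 3
    positions anywhere) is uninformative.
    """
    if hits is None or len(hits) == 0:
        return ContigPlacement(contig_id, "no_hit")
    subjects = hits["sseqid"].unique()
    named = sorted(s for s in subjects if not _is_chrun(s, chrun_pattern))
    unknown = sorted(s for s in subjects if _is_chrun(s, chrun_pattern))

    def npos(subj: str) -> int:
        sub = hits[hits["sseqid"] == subj]
        return count_positions(list(zip(sub["s_lo"], sub["s_hi"])), merge_gap)

    if len(named) >= 2 or len(unknown) >= 2:
        return ContigPlacement(contig_id, "uninformative")

    if len(named) == 1:
        n = npos(named[0])
        if unknown:
            n_un = npos(unknown[0])
            status = "informative_multi" if n <= 3 and n_un <= 3 else "uninformative"
            return ContigPlacement(
                contig_id, status, chromosome=named[0] if status != "uninformative" else None,
                n_positions=n, has_chrun_partner=True,
            )
        if n == 1:
            top = hits.loc[hits["bitscore"].idxmax()]
            lo = int(hits["s_lo"].min())
            hi = int(hits["s_hi"].max())
            return ContigPlacement(
                contig_id, "unique", chromosome=named[0], strand=str(top["strand"]),
                interval=(lo, hi),
                query_interval=(int(top["q_lo"]), int(top["q_hi"])),
                n_positions=1,
            )
        status = "informative_multi" if n <= 3 else "uninformative"
        return ContigPlacement(
            contig_id, status, chromosome=named[0] if status != "uninformative" else None,
            n_positions=n,
        )

    # chrUn only (exactly one scaffold)
    n = npos(unknown[0])
    status = "informative_multi" if n <= 3 else "uninformative"
    return ContigPlacement(
        contig_id, status, chromosome=unknown[0] if status != "uninformative" else None,
        n_positions=n, has_chrun_partner=True,
    )


def classify_all(hits: pd.DataFrame, all_contigs: Sequence[str] | None = None,
                 merge_gap: int = 0) -> dict:
    """Classify every contig; contigs absent from ``hits`` become no_hit."""
    placements: dict[str, ContigPlacement] = {}
    for cid, group in hits.groupby("qseqid", sort=False):
        placements[cid] = classify_contig(str(cid), group, merge_gap=merge_gap)
    for cid in all_contigs or []:
        placements.setdefault(cid, ContigPlacement(cid, "no_hit"))
    return placements


def project_snp(placement: ContigPlacement, contig_offset: int) -> int | None:
    """Map a 0-based contig offset onto the placed chromosome (0-based).

    Plus strand: chromosome = s_lo + (offset - q_lo); minus strand mirrors
    within the subject interval.  Offsets outside the aligned query interval
    return None.
    """
    if placement.status != "unique":
        return None
    q_lo, q_hi = placement.query_interval
    if not q_lo <= contig_offset < q_hi:
        return None
    s_lo, s_hi = placement.interval
    if placement.strand == "+":
        return s_lo + (contig_offset - q_lo)
    return (s_hi - 1) - (contig_offset - q_lo)


def reverse_project_snp(placement: ContigPlacement, chrom_pos: int) -> int | None:
    """Inverse of :func:`project_snp`; exact round-trip on both strands."""
    if placement.status != "unique":
        return None
    q_lo, q_hi = placement.query_interval
    s_lo, s_hi = placement.interval
    if placement.strand == "+":
        off = q_lo + (chrom_pos - s_lo)
    else:
        off = q_lo + ((s_hi - 1) - chrom_pos)
    return off if q_lo <= off < q_hi else None


def project_snps(
    snps: pd.DataFrame, placements: dict
) -> pd.DataFrame:
    """Project SNP calls onto chromosome coordinates via unique placements.

    ``snps`` needs columns ``contig_id`` and ``pos`` (0-based contig offset).
    Returns a BED-like table with ``chrom``, ``chrom_start``, ``chrom_end``
    for projected SNPs and a ``status`` column (projected / outside_alignment
    / not_unique / no_hit) for the rest.
    """
    rows = []
    for _, snp in snps.iterrows():
        cid = snp["contig_id"]
        pl = placements.get(cid)
        row = dict(snp)
        if pl is None or pl.status == "no_hit":
            row.update(status="no_hit", chrom=None, chrom_start=-1, chrom_end=-1)
        elif pl.status != "unique":
            row.update(status="not_unique", chrom=None, chrom_start=-1, chrom_end=-1)
        else:
            cpos = project_snp(pl, int(snp["pos"]))
            if cpos is None:
                row.update(status="outside_alignment", chrom=None,
                           chrom_start=-1, chrom_end=-1)
            else:
                row.update(status="projected", chrom=pl.chromosome,
                           chrom_start=int(cpos), chrom_end=int(cpos) + 1)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize(
    placements: dict,
    projected_snps: pd.DataFrame | None,
    chromosome_lengths: pd.DataFrame,
    bin_width: int = 10_000_000,
    sd_ddof: int = 1,
) -> tuple[pd.DataFrame, float, float]:
    """Per-chromosome contig/SNP counts, densities and an overall mean +/- SD.

    Density is kb of chromosome per placed contig; the overall figure is the
    unweighted mean across chromosomes with at least one hit, with sample SD
    by default (``sd_ddof=1``).  Only unique placements are counted.  A
    placement on a chromosome missing from the length table raises.
    """
    sizes = dict(zip(chromosome_lengths["name"], chromosome_lengths["length"]))
    hit_counts: dict[str, int] = {}
    bins: dict[str, np.ndarray] = {}
    for pl in placements.values():
        if pl.status != "unique":
            continue
        if pl.chromosome not in sizes:
            raise KeyError(f"chromosome {pl.chromosome} absent from length table")
        hit_counts[pl.chromosome] = hit_counts.get(pl.chromosome, 0) + 1
        nbins = int(np.ceil(sizes[pl.chromosome] / bin_width))
        arr = bins.setdefault(pl.chromosome, np.zeros(nbins, dtype=int))
        arr[min(pl.interval[0] // bin_width, nbins - 1)] += 1

    snp_counts: dict[str, int] = {}
    if projected_snps is not None and len(projected_snps):
        proj = projected_snps[projected_snps["status"] == "projected"]
        snp_counts = proj.groupby("chrom").size().to_dict()

    rows = []
    densities = []
    for chrom in chromosome_lengths["name"]:
        hits = hit_counts.get(chrom, 0)
        density = sizes[chrom] / hits / 1000.0 if hits else np.nan
        if hits:
            densities.append(density)
        rows.append(
            {
                "chromosome": chrom,
                "length_bp": sizes[chrom],
                "contig_hits": hits,
                "snps": int(snp_counts.get(chrom, 0)),
                "density_kb_per_hit": density,
                "bin_counts": ",".join(map(str, bins.get(chrom, []))),
            }
        )
    table = pd.DataFrame(rows)
    mean = float(np.mean(densities)) if densities else float("nan")
    sd = float(np.std(densities, ddof=sd_ddof)) if len(densities) > sd_ddof else float("nan")
    return table, mean, sd


def find_snp_hotspots(
    projected_snps: pd.DataFrame,
    window: int,
    min_snps: int,
    contig_of: dict | None = None,
) -> pd.DataFrame:
    """SNP-dense chromosomal intervals (clusters of projected SNPs).

    A sliding window of ``window`` bp anchored at each SNP is scanned; windows
    holding >= ``min_snps`` SNPs are merged when they overlap.  Each hotspot
    reports its interval, SNP count and member contigs.
    """
    rows = []
    proj = projected_snps[projected_snps["status"] == "projected"]
    for chrom, group in proj.groupby("chrom"):
        pos = np.sort(group["chrom_start"].to_numpy())
        hi_idx = np.searchsorted(pos, pos + window, side="left")
        qualifying = np.nonzero(hi_idx - np.arange(len(pos)) >= min_snps)[0]
        if not len(qualifying):
            continue
        # merge overlapping qualifying windows
        merged: list[list[int]] = []
        for i in qualifying:
            lo, hi = int(pos[i]), int(pos[i]) + window
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        for lo, hi in merged:
            members = group[(group["chrom_start"] >= lo) & (group["chrom_start"] < hi)]
            contigs = sorted(members["contig_id"].unique())
            rows.append(
                {
                    "chromosome": chrom,
                    "start": lo,
                    "end": hi,
                    "n_snps": len(members),
                    "n_contigs": len(contigs),
                    "contigs": ",".join(map(str, contigs)),
                }
            )
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_snps",
                                       "n_contigs", "contigs"])
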