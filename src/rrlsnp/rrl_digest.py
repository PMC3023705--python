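"""In-silico restriction digestion and fragment size selection.

Reduced-representation libraries (RRLs) sample a genome by digesting pooled
DNA with a frequent-cutting restriction enzyme and sequencing only the
fragments inside a gel-excised size window.  This module predicts that
reduced fraction computationally: it scans a sequence for enzyme recognition
sites (IUPAC-aware, both strands for non-palindromic sites), cuts at every
occurrence, and applies an inclusive length window.

Coordinates are 0-based half-open throughout; digestion is complete (every
site is cut) and fragments tile each source sequence without gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

__all__ = [
    "Enzyme",
    "Fragment",
    "SelectionWindow",
    "DigestStats",
    "ALU_I",
    "HAE_III",
    "digest",
    "size_select",
    "reduction_report",
    "fragment_length_pmf",
]

# IUPAC nucleotide codes -> set of unambiguous bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme defined by its recognition site and cut offset.

    ``cut_offset`` is the 0-based position within the site where the enzyme
    cleaves the top strand (AluI, AG^CT, has offset 2).
    """

    name: str
    recognition_site: str
    cut_offset: int

    def __post_init__(self) -> None:
        site = self.recognition_site.upper()
        if not site or any(b not in IUPAC for b in site):
            raise ValueError(f"invalid recognition site {self.recognition_site!r}")
        if not 0 <= self.cut_offset <= len(site):
            raise ValueError("cut_offset outside recognition site")
        object.__setattr__(self, "recognition_site", site)

    @property
    def is_palindromic(self) -> bool:
        rc = self.recognition_site.translate(_COMPLEMENT)[::-1]
        return rc == self.recognition_site


ALU_I = Enzyme("AluI", "AGCT", 2)
HAE_III = Enzyme("HaeIII", "GGCC", 2)


@dataclass(frozen=True)
class Fragment:
    """A restriction fragment with its source coordinates (0-based half-open)."""

    source_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("fragment end must exceed start")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length inconsistent with coordinates")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SelectionWindow:
    """Inclusive fragment-length bounds emulating gel excision."""

    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("require 1 <= min_len <= max_len")

    def contains(self, length: int) -> bool:
        return self.min_len <= length <= self.max_len


@dataclass
class DigestStats:
    n_fragments: int
    n_selected: int
    total_bp: int
    selected_bp: int
    reduction_fraction: float


def _site_regex(site: str) -> re.Pattern[str]:
    # Lookahead so overlapping occurrences are all found.  Sequence-side
    # ambiguity codes (N etc.) never match: character classes contain only
    # unambiguous bases.
    cls = "".join(f"[{IUPAC[b]}]" if len(IUPAC[b]) > 1 else IUPAC[b] for b in site)
    return re.compile(f"(?=({cls}))")


def cut_positions(sequence: str, enzyme: Enzyme) -> list[int]:
    """All cleavage positions of ``enzyme`` in ``sequence`` (0-based, sorted).

    Palindromic sites are scanned once; otherwise the reverse-complement site
    is scanned too, with the bottom-strand cut mapped onto top-strand
    coordinates.
    """
    seq = sequence.upper()
    site = enzyme.recognition_site
    cuts = {m.start() + enzyme.cut_offset for m in _site_regex(site).finditer(seq)}
    if not enzyme.is_palindromic:
        rc_site = site.translate(_COMPLEMENT)[::-1]
        rc_offset = len(site) - enzyme.cut_offset
        cuts |= {m.start() + rc_offset for m in _site_regex(rc_site).finditer(seq)}
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(sequence: str, enzyme: Enzyme, source_id: str = "seq") -> list[Fragment]:
    """Completely digest ``sequence``; fragments tile it without gaps.

    An empty sequence yields an empty list; a sequence with no site yields a
    single fragment equal to itself.
    """
    seq = str(sequence).upper()
    if not seq:
        return []
    bounds = [0, *cut_positions(seq, enzyme), len(seq)]
    return [
        Fragment(source_id, a, b, seq[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def size_select(
    fragments: Sequence[Fragment], window: SelectionWindow
) -> tuple[list[Fragment], DigestStats]:
    """Keep fragments whose length falls in the inclusive window."""
    selected = [f for f in fragments if window.contains(len(f))]
    total_bp = sum(len(f) for f in fragments)
    selected_bp = sum(len(f) for f in selected)
    stats_ = DigestStats(
        n_fragments=len(fragments),
        n_selected=len(selected),
        total_bp=total_bp,
        selected_bp=selected_bp,
        reduction_fraction=selected_bp / total_bp if total_bp else 0.0,
    )
    return selected, stats_


def reduction_report(
    genome: str | Iterable[SeqIO.SeqRecord],
    enzyme: Enzyme,
    window: SelectionWindow,
    bin_width: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence digestion/selection summary plus a fragment-length histogram.

    ``genome`` is a FASTA path or an iterable of SeqRecords.  Returns
    ``(per_seq, histogram)`` DataFrames; ``per_seq`` ends with a ``TOTAL`` row.
    """
    if isinstance(genome, (str,)):
        records = list(SeqIO.parse(genome, "fasta"))
    else:
        records = list(genome)
    if not records:
        raise ValueError("empty or unreadable FASTA input")

    rows = []
    lengths: list[int] = []
    for rec in records:
        frags = digest(str(rec.seq), enzyme, source_id=rec.id)
        _, st = size_select(frags, window)
        rows.append(
            {
                "sequence": rec.id,
                "length_bp": len(rec.seq),
                "n_fragments": st.n_fragments,
                "n_selected": st.n_selected,
                "selected_bp": st.selected_bp,
                "reduction_fraction": st.reduction_fraction,
            }
        )
        lengths.extend(len(f) for f in frags)

    per_seq = pd.DataFrame(rows)
    total = {
        "sequence": "TOTAL",
        "length_bp": int(per_seq["length_bp"].sum()),
        "n_fragments": int(per_seq["n_fragments"].sum()),
        "n_selected": int(per_seq["n_selected"].sum()),
        "selected_bp": int(per_seq["selected_bp"].sum()),
        "reduction_fraction": float(per_seq["selected_bp"].sum())
        / float(per_seq["length_bp"].sum()),
    }
    per_seq = pd.concat([per_seq, pd.DataFrame([total])], ignore_index=True)

    arr = np.asarray(lengths)
    edges = np.arange(0, arr.max() + bin_width + 1, bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    hist = pd.DataFrame(
        {"bin_start": edges[:-1].astype(int), "bin_end": edges[1:].astype(int), "count": counts}
    )
    return per_seq, hist


def geometric_spacing_pmf(site_probability: float, lengths: np.ndarray) -> np.ndarray:
    """Geometric approximation to the fragment-length law: P(L = k) for each k.

    Treats site occurrences as a Bernoulli process with per-position success
    probability ``p``; accurate for lengths well above the site length.
    """
    return stats.geom.pmf(lengths, site_probability)


def fragment_length_pmf(
    enzyme: Enzyme, max_length: int, base_probs: dict | None = None
) -> np.ndarray:
    """Exact fragment-length distribution for an i.i.d. random genome.

    Fragment length equals the spacing between consecutive site occurrences,
    i.e. the first-passage time of the recognition-site prefix automaton
    (KMP) from its post-occurrence state to the next full match under i.i.d.
    bases.  Returns ``pmf`` with ``pmf[k]`` = P(L = k) for k in
    [0, max_length]; the tail beyond the site length decays geometrically
    with rate ~ site probability.  Ambiguity codes in the site are handled
    through their IUPAC base sets.
    """
    if base_probs is None:
        base_probs = {b: 0.25 for b in "ACGT"}
    site = enzyme.recognition_site
    L = len(site)
    # KMP prefix automaton over states 0..L (L = absorbing full match)
    def delta(state: int, base: str) -> int:
        # longest suffix of (matched prefix + base) that is a site prefix
        prefix = site[:state] + base
        for k in range(min(len(prefix), L), 0, -1):
            tail = prefix[-k:]
            if all(t in IUPAC[s] for s, t in zip(site[:k], tail)):
                return k
        return 0

    trans = np.zeros((L + 1, L + 1))
    for s in range(L):
        for b, pb in base_probs.items():
            trans[s, delta(s, b)] += pb
    # restart state after an occurrence = automaton state of the full word's
    # proper-suffix overlap with the site (0 for non-self-overlapping sites)
    restart = 0
    for k in range(L - 1, 0, -1):
        if all(t in IUPAC[s] for s, t in zip(site[:k], site[-k:])):
            restart = k
            break
    pmf = np.zeros(max_length + 1)
    state = np.zeros(L + 1)
    state[restart] = 1.0
    for k in range(1, max_length + 1):
        state = state @ trans
        pmf[k] = state[L]
        state[L] = 0.0
    return pmf
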