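"""Degenerate-motif scanning over SNP-masked chromosomes.

The scanner slides a IUPAC motif (and its reverse complement) across a
masked chromosome one nucleotide at a time.  A window is a hit when
every genome symbol's expansion intersects the corresponding motif
symbol's expansion; a genome ``N`` (assembly gap) rejects the window
outright.  Within each hit, positions carrying a SNP mask code are
recorded, which is what turns a motif scan into a SNP-discovery step.

Matching is vectorised with 4-bit base masks (A=1, C=2, G=4, T=8): a
genome symbol matches a motif symbol iff the bitwise AND of their
masks is nonzero.  Genome ``N`` encodes to 0 so it can never match.
Chromosomes are processed one at a time; nothing here holds more than
one chromosome in memory.

A window that matches both orientations (palindromic under the
pattern) is reported once with strand ``'±'`` so its SNPs are not
double-counted in the statistics; its offsets use the forward
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError
from .formats import MaskedSequence
from .iupac import EXPANSION, SNP_CODES, MotifPattern, reverse_complement

log = logging.getLogger(__name__)

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}


def _mask_of(symbol: str) -> int:
    return sum(_BASE_BIT[b] for b in EXPANSION[symbol])


# genome-side lookup: N -> 0 (matches nothing), invalid byte -> 255 sentinel
_GENOME_TABLE = np.full(256, 255, dtype=np.uint8)
for _sym in EXPANSION:
    _GENOME_TABLE[ord(_sym)] = 0 if _sym == "N" else _mask_of(_sym)
    _GENOME_TABLE[ord(_sym.lower())] = _GENOME_TABLE[ord(_sym)]

_SNP_TABLE = np.zeros(256, dtype=bool)
for _sym in SNP_CODES:
    _SNP_TABLE[ord(_sym)] = True
    _SNP_TABLE[ord(_sym.lower())] = True


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence on the forward-strand coordinate system.

    ``snp_offsets`` are 0-based positions within the motif as read
    5'->3' on the hit strand; ``snp_positions`` are the matching
    genomic bp (1-based), aligned index-for-index with the offsets.
    """

    chrom: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive, start + L - 1
    strand: str         # '+', '-' or '±'
    snp_offsets: tuple[int, ...] = ()
    snp_positions: tuple[int, ...] = ()

    @property
    def n_snps(self) -> int:
        return len(self.snp_offsets)


@dataclass
class ScanStats:
    """Descriptive statistics accumulated over one or many scans."""

    motif_length: int
    motifs_total: int = 0
    motifs_with_snps: int = 0
    per_position_counts: list[int] = field(default_factory=list)
    histogram: dict[int, int] = field(default_factory=dict)
    multi_snp_hits: list[MotifHit] = field(default_factory=list)


def match_start_arrays(code: np.ndarray,
                       motif: MotifPattern) -> tuple[np.ndarray, np.ndarray]:
    """Boolean per-window match arrays (forward, reverse) over a byte
    array of uppercase IUPAC sequence.  Shared by the scanner and the
    fixture generator."""
    L = len(motif)
    n = len(code)
    if n < L:
        empty = np.zeros(0, dtype=bool)
        return empty, empty
    gmask = _GENOME_TABLE[code]
    if (gmask == 255).any():
        bad = chr(code[int(np.argmax(gmask == 255))])
        raise FormatError(f"non-IUPAC character {bad!r} in sequence")
    n_windows = n - L + 1
    fwd = np.ones(n_windows, dtype=bool)
    rev = np.ones(n_windows, dtype=bool)
    rc = reverse_complement(motif)
    for j in range(L):
        col = gmask[j:j + n_windows]
        fwd &= (col & _mask_of(motif.sequence[j])) != 0
        rev &= (col & _mask_of(rc.sequence[j])) != 0
    return fwd, rev


def scan_chromosome(seq: MaskedSequence, motif: MotifPattern) -> list[MotifHit]:
    """Find every occurrence of *motif* (both strands) in one chromosome.

    Returns hits sorted by start position.  Overlapping occurrences are
    all reported (step size is one nucleotide); a window matching both
    orientations is collapsed to a single ``'±'`` hit.
    """
    L = len(motif)
    n = len(seq.seq)
    if n < L:
        return []

    code = np.frombuffer(seq.seq.encode("ascii"), dtype=np.uint8)
    try:
        fwd, rev = match_start_arrays(code, motif)
    except FormatError as exc:
        raise FormatError(f"chromosome {seq.chrom}: {exc}") from exc

    is_snp = _SNP_TABLE[code]
    hits: list[MotifHit] = []
    for s in np.nonzero(fwd | rev)[0]:
        s = int(s)
        both = fwd[s] and rev[s]
        strand = "±" if both else ("+" if fwd[s] else "-")
        window_snps = np.nonzero(is_snp[s:s + L])[0]
        genomic = tuple(int(s + off + 1) for off in window_snps)
        if strand == "-":
            offsets = tuple(int(L - 1 - off) for off in window_snps)
        else:
            offsets = tuple(int(off) for off in window_snps)
        hits.append(MotifHit(seq.chrom, s + 1, s + L, strand, offsets, genomic))
    return hits


def collect_stats(hits: list[MotifHit], motif_length: int,
                  stats: ScanStats | None = None) -> ScanStats:
    """Accumulate per-position and per-hit SNP statistics.

    Per-position counts are indexed by offset on the hit strand (a
    reverse-strand hit's offset 0 is the motif's first symbol, not the
    genome's leftmost base).  May be called repeatedly with a running
    ``stats`` to fold in one chromosome at a time.
    """
    if stats is None:
        stats = ScanStats(motif_length,
                          per_position_counts=[0] * motif_length)
    for hit in hits:
        stats.motifs_total += 1
        k = hit.n_snps
        stats.histogram[k] = stats.histogram.get(k, 0) + 1
        if k >= 1:
            stats.motifs_with_snps += 1
        if k >= 2:
            stats.multi_snp_hits.append(hit)
        for off in hit.snp_offsets:
            stats.per_position_counts[off] += 1
    return stats


def warn_multi_snp(stats: ScanStats, sink: logging.Logger = log) -> int:
    """Warn once per hit carrying two or more SNPs (possible
    low-quality sequence); returns the number of warnings issued."""
    for hit in stats.multi_snp_hits:
        sink.warning(
            "motif at %s:%d-%d contains %d SNPs -- may indicate "
            "low-quality sequencing data",
            hit.chrom, hit.start, hit.end, hit.n_snps)
    return len(stats.multi_snp_hits)
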