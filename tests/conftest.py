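"""Shared fixtures and independent oracles.

The oracles here deliberately re-state IUPAC semantics from their own
literal tables and use naive per-window loops, so they cannot share a
bug with the vectorised implementation they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifsnps.fixtures import FixtureSpec, generate, validate

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# --- independent IUPAC oracle -------------------------------------------

ORACLE_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
ORACLE_SNP_CODES = set("RYSWKMBDHV")
_COMP_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODE_OF = {frozenset(v): k for k, v in ORACLE_EXPAND.items()}


def oracle_match(genome_sym: str, motif_sym: str) -> bool:
    """Genome N matches nothing; otherwise expansion intersection."""
    if genome_sym == "N":
        return False
    return bool(set(ORACLE_EXPAND[genome_sym]) & set(ORACLE_EXPAND[motif_sym]))


def oracle_revcomp(pattern: str) -> str:
    return "".join(
        _CODE_OF[frozenset(_COMP_BASE[b] for b in ORACLE_EXPAND[s])]
        for s in reversed(pattern))


def brute_scan(chrom: str, seq: str, motif: str):
    """Naive per-window, per-position scan; mirrors the documented hit
    conventions (forward-strand coordinates, '±' for palindromic
    double matches, offsets read 5'->3' on the hit strand)."""
    L = len(motif)
    rc = oracle_revcomp(motif)
    hits = []
    for i in range(len(seq) - L + 1):
        win = seq[i:i + L]
        f = all(oracle_match(win[j], motif[j]) for j in range(L))
        r = all(oracle_match(win[j], rc[j]) for j in range(L))
        if not (f or r):
            continue
        strand = "±" if (f and r) else ("+" if f else "-")
        offs = [j for j in range(L) if win[j] in ORACLE_SNP_CODES]
        positions = tuple(i + j + 1 for j in offs)
        offsets = tuple(offs) if strand != "-" else tuple(L - 1 - j for j in offs)
        hits.append((chrom, i + 1, i + L, strand, offsets, positions))
    return hits


def hit_tuples(hits):
    """Normalise package MotifHit objects for comparison with brute_scan."""
    return [(h.chrom, h.start, h.end, h.strand, h.snp_offsets, h.snp_positions)
            for h in hits]


def random_masked_sequence(rng: np.random.Generator, length: int,
                           snp_rate: float = 0.002,
                           n_rate: float = 0.001) -> str:
    """Random ACGT sequence with SNP mask codes and a few gap Ns."""
    seq = list("ACGT"[i] for i in rng.integers(0, 4, length))
    for i in np.nonzero(rng.random(length) < snp_rate)[0]:
        seq[i] = sorted(ORACLE_SNP_CODES)[int(rng.integers(10))]
    for i in np.nonzero(rng.random(length) < n_rate)[0]:
        seq[i] = "N"
    return "".join(seq)


def random_motif(rng: np.random.Generator, lo: int = 4, hi: int = 8) -> str:
    """Random IUPAC motif with at least one degenerate symbol."""
    symbols = sorted(ORACLE_EXPAND)
    degenerate = sorted(set(symbols) - set("ACGT"))
    L = int(rng.integers(lo, hi + 1))
    motif = [symbols[int(rng.integers(len(symbols)))] for _ in range(L)]
    motif[int(rng.integers(L))] = degenerate[int(rng.integers(len(degenerate)))]
    return "".join(motif)


# --- shared generated dataset -------------------------------------------

STD_SPEC = FixtureSpec(seed=11, n_chromosomes=3, chrom_length=50_000,
                       n_planted_motifs=18, n_regions=6)


@pytest.fixture(scope="session")
def std_fixture(tmp_path_factory):
    """One validated synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("fixture")
    truth = generate(STD_SPEC, out)
    validate(out, truth)
    return out, truth, STD_SPEC
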