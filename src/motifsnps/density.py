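"""SNP density and distribution statistics.

Densities are simple ratios: SNPs per base pair inside the user's
regions, inside all motif occurrences, and across the genome at large
(total catalogue SNPs over total FASTA length).  Regions are NOT
merged before their lengths are summed -- the denominator is the total
length of all regions as given.  Densities are compared between
groups with a Pearson chi-square on the implied 2x2 table (SNP /
non-SNP x group), one degree of freedom, no continuity correction
(genome-scale cell counts make the correction immaterial).

Numerators count catalogue (rsid-bearing) SNPs throughout, so the
region, motif and genome densities are computed over the same marker
universe.

The within-motif SNP distribution is reported two ways: the fraction
of SNPs at each motif position (normalised to the total SNP count for
the motif), and the same fractions aggregated by the motif's symbol
at each position (so e.g. the two A positions of AGGTCA pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import stats as sps

from .errors import DensityError
from .formats import GenomicRegion
from .iupac import MotifPattern
from .scanner import MotifHit


def region_density(n_snps: int, regions: list[GenomicRegion]) -> float:
    """SNPs per bp over the summed (unmerged) region lengths."""
    total = sum(r.length for r in regions)
    if total <= 0:
        raise DensityError("region density undefined: zero total region length")
    return n_snps / total


def motif_density(n_motif_snps: int, motif_length: int, n_motifs: int) -> float:
    """SNPs per bp over motif_length x number of occurrences."""
    if n_motifs <= 0 or motif_length <= 0:
        raise DensityError("motif density undefined: no motif occurrences")
    return n_motif_snps / (motif_length * n_motifs)


def genome_density(n_catalogue_snps: int, genome_length: int) -> float:
    """Catalogue SNPs per bp of total FASTA length."""
    if genome_length <= 0:
        raise DensityError("genome density undefined: zero genome length")
    return n_catalogue_snps / genome_length


def chi_square_density(count_a: tuple[int, int],
                       count_b: tuple[int, int]) -> tuple[float, float]:
    """Pearson chi-square comparing two (snps, bases) groups.

    Builds the 2x2 table [[snps, non-snp bases]] per group; 1 df, no
    continuity correction.  All four cells must be positive.
    """
    (sa, na), (sb, nb) = count_a, count_b
    table = [[sa, na - sa], [sb, nb - sb]]
    if any(cell <= 0 for row in table for cell in row):
        raise DensityError(f"degenerate 2x2 table {table}: all cells must be positive")
    stat, p, dof, _ = sps.chi2_contingency(table, correction=False)
    assert dof == 1
    return float(stat), float(p)


@dataclass
class NucleotideDistribution:
    """Per-position and per-symbol SNP fractions within the motif."""

    per_position_counts: list[int]
    per_position_fractions: list[float]
    per_symbol_fractions: dict[str, float]
    total_snps: int
    no_data: bool = False


def nucleotide_distribution(hits: list[MotifHit],
                            motif: MotifPattern) -> NucleotideDistribution:
    """SNP fractions per motif position, normalised to the total SNP
    count, plus the aggregation over positions sharing a motif symbol.

    With zero SNPs the fractions are all zero and ``no_data`` is set.
    """
    L = len(motif)
    counts = [0] * L
    for hit in hits:
        for off in hit.snp_offsets:
            counts[off] += 1
    total = sum(counts)
    if total == 0:
        return NucleotideDistribution(counts, [0.0] * L, {}, 0, no_data=True)
    fractions = [c / total for c in counts]
    per_symbol: dict[str, float] = {}
    for sym, frac in zip(motif.sequence, fractions):
        per_symbol[sym] = per_symbol.get(sym, 0.0) + frac
    return NucleotideDistribution(counts, fractions, per_symbol, total)


@dataclass
class DensityReport:
    """The density section of the run report."""

    region_density: float | None
    motif_density: float | None
    genome_density: float | None
    chi2_region_vs_genome: tuple[float, float] | None
    chi2_motif_vs_genome: tuple[float, float] | None
    inputs: dict = field(default_factory=dict)


def build_density_report(*,
                         n_region_snps: int,
                         regions: list[GenomicRegion],
                         n_motif_snps: int,
                         motif_length: int,
                         n_motifs: int,
                         n_catalogue_snps: int,
                         genome_length: int) -> DensityReport:
    """Compute all densities and both chi-square comparisons at once.

    Quantities whose denominators are empty (no regions, no motif
    occurrences) are reported as None rather than raising, so a
    motif-only or region-only run still gets a report.
    """
    gdens = genome_density(n_catalogue_snps, genome_length)
    region_bases = sum(r.length for r in regions)
    rdens = region_density(n_region_snps, regions) if region_bases else None
    mdens = (motif_density(n_motif_snps, motif_length, n_motifs)
             if n_motifs else None)

    def safe_chi2(count_a, count_b):
        try:
            return chi_square_density(count_a, count_b)
        except DensityError:
            return None

    chi_r = (safe_chi2((n_region_snps, region_bases),
                       (n_catalogue_snps, genome_length))
             if rdens is not None else None)
    motif_bases = motif_length * n_motifs
    chi_m = (safe_chi2((n_motif_snps, motif_bases),
                       (n_catalogue_snps, genome_length))
             if mdens is not None else None)
    return DensityReport(
        rdens, mdens, gdens, chi_r, chi_m,
        inputs=dict(n_region_snps=n_region_snps, region_bases=region_bases,
                    n_motif_snps=n_motif_snps, motif_bases=motif_bases,
                    n_catalogue_snps=n_catalogue_snps,
                    genome_length=genome_length))
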