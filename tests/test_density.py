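"""SNP density ratios, chi-square comparison, within-motif distribution."""

import numpy as np
import pytest

from motifsnps.density import (chi_square_density, genome_density,
                               motif_density, nucleotide_distribution,
                               region_density)
from motifsnps.errors import DensityError
from motifsnps.formats import GenomicRegion, MaskedSequence
from motifsnps.iupac import MotifPattern
from motifsnps.scanner import scan_chromosome


def regions_of_lengths(*lengths):
    out, start = [], 1
    for ln in lengths:
        out.append(GenomicRegion("1", start, start + ln - 1))
        start += ln + 10
    return out


def test_region_density_arithmetic_and_unmerged_lengths():
    assert region_density(3, regions_of_lengths(100, 200)) == pytest.approx(0.01)
    assert region_density(0, regions_of_lengths(100)) == 0.0
    # overlapping regions: lengths are summed as given, not merged
    overlapping = [GenomicRegion("1", 1, 100), GenomicRegion("1", 51, 150)]
    assert region_density(2, overlapping) == pytest.approx(2 / 200)
    with pytest.raises(DensityError):
        region_density(1, [])


def test_motif_density():
    assert motif_density(9, 6, 300) == pytest.approx(0.005)
    assert motif_density(0, 6, 10) == 0.0
    with pytest.raises(DensityError):
        motif_density(1, 6, 0)


def test_genome_density():
    assert genome_density(100, 100_000) == pytest.approx(0.001)
    with pytest.raises(DensityError):
        genome_density(1, 0)


def test_chi_square_zero_on_proportional_tables():
    stat, p = chi_square_density((10, 1000), (10, 1000))
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    stat, _ = chi_square_density((10, 1000), (30, 3000))
    assert stat == pytest.approx(0.0, abs=1e-12)


def closed_form_chi2(sa, na, sb, nb):
    """Independent textbook Pearson statistic: sum (O-E)^2 / E."""
    obs = [[sa, na - sa], [sb, nb - sb]]
    total = na + nb
    col = [sa + sb, (na - sa) + (nb - sb)]
    row = [na, nb]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = row[i] * col[j] / total
            stat += (obs[i][j] - e) ** 2 / e
    return stat


def test_chi_square_matches_closed_form():
    stat, _ = chi_square_density((30, 1000), (10, 1000))
    assert stat == pytest.approx(closed_form_chi2(30, 1000, 10, 1000), abs=1e-9)
    rng = np.random.default_rng(12)
    for _ in range(20):
        na, nb = (int(x) for x in rng.integers(50, 5000, 2))
        sa = int(rng.integers(1, na))
        sb = int(rng.integers(1, nb))
        stat, p = chi_square_density((sa, na), (sb, nb))
        assert stat == pytest.approx(closed_form_chi2(sa, na, sb, nb), abs=1e-9)
        assert 0 <= p <= 1


def test_chi_square_is_symmetric_and_rejects_degenerate_tables():
    a, b = (37, 900), (12, 1100)
    assert chi_square_density(a, b)[0] == pytest.approx(
        chi_square_density(b, a)[0])
    with pytest.raises(DensityError):
        chi_square_density((0, 100), (5, 100))
    with pytest.raises(DensityError):
        chi_square_density((100, 100), (5, 100))


def test_nucleotide_distribution_all_snps_at_one_position():
    motif = MotifPattern("AGGNCA")
    hits = scan_chromosome(MaskedSequence("1", "AGGRCA"), motif)
    dist = nucleotide_distribution(hits, motif)
    assert dist.per_position_fractions == [0, 0, 0, 1.0, 0, 0]
    assert dist.total_snps == 1 and not dist.no_data


def test_nucleotide_distribution_zero_snps_flagged_no_data():
    motif = MotifPattern("AGGTCA")
    hits = scan_chromosome(MaskedSequence("1", "AGGTCA"), motif)
    dist = nucleotide_distribution(hits, motif)
    assert dist.no_data and dist.per_position_fractions == [0.0] * 6


def test_nucleotide_distribution_sums_to_one_and_pools_by_symbol():
    rng = np.random.default_rng(8)
    from conftest import random_masked_sequence
    motif = MotifPattern("RGNACA")
    seq = random_masked_sequence(rng, 20_000, snp_rate=0.02)
    hits = scan_chromosome(MaskedSequence("1", seq), motif)
    dist = nucleotide_distribution(hits, motif)
    assert dist.total_snps > 0
    assert sum(dist.per_position_fractions) == pytest.approx(1.0, abs=1e-12)
    assert sum(dist.per_symbol_fractions.values()) == pytest.approx(1.0, abs=1e-12)
    # the two A positions (offsets 3 and 5) pool under symbol 'A'
    expected_a = dist.per_position_fractions[3] + dist.per_position_fractions[5]
    assert dist.per_symbol_fractions["A"] == pytest.approx(expected_a)
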