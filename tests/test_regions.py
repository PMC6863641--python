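"""rsid annotation, region intersection and AND/OR/SCORE set logic."""

import numpy as np
import pytest

from motifsnps.errors import ConfigError
from motifsnps.formats import GenomicRegion, SnpCatalogue, SnpLocus
from motifsnps.regions import (CombineMode, combine, lookup_rsids,
                               snps_in_regions)


def make_catalogue(entries):
    return SnpCatalogue(SnpLocus(c, p, r) for c, p, r in entries)


def test_lookup_rsids_annotates_and_reports_unmatched():
    catalogue = make_catalogue([("1", 1234, "rs42"), ("1", 99, "rs7")])
    annotated, unmatched = lookup_rsids(
        [("1", 1234), ("1", 500), ("chr1", 99)], catalogue)
    assert [(a.rsid, a.position) for a in annotated] == [("rs42", 1234), ("rs7", 99)]
    assert unmatched == [("1", 500)]


def test_lookup_rsids_fixture_truth_table():
    # ten planted positions, seven catalogued
    catalogue = make_catalogue([("1", p, f"rs{p}") for p in range(1, 8)])
    positions = [("1", p) for p in range(1, 11)]
    annotated, unmatched = lookup_rsids(positions, catalogue)
    assert len(annotated) == 7 and len(unmatched) == 3


def test_region_boundaries_are_inclusive():
    catalogue = make_catalogue([("1", 10, "rsA"), ("1", 12, "rsB"), ("1", 13, "rsC")])
    region = GenomicRegion("1", 10, 12, "r", 1.0)
    pairs = snps_in_regions(catalogue, [region])
    assert {locus.rsid for locus, _ in pairs} == {"rsA", "rsB"}


def test_overlapping_regions_yield_one_pair_each():
    catalogue = make_catalogue([("1", 15, "rsA")])
    r1 = GenomicRegion("1", 10, 20, "r1", 1.0)
    r2 = GenomicRegion("1", 12, 18, "r2", 5.0)
    pairs = snps_in_regions(catalogue, [r1, r2])
    assert [(l.rsid, r.name) for l, r in pairs] == [("rsA", "r1"), ("rsA", "r2")]


def test_snps_in_regions_equals_double_loop_oracle():
    rng = np.random.default_rng(5)
    loci = [("1", int(p), f"rs{i}") for i, p in
            enumerate(sorted(rng.choice(5_000, size=50, replace=False)), 1)]
    catalogue = make_catalogue(loci)
    regions = []
    for i in range(5):
        start = int(rng.integers(1, 4_500))
        regions.append(GenomicRegion("1", start, start + int(rng.integers(50, 500)),
                                     f"r{i}", float(i)))
    got = {(l.rsid, r.name) for l, r in snps_in_regions(catalogue, regions)}
    oracle = {(rsid, r.name) for _, p, rsid in loci for r in regions
              if r.start <= p <= r.end}
    assert got == oracle


# --- combine -------------------------------------------------------------

MOTIF = [SnpLocus("1", 10, "rs1"), SnpLocus("1", 20, "rs2")]
REGION = [
    (SnpLocus("1", 20, "rs2"), GenomicRegion("1", 15, 25, "hi", 5.0)),
    (SnpLocus("1", 30, "rs3"), GenomicRegion("1", 28, 35, "lo", 1.0)),
]


def rsids(candidates):
    return {c.rsid for c in candidates}


def test_combine_and_or():
    assert rsids(combine(MOTIF, REGION, CombineMode("AND"))) == {"rs2"}
    assert rsids(combine(MOTIF, REGION, CombineMode("OR"))) == {"rs1", "rs2", "rs3"}


@pytest.mark.parametrize("threshold,expected", [
    (2.0, {"rs2"}),            # rs3's score 1 is not strictly above 2
    (1.0, {"rs2"}),            # strictly-greater: score 1 at threshold 1 fails
    (0.0, {"rs2", "rs3"}),
])
def test_combine_score_threshold_is_strict(threshold, expected):
    got = combine([SnpLocus("1", 20, "rs2")], REGION,
                  CombineMode("SCORE", threshold))
    assert rsids(got) == expected


def test_score_mode_requires_threshold():
    with pytest.raises(ConfigError):
        CombineMode("SCORE")
    with pytest.raises(ConfigError):
        CombineMode("AND", 3.0)


def test_candidate_flags_scores_and_ordering():
    got = combine(MOTIF, REGION, CombineMode("OR"))
    by = {c.rsid: c for c in got}
    assert by["rs1"].in_motif and not by["rs1"].in_region
    assert by["rs2"].in_motif and by["rs2"].in_region
    assert by["rs2"].region_score == 5.0 and by["rs2"].source_region_name == "hi"
    assert not by["rs3"].in_motif and by["rs3"].in_region
    assert [c.position for c in got] == sorted(c.position for c in got)


def test_snp_in_multiple_regions_takes_max_score():
    pairs = [
        (SnpLocus("1", 20, "rs2"), GenomicRegion("1", 15, 25, "weak", 2.0)),
        (SnpLocus("1", 20, "rs2"), GenomicRegion("1", 18, 22, "strong", 9.0)),
    ]
    c, = combine([], pairs, CombineMode("SCORE", 5.0))
    assert c.region_score == 9.0 and c.source_region_name == "strong"
    assert combine([], pairs, CombineMode("SCORE", 9.0)) == []


def test_lattice_and_threshold_extremes():
    rng = np.random.default_rng(9)
    motif = [SnpLocus("1", int(p), f"rs{p}")
             for p in rng.choice(1000, 30, replace=False)]
    region = [(SnpLocus("1", int(p), f"rs{p}"),
               GenomicRegion("1", int(p), int(p) + 1, f"r{p}",
                             float(rng.integers(1, 10))))
              for p in rng.choice(1000, 30, replace=False)]
    and_set = rsids(combine(motif, region, CombineMode("AND")))
    or_set = rsids(combine(motif, region, CombineMode("OR")))
    scores = [r.score for _, r in region]
    for thr in (-1.0, 0.0, 3.0, 5.5, 20.0):
        score_set = rsids(combine(motif, region, CombineMode("SCORE", thr)))
        assert and_set <= score_set <= or_set
    assert rsids(combine(motif, region, CombineMode("SCORE", max(scores)))) == and_set
    all_region = {l.rsid for l, _ in region}
    assert rsids(combine(motif, region,
                         CombineMode("SCORE", min(scores) - 1))) == and_set | all_region
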