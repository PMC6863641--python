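"""Genotype intersection and LD-proxy selection."""

import itertools

from motifsnps.formats import GenotypedMarker, LdRecord
from motifsnps.ldproxy import (GenotypedPanel, find_proxies, resolve)
from motifsnps.regions import CandidateSnp


def ld(chrom, pos_a, pos_b, rs_a, rs_b, r2):
    return LdRecord(chrom, pos_a, pos_b, "CEU", rs_a, rs_b, 1.0, r2, 10.0)


def cand(rsid, pos=1000, chrom="1"):
    return CandidateSnp(rsid, chrom, pos, True, True, 5.0, "r")


def panel_of(*rsids):
    return GenotypedPanel([GenotypedMarker("1", r, 0.0, i + 1)
                           for i, r in enumerate(rsids)])


def test_find_proxies_searches_both_pair_members():
    records = [ld("1", 1000, 2000, "rs5", "rs7", 0.95),
               ld("1", 500, 1000, "rs2", "rs5", 0.80)]
    proxies = find_proxies(cand("rs5"), records, 0.8, panel_of())
    assert [(p.rsid, p.r2) for p in proxies] == [("rs7", 0.95), ("rs2", 0.80)]
    proxies = find_proxies(cand("rs5"), records, 0.9, panel_of())
    assert [(p.rsid, p.r2) for p in proxies] == [("rs7", 0.95)]


def test_find_proxies_threshold_is_inclusive():
    records = [ld("1", 1000, 2000, "rs5", "rs7", 0.8)]
    assert find_proxies(cand("rs5"), records, 0.8, panel_of())[0].rsid == "rs7"


def test_find_proxies_absent_candidate_gives_empty_list():
    records = [ld("1", 1, 2, "rsA", "rsB", 0.99)]
    assert find_proxies(cand("rs5"), records, 0.5, panel_of()) == []


def test_resolve_direct_skips_proxy_search():
    res = resolve([cand("rs5")], panel_of("rs5"),
                  {"1": [ld("1", 1000, 2000, "rs5", "rs7", 0.99)]}, 0.8)
    r, = res.resolutions
    assert r.status == "DIRECT" and r.proxy_rsid is None
    assert res.lddata_rows == [] and res.genotyped_lddata_rows == []


def test_resolve_picks_highest_r2_genotyped_proxy():
    records = [ld("1", 1000, 2000, "rs5", "rs7", 0.95),
               ld("1", 500, 1000, "rs2", "rs5", 0.80),
               ld("1", 1000, 3000, "rs5", "rs9", 0.99)]  # rs9 not genotyped
    res = resolve([cand("rs5")], panel_of("rs7", "rs2"), {"1": records}, 0.8)
    r, = res.resolutions
    assert (r.status, r.proxy_rsid, r.proxy_r2) == ("PROXY", "rs7", 0.95)
    # all qualifying proxies (even ungenotyped rs9) are logged
    assert {row[3] for row in res.lddata_rows} == {"rs2", "rs7", "rs9"}
    assert [row[3] for row in res.genotyped_lddata_rows] == ["rs7"]


def test_resolve_tie_breaks_distance_then_rsid_order_invariant():
    records = [ld("1", 1000, 11000, "rs5", "rs7", 0.90),   # 10 kb away
               ld("1", 1000, 3000, "rs5", "rs9", 0.90)]    # 2 kb away
    for perm in itertools.permutations(records):
        r, = resolve([cand("rs5")], panel_of("rs7", "rs9"),
                     {"1": list(perm)}, 0.8).resolutions
        assert (r.proxy_rsid, r.proxy_distance) == ("rs9", 2000)
    # equal r2 AND equal distance: lexicographically smallest rsid
    records = [ld("1", 1000, 3000, "rs5", "rsB", 0.90),
               ld("1", 1000, 3000, "rs5", "rsA", 0.90)]
    for perm in itertools.permutations(records):
        r, = resolve([cand("rs5")], panel_of("rsA", "rsB"),
                     {"1": list(perm)}, 0.8).resolutions
        assert r.proxy_rsid == "rsA"


def test_resolve_partition_and_unresolved():
    cands = [cand("rs1", 10), cand("rs2", 20), cand("rs3", 30)]
    records = [ld("1", 20, 99, "rs2", "rsP", 0.9)]
    res = resolve(cands, panel_of("rs1", "rsP"), {"1": records}, 0.8)
    counts = res.counts()
    assert counts == {"DIRECT": 1, "PROXY": 1, "UNRESOLVED": 1}
    assert sum(counts.values()) == len(cands)


def test_resolve_empty_panel_everything_enters_proxy_search():
    res = resolve([cand("rs1", 10)], panel_of(), {"1": []}, 0.8)
    assert res.resolutions[0].status == "UNRESOLVED"


def test_resolve_missing_chromosome_warns_and_unresolves(caplog):
    with caplog.at_level("WARNING", logger="motifsnps.ldproxy"):
        res = resolve([cand("rs1")], panel_of(), {}, 0.8)
    assert res.resolutions[0].status == "UNRESOLVED"
    assert any("no LD data" in rec.getMessage() for rec in caplog.records)


def test_duplicate_map_rsids_kept_once(caplog):
    with caplog.at_level("WARNING", logger="motifsnps.ldproxy"):
        panel = GenotypedPanel([GenotypedMarker("1", "rs1", 0.0, 5),
                                GenotypedMarker("1", "rs1", 0.0, 6)])
    assert len(panel) == 1 and "rs1" in panel
    assert any("duplicate" in rec.getMessage() for rec in caplog.records)


def test_no_proxy_below_threshold_no_unresolved_with_genotyped_proxy(std_fixture):
    """Brute-force re-check of resolution invariants over the fixture
    LD table."""
    from motifsnps.formats import read_ld, read_map
    out, truth, spec = std_fixture
    ld_tables = {c: read_ld(out / "ld" / f"ld_chr{c}.txt.gz", c)
                 for c in ("1", "2", "3")}
    genotyped = {m.rsid for m in read_map(out / "markers.map")}
    for row in truth.rows:
        if row.expected_status == "EXCLUDED":
            continue
        qualifying = [
            (rec.r2, got[0]) for rec in ld_tables[row.chrom]
            if (got := rec.partner_of(row.rsid)) is not None
            and rec.r2 >= spec.r2_threshold and got[0] in genotyped]
        if row.expected_status == "PROXY":
            assert row.best_proxy_r2 >= spec.r2_threshold
            assert qualifying
        elif row.expected_status == "UNRESOLVED":
            assert not qualifying
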