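"""Genotype intersection and LD-proxy resolution.

A candidate SNP that is present in the user's genotyped marker panel
is resolved DIRECT.  For the rest, the pairwise-LD table for its
chromosome is searched for genotyped proxies with r² at or above the
user threshold (a proxy exactly at the threshold qualifies).  Among
qualifying genotyped proxies the one with the highest r² is chosen;
ties break to the smallest bp distance from the candidate, then to the
lexicographically smallest rsid, so resolution is deterministic and
independent of LD-file record order.  A candidate with no genotype
and no qualifying genotyped proxy is UNRESOLVED.

Every qualifying proxy found (genotyped or not) is logged to
``lddata.txt``; the chosen genotyped proxies go to
``genotyped.lddata.txt``.  Proxies are only searched within the
candidate's own chromosome (LD tables are per-chromosome;
inter-chromosomal LD is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .formats import GenotypedMarker, LdRecord
from .regions import CandidateSnp

log = logging.getLogger(__name__)

DIRECT = "DIRECT"
PROXY = "PROXY"
UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class ProxyHit:
    """One qualifying LD partner of a candidate."""

    rsid: str
    r2: float
    distance: int
    position: int
    genotyped: bool


@dataclass(frozen=True)
class Resolution:
    """Final genotype status of one candidate SNP."""

    candidate: CandidateSnp
    status: str
    proxy_rsid: str | None = None
    proxy_r2: float | None = None
    proxy_distance: int | None = None


@dataclass
class ResolvedSet:
    """Resolutions plus the two proxy-log row streams the writers emit."""

    resolutions: list[Resolution] = field(default_factory=list)
    lddata_rows: list[tuple] = field(default_factory=list)
    genotyped_lddata_rows: list[tuple] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {DIRECT: 0, PROXY: 0, UNRESOLVED: 0}
        for r in self.resolutions:
            out[r.status] += 1
        return out


class GenotypedPanel:
    """O(1) rsid membership over the user's MAP file.

    Duplicate rsids are logged and the first occurrence kept.
    """

    def __init__(self, markers: list[GenotypedMarker]):
        self._markers: dict[str, GenotypedMarker] = {}
        for m in markers:
            if m.rsid in self._markers:
                log.warning("duplicate MAP rsid %s; keeping first entry", m.rsid)
                continue
            self._markers[m.rsid] = m

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._markers

    def __len__(self) -> int:
        return len(self._markers)


def find_proxies(candidate: CandidateSnp,
                 ld_records: list[LdRecord],
                 r2_threshold: float,
                 panel: GenotypedPanel) -> list[ProxyHit]:
    """All LD partners of *candidate* with r² >= threshold.

    The candidate may appear as either member of an LD pair.  Repeat
    partners keep their best row (highest r², then nearest).  The
    result is sorted best-first under the documented tie-break, so
    element 0 of the genotyped subset is the proxy to choose.
    """
    best: dict[str, ProxyHit] = {}
    for rec in ld_records:
        partner = rec.partner_of(candidate.rsid)
        if partner is None or rec.r2 < r2_threshold:
            continue
        rsid, pos = partner
        if rsid == candidate.rsid:
            continue
        hit = ProxyHit(rsid, rec.r2, abs(pos - candidate.position), pos,
                       rsid in panel)
        prev = best.get(rsid)
        if prev is None or (hit.r2, -hit.distance) > (prev.r2, -prev.distance):
            best[rsid] = hit
    return sorted(best.values(), key=lambda h: (-h.r2, h.distance, h.rsid))


def resolve(candidates: list[CandidateSnp],
            panel: GenotypedPanel,
            ld_by_chrom: dict[str, list[LdRecord]],
            r2_threshold: float) -> ResolvedSet:
    """Resolve every candidate to DIRECT, PROXY or UNRESOLVED.

    ``ld_by_chrom`` maps chromosome label to that chromosome's LD
    records; a missing chromosome is warned about once and treated as
    an empty table.
    """
    out = ResolvedSet()
    missing_warned: set[str] = set()
    for cand in candidates:
        if cand.rsid in panel:
            out.resolutions.append(Resolution(cand, DIRECT))
            continue
        records = ld_by_chrom.get(cand.chrom)
        if records is None:
            if cand.chrom not in missing_warned:
                log.warning("no LD data for chromosome %s; candidates there "
                            "cannot be proxied", cand.chrom)
                missing_warned.add(cand.chrom)
            records = []
        proxies = find_proxies(cand, records, r2_threshold, panel)
        for p in proxies:
            out.lddata_rows.append((cand.chrom, cand.rsid, cand.position,
                                    p.rsid, p.position, f"{p.r2:g}", p.distance))
        chosen = next((p for p in proxies if p.genotyped), None)
        if chosen is None:
            out.resolutions.append(Resolution(cand, UNRESOLVED))
        else:
            out.resolutions.append(Resolution(
                cand, PROXY, chosen.rsid, chosen.r2, chosen.distance))
            out.genotyped_lddata_rows.append(
                (cand.chrom, cand.rsid, cand.position, chosen.rsid,
                 chosen.position, f"{chosen.r2:g}", chosen.distance))
    return out
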