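"""Candidate-set construction: rsid annotation, region intersection,
and the AND/OR/SCORE combination logic.

Motif-SNP positions found by the scanner carry no marker IDs; they are
annotated against the SNP catalogue first.  Catalogue SNPs inside the
user's scored regions form the second list.  The two lists are then
combined by rsid under one of three modes:

``AND``
    SNPs in a motif *and* inside a region.
``OR``
    SNPs in a motif *or* inside a region.
``SCORE``
    the AND result, plus every region SNP whose best overlapping
    region score is strictly greater than a user threshold -- regions
    with strong experimental support survive even without a motif.

"Above the threshold" is strict (score > threshold); a SNP covered by
several regions takes the maximum score among them.  Set logic is
rsid-keyed because the downstream genotype match is rsid-keyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import ConfigError
from .formats import GenomicRegion, SnpCatalogue, SnpLocus

log = logging.getLogger(__name__)

MODES = ("AND", "OR", "SCORE")


@dataclass(frozen=True)
class CombineMode:
    """Combination mode with its (SCORE-only) threshold."""

    mode: str
    score_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"combine mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "SCORE" and self.score_threshold is None:
            raise ConfigError("SCORE mode requires a score threshold")
        if self.mode != "SCORE" and self.score_threshold is not None:
            raise ConfigError(f"{self.mode} mode takes no score threshold")


@dataclass(frozen=True)
class CandidateSnp:
    """A catalogue SNP selected by the set logic, with provenance."""

    rsid: str
    chrom: str
    position: int
    in_motif: bool
    in_region: bool
    region_score: float | None = None
    source_region_name: str = ""

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ConfigError("candidate SNPs must carry an rsid")
        if not (self.in_motif or self.in_region):
            raise ConfigError("candidate must be in a motif or a region")


def lookup_rsids(snp_positions, catalogue: SnpCatalogue):
    """Annotate (chrom, position) pairs with catalogue rsids.

    Returns ``(annotated, unmatched)``: annotated positions become
    :class:`SnpLocus` with their rsid; positions absent from the
    catalogue are returned separately and logged, never dropped
    silently.
    """
    annotated: list[SnpLocus] = []
    unmatched: list[tuple[str, int]] = []
    for chrom, position in snp_positions:
        rsid = catalogue.lookup(chrom, position)
        if rsid is None:
            unmatched.append((chrom, position))
            log.info("no catalogue rsid for SNP position %s:%d", chrom, position)
        else:
            annotated.append(SnpLocus(chrom, position, rsid))
    if unmatched:
        log.warning("%d SNP position(s) had no catalogue entry", len(unmatched))
    return annotated, unmatched


def snps_in_regions(catalogue: SnpCatalogue,
                    regions: list[GenomicRegion]) -> list[tuple[SnpLocus, GenomicRegion]]:
    """All (SNP, region) pairs with region.start <= position <= region.end.

    A SNP covered by k overlapping regions yields k pairs; each pair
    keeps its region's score.
    """
    pairs: list[tuple[SnpLocus, GenomicRegion]] = []
    for region in regions:
        for locus in catalogue.in_interval(region.chrom, region.start, region.end):
            pairs.append((locus, region))
    return pairs


def _chrom_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def combine(motif_snps: list[SnpLocus],
            region_pairs: list[tuple[SnpLocus, GenomicRegion]],
            mode: CombineMode) -> list[CandidateSnp]:
    """Combine the annotated motif list and the region pairs into the
    candidate set, sorted by (chromosome, position).

    Inputs are deduplicated by rsid before the set logic; a region SNP
    keeps the maximum score (and that region's name) among all regions
    covering it.
    """
    motif_by_rsid: dict[str, SnpLocus] = {}
    for locus in motif_snps:
        motif_by_rsid.setdefault(locus.rsid, locus)

    region_by_rsid: dict[str, tuple[SnpLocus, GenomicRegion]] = {}
    for locus, region in region_pairs:
        prev = region_by_rsid.get(locus.rsid)
        if prev is None or region.score > prev[1].score:
            region_by_rsid[locus.rsid] = (locus, region)

    motif_rsids = set(motif_by_rsid)
    region_rsids = set(region_by_rsid)
    if mode.mode == "AND":
        chosen = motif_rsids & region_rsids
    elif mode.mode == "OR":
        chosen = motif_rsids | region_rsids
    else:  # SCORE
        passing = {r for r in region_rsids
                   if region_by_rsid[r][1].score > mode.score_threshold}
        chosen = (motif_rsids & region_rsids) | passing

    candidates: list[CandidateSnp] = []
    for rsid in chosen:
        in_motif = rsid in motif_rsids
        in_region = rsid in region_rsids
        if in_region:
            locus, region = region_by_rsid[rsid]
            score, name = region.score, region.name
        else:
            locus, score, name = motif_by_rsid[rsid], None, ""
        candidates.append(CandidateSnp(
            rsid, locus.chrom, locus.position, in_motif, in_region, score, name))
    candidates.sort(key=lambda c: (_chrom_key(c.chrom), c.position))
    return candidates
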