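"""Deterministic synthetic-fixture generator with planted ground truth.

Real runs of this pipeline need a masked genome, a SNP catalogue, a
region file, a genotyped panel and per-chromosome LD tables that are
all mutually consistent -- gigabytes of downloads.  This module emits
a toy version of all six inputs from a single seeded specification,
together with a machine-readable truth table, so that every pipeline
stage is testable end to end.

What the generator emulates: IUPAC-masked chromosomes with a
background SNP rate (optionally elevated inside regions), planted
motif occurrences at known positions of which a chosen fraction carry
exactly one SNP, scored regions, a catalogue covering a configurable
subset of mask positions, a genotyped subset of the catalogue, and a
prescribed pairwise-LD table realising known best-proxy answers.

What it does not emulate: coalescent LD structure, allele
frequencies, mutation-rate heterogeneity, or genome-scale repeat
content.  The LD table is prescribed, not simulated.

The background sequence is actively scrubbed of accidental motif
occurrences (both strands, degenerate matching, mask codes included)
so planted-recovery assertions can be exact: the scanner must find
exactly the planted windows and nothing else.  A fixed seed gives
byte-identical output directories (gzip timestamps are pinned).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import FixtureError, FixtureValidationError
from .formats import (GenomicRegion, GenotypedMarker, LdRecord, MaskedSequence,
                      SnpCatalogue, SnpLocus, read_bed, read_hapmap, read_ld,
                      read_map, read_masked_fasta, write_bed, write_fasta,
                      write_hapmap, write_ld, write_map, write_motif)
from .iupac import EXPANSION, SNP_CODES, MotifPattern, reverse_complement
from .scanner import match_start_arrays

log = logging.getLogger(__name__)

_BASES = "ACGT"
_AMBIG = {frozenset(v): k for k, v in EXPANSION.items()}

EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generator needs; a fixed seed fixes every byte."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 50_000
    motif: str | None = "AGGTCA"
    motif_label: str = "fixture-motif"
    background_snp_rate: float = 0.002
    region_snp_rate_multiplier: float = 1.0
    n_planted_motifs: int = 30
    fraction_with_snp: float = 0.5
    fraction_planted_in_regions: float = 0.5
    n_regions: int = 9
    region_length: int = 1_000
    region_score_low: int = 1
    region_score_high: int = 10
    catalogue_fraction: float = 0.9
    genotyped_fraction: float = 0.5
    r2_threshold: float = 0.8
    combine_mode: str = "AND"
    population: str = "CEU"
    #: optional explicit proxy plan: candidate rsid -> [(partner rsid, r2)];
    #: None selects the automatic policy described in generate().
    ld_proxy_spec: tuple | None = None


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted motif-SNP."""

    chrom: str
    position: int
    rsid: str
    motif_start: int
    motif_offset: int
    region_name: str
    region_score: float | None
    in_catalogue: bool
    genotyped: bool
    best_proxy_rsid: str
    best_proxy_r2: float | None
    expected_status: str      # DIRECT | PROXY | UNRESOLVED | EXCLUDED


@dataclass
class TruthTable:
    """All truth rows plus the conditions they were derived under."""

    rows: list[TruthRow]
    combine_mode: str
    r2_threshold: float
    n_planted_motifs: int = 0

    def expected_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.rows:
            out[r.expected_status] = out.get(r.expected_status, 0) + 1
        return out


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _split_count(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def _sample_nonoverlapping(rng, n: int, length: int, limit: int,
                           gap: int, forbidden: list[tuple[int, int]],
                           inside: tuple[int, int] | None = None) -> list[int]:
    """Sample n non-overlapping 0-based starts for windows of *length*.

    Keeps *gap* bases clear between sampled windows, avoids the
    *forbidden* intervals entirely, and (optionally) stays strictly
    inside one interval.
    """
    lo, hi = (0, limit - length) if inside is None else (inside[0], inside[1] - length + 1)
    if hi < lo:
        raise FixtureError("window does not fit in the allotted interval")
    starts: list[int] = []
    for _ in range(10_000):
        if len(starts) == n:
            return starts
        s = int(rng.integers(lo, hi + 1))
        if any(s < e + gap and s + length + gap > b for b, e in forbidden):
            continue
        if any(s < t + length + gap and s + length + gap > t for t in starts):
            continue
        starts.append(s)
    raise FixtureError(f"could not place {n} windows of length {length}")


def _break_window(seq: np.ndarray, s: int, motif: MotifPattern,
                  protected: np.ndarray, rng) -> bool:
    """Mutate one unprotected base of window [s, s+L) so that it no
    longer matches the motif in either orientation.  Returns success."""
    L = len(motif)
    rc = reverse_complement(motif)
    order = list(rng.permutation(L))
    for j in order:
        p = s + j
        if protected[p]:
            continue
        fwd_set = EXPANSION[motif.sequence[j]]
        rev_set = EXPANSION[rc.sequence[j]]
        both = [b for b in _BASES if b not in fwd_set and b not in rev_set]
        one = [b for b in _BASES if b not in fwd_set] or \
              [b for b in _BASES if b not in rev_set]
        pool = both or one
        if not pool:
            continue  # motif symbol is n in both orientations here
        seq[p] = ord(pool[int(rng.integers(len(pool)))])
        return True
    return False


def _scrub(seq: np.ndarray, motif: MotifPattern, planted: set[int],
           protected: np.ndarray, rng,
           revertable: dict[int, int] | None = None,
           removed: set[int] | None = None) -> None:
    """Remove every non-planted motif occurrence from *seq* in place.

    Preference order per accidental window: revert a background SNP
    code inside it to its reference base (``revertable`` maps position
    to reference byte; reverting only ever shrinks the match set),
    else mutate an unprotected base.  Raises when no progress is
    possible.
    """
    for _ in range(500):
        fwd, rev = match_start_arrays(seq, motif)
        accidental = [int(s) for s in np.nonzero(fwd | rev)[0] if int(s) not in planted]
        if not accidental:
            return
        for s in accidental:
            L = len(motif)
            handled = False
            if revertable:
                inside = [p for p in range(s, s + L) if p in revertable]
                if inside:
                    p = inside[int(rng.integers(len(inside)))]
                    seq[p] = revertable.pop(p)
                    if removed is not None:
                        removed.add(p)
                    handled = True
            if not handled and not _break_window(seq, s, motif, protected, rng):
                raise FixtureError(
                    f"cannot exclude motif {motif.sequence} from background "
                    f"around position {s}")
    raise FixtureError("motif scrubbing did not converge")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: FixtureSpec, out_dir) -> TruthTable:
    """Generate the six mutually consistent input files plus truth.tsv.

    Layout under *out_dir*: ``fasta/chr<k>.fa``, ``ld/ld_chr<k>.txt.gz``,
    ``regions.bed``, ``hapmap.txt``, ``markers.map``, ``motif.txt`` and
    ``truth.tsv``.

    Automatic LD policy (when ``ld_proxy_spec`` is None): every
    ungenotyped candidate receives 0-3 LD partners drawn from other
    SNPs on its chromosome, with r² values scattered around the
    threshold (including exactly at it, the boundary case), an
    occasional tied-r² pair to exercise the distance tie-break, and
    decoy rows between non-candidate markers.
    """
    if spec.motif is None and spec.n_planted_motifs:
        raise FixtureError("cannot plant motifs without a motif pattern")
    rng = np.random.default_rng(spec.seed)
    motif = MotifPattern(spec.motif, spec.motif_label) if spec.motif else None
    L = len(motif) if motif else 0

    out_dir = Path(out_dir)
    (out_dir / "fasta").mkdir(parents=True, exist_ok=True)
    (out_dir / "ld").mkdir(exist_ok=True)

    regions_per_chrom = _split_count(spec.n_regions, spec.n_chromosomes)
    motifs_per_chrom = _split_count(spec.n_planted_motifs, spec.n_chromosomes)

    all_regions: list[GenomicRegion] = []
    # per-SNP records: (chrom, pos0, kind, motif_start0, offset, region_idx)
    snp_records: list[dict] = []
    sequences: list[MaskedSequence] = []

    for ci in range(spec.n_chromosomes):
        chrom = str(ci + 1)
        Lc = spec.chrom_length
        seq = rng.integers(0, 4, Lc)
        seq = np.frombuffer("".join(_BASES[i] for i in seq).encode(), np.uint8).copy()

        # regions
        region_starts = _sample_nonoverlapping(
            rng, regions_per_chrom[ci], spec.region_length, Lc,
            gap=max(2 * L + 4, 20), forbidden=[])
        chrom_regions: list[GenomicRegion] = []
        for ri, r0 in enumerate(sorted(region_starts)):
            score = float(rng.integers(spec.region_score_low,
                                       spec.region_score_high + 1))
            chrom_regions.append(GenomicRegion(
                chrom, r0 + 1, r0 + spec.region_length,
                f"region_{chrom}_{ri}", score))
        all_regions.extend(chrom_regions)

        planted_starts: list[tuple[int, GenomicRegion | None]] = []
        protected = np.zeros(Lc, dtype=bool)
        if motif:
            n_m = motifs_per_chrom[ci]
            n_in = int(round(spec.fraction_planted_in_regions * n_m))
            region_ivs = [(r.start - 1, r.end - 1) for r in chrom_regions]
            # inside regions, cycling through them
            taken: list[int] = []
            for k in range(n_in):
                region = chrom_regions[k % len(chrom_regions)]
                s = _sample_nonoverlapping(
                    rng, 1, L, Lc, gap=L + 2,
                    forbidden=[(t, t + L - 1) for t in taken],
                    inside=(region.start - 1, region.end - 1))[0]
                taken.append(s)
                planted_starts.append((s, region))
            # outside every region
            for _ in range(n_m - n_in):
                s = _sample_nonoverlapping(
                    rng, 1, L, Lc, gap=L + 2,
                    forbidden=[(t, t + L - 1) for t in taken] +
                              [(b, e) for b, e in region_ivs])[0]
                taken.append(s)
                planted_starts.append((s, None))
            planted_starts.sort(key=lambda t: t[0])

            # write realizations
            for s, _region in planted_starts:
                for j, sym in enumerate(motif.sequence):
                    pool = sorted(EXPANSION[sym])
                    seq[s + j] = ord(pool[int(rng.integers(len(pool)))])
                protected[s:s + L] = True

            planted_set = {s for s, _ in planted_starts}
            _scrub(seq, motif, planted_set, protected, rng)

            # plant exactly one SNP in a chosen fraction of the motifs
            n_snp = int(round(spec.fraction_with_snp * len(planted_starts)))
            which = sorted(rng.permutation(len(planted_starts))[:n_snp])
            for idx in which:
                s, region = planted_starts[idx]
                off = int(rng.integers(L))
                ref = chr(seq[s + off])
                alt = rng.permutation([b for b in _BASES if b != ref])[0]
                seq[s + off] = ord(_AMBIG[frozenset({ref, alt})])
                snp_records.append(dict(
                    chrom=chrom, pos0=s + off, kind="motif",
                    motif_start0=s, offset=off, region=region))
            _scrub(seq, motif, planted_set, protected, rng)

        # background SNPs (regions may carry an elevated rate)
        rate = np.full(Lc, spec.background_snp_rate)
        for r in chrom_regions:
            rate[r.start - 1:r.end] = (spec.background_snp_rate *
                                       spec.region_snp_rate_multiplier)
        rate[protected] = 0.0
        draw = rng.random(Lc) < rate
        bg_positions = [int(p) for p in np.nonzero(draw)[0]]
        revertable: dict[int, int] = {}
        for p in bg_positions:
            ref = chr(seq[p])
            if ref not in _BASES:      # N never generated, but stay safe
                continue
            alt = [b for b in _BASES if b != ref][int(rng.integers(3))]
            revertable[p] = seq[p]
            seq[p] = ord(_AMBIG[frozenset({ref, alt})])
        removed: set[int] = set()
        if motif:
            _scrub(seq, motif, {s for s, _ in planted_starts}, protected, rng,
                   revertable=revertable, removed=removed)
        for p in bg_positions:
            if p in removed:
                continue
            region = next((r for r in chrom_regions
                           if r.start - 1 <= p <= r.end - 1), None)
            snp_records.append(dict(chrom=chrom, pos0=p, kind="background",
                                    motif_start0=None, offset=None,
                                    region=region))

        sequences.append(MaskedSequence(chrom, seq.tobytes().decode()))
        write_fasta([sequences[-1]], out_dir / "fasta" / f"chr{chrom}.fa")

    # ------------------------------------------------------------------
    # rsids, catalogue, panel
    # ------------------------------------------------------------------
    snp_records.sort(key=lambda r: (int(r["chrom"]), r["pos0"]))
    for i, rec in enumerate(snp_records):
        rec["rsid"] = f"rs{i + 1:05d}"
        rec["in_catalogue"] = bool(rng.random() < spec.catalogue_fraction)
    for rec in snp_records:
        rec["genotyped"] = bool(rec["in_catalogue"] and
                                rng.random() < spec.genotyped_fraction)

    catalogue = SnpCatalogue(
        SnpLocus(r["chrom"], r["pos0"] + 1, r["rsid"])
        for r in snp_records if r["in_catalogue"])
    write_hapmap(catalogue, out_dir / "hapmap.txt")
    write_bed(all_regions, out_dir / "regions.bed")
    if motif:
        write_motif(motif, out_dir / "motif.txt")
    markers = [GenotypedMarker(r["chrom"], r["rsid"], 0.0, r["pos0"] + 1)
               for r in snp_records if r["genotyped"]]
    write_map(markers, out_dir / "markers.map")

    # ------------------------------------------------------------------
    # LD tables
    # ------------------------------------------------------------------
    def is_candidate(rec) -> bool:
        if rec["kind"] != "motif" or not rec["in_catalogue"]:
            return False
        if spec.combine_mode == "OR":
            return True
        return rec["region"] is not None     # AND, SCORE both need the region

    by_rsid = {r["rsid"]: r for r in snp_records}
    candidates = [r for r in snp_records if is_candidate(r)]
    candidate_rsids = {r["rsid"] for r in candidates}
    ld_rows: dict[str, list[LdRecord]] = {str(c + 1): []
                                          for c in range(spec.n_chromosomes)}

    def add_ld(chrom: str, rec_a, rec_b, r2: float) -> None:
        pa, pb = rec_a["pos0"] + 1, rec_b["pos0"] + 1
        ra, rb = rec_a["rsid"], rec_b["rsid"]
        if pa > pb:
            pa, pb, ra, rb = pb, pa, rb, ra
        elif pa == pb:
            return
        r2 = round(min(max(r2, 0.01), 1.0), 3)
        ld_rows[chrom].append(LdRecord(
            chrom, pa, pb, spec.population, ra, rb,
            round(min(1.0, r2 + 0.05), 3), r2, round(r2 * 15 + 2, 2)))

    if spec.ld_proxy_spec is not None:
        for cand_rsid, partner_rsid, r2 in spec.ld_proxy_spec:
            a, b = by_rsid[cand_rsid], by_rsid[partner_rsid]
            if a["chrom"] != b["chrom"]:
                raise FixtureError("LD pairs must be intra-chromosomal")
            add_ld(a["chrom"], a, b, r2)
    else:
        offsets = np.array([-0.2, -0.1, 0.0, 0.05, 0.1, 0.15])
        for cand in candidates:
            if cand["genotyped"]:
                continue
            chrom = cand["chrom"]
            pool = [r for r in snp_records
                    if r["chrom"] == chrom and r["rsid"] != cand["rsid"]]
            if not pool:
                continue
            k = int(rng.integers(0, 4))
            picks = [pool[int(i)] for i in
                     rng.choice(len(pool), size=min(k, len(pool)), replace=False)]
            chosen_r2 = [float(spec.r2_threshold + offsets[int(i)])
                         for i in rng.integers(0, len(offsets), len(picks))]
            for partner, r2 in zip(picks, chosen_r2):
                add_ld(chrom, cand, partner, r2)
            # occasionally duplicate the top r2 with another partner so the
            # distance tie-break is exercised
            if picks and rng.random() < 0.3:
                others = [r for r in pool if r not in picks]
                if others:
                    extra = others[int(rng.integers(len(others)))]
                    add_ld(chrom, cand, extra, max(chosen_r2))
        # decoy rows among non-candidate markers
        for chrom in ld_rows:
            pool = [r for r in snp_records
                    if r["chrom"] == chrom and r["rsid"] not in candidate_rsids]
            for _ in range(10):
                if len(pool) < 2:
                    break
                i, j = rng.choice(len(pool), size=2, replace=False)
                add_ld(chrom, pool[int(i)], pool[int(j)],
                       float(rng.uniform(0.05, 1.0)))

    for chrom, rows in ld_rows.items():
        rows.sort(key=lambda r: (r.pos_a, r.pos_b, r.rsid_a, r.rsid_b))
        write_ld(rows, out_dir / "ld" / f"ld_chr{chrom}.txt.gz")

    # ------------------------------------------------------------------
    # truth table: best genotyped proxy recomputed from the emitted LD
    # table by plain loops (construction truth)
    # ------------------------------------------------------------------
    rows: list[TruthRow] = []
    for rec in (r for r in snp_records if r["kind"] == "motif"):
        status, best_rsid, best_r2 = EXCLUDED, "", None
        if is_candidate(rec):
            if rec["genotyped"]:
                status = "DIRECT"
            else:
                partners: dict[str, tuple[float, int]] = {}
                for ld in ld_rows[rec["chrom"]]:
                    got = ld.partner_of(rec["rsid"])
                    if got is None or ld.r2 < spec.r2_threshold:
                        continue
                    prsid, ppos = got
                    dist = abs(ppos - (rec["pos0"] + 1))
                    prev = partners.get(prsid)
                    if prev is None or (ld.r2, -dist) > (prev[0], -prev[1]):
                        partners[prsid] = (ld.r2, dist)
                genotyped = [(r2, d, prsid) for prsid, (r2, d) in partners.items()
                             if by_rsid[prsid]["genotyped"]]
                if genotyped:
                    best = min(genotyped, key=lambda t: (-t[0], t[1], t[2]))
                    status, best_rsid, best_r2 = "PROXY", best[2], best[0]
                else:
                    status = "UNRESOLVED"
        region = rec["region"]
        rows.append(TruthRow(
            rec["chrom"], rec["pos0"] + 1, rec["rsid"],
            rec["motif_start0"] + 1, rec["offset"],
            region.name if region else "",
            region.score if region else None,
            rec["in_catalogue"], rec["genotyped"],
            best_rsid, best_r2, status))

    truth = TruthTable(rows, spec.combine_mode, spec.r2_threshold,
                       spec.n_planted_motifs)
    write_truth(truth, out_dir / "truth.tsv")
    return truth


# ---------------------------------------------------------------------------
# truth table serialisation
# ---------------------------------------------------------------------------

_TRUTH_HEADER = ("chrom", "position", "rsid", "motif_start", "motif_offset",
                 "region_name", "region_score", "in_catalogue", "genotyped",
                 "best_proxy_rsid", "best_proxy_r2", "expected_status")


def write_truth(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# combine_mode={truth.combine_mode}\t"
                 f"r2_threshold={truth.r2_threshold:g}\t"
                 f"n_planted_motifs={truth.n_planted_motifs}\n")
        fh.write("# " + "\t".join(_TRUTH_HEADER) + "\n")
        for r in truth.rows:
            fh.write("\t".join([
                r.chrom, str(r.position), r.rsid, str(r.motif_start),
                str(r.motif_offset), r.region_name or ".",
                "." if r.region_score is None else f"{r.region_score:g}",
                "1" if r.in_catalogue else "0",
                "1" if r.genotyped else "0",
                r.best_proxy_rsid or ".",
                "." if r.best_proxy_r2 is None else f"{r.best_proxy_r2:g}",
                r.expected_status]) + "\n")


def read_truth(path) -> TruthTable:
    rows: list[TruthRow] = []
    mode, thr, n_planted = "AND", 0.8, 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# combine_mode="):
                fields = dict(f.split("=", 1) for f in line[2:].split("\t"))
                mode = fields["combine_mode"]
                thr = float(fields["r2_threshold"])
                n_planted = int(fields.get("n_planted_motifs", 0))
                continue
            if not line or line.startswith("#"):
                continue
            c = line.split("\t")
            rows.append(TruthRow(
                c[0], int(c[1]), c[2], int(c[3]), int(c[4]),
                "" if c[5] == "." else c[5],
                None if c[6] == "." else float(c[6]),
                c[7] == "1", c[8] == "1",
                "" if c[9] == "." else c[9],
                None if c[10] == "." else float(c[10]),
                c[11]))
    return TruthTable(rows, mode, thr, n_planted)


# ---------------------------------------------------------------------------
# self-validation
# ---------------------------------------------------------------------------

def validate(out_dir, truth: TruthTable) -> None:
    """Cross-check every truth row against the emitted files.

    Checks: the mask code is present at the stated position, the
    catalogue row exists iff in_catalogue, region containment matches,
    MAP membership matches the genotyped flag, and the recorded best
    proxy has a supporting LD row at the recorded r².  Any mismatch
    raises :class:`FixtureValidationError` listing the offending rows.
    """
    out_dir = Path(out_dir)
    seqs = {rec.chrom: rec
            for p in sorted((out_dir / "fasta").glob("*.fa"))
            for rec in read_masked_fasta(p)}
    catalogue = read_hapmap(out_dir / "hapmap.txt")
    regions = {r.name: r for r in read_bed(out_dir / "regions.bed")}
    genotyped = {m.rsid for m in read_map(out_dir / "markers.map")}
    ld: dict[str, list[LdRecord]] = {}
    for p in sorted((out_dir / "ld").glob("ld_chr*.txt.gz")):
        chrom = p.name[len("ld_chr"):-len(".txt.gz")]
        ld[chrom] = read_ld(p, chrom)

    problems: list[str] = []
    for row in truth.rows:
        seq = seqs.get(row.chrom)
        if seq is None or len(seq) < row.position:
            problems.append(f"{row.rsid}: chromosome {row.chrom} missing/short")
            continue
        if seq.seq[row.position - 1] not in SNP_CODES:
            problems.append(f"{row.rsid}: no SNP mask code at "
                            f"{row.chrom}:{row.position}")
        got = catalogue.lookup(row.chrom, row.position)
        if row.in_catalogue and got != row.rsid:
            problems.append(f"{row.rsid}: catalogue row missing or wrong ({got})")
        if not row.in_catalogue and got is not None:
            problems.append(f"{row.rsid}: unexpected catalogue row {got}")
        if row.region_name:
            region = regions.get(row.region_name)
            if region is None or not region.contains(row.chrom, row.position):
                problems.append(f"{row.rsid}: region {row.region_name} does not "
                                f"contain {row.chrom}:{row.position}")
        else:
            covering = [r for r in regions.values()
                        if r.contains(row.chrom, row.position)]
            if covering:
                problems.append(f"{row.rsid}: unexpectedly inside {covering[0].name}")
        if row.genotyped != (row.rsid in genotyped):
            problems.append(f"{row.rsid}: MAP membership != genotyped flag")
        if row.best_proxy_rsid:
            support = any(
                (got := rec.partner_of(row.rsid)) is not None
                and got[0] == row.best_proxy_rsid
                and abs(rec.r2 - (row.best_proxy_r2 or -1)) < 1e-9
                for rec in ld.get(row.chrom, []))
            if not support:
                problems.append(f"{row.rsid}: no LD row supports proxy "
                                f"{row.best_proxy_rsid}@{row.best_proxy_r2}")
    if problems:
        raise FixtureValidationError(
            "fixture/truth mismatch:\n  " + "\n  ".join(problems))
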