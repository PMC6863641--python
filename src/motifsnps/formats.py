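"""Readers and writers for every file dialect the pipeline touches.

Input side: SNP-masked per-chromosome FASTA, BED-style region files
(3-5 columns), three-column HapMap SNP catalogues, one-motif text
files, four-column PLINK-style MAP files, and gzipped HapMap-dialect
pairwise-LD files.  Output side: the four literal result files the
resolver produces plus write counterparts for each input dialect (the
synthetic-fixture generator uses those, and they give cheap
round-trip guarantees).

Coordinate conventions: BED input is standard 0-based half-open and is
converted on read to 1-based inclusive, which is what every other file
here (HapMap positions, MAP positions, LD positions, FASTA offsets)
already uses.  Chromosome labels are normalised by stripping an
optional ``chr`` prefix, because public catalogues mix ``chr1`` and
``1`` across releases.

There is no way to verify that the FASTA and the SNP catalogue come
from the same genome build; a prominent warning restates that the user
must guarantee it.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from .errors import FormatError
from .iupac import EXPANSION, SNP_CODES, MotifPattern

if TYPE_CHECKING:  # pragma: no cover
    from .ldproxy import ResolvedSet

log = logging.getLogger(__name__)

_IUPAC_SET = frozenset(EXPANSION)

#: Literal names of the four result files.
OUT_MAIN = "ReMo.SNPs.out"
OUT_UNRESOLVED = "list.of.markers.with.no.genotype.and.no.proxy.out"
OUT_LDDATA = "lddata.txt"
OUT_GENOTYPED_LDDATA = "genotyped.lddata.txt"


def normalize_chrom(label: str) -> str:
    """Strip an optional 'chr' prefix; 'chr1' and '1' compare equal."""
    label = label.strip()
    if label.lower().startswith("chr"):
        return label[3:]
    return label


def warn_build_consistency() -> None:
    """Log the build-consistency caveat the tool cannot check itself."""
    log.warning(
        "Cannot verify genome builds: it is absolutely crucial that the "
        "masked FASTA files and the SNP catalogue are based on the same "
        "genome build -- the tool has no way to check this."
    )


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskedSequence:
    """One chromosome of SNP-masked sequence (uppercase IUPAC)."""

    chrom: str
    seq: str

    def snp_positions(self) -> list[int]:
        """1-based positions whose symbol is a SNP mask code."""
        return [i + 1 for i, c in enumerate(self.seq) if c in SNP_CODES]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicRegion:
    """A scored interval of interest, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"region {self.chrom}:{self.start}-{self.end}: start > end")
        if self.score < 0:
            raise FormatError(f"region {self.name or self.chrom}: negative score")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, position: int) -> bool:
        return chrom == self.chrom and self.start <= position <= self.end


@dataclass(frozen=True)
class SnpLocus:
    """A catalogued SNP: chromosome, 1-based position, marker ID."""

    chrom: str
    position: int
    rsid: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"SNP position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class GenotypedMarker:
    """One line of a PLINK-style MAP file."""

    chrom: str
    rsid: str
    genetic_distance: float
    position: int


@dataclass(frozen=True)
class LdRecord:
    """One pairwise-LD entry from a HapMap bulk-LD file."""

    chrom: str
    pos_a: int
    pos_b: int
    population: str
    rsid_a: str
    rsid_b: str
    dprime: float
    r2: float
    lod: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0:
            raise FormatError(f"r2 out of [0,1]: {self.r2}")
        if not 0.0 <= self.dprime <= 1.0:
            raise FormatError(f"D' out of [0,1]: {self.dprime}")

    def partner_of(self, rsid: str) -> tuple[str, int] | None:
        """(partner rsid, partner position) if *rsid* is one member."""
        if rsid == self.rsid_a:
            return self.rsid_b, self.pos_b
        if rsid == self.rsid_b:
            return self.rsid_a, self.pos_a
        return None


class SnpCatalogue:
    """HapMap-style SNP catalogue with O(log n) positional lookup.

    Duplicate (chrom, position) entries keep the first rsid seen and
    log a warning.
    """

    def __init__(self, loci: Iterable[SnpLocus] = ()) -> None:
        self._rsids: dict[tuple[str, int], str] = {}
        self._positions: dict[str, list[int]] = {}
        staged: dict[str, list[int]] = {}
        for locus in loci:
            key = (locus.chrom, locus.position)
            if key in self._rsids:
                log.warning(
                    "duplicate catalogue entry at %s:%d (%s); keeping first (%s)",
                    locus.chrom, locus.position, locus.rsid, self._rsids[key])
                continue
            self._rsids[key] = locus.rsid
            staged.setdefault(locus.chrom, []).append(locus.position)
        for chrom, positions in staged.items():
            self._positions[chrom] = sorted(positions)

    def __len__(self) -> int:
        return len(self._rsids)

    def chromosomes(self) -> list[str]:
        return sorted(self._positions)

    def lookup(self, chrom: str, position: int) -> str | None:
        """rsid at (chrom, position), or None when absent."""
        return self._rsids.get((normalize_chrom(chrom), position))

    def in_interval(self, chrom: str, start: int, end: int) -> list[SnpLocus]:
        """All catalogue SNPs with start <= position <= end (1-based)."""
        chrom = normalize_chrom(chrom)
        positions = self._positions.get(chrom, [])
        lo = bisect_left(positions, start)
        hi = bisect_right(positions, end)
        return [SnpLocus(chrom, p, self._rsids[(chrom, p)]) for p in positions[lo:hi]]

    def loci(self) -> Iterator[SnpLocus]:
        for chrom in self.chromosomes():
            for p in self._positions[chrom]:
                yield SnpLocus(chrom, p, self._rsids[(chrom, p)])

    def count(self, chrom: str | None = None) -> int:
        if chrom is None:
            return len(self._rsids)
        return len(self._positions.get(normalize_chrom(chrom), []))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_masked_fasta(path) -> list[MaskedSequence]:
    """Read a SNP-masked FASTA file (one or more records).

    Sequence is uppercased; the chromosome label is the first
    whitespace-delimited header token, 'chr' prefix stripped.  Any
    character outside the IUPAC alphabet is a format error naming the
    file, line and character.
    """
    path = Path(path)
    records: list[MaskedSequence] = []
    chrom: str | None = None
    parts: list[str] = []

    def flush() -> None:
        if chrom is not None:
            records.append(MaskedSequence(chrom, "".join(parts)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                token = line[1:].split()
                if not token:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                chrom = normalize_chrom(token[0])
                parts = []
            else:
                if chrom is None:
                    raise FormatError(f"{path}:{lineno}: sequence before any header")
                up = line.upper()
                bad = set(up) - _IUPAC_SET
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC character {sorted(bad)[0]!r}")
                parts.append(up)
    flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def read_bed(path) -> list[GenomicRegion]:
    """Read a 3-5 column BED file into 1-based inclusive regions.

    BED coordinates are 0-based half-open; a line ``chrom 9 12`` means
    bases 10..12 in 1-based inclusive space.  A missing score defaults
    to 1, a missing name to the empty string.
    """
    path = Path(path)
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if not 3 <= len(cols) <= 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 3-5 columns, got {len(cols)}")
            try:
                start0, end0 = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinate") from exc
            if start0 >= end0:
                raise FormatError(
                    f"{path}:{lineno}: empty or inverted interval {start0}-{end0}")
            name = cols[3] if len(cols) >= 4 else ""
            if len(cols) == 5:
                try:
                    score = float(cols[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            else:
                score = 1.0
            regions.append(GenomicRegion(
                normalize_chrom(cols[0]), start0 + 1, end0, name, score))
    return regions


def read_hapmap(path) -> SnpCatalogue:
    """Read a three-column SNP catalogue (chrom, position, rsid)."""
    path = Path(path)
    loci: list[SnpLocus] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            try:
                position = int(cols[1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric position") from exc
            loci.append(SnpLocus(normalize_chrom(cols[0]), position, cols[2]))
    return SnpCatalogue(loci)


def read_map(path) -> list[GenotypedMarker]:
    """Read a PLINK-style MAP file: exactly four columns per line."""
    path = Path(path)
    markers: list[GenotypedMarker] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 4:
                raise FormatError(
                    f"{path}:{lineno}: MAP lines must contain exactly four "
                    f"columns, got {len(cols)}")
            try:
                cm = float(cols[2])
                position = int(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            markers.append(GenotypedMarker(
                normalize_chrom(cols[0]), cols[1], cm, position))
    return markers


def read_ld(path, chrom: str) -> list[LdRecord]:
    """Read a gzipped HapMap bulk-LD file for one chromosome.

    Line dialect: ``pos_a pos_b population rsid_a rsid_b D' r2 LOD``.
    The chromosome is not on the line; it comes from the filename
    convention, so the caller passes it in.
    """
    path = Path(path)
    chrom = normalize_chrom(chrom)
    records: list[LdRecord] = []
    try:
        with gzip.open(path, "rt") as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split()
                if len(cols) != 8:
                    raise FormatError(
                        f"{path}:{lineno}: expected 8 columns, got {len(cols)}")
                try:
                    pos_a, pos_b = int(cols[0]), int(cols[1])
                    dprime, r2, lod = float(cols[5]), float(cols[6]), float(cols[7])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
                if pos_a >= pos_b:
                    raise FormatError(f"{path}:{lineno}: pos_a must be < pos_b")
                try:
                    records.append(LdRecord(
                        chrom, pos_a, pos_b, cols[2], cols[3], cols[4],
                        dprime, r2, lod))
                except FormatError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from exc
    except gzip.BadGzipFile as exc:
        raise OSError(f"{path}: not a gzip file") from exc
    return records


def read_motif(path) -> MotifPattern:
    """Read a motif file: exactly one IUPAC pattern, optional label.

    The first non-empty, non-comment line is the pattern; an optional
    second token on the same line is taken as the label.  More than
    one pattern line is a format error (one motif per file).
    """
    path = Path(path)
    pattern: MotifPattern | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if pattern is not None:
                raise FormatError(
                    f"{path}:{lineno}: only one motif per file is allowed")
            cols = line.split()
            label = cols[1] if len(cols) > 1 else path.stem
            try:
                pattern = MotifPattern(cols[0], label=label)
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if pattern is None:
        raise FormatError(f"{path}: no motif found")
    return pattern


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[MaskedSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">chr{rec.chrom}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def write_bed(regions: Iterable[GenomicRegion], path) -> None:
    """Write regions back out as 0-based half-open BED (5 columns)."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(f"chr{r.chrom}\t{r.start - 1}\t{r.end}\t{r.name or '.'}\t{score}\n")


def write_hapmap(catalogue: SnpCatalogue, path) -> None:
    with open(path, "w") as fh:
        for locus in catalogue.loci():
            fh.write(f"chr{locus.chrom}\t{locus.position}\t{locus.rsid}\n")


def write_map(markers: Iterable[GenotypedMarker], path) -> None:
    with open(path, "w") as fh:
        for m in markers:
            cm = int(m.genetic_distance) if float(m.genetic_distance).is_integer() \
                else m.genetic_distance
            fh.write(f"{m.chrom}\t{m.rsid}\t{cm}\t{m.position}\n")


def write_ld(records: Iterable[LdRecord], path) -> None:
    """Write LD records gzipped; mtime pinned to 0 so identical record
    streams give byte-identical files."""
    with open(path, "wb") as raw:
        with gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz:
            for r in records:
                line = (f"{r.pos_a} {r.pos_b} {r.population} {r.rsid_a} "
                        f"{r.rsid_b} {r.dprime:g} {r.r2:g} {r.lod:g}\n")
                gz.write(line.encode())


def write_motif(motif: MotifPattern, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{motif.sequence}\t{motif.label}\n" if motif.label
                 else f"{motif.sequence}\n")


# ---------------------------------------------------------------------------
# result files
# ---------------------------------------------------------------------------

def write_outputs(resolved: "ResolvedSet", out_dir) -> dict[str, Path]:
    """Write the four literal result files of a long run.

    ``ReMo.SNPs.out``
        every candidate resolved directly or through a genotyped
        proxy; one row per *tested* rsid (if several candidates share
        a proxy, their provenance is concatenated on one row).
    ``list.of.markers.with.no.genotype.and.no.proxy.out``
        candidates with no genotype and no qualifying genotyped proxy.
    ``lddata.txt``
        every qualifying proxy found (genotyped or not).
    ``genotyped.lddata.txt``
        the chosen genotyped proxy per proxied candidate.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "main": out_dir / OUT_MAIN,
        "unresolved": out_dir / OUT_UNRESOLVED,
        "lddata": out_dir / OUT_LDDATA,
        "genotyped_lddata": out_dir / OUT_GENOTYPED_LDDATA,
    }

    def source_of(candidate) -> str:
        if candidate.in_motif and candidate.in_region:
            return "both"
        return "motif" if candidate.in_motif else "region"

    # group resolved rows by the rsid actually tested
    grouped: dict[str, list] = {}
    order: list[str] = []
    for res in resolved.resolutions:
        if res.status == "UNRESOLVED":
            continue
        tested = res.candidate.rsid if res.status == "DIRECT" else res.proxy_rsid
        if tested not in grouped:
            grouped[tested] = []
            order.append(tested)
        grouped[tested].append(res)

    with open(paths["main"], "w") as fh:
        fh.write("# rsid_tested\tchrom\tposition\tsource\tresolution\t"
                 "original_rsid\tproxy_r2\n")
        for tested in order:
            group = grouped[tested]
            first = group[0]
            source = ",".join(dict.fromkeys(source_of(r.candidate) for r in group))
            resolution = ",".join(dict.fromkeys(
                "direct" if r.status == "DIRECT" else "proxy" for r in group))
            originals = ",".join(dict.fromkeys(r.candidate.rsid for r in group))
            r2s = ",".join(f"{r.proxy_r2:g}" for r in group if r.status == "PROXY")
            fh.write(f"{tested}\t{first.candidate.chrom}\t"
                     f"{first.candidate.position}\t{source}\t{resolution}\t"
                     f"{originals}\t{r2s or '.'}\n")

    with open(paths["unresolved"], "w") as fh:
        fh.write("# rsid\tchrom\tposition\tsource\n")
        for res in resolved.resolutions:
            if res.status != "UNRESOLVED":
                continue
            c = res.candidate
            fh.write(f"{c.rsid}\t{c.chrom}\t{c.position}\t{source_of(c)}\n")

    with open(paths["lddata"], "w") as fh:
        fh.write("# chrom\tcandidate_rsid\tcandidate_pos\tproxy_rsid\t"
                 "proxy_pos\tr2\tdistance\n")
        for row in resolved.lddata_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    with open(paths["genotyped_lddata"], "w") as fh:
        fh.write("# chrom\tcandidate_rsid\tcandidate_pos\tproxy_rsid\t"
                 "proxy_pos\tr2\tdistance\n")
        for row in resolved.genotyped_lddata_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    return paths
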