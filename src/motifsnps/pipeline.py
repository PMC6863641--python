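"""Seven-step pipeline wiring: scan, annotate, intersect, combine,
panel intersection, LD-proxy resolution, output.

Run modes mirror the tool's three use cases:

``long`` (default)
    all seven steps; produces the four result files and is the mode
    used to prepare markers for an association study.
``medium``
    steps 1-4 plus a report of multi-SNP motifs (possible low-quality
    sequence) with their rsids; stops before any genotype data is
    read.
``short``
    steps 1-4, writing the SNPs located in motifs and in regions to
    two separate files plus the descriptive statistics report.

Medium and short runs never open the MAP or LD files.  Outputs for a
given configuration are deterministic; the run log (file handler uses
no timestamps) is byte-identical across reruns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import density as density_mod
from .errors import ConfigError
from .formats import (GenomicRegion, SnpCatalogue, read_bed, read_hapmap,
                      read_ld, read_map, read_masked_fasta, read_motif,
                      warn_build_consistency, write_outputs)
from .iupac import MotifPattern
from .ldproxy import GenotypedPanel, ResolvedSet, resolve
from .regions import CombineMode, combine, lookup_rsids, snps_in_regions
from .scanner import MotifHit, ScanStats, collect_stats, scan_chromosome, warn_multi_snp

log = logging.getLogger(__name__)

RUN_MODES = ("long", "medium", "short")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    fasta_dir: Path
    motif_file: Path
    bed_file: Path
    hapmap_file: Path
    out_dir: Path
    map_file: Path | None = None
    ld_dir: Path | None = None
    run_mode: str = "long"
    combine_mode: str = "AND"
    score_threshold: float | None = None
    r2_threshold: float = 0.8
    chromosomes: tuple[str, ...] | None = None
    merge_regions: bool = False

    def validate(self) -> None:
        if self.run_mode not in RUN_MODES:
            raise ConfigError(f"run mode must be one of {RUN_MODES}")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ConfigError("r2 threshold must be in (0, 1]")
        CombineMode(self.combine_mode, self.score_threshold)  # range-checks
        for label, path in (("fasta dir", self.fasta_dir),
                            ("motif file", self.motif_file),
                            ("BED file", self.bed_file),
                            ("HapMap file", self.hapmap_file)):
            if path is None or not Path(path).exists():
                raise ConfigError(f"{label} not found: {path}")
        if self.run_mode == "long":
            if self.map_file is None or not Path(self.map_file).exists():
                raise ConfigError(f"long run needs a MAP file: {self.map_file}")
            if self.ld_dir is None or not Path(self.ld_dir).exists():
                raise ConfigError(f"long run needs an LD directory: {self.ld_dir}")


@dataclass
class RunResult:
    """Everything a run computed, plus the files it wrote."""

    counts: dict[str, int]
    stats: ScanStats | None
    density_report: density_mod.DensityReport | None
    nucleotide: density_mod.NucleotideDistribution | None
    candidates: list = field(default_factory=list)
    resolved: ResolvedSet | None = None
    output_paths: dict[str, Path] = field(default_factory=dict)
    hits: list[MotifHit] = field(default_factory=list)


def _fasta_files(fasta_dir: Path) -> list[Path]:
    files = sorted(p for p in Path(fasta_dir).iterdir()
                   if p.suffix in (".fa", ".fasta", ".fna"))
    if not files:
        raise ConfigError(f"no FASTA files in {fasta_dir}")
    return files


def _ld_path(ld_dir: Path, chrom: str) -> Path:
    """Per-chromosome LD filename convention: ld_chr<label>.txt.gz."""
    return Path(ld_dir) / f"ld_chr{chrom}.txt.gz"


def _merge_for_density(regions: list[GenomicRegion]) -> list[GenomicRegion]:
    """Union of overlapping intervals per chromosome (opt-in for the
    density denominator only)."""
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[GenomicRegion] = []
    for chrom, rs in sorted(by_chrom.items()):
        rs.sort(key=lambda r: r.start)
        cur_start, cur_end = rs[0].start, rs[0].end
        for r in rs[1:]:
            if r.start <= cur_end + 1:
                cur_end = max(cur_end, r.end)
            else:
                merged.append(GenomicRegion(chrom, cur_start, cur_end))
                cur_start, cur_end = r.start, r.end
        merged.append(GenomicRegion(chrom, cur_start, cur_end))
    return merged


def log_summary(counts: dict[str, int], sink: logging.Logger = log) -> str:
    """Render the per-step tally block; identical rerun, identical block."""
    lines = ["run summary:"]
    for key in ("motif_positions", "motif_snps_annotated", "region_snps",
                "candidates", "direct", "proxy", "unresolved"):
        if key in counts:
            lines.append(f"  {key:<22s} {counts[key]}")
    block = "\n".join(lines)
    sink.info("%s", block)
    return block


def run(config: RunConfig) -> RunResult:
    """Execute the configured run and write its outputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    file_handler = logging.FileHandler(out_dir / "run.log", mode="w")
    file_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("motifsnps")
    root.addHandler(file_handler)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(file_handler)
        file_handler.close()


def _run(config: RunConfig, out_dir: Path) -> RunResult:
    warn_build_consistency()
    motif = read_motif(config.motif_file)
    catalogue = read_hapmap(config.hapmap_file)
    regions = read_bed(config.bed_file)
    wanted = set(config.chromosomes) if config.chromosomes else None
    if wanted is not None:
        regions = [r for r in regions if r.chrom in wanted]

    # step 1: scan every chromosome, one at a time
    hits: list[MotifHit] = []
    stats: ScanStats | None = None
    genome_length = 0
    scanned: list[str] = []
    for path in _fasta_files(config.fasta_dir):
        for record in read_masked_fasta(path):
            if wanted is not None and record.chrom not in wanted:
                continue
            chrom_hits = scan_chromosome(record, motif)
            stats = collect_stats(chrom_hits, len(motif), stats)
            hits.extend(chrom_hits)
            genome_length += len(record)
            scanned.append(record.chrom)
            log.info("step 1: chromosome %s: %d motif hits over %d bp",
                     record.chrom, len(chrom_hits), len(record))
    if stats is None:
        stats = collect_stats([], len(motif))
    n_warnings = warn_multi_snp(stats)
    log.info("step 1: %d motif occurrence(s), %d with SNPs, %d multi-SNP warning(s)",
             stats.motifs_total, stats.motifs_with_snps, n_warnings)

    # step 2: rsids for motif-SNP positions (deduplicated by position)
    positions = sorted({(h.chrom, p) for h in hits for p in h.snp_positions})
    motif_snps, unmatched = lookup_rsids(positions, catalogue)
    log.info("step 2: %d motif-SNP position(s), %d annotated, %d absent "
             "from the catalogue", len(positions), len(motif_snps), len(unmatched))

    # step 3: catalogue SNPs inside the scored regions
    region_pairs = snps_in_regions(catalogue, regions)
    region_rsids = {locus.rsid for locus, _ in region_pairs}
    log.info("step 3: %d (SNP, region) pair(s) over %d region(s)",
             len(region_pairs), len(regions))

    # step 4: combine
    mode = CombineMode(config.combine_mode, config.score_threshold)
    candidates = combine(motif_snps, region_pairs, mode)
    log.info("step 4: %d candidate SNP(s) under %s", len(candidates), mode.mode)

    counts = {
        "motif_positions": len(positions),
        "motif_snps_annotated": len(motif_snps),
        "region_snps": len(region_rsids),
        "candidates": len(candidates),
    }

    # statistics report (all modes)
    density_regions = _merge_for_density(regions) if config.merge_regions else regions
    n_catalogue = sum(catalogue.count(c) for c in set(scanned))
    report = density_mod.build_density_report(
        n_region_snps=len(region_rsids),
        regions=density_regions,
        n_motif_snps=len(motif_snps),
        motif_length=len(motif),
        n_motifs=stats.motifs_total,
        n_catalogue_snps=n_catalogue,
        genome_length=genome_length,
    ) if genome_length else None
    nucleotide = density_mod.nucleotide_distribution(hits, motif)
    paths: dict[str, Path] = {}
    if report is not None:
        paths.update(_write_stats_report(out_dir, motif, stats, report, nucleotide))

    result = RunResult(counts, stats, report, nucleotide,
                       candidates=candidates, output_paths=paths, hits=hits)

    if config.run_mode == "medium":
        paths["multi_snp"] = _write_multi_snp_report(out_dir, stats, catalogue)
        log_summary(counts)
        return result
    if config.run_mode == "short":
        paths["motif_snps"] = out_dir / "motif.snps.out"
        with open(paths["motif_snps"], "w") as fh:
            fh.write("# rsid\tchrom\tposition\n")
            for locus in motif_snps:
                fh.write(f"{locus.rsid}\t{locus.chrom}\t{locus.position}\n")
        paths["region_snps"] = out_dir / "region.snps.out"
        with open(paths["region_snps"], "w") as fh:
            fh.write("# rsid\tchrom\tposition\tregion\tscore\n")
            for locus, region in region_pairs:
                fh.write(f"{locus.rsid}\t{locus.chrom}\t{locus.position}\t"
                         f"{region.name or '.'}\t{region.score:g}\n")
        log_summary(counts)
        return result

    # step 5: genotyped panel
    panel = GenotypedPanel(read_map(config.map_file))
    log.info("step 5: %d genotyped marker(s) in the panel", len(panel))

    # step 6: LD-proxy resolution, per chromosome
    ld_by_chrom = {}
    for chrom in sorted({c.chrom for c in candidates}):
        path = _ld_path(config.ld_dir, chrom)
        if path.exists():
            ld_by_chrom[chrom] = read_ld(path, chrom)
        # a missing file is handled (with a warning) inside resolve()
    resolved = resolve(candidates, panel, ld_by_chrom, config.r2_threshold)
    res_counts = resolved.counts()
    counts.update(direct=res_counts["DIRECT"], proxy=res_counts["PROXY"],
                  unresolved=res_counts["UNRESOLVED"])
    log.info("step 6: %d direct, %d proxied, %d unresolved",
             counts["direct"], counts["proxy"], counts["unresolved"])

    # step 7: the four result files
    paths.update(write_outputs(resolved, out_dir))
    result.resolved = resolved
    log_summary(counts)
    return result


def _write_multi_snp_report(out_dir: Path, stats: ScanStats,
                            catalogue: SnpCatalogue) -> Path:
    """Medium run: rsids of the potentially problematic multi-SNP motifs."""
    path = out_dir / "multi.snp.motifs.out"
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tn_snps\trsids\n")
        for hit in stats.multi_snp_hits:
            rsids = [catalogue.lookup(hit.chrom, p) or "."
                     for p in hit.snp_positions]
            fh.write(f"{hit.chrom}\t{hit.start}\t{hit.end}\t{hit.n_snps}\t"
                     f"{','.join(rsids)}\n")
            log.info("multi-SNP motif %s:%d-%d carries %s",
                     hit.chrom, hit.start, hit.end, ",".join(rsids))
    return path


def _write_stats_report(out_dir: Path, motif: MotifPattern, stats: ScanStats,
                        report: density_mod.DensityReport,
                        nucleotide: density_mod.NucleotideDistribution,
                        ) -> dict[str, Path]:
    txt = out_dir / "statistics.report.txt"
    tsv = out_dir / "statistics.tsv"

    def pct(x: float | None) -> str:
        return "n/a" if x is None else f"{100 * x:.4f}%"

    with open(txt, "w") as fh:
        fh.write(f"motif {motif.sequence} ({motif.label})\n")
        fh.write(f"motif occurrences          {stats.motifs_total}\n")
        fh.write(f"occurrences with SNPs      {stats.motifs_with_snps}\n")
        hist = ", ".join(f"{k}:{v}" for k, v in sorted(stats.histogram.items()))
        fh.write(f"SNPs-per-motif histogram   {hist}\n")
        fh.write(f"per-position SNP counts    "
                 f"{', '.join(map(str, stats.per_position_counts))}\n")
        if not nucleotide.no_data:
            fracs = ", ".join(f"{f:.4f}" for f in nucleotide.per_position_fractions)
            fh.write(f"per-position SNP fraction  {fracs}\n")
            sym = ", ".join(f"{s}:{f:.4f}"
                            for s, f in sorted(nucleotide.per_symbol_fractions.items()))
            fh.write(f"per-symbol SNP fraction    {sym}\n")
        else:
            fh.write("per-position SNP fraction  no data (zero SNPs)\n")
        fh.write(f"region SNP density         {pct(report.region_density)}\n")
        fh.write(f"motif SNP density          {pct(report.motif_density)}\n")
        fh.write(f"genome SNP density         {pct(report.genome_density)}\n")
        for name, chi in (("region", report.chi2_region_vs_genome),
                          ("motif", report.chi2_motif_vs_genome)):
            if chi is not None:
                fh.write(f"chi-square {name} vs genome  "
                         f"stat={chi[0]:.4f} p={chi[1]:.3g}\n")

    with open(tsv, "w") as fh:
        fh.write("# key\tvalue\n")
        fh.write(f"motifs_total\t{stats.motifs_total}\n")
        fh.write(f"motifs_with_snps\t{stats.motifs_with_snps}\n")
        for k, v in sorted(stats.histogram.items()):
            fh.write(f"histogram_{k}\t{v}\n")
        for i, c in enumerate(stats.per_position_counts):
            fh.write(f"position_count_{i}\t{c}\n")
        for i, f in enumerate(nucleotide.per_position_fractions):
            fh.write(f"position_fraction_{i}\t{f:.12g}\n")
        for key, value in (("region_density", report.region_density),
                           ("motif_density", report.motif_density),
                           ("genome_density", report.genome_density)):
            fh.write(f"{key}\t{'' if value is None else f'{value:.12g}'}\n")
        for name, chi in (("region", report.chi2_region_vs_genome),
                          ("motif", report.chi2_motif_vs_genome)):
            if chi is not None:
                fh.write(f"chi2_{name}_vs_genome_stat\t{chi[0]:.12g}\n")
                fh.write(f"chi2_{name}_vs_genome_p\t{chi[1]:.12g}\n")
    return {"stats_txt": txt, "stats_tsv": tsv}
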