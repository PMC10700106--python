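"""End-to-end recombinant analysis: homology map -> SNP typing -> breakpoints.

`analyze_recombinants` is the in-memory entry point; `run_pipeline` wraps it
with file I/O, logging, and report writing for the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .breakpoints import (
    CrossoverInterval,
    FlipflopTract,
    LandmarkError,
    ModuleEstimate,
    OriginBlock,
    RecombinantReport,
    call_crossover_intervals,
    classify_architecture,
    detect_flipflops,
    estimate_modules,
    genome_length_delta,
    segment_origins,
)
from .homology import HomologyRegion, find_homology_regions, regions_to_tsv
from .io_formats import GenomeInterval, GenomeRecord, read_fasta, write_bed
from .origin_typing import (
    OriginCall,
    PlacementError,
    SnpPanel,
    build_snp_panel,
    calls_to_tsv,
    extract_informative_sites,
    genotype_sites,
    locate_region_in_recombinant,
)
from .pcr import read_primer_panel, run_panel, type_plaque

logger = logging.getLogger(__name__)


@dataclass
class RecombinantAnalysis:
    """Report plus the raw per-region calls behind it."""

    report: RecombinantReport
    calls: dict[str, list[OriginCall]]


def analyze_recombinant(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    regions: Sequence[HomologyRegion],
    rec: GenomeRecord,
    max_tract_sites: int = 3,
    min_identity: float = 60.0,
) -> RecombinantAnalysis:
    """Type one recombinant against the parental homology map."""
    calls_per_region: dict[str, list[OriginCall]] = {}
    blocks_per_region: list[list[OriginBlock]] = []
    crossovers: dict[str, list[CrossoverInterval]] = {}
    flipflops: dict[str, list[FlipflopTract]] = {}
    placements = []
    n_novel = n_missing = 0
    unreliable: list[str] = []

    for region in regions:
        sites = extract_informative_sites(region)
        placement = locate_region_in_recombinant(region, rec, min_identity=min_identity)
        placements.append(placement)
        calls = genotype_sites(sites, placement, rec, region)
        calls_per_region[region.region_id] = calls
        novel = sum(1 for c in calls if c.origin == "novel")
        n_novel += novel
        n_missing += sum(1 for c in calls if c.origin == "missing")
        if calls and novel > len(calls) / 2:
            unreliable.append(region.region_id)
            logger.warning(
                "region %s in %s: >50%% novel calls — unreliable", region.region_id, rec.id
            )
        blocks = segment_origins(calls)
        blocks_per_region.append(blocks)
        crossovers[region.region_id] = call_crossover_intervals(blocks)
        flipflops[region.region_id] = detect_flipflops(blocks, max_tract_sites)

    architecture = classify_architecture(
        blocks_per_region, placements, list(regions), parent_a, parent_b, rec, max_tract_sites
    )

    modules: ModuleEstimate | None = None
    module_error: str | None = None
    if len(regions) >= 2:
        try:
            modules = estimate_modules(
                calls_per_region[regions[0].region_id],
                calls_per_region[regions[1].region_id],
            )
        except LandmarkError as exc:
            module_error = str(exc)
            logger.warning("%s: %s", rec.id, exc)

    report = RecombinantReport(
        recombinant_id=rec.id,
        architecture=architecture,
        genome_delta=genome_length_delta(parent_a, rec),
        blocks={r.region_id: b for r, b in zip(regions, blocks_per_region)},
        crossovers=crossovers,
        flipflops=flipflops,
        modules=modules,
        n_novel=n_novel,
        n_missing=n_missing,
        error=module_error,
        unreliable_regions=unreliable,
    )
    return RecombinantAnalysis(report=report, calls=calls_per_region)


def analyze_recombinants(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    recombinants: Sequence[GenomeRecord],
    min_aligned_len: int = 300,
    min_identity: float = 60.0,
    max_tract_sites: int = 3,
) -> tuple[list[HomologyRegion], list[RecombinantAnalysis], dict[str, str]]:
    """Full in-memory pipeline; per-recombinant failures do not stop the rest.

    Returns the homology map, one analysis per typed recombinant, and a map of
    recombinant id -> error message for those that could not be typed.
    """
    regions = find_homology_regions(parent_a, parent_b, min_aligned_len, min_identity)
    analyses = []
    errors: dict[str, str] = {}
    for rec in recombinants:
        try:
            analyses.append(
                analyze_recombinant(parent_a, parent_b, regions, rec, max_tract_sites, min_identity)
            )
        except PlacementError as exc:
            errors[rec.id] = str(exc)
            logger.error("%s: %s", rec.id, exc)
    return regions, analyses, errors


def module_table_tsv(reports: Sequence[RecombinantReport]) -> str:
    """Donor/replaced module table; recombinants without an A-B-A module
    estimate are omitted (their reports carry the explanation)."""
    lines = ["recombinant\tdonor_module_bp\treplaced_module_bp\tdifference_bp"]
    for rep in reports:
        if rep.modules is not None:
            m = rep.modules
            lines.append(f"{rep.recombinant_id}\t{m.donor_len}\t{m.replaced_len}\t{m.delta}")
    return "\n".join(lines) + "\n"


@dataclass
class PipelineConfig:
    parent_a_path: str
    parent_b_path: str
    recombinant_paths: list[str]
    out_dir: str
    min_aligned_len: int = 300
    min_identity: float = 60.0
    max_tract_sites: int = 3
    primer_panel_path: str | None = None
    log_level: str = "INFO"


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write reports under ``cfg.out_dir``.

    Outputs: homology TSV + per-parent BEDs, per-region SNP panels, per
    recombinant a JSON report, origin-call TSV and crossover/flipflop BEDs, a
    module table in donor/replaced/difference layout, optional PCR typing
    TSV, and a provenance log. Returns a summary dict; per-recombinant errors
    are recorded and do not stop other recombinants.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=cfg.log_level)
    fh = logging.FileHandler(out / "pipeline.log", mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phagemosaic")
    root.addHandler(fh)
    try:
        logger.info("phagemosaic %s", __version__)
        logger.info(
            "thresholds: min_aligned_len=%d min_identity=%.1f max_tract_sites=%d",
            cfg.min_aligned_len, cfg.min_identity, cfg.max_tract_sites,
        )
        for path in [cfg.parent_a_path, cfg.parent_b_path, *cfg.recombinant_paths]:
            logger.info("input %s sha256=%s", path, _sha256(path))

        (parent_a,) = read_fasta(cfg.parent_a_path)[:1]
        (parent_b,) = read_fasta(cfg.parent_b_path)[:1]
        recombinants = []
        for path in cfg.recombinant_paths:
            recombinants.extend(read_fasta(path))

        regions, analyses, errors = analyze_recombinants(
            parent_a, parent_b, recombinants,
            cfg.min_aligned_len, cfg.min_identity, cfg.max_tract_sites,
        )

        _write_atomic(out / "homology_regions.tsv", regions_to_tsv(regions))
        write_bed([r.interval_a for r in regions], out / "regions_parentA.bed")
        write_bed([r.interval_b for r in regions], out / "regions_parentB.bed")

        typed = [r for r in recombinants if r.id not in errors]
        for region in regions:
            panel = build_snp_panel(
                region, parent_a, parent_b, typed, min_identity=cfg.min_identity
            )
            _write_atomic(out / f"snp_panel_{region.region_id}.tsv", panel.to_tsv())
            _write_atomic(out / f"snp_panel_{region.region_id}.txt", panel.to_text())

        reports = []
        for analysis in analyses:
            rep = analysis.report
            reports.append(rep)
            rid = rep.recombinant_id
            _write_atomic(out / f"{rid}.report.json", json.dumps(rep.to_dict(), indent=2) + "\n")
            all_calls = [c for calls in analysis.calls.values() for c in calls]
            _write_atomic(out / f"{rid}.calls.tsv", calls_to_tsv(all_calls))
            xo_intervals = [
                GenomeInterval(rid, x.left_pos_rec + 1, x.right_pos_rec - 1,
                               f"{x.region_id}:{x.left_origin}->{x.right_origin}")
                for xs in rep.crossovers.values() for x in xs if x.width > 0
            ]
            write_bed(xo_intervals, out / f"{rid}.crossovers.bed")
            ff_intervals = [
                GenomeInterval(rid, t.block.rec_span.start, t.block.rec_span.end,
                               f"{t.region_id}:flipflop-{t.block.origin}")
                for ts in rep.flipflops.values() for t in ts
            ]
            write_bed(ff_intervals, out / f"{rid}.flipflops.bed")
            if rep.modules is None:
                logger.warning("%s: no module estimate (architecture %s)", rid, rep.architecture)

        _write_atomic(out / "module_table.tsv", module_table_tsv(reports))

        if cfg.primer_panel_path:
            panel = read_primer_panel(cfg.primer_panel_path)
            lines = ["genome\ttype"]
            for rec in [parent_a, parent_b, *recombinants]:
                results = run_panel(rec, panel)
                lines.append(f"{rec.id}\t{type_plaque(results, panel)}")
            _write_atomic(out / "pcr_typing.tsv", "\n".join(lines) + "\n")

        return {
            "regions": regions,
            "reports": reports,
            "errors": errors,
            "out_dir": str(out),
        }
    finally:
        root.removeHandler(fh)
        fh.close()
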