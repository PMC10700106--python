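#!/usr/bin/env python
"""Validate the pipeline against the deposited Butters/Island3/BIB genomes.

Requires network access to NCBI (or a directory of pre-downloaded FASTA
files named <accession>.fasta). Downloads Butters (KC576783), Island3
(HM152765) and the nine BIB recombinants, then checks the published
genome-scale facts:

- every BIB is 2,762 bp shorter than Butters, and the estimated module
  delta (replaced - donor) equals that same 2,762 bp;
- BIB1's modules are 8,797 bp donor / 11,559 bp replaced;
- donor modules across all BIBs range from 6,722 to 8,854 bp;
- the two homology regions localize within 150 bp of the published
  coordinates (Butters 21,825-23,917 / Island3 25,302-27,409 and
  Butters 33,050-35,516 / Island3 33,774-35,854);
- an allele-specific typing panel designed at the published 1,367 bp
  product size amplifies each BIB once and neither parent.

Usage:
    python examples/validate_accessions.py [--cache-dir accessions]
"""

import argparse
import sys
import urllib.request
from pathlib import Path

from phagemosaic import (
    analyze_recombinant,
    design_typing_panel,
    find_homology_regions,
    genome_length_delta,
    predict_amplicons,
    read_fasta,
    write_fasta,
)

EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&rettype=fasta&retmode=text&id={acc}"
)

PARENT_A = "KC576783"  # Butters
PARENT_B = "HM152765"  # Island3
BIBS = {
    "BIB1": "OP961731", "BIB2": "OP961730", "BIB3": "OP961729",
    "BIB4": "OP961728", "BIB6": "OP961727", "BIB7": "OP961726",
    "BIB8": "OP961725", "BIB9": "OP961724", "BIB10": "OP961723",
}

PUBLISHED_REGIONS = [  # (a_start, a_end, b_start, b_end)
    (21825, 23917, 25302, 27409),
    (33050, 35516, 33774, 35854),
]


def fetch(acc: str, cache_dir: Path):
    path = cache_dir / f"{acc}.fasta"
    if not path.exists():
        print(f"downloading {acc} ...")
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            data = resp.read()
        path.write_bytes(data)
    (record,) = read_fasta(path, source="accession")
    return record


def check(label: str, ok: bool, detail: str = "") -> bool:
    print(f"  [{'ok' if ok else 'FAIL'}] {label}" + (f": {detail}" if detail else ""))
    return ok


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cache-dir", type=Path, default=Path("accessions"))
    args = ap.parse_args()
    args.cache_dir.mkdir(parents=True, exist_ok=True)

    try:
        butters = fetch(PARENT_A, args.cache_dir)
        island3 = fetch(PARENT_B, args.cache_dir)
        bibs = {name: fetch(acc, args.cache_dir) for name, acc in BIBS.items()}
    except OSError as exc:
        sys.exit(f"could not fetch accessions (offline?): {exc}")

    all_ok = True

    print("\n== homology regions vs published coordinates ==")
    regions = find_homology_regions(butters, island3)
    all_ok &= check("two regions found", len(regions) == 2, f"found {len(regions)}")
    for region, pub in zip(regions, PUBLISHED_REGIONS):
        got = (region.interval_a.start, region.interval_a.end,
               region.interval_b.start, region.interval_b.end)
        worst = max(abs(g - p) for g, p in zip(got, pub))
        all_ok &= check(
            f"{region.region_id} within 150 bp of published",
            worst <= 150,
            f"got {got}, published {pub}, max deviation {worst} bp "
            f"(ANI {region.ani:.1f}%)",
        )

    print("\n== per-BIB module estimates ==")
    donors = {}
    for name, bib in sorted(bibs.items()):
        analysis = analyze_recombinant(butters, island3, regions, bib)
        report = analysis.report
        delta = genome_length_delta(butters, bib)
        ok = (
            report.modules is not None
            and report.modules.delta == delta == 2762
        )
        detail = (
            f"donor {report.modules.donor_len:,} / replaced "
            f"{report.modules.replaced_len:,} / delta {report.modules.delta:,}"
            if report.modules
            else f"module estimation failed: {report.error}"
        )
        all_ok &= check(f"{name}: delta == len(Butters) - len(rec) == 2,762",
                        ok, detail)
        if report.modules:
            donors[name] = report.modules.donor_len
            if name == "BIB1":
                all_ok &= check(
                    "BIB1 modules are 8,797 / 11,559",
                    (report.modules.donor_len, report.modules.replaced_len)
                    == (8797, 11559),
                )
    if donors:
        lo, hi = min(donors.values()), max(donors.values())
        all_ok &= check("donor modules span 6,722-8,854 bp",
                        (lo, hi) == (6722, 8854), f"got {lo:,}-{hi:,}")

    print("\n== in-silico PCR typing at the published 1,367 bp product ==")
    # Reconstruct a typing panel from region 1 at the published product size.
    # design_typing_panel expects a co-linear (substitution-only) region, so
    # only alignment columns with zero net indel shift count as diagnostic
    # offsets; the crossover offset comes from BIB1's called interval.
    region1 = regions[0]
    bib1 = analyze_recombinant(butters, island3, regions, bibs["BIB1"])
    (xo,) = bib1.report.crossovers[region1.region_id]
    xo_offset = xo.left.site.pos_a - region1.interval_a.start + 1

    class ColinearRegion:
        a_start = region1.interval_a.start
        b_start = region1.interval_b.start
        length = min(region1.interval_a.length, region1.interval_b.length)
        pos_a_cols, pos_b_cols = region1.column_positions()
        diff_offsets = tuple(
            pa - region1.interval_a.start + 1
            for ca, cb, pa, pb in zip(
                region1.row_a, region1.row_b, pos_a_cols, pos_b_cols
            )
            if ca != cb and pa and pb
            and pa - region1.interval_a.start == pb - region1.interval_b.start
        )

    panel = design_typing_panel(butters, island3, ColinearRegion(), xo_offset)
    bib_pair = next(p for p in panel if p.target_type == "BIB")
    for name, genome in [("Butters", butters), ("Island3", island3)] + sorted(bibs.items()):
        amps = predict_amplicons(genome, bib_pair)
        if name in bibs:
            all_ok &= check(
                f"{name}: single BIB-specific product",
                len(amps) == 1,
                f"sizes {[a.size for a in amps]} "
                f"(published primer pair product: 1,367 bp)",
            )
        else:
            all_ok &= check(f"{name}: no BIB-specific product", not amps)

    print("\nall checks passed" if all_ok else "\nSOME CHECKS FAILED")
    sys.exit(0 if all_ok else 1)


if __name__ == "__main__":
    main()
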