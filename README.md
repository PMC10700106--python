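# phagemosaic

Breakpoint mapping of double-recombinant bacteriophage genomes.

When a phage infects a bacterium that already carries a related prophage, a
double homologous recombination between the two genomes can produce a viable
chimera: the infecting phage's backbone with one module swapped for the
resident prophage's version, or vice versa. The recombinant's genome reads
A-B-A left to right by parental origin — it matches parent A outside two
shared homology regions and parent B between them, with one crossover hidden
inside each region. This package detects and characterizes such recombinants
from assembled genome sequences:

- **homology mapping** — find the regions the two parents share, with
  per-region average nucleotide identity (ANI), via k-mer anchor seeding,
  co-linear chaining, X-drop extension, and global re-alignment;
- **origin typing** — catalog the diagnostic SNPs inside each region (the
  positions where the parents disagree) and type each one in the recombinant
  by parental origin;
- **breakpoint calling** — segment the origin calls into blocks, call the
  crossover interval that must contain each junction, and flag short
  "flipflop" tracts that switch origin and back (gene-conversion-like
  signatures);
- **module estimation** — measure the donor module (parent-B segment
  incorporated) and the replaced module (parent-A segment swapped out);
  their difference equals the genome-length deficit exactly, an identity that
  holds for every two-crossover recombinant regardless of where the
  crossovers fell;
- **screening statistics** — the closed-form sample size for detecting a
  minority phage type among plaques at a chosen confidence;
- **in-silico PCR** — primer-site finding with a 3'-exact-match rule,
  amplicon prediction, allele-specific typing-panel design, and plaque
  typing;
- **simulation** — a ground-truthed generator of parent pairs and
  recombinants (with optional planted conversion tracts) whose defaults
  reproduce the study system's geometry: a 41.5 kb parent A and 47 kb parent
  B sharing a ~2.1 kb region at 84% identity and a ~2.2 kb region at 98%
  identity, with a constant 2,762 bp recombinant genome-length deficit.

All coordinates are 1-based inclusive throughout the library; conversion to
0-based half-open happens only at BED export.

## Worked example

```python
from phagemosaic import (
    SimConfig, simulate_trio, find_homology_regions,
    analyze_recombinant, genome_length_delta,
)

parent_a, parent_b, rec, truth = simulate_trio(SimConfig(seed=11))

regions = find_homology_regions(parent_a, parent_b)
for r in regions:
    print(r.region_id, r.interval_a.start, r.interval_a.end, round(r.ani, 2))

report = analyze_recombinant(parent_a, parent_b, regions, rec).report
print(report.architecture, report.modules.donor_len,
      report.modules.replaced_len, report.modules.delta)
```

Running `python examples/map_recombinant.py` (which adds truth checks)
prints:

```
== homology regions shared by the parents ==
R1: A 21,804-23,900  B 25,304-27,400  ANI 84.02%  (2,097 aligned columns)
R2: A 33,048-35,252  B 33,786-35,990  ANI 98.00%  (2,205 aligned columns)

== recombinant analysis ==
architecture: A-B-A
R1 origin blocks: Ax110 Bx225
R2 origin blocks: Bx19 Ax25
R1 crossover interval: rec 22,541-22,553 (width 11 bp)
R2 crossover interval: rec 30,831-30,942 (width 110 bp)

donor module:    8,389 bp (rec 22,553-30,942)
replaced module: 11,151 bp
delta (replaced - donor): 2,762 bp
genome length delta (parent A - recombinant): 2,762 bp

== checks against simulation truth ==
conservation identity holds: delta == len(A) - len(rec)
true junction at rec 22,552 inside called interval (R1): True
true junction at rec 30,864 inside called interval (R2): True
```

## Command line

A thin CLI wraps the same library calls:

```
phagemosaic simulate --seed 11 --out-dir sim      # parents + recombinant + truth.json
phagemosaic map --parent-a sim/parentA.fasta \
                --parent-b sim/parentB.fasta \
                --recombinant sim/recombinant.fasta --out-dir mapped
phagemosaic screen-size -p 0.1 -c 0.95            # n_real = 28.433, n_int = 29
phagemosaic type-plaque --genome lysate.fasta --panel panel.tsv
```

`map` writes the homology-region TSV/BED, per-region SNP panels, per-
recombinant JSON reports, calls/crossovers/flipflop tables, and a module
table; reruns are byte-identical.

## Examples

- `examples/map_recombinant.py` — the full analysis with truth checks (above).
- `examples/simulate_dataset.py` — write a ground-truthed dataset to disk.
- `examples/screening_design.py` — plaque-screening sample-size tables.
- `examples/insilico_typing.py` — design an allele-specific panel and type
  four templates plus a mixed lysate.
- `examples/validate_accessions.py` — optional, requires network: download
  the deposited Butters (KC576783), Island3 (HM152765) and nine BIB
  recombinant genomes from NCBI and validate the published module lengths,
  the constant 2,762 bp deficit, the homology-region coordinates, and
  BIB-specific PCR typing against this implementation.

## Tests

```
python -m pytest -q
```

The suite covers each module plus end-to-end acceptance checks: the
screening closed form, the module/genome-length conservation identity over
100 simulations, crossover containment and flipflop recovery on
ground-truthed simulations, and origin-call agreement with a brute-force
per-site oracle.

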