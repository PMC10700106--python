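# Methods

This document records the model behind each component, the default
parameters and why they hold, and the package's known limitations.

## Problem setting

Two co-linear phage genomes (parent A, the resident prophage; parent B, the
infecting phage) share two or more homologous regions separated by
non-homologous segments of unequal length. A double homologous recombination
— one crossover inside each of two regions — produces a chimera that carries
parent B's segment between the regions (the **donor module**) in place of
parent A's segment (the **replaced module**). Because the chimera is parent A
outside the exchange and parent B inside it,

```
len(parent A) − len(recombinant) = replaced_len − donor_len
```

holds exactly, independent of where within the regions the crossovers fell.
The package reproduces this as a checked invariant; in the Butters/Island3
system it fixes the deficit at 2,762 bp for every recombinant.

Coordinates are 1-based inclusive everywhere in the library. BED export
converts to 0-based half-open at the boundary and nowhere else.

## Homology mapping (`homology.py`)

Seed–chain–extend with a final global re-alignment:

1. **Anchors**: exact k-mer matches (default `k=12`); k-mers occurring more
   than 50 times on parent B are skipped as repeats. At 84% identity an exact
   12-mer survives with probability 0.84¹² ≈ 0.12, so a 2 kb region still
   yields hundreds of anchors; k=12 therefore sets a practical identity floor
   around 75–80% for sparse-anchor regions, well below the 84–98% regions of
   interest.
2. **Chaining**: greedy co-linear chaining; consecutive anchors join a
   cluster if both coordinates advance, the gap on each genome is ≤
   `max_gap=400`, and the diagonal drifts ≤ `max_diag_drift=200`. Clusters
   with fewer than 4 anchors or spanning less than a third of
   `min_aligned_len` are discarded: sparse chains of chance hits between
   unrelated sequence are not credible seeds.
3. **Extension**: ungapped X-drop extension from each cluster end
   (match +1, mismatch −2, X-drop 12).
4. **Re-alignment**: the spanned subsequences are globally re-aligned with a
   **mismatch-preferring** scoring scheme — match +1, mismatch −2, gap open
   −6, gap extend −1 — chosen so a substitution is never rewritten as an
   insertion–deletion pair. Under a unit-cost edit-distance alignment,
   clusters of SNPs get rewritten as gap pairs; since ANI excludes gap
   columns, that silently inflates identity (an 84% region measured ~86%)
   and deletes diagnostic SNP columns. With gap open −6 > 2 × mismatch, the
   aligner keeps substitutions as substitutions.
5. **End trimming**: each re-aligned candidate is trimmed to its
   maximal-scoring contiguous run of columns (+1 match, −2 otherwise).
   Candidate spans occasionally overrun into non-homologous flanking
   sequence; such flanks score negative on balance and would otherwise seed
   spurious "informative sites" that genotype randomly.
6. **Overlap resolution**: overlapping candidates are resolved by keeping
   the higher *alignment score* (not the higher percent identity — a
   fragment of a region can out-score its superset on identity, and a
   junk-padded superset can out-count a clean region on raw matches; the
   affine score penalizes both failure modes). Ties break to the leftmost
   start on parent A.
7. **Two-level chaining**: adjacent surviving regions separated by ≤
   `max_gap` on both genomes are merged when the joint re-alignment still
   passes both identity thresholds, so a rare anchor-gap inside one
   homologous segment cannot split it into two reported regions.

**ANI** is matches / (matches + mismatches) over aligned columns; gap and N
columns are excluded from both counts. A second, gap-inclusive identity
filter (matches / total columns ≥ `min_identity`) additionally rejects
gap-riddled alignments of unrelated sequence whose few comparable columns
happen to agree.

**Thresholds**: `min_aligned_len=300` and `min_identity=60%` replace a
BLAST-style E-value cutoff (E-values depend on database size and are not
reproducible without fixing a search tool); on genomes of this size they
select the same segments a BLAST screen at E ≤ 1e−20 would.

## Origin typing (`origin_typing.py`)

**Informative sites** are the substitution columns of a region's alignment —
positions where the parents carry different bases (gap and N columns are
skipped). Each site records its position on both parents.

**Placement**: a region's parent-A subsequence is located in the recombinant
with edlib in infix (HW) mode. Two well-separated equally-scoring loci raise
a `PlacementError` (ambiguous placement). The located window is padded by
8 bp per side — infix end coordinates are ambiguous by a few bases when the
window ends in mismatches, and a window short by one base would force a gap
into the re-alignment and shift every downstream site's coordinate — and
then re-aligned **semiglobally** (free end gaps on the window, penalized on
the query, same mismatch-preferring scores), after which the slop columns
are trimmed back off. A symmetric pad with penalized end gaps would not
work: under affine costs one long end gap is cheaper than two short ones, so
the aligner would misplace the slop. Placements below 60% identity or with
less than 90% of region bases aligned are rejected.

**Genotyping** compares the recombinant base at each mapped site with the
two parental alleles: `A`, `B`, `novel` (matches neither), or `missing`
(site fell in an unaligned/gap position).

## Breakpoints and modules (`breakpoints.py`)

- **Segmentation** is a run-length encoding of the A/B origin calls
  (`novel`/`missing` calls are skipped, not treated as block boundaries).
- A **crossover interval** is the open interval between the last site of one
  origin and the first site of the other: the junction must lie at or after
  the left site and strictly before the right site. Interval width is the
  number of interior positions; `contains` implements exactly that
  convention.
- A **flipflop tract** is an interior block of at most `max_tract_sites=3`
  sites flanked on both sides by blocks of the opposite origin — the
  signature of a short gene-conversion-like event rather than a third
  crossover.
- **Module estimation** uses two landmark sites: the first donor-origin (B)
  site in region 1 and the first resident-origin (A) site after the donor
  segment in region 2. Donor length is the exclusive difference of their
  recombinant positions; replaced length applies the same landmarks to their
  parent-A positions. If either landmark is missing the recombinant is not a
  two-crossover A-B-A chimera and a `LandmarkError` is raised (reported, not
  fatal, in the pipeline).
- **Architecture** labels the segments outside the regions by whichever
  parent they match better (edlib identity, threshold 60%), interleaves the
  region block origins (flipflop blocks excluded, since they are conversion
  tracts rather than architectural segments), and collapses repeats:
  a true double recombinant reads `A-B-A`.

## Screening statistics (`screening.py`)

Detection probability after n plaques for a type at frequency p is
1 − (1 − p)ⁿ. `required_sample_size(p, c)` returns the exact real root
n = ln(1 − c) / ln(1 − p) and the smallest integer n with detection
probability ≥ c (verified by boundary adjustment rather than blind
rounding). At p = 0.1, c = 0.95: n_real ≈ 28.43, n_int = 29; screening 30
plaques gives 0.9576.

## In-silico PCR (`pcr.py`)

A primer binds where it matches the template within `max_mismatch`
(default 0) and its 3'-terminal base matches exactly (polymerase extension
fails on a 3' mismatch); forward-sense sites are matches of the primer,
reverse-sense sites are matches of its reverse complement. The scan is a
vectorized numpy windowed mismatch count. A product forms between a
forward-sense site and a strictly-downstream reverse-sense site within
`max_amplicon_len=5000`; product size is first base of the forward site
through last base of the reverse site, inclusive.

`design_typing_panel` derives four allele-specific pairs from one homology
region: each 20-mer window sits inside the region, spans ≥ 2 diagnostic
SNPs (so the A- and B-versions cannot cross-bind at zero mismatches), the
forward window precedes the crossover offset and the reverse window follows
it, and all four pairs share one product size (default 1,367 bp). The four
pairs amplify exactly parent A, parent B, the A-B-A chimera, and the B-A-B
chimera, and a mixed lysate types as `mixed`.

## Simulation (`simulate.py`)

A single `numpy.random.default_rng` stream per config seed generates, in
documented order, the parent-A backbone, parent-B's non-homologous
segments, and the per-region divergence; substitutions are planted at
exactly the count implied by the target identity, so realized per-region ANI
matches the target to rounding. Divergence is substitution-only: the
simulator emulates diagnostic-SNP structure, not parental indel
polymorphism (real genome pairs also differ by indels inside homology
regions; the analysis side handles them, the generator does not produce
them).

Defaults are the study-scale geometry: 41,500 bp parent A, 47,000 bp parent
B, a 2,100 bp region at 84% identity (A 21,801 / B 25,301) and a 2,200 bp
region at 98% (A 33,051 / B 33,789), inter-region segments of 9,150 vs
6,388 bp — hence a constant 2,762 bp deficit. `compact_config()` is a
smaller geometry (15/16.5 kb, 1,200 bp regions at 90%/97%, deficit
1,400 bp) used for fast Monte Carlo loops; it is this package's own choice
of problem size, not a property of the study system.

Recombinants are built by splicing at per-region crossover offsets;
`random_crossovers` keeps offsets away from region edges by a 10% margin.
Planted conversion tracts span exactly n diagnostic donor-segment sites and
are separated from the crossover and the region edge by more donor sites
than the flipflop detector's tract-size threshold, so the planted tract is
the unique short-block anomaly (a closer tract would make the intervening
donor run itself tract-sized, and the detector would be right to flag it).
Truth records (planted regions, diff offsets, crossovers, conversions,
recombinant spans) serialize to JSON.

## Numerical and reproducibility notes

- The same mismatch-preferring scores are used for region re-alignment,
  placement re-alignment, and end trimming; edlib is used only to *locate*
  placements and to classify flank origins, never to measure identity at
  SNP resolution.
- Pipeline runs log the package version, thresholds, and SHA-256 checksums
  of all inputs; outputs are written atomically and reruns are
  byte-identical.
- `scripts/acceptance.py` derives all child seeds from `--seed` via one
  `default_rng`; every derived seed is below 2³¹.

## Limitations

- Only forward-strand, co-linear genome pairs: no inversion or
  rearrangement detection, no multi-contig assemblies.
- Crossovers are only localizable between diagnostic sites; a junction with
  no diagnostic site on one side (e.g. a crossover in the first ~200 bp of
  a 98%-identity region that happens to precede the first SNP) is
  informationally invisible, and the corresponding interval is simply not
  called. Monte Carlo containment fractions of ~199/200 trace to this, not
  to a calling error.
- Diagnostic SNPs at the extreme edge of a region can be clipped by
  extension (a terminal mismatch is not extendable homology); origin typing
  then starts a few bases inside the true region.
- The flipflop definition is site-count based (≤ 3 sites); a conversion
  tract spanning more sites is reported as extra architecture blocks, and a
  real triple-crossover would be indistinguishable from a long conversion
  tract.
- In-silico PCR models perfect-specificity annealing with a hard mismatch
  budget; no melting-temperature or secondary-structure model.
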