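"""Synthetic genome pairs and recombinants with known ground truth.

Emulates the architecture of a resident-prophage / infecting-phage pair like
Butters and Island3: two co-linear genomes of unequal length sharing two
homologous regions (a few kb each, mid-80s to high-90s percent identity)
separated by unrelated segments of unequal length, and recombinants built by
one crossover inside each homology region — yielding an A-B-A mosaic whose
replaced-minus-donor module difference equals the whole-genome length
difference. Optional short conversion tracts produce the "flipflop" signal.

Divergence inside homology regions is substitution-only by default, matching
SNP-based origin typing; the substitution count is fixed by the target
identity, so realized ANI hits the target up to rounding. All randomness
flows from a single numpy Generator seeded once; the stream order is: parent
A bases, then per-region substitution positions and replacement bases (left
to right), then parent B flank segments (left to right).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import GenomeRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RegionSpec:
    """One planted homology region: positions on both parents, length, identity."""

    a_start: int  # 1-based start on parent A
    b_start: int  # 1-based start on parent B
    length: int
    identity: float  # target percent identity

    def __post_init__(self) -> None:
        if self.length < 300:
            raise ValueError("homology regions must be at least 300 bp")
        if not 50.0 < self.identity <= 100.0:
            raise ValueError("region identity must be in (50, 100]")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: ~41.5/47 kb parents, two regions of 2.1 kb @84%
    and 2.2 kb @98%, inter-region segments differing by 2,762 bp."""

    seed: int = 0
    len_a: int = 41500
    len_b: int = 47000
    regions: tuple[RegionSpec, ...] = (
        RegionSpec(a_start=21801, b_start=25301, length=2100, identity=84.0),
        RegionSpec(a_start=33051, b_start=33789, length=2200, identity=98.0),
    )
    gc: float = 0.615  # mycobacteriophage-like GC content

    def __post_init__(self) -> None:
        prev_a = prev_b = 0
        for r in self.regions:
            if r.a_start <= prev_a or r.b_start <= prev_b:
                raise ValueError("regions must be ordered and non-overlapping on both parents")
            prev_a, prev_b = r.a_start + r.length - 1, r.b_start + r.length - 1
        if prev_a > self.len_a or prev_b > self.len_b:
            raise ValueError("regions exceed genome lengths")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("GC fraction must be in (0, 1)")


def compact_config(seed: int = 0) -> SimConfig:
    """Reduced-size configuration (~15 kb parents) for fast repeated runs.

    Keeps the defining features — two regions of distinct identity, unequal
    inter-region segments — at a size where hundred-seed sweeps are cheap.
    """
    return SimConfig(
        seed=seed,
        len_a=15000,
        len_b=16500,
        regions=(
            RegionSpec(a_start=3001, b_start=3501, length=1200, identity=90.0),
            RegionSpec(a_start=9001, b_start=8101, length=1200, identity=97.0),
        ),
    )


@dataclass(frozen=True)
class PlantedRegion:
    """Truth record for one homology region."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    length: int
    identity: float
    diff_offsets: tuple[int, ...]  # 1-based offsets within the region
    alleles_a: str  # parent A base at each diff offset
    alleles_b: str


@dataclass(frozen=True)
class ConversionTract:
    """A short segment inside a region overwritten with the other parent."""

    region_index: int
    start_offset: int  # 1-based within the region
    end_offset: int
    origin: str  # "A" or "B": whose bases the tract carries


@dataclass
class SimTruth:
    """Everything planted: regions, crossovers, tracts, recombinant layout."""

    regions: list[PlantedRegion]
    crossover_offsets: tuple[int, int] | None = None
    crossover_rec_left: tuple[int, int] | None = None  # rec pos of last base before each junction
    rec_region_spans: list[tuple[int, int]] = field(default_factory=list)
    conversions: list[ConversionTract] = field(default_factory=list)
    rec_id: str | None = None
    rec_len: int | None = None

    def to_dict(self) -> dict:
        return {
            "regions": [vars(r) | {"diff_offsets": list(r.diff_offsets)} for r in self.regions],
            "crossover_offsets": list(self.crossover_offsets) if self.crossover_offsets else None,
            "crossover_rec_left": list(self.crossover_rec_left) if self.crossover_rec_left else None,
            "rec_region_spans": [list(s) for s in self.rec_region_spans],
            "conversions": [vars(c) for c in self.conversions],
            "rec_id": self.rec_id,
            "rec_len": self.rec_len,
        }


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(_BASES, size=n, p=probs))


def _mutate_to_identity(
    rng: np.random.Generator, seq: str, identity: float
) -> tuple[str, tuple[int, ...], str, str]:
    """Substitute a fixed number of positions so identity hits the target."""
    n = len(seq)
    n_sub = round(n * (1.0 - identity / 100.0))
    positions = np.sort(rng.choice(n, size=n_sub, replace=False))
    out = list(seq)
    alleles_a = []
    alleles_b = []
    for pos in positions:
        old = out[pos]
        choices = [b for b in "ACGT" if b != old]
        new = choices[rng.integers(0, 3)]
        out[pos] = new
        alleles_a.append(old)
        alleles_b.append(new)
    offsets = tuple(int(p) + 1 for p in positions)
    return "".join(out), offsets, "".join(alleles_a), "".join(alleles_b)


def simulate_parent_pair(cfg: SimConfig) -> tuple[GenomeRecord, GenomeRecord, SimTruth]:
    """Generate the two parents sharing exactly the planted homology regions."""
    rng = np.random.default_rng(cfg.seed)
    seq_a = _random_seq(rng, cfg.len_a, cfg.gc)

    planted: list[PlantedRegion] = []
    region_seqs_b: list[str] = []
    for spec in cfg.regions:
        sub_a = seq_a[spec.a_start - 1 : spec.a_start - 1 + spec.length]
        sub_b, offsets, alleles_a, alleles_b = _mutate_to_identity(rng, sub_a, spec.identity)
        region_seqs_b.append(sub_b)
        planted.append(
            PlantedRegion(
                a_start=spec.a_start,
                a_end=spec.a_start + spec.length - 1,
                b_start=spec.b_start,
                b_end=spec.b_start + spec.length - 1,
                length=spec.length,
                identity=spec.identity,
                diff_offsets=offsets,
                alleles_a=alleles_a,
                alleles_b=alleles_b,
            )
        )

    parts_b: list[str] = []
    prev_end = 0
    for spec, sub_b in zip(cfg.regions, region_seqs_b):
        gap = spec.b_start - 1 - prev_end
        parts_b.append(_random_seq(rng, gap, cfg.gc))
        parts_b.append(sub_b)
        prev_end = spec.b_start - 1 + spec.length
    parts_b.append(_random_seq(rng, cfg.len_b - prev_end, cfg.gc))
    seq_b = "".join(parts_b)

    parent_a = GenomeRecord("parentA", seq_a, source="synthetic")
    parent_b = GenomeRecord("parentB", seq_b, source="synthetic")
    return parent_a, parent_b, SimTruth(regions=planted)


def simulate_recombinant(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    truth: SimTruth,
    crossovers: tuple[int, int] | None,
    conversions: Sequence[ConversionTract] = (),
    rec_id: str = "rec1",
) -> tuple[GenomeRecord, SimTruth]:
    """Build a double-crossover recombinant (or a parent-A copy).

    ``crossovers`` gives one 1-based offset per region; the junction falls
    between that offset and the next, so offsets must satisfy
    1 <= xo < region length. The recombinant takes parent A up to the first
    junction, parent B between the junctions (via parent B coordinates), and
    parent A after the second. Conversion tracts then overwrite the stated
    offsets with the named parent's bases.
    """
    if crossovers is None:
        rec = GenomeRecord(rec_id, parent_a.seq, source="synthetic")
        return rec, replace_truth(truth, rec_id=rec_id, rec_len=rec.length)
    if len(truth.regions) != 2:
        raise ValueError("double-crossover construction requires exactly two regions")
    r1, r2 = truth.regions
    xo1, xo2 = crossovers
    if not (1 <= xo1 < r1.length and 1 <= xo2 < r2.length):
        raise ValueError("crossover offsets must fall strictly inside their regions")

    seq = (
        parent_a.seq[: r1.a_start - 1 + xo1]
        + parent_b.seq[r1.b_start - 1 + xo1 : r2.b_start - 1 + xo2]
        + parent_a.seq[r2.a_start - 1 + xo2 :]
    )

    rec_r1 = (r1.a_start, r1.a_start + r1.length - 1)
    mid_b = r2.b_start - (r1.b_start + r1.length)
    rec_r2_start = rec_r1[1] + mid_b + 1
    rec_r2 = (rec_r2_start, rec_r2_start + r2.length - 1)
    xo1_rec_left = r1.a_start - 1 + xo1
    xo2_rec_left = rec_r2_start - 1 + xo2 - 1 + 1  # last donor base before junction 2
    rec_spans = [rec_r1, rec_r2]

    out = list(seq)
    applied: list[ConversionTract] = []
    for tract in conversions:
        pr = truth.regions[tract.region_index]
        if not (1 <= tract.start_offset <= tract.end_offset <= pr.length):
            raise ValueError("conversion tract outside its region")
        src = parent_a if tract.origin == "A" else parent_b
        src_start = (pr.a_start if tract.origin == "A" else pr.b_start) - 1
        rec_start = rec_spans[tract.region_index][0] - 1
        for off in range(tract.start_offset - 1, tract.end_offset):
            out[rec_start + off] = src.seq[src_start + off]
        applied.append(tract)
    seq = "".join(out)

    rec = GenomeRecord(rec_id, seq, source="synthetic")
    new_truth = SimTruth(
        regions=truth.regions,
        crossover_offsets=(xo1, xo2),
        crossover_rec_left=(xo1_rec_left, xo2_rec_left),
        rec_region_spans=rec_spans,
        conversions=applied,
        rec_id=rec_id,
        rec_len=rec.length,
    )
    return rec, new_truth


def replace_truth(truth: SimTruth, **kwargs) -> SimTruth:
    d = dict(
        regions=truth.regions,
        crossover_offsets=truth.crossover_offsets,
        crossover_rec_left=truth.crossover_rec_left,
        rec_region_spans=list(truth.rec_region_spans),
        conversions=list(truth.conversions),
        rec_id=truth.rec_id,
        rec_len=truth.rec_len,
    )
    d.update(kwargs)
    return SimTruth(**d)


def random_crossovers(
    truth: SimTruth, rng: np.random.Generator, margin_frac: float = 0.1
) -> tuple[int, int]:
    """Uniform crossover offsets away from region edges."""
    offsets = []
    for pr in truth.regions[:2]:
        lo = max(1, int(pr.length * margin_frac))
        hi = int(pr.length * (1 - margin_frac))
        offsets.append(int(rng.integers(lo, hi + 1)))
    return offsets[0], offsets[1]


def pick_conversion_tract(
    truth: SimTruth,
    region_index: int,
    crossovers: tuple[int, int],
    n_sites: int,
    rng: np.random.Generator,
    pad: int = 4,
) -> ConversionTract | None:
    """Choose a tract covering exactly ``n_sites`` diagnostic positions inside
    the donor (parent B) segment of a region, flanked by >= ``pad`` donor sites
    on each side, and overwrite it with parent A — a planted flipflop.

    The default pad exceeds the default flipflop tract-size threshold (3
    sites), so the donor runs separating the tract from the crossover and the
    region edge are never themselves tract-sized; the planted tract is then
    the unique short-block anomaly in the region.

    Returns None when the donor segment has too few diagnostic sites.
    """
    pr = truth.regions[region_index]
    xo1, xo2 = crossovers
    if region_index == 0:
        donor = [o for o in pr.diff_offsets if o > xo1]
    else:
        donor = [o for o in pr.diff_offsets if o <= xo2]
    if len(donor) < n_sites + 2 * pad:
        return None
    start_idx = int(rng.integers(pad, len(donor) - n_sites - pad + 1))
    chosen = donor[start_idx : start_idx + n_sites]
    # span exactly the chosen sites, stopping short of the neighbours
    lo = chosen[0]
    hi = chosen[-1]
    return ConversionTract(region_index, lo, hi, origin="A")


def simulate_trio(
    cfg: SimConfig,
    crossovers: tuple[int, int] | None = "random",  # type: ignore[assignment]
    conversion_sites: Sequence[tuple[int, int]] = (),
    rec_id: str = "rec1",
) -> tuple[GenomeRecord, GenomeRecord, GenomeRecord, SimTruth]:
    """Parents plus one recombinant in a single call.

    ``crossovers="random"`` draws offsets from the config's generator stream;
    ``conversion_sites`` lists (region_index, n_sites) flipflop tracts to plant.
    """
    parent_a, parent_b, truth = simulate_parent_pair(cfg)
    rng = np.random.default_rng((cfg.seed, 1))
    if crossovers == "random":
        crossovers = random_crossovers(truth, rng)
    tracts = []
    if crossovers is not None:
        for region_index, n_sites in conversion_sites:
            tract = pick_conversion_tract(truth, region_index, crossovers, n_sites, rng)
            if tract is not None:
                tracts.append(tract)
    rec, truth = simulate_recombinant(parent_a, parent_b, truth, crossovers, tracts, rec_id)
    return parent_a, parent_b, rec, truth
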