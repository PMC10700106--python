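"""Segmentation of origin calls into parental blocks, crossover-interval and
flipflop calling, exchanged-module length estimation, and architecture
classification of recombinant genomes.

The module-length rule: the donor module runs from the first donor-origin
(parent B) informative site in the first homology region to the site just
before the first resident-origin (parent A) site of the second region; the
replaced module is the same pair of landmark sites differenced on parent A
coordinates. Both use exclusive differencing (no +1), applied identically to
both genomes so their difference is convention-invariant. For a co-linear
double-crossover recombinant that difference equals the whole-genome length
difference exactly — a conservation identity, not a coincidence.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field as dataclass_field
from typing import Literal, Sequence

import edlib

from .io_formats import GenomeInterval, GenomeRecord
from .homology import HomologyRegion
from .origin_typing import InformativeSite, OriginCall, RegionPlacement


class LandmarkError(ValueError):
    """The recombinant lacks the landmarks of a two-crossover A-B-A product."""


@dataclass(frozen=True)
class OriginBlock:
    """A maximal run of consecutive same-origin calls within one region."""

    region_id: str
    origin: Literal["A", "B"]
    first_site: InformativeSite
    last_site: InformativeSite
    n_sites: int
    rec_span: GenomeInterval

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("block must contain at least one site")


@dataclass(frozen=True)
class CrossoverInterval:
    """Open interval on the recombinant that must contain a crossover.

    Bounded by the last informative site of one parental block and the first
    of the next, exclusive on both sides; width 0 means adjacent sites.
    """

    region_id: str
    left_site: InformativeSite
    right_site: InformativeSite
    left_pos_rec: int
    right_pos_rec: int
    left_origin: str
    right_origin: str

    @property
    def width(self) -> int:
        return self.right_pos_rec - self.left_pos_rec - 1

    @property
    def rec_interval(self) -> GenomeInterval | None:
        if self.width <= 0:
            return None
        return GenomeInterval(
            "", self.left_pos_rec + 1, self.right_pos_rec - 1,
            f"{self.region_id}:{self.left_origin}->{self.right_origin}",
        )

    def contains(self, pos: int) -> bool:
        """True when a junction between pos and pos+1 is compatible."""
        return self.left_pos_rec <= pos <= self.right_pos_rec - 1


@dataclass(frozen=True)
class FlipflopTract:
    """A short same-origin block flanked on both sides by the opposite origin,
    suggestive of a gene-conversion-like tract."""

    region_id: str
    block: OriginBlock


@dataclass(frozen=True)
class ModuleEstimate:
    """Exchanged-module lengths from the two landmark informative sites."""

    donor_start_rec: int  # first donor-origin site in region 1, on recombinant
    donor_end_rec: int  # first resident-origin site in region 2, on recombinant
    donor_len: int  # donor module length on the recombinant
    replaced_len: int  # replaced module length on parent A
    delta: int  # replaced_len - donor_len

    def __post_init__(self) -> None:
        if self.donor_len <= 0:
            raise ValueError("donor module length must be positive")


def segment_origins(calls: Sequence[OriginCall]) -> list[OriginBlock]:
    """Run-length encode A/B origin calls into maximal blocks.

    ``novel`` and ``missing`` calls neither extend nor break a run; they are
    simply skipped (their counts are reported at the recombinant level).
    """
    informative = [c for c in calls if c.origin in ("A", "B")]
    blocks: list[OriginBlock] = []
    run: list[OriginCall] = []

    def flush() -> None:
        if run:
            blocks.append(
                OriginBlock(
                    region_id=run[0].site.region_id,
                    origin=run[0].origin,  # type: ignore[arg-type]
                    first_site=run[0].site,
                    last_site=run[-1].site,
                    n_sites=len(run),
                    rec_span=GenomeInterval(
                        "", run[0].pos_rec, run[-1].pos_rec, run[0].origin
                    ),
                )
            )

    for call in informative:
        if run and call.origin != run[-1].origin:
            flush()
            run = []
        run.append(call)
    flush()
    return blocks


def call_crossover_intervals(blocks: Sequence[OriginBlock]) -> list[CrossoverInterval]:
    """One crossover interval per adjacent opposite-origin block pair."""
    intervals = []
    for left, right in zip(blocks, blocks[1:]):
        if left.origin == right.origin:
            continue
        intervals.append(
            CrossoverInterval(
                region_id=left.region_id,
                left_site=left.last_site,
                right_site=right.first_site,
                left_pos_rec=left.rec_span.end,
                right_pos_rec=right.rec_span.start,
                left_origin=left.origin,
                right_origin=right.origin,
            )
        )
    return intervals


def detect_flipflops(
    blocks: Sequence[OriginBlock], max_tract_sites: int = 3
) -> list[FlipflopTract]:
    """Interior blocks of at most ``max_tract_sites`` sites flanked on both
    sides by blocks of the opposite origin."""
    tracts = []
    for prev, cur, nxt in zip(blocks, blocks[1:], blocks[2:]):
        if (
            cur.n_sites <= max_tract_sites
            and prev.origin == nxt.origin
            and prev.origin != cur.origin
        ):
            tracts.append(FlipflopTract(cur.region_id, cur))
    return tracts


def estimate_modules(
    region1_calls: Sequence[OriginCall],
    region2_calls: Sequence[OriginCall],
) -> ModuleEstimate:
    """Landmark-based exchanged-module length estimation.

    Landmark 1 is the first B-origin (donor) site in the first region;
    landmark 2 is the first A-origin (resident) site in the second region
    following the donor segment. Lengths are exclusive differences of the two
    landmark positions, on the recombinant (donor module) and on parent A
    (replaced module).
    """
    l1 = next(
        (c for c in region1_calls if c.origin == "B" and c.pos_rec is not None), None
    )
    if l1 is None:
        raise LandmarkError(
            "not a two-crossover A-B-A recombinant: no donor-origin site in region 1"
        )
    seen_b = False
    l2 = None
    for c in region2_calls:
        if c.origin == "B":
            seen_b = True
        elif c.origin == "A" and seen_b and c.pos_rec is not None:
            l2 = c
            break
    if l2 is None:
        raise LandmarkError(
            "not a two-crossover A-B-A recombinant: no resident-origin site "
            "after the donor segment in region 2"
        )
    donor_len = l2.pos_rec - l1.pos_rec
    replaced_len = l2.site.pos_a - l1.site.pos_a
    return ModuleEstimate(
        donor_start_rec=l1.pos_rec,
        donor_end_rec=l2.pos_rec,
        donor_len=donor_len,
        replaced_len=replaced_len,
        delta=replaced_len - donor_len,
    )


def genome_length_delta(parent_a: GenomeRecord, rec: GenomeRecord) -> int:
    """Whole-genome length difference, parent A minus recombinant."""
    return parent_a.length - rec.length


def _flank_identity(seq_rec: str, seq_parent: str) -> float:
    """Global-alignment identity of two flank sequences, as a fraction."""
    if not seq_rec or not seq_parent:
        return 0.0
    d = edlib.align(seq_rec, seq_parent, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(seq_rec), len(seq_parent))


def classify_architecture(
    blocks_per_region: Sequence[Sequence[OriginBlock]],
    placements: Sequence[RegionPlacement],
    regions: Sequence[HomologyRegion],
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    rec: GenomeRecord,
    max_tract_sites: int = 3,
    min_flank_identity: float = 0.6,
) -> str:
    """Collapse block origins (plus flank assignments) into a string like "A-B-A".

    Flipflop tracts are excluded from the string (reported separately by
    :func:`detect_flipflops`). Flanks outside the homology regions are
    assigned to whichever parent aligns with higher identity; flanks matching
    neither parent above ``min_flank_identity`` are labelled "?".
    """
    labels: list[str] = []

    # flanks between / outside the placed regions, ordered along the recombinant
    order = sorted(range(len(placements)), key=lambda i: placements[i].rec_interval.start)
    bounds = []  # (rec_lo, rec_hi, a_lo, a_hi, b_lo, b_hi) per flank, 1-based
    prev_rec, prev_a, prev_b = 0, 0, 0
    for i in order:
        p, r = placements[i], regions[i]
        bounds.append(
            (prev_rec + 1, p.rec_interval.start - 1,
             prev_a + 1, r.interval_a.start - 1,
             prev_b + 1, r.interval_b.start - 1)
        )
        prev_rec, prev_a, prev_b = p.rec_interval.end, r.interval_a.end, r.interval_b.end
    bounds.append((prev_rec + 1, rec.length, prev_a + 1, parent_a.length, prev_b + 1, parent_b.length))

    def flank_label(rec_lo, rec_hi, a_lo, a_hi, b_lo, b_hi) -> str | None:
        if rec_hi < rec_lo:
            return None
        sub = rec.seq[rec_lo - 1 : rec_hi]
        id_a = _flank_identity(sub, parent_a.seq[a_lo - 1 : a_hi]) if a_hi >= a_lo else 0.0
        id_b = _flank_identity(sub, parent_b.seq[b_lo - 1 : b_hi]) if b_hi >= b_lo else 0.0
        if max(id_a, id_b) < min_flank_identity:
            return "?"
        return "A" if id_a >= id_b else "B"

    flipflop_ids = set()
    for blocks in blocks_per_region:
        for t in detect_flipflops(blocks, max_tract_sites):
            flipflop_ids.add(id(t.block))

    for i, region_idx in enumerate(order):
        lbl = flank_label(*bounds[i])
        if lbl:
            labels.append(lbl)
        for block in blocks_per_region[region_idx]:
            if id(block) not in flipflop_ids:
                labels.append(block.origin)
    lbl = flank_label(*bounds[-1])
    if lbl:
        labels.append(lbl)

    collapsed: list[str] = []
    for lbl in labels:
        if not collapsed or collapsed[-1] != lbl:
            collapsed.append(lbl)
    return "-".join(collapsed)


@dataclass
class RecombinantReport:
    """Everything the pipeline knows about one recombinant genome."""

    recombinant_id: str
    architecture: str
    genome_delta: int
    blocks: dict[str, list[OriginBlock]]
    crossovers: dict[str, list[CrossoverInterval]]
    flipflops: dict[str, list[FlipflopTract]]
    modules: ModuleEstimate | None
    n_novel: int
    n_missing: int
    error: str | None = None
    unreliable_regions: list[str] = dataclass_field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "recombinant_id": self.recombinant_id,
            "coord_system": "1-based inclusive",
            "architecture": self.architecture,
            "genome_delta": self.genome_delta,
            "n_novel": self.n_novel,
            "n_missing": self.n_missing,
            "error": self.error,
            "unreliable_regions": list(self.unreliable_regions),
            "blocks": {
                rid: [
                    {
                        "origin": b.origin,
                        "n_sites": b.n_sites,
                        "rec_start": b.rec_span.start,
                        "rec_end": b.rec_span.end,
                    }
                    for b in blocks
                ]
                for rid, blocks in self.blocks.items()
            },
            "crossovers": {
                rid: [
                    {
                        "left_pos_rec": x.left_pos_rec,
                        "right_pos_rec": x.right_pos_rec,
                        "width": x.width,
                        "transition": f"{x.left_origin}->{x.right_origin}",
                    }
                    for x in xs
                ]
                for rid, xs in self.crossovers.items()
            },
            "flipflops": {
                rid: [
                    {
                        "origin": t.block.origin,
                        "n_sites": t.block.n_sites,
                        "rec_start": t.block.rec_span.start,
                        "rec_end": t.block.rec_span.end,
                    }
                    for t in ts
                ]
                for rid, ts in self.flipflops.items()
            },
            "modules": asdict(self.modules) if self.modules else None,
        }
        return d
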