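"""Informative-site cataloguing and parental-origin typing of recombinants.

An informative site is an alignment column inside a homology region where the
two parents carry different bases; the base a recombinant shows at such a site
assigns that position to one parent or the other. Runs of same-origin calls
reveal the mosaic block structure; transitions localize crossovers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import edlib

from .homology import HomologyRegion, align_infix
from .io_formats import GenomeInterval, GenomeRecord

logger = logging.getLogger(__name__)

DNA = frozenset("ACGT")

Origin = Literal["A", "B", "novel", "missing"]


class PlacementError(ValueError):
    """A homology region could not be uniquely placed in a recombinant."""


@dataclass(frozen=True)
class InformativeSite:
    """A substitution column between the parents inside a homology region."""

    region_id: str
    column: int  # 0-based index into the region alignment
    pos_a: int  # 1-based on parent A
    pos_b: int  # 1-based on parent B
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("informative site alleles must differ")
        if self.allele_a not in DNA or self.allele_b not in DNA:
            raise ValueError("informative site alleles must be A/C/G/T")


@dataclass(frozen=True)
class OriginCall:
    """Observed parental origin of one informative site in a recombinant."""

    site: InformativeSite
    pos_rec: int | None  # 1-based on the recombinant; None when missing
    observed: str | None
    origin: Origin


@dataclass
class RegionPlacement:
    """Best placement of a homology region's parent subsequence in a recombinant.

    ``offset_to_rec`` maps 1-based offsets within the placed parent interval to
    1-based recombinant positions; offsets deleted in the recombinant are absent.
    """

    region_id: str
    parent: Literal["a", "b"]
    rec_id: str
    rec_interval: GenomeInterval
    row_query: str
    row_rec: str
    offset_to_rec: dict[int, int] = field(repr=False)

    @property
    def coverage(self) -> float:
        n_query = len(self.row_query.replace("-", ""))
        return len(self.offset_to_rec) / n_query


def extract_informative_sites(region: HomologyRegion) -> list[InformativeSite]:
    """All substitution columns of a region alignment, sorted by column.

    Gap and N columns are skipped: indels are not informative sites, and N
    masks the parental allele.
    """
    pos_a, pos_b = region.column_positions()
    sites = []
    for col, (ca, cb) in enumerate(zip(region.row_a, region.row_b)):
        if ca in DNA and cb in DNA and ca != cb:
            sites.append(
                InformativeSite(region.region_id, col, pos_a[col], pos_b[col], ca, cb)
            )
    return sites


def locate_region_in_recombinant(
    region: HomologyRegion,
    rec: GenomeRecord,
    parent: Literal["a", "b"] = "a",
    min_identity: float = 60.0,
    min_coverage: float = 0.9,
) -> RegionPlacement:
    """Place one parent's region subsequence at its unique best recombinant locus.

    The de-gapped parent row is aligned in infix mode against the full
    recombinant. Raises :class:`PlacementError` when the best hit falls below
    ``min_identity``, when two well-separated loci tie for the best score, or
    when fewer than ``min_coverage`` of the region's bases are aligned.
    """
    row = region.row_a if parent == "a" else region.row_b
    query = row.replace("-", "")
    res = edlib.align(query, rec.seq, mode="HW", task="locations")
    locations = res["locations"]
    if not locations:
        raise PlacementError(f"region {region.region_id}: no placement in {rec.id}")

    starts = sorted(loc[0] for loc in locations)
    distinct = [starts[0]]
    for s in starts[1:]:
        if s - distinct[-1] > len(query) // 2:
            distinct.append(s)
    if len(distinct) > 1:
        raise PlacementError(
            f"region {region.region_id}: {len(distinct)} equally-scoring "
            f"placements in {rec.id} (starts {distinct})"
        )

    # re-align over the located window with mismatch-preferring scoring, so
    # diagnostic SNP columns stay substitutions rather than gap pairs. The
    # window is padded first: infix-mode endpoints are ambiguous by a few
    # bases when the window ends in mismatches, and a window one base short
    # would force a gap into the re-alignment, shifting every downstream
    # site's recombinant coordinate by one.
    pad = 8
    loc_start, loc_end = locations[0]
    loc_start = max(0, loc_start - pad)
    loc_end = min(len(rec.seq) - 1, loc_end + pad)
    row_query, row_rec = align_infix(query, rec.seq[loc_start : loc_end + 1])
    # trim the slop back off: end-gap columns where the query row is gapped
    lead = len(row_query) - len(row_query.lstrip("-"))
    trail = len(row_query) - len(row_query.rstrip("-"))
    loc_start += sum(1 for c in row_rec[:lead] if c != "-")
    loc_end -= sum(1 for c in row_rec[len(row_rec) - trail :] if c != "-")
    end = len(row_query) - trail
    row_query, row_rec = row_query[lead:end], row_rec[lead:end]
    matches = sum(
        1 for cq, cr in zip(row_query, row_rec) if cq == cr and cq in DNA
    )
    comparable = sum(
        1
        for cq, cr in zip(row_query, row_rec)
        if cq in DNA and cr in DNA
    )
    if comparable == 0 or 100.0 * matches / comparable < min_identity:
        raise PlacementError(
            f"region {region.region_id}: best hit in {rec.id} below "
            f"{min_identity}% identity — region unplaceable"
        )

    offset_to_rec: dict[int, int] = {}
    qoff = 0
    rpos = loc_start  # 0-based; +1 below for 1-based
    for cq, cr in zip(row_query, row_rec):
        if cr != "-":
            rpos += 1
        if cq != "-":
            qoff += 1
            if cr != "-":
                offset_to_rec[qoff] = rpos
    placement = RegionPlacement(
        region_id=region.region_id,
        parent=parent,
        rec_id=rec.id,
        rec_interval=GenomeInterval(rec.id, loc_start + 1, loc_end + 1, region.region_id),
        row_query=row_query,
        row_rec=row_rec,
        offset_to_rec=offset_to_rec,
    )
    if placement.coverage < min_coverage:
        raise PlacementError(
            f"region {region.region_id}: only {placement.coverage:.0%} of the "
            f"region aligned in {rec.id} — region unplaceable"
        )
    return placement


def genotype_sites(
    sites: Sequence[InformativeSite],
    placement: RegionPlacement,
    rec: GenomeRecord,
    region: HomologyRegion,
) -> list[OriginCall]:
    """Assign a parental origin to every informative site in one recombinant.

    Sites falling in recombinant gaps or on N bases become ``missing`` rather
    than being dropped, so downstream segmentation can report evidence gaps.
    """
    if placement.parent == "a":
        interval = region.interval_a
        site_pos = lambda s: s.pos_a  # noqa: E731
    else:
        interval = region.interval_b
        site_pos = lambda s: s.pos_b  # noqa: E731

    calls = []
    for site in sites:
        offset = site_pos(site) - interval.start + 1
        pos_rec = placement.offset_to_rec.get(offset)
        if pos_rec is None:
            calls.append(OriginCall(site, None, None, "missing"))
            continue
        observed = rec.base(pos_rec)
        if observed == site.allele_a:
            origin: Origin = "A"
        elif observed == site.allele_b:
            origin = "B"
        elif observed in DNA:
            origin = "novel"
        else:
            origin = "missing"
        calls.append(OriginCall(site, pos_rec, observed, origin))
    return calls


@dataclass
class SnpPanel:
    """Redacted SNP matrix for one region: parents plus recombinants.

    One row per genome, one column per informative site; missing calls are
    rendered as ".".
    """

    region_id: str
    sites: list[InformativeSite]
    rows: dict[str, str]  # genome id -> string of bases, "." for missing

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_tsv(self) -> str:
        header = "genome\t" + "\t".join(str(s.pos_a) for s in self.sites)
        lines = [header]
        for genome_id, row in self.rows.items():
            lines.append(genome_id + "\t" + "\t".join(row))
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        """Plain-text redacted view, one genome per line."""
        width = max((len(g) for g in self.rows), default=0)
        return "\n".join(f"{g:<{width}}  {row}" for g, row in self.rows.items()) + "\n"


def build_snp_panel(
    region: HomologyRegion,
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    recombinants: Sequence[GenomeRecord],
    min_identity: float = 60.0,
) -> SnpPanel:
    """Assemble the per-region SNP matrix across parents and recombinants."""
    sites = extract_informative_sites(region)
    if not sites:
        logger.warning("region %s has no informative sites", region.region_id)
    rows = {
        parent_a.id: "".join(s.allele_a for s in sites),
        parent_b.id: "".join(s.allele_b for s in sites),
    }
    for rec in recombinants:
        placement = locate_region_in_recombinant(region, rec, min_identity=min_identity)
        calls = genotype_sites(sites, placement, rec, region)
        rows[rec.id] = "".join(
            c.observed if c.observed is not None else "." for c in calls
        )
    return SnpPanel(region.region_id, sites, rows)


def calls_to_tsv(calls: Sequence[OriginCall]) -> str:
    """One row per origin call in the region."""
    lines = ["region_id\tpos_a\tpos_b\tpos_rec\tallele_a\tallele_b\tobserved\torigin"]
    for c in calls:
        lines.append(
            f"{c.site.region_id}\t{c.site.pos_a}\t{c.site.pos_b}"
            f"\t{c.pos_rec if c.pos_rec is not None else '.'}"
            f"\t{c.site.allele_a}\t{c.site.allele_b}"
            f"\t{c.observed if c.observed is not None else '.'}\t{c.origin}"
        )
    return "\n".join(lines) + "\n"
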