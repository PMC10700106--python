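"""In-silico PCR: primer site finding, amplicon prediction, plaque typing.

Models the type-specific PCR screen used to distinguish parental phages from
their recombinants: a primer binds where it matches the template within a
mismatch budget, the 3'-terminal base must match exactly (extension fails on a
3' mismatch), and a product forms between a forward-sense site and a
downstream reverse-sense site within a maximum length. Product size is the
standard convention: first base of the forward site through last base of the
reverse site, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_formats import GenomeInterval, GenomeRecord, revcomp

_BASE_CODE = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair targeting one phage type."""

    name: str
    target_type: str
    fwd: str
    rev: str  # given 5'->3' on the opposite strand, as primers are ordered
    expected_size: int | None = None

    def __post_init__(self) -> None:
        for primer in (self.fwd, self.rev):
            if not set(primer) <= set("ACGT"):
                raise ValueError(f"primer {primer!r} contains non-ACGT characters")
            if not 10 <= len(primer) <= 50:
                raise ValueError(f"primer length {len(primer)} outside 10-50 nt")


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding site: interval, strand sense, mismatch count."""

    interval: GenomeInterval
    sense: str  # "+" forward, "-" reverse
    mismatches: int


@dataclass(frozen=True)
class AmpliconPrediction:
    genome_id: str
    pair_name: str
    fwd_site: GenomeInterval
    rev_site: GenomeInterval
    fwd_mismatches: int
    rev_mismatches: int

    @property
    def size(self) -> int:
        return self.rev_site.end - self.fwd_site.start + 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(_BASE_CODE), dtype=np.uint8)


def _scan(genome_arr: np.ndarray, primer: str, max_mismatch: int, anchor_3p: str) -> list[tuple[int, int]]:
    """All 0-based window starts where ``primer`` matches with <= max_mismatch.

    ``anchor_3p`` is "last" or "first": which window base models the primer's
    3' terminus and must match exactly.
    """
    m = len(primer)
    n = len(genome_arr)
    if n < m:
        return []
    p = _encode(primer)
    n_windows = n - m + 1
    mism = np.zeros(n_windows, dtype=np.int32)
    for k in range(m):
        mism += genome_arr[k : k + n_windows] != p[k]
    ok = mism <= max_mismatch
    if anchor_3p in ("last", "first"):
        anchor = m - 1 if anchor_3p == "last" else 0
        ok &= genome_arr[anchor : anchor + n_windows] == p[anchor]
    return [(int(i), int(mism[i])) for i in np.nonzero(ok)[0]]


def find_primer_sites(
    genome: GenomeRecord,
    primer: str,
    max_mismatch: int = 0,
    require_3prime_match: bool = True,
) -> list[PrimerSite]:
    """Locate all binding sites of a primer on both senses of a genome.

    Forward-sense sites are matches of the primer itself; reverse-sense sites
    are matches of its reverse complement (the primer anneals to the forward
    strand and extends leftward). The 3'-terminal base must match exactly
    unless ``require_3prime_match`` is off.
    """
    if len(primer) < 10:
        raise ValueError("primer must be at least 10 nt")
    primer = primer.upper()
    arr = _encode(genome.seq)
    m = len(primer)
    sites = []
    for start, mm in _scan(arr, primer, max_mismatch, "last" if require_3prime_match else "none"):
        sites.append(
            PrimerSite(GenomeInterval(genome.id, start + 1, start + m), "+", mm)
        )
    for start, mm in _scan(arr, revcomp(primer), max_mismatch, "first" if require_3prime_match else "none"):
        sites.append(
            PrimerSite(GenomeInterval(genome.id, start + 1, start + m), "-", mm)
        )
    return sites


def predict_amplicons(
    genome: GenomeRecord,
    pair: PrimerPair,
    max_amplicon_len: int = 5000,
    max_mismatch: int = 0,
    require_3prime_match: bool = True,
) -> list[AmpliconPrediction]:
    """All properly-oriented products of a primer pair on one template."""
    fwd_sites = [
        s for s in find_primer_sites(genome, pair.fwd, max_mismatch, require_3prime_match)
        if s.sense == "+"
    ]
    rev_sites = [
        s for s in find_primer_sites(genome, pair.rev, max_mismatch, require_3prime_match)
        if s.sense == "-"
    ]
    amplicons = []
    for f in fwd_sites:
        for r in rev_sites:
            if r.interval.start <= f.interval.start or r.interval.end <= f.interval.end:
                continue  # outward or overlapping orientation: no product
            size = r.interval.end - f.interval.start + 1
            if size > max_amplicon_len:
                continue
            amplicons.append(
                AmpliconPrediction(
                    genome_id=genome.id,
                    pair_name=pair.name,
                    fwd_site=f.interval,
                    rev_site=r.interval,
                    fwd_mismatches=f.mismatches,
                    rev_mismatches=r.mismatches,
                )
            )
    return amplicons


def type_plaque(
    panel_results: Mapping[str, Sequence[AmpliconPrediction]],
    panel: Sequence[PrimerPair],
) -> str:
    """Classify a template by which type-specific pairs amplified.

    Returns the unique amplifying type, "mixed" when more than one type
    amplified, or "untyped" when none did.
    """
    pair_types = {p.name: p.target_type for p in panel}
    amplified = {
        pair_types[name]
        for name, amps in panel_results.items()
        if amps and name in pair_types
    }
    if not amplified:
        return "untyped"
    if len(amplified) > 1:
        return "mixed"
    return amplified.pop()


def run_panel(
    genome: GenomeRecord,
    panel: Sequence[PrimerPair],
    max_amplicon_len: int = 5000,
    max_mismatch: int = 0,
) -> dict[str, list[AmpliconPrediction]]:
    """Predict amplicons for every pair of a panel against one template."""
    return {
        pair.name: predict_amplicons(genome, pair, max_amplicon_len, max_mismatch)
        for pair in panel
    }


def read_primer_panel(path: str | Path) -> list[PrimerPair]:
    """Read a primer panel from TSV: name, target_type, fwd, rev[, expected_size]."""
    panel = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("name\t"):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"malformed primer panel line: {line!r}")
        expected = int(parts[4]) if len(parts) > 4 and parts[4] not in ("", ".") else None
        panel.append(PrimerPair(parts[0], parts[1], parts[2].upper(), parts[3].upper(), expected))
    names = [p.name for p in panel]
    if len(set(names)) != len(names):
        raise ValueError("duplicate primer pair names in panel")
    return panel


def write_primer_panel(panel: Sequence[PrimerPair], path: str | Path) -> None:
    lines = ["name\ttarget_type\tfwd\trev\texpected_size"]
    for p in panel:
        lines.append(
            f"{p.name}\t{p.target_type}\t{p.fwd}\t{p.rev}"
            f"\t{p.expected_size if p.expected_size is not None else '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def design_typing_panel(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    region,  # a simulate.PlantedRegion (duck-typed: a_start, b_start, length, diff_offsets)
    xo_offset: int,
    product_size: int = 1367,
    primer_len: int = 20,
    min_diffs: int = 2,
) -> list[PrimerPair]:
    """Derive allele-specific typing pairs from a shared homology region.

    Each primer window sits inside the region and spans at least ``min_diffs``
    diagnostic positions, so the parent-A and parent-B versions of the window
    cannot cross-bind at zero mismatches. The forward window lies before the
    crossover offset and the reverse window after it; combining windows from
    the two parents yields four pairs that each amplify exactly one template
    type: parent A, parent B, the A-B-A chimera ("BIB"-like) and the B-A-B
    chimera ("IBI"-like), all with the same expected product size.
    """
    diffs = set(region.diff_offsets)

    def window_diffs(lo: int, hi: int) -> int:
        return sum(1 for o in range(lo, hi + 1) if o in diffs)

    chosen_f = None
    for f in range(1, xo_offset - primer_len + 2):
        r = f + product_size - 1
        if r > region.length:
            break
        if r - primer_len + 1 <= xo_offset:
            continue
        if (
            window_diffs(f, f + primer_len - 1) >= min_diffs
            and window_diffs(r - primer_len + 1, r) >= min_diffs
        ):
            chosen_f = f
            break
    if chosen_f is None:
        raise ValueError(
            f"no primer placement with {min_diffs} diagnostic sites per window "
            f"and product size {product_size} around crossover offset {xo_offset}"
        )
    f = chosen_f
    r = f + product_size - 1

    def window(parent: GenomeRecord, start_attr: int, lo: int, hi: int) -> str:
        return parent.subseq(start_attr + lo - 1, start_attr + hi - 1)

    fwd_a = window(parent_a, region.a_start, f, f + primer_len - 1)
    fwd_b = window(parent_b, region.b_start, f, f + primer_len - 1)
    rev_a = revcomp(window(parent_a, region.a_start, r - primer_len + 1, r))
    rev_b = revcomp(window(parent_b, region.b_start, r - primer_len + 1, r))

    return [
        PrimerPair("pairA", "parentA", fwd_a, rev_a, product_size),
        PrimerPair("pairB", "parentB", fwd_b, rev_b, product_size),
        PrimerPair("pairABA", "BIB", fwd_a, rev_b, product_size),
        PrimerPair("pairBAB", "IBI", fwd_b, rev_a, product_size),
    ]


def predictions_to_tsv(results: Mapping[str, Sequence[AmpliconPrediction]]) -> str:
    lines = ["pair\tgenome\tfwd_start\tfwd_end\trev_start\trev_end\tsize\tfwd_mm\trev_mm"]
    for name, amps in results.items():
        for a in amps:
            lines.append(
                f"{name}\t{a.genome_id}\t{a.fwd_site.start}\t{a.fwd_site.end}"
                f"\t{a.rev_site.start}\t{a.rev_site.end}\t{a.size}"
                f"\t{a.fwd_mismatches}\t{a.rev_mismatches}"
            )
    return "\n".join(lines) + "\n"
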