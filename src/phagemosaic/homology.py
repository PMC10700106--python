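"""Homologous-region discovery between two co-linear genomes.

Shared segments are seeded with exact k-mer anchors, chained co-linearly,
extended by ungapped X-drop extension, and each candidate is then globally
re-aligned over its spanned subsequences. Per-region average nucleotide
identity (ANI) is matches / (matches + mismatches) over aligned columns,
with gap and N columns excluded from both counts.

Thresholds (minimum aligned length, minimum identity) replace database-size
dependent E-values; defaults of 300 bp and 60% select the same kind of
segment a BLAST screen at E <= 1e-20 would on genomes of this size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from Bio import Align

from .io_formats import GenomeInterval, GenomeRecord

GAPLIKE = frozenset("-N")

# Mismatch-preferring scoring: a substitution must never be rewritten as an
# insertion-deletion pair, or clustered SNPs would vanish into gap columns
# and inflate ANI.
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 1
_ALIGNER.mismatch_score = -2
_ALIGNER.open_gap_score = -6
_ALIGNER.extend_gap_score = -1


def align_global(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise alignment of two sequences; returns gapped rows."""
    if seq_a == seq_b:
        return seq_a, seq_b
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


# Semiglobal variant for placing a query inside a longer window: end gaps on
# the window (the second sequence) are free, so window slop is absorbed at
# the ends instead of distorting the interior alignment.
_INFIX_ALIGNER = Align.PairwiseAligner()
_INFIX_ALIGNER.mode = "global"
_INFIX_ALIGNER.match_score = _ALIGNER.match_score
_INFIX_ALIGNER.mismatch_score = _ALIGNER.mismatch_score
_INFIX_ALIGNER.open_gap_score = _ALIGNER.open_gap_score
_INFIX_ALIGNER.extend_gap_score = _ALIGNER.extend_gap_score
try:
    _INFIX_ALIGNER.end_insertion_score = 0
except AttributeError:  # renamed from target_end_gap_score in newer Biopython
    _INFIX_ALIGNER.target_end_gap_score = 0


def align_infix(query: str, window: str) -> tuple[str, str]:
    """Align a full query inside a window; window end gaps are free."""
    if query == window:
        return query, window
    aln = _INFIX_ALIGNER.align(query, window)[0]
    return str(aln[0]), str(aln[1])


def compute_ani(alignment: tuple[str, str]) -> float:
    """Percent identity over comparable alignment columns.

    Columns containing a gap or N in either row are excluded from both the
    match and mismatch counts. Raises if no comparable column exists.
    """
    row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows must have equal length")
    matches = mismatches = 0
    for ca, cb in zip(row_a, row_b):
        if ca in GAPLIKE or cb in GAPLIKE:
            continue
        if ca == cb:
            matches += 1
        else:
            mismatches += 1
    total = matches + mismatches
    if total == 0:
        raise ValueError("alignment has no comparable (non-gap, non-N) columns")
    return 100.0 * matches / total


@dataclass(frozen=True)
class HomologyRegion:
    """A pairwise-aligned homologous segment between parent A and parent B."""

    region_id: str
    interval_a: GenomeInterval
    interval_b: GenomeInterval
    row_a: str  # gapped alignment row for the parent-A subsequence
    row_b: str

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows must have equal length")
        if len(self.row_a.replace("-", "")) != self.interval_a.length:
            raise ValueError("row A does not match interval A length")
        if len(self.row_b.replace("-", "")) != self.interval_b.length:
            raise ValueError("row B does not match interval B length")

    @property
    def aligned_length(self) -> int:
        return len(self.row_a)

    @property
    def ani(self) -> float:
        return compute_ani((self.row_a, self.row_b))

    @property
    def alignment(self) -> tuple[str, str]:
        return (self.row_a, self.row_b)

    def column_positions(self) -> tuple[list[int], list[int]]:
        """Per-column 1-based genome positions (0 where the row has a gap)."""
        pos_a, pos_b = [], []
        a = self.interval_a.start - 1
        b = self.interval_b.start - 1
        for ca, cb in zip(self.row_a, self.row_b):
            if ca != "-":
                a += 1
            if cb != "-":
                b += 1
            pos_a.append(a if ca != "-" else 0)
            pos_b.append(b if cb != "-" else 0)
        return pos_a, pos_b


def _alignment_score(row_a: str, row_b: str) -> int:
    """Score of a gapped alignment under the module's scoring scheme."""
    score = 0
    in_gap = False
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            score += int(_ALIGNER.extend_gap_score)
            if not in_gap:
                score += int(_ALIGNER.open_gap_score - _ALIGNER.extend_gap_score)
            in_gap = True
            continue
        in_gap = False
        if ca in GAPLIKE or cb in GAPLIKE:
            continue
        score += int(_ALIGNER.match_score if ca == cb else _ALIGNER.mismatch_score)
    return score


def _max_scoring_window(row_a: str, row_b: str) -> tuple[int, int]:
    """0-based inclusive column range of the maximal-scoring contiguous run.

    Columns score +1 for a match, -2 for a mismatch or N, -2 for a gap (a
    flat per-column approximation of the aligner's gap costs, used only for
    end trimming). Returns (0, -1) when every window scores <= 0.
    """
    best = cur = 0
    best_lo, best_hi, cur_lo = 0, -1, 0
    for i, (ca, cb) in enumerate(zip(row_a, row_b)):
        score = 1 if (ca == cb and ca not in GAPLIKE) else -2
        cur += score
        if cur <= 0:
            cur, cur_lo = 0, i + 1
        elif cur > best:
            best, best_lo, best_hi = cur, cur_lo, i
    return best_lo, best_hi


def _kmer_anchors(seq_a: str, seq_b: str, k: int, max_hits: int = 50) -> list[tuple[int, int]]:
    """Exact k-mer matches as 0-based (pos_a, pos_b) anchor pairs."""
    index: dict[str, list[int]] = {}
    for j in range(len(seq_b) - k + 1):
        index.setdefault(seq_b[j : j + k], []).append(j)
    anchors = []
    for i in range(len(seq_a) - k + 1):
        hits = index.get(seq_a[i : i + k])
        if hits and len(hits) <= max_hits:
            for j in hits:
                anchors.append((i, j))
    anchors.sort()
    return anchors


def _chain_anchors(
    anchors: list[tuple[int, int]], k: int, max_gap: int, max_diag_drift: int
) -> Iterator[list[tuple[int, int]]]:
    """Greedy co-linear chaining of sorted anchors into clusters.

    Consecutive anchors join a cluster when both coordinates advance, the gap
    on each genome is at most ``max_gap``, and the diagonal offset drifts by
    at most ``max_diag_drift`` (allowing modest indels).
    """
    cluster: list[tuple[int, int]] = []
    for i, j in anchors:
        if cluster:
            pi, pj = cluster[-1]
            if (
                i >= pi
                and j > pj - k
                and i - pi <= max_gap
                and abs((j - i) - (pj - pi)) <= max_diag_drift
            ):
                cluster.append((i, j))
                continue
            yield cluster
        cluster = [(i, j)]
    if cluster:
        yield cluster


def _xdrop_extend(
    seq_a: str, seq_b: str, a: int, b: int, step: int, match: int = 1, mismatch: int = -2, xdrop: int = 12
) -> tuple[int, int]:
    """Ungapped X-drop extension from (a, b) in direction ``step`` (+1/-1).

    Returns the 0-based coordinates of the last position kept on each genome.
    """
    best_a, best_b = a, b
    score = best = 0
    while True:
        a += step
        b += step
        if not (0 <= a < len(seq_a) and 0 <= b < len(seq_b)):
            break
        score += match if seq_a[a] == seq_b[b] else mismatch
        if score > best:
            best, best_a, best_b = score, a, b
        elif best - score > xdrop:
            break
    return best_a, best_b


def find_homology_regions(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    min_aligned_len: int = 300,
    min_identity: float = 60.0,
    k: int = 12,
    max_gap: int = 400,
    max_diag_drift: int = 200,
) -> list[HomologyRegion]:
    """Locate homologous segments shared by two co-linear genomes.

    Returns maximal non-overlapping regions sorted by their start on parent A,
    each globally re-aligned over the spanned subsequences. Overlapping
    candidates are resolved by keeping the segment with the higher alignment
    score (ties broken by leftmost start on parent A). Score-based ranking,
    unlike percent identity, lets a full region outrank a higher-identity
    fragment of itself, while still rejecting candidates padded with
    low-identity flanking sequence. Adjacent co-linear regions separated by
    at most ``max_gap`` on both genomes are merged when the joint
    re-alignment still passes both identity thresholds, so a rare seed-chain
    break inside one homologous segment cannot split it in two.
    """
    if not parent_a.seq or not parent_b.seq:
        raise ValueError("empty genome")
    if min(parent_a.length, parent_b.length) < min_aligned_len:
        raise ValueError("genomes shorter than the minimum aligned length")

    def realign_span(a_lo: int, a_hi: int, b_lo: int, b_hi: int) -> HomologyRegion | None:
        """Globally re-align a 0-based inclusive span, trimmed to its
        maximal-scoring window; None if it fails the length or either
        identity threshold."""
        sub_a = parent_a.seq[a_lo : a_hi + 1]
        sub_b = parent_b.seq[b_lo : b_hi + 1]
        row_a, row_b = align_global(sub_a, sub_b)
        # trim to the maximal-scoring run of columns: candidate spans can
        # overrun into non-homologous flanking sequence, whose columns score
        # negative on balance and would seed spurious informative sites
        lo, hi = _max_scoring_window(row_a, row_b)
        if hi < lo:
            return None
        a_lo += sum(1 for c in row_a[:lo] if c != "-")
        b_lo += sum(1 for c in row_b[:lo] if c != "-")
        a_hi -= sum(1 for c in row_a[hi + 1 :] if c != "-")
        b_hi -= sum(1 for c in row_b[hi + 1 :] if c != "-")
        row_a, row_b = row_a[lo : hi + 1], row_b[lo : hi + 1]
        if len(row_a) < min_aligned_len:
            return None
        try:
            ani = compute_ani((row_a, row_b))
        except ValueError:
            return None
        if ani < min_identity:
            return None
        # gap-inclusive identity guard: excludes gap-riddled alignments of
        # unrelated sequence whose few comparable columns happen to agree
        matches = sum(1 for ca, cb in zip(row_a, row_b) if ca == cb and ca not in GAPLIKE)
        if 100.0 * matches / len(row_a) < min_identity:
            return None
        return HomologyRegion(
            region_id="",
            interval_a=GenomeInterval(parent_a.id, a_lo + 1, a_hi + 1),
            interval_b=GenomeInterval(parent_b.id, b_lo + 1, b_hi + 1),
            row_a=row_a,
            row_b=row_b,
        )

    anchors = _kmer_anchors(parent_a.seq, parent_b.seq, k)
    candidates: list[tuple[int, int, HomologyRegion]] = []
    for cluster in _chain_anchors(anchors, k, max_gap, max_diag_drift):
        a_lo, b_lo = cluster[0]
        a_hi, b_hi = cluster[-1][0] + k - 1, cluster[-1][1] + k - 1
        # sparse chains of chance k-mer hits between unrelated sequence are
        # not credible seeds; true homologous segments anchor densely
        if len(cluster) < 4 or a_hi - a_lo + 1 < min_aligned_len // 3:
            continue
        a_lo, b_lo = _xdrop_extend(parent_a.seq, parent_b.seq, a_lo, b_lo, -1)
        a_hi, b_hi = _xdrop_extend(parent_a.seq, parent_b.seq, a_hi, b_hi, +1)
        region = realign_span(a_lo, a_hi, b_lo, b_hi)
        if region is None:
            continue
        candidates.append((_alignment_score(region.row_a, region.row_b), a_lo, region))

    # higher alignment score wins overlaps; ties broken by leftmost start on A
    candidates.sort(key=lambda t: (-t[0], t[1]))
    kept: list[HomologyRegion] = []
    for _, _, region in candidates:
        clash = any(
            region.interval_a.overlaps(r.interval_a) or region.interval_b.overlaps(r.interval_b)
            for r in kept
        )
        if not clash:
            kept.append(region)

    kept.sort(key=lambda r: r.interval_a.start)

    # two-level chaining: a seed-chain break inside one homologous segment
    # leaves two adjacent co-linear regions; rejoin them when the merged
    # re-alignment still clears both identity thresholds
    merged: list[HomologyRegion] = []
    for region in kept:
        if merged:
            prev = merged[-1]
            gap_a = region.interval_a.start - prev.interval_a.end - 1
            gap_b = region.interval_b.start - prev.interval_b.end - 1
            if 0 <= gap_a <= max_gap and 0 <= gap_b <= max_gap:
                joint = realign_span(
                    prev.interval_a.start - 1,
                    region.interval_a.end - 1,
                    prev.interval_b.start - 1,
                    region.interval_b.end - 1,
                )
                if joint is not None:
                    merged[-1] = joint
                    continue
        merged.append(region)

    return [
        HomologyRegion(f"R{i + 1}", r.interval_a, r.interval_b, r.row_a, r.row_b)
        for i, r in enumerate(merged)
    ]


def regions_to_tsv(regions: list[HomologyRegion]) -> str:
    """TSV report: region_id, coordinates on both parents, length, ANI."""
    lines = ["region_id\ta_start\ta_end\tb_start\tb_end\taligned_length\tani"]
    for r in regions:
        lines.append(
            f"{r.region_id}\t{r.interval_a.start}\t{r.interval_a.end}"
            f"\t{r.interval_b.start}\t{r.interval_b.end}"
            f"\t{r.aligned_length}\t{r.ani:.2f}"
        )
    return "\n".join(lines) + "\n"
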