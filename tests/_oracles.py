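"""Independent oracles used to check the pipeline, kept free of the code paths
they verify: everything here is direct arithmetic on the simulation truth."""

from __future__ import annotations

import numpy as np

from phagemosaic.io_formats import GenomeRecord
from phagemosaic.simulate import SimTruth


def truth_site_calls(
    parent_a: GenomeRecord,
    parent_b: GenomeRecord,
    rec: GenomeRecord,
    truth: SimTruth,
    region_index: int,
) -> list[tuple[int, int, str]]:
    """Per-site triple comparison located by truth coordinates.

    For every planted diagnostic offset, reads the recombinant base at the
    truth-derived position and compares it against both parental alleles.
    Returns (pos_a, pos_rec, origin) per site, origin in {A, B, novel}.
    """
    pr = truth.regions[region_index]
    rec_start = truth.rec_region_spans[region_index][0]
    calls = []
    for off, aa, ab in zip(pr.diff_offsets, pr.alleles_a, pr.alleles_b):
        pos_a = pr.a_start + off - 1
        pos_rec = rec_start + off - 1
        observed = rec.base(pos_rec)
        assert parent_a.base(pos_a) == aa
        assert parent_b.base(pr.b_start + off - 1) == ab
        if observed == aa:
            origin = "A"
        elif observed == ab:
            origin = "B"
        else:
            origin = "novel"
        calls.append((pos_a, pos_rec, origin))
    return calls


def rle(origins: list[str]) -> list[tuple[str, int]]:
    """Run-length encoding over A/B origins, skipping everything else."""
    runs: list[tuple[str, int]] = []
    for o in origins:
        if o not in ("A", "B"):
            continue
        if runs and runs[-1][0] == o:
            runs[-1] = (o, runs[-1][1] + 1)
        else:
            runs.append((o, 1))
    return runs


def max_ungapped_window_identity(seq_a: str, seq_b: str, window: int) -> float:
    """Highest fraction of matches in any length-`window` ungapped comparison
    of the two sequences over all diagonal offsets."""
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    best = 0.0
    for shift in range(-(len(b) - window), len(a) - window + 1):
        if shift >= 0:
            eq = a[shift : shift + len(b)] == b[: len(a) - shift]
        else:
            eq = a[: len(b) + shift] == b[-shift:]
        if len(eq) < window:
            continue
        csum = np.concatenate([[0], np.cumsum(eq)])
        wins = csum[window:] - csum[:-window]
        best = max(best, wins.max() / window)
    return best


def brute_force_required_n(p: float, c: float, n_max: int = 100000) -> int:
    """Smallest n with 1-(1-p)^n >= c, by direct search."""
    for n in range(1, n_max + 1):
        if 1.0 - (1.0 - p) ** n >= c:
            return n
    raise AssertionError("no n found")


def brute_force_primer_sites(genome: str, primer: str, max_mismatch: int) -> list[int]:
    """0-based window starts matching the primer within the mismatch budget,
    3'-terminal base exact — naive sliding-window comparison."""
    hits = []
    m = len(primer)
    for i in range(len(genome) - m + 1):
        window = genome[i : i + m]
        if window[-1] != primer[-1]:
            continue
        if sum(1 for x, y in zip(window, primer) if x != y) <= max_mismatch:
            hits.append(i)
    return hits
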