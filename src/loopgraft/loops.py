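"""Supersecondary-structure segmentation: a "loop" here is an aperiodic
coil together with its two flanking regular secondary-structure elements.
Consecutive loops share a flank — the C-terminal regular SSE of loop n is
the N-terminal regular SSE of loop n+1 — and chain-terminal coils without
two regular flanks are not loops (they offer no recombination flanks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enm import region_cross_correlation, region_mean_flexibility
from .structures import Region


@dataclass(frozen=True)
class SSESegment:
    kind: str  # H, E or C
    region: Region

    def __post_init__(self) -> None:
        if self.kind not in "HEC":
            raise ValueError(f"segment kind must be H, E or C, got {self.kind!r}")


@dataclass(frozen=True)
class LoopRegion:
    loop_id: int
    n_flank: SSESegment
    coil: SSESegment
    c_flank: SSESegment

    def __post_init__(self) -> None:
        if self.coil.kind != "C":
            raise ValueError("middle segment must be coil")
        if self.n_flank.kind == "C" or self.c_flank.kind == "C":
            raise ValueError("flanks must be regular (H or E)")
        if not (self.n_flank.region.end + 1 == self.coil.region.start
                and self.coil.region.end + 1 == self.c_flank.region.start):
            raise ValueError("loop segments must be contiguous")

    @property
    def region(self) -> Region:
        """Whole supersecondary region, flanks included."""
        return Region(self.n_flank.region.start, self.c_flank.region.end)


def segment(labels: str) -> list[SSESegment]:
    """Maximal runs of identical 3-state labels, in chain order."""
    if not labels:
        raise ValueError("empty label string")
    segments: list[SSESegment] = []
    start = 0
    for k in range(1, len(labels) + 1):
        if k == len(labels) or labels[k] != labels[start]:
            segments.append(SSESegment(labels[start], Region(start, k - 1)))
            start = k
    return segments


def build_loops(segments: list[SSESegment]) -> list[LoopRegion]:
    """Every (regular, coil, regular) consecutive triple becomes one loop,
    numbered 1.. in sequence order."""
    loops: list[LoopRegion] = []
    for a, b, c in zip(segments, segments[1:], segments[2:]):
        if a.kind in "HE" and b.kind == "C" and c.kind in "HE":
            loops.append(LoopRegion(len(loops) + 1, a, b, c))
    return loops


def loop_table(loops: list[LoopRegion], profile: np.ndarray) -> pd.DataFrame:
    """Per-loop mean flexibility of the whole supersecondary region, of
    the coil only, and of each flank."""
    rows = []
    for lp in loops:
        rows.append(
            {
                "loop_id": lp.loop_id,
                "start": lp.region.start,
                "end": lp.region.end,
                "flex_loop": region_mean_flexibility(profile, lp.region),
                "flex_coil": region_mean_flexibility(profile, lp.coil.region),
                "flex_n_flank": region_mean_flexibility(profile, lp.n_flank.region),
                "flex_c_flank": region_mean_flexibility(profile, lp.c_flank.region),
            }
        )
    return pd.DataFrame(rows)


def loop_pair_correlations(loops: list[LoopRegion],
                           C: np.ndarray) -> pd.DataFrame:
    """Mean motion cross-correlation between every pair of supersecondary
    regions (flanks included), as a square table indexed by loop id."""
    ids = [lp.loop_id for lp in loops]
    values = np.array(
        [
            [region_cross_correlation(C, a.region, b.region) for b in loops]
            for a in loops
        ]
    )
    return pd.DataFrame(values, index=ids, columns=ids)


def coil_sse_correlations(loop: LoopRegion, segments: list[SSESegment],
                          C: np.ndarray) -> pd.DataFrame:
    """Correlation of one loop's coil against every SSE segment of the
    chain — the hinge/cross-talk diagnostic used to pick graft targets."""
    rows = []
    for seg in segments:
        rows.append(
            {
                "sse_kind": seg.kind,
                "sse_start": seg.region.start,
                "sse_end": seg.region.end,
                "corr_with_coil": region_cross_correlation(
                    C, loop.coil.region, seg.region
                ),
            }
        )
    return pd.DataFrame(rows)


def loop_report(loops: list[LoopRegion], segments: list[SSESegment],
                profile: np.ndarray, C: np.ndarray) -> dict[str, pd.DataFrame]:
    """Bundle of the three analytic tables for a chain."""
    report = {
        "loops": loop_table(loops, profile),
        "loop_pair_correlation": loop_pair_correlations(loops, C),
    }
    for lp in loops:
        report[f"coil_{lp.loop_id}_vs_sse"] = coil_sse_correlations(
            lp, segments, C
        )
    return report


def loop_by_region(loops: list[LoopRegion], region: Region,
                   coil_only_match: bool = False) -> LoopRegion:
    """Find the loop whose supersecondary region equals ``region``
    (used to pin user-selected loops given as author-number ranges)."""
    for lp in loops:
        target = lp.coil.region if coil_only_match else lp.region
        if target.start == region.start and target.end == region.end:
            return lp
    raise KeyError(f"no loop spanning region {region}")


def match_insert_loop(loop_s: LoopRegion, loops_i: list[LoopRegion],
                      pairing) -> LoopRegion:
    """Insert-chain loop corresponding to a scaffold loop: the one whose
    supersecondary region overlaps most of the pairing image of the
    scaffold loop's region."""
    i2j = pairing.i_to_j()
    image = {i2j[i] for i in loop_s.region.indices() if i in i2j}
    if not image:
        raise ValueError(f"loop {loop_s.loop_id} has no paired residues")
    best = max(
        loops_i,
        key=lambda lp: len(image & set(lp.region.indices())),
    )
    if not (image & set(best.region.indices())):
        raise ValueError(f"no insert loop overlaps loop {loop_s.loop_id}")
    return best
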