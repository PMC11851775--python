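"""Geometric sequence pairing: derive a monotonic one-to-one residue
correspondence from a structural superposition.

Given the matrix D of all pairwise CA-CA distances between two superposed
chains, the algorithm greedily pairs the globally closest unused residue
pair while its distance does not exceed a threshold T (default 1.9 Å).
Sequence non-correlativeness is then repaired by unpairing the fewest
pairs needed to make both index sequences strictly increasing, and pairs
whose sequence offset i - j deviates from the mean offset by more than a
multiple (default 4) of the offset standard deviation are removed.  The
result doubles as a structure-based sequence alignment that downstream
steps use to place recombination points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np

from .structures import ChainStructure
from .superpose import RigidTransform, pairwise_ca_distances


@dataclass(frozen=True)
class PairingParams:
    """T and the offset-filter width are the algorithm's only parameters."""

    distance_threshold: float = 1.9     # T, Å
    offset_sd_multiplier: float = 4.0   # s_ij filter width, dimensionless

    def __post_init__(self) -> None:
        if self.distance_threshold <= 0 or self.offset_sd_multiplier <= 0:
            raise ValueError("pairing parameters must be positive")


class ResiduePair(NamedTuple):
    i: int          # first-chain (scaffold) residue index
    j: int          # second-chain (insert) residue index
    distance: float  # Å in the common frame


@dataclass
class Pairing:
    """One-to-one monotonic correspondence, sorted by scaffold index."""

    pairs: list[ResiduePair]

    def __post_init__(self) -> None:
        self.pairs = sorted(self.pairs, key=lambda p: p.i)
        i_vals = [p.i for p in self.pairs]
        j_vals = [p.j for p in self.pairs]
        if any(b <= a for a, b in zip(i_vals, i_vals[1:])) or \
           any(b <= a for a, b in zip(j_vals, j_vals[1:])):
            raise ValueError("pairing indices must be strictly increasing")
        if any(p.distance < 0 for p in self.pairs):
            raise ValueError("pair distances must be non-negative")

    def __len__(self) -> int:
        return len(self.pairs)

    def i_to_j(self) -> dict[int, int]:
        return {p.i: p.j for p in self.pairs}

    def j_to_i(self) -> dict[int, int]:
        return {p.j: p.i for p in self.pairs}

    @classmethod
    def identity(cls, n: int) -> "Pairing":
        return cls([ResiduePair(k, k, 0.0) for k in range(n)])


def greedy_pair(D: np.ndarray, threshold: float) -> list[ResiduePair]:
    """Greedy global closest-pair matching on a distance matrix.

    Repeatedly selects the smallest remaining entry whose row and column
    are both unused and whose value is <= ``threshold``.  Ties are broken
    by (smaller i, then smaller j).  Implemented by ranking the candidate
    entries once and sweeping them in order, which is equivalent to
    repeated minimum scans but O(K log K) in the number of candidates.

    The result is one-to-one but not necessarily monotonic in sequence.
    """
    D = np.asarray(D, dtype=float)
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix must be finite")
    rows, cols = np.nonzero(D <= threshold)
    if len(rows) == 0:
        return []
    dists = D[rows, cols]
    # rank by (distance, i, j): lexsort keys are applied last-key-major
    order = np.lexsort((cols, rows, dists))
    used_i = np.zeros(D.shape[0], dtype=bool)
    used_j = np.zeros(D.shape[1], dtype=bool)
    out: list[ResiduePair] = []
    for k in order:
        i, j = int(rows[k]), int(cols[k])
        if used_i[i] or used_j[j]:
            continue
        used_i[i] = used_j[j] = True
        out.append(ResiduePair(i, j, float(dists[k])))
    return out


def enforce_monotonic(pairs: list[ResiduePair]) -> list[ResiduePair]:
    """Unpair the non-correlative matches: keep a maximum-cardinality
    subset whose i and j are both strictly increasing.

    Weighted longest-increasing-subsequence over pairs sorted by i; among
    equal-cardinality optima the subset with minimal total distance is
    kept, so as little of the greedy solution as possible is discarded.
    """
    if len(pairs) <= 1:
        return list(pairs)
    ordered = sorted(pairs, key=lambda p: p.i)
    n = len(ordered)
    # dp[k] = (chain length ending at k, total distance, predecessor)
    length = [1] * n
    total = [p.distance for p in ordered]
    prev = [-1] * n
    for k in range(n):
        for m in range(k):
            if ordered[m].i < ordered[k].i and ordered[m].j < ordered[k].j:
                cand_len = length[m] + 1
                cand_tot = total[m] + ordered[k].distance
                if cand_len > length[k] or (
                    cand_len == length[k] and cand_tot < total[k]
                ):
                    length[k], total[k], prev[k] = cand_len, cand_tot, m
    best = max(range(n), key=lambda k: (length[k], -total[k], -k))
    chain = []
    k = best
    while k != -1:
        chain.append(ordered[k])
        k = prev[k]
    return chain[::-1]


def offset_filter(pairs: list[ResiduePair],
                  multiplier: float = 4.0) -> list[ResiduePair]:
    """Remove pairs far away in sequence: with offsets o = i - j over all
    input pairs, pairs with |o - mean| > multiplier * population SD are
    dropped.  Statistics are computed once, before any removal.  With
    fewer than 2 pairs, or a degenerate (zero-SD) offset distribution,
    the input is returned unchanged.
    """
    if len(pairs) < 2:
        return list(pairs)
    offsets = np.array([p.i - p.j for p in pairs], dtype=float)
    mu = offsets.mean()
    sigma = offsets.std()  # population SD
    if sigma == 0:
        return list(pairs)
    keep = np.abs(offsets - mu) <= multiplier * sigma
    return [p for p, k in zip(pairs, keep) if k]


def pair_structures(a: ChainStructure, b: ChainStructure,
                    transform: RigidTransform | None = None,
                    params: PairingParams | None = None) -> Pairing:
    """Full pairing pipeline: greedy matching on the superposed distance
    matrix, monotonicity repair, then the sequence-offset filter."""
    if params is None:
        params = PairingParams()
    D = pairwise_ca_distances(a, b, transform)
    return pairing_from_distances(D, params)


def pairing_from_distances(D: np.ndarray,
                           params: PairingParams | None = None) -> Pairing:
    if params is None:
        params = PairingParams()
    raw = greedy_pair(D, params.distance_threshold)
    mono = enforce_monotonic(raw)
    kept = offset_filter(mono, params.offset_sd_multiplier)
    return Pairing(kept)


def to_gapped_alignment(pairing: Pairing, seq_a: str,
                        seq_b: str) -> tuple[str, str]:
    """Render the pairing as a pairwise gapped alignment.

    Paired residues share a column; unpaired stretches between consecutive
    pairs are placed as mutually gapped blocks, first-chain block before
    second-chain block.
    """
    for p in pairing.pairs:
        if p.i >= len(seq_a) or p.j >= len(seq_b):
            raise IndexError(f"pair {p} outside sequences")
    out_a: list[str] = []
    out_b: list[str] = []
    prev_i, prev_j = -1, -1
    anchors = [(p.i, p.j) for p in pairing.pairs] + [(len(seq_a), len(seq_b))]
    for i, j in anchors:
        block_a = seq_a[prev_i + 1:i]
        block_b = seq_b[prev_j + 1:j]
        out_a.append(block_a + "-" * len(block_b))
        out_b.append("-" * len(block_a) + block_b)
        if i < len(seq_a):
            out_a.append(seq_a[i])
            out_b.append(seq_b[j])
        prev_i, prev_j = i, j
    return "".join(out_a), "".join(out_b)


def pairing_table(pairing: Pairing, a: ChainStructure, b: ChainStructure):
    """TSV-ready table of (scaffold auth number, insert auth number,
    distance in Å) rows, one per retained pair."""
    import pandas as pd

    return pd.DataFrame(
        {
            "scaffold_auth": [a.residues[p.i].auth_label for p in pairing.pairs],
            "insert_auth": [b.residues[p.j].auth_label for p in pairing.pairs],
            "scaffold_aa": [a.residues[p.i].aa for p in pairing.pairs],
            "insert_aa": [b.residues[p.j].aa for p in pairing.pairs],
            "distance_A": [round(p.distance, 3) for p in pairing.pairs],
        }
    )
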