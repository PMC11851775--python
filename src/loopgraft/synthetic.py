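"""Idealized CA-trace homolog pairs with known ground truth.

The generator emulates the study setup — a scaffold protein and a
homologous insert protein that differ by coordinate noise and by one
divergent (replaced) loop — so every pipeline stage can be exercised
against a known residue correspondence without downloading structures.
Helix geometry uses textbook CA parameters (radius 2.3 Å, rise
1.5 Å/residue, 100°/residue); coils are self-avoiding random walks with
a fixed 3.8 Å CA-CA step.  All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairing import Pairing, ResiduePair
from .structures import ChainStructure, Region, Residue

HELIX_RADIUS = 2.3      # Å
HELIX_RISE = 1.5        # Å per residue
HELIX_TWIST = 100.0     # degrees per residue
COIL_STEP = 3.8         # Å CA-CA
MIN_SELF_DISTANCE = 3.0  # Å within a 5-residue window

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ToyArchitecture:
    """Blueprint of (kind, length) segments; kinds are H (helix) and C
    (coil).  Total length should be >= 10 for elastic-network stages."""

    blueprint: tuple[tuple[str, int], ...] = (
        ("H", 10), ("C", 6), ("H", 12), ("C", 6), ("H", 10),
    )
    seed: int = 0
    noise_sigma: float = 0.3  # Å, isotropic per-CA Gaussian noise

    def __post_init__(self) -> None:
        for kind, length in self.blueprint:
            if kind not in "HC" or length < 1:
                raise ValueError(f"bad blueprint segment ({kind}, {length})")

    @property
    def labels(self) -> str:
        return "".join(kind * length for kind, length in self.blueprint)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.blueprint)


@dataclass
class HomologPair:
    scaffold: ChainStructure
    insert: ChainStructure
    truth: Pairing
    swapped_region: Region | None = None         # scaffold indices
    insert_swapped_region: Region | None = None  # insert indices


def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w = np.asarray(axis, dtype=float)
    w = w / np.linalg.norm(w)
    helper = np.array([0.0, 0.0, 1.0]) if abs(w[2]) < 0.9 \
        else np.array([1.0, 0.0, 0.0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def ideal_helix(n: int, origin=(0.0, 0.0, 0.0),
                axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Canonical alpha-helix CA trace along ``axis`` starting near
    ``origin`` (first CA at one radius from the axis)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    u, v, w = _frame(axis)
    origin = np.asarray(origin, dtype=float)
    k = np.arange(n)[:, None]
    theta = np.deg2rad(HELIX_TWIST) * k
    return (origin
            + HELIX_RISE * k * w
            + HELIX_RADIUS * (np.cos(theta) * u + np.sin(theta) * v))


def random_coil(n: int, rng: np.random.Generator,
                start=(0.0, 0.0, 0.0),
                direction=(1.0, 0.0, 0.0)) -> np.ndarray:
    """Self-avoiding random walk with fixed 3.8 Å steps.

    The step direction is jittered each residue; proposals bringing the
    new CA closer than 3 Å to any of the previous 5 residues are
    rejected (bounded retries keep the walk deterministic per rng)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pts = [np.asarray(start, dtype=float)]
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    while len(pts) < n:
        placed = False
        for _ in range(64):
            proposal = d + 0.8 * rng.normal(size=3)
            proposal /= np.linalg.norm(proposal)
            new = pts[-1] + COIL_STEP * proposal
            window = pts[-6:-1]  # previous 5 excluding the immediate one
            if all(np.linalg.norm(new - q) >= MIN_SELF_DISTANCE
                   for q in window):
                pts.append(new)
                d = proposal
                placed = True
                break
        if not placed:  # pragma: no cover - extremely unlikely
            pts.append(pts[-1] + COIL_STEP * d)
    return np.array(pts)


def _build_trace(blueprint, rng: np.random.Generator) -> np.ndarray:
    """Fold the blueprint into one connected CA trace.  Helix axes turn
    ~120 degrees between consecutive segments so the toy packs back on
    itself instead of extending."""
    coords: list[np.ndarray] = []
    pos = np.zeros(3)
    direction = np.array([0.0, 0.0, 1.0])
    for seg_idx, (kind, length) in enumerate(blueprint):
        if kind == "H":
            seg = ideal_helix(length, origin=pos, axis=direction)
        else:
            seg = random_coil(length, rng, start=pos, direction=direction)
        coords.append(seg)
        end_dir = seg[-1] - seg[-2] if length > 1 else direction
        end_dir = end_dir / np.linalg.norm(end_dir)
        # turn for the next segment: fold back at ~120 degrees with a
        # deterministic wobble
        angle = np.deg2rad(120.0 + 15.0 * rng.standard_normal())
        u, v, w = _frame(end_dir)
        turned = np.cos(angle) * w + np.sin(angle) * (
            np.cos(seg_idx) * u + np.sin(seg_idx) * v
        )
        direction = turned / np.linalg.norm(turned)
        pos = seg[-1] + COIL_STEP * direction
    return np.vstack(coords)


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_LETTERS), size=n))


def _as_chain(coords: np.ndarray, sequence: str, chain_id: str,
              source_id: str) -> ChainStructure:
    residues = [
        Residue(index=k, auth_number=k + 1, insertion_code="",
                aa=sequence[k], ca=coords[k])
        for k in range(len(sequence))
    ]
    return ChainStructure(chain_id, residues, source_id)


def make_homolog_pair(arch: ToyArchitecture,
                      swap: tuple[int, int] | None = None) -> HomologPair:
    """Scaffold plus noisy homolog, optionally with one coil replaced.

    ``swap`` = (blueprint segment ordinal, new coil length): the targeted
    coil of the insert is regenerated from scratch at the new length with
    fresh letters, emulating a divergent loop.  The ground-truth pairing
    covers all unswapped positions.
    """
    rng = np.random.default_rng(arch.seed)
    scaffold_coords = _build_trace(arch.blueprint, rng)
    n = arch.total_length
    scaffold_seq = _random_sequence(n, rng)
    scaffold = _as_chain(scaffold_coords, scaffold_seq, "A",
                         f"toy-scaffold-seed{arch.seed}")

    noise = arch.noise_sigma * rng.normal(size=(n, 3)) \
        if arch.noise_sigma > 0 else np.zeros((n, 3))
    insert_coords = scaffold_coords + noise
    insert_seq = scaffold_seq
    swapped_region = insert_swapped = None

    if swap is not None:
        seg_ordinal, new_length = swap
        kind, old_length = arch.blueprint[seg_ordinal]
        if kind != "C":
            raise ValueError("swap must target a coil (C) segment")
        start = sum(l for _, l in arch.blueprint[:seg_ordinal])
        end = start + old_length - 1
        swapped_region = Region(start, end)

        anchor = insert_coords[start - 1] if start > 0 else np.zeros(3)
        direction = (insert_coords[end + 1] - anchor) if end + 1 < n \
            else np.array([1.0, 0.0, 0.0])
        if np.linalg.norm(direction) < 1e-9:
            direction = np.array([1.0, 0.0, 0.0])
        new_coil = random_coil(new_length, rng,
                               start=anchor + COIL_STEP
                               * direction / np.linalg.norm(direction),
                               direction=direction)
        insert_coords = np.vstack([
            insert_coords[:start], new_coil, insert_coords[end + 1:]
        ])
        new_letters = []
        for k in range(new_length):
            letter = rng.choice(list(AA_LETTERS))
            if k < old_length and letter == scaffold_seq[start + k]:
                # force divergence from the scaffold coil
                letter = AA_LETTERS[
                    (AA_LETTERS.index(letter) + 1) % len(AA_LETTERS)
                ]
            new_letters.append(letter)
        insert_seq = (scaffold_seq[:start] + "".join(new_letters)
                      + scaffold_seq[end + 1:])
        insert_swapped = Region(start, start + new_length - 1)

        shift = new_length - old_length
        truth_pairs = (
            [ResiduePair(i, i, 0.0) for i in range(start)]
            + [ResiduePair(i, i + shift, 0.0) for i in range(end + 1, n)]
        )
    else:
        truth_pairs = [ResiduePair(i, i, 0.0) for i in range(n)]

    insert = _as_chain(insert_coords, insert_seq, "B",
                       f"toy-insert-seed{arch.seed}")
    return HomologPair(scaffold, insert, Pairing(truth_pairs),
                       swapped_region, insert_swapped)


def pairing_recovery(found: Pairing, truth: Pairing) -> float:
    """Fraction of ground-truth correspondences present in a recovered
    pairing."""
    truth_set = {(p.i, p.j) for p in truth.pairs}
    if not truth_set:
        raise ValueError("empty ground truth")
    found_set = {(p.i, p.j) for p in found.pairs}
    return len(truth_set & found_set) / len(truth_set)
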