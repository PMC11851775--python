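"""Recombination-point enumeration and chimera assembly.

Every aligned position on a loop's flanking regular SSEs is a potential
recombination point.  Candidates are explored per flank from the residue
most distal to the coil inward; gapped alignment positions are resolved
to the gap-flanking residue of the other chain at the shorter Euclidean
distance.  The cross product of N-flank and C-flank candidates defines
the designs; a design is accepted only if its chimeric sequence differs
from the scaffold and from every previously accepted design.

Boundary semantics (default): the boundary residue pair itself is kept
from the scaffold; the replaced material is the open interval between the
N- and C-boundary scaffold residues, substituted by the corresponding
open interval of the insert.  An inclusive mode (boundary residues taken
from the insert) is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .loops import LoopRegion
from .pairing import Pairing
from .structures import ChainStructure, Region, write_fragment


@dataclass(frozen=True)
class BoundaryCandidate:
    scaffold_index: int
    insert_index: int
    flank: str            # "N" or "C"
    from_gap: bool
    distance: float       # Å in the common frame


@dataclass(frozen=True)
class GraftWindow:
    """One grafted loop: a resolved N/C boundary pair.

    ``scaffold_removed`` / ``insert_kept`` are half-open index ranges of
    the replaced scaffold span and the transplanted insert span.
    """

    loop_id: int
    n_boundary: BoundaryCandidate
    c_boundary: BoundaryCandidate
    inclusive: bool = False

    def __post_init__(self) -> None:
        if not (self.n_boundary.scaffold_index < self.c_boundary.scaffold_index
                and self.n_boundary.insert_index < self.c_boundary.insert_index):
            raise ValueError("N boundary must precede C boundary on both chains")

    @property
    def scaffold_removed(self) -> range:
        if self.inclusive:
            return range(self.n_boundary.scaffold_index,
                         self.c_boundary.scaffold_index + 1)
        return range(self.n_boundary.scaffold_index + 1,
                     self.c_boundary.scaffold_index)

    @property
    def insert_kept(self) -> range:
        if self.inclusive:
            return range(self.n_boundary.insert_index,
                         self.c_boundary.insert_index + 1)
        return range(self.n_boundary.insert_index + 1,
                     self.c_boundary.insert_index)


@dataclass
class GraftDesign:
    windows: list[GraftWindow]
    chimera_sequence: str
    insert_segments: list[str]      # one per window, insert subsequence
    provenance: list[str]           # per chimera position: "scaffold"/"insert"
    design_id: str = ""

    def __post_init__(self) -> None:
        if len(self.provenance) != len(self.chimera_sequence):
            raise ValueError("provenance must tag every chimera position")


@dataclass
class DesignSet:
    designs: list[GraftDesign]

    def __post_init__(self) -> None:
        seqs = [d.chimera_sequence for d in self.designs]
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate chimera sequences in design set")

    def __len__(self) -> int:
        return len(self.designs)

    def sequences(self) -> set[str]:
        return {d.chimera_sequence for d in self.designs}


# --- boundary exploration ----------------------------------------------


def _flank_candidates(flank_s: Region, flank_i: Region, flank: str,
                      pairing: Pairing, coords_s: np.ndarray,
                      coords_i: np.ndarray) -> list[BoundaryCandidate]:
    i2j = pairing.i_to_j()
    dist_of = {(p.i, p.j): p.distance for p in pairing.pairs}
    pair_is = sorted(i2j)
    pair_js = sorted(i2j.values())
    j2i = pairing.j_to_i()

    def euclid(i: int, j: int) -> float:
        return float(np.linalg.norm(coords_s[i] - coords_i[j]))

    candidates: dict[tuple[int, int], BoundaryCandidate] = {}

    # scaffold-side walk: paired positions and scaffold residues opposite
    # an insert gap
    for i in flank_s.indices():
        if i in i2j:
            j = i2j[i]
            if j in flank_i:
                candidates.setdefault(
                    (i, j),
                    BoundaryCandidate(i, j, flank, False, dist_of[(i, j)]),
                )
        else:
            anterior = max((k for k in pair_is if k < i), default=None)
            posterior = min((k for k in pair_is if k > i), default=None)
            options = [i2j[k] for k in (anterior, posterior) if k is not None]
            options = [j for j in options if j in flank_i]
            if not options:
                continue
            # shorter distance wins; tie broken toward the anterior residue
            j = min(options, key=lambda j_: (euclid(i, j_), options.index(j_)))
            candidates.setdefault(
                (i, j), BoundaryCandidate(i, j, flank, True, euclid(i, j))
            )

    # insert-side gaps: unpaired insert residues opposite a scaffold gap
    for j in flank_i.indices():
        if j in j2i:
            continue
        anterior = max((k for k in pair_js if k < j), default=None)
        posterior = min((k for k in pair_js if k > j), default=None)
        options = [j2i[k] for k in (anterior, posterior) if k is not None]
        options = [i for i in options if i in flank_s]
        if not options:
            continue
        i = min(options, key=lambda i_: (euclid(i_, j), options.index(i_)))
        candidates.setdefault(
            (i, j), BoundaryCandidate(i, j, flank, True, euclid(i, j))
        )

    out = list(candidates.values())
    # distal -> proximal order: ascending scaffold index on the N flank,
    # descending on the C flank
    reverse = flank == "C"
    out.sort(key=lambda c: (c.scaffold_index, c.insert_index), reverse=reverse)
    return out


def boundary_candidates(loop_s: LoopRegion, loop_i: LoopRegion,
                        pairing: Pairing, coords_s: np.ndarray,
                        coords_i: np.ndarray
                        ) -> tuple[list[BoundaryCandidate],
                                   list[BoundaryCandidate]]:
    """Candidate recombination points for one loop, per flank, ordered
    distal to proximal.  A flank with no usable pairing yields an empty
    list and a warning (the loop is not graftable)."""
    n_list = _flank_candidates(loop_s.n_flank.region, loop_i.n_flank.region,
                               "N", pairing, coords_s, coords_i)
    c_list = _flank_candidates(loop_s.c_flank.region, loop_i.c_flank.region,
                               "C", pairing, coords_s, coords_i)
    if not n_list or not c_list:
        warnings.warn(
            f"loop {loop_s.loop_id}: no boundary candidates on the "
            f"{'N' if not n_list else 'C'} flank; loop not graftable",
            stacklevel=2,
        )
    return n_list, c_list


# --- chimera assembly ---------------------------------------------------


def build_chimera(scaffold_seq: str, insert_seq: str,
                  windows: list[GraftWindow]) -> tuple[str, list[str], list[str]]:
    """Assemble the chimeric sequence for a set of non-overlapping windows.

    Returns (chimera sequence, per-position provenance, per-window insert
    segments).  Positions outside every window are identical to the
    scaffold; chimera length = scaffold - sum(excised) + sum(inserted).
    """
    ordered = sorted(windows, key=lambda w: w.scaffold_removed.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.scaffold_removed.stop > b.scaffold_removed.start:
            raise ValueError("overlapping graft windows")
    seq: list[str] = []
    prov: list[str] = []
    segments: list[str] = []
    pos = 0
    for w in ordered:
        head = scaffold_seq[pos:w.scaffold_removed.start]
        seq.append(head)
        prov.extend(["scaffold"] * len(head))
        piece = insert_seq[w.insert_kept.start:w.insert_kept.stop]
        seq.append(piece)
        prov.extend(["insert"] * len(piece))
        segments.append(piece)
        pos = w.scaffold_removed.stop
    tail = scaffold_seq[pos:]
    seq.append(tail)
    prov.extend(["scaffold"] * len(tail))
    # report segments in input window order
    order = sorted(range(len(windows)),
                   key=lambda k: windows[k].scaffold_removed.start)
    inverse = [segments[order.index(k)] for k in range(len(windows))]
    return "".join(seq), prov, inverse


def enumerate_designs(loop_s: LoopRegion, loop_i: LoopRegion,
                      pairing: Pairing, scaffold: ChainStructure,
                      insert: ChainStructure,
                      inclusive: bool = False) -> DesignSet:
    """All N x C boundary combinations for one loop, filtered for novelty.

    A combination is accepted only if the resulting chimera differs from
    the scaffold sequence and from every previously accepted design.
    Enumeration order is deterministic (N candidates outer, C inner, each
    distal to proximal)."""
    n_list, c_list = boundary_candidates(
        loop_s, loop_i, pairing, scaffold.coords, insert.coords
    )
    seen = {scaffold.sequence}
    designs: list[GraftDesign] = []
    for nb in n_list:
        for cb in c_list:
            if not (nb.scaffold_index < cb.scaffold_index
                    and nb.insert_index < cb.insert_index):
                continue
            window = GraftWindow(loop_s.loop_id, nb, cb, inclusive)
            seq, prov, segs = build_chimera(
                scaffold.sequence, insert.sequence, [window]
            )
            if seq in seen:
                continue
            seen.add(seq)
            designs.append(GraftDesign([window], seq, segs, prov))
    _assign_ids(designs, prefix=f"L{loop_s.loop_id}")
    return DesignSet(designs)


def combine(sets: list[DesignSet], scaffold: ChainStructure,
            insert: ChainStructure) -> DesignSet:
    """Cross product of per-loop design sets into multi-window designs.

    Windows of different loops must not overlap on the scaffold; the
    novelty filter is re-applied to the merged sequences."""
    if len(sets) == 1:
        return sets[0]
    import itertools

    seen = {scaffold.sequence}
    designs: list[GraftDesign] = []
    for combo in itertools.product(*[s.designs for s in sets]):
        windows = [w for d in combo for w in d.windows]
        loop_ids = [w.loop_id for w in windows]
        if len(set(loop_ids)) != len(loop_ids):
            raise ValueError("combined sets must address disjoint loops")
        seq, prov, segs = build_chimera(
            scaffold.sequence, insert.sequence, windows
        )
        if seq in seen:
            continue
        seen.add(seq)
        designs.append(GraftDesign(list(windows), seq, segs, prov))
    loop_ids = sorted({w.loop_id for s in sets for d in s.designs
                       for w in d.windows})
    _assign_ids(designs, prefix="+".join(f"L{i}" for i in loop_ids))
    return DesignSet(designs)


def _assign_ids(designs: list[GraftDesign], prefix: str) -> None:
    width = max(3, len(str(len(designs))))
    for k, d in enumerate(designs, start=1):
        d.design_id = f"{prefix}_{k:0{width}d}"


# --- partial structures and modelling inputs ---------------------------


def excised_scaffold_structure(scaffold: ChainStructure,
                               windows: list[GraftWindow]) -> str:
    """Single PDB fragment of the scaffold with every replaced span
    omitted (one file regardless of how many loops are grafted)."""
    removed = sorted(windows, key=lambda w: w.scaffold_removed.start)
    for a, b in zip(removed, removed[1:]):
        if a.scaffold_removed.stop > b.scaffold_removed.start:
            raise ValueError("overlapping graft windows")
    keep: list[Region] = []
    pos = 0
    for w in removed:
        if w.scaffold_removed.start > pos:
            keep.append(Region(pos, w.scaffold_removed.start - 1))
        pos = max(pos, w.scaffold_removed.stop)
    if pos < len(scaffold):
        keep.append(Region(pos, len(scaffold) - 1))
    return write_fragment(scaffold, keep)


def insert_structures(insert: ChainStructure,
                      windows: list[GraftWindow]) -> list[str]:
    """One PDB fragment per window containing exactly the grafted insert
    residues."""
    out = []
    for w in windows:
        span = w.insert_kept
        keep = [Region(span.start, span.stop - 1)] if len(span) else []
        out.append(write_fragment(insert, keep))
    return out


def write_pir(design: GraftDesign, scaffold: ChainStructure,
              insert: ChainStructure) -> str:
    """PIR alignment for comparative modelling: the excised-scaffold
    template, one insert template per window, and the chimera target.

    Columns follow the chimera (ungapped in the target row); each chimera
    position aligns to its provenance reference, so the scaffold row
    restricted to scaffold-provenance columns reproduces the retained
    scaffold residues and each insert row covers exactly its window."""
    n = len(design.chimera_sequence)
    scaffold_row = [
        c if p == "scaffold" else "-"
        for c, p in zip(design.chimera_sequence, design.provenance)
    ]
    # locate each window's column span in order of scaffold position
    ordered = sorted(range(len(design.windows)),
                     key=lambda k: design.windows[k].scaffold_removed.start)
    insert_rows = []
    col = 0
    prov = design.provenance
    spans = []
    k = 0
    while k < n:
        if prov[k] == "insert":
            start = k
            while k < n and prov[k] == "insert":
                k += 1
            spans.append((start, k))
        else:
            k += 1
    if len(spans) != len(design.windows):
        raise ValueError("design provenance inconsistent with windows")
    for (start, stop), widx in zip(spans, ordered):
        w = design.windows[widx]
        row = ["-"] * n
        row[start:stop] = design.chimera_sequence[start:stop]
        first = insert.residues[w.insert_kept.start].auth_label \
            if len(w.insert_kept) else ""
        last = insert.residues[w.insert_kept.stop - 1].auth_label \
            if len(w.insert_kept) else ""
        insert_rows.append((f"insert_w{widx + 1}", first, last, "".join(row)))

    def entry(name: str, kind: str, seq: str, first="", last="",
              chain="") -> str:
        lines = [f">P1;{name}",
                 f"{kind}:{name}:{first}:{chain}:{last}:{chain}::::"]
        for k0 in range(0, len(seq) + 1, 60):
            chunk = seq[k0:k0 + 60]
            if k0 + 60 > len(seq):
                chunk += "*"
            lines.append(chunk)
        return "\n".join(lines)

    parts = [
        entry("scaffold_excised", "structureX", "".join(scaffold_row),
              scaffold.residues[0].auth_label,
              scaffold.residues[-1].auth_label, scaffold.chain_id),
    ]
    for name, first, last, row in insert_rows:
        parts.append(entry(name, "structureX", row, first, last,
                           insert.chain_id))
    target = design.design_id or "chimera"
    parts.append(entry(target, "sequence", design.chimera_sequence))
    return "\n\n".join(parts) + "\n"


def design_table(sets: dict[str, DesignSet], scaffold: ChainStructure,
                 insert: ChainStructure) -> pd.DataFrame:
    """Flat TSV-ready summary of every design across one or more sets."""
    rows = []
    for set_name, dset in sets.items():
        for d in dset.designs:
            for w in d.windows:
                span = w.insert_kept
                ins_range = (
                    f"{insert.residues[span.start].auth_label}-"
                    f"{insert.residues[span.stop - 1].auth_label}"
                    if len(span) else "(deletion)"
                )
                rows.append(
                    {
                        "set": set_name,
                        "design_id": d.design_id,
                        "loop_id": w.loop_id,
                        "scaffold_n_auth":
                            scaffold.residues[w.n_boundary.scaffold_index].auth_label,
                        "scaffold_c_auth":
                            scaffold.residues[w.c_boundary.scaffold_index].auth_label,
                        "insert_n_auth":
                            insert.residues[w.n_boundary.insert_index].auth_label,
                        "insert_c_auth":
                            insert.residues[w.c_boundary.insert_index].auth_label,
                        "insert_range": ins_range,
                        "insert_segment":
                            d.insert_segments[d.windows.index(w)],
                        "chimera_length": len(d.chimera_sequence),
                    }
                )
    return pd.DataFrame(rows)
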