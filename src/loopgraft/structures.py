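"""Chain structures, secondary-structure labels and residue regions.

The whole pipeline is alpha-carbon based: every downstream computation
(pairing distances, elastic network models, boundary exploration) consumes
CA positions only, so full-atom records are read but only the CA of each
residue is retained.  Residues carry their author numbering (plus insertion
code) for reporting, while all internal computation uses 0-based contiguous
indices.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Region:
    """Inclusive 0-based residue index range [start, end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid region [{self.start}, {self.end}]")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def indices(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, idx: object) -> bool:
        return isinstance(idx, (int, np.integer)) and self.start <= idx <= self.end

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Residue:
    index: int
    auth_number: int
    insertion_code: str
    aa: str
    ca: np.ndarray

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca, dtype=float)
        if ca.shape != (3,) or not np.all(np.isfinite(ca)):
            raise ValueError("ca must be a finite 3-vector")
        object.__setattr__(self, "ca", ca)
        if self.aa not in STANDARD_AA and self.aa != "X":
            raise ValueError(f"unknown amino-acid letter {self.aa!r}")

    @property
    def auth_label(self) -> str:
        return f"{self.auth_number}{self.insertion_code}"


@dataclass
class ChainStructure:
    """Ordered CA-only record of one protein chain."""

    chain_id: str
    residues: list[Residue]
    source_id: str = ""
    n_skipped: int = 0  # residues dropped on load (no CA)

    def __post_init__(self) -> None:
        for k, res in enumerate(self.residues):
            if res.index != k:
                raise ValueError("residue indices must be 0..N-1 in order")
        keys = [(r.auth_number, r.insertion_code) for r in self.residues]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (auth_number, insertion_code) in chain")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """N x 3 array of CA coordinates (copy)."""
        return np.array([r.ca for r in self.residues], dtype=float)

    def index_of_auth(self, auth_number: int, insertion_code: str = "") -> int:
        for r in self.residues:
            if r.auth_number == auth_number and r.insertion_code == insertion_code:
                return r.index
        raise KeyError(f"no residue with author number {auth_number}{insertion_code}")

    def region_from_auth(self, start_auth: int, end_auth: int) -> Region:
        """Translate an author-numbering range into an index Region."""
        return Region(self.index_of_auth(start_auth), self.index_of_auth(end_auth))

    def subset(self, keep: list[Region]) -> "ChainStructure":
        """New chain containing only residues inside ``keep`` (re-indexed)."""
        _check_disjoint(keep)
        picked = sorted({i for reg in keep for i in reg.indices()})
        if picked and picked[-1] >= len(self):
            raise IndexError("region exceeds chain length")
        residues = [
            replace(self.residues[i], index=k) for k, i in enumerate(picked)
        ]
        return ChainStructure(self.chain_id, residues, self.source_id)


def _check_disjoint(regions: list[Region]) -> None:
    ordered = sorted(regions, key=lambda r: r.start)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise ValueError(f"overlapping regions {a} and {b}")


def load_chain(pdb_text: str, chain_id: str, model_index: int = 0) -> ChainStructure:
    """Extract the CA trace of one chain from PDB-format text.

    Only ATOM records are considered (HETATM excluded); for alternate
    locations the first listed conformer is used; residues lacking a CA
    are skipped with a warning and counted in ``n_skipped``.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("PDB text contains no models")
    if model_index >= len(structure):
        raise ValueError(
            f"model {model_index} not present ({len(structure)} models)"
        )
    model = structure[model_index]
    chain = model.find_chain(chain_id)
    if chain is None:
        available = ", ".join(ch.name for ch in model) or "(none)"
        raise KeyError(
            f"chain {chain_id!r} not found; available chains: {available}"
        )
    residues: list[Residue] = []
    skipped = 0
    for res in chain:
        if res.het_flag != "A":  # ATOM records only
            continue
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom  # first-listed altloc wins
                break
        if ca is None:
            skipped += 1
            continue
        aa = _THREE_TO_ONE.get(res.name.upper(), "X")
        residues.append(
            Residue(
                index=len(residues),
                auth_number=res.seqid.num,
                insertion_code=(res.seqid.icode or "").strip(),
                aa=aa,
                ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
            )
        )
    if skipped:
        warnings.warn(
            f"chain {chain_id}: skipped {skipped} residue(s) without CA",
            stacklevel=2,
        )
    cs = ChainStructure(
        chain_id,
        residues,
        source_id=f"{structure.name or 'pdb'}:{chain_id}",
    )
    cs.n_skipped = skipped
    return cs


# --- DSSP ---------------------------------------------------------------

#: DSSP 8-state to 3-state collapse: helices to H, strands/bridges to E,
#: everything aperiodic (turn, bend, blank, PPII) to C.
DSSP_TO_3STATE = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E"}


def parse_dssp(dssp_text: str, chain_id: str,
               chain: ChainStructure | None = None) -> str:
    """Three-state secondary-structure string for one chain of a classic
    DSSP output file.

    If ``chain`` is given, the DSSP rows are checked one-to-one against its
    residues (author numbering) and a mismatch raises with the offending
    residues listed.
    """
    from Bio.PDB.DSSP import make_dssp_dict
    import tempfile, os

    with tempfile.NamedTemporaryFile("w", suffix=".dssp", delete=False) as fh:
        fh.write(dssp_text)
        path = fh.name
    try:
        dssp_dict, keys = make_dssp_dict(path)
    finally:
        os.unlink(path)

    rows = [(key, dssp_dict[key]) for key in keys if key[0] == chain_id]
    if not rows:
        raise KeyError(f"chain {chain_id!r} not present in DSSP output")
    labels = "".join(DSSP_TO_3STATE.get(row[1][1], "C") for row in rows)

    if chain is not None:
        dssp_ids = [(key[1][1], (key[1][2] or " ").strip()) for key, _ in rows]
        chain_ids_ = [(r.auth_number, r.insertion_code) for r in chain.residues]
        if dssp_ids != chain_ids_:
            missing = sorted(set(chain_ids_) ^ set(dssp_ids))
            raise ValueError(
                f"DSSP rows do not match chain residues; unmatched: {missing}"
            )
    return labels


def check_labels(labels: str, chain: ChainStructure) -> str:
    if len(labels) != len(chain):
        raise ValueError(
            f"label string length {len(labels)} != chain length {len(chain)}"
        )
    if set(labels) - set("HEC"):
        raise ValueError("labels must be over alphabet {H, E, C}")
    return labels


def apply_sse_overrides(labels: str,
                        overrides: list[tuple[Region, str]]) -> str:
    """Replace labels inside each region; later overrides win."""
    out = list(labels)
    for region, label in overrides:
        if label not in "HEC" or len(label) != 1:
            raise ValueError(f"override label must be H, E or C, got {label!r}")
        if region.end >= len(out):
            raise IndexError(f"override region {region} outside chain of "
                             f"length {len(out)}")
        for i in region.indices():
            out[i] = label
    return "".join(out)


# --- PDB writing --------------------------------------------------------

def write_fragment(structure: ChainStructure, keep: list[Region]) -> str:
    """PDB text of the CA trace restricted to the kept regions.

    Author numbering is preserved, so chain breaks are implied by numbering
    gaps.  Regions must not overlap.
    """
    _check_disjoint(keep)
    picked = sorted({i for reg in keep for i in reg.indices()})
    if picked and picked[-1] >= len(structure):
        raise IndexError("keep region exceeds chain length")

    st = gemmi.Structure()
    st.name = structure.source_id or "fragment"
    model = gemmi.Model(1)
    chain = gemmi.Chain(structure.chain_id or "A")
    for i in picked:
        res = structure.residues[i]
        g = gemmi.Residue()
        g.name = _ONE_TO_THREE.get(res.aa, "UNK")
        g.seqid = gemmi.SeqId(res.auth_number, res.insertion_code or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*res.ca)
        atom.occ = 1.0
        atom.b_iso = 0.0
        g.add_atom(atom)
        chain.add_residue(g)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()
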