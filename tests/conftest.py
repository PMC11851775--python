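import numpy as np
import pytest

from loopgraft import (
    ChainStructure,
    Region,
    Residue,
    ToyArchitecture,
    make_homolog_pair,
)


def make_chain(coords, sequence=None, chain_id="A", auth_start=1):
    coords = np.asarray(coords, dtype=float)
    if sequence is None:
        sequence = "A" * len(coords)
    residues = [
        Residue(index=k, auth_number=auth_start + k, insertion_code="",
                aa=sequence[k], ca=coords[k])
        for k in range(len(coords))
    ]
    return ChainStructure(chain_id, residues, source_id="test")


def minimal_pdb(records):
    """PDB text from (serial, atom, altloc, resname, chain, resnum, xyz)."""
    lines = []
    for serial, name, altloc, resname, chain, resnum, (x, y, z) in records:
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s}{altloc:1s}{resname:<3s} "
            f"{chain:1s}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {name[0]:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def dssp_text(rows):
    """Classic DSSP output from (resnum, chain, aa, ss) rows."""
    header = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "REFERENCE ...",
        "HEADER test",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA"
        "   Y-CA   Z-CA",
    ]
    body = []
    for k, (resnum, chain, aa, ss) in enumerate(rows, start=1):
        line = f"{k:5d}{resnum:5d} {chain:1s} {aa:1s}  {ss:1s}"
        line += " " * (34 - len(line))
        line += f"{0:4d}"                                    # acc
        line += f"{0:7d},{0.0:4.1f}" + f"{0:6d},{0.0:4.1f}" * 3  # H bonds
        line += " " * 20
        line += f"{0.0:6.1f}{0.0:6.1f}"                      # phi, psi
        body.append(line)
    return "\n".join(header + body) + "\n"


@pytest.fixture
def triangle_coords():
    """Equilateral triangle with unit side, well inside the GNM cutoff."""
    return np.array([[0.0, 0.0, 0.0],
                     [1.0, 0.0, 0.0],
                     [0.5, np.sqrt(3) / 2, 0.0]])


@pytest.fixture
def toy_pair():
    """Noisy homolog pair with coil 2 swapped from 6 to 9 residues."""
    return make_homolog_pair(ToyArchitecture(seed=7), swap=(3, 9))


@pytest.fixture
def clean_pair():
    """Noise-free identical pair (identity ground truth)."""
    return make_homolog_pair(ToyArchitecture(seed=3, noise_sigma=0.0))


POOL_S = "ACDEFGHIKL"
POOL_I = "MNPQRSTVWY"


@pytest.fixture
def divergent_pair():
    """Identical geometry but fully divergent sequences (disjoint letter
    pools), so every recombination-point combination yields a distinct
    chimera sequence.  Three loops; loops 1 and 3 share no flank."""
    arch = ToyArchitecture(
        blueprint=(("H", 10), ("C", 6), ("H", 12), ("C", 6), ("H", 10),
                   ("C", 6), ("H", 10)),
        seed=11, noise_sigma=0.0,
    )
    pair = make_homolog_pair(arch)
    n = arch.total_length
    seq_s = "".join(POOL_S[k % 10] for k in range(n))
    seq_i = "".join(POOL_I[k % 10] for k in range(n))
    scaffold = make_chain(pair.scaffold.coords, seq_s, "A")
    insert = make_chain(pair.insert.coords, seq_i, "B")
    return arch, scaffold, insert
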