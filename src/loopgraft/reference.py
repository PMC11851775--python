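"""Runner for the published luciferase/dehalogenase study configuration.

Reproduces the design enumeration for grafting Renilla luciferase loops
onto the bifunctional dehalogenase/luciferase ancestor scaffold: scaffold
PDB 6G75 chain A, insert PDB 2PSF chain B, loops L9 (scaffold residues
135-166, with the short helical element at 151-153 treated as coil) and
L14 (residues 210-244), pairing threshold T = 1.9 Å and offset filter
width 4 SD.  The two structures must be supplied by the user (downloaded
from RCSB and superposed externally, e.g. with CE, into a common frame)
along with DSSP outputs for both chains; nothing is downloaded here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .grafting import DesignSet, combine, enumerate_designs
from .loops import build_loops, loop_by_region, match_insert_loop, segment
from .pairing import PairingParams, pair_structures
from .structures import apply_sse_overrides, load_chain, parse_dssp

#: Scaffold supersecondary regions selected in the study, author numbering.
L9_AUTH = (135, 166)
L14_AUTH = (210, 244)
#: Short helical element inside L9 treated as coil.
L9_COIL_OVERRIDE_AUTH = (151, 153)


@dataclass
class ReferenceResult:
    l9: DesignSet
    l14: DesignSet
    combined: DesignSet
    pairing_size: int

    @property
    def counts(self) -> dict[str, int]:
        total = len(self.l9) + len(self.l14) + len(self.combined)
        return {
            "l9_only": len(self.l9),
            "l14_only": len(self.l14),
            "combined": len(self.combined),
            "total": total,
        }


def reference_design_counts(scaffold_pdb: str, insert_pdb: str,
                            scaffold_dssp: str, insert_dssp: str,
                            scaffold_chain: str = "A",
                            insert_chain: str = "B") -> ReferenceResult:
    """Full enumeration for the study setup on pre-superposed inputs.

    ``scaffold_pdb``/``insert_pdb`` are PDB texts already in a common
    frame; ``scaffold_dssp``/``insert_dssp`` are classic DSSP outputs.
    """
    scaffold = load_chain(scaffold_pdb, scaffold_chain)
    insert = load_chain(insert_pdb, insert_chain)
    labels_s = parse_dssp(scaffold_dssp, scaffold_chain, scaffold)
    labels_i = parse_dssp(insert_dssp, insert_chain, insert)
    labels_s = apply_sse_overrides(
        labels_s,
        [(scaffold.region_from_auth(*L9_COIL_OVERRIDE_AUTH), "C")],
    )

    params = PairingParams(distance_threshold=1.9, offset_sd_multiplier=4.0)
    pairing = pair_structures(scaffold, insert, None, params)

    loops_s = build_loops(segment(labels_s))
    loops_i = build_loops(segment(labels_i))
    l9_s = loop_by_region(loops_s, scaffold.region_from_auth(*L9_AUTH))
    l14_s = loop_by_region(loops_s, scaffold.region_from_auth(*L14_AUTH))
    l9_i = match_insert_loop(l9_s, loops_i, pairing)
    l14_i = match_insert_loop(l14_s, loops_i, pairing)

    l9_set = enumerate_designs(l9_s, l9_i, pairing, scaffold, insert)
    l14_set = enumerate_designs(l14_s, l14_i, pairing, scaffold, insert)
    both = combine([l9_set, l14_set], scaffold, insert)
    return ReferenceResult(l9_set, l14_set, both, len(pairing))
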