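# Reference structures (user-supplied)

The full-scale enumeration check and the `loopgraft` reference runner
(`loopgraft.reference`) operate on the two published crystal structures,
which cannot be redistributed with this repository:

- scaffold: RCSB PDB **6G75**, chain A (dehalogenase/luciferase ancestor)
- insert: RCSB PDB **2PSF**, chain B (Renilla luciferase 8, closed form)

To enable them, place here:

| file | content |
| --- | --- |
| `6g75_superposed.pdb` | 6G75 in the common frame (reference frame) |
| `2psf_superposed.pdb` | 2PSF superposed onto 6G75 (e.g. with CE) |
| `6g75.dssp` | classic DSSP output for 6G75 |
| `2psf.dssp` | classic DSSP output for 2PSF |

The design enumeration is sensitive to the superposition engine; the
published counts were obtained from a CE superposition.
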