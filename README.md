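# loopgraft

Loop grafting transplants a loop — an aperiodic coil together with its two
flanking regular secondary-structure elements — from a donor protein (the
*insert*) into a homologous acceptor (the *scaffold*), aiming to transfer
dynamic behaviour such as the hinge motion that gates a luciferase active
site. `loopgraft` implements the computational side of that workflow for
structural biologists and enzyme engineers:

1. **Secondary structure definition** — DSSP labels collapsed to three
   states (H/E/C), with manual per-range overrides.
2. **Loop exploration** — supersecondary segmentation; consecutive loops
   share a flank (the C-terminal SSE of loop *n* is the N-terminal SSE of
   loop *n*+1).
3. **Flexibility evaluation** — Gaussian and anisotropic elastic network
   models (GNM/ANM) on the Cα trace: mean-square fluctuations
   ⟨(Δ*R*ᵢ)²⟩, predicted B factors *B*ᵢ = (8π²/3)·⟨(Δ*R*ᵢ)²⟩, and
   normalized motion cross-correlations
   *C*ᵢⱼ = ⟨Δ*R*ᵢ·Δ*R*ⱼ⟩ / √(⟨Δ*R*ᵢ²⟩⟨Δ*R*ⱼ²⟩).
4. **Geometric sequence pairing** — from a structural superposition, a
   greedy algorithm pairs the globally closest Cα atoms subject to a
   distance threshold *T* (default 1.9 Å), repairs sequence order by a
   minimal unpairing (weighted longest-increasing-subsequence), and drops
   pairs whose sequence offset *i*−*j* deviates from the mean by more
   than 4 standard deviations of the offset distribution.
5. **Recombination-point enumeration** — every aligned flank position is
   a candidate boundary (gapped positions resolve to the nearer
   gap-flanking residue); the N×C cross product of boundaries yields
   chimeric sequences, kept only when they are novel; multi-loop designs
   are the products of per-loop design sets.
6. **Stability evaluation** — external per-design score tables (DOPE,
   Rosetta FastRelax; lower = more stable) are ingested and ranked, with
   joint and sequential grafting selection strategies.

The package also emits everything a comparative-modelling step needs:
excised-scaffold and insert partial structures (PDB) and per-design PIR
alignments. External modelling/relax programs are never invoked.

## Worked example

Generate a synthetic homolog pair (a helix/coil toy whose second coil was
replaced by a longer divergent coil), pair it, and enumerate designs:

```bash
loopgraft demo --seed 5 --outdir fixtures
cat > config.yaml <<'YAML'
scaffold: {file: fixtures/scaffold.pdb, chain: A}
insert: {file: fixtures/insert.pdb, chain: B}
presuperposed: true
sse:
  scaffold: {labels: "HHHHHHHHHHCCCCCCHHHHHHHHHHHHCCCCCCHHHHHHHHHH"}
  insert:   {labels: "HHHHHHHHHHCCCCCCHHHHHHHHHHHHCCCCCCCCCHHHHHHHHHH"}
loops:
  - {scaffold: [17, 44], insert: [17, 47]}
outdir: out
YAML
loopgraft pair --config config.yaml
loopgraft graft --config config.yaml
```

which prints

```
paired 39 residues (T=1.9 Å); outputs in out
designs: L2=1, total=1; outputs in out
```

39 of 44 scaffold residues found a partner within 1.9 Å (most of the
replaced coil lies beyond the threshold and stays unpaired).  The loop
spanning scaffold residues 17–44 yields exactly one novel chimera: the
insert's flanks are sequence-identical to the scaffold's here, so every
boundary combination produces the same chimeric sequence — the novelty
filter keeps one and discards the rest.  With a sequence-divergent
insert, the same enumeration returns the full N×C cross product of
boundary combinations.  `out/designs.tsv` lists each design's
boundary residues on both chains, the transplanted insert segment and the
chimera length; `out/chimeras.fasta`, `out/alignments/*.pir` and
`out/partial_structures/*.pdb` feed a comparative-modelling step, whose
scores return via `loopgraft select`.

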