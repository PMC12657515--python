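# qmmdock

Hybrid QM/MM rescoring of protein–ligand docking poses, as a
self-contained, desk-scale engine:

- **Subtractive QM/MM energies** with electrostatic embedding: the
  primary system (PS) is evaluated by a pluggable QM backend in the
  field of scaled secondary-system (SS) point charges; boundary bonds
  are capped with hydrogen link atoms and the first classical neighbor's
  embedding charge is zeroed. For engines that fold the SS
  self-repulsion into their energy (HF/DFT-like), the term is subtracted
  a posteriori.
- **PS selection modes**: ligand only (covalently bound protein residues
  are added automatically), ligand + nearby metals (≤ 5 Å) with their
  coordinating residues, and ligand + every residue with an atom inside
  a cubic box; side-chain-only boundaries cut at Cα–Cβ, backbone
  inclusion cuts at C–Cα.
- **Classical and hybrid MM-GBSA-style scores** (intra-ligand +
  flexible-receptor + cross vdW/electrostatics + GB/SA solvation, with
  an optional Morse-like metal binding potential), with solvation
  charges taken from the force field or from the engine's QM-derived
  (Mulliken-like) charges.
- **Pose workflow**: greedy leader clustering by symmetry-adapted RMSD,
  best-of-N / all-of-N cluster selection with native-pose augmentation,
  quasi-Newton pose optimization with monotone-descent guarantees, and
  second-level refinement (single-point or short optimization).
- **Evaluation & curation**: symmetry-adapted RMSD over graph
  automorphisms (no superposition, heavy atoms only), redocking success
  at 1.5 Å (inclusive) on the best-scored converged pose,
  scoring-failure detection against the relaxed native score,
  converged-only success rates, and the full structure/ligand quality
  filter stack for benchmark metadata tables.

Two QM backends ship built in, so the whole scheme is testable without
any external program: `mirror-mm` (an oracle that answers with exactly
the MM energies, making the hybrid score provably identical to the
classical one) and `eem` (an electronegativity-equalization solver that
produces genuinely polarized, embedding-responsive charges). External
engines plug in through a documented file-exchange adapter contract.

A deterministic fixture generator (`qmmdock.fixtures`) builds small
parameterized pocket–ligand complexes — optionally with a divalent
metal site, a covalent anchor, or one explicit water — whose native
pose is a verified local minimum of the classical score. No downloads
are ever required.

## CLI

```bash
# build a synthetic complex (receptor.pdb, ligand.sdf, complex.pdb, params.yaml)
qmmdock fixtures make --seed 7 --ligand-size 3 --out-dir toy

# PS/SS partition -> PS PDB + embedding-charge TSV
qmmdock partition --complex toy/complex.pdb --params toy/params.yaml \
    --mode lig+MB --scale 0.5 --out-prefix part

# rescore a pose ensemble (cluster -> select -> optimize -> rank)
qmmdock rescore run --complex toy/complex.pdb --params toy/params.yaml \
    --poses poses.sdf --config run.yaml --seed 1 --out-prefix run

# evaluate and curate
qmmdock evaluate rmsd a.sdf b.sdf
qmmdock evaluate rank --poses run_poses.sdf --native toy/ligand.sdf
qmmdock curate filter records.tsv
```

`run.yaml` accepts nested keys mirroring the library defaults:
`ps.mode`, `ps.box_edge`, `ps.sidechain_only`, `ps.link_length`,
`ps.metal_cutoff`, `ps.coordination_cutoff`, `embedding.scale`,
`qm.method`, `qm.basis`, `qm.multiplicity`, `solv.dielectric_solute`,
`solv.gamma`, `solv.probe`, `nb.cutoff`, `mmbp.params`,
`cluster.radius`, `select.mode`, `select.n`, `opt.dof`, `opt.conv`,
`opt.max_steps`, `charge_source`.

## Conventions

Units are Å, kcal/mol, elementary charges; the Coulomb constant is
332.0637 kcal·Å/mol/e². Lennard-Jones uses the Rmin convention; 1-2 and
1-3 nonbonded pairs are excluded, 1-4 counts at full strength; plain
truncation at a 12 Å cutoff. The polar solvation surrogate is a
generalized-Born model (HCT pairwise-descreening radii, solute
dielectric 2, solvent 78.5); the nonpolar term is 0.015 kcal/mol/Å²
times a point-sampled SASA with a 1.4 Å probe. Receptors must come
pre-protonated: hydrogens are explicit everywhere, and no
protonation-state prediction is attempted.
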