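# channelsift

Structure/trajectory analysis toolkit for liganded pentameric ion channels:

* **9-bit protein–ligand interaction fingerprints** per residue, subunit and
  frame — apolar carbon contacts, face-to-face and edge-to-face aromatic
  stacking, hydrogen bonds with the protein as donor or acceptor,
  electrostatics with the protein group positive or negative, and one- and
  two-water-mediated hydrogen-bond bridges.
* **Bayesian uncertainty** for interaction probabilities from a two-state
  Markov model: transition counts pooled across subunits, conjugate Beta
  (symmetric Dirichlet) posteriors, stationary-probability credible
  intervals.
* **Conformational descriptors**: ligand-pose RMSD per subunit (whole ligand
  or a named substructure) after alignment on a configurable Cα core,
  binding-site loop backbone RMSD and orientation dihedral, salt-bridge gate
  distance with an engagement threshold, binding-site water counts, and
  per-residue Cα displacement maps with optional spline smoothing.
* **Pore-radius profiling**: the maximal-sphere radius along the channel
  axis (deterministic multi-start simplex + grid refinement instead of
  Monte-Carlo annealing), per structure or per trajectory frame, with
  cross-frame statistics.
* **Synthetic data generators** that plant each interaction type at exactly
  controlled geometry, drive per-frame occupancy with simulated two-state
  Markov chains, and build pore linings with analytically known radius
  profiles — so every stage is testable against ground truth.

Structures and trajectories are read and written as (multi-model) PDB;
coordinates are Å, times ps, residue numbering 1-based.

## CLI

All subcommands are driven by a YAML config (`output_dir`, `seed`,
`trajectory`, `ligand_spec`, optional overrides) and write CSV/JSON plus a
`manifest.json` (config hash + seed) for bit-identical reruns.

```sh
# generate a fully labeled synthetic scene bundle
channelsift simulate --out bundle/ --seed 7 --n-frames 200

# fingerprint it
cat > config.yaml <<EOF
trajectory: bundle/scene_trajectory.pdb
ligand_spec: bundle/ligand.yaml
output_dir: out/
seed: 7
EOF
channelsift fingerprint --config config.yaml

# descriptors and pore profiles use the same config shape
channelsift descriptors --config config.yaml
channelsift pore --config config.yaml

# end-to-end recovery self-check
channelsift validate --seed 1
```

Exit codes: 0 success, 2 validation error, 3 computation error.

## Library layout

| module | contents |
| --- | --- |
| `channelsift.structure` | PDB I/O, `Structure`/`Trajectory`, selections, bond inference |
| `channelsift.geometry` | dihedrals, ring planes, Kabsch superposition, RMSD, minimum distances |
| `channelsift.fingerprints` | the 9-bit classifier, water-bridge enumeration, trajectory fingerprinting |
| `channelsift.markov` | occupancy probabilities, Markov posterior errors, stability classes |
| `channelsift.descriptors` | pose RMSD, loop RMSD/dihedral, gate distance, water counts, displacement maps |
| `channelsift.pore` | maximal-sphere pore profiles and statistics |
| `channelsift.synthetic` | ground-truth scene/trajectory/pore generators |
| `channelsift.cli` | the `channelsift` command |
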