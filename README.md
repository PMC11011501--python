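# ligmodes

Analysis toolkit for protein–ligand molecular-dynamics trajectories, built
around the question of how an enzyme recognises a small charged substrate
when the recognising residues sit on flexible regions. The motivating
system is the human glycerol-3-phosphate acyltransferase GPAT4 binding its
substrate glycerol-3-phosphate (G3P): the phosphate group of G3P is
transiently trapped at several *hotspots* formed by arginines and lysines
(R427, K426, K365, K296, R292, R148, R374) near the catalytic histidine
H248, and the ligand hops between them over the course of the simulations.

The toolkit provides, as reusable library modules plus a CLI:

- **Contact frequencies** (`ligmodes.contacts`): the fraction of frames in
  which each residue has any heavy atom within a cutoff (default 3 Å) of
  the ligand's heavy atoms, pooled over trajectory copies.
- **Pose clustering** (`ligmodes.clustering`): Gromos/Daura greedy
  neighbour-count clustering of ligand poses under a ligand-RMSD cutoff
  (default 3 Å), computed in the receptor-aligned frame — each frame is
  first superposed onto a reference via a protein selection, then ligand
  RMSD is taken without re-fitting. Reports cluster sizes as percentages
  and extracts centroid structures.
- **Binding-mode assignment** (`ligmodes.modes`): the central analysis. A
  binding mode is a set of distance conditions from the ligand's
  phosphorus atom to anchor atoms (CZ for Arg, NZ for Lys, NE2 for His);
  a frame receives the highest-precedence mode whose conditions all hold
  (cutoffs 5 Å, except the H248 condition at 11 Å), with a dummy mode 6
  collecting everything else. Occupancies, a 1000-frame-per-copy timeline
  representation, and transition statistics (excluding concatenation
  boundaries) follow.
- **Ligand grafting** (`ligmodes.grafting`): build a complex model for a
  receptor with no resolved structure by superposing a resolved homolog
  complex onto the predicted apo model (Kabsch over matched atom
  selections) and transferring the ligand coordinates, then auditing the
  steric clashes that restrained minimisation must later fix.
- **Synthetic trajectories** (`ligmodes.synthetic`): a generator that
  emulates the hotspot-hopping statistics — a Markov chain over modes
  drives a rigid 10-heavy-atom ligand between hotspot points with
  Gaussian positional jitter — providing exact ground truth for every
  analysis stage.
- **Sequence utilities** (`ligmodes.sequences`): FASTA reading and motif
  search with `X` wildcards (e.g. the acyltransferase catalytic motif
  `HXXXXD`), 1-based positions.

## Worked example

Simulate eight-thousand frames of hotspot hopping with 0.5 Å jitter,
assign binding modes, and profile contacts:

```python
import numpy as np
import ligmodes as lm

receptor = lm.make_reference_receptor(seed=0)
spec = lm.SyntheticSpec(jitter_sigma=0.5, n_frames=8000, seed=42)
labels = lm.simulate_mode_walk(spec.transition_matrix, spec.n_frames,
                               seed=42, mode_ids=spec.mode_ids)
traj, truth = lm.emit_trajectory(receptor, labels, spec)

definitions = lm.default_mode_definitions()
anchors = sorted({a for d in definitions for a, _ in d.conditions},
                 key=lambda a: a.label)
table = lm.compute_distance_table(traj, "resname G3P and name P", anchors)
trace = lm.assign_modes(table, definitions)

print(lm.mode_occupancy(trace).round(2).to_string())
matrix, events = lm.transition_summary(trace)
print(f"transitions observed: {len(events)}")
print(f"label agreement with ground truth: "
      f"{100 * np.mean(trace.labels == labels):.2f}%")
```

prints

```
1    24.61
2    14.42
3    11.91
4    14.16
5    14.28
6    20.61
transitions observed: 148
label agreement with ground truth: 100.00%
```

The occupancies are the percentage of frames assigned to each binding
mode (they always sum to 100). This particular realisation hopped 148
times between hotspots, and every frame's assigned mode matched the
generator's hidden label — at 0.5 Å jitter the hotspot geometry leaves
≥ 2 Å of margin on every distance condition, so misassignment is rare
(guaranteed < 1% on average, usually far better).

Contact profiling on the same trajectory ranks R427 first
(`lm.rank_contacts(lm.contact_frequency(traj, "resname G3P"), 0.10)`),
at frequency 0.485 — it participates in modes 1, 3 and 5 — followed by
the per-hotspot probe residues whose frequencies equal the mode
occupancies by construction.

The same analyses are available from the shell:

```sh
ligmodes simulate --n-frames 8000 --sigma 0.5 --seed 42 --out sim/
ligmodes modes    --top sim/topology.pdb --traj sim/trajectory.pdb --out modes/
ligmodes timeline --top sim/topology.pdb --traj sim/trajectory.pdb --n 1000 --out tl/
```

Real trajectories are read the same way (`--top receptor.pdb --traj
copy1.xtc --traj copy2.xtc ...`); PDB, GRO, XTC, DCD and multi-model PDB
are supported, and mode profiles for other receptors are plain YAML files
(`--profile mymodes.yaml`).

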