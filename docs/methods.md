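# Methods

This note documents the models and procedures implemented in `ligmodes`,
the parameters that matter, the design decisions that were genuinely open,
and what the synthetic-data validation does and does not demonstrate.

## Contact frequencies

A residue is *in contact* with the ligand in a frame iff the minimum
heavy-atom/heavy-atom Euclidean distance between the residue and the
ligand is at or below the cutoff. The boundary is inclusive: "within
3 Å" is read as ≤ 3.0 Å. Hydrogens are excluded on both sides —
experimental structures typically lack them, and including them would
make frequencies incomparable between inputs with and without hydrogens.
Frequencies are pooled over all supplied trajectory copies (the pooled
frequency is exactly the frame-count-weighted mean of per-copy
frequencies, which is asserted by a test); a per-copy breakdown is
emitted alongside. Residue-centre or Cα-based contact definitions are
deliberately not offered: the atom-level minimum is the stricter and more
common convention, and switching conventions silently changes frequencies.

`rank_contacts` filters at a strict threshold (frequency > f), sorts
descending, and breaks ties by ascending residue number so output order
is deterministic.

## Receptor-aligned pose clustering

Ligand poses are compared in the receptor frame: every frame is
superposed onto a reference frame (frame 0 of the first trajectory by
default, or an external reference structure) by a least-squares fit over
a protein atom selection, and pairwise ligand RMSD is then computed
**without re-fitting the ligand**. This makes the RMSD sensitive to where
the ligand sits on the receptor, not merely to its internal conformation,
which is the property that distinguishes binding *poses*. RMSD is
unweighted (uniform atom weights) and matched by selection order; when
two ligands are selected together their atoms are concatenated into one
vector, so they are clustered jointly; selecting one ligand clusters it
alone. Pairwise RMSDs are computed via the flattened-coordinate identity
rmsd²(i,j) = ‖xᵢ − xⱼ‖²/L, which reduces the T×T matrix to one pairwise
squared-distance computation.

Clustering is the greedy neighbour-count (Gromos/Daura) algorithm: count,
for every unassigned frame, its unassigned neighbours within the cutoff
(inclusive); the frame with the most neighbours (lowest index on ties,
for determinism) becomes a centroid; it and its neighbours form the next
cluster and are removed; repeat. Formation order therefore has
non-increasing cluster sizes. Cluster sizes are reported as percentages
of the total frame count and always sum to 100. The implementation is
tested for exact equivalence with an independently written plain-loop
implementation on hundreds of random distance matrices.

Default cutoff: 3.0 Å ligand RMSD, appropriate for separating binding
poses of small ligands; it is a parameter everywhere.

## Binding-mode assignment

The central statistic. A *binding mode* is a set of conditions
(anchor atom, cutoff) on the distance from the ligand's phosphorus atom
to specific side-chain atoms: CZ for arginine, NZ for lysine, NE2 for
histidine. The shipped default profile encodes the G3P/GPAT4 hotspot
set:

| mode | conditions (distance ≤ cutoff)     | precedence |
|------|------------------------------------|------------|
| 1    | R427·CZ ≤ 5 Å and H248·NE2 ≤ 11 Å  | 1 |
| 2    | K296·NZ ≤ 5 Å and R292·CZ ≤ 5 Å    | 2 |
| 4    | R148·CZ ≤ 5 Å and R374·CZ ≤ 5 Å    | 3 |
| 5    | R427·CZ ≤ 5 Å and K365·NZ ≤ 5 Å    | 4 |
| 3    | R427·CZ ≤ 5 Å and K426·NZ ≤ 5 Å    | 5 |
| 6    | fallback (no conditions)           | 6 |

A frame is assigned the highest-precedence mode whose conditions all hold
(inclusive boundaries, consistent with "constantly below 5 Å" behaviour
at the threshold); frames matching nothing get mode 6. Assignment is a
pure function of the distance table and the definitions.

Design decisions that were genuinely open:

- **Precedence order 1 > 2 > 4 > 5 > 3 > 6.** Mode 1 (active site,
  gated by the H248 distance) is evaluated first because that distance
  cleanly separates active-site binding from everything else. Modes 2
  and 4 are defined by residue pairs unique to them; mode 5 precedes
  mode 3 so that mode 3 acts as the "still holding on to R427/K426 but
  not in any other mode" remainder class. The order among 2/4/5 is
  arbitrary — their hotspots are spatially disjoint, so simultaneous
  satisfaction is geometrically rare — and is configurable via the
  profile file.
- **Histidine "NE" → NE2.** Standard histidine has no atom literally
  named NE; NE2 (the ε-nitrogen, nearer the catalytic face) is the
  default and ND1 is selectable when constructing the anchor.
- **Mode definitions are data, not code**: a YAML profile (anchor label,
  residue id, atom, cutoff, precedence) so other receptors can be
  analysed with the same machinery.

Occupancy is 100·count/T per declared mode, including zero-count modes;
it always sums to 100 (asserted). For timeline presentation each source
trajectory is down-sampled to n = 1000 uniformly strided frames
(indices ⌊k·T/n⌋, always keeping the first frame); sources shorter than
n are kept whole with a warning. Transition counting excludes
consecutive-frame pairs that straddle a source boundary — such "changes"
are artefacts of concatenating independent copies — but boundaries are
drawn as ticks in the timeline plot. No Markov-state-model or lag-time
analysis is attempted: the outputs are label sequences and transition
counts only.

## Superposition and grafting

Superposition is SVD-based Kabsch with uniform weights and a determinant
guard that forbids reflections; degenerate inputs (< 3 points, collinear
sets detected by a vanishing second singular value) are errors. The
implementation is cross-checked against an independently implemented
quaternion (Horn) absolute-orientation solver.

Complex grafting builds a holo model for a receptor with no resolved
structure: the template complex (a resolved homolog with ligands) is
Kabsch-fitted onto the receptor over **explicitly supplied matched atom
selections** (e.g. shared-pocket Cα atoms) and the ligand residues are
carried through the fitted transform into a merged structure. Automatic
sequence-based pairing is deliberately out of scope so the alignment
stays auditable between non-identical sequences. The clash report lists
all protein-heavy/ligand-heavy pairs below a threshold (default 2.0 Å —
a conventional hard-overlap criterion, configurable), sorted by
distance; fixing them (restrained minimisation) is an upstream/downstream
step outside this package, as is rebuilding reactants from product
coordinates.

## Synthetic trajectory generator

The generator emulates the statistics the analyses consume, not the
physics that produced them. Its parts:

- **Geometry.** Eight anchor atoms at fixed coordinates. Modes 1, 3 and
  5 share R427, so H248 (12 Å from R427), K426 and K365 (5.83 Å from
  R427, symmetric) necessarily cluster around it; the mode-2 and mode-4
  anchor pairs and the detached mode-6 region are ≥ 15 Å from every
  other group. Each mode's geometry point is placed (midway between its
  anchor pair, or along the R427–H248 axis for mode 1) so that its own
  conditions hold with **≥ 2 Å margin** and every higher-precedence
  mode's condition set is violated with ≥ 2 Å margin; the `SyntheticSpec`
  validator recomputes this at construction and rejects geometries that
  break it.
- **Dynamics.** A Markov chain over modes. The default transition matrix
  is persistence-plus-redraw, T = (1−a)·I + a·1πᵀ with hop rate
  a = 0.02 per frame, whose stationary law π is exactly the default
  occupancy vector (32.3, 17.8, 9.1, 8.9, 13.2, 18.7)% for modes 1–6 —
  a realistic regime of long dwells with occasional hops. Because the
  chain is autocorrelated, finite-sample label frequencies differ from π;
  all recovery statements therefore compare against the *realised* label
  frequencies, which is the quantity the classifier can be held to.
- **Emission.** A rigid 10-heavy-atom ligand (one P atom at the centre,
  nine C/O atoms at 1 Å radius) is translated to the labelled mode's
  point plus one isotropic Gaussian displacement per frame (σ =
  `jitter_sigma`, default 0.5 Å). With ≥ 2 Å margins, a condition can
  only flip if the displacement magnitude exceeds the margin, so the
  per-frame misassignment probability is bounded by
  12·P(χ²₃ > (margin/σ)²) ≈ 1.4 % at σ = 0.5 (in practice far lower,
  since the bound ignores direction); the generator warns when the bound
  exceeds 5 %.
- **Contact probes.** One glycine per mode sits 1.2 Å above the mode
  point, so its contact with the ligand is equivalent to the ligand
  occupying that mode: its designed contact probability is the mode's
  label frequency. Designed-probability tests use σ = 0.25 Å because the
  contact criterion involves the whole 1 Å-radius ligand, which consumes
  part of the ~5 Å inter-hotspot spacing; at σ = 0.25 false contacts are
  negligible relative to the 3-standard-error test tolerance. A far
  glycine (60, 60, 60) provides a guaranteed zero-frequency control.
- **Pose blobs.** For clustering tests, k rigid poses (distinct seeded
  orientations, centres spaced `separation` apart) with per-atom
  Gaussian jitter, plus a static 4-atom scaffold so receptor alignment
  is well defined.

All generators are pure functions of their seeds; structures rewrite
byte-identically.

What passing these tests shows — and does not. They show the analysis
chain is *correct*: it recovers exactly the labels, occupancies,
transition counts, cluster memberships and contact probabilities that
generated the data, under noise levels where recovery is provably
possible. They do not show anything about force fields, sampling
convergence, or whether 3 Å / 5 Å / 11 Å are the right cutoffs for a
given real receptor — the synthetic ligand is rigid, the receptor is
static, jitter is isotropic and uncorrelated in time, and hotspots are
ideally separated, none of which holds in real MD.

## Numerical and I/O choices

- Units: Å internally everywhere; GRO input (nm) is scaled on read.
- Author residue numbering is authoritative and never rewritten.
- Periodic boundaries: trajectories are assumed pre-imaged
  (whole molecules, ligand near protein); no minimum-image correction.
- XTC output is written at 4 decimal places (nm), keeping coordinate
  round-trips below 0.001 Å; multi-model PDB round-trips at PDB's
  3-decimal Å precision.
- Selection grammar: `resid / resname / name / chain / element / heavy`
  with `and / or / not` and parentheses; malformed expressions report
  the character position. Unknown elements are inferred from atom names.
- Distance-matrix symmetry is enforced to 1e-9; rotation orthogonality
  to 1e-8; tie-breaks (clustering centroid choice, contact ranking) are
  always by lowest index/residue number for determinism.
- Problem sizes in the shipped validation: 10,000-frame mode-recovery
  runs, 5,000-frame contact runs, 200 random 12-frame matrices for the
  clustering oracle, 100 random point sets for the superposition oracle
  — sizes at which the binomial error bars in the tests are meaningful
  while the whole suite runs in seconds.

## Known limitations

- Superposition requires matched atom lists; there is no sequence-based
  structural alignment, so comparing non-identical proteins requires the
  caller to supply the residue correspondence.
- The mode classifier is purely geometric and memoryless; brief recrossings
  at a cutoff boundary count as transitions (no hysteresis or smoothing).
- `clash_report` is O(N·M) over protein × ligand heavy atoms — fine for
  single complexes, not intended for screening-scale batches.
- The synthetic receptor is rigid; analyses whose interest comes from
  receptor flexibility (e.g. the loop motion that carries R427) can only
  be validated for their bookkeeping here, not for their sensitivity to
  that motion.
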