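# Methods

## Model and assumptions

`sompath` treats pathway identification as a vector-quantization
problem. Each trajectory frame is a point in the space of capped
protein–ligand atom-pair distances; a self-organizing map places a
small set of prototype vectors (neurons) on a 2-D lattice such that
(i) prototypes quantize the sampled conformational density and
(ii) lattice neighbours hold similar prototypes. Property (ii) is what
makes per-replica BMU sequences readable as *pathways*: geometrically
gradual unbinding shows up as a continuous walk across the sheet, and
distinct exit routes occupy distinct map regions.

The transition network treats neurons as microstates and the observed
lag-τ BMU hops as a Markov chain. This is an *approximate* transition
model: no Markovianity test is performed, and biased sampling (SMD,
metadynamics) distorts the hop statistics. Committor values and
community structure computed from biased counts locate barriers and
metastable groupings; they are quantitative only for unbiased or
externally reweighted input (`transition_matrix` accepts per-frame
weights as the hook for such schemes).

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| distance cap | 12 | input distance unit (Å assumed) | exceeds typical binding-site contact distances; flattens unbound-state noise so training is not dominated by it. Interpreted in the input's own unit, never converted. |
| grid | 10 × 10, hexagonal, non-periodic | — | ~100 microstates summarizes single-ligand (un)binding without fragmenting; hexagonal lattice gives 6 equidistant neighbours (all at map distance exactly 1). |
| training cycles | 5000 | full passes over the data | conservative default for production maps; the synthetic studies in the test-suite use 500, which already saturates recovery on that geometry. |
| learning rate | 0.05 → 0.01, linear per presentation | — | standard online-SOM magnitudes; exposed via `schedules`. |
| radius | (2/3 of max map distance) → 0.5, linear | map units | starts global (topology ordering), ends essentially BMU-only (fine quantization). |
| neuron-cluster range | k = 9…15 | — | coarse enough to interpret, fine enough to resolve binding intermediates; argmax of mean silhouette width, ties to smaller k; per-k profile always emitted for manual override. |
| path metric | `ti` | map units | time-independent metric compares replicas evolving at different speeds; use `td` when replicas advance in lockstep (constant-velocity pulling). |
| lag | 1 frame | frames | the transition matrix is approximate regardless; lag exposed for coarser sampling. |
| walktrap steps | 4 | — | standard short-walk length. |

## Numerical and algorithmic choices

- **Kernel and schedules.** The neighbourhood kernel is a Gaussian in
  map distance with σ equal to the current radius, truncated at that
  radius; both schedules decay linearly per frame presentation. These
  are the smooth standard choices where only "decreases with distance
  and along training" is dictated by the protocol.
- **Initialization** samples codebook rows from the data without
  replacement (on-manifold start, fast ordering); a uniform-random mode
  (`init="random"`) is kept as an option.
- **Determinism.** One seed drives initialization and every per-cycle
  permutation through a single `numpy` generator. Updates are strictly
  sequential per presented frame, so a fixed seed reproduces the
  codebook bit-for-bit. The training loop is numba-compiled; the
  pure-numpy fallback applies the same sequence of updates but
  vectorizes per-neuron reductions, so cross-backend agreement is to
  floating-point rounding rather than bit-level.
- **Tie-breaks.** BMU ties resolve to the lowest neuron index;
  representative-frame ties to the earliest frame; representative-neuron
  and centrality ties to the lowest neuron index. Hierarchical
  clustering is delegated to `scipy.cluster.hierarchy` (complete linkage
  for neurons, average linkage for pathways), whose internal merge-tie
  order is deterministic but unspecified; merge trees are validated
  against a naive O(n³) oracle on tie-free data.
- **Silhouette convention.** s(i) = (b−a)/max(a,b); singleton clusters
  and the degenerate 0/0 case (coincident points) score 0. Silhouettes
  are computed on unweighted codebook vectors, not population-weighted.
- **Unequal path lengths.** The time-dependent metric pads the shorter
  path by repeating its final BMU (the end state is persistent); the
  time-independent metric is symmetrized as the arithmetic mean of its
  two directed averages.
- **Graph weighting.** Walktrap and eigenvector centrality run on
  symmetrized affinities (C + Cᵀ on counts, P + Pᵀ per community
  subgraph): a random walker must see high transition probability as
  closeness. The −ln P costs are reserved for shortest-path quantities
  (betweenness). Self-loops stay in P and in the committor chain but
  are excluded from betweenness and community detection, where they are
  meaningless.
- **Committor.** Solved as the dense linear boundary-value problem on
  interior states (I − P_II)q = P_IA·𝟙, clipped to [0, 1] against
  solver round-off. States from which neither boundary set is reachable
  get NaN rather than an error — a disconnected side basin has no
  defined committor. Degenerate/absorbing interiors therefore yield
  missing markers, not failures.
- **Unoccupied rows** of the transition matrix are flagged, never
  normalized; row-stochasticity of occupied rows is exact to 1e-12.

## The synthetic generator

The fixture emulates the geometry of a ligand-unbinding study: a bound
waypoint at the origin surrounded by 8 receptor atoms on a ring of
radius 6, and two exit channels that share bound and unbound endpoints,
diverge by 90°, and rejoin at radius 20 (feature units). A rigid
3-atom ligand is translated along the assigned channel at constant
arc-length speed with Gaussian noise (σ = 0.5 by default, small against
the ~14-unit mid-path channel separation but large enough to scatter
BMUs). The recrossing variant chains alternating unbind/rebind
traversals into one long trajectory with a per-event channel log,
emulating a single enhanced-sampling run with many events. With the
default cap of 12, the unbound tail of every channel is clipped to an
identical all-capped feature vector — deliberately, to exercise the
capping rationale.

What the generator does *not* emulate: internal ligand or receptor
flexibility, rugged free-energy surfaces, velocity autocorrelation,
bias-dependent sampling density, or solvent effects. Passing tests
therefore demonstrate that the pipeline recovers *geometric* pathway
structure it was designed to see, not that it resolves subtle kinetics
in real systems.

## Problem sizes used in the validation suite

The end-to-end studies run 20 replicas × 200 frames (funnel) and
40 × 100 frames (recrossing) on 10 × 10 maps for 500 cycles, repeated
over 20 seeds for pathway recovery; oracle-equivalence checks use ≥ 50
random instances of ≤ 12 nodes / ≤ 100 frames per algorithm, and the
Monte-Carlo committor oracle uses 10⁵ walks per state. These sizes were
chosen so the whole suite documents the method's behaviour at desk
scale; production maps on real trajectories typically use the 5000-cycle
default.

## Known limitations

- Pathway discontinuities caused by genuinely large conformational
  jumps between consecutive frames are reported as-is; the map cannot
  distinguish them from undersampling.
- The silhouette argmax is a batch-friendly stand-in for visual
  inspection of silhouette profiles; the per-k profile is emitted so a
  user can override the choice.
- Committor and community results inherit all biases of the input
  sampling (see above); no implied-timescale or Chapman–Kolmogorov
  validation is provided, by design.
- The xvg reader handles `gmx traj`-style coordinate dumps (one time
  column + 3 columns per atom), not arbitrary Grace files; full-system
  trajectory parsing (PDB/GRO/XTC) is out of scope — users pre-select
  atoms upstream.
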