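# Methods

## Overview

`cafold` reconstructs protein Cα traces ab initio. Three components
interact:

1. **A trainable scoring function** ("neural pairwise-interaction field"):
   a two-stage feed-forward network that maps a conformation to a scalar
   native-likeness score O ∈ ≈[−1, 1].
2. **A fragment-insertion simulated-annealing reconstructor** that perturbs
   the current trace by replacing 9-residue windows with template fragments
   ("snippets") and accepts or rejects moves by the Metropolis rule under a
   pseudo-energy built from O.
3. **An iterative training protocol** that harvests labelled decoys from the
   reconstructor's own search pathways, expanding the training set between
   phases; plus **clustering-based model selection** over the mutual-GDT
   matrix of many reconstructions.

## The scoring model

For each residue i, the ten spatially closest residues with sequence
separation ≥ 6 form the neighbour set C_i. Every ordered pair (i, j ∈ C_i)
is encoded as a real vector over the windows [i−1, i+1] and [j−1, j+1]:

- amino-acid identity (20 + unknown), 3-state secondary structure (H/E/C)
  and 2-class solvent accessibility (buried/exposed) one-hots per window
  residue (6 × 26 values);
- the cosine of the angle between consecutive virtual Cα–Cα bonds at each
  window residue (6 values, 0 with a flag at chain termini);
- all 15 pairwise Euclidean distances among the six window residues;
- 6 pad flags for window positions off the chain ends.

Total dimension 183. The encoding depends on the coordinates only through
distances and bond-angle cosines, so it is rigid-motion- and
mirror-invariant.

The pair stage N^F (input → 5 tanh → 3 tanh) maps each pair vector to a
3-vector X_ij; per-residue features Y_i = K Σ_{j∈C_i} X_ij are summed over
the chain and the global stage N^G (3 → 3 tanh → 1 linear) maps Σ_i Y_i to
O. Both sums commute, so O is invariant under any permutation of pairs and
residues. Training minimizes (O − q)² by plain mini-batch gradient descent
(batch 2, no momentum or decay) with the exact gradient from
back-propagation through both stages.

The training target q is the contact-map quality of the conformation
against the known native: recall + precision − 1 over the sets of Cα pairs
within 8 Å at sequence separation ≥ 6. q = 1 iff the maps coincide, −1 iff
they are disjoint. A model with no contacts has precision 0; a native with
no contacts has no defined label and such decoys are excluded.

### Numerical choices

- **K = 1/10** (the neighbour-count cap), making Y_i a bounded mean. The
  global sum Σ_i Y_i still grows with chain length L.
- **Distance features are expressed in units of 10 Å.** Raw Å distances
  carry ~50× the variance of the one-hot features; with that conditioning
  mismatch gradient descent measurably stalls (training error pinned at the
  label variance), while the rescaled encoding converges.
- **Initialization**: all weights uniform in [−0.1, 0.1] except the
  global-stage input matrix, drawn from [−0.01, 0.01]. Because ‖Σ_i Y_i‖
  can reach O(L), the larger init saturates the global tanh units at the
  start of training and every gradient vanishes through the (1 − h²)
  factor; the smaller scale keeps the units in their sensitive range. Both
  constants are exposed, seeded and reproducible.
- **Learning rate** = 0.5 / (size of the first-phase training set), kept
  fixed as the set grows.

## The reconstructor

A snippet is a 9-residue fragment taken from a template trace, keyed to the
target window start i. Insertion is an internal-coordinate splice: the
virtual bonds, planar angles and torsions fully contained in the window
[i, i+8] take the snippet's values; junction terms and everything outside
keep the current model's values. Rebuilding the chain from the edited
internal coordinates (NeRF chaining, anchored in the frame of the first
residue) leaves upstream residues bit-identical and moves the downstream
segment rigidly — the standard lever-arm fragment move. Inserting a
window's own fragment is a no-op to < 1e-9 Å.

The pseudo-energy of a model of length L is `P_E = L − L·O01 + C` with
O01 = (O + 1)/2 and C a clash penalty counting residue pairs (|i−j| ≥ 2)
closer than 3.73 Å, weight 1 per pair. Moves are accepted by the standard
Metropolis rule p = exp(−(E_new − E_cur)/T); the temperature is cooled
quadratically, T(s) = T0·(1 − s/S)², floored at 1e-6 so the rule stays
defined at the end of the schedule. T0 defaults to L/10 — the energy scale
is O(L), so this accepts moves costing a few percent of the range early on.
Insertion sites are drawn from positions predicted coil with probability
0.8 (uniform over all positions otherwise, and as a fallback when no coil
exists); the snippet within a position is uniform.

## Iterative decoy-set construction

Training alternates with decoy harvesting. Each harvest round runs, per
training target, one search started from the native ("backward") and one
from a random extended chain ("forward"; bond lengths uniform in
[3.73, 3.87] Å, first atom at the origin). Up to 50 snapshots per
trajectory are taken at an interval drawn per-reconstruction from
{10, 50, 100} steps; a snapshot at which no move has been accepted since
the previously retained one is dropped, and retained snapshots are labelled
with q against the native. Merging deduplicates on coordinates rounded to
0.01 Å (keyed by target).

A round runs before *every* phase, including the first: the initial
network has random weights, and its (essentially random) searches provide
the first labelled set alongside the natives (q = +1), which also fixes the
learning-rate denominator. Phase p trains for `epochs_per_phase`·p epochs.
Held-out targets never contribute to training; their decoys, generated by
the same current model each phase, form the test set evaluated every 10
epochs, with an epoch-0 point (the untrained network) recorded so the
error curves cover the whole run.

Expanding the set at a phase boundary raises the first-epoch training error
(the "spike"): the model generates new samples while scoring them, and
their labels expose its overconfidence in the regions its own search
visits.  The held-out error curve is judged by its net trend over the whole
run — final model versus untrained model on the same set.  At desk-scale
set sizes (hundreds of decoys against ~10³ network weights) the
phase-2 epoch budget measurably overfits, so the later-phase-end versus
earlier-phase-end comparison can rise even while the net trend is down and
discrimination (native-vs-decoy ranking) keeps improving; with the
thousands of decoys per phase of a full-scale run, added data outweighs the
added epochs.

## Model selection

The mutual-GDT matrix M(i, j) = GDT(model_i, model_j) feeds DBSCAN with
similarity neighbourhoods {j : M(i, j) ≥ ε}. A deterministic grid search
(ε from 0.9 down to 0.3 in steps of 0.05; min_pts in {3, 5, 10, 20})
returns the first configuration with ≥ 5 clusters whose largest holds at
least 20 models; below 1,000 models the size requirement scales as
max(3, 0.02·n). If no configuration qualifies, the one maximizing
(cluster count, largest size) is returned with a warning flag. From each of
the five largest clusters the member with the highest within-cluster GDT
sum is selected. The mean m of M (diagonal included) is reported as a
funnel-likeness proxy.

GDT itself is the mean over thresholds 1, 2, 4, 8 Å of the largest fraction
of atoms within the threshold after superposition. The superposition search
seeds from the global Kabsch fit plus every contiguous window of length
max(5, L/10), then iteratively re-superposes on the in-threshold subset to
a fixed point (≤ 10 rounds). It is deterministic and approximately
symmetric (observed |GDT(a,b) − GDT(b,a)| ≤ 0.02 on decoy pairs).

## Synthetic study conditions

The generator emulates short single-domain proteins: ideal Cα helices
(radius 2.3 Å, rise 1.5 Å, 100°/residue — canonical ~3.8 Å spacing),
near-extended strand zig-zags and self-avoiding random-walk coils, packed
segment-by-segment with seeded rigid placements that reject non-bonded
pairs closer than 3.73 Å and bias each segment towards the current
centroid. Natives are regenerated until they carry at least max(4, L/8)
contacts — a contact-free "native" has no defined quality label. Secondary
structure comes from the construction itself; the accessibility label is a
burial proxy (neighbour count within 10 Å above the median). Snippet
libraries cover every window with a configurable mixture of (jittered)
native fragments and fragments from unrelated random chains
(`native_fraction`, default 0.3, jitter 0.3 Å), emulating a template
library that contains locally right pieces among noise.  Sequences follow
a hydrophobic-burial pattern — buried positions draw hydrophobic residues
with 80% adherence, exposed ones polar — because real sequences encode
burial and uniform-random letters would make the amino-acid channels pure
memorization fuel.

What the synthetic suite does *not* model: real amino-acid statistics
beyond the burial pattern, Ramachandran-level local geometry,
predictor-correlated feature errors, and chain lengths beyond ~60
residues. Passing tests therefore demonstrate that the
machinery — encoding, exact gradients, search, protocol dynamics and
selection — behaves as designed, not that the learned potential would fold
real proteins at the reported level.

## Scaled run sizes

The full-scale protocol (hundreds of targets, 3,500-step harvests,
1,000-model selection runs with 100,000 steps each) is far beyond a desk
run. The package defaults keep the published constants (3,500 steps,
50/phase epochs, batch 2, lr numerator 0.5); the test suite and the
acceptance script run the same code at reduced sizes chosen once: 10
targets of 30–45 residues, 800-step harvest searches, 2 phases of 100
epochs (compensating the far fewer gradient updates per epoch of a
few-hundred-example set), 60 reconstructions of 400 steps per target for
the selection study. Under these conditions the two-phase run finishes in
about 2 minutes on one CPU and the trained scorer folds held-out synthetic
targets well above the unfolded baseline.

## Known limitations

- The GDT superposition search is a deterministic approximation of the
  full iterative-superposition algorithms used by structure-comparison
  servers; absolute values can differ slightly from theirs.
- The quality label saturates near 0 for unrelated compact conformations
  (chance contact overlap), so the score resolves "wrong" from "very
  wrong" only weakly.
- Fragment insertion at window starts 0–2 anchors in the frame of the old
  first residue rather than an upstream junction (there is none); the
  window then adopts the snippet geometry in place.
- DBSCAN border-point assignment depends on scan order; it is
  deterministic for a fixed model order, and tie-breaks in centroid
  selection are documented (lowest index wins).
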