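# Methods

## The subsampling problem

Given an MD trajectory of `n` frames and a per-frame scalar reference
property `v_1 … v_n`, select `m ≪ n` frames such that the empirical
distribution of the property in the subsample matches the full trajectory.
The property is a proxy for conformational state; preserving its
distribution keeps the subsample representative of what the simulation
actually visited. The approach is purely *a posteriori*: nothing about the
integrator, ensemble or bias of the original run is used, so it applies
equally to unbiased and biased simulations (reweighting biased data is out
of scope — weights must then be supplied by the user).

## Distribution comparison

Both the full series and the subsample are histogrammed on **the same bin
edges**, always computed from the full series (equal-width bins over its
min–max, or an explicit range override). Edges from the subsample would
make the two histograms incomparable and the dissimilarity meaningless, so
shared edges are enforced structurally: comparing distributions with
different edges raises, never silently proceeds.

The primary measure is the Bhattacharyya distance
`D_B(p,q) = −ln Σ_i √(p_i q_i)`. Properties relied on:

- `D_B(p,p) = 0` exactly (elementwise-identical probability vectors
  short-circuit to 0.0 — the floating-point round trip through
  `−ln Σ √(p_i²)` is not guaranteed exact when probabilities do not sum to
  exactly 1);
- symmetric, nonnegative;
- `+∞` for disjoint supports. Infinity is an ordinary comparable value
  (serialized as `inf` in reports), so a size sweep ranks a
  degenerate sample worse than any finite one without crashing;
- invariant under proportional bin refinement.

Zero-probability bins contribute zero terms; no pseudocounts by default,
because pseudocounts change the textbook quantity. An optional
`pseudocount` argument adds ε to all bins of both histograms and
renormalizes, for users who need finite values on sparse comparisons.
Kullback–Leibler divergence and 1 − Pearson correlation of bin
probabilities are available behind the same interface as extension
measures; they are not used by any default path.

The default bin count is 100 equal-width bins. The choice is a compromise:
enough resolution to separate conformational modes, few enough that a
percent-scale subsample still populates the occupied bins. It is a free
parameter everywhere and recorded in every provenance record.

## Properties

- **RMSD**: each frame's selected atoms are superposed onto the reference
  by translation to the common centroid plus the least-squares (Kabsch)
  rotation, computed via SVD (`scipy`'s Wahba solver). The residual is
  evaluated explicitly after applying the fitted rotation rather than taken
  from the solver's aggregate output, which loses ~1e-6 Å to cancellation
  near zero RMSD at typical coordinate magnitudes. The reference defaults
  to frame 0 — reproducible without any external file — and any `(k, 3)`
  coordinate block (e.g. an experimental structure) can be passed instead.
  Selections need ≥ 3 atoms; superposition on fewer is degenerate.
- **Centroid distance** between two selections and **radius of gyration**
  are computed unweighted. Mass weighting is deliberately off: the
  synthetic topologies carry no reliable masses, and the property serves as
  a sampling coordinate, not an observable to publish.
- **Imported properties** (cavity volumes, rescoring energies, …) are
  two-column text, one value per frame, 0-based frame indices by default
  with an explicit `one_based` escape hatch. Exactly-one-value-per-frame is
  enforced with errors naming the offending frames; a file whose indices
  end at `n` instead of `n−1` triggers a hint about the 1-based flag.

## Samplers

All five samplers are pure functions of their inputs plus an integer seed
(one `numpy` generator stream per call; bootstrap replicate `r` derives its
stream from `(seed, r)` so single replicates are independently
reproducible).

Quota rules for uniform (property strata) and stratified (labels): base
quota `floor(size / n_strata)`, the remainder assigned one extra frame to
the lowest-indexed occupied strata in order — deterministic and
seed-independent. Strata holding fewer frames than their quota contribute
everything they have; the shortfall is recorded on the returned sample and
**never redistributed**, because silently topping up other strata would
break the equal-representation guarantee the sampler exists to provide.
The realized size can therefore undershoot the request; both numbers are in
the provenance record.

Weighted sampling draws without replacement by default (sequential draws
with renormalization), with an opt-in replacement flag; bootstrap is always
with replacement; random/uniform/stratified are always without. Downstream
consumers (docking, ML) want distinct conformations; only bootstrap
semantically requires replacement.

`weights_from_frequency` gives every frame the probability mass of its
property bin, then normalizes over frames. Consequence worth stating: a
*state's* total selection mass scales as (frequency × member count), i.e.
as frequency squared. On a 90/10 bimodal series the dominant state receives
`0.9·N₁/(0.9·N₁+0.1·N₂) ≈ 98.9 %` of the selection mass, not 90 %. This is
the literal reading of "chance proportional to the frequency of the
frame's property value"; users wanting state-mass-proportional selection
should supply explicit weights.

Boundary values follow one shared edge convention everywhere (half-open
bins, last bin closed on the right), used identically by histogramming,
frequency weights and uniform-sampler strata.

## Size sweep

For each candidate size (absolute count or percentage, converted by
rounding half up; a percentage that rounds to zero frames is an error, not
a silent clamp to 1), `n_replicates` (default 50) random subsamples are
drawn and scored; the selected size is the smallest whose **mean** distance
meets the threshold. A single-draw criterion would be unstable at small
sizes, where the distance distribution is wide. Replicate streams derive
from `(seed, size, replicate)`, so adding grid points does not perturb
existing ones.

## Trajectory handling

File I/O and the selection grammar are delegated to MDAnalysis behind the
package's own types: coordinates live in Angstrom internally (nm-native
formats are converted on read and write), frames are indexed globally and
0-based across concatenated files, and subsamples are written in ascending
original-frame order (duplicates repeated for bootstrap samples) to
preserve temporal ordering for time-aware consumers. Multi-file input must
share one topology; atom-count mismatches are rejected with both counts in
the message. Selections that match nothing raise — an empty selection is
never returned silently.

Round-trip precision is format-bound: DCD stores float32 (~1e-5 Å at
typical magnitudes), XTC compresses to 0.001 nm (0.01 Å); tests assert at
these bounds.

## Synthetic data

The generator emulates the one feature of real protein trajectories this
package's statistics depend on: a multi-modal reference-property
distribution with tunable mode separation, populations and noise. It
builds an idealized Cα helix (3.8 Å spacing), assigns each frame
independently to "open" with probability `open_fraction`, displaces the
open-state lid segment, and adds isotropic Gaussian noise.

The open-state motion is a **non-rigid** bulge (per-atom displacement
along a fixed direction, scaled by `sin(πt)` across the lid, peak
`displacement`): a rigid translation or rotation of the whole lid would be
absorbed exactly by the superposition step and produce zero lid-RMSD, so a
deformation is required for the property to see the transition. The
noiseless open/closed RMSD gap is therefore measured (and tested) against
an independent Kabsch evaluation of the two state templates rather than
assumed from a closed form.

Defaults — 4000 frames, 214 residues, lid at residues 120–160,
`open_fraction` 0.5, peak displacement 5 Å, noise 0.3 Å — model a modest
production run of a mid-size two-state protein with a clearly resolved
conformational change (mode separation ≫ intra-state spread). Frame
assignments are i.i.d.; real trajectories are time-correlated, visit
intermediate states, and have property distributions that drift with
sampling time. Passing tests therefore demonstrate the statistical
machinery (quotas, weights, distances, round-trips), not robustness to
kinetic correlation — for strongly correlated data the effective sample
size of a random subsample is smaller than its frame count, and the sweep
threshold should be chosen accordingly.

What the generator does not emulate: solvent, periodic boundary wrap,
mass heterogeneity, side chains, and realistic secondary-structure
geometry. None of these enter the sampling statistics.

## Problem sizes in tests

Statistical assertions use sizes chosen so that 3–4σ bounds are decisive:
1000 seeds for single-draw binomial checks, 500 bootstrap replicates
against the closed-form coverage `1 − (1 − 1/N)^m`, 50-replicate sweeps on
the 4000-frame fixture. Bounds on quantities maximized over many frames use
4σ (union-bound safe) rather than 3σ per frame. All Monte-Carlo loops are
seeded, so test outcomes are deterministic.

## Known limitations

- No kinetic/MSM-aware or energy-reweighted sampling; frames are treated
  as exchangeable.
- No trajectory alignment, imaging or PBC unwrapping beyond the
  superposition inside the RMSD property.
- The uniform sampler's equal-width strata inherit the property's scale;
  heavy-tailed properties may want a transformed series instead.
- Replay requires the original input files at their recorded paths;
  in-memory ensembles cannot be replayed and say so explicitly.
- Heterogeneous topologies across trajectory files are rejected rather
  than reconciled.
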