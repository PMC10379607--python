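# Methods

This note documents the models, estimators and numerical choices behind
`porescan`, and what the synthetic campaigns do and do not show about
real trajectory data.

## Per-frame observables

**RMSD.** All-atom root-mean-square deviation after optimal rigid
superposition (Kabsch). The core is a batched closed form — covariance
SVD per frame with the reflection-corrected singular-value trace — so a
2,000-frame replica costs one vectorised call rather than 2,000
alignments. `superpose` additionally returns the explicit proper
rotation and translation; it refuses sets with fewer than three
non-collinear atoms, where the optimal rotation is not unique. The RMSD
*value* is still well defined there, so `rmsd` itself accepts two-atom
and collinear inputs (the n = 2 optimum has the closed form
|d₁ − d₂|/2). `fit=False` gives the raw positional deviation without
superposition. Tests pin the implementation against an independent
2°-spaced rotation-grid search and against
`scipy.spatial.transform.Rotation.align_vectors`.

**FNC.** Native contacts are all atom pairs within 0.8 nm (8 Å) in the
reference frame, the universal hard-cutoff convention; the fraction
surviving in a frame is counted with no smoothing. For bead models every
bead counts and the minimum sequence separation defaults to 0 (only self
pairs excluded); for real chains a separation of 3 drops trivially
bonded neighbours. Both observables are computed against *each replica's
own first frame* — there is no shared global reference, so rmsd[0] = 0
and fnc[0] = 1 identically.

Atom matching is strictly positional (index i ↔ index i). Coordinates
are nanometres internally; PDB files are converted from/to Ångström on
I/O.

## Replica-selection funnel

Replicas that never settled, and replicas that settled without opening a
pore, would both pollute the tuple space. Two sequential criteria:

* **Stability** — "change in the RMSD first derivative over the final
  window" is operationalised as the relative difference of least-squares
  slopes over the two halves of the final 10 ns:
  |s₂ − s₁| / max(|s₁|, floor) < 0.15. Least-squares slopes are
  noise-robust compared with pointwise finite differences; the floor
  (0.005 nm/ns) keeps flat series — which should always pass — from
  dividing by ≈0. With ~500 frames per half-window the slope-difference
  noise is ≈3×10⁻⁴ nm/ns, safely inside the 7.5×10⁻⁴ pass band; shorter
  windows or sparser sampling widen this noise, which is the main
  practical failure mode to watch when re-parameterising.
* **Pore proxy** — final-frame RMSD ≥ 0.35 nm, the threshold above
  which full VSD pores form. "Ended below 0.35 nm" is removed, so the
  boundary is inclusive-pass. The final *frame's* value is used, not an
  average, matching the criterion's "ended with" semantics.

Tightening either threshold can only shrink the kept set, and the kept
set is independent of replica ordering; both are property-tested.

## Tuple space

Kept replicas are subsampled at 1 ns (frames at t = stride, 2·stride, …;
the reference first frame is retained separately). Every unordered frame
pair {x, y} yields (RMSD(x,y), FNC(x,x₀), FNC(y,y₀)), with the canonical
(replica id, frame index) order fixing which frame is x. Two pairing
scopes exist:

* `all_cross` (default) — pairs within and across replicas, the literal
  "pairwise comparisons of frames extracted from all replicas".
* `within` — same-replica pairs only. Cross-replica pairs whose frames
  sit in *different* latent states land at (inter-state RMSD, FNC_i,
  FNC_j) — a separate "mixed" cluster per state pair — so when the goal
  is recovering per-state populations, within-replica pairing is the
  scope under which cluster weights are proportional to state
  populations. The ground-truth recovery tests therefore use `within`.

Tuples identical after rounding to 4 decimals (raw units) are merged;
the weight equals the provenance multiplicity and total weight is
conserved. Scaling is a weighted z-score per dimension (weighted mean /
population SD), with min–max offered as an alternative; a zero-variance
dimension gets scale 1 with a warning. The fitted scaler is persisted
for exact inverse transforms.

## Clustering and representatives

`WeightedKMeans` wraps scikit-learn's k-means (k-means++, best of
n_init = 10 restarts, tol 10⁻⁶, max_iter 300) with sample weights — a
weight-w tuple is exactly equivalent to w unit replicas, which is
asserted against replication and against exhaustive partition
enumeration on ≤10-point instances. Clusters are relabelled by
descending population so outputs are canonical.

**Elbow.** k is chosen where the *log*-inertia curve has its maximum
discrete second difference over k = 1..8. The plain-inertia second
difference fails for near-collinear centroid arrangements: with three
equally spaced collinear groups, I₁ − 2I₂ + I₃ > I₂ − 2I₃ + I₄ even for
a perfect 3-way split, so the plain knee picks k = 2. The log form keys
on the relative collapse of inertia at the true group count and handles
both compact and collinear layouts; the raw curve is always written out
so a human can override k in the config. A `low_confidence` flag is set
when inertia at the chosen k is still >30% of the k = 1 inertia — i.e.
there was little structure to find (a single Gaussian blob trips it).

**KDE and representatives.** Each cluster gets a weighted Gaussian KDE
(scikit-learn KernelDensity) in the scaled space. The default bandwidth
is Scott's rule on the weighted effective sample size
n_eff = (Σw)²/Σw², h = σ̄·n_eff^(−1/(d+4)) with σ̄ the mean per-dimension
weighted SD; a fixed bandwidth can be forced. The density maximum is
located by Nelder–Mead ascent from the highest-density member (with the
member itself as a logged fallback if the ascent fails), and the
representative is the member tuple minimising the squared Euclidean
distance to that maximum — ties break toward higher weight, then lower
tuple index. A per-cluster KDE is the default; a single global KDE over
all tuples is available behind `global_kde`. The representative's
provenance pair maps back to concrete frames, which are written as PDBs.

## Thermodynamics and field arithmetic

ΔG⁰ = −R·T·ln(P₁/P₂) with populations = total tuple weights,
R = 8.314 J/(mol·K), T = 310 K (the simulation ensemble temperature) by
default; these constants reproduce the reference free-energy table
(−80.5 / −1760.2 / −1679.7 J/mol from tuple counts
2,269,895 / 2,200,065 / 1,146,558) to the printed decimal. Antisymmetry
and additivity are exact log identities and are property-tested to
10⁻⁹. ΔV = E_z·L_z (0.13 V/nm × 8.5 nm = 1.105 ≈ 1.1 V;
0.2 × 8.5 = 1.7 V) and F = q·E_z with 1 e·V/nm = 96.485 kJ/(mol·nm) are
bookkeeping only — no force is ever integrated. R·T at 310 K is
2.577 kJ/mol (2.47 kJ/mol corresponds to ≈297 K; `thermal_noise` takes
T explicitly rather than claiming either value).

## Synthetic campaigns

The generator emulates the study design the analysis is meant for — many
short replicas relaxing from one native conformation into a small set of
latent conformational states — with every downstream quantity
controllable:

* **Native** — 4 antiparallel pseudo-helices of identical beads on a
  0.5 nm circle (helix radius 0.25 nm, 0.15 nm rise), with a seeded
  jitter; rescaled if needed so at least one native contact exists even
  at n = 4.
* **States** — template k = native + k·A·mode_k, where mode_k is a
  smooth random deformation field (Gaussian-filtered along the bead
  index, σ = 3 beads) with its rigid-body component projected out, so
  the superposed RMSD from the native is ≈ k·A and strictly increasing
  (A = 0.5 nm by default → plateaus near 0.5/1.0/1.5 nm). Labels follow
  the closed / simple-pore / complex-pore taxonomy with populations
  (0.404, 0.392, 0.204), the reference campaign's cluster proportions.
* **Dynamics** — frame(t) = native + (1 − e^(−rt))(template − native)
  + ε, ε i.i.d. Gaussian per coordinate. r = 4 ns⁻¹ so the e-fold time
  (0.25 ns) sits well inside both the 1 ns tuple stride and the 10 ns
  stability window; frames are at t = Δt..T, so the reference first
  frame is essentially native. Base noise σ = 0.025 nm, multiplied by a
  per-state scale (1.0, 1.5, 2.0): more open states fluctuate more,
  matching the observation that the complex-pore cluster's data cloud
  is visibly more dispersed — and giving the pair-RMSD tuple dimension
  real between-state signal instead of a constant noise floor that
  z-scoring would inflate into a spurious splitting direction.
* **Planted counterexamples** — a fraction of replicas get an
  accelerating (quadratic-in-time) drift over the final window, so the
  RMSD derivative keeps changing there and the stability filter fires; a
  *linear* ramp spanning the whole window would have identical
  least-squares slopes in both halves and would pass. Another fraction
  is pinned at the native (final RMSD ≪ 0.35 nm) to be caught by the
  pore proxy. Defaults (19% unstable, 20/162 of the rest closed) make
  the expected funnel exactly 200 → 162 → 142.
* **Durations** — the frame-count arithmetic anchor is 10 ns at 10 ps
  (142 replicas → 142,000 frames → 1,420 at 1 ns stride). Funnel
  demonstrations use 20 ns trajectories so the 10 ns analysis window
  contains only plateau: when the window equals the full duration the
  relaxation transient sits in the first half-window and *every*
  relaxing replica fails the derivative test (the least-squares slope of
  d(1 − e^(−rt)) over the first half is ≈0.04–0.15·d nm/ns against ≈0 in
  the second).

Everything is seeded through a `SeedSequence` tree (campaign seed →
native / templates / assignments / per-replica streams), so campaigns
are bit-reproducible and any single replica can be regenerated in
isolation — which is how the pipeline re-materialises representative
frames without caching trajectories.

**What the synthetic tests do not show.** Bead replicas have no force
field, membrane, water or electric field; state templates are fixed
endpoints rather than emergent minima; noise is isotropic and
uncorrelated. Passing the recovery tests demonstrates that the
*analysis* — features, funnel, tuple construction, weighted clustering,
representative selection, Boltzmann inversion — does what it claims on
data with known structure. It says nothing about whether a particular
real system forms pores, and the reference campaign's structural
findings (which replicas form complex pores, maximum final RMSD, pore
imagery) are not desk-reproducible by construction.

## Pipeline, determinism, problem sizes

`porescan run` executes generate → featurize → filter → tuples →
cluster → thermo from one YAML config; every stage persists plain-text
TSV/JSON intermediates, and a run can resume from any stage
(`--from tuples`), with synthetic coordinates regenerated
deterministically rather than cached. A single global seed fans out to
stages via stage-name-hashed SeedSequences. Config values accept units
("8 A", "10000 ps") and are normalised; unknown keys are rejected by
name. An empty post-filter set ends the run gracefully with the report
saying so.

Test problem sizes are chosen for desk-scale runtimes: funnel-rate
checks pool ten 200-replica campaigns (2,000 replicas × 2,000 frames,
~1–2 min); recovery checks use ten 200-replica campaigns at 100 ps
sampling (~9,000 weighted tuples each, seconds); k-means exactness uses
≤10 points where partition enumeration is exhaustive. The all-cross
pairing of a full 142 × 10-frame campaign (≈10⁶ pairs) runs in minutes
but is not part of the default suite.

## Known limitations

* The all-cross tuple universe of the reference campaign cannot be
  reconciled with its published per-cluster tuple totals from the
  printed frame counts alone; the pairing scope is therefore exposed as
  a parameter rather than resolved.
* The elbow is automated; on weakly structured clouds it still returns
  an argmax, flagged `low_confidence`, and the human override remains
  the honest path there.
* The stability estimator (two-half least-squares slopes) is one
  reasonable reading of "change in the first derivative"; alternatives
  (smoothed derivatives, different splits) would shift individual pass
  decisions near the 15% boundary.
* KDE bandwidth uses a single isotropic h per cluster; strongly
  anisotropic clusters would bias the density maximum slightly along
  their long axis.
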