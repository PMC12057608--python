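# Methods

This note records the models the package implements, the assumptions and
parameter choices behind them, and what the synthetic test bed does and does
not establish about real data.

## Diffusion from trajectories

**Model.** Translational self-diffusion in 3D obeys the Einstein relation
MSD(t) = 6 D t in the long-time (diffusive) regime. The estimator chain is:
minimum-image unwrapping of periodic coordinates (valid when no molecule
moves half a box edge between saved frames); centre-of-mass MSD per molecule
averaged over **all** time origins (overlapping windows, computed with the
FFT autocorrelation identity); pointwise averaging of per-replicate curves;
ordinary least squares of MSD against lag over a fit window; D = slope/6.

**Units.** Coordinates nm, times ps internally; MSD curves carry ns and nm²;
an MSD slope of 1 nm²/ns equals 10 × 10⁻¹⁰ m²/s. Reported D values use
10⁻¹⁰ m²/s, the customary scale for small molecules in chloroform — result
tables in the DOSY literature usually print numbers on this scale without
units, and this package follows that convention explicitly.

**Fit window.** The default window spans 10–90% of the trajectory duration,
the standard linear-regime choice (e.g. 10–90 ns on 100 ns production runs).
Two caveats discovered while validating the estimator, both intrinsic to MSD
statistics rather than to this implementation:

* At lags close to the run length very few independent time origins remain,
  so the long-lag part of the curve is extremely noisy; fits that include it
  have large variance even after 15-replicate averaging.
* For a tracer exchanging between a free state (D_free) and a bound state
  (D_bound) with stationary occupancies, the *ensemble-averaged* MSD is
  linear at **every** lag with slope 6·D_eff, D_eff = f_free·D_free +
  f_bound·D_bound. Short-lag fits are therefore unbiased for the effective
  diffusion coefficient and far more precise. The exchange-kinetics
  validation studies consequently fit lags ≤ 3/8 of the run length
  (0.5–6 ns of 16 ns runs); the 10–90% default remains for production-style
  analyses where the early MSD may contain non-diffusive transients.

**Error convention.** When per-replicate curves are available the quoted
uncertainty is the standard error of the mean of the per-replicate D values
(n = 15 by default); otherwise the OLS slope standard error is propagated.
The convergence report re-fits the running average of the first n curves in
supplied order, with the SEM over those n single-replicate fits.

**Molecule position.** Unweighted centroid of the molecule's particles. The
synthetic molecules are beads without masses; for atomistic trajectories a
mass-weighted centre of mass would be the appropriate refinement (not
currently implemented — see Limitations).

## The synthetic generator

**What it emulates.** A dilute chloroform-like box: two enantiomeric tracer
populations (5 R-MA + 5 S-MA by default) and an enantiopure resolving agent
(50 CRA), solvent implicit (the nominal solvent count, 2338, is metadata
only). Each molecule is one overdamped Brownian bead; each tracer carries a
chiral-H reporter satellite rigidly tethered at 0.25 nm with its orientation
re-randomized every step. Free beads step with per-dimension variance
2·D_free·dt; a bound tracer–CRA pair moves as one unit with variance
2·D_bound·dt. Association is kinetic: a free pair whose minimum
inter-particle distance is inside the capture radius binds with probability
1−exp(−k_on·dt) per step; a bound pair dissociates with probability
1−exp(−k_off·dt), with k_off depending on the (tracer, CRA) chirality
pairing. This yields closed-form ground truth: free-tracer MSD = 6·D_free·t,
residence times ~ Exp(k_off), and a mirror-symmetric system under exchange
of all chirality labels.

**Kinetic-geometric consistency.** The simulator guarantees that the
bound/unbound telegraph signal is *exactly* recoverable from saved
coordinates by a distance criterion at the capture radius: bound pairs are
held at a contact distance of half the capture radius; on dissociation the
partner is ejected just outside the capture shell; and proximity of a
non-binding pair is rejected (an excluded shell, enforced for free–free,
free–bound and complex–complex encounters alike). The distance metric for
capture and exclusion is the same minimum inter-particle distance used by
complex detection. This is a deliberate idealization that turns event
detection into an exactly testable operation.

**What it does not emulate.** No interaction potentials, no hydrodynamic
coupling, no solvent structure, no internal degrees of freedom, no
finite-size (Yeh–Hummer) effects, no competition chemistry beyond 1:1
kinetic binding. Detection-level 1:2 and higher stoichiometries arise only
geometrically (a second CRA inside the detection cutoff), not kinetically.
Passing tests on this generator therefore validate the *estimators* —
unwrapping, MSD algebra, fit and error conventions, event bookkeeping,
binning, normalization — not force fields or sampling adequacy of any real
simulation.

**Presets.** `production` mirrors the production composition at 100 ns with
slow dissociation (mean residence ≈ 85 ns, i.e. k_off ≈ 0.012 ns⁻¹);
`production-ci` is the same box scaled to 1 ns for fast pipelines;
`free-tracers` (k_on = 0, D_free = 11.15) backs diffusion recovery;
`symmetric-kinetic` (k_off = 0.5 ns⁻¹ for both pairings) is the
no-discrimination null; `hetero-bias-kinetic` (k_off = 2.0 ns⁻¹ homochiral
vs 0.1 ns⁻¹ heterochiral, D_bound = 2) is the ordering oracle. The biased
preset's contrast is deliberately strong: with 15 replicates of 16 ns and
5+5 tracers, the resulting separation in effective D is a ≈8σ effect, so the
qualitative ordering test reflects the construction, not seed luck. A weaker
contrast (factor 4 in k_off) was found to give only a ≈2σ effect at this
problem size, which is statistically meaningless for a deterministic test.

**Step-size guard.** Specs whose rms free displacement per step exceeds a
quarter box edge are refused (minimum-image bookkeeping would break).

## Complex detection and statistics

**Contact definition.** Minimum inter-particle distance between the two
molecules with hysteresis: enter bound at d ≤ r_on, leave at d > r_off
(defaults 4.0 / 5.0 Å), unbound gaps shorter than gap_tolerance (default
100 ps) bridged into one event. The generous defaults reflect residence
events that are orders of magnitude longer than individual contact breaks;
all three values are explicit arguments and are embedded in every output.

**Event times.** A bound run of frames [f₀…f₁] maps to the half-open
interval [t(f₀), t(f₁+1)), clipped at the final frame. Consequences, all
tested: bound plus unbound durations per pair exactly tile the trajectory
span at zero gap tolerance; a pair bound throughout yields one event of the
full duration; measured exponential lifetimes carry only an O(frame-spacing)
discretization bias.

**Lifetime errors.** `lifetimes` pools events (SEM over events);
`replicate_lifetimes` averages per-replicate means (SEM over replicates) —
the convention used for replicate-based tables.

**Census.** Per frame, a tracer bound to k CRAs occupies the single state
1:k (never k separate 1:1 states); states partition all (frame, tracer)
cells. The heterochiral-excess statistic is the per-replicate difference of
total heterochiral minus homochiral 1:1 frame counts, mean ± SEM across
replicates; it is undefined (NaN error) for a single replicate.

**Distance histograms and frame selection.** Chiral-H to CRA
centre-of-mass distances for 1:1 frames only, left-closed right-open bins,
default 0.5 Å over [2.5, 15] Å. Frame selection filters the same
observations by a distance window; by construction the selected count equals
the histogram mass in that window.

**Mirror symmetries.** Swapping the resolving agent's chirality labels swaps
homochiral ↔ heterochiral outputs exactly; swapping *all* labels (the full
mirror system) leaves pairing labels invariant. Both are regression-tested.

## Spatial distribution functions

For each frame and reference molecule the reference particles are superposed
onto the first frame's reference geometry by the Kabsch algorithm (proper
rotations only), target particles are expressed in that body frame and
deposited on a cubic grid (default 20 Å extent, 0.5 Å spacing, reference
centroid at origin). Normalization divides by frame count, voxel volume, and
bulk target density, so far-field density → 1 and isovalues are relative
densities; a raw counts mode exists because isovalue conventions differ
between tools. Two-particle references (bead + satellite) get an axis frame
completed by a deterministic lab-vector orthogonalization — sufficient for
axially symmetric statistics but not a full body frame. With ≥3 non-collinear
reference particles the construction is exactly equivariant under reflection:
mirroring the system yields the parity-flipped grid to machine precision.
Output is the Gaussian cube format (Bohr lengths), with a matching reader.

## DOSY fitting

Peak attenuation follows I(g) = I₀·exp(−b(g)·D) with the Oneshot decay
constant b = γ²δ²g²[Δ + δ(α²−2)/6 + τ(α²−1)/2]; α = τ = 0 recovers the
classical Stejskal–Tanner form Δ − δ/3 and is the default because pulse
sequences in the wild rarely publish their imbalance factor. The nonlinear
fit over (I₀, D) is initialized from the log-linear regression of ln I on b
and is unweighted by default (inverse-variance weighting by flag); D_err is
the covariance diagonal. Degenerate inputs error out: non-positive fitted D,
or relative attenuation below 10⁻³ over the whole gradient range.

Monte-Carlo calibration (200 seeds, 1% additive noise, 16 increments):
the fitted D is unbiased within 0.1% and the 1σ error covers the truth at
≈ 68–70%.

ΔD = D_R − D_S with quadrature errors; the selectivity ratio
|ΔD_S-agent / ΔD_R-agent| uses first-order error propagation. For inputs with
~40% relative errors (as in the experimental tables) the ratio distribution
is heavy-tailed and any first-order error bar is a bulk summary, not a
coverage statement; the propagation formula is validated against direct
Monte-Carlo on well-conditioned inputs, where it is exact to the stated 2%.
Comparisons with printed table values use round-half-even at the printed
number of decimals; full precision is retained internally.

The default synthetic schedule (16 increments, quadratic ramp from 10% to
80% of a 0.535 T/m maximum gradient, δ = 1.5 ms, Δ = 60 ms) produces ~85%
attenuation between first and last increment for D ≈ 11 × 10⁻¹⁰ m²/s — the
usual optimization target for such experiments.

## Ensemble thermodynamics

Boltzmann weights w_i ∝ exp(−(G_i − G_min)/kT) (shift for numerical
stability; weights invariant to any constant added to all G_i). kT is
computed from the CODATA gas constant (0.0019872 kcal mol⁻¹ K⁻¹ × 298.15 K =
0.59248 kcal/mol), overridable per call. Two ensemble-energy conventions are
provided because published tables rarely state which they use: the
Boltzmann-weighted arithmetic mean of G_i, and the ensemble free energy
−kT·ln Σ exp(−G_i/kT); the mode is recorded in every summary, and both are
tested against two-state closed forms. Binding free energy is
ΔG_bind = G_complex − G_host − G_guest. Sign conventions:
ΔΔG = ΔG_bind(R-analyte) − ΔG_bind(S-analyte) and Δδ = shift(R) − shift(S),
so a heterochiral-preferring system with an R resolving agent has ΔΔG > 0
and Δδ < 0. Chemical shifts are assumed already referenced in the input
tables.

## Reproducibility

A single master seed deterministically derives all per-replicate and
Monte-Carlo seeds through `numpy.random.SeedSequence` spawning (kept below
2³¹); re-running any configuration reproduces every stochastic output
bit-identically, which is itself under test. Every numerical output carries
the cutoffs, windows, and error conventions that produced it.

## Problem sizes used in the validation suite

Chosen to give each check clear statistical power at desk scale: diffusion
recovery uses 15 replicates × 1 ns × 10 tracers; residence-time recovery one
80 ns run with 20 tracers/20 CRAs (≈600 events at k_off = 0.5 ns⁻¹, mean
within 5% of 2 ns); the null and ordering studies 15 replicates × 16 ns of
the kinetic presets; DOSY calibration 200 Monte-Carlo seeds; SDF
normalization 400 frames × 200 ideal-gas targets.

## Limitations

* The generator's idealizations (listed above) mean agreement on synthetic
  data does not validate force fields, sampling, or solvent models for real
  systems.
* GRO files are read single-frame (structure + box); multi-frame
  trajectories use XYZ, multi-model PDB, or the HDF5 container.
* No mass-weighted centres of mass, no finite-size diffusion corrections,
  no anomalous-diffusion exponents, no multi-component (biexponential) DOSY
  decays.
* Complex detection assumes orthorhombic boxes and the minimum-image
  convention.
* PDB round-trips are limited to the format's fixed 3-decimal precision in
  Angstrom.
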