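# Methods

This note documents the models implemented in `ngfc`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical
choices that were genuinely open. Units throughout: µm, ms, mV, pA, µM;
all random draws flow from explicit integer seeds.

## Binomial-quantal model and Bayesian quantal analysis

A unitary GABAergic connection is modeled as `N` functional release
sites, each releasing independently with probability `p` set by the
extracellular Ca²⁺/Mg²⁺ condition. A trial's IPSC amplitude is the sum
of the released quanta plus Gaussian baseline noise; each quantum is
gamma-distributed with mean `q` (pA) and coefficient of variation `cv`.
The gamma choice keeps single-quantum amplitudes positive; a truncated
normal would bias the mean. Analytic moments (used in tests):
mean `N·p·q`, variance `N·p(1−p)q² + N·p(q·cv)² + σ²`.

`bqa_fit` shares `N`, `q`, `cv` and noise across conditions with a
condition-specific `p`. The likelihood marginalizes the released-site
count `k`; each `k`-quantum mixture component is moment-matched by a
Gaussian `N(kq, k(q·cv)² + σ²)`, a standard approximation that is
accurate away from the extreme low-noise limit. Inference combines
discrete marginalization over `N` (support 1..30) with affine-invariant
ensemble MCMC over `(log q, logit p_c, log cv, log σ)`; priors are
log-uniform `q ∈ [0.5, 20]` pA, `cv ∈ [0.05, 1]`, `σ ∈ [0.1, 10]` pA,
`p` uniform on (0, 1). The default prior on `N` is `P(N) ∝ 1/N`
(uniform on log N): the site count behaves as a scale parameter, and a
flat prior lets the sub-harmonic mode — `2N` sites of quantal size
`q/2`, which reproduces the same amplitude peaks — capture the
posterior median whenever the data are peaky; a flat prior remains
available as `n_prior="uniform"`. The posterior over `N` is the average
of the conditional `P(N | θ)` over retained draws; point estimates are
posterior medians.

Identifiability: `N` and `q` form a ridge `N·q ≈ mean/p`, with the
sub-harmonic `(2N, q/2)` ambiguity on top. The ridge is broken only
when quantal peaks are resolvable in the amplitude histogram, i.e. when
`sqrt(k)·q·cv` and `σ` are small relative to `q`.
The package's own sensitivity experiments show that with 33 trials per
condition and `cv = 0.25, σ = 1 pA` even exact grid-posterior medians
recover `N = 11` within ±3 in only ~60% of replicates — the information
is simply not in the data; at `cv = 0.1, σ = 0.3 pA` recovery reaches
~90%. The recovery test therefore runs in the peak-resolvable regime,
and results on noisier data should be read as interval estimates, not
point estimates. K-means uniquantal separation standardizes the three
event features (initial slope, peak amplitude, area), ranks the k = 3
clusters by mean amplitude and labels them failure / uniquantal /
multiquantal.

## Axon growth, Sholl calibration, and boutons

Model arbors grow from the soma in elementary segments (default 10 µm,
drawn so the realized total length follows a positive-truncated normal).
Branch events are scheduled uniformly over segments (count from a
rounded truncated normal); at each extension the direction deviates from
the parent by a polar angle `~N(40°, 25°)` with uniform azimuth. These
defaults produce arbors with most cable within ~150 µm of the soma,
matching the dense, compact arborization typical of the cell class; the
calibrator treats them only as a starting point.

Sholl analysis resamples the cable at 0.25 µm and partitions length into
half-open shells `[k·step, (k+1)·step)` by Euclidean distance from the
soma; the partition conserves total cable length to < 0.5%. Calibration
anneals the orientation parameters and segment step, with the energy the
two-sample Kolmogorov–Smirnov D between a length-weighted radial sample
of a generated population and a sample drawn from the target profile;
the loop stops as soon as the K-S p-value reaches the threshold
(default 0.05), i.e. when the model and target distributions are
statistically indistinguishable at that sample size.

Boutons are placed along each maximal unbranched path with consecutive
spacings drawn from a gamma distribution parameterized by mean and SD
(defaults 3.36 and 2.54 µm). The gamma keeps spacings positive with the
realized mean equal to the configured mean in expectation. A path
shorter than its first spacing receives no boutons.

## Population layout and coverage mapping

Somata are placed uniformly in x, y and by a depth-density profile in z
inside a 354 × 354 × 140 µm³ volume (default n = 374). The published
depth histogram is not available as numbers, so the default profile is a
Gaussian bump peaking at 100 µm depth (SD 45 µm), consistent with a
peak 50–150 µm below the pia, and is user-overridable.

The coverage map counts, at every voxel center (default 1 µm voxels),
boutons within the transmitter interaction radius (default 1.5 µm) and
the number of distinct source cells among them; a brute-force per-voxel
scan is the test oracle. Voxels whose center lies within one radius of a
volume face are flagged `edge` and excluded from multiplicity
percentages, since their counts are deflated by construction. Source
multiplicity reports the percentage of covered voxels reached by exactly
1, 2, 3 or ≥4 distinct active cells; cells can be subsampled
Bernoulli(active fraction) to represent partial population activation
(all-active is the default; two-thirds approximates the fraction of the
population co-active in vivo). With arbors grown at the synthetic
defaults the single- plus two-source share dominates (> 50%); the
published 67.7/15.34/8.5/8.45% split depends on the reconstructed
arbors and is not reproducible from synthetic morphology alone.

## Transmission range

For each connection the cumulative count of presynaptic boutons within
radius `r` of the postsynaptic dendrite (polyline centerline; an
optional dendrite radius is subtracted) is inverted at the quantal
estimate `Nfrs mean ± SD` by linear interpolation between radii
(default grid 0.25–3.0 µm, step 0.25). Targets below the first count
or above the last are clamped and flagged (`below_min` / `above_max`).
Per-connection intervals are aggregated as the mean of lower and upper
endpoints — the aggregation rule is a declared choice, as no convention
exists. The correlation scan reports Pearson r between `Nfrs` and
counts per radius, skipping radii with zero count variance.

## Summation metrics

Kinetics follow electrophysiological conventions: 10–90% rise, width at
half peak, decay measured where the response has decayed by 67.3%
(to 32.7% of peak); baseline is the mean over 50 ms before the
stimulus; peak search windows default to 50 ms (fast, ionotropic) and
400 ms (slow, metabotropic). The calculated sum is the pointwise sum of
unitary traces; nonlinearity is `100·(|measured peak| − |calculated
peak|)/|calculated peak|` (negative = sublinear), and the time-resolved
version normalizes the difference trace by the calculated peak.
Burst responses are normalized per set to the single-AP peak; note that
per-set normalization then averaging differs from ratios of grand means,
so published grand means are not used as normalization truth.

`conductance_response` provides the minimal driving-force model on a
passive compartment (`C V̇ = −g_L(V−E_L) − Σ g_i(t)(V−E_syn)`): identical
hyperpolarizing conductances sum sublinearly because simultaneous inputs
share a reduced driving force. The default integrator is per-step
exponential (exact for piecewise-constant conductance); an adaptive
Runge-Kutta route exists purely as an independent cross-check.

## Calcium imaging

ΔF/F uses a running-percentile baseline, `F₀(t)` = 20th percentile of
`F` in a sliding 3 s window (both configurable), `R = (F − F₀)/F₀`.
A cell is responsive when the trial-averaged trace peaks above 3× the
SD of its pre-stimulus noise (1 s window) within 500 ms after the
stimulus. The response window bounds the number of samples the maximum
is taken over; leaving it unbounded inflates the false-positive rate of
the 3×SD rule well above the ~5% the rule is meant to deliver at this
frame rate.

## Extracellular-space lattice and tortuosity

The ECS is a periodic array of 800 nm solid cuboids separated by 32 nm
fluid gaps; each cuboid carries a dead-end cavity (400 × 400 nm opening,
340 nm deep) whose opening face alternates deterministically from cell
to cell so the medium is isotropic on average. The analytic
extracellular volume fraction, (period³ − cuboid³ + cavity)/period³ =
0.2055, rounds to the tissue value 0.2. The printed bounding box
13.28 × 13.28 × 6.592 µm³ gives the domain volume 1162.55 µm³.

Tortuosity is estimated with a blind-ant random walk: fixed-length steps
in uniform directions, rejected when they would end in solid. λ =
sqrt(D_free/D_eff) with D_eff from the slope of the mean-squared
displacement over the second half of the walk. Defaults (4000 walkers,
10⁵ steps of 9 nm) land at λ ≈ 1.63; the finite step size biases λ
upward slightly (1.66–1.69 at 12 nm steps) because rejection near walls
over-retards the walk, and the estimate approaches the tissue value 1.6
as the step is refined. The step must stay well below the 32 nm gap.

## Cluster placement and its calibration

Receptor/channel clusters arise from a two-stage seed cascade: primary
seeds land on the membrane (area-weighted), subdivide into secondary
seeds; channel-destined secondaries nucleate in place (GIRK clusters are
immobile, 1–4 channels), receptor-destined secondaries diffuse laterally
for `delay + Exp(forward rate)` before nucleating (GABA_B clusters,
1–8 receptors, remain laterally mobile). Cluster sizes are drawn
uniformly within their stoichiometric ranges with the last cluster
trimmed so totals match density × area. On meshes, lateral displacement
is applied in the local tangent plane and reprojected to the surface
(an rtree-free vectorized point-triangle projection).

Calibration anneals `(delay, forward rate)` on a flat test plane against
a target distribution of receptor-to-nearest-channel cluster distances;
the energy is the K-S D averaged over three independent cascade
realizations (averaging prevents the annealer from overfitting sampling
noise), and the acceptance tolerance defaults to the α = 0.05 critical
D for the sample sizes. The two parameters are only jointly identified
through the displacement-time distribution, so distinct `(delay, rate)`
pairs reproducing the same distance distribution are equivalent
solutions.

## Particle-based signaling simulator

Species and reactions: 3D GABA particles (released at boutons, diffusing
with `D/λ²` to account for tissue tortuosity, cleared by a first-order
sink calibrated so a single release decays with τ ≈ 11.5 ms);
GABA_B receptor clusters (activation consumes the GABA particle,
deactivation first-order); immobile G-protein heterotrimers on the
membrane, converted catalytically to laterally diffusing Gβγ near active
receptor clusters; GIRK channel clusters with four Gβγ binding sites per
channel, filled sequentially (the cooperative limit) — a channel counts
as open while all four sites of its slot are occupied, and "distinct
channels opened" is the running maximum of the open count per cluster.
Conservation invariants (receptor and channel totals; trimer + free +
bound Gβγ) are checked in tests at every recorded step.

Bimolecular events use reaction-radius sampling: a pair within the
encounter radius R reacts per step with probability `k·dt/V_R` (3D,
`V_R = 4/3 πR³`) or `k·dt/A_R` (surface, `A_R = πR²`), which reproduces
mass action in the well-mixed limit; per-cluster events are drawn as
binomials over the candidates near each cluster (the within-step
depletion correction is second order in dt). A per-step event
probability above 0.2 raises a stability error; the default dt is 1 µs,
and the scaled test configurations use 20 µs with rates that respect the
bound. Rate constants and surface densities are configuration entries
with literature-scale defaults calibrated so that a single release
activates a handful of receptors on the synthetic dendrite; they are
declared choices, not measurements.

The well-mixed oracle test runs the simulator in a 1 µm³ box with fast
3D diffusion and sparse surface clusters and compares mean free-GABA and
active-receptor trajectories to the mass-action ODE; receptors sit on
the reflecting z = 0 face, so only the inward half-sphere of each
encounter volume is accessible and the effective bimolecular rate is
`k_on/2`. Production and channel gating reuse the identical sampling
machinery validated there.

### Scaled experiment configurations

Full-scale runs of the published kind (EM-reconstructed dendrite, µs
steps, ~10⁵ s of particle updates) are out of scope; the shipped presets
preserve the cascade's structure on the synthetic spiny dendrite
(8 × 1 µm cylinder, 6 mushroom spines) with ~10³ GABA particles per
release and tens to hundreds of clusters.

*Burst linearity* (`linearity_experiment`): 4 release sites at
1.2 ± 0.7 µm from the shaft, 80 receptor/channel cluster pairs per
compartment, sparse-activation rates (per-receptor and per-channel hit
probabilities ≪ 1), matched post-release tails across AP counts, and
the deviation computed on across-seed mean counts (a ratio of means is
robust to seeds with few openings). Near-linearity of 2-AP GIRK
recruitment requires exactly the conditions the biological system
provides: receptor pools far from local saturation, a G-protein
substrate that replenishes between APs, and many channels each with a
small opening probability. Under cluster-saturating drive the same
simulator produces strongly sublinear summation — that regime dependence
is a finding of the model, not an artifact.

*Compartment effectiveness*: receptor-channel pairs are colocalized on
spines (50 nm) and segregated on the shaft (600 nm). Because Gβγ
diffuses only ~0.1–0.2 µm in its lifetime at 0.1 µm²/s, spine complexes
open channels per activated receptor far more effectively than shaft
complexes, reproducing the spine-over-shaft ordering.

## What the synthetic data do and do not show

The generators reproduce the statistical structure the analyses assume
(binomial-quantal amplitudes, prescribed IPSP kinetics, stimulus-locked
calcium transients, gamma interbouton spacings, Sholl-profile targets,
a spine-labeled surface). They do not emulate electrode noise spectra,
use-dependent depression, real arbor geometry, or EM-level membrane
shape, so passing tests demonstrate correctness of the implementations
under the stated models — not that the models capture every property of
the recordings they imitate.

## Known limitations

- The BQA Gaussian component approximation understates skew at very low
  noise; the exact gamma convolution would be preferable there.
- Blind-ant tortuosity carries an O(step) upward bias (~2% at the
  default step).
- Sequential (fully cooperative) Gβγ site filling is one limit of the
  channel-gating model; independent per-channel filling would lower
  opening counts at equal Gβγ.
- The coverage map holds all (voxel, cell) incidence pairs in memory;
  full-volume 1 µm maps of dense populations need several GB and are
  better run at 2 µm voxels.
- GABA_A receptors, transporters and vesicle-pool depletion are outside
  the simulator's scope by design.
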