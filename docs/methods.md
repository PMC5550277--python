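# Methods

## The cycle model

The closed TRAP1 dimer is modeled as a continuous-time Markov chain over
states `(conformation, nucleotide per protomer, buckled arm)`.  A dimer
state is `Open(n0, n1)` or `Closed(n0, n1; buckled = 0|1)` with nucleotides
`T` (ATP) or `D` (ADP).  Transitions:

| step | rate | notes |
| --- | --- | --- |
| closure | `k_close` | ATP binding is folded into closure (assays run far above the closure half-max, so binding is never rate-limiting); the buckled arm is chosen by a fair coin unless one protomer is pinned |
| buckling exchange (ATP/ATP only) | `k_swap_tt` | see below |
| hydrolysis, buckled arm | `k_hyd_buckled` | only the buckled conformation is catalytically competent in solution |
| hydrolysis, straight arm | `k_hyd_straight` | default 0 in solution; used in crystal mode |
| asymmetry flip | `k_flip` | fires from the hemi state (ADP buckled / ATP straight); `inf` folds the flip into the hydrolysis step (instantaneous on Pi release) |
| reopening from ADP/ADP | `k_open_dd` | in multiple-turnover mode the reopened dimer instantly exchanges to Open(ATP,ATP) |
| residual reopening | `k_open_leak` | from all other closed states; default 0 |

**Why the ATP/ATP closed state exchanges its buckling.**  Two observations
must hold simultaneously: (i) a labeled protomer of a wild-type dimer
partitions 50:50 between buckled and straight in the ATP/ATP closed state,
and (ii) a +/hydrolysis-dead heterodimer hydrolyzes *half* of its bound ATP
under single-turnover conditions.  If the buckling coin were flipped once at
closure and then frozen, the dimers that buckled on the dead arm could never
fire and the single-turnover asymptote would be 0.25, not 0.5.  The model
therefore treats the ATP/ATP asymmetry as dynamic — the closed dimer
exchanges buckled and straight arms at `k_swap_tt` — and locks the asymmetry
only once the first ATP is hydrolyzed (which is what the deterministic
hemi-state conformer assignment shows).  With a symmetric exchange the
50:50 partition is preserved exactly, and the hydrolysis-competent arm of a
heterodimer always reaches the catalytic conformation eventually, giving the
0.5 asymptote exactly.  `k_swap_tt` defaults to being fast relative to
hydrolysis (10/min with Mg, 60/hr Mg-free); its precise value only rescales
the effective first-hydrolysis rate of heterodimers.

**Variants.**  `hydrolysis_competent=False` (E115A) removes that protomer's
hydrolysis edge.  `gamma_sensor_intact=False` (R402A/R417A) pins the
protomer straight: its partner buckles at every closure, and swap/flip edges
that would buckle it are absent.  This is an idealization — the real R402A
homodimer still hydrolyzes ATP — but it is the conformational role the
variant plays in conformer-statistics experiments.  Pinning both protomers
is contradictory and rejected.

**Single-turnover mode.**  No nucleotide is replenished: the ADP/ADP dimer
reopens into an absorbing Open(ADP,ADP) state.  With a reopening leak, a
leaked-open dimer re-assorts its own two nucleotides randomly over the two
sites on re-closure (they are exchangeable in the open state); this yields
the slow second phase of +/dead single-turnover traces, which creeps from
0.5 toward 1.0 on the leak timescale.

**Crystal mode.**  The lattice fixes the closed conformation: no closure,
swap, flip or reopening; both arms hydrolyze independently
(`k_hyd_buckled`, `k_hyd_straight`).  The ATP/ADP intermediate then carries
its remaining ATP on the straight arm with probability
`k_hyd_buckled/(k_hyd_buckled + k_hyd_straight)`.

**Engines.**  `simulate_ssa` is an exact Gillespie simulation of independent
dimers; per-dimer random substreams are spawned deterministically from one
integer seed.  `simulate_master` propagates the chemical master equation on
the same enumerated state graph with matrix exponentials of the generator
(probability conservation enforced to 1e-9).  Cumulative Pi per dimer is an
event count in the SSA and the trapezoidal integral of the hydrolysis flux
in the master engine (quadrature-limited, ~1e-3 at the default grids).
Branching transitions (buckling coin, nucleotide re-assortment) are encoded
as parallel edges with the branch probability folded into the rate, so both
engines share one transition list.

**Default rates.**  With Mg (regime `mg`, per min): `k_close = 0.16` (the
measured heterodimer closure buildup), and post-closure steps fast enough
that closure is rate-limiting (`k_hyd_buckled = 2`, `k_flip = 10`,
`k_open_dd = 5`) — the measured steady-state turnover (0.19/min) only
constrains these to be faster than closure, so they are model choices.
Mg-free (regime `mg_free`, per hr): `k_close = 6.95`,
`k_hyd_buckled = 0.5808` (the solution measurements); flip and reopening
remain fast relative to hydrolysis.  All defaults are overridable.

## Kinetic fitting

Exponential fits use `offset + A(1 − e^(−kt))` for buildup and
`offset + A·e^(−kt)` for decay, with an optional `+ slope·t` linear term for
slow steady-state activity on top of a fast phase.  All fits are unweighted
least squares (lmfit); initial guesses are the rate from the half-change
time and the amplitude from the signal range, with `k >= 0` bounded.
Non-convergence flags the result but still reports parameters.

The linear regime for initial rates is the longest prefix of the trace whose
linear fit keeps R² at or above a threshold (default 0.995, at least 5
points).  The default suits noisy data; for noise-free or very clean traces
a tighter threshold (e.g. 0.9999) keeps the window near t = 0, where the
slope approximates the analytic derivative A·k.  If no prefix qualifies the
first 5 points are used with a warning.

The phosphate-sensor standard curve is a line `RFU = intercept + slope·[Pi]`
fitted only on standards below the detector-linearity cap (default 20000
RFU); application inverts the line.  The NADH-coupled conversion is
`rate = |slope| / (ε · pathlength)` with ε defaulting to the standard
6220 M⁻¹cm⁻¹.  Time units are always explicit; rounding to whole days/hours
lives in reporting helpers only (round-half-to-even), never in computation.

## Mixing deconvolution

Re-assorted dimer species follow the binomial `f², (1−f)², 2f(1−f)`.  The
default total-activity convention includes the binomial factor 2 on the
heterodimer term, which is the form consistent with the independence
expectation being the plain average of the homodimer activities (and hence a
straight line in f); the literal no-factor-2 form is available behind a
flag, where the fitted parameter simply absorbs the 2.  The fit is a
one-parameter linear least squares solved in closed form, with the
homodimer anchors fixed from the pure f = 0 and f = 1 measurements and the
standard error taken from the residual variance.  Dimer exchange is assumed
complete (the assay pre-incubates mixtures long enough); replicates are
unweighted.

## Pocket-water analysis

Waters are their oxygens; the pocket "site" is the supplied set of β/γ-
phosphate atoms.  A water counts as in-pocket when its minimum distance to
any site atom is strictly below the cutoff (default 5 Å; the boundary
convention is configurable to `<=`).  Distances use a k-d tree; an
orthorhombic box enables the periodic minimum-image convention.  Fractional
residence is in-cutoff frames over total frames; the longest dwell counts
one frame interval per in-cutoff frame in the longest contiguous run
(optionally bridging `gap_tolerance_frames` excursions), capped at the
trajectory span; non-uniform frame spacing falls back to actual timestamps
with a warning.  Residence classes (short/medium/long) are reporting bins
with configurable thresholds.  Kabsch alignment (proper rotation enforced,
degenerate selections rejected) matters only for positional density maps —
counting is rigid-motion invariant.

## DEER conformer fitting

P(r) is fitted as a two-Gaussian mixture with the weight pair constrained to
the simplex; centers are seeded from the two highest well-separated local
maxima (quantile fallback for unimodal input) and ordered µ1 ≤ µ2 after the
fit.  Centers within 2 Å flag a degenerate (effectively unimodal) fit.
Components map to conformers by proximity to reference distances (defaults
22 Å buckled / 41 Å straight, overridable because the spin-label linker
offsets the crystallographic distances); assignments that collapse onto one
reference are flagged ambiguous.  The package starts from processed P(r);
raw dipolar-signal processing is out of scope.

## Synthetic data

Generators share a `GeneratorSpec` (seed + homoscedastic Gaussian noise,
default σ = 2% of the signal scale) and echo every parameter; identical
specs give bit-identical output.  Conditions default to the study values:
closure 0.16/min (Mg) or 6.95/hr (Mg-free), per-site Mg-free hydrolysis
0.5808/hr over a spontaneous 0.00155/hr, 500 µM initial ATP, P(r) centers
22/41 Å, frames every 3 ns.  The FRET generator maps the model's closed
fraction f to channels `donor0(1 − η f)` and `acceptor0(1 + κ f)` with
modest default contrasts (η = κ = 0.1) so the Δ-ratio stays close to a
single exponential, as in the real assay; large contrasts would curve the
ratio and bias naive exponential fits.  The phosphate generator assumes all
sites closed and loaded (the titration data justify ≥80% closed at 500 µM
ATP; a closed-efficiency factor exposes the correction, default 1) and
renders Pi through the standard curve, compressing the response above the
detector cap so the analysis-side exclusion rule has something to exclude.
Trajectory waters follow an exact two-state telegraph process sampled at the
frame interval (stationary occupancy k_on/(k_on+k_off)); bound waters sit
within 3 Å of their pocket center, unbound waters are uniform in the box
but excluded from both cutoff shells.  The default kinetics make the
buckled pocket drier (occupancy 0.10 vs 0.20) and shorter-lived (mean dwell
5.6 vs 16.7 ns) than the straight pocket — the direction of the real
observation.  The generators emulate none of: detector drift,
photobleaching, correlated noise, protein atoms, or real water structure —
so passing round-trip tests shows the estimators are unbiased and correctly
scaled under the assumed noise model, not that they are robust to real-data
artifacts.

## Problem sizes and tolerances

Stochastic checks run 10,000 dimers (binomial SE ≈ 0.5%, asserted within 3
SE); SSA/master cross-validation uses pointwise 3·SE bands plus a small
absolute floor for near-empty states.  Noise-free fit recoveries assert
≤1e-6 relative error (exponential/Hill) or ≤1e-3 (two-Gaussian); ensemble
recoveries assert the median relative rate error ≤5% at 2% noise over 100
seeds and median weight error ≤0.03 at 1% grid noise.  Master-equation
probability sums are enforced to 1e-9.

## Known limitations

- The cycle model has no client binding, no temperature dependence of the
  closure barrier, no cochaperones and no explicit ATP-binding step.
- The mapping between per-dimer cycle flux and measured steady-state rate
  depends on the per-site vs per-dimer basis of the reported turnover;
  both bases are exposed rather than asserted.
- Whether the straight protomer hydrolyzes at all in solution is unresolved;
  `k_hyd_straight` defaults to 0 outside crystal mode.
- Crystal-mode rates are user-set; the in-lattice rates are only known to
  correspond to the solution rates within an order of magnitude.
- The water generator's pockets are isotropic shells; real pockets are
  anisotropic and water exchange is not Markovian at all timescales.
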