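# Methods

## The model

Two all-to-all layers of `N` identical phase oscillators represent a volume
element of organ tissue: layer 1 the parenchyma, layer 2 the stroma/innate
immune system.  A node's phase stands for its metabolic rhythm; a pair's
coupling weight `κ_ij ∈ [−1, 1]` stands for the cytokine-mediated
information flow between the cells.  The governing equations are

    dφ_i^μ/dt = ω^μ − (1/N) Σ_{j≠i} w_ij^μ sin(φ_i^μ − φ_j^μ + α^μμ)
                − σ sin(φ_i^μ − φ_i^ν + α^μν)
    dκ_ij^μ/dt = −ε^μ (κ_ij^μ + sin(φ_i^μ − φ_j^μ − β)),       i ≠ j

with `w_ij^1 = a_ij + κ_ij^1` (fixed all-to-all adjacency plus adaptive
weights) and `w_ij^2 = κ_ij^2` (purely adaptive).  Sums run over `j ≠ i`
and the weight diagonals are identically zero; a self-weight would only add
a common constant drift, and excluding it keeps the reduced model exact up
to the finite-size factor `(N−1)/N`.

Assumptions inherited from the modeling framework: identical natural
frequencies (set to 0 in a co-rotating frame), equal intralayer lags
`α¹¹ = α²² = α⁰`, symmetric interlayer coupling, time-scale separation
`ε¹ ≪ ε² ≪ 1` ("slow-fast-faster": slow parenchymal cytokines, faster
immune cytokines, fast phases).

### Parameters (defaults = the reference regime-map set)

| parameter | meaning | default |
|---|---|---|
| `N` | nodes per layer | 200 (50 at desk scale) |
| `α⁰` | intralayer phase lag (interaction delay), rad | −0.28π |
| `α¹² = α²¹` | interlayer phase lag, rad | 0 |
| `β` | age parameter (plasticity-rule lag), rad | 0.5π reference |
| `ε¹`, `ε²` | adaptation rates, 1/time | 0.03, 0.3 |
| `σ` | interlayer coupling strength, dimensionless | 1.0 reference |
| `C` | initially activated immune-cluster size | 40 (C/N = 0.2) |

`ε = 0` is accepted by the validator; it freezes the weights and recovers
the classical Kuramoto–Sakaguchi limit, used as an integrator sanity check.

## Initial conditions (the "infection")

Phases in both layers: i.i.d. uniform on `[0, 2π)` (half-open; the closed
endpoint is a measure-zero difference).  Parenchymal weights: i.i.d.
uniform on `[−1, 1]` off-diagonal.  Immune weights: a deterministic
two-block matrix — 1 inside the first `C` indices and inside the remaining
`N − C`, 0 between and on the diagonal — representing a systemic immune
activation by a local infection of size `C`.  The small cluster occupies
the first `C` indices; under all-to-all base coupling the labeling is
arbitrary, and fixing it aids reproducibility.  One PCG64 generator per
state, draw order `phi1, phi2, kappa1` (row-major), so equal seeds give
bitwise-equal states.  Ensemble member seeds are spawned deterministically
from a master seed and the *same* member list is reused at every grid point
of a sweep, so that differences across a regime map reflect parameters, not
initial conditions.

These random initial conditions deliberately do *not* start from the
healthy synchronized state: they map out the multistable state space after
a perturbation.  Consequently all regime statistics are probabilities over
initial conditions, not properties of a single trajectory.

## Integration

Adaptive explicit Runge–Kutta 5(4) (`scipy.integrate.solve_ivp`, RK45) with
rtol 1e−6, atol 1e−8, sampled every 0.5 time units; the dynamics are
slow–fast but not stiff, and an explicit adaptive scheme is reproducible
across platforms.  The `2N + 2N(N−1)` unknowns are packed into one flat
vector (`phi1, phi2, kappa1` off-diagonals row-major, `kappa2` likewise);
the packed right-hand side is JIT-compiled and is asserted, in the test
suite, to agree with both a vectorized NumPy implementation and a literal
double-loop transcription to 1e−12.

Phases are integrated and stored unwrapped (never reduced mod 2π), because
mean phase velocities are endpoint differences over the averaging window.
A guard (`unwrap_check`) flags sampling too coarse to resolve the
oscillation.  Because the relative error control acts on the growing
unwrapped phases, a long run accumulates a slow O(|φ|·rtol) wander in the
absolute phases; all reported measures (velocities, order parameters,
interlayer offsets) are differences or window averages, which are
insensitive to it.  Weights started in `[−1, 1]` remain there (the
adaptation law is inward-pointing on the boundary); this is asserted, not
enforced by clipping.

## Measures and state taxonomy

* Mean phase velocity per node: `(φ(t_end) − φ(t_end − T)) / T`, default
  window `T` = half the run.
* Phase coherence: the second Kuramoto–Daido moment
  `R2 = |N⁻¹ Σ e^{2iφ}|`, time-averaged over the trailing window.  `R2 = 1`
  marks antipodal states (in-phase included), `R2 = 0` splay states.
* Frequency spread: population standard deviation σ_χ of the node
  velocities about the layer mean.
* A layer holds a **frequency cluster** iff some node's velocity deviates
  from the layer mean by more than δ = 0.01 rad/time; node groups are
  formed by single-linkage on sorted velocities with gap > δ.  δ is the
  numerical rendering of the strict "≠" on finite windows and sits well
  above the finite-window noise (~2π/T) and well below observed cluster
  splittings (~0.1–0.5).
* **Splay** detection: frequency-synchronized and time-averaged R2 < 0.05.
* **Interlayer locking**: every per-node difference `φ_i¹ − φ_i²` has
  standard deviation < 0.01 rad over the window; offsets are window means.
* Classification (total, priority top-down): parenchymal cluster →
  `frequency-cluster-pathological`; immune cluster only →
  `immune-activated-parenchyma-healthy` (resilient); splay parenchyma →
  `splay-vulnerable`; otherwise `in-phase-healthy`.

## Ensembles and regime maps

The ensemble statistics per grid cell are `s^μ` (mean of member σ_χ), its
normalized variant, the frequency-cluster ratio `f^μ` (fraction of members
with a cluster — the model's proxy for the probability of a pathological
state), and the splay ratio.  Desk scale is `N = 50, N_E = 10,
t_end = 1000, T = 1000…500` discarding the first half; full scale
(`N = 200, N_E = 50, t_end = 2000, T = 1000`) is available behind the
`full_scale` flag.  All-to-all coupling makes the regime boundaries only
weakly N-dependent, which is what desk scale exploits; the test suite and
the acceptance script use desk scale throughout.  1-D curves can be
smoothed with a trailing 4-point moving average (edges truncated).

### Measuring regime onsets

The system is strongly multistable, and isolated solitary-node frequency
clusters (1–2 nodes splitting off, Δω ≈ 0.5) occur with probability
~0.1–0.3 per random initial condition even *below* the critical interlayer
coupling — at desk scale and at N = 200 alike, and robust under a
1000-fold tightening of the integration tolerances.  The parenchyma below
the critical coupling therefore synchronizes in *most* but not all members,
and the first grid point with a nonzero cluster ratio is a biased estimator
of the regime boundary.  Both reported onsets consequently use a sustained
rule: the smallest swept value at which the cluster ratio exceeds its
threshold (0 for the coupling sweep, 0.2 for the age sweep) *and* is
nondecreasing over the next two grid points.  On the desk-scale grids this
yields a critical interlayer coupling σ_c = 0.5 (β = 0.7π) and an
age-parameter onset of 0.56π (σ = 1).

## Analytic reduction

The adaptation ODE is linear in κ, so each weight is the convolution of an
exponential kernel `ε e^{−εs}` with `−sin(Δφ(t−s) − β)`; the kernel
evaluation truncates at `s_max = −ln(1e−10)/ε` (exponential tail bound) and
the quadrature is cross-checked against direct integration of the
adaptation ODE.  On the fully synchronized manifold the kernel integrates
to one and each layer obeys a scalar phase equation; equating the two layer
frequencies gives

    sin(φ¹ − φ²) = −sin α⁰ / (2σ),

hence the existence bound `σ > |sin α⁰| / 2` (0.385 at α⁰ = −0.28π), the
principal-branch lag `Δ = arcsin(−sin α⁰ / 2σ)` (0.126π at σ = 1; the
second branch `π − Δ` is the unstable lock — stability is checked
numerically, not claimed analytically), and the common locked frequency
`−sin α⁰ (sin β + ½)`.  Full-model comparisons apply the `(N−1)/N`
finite-size factor inside the arcsin.  Correction terms for coexisting
frequency-cluster states (beyond the synchronized manifold) are out of
scope: no closed formulas are implemented for them.

## What the generator emulates — and what it does not

The synthetic initial conditions reproduce the statistical structure of the
model's study design (uniform phases/weights plus the two-block immune
activation); they are not patient data.  Passing tests show that the
*dynamical mechanism* — age- and coupling-dependent loss of parenchymal
synchrony after an immune perturbation — behaves as described, at desk
scale; they say nothing about clinical calibration of β, σ, or the
time unit.  Layer 2 is a severe coarse-graining of the innate immune
system; fixed one-to-one interlayer links ignore organ heterogeneity.

## Numerical choices and degenerate inputs

* Angle inputs accept the `pi` suffix (`"-0.28pi"`); stored in radians.
* `σ = 0` decouples the layers exactly (the layer-1 flow is independent of
  layer-2 state; numerically verified to integrator tolerance — bitwise
  independence is not expected because adaptive step control is shared).
* `C` is validated to `1 < C < N`; sweep axis values in (0, 1) are read as
  fractions `C/N`.
* Member failures inside an ensemble are recorded and excluded from
  aggregates rather than aborting the sweep; grids are checkpoint/resume
  safe per cell.
* Ties in the frequency partition are resolved by stable sorting; groups
  are reported largest-first.

## Known limitations

* Desk-scale ensembles (10 members) quantize ratio estimates to 0.1; regime
  boundaries are accurate to about one grid step.
* The splay/locking thresholds (0.05 on R2, 0.01 rad) are numerical
  renderings of exact statements; states hovering at a threshold can
  classify either way.
* The reduced model assumes equal intralayer lags and zero interlayer lags;
  it is not valid for the α-sweep regime maps.
* Long trajectories accumulate slow absolute-phase wander from relative
  error control (see Integration); quantities derived from phase
  differences are unaffected.
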