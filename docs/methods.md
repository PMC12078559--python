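# Methods

## The two-state swimming model

A photoswitchable DNA condensate under localized alternating irradiation is
reduced to two well-mixed compartments: a Liquid domain of mass `m_L(t)`
(the condensate proper) and a Dissociated domain of mass `m_D(t)` (the
cloud of free motifs discharged around it). Photoswitching is instantaneous
("a pulse-like shot"); the system alternates between UV-to-Vis and
Vis-to-UV intervals of equal length `T`. The lap time `t'` runs from 0 to
`T` within each interval and resets at every switch. We count switching
frequency in full UV+Vis cycles, `f = 1/(2T)`; this convention is
configurable in the sense that all interval-level APIs take `T` directly.

Mass transport (all quantities dimensionless):

- UV-to-Vis: `dm_L/dt = -A(t') m_L`; a fraction `λ(t')` of the transfer is
  lost to free diffusion (`m_lost`), the rest enters `m_D`.
- Vis-to-UV: `dm_D/dt = -B m_D` with constant disengagement `κ`; the kept
  fraction returns to `m_L`.

`A(t')` and `λ(t')` grow nonlinearly with `t'` relative to a characteristic
diffusion time `t*`. We use the saturating form
`A(t') = A_max (1 - exp(-(t'/t*)²))` (and likewise for `λ` with `λ_max`):
quadratic at small lap times — a diffusion-limited onset — and bounded by
the maximum ratio. The onset profile is pluggable (`ModelParams.ramp`), so
alternative forms can be swapped in without touching the integrator.

### Velocity model

Motion is one-dimensional (positive = away from the irradiated ROI), with
two contributions per interval — momentum exchange and viscous
dissipation — integrated together with the masses:

- **UV recoil.** Mass ejected backward at relative speed `v_eject` produces
  rocket-type recoil `du = A(t') v_eject dt`. Note the per-mass form: the
  recoil does not depend on the absolute mass, only on the fractional
  ejection rate.
- **Dissociated momentum pool.** The kept ejected mass enters the
  Dissociated domain at lab velocity `u - v_eject`; the pool's bulk
  velocity `u_D` is the mass-weighted mix and relaxes toward zero at rate
  `β` (diffusive randomization of the discharged cloud), in both intervals.
- **Vis-interval exchange.** Returning mass mixes perfectly into the
  Liquid domain carrying velocity `u_D - v_reverse` (the conserved ejection
  momentum plus the reversing flow at speed `v_reverse` toward the ROI):
  `du = (1-κ) B (m_D/m_L) ((u_D - v_reverse) - u) dt`, with `m_L` floored
  at 1e-12 in the denominator. This is the momentum-exchange term that the
  `exchange_enabled=False` ablation removes (the recoil and the drag stay).
- **Drag.** `du = -γ u dt` in both intervals.

Integration is forward (explicit) Euler with step `dt`; validation enforces
`A_max·dt < 1` and `B·dt < 1` so masses stay nonnegative. The mass updates
are split as `dm_kept = dm - dm_lost` so the ledger
`m_L + m_D + m_lost = m_L(0)` holds to floating-point rounding (tested at
1e-9 relative). The model has no randomness: identical inputs give
bit-identical series.

### Default parameters and calibration

Initial condition `m_L(0) = 100`, `m_D(0) = 0`; `dt = 0.01`;
`t* = 800·dt = 8`. The remaining defaults (shipped in
`src/azoswim/data/defaults.yaml`) were calibrated once, by a coarse grid
search over the momentum/rate parameters, to reproduce the qualitative
switching-frequency regimes of the system — push at low `f`, stronger pull
at intermediate `f`, near-zero motion at high `f`, lifetime nondecreasing
in `f`, push-only under the exchange ablation — and then frozen:

| parameter | value | meaning |
|---|---|---|
| `A_max` | 0.05 | max UV disassembly ratio (1/time) |
| `λ_max` | 1.0 | UV disengagement saturates at total loss |
| `B` | 0.3 | Vis reassociation ratio (1/time) |
| `κ` | 0.05 | Vis disengagement ratio |
| `v_eject` | 1.0 | UV ejection speed relative to the Liquid domain |
| `v_reverse` | 5.0 | Vis reversing-flow speed toward the ROI |
| `γ` | 0.2 | viscous drag rate (1/time) |
| `β` | 0.1 | momentum-decay rate of the Dissociated pool |

Two of these choices carry the regime structure and deserve comment.
First, `λ_max = 1`: at lap times long compared with `t*`, essentially all
UV-discharged motifs diffuse away irrecoverably. This is what makes
low-frequency swimming push-dominated (almost no mass returns to pull) and
intermediate-frequency swimming pull-dominated (short laps keep `λ` small,
so most discharged mass survives to return). Second,
`v_reverse > v_eject`: the reversing flow must inject fresh momentum,
because the momentum conserved from the ejection alone can never exceed
what the recoil already imparted (mixing and randomization only lose it).
The default regime margins are robust to ±10 % perturbations of every other
parameter.

The default sweep uses frequencies (0.0125, 0.0625, 0.5) — half-cycles of
5`t*`, `t*`, and `t*`/8 — over a horizon of 200 time units. The horizon is
an odd multiple of the low-frequency half-cycle so every run ends exactly
at a switching moment after a completed UV interval; displacements are read
off at switching moments, matching how interface positions are recorded
experimentally. Net displacement at low `f` oscillates within each UV/Vis
cycle, so summaries are only meaningful at these cycle-aligned horizons.
A run of the three-frequency sweep takes well under a second.

`lifetime` is defined as the first passage of `m_L` below 10 % of `m_L(0)`
(infinity if it never happens within the horizon); the threshold is a
parameter of `summarize_run`.

## MSD and signed diffusion coefficient

The time-averaged MSD of a uniformly sampled 2D track is computed by the
FFT/autocorrelation route: writing
`MSD(k)·(N-k) = Σᵢ(|rᵢ|² + |rᵢ₊ₖ|²) - 2 Σᵢ rᵢ·rᵢ₊ₖ`, the second sum is an
autocorrelation obtained with zero-padded FFTs (Wiener–Khinchin) and the
first by a running-sum recursion, giving O(N log N) overall. The naive
O(N²) implementation is kept as an independent oracle; equivalence is
tested to 1e-9 relative on randomized tracks up to length 2048.
Non-uniformly sampled tracks are routed to the naive path.

Fitting protocol for `D'`: drop lags averaging fewer than two displacement
pairs, keep the first 20 % of lags (the statistically reliable head of the
curve), fit an unweighted least-squares line to the largest 20 % of the
retained lags, and take `D' = slope/4` (in 2D, `⟨r²(τ)⟩ ~ 2dDτ` with
`d = 2`). Both fractions are parameters. A negative fitted slope is clipped
to `D' = 0` with a warning rather than propagating a negative diffusivity.
The fit is unweighted ordinary least squares; lag-dependent weighting by
pair counts is not applied.

Ensemble flow direction is automated as the sign of the net radial
displacement with respect to a supplied ROI center (default: ensemble
centroid of initial positions), with a ±0.5 µm noise floor mapped to
`unclassified`; a per-experiment manual override is available in the CLI.
The signed mobility is `D* = -D'` for inward flow and `+D'` otherwise, so
`|D*| = D'` always. `select_top` returns up to k estimates with the largest
`D'`, ties broken by track id for determinism.

## Swimming kinematics and the threshold frequency

Interface positions at successive switching moments give step displacements
`Δr_i`, running vector sums `(Δx, Δy)`, the net displacement
`L(t) = |Σ Δr_i|` and its maximum `L_max`, and a normalized elapsed time.
The threshold estimate treats one swimming cycle as a diffusive traversal
of the condensate size `a` by the UV-spread flow (effective mobility
`D_S`) plus the reverse traversal by the Vis flow (`D_R`), using the 2D MSD
relation `⟨r²⟩ ~ 4Dτ`:

    τ_c = a²/(4 D_S) + a²/(4 D_R),  f_c = 1/τ_c .

With a = 20 µm, D_S = 20 µm²/s, D_R = 10 µm²/s this gives τ_c = 15 s and
f_c ≈ 0.07 s⁻¹ (full precision 1/15 retained internally; two decimals for
display). `f < f_c` is classified dissipation-dominant push-swimming,
`f > f_c` exchange-dominant pull-swimming; the boundary `f = f_c` is
assigned to pull with an explicit flag (an arbitrary but stated tie-break).
The mobilities are used in µm²/s, the only unit for which `a²/4D` is a
time.

## Temperature–flow-mode classifier

Each variant (named by the azobenzene insertion site in the 8-nt sticky
end: Y_1x7, Y_3x5, Y_2x1x5) carries, per isomer state, a gel–liquid
transition temperature `T_GL` and a dissolving temperature `T_D`, with the
ladder gel → liquid → dissociated on half-open intervals
`[T_GL, T_D)`; temperatures within 0.1 °C of a boundary are snapped onto
it. Invariants: `T_GL ≤ T_D` per state and `T_D(cis) ≤ T_D(trans)` (cis
destabilizes binding). The flow mode is a pure function of the
(Vis-state, UV-state) pair: (gel, dissociated) → spread;
(gel, liquid) → collapse; (liquid, dissociated) → spread-and-collect;
anything else → none. Spread vs spread-and-collect (both dissociated under
UV) is resolved by the initial Vis state — gel gives the fast outward
dissolution, liquid the cyclic out-and-back flow.

The shipped fixtures carry the measured dissolving temperatures where
printed (50 °C for Y_2x1x5 and 65 °C for Y_3x5 under trans); all `T_GL`
values and the remaining `T_D` values are *derived*, back-solved so the
classifier reproduces the observed mode/temperature ranges, and are labeled
synthetic in the code. The observed Y_3x5 assignments overlap at 55–60 °C
(spread in one experimental configuration, spread-and-collect in another);
a pure function of (variant, T) cannot produce both, and the classifier
resolves the overlap to spread-and-collect, reproducing the spread
assignment on 45–54 °C. Sticky-end binding-enthalpy magnitudes
(`dH_trans`, `dH_cis`) are carried as passthrough metadata only; no melting
thermodynamics is computed. The sharp `T_GL` boundary is a simplification
of what is experimentally a rheological crossover.

## Synthetic data

Generators are deterministic under a fixed seed
(`numpy.random.default_rng`), and every output track embeds its generating
spec. Brownian tracks use Gaussian increments of variance `2 D Δt` per
axis; ballistic tracks a per-particle random heading at constant speed;
radial ensembles start on a 20–50 µm annulus and drift at `v_true` outward
(spread) or inward (collapse, stopping at a 0.5 µm core) superposed on
diffusion, with the ground-truth direction attached. Interface walks use a
persistent heading with angular jitter; push-walks take ~5 µm steps for 11
switches, pull-walks ~1.5 µm steps for 30 switches with a step-length decay
(plateau) after 60 % of the walk — emulating the larger stepwise
displacements but shorter life of push-swimming versus the longer plateaued
pull-swimming. Isotropic Gaussian localization noise (default 0.05 µm) is
added to every recorded position, the standard tracking-error model; frame
interval defaults to 0.2 s, matching 200-ms video sampling.

What the generators do *not* emulate: detection/linking errors other than
Gaussian jitter (no missed detections, no track fragmentation or identity
swaps), spatially correlated flows, condensate shape change, or 3D motion.
Passing tests therefore validate the estimators under idealized sampling,
not robustness to tracking artifacts.

## Test problem sizes

The default suite runs in well under a minute: MSD oracle equivalence on
200 randomized tracks up to length 2048; diffusion recovery on 50 Brownian
tracks × 5000 steps at D = 0.5 µm²/s (mean `D'` recovered within 15 %;
observed error ≈ 0.2 %); radial direction calls on 100-track ensembles
(≥ 95 % correct); model sweeps at three frequencies over a horizon of 200
time units (20 000 Euler steps each). These sizes are the package's chosen
defaults for fast, deterministic regression testing.

## Known limitations

- The two-state model is 0-dimensional in space and 1-dimensional in
  motion: no hydrodynamics, no concentration fields, no condensate
  morphology, and no parameter fitting to experimental movies.
- After the Liquid mass has decayed far below its initial value the
  velocity dynamics continue at full per-mass strength (both recoil and
  exchange are mass-ratio terms); summaries past the lifetime describe the
  model, not a physical condensate.
- The onset forms of `A(t')`/`λ(t')` and the explicit momentum terms are
  this package's own constructions from momentum conservation plus the
  qualitative description of the mechanism; they are pluggable by design.
- The MSD fit window (head-truncation then tail-fit) assumes uniformly
  sampled tracks long enough to leave ≥ 5 usable lags.
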