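# Methods

## Model overview

`spindlesim` simulates the receptor potential of a muscle-spindle Ia
afferent as the weighted output of two intrafusal half-sarcomere models
operating in parallel under an imposed length trajectory and an imposed
calcium activation.  The bag fibre (slow, dynamic, bag1-like) and the chain
fibre (fast, static, bag2/chain-like) share the same structure and differ
only in their myosin rate parameters, detachment offsets and passive
elements.

Assumptions inherited from this modelling tradition:

* contractile properties are uniform along the fibre, so one half-sarcomere
  represents the whole fibre and length is imposed directly (no
  series-elastic or force-balance coupling, no extracellular matrix);
* myosin has exactly two states (detached, attached-with-strain); no
  power-stroke sub-states;
* calcium is a control input (pCa), not a state variable;
* the afferent's spike generation and mechanotransduction are not modelled;
  the receptor potential is a phenomenological force/yank readout in
  arbitrary units.

## Half-sarcomere kinetics

State: activated-actin fraction `A`, bound-myosin fraction per strain bin
`M_i` (detached fraction is `1 − Σ M_i` by construction), half-sarcomere
length `L` (nm).

* **Overlap.**  `n_ov = (l_thin − (L − l_thick)) / (l_thick − l_bare)`,
  clamped to [0, 1].  With the default geometry (1120, 815, 80 nm,
  L0 = 1300 nm) the resting overlap is 635/735 ≈ 0.864.
* **Thin filament.**  `dA/dt = k_on [Ca] (n_ov − A)(1 + k_coop A/n_ov)
  − k_off (A − cb)(1 + k_coop (n_ov − A)/n_ov)` with `cb = Σ M_i`.  Sites
  carrying a bound cross-bridge cannot deactivate; cooperativity (k_coop)
  boosts activation in proportion to existing activation and suppresses
  deactivation near saturation.  At `n_ov = 0` the cooperativity ratios and
  the activation term are defined as zero.
* **Myosin.**  Attachment is Gaussian in strain,
  `f(Δx) = slope · exp(−k_cb Δx² / const_f)` (1/e half-width
  `sqrt(const_f/k_cb)` ≈ 8.5 nm with the defaults), drawing on the detached
  pool in proportion to the free activated actin `(A − cb)`; new attachments
  are distributed over bins by the normalized f profile (per-bin flux
  `f_i w_i (1 − cb)(A − cb)` with `w_i = f_i / Σf`, whose bin-sum is
  grid-refinement invariant and reduces to the scalar two-state law on a
  single-bin grid).  Detachment `g(Δx)` is a U-shaped piecewise cubic:
  coefficient 0.2 nm⁻³ s⁻¹ below the breakpoint at −5 nm, 0.3 above, plus
  the fibre-specific extra offset on both branches, so the minimum is
  `b_g + offset` at the breakpoint (7.5 s⁻¹ bag, 310 s⁻¹ chain).  The 20×
  gap between the fibres' pool lifetimes is what makes the bag dynamic and
  the chain static.
* **Stress.**  `σ = 1e-9 · cb_density · k_cb · (Σ Δx_i M_i) + k_p (L −
  L_slack)`.  The 1e-9 converts nm strain to m so that, with the
  tabulated `k_cb = 0.001` and density 6.9×10¹⁶ m⁻², the cross-bridge term
  is 6.9×10⁴ N m⁻² per (nm · unit bound fraction) — the per-bridge spring
  constant is effectively 1 pN/nm.  The passive term is signed linear (it
  goes negative below slack; no clipping).

## Receptor potential

`r = scale (k_fc F_c + k_fb F_b + k_yb [dF_b/dt]₊)` with k_fb = 0.4,
k_fc = 0.5, k_yb = 0.005, scale = 2×10⁵.  The yank is a causal first-order
backward difference, rectified before weighting (equivalent for positive
k_yb); the first sample's yank is zero.  Stress is converted to force with
a nominal cross-sectional area of 1×10⁻⁹ m² (≈ (32 µm)², a realistic
intrafusal cross-section) — chosen a priori by dimensional analysis so the
receptor potential lands on an O(1)-a.u. scale; all receptor-potential
units are arbitrary.

## Numerics

* **Time stepping** (dt = 0.1 ms): operator splitting per step — explicit
  Euler for `A`, then per-bin exponential relaxation
  `M_i ← M_i e^{−g_i dt} + flux_i (1 − e^{−g_i dt})/g_i` (exact for frozen
  coefficients, unconditionally stable, and with fixed points identical to
  the continuous ones), then advection.
* **Advection** is an exact lazy-rolled translation: the sub-bin part of the
  imposed displacement accumulates in a grid-wide strain offset δ
  (|δ| ≤ bin/2) and whole-bin rolls are applied when it overflows.  This is
  mass-conserving and diffusion-free; interpolation-based shifting was
  rejected because its numerical diffusion smeared the shortening-swept
  cohort by several nm and its residual offset biased the post-ramp steady
  state.  All rate functions are evaluated at the true strains
  (bin centre + δ), and the stress sum uses them as well.  Mass rolled past
  a grid edge is treated as forcibly detached.
* **Strain grid**: 0.5 nm bins over [−40, +25] nm.  The span is set so that
  the occupancy of the outermost bins stays below 10⁻⁶ in every shipped
  protocol (measured ≤ 4×10⁻⁸); exceeding that tolerance raises a
  grid-overflow error rather than silently losing bound mass.  The negative
  side needs the headroom: during a 12 %L0/s shortening ~2% of the bound
  cohort survives beyond −15 nm.
* **Convergence**: halving dt and the bin width together changes the
  ramp-and-hold bag stress trace by 0.056% RMS (enforced < 1% by a test).
* **Protocols** are generated at 10 kHz from exact breakpoints
  (piecewise-linear) or closed-form sinusoids and linearly resampled to the
  engine step.  Every shipped protocol begins with a 2 s isometric pre-hold
  at the protocol pCa (default 6.4) so activation and the bound pool are at
  steady state before any length change.

## Feature conventions

* **Initial burst**: baseline = mean response over the 0.5 s before stretch
  onset; the burst is the first strictly interior local maximum inside the
  ramp window that is followed by an interior local minimum (the post-burst
  dip) before the ramp ends.  Requiring the dip distinguishes a genuine
  short-range-stiffness transient from the peak a monotonically rising
  response reaches at the stretch turnaround.  Presence additionally
  requires the value to exceed ε_burst = 2% of the reference
  (conditioning/unconditioned) burst.
* **Dynamic response**: least-squares line from the response minimum after
  the burst peak to the end of the ramp (from ramp onset when no burst);
  reported as slope × fit-interval (the raw slope is also exposed).
* **Dynamic index**: maximum of the response between the post-burst dip and
  the end of the ramp, minus the response at the end of the hold.
* **Recovery time**: first time after the test-stretch onset at which the
  signal exceeds its pre-conditioning resting mean by ε_recovery = 1% of the
  conditioning peak's rise above rest; zero if already above, undefined if
  never reached.

## Experiment drivers

The ladder enables thin-filament mechanisms one at a time
(`activation_only`: k_off = 0, k_coop = 0; `activation_plus_deactivation`:
k_coop = 0; `full_with_cooperativity`: k_coop = 1 — the tuned final model).
The rate sweep crosses decade steps of the bag detachment offset b_g with
decade steps of the chain attachment slope c_f around the tuned set
(b_f = 600, b_g = 7, c_f = 400, c_g = 300 s⁻¹).  The history sweeps scan the
inter-stretch interval (0–10 s, 0.1 s grid), the conditioning amplitude
(0–5.6 %L0, 0.1 %L0 grid) and sinusoid amplitudes (0.0016–1.6 %L0 at 1 Hz,
3 cycles).  Long sweeps continue deterministic state snapshots of shared
protocol prefixes instead of re-simulating them; a regression test checks
the continuation against a single-piece simulation.  Everything is
deterministic: identical configs give bit-identical tables.

Two discretization caveats for sweep consumers: ramp durations such as
5.6/12 s do not fall on the 0.1 ms sample grid, so stitched and
single-piece simulations of the same nominal protocol can differ by
sub-sample knot placement; and at a shorten-to-stretch reversal the
rectified yank jumps discontinuously, so the height of the resulting
one-sample spike in `r_total` is sensitive to that placement.  At
inter-stretch intervals below ~0.5 s the detected "test burst" is this
corner spike.

## Design choices at genuinely open points

* The detachment cubic uses the magnitude of the distance below the
  breakpoint (U-shape) and applies the fibre-specific extra offset to both
  branches.
* The attachment exponent uses the tabulated numbers as printed
  (k_cb/const_f = 1/72 nm⁻²).
* Sinusoids are raised cosines (start at L0 moving into stretch) and their
  amplitude is the peak (not peak-to-peak) excursion.
* The hold-phase reference for the dynamic index is the end of the
  protocol.
* Triangular test stretches are followed by a 1 s trailing hold.

## What the generator does and does not emulate

The protocol generator reproduces idealized laboratory stretch paradigms
(constant-velocity ramps, symmetric triangles, fixed-frequency sinusoids)
under constant pharmacological-style activation.  It does not emulate
natural movement trajectories, fusimotor (gamma) drive transients, spiking,
or biological variability — there is no noise model at all.  A green test
therefore establishes the deterministic input–output behaviour of this
model under these idealized protocols, not agreement with any particular
biological recording.

## Known limitations

* **History dependence is much faster and weaker than in real spindles.**
  With the shipped rate constants the bag fibre operates at a very high
  duty ratio: effective attachment (hundreds per second) far exceeds the
  detachment minimum (7.5 s⁻¹), so bound myosin locks activation on
  (A ≈ 0.58, cb ≈ 0.52 at rest) and the bound pool is replenished during a
  shortening about as fast as the strain drag destroys it.  Consequently
  bag stress reappears within ~10 ms of a test stretch (biological
  intrafusal fibres take ~0.15–0.3 s), the test-stretch burst is only
  partially suppressed at zero inter-stretch interval (~60–110% of the
  conditioning burst depending on the baseline window) instead of being
  abolished, and burst recovery versus ISI is non-monotone at short
  intervals because of the corner-yank spike.  This is structural: the
  replenishment ratio during shortening is (pool detachment rate) ×
  (drag transit time), independent of the attachment scale, so no
  re-normalization of the attachment flux restores the slow regime, and
  alternative readings of the rate conventions (narrow attachment windows,
  clamped detachment floors, a mirrored breakpoint, a power-stroke force
  offset) were each tested and either behave identically or destabilize the
  cooperative activation dynamics.  The chain fibre, by contrast, matches
  its expected behaviour closely (steady activation ~12%, stress recovery
  ~2 ms, no history dependence).
* **Receptor-potential magnitudes are arbitrary-unit.**  The stress→force
  area constant fixes only the scale's order of magnitude; feature values
  (e.g., the 20.6 a.u. ramp-and-hold burst) should be compared across
  conditions, not across implementations.
* The resting bag cross-bridge stress is large and negative because the
  detachment minimum at −5 nm concentrates the bound pool at negative
  strains while the spring force is proportional to the signed strain.  A
  power-stroke offset in the force sum would shift this to a positive
  resting tension but is not part of the printed stress convention adopted
  here.
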