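# spindlesim

A biophysical simulator of the muscle-spindle Ia-afferent receptor potential.

Muscle spindles are the stretch sensors embedded in skeletal muscle.  Their
primary (Ia) afferents wrap specialized intrafusal fibres and fire with
characteristic, strongly history-dependent dynamics: a sharp *initial burst*
at stretch onset, a rising *dynamic response* during the ramp, adaptation
during the hold, and suppression of the burst when a stretch follows shortly
after a previous stretch–shorten cycle.  `spindlesim` models these behaviours
from the cross-bridge level up, for users in computational neurophysiology
and muscle biophysics who want to link intrafusal contractile properties
(myosin attachment/detachment rates, thin-filament activation) to the sensory
signal.

## Model

Two intrafusal fibres are simulated as independent half-sarcomeres with
imposed length L(t) (in % of the resting length L0 = 1300 nm) and imposed
calcium activation (pCa):

* a slow, **dynamic bag1** fibre ("bag"), and
* a fast, **static bag2/chain** fibre ("chain").

Each half-sarcomere couples calcium-activated thin-filament kinetics to
two-state myosin cycling over a strain grid:

* Thick/thin filament overlap
  `n_ov(L) = (l_thin − (L − l_thick)) / (l_thick − l_bare)`, clamped to [0, 1].
* Activated actin fraction A(t):
  `dA/dt = k_on·[Ca]·(n_ov − A)·(1 + k_coop·A/n_ov)
          − k_off·(A − cb)·(1 + k_coop·(n_ov − A)/n_ov)`,
  where `cb` is the bound-myosin fraction — bound cross-bridges block
  deactivation, and `k_coop` is the inter-filament cooperativity.
* Bound myosin M(Δx, t) per strain bin Δx:
  attachment `f(Δx) = b_f·exp(−k_cb·Δx²/const_f)` (Gaussian window around
  zero strain, distributed over bins by the normalized f profile), detachment
  `g(Δx)` a U-shaped cubic with minimum `b_g + offset` at Δx = −5 nm.
  Imposed length changes advect the whole bound distribution along the
  strain axis.
* Stress `σ = 1e-9·cb_density·k_cb·Σ Δx·M(Δx) + k_passive·(L − L_slack)`.

The receptor potential is a phenomenological readout of the two fibre
forces (force = stress × nominal cross-sectional area):

```
r_total(t) = scale · ( k_fc·F_chain + k_fb·F_bag + k_yb·[dF_bag/dt]₊ )
```

with fixed weights k_fb = 0.4, k_fc = 0.5, k_yb = 0.005, scale = 2×10⁵, and
half-wave-rectified yank `[dF/dt]₊`.  The feature extractors quantify the
initial burst, dynamic response, dynamic index and post-shortening recovery
time, and the experiment drivers reproduce the shipped protocol families:
ramp-and-hold, paired triangular stretch–shorten cycles (inter-stretch
interval and conditioning-amplitude sweeps) and sinusoidal cycles.

All simulations are deterministic; there is no stochastic component anywhere.

## Worked example

```python
import spindlesim as ss

cfg = ss.default_config()
protocol = ss.ramp_hold(36, 5.6)          # 36 %L0/s ramp to 5.6 %L0, pCa 6.4
res = ss.simulate_spindle(protocol, cfg)
ev = protocol.events
fs = ss.extract_ramp_hold_features(
    res.r_total, res.time, ev["onset"], ev["ramp_end"], ev["hold_end"]
)
print(f"initial burst:    {fs.initial_burst:6.2f} a.u.")
print(f"dynamic response: {fs.dynamic_response:6.2f} a.u.")
print(f"dynamic index:    {fs.dynamic_index:6.2f} a.u.")

ladder = ss.run_thin_filament_ladder(cfg)
print(ladder[["variant", "bag_recovery_s", "chain_recovery_s"]].to_string(index=False))
```

prints

```
initial burst:     20.65 a.u.
dynamic response:   1.74 a.u.
dynamic index:     10.25 a.u.
                     variant  bag_recovery_s  chain_recovery_s
             activation_only        0.011267          0.001867
activation_plus_deactivation        0.009167          0.002067
     full_with_cooperativity        0.008767          0.002167
```

The burst is the baseline-subtracted first transient peak of `r_total` after
stretch onset (driven by the short-range stiffness of the pre-attached
cross-bridge population); the dynamic response is the fitted rise of
`r_total` during the ramp after the burst; the dynamic index is the decay
from the peak ramp response to the settled hold-phase response.  The ladder
table shows how fast each fibre's stress reappears on the second of two
back-to-back stretch–shorten cycles as thin-filament mechanisms are enabled
one at a time — the chain recovers within ~2 ms in every variant.

There is also a thin CLI:

```bash
spindlesim simulate --protocol ramp_hold -o out/   # writes spindle_trace.csv
spindlesim ladder -o out/
spindlesim ratesweep -o out/
spindlesim history -o out/                         # ISI/amplitude/sinusoid sweeps
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from fresh simulations, the recovery times of bag stress and
receptor potential after paired stretch–shorten cycles (with and without
cooperativity), the inter-stretch-interval sweep statistics of the test
burst, the conditioning-amplitude suppression ratio, the ramp-and-hold
receptor-potential features of the tuned model, and the chain fibre's
steady-state activation at pCa 6.4, and writes them to a JSON file keyed by
target id.  The model is deterministic, so `--seed` has no effect on the
values.
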