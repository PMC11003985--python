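# whiskvis

Tools for studying **visuo-tactile cross-modal suppression** in the mouse:
when the whiskers are stimulated, visually evoked activity in primary visual
cortex (VISp) is suppressed, even though the long-range input from barrel
cortex (SSp-bfd) is glutamatergic and targets excitatory and inhibitory
neurons with similar strength. The package bundles three analysis layers
that together explain how such an excitatory projection can suppress, and
why it makes behavioral sense given the geometry of the whisker array and
the visual field:

1. **`whiskvis.network`** — a two-population rate model of VISp. Pyramidal
   (P) and fast-spiking interneuron (F) populations evolve as

   ```
   τ_P dA_P/dt = −A_P + f_P(J_PP A_P − J_PF A_F + I^cm + I^v_P)
   τ_F dA_F/dt = −A_F + f_F(J_FP A_P − J_FF A_F + I^cm + I^v_F)
   ```

   with threshold-linear transfer `f_i(h) = G_i max(h − θ_i, 0)` and a
   cross-modal (tactile) drive capped at `ρ = δ·θ_P`:
   `I^cm ← max(min(I^cm, ρ), 0)`, so it can fire F (`θ_F < θ_P`) but only
   depolarize P. In the active state the fixed point is linear; adding the
   capped drive shifts it by

   ```
   ΔA_P* = I^cm G_P [1 + G_F (J_FF − J_PF)] / φ
   ΔA_F* = I^cm G_F [1 + G_P (J_FP − J_PP)] / φ,
   φ = w_FP w_PF − (w_PP − 1)(w_FF + 1),  w_ij = G_i J_ij.
   ```

   The module integrates the dynamics (forward Euler), evaluates the
   closed forms, classifies the inhibition-stabilized-network (ISN) regime
   and the two suppression conditions, and sweeps parameter grids.

2. **`whiskvis.geometry`** — 3D whisker arrays and their overlap with the
   visual field. Whiskers protract/retract within per-row whisking planes,
   planes can be inclined, whiskers can roll about their own axes; tips are
   expressed in left-eye-centered spherical coordinates and tested against
   the VISp coverage polygon in (azimuth, elevation). Tip-position
   uncertainty is propagated from emergence-angle and basepoint errors
   into per-whisker "uncertainty spheres".

3. **`whiskvis.spatial`** — statistics for cell-position maps: PCA-based
   parcellation with equally spaced section lines, Gaussian-KDE density
   maps (Scott bandwidth), the area-normalized barrel enrichment index
   `fr_b = (#Cells_b / #Cells_tot)·(#Area_tot / #Area_b)` with a one-tailed
   permutation test, and the assignment of visual-space coordinates to
   cortical parcels through a retinotopy.

`whiskvis.synth` generates every synthetic input (whisker arrays, coverage
polygons, cell clouds, barrel fields, retinotopies) with recorded ground
truth; `whiskvis.workflow`/the `whiskvis` CLI orchestrate reproducible
end-to-end runs.

## Worked example

```python
from whiskvis import NetworkParams, simulate, steady_state_analytic, \
    suppression_analytic, classify_regime
from whiskvis.network import StimulusProtocol, measure_steady_states

params = NetworkParams()          # reference parameter set
protocol = StimulusProtocol()     # visual 0-10 s, tactile added at 5 s

print(classify_regime(params).phi)               # 3.0
print(steady_state_analytic(params, "v"))        # A_P = 3.5, A_F = 1.65 Hz
print(steady_state_analytic(params, "v+w"))      # A_P = 1.0, A_F = 1.15 Hz
print(suppression_analytic(params))              # dA_P = -2.5, dA_F = -0.5 Hz

traj = simulate(params, protocol)
pre, post = measure_steady_states(traj, protocol)
print(post[0] - pre[0])                          # -2.4999999999997 (Hz)
```

The printed values mean: under visual stimulation alone VISp settles at
3.5 Hz (pyramidal) and 1.65 Hz (interneuron); adding the capped tactile
drive *lowers both* to 1.0 and 1.15 Hz — suppression of 2.5 and 0.5 Hz —
because the network is inhibition stabilized (`φ = 3 > 0`) and the
feedforward recruitment of inhibition outweighs the direct excitation.
The simulated suppression matches the closed form to better than 1e-6 Hz.

On the geometry side:

```python
from whiskvis.synth import gen_whisker_array, gen_visual_space
from whiskvis.geometry import whisk_scenario, tips_in_space

array, _ = gen_whisker_array(seed=1)
vmap, _ = gen_visual_space(seed=1)
for angle in (-40, 0, 40):        # retraction / rest / protraction
    print(angle, tips_in_space(whisk_scenario(array, angle), vmap).fraction)
# -40 0.1667   0 0.375   40 0.625
```

i.e. protracting the whiskers sweeps their tips into the visual-space
region covered by VISp (17% → 63% of tips on this synthetic array).

Or from the shell:

```sh
whiskvis run-all --seed 1 --out results/demo
whiskvis sweep-network --axis I_cm --grid 0:2:41 --out results/sweep.csv
```

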