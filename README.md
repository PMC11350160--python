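# lungtdos

Time-domain diffuse optical sensing of the human lung: a simulation and
analysis toolkit for transcutaneous, picosecond-pulse near-infrared
measurements of the chest.

Pulsed light injected on the chest wall and collected a few centimetres away
produces a distribution of photon times of flight (DTOF). Late photons — a
few nanoseconds after injection — have diffused several centimetres deep,
potentially into lung tissue, so breathing-related changes in lung optical
properties should modulate the late, time-gated part of the signal. This
package implements the full computational chain needed to study that
feasibility question:

- **Forward model** — time-resolved reflectance `R(ρ, t)` of a homogeneous
  semi-infinite medium from the diffusion equation under the extrapolated
  boundary condition, convolved with a measured or synthetic instrument
  response function (IRF).
- **Monte Carlo transport** — layered-slab, time-resolved photon transport
  (numba-compiled) using the microscopic Lambert–Beer approach: trajectories
  are simulated *without* absorption while storing the path length `L_j`
  spent in each layer, then weighted afterwards by `exp(−Σ_j μa_j L_j)`.
  One run serves every absorption state, and perturbation contrasts computed
  from the same trajectories (correlated sampling) are nearly noise-free.
- **DTOF fitting** — recovery of the absorption and reduced scattering
  coefficients (μa, μs′) by IRF-convolved diffusion-model fits restricted to
  the channels above 80% (leading edge) and 1% (falling edge) of the peak.
- **Broadband spectroscopy** — Beer–Lambert decomposition of μa(λ) into five
  absorbers (Hb, HbO₂, water, lipid, collagen; non-negative least squares)
  and the scattering power law μs′(λ) = a(λ/600 nm)^−b.
- **Breathing-protocol analysis** — time-gated relative contrast
  `C(t) = (∫gate R − ∫gate R₀)/∫gate R₀` against the whole-exercise mean,
  folding averages over protocol repetitions, IN/OUT breath-hold plateau
  summaries, and per-acquisition fit time series.
- **Synthetic data** — TCSPC-like Poisson-count DTOFs (~1 Mcounts/s), IRFs,
  broadband series and full breathing-protocol series with ground truth, so
  every stage is testable without measured data.

## Worked example

How deep do photons detected at 3.2 ns probe a chest with μs′(820 nm)
≈ 9.1 cm⁻¹, and is a 10% drop in lung absorption visible at ρ = 6 cm?

```python
import numpy as np
from lungtdos import (
    DetectionGeometry, LayeredSlabMedium, OpticalProperties,
    PowerLawFit, eval_power_law, perturbation_contrast, run_mc,
)

musp = eval_power_law(PowerLawFit(a=11.1, b=0.63), 820.0)   # 9.12 1/cm
depth_run = run_mc(
    LayeredSlabMedium.homogeneous(OpticalProperties(0.0, musp)),
    DetectionGeometry(rho=3.0, accept_all_exits=True, t_max_record=3.5),
    n_detected_target=150_000, seed=1,
)
sel = np.abs(depth_run.exit_time - 3.2) < 0.1
print(f"<z_max>(3.2 ns) = {depth_run.max_depth[sel].mean():.2f} cm")

chest = OpticalProperties(mua=0.15, musp=7.0)
lung = OpticalProperties(mua=0.15, musp=12.0)
run = run_mc(
    LayeredSlabMedium.two_layer(chest, 3.0, lung),
    DetectionGeometry(rho=6.0, t_max_record=10.0),
    n_detected_target=100_000, seed=2,
)
gate = perturbation_contrast(run, [0.15, 0.15], [0.15, 0.135], [(4.0, 0.5)])[0]
print(f"C(4 ns gate) = {100 * gate.contrast:.1f}%")
```

Output:

```
<z_max>(3.2 ns) = 2.55 cm
C(4 ns gate) = 11.3%
```

Photons arriving at 3.2 ns have, on average, dived 2.6 cm below the surface —
enough to cross a typical chest wall — and the 10% lung-absorption reduction
produces a clearly positive gated contrast at the 4 ns gate through 3 cm of
overlying tissue.

The numbered drivers under `analysis/` run the complete studies and write
their tables under `results/`:

```bash
python analysis/01_penetration_depth.py    # <z_max>(t) per volunteer
python analysis/02_layered_contrast.py     # C(t) vs lung depth; competing effects
python analysis/03_broadband_recovery.py   # 600-1100 nm round trip
python analysis/04_breathing_protocol.py   # gated contrast + plateau summary
```

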