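# Methods

This note records the models implemented in `lungtdos`, the numerical and
design choices behind them, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Physical setting and conventions

All lengths are in cm, times in ns, optical coefficients in 1/cm. A single
refractive index `n_in` (default 1.4, standard for soft tissue) applies to
every layer; the external medium has `n_out` (default 1.0). The speed of
light in tissue is `v = c/n_in` with `c = 29.9792458 cm/ns` declared once in
`lungtdos.constants`. Time zero is the peak of the instrument response
function (IRF); fits carry a bounded time-shift parameter to absorb residual
offset in that convention.

## Forward model: time-resolved diffuse reflectance

`forward.tr_reflectance` evaluates the time-dependent diffusion equation for
a homogeneous semi-infinite medium with the extrapolated boundary condition,
using one positive/negative image pair: an isotropic source at depth
`z0 = 1/μs′` mirrored across the zero-fluence plane at `z_e = 2AD` above the
surface, with `D = 1/(3 μs′)` (absorption-independent convention) and the
boundary factor `A` from the Groenhuis polynomial approximation of the
angle-averaged internal Fresnel reflectance (`A(1.4) ≈ 3.25`; `A = 1` for
matched indices). A single dipole suffices for reflectance from a
semi-infinite medium; slab and multi-layer analytic solutions are out of
scope. Two exact properties are used as tests: causality (`R = 0` for
`t ≤ 0`) and the Beer–Lambert factorisation
`R(μa)(t) = R(0)(t)·exp(−μa v t)`.

The overall amplitude of `R` is arbitrary; every fit carries a free scale.
IRF convolution is discrete linear convolution on a shared channel width,
truncated to the model axis, with the IRF's (possibly negative) start time
handled as an integer channel offset.

## Monte Carlo transport

`montecarlo.run_mc` propagates photons through a layered slab with a single
numba-compiled kernel:

- **Scattering.** Isotropic (g = 0), so `μs = μs′`; free paths are sampled in
  optical depth and converted layer by layer, which makes a layer interface
  between identical media an exact no-op (asserted in tests). The similarity
  relation makes late-time observables insensitive to g at fixed μs′; g is a
  documented model restriction rather than a parameter.
- **Absorption.** Never sampled during transport. Per-layer geometric path
  lengths are stored for every detected photon and absorption is applied
  afterwards as `w = exp(−Σ_j μa_j L_j)` (microscopic Lambert–Beer). The
  bookkeeping identity `Σ_j L_j = v·t_exit` holds to 10⁻⁶ cm.
- **Boundary.** Unpolarised Fresnel reflection/refraction at the top surface
  from the `n_in/n_out` mismatch, including total internal reflection.
- **Detection.** Either an annular ring of half-width 0.25 cm around the
  nominal source–detector distance ρ, or accept-all-exits mode for depth
  statistics (which are rigorously independent of ρ and μa). Trajectories
  are abandoned beyond `t_max_record` (default 10 ns); an exact geometric
  cull removes photons whose shortest remaining path to any accepted exit
  already exceeds the remaining time budget — this changes no recorded
  statistic, only the cost.
- **Randomness.** An inline xoroshiro128+ generator seeded via splitmix64
  from the user seed; identical (seed, parameters) reproduce the run
  bit-for-bit. The azimuthal scattering angle uses von Neumann rejection
  instead of trigonometry for speed.
- **Budgets.** Headline runs use 1e5–1.5e5 detected photons (the analysis
  scripts and acceptance script); unit tests use 5e3–5e4. If the launch
  budget (default 10⁴ × target) is exhausted first, a partial result is
  returned flagged `complete=False` rather than raising.

**Perturbation contrast.** `perturbation_contrast` computes the gated
relative contrast `C = (S_pert − S_base)/S_base` from two reweightings of the
*same* trajectories (correlated sampling), so absorption-only perturbations
have variance far below independent-run noise — a few hundred photons in a
late gate already give a stable contrast. Scattering perturbations change the
transport itself, so they are computed from a second, paired-seed run and
normalised per launched photon; this is documented as statistically
independent (noisier) by construction. An empty gate is reported as
undefined, never as zero.

**Contrast regimes and the lung absorption baseline.** With equal baseline
absorption in both layers the baseline weight `exp(−μa v t)` is constant
within a time gate, so the correlated-sampling contrast reduces to the
*unweighted* gate mean of `exp(−Δμa·L_lung) − 1`. The distribution of lung
path lengths is heavy-tailed (a few photons dwell tens of centimetres in the
lung), so for a 10–20% lung-absorption reduction the contrast grows
super-linearly with gate time and can reach tens or hundreds of percent —
and a lung-*scattering* reduction, by deepening trajectories and lengthening
lung paths, then *amplifies* the combined contrast instead of cancelling it.
The visibility studies (lung at 3–4 cm, 4 and 8 ns gates) use the equal-μa
baseline of 0.15 cm⁻¹ and report contrasts in this regime; the
competing-perturbations study instead uses a blood-rich lung baseline
(μa = 0.40 cm⁻¹ against 0.15 cm⁻¹ in the chest wall, plausible for perfused
lung tissue at 820 nm). The higher lung absorption damps the long-path tail,
the gated contrasts stay linear in gate time at the few-to-20% level, and
the expected structure emerges: absorption-only reduction raises C(t)
steadily, scattering-only reduction lowers late gates by a comparable
amount, and the combined reduction largely cancels.

**Depth statistics.** `mean_max_depth_curve` averages, per exit-time bin, the
maximum depth visited by each detected trajectory, unweighted: within a time
bin a homogeneous absorption weight `exp(−μa v t)` is constant, so the mean
is absorption-invariant (asserted numerically). Bins with fewer than 50
records are flagged unreliable.

## Fitting

`fit_homogeneous` minimises a Pearson chi-square (variance = model counts,
the Poisson-appropriate choice) between the measured DTOF and the
IRF-convolved, amplitude-scaled, time-shifted diffusion model, restricted to
the fit range: scanning back from the peak, the contiguous leading-edge
channels above 80% of the peak; on the falling edge, down to and including
the first channel at or below 1% of the peak. Both thresholds are relative,
so the range is scale-invariant. The optimiser is `scipy.optimize.least_squares`
(trust-region reflective) with bounds μa ∈ [0, 2], μs′ ∈ [1, 50] cm⁻¹ and
|shift| ≤ 100 ps, the amplitude fitted as a log-scale parameter initialised
from the count totals; up to three perturbed restarts are attempted before
returning `converged=False`. On noiseless self-generated data the fit is
exact; at 4×10⁶ counts (1 Mcounts/s × 4 s) recovery is at the percent level.

`estimate_tmax` returns the latest gate start (default width 0.5 ns, the
same width as the contrast gates) whose gated counts still exceed
10,000 counts/s × acquisition time — the 1% shot-noise condition; only gates
fully on the time axis are considered.

`fit_composition` solves the non-negative least-squares Beer–Lambert system
μa(λ) = Σ cᵢ εᵢ(λ) over five absorbers (Hb, HbO₂ in µM; water, lipid,
collagen in g/cm³), rejecting rank-deficient bases. No scattering-background
term is included: non-negativity is the only regularisation, matching the
minimal published analysis. `fit_power_law` is linear regression of
ln μs′ on ln(λ/600 nm), exact on noiseless power-law inputs.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes:

- **IRF** — exponentially modified Gaussian (Gaussian rise, exponential
  tail), default 150 ps FWHM with tail constant equal to the FWHM, peak in
  the channel containing t = 0, Poisson-sampled. The width is a plausible
  figure for SiPM/hybrid-PMT TCSPC chains; real IRFs should be substituted
  when available.
- **DTOF** — diffusion forward model → IRF convolution → scaling to
  `rate × acq_time` expected counts (default 10⁶ counts/s, the single-photon
  operating point) → per-channel Poisson sampling, plus optional Poisson
  background (default 0).
- **Broadband series** — 600–1100 nm in 10 nm steps, 4 s acquisitions;
  μa(λ) from the chromophore basis, μs′(λ) from the power law; ground truth
  returned with the curves.
- **Protocol series** — two-layer Monte Carlo reweighting rather than any
  analytic model: one absorption-free run per distinct scattering state,
  reweighted per acquisition for that phase's lung absorption, convolved
  with the IRF and Poisson-sampled at 1 acquisition/s (configurable
  cadence). Default modulation: lung μa × 0.9 during inspiration, scattering
  unchanged. Protocols: 5 repetitions of 10 s IN + 10 s OUT, or 10
  repetitions of 5 s phases preceded by one normal-breathing repetition
  (excluded from folding and from the reference state by default).

The chromophore basis bundled in `spectra.synthetic_chromophore_basis` is
**synthetic**: smooth Gaussian-band spectra with realistic band positions and
magnitudes (Hb band near 760 nm, HbO₂ rising past 800 nm, the dominant water
band at 975 nm, lipid at 930 nm, a broad collagen band near 1030 nm), scaled
so physiological compositions give chest-like μa of 0.05–0.3 cm⁻¹. It is not
a literature compilation; composition results on real data are
basis-dependent, so all recovery tests are self-consistent (generate and fit
with the same basis). Real extinction tables drop in through the
`ChromophoreBasis` container.

What the generator does **not** emulate: anatomical chest structure (ribs,
pleura and its possible light-guiding, curvature), detector afterpulsing and
dead time, wavelength-dependent IRF shape, motion artefacts, physiological
drifts (oxygenation dynamics, heartbeat), or anisotropic scattering.
Passing recovery tests therefore demonstrate the correctness and statistical
power of the analysis chain under its own model assumptions, not the fidelity
of a two-layer slab to a real thorax.

## Protocol analysis conventions

Gated contrast uses the element-wise mean of the count-rate-normalised
curves over the whole exercise as the reference state (reference-labelled
acquisitions excluded by default), making C invariant under global rescaling
and zero-mean over the exercise by construction. Folding averages across
repetitions after dropping the normal-breathing prefix. The breath-hold
"plateau" excludes the first 2 s of each phase (configurable) to skip the
inhalation/exhalation transition; the published analysis does not define its
plateau window, so this is a package choice.

## Numerical choices and degenerate inputs

- Fit-range determination rejects all-zero curves and curves whose peak sits
  at the trailing edge (no usable falling edge).
- Ties at the DTOF peak break toward the earliest channel.
- Gate sums include channels whose centres fall in `[t, t + Δt)`.
- `estimate_tmax` returns `None` (an explicit no-gate result) when no gate
  meets the rate threshold.
- Weighted histograms may legitimately contain non-integer "counts"; count
  validation only enforces non-negativity and finiteness.
- The composition fit clips nothing: negative input spectra are the caller's
  responsibility, but concentrations are constrained non-negative.

## Problem sizes

Analysis drivers use 5×10⁴–1.5×10⁵ detected photons per Monte Carlo run and
full 51-wavelength broadband grids; the test suite uses 5×10³–5×10⁴ photons,
reduced wavelength grids and 6–20 noise seeds per recovery experiment. These
sizes keep every statistical assertion comfortably powered (sign tests at
the 5% level, 3σ per-bin agreement checks) while the whole suite runs in
minutes on one CPU.

## Known limitations

- Isotropic scattering only; no Henyey–Greenstein option is exposed.
- Homogeneous-model inversion only; two-layer inverse fitting is out of
  scope (the forward two-layer machinery exists in the Monte Carlo module).
- The dipole diffusion solution deviates from transport at sub-0.5 ns times
  and short distances; fits restricted by the 80%/1% rule operate where the
  approximation is adequate, and Monte Carlo agreement is asserted only
  within counting statistics over 0.5–4 ns.
- Scattering perturbation contrasts carry independent-run noise; only
  absorption perturbations enjoy correlated-sampling variance reduction.
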