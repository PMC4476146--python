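# Methods

## The model

`livermet` quantifies experimental liver metastasis in the intrasplenic
injection model: a known dose of optically labeled tumor cells (default
2.0×10⁶) is injected into the spleen, reaches the liver through the portal
circulation, and a small fraction founds macroscopic colonies. Two
parameters summarize a clone's metastatic potential:

* **Colonizing fraction** `Fc = n_tumors / n_injected` — the per-cell
  probability of founding a macroscopic colony.
* **Doubling time** `Td` — hours per population doubling. Each colony is
  assumed to grow exponentially from exactly **one** founding cell with no
  lag phase, so a colony of `N` cells harvested `t` hours after injection
  gives `Td = t·ln2 / ln N` and has completed `log₂ N` divisions. One cell
  is the minimal founder assumption consistent with counting tumors as
  colonizing cells; any larger founder or a lag phase would bias `Td`
  downward by a fixed transformation, not change orderings.

Cell numbers per colony are never observed directly; they are read off the
fluorescence **standard curve**, an OLS line of signal on plated cell number
(densities 0–10⁵ cells/well, triplicated). The regression keeps an
intercept — empty wells have real background — and inversion clamps at zero
with a warning. Detected colonies are floored at one cell so faint foci keep
`Fc` and `n_av` well defined. No log transform is applied to either axis;
the response is linear over the plated range and the Pearson R of the pooled
(not replicate-averaged) points is the reported fit quality. Macroscopic
volumes assume spherical colonies, `V = π d³/6`.

Two thresholds place a clone on the (Fc, Td) plane (defaults `Fc = 2×10⁻⁵`,
`Td = 24.5 h`, chosen to separate the characterized clones; always explicit
parameters): high-Fc/slow → many small foci (polymetastatic, P1-like),
low-Fc/fast → few large foci (P2-like), low-Fc/slow → few small foci
(oligometastatic-like), high-Fc/fast → labeled `many_large` though not
observed experimentally.

## The generative model (`livermet.simulate`)

The simulator is the synthetic stand-in for the animal experiment and fixes
the study conditions the estimators are validated under:

| parameter | default | meaning |
|---|---|---|
| `n_injected` | 2.0×10⁶ cells | injected dose per mouse |
| `fc` | per clone | Binomial seeding probability per injected cell |
| `td_mean` | per clone (h) | mean colony doubling time |
| `td_cv` | 0.05 | lognormal CV of inter-colony Td heterogeneity |
| `harvest_time` | 504 h (P), 672 h (O) | hours from injection to harvest |
| `noise_cv` | 0.05 | multiplicative lognormal measurement noise |
| `packing_density` | 10⁶ cells/mm³ | links cell number to diameter |

Per mouse the colony count is `Binomial(n_injected, fc)` — cells act
independently, and no Poisson approximation is used so `fc ≤ 1` stays
enforceable. Each colony draws `Td ~ lognormal(mean td_mean, CV td_cv)` and
reaches `N = 2^(t/Td)` cells; its fluorescence is the standard-curve
prediction times a mean-one lognormal noise factor (optical signals are
positive and heteroscedastic, so noise is multiplicative); its diameter is
`(6N/(π·ρ))^(1/3)`. Characterized clone presets: P1 (Fc 8.2×10⁻⁵, Td
26.5 h), P2 (1.1×10⁻⁵, 22.7 h), O1 (6.0×10⁻⁶, 26.5 h). No point estimates
exist for O2; its preset (5×10⁻⁶, 27.0 h) is representative oligometastatic
values, and quantitative clone comparisons use P1/P2/O1 only. P-clone
cohorts default to 3-week harvest (their follow-up window), O clones to
4 weeks; both are per-mouse configurable because the exact elapsed time
behind the published estimates is ambiguous. A week is fixed at 168 h.

`td_cv = 0.05` is a modeling choice: inter-colony Td variability is not
directly estimated by the experiment; 5% is consistent with the small
published Td dispersions (±0.2–0.3 h on clone means). It is a prominent
knob, not a fitted value.

Randomness: one integer seed with hierarchical substreams
`SeedSequence((seed, stream, mouse_index))` — stream 0 for harvested
cohorts, stream 1 for longitudinal imaging, stream 2 for recovery-replicate
seed derivation. Identical seeds reproduce cohorts bit for bit; the scheme
is stable across versions.

What the generator does **not** emulate: inter-mouse random effects beyond
seeding stochasticity, spatial competition between colonies, non-exponential
(Gompertzian/logistic) growth, immune interaction, and circulation or
extravasation mechanics. Passing tests therefore validate the estimators
under the stated model, not the biology of any particular animal.

## Estimation (`livermet.estimation`)

`estimate_fc` computes per-mouse `Fc` and aggregates mean ± sample SD
(n−1 denominator) across mice; the SD is NaN (flagged, not an error) for a
single mouse. `estimate_td` mirrors the experimental procedure of
quantifying a handful of representative colonies: up to `sample_size = 5`
colonies per liver are drawn uniformly without replacement (seeded;
`all_colonies=True` disables sampling — how "representative" colonies were
chosen experimentally is unknown, so uniform sampling is the neutral
choice), converted to cells through the fluorescence curve, and pooled
within the clone; dispersion is the pooled sample SD across sampled
colonies, not a per-mouse-then-pooled SD. Fc dispersion is across mice, Td
dispersion across colonies. No outlier rejection anywhere.

In vitro growth curves are fitted log-linearly: signals normalized to t = 0
(normalization cannot change the slope, so the fitted Td is scale
invariant), log₂-transformed, regressed on time; the slope is divisions per
hour and `Td = 1/slope`, with a flat culture flagged as infinite Td.
Log-linear regression was chosen over pairwise doubling ratios because it
uses all time points symmetrically.

`recover_params` closes the loop: replicate cohorts are simulated at known
parameters (replicate seeds derived deterministically from the params seed,
kept below 2³¹), re-estimated, and summarized as aggregate bias and relative
error. Under the defaults the Fc estimator is unbiased (it is a Binomial
proportion) and the Td estimator's bias is second order in the noise CVs
(≈ cv²/2 through Jensen terms, ≪ 1% at cv = 0.05).

## Synthetic imaging (`livermet.imaging`)

The rendering/detection pair stands in for vendor ROI quantification of
ex vivo liver images; it is a documented replacement, not a reconstruction
of that software. Rendering places each colony as an isotropic Gaussian
blob whose **integrated** signal equals its fluorescence (the PSF spreads
but conserves radiant efficiency) on a constant background, with optional
additive Gaussian pixel noise clipped at zero. Defaults: 512×512 field,
0.05 mm/pixel, PSF σ = 0.15 mm (3 px). Positions are uniform random under a
minimum-separation constraint via rejection sampling with bounded retries;
a too-dense burden raises a diagnostic placement error rather than rendering
overlapping foci (touching-colony splitting is out of scope).

Numerical choices:

* Discretized Gaussian mass is conserved to ≪1% for σ ≥ 2 px with centers
  ≥ 3σ from borders (the placement margin).
* The default minimum center separation is **8σ**. The hard non-overlap
  floor is 3σ, but two comparable Gaussians 3σ apart form a single
  connected component above any threshold (their midpoint is ~0.65 of
  peak), so count-exact threshold detection is impossible there; 8σ leaves
  the midpoint ≈ 7×10⁻⁴ of peak, below the detection floor.
* Detection thresholds at `median + k_sigma · max(1.4826·MAD, floor)` with
  `k_sigma = 5`; median/MAD are robust to sparse bright colonies and make
  detection invariant to constant offsets. The floor, 5×10⁻⁴ of the
  above-background dynamic range, exists because a noiseless synthetic
  image has MAD = 0; it still catches colonies ~30× dimmer than the
  brightest.
* Components are 8-connected; those under `min_pixels = 4` are discarded.
  Before integration each component is expanded by ~2 PSF σ (nearest-label
  assignment, so neighboring colonies never share pixels) because the
  threshold cuts the Gaussian tail: without expansion the truncation loss
  alone can approach 5%, with it the captured mass is >99.9%. Integration is
  background-subtracted; centroids are intensity-weighted.
* Greedy truth matching orders candidate pairs by distance, ties broken by
  lowest detection label, each side used at most once — fully deterministic.

Images are written as single-channel 32-bit float TIFF (no quantization of
radiant efficiency); a 16-bit export stores its scale factor in a JSON
sidecar for viewers. Coordinates are 0-based row-major, row 0 at top;
physical units attach only through the pixel size.

## Problem sizes used in the shipped analyses

The numbered scripts under `analysis/` and the acceptance checks run at
desk scale as the package's own choice of study size: cohorts of 3 mice
(matching the experimental n = 3) for the clone comparisons, 20 mice × 50
replicates for parameter recovery, 100 seeds for distributional claims
(calibration linearity, scenario orderings), and single-liver renders of
≤ 50 colonies for imaging round trips. Absolute published signal levels
(e.g. whole-animal photon flux magnitudes) depend on instrument geometry
and are not reproduced; the analysis reproduces ratios, correlations, and
the (Fc, Td) quantities.

## Known limitations

* The single-founder, no-lag growth model makes `Td` a deterministic
  function of (N, t); real colonies may seed as clusters or pause before
  expanding, which would inflate apparent `Td`.
* `Fc` conflates extravasation, survival, and outgrowth into one
  probability; the simulator inherits that conflation deliberately.
* The detector requires foci resolvable at the PSF scale; merged foci are
  counted as one (no watershed), as in macroscopic counting.
* Calibration assumes linearity over the plated range; saturation outside
  0–10⁵ cells/well is not modeled.
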