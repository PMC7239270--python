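# Methods

## The measurement model

An excised leaf loses water through three routes: the adaxial cuticle, the
abaxial cuticle, and residually open stomata on the abaxial surface. The
pipeline treats the drying curve of each leaf gravimetrically:

- water loss at reading time `t`: `(W_i − W_t)/A` (mg cm⁻²),
- interval transpiration rate: `(W_t − W_{t+1})/A`, normalized per hour
  when intervals differ from 1 h (mg h⁻¹ cm⁻²),
- relative water deficit: `RWD = 1 − (W_t − W_d)/(W_i − W_d)`,

with `W_i` the water-saturated fresh weight, `W_d` the oven dry weight and
`A` the projected one-sided leaf area. Weights are stored in g, areas in
cm²; the single g→mg conversion happens at rate computation.

Six simultaneous treatment groups make the surface components identifiable
(see the README for the equations): control, each surface vaseline-sealed,
both sealed, and each surface gum-arabic-stripped with the opposite surface
sealed. The inversion is closed-form. Three of the equations overdetermine
`(T_Ad, T_Ab)`; we invert the two sealed-surface equations exactly and
report the residual `T − (T_Ad + T_Ab)` as a consistency diagnostic rather
than least-squares-averaging the discrepancy away, because the closed forms
reproduce the published arithmetic and keep each estimate traceable to
named observables. A least-squares variant using all four control/sealed
equations is available behind `least_squares=True`.

Key assumptions inherited from the design:

1. **Equal leakage on both surfaces.** A single `k` describes the vaseline
   film. The simulator can violate this (`k_ad ≠ k_ab`), and a test
   confirms that the estimator's bias in `T_Ad` grows monotonically with
   the asymmetry — the price of the assumption is quantified, not hidden.
2. **Cuticular transpiration independent of RWD** over the observation
   window; only the stomatal term responds to water status.
3. **Additivity** of surface fluxes.

## Residual stomatal transpiration

`T_Ab_s` is estimated from the control group as (mean rate at hour 1) −
(mean post-closure rate). Two choices of the second term are implemented:

- `single_hour`: the rate at the detected closure hour — the textbook
  difference, used by the printed-value oracles;
- `plateau` (default): each leaf's mean rate over the hours strictly after
  the closure hour. When closure is gradual, the closure hour itself
  straddles the transition and the single-hour difference underestimates
  the stomatal component; the settled plateau removes that bias, and since
  a per-leaf mean of consecutive interval rates telescopes to
  `(W_first − W_last)/(Δt·A)`, it is also far less sensitive to balance
  noise. On data that are genuinely flat after closure the two estimators
  coincide, which is what the oracle tests assert.

The intracuticular column can subtract either the control residual
(`residual_mode="control"`) or the abaxially stripped group's own drop
(`"group_specific"`, default). The default follows the internal structure
of the published hourly table, whose intracuticular column pair differs by
a constant ≈ 0.039 mg h⁻¹ cm⁻² — the stripped group's own estimate — rather
than the control's ≈ 0.057. The shipped reference table and
`scan_table_consistency` verify both constants to within 0.002. The
published prose value 0.06 ± 0.008 for the control residual is the rounded
form of the 0.057 implied by that table's rows; the package reports
whatever its inputs imply and takes no side.

## Closure-hour detection

The published protocol identifies the closure hour by the first
statistically significant drop of the control rate. A literal
hour-by-hour sequential t-test rule has poor operating characteristics at
realistic noise (it fires early on single-hour fluctuations and, during a
gradual transition, rejects the true plateau onset), so the detector is a
standard single-changepoint procedure with the same test family:

1. **Location.** Scan all splits of the leaf × hour rate matrix; the split
   maximizing the between-segment sum of squares is the candidate, and the
   first post-split hour is the candidate closure hour.
2. **Drop test.** Paired one-sided Student's t (α = 0.05) on per-leaf
   pre-split vs post-split mean rates. Pairing uses the telescoping of
   consecutive weighings, which makes per-leaf segment means nearly
   noise-free.
3. **Plateau test.** The hours after the first post-split hour must show no
   significant linear trend (two-sided t on the regression slope,
   α = 0.05); a monotone decline therefore yields "none detected" rather
   than a spurious changepoint.

If no candidate passes, the result is a sentinel and downstream code falls
back to the configured fixed hour (default 5, `plateau_method="fixed"`
forces it). `max_hour` can confine the scan to an early observation
window. On the simulator's default conditions the Monte-Carlo acceptance
test requires the detected hour to fall in {4, 5, 6} in ≥ 90 % of 200
seeded runs, and the recovered median first-hour `T_Ad` and `T_Ab_c` to sit
within 10 % of truth.

## Rate versus RWD

`fit_rate_vs_rwd` fits a declining line (slope constrained ≤ 0) joined
continuously to a constant plateau, the shape expected when a closing
stomatal component rides on an RWD-independent cuticular floor. The
breakpoint is chosen by grid search over the observed RWD values (exact
recovery on noise-free data that contain the true breakpoint among their
abscissae); ties go to the smallest SSE first encountered in ascending
breakpoint order. Degenerate inputs — fewer than 5 points or zero RWD
range — are rejected.

## Group statistics and letters

Group summaries are mean ± SE (sample SD/√n). Pairwise comparisons default
to the pooled-variance Student t (the named test of the original analysis);
Welch is available. No multiple-testing correction is applied by default
because the original analysis applies none. Letter displays use
insert-and-absorb followed by a redundancy sweep, giving a minimal letter
set satisfying "share a letter ⇔ not significantly different"; ties are
broken by group input order so output is deterministic. Zero-variance
degeneracies resolve to p = 1 (equal means) or p = 0 with a flag (unequal).

## Wax quantification

Coverage is `peak_area / IS_area × IS_amount / leaf_area` with a 75 µg
n-tetracosane internal standard and FID response factor 1 for every class
(a per-class response-factor map is accepted for extensions). A replicate
is a pooled-leaf batch. Aggregation sums within replicate first, then
averages across replicates, so class totals equal the sum of their
chain-length rows exactly. The leaf-area basis is the projected one-sided
area — the published protocol does not state the basis, and the projected
area is the quantity actually measured.

## Uncertainty

Published tables of this kind report "± SE" without stating a propagation
method. Because every component shares the same estimated `k`, analytic
propagation would need the full covariance; we instead bootstrap leaves
with replacement within each treatment group (default B = 1000, seeded),
rerunning the entire chain — group means, `k`, residual, inversion — per
replicate, and report the SD across replicates. Each replicate's residual
is computed from the same resampled control leaves as its means, so the
`T_Ab`–`T_Ab_s` correlation is preserved. Replicates with a non-invertible
system (control ≤ 0 or k ≥ 1) are dropped and counted; more than 10 %
dropped aborts with an error.

## The synthetic-data generator

`synthetic_leaf` integrates `dW/dt = −A · flux(t, RWD)` per leaf (explicit
Euler, `dt = 0.01 h`; halving `dt` moves hourly weights by far less than
the balance noise), with

`flux = c_ad · g_ad_eff + c_ab · (g_ab_eff + g_s · s(t) · max(0, 1 − β·RWD))`

where `s(t)` is a logistic closure gate with midpoint `t_c = 4.5 h` and
steepness `r = 3 h⁻¹`, `c` factors apply the leakage `k` on sealed
surfaces, and stripping switches a surface to its intracuticular rate. The
logistic form is a modeling choice — no functional form for closure
kinetics is established — and is isolated in `closure_function` so
alternatives can be swapped.

Defaults encode the study conditions: per-group n = 6 leaves, hourly
weighings, 10 h horizon, additive balance noise SD 1 mg (a 1 mg-readability
laboratory balance), and component rates at the published first-hour scale
(`g_ad_full = 0.094`, `g_ab_full = 0.142`, `g_ad_intra = 0.104`,
`g_ab_intra = 0.413`, `g_s0 = 0.057` mg h⁻¹ cm⁻², `k = 0.206`). Leaf
geometry uses area 35 ± 4 cm², dry weight 0.45 g and saturating water
content 0.90 ± 0.08 g — a mature, fully hydrated tea leaf (roughly two
thirds water by fresh weight). `g_s0` is the residual stomatal rate of the
standard ABA-pretreated leaf; `aba_factor = 0.66` encodes the ~34 %
stomatal-aperture reduction attributed to ABA, so auxiliary non-ABA groups
transpire `g_s0 / 0.66` through stomata. RWD feedback (β = 0.2) applies
only to the stomatal term, matching the observation that cuticular
transpiration is RWD-independent.

The generator's population truth sets `T_Ab_s` to the exact logistic-gate
mean over the first hour (the within-hour RWD feedback it ignores is below
reporting precision). It deliberately omits: boundary-layer and VPD
physics, leaf energy balance, spatially resolved stomata, leaf-to-leaf
variation in the per-area component rates (leaves differ only in geometry
and noise), and any interaction of vaseline with cuticular lipids. Passing
recovery tests therefore demonstrate correctness of the estimation
arithmetic and robustness to balance noise and geometric variation — not
robustness to biological rate heterogeneity or micrometeorology.

## Monte-Carlo summaries

Stochastic performance is always summarized by the median across seeded
replicates (the median estimate against truth, the median breakpoint):
medians are stable at the replicate counts used (200 in tests, 100 in the
acceptance script) and insensitive to the occasional ill-conditioned
replicate, whereas per-run relative errors at n = 6 leaves and 1 mg noise
are dominated by sampling noise that the design averages away in practice
by reporting group means with SEs.

## Known limitations

- The method presumes the six groups are exchangeable leaf populations;
  the package checks grid completeness, not exchangeability.
- `k` outside (0, 1), negative component rates and negative residuals are
  flagged, never truncated — downstream consumers must heed the flags.
- Hourly tables require a common time grid across groups; irregular grids
  are accepted for rate computation only.
- The changepoint detector assumes at most one closure transition in the
  window; multi-phase declines return the dominant split or none.
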