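# Methods

## The two-phase model

The package models interfollicular epidermal growth between E12.5 and E18.5
as two kinetic regimes joined at E15.5.

Phase 1 treats the tissue as a single equipotent progenitor pool that
duplicates at a constant per-cell rate λ₁ (default 0.66/day), giving
exponential expansion n(t) = n₀·e^{λ₁(t−t₀)}. No basal/suprabasal
distinction is made during this phase: proliferative cells occupy both
layers, and stratification proceeds by transfer (crowding/delamination)
rather than by fate asymmetry.

Phase 2 distinguishes cycling basal progenitors b from post-mitotic
suprabasal cells s. Each basal event (total rate λ₂·b, default λ₂ =
0.7/day) is a duplication b → b+b with probability 1−r, or a direct
conversion b → s with probability r. The mean-field equations are
db/dt = λ₂(1−2r)b and ds/dt = λ₂rb. Requiring the two layers to expand
proportionately (db/dt = ds/dt) fixes r = 1/3; starting from density parity
this yields b(t) = s(t) = b₀·e^{λ₂(t−t₀)/3}, a slow exponential whose
3-day fold is e^{0.7} ≈ 2.01 — observationally indistinguishable from a
linear trend at this scale.

The "conversion" reading of stratification (one b removed, one s added per
stratifying event) is the unique interpretation consistent with
db/dt = λ(1−2r)b under a single event rate λ·b; a variant in which
stratification accompanies a division (b → b+s) would give db/dt = λ(1−r)b
instead. The biological mechanism (oriented division vs delamination) is
deliberately not encoded.

At r = 1/2 the closed form for s has a removable singularity; the analytic
continuity limit s = s₀ + λr·b₀·Δt is used within 10⁻¹² of r = 1/2.

## Stochastic simulation

Both phases are simulated exactly (Gillespie). Phase 1 exploits the
pure-birth structure: the waiting time from k to k+1 cells is
Exponential(λk), so the whole event-time sequence is a cumulative sum of
independent exponentials, generated vectorised in chunks. Phase 2 draws
per-event waiting times Exponential(λb) and fate (duplication vs conversion)
sequentially, with pre-drawn randomness in blocks of 4096 for speed. A
replicate whose basal pool reaches zero is absorbed. Trajectories are
sampled onto a fixed 0.1-day output grid regardless of event times.
Replicate-mean agreement with the closed forms (within 3 Monte-Carlo
standard errors at ≥200 replicates, populations ≥1000) is enforced by the
test suite across a (λ, r) grid.

## Cell-number index and error propagation

Absolute cell counts are not observable from sections; the index
ρ_s·l_s × ρ_o·l_o per layer is proportional to total layer cell number, so
only cross-stage ratios are interpreted. Stage means of the four factors are
combined and the index SE is propagated to first order (delta method),
treating the four group means as independent — the measurements come from
different animals, and no covariance is reported for this kind of data. The
"total" layer is the exact sum of the two layer indices (SEs in quadrature).

Phase folds are ratios of the index at the phase endpoints. The
exponential-vs-linear trend call compares a Gaussian linear model
(index ~ stage) with a log-normal model (log index ~ stage) by AIC, adding
the Jacobian term 2·Σ log(index) so the two likelihoods are on the same
scale; ties break to linear, and a zero-residual fit is floored at
σ² = 10⁻³⁰⁰ so exact data produce a decisive score without dividing by zero.

## Parameter inference

λ₁ is the log-linear OLS slope of the total index within phase 1; the
phase-2 slope estimates λ₂(1−2r), converted to λ₂ with r = c/(1+2c) from
the flux ratio c (default c = 1, r = 1/3). The switch is fixed at E15.5:
seven stage points cannot support a free changepoint plus two exponents.
Confidence intervals come from a percentile bootstrap (default 95%)
resampling animals/embryos with replacement within each stage — the animal
is the replicate unit — and rebuilding the series each time; when only a
series is available, a parametric Gaussian bootstrap from the index SEs is
used instead. Recovery on the default synthetic conditions is essentially
unbiased (|bias| < 0.01/day, RMSE ≈ 0.02–0.04/day over 50 studies).

## EdU model

The analytic predictions are the standard labeled-fraction identities:
a short pulse marks min(1, λ·t_s) of cycling cells (λ·t_s = 0.8 × 1/3 =
0.27 at the defaults), and n completed divisions of the marked cohort scale
this by 2ⁿ (one division: 0.53, "around 50%").

The agent simulation makes the mechanism explicit: each cell has cycle
length 1/λ (optionally gamma-distributed with a CV parameter), a uniformly
random starting phase, and an S-phase window of length t_s placed
immediately before division (G2+M collapsed; an offset parameter moves it).
Cells whose S-phase overlaps the pulse window are labeled; both daughters
inherit the label. The simulation converges to λ·t_s in the short-pulse
limit, as required.

The simulation also shows the limit of the 2ⁿ heuristic: because the
labeled cells are precisely those closest to division, they divide first and
the labeled fraction transiently peaks at 2λt_s/(1+λt_s) ≈ 0.42 — not
2λt_s = 0.53 — before unlabeled cells divide and the fraction relaxes back
toward λ·t_s after one full cycle. The heuristic doubles the numerator but
ignores growth of the denominator. Consequently the labeled *fraction* is
monotone in pulse length but not in chase time; the doubling formula is
exposed through an explicit `n_divisions_chase` parameter rather than
inferred from chase timing.

## Orientation statistics

Continuous angles in [0, 90]° are binned with the half-open convention
[0, 30), [30, 60), [60, 90] — consistent with the printed integer ranges
0–29/30–59/60–90 — and inputs outside the range are rejected rather than
folded (folding is the measurement step's job). Group comparisons:

* Pearson chi-squared on the 2×3 genotype-by-bin table (no continuity
  correction, df = 2); bins empty in both groups are dropped with a warning
  and reduced df, and expected counts < 5 set a warning flag. The statistic
  scales with total count — that is inherent to chi-squared and documented,
  not hidden.
* Two-sample Kolmogorov–Smirnov on raw angles (asymptotic p).
* A two-way ANOVA on per-animal bin proportions with the genotype × bin
  interaction as the reported effect. The genotype main effect is
  structurally null (proportions sum to one per animal), which is exactly
  why the interaction carries the distributional shift. Because of the same
  sum-to-one constraint each animal contributes only two free residual
  dimensions, so the residual degrees of freedom are set to
  2·Σ_g(n_g−1) rather than the naive OLS count; without this correction the
  residual mean square is understated by a third and the simulated null
  rejection rate at α = 0.05 rises to ~14%. With it, simulation places the
  type-I error back at the nominal level. Zero-residual designs (identical
  animals) are resolved by limits: interaction SS > 0 ⇒ p = 0, else p = 1.
* Plain pooled-variance two-tailed t-tests for scalar summaries.

p-values are reported raw, without multiple-testing adjustment.

## Synthetic data generator

The generator emulates the measurement tables of a sectioning study; it
generates numbers, not images, and therefore cannot stand in for real data
on segmentation error, staining variability, spatial correlation within a
section, or litter effects. What passing tests show is that the pipeline's
reconstruction, inference and statistics behave correctly when the data are
generated by the model they assume, at realistic noise and replicate scale.

Conditions (defaults):

* **Stages** E12.5–E18.5 in 1-day steps; 10 embryos/stage for lengths,
  5 animals/stage for densities, EdU and angles (matching typical study n).
* **Lengths**: linear laws per axis — crown–rump 8.5 → 22.0 mm and
  dorso-ventral 5.0 → 12.0 mm across the window (slopes 2.25 and 1.17
  mm/day), Gaussian noise SD 0.5/0.3 mm, truncated at a 0.1 mm floor. A
  configuration whose expected length is non-positive at any requested stage
  is rejected.
* **Densities**: per-stage knots derived from the two-phase trajectory —
  the layer's cell-number curve (suprabasal share 0 at E12.5, 0.15, 0.35,
  then 0.5 from E15.5) divided by the area proxy l_s·l_o, square-rooted so
  the per-axis densities reproduce the layer curve when multiplied back,
  and scaled so basal density at E12.5 is 12 cells/100 µm. This puts basal
  density at 12–13 cells/100 µm throughout (roughly flat, as observed) and
  makes the reconstructed index fold exactly e^{3λ₁} ≈ 7.24 and e^{λ₂} ≈
  2.01 in the noise-free limit. Gaussian noise SD 0.8 cells/100 µm,
  truncated at zero; knots that are exactly zero stay exactly zero (a layer
  that does not exist has no cells to miscount).
* **EdU**: binomial counts at per-stage fraction knots — basal 0.5 through
  the amplification phase dropping to 0.3 after E15.5 (the ~40% slowdown),
  suprabasal 0.45 during E13.5–E15.5 collapsing to ≤0.03 from E16.5.
  100 cells counted per animal (an assumption; per-animal denominators are
  not reported for this kind of figure).
* **Angles**: three-component truncated-normal mixtures on [0, 90]° with
  component means 12/45/78° (SDs 9/10/9°). Component weights are solved
  from a 3×3 linear system so the analytic bin masses hit the target
  proportions: equal thirds at E15.5 for both genotypes ("random"
  orientation), control (0.42, 0.18, 0.40) and mutant (0.17, 0.23, 0.60)
  at E16.5/E17.5 — i.e. ~40% vs ~60% perpendicular. 30 angles per animal.

A single master seed spawns fixed, named substreams per table
(`SeedSequence(seed, spawn_key)`), so any table can be regenerated
independently and identically.

## Problem sizes

Stochastic checks use 200 replicates of 1000–2000 cells (lineage), 20–50k
agent cells (EdU), 400–1000 simulated datasets (test calibration/power),
40 synthetic studies × 120 bootstrap draws (CI coverage) and 50 studies for
recovery. These sizes keep Monte-Carlo error well below the effect sizes
being checked while remaining desk-scale.

## Known limitations

* The three printed division rates (0.66, 0.7, 0.8/day) are kept as
  independent parameters, as in the source analysis; no reconciliation is
  attempted.
* The phase boundary is fixed, not estimated; the optional grid-search
  changepoint is not implemented beyond the fixed-switch fit.
* The index is relative; no absolute cell counts, no 3-D geometry, no
  spatial structure.
* EdU label dilution over many divisions and in-vivo pharmacokinetics are
  out of scope; the agent model's S-phase placement is a simplification
  (sensitivity exposed via the offset parameter).
* The ANOVA design on angle data admits several readings; the per-animal
  proportion interaction implemented here is one defensible choice, with
  its df correction stated above.
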