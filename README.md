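# epistrat

Quantitative kinetics of embryonic skin epidermal stratification.

Between E12.5 and E18.5 the single-layered mouse epidermis becomes a
stratified barrier. This package implements a two-phase model of that
process and the analyses around it, driven by a calibrated synthetic-data
generator that emulates the microscopy-derived measurement tables
(body-axis lengths, layer densities, EdU counts, division-orientation
angles). It is aimed at quantitative/systems biologists who want to work
with the model, test inference on it, or reuse the pieces (Gillespie lineage
simulation, EdU pulse-chase prediction, orientation statistics).

## The model

Relative total cell number per layer is reconstructed from sections as

    n_{b/s}(t) ∝ ρ_{b/s,s}(t)·l_s(t) × ρ_{b/s,o}(t)·l_o(t)

with ρ the basal/suprabasal density per 100 µm along the sagittal and
orthogonal axes and l the corresponding body-axis lengths.

**Phase 1 (amplification, E12.5–E15.5).** Equipotent progenitors duplicate,
p →(λ) p + p, so n(t) = n₀·e^{λt}. A ~7.4-fold rise over three days gives
λ = ln(7.4)/3 ≈ 0.66/day.

**Phase 2 (maintenance, E15.5–E18.5).** Basal progenitors b fire at rate λ
and duplicate with probability 1−r or stratify into post-mitotic suprabasal
cells s with probability r:

    db/dt = λ(1−2r)·b,   ds/dt = λr·b

Proportionate growth of the two layers (db/dt = ds/dt) pins r = 1/3, and a
twofold rise over three days gives λ = ln 2 ≈ 0.7/day. From density parity
at E15.5, b(t) = s(t) = b₀·e^{λ(t−t₀)/3}.

**EdU consistency check.** With cycle time 1/λ ≈ 1/0.8 day and S-phase
t_s = 8 h, a short pulse marks λ·t_s = 0.27 of cycling cells; one round of
division doubles the marked cohort (~50%).

**Division orientation.** Angles between the division axis and the basement
membrane are binned as parallel (0–29°), oblique (30–59°) and perpendicular
(60–90°) and compared across genotypes by chi-squared, Kolmogorov–Smirnov
and a genotype × bin ANOVA interaction on per-animal proportions.

## Worked example

```python
from epistrat import (default_config, generate_all_tables,
                      build_cell_number_series, summarize_phase, fit_two_phase)

tables = generate_all_tables(default_config(seed=1))
series = build_cell_number_series(tables["density"], tables["growth"])
for start, end in ((12.5, 15.5), (15.5, 18.5)):
    ph = summarize_phase(series, "total", start, end)
    print(f"E{start}-E{end}: fold {ph.fold_change:.2f}, trend {ph.trend}")
for f in fit_two_phase(series, n_bootstrap=300, seed=1,
                       density_table=tables["density"],
                       growth_table=tables["growth"]):
    print(f"{f.parameter} = {f.estimate:.3f} [{f.ci_low:.3f}, {f.ci_high:.3f}]")
```

prints

```
E12.5-E15.5: fold 7.15, trend exponential
E15.5-E18.5: fold 2.04, trend exponential
lambda_phase1 = 0.653 [0.615, 0.695]
lambda_phase2 = 0.719 [0.661, 0.774]
```

i.e. the reconstructed total cell number rises ~7-fold during amplification
and ~2-fold during maintenance, and the log-linear fits recover the
generating rates (0.66 and 0.7 per day) within their bootstrap intervals.

The same pipeline is available from the shell
(`epistrat synth | index | simulate | fit | edu | angles | run`), and the
numbered scripts under `analysis/` walk through the full study:
table generation, phase characterisation, stochastic-vs-closed-form
simulation, parameter recovery, the EdU check and the orientation analysis,
writing their tables under `results/`.

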