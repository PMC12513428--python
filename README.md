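# trophostab

Mass-balanced trophic web models, multidimensional stability metrics, and
the statistics that link food web structure to stability.

`trophostab` is for ecologists who work with Ecopath-style food web models
and want to ask how diversity (the number of living groups, NLG) and web
architecture (connectance, interaction-strength heterogeneity, omnivory,
cycling) relate to three complementary dimensions of ecosystem stability:

* **local stability** — `-Re[λ_max(A)]` of the community interaction matrix
  `A`, with `a_ij = -[(Q/B)_j · DC_ij]/B_i` for prey *i* and predator *j*,
  `a_ji = -e_ij · a_ij`, and `e_ij = (P/B)_j/(Q/B)_j`;
* **resistance** — `Y'_n / |Y_e − Y'_n|`, the pre-disturbance biomass over
  the largest biomass excursion during a press mortality disturbance;
* **resilience** — `|Y_e − Y'_n| / |Y_{e+1} − Y'_n|`, the excursion over the
  deviation remaining one year after the press is released.

The pipeline runs end to end: Ecopath mass balance
`(P/B)_i B_i EE_i − Σ_j B_j (Q/B)_j DC_ij − Y_i − E_i − BA_i = 0` →
community matrix and eigenvalue analysis → foraging-arena dynamic
simulation (`Q_ij = a v B_i B_j / (2v + a B_j)`, vulnerabilities random on
[1, 40]) under a 3 × 3 grid of press intensities {5, 25, 50}% × durations
{5, 10, 25} yr → per-group and median stability → ecological network
indices (connectance, SOI, Finn's cycling index and mean path length) →
variance-inflation screening, standardized linear mixed models with an
ecosystem-type random intercept, random-forest permutation importance,
piecewise structural equation models with backward elimination, and
mediation decompositions of the diversity → structure → stability paths.

Because curated model collections are not redistributable, the package
ships a generator of mass-balanced synthetic webs (niche-model topology,
6–81 living groups, connectance 0.1–0.7, six ecosystem types) and of
statistical benchmarks with known coefficients, used throughout the tests.

## Worked example

```python
from trophostab import (generate_balanced_web, nlg, connectance_index,
    build_interaction_matrix, local_stability, interaction_strength_stats,
    build_flow_network, finn_cycling_index, calibrate_dynamics, simulate,
    ScenarioConfig, group_metrics, aggregate_web)

web = generate_balanced_web(seed=7, s=20, c_target=0.25, name="demo")
print(f"NLG = {nlg(web)}, CI = {connectance_index(web):.3f}")

im = build_interaction_matrix(web)
print(f"local stability = {local_stability(im):.4f} /yr")
isi = interaction_strength_stats(im)
print(f"ISI_mean = {isi['ISI_mean']:.3f}, ISI_sd = {isi['ISI_sd']:.3f}")
print(f"FCI = {finn_cycling_index(build_flow_network(web)):.4f}")

dyn = calibrate_dynamics(web, seed=7)
scenario = ScenarioConfig(intensity=0.25, duration=10.0)  # main scenario
traj = simulate(web, dyn, scenario)
gm = group_metrics(traj)
print(f"median resistance = {aggregate_web(gm['resistance']):.3f}")
print(f"median resilience = {aggregate_web(gm['resilience']):.3f}")
```

prints

```
NLG = 20, CI = 0.270
local stability = -0.0009 /yr
ISI_mean = 0.011, ISI_sd = 0.033
FCI = 0.0342
median resistance = 1.835
median resilience = 1.019
```

Read: this 20-group web sits near the neutral edge of local stability
(zero-diagonal community matrices can never be strictly stable, so values
near 0 are the most stable attainable); under a 25% press on natural
mortality held for 10 years, the median group's largest biomass excursion
is its baseline divided by 1.8 (≈ 55% of B₀, resistance 1.8), and one year
after release the median group has barely begun to recover
(resilience ≈ 1).

The same pipeline runs from the shell:

```bash
trophostab synth webs --n 40 --seed 7 --out webs/
trophostab stability --models webs/ --scenarios grid --seed 7 --out stability.csv
trophostab run --config run.yaml     # full run incl. GLMM / SEM / mediation
```

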