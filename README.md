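# sharedrisk

Bayesian small-area analysis of **two spatially indexed count outcomes**:
how much of the between-area variation in risk do they share, and where
do their risk surfaces coincide?

The package is aimed at spatial epidemiologists and criminologists who
have two event counts per areal unit (e.g. two kinds of police calls per
census block group, or two disease registries per municipality), a
population denominator, and a contiguity structure, and who want to go
beyond mapping each outcome separately.

## Models

**Shared-component joint model.** Both outcomes are Poisson with expected
counts `E_ik` (proportional to population) as offsets:

    Y_ik ~ Poisson(mu_ik)
    log mu_i1 = log E_i1 + alpha_1 + phi_i * delta + psi_i1
    log mu_i2 = log E_i2 + alpha_2 + phi_i / delta + psi_i2

One latent surface `phi` is common to both outcomes — scaled by `delta`
for outcome 1 and `1/delta` for outcome 2 — while `psi_1`, `psi_2` are
outcome-specific; every surface is the sum of an intrinsic-CAR structured
part and an iid heterogeneity part.  The key output is the pair of
shared-variance fractions `eta_k = V(c_k phi) / (V(c_k phi) + V(psi_k))`
(`c_1 = delta`, `c_2 = 1/delta`): the proportion of each outcome's
between-area log-risk variation captured by the shared surface.

**BYM spatial regression**, per outcome, for covariate-adjusted relative
risks: `log mu_i = log E_i + alpha + X_i beta + phi_i + theta_i`, with the
relative risk `RR_i = exp(alpha + X_i beta + phi_i + theta_i)` (1 = the
average risk, 2 = twice the average) and an exceedance probability
`P(RR_i > 1)` per area.  A covariate is reported *relevant* when its
posterior probability of being positive (or negative) exceeds 80%.

**Comparison stage**: Pearson correlation of the two log-RR surfaces and
a four-way high/low coincidence classification (matched = high-high or
low-low against the average risk) with matched/mismatched percentages.

Inference is Metropolis-within-Gibbs with a partially collapsed core
(the shared/specific allocation is integrated out analytically when
updating `delta` and the variance scales, then redrawn exactly);
convergence is monitored with split-R-hat across chains.  See
`docs/methods.md` for the full account.

## Worked example

Simulate a two-outcome dataset on a 10x10 lattice with a dominant shared
surface, fit the joint model, fit the two regressions, and compare the
risk surfaces:

```python
import sharedrisk as sr

graph = sr.build_lattice(10, 10, "rook")
data, truth = sr.simulate_joint_dataset(graph, sr.JointScenario(), seed=42)

joint = sr.SharedComponentModel(random_state=1).fit(data, graph)
print(f"delta = {joint.delta_:.3f}")
print(f"eta   = ({joint.eta_[0]:.3f}, {joint.eta_[1]:.3f})")
print(f"max R-hat = {joint.rhat_max_:.3f}")

surfaces = [
    sr.BymPoissonRegression(outcome=k, random_state=k).fit(data, graph).risk_surface_
    for k in (1, 2)
]
result = sr.compare_surfaces(surfaces[0], surfaces[1])
print(f"r(log RR) = {result.pearson_r:.3f}, "
      f"matched {result.matched_pct:.1f}% / mismatched {result.mismatched_pct:.1f}%")
```

Output:

```
delta = 1.145
eta   = (0.709, 0.804)
max R-hat = 1.025
r(log RR) = 0.685, matched 76.0% / mismatched 24.0%
```

`delta` near 1 says the shared surface acts with similar magnitude on
both outcomes.  `eta` says roughly 70% of outcome 1's and 80% of outcome
2's between-area risk variation is shared (the generator's realized
fractions for this seed are 0.64 and 0.92; at 100 areas the eta
posteriors carry SDs around 0.1–0.15).  The matched percentage says 76 of
the 100 cells are high (or low) for *both* outcomes relative to the
average risk.

The same pipeline runs from the shell:

```bash
sharedrisk run --config examples/demo.yaml --output-dir out/
```

with a YAML config naming either a simulation scenario or a data CSV
(`area_id,population,y1,y2[,e1,e2,covariates...]`) plus an adjacency file
(edge-list CSV or GAL).  Every run writes per-stage CSV/JSON artifacts
and a `manifest.json` with seeds, SHA-256 checksums and R-hat flags; two
runs with the same config are bit-identical.

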