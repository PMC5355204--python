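# sealmove

Harbor seals (*Phoca vitulina*) and spotted seals (*Phoca largha*) are
near-identical sibling species whose ranges meet in the Bering Sea. Where they
haul out together, field identification fails and their ecological separation
is an open question. `sealmove` implements the full analysis pipeline used to
quantify that separation from satellite telemetry and molecular data:

1. **Argos track filtering** — the speed–distance–angle (SDA) filter: class-Z
   fixes removed; fixes implying swim speeds > 2.5 m/s removed unless within
   5 km of the previous fix; out-and-back spikes removed when the turning
   angle exceeds 165°/155° with incoming legs > 2.5/5 km; iterated to a
   fixpoint.
2. **Brownian-bridge utilization distributions (UDs)** — the position at
   bridge fraction α between fixes *z₁*, *z₂* is N((1−α)z₁ + αz₂,
   Tα(1−α)σ₁² + (1−α)²σ₂,₁² + α²σ₂,₂²), with σ₁ (motion) estimated by maximum
   likelihood and σ₂ (Argos error, km) set per quality class
   {3: 0.5, 2: 1, 1: 1.2, 0: 4.2, A: 6.2, B: 10.3}. Monthly UDs, 50%/90%
   isopleths, land subtraction, and between-group overlap fractions.
3. **Dive-bin statistics** — from 10-bin depth/duration histograms per 6-hr
   interval: mean/max depth and duration, the dive focus index
   Σ nᵢ(nᵢ−1)/[N(N−1)] (the probability two dives drawn without replacement
   share a bin), and the focal depth (dominant bin when focus > 0.50).
4. **AICc multimodel inference** — candidate linear mixed models (random
   intercept per animal; AR1 or continuous-time AR1 residual correlation)
   over species, month, sex, mass and species×month; AICc weights; natural
   model averaging over the top models holding 95% of the weight, with
   unconditional standard errors and 95% CIs.
5. **Genetic assignment** — two-cluster Bayesian Gibbs sampler over diploid
   microsatellite genotypes (admixture and no-admixture models, sampled
   ancestry concentration α), posterior mean ancestry Q per individual,
   threshold species calls (Q > 0.81), mtDNA nearest-haplotype assignment,
   and nuclear-vs-mtDNA concordance for hybrid detection.
6. **Synthetic data** — generators for tracks (two-state haul-out/at-sea
   movement, Argos-class errors, gross outliers), dive histograms
   (multinomial with controllable focus), and two-population Hardy–Weinberg
   genotypes with optional F1 hybrids; every record carries its generating
   truth.

The estimators follow scikit-learn conventions (`SDAFilter`,
`BrownianBridgeUD`, `DiveSummarizer`, `AICcModelAverager`, `TwoClusterGibbs`:
`fit`/`transform`/`predict`, `get_params`, trailing-underscore fitted
attributes) and compose with sklearn pipelines; module-level functions
(`sda_filter`, `bb_ud`, `dive_focus`, `model_average`, `gibbs_cluster`, ...)
are thin wrappers.

## Worked example

```python
import sealmove as sm

# simulate 3 seals for a month with 5% gross outliers, then filter
params = sm.SimTrackParams(n_animals=3, n_days=30, outlier_fraction=0.05,
                           outlier_km=60.0, seed=7)
tracks = sm.simulate_tracks(params)
kept, reports = sm.filter_tracks(tracks)
rep = reports["SIM000"]
print(f"removed {rep.n_removed}/{rep.n_input} fixes "
      f"({100 * rep.removed_fraction:.1f}%)")
# removed 112/267 fixes (41.9%)

# monthly Brownian-bridge UD and isopleth areas for one seal
seal = kept[kept.animal_id == "SIM000"]
est = sm.BrownianBridgeUD(sig1="estimate", cell_km=1.0).fit(seal)
print(f"sig1 = {est.sig1_:.2f} km/sqrt(hr)")
# sig1 = 2.71 km/sqrt(hr)
for (month, level), iso in sorted(est.isopleths_.items()):
    print(month, f"{int(100 * level)}% area = {iso.area_km2:.0f} km2")
# 2000-09 50% area = 805 km2
# 2000-09 90% area = 3324 km2
# 2000-10 50% area = 612 km2
# 2000-10 90% area = 2347 km2

# dive focus of one 6-hr histogram
print(sm.dive_focus([6, 4, 0, 0, 0, 0, 0, 0, 0, 0]))
# 0.4666666666666667  (below 0.50: no focal depth defined)
```

The filter removes ~42% of the fixes here because the simulated error mix is
dominated by low-quality Argos classes (B alone has a 10.3-km error SD); on
good-quality tracks the removal rate drops to the injected-outlier fraction.
The 50% isopleth is the core area holding half the seal's monthly space use;
the 90%/50% area ratio of ~4 exceeds the Gaussian reference value of 3.32
because the multi-site trips make the UD heavier-tailed than a single
Gaussian.

A command-line interface mirrors the library:

```bash
sealmove simulate --kind tracks --seed 1 --out tracks.csv
sealmove filter tracks.csv --out filtered.csv --report report.json
sealmove ud filtered.csv --out-prefix ud --cell-km 1 --sig1 estimate
sealmove assign genotypes.str --model admixture --out qvalues.csv
```

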