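# orcadiet

Quantitative diet analysis from faecal DNA metabarcoding of resident killer
whales (*Orcinus orca*), built around four stages:

1. **Calibration** — mock communities of known composition are used to
   estimate species-specific PCR amplification bias and invert it, turning
   raw read counts into calibrated prey proportions.
2. **Prey screening** — replicate deduplication and the major/minor prey
   rules (a species is *major* prey if it exceeds 1% of reads in ≥ 4
   samples, *minor* in 1–3).
3. **Individual identification** — samples genotyped at ≥ 85% of a
   68-locus SNP panel are clustered by allele-sharing distance and matched
   against a reference database of known whales via a fixed decision tree.
4. **Diet statistics** — PERMANOVA on Bray–Curtis distances across strata
   (population, month, year, pod) and loess-smoothed seasonal diet
   profiles (span 0.85).

A synthetic-data module generates every input — distorted mock and field
read counts, sample metadata with population/month/pod structure,
replicate pairs, and noisy diploid SNP genotypes — with ground truth, so
the entire pipeline is testable end to end without sequencing data.

## The calibration model

Amplicon sequencing distorts compositions multiplicatively: if a sample's
true prey composition is `p` and species *i* has log-efficiency offset
`α_i` relative to a reference species (`α_ref ≡ 0`), the expected observed
read proportion is

```
θ_i = p_i · exp(α_i) / Σ_k p_k · exp(α_k)
```

Mock-community read counts `y` with known `p` are modelled as

```
y ~ Multinomial(N, θ),   α_i ~ Normal(0, τ),   τ ~ half-Normal(1)
```

and the posterior over the free offsets is sampled by ensemble MCMC (three
independent ensembles; default 10,000 iterations with a 5,000-iteration
warm-up), with potential-scale-reduction and effective-sample-size
diagnostics. Field samples are then corrected by inverting the distortion,
`p̂_i ∝ r_i · exp(−α_i)`, either at the posterior mean or propagating full
posterior draws. Species never present in a mock pass through uncorrected.

## Worked example

```python
import pandas as pd
import orcadiet as od
from orcadiet.calibration import SamplerSettings

# draw "true" amplification offsets and simulate the two mock controls
alpha = od.sim_efficiencies(list(od.MOCK_SPECIES), alpha_sd=0.3, seed=11)
mock_counts, design = od.sim_mock_dataset(alpha, n_replicates=5,
                                          depth=50_000, seed=12)

# fit the hierarchical efficiency model (shortened chains for the example)
est = od.fit_efficiencies(
    mock_counts, design,
    SamplerSettings(chains=3, iterations=2_000, warmup=1_000), seed=5)

# calibrate a held-out sample drawn from the general control design
known = pd.Series({s: od.GENERAL_CONTROL.get(s, 0.0)
                   for s in sorted(design.species)})
counts = od.sim_reads(known, alpha, depth=50_000, seed=99)
cal = od.calibrate_sample(counts, est)
print((100 * pd.DataFrame({"design": known, "raw": counts / counts.sum(),
                           "calibrated": cal.proportions})
       [known > 0]).round(1))
```

prints

```
         design   raw  calibrated
chinook    15.0  20.4        15.1
halibut    40.0  32.9        39.9
herring     5.0   3.9         5.0
lingcod    40.0  42.9        39.9
```

Raw proportions are off the design by up to 7 percentage points
(e.g. halibut amplifies poorly, 32.9% observed vs 40% input); after
inverting the fitted offsets every species lands within 0.2 points of its
known proportion. `od.convergence_report(est)` tabulates per-species
posterior summaries with rhat / effective-sample-size pass flags.

## Command line

```sh
orcadiet simulate --seed 13 --outdir data/          # synthetic dataset + truth
orcadiet all --config run.yaml --outdir results/    # full pipeline
orcadiet calibrate|screen|genotype|stats|trend ...  # individual stages
```

Every stochastic stage takes `--seed` and logs it; outputs are CSV plus a
JSON run report, byte-reproducible from configuration + seed.

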