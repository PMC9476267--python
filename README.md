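# grazekit

From GPS collars to grazing genetics: `grazekit` computes the eleven daily
**grazing-personality behaviours** of free-ranging cattle from GPS
relocations and a digital elevation model, and tests their association with
genotypes using linear and generalised linear mixed models.

It is written for movement ecologists and animal-breeding researchers who
track cows (or other grazers) on rugged terrain at a fixed relocation
cadence and want a reproducible path from raw fix tables to
behaviour–genotype association tables — including a synthetic-herd
simulator with known ground truth, so every stage of the pipeline can be
validated without access to field data.

## What it computes

Per cow per day, from cleaned trajectories annotated with a DEM:
horizontal/vertical/3-D distance travelled, elevation range and gain,
herd-relative elevation metrics (mean, 85th quantile, range), 85th quantile
of slope, home range as the 100% minimum convex polygon (ha/d), and
movement tortuosity = horizontal distance / home range (m/ha). Days with a
recording rate below 75% (fewer than 216 of 288 fixes at 5-min cadence) are
discarded, analysis windows keep the first ≤ 28 days on which the herd's
median slope exceeds 8°, and cows with fewer than 7 valid days are excluded.

Association then proceeds in the standard two steps. For each behaviour
(log-transformed, or logit-linked if bounded in 0–1), twelve candidate
random-intercept structures over {farm, year, farm:year, mob, sire,
genotype} — always plus cow identity, since daily records are repeated
measures — are fitted by ML and ranked by a deterministic AIC / parameter
count / BIC cascade with likelihood-ratio simplification. With the chosen
structure, allele-presence (dominance) and genotype models are fitted by
REML, with cow age class retained only when an ML comparison supports it:

    y_behaviour = genotype (or allele presence) + age_class
                  + (1|cow) + (1|mob) + (1|sire) + ...   [selected]

Fixed effects get Satterthwaite-approximate t-tests; estimated marginal
means are back-transformed to measured units with delta-method SEs;
pairwise comparisons are Benjamini–Hochberg adjusted and summarised with
compact letters. P-values are not adjusted across behaviours.

The mixed-model engine is implemented in the package (profiled REML/ML for
crossed random intercepts with Satterthwaite df and PQL for logit links)
and is cross-checked against statsmodels `MixedLM` in the test suite.

## Worked example

Simulate a small herd (8 mobs × 12 cows, 10 days at 5-min cadence on
synthetic hill country), compute behaviours, and run the association suite:

```python
from scipy import stats
from grazekit import PipelineConfig
from grazekit.cli import run_simulate, run_metrics, run_associate

cfg = PipelineConfig(outdir="demo", seed=42)
cfg.simulation.n_mobs = 8
cfg.simulation.cows_per_mob = 12
cfg.simulation.days = 10

run_simulate(cfg)
res = run_metrics(cfg)
profiles = res["profiles"]
print(profiles[["ho_dist", "hr_mcp", "sp_tortuosity"]].mean().round(1))
r, p = stats.pearsonr(profiles["hr_mcp"], profiles["sp_tortuosity"])
print(f"home range vs tortuosity: r = {r:.2f} (p = {p:.1e})")

out = run_associate(cfg, res["retained"], profiles)
hr = out["results"]["hr_mcp"]
print(f"hr_mcp: genotype ANOVA p = {hr.genotype_anova_p:.2e}")
print(hr.variants[["variant", "mean", "se", "p"]].round(3))
```

which prints:

```
ho_dist          3480.4
hr_mcp             16.0
sp_tortuosity     250.1
dtype: float64
home range vs tortuosity: r = -0.92 (p = 8.2e-40)
hr_mcp: genotype ANOVA p = 1.95e-10
  variant    mean     se      p
0       A  19.998  1.017  0.000
1       B  13.617  0.302  0.000
2       C  14.839  0.302  0.387
```

Cows travel ~3.5 km/d over daily home ranges of ~16 ha. Home range and
tortuosity are strongly negatively correlated — the trade-off the simulator
encodes (cows with stronger home-point attraction cover similar distances
inside smaller polygons, so their paths are more tortuous). The genotype
model detects the built-in genetic effect on home range: carriers of
allele A (low attraction, straight movers) average ~20 ha/d against
~14 ha/d for B carriers — the marginal means are back-transformed from the
log scale to hectares — and the allele-A and allele-B presence tests are
highly significant while allele C, which carries no effect in the
generator, is not (p = 0.387).

The same pipeline runs from the shell:

```
grazekit all --outdir demo --seed 42
grazekit simulate --config my.yaml     # or stage by stage
grazekit metrics  --config my.yaml
grazekit associate --config my.yaml --glmm-mode pql
```

Each stage writes CSV interchange files plus `config.yaml`, a config hash,
and a QC report (`qc.json`, `models.json`, `report.md`) into the output
directory. Real data enter through `fixes_path` (CSV or GPX),
`dem_path` (ESRI ASCII or GeoTIFF) and `metadata_path` (CSV with cow_id,
genotype, age_class, farm, mob, sire, year).

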