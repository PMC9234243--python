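# lipidflux

Which tissues feed the circulating lipid pool, and which drain it?

`lipidflux` is a Python pipeline for multi-tissue LC-MS lipidomics under
an acute physiological stress — the motivating design is mice housed at
room temperature or cold-exposed for a few hours, with plasma and nine
solid tissues (liver, BAT, iWAT, eWAT, kidney, intestine, lung, heart,
gastrocnemius) profiled at n = 6 mice per group. It is aimed at
lipidomics and metabolism researchers who have curated feature tables and
want a tested, reproducible implementation of the computational steps:

* **nomenclature** — parse shorthand lipid names (`ACar 18:0`,
  `Cer_NS d18:1_23:0`, `PC 34:4`) into class/subclass/chain structure
  with order-invariant canonical keys;
* **curation** — collapse redundant annotations (RT < 0.10 min twins,
  < 25% intensity satellites, dual-mode detections) into unique
  high-confidence identifications;
* **quantify** — internal-standard semiquantification to pmol/mg
  (pmol/ml for plasma), log2 z-scoring, the > 2 SD outlier rule;
* **differential** — cold-vs-room Student's t volcano screen with
  Benjamini–Hochberg correction (q < 0.30), Venn overlaps, tissue PCA;
* **correlation** — mouse-paired cross-tissue Pearson r with exact
  t-based p-values;
* **regression** — the core screen: every standardized tissue lipid X
  regressed against a standardized plasma lipid Y,

      Y = β₀ + β₁·Temperature + β₂·X      (cold = 0, room = 1),

  with X called *significantly predictive* only when **both** the
  temperature and lipid terms have P < 0.05. Positive β₂ predictors are
  candidate contributors to the circulating pool; negative ones,
  candidate consumers;
* **chains** — acyl-chain occurrence and composition signatures, lipid
  class distributions;
* **synthetic** — a ground-truthed generator of whole studies (planted
  temperature shifts, planted contributor/consumer links at a designed
  standardized partial correlation, log-normal noise) plus recovery
  scoring, so every stage is validated against known truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Generate a small synthetic study (4 tissues, tens of lipids, seed 17),
run the differential screen on liver, correlate the major plasma
acylcarnitine with liver, and run the contribution screen:

```python
from lipidflux import synthetic, pipeline
from lipidflux.differential import ttest_screen
from lipidflux.correlation import cross_tissue_correlation

study = synthetic.generate_study(synthetic.small_design(seed=17))

liver = study.normalized("liver")          # pmol/mg via class IS
records = ttest_screen(liver)              # cold vs room, BH within tissue
print(records.nsmallest(3, "q_value")[
    ["lipid", "log2_fold_change", "p_value", "q_value", "direction"]])

rec = cross_tissue_correlation(study.normalized("plasma"), liver, "ACar 18:1")
print(f"plasma~liver ACar 18:1: r = {rec.r:.2f}, P = {rec.p_value:.2g}, n = {rec.n_pairs}")

screen = pipeline.run_screens(study)       # standardize + regress every tissue lipid
print(synthetic.evaluate_recovery(screen, study.truth))
```

Output:

```
    lipid  log2_fold_change  p_value  q_value  direction
ACar 18:0          1.710201 0.000192 0.009599 up_in_cold
ACar 16:0          1.499906 0.001555 0.024341 up_in_cold
ACar 18:1          1.706933 0.001215 0.024341 up_in_cold
plasma~liver ACar 18:1: r = 0.95, P = 3.2e-06, n = 12
RecoveryMetrics(sensitivity=1.0, false_flag_rate=0.043, sign_accuracy=1.0,
                top_tissue='liver', contributor_top_ranked=True,
                n_planted=16, n_null=254)
```

Reading it: the acylcarnitines planted as cold-responsive rise ~1.5–1.7
log2 units in cold liver and survive FDR easily; plasma and liver
ACar 18:1 correlate strongly across the 12 mice; and the regression
screen flags all 16 planted contributor/consumer links with the correct
sign, a ~4% false-flag rate on the 254 null lipids (the dual criterion
bounds it by 5%), and correctly ranks liver as the top contributor
tissue.

The same stages are scriptable from a shell:

```bash
lipidflux simulate --seed 17 --small --out results/sim
lipidflux curate --positive pos.csv --negative neg.csv --out curated.csv
lipidflux diff --values liver.csv --meta samples.csv --out liver_diff.csv
```

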