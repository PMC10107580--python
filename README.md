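# acqsar — activity-cliff evaluation of QSAR models

Activity cliffs (ACs) are pairs of structurally similar compounds — matched
molecular pairs (MMPs) sharing a core and differing by one substituent
exchange — whose activities against a target differ by at least a factor of
100 (≥ 2 log10 units). They are where the molecular similarity principle
fails, and they are suspected to be a major source of QSAR prediction
error. `acqsar` is for computational chemists who want to measure exactly
that: it repurposes any QSAR regression f as a pair classifier and
quantifies how well it detects ACs and their potency direction, as a
function of how much of the pair is already known.

The pipeline:

1. **Curation** — desalt, strip isotopes, canonicalise; drop unparseable
   rows; unify duplicate structures by geometric averaging when their
   activities agree within a factor of 10, discard them otherwise. Labels
   are a(s) = −log10(activity in its original unit) (shifted pK_i/pIC_50).
2. **MMP detection** — single cuts of acyclic single bonds (plus hydrogen
   replacements), shared canonical core, size constraints
   (core ≥ 2× either variable part, variable parts ≤ 13 heavy atoms,
   size difference ≤ 8); one record per pair, carrying the largest valid
   core. Pairs are labelled AC (Δ ≥ 2), non-AC (Δ ≤ 1) or half-AC
   (removed), plus a potency-direction (PD) label.
3. **Pair-aware splitting** — k-fold compound-level splits repeated with m
   seeds (default (m, k) = (3, 2)) induce the pair sets M_train, M_inter
   (one compound known), M_test (both unknown) and M_cores (core never seen
   in training); under k = 2 the expected sizes are 1:2:1.
4. **QSAR models** — {ECFP, PDV, GIN} × {RF, kNN, MLP}, each with an inner
   hyperparameter-optimisation loop on the training set only.
5. **Pair-level metrics** — a pair is called AC when the (predicted or
   known) label difference exceeds d_crit = 1.5; metrics are MAE over all
   test compounds, MCC / sensitivity / precision for AC classification, and
   PD accuracy, aggregated over the m·k trials.

A bundled synthetic-landscape generator (congeneric series with planted,
context-dependent cliffs, duplicates and salts) makes the whole pipeline
runnable and testable without any external data.

## Worked example

```python
from acqsar.workbench import RunConfig, run_all

cfg = RunConfig(outdir="demo", n_scaffolds=10, n_substituents=16,
                models=("ecfp-rf",), n_trials=2, epochs=10)
out = run_all(cfg)
```

This generates 168 raw rows (160 unique compounds; 8 duplicate sets are
unified during curation), detects 1200 MMPs — 73 ACs, 112 half-ACs, 1015
non-ACs — and trains a fingerprint random forest on all six (seed, fold)
trials. From `demo/aggregate.json`:

| pair set | MCC | sensitivity | precision | PD accuracy |
|----------|-----|-------------|-----------|-------------|
| M_inter  | 0.73 | 0.69 | 0.84 | 0.72 |
| M_test   | 0.37 | 0.42 | 0.62 | 0.61 |
| M_cores  | 0.0  | —    | —    | 0.63 |

with QSAR MAE 0.43 ± 0.04 over the test compounds. The reading: the model
finds most cliffs when one activity of the pair is known (M_inter) but
misses most of them when both compounds are unseen (M_test) — the central
phenomenon this package measures. On this small run M_cores contains no
true ACs in any trial, so its MCC is recorded as 0 and its sensitivity and
precision as missing, per the edge-case rules for the imbalanced AC task.

The same run is available from the shell:

```bash
acqsar init-config --out config.yaml   # all study constants, editable
acqsar run --config config.yaml
acqsar stage mmp --config config.yaml  # stages are individually resumable
```

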