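# riboswap

Dynamic-SILAC analysis of ribosomal-protein (RP) incorporation into mature
ribosomes — from peptide-level heavy/light peak areas through kinetic
clustering, exchanger calling under biogenesis inhibition, and
stress-modulated differential incorporation.

## The scientific problem

Ribosomes are long-lived machines (a neuronal RP pool turns over with a
half-life of roughly 8 days), so under steady-state first-order turnover
only

&nbsp;&nbsp;&nbsp;&nbsp;1 − exp(−ln2 · t / t½) ≈ **0.36%**

of each RP is expected to be newly made after one hour of labeling.  Brief
dynamic-SILAC pulses therefore resolve which *individual* RPs enter
assembled ribosomes faster than bulk biogenesis allows — the signature of
RPs that **exchange** on pre-existing ribosomes instead of entering only
through de novo assembly.  The package implements the complete analysis
used to detect such exchangers, driven by a kinetic simulator so every
stage is testable without any proteomics download:

| stage | what it does |
|---|---|
| `simkit` | simulates peptide-level H/L peak areas for pulse, pulse-chase, biogenesis-inhibited (LMB) and oxidative-stress experiments, with planted ground truth |
| `quant` | %H = H/(H+L) per peptide, technical-replicate merge (mean), 3× no-label background filter, protein roll-up (median), peptide-level fold changes |
| `kinetics` | turnover expectation, replicate-resolved incorporation profiles, hierarchical clustering (Euclidean, silhouette-selected k), rapid-group and chase-response calls |
| `exchange` | subunit-median normalization of LMB/control fold changes and ROUT outlier calling (Q = 0.2%) |
| `stress` | global translation-inhibition normalization and a peptide-level mixed model with BH FDR and a minimal-difference gate |
| `structure` | Shrake–Rupley solvent-accessible surface areas; per-chain accessible fraction in a complex; stable-vs-exchanger Mann–Whitney comparison |
| `occupancy` | sub-stoichiometry normalization across polysome-profile fractions |

## The kinetic model

Each protein's labeled fraction in the mature ribosome pool follows

&nbsp;&nbsp;&nbsp;&nbsp;dm/dt = k_r·(g(t) − m) + k_ex·(f(t) − m)

where k_r = ln2/T_r is biogenesis-driven replacement of the ribosome pool
(zero when nuclear export of new ribosomes is blocked), g(t) = ℓ(t − τ) is
the label state of proteins entering through new ribosomes after an
assembly delay τ, and f(t) is the labeled fraction of the fast-turning
free precursor pool, df/dt = k_f·(ℓ(t) − f).  Stable proteins have
k_ex = 0; exchangers have k_ex > 0 and keep incorporating when k_r is
silenced.  All trajectories are piecewise-exponential closed forms,
validated against a numerical integrator to < 1e-6 relative error.

## Worked example

Simulate the 2-day biogenesis-inhibition experiment (70 RPs, 4 biological
replicates, 10% multiplicative noise) and call exchangers:

```python
from riboswap import simkit, quant, exchange

cfg = simkit.lmb_config(seed=1)
peptides, truth = simkit.simulate_experiment(cfg)
table = quant.merge_technical(quant.add_heavy_fraction(peptides))
fc = quant.protein_foldchange(table, treated="lmb", control="ctrl")
calls = exchange.call_exchangers(fc, q=0.2)
sorted(calls["exchangers"]["all"])
```

```
['RACK1', 'RPL10', 'RPL22', 'RPL24', 'RPL27', 'RPL36', 'RPL36A',
 'RPL38', 'RPLP0', 'RPLP1', 'RPLP2', 'RPS26']
```

Exactly the 12 planted exchangers are recovered.  Blocking biogenesis
collapses a stable protein's heavy fraction to the no-label background, so
its LMB/control fold change is ≪ 1, while exchangers stay near 1; after
dividing by the subunit median the stable distribution sits at ~1.0
(sd ≈ 0.04 here) and exchangers stand out ~77-fold higher, far beyond the
ROUT outlier threshold at Q = 0.2%:

```
protein subunit  fold_change  normalized_fold_change
  RACK1     40S        0.979                  77.254
  RPL10     60S        1.000                  76.454
  RPL27     60S        1.000                  76.446
```

The same run is available from the shell:

```sh
riboswap simulate --experiment lmb --seed 1 --out-dir run
riboswap exchange --in run/peptides.csv --treated lmb --control ctrl --out-dir run
```

which writes `exchanger_calls.csv` and a `manifest.json` with parameters
and output hashes (identical configuration ⇒ identical hashes).

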