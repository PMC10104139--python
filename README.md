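# dcacheam

Sequence-motif scanning and binding-assay analysis for amine-sensing
dCache_1 sensor domains.

dCache_1 is the most common extracellular sensor module in bacterial and
archaeal receptors (chemoreceptors, sensor histidine kinases, cyclic-
(di)nucleotide turnover enzymes, Ser/Thr phosphatases). Which ligand a given
dCache_1 domain binds is poorly predicted by overall sequence identity, but
a small set of binding-pocket residues at structure-defined positions is
diagnostic. This package implements that logic for biogenic amines:

* an **amine-binding motif (AM)** — residue-class constraints at ten
  positions of the PctD reference numbering (R103, D133, W155, D173, F188,
  Y189, Y206, M215, S217, D235), with an optional aromatic at 206 and the
  salt-bridge pair R103/D133 of the helical insertion above the pocket as
  supporting evidence;
* an **amino-acid-binding motif (AA)** in PctA numbering, for
  distinguishing amine sensors from the ancestral amino-acid sensors they
  evolved from;
* **reference-anchored scanning**: motif positions are carried from the
  reference to each query through an alignment (a supplied MSA, or a
  built-in Needleman–Wunsch/Gotoh affine-gap pairwise aligner), so queries
  with indels are still evaluated at the right sites. A query matching all
  required positions is a `full_match`; exactly one failed position is a
  `near_miss` (the predicted-non-binder negative-control category);
* **receptor-family classification** from domain-hit tables (HMMER
  `--domtblout` or plain TSV): MCPsignal → chemoreceptor, HATPase_c →
  histidine kinase, GGDEF/EAL/Guanylate_cyc/HD → cyclase/phosphodiesterase,
  SpoIIE → Ser/Thr phosphatase, sensor-only → standalone; plus phylum ×
  family contingency tables from GTDB-style taxonomy;
* **assay analysis**: thermal-shift Tm extraction (extremum of the first
  derivative of the fluorescence trace, ΔTm ≥ 2 °C screen) and one-site
  (Wiseman) ITC fits exposed statsmodels-style — a model object built from
  an isotherm whose `fit()` returns estimates, standard errors and a
  `summary()` table — with mutant fold-reduction reporting;
* a **synthetic-data module** generating every input with known ground
  truth (motif-implanted sequences, melt curves, isotherms, domain and
  taxonomy tables), so the entire pipeline runs with no downloads.

## The one-site ITC model

After injection *i*, with cell concentrations Mt (macromolecule) and Xt
(ligand) corrected for displaced volume, the bound fraction Θ solves

    Θ² − Θ·(1 + Xt/(n·Mt) + K_D/(n·Mt)) + Xt/(n·Mt) = 0,   Θ ∈ [0, 1]

and the cumulative heat is Q_i = n·Θ·Mt·ΔH·V₀. The per-injection heat is
Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2, normalized per mole of
injectant. `OneSiteBindingModel.fit()` estimates (n, K_D, ΔH) by bounded
least squares (K_D fitted on a log scale, multi-start across c-value
regimes) and reports the c-value n·Mt₀/K_D with a low-c warning.

## Worked example

```python
import numpy as np
from dcacheam import *
from dcacheam.synthetic import *

# 1. scan a synthetic benchmark for the amine motif
spec = SequenceSimSpec(n_am=50, n_near_miss=25, n_random=50,
                       mutation_rate=0.05, seed=7)
template, records, truth = generate_sequences(spec)
table = scan_collection(records, [builtin_motif("AM")], reference=template)
print(table.summary())
# {'AM': {'full_match': 50, 'near_miss': 25, 'no_match': 50}}

# 2. fit a noisy one-site isotherm (16 uM protein, 29 x 9.6 uL of 0.5 mM ligand)
proto = choline_reference_protocol()
iso = generate_itc_experiment(1.0, 2.6, -10.0, proto, noise_sd=0.2, seed=7)
res = OneSiteBindingModel(iso).fit()
print(res.summary())
# One-site binding model
# ==============================================
#              n          1.02  +/-    0.0281
#       K_D (uM)         2.578  +/-      0.32
#  dH (kcal/mol)        -9.923  +/-     0.358
#        c-value         6.329
#      converged  True
#            RSS        0.9559
print(fold_reduction(421.0, res.kd_uM))   # 163.0 — affinity loss of a mutant

# 3. thermal-shift screen against the ligand-free control
ctrl = compute_tm(generate_melt_curve(50.0, noise_sd=10.0, seed=1))
samp = compute_tm(generate_melt_curve(54.2, noise_sd=10.0, seed=2))
rec = delta_tm(samp, ctrl)
# Tm 54.53 vs 49.47: dTm=5.06, significant=True
```

The scan recovered exactly the generator's truth labels (50 implanted
matches, 25 single-mismatch near misses, 50 random non-matches); the fit
recovered the generating K_D = 2.6 µM within its standard error; and the
4.2 °C programmed shift passed the 2 °C significance screen.

The same stages are available from a shell via the `dcacheam` CLI
(`simulate`, `scan`, `architecture`, `tsa`, `itc`, `report`).

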