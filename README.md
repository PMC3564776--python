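# thermocomp

Comparative survey of sequence-composition thermostability measures across
orthologous protein sets.

## The problem

Thermophilic proteomes differ from mesophilic ones in amino-acid
composition: charged residues (E, D, K, R) are enriched and polar residues
(S, T, N, Q) depleted. The **CvP-bias** quantifies this axis per protein:

    CvP = 100 · (N_EDKR − N_STNQ) / L

where L is the effective sequence length. Companion measures implemented
here: **IVYWREL** content, the **(E+K)/(Q+H)** ratio, serine and charged
content, mean hydrophobicity (Kyte–Doolittle by default), trimmed-fragment
length, plus pluggable external scores (disorder predictions, trained
rankers) merged by protein id.

`thermocomp` is for comparative genomicists and structural biologists who
want to ask: *given orthologous proteins from several species, which species
looks most thermoadapted, and can the measure be trusted?* The package
provides the full survey pipeline —

1. fragment extraction from translated transcripts and greedy 98%-identity
   redundancy reduction,
2. reciprocal-best-hit ortholog sets (strict best-hit consistency across all
   ordered species pairs) from 12-column tabular hit files,
3. trimming of externally built alignments to their shared gap-free core,
4. per-set species ranking and cumulative rank sums (rank 1 = most
   thermostable-looking; ties averaged),
5. validation: ROC AUC on labeled thermophile/mesophile proteins
   (pair-counting, equal to the trapezoidal area), GC3 confound regressions,
   Pearson correlation of proteome means with body temperature, and sign
   concordance of paired CvP differences against experimental Tm differences
   (convention: mesophilic − thermophilic),
6. melting-temperature estimation from thermal-shift fluorescence plates by
   Boltzmann sigmoid fitting,

and a synthetic-data generator whose planted effects have closed forms (a
polar→charged shift of δ raises expected CvP by exactly 200δ), so every
stage is tested without downloading anything.

## Worked example

```python
from thermocomp import cvp_bias, roc_auc
from thermocomp.synthetic_data import gen_pair_dataset

pairs = gen_pair_dataset(500, delta_thermo=0.08, length=300, seed=1)
scores = [(cvp_bias(t.residues), "thermophile") for t, _ in pairs]
scores += [(cvp_bias(m.residues), "mesophile") for _, m in pairs]
print(f"AUC = {roc_auc(scores).auc:.4f}")
```

prints

```
AUC = 0.9988
```

— 500 homolog pairs whose thermophilic member carries a polar→charged
composition shift of 0.08 (expected CvP excess ≈ 16 percentage points) are
almost perfectly separated by CvP-bias; at shift 0 the same computation
gives AUC = 0.5000.

The bundled reference analysis of ten homeothermic vertebrates
(`python analysis/05_body_temperature.py`) prints

```
    cvp_bias: r = +0.71, p = 0.022 (n = 10)
    tm_index: r = +0.23, p = 0.531 (n = 10)
      iupred: r = -0.44, p = 0.206 (n = 10)
     ivywrel: r = +0.02, p = 0.949 (n = 10)
```

— of the four proteome-mean measures, only the mean CvP-bias correlates
significantly with body temperature across mammals and birds.

## Analysis drivers

Numbered scripts under `analysis/` re-run the survey end to end on synthetic
cohorts and the bundled reference tables, writing tables under `results/`
(bulky regenerable inputs go to `scratch/`):

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | 10-species cohort, 120 planted ortholog sets, 2 shifted species |
| `02_rank_survey.py` | RBH orthology → trimming → measures → cumulative ranks |
| `03_roc_benchmark.py` | AUC of each measure across a shift gradient |
| `04_gc_confound.py` | GARP/FYMINK vs GC3; CvP-bias stays GC-neutral |
| `05_body_temperature.py` | proteome means vs body temperature (10 vertebrates) |
| `06_melt_curves.py` | Boltzmann Tm fits on a noisy plate; CvP/Tm sign concordance |

Run them in order (01 before 02); each prints what it found.

There is also a CLI: `thermocomp run --config run.yaml` for the full survey,
plus `validate`, `preprocess`, `measures`, `roc`, `fit-tm` and `synth`
subcommands for the individual stages.

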