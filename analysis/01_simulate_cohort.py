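#!/usr/bin/env python
"""Simulate a 10-species study cohort with one composition-shifted annelid-like
species and one shifted fungus-like species, and write every pipeline input
(per-species proteome FASTA, all-vs-all hit table, per-set alignments).

The two planted thermophiles receive a polar-to-charged shift of 0.03 (an
expected CvP-bias excess of 6 percentage points, comparable in size to real
proteome differences); all species get a small seeded composition jitter.
Generated inputs are bulky and regenerable, so they go to scratch/cohort/.
"""

import json
from pathlib import Path

from thermocomp.synthetic_data import (
    gen_ortholog_sets,
    make_profiles,
    write_ortholog_inputs,
)

SPECIES = ["apo", "cap", "hel", "lot", "hum", "dro", "dan", "cae", "sac", "cha"]
THERMO_SHIFTS = {"apo": 0.03, "cha": 0.03}
GC3_TARGETS = {"cha": 0.8, "lot": 0.3, "sac": 0.35}
N_SETS = 120
SEED = 20260921

out = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
profiles = make_profiles(SPECIES, thermo_shifts=THERMO_SHIFTS, gc3_targets=GC3_TARGETS, seed=SEED)
data = gen_ortholog_sets(profiles, n_sets=N_SETS, len_range=(100, 300), indel_rate=0.05, seed=SEED + 1)

paths = write_ortholog_inputs(data, out)
manifest = {
    "species": SPECIES,
    "thermo_shifts": THERMO_SHIFTS,
    "gc3_targets": GC3_TARGETS,
    "n_sets": N_SETS,
    "seed": SEED,
    "paths": paths,
}
(out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
n_prot = sum(len(v) for v in data.proteomes.values())
print(f"wrote {N_SETS} planted ortholog sets across {len(SPECIES)} species "
      f"({n_prot} proteins, {len(data.hits)} hits) to {out}")
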