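# Methods

## Scope and model

`thermocomp` implements a comparative survey of sequence-composition
thermostability measures over orthologous protein sets, together with the
validation machinery such a survey needs: ROC discrimination on labeled
thermophile/mesophile data, GC-content confound controls, correlation of
proteome means with body temperature, sign concordance against experimental
melting temperatures, and Boltzmann melt-curve fitting. Every stage is
testable offline through a synthetic-data generator with closed-form planted
effects.

## Composition measures

All measures operate on the *effective* sequence: the 20 standard residues
only. Ambiguity letters (B, Z, X, U, O) and stop markers are removed from
both numerators and denominators, so percentage measures remain comparable
between records with and without ambiguous positions.

- **CvP-bias** = 100·(N_{E,D,K,R} − N_{S,T,N,Q}) / L. Bounded in [−100, 100];
  identically equal to charged% − polar%, and mixes length-weighted under
  concatenation — both identities are asserted as property tests.
- **IVYWREL** = 100·N_{I,V,Y,W,R,E,L} / L (reported as a percent).
- **(E+K)/(Q+H)**: a count ratio; a zero denominator yields a *missing*
  value, never infinity. Orthologous sets containing a missing value are
  skipped for that measure so cumulative rank sums stay comparable.
- **Serine content, charged content, GARP% and FYMINK%**: simple set
  percentages. GARP (G, A, R, P: GC-rich codons) versus FYMINK (F, Y, M, I,
  N, K: AT-rich codons) diagnoses GC-content confounding.
- **Mean hydrophobicity**: average per-residue value on a named scale. The
  scale is a genuinely open choice; the default is Kyte–Doolittle, selectable
  by name so other scales can be registered.
- **Length of the trimmed alignment fragment** acts as a compactness measure
  (direction −: shorter fragments, i.e. shorter surface loops, point toward
  thermostability).

Measure *directions* (+1: larger is more thermostable-looking) are part of
the registry: CvP, IVYWREL, (E+K)/(Q+H), charged content and hydrophobicity
point up; serine content and length point down. Externally computed scores
(e.g. disorder predictions or trained rankers) are merged by protein id
through `ScoreTable` with their own declared direction; name collisions with
built-ins are configuration errors.

## GC statistics

`gc_by_codon_position` computes GC% at each codon position and overall.
Only complete codons enter; codons containing N are excluded entirely; a
length not divisible by three is a frame error. GC3 (third, most degenerate
position) is the standard proxy for genomic GC pressure.

## Fragment extraction and clustering

Translated frames are split on stop symbols and trimmed to the longest
stop-free fragment (leftmost on ties). A fragment that follows a stop codon
is scanned to its first methionine, which becomes the protein start; a
post-stop fragment without methionine is discarded, as is any fragment
shorter than 60 residues (default). Whether the methionine scan applies
before or after choosing the longest fragment is ambiguous in the field's
practice; both behaviors are implemented (`met_scan_before_selection`),
defaulting to scan-after-selection.

Redundancy reduction is a deterministic greedy clustering at 98% identity
(default): records are processed longest-first (ties by id) and join the
first earlier representative they match. Identity is exact matches over
aligned columns of a global alignment (match +1, mismatch 0, linear gap −1),
computed with Biopython's `PairwiseAligner`; pairs whose length ratio already
caps identity below the threshold skip alignment. This is a transparent
substitute for word-filtered greedy clusterers: it reproduces their
representative-set semantics without their speed heuristics, and it is
idempotent by construction.

## Orthology

`best_hits` reduces an all-vs-all tabular hit list to the best subject per
(query, target species): maximal bitscore, ties by lower e-value, then
lexicographically smallest subject id — fully deterministic. An orthologous
set is emitted only under the strictest reading of best-hit consistency:
one protein per species such that *every* directed best hit between members
stays inside the set (all S·(S−1) relations). Construction seeds from each
protein of the first species and verifies closure; consistent tuples are
provably disjoint, and a brute-force enumeration oracle confirms the
construction on small random instances. Proteins absent from a pairwise
search are ineligible (no imputation). A laxer mutual-best-pair view is
available (`mutual_best_pairs`) for two-species analyses.

Alignments are consumed, not produced (they come from an external aligner).
`trim_alignment` cuts both ends to the first and last columns that are
gap-free in every row; fragments are the rows over that span with interior
gaps removed, so fragment lengths may differ. An alignment with no gap-free
column raises an error and the set is excluded (and logged) by the pipeline.

## Ranking and ROC

Within each set, species are ranked by each measure (rank 1 = most
thermostable under the measure's direction; average ranks on ties), and
ranks are summed over sets. The tie scheme preserves the column-sum
invariant n_sets_used · S(S+1)/2, asserted on every run. Sets with any
missing value for a measure are skipped for that measure rather than
re-ranked over a subset, keeping sums comparable across species.

ROC analysis scores individual labeled proteins (pooled mode, the default);
a paired read-out (`paired_concordance`: fraction of homolog pairs where the
thermophile member scores higher, ties 0.5) is provided separately for
pair-structured benchmarks. The AUC uses the rank/pair-counting identity
(ties weighted 0.5), which equals the trapezoidal area under the threshold
sweep; tests verify the identity exhaustively on small instances and
cross-check against an independent reference implementation.

## Correlations and paired differences

Correlations are ordinary Pearson coefficients with two-sided p-values from
the t transform (n − 2 df) and an OLS line with a 95% slope band. Proteome
means are unweighted over proteins. The paired-difference convention is
fixed to **mesophilic − thermophilic** for both the measure and the melting
temperature; sign concordance counts pairs where the two differences agree
in sign (zero differences count discordant and are flagged; pairs lacking a
Tm are skipped with a warning). Melting temperatures reported as ranges are
carried as ranges and used via their midpoints when a scalar is required.

## Melt-curve fitting

The Boltzmann sigmoid F(T) = F_low + (F_high − F_low)/(1 + exp((Tm − T)/a))
is fitted by trust-region nonlinear least squares (tolerances 1e-8).
Numerical choices:

- the fit region runs from the global minimum to the global maximum of a
  lightly smoothed curve (centered moving average, window 5 — used for
  initialization and region selection only, never in the objective), which
  excludes the post-peak aggregation decay of dye-based assays;
- initialization: baselines at the 5th/95th percentiles of the region, Tm at
  the maximal finite-difference slope, a = 1 °C;
- if the optimizer does not converge, three deterministic restarts perturb
  the initial Tm by −5, +5, −10 °C (fixed order, no RNG);
- the (Tm, a, F_low, F_high) ↔ mirrored sign ambiguity is normalized to
  a > 0 after fitting.

Flat or falling curves raise a no-transition error; a fitted Tm outside the
observed range or non-rising baselines emit an `UnreliableFitWarning`.
Temperature-shift equivariance and fluorescence-scale invariance of the
fitted Tm are asserted as properties. On the standard plate grid (20–80 °C,
0.2 °C steps, 301 points) with 1% amplitude noise, Tm is recovered to well
under 0.2 °C across Tm ∈ [35, 65].

## Synthetic data: what it emulates, and what it does not

Sets derive from one ancestral uniform vector per position; each species
maps the shared uniforms through the inverse CDF of its own residue profile
(comonotone coupling). Consequences used as oracles:

- each species' marginal composition is exactly its profile, so moving a
  mass δ from polar {S,T,N,Q} to charged {E,D,K,R} raises the expected
  CvP-bias by exactly 200δ percentage points;
- species with identical profiles produce identical sequences, so
  within-set similarity is high and reciprocal-best-hit recovery of planted
  sets is exact at indel rate 0;
- hit-table bitscores are pairwise identities ×100 — an identity proxy
  sufficient for best-hit logic, not an alignment score.

Default study conditions: a mesophilic baseline profile set to the average
residue frequencies of curated protein databases, 2% log-normal per-species
composition jitter, set lengths uniform on 100–300 residues, benchmark pairs
of length 300. An optional GC coupling tilts GARP up / FYMINK down with the
GC3 target while *preserving* charged and polar masses, so the planted GC
gradient is CvP-neutral — mirroring the empirical situation in which GC
content drives composition strongly but does not explain the
charged-vs-polar axis. Coding sequences are reverse-translated with a
Bernoulli(gc3_target) preference for G/C third positions (every residue has
at least one G/C-ending codon, so the target 1.0 limit is exact; M and W
have no A/T-ending codon, which pulls the realized GC3 slightly above a 0.5
target).

Not emulated: substitution-matrix evolution, real codon-usage tables,
paralogy, domain shuffling, alignment error, and length variation beyond a
uniform indel process. Passing tests therefore demonstrate correctness of
the *computations* and recoverability of *planted* effects, not performance
on real proteomes.

## Problem sizes

The bundled analyses use 10 species × 120 sets (survey), 500 pairs per shift
level (ROC), 60 sets × 10 species (GC confound), and 12 wells (melt plate);
the acceptance script uses 5 species × 40 sets, 500/400 pairs, and 70 melt
curves. These sizes keep every simulated estimate's Monte-Carlo error an
order of magnitude below the assertion tolerances.

## Known limitations

- The greedy clusterer is quadratic in proteome size; it targets the tested
  scales, not millions of sequences.
- Strict best-hit closure requires a protein in every species; absences
  drop the set rather than tolerating gaps.
- The pooled ROC treats proteins as independent; for paired benchmarks the
  paired concordance read-out is the safer statistic.
- Only single-transition melt curves are modeled (no biphasic unfolding,
  no van't Hoff thermodynamics).
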