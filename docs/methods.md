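# Methods

This note records the model, the conventions adopted where several
readings were defensible, the synthetic-data design, and the limits of
what the test suite demonstrates.

## Data model

Input is a delimited episode table: `patient_id`, `episode_id`,
`admit_date` (ISO-8601), `icd_code`, optionally `icd_version` and
`discharge_date`; one code per row or semicolon-separated lists.
Episodes are ordered by admission date with episode id as a deterministic
tie-break for same-day admissions.  When no version column is present the
version is inferred: leading digit or `V` → ICD-9, any leading letter →
ICD-10.  ICD-9 external-cause codes (E800–E999) are shape-identical to
ICD-10 chapter-E codes and resolve to ICD-10, because chapter E carries
the endocrine/metabolic diagnoses the analysis needs while external-cause
codes map to no comorbidity under either reading.  Supply a version
column when external-cause codes matter.

## Code matching

Patterns use exact (`404.11`), wildcard (`428.x` — prefix), and inclusive
range (`250.0–250.3`) notation on canonical codes (uppercase, dot
removed).  A code is in a range when its canonical form truncated to each
bound's length lies within that bound; this reproduces the clinical
reading "250.0–250.3 covers 250.0x through 250.3x" and handles
unequal-length bounds such as `424.0–424.91`.

## Comorbidity map

The bundled table implements the Quan et al. (2005) enhanced ICD-9-CM /
ICD-10 coding of the Elixhauser index, with seven categories promoted out
of the comorbidity list into index-disease definitions: T2DM (two
diabetes categories collapsed into one definition) and CVD (congestive
heart failure, cardiac arrhythmias, valvular disease, pulmonary
circulation disorders, peripheral vascular disorders), leaving 24
comorbidity categories as network nodes.

The published Quan code sets overlap between categories (e.g. renal
hypertension codes appear under both complicated hypertension and renal
failure, alcoholic liver disease under both liver disease and alcohol
abuse).  Because the mapper treats a double match as a corrupt-table
error, the bundle is curated to be disjoint: each overlapping code is
kept in the more specific category, and comorbidity codes that collide
with the CVD index definitions (e.g. `I27.8`, `416.8` under chronic
pulmonary disease) are dropped.  All edits are documented as comments in
`data/elixhauser_quan.tsv`; users can supply their own table (same
four-column format) without code changes.  Overlaps *between* the
comorbidity list and the index definitions are allowed and faithful to
the source coding — a code such as `404.11` (hypertensive heart and
kidney disease with heart failure) is both a complicated-hypertension
comorbidity and a heart-failure diagnosis.

Exclusion filters ("physical injuries, fever, vomiting") are concepts,
not printed code sets; the editable default is ICD-10 chapters S and T
plus `R50.x`/`R11.x`, ICD-9 800–999 plus `780.6x`/`787.0x`.  Note the
injury chapters also swallow a handful of index/comorbidity codes that
live there (`T82.1`, `T51.x`); keep them out of the exclusion list if
those diagnoses matter for a given dataset.

## Cohort windows

The dual cohort requires first-T2DM strictly before first-CVD (strictly,
in both episode order and calendar date — same-episode co-diagnosis
excludes the patient), at least one admission strictly between the two
index episodes, and at least one mapped comorbidity code in the window.
The window itself spans from the first-T2DM episode *inclusive* (codes
co-recorded with the index diagnosis count toward the trajectory) up to
but excluding the first-CVD episode.  The single cohort requires a T2DM
code, no CVD code anywhere, and at least one admission carrying a mapped
comorbidity strictly before the first T2DM date; its window is every
episode before that date.  The single-cohort window deliberately looks
*backward* from the index diagnosis: the two cohorts are contrasted as
"trajectory while progressing toward CVD" versus "trajectory while not
(yet) diabetic", which is the printed selection criterion this package
follows.

Equal cohort sizes are enforced by uniform down-sampling of the larger
cohort (`sample_size: min`, the default), with sub-seeds derived from the
run seed.

## Attribution formula

The merge of the two baselines is specified only as a "relative frequency
increment", so the formula is a design choice, isolated behind one
function and recorded in the output metadata:

    raw(d)   = max(0, p_dual(d) − p_single(d)),   p(d) = freq(d) / Σ freq
    score(d) = raw(d) / max raw                   (0 if all raw are 0)

It was chosen because (i) a category absent from the single cohort and
prevalent in the dual cohort scores exactly 1 ("exclusive or more
prevalent"), (ii) proportions make it invariant to scaling either
baseline, and (iii) with clipping at zero, max-normalization and min–max
normalization coincide.  Alternatives (ratio, log-ratio) can be swapped
in without touching the rest of the pipeline.  Negative increments are
clipped because the final network is defined over the progressing
cohort's excess burden; zero-score items are retained and can be pruned
on export.

Significance uses a two-sided two-proportion Z-test with pooled variance,
treating each baseline's total node frequency (or total edge weight) as
the denominator.  A degenerate pooled proportion (0 or 1) returns p = 1.
No multiple-testing correction is applied by default; a
Benjamini–Hochberg option exists behind the `fdr` flag.

## Network measures

Density uses the directed formula E/(N(N−1)); clustering, diameter and
average path length use the undirected unweighted projection, with path
measures restricted to the largest connected component (whose share of
nodes is reported).  Nodes and edges with non-positive
frequency/weight/score are excluded before measuring.  Undirected density
is available via `density_convention`; the convention used is recorded in
each summary row.

## Synthetic generator

Defaults mirror the study scale the framework targets: 172 patients per
cohort, 3–11 episodes each (≈1,150–1,240 admissions per cohort), 24
categories, admissions spread over 2000–2017.  Dual-regime patients get a
T2DM code in the first episode, a CVD code in the last, and independent
Bernoulli draws of comorbidity categories per episode at dual-regime
rates, with transition boosts multiplying a target category's probability
in the episode after its source occurred.  Single-regime patients get
comorbidity episodes followed by a terminal first-T2DM episode and never
a CVD code.  Default rates encode the qualitative asymmetry of interest
(renal failure, fluid/electrolyte disorders, chronic pulmonary disease,
hypertension elevated in the dual regime; depression, metastatic cancer,
obesity elevated in the single regime), and the default boosts follow the
fluid/electrolyte→renal motif.  Each category occurrence emits one
representative code, alternating between ICD-9 and ICD-10 forms so both
matching paths are exercised.

Two guarantees keep every generated patient inside their cohort: each
episode carries at least one code (a benign unmapped code is added if no
draw fired — real admissions always carry a diagnosis), and if an entire
observation window drew no comorbidity, one rate-weighted category is
injected into a random window episode.  The injection is a negligible
perturbation of the configured rates at the default 24-category
configuration (empirical prevalences match configured rates within three
standard errors at 1,000 patients) but becomes visible for sparse
two-or-three-category configurations.

What the generator does **not** emulate: realistic coding depth (one code
per category occurrence), age/sex structure, length-of-stay effects,
provider mix, temporal drift between ICD editions, and correlated
comorbidity clusters beyond first-order transition boosts.  Passing
recovery tests therefore demonstrate the pipeline's correctness and
sensitivity under the stated generative model, not clinical validity on
real claims data.

## Numerical and degenerate cases

All stochastic steps draw from `numpy.random.default_rng` seeded from a
single run seed; exports iterate in sorted order so reruns are
byte-identical.  Empty windows yield empty individual networks; an empty
dual-cohort baseline is a hard error (no exposure signal); an all-zero
score vector normalizes to all zeros; single-node graphs report NaN path
measures and zero density.  Problem sizes in the test suite (≤1,000
patients, graphs ≤50 nodes, 20-seed recovery sweeps at 172+172 patients)
were chosen so the full suite completes in well under a minute while
keeping standard errors small relative to the tested tolerances.

## Known limitations

* Transfers, nested episodes and cross-provider record linkage are out of
  scope; episodes are treated as independent dated admissions.
* Only immediately consecutive admissions contribute transition edges;
  the time gap between admissions is not used.
* The attribution score is descriptive, not causal, and carries no
  uncertainty beyond the per-item Z-test.
* The bundled map targets the Quan Elixhauser coding; Charlson-style
  weighted scores are deliberately not computed.
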