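# Methods

## The workflow

The package estimates the comorbidity burden of an index disease in four
stages. Stage boundaries are deliberate: each stage is a pure function of
its persisted inputs, so any stage can be re-run and audited in isolation
(the pipeline writes every intermediate artifact).

**Literature selection.** Candidate comorbidities are MeSH descriptors
restricted to a hierarchy subtree given by a tree-number prefix. Tree
numbers are positional addresses, so prefix matching respects dot
boundaries: `C20.111` covers `C20.111` and `C20.111.199`, never `C20.1115`.
Candidates are ranked by the number of MEDLINE citations indexed with both
their descriptor and the index disease's descriptor, and the top *k* are
kept. Co-occurrence pairs are unordered; duplicate rows are summed with a
warning. A tie exactly at rank *k* is never truncated arbitrarily: all tied
members are kept (the panel may exceed *k*) with a warning, and a secondary
sort by DUI makes the output order deterministic and independent of input
order. The on-disk dialect is a simple three-column delimited file;
release-specific NLM distributions must be converted to it first.

**Terminology mapping.** Concept mapping to ICD-10/ATC is externalized to a
validated YAML config — the package applies mappings, it does not query a
terminology server (which would require a license and a network). ICD-10
codes are normalized (upper-case, dots stripped) before comparison because
billing extracts disagree on formatting; `E10*` covers all descending
codes, `|` separates alternatives. ATC detection is prefix-based so a short
stem covers every formulation of a drug family. Text detectors are regular
expressions compiled case-insensitively over accent-folded text (the
reference EHR is French); the pattern literal is folded too, so `thyroïdite`
and `thyroidite` are interchangeable in configs. The shipped term catalog is
a reconstruction from disease names and common French/English synonyms, not
a validated lexicon. A static guard rejects patterns with nested
quantifiers (`(\w+)+`-style), the common catastrophic-backtracking shape;
it is a heuristic, not a completeness guarantee.

**Cohort and phenotyping.** The cohort is the union of a disease registry
and patients meeting four conjunctive warehouse criteria (encounter in the
closed study window, defaulting to 2000-01-01..2014-12-31; an index billing
code; an index-department encounter; an index term in a document). Union
semantics make inclusion monotone: adding data never removes a patient.
Phenotyping treats the panel diseases as chronic: one firing of any source
at any time makes a case, so calls are invariant to event dates. Text
candidates may be reviewed; under the default `consensus` policy a case
needs every reviewer's approval and mixed votes stay `unresolved` —
excluded from case counts and reported separately, since there is no
principled way to resolve them automatically. Raw-match mode (no votes) is
over-sensitive by construction: no negation or context handling is
attempted, deliberately, because the workflow's design point is human
review assisted by highlighting. Fuzzy matching (off by default) accepts
whole word tokens within edit distance 1 of a pattern's literal form.
Match spans are 0-based half-open offsets over code points of the folded
text, with a per-character map back to original offsets.

## Statistics

* **Prevalence CI.** Point estimate 1000·k/n. The Wald interval
  `p ± z·√(p(1−p)/n)` (z = 1.959964 at α = 0.05) is used unless it leaves
  [0, 1] — including k = 0, whose Wald interval collapses to a point — in
  which case the Wilson score interval is used. This operationalizes
  "Wilson when the proportion is close to 0%" and guarantees reported lower
  bounds ≥ 0. The Wilson lower bound at k = 0 is clamped to exactly 0
  (naively evaluated it is a ~1e-17 float, which breaks the invariant that
  zero successes give a zero lower bound). Reported values are rounded to
  one decimal per 1000, half-up; internal computation keeps full precision.
  CI endpoints of the saturated case k = n degenerate to [1000, 1000] under
  Wald; arguably Wilson would be better there, but proportions near 1 do
  not occur in this design (per-disease prevalences are small).
* **Sperrin's I.** For a patient with n ≥ 2 encounters, the n−1
  inter-encounter gaps are normalized by the follow-up span (they sum
  to 1) and I = 2/n + ((n−2)/n)[1 − √((n−1)·Var(gᵢ))] with the population
  (mean-squared-deviation) variance. The normalization and variance
  convention are chosen so that perfect regularity gives exactly I = 1
  (equal gaps make Var = 0; n = 2 zeroes the coefficient), matching the
  index's interpretation; the index is then invariant to shifting/scaling
  the date axis. Fewer than 2 distinct dates or a zero span are signaled
  as undefined, never silently scored 0. Values are clamped to [0, 1].
* **Cohen's κ** from the 2×2 two-reviewer table (statsmodels); degenerate
  marginals (expected agreement 1) are signaled. **Spearman ρ** uses
  average ranks for ties (scipy); constant vectors are signaled. Both have
  from-first-principles oracles in the test suite (direct p_o/p_e
  computation; rank-then-Pearson), keeping implementation and check on
  separate routes.
* **Burden** is the prevalence of the indicator "≥ 1 panel disease
  present", with the same CI machinery.

## The synthetic generator

`litcomorbid.synth` emulates the study conditions, not real clinical
language. Defaults, chosen once:

* cohort size 741; per-disease prevalences equal to the published case
  counts over 741 (0 for the two diseases with no observed case and for the
  panel disease absent from the prevalence table);
* source sensitivities p_text = 0.95, p_icd = 0.15, p_drug = 0.10 given
  case status, independent by default. The text-dominant profile mirrors
  the published source attribution, where text is involved in ~95% of
  detections and structured sources in ~21%. A correlation knob (shared
  latent severity, Gaussian copula) lets sources co-fire; a false-positive
  knob (default 0 — non-cases never fire) supports robustness tests. Drug
  firing is only materialized for diseases with an ATC marker (insulin for
  type 1 diabetes, levothyroxine for thyroiditis), as in the source study.
* encounters per patient 1 + NegBin(2, 0.5) (median ≈ 3), dates placed in
  the study window by a regularity spec: `regular` (equal spacing),
  `jittered` (default, Gaussian noise at 0.3 of the mean gap), `clustered`
  (uniform, irregular); duplicate same-day encounters collapse;
* every patient carries the index disease: a baseline document mentioning
  it (French template with accented text 70% of the time, exercising accent
  folding), an index billing code and an index-department encounter, so the
  synthetic cohort is the full bundle; registry membership is a 60% coin;
* a text firing inserts one extra document containing a disease mention
  that the shipped term catalog provably matches (generator and detector
  are consistency-tested against each other); ICD/drug firings add concrete
  codes covered by the shipped patterns;
* the co-occurrence generator plants the published pair counts for the
  panel under synthetic `C20.111.*` tree addresses and adds decoy
  descriptors outside the subtree whose counts may exceed every planted
  count — subtree restriction, not count magnitude, must keep them out.

What passing tests on this generator do **not** show: robustness to
negated or hypothetical mentions, misspellings beyond edit distance 1,
coding practice variation, correlated comorbidities (case statuses are
independent across diseases), or documents whose language differs from the
catalog. Estimates inherit a small downward bias from the detection union
(≈ 0.96 sensitivity under defaults), which is visible in the
coverage-style tests: CIs cover planted parameters slightly below their
nominal rate for the high-prevalence disease and conservatively for rare
ones.

## Problem sizes and numerical choices

Simulation-based tests use 741-patient bundles (the study's cohort size)
and 200 seeded replicates for coverage checks; the calibration check uses
one 50 000-patient bundle. Monte-Carlo expectations asserted in tests were
derived beforehand with an independent binomial oracle (direct simulation
of case and detection draws, no package code), and assertions carry the
oracle's own Monte-Carlo error where the quantity is stochastic. All
randomness flows from explicit integer seeds through numpy Generators;
identical configs give byte-identical bundles.

## Known limitations

* The MRCOC dialect is canonical, not NLM's release format; a converter is
  the user's responsibility.
* No negation/temporality handling; raw-match prevalence overestimates.
* The Wilson-vs-Wald switch is a reconstruction of an informally stated
  rule; published CI endpoints can differ from recomputed ones by about
  one unit in the last printed digit due to unstated rounding conventions
  (point estimates reproduce exactly).
* Diagnosis dates are deliberately not modeled (chronic-disease logic);
  no incidence or survival quantities can be derived.
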