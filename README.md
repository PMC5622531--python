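# litcomorbid

Estimating the comorbidity burden of an index disease by combining the
biomedical literature with electronic health records (EHRs).

Clinicians and epidemiologists who want to know *which* comorbidities matter
for a disease, and *how common* they are in a real patient population,
usually rely on expert elicitation. `litcomorbid` implements a data-driven
alternative, developed around the case of autoimmune comorbidities in
celiac-disease patients:

1. **Literature selection.** Candidate comorbidities are the MeSH
   descriptors of a target domain (a hierarchy subtree, e.g. the autoimmune
   diseases under tree number `C20.111`) ranked by how often each co-occurs
   with the index disease's descriptor in MEDLINE citations. The top *k*
   (default 15) form the study panel.
2. **Terminology mapping.** Each panel disease is expressed as machine
   usable detectors: ICD-10 billing-code patterns (with OR alternatives
   `E271|E272` and descendant semantics `E10*`), ATC prescription prefixes
   (e.g. `A10A` for insulins), and regular-expression term patterns applied
   to accent-folded clinical text (e.g. `\bdiab\w+\b`).
3. **Cohort & phenotyping.** A cohort is selected as a disease registry
   unioned with patients meeting four warehouse criteria (encounter in the
   study window, index billing code, index-department encounter, index term
   in a document). A patient is a case for a panel disease if *any* source
   fires at least once — chronic-disease logic, insensitive to event dates.
   Text candidates can be adjudicated by two reviewers (consensus policy by
   default).
4. **Statistics.** Per-disease prevalence per 1000 patients with a 95% CI —
   Wald `p ± z√(p(1−p)/n)` by default, the Wilson score interval when the
   proportion is close to 0 (operationally: when the Wald bound leaves
   [0, 1]); overall burden (≥1 panel disease); source attribution
   (text-only / structured-only / both); Cohen's κ for reviewer agreement;
   tie-aware Spearman ρ between literature ranking and observed prevalence;
   and Sperrin's *I* encounter-regularity index,

   I = 2/n + ((n−2)/n)·[1 − √((n−1)·Var(gᵢ))],

   over the n−1 normalized inter-encounter gaps gᵢ of each patient.

Real clinical data cannot ship with the package, so a first-class synthetic
generator (`litcomorbid.synth`) produces EHR bundles with configurable
per-disease prevalence, per-source detection sensitivity and
encounter-timing regularity, plus co-occurrence files with planted counts
and decoy pairs — every stage is testable against known ground truth.

## Worked example

```bash
# generate a synthetic 741-patient study and run the full pipeline
litcomorbid simulate --seed 1 --n-patients 741 --out sim/
litcomorbid rank --descriptors sim/descriptors.txt --cooc sim/cooccurrence.txt \
    --index D002446 --subtree C20.111 --top 15 --out panel.csv
litcomorbid phenotype --bundle sim/ --out run/
```

`rank` writes the 15-disease panel; its first rows are

```
dui,n_cooccurrence,name
D003922,523,"Diabetes Mellitus, Type 1"
D003874,478,Dermatitis Herpetiformis
D013967,96,"Thyroiditis, Autoimmune"
```

i.e. type 1 diabetes is the most literature-co-occurring autoimmune disease
of celiac disease (523 citations), and none of the 40 decoy descriptors
outside the `C20.111` subtree enter the panel. `phenotype` prints

```
cohort 741, burden per 1000 210.5
```

and writes `run/prevalence.csv`, `run/attribution.csv` and
`run/summary.json`. Under the default generator conditions the planted
per-disease prevalences (published case counts over 741) are independent,
so the planted overall burden is 1 − ∏(1 − p_d) ≈ 0.202; this seed detects
21.0% of patients with at least one panel disease (detection-union
sensitivity ≈ 0.96 pulls estimates slightly below truth, sampling noise
moves them either way).

The same steps are available as library calls (`literature.rank_comorbidities`,
`phenotype.combine_sources`, `stats.prevalence_ci`, ...); see the module
docstrings and `docs/methods.md`.

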