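# Methods

This note documents the model behind `depclaims`: the selection rules and
their exact window semantics, the statistics reported for cohorts, the
synthetic-population generator and its calibration, the numerical
conventions, and the design choices made where the rules as usually stated
leave room.

## Selection model

All rules operate on four linked tables (beneficiaries,
long-term-condition episodes, hospital stays, drug dispensings) for a study
calendar year *y*.  Diagnoses are ICD-10, drugs are ATC; a code matches a
code set when, after normalisation (uppercase, dots stripped), it starts
with an include prefix and no exclude prefix.  Prefix matching mirrors the
ICD-10/ATC hierarchies: `F32` covers every `F32.x`.  Depression is F32–F39
(F35–F38 are unused blocks; harmless to list), the bipolar exclusion
diagnoses are F30–F31, antidepressants are N06A minus oxitriptan (N06AX01).

**Calendar-year windows.**  All temporal logic uses calendar years: "last
*k* years" means the *k* calendar years ending at and *including* the study
year, so the elapsed time between a qualifying event and the study year end
varies within the window (1–24 rolling months for the 2-year case).  A stay
is dated by its **admission** year — the usual claims convention; the rules
never need a discharge date, so the schema omits it.

**Treatment.**  "Treated by antidepressant" means ≥ 3 dispensings of
antidepressants on ≥ 3 **distinct dates** within the study year.  Distinct
dates stand in for distinct reimbursement events because a prescription is
typically dispensed monthly; a same-day multi-item dispensing should count
once.  The threshold and the distinct-date behaviour are configurable
(`SelectionConfig`).

**The five methods** (decreasing reliability):

* **A** — a depression ALD episode whose [start, end-or-open] interval
  overlaps any day of the study year.  Activity-based, not ever-granted:
  an episode that ended before the study year does not qualify.
* **B** — depression as principal or associated diagnosis of a psychiatric
  stay, or as principal diagnosis of a general stay, with 1-year and 2-year
  windows.  Associated diagnoses of general stays are deliberately not part
  of B: they are the least reliable position and are quarantined in D/E.
* **C** — treated in the study year AND a B-qualifying stay within the
  5-year window.  The stay may fall in any of the 5 years *including* the
  study year itself; nothing in the rule forbids same-year overlap, and a
  person hospitalised this year who is also treated clearly satisfies
  "treatment + hospitalisation history".
* **D** — a general stay with depression among the associated diagnoses,
  1- and 2-year windows.
* **E** — treated AND a D-qualifying stay within the 5-year window.
* **Bipolar exclusion** — any stay (either hospital type, either diagnosis
  position — symmetry argues for the broadest net) carrying F30/F31 within
  the 5-year window, or ≥ 1 dispensing of lithium (N05AN01), valproic
  acid/divalproex (N03AG01) or valpromide (N03AG02) during the study year.
  One dispensing suffices because an exclusion should be sensitive; the
  threshold and the drug list are configurable.  The WHO ATC index does not
  separate divalproex from plain valproic acid, so N03AG01 covers both;
  national dictionaries that distinguish them can be accommodated by
  editing the registry.  Drugs dispensed outside the study year do not
  exclude (configurable by re-running with another study year).

`run_selection` computes all ten sub-source sets and subtracts the
exclusion set from each.  Note that the nesting chain 1-year ⊆ 2-year ⊆
5-year holds for the *stay-history* sets (exposed as
`psy_stay_history_5y` / `gen_principal_stay_history_5y`); the C sets are
treatment-conditioned subsets of those histories, so an untreated
hospitalised person is in B but not C by design.

## Attribution, prevalence, overlap

Incremental attribution applies sub-sources in reliability order (the
default order is A, then B by source and window, then C, D, E); increments
are exact set differences, so they are pairwise disjoint, conserve the
union, and the final cumulative count is order-invariant.  Counts are
rounded to the nearest 5 only at report time (remainder 2 rounds down, 3
up, so |rounded − raw| ≤ 2); because rounding is applied per cell, rounded
incrementals can drift a few units from rounded cumulatives — raw counts
are therefore carried and reported alongside.  Prevalence is
100·count/denominator, half-up to 2 decimals (decimal arithmetic, not
binary floats).  The overlap analysis partitions the aggregate A, B
(2-year) and C (5-year history) sets into the 7 non-empty regions of a
three-set system and reports the multi-source fraction (members of ≥ 2
methods over the union) and per-method overlap rates.

## Cohort profiles

For any id set: age = study_year − birth_year (mean, **population** SD
(ddof = 0), and IQR by the **nearest-rank** method, i.e. the ⌈p·n⌉-th order
statistic — both chosen for exactness on tiny fixtures and pinned by
tests); % male; treatment rates per psychotropic class (≥ 3 distinct-date
dispensings; anxiolytics N05B, hypnotics N05C, neuroleptics N05A minus the
lithium subgroup N05AN, plus the antidepressant set; "any" is the union of
the four user sets); in-year mortality (deaths dated in the study year over
cohort size — a death the following January does not count); CMUC coverage
restricted to members under 60 (different benefits apply from 60, so the
rate is undefined — reported absent — for an all-60-plus cohort);
comorbidity-flag rates and per-category cost sums with a grand total.
Comorbidity flags and costs are tabulated as carried on the beneficiary
row; deriving them from claims is out of scope.  An empty cohort yields an
n = 0 profile with absent statistics rather than an error.

## Synthetic population

The generator draws, per person and independently across persons:

* a **recency category** per stay source (psychiatric; general-principal;
  general-associated): none / study year / previous year / uniformly one of
  years −2…−4.  One stay per source at most — overlap between the 1- and
  2-year sets of one source then comes from windowing, exactly as in the
  rules;
* **ALD full coverage** with probability `p_ald_given_structure` (default
  0.10) when the person has any stay structure, `p_ald_baseline` otherwise
  — the lever for the A-vs-rest overlap;
* **treatment** with a probability keyed to recency: `treat_recent` for a
  recent stay, `treat_history` (0.8 — history-selected persons are by
  definition still treated) for history-only, 0.72 for ALD-only and 0.05
  background — the recency lever controls the B∩C overlap;
* an independent **bipolar flag** (0.5 %), forcing at least one exclusion
  marker (5-year F30/F31 stay and/or study-year bipolar-drug dispensing);
  since the flag is independent of everything else, bipolar persons carry
  depression-like records at the population rates, which is precisely the
  contamination the exclusion rule must remove;
* demographics, CMUC, comorbidity flags and gamma-distributed costs by
  stratum, and an **in-year death** probability of 8 % for persons whose
  only marker is a general-hospital associated diagnosis, 2.5 % for other
  selected persons, 0.9 % background — reproducing the mortality contrast
  that makes the associated-diagnosis stratum clinically distinct;
* noise that must select nobody: sub-threshold antidepressant use (1–2
  dates), non-depression ALD episodes, depression ALD episodes expired
  before the study year, somatic-only hospital stays, and
  non-antidepressant psychotropic dispensings (used only by profiling).

**Calibration** (`calibrated_params`).  Recency probabilities are set so
each sub-source's expected post-exclusion selected fraction equals the
published national count over the 58,753,200-person denominator (for the
2-year rows, the aggregate 2-year set sizes — 179,470 psychiatric and
66,595 general-principal — not the previous-year-only increments printed in
the source table).  `treat_recent` is then solved by bisection on an exact
128-cell enumeration of the latent joint distribution
(`expected_multi_source_fraction`) so the expected A/B/C multi-source
overlap is 16 %; the history-stratum masses follow from the
treated-with-history set sizes at `treat_history` = 0.8.  The solution
lands near `treat_recent` ≈ 0.27.  A consequence worth stating: the
published tables report 70–75 % antidepressant use among recently
hospitalised cohorts, which is arithmetically incompatible with
simultaneously matching the published C set sizes and overlap under a
5-year history window that includes the current year (treated∩B alone
would exceed |C|); the generator therefore matches the set sizes and the
overlap — the quantities the analysis hinges on — and lets within-B
treatment rates float low.  Cross-source joint memberships are neglected
in the closed-form part of the calibration; the exact enumeration shows
the resulting error is ≤ 0.4 % relative, far inside sampling noise at the
population sizes used.

**What passing tests do and do not show.**  The generator reproduces
marginal source sizes, the three-way overlap structure, the exclusion
contamination and the mortality contrast.  It does *not* model within-source
repeat hospitalisations, persons hospitalised in both hospital types (so
aggregate B and C unions are slightly larger, relative to the sub-source
sums, than in real data, and the full A–E union prevalence runs ~1.8 %
rather than ~1.65 %), regional structure, realistic euro distributions, or
coding error.  Tests passing on this population demonstrate the pipeline's
correctness and calibration recovery, not epidemiological validity on real
claims.

## Numerical conventions and degenerate inputs

Deterministic generation from a single `numpy` PCG64 stream per bundle;
identical seed + params give byte-identical bundles, and all pipeline
outputs are byte-stable across runs.  All selection results are invariant
under row permutation of any input table.  Empty tables, empty cohorts and
n = 0 populations are valid and produce empty/absent results rather than
errors; malformed inputs (missing files or columns, unparseable dates,
dangling foreign keys, temporal impossibilities) are reported with table
name and row index.  Counts are integers throughout; only report-time
prevalences and rates are floats.

## Problem sizes

The test suite and the acceptance script use: a hand-enumerated 10-person
fixture covering every rule branch; 1,000-person bundles (×20 seeds) for
brute-force oracle equivalence; 20,000 persons for Monte-Carlo rate checks;
100,000 persons for parameter recovery (each sub-source within 3 binomial
SEs of its calibrated expectation; overlap within 3 points of 16 %); and
50,000 persons for the mortality contrast.  These sizes keep every check
comfortably inside a binomial-noise budget appropriate to its tolerance.
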