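# Methods

This note documents the models, rules and numerical choices behind
`ehrpfs`: what each endpoint derivation assumes, what the synthetic
cohort generator emulates (and deliberately does not), and where the
design was genuinely open.

## Conventions

* **Dates** are whole calendar days; months are converted at a fixed
  30.4375 days (the mean Gregorian month), so a 404-day interval reports
  as 13.3 months. Summaries print months to one decimal; internal
  arithmetic keeps full precision.
* **PFS origin** is the last day of chemoirradiation (CRT) for every
  method, including the clinical standard. An alternative convention
  measures PFS from diagnosis; the CRT-end origin is used because all
  post-treatment filters and surveillance schedules anchor there.
* **Eligibility**: a patient enters the analysis with ≥ 1 radiology
  report, ≥ 1 prescription, ≥ 2 brain-MRI scans dated after CRT end
  (on top of the pre-CRT baseline the volumetric method needs), and a
  resolvable clinical determination (`clinical_determined`); patients
  lost to follow-up are excluded. The check is idempotent and monotone.

## Endpoint derivations

### Steroid taper

Dexamethasone is the steroid of interest; brand synonyms (Decadron, etc.)
ship as an editable set, matching is case-insensitive, and dose/route
never filter. Because steroids are routine immediately after surgery and
CRT, only orders dated ≥ CRT end + 30.4375 days (boundary inclusive) are
progression-relevant; the boundary rule is our operationalization of
"one month after", since calendar-month vs 30-day conventions differ.
All post-CRT dexamethasone is treated as one course: start = earliest
date among maximal-dose orders, end = latest date among minimal-dose
orders, ties resolved by exhaustive min/max. On a true taper the start
precedes the end by construction; if adversarial data invert the window
(largest dose ordered last), the end is clamped to the start rather than
reporting a negative-length course. The course start is the progression
date; no post-CRT course means no steroid-derived progression.

### Report NLP

The document pipeline is deterministic and rule-based, chosen for
auditability: every decision traces to a term match with its sentence
context.

* **Filtering**: document types matching configurable brain-MRI patterns
  (default: `mri.*brain` / `brain.*mri`, case-insensitive), dated
  strictly after radiotherapy end.
* **Normalization** collapses repeated whitespace and blank lines and is
  idempotent.
* **Matching**: lexicon entries are *stems* matched by prefix against
  lowercased tokens ("increas" hits increased/increasing), segmented
  into sentences at `.!?;` and newlines. The shipped lexicon is a
  reconstruction from RANO response language plus terms frequent in
  surveillance reports; it is packaged as editable YAML
  (`ehrpfs/data/default_lexicon.yaml`) and results depend directly on
  it. Bare "enhancement" is deliberately not a progression stem — it is
  not directional on its own; directional qualifiers ("increased",
  "enlarging") carry the signal.
* **Context attribution** is ConText-style: each trigger phrase has a
  declared direction (forward / backward / bidirectional) and a
  sentence-bounded scope cut at terminator tokens (but, however, …).
  The negation family is expanded with no-change phrasing ("no interval
  change"); a custom surgical family (postoperative, resection cavity,
  …) captures peri-cavity changes that usually reflect
  pseudoprogression. Scope lengths are not specified by any standard;
  sentence-bounded scope with terminators is the package's choice.
* **Re-categorization** (precedence NEGATED > HISTORICAL > SURGICAL >
  HYPOTHETICAL/FAMILY): negated or historical progression terms count as
  stability; surgical-context progression terms form their own bucket;
  purely hypothetical/familial mentions are dropped. Negated stability
  terms are dropped, not inverted — counting "no longer stable" as
  progression would encode a rule nothing supports. Historical or
  surgical stability terms still count as stability.
* **Document rule** (one-to-one weighting): progression iff unmodified
  progression mentions strictly outnumber stability mentions. On a tie
  the surgical bucket joins the stability side — surgical change is read
  as stability — so ties and empty documents resolve to no progression.
  The tie direction was an open choice; the stability reading is the
  conservative one for an endpoint that should not fire on
  post-operative change.

The first progression-positive report dates the endpoint; the evidence
payload retains every per-report assessment for review.

### Volumetry

Only contrast-enhancing (CE) tumor drives the rule; non-enhancing tumor
and edema are carried in evidence for reporting. Each post-CRT scan is
compared to the fixed post-surgery/pre-CRT baseline (earliest scan in
that window) by the ratio scan/baseline, at full floating precision, and
a ratio ≥ 1.05 — boundary inclusive — flags progression. The earliest
flagged scan dates the endpoint; later shrinkage never un-calls it. A
missing baseline, or a baseline CE volume of zero (complete resection),
makes the patient *not evaluable* for this method — distinct from
"evaluated, no progression" — because any growth ratio against a zero
baseline would be an invented number. The record schema carries CRT end
but not CRT start, so CRT end bounds the baseline window; generated
baselines always precede CRT start, making the two bounds equivalent
here.

## Comparison battery

Summaries report the percent progressed over the full cohort (integer
percent) and moments over progressed patients only. Paired differences
are method − clinical in months (negative = automated earlier), over
patients with both dates. PFS distributions are strongly right-skewed,
so tests are nonparametric:

* **Kruskal–Wallis** (tie-corrected, χ² reference, k−1 df) over the
  complete-case subset — patients dated by all four methods. An
  all-identical input short-circuits to H = 0, p = 1.
* **Wilcoxon signed-rank** per method pair on that pair's complete
  cases; zeros discarded before ranking (classic variant). W is the rank
  sum of the less frequent sign (min of the two sums on a tie). The
  two-sided p is exact by enumeration of all 2ⁿ sign patterns for
  n ≤ 12 — including tied magnitudes, which off-the-shelf exact
  implementations refuse — and a normal approximation with tie and
  continuity corrections otherwise. Bonferroni family size defaults to
  m = 6 (three methods vs clinical plus three method-method pairs),
  exposed as a flag.
* **Agreement** is the fraction of pairs within ±2 months (inclusive),
  window configurable. **Trend lines** use ordinary least squares
  (statsmodels) with R² and the F test; a constant response reports a
  flat fit (slope 0, R² 0).

## Synthetic cohort generator

The generator emulates the *observable behavior* of a surveilled GBM
cohort, not its biology. Defaults (all in `GeneratorConfig`):

| parameter | default | rationale |
| --- | --- | --- |
| `n_patients` | 92 | cohort size under study |
| `p_progression` | 91/92 | near-universal progression |
| truth PFS | lognormal, μ = ln 6.5, σ = √(2 ln(13.3/6.5)) ≈ 1.197 | hits median 6.5 and mean 13.3 months in closed form; the implied sd (≈ 23.7) overshoots a 20.9-month target — a two-parameter lognormal cannot match all three, and mean/median were prioritized |
| steroid lag | N(4.5, 8.3) months after truth, untruncated | observed taper delays include negative values down to about −6 months; truncation would bias the mean |
| report lead | N(6.9, 19.2) months before truth | textual evidence precedes the clinical declaration |
| volume lead | N(2.6, 5.8) months before truth | time at which the CE ratio crosses 1.05; growth is back-dated by t* = ln 1.05 / ln(1+g) so the crossing, not the silent growth onset, carries the configured lead |
| surveillance | gaps uniform in [2, 4] months | standard follow-up imaging cadence |
| `p_report_detect` | 0.9 | a post-onset report uses progression templates |
| taper | 8, 4, 2, 1 mg at 10-day spacing | a ~30-day taper; the spacing also guarantees that a taper beginning right at CRT end still has an order outside the 1-month filter |
| CE growth | +10%/month post-onset, noise CV 0.02, no pre-onset drift | slow enhancing growth over a flat stable period |
| `frac_volume_silent` | 0.46 | fraction of progressors whose ratio never reaches 1.05 (clamped at generation; detection rate ≈ 54%) |
| `p_steroid_missing` | 0.25 | with post-CRT filter censoring, yields ≈ 63% steroid detection |
| horizons | truth + 12 months (progressors), 36 months (non-progressors) | guarantees ≥ 2 post-CRT scans and post-truth surveillance |

Report text is template-built exclusively from the shipped lexicon's
stems plus neutral filler, each sentence annotated with the counts the
pipeline assigns it, so gold labels are exact by construction and never
re-derived. Prescriptions include a routine post-surgical dexamethasone
course (exercising the 1-month filter) and non-steroid distractors.
`GeneratorConfig.perfect_information()` is the idealized preset — certain
detection, zero lags/leads and noise, no silent fraction, and growth
fast enough (doubling monthly) that the first post-truth scan crosses
the threshold — under which every method should date every progressor
within one surveillance interval of truth.

What the generator does **not** model: realistic clinical prose (only
template sentences), pseudoprogression dynamics beyond surgical-context
sentences, repeat steroid courses, scan quality failures, or any
correlation between modality noise terms. Passing tests therefore
demonstrate that the rules behave as specified and recover known
structure — not that they would achieve any particular accuracy on real
reports, where lexicon coverage dominates. No distributional form here
is taken from the study being emulated, which reports only summary
statistics; all distributions are stand-ins.

## Numerical and testing choices

* Cohort files round-trip bit-exactly: floats are written with `%.17g`
  and parsed with round-trip precision.
* Exact Wilcoxon enumeration is capped at n = 12 (4096 sign patterns);
  beyond that the corrected normal approximation is standard.
* The steroid-lag *recovery* experiment fixes truth PFS at 12 months so
  the 1-month post-CRT filter does not censor the lag distribution;
  under short-PFS conditions the filter induces a positive selection
  bias in the measured mean lag (the estimator sees only courses it can
  keep), which is a property of the method, not an estimation error.
* Generator calibration tests check mean and median on the natural scale
  (10%) and spread on the log scale: for σ ≈ 1.2 the natural-scale sd
  estimator has ≈ 12% relative standard error at n = 5000, making it
  useless as a calibration check at that tolerance.
* Stochastic sign-reproduction checks run at n = 600 patients, where the
  standard error of the volumetric mean difference (the smallest effect,
  ≈ −0.7 months after surveillance discretization erodes the configured
  2.6-month lead) is small enough for the sign to be stable.

## Known limitations

* The lexicon is a reconstruction; real-site deployment requires
  reviewing it against local report language.
* The volumetric method compares to a single fixed baseline; RANO-style
  nadir-referenced or bidimensional measurements are out of scope.
* A single steroid taper course per patient is assumed; multi-course
  segmentation is not attempted.
* No multi-modal fusion: each endpoint is single-stream by design.
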