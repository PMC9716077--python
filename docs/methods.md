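# Methods

## Counting model

The unit of analysis is one individual safety report (ISR).  A *case* may
appear as several report versions; deduplication keeps, per case, the
report with the highest version, breaking ties by latest receipt quarter
and then by lexicographically largest report id.  This rule is the
package's own choice of a deterministic analogue of the duplicate
detection that pharmacovigilance front-ends apply; it is idempotent and
order-independent.

A report belongs to a drug's cohort iff the drug (after lexicon
normalization of brand/generic spellings) appears among its
*primary-suspect* entries.  A report may name several primary suspects and
then contributes to each cohort.  Event occurrence is judged on the full
reaction list regardless of which drug a term was attributed to — FAERS
does not link reactions to drugs — and a term repeated within one report
counts once.  The background of every 2×2 table is all deduplicated
reports whose primary suspects do not include the target drug; comparator
drugs stay in the background unless the caller removes them.  The grand
total C is therefore the deduplicated report count of whatever database
was loaded.

Time is modelled at calendar-quarter resolution (`YYYYQn`), the native
granularity of quarterly FAERS extracts; finer dates are out of the data
model.

## Disproportionality statistics

ROR = ad/bc with the Wald interval exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
z = 1.96 by default and configurable.  No continuity correction is applied
to zero cells: the ROR is reported as undefined there, and the a ≥ 3
report-count gate governs sparse pairs.

The BCPNN information component uses the standard closed forms for E(IC),
V(IC) and the joint-cell prior scale γ (base-2 logarithm, so units are
bits), with default priors α₁ = β₁ = γ₁₁ = 1, α = β = 2.  These priors make
E(IC) ≈ 0 at independence and keep every statistic finite for any
non-negative table, including a = 0.  IC−2SD = E(IC) − 2√V(IC) is the
lower credibility bound; IC+2SD is also computed to support band plots.

Signal rules: ROR-positive ⇔ a ≥ 3 ∧ CI lower bound > 1; BCPNN-positive ⇔
a ≥ 3 ∧ IC−2SD > 0; *suspicious* ⇔ both; *medium-strong* ⇔ additionally
IC−2SD ≥ 1.5.  The strength tier is only assigned to BCPNN-positive pairs:
a pair below the report-count gate is tier "none" however large its IC,
keeping the tier consistent with the signal decision.  All thresholds are
configurable (`SignalThresholds`).  No multiple-comparison adjustment is
applied; the dual-algorithm requirement and the strength cut are the only
false-positive controls, which mirrors standard practice and is stated
rather than silently changed.

Display rounding is half-up to 2 decimals (matching how such tables are
printed); full precision is retained internally and in JSON outputs.

## Recovering tables from printed marginals

Published signal tables print a and the ROR but not the background cell c.
Given the cohort total Cx and grand total C, ROR(c) = a(C−Cx−c)/((Cx−a)c)
is strictly decreasing in c, so the set of integers c whose exact ROR
rounds (half-up) to the printed value is a contiguous interval; the
implementation inverts the rounding bounds analytically and scans only
that interval, returning the candidate with minimal |exact − printed|
(ties toward smaller c) plus a flag when the rounding-consistent set has
more than one member.  At full-precision ROR input the recovery is exact
(`recover ∘ summarize = identity`).  If no c is rounding-consistent the
marginals are declared inconsistent — a hard error, never a nearest guess.

## Time scan

The IC series for a pair accumulates by quarter: the point at quarter q is
the BCPNN result on the table built from all reports received up to and
including q, background cells included, so early points reflect the
database as of that quarter.  The band is IC ± 2SD (≈95.4% under the
normal approximation) — the same machinery as the IC−2SD criterion rather
than a separate 1.96 band; the multiplier follows the priors'
variance expression and is not separately configurable.  By default the
series starts at the first quarter containing any target-drug report and
ends at the last quarter present in the data.  Quarters with cumulative
a = 0 are emitted (finite, shrinkage-dominated IC) and flagged.

## Descriptives

Cohort summaries count deduplicated primary-suspect reports — the
denominator is stated explicitly because "number of events" in published
tables is ambiguous between reports and report×term pairs; both counts are
available (`len(cohort)` vs summing per-event a's).  Age bands are
closed-open: <18, 18–49, 50–79, ≥80, plus unknown.  Sex, age and country
blocks each sum to the cohort size.  Serious-outcome codes are not
mutually exclusive: a report counts once per code in the per-code rows but
once overall in the serious total ("other" is not a serious code).
Unknown sex/age/country are first-class categories and never imputed.

## Synthetic-report generator

Reports are independent draws.  Each report gets one cohort label (a
target drug with its configured fraction, else the pooled background, in
which case a background drug name is drawn); each monitored event is then
sampled with a cohort-conditional probability.  For a planted
(drug, event, ψ) triple the joint-cell probability p₁₁ is the Plackett
root of (ψ−1)p₁₁² − [(ψ−1)(pₓ+p_y)+1]p₁₁ + ψpₓp_y = 0 in
[max(0, pₓ+p_y−1), min(pₓ, p_y)], giving conditional rates p₁₁/pₓ inside
the cohort and (p_y−p₁₁)/(1−pₓ) outside — so the population odds ratio
equals ψ exactly.  One planted signal per event is allowed; a second would
change the complement pool and break exactness, so it is rejected at
validation, as are degenerate margins (cohort fraction or event rate of 0
or 1).

Extra reaction terms (multi-PT reports) and the guaranteed-non-empty
filler term are drawn from a separate background-term pool, not from the
monitored events, so planting stays exact.  Duplicate case versions are
injected at a configurable rate (1–3 earlier versions with identical
content); deduplication must recover exactly the final versions.
Demographics (sex, age band with uniform age within band, serious
outcomes, country, receipt quarter) are drawn independently of signal
status; their defaults imitate a large post-marketing ophthalmology
cohort: female-majority sex split, mass concentrated in the 50–79 and ≥80
age bands with a large unknown fraction, USA-dominant reporter countries,
and roughly 45% of reports carrying at least one serious outcome.

What the generator does *not* emulate: reporting waves after label
changes, masking/competition between signals, drug–PT attribution
structure, missing-not-at-random demographics, or correlated events within
a report beyond the shared cohort label.  Green tests therefore validate
the estimators and the pipeline mechanics under a clean independence
model, not robustness to real-world reporting artifacts.

`realize_table` is the deterministic complement: it materializes any 2×2
table as exactly a+b+c+d single-term reports, so a published table becomes
an executable fixture (`build_table ∘ realize_table = identity`).

## Problem sizes and numerical checks

The test suite validates the statistics against independent
re-implementations (exact rational arithmetic for the ROR, 50-digit
decimal arithmetic for the interval and the BCPNN moments) on 1,000 random
tables to ≥10 significant digits.  Monte-Carlo calibration uses 200
replicate streams of 100,000 reports per planted odds ratio ψ ∈ {1, 5, 20}
(cohort fraction 0.05, event rate 0.01 — a mid-sized drug and an uncommon
event): the mean log-ROR must sit within 3 Monte-Carlo standard errors of
log ψ, and under ψ = 1 the one-sided Wald criterion may fire in at most
2.5% of pairs plus 3·MCSE.  Round-trip and invariance properties
(dedup idempotence, table round-trips, time-scan prefix consistency) run
on streams of 2,000–8,000 reports.  The full-scale published tables
(C ≈ 10.6M) are exercised directly at the table level via marginal
recovery; materializing them as reports is reserved for the
thousandfold-scaled variant, which keeps the default suite fast without
changing what is being verified.

## Interfaces

Two ingestion dialects (one-file TSV; four-file DEMO/DRUG/REAC/OUTC-style
directory joined on the report key) with symmetric writers; row-level
malformations are counted and reported, never silently dropped, while a
missing mandatory column is a hard error.  The SMQ map and exclusion list
are plain TSVs; the package bundles only a small illustrative anti-VEGF
lexicon (generic + brand names) as a default, and the indication-exclusion
list ships as a user-editable mechanism because no authoritative list of
disease-related terms is bundled.  A term mapped to both an excluded and a
retained SMQ is retained — exclusion must be total — the conservative
choice that keeps borderline signals visible.  SMQ-level outputs count a
report once per group (union, not sum) to avoid inflating a.  The CLI is a
thin click layer; JSON run configs, TSV/JSON outputs, exit codes 0/2/3
(success/validation error/data error), and a run manifest with config hash
and package version.
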