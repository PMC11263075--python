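# Methods

## Data model

The unit of analysis is the individual case safety report: one
primary-suspect (PS) drug, optional concomitant drug entries, one or
more reaction preferred terms (PTs), demographic fields with
missingness, and a receipt quarter. On disk a dataset is a flat CSV with
one row per report × drug × PT
(`report_id,drug,role,pt,age,sex,country,quarter,indication,outcome,daily_dose_mg`);
in memory a pandas frame, convertible to/from `AEReport` objects.
Rows sharing `report_id,drug,role,pt` are collapsed before counting
(last wins, logged), and every count is report-level: a report
contributes at most once to any 2×2 cell regardless of how many
qualifying PTs or drug rows it carries. Only the PS role counts as
exposure; suspect roles SS/C/I are deliberately ignored, and the
synthetic generator plants concomitant decoys to exercise that filter.

## Vocabulary

A termset maps PT → HLGT, PT → symptom subgroup (hypersexuality,
hyposexuality, erectile dysfunction, ejaculatory dysfunction, or none)
and flags impulse-control-disorder (ICD) related PTs (compulsive sexual
behavior, hypersexuality, excessive masturbation, libido increased).
The SD event set is structural: all PTs whose HLGT is "sexual function
and fertility disorders" or "sexual dysfunctions, disturbances and
gender identity disorders". PT matching is case-insensitive after
whitespace normalization, since report sources are inconsistent across
eras. The shipped default termset contains the fourteen PTs named in
the study literature; it is an approximation of the full licensed MedDRA
HLGT membership, so analyses accept any substitute termset with the same
four columns. Subgroup placements without an authoritative source are
package choices: priapism under erectile dysfunction (an erection
disorder), anorgasmia under none (an orgasm disorder outside the four
subgroups).

## Estimators

**ROR.** `(a·d)/(b·c)` with Woolf interval on the log scale
(z = 1.959963984540054). Zero cells leave the estimate NaN rather than
applying a Haldane correction: the inclusion filter (below) removes
small-`a` pairs anyway, and silent corrections would distort the
per-drug medians. Signal flag: lower bound > 1.

**IC.** The observed/expected shrinkage form
`IC = log₂((a+0.5)/(E+0.5))` with `E=(a+b)(a+c)/n` and
`IC₀₂₅ = IC − 3.3(a+0.5)^{−1/2} − 2.0(a+0.5)^{−3/2}`. This is the
contemporary standard implementation of the information-component
method; the original BCPNN beta-binomial posterior is a documented
alternative not implemented here. Signal flag: IC₀₂₅ > 0.

**Inclusion.** A pair is included iff its case count exceeds 3
(`a ≥ 4`, strict reading of "greater than 3"). The per-drug median ROR
is taken over all included PT-level estimates (even count → midpoint);
a `median_over="significant"` switch restricts to ROR signals instead,
since either convention is defensible.

## Occupancy

`occupancy% = 100·C_U/(Ki + C_U)`, `C_U[nM] = 1000·F_U·C_T/MW`. C_T is
the upper bound of the recommended therapeutic range in ng/mL — the only
unit under which the conversion lands in nmol/L, and the unit in which
therapeutic-drug-monitoring ranges are published. Multiple Ki rows per
drug × receptor collapse by geometric mean (Ki spans orders of
magnitude). Muscarinic and α receptors are treated as single
pseudo-receptors irrespective of subtype. pKi is the standard molar
convention `9 − log₁₀(Ki[nM])`; since OLS p and R² are invariant to
affine transforms of the predictor, any alternative log convention
changes only the sign/scale of β. The signed predictor negates
occupancy for antagonists and inverse agonists and is missing when the
activity is unknown (such drugs drop out of the signed modes only).
The shipped pharmacology table is synthetic (plausible magnitudes,
labelled as such); real Ki/F_U/C_T/MW curation is the user's input.

## Regression

Per receptor, univariate OLS of per-drug median ROR on the predictor,
fitted via `scipy.stats.linregress` behind the `fit_univariate`
surface; p is the two-sided slope t-test with n−2 df and R² the squared
Pearson correlation (R² of a constant response is defined as 0).
Receptors need ≥ 3 drug points after pairwise dropping of missing
predictors or medians. No multiplicity correction is applied — the
per-receptor p-values are reported raw, as is conventional for this
design. Iloperidone is excluded from the regression stage by default
(sparse reporting makes its median unstable); the exclusion list is a
config knob. Median RORs are not log-transformed by default.

## Synthetic generator

Given the PS drug (and quarter), each configured PT enters a report
independently with probability `p_pt · ρ(drug, pt)` clipped at 1;
ρ = 1 means independence. An optional warning surge multiplies ICD-PT
probabilities after a cut quarter (default 2016Q2), optionally for a
subset of drugs, emulating notoriety bias. Conditional independence
makes the population ROR of every pair available by exact enumeration
over the drug × quarter mixture (`expected_ror`), and
`rho_for_target_ror` inverts it so tests can plant an exact truth.
A report that samples no PT receives the reserved background term
"drug ineffective", keeping reaction lists non-empty without touching
any configured PT's marginal (the reserved name cannot be configured).
Demographics (sex, age band, country, indication, outcome, dose
missingness) are independent categorical draws that mirror the broad
structure of published antipsychotic SD report cohorts: mostly male,
~46% missing age, ~76% missing dose. Quarters are uniform on
2004Q1–2023Q3.

Default study conditions (`default_study_config`): 150,000 reports;
twelve antipsychotics totalling ~11.7% of primary suspects against a
dominant "other" background; rare SD PT backgrounds (2×10⁻⁴–4×10⁻³)
padded by common non-SD PTs; 31 planted multipliers reproducing the
class's qualitative structure (strong hypersexuality/ICD reporting for
the D2 partial agonist, ejaculatory signals for strong α1 antagonists);
surge ×3 on ICD PTs after 2016Q2.

What the generator does **not** emulate — duplicate and versioned
reports, free-text drug-name noise, secular reporting trends,
correlated reactions within a report, dose–response — bounds what
passing tests show: they validate the estimators, filters and
orchestration against a known truth, not robustness to real FAERS
artefacts.

## Sensitivity analyses

Window split: the month-bounded study windows are quarter-rounded
inward to pre = 2004Q1–2015Q1 and post = 2016Q3–2023Q3; the straddling
2015Q2–2016Q2 gap belongs to neither window. Each window is analysed
in isolation with its own comparator background, at the drug level over
the pooled SD event set. Rare-PT rule: a PT survives iff mentioned in
≥ 500 distinct reports dataset-wide (any drug, any role; "fewer than"
strict). The 500-report threshold is calibrated to multi-million-report
databases; at the default synthetic scale of 150,000 reports only the
commonest SD PTs survive it, which the outputs show honestly.

## Numerical and testing choices

Determinism: one `numpy` Generator seeded from the config; identical
config + seed gives byte-identical CSVs (floats written with `%.10g`).
Statistical tests fix their seeds and tolerance bands follow the exact
sampling theory: Woolf-CI coverage of a planted ROR of 10 at 100,000
reports is checked over 200 seeded datasets against a 95% ± 3% band;
the null false-signal rate over included pairs is bounded at 7.5%
(nominal 2.5% one-sided plus selection by the count filter — observed
≈ 2.5–3%); slope recovery uses the planted noise sd (σ = 1), so the
slope estimator's exact sampling SE σ/√Sxx defines the 2·SE event
(probability 95.45%) rather than a residual-estimated SE whose t₉
coverage (92.3%) would make a ≥ 90/100 bound fragile. The acceptance
script uses 100 seeds for coverage and 50 for null calibration to keep
its runtime near one minute; the test suite uses 200/100.

## Known limitations

Single-source field collapse (one Ki per drug × receptor), no
stratified or EBGM-style estimators, no duplicate detection beyond
`report_id`, no PK modelling (the active-metabolite contribution of,
e.g., partial agonists' metabolites is ignored), and the shipped
termset/pharmacology tables are stand-ins for licensed or curated data.
Quarter resolution makes the warning windows approximate to within one
quarter of the study's month boundaries.
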