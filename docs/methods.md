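# Methods

## The estimation problem

`pssnet` studies how adoption of a new prescribing practice — prescribed
safer supply (PSS) — diffuses through a patient-sharing network of
prescribers. The data model is record-level administrative claims: drug
dispensations (with free-text directions-for-use), outpatient and
acute-care visits with diagnostic codes, and prescriber/client attribute
tables. The analysis proceeds in stages; each stage is a pure function of
the record tables so every derived quantity can be recomputed and audited.

**Cohort.** A client has a substance use disorder (SUD) if any pathway
qualifies them: receipt of opioid agonist treatment, three outpatient
visits on *distinct dates* with an SUD diagnostic code, one acute-care
visit with such a code, or an SUD-indicating perinatal record. The first
indication date is the earliest date on which any pathway's condition is
met — for the visit-count rule, the date of the qualifying third distinct
visit — evaluated over all historical records (visits on the same date
count once; whether they involve distinct prescribers is irrelevant). A
prescriber enters the cohort if they have at least one dispensation inside
the study window (2020-03-27 to 2021-08-31 by default) to a client whose
first indication *strictly* precedes that dispensation; a same-day
indication does not qualify ("prior" is resolved conservatively).

**PSS case finding.** PSS dispensations carry no dedicated drug
identifiers, so they are recognized by case-insensitive keyword patterns
over the directions text, restricted to an eligible medication-class set
(opioids, stimulants, benzodiazepines). Two tiers exist: *sensitive*
(default) and *specific*, whose patterns and classes are constrained at
configuration-validation time to be subsets of the sensitive tier — hence
the specific positive set is contained in the sensitive one on any input.
The shipped lexicon is a documented, editable default (the structure of the
algorithm is fixed; its lexicon is deployment-specific). Records with null
directions are negative and tallied in the log, not errors.

**Adoption status.** A prescriber's first PSS dispensation dates them:
initiation inside the innovation window (2020-03-27 to 2020-04-30 by
default) makes an *innovator*, any later initiation an *early adopter*,
none a *non-adopter*. The three statuses partition the cohort.

**Networks and exposure.** For measurement month *m*, dispensation records
in the accumulation window are projected from the bipartite client ×
prescriber incidence onto prescribers: an edge joins two cohort prescribers
sharing ≥1 client, weighted by the count of distinct shared clients. The
default accumulation window is cumulative from the study start through the
end of *m*; a trailing-k-month window is available. Cumulative accumulation
makes edge sets monotone over months and represents the stable professional
network through which influence plausibly travels; the monthly update then
comes from the adopter set, which is *ever adopted by the end of m−1* (not
"actively prescribing in m−1"). Exposure variants: unweighted (share of
adopter neighbours), weighted (share of incident edge weight attached to
adopter neighbours), and two-step (share of adopters within the ≤2-step
neighbourhood, a supplementary regressor). Isolated nodes have exposure 0.
Categories are closed on the right — none (exactly 0), (0, 0.10],
(0.10, 0.20], (0.20, 1] — matching the printed labels "10% or less" and
"> 10 to 20%". The >20% top category corresponds to the upper quartile of
the exposure distribution observed in the emulated setting; the boundaries
are fixed constants in replication mode, while quartile bins for the
prescriber-level covariates can be recomputed empirically (below).

**Node covariates.** Clustering coefficient is the per-node fraction of
neighbour pairs that are themselves connected (0 when degree < 2); degree
centrality is degree/(N−1) over the N cohort nodes. Adjusted strength is
defined on *clients*, not on the projected graph: the mean, over a
prescriber's clients in the window, of the number of other prescribers each
client received dispensations from.

**Panels.** One row per prescriber-month. The adoption panel runs from
2020-05 (so that the first lagged measurement month is 2020-04) to the
study end over prescribers with no PSS dispensation before the row's month,
plus the initiation-month row (outcome 1); innovators initiate before the
panel starts and contribute no rows, which is precisely the point — the
panel isolates prescribers who could have been subject to peer influence.
The discontinuation panel runs from 2020-07 over initiators, from the month
after initiation until the event or study end. The event is the *first*
month of a gap of ≥3 consecutive months with no PSS dispensation; the whole
gap must be observable inside the study window, so a prescriber who stops
with fewer than 3 observable months remaining is censored (outcome-0 rows
to the study end). A re-initiation after a confirmed discontinuation does
not re-enter either panel. Every time-varying regressor in a month-*m* row
(exposure, clustering, adjusted strength, caseload, case-mix aggregates) is
computed from records dated ≤ end of month m−1; the test suite enforces
this by recomputing covariates from data truncated at m−1.

**Covariates.** Monthly SUD caseload is the count of distinct clients with
a dispensation from the prescriber in the (lagged) calendar month — the
"past 30 days" reading consistent with monthly binning. Experience is years
since the prescriber's first SUD-related billing record, measured at the
lag month. Both are categorized into quartiles: in `empirical` mode (the
default) cut points are the quartiles of the panel-entry distribution,
computed once, not re-quantiled monthly; `printed` mode uses the fixed
replication cut points (adoption: caseload ≤2 / 3–6 / 7–13 / ≥14,
experience <4.5 / 4.5–10.9 / 10.9–22.4 / ≥22.4 years; discontinuation:
caseload ≤18 / 19–43 / 44–85 / ≥86 — resolving the overlapping printed
labels in favour of ≤18 and 19–43 — and experience <4 / 4–8.3 / 8.3–17.4 /
≥17.4). Integer-valued caseload bins close on the right (x ≤ cut);
continuous experience bins close on the left (x < cut), matching the
printed interval notation. Case-mix aggregates are percentages over the lag
month's caseload clients (age ≥40, comorbidity index >1, ≥1
benzodiazepine dispensation in the trailing 12 months, any social
assistance, overdose in the trailing 12 months) plus a flag for ever having
treated a client with a COVID-19 diagnosis by the lag month's end. An empty
monthly caseload yields 0 for every percentage and a 0 flag — a stated
convention that keeps those rows estimable rather than missing.

**Sensitivity variants.** Every robustness analysis is a configuration
switch, not a code fork: the mid-month binning scheme, the trailing-window
network accumulation, the weighted and two-step exposure variants, a later
panel start (longer innovation period), minimum monthly client-load
inclusion thresholds, the specific case-finding tier, and medication-class
subgroups. The subgroup switch restricts both the outcome and the adopter
set to the chosen classes — peers count as adopters once they have
prescribed that medication type — so the subgroup question stays symmetric.
The optional rolling window for the 3-visit rule requires the qualifying
visits to fall within a configurable number of days instead of the default
lifetime lookback.

**Month binning.** All dates are binned with one pipeline-wide function:
`calendar` (default) or `mid-month`, where a measurement month runs from
the 16th to the 15th and is labelled by the month in which it ends (a
record dated on/after the 16th moves to the next label). The switch
propagates through case finding, networks, panels and reports.

**Estimation.** The mean model is logistic in the panel terms with
categorical reference levels: exposure "none", region "Interior", specialty
"general practice", lowest experience and caseload quartiles. Estimation is
by generalized estimating equations clustered on prescriber with
sandwich-robust standard errors, so point estimates are consistent under
working-correlation misspecification. The requested working correlation is
unstructured (matching the repeated monthly measurements); with 16+
occasions and severely unbalanced cluster lengths its estimation often
degenerates, so the fitter falls back unstructured → exchangeable →
independence, treating a fit as degenerate when any parameter is
non-finite, |β̂| > 30, or a robust SE is non-positive; the structure used
and the recorded fallbacks are part of the result metadata. CIs use the
fixed normal multiplier 1.96; no multiple-testing adjustment is applied.
Constant outcomes, constant design columns and quasi-separated categorical
levels (a level whose rows are all events) raise errors naming the term.

As an advisory diagnostic, `glmm_variance_check` fits the random-intercept
logistic companion by direct maximum likelihood with 25-node Gauss-Hermite
quadrature (σ bounded at 0; all-singleton clusters reported as
unidentifiable). No pre-installed Python package fits this frequentist
GLMM, so the quadrature is implemented here on scipy primitives; it exists
to let an analyst verify the between-cluster variance that motivates
choosing GEE over a mixed model.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults chosen as the bundled study conditions:

- **Population**: 500 prescribers, 2,000 clients, 5 regions with unequal
  weights plus a small unknown-region fraction (3.5%); specialty mix
  dominated by general practice (56%); prescriber first-SUD-billing dates
  uniform over 1996 to the study start. Every client is an SUD-care client
  (the client universe in this design *is* the SUD caseload), with a
  qualifying pathway (OAT 28%, outpatient visits 47%, acute care 20%,
  perinatal 5%) and an indication date that is pre-study 97% of the time —
  the residual during-study indications exercise the prior-indication
  eligibility rule.
- **Affiliation**: each client draws 1 + Poisson(sharing_rate − 1)
  distinct prescribers (default sharing_rate 2.0, i.e. one additional
  prescriber per client on average, the magnitude observed in the emulated
  setting), within their own region except with mixing probability 0.10,
  with selection weights lognormal(0, σ=1.0) — the heavy-tailed caseloads
  that give realistic exposure heterogeneity. Each attachment emits a
  dispensation per month with probability 0.35 (at least one overall).
- **Diffusion**: 10 innovator seeds (drawn with caseload-proportional
  probability, mirroring the high-caseload profile of real innovators)
  adopt in months 1–2. From month 3, each non-adopter's monthly adoption
  indicator is Bernoulli with logit −5.0 + log(3.79)·exposure +
  0.4·caseload_z, where exposure is the lagged unweighted peer-exposure
  proportion computed *with the analysis modules themselves* on the records
  emitted so far, and caseload_z is standardized log(1 + cumulative distinct
  clients). Adopters discontinue with logit −2.2 − 1.2·exposure; after the
  event no further PSS is emitted, making the ledger's event month exactly
  the analysis's first-gap month. Adopted prescriber-months emit PSS
  dispensations whose directions carry a planted keyword (70% matching the
  specific tier, the rest only the sensitive tier). The intercepts yield
  roughly 10–15% cumulative adoption over 18 months, the order of magnitude
  of the emulated rollout.
- **Reproducibility**: one RNG stream per stage (population, affiliation,
  diffusion), spawned from the master seed; identical seeds give
  byte-identical tables. The truth ledger records the coefficients, seed
  ids, event months, the planted PSS dispensation ids, and the hazard
  trace — the exact (exposure, caseload_z) pairs each adoption draw used —
  which the tests compare 1:1 against the assembled panel.

Because exposure and (up to an affine transform) caseload_z in the panel
are exactly the generator's hazard inputs, the planted log-odds are the
estimands of the panel regression, and the recovery experiment is a clean
consistency check of the whole pipeline rather than of the generator alone.

**What the generator does not emulate**: client-level outcomes, COVID-19
epidemiology, seasonal or secular prescribing trends, record linkage noise,
co-signed prescriptions, region-differential adoption propensity, and any
calibration to the real population beyond the marginal shapes above. The
emulated study is also two orders of magnitude smaller than the real one
(500 vs ~14,000 prescribers). Passing tests therefore demonstrate the
*operations* are correct and the *estimator* recovers known diffusion
parameters under the stated mechanism — not that real-world confounding,
misclassification or linkage artifacts are absent.

## Simulation experiments and problem sizes

The recovery experiment fits, per replicate, the correctly specified
adoption model — continuous lagged exposure plus caseload_z — with the
independence working structure. The adoption outcome is an event history
(each row is Bernoulli given the past and prescribers exit at the event),
for which pooled logistic with cluster-robust errors is the standard
consistent GEE; non-diagonal working correlations are not generally
consistent for such dynamic models, so independence is the right choice for
this experiment even though the replication model default is unstructured.
The type-I experiment plants a zero exposure effect and fits the
categorical-exposure model, checking that each category's 95% CI covers the
null.

Problem sizes: the acceptance tests use 50 replicates of 500 prescribers ×
18 months for both experiments; the acceptance script defaults to 25
replicates per experiment (`--replicates` raises it), 100 random graphs of
up to 100 nodes for the brute-force oracle sweep, and the default
conditions for the single descriptive end-to-end run. These sizes give
Monte-Carlo standard errors around 0.06–0.08 on the recovered log-odds,
small against the planted log(3.79) ≈ 1.33.

## Numerical and formatting choices

- Exposure-category boundaries compare float ratios against the 0.10/0.20
  literals directly; ratios like 1/10 are the same double as the literal,
  so no epsilon is needed.
- Empirical quartile cuts use linear-interpolation quantiles; on heavily
  tied data cut points are nudged by ≤3e-9 to stay strictly increasing.
- Percentages and medians render half-up to one decimal (Decimal
  arithmetic, not banker's rounding).
- Small-cell suppression: counts 1–9 render as "<10"; zero cells are shown
  (an absent category is not a disclosure); when exactly one cell of a
  variable-stratum group is masked, the smallest remaining nonzero cell is
  secondarily masked as "<=10" so the hidden count cannot be recovered from
  a printed group total. Suppression operates on counts after all
  aggregation and is idempotent.
- Top-quantile edge pruning keeps an edge when its weight is ≥ the
  ceil(q·degree)-th largest incident weight for *both* endpoints; ties at
  the boundary are retained (uniform-weight graphs keep every edge).
- Empty record sets produce empty graphs, empty flag tables and empty
  series — never errors; invalid configuration (non-normalized probability
  vectors, unknown variants/windows/schemes, inverted windows) raises
  `ConfigurationError` eagerly.

## Known limitations

- The GLMM diagnostic uses non-adaptive quadrature and Nelder-Mead; it is
  sized for advisory use on panels of a few thousand rows, not for
  production mixed-model inference.
- The unstructured working correlation rarely survives the default
  18-month unbalanced design; results are then exchangeable or
  independence fits (always recorded). This affects efficiency, not
  consistency.
- The case-finding lexicon ships as a default; real deployments must
  supply the jurisdiction's own keyword tables, and the sensitivity /
  specificity of the classification is entirely lexicon-dependent.
- The two "stopped prescribing" descriptive conventions (lapsed at end of
  follow-up vs confirmed 3-month discontinuation) are both computed but are
  different quantities; reports label them separately and make no attempt
  to reconcile them.
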