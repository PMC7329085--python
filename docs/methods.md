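# Methods

This note documents the model implemented in `lynchcea`: its structure,
assumptions, parameter handling, numerical conventions and limitations.

## Decision problem

An annual national cohort of newly diagnosed colorectal cancer (CRC)
patients (default 49,000, with a consent rate of 84.8 %) is screened for
Lynch syndrome (LS), present in 2.81 % of probands. Identifying a proband's
pathogenic MMR variant unlocks cascade predictive testing of first-degree
relatives (FDRs); carrier relatives who are found enter an intensive
prevention programme, carriers who are not found follow standard relative
surveillance. The decision-relevant output is the lifetime difference in
discounted costs and QALYs across the carrier-relative population, plus the
one-time screening and cascade costs, expressed as ICERs between strategies.

## Diagnostic decision trees

Strategies are evaluated by exact expectation propagation: every
root-to-leaf path of a tree carries a probability weight, and test volumes,
costs and detections are weight sums over paths. Fractional persons are kept
throughout; reported case counts are rounded down only at presentation.
Tree-specific conventions:

* IHC routing is gene-resolved. LS tumors present the absent-protein
  pattern of their causal gene (composition configurable); only MLH1-absent
  tumors are triaged by methylation-specific MLPA. Hereditary MLH1 tumors
  are unmethylated, so the MLPA *specificity* governs whether they proceed
  to sequencing; sporadic MLH1-methylated tumors (10 % of sporadics) are
  dismissed when MLPA finds the methylation.
* IHC false positives among MMR-proficient sporadic tumors present a
  staining pattern drawn from the same gene composition; the MLH1-pattern
  fraction passes through MLPA before (uselessly) being sequenced. All
  sequencing of non-carriers is costed: imperfect specificity must cost
  money.
* In the age-targeted strategy, probands under 70 skip the Bethesda gate
  entirely; LS prevalence is assumed independent of the age split.
* The relatives' predictive test is perfect (sensitivity = specificity = 1),
  so no false-reassurance branch exists downstream of the cascade.

A path-independent Monte-Carlo simulation of individual probands through the
same decision rules serves as an oracle in the test suite.

## Cascade

Detected probands × mean FDR count (default 3) × relative uptake (38.9 %)
gives tested relatives; half carry the familial variant. The carrier pool —
all carriers among FDRs of *all* LS probands in the incidence year — is an
epidemiological constant, so `carriers_detected + carriers_undetected` is
invariant across strategies; strategies only move carriers between the
detected (surveilled) and undetected (unsurveilled) arms.

## Markov cohort model

34 states: well; CRC in 4 stages × 5 tunnel years; endometrial cancer (EC)
in 5 tunnel years; second cancer in 5 tunnel years; alive-after-first-cancer;
alive-after-second-cancer; death. One-year cycles from the entry age
(default 25) to the horizon (default age 100).

* **Incidence.** Cumulative risks to age 70 (CRC 38 % male / 31 % female,
  EC 35 %) are converted to constant annual probabilities p = 1 − (1 −
  R)^(1/w) over the risk window (25–70) and are zero outside it. Aspirin
  multiplies CRC incidence by a relative risk (default 0.65) in the
  adherent surveilled stratum. Prophylactic surgery (accepted by 19 % of
  surveilled women) zeroes EC incidence from the surgery age.
* **Competing events** within a cycle are applied in a fixed order —
  background death, then CRC, then EC — which keeps rows exactly
  stochastic; the ordering bias at annual probabilities of this magnitude
  is far below parameter uncertainty.
* **Cancer survival.** Stage-specific CRC and time-since-diagnosis-specific
  EC death probabilities act only during the 5 tunnel years, combined
  independently with background mortality. Fifth-year survivors are cured:
  they carry background mortality only and a utility of 0.95. A second
  cancer (single rate, at most one) is reachable from a tunnel exit or from
  the alive-after-first-cancer state.
* **Stage distributions.** The surveilled distribution
  (69.4/25.0/5.6/0.04 %) is renormalised because the printed values total
  100.04 %; the plausible reading that the last entry is 0.0 % can be set
  in the configuration. Non-adherent members of the surveilled arm (20 %)
  keep the unsurveilled stage distribution, lose the aspirin effect and
  accrue no prevention costs.
* **Background mortality** is a two-parameter Gompertz hazard
  a·e^{b·age} per sex, calibrated to the order of magnitude of contemporary
  Italian all-cause mortality (q ≈ 2 % for a 70-year-old man). A life-table
  override (annual death probability by age and sex) is accepted in the
  configuration.
* **Rewards.** Costs and utilities accrue on the post-transition occupancy
  of each cycle and cycle t is discounted by (1 + r)^−t, r = 3.5 %. No
  half-cycle correction is applied by default (the convention of simple
  spreadsheet cohort models); it can be switched on, in which case rewards
  accrue on the average of pre- and post-transition occupancy. Scheduled
  interventions are costed as expected cost per cycle (unit cost divided by
  the interval) rather than parity-gated charges, avoiding 2-year/5-year
  phase artifacts on the annual grid; prophylactic surgery is a one-off
  charge in the cycle reaching the surgery age.

Arm outcomes are sex- and behaviour-weighted averages over seven strata
(sex × adherence × surgery acceptance in the surveilled arm; sex in the
unsurveilled arm). Strategy totals are
`screening + cascade + detected·C_surv + undetected·C_unsurv` (QALYs
analogously), i.e. per-carrier outcomes scale linearly with the carrier
counts of the cascade — the scaling convention is explicit because the
original study does not state its own.

## Parameters and provenance

Every input carries a provenance tag. `printed` values are fixed by the
main text of the underlying study. `supplementary_placeholder` values were
only published in supplementary material not reproduced here; the shipped
defaults are plausible mid-range choices (test operating characteristics
from the cited IHC/Bethesda literature, Italian outpatient-tariff-scale unit
costs, germline sequencing at €250 — the value implied by dividing the
printed strategy-1 screening total by the tested cohort — and a
per-relative predictive test of €82.17, implied the same way by the printed
cascade costs). Every run logs a warning per placeholder in use. Absolute
cost/QALY totals, and therefore the model-computed ICER level, are
conditional on these placeholders; the package's exactly reproducible
surface (screening arithmetic, ICER/frontier arithmetic on published cells,
scenario contracts, engine invariants) is not.

## Sensitivity analysis

* **One-way/tornado:** each parameter (dotted-path addressable) is moved to
  a low and high value (default ±20 %, truncated to valid domains) with
  everything else fixed; the spread of the s3-vs-no-screening ICER ranks the
  entries. The analysis is deterministic and order-invariant.
* **PSA:** 1,000 iterations by default. Hyperparameters are derived by
  method of moments from the base value m and a coefficient of variation
  (default 0.2): beta with sd = cv·min(m, 1−m) for probabilities and
  utilities (the shrinking sd near the boundaries keeps the beta feasible
  and the mean exact), gamma with shape 1/cv² for costs and counts,
  Dirichlet with concentration 1/cv² − 1 for compositions. cv = 0
  degenerates to the base case exactly. A single integer seed drives all
  draws; reruns are bit-identical.
* **Scenarios:** `no_aspirin` (RR → 1, aspirin cost → 0) and
  `no_gyn_monitoring` (gynecologic visit + sampling, transvaginal
  ultrasound and prophylactic-surgery costs → 0). The latter is cost-only
  by construction: QALY totals are provably unchanged.
* **CEAC:** joint mode (probability of maximal NMB, ties split evenly) and
  pairwise-versus-no-screening mode are both available; the pairwise mode
  matches how acceptability is usually reported for this comparison.

## What the synthetic module emulates

`make_degenerate_params` produces parameter sets whose outcomes have closed
forms (two-state geometric QALY series; immortal no-cancer counting;
perfect tests; zero uptake; collapsed arms), used to validate the engines
without circularity. `microsim_oracle` re-runs a cohort stratum as 50,000
individual trajectories drawn from the *same* transition matrices, so
agreement (within Monte-Carlo error) validates the cohort algebra
specifically — not the clinical realism of the inputs. `make_fixture_outcomes`
returns the published per-strategy cost/QALY cells as inputs for exact ICER
regression tests. Passing these tests demonstrates that the arithmetic
machinery is correct; it does not validate the placeholder natural-history
values against real Italian data.

## Problem sizes

The test suite and the acceptance script use the model at its natural size:
the full 41,552-proband expected cohort (expectation propagation is
O(paths), not O(persons)), 75-cycle lifetime cohorts, 50,000-individual
microsimulation, 1,000-iteration PSA, 120,000-proband tree simulations.
A complete run of either finishes in about a minute on one CPU.

## Known limitations

* Only CRC and EC are modelled; ovarian, gastric and other LS-spectrum
  cancers are out of scope, as are gene-specific (MLH1/MSH2 vs MSH6/PMS2)
  risk differences — all carriers share one risk profile.
* Colonoscopy surveillance acts through the stage distribution only; no
  incidence reduction from polypectomy is modelled, and gynecologic
  surveillance carries costs but no effectiveness (stage shift or
  otherwise) for EC.
* Only direct medical costs are included; no indirect/societal costs, no
  currency conversion or inflation adjustment, and no value-of-information
  analysis.
* The per-carrier QALY gain achievable under this structure with any
  physically plausible parameterisation is of order 0.5–1.5; published
  aggregate tables for this decision problem imply much larger per-carrier
  spreads, which cannot be reproduced without the unpublished supplementary
  inputs. Conclusions based on absolute totals should treat the shipped
  placeholders as illustrative.
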