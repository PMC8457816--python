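# Methods

## Model structure

The model estimates, for one incident breast-cancer cohort, (i) the
fraction of patients with a first-course indication for each
systemic-therapy modality under each resource-stratified guideline level,
(ii) the number of people needing each modality when country-level
incidence is pooled by World Bank income group, and (iii) the cost of the
recommended regimens. It deliberately covers **first-course therapy
only** (one adjuvant or first-line metastatic course per person), prices
**drugs and directly attached services only** (no delivery,
hospitalization, toxicity, imaging, surgery or radiotherapy costs), and
reports **relative** rather than absolute economics: prices are a single
country's list prices (PBS-style, AUD) applied worldwide, with no FX
conversion or discounting, held fixed between 2018 and 2040.

### Decision trees

Each resource level has a tree whose internal nodes split on patient
attributes and whose leaves carry indication lists
`(modality, category, setting, regimen_set)`. Invariants enforced at load
time: branch probabilities in [0, 1] summing to 1 (tolerance 1e-9) at every
node, a single root, acyclicity with single parentage (so the path
probability is the product of branch probabilities along the unique root
path), and total reachable leaf mass 1 ± 1e-9.

Utilization is person-level: a leaf with both an adjuvant and a
metastatic indication for the same modality counts once. The
recommendation-category policy is applied before evaluation; the default
models category 1 for adjuvant chemotherapy and HER2 therapy, category 2A
for metastatic chemotherapy and immunotherapy, and categories 1/2A/2B for
endocrine therapy (and oophorectomy). Adding categories to a policy can
only add indications, so utilization is monotone in the policy — a
property the test suite checks on random trees.

`simulate_cohort` draws each patient's leaf directly from the
path-probability distribution (equivalent to sampling branch-by-branch,
but vectorized) with a single seeded NumPy generator per call; the
empirical modality proportions must agree with the analytic expectation
within 4 binomial standard errors at n = 10⁶, and an explicit
path-enumeration oracle must agree exactly on small trees.

### The calibrated fixture trees

The four packaged trees share one topology (identical attribute
distributions at every level — the model's stated assumption; levels
differ only in leaf indications) with 33 leaves over: stage
(early 94% / de-novo metastatic 6%), ER (80%+), HER2, nodal status
(62% node-negative), a "favorable" tumor-profile class within early
ER+/HER2−/node-negative disease, multigene-assay risk, performance
status (85% good among metastatic), disease tempo for metastatic
ER+/HER2− disease, PD-L1 status for metastatic triple-negative disease,
and menopausal status (33% premenopausal).

Five of these probabilities are not free choices but are solved in closed
form from the headline utilization targets the fixture must reproduce:

| parameter | pinned by | value |
|---|---|---|
| P(HER2+) | HER2-therapy proportion 183,943/1,560,183 at Enhanced/Maximal | 0.1190 |
| P(favorable) | Core chemotherapy proportion 61,593/70,401 = 87.49% | 0.2827 |
| P(indolent) | Enhanced chemotherapy proportion 634,905/736,657 = 86.19% | 0.3620 |
| P(multigene low) | Maximal chemotherapy proportion 1,034,264/2,072,659 = 49.90% | 0.6221 |
| P(PD-L1+) | Maximal immunotherapy proportion 3,946/823,526 = 0.479% | 0.5332 |

The indication logic that makes those parameters identifiable: Basic
recommends no chemotherapy; Core gives category-1 adjuvant chemotherapy
to all early disease except the favorable class (which carries a
category-2B option the default policy strips) and 2A metastatic
chemotherapy to good-PS patients; Enhanced adds HER2 therapy and treats
indolent metastatic ER+/HER2− disease with endocrine therapy first;
Maximal adds multigene-assay triage (low-risk ER+/HER2− disease is
spared chemotherapy), dose-dense regimens with growth-factor support,
CDK4/6 inhibitors instead of first-line chemotherapy for metastatic
ER+/HER2− disease, and immunotherapy for PD-L1-positive metastatic
triple-negative disease. ER positivity (0.80) makes endocrine-therapy
utilization exactly 80% at every level. The solved values are
epidemiologically plausible (e.g. ~62% low/intermediate multigene risk,
~53% PD-L1 positivity in metastatic TNBC), which is a useful sanity check
on the structure, not evidence of validation.

### Synthetic incidence

`make_incidence` splits fixed income-group totals (2018:
70,401 L / 442,075 LM / 736,657 UM / 823,526 H) across synthetic
countries by a seeded Dirichlet draw with largest-remainder integer
rounding, so group totals are exact for every seed; all group-level
results are therefore seed-invariant, and country identity is pure
plumbing (real GLOBOCAN extracts use the same
`country,income_group,year,cases` schema). 2040 totals are back-derived
from the published 2040 chemotherapy needs and the calibrated level
proportions, with the low-income group as the remainder to the published
grand total 2,798,001; `project_incidence` moves each country linearly
toward its target-year share, again with exact group sums.

### Costing

All doses are for one reference patient (BSA 1.8 m², weight 75 kg,
CrCl 75 mL/min; Calvert formula for carboplatin). Adjuvant regimens run a
fixed cycle count or a mean duration where guidelines give a range
(e.g. 7.5 years for extended aromatase-inhibitor therapy); metastatic
regimens run the median PFS/TTP of their pivotal trial converted to
fractional cycles (no rounding up — a deliberately conservative choice,
switchable); GnRH agonists are always costed over 5 years. Pricing is
exact-milligram by default (`vial_rounding=True` rounds each
administration up to whole units). Recommended regimens within a set are
used with equal probability; per-person cost divides the expected cost
over tree paths by the group's denominator-modality proportion
(chemotherapy for the chemo/HER2/IO group, endocrine therapy for the
endocrine/CDK4/6 group, which also carries oophorectomy; a zero
denominator reports zero with the Basic level's chemotherapy group as the
only instance).

Seven "knob" prices are solved, sequentially and linearly, so the
published per-person costs emerge: a common scale on the six generic
cytotoxics (Core chemo target 1,278 AUD), trastuzumab (Enhanced 5,823),
pertuzumab (Maximal 22,313), tamoxifen (Basic endocrine 1,236),
anastrozole (Core 1,800), goserelin (Enhanced 3,100) and palbociclib
(Maximal 9,809). Core/Enhanced endocrine targets are this package's own
choices (the source tables are unpublished), fixed so global endocrine
cost lands on ~$9B in 2018. Solved prices are rounded to 4 decimals and
come out at realistic PBS magnitudes. The highest price tier is a fixed
per-drug multiple of the lowest (1.3× for biologics to 2.5× for old
generics), used only by the price-sensitivity bounds.

### Scenarios and sensitivity analyses

The upscaling ladder starts from the base mapping and raises the group
with the lowest current resource rank one level per scenario (ties to the
lower income group): (B,C,E,M) → (C,C,E,M) → (E,C,E,M) → (E,E,E,M) →
(M,E,E,M) → (M,M,E,M) → (M,M,M,M). The base mapping's total rank deficit
is six, so seven scenarios reach all-Maximal exactly; the exact middle
rungs are this package's documented choice (user-overridable) since only
the endpoints are pinned. Grand total cost is non-decreasing along the
ladder under the fixture prices, while chemotherapy need is deliberately
non-monotone and ends 28% below baseline.

Price sensitivity selects the min/max-cost regimen per indication at the
lowest/highest tier, then halves/doubles, giving the ordering
half_lowest ≤ lowest ≤ baseline ≤ highest ≤ double_highest per group.
The de-escalation sensitivity retargets the chemotherapy rate within
early ER+/HER2−/node-negative disease by tilting leaf masses inside that
subgroup and renormalizing branch probabilities bottom-up (an exact
conditional reweighting that preserves all tree invariants); the packaged
subgroup rates (30.1% Core, 45.0% Enhanced) are back-derived so the
overall rates land on the published de-escalated 70.4% and 75.2%.

## Numerical and reporting choices

Needs and costs are carried as floats end to end; integer and percent
rounding happen only in reports (round half-up, one decimal for sub-1%
values). Fold changes report half-up to an integer when the ratio is ≥ 2,
else to one decimal — the rule that reproduces all published folds (17,
8, 1.8, 1.7) from unrounded inputs. Probability-sum tolerance is 1e-9
throughout. Duplicate indications on a leaf collapse for utilization but
each indication's regimen cost accrues separately for costing.

## What the generator does and does not emulate

The synthetic bundle reproduces the *structure* of the published model —
income-stratified incidence with exact group totals, attribute-driven
indication logic, equiprobable regimen costing — and is calibrated to its
headline outputs. It does not emulate: the full >300-node clinical logic
(grade, age, histology, tumor size as explicit attributes), real
per-country incidence, stage-distribution differences between income
settings (attribute distributions are identical by assumption; a custom
tree or assignment can model shifts), second/third treatment courses,
within-country heterogeneity of service levels, or real price lists.
Passing tests therefore demonstrate that the machinery is correct and
that the calibration reproduces the published aggregates — not that the
fixture parameters are independently valid estimates for any real
population. Problem sizes used in the test suite: 10⁶-patient
microsimulations, 30–40 random trees per property, full pipeline runs on
the 80-country fixture; the whole suite runs in well under a minute.

## Known limitations

* Per-person costs at a level are averages over the whole indicated
  population; the model cannot price an individual pathway.
* The Maximal chemotherapy proportion implied by different published
  figures differs in the third decimal (49.86–49.90%); the scenario-7
  value is used, and downstream figures inherit ≤0.1% discrepancies.
* The chemo/HER2/IO group's "per person needing treatment" denominator is
  chemotherapy need; at a hypothetical level recommending HER2 therapy
  but no chemotherapy the convention would need revisiting.
* Percent reporting uses round-half-up, which matches the published
  tables but differs from banker's rounding.
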