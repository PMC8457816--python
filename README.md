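# rsgneed

Resource-stratified need and cost model for first-course breast-cancer
systemic therapy.

Breast cancer is the most common cancer worldwide (about 2.1 million new
cases in 2018, projected to 2.8 million by 2040), and treatment guidelines
tiered by health-system resources — Basic, Core, Enhanced and Maximal
service levels — prescribe very different systemic therapy depending on
what a country can deliver. This package answers a health-services
planning question: **if every country delivered guideline-based care at the
level matching its World Bank income group, how many people would need
each treatment modality, and what would it cost?** It is aimed at
health-services researchers and planners who want a transparent,
re-parameterizable model rather than a spreadsheet.

## The model

1. **Decision trees.** For each resource level $\ell$, a decision tree
   partitions incident patients over clinical attributes (stage, ER, HER2,
   nodal status, performance status, multigene-assay risk, menopausal
   status, PD-L1). Leaves carry treatment indications
   (modality, guideline recommendation category, adjuvant/metastatic
   setting, regimen set). The utilization proportion for modality $m$ is
   the person-level expectation over root-to-leaf paths

   $$p_\ell(m) \;=\; \sum_{\text{leaves } v}
       \Big(\prod_{e \in \text{path}(v)} \pi_e\Big)\,
       \mathbf{1}\{v \text{ carries an indication for } m\},$$

   after filtering indications through a recommendation-category policy
   (category 1 for adjuvant chemotherapy and HER2 therapy, 2A for
   metastatic chemotherapy, 1/2A/2B for endocrine therapy). A seeded
   microsimulation of $n$ patients provides an independent Monte-Carlo
   check of $p_\ell(m)$.

2. **Need.** Country-level incidence $I_c$ (GLOBOCAN-style, 2018 and a
   linear projection to 2040) is merged with the income-to-level mapping
   (L→Basic, LM→Core, UM→Enhanced, H→Maximal):
   $\text{need}(g, m) = \sum_{c \in g} I_c \cdot p_{\ell(g)}(m)$.

3. **Cost.** Each indicated leaf contributes the equiprobable mean over
   its recommended regimens, costed for a reference patient (BSA 1.8 m²,
   75 kg, CrCl 75 mL/min; carboplatin by the Calvert formula
   $\text{dose} = \text{AUC}\times(\text{CrCl}+25)$), with fixed adjuvant
   courses, median-PFS metastatic durations, 5-year GnRH agonist courses,
   and exact-milligram pricing in AUD. Dividing by the group's utilization
   proportion gives cost per person needing treatment.

4. **Scenarios.** Seven upscaling scenarios raise income groups one
   resource level at a time until everyone is treated at Maximal; price
   sensitivity brackets costs with the cheapest/most expensive regimen per
   indication (and half/double those); a de-escalation sensitivity lowers
   the chemotherapy rate in ER+/HER2−/node-negative disease.

Because the published tree (>300 nodes) and regimen prices live in an
unpublished supplement, the package ships a **calibrated synthetic
fixture bundle**: a 33-leaf tree per level and a PBS-style price table
whose free parameters are solved so the headline level outputs emerge
from the machinery (see `docs/methods.md`). Real incidence tables, trees
and price lists drop in through the same CSV/YAML schemas.

## Worked example

```sh
rsgneed generate-fixtures --outdir fixtures --seed 1
rsgneed run --bundle fixtures --outdir results
```

prints (abridged):

```
=== 2018 (incident cases: 2,072,659) ===
incidence by income group: L 3%, LM 21%, UM 36%, H 40%
need, chemotherapy: 1,432,613 persons (69% of incident cases)
need, her2: 183,943 persons (9% of incident cases)
need, endocrine: 1,658,127 persons (80% of incident cases)
global cost, chemo_her2_io: $13.36 billion AUD
global cost, endocrine_cdk46: $9.00 billion AUD

per-person cost (AUD per person needing treatment):
  Basic     endocrine_cdk46          1,236
  Core      chemo_her2_io            1,278
  Enhanced  chemo_her2_io            5,823
  Maximal   chemo_her2_io           22,313
  Maximal   endocrine_cdk46          9,809

upscaling to all-Maximal in 2018: chemotherapy need declines by 28%,
total cost rises 1.8-fold ($22B to $39B AUD)
Core services in low-income countries would add 61,593 chemotherapy
courses ($79 million AUD)
```

Reading the output: chemotherapy is indicated for 0% of patients under
Basic guidelines but 87–86% under Core/Enhanced, falling to 50% at
Maximal where multigene assays spare low-risk ER-positive disease — so
upscaling *reduces* chemotherapy need by 28% while the cost per treated
person rises 17-fold (AUD 1,278 → 22,313), driven by HER2 therapy,
growth-factor-supported dose-dense chemotherapy and immunotherapy.
Endocrine-therapy need (80%) is level-independent, but its cost rises
eight-fold from Basic (tamoxifen, oophorectomy) to Maximal (aromatase
inhibitors, GnRH agonists, CDK4/6 inhibitors).

Sensitivity analyses:

```sh
rsgneed sensitivity --mode upscaling    --bundle fixtures --outdir results
rsgneed sensitivity --mode prices       --bundle fixtures --outdir results
rsgneed sensitivity --mode deescalation --bundle fixtures --outdir results
rsgneed simulate --bundle fixtures --level Core -n 1000000 --seed 1
```

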