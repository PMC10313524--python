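# idhtrial

Analysis toolkit for perioperative ("window-of-opportunity") trials of
mutant-IDH1 inhibitors in low-grade glioma, built around **Bayesian dynamic
borrowing of external controls** for the pharmacodynamic primary endpoint —
tumor d-2-hydroxyglutarate (2-HG) suppression — and driven end to end by a
synthetic-cohort generator, so everything runs offline and reproducibly.

It is written for trial statisticians and translational scientists who want
to study, stress-test or reuse this design: the borrowing model and its
Gibbs sampler, the simulation machinery behind its operating
characteristics, RANO-LGG response/ORR statistics, and the downstream
pharmacodynamic association analyses (regressions, signed-significance gene
ranks, preranked GSEA, BH FDR).

## The model

Tumor 2-HG (µg g⁻¹) is compared on the log10 scale between each treated arm
and the untreated control level.  Because few enrolled patients go
untreated, the controls are augmented with archival untreated mIDH1 tumors
through a commensurate hierarchy.  With y_gj = log10 2-HG for subject j of
group g:

    y_gj | θ_g, σ²_g ~ N(θ_g, σ²_g)
    θ_t ~ N(m₀, v₀)                       (treated arms)
    θ_c | µ_c, τ² ~ N(µ_c, τ²)           (internal & external control sources)
    µ_c ~ N(m₀, v₀),  τ² ~ IG(a_τ, b_τ),  σ²_g ~ IG(a_σ, b_σ)

τ² governs borrowing strength and is learned from the data ("dynamic"
borrowing).  All full conditionals are conjugate; the model is fitted by a
hand-written, seeded Gibbs sampler with chains vectorized.  The reported
effect per arm is the percent reduction relative to untreated controls,
R_t = 100·(1 − 10^(θ_t − µ_c)), computed per posterior draw and summarized
by its posterior mean and equal-tail 95 % credible interval.
See `docs/methods.md` for priors, diagnostics and design discussion.

## Worked example

Fit the borrowing model to a synthetic cohort moment-matched to the per-arm
summary statistics of a 49-patient perioperative trial (treated arms
n = 11/7/10/7, internal controls n = 5, external mIDH1 bank n = 61):

```python
import numpy as np
from idhtrial import BorrowingModel, GroupData, moment_match_lognormal

arms = {  # label: (n, arithmetic mean, s.d.) in µg/g
    "VOR50": (11, 8.9, 4.1),    "VOR10": (7, 67.5, 65.4),
    "IVO500": (10, 20.9, 30.7), "IVO250": (7, 16.8, 18.1),
    "CTRL_INTERNAL": (5, 154.9, 146.9), "CTRL_EXTERNAL": (61, 276.8, 231.4),
}
rng = np.random.default_rng(1000)
groups = []
for label, (n, mean, sd) in arms.items():
    p = moment_match_lognormal(mean, sd)
    groups.append(GroupData(label, p.location + p.scale * rng.standard_normal(n)))

results = BorrowingModel(groups).fit(seed=1001)
print(results.summary())
```

```
Bayesian hierarchical borrowing model — tumor 2-HG (log10 scale)
groups: VOR50, VOR10, IVO500, IVO250, CTRL_INTERNAL, CTRL_EXTERNAL
chains: 4  draws/chain: 8000  seed: 1001

arm        reduction %   CrI low  CrI high  P(lower)     ESS
VOR50             94.1      85.1      98.2     1.000   25192
VOR10             79.9      45.1      94.8     0.996   26060
IVO500            92.6      79.9      98.1     1.000   25307
IVO250            83.9      57.9      95.5     0.999   25037

control hypermean mu_c: 2.260 (log10 µg/g)
max split-Rhat: 1.0002
```

Reading the table: the vorasidenib 50 mg q.d. arm suppresses tumor 2-HG by
an estimated 94.1 % (95 % CrI 85.1–98.2) relative to the borrowed untreated
control level of 10^2.26 ≈ 182 µg/g, and the posterior probability that the
treated mean lies below the control mean is ≈ 1 — the detection event the
design's power simulations target.  `results.reduction_summary("VOR50")`,
`results.prob_treatment_lower(...)` and `results.diagnostics()` expose the
same quantities programmatically.

The full pipeline (simulate → filter → fit → summarize → response →
associations) runs from the command line:

```
idhtrial all --seed 7 --outdir runs/demo
```

writing per-stage CSVs and a manifest with content hashes and all derived
seeds; `idhtrial oc` runs the operating-characteristics sweep when the
config has an `oc` section.

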