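# seqpoint

Bias-adjusted point estimation for two-stage group sequential trials with
early stopping for efficacy.

## The problem

A group sequential trial inspects the accumulating data at an interim
analysis and stops early if the standardized test statistic crosses an
efficacy boundary. This makes the conventional maximum-likelihood estimate
(MLE) of the treatment effect biased: trials that stop early have selected
large interim effects, so marginally the MLE overshoots, while conditional on
*continuing* the MLE undershoots. `seqpoint` is for trial statisticians who
need to report corrected point estimates after such a design, and for
methodologists studying the bias-variance trade-offs between the corrections.

For a two-stage design, let `I1 < I2` be the statistical information at the
interim and final analyses, `Z1, Z2` the standardized Wald statistics
(canonically bivariate normal with means `θ√I1, θ√I2` and correlation
`√(I1/I2)`), and `e` the z-scale interim efficacy boundary (O'Brien–Fleming:
`e_k = C(K, α)·√(K/k)` with `C` solved so the design spends exactly `α`).
The package implements, for a binary endpoint with effect
`θ = p_treatment − p_control`:

**Unconditional (marginal) perspective**

- marginal bias of the overall MLE,
  `bias(θ) = ((I2−I1)/(I2·√I1))·φ(e − θ√I1)`;
- **UBC-MLE** — the fixed point `θ̃ = θ̂ − bias_θ̃(θ̂)`;
- **UMVUE** — Rao–Blackwellization of the unbiased stage-1 MLE: after
  continuation, the mean of a normal `(θ̂, 1/I1 − 1/I2)` truncated above at
  `e/√I1`;
- **MUE** — the median-unbiased estimator under stagewise ordering, solving
  `P(θ) = ½` with `P(θ) = Pr_θ(Z1 ≥ e) + Pr_θ(Z1 < e, Z2 ≥ z2)`.

**Conditional perspective (given continuation, `T = 2`)**

- conditional bias `−(√I1/I2)·φ(d)/Φ(d)`, `d = e − θ√I1`;
- **CBC-MLE** — its fixed-point correction (upward);
- **UMVCUE** — Rao–Blackwellization of the conditionally unbiased stage-2
  MLE; satisfies `I1·UMVUE + (I2−I1)·UMVCUE = I2·θ̂` exactly;
- **CMUE** — the `θ` whose conditional median of the MLE equals the observed
  MLE.

Around the estimators sit the design calculus (boundary solving, exact
type-I-error computation for any number of stages), analytic bias and
stopping-probability profiles, and a canonical-distribution simulator for
sampling distributions and parametric-bootstrap standard errors.

## Worked example

The bundled dataset is the MUSEC trial (oral cannabis extract vs placebo for
muscle stiffness in multiple sclerosis): a two-stage design with one-sided
O'Brien–Fleming boundaries that continued to its final analysis with
cumulative counts 12/97 vs 27/101 at the interim and 21/134 vs 42/143 at the
end.

```python
import seqpoint as sp

interim, final = sp.load_musec_counts()
info = sp.musec_information()
print(f"I1={info.i1:.1f} I2={info.i2:.1f} "
      f"z1={info.z1:.3f} z2={info.z2:.3f} "
      f"boundary(effect scale)={info.effect_scale_boundary:.4f}")

for r in sp.estimate_report(interim, final, e=info.e):
    print(f"{r.estimator:12s} {r.perspective:13s} {r.estimate:.4f}")
```

prints

```
I1=312.8 I2=393.7 z1=2.540 z2=2.718 boundary(effect scale)=0.1581
mle_overall  naive         0.1370
mle_stage1   unconditional 0.1436
mue          unconditional 0.1341
umvue        unconditional 0.1278
ubc_mle      unconditional 0.1328
mle_stage2   conditional   0.1139
cmue         conditional   0.1851
umvcue       conditional   0.1724
cbc_mle      conditional   0.1909
```

The interim statistic (2.540) came close to the boundary (2.796), so the two
perspectives pull hard in opposite directions: unconditional corrections
nudge the MLE down (toward 0.128–0.134), while conditional corrections —
which account for the downward selection pressure among trials that
*continue* — push it up by as much as 39% (CBC-MLE 0.1909). Which to report
depends on the estimand: the effect averaged over all possible stopping
outcomes, or the effect given the trial actually ran to completion.

The same suite is scriptable:

```bash
seqpoint estimate --counts counts.csv --boundary 2.7965 --output-dir out/
seqpoint design --stages 2 --alpha 0.05
seqpoint profile --counts counts.csv --boundary 2.7965
seqpoint simulate --counts counts.csv --boundary 2.7965 \
    --theta 0.10 --theta 0.14 --theta 0.18 --n-reps 10000 --seed 1
```

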