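# rezddm — robust hierarchical Bayesian EZ drift-diffusion modeling

`rezddm` implements a contamination-robust variant of the hierarchical
Bayesian EZ diffusion model (EZ-DDM) for two-choice response-time data,
together with the simulation harness needed to validate it: a trial-level
Wiener data generator, a contaminant-injection procedure, and
ROC/AUC/RMSE/bias evaluation of hypothesis-testing performance.

## The problem

The drift-diffusion model describes a two-choice decision as noisy evidence
accumulation with drift ν and diffusion coefficient s between absorbing
boundaries 0 and α (start point α/2, unbiased); observed RT is the
first-passage time plus a non-decision time τ. The EZ method of moments
maps three summary statistics of a participant–condition cell — accuracy
rate Pc, mean RT, and RT variance — to (ν, α, τ) in closed form, with
k = αν/s²:

    Pc  = 1 / (1 + e^(−k))
    MRT = τ + (α / 2ν) (2 Pc − 1)
    VRT = (α s² / ν³) (Pc − 1/2 − k Pc (1 − Pc))

Embedding these moments in the sampling distributions of the summary
statistics gives a *proxy likelihood* per cell,

    n_correct ~ Binomial(n, Pc)
    mean RT   ~ Normal(MRT, VRT / n)
    var RT    ~ Normal(VRT, 2 VRT² / (n − 1))

which supports scalable hierarchical Bayesian inference without a
trial-level Wiener likelihood. The catch: the sample mean and variance are
maximally non-robust. A few contaminant trials — lapses, delayed startups,
guesses — can wreck them, and with them the inference.

The robust variant substitutes the **median** for the mean and the
interquartile-range variance estimate

    Var_IQR = ((Q3 − Q1) / 1.349)²

for the sample variance (1.349 = IQR of a standard normal, making Var_IQR
consistent for the variance under normality), leaving everything else —
proxy likelihood, hierarchy, priors — unchanged.

The hierarchy is a within-subject two-condition meta-regression on drift:

    ν_pred(p,k) = μν + β X_k,   X_k ∈ {0, 1}
    ν(p,k) ~ N(ν_pred(p,k), σν²),  α_p ~ N(μα, σα²),  τ_p ~ N(μτ, στ²)

so testing the condition effect is testing β = 0.

## Worked example

Forty participants, eighty trials per condition, true effect β = 0.4;
one clean dataset and a 5%-contaminated copy (half delayed startups with
+U(2,3) s on the RT, half zero-drift guesses), fit all four ways:

```python
import numpy as np
from rezddm import (draw_population, draw_individuals, generate_dataset,
                    contaminate, summarize_dataset, build_model, ModelSpec,
                    fit, decision_statistic)

rng = np.random.default_rng(42)
pop = draw_population("main", beta=0.4, rng=rng)     # mu_nu=1.644, mu_alpha=2.878
ind = draw_individuals(pop, 40, rng)
clean = generate_dataset(ind, 80, rng)
dirty = contaminate(clean, ind, np.random.default_rng(43), rate=0.05)

for label, data in [("clean", clean), ("contaminated", dirty)]:
    for method in ("standard", "robust"):
        cells = summarize_dataset(data, method, rt_scope="all")
        res = fit(build_model(cells, ModelSpec(rt_scope="all", method=method)), seed=7)
        z = decision_statistic(res, "z_abs")
        bf = decision_statistic(res, "savage_dickey_bf10")
        print(f"{label:13s} {method:8s} beta = {res.beta_mean:+.3f} "
              f"+- {res.beta_sd:.3f}  z = {z:.2f}  BF10 = {bf:.3g}")
```

Output:

```
clean         standard beta = +0.371 +- 0.158  z = 2.36  BF10 = 2.53
clean         robust   beta = +0.447 +- 0.162  z = 2.75  BF10 = 7.18
contaminated  standard beta = +0.163 +- 0.093  z = 1.75  BF10 = 0.432
contaminated  robust   beta = +0.411 +- 0.149  z = 2.77  BF10 = 6.8
```

On clean data the two methods agree. Under 5% contamination the standard
summaries attenuate the effect estimate toward zero (+0.16, Bayes factor
now *against* the effect), while the robust summaries are essentially
untouched (+0.41). Aggregated over 30 replicates per effect size at the
high-drift preset (where contamination bites hardest), the same pattern
shows up in diagnostic accuracy: AUC ≈ 0.93 / 0.91 / 0.90 for
clean-robust / clean-standard / contaminated-robust versus **0.68** for
contaminated-standard.

The factorial harness behind those numbers is one call:

```bash
rezddm run-study --seed 0 -o study_results   # or: StudyConfig(...) + run_study(cfg)
```

writing per-replicate results, aggregate AUC/RMSE/bias tables, and a
manifest. `simulate`, `contaminate`, `summarize`, `fit`, and `evaluate`
subcommands expose the individual pipeline stages.

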