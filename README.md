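# speechrecal

Rapid recalibration of speech sound categories, simulated with a Bayesian
model of audiovisual syllable perception.

## The problem

When an acoustic /aba/ is dubbed onto a video of a speaker articulating
/aga/, most listeners hear the illusory fusion /ada/ — the McGurk effect.
Behaviorally, a *fused* McGurk trial leaves a trace: an acoustic-only /aba/
presented on the next trial is more often categorized as 'ada' (about 29%
of the time, versus about 16% after other stimuli, in a 27-participant
3-alternative experiment with six stimulus types). This package simulates
that experiment end to end and asks which per-trial learning rule can
reproduce the *transient*, next-trial effect: is recalibration cumulative
Bayesian belief updating, a constant-rate delta rule, or learning at two
time scales with decay toward a long-term representation?

It is aimed at computational-perception researchers who want a compact,
fully reproducible test bed for trial-by-trial recalibration models.

## The model

A listener represents each category k ∈ {/aba/, /ada/, /aga/} by Gaussian
expectations over two stimulus features — lip-closure amplitude (visual,
V) and 2nd-formant-transition amplitude (acoustic, A):
C_f | k ~ N(θ_{k,f}, σ_{k,f}²), observed through sensory noise
s_f | C_f ~ N(C_f, σ_f²). Marginalizing the hidden amplitudes gives the
closed-form posterior

    p(k | s_V, s_A) ∝ N(s_V; θ_{k,V}, σ_V²+σ_{k,V}²) · N(s_A; θ_{k,A}, σ_A²+σ_{k,A}²) · p(k),

and the percept is the MAP category (acoustic-only trials use the acoustic
factor alone). After each percept the *perceived* category's parameters are
recalibrated toward the experienced features. Four regimes are compared:

| rule    | update (perceived category k, feature f)                               |
|---------|------------------------------------------------------------------------|
| none    | no change (control)                                                     |
| bayes   | conjugate Normal–Inverse-χ²: Δθ = (s−θ)/(κ₀+n(k)), spread likewise      |
| delta   | Δθ = rate·(s−θ)·p(k\|s), constant rate                                  |
| decay   | Δθ = R1·(s−θ)·p(k\|s), then every θ relaxes: θ ← θ + D·(μ−θ)            |

The decay rule keeps a fast "working" location θ and a stable long-term
anchor μ; with D = 0.14 per 5-s inter-trial interval the implied time
constant is τ = Δt/D ≈ 36 s, so recalibration is strongest exactly one
trial after a fused McGurk — the signature observed behaviorally.

The experiment simulator presents 6 stimulus types × 69 repetitions
(414 trials) in random order, with stimulus amplitudes tailored to the
listener's initial model. Evaluation simulates 100 listeners, selects the
perceptual noise parameters minimizing the McGurk-contrast MSE over the 20
tested combinations, resamples 6000 groups of 27 listeners, and reports
the representative sample (median combined fit score) with a paired
Wilcoxon signed-rank test and a 95% CI for the contrast.

## Worked example

```python
import numpy as np
import speechrecal as sr

model = sr.PerceptualModel.default(noise_V=0.12, noise_A=0.12,
                                   sigma_kA=0.2, sigma_kV=0.1)

# a noiseless McGurk input (visual /aga/ amplitude, acoustic /aba/ amplitude)
post = sr.category_posterior(model, sr.SensoryInput(s_V=0.37, s_A=0.1))
print("posterior:", np.round(post, 3), "->", sr.choose_percept(post))

# simulate 100 listeners under the two-timescale rule and test the contrast
rule = sr.RuleParams.decay(R1=0.4, D=0.14)
cohort = sr.run_cohort(model, rule, n_listeners=100, master_seed=42)
dist = sr.resample_groups(sr.summarize_cohort(cohort),
                          n_samples=6000, group_size=27, rng=42)
i = dist.representative_index
print(f"after fused McGurk: {dist.p_mc[i]:.1f}%  after controls: {dist.p_oth[i]:.1f}%")
lo, hi = sr.ci_median_difference(dist)
print(f"Wilcoxon p = {dist.wilcoxon_p[i]:.4f}  95% CI of median difference = [{lo:.1f}, {hi:.1f}]%")
```

prints

```
posterior: [0.002 0.994 0.004] -> ada
after fused McGurk: 25.0%  after controls: 17.0%
Wilcoxon p = 0.0552  95% CI of median difference = [0.9, 12.0]%
```

The McGurk input is confidently fused to /ada/, and under the decay rule
acoustic /aba/ is mis-heard as 'ada' more often right after a fused McGurk
trial than after control stimuli, with the CI of the median difference
excluding zero. (This example fixes one perceptual parameter set; the full
protocol below additionally selects the best-fitting set out of 20.)

The same pipeline is scriptable from the shell:

```sh
speechrecal simulate --rule decay --r1 0.4 --decay-d 0.14 --outdir out/
speechrecal evaluate --all-rules --outdir out/   # full grid, ~30 s
speechrecal report --outdir out/
```

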