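# laminarct

Laminar cortical-thickness profiling and opposite-correlation statistics
for two-group individual-differences studies, exercised end to end on
synthetic data.

## The problem

Face and car recognition abilities correlate with the cortical thickness
(CT) of the face-selective fusiform region in *opposite* directions — face
ability negatively, car ability positively. The **opposite correlation
effect (OCE)** turns this crossover into one statistic: multiply face
ability by −1, sum with car ability, and correlate the composite with CT,

&nbsp;&nbsp;&nbsp;&nbsp;OCE = corr(car − face, CT).

When the two opposite correlations are strong and independent, the
composite correlation exceeds either alone, so a small two-group design
(e.g. autistic adults vs typically developing controls, n ≈ 16–17 per
group) can test whether the crossover is attenuated in one group via the
Fisher r-to-z comparison z = (atanh r₂ − atanh r₁)/√(1/(n₁−3) + 1/(n₂−3)).

CT itself comes from ultra-high-resolution slice images: lines ("traces")
are drawn between manually traced superficial (gray–CSF) and deep
(gray–white) boundaries, intensity is sampled along each trace as a
function of normalized depth, a quartic is fitted to the mean depth
profile, and the quartic's two inflection points split total CT into
superficial / middle / deep laminar compartments.

The package provides, as tested library modules plus a thin CLI:

- `laminarct.synthetic` — cortical-ribbon phantoms with ground-truth
  contours and layer fractions; two-group cohorts with specified
  ability–thickness correlation structure
- `laminarct.laminar` — traces, depth profiles, quartic fit, inflection
  detection, laminar thickness
- `laminarct.behavior` — d′, pooled standardization, category aggregates,
  directional group tests with Bonferroni correction
- `laminarct.oce` — OCE, Fisher-z group comparison, Williams' test for
  dependent correlations, partial correlation controlling novel-object
  ability, Brown–Forsythe variance comparison with η²
- `laminarct.power` — analytic and Monte-Carlo power / sample size for
  differences between independent correlations
- `laminarct.pipeline` / `laminarct.cli` — the end-to-end synthetic study

See `docs/methods.md` for the model details, calibration of the phantom,
and known limitations.

## Worked example

Required per-group sample size to detect an OCE of 0.946 against 0.1 with
80% power (two-sided α = .05):

```sh
$ laminarct power 0.946 0.1
{
  "r1": 0.946,
  "r2": 0.1,
  "alpha": 0.05,
  "n_per_group": 9,
  "power_target": 0.8
}
```

Nine subjects per group suffice for the total-CT scenario; the same command
with `--n1 17 --n2 16` reports the power achieved at the study's actual
sizes (0.625 for the deep-layer OCE 0.752, i.e. 62%).

The full synthetic study — cohort draw, per-subject ribbon phantom, laminar
measurement, OCE and comparisons:

```sh
$ laminarct run-all --outdir demo --seed 0
       measure         z        p  order
         ct_mm -2.886798 0.003892 AUT-TD
      total_mm -2.886798 0.003892 AUT-TD
superficial_mm -2.962799 0.003049 AUT-TD
     middle_mm -2.835125 0.004581 AUT-TD
       deep_mm -2.811808 0.004926 AUT-TD
```

Under the default generating structure (controls: face −0.55, car +0.45
with thickness; autism group attenuated) this seed's cohort yields a
control-group OCE of r = 0.76 (p < .001, n = 17) against −0.11 (p = .68,
n = 16) in the comparison group, and the Fisher-z comparisons above reject
the equal-OCE null on every thickness measure: the pipeline recovers the
group difference it was asked to embed. `demo/` then contains the cohort
and thickness table, per-group OCE results (with the
difference-of-correlations reading and the novel-object partial control
alongside), comparisons, variance test, and a power table, all stamped with
the seed and config hash. With single draws at n = 16 expect sampling
noise: an occasional seed produces a spuriously large attenuated-group OCE.

Library use mirrors the CLI:

```python
from laminarct import RibbonSpec, generate_ribbon, subject_laminar_ct

img = generate_ribbon(RibbonSpec(noise_sd=4.0, seed=1))
lam, prof = subject_laminar_ct([(img, img.truth["boundaries"])])
print(lam.total_mm, prof.inflection_depths)
# 2.4375 (0.3365..., 0.6707...)
```

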