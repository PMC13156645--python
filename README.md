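# gwnbr — geographically weighted negative binomial regression

A library and command-line tool for regression modelling of **overdispersed,
spatially heterogeneous count data** over areal units (provinces, districts,
health zones): disease case counts, accident counts, crime counts — any
nonnegative integer response observed once per region together with
covariates and centroid coordinates.

It is aimed at spatial epidemiologists and regional statisticians who want
the full global-to-local workflow in one place:

1. **VIF screening** of the covariates (multicollinearity flag at VIF > 10).
2. **Global Poisson regression**, log(μᵢ) = xᵢ′β, with the
   deviance/df **overdispersion diagnostic** (ratio ≫ 1 ⇒ the Poisson
   equidispersion assumption fails).
3. **Global negative binomial (NB) regression** — the Poisson-Gamma mixture
   with Var(Y) = μ + θμ², where θ is the dispersion parameter (θ → 0
   recovers Poisson). β is estimated by IRLS, θ by profile likelihood.
4. **Spatial diagnostics on the NB Pearson residuals**: Moran's *I*
   (spatial dependence, zero-diagonal distance weights) and the classical
   **Breusch–Pagan** score test ½ f′Z(Z′Z)⁻¹Z′f (spatial heterogeneity).
5. **Kernel bandwidth selection** by leave-one-out cross-validation,
   CV(b) = Σᵢ (yᵢ − ŷ₋ᵢ(b))², over fixed/adaptive Gaussian and bisquare
   kernels, via golden-section search.
6. **GWNBR**: at every location i, maximize the kernel-weighted NB
   log-likelihood Σⱼ wᵢⱼ ℓ(yⱼ; exp(xⱼ′β(uᵢ,vᵢ)), θ(uᵢ,vᵢ)) by
   Newton–Raphson (analytic gradient/Hessian, tolerance 10⁻⁸, ≤ 20
   iterations, initialized from the global NB fit) with a local
   profile-likelihood dispersion; local SEs and Z statistics from the
   final Hessian; effective model size tr(S) from the spatial hat matrix.
7. **Model comparison**: F-type fit test F = (D_glob/df₁)/(D_spat/df₂)
   with df₂ = n − tr(S), MLRT simultaneous test of the covariates, and AIC
   ranking (AIC = −2 ln L + 2k, with k = tr(S) + 1 for GWNBR).

A seeded synthetic-data generator (`gwnbr.simulate`) produces spatially
varying-coefficient NB datasets with known truth, so the whole workflow is
testable without any external data.

## Worked example

```python
import gwnbr

# a 200-unit synthetic province dataset with known coefficient surfaces
dataset, truth = gwnbr.generate(gwnbr.default_scenario())

report = gwnbr.run_pipeline(dataset, gwnbr.RunConfig(), out_dir="results")
for stage in report["stages"]:
    print(f"{stage['name']:>20}: {stage['decision']}")
print("selected:", report["selected_model"])
```

prints (seed 20260419):

```
                 vif: no multicollinearity
             poisson: reject H0 (some covariate matters)
      overdispersion: overdispersed
              negbin: reject H0 (some covariate matters)
            morans_i: reject H0 (spatial dependence)
       breusch_pagan: reject H0 (spatial heterogeneity)
 bandwidth_selection: selected adaptive bisquare bandwidth 0.264947
               gwnbr: 200/200 local fits converged
         f_type_test: retain H0 (no improvement)
   mlrt_simultaneous: reject H0 (covariates jointly significant)
         aic_ranking: selected gwnbr
selected: gwnbr
```

Reading the output: the Poisson deviance/df ratio is 14.05, far above
the 1.5 rule of thumb, so the counts are severely overdispersed and the NB
family is required.  Moran's *I* on the NB residuals rejects decisively
(z ≈ 23.0) and Breusch–Pagan rejects too — the global model leaves spatial
structure unexplained — so coefficients are allowed to vary over space.
Cross-validation picks an adaptive bisquare kernel using ~26% of
neighbours per location, and the GWNBR fit wins the AIC comparison
(1588.6 vs 1741.9 for global NB and 3806.4 for Poisson), with the local
poverty coefficient tracking the true generating surface at r = 0.858.
`results/` contains the per-location
coefficient and inference tables, the CV curve, a predicted-vs-actual
table and a JSON summary of every test statistic.

The same workflow runs from the shell on any CSV with count, covariate and
longitude/latitude columns:

```bash
spatial-count-glm simulate --out sim/
spatial-count-glm run --data sim/dataset.csv --out results/
spatial-count-glm select-bandwidth --data sim/dataset.csv --kernel all --mode all --out bw/
```

## Layout

| module | contents |
|---|---|
| `gwnbr.io` | `SpatialCountDataset`, `RunConfig`, CSV/YAML reading, result writing |
| `gwnbr.glm` | Poisson/NB likelihoods and fits, overdispersion ratio, Wald Z, VIF |
| `gwnbr.diagnostics` | Moran's *I*, Breusch–Pagan (classical + Koenker variant) |
| `gwnbr.kernels` | distances, kernel weights, adaptive bandwidths, LOO-CV selection |
| `gwnbr.gwnbr` | local Newton–Raphson, local dispersion profile, hat trace, `fit_gwnbr` |
| `gwnbr.compare` | F-type test, MLRT, quantiles, rate ratios, AIC ranking |
| `gwnbr.simulate` | seeded spatially varying-coefficient NB generator |
| `gwnbr.pipeline`, `gwnbr.cli` | end-to-end driver and `spatial-count-glm` CLI |

See `docs/methods.md` for the model details, numerical choices and known
limitations.
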