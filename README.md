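# polyscission

Moment-based population-balance modelling of hydrolytic chain scission in
bioresorbable polyester films, with least-squares estimation of the
degradation kinetic constant from molecular-weight decay data.

## The problem

Bioresorbable devices made of aliphatic polyesters (PLA, PCL and their
copolymers) degrade by hydrolysis of ester bonds. Terminal sterilization by
electron beam cuts chains, lowering the initial molecular weight — and the
shorter, acid-terminated chains then autocatalyse hydrolysis, so the
sterilized material also degrades *faster*. Quantifying that acceleration
requires fitting a degradation model to number-average molecular weight
Mn(t) series measured (e.g. by GPC) at each radiation dose.

This package is aimed at people modelling polymer-device degradation: it
provides the forward reaction–diffusion model, a statsmodels-style fitting
interface, a chain-length-resolved oracle for validating the moment
closure, and a synthetic-data generator for method studies.

## The model

The chain-length distribution C_n is summarised by its statistical moments
μ_j = Σ_n n^j C_n. Over the film half-thickness the model tracks water
(C_W), monomer (C_M), mobile oligomers C_n for 2 ≤ n ≤ 9 (longer chains
cannot diffuse through the matrix), and μ₀, μ₁, μ₂:

    ∂C_M/∂t = ∇·(D_M ∇C_M) + 2 k_d C_W (μ₀ − C_M) μ₀
    ∂C_W/∂t = ∇·(D_W ∇C_W) − k_d C_W (μ₁ − μ₀) μ₀
    ∂C_n/∂t = ∇·(D_olig ∇C_n) + 2 k_d C_W (μ₀ − Σ_{j≤n} C_j) μ₀
              − (n−1) k_d C_W C_n μ₀                      (2 ≤ n ≤ 9)
    ∂μ₀/∂t  = Σ_j ∇·(D_j ∇C_j) + k_d C_W (μ₁ − μ₀) μ₀
    ∂μ₁/∂t  = Σ_j j ∇·(D_j ∇C_j)
    ∂μ₂/∂t  = Σ_j j² ∇·(D_j ∇C_j)
              + k_d C_W (μ₀/3) (μ₁ − 2μ₂²/μ₁ + μ₂μ₁/μ₀)

Scission is random along the chain and autocatalysed by carboxylic chain
ends (the μ₀ factor), giving third-order kinetics with constant k_d
(cm⁶ mol⁻² s⁻¹). The μ₂ balance is closed with μ₃ ≈ 2μ₂²/μ₁ − μ₂μ₁/μ₀,
exact for monodisperse distributions. Diffusivities grow as degradation
opens the matrix: D_i = D_i⁰ exp[2.5 (1 − Mn/Mn(0))^0.5]. Averages follow
from the moments: Mn = (μ₁/μ₀)·M_mon, Mw = (μ₂/μ₁)·M_mon, PD = μ₂μ₀/μ₁².

The PDEs are solved by the method of lines (conservative centred
differences over the film half-thickness, symmetry at the centre, Dirichlet
water / perfect-sink oligomer conditions at the surface) with a stiff
implicit integrator. A single-node "well-mixed" mode — appropriate for thin
films, which hydrate much faster than they degrade — is the default forward
model for fitting: k_d is estimated by minimising relative residuals
Σ_t [(Mn_model − Mn_data)/Mn_data]² over log₁₀(k_d).

## Worked example

Generate a synthetic decay series for the film irradiated at 5 Mrad
(initial Mn = 64,700 g/mol, PD = 1.68, true k_d = 1.27e-4, 3% GPC noise)
and re-estimate the constant:

```python
from polyscission import ChainScissionModel, generate_dataset

ds = generate_dataset(kd=1.27e-4, Mn0=64_700, PD0=1.68,
                      noise_cv=0.03, seed=185, label="5 Mrad")
print(ChainScissionModel(ds).fit().summary())
```

```
Chain-Scission Hydrolysis Fit
==============================================
dataset                 5 Mrad
observations            12
forward model           well-mixed
initial Mn (g/mol)      64,700
initial PD              1.680
----------------------------------------------
kd (cm^6 mol^-2 s^-1)   1.2833e-04
residual norm (rel.)    9.464e-02
function evaluations    8
converged               True
==============================================
```

The estimate (1.2833e-4) recovers the true constant within ~1% despite the
3% measurement noise; the residual norm is the Euclidean norm of the
relative misfits. Normalizing the four reference constants by the
non-irradiated one quantifies the sterilization effect:

```python
from polyscission import normalize_constants, DOSE_TABLE
out = normalize_constants({lab: c.kd for lab, c in DOSE_TABLE.items()},
                          "0 Mrad")
print(out.ratios)       # {'0 Mrad': 1.0, '5 Mrad': 3.299, '10 Mrad': 3.818, '20 Mrad': 3.143}
print(out.mean_ratio)   # 3.42  -> hydrolysis ~3.5x faster after e-beam
print(out.spread)       # 1.21  -> acceleration is dose-independent
```

A CLI wraps the same operations:

```sh
polyscission generate --dose 5 --seed 185 --out dose5.csv
polyscission fit --data dose5.csv
polyscission simulate --config film.yaml --t-end-days 300 --out traj.csv
polyscission oracle-check
```

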