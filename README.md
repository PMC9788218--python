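# trtsim

Simulation and estimation toolkit for **targeted alpha therapy** in the
implanted-tumor mouse model: what happens to a tumor after an intravenous
injection of an alpha-emitting radiopharmaceutical (astatine-211,
half-life 7.21 h), from drug delivery through absorbed dose to the tumor
volume curve measured with calipers over the following weeks.

It is aimed at preclinical modelers who want to interpolate and
extrapolate dose–response behavior from sparse xenograft experiments —
e.g. to pick a starting activity for which efficacy is expected with a
safety margin — without running another cohort of mice.

## The model

**Delivery.** Injected activity moves between four compartments — blood
(R₁), tumor (R₂), body organs (R₃) and excretion (R₄) — with first-order
transfer coefficients α and physical decay rate *y* = ln2/7.21 h⁻¹:

    dR₁/dt = −(α₁₂+α₁₃+α₁₄) R₁ + α₂₁R₂ + α₃₁R₃ − yR₁
    dR₂/dt = α₁₂R₁ − α₂₁R₂ − yR₂          (tumor)
    dR₃/dt = α₁₃R₁ − α₃₁R₃ − yR₃
    dR₄/dt = α₁₄R₁ − yR₄

With the return paths dropped (α₂₁ = α₃₁ = 0) the system is solvable in
closed form; with A = α₁₂+α₁₃+α₁₄+y the time-integrated tumor activity is
Q·α₁₂/(yA), so the total absorbed dose for an injected activity Q is

    D(∞) = 5.45 Gy·h⁻¹·MBq⁻¹ × Q·α₁₂/(yA)  ≈ 9.7 Gy at Q = 1 MBq

with the default rate constants (α₁₂ = 0.33, α₁₃ = 1, α₁₄ = 0.5 h⁻¹).

**Response.** Proliferating cells N grow logistically and are killed at
rate b·d(t) by the dose rate; damaged cells N_D stop proliferating at
once but lose volume only slowly (clearance c ≈ 0.1/day), and the
regrowth rate is impaired by the cumulative dose:

    dN/dt   = (λ_mod(t) − b·d(t)) · N · (1 − N/Nm)
    dN_D/dt = b·d(t)·N
    V(t)    = v·N(t) + v·N_D(t)·e^(−ct)
    λ_mod(t) = λ / (1 + D(t)^¼),   D(t) = ∫₀ᵗ d(τ)dτ

Defaults: λ = 0.14/day, b = 0.3/Gy, N₀ = 2×10⁹, Nm = 4×10¹⁰,
V₀ = 577 mm³. In the impulse limit the surviving fraction is e^(−bD).

**Estimation.** Control growth rates are fitted per animal by ordinary
least squares of ln V on time over the first 10 days (V = V₀e^{λt}), and
cohorts are summarized by mean ± sample SD. Since no machine-readable
animal data exist, a synthetic-cohort generator produces realistic
volume tables (per-animal λ and V₀ heterogeneity, multiplicative caliper
noise) for testing the whole pipeline end to end.

## Worked example

```
$ trt-sim dose -Q 1 --t-max-h 48 --dt-h 1 | head -4
t_h   dose_rate_gy_per_h  cum_dose_gy
0.0   0.0                 0.0
1.0   0.7495024055377112  0.5011333925113394
2.0   0.7900127419145502  1.2887558190154547
```

The dose rate is zero at injection (no activity has reached the tumor
yet), peaks below 0.8 Gy/h within a couple of hours, and the cumulative
dose climbs toward the 9.7 Gy total — about 90% of it within the first
day, a consequence of the short physical half-life.

```python
from trtsim import DeliveryRates, DoseConversion, TumorParams, run_scenarios
tab = run_scenarios([0, 0.1, 0.4, 1.0], DeliveryRates(), DoseConversion(),
                    TumorParams(), horizon_days=40)
print(tab[tab.t_day == 40.0][["activity_mbq", "V"]].round(1))
#  activity_mbq        V
#           0.0  10782.4
#           0.1   4582.4
#           0.4   1682.5
#           1.0    256.6
```

Day-40 volumes fall monotonically with injected activity: the control
tumor has grown ~19-fold toward its carrying capacity, while 1 MBq
(9.7 Gy) has reduced the tumor to less than half its initial 577 mm³ and
its regrowth rate from 0.14/day to ≈0.051/day.

The synthetic-cohort / estimation round trip:

```
$ trt-sim make-fixtures --seed 42 --n-per-group 6 --out cohort.tsv
$ trt-sim fit-growth cohort.tsv
parameter     mean                 sd
lam_per_day   0.10917043973975876  0.056080355199484434
V0_mm3        421.6010854316037    148.24855341819017
```

Six noisy control animals recover a growth-rate mean in the right range
(0.11 vs the generating 0.14/day — at n = 6 the sampling spread of a
cohort with SD 0.08/day is large, which is exactly what the generator is
for quantifying).

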