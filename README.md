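# chondrosim

A deterministic continuum simulator of cartilage regeneration in a chondral
defect after cell implantation, for researchers studying cell-based cartilage
therapies (autologous chondrocyte implantation and its stem-cell variant) and
the growth-factor cross-talk between mesenchymal stem cells (MSCs) and
chondrocytes.

## The model

The defect is treated as a one-dimensional domain across its thickness,
x ∈ [0, d], from the subchondral bone (x = 0) to the cartilage surface
(x = d). Six fields evolve by reaction–diffusion dynamics:

- C_S — MSC density; implanted as a Gaussian bump against the bone,
  proliferates under Michaelis–Menten nutrient limitation, and
  differentiates into chondrocytes at rate p2 once its density exceeds a
  threshold C_S0,
- C_C — chondrocyte density; proliferates (nutrient-limited, crowding-
  limited), produces matrix,
- m — extracellular matrix density; deposited by chondrocytes at rate
  p8(m, g) = (p80 − p81 m)(1 + p800 · g/(g + g0)),
- n — nutrient (oxygen), diffusing in from a reservoir at the cartilage
  surface (n = N0 there) and consumed by both cell types; below a critical
  level n1, proliferation stops and cells die,
- g — FGF-1, produced by MSCs, degrading and leaking out at the surface;
  it boosts chondrocyte proliferation through a saturating term,
- b — BMP-2, produced by chondrocytes; it lowers the MSC differentiation
  threshold, C_S0(b) = (C_S0,max − C_S0,min)·e^(−αb) + C_S0,min, closing a
  positive feedback loop that accelerates chondrogenesis.

Cell motility is biphasic in matrix density, D(m) = D0·m/(m² + m1²): cells
need matrix to migrate but are trapped when it is dense. Switching
(differentiation threshold, critical nutrient) uses Heaviside gates,
regularised here by a tanh sigmoid of width `eps`.

The system is solved in dimensionless form (densities scaled by the maximum
total cell density, matrix by its maximum, time by the matrix-production
time scale mmax/(p80·C_total,max0) ≈ 266.7 h ≈ 11.1 days), with a
second-order conservative finite-difference discretisation in space and a
stiff implicit BDF integrator in time.

## Worked example

Compare four months of healing with and without the two growth factors:

```python
from chondrosim import ScenarioSpec, run_scenario, percent_difference, spatial_mean

base = run_scenario(ScenarioSpec(name="baseline", gf_config="none", duration_months=4))
gf = run_scenario(ScenarioSpec(name="gf", gf_config="both", duration_months=4))
for field, label in [("m", "matrix"), ("c_c", "chondrocytes"), ("c_s", "stem cells")]:
    print(f"{label:12s} 4-month mean {spatial_mean(gf, field, 4.0):.4f} "
          f"({percent_difference(gf, base, field, 4.0):+.1f}% vs baseline)")
```

prints

```
matrix       4-month mean 0.0558 (+24.2% vs baseline)
chondrocytes 4-month mean 0.0765 (+27.4% vs baseline)
stem cells   4-month mean 0.1545 (+4.4% vs baseline)
```

At four months the growth-factor feedback loop has produced about a quarter
more matrix and chondrocytes than the baseline: BMP-2 secreted by the early
chondrocytes lowered the MSC differentiation threshold, so chondrogenesis —
and with it matrix deposition — started earlier. The stem-cell pool is still
marginally larger at this time point; it falls below the baseline from about
month five onward as the extra differentiation drains it. The same
comparison is available from the shell:

```sh
chondrosim compare --a both --b none --months 24 --out results/
chondrosim run --scenario none --months 24 --out results/baseline/
chondrosim sweep --param p12 --values 26.67,267 --months 2 --out results/sweep/
chondrosim convergence --grids 51,101,201 --months 2
```

Every run writes `profiles.csv`, `means.csv`, `params.json` and a
checksummed `manifest.json`; the model has no stochastic elements, so
identical configurations reproduce bit-for-bit.

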