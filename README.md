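# fcspat

Spatial point-pattern statistics for arid-grassland surveys of fairy
circles and Euphorbia shrubs.

Fairy circles (FCs) are circular bare-soil gaps in Namib-desert grasslands
whose hallmark is an extraordinarily ordered — spatially periodic — spacing:
each circle has about six nearest neighbors at nearly equal distances. A
long-standing hypothesis attributes FCs to the decay of Euphorbia shrubs.
If that were true, the spatial pattern of shrubs should be able to produce
the pattern of FCs mapped in the same plots. `fcspat` provides the
statistical machinery to test exactly that, plus seeded synthetic
generators so the entire pipeline runs and is validated without field data.

## What it computes

- **Nearest-neighbor statistics** — mean NN distance `r̄_A`, its CV, and the
  Clark-Evans index `R = r̄_A / r̄_E` with `r̄_E = 1/(2√λ)`, `λ = n/A`
  (no edge correction), with an exact conditional Monte-Carlo test against
  complete spatial randomness (CSR): two-sided rank p-value from 999 CSR
  simulations with the observed point count, labels Regular / Clustered /
  Random at α = 0.05.
- **Second-order statistics** — Ripley's `K(r)`, its transform
  `L(r) = √(K/π) − r`, and the kernel-estimated pair-correlation function
  `g(r)` (Epanechnikov kernel, Stoyan bandwidth `0.15/√λ`, translation edge
  correction), each with pointwise CSR simulation envelopes from the
  5th-lowest/highest of 199 simulations (≈ 95%).
- **Pattern classification** — regular / clustered / random / mixed /
  spatially periodic, the last detected as a significant trough-then-peak
  of `g(r)` against the envelopes with the peak near the mean NN distance.
- **Field comparisons** — diameter min/max/mean summaries, one-sided Welch
  t-tests (are the mega circles larger than the largest dead shrubs?), size
  ratios, and inside/outside infiltration-time descriptives.
- **Synthetic regimes** — jittered hexagonal lattices (periodic), simple
  sequential inhibition (regular), CSR (random), Matérn cluster processes
  (clustered shrubs), truncated-normal diameters and lognormal infiltration
  times matching the printed regimes, bundled per region by
  `make_study_fixture`.

See `docs/methods.md` for the formulas, defaults and their rationale.

## Worked example

```python
import fcspat as f

# a synthetic Giribes-like plot: periodic fairy circles, clustered shrubs
fx = f.make_study_fixture("Giribes", seed=11)

nn_fc = f.clark_evans_test(fx.fc_pattern, n_sim=999, seed=1)
nn_eu = f.clark_evans_test(fx.euphorbia_pattern, n_sim=999, seed=2)
print(nn_fc.to_row())
print(nn_eu.to_row())

env = f.csr_envelope(fx.fc_pattern, "g", n_sim=199, rank=5,
                     grid=f.DistanceGrid.regular(25, 0.5), seed=3)
print(f.classify_pattern(env, nn_fc))
```

prints

```
{'label': 'Giribes Fairy Circles', 'n': 2000, 'mean_nn_m': 9.5, 'cv_nn_pct': 14.2, 'clark_evans_R': 1.69, 'p_value': 0.002, 'pattern': 'Regular'}
{'label': 'Giribes Euphorbias', 'n': 152, 'mean_nn_m': 16.4, 'cv_nn_pct': 73.9, 'clark_evans_R': 0.81, 'p_value': 0.002, 'pattern': 'Clustered'}
spatially_periodic
```

The fairy-circle pattern is strongly regular (R = 1.69, p at the 0.002
floor of the 999-simulation rank test) and carries the periodic
trough-then-peak g-signature, while the shrub pattern in the same window is
significantly clustered (R = 0.81) — opposite pattern signatures, which is
the core of the argument that one cannot generate the other.

The same pipeline runs from the shell:

```
fcspat simulate --region Giribes --seed 1 --out fixture/
fcspat analyze fixture/giribes_fc_points.csv --window 500x500 --seed 0
fcspat envelope fixture/giribes_fc_points.csv --window 500x500 --statistic g
fcspat size-test fixture/giribes_diameters.csv --group-a FC --group-b dead_Euphorbia
fcspat infiltration fixture/giribes_infiltration.csv --region Giribes
```

To re-analyze the deposited survey coordinates (an XLSX workbook with one
sheet per plot × object type, not redistributed here), use

```
fcspat reproduce-table1 --data Additional_Spatial_Data_FCs_Euphorbias.xlsx
```

which prints each recomputed row next to the published values with
per-cell deltas.

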