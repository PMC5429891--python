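# stereovem

Design-based stereology for volume scanning electron microscopy (FIB-SEM,
SBF-SEM, array-SEM), built around the Golgi apparatus as the model organelle.

Volume-SEM instruments produce hundreds to thousands of serial sections per
cell. Reconstructing them exhaustively is slow and limits studies to a handful
of cells. Sampling-based stereology takes the opposite route: probe a tiny,
randomly placed fraction of the sections with geometric test systems and
convert the interaction counts into unbiased 3D quantities — volume, surface,
number, thickness, stack composition — with known precision. This package is
a simulation engine and estimation toolkit for that workflow: it generates
Golgi-like 3D phantoms with exact analytic ground truth, sections them
virtually under the standard sampling designs, applies the classical probes,
and verifies by Monte Carlo that every estimator recovers the truth.

It is intended for microscopists designing a sampling scheme before an
acquisition, for method developers who need a ground-truth test bed for
quantitation pipelines, and for teaching the estimators themselves.

## The estimators

With `P` point hits, `I` line/arc intersections, and `Q−` disector
disappearance counts, all pooled over images (ratio of sums):

| quantity | estimator | probe / design |
|---|---|---|
| volume fraction | `Vv = ΣP_str / ΣP_ref` | point grid, SUR sections |
| surface density | `Sv = 2ΣI / L`, `L = ΣP_ref · l_p` | IUR lines, or cycloids on vertical sections |
| absolute volume | `V = ΣA·k = ΣP·a·k` (Cavalieri) | SUR parallel stack, random start |
| number density | `Nv = ΣQ− / (ΣP·a·h)` | disector pair + point grid |
| total number | `N̂ = ΣQ− × spacing / directions` | SUR disector pairs along the stack |
| mean reference volume | `v̄ = ΣP·a·h / ΣQ−` | low-magnification disector |
| star area | `ā* = (π/3)·mean(l₀²)` | point-sampled intercepts, IUR sections |
| thickness | `t̂ = (π/4)·mean(w)`, `(8/3π)·harm(w)`, or `2/Ŝv` | hit-weighted apparent widths |

Standard errors of all ratio estimates use the classical Cochran ratio
estimator over images. Counting rules are the standard ones: the Gundersen
unbiased counting frame with forbidden line (tiling-exact), strict-sign-change
intersection counting (tangencies count zero), boundary points do not count.

## Worked example

Plan the classic vesicle count — adjacent-pair disectors every 50 sections
through a 250-section (5 µm / 20 nm) organelle, counting both directions:

```text
$ stereovem plan --sections 250 --use 5 --pair-spacing 50 --expected-n 1000
sampling fraction: 2%
inverse-fraction multiplier: 50
count multiplier (spacing/directions): 25
expected Q- per specimen: 40
warning: expected counts 40.0 outside the 100-200 band (advisory)
```

40 expected edge counts, each multiplied by 50/2 = 25, recover the ~1000
vesicles. The same design simulated end to end:

```python
>>> from stereovem.validation import copi_number_simulation
>>> out = copi_number_simulation(n_seeds=500, seed=0)
>>> round(out["mean_total_qminus"], 1), round(out["mean_number_estimate"])
(39.2, 980)
```

The mean total Q− per cell is ~40 and the inverse-fraction estimate is
unbiased for the true 1000 vesicles. Density estimation from a manual count
sheet works the same way from the CLI:

```text
$ stereovem estimate --counts counts.csv --out estimates.csv
Vv[cisterna/cell] = 0.236842 dimensionless (se 0.0139, n=2)
Sv[cisterna/cell] = 0.947368 1/um (se 0.0554, n=2)
```

`stereovem validate` runs the unbiasedness suite (Vv, Sv by IUR lines and by
vertical-section cycloids, total N, mean reference volume, star area) on
built-in phantoms and exits non-zero if any estimate departs from ground
truth by more than two standard errors.

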