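# persig — statistical significance for persistent homology

Persistent homology summarizes the multi-scale shape of a point cloud as
a diagram of cycles with birth and death radii, but deciding *which*
cycles are real structure and which are sampling noise has mostly been a
judgement call.  `persig` turns it into a hypothesis test.  It is aimed
at anyone who computes persistence diagrams from point data —
conformational ensembles, embedding spaces, dynamical-system
reconstructions, spatial samples — and wants a p-value per cycle instead
of "far from the diagonal".

## The statistic

For each degree-k cycle (k ≥ 1) with birth `b` and death `d`, take the
multiplicative persistence `π = d/b` and normalize:

    ℓ = A · log log π + B,    A = 1 (Rips), ½ (Čech),
    B = −λ − A · mean(log log π),   λ = 0.5772156649… (Euler–Mascheroni)

Across a remarkably wide range of sampling models the ℓ-values of noise
cycles follow one parameter-free law, the left-skewed Gumbel distribution
`F(x) = 1 − exp(−e^x)`.  That gives every cycle a p-value
`exp(−e^ℓ)`; cycles clearing the Bonferroni level `α/|dgm_k|` form the
signal part of the diagram.  Cycles still open at a truncation radius τ
are tested through the bound `π > τ/b`, and an iterative search raises τ
just far enough to decide each one — typically touching a small fraction
of the edges the full filtration would need.

The package bundles its own persistence backends (numba-compiled
Vietoris–Rips with boundary-matrix reduction, Čech via Delaunay–alpha in
2-D/3-D, plus an independent small-instance reduction oracle they are
tested against) and seedable samplers for a battery of synthetic models:
box, ball, annulus, sphere, beta/normal/Cauchy products, torus, Klein
bottle, projective plane, pentagon-linkage configuration space, Henneberg
surface, stratified spaces, Brownian paths, Lorenz trajectories, surface
meshes (OFF/PLY), time-delay embeddings, and a noisy figure-eight.

## Worked example: the figure eight

Two unit circles tangent at the origin, a neck gap of width `W`, 1000
sample points.  Is the second loop statistically real?

```sh
$ persig demo-eight --w 0.1 --n 1000 --seed 0
307 cycles tested at alpha=0.05 (Bonferroni level 0.000163); 2 significant
     birth      death      pi     ell     p_value  significant
  0.044331   0.980492 22.1175 2.43848 1.05904e-05         True
 0.0762297   0.977884 12.8281 2.34173 3.04571e-05         True
0.00705139 0.00894084 1.26795 1.15436   0.0419194        False
...
```

With a narrow neck both loops have π an order of magnitude above the
noise (which piles up at π ≈ 1.2) and both p-values clear the Bonferroni
level: two significant cycles.  Widening the neck to `W = 0.4` delays
the inner loop's birth to ≈ `W/2`, collapsing its ratio:

```sh
$ persig demo-eight --w 0.4 --n 1000 --seed 7
308 cycles tested at alpha=0.05 (Bonferroni level 0.000162); 1 significant
    birth    death      pi     ell     p_value  significant
0.0489826 0.979097 19.9887 2.24217 8.15945e-05         True
 0.206895 0.978486 4.72939 1.91402  0.00113593        False
```

Only the outer loop survives — the inner one (π ≈ 4.7, p ≈ 1.1e-3) is
no longer distinguishable from noise at the corrected level.

The same pipeline is available programmatically, sklearn-style:

```python
from persig import SignificantCycles, sample_eight
est = SignificantCycles(degree=1, filtration="cech", alpha=0.05)
est.fit(sample_eight(1000, neck_width=0.1, seed=0).points)
est.n_significant_        # -> 2
est.report_.to_frame()    # per-cycle birth, death, pi, ell, p-value
```

and as composable pieces (`sample`, `compute_diagram`, `ell_transform`,
`signal_features`, `find_infinite_threshold`) — see `docs/methods.md` for
the model, the algorithms, and the numerical choices.

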