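# Methods

## The statistical model

A point cloud `X` of `n` points, filtered by the Vietoris–Rips or the
Čech construction at growing radius `r`, produces a persistence diagram
`dgm_k`: a multiset of `(birth, death)` radii for the degree-`k` cycles
(`k = 1` loops, `k = 2` cavities) that appear and fill in along the
filtration.  Persistence of a cycle is measured multiplicatively,

    pi = death / birth,

because the ratio is scale-free and robust to outliers: two copies of the
same structure at different scales get the same `pi`, while a loop
spanned by a few distant outliers gets a large lifetime `death - birth`
but a small `pi`.

The package is built around one empirical regularity: if the diagram
contains only *noise* — cycles created by sampling randomness rather than
by the latent geometry of the support — then the normalized values

    ell = A * log(log(pi)) + B,
    A   = 1   (Rips)  or  1/2  (Čech),
    B   = -lambda - A * mean(log log pi),      lambda = 0.57721566490153...

follow, to a good approximation and across a very wide range of sampling
models, one parameter-free law: the left-skewed Gumbel distribution

    F(x) = 1 - exp(-exp(x)),    f(x) = exp(x - exp(x)),

whose mean is `-lambda` (the constant is hard-coded to 20 digits, not
recomputed).  The centering constant `B` makes `mean(ell) = -lambda` an
algebraic identity on every diagram, and because `log log` turns powers
into additive shifts absorbed by `B`, the `ell`-values are invariant to
`pi -> pi^c` — hence to the radius-vs-diameter and radius-vs-squared-radius
conventions that differ between persistence packages.  Only `A` is
filtration-specific.

### Hypothesis tests

Each degree-`k` cycle is tested against the null "this cycle is noise",
under which `ell ~ LGumbel`, so an observed `ell = x` has

    p-value = P(ell >= x) = exp(-exp(x)).

Testing all `m = |dgm_k|` cycles simultaneously uses the Bonferroni level
`alpha / m`, where `m` counts every tested cycle (finite and, for
truncated filtrations, still-open ones).  The surviving cycles form the
signal part of the diagram.  `B` is estimated from the finite cycles of
the diagram under test; in the log-log scale a handful of signal cycles
among hundreds of noise cycles shifts `B` negligibly.  For controlled
simulations a known `B` can be injected instead.

### Infinite (open) cycles

Computing a full filtration is often intractable, so the diagram is
truncated at a radius `tau`; cycles born before `tau` but not yet dead
are "open" and their `pi` is unknown.  Since `pi > tau/birth`, the map
above still yields an upper bound

    p-value  <  exp(-exp( A loglog(tau/birth) + B ))

(the ratio `tau/birth` passed through the `ell`-map — the only reading
consistent with the threshold update below).  If the bound already clears
the Bonferroni level the cycle is significant without ever knowing its
death.  Otherwise the truncation must grow.  Let `pi_min(x)` be the
smallest ratio whose p-value is below `x`:

    pi_min(x) = exp(exp( (loglog(1/x) - B) / A )).

The iterative search repeats: compute `D = dgm_k(tau)`; collect the open
cycles with `tau/birth < pi_min(alpha/|D|)` (undecided); if any remain,
set `tau <- min(I) * pi_min(alpha/|D|)` and recompute.  Choosing the
earliest birth (`min`) gives the smallest threshold but possibly more
iterations; `max` is available as an option.  The update is nudged up by
one part in 1e9 so that `tau/birth` clears `pi_min` strictly even after
roundoff — without it the search can stall exactly on the significance
boundary.  `tau` is capped (default: the cloud's enclosing radius, where
the Rips complex becomes a cone and nothing stays open; any smaller
budget cap may leave cycles undecided, which the trace flags).

Two limitations are inherent: the search only examines cycles *born* by
the current `tau` — the default starting radius is 1.5x the connectivity
radius (half the longest minimum-spanning-tree edge), by which cycles
bounded by gaps comparable to the sparsest region have typically
appeared, but a latent cycle born later needs a user-supplied `tau0`; and
the Bonferroni denominator `|D|` grows with `tau`, so a verdict reached
at truncation `tau*` can in principle differ from the full-filtration
verdict (in the consistency tests on annuli it never does).

## Computing persistence

All scales are radii: a Rips simplex enters at half its diameter, a Čech
simplex at its minimal-enclosing-ball radius, making the two filtrations
of one cloud directly comparable.  Three construction paths exist:

- **Rips (production)** — numba-compiled neighbor enumeration (edges,
  triangles, tetrahedra; degrees up to 2) followed by GF(2) boundary
  reduction in clearing order, dimension by dimension from the top.
  Degree 0 is done by union–find, which also labels the positive
  (cycle-creating) edges.  Columns are kept as sorted index arrays in a
  growable flat buffer; the pivot array pairs births to deaths.
- **Čech as Delaunay–alpha (production, d = 2, 3)** — scipy's Delaunay
  triangulation filtered by squared circumradii with the standard Gabriel
  rule: a simplex whose circumball contains a neighboring vertex inherits
  the smallest value among its cofaces.  For points in general position
  the positive-persistence content equals the true Čech diagram at a tiny
  fraction of the cost.
- **Oracle (reference)** — a deliberately simple, fully independent
  implementation: enumerate every simplex, sort simplexwise, reduce the
  boundary matrix with Python sets.  Capped at 64 points.  The same
  machinery drives a genuine Čech construction (brute-force minimal
  enclosing balls) valid in any ambient dimension for small clouds, which
  is also the fallback for Čech requests outside d = 2, 3.  The fast Rips
  path is tested to be multiset-identical to the oracle; the alpha path
  to agree on every feature of positive persistence.

Simplex-wise ties are broken by (value, dimension, lexicographic
vertices); the value multiset of the diagram does not depend on this
refinement.  Degenerate (cospherical/collinear) inputs fall back to
joggled Delaunay.

A full Rips diagram in positive degree is obtained by truncating at the
enclosing radius `min_i max_j d(i,j) / 2`, past which the complex is a
cone over the minimizing vertex and no cycle survives; the same inclusive
truncation is applied in the oracle, so the two filtrations are
identical.  A consequence shared by both: pairs of zero persistence born
beyond that radius are not enumerated.  Zero-persistence pairs that are
enumerated stay in the raw diagram and are dropped only at selection
time, together with zero-birth features.

For clouds too large to fill, `rips_auto_threshold` grows the truncation
geometrically (start: three median nearest-neighbor spacings, factor 1.5)
until no cycle of the requested degree — or a stated number of known
essential cycles — remains open.  On noise clouds the result has always
matched the larger-truncation diagram in testing, but late-born cycles
past the final radius are invisible in principle; the threshold is
recorded in the diagram.  A simplex budget (default 3e7) guards memory.

## Synthetic point clouds

The samplers reproduce the study battery: uniform box, ball and annulus
(radii 1/2 and 1, rejection sampling), spheres (normalized Gaussians),
iid products of beta/normal/Cauchy coordinates, the torus with radii
R1 = 2, R2 = 1, a Klein bottle and the real projective plane embedded in
R^4, the configuration space of unit pentagon linkages (two anchored
vertices, rejection when no pentagon closes, the two circle-intersection
branches for the free vertex taken with equal probability), the
Henneberg surface, a stratified plane-in-cube mixture, Brownian paths
(partial sums of iid Gaussian increments), and a Lorenz trajectory with
sigma = 45, rho = 54, beta = 10 started uniformly in the unit cube.
`dt = 0.1` is the sampling interval of the trajectory; at these stiff
parameter values one explicit step of that size diverges, so each sample
advances by 100 internal fixed RK4 substeps (forward Euler available,
same substepping).  Beta defaults to a = b = 2 (a smooth unimodal density
on the unit interval); the parameters are exposed.

Triangulated surfaces are sampled with triangle probability proportional
to area and uniform barycentric placement, giving the uniform surface
measure.  Scalar signals (text or PCM WAV) become point clouds by the
time-delay embedding with default stride 3 and lag 7.

The figure-eight testbed draws points uniformly on two unit circles
tangent at the origin, deletes a ball of diameter `W` (the neck gap) with
redrawing, and adds Gaussian jitter.  The jitter default is 0.0075 —
sub-percent relative to the loops.  This default matters: the detection
experiment tests every 1-cycle of the diagram at level `alpha/m`, and at
jitter a few times larger the alpha diagram of 1000 points fills with
hundreds of small noise cycles, deflating the Bonferroni level to the
point where the inner loop (and eventually both loops) cannot clear it.
The default keeps the tested family in the signal-dominated regime the
experiment is about, and the parameter is exposed for studying exactly
that transition.

What the generators do *not* emulate: measurement pipelines of real data
(image-patch preprocessing, learned embeddings), non-Euclidean metrics,
and homogeneous-spacing models (perturbed lattices, repulsive processes),
for which the universal law is known not to hold.  Passing tests on these
generators therefore says nothing about such data.

## Desk-scale study conditions

The shipped checks run on one CPU in minutes, at reduced problem sizes
chosen as the package's own study conditions: universality fit at
n = 2000 (box and torus, both filtrations, 20 seeds), detection on
1000-point figure-eights, error control over 100 null runs at n = 1000,
search consistency on 250-point annuli, and a 2000-point torus for the
edge-saving demonstration with a 0.6-radius budget cap.  The torus Rips
runs truncate once only the two essential loops remain open, so the
ensemble tested against the null is the noise part, mirroring the
practice of excluding known signal.

## Known limitations

- The one-sample KS test treats the `ell`-values as iid and `B` as known;
  both are false (features of one diagram are dependent, `B` is estimated
  from them).  The test is used as a diagnostic, not a calibrated test.
- At desk scale the right tail of the `pi`-ensemble is truncated — the
  largest noise ratio grows only logarithmically in `n` — so the
  empirical `ell`-distribution is slightly narrower than LGumbel.  The KS
  distance plateaus near 0.03 (d = 2, Čech, k = 1) rather than vanishing,
  and with thousands of values per diagram the full-sample KS p-value
  falls below 0.01 in roughly a fifth of seeds.  This is a property of
  finite samples, not of the computation: the same diagrams are
  multiset-exact against the reduction oracle.
- Under the Čech constant `A = 1/2` significance requires very large
  ratios: at a few hundred points an annulus hole (`pi` around 5–10) is
  not Bonferroni-significant, while the same cloud under Rips (`A = 1`)
  is.  Detection power differs markedly between filtrations at small `n`.
- Degree-0 features are never tested (`pi` is undefined at birth 0).
- The alpha path covers d = 2, 3; higher-dimensional Čech falls back to
  the small-instance construction, and Rips handles any dimension
  through distances.
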