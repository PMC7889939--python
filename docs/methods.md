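# Methods

## The model

The object computed throughout is a free energy surface (potential of mean
force) over collective variables: A(**d**) = −k_BT ln p(**d**) up to an
additive constant, where p is the marginal Boltzmann density of the six
inter-nucleosome distances **d** = (d12, d13, d14, d23, d24, d34).  Because
A depends only on internal coordinates, relabelling the nucleosomes in
reverse order must leave it unchanged: A(**d**) = A(**d̃**) with
**d̃** = (d34, d24, d14, d23, d13, d12).  The package enforces this exactly
by expressing A as a network over the symmetric features
s(**d**) = (d12+d34, d12·d34, d13+d24, d13·d24, d14, d23): each swapped pair
is encoded by its (sum, product), which determines the unordered pair
uniquely for positive distances, so the identification loses nothing beyond
the intended symmetry.

Units are fixed package-wide: nm, kcal/mol, Kelvin,
k_B = 0.0019872041 kcal/(mol·K).  Nucleosome centres are unweighted
centroids of beads labelled `core` (the rigid part of each nucleosome);
the radius of gyration is unweighted over all beads — coarse-grained beads
are near-uniform in mass at this resolution, and the choice is configurable
at the reader level (the CSV dialect carries per-bead labels).

## Samplers

All dynamics are overdamped Euler–Maruyama:
x ← x − (dt/γ)∇A + sqrt(2k_BT dt/γ)ξ.  Only equilibrium statistics matter
for mean forces, umbrella windows and string-cell sampling, so inertial
dynamics would add parameters without adding information.  Walkers reflect
at the rectangular domain bounds of each surface (reflection preserves the
Boltzmann law); leaving the domain by a large factor raises an instability
error naming the timestep.  Every sampler takes an explicit seed and is
bit-reproducible.

Biased exploration couples two accelerations.  Metadynamics deposits
repulsive Gaussian hills at the visited CV values (plain hills by default;
a well-tempered scaling factor is available).  TAMD tethers each CV
θ(x) to an extended variable z via a harmonic spring κ_ext and evolves z at
an elevated temperature T̄ ≥ T; the hills act on z.  With zero hills and
T̄ = T the physical marginal reduces to the unbiased Boltzmann law — a
property test.  CV gradients use the analytic chain rule when the CV
provides one, else central differences (step 1e−4 in CV units).

## Mean forces and force matching

Mean forces at K-means centres **d**ₒ are restrained-ensemble averages
**F**(**d**ₒ) = ⟨k(**d** − **d**ₒ)⟩ with an isotropic scalar spring k (the
per-component option exists), burn-in 20% of steps, and batch-means
standard errors over 20 batches.  On a quadratic surface of stiffness κ the
estimator is exactly −κ(**d**ₒ−μ)·k/(k+κ): biased toward zero by k/(k+κ),
vanishing as the restraint stiffens.  The tests assert both the closed form
and the monotone approach to −∇A.

The surface is a multilayer perceptron (default 6→64→64→1, tanh) over the
symmetric features, standardised to zero mean and unit variance on the
training centres — the raw features span 6–600 in mixed units (distances
and products of distances), and unnormalised inputs stall training.  A
smooth activation is required, not cosmetic: the string method consumes
∇A, so the learned gradient must be continuous.  Training minimises the
mean squared force residual |∇A(**d**ₒ) + **F**(**d**ₒ)|².  Because the
loss involves the network's input gradient, its weight gradient is a
second-order backward pass; the implementation derives it analytically
(a tangent sweep through the reverse pass plus a standard backward sweep
over the pre-activations) and the test suite verifies every component
against finite differences.  Optimisation is full-batch Adam with decoupled
weight decay (1e−5), learning rate 3e−3 decaying exponentially to 10% over
the run, early stopping on a 20% validation split with patience 50, best
weights restored.  Reported correlations are computed on the held-out split
only.  The energy gauge (force matching determines A only up to a constant)
is fixed by shifting the minimum over training centres to zero.

Predictions are trusted only near the data: a point is in the trusted
domain if its distance to the nearest training centre is at most twice the
95th percentile of the centres' nearest-neighbour distances.  Marginals of
a learned model integrate over the trusted region only, since the network
is unconstrained where no forces were ever estimated.

## Marginals

For analytic surfaces, marginals use closed forms when the Boltzmann factor
is an explicit Gaussian mixture (exact, zero standard error — this is the
oracle the learned surface is compared against), tensor Gauss–Legendre
quadrature for up to three integrated dimensions, and seeded uniform
Monte-Carlo with reported standard errors above that.  For learned models,
each grid value conditions an importance-sampled integral: the proposal
over the integrated coordinates is a Gaussian mixture centred on the
training centres, weighted by each centre's Boltzmann factor and its
proximity to the conditioning slice (component width 1.5× the median
nearest-neighbour distance).  Cells whose trusted volume captures no
samples are reported missing, not fabricated.  Profile comparisons remove
the mean offset over the common support first — profiles are gauge
quantities.

## WHAM

Umbrella windows are restrained Langevin runs on one coordinate; by default
three independent replicas per window are pooled, a hedge against a replica
trapping in one basin of a rugged landscape.  The solver iterates the
standard self-consistent equations over fixed-width bins (default 100)
until the window offsets move by less than 1e−6 kcal/mol.  Empty bins carry
zero counts and appear as missing values rather than being regularised —
silent smoothing would bias exactly the sparse regions one should distrust.
Non-overlapping adjacent windows converge but are flagged unreliable.

## String method

A pathway is M+1 images (default M = 32; the benchmark tests use 16–24).
Each iteration: (1) per-image Langevin sampling with proposals rejected
when their nearest image is not the cell's own — rejection sampling of the
cell-restricted Boltzmann law, chosen over reflecting walls because it is
exact and parameter-free; (2) images move a fraction α = 0.1 toward their
cell means; (3) interior smoothing with λ = 0.1; (4) equal-arc-length
reparameterisation by piecewise-linear interpolation.  Endpoints are fixed
at the supplied minima by default (a relaxed mode lets them move within
their own cells).  Convergence is a maximum image displacement below tol
(default 1e−3 CV units); with finite cell sampling the displacement floor
scales like sqrt(k_BT/n_cell_samples), so stochastic benchmark runs use
looser tolerances.  Path free energies are surface evaluations at the
images, shifted to zero at the reactant endpoint and indexed by image
number.  Multi-start protocols (default 8 initialisations through
perturbed waypoints; production-scale studies use many more) are clustered
by mean per-image Euclidean distance with single linkage.

## The synthetic benchmark and what it shows

`sym6d_wells` is A(**d**) = −k_BT ln[w_f G(**d**; c_f, 3 nm) +
w_o G(**d**; c_o, 3 nm)] at T = 300 K with reversal-symmetric centres
c_f = (9, 6, 12, 9, 6, 9) nm (compact, "folded") and
c_o = (15, 25, 32, 15, 25, 15) nm (extended, "open"), and weights making
the folded basin 2 kcal/mol deeper.  All constants are design choices of
the benchmark, frozen in code.  It reproduces the structural features the
method must cope with — six coupled dimensions, two basins separated by a
high ridge, exact index-reversal symmetry, mean forces only available at
scattered centres — and, being a Gaussian mixture, it has closed-form
marginals to validate against.

The benchmark's mean forces are drawn around the analytic gradient with
Gaussian noise of SD equal to 5% of the pooled force RMS, emulating the
statistical error of restrained simulations.  What it does not emulate:
systematic error in mean forces (finite spring, finite sampling
correlations), CV-space ruggedness on scales below the basin widths, the
anisotropy and multimodality of real chromatin landscapes, or any
force-field physics.  Passing the benchmark therefore demonstrates the
correctness and internal consistency of the machinery — not the accuracy
of any particular chromatin model.

Desk-scale problem sizes (chosen so the full pipeline runs in minutes on
one CPU): 400k biased steps saved every 20, 2,000 centres, a 64×64 network,
60-point marginals at 4,000 importance samples per point.  Production-scale
equivalents would raise each by one to two orders of magnitude; nothing in
the code fixes the scale.

## Known limitations

* The uniform Monte-Carlo fallback for high-dimensional marginals of
  generic (non-mixture) analytic surfaces has poor variance on tightly
  peaked integrands; it reports its standard error, but importance
  sampling is only implemented for learned models.
* The trusted-domain cutoff is a single global radius; strongly anisotropic
  centre clouds would merit per-region cutoffs.  Near the edge of the
  sampled region the learned marginal inherits a truncation bias visible
  as a small basin-dependent offset in the benchmark comparison.
* WHAM is 1-D only (no MBAR, no 2-D recombination) — it exists here as an
  independent cross-check, not as the primary estimator.
* `cluster_paths` uses single linkage on mean image distance; paths that
  hybridise between channels can chain clusters at intermediate
  thresholds.
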