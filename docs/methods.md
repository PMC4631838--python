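# Methods

## Scope and shape

`intmod` implements a four-stage integrative structure-determination
pipeline: (1) assemble and validate restraint datasets, (2) build a
multi-scale representation and translate data into a Bayesian scoring
function, (3) sample configurations by replica-exchange Gibbs Monte Carlo,
(4) analyze the solution ensemble. The repository is organized as an
analysis project: the computation lives in `src/intmod/`, and the numbered
scripts in `analysis/` are thin drivers that exercise it on synthetic
assemblies with known ground truth.

## Representation

Structured regions carry three scales. Fine beads sit one per residue at
the Cα. Coarse beads cover consecutive 10-residue segments (terminal
segment possibly shorter), centered at the segment's mass-weighted center;
segmentation starts at the first modeled residue of each rigid segment.
Each rigid body also carries a Gaussian-mixture density with
`max(1, n_residues // 50)` components, fitted by expectation–maximization to
its mass-weighted Cα point cloud — we fit the atom/Cα points directly
rather than going through a rasterized intermediate, which targets the same
density at lower cost. Unstructured regions become flexible strings: a
residue range is split into near-equal elements of at most 40 residues
(`ceil(n/40)` elements, the remainder distributed one residue at a time from
the front), each carrying a coarse bead and a co-centered isotropic
Gaussian.

Bead radii come from the statistical volume–residue relationship
`V(n) = n · v_res` with `v_res = 132.9 Å³` (a standard mean amino-acid
volume; the constant is configurable since published volume tables vary by
a few percent), so `r(n) = (3V/4π)^{1/3}`. The flexible-element Gaussian
variance is `r²/5` per axis — the variance of a uniform ball of the same
radius — so the Gaussian describes the same molecular volume as the bead.

Weighted EM fitting is implemented in the package (scikit-learn's
`GaussianMixture` does not accept sample weights, which density-weighted
voxel fits and mass-weighted point fits require); it is initialized with
scikit-learn's k-means and is checked against `GaussianMixture` on
unweighted fixtures in the test suite. Degenerate point clouds (all points
identical) yield a single component with covariance `reg_covar · I`.

## Scoring function

The score is the negative log posterior. Terms:

**Cross-link forward model.** `f(d; σᵢ, σⱼ, l_XL)` is the probability that
two points drawn uniformly from spheres of radii σᵢ, σⱼ centered `d` apart
are within `l_XL`. We evaluate it exactly as a one-dimensional integral:
the distance from a uniform point in one sphere to the other sphere's
center has a known piecewise closed-form density, and the fraction of a
sphere inside a ball is the standard two-sphere lens volume; their product
is integrated with 16-node Gauss–Legendre panels split at the breakpoints
of both piecewise forms, which is exact to machine precision for these
near-polynomial integrands (verified against adaptive quadrature and a
10⁶-sample Monte-Carlo oracle). Limit cases short-circuit exactly: `f = 1`
when `d + σᵢ + σⱼ ≤ l_XL`, `f = 0` when `d − σᵢ − σⱼ ≥ l_XL`. A single
global σ is used for all residues. `l_XL` defaults to 21 Å; a per-source
length increment is available for datasets collected with longer reagents
(default 0).

**Likelihood.** `p = ψ(1−f) + f(1−ψ)` per link, multiplied over links;
each link's log term is weighted by `w = min(1 + log2(n_spectra), 4)` —
spectral redundancy promotes well-evidenced links, with a cap so no single
link dominates. Site-ambiguous matches contribute their spectral count
divided equally over candidate residue pairs at the reporting stage.

**Nuisance priors.** σ is flat on [0, 100] Å. ψ is flat on [0.01, 0.30],
one value per link class (intra-module, inter-module), both sampled. The
upper bound matters: the likelihood form is a noise model only for
ψ < 0.5, and values approaching 0.5 make the likelihood nearly flat in the
coordinates — in early experiments with a 0.49 bound the sampler spent long
periods on that "links ignored" plateau before converging. 0.30 is far
above any plausible inconsistent-link fraction (the synthetic benchmark
plants 5% noise) while keeping every reported link informative. Sampling ψ
per class reproduces the automatic down-weighting of an inconsistent
class; a fixed-ψ mode is available by omitting the ψ movers.

**EM restraint.** Model and data mixtures are compared by
`CC = 2·ov(M,D)/(ov(M,M) + ov(D,D))` with `ov` the closed-form Gaussian
overlap integral; the score is `−scale·log CC`, `scale = 100`. Model
component weights are normalized to the component's mass fraction of the
restrained selection, data weights to 1. The printed generalized form of
the denominator in some descriptions of this score
(`ov(M,D) + ov(D,D)`) is inconsistent with the defining integral
`2∫f_M f_D / ∫(f_M² + f_D²)`; we implement the integral form, the only one
with `CC = 1` for identical densities. The restraint can be applied per
module (each module's model mixture against its segmented density).

**Structural priors.** Excluded volume: harmonic in the bead-sphere
overlap, `0.5·k·(rᵢ + rⱼ − d)²` for overlapping coarse-bead pairs, pairs
within one rigid body exempt, `k = 1 Å⁻²` (the restraint's functional form
is not fixed by convention; harmonic-on-overlap with unit force constant is
the simplest soft-sphere choice). Connectivity: harmonic upper bound at
`4·(rᵢ + rⱼ)` between sequence-consecutive segments. A weak linear
restraint, slope 0.01 Å⁻¹ times the sum of cross-link distances, provides
long-range attraction where the forward model has no gradient.

## Sampling

Metropolis-within-Gibbs: one sweep proposes, for each mobile element in a
fixed order, a symmetric random move (rigid bodies: translation uniform in
±2 Å per axis plus rotation by a uniform angle ≤0.04 rad about a random
axis through the body center; flexible beads: ±3 Å per axis; σ: ±0.5 Å;
ψ: ±0.02, clamped to bounds) and accepts with probability
`min(1, exp(−Δscore/T))`. Replicas run on a geometric temperature ladder
(the spacing is our choice; the range 1.0–2.5 is standard for this score
scale), with adjacent swaps attempted each sweep on alternating odd/even
pairs under the standard exchange criterion; temperatures multiply the full
score (likelihood and priors — tempering only the likelihood is a
configuration choice we did not take). Every run starts from an independent
random configuration: mobile bodies uniformly positioned and oriented
inside the density bounding box inflated by 20 Å, σ starting at 5 Å and ψ
at 0.05. The coldest chain is saved every 10 sweeps. All randomness flows
from spawned `numpy` SeedSequences, so runs are bitwise reproducible and
scheduling-independent; a single-replica ladder reduces exactly to plain
Metropolis.

## Analysis

Solutions are compared by size-weighted RMSD over coarse-scale bead
centers, `sqrt(Σ n_b |Δx_b|² / Σ n_b)`, without superposition (the EM
restraint fixes the global frame). The best-scoring frames (default 500)
are clustered by k-medoids (PAM) on the precomputed RMSD matrix —
"k-means by RMSD" has no exact centroid under a size-weighted metric, and
the medoid is precisely the cluster-center definition used downstream
(minimal summed RMSD to the other members). Initialization is
deterministic (most-central point first, then farthest-point seeding), and
clusters are reported in order of ascending mean score with per-cluster
precision (mean RMSD of members to the center) and between-cluster mean
RMSD; k comes from configuration, with the within/between table as the
guide for choosing it. Per-residue RMSF is the root-mean-square distance of
the residue's bead center from its cluster-center position. Localization
densities rasterize each bead as a hard sphere on a voxel grid (Gaussian
rasterization optional) and average binary occupancy over the cluster;
values are probabilities in [0, 1], displayed at an 0.15 iso-threshold.
Contact maps use bead surface distance (center distance minus radii) below
10 Å, aggregated over 200-residue sequence domains as "any bead pair in
contact", reported as frequencies over the cluster. Cross-link
satisfaction compares per-link distances on the cluster center (and the
per-link minimum over the cluster, since either convention is defensible)
against a threshold — 35 Å for Cα-level validation against known
structures, the generation cutoff for synthetic recovery; endpoints
represented by flexible beads subtract the bead radius first, because the
threshold is calibrated for Cα pairs. Exhaustiveness splits runs into
halves and cross-correlates per-subunit localization densities on a common
grid, using a small top-scoring fraction of each half's frames (the
production-scale version of this protocol compares the best fraction of a
percent of each half). Jackknifing removes `floor(fraction·N)` links uniformly at random
(seeded). Density segmentation subtracts the rasterized fixed-component
mixture (scaled to its mass fraction of the map) and partitions the
remaining above-threshold voxels by a plane sweep along the remainder's
principal axis so that module volumes are proportional to module masses —
a deterministic realization of volume-proportional apportionment; the
resulting boundary is a plane, which matches the analytic expectation on
symmetric test maps.

## Synthetic data

The generator emulates the statistical structure the method assumes, not
any real complex. Subunits are compact self-avoiding Cα chains (3.8 Å
bonds, 4 Å self-avoidance, confined to 1.35× the volume-equivalent radius)
placed by breadth-first traversal of a contact graph so that contact-edge
pairs approach within 8 Å, non-edges stay beyond 25 Å, and nothing
clashes; packing retries are bounded and failure raises. The default
benchmark is a 4-subunit assembly A–B–C–D (chain contacts plus an A–C
edge) of distinct subunit sizes (80/65/50/45 residues) in two modules
({A,B}, {C,D}), with A fixed (the docked component) and B split into two
rigid domains joined by a 10-residue flexible linker — exercising every
representation type. Distinct sizes and a non-minimal contact graph
reflect real assemblies and keep the ground truth identifiable: with
identical subunit masses the EM term is nearly permutation-invariant, and
a minimal chain leaves wide "patch-rotation" decoy basins in which a
subunit keeps its interface links satisfied while rotated about the
contact patch.

Cross-links: `n_true` residue pairs drawn from pairs within the 21 Å
cutoff whose endpoints belong to different rigid bodies or flexible beads
(within-body pairs carry no restraint information), plus
`ceil(nf/(1−nf)·n_true)` noise pairs uniform over all residue pairs (they
may satisfy the cutoff by chance; recovery statistics use the hidden
truth labels, not distances). Spectral counts are geometric(0.5). The
density is a mixture fitted to the true residue positions (one component
per 10 residues — the data mixture represents the map faithfully, unlike
the deliberately coarse model mixtures; effective resolution is set by the
blur) with covariances inflated by a 5 Å blur — features on the ~15–20 Å
scale, comparable to the maps this method is used with — and rasterized at
4 Å voxels. In the recovery benchmark the EM restraint is applied per
module (each module's model mixture against that module's density), the
same segmentation-based arrangement used for real maps. CSM tables draw target classifier scores from
N(separation, 1) and decoys from N(0, 1) with a 10× decoy excess, plus
auxiliary columns spanning the quality-filter thresholds.

What the generator does not emulate: real fold geometry and surface
chemistry, lysine-specific linkage, digestion and detectability biases,
non-uniform noise (real spurious links correlate with abundance), and map
artifacts (anisotropy, missing density). Passing the recovery benchmark
therefore demonstrates the correctness and convergence of the machinery on
data satisfying the model's assumptions, not performance on real XL-MS
data.

## Benchmark sizes and determinism

The recovery benchmark runs 8 replicas × 5000 sweeps × 4 independent runs
(~2000 saved frames, about 12 minutes on one CPU), clusters the 500 best
frames into k = 2, and checks: every mobile subunit's weighted RMSD to
ground truth below twice the 10-residue coarse-bead radius (≈13.6 Å),
intra-module satisfaction at the generation cutoff ≥ 90%, recovered
ψ_intra within 0.1 of the planted noise fraction, and half-versus-half
localization-density cross-correlation > 0.8 per subunit. The production
scale of such studies (tens of replicas, tens of runs, >10⁵ models) is
reachable through the same configuration parameters.

## Known limitations

- The forward model assumes a single global σ; per-residue uncertainties
  are out of scope.
- Orientational convergence is bounded by the 0.04 rad move size; assemblies
  with many same-mass subunits have permutation-degenerate EM landscapes
  and may need more runs than the desk-scale default. In particular, the
  half-versus-half localization-density agreement reported by the
  exhaustiveness check depends on every half containing deeply converged
  runs; with only two runs per half, run-to-run differences in convergence
  depth dominate this statistic, and the production-scale version of the
  protocol (many runs per half) is the appropriate setting for a strict
  convergence claim.
- k-medoids with deterministic seeding can split a single broad basin when
  k exceeds the number of truly distinct states; inspect the within/between
  RMSD table before trusting a particular k.
- MRC I/O supports isotropic voxels only; anisotropic maps are rejected
  explicitly.
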