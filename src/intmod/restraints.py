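"""The Bayesian scoring function.

The score is the negative log of likelihood times prior.  The cross-link
likelihood uses a forward model f(d): the probability that two points drawn
uniformly from spheres of radius sigma centered on the linked residues lie
within the maximum linker length l_XL of each other, combined with a
per-class uncertainty psi via  p = psi*(1-f) + f*(1-psi).  The prior
comprises excluded volume, sequence connectivity, a weak linear
distance restraint on cross-links, a flat prior on sigma over [0, 100] Å,
and the EM restraint -scale*log CC between the model and data Gaussian
mixtures, with CC = 2*ov(M,D) / (ov(M,M) + ov(D,D)).

The forward model is evaluated by exact 1-D quadrature: the density of the
distance from a uniform point in one sphere to the other sphere's center is
known in closed form, as is the fractional overlap volume of two spheres;
their product is integrated with Gauss-Legendre panels split at the
piecewise-form breakpoints, which is exact to near machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .representation import GMM

__all__ = [
    "NuisanceParams",
    "RestraintParams",
    "ScoreBreakdown",
    "forward_model",
    "crosslink_likelihood",
    "gmm_overlap",
    "em_score",
    "excluded_volume_score",
    "connectivity_score",
    "sigma_prior",
    "PosteriorScorer",
    "redundancy_weight",
]

INTRA = "intra_module"
INTER = "inter_module"

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(16)


@dataclass
class NuisanceParams:
    """Sampled nuisance parameters: a single position-uncertainty radius
    sigma (Å) for all residues, and one cross-link uncertainty psi per
    class."""

    sigma: float = 5.0
    psi: dict = field(default_factory=lambda: {INTRA: 0.05, INTER: 0.05})

    def copy(self) -> "NuisanceParams":
        return NuisanceParams(sigma=self.sigma, psi=dict(self.psi))


@dataclass
class RestraintParams:
    l_xl: float = 21.0  # maximum Cα-Cα linker length, Å
    slope: float = 0.01  # linear-prior slope, Å^-1
    em_scale: float = 100.0  # EM score scaling factor
    connectivity_factor: float = 4.0  # threshold = factor * (r1 + r2)
    k_excluded: float = 1.0  # harmonic force constant on bead overlap
    k_connectivity: float = 1.0
    redundancy_cap: float = 4.0  # cap on w = 1 + log2(n_spectra)
    sigma_bounds: tuple = (0.0, 100.0)
    # psi well below 0.5: a reported link must always carry appreciable
    # positive evidence.  Near 0.5 the likelihood is almost flat in the
    # coordinates, which both admits the degenerate "everything is noise"
    # solution and creates a vast plateau where cross-links stop guiding
    # the sampler.
    psi_bounds: tuple = (0.01, 0.30)
    # per-source increment to l_xl (longer reagents), Å
    source_length_increment: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("l_xl", "slope", "em_scale", "connectivity_factor",
                     "k_excluded", "k_connectivity", "redundancy_cap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ScoreBreakdown:
    crosslink: float = 0.0
    em: float = 0.0
    excluded_volume: float = 0.0
    connectivity: float = 0.0
    linear: float = 0.0
    sigma_prior: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.crosslink
            + self.em
            + self.excluded_volume
            + self.connectivity
            + self.linear
            + self.sigma_prior
        )

    def as_dict(self) -> dict:
        return {
            "crosslink": self.crosslink,
            "em": self.em,
            "excluded_volume": self.excluded_volume,
            "connectivity": self.connectivity,
            "linear": self.linear,
            "sigma_prior": self.sigma_prior,
            "total": self.total,
        }


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def _sphere_overlap_fraction(t, r_ball, r_sphere):
    """Fraction of a sphere of radius ``r_sphere``, centered at distance
    ``t`` from a point, lying within the ball of radius ``r_ball`` around
    that point.  Vectorized in ``t``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    full = t + r_sphere <= r_ball
    out[full] = 1.0
    engulfed = (t + r_ball <= r_sphere) & ~full
    out[engulfed] = (r_ball / r_sphere) ** 3
    lens = (~full) & (~engulfed) & (t < r_ball + r_sphere)
    if lens.any():
        tl = t[lens]
        v = (
            np.pi
            * (r_ball + r_sphere - tl) ** 2
            * (
                tl**2
                + 2 * tl * r_sphere
                - 3 * r_sphere**2
                + 2 * tl * r_ball
                + 6 * r_ball * r_sphere
                - 3 * r_ball**2
            )
            / (12.0 * tl)
        )
        out[lens] = v / (4.0 / 3.0 * np.pi * r_sphere**3)
    return out


def _point_in_sphere_distance_pdf(t, d, radius):
    """Density of the distance from a uniform point in a sphere of given
    radius (centered at the origin) to a fixed point at distance ``d``.
    ``t`` may be (n, k) with per-row distances ``d`` of shape (n,)."""
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if t.ndim == 2:
        d = d[:, None]
    out = np.zeros_like(t)
    inner = t <= radius - d  # full sphere shells (point inside the sphere)
    np.copyto(out, 3.0 * t**2 / radius**3, where=inner)
    safe_d = np.maximum(d, 1e-12)
    cap = (~inner) & (t >= np.abs(radius - d)) & (t <= radius + d)
    np.copyto(
        out,
        3.0 * t * (radius**2 - (d - t) ** 2) / (4.0 * radius**3 * safe_d),
        where=cap,
    )
    return out


def forward_model(d, sigma_i, sigma_j, l_xl) -> float | np.ndarray:
    """Probability that two points drawn uniformly from spheres of radii
    sigma_i and sigma_j, centered distance ``d`` apart, are within ``l_xl``
    of each other.  Continuous, non-increasing in d, non-decreasing in l_xl.
    Vectorized over ``d``.
    """
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    if sigma_i <= 0 or sigma_j <= 0:
        raise ValueError("sphere radii must be positive")
    if (d_arr < 0).any():
        raise ValueError("distance must be non-negative")
    out = np.empty_like(d_arr)
    hi_all = d_arr + sigma_i + sigma_j
    lo_all = np.maximum(0.0, d_arr - sigma_i - sigma_j)
    out[hi_all <= l_xl] = 1.0
    out[lo_all >= l_xl] = 0.0
    todo = (hi_all > l_xl) & (lo_all < l_xl)
    if todo.any():
        dv = d_arr[todo]
        lo = np.maximum(0.0, dv - sigma_i)
        hi = dv + sigma_i
        # breakpoints of the piecewise integrand, clipped to the support
        bps = np.stack(
            [
                lo,
                np.clip(np.abs(sigma_i - dv), lo, hi),
                np.clip(abs(l_xl - sigma_j), lo, hi),
                np.clip(l_xl + sigma_j, lo, hi),
                hi,
            ],
            axis=1,
        )
        bps = np.sort(bps, axis=1)
        half = 0.5 * np.diff(bps, axis=1)  # (n, n_seg)
        mid = 0.5 * (bps[:, 1:] + bps[:, :-1])
        t = (mid[:, :, None] + half[:, :, None] * _GL_NODES).reshape(len(dv), -1)
        wq = (half[:, :, None] * _GL_WEIGHTS).reshape(len(dv), -1)
        pdf = _point_in_sphere_distance_pdf(t, dv, sigma_i)
        frac = _sphere_overlap_fraction(t.ravel(), l_xl, sigma_j).reshape(t.shape)
        out[todo] = np.clip((pdf * frac * wq).sum(axis=1), 0.0, 1.0)
    return float(out[0]) if np.isscalar(d) or np.ndim(d) == 0 else out


def crosslink_likelihood(f, psi):
    """p(d_n | X, psi) = psi*(1 - f) + f*(1 - psi)."""
    return psi * (1.0 - np.asarray(f)) + np.asarray(f) * (1.0 - psi)


def redundancy_weight(n_spectra, cap: float = 4.0):
    """Spectral-redundancy weight w = 1 + log2(n_spectra), capped."""
    return np.minimum(1.0 + np.log2(np.asarray(n_spectra, dtype=float)), cap)


# ---------------------------------------------------------------------------
# GMM overlap and EM score
# ---------------------------------------------------------------------------


def _overlap_arrays(w1, m1, c1, w2, m2, c2) -> float:
    S = c1[:, None, :, :] + c2[None, :, :, :]
    det = np.linalg.det(S)
    if (det <= 0).any():
        raise ValueError("non-positive-definite covariance sum")
    diff = m1[:, None, :] - m2[None, :, :]
    inv = np.linalg.inv(S)
    q = np.einsum("nmi,nmij,nmj->nm", diff, inv, diff)
    kern = (2.0 * np.pi) ** (-1.5) * det**-0.5 * np.exp(-0.5 * q)
    return float((w1[:, None] * w2[None, :] * kern).sum())


def gmm_overlap(a: GMM, b: GMM) -> float:
    """Integral of the product of two Gaussian mixtures (symmetric)."""
    return _overlap_arrays(
        a.weights, a.means, a.covariances, b.weights, b.means, b.covariances
    )


def gmm_cross_correlation(model_gmm: GMM, data_gmm: GMM, ov_dd: float | None = None) -> float:
    ov_md = gmm_overlap(model_gmm, data_gmm)
    ov_mm = gmm_overlap(model_gmm, model_gmm)
    if ov_dd is None:
        ov_dd = gmm_overlap(data_gmm, data_gmm)
    return 2.0 * ov_md / (ov_mm + ov_dd)


def em_score(model_gmm: GMM, data_gmm: GMM, scale: float = 100.0) -> float:
    """-scale * log CC; non-negative, zero iff the mixtures coincide as
    densities.  Both mixtures are normalized to unit total weight before
    comparison (model weights are mass fractions of the module)."""
    cc = gmm_cross_correlation(model_gmm.normalized(), data_gmm.normalized())
    cc = max(cc, 1e-300)  # guard against underflow for far-apart mixtures
    return -scale * float(np.log(cc))


# ---------------------------------------------------------------------------
# Structural priors
# ---------------------------------------------------------------------------


def excluded_volume_score(
    centers: np.ndarray,
    radii: np.ndarray,
    pairs: tuple | None = None,
    k: float = 1.0,
) -> float:
    """Harmonic penalty on bead-sphere overlap: 0.5*k*(r_i + r_j - d)^2 for
    overlapping pairs, zero otherwise.  ``pairs`` restricts evaluation (used
    to exempt pairs within one rigid body)."""
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    if pairs is None:
        ii, jj = np.triu_indices(len(centers), k=1)
    else:
        ii, jj = pairs
    if len(ii) == 0:
        return 0.0
    d = np.linalg.norm(centers[ii] - centers[jj], axis=1)
    overlap = radii[ii] + radii[jj] - d
    overlap = overlap[overlap > 0]
    return 0.5 * k * float((overlap**2).sum())


def connectivity_score(
    distances: np.ndarray,
    radii_a: np.ndarray,
    radii_b: np.ndarray,
    factor: float = 4.0,
    k: float = 1.0,
) -> float:
    """Harmonic upper bound on sequence-consecutive bead distances with
    threshold factor*(r_a + r_b)."""
    d = np.asarray(distances, float)
    thr = factor * (np.asarray(radii_a, float) + np.asarray(radii_b, float))
    excess = d - thr
    excess = excess[excess > 0]
    return 0.5 * k * float((excess**2).sum())


def sigma_prior(sigma: float, bounds=(0.0, 100.0)) -> float:
    """Negative log of a flat prior: 0 inside the bounds, +inf outside."""
    return 0.0 if bounds[0] <= sigma <= bounds[1] else np.inf


# ---------------------------------------------------------------------------
# Full posterior scorer
# ---------------------------------------------------------------------------


class PosteriorScorer:
    """Evaluates the full negative-log-posterior for a model state.

    Parameters
    ----------
    model : MultiScaleModel
    xlset : CrossLinkSet
        Links must have endpoints resolvable to beads; unclassified links
        count as intra-module.
    em_data : list[(subunit selection or None, data GMM)] | GMM | None
        Each entry restrains the selected subunits' model mixture to its
        data mixture.
    """

    def __init__(self, model, xlset, em_data=None, params: RestraintParams | None = None):
        self.model = model
        self.params = params or RestraintParams()
        p = self.params

        # -- cross-links -> flat arrays
        links = list(xlset) if xlset is not None else []
        self.links = links
        end_refs = []
        self.xl_weights = np.empty(len(links))
        self.xl_class = np.empty(len(links), dtype=int)  # 0 intra, 1 inter
        self.xl_length = np.empty(len(links))
        for n, xl in enumerate(links):
            a = model.endpoint_of(xl.protein1, xl.residue1)
            b = model.endpoint_of(xl.protein2, xl.residue2)
            end_refs.append((a, b))
            self.xl_weights[n] = redundancy_weight(xl.n_spectra, p.redundancy_cap)
            self.xl_class[n] = 0 if (xl.xl_class or INTRA) == INTRA else 1
            inc = max(
                (v for s, v in p.source_length_increment.items() if s in (xl.source or "")),
                default=0.0,
            )
            self.xl_length[n] = p.l_xl + inc
        # group endpoint refs by owner for vectorized coordinate gathering
        self._rb_gather = []  # (body index, local coords (m,3), rows, sides)
        self._flex_gather = []  # (flex indices, rows, sides)
        by_body: dict = {}
        by_flex_rows, by_flex_sides, by_flex_idx = [], [], []
        for n, (a, b) in enumerate(end_refs):
            for side, ref in enumerate((a, b)):
                if ref[0] == "rb":
                    by_body.setdefault(ref[1], []).append((n, side, ref[2]))
                else:
                    by_flex_rows.append(n)
                    by_flex_sides.append(side)
                    by_flex_idx.append(ref[1])
        for bi, items in by_body.items():
            rows = np.array([t[0] for t in items])
            sides = np.array([t[1] for t in items])
            local = model.rigid_bodies[bi].fine_local[[t[2] for t in items]]
            self._rb_gather.append((bi, local, rows, sides))
        self._flex_rows = np.array(by_flex_rows, dtype=int)
        self._flex_sides = np.array(by_flex_sides, dtype=int)
        self._flex_idx = np.array(by_flex_idx, dtype=int)

        # -- excluded volume pairs (exempt pairs within one rigid body)
        owner_body = np.array(
            [o[1] if o[0] == "rb" else -1 - o[1] for o in model.bead_owner]
        )
        ii, jj = np.triu_indices(len(owner_body), k=1)
        keep = ~((owner_body[ii] == owner_body[jj]) & (owner_body[ii] >= 0))
        self._ev_pairs = (ii[keep], jj[keep])

        # -- connectivity
        self._conn_refs_a = [c[0] for c in model.connectivity]
        self._conn_refs_b = [c[1] for c in model.connectivity]
        self._conn_ra = np.array([c[2] for c in model.connectivity])
        self._conn_rb = np.array([c[3] for c in model.connectivity])

        # -- EM restraint: precompute static arrays per entry
        self._em = []
        if em_data is not None:
            if isinstance(em_data, GMM):
                em_data = [(None, em_data)]
            for subunits, dgmm in em_data:
                dnorm = dgmm.normalized()
                ov_dd = gmm_overlap(dnorm, dnorm)
                body_parts = []  # (body index, mass weights, local means, local covs)
                flex_parts = []  # (flex index, mass, covariance)
                for bi, body in enumerate(model.rigid_bodies):
                    if subunits is not None:
                        body_subunits = {su for su, _ in body.fine_keys}
                        if not (body_subunits & set(subunits)):
                            continue
                    g = body.gmm_local
                    body_parts.append((bi, g.weights, g.means, g.covariances))
                for qi, fb in enumerate(model.flex_beads):
                    if subunits is not None and fb.subunit not in subunits:
                        continue
                    flex_parts.append((qi, fb.mass, fb.var * np.eye(3)))
                total_mass = sum(p[1].sum() for p in body_parts) + sum(
                    p[1] for p in flex_parts
                )
                if total_mass <= 0:
                    raise ValueError("empty subunit selection for EM restraint")
                wm = np.concatenate(
                    [p[1] for p in body_parts] + [np.array([p[1]]) for p in flex_parts]
                    if flex_parts
                    else [p[1] for p in body_parts]
                ) / total_mass
                self._em.append(
                    (body_parts, flex_parts, wm, dnorm, ov_dd)
                )

    # -- individual terms --------------------------------------------------

    def link_coords(self, state) -> np.ndarray:
        P = np.empty((len(self.links), 2, 3))
        for bi, local, rows, sides in self._rb_gather:
            P[rows, sides] = local @ state.rot[bi].T + state.trans[bi]
        if len(self._flex_rows):
            P[self._flex_rows, self._flex_sides] = state.flex[self._flex_idx]
        return P

    def link_distances(self, state) -> np.ndarray:
        P = self.link_coords(state)
        return np.linalg.norm(P[:, 0] - P[:, 1], axis=1)

    def crosslink_score(self, state, distances=None) -> float:
        """-sum_n w_n log p(d_n | X, psi_class(n))."""
        if not self.links:
            return 0.0
        d = self.link_distances(state) if distances is None else distances
        sigma = max(state.nuisances.sigma, 1e-3)
        psi_vec = np.array(
            [state.nuisances.psi[INTRA], state.nuisances.psi[INTER]]
        )[self.xl_class]
        if np.all(self.xl_length == self.xl_length[0]):
            f = forward_model(d, sigma, sigma, self.xl_length[0])
        else:
            f = np.array(
                [forward_model(dn, sigma, sigma, ln) for dn, ln in zip(d, self.xl_length)]
            )
        pr = crosslink_likelihood(f, psi_vec)
        return -float((self.xl_weights * np.log(np.maximum(pr, 1e-300))).sum())

    def em_term(self, state) -> float:
        total = 0.0
        for body_parts, flex_parts, wm, dnorm, ov_dd in self._em:
            means, covs = [], []
            for bi, _, m_local, c_local in body_parts:
                R, t = state.rot[bi], state.trans[bi]
                means.append(m_local @ R.T + t)
                covs.append(np.einsum("ij,njk,lk->nil", R, c_local, R))
            for qi, _, cov in flex_parts:
                means.append(state.flex[qi][None, :])
                covs.append(cov[None])
            mM = np.vstack(means)
            cM = np.vstack(covs)
            ov_md = _overlap_arrays(wm, mM, cM, dnorm.weights, dnorm.means, dnorm.covariances)
            ov_mm = _overlap_arrays(wm, mM, cM, wm, mM, cM)
            cc = max(2.0 * ov_md / (ov_mm + ov_dd), 1e-300)
            total += -self.params.em_scale * np.log(cc)
        return float(total)

    def evaluate(self, state) -> ScoreBreakdown:
        p = self.params
        bd = ScoreBreakdown()
        bd.sigma_prior = sigma_prior(state.nuisances.sigma, p.sigma_bounds)
        lo, hi = p.psi_bounds
        for v in state.nuisances.psi.values():
            if not (lo <= v <= hi):
                bd.sigma_prior = np.inf
        if not np.isfinite(bd.sigma_prior):
            return bd

        if self.links:
            d = self.link_distances(state)
            bd.crosslink = self.crosslink_score(state, distances=d)
            bd.linear = p.slope * float(d.sum())
        centers = self.model.coarse_centers(state)
        bd.excluded_volume = excluded_volume_score(
            centers, self.model.bead_radii, self._ev_pairs, p.k_excluded
        )
        if self._conn_refs_a:
            ca = self.model.coarse_ref_coords(state, self._conn_refs_a)
            cb = self.model.coarse_ref_coords(state, self._conn_refs_b)
            dist = np.linalg.norm(ca - cb, axis=1)
            bd.connectivity = connectivity_score(
                dist, self._conn_ra, self._conn_rb, p.connectivity_factor, p.k_connectivity
            )
        bd.em = self.em_term(state)
        return bd

    def __call__(self, state) -> float:
        return self.evaluate(state).total


def crosslink_score(model, state, xlset, nuisances=None, params=None) -> float:
    """Functional wrapper: cross-link term of the posterior for one state."""
    scorer = PosteriorScorer(model, xlset, em_data=None, params=params)
    if nuisances is not None:
        state = state.with_nuisances(nuisances)
    return scorer.crosslink_score(state)


def total_score(scorer: PosteriorScorer, state) -> ScoreBreakdown:
    """Full per-term breakdown; ``breakdown.total`` is their sum."""
    return scorer.evaluate(state)
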