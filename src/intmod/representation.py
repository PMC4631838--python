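"""Multi-scale representation of an assembly.

Structured regions (crystal structures, comparative models, or synthetic
ground-truth folds) carry three simultaneous scales:

* fine — one bead per residue, centered on the Cα atom;
* coarse — one bead per 10-residue segment, centered on the segment's
  mass-weighted center, with a radius derived from the statistical
  volume-per-residue relationship;
* density — a Gaussian mixture model (GMM) approximating the region's mass
  density, with one component per 50 residues (floor division, minimum 1).

Unstructured regions are flexible strings: each element covers up to 40
residues and carries a single coarse bead plus a co-centered spherical
Gaussian describing the segment's molecular volume.

Within a rigid body all beads and Gaussians keep fixed relative positions;
a pose (rotation + translation) moves them together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .io_formats import MEAN_RESIDUE_MASS, TopologyConfig, VoxelMap

__all__ = [
    "MEAN_RESIDUE_VOLUME",
    "GMM",
    "Bead",
    "RigidBody",
    "FlexBead",
    "MultiScaleModel",
    "bead_radius",
    "build_beads",
    "split_flexible_range",
    "build_flexible_string",
    "fit_gmm",
    "gmm_from_voxels",
    "build_model",
]

# mean amino-acid volume (Å^3); standard protein density
MEAN_RESIDUE_VOLUME = 132.9
# residues per Gaussian component for structured regions
RESIDUES_PER_GAUSSIAN = 50
# residues per coarse bead in structured regions
COARSE_SEGMENT = 10
# maximum residues per flexible-string element
MAX_FLEX_RESIDUES = 40

_LOG_2PI = np.log(2.0 * np.pi)


def bead_radius(n_residues: int, v_res: float = MEAN_RESIDUE_VOLUME) -> float:
    """Radius of a bead covering ``n_residues``, from V(n) = n * v_res."""
    if n_residues < 1:
        raise ValueError("a bead must cover at least one residue")
    return float((3.0 * n_residues * v_res / (4.0 * np.pi)) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# Gaussian mixtures
# ---------------------------------------------------------------------------


@dataclass
class GMM:
    """Weighted 3-D Gaussian mixture."""

    weights: np.ndarray  # (n,)
    means: np.ndarray  # (n, 3)
    covariances: np.ndarray  # (n, 3, 3)

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float).reshape(-1, 3, 3)
        if (self.weights < 0).any():
            raise ValueError("GMM weights must be non-negative")
        # symmetric positive-definite check (cheap: Cholesky)
        try:
            np.linalg.cholesky(self.covariances)
        except np.linalg.LinAlgError as exc:
            raise ValueError("GMM covariances must be positive-definite") from exc

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    def normalized(self) -> "GMM":
        return GMM(self.weights / self.weights.sum(), self.means, self.covariances)

    def scaled(self, factor: float) -> "GMM":
        return GMM(self.weights * factor, self.means, self.covariances)

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "GMM":
        means = self.means @ rot.T + trans
        covs = np.einsum("ij,njk,lk->nil", rot, self.covariances, rot)
        return GMM(self.weights.copy(), means, covs)

    def density(self, points: np.ndarray) -> np.ndarray:
        """Mixture density evaluated at (N, 3) points."""
        points = np.atleast_2d(points)
        out = np.zeros(len(points))
        for w, mu, cov in zip(self.weights, self.means, self.covariances):
            L = np.linalg.cholesky(cov)
            y = np.linalg.solve(L, (points - mu).T)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            lp = -0.5 * (y**2).sum(axis=0) - 0.5 * (3 * _LOG_2PI + logdet)
            out += w * np.exp(lp)
        return out

    def rasterize(
        self, spacing: float = 4.0, margin_sigmas: float = 3.5, grid: VoxelMap | None = None
    ) -> VoxelMap:
        """Evaluate the mixture on a voxel grid (new or matching ``grid``)."""
        if grid is None:
            sd = np.sqrt(np.linalg.eigvalsh(self.covariances).max())
            lo = self.means.min(axis=0) - margin_sigmas * sd
            hi = self.means.max(axis=0) + margin_sigmas * sd
            shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
            origin = lo
        else:
            shape = np.array(grid.data.shape)
            origin = grid.origin
            spacing = grid.spacing
        vmap = VoxelMap(origin=origin, spacing=spacing, data=np.zeros(shape))
        vals = self.density(vmap.voxel_centers())
        vmap.data = vals.reshape(shape)
        return vmap


def _weighted_em(points, weights, n_components, seed, reg_covar, tol, max_iter):
    """EM for a weighted Gaussian mixture; returns (mix, means, covs, logliks).

    The per-iteration weighted log-likelihood sequence is non-decreasing.
    """
    points = np.asarray(points, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    n, _ = points.shape
    k = n_components

    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(points, sample_weight=w)
    resp = np.zeros((n, k))
    resp[np.arange(n), km.labels_] = 1.0

    logliks = []
    log_prob = np.empty((n, k))
    for _ in range(max_iter):
        # M step from responsibilities
        wk = (w[:, None] * resp).sum(axis=0) + 1e-300
        mix = wk / wk.sum()
        means = (w[:, None, None] * resp[:, :, None] * points[:, None, :]).sum(axis=0) / wk[:, None]
        covs = np.empty((k, 3, 3))
        for j in range(k):
            d = points - means[j]
            cw = w * resp[:, j]
            covs[j] = (cw[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / wk[j]
            covs[j] += reg_covar * np.eye(3)
        # E step
        for j in range(k):
            L = np.linalg.cholesky(covs[j])
            y = np.linalg.solve(L, (points - means[j]).T)
            logdet = 2.0 * np.log(np.diag(L)).sum()
            log_prob[:, j] = (
                np.log(mix[j] + 1e-300) - 0.5 * (y**2).sum(axis=0) - 0.5 * (3 * _LOG_2PI + logdet)
            )
        m = log_prob.max(axis=1)
        lse = m + np.log(np.exp(log_prob - m[:, None]).sum(axis=1))
        ll = float((w * lse).sum())
        resp = np.exp(log_prob - lse[:, None])
        if logliks and ll - logliks[-1] < tol:
            logliks.append(ll)
            break
        logliks.append(ll)
    return mix, means, covs, logliks


def fit_gmm(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    n_components: int = 1,
    seed: int = 0,
    reg_covar: float = 1e-4,
    tol: float = 1e-8,
    max_iter: int = 200,
    return_loglik: bool = False,
):
    """Fit a weighted GMM to points by expectation-maximization.

    Mixture weights sum to 1; the fit is deterministic given ``seed``.  A
    degenerate point cloud (all points identical) yields a single tight
    component of covariance ``reg_covar * I``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if weights is None:
        weights = np.ones(len(points))
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if len(points) < n_components:
        raise ValueError("need at least n_components points")
    if np.allclose(points, points[0]):
        if n_components > 1:
            raise ValueError("cannot fit multiple components to identical points")
        gmm = GMM(np.ones(1), points[:1].copy(), reg_covar * np.eye(3)[None])
        return (gmm, [0.0]) if return_loglik else gmm
    mix, means, covs, logliks = _weighted_em(
        points, weights, n_components, seed, reg_covar, tol, max_iter
    )
    gmm = GMM(mix, means, covs)
    return (gmm, logliks) if return_loglik else gmm


def n_gaussians_for(n_residues: int) -> int:
    """Component-count rule for structured regions: one per 50 residues,
    floor division with a minimum of one."""
    return max(1, n_residues // RESIDUES_PER_GAUSSIAN)


def gmm_from_voxels(
    vmap: VoxelMap, n_components: int, threshold: float = 0.0, seed: int = 0
) -> GMM:
    """Fit a GMM to voxel centers weighted by density above ``threshold``.

    The fitted component weights sum to 1; renormalization to module mass
    happens when the mixture is assembled into an EM restraint.
    """
    mask = vmap.data > threshold
    if not mask.any():
        raise ValueError("no voxels above threshold")
    centers = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[mask]
    dens = vmap.data[mask]
    return fit_gmm(centers, dens, n_components=n_components, seed=seed)


# ---------------------------------------------------------------------------
# Beads and bodies
# ---------------------------------------------------------------------------


@dataclass
class Bead:
    subunit: str
    first: int
    last: int
    n_residues: int
    center: np.ndarray
    radius: float
    scale: str  # "fine" | "coarse" | "flexible"
    mobile: bool = True


def build_beads(residues, subunit: str, scale: str, mobile: bool = True):
    """Beads for a structured region.

    ``residues`` is a sequence of :class:`~intmod.io_formats.Residue`.  Fine
    scale gives one bead per residue at the Cα; coarse scale gives
    consecutive 10-residue segments (the terminal segment may be shorter),
    centered at the segment's mass-weighted atomic center of mass.
    """
    residues = list(residues)
    if not residues:
        raise ValueError("empty residue list")
    beads = []
    if scale == "fine":
        for r in residues:
            beads.append(
                Bead(subunit, r.index, r.index, 1, np.asarray(r.ca, float), bead_radius(1), "fine", mobile)
            )
        return beads
    if scale != "coarse":
        raise ValueError(f"unknown scale {scale!r}")
    for start in range(0, len(residues), COARSE_SEGMENT):
        seg = residues[start : start + COARSE_SEGMENT]
        coords, masses = [], []
        for r in seg:
            if r.atoms:
                for m, xyz in r.atoms:
                    coords.append(xyz)
                    masses.append(m)
            else:
                coords.append(r.ca)
                masses.append(r.mass)
        coords = np.asarray(coords, float)
        masses = np.asarray(masses, float)
        center = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        beads.append(
            Bead(subunit, seg[0].index, seg[-1].index, len(seg), center, bead_radius(len(seg)), "coarse", mobile)
        )
    return beads


def split_flexible_range(first: int, last: int, max_per_bead: int = MAX_FLEX_RESIDUES):
    """Deterministic near-equal split of a residue range into elements of at
    most ``max_per_bead`` residues.

    The number of elements is the ceiling of n / max_per_bead; the first
    ``n % k`` elements carry one extra residue.
    """
    n = last - first + 1
    if n < 1:
        raise ValueError("zero-length flexible range")
    k = -(-n // max_per_bead)  # ceil
    base, extra = divmod(n, k)
    ranges = []
    lo = first
    for i in range(k):
        size = base + (1 if i < extra else 0)
        ranges.append((lo, lo + size - 1))
        lo += size
    return ranges


@dataclass
class FlexBead:
    """One flexible-string element: a coarse bead and a co-centered
    spherical Gaussian whose variance describes the segment's molecular
    volume (uniform-ball variance r^2/5 per axis)."""

    subunit: str
    first: int
    last: int
    n_residues: int
    center: np.ndarray
    radius: float
    mass: float
    var: float

    @classmethod
    def for_range(cls, subunit, first, last, center):
        n = last - first + 1
        r = bead_radius(n)
        return cls(
            subunit=subunit,
            first=first,
            last=last,
            n_residues=n,
            center=np.asarray(center, float),
            radius=r,
            mass=n * MEAN_RESIDUE_MASS,
            var=r * r / 5.0,
        )


def build_flexible_string(
    subunit: str, first: int, last: int, centers=None, max_per_bead: int = MAX_FLEX_RESIDUES
):
    """Flexible string for an unstructured residue range.

    ``centers`` optionally supplies per-residue coordinates (e.g. ground
    truth); each element's bead is then placed at its segment centroid,
    otherwise at the origin.  The bead and Gaussian centers are identical by
    construction.
    """
    ranges = split_flexible_range(first, last, max_per_bead)
    beads = []
    for lo, hi in ranges:
        if centers is not None:
            centers = np.asarray(centers, float)
            seg = centers[lo - first : hi - first + 1]
            c = seg.mean(axis=0)
        else:
            c = np.zeros(3)
        beads.append(FlexBead.for_range(subunit, lo, hi, c))
    return beads


@dataclass
class RigidBody:
    """A rigid group of fine beads, coarse beads, and Gaussian components.

    Local coordinates are stored relative to the coarse-bead centroid; a
    pose (rotation about the centroid + translation of the centroid) places
    the body in the global frame.  Fixed bodies keep the identity pose.
    """

    name: str
    fixed: bool
    fine_local: np.ndarray  # (m, 3)
    fine_keys: list  # [(subunit, residue)]
    coarse_local: np.ndarray  # (k, 3)
    coarse_radii: np.ndarray
    coarse_nres: np.ndarray
    coarse_keys: list  # [(subunit, first, last)]
    gmm_local: GMM  # component weights are segment masses (Da)
    mass: float
    origin: np.ndarray  # global position of the local frame origin at build time

    def internal_distances(self) -> np.ndarray:
        d = self.fine_local[:, None, :] - self.fine_local[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# The full multi-scale model
# ---------------------------------------------------------------------------


class MultiScaleModel:
    """Subunits decomposed into rigid bodies and flexible strings, with
    per-scale views used by the restraints, the sampler, and the analysis.

    Coordinate state (rigid-body poses and flexible-bead centers) lives in a
    separate ``ModelState``; this class holds the immutable reference
    geometry and index maps.
    """

    def __init__(self, topology: TopologyConfig):
        self.topology = topology
        self.rigid_bodies: list[RigidBody] = []
        self.flex_beads: list[FlexBead] = []
        self._endpoint: dict = {}  # (subunit, residue) -> ("rb", bi, fi) | ("flex", qi)
        self.connectivity: list = []  # (end_a, end_b, r_a, r_b); ends are coarse refs

    # -- construction ------------------------------------------------------

    def add_rigid_body(self, body: RigidBody) -> int:
        bi = len(self.rigid_bodies)
        self.rigid_bodies.append(body)
        for fi, key in enumerate(body.fine_keys):
            self._endpoint[key] = ("rb", bi, fi)
        return bi

    def add_flex_bead(self, bead: FlexBead) -> int:
        qi = len(self.flex_beads)
        self.flex_beads.append(bead)
        for resi in range(bead.first, bead.last + 1):
            self._endpoint[(bead.subunit, resi)] = ("flex", qi)
        return qi

    def finalize(self) -> None:
        """Build sequence-connectivity pairs and flat scoring arrays."""
        self.connectivity = []
        for su in self.topology.subunits:
            segs = sorted(su.segments, key=lambda s: s.first)
            for a, b in zip(segs[:-1], segs[1:]):
                if a.kind == "rigid" and b.kind == "rigid" and a.body == b.body:
                    continue  # same body: connectivity is implicit
                end_a = self._coarse_ref(su.name, a.last)
                end_b = self._coarse_ref(su.name, b.first)
                r_a = self._coarse_radius(end_a)
                r_b = self._coarse_radius(end_b)
                self.connectivity.append((end_a, end_b, r_a, r_b))
            # consecutive elements within a flexible string
            flex_in_su = [
                (qi, fb) for qi, fb in enumerate(self.flex_beads) if fb.subunit == su.name
            ]
            flex_in_su.sort(key=lambda t: t[1].first)
            for (qa, fa), (qb, fb) in zip(flex_in_su[:-1], flex_in_su[1:]):
                if fa.last + 1 == fb.first:
                    self.connectivity.append(
                        (("flex", qa), ("flex", qb), fa.radius, fb.radius)
                    )
        self._build_flat_views()

    def _coarse_ref(self, subunit: str, residue: int):
        kind = self._endpoint[(subunit, residue)]
        if kind[0] == "flex":
            return kind
        _, bi, _ = kind
        body = self.rigid_bodies[bi]
        for ci, (su, first, last) in enumerate(body.coarse_keys):
            if su == subunit and first <= residue <= last:
                return ("rbc", bi, ci)
        raise KeyError(f"no coarse bead covers {subunit}:{residue}")

    def _coarse_radius(self, ref) -> float:
        if ref[0] == "flex":
            return self.flex_beads[ref[1]].radius
        _, bi, ci = ref
        return float(self.rigid_bodies[bi].coarse_radii[ci])

    def _build_flat_views(self) -> None:
        """Flat per-coarse-bead arrays in a fixed order: all rigid bodies'
        coarse beads (body order), then flexible beads."""
        radii, nres, subunits, firsts, lasts, owner = [], [], [], [], [], []
        for bi, body in enumerate(self.rigid_bodies):
            for ci, (su, first, last) in enumerate(body.coarse_keys):
                radii.append(body.coarse_radii[ci])
                nres.append(body.coarse_nres[ci])
                subunits.append(su)
                firsts.append(first)
                lasts.append(last)
                owner.append(("rb", bi, ci))
        for qi, fb in enumerate(self.flex_beads):
            radii.append(fb.radius)
            nres.append(fb.n_residues)
            subunits.append(fb.subunit)
            firsts.append(fb.first)
            lasts.append(fb.last)
            owner.append(("flex", qi))
        self.bead_radii = np.array(radii, dtype=float)
        self.bead_nres = np.array(nres, dtype=float)
        self.bead_subunits = np.array(subunits)
        self.bead_first = np.array(firsts, dtype=int)
        self.bead_last = np.array(lasts, dtype=int)
        self.bead_owner = owner
        mobile = []
        for o in owner:
            if o[0] == "rb":
                mobile.append(not self.rigid_bodies[o[1]].fixed)
            else:
                mobile.append(True)
        self.bead_mobile = np.array(mobile, dtype=bool)

    # -- state-dependent views --------------------------------------------

    @property
    def n_rigid(self) -> int:
        return len(self.rigid_bodies)

    @property
    def n_flex(self) -> int:
        return len(self.flex_beads)

    @property
    def mobile_rigid(self):
        return [i for i, b in enumerate(self.rigid_bodies) if not b.fixed]

    def endpoint_of(self, subunit: str, residue: int):
        try:
            return self._endpoint[(subunit, residue)]
        except KeyError:
            raise KeyError(f"residue {subunit}:{residue} maps to no bead") from None

    def coarse_centers(self, state) -> np.ndarray:
        """(B, 3) global coarse-bead centers in the flat bead order."""
        chunks = []
        for bi, body in enumerate(self.rigid_bodies):
            chunks.append(body.coarse_local @ state.rot[bi].T + state.trans[bi])
        if self.n_flex:
            chunks.append(state.flex)
        return np.vstack(chunks) if chunks else np.zeros((0, 3))

    def endpoint_coords(self, state, endpoints) -> np.ndarray:
        """Global coordinates for a list of endpoint refs (fine for rigid
        regions, coarse-bead center for flexible strings)."""
        out = np.empty((len(endpoints), 3))
        for i, ref in enumerate(endpoints):
            if ref[0] == "rb":
                _, bi, fi = ref
                body = self.rigid_bodies[bi]
                out[i] = state.rot[bi] @ body.fine_local[fi] + state.trans[bi]
            else:
                out[i] = state.flex[ref[1]]
        return out

    def coarse_ref_coords(self, state, refs) -> np.ndarray:
        out = np.empty((len(refs), 3))
        for i, ref in enumerate(refs):
            if ref[0] == "rbc":
                _, bi, ci = ref
                body = self.rigid_bodies[bi]
                out[i] = state.rot[bi] @ body.coarse_local[ci] + state.trans[bi]
            else:
                out[i] = state.flex[ref[1]]
        return out

    def model_gmm(self, state, subunits=None) -> GMM:
        """Assembled model mixture (weights = masses in Da) for the given
        subunit selection (default: all)."""
        weights, means, covs = [], [], []
        for bi, body in enumerate(self.rigid_bodies):
            if subunits is not None:
                # a body belongs to the subunits of its fine keys
                body_subunits = {su for su, _ in body.fine_keys}
                if not (body_subunits & set(subunits)):
                    continue
            g = body.gmm_local.transformed(state.rot[bi], state.trans[bi])
            weights.append(g.weights)
            means.append(g.means)
            covs.append(g.covariances)
        for qi, fb in enumerate(self.flex_beads):
            if subunits is not None and fb.subunit not in subunits:
                continue
            weights.append(np.array([fb.mass]))
            means.append(state.flex[qi][None, :])
            covs.append((fb.var * np.eye(3))[None])
        if not weights:
            raise ValueError("empty subunit selection")
        return GMM(np.concatenate(weights), np.vstack(means), np.vstack(covs))

    def residue_coords(self, state, subunit: str) -> dict:
        """Per-residue representative coordinate (fine bead or covering
        flexible bead center) for one subunit."""
        out = {}
        su = self.topology.subunit(subunit)
        for resi in range(1, su.length + 1):
            ref = self._endpoint.get((subunit, resi))
            if ref is None:
                continue
            out[resi] = self.endpoint_coords(state, [ref])[0]
        return out


def build_model(topology: TopologyConfig, coords: dict, masses: dict | None = None,
                gmm_seed: int = 0) -> MultiScaleModel:
    """Build a multi-scale model from per-subunit Cα coordinate arrays.

    ``coords[name]`` is an (L, 3) array of per-residue coordinates in the
    reference (e.g. ground-truth or crystallographic) frame.  Rigid segments
    sharing a body id are grouped into one rigid body; flexible segments
    become strings of ≤40-residue elements.
    """
    from .io_formats import Residue

    model = MultiScaleModel(topology)
    body_members: dict = {}
    body_fixed: dict = {}
    for su in topology.subunits:
        xyz = np.asarray(coords[su.name], dtype=float)
        if xyz.shape != (su.length, 3):
            raise ValueError(
                f"coords for {su.name} must be ({su.length}, 3), got {xyz.shape}"
            )
        m = None if masses is None else masses.get(su.name)
        for seg in sorted(su.segments, key=lambda s: s.first):
            if seg.kind == "rigid":
                body_id = seg.body or f"{su.name}_{seg.first}"
                body_members.setdefault(body_id, []).append((su.name, seg, xyz, m))
                body_fixed[body_id] = body_fixed.get(body_id, False) or seg.fixed
            elif seg.kind == "flexible":
                for fb in build_flexible_string(
                    su.name, seg.first, seg.last, centers=xyz[seg.first - 1 : seg.last]
                ):
                    model.add_flex_bead(fb)
            else:
                raise ValueError(f"unknown segment kind {seg.kind!r}")

    for body_id, members in body_members.items():
        fine_xyz, fine_keys, fine_mass = [], [], []
        coarse_local, coarse_radii, coarse_nres, coarse_keys = [], [], [], []
        for su_name, seg, xyz, m in members:
            residues = [
                Residue(
                    index=resi,
                    ca=xyz[resi - 1],
                    mass=(m[resi - 1] if m is not None else MEAN_RESIDUE_MASS),
                )
                for resi in range(seg.first, seg.last + 1)
            ]
            for b in build_beads(residues, su_name, "fine"):
                fine_xyz.append(b.center)
                fine_keys.append((su_name, b.first))
                fine_mass.append(residues[b.first - seg.first].mass)
            for b in build_beads(residues, su_name, "coarse"):
                coarse_local.append(b.center)
                coarse_radii.append(b.radius)
                coarse_nres.append(b.n_residues)
                coarse_keys.append((su_name, b.first, b.last))
        fine_xyz = np.asarray(fine_xyz)
        fine_mass = np.asarray(fine_mass)
        coarse_local = np.asarray(coarse_local)
        centroid = coarse_local.mean(axis=0)
        n_res = len(fine_keys)
        n_comp = max(1, n_res // RESIDUES_PER_GAUSSIAN)
        gmm = fit_gmm(fine_xyz, fine_mass, n_components=n_comp, seed=gmm_seed, reg_covar=1.0)
        total_mass = float(fine_mass.sum())
        gmm = GMM(gmm.weights * total_mass, gmm.means - centroid, gmm.covariances)
        body = RigidBody(
            name=body_id,
            fixed=body_fixed[body_id],
            fine_local=fine_xyz - centroid,
            fine_keys=fine_keys,
            coarse_local=coarse_local - centroid,
            coarse_radii=np.asarray(coarse_radii),
            coarse_nres=np.asarray(coarse_nres),
            coarse_keys=coarse_keys,
            gmm_local=gmm,
            mass=total_mass,
            origin=centroid,
        )
        model.add_rigid_body(body)

    model.finalize()
    return model
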