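"""Ensemble analysis: clustering of best-scoring solutions, precision,
RMSF, localization densities, contact maps, restraint-satisfaction
statistics, sampling-exhaustiveness checks, and density segmentation.

All structure comparisons use the size-weighted RMSD

    RMSD_ij = sqrt( sum_b n_b |x_b,i - x_b,j|^2 / sum_b n_b )

over coarse-scale bead centers, without superposition: the EM restraint
fixes the global frame, so solutions are compared in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import VoxelMap
from .representation import GMM
from .xl_dataset import CrossLinkSet, INTRA, INTER

__all__ = [
    "ClusterEnsemble",
    "LocalizationDensity",
    "weighted_rmsd",
    "rmsd_matrix",
    "select_and_cluster",
    "rmsf",
    "subunit_precision",
    "localization_density",
    "contact_maps",
    "satisfaction_stats",
    "exhaustiveness_check",
    "jackknife",
    "segment_density",
    "map_cross_correlation",
]


def weighted_rmsd(coords_a, coords_b, nres) -> float:
    """Size-weighted RMSD between two matching bead-coordinate arrays."""
    coords_a = np.asarray(coords_a, float)
    coords_b = np.asarray(coords_b, float)
    if coords_a.shape != coords_b.shape:
        raise ValueError("mismatched bead lists")
    w = np.asarray(nres, float)
    sq = ((coords_a - coords_b) ** 2).sum(axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def rmsd_matrix(coords: np.ndarray, nres: np.ndarray) -> np.ndarray:
    """Pairwise weighted-RMSD matrix for (N, B, 3) bead coordinates."""
    coords = np.asarray(coords, float)
    w = np.asarray(nres, float)
    wsum = w.sum()
    n = len(coords)
    out = np.zeros((n, n))
    # row-blocked to bound memory
    block = max(1, int(2e7 // (n * coords.shape[1])))
    for i0 in range(0, n, block):
        chunk = coords[i0 : i0 + block]
        d2 = ((chunk[:, None, :, :] - coords[None, :, :, :]) ** 2).sum(axis=-1)
        out[i0 : i0 + block] = np.sqrt((d2 * w).sum(axis=-1) / wsum)
    np.fill_diagonal(out, 0.0)
    return out


def frames_bead_coords(model, frames) -> np.ndarray:
    """(N, B, 3) coarse-bead centers for a list of frames."""
    return np.array([model.coarse_centers(f.to_state()) for f in frames])


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterEnsemble:
    """Best-scoring solutions grouped by weighted-RMSD k-medoids."""

    frames: list
    bead_coords: np.ndarray  # (N, B, 3)
    bead_nres: np.ndarray
    scores: np.ndarray
    rmsd: np.ndarray  # (N, N), symmetric, zero diagonal
    labels: np.ndarray  # (N,)
    medoids: np.ndarray  # (k,) frame indices; medoid = cluster center
    model: object = None

    @property
    def n_clusters(self) -> int:
        return len(self.medoids)

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)

    def center_index(self, cluster: int = 0) -> int:
        return int(self.medoids[cluster])

    def center_state(self, cluster: int = 0):
        return self.frames[self.center_index(cluster)].to_state()

    def precision(self, cluster: int = 0) -> float:
        """Average RMSD of cluster members to the cluster center."""
        m = self.members(cluster)
        c = self.center_index(cluster)
        others = m[m != c]
        if len(others) == 0:
            return 0.0
        return float(self.rmsd[c, others].mean())

    def population(self, cluster: int) -> float:
        return float((self.labels == cluster).mean())

    def between_rmsd(self, c1: int, c2: int) -> float:
        """Average RMSD between every pair of solutions from two clusters."""
        m1, m2 = self.members(c1), self.members(c2)
        return float(self.rmsd[np.ix_(m1, m2)].mean())


def _pam(dist: np.ndarray, k: int, max_iter: int = 100):
    """k-medoids (PAM-style alternation) on a precomputed distance matrix.

    Deterministic: the first medoid minimizes the total distance to all
    points; each further medoid is the point farthest from the chosen set.
    """
    n = len(dist)
    if k > n:
        raise ValueError("k exceeds the number of frames")
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        mind = dist[:, medoids].min(axis=1)
        medoids.append(int(np.argmax(mind)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = []
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                new.append(medoids[c])
                continue
            sub = dist[np.ix_(members, members)].sum(axis=1)
            new.append(int(members[np.argmin(sub)]))
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, medoids


def select_and_cluster(model, trajectories, n_best: int = 500, k: int = 1) -> ClusterEnsemble:
    """Take the n_best lowest-score frames across runs and partition them by
    k-medoids on the weighted-RMSD matrix.

    Clusters are relabeled in order of ascending mean score, so cluster 0 is
    the best-scoring cluster.
    """
    frames = [f for traj in trajectories for f in traj.frames]
    if len(frames) < n_best:
        raise ValueError(f"only {len(frames)} frames available, need {n_best}")
    scores = np.array([f.score for f in frames])
    order = np.argsort(scores, kind="mergesort")[:n_best]
    frames = [frames[i] for i in order]
    scores = scores[order]
    coords = frames_bead_coords(model, frames)
    dist = rmsd_matrix(coords, model.bead_nres)
    labels, medoids = _pam(dist, k)
    mean_scores = np.array(
        [scores[labels == c].mean() if (labels == c).any() else np.inf for c in range(k)]
    )
    rank = np.argsort(mean_scores, kind="mergesort")
    relabel = np.empty(k, dtype=int)
    relabel[rank] = np.arange(k)
    return ClusterEnsemble(
        frames=frames,
        bead_coords=coords,
        bead_nres=model.bead_nres,
        scores=scores,
        rmsd=dist,
        labels=relabel[labels],
        medoids=medoids[rank],
        model=model,
    )


# ---------------------------------------------------------------------------
# Per-residue statistics
# ---------------------------------------------------------------------------


def _bead_index_of(model, subunit: str, residue: int) -> int:
    sel = (
        (model.bead_subunits == subunit)
        & (model.bead_first <= residue)
        & (model.bead_last >= residue)
    )
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise KeyError(f"no bead covers {subunit}:{residue}")
    return int(idx[0])


def rmsf(ensemble: ClusterEnsemble, subunit: str, residue: int, cluster: int = 0) -> float:
    """Root-mean-square fluctuation of one residue about its cluster-center
    position (the residue's position is the center of its covering bead)."""
    model = ensemble.model
    b = _bead_index_of(model, subunit, residue)
    m = ensemble.members(cluster)
    center = ensemble.bead_coords[ensemble.center_index(cluster), b]
    d2 = ((ensemble.bead_coords[m, b] - center) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()))


def subunit_precision(ensemble: ClusterEnsemble, selection, cluster: int = 0) -> float:
    """Cluster precision restricted to a subunit (or list of subunits)."""
    model = ensemble.model
    if isinstance(selection, str):
        selection = [selection]
    mask = np.isin(model.bead_subunits, list(selection))
    if not mask.any():
        raise KeyError(f"unknown selection {selection!r}")
    m = ensemble.members(cluster)
    c = ensemble.center_index(cluster)
    others = m[m != c]
    if len(others) == 0:
        return 0.0
    vals = [
        weighted_rmsd(
            ensemble.bead_coords[i][mask],
            ensemble.bead_coords[c][mask],
            model.bead_nres[mask],
        )
        for i in others
    ]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Localization densities
# ---------------------------------------------------------------------------


@dataclass
class LocalizationDensity:
    """Per-subunit occupancy probability on a voxel grid, values in [0, 1]."""

    subunit: str
    map: VoxelMap
    threshold: float = 0.15


def _occupancy(grid: VoxelMap, centers, radii) -> np.ndarray:
    """Binary voxel occupancy of a set of hard spheres."""
    occ = np.zeros(grid.data.shape, dtype=bool)
    shape = np.array(grid.data.shape)
    for c, r in zip(centers, radii):
        lo = np.maximum(np.floor((c - r - grid.origin) / grid.spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r - grid.origin) / grid.spacing).astype(int) + 1, shape)
        if (hi <= lo).any():
            continue
        ax = [grid.origin[k] + np.arange(lo[k], hi[k]) * grid.spacing for k in range(3)]
        d2 = (
            (ax[0][:, None, None] - c[0]) ** 2
            + (ax[1][None, :, None] - c[1]) ** 2
            + (ax[2][None, None, :] - c[2]) ** 2
        )
        occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= r * r
    return occ


def density_grid_for(model, coords_list, spacing: float = 4.0, margin: float = 8.0) -> VoxelMap:
    """A voxel grid covering all frames' beads with a margin."""
    allc = np.concatenate([np.asarray(c).reshape(-1, 3) for c in coords_list])
    rmax = float(model.bead_radii.max())
    lo = allc.min(axis=0) - rmax - margin
    hi = allc.max(axis=0) + rmax + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    return VoxelMap(origin=lo, spacing=spacing, data=np.zeros(shape))


def localization_density(
    ensemble_or_coords,
    subunit: str,
    model=None,
    cluster: int = 0,
    grid: VoxelMap | None = None,
    spacing: float = 4.0,
    threshold: float = 0.15,
    rasterize: str = "sphere",
) -> LocalizationDensity:
    """Fraction of cluster solutions in which the subunit's beads (as hard
    spheres) cover each voxel.

    ``rasterize="gaussian"`` instead accumulates each bead as an isotropic
    Gaussian of variance r²/5 (the bead's volume-equivalent spread) and
    averages over frames, yielding a smooth localization density rather
    than a binary-occupancy probability — the standard estimator when
    comparing densities between small ensembles.
    """
    if isinstance(ensemble_or_coords, ClusterEnsemble):
        ens = ensemble_or_coords
        model = ens.model
        coords = ens.bead_coords[ens.members(cluster)]
    else:
        coords = np.asarray(ensemble_or_coords)
        if model is None:
            raise ValueError("model required when passing raw coordinates")
    if len(coords) == 0:
        raise ValueError("empty cluster")
    mask = model.bead_subunits == subunit
    if not mask.any():
        raise KeyError(f"unknown subunit {subunit!r}")
    radii = model.bead_radii[mask]
    if grid is None:
        grid = density_grid_for(model, coords[:, mask, :], spacing=spacing)
    acc = np.zeros(grid.data.shape)
    if rasterize == "sphere":
        for frame_coords in coords:
            acc += _occupancy(grid, frame_coords[mask], radii)
    elif rasterize == "gaussian":
        from .representation import GMM

        var = radii**2 / 5.0
        covs = var[:, None, None] * np.eye(3)[None]
        nres = model.bead_nres[mask]
        for frame_coords in coords:
            g = GMM(nres.astype(float), frame_coords[mask], covs)
            acc += g.density(grid.voxel_centers()).reshape(grid.data.shape)
    else:
        raise ValueError(f"unknown rasterization mode {rasterize!r}")
    out = VoxelMap(
        origin=grid.origin.copy(),
        spacing=grid.spacing,
        data=acc / len(coords),
        threshold=threshold,
    )
    return LocalizationDensity(subunit=subunit, map=out, threshold=threshold)


def map_cross_correlation(a: VoxelMap, b: VoxelMap) -> float:
    """Voxelwise cross-correlation sum(ab)/sqrt(sum(a^2) sum(b^2)) of two
    maps on the same grid."""
    if a.data.shape != b.data.shape:
        raise ValueError("maps must share a grid")
    num = float((a.data * b.data).sum())
    den = float(np.sqrt((a.data**2).sum() * (b.data**2).sum()))
    return num / den if den > 0 else 0.0


# ---------------------------------------------------------------------------
# Contact maps
# ---------------------------------------------------------------------------


def contact_maps(
    ensemble: ClusterEnsemble, cutoff: float = 10.0, domain_size: int = 200, cluster: int = 0
):
    """Bead- and domain-pair contact frequencies across a cluster.

    Two beads are in contact when their surface distance (center distance
    minus both radii) is below ``cutoff``; two domains (200-residue sequence
    blocks) are in contact when any bead pair between them is.  Frequencies
    are fractions of cluster solutions showing the contact.
    """
    model = ensemble.model
    coords = ensemble.bead_coords[ensemble.members(cluster)]
    radii = model.bead_radii
    n_frames, n_beads, _ = coords.shape
    domains = sorted(
        {(su, (f - 1) // domain_size) for su, f in zip(model.bead_subunits, model.bead_first)}
    )
    dom_index = {d: i for i, d in enumerate(domains)}
    bead_dom = np.array(
        [
            dom_index[(su, (f - 1) // domain_size)]
            for su, f in zip(model.bead_subunits, model.bead_first)
        ]
    )
    bead_freq = np.zeros((n_beads, n_beads))
    dom_freq = np.zeros((len(domains), len(domains)))
    rsum = radii[:, None] + radii[None, :]
    for fc in coords:
        d = np.linalg.norm(fc[:, None, :] - fc[None, :, :], axis=-1)
        contact = (d - rsum) < cutoff
        np.fill_diagonal(contact, False)
        bead_freq += contact
        dc = np.zeros_like(dom_freq, dtype=bool)
        ii, jj = np.nonzero(contact)
        dc[bead_dom[ii], bead_dom[jj]] = True
        dom_freq += dc
    return {
        "bead_frequency": bead_freq / n_frames,
        "domain_frequency": dom_freq / n_frames,
        "domains": domains,
        "bead_domain": bead_dom,
    }


# ---------------------------------------------------------------------------
# Cross-link satisfaction
# ---------------------------------------------------------------------------


def satisfaction_stats(
    model,
    states,
    xlset: CrossLinkSet,
    threshold: float = 35.0,
    surface_slack: bool = True,
):
    """Per-link distances and per-class satisfied fractions.

    ``states`` is a single state (cluster center) or a list (the cluster);
    with a list, the per-link minimum over the cluster is also reported.
    For endpoints represented by coarse/flexible beads, the bead radius is
    subtracted from the center distance (a surface-distance slack), since
    the threshold is calibrated for Cα pairs.
    """
    single = not isinstance(states, (list, tuple))
    state_list = [states] if single else list(states)
    links = list(xlset)
    refs = []
    slack = np.zeros(len(links))
    for n, xl in enumerate(links):
        a = model.endpoint_of(xl.protein1, xl.residue1)
        b = model.endpoint_of(xl.protein2, xl.residue2)
        refs.append((a, b))
        if surface_slack:
            for ref in (a, b):
                if ref[0] == "flex":
                    slack[n] += model.flex_beads[ref[1]].radius
    classes = np.array([(xl.xl_class or INTRA) for xl in links])
    dists = np.empty((len(state_list), len(links)))
    for si, st in enumerate(state_list):
        pa = model.endpoint_coords(st, [r[0] for r in refs])
        pb = model.endpoint_coords(st, [r[1] for r in refs])
        dists[si] = np.linalg.norm(pa - pb, axis=1) - slack
    center_d = dists[0]
    min_d = dists.min(axis=0)
    result = {
        "threshold": threshold,
        "per_link": [
            {
                "protein1": xl.protein1,
                "residue1": xl.residue1,
                "protein2": xl.protein2,
                "residue2": xl.residue2,
                "xl_class": classes[n],
                "distance": float(center_d[n]),
                "min_distance": float(min_d[n]),
                "satisfied": bool(center_d[n] <= threshold),
            }
            for n, xl in enumerate(links)
        ],
    }
    for cls in (INTRA, INTER):
        m = classes == cls
        result[cls] = {
            "n_links": int(m.sum()),
            "satisfied_fraction": float((center_d[m] <= threshold).mean()) if m.any() else np.nan,
            "satisfied_fraction_min": float((min_d[m] <= threshold).mean()) if m.any() else np.nan,
        }
    m_all = np.ones(len(links), dtype=bool)
    result["all"] = {
        "n_links": int(m_all.sum()),
        "satisfied_fraction": float((center_d <= threshold).mean()) if len(links) else np.nan,
        "satisfied_fraction_min": float((min_d <= threshold).mean()) if len(links) else np.nan,
    }
    return result


# ---------------------------------------------------------------------------
# Exhaustiveness and jackknifing
# ---------------------------------------------------------------------------


def exhaustiveness_check(
    model,
    trajectories,
    subunits=None,
    n_best_half: int = 250,
    spacing: float = 4.0,
    k: int = 1,
    rasterize: str = "sphere",
):
    """Half-versus-half convergence check.

    Runs are split into first and second halves; each half's best-scoring
    frames become per-subunit localization densities on a common grid, and
    the voxel cross-correlation between halves is reported per subunit,
    together with each half's cluster precision.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least two runs")
    half = len(trajectories) // 2
    halves = [trajectories[:half], trajectories[half:]]
    n_best_half = min(n_best_half, *(sum(len(t.frames) for t in h) for h in halves))
    ensembles = [select_and_cluster(model, h, n_best=n_best_half, k=k) for h in halves]
    if subunits is None:
        subunits = sorted({su.name for su in model.topology.subunits})
    all_coords = np.concatenate([e.bead_coords for e in ensembles])
    grid = density_grid_for(model, [all_coords.reshape(-1, 3)], spacing=spacing)
    per_subunit = {}
    for su in subunits:
        maps = [
            localization_density(e, su, grid=grid, rasterize=rasterize).map
            for e in ensembles
        ]
        per_subunit[su] = map_cross_correlation(maps[0], maps[1])
    return {
        "per_subunit_cc": per_subunit,
        "min_cc": min(per_subunit.values()),
        "half_precisions": [e.precision(0) for e in ensembles],
    }


def jackknife(xlset: CrossLinkSet, fraction: float = 0.1, rng=None) -> CrossLinkSet:
    """Randomly remove floor(fraction * N) links (seeded, reproducible)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    links = xlset.links
    n_remove = int(np.floor(fraction * len(links)))
    drop = set(rng.choice(len(links), size=n_remove, replace=False).tolist())
    kept = [xl for i, xl in enumerate(links) if i not in drop]
    return CrossLinkSet.from_links(kept, provenance=xlset.provenance + "+jackknife")


# ---------------------------------------------------------------------------
# Density segmentation
# ---------------------------------------------------------------------------


def segment_density(
    vmap: VoxelMap,
    fixed_gmm: GMM | None,
    module_masses: dict,
    fixed_mass: float = 0.0,
    threshold: float | None = None,
):
    """Apportion a density map between modules after removing the fixed
    (docked) component.

    The fixed component's mixture is rasterized on the map grid, scaled so
    its integral carries its mass fraction of the map, and subtracted.  The
    remaining above-threshold voxels are sorted by their projection on the
    remainder's principal axis and split by a plane sweep so that each
    module's above-threshold volume is proportional to its mass.  Returns
    {module: VoxelMap}.
    """
    masses = {k: float(v) for k, v in module_masses.items()}
    if any(v < 0 for v in masses.values()) or sum(masses.values()) <= 0:
        raise ValueError("module masses must be non-negative with a positive sum")
    data = vmap.data.copy()
    total_map = data.sum() * vmap.voxel_volume
    if fixed_gmm is not None and fixed_mass > 0:
        raster = fixed_gmm.rasterize(grid=vmap)
        frac = fixed_mass / (fixed_mass + sum(masses.values()))
        target = frac * total_map
        integral = raster.data.sum() * vmap.voxel_volume
        if integral > 0:
            data -= raster.data * (target / integral)
        data = np.maximum(data, 0.0)
    if threshold is None:
        threshold = vmap.threshold
    mask = data > threshold
    n_above = int(mask.sum())
    if n_above < len(masses):
        raise ValueError("remainder volume too small to apportion")
    centers = vmap.voxel_centers().reshape(*vmap.data.shape, 3)[mask]
    dens = data[mask]
    centroid = (dens[:, None] * centers).sum(axis=0) / dens.sum()
    dc = centers - centroid
    cov = (dens[:, None, None] * dc[:, :, None] * dc[:, None, :]).sum(axis=0) / dens.sum()
    axis = np.linalg.eigh(cov)[1][:, -1]
    proj = dc @ axis
    order = np.argsort(proj, kind="mergesort")
    names = list(masses)
    quotas = np.cumsum([masses[n] for n in names]) / sum(masses.values())
    cut_indices = np.round(quotas * n_above).astype(int)
    out = {}
    lo = 0
    flat_idx = np.flatnonzero(mask.ravel())
    for name, hi in zip(names, cut_indices):
        seg = np.zeros(vmap.data.size)
        chosen = flat_idx[order[lo:hi]]
        seg[chosen] = data.ravel()[chosen]
        out[name] = VoxelMap(
            origin=vmap.origin.copy(),
            spacing=vmap.spacing,
            data=seg.reshape(vmap.data.shape),
            threshold=threshold,
        )
        lo = hi
    return out
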