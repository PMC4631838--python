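"""Synthetic toy assemblies with known ground truth.

The generator emulates the statistical structure the pipeline assumes: a
multi-subunit assembly of compact random folds (self-avoiding Cα chains)
arranged to realize a contact graph, rigid bodies joined by flexible
linkers, a simulated density map (blurred mass-weighted GMM), cross-links
drawn from residue pairs within a linker cutoff plus a stated fraction of
uniformly random noise links, and CSM score tables with separated
target/decoy score distributions.

Toy subunits are random self-avoiding bead chains, not real folds: the
scoring and sampling machinery depends only on bead geometry.  All
generators are deterministic given their rng/seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_uppercase

import numpy as np
import pandas as pd

from .io_formats import MEAN_RESIDUE_MASS, TopologyConfig, topology_from_dict
from .representation import GMM, MultiScaleModel, bead_radius, build_model, fit_gmm
from .xl_dataset import CrossLink, CrossLinkSet, classify_crosslinks

__all__ = [
    "ToyAssemblySpec",
    "GroundTruth",
    "make_toy_assembly",
    "simulate_crosslinks",
    "simulate_density",
    "simulate_csm_table",
]


@dataclass
class ToyAssemblySpec:
    """Layout of a toy assembly.

    Defaults give a 4-subunit assembly (chain A-B-C-D plus an A-C contact)
    of distinct subunit sizes in two modules, with subunit A fixed (playing
    the docked component) and subunit B split into two rigid domains joined
    by a 10-residue flexible linker.  Distinct sizes and a non-minimal
    contact graph mirror real assemblies, whose subunits differ in mass and
    typically touch more than one neighbor.
    """

    lengths: tuple = (80, 65, 50, 45)
    contact_edges: tuple = ((0, 1), (1, 2), (2, 3), (0, 2))
    modules: tuple = ("M1", "M1", "M2", "M2")
    # subunit index -> list of (first, last, kind, body_suffix)
    layouts: dict = field(
        default_factory=lambda: {
            1: [(1, 25, "rigid", "1"), (26, 35, "flexible", None), (36, 65, "rigid", "2")]
        }
    )
    fixed_subunit: int = 0
    bond_length: float = 3.8  # Cα-Cα, Å
    min_separation: float = 4.0  # self-avoidance, Å
    contact_distance: float = 8.0  # max closest-approach on contact edges, Å
    clash_distance: float = 25.0  # min closest-approach on non-edges, Å
    max_retries: int = 40

    def __post_init__(self):
        if min(self.lengths) < 1:
            raise ValueError("subunit lengths must be >= 1")
        n = len(self.lengths)
        # contact graph must be connected
        adj = {i: set() for i in range(n)}
        for a, b in self.contact_edges:
            adj[a].add(b)
            adj[b].add(a)
        seen, stack = set(), [0]
        while stack:
            i = stack.pop()
            if i in seen:
                continue
            seen.add(i)
            stack.extend(adj[i])
        if len(seen) != n:
            raise ValueError("contact graph must be connected")

    @property
    def names(self):
        return tuple(ascii_uppercase[i] for i in range(len(self.lengths)))


@dataclass
class GroundTruth:
    """True coordinates and generation parameters of a toy assembly."""

    spec: ToyAssemblySpec
    coords: dict  # subunit name -> (L, 3) Cα array
    topology: TopologyConfig
    params: dict = field(default_factory=dict)

    def residue_coord(self, subunit: str, residue: int) -> np.ndarray:
        return self.coords[subunit][residue - 1]

    def distance(self, su1, r1, su2, r2) -> float:
        return float(np.linalg.norm(self.residue_coord(su1, r1) - self.residue_coord(su2, r2)))

    def all_coords(self) -> np.ndarray:
        return np.vstack([self.coords[su.name] for su in self.topology.subunits])


def _random_chain(n, rng, bond, min_sep, confine):
    """Self-avoiding random Cα chain confined to a sphere (compact fold)."""
    for _ in range(200):
        coords = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            for _trial in range(300):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                cand = coords[i - 1] + bond * u
                if np.linalg.norm(cand) > confine:
                    continue
                if i > 1:
                    d = np.linalg.norm(coords[: i - 1] - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                coords[i] = cand
                break
            else:
                ok = False
                break
        if ok:
            return coords - coords.mean(axis=0)
    raise RuntimeError("could not generate a self-avoiding chain")


def _min_interchain_distance(a: np.ndarray, b: np.ndarray) -> float:
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _random_rotation(rng) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _toy_topology(spec: ToyAssemblySpec) -> TopologyConfig:
    doc = {"subunits": []}
    for i, name in enumerate(spec.names):
        length = spec.lengths[i]
        layout = spec.layouts.get(i, [(1, length, "rigid", "")])
        segments = []
        for first, last, kind, suffix in layout:
            seg = {"range": [first, last], "kind": kind}
            if kind == "rigid":
                seg["body"] = f"{name}{suffix or ''}"
                if i == spec.fixed_subunit:
                    seg["fixed"] = True
            segments.append(seg)
        doc["subunits"].append(
            {
                "name": name,
                "length": length,
                "modules": [{"range": [1, length], "module": spec.modules[i]}],
                "segments": segments,
            }
        )
    return topology_from_dict(doc)


def make_toy_assembly(spec: ToyAssemblySpec | None = None, rng=None):
    """Generate ground-truth coordinates and the matching multi-scale model.

    Subunits are placed by breadth-first traversal of the contact graph:
    each child is positioned against its parent so that contact-edge pairs
    approach within ``contact_distance`` while non-edge pairs stay beyond
    ``clash_distance`` and no residues clash.  Raises after ``max_retries``
    failed packings.

    Returns (GroundTruth, MultiScaleModel).
    """
    spec = spec or ToyAssemblySpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    names = spec.names
    n = len(names)
    adj = {i: set() for i in range(n)}
    for a, b in spec.contact_edges:
        adj[a].add(b)
        adj[b].add(a)

    chains = []
    for length in spec.lengths:
        confine = 1.35 * bead_radius(length)
        chains.append(_random_chain(length, rng, spec.bond_length, spec.min_separation, confine))
    blob_r = [np.linalg.norm(c, axis=1).max() for c in chains]

    for _attempt in range(spec.max_retries):
        placed: dict[int, np.ndarray] = {0: chains[0].copy()}
        order = []
        stack = [0]
        seen = {0}
        while stack:
            i = stack.pop(0)
            order.append(i)
            for j in sorted(adj[i]):
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        ok = True
        for j in order[1:]:
            parent = next(p for p in order if j in adj[p] and p in placed)
            success = False
            for _trial in range(300):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                gap = rng.uniform(-2.0, 3.0)
                center = placed[parent].mean(axis=0) + u * (blob_r[parent] + blob_r[j] + gap)
                cand = chains[j] @ _random_rotation(rng).T + center
                dmin_parent = _min_interchain_distance(cand, placed[parent])
                if not (spec.min_separation <= dmin_parent <= spec.contact_distance):
                    continue
                good = True
                for p, xyz in placed.items():
                    if p == parent:
                        continue
                    dmin = _min_interchain_distance(cand, xyz)
                    if p in adj[j]:
                        if not (spec.min_separation <= dmin <= spec.contact_distance):
                            good = False
                            break
                    elif dmin < spec.clash_distance:
                        good = False
                        break
                if good:
                    placed[j] = cand
                    success = True
                    break
            if not success:
                ok = False
                break
        if ok:
            coords = {names[i]: placed[i] for i in range(n)}
            topology = _toy_topology(spec)
            truth = GroundTruth(spec=spec, coords=coords, topology=topology)
            model = build_model(topology, coords)
            return truth, model
    raise RuntimeError(f"infeasible packing after {spec.max_retries} retries")


# ---------------------------------------------------------------------------
# Simulated data
# ---------------------------------------------------------------------------


def _informative_pairs(truth: GroundTruth, model: MultiScaleModel):
    """Residue pairs whose relative geometry is not fixed: endpoints owned
    by different rigid bodies or flexible beads.  Within-body pairs carry no
    restraint information and are excluded from the true-link pool."""
    keys, owners, coords = [], [], []
    for su in truth.topology.subunits:
        for resi in range(1, su.length + 1):
            ref = model.endpoint_of(su.name, resi)
            keys.append((su.name, resi))
            owners.append(ref[:2])
            coords.append(truth.residue_coord(su.name, resi))
    coords = np.array(coords)
    pairs = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if owners[i] != owners[j]:
                pairs.append((i, j))
    return keys, coords, np.array(pairs)


def simulate_crosslinks(
    truth: GroundTruth,
    model: MultiScaleModel,
    n_true: int = 50,
    cutoff: float = 21.0,
    noise_fraction: float = 0.05,
    spectra_p: float = 0.5,
    rng=None,
) -> CrossLinkSet:
    """Simulated cross-link dataset: ``n_true`` residue pairs with true
    distance within ``cutoff``, plus ceil(nf/(1-nf) * n_true) uniformly
    random noise pairs; spectral counts are geometric(p).  Each link's
    hidden truth status is recorded in ``meta['true']``, and links are
    classified intra/inter-module against the topology.
    """
    if not (0 <= noise_fraction < 1):
        raise ValueError("noise_fraction must be in [0, 1)")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    keys, coords, pairs = _informative_pairs(truth, model)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    eligible = pairs[d <= cutoff]
    if len(eligible) < n_true:
        raise ValueError(f"only {len(eligible)} residue pairs within {cutoff} Å; need {n_true}")
    chosen = eligible[rng.choice(len(eligible), size=n_true, replace=False)]
    links = []
    used = set()
    for i, j in chosen:
        (p1, r1), (p2, r2) = keys[i], keys[j]
        links.append(
            CrossLink(
                protein1=p1, residue1=r1, protein2=p2, residue2=r2,
                n_spectra=int(rng.geometric(spectra_p)), source="sim_true",
                meta={"true": True},
            )
        )
        used.add(links[-1].key)
    n_noise = int(np.ceil(noise_fraction / (1.0 - noise_fraction) * n_true))
    n_res_total = len(keys)
    while n_noise > 0:
        i, j = rng.integers(n_res_total, size=2)
        if i == j:
            continue
        (p1, r1), (p2, r2) = keys[i], keys[j]
        xl = CrossLink(
            protein1=p1, residue1=r1, protein2=p2, residue2=r2,
            n_spectra=int(rng.geometric(spectra_p)), source="sim_noise",
            meta={"true": False},
        )
        if xl.key in used:
            continue
        links.append(xl)
        used.add(xl.key)
        n_noise -= 1
    xlset = CrossLinkSet.from_links(links, provenance="synthetic")
    return classify_crosslinks(xlset, truth.topology)


def simulate_density(
    truth: GroundTruth,
    n_components: int | None = None,
    blur: float = 5.0,
    spacing: float = 4.0,
    seed: int = 0,
    subunits=None,
):
    """Simulated EM data: a GMM fitted to the true residue positions
    (mass-weighted), covariances inflated by ``blur``^2 (emulating limited
    resolution), and its rasterization to a voxel map.

    ``subunits`` restricts the density to a selection (e.g. one module's
    segmented density).  Returns (GMM, VoxelMap); the GMM total weight
    equals the selection's mass.
    """
    if subunits is None:
        coords = truth.all_coords()
    else:
        coords = np.vstack([truth.coords[name] for name in subunits])
    if n_components is None:
        # the data mixture represents the map faithfully (unlike model
        # mixtures, which are deliberately coarse at one component per 50
        # residues); resolution is set by the blur, not the component count
        n_components = max(1, len(coords) // 10)
    gmm = fit_gmm(coords, None, n_components=n_components, seed=seed, reg_covar=1.0)
    covs = gmm.covariances + (blur**2) * np.eye(3)
    total_mass = len(coords) * MEAN_RESIDUE_MASS
    gmm = GMM(gmm.weights * total_mass, gmm.means, covs)
    vmap = gmm.rasterize(spacing=spacing)
    return gmm, vmap


def simulate_csm_table(
    n_target: int = 100,
    decoy_ratio: int = 10,
    score_separation: float = 3.0,
    rng=None,
) -> pd.DataFrame:
    """Synthetic CSM score table: target classifier scores ~ N(sep, 1),
    decoy scores ~ N(0, 1), with decoy_ratio times as many decoy rows, and
    auxiliary score columns spanning the quality-filter thresholds."""
    if decoy_ratio < 1:
        raise ValueError("decoy_ratio must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_decoy = decoy_ratio * n_target
    n = n_target + n_decoy
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[n_target:] = True
    scores = np.where(
        is_decoy, rng.normal(0.0, 1.0, size=n), rng.normal(score_separation, 1.0, size=n)
    )
    df = pd.DataFrame(
        {
            "spectrum_id": np.arange(n),
            "protein1": [f"P{int(i)}" for i in rng.integers(1, 6, size=n)],
            "residue1": rng.integers(1, 200, size=n),
            "protein2": [f"P{int(i)}" for i in rng.integers(1, 6, size=n)],
            "residue2": rng.integers(1, 200, size=n),
            "peptide1_length": rng.integers(2, 21, size=n),
            "peptide2_length": rng.integers(2, 21, size=n),
            "peptide_score": rng.uniform(5.0, 60.0, size=n),
            "expect_peptide": rng.uniform(0.0, 80.0, size=n),
            "expect_protein": rng.uniform(0.0, 80.0, size=n),
            "expect_worse": rng.uniform(0.0, 80.0, size=n),
            "score_difference": rng.uniform(-5.0, 20.0, size=n),
            "classifier_score": scores,
            "is_decoy1": is_decoy,
            "is_decoy2": np.zeros(n, dtype=bool),
        }
    )
    return df
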