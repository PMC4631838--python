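"""Readers and writers for every external representation the pipeline touches.

Conventions
-----------
* All coordinates are in Angstrom (Å); residue numbering is 1-based,
  per-subunit sequence numbering.
* Voxel grids are stored in canonical (x, y, z) axis order with x fastest
  in memory layout terms of ``data[ix, iy, iz]``; MRC/CCP4 files with
  permuted axis headers are re-ordered on read.
* Cross-link identity is the unordered pair of (protein, residue);
  duplicate rows merge by summing spectral counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Residue",
    "AtomicModel",
    "VoxelMap",
    "SegmentSpec",
    "SubunitSpec",
    "TopologyConfig",
    "read_structure",
    "write_structure",
    "read_density_map",
    "write_density_map",
    "read_crosslink_table",
    "write_crosslink_table",
    "read_gmm",
    "write_gmm",
    "read_topology",
]

# mean residue mass used when a file carries no atom records beyond CA
MEAN_RESIDUE_MASS = 110.0  # Da

XL_COLUMNS = ["protein1", "residue1", "protein2", "residue2", "n_spectra", "source"]


@dataclass
class Residue:
    """One residue: 1-based index, CA coordinate in Å, mass in Da."""

    index: int
    ca: np.ndarray
    mass: float = MEAN_RESIDUE_MASS
    atoms: list | None = None  # optional [(mass, xyz)], for center-of-mass work


@dataclass
class AtomicModel:
    """Chains of residues with CA coordinates; gaps are recorded, not fabricated."""

    chains: list  # list of (chain_id, list[Residue])
    missing: dict = field(default_factory=dict)  # chain_id -> sorted missing indices

    def chain(self, chain_id: str) -> list:
        for cid, residues in self.chains:
            if cid == chain_id:
                return residues
        raise KeyError(f"chain {chain_id!r} not present in structure")

    def residue(self, chain_id: str, index: int) -> Residue:
        for res in self.chain(chain_id):
            if res.index == index:
                return res
        raise KeyError(f"residue {index} not found in chain {chain_id!r}")

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return np.array([r.ca for r in self.chain(chain_id)], dtype=float)


@dataclass
class VoxelMap:
    """Isotropic voxel grid of densities with an Å origin."""

    origin: np.ndarray  # (3,), Å position of voxel (0,0,0) center
    spacing: float  # Å per voxel, isotropic
    data: np.ndarray  # (nx, ny, nz)
    threshold: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("voxel grid must be 3-D with at least one voxel per axis")

    def voxel_centers(self) -> np.ndarray:
        """(N, 3) Å coordinates of all voxel centers, C order of the grid."""
        nx, ny, nz = self.data.shape
        ix, iy, iz = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        idx = np.stack([ix, iy, iz], axis=-1).reshape(-1, 3)
        return self.origin + idx * self.spacing

    @property
    def voxel_volume(self) -> float:
        return float(self.spacing) ** 3


def read_structure(path, fmt: str | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    CA coordinates and per-residue masses are populated from the file; chain
    interior gaps in the 1-based residue numbering are flagged in
    ``missing`` rather than fabricated.
    """
    path = str(path)
    if fmt is None:
        st = gemmi.read_structure(path)
    else:
        fmt_map = {"pdb": gemmi.CoorFormat.Pdb, "mmcif": gemmi.CoorFormat.Mmcif}
        if fmt not in fmt_map:
            raise ValueError(f"unsupported structure format {fmt!r}")
        st = gemmi.read_structure(path, format=fmt_map[fmt])
    if len(st) == 0:
        raise ValueError(f"no models in structure file {path}")
    model = st[0]
    chains = []
    missing: dict[str, list[int]] = {}
    for ch in model:
        residues = []
        for res in ch:
            ca = res.find_atom("CA", "*")
            if ca is None:
                continue
            mass = sum(a.element.weight for a in res)
            if len(res) <= 1:  # CA-only record: use the mean residue mass
                mass = MEAN_RESIDUE_MASS
            atoms = [(a.element.weight, np.array([a.pos.x, a.pos.y, a.pos.z])) for a in res]
            residues.append(
                Residue(
                    index=res.seqid.num,
                    ca=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                    mass=mass,
                    atoms=atoms,
                )
            )
        residues.sort(key=lambda r: r.index)
        present = [r.index for r in residues]
        if len(set(present)) != len(present):
            raise ValueError(f"duplicate residue indices in chain {ch.name} of {path}")
        gaps = sorted(set(range(min(present), max(present) + 1)) - set(present)) if present else []
        if gaps:
            missing[ch.name] = gaps
        chains.append((ch.name, residues))
    return AtomicModel(chains=chains, missing=missing)


def write_structure(model: AtomicModel, path) -> None:
    """Write CA-trace PDB (one ALA CA atom per residue)."""
    st = gemmi.Structure()
    st.name = "model"
    gm = gemmi.Model("1")
    for cid, residues in model.chains:
        ch = gemmi.Chain(cid)
        for r in residues:
            gr = gemmi.Residue()
            gr.name = "ALA"
            gr.seqid = gemmi.SeqId(int(r.index), " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, r.ca))
            gr.add_atom(atom)
            ch.add_residue(gr)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def read_density_map(path) -> VoxelMap:
    """Read an MRC/CCP4 map; axes are normalized to canonical (x, y, z) order.

    Raises on anisotropic voxel spacing, which this pipeline does not support.
    """
    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))  # reorders permuted axes to canonical order
    grid = m.grid
    sx, sy, sz = grid.spacing
    if not (abs(sx - sy) < 1e-4 and abs(sx - sz) < 1e-4):
        raise ValueError(f"anisotropic voxel spacing {grid.spacing} is unsupported")
    data = np.array(grid.array, dtype=float)
    data = np.nan_to_num(data, nan=0.0)
    origin = np.array([m.header_float(50), m.header_float(51), m.header_float(52)])
    return VoxelMap(origin=origin, spacing=float(sx), data=data)


def write_density_map(vmap: VoxelMap, path) -> None:
    nx, ny, nz = vmap.data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    grid.set_unit_cell(
        gemmi.UnitCell(nx * vmap.spacing, ny * vmap.spacing, nz * vmap.spacing, 90, 90, 90)
    )
    grid.array[:] = vmap.data.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for i, v in enumerate(vmap.origin):
        m.set_header_float(50 + i, float(v))
    m.write_ccp4_map(str(path))


def read_crosslink_table(path):
    """Read a cross-link TSV into a :class:`~intmod.xl_dataset.CrossLinkSet`.

    Required columns: protein1, residue1, protein2, residue2, n_spectra,
    source. Rows carrying the same unordered (protein, residue) pair are
    collapsed with spectral counts summed.
    """
    from .xl_dataset import CrossLink, CrossLinkSet

    df = pd.read_csv(path, sep="\t", dtype={"protein1": str, "protein2": str})
    for col in XL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cross-link table missing required column {col!r}")
    links = []
    for i, row in df.iterrows():
        try:
            r1, r2, n = int(row.residue1), int(row.residue2), int(row.n_spectra)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed cross-link row at line {i + 2}: {exc}") from exc
        if n < 0:
            raise ValueError(f"negative spectral count at line {i + 2}")
        links.append(
            CrossLink(
                protein1=str(row.protein1),
                residue1=r1,
                protein2=str(row.protein2),
                residue2=r2,
                n_spectra=n,
                source=str(row.source),
            )
        )
    return CrossLinkSet.from_links(links)


def write_crosslink_table(xlset, path) -> None:
    rows = []
    for xl in xlset:
        rows.append(
            {
                "protein1": xl.protein1,
                "residue1": xl.residue1,
                "protein2": xl.protein2,
                "residue2": xl.residue2,
                "n_spectra": xl.n_spectra,
                "source": xl.source,
                "xl_class": xl.xl_class or "",
            }
        )
    pd.DataFrame(rows, columns=XL_COLUMNS + ["xl_class"]).to_csv(path, sep="\t", index=False)


def write_gmm(gmm, path) -> None:
    """Plain-text GMM: one component per line — weight, 3 mean values, and the
    6 upper-triangle covariance values (xx, xy, xz, yy, yz, zz)."""
    lines = ["# weight mx my mz cxx cxy cxz cyy cyz czz"]
    for w, mu, cov in zip(gmm.weights, gmm.means, gmm.covariances):
        tri = [cov[0, 0], cov[0, 1], cov[0, 2], cov[1, 1], cov[1, 2], cov[2, 2]]
        vals = [w, *mu, *tri]
        lines.append(" ".join(f"{v:.10g}" for v in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmm(path):
    from .representation import GMM

    weights, means, covs = [], [], []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        vals = [float(x) for x in line.split()]
        if len(vals) != 10:
            raise ValueError(f"malformed GMM line {ln}: expected 10 values, got {len(vals)}")
        weights.append(vals[0])
        means.append(vals[1:4])
        xx, xy, xz, yy, yz, zz = vals[4:10]
        covs.append([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
    return GMM(
        weights=np.array(weights), means=np.array(means), covariances=np.array(covs)
    )


# ---------------------------------------------------------------------------
# Topology configuration
# ---------------------------------------------------------------------------


@dataclass
class SegmentSpec:
    """One representation segment of a subunit."""

    first: int
    last: int
    kind: str  # "rigid" | "flexible"
    body: str | None = None  # rigid-body id; segments may share a body
    source_file: str | None = None
    source_chain: str | None = None
    fixed: bool = False

    @property
    def n_residues(self) -> int:
        return self.last - self.first + 1


@dataclass
class SubunitSpec:
    name: str
    length: int
    modules: list  # [(first, last, module_name)]
    segments: list  # [SegmentSpec]

    def module_of(self, residue: int) -> str:
        for first, last, module in self.modules:
            if first <= residue <= last:
                return module
        raise KeyError(
            f"residue {residue} of subunit {self.name} outside any declared module range"
        )


@dataclass
class TopologyConfig:
    subunits: list  # [SubunitSpec]
    restraints: dict = field(default_factory=dict)
    sampling: dict = field(default_factory=dict)

    def subunit(self, name: str) -> SubunitSpec:
        for su in self.subunits:
            if su.name == name:
                return su
        raise KeyError(f"unknown subunit {name!r}")

    def module_of(self, subunit: str, residue: int) -> str:
        return self.subunit(subunit).module_of(residue)

    def validate(self) -> None:
        for su in self.subunits:
            covered = np.zeros(su.length, dtype=int)
            for seg in su.segments:
                if not (1 <= seg.first <= seg.last <= su.length):
                    raise ValueError(
                        f"segment {seg.first}-{seg.last} outside subunit {su.name}"
                    )
                covered[seg.first - 1 : seg.last] += 1
            if (covered > 1).any():
                raise ValueError(f"overlapping segments in subunit {su.name}")
            if (covered == 0).any():
                raise ValueError(f"residues of {su.name} not covered by any segment")
            mod_cov = np.zeros(su.length, dtype=int)
            for first, last, _ in su.modules:
                mod_cov[first - 1 : last] += 1
            if (mod_cov != 1).any():
                raise ValueError(
                    f"module assignment of {su.name} must cover every residue exactly once"
                )


def _parse_range(r) -> tuple[int, int]:
    return int(r[0]), int(r[1])


def topology_from_dict(doc: dict) -> TopologyConfig:
    subunits = []
    for su in doc.get("subunits", []):
        modules = []
        for m in su.get("modules", []):
            first, last = _parse_range(m["range"])
            modules.append((first, last, str(m["module"])))
        segments = []
        for s in su.get("segments", []):
            first, last = _parse_range(s["range"])
            src = s.get("source", {}) or {}
            segments.append(
                SegmentSpec(
                    first=first,
                    last=last,
                    kind=str(s["kind"]),
                    body=s.get("body"),
                    source_file=src.get("file"),
                    source_chain=src.get("chain"),
                    fixed=bool(s.get("fixed", False)),
                )
            )
        subunits.append(
            SubunitSpec(
                name=str(su["name"]), length=int(su["length"]), modules=modules, segments=segments
            )
        )
    cfg = TopologyConfig(
        subunits=subunits,
        restraints=doc.get("restraints", {}) or {},
        sampling=doc.get("sampling", {}) or {},
    )
    cfg.validate()
    return cfg


def read_topology(path) -> TopologyConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return topology_from_dict(doc)


def write_topology(cfg: TopologyConfig, path) -> None:
    doc = {
        "subunits": [
            {
                "name": su.name,
                "length": su.length,
                "modules": [
                    {"range": [f, l], "module": m} for f, l, m in su.modules
                ],
                "segments": [
                    {
                        "range": [s.first, s.last],
                        "kind": s.kind,
                        **({"body": s.body} if s.body else {}),
                        **(
                            {"source": {"file": s.source_file, "chain": s.source_chain}}
                            if s.source_file
                            else {}
                        ),
                        **({"fixed": True} if s.fixed else {}),
                    }
                    for s in su.segments
                ],
            }
            for su in cfg.subunits
        ],
        "restraints": cfg.restraints,
        "sampling": cfg.sampling,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
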