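"""Generate the toy assembly and its simulated data, and write them out.

Creates, under --out (default results/toy):
  topology.yaml    subunit layout (rigid bodies, flexible linker, modules)
  truth_<X>.pdb    per-subunit ground-truth CA traces
  crosslinks.tsv   simulated cross-links (5% planted noise by default)
  density.mrc      simulated EM map
  density.gmm      the generating Gaussian mixture
  csms.tsv         synthetic CSM score table for the FDR stage

Every output is reproducible from --seed.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from intmod.io_formats import (
    AtomicModel,
    Residue,
    write_crosslink_table,
    write_density_map,
    write_gmm,
    write_structure,
    write_topology,
)
from intmod.synthetic_data import (
    make_toy_assembly,
    simulate_crosslinks,
    simulate_csm_table,
    simulate_density,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-true", type=int, default=50)
    ap.add_argument("--noise", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results/toy"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    truth, model = make_toy_assembly(rng=rng)
    xlset = simulate_crosslinks(
        truth, model, n_true=args.n_true, noise_fraction=args.noise, rng=rng
    )
    gmm, vmap = simulate_density(truth, seed=args.seed)
    csms = simulate_csm_table(rng=rng)

    # Stage-1 style density segmentation: subtract the fixed (docked)
    # subunit's mixture, apportion the remainder between modules by mass
    from intmod.analysis import segment_density
    from intmod.representation import fit_gmm, GMM
    import numpy as np_

    fixed_name = truth.spec.names[truth.spec.fixed_subunit]
    fixed_coords = truth.coords[fixed_name]
    fg = fit_gmm(fixed_coords, n_components=max(1, len(fixed_coords) // 10), seed=args.seed, reg_covar=1.0)
    fixed_gmm = GMM(fg.weights, fg.means, fg.covariances + 25.0 * np_.eye(3))
    module_masses = {}
    for i, name in enumerate(truth.spec.names):
        if name == fixed_name:
            continue
        m = truth.spec.modules[i]
        module_masses[m] = module_masses.get(m, 0.0) + truth.spec.lengths[i] * 110.0
    segments = segment_density(
        vmap, fixed_gmm, module_masses,
        fixed_mass=truth.spec.lengths[truth.spec.fixed_subunit] * 110.0,
        threshold=1e-4,
    )
    for mod, seg_map in segments.items():
        write_density_map(seg_map, args.out / f"density_{mod}.mrc")

    write_topology(truth.topology, args.out / "topology.yaml")
    for name, xyz in truth.coords.items():
        chains = [(name, [Residue(i + 1, xyz[i]) for i in range(len(xyz))])]
        write_structure(AtomicModel(chains=chains), args.out / f"truth_{name}.pdb")
    write_crosslink_table(xlset, args.out / "crosslinks.tsv")
    write_density_map(vmap, args.out / "density.mrc")
    write_gmm(gmm, args.out / "density.gmm")
    csms.to_csv(args.out / "csms.tsv", sep="\t", index=False)

    n_intra = sum(1 for x in xlset if x.xl_class == "intra_module")
    summary = {
        "seed": args.seed,
        "subunits": {su.name: su.length for su in truth.topology.subunits},
        "n_crosslinks": len(xlset),
        "n_intra_module": n_intra,
        "n_inter_module": len(xlset) - n_intra,
        "planted_noise_fraction": args.noise,
        "density_components": len(gmm),
        "map_shape": list(vmap.data.shape),
        "segmented_module_voxels": {
            mod: int((seg.data > 0).sum()) for mod, seg in segments.items()
        },
    }
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
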