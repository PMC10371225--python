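#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a 100-parcel spherical "cortex" and a 30-voxel volumetric
"subcortex", simulates the 19-molecule density panels (3 planted cortical
axes, 1 subcortical axis), and the 20-subject FC/SC/MPC stacks. Everything
is written under results/data/ as TSV + JSON sidecars.
"""

from pathlib import Path

import numpy as np

import receptome as rc

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cortex = rc.make_sphere_geometry(100, seed=SEED)
    subcortex = rc.make_volumetric_geometry(30, seed=SEED + 1)
    np.savetxt(OUT / "cortex_dist.tsv", cortex.dist, delimiter="\t")
    np.savetxt(OUT / "cortex_coords.tsv", cortex.coords, delimiter="\t")
    np.savetxt(OUT / "subcortex_dist.tsv", subcortex.dist, delimiter="\t")

    panel, truth = rc.simulate_density_panel(cortex, 19, 3, 0.1, seed=SEED + 2)
    rc.write_panel(panel, OUT / "cortical_panel.tsv")
    np.savetxt(OUT / "cortical_planted_axes.tsv", truth.planted_axes, delimiter="\t")

    sub_panel, sub_truth = rc.simulate_density_panel(
        subcortex, 19, 1, 0.1, seed=SEED + 3
    )
    rc.write_panel(sub_panel, OUT / "subcortical_panel.tsv")
    np.savetxt(OUT / "subcortical_planted_axes.tsv", sub_truth.planted_axes,
               delimiter="\t")

    for kind in ("FC", "SC", "MPC"):
        stack = rc.simulate_subject_stack(cortex, 20, kind, seed=SEED + 4)
        for i, m in enumerate(stack):
            rc.write_matrix(m, OUT / f"{kind.lower()}_subject{i:02d}.tsv")

    print(f"wrote synthetic cortex (100 parcels), subcortex (30 voxels), "
          f"panels and 20-subject FC/SC/MPC stacks to {OUT}")


if __name__ == "__main__":
    main()
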