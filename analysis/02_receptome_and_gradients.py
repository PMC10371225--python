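#!/usr/bin/env python
"""Build the receptomes and decompose them into gradients.

Reads the panels from results/data/, z-scores them (jointly for cortex,
within-compartment for subcortex), builds the square and subcortico-cortical
cross receptomes, and runs the gradient pipeline (90% row threshold,
normalized-angle kernel, diffusion embedding at alpha = 0.5). Reports the
relative variance of the leading gradients, how well gradient 1 recovers the
planted axes, per-molecule gradient correlations against variogram-matched
nulls, and the surrogate significance of each component's variance share.
"""

import json
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

import receptome as rc

SEED = 2
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "gradients"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    panel = rc.read_panel(DATA / "cortical_panel.tsv")
    axes = np.loadtxt(DATA / "cortical_planted_axes.tsv")
    dist = np.loadtxt(DATA / "cortex_dist.tsv")
    zpanel = rc.zscore_panel(panel, "joint")

    receptome = rc.build_receptome(zpanel)
    rc.write_matrix(receptome, OUT / "cortical_receptome.tsv")
    gs = rc.gradients_from_matrix(receptome, 90.0, 0.5, 10)
    np.savetxt(OUT / "cortical_gradients.tsv", gs.components, delimiter="\t")

    recovery = [
        max(abs(spearmanr(gs.components[:, k], axes[:, a]).statistic)
            for a in range(axes.shape[1]))
        for k in range(3)
    ]
    print("cortical receptome gradients:")
    for k in range(3):
        print(f"  G{k + 1}: {100 * gs.variance_fraction[k]:.1f}% relative variance, "
              f"best planted-axis |rho| = {recovery[k]:.2f}")

    nulls = rc.vgm_surrogates(gs.components[:, 0], dist, 500, seed=SEED)
    fingerprints = rc.correlate_fingerprints_with_gradient(
        zpanel, gs.components[:, 0], nulls
    )
    n_sig = sum(sig for _, _, sig in fingerprints.values())
    print(f"  G1 fingerprint correlations: {n_sig}/19 molecules significant "
          "against variogram-matched nulls")

    geom = rc.Geometry(
        coords=np.loadtxt(DATA / "cortex_coords.tsv"),
        dist=dist,
        hemisphere=np.full(100, "L"),
        medial_mask=np.zeros(100, dtype=bool),
    )
    p_comp, obs_vf, _, skipped = rc.component_significance(
        panel, geom, n_null=100, seed=SEED + 1
    )
    n_sig_comp = int((p_comp < 0.05).sum())
    print(f"  {n_sig_comp}/10 components concentrate more relative variance "
          f"than autocorrelation-matched surrogate receptomes "
          f"(p < 0.05; {skipped} surrogates skipped). Smooth surrogate maps "
          "share low-order harmonics, so their receptomes are themselves "
          "low-dimensional - a conservative null on this synthetic cortex.")

    # subcortical + cross-compartment receptome
    sub_panel = rc.read_panel(DATA / "subcortical_panel.tsv")
    sub_axes = np.loadtxt(DATA / "subcortical_planted_axes.tsv", ndmin=2)
    sub_z = rc.zscore_panel(sub_panel, "subcortical")
    sub_rc = rc.build_receptome(sub_z)
    sub_gs = rc.gradients_from_matrix(sub_rc, 90.0, 0.5, 5)
    rho_sub = abs(spearmanr(sub_gs.components[:, 0], sub_axes[:, 0]).statistic)
    print(f"subcortical receptome: G1 {100 * sub_gs.variance_fraction[0]:.1f}% "
          f"relative variance, planted-axis |rho| = {rho_sub:.2f}")

    cross = rc.build_cross_receptome(sub_z, zpanel)
    cross_gs = rc.embed_rectangular(cross, 90.0, 0.5, 5)
    rho_proj = abs(spearmanr(cross_gs.col_projection[:, 0],
                             gs.components[:, 0]).statistic)
    print(f"subcortico-cortical receptome: cortical projection of G1 correlates "
          f"with cortical G1 at |rho| = {rho_proj:.2f} (the two synthetic "
          "compartments are generated independently, so no strong overlap is "
          "expected)")

    report = {
        "variance_fraction": gs.variance_fraction.tolist(),
        "planted_axis_recovery_g1_g3": recovery,
        "g1_significant_molecules": n_sig,
        "significant_components": n_sig_comp,
        "component_p": p_comp.tolist(),
        "subcortical_variance_fraction": sub_gs.variance_fraction.tolist(),
        "subcortical_axis_recovery": rho_sub,
        "cross_projection_corr_to_cortical_g1": rho_proj,
    }
    (OUT / "summary.json").write_text(json.dumps(report, indent=1))


if __name__ == "__main__":
    main()
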