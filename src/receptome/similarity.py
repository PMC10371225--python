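"""Receptome construction: interregional Spearman similarity of fingerprints.

The receptome entry (i, j) is the Spearman rank correlation (average ranks
for ties) between the receptor fingerprints of regions i and j — the rows of
a z-scored density panel. A rectangular variant correlates fingerprints
across compartments (e.g. subcortical voxels × cortical parcels).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .matrices import SimilarityMatrix
from .panel import DensityPanel

__all__ = [
    "build_receptome",
    "build_cross_receptome",
    "correlate_fingerprints_with_gradient",
]


def _rank_rows(values: np.ndarray, what: str, ids: list[str]) -> np.ndarray:
    sd = values.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [ids[i] for i in bad[:5]]
        raise ValueError(f"constant fingerprint ({what}) for regions {names}; "
                         "Spearman correlation undefined")
    r = rankdata(values, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    return r / np.sqrt((r**2).sum(axis=1, keepdims=True))


def build_receptome(panel: DensityPanel, require_zscored: bool = True) -> SimilarityMatrix:
    """regions × regions Spearman correlation of fingerprint rows."""
    if panel.n_molecules < 3:
        raise ValueError("need at least 3 molecules for meaningful fingerprints")
    if require_zscored and panel.zscored is False:
        raise ValueError("panel must be z-scored before building the receptome")
    r = _rank_rows(panel.values, "row", panel.region_ids)
    values = np.clip(r @ r.T, -1.0, 1.0)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(
        values=values,
        row_ids=list(panel.region_ids),
        col_ids=list(panel.region_ids),
        kind="receptome",
        symmetric=True,
    )


def build_cross_receptome(
    panel_a: DensityPanel, panel_b: DensityPanel
) -> SimilarityMatrix:
    """Rectangular Spearman similarity between two compartments' fingerprints.

    Rows come from ``panel_a`` (e.g. subcortical voxels), columns from
    ``panel_b`` (e.g. cortical parcels); both must list the same molecules in
    the same order, each z-scored within its own scope.
    """
    if list(panel_a.molecules) != list(panel_b.molecules):
        raise ValueError("panels list different molecules (names or order)")
    ra = _rank_rows(panel_a.values, "row", panel_a.region_ids)
    rb = _rank_rows(panel_b.values, "column", panel_b.region_ids)
    values = np.clip(ra @ rb.T, -1.0, 1.0)
    return SimilarityMatrix(
        values=values,
        row_ids=list(panel_a.region_ids),
        col_ids=list(panel_b.region_ids),
        kind="cross",
        symmetric=False,
    )


def correlate_fingerprints_with_gradient(
    panel: DensityPanel, gradient: np.ndarray, nulls
):
    """Spearman rho of each molecule's density map with a gradient, with
    surrogate-based two-sided p-values.

    ``nulls`` is a :class:`~receptome.nulls.NullEnsemble` built for the
    gradient map; each molecule's rho is compared against the distribution
    of correlations between the surrogate gradients and that molecule.

    Returns a dict: molecule → (rho, p, significant_at_05).
    """
    from .nulls import association_test

    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape[0] != panel.n_regions:
        raise ValueError("gradient length does not match panel regions")
    out = {}
    for j, mol in enumerate(panel.molecules):
        rho, p = association_test(gradient, panel.values[:, j], nulls)
        out[mol] = (rho, p, p < 0.05)
    return out
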