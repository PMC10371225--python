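"""Diffusion-map embedding of similarity matrices into gradients.

The pipeline follows the standard gradient-mapping toolchain: per-row
sparsification at a percentile threshold (default 90, keeping each row's
top 10% strongest entries with their signs), a normalized-angle similarity
kernel turning row profiles into a non-negative affinity, and diffusion-map
embedding with anisotropic normalisation alpha (default 0.5, balancing
geometry against sampling density). Components are scaled with the
diffusion-time-0 convention lambda/(1 - lambda); a component's "relative
variance" is its eigenvalue's share of the retained non-trivial eigenvalue
mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from .geometry import Geometry
from .matrices import SimilarityMatrix
from .panel import DensityPanel

__all__ = [
    "GradientSet",
    "threshold_rows",
    "normalized_angle_affinity",
    "diffusion_embedding",
    "gradients_from_matrix",
    "embed_rectangular",
    "align_procrustes",
    "component_significance",
]


@dataclass
class GradientSet:
    """Eigenvectors ("gradients"), eigenvalues and relative-variance shares."""

    components: np.ndarray          # n_regions × k
    eigenvalues: np.ndarray         # k, non-increasing, nonnegative
    variance_fraction: np.ndarray   # k, sums to 1 over retained components
    alpha: float = 0.5
    threshold_pct: float = 90.0
    kernel: str = "normalized_angle"
    row_ids: list[str] = field(default_factory=list)
    col_projection: np.ndarray | None = None  # columns of a rectangular input

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.variance_fraction = np.asarray(self.variance_fraction, dtype=float)
        if self.components.shape[1] != self.eigenvalues.shape[0]:
            raise ValueError("component/eigenvalue count mismatch")
        if np.any(np.diff(self.eigenvalues) > 1e-10):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def k(self) -> int:
        return self.eigenvalues.shape[0]


def threshold_rows(matrix: SimilarityMatrix, pct: float = 90.0) -> SimilarityMatrix:
    """Per-row percentile sparsification keeping the strongest signed entries.

    For each row, entries below that row's ``pct``-th percentile (computed
    over off-diagonal entries, signed values) are zeroed; ties at the cutoff
    are all kept. The diagonal is zeroed and never enters the percentile.
    The result is generally asymmetric; the row-profile kernel downstream
    restores symmetry.
    """
    if not 0 <= pct < 100:
        raise ValueError("pct must be in [0, 100)")
    values = np.array(matrix.values, dtype=float)
    n, m = values.shape
    square = n == m
    out = np.zeros_like(values)
    for i in range(n):
        row = values[i]
        mask = np.ones(m, dtype=bool)
        if square:
            mask[i] = False
        cutoff = np.percentile(row[mask], pct)
        keep = mask & (row >= cutoff)
        out[i, keep] = row[keep]
        if not np.any(out[i] != 0):
            raise ValueError(f"row {matrix.row_ids[i]!r} is all-zero after thresholding")
    return SimilarityMatrix(
        values=out,
        row_ids=list(matrix.row_ids),
        col_ids=list(matrix.col_ids),
        kind="generic",
        symmetric=bool(square and np.allclose(out, out.T)),
        meta={**matrix.meta, "threshold_pct": pct},
    )


def normalized_angle_affinity(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Affinity(i, j) = 1 - arccos(cosine(row_i, row_j)) / pi.

    Maps parallel row profiles to 1, orthogonal to 0.5, anti-parallel to 0;
    always symmetric and in [0, 1] regardless of the input's signs.
    """
    values = np.asarray(matrix.values, dtype=float)
    norms = np.linalg.norm(values, axis=1)
    if np.any(norms == 0):
        bad = [matrix.row_ids[i] for i in np.where(norms == 0)[0][:5]]
        raise ValueError(f"zero-norm rows {bad}; cosine undefined")
    cos = np.clip((values / norms[:, None]) @ (values / norms[:, None]).T, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    aff = 0.5 * (aff + aff.T)
    np.fill_diagonal(aff, 1.0)
    return SimilarityMatrix(
        values=aff,
        row_ids=list(matrix.row_ids),
        col_ids=list(matrix.row_ids),
        kind="affinity",
        symmetric=True,
    )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    # deterministic sign: the node with maximal |value| is positive
    out = components.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def diffusion_embedding(
    affinity: SimilarityMatrix, alpha: float = 0.5, n_components: int = 10
) -> GradientSet:
    """Diffusion-map embedding of a symmetric non-negative affinity.

    Anisotropic normalisation W' = W / (d_i^alpha d_j^alpha) is followed by
    row-normalisation to a Markov operator, solved through its symmetric
    conjugate. The trivial constant eigenvector is dropped; retained
    components are scaled by lambda/(1 - lambda) (diffusion time 0) and
    sign-fixed so the node of maximal |value| is positive.
    """
    W = np.asarray(affinity.values, dtype=float)
    n = W.shape[0]
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be square symmetric")
    if W.min() < -1e-12:
        raise ValueError("affinity must be non-negative")
    n_comp_graph, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"affinity graph is disconnected ({n_comp_graph} components); "
            "diffusion embedding requires an irreducible operator"
        )
    if not 1 <= n_components < n:
        raise ValueError("need 1 <= n_components < n_regions")
    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    d1 = W1.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d1)
    A = W1 * np.outer(inv_sqrt, inv_sqrt)
    A = 0.5 * (A + A.T)
    lambdas, vecs = eigh(A)
    order = np.argsort(lambdas)[::-1]
    lambdas, vecs = lambdas[order], vecs[:, order]
    # psi = D^{-1/2} v, rescaled so the trivial eigenvector is constant 1
    psi = vecs / vecs[:, [0]]
    lam = lambdas[1 : n_components + 1]
    if np.any(lam < -1e-8):
        raise ValueError("retained eigenvalues are negative; affinity too indefinite")
    lam = np.clip(lam, 0.0, 1.0 - 1e-12)
    scale = lam / (1.0 - lam)
    components = _fix_signs(psi[:, 1 : n_components + 1] * scale[None, :])
    vf = lam / lam.sum() if lam.sum() > 0 else np.full(lam.shape, np.nan)
    return GradientSet(
        components=components,
        eigenvalues=lam,
        variance_fraction=vf,
        alpha=alpha,
        row_ids=list(affinity.row_ids),
    )


def gradients_from_matrix(
    matrix: SimilarityMatrix,
    threshold_pct: float = 90.0,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientSet:
    """threshold_rows → normalized-angle kernel → diffusion embedding."""
    sparse = threshold_rows(matrix, threshold_pct)
    aff = normalized_angle_affinity(sparse)
    gs = diffusion_embedding(aff, alpha=alpha, n_components=n_components)
    gs.threshold_pct = threshold_pct
    return gs


def embed_rectangular(
    cross: SimilarityMatrix,
    threshold_pct: float = 90.0,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientSet:
    """Embed the rows of a rectangular cross-similarity; project the columns.

    The affinity is built over row profiles exactly as in the square case.
    Column values are an affinity-weighted average of row gradient values,
    with weights (cross + 1)/2 mapping Spearman similarity onto [0, 1].
    """
    gs = gradients_from_matrix(cross, threshold_pct, alpha, n_components)
    weights = (np.asarray(cross.values, dtype=float) + 1.0) / 2.0
    colsum = weights.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("a column has no positive affinity to any row")
    gs.col_projection = (weights.T @ gs.components) / colsum[:, None]
    return gs


def align_procrustes(reference: GradientSet, target: GradientSet) -> GradientSet:
    """Rotate/reflect target components onto the reference (no scaling)."""
    if reference.k != target.k:
        raise ValueError("gradient sets have different numbers of components")
    R, _ = orthogonal_procrustes(target.components, reference.components)
    return GradientSet(
        components=target.components @ R,
        eigenvalues=target.eigenvalues.copy(),
        variance_fraction=target.variance_fraction.copy(),
        alpha=target.alpha,
        threshold_pct=target.threshold_pct,
        kernel=target.kernel,
        row_ids=list(target.row_ids),
    )


def component_significance(
    panel: DensityPanel,
    geom: Geometry,
    n_null: int = 1000,
    seed: int = 0,
    threshold_pct: float = 90.0,
    alpha: float = 0.5,
    n_components: int = 10,
):
    """Surrogate test of how much variance each gradient explains.

    Each molecule map is replaced by a variogram-matched surrogate
    (preserving its spatial autocorrelation), the receptome is rebuilt and
    re-embedded, and the observed relative-variance fractions are compared
    against the surrogate distribution: p_i = (1 + #{null vf_i >= observed
    vf_i}) / (n_valid + 1). Surrogate panels that produce degenerate rows
    are skipped and counted.

    Returns (p_values, observed_vf, null_vf_matrix, n_skipped).
    """
    from .nulls import vgm_surrogates
    from .panel import zscore_panel
    from .similarity import build_receptome

    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    obs = gradients_from_matrix(
        build_receptome(zscore_panel(panel, "joint")), threshold_pct, alpha, n_components
    ).variance_fraction
    rng = np.random.default_rng(seed)
    per_mol = [
        vgm_surrogates(panel.values[:, j], geom.dist, n_null, int(rng.integers(2**31)))
        for j in range(panel.n_molecules)
    ]
    null_vf = []
    skipped = 0
    for s in range(n_null):
        surro_values = np.column_stack([pm.surrogates[s] for pm in per_mol])
        surro_panel = DensityPanel(
            values=surro_values,
            molecules=list(panel.molecules),
            region_ids=list(panel.region_ids),
            compartment=panel.compartment.copy(),
        )
        try:
            vf = gradients_from_matrix(
                build_receptome(zscore_panel(surro_panel, "joint")),
                threshold_pct, alpha, n_components,
            ).variance_fraction
        except ValueError:
            skipped += 1
            continue
        null_vf.append(vf)
    null_vf = np.array(null_vf)
    n_valid = null_vf.shape[0]
    if n_valid == 0:
        raise ArithmeticError("all surrogate embeddings failed")
    p = (1 + (null_vf >= obs[None, :]).sum(axis=0)) / (n_valid + 1)
    return p, obs, null_vf, skipped
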