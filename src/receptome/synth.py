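"""Synthetic inputs with the statistical structure the analyses assume.

Every downstream stage (panel → receptome → gradients → nulls →
communities → coupling) is exercised on data from this module: spatially
autocorrelated molecule maps with planted low-dimensional gradients, signed
block matrices with planted communities, and subject stacks of FC/SC/MPC-like
matrices with distance-dependent edge structure. Each generator returns the
ground truth it planted so recovery can be tested, and is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .matrices import SimilarityMatrix

__all__ = [
    "SynthTruth",
    "simulate_autocorrelated_map",
    "simulate_density_panel",
    "simulate_signed_blocks",
    "simulate_subject_stack",
    "simulate_coupled_matrix",
]


@dataclass
class SynthTruth:
    """Ground truth planted by a generator (whatever fields apply)."""

    planted_axes: np.ndarray | None = None       # n_nodes × k latent gradients
    loadings: np.ndarray | None = None           # molecules × k
    planted_partition: np.ndarray | None = None  # node labels
    coupling_by_class: dict | None = None        # class label → target coupling
    params: dict = field(default_factory=dict)


def simulate_autocorrelated_map(
    geom: Geometry, length_scale: float, seed: int, jitter: float = 1e-8
) -> np.ndarray:
    """Draw a zero-mean Gaussian random field with covariance exp(-d/l).

    The exponential kernel gives rough, heavy-tailed fields — a harder test
    for variogram fitting than a smooth Gaussian kernel. A small diagonal
    jitter keeps the Cholesky factorisation stable.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    cov = np.exp(-geom.dist / length_scale)
    cov[np.diag_indices_from(cov)] += jitter
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological geometry
        raise ArithmeticError("covariance not positive definite after jitter") from exc
    rng = np.random.default_rng(seed)
    return chol @ rng.standard_normal(geom.n_nodes)


def _orthogonalized_axes(
    geom: Geometry, n_axes: int, length_scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth maps, centered then Gram–Schmidt orthogonalised, unit variance."""
    axes = np.column_stack(
        [
            simulate_autocorrelated_map(geom, length_scale, int(rng.integers(2**31)))
            for _ in range(n_axes)
        ]
    )
    axes -= axes.mean(axis=0)
    q, _ = np.linalg.qr(axes)
    q /= q.std(axis=0, ddof=0)
    return q


def simulate_density_panel(
    geom: Geometry,
    n_molecules: int = 19,
    n_axes: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    length_scale: float = 0.5,
):
    """Molecule maps as noisy mixtures of k orthogonal smooth gradients.

    Each molecule m is sum_k loadings[m, k] * axis_k + noise. Axes have unit
    variance so ``noise_sd`` reads directly as a noise-to-signal fraction.

    Returns (panel, truth); import of :class:`~receptome.panel.DensityPanel`
    is deferred to avoid a cycle at module import time.
    """
    from .panel import MOLECULES_19, DensityPanel

    if n_axes < 1 or n_molecules < n_axes:
        raise ValueError("need n_molecules >= n_axes >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    axes = _orthogonalized_axes(geom, n_axes, length_scale, rng)
    loadings = rng.standard_normal((n_molecules, n_axes))
    values = axes @ loadings.T + noise_sd * rng.standard_normal(
        (geom.n_nodes, n_molecules)
    )
    if n_molecules == len(MOLECULES_19):
        molecules = list(MOLECULES_19)
    else:
        molecules = [f"mol{m}" for m in range(n_molecules)]
    compartment = "cortical" if geom.kind == "sphere" else "subcortical"
    panel = DensityPanel(
        values=values,
        molecules=molecules,
        compartment=np.full(geom.n_nodes, compartment),
    )
    truth = SynthTruth(
        planted_axes=axes,
        loadings=loadings,
        params={"noise_sd": noise_sd, "length_scale": length_scale, "seed": seed},
    )
    return panel, truth


def simulate_signed_blocks(
    n_nodes: int,
    n_blocks: int,
    w_in: float = 0.8,
    w_out: float = -0.4,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[SimilarityMatrix, SynthTruth]:
    """Signed similarity matrix with planted communities.

    Within-block entries are ``w_in`` (> 0), between-block ``w_out`` (< 0),
    plus symmetric Gaussian noise, clipped to [-1, 1]; diagonal is 1.
    """
    if not (w_in > 0 > w_out):
        raise ValueError("need w_in > 0 > w_out")
    if n_blocks > n_nodes:
        raise ValueError("n_blocks cannot exceed n_nodes")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    labels = np.repeat(np.arange(n_blocks), int(np.ceil(n_nodes / n_blocks)))[:n_nodes]
    same = labels[:, None] == labels[None, :]
    values = np.where(same, w_in, w_out).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0, noise_sd, size=(n_nodes, n_nodes))
        values += np.triu(noise, 1) + np.triu(noise, 1).T
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    mat = SimilarityMatrix(values=values, kind="receptome")
    truth = SynthTruth(
        planted_partition=labels,
        params={"w_in": w_in, "w_out": w_out, "noise_sd": noise_sd, "seed": seed},
    )
    return mat, truth


def _group_fc_template(geom: Geometry, rng: np.random.Generator) -> np.ndarray:
    """Latent spatial loadings whose signal correlations define group FC."""
    k = 4
    loadings = np.column_stack(
        [
            simulate_autocorrelated_map(geom, 0.7, int(rng.integers(2**31)))
            for _ in range(k)
        ]
    )
    return loadings


def _correlation_from_signals(signals: np.ndarray) -> np.ndarray:
    c = np.corrcoef(signals)
    np.fill_diagonal(c, 1.0)
    return np.clip(c, -1.0, 1.0)


def simulate_subject_stack(
    geom: Geometry,
    n_subjects: int,
    kind: str,
    seed: int = 0,
    n_timepoints: int = 150,
    edge_length_scale: float = 0.6,
) -> list[SimilarityMatrix]:
    """Per-subject FC / SC / MPC-like matrices around a group template.

    FC: sample correlations of latent-factor time series (entries in
    [-1, 1], diagonal 1). SC: nonnegative sparse weights whose edges are
    kept with probability exp(-d / edge_length_scale), so short-range
    connections are over-represented exactly as the distance-dependent
    consensus step must correct. MPC: symmetric log-scale covariance-like
    entries with subject noise.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if kind not in {"FC", "SC", "MPC"}:
        raise ValueError(f"unknown stack kind {kind!r}")
    rng = np.random.default_rng(seed)
    n = geom.n_nodes
    out: list[SimilarityMatrix] = []
    if kind == "FC":
        loadings = _group_fc_template(geom, rng)
        for _ in range(n_subjects):
            factors = rng.standard_normal((loadings.shape[1], n_timepoints))
            signals = loadings @ factors + 1.5 * rng.standard_normal((n, n_timepoints))
            c = _correlation_from_signals(signals)
            out.append(SimilarityMatrix(values=c, kind="FC"))
    elif kind == "SC":
        base_w = np.exp(rng.normal(0, 1, size=(n, n)))
        base_w = np.triu(base_w, 1) + np.triu(base_w, 1).T
        p_edge = np.exp(-geom.dist / edge_length_scale)
        np.fill_diagonal(p_edge, 0.0)
        for _ in range(n_subjects):
            u = rng.random((n, n))
            mask = np.triu(u, 1) < np.triu(p_edge, 1)
            mask = mask | mask.T
            w = base_w * np.exp(rng.normal(0, 0.3, size=(n, n))) * mask
            w = np.triu(w, 1) + np.triu(w, 1).T
            out.append(SimilarityMatrix(values=w, kind="SC"))
    else:  # MPC
        g = np.column_stack(
            [
                simulate_autocorrelated_map(geom, 0.8, int(rng.integers(2**31)))
                for _ in range(3)
            ]
        )
        template = np.log1p(np.exp(-0.5 * ((g[:, None, :] - g[None, :, :]) ** 2).sum(-1)))
        for _ in range(n_subjects):
            noise = rng.normal(0, 0.05, size=(n, n))
            m = template + np.triu(noise, 1) + np.triu(noise, 1).T
            np.fill_diagonal(m, template.diagonal())
            out.append(SimilarityMatrix(values=m, kind="MPC"))
    return out


def simulate_coupled_matrix(
    reference: SimilarityMatrix,
    class_labels: np.ndarray,
    coupling_by_class: dict,
    seed: int = 0,
) -> tuple[SimilarityMatrix, SynthTruth]:
    """A matrix whose row-wise coupling to ``reference`` differs by class.

    Row i is a mixture c * reference_row_i + sqrt(1 - c^2) * noise with c
    the target coupling of region i's class — emulating class-dependent
    structure-receptome coupling. The result is not symmetrised so the
    planted per-row coupling stays exact in expectation.
    """
    labels = np.asarray(class_labels)
    vals = np.asarray(reference.values, dtype=float)
    n = vals.shape[0]
    if labels.shape[0] != n:
        raise ValueError("class labels do not match matrix size")
    missing = set(np.unique(labels)) - set(coupling_by_class)
    if missing:
        raise ValueError(f"no coupling target for classes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    off = ~np.eye(n, dtype=bool)
    z = vals.copy()
    z[off] = (z[off] - z[off].mean()) / z[off].std()
    out = np.zeros_like(vals)
    for i in range(n):
        c = float(coupling_by_class[labels[i]])
        noise = rng.standard_normal(n)
        out[i] = c * z[i] + np.sqrt(max(0.0, 1 - c**2)) * noise
    np.fill_diagonal(out, 0.0)
    mat = SimilarityMatrix(values=out, kind="generic", row_ids=list(reference.row_ids),
                           col_ids=list(reference.col_ids))
    truth = SynthTruth(coupling_by_class=dict(coupling_by_class), params={"seed": seed})
    return mat, truth
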