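"""Group-consensus connectivity matrices and receptome coupling statistics.

Consensus builders follow the field's standard recipes: FC is averaged on
the Fisher r-to-z scale; SC is log(1 + w)-averaged and then thresholded
within edge-length bins so the consensus keeps the average subject's edge
count *and* the pooled subject edge-length distribution (plain averaging
over-represents short-range connections); MPC is the partial correlation of
depth-wise intensity profiles controlling for the grand-mean profile,
monotonically log-transformed. Coupling is the row-wise Spearman
correlation between the receptome and another modality over shared nonzero
entries, compared across cytoarchitectural classes with Kruskal-Wallis and
Dunn's post hoc test (Bonferroni).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import kruskal, norm, rankdata, spearmanr

from .matrices import SimilarityMatrix

__all__ = [
    "ClassAtlas",
    "ClassComparisonResult",
    "consensus_fc",
    "consensus_sc",
    "compute_mpc",
    "row_coupling",
    "class_comparison",
]


@dataclass
class ClassAtlas:
    """Per-region categorical labels (e.g. the four Mesulam laminar classes
    idiotypic / unimodal / heteromodal / paralimbic, or functional networks)."""

    labels: np.ndarray
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.names is None:
            self.names = [str(x) for x in np.unique(self.labels)]


@dataclass
class ClassComparisonResult:
    """Kruskal-Wallis h with Dunn pairwise z and Bonferroni-adjusted p."""

    h: float
    p_global: float
    pairwise: dict  # (class_a, class_b) -> {"z": ..., "p_adj": ...}
    class_means: dict


def consensus_fc(stack: list[SimilarityMatrix], back_transform: bool = False) -> SimilarityMatrix:
    """Average subject FC matrices on the Fisher r-to-z scale.

    Values are kept on the z scale by default (all downstream uses are
    rank-based, for which the scales are equivalent); ``back_transform``
    returns to correlations via tanh. The diagonal is zeroed.
    """
    if not stack:
        raise ValueError("empty FC stack")
    n = stack[0].shape[0]
    z_sum = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    for k, mat in enumerate(stack):
        v = np.asarray(mat.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError("FC matrices differ in shape")
        if np.any(np.abs(v[off]) >= 1):
            i, j = np.argwhere((np.abs(v) >= 1) & off)[0]
            raise ValueError(
                f"|r| >= 1 at entry ({i}, {j}) of subject {k}: infinite z-transform"
            )
        z = np.zeros_like(v)
        z[off] = np.arctanh(v[off])
        z_sum += z
    out = z_sum / len(stack)
    if back_transform:
        out = np.tanh(out)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return SimilarityMatrix(values=out, row_ids=list(stack[0].row_ids), kind="FC")


def consensus_sc(
    stack: list[SimilarityMatrix], dist: np.ndarray, n_bins: int = 10
) -> SimilarityMatrix:
    """Distance-binned consistency thresholding of log-averaged SC.

    Subject matrices are log(1 + w)-transformed and averaged; edges are then
    retained per edge-length bin, most-consistent first (ties by higher mean
    weight), with per-bin retention counts matched to the pooled subject
    edge-length distribution and the total matched to the average subject
    edge count. This corrects the short-edge over-representation a naive
    average-and-threshold consensus shows.
    """
    if not stack:
        raise ValueError("empty SC stack")
    n = stack[0].shape[0]
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (n, n):
        raise ValueError("distance matrix does not match SC matrices")
    iu, ju = np.triu_indices(n, 1)
    supports = []
    log_sum = np.zeros((n, n))
    for mat in stack:
        v = np.asarray(mat.values, dtype=float)
        if v.shape != (n, n):
            raise ValueError("SC matrices differ in shape")
        if v.min() < 0:
            raise ValueError("SC weights must be nonnegative")
        supports.append(v[iu, ju] > 0)
        log_sum += np.log1p(v)
    log_mean = log_sum / len(stack)
    supports = np.array(supports)                   # n_subjects × n_edges
    consistency = supports.sum(axis=0)
    target_total = int(round(supports.sum(axis=1).mean()))
    d_edges = dist[iu, ju]
    edges = np.linspace(d_edges.min(), d_edges.max() + 1e-12, n_bins + 1)
    bin_idx = np.clip(np.digitize(d_edges, edges) - 1, 0, n_bins - 1)
    # pooled subject edge-length histogram sets the per-bin retention share
    pooled = np.zeros(n_bins)
    for s in range(supports.shape[0]):
        pooled += np.bincount(bin_idx[supports[s]], minlength=n_bins)
    pooled_frac = pooled / pooled.sum() if pooled.sum() > 0 else np.zeros(n_bins)
    keep = np.zeros(d_edges.size, dtype=bool)
    weight_edge = log_mean[iu, ju]
    for b in range(n_bins):
        members = np.where(bin_idx == b)[0]
        if members.size == 0:
            continue
        quota = int(round(target_total * pooled_frac[b]))
        quota = min(quota, int((consistency[members] > 0).sum()))
        if quota <= 0:
            continue
        order = np.lexsort((-weight_edge[members], -consistency[members]))
        keep[members[order[:quota]]] = True
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = log_mean[iu[keep], ju[keep]]
    out = out + out.T
    return SimilarityMatrix(values=out, row_ids=list(stack[0].row_ids), kind="SC")


def compute_mpc(
    profiles: np.ndarray,
    region_ids: list[str] | None = None,
    transform: str = "log1p",
    eps: float = 1e-6,
) -> SimilarityMatrix:
    """Microstructural profile covariance from depth-wise intensity profiles.

    ``profiles`` is regions × depth (>= 3 depth samples). Each pair of
    profiles is partially correlated controlling for the grand-mean profile
    (residualise on the mean, then Pearson). The log step is monotone:
    ``log1p`` (default) maps r to log(1 + clip(r, -1 + eps, 1 - eps)) after
    zeroing non-positive partials; ``fisherz`` applies arctanh instead.
    Rank-based downstream analyses are invariant to the choice.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] < 3:
        raise ValueError("need regions × depth profiles with >= 3 depth samples")
    if transform not in {"log1p", "fisherz"}:
        raise ValueError("transform must be 'log1p' or 'fisherz'")
    n = profiles.shape[0]
    if region_ids is None:
        region_ids = [f"region{i}" for i in range(n)]
    mean_profile = profiles.mean(axis=0)
    mc = mean_profile - mean_profile.mean()
    denom = (mc**2).sum()
    resid = profiles - profiles.mean(axis=1, keepdims=True)
    if denom > 0:
        coef = (resid @ mc) / denom
        resid = resid - np.outer(coef, mc)
    norms = np.sqrt((resid**2).sum(axis=1))
    bad = np.where(norms < 1e-12)[0]
    if bad.size:
        names = [region_ids[i] for i in bad[:5]]
        raise ValueError(
            f"degenerate profiles (constant after controlling the mean) for {names}"
        )
    r = np.clip((resid / norms[:, None]) @ (resid / norms[:, None]).T, -1 + eps, 1 - eps)
    if transform == "log1p":
        r = np.where(r > 0, r, 0.0)
        out = np.log1p(np.clip(r, 0, 1 - eps))
    else:
        out = np.arctanh(r)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return SimilarityMatrix(values=out, row_ids=list(region_ids), kind="MPC",
                            meta={"transform": transform, "eps": eps})


def row_coupling(
    receptome: SimilarityMatrix, other: SimilarityMatrix, min_entries: int = 3
) -> np.ndarray:
    """Per-region Spearman correlation between matching matrix rows.

    Row i of the receptome is correlated with row i of ``other`` over the
    column indices where both are nonzero (intersection of supports) and
    j != i. Rows with fewer than ``min_entries`` shared nonzero entries get
    NaN with a warning.
    """
    a = np.asarray(receptome.values, dtype=float)
    b = np.asarray(other.values, dtype=float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and share the region set")
    n = a.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        mask = (a[i] != 0) & (b[i] != 0)
        mask[i] = False
        if mask.sum() < min_entries:
            warnings.warn(
                f"region {receptome.row_ids[i]!r}: only {int(mask.sum())} shared "
                "nonzero entries; coupling undefined"
            )
            continue
        out[i] = spearmanr(a[i, mask], b[i, mask]).statistic
    return out


def _dunn_pairwise(groups: dict) -> dict:
    """Dunn's z for all class pairs with tie correction, Bonferroni-adjusted."""
    all_vals = np.concatenate(list(groups.values()))
    N = all_vals.size
    ranks = rankdata(all_vals)
    mean_rank = {}
    pos = 0
    for name, vals in groups.items():
        mean_rank[name] = ranks[pos : pos + vals.size].mean()
        pos += vals.size
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (N - 1))
    var_base = N * (N + 1) / 12 - tie_term
    pairs = list(combinations(groups.keys(), 2))
    out = {}
    for a, b in pairs:
        na, nb = groups[a].size, groups[b].size
        se = np.sqrt(var_base * (1 / na + 1 / nb))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2 * norm.sf(abs(z))
        out[(a, b)] = {"z": float(z), "p_adj": float(min(1.0, p * len(pairs)))}
    return out


def class_comparison(values: np.ndarray, atlas: ClassAtlas) -> ClassComparisonResult:
    """Kruskal-Wallis across classes with Dunn/Bonferroni post hoc tests.

    NaN values are dropped; classes left with fewer than 2 members are
    excluded with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = atlas.labels
    if values.shape[0] != labels.shape[0]:
        raise ValueError("values and class labels differ in length")
    groups = {}
    for cls in np.unique(labels):
        v = values[(labels == cls) & np.isfinite(values)]
        if v.size < 2:
            warnings.warn(f"class {cls!r} has fewer than 2 usable values; excluded")
            continue
        groups[cls] = v
    if len(groups) < 2:
        raise ValueError("need at least 2 classes with >= 2 members")
    h, p_global = kruskal(*groups.values())
    return ClassComparisonResult(
        h=float(h),
        p_global=float(p_global),
        pairwise=_dunn_pairwise(groups),
        class_means={k: float(v.mean()) for k, v in groups.items()},
    )
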