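"""Independent brute-force oracles used to validate the library paths.

Everything here is deliberately naive — double loops, exhaustive
enumeration, direct textbook formulas — and shares no code with the
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg


def naive_spearman(a, b) -> float:
    """Spearman rho via explicit average ranks and the Pearson formula."""

    def avg_ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="stable")
        ranks = np.empty_like(x)
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = avg_ranks(a), avg_ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, m):
        if i == n:
            yield labels.copy()
            return
        for lab in range(m + 1):
            labels[i] = lab
            yield from rec(i + 1, max(m, lab + 1))

    yield from rec(1, 1) if n > 1 else iter([np.zeros(1, dtype=int)])


def brute_signed_quality(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Q* by explicit edge sums over the positive and negative subnetworks."""
    n = W.shape[0]
    qp = qn = 0.0
    sp = np.zeros(n)
    sn = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            w = W[i, j]
            if w > 0:
                sp[i] += w
            else:
                sn[i] += -w
    vp, vn = sp.sum(), sn.sum()
    # weight diagonal is excluded; the null term runs over all same-community
    # (i, j) including i = j, as in the standard modularity sum
    for i in range(n):
        for j in range(n):
            if labels[i] != labels[j]:
                continue
            w = W[i, j] if i != j else 0.0
            if vp > 0:
                qp += ((w if w > 0 else 0.0) - gamma * sp[i] * sp[j] / vp) / vp
            if vn > 0:
                qn += ((-w if w < 0 else 0.0) - gamma * sn[i] * sn[j] / vn) / vn
    lam = vn / (vp + vn) if (vp + vn) > 0 else 0.0
    return qp - lam * qn


def masked_signed_quality(W: np.ndarray, labels: np.ndarray, gamma: float) -> float:
    """Q* via explicit positive/negative masks (fast enumeration oracle)."""
    n = W.shape[0]
    off = ~np.eye(n, dtype=bool)
    Wp = np.where((W > 0) & off, W, 0.0)
    Wn = np.where((W < 0) & off, -W, 0.0)
    sp, sn = Wp.sum(1), Wn.sum(1)
    vp, vn = sp.sum(), sn.sum()
    same = labels[:, None] == labels[None, :]
    qp = ((Wp - gamma * np.outer(sp, sp) / vp)[same].sum() / vp) if vp > 0 else 0.0
    qn = ((Wn - gamma * np.outer(sn, sn) / vn)[same].sum() / vn) if vn > 0 else 0.0
    lam = vn / (vp + vn) if (vp + vn) > 0 else 0.0
    return qp - lam * qn


def pair_count(p: np.ndarray, q: np.ndarray) -> int:
    """Number of node pairs co-assigned in both partitions (double loop)."""
    n = len(p)
    w = 0
    for i in range(n):
        for j in range(i + 1, n):
            if p[i] == p[j] and q[i] == q[j]:
                w += 1
    return w


def exhaustive_pair_null_mean(p: np.ndarray, q: np.ndarray) -> float:
    """Exact E[w] under relabelling: average over all permutations of q."""
    total = 0
    count = 0
    q = np.asarray(q)
    for perm in itertools.permutations(range(len(q))):
        total += pair_count(p, q[list(perm)])
        count += 1
    return total / count


def wpgma_by_hand(points: np.ndarray):
    """WPGMA recursion on 1-D points; returns merge heights in order."""
    clusters = {i: [i] for i in range(len(points))}
    dist = {
        (i, j): abs(float(points[i] - points[j]))
        for i in range(len(points))
        for j in range(i + 1, len(points))
    }
    heights = []
    next_id = len(points)
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for c in clusters:
            da = dist.get((min(a, c), max(a, c)))
            db = dist.get((min(b, c), max(b, c)))
            new_d[(c, next_id)] = (da + db) / 2
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        dist.update(new_d)
        clusters[next_id] = merged
        next_id += 1
    return heights


def diffusion_oracle(W: np.ndarray, alpha: float, n_components: int):
    """Diffusion-map components via the non-symmetric Markov operator.

    Independent route: anisotropic normalisation, explicit row-normalised
    operator P, dense non-symmetric eigendecomposition, then the same
    trivial-eigenvector normalisation and lambda/(1-lambda) scaling.
    """
    d = W.sum(axis=1)
    W1 = W / np.outer(d**alpha, d**alpha)
    d1 = W1.sum(axis=1)
    P = W1 / d1[:, None]
    vals, vecs = scipy.linalg.eig(P)
    vals = vals.real
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order].real
    # recover the symmetric-problem eigenvectors and normalise as u / u[:, 0]
    u = np.sqrt(d1)[:, None] * vecs
    u /= np.linalg.norm(u, axis=0, keepdims=True)
    psi = u / u[:, [0]]
    lam = np.clip(vals[1 : n_components + 1], 0, 1 - 1e-12)
    return psi[:, 1 : n_components + 1] * (lam / (1 - lam))[None, :], lam
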