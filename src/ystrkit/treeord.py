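"""Neighbor-joining trees and classical (Torgerson) MDS from population
distance matrices."""

from __future__ import annotations

import warnings

import numpy as np

from .distance import DistanceMatrix


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string.

    Negative branch lengths are clamped to zero with the excess shifted to
    the sibling branch (so the path length between the joined pair is
    preserved).  Infinite entries (e.g. Nei distance between populations
    sharing no alleles) are rejected.
    """
    D = np.array(dist.values, dtype=float)
    labels = [str(x) for x in dist.labels]
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if not np.isfinite(D).all():
        raise ValueError(
            "infinite distances; recompute with a pseudocount or drop taxa"
        )

    def fmt(x: float) -> str:
        return f"{x:.6g}"

    nodes = [lab for lab in labels]  # newick fragment per active node
    while n > 2:
        r = D.sum(axis=1)
        q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = D[i, j], 0.0
        if lj < 0:
            li, lj = D[i, j], 0.0
        new = f"({nodes[i]}:{fmt(li)},{nodes[j]}:{fmt(lj)})"
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], du[keep][None, :]])
        D = np.hstack([D, np.append(du[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        n -= 1
    d = max(D[0, 1], 0.0)
    return f"({nodes[0]}:{fmt(d / 2)},{nodes[1]}:{fmt(d / 2)});"


def classical_mds(
    dist: DistanceMatrix, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson double-centering MDS.

    Returns (coordinates, eigenvalues): coordinates are n x k', centered at
    the origin, where k' <= k is reduced (with a warning) if fewer positive
    eigenvalues exist.  Eigenvalues (all of them, descending) are returned
    so callers can judge distortion.  Sign convention: in each axis the
    largest-magnitude coordinate is made positive.
    """
    D = np.array(dist.values, dtype=float)
    n = D.shape[0]
    if n < k + 1:
        raise ValueError("need at least k+1 labels")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = int(np.sum(vals > 1e-10))
    k_eff = min(k, pos)
    if k_eff < k:
        warnings.warn(
            f"only {pos} positive eigenvalues; returning {k_eff} axes",
            stacklevel=2,
        )
    if k_eff == 0:
        return np.zeros((n, 0)), vals
    coords = vecs[:, :k_eff] * np.sqrt(vals[:k_eff])
    for a in range(k_eff):
        i = np.argmax(np.abs(coords[:, a]))
        if coords[i, a] < 0:
            coords[:, a] = -coords[:, a]
    return coords, vals
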