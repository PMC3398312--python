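"""Sequence-space landscape of compatibility scores.

Segment sequences are embedded in two dimensions by classical scaling
(Torgerson multidimensional scaling) of their pairwise Hamming distances —
the standard realisation of "PCA with a dissimilarity matrix", equal to PCA
of the implied one-hot encoding up to scale.  Compatibility scores S are
then interpolated over the PC1-PC2 plane into a regular grid, giving a
contour-ready evolutionary landscape: high regions are sequences compatible
with the structural motif, and family members can be watched drifting
toward or away from them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.linalg import eigh

from .profile_builder import _AA_INDEX


@dataclass
class LandscapeEmbedding:
    ids: list[str]
    families: list[str]
    coords: np.ndarray        # n x 2 (PC1, PC2), centered
    eigenvalues: np.ndarray   # descending
    S: np.ndarray | None = None

    def to_tsv(self) -> str:
        lines = ["id\tfamily\tPC1\tPC2\tS"]
        for k, (i, f) in enumerate(zip(self.ids, self.families)):
            s = f"{self.S[k]:.6f}" if self.S is not None else "nan"
            lines.append(f"{i}\t{f}\t{self.coords[k,0]:.6f}\t{self.coords[k,1]:.6f}\t{s}")
        return "\n".join(lines) + "\n"


@dataclass
class GridSurface:
    x: np.ndarray             # grid axis, length nx
    y: np.ndarray             # grid axis, length ny
    values: np.ndarray        # ny x nx interpolated S
    method: str

    def to_tsv(self) -> str:
        lines = ["x\ty\tS_interp"]
        for iy in range(len(self.y)):
            for ix in range(len(self.x)):
                lines.append(f"{self.x[ix]:.6f}\t{self.y[iy]:.6f}\t{self.values[iy, ix]:.6f}")
        return "\n".join(lines) + "\n"


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    """Pairwise count of differing positions.  Gap vs residue differs; gap
    vs gap is equal.  Requires >= 2 equal-length sequences."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("ragged lengths")
    arr = np.array([list(s) for s in seqs])
    m = len(seqs)
    D = np.zeros((m, m))
    for i in range(m):
        diff = (arr[i + 1 :] != arr[i]).sum(axis=1)
        D[i, i + 1 :] = diff
        D[i + 1 :, i] = diff
    return D


def pca_embed(D: np.ndarray, ids: list[str] | None = None,
              families: list[str] | None = None) -> LandscapeEmbedding:
    """Classical scaling of a dissimilarity matrix to 2 components.

    Gram = -1/2 * J D^2 J with J the centering matrix; the top-2 eigenpairs
    give coordinates v * sqrt(lambda).  Negative eigenvalues (non-Euclidean
    dissimilarities) are clipped to zero.  Sign convention: the first
    nonzero loading of each axis is positive.  An all-zero D maps every
    point to the origin.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("need a symmetric zero-diagonal dissimilarity matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D * D) @ J
    w, v = eigh(G)
    order = np.argsort(w)[::-1][:2]
    lams = np.clip(w[order], 0.0, None)
    coords = v[:, order] * np.sqrt(lams)[None, :]
    for k in range(2):
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    coords -= coords.mean(axis=0)
    return LandscapeEmbedding(
        ids=ids or [str(i) for i in range(n)],
        families=families or ["-"] * n,
        coords=coords,
        eigenvalues=lams,
    )


def _idw(points: np.ndarray, values: np.ndarray, targets: np.ndarray,
         power: float = 2.0) -> np.ndarray:
    d2 = ((targets[:, None, :] - points[None, :, :]) ** 2).sum(axis=2)
    out = np.empty(len(targets))
    exact = d2.min(axis=1) == 0.0
    out[exact] = values[np.argmin(d2[exact], axis=1)]
    rest = ~exact
    if rest.any():
        w = d2[rest] ** (-power / 2.0)
        out[rest] = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
    return out


def surface_interpolate(embedding: LandscapeEmbedding,
                        grid: int | tuple[int, int] = 100,
                        method: str = "linear") -> GridSurface:
    """Interpolate S over the PC1-PC2 bounding box.

    ``linear``: barycentric interpolation on the Delaunay triangulation,
    with inverse-distance-weighted (power 2) extrapolation outside the
    hull; needs >= 3 non-collinear points.  ``idw``: pure inverse-distance
    weighting, defined for >= 2 points.  Both are exact at data nodes.
    """
    if embedding.S is None:
        raise ValueError("embedding carries no S values")
    pts = embedding.coords
    vals = np.asarray(embedding.S, dtype=float)
    nx, ny = (grid, grid) if isinstance(grid, int) else grid
    if method == "linear" and len(pts) < 3:
        raise ValueError("linear interpolation needs >= 3 points")
    if len(pts) < 2:
        raise ValueError("need at least 2 points")

    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    x = np.linspace(mins[0] - 0.05 * span[0], maxs[0] + 0.05 * span[0], nx)
    y = np.linspace(mins[1] - 0.05 * span[1], maxs[1] + 0.05 * span[1], ny)
    gx, gy = np.meshgrid(x, y)
    targets = np.column_stack([gx.ravel(), gy.ravel()])

    if method == "idw":
        flat = _idw(pts, vals, targets)
    elif method == "linear":
        try:
            interp = LinearNDInterpolator(pts, vals)
            flat = interp(targets)
        except Exception:  # collinear points: Delaunay fails
            flat = np.full(len(targets), np.nan)
        nanmask = np.isnan(flat)
        if nanmask.any():
            flat[nanmask] = _idw(pts, vals, targets[nanmask])
    else:
        raise ValueError(f"unknown method {method!r}")
    return GridSurface(x=x, y=y, values=flat.reshape(ny, nx), method=method)


def virtual_mutants(seqs: list[str], n_mutants: int, seed: int) -> list[str]:
    """Seeded single/double mutants of the input sequences, used to densify
    the landscape with 'virtual' sequences."""
    from .profile_builder import ALPHABET

    rng = np.random.default_rng(seed)
    out: list[str] = []
    aa = list(ALPHABET)
    residue_pos = [
        [i for i, c in enumerate(s) if c in _AA_INDEX] for s in seqs
    ]
    candidates = [k for k, pos in enumerate(residue_pos) if pos]
    if not candidates:
        raise ValueError("no mutable sequences")
    for _ in range(n_mutants):
        k = int(rng.choice(candidates))
        s = list(seqs[k])
        n_mut = int(rng.integers(1, 3))
        for _m in range(n_mut):
            p = int(rng.choice(residue_pos[k]))
            s[p] = aa[int(rng.integers(0, 20))]
        out.append("".join(s))
    return out
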