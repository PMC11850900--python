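"""Real symmetric spherical-harmonic (SH) machinery for fODF fields.

Symmetric fiber orientation distribution functions (fODFs) are represented
in a real, even-order SH basis of the kind introduced for Q-ball imaging
(Descoteaux-style).  For a maximum order ``lmax`` the basis has
``(lmax + 1)(lmax + 2) / 2`` functions; the default ``lmax = 8`` gives 45
coefficients per voxel.  Dividing a coefficient vector by ``sqrt(4*pi) * A0``
turns the fODF into a proper probability density on the sphere (integral 1)
and makes the leading coefficient redundant, leaving 44 free numbers.

Basis convention
----------------
Let ``Y_l^m`` be the complex spherical harmonic with Condon–Shortley phase
(as in :func:`scipy.special.sph_harm_y`).  The real basis function for the
pair ``(l, m)``, with ``l`` even and ``m = -l..l``, is::

    m < 0 : sqrt(2) * Re(Y_l^|m|)
    m = 0 : Y_l^0                     (already real)
    m > 0 : sqrt(2) * Im(Y_l^m)

Basis functions are ordered by ``l`` ascending, then ``m`` ascending, so
index 0 is the constant ``Y_00 = 1 / sqrt(4*pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "SHBasisSpec",
    "SphereTessellation",
    "DesignMatrix",
    "n_coefficients",
    "sh_index_pairs",
    "build_basis",
    "real_sh_matrix",
    "fit_sh",
    "evaluate_sh",
    "normalize_fodf",
    "denormalize_fodf",
    "sphere_quadrature",
    "default_tessellation",
]

SQRT_4PI = float(np.sqrt(4.0 * np.pi))
Y00 = 1.0 / SQRT_4PI


def n_coefficients(lmax: int) -> int:
    """Number of real even-order SH basis functions up to ``lmax``."""
    if lmax < 0 or lmax % 2:
        raise ValueError(f"lmax must be even and >= 0, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def sh_index_pairs(lmax: int) -> np.ndarray:
    """(n, 2) array of (l, m) pairs, l ascending even, m ascending."""
    pairs = [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]
    return np.asarray(pairs, dtype=int)


@dataclass(frozen=True)
class SHBasisSpec:
    """Specification of the real symmetric SH basis.

    Parameters
    ----------
    lmax : int
        Maximum (even) harmonic order.  The default of 8 yields 45
        coefficients per voxel.
    """

    lmax: int = 8
    convention: str = "descoteaux"

    def __post_init__(self) -> None:
        if self.lmax < 2 or self.lmax % 2:
            raise ValueError(f"lmax must be even and >= 2, got {self.lmax}")

    @property
    def n_coef(self) -> int:
        return n_coefficients(self.lmax)

    @property
    def index_pairs(self) -> np.ndarray:
        return sh_index_pairs(self.lmax)


@dataclass
class SphereTessellation:
    """Unit directions on the sphere with neighbor structure.

    ``hemisphere`` marks an antipodally-unique set (one representative per
    orientation); ``adjacency`` lists neighbor indices per vertex and is
    used for local-maximum (peak) detection.
    """

    directions: np.ndarray
    hemisphere: bool = False
    adjacency: list[np.ndarray] | None = None
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.directions = np.ascontiguousarray(self.directions, dtype=float)
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("tessellation directions must be unit vectors")

    def __len__(self) -> int:
        return len(self.directions)

    @property
    def neighbor_matrix(self) -> np.ndarray:
        """Adjacency as a padded index array (pad = own index)."""
        if self.adjacency is None:
            raise ValueError("tessellation carries no adjacency")
        width = max(len(a) for a in self.adjacency)
        out = np.empty((len(self), width), dtype=np.intp)
        for i, nb in enumerate(self.adjacency):
            out[i, : len(nb)] = nb
            out[i, len(nb):] = i
        return out


@dataclass
class DesignMatrix:
    """Basis functions evaluated on a tessellation: shape (n_dirs, n_coef)."""

    matrix: np.ndarray
    basis: SHBasisSpec
    tessellation: SphereTessellation

    @property
    def n_coef(self) -> int:
        return self.matrix.shape[1]


def _dirs_to_angles(dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dirs = np.atleast_2d(dirs)
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])  # azimuth
    return theta, phi


def real_sh_matrix(lmax: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the real symmetric basis at unit directions.

    Returns an array of shape ``(len(dirs), n_coefficients(lmax))``.
    """
    theta, phi = _dirs_to_angles(dirs)
    pairs = sh_index_pairs(lmax)
    out = np.empty((len(theta), len(pairs)))
    for k, (l, m) in enumerate(pairs):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m < 0:
            out[:, k] = np.sqrt(2.0) * y.real
        elif m == 0:
            out[:, k] = y.real
        else:
            out[:, k] = np.sqrt(2.0) * y.imag
    return out


def build_basis(tess: SphereTessellation, spec: SHBasisSpec | None = None) -> DesignMatrix:
    """Design matrix of the real SH basis on a tessellation."""
    spec = spec or SHBasisSpec()
    if len(tess) == 0:
        raise ValueError("empty tessellation")
    return DesignMatrix(real_sh_matrix(spec.lmax, tess.directions), spec, tess)


def evaluate_sh(coeffs: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Evaluate SH coefficient vectors on the design's tessellation.

    ``coeffs`` may be a single vector or an ``(..., n_coef)`` stack of full
    (un-normalized) coefficient vectors.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape[-1] != design.n_coef:
        raise ValueError(
            f"coefficient length {coeffs.shape[-1]} does not match "
            f"basis size {design.n_coef}"
        )
    return coeffs @ design.matrix.T


def fit_sh(samples: np.ndarray, design: DesignMatrix) -> np.ndarray:
    """Least-squares projection of per-direction samples onto the basis.

    ``samples`` has shape ``(..., n_dirs)``; returns full coefficient
    vectors of shape ``(..., n_coef)``.  Band-limited functions round-trip
    exactly (up to numerical precision).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.shape[-1] != design.matrix.shape[0]:
        raise ValueError("sample count does not match tessellation size")
    if design.matrix.shape[0] < design.matrix.shape[1]:
        raise ValueError("underdetermined fit: fewer directions than basis functions")
    sol, *_ = np.linalg.lstsq(design.matrix, samples.reshape(-1, samples.shape[-1]).T)
    return np.moveaxis(sol, 0, -1).reshape(*samples.shape[:-1], design.n_coef)


def normalize_fodf(coeffs: np.ndarray, eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Normalize full fODF coefficients to unit spherical integral.

    Divides all coefficients by ``sqrt(4*pi) * A0`` and drops the leading
    entry, whose value becomes ``1/sqrt(4*pi)`` by construction.  Voxels
    with ``|A0| <= eps`` (background / degenerate) yield all-zero rows and
    are marked invalid in the returned mask.

    Returns
    -------
    normalized : (..., n_coef - 1) array
    valid : (...) boolean array
    """
    coeffs = np.asarray(coeffs, dtype=float)
    a0 = coeffs[..., 0]
    valid = np.abs(a0) > eps
    denom = np.where(valid, SQRT_4PI * a0, 1.0)
    out = coeffs[..., 1:] / denom[..., None]
    out[~valid] = 0.0
    return out, valid


def denormalize_fodf(coeffs: np.ndarray) -> np.ndarray:
    """Prepend the implied ``A0 = 1/sqrt(4*pi)`` to normalized coefficients."""
    coeffs = np.asarray(coeffs, dtype=float)
    full = np.empty(coeffs.shape[:-1] + (coeffs.shape[-1] + 1,))
    full[..., 0] = Y00
    full[..., 1:] = coeffs
    return full


def sphere_quadrature(n_polar: int = 24, n_azimuth: int = 49) -> SphereTessellation:
    """Gauss–Legendre x uniform-azimuth quadrature grid on the sphere.

    Exact (to machine precision) for band-limited functions of order up to
    ``2 * n_polar - 1`` in the polar direction and ``n_azimuth - 1`` in
    azimuth; the defaults comfortably cover products of two order-8
    expansions.  The tessellation's ``weights`` sum to ``4*pi``.
    """
    t, wt = np.polynomial.legendre.leggauss(n_polar)
    phi = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    ct = t[:, None] * np.ones_like(phi)[None, :]
    st = np.sqrt(1.0 - t**2)[:, None]
    dirs = np.stack(
        [st * np.cos(phi)[None, :], st * np.sin(phi)[None, :], ct], axis=-1
    ).reshape(-1, 3)
    w = (wt[:, None] * np.full((1, n_azimuth), 2.0 * np.pi / n_azimuth)).ravel()
    return SphereTessellation(dirs, hemisphere=False, weights=w)


def _icosphere_vertices(subdivisions: int):
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=subdivisions)
    verts = np.asarray(mesh.vertices, dtype=float)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    edges = np.asarray(mesh.edges_unique)
    return verts, edges


def default_tessellation(subdivisions: int = 4, hemisphere: bool = True) -> SphereTessellation:
    """Subdivided-icosahedron tessellation with adjacency for peak finding.

    ``subdivisions=4`` gives 2562 sphere vertices (1281 hemisphere
    orientations), dense enough to localize order-8 fODF peaks; 3 gives a
    coarser grid (321 orientations) suitable as a nonnegativity-constraint
    set.
    """
    verts, edges = _icosphere_vertices(subdivisions)
    if not hemisphere:
        adj = [[] for _ in range(len(verts))]
        for a, b in edges:
            adj[a].append(b)
            adj[b].append(a)
        return SphereTessellation(
            verts, hemisphere=False, adjacency=[np.array(sorted(x)) for x in adj]
        )

    tol = 1e-9
    z, y, x = verts[:, 2], verts[:, 1], verts[:, 0]
    keep = (z > tol) | ((np.abs(z) <= tol) & (y > tol)) | (
        (np.abs(z) <= tol) & (np.abs(y) <= tol) & (x > 0)
    )
    reps = verts[keep]

    # map every sphere vertex (and its antipode) to its hemisphere representative
    from scipy.spatial import cKDTree

    tree = cKDTree(reps)
    d_pos, i_pos = tree.query(verts)
    d_neg, i_neg = tree.query(-verts)
    rep_of = np.where(d_pos <= d_neg, i_pos, i_neg)
    adj = [set() for _ in range(len(reps))]
    for a, b in edges:
        ra, rb = rep_of[a], rep_of[b]
        if ra != rb:
            adj[ra].add(rb)
            adj[rb].add(ra)
    return SphereTessellation(
        reps, hemisphere=True, adjacency=[np.array(sorted(s)) for s in adj]
    )
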