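"""Single-shell constrained spherical deconvolution (CSD).

Estimates the per-voxel fiber orientation distribution function (fODF) as
an order-8 real SH vector by deconvolving the shell signal with an axially
symmetric single-fiber response, under an iteratively reweighted
soft nonnegativity constraint: directions on a constraint tessellation
whose current fODF amplitude falls below a threshold are penalized
quadratically, and the active set is re-derived until it stabilizes.

Per voxel the update solves

    min_a ||F a - s||^2 + lam^2 ||B_w a||^2

where ``F`` maps fODF SH coefficients to predicted shell attenuations
through the spherical convolution theorem (per-degree factors
``sqrt(4 pi / (2l+1)) r_l``), ``B_w`` stacks the constraint-tessellation
basis rows currently below threshold, and the threshold is
``tau * mean(initial fODF amplitude)``.

:func:`nnls_deconvolve` provides an algorithmically independent route —
nonnegative least squares on a dense grid of candidate fiber amplitudes,
projected to SH — used to cross-validate the iterative solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.special import eval_legendre

from .phantom import DWIVolume, GradientScheme, ResponseFunction
from .sh import (
    SHBasisSpec,
    SphereTessellation,
    default_tessellation,
    real_sh_matrix,
    sh_index_pairs,
)

__all__ = [
    "CSDConfig",
    "ForwardConvolutionMatrix",
    "response_to_rl",
    "forward_matrix",
    "fit_csd",
    "fit_csd_voxel",
    "nnls_deconvolve",
    "estimate_response",
]


@dataclass
class CSDConfig:
    """Hyperparameters of the constrained deconvolution.

    ``lambda_reg`` (constraint weight), ``tau`` (amplitude threshold as a
    fraction of the mean initial fODF amplitude) and ``max_iter`` default
    to the standard published settings; the constraint tessellation is a
    ~300-orientation hemisphere grid.
    """

    lmax: int = 8
    lambda_reg: float = 1.0
    tau: float = 0.1
    max_iter: int = 50
    init_lmax: int = 4
    constraint_tess: SphereTessellation | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.lambda_reg < 0:
            raise ValueError("lambda_reg must be nonnegative")
        if not 0 < self.tau < 1:
            raise ValueError("tau must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def tessellation(self) -> SphereTessellation:
        if self.constraint_tess is None:
            self.constraint_tess = default_tessellation(3, hemisphere=True)
        return self.constraint_tess


def response_to_rl(
    resp: ResponseFunction, scheme: GradientScheme, lmax: int = 8, n_quad: int = 64
) -> np.ndarray:
    """Per-degree SH factors r_l of the single-fiber response on the shell.

    ``r_l`` is the m=0 coefficient of the axially symmetric response
    signal, computed by Gauss–Legendre quadrature:
    ``r_l = 2 pi * int R(t) Y_l0(t) dt`` with ``t = cos(theta)``.  With
    this scaling, convolving a unit delta fODF reproduces the response
    signal itself.
    """
    b = scheme.require_single_shell()
    t, w = np.polynomial.legendre.leggauss(n_quad)
    sig = resp.signal(b, t)
    ls = np.arange(0, lmax + 1, 2)
    y_l0 = np.sqrt((2 * ls[:, None] + 1) / (4 * np.pi)) * eval_legendre(ls[:, None], t)
    return 2.0 * np.pi * (y_l0 * sig * w).sum(axis=1)


@dataclass
class ForwardConvolutionMatrix:
    """fODF SH coefficients -> predicted shell attenuation at the gradients."""

    matrix: np.ndarray
    r_l: np.ndarray
    lmax: int

    @classmethod
    def build(
        cls, scheme: GradientScheme, resp: ResponseFunction, lmax: int = 8
    ) -> "ForwardConvolutionMatrix":
        r_l = response_to_rl(resp, scheme, lmax)
        g = scheme.bvecs[scheme.dw_mask]
        basis = real_sh_matrix(lmax, g)
        ls = sh_index_pairs(lmax)[:, 0]
        kernel = np.sqrt(4 * np.pi / (2 * ls + 1)) * r_l[ls // 2]
        return cls(basis * kernel[None, :], r_l, lmax)


def forward_matrix(
    scheme: GradientScheme, resp: ResponseFunction, lmax: int = 8
) -> ForwardConvolutionMatrix:
    return ForwardConvolutionMatrix.build(scheme, resp, lmax)


class _CSDSolver:
    """Precomputed matrices for repeated per-voxel solves."""

    def __init__(self, scheme: GradientScheme, resp: ResponseFunction, cfg: CSDConfig):
        self.cfg = cfg
        fwd = ForwardConvolutionMatrix.build(scheme, resp, cfg.lmax)
        self.F = fwd.matrix
        self.r_l = fwd.r_l
        tess = cfg.tessellation()
        self.B = real_sh_matrix(cfg.lmax, tess.directions)
        # constraint weight scaled to the data term, following common practice
        lam = cfg.lambda_reg * self.F.shape[0] * abs(self.r_l[0]) / self.B.shape[0]
        self.Blam = lam * self.B
        self.FtF = self.F.T @ self.F
        ls = sh_index_pairs(cfg.lmax)[:, 0]
        self.init_cols = np.flatnonzero(ls <= cfg.init_lmax)
        self.F_init_pinv = np.linalg.pinv(self.F[:, self.init_cols])

    def solve(self, s: np.ndarray) -> tuple[np.ndarray, bool]:
        """CSD fit of one attenuation vector; returns (coeffs, converged)."""
        cfg = self.cfg
        n = self.F.shape[1]
        a = np.zeros(n)
        a[self.init_cols] = self.F_init_pinv @ s
        fodf = self.B @ a
        threshold = cfg.tau * fodf.mean()
        Fts = self.F.T @ s
        prev = None
        converged = False
        for _ in range(cfg.max_iter):
            active = fodf < threshold
            if prev is not None and np.array_equal(active, prev):
                converged = True
                break
            if active.sum() + self.F.shape[0] < n:
                # not enough constraints to regularize: accept current fit
                break
            Bw = self.Blam[active]
            M = self.FtF + Bw.T @ Bw
            a = np.linalg.solve(M, Fts)
            fodf = self.B @ a
            prev = active
        return a, converged


def fit_csd_voxel(
    signal: np.ndarray,
    scheme: GradientScheme,
    resp: ResponseFunction,
    cfg: CSDConfig | None = None,
) -> np.ndarray:
    """Fit a single voxel's measured signal (including b0 volumes)."""
    cfg = cfg or CSDConfig()
    solver = _CSDSolver(scheme, resp, cfg)
    b0 = signal[scheme.b0_mask].mean()
    if b0 <= 0:
        raise ValueError("voxel has nonpositive b0 signal")
    a, _ = solver.solve(signal[scheme.dw_mask] / b0)
    return a


def fit_csd(
    dwi: DWIVolume,
    resp: ResponseFunction | None = None,
    cfg: CSDConfig | None = None,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise CSD over a 4D volume.

    The signal is normalized to attenuation by the per-voxel mean of the
    b=0 volumes before deconvolution.  Returns the full 45-coefficient SH
    volume (zeros outside the mask) and a validity mask; voxels with
    nonpositive b0 are marked invalid.
    """
    resp = resp or ResponseFunction()
    cfg = cfg or CSDConfig()
    scheme = dwi.scheme
    if not scheme.b0_mask.any():
        raise ValueError("scheme contains no b=0 volume")
    solver = _CSDSolver(scheme, resp, cfg)

    shape = dwi.signal.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    b0 = dwi.signal[..., scheme.b0_mask].mean(-1)
    valid = mask & (b0 > 0)

    n = solver.F.shape[1]
    out = np.zeros(shape + (n,))
    dw = dwi.signal[..., scheme.dw_mask]
    idx = np.argwhere(valid)
    for i, j, k in idx:
        out[i, j, k] = solver.solve(dw[i, j, k] / b0[i, j, k])[0]
    return out, valid


def nnls_deconvolve(
    signal: np.ndarray,
    scheme: GradientScheme,
    resp: ResponseFunction,
    lmax: int = 8,
    grid: SphereTessellation | None = None,
) -> np.ndarray:
    """Direct nonnegative deconvolution of one voxel (cross-check route).

    Models the fODF as nonnegative amplitudes on a dense orientation grid,
    solves ``min_w ||K w - s||, w >= 0`` where column ``K[:, d]`` is the
    single-fiber signal of a unit-mass fiber along grid direction ``d``,
    and projects the amplitude field to SH.  Shares no code path with the
    iterative solver above.
    """
    grid = grid or default_tessellation(3, hemisphere=True)
    b = scheme.require_single_shell()
    g = scheme.bvecs[scheme.dw_mask]
    b0 = signal[scheme.b0_mask].mean()
    s = signal[scheme.dw_mask] / b0
    K = resp.signal(b, g @ grid.directions.T)  # (n_grad, n_dirs)
    w, _ = nnls(K, s)
    # delta at direction u has SH coefficients Y_lm(u); sum them with weights
    return real_sh_matrix(lmax, grid.directions).T @ w


def _ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least-distance program min ||x|| s.t. G x >= h (Lawson–Hanson)."""
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f)
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise RuntimeError("LDP constraints infeasible")
    return -r[:-1] / r[-1]


def qp_deconvolve(
    signal: np.ndarray,
    scheme: GradientScheme,
    resp: ResponseFunction,
    cfg: CSDConfig | None = None,
) -> np.ndarray:
    """Hard-constrained deconvolution of one voxel (cross-check route).

    Solves ``min_a ||F a - s||^2  s.t.  B a >= 0`` exactly, via the
    classical reduction least-squares-with-inequalities -> least-distance
    program -> NNLS.  The iterative soft-penalty solver of
    :func:`fit_csd_voxel` converges to this optimum as its constraint
    weight grows, which makes this an algorithmically independent oracle
    for it.
    """
    cfg = cfg or CSDConfig()
    F = ForwardConvolutionMatrix.build(scheme, resp, cfg.lmax).matrix
    B = real_sh_matrix(cfg.lmax, cfg.tessellation().directions)
    b0 = signal[scheme.b0_mask].mean()
    s = signal[scheme.dw_mask] / b0
    Q, R = np.linalg.qr(F)
    Qts = Q.T @ s
    Rinv = np.linalg.inv(R)
    G = B @ Rinv
    y = _ldp(G, -G @ Qts)
    return Rinv @ (y + Qts)


def estimate_response(
    dwi: DWIVolume, mask: np.ndarray, reg: float = 0.0
) -> ResponseFunction:
    """Single-fiber response from user-selected highly anisotropic voxels.

    Log-linear tensor fit per masked voxel; the response eigenvalues are
    the means of the largest eigenvalue and of the two smaller ones.
    """
    scheme = dwi.scheme
    g = scheme.bvecs[scheme.dw_mask]
    bv = dwi.scheme.bvals[scheme.dw_mask]
    # design for ln S = -b g D g^T, D symmetric
    G = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    ) * bv[:, None]
    b0 = dwi.signal[..., scheme.b0_mask].mean(-1)
    lpar, lperp = [], []
    for i, j, k in np.argwhere(mask & (b0 > 0)):
        s = dwi.signal[i, j, k, scheme.dw_mask] / b0[i, j, k]
        y = -np.log(np.clip(s, 1e-10, None))
        d, *_ = np.linalg.lstsq(G, y)
        D = np.array(
            [[d[0], d[3], d[4]], [d[3], d[1], d[5]], [d[4], d[5], d[2]]]
        )
        ev = np.sort(np.linalg.eigvalsh(D))
        lpar.append(ev[2])
        lperp.append((ev[0] + ev[1]) / 2)
    if not lpar:
        raise ValueError("response mask selects no usable voxel")
    return ResponseFunction(float(np.mean(lpar)), float(max(np.mean(lperp), 1e-6)))
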