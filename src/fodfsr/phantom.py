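"""Synthetic single-shell diffusion-MRI phantoms.

Generates voxel-wise fiber configurations (orientations + volume
fractions), simulates the diffusion-weighted signal with a prolate-tensor
single-fiber response, injects Rician noise at a prescribed SNR, and
produces low-resolution companions by non-overlapping 2x2x2 block
averaging of the signal — the acquisition model under which one
low-resolution voxel integrates eight high-resolution ones.

SNR is defined as ``1 / sigma_g`` where ``sigma_g`` is the standard
deviation of the Gaussian noise underlying the magnitude signal, with the
noiseless b0 signal equal to 1.  A directly-acquired low-resolution scan
enjoys an 8-fold SNR gain from the larger voxel volume plus a sqrt(2)
repetition gain: ``SNR_lr = 8 * sqrt(2) * SNR_hr``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "GradientScheme",
    "FiberConfig",
    "ResponseFunction",
    "NoiseSpec",
    "DWIVolume",
    "make_scheme",
    "make_phantom",
    "simulate_signal",
    "add_noise",
    "block_downsample",
    "lowres_snr",
]

MAX_FIBERS = 5

#: default phantom tissue labels
LABEL_BACKGROUND = 0
LABEL_WM_SINGLE = 1
LABEL_WM_CROSSING = 2
LABEL_ISOTROPIC = 3


@dataclass(frozen=True)
class GradientScheme:
    """Single- or multi-volume gradient table (FSL bval/bvec semantics)."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (len(bvals), 3):
            raise ValueError("bvals must be (n,), bvecs (n, 3)")
        dw = bvals > 0
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dw_mask(self) -> np.ndarray:
        return self.bvals > 0

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.bvals[self.dw_mask])

    def require_single_shell(self) -> float:
        shells = self.shells
        if len(shells) != 1:
            raise ValueError(f"single-shell scheme required, got shells {shells}")
        return float(shells[0])


@dataclass
class FiberConfig:
    """Per-voxel discrete fiber configurations on a 3D grid.

    ``orientations`` has shape (X, Y, Z, 5, 3) and ``fractions``
    (X, Y, Z, 5); absent fiber slots are zero-padded.  A voxel whose
    fractions are all zero is an isotropic (or background) voxel.
    """

    orientations: np.ndarray
    fractions: np.ndarray
    voxel_size: float = 1.25
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.orientations.shape[-2:] != (MAX_FIBERS, 3):
            raise ValueError("orientations must have shape (..., 5, 3)")
        if self.fractions.shape != self.orientations.shape[:-1]:
            raise ValueError("fractions shape inconsistent with orientations")
        tot = self.fractions.sum(-1)
        fibered = tot > 0
        if fibered.any() and not np.allclose(tot[fibered], 1.0, atol=1e-8):
            raise ValueError("per-voxel fiber fractions must sum to 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[:3]

    @property
    def n_fibers(self) -> np.ndarray:
        return (self.fractions > 0).sum(-1)


@dataclass(frozen=True)
class ResponseFunction:
    """Axially symmetric single-fiber response.

    Prolate tensor with axial/radial diffusivities in mm^2/s; defaults are
    typical coherent white-matter values.
    """

    lambda_par: float = 1.7e-3
    lambda_perp: float = 0.2e-3

    def __post_init__(self) -> None:
        if not (self.lambda_par >= self.lambda_perp > 0):
            raise ValueError("need lambda_par >= lambda_perp > 0")

    def signal(self, b: float, cos_theta: np.ndarray) -> np.ndarray:
        """Attenuation for gradient at angle theta from the fiber axis."""
        ct2 = np.square(cos_theta)
        return np.exp(-b * (self.lambda_perp + (self.lambda_par - self.lambda_perp) * ct2))


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise at ``SNR = 1 / sigma_g`` relative to the unit b0."""

    snr: float
    model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")

    @property
    def sigma(self) -> float:
        return 1.0 / self.snr


@dataclass
class DWIVolume:
    """4D diffusion-weighted signal with its gradient scheme."""

    signal: np.ndarray
    scheme: GradientScheme
    voxel_size: float

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[-1] != len(self.scheme.bvals):
            raise ValueError("volume count does not match gradient scheme")


def make_scheme(
    n_dirs: int = 60,
    bval: float = 3000.0,
    n_b0: int = 1,
    seed: int = 42,
    n_iter: int = 200,
) -> GradientScheme:
    """Near-uniform single-shell scheme via electrostatic repulsion.

    Starts from seeded random directions and relaxes pairwise antipodal
    Coulomb repulsion by projected gradient descent, giving a deterministic
    well-spread set of ``n_dirs`` diffusion directions preceded by ``n_b0``
    b=0 volumes.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        # antipodally symmetric repulsion: force from both u_j and -u_j
        diff_p = v[:, None, :] - v[None, :, :]
        diff_m = v[:, None, :] + v[None, :, :]
        dp = np.linalg.norm(diff_p, axis=-1)
        dm = np.linalg.norm(diff_m, axis=-1)
        np.fill_diagonal(dp, np.inf)
        np.fill_diagonal(dm, np.inf)
        force = (diff_p / dp[..., None] ** 3).sum(1) + (diff_m / dm[..., None] ** 3).sum(1)
        # project onto tangent plane and take a small step
        force -= (force * v).sum(-1, keepdims=True) * v
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        v += step * force / np.maximum(norm.max(), 1e-12)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), v])
    return GradientScheme(bvals, bvecs)


def _rotate_about(u: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    c, s = np.cos(angle), np.sin(angle)
    return c * u + s * np.cross(axis, u) + (1 - c) * (axis @ u) * axis


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 24),
    layout: str = "default",
    seed: int = 0,
    voxel_size: float = 1.25,
    bend_deg: float = 30.0,
    jitter_deg: float = 8.0,
) -> FiberConfig:
    """Seeded three-region phantom: single-fiber slab, 90-degree crossing, isotropic.

    The volume is split into three slabs along z.  The single-fiber region
    holds one orientation per voxel that rotates smoothly with x by up to
    ``bend_deg`` degrees (so sub-voxel structure exists for an upsampler to
    learn); the crossing region holds two equal-fraction orientations 90
    degrees apart; the last region is isotropic (no fibers).  Slab
    boundaries are placed at odd high-resolution indices so that 2x2x2
    blocks straddle them.

    Phantoms model subjects drawn from a shared anatomy: the fiber frame is
    a canonical one rotated by a small seeded random rotation (up to
    ``jitter_deg`` degrees), so different seeds give distinct but mutually
    consistent phantoms — as with real subjects, a model trained on some of
    them faces familiar statistics on the others.  Fully deterministic
    given (shape, layout, seed).
    """
    if layout != "default":
        raise ValueError(f"unknown layout {layout!r}")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 or s % 2 for s in shape):
        raise ValueError("shape must be three positive even integers")
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)

    # canonical frame plus small seeded per-subject rotation
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(jitter_deg) * rng.uniform(0.0, 1.0)
    base = np.eye(3)
    u1 = _rotate_about(base[0], axis, angle)
    u2 = _rotate_about(base[1], axis, angle)
    u3 = _rotate_about(base[2], axis, angle)

    orientations = np.zeros(shape + (MAX_FIBERS, 3))
    fractions = np.zeros(shape + (MAX_FIBERS,))
    labels = np.zeros(shape, dtype=np.int16)

    # slab boundaries at odd HR indices -> LR voxels straddle them
    z1 = max(1, (nz // 3) | 1)
    z2 = max(z1 + 2, (2 * nz // 3) | 1)
    bend = np.deg2rad(bend_deg)
    xs = np.linspace(-0.5, 0.5, nx)

    for ix in range(nx):
        a = bend * xs[ix]
        f1 = _rotate_about(u1, u3, a)
        c1 = _rotate_about(u2, u1, a)
        c2 = _rotate_about(u3, u1, a)
        orientations[ix, :, :z1, 0] = f1
        fractions[ix, :, :z1, 0] = 1.0
        labels[ix, :, :z1] = LABEL_WM_SINGLE
        orientations[ix, :, z1:z2, 0] = c1
        orientations[ix, :, z1:z2, 1] = c2
        fractions[ix, :, z1:z2, 0] = 0.5
        fractions[ix, :, z1:z2, 1] = 0.5
        labels[ix, :, z1:z2] = LABEL_WM_CROSSING
    labels[:, :, z2:] = LABEL_ISOTROPIC
    return FiberConfig(orientations, fractions, voxel_size=voxel_size, labels=labels)


def simulate_signal(
    cfg: FiberConfig,
    resp: ResponseFunction | None = None,
    scheme: GradientScheme | None = None,
    d_iso: float = 3.0e-3,
) -> DWIVolume:
    """Noiseless single-shell signal from a fiber configuration.

    Fibered voxels follow the multi-tensor model
    ``S(g) = sum_k f_k exp(-b (l_perp + (l_par - l_perp) (g.u_k)^2))``;
    voxels without fibers decay isotropically with free-water diffusivity
    ``d_iso``.  b=0 volumes are exactly 1 everywhere.
    """
    resp = resp or ResponseFunction()
    scheme = scheme or make_scheme()
    b = scheme.require_single_shell()
    dw = scheme.dw_mask
    g = scheme.bvecs[dw]

    frac = cfg.fractions
    # (X,Y,Z,5,ndir) dot products
    dots = np.einsum("...kc,dc->...kd", cfg.orientations, g)
    atten = resp.signal(b, dots)
    sig_dw = np.einsum("...k,...kd->...d", frac, atten)
    iso = frac.sum(-1) == 0
    sig_dw[iso] = np.exp(-b * d_iso)

    signal = np.ones(cfg.shape + (len(scheme.bvals),))
    signal[..., dw] = sig_dw
    return DWIVolume(signal, scheme, cfg.voxel_size)


def add_noise(dwi: DWIVolume, noise: NoiseSpec) -> DWIVolume:
    """One seeded noise realization on top of the given signal.

    Rician: magnitude of the signal after adding independent Gaussian noise
    of std ``sigma = 1/snr`` to real and imaginary channels.  The
    ``gaussian`` model (real channel only) exists for oracle tests.
    """
    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma
    s = dwi.signal
    if noise.model == "gaussian":
        out = s + sigma * rng.standard_normal(s.shape)
    else:
        e1 = rng.standard_normal(s.shape)
        e2 = rng.standard_normal(s.shape)
        out = np.hypot(s + sigma * e1, sigma * e2)
    return replace(dwi, signal=out)


def block_downsample(dwi: DWIVolume, factor: int = 2) -> DWIVolume:
    """Average the signal over non-overlapping ``factor``^3 voxel blocks."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x, y, z, n = dwi.signal.shape
    if any(dim % factor for dim in (x, y, z)):
        raise ValueError(f"spatial dims {x, y, z} not divisible by {factor}")
    s = dwi.signal.reshape(x // factor, factor, y // factor, factor, z // factor, factor, n)
    return DWIVolume(s.mean(axis=(1, 3, 5)), dwi.scheme, dwi.voxel_size * factor)


def lowres_snr(snr_hr: float) -> float:
    """SNR of a direct low-resolution acquisition: ``8 * sqrt(2) * SNR_hr``."""
    if snr_hr <= 0:
        raise ValueError("snr_hr must be positive")
    return 8.0 * np.sqrt(2.0) * snr_hr
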