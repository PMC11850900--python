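"""Evaluation stack: fODF peaks, angular EMD, SH similarity, anisotropy.

Peaks are local maxima of the fODF on a dense hemisphere tessellation,
kept when their amplitude reaches a relative threshold (default 0.5 of the
voxel maximum), separated by at least a minimum angle (default 25 degrees,
greedy suppression), and truncated to at most 5.

The angular earth mover's distance (EMD) between two weighted peak sets
normalizes each set's amplitudes to unit mass and solves the minimum-cost
transportation problem under the orientation ground cost
``c(u, v) = arccos(|u . v|)`` in degrees (antipodally symmetric, so costs
lie in [0, 90]).  The value reads as the total angular work needed to
morph one orientation distribution into the other.

Generalized anisotropy maps the analytic variance of the fODF over the
sphere, ``V_Y = (1/4 pi) * sum_{l>=2} A_lm^2`` for a unit-integral fODF,
through ``GA = tanh(V_Y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .sh import DesignMatrix, SphereTessellation, evaluate_sh

__all__ = [
    "PeakSet",
    "extract_peaks",
    "peaks_from_sh",
    "peak_volume",
    "angular_emd",
    "emd_error_map",
    "best_method_fraction",
    "sh_similarity",
    "generalized_anisotropy",
    "average_peak_count",
]

EMPTY_SET_EMD = 90.0  # one distribution empty: all mass at maximal cost


@dataclass
class PeakSet:
    """Weighted antipodally-unique peak orientations of one voxel."""

    directions: np.ndarray
    amplitudes: np.ndarray
    voxel: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if len(self.directions) != len(self.amplitudes):
            raise ValueError("directions and amplitudes disagree in length")
        if np.any(self.amplitudes <= 0):
            raise ValueError("peak amplitudes must be positive")
        if np.any(np.diff(self.amplitudes) > 1e-12):
            raise ValueError("amplitudes must be sorted descending")

    def __len__(self) -> int:
        return len(self.amplitudes)

    @property
    def masses(self) -> np.ndarray:
        return self.amplitudes / self.amplitudes.sum()


def _angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Orientation angle arccos(|u.v|) in degrees, broadcasting over rows."""
    dots = np.abs(u @ v.T)
    return np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))


def extract_peaks(
    amplitudes: np.ndarray,
    tess: SphereTessellation,
    rel_thresh: float = 0.5,
    min_sep: float = 25.0,
    max_peaks: int = 5,
    voxel=None,
) -> PeakSet:
    """Peak set of an fODF sampled on a hemisphere tessellation.

    Local maxima over the tessellation adjacency are ordered by descending
    amplitude (ties broken lexicographically on direction components),
    thresholded at ``rel_thresh`` times the global maximum, greedily
    suppressed within ``min_sep`` degrees of an accepted stronger peak and
    truncated to ``max_peaks``.
    """
    if tess.adjacency is None:
        raise ValueError("tessellation must carry adjacency")
    amp = np.asarray(amplitudes, dtype=float)
    if amp.shape != (len(tess),):
        raise ValueError("amplitude count does not match tessellation")
    if amp.max(initial=0.0) <= 0:
        return PeakSet(np.empty((0, 3)), np.empty(0), voxel)

    nbm = tess.neighbor_matrix
    is_max = (amp[:, None] >= amp[nbm]).all(axis=1) & (amp > 0)
    cand = np.flatnonzero(is_max)
    dirs = tess.directions[cand]
    amps = amp[cand]
    order = np.lexsort((dirs[:, 2], dirs[:, 1], dirs[:, 0], -amps))
    dirs, amps = dirs[order], amps[order]

    keep = amps >= rel_thresh * amps[0]
    dirs, amps = dirs[keep], amps[keep]

    acc_d, acc_a = [], []
    for d, a in zip(dirs, amps):
        if all(_angle_deg(d[None], ad[None])[0, 0] >= min_sep for ad in acc_d):
            acc_d.append(d)
            acc_a.append(a)
            if len(acc_d) == max_peaks:
                break
    return PeakSet(np.array(acc_d), np.array(acc_a), voxel)


def peaks_from_sh(
    coeffs_full: np.ndarray, design: DesignMatrix, **kwargs
) -> PeakSet:
    """Evaluate full SH coefficients on the design's tessellation and extract peaks."""
    return extract_peaks(evaluate_sh(coeffs_full, design), design.tessellation, **kwargs)


def peak_volume(
    sh_full: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    **kwargs,
) -> np.ndarray:
    """Per-voxel peak sets of a full SH volume as an object array."""
    shape = sh_full.shape[:3]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    out = np.empty(shape, dtype=object)
    empty = PeakSet(np.empty((0, 3)), np.empty(0))
    out[...] = empty
    amp_all = evaluate_sh(sh_full[mask], design)
    for (i, j, k), amp in zip(np.argwhere(mask), amp_all):
        out[i, j, k] = extract_peaks(amp, design.tessellation, voxel=(i, j, k), **kwargs)
    return out


def _transport_cost(cost: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Minimum-cost transport between mass vectors a, b (both sum to 1)."""
    n, m = cost.shape
    if n == 1:
        return float(b @ cost[0])
    if m == 1:
        return float(a @ cost[:, 0])
    if n == 2 and m == 2:
        # one degree of freedom; the linear cost is minimized at an endpoint
        lo = max(0.0, b[0] - a[1])
        hi = min(a[0], b[0])
        vals = [
            cost[0, 0] * t + cost[0, 1] * (a[0] - t)
            + cost[1, 0] * (b[0] - t) + cost[1, 1] * (a[1] - b[0] + t)
            for t in (lo, hi)
        ]
        return float(min(vals))
    # general transportation LP
    A_eq = np.zeros((n + m - 1, n * m))
    for i in range(n):
        A_eq[i, i * m: (i + 1) * m] = 1.0
    for j in range(m - 1):  # last column constraint is redundant
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(cost.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - transportation LPs are always feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def angular_emd(a: PeakSet, b: PeakSet) -> float:
    """Angular earth mover's distance between two peak sets, in degrees.

    Empty vs empty is 0; empty vs nonempty is the flagged convention value
    of 90 degrees (all mass at the maximal orientation cost).
    """
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return EMPTY_SET_EMD
    cost = _angle_deg(a.directions, b.directions)
    return _transport_cost(cost, a.masses, b.masses)


def emd_error_map(
    gt_peaks: np.ndarray, pred_peaks: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-voxel angular EMD between aligned peak-set volumes (NaN outside mask)."""
    if gt_peaks.shape != pred_peaks.shape:
        raise ValueError("peak volumes are not aligned")
    if mask is None:
        mask = np.ones(gt_peaks.shape, dtype=bool)
    out = np.full(gt_peaks.shape, np.nan)
    for i, j, k in np.argwhere(mask):
        out[i, j, k] = angular_emd(gt_peaks[i, j, k], pred_peaks[i, j, k])
    return out


def best_method_fraction(
    error_maps: dict[str, np.ndarray],
    mask: np.ndarray,
    tol: float = 1e-9,
) -> dict[str, float]:
    """Fraction of masked voxels where each method attains the smallest error.

    All methods within ``tol`` degrees of the voxel minimum are flagged
    best, so ties count for every tied method and the fractions may sum to
    more than 1.
    """
    if len(error_maps) < 2:
        raise ValueError("need at least two methods to compare")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    stack = {name: np.asarray(m)[mask] for name, m in error_maps.items()}
    if any(v.shape != (n,) for v in stack.values()):
        raise ValueError("error maps are not aligned with the mask")
    best = np.min(np.stack(list(stack.values())), axis=0)
    return {name: float(np.mean(v <= best + tol)) for name, v in stack.items()}


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def sh_similarity(
    gt_sh: np.ndarray,
    pred_sh: np.ndarray,
    mask: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-coefficient similarity metrics between two SH volumes.

    Returns a tidy table with columns ``metric, tissue, coef, value``
    holding MSE, Pearson correlation and MAE over masked voxels, plus PSNR
    and SSIM computed per coefficient on the 3D maps (masked-out voxels
    zeroed in both).  With ``labels``, metrics are additionally reported
    per tissue label.
    """
    from skimage.metrics import peak_signal_noise_ratio, structural_similarity

    if gt_sh.shape != pred_sh.shape:
        raise ValueError("SH volumes are not aligned")
    if mask is None:
        mask = np.ones(gt_sh.shape[:3], dtype=bool)
    groups: dict[str, np.ndarray] = {"all": mask}
    if labels is not None:
        names = label_names or {}
        for lab in np.unique(labels[mask]):
            groups[names.get(int(lab), str(int(lab)))] = mask & (labels == lab)

    win = min(7, min(s - (s % 2 == 0) for s in gt_sh.shape[:3]))
    rows = []
    for tissue, m in groups.items():
        g = gt_sh[m]
        p = pred_sh[m]
        for c in range(gt_sh.shape[3]):
            diff = p[:, c] - g[:, c]
            rows.append(("mse", tissue, c, float(np.mean(diff**2))))
            rows.append(("mae", tissue, c, float(np.mean(np.abs(diff)))))
            rows.append(("correlation", tissue, c, _pearson(g[:, c], p[:, c])))
            gm = np.where(m, gt_sh[..., c], 0.0)
            pm = np.where(m, pred_sh[..., c], 0.0)
            rng = float(gm.max() - gm.min())
            if rng > 0:
                rows.append(
                    ("psnr", tissue, c,
                     float(peak_signal_noise_ratio(gm, pm, data_range=rng)))
                )
                rows.append(
                    ("ssim", tissue, c,
                     float(structural_similarity(gm, pm, data_range=rng, win_size=win)))
                )
            else:
                rows.append(("psnr", tissue, c, float("nan")))
                rows.append(("ssim", tissue, c, float("nan")))
    return pd.DataFrame(rows, columns=["metric", "tissue", "coef", "value"])


def generalized_anisotropy(norm_sh: np.ndarray) -> np.ndarray:
    """GA = tanh(V_Y) from normalized (44-entry) SH coefficients.

    For a unit-integral fODF the spherical variance is
    ``V_Y = (1/4 pi) * sum A_lm^2`` over degrees l >= 2, which is exactly
    the sum of squared normalized coefficients scaled by ``1/4 pi``.
    """
    norm_sh = np.asarray(norm_sh, dtype=float)
    v_y = np.sum(norm_sh**2, axis=-1) / (4.0 * np.pi)
    return np.tanh(v_y)


def average_peak_count(
    peaks: np.ndarray,
    labels: np.ndarray,
    mask: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
) -> dict[str, float]:
    """Mean per-voxel peak count within each tissue label."""
    if mask is None:
        mask = np.ones(peaks.shape, dtype=bool)
    counts = np.vectorize(len)(peaks)
    names = label_names or {}
    out = {}
    for lab in np.unique(labels[mask]):
        sel = mask & (labels == lab)
        out[names.get(int(lab), str(int(lab)))] = float(counts[sel].mean())
    return out
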