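"""Full-reference image quality (PSNR, SSIM) and segmentation agreement
(adapted Rand error) used to evaluate deblurring.

SSIM follows the canonical formulation: an 11x11 Gaussian window
(sigma 1.5), stabilizers C1 = (K1 L)^2, C2 = (K2 L)^2 with K1 = 0.01,
K2 = 0.03, population (weighted) covariances, evaluated on the valid
interior and averaged.  The adapted Rand error is the foreground-
restricted 1 - F-score of Rand precision/recall over all co-clustered
pixel pairs, the convention of the EM segmentation challenges; it is
invariant to label permutation and 0 exactly when the partitions agree.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal, sparse


def psnr(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    ref, test = np.asarray(ref, float), np.asarray(test, float)
    if ref.shape != test.shape:
        raise ValueError("shape mismatch")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def _gaussian_window(win_size: int, sigma: float) -> np.ndarray:
    r = (win_size - 1) // 2
    x = np.arange(-r, r + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def ssim(ref: np.ndarray, test: np.ndarray, data_range: float = 1.0,
         win_size: int = 11, sigma: float = 1.5,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity over the valid (fully-windowed) interior."""
    x, y = np.asarray(ref, float), np.asarray(test, float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if min(x.shape) < win_size:
        raise ValueError("image smaller than the SSIM window")
    w = _gaussian_window(win_size, sigma)
    filt = lambda a: signal.convolve2d(a, w, mode="valid")  # w symmetric
    ux, uy = filt(x), filt(y)
    uxx, uyy, uxy = filt(x * x), filt(y * y), filt(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    vxy = uxy - ux * uy
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    s = ((2 * ux * uy + c1) * (2 * vxy + c2)) / ((ux ** 2 + uy ** 2 + c1) * (vx + vy + c2))
    return float(s.mean())


def adapted_rand_error(pred: np.ndarray, gt: np.ndarray) -> float:
    """Foreground-restricted adapted Rand error, in [0, 1]; lower is better.

    Pixels with ground-truth label 0 (background) are excluded; the
    remaining pixels' predicted/true label co-occurrence table yields
    Rand precision and recall over unordered pixel pairs, and the error
    is one minus their harmonic mean.
    """
    pred, gt = np.asarray(pred), np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("shape mismatch")
    mask = gt > 0
    if not mask.any():
        raise ValueError("ground truth contains no foreground")
    p = pred[mask].ravel()
    g = gt[mask].ravel()
    _, pi = np.unique(p, return_inverse=True)
    _, gi = np.unique(g, return_inverse=True)
    n = sparse.coo_matrix((np.ones(len(pi)), (pi, gi))).tocsr()
    nij = n.data
    a = np.asarray(n.sum(axis=1)).ravel()  # predicted segment sizes
    b = np.asarray(n.sum(axis=0)).ravel()  # true segment sizes
    tp = float((nij * (nij - 1) / 2).sum())
    pairs_pred = float((a * (a - 1) / 2).sum())
    pairs_gt = float((b * (b - 1) / 2).sum())
    if pairs_pred == 0 and pairs_gt == 0:
        return 0.0  # both partitions are all singletons, hence identical
    precision = tp / pairs_pred if pairs_pred > 0 else 1.0
    recall = tp / pairs_gt if pairs_gt > 0 else 1.0
    if precision + recall == 0:
        return 1.0
    return 1.0 - 2.0 * precision * recall / (precision + recall)


@dataclass
class QualityReport:
    names: list[str]
    psnr_values: list[float]
    ssim_values: list[float]

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr_values))

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim_values))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["image", "psnr_db", "ssim"])
            for name, p, s in zip(self.names, self.psnr_values, self.ssim_values):
                w.writerow([name, f"{p:.6g}", f"{s:.6g}"])
            w.writerow(["mean", f"{self.mean_psnr:.6g}", f"{self.mean_ssim:.6g}"])


def evaluate_pairs(refs: list[np.ndarray], tests: list[np.ndarray],
                   names: list[str] | None = None,
                   data_range: float = 1.0) -> QualityReport:
    if len(refs) != len(tests):
        raise ValueError("ref/test count mismatch")
    names = names or [f"img{i:04d}" for i in range(len(refs))]
    return QualityReport(
        names,
        [psnr(r, t, data_range) for r, t in zip(refs, tests)],
        [ssim(r, t, data_range) for r, t in zip(refs, tests)],
    )
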