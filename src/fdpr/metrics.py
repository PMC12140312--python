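"""Image-quality and resolution metrics.

Notes on the estimators: the no-reference noise level uses the Laplacian
residual estimator (Immerkaer's fast method), and contrast is RMS contrast
(std/mean).  Both are scale-equivariant and serve as within-repository
quality measures.  PSNR/SSIM follow the standard reference definitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from skimage.metrics import structural_similarity

__all__ = [
    "QualityReport",
    "noise_level",
    "contrast",
    "psnr",
    "ssim",
    "usaf_linewidth",
    "abbe_resolution",
    "pupil_phase_rms_error",
    "evaluate",
]

_LAPLACIAN_MASK = np.array([[1.0, -2.0, 1.0],
                            [-2.0, 4.0, -2.0],
                            [1.0, -2.0, 1.0]])


@dataclass
class QualityReport:
    noise_level: float
    contrast: float
    psnr_db: float | None = None
    ssim: float | None = None

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        if self.ssim is not None and not (-1.0 <= self.ssim <= 1.0 + 1e-12):
            raise ValueError("ssim out of range")

    def to_dict(self) -> dict:
        return {"noise_level": self.noise_level, "contrast": self.contrast,
                "psnr_db": self.psnr_db, "ssim": self.ssim}


def noise_level(frame: np.ndarray) -> float:
    """Laplacian-mask residual estimate of additive noise sigma.

    ``sqrt(pi/2) / (6 (W-2)(H-2)) * sum |frame * M|`` with the 3x3 mask M
    that annihilates constants and planar ramps, so only noise (and very
    fine texture) contributes.
    """
    f = np.asarray(frame, dtype=float)
    if f.ndim != 2 or min(f.shape) < 3:
        raise ValueError("frame must be 2-D and at least 3x3")
    resid = convolve(f, _LAPLACIAN_MASK, mode="constant")[1:-1, 1:-1]
    h, w = f.shape
    return float(np.sqrt(np.pi / 2.0) / (6.0 * (w - 2) * (h - 2))
                 * np.abs(resid).sum())


def contrast(frame: np.ndarray) -> float:
    """RMS contrast: standard deviation over mean (mean must be positive)."""
    f = np.asarray(frame, dtype=float)
    m = f.mean()
    if m <= 0:
        raise ValueError("frame mean must be positive for RMS contrast")
    return float(f.std() / m)


def psnr(frame: np.ndarray, reference: np.ndarray,
         peak: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB (inf for identical inputs)."""
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    mse = float(((a - b) ** 2).mean())
    if mse == 0:
        return float("inf")
    if peak is None:
        peak = float(b.max() - b.min()) or 1.0
    return float(10.0 * np.log10(peak ** 2 / mse))


def ssim(frame: np.ndarray, reference: np.ndarray,
         data_range: float | None = None) -> float:
    """Structural similarity with the standard 11x11 Gaussian window."""
    a = np.asarray(frame, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if data_range is None:
        rng = float(max(a.max(), b.max()) - min(a.min(), b.min()))
        data_range = rng if rng > 0 else 1.0
    return float(structural_similarity(
        a, b, gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
        K1=0.01, K2=0.03, data_range=data_range))


def usaf_linewidth(group: int, element: int) -> tuple[float, float]:
    """Line width (um) and spatial frequency (lp/mm) of a USAF-1951 element.

    ``frequency = 2**(group + (element - 1)/6)`` line pairs per mm; one line
    is half a period, hence ``width_um = 500 / frequency``.
    """
    if not 1 <= element <= 6:
        raise ValueError("element must be in 1..6")
    freq_lpmm = 2.0 ** (group + (element - 1) / 6.0)
    return 500.0 / freq_lpmm, freq_lpmm


def abbe_resolution(wavelength_um: float, na: float) -> float:
    """Coherent diffraction-limited resolution ``lambda / (2 NA)`` in um."""
    if not (0 < na <= 1.5):
        raise ValueError("NA must be in (0, 1.5]")
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    return round(wavelength_um / (2.0 * na), 3)


def pupil_phase_rms_error(recovered_pupil: np.ndarray,
                          true_phase: np.ndarray,
                          mask: np.ndarray,
                          allow_conjugate: bool = True) -> float:
    """RMS pupil-phase error (rad) after piston/tip/tilt removal.

    Joint object-pupil recovery is blind to a global phase and to a linear
    pupil phase (an object shift), and every intensity-only model admits the
    conjugate-twin solution; all three are removed before comparing.  The
    tilt is estimated wrap-safely from neighbor phase differences so that
    multi-cycle tilts do not corrupt the fit.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty pupil mask")
    yy, xx = np.mgrid[: mask.shape[0], : mask.shape[1]]
    candidates = [np.asarray(recovered_pupil, dtype=complex)]
    if allow_conjugate:
        twin = np.conj(np.roll(recovered_pupil[::-1, ::-1], (1, 1),
                               axis=(0, 1)))
        candidates.append(twin)
    best = np.inf
    for pr in candidates:
        d = pr * np.exp(-1j * np.asarray(true_phase))
        w = np.abs(d) * mask
        dy = np.angle(d[1:, :] * np.conj(d[:-1, :]))
        wy = w[1:, :] * w[:-1, :]
        dx = np.angle(d[:, 1:] * np.conj(d[:, :-1]))
        wx = w[:, 1:] * w[:, :-1]
        sy = float((dy * wy).sum() / max(wy.sum(), 1e-300))
        sx = float((dx * wx).sum() / max(wx.sum(), 1e-300))
        d2 = d * np.exp(-1j * (sy * yy + sx * xx))
        piston = np.angle((d2 * mask).sum())
        resid = np.angle(d2 * np.exp(-1j * piston))[mask]
        best = min(best, float(np.sqrt((resid ** 2).mean())))
    return best


def evaluate(frame: np.ndarray,
             reference: np.ndarray | None = None) -> QualityReport:
    """Full quality report; PSNR/SSIM only when a reference is given."""
    rep = QualityReport(noise_level=noise_level(frame),
                        contrast=contrast(frame))
    if reference is not None:
        rep.psnr_db = psnr(frame, reference)
        rep.ssim = ssim(frame, reference)
    return rep
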