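"""Decode confidence maps to keypoint coordinates and confidence scores.

Two decoders are provided.  :func:`integer_maxima` is the baseline: the row
and column of each map's global maximum, scaled by the output stride.
:func:`subpixel_maxima` registers a Gaussian template against each map by
Fourier cross-correlation and refines the correlation peak on an upsampled
grid evaluated directly in the frequency domain, recovering fractional-pixel
locations even from heavily downsampled maps.

:func:`bruteforce_peak_oracle` is an independent check: it scans an
analytically shifted Gaussian over a dense grid in the spatial domain and
returns the correlation argmax.  It shares no code path with the FFT route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PeakResult",
    "integer_maxima",
    "subpixel_maxima",
    "bruteforce_peak_oracle",
    "save_predictions_csv",
]

#: Default upsampling factor for the refinement grid (1/16 map pixel).
DEFAULT_UPSAMPLE = 16


@dataclass
class PeakResult:
    """Decoded peak locations for one stack of confidence maps.

    ``coords`` is ``(K, 2)`` float ``(x, y)`` in input-image pixels, clipped
    to the image bounds; ``confidence`` is the map value at the peak,
    clipped to [0, 1].
    """

    coords: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)


def _as_stack(maps: np.ndarray) -> np.ndarray:
    maps = np.asarray(maps, dtype=np.float64)
    if maps.ndim == 2:
        maps = maps[None]
    if maps.ndim != 3 or maps.size == 0:
        raise ValueError("maps must be a nonempty (K, h, w) stack")
    return maps


def integer_maxima(maps: np.ndarray, stride: int = 1) -> PeakResult:
    """Global-maximum decoding at integer map resolution.

    Per map the peak is the row/column of the global maximum (ties broken by
    lowest row, then lowest column — row-major argmax order), scaled by the
    stride.  Confidence is the maximum map value.
    """
    maps = _as_stack(maps)
    k, h, w = maps.shape
    flat = maps.reshape(k, -1)
    idx = flat.argmax(axis=1)
    rows, cols = np.divmod(idx, w)
    coords = np.stack([cols * stride, rows * stride], axis=1).astype(np.float64)
    confidence = np.clip(flat[np.arange(k), idx], 0.0, 1.0)
    return PeakResult(coords=coords, confidence=confidence)


def _gaussian_template(h: int, w: int, sigma: float) -> np.ndarray:
    """Amplitude-1 Gaussian centred at ((w-1)/2, (h-1)/2)."""
    tcx, tcy = (w - 1) / 2.0, (h - 1) / 2.0
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    return np.exp(-(((jj - tcx) ** 2 + (ii - tcy) ** 2) / (2.0 * sigma**2)))


def _bilinear(map_: np.ndarray, x: float, y: float) -> float:
    """Bilinear interpolation of a 2-D map at (x, y), clamped to the grid."""
    h, w = map_.shape
    x = min(max(x, 0.0), w - 1.0)
    y = min(max(y, 0.0), h - 1.0)
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, w - 1), min(y0 + 1, h - 1)
    fx, fy = x - x0, y - y0
    top = map_[y0, x0] * (1 - fx) + map_[y0, x1] * fx
    bot = map_[y1, x0] * (1 - fx) + map_[y1, x1] * fx
    return float(top * (1 - fy) + bot * fy)


def _upsampled_idft(
    spectrum: np.ndarray, dy: np.ndarray, dx: np.ndarray
) -> np.ndarray:
    """Real part of the inverse DFT of ``spectrum`` at fractional shifts.

    Direct matrix evaluation of the restricted transform on the grid
    ``dy x dx`` (row shifts by column shifts), with wrapped frequencies.
    """
    h, w = spectrum.shape
    fy = np.fft.fftfreq(h) * h  # integer frequency indices, wrapped
    fx = np.fft.fftfreq(w) * w
    ey = np.exp(2j * np.pi * np.outer(dy, fy) / h)  # (n, h)
    ex = np.exp(2j * np.pi * np.outer(fx, dx) / w)  # (w, n)
    return np.real(ey @ spectrum @ ex) / (h * w)


def subpixel_maxima(
    maps: np.ndarray,
    stride: int = 1,
    kernel_sigma: float = 1.25,
    upsample: int = DEFAULT_UPSAMPLE,
) -> PeakResult:
    """Subpixel peak decoding by Fourier template registration.

    Each map is cross-correlated with a mean-subtracted Gaussian template
    (scale ``kernel_sigma`` in map pixels, matched to the drawn target peaks:
    training sigma divided by the stride).  The integer correlation argmax
    gives a coarse shift, refined by evaluating the correlation on a
    ``ceil(1.5 u) x ceil(1.5 u)`` grid of spacing ``1/u`` directly in the
    frequency domain.  Peak position in map coordinates is the template
    centre plus the refined shift; image coordinates are that times the
    stride.  Confidence is the bilinear map value at the peak.
    """
    maps = _as_stack(maps)
    if not np.isfinite(maps).all():
        raise ValueError("maps contain non-finite values")
    if upsample < 1 or int(upsample) != upsample:
        raise ValueError("upsample must be a positive integer")
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    k, h, w = maps.shape
    if h < 8 or w < 8:
        raise ValueError("maps must be at least 8x8")

    template = _gaussian_template(h, w, kernel_sigma)
    template = template - template.mean()  # insensitive to constant offsets
    t_spec_conj = np.conj(np.fft.fft2(template))
    tcx, tcy = (w - 1) / 2.0, (h - 1) / 2.0

    n = int(np.ceil(1.5 * upsample))
    if n % 2 == 0:  # odd grid: include the zero offset exactly
        n += 1
    local = (np.arange(n) - (n - 1) / 2.0) / upsample

    coords = np.empty((k, 2))
    confidence = np.empty(k)
    for m in range(k):
        spectrum = np.fft.fft2(maps[m]) * t_spec_conj
        corr = np.real(np.fft.ifft2(spectrum))
        r, c = np.unravel_index(np.argmax(corr), corr.shape)
        shift_y = r if r <= h / 2 else r - h
        shift_x = c if c <= w / 2 else c - w

        fine = _upsampled_idft(spectrum, shift_y + local, shift_x + local)
        fr, fc = np.unravel_index(np.argmax(fine), fine.shape)
        px = tcx + shift_x + local[fc]
        py = tcy + shift_y + local[fr]

        confidence[m] = np.clip(_bilinear(maps[m], px, py), 0.0, 1.0)
        coords[m, 0] = np.clip(px * stride, 0.0, (w - 1) * stride)
        coords[m, 1] = np.clip(py * stride, 0.0, (h - 1) * stride)
    return PeakResult(coords=coords, confidence=confidence)


def bruteforce_peak_oracle(
    map_: np.ndarray,
    kernel_sigma: float,
    upsample: int = DEFAULT_UPSAMPLE,
    halfwidth: float = 2.0,
) -> tuple[float, float]:
    """Dense spatial-domain correlation scan; returns the peak ``(x, y)``.

    The Gaussian template is resampled analytically at every candidate
    position on a grid of spacing ``1/upsample`` within ``halfwidth`` map
    pixels of the integer argmax, and the position maximising the spatial
    correlation sum is returned in map coordinates.  Quadratic cost — meant
    for small maps as an independent check of :func:`subpixel_maxima`.
    """
    map_ = np.asarray(map_, dtype=np.float64)
    if map_.ndim != 2:
        raise ValueError("oracle takes a single 2-D map")
    h, w = map_.shape
    if h > 64 or w > 64:
        raise ValueError("oracle is restricted to maps of at most 64x64")
    r, c = np.unravel_index(np.argmax(map_), map_.shape)
    offsets = np.arange(
        -halfwidth, halfwidth + 0.5 / upsample, 1.0 / upsample
    )
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    best, best_xy = -np.inf, (float(c), float(r))
    for dy in offsets:
        cy = r + dy
        gy = np.exp(-((ii - cy) ** 2) / (2.0 * kernel_sigma**2))
        for dx in offsets:
            cx = c + dx
            gx = np.exp(-((jj - cx) ** 2) / (2.0 * kernel_sigma**2))
            score = float(np.sum(map_ * gy * gx))
            if score > best:
                best, best_xy = score, (float(cx), float(cy))
    return best_xy


def save_predictions_csv(results: list[PeakResult], names, path) -> None:
    """Write decoded peaks as CSV with columns frame,keypoint,x,y,confidence."""
    rows = []
    for frame, res in enumerate(results):
        for k, name in enumerate(names):
            rows.append(
                {
                    "frame": frame,
                    "keypoint": name,
                    "x": res.coords[k, 0],
                    "y": res.coords[k, 1],
                    "confidence": res.confidence[k],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_predictions_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "keypoint", "x", "y", "confidence"}
    if not required.issubset(df.columns):
        raise ValueError(f"prediction CSV must have columns {sorted(required)}")
    return df
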