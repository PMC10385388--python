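"""Savitzky–Golay smoothing of reflectance spectra.

The S-G filter replaces each band value by the value of a least-squares
polynomial fit over a sliding window, which suppresses band-to-band noise
while reproducing polynomial signal of degree <= poly_order exactly. Edge
bands are handled by fitting the boundary window's polynomial and
evaluating it at the edge positions, so output length equals input length.
Reflectance is physically bounded, so results are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectralDataset

__all__ = ["SmoothingConfig", "savgol_smooth", "smooth_dataset"]


@dataclass(frozen=True)
class SmoothingConfig:
    """S-G window length (odd, in bands) and polynomial order.

    Defaults (11, 2) are conventional for 125-band reflectance curves.
    """

    window_length: int = 11
    poly_order: int = 2

    def __post_init__(self):
        w, p = self.window_length, self.poly_order
        if w % 2 == 0 or w < 3 or w > 125:
            raise ValueError(
                f"window_length must be odd and in [3, 125], got {w}"
            )
        if not 0 <= p < w:
            raise ValueError(
                f"poly_order must satisfy 0 <= poly_order < window_length, got {p}"
            )


def savgol_smooth(
    spectrum: np.ndarray, cfg: SmoothingConfig | None = None, clip: bool = True
) -> np.ndarray:
    """Smooth one spectrum (or a stack along the last axis).

    ``clip=False`` returns the raw linear filter output (useful for
    verifying linearity and polynomial exactness).
    """
    cfg = cfg or SmoothingConfig()
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.shape[-1] < cfg.window_length:
        raise ValueError(
            f"spectrum has {spectrum.shape[-1]} bands, fewer than "
            f"window_length={cfg.window_length}"
        )
    out = savgol_filter(
        spectrum, cfg.window_length, cfg.poly_order, axis=-1, mode="interp"
    )
    return np.clip(out, 0.0, 1.0) if clip else out


def smooth_dataset(
    ds: SpectralDataset, cfg: SmoothingConfig | None = None
) -> SpectralDataset:
    """Apply S-G smoothing to every record; labels and metadata unchanged."""
    cfg = cfg or SmoothingConfig()
    if ds.n_samples == 0:
        return ds.replace_data(ds.data.copy())
    # (N, S, M) → smooth along the band axis S for each variable
    smoothed = np.empty_like(ds.data)
    for m in range(ds.n_vars):
        smoothed[:, :, m] = savgol_smooth(ds.data[:, :, m], cfg)
    return ds.replace_data(smoothed)
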