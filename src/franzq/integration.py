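"""Baseline-corrected peak integration and the analyte/calibrant ratio.

The quantity the internal-standard assay consumes is the ratio of two window
integrals, I_analyte/I_calibrant. Integration is plain trapezoidal over a
ppm window; the optional baseline is the straight line joining the mean
intensity of the three outermost points at each window edge, which removes
constant and linear backgrounds exactly.

No Lorentzian-tail truncation correction is applied: when both peaks are
integrated over windows of the same width-to-linewidth ratio, the truncated
tail fraction is identical and cancels in the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCalibrantError, InvalidConfigError, WindowError
from .spectra import ANALYTE_PPM, CALIBRANT_PPM, Spectrum

#: Default half-width (ppm) of the integration windows around each peak.
DEFAULT_HALF_WIDTH_PPM = 0.10

BASELINE_MODES = ("none", "linear_endpoints")
# Points averaged at each window edge to anchor the linear baseline.
_EDGE_POINTS = 3


@dataclass(frozen=True)
class IntegrationWindow:
    """A ppm interval [low_ppm, high_ppm] with a baseline treatment."""

    low_ppm: float
    high_ppm: float
    baseline_mode: str = "linear_endpoints"

    def __post_init__(self) -> None:
        if not self.low_ppm < self.high_ppm:
            raise InvalidConfigError(
                f"window low {self.low_ppm} must be < high {self.high_ppm}"
            )
        if self.baseline_mode not in BASELINE_MODES:
            raise InvalidConfigError(
                f"baseline_mode must be one of {BASELINE_MODES}"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.low_ppm + self.high_ppm)

    @property
    def width(self) -> float:
        return self.high_ppm - self.low_ppm

    @classmethod
    def around(cls, center_ppm: float, half_width_ppm: float = DEFAULT_HALF_WIDTH_PPM,
               baseline_mode: str = "linear_endpoints") -> "IntegrationWindow":
        return cls(center_ppm - half_width_ppm, center_ppm + half_width_ppm,
                   baseline_mode)

    @classmethod
    def parse(cls, text: str, baseline_mode: str = "linear_endpoints"
              ) -> "IntegrationWindow":
        """Parse the CLI form ``LOW:HIGH`` (ppm)."""
        try:
            low, high = (float(p) for p in text.split(":"))
        except ValueError:
            raise InvalidConfigError(f"cannot parse window {text!r}; want LOW:HIGH") from None
        return cls(low, high, baseline_mode)


def default_analyte_window() -> IntegrationWindow:
    """5.57 ± 0.10 ppm — the cannabidiol olefinic-proton region."""
    return IntegrationWindow.around(ANALYTE_PPM)


def default_calibrant_window() -> IntegrationWindow:
    """7.48 ± 0.10 ppm — the naphthalene aromatic region."""
    return IntegrationWindow.around(CALIBRANT_PPM)


def _window_slice(spectrum: Spectrum, window: IntegrationWindow):
    """Ascending (ppm, intensity) arrays restricted to the window."""
    ppm = spectrum.shifts[::-1]  # stored descending; integrate ascending
    y = spectrum.intensities[::-1]
    mask = (ppm >= window.low_ppm) & (ppm <= window.high_ppm)
    n_inside = int(mask.sum())
    if n_inside < 4:
        raise WindowError(
            f"window [{window.low_ppm}, {window.high_ppm}] ppm covers only "
            f"{n_inside} spectrum points (need >= 4)"
        )
    return ppm[mask], y[mask]


def integrate_window(spectrum: Spectrum, window: IntegrationWindow) -> float:
    """Trapezoidal integral of intensity over the window, baseline-subtracted.

    With ``linear_endpoints`` the subtracted baseline is the line through
    (mean ppm, mean intensity) of the 3 outermost points at each edge.
    The result may be negative in pure noise and is returned unclipped.
    """
    ppm, y = _window_slice(spectrum, window)
    if window.baseline_mode == "linear_endpoints":
        xl, yl = ppm[:_EDGE_POINTS].mean(), y[:_EDGE_POINTS].mean()
        xr, yr = ppm[-_EDGE_POINTS:].mean(), y[-_EDGE_POINTS:].mean()
        slope = (yr - yl) / (xr - xl)
        y = y - (yl + slope * (ppm - xl))
    return float(np.trapezoid(y, ppm))


def integral_ratio(
    spectrum: Spectrum,
    analyte_window: IntegrationWindow,
    calibrant_window: IntegrationWindow,
) -> float:
    """I_analyte / I_calibrant for one spectrum.

    Invariant under global intensity rescaling. A non-positive calibrant
    integral marks the spectrum unusable and raises
    :class:`DegenerateCalibrantError`.
    """
    if not (analyte_window.high_ppm <= calibrant_window.low_ppm
            or calibrant_window.high_ppm <= analyte_window.low_ppm):
        raise InvalidConfigError("analyte and calibrant windows must be disjoint")
    i_cal = integrate_window(spectrum, calibrant_window)
    if i_cal <= 0:
        raise DegenerateCalibrantError(
            f"calibrant integral {i_cal:.4g} <= 0: spectrum unusable"
        )
    i_ana = integrate_window(spectrum, analyte_window)
    return i_ana / i_cal
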