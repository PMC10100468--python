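"""1D ¹H-NMR spectra: container, CSV I/O, and synthetic generation.

The synthetic generator produces the two situations the assay meets in
practice: a single extraction spectrum carrying one analyte resonance
(cannabidiol's olefinic proton at 5.57 ppm) and one calibrant resonance
(naphthalene's four equivalent protons at 7.48 ppm), and a Franz-cell time
series in which the analyte resonance shrinks as drug leaves the patch disc
while the internal-standard resonance stays fixed.

Lineshapes are pure Lorentzians — the standard liquid-state ¹H model — so
every simulated peak has a closed-form window integral that tests can check
against:  the mass of a unit-area Lorentzian within ±k·FWHM of its centre is
(2/π)·arctan(2k).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np

from .errors import InvalidConfigError, SpectrumFormatError

logger = logging.getLogger(__name__)

#: Default chemical shift (ppm) of the quantified cannabidiol resonance.
ANALYTE_PPM = 5.57
#: Default chemical shift (ppm) of the quantified naphthalene resonance.
CALIBRANT_PPM = 7.48
#: Default full width at half maximum (ppm) for simulated resonances.
DEFAULT_FWHM_PPM = 0.01
#: Default digitization: 16,384 points over 0–10 ppm resolves 0.01-ppm lines.
DEFAULT_PPM_RANGE = (0.0, 10.0)
DEFAULT_POINTS = 16384


@dataclass
class Spectrum:
    """A digitized 1D spectrum: chemical-shift axis plus intensities.

    Shifts are stored strictly descending (the conventional NMR display
    order); intensities are in arbitrary units. ``meta`` carries free-form
    annotations such as a sample id or the Franz-cell time point in hours.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.ndim != 1 or self.intensities.ndim != 1:
            raise InvalidConfigError("shifts and intensities must be 1-D")
        if self.shifts.size != self.intensities.size:
            raise InvalidConfigError(
                f"axis length {self.shifts.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.shifts.size < 2:
            raise InvalidConfigError("a spectrum needs at least 2 points")
        diffs = np.diff(self.shifts)
        if np.all(diffs > 0):
            logger.info("ascending ppm axis re-sorted to descending")
            self.shifts = self.shifts[::-1].copy()
            self.intensities = self.intensities[::-1].copy()
        elif not np.all(diffs < 0):
            raise InvalidConfigError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidConfigError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.shifts.size)


@dataclass(frozen=True)
class Resonance:
    """One Lorentzian resonance: centre (ppm), FWHM (ppm), integrated area."""

    center_ppm: float
    fwhm_ppm: float
    area: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm_ppm <= 0:
            raise InvalidConfigError("fwhm_ppm must be > 0")
        if self.area < 0:
            raise InvalidConfigError("area must be >= 0")

    def evaluate(self, ppm: np.ndarray) -> np.ndarray:
        """Lorentzian intensity (2A/π)·w / (4(δ−δ₀)² + w²) at each shift."""
        w = self.fwhm_ppm
        return (2.0 * self.area / math.pi) * w / (
            4.0 * (ppm - self.center_ppm) ** 2 + w**2
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to render one synthetic spectrum reproducibly."""

    resonances: tuple[Resonance, ...] = ()
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE
    points: int = DEFAULT_POINTS
    noise_sd: float = 0.0
    baseline: tuple[float, float] = (0.0, 0.0)  # (constant, slope per ppm)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "resonances", tuple(self.resonances))
        low, high = self.ppm_range
        if not low < high:
            raise InvalidConfigError(f"ppm_range low {low} must be < high {high}")
        if self.points < 64:
            raise InvalidConfigError("points must be >= 64")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        res = tuple(
            Resonance(
                center_ppm=float(r["center_ppm"]),
                fwhm_ppm=float(r.get("fwhm_ppm", DEFAULT_FWHM_PPM)),
                area=float(r["area"]),
                label=str(r.get("label", "")),
            )
            for r in d.get("resonances", [])
        )
        return cls(
            resonances=res,
            ppm_range=tuple(d.get("ppm_range", DEFAULT_PPM_RANGE)),
            points=int(d.get("points", DEFAULT_POINTS)),
            noise_sd=float(d.get("noise_sd", 0.0)),
            baseline=tuple(d.get("baseline", (0.0, 0.0))),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class FranzSeriesTruth:
    """Noiseless ground truth carried alongside a simulated Franz series."""

    times_h: np.ndarray
    true_remaining_mg: np.ndarray
    model_id: str
    model_params: dict
    initial_mg: float
    clipped: bool = False

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.true_remaining_mg = np.asarray(self.true_remaining_mg, dtype=float)
        if np.any(self.times_h < 0) or np.any(np.diff(self.times_h) <= 0):
            raise InvalidConfigError("times must be non-negative, strictly increasing")

    @property
    def true_released_percent(self) -> np.ndarray:
        return 100.0 * (1.0 - self.true_remaining_mg / self.initial_mg)


def simulate_spectrum(config: SimulationConfig) -> Spectrum:
    """Render one spectrum: baseline + Lorentzian resonances + Gaussian noise.

    Identical configs (including ``seed``) give bitwise-identical output.
    """
    low, high = config.ppm_range
    # Ascending grid, flipped once at the end to the descending display order.
    ppm = np.linspace(low, high, config.points)
    c0, c1 = config.baseline
    intensity = c0 + c1 * ppm
    for res in config.resonances:
        intensity = intensity + res.evaluate(ppm)
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.size)
    return Spectrum(
        shifts=ppm[::-1].copy(),
        intensities=intensity[::-1].copy(),
        meta={"seed": config.seed},
    )


def simulate_franz_series(
    initial_mg: float,
    schedule: Sequence[float],
    model_id: str,
    model_params: dict,
    noise: float = 0.0,
    seed: int = 0,
    assay=None,
    calibrant_area: float = 100.0,
    fwhm_ppm: float = DEFAULT_FWHM_PPM,
    points: int = DEFAULT_POINTS,
) -> tuple[list[Spectrum], FranzSeriesTruth]:
    """Simulate the qNMR spectra of independent patch discs pulled from a
    Franz cell at each scheduled time.

    Each time point is a fresh specimen: the analyte resonance area is
    proportional to the mass remaining in the disc under the chosen kinetic
    law, perturbed multiplicatively by (1 + ε), ε ~ N(0, ``noise``), while
    the internal-standard resonance area stays fixed. The mass→area map
    inverts the internal-standard equation for ``assay`` (default: the
    1 mg-naphthalene Franz-disc assay), so quantifying a noiseless spectrum
    returns the true remaining mass exactly up to integration error.

    Released percentages beyond 100 are clipped to [0, 100] and the series
    is flagged in the returned truth.
    """
    from .kinetics import predict_release_percent  # deferred: avoids cycle
    from .quantification import default_franz_assay, ratio_for_mass

    if initial_mg <= 0:
        raise InvalidConfigError("initial_mg must be > 0")
    times = np.asarray(schedule, dtype=float)
    if times.size < 2 or np.any(np.diff(times) <= 0) or np.any(times < 0):
        raise InvalidConfigError("schedule must be >= 2 strictly increasing times")
    if noise < 0:
        raise InvalidConfigError("noise must be >= 0")
    if assay is None:
        assay = default_franz_assay()

    released_pct = predict_release_percent(model_id, model_params, times)
    clipped = bool(np.any(released_pct > 100.0) or np.any(released_pct < 0.0))
    if clipped:
        logger.warning("release percent outside [0, 100] clipped for %s", model_id)
    released_pct = np.clip(released_pct, 0.0, 100.0)
    remaining_mg = initial_mg * (1.0 - released_pct / 100.0)

    rng = np.random.default_rng(seed)
    spectra: list[Spectrum] = []
    for i, (t, rem) in enumerate(zip(times, remaining_mg)):
        eps = rng.normal(0.0, noise) if noise > 0 else 0.0
        analyte_area = ratio_for_mass(rem, assay) * calibrant_area * (1.0 + eps)
        cfg = SimulationConfig(
            resonances=(
                Resonance(assay.analyte.window.center, fwhm_ppm,
                          max(analyte_area, 0.0), "analyte"),
                Resonance(assay.calibrant.window.center, fwhm_ppm,
                          calibrant_area, "calibrant"),
            ),
            points=points,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        spec = simulate_spectrum(cfg)
        spec.meta.update({"time_h": float(t), "sample_id": f"disc_{i}"})
        spectra.append(spec)

    truth = FranzSeriesTruth(
        times_h=times,
        true_remaining_mg=remaining_mg,
        model_id=model_id,
        model_params=dict(model_params),
        initial_mg=initial_mg,
        clipped=clipped,
    )
    return spectra, truth


def read_spectrum(source: TextIO | str) -> Spectrum:
    """Read a two-column CSV spectrum (header ``ppm,intensity``).

    Comment lines starting with ``#`` are ignored. An ascending axis is
    accepted and re-sorted to descending with a logged notice. Non-numeric
    rows, duplicated shifts, and fewer than 2 data rows raise
    :class:`SpectrumFormatError` naming the offending line.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    shifts: list[float] = []
    intensities: list[float] = []
    header_seen = False
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            if line.lower().replace(" ", "") != "ppm,intensity":
                raise SpectrumFormatError(
                    f"line {lineno}: expected header 'ppm,intensity', got {line!r}"
                )
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(f"line {lineno}: expected 2 columns, got {line!r}")
        try:
            shifts.append(float(parts[0]))
            intensities.append(float(parts[1]))
        except ValueError:
            raise SpectrumFormatError(f"line {lineno}: non-numeric row {line!r}") from None
    if len(shifts) < 2:
        raise SpectrumFormatError(f"need at least 2 data rows, got {len(shifts)}")
    if len(set(shifts)) != len(shifts):
        raise SpectrumFormatError("duplicated chemical shifts in input")
    try:
        return Spectrum(np.array(shifts), np.array(intensities))
    except InvalidConfigError as exc:
        raise SpectrumFormatError(str(exc)) from None


def write_spectrum(spectrum: Spectrum, dest: TextIO | None = None) -> str:
    """Serialize a spectrum to CSV, preserving ≥ 9 significant digits."""
    buf = io.StringIO()
    buf.write("ppm,intensity\n")
    for s, y in zip(spectrum.shifts, spectrum.intensities):
        buf.write(f"{s:.12g},{y:.12g}\n")
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text
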