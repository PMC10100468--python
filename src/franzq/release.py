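"""Franz-cell release profiles from remaining-mass measurements.

Each observation is an independent 10-mm patch disc quantified by qNMR
after a set residence time in the Franz cell. Released mass is the initial
disc content minus the remaining content; from it follow the release
percentage (relative to the t = 0 qNMR determination) and the release per
area (relative to the disc area, since each Franz specimen is a disc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, InvalidConfigError
from .quantification import PatchSpec, disc_area_cm2

logger = logging.getLogger(__name__)

#: Sampling schedule (h) used for the Franz-cell time course.
DEFAULT_SCHEDULE_H = (4.0, 12.0, 24.0, 36.0, 48.0)


@dataclass(frozen=True)
class ReleaseObservation:
    """Remaining analyte mass in one disc at one time point."""

    time_h: float
    remaining_mg: float
    replicate: str | None = None

    def __post_init__(self) -> None:
        if self.time_h <= 0:
            raise InvalidConfigError("time_h must be > 0 (t=0 is carried as m0)")
        if self.remaining_mg < 0:
            raise InvalidConfigError("remaining_mg must be >= 0")


@dataclass
class ReleaseProfile:
    """Aggregated release time series for one patch.

    ``m0_mg`` is the t = 0 qNMR determination; derived series are aligned
    with ``times_h``. Negative released values (measurement noise pushing
    remaining above m0) are retained but flagged.
    """

    patch: PatchSpec
    m0_mg: float
    times_h: np.ndarray
    remaining_mg: np.ndarray
    remaining_sd_mg: np.ndarray
    released_mg: np.ndarray
    release_percent: np.ndarray
    release_per_area_mg_cm2: np.ndarray
    disc_diameter_mm: float = 10.0
    flags: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times_h,
                "remaining_mg": self.remaining_mg,
                "remaining_sd_mg": self.remaining_sd_mg,
                "released_mg": self.released_mg,
                "release_percent": self.release_percent,
                "release_per_area_mg_cm2": self.release_per_area_mg_cm2,
            }
        )


def build_release_profile(
    m0_mg: float,
    observations: list[ReleaseObservation],
    patch: PatchSpec,
    disc_diameter_mm: float = 10.0,
) -> ReleaseProfile:
    """Aggregate replicate observations and derive the release series.

    Replicates at the same nominal time are averaged first (dispersion kept
    as the sample sd for error bars). Then, per time point:

    * released(t) = m0 − remaining(t)
    * release_percent(t) = 100 · released(t) / m0
    * release_per_area(t) = released(t) / disc area (cm²)
    """
    if m0_mg <= 0:
        raise InputError("m0_mg must be > 0")
    if not observations:
        raise InputError("no observations given")

    df = pd.DataFrame(
        {
            "time_h": [o.time_h for o in observations],
            "remaining_mg": [o.remaining_mg for o in observations],
            "replicate": [o.replicate for o in observations],
        }
    )
    dup_unlabeled = df[df["replicate"].isna()].duplicated(subset="time_h")
    if dup_unlabeled.any():
        t_bad = df.loc[dup_unlabeled[dup_unlabeled].index[0], "time_h"]
        raise InputError(
            f"duplicate observations at t={t_bad} h without replicate ids; "
            "tag replicates to have them averaged"
        )
    agg = (
        df.groupby("time_h")["remaining_mg"]
        .agg(["mean", "std", "count"])
        .sort_index()
        .reset_index()
    )
    times = agg["time_h"].to_numpy(dtype=float)
    if times.size < 2:
        raise InputError("need >= 2 distinct time points")
    remaining = agg["mean"].to_numpy(dtype=float)
    sd = agg["std"].fillna(0.0).to_numpy(dtype=float)

    released = m0_mg - remaining
    flags: list[str] = []
    if np.any(released < 0):
        flags.append("negative_release")
        logger.warning(
            "remaining mass exceeds m0 at %d point(s): retained, flagged",
            int((released < 0).sum()),
        )
    if np.all(remaining > m0_mg):
        flags.append("suspicious_profile")
        logger.warning("remaining > m0 at every point — suspicious profile")

    area = disc_area_cm2(disc_diameter_mm)
    return ReleaseProfile(
        patch=patch,
        m0_mg=m0_mg,
        times_h=times,
        remaining_mg=remaining,
        remaining_sd_mg=sd,
        released_mg=released,
        release_percent=100.0 * released / m0_mg,
        release_per_area_mg_cm2=released / area,
        disc_diameter_mm=disc_diameter_mm,
        flags=flags,
    )


def profile_from_release_percent(
    times_h,
    release_percent,
    m0_mg: float = 100.0,
    patch: PatchSpec | None = None,
    disc_diameter_mm: float = 10.0,
) -> ReleaseProfile:
    """Build a profile directly from a (time, release %) series.

    Convenience for re-importing an exported profile or fitting kinetics to
    percentages alone; the mass scale (``m0_mg``) only matters for the
    mg-valued series, not for percent-based model fits.
    """
    times = np.asarray(times_h, dtype=float)
    pct = np.asarray(release_percent, dtype=float)
    if times.size != pct.size or times.size < 2:
        raise InputError("need matching series with >= 2 points")
    if np.any(np.diff(times) <= 0):
        raise InputError("times must be strictly increasing")
    released = m0_mg * pct / 100.0
    if patch is None:
        patch = PatchSpec(brand="unnamed", labeled_mg=m0_mg, patch_area_cm2=1.0,
                          sample_diameter_mm=disc_diameter_mm)
    return ReleaseProfile(
        patch=patch,
        m0_mg=m0_mg,
        times_h=times,
        remaining_mg=m0_mg - released,
        remaining_sd_mg=np.zeros_like(times),
        released_mg=released,
        release_percent=pct,
        release_per_area_mg_cm2=released / disc_area_cm2(disc_diameter_mm),
        disc_diameter_mm=disc_diameter_mm,
    )


def read_release_table(source) -> list[ReleaseObservation]:
    """Read a CSV with header ``time_h,remaining_mg,replicate``."""
    df = pd.read_csv(source, comment="#")
    required = {"time_h", "remaining_mg"}
    if not required.issubset(df.columns):
        raise InputError(
            f"release table must have columns {sorted(required)}; got {list(df.columns)}"
        )
    reps = df["replicate"] if "replicate" in df.columns else [None] * len(df)
    try:
        return [
            ReleaseObservation(float(t), float(m),
                               None if pd.isna(r) else str(r))
            for t, m, r in zip(df["time_h"], df["remaining_mg"], reps)
        ]
    except (TypeError, ValueError) as exc:
        raise InputError(f"non-numeric value in release table: {exc}") from None
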