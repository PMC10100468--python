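"""Release-kinetics model fitting, selection, and depletion extrapolation.

Four empirical laws describe cumulative release Q(t) (in percent of the
initial content) and each is fitted through its standard linearization by
ordinary least squares:

======================  =============================  =======================
model                   form                           linearized coordinates
======================  =============================  =======================
zero order              Q = Q0 + K0·t                  Q vs t
first order             Q = Q0·e^(−K·t)                log10(Q) vs t
Higuchi                 Q = c + K_H·√t                 Q vs √t
Weibull                 Q = 100·(1 − e^(−α·t^β))       log10(−ln(1−Q/100))
                                                       vs log10(t)
======================  =============================  =======================

Goodness of fit is the squared Pearson correlation of the transformed
pairs; the best model is simply the one with the highest r². From the
Higuchi fit follow the release rate (K_H, in release%/h^0.5) and the
extrapolated time of complete release, t = ((100 − c)/K_H)².

The first-order linearization regresses log(release%) on t, the form used
for tabulated release comparisons; conventional first-order kinetics
(log of the *remaining* percentage) is available via ``convention=
"remaining"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AnalysisError,
    DegenerateFitError,
    InsufficientDataError,
    InvalidConfigError,
    NoReleaseError,
)
from .release import ReleaseProfile

logger = logging.getLogger(__name__)

MODEL_IDS = ("zero_order", "first_order", "higuchi", "weibull")
# Tie-break preference: simpler/mechanistic first when r² ties within _R2_TIE.
_SELECTION_ORDER = ("zero_order", "higuchi", "first_order", "weibull")
_R2_TIE = 1e-6

_LN10 = math.log(10.0)


def predict_release_percent(model_id: str, params: dict,
                            times_h: Sequence[float]) -> np.ndarray:
    """Forward evaluation of a kinetic law: released percent at each time."""
    t = np.asarray(times_h, dtype=float)
    if model_id == "zero_order":
        return params.get("Q0", 0.0) + params["K0"] * t
    if model_id == "first_order":
        return params["Q0"] * np.exp(-params["K"] * t)
    if model_id == "higuchi":
        return params.get("c", 0.0) + params["KH"] * np.sqrt(t)
    if model_id == "weibull":
        return 100.0 * (1.0 - np.exp(-params["alpha"] * t ** params["beta"]))
    raise InvalidConfigError(f"unknown model {model_id!r}; want one of {MODEL_IDS}")


class TransformedSeries(NamedTuple):
    """Linearized coordinates plus how many points the transform dropped."""

    x: np.ndarray
    y: np.ndarray
    n_dropped: int


@dataclass
class KineticFit:
    """One linearized model fit.

    ``slope``/``intercept`` live on the transformed scale; ``params`` holds
    the back-transformed model parameters (K0 and Q0; K; K_H and c; α and β).
    """

    model_id: str
    slope: float
    intercept: float
    params: dict
    r2: float
    n_points: int
    n_dropped: int = 0
    convention: str = "literal"

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise AnalysisError(f"r2 {self.r2} outside [0, 1]")
        if self.n_points < 3:
            raise AnalysisError("a fit needs >= 3 points")

    def predict(self, times_h: Sequence[float]) -> np.ndarray:
        """Released percent the fitted model predicts at the given times."""
        if self.model_id == "first_order" and self.convention == "remaining":
            t = np.asarray(times_h, dtype=float)
            return 100.0 - self.params["remaining0"] * np.exp(-self.params["K"] * t)
        return predict_release_percent(self.model_id, self.params, times_h)


@dataclass(frozen=True)
class RateSummary:
    """Higuchi-derived release rate and extrapolated depletion time."""

    higuchi_rate: float  # release% per sqrt-hour
    t_complete_h: float  # hours to 100% release


def transform_profile(
    profile: ReleaseProfile,
    model_id: str,
    convention: str = "literal",
) -> TransformedSeries:
    """Map a release profile onto a model's linearized coordinates.

    Points whose transformed value is undefined (release% ≤ 0 for the
    logarithmic transforms, additionally ≥ 100 for Weibull) are dropped and
    counted. Fewer than 3 usable points raise
    :class:`InsufficientDataError`.
    """
    t = profile.times_h
    q = profile.release_percent
    if model_id == "zero_order":
        x, y, keep = t, q, np.ones_like(t, dtype=bool)
    elif model_id == "first_order":
        if convention == "remaining":
            rem = 100.0 - q
            keep = rem > 0
            x, y = t, np.log10(np.where(keep, rem, 1.0))
        else:
            keep = q > 0
            x, y = t, np.log10(np.where(keep, q, 1.0))
    elif model_id == "higuchi":
        x, y, keep = np.sqrt(t), q, np.ones_like(t, dtype=bool)
    elif model_id == "weibull":
        keep = (q > 0) & (q < 100.0)
        safe = np.where(keep, q, 50.0)
        x = np.log10(t)
        y = np.log10(-np.log1p(-safe / 100.0))
    else:
        raise InvalidConfigError(f"unknown model {model_id!r}; want one of {MODEL_IDS}")

    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s transform dropped %d point(s)", model_id, n_dropped)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise InsufficientDataError(
            f"{model_id}: only {x.size} usable points after transform (need >= 3)"
        )
    return TransformedSeries(x, y, n_dropped)


def _back_transform(model_id: str, slope: float, intercept: float,
                    convention: str) -> dict:
    if model_id == "zero_order":
        return {"K0": slope, "Q0": intercept}
    if model_id == "first_order":
        if convention == "remaining":
            return {"K": -slope * _LN10, "remaining0": 10.0**intercept}
        return {"K": -slope * _LN10, "Q0": 10.0**intercept}
    if model_id == "higuchi":
        return {"KH": slope, "c": intercept}
    # weibull: log10(-ln(1 - Q/100)) = log10(alpha) + beta*log10(t)
    return {"alpha": 10.0**intercept, "beta": slope}


def fit_model(
    profile: ReleaseProfile,
    model_id: str,
    convention: str = "literal",
    higuchi_intercept: str = "free",
) -> KineticFit:
    """Ordinary least squares on the model's linearized coordinates.

    The intercept is included for every model; for Higuchi it can be pinned
    to zero with ``higuchi_intercept="zero"`` (the textbook Q = K_H·√t
    form). r² is the squared Pearson correlation of the transformed pairs
    regardless of the intercept treatment.
    """
    ts = transform_profile(profile, model_id, convention)
    x, y = ts.x, ts.y
    if np.ptp(x) == 0:
        raise DegenerateFitError(f"{model_id}: zero variance in x")
    res = stats.linregress(x, y)
    slope, intercept, r2 = res.slope, res.intercept, res.rvalue**2
    if model_id == "higuchi" and higuchi_intercept == "zero":
        slope = float(np.dot(x, y) / np.dot(x, x))  # OLS through the origin
        intercept = 0.0
    return KineticFit(
        model_id=model_id,
        slope=float(slope),
        intercept=float(intercept),
        params=_back_transform(model_id, float(slope), float(intercept), convention),
        r2=float(r2),
        n_points=int(x.size),
        n_dropped=ts.n_dropped,
        convention=convention,
    )


def fit_all_and_select(
    profile: ReleaseProfile,
    models: Sequence[str] = MODEL_IDS,
    convention: str = "literal",
    higuchi_intercept: str = "free",
) -> tuple[list[KineticFit], str]:
    """Fit every requested model and pick the best by r².

    Models whose transform fails (too few usable points, degenerate design)
    are skipped with a logged reason. r² ties within 1e-6 go to the simpler
    model (zero-order and Higuchi before Weibull).
    """
    fits: list[KineticFit] = []
    for mid in models:
        try:
            fits.append(fit_model(profile, mid, convention, higuchi_intercept))
        except (InsufficientDataError, DegenerateFitError) as exc:
            logger.warning("skipping %s: %s", mid, exc)
    if not fits:
        raise AnalysisError("no kinetic model could be fitted to this profile")
    best_r2 = max(f.r2 for f in fits)
    contenders = {f.model_id for f in fits if best_r2 - f.r2 <= _R2_TIE}
    best = next(m for m in _SELECTION_ORDER if m in contenders)
    return fits, best


def rate_summary(higuchi_fit: KineticFit) -> RateSummary:
    """Release rate and extrapolated 100%-release time from a Higuchi fit.

    The rate is the Higuchi constant K_H itself; the depletion time solves
    c + K_H·√t = 100, i.e. t = ((100 − c)/K_H)².
    """
    if higuchi_fit.model_id != "higuchi":
        raise InvalidConfigError("rate_summary needs a higuchi fit")
    kh = higuchi_fit.params["KH"]
    c = higuchi_fit.params.get("c", 0.0)
    if kh <= 0:
        raise NoReleaseError(f"Higuchi slope {kh:.4g} <= 0: no release to extrapolate")
    if c >= 100.0:
        raise NoReleaseError("fitted intercept >= 100%: already depleted at t=0")
    return RateSummary(higuchi_rate=kh, t_complete_h=((100.0 - c) / kh) ** 2)
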