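"""Internal-standard qNMR mass calculation and label-accuracy statistics.

The core relation converts the analyte/calibrant integral ratio into an
absolute analyte mass:

    m_analyte = (I_analyte / I_cal) · (N_cal / N_analyte)
                · (m_cal / MW_cal) · MW_analyte · (p_cal / p_analyte)

where N are the proton counts behind each integrated resonance, m_cal the
weighed-in calibrant mass (mg), MW molecular weights (g/mol) and p mass
purities. For cannabidiol quantified against naphthalene: N_cal/N_analyte
= 4/1, MW 314.47 vs 128.17 g/mol, both purities 0.99.

Whole-patch contents follow from disc measurements by areal scaling, and
label accuracy is judged with the signed symmetric percent difference
against a ±10% margin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import mean, stdev
from typing import Sequence

from .errors import DegenerateInputError, InputError, InvalidConfigError
from .integration import (
    IntegrationWindow,
    default_analyte_window,
    default_calibrant_window,
)

# Reference constants for the cannabidiol / naphthalene assay.
MW_CBD_G_PER_MOL = 314.47
MW_NAPHTHALENE_G_PER_MOL = 128.17
DEFAULT_PURITY = 0.99
#: Proton counts behind the quantified resonances (olefinic H vs 4 aromatic H).
N_CBD = 1
N_NAPHTHALENE = 4

#: Labeling margin: a ±10% variance is the accepted industry threshold.
DEFAULT_MARGIN_PERCENT = 10.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One chemical species in the assay: identity plus its quantified peak."""

    name: str
    mw_g_per_mol: float
    purity: float
    nuclei_count: int
    window: IntegrationWindow

    def __post_init__(self) -> None:
        if self.mw_g_per_mol <= 0:
            raise InvalidConfigError("molecular weight must be > 0")
        if not 0 < self.purity <= 1:
            raise InvalidConfigError("purity must be in (0, 1]")
        if self.nuclei_count < 1:
            raise InvalidConfigError("nuclei_count must be >= 1")


@dataclass(frozen=True)
class QuantAssay:
    """Analyte + calibrant descriptors and the weighed calibrant mass (mg)."""

    analyte: SpeciesSpec
    calibrant: SpeciesSpec
    calibrant_mass_mg: float

    def __post_init__(self) -> None:
        if self.calibrant_mass_mg <= 0:
            raise InvalidConfigError("calibrant_mass_mg must be > 0")

    @property
    def response_factor(self) -> float:
        """mg of analyte per unit integral ratio."""
        return (
            (self.calibrant.nuclei_count / self.analyte.nuclei_count)
            * (self.calibrant_mass_mg / self.calibrant.mw_g_per_mol)
            * self.analyte.mw_g_per_mol
            * (self.calibrant.purity / self.analyte.purity)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "QuantAssay":
        def species(sd: dict, default_window: IntegrationWindow) -> SpeciesSpec:
            win = default_window
            if "window" in sd:
                w = sd["window"]
                win = IntegrationWindow(
                    float(w["low_ppm"]), float(w["high_ppm"]),
                    w.get("baseline_mode", "linear_endpoints"),
                )
            return SpeciesSpec(
                name=str(sd["name"]),
                mw_g_per_mol=float(sd["mw_g_per_mol"]),
                purity=float(sd.get("purity", DEFAULT_PURITY)),
                nuclei_count=int(sd["nuclei_count"]),
                window=win,
            )

        return cls(
            analyte=species(d["analyte"], default_analyte_window()),
            calibrant=species(d["calibrant"], default_calibrant_window()),
            calibrant_mass_mg=float(d["calibrant_mass_mg"]),
        )


@dataclass(frozen=True)
class QuantResult:
    """Outcome of one quantification: mass, the ratio used, the assay."""

    mass_mg: float
    ratio: float
    assay: QuantAssay


@dataclass(frozen=True)
class PatchSpec:
    """Descriptor of one commercial patch under test."""

    brand: str
    labeled_mg: float
    patch_area_cm2: float
    sample_diameter_mm: float = 10.0
    adhesive_thickness_um: float | None = None

    def __post_init__(self) -> None:
        if self.patch_area_cm2 <= 0 or self.sample_diameter_mm <= 0:
            raise InvalidConfigError("areas and diameters must be > 0")
        if self.labeled_mg < 0:
            raise InvalidConfigError("labeled_mg must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PatchSpec":
        return cls(
            brand=str(d["brand"]),
            labeled_mg=float(d["labeled_mg"]),
            patch_area_cm2=float(d["patch_area_cm2"]),
            sample_diameter_mm=float(d.get("sample_diameter_mm", 10.0)),
            adhesive_thickness_um=(
                float(d["adhesive_thickness_um"])
                if d.get("adhesive_thickness_um") is not None else None
            ),
        )


def default_assay(calibrant_mass_mg: float = 10.0) -> QuantAssay:
    """The cannabidiol/naphthalene assay; 10 mg calibrant (whole-patch vial)."""
    return QuantAssay(
        analyte=SpeciesSpec("cannabidiol", MW_CBD_G_PER_MOL, DEFAULT_PURITY,
                            N_CBD, default_analyte_window()),
        calibrant=SpeciesSpec("naphthalene", MW_NAPHTHALENE_G_PER_MOL,
                              DEFAULT_PURITY, N_NAPHTHALENE,
                              default_calibrant_window()),
        calibrant_mass_mg=calibrant_mass_mg,
    )


def default_franz_assay() -> QuantAssay:
    """The Franz-disc variant: 1 mg naphthalene per 1 ml CDCl₃ vial."""
    return default_assay(calibrant_mass_mg=1.0)


def quantify_mass(ratio: float, assay: QuantAssay) -> float:
    """Analyte mass (mg) from an integral ratio via the internal standard.

    Linear in both the ratio and the calibrant mass. Negative ratios signal
    a degenerate spectrum and are rejected.
    """
    if ratio < 0:
        raise DegenerateInputError(f"integral ratio {ratio:.4g} < 0")
    return ratio * assay.response_factor


def ratio_for_mass(mass_mg: float, assay: QuantAssay) -> float:
    """Inverse of :func:`quantify_mass`: the ratio a given mass produces."""
    if mass_mg < 0:
        raise DegenerateInputError(f"mass {mass_mg:.4g} < 0")
    return mass_mg / assay.response_factor


def scale_to_patch(mass_sample_mg: float, sample_diameter_mm: float,
                   patch_area_cm2: float) -> float:
    """Extrapolate a punched-disc mass to the whole patch by area ratio.

    Assumes uniform areal drug loading across the patch. A patch smaller
    than the disc is allowed (partial patches) — scaling simply shrinks.
    """
    if min(mass_sample_mg, sample_diameter_mm, patch_area_cm2) <= 0:
        raise InputError("all scale_to_patch inputs must be > 0")
    disc_area_cm2 = math.pi * (sample_diameter_mm / 20.0) ** 2
    return mass_sample_mg * patch_area_cm2 / disc_area_cm2


def disc_area_cm2(diameter_mm: float = 10.0) -> float:
    """Area of the punched Franz-cell disc in cm² (10 mm → 0.785 cm²)."""
    return math.pi * (diameter_mm / 20.0) ** 2


def recovery_percent(calculated_mg: float, known_mg: float) -> float:
    """Assay-validation recovery: 100 · measured / true."""
    if known_mg <= 0:
        raise DegenerateInputError("known mass must be > 0")
    return 100.0 * calculated_mg / known_mg


def summarize_recovery(recoveries: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample standard deviation (n−1) of recoveries."""
    if len(recoveries) < 2:
        raise DegenerateInputError("need at least 2 recovery values")
    return mean(recoveries), stdev(recoveries)


def percent_difference(determined_mg: float, labeled_mg: float) -> float:
    """Signed symmetric percent difference between determined and labeled mass.

    100 · (determined − labeled) / ((determined + labeled)/2). Positive means
    the patch contains more than stated. Antisymmetric under argument swap.
    """
    if determined_mg + labeled_mg <= 0:
        raise DegenerateInputError("determined + labeled must be > 0")
    return 100.0 * (determined_mg - labeled_mg) / ((determined_mg + labeled_mg) / 2.0)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (tabulation rule)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


LABEL_CORRECT = "correct"
LABEL_UNDER = "under_labeled"
LABEL_OVER = "over_labeled"


def classify_label(diff_percent: float,
                   margin_percent: float = DEFAULT_MARGIN_PERCENT) -> str:
    """Judge label accuracy from the signed percent difference.

    |diff| ≤ margin (inclusive) is ``correct``; a positive excess means the
    patch holds more than stated (``under_labeled``), a negative one less
    (``over_labeled``).
    """
    if margin_percent <= 0:
        raise InvalidConfigError("margin must be > 0")
    if abs(diff_percent) <= margin_percent:
        return LABEL_CORRECT
    return LABEL_UNDER if diff_percent > 0 else LABEL_OVER
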