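"""End-to-end orchestration: spectra → contents → release → kinetics → report.

One run takes an assay description plus, per patch, either raw qNMR spectra
(a t = 0 determination and timed Franz-cell spectra), a precomputed release
table, or just a determined content — and produces three table-shaped
outputs: a content/labeling table, per-patch release profiles, and a
kinetic-fit table with the selected model, Higuchi release rate, and the
extrapolated depletion time.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import AnalysisError, InputError, InvalidConfigError, NoReleaseError
from .integration import integral_ratio
from .kinetics import MODEL_IDS, KineticFit, RateSummary, fit_all_and_select, rate_summary
from .quantification import (
    DEFAULT_MARGIN_PERCENT,
    PatchSpec,
    QuantAssay,
    classify_label,
    default_franz_assay,
    percent_difference,
    quantify_mass,
    round_half_away,
    scale_to_patch,
)
from .release import (
    ReleaseObservation,
    ReleaseProfile,
    build_release_profile,
    read_release_table,
)
from .spectra import Spectrum

logger = logging.getLogger(__name__)


@dataclass
class PatchInput:
    """Everything known about one patch before analysis.

    Exactly one content route must be supplied: timed ``spectra`` (metadata
    key ``time_h``, with 0 marking the pre-Franz determination), a
    precomputed ``observations`` release table with its ``m0_mg``, or a
    bare ``content_mg`` (labeling check only).
    """

    patch: PatchSpec
    spectra: list[Spectrum] | None = None
    observations: list[ReleaseObservation] | None = None
    m0_mg: float | None = None
    content_mg: float | None = None


@dataclass
class RunConfig:
    """Run-level settings; all randomness downstream flows from ``seed``."""

    assay: QuantAssay = field(default_factory=default_franz_assay)
    margin_percent: float = DEFAULT_MARGIN_PERCENT
    seed: int = 0
    output_dir: str = "franzq_out"

    def __post_init__(self) -> None:
        if self.margin_percent <= 0:
            raise InvalidConfigError("margin_percent must be > 0")


@dataclass
class PatchResult:
    """Per-patch analysis outcome (content row + release + kinetics)."""

    brand: str
    determined_mg: float
    labeled_mg: float
    diff_percent: float
    diff_tabulated: int
    classification: str
    profile: ReleaseProfile | None = None
    fits: list[KineticFit] = field(default_factory=list)
    best_model: str | None = None
    rate: RateSummary | None = None
    warnings: list = field(default_factory=list)


@dataclass
class ReportBundle:
    """Full run output: per-patch results plus labeling summary counts."""

    results: list[PatchResult]
    margin_percent: float
    seed: int
    warnings: list = field(default_factory=list)

    @property
    def label_counts(self) -> dict:
        counts = {"correct": 0, "under_labeled": 0, "over_labeled": 0}
        for r in self.results:
            counts[r.classification] += 1
        return counts

    def content_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "brand": [r.brand for r in self.results],
                "determined_mg": [r.determined_mg for r in self.results],
                "labeled_mg": [r.labeled_mg for r in self.results],
                "diff_percent": [r.diff_percent for r in self.results],
                "diff_tabulated": [r.diff_tabulated for r in self.results],
                "classification": [r.classification for r in self.results],
            }
        )

    def kinetics_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row: dict = {"brand": r.brand, "best_model": r.best_model}
            for f in r.fits:
                row[f"r2_{f.model_id}"] = f.r2
            if r.rate is not None:
                row["higuchi_rate"] = r.rate.higuchi_rate
                row["t_complete_h"] = r.rate.t_complete_h
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def fit_d(f: KineticFit) -> dict:
            return {
                "model_id": f.model_id, "slope": f.slope, "intercept": f.intercept,
                "params": f.params, "r2": f.r2, "n_points": f.n_points,
                "n_dropped": f.n_dropped, "convention": f.convention,
            }

        def result_d(r: PatchResult) -> dict:
            d = {
                "brand": r.brand,
                "determined_mg": r.determined_mg,
                "labeled_mg": r.labeled_mg,
                "diff_percent": r.diff_percent,
                "diff_tabulated": r.diff_tabulated,
                "classification": r.classification,
                "fits": [fit_d(f) for f in r.fits],
                "best_model": r.best_model,
                "rate": (
                    {"higuchi_rate": r.rate.higuchi_rate,
                     "t_complete_h": r.rate.t_complete_h}
                    if r.rate else None
                ),
                "warnings": list(r.warnings),
            }
            if r.profile is not None:
                d["profile"] = {
                    "m0_mg": r.profile.m0_mg,
                    "disc_diameter_mm": r.profile.disc_diameter_mm,
                    "series": r.profile.to_frame().to_dict(orient="list"),
                    "flags": list(r.profile.flags),
                }
            return d

        return {
            "version": __version__,
            "seed": self.seed,
            "margin_percent": self.margin_percent,
            "label_counts": self.label_counts,
            "warnings": list(self.warnings),
            "results": [result_d(r) for r in self.results],
        }


def analyze_patch(
    inp: PatchInput,
    assay: QuantAssay,
    margin_percent: float = DEFAULT_MARGIN_PERCENT,
    models=MODEL_IDS,
    higuchi_intercept: str = "free",
) -> PatchResult:
    """Run the full chain for one patch: content, labeling, release, kinetics."""
    patch = inp.patch
    warnings: list[str] = []
    profile: ReleaseProfile | None = None
    m0 = inp.m0_mg
    observations = list(inp.observations) if inp.observations else None

    if inp.spectra is not None:
        zero, timed = [], []
        for spec in inp.spectra:
            t = float(spec.meta.get("time_h", -1.0))
            (zero if t == 0.0 else timed).append((t, spec))
        if not zero:
            raise InvalidConfigError(
                f"patch {patch.brand!r}: no t=0 spectrum for the content determination"
            )
        disc_masses = [
            quantify_mass(
                integral_ratio(s, assay.analyte.window, assay.calibrant.window), assay
            )
            for _, s in zero
        ]
        m0 = float(np.mean(disc_masses))
        observations = observations or []
        for t, s in timed:
            if t < 0:
                raise InputError(
                    f"patch {patch.brand!r}: spectrum without time_h metadata"
                )
            ratio = integral_ratio(s, assay.analyte.window, assay.calibrant.window)
            observations.append(
                ReleaseObservation(t, quantify_mass(ratio, assay),
                                   replicate=str(s.meta.get("sample_id", ""))))

    if inp.content_mg is not None:
        determined = inp.content_mg
    elif m0 is not None:
        determined = scale_to_patch(m0, patch.sample_diameter_mm, patch.patch_area_cm2)
    else:
        raise InvalidConfigError(
            f"patch {patch.brand!r}: need spectra, a release table with m0, "
            "or a precomputed content"
        )

    diff = percent_difference(determined, patch.labeled_mg)
    result = PatchResult(
        brand=patch.brand,
        determined_mg=determined,
        labeled_mg=patch.labeled_mg,
        diff_percent=diff,
        diff_tabulated=round_half_away(diff),
        classification=classify_label(diff, margin_percent),
    )

    if observations and m0 is not None and len({o.time_h for o in observations}) >= 2:
        profile = build_release_profile(m0, observations, patch,
                                        patch.sample_diameter_mm)
        result.profile = profile
        warnings.extend(profile.flags)
        try:
            fits, best = fit_all_and_select(profile, models=models,
                                            higuchi_intercept=higuchi_intercept)
            result.fits, result.best_model = fits, best
            hig = next((f for f in fits if f.model_id == "higuchi"), None)
            if hig is not None:
                try:
                    result.rate = rate_summary(hig)
                except NoReleaseError as exc:
                    warnings.append(str(exc))
        except AnalysisError as exc:
            warnings.append(f"kinetics failed: {exc}")
    result.warnings = warnings
    return result


def run_pipeline(config: RunConfig, patch_inputs: list[PatchInput]) -> ReportBundle:
    """Analyze every patch and assemble the report bundle.

    An empty patch list yields an empty report with a warning (success).
    Deterministic given the inputs and ``config.seed``.
    """
    bundle = ReportBundle(results=[], margin_percent=config.margin_percent,
                          seed=config.seed)
    if not patch_inputs:
        bundle.warnings.append("no patches configured: empty report")
        logger.warning("no patches configured: empty report")
        return bundle
    for inp in patch_inputs:
        logger.info("analyzing patch %s", inp.patch.brand)
        bundle.results.append(
            analyze_patch(inp, config.assay, config.margin_percent)
        )
    return bundle


def generate_report(bundle: ReportBundle, output_dir: str | Path) -> Path:
    """Write the machine-readable report: CSV per table shape + JSON manifest.

    Re-running on identical inputs is byte-identical (no timestamps are
    written). Returns the output directory path.
    """
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        bundle.content_table().to_csv(out / "content_table.csv", index=False)
        kin = bundle.kinetics_table()
        if not kin.empty:
            kin.to_csv(out / "kinetics_table.csv", index=False)
        for r in bundle.results:
            if r.profile is not None:
                r.profile.to_frame().to_csv(
                    out / f"release_{_slug(r.brand)}.csv", index=False
                )
        (out / "manifest.json").write_text(
            json.dumps(bundle.to_dict(), indent=1, sort_keys=True) + "\n"
        )
        (out / "summary.txt").write_text(_summary_text(bundle))
    except OSError as exc:
        raise InputError(f"cannot write report to {out}: {exc}") from exc
    return out


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in name).strip("_").lower()


def _summary_text(bundle: ReportBundle) -> str:
    lines = [f"franzq report (seed {bundle.seed}, margin ±{bundle.margin_percent}%)", ""]
    for w in bundle.warnings:
        lines.append(f"WARNING: {w}")
    counts = bundle.label_counts
    lines.append(
        f"patches: {len(bundle.results)} "
        f"({counts['correct']} correct, {counts['under_labeled']} under-labeled, "
        f"{counts['over_labeled']} over-labeled)"
    )
    for r in bundle.results:
        lines.append(
            f"  {r.brand}: determined {r.determined_mg:.1f} mg vs labeled "
            f"{r.labeled_mg:.1f} mg -> {r.diff_tabulated:+d}% ({r.classification})"
        )
        if r.best_model:
            lines.append(f"    best kinetic model: {r.best_model}")
        if r.rate:
            lines.append(
                f"    Higuchi rate {r.rate.higuchi_rate:.1f} %/h^0.5, "
                f"100% release extrapolated at {r.rate.t_complete_h:.0f} h"
            )
        for w in r.warnings:
            lines.append(f"    note: {w}")
    return "\n".join(lines) + "\n"


def load_run_inputs(config_path: str | Path) -> tuple[RunConfig, list[PatchInput]]:
    """Parse a run-config JSON and resolve its file references.

    Schema: ``{"assay": {...}, "margin_percent": 10, "seed": 0,
    "output_dir": "...", "patches": [{"brand": ..., "labeled_mg": ...,
    "patch_area_cm2": ..., and one of "content_mg" | "release_table" (+
    "m0_mg") | "spectra": [{"path": ..., "time_h": ...}]}]}``. Relative
    paths resolve against the config file's directory.
    """
    from .spectra import read_spectrum  # local: keeps module import light

    path = Path(config_path)
    try:
        raw = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read run config {path}: {exc}") from exc
    base = path.parent
    assay = (QuantAssay.from_dict(raw["assay"]) if "assay" in raw
             else default_franz_assay())
    config = RunConfig(
        assay=assay,
        margin_percent=float(raw.get("margin_percent", DEFAULT_MARGIN_PERCENT)),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "franzq_out")),
    )
    inputs: list[PatchInput] = []
    for pd_raw in raw.get("patches", []):
        patch = PatchSpec.from_dict(pd_raw)
        inp = PatchInput(patch=patch)
        if "content_mg" in pd_raw:
            inp.content_mg = float(pd_raw["content_mg"])
        if "m0_mg" in pd_raw:
            inp.m0_mg = float(pd_raw["m0_mg"])
        if "release_table" in pd_raw:
            table_path = base / pd_raw["release_table"]
            if not table_path.exists():
                raise InputError(f"release table {table_path} does not exist")
            inp.observations = read_release_table(table_path)
        if "spectra" in pd_raw:
            specs = []
            for s in pd_raw["spectra"]:
                spath = base / s["path"]
                if not spath.exists():
                    raise InputError(f"spectrum file {spath} does not exist")
                with open(spath) as fh:
                    spec = read_spectrum(fh)
                spec.meta["time_h"] = float(s["time_h"])
                spec.meta.setdefault("sample_id", spath.stem)
                specs.append(spec)
            inp.spectra = specs
        inputs.append(inp)
    return config, inputs
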