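"""Experimental design presets and condition comparison.

The preset table encodes the published experimental conditions for
bacteriorhodopsin reconstituted into POPC, POPG and DOPC vesicles — lipid
baselines plus ionic-strength, pH and vesicle-size variations — together
with the reported mean protected fraction for each. These reported means
serve as generating truths for simulation; :func:`compare_conditions` builds
the pairwise single-factor contrasts with pooled errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import math

import pandas as pd

from .inference import OrientationCall, ReplicateSummary, classify_orientation
from .models import Condition

__all__ = [
    "Preset",
    "ConditionResult",
    "Contrast",
    "StudyReport",
    "reference_presets",
    "get_preset",
    "single_run_fractions",
    "compare_conditions",
    "report_frames",
    "format_report",
]

#: Baseline buffer / vesicle settings shared by the lipid-comparison runs.
BASELINE_IONIC_MM = 10.0
BASELINE_PH = 7.0
BASELINE_DIAMETER_NM = 100.0


@dataclass(frozen=True)
class Preset:
    """One published condition with its reported protected fraction.

    ``x_true``/``x_err`` are the reported mean and error; ``available`` is
    False for conditions that were announced but whose value was never
    tabulated (their ``x_true`` is None).
    """

    condition: Condition
    group: str  # baseline | ionic_strength | ph | size
    x_true: Optional[float]
    x_err: Optional[float]
    available: bool = True


def _c(lipid: str, ionic=BASELINE_IONIC_MM, ph=BASELINE_PH, d=BASELINE_DIAMETER_NM):
    return Condition(lipid=lipid, ionic_strength=ionic, ph=ph, vesicle_diameter=d)


_PRESETS: Tuple[Preset, ...] = (
    # replicate-averaged lipid baselines
    Preset(_c("POPC"), "baseline", 0.63, 0.02),
    Preset(_c("POPG"), "baseline", 0.40, 0.01),
    Preset(_c("DOPC"), "baseline", 0.53, 0.01),
    # ionic-strength series (250 mM announced but never tabulated)
    Preset(_c("POPC", ionic=10.0), "ionic_strength", 0.64, 0.01),
    Preset(_c("POPC", ionic=50.0), "ionic_strength", 0.66, 0.03),
    Preset(_c("POPC", ionic=250.0), "ionic_strength", None, None, available=False),
    Preset(_c("POPG", ionic=10.0), "ionic_strength", 0.41, 0.01),
    Preset(_c("POPG", ionic=50.0), "ionic_strength", 0.49, 0.01),
    Preset(_c("POPG", ionic=250.0), "ionic_strength", None, None, available=False),
    # pH series
    Preset(_c("POPC", ph=6.2), "ph", 0.64, 0.03),
    Preset(_c("POPC", ph=8.0), "ph", 0.57, 0.02),
    Preset(_c("POPG", ph=6.2), "ph", 0.48, 0.01),
    Preset(_c("POPG", ph=8.0), "ph", 0.44, 0.01),
    # vesicle-size series
    Preset(_c("POPC", d=50.0), "size", 0.64, 0.01),
    Preset(_c("POPC", d=100.0), "size", 0.64, 0.01),
    Preset(_c("POPG", d=50.0), "size", 0.43, 0.01),
    Preset(_c("POPG", d=100.0), "size", 0.40, 0.01),
    Preset(_c("DOPC", d=50.0), "size", 0.57, 0.01),
    Preset(_c("DOPC", d=100.0), "size", 0.53, 0.01),
)

#: Single-titration protected fractions for the three lipid baselines
#: (one experiment each, before replicate averaging).
_SINGLE_RUN_X = {"POPC": 0.64, "POPG": 0.41, "DOPC": 0.52}


def reference_presets(include_unavailable: bool = False) -> List[Preset]:
    """All built-in condition presets with their reported fractions."""
    return [p for p in _PRESETS if include_unavailable or p.available]


def single_run_fractions() -> dict:
    """Single-experiment baseline fractions keyed by lipid."""
    return dict(_SINGLE_RUN_X)


def get_preset(
    lipid: str,
    ionic_strength: Optional[float] = None,
    ph: Optional[float] = None,
    vesicle_diameter: Optional[float] = None,
) -> Preset:
    """Look up one preset by lipid and the single factor being varied.

    With no factor argument the replicate-averaged baseline row is returned.
    """
    n_given = sum(v is not None for v in (ionic_strength, ph, vesicle_diameter))
    if n_given > 1:
        raise ValueError("specify at most one of ionic_strength, ph, vesicle_diameter")
    if ionic_strength is not None:
        group, match = "ionic_strength", lambda c: c.ionic_strength == ionic_strength
    elif ph is not None:
        group, match = "ph", lambda c: c.ph == ph
    elif vesicle_diameter is not None:
        group, match = "size", lambda c: c.vesicle_diameter == vesicle_diameter
    else:
        group, match = "baseline", lambda c: True
    for p in _PRESETS:
        if p.group == group and p.condition.lipid == lipid and match(p.condition):
            return p
    raise KeyError(f"no preset for lipid={lipid!r}, group={group}")


@dataclass
class ConditionResult:
    """Replicate summary and orientation call for one condition."""

    condition: Condition
    summary: ReplicateSummary
    call: OrientationCall

    @classmethod
    def from_summary(cls, condition: Condition, summary: ReplicateSummary) -> "ConditionResult":
        return cls(condition=condition, summary=summary, call=classify_orientation(summary))


@dataclass(frozen=True)
class Contrast:
    """Difference in x between two conditions varying in a single factor."""

    label_a: str
    label_b: str
    factor: str
    delta_x: float
    pooled_err: float
    flagged: bool


@dataclass
class StudyReport:
    results: List[ConditionResult]
    contrasts: List[Contrast]


def _varied_factor(a: Condition, b: Condition) -> Optional[str]:
    """Name of the single differing factor, or None if 0 or >1 differ."""
    diffs = []
    if a.lipid != b.lipid:
        diffs.append("lipid")
    if a.ionic_strength != b.ionic_strength:
        diffs.append("ionic_strength")
    if a.ph != b.ph:
        diffs.append("ph")
    if a.vesicle_diameter != b.vesicle_diameter:
        diffs.append("size")
    return diffs[0] if len(diffs) == 1 else None


def compare_conditions(results: Sequence[ConditionResult]) -> StudyReport:
    """Pairwise single-factor contrasts with pooled standard errors.

    Each pair of results whose conditions differ in exactly one factor
    (lipid, ionic strength, pH, vesicle size) contributes a contrast
    ``delta_x = x_A - x_B`` with pooled error ``sqrt(errA^2 + errB^2)``;
    contrasts with ``|delta_x|`` above twice the pooled error are flagged.
    """
    if len(results) < 2:
        raise ValueError("need at least two condition results to compare")
    contrasts: List[Contrast] = []
    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            ra, rb = results[i], results[j]
            factor = _varied_factor(ra.condition, rb.condition)
            if factor is None:
                continue
            delta = ra.summary.x_mean - rb.summary.x_mean
            pooled = math.sqrt(ra.summary.x_err**2 + rb.summary.x_err**2)
            contrasts.append(
                Contrast(
                    label_a=ra.condition.label(),
                    label_b=rb.condition.label(),
                    factor=factor,
                    delta_x=delta,
                    pooled_err=pooled,
                    flagged=abs(delta) > 2.0 * pooled,
                )
            )
    return StudyReport(results=list(results), contrasts=contrasts)


def report_frames(report: StudyReport) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(conditions, contrasts) as data frames for CSV export."""
    cond_rows = [
        {
            "condition": r.condition.label(),
            "lipid": r.condition.lipid,
            "ionic_strength_mM": r.condition.ionic_strength,
            "ph": r.condition.ph,
            "vesicle_diameter_nm": r.condition.vesicle_diameter,
            "x_mean": r.summary.x_mean,
            "x_err": r.summary.x_err,
            "n_replicates": r.summary.n_replicates,
            "call": r.call.label,
            "margin": r.call.margin,
        }
        for r in report.results
    ]
    con_rows = [
        {
            "condition_a": c.label_a,
            "condition_b": c.label_b,
            "factor": c.factor,
            "delta_x": c.delta_x,
            "pooled_err": c.pooled_err,
            "flagged": c.flagged,
        }
        for c in report.contrasts
    ]
    return pd.DataFrame(cond_rows), pd.DataFrame(con_rows)


def format_report(report: StudyReport) -> str:
    """Human-readable study summary."""
    lines = ["Condition results", "-----------------"]
    for r in report.results:
        lines.append(
            f"{r.condition.label():<32} x = {r.summary.x_mean:.3f} "
            f"+/- {r.summary.x_err:.3f} (n={r.summary.n_replicates})  -> {r.call.label}"
        )
    lines += ["", "Contrasts (single-factor)", "-------------------------"]
    for c in report.contrasts:
        mark = " *" if c.flagged else ""
        lines.append(
            f"{c.label_a} vs {c.label_b} [{c.factor}]: "
            f"dx = {c.delta_x:+.3f} +/- {c.pooled_err:.3f}{mark}"
        )
    if report.contrasts:
        lines += ["", "* |dx| exceeds twice the pooled error"]
    return "\n".join(lines)
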