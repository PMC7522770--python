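"""Well-level aggregation, vehicle-control normalization, 4PL fitting, CV%.

Cells are pooled across all fields of a well; wells are the replicate unit.
The response used for the IC50 is the percentage of healthy cells by
default (with the normalized healthy count as an alternative). The curve is
the four-parameter logistic on log10 concentration

    r(c) = bottom + (top - bottom) / (1 + (c / ic50)^hill)

fit by least squares with multi-start initialization; vehicle wells
(concentration 0, undefined on the log scale) are excluded from the fit but
reported alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .features import CLASS_LABELS, CellRecord
from .io import PlateMap, PlateMapRow


class NormalizationError(RuntimeError):
    pass


@dataclass
class WellSummary:
    """Per-well class counts, fractions and normalized healthy count."""

    well: str
    compound_id: str
    concentration_um: float
    role: str = "sample"
    replicate: int = 1
    counts: dict[str, int] = field(default_factory=dict)
    total_classified: int = 0
    fractions: dict[str, float] = field(default_factory=dict)
    healthy_count_normalized: float = math.nan
    percent_healthy: float = math.nan

    def validate(self) -> None:
        assert all(v >= 0 for v in self.counts.values())
        assert sum(self.counts.values()) == self.total_classified
        if self.total_classified > 0:
            assert abs(sum(self.fractions.values()) - 1.0) <= 1e-9
            assert 0.0 <= self.percent_healthy <= 100.0


@dataclass
class DoseResponseFit:
    """4PL parameters and IC50 for one compound."""

    compound_id: str
    bottom: float = math.nan
    top: float = math.nan
    hill_slope: float = math.nan
    ic50_um: float = math.nan
    rss: float = math.nan
    n_points: int = 0
    converged: bool = False


def summarize_well(cells: Sequence[CellRecord], plate_map_row: PlateMapRow) -> WellSummary:
    """Count classes for one well (cells pooled across its fields).

    All cells must already carry a class label and belong to the row's
    well. An empty well has total 0 and undefined (NaN) fractions.
    """
    counts = {c: 0 for c in CLASS_LABELS}
    for rec in cells:
        if rec.well != plate_map_row.well:
            raise ValueError(f"cell from well {rec.well} passed to summary of {plate_map_row.well}")
        if rec.class_label is None:
            raise ValueError("unlabeled cell: classification must precede summarization")
        counts[rec.class_label] += 1
    total = sum(counts.values())
    if total > 0:
        fractions = {c: counts[c] / total for c in CLASS_LABELS}
        percent_healthy = 100.0 * fractions["healthy"]
    else:
        fractions = {c: math.nan for c in CLASS_LABELS}
        percent_healthy = math.nan
    return WellSummary(
        well=plate_map_row.well,
        compound_id=plate_map_row.compound_id,
        concentration_um=plate_map_row.concentration_um,
        role=plate_map_row.role,
        replicate=plate_map_row.replicate,
        counts=counts,
        total_classified=total,
        fractions=fractions,
        percent_healthy=percent_healthy,
    )


def normalize_to_control(
    summaries: Sequence[WellSummary], plate_map: PlateMap
) -> list[WellSummary]:
    """Divide each well's healthy count by the vehicle-control mean healthy count."""
    plate_map.require_vehicle_controls()
    vehicle = set(plate_map.vehicle_wells)
    control_counts = [
        s.counts.get("healthy", 0) for s in summaries if s.well in vehicle and s.total_classified > 0
    ]
    if not control_counts:
        raise NormalizationError("no vehicle_control well with classified cells")
    mean_control = float(np.mean(control_counts))
    if mean_control == 0:
        raise NormalizationError("vehicle-control mean healthy count is zero")
    for s in summaries:
        s.healthy_count_normalized = s.counts.get("healthy", 0) / mean_control
    return list(summaries)


def _fourpl(logc: np.ndarray, bottom: float, top: float, hill: float, logic50: float) -> np.ndarray:
    expo = np.clip(hill * (logc - logic50), -300.0, 300.0)
    return bottom + (top - bottom) / (1.0 + 10.0**expo)


def fit_4pl(
    concentrations_um: Sequence[float],
    responses: Sequence[float],
    compound_id: str = "",
    flat_sd_tol: float = 1e-12,
    fixed_top: float | None = None,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log10 concentration with multi-start.

    Requires >= 4 distinct positive concentrations. A flat response (sd
    below tolerance) yields ``converged=False`` and no IC50. The fit is
    equivariant under a consistent rescaling of the concentration unit.
    ``fixed_top`` anchors the top asymptote (e.g. to the vehicle-control
    mean) and fits the remaining three parameters.
    """
    conc = np.asarray(concentrations_um, dtype=np.float64)
    resp = np.asarray(responses, dtype=np.float64)
    if conc.shape != resp.shape:
        raise ValueError("concentrations and responses differ in length")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive (exclude vehicle wells)")
    if not np.all(np.isfinite(resp)):
        raise ValueError("responses must be finite")
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct positive concentrations")

    fit = DoseResponseFit(compound_id=compound_id, n_points=len(conc))
    if float(np.std(resp)) < max(flat_sd_tol, 1e-9 * max(abs(float(np.mean(resp))), 1.0)):
        return fit  # flat: not converged, no IC50

    logc = np.log10(conc)

    if fixed_top is None:
        def residuals(theta):
            bottom, top, hill, logic50 = theta
            return _fourpl(logc, bottom, top, hill, logic50) - resp
    else:
        def residuals(theta):
            bottom, hill, logic50 = theta
            return _fourpl(logc, bottom, fixed_top, hill, logic50) - resp

    lo, hi = float(resp.min()), float(resp.max())
    span = hi - lo
    starts = []
    for logic50 in np.linspace(logc.min() - 1, logc.max() + 1, 5):
        for hill in (0.5, 1.0, 2.0, -1.0):
            if fixed_top is None:
                starts.append((lo, hi, hill, logic50))
            else:
                starts.append((lo, hill, logic50))
    best = None
    for theta0 in starts:
        try:
            sol = least_squares(residuals, theta0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-18:
            best = sol
    if best is None:
        return fit

    if fixed_top is None:
        bottom, top, hill, logic50 = best.x
    else:
        bottom, hill, logic50 = best.x
        top = fixed_top
    if bottom > top:  # 4PL symmetry: swap asymptotes, flip the slope sign
        bottom, top, hill = top, bottom, -hill
    rss = float(2 * best.cost)
    ic50 = float(10.0**logic50)
    # honest convergence: finite, positive ic50 inside a generous window of
    # the tested range, and a non-degenerate span
    window = (10 ** (logc.min() - 3), 10 ** (logc.max() + 3))
    converged = bool(
        best.success
        and np.isfinite([bottom, top, hill, ic50]).all()
        and window[0] <= ic50 <= window[1]
        and (top - bottom) > 1e-3 * max(span, 1e-12)
    )
    fit.bottom, fit.top, fit.hill_slope = float(bottom), float(top), float(hill)
    fit.rss = rss
    fit.converged = converged
    fit.ic50_um = ic50 if converged else math.nan
    return fit


def fit_compound(
    summaries: Sequence[WellSummary],
    compound_id: str,
    response: str = "percent_healthy",
    anchor_top_to_vehicle: bool = False,
) -> DoseResponseFit:
    """Fit one compound's dose series from well summaries.

    ``response`` is ``percent_healthy`` (default) or
    ``healthy_count_normalized``. Vehicle wells are excluded from the fit;
    with ``anchor_top_to_vehicle`` their mean response fixes the top
    asymptote instead of leaving it free.
    """
    rows = [
        s
        for s in summaries
        if s.compound_id == compound_id and s.role == "sample" and s.concentration_um > 0
    ]
    conc = [s.concentration_um for s in rows]
    resp = [getattr(s, response) for s in rows]
    pairs = [(c, r) for c, r in zip(conc, resp) if not math.isnan(r)]
    if not pairs:
        raise ValueError(f"no usable wells for compound {compound_id!r}")
    fixed_top = None
    if anchor_top_to_vehicle:
        vehicle = [
            getattr(s, response)
            for s in summaries
            if s.role == "vehicle_control" and not math.isnan(getattr(s, response))
        ]
        if not vehicle:
            raise ValueError("anchor_top_to_vehicle requires vehicle-control wells")
        fixed_top = float(np.mean(vehicle))
    conc, resp = zip(*pairs)
    return fit_4pl(conc, resp, compound_id=compound_id, fixed_top=fixed_top)


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation between technical replicates, in percent.

    100 * sd / mean with the sample standard deviation (ddof=1). Requires
    n >= 2; a zero mean yields NaN.
    """
    vals = np.asarray(values, dtype=np.float64)
    if vals.size < 2:
        raise ValueError("replicate CV needs at least 2 values")
    mean = float(vals.mean())
    if mean == 0:
        return math.nan
    return 100.0 * float(vals.std(ddof=1)) / mean


def replicate_cv_table(
    summaries: Sequence[WellSummary], value: str = "healthy_count_normalized"
) -> pd.DataFrame:
    """CV% per (compound, concentration) replicate group with n >= 2."""
    rows = []
    groups: dict[tuple, list[float]] = {}
    for s in summaries:
        if s.role != "sample":
            continue
        groups.setdefault((s.compound_id, s.concentration_um), []).append(getattr(s, value))
    for (compound, conc), vals in sorted(groups.items()):
        if len(vals) >= 2:
            rows.append(
                {
                    "compound_id": compound,
                    "concentration_um": conc,
                    "n": len(vals),
                    "cv_percent": replicate_cv(vals),
                }
            )
    return pd.DataFrame(rows, columns=["compound_id", "concentration_um", "n", "cv_percent"])


# ---------------------------------------------------------------------------
# Tabular conversion
# ---------------------------------------------------------------------------

def summaries_to_frame(summaries: Sequence[WellSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "well": s.well,
            "compound_id": s.compound_id,
            "concentration_um": s.concentration_um,
            "role": s.role,
            "replicate": s.replicate,
            "total_classified": s.total_classified,
            "healthy_count_normalized": s.healthy_count_normalized,
            "percent_healthy": s.percent_healthy,
        }
        for c in CLASS_LABELS:
            row[f"count_{c}"] = s.counts.get(c, 0)
            row[f"fraction_{c}"] = s.fractions.get(c, math.nan)
        rows.append(row)
    cols = (
        ["well", "compound_id", "concentration_um", "role", "replicate", "total_classified"]
        + [f"count_{c}" for c in CLASS_LABELS]
        + [f"fraction_{c}" for c in CLASS_LABELS]
        + ["healthy_count_normalized", "percent_healthy"]
    )
    return pd.DataFrame(rows, columns=cols)


def frame_to_summaries(frame: pd.DataFrame) -> list[WellSummary]:
    out = []
    for row in frame.itertuples(index=False):
        d = row._asdict()
        counts = {c: int(d[f"count_{c}"]) for c in CLASS_LABELS}
        fractions = {c: float(d[f"fraction_{c}"]) for c in CLASS_LABELS}
        out.append(
            WellSummary(
                well=str(d["well"]),
                compound_id=str(d["compound_id"]),
                concentration_um=float(d["concentration_um"]),
                role=str(d["role"]),
                replicate=int(d["replicate"]),
                counts=counts,
                total_classified=int(d["total_classified"]),
                fractions=fractions,
                healthy_count_normalized=float(d["healthy_count_normalized"]),
                percent_healthy=float(d["percent_healthy"]),
            )
        )
    return out


def plot_dose_response(fit: DoseResponseFit, summaries: Sequence[WellSummary], path):
    """Save a dose-response plot (points + fitted curve) for one compound."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [
        s for s in summaries if s.compound_id == fit.compound_id and s.concentration_um > 0
    ]
    conc = np.array([s.concentration_um for s in rows])
    resp = np.array([s.percent_healthy for s in rows])
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.semilogx(conc, resp, "o", label="wells")
    if fit.converged:
        grid = np.logspace(np.log10(conc.min()) - 0.5, np.log10(conc.max()) + 0.5, 200)
        curve = _fourpl(np.log10(grid), fit.bottom, fit.top, fit.hill_slope, np.log10(fit.ic50_um))
        ax.semilogx(grid, curve, "-", label=f"4PL, IC50={fit.ic50_um:.3g} uM")
    ax.set_xlabel("concentration (uM)")
    ax.set_ylabel("% healthy cells")
    ax.set_title(fit.compound_id)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
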