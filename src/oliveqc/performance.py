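"""Method-performance procedures: linearity and repeatability.

Linearity is assessed per compound from the standard-mixture dilution
series: an ordinary least-squares calibration line is fitted over the widest
contiguous run of dilution levels that still responds linearly, and the run's
endpoints define the reported linear range.  Repeatability is the relative
standard deviation (RSD%) of the raw maximum dimer intensity of two marker
compounds per quality grade over 7 same-day replicates (intra-day) or 7
daily analyses (inter-day).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .chemometrics import rsd_percent
from .heatmap import HeatMap, extract_signal, normalize_rip
from .library import CompoundLibrary, SignalDef, default_compound_library
from .simulate import REPEATABILITY_MARKERS

__all__ = [
    "CalibrationResult",
    "RepeatabilityResult",
    "fit_calibration",
    "determine_linear_range",
    "linearity_study",
    "repeatability_study",
]

#: Minimum acceptable determination coefficient for a linear run (the lowest
#: value observed among the reference calibration fits).
DEFAULT_R2_MIN = 0.93
#: Maximum tolerated relative deviation of the next dilution level from the
#: prediction of the current line before the run is cut.
DEFAULT_REL_TOL = 0.05
MIN_RUN_LEVELS = 4
N_REPLICATES = 7


@dataclass
class CalibrationResult:
    """Fitted calibration line over the detected linear run."""

    compound: str
    slope: float
    intercept: float
    r2: float
    linear_range: tuple[float, float]
    points_used: int
    qualifying: bool = True
    diagnostics: str = ""

    def __post_init__(self) -> None:
        if self.qualifying and not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


@dataclass
class RepeatabilityResult:
    grade: str
    compound: str
    mode: str  # "intra" | "inter"
    n: int
    rsd_pct: float

    def __post_init__(self) -> None:
        if self.n != N_REPLICATES:
            raise ValueError(f"expected {N_REPLICATES} replicates/days, "
                             f"got {self.n}")
        if self.rsd_pct < 0:
            raise ValueError("RSD% must be >= 0")


def fit_calibration(concentrations: Sequence[float],
                    responses: Sequence[float],
                    ) -> tuple[float, float, float]:
    """Ordinary least-squares calibration line; returns (slope, intercept, R^2)."""
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired points")
    if np.unique(x).size < 2:
        raise ValueError("all concentrations equal; line undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sstot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sstot == 0 else 1.0 - float((resid**2).sum()) / sstot
    return float(slope), float(intercept), r2


def _extend_run(x: np.ndarray, y: np.ndarray, start: int,
                rel_tol: float) -> int:
    """Greedy end index (exclusive) of the linear run beginning at ``start``.

    Starting from the minimum run length, each next level is accepted if its
    response lies within ``max(3 * s_pred, rel_tol * |prediction|)`` of the
    extrapolated current line, where ``s_pred`` is the residual scale of the
    current fit.  This localizes the saturation onset even when the overall
    R-squared of an over-extended run would still look acceptable.
    """
    n = x.size
    end = min(start + MIN_RUN_LEVELS, n)
    while end < n:
        slope, intercept = np.polyfit(x[start:end], y[start:end], 1)
        pred = slope * x[end] + intercept
        resid = y[start:end] - (slope * x[start:end] + intercept)
        dof = max(end - start - 2, 1)
        s = float(np.sqrt((resid**2).sum() / dof))
        if abs(y[end] - pred) > max(3.0 * s, rel_tol * abs(pred)):
            break
        end += 1
    return end


def determine_linear_range(dilution_series: Sequence[float],
                           responses: Sequence[float],
                           r2_min: float = DEFAULT_R2_MIN,
                           rel_tol: float = DEFAULT_REL_TOL,
                           compound: str = "") -> CalibrationResult:
    """Detect the linear range of a dilution series and fit its line.

    Candidate runs are contiguous, at least ``MIN_RUN_LEVELS`` long, start
    from the lowest feasible level, extend greedily until the next level
    departs from the extrapolated line (see :func:`_extend_run`), and must
    achieve ``R^2 >= r2_min``.  The widest qualifying run wins; ties go to
    the higher R^2.  Without any qualifying run a non-qualifying result with
    diagnostics is returned.
    """
    x = np.asarray(dilution_series, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size != y.size:
        raise ValueError("series and responses differ in length")
    if x.size < MIN_RUN_LEVELS:
        raise ValueError(f"need >= {MIN_RUN_LEVELS} dilution levels")
    if np.any(np.diff(x) <= 0):
        raise ValueError("dilution series must be strictly ascending")

    best: CalibrationResult | None = None
    for start in range(0, x.size - MIN_RUN_LEVELS + 1):
        end = _extend_run(x, y, start, rel_tol)
        if end - start < MIN_RUN_LEVELS:
            continue
        y_run = y[start:end]
        if np.ptp(y_run) == 0:  # flat plateau: no calibration response
            continue
        slope, intercept, r2 = fit_calibration(x[start:end], y_run)
        if r2 < r2_min or slope <= 0:
            continue
        cand = CalibrationResult(compound, slope, intercept, r2,
                                 (float(x[start]), float(x[end - 1])),
                                 points_used=end - start)
        if (best is None or cand.points_used > best.points_used
                or (cand.points_used == best.points_used and cand.r2 > best.r2)):
            best = cand
    if best is None:
        slope, intercept, r2 = fit_calibration(x, y)
        return CalibrationResult(compound, slope, intercept, r2,
                                 (float(x[0]), float(x[-1])),
                                 points_used=int(x.size), qualifying=False,
                                 diagnostics=f"no run of >= {MIN_RUN_LEVELS} "
                                             f"levels reached R^2 >= {r2_min}")
    return best


def _monomer_signal(library: CompoundLibrary, name: str) -> SignalDef:
    for sig in library.signal_defs():
        if sig.compound == name and sig.form == "monomer":
            return sig
    raise KeyError(name)


def _dimer_signal(library: CompoundLibrary, name: str) -> SignalDef:
    for sig in library.signal_defs():
        if sig.compound == name and sig.form == "dimer":
            return sig
    raise KeyError(f"{name} has no dimer signal")


def linearity_study(maps: Sequence[HeatMap],
                    levels: Sequence[float],
                    mixture: str,
                    library: CompoundLibrary | None = None,
                    r2_min: float = DEFAULT_R2_MIN,
                    rel_tol: float = DEFAULT_REL_TOL,
                    ) -> list[CalibrationResult]:
    """Calibration lines for every compound of a standard-mixture series.

    Responses are the raw (mV) monomer window maxima, matching how the
    calibration equations are expressed.
    """
    library = library or default_compound_library()
    sub = library.mixture(mixture)
    results = []
    for compound in sub.names:
        sig = _monomer_signal(library, compound)
        resp = [extract_signal(m, sig) for m in maps]
        results.append(determine_linear_range(levels, resp, r2_min=r2_min,
                                              rel_tol=rel_tol,
                                              compound=compound))
    return results


def repeatability_study(maps_by_grade: Mapping[str, Sequence[HeatMap]],
                        mode: str,
                        markers: Mapping[str, tuple[str, str]] | None = None,
                        library: CompoundLibrary | None = None,
                        use_normalized: bool = False,
                        ) -> list[RepeatabilityResult]:
    """RSD% of marker dimer maxima over replicate (or daily) analyses.

    Two marker compounds are tracked per grade: (E)-2-hexenal and hexanal
    for EVOO, ethanol and ethyl acetate for VOO (winey-vinegary), ethyl
    propanoate and 3-methyl-1-butanol for LOO (fusty/muddy sediment).
    Raw mV maxima are used by default; ``use_normalized`` switches to
    RIP-normalized values.
    """
    library = library or default_compound_library()
    markers = markers or REPEATABILITY_MARKERS
    results = []
    for grade, maps in maps_by_grade.items():
        if len(maps) != N_REPLICATES:
            raise ValueError(f"{grade}: expected {N_REPLICATES} "
                             f"{'replicates' if mode == 'intra' else 'days'}, "
                             f"got {len(maps)}")
        prepared = [normalize_rip(m) if use_normalized else m for m in maps]
        for compound in markers[grade]:
            sig = _dimer_signal(library, compound)
            values = [extract_signal(m, sig) for m in prepared]
            results.append(RepeatabilityResult(
                grade=grade, compound=compound, mode=mode,
                n=len(values), rsd_pct=rsd_percent(values)))
    return results
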