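"""Heat-map container, RIP normalization and 25-signal feature extraction.

A GC-IMS measurement is a 2-D intensity grid ("heat map"): GC retention time
(seconds) on one axis, IMS drift time (milliseconds) on the other, ion-current
intensity in millivolts.  The reactant ion peak (RIP) is a ridge at a fixed
drift time spanning all retention times; analyte ionization depletes it, so
each drift spectrum is normalized by dividing by its own RIP apex.  Features
are the maximum normalized intensities inside fixed per-signal windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .library import CompoundLibrary, SignalDef

__all__ = ["HeatMap", "normalize_rip", "extract_signal", "build_feature_matrix"]

#: Half-width of the drift window used to locate the RIP apex, ms.
RIP_SEARCH_HALF_MS = 0.25


@dataclass
class HeatMap:
    """Gridded GC-IMS intensity map.

    ``intensity`` has shape ``(len(rt_axis), len(dt_axis))``; a row is one
    drift spectrum at fixed retention time.
    """

    rt_axis: np.ndarray  # s, ascending
    dt_axis: np.ndarray  # ms, ascending
    intensity: np.ndarray  # mV (dimensionless once RIP-normalized)
    rip_dt: float  # ms
    sample_id: str = ""
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rt_axis = np.asarray(self.rt_axis, dtype=float)
        self.dt_axis = np.asarray(self.dt_axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.rt_axis.size, self.dt_axis.size):
            raise ValueError("intensity grid does not match axes")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities in heat map")
        if not (self.dt_axis[0] <= self.rip_dt <= self.dt_axis[-1]):
            raise ValueError("rip_dt outside drift-time axis span")

    def rip_slice(self) -> slice:
        lo = np.searchsorted(self.dt_axis, self.rip_dt - RIP_SEARCH_HALF_MS, "left")
        hi = np.searchsorted(self.dt_axis, self.rip_dt + RIP_SEARCH_HALF_MS, "right")
        return slice(lo, hi)

    def window_view(self, rt_window: tuple[float, float],
                    dt_window: tuple[float, float]) -> np.ndarray:
        r0 = np.searchsorted(self.rt_axis, rt_window[0], "left")
        r1 = np.searchsorted(self.rt_axis, rt_window[1], "right")
        d0 = np.searchsorted(self.dt_axis, dt_window[0], "left")
        d1 = np.searchsorted(self.dt_axis, dt_window[1], "right")
        if r0 >= r1 or d0 >= d1:
            raise ValueError(
                f"window rt={rt_window} dt={dt_window} outside heat-map axes")
        return self.intensity[r0:r1, d0:d1]

    # ------------------------------------------------------------------ I/O
    def to_csv(self, path) -> None:
        """Write the grid as CSV (drift times as header, retention as index)."""
        df = pd.DataFrame(self.intensity, index=self.rt_axis, columns=self.dt_axis)
        df.index.name = f"rt_s/rip_dt={self.rip_dt}/id={self.sample_id}"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "HeatMap":
        df = pd.read_csv(path, index_col=0)
        tag = df.index.name or ""
        rip_dt, sample_id = 8.5, Path(str(path)).stem
        for part in tag.split("/"):
            if part.startswith("rip_dt="):
                rip_dt = float(part.split("=", 1)[1])
            elif part.startswith("id="):
                sample_id = part.split("=", 1)[1]
        return cls(rt_axis=df.index.to_numpy(float),
                   dt_axis=np.array([float(c) for c in df.columns]),
                   intensity=df.to_numpy(float), rip_dt=rip_dt,
                   sample_id=sample_id)


def normalize_rip(hmap: HeatMap) -> HeatMap:
    """Divide every drift spectrum by that spectrum's RIP apex intensity.

    Row-wise division makes the output dimensionless, maps the RIP apex of
    every row to 1, and renders downstream features invariant to any global
    intensity rescaling.  Idempotent by construction.
    """
    rip = hmap.intensity[:, hmap.rip_slice()].max(axis=1)
    if np.any(rip <= 0):
        bad = hmap.rt_axis[int(np.argmax(rip <= 0))]
        raise ValueError(
            f"corrupt heat map {hmap.sample_id!r}: RIP apex <= 0 at rt={bad:g} s")
    return HeatMap(rt_axis=hmap.rt_axis, dt_axis=hmap.dt_axis,
                   intensity=hmap.intensity / rip[:, None],
                   rip_dt=hmap.rip_dt, sample_id=hmap.sample_id,
                   normalized=True, meta=dict(hmap.meta))


def extract_signal(hmap: HeatMap, sig: SignalDef) -> float:
    """Maximum intensity inside the signal's rt x dt window.

    For the ethanol dimer the ghost spot cannot be resolved from the dimer,
    so the returned value is the sum of the dimer-window maximum and the
    ghost-window maximum.  An absent spot simply yields the in-window
    baseline-level maximum — the feature matrix has no missing-value
    mechanism.
    """
    value = float(hmap.window_view(sig.rt_window, sig.dt_window).max())
    if sig.merge_with_ghost:
        value += float(hmap.window_view(sig.ghost_rt_window, sig.ghost_dt_window).max())
    return value


def build_feature_matrix(maps: Iterable[HeatMap],
                         library: CompoundLibrary) -> pd.DataFrame:
    """Extract the RIP-normalized signal maxima for every map.

    Rows follow the input order (one per sample id); columns are the
    library's signals in library order (``<compound>_<form>``).  Accepts any
    iterable, so maps may be generated lazily and discarded after extraction.
    """
    sigs = library.signal_defs()
    ids: list[str] = []
    rows: list[list[float]] = []
    for m in maps:
        norm = m if m.normalized else normalize_rip(m)
        ids.append(m.sample_id)
        rows.append([extract_signal(norm, s) for s in sigs])
    if not rows:
        raise ValueError("no heat maps given")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in heat-map collection")
    return pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                        columns=[s.name for s in sigs])
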