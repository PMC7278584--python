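"""Targeted volatile-compound library for HS-GC-IMS olive-oil screening.

The method is semi-targeted: fifteen volatile markers, split across two
standard mixtures (SMA, low-concentration compounds; SMB, high-concentration
compounds), are located in the retention-time x drift-time plane.  Each
compound contributes a monomer spot and, for ten of the fifteen, a proton-bound
dimer spot at a longer drift time, giving 25 extractable signals in total.
Calibration lines (response in mV vs concentration in mg kg^-1) and linear
ranges are part of the library and drive both the simulator and the
method-performance procedures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "CompoundDef",
    "CompoundLibrary",
    "SignalDef",
    "default_compound_library",
]

#: Total GC program length, seconds (32-minute run).
RT_MAX_S = 1920.0

# Half-widths of the extraction windows.  Retention-time spread grows with
# retention time under the flow-ramp program; drift-time spread does not.
RT_WINDOW_MIN_HALF_S = 6.0
RT_WINDOW_REL_HALF = 0.015
DT_WINDOW_HALF_MS = 0.08

# The ghost spot partially co-elutes with the ethanol dimer under isothermal
# operation; its window is a fixed offset from the dimer window.
GHOST_RT_OFFSET_S = 15.0
GHOST_DT_OFFSET_MS = 0.12
ETHANOL = "Ethanol"


@dataclass(frozen=True)
class CompoundDef:
    """One targeted volatile compound.

    Parameters
    ----------
    name : str
        Compound name.
    rt : float
        Monomer retention time, s.
    dt : float
        Monomer drift time, ms.
    slope, intercept : float
        Calibration line ``response_mV = slope * c + intercept`` with *c* in
        mg kg^-1.
    linear_range : tuple of float
        (low, high) bounds of the linear response range, mg kg^-1.
    has_dimer : bool
        Whether the compound also forms a detectable dimer spot.
    dimer_dt : float or None
        Dimer drift time, ms (present iff ``has_dimer``).
    mixture : str
        Standard mixture the compound belongs to, ``"SMA"`` or ``"SMB"``.
    r2 : float
        Determination coefficient of the reference calibration fit.
    """

    name: str
    rt: float
    dt: float
    slope: float
    intercept: float
    linear_range: tuple[float, float]
    has_dimer: bool
    dimer_dt: float | None
    mixture: str
    r2: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.rt <= RT_MAX_S:
            raise ValueError(f"{self.name}: rt {self.rt} outside (0, {RT_MAX_S}] s")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.name}: empty linear range {self.linear_range}")
        if self.slope <= 0:
            raise ValueError(f"{self.name}: calibration slope must be positive")
        if self.has_dimer != (self.dimer_dt is not None):
            raise ValueError(f"{self.name}: dimer_dt present iff has_dimer")
        if self.mixture not in ("SMA", "SMB"):
            raise ValueError(f"{self.name}: unknown mixture {self.mixture!r}")

    def response(self, c: float) -> float:
        """Linear in-range response, mV (no saturation applied)."""
        return self.slope * c + self.intercept


@dataclass(frozen=True)
class SignalDef:
    """One extractable heat-map signal: a compound in monomer or dimer form."""

    compound: str
    form: str  # "monomer" | "dimer"
    rt_window: tuple[float, float]
    dt_window: tuple[float, float]
    merge_with_ghost: bool = False

    @property
    def name(self) -> str:
        return f"{self.compound}_{self.form}"

    @property
    def ghost_rt_window(self) -> tuple[float, float]:
        lo, hi = self.rt_window
        return (lo + GHOST_RT_OFFSET_S, hi + GHOST_RT_OFFSET_S)

    @property
    def ghost_dt_window(self) -> tuple[float, float]:
        lo, hi = self.dt_window
        return (lo + GHOST_DT_OFFSET_MS, hi + GHOST_DT_OFFSET_MS)


def rt_window(rt: float) -> tuple[float, float]:
    half = max(RT_WINDOW_MIN_HALF_S, RT_WINDOW_REL_HALF * rt)
    return (rt - half, rt + half)


def dt_window(dt: float) -> tuple[float, float]:
    return (dt - DT_WINDOW_HALF_MS, dt + DT_WINDOW_HALF_MS)


class CompoundLibrary:
    """Ordered collection of :class:`CompoundDef` with signal definitions."""

    def __init__(self, compounds: Iterable[CompoundDef]):
        self._compounds = list(compounds)
        names = [c.name for c in self._compounds]
        if len(set(names)) != len(names):
            raise ValueError("duplicate compound names in library")
        self._by_name = {c.name: c for c in self._compounds}

    def __iter__(self) -> Iterator[CompoundDef]:
        return iter(self._compounds)

    def __len__(self) -> int:
        return len(self._compounds)

    def __getitem__(self, name: str) -> CompoundDef:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [c.name for c in self._compounds]

    def subset(self, names: Iterable[str]) -> "CompoundLibrary":
        return CompoundLibrary([self._by_name[n] for n in names])

    def mixture(self, code: str) -> "CompoundLibrary":
        if code not in ("SMA", "SMB"):
            raise ValueError(f"unknown mixture code {code!r}")
        return CompoundLibrary([c for c in self._compounds if c.mixture == code])

    def with_dimer_set(self, dimer_names: Iterable[str],
                       dt_offset_ms: float = 1.0) -> "CompoundLibrary":
        """Return a copy where exactly ``dimer_names`` carry dimer spots."""
        dimer_names = set(dimer_names)
        unknown = dimer_names - set(self.names)
        if unknown:
            raise ValueError(f"unknown compounds: {sorted(unknown)}")
        out = []
        for c in self._compounds:
            if c.name in dimer_names:
                out.append(replace(c, has_dimer=True,
                                   dimer_dt=c.dimer_dt or c.dt + dt_offset_ms))
            else:
                out.append(replace(c, has_dimer=False, dimer_dt=None))
        return CompoundLibrary(out)

    def signal_defs(self) -> list[SignalDef]:
        """The extractable signals, monomer first, in library order.

        The ethanol dimer is merged with the ghost signal: under isothermal
        IMS operation a spurious spot partially co-elutes with it, so the
        extracted value is the sum of the two window maxima.
        """
        sigs: list[SignalDef] = []
        for c in self._compounds:
            sigs.append(SignalDef(c.name, "monomer", rt_window(c.rt), dt_window(c.dt)))
            if c.has_dimer:
                assert c.dimer_dt is not None
                sigs.append(SignalDef(
                    c.name, "dimer", rt_window(c.rt), dt_window(c.dimer_dt),
                    merge_with_ghost=(c.name == ETHANOL)))
        return sigs

    @property
    def n_signals(self) -> int:
        return sum(1 + c.has_dimer for c in self._compounds)

    # ---------------------------------------------------------------- I/O
    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "name": c.name, "rt_s": c.rt, "dt_ms": c.dt,
            "slope": c.slope, "intercept": c.intercept,
            "range_low": c.linear_range[0], "range_high": c.linear_range[1],
            "r2": c.r2, "has_dimer": int(c.has_dimer),
            "dimer_dt_ms": c.dimer_dt if c.has_dimer else "",
            "mixture": c.mixture,
        } for c in self._compounds]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CompoundLibrary":
        df = pd.read_csv(path)
        compounds = []
        for _, r in df.iterrows():
            has_dimer = bool(int(r["has_dimer"]))
            compounds.append(CompoundDef(
                name=str(r["name"]), rt=float(r["rt_s"]), dt=float(r["dt_ms"]),
                slope=float(r["slope"]), intercept=float(r["intercept"]),
                linear_range=(float(r["range_low"]), float(r["range_high"])),
                has_dimer=has_dimer,
                dimer_dt=float(r["dimer_dt_ms"]) if has_dimer else None,
                mixture=str(r["mixture"]),
                r2=float(r["r2"]) if "r2" in df.columns else float("nan"),
            ))
        return cls(compounds)


# Reference table: compound, rt (s), dt (ms), slope, intercept, linear range
# (mg kg^-1), R^2, mixture.  SMA holds the low-concentration markers, SMB the
# high-concentration ones.
_TABLE = """\
name|rt|dt|slope|intercept|lo|hi|r2|mixture
Ethyl acetate|170|10.908|672.5|70.5|0.05|0.5|0.980|SMA
Ethyl propanoate|230|11.844|549.7|9.6|0.05|0.5|0.978|SMA
Propanoic acid|218|9.102|15.3|68.4|0.05|10|0.932|SMA
3-methyl-1-butanol|259|12.203|279.9|43.6|0.05|1.5|0.986|SMA
(E,E)-2,4-hexadienal|522|11.827|87.3|27.8|1.5|10|0.982|SMA
(E)-2-heptenal|639|13.71|18.4|175.6|1.5|10|0.969|SMA
6-methyl-5-hepten-2-one|749|9.588|72.2|162.5|0.05|10|0.994|SMA
Ethanol|121|9.255|345.4|150.4|0.05|0.5|0.980|SMB
Acetic acid|149|9.434|14.5|42.7|0.10|25|0.982|SMB
Hexanal|317|12.723|198.3|23.3|0.05|1.5|0.991|SMB
(E)-2-hexenal|404|12.358|47.3|7.3|0.10|10|0.989|SMB
1-hexanol|450|13.415|32.9|83.8|0.05|25|0.988|SMB
1-octen-3-ol|733|9.451|33.0|176.2|0.05|20|0.996|SMB
(Z)-3-hexenyl acetate|846|14.908|6.9|281.7|5.0|25|0.989|SMB
Nonanal|1554|12.128|5.1|138.0|0.05|15|0.990|SMB
"""

#: Compounds whose dimer spot is not observed (low-response or late-eluting);
#: the remaining ten carry dimers, for 25 signals in total.  Configurable via
#: :meth:`CompoundLibrary.with_dimer_set`.
DEFAULT_MONOMER_ONLY = frozenset({
    "Propanoic acid",
    "Acetic acid",
    "(E,E)-2,4-hexadienal",
    "(Z)-3-hexenyl acetate",
    "Nonanal",
})

#: Drift-time offset of a dimer spot relative to its monomer, ms.
DEFAULT_DIMER_DT_OFFSET_MS = 1.0


def default_compound_library() -> CompoundLibrary:
    """The 15-marker library with reference calibration parameters.

    Ten compounds carry dimer spots (25 signals in total); the ethanol dimer
    is flagged for ghost-signal merging at extraction time.
    """
    df = pd.read_csv(io.StringIO(_TABLE), sep="|")
    compounds = []
    for _, r in df.iterrows():
        has_dimer = r["name"] not in DEFAULT_MONOMER_ONLY
        compounds.append(CompoundDef(
            name=r["name"], rt=float(r["rt"]), dt=float(r["dt"]),
            slope=float(r["slope"]), intercept=float(r["intercept"]),
            linear_range=(float(r["lo"]), float(r["hi"])),
            has_dimer=has_dimer,
            dimer_dt=float(r["dt"]) + DEFAULT_DIMER_DT_OFFSET_MS if has_dimer else None,
            mixture=r["mixture"], r2=float(r["r2"]),
        ))
    return CompoundLibrary(compounds)
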