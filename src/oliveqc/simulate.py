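"""Synthetic HS-GC-IMS heat maps and labeled olive-oil sample sets.

The study population the classifiers assume — extra virgin (EVOO), virgin
(VOO) and lampante (LOO) oils, the latter two carrying one or more sensory
defects — is emulated by class-conditional log-normal concentration profiles
over the 15 targeted volatile compounds, rendered into gridded heat maps with
the instrument's structural features: a reactant-ion-peak (RIP) ridge that is
depleted where analytes ionize, 2-D Gaussian monomer spots whose apex follows
each compound's calibration line inside its linear range and rolls off
smoothly to a plateau above it, quadratic-response dimer spots for the ten
dimer-forming compounds, a ghost spot partially co-eluting with the ethanol
dimer, and multiplicative intensity noise.

Concentration separations between classes are driven by the marker chemistry:
(E)-2-hexenal and hexanal mark fruity EVOOs; ethanol and ethyl acetate the
winey-vinegary defect; 3-methyl-1-butanol and ethyl propanoate the
fusty/muddy-sediment defect; hexanal, nonanal and (E)-2-heptenal rancidity;
1-octen-3-ol the musty defect.  A single ``effect_scale`` knob scales every
class contrast, so ``effect_scale=0`` yields an exchangeable null population
on which downstream classifiers must perform at chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .heatmap import HeatMap
from .library import (
    GHOST_DT_OFFSET_MS,
    GHOST_RT_OFFSET_S,
    CompoundDef,
    CompoundLibrary,
    default_compound_library,
)

__all__ = [
    "GridSpec",
    "ClassProfile",
    "SensoryLabel",
    "StudyDesign",
    "default_profiles",
    "sample_concentrations",
    "render_heatmap",
    "generate_dataset",
    "iter_dataset",
    "generate_calibration_series",
    "simulate_repeatability_maps",
    "SMA_LEVELS",
    "SMB_LEVELS",
]

GRADES = ("EVOO", "VOO", "LOO")
#: Modeled defects (binary classifiers are built for the first three only).
DEFECTS = ("musty", "rancid", "fusty")
#: Winey-vinegary is part of the sensory vocabulary but not modeled.
ALL_DEFECTS = DEFECTS + ("winey",)

#: Dilution series of the low- and high-concentration standard mixtures,
#: mg kg^-1 (12 and 15 levels).
SMA_LEVELS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.5, 1.00, 1.50, 2.00, 2.50,
              5.00, 10.00)
SMB_LEVELS = SMA_LEVELS + (15.00, 20.00, 25.00)


# --------------------------------------------------------------------- grid
@dataclass(frozen=True)
class GridSpec:
    """Instrument grid and spot-shape parameters.

    The baseline must stay below the smallest calibration intercept
    (7.3 mV) so that a monomer apex can equal ``slope*c + intercept``
    exactly: spots are rendered with amplitude ``response - baseline``.
    """

    rt_start: float = 0.0
    rt_stop: float = 1920.0  # 32-min GC program
    rt_step: float = 1.0
    dt_start: float = 7.0
    dt_stop: float = 16.0
    dt_step: float = 0.01
    rip_dt: float = 8.5  # ms
    rip_intensity: float = 2000.0  # mV
    rip_sigma_ms: float = 0.05
    rip_depletion: float = 0.6  # mV of RIP lost per mV of analyte signal
    rip_floor_frac: float = 0.1
    baseline: float = 5.0  # mV
    sigma_dt_ms: float = 0.03
    sigma_rt_min_s: float = 2.0
    sigma_rt_rel: float = 0.005
    dimer_ratio: float = 0.4  # dimer/monomer apex at linear-range midpoint
    ghost_ratio: float = 0.5  # ghost apex relative to ethanol dimer apex
    saturation_margin: float = 0.1  # plateau headroom, fraction of S*hi

    def rt_axis(self) -> np.ndarray:
        n = int(round((self.rt_stop - self.rt_start) / self.rt_step)) + 1
        return self.rt_start + self.rt_step * np.arange(n)

    def dt_axis(self) -> np.ndarray:
        n = int(round((self.dt_stop - self.dt_start) / self.dt_step)) + 1
        return self.dt_start + self.dt_step * np.arange(n)

    def sigma_rt(self, rt: float) -> float:
        return max(self.sigma_rt_min_s, self.sigma_rt_rel * rt)


#: A coarser grid (same physics, 5 s x 0.02 ms steps) for large simulated
#: cohorts where per-map resolution is not under test.
COARSE_GRID = GridSpec(rt_step=5.0, dt_step=0.02)


# ---------------------------------------------------------- response model
def monomer_response(compound: CompoundDef, c: float,
                     grid: GridSpec = GridSpec()) -> float:
    """Monomer apex intensity (mV) at concentration ``c`` (mg kg^-1).

    Affine ``slope*c + intercept`` inside the linear range; above its top the
    response approaches a plateau exponentially, continuous in value and
    slope at the junction.  The plateau sits ``saturation_margin * slope * hi``
    above the junction response, so saturation bites within roughly one
    dilution step — reproducing the narrow linear ranges the calibration
    procedure must recover.
    """
    if c < 0:
        raise ValueError("negative concentration")
    hi = compound.linear_range[1]
    if c <= hi:
        return compound.slope * c + compound.intercept
    y0 = compound.slope * hi + compound.intercept
    head = grid.saturation_margin * compound.slope * hi  # plateau headroom
    return y0 + head * -math.expm1(-compound.slope * (c - hi) / head)


def dimer_response(compound: CompoundDef, c: float,
                   grid: GridSpec = GridSpec()) -> float:
    """Dimer apex intensity above baseline, mV.

    Dimers form at higher analyte abundance: response grows quadratically in
    concentration below the linear-range top, scaled so the dimer apex is
    ``dimer_ratio`` of the monomer apex at the range midpoint, then rolls off
    to a plateau like the monomer.
    """
    if c < 0:
        raise ValueError("negative concentration")
    lo, hi = compound.linear_range
    cm = 0.5 * (lo + hi)
    k = grid.dimer_ratio * compound.response(cm) / cm**2
    if c <= hi:
        return k * c * c
    y0 = k * hi * hi
    slope = 2.0 * k * hi
    head = grid.saturation_margin * slope * hi
    return y0 + head * -math.expm1(-slope * (c - hi) / head)


def _spot_amplitudes(concentrations: Mapping[str, float],
                     library: CompoundLibrary,
                     grid: GridSpec) -> list[tuple[float, float, float]]:
    """(rt, dt, amplitude-above-baseline) for every rendered spot."""
    spots: list[tuple[float, float, float]] = []
    for name, c in concentrations.items():
        if name not in library:
            raise KeyError(f"unknown compound {name!r} in concentration table")
        if c < 0:
            raise ValueError(f"negative concentration for {name!r}")
        cd = library[name]
        if c > 0:
            amp = monomer_response(cd, c, grid) - grid.baseline
            spots.append((cd.rt, cd.dt, max(amp, 0.0)))
            if cd.has_dimer:
                d = dimer_response(cd, c, grid)
                spots.append((cd.rt, cd.dimer_dt, d))
                if cd.name == "Ethanol":
                    spots.append((cd.rt + GHOST_RT_OFFSET_S,
                                  cd.dimer_dt + GHOST_DT_OFFSET_MS,
                                  grid.ghost_ratio * d))
        else:
            # Zero concentration: the intercept-level residual spot only.
            amp = max(cd.intercept - grid.baseline, 0.0)
            spots.append((cd.rt, cd.dt, amp))
    return spots


def render_heatmap(concentrations: Mapping[str, float],
                   library: CompoundLibrary | None = None,
                   noise_cv: float = 0.0,
                   seed: int | np.random.Generator | None = None,
                   grid: GridSpec = GridSpec(),
                   day_factor: float = 1.0,
                   sample_id: str = "") -> HeatMap:
    """Render one heat map from per-compound concentrations (mg kg^-1).

    ``day_factor`` multiplies every analyte amplitude (instrument response
    drift between days); ``noise_cv`` is the coefficient of variation of
    i.i.d. multiplicative intensity noise over the whole grid.
    """
    library = library or default_compound_library()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rt = grid.rt_axis()
    dt = grid.dt_axis()
    out = np.full((rt.size, dt.size), grid.baseline)

    spots = _spot_amplitudes(concentrations, library, grid)

    # Analyte load per retention time, for RIP depletion.
    load = np.zeros(rt.size)
    for srt, sdt, amp in spots:
        amp *= day_factor
        if amp <= 0:
            continue
        s_rt = grid.sigma_rt(srt)
        r0 = np.searchsorted(rt, srt - 5 * s_rt)
        r1 = np.searchsorted(rt, srt + 5 * s_rt, "right")
        d0 = np.searchsorted(dt, sdt - 5 * grid.sigma_dt_ms)
        d1 = np.searchsorted(dt, sdt + 5 * grid.sigma_dt_ms, "right")
        prof_rt = np.exp(-0.5 * ((rt[r0:r1] - srt) / s_rt) ** 2)
        prof_dt = np.exp(-0.5 * ((dt[d0:d1] - sdt) / grid.sigma_dt_ms) ** 2)
        out[r0:r1, d0:d1] += amp * prof_rt[:, None] * prof_dt[None, :]
        load[r0:r1] += amp * prof_rt

    rip_amp = np.maximum(grid.rip_floor_frac * grid.rip_intensity,
                         grid.rip_intensity - grid.rip_depletion * load)
    rip_prof = np.exp(-0.5 * ((dt - grid.rip_dt) / grid.rip_sigma_ms) ** 2)
    out += rip_amp[:, None] * rip_prof[None, :]

    if noise_cv > 0:
        out *= rng.normal(1.0, noise_cv, size=out.shape)
        np.maximum(out, 0.0, out=out)

    return HeatMap(rt_axis=rt, dt_axis=dt, intensity=out, rip_dt=grid.rip_dt,
                   sample_id=sample_id, meta={"noise_cv": noise_cv,
                                              "day_factor": day_factor})


# ----------------------------------------------------------- study profiles
@dataclass(frozen=True)
class ClassProfile:
    """Log-normal concentration profile for one grade or defect.

    ``params`` maps every compound name to ``(location, scale)`` of
    ``log(concentration)``; the distribution median is ``exp(location)``
    mg kg^-1.
    """

    label: str
    params: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (_, sigma) in self.params.items():
            if sigma < 0:
                raise ValueError(f"{self.label}/{name}: scale must be >= 0")

    def location(self, name: str) -> float:
        return self.params[name][0]


@dataclass(frozen=True)
class SensoryLabel:
    """Panel-style label: quality grade plus perceived defects."""

    sample_id: str
    grade: str
    defects: tuple[str, ...]
    fruity_median: float
    defect_median: float

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"unknown grade {self.grade!r}")
        if self.grade == "EVOO" and (self.defects or self.defect_median != 0):
            raise ValueError("EVOO must carry no defects")
        if self.grade in ("VOO", "LOO") and not self.defects:
            raise ValueError(f"{self.grade} sample must carry >= 1 defect")

    def has_defect(self, name: str) -> bool:
        return name in self.defects


@dataclass(frozen=True)
class StudyDesign:
    """Sampling plan for a synthetic study.

    Defaults mirror a commercial survey of 198 oils (83 EVOO, 69 VOO,
    46 LOO) in which, among the defective (VOO+LOO) samples, 49% carry the
    fusty/muddy-sediment defect, 29% musty-humid-earthy and 44% rancid
    (samples may carry several).  ``noise_cv`` is the instrument's intensity
    noise (intra-day RSD% scale); ``day_effect_cv`` the between-day response
    drift.
    """

    n_evoo: int = 83
    n_voo: int = 69
    n_loo: int = 46
    defect_prevalences: dict = field(default_factory=lambda: {
        "fusty": 0.49, "musty": 0.29, "rancid": 0.44, "winey": 0.35})
    noise_cv: float = 0.015
    day_effect_cv: float = 0.02
    effect_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_evoo, self.n_voo, self.n_loo) < 0:
            raise ValueError("sample counts must be >= 0")
        if self.n_evoo + self.n_voo + self.n_loo == 0:
            raise ValueError("empty study design")
        for k, p in self.defect_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {k!r} outside [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_evoo + self.n_voo + self.n_loo


# Baseline log-medians (mg kg^-1) of the 15 compounds in an unremarkable oil.
_BASE_MEDIAN = {
    "Ethyl acetate": 0.10, "Ethyl propanoate": 0.08, "Propanoic acid": 0.5,
    "3-methyl-1-butanol": 0.15, "(E,E)-2,4-hexadienal": 2.0,
    "(E)-2-heptenal": 2.0, "6-methyl-5-hepten-2-one": 0.5,
    "Ethanol": 0.15, "Acetic acid": 1.0, "Hexanal": 0.4,
    "(E)-2-hexenal": 1.0, "1-hexanol": 1.5, "1-octen-3-ol": 0.5,
    "(Z)-3-hexenyl acetate": 6.0, "Nonanal": 1.0,
}

# Log-scale contrasts of each grade against the neutral baseline.
_GRADE_DELTA = {
    "EVOO": {"(E)-2-hexenal": 1.2, "Hexanal": 0.5, "(Z)-3-hexenyl acetate": 0.4,
             "1-hexanol": 0.3},
    "VOO": {"(E)-2-hexenal": 0.4, "Hexanal": 0.2, "Ethanol": 0.3,
            "Ethyl acetate": 0.3},
    # The lampante grade itself contributes low fruitiness and a general
    # fermentative background; the large defect-marker elevations come from
    # the (unattenuated) defect profiles a LOO carries, so that e.g. fusty
    # markers are high in fusty LOOs, not in every LOO.
    "LOO": {"(E)-2-hexenal": -0.8, "Hexanal": -0.3, "Ethanol": 0.4,
            "Acetic acid": 0.4},
}

# Log-scale contrasts of each defect (full strength, as perceived in LOOs).
_DEFECT_DELTA = {
    "fusty": {"3-methyl-1-butanol": 1.6, "Ethyl propanoate": 1.4,
              "Propanoic acid": 1.2},
    "musty": {"1-octen-3-ol": 1.8},
    "rancid": {"Hexanal": 1.2, "Nonanal": 1.4, "(E)-2-heptenal": 1.3,
               "(E,E)-2,4-hexadienal": 0.6},
    "winey": {"Ethanol": 1.3, "Ethyl acetate": 1.3, "Acetic acid": 1.0},
}

#: Defect contrasts in VOOs are attenuated relative to LOOs (defects are
#: perceived but milder; sensory medians below the lampante cut-off).
VOO_DEFECT_ATTENUATION = 0.6

#: Default log-scale spread of every compound within a class.
DEFAULT_LOG_SCALE = 0.45


def default_profiles(effect_scale: float = 1.0,
                     log_scale: float = DEFAULT_LOG_SCALE,
                     library: CompoundLibrary | None = None,
                     ) -> dict[str, ClassProfile]:
    """Class-conditional profiles for the three grades and four defects.

    ``effect_scale`` multiplies every class contrast; 0 collapses all
    classes onto the same distribution (chance-level separability).
    """
    library = library or default_compound_library()
    profiles: dict[str, ClassProfile] = {}
    for label, deltas in {**_GRADE_DELTA, **_DEFECT_DELTA}.items():
        params = {}
        for name in library.names:
            mu = math.log(_BASE_MEDIAN[name]) + effect_scale * deltas.get(name, 0.0)
            params[name] = (mu, log_scale)
        profiles[label] = ClassProfile(label, params)
    return profiles


def combine_profiles(grade_profile: ClassProfile,
                     defect_profiles: Sequence[ClassProfile],
                     attenuation: float = 1.0) -> ClassProfile:
    """Element-wise maximum-effect combination of defects over a grade.

    Each compound's log-location is the maximum of the grade location and
    the (attenuated) defect locations; the defective profile can only raise
    a marker, never mask it.
    """
    params = {}
    for name, (mu_g, sg) in grade_profile.params.items():
        mu = mu_g
        for dp in defect_profiles:
            mu_d, _ = dp.params[name]
            base = math.log(_BASE_MEDIAN[name])
            mu = max(mu, base + attenuation * (mu_d - base))
        params[name] = (mu, sg)
    labels = "+".join(dp.label for dp in defect_profiles)
    return ClassProfile(f"{grade_profile.label}+{labels}", params)


def sample_concentrations(profile: ClassProfile, n: int,
                          seed: int | np.random.Generator = 0,
                          library: CompoundLibrary | None = None,
                          ) -> pd.DataFrame:
    """Draw ``n`` log-normal concentration vectors (mg kg^-1) from a profile."""
    if n < 1:
        raise ValueError("n must be >= 1")
    library = library or default_compound_library()
    for name in profile.params:
        if name not in library:
            raise KeyError(f"profile {profile.label!r} names unknown "
                           f"compound {name!r}")
    missing = set(library.names) - set(profile.params)
    if missing:
        raise KeyError(f"profile {profile.label!r} missing compounds "
                       f"{sorted(missing)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cols = {}
    for name in library.names:
        mu, sigma = profile.params[name]
        cols[name] = np.exp(rng.normal(mu, sigma, size=n)) if sigma > 0 \
            else np.full(n, math.exp(mu))
    return pd.DataFrame(cols)


# ------------------------------------------------------------ study samples
def _draw_defects(rng: np.random.Generator,
                  prevalences: Mapping[str, float]) -> tuple[str, ...]:
    """Independent defect draws; winey is forced when nothing else fires.

    Keeps the marginal prevalence of each modeled defect exactly at its
    configured value while guaranteeing every defective-grade sample carries
    at least one defect from the sensory vocabulary.
    """
    present = tuple(d for d in ALL_DEFECTS
                    if rng.random() < prevalences.get(d, 0.0))
    if not present:
        present = ("winey",)
    return present


def _draw_label(rng: np.random.Generator, grade: str, idx: int,
                design: StudyDesign) -> SensoryLabel:
    sid = f"{grade}_{idx:03d}"
    if grade == "EVOO":
        return SensoryLabel(sid, grade, (), float(rng.uniform(2.0, 6.0)), 0.0)
    defects = _draw_defects(rng, design.defect_prevalences)
    if grade == "VOO":
        fruity = float(rng.uniform(0.5, 4.0))
        median = float(rng.uniform(0.5, 3.4))
    else:  # LOO: intense defect or no fruitiness
        fruity = float(rng.uniform(0.0, 1.5))
        median = float(rng.uniform(3.5, 8.0))
    return SensoryLabel(sid, grade, defects, fruity, median)


def iter_dataset(design: StudyDesign,
                 profiles: Mapping[str, ClassProfile] | None = None,
                 library: CompoundLibrary | None = None,
                 grid: GridSpec = GridSpec(),
                 ) -> Iterator[tuple[HeatMap, SensoryLabel]]:
    """Lazily generate (heat map, label) pairs for a study design.

    All randomness flows from ``design.seed``; maps can be consumed one at a
    time so a full cohort never needs to reside in memory.
    """
    library = library or default_compound_library()
    if profiles is None:
        profiles = default_profiles(design.effect_scale, library=library)
    for grade in GRADES:
        if grade not in profiles:
            raise KeyError(f"profiles missing grade {grade!r}")
    ss = np.random.SeedSequence(design.seed)
    label_rng = np.random.default_rng(ss.spawn(1)[0])
    counts = {"EVOO": design.n_evoo, "VOO": design.n_voo, "LOO": design.n_loo}
    plan = [(g, i) for g in GRADES for i in range(counts[g])]
    child_seeds = ss.spawn(len(plan) + 1)[1:]
    for (grade, idx), child in zip(plan, child_seeds):
        label = _draw_label(label_rng, grade, idx, design)
        prof = profiles[grade]
        if label.defects:
            dps = [profiles[d] for d in label.defects if d in profiles]
            att = VOO_DEFECT_ATTENUATION if grade == "VOO" else 1.0
            prof = combine_profiles(prof, dps, attenuation=att)
        rng = np.random.default_rng(child)
        conc = sample_concentrations(prof, 1, seed=rng, library=library).iloc[0]
        hmap = render_heatmap(conc.to_dict(), library, design.noise_cv,
                              seed=rng, grid=grid, sample_id=label.sample_id)
        yield hmap, label


def generate_dataset(design: StudyDesign,
                     profiles: Mapping[str, ClassProfile] | None = None,
                     library: CompoundLibrary | None = None,
                     grid: GridSpec = GridSpec(),
                     ) -> tuple[list[HeatMap], list[SensoryLabel]]:
    """Materialize :func:`iter_dataset` into paired lists."""
    maps, labels = [], []
    for m, l in iter_dataset(design, profiles, library, grid):
        maps.append(m)
        labels.append(l)
    return maps, labels


def labels_to_frame(labels: Iterable[SensoryLabel]) -> pd.DataFrame:
    rows = [{
        "sample_id": l.sample_id, "grade": l.grade,
        "musty": int(l.has_defect("musty")), "rancid": int(l.has_defect("rancid")),
        "fusty": int(l.has_defect("fusty")), "winey": int(l.has_defect("winey")),
        "fruity_median": l.fruity_median, "defect_median": l.defect_median,
    } for l in labels]
    return pd.DataFrame(rows).set_index("sample_id")


def labels_from_frame(df: pd.DataFrame) -> list[SensoryLabel]:
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    out = []
    for sid, r in df.iterrows():
        defects = tuple(d for d in ALL_DEFECTS if int(r.get(d, 0)))
        out.append(SensoryLabel(str(sid), str(r["grade"]), defects,
                                float(r["fruity_median"]),
                                float(r["defect_median"])))
    return out


# ------------------------------------------------------------- calibration
def generate_calibration_series(library: CompoundLibrary | None = None,
                                mixture: str = "SMA",
                                noise_cv: float = 0.0,
                                seed: int = 0,
                                grid: GridSpec = GridSpec(),
                                ) -> tuple[list[HeatMap], tuple[float, ...]]:
    """Heat maps of the standard-mixture dilution series.

    SMA: 12 dilutions 0.05-10 mg kg^-1; SMB: 15 dilutions extending to
    25 mg kg^-1.  Each map carries only that mixture's compounds, all at the
    level concentration.
    """
    library = library or default_compound_library()
    if mixture == "SMA":
        levels = SMA_LEVELS
    elif mixture == "SMB":
        levels = SMB_LEVELS
    else:
        raise ValueError(f"unknown mixture code {mixture!r}")
    sub = library.mixture(mixture)
    ss = np.random.SeedSequence(seed)
    maps = []
    for level, child in zip(levels, ss.spawn(len(levels))):
        conc = {name: level for name in sub.names}
        maps.append(render_heatmap(conc, library, noise_cv,
                                   seed=np.random.default_rng(child), grid=grid,
                                   sample_id=f"{mixture}_{level:g}"))
    return maps, levels


# ------------------------------------------------------------ repeatability
#: Marker compounds whose dimer maxima are tracked per quality grade.
REPEATABILITY_MARKERS = {
    "EVOO": ("(E)-2-hexenal", "Hexanal"),
    "VOO": ("Ethanol", "Ethyl acetate"),
    "LOO": ("Ethyl propanoate", "3-methyl-1-butanol"),
}


def simulate_repeatability_maps(grade: str,
                                mode: str = "intra",
                                n: int = 7,
                                noise_cv: float = 0.015,
                                day_effect_cv: float = 0.0,
                                seed: int = 0,
                                library: CompoundLibrary | None = None,
                                profiles: Mapping[str, ClassProfile] | None = None,
                                grid: GridSpec = GridSpec(),
                                ) -> list[HeatMap]:
    """Replicate analyses of one representative sample of a grade.

    Intra-day: the same oil measured ``n`` times on one day (instrument
    noise only).  Inter-day: once per day for ``n`` days, each day sharing a
    multiplicative log-normal response factor with CV ``day_effect_cv``.
    """
    if mode not in ("intra", "inter"):
        raise ValueError(f"mode must be 'intra' or 'inter', got {mode!r}")
    library = library or default_compound_library()
    if profiles is None:
        profiles = default_profiles(library=library)
    ss = np.random.SeedSequence(seed)
    conc_rng = np.random.default_rng(ss.spawn(1)[0])
    grade_prof = profiles[grade]
    if grade == "VOO":
        grade_prof = combine_profiles(grade_prof, [profiles["winey"]],
                                      attenuation=VOO_DEFECT_ATTENUATION)
    elif grade == "LOO":
        grade_prof = combine_profiles(grade_prof, [profiles["fusty"]])
    conc = sample_concentrations(grade_prof, 1, seed=conc_rng,
                                 library=library).iloc[0].to_dict()
    sigma_day = math.sqrt(math.log1p(day_effect_cv**2))
    maps = []
    for i, child in enumerate(ss.spawn(n + 1)[1:]):
        rng = np.random.default_rng(child)
        day = 1.0
        if mode == "inter" and day_effect_cv > 0:
            day = float(np.exp(rng.normal(-0.5 * sigma_day**2, sigma_day)))
        maps.append(render_heatmap(conc, library, noise_cv, seed=rng, grid=grid,
                                   day_factor=day,
                                   sample_id=f"{grade}_{mode}_{i}"))
    return maps
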