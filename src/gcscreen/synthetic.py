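"""Seeded generator of synthetic phage-host co-culture growth curves.

The generator emulates the acquisition protocol of a 96-well plate-reader
screen — 24 h runs sampled every 10 min (145 points) at 37 degC — with
species-specific lysis phenotypes and MOI-dependent onset shifts, so the
whole pipeline (preprocessing, feature extraction, clustering, evaluation)
is exercisable without instrument data.

Curves are piecewise-smooth parametric functions rather than a mechanistic
phage-host ODE: the package under test measures landmarks and clusters, and
the piecewise construction gives analytic ground truth for those landmarks
(onset, maximum lysis rate, bottom level, regrowth timing). An uninfected
control follows logistic growth; an infected well follows logistic growth
until the MOI-shifted lysis onset, then decays exponentially toward the
bottom OD, holds through the regrowth lag, regrows logistically toward the
regrowth capacity and may carry one damped secondary hump (a multi-peak
phenotype driven by resistant subpopulations). Measurement noise is
Gaussian per read plus a constant per-well offset; raw wells additionally
sit on a media background so blank subtraction has work to do.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .plate_io import PlateRun, WellAnnotation
from .preprocess import GrowthCurve

#: 24 h sampled every 10 min -> 145 points.
DEFAULT_GRID = np.arange(0.0, 1441.0, 10.0)
REFERENCE_MOI = 0.01
MEDIA_BASELINE_OD = 0.04
INITIAL_OD = 0.05
#: Decay is treated as complete after this many lysis-rate time constants.
DECAY_SPAN = 5.0


@dataclass
class SpeciesArchetype:
    """Parameter tuple defining one synthetic phage phenotype.

    Rates are per minute, times in minutes, ODs in OD600 units. The lysis
    onset is specified at the reference MOI (0.01); higher MOIs start lysis
    earlier by ``moi_sensitivity`` minutes per log10 fold.
    """

    name: str
    growth_rate: float
    carrying_capacity: float
    lysis_onset: float
    moi_sensitivity: float
    lysis_rate: float
    bottom_od: float
    regrowth_lag: float
    regrowth_capacity: float
    secondary_peak_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.growth_rate <= 0 or self.lysis_rate <= 0:
            raise ValueError(f"{self.name}: rates must be positive")
        if not 0 < self.bottom_od < self.carrying_capacity:
            raise ValueError(f"{self.name}: bottom OD must lie in (0, carrying capacity)")
        if self.regrowth_capacity > self.carrying_capacity:
            raise ValueError(f"{self.name}: regrowth capacity exceeds carrying capacity")
        if self.secondary_peak_amplitude < 0:
            raise ValueError(f"{self.name}: secondary peak amplitude must be >= 0")

    def onset_at(self, moi: float) -> float:
        """Lysis onset time for a given MOI (earlier at higher MOI)."""
        return self.lysis_onset - self.moi_sensitivity * np.log10(moi / REFERENCE_MOI)


@dataclass
class NoiseModel:
    """Measurement noise: per-read Gaussian sd plus a per-well constant offset.

    Defaults approximate the repeatability of a shaken-plate OD600 read.
    """

    read_sd: float = 0.003
    well_offset_sd: float = 0.002

    def __post_init__(self) -> None:
        if self.read_sd < 0 or self.well_offset_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")


ZERO_NOISE = NoiseModel(read_sd=0.0, well_offset_sd=0.0)


def _logistic(t: np.ndarray, od0: float, rate: float, capacity: float) -> np.ndarray:
    e = np.exp(rate * t)
    return capacity * od0 * e / (capacity + od0 * (e - 1.0))


def lysis_trajectory(
    archetype: SpeciesArchetype, moi: float, grid: np.ndarray
) -> np.ndarray:
    """Noise-free infected trajectory (no media baseline)."""
    t_l = archetype.onset_at(moi)
    od_onset = float(
        _logistic(np.array([t_l]), INITIAL_OD, archetype.growth_rate, archetype.carrying_capacity)[0]
    )
    bottom = min(archetype.bottom_od, od_onset)
    t_decay_end = t_l + DECAY_SPAN / archetype.lysis_rate
    t_regrow = t_decay_end + archetype.regrowth_lag

    od = _logistic(grid, INITIAL_OD, archetype.growth_rate, archetype.carrying_capacity)
    lysing = grid >= t_l
    od[lysing] = bottom + (od_onset - bottom) * np.exp(
        -archetype.lysis_rate * (grid[lysing] - t_l)
    )
    regrowing = grid >= t_regrow
    if np.any(regrowing) and archetype.regrowth_capacity > bottom * 1.01:
        od_start = bottom + (od_onset - bottom) * np.exp(
            -archetype.lysis_rate * (t_regrow - t_l)
        )
        od[regrowing] = _logistic(
            grid[regrowing] - t_regrow,
            od_start,
            archetype.growth_rate,
            archetype.regrowth_capacity,
        )
    if archetype.secondary_peak_amplitude > 0:
        t_hump = min(t_regrow + 300.0, grid[-1] - 120.0)
        od += archetype.secondary_peak_amplitude * np.exp(
            -(((grid - t_hump) / 50.0) ** 2)
        )
    return od


def simulate_curve(
    archetype: Optional[SpeciesArchetype],
    moi: Optional[float],
    noise: NoiseModel = ZERO_NOISE,
    grid: np.ndarray = DEFAULT_GRID,
    rng: Optional[np.random.Generator] = None,
    sample_id: str = "sample",
    role: Optional[str] = None,
) -> GrowthCurve:
    """Simulate one well's curve (control when ``moi`` is None).

    Deterministic given the random generator state; a control well must not
    carry an MOI and an infected well must carry a positive one.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    grid = np.asarray(grid, dtype=float)
    if moi is None:
        if archetype is None:
            od = np.zeros_like(grid)  # media blank
            role = role or "blank"
        else:
            od = _logistic(grid, INITIAL_OD, archetype.growth_rate, archetype.carrying_capacity)
            role = role or "control"
    else:
        if moi <= 0:
            raise ValueError("moi must be positive for infected wells")
        if archetype is None:
            raise ValueError("infected wells need an archetype")
        od = lysis_trajectory(archetype, moi, grid)
        role = role or "infected"
    offset = rng.normal(0.0, noise.well_offset_sd) if noise.well_offset_sd > 0 else 0.0
    reads = rng.normal(0.0, noise.read_sd, size=grid.size) if noise.read_sd > 0 else 0.0
    return GrowthCurve(
        times=grid.copy(),
        od=od + offset + reads,
        sample_id=sample_id,
        role=role,
        species=archetype.name if (archetype is not None and moi is not None) else None,
        moi=moi,
    )


def load_archetypes(path: Optional[str | Path] = None) -> list[SpeciesArchetype]:
    """Load an archetype panel from YAML (the packaged default when no path)."""
    if path is None:
        text = (
            importlib.resources.files("gcscreen")
            .joinpath("data", "default7.yaml")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    return [
        SpeciesArchetype(name=name, **params)
        for name, params in cfg["archetypes"].items()
    ]


def default_archetypes() -> list[SpeciesArchetype]:
    return load_archetypes(None)


@dataclass
class SyntheticPanel:
    """A simulated plate plus its ground-truth annotations."""

    run: PlateRun
    annotations: list[WellAnnotation]
    seed: int = 0


def _well_names(n: int) -> list[str]:
    rows = "ABCDEFGH"
    names = [f"{r}{c}" for r in rows for c in range(1, 13)]
    if n > len(names):
        raise ValueError("panel does not fit on a 96-well plate")
    return names[:n]


def simulate_panel(
    archetypes: Optional[Sequence[SpeciesArchetype]] = None,
    replicates: int = 3,
    mois: Sequence[float] = (REFERENCE_MOI,),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    n_blanks: int = 3,
    n_controls: int = 3,
    grid: np.ndarray = DEFAULT_GRID,
) -> SyntheticPanel:
    """Simulate a complete screening plate.

    The default design mirrors a reference-phage validation screen: 7
    archetypes x 3 replicates at MOI 0.01 (21 infected wells) plus 3
    uninfected controls and 3 media blanks. Per-well seeds derive
    deterministically from the master seed, so panels are reproducible and
    independent of well ordering. Raw readings include the media background
    that blank subtraction removes.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    archetypes = list(archetypes)
    if len(archetypes) < 2:
        raise ValueError("need at least two archetypes")
    specs: list[tuple[str, Optional[SpeciesArchetype], Optional[float], str, Optional[int]]] = []
    for b in range(n_blanks):
        specs.append((f"blank_{b + 1}", None, None, "blank", None))
    for c in range(n_controls):
        specs.append((f"control_{c + 1}", None, None, "control", None))
    # controls use the mean growth phenotype of the panel host
    control_arch = archetypes[0]
    for arch in archetypes:
        for moi in mois:
            for rep in range(1, replicates + 1):
                sid = f"{arch.name}_moi{moi:g}_r{rep}"
                specs.append((sid, arch, float(moi), "infected", rep))

    seeds = np.random.SeedSequence(seed).spawn(len(specs))
    wells = _well_names(len(specs))
    readings: dict[str, np.ndarray] = {}
    annotations: list[WellAnnotation] = []
    for (sid, arch, moi, role, rep), well, ss in zip(specs, wells, seeds):
        rng = np.random.default_rng(ss)
        if role == "blank":
            curve = simulate_curve(None, None, noise, grid, rng, sid, role="blank")
        elif role == "control":
            curve = simulate_curve(control_arch, None, noise, grid, rng, sid, role="control")
        else:
            curve = simulate_curve(arch, moi, noise, grid, rng, sid)
        readings[well] = curve.od + MEDIA_BASELINE_OD
        annotations.append(
            WellAnnotation(
                well=well,
                sample_id=sid,
                role=role,
                species=arch.name if role == "infected" else None,
                moi=moi,
                replicate=rep,
            )
        )
    run = PlateRun(times=grid.copy(), readings=readings, plate_id=f"synthetic_seed{seed}")
    return SyntheticPanel(run=run, annotations=annotations, seed=seed)
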