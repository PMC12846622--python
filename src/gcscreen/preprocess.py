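"""Growth-curve preprocessing: blank subtraction, smoothing, alignment, offset.

The pipeline order is fixed and recorded in provenance:

1. blank subtraction — subtract the pointwise mean of all media-only blank
   wells from every non-blank well;
2. Savitzky–Golay smoothing (default window 3, polynomial order 1);
3. time alignment — shift the time axis so that t = 0 falls at the minimum
   of the mean uninfected-control curve;
4. positivity offset — if any OD is negative after the steps above, add the
   absolute value of the global dataset minimum to every reading.

Blank subtraction can push readings below zero; negatives are retained until
the final offset, which guarantees strictly usable values for the ratio- and
area-based features downstream. Alignment never changes OD values, and the
offset never changes differences between readings, so drop magnitude and
drop slope are offset-invariant while absolute levels (OD at bottom, AUC,
the 110% regrowth threshold) are offset-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .plate_io import PlateRun, WellAnnotation


class PreprocessError(ValueError):
    pass


@dataclass
class GrowthCurve:
    """One well's processed OD600 time series plus sample identity."""

    times: np.ndarray
    od: np.ndarray
    sample_id: str
    role: str
    species: Optional[str] = None
    moi: Optional[float] = None
    well: Optional[str] = None
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape:
            raise PreprocessError(
                f"{self.sample_id}: times and od length mismatch"
            )

    def copy_with(self, **kw) -> "GrowthCurve":
        data = dict(
            times=self.times.copy(),
            od=self.od.copy(),
            sample_id=self.sample_id,
            role=self.role,
            species=self.species,
            moi=self.moi,
            well=self.well,
            replicate=self.replicate,
        )
        data.update(kw)
        return GrowthCurve(**data)


@dataclass
class PreprocessProvenance:
    """Parameters and constants produced while preprocessing a dataset."""

    sg_window: int
    sg_order: int
    t_star: float = 0.0
    offset: float = 0.0
    n_blanks: int = 0
    n_controls: int = 0
    steps: list = field(default_factory=list)


def subtract_blank(run: PlateRun, annotations: Sequence[WellAnnotation]) -> PlateRun:
    """Subtract the pointwise mean of blank (media-only) wells.

    Returns a new :class:`PlateRun` containing only the annotated non-blank
    wells; wells on the plate without an annotation are dropped (a partial
    plate is normal). Negative values are retained — the positivity offset
    applied at the end of the pipeline handles them.
    """
    by_well = {a.well: a for a in annotations}
    blanks = [
        run.readings[a.well]
        for a in annotations
        if a.role == "blank" and a.well in run.readings
    ]
    if not blanks:
        raise PreprocessError(
            "no blank wells found: supply wells with role 'blank' or skip blank subtraction"
        )
    blank_mean = np.mean(np.vstack(blanks), axis=0)
    readings = {
        well: series - blank_mean
        for well, series in run.readings.items()
        if well in by_well and by_well[well].role != "blank"
    }
    return PlateRun(times=run.times.copy(), readings=readings, plate_id=run.plate_id)


def smooth_savgol(curve: GrowthCurve, window: int = 3, order: int = 1) -> GrowthCurve:
    """Savitzky–Golay smoothing of one curve.

    With the default (window 3, order 1) filter the interior points equal a
    centered 3-point moving average; boundaries use the one-sided polynomial
    fit, so series length is preserved. Constant and linear signals pass
    through unchanged.
    """
    if window % 2 == 0:
        raise PreprocessError("Savitzky-Golay window must be odd")
    if order >= window:
        raise PreprocessError("polynomial order must be smaller than window")
    if curve.od.size < window:
        raise PreprocessError(
            f"{curve.sample_id}: series length {curve.od.size} < window {window}"
        )
    smoothed = savgol_filter(curve.od, window_length=window, polyorder=order, mode="interp")
    return curve.copy_with(od=smoothed)


def align_time_zero(curves: Sequence[GrowthCurve]) -> tuple[list[GrowthCurve], float]:
    """Shift the time axis so t = 0 sits at the minimum of the mean control curve.

    Returns the shifted curves and the shift t* that was applied. Points
    measured before the control minimum acquire negative times and are
    retained. OD values are untouched.
    """
    controls = [c for c in curves if c.role == "control"]
    if not controls:
        raise PreprocessError("no uninfected control curves: cannot align time axis")
    grid = controls[0].times
    for c in controls[1:]:
        if not np.array_equal(c.times, grid):
            raise PreprocessError("control curves are not on a shared time grid")
    mean_control = np.mean(np.vstack([c.od for c in controls]), axis=0)
    t_star = float(grid[int(np.argmin(mean_control))])
    shifted = [c.copy_with(times=c.times - t_star) for c in curves]
    return shifted, t_star


def ensure_positive_offset(curves: Sequence[GrowthCurve]) -> tuple[list[GrowthCurve], float]:
    """Add a constant so every OD reading in the dataset is non-negative.

    The constant is the absolute value of the global minimum across all
    curves, or 0 if nothing is negative; applying the operation twice is a
    no-op. The offset is a preprocessing constant of the dataset, not a
    fitted parameter, and is reported for provenance.
    """
    if not curves:
        return [], 0.0
    global_min = min(float(np.min(c.od)) for c in curves)
    offset = abs(global_min) if global_min < 0 else 0.0
    if offset == 0.0:
        return [c.copy_with() for c in curves], 0.0
    return [c.copy_with(od=c.od + offset) for c in curves], offset


def curves_from_run(run: PlateRun, annotations: Sequence[WellAnnotation]) -> list[GrowthCurve]:
    """Pair plate wells with their annotations into raw GrowthCurve objects."""
    out = []
    for a in annotations:
        if a.role == "blank" or a.well not in run.readings:
            continue
        out.append(
            GrowthCurve(
                times=run.times.copy(),
                od=run.readings[a.well].copy(),
                sample_id=a.sample_id,
                role=a.role,
                species=a.species,
                moi=a.moi,
                well=a.well,
                replicate=a.replicate,
            )
        )
    return out


def preprocess_dataset(
    run: PlateRun,
    annotations: Sequence[WellAnnotation],
    sg_window: int = 3,
    sg_order: int = 1,
) -> tuple[list[GrowthCurve], PreprocessProvenance]:
    """Run the full pipeline: blank -> smooth -> align -> offset."""
    prov = PreprocessProvenance(sg_window=sg_window, sg_order=sg_order)
    prov.n_blanks = sum(1 for a in annotations if a.role == "blank")
    prov.n_controls = sum(1 for a in annotations if a.role == "control")
    subtracted = subtract_blank(run, annotations)
    prov.steps.append("blank_subtraction")
    curves = curves_from_run(subtracted, annotations)
    curves = [smooth_savgol(c, window=sg_window, order=sg_order) for c in curves]
    prov.steps.append(f"savgol(window={sg_window},order={sg_order})")
    curves, t_star = align_time_zero(curves)
    prov.t_star = t_star
    prov.steps.append(f"align(t*={t_star:g})")
    curves, offset = ensure_positive_offset(curves)
    prov.offset = offset
    prov.steps.append(f"offset({offset:g})")
    return curves, prov
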