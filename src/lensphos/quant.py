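"""Label-free quantitation over centroided LC-MS feature maps.

The workflow mirrors the classic identification-directed label-free design:

1. confident identifications from every run are merged into a global peptide
   list (sequence + modifications + charge, consensus m/z, per-run elution
   times);
2. each run's elution-time axis is aligned to a reference run by linear
   regression on shared identified peptides, followed by additive median
   corrections over fixed-width elution-time segments to absorb local
   chromatographic shifts;
3. for every list entry and run, an extracted ion chromatogram (XIC) is
   reconstructed in a narrow m/z window around the expected elution time —
   identified directly in that run, or cross-assigned through the alignment
   when the peptide was identified only elsewhere;
4. the trapezoidal XIC area is the peptide abundance, and the fold-change is
   the ratio of case (cataract) to control (normal) condition abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GRADIENT = (0.0, 120.0)


@dataclass
class FeatureMap:
    """One run's centroided MS1 points (m/z, retention time, intensity)."""

    run_id: str
    condition: str
    points: pd.DataFrame  # columns: mz, rt, intensity
    gradient: tuple[float, float] = DEFAULT_GRADIENT

    def __post_init__(self) -> None:
        required = {"mz", "rt", "intensity"}
        if not required.issubset(self.points.columns):
            raise ValueError(f"feature map needs columns {sorted(required)}")
        lo, hi = self.gradient
        rt = self.points["rt"].to_numpy()
        if len(rt) and (rt.min() < lo or rt.max() > hi):
            raise ValueError(f"run {self.run_id}: retention times outside gradient {self.gradient}")
        if len(self.points) and (self.points["intensity"].to_numpy() < 0).any():
            raise ValueError(f"run {self.run_id}: negative intensities")
        self.points = self.points.sort_values("rt", kind="stable").reset_index(drop=True)

    @classmethod
    def read_tsv(cls, source, gradient: tuple[float, float] = DEFAULT_GRADIENT) -> list["FeatureMap"]:
        """Load feature maps from a TSV with run_id, condition, mz, rt, intensity."""
        df = pd.read_csv(source, sep="\t", comment="#")
        maps = []
        for (run_id, condition), grp in df.groupby(["run_id", "condition"], sort=False):
            maps.append(cls(str(run_id), str(condition),
                            grp[["mz", "rt", "intensity"]].copy(), gradient))
        return maps

    def to_frame(self) -> pd.DataFrame:
        out = self.points.copy()
        out.insert(0, "condition", self.condition)
        out.insert(0, "run_id", self.run_id)
        return out


@dataclass
class GlobalPeptideEntry:
    """One merged identification: peptide key, consensus m/z, per-run times."""

    key: str
    mz: float
    run_times: dict[str, float]
    flagged: bool = False  # conflicting m/z across runs

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.key}: m/z must be positive")
        if not self.run_times:
            raise ValueError(f"{self.key}: needs at least one run elution time")


def build_global_list(identifications: pd.DataFrame,
                      mz_tolerance: float = 0.05) -> list[GlobalPeptideEntry]:
    """Merge per-run identifications into a global peptide list.

    ``identifications`` columns: run_id, key (sequence+mods+charge), rt, mz.
    Entries are keyed by the peptide key; the consensus m/z is the median of
    the observations, and entries whose observations disagree by more than
    ``mz_tolerance`` are flagged.
    """
    required = {"run_id", "key", "rt", "mz"}
    if not required.issubset(identifications.columns):
        raise ValueError(f"identifications need columns {sorted(required)}")
    entries = []
    for key, grp in identifications.groupby("key", sort=False):
        mzs = grp["mz"].to_numpy(dtype=float)
        if (mzs <= 0).any():
            raise ValueError(f"{key}: nonpositive m/z")
        run_times = {}
        for r in grp.itertuples(index=False):
            run_times[str(r.run_id)] = float(r.rt)  # last observation per run wins
        entries.append(GlobalPeptideEntry(
            key=str(key),
            mz=float(np.median(mzs)),
            run_times=run_times,
            flagged=bool(mzs.max() - mzs.min() > mz_tolerance),
        ))
    return entries


@dataclass
class AlignmentModel:
    """Linear map source-run time -> reference time, plus segment offsets.

    Segments partition the reference-side gradient; each carries an additive
    correction applied after the linear map.
    """

    slope: float
    intercept: float
    segments: tuple[tuple[float, float, float], ...] = ()  # (start, end, offset)

    def linear(self, t):
        return self.slope * np.asarray(t, dtype=float) + self.intercept

    def invert_linear(self, t_ref):
        return (np.asarray(t_ref, dtype=float) - self.intercept) / self.slope

    def segment_offset(self, t_ref):
        t_ref = np.asarray(t_ref, dtype=float)
        off = np.zeros_like(t_ref)
        for start, end, offset in self.segments:
            off = np.where((t_ref >= start) & (t_ref < end), offset, off)
        return off


IDENTITY_ALIGNMENT = AlignmentModel(1.0, 0.0)


def fit_alignment(anchors: Sequence[tuple[float, float]],
                  segment_width: float = 10.0,
                  gradient: tuple[float, float] = DEFAULT_GRADIENT) -> AlignmentModel:
    """Linear regression of reference on source anchor times, then per-segment
    median-residual corrections over the reference gradient.

    The linear part is a Theil-Sen (median-of-pairwise-slopes) fit: localised
    chromatographic shifts affecting a minority of anchors would tilt an
    ordinary least-squares line, whereas the robust line leaves them to the
    segment corrections, which is where they belong. With two anchors both
    estimators reduce to the interpolating line. Segments with no anchors get
    zero correction.
    """
    anchors = np.asarray(anchors, dtype=float)
    if anchors.ndim != 2 or anchors.shape[0] < 2:
        raise ValueError("need at least 2 anchors")
    src, ref = anchors[:, 0], anchors[:, 1]
    if np.ptp(src) == 0:
        raise ValueError("anchors have identical source times")
    if src.size == 2:
        slope = (ref[1] - ref[0]) / (src[1] - src[0])
        intercept = ref[0] - slope * src[0]
    else:
        slope, intercept, *_ = stats.theilslopes(ref, src)
    predicted = slope * src + intercept
    residual = ref - predicted
    lo, hi = gradient
    edges = np.arange(lo, hi + segment_width, segment_width)
    segments = []
    for start, end in zip(edges[:-1], edges[1:]):
        mask = (predicted >= start) & (predicted < end)
        offset = float(np.median(residual[mask])) if mask.any() else 0.0
        segments.append((float(start), float(end), offset))
    return AlignmentModel(float(slope), float(intercept), tuple(segments))


def apply_alignment(model: AlignmentModel, time):
    """Map a source-run time into the reference frame."""
    t_lin = model.linear(time)
    return t_lin + model.segment_offset(t_lin)


def invert_alignment(model: AlignmentModel, t_ref):
    """Approximate inverse: reference-frame time back to the source run."""
    return model.invert_linear(np.asarray(t_ref, dtype=float) - model.segment_offset(t_ref))


def extract_xic(fmap: FeatureMap, mz_center: float, mz_tol: float,
                rt_window: tuple[float, float]) -> pd.DataFrame:
    """All points with |m/z - center| <= tol inside the RT window, RT-ordered."""
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    start, end = rt_window
    if start > end:
        raise ValueError(f"inverted RT window {rt_window}")
    lo, hi = fmap.gradient
    if end < lo or start > hi:
        raise ValueError(f"RT window {rt_window} outside gradient {fmap.gradient}")
    pts = fmap.points
    mask = ((pts["mz"] - mz_center).abs() <= mz_tol) & (pts["rt"] >= start) & (pts["rt"] <= end)
    return pts.loc[mask, ["rt", "intensity"]].reset_index(drop=True)


def xic_area(trace: pd.DataFrame) -> float:
    """Trapezoidal integral of a time/intensity trace (intensity * minutes)."""
    if len(trace) < 2:
        return 0.0
    return float(np.trapezoid(trace["intensity"].to_numpy(), trace["rt"].to_numpy()))


@dataclass
class QuantConfig:
    mz_tol: float = 0.05            # Th
    rt_halfwidth: float = 1.0       # min, XIC window around the expected apex
    segment_width: float = 10.0     # min, alignment correction segments
    gradient: tuple[float, float] = DEFAULT_GRADIENT
    control_condition: str = "normal"
    case_condition: str = "cataract"
    reference_run: Optional[str] = None   # default: first control run
    tic_normalize: bool = False           # total-ion-current scaling, off by default


@dataclass
class QuantResult:
    key: str
    mz: float
    run_areas: dict[str, float]
    control_abundance: Optional[float]
    case_abundance: Optional[float]
    fold_change: Optional[float]
    cross_assigned_runs: tuple[str, ...]
    empty_runs: tuple[str, ...]


def fit_run_alignments(runs: Sequence[FeatureMap],
                       entries: Sequence[GlobalPeptideEntry],
                       config: QuantConfig) -> tuple[str, dict[str, AlignmentModel]]:
    """Alignment model per run against the reference, anchored on shared IDs."""
    if config.reference_run is not None:
        reference = config.reference_run
    else:
        controls = [r.run_id for r in runs if r.condition == config.control_condition]
        reference = controls[0] if controls else runs[0].run_id
    models: dict[str, AlignmentModel] = {reference: IDENTITY_ALIGNMENT}
    for run in runs:
        if run.run_id == reference:
            continue
        anchors = [
            (entry.run_times[run.run_id], entry.run_times[reference])
            for entry in entries
            if run.run_id in entry.run_times and reference in entry.run_times
        ]
        if len(anchors) >= 2 and np.ptp([a[0] for a in anchors]) > 0:
            models[run.run_id] = fit_alignment(anchors, config.segment_width, config.gradient)
        else:
            models[run.run_id] = IDENTITY_ALIGNMENT
    return reference, models


def quantify(runs: Sequence[FeatureMap],
             entries: Sequence[GlobalPeptideEntry],
             config: QuantConfig = QuantConfig()) -> list[QuantResult]:
    """XIC-area quantitation with cross-assignment of unidentified runs.

    For each global-list entry, the expected elution time in a run is its
    identified time there, or — when identified only in other runs — the
    consensus reference-frame time mapped back through that run's alignment
    (the run is then flagged cross-assigned). Condition abundance is the mean
    of replicate areas; the fold-change is case/control and is absent when
    either side has no signal.
    """
    if not runs:
        raise ValueError("no runs")
    conditions = {r.condition for r in runs}
    for cond in (config.control_condition, config.case_condition):
        if cond not in conditions:
            raise ValueError(f"no run with condition {cond!r}")
    reference, models = fit_run_alignments(runs, entries, config)

    tic = {r.run_id: max(float(r.points["intensity"].sum()), 1e-300) for r in runs}
    tic_mean = float(np.mean(list(tic.values())))

    results = []
    for entry in sorted(entries, key=lambda e: e.key):
        # consensus elution time in the reference frame
        ref_times = [
            float(apply_alignment(models[rid], t))
            for rid, t in entry.run_times.items() if rid in models
        ]
        consensus_ref = float(np.median(ref_times))
        run_areas: dict[str, float] = {}
        cross, empty = [], []
        for run in sorted(runs, key=lambda r: r.run_id):
            if run.run_id in entry.run_times:
                expected = entry.run_times[run.run_id]
            else:
                expected = float(invert_alignment(models[run.run_id], consensus_ref))
                cross.append(run.run_id)
            lo = max(expected - config.rt_halfwidth, run.gradient[0])
            hi = min(expected + config.rt_halfwidth, run.gradient[1])
            trace = extract_xic(run, entry.mz, config.mz_tol, (lo, hi))
            area = xic_area(trace)
            if config.tic_normalize:
                area *= tic_mean / tic[run.run_id]
            if area == 0.0:
                empty.append(run.run_id)
            run_areas[run.run_id] = area
        by_cond: dict[str, list[float]] = {}
        for run in runs:
            by_cond.setdefault(run.condition, []).append(run_areas[run.run_id])
        control = float(np.mean(by_cond[config.control_condition]))
        case = float(np.mean(by_cond[config.case_condition]))
        fold = case / control if control > 0 and case > 0 else None
        results.append(QuantResult(
            key=entry.key, mz=entry.mz, run_areas=run_areas,
            control_abundance=control if control > 0 else None,
            case_abundance=case if case > 0 else None,
            fold_change=fold,
            cross_assigned_runs=tuple(cross),
            empty_runs=tuple(empty),
        ))
    return results


def results_to_frame(results: Sequence[QuantResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"key": r.key, "mz": r.mz,
               "control_abundance": r.control_abundance,
               "case_abundance": r.case_abundance,
               "fold_change": r.fold_change,
               "cross_assigned": ";".join(r.cross_assigned_runs),
               "empty_runs": ";".join(r.empty_runs)}
        for rid, area in r.run_areas.items():
            row[f"area_{rid}"] = area
        rows.append(row)
    return pd.DataFrame(rows)
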