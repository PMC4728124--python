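"""End-to-end pipeline: simulate -> analyze -> classify -> stats.

Configuration is a single structured (YAML) file covering every stage;
unknown keys are rejected.  The per-curve analysis keeps rejected curves
(with machine-readable reasons) because the censoring correction needs
the rupture forces of fingerprint-censored traces: every trace ends in
an observable complex rupture even when its fingerprint never unfolded.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Union, get_args, get_origin, get_type_hints

import numpy as np
import pandas as pd
import yaml

from .classify import (
    DOUBLE_WINDOW_CENTER,
    DOUBLE_WINDOW_HALFWIDTH,
    assign_peaks_to_barriers,
    classify_final_event,
)
from .polymer import PolymerParams, tether_equilibrium_force
from .simulate import (
    SimulationConfig,
    generate_dataset,
    read_curve_tsv,
)
from .stats import (
    BiasingReport,
    CorrectionResult,
    EventCounts,
    biasing_report,
    censoring_weights,
    correct_binding_mode_ratio,
    overlap_probability,
)
from .traces import (
    ILOV,
    XYLANASE,
    CurveRejected,
    FingerprintMatch,
    FingerprintSpec,
    ForceCurve,
    RejectionLimits,
    detect_peaks,
    measure_increments,
    preprocess,
    reject_curve,
    screen_fingerprint,
    transform_to_contour_space,
)

__all__ = [
    "ProcessingConfig",
    "StatsConfig",
    "PipelineConfig",
    "RunReport",
    "analyze_curve",
    "analyze_curves",
    "summarize_records",
    "run_pipeline",
]

log = logging.getLogger("smfspipe")


@dataclass(frozen=True)
class ProcessingConfig:
    """Thresholds of the per-curve analysis.

    The default minimum peak count is 2 because the default simulated
    construct carries a single one-step fingerprint domain (fingerprint
    peak + final rupture for a valid single event); constructs with
    multi-substep or multiple fingerprint domains warrant 3.
    """

    baseline_fraction: float = 0.1
    force_cutoff: float = 10.0
    min_drop: float = 20.0
    smooth_window: int = 5
    lookahead: int = 50
    min_separation: int = 20
    kde_bandwidth: float = 1.0
    increment_kde_bandwidth: float = 0.75
    grid_step: float = 0.2
    min_points: int = 20
    prominence_fraction: float = 0.02
    fingerprints: tuple[FingerprintSpec, ...] = (XYLANASE, ILOV)
    allow_substep_summing: bool = True
    double_window_center: float = DOUBLE_WINDOW_CENTER
    double_window_halfwidth: float = DOUBLE_WINDOW_HALFWIDTH
    limits: RejectionLimits = field(
        default_factory=lambda: RejectionLimits(min_peaks=2))


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    bootstrap_replicates: int = 2000
    force_kde_bandwidth: float | None = None
    seed: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    polymer: PolymerParams = field(default_factory=PolymerParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    group: str = "all"

    # -- construction from structured text -----------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build_dataclass(cls, data, path="config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj
        return plain(dataclasses.asdict(self))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _build_dataclass(cls, data: Any, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping for {cls.__name__}")
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    hints = get_type_hints(cls)
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            kwargs[f.name] = _convert(hints[f.name], data[f.name],
                                      f"{path}.{f.name}")
    return cls(**kwargs)


def _convert(tp, val, path: str):
    origin = get_origin(tp)
    if origin is Union:
        args = [a for a in get_args(tp) if a is not type(None)]
        if val is None:
            return None
        tp = args[0]
        origin = get_origin(tp)
    if is_dataclass(tp) and isinstance(val, dict):
        return _build_dataclass(tp, val, path)
    if origin is tuple and isinstance(val, (list, tuple)):
        inner = get_args(tp)[0]
        return tuple(_convert(inner, v, f"{path}[{i}]")
                     for i, v in enumerate(val))
    return val


# ---------------------------------------------------------------------------
# Per-curve analysis
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = [
    "curve_id", "group", "status", "reject_reason", "fingerprint",
    "final_event", "final_increment", "first_rupture_force",
    "final_rupture_force", "relative_force_difference", "fingerprint_force",
    "sub_peak_force", "n_peaks", "n_barriers", "baseline_offset",
]


def _refine_peak_forces(proc, rep, peaks, params) -> list:
    """Re-read each peak force from its fitted WLC branch.

    The barrier contour length pools the whole branch's points, so the
    noise-free force at the drop position follows from the lever/tether
    force balance; this removes most of the single-point force noise from
    the reported rupture forces.  A refinement that disagrees with the raw
    reading by more than 15 pN (misassigned barrier) is discarded.
    """
    barriers = np.sort(np.asarray(rep.barriers, dtype=float))
    if barriers.size == 0:
        return list(peaks)
    peak_map = assign_peaks_to_barriers(rep, peaks)
    refined = {}
    for b_idx, peak in peak_map.items():
        z = peak.extension + peak.force / proc.spring_constant
        try:
            f = tether_equilibrium_force(z, float(barriers[b_idx]),
                                         proc.spring_constant, params)
        except ValueError:
            continue
        if abs(f - peak.force) < 15.0:
            refined[peak.index] = float(f)
    return [dataclasses.replace(p, force=refined[p.index])
            if p.index in refined else p for p in peaks]


def _sub_peak_force(rep, peaks, increments, consumed, center, halfwidth) -> float:
    """Force of the peak that starts the (last) window-sized increment.

    This is the first peak of a double event — the receptor sub-step —
    measurable even on curves later rejected for a missing or late
    fingerprint, which the censoring correction relies on.
    """
    candidates = [i for i, inc in enumerate(increments)
                  if i not in consumed and abs(inc - center) <= halfwidth]
    if not candidates:
        return math.nan
    peak_map = assign_peaks_to_barriers(rep, peaks)
    p = peak_map.get(candidates[-1])
    return float(p.force) if p is not None else math.nan


def analyze_curve(curve: ForceCurve, config: PipelineConfig) -> dict:
    """Run one curve through correction, peak screening, the contour-length
    transform and single/double classification; returns a flat record.

    Rejected curves keep whatever quantities were measurable (peak count,
    final rupture force, final increment) so that downstream censoring
    statistics can use them.
    """
    proc_cfg = config.processing
    rec: dict[str, Any] = {c: math.nan for c in _RECORD_COLUMNS}
    rec.update(curve_id=curve.id, group=config.group, status="rejected",
               reject_reason=None, fingerprint=None, final_event="rejected")
    try:
        processed = preprocess(curve, proc_cfg.baseline_fraction)
    except CurveRejected as err:
        rec["reject_reason"] = err.reason
        return rec
    rec["baseline_offset"] = processed.baseline_offset

    peaks = detect_peaks(processed, min_drop=proc_cfg.min_drop,
                         smooth_window=proc_cfg.smooth_window,
                         lookahead=proc_cfg.lookahead,
                         min_separation=proc_cfg.min_separation)
    rec["n_peaks"] = len(peaks)
    if peaks:
        rec["final_rupture_force"] = peaks[-1].force

    try:
        rep = transform_to_contour_space(
            processed, config.polymer,
            force_cutoff=proc_cfg.force_cutoff,
            bandwidth=proc_cfg.kde_bandwidth,
            grid_step=proc_cfg.grid_step,
            min_points=proc_cfg.min_points,
            prominence_fraction=proc_cfg.prominence_fraction)
    except CurveRejected as err:
        rec["reject_reason"] = err.reason
        return rec
    rec["n_barriers"] = rep.barriers.size
    increments = measure_increments(rep)
    if increments.size:
        rec["final_increment"] = float(increments[-1])
    peaks = _refine_peak_forces(processed, rep, peaks, config.polymer)
    if peaks:
        rec["final_rupture_force"] = peaks[-1].force

    match = FingerprintMatch(False)
    for spec in proc_cfg.fingerprints:
        match = screen_fingerprint(increments, spec,
                                   proc_cfg.allow_substep_summing)
        if match.found:
            break
    rec["sub_peak_force"] = _sub_peak_force(
        rep, peaks, increments, set(match.consumed),
        proc_cfg.double_window_center, proc_cfg.double_window_halfwidth)

    keep, reason = reject_curve(peaks, proc_cfg.limits)
    if not keep:
        rec["reject_reason"] = reason
        log.debug("curve %s rejected: %s", curve.id, reason)
        return rec

    cls = classify_final_event(rep, peaks, match,
                               window_center=proc_cfg.double_window_center,
                               window_halfwidth=proc_cfg.double_window_halfwidth,
                               curve_id=curve.id)
    rec.update(
        status="classified" if cls.final_event != "rejected" else "rejected",
        reject_reason=cls.reject_reason,
        fingerprint=cls.fingerprint,
        final_event=cls.final_event,
        final_increment=cls.final_increment,
        first_rupture_force=cls.first_rupture_force,
        final_rupture_force=cls.final_rupture_force,
        relative_force_difference=cls.relative_force_difference,
        fingerprint_force=cls.fingerprint_force,
    )
    return rec


def analyze_curves(curves, config: PipelineConfig) -> pd.DataFrame:
    """Analyze an iterable of ForceCurve objects into a record table."""
    records = [analyze_curve(c, config) for c in curves]
    return pd.DataFrame.from_records(records, columns=_RECORD_COLUMNS)


# ---------------------------------------------------------------------------
# Dataset-level statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    counts: EventCounts
    double_fraction: float
    force_differences: np.ndarray
    correction: CorrectionResult | None
    biasing: BiasingReport | None


@dataclass(frozen=True)
class RunReport:
    n_input: int
    n_classified: int
    rejected_by_reason: dict[str, int]
    groups: dict[str, GroupSummary]
    config_hash: str
    seed: int | None

    def reconciles(self) -> bool:
        return self.n_input == self.n_classified + sum(
            self.rejected_by_reason.values())

    def to_dict(self) -> dict:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, float) and math.isnan(obj):
                return None
            return obj
        return {
            "n_input": self.n_input,
            "n_classified": self.n_classified,
            "rejected_by_reason": dict(self.rejected_by_reason),
            "groups": {g: enc(s) for g, s in self.groups.items()},
            "config_hash": self.config_hash,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True,
                      allow_nan=False, default=lambda o: None)


_CENSOR_REASONS = ("no_fingerprint", "early_double", "too_few_peaks")


def _censoring_pools(df: pd.DataFrame
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Force pools that identify the class survival probabilities.

    A single event survives fingerprint screening when the fingerprint
    unfolds below its (final) rupture force; a countable double survives
    when the fingerprint unfolds below its sub-step (first-peak) force.
    Both the per-class barrier forces and the pooled final rupture forces
    are observable on every trace — kept, fingerprint-censored or
    early-double — so the pools below are free of the selection bias that
    affects the kept curves alone.

    Returns (fingerprint_forces, single_ruptures, double_sub_forces,
    all_final_ruptures).
    """
    accepted = df[df["final_event"].isin(["single", "double"])]
    # every measured fingerprint force counts, including curves later
    # excluded as early doubles: the only selection acting on a
    # fingerprint draw is that the complex survived past it (IPW below)
    fp = df["fingerprint_force"].to_numpy(dtype=float)
    fp = fp[np.isfinite(fp)]

    excluded = df[df["final_event"].eq("rejected")
                  & df["reject_reason"].isin(_CENSOR_REASONS)]
    sub_all = excluded["sub_peak_force"].to_numpy(dtype=float)
    is_double_like = np.isfinite(sub_all)

    singles = np.concatenate([
        accepted.loc[accepted["final_event"].eq("single"),
                     "final_rupture_force"].to_numpy(dtype=float),
        excluded["final_rupture_force"].to_numpy(dtype=float)[~is_double_like],
    ])
    singles = singles[np.isfinite(singles)]
    doubles = np.concatenate([
        accepted.loc[accepted["final_event"].eq("double"),
                     "sub_peak_force"].to_numpy(dtype=float),
        sub_all[is_double_like],
    ])
    doubles = doubles[np.isfinite(doubles)]
    ruptures = df["final_rupture_force"].to_numpy(dtype=float)
    ruptures = ruptures[np.isfinite(ruptures)]
    return fp, singles, doubles, ruptures


def summarize_records(df: pd.DataFrame, config: PipelineConfig,
                      seed: int | None = None) -> RunReport:
    """Dataset-level statistics from a per-curve record table."""
    st = config.stats
    seed = st.seed if seed is None else seed
    rejected = df[df["status"].ne("classified")]
    reasons = rejected["reject_reason"].fillna("unknown").value_counts().to_dict()
    groups: dict[str, GroupSummary] = {}
    for gname, gdf in df.groupby("group", sort=False):
        acc = gdf[gdf["final_event"].isin(["single", "double"])]
        n_s = int(acc["final_event"].eq("single").sum())
        n_d = int(acc["final_event"].eq("double").sum())
        if n_s + n_d == 0:
            groups[str(gname)] = GroupSummary(
                counts=EventCounts(0, 0, st.alpha),
                double_fraction=math.nan,
                force_differences=np.empty(0),
                correction=None, biasing=None)
            continue
        counts = EventCounts.from_counts(n_s, n_d, st.alpha)
        fdiff = acc.loc[acc["final_event"].eq("double"),
                        "relative_force_difference"].dropna().to_numpy(dtype=float)

        correction = None
        biasing = None
        fp, singles, doubles, all_ruptures = _censoring_pools(gdf)
        if fp.size and singles.size and doubles.size and n_s and n_d:
            w = censoring_weights(fp, all_ruptures)
            floor = 1.0 / (fp.size + 1)
            o_s = min(1.0, max(floor, overlap_probability(fp, singles, w)))
            o_d = min(1.0, max(floor, overlap_probability(fp, doubles, w)))
            correction = correct_binding_mode_ratio(
                counts, o_s, o_d,
                bootstrap_replicates=st.bootstrap_replicates, seed=seed,
                force_samples={"fingerprint": fp, "fingerprint_weights": w,
                               "singles": singles, "doubles": doubles})
        # the biasing comparison conditions on termination class, not on
        # countability: an early double (sub-step before fingerprint) is
        # still a double-terminated curve with a measurable fingerprint
        # force, even though the counting statistics must exclude it
        fp_s = acc.loc[acc["final_event"].eq("single"),
                       "fingerprint_force"].dropna().to_numpy(dtype=float)
        fp_d = np.concatenate([
            acc.loc[acc["final_event"].eq("double"),
                    "fingerprint_force"].dropna().to_numpy(dtype=float),
            gdf.loc[gdf["reject_reason"].eq("early_double"),
                    "fingerprint_force"].dropna().to_numpy(dtype=float),
        ])
        if fp_s.size and fp_d.size:
            biasing = biasing_report(fp_s, fp_d, st.force_kde_bandwidth)
        groups[str(gname)] = GroupSummary(
            counts=counts,
            double_fraction=counts.p_double,
            force_differences=fdiff,
            correction=correction,
            biasing=biasing,
        )
    return RunReport(
        n_input=len(df),
        n_classified=int(df["status"].eq("classified").sum()),
        rejected_by_reason={str(k): int(v) for k, v in reasons.items()},
        groups=groups,
        config_hash=config.config_hash(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# End-to-end runs
# ---------------------------------------------------------------------------

def _load_directory(in_dir: str | Path) -> list[ForceCurve]:
    in_dir = Path(in_dir)
    curves = []
    for path in sorted(in_dir.glob("*.tsv")):
        try:
            curves.append(read_curve_tsv(path))
        except (ValueError, OSError) as err:
            log.warning("skipping malformed curve file %s: %s", path, err)
    return curves


def run_pipeline(config: PipelineConfig, in_dir: str | Path | None = None,
                 n_simulate: int | None = None, seed: int | None = None,
                 out_dir: str | Path | None = None) -> tuple[RunReport, pd.DataFrame]:
    """Full workflow on an input directory or a fresh simulation.

    Returns the run report and the per-curve record table; when `out_dir`
    is given, persists results.csv, rejected.csv and report.json.
    """
    if (in_dir is None) == (n_simulate is None):
        raise ValueError("provide exactly one of in_dir / n_simulate")
    if in_dir is not None:
        curves = _load_directory(in_dir)
    else:
        dataset, _ = generate_dataset(config.simulation, n_simulate, seed=seed)
        curves = [c for c, _ in dataset]
    log.info("analyzing %d curves", len(curves))
    records = analyze_curves(curves, config)
    report = summarize_records(records, config, seed=seed)
    if not report.reconciles():
        raise AssertionError("stage counts do not reconcile")
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        records.to_csv(outp / "results.csv", index=False)
        records[records["status"].ne("classified")].to_csv(
            outp / "rejected.csv", index=False)
        report.to_json(outp / "report.json")
    n_rej = report.n_input - report.n_classified
    log.info("classified %d curves, rejected %d", report.n_classified, n_rej)
    return report, records
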