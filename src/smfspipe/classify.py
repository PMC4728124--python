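"""Final-event classification: single vs double complex rupture.

A curve that shows a fingerprint increment is classified by the contour
increment between its last two barrier positions: an increment inside the
8 +- 4 nm window marks a double event (binding mode A, the receptor
sub-step fired before the final rupture); anything else is a single event
(binding mode B, or a mode-A complex that passed both barriers together).
Curves without a fingerprint are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .traces import ContourRepresentation, FingerprintMatch, Peak

__all__ = [
    "DOUBLE_WINDOW_CENTER",
    "DOUBLE_WINDOW_HALFWIDTH",
    "CurveClassification",
    "classify_final_event",
    "relative_force_difference",
    "tabulate_events",
]

#: Contour-length window for the receptor sub-step of a double event, nm.
DOUBLE_WINDOW_CENTER = 8.0
DOUBLE_WINDOW_HALFWIDTH = 4.0


@dataclass(frozen=True)
class CurveClassification:
    """Per-curve verdict of the single/double screening."""

    curve_id: str
    fingerprint: str | None
    final_event: str                 # "single" | "double" | "rejected"
    final_increment: float           # nm; NaN when < 2 barriers
    first_rupture_force: float       # pN; NaN unless double
    final_rupture_force: float       # pN
    relative_force_difference: float  # percent; NaN unless double
    fingerprint_force: float         # pN; NaN when not identified
    reject_reason: str | None = None

    @property
    def shielded(self) -> bool:
        """Double event whose final peak is weaker than its first peak."""
        return (self.final_event == "double"
                and self.relative_force_difference < 0)


def relative_force_difference(first_force: float, final_force: float) -> float:
    """Percentual difference of the final vs the first rupture peak force.

    100 * (final - first) / first; positive values indicate a stronger
    final peak, negative values a shielded double event.
    """
    if first_force <= 0:
        raise ValueError("first_force must be > 0")
    return 100.0 * (final_force - first_force) / first_force


def assign_peaks_to_barriers(rep: ContourRepresentation,
                             peaks: Sequence[Peak]) -> dict[int, Peak]:
    """Map each barrier index to the last peak whose contour level is nearest.

    A rupture peak sits at the top of its contour branch, so its contour
    value (looked up from the retained points at/before the peak index)
    identifies the barrier it terminates.
    """
    barriers = np.sort(np.asarray(rep.barriers, dtype=float))
    out: dict[int, Peak] = {}
    if barriers.size == 0:
        return out
    for peak in peaks:
        pos = np.searchsorted(rep.point_index, peak.index, side="right") - 1
        if pos < 0:
            continue
        c = rep.contour[pos]
        b = int(np.argmin(np.abs(barriers - c)))
        out[b] = peak  # later peaks overwrite; each barrier keeps its last peak
    return out


def classify_final_event(rep: ContourRepresentation, peaks: Sequence[Peak],
                         fingerprint: FingerprintMatch,
                         window_center: float = DOUBLE_WINDOW_CENTER,
                         window_halfwidth: float = DOUBLE_WINDOW_HALFWIDTH,
                         curve_id: str = "") -> CurveClassification:
    """Classify the final rupture of an accepted curve.

    Requires the fingerprint screen verdict; without a fingerprint the
    curve is rejected regardless of its increments.  Rupture forces are
    read from the detected peaks (the final rupture is the last peak, the
    first peak of a double is the one preceding it).
    """
    barriers = np.sort(np.asarray(rep.barriers, dtype=float))
    increments = np.diff(barriers)
    final_increment = float(increments[-1]) if increments.size else math.nan

    if len(peaks) == 0:
        return CurveClassification(curve_id, None, "rejected", final_increment,
                                   math.nan, math.nan, math.nan, math.nan,
                                   reject_reason="no_final_peak")

    final_force = float(peaks[-1].force)

    # fingerprint unfolding force: peak terminating the barrier at the
    # start of the consumed increment run
    fp_force = math.nan
    if fingerprint.found and fingerprint.consumed:
        peak_map = assign_peaks_to_barriers(rep, peaks)
        p = peak_map.get(fingerprint.consumed[0])
        if p is not None:
            fp_force = float(p.force)

    if not fingerprint.found:
        return CurveClassification(curve_id, None, "rejected", final_increment,
                                   math.nan, final_force, math.nan, math.nan,
                                   reject_reason="no_fingerprint")

    is_double = (increments.size > 0
                 and abs(final_increment - window_center) <= window_halfwidth)

    # A window-sized increment before the fingerprint marks a double event
    # whose receptor sub-step fired before fingerprint unfolding; such
    # curves are excluded from the counting statistics rather than being
    # miscounted as singles.
    if not is_double:
        consumed = set(fingerprint.consumed)
        early = [i for i, inc in enumerate(increments[:-1] if increments.size
                                           else [])
                 if i not in consumed
                 and abs(inc - window_center) <= window_halfwidth]
        if early:
            return CurveClassification(curve_id, fingerprint.name, "rejected",
                                       final_increment, math.nan, final_force,
                                       math.nan, fp_force,
                                       reject_reason="early_double")
    if is_double and len(peaks) >= 2:
        first_force = float(peaks[-2].force)
        rel = relative_force_difference(first_force, final_force)
    elif is_double:
        # double-sized increment but only one peak resolvable: cannot
        # quantify the force relation
        first_force = math.nan
        rel = math.nan
    else:
        first_force = math.nan
        rel = math.nan

    return CurveClassification(
        curve_id=curve_id,
        fingerprint=fingerprint.name,
        final_event="double" if is_double else "single",
        final_increment=final_increment,
        first_rupture_force=first_force,
        final_rupture_force=final_force,
        relative_force_difference=rel,
        fingerprint_force=fp_force,
    )


def tabulate_events(classifications: Sequence[CurveClassification],
                    groups: Sequence[str] | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Per-group event counts and force-difference samples.

    `groups` assigns a variant label to each classification (one label per
    curve, default: a single group "all").  Returns a counts table with
    one row per group (n_single, n_double, n_rejected, double_fraction)
    and, per group, the relative force differences of its double events.
    """
    if groups is None:
        groups = ["all"] * len(classifications)
    if len(groups) != len(classifications):
        raise ValueError("groups must match classifications in length")
    rows = []
    diffs: dict[str, np.ndarray] = {}
    order = list(dict.fromkeys(groups))
    for g in order:
        cls = [c for c, gg in zip(classifications, groups) if gg == g]
        n_single = sum(c.final_event == "single" for c in cls)
        n_double = sum(c.final_event == "double" for c in cls)
        n_rejected = sum(c.final_event == "rejected" for c in cls)
        accepted = n_single + n_double
        rows.append({
            "group": g,
            "n_single": n_single,
            "n_double": n_double,
            "n_rejected": n_rejected,
            "double_fraction": n_double / accepted if accepted else math.nan,
        })
        diffs[g] = np.array([c.relative_force_difference for c in cls
                             if c.final_event == "double"
                             and not math.isnan(c.relative_force_difference)])
    columns = ["group", "n_single", "n_double", "n_rejected", "double_fraction"]
    return pd.DataFrame(rows, columns=columns).set_index("group"), diffs
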