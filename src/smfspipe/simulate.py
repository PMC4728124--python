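"""Synthetic force-extension trace generator.

Emulates constant-speed AFM pulling on a PEG-tethered fingerprint-domain /
receptor-ligand (Coh:Doc) construct with a latent dual binding mode:

* the tether stretches as a WLC with fixed persistence length;
* a fingerprint domain (xylanase-like 89 nm or iLOV-like 36 nm contour
  gain) unfolds at a Bell-Evans-distributed force;
* the complex ruptures either as a single event (binding mode B) or as a
  double event with an ~8 nm contour sub-step (binding mode A);
* a trace whose complex ruptures before the fingerprint unfolded lacks
  the fingerprint increment and is naturally censored downstream.

The generator uses a threshold-order model: one rupture force is sampled
per intact barrier from the analytic Bell-Evans distribution at the
nominal loading rate; as the extension ramps, whichever outstanding
threshold is reached first fires.  A mode-A complex whose final threshold
falls below its sub-step threshold therefore presents as an apparent
single event (both barriers pass together).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .polymer import (
    BellEvansParams,
    LoadingContext,
    PolymerParams,
    bell_evans_params_for_mode,
    sample_rupture_forces,
    tether_equilibrium_force,
    wlc_inverse_extension,
)
from .traces import ForceCurve

__all__ = [
    "DomainSpec",
    "ComplexSpec",
    "SimulationConfig",
    "SimEvent",
    "GroundTruth",
    "xylanase_domain",
    "xylanase_domain_substeps",
    "ilov_domain",
    "cbm_domain",
    "default_complex",
    "generate_trace",
    "generate_dataset",
    "sample_event_table",
    "write_curve_tsv",
    "read_curve_tsv",
    "MANIFEST_NAME",
]

# Default loading context for barrier calibration: 800 nm/s pulling speed
# against an effective tether stiffness of 15 pN/nm.
_DEFAULT_LOADING = LoadingContext(pulling_speed=800.0, effective_stiffness=15.0)

# Most-probable rupture forces (pN, at 800 nm/s) the default barriers are
# calibrated to: single-event complex ruptures peak near 104 pN and double
# finals near 140 pN; the sub-step barrier sits ~15% below the mode-A
# final.  The iLOV barrier is placed in the same force range as the
# ruptures (conditional unfolding modes near 96/103 pN), the xylanase
# barrier higher so that it unfolds below a single rupture with
# probability ~0.4.
SINGLE_FSTAR = 104.0
DOUBLE_FINAL_FSTAR = 140.0
SUB_FSTAR = 120.0
ILOV_FSTAR = 103.0
XYLANASE_FSTAR = 108.3
CBM_FSTAR = 170.0
_DELTA_X = 0.4


@dataclass(frozen=True)
class DomainSpec:
    """An unfoldable domain: contour gain (nm) and its rupture barrier."""

    name: str
    contour_gain: float
    barrier: BellEvansParams

    def __post_init__(self) -> None:
        if self.contour_gain < 0:
            raise ValueError("contour_gain must be >= 0")


@dataclass(frozen=True)
class ComplexSpec:
    """Dual-binding-mode receptor-ligand complex.

    Mode A (probability `mode_A_probability`) carries an internal sub-step
    barrier releasing `sub_contour_gain` nm of contour before the final
    rupture; mode B ruptures in a single step.
    """

    mode_A_probability: float
    sub_barrier: BellEvansParams
    final_barrier_A: BellEvansParams
    final_barrier_B: BellEvansParams
    sub_contour_gain: float = 7.6

    def __post_init__(self) -> None:
        if not 0.0 <= self.mode_A_probability <= 1.0:
            raise ValueError("mode_A_probability must be in [0, 1]")
        if self.sub_contour_gain < 0:
            raise ValueError("sub_contour_gain must be >= 0")


def xylanase_domain(loading: LoadingContext = _DEFAULT_LOADING) -> DomainSpec:
    """Xylanase fingerprint: one-step ~89 nm contour gain."""
    return DomainSpec("xylanase", 89.0,
                      bell_evans_params_for_mode(XYLANASE_FSTAR, _DELTA_X, loading))


def xylanase_domain_substeps(loading: LoadingContext = _DEFAULT_LOADING) -> tuple[DomainSpec, DomainSpec]:
    """Two-substep xylanase variant (45 + 44 nm); screening must sum them."""
    b = bell_evans_params_for_mode(XYLANASE_FSTAR, _DELTA_X, loading)
    b2 = bell_evans_params_for_mode(XYLANASE_FSTAR - 15.0, _DELTA_X, loading)
    return (DomainSpec("xylanase_sub1", 45.0, b),
            DomainSpec("xylanase_sub2", 44.0, b2))


def ilov_domain(loading: LoadingContext = _DEFAULT_LOADING) -> DomainSpec:
    """iLOV fingerprint: one-step 36 nm contour gain, unfolding forces in
    the same range as the complex ruptures (effective biasing)."""
    return DomainSpec("iLOV", 36.0,
                      bell_evans_params_for_mode(ILOV_FSTAR, _DELTA_X, loading))


def cbm_domain(loading: LoadingContext = _DEFAULT_LOADING) -> DomainSpec:
    """CBM marker: ~57 nm gain with a barrier above typical rupture forces,
    so its unfolding is only rarely observed."""
    return DomainSpec("CBM", 57.0,
                      bell_evans_params_for_mode(CBM_FSTAR, _DELTA_X, loading))


def default_complex(mode_A_probability: float = 0.5,
                    loading: LoadingContext = _DEFAULT_LOADING,
                    sub_fstar: float = SUB_FSTAR) -> ComplexSpec:
    return ComplexSpec(
        mode_A_probability=mode_A_probability,
        sub_barrier=bell_evans_params_for_mode(sub_fstar, _DELTA_X, loading),
        final_barrier_A=bell_evans_params_for_mode(DOUBLE_FINAL_FSTAR, _DELTA_X, loading),
        final_barrier_B=bell_evans_params_for_mode(SINGLE_FSTAR, _DELTA_X, loading),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated pulling experiment."""

    linker_contour: float = 60.0
    polymer: PolymerParams = field(default_factory=PolymerParams)
    fingerprint: DomainSpec = field(default_factory=xylanase_domain)
    extra_domains: tuple[DomainSpec, ...] = ()
    complex: ComplexSpec = field(default_factory=default_complex)
    pulling_speed: float = 800.0
    spring_constant: float = 100.0
    effective_stiffness: float = 15.0
    force_noise_sd: float = 5.0
    sample_spacing: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("linker_contour", "pulling_speed", "spring_constant",
                     "effective_stiffness", "force_noise_sd", "sample_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def loading(self) -> LoadingContext:
        return LoadingContext(self.pulling_speed, self.effective_stiffness)


@dataclass(frozen=True)
class SimEvent:
    """One realised event: barrier name, where it fired and what it did."""

    name: str
    extension: float
    peak_force: float
    force_drop: float
    contour_gain: float


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side latent record for one trace."""

    curve_id: str
    binding_mode: str                      # "A" | "B"
    thresholds: dict[str, float]           # sampled rupture force per barrier
    events: tuple[SimEvent, ...]           # events that actually fired, in order
    fingerprint_unfolded: bool
    apparent_event: str                    # "single" | "double"
    countable_double: bool = False         # double with fingerprint before sub-step
    degenerate: bool = False

    @property
    def censored(self) -> bool:
        """True when the complex ruptured before the fingerprint unfolded."""
        return not self.fingerprint_unfolded

    @property
    def early_double(self) -> bool:
        """Double whose sub-step fired before the fingerprint unfolded.

        The analysis excludes such curves (the 8 nm increment precedes the
        fingerprint increment), so they are not countable doubles.
        """
        return self.apparent_event == "double" and not self.countable_double


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

def generate_trace(config: SimulationConfig, rng: np.random.Generator,
                   curve_id: str = "curve") -> tuple[ForceCurve, GroundTruth]:
    """Simulate one retraction trace and its latent ground truth."""
    loading = config.loading
    mode = "A" if rng.uniform() < config.complex.mode_A_probability else "B"

    def draw(barrier: BellEvansParams) -> float:
        return float(sample_rupture_forces(barrier, loading, 1, rng,
                                           kBT=config.polymer.kBT)[0])

    barriers: list[tuple[str, float | None, float]] = [
        (config.fingerprint.name, config.fingerprint.contour_gain,
         draw(config.fingerprint.barrier)),
    ]
    for dom in config.extra_domains:
        barriers.append((dom.name, dom.contour_gain, draw(dom.barrier)))
    if mode == "A":
        barriers.append(("complex_sub", config.complex.sub_contour_gain,
                         draw(config.complex.sub_barrier)))
        final_thr = draw(config.complex.final_barrier_A)
    else:
        final_thr = draw(config.complex.final_barrier_B)
    barriers.append(("complex_final", None, final_thr))
    thresholds = {name: thr for name, _, thr in barriers}

    # Only barriers weaker than the final rupture ever fire.
    firing = sorted((thr, name, gain) for name, gain, thr in barriers
                    if thr < final_thr or name == "complex_final")

    contour_at_final = config.linker_contour + sum(
        gain for thr, name, gain in firing if gain is not None)
    x_final = wlc_inverse_extension(final_thr, contour_at_final, config.polymer)
    z_rupture = x_final + final_thr / config.spring_constant
    # leave a post-rupture baseline segment (>= 20% of the trace) so the
    # trailing-window zero-force estimate sees only ruptured baseline
    z_max = z_rupture + max(5.0, 0.25 * z_rupture)
    z = np.arange(config.sample_spacing, z_max, config.sample_spacing)

    force = np.zeros_like(z)
    contour = config.linker_contour
    start = 0
    events: list[SimEvent] = []
    degenerate = False
    for thr, name, gain in firing:
        seg = tether_equilibrium_force(z[start:], contour,
                                       config.spring_constant, config.polymer)
        hit = np.flatnonzero(seg >= thr)
        if hit.size == 0:
            force[start:] = seg
            degenerate = True
            break
        i = start + int(hit[0])
        force[start:i + 1] = seg[:hit[0] + 1]
        peak_f = force[i]
        x_peak = z[i] - peak_f / config.spring_constant
        if name == "complex_final":
            force[i + 1:] = 0.0
            events.append(SimEvent(name, float(x_peak), float(peak_f),
                                   float(peak_f), 0.0))
            break
        contour += gain
        if i + 1 < z.size:
            f_after = tether_equilibrium_force(
                z[i + 1:i + 2], contour, config.spring_constant,
                config.polymer)[0]
        else:
            f_after = 0.0
        events.append(SimEvent(name, float(x_peak), float(peak_f),
                               float(peak_f - f_after), float(gain)))
        start = i + 1
        if start >= z.size:
            degenerate = True
            break

    if config.force_noise_sd > 0:
        force = force + rng.normal(0.0, config.force_noise_sd, size=force.size)

    fired = [ev.name for ev in events]
    is_double = mode == "A" and "complex_sub" in fired
    fp_name = config.fingerprint.name
    truth = GroundTruth(
        curve_id=curve_id,
        binding_mode=mode,
        thresholds=thresholds,
        events=tuple(events),
        fingerprint_unfolded=fp_name in fired,
        apparent_event="double" if is_double else "single",
        countable_double=(is_double and fp_name in fired
                          and fired.index(fp_name) < fired.index("complex_sub")),
        degenerate=degenerate,
    )
    curve = ForceCurve(piezo_position=z, force=force,
                       spring_constant=config.spring_constant,
                       pulling_speed=config.pulling_speed, id=curve_id)
    return curve, truth


def _curve_rng(seed: int, index: int) -> np.random.Generator:
    """Per-curve substream derived from the root seed by counter."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(index,)))


MANIFEST_NAME = "manifest.csv"


def _truth_row(truth: GroundTruth, filename: str) -> dict:
    return {
        "file": filename,
        "curve_id": truth.curve_id,
        "binding_mode": truth.binding_mode,
        "apparent_event": truth.apparent_event,
        "countable_double": truth.countable_double,
        "fingerprint_unfolded": truth.fingerprint_unfolded,
        "degenerate": truth.degenerate,
        "n_events": len(truth.events),
        "thresholds": json.dumps(truth.thresholds, sort_keys=True),
    }


def generate_dataset(config: SimulationConfig, n: int, seed: int | None = None,
                     out_dir: str | Path | None = None,
                     ) -> tuple[list[tuple[ForceCurve, GroundTruth]], pd.DataFrame]:
    """Simulate `n` traces with per-curve substreams of the root seed.

    Returns the traces plus a one-row-per-curve manifest.  When `out_dir`
    is given, each curve is written as a TSV file and the manifest as CSV.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    root = config.seed if seed is None else seed
    dataset = []
    rows = []
    outp = Path(out_dir) if out_dir is not None else None
    if outp is not None:
        outp.mkdir(parents=True, exist_ok=True)
    for i in range(n):
        cid = f"curve_{i:05d}"
        curve, truth = generate_trace(config, _curve_rng(root, i), curve_id=cid)
        fname = f"{cid}.tsv"
        dataset.append((curve, truth))
        row = _truth_row(truth, fname)
        row["seed"] = root
        row["substream"] = i
        rows.append(row)
        if outp is not None:
            write_curve_tsv(outp / fname, curve, extra_meta={"seed": root,
                                                             "substream": i})
    manifest = pd.DataFrame(rows)
    if outp is not None:
        manifest.to_csv(outp / MANIFEST_NAME, index=False)
    return dataset, manifest


# ---------------------------------------------------------------------------
# Fast barrier-level sampling (no trace synthesis)
# ---------------------------------------------------------------------------

def sample_event_table(config: SimulationConfig, n: int, seed: int | None = None
                       ) -> pd.DataFrame:
    """Sample the latent barrier thresholds for `n` traces, vectorised.

    Produces the same per-trace event statistics as `generate_dataset`
    (binding mode, apparent class, censoring, fingerprint/rupture forces)
    without synthesising force curves; used for statistical studies where
    only the event-level quantities matter.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loading = config.loading
    kbt = config.polymer.kBT
    mode_a = rng.uniform(size=n) < config.complex.mode_A_probability
    f_fp = sample_rupture_forces(config.fingerprint.barrier, loading, n, rng, kBT=kbt)
    f_sub = sample_rupture_forces(config.complex.sub_barrier, loading, n, rng, kBT=kbt)
    f_a = sample_rupture_forces(config.complex.final_barrier_A, loading, n, rng, kBT=kbt)
    f_b = sample_rupture_forces(config.complex.final_barrier_B, loading, n, rng, kBT=kbt)
    f_final = np.where(mode_a, f_a, f_b)
    sub_fired = mode_a & (f_sub < f_final)
    return pd.DataFrame({
        "binding_mode": np.where(mode_a, "A", "B"),
        "fingerprint_threshold": f_fp,
        "sub_threshold": np.where(mode_a, f_sub, np.nan),
        "final_threshold": f_final,
        "apparent_event": np.where(sub_fired, "double", "single"),
        "countable_double": sub_fired & (f_fp < f_sub),
        "fingerprint_unfolded": f_fp < f_final,
        "first_rupture_force": np.where(sub_fired, f_sub, f_final),
    })


# ---------------------------------------------------------------------------
# Curve file I/O (two-column TSV with '#' metadata header)
# ---------------------------------------------------------------------------

def write_curve_tsv(path: str | Path, curve: ForceCurve,
                    extra_meta: dict | None = None) -> None:
    path = Path(path)
    meta = {
        "id": curve.id,
        "spring_constant_pN_per_nm": curve.spring_constant,
        "pulling_speed_nm_per_s": curve.pulling_speed,
    }
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        fh.write("# piezo_nm\tforce_pN\n")
        np.savetxt(fh, np.column_stack([curve.piezo_position, curve.force]),
                   fmt="%.5f", delimiter="\t")


def read_curve_tsv(path: str | Path) -> ForceCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    data = np.loadtxt(path, delimiter="\t", comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    return ForceCurve(
        piezo_position=data[:, 0],
        force=data[:, 1],
        spring_constant=float(meta.get("spring_constant_pN_per_nm", "nan")),
        pulling_speed=float(meta.get("pulling_speed_nm_per_s", "nan")),
        id=meta.get("id", path.stem),
    )
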