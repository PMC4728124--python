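"""Polymer elasticity and rupture kinetics.

Worm-like chain (WLC) force-extension relation in the Marko-Siggia
interpolation, its two inverses (extension at given force, contour length
at given force and extension), and the Bell-Evans model for rupture-force
distributions under a constant loading rate.

Units throughout: lengths in nm, forces in pN, energies in pN nm,
loading rates in pN/s, rates in 1/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "KB",
    "DEFAULT_KBT",
    "LENGTH_PER_RESIDUE",
    "PolymerParams",
    "BellEvansParams",
    "LoadingContext",
    "wlc_force",
    "wlc_inverse_extension",
    "wlc_inverse_contour",
    "tether_equilibrium_force",
    "bell_evans_pdf",
    "most_probable_force",
    "bell_evans_params_for_mode",
    "sample_rupture_forces",
    "contour_gain_from_residues",
]

#: Boltzmann constant in pN nm / K.
KB = 1.380649e-2

#: Default thermal energy scale, pN nm (room temperature).
DEFAULT_KBT = 4.114

#: Contour length per stretched amino acid, nm.
LENGTH_PER_RESIDUE = 0.4


@dataclass(frozen=True)
class PolymerParams:
    """WLC parameters: persistence length (nm) and thermal energy (pN nm).

    Polypeptide backbones in constant-speed pulling experiments are well
    described by a fixed persistence length of 0.4 nm.
    """

    persistence_length: float = 0.4
    kBT: float = DEFAULT_KBT

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.kBT <= 0:
            raise ValueError("kBT must be > 0")


@dataclass(frozen=True)
class BellEvansParams:
    """Bell-Evans barrier: zero-force off-rate (1/s) and Δx (nm)."""

    koff0: float
    delta_x: float

    def __post_init__(self) -> None:
        if self.koff0 <= 0:
            raise ValueError("koff0 must be > 0")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be > 0")


@dataclass(frozen=True)
class LoadingContext:
    """Pulling speed (nm/s) and effective stiffness (pN/nm) of the tether.

    The product is the nominal loading rate in pN/s used by the analytic
    rupture-force model; the true instantaneous loading rate of a WLC
    tether is force dependent and is not modelled here.
    """

    pulling_speed: float
    effective_stiffness: float

    def __post_init__(self) -> None:
        if self.pulling_speed <= 0:
            raise ValueError("pulling_speed must be > 0")
        if self.effective_stiffness <= 0:
            raise ValueError("effective_stiffness must be > 0")

    @property
    def loading_rate(self) -> float:
        """Nominal loading rate, pN/s."""
        return self.pulling_speed * self.effective_stiffness


# ---------------------------------------------------------------------------
# Worm-like chain
# ---------------------------------------------------------------------------

def wlc_force(extension, contour_length, params: PolymerParams = PolymerParams()):
    """Marko-Siggia WLC force at a given extension.

    F(x) = (kBT/p) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    Accepts scalars or arrays (broadcast). Raises for extensions outside
    [0, Lc) or negative inputs.
    """
    x = np.asarray(extension, dtype=float)
    lc = np.asarray(contour_length, dtype=float)
    if np.any(lc <= 0):
        raise ValueError("contour_length must be > 0")
    if np.any(x < 0):
        raise ValueError("extension must be >= 0")
    if np.any(x >= lc):
        raise ValueError("extension must be < contour_length")
    u = x / lc
    f = (params.kBT / params.persistence_length) * (
        0.25 / (1.0 - u) ** 2 - 0.25 + u
    )
    return f if f.shape else float(f)


def _ms_reduced_force(u):
    """Marko-Siggia force in units of kBT/p as a function of u = x/Lc."""
    return 0.25 / (1.0 - u) ** 2 - 0.25 + u


def _ms_inverse_u(reduced_force, n_iter: int = 80):
    """Invert the (monotone) Marko-Siggia relation for u = x/Lc.

    Vectorised bisection on u in (0, 1); `reduced_force` is F p / kBT > 0.
    """
    g = np.asarray(reduced_force, dtype=float)
    lo = np.zeros_like(g)
    hi = np.full_like(g, 1.0 - 1e-15)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        too_low = _ms_reduced_force(mid) < g
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def wlc_inverse_extension(force, contour_length, params: PolymerParams = PolymerParams()):
    """Extension of a WLC of given contour length at a given force (> 0)."""
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be > 0")
    u = _ms_inverse_u(f * params.persistence_length / params.kBT)
    out = u * np.asarray(contour_length, dtype=float)
    return out if out.shape else float(out)


def tether_equilibrium_force(piezo, contour_length, stiffness,
                             params: PolymerParams = PolymerParams(),
                             n_iter: int = 60):
    """Force balance of a Hookean lever against a WLC tether.

    For each piezo position z solves wlc_force(x, Lc) = k (z - x) for the
    tip-sample separation x by vectorised bisection and returns the force
    k (z - x).  This is the noise-free force a constant-speed instrument
    records while a tether of fixed contour length is stretched.
    """
    z = np.atleast_1d(np.asarray(piezo, dtype=float))
    if contour_length <= 0 or stiffness <= 0:
        raise ValueError("contour_length and stiffness must be > 0")
    lo = np.zeros_like(z)
    hi = np.minimum(z, contour_length * (1.0 - 1e-12))
    kbt_p = params.kBT / params.persistence_length
    inv_c = 1.0 / contour_length
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        u = mid * inv_c
        fw = kbt_p * (0.25 / (1.0 - u) ** 2 - 0.25 + u)
        too_high = fw > stiffness * (z - mid)
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    x = 0.5 * (lo + hi)
    out = stiffness * (z - x)
    return out if np.asarray(piezo).shape else float(out[0])


def wlc_inverse_contour(force, extension, params: PolymerParams = PolymerParams()):
    """Contour length of the WLC passing through (extension, force).

    This is the pointwise contour-length transformation: each
    (force, extension) pair with force > 0 maps to the unique Lc for which
    the Marko-Siggia WLC predicts that force at that extension.  Since the
    relative extension u = x/Lc depends only on force, Lc = x / u(F).

    Raises ValueError for force <= 0 (the WLC is not invertible there;
    such points must be excluded from the transform) or extension <= 0.
    """
    f = np.asarray(force, dtype=float)
    x = np.asarray(extension, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be > 0 for the inverse WLC transform")
    if np.any(x <= 0):
        raise ValueError("extension must be > 0")
    u = _ms_inverse_u(f * params.persistence_length / params.kBT)
    out = x / u
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# Bell-Evans rupture-force model
# ---------------------------------------------------------------------------

def bell_evans_pdf(force, params: BellEvansParams, loading: LoadingContext,
                   kBT: float = DEFAULT_KBT):
    """Rupture-force probability density under a constant loading rate r.

    With beta = delta_x / kBT and a = koff0 * kBT / (r * delta_x):

        p(F) = (koff0 / r) * exp(beta F) * exp(-a (exp(beta F) - 1))

    supported on F >= 0 and normalised to 1 there.
    """
    f = np.asarray(force, dtype=float)
    r = loading.loading_rate
    beta = params.delta_x / kBT
    a = params.koff0 * kBT / (r * params.delta_x)
    pdf = np.where(
        f < 0,
        0.0,
        (params.koff0 / r) * np.exp(beta * f) * np.exp(-a * np.expm1(beta * f)),
    )
    return pdf if pdf.shape else float(pdf)


def most_probable_force(params: BellEvansParams, loading: LoadingContext,
                        kBT: float = DEFAULT_KBT) -> float:
    """Analytic mode of the Bell-Evans distribution, pN.

    F* = (kBT / delta_x) * ln( r delta_x / (koff0 kBT) ), clipped at 0
    when the log argument is below 1 (mode at the support boundary).
    """
    arg = loading.loading_rate * params.delta_x / (params.koff0 * kBT)
    return max(0.0, (kBT / params.delta_x) * np.log(arg))


def bell_evans_params_for_mode(fstar: float, delta_x: float,
                               loading: LoadingContext,
                               kBT: float = DEFAULT_KBT) -> BellEvansParams:
    """Bell-Evans parameters whose most probable force equals `fstar`.

    Inverts the mode formula for koff0 at fixed delta_x; used to calibrate
    simulated barriers to reported peak rupture forces.
    """
    if fstar <= 0:
        raise ValueError("fstar must be > 0")
    koff0 = (loading.loading_rate * delta_x / kBT) * np.exp(-fstar * delta_x / kBT)
    return BellEvansParams(koff0=koff0, delta_x=delta_x)


def sample_rupture_forces(params: BellEvansParams, loading: LoadingContext,
                          n: int, seed=None, kBT: float = DEFAULT_KBT) -> np.ndarray:
    """Draw `n` rupture forces by exact inverse-CDF sampling.

    The Bell-Evans CDF is 1 - exp(-a (exp(beta F) - 1)), which inverts to
    F = (1/beta) * log1p( -log(1 - U) / a ).  `seed` may be an integer or
    a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = params.delta_x / kBT
    a = params.koff0 * kBT / (loading.loading_rate * params.delta_x)
    u = rng.uniform(size=n)
    return np.log1p(-np.log1p(-u) / a) / beta


def contour_gain_from_residues(n_residues: int,
                               length_per_residue: float = LENGTH_PER_RESIDUE) -> float:
    """Predicted contour-length gain for unfolding `n_residues` amino acids.

    Each stretched residue contributes ~0.4 nm of contour length, so e.g.
    unraveling a 19-residue segment releases 7.6 nm.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    return n_residues * length_per_residue
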