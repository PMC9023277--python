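"""Volume/hydration equations and a Kirkwood bead-model hydrodynamics stand-in.

Sedimentation coefficients of candidate structural models are estimated from
bead representations via the Kirkwood double-sum approximation to the
translational friction,

    f = 6 pi eta N a_bar / (1 + (a_bar / N) * sum_{i != j} 1 / R_ij),

then s20,w = M (1 - vbar rho) / (N_A f) and D_t = k_B T / f.  A closed shell
of beads converges to the Stokes value of the enclosed sphere, while beads
buried inside a filled body are hydrodynamically screened and, if included,
bias the friction low (for a uniform ball the double sum tends to 5/6 of
Stokes).  The estimator therefore restricts the sum to the solvent-exposed
bead layer by default (ray-cast exposure test), the same physics that leads
shell modellers like HYDROPRO to discard interior elements; the literal
all-bead sum is available with ``surface_only=False``.

Volume bookkeeping uses the anhydrous volume

    V_anh (A^3) = M (Da) * (vbar * 1e24) / 6.023e23

with the Avogadro constant exactly as conventionally printed in this
formula (6.023e23, not the CODATA value) so tabulated arithmetic is
reproduced; hydration enters as V_hyd = (delta / (rho vbar) + 1) V_anh.
The frictional ratio f/f0 uses the *anhydrous* reference sphere
(f0 = 6 pi eta r0, r0 from V_anh), the convention consistent with standard
AUC practice; hydration is accounted separately through delta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import BuoyancyError, GeometryError, ParameterError
from .formfactor import AtomicModel

__all__ = [
    "SolutionConditions",
    "BeadModel",
    "HydroResult",
    "anhydrous_volume",
    "hydrated_volume",
    "aer_from_bead_volume",
    "exposed_beads",
    "kirkwood_s20w",
    "frictional_ratio",
    "atoms_to_beads",
]

AVOGADRO_PRINTED = 6.023e23  # Da/g, exactly as printed in the volume equation
KB_CGS = 1.380649e-16  # erg/K
CM_PER_ANGSTROM = 1e-8
SVEDBERG = 1e-13  # s

#: HYDROPRO-style atomic-level bead radius (Angstrom)
DEFAULT_AER = 2.53


@dataclass(frozen=True)
class SolutionConditions:
    """Buffer and particle constants for hydrodynamic conversions."""

    temperature: float = 20.0  # Celsius
    viscosity: float = 0.0101  # poise
    density: float = 1.0092  # g/cm^3
    vbar: float = 0.55  # cm^3/g, partial specific volume of DNA
    hydration_delta: float = 0.3  # g H2O per g

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0 or self.vbar <= 0:
            raise ParameterError("viscosity, density and vbar must be positive")
        if self.hydration_delta < 0:
            raise ParameterError("hydration_delta must be non-negative")

    @property
    def temperature_k(self) -> float:
        return self.temperature + 273.15


@dataclass(frozen=True)
class BeadModel:
    """Spheres (centres in Angstrom, per-bead radii) plus total mass in Da."""

    centers: np.ndarray  # (N, 3)
    radii: np.ndarray  # (N,)
    mass: float  # Da

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float).reshape(-1, 3)
        r = np.broadcast_to(np.asarray(self.radii, float), (len(c),)).copy()
        if len(c) < 1:
            raise GeometryError("bead model needs at least one bead")
        if np.any(r <= 0):
            raise ParameterError("bead radii must be positive")
        object.__setattr__(self, "centers", c)
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.radii)


@dataclass(frozen=True)
class HydroResult:
    s20w: float  # Svedberg
    f_over_f0: float
    rg: float  # Angstrom
    volume_anhydrous: float  # A^3
    volume_hydrated: float  # A^3
    Dt: float  # cm^2/s
    n_beads_used: int = 0


def anhydrous_volume(mw: float, vbar: float = 0.55) -> float:
    """V (A^3) = M * (vbar * 1e24) / 6.023e23."""
    if mw <= 0:
        raise ParameterError("molecular weight must be positive")
    if vbar <= 0:
        raise ParameterError("vbar must be positive")
    return mw * (vbar * 1e24) / AVOGADRO_PRINTED


def hydrated_volume(v_anh: float, cond: SolutionConditions) -> float:
    """V_hyd = (delta / (rho * vbar) + 1) * V_anh."""
    if v_anh <= 0:
        raise ParameterError("anhydrous volume must be positive")
    return (cond.hydration_delta / (cond.density * cond.vbar) + 1.0) * v_anh


def aer_from_bead_volume(v_a: float) -> float:
    """Radius of the sphere with volume v_a: (3 v_a / 4 pi)^(1/3)."""
    if v_a <= 0:
        raise ParameterError("bead volume must be positive")
    return float((3.0 * v_a / (4.0 * np.pi)) ** (1.0 / 3.0))


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def exposed_beads(model: BeadModel, n_rays: int = 66) -> np.ndarray:
    """Boolean mask of beads with at least one unobstructed ray to solvent.

    A ray from a bead centre is blocked by bead j when it passes within j's
    blocking radius, taken as max(radius_j, 0.8 * nearest-neighbour spacing)
    so that volume-filling beads that do not quite touch still screen their
    interior.  Beads with no clear ray in ``n_rays`` Fibonacci directions
    are buried.
    """
    C, a = model.centers, model.radii
    n = len(model)
    if n <= 2:
        return np.ones(n, bool)
    tree = cKDTree(C)
    dnn = tree.query(C, k=2)[0][:, 1]
    block = np.maximum(a, 0.8 * dnn)
    dirs = _fibonacci_directions(n_rays)
    out = np.zeros(n, bool)
    for i in range(n):
        d = C - C[i]
        t = d @ dirs.T  # (n, n_rays) projection along each ray
        perp2 = np.sum(d * d, axis=1)[:, None] - t**2
        blocked = (t > 1e-9) & (perp2 < block[:, None] ** 2)
        blocked[i, :] = False
        out[i] = bool((~blocked.any(axis=0)).any())
    return out


def kirkwood_s20w(
    model: BeadModel,
    cond: SolutionConditions = SolutionConditions(),
    surface_only: bool = True,
) -> HydroResult:
    """Sedimentation coefficient etc. from the Kirkwood friction of a bead model.

    With ``surface_only`` (default) the double sum runs over the
    solvent-exposed bead layer; buried beads contribute neither friction nor
    hydrodynamic interaction.  Rg is the bead-volume-weighted RMS distance
    from the centroid of the *full* model.
    """
    mask = exposed_beads(model) if surface_only else np.ones(len(model), bool)
    C = model.centers[mask] * CM_PER_ANGSTROM
    a = model.radii[mask] * CM_PER_ANGSTROM
    n = len(C)
    eta = cond.viscosity
    abar = float(np.mean(a))
    if n == 1:
        f = 6.0 * np.pi * eta * a[0]
    else:
        diff = C[:, None, :] - C[None, :, :]
        dist = np.sqrt(np.sum(diff * diff, axis=-1))
        np.fill_diagonal(dist, np.inf)
        if np.any(dist < 1e-12):
            raise GeometryError("coincident bead centres in the interaction sum")
        inv_sum = float(np.sum(1.0 / dist))
        f = 6.0 * np.pi * eta * n * abar / (1.0 + (abar / n) * inv_sum)

    buoy = model.mass * (1.0 - cond.vbar * cond.density)
    if buoy <= 0:
        raise BuoyancyError("M(1 - vbar*rho) must be positive")
    s = buoy / (AVOGADRO_PRINTED * f) / SVEDBERG
    dt = KB_CGS * cond.temperature_k / f

    w = model.radii**3
    com = np.average(model.centers, axis=0, weights=w)
    rg = float(np.sqrt(np.average(np.sum((model.centers - com) ** 2, axis=1), weights=w)))
    v_anh = anhydrous_volume(model.mass, cond.vbar)
    return HydroResult(
        s20w=float(s),
        f_over_f0=frictional_ratio(float(s), model.mass, cond),
        rg=rg,
        volume_anhydrous=v_anh,
        volume_hydrated=hydrated_volume(v_anh, cond),
        Dt=float(dt),
        n_beads_used=n,
    )


def frictional_ratio(s20w: float, mw: float, cond: SolutionConditions = SolutionConditions()) -> float:
    """f/f0 with an anhydrous reference sphere.

    f follows from the Svedberg relation, f = M (1 - vbar rho) / (N_A s);
    f0 = 6 pi eta r0 with r0 the radius of the sphere of the anhydrous
    volume.
    """
    if mw <= 0 or s20w <= 0:
        raise ParameterError("mw and s20w must be positive")
    buoy = mw * (1.0 - cond.vbar * cond.density)
    if buoy <= 0:
        raise BuoyancyError("M(1 - vbar*rho) must be positive")
    f = buoy / (AVOGADRO_PRINTED * s20w * SVEDBERG)
    r0 = aer_from_bead_volume(anhydrous_volume(mw, cond.vbar)) * CM_PER_ANGSTROM
    f0 = 6.0 * np.pi * cond.viscosity * r0
    return float(f / f0)


def atoms_to_beads(model: AtomicModel, mass: float, aer: float = DEFAULT_AER) -> BeadModel:
    """Atomic-level bead model: one bead per atom with uniform AER radius."""
    if aer <= 0:
        raise ParameterError("AER must be positive")
    return BeadModel(model.coords, np.full(len(model), float(aer)), mass)
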