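"""Synthetic fixtures: idealized stacked-tetrad models, analytic scattering
profiles with noise, CD spectra and bead spheres.

Every generator is a pure function of its arguments (including the seed), so
fixtures are bit-reproducible.  Tetrad-stack models use pseudo-atoms, not
full nucleotides: scattering and hydrodynamic observables depend on the
electron distribution, not the chemistry, and four guanine-equivalent
scatterers per quartet plane capture the axial-rise geometry that the
analyses probe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import fixed_quad
from scipy.special import j1

from .cdspec import CalibrationLine, CDSpectrum, DEFAULT_CALIBRATION
from .errors import ParameterError
from .formfactor import AtomicModel, debye_intensity
from .hydrocalc import BeadModel
from .saxscore import ScatteringProfile

__all__ = [
    "SynthSpec",
    "make_tetrad_stack_model",
    "make_sphere_model",
    "make_bead_sphere",
    "sphere_form_factor",
    "sphere_pddf",
    "synth_scattering",
    "synth_cd",
    "apply_noise",
]

# guanosine-nucleotide-equivalent pseudo-atom: one scatterer per guanine
# stands for the whole dGMP residue (electrons and displaced volume),
# not just the base, so excluded-volume effects carry realistic weight
PSEUDO_ELECTRONS = 170.0
PSEUDO_VOLUME = 300.0  # A^3

#: relative sigma floor used when a profile is generated noise-free
SIGMA_FLOOR_FRAC = 1e-3


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic scattering profile."""

    kind: str  # {sphere, cylinder, dumbbell, tetrad_stack}
    radius: float = 30.0  # A (sphere/dumbbell/cylinder radius)
    length: float = 100.0  # A (cylinder)
    separation: float = 80.0  # A (dumbbell centre-centre)
    n_tetrads: int = 6
    rise: float = 3.3  # A
    twist: float = 30.0  # deg
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sphere", "cylinder", "dumbbell", "tetrad_stack"):
            raise ParameterError(f"unknown synthetic kind {self.kind!r}")
        if min(self.radius, self.length, self.separation, self.rise) <= 0:
            raise ParameterError("geometry parameters must be positive")
        if self.n_tetrads < 1:
            raise ParameterError("n_tetrads must be >= 1")
        if self.noise_frac < 0:
            raise ParameterError("noise_frac must be non-negative")


def make_tetrad_stack_model(
    n_tetrads: int,
    rise: float = 3.3,
    twist: float = 30.0,
    quartet_radius: float = 6.5,
    axial_ions: bool = False,
    label: str = "",
) -> AtomicModel:
    """Idealized stacked G-quartet core as pseudo-atoms.

    Four guanine-equivalent scatterers per tetrad sit at ``quartet_radius``
    from the helix axis; successive tetrads are translated by ``rise`` and
    rotated by ``twist``.  ``axial_ions`` adds K+ pseudo-ions on the axis
    between planes.
    """
    if n_tetrads < 1:
        raise ParameterError("n_tetrads must be >= 1")
    elements, coords, z, v = [], [], [], []
    for k in range(n_tetrads):
        zpos = k * rise
        for m in range(4):
            ang = np.deg2rad(90.0 * m + twist * k)
            coords.append([quartet_radius * np.cos(ang), quartet_radius * np.sin(ang), zpos])
            elements.append("X")
            z.append(PSEUDO_ELECTRONS)
            v.append(PSEUDO_VOLUME)
    if axial_ions:
        for k in range(n_tetrads - 1):
            coords.append([0.0, 0.0, (k + 0.5) * rise])
            elements.append("K")
            z.append(19.0)
            v.append(11.01)
    return AtomicModel(
        tuple(elements),
        np.array(coords, float),
        np.array(z),
        np.array(v),
        label or f"tetrad_stack_{n_tetrads}",
    )


def make_sphere_model(radius: float, n_points: int = 500, seed: int = 0) -> AtomicModel:
    """Uniform point-cloud sphere of unit-Z pseudo-atoms (form-factor tests)."""
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(4 * n_points, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    rr = radius * rng.random(4 * n_points) ** (1.0 / 3.0)
    coords = (pts * rr[:, None])[:n_points]
    n = len(coords)
    return AtomicModel(
        ("X",) * n, coords, np.ones(n), np.zeros(n), f"sphere_cloud_R{radius:g}"
    )


def _fibonacci_sphere(n: int, r: float) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return r * np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def make_bead_sphere(radius: float, n_beads: int = 1000, mass: float = 1.0e4) -> BeadModel:
    """Bead-filled sphere: concentric shells sampling the closed ball.

    Shell counts scale with r^2 so beads sample the ball at uniform density,
    with the outermost shell centred exactly on ``radius``; bead radii
    preserve the per-bead volume (a = spacing * (3/4pi)^(1/3)).
    """
    n_shells = max(2, int(round(((n_beads - 1) * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0) * 1.61)))
    r_shells = np.arange(1, n_shells + 1) * radius / n_shells
    w = r_shells**2 / np.sum(r_shells**2)
    counts = np.maximum(1, np.round(w * (n_beads - 1))).astype(int)
    pts = [np.zeros((1, 3))]
    for rk, nk in zip(r_shells, counts):
        pts.append(_fibonacci_sphere(nk, rk))
    centers = np.vstack(pts)
    spacing = radius / n_shells
    a = spacing * (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return BeadModel(centers, np.full(len(centers), a), mass)


def sphere_form_factor(q: np.ndarray, radius: float) -> np.ndarray:
    """Normalized sphere intensity [3 (sin x - x cos x)/x^3]^2, x = qR."""
    x = np.asarray(q, float) * radius
    with np.errstate(invalid="ignore", divide="ignore"):
        amp = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
    amp = np.where(x < 1e-6, 1.0 - x**2 / 10.0, amp)
    return amp**2


def sphere_pddf(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a uniform sphere on [0, 2R].

    p(r) proportional to r^2 (1 - 3r/(4R) + r^3/(16 R^3)), zero outside;
    normalized to unit peak.
    """
    r = np.asarray(r, float)
    p = r**2 * (1.0 - 3.0 * r / (4.0 * radius) + r**3 / (16.0 * radius**3))
    p = np.where((r >= 0) & (r <= 2 * radius), p, 0.0)
    return p / p.max()


def _cylinder_intensity(q: np.ndarray, radius: float, length: float) -> np.ndarray:
    """Orientation-averaged cylinder form factor by fixed-order quadrature."""

    def integrand(alpha, qv):
        qa = qv * radius * np.sin(alpha)
        qlh = qv * length * np.cos(alpha) / 2.0
        fa = np.where(qa < 1e-8, 1.0, 2.0 * j1(qa) / np.where(qa < 1e-8, 1.0, qa))
        fl = np.where(np.abs(qlh) < 1e-8, 1.0, np.sin(qlh) / np.where(np.abs(qlh) < 1e-8, 1.0, qlh))
        return (fa * fl) ** 2 * np.sin(alpha)

    out = np.empty(len(q))
    for k, qv in enumerate(q):
        val, _ = fixed_quad(integrand, 0.0, np.pi / 2.0, args=(qv,), n=64)
        out[k] = val
    return out / out[0] if out[0] > 0 else out


def apply_noise(
    q: np.ndarray, intensity: np.ndarray, noise_frac: float, seed: int
) -> ScatteringProfile:
    """Multiplicative Gaussian noise of relative width ``noise_frac``.

    sigma is noise_frac * I plus a small floor (a detector never reports a
    vanishing error, and exact zeros at form-factor minima would otherwise
    carry infinite weight in fits).
    """
    rng = np.random.default_rng(seed)
    i = np.asarray(intensity, float)
    floor = SIGMA_FLOOR_FRAC * float(np.max(np.abs(i)))
    if noise_frac > 0:
        noisy = i * (1.0 + noise_frac * rng.standard_normal(i.size))
        # sigma matches the applied noise; the tiny floor only guards the
        # rare exact zero at a form-factor minimum
        sigma = np.maximum(noise_frac * np.abs(i), 1e-6 * floor)
    else:
        noisy = i.copy()
        sigma = np.full(i.size, floor) + SIGMA_FLOOR_FRAC * np.abs(i)
    return ScatteringProfile(np.asarray(q, float), noisy, sigma)


def synth_scattering(spec: SynthSpec, q_grid: np.ndarray) -> ScatteringProfile:
    """Analytic (or Debye) intensity for ``spec`` with seeded noise."""
    q = np.asarray(q_grid, float)
    if spec.kind == "sphere":
        i = 100.0 * sphere_form_factor(q, spec.radius)
    elif spec.kind == "cylinder":
        i = 100.0 * _cylinder_intensity(q, spec.radius, spec.length)
    elif spec.kind == "dumbbell":
        amp = np.sqrt(sphere_form_factor(q, spec.radius))
        x = q * spec.separation
        sinc = np.where(x < 1e-8, 1.0, np.sin(x) / np.where(x < 1e-8, 1.0, x))
        i = 100.0 * amp**2 * (1.0 + sinc)
    else:  # tetrad_stack
        model = make_tetrad_stack_model(spec.n_tetrads, spec.rise, spec.twist)
        i = debye_intensity(model, q).intensity
    return apply_noise(q, i, spec.noise_frac, spec.seed)


def synth_cd(
    n_stacks: float | None = None,
    line: CalibrationLine = DEFAULT_CALIBRATION,
    apex_delta_eps: float | None = None,
    band_centers: tuple[float, float] = (264.0, 240.0),
    band_widths: tuple[float, float] = (9.0, 7.0),
    neg_ratio: float = -0.45,
    noise: float = 0.0,
    seed: int = 0,
    wavelength: np.ndarray | None = None,
) -> CDSpectrum:
    """Synthetic parallel-G4 CD spectrum.

    A positive Gaussian band at 264 nm whose apex equals m * n_stacks + b
    (or ``apex_delta_eps`` when given directly), a negative band at 240 nm
    at a fixed amplitude ratio, additive Gaussian noise of width ``noise``
    delta-eps units.  The clean composite is rescaled so the 264 nm value is
    exact despite band overlap.
    """
    if apex_delta_eps is None:
        if n_stacks is None or n_stacks <= 0:
            raise ParameterError("n_stacks must be positive (or give apex_delta_eps)")
        apex = line.m * n_stacks + line.b
    else:
        apex = apex_delta_eps
    wl = np.arange(220.0, 321.0) if wavelength is None else np.asarray(wavelength, float)
    c1, c2 = band_centers
    w1, w2 = band_widths
    clean = np.exp(-((wl - c1) ** 2) / (2 * w1**2)) + neg_ratio * np.exp(
        -((wl - c2) ** 2) / (2 * w2**2)
    )
    at_peak = np.exp(-((np.array([c1]) - c1) ** 2) / (2 * w1**2))[0] + neg_ratio * np.exp(
        -((c1 - c2) ** 2) / (2 * w2**2)
    )
    clean = clean * (apex / at_peak)
    rng = np.random.default_rng(seed)
    de = clean + (noise * rng.standard_normal(wl.size) if noise > 0 else 0.0)
    return CDSpectrum(wl, de, "strand")
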