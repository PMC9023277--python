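"""Primary SAXS analysis: Guinier, regularized P(r) inversion, Kratky.

Covers the model-free reductions of a 1-D scattering profile:

* Guinier regression — weighted fit of ln I vs q^2 at low angle, giving the
  radius of gyration Rg = sqrt(-3 * slope) and forward intensity
  I(0) = exp(intercept); the fit window expands until q_max * Rg reaches a
  configurable limit (1.3 by default) by self-consistent iteration.
* Indirect Fourier transform — the pair distance distribution function p(r)
  solving I(q) = 4 pi int_0^Dmax p(r) sinc(q r) dr as a Tikhonov-regularized
  linear inverse problem with p(0) = p(Dmax) = 0, smoothness weight chosen
  by an L-curve corner search, and soft (or hard) positivity.
* Rg and I(0) from p(r): Rg^2 = int r^2 p dr / (2 int p dr),
  I(0) = 4 pi int p dr.
* Dimensionless Kratky transform (q Rg)^2 I/I(0) vs q Rg; a globular
  particle peaks at (sqrt(3), 3/e).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import FitError, InputError, NumericError, ParameterError

__all__ = [
    "ScatteringProfile",
    "GuinierResult",
    "PDDF",
    "KratkyCurve",
    "guinier_fit",
    "pddf_ift",
    "pddf_forward",
    "rg_from_pddf",
    "estimate_dmax",
    "dimensionless_kratky",
]


@dataclass(frozen=True)
class ScatteringProfile:
    """A 1-D scattering curve: q (A^-1, ascending), I(q) and 1-sigma errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    sigma_imputed: bool = False  # set by readers when no sigma column existed

    def __post_init__(self) -> None:
        q = np.asarray(self.q, float)
        i = np.asarray(self.intensity, float)
        s = np.asarray(self.sigma, float)
        if q.ndim != 1 or q.size != i.size or q.size != s.size:
            raise ParameterError("q, intensity, sigma must be 1-D of equal length")
        if q.size and (np.any(np.diff(q) <= 0) or q[0] <= 0):
            raise ParameterError("q must be strictly ascending and positive")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        object.__setattr__(self, "sigma", s)

    def truncated(self, q_max: float | None = None, q_min: float | None = None) -> "ScatteringProfile":
        m = np.ones(self.q.size, bool)
        if q_min is not None:
            m &= self.q >= q_min
        if q_max is not None:
            m &= self.q <= q_max
        return ScatteringProfile(self.q[m], self.intensity[m], self.sigma[m], self.sigma_imputed)


@dataclass(frozen=True)
class GuinierResult:
    rg: float  # Angstrom
    i0: float
    q_range_used: tuple[float, float]
    qmax_rg: float
    fit_r2: float
    rg_se: float
    n_points: int


@dataclass(frozen=True)
class PDDF:
    """Real-space distance distribution on [0, d_max] with p(0)=p(Dmax)=0."""

    r: np.ndarray
    p: np.ndarray
    d_max: float
    rg: float
    i0: float
    alpha: float


@dataclass(frozen=True)
class KratkyCurve:
    qrg: np.ndarray
    y: np.ndarray  # (q Rg)^2 I / I0
    peak_qrg: float | None
    peak_height: float | None
    globular: bool


def guinier_fit(
    profile: ScatteringProfile,
    qmax_rg_limit: float = 1.3,
    q_min: float | None = None,
) -> GuinierResult:
    """Weighted Guinier regression with a self-consistent q_max * Rg window.

    Starting from the lowest usable angles, ln I is regressed on q^2 with
    weights (I/sigma)^2; the window's upper edge is moved to
    q_max = limit / Rg and the fit repeated until Rg changes by < 0.1%.
    """
    q, i, s = profile.q, profile.intensity, profile.sigma
    usable = i > 0
    if q_min is not None:
        usable &= q >= q_min
    if usable.sum() < 10:
        raise InputError("fewer than 10 usable points for Guinier analysis")
    qu, iu, su = q[usable], i[usable], s[usable]

    def wfit(mask):
        x = qu[mask] ** 2
        y = np.log(iu[mask])
        w = (iu[mask] / su[mask]) ** 2  # var(ln I) = (sigma/I)^2
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * y) / W
        sxx = np.sum(w * (x - xm) ** 2)
        if sxx <= 0:
            raise FitError("degenerate q^2 range in Guinier window")
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        intercept = ym - slope * xm
        resid = y - (intercept + slope * x)
        sst = np.sum(w * (y - ym) ** 2)
        r2 = 1.0 - np.sum(w * resid**2) / sst if sst > 0 else 1.0
        # weighted slope standard error
        dof = max(mask.sum() - 2, 1)
        s2 = np.sum(w * resid**2) / dof
        slope_se = np.sqrt(s2 / sxx)
        return slope, intercept, r2, slope_se

    # initial window: first 10..n points, widened until a negative slope is found
    n0 = 10
    slope = 0.0
    while n0 <= qu.size:
        mask = np.zeros(qu.size, bool)
        mask[:n0] = True
        slope, intercept, r2, slope_se = wfit(mask)
        if slope < 0:
            break
        n0 += 5
    if slope >= 0:
        raise FitError("no negative Guinier slope found (Rg^2 < 0)")
    rg = float(np.sqrt(-3.0 * slope))

    for _ in range(100):
        qmax = qmax_rg_limit / rg
        mask = qu <= qmax
        if mask.sum() < 10:
            raise InputError("fewer than 10 points below the q_max*Rg limit")
        slope, intercept, r2, slope_se = wfit(mask)
        if slope >= 0:
            raise FitError("Guinier slope turned non-negative while iterating")
        rg_new = float(np.sqrt(-3.0 * slope))
        done = abs(rg_new - rg) < 1e-3 * rg
        rg = rg_new
        if done:
            break
    used = qu[mask]
    rg_se = float(3.0 / (2.0 * rg) * slope_se)
    return GuinierResult(
        rg=rg,
        i0=float(np.exp(intercept)),
        q_range_used=(float(used[0]), float(used[-1])),
        qmax_rg=float(used[-1] * rg),
        fit_r2=float(r2),
        rg_se=rg_se,
        n_points=int(mask.sum()),
    )


def _ift_matrices(q, r):
    dr = r[1] - r[0]
    w = np.full(r.size, dr)
    w[0] = w[-1] = dr / 2.0  # trapezoid
    X = np.outer(q, r)
    K = 4.0 * np.pi * np.sinc(X / np.pi) * w  # sinc(qr) = sin(qr)/(qr)
    return K


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator on the interior nodes, boundary values 0."""
    D = np.zeros((n, n))
    for k in range(n):
        D[k, k] = -2.0
        if k > 0:
            D[k, k - 1] = 1.0
        if k < n - 1:
            D[k, k + 1] = 1.0
    return D


def _solve_ift(Aw, y, D, alpha, positivity):
    stack_A = np.vstack([Aw, np.sqrt(alpha) * D])
    stack_y = np.concatenate([y, np.zeros(D.shape[0])])
    if positivity == "hard":
        p, _ = optimize.nnls(stack_A, stack_y)
        return p
    p, *_ = np.linalg.lstsq(stack_A, stack_y, rcond=None)
    if positivity == "soft":
        base = np.linalg.norm(Aw) / np.sqrt(Aw.shape[1])
        for it in range(4):
            neg = p < 0
            if not neg.any():
                break
            P = np.diag(neg.astype(float)) * base * 3.0**it
            A2 = np.vstack([stack_A, P])
            y2 = np.concatenate([stack_y, np.zeros(P.shape[0])])
            p, *_ = np.linalg.lstsq(A2, y2, rcond=None)
    return p


def pddf_ift(
    profile: ScatteringProfile,
    d_max: float,
    n_r: int = 101,
    alpha: float | None = None,
    q_cut: float = 0.3,
    positivity: str = "soft",
) -> PDDF:
    """Regularized indirect Fourier transform of I(q) into p(r).

    Solves I(q) = 4 pi int_0^Dmax p(r) sinc(qr) dr on an ``n_r``-node grid,
    minimising chi^2 + alpha * ||p''||^2 with p pinned to zero at both ends.
    When ``alpha`` is None it is chosen by an L-curve corner search (maximum
    curvature of log-residual vs log-seminorm), falling back to the largest
    alpha whose chi^2 stays within 10% of the minimum.  Positivity of p is
    enforced softly by default (penalty), or exactly with "hard" (NNLS).
    """
    if d_max <= 0:
        raise ParameterError("d_max must be positive")
    if n_r < 10:
        raise ParameterError("n_r too small")
    prof = profile.truncated(q_max=q_cut)
    q, i, s = prof.q, prof.intensity, prof.sigma
    if q.size < 10:
        raise InputError("too few points below q_cut for the inversion")
    if d_max < np.pi / q[-1]:
        # below the resolution limit of the data; proceed but the system
        # is effectively unconstrained at small r
        pass
    r = np.linspace(0.0, d_max, n_r)
    K = _ift_matrices(q, r)
    A = K[:, 1:-1]  # boundary nodes pinned at zero
    Aw = A / s[:, None]
    y = i / s
    D = _second_difference(n_r - 2)
    # scale-free regularization weight
    norm_ratio = (np.linalg.norm(Aw) / max(np.linalg.norm(D), 1e-300)) ** 2

    if alpha is None:
        alphas = np.logspace(-8, 2, 30) * norm_ratio
        rho = np.empty(alphas.size)
        eta = np.empty(alphas.size)
        sols = []
        for k, a in enumerate(alphas):
            p = _solve_ift(Aw, y, D, a, positivity="none")
            sols.append(p)
            rho[k] = np.linalg.norm(Aw @ p - y)
            eta[k] = max(np.linalg.norm(D @ p), 1e-300)
        lr, le, la = np.log(rho), np.log(eta), np.log(alphas)
        # curvature of the L-curve parametrised by log alpha
        d1r, d1e = np.gradient(lr, la), np.gradient(le, la)
        d2r, d2e = np.gradient(d1r, la), np.gradient(d1e, la)
        curv = (d1r * d2e - d2r * d1e) / np.maximum((d1r**2 + d1e**2) ** 1.5, 1e-300)
        curv[~np.isfinite(curv)] = -np.inf
        k_best = int(np.argmax(curv))
        chi_min = (rho.min() ** 2) / q.size
        if not np.isfinite(curv[k_best]) or (rho[k_best] ** 2) / q.size > 3.0 * max(chi_min, 1e-12):
            ok = (rho**2) / q.size <= 1.1 * max(chi_min, 1e-12)
            k_best = int(np.max(np.nonzero(ok)[0])) if ok.any() else int(np.argmin(rho))
        alpha = float(alphas[k_best])

    p_int = _solve_ift(Aw, y, D, alpha, positivity)
    p = np.zeros(n_r)
    p[1:-1] = p_int
    i0 = float(4.0 * np.pi * np.trapezoid(p, r))
    pd = PDDF(r=r, p=p, d_max=float(d_max), rg=0.0, i0=i0, alpha=float(alpha))
    rg = rg_from_pddf(pd)
    return PDDF(r=r, p=p, d_max=float(d_max), rg=rg, i0=i0, alpha=float(alpha))


def pddf_forward(pddf: PDDF, q: np.ndarray) -> np.ndarray:
    """Forward transform of a p(r) back to I(q) (round-trip checks)."""
    K = _ift_matrices(np.asarray(q, float), pddf.r)
    return K @ pddf.p


def rg_from_pddf(pddf: PDDF) -> float:
    """Rg from the second moment: Rg^2 = int r^2 p dr / (2 int p dr)."""
    denom = np.trapezoid(pddf.p, pddf.r)
    if denom <= 0:
        raise NumericError("p(r) integrates to a non-positive value")
    rg2 = np.trapezoid(pddf.r**2 * pddf.p, pddf.r) / (2.0 * denom)
    if rg2 <= 0:
        raise NumericError("negative Rg^2 from p(r) moments")
    return float(np.sqrt(rg2))


def estimate_dmax(
    profile: ScatteringProfile,
    dmax_grid: np.ndarray,
    q_cut: float = 0.3,
    neg_tol: float = 0.02,
    chi2_plateau: float = 1.05,
    **ift_kwargs,
) -> tuple[float, PDDF]:
    """Pick the smallest d_max with non-negative p(r) and plateaued chi^2.

    Scans ``dmax_grid`` (ascending), inverting at each value without a
    positivity constraint, and accepts the first d_max where min(p) >=
    -neg_tol * max(p) and the fit chi^2 is within ``chi2_plateau`` of the
    best chi^2 over the grid.
    """
    dmax_grid = np.asarray(dmax_grid, float)
    results = []
    chis = []
    prof = profile.truncated(q_max=q_cut)
    for d in dmax_grid:
        pd = pddf_ift(profile, d, q_cut=q_cut, positivity="none", **ift_kwargs)
        ic = pddf_forward(pd, prof.q)
        chis.append(float(np.mean(((prof.intensity - ic) / prof.sigma) ** 2)))
        results.append(pd)
    chi_best = min(chis)
    for d, pd, c in zip(dmax_grid, results, chis):
        if pd.p.min() >= -neg_tol * pd.p.max() and c <= chi2_plateau * chi_best:
            return float(d), pd
    k = int(np.argmin(chis))
    return float(dmax_grid[k]), results[k]


def dimensionless_kratky(profile: ScatteringProfile, rg: float, i0: float) -> KratkyCurve:
    """(q Rg)^2 I/I(0) vs q Rg with quadratic-interpolated peak location.

    A globular particle peaks at q Rg = sqrt(3) ~ 1.73 with height
    3/e ~ 1.104; curves rising monotonically to the data edge are flagged
    non-globular (peak undefined).
    """
    if rg <= 0 or i0 <= 0:
        raise ParameterError("rg and i0 must be positive")
    x = profile.q * rg
    y = x**2 * profile.intensity / i0
    k = int(np.argmax(y))
    if k == 0 or k == y.size - 1:
        return KratkyCurve(x, y, None, None, globular=False)
    # quadratic through the three points around the maximum
    x3, y3 = x[k - 1 : k + 2], y[k - 1 : k + 2]
    denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
    a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
    b = (
        x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0]) + x3[0] ** 2 * (y3[1] - y3[2])
    ) / denom
    c = (
        x3[1] * x3[2] * (x3[1] - x3[2]) * y3[0]
        + x3[2] * x3[0] * (x3[2] - x3[0]) * y3[1]
        + x3[0] * x3[1] * (x3[0] - x3[1]) * y3[2]
    ) / denom
    if a >= 0:
        return KratkyCurve(x, y, float(x[k]), float(y[k]), globular=True)
    xp = -b / (2.0 * a)
    yp = c - b**2 / (4.0 * a)
    return KratkyCurve(x, y, float(xp), float(yp), globular=True)
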