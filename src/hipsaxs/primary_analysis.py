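"""Model-free analysis of 1-D solution scattering curves.

Implements the standard primary-analysis chain: Guinier fit (radius of
gyration Rg and forward scattering I0), molar mass from the forward
scattering on absolute scale, indirect Fourier transform to the pair
distance distribution p(r) with maximum dimension Dmax, and the normalized
dimensionless Kratky transform used to assess compactness.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .scattering import AVOGADRO

logger = logging.getLogger("hipsaxs")


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# curve container and I/O
# ---------------------------------------------------------------------------

@dataclass
class SAXSCurve:
    """Measured (or simulated) intensity curve: q [1/A], I, 1-sigma errors."""
    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise AnalysisError("q, I, sigma must have equal lengths")
        if self.q.size < 2:
            raise AnalysisError("curve needs at least two points")
        if np.any(self.q < 0) or np.any(np.diff(self.q) <= 0):
            raise AnalysisError("q must be non-negative and strictly increasing")
        if np.any(self.sigma <= 0):
            raise AnalysisError("sigma must be strictly positive")

    @property
    def n_points(self) -> int:
        return self.q.size


def load_curve(source, q_unit: str = "1/A") -> SAXSCurve:
    """Read a three-column whitespace text curve ('#' comments ignored).

    ``q_unit`` may be ``"1/A"`` or ``"1/nm"`` (converted to 1/A).  A missing
    third column sets sigma to 1% of I with a warning.
    """
    if hasattr(source, "read"):
        data = np.loadtxt(source, comments="#", ndmin=2)
    else:
        data = np.loadtxt(str(source), comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise AnalysisError("curve file needs at least two columns (q, I)")
    q = data[:, 0]
    if q_unit == "1/nm":
        q = q / 10.0
    elif q_unit != "1/A":
        raise AnalysisError(f"unknown q unit {q_unit!r}")
    intens = data[:, 1]
    if data.shape[1] >= 3 and np.all(data[:, 2] > 0):
        sigma = data[:, 2]
    else:
        logger.warning("no usable error column; assuming sigma = 1%% of I")
        sigma = 0.01 * np.abs(intens)
        sigma[sigma == 0] = 0.01 * np.abs(intens).max()
    return SAXSCurve(q, intens, sigma)


def loads_curve(text: str, q_unit: str = "1/A") -> SAXSCurve:
    return load_curve(io.StringIO(text), q_unit=q_unit)


def save_curve(path, curve: SAXSCurve, header: str = "q[1/A] I sigma") -> None:
    np.savetxt(path, np.column_stack([curve.q, curve.I, curve.sigma]), header=header)


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuinierResult:
    rg: float
    i0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float

    @property
    def fit_range(self) -> tuple[float, float]:
        return (self.q_min, self.q_max)


def guinier_fit(curve: SAXSCurve, qrg_max: float = 1.3, qmin: float | None = None,
                min_points: int = 5) -> GuinierResult:
    """Self-consistent Guinier fit: ln I = ln I0 - (Rg^2/3) q^2.

    A weighted linear regression is run over the largest low-q window
    satisfying q * Rg <= ``qrg_max`` (community convention 1.3 for globular
    particles), iterating window and Rg until stable.
    """
    sel = np.ones(curve.n_points, bool) if qmin is None else curve.q >= qmin
    if sel.sum() < min_points:
        raise AnalysisError("too few points above qmin for a Guinier fit")
    qs, is_, sg = curve.q[sel], curve.I[sel], curve.sigma[sel]

    def fit_window(n):
        qq, ii, ss = qs[:n], is_[:n], sg[:n]
        if np.any(ii <= 0):
            raise AnalysisError("non-positive intensities in the Guinier window")
        x = qq**2
        y = np.log(ii)
        w = (ii / ss) ** 2          # var(ln I) = (sigma/I)^2
        wx = w.sum()
        xm = (w * x).sum() / wx
        ym = (w * y).sum() / wx
        sxx = (w * (x - xm) ** 2).sum()
        if sxx == 0:
            raise AnalysisError("degenerate Guinier window")
        slope = (w * (x - xm) * (y - ym)).sum() / sxx
        intercept = ym - slope * xm
        ss_res = (w * (y - slope * x - intercept) ** 2).sum()
        ss_tot = (w * (y - ym) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return slope, intercept, r2

    n = min(max(min_points, 20), len(qs))
    seen: set[int] = set()
    for _ in range(100):
        slope, intercept, r2 = fit_window(n)
        if slope >= 0:
            # window too wide or curve not decaying; shrink
            n_new = max(min_points, n - max(1, n // 4))
        else:
            rg = float(np.sqrt(-3.0 * slope))
            n_new = int(np.searchsorted(qs, qrg_max / rg, side="right"))
            n_new = min(max(n_new, min_points), len(qs))
        if n_new == n:
            break
        if n_new in seen:   # oscillating between two windows: keep smaller
            n = min(n, n_new)
            slope, intercept, r2 = fit_window(n)
            break
        seen.add(n)
        n = n_new
    else:
        raise AnalysisError("Guinier window iteration did not converge")
    if slope >= 0:
        raise AnalysisError("no self-consistent Guinier window (non-decaying curve)")
    rg = float(np.sqrt(-3.0 * slope))
    return GuinierResult(rg=rg, i0=float(np.exp(intercept)), q_min=float(qs[0]),
                         q_max=float(qs[n - 1]), n_points=n, r_squared=float(r2))


# ---------------------------------------------------------------------------
# molar mass from forward scattering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassEstimate:
    """Molar mass from absolute-scale forward scattering,
    M = I0 N_A / (c delta_rho_m^2)."""
    M: float
    i0: float
    c: float
    delta_rho_m: float
    n_a: float


def molar_mass_from_i0(i0: float, c: float, delta_rho_m: float = 2.00e10,
                       n_a: float = AVOGADRO) -> MassEstimate:
    """Molar mass (g/mol) from forward scattering ``i0`` (1/cm) and mass
    concentration ``c`` (g/cm^3), with the typical protein excess scattering
    length per mass delta_rho_m = 2.00e10 cm/g."""
    if i0 <= 0 or c <= 0 or delta_rho_m <= 0:
        raise AnalysisError("i0, c, delta_rho_m must all be positive")
    return MassEstimate(M=i0 * n_a / (c * delta_rho_m**2), i0=i0, c=c,
                        delta_rho_m=delta_rho_m, n_a=n_a)


# ---------------------------------------------------------------------------
# indirect Fourier transform
# ---------------------------------------------------------------------------

@dataclass
class PofR:
    """Pair distance distribution from an indirect Fourier transform."""
    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    alpha: float
    chi2_reduced: float
    fit_intensity: np.ndarray = field(repr=False, default=None)

    def back_transform(self, q) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        dr = self.r[1] - self.r[0]
        qr = np.outer(q, self.r)
        return 4.0 * np.pi * dr * (np.sinc(qr / np.pi) @ self.p)


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator on a length-n vector padded with zeros,
    so curvature is also penalized at the fixed endpoints."""
    rows = []
    for j in range(-1, n - 1):
        row = np.zeros(n)
        for k, c in ((j, 1.0), (j + 1, -2.0), (j + 2, 1.0)):
            if 0 <= k < n:
                row[k] = c
        rows.append(row)
    return np.array(rows)


def _ift_solve(curve: SAXSCurve, dmax: float, n_bins: int, alpha: float,
               nonneg: bool):
    r = np.linspace(0.0, dmax, n_bins)
    dr = r[1] - r[0]
    rfree = r[1:-1]                       # p(0) = p(Dmax) = 0
    kernel = 4.0 * np.pi * dr * np.sinc(np.outer(curve.q, rfree) / np.pi)
    a = kernel / curve.sigma[:, None]
    y = curve.I / curve.sigma
    reg = np.sqrt(alpha) * _second_difference(len(rfree))
    a_full = np.vstack([a, reg])
    y_full = np.concatenate([y, np.zeros(len(reg))])
    if nonneg:
        sol, _ = nnls(a_full, y_full, maxiter=10 * a_full.shape[1])
    else:
        sol, *_ = np.linalg.lstsq(a_full, y_full, rcond=None)
    p = np.zeros(n_bins)
    p[1:-1] = sol
    fit = kernel @ sol
    chi2 = float(np.sum(((fit - curve.I) / curve.sigma) ** 2))
    return r, p, fit, chi2


def _lcurve_alpha(curve: SAXSCurve, dmax: float, n_bins: int, nonneg: bool,
                  n_alpha: int = 15) -> float:
    """L-curve corner: maximum curvature of (log residual, log seminorm)
    over a log-spaced alpha grid."""
    # scale-aware alpha range from the kernel magnitude
    r, p0, fit0, chi0 = _ift_solve(curve, dmax, n_bins, 0.0, nonneg)
    base = max(chi0, 1.0) / max(float(np.sum(np.diff(p0, 2) ** 2)), 1e-30)
    alphas = base * np.logspace(-4, 4, n_alpha)
    rho, eta = [], []
    for al in alphas:
        _, p, _, chi2 = _ift_solve(curve, dmax, n_bins, al, nonneg)
        rho.append(np.log(max(chi2, 1e-30)))
        eta.append(np.log(max(float(np.sum(np.diff(p, 2) ** 2)), 1e-30)))
    rho, eta = np.array(rho), np.array(eta)
    d1r, d1e = np.gradient(rho), np.gradient(eta)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    denom = (d1r**2 + d1e**2) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = (d1r * d2e - d2r * d1e) / np.where(denom > 0, denom, np.inf)
    k = int(np.nanargmax(curv)) if np.any(np.isfinite(curv)) else n_alpha // 2
    return float(alphas[k])


def ift(curve: SAXSCurve, dmax="auto", n_bins: int = 100, alpha="auto",
        nonneg: bool = True) -> PofR:
    """Indirect Fourier transform: fit p(r) on [0, Dmax] to the curve.

    The back-transform I(q) = 4 pi sum_j p(r_j) sinc(q r_j) dr is fitted by
    error-weighted least squares with a second-difference (Tikhonov)
    smoothness penalty ``alpha`` and the boundary conditions
    p(0) = p(Dmax) = 0; ``nonneg`` additionally enforces p >= 0.

    ``dmax="auto"`` scans a grid of candidates and keeps the smallest Dmax
    whose chi^2 is within 5% of the minimum (parsimonious support);
    ``alpha="auto"`` takes the L-curve corner.  The reduced chi^2 reported
    uses the number of data points as the degrees of freedom, since the
    effective parameter count of a regularized fit is not well defined.
    """
    if dmax != "auto":
        dmax = float(dmax)
        if dmax <= 0:
            raise AnalysisError("dmax must be positive")
        if dmax < np.pi / curve.q.max():
            logger.warning("dmax below the resolution limit pi/q_max")
        candidates = [dmax]
    else:
        try:
            rg_guess = guinier_fit(curve).rg
        except AnalysisError:
            rg_guess = np.pi / curve.q.min() / 3.0
        candidates = list(np.linspace(2.0 * rg_guess, 5.0 * rg_guess, 25))

    if alpha == "auto":
        alpha_val = _lcurve_alpha(curve, max(candidates), n_bins, nonneg)
    else:
        alpha_val = float(alpha)

    results = []
    for dm in candidates:
        r, p, fit, chi2 = _ift_solve(curve, dm, n_bins, alpha_val, nonneg)
        results.append((dm, r, p, fit, chi2))
    chis = np.array([res[4] for res in results])
    best = chis.min()
    if best == 0:
        k = int(np.argmin(chis))
    else:
        ok = np.flatnonzero(chis <= 1.05 * best)
        k = int(ok[0])          # smallest Dmax within 5% of the best fit
    dm, r, p, fit, chi2 = results[k]
    dr = r[1] - r[0]
    integral = float(np.sum(p) * dr)
    if integral <= 0:
        raise AnalysisError("singular IFT system; try increasing alpha")
    i0 = 4.0 * np.pi * integral
    rg = float(np.sqrt(np.sum(p * r**2) * dr / (2.0 * integral)))
    return PofR(r=r, p=p, dmax=float(dm), rg=rg, i0=i0, alpha=alpha_val,
                chi2_reduced=chi2 / curve.n_points, fit_intensity=fit)


# ---------------------------------------------------------------------------
# normalized Kratky transform
# ---------------------------------------------------------------------------

def normalized_kratky(curve: SAXSCurve, guinier: GuinierResult):
    """Dimensionless Kratky transform: x = q Rg, y = (q Rg)^2 I(q) / I0.

    For a compact globular particle the curve peaks near
    (sqrt(3), 3/e) ~ (1.73, 1.10); a random coil plateaus instead.
    """
    x = curve.q * guinier.rg
    y = x**2 * curve.I / guinier.i0
    return x, y
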