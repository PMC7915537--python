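"""Thermotropic analysis of meibum melting curves.

Hot-stage polarized light microscopy records the birefringence
intensity I_br of a meibum film as it is heated.  Meibum melts
cooperatively through (at least) two transitions — a low-melting and a
high-melting component — captured by a two-term Hill-type model

    I_br(T) = A - B * T^k / (T1^k + T^k) - C * T^m / (T2^m + T^m)

with T in Kelvin.  A is the birefringence of the fully crystallized
film (1 when normalized), B and C the contributions of the two
liquid-crystal forms or compositional domains, T1 < T2 their transition
temperatures, and k, m unitless Hill cooperativity coefficients that
set the steepness of each transition.  Whether B and C are aggregation
states or compositional domains is left open; the model is agnostic.

Each Hill term is evaluated as B * expit(k * ln(T/T1)), algebraically
identical to the ratio form but immune to overflow of T^k, which
matters because healthy meibum melts with cooperativity around 120.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq, least_squares
from scipy.signal import find_peaks
from scipy.special import expit

__all__ = [
    "HillParams",
    "MeltingCurve",
    "FitResult",
    "hill_model",
    "spline_transitions",
    "fit_melting",
    "melt_fraction_at",
    "SOAT1_NULL_PARAMS",
    "WILD_TYPE_PARAMS",
]


@dataclass(frozen=True)
class HillParams:
    """Parameter vector of the two-transition melting model."""

    A: float  # birefringence of the fully crystallized film
    B: float  # contribution of the low-melting form
    C: float  # contribution of the high-melting form
    T1: float  # low transition temperature, K
    T2: float  # high transition temperature, K
    k: float  # Hill cooperativity of the low transition
    m: float  # Hill cooperativity of the high transition

    def __post_init__(self):
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.B < 0 or self.C < 0:
            raise ValueError("B and C must be non-negative")
        if not 0 < self.T1 < self.T2:
            raise ValueError("transition temperatures must satisfy 0 < T1 < T2")
        if self.k <= 0 or self.m <= 0:
            raise ValueError("Hill coefficients must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.C, self.T1, self.T2, self.k, self.m])


#: Parameter sets measured for expressed mouse meibum: the Soat1-null
#: secretion melts in two well-separated transitions (T1 304 K, T2
#: 359 K; k 39, m 29) while wild-type meibum melts sharply and low
#: (T1 289 K, T2 307 K, cooperativity around 120 for both).  B and C
#: are not reported; 0.5/0.5 spans a normalized curve from 1 to 0.
SOAT1_NULL_PARAMS = HillParams(A=1.0, B=0.5, C=0.5, T1=304.0, T2=359.0, k=39.0, m=29.0)
WILD_TYPE_PARAMS = HillParams(A=1.0, B=0.5, C=0.5, T1=289.0, T2=307.0, k=120.0, m=120.0)


@dataclass
class MeltingCurve:
    """Birefringence vs temperature (Kelvin, strictly increasing)."""

    temperature_k: np.ndarray
    birefringence: np.ndarray

    def __post_init__(self):
        self.temperature_k = np.asarray(self.temperature_k, dtype=float)
        self.birefringence = np.asarray(self.birefringence, dtype=float)
        if self.temperature_k.shape != self.birefringence.shape:
            raise ValueError("temperature and birefringence arrays differ in length")
        if self.temperature_k.size < 7:
            raise ValueError("a melting curve needs at least 7 points")
        if np.any(self.temperature_k <= 0):
            raise ValueError("temperatures must be positive Kelvin")
        if not np.all(np.diff(self.temperature_k) > 0):
            raise ValueError("temperatures must be strictly increasing")


def hill_model(T, p: HillParams):
    """Evaluate the two-transition model at temperature(s) T (Kelvin).

    Uses the logistic form of each Hill term, finite for any k, m.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive Kelvin")
    term1 = p.B * expit(p.k * np.log(T / p.T1))
    term2 = p.C * expit(p.m * np.log(T / p.T2))
    return p.A - term1 - term2


def _naive_hill(T, p: HillParams):
    """Direct ratio form; overflows for large k — test oracle only."""
    T = np.asarray(T, dtype=float)
    return (p.A - p.B * T**p.k / (p.T1**p.k + T**p.k)
            - p.C * T**p.m / (p.T2**p.m + T**p.m))


def spline_transitions(curve: MeltingCurve, n_eval: int = 2000) -> list[float]:
    """Transition temperatures by spline differentiation.

    A smoothing spline (penalty chosen by generalized cross-validation)
    is fit to the curve; transitions are the local minima of its first
    derivative, i.e. the temperatures of steepest birefringence loss.
    Mechanism-free: no Hill model is assumed.
    """
    T, I = curve.temperature_k, curve.birefringence
    if np.ptp(I) < 1e-12:
        return []
    spl = make_smoothing_spline(T, I)  # lam=None -> GCV
    grid = np.linspace(T[0], T[-1], n_eval)
    deriv = spl.derivative()(grid)
    descent = -deriv
    peak_idx, _ = find_peaks(descent, height=0.25 * descent.max())
    if descent.max() <= 0:
        return []
    return sorted(float(grid[i]) for i in peak_idx)


@dataclass
class FitResult:
    params: HillParams
    r_squared: float
    residuals: np.ndarray
    converged: bool
    n_iter: int


def _auto_init(curve: MeltingCurve) -> HillParams:
    T, I = curve.temperature_k, curve.birefringence
    A0 = float(I.max())
    span = max(float(A0 - I.min()), 1e-6)
    trans = spline_transitions(curve)
    if len(trans) >= 2:
        T1, T2 = trans[0], trans[-1]
    elif len(trans) == 1:
        T1 = trans[0]
        T2 = min(trans[0] + 0.2 * np.ptp(T), T[-1])
    else:
        T1 = T[0] + 0.3 * np.ptp(T)
        T2 = T[0] + 0.7 * np.ptp(T)
    if T2 - T1 < 1.0:
        T2 = T1 + 1.0
    return HillParams(A=A0, B=span / 2, C=span / 2, T1=float(T1), T2=float(T2),
                      k=30.0, m=30.0)


_BOUNDS_LO = np.array([1e-6, 0.0, 0.0, 200.0, 200.0, np.log(1.0), np.log(1.0)])
_BOUNDS_HI = np.array([10.0, 10.0, 10.0, 500.0, 500.0, np.log(500.0), np.log(500.0)])


def _pack(p: HillParams) -> np.ndarray:
    return np.array([p.A, p.B, p.C, p.T1, p.T2, np.log(p.k), np.log(p.m)])


def _unpack(x: np.ndarray) -> HillParams:
    A, B, C, T1, T2, lnk, lnm = x
    if T1 > T2:  # identifiability tie-break: report with T1 < T2
        T1, T2 = T2, T1
        B, C = C, B
        lnk, lnm = lnm, lnk
    if T1 == T2:
        T2 = T1 + 1e-9
    return HillParams(A=A, B=B, C=C, T1=T1, T2=T2, k=float(np.exp(lnk)),
                      m=float(np.exp(lnm)))


def fit_melting(curve: MeltingCurve, init: HillParams | str = "auto",
                max_nfev: int = 10000) -> FitResult:
    """Least-squares fit of the two-transition model to a melting curve.

    Cooperativity coefficients are optimized in log-space (they span
    roughly 30-120 between genotypes); the T1 < T2 ordering is restored
    by swapping (T1, k, B) with (T2, m, C) after optimization if the
    optimizer crossed them.  Non-convergence is reported through the
    ``converged`` flag, not raised.
    """
    if isinstance(init, str):
        if init != "auto":
            raise ValueError(f"unknown init mode {init!r}")
        p0 = _auto_init(curve)
    else:
        p0 = init
    x0 = np.clip(_pack(p0), _BOUNDS_LO, _BOUNDS_HI)
    T, I = curve.temperature_k, curve.birefringence

    def resid(x):
        A, B, C, T1, T2, lnk, lnm = x
        model = (A - B * expit(np.exp(lnk) * np.log(T / T1))
                 - C * expit(np.exp(lnm) * np.log(T / T2)))
        return model - I

    res = least_squares(resid, x0, bounds=(_BOUNDS_LO, _BOUNDS_HI),
                        method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12,
                        max_nfev=max_nfev)
    params = _unpack(res.x)
    residuals = hill_model(T, params) - I
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return FitResult(params=params, r_squared=r2, residuals=residuals,
                     converged=bool(res.status > 0), n_iter=int(res.nfev))


def melt_fraction_at(p: HillParams, fraction: float) -> float:
    """Temperature (K) at which a given fraction of melting is reached.

    The melted fraction is (A - I(T)) / (B + C), monotone in T; the
    crossing is bracketed and solved by bisection.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if p.B + p.C == 0:
        raise ValueError("melt fraction undefined when B + C = 0")

    def f(T):
        return (p.A - float(hill_model(T, p))) / (p.B + p.C) - fraction

    lo, hi = p.T1 / 100.0, p.T2 * 100.0
    return float(brentq(f, lo, hi, xtol=1e-9))
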