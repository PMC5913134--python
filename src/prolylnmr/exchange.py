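"""Closed-form two-site longitudinal exchange model with relaxation.

Models the magnetization transfer between the *cis* and *trans* conformers
of an Xaa-Pro peptide bond during the mixing time of a ROESY/EXSY
experiment.  The longitudinal two-site kinetic matrix

    d/dt [M_c, M_t] = -A [M_c, M_t],
    A = [[k_ct + R2c, -k_tc], [-k_ct, k_tc + R2t]]

has eigenvalues lambda_1 >= lambda_2 and yields closed-form diagonal
(I_cc, I_tt) and cross-peak (I_ct, I_tc) intensities as biexponentials in
the mixing time.  Cross peaks are absent at t_m = 0 and build up at a rate
set by the exchange rates; the equilibrium trans/cis population ratio
K_isom = k_ct / k_tc follows from detailed balance.

Rates and relaxation rates are in s^-1, mixing times in s.  Intensities
are in arbitrary units; only their ratios matter to the fitting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExchangeParameters",
    "EigenSystem",
    "IntensityCurve",
    "RatioCurve",
    "eigen_system",
    "predict_intensities",
    "predict_ratios",
    "k_ex",
    "equilibrium_ratio",
    "DEGENERACY_RTOL",
]

#: Relative eigenvalue-gap threshold below which the analytic degenerate
#: limit (t * exp(-lambda t)) replaces the difference quotient, avoiding
#: catastrophic cancellation.
DEGENERACY_RTOL = 1e-8


@dataclass(frozen=True)
class ExchangeParameters:
    """Kinetic and relaxation parameters of the two-site exchange model.

    Attributes
    ----------
    k_ct, k_tc:
        Apparent (catalyzed) cis->trans and trans->cis rate constants, s^-1.
    R2_c, R2_t:
        Rotating-frame relaxation rates of cis and trans magnetization, s^-1.
    I0_c, I0_t:
        Diagonal peak intensities at zero mixing time, arbitrary units.
    """

    k_ct: float
    k_tc: float
    R2_c: float = 0.0
    R2_t: float = 0.0
    I0_c: float = 1.0
    I0_t: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_ct", "k_tc", "R2_c", "R2_t"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {getattr(self, name)}")
        for name in ("I0_c", "I0_t"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {getattr(self, name)}")


@dataclass(frozen=True)
class EigenSystem:
    """Eigenvalues and coefficients of the 2x2 exchange-relaxation matrix."""

    lambda1: float
    lambda2: float
    a11: float
    a22: float
    a12: float
    a21: float


@dataclass
class IntensityCurve:
    """ROESY diagonal and cross-peak intensities versus mixing time."""

    mixing_times: np.ndarray
    I_cc: np.ndarray
    I_tt: np.ndarray
    I_ct: np.ndarray
    I_tc: np.ndarray

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        for name in ("I_cc", "I_tt", "I_ct", "I_tc"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.mixing_times.shape:
                raise ValueError(f"{name} length {arr.shape} != mixing_times {self.mixing_times.shape}")
            setattr(self, name, arr)
        t = self.mixing_times
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("mixing_times must be non-negative and strictly increasing")


@dataclass
class RatioCurve:
    """Cross/diagonal intensity ratios r_ct = I_ct/I_cc, r_tc = I_tc/I_tt.

    ``sigma_ct`` / ``sigma_tc`` are optional per-point ratio uncertainties
    (e.g. propagated from the spectral noise floor); when present the fit
    weights points by 1/sigma^2, otherwise weights are unit.
    """

    mixing_times: np.ndarray
    r_ct: np.ndarray
    r_tc: np.ndarray
    sigma_ct: np.ndarray | None = None
    sigma_tc: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        self.r_ct = np.asarray(self.r_ct, dtype=float)
        self.r_tc = np.asarray(self.r_tc, dtype=float)
        if self.r_ct.shape != self.mixing_times.shape or self.r_tc.shape != self.mixing_times.shape:
            raise ValueError("ratio arrays must match mixing_times in length")
        t = self.mixing_times
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("mixing_times must be non-negative and strictly increasing")
        if not (np.all(np.isfinite(self.r_ct)) and np.all(np.isfinite(self.r_tc))):
            raise ValueError("ratios must be finite")
        for name in ("sigma_ct", "sigma_tc"):
            sig = getattr(self, name)
            if sig is not None:
                sig = np.asarray(sig, dtype=float)
                if sig.shape != self.mixing_times.shape:
                    raise ValueError(f"{name} must match mixing_times in length")
                if np.any(sig <= 0):
                    raise ValueError(f"{name} must be > 0 where given")
                setattr(self, name, sig)


def eigen_system(params: ExchangeParameters) -> EigenSystem:
    """Rate-matrix coefficients and decay eigenvalues.

    a11 = k_ct + R2_c, a22 = k_tc + R2_t, a12 = -k_tc, a21 = -k_ct;
    lambda_{1,2} = (a11 + a22)/2 +/- sqrt((a11 - a22)^2 + 4 k_ct k_tc)/2,
    ordered lambda1 >= lambda2.
    """
    a11 = params.k_ct + params.R2_c
    a22 = params.k_tc + params.R2_t
    disc = math.sqrt((a11 - a22) ** 2 + 4.0 * params.k_ct * params.k_tc)
    lam1 = 0.5 * ((a11 + a22) + disc)
    lam2 = 0.5 * ((a11 + a22) - disc)
    return EigenSystem(lambda1=lam1, lambda2=lam2, a11=a11, a22=a22,
                       a12=-params.k_tc, a21=-params.k_ct)


def _biexp_curves(params: ExchangeParameters, t: np.ndarray,
                  degeneracy_rtol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    es = eigen_system(params)
    lam1, lam2, a11, a22 = es.lambda1, es.lambda2, es.a11, es.a22
    gap = lam1 - lam2
    if gap < degeneracy_rtol * (lam1 + lam2 + 1.0):
        # Degenerate limit lambda1 -> lambda2 = lam:
        #   I_cc -> I0_c e^{-lam t} [1 + (lam - a11) t], cross -> -a21 I0_c t e^{-lam t}
        lam = 0.5 * (lam1 + lam2)
        e = np.exp(-lam * t)
        I_cc = params.I0_c * e * (1.0 + (lam - a11) * t)
        I_tt = params.I0_t * e * (1.0 + (lam - a22) * t)
        I_ct = params.I0_c * params.k_ct * t * e
        I_tc = params.I0_t * params.k_tc * t * e
        return I_cc, I_tt, I_ct, I_tc
    e1 = np.exp(-lam1 * t)
    e2 = np.exp(-lam2 * t)
    I_cc = params.I0_c * (-(lam2 - a11) * e1 + (lam1 - a11) * e2) / gap
    I_tt = params.I0_t * (-(lam2 - a22) * e1 + (lam1 - a22) * e2) / gap
    I_ct = params.I0_c * (es.a21 * e1 - es.a21 * e2) / gap
    I_tc = params.I0_t * (es.a12 * e1 - es.a12 * e2) / gap
    return I_cc, I_tt, I_ct, I_tc


def predict_intensities(params: ExchangeParameters, mixing_times,
                        degeneracy_rtol: float = DEGENERACY_RTOL) -> IntensityCurve:
    """Closed-form diagonal and cross-peak intensities at each mixing time.

    Near eigenvalue degeneracy (relative gap below ``degeneracy_rtol``) the
    analytic ``t * exp(-lambda t)`` limit replaces the difference quotient.
    """
    if degeneracy_rtol <= 0:
        raise ValueError("degeneracy_rtol must be > 0")
    t = np.asarray(mixing_times, dtype=float)
    if np.any(t < 0):
        raise ValueError("mixing times must be >= 0")
    I_cc, I_tt, I_ct, I_tc = _biexp_curves(params, t, degeneracy_rtol)
    return IntensityCurve(mixing_times=t, I_cc=I_cc, I_tt=I_tt, I_ct=I_ct, I_tc=I_tc)


def predict_ratios(params: ExchangeParameters, mixing_times,
                   degeneracy_rtol: float = DEGENERACY_RTOL,
                   diagonal_floor: float = 1e-12) -> RatioCurve:
    """Cross/diagonal ratios r_ct = I_ct/I_cc and r_tc = I_tc/I_tt.

    The ratios are independent of the initial intensities and of the common
    part of the relaxation: they depend only on (k_ct, k_tc, R2_c - R2_t).
    Points where a predicted diagonal falls below ``diagonal_floor`` times
    its initial value are dropped with a warning record.
    """
    curve = predict_intensities(params, mixing_times, degeneracy_rtol)
    t = curve.mixing_times
    floor_c = diagonal_floor * params.I0_c
    floor_t = diagonal_floor * params.I0_t
    ok = (np.abs(curve.I_cc) > floor_c) & (np.abs(curve.I_tt) > floor_t)
    ok |= t == 0.0  # t=0 ratios are identically 0 regardless of the diagonals
    warnings = []
    if not np.all(ok):
        dropped = t[~ok]
        warnings.append(f"dropped {dropped.size} point(s) with underflowing diagonal: t_m={dropped.tolist()}")
    t_ok = t[ok]
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ct = np.where(t_ok == 0.0, 0.0, curve.I_ct[ok] / curve.I_cc[ok])
        r_tc = np.where(t_ok == 0.0, 0.0, curve.I_tc[ok] / curve.I_tt[ok])
    return RatioCurve(mixing_times=t_ok, r_ct=r_ct, r_tc=r_tc, warnings=warnings)


def k_ex(params: ExchangeParameters) -> float:
    """Total exchange rate k_ex = k_ct + k_tc, s^-1."""
    return params.k_ct + params.k_tc


def equilibrium_ratio(params: ExchangeParameters) -> float:
    """Equilibrium trans/cis population ratio K_isom = k_ct / k_tc."""
    if params.k_tc == 0:
        raise ZeroDivisionError("K_isom undefined: k_tc = 0")
    return params.k_ct / params.k_tc
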