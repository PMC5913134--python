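"""Fitting ROESY cross/diagonal build-up ratios to the two-site exchange model.

The observed quantities are the cross-to-diagonal intensity ratios
r_ct(t_m) = I_ct/I_cc and r_tc(t_m) = I_tc/I_tt as functions of mixing
time.  In ratio space the initial intensities and the common part of the
relaxation cancel, leaving three identifiable parameters: the two exchange
rates (k_ct, k_tc) and the relaxation difference dR2 = R2_c - R2_t.  Both
ratio branches are fit jointly by weighted least squares with non-negative
rate bounds and seeded multi-start restarts; an optional detailed-balance
constraint ties k_ct to k_tc through an independently measured (TOCSY)
trans/cis population ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .exchange import (
    DEGENERACY_RTOL,
    ExchangeParameters,
    IntensityCurve,
    RatioCurve,
    predict_ratios,
)

__all__ = [
    "TocsyMeasurement",
    "ExchangeFitResult",
    "build_ratio_curves",
    "estimate_initial_rates",
    "fit_exchange",
    "tocsy_population_ratio",
    "detailed_balance_check",
]

_DIAGONAL_FLOOR = 1e-12  # a.u.; diagonals below this are unusable for ratios
_MIN_POINTS = 4
_FALLBACK_RATE = 1.0  # s^-1, used when slope initialization is degenerate


@dataclass(frozen=True)
class TocsyMeasurement:
    """Equilibrium trans and cis peak intensities from a TOCSY spectrum."""

    I_trans: float
    I_cis: float

    def __post_init__(self) -> None:
        if not (self.I_trans > 0 and self.I_cis > 0):
            raise ValueError("TOCSY intensities must be > 0")


@dataclass
class ExchangeFitResult:
    """Recovered exchange rates with derived quantities and diagnostics.

    ``k_ex = k_ct + k_tc`` and ``K_isom_rates = k_ct/k_tc`` are derived from
    the fitted rates; when the detailed-balance constraint was applied,
    K_isom_rates equals the TOCSY ratio by construction.
    """

    k_ct: float
    k_tc: float
    delta_R2: float
    k_ex: float
    K_isom_rates: float
    standard_errors: dict[str, float | None]
    rss: float
    n_points: int
    converged: bool
    constrained: bool
    warnings: list[str] = field(default_factory=list)


def _ratio_params(k_ct: float, k_tc: float, delta_R2: float) -> ExchangeParameters:
    # Ratios depend on R2 only through the difference; shift the common part
    # out so both internal relaxation rates stay non-negative.
    return ExchangeParameters(
        k_ct=k_ct, k_tc=k_tc,
        R2_c=max(delta_R2, 0.0), R2_t=max(-delta_R2, 0.0),
    )


def predict_ratio_model(k_ct: float, k_tc: float, delta_R2: float,
                        mixing_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model ratios (r_ct, r_tc) at the given mixing times."""
    rc = predict_ratios(_ratio_params(k_ct, k_tc, delta_R2), mixing_times,
                        degeneracy_rtol=DEGENERACY_RTOL)
    if rc.mixing_times.size != np.asarray(mixing_times).size:
        raise FloatingPointError("diagonal underflow inside fitted ratio model")
    return rc.r_ct, rc.r_tc


def build_ratio_curves(curve: IntensityCurve,
                       intensity_noise_sd: float | None = None,
                       diagonal_floor: float = _DIAGONAL_FLOOR) -> RatioCurve:
    """Pointwise cross/diagonal ratios from measured intensities.

    Points at t_m = 0 are retained with ratio 0; points whose diagonal
    magnitude falls below ``diagonal_floor`` are dropped and logged.  Fewer
    than four usable points is an error.

    When ``intensity_noise_sd`` (the spectral noise floor, in intensity
    units) is given, per-point ratio uncertainties are propagated as
    sigma_r = |r| sqrt((sd/I_cross)^2 + (sd/I_diag)^2) and attached to the
    curve, so the subsequent fit downweights late mixing times where the
    decayed diagonals amplify the noise.
    """
    t = curve.mixing_times
    ok = (np.abs(curve.I_cc) > diagonal_floor) & (np.abs(curve.I_tt) > diagonal_floor)
    ok |= t == 0.0
    warnings = []
    if not np.all(ok):
        warnings.append(
            f"dropped {int(np.sum(~ok))} point(s) with near-zero diagonal: t_m={t[~ok].tolist()}")
    t_ok = t[ok]
    if t_ok.size < _MIN_POINTS:
        raise ValueError(f"insufficient data: {t_ok.size} usable points (< {_MIN_POINTS})")
    with np.errstate(divide="ignore", invalid="ignore"):
        r_ct = np.where(t_ok == 0.0, 0.0, curve.I_ct[ok] / curve.I_cc[ok])
        r_tc = np.where(t_ok == 0.0, 0.0, curve.I_tc[ok] / curve.I_tt[ok])
    sigma_ct = sigma_tc = None
    if intensity_noise_sd is not None:
        if intensity_noise_sd <= 0:
            raise ValueError("intensity_noise_sd must be > 0 when given")
        sd = intensity_noise_sd
        with np.errstate(divide="ignore", invalid="ignore"):
            # at t=0 the ratio is pinned to 0; its uncertainty is the
            # cross-peak noise seen through the diagonal
            sigma_ct = np.where(
                t_ok == 0.0, sd / np.abs(curve.I_cc[ok]),
                np.abs(r_ct) * np.sqrt((sd / curve.I_ct[ok]) ** 2 + (sd / curve.I_cc[ok]) ** 2))
            sigma_tc = np.where(
                t_ok == 0.0, sd / np.abs(curve.I_tt[ok]),
                np.abs(r_tc) * np.sqrt((sd / curve.I_tc[ok]) ** 2 + (sd / curve.I_tt[ok]) ** 2))
        sigma_ct = np.where(np.isfinite(sigma_ct) & (sigma_ct > 0), sigma_ct, sd)
        sigma_tc = np.where(np.isfinite(sigma_tc) & (sigma_tc > 0), sigma_tc, sd)
    return RatioCurve(mixing_times=t_ok, r_ct=r_ct, r_tc=r_tc,
                      sigma_ct=sigma_ct, sigma_tc=sigma_tc, warnings=warnings)


def _origin_slope(t: np.ndarray, r: np.ndarray) -> float:
    # least-squares slope of r = s*t through the origin
    denom = float(np.dot(t, t))
    if denom == 0.0:
        return math.nan
    return float(np.dot(t, r) / denom)


def estimate_initial_rates(ratios: RatioCurve) -> tuple[float, float, float, list[str]]:
    """Short-time slope initialization: r_ct ~ k_ct * t_m, r_tc ~ k_tc * t_m.

    Uses the first three nonzero-t_m points of each branch.  Non-finite or
    non-positive slopes fall back to 1.0 s^-1 with a warning.
    """
    nz = ratios.mixing_times > 0
    t = ratios.mixing_times[nz]
    if t.size < 3:
        raise ValueError("need >= 3 nonzero-mixing-time points for initialization")
    warnings: list[str] = []
    out = []
    for name, r in (("k_ct0", ratios.r_ct[nz]), ("k_tc0", ratios.r_tc[nz])):
        s = _origin_slope(t[:3], r[:3])
        if not math.isfinite(s) or s <= 0:
            warnings.append(f"{name}: degenerate initial slope {s}; falling back to {_FALLBACK_RATE}")
            s = _FALLBACK_RATE
        out.append(s)
    return out[0], out[1], 0.0, warnings


def tocsy_population_ratio(tocsy: TocsyMeasurement) -> float:
    """Equilibrium trans/cis population ratio I_trans / I_cis."""
    return tocsy.I_trans / tocsy.I_cis


def _fit_once(theta0: np.ndarray, resid, bounds) -> object:
    return least_squares(resid, theta0, bounds=bounds, method="trf",
                         xtol=1e-14, ftol=1e-14, gtol=1e-14)


def _standard_errors(res, n_points: int, names: list[str]) -> dict[str, float | None]:
    # local quadratic approximation: cov = s^2 (J^T J)^-1
    p = res.x.size
    dof = max(n_points - p, 1)
    s2 = 2.0 * res.cost / dof
    try:
        jtj = res.jac.T @ res.jac
        cov = s2 * np.linalg.inv(jtj)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        return {n: float(math.sqrt(d)) for n, d in zip(names, diag)}
    except np.linalg.LinAlgError:
        return {n: None for n in names}


def fit_exchange(ratios: RatioCurve,
                 tocsy: TocsyMeasurement | None = None,
                 use_constraint: bool = False,
                 seed: int | None = 0,
                 n_starts: int = 5) -> ExchangeFitResult:
    """Weighted least-squares fit of both ratio branches jointly.

    Free parameters are (k_ct, k_tc, delta_R2) with rates bounded at zero.
    With ``use_constraint`` the detailed-balance relation
    k_ct = K_isom_TOCSY * k_tc eliminates k_ct, leaving (k_tc, delta_R2).
    Weights are 1/sigma^2 when per-point ratio uncertainties are attached,
    unit otherwise.  ``n_starts`` seeded restarts perturb the slope-based
    initialization log-uniformly in [1/3, 3]; the best residual sum of
    squares wins.  Non-convergence of every start yields a flagged result,
    not an exception.
    """
    if use_constraint and tocsy is None:
        raise ValueError("use_constraint requires a TOCSY measurement")
    t = ratios.mixing_times
    obs = np.concatenate([ratios.r_ct, ratios.r_tc])
    if ratios.sigma_ct is not None and ratios.sigma_tc is not None:
        w = 1.0 / np.concatenate([ratios.sigma_ct, ratios.sigma_tc])
    else:
        w = np.ones_like(obs)
    n_points = obs.size

    k_ct0, k_tc0, dR0, warnings = estimate_initial_rates(ratios)
    K_tocsy = tocsy_population_ratio(tocsy) if tocsy is not None else None

    if use_constraint:
        names = ["k_tc", "delta_R2"]
        theta0 = np.array([k_tc0, dR0])
        bounds = ([0.0, -np.inf], [np.inf, np.inf])

        def unpack(theta):
            return K_tocsy * theta[0], theta[0], theta[1]
    else:
        names = ["k_ct", "k_tc", "delta_R2"]
        theta0 = np.array([k_ct0, k_tc0, dR0])
        bounds = ([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf])

        def unpack(theta):
            return theta[0], theta[1], theta[2]

    def resid(theta):
        k_ct, k_tc, dR2 = unpack(theta)
        r_ct, r_tc = predict_ratio_model(k_ct, k_tc, dR2, t)
        return w * (np.concatenate([r_ct, r_tc]) - obs)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_starts - 1, 0)):
        factors = np.exp(rng.uniform(math.log(1 / 3), math.log(3), size=theta0.size))
        starts.append(theta0 * factors)

    best = None
    any_converged = False
    for s0 in starts:
        try:
            res = _fit_once(np.maximum(s0, bounds[0]), resid, bounds)
        except (FloatingPointError, ValueError):
            continue
        any_converged = any_converged or bool(res.success)
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return ExchangeFitResult(
            k_ct=math.nan, k_tc=math.nan, delta_R2=math.nan, k_ex=math.nan,
            K_isom_rates=math.nan, standard_errors={n: None for n in names},
            rss=math.inf, n_points=n_points, converged=False,
            constrained=use_constraint,
            warnings=warnings + ["all multi-start fits failed"])

    k_ct, k_tc, dR2 = unpack(best.x)
    errs = _standard_errors(best, n_points, names)
    if errs.get(names[0]) is None:
        warnings = warnings + ["standard errors unavailable (singular or indefinite Hessian)"]
    return ExchangeFitResult(
        k_ct=float(k_ct), k_tc=float(k_tc), delta_R2=float(dR2),
        k_ex=float(k_ct + k_tc),
        K_isom_rates=float(k_ct / k_tc) if k_tc > 0 else math.inf,
        standard_errors=errs, rss=float(2.0 * best.cost), n_points=n_points,
        converged=any_converged, constrained=use_constraint, warnings=warnings)


def detailed_balance_check(result: ExchangeFitResult, tocsy: TocsyMeasurement,
                           tolerance: float = 0.10) -> dict:
    """Consistency of the fitted rate ratio with the TOCSY population ratio.

    Reports the relative discrepancy |k_ct/k_tc - K_TOCSY| / K_TOCSY and a
    pass flag against ``tolerance`` (default 10%).
    """
    K_tocsy = tocsy_population_ratio(tocsy)
    disc = abs(result.K_isom_rates - K_tocsy) / K_tocsy
    return {
        "K_isom_rates": result.K_isom_rates,
        "K_isom_tocsy": K_tocsy,
        "relative_discrepancy": disc,
        "tolerance": tolerance,
        "pass": bool(disc <= tolerance),
    }
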