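"""Chemical-shift-perturbation titration analysis under fast exchange.

For a 1:1 protein-ligand equilibrium P + L <-> PL with dissociation
constant K_D, the complex concentration follows the exact (ligand-depleting)
quadratic solution

    [PL] = ((P + L + K_D) - sqrt((P + L + K_D)^2 - 4 P L)) / 2

with P and L the total concentrations.  In fast exchange the observed amide
shift is the population-weighted average of free and bound states, so the
composite chemical-shift perturbation tracks the bound fraction:
ddelta = delta_max * [PL]/P.  Per-peak two-parameter (K_D, delta_max)
bound-constrained fits are aggregated as unweighted mean +/- sample s.d.;
an optional global fit shares one K_D across peaks.

Concentrations are in uM, shifts in ppm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "TitrationPoint",
    "TitrationSeries",
    "PeakFit",
    "BindingFitResult",
    "composite_csp",
    "bound_fraction",
    "predict_csp",
    "fit_peak_kd",
    "fit_global_kd",
    "aggregate_kd",
    "reverse_titration_design",
    "concentration_from_absorbance",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_RESPONSE",
]

#: 15N scaling weight in the composite amide CSP (standard convention).
DEFAULT_ALPHA = 0.14
#: Minimum composite CSP (ppm) at the highest ligand point for a peak to
#: enter the K_D statistics.
DEFAULT_MIN_RESPONSE = 0.02


@dataclass(frozen=True)
class TitrationPoint:
    """One titration sample: total concentrations plus per-peak shifts."""

    protein_total: float  # uM
    ligand_total: float  # uM
    shifts: dict[str, tuple[float, float]]  # peak_id -> (delta_H ppm, delta_N ppm)

    def __post_init__(self) -> None:
        if self.protein_total < 0 or self.ligand_total < 0:
            raise ValueError("concentrations must be >= 0")


@dataclass
class TitrationSeries:
    """Ordered titration points with an apo (ligand-free) reference."""

    points: list[TitrationPoint]
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.ligand_total)
        if not self.points or self.points[0].ligand_total != 0:
            raise ValueError("series must contain an apo (ligand_total=0) reference point")

    @property
    def reference_point(self) -> TitrationPoint:
        return self.points[0]

    @property
    def peak_ids(self) -> list[str]:
        return sorted(self.reference_point.shifts)

    def peak_data(self, peak_id: str, alpha: float = DEFAULT_ALPHA
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(protein_total, ligand_total, composite CSP) arrays for one peak.

        Points missing the peak are excluded with a log entry.
        """
        ref = self.reference_point.shifts.get(peak_id)
        if ref is None:
            raise KeyError(f"peak {peak_id!r} absent from the apo reference")
        P, L, csp = [], [], []
        for pt in self.points:
            sh = pt.shifts.get(peak_id)
            if sh is None:
                self.log.append(f"peak {peak_id!r} missing at ligand_total={pt.ligand_total}; excluded")
                continue
            P.append(pt.protein_total)
            L.append(pt.ligand_total)
            csp.append(composite_csp(sh[0] - ref[0], sh[1] - ref[1], alpha))
        return np.array(P), np.array(L), np.array(csp)


@dataclass
class PeakFit:
    peak_id: str
    K_D: float  # uM
    delta_max: float  # ppm
    K_D_stderr: float | None
    delta_max_stderr: float | None
    rss: float
    converged: bool
    excluded: bool = False
    exclusion_reason: str | None = None


@dataclass
class BindingFitResult:
    per_peak: list[PeakFit]
    aggregate_KD_mean: float
    aggregate_KD_sd: float
    n_peaks_used: int


def composite_csp(delta_H: float, delta_N: float, alpha: float = DEFAULT_ALPHA) -> float:
    """Composite amide CSP sqrt(dH^2 + (alpha*dN)^2), ppm."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return math.hypot(delta_H, alpha * delta_N)


def bound_fraction(protein_total, ligand_total, K_D):
    """Fraction of protein bound, from the exact quadratic solution.

    Accepts scalars or arrays; all concentrations in the same unit (uM).
    """
    P = np.asarray(protein_total, dtype=float)
    L = np.asarray(ligand_total, dtype=float)
    if np.any(P <= 0) or np.any(L < 0) or K_D < 0:
        raise ValueError("require protein_total > 0, ligand_total >= 0, K_D >= 0")
    s = P + L + K_D
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)  # guard tiny negative round-off
    pl = 0.5 * (s - np.sqrt(disc))
    out = np.clip(pl / P, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def predict_csp(protein_total, ligand_total, K_D: float, delta_max: float):
    """Fast-exchange CSP: delta_max times the bound fraction, ppm."""
    return delta_max * bound_fraction(protein_total, ligand_total, K_D)


def _fit_isotherm(P: np.ndarray, L: np.ndarray, csp: np.ndarray,
                  seed: int | None, n_starts: int) -> tuple[np.ndarray, object]:
    cmax = float(np.max(csp))
    half = 0.5 * cmax
    above = L[csp >= half]
    kd0 = float(np.min(above)) if above.size else float(np.max(L))
    kd0 = max(kd0, 1e-6)
    theta0 = np.array([kd0, 1.2 * cmax])

    def resid(theta):
        return predict_csp(P, L, theta[0], theta[1]) - csp

    rng = np.random.default_rng(seed)
    starts = [theta0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(theta0 * np.exp(rng.uniform(math.log(1 / 3), math.log(3), size=2)))
    best = None
    for s0 in starts:
        res = least_squares(resid, s0, bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or res.cost < best.cost:
            best = res
    return best.x, best


def fit_peak_kd(series: TitrationSeries, peak_id: str,
                alpha: float = DEFAULT_ALPHA,
                min_response: float = DEFAULT_MIN_RESPONSE,
                seed: int | None = 0, n_starts: int = 5) -> PeakFit:
    """Two-parameter (K_D, delta_max) bound-constrained fit for one peak.

    Initialized at K_D = ligand concentration at half-maximal CSP and
    delta_max = 1.2x the maximum observed CSP, with seeded multi-start.
    Peaks whose maximal response is below ``min_response`` are excluded.
    """
    P, L, csp = series.peak_data(peak_id, alpha)
    if P.size < 4:
        raise ValueError(f"peak {peak_id!r}: need >= 4 titration points, have {P.size}")
    if float(np.max(csp)) < min_response:
        return PeakFit(peak_id, math.nan, math.nan, None, None, math.nan,
                       converged=False, excluded=True,
                       exclusion_reason=f"max CSP {np.max(csp):.4f} ppm < threshold {min_response} ppm")
    theta, res = _fit_isotherm(P, L, csp, seed, n_starts)
    dof = max(P.size - 2, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        kd_se, dm_se = (float(math.sqrt(v)) if v >= 0 else None for v in np.diag(cov))
    except np.linalg.LinAlgError:
        kd_se = dm_se = None
    return PeakFit(peak_id, float(theta[0]), float(theta[1]), kd_se, dm_se,
                   rss=float(2.0 * res.cost), converged=bool(res.success))


def fit_global_kd(series: TitrationSeries, alpha: float = DEFAULT_ALPHA,
                  min_response: float = DEFAULT_MIN_RESPONSE,
                  seed: int | None = 0) -> tuple[float, list[str]]:
    """Shared-K_D fit across all responsive peaks (per-peak delta_max).

    Returns (K_D, peak ids used).  Provided as the alternative to per-peak
    aggregation; the per-peak route is the default reporting path.
    """
    used, data = [], []
    for pid in series.peak_ids:
        P, L, csp = series.peak_data(pid, alpha)
        if P.size >= 4 and float(np.max(csp)) >= min_response:
            used.append(pid)
            data.append((P, L, csp))
    if not used:
        raise ValueError("no responsive peaks for the global fit")
    kd0 = float(np.median([_fit_isotherm(P, L, c, seed, 3)[0][0] for P, L, c in data]))
    theta0 = np.array([kd0] + [1.2 * float(np.max(c)) for _, _, c in data])

    def resid(theta):
        kd = theta[0]
        return np.concatenate([
            predict_csp(P, L, kd, dm) - c
            for (P, L, c), dm in zip(data, theta[1:])])

    res = least_squares(resid, theta0, bounds=(1e-12, np.inf), method="trf",
                        xtol=1e-15, ftol=1e-15)
    return float(res.x[0]), used


def aggregate_kd(per_peak: list[PeakFit]) -> tuple[float, float, int]:
    """Unweighted mean and sample s.d. (n-1) of K_D over usable peaks.

    Usable means converged and not excluded.  A single usable peak reports
    s.d. 0 with n = 1; zero usable peaks is an error.
    """
    kds = [p.K_D for p in per_peak if p.converged and not p.excluded]
    if not kds:
        raise ValueError("no converged, above-threshold peaks to aggregate")
    n = len(kds)
    mean = float(np.mean(kds))
    sd = float(np.std(kds, ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def fit_all_peaks(series: TitrationSeries, alpha: float = DEFAULT_ALPHA,
                  min_response: float = DEFAULT_MIN_RESPONSE,
                  seed: int | None = 0) -> BindingFitResult:
    """Per-peak fits over every tracked peak plus mean +/- s.d. aggregation."""
    fits = [fit_peak_kd(series, pid, alpha, min_response, seed) for pid in series.peak_ids]
    mean, sd, n = aggregate_kd(fits)
    return BindingFitResult(per_peak=fits, aggregate_KD_mean=mean,
                            aggregate_KD_sd=sd, n_peaks_used=n)


def reverse_titration_design(protein_total: float, ligand_max: float,
                             n_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-titration concentration series.

    Constant protein; ligand starts at ``ligand_max`` and is halved at each
    of ``n_points - 2`` successive steps, plus an apo point.  Returns
    (protein, ligand) arrays ordered from apo upward.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    lig = [ligand_max * 0.5 ** i for i in range(n_points - 1)] + [0.0]
    lig = np.array(sorted(lig))
    return np.full_like(lig, float(protein_total)), lig


def concentration_from_absorbance(A280: float, extinction: float, path_cm: float = 1.0) -> float:
    """Beer-Lambert concentration A/(eps*l), reported in uM."""
    if extinction <= 0 or path_cm <= 0 or A280 < 0:
        raise ValueError("require A280 >= 0, extinction > 0, path > 0")
    return A280 / (extinction * path_cm) * 1e6
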