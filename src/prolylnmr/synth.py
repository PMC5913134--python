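"""Seeded synthetic-data generators with known ground truth.

Produces ROESY intensity tables, TOCSY population-ratio measurements,
reverse-titration CSP series, and toy structural ensembles, so that every
fitting stage can be exercised end to end without any external data.
All generators are pure functions of (parameters, config, seed).

Noise is additive Gaussian on raw intensities (not on ratios): experimental
noise lives in the spectrum, and the ratio noise it induces is naturally
correlated between cross and diagonal peaks.  Default noise levels — 1% of
the initial intensity, 0.005 ppm for 1H and 0.02 ppm for 15N shifts — match
typical HSQC measurement precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exchange import ExchangeParameters, IntensityCurve, predict_intensities
from .structure import StructureEnsemble
from .titration import TitrationPoint, TitrationSeries, bound_fraction, reverse_titration_design

__all__ = [
    "SyntheticConfig",
    "PS110_MIXING_TIMES_MS",
    "S110E_MIXING_TIMES_MS",
    "generate_roesy_dataset",
    "generate_tocsy_ratio",
    "generate_titration_dataset",
    "generate_toy_ensemble",
]

#: ROESY mixing-time series used for the phosphopeptide experiment, ms.
PS110_MIXING_TIMES_MS = (0.0, 4.0, 8.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0)
#: ROESY mixing-time series used for the phosphomimetic (S110E) experiment, ms.
S110E_MIXING_TIMES_MS = (0.0, 16.0, 20.0, 40.0, 60.0, 80.0, 100.0, 150.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; identical (config, seed) gives identical output."""

    seed: int = 0
    noise_sd_intensity: float = 0.01  # a.u., additive on raw intensities (I0_c = 1 scale)
    noise_sd_shift_H: float = 0.005  # ppm
    noise_sd_shift_N: float = 0.02  # ppm
    mixing_times_ms: tuple[float, ...] = PS110_MIXING_TIMES_MS
    protein_total: float = 50.0  # uM
    ligand_max: float = 2000.0  # uM
    n_titration_points: int = 9  # 8 halving steps + apo
    n_peaks: int = 10
    delta_max_range: tuple[float, float] = (0.05, 0.3)  # ppm, composite scale

    def __post_init__(self) -> None:
        if min(self.noise_sd_intensity, self.noise_sd_shift_H, self.noise_sd_shift_N) < 0:
            raise ValueError("noise parameters must be >= 0")


def generate_roesy_dataset(params: ExchangeParameters, config: SyntheticConfig
                           ) -> tuple[IntensityCurve, dict]:
    """Noisy ROESY intensity curves drawn from the two-site exchange model.

    Unless the caller overrides the initial intensities, they are set to the
    equilibrium populations I0_t / I0_c = k_ct / k_tc (detailed balance).
    Returns the curve and a ground-truth record.
    """
    if params.I0_c == params.I0_t == 1.0 and params.k_tc > 0:
        params = ExchangeParameters(
            k_ct=params.k_ct, k_tc=params.k_tc, R2_c=params.R2_c, R2_t=params.R2_t,
            I0_c=1.0, I0_t=params.k_ct / params.k_tc)
    t_s = np.asarray(config.mixing_times_ms, dtype=float) / 1e3
    clean = predict_intensities(params, t_s)
    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd_intensity
    noisy = IntensityCurve(
        mixing_times=t_s,
        I_cc=clean.I_cc + rng.normal(0, sd, t_s.shape),
        I_tt=clean.I_tt + rng.normal(0, sd, t_s.shape),
        I_ct=clean.I_ct + rng.normal(0, sd, t_s.shape),
        I_tc=clean.I_tc + rng.normal(0, sd, t_s.shape),
    )
    truth = {
        "k_ct": params.k_ct, "k_tc": params.k_tc,
        "R2_c": params.R2_c, "R2_t": params.R2_t,
        "I0_c": params.I0_c, "I0_t": params.I0_t,
        "k_ex": params.k_ct + params.k_tc,
        "noise_sd_intensity": sd, "seed": config.seed,
    }
    return noisy, truth


def generate_tocsy_ratio(K_isom: float, noise_cv: float = 0.0, seed: int = 0
                         ) -> tuple[float, float]:
    """(I_trans, I_cis) with multiplicative Gaussian noise of CV ``noise_cv``."""
    if K_isom <= 0:
        raise ValueError("K_isom must be > 0")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0, noise_cv, size=2) if noise_cv > 0 else np.zeros(2)
    return K_isom * (1.0 + eps[1]), 1.0 * (1.0 + eps[0])


def generate_titration_dataset(K_D: float, config: SyntheticConfig
                               ) -> tuple[TitrationSeries, dict]:
    """Reverse-titration CSP series under the single-site fast-exchange model.

    Each peak gets independent 1H and 15N maximal shift changes: the 1H
    component is drawn uniformly from ``delta_max_range`` and the 15N
    component from the same range rescaled to typical amide-nitrogen
    dispersion, each with a random sign.  Shift noise is added per nucleus;
    the apo point carries zero perturbation by construction.
    """
    rng = np.random.default_rng(config.seed)
    P, L = reverse_titration_design(config.protein_total, config.ligand_max,
                                    config.n_titration_points)
    lo, hi = config.delta_max_range
    peak_ids = [f"peak{i:02d}" for i in range(config.n_peaks)]
    dmax_H = rng.uniform(lo, hi, config.n_peaks) * rng.choice([-1, 1], config.n_peaks)
    # 15N shifts disperse ~7x wider than 1H; keep the composite in range.
    dmax_N = rng.uniform(lo, hi, config.n_peaks) / 0.14 * rng.choice([-1, 1], config.n_peaks)
    ref_H = rng.uniform(6.5, 10.5, config.n_peaks)
    ref_N = rng.uniform(105.0, 130.0, config.n_peaks)

    points = []
    for p_tot, l_tot in zip(P, L):
        fb = bound_fraction(p_tot, l_tot, K_D) if l_tot > 0 else 0.0
        shifts = {}
        for i, pid in enumerate(peak_ids):
            nH = rng.normal(0, config.noise_sd_shift_H) if (config.noise_sd_shift_H > 0 and l_tot > 0) else 0.0
            nN = rng.normal(0, config.noise_sd_shift_N) if (config.noise_sd_shift_N > 0 and l_tot > 0) else 0.0
            shifts[pid] = (ref_H[i] + fb * dmax_H[i] + nH,
                           ref_N[i] + fb * dmax_N[i] + nN)
        points.append(TitrationPoint(protein_total=float(p_tot),
                                     ligand_total=float(l_tot), shifts=shifts))
    truth = {
        "K_D": K_D, "delta_max_H": dmax_H.tolist(), "delta_max_N": dmax_N.tolist(),
        "peak_ids": peak_ids, "seed": config.seed,
        "protein_total": config.protein_total, "ligand_max": config.ligand_max,
    }
    return TitrationSeries(points=points), truth


def generate_toy_ensemble(n_models: int, n_residues: int,
                          displacement_sd: float, seed: int = 0,
                          rigid_motion: bool = True) -> tuple[StructureEnsemble, dict]:
    """Synthetic backbone ensemble: a base trace plus per-model perturbation.

    The base structure is an idealized helical backbone trace (N, CA, C per
    residue).  Each model is the base plus an optional random rigid-body
    rotation/translation plus isotropic per-atom Gaussian jitter of sd
    ``displacement_sd`` (Angstrom).  Returns models as a list of records
    compatible with the structure module, plus the ground truth.
    """
    if n_models < 2:
        raise ValueError("need >= 2 models")
    rng = np.random.default_rng(seed)
    # idealized alpha-helical trace: rise 1.5 A / residue, 100 deg twist, r=2.3 A
    atoms_per_res = [("N", 0.0), ("CA", 0.5), ("C", 1.0)]
    base, meta = [], []
    for r in range(n_residues):
        for k, (name, frac) in enumerate(atoms_per_res):
            s = r + frac / 3.0
            ang = np.deg2rad(100.0) * s
            base.append([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * s])
            meta.append((name, r + 1))
    base = np.array(base)

    models = []
    for _ in range(n_models):
        coords = base.copy()
        if rigid_motion:
            # random proper rotation via QR of a Gaussian matrix
            q, r_ = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.sign(np.diag(r_))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            coords = coords @ q.T + rng.uniform(-20, 20, 3)
        if displacement_sd > 0:
            coords = coords + rng.normal(0, displacement_sd, coords.shape)
        models.append([
            {"name": name, "resnum": resnum, "chain": "A", "element": name[0],
             "coord": tuple(map(float, xyz))}
            for (name, resnum), xyz in zip(meta, coords)])
    truth = {"displacement_sd": displacement_sd, "n_models": n_models,
             "n_residues": n_residues, "seed": seed, "rigid_motion": rigid_motion}
    return StructureEnsemble(models=models), truth
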