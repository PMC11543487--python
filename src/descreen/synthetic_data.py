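"""Seeded generators emulating every input the screening pipeline consumes.

The generators stand in for the study's raw measurements so each stage is
testable without laboratory data: first-order activity/absorbance decays
with multiplicative noise (assay-CV-like), Michaelis-Menten depletion
progress curves with additive noise, three-peak sigma-profiles
(HBD / nonpolar / HBA) as sums of Gaussian bumps, and screening tables
drawn from a planted piecewise-linear model with triplicate replicates.
Noiseless modes reproduce the corresponding forward models exactly, and
identical seeds give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import DecayTimeSeries
from .mm_productivity import MMKinetics, ProgressCurve, simulate_depletion
from .sigma_descriptors import SigmaProfile, mix_profiles, region_areas
from .plr_qsar import PLRModel

__all__ = [
    "gen_decay",
    "gen_mm_progress",
    "gen_sigma_profile",
    "sigma_preset",
    "gen_screening_table",
    "SIGMA_PRESETS",
]


def gen_decay(
    rate: float,
    amplitude: float,
    schedule: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    time_unit: str = "day",
    signal_kind: str = "activity",
) -> DecayTimeSeries:
    """Exponential decay ``A0 exp(-k t)`` with multiplicative Gaussian noise.

    ``noise_sd`` is the coefficient of variation (e.g. 0.05 for 5%); values
    are clipped at zero. Reproducible per seed.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule must be non-empty")
    clean = amplitude * np.exp(-rate * schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean * (1.0 + noise_sd * rng.standard_normal(schedule.shape))
    return DecayTimeSeries(
        times=schedule,
        values=np.clip(clean, 0.0, None),
        time_unit=time_unit,
        signal_kind=signal_kind,
    )


def gen_mm_progress(
    vmax: float,
    ks: float,
    c0: float,
    schedule: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> ProgressCurve:
    """Michaelis-Menten depletion curve plus additive Gaussian noise.

    ``noise_sd`` is absolute (umol/mL); concentrations are clipped at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    curve = simulate_depletion(MMKinetics(vmax=vmax, ks=ks), c0, np.asarray(schedule, float))
    conc = curve.concentrations
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        conc = conc + noise_sd * rng.standard_normal(conc.shape)
    return ProgressCurve(times=curve.times, concentrations=np.clip(conc, 0.0, None))


#: Three-Gaussian presets (center e/A^2, width, area) qualitatively matching
#: the study's components: water symmetric polar peaks; a glycerol-like
#: polyol with heavier HBD-side (sigma < -0.01) mass than HBA-side; a
#: choline-chloride-like salt dominated by the nonpolar cation peak plus a
#: chloride peak beyond +0.01.
SIGMA_PRESETS: dict[str, list[tuple[float, float, float]]] = {
    "water": [(-0.016, 0.0035, 20.0), (0.0, 0.002, 8.0), (0.016, 0.0035, 20.0)],
    "glycerol_like": [(-0.014, 0.004, 55.0), (-0.002, 0.004, 60.0), (0.0115, 0.003, 38.0)],
    "chcl_like": [(-0.008, 0.004, 25.0), (0.002, 0.005, 90.0), (0.016, 0.004, 40.0)],
}


def gen_sigma_profile(
    peaks: list[tuple[float, float, float]],
    sigma_min: float = -0.03,
    sigma_max: float = 0.03,
    n_points: int = 241,
) -> SigmaProfile:
    """Sum of Gaussian bumps (center, width, area) sampled on a uniform grid.

    The grid must span at least the conventional [-0.025, +0.025] e/A^2
    descriptor range.
    """
    if sigma_min > -0.025 or sigma_max < 0.025:
        raise ValueError("grid must span at least [-0.025, +0.025] e/A^2")
    for _, width, _ in peaks:
        if width <= 0:
            raise ValueError("peak widths must be > 0")
    grid = np.linspace(sigma_min, sigma_max, n_points)
    vals = np.zeros_like(grid)
    for center, width, area in peaks:
        vals += area / (width * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((grid - center) / width) ** 2
        )
    return SigmaProfile(sigma_grid=grid, areas=vals)


def sigma_preset(name: str, **kwargs) -> SigmaProfile:
    """One of the built-in component profiles: water, glycerol_like, chcl_like."""
    if name not in SIGMA_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(SIGMA_PRESETS)}")
    return gen_sigma_profile(SIGMA_PRESETS[name], **kwargs)


#: Predictor ranges mirroring the screening table's observed extremes.
PREDICTOR_RANGES = {
    "viscosity": (1.0, 360.0),   # log-uniform, mPa s
    "density": (1.02, 1.21),     # uniform, g/cm^3
    "ph": (5.3, 9.2),            # uniform
}


def gen_screening_table(
    planted: PLRModel,
    n_systems: int = 21,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Screening table drawn from a planted piecewise-linear model.

    Predictors named "viscosity"/"density"/"ph" draw from the study's
    observed ranges; any "smix*" predictor draws from descriptors of random
    water/glycerol-like/chcl-like mixtures, scaled to each region's span.
    The response applies the planted model (membership from the noiseless
    response) plus additive Gaussian noise of SD ``noise_sd``; replicate
    rows share predictors with independent noise.
    """
    if n_systems < 6:
        raise ValueError("need at least 6 systems to populate two segments")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)

    def draw_predictors(n: int) -> pd.DataFrame:
        smix_names = [nm for nm in planted.input_names if nm.startswith("smix")]
        smix_table = None
        if smix_names:
            profiles = {k: sigma_preset(k) for k in SIGMA_PRESETS}
            rows = []
            for _ in range(n):
                w = rng.dirichlet(np.ones(3))
                mixed = mix_profiles(profiles, dict(zip(SIGMA_PRESETS, w)))
                rows.append(region_areas(mixed).as_dict())
            smix_table = pd.DataFrame(rows)
        cols = {}
        for nm in planted.input_names:
            if nm == "viscosity":
                lo, hi = PREDICTOR_RANGES["viscosity"]
                cols[nm] = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
            elif nm == "density":
                cols[nm] = rng.uniform(*PREDICTOR_RANGES["density"], n)
            elif nm == "ph":
                cols[nm] = rng.uniform(*PREDICTOR_RANGES["ph"], n)
            elif nm.startswith("smix") and smix_table is not None and nm in smix_table:
                cols[nm] = smix_table[nm].to_numpy()
            else:
                cols[nm] = rng.uniform(0.0, 1.0, n)
        return pd.DataFrame(cols)[planted.input_names]

    # rejection-sample design points whose noiseless response is
    # self-consistent with the response-side membership rule (lo <= b_n, or
    # hi > b_n when the low segment overshoots); ambiguous rows would not be
    # realisable under the planted piecewise model
    kept_X: list[pd.DataFrame] = []
    kept_y: list[np.ndarray] = []
    n_found = 0
    for _ in range(200):
        batch = draw_predictors(n_systems)
        lo_vals, hi_vals = planted.segment_values(batch.to_numpy())
        lo_ok = lo_vals <= planted.breakpoint
        hi_ok = hi_vals > planted.breakpoint
        valid = lo_ok ^ hi_ok  # exactly one branch realisable: unambiguous row
        y_batch = np.where(lo_ok, lo_vals, hi_vals)
        kept_X.append(batch[valid])
        kept_y.append(y_batch[valid])
        n_found += int(valid.sum())
        if n_found >= n_systems:
            break
    else:
        raise RuntimeError("planted model admits too few self-consistent rows")
    X = pd.concat(kept_X, ignore_index=True).iloc[:n_systems]
    y_clean = np.concatenate(kept_y)[:n_systems]

    frames = []
    for rep in range(replicates):
        noise = noise_sd * rng.standard_normal(n_systems) if noise_sd > 0 else 0.0
        f = X.copy()
        f.insert(0, "system", [f"sys{i + 1:02d}" for i in range(n_systems)])
        f["replicate"] = rep + 1
        f["response"] = y_clean + noise
        frames.append(f)
    return pd.concat(frames, ignore_index=True)
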