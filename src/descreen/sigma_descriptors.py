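"""Mixture descriptors from COSMO-RS sigma-profiles.

A sigma-profile is the unnormalized histogram of a molecule's screened
surface-charge density sigma (e/A^2). Negative sigma marks hydrogen-bond
donor (HBD) atoms, near-zero sigma the nonpolar surface, positive sigma
hydrogen-bond acceptor (HBA) atoms. For a solvent mixture, the profile is
the mole-fraction-weighted sum of the component profiles; splitting the
conventional plotting range [-0.025, +0.025] e/A^2 into ten equal-width
regions and integrating the mixture profile over each yields the ten
mixture descriptors S1mix..S10mix used as QSAR inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SigmaProfile",
    "MixtureComposition",
    "MixtureDescriptor",
    "DEFAULT_BOUNDS",
    "WATER_MOLAR_MASS",
    "MOLAR_MASSES",
    "mole_fractions",
    "mix_profiles",
    "region_areas",
    "classify_sigma",
]

DEFAULT_BOUNDS = (-0.025, 0.025)
WATER_MOLAR_MASS = 18.015

#: Molar masses (g/mol) of the screening study's components.
MOLAR_MASSES = {
    "choline chloride": 139.62,
    "betaine": 117.15,
    "glycerol": 92.09,
    "water": WATER_MOLAR_MASS,
}


@dataclass
class SigmaProfile:
    """Profile values on a strictly increasing, uniform sigma grid."""

    sigma_grid: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.sigma_grid.ndim != 1 or self.sigma_grid.shape != self.areas.shape:
            raise ValueError("grid and areas must be 1-D and the same length")
        d = np.diff(self.sigma_grid)
        if np.any(d <= 0):
            raise ValueError("sigma grid must be strictly increasing")
        if not np.allclose(d, d[0], rtol=1e-8, atol=1e-15):
            raise ValueError("sigma grid must be uniform")
        if np.any(self.areas < 0):
            raise ValueError("profile values must be non-negative")

    @property
    def spacing(self) -> float:
        return float(self.sigma_grid[1] - self.sigma_grid[0])

    def total_area(self, bounds: tuple[float, float] | None = None) -> float:
        lo, hi = bounds if bounds is not None else (self.sigma_grid[0], self.sigma_grid[-1])
        return _trapezoid_between(self.sigma_grid, self.areas, lo, hi)


@dataclass
class MixtureComposition:
    """HBA:HBD molar ratio plus diluent (water/buffer) mass fraction.

    The buffer diluent is treated as pure water for descriptor purposes
    (the 50 mM phosphate is ignored).
    """

    hba: str
    hbd: str
    hba_hbd_ratio: tuple[int, int] = (1, 2)
    diluent_mass_fraction: float = 0.0
    molar_masses: dict = field(default_factory=lambda: dict(MOLAR_MASSES))

    def __post_init__(self) -> None:
        if not 0.0 <= self.diluent_mass_fraction <= 1.0:
            raise ValueError("diluent mass fraction outside [0, 1]")
        for m in self.molar_masses.values():
            if m <= 0:
                raise ValueError("molar masses must be > 0")


@dataclass
class MixtureDescriptor:
    """The ten region areas S1mix..S10mix (ordered most-negative sigma first)."""

    s_mix: np.ndarray
    bounds: tuple[float, float] = DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        self.s_mix = np.asarray(self.s_mix, dtype=float)
        if np.any(self.s_mix < 0):
            raise ValueError("region areas must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {f"smix{i + 1}": float(v) for i, v in enumerate(self.s_mix)}


def mole_fractions(composition: MixtureComposition) -> dict[str, float]:
    """Convert w/w diluent fraction plus HBA:HBD molar ratio to mole fractions.

    Works per unit mass: the DES part contributes ``ratio_a : ratio_b`` moles
    of HBA and HBD per formula unit; the diluent contributes as water.
    """
    w = composition.diluent_mass_fraction
    mm = composition.molar_masses
    if w >= 1.0:
        return {"water": 1.0}
    ra, rb = composition.hba_hbd_ratio
    if ra <= 0 or rb <= 0:
        raise ValueError("HBA:HBD ratio must be positive")
    m_unit = ra * mm[composition.hba] + rb * mm[composition.hbd]
    n_unit = (1.0 - w) / m_unit       # formula units per gram of mixture
    n_hba = ra * n_unit
    n_hbd = rb * n_unit
    n_water = w / mm["water"]
    total = n_hba + n_hbd + n_water
    fracs = {
        composition.hba: n_hba / total,
        composition.hbd: n_hbd / total,
    }
    if n_water > 0:
        fracs["water"] = n_water / total
    assert abs(sum(fracs.values()) - 1.0) < 1e-12
    return fracs


def mix_profiles(profiles: dict[str, SigmaProfile], fractions: dict[str, float]) -> SigmaProfile:
    """Mole-fraction-weighted pointwise sum of component profiles.

    Profiles on different grids are linearly resampled onto the finest
    common grid spanning the union of their ranges (zero outside a
    component's own range).
    """
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("mole fractions must sum to 1")
    missing = set(fractions) - set(profiles)
    if missing:
        raise ValueError(f"no sigma-profile supplied for: {sorted(missing)}")

    used = [profiles[name] for name in fractions]
    spacings = [p.spacing for p in used]
    grids = [p.sigma_grid for p in used]
    same = all(
        len(g) == len(grids[0]) and np.allclose(g, grids[0], atol=1e-12) for g in grids
    )
    if same:
        grid = grids[0]
    else:
        lo = min(g[0] for g in grids)
        hi = max(g[-1] for g in grids)
        step = min(spacings)
        n = int(round((hi - lo) / step)) + 1
        grid = np.linspace(lo, hi, n)

    mixed = np.zeros_like(grid)
    for name, x in fractions.items():
        p = profiles[name]
        vals = np.interp(grid, p.sigma_grid, p.areas, left=0.0, right=0.0)
        mixed += x * vals
    return SigmaProfile(sigma_grid=grid, areas=mixed)


def _trapezoid_between(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal integral of the piecewise-linear profile over [lo, hi]."""
    if lo < x[0] - 1e-12 or hi > x[-1] + 1e-12:
        raise ValueError("integration bounds outside the profile's sigma range")
    inner = x[(x > lo) & (x < hi)]
    pts = np.concatenate(([lo], inner, [hi]))
    vals = np.interp(pts, x, y)
    return float(np.trapezoid(vals, pts))


def region_areas(
    profile: SigmaProfile,
    n_regions: int = 10,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> MixtureDescriptor:
    """Integrate the profile over ``n_regions`` contiguous equal-width sigma
    intervals spanning ``bounds``, ordered from most negative sigma.

    The sum of the region areas equals the total trapezoidal area over the
    bounds (conservation).
    """
    lo, hi = bounds
    if profile.sigma_grid[0] > lo + 1e-12 or profile.sigma_grid[-1] < hi - 1e-12:
        raise ValueError("profile narrower than the requested bounds")
    edges = np.linspace(lo, hi, n_regions + 1)
    areas = np.array(
        [
            _trapezoid_between(profile.sigma_grid, profile.areas, edges[i], edges[i + 1])
            for i in range(n_regions)
        ]
    )
    return MixtureDescriptor(s_mix=areas, bounds=bounds)


def classify_sigma(sigma: float, threshold: float = 0.01) -> str:
    """Label a screening charge density: HBD (< -threshold), HBA (> +threshold),
    else nonpolar. Donor atoms screen at negative sigma."""
    if not np.isfinite(sigma):
        raise ValueError("sigma must be finite")
    if sigma < -threshold:
        return "HBD"
    if sigma > threshold:
        return "HBA"
    return "nonpolar"
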