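"""0-100 rating normalization and balanced-candidate ranking.

Solvent screening rarely yields one candidate that wins every target
property; the selection step therefore rates each candidate 0-100 per
property (min-max over the displayed candidate set, oriented so "better"
is larger) and looks for a balanced profile. The maximin rule — rank by
the worst per-property rating — formalizes that visual judgement; a mean
rule and a ratio-to-best rating alternative are available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset_io import ScreeningTable, load_reported_kinetics

__all__ = [
    "RatingTable",
    "rate_property",
    "build_rating_table",
    "rank_balanced",
    "buffered_panel_values",
]


@dataclass
class RatingTable:
    """Candidates x properties matrix of ratings in [0, 100]."""

    ratings: pd.DataFrame       # index: candidates, columns: properties
    directions: dict[str, str]  # property -> "higher" | "lower"

    def __post_init__(self) -> None:
        vals = self.ratings.to_numpy(dtype=float)
        if np.any(vals < -1e-9) or np.any(vals > 100 + 1e-9):
            raise ValueError("ratings must lie in [0, 100]")

    @property
    def candidates(self) -> list[str]:
        return list(self.ratings.index)

    def to_long(self) -> pd.DataFrame:
        """Long-format (candidate, property, rating) export for radar plotting."""
        long = self.ratings.reset_index(names="candidate").melt(
            id_vars="candidate", var_name="property", value_name="rating"
        )
        return long


def rate_property(
    values: pd.Series | np.ndarray,
    direction: str = "higher",
    scheme: str = "minmax",
) -> np.ndarray:
    """Scale raw property values to 0-100 ratings.

    ``direction`` "lower" negates values first so the best candidate always
    rates 100. ``scheme`` "minmax" (default) anchors the worst candidate at
    0; "ratio" rates 100 * v / best (higher-better positive values only).
    All-equal values rate 100 everywhere with a warning.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 candidates")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if np.ptp(v) == 0:
        warnings.warn("all property values equal; every candidate rated 100", stacklevel=2)
        return np.full_like(v, 100.0)
    if scheme == "minmax":
        orient = v if direction == "higher" else -v
        return 100.0 * (orient - orient.min()) / (orient.max() - orient.min())
    if scheme == "ratio":
        if direction == "lower":
            if np.any(v <= 0):
                raise ValueError("ratio scheme with 'lower' needs positive values")
            orient = 1.0 / v
        else:
            orient = v
        if np.any(orient < 0):
            raise ValueError("ratio scheme needs non-negative oriented values")
        return 100.0 * orient / orient.max()
    raise ValueError("scheme must be 'minmax' or 'ratio'")


def build_rating_table(
    values: pd.DataFrame,
    directions: dict[str, str],
    scheme: str = "minmax",
) -> RatingTable:
    """Column-wise :func:`rate_property` over a candidates x properties frame.

    Every property needs a direction flag and a value for every candidate;
    a missing cell raises, naming the candidate and property.
    """
    missing_dir = [c for c in values.columns if c not in directions]
    if missing_dir:
        raise KeyError(f"no direction flag for propert(ies): {missing_dir}")
    for prop in values.columns:
        nulls = values.index[values[prop].isna()]
        if len(nulls):
            raise ValueError(f"missing value for candidate {nulls[0]!r}, property {prop!r}")
    rated = {
        prop: rate_property(values[prop], directions[prop], scheme) for prop in values.columns
    }
    frame = pd.DataFrame(rated, index=values.index)
    return RatingTable(ratings=frame, directions=dict(directions))


def rank_balanced(table: RatingTable, rule: str = "maximin") -> pd.Series:
    """Score candidates and return them best-first.

    "maximin": score is the minimum rating across properties (prefers
    balanced profiles over spiky ones); "mean": arithmetic mean. Ties keep
    the table's candidate order (stable sort).
    """
    if rule == "maximin":
        scores = table.ratings.min(axis=1)
    elif rule == "mean":
        scores = table.ratings.mean(axis=1)
    else:
        raise ValueError("rule must be 'maximin' or 'mean'")
    return scores.sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# Case-study panel assembly

#: Radar-axis directions for the screening case study. NADH stability after
#: CO2 saturation enters as the negated short-term degradation constant, so
#: it is higher-better; viscosity is lower-better.
PANEL_DIRECTIONS = {
    "fdh_activity": "higher",
    "fdh_half_life": "higher",
    "co2_solubility": "higher",
    "nadh_stability_co2": "higher",
    "viscosity": "lower",
}


def buffered_panel_values(
    table: ScreeningTable,
    candidates: list[str] | None = None,
    fill_values: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Raw axis values for the buffered-dilution radar panel.

    Axes: FDH relative activity (%), FDH half-life (days), CO2 solubility
    (mg/L), NADH stability after CO2 saturation (-k, min^-1) and viscosity
    (mPa s). Activity and half-life come from the narrative-report fixture;
    ``fill_values`` (same columns, indexed by system id) may supply values
    for systems the narrative omits — the packaged synthetic reconstruction
    serves that purpose for the choline chloride panel.
    """
    if candidates is None:
        candidates = [
            r.system_id
            for r in table
            if r.diluent == "buffer" and r.hba == "choline chloride"
        ] + ["buffer"]
    reported = load_reported_kinetics()
    frame = table.to_frame().loc[candidates]
    out = pd.DataFrame(index=pd.Index(candidates, name="candidate"))
    act = reported["relative_activity_pct"].reindex(candidates)
    hl = reported["fdh_half_life_d"].reindex(candidates)
    if fill_values is not None:
        act = act.fillna(fill_values["relative_activity_pct"].reindex(candidates))
        hl = hl.fillna(fill_values["fdh_half_life_d"].reindex(candidates))
    out["fdh_activity"] = act
    out["fdh_half_life"] = hl
    out["co2_solubility"] = frame["co2_saturation_mg_per_l"]
    out["nadh_stability_co2"] = -frame["k_nadh_star_per_min"]
    out["viscosity"] = frame["viscosity_mpa_s"]
    return out
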