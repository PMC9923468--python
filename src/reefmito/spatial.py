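"""Geographic distances, isolation-by-distance and temperature regressions,
and molecular-rate arithmetic.

Reef-pair summaries relate genetic similarity to great-circle separation:
per unordered reef pair, the mean nucleotide distance over cross-reef colony
pairs, the fraction of cross-reef pairs sharing a haplogroup (plus a
rare-group-restricted variant, where the small-group signal is strongest),
and the absolute difference in heat exposure.  Regressions are plain OLS on
reef pairs; pair rows are not independent, so an optional Mantel-style
permutation p-value (permuting reef identities) is provided alongside.

Rate arithmetic treats the molecular rate as PAIRWISE divergence accumulation
(percent per million years): dividing 0.2% inter-clade divergence by
0.1%/Myr dates a split at 2 Myr, and the expected wait between mutations on
a genome of L bases is 1 / (L * rate per site per year).  The per-lineage
convention (half the pairwise rate per lineage) is available via
``per_lineage=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .distances import DistanceMatrix
from .errors import InsufficientDataError, ParameterError, ValidationError
from .haplogroups import HaplogroupAssignment
from .seqio import ColonyTable

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    for lat in (lat1, lat2):
        if not -90 <= lat <= 90:
            raise ValidationError(f"latitude {lat} outside [-90, 90]")
    for lon in (lon1, lon2):
        if not -180 <= lon <= 180:
            raise ValidationError(f"longitude {lon} outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


@dataclass
class RegressionResult:
    """OLS fit summary for reef-pair regressions."""

    params: pd.DataFrame       # coef, se, t, p per term
    f_pvalue: float
    r2: float
    r2_adj: float
    n: int
    condition_number: float
    mantel_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "coefficients": self.params.to_dict(orient="index"),
            "overall_p": self.f_pvalue,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "n_pairs": self.n,
            "mantel_p": self.mantel_p,
        }


def reef_pair_table(
    dm: DistanceMatrix,
    h: HaplogroupAssignment,
    meta: ColonyTable,
    rare_range: tuple[int, int] = (2, 10),
) -> pd.DataFrame:
    """Per-unordered-reef-pair genetic and geographic summaries.

    Columns: reef_a, reef_b, geo_km, nt_distance (mean cross-reef d_ij in
    bases), sharing (fraction of cross-reef colony pairs in the same
    haplogroup), rare_sharing (same, counting only pairs in rare groups) and
    heat_diff (absolute heat-exposure difference; NaN when unavailable).
    Reefs without coordinates are dropped with a warning.
    """
    rows = meta.aligned_to(dm.ids)
    reef_info = rows.drop_duplicates("reef").set_index("reef")
    good = reef_info.index[reef_info[["lat", "lon"]].notna().all(axis=1)]
    dropped = sorted(set(reef_info.index) - set(good))
    if dropped:
        warnings.warn(f"reefs lacking coordinates dropped: {dropped}", stacklevel=2)
    reefs = sorted(good)
    if len(reefs) < 2:
        raise InsufficientDataError("need >= 2 reefs with coordinates")

    reef_arr = rows["reef"].to_numpy()
    labels = h.labels
    sizes = h.sizes()
    lo, hi = rare_range
    rare_labels = {g for g, s in sizes.items() if lo <= s <= hi}
    is_rare = np.array([g in rare_labels for g in labels])
    has_hf = "heat_fraction" in rows.columns

    records = []
    idx_of = {r: np.nonzero(reef_arr == r)[0] for r in reefs}
    for a_i, ra in enumerate(reefs):
        for rb in reefs[a_i + 1:]:
            ia, ib = idx_of[ra], idx_of[rb]
            sub = dm.D[np.ix_(ia, ib)]
            la, lb = labels[ia], labels[ib]
            same = (la[:, None] == lb[None, :]) & (la[:, None] > 0)
            same_rare = same & is_rare[ia][:, None] & is_rare[ib][None, :]
            n_pairs = sub.size
            records.append(
                {
                    "reef_a": ra,
                    "reef_b": rb,
                    "geo_km": haversine_km(
                        reef_info.loc[ra, "lat"], reef_info.loc[ra, "lon"],
                        reef_info.loc[rb, "lat"], reef_info.loc[rb, "lon"],
                    ),
                    "nt_distance": float(sub.mean()),
                    "sharing": float(same.sum() / n_pairs),
                    "rare_sharing": float(same_rare.sum() / n_pairs),
                    "heat_diff": (
                        abs(float(reef_info.loc[ra, "heat_fraction"])
                            - float(reef_info.loc[rb, "heat_fraction"]))
                        if has_hf else np.nan
                    ),
                }
            )
    return pd.DataFrame(records)


def ibd_regression(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | str,
    mantel_permutations: int = 0,
    seed: int | None = None,
) -> RegressionResult:
    """OLS of a reef-pair response on one or more predictors, with intercept.

    Set ``mantel_permutations`` > 0 to add a Mantel-style p-value for the
    first predictor (reef identities permuted), accounting for the
    non-independence of pair rows.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    data = table.dropna(subset=[response, *predictors])
    if len(data) < 3:
        raise InsufficientDataError("need >= 3 reef pairs")
    for p in predictors:
        if np.var(data[p].to_numpy(dtype=float)) == 0:
            raise ValidationError(f"predictor {p!r} has zero variance")
    X = sm.add_constant(data[predictors].astype(float))
    fit = sm.OLS(data[response].astype(float), X).fit()
    if fit.condition_number > 1e8:
        warnings.warn(
            f"ill-conditioned design (condition number {fit.condition_number:.3g})",
            stacklevel=2,
        )
    params = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues}
    )
    mantel_p = None
    if mantel_permutations > 0:
        mantel_p = _mantel_p(
            data, response, predictors, fit.params[predictors[0]],
            mantel_permutations, seed,
        )
    return RegressionResult(
        params=params,
        f_pvalue=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        r2_adj=float(fit.rsquared_adj),
        n=len(data),
        condition_number=float(fit.condition_number),
        mantel_p=mantel_p,
    )


def _mantel_p(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    obs_slope: float,
    B: int,
    seed: int | None,
) -> float:
    """Two-tailed Mantel permutation p for the first predictor's slope."""
    rng = np.random.default_rng(seed)
    reefs = sorted(set(data["reef_a"]) | set(data["reef_b"]))
    y = data[response].to_numpy(dtype=float)
    Xp = data[predictors].to_numpy(dtype=float)
    exceed = 0
    for _ in range(B):
        relab = dict(zip(reefs, rng.permutation(reefs)))
        key = {
            tuple(sorted((relab[a], relab[b]))): i
            for i, (a, b) in enumerate(zip(data["reef_a"], data["reef_b"]))
        }
        order = [key[tuple(sorted((a, b)))] for a, b in zip(data["reef_a"], data["reef_b"])]
        X = sm.add_constant(Xp)
        fit = sm.OLS(y[order], X).fit()
        if abs(fit.params[1]) >= abs(obs_slope):
            exceed += 1
    return (1 + exceed) / (B + 1)


def mutation_wait_time(
    L: float, rate_pct_per_myr: float, per_lineage: bool = False
) -> float:
    """Expected years between mutations anywhere on a genome of L bases.

    ``rate_pct_per_myr`` is pairwise divergence accumulation in percent per
    million years; the per-site per-year rate is rate/100/1e6 (halved per
    lineage under ``per_lineage=True``).
    """
    if L <= 0 or rate_pct_per_myr <= 0:
        raise ParameterError("genome length and rate must be positive")
    rate_site_year = (rate_pct_per_myr / 100.0) / 1e6
    if per_lineage:
        rate_site_year /= 2.0
    return 1.0 / (L * rate_site_year)


def divergence_time(
    pct_divergence: float, rate_pct_per_myr: float, per_lineage: bool = False
) -> float:
    """Million years for clades to accumulate ``pct_divergence`` at the given rate."""
    if pct_divergence < 0:
        raise ParameterError("divergence must be non-negative")
    if rate_pct_per_myr <= 0:
        raise ParameterError("rate must be positive")
    rate = 2.0 * rate_pct_per_myr if per_lineage else rate_pct_per_myr
    return pct_divergence / rate
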