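"""Hierarchical AMOVA with Phi statistics, permutation p-values, and
per-haplogroup chi-square tests of regional homogeneity.

The design is colonies nested in reefs nested in regions.  Following the
haplotypic-distance AMOVA convention for sequence data, the squared
inter-individual distance delta^2_ij is taken to be the number of differing
sites d_ij itself (set ``squared=True`` to use d_ij^2 instead, as for a
Euclidean embedding).  Sums of squares for a set S of colonies are

    SS(S) = (1/|S|) * sum_{i<j in S} delta^2_ij,

partitioned as within reefs, among reefs within regions, and among regions.
Variance components (sigma2_a: among regions, sigma2_b: among reefs within
regions, sigma2_c: within reefs) come from the expected mean squares of the
unbalanced three-level design:

    E[MS_within]  = sigma2_c
    E[MS_reefs]   = sigma2_c + n1 * sigma2_b
    E[MS_regions] = sigma2_c + n2 * sigma2_b + n3 * sigma2_a

with the standard unequal-sample-size coefficients n1, n2, n3.  Fixation
indices: PhiRT = sigma2_a / sigma2_T, PhiPR = sigma2_b / (sigma2_b +
sigma2_c), PhiST = (sigma2_a + sigma2_b) / sigma2_T, computed from the raw
(possibly negative) component estimates; percents of total truncate negative
components at zero.

Significance is assessed by permutation: whole reefs among regions for PhiRT,
colonies among reefs within their region for PhiPR, colonies among all reefs
for PhiST, with p = (1 + #{Phi* >= Phi_obs}) / (B + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .distances import DistanceMatrix
from .errors import StratumError
from .haplogroups import HaplogroupAssignment, UNGROUPED
from .seqio import ColonyTable


@dataclass
class AmovaResult:
    """df/SS/MS/variance components per stratum plus Phi statistics."""

    table: pd.DataFrame            # Source, df, SS, MS, est_var, pct
    sigma: dict[str, float]        # raw components: a (regions), b (reefs), c (within)
    phi: dict[str, float | None]   # PhiRT, PhiPR, PhiST (None if undefined)
    undefined: bool                # all distances zero -> Phi undefined
    p_values: dict[str, float | None] = field(default_factory=dict)
    n_permutations: int = 0

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _codes(meta_rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(reef code per colony, region code per reef, region code per colony)."""
    reefs, reef_code = np.unique(meta_rows["reef"].to_numpy(), return_inverse=True)
    reef_region = (
        meta_rows.drop_duplicates("reef").set_index("reef")["region"].loc[reefs]
    )
    regions, region_of_reef = np.unique(reef_region.to_numpy(), return_inverse=True)
    return reef_code, region_of_reef, region_of_reef[reef_code]


def _group_ss(E: np.ndarray, code: np.ndarray, k: int) -> float:
    """sum over groups g of SS({i: code_i = g})."""
    Z = np.zeros((len(code), k))
    Z[np.arange(len(code)), code] = 1.0
    per = np.einsum("ig,ij,jg->g", Z, E, Z)  # within-group total (double-counted)
    sizes = Z.sum(axis=0)
    return float((per / (2.0 * sizes)).sum())


def _components(
    E: np.ndarray, reef_code: np.ndarray, region_of_reef: np.ndarray
) -> dict[str, float]:
    """SS partition and raw variance components for one labelling."""
    N = len(reef_code)
    P = region_of_reef.shape[0]
    region_code = region_of_reef[reef_code]
    G = int(region_of_reef.max()) + 1

    ss_total = E.sum() / (2.0 * N)
    ss_within = _group_ss(E, reef_code, P)
    ss_by_region = _group_ss(E, region_code, G)
    ssd_wp = ss_within
    ssd_ap = ss_by_region - ss_within
    ssd_ag = ss_total - ss_by_region

    df_a, df_b, df_c = G - 1, P - G, N - P
    n_p = np.bincount(reef_code, minlength=P).astype(float)
    N_g = np.bincount(region_code, minlength=G).astype(float)
    sum_np2_by_g = np.bincount(region_of_reef, weights=n_p**2, minlength=G)

    ms_c = ssd_wp / df_c if df_c > 0 else 0.0
    sigma_c = ms_c
    if df_b > 0:
        n1 = (N - (sum_np2_by_g / N_g).sum()) / df_b
        ms_b = ssd_ap / df_b
        sigma_b = (ms_b - sigma_c) / n1
    else:
        ms_b, sigma_b = np.nan, 0.0
    if df_a > 0:
        n2 = ((sum_np2_by_g / N_g).sum() - (n_p**2).sum() / N) / df_a
        n3 = (N - (N_g**2).sum() / N) / df_a
        ms_a = ssd_ag / df_a
        sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    else:
        ms_a, sigma_a = np.nan, 0.0
    return {
        "N": N, "P": P, "G": G,
        "df": (df_a, df_b, df_c),
        "ss": (ssd_ag, ssd_ap, ssd_wp, ss_total),
        "ms": (ms_a, ms_b, ms_c),
        "sigma": (sigma_a, sigma_b, sigma_c),
    }


def _phi(sigma: tuple[float, float, float]) -> dict[str, float | None]:
    a, b, c = sigma
    total = a + b + c
    if total <= 0:
        return {"PhiRT": None, "PhiPR": None, "PhiST": None}
    phi_pr = b / (b + c) if (b + c) > 0 else None
    return {"PhiRT": a / total, "PhiPR": phi_pr, "PhiST": (a + b) / total}


def _delta2(dm: DistanceMatrix, squared: bool) -> np.ndarray:
    D = dm.D.astype(float)
    return D**2 if squared else D


def amova(
    dm: DistanceMatrix, meta: ColonyTable, squared: bool = False
) -> AmovaResult:
    """Three-level AMOVA of colonies nested in reefs nested in regions.

    Requires >= 2 reefs.  When every region holds a single reef the
    among-reefs stratum has zero df: sigma2_b is fixed at 0, PhiPR is
    undefined and PhiST equals PhiRT.  With a single region the design
    degrades to two levels (reefs within one region) and PhiRT is reported
    as not applicable.  If all distances are zero, components are zero and
    every Phi is flagged undefined rather than NaN.
    """
    rows = meta.aligned_to(dm.ids)
    reef_code, region_of_reef, _ = _codes(rows)
    P = len(np.unique(reef_code))
    G = int(region_of_reef.max()) + 1
    if P < 2:
        raise StratumError("AMOVA needs >= 2 reefs")
    E = _delta2(dm, squared)
    c = _components(E, reef_code, region_of_reef)
    sigma_a, sigma_b, sigma_c = c["sigma"]
    undefined = E.max() == 0
    phi = (
        {"PhiRT": None, "PhiPR": None, "PhiST": None}
        if undefined
        else _phi(c["sigma"])
    )
    if G < 2:
        phi["PhiRT"] = None
    if c["df"][1] == 0 and phi["PhiPR"] is not None:
        phi["PhiPR"] = None
    trunc = np.maximum([sigma_a, sigma_b, sigma_c], 0.0)
    total_trunc = trunc.sum()
    pct = 100.0 * trunc / total_trunc if total_trunc > 0 else np.zeros(3)
    df_a, df_b, df_c = c["df"]
    ssd_ag, ssd_ap, ssd_wp, ss_total = c["ss"]
    ms_a, ms_b, ms_c = c["ms"]
    table = pd.DataFrame(
        {
            "Source": ["Among Regions", "Among Reefs", "Within Reefs", "Total"],
            "df": [df_a, df_b, df_c, c["N"] - 1],
            "SS": [ssd_ag, ssd_ap, ssd_wp, ss_total],
            "MS": [ms_a, ms_b, ms_c, np.nan],
            "est_var": [sigma_a, sigma_b, sigma_c, sigma_a + sigma_b + sigma_c],
            "pct": [*pct, pct.sum()],
        }
    )
    return AmovaResult(
        table=table,
        sigma={"a": sigma_a, "b": sigma_b, "c": sigma_c},
        phi=phi,
        undefined=undefined,
    )


def amova_permutation_p(
    dm: DistanceMatrix,
    meta: ColonyTable,
    B: int = 999,
    seed: int | np.random.Generator | None = None,
    squared: bool = False,
) -> AmovaResult:
    """AMOVA plus one-tailed permutation p-values for each Phi.

    PhiRT permutes whole reefs among regions (reef counts per region fixed);
    PhiPR permutes colonies among reefs within their region; PhiST permutes
    colonies among all reefs.  With a single region, the PhiRT p-value is
    reported as not applicable (None).
    """
    if B < 99:
        warnings.warn(f"B={B} permutations gives a coarse p-value", stacklevel=2)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = amova(dm, meta, squared=squared)
    if result.undefined:
        result.p_values = {"PhiRT": None, "PhiPR": None, "PhiST": None}
        return result
    rows = meta.aligned_to(dm.ids)
    reef_code, region_of_reef, _ = _codes(rows)
    E = _delta2(dm, squared)
    obs = result.phi
    G = int(region_of_reef.max()) + 1
    exceed = {"PhiRT": 0, "PhiPR": 0, "PhiST": 0}
    valid = {"PhiRT": 0, "PhiPR": 0, "PhiST": 0}
    region_code = region_of_reef[reef_code]

    for _ in range(B):
        # PhiST: colonies among all reefs
        if obs["PhiST"] is not None:
            perm = rng.permutation(reef_code)
            phi = _phi(_components(E, perm, region_of_reef)["sigma"])["PhiST"]
            if phi is not None:
                valid["PhiST"] += 1
                exceed["PhiST"] += phi >= obs["PhiST"]
        # PhiPR: colonies among reefs within regions
        if obs["PhiPR"] is not None:
            perm = reef_code.copy()
            for g in range(G):
                mask = region_code == g
                perm[mask] = rng.permutation(perm[mask])
            phi = _phi(_components(E, perm, region_of_reef)["sigma"])["PhiPR"]
            if phi is not None:
                valid["PhiPR"] += 1
                exceed["PhiPR"] += phi >= obs["PhiPR"]
        # PhiRT: whole reefs among regions
        if obs["PhiRT"] is not None and G >= 2:
            phi = _phi(
                _components(E, reef_code, rng.permutation(region_of_reef))["sigma"]
            )["PhiRT"]
            if phi is not None:
                valid["PhiRT"] += 1
                exceed["PhiRT"] += phi >= obs["PhiRT"]

    p: dict[str, float | None] = {}
    for k in exceed:
        if obs[k] is None or (k == "PhiRT" and G < 2):
            p[k] = None
        else:
            p[k] = (1 + exceed[k]) / (valid[k] + 1)
    result.p_values = p
    result.n_permutations = B
    return result


def chisq_regional_homogeneity(
    h: HaplogroupAssignment,
    meta: ColonyTable,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> pd.DataFrame:
    """Chi-square test of regional homogeneity for each haplogroup.

    For each group, observed regional counts are compared with expectations
    proportional to regional sampling totals (all colonies).  P-values are
    corrected across groups (Benjamini-Hochberg by default, ``method="bonferroni"``
    for the conservative option).  Rows flag expected cells below 5.
    """
    rows = meta.aligned_to(h.ids)
    regions, region_code = np.unique(rows["region"].to_numpy(), return_inverse=True)
    R = len(regions)
    totals = np.bincount(region_code, minlength=R).astype(float)
    frac = totals / totals.sum()
    records = []
    for g in range(1, h.n_groups + 1):
        mask = h.labels == g
        size = int(mask.sum())
        obs = np.bincount(region_code[mask], minlength=R).astype(float)
        exp = size * frac
        stat = float(((obs - exp) ** 2 / exp).sum())
        p = float(stats.chi2.sf(stat, df=R - 1))
        records.append(
            {
                "group": g,
                "size": size,
                "chi2": stat,
                "df": R - 1,
                "p": p,
                "low_expected": bool((exp < 5).any()),
            }
        )
    out = pd.DataFrame(records)
    if len(out):
        reject, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method=method)
        out["p_adj"] = p_adj
        out["significant"] = reject
    return out
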