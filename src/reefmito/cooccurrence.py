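"""Excess co-location of same-haplogroup colonies on the same reef, with a
constrained permutation null.

The observed statistic counts, over every (group g, reef r) cell with k_gr
labelled members, either unordered pairs sum C(k_gr, 2) (default — the
natural reading of "pairs") or incidences sum max(k_gr - 1, 0)
(``statistic="instances"``).  The null shuffles the colony -> reef assignment
uniformly at random while holding fixed the number of colonies per reef, the
number of groups and the group-size spectrum; ungrouped colonies keep
occupying reef slots but never contribute pairs.  The one-tailed p-value is
(1 + #{null >= observed}) / (B + 1).

A second statistic targets rare groups (2-10 members by default): the number
of such groups with at least one same-reef pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .haplogroups import HaplogroupAssignment
from .seqio import ColonyTable

PAIR_STATISTICS = ("pairs", "instances")


@dataclass
class CooccurResult:
    """Observed statistic, permutation-null summary and replicate trace."""

    mode: str                 # "haplogroup" or "strict"
    statistic: str            # "pairs", "instances" or "rare-groups"
    observed: int
    null_mean: float
    null_sd: float
    p: float
    B: int
    seed: int | None
    replicates: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "statistic": self.statistic,
            "observed": int(self.observed),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "p": float(self.p),
            "B": int(self.B),
            "seed": self.seed,
        }

    def write_replicates_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"replicate": np.arange(1, self.B + 1), "value": self.replicates}
        ).to_csv(path, sep="\t", index=False)


def _labels_and_reefs(
    h: HaplogroupAssignment, meta: ColonyTable
) -> tuple[np.ndarray, np.ndarray, int, int]:
    rows = meta.aligned_to(h.ids)
    reefs, reef_code = np.unique(rows["reef"].to_numpy(), return_inverse=True)
    return h.labels, reef_code, h.n_groups, len(reefs)


def _cell_counts(
    labels: np.ndarray, reef_code: np.ndarray, n_groups: int, n_reefs: int
) -> np.ndarray:
    mask = labels > 0
    flat = (labels[mask] - 1) * n_reefs + reef_code[mask]
    return np.bincount(flat, minlength=n_groups * n_reefs)


def _pair_statistic(k: np.ndarray, statistic: str) -> int:
    if statistic == "pairs":
        return int((k * (k - 1) // 2).sum())
    if statistic == "instances":
        return int(np.maximum(k - 1, 0).sum())
    raise ParameterError(f"unknown statistic {statistic!r}; use one of {PAIR_STATISTICS}")


def pair_count(
    h: HaplogroupAssignment, meta: ColonyTable, statistic: str = "pairs"
) -> int:
    """Total same-reef, same-group pairs (or incidences) across all groups."""
    labels, reef_code, G, R = _labels_and_reefs(h, meta)
    return _pair_statistic(_cell_counts(labels, reef_code, G, R), statistic)


def rare_group_count(
    h: HaplogroupAssignment,
    meta: ColonyTable,
    size_range: tuple[int, int] = (2, 10),
) -> int:
    """Number of rare groups (size in the inclusive range) with a same-reef pair."""
    lo, hi = size_range
    if hi < lo:
        raise ParameterError(f"empty size range {size_range}")
    labels, reef_code, G, R = _labels_and_reefs(h, meta)
    return _rare_count(_cell_counts(labels, reef_code, G, R), labels, G, R, lo, hi)


def _rare_count(
    cells: np.ndarray, labels: np.ndarray, G: int, R: int, lo: int, hi: int
) -> int:
    sizes = np.bincount(labels[labels > 0] - 1, minlength=G)
    k = cells.reshape(G, R)
    rare = (sizes >= lo) & (sizes <= hi)
    return int((rare & (k.max(axis=1) >= 2)).sum())


def permutation_null(
    h: HaplogroupAssignment,
    meta: ColonyTable,
    statistic: str = "pairs",
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    size_range: tuple[int, int] = (2, 10),
    mode: str = "haplogroup",
) -> CooccurResult:
    """Constrained permutation null for a co-occurrence statistic.

    ``statistic`` is "pairs", "instances" or "rare-groups".  Each replicate
    permutes the reef-label multiset over all colonies (reef sizes, group
    memberships and group sizes fixed) and recomputes the statistic.
    """
    if B < 1:
        raise ParameterError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels, reef_code, G, R = _labels_and_reefs(h, meta)
    if R < 2:
        # Single reef: every permutation reproduces the observed value.
        if statistic == "rare-groups":
            observed = _rare_count(
                _cell_counts(labels, reef_code, G, R), labels, G, R, *size_range
            )
        else:
            observed = _pair_statistic(
                _cell_counts(labels, reef_code, G, R), statistic
            )
        reps = np.full(B, observed)
        return CooccurResult(mode, statistic, observed, float(observed), 0.0, 1.0,
                             B, seed if isinstance(seed, int) else None, reps)

    lo, hi = size_range
    if statistic == "rare-groups":
        if hi < lo:
            raise ParameterError(f"empty size range {size_range}")
        def stat(code):
            return _rare_count(_cell_counts(labels, code, G, R), labels, G, R, lo, hi)
    else:
        def stat(code):
            return _pair_statistic(_cell_counts(labels, code, G, R), statistic)

    observed = stat(reef_code)
    reps = np.empty(B, dtype=np.int64)
    for b in range(B):
        reps[b] = stat(rng.permutation(reef_code))
    p = (1 + int((reps >= observed).sum())) / (B + 1)
    return CooccurResult(
        mode=mode,
        statistic=statistic,
        observed=observed,
        null_mean=float(reps.mean()),
        null_sd=float(reps.std(ddof=1)) if B > 1 else 0.0,
        p=p,
        B=B,
        seed=seed if isinstance(seed, int) else None,
        replicates=reps,
    )


def cooccurrence_report(
    h_full: HaplogroupAssignment,
    h_strict: HaplogroupAssignment,
    meta: ColonyTable,
    B: int = 1000,
    seed: int | None = None,
    statistic: str = "pairs",
    size_range: tuple[int, int] = (2, 10),
) -> dict[str, CooccurResult]:
    """The four observed/null/p summaries: {haplogroup, strict} x {pairs, rare}."""
    rng = np.random.default_rng(seed)
    out: dict[str, CooccurResult] = {}
    for mode, h in (("haplogroup", h_full), ("strict", h_strict)):
        out[f"{mode}_pairs"] = permutation_null(
            h, meta, statistic=statistic, B=B, seed=rng, mode=mode
        )
        out[f"{mode}_rare"] = permutation_null(
            h, meta, statistic="rare-groups", B=B, seed=rng,
            size_range=size_range, mode=mode,
        )
    return out
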