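"""Haplogroup construction: identity clustering plus single-base folding.

A Haplogroup starts as a cluster of colonies whose mitogenomes are identical
at every jointly called site (distance 0 under pairwise deletion).  Because
identity-with-missing-data is not transitive, clusters are defined as
connected components of the zero-distance graph; components in which some
pair has d > 0 are flagged in the log rather than silently split.

Remaining singletons that sit one called base away from exactly one group's
consensus are folded into that group; a singleton one base from several
consensuses goes to the largest group (core size, ties to the lowest label)
with the ambiguity logged.  Everything else stays ungrouped.

Group labels are deterministic: groups are numbered 1..G by decreasing core
size, ties broken by the lexicographically smallest core member id, so any
input ordering yields the same assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix, pairwise_difference_matrix
from .seqio import Alignment, BASES, UNCALLED

CORE = "core"
FOLDED = "folded"
UNGROUPED = "ungrouped"


@dataclass
class IdentityPartition:
    """Connected components of the d = 0 graph."""

    ids: list[str]
    groups: list[list[int]]      # components of size >= 2, in label order
    singletons: list[int]        # size-1 components (provisional)
    log: list[str] = field(default_factory=list)


@dataclass
class HaplogroupAssignment:
    """colony -> group mapping with membership kind and group consensuses."""

    ids: list[str]
    labels: np.ndarray           # int, 0 = no group, 1..G
    kinds: np.ndarray            # object array of {core, folded, ungrouped}
    consensus: dict[int, str]
    d_to_consensus: dict[str, int] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return int(self.labels.max()) if len(self.labels) else 0

    def sizes(self) -> dict[int, int]:
        """Group sizes counting every labelled member (core + folded)."""
        out: dict[int, int] = {}
        for g in range(1, self.n_groups + 1):
            out[g] = int((self.labels == g).sum())
        return out

    def members(self, group: int) -> list[str]:
        return [i for i, g in zip(self.ids, self.labels) if g == group]

    def n_kind(self, kind: str) -> int:
        return int((self.kinds == kind).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "colony": self.ids,
                "group": self.labels,
                "kind": self.kinds,
                "d_to_consensus": [
                    self.d_to_consensus.get(i, 0 if k == CORE else pd.NA)
                    for i, k in zip(self.ids, self.kinds)
                ],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_identity_groups(dm: DistanceMatrix) -> IdentityPartition:
    """Partition colonies into zero-distance connected components.

    Components of size >= 2 become candidate Haplogroups, ordered by
    (core size desc, smallest member id); size-1 components are provisional
    singletons.  Non-transitive identity (a component containing a pair with
    d > 0) is logged.
    """
    adj = sp.csr_matrix((dm.D == 0).astype(np.int8))
    _, comp = connected_components(adj, directed=False)
    log: list[str] = []
    members: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        members.setdefault(int(c), []).append(i)
    groups = [m for m in members.values() if len(m) >= 2]
    singletons = [m[0] for m in members.values() if len(m) == 1]
    groups.sort(key=lambda m: (-len(m), min(dm.ids[i] for i in m)))
    for m in groups:
        sub = dm.D[np.ix_(m, m)]
        if sub.max() > 0:
            pairs = int((sub > 0).sum() // 2)
            log.append(
                "non-transitive identity: component "
                f"{sorted(dm.ids[i] for i in m)} holds {pairs} pair(s) with d>0 "
                "(missing data); kept as one group"
            )
    return IdentityPartition(list(dm.ids), groups, sorted(singletons), log)


def _consensus(X: np.ndarray, rows: list[int]) -> np.ndarray:
    """Per-column majority called base over ``rows``; UNCALLED where none."""
    sub = X[rows]
    counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
    best = counts.argmax(axis=0)
    cons = best.astype(np.uint8)
    cons[counts.max(axis=0) == 0] = UNCALLED
    return cons


def _decode(code: np.ndarray) -> str:
    lut = np.frombuffer((BASES + "N").encode(), dtype=np.uint8)
    safe = np.where(code == UNCALLED, 4, code)
    return lut[safe].tobytes().decode()


def _d_to(seq: np.ndarray, cons: np.ndarray) -> int:
    both = (seq != UNCALLED) & (cons != UNCALLED)
    return int(((seq != cons) & both).sum())


def fold_single_base_variants(
    partition: IdentityPartition, dm: DistanceMatrix, aln: Alignment
) -> HaplogroupAssignment:
    """Fold singletons one called base from a group consensus into that group."""
    X = aln.encoded()
    if list(aln.ids) != partition.ids:
        order = {c: i for i, c in enumerate(aln.ids)}
        X = X[[order[c] for c in partition.ids]]
    n = len(partition.ids)
    labels = np.zeros(n, dtype=np.int64)
    kinds = np.array([UNGROUPED] * n, dtype=object)
    log = list(partition.log)

    cons_codes: dict[int, np.ndarray] = {}
    for g, rows in enumerate(partition.groups, start=1):
        labels[rows] = g
        kinds[rows] = CORE
        cons_codes[g] = _consensus(X, rows)

    core_size = {g: len(rows) for g, rows in enumerate(partition.groups, start=1)}
    d_to: dict[str, int] = {}
    for i in partition.singletons:
        cid = partition.ids[i]
        dists = {g: _d_to(X[i], cons_codes[g]) for g in cons_codes}
        hits = sorted(g for g, d in dists.items() if d <= 1)
        if not hits:
            continue
        if len(hits) > 1:
            hits.sort(key=lambda g: (-core_size[g], g))
            log.append(
                f"fold ambiguity: {cid} is <=1 base from groups {sorted(hits)}; "
                f"folded into {hits[0]} (largest core, lowest label)"
            )
        g = hits[0]
        if dists[g] == 0:
            log.append(
                f"{cid} matches group {g} consensus exactly despite d>0 to some "
                "member (missing data); folded"
            )
        labels[i] = g
        kinds[i] = FOLDED
        d_to[cid] = dists[g]
        # Is the variant base unique in the dataset? Logged, not enforced.
        diff = np.nonzero(
            (X[i] != cons_codes[g])
            & (X[i] != UNCALLED)
            & (cons_codes[g] != UNCALLED)
        )[0]
        if len(diff) == 1:
            site = int(diff[0])
            elsewhere = int(
                ((X[:, site] == X[i, site]).sum()) - 1
            )
            if elsewhere > 0:
                log.append(
                    f"folded variant of {cid} at column {site} also occurs in "
                    f"{elsewhere} other colony(ies); folded regardless"
                )
    return HaplogroupAssignment(
        ids=list(partition.ids),
        labels=labels,
        kinds=kinds,
        consensus={g: _decode(c) for g, c in cons_codes.items()},
        d_to_consensus=d_to,
        log=log,
    )


def strict_identity_assignment(partition: IdentityPartition) -> HaplogroupAssignment:
    """Assignment restricted to exactly identical genomes.

    Only core members of multi-member identity groups keep a label; folded
    single-base variants and singletons are left ungrouped (they still occupy
    reef slots in permutation tests but contribute no pairs).
    """
    n = len(partition.ids)
    labels = np.zeros(n, dtype=np.int64)
    kinds = np.array([UNGROUPED] * n, dtype=object)
    for g, rows in enumerate(partition.groups, start=1):
        labels[rows] = g
        kinds[rows] = CORE
    return HaplogroupAssignment(
        ids=list(partition.ids), labels=labels, kinds=kinds, consensus={}
    )


def group_size_spectrum(
    h: HaplogroupAssignment, rare_range: tuple[int, int] = (2, 10)
) -> pd.DataFrame:
    """Group sizes (folded members included) with a rare flag (inclusive range)."""
    lo, hi = rare_range
    rows = [
        {"group": g, "size": s, "rare": lo <= s <= hi}
        for g, s in h.sizes().items()
    ]
    return pd.DataFrame(rows, columns=["group", "size", "rare"])


def assign_haplogroups(
    aln: Alignment, dm: DistanceMatrix | None = None
) -> tuple[HaplogroupAssignment, HaplogroupAssignment]:
    """Convenience: (full haplogroup assignment, strict-identity assignment)."""
    if dm is None:
        dm = pairwise_difference_matrix(aln)
    part = build_identity_groups(dm)
    return fold_single_base_variants(part, dm, aln), strict_identity_assignment(part)
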