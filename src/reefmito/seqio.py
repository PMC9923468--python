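"""Read, validate and write aligned mitogenomes and colony metadata.

The pipeline consumes two artifacts: a multiple alignment of whole
mitochondrial genomes in FASTA (one record per coral colony, all records the
same length, alphabet A/C/G/T plus N for uncalled loci and ``-`` for alignment
gaps) and a delimited colony table giving, for every colony, its reef, the
region the reef belongs to, coordinates, collection date and optionally the
reef's heat exposure (fraction of time intervals above 31°C).

Both ``N`` and ``-`` are treated downstream as "not called" and are preserved
verbatim on round trips.  FASTA headers are split on the first whitespace; the
leading token is the colony id.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentShapeError, CrossReferenceError, ValidationError

#: Called bases are encoded 0..3; N and - share the "uncalled" code.
BASES = "ACGT"
UNCALLED = 255

_ENCODE = np.full(256, 254, dtype=np.uint8)  # 254 = illegal character
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
for _c in "Nn-":
    _ENCODE[ord(_c)] = UNCALLED

METADATA_COLUMNS = ("colony", "reef", "region", "lat", "lon", "date")


@dataclass
class Alignment:
    """Equal-length haploid sequences keyed by colony id."""

    ids: list[str]
    seqs: list[str]
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValidationError("ids and seqs must have the same length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValidationError(f"duplicate colony ids: {dupes}")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            ref = len(self.seqs[0])
            for cid, s in zip(self.ids, self.seqs):
                if len(s) != ref:
                    raise AlignmentShapeError(
                        f"record {cid!r} has length {len(s)}, expected {ref}"
                    )
        self.seqs = [s.upper() for s in self.seqs]
        for cid, s in zip(self.ids, self.seqs):
            bad = set(s) - set("ACGTN-")
            if bad:
                raise ValidationError(
                    f"record {cid!r} contains characters outside ACGTN-: "
                    f"{sorted(bad)} (IUPAC ambiguity codes are rejected)"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def L(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def encoded(self) -> np.ndarray:
        """(n, L) uint8 matrix: A/C/G/T -> 0..3, N or gap -> 255."""
        if self._encoded is None:
            if self.n == 0:
                self._encoded = np.empty((0, 0), dtype=np.uint8)
            else:
                raw = np.frombuffer(
                    "".join(self.seqs).encode("ascii"), dtype=np.uint8
                ).reshape(self.n, self.L)
                self._encoded = _ENCODE[raw]
        return self._encoded

    def uncalled_counts(self) -> np.ndarray:
        """Per-colony number of N/gap positions."""
        return (self.encoded() == UNCALLED).sum(axis=1)


@dataclass
class ColonyTable:
    """Per-colony sampling metadata with a reef-nested-in-region design."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        df = self.df.copy()
        for col in ("colony", "reef", "region", "date"):
            df[col] = df[col].astype(str)
        for col in ("lat", "lon"):
            df[col] = pd.to_numeric(df[col])
        if df["colony"].duplicated().any():
            dupes = sorted(df.loc[df["colony"].duplicated(), "colony"])
            raise ValidationError(f"duplicate colony ids in metadata: {dupes}")
        if (df["lat"].abs() > 90).any():
            raise ValidationError("latitude outside [-90, 90]")
        if (df["lon"].abs() > 180).any():
            raise ValidationError("longitude outside [-180, 180]")
        multi = df.groupby("reef")["region"].nunique()
        bad = multi[multi > 1].index.tolist()
        if bad:
            raise ValidationError(f"reefs mapped to more than one region: {bad}")
        if "heat_fraction" in df.columns:
            hf = pd.to_numeric(df["heat_fraction"])
            if ((hf < 0) | (hf > 1)).any():
                raise ValidationError("heat_fraction outside [0, 1]")
            df["heat_fraction"] = hf
        self.df = df.reset_index(drop=True)

    @property
    def colonies(self) -> list[str]:
        return self.df["colony"].tolist()

    def reefs(self) -> list[str]:
        return sorted(self.df["reef"].unique())

    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    def region_of_reef(self) -> dict[str, str]:
        return dict(self.df.drop_duplicates("reef")[["reef", "region"]].values)

    def aligned_to(self, ids: Iterable[str]) -> pd.DataFrame:
        """Rows reordered to match an alignment's colony order."""
        idx = self.df.set_index("colony")
        ids = list(ids)
        missing = [i for i in ids if i not in idx.index]
        if missing:
            raise CrossReferenceError(
                f"colonies absent from metadata: {missing[:10]}"
            )
        return idx.loc[ids].reset_index()


@dataclass
class ValidationReport:
    passed: bool
    messages: list[str]
    n_counts: dict[str, int]
    reef_counts: dict[str, int]
    region_roster: dict[str, list[str]]

    @property
    def mean_uncalled(self) -> float:
        return float(np.mean(list(self.n_counts.values()))) if self.n_counts else 0.0


def read_alignment(path: str | Path) -> Alignment:
    """Parse an aligned FASTA into an :class:`Alignment`.

    Record ids are the first whitespace-delimited token of each header.
    Unequal record lengths raise :class:`AlignmentShapeError` naming the
    offending record; duplicate ids and non-ACGTN- characters raise
    :class:`ValidationError`.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    ref_len: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if ref_len is None:
            ref_len = len(s)
        elif len(s) != ref_len:
            raise AlignmentShapeError(
                f"record {rec.id!r} has length {len(s)}, expected {ref_len}"
            )
        ids.append(rec.id)
        seqs.append(s)
    if not ids:
        raise ValidationError(f"no FASTA records in {path}")
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def read_metadata(path: str | Path) -> ColonyTable:
    """Read the colony table (CSV or TSV, auto-detected, UTF-8)."""
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text[:4096])
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str)
    return ColonyTable(df)


def write_metadata(table: ColonyTable, path: str | Path, sep: str = ",") -> None:
    table.df.to_csv(path, sep=sep, index=False)


def validate_dataset(aln: Alignment, table: ColonyTable) -> ValidationReport:
    """Cross-check alignment against metadata and summarise the design.

    Passes iff the two id sets are identical (type invariants were already
    enforced on construction).  The report carries per-sequence uncalled-base
    counts, per-reef colony counts and the region roster regardless.
    """
    messages: list[str] = []
    aln_ids = set(aln.ids)
    meta_ids = set(table.colonies)
    only_aln = sorted(aln_ids - meta_ids)
    only_meta = sorted(meta_ids - aln_ids)
    if only_aln:
        messages.append(f"alignment ids absent from metadata: {only_aln}")
    if only_meta:
        messages.append(f"metadata ids absent from alignment: {only_meta}")
    n_counts = dict(zip(aln.ids, (int(x) for x in aln.uncalled_counts())))
    reef_counts = table.df.groupby("reef")["colony"].count().to_dict()
    roster = {
        region: sorted(g["reef"].unique())
        for region, g in table.df.groupby("region")
    }
    return ValidationReport(
        passed=not messages,
        messages=messages,
        n_counts=n_counts,
        reef_counts={k: int(v) for k, v in reef_counts.items()},
        region_roster=roster,
    )


def write_json(obj: Mapping, path: str | Path) -> None:
    """Shared JSON result writer (numpy scalars coerced to Python)."""

    def default(o):
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
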