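"""Cohort and variant-weight tables: domain types and delimited-text I/O.

A cohort row is one participant's follow-up interval on the age axis:
entry age (delayed entry / left truncation), exit age (diagnosis,
death, loss to follow-up or administrative end) and an event flag that
is true when exit is the age at Alzheimer's disease diagnosis.  APOE
alleles and per-variant dosages are optional; participants missing them
are loaded and flagged, and excluded only by the genetic analyses that
need them.

Files are plain delimited text (comma or tab, auto-detected), UTF-8,
with a header row.  Mandatory columns: ``id, entry_age, exit_age,
event``; optional: ``apoe_a1, apoe_a2`` (values ``e2/e3/e4``) followed
by one dosage column per variant, named by its variant id.  An empty
field or ``NA`` means missing.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import RowParseError, SchemaError

APOE_ALLELES = frozenset({"e2", "e3", "e4"})
NUCLEOTIDES = frozenset({"A", "C", "G", "T"})
MANDATORY_COLUMNS = ("id", "entry_age", "exit_age", "event")
APOE_COLUMNS = ("apoe_a1", "apoe_a2")
MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})


@dataclass(frozen=True)
class Participant:
    """One subject's follow-up interval, event flag and genetic data.

    ``apoe_alleles`` is an unordered pair from {e2, e3, e4} or ``None``
    when ungenotyped.  ``dosages`` maps variant id to an effect-allele
    dosage in [0, 2]; a variant absent from the mapping is missing.
    """

    id: str
    entry_age: float
    exit_age: float
    event: bool
    apoe_alleles: tuple[str, str] | None = None
    dosages: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entry_age > 0:
            raise ValueError(f"participant {self.id}: entry_age must be > 0")
        if not self.exit_age > self.entry_age:
            raise ValueError(
                f"participant {self.id}: exit_age ({self.exit_age}) must exceed "
                f"entry_age ({self.entry_age})"
            )
        if self.apoe_alleles is not None:
            pair = tuple(sorted(self.apoe_alleles))
            if len(pair) != 2 or any(a not in APOE_ALLELES for a in pair):
                raise ValueError(f"participant {self.id}: bad APOE pair {self.apoe_alleles}")
            object.__setattr__(self, "apoe_alleles", pair)
        for vid, d in self.dosages.items():
            if not (0.0 <= d <= 2.0):
                raise ValueError(
                    f"participant {self.id}: dosage {d} for {vid} outside [0, 2]"
                )

    @property
    def follow_up(self) -> float:
        return self.exit_age - self.entry_age


@dataclass(frozen=True)
class VariantWeight:
    """A risk variant's effect allele and per-allele weight (log-odds scale)."""

    variant_id: str
    effect_allele: str
    beta: float

    def __post_init__(self) -> None:
        if self.effect_allele not in NUCLEOTIDES:
            raise ValueError(f"{self.variant_id}: effect allele {self.effect_allele!r}")
        if not math.isfinite(self.beta):
            raise ValueError(f"{self.variant_id}: beta must be finite")


class CohortTable:
    """Ordered collection of participants with provenance metadata.

    Backed by a :class:`pandas.DataFrame` (one row per participant,
    dosage columns named by variant id) so that downstream accrual,
    scoring and simulation stay vectorised; iteration materialises
    :class:`Participant` objects on demand.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        dosage_columns: Sequence[str] = (),
        provenance: str = "",
        diagnostics: Sequence[str] = (),
    ) -> None:
        if frame["id"].duplicated().any():
            dups = frame.loc[frame["id"].duplicated(), "id"].iloc[0]
            raise SchemaError(f"duplicate participant id {dups!r}")
        self.frame = frame.reset_index(drop=True)
        self.dosage_columns = list(dosage_columns)
        self.provenance = provenance
        self.diagnostics = list(diagnostics)

    @classmethod
    def from_participants(
        cls, participants: Iterable[Participant], provenance: str = ""
    ) -> "CohortTable":
        participants = list(participants)
        dosage_cols: list[str] = []
        for p in participants:
            for vid in p.dosages:
                if vid not in dosage_cols:
                    dosage_cols.append(vid)
        rows = []
        for p in participants:
            a1, a2 = p.apoe_alleles if p.apoe_alleles is not None else (None, None)
            row = {
                "id": p.id,
                "entry_age": p.entry_age,
                "exit_age": p.exit_age,
                "event": bool(p.event),
                "apoe_a1": a1,
                "apoe_a2": a2,
            }
            for vid in dosage_cols:
                row[vid] = p.dosages.get(vid, float("nan"))
            rows.append(row)
        cols = list(MANDATORY_COLUMNS) + list(APOE_COLUMNS) + dosage_cols
        frame = pd.DataFrame(rows, columns=cols)
        return cls(frame, dosage_cols, provenance)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[Participant]:
        for _, row in self.frame.iterrows():
            yield self._row_to_participant(row)

    def __getitem__(self, i: int) -> Participant:
        return self._row_to_participant(self.frame.iloc[i])

    def _row_to_participant(self, row: pd.Series) -> Participant:
        a1, a2 = row.get("apoe_a1"), row.get("apoe_a2")
        apoe = None
        if isinstance(a1, str) and isinstance(a2, str):
            apoe = (a1, a2)
        dosages = {
            vid: float(row[vid])
            for vid in self.dosage_columns
            if not pd.isna(row[vid])
        }
        return Participant(
            id=str(row["id"]),
            entry_age=float(row["entry_age"]),
            exit_age=float(row["exit_age"]),
            event=bool(row["event"]),
            apoe_alleles=apoe,
            dosages=dosages,
        )

    @property
    def n_events(self) -> int:
        return int(self.frame["event"].sum())

    def total_follow_up(self) -> float:
        return float((self.frame["exit_age"] - self.frame["entry_age"]).sum())

    def has_apoe(self) -> pd.Series:
        """Boolean mask: both APOE alleles present."""
        return self.frame["apoe_a1"].notna() & self.frame["apoe_a2"].notna()

    def subset(self, mask) -> "CohortTable":
        return CohortTable(
            self.frame.loc[mask],
            self.dosage_columns,
            provenance=self.provenance,
        )


def _parse_field(token: str) -> str | None:
    token = token.strip()
    return None if token in MISSING_TOKENS else token


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def read_cohort(
    path: str | Path, dialect: str | None = None, strict: bool = False
) -> CohortTable:
    """Read a participant table from delimited text.

    Rows violating the participant invariants (non-positive entry age,
    exit <= entry, unparseable numbers, dosages outside [0, 2]) are
    rejected with a per-row diagnostic recorded on the returned table;
    with ``strict=True`` the first bad row raises :class:`RowParseError`
    instead.  Missing APOE alleles or dosages are preserved as missing.
    """
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for col in MANDATORY_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        idx = {col: header.index(col) for col in header}
        has_apoe = all(c in header for c in APOE_COLUMNS)
        dosage_cols = [
            c for c in header if c not in MANDATORY_COLUMNS and c not in APOE_COLUMNS
        ]

        participants: list[Participant] = []
        diagnostics: list[str] = []
        for rownum, raw in enumerate(reader, start=2):
            if not any(f.strip() for f in raw):
                continue
            try:
                participants.append(
                    _parse_row(raw, idx, has_apoe, dosage_cols, rownum)
                )
            except (ValueError, IndexError) as exc:
                if strict:
                    raise RowParseError(f"{path}: row {rownum}: {exc}") from exc
                diagnostics.append(f"row {rownum}: {exc}")

    table = CohortTable.from_participants(participants, provenance=str(path))
    # keep declared dosage columns even if every value is missing
    for c in dosage_cols:
        if c not in table.dosage_columns:
            table.frame[c] = float("nan")
            table.dosage_columns.append(c)
    table.diagnostics = diagnostics
    return table


def _parse_row(raw, idx, has_apoe, dosage_cols, rownum) -> Participant:
    get = lambda col: _parse_field(raw[idx[col]])
    pid = get("id")
    if pid is None:
        raise ValueError("missing id")
    entry = _parse_float(get("entry_age"), "entry_age")
    exit_ = _parse_float(get("exit_age"), "exit_age")
    ev_tok = get("event")
    if ev_tok not in {"0", "1"}:
        raise ValueError(f"event must be 0 or 1, got {ev_tok!r}")
    apoe = None
    if has_apoe:
        a1, a2 = get("apoe_a1"), get("apoe_a2")
        if (a1 is None) != (a2 is None):
            raise ValueError("half-missing APOE pair")
        if a1 is not None:
            apoe = (a1, a2)
    dosages = {}
    for c in dosage_cols:
        tok = get(c)
        if tok is not None:
            dosages[c] = _parse_float(tok, c)
    return Participant(pid, entry, exit_, ev_tok == "1", apoe, dosages)


def _parse_float(token: str | None, col: str) -> float:
    if token is None:
        raise ValueError(f"missing {col}")
    try:
        value = float(token)
    except ValueError:
        raise ValueError(f"non-numeric {col}: {token!r}") from None
    if not math.isfinite(value):
        raise ValueError(f"non-finite {col}: {token!r}")
    return value


def write_cohort(cohort: CohortTable, path: str | Path, sep: str = ",") -> None:
    """Write a cohort as delimited text; ``read_cohort`` round-trips it.

    Floats are written with :func:`repr` (shortest exact decimal), so
    the round-trip is lossless; missing values are written as ``NA``.
    """
    path = Path(path)
    cols = list(MANDATORY_COLUMNS) + list(APOE_COLUMNS) + list(cohort.dosage_columns)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep, lineterminator="\n")
        writer.writerow(cols)
        for _, row in cohort.frame.iterrows():
            out = [str(row["id"])]
            out.append(repr(float(row["entry_age"])))
            out.append(repr(float(row["exit_age"])))
            out.append("1" if row["event"] else "0")
            for c in APOE_COLUMNS:
                v = row.get(c)
                out.append("NA" if v is None or pd.isna(v) else str(v))
            for c in cohort.dosage_columns:
                v = row[c]
                out.append("NA" if pd.isna(v) else repr(float(v)))
            writer.writerow(out)


def read_variant_weights(path: str | Path) -> list[VariantWeight]:
    """Read a variant-weight table (columns variant_id, effect_allele, beta)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("variant_id", "effect_allele", "beta"):
        if col not in frame.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    weights: list[VariantWeight] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        vid = row["variant_id"].strip()
        if vid in seen:
            raise SchemaError(f"{path}: duplicate variant_id {vid!r}")
        seen.add(vid)
        try:
            beta = float(row["beta"])
            if not math.isfinite(beta):
                raise ValueError
        except ValueError:
            raise RowParseError(
                f"{path}: unparseable beta {row['beta']!r} for variant {vid}"
            ) from None
        weights.append(VariantWeight(vid, row["effect_allele"].strip(), beta))
    return weights


def load_default_variant_weights() -> list[VariantWeight]:
    """Load the packaged synthetic 23-variant weight set.

    The shipped weights are illustrative stand-ins (real rs identifiers
    of known AD-associated loci, synthetic effect sizes), suitable for
    simulation and testing, not for scoring real genotypes.
    """
    from importlib.resources import files

    res = files("multistage").joinpath("data/synthetic_variant_weights.tsv")
    with res.open("rb") as fh:  # type: ignore[attr-defined]
        data = fh.read().decode("utf-8")
    tmp = io.StringIO(data)
    frame = pd.read_csv(tmp, sep="\t", dtype=str)
    return [
        VariantWeight(r["variant_id"], r["effect_allele"], float(r["beta"]))
        for _, r in frame.iterrows()
    ]
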