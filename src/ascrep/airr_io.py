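"""Reading, validation, and writing of AIRR-style rearrangement tables.

Input follows the AIRR Rearrangement convention: a tab-separated table with
MiAIRR column names (``sequence_id``, ``v_call``, ``j_call``, ``junction``,
and optionally ``junction_length``, ``duplicate_count``, ``v_mutation_count``,
``population``, ``subject``).  One file per sorted cell population, or a
single pooled file carrying a ``population`` column.

The junction column (CDR3 plus its anchor codons, nucleotide alphabet) is the
substrate for all downstream homology computations, so validation rejects any
row whose junction contains characters outside ``A/C/G/T`` — including ``N``
ambiguity codes — rather than wildcarding them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AirrFormatError",
    "EmptyRepertoireError",
    "InvalidCallError",
    "Rearrangement",
    "Repertoire",
    "read_airr_table",
    "read_pooled_table",
    "normalize_gene_call",
    "validate_repertoire",
    "write_table",
    "read_table",
]

REQUIRED_COLUMNS = ("sequence_id", "v_call", "j_call", "junction")

#: Canonical column order for the rearrangement frame held by a Repertoire.
REARRANGEMENT_COLUMNS = (
    "sequence_id",
    "v_call",
    "j_call",
    "junction",
    "junction_length",
    "duplicate_count",
    "v_mutation_count",
    "population",
    "subject",
)

_ACGT = frozenset("ACGT")


class AirrFormatError(ValueError):
    """A rearrangement table does not conform to the expected schema."""


class EmptyRepertoireError(ValueError):
    """A repertoire holds no (retained) rearrangements."""


class InvalidCallError(ValueError):
    """A V/J gene annotation string cannot be normalized."""


@dataclass(frozen=True)
class Rearrangement:
    """One sequenced V(D)J read with its gene calls, junction, and counts."""

    sequence_id: str
    v_call: str
    j_call: str
    junction: str
    junction_length: int
    duplicate_count: int = 1
    v_mutation_count: int | None = None
    population: str = ""
    subject: str = ""


@dataclass
class Repertoire:
    """All rearrangements of one sorted population of one subject.

    The rearrangements are stored as a pandas DataFrame with the columns in
    :data:`REARRANGEMENT_COLUMNS`; row order is the retained input order.
    """

    subject: str
    population: str
    frame: pd.DataFrame = field(repr=False)

    @property
    def total_sequences(self) -> int:
        return len(self.frame)

    def rearrangements(self) -> list[Rearrangement]:
        out = []
        for row in self.frame.itertuples(index=False):
            mut = row.v_mutation_count
            out.append(
                Rearrangement(
                    sequence_id=row.sequence_id,
                    v_call=row.v_call,
                    j_call=row.j_call,
                    junction=row.junction,
                    junction_length=int(row.junction_length),
                    duplicate_count=int(row.duplicate_count),
                    v_mutation_count=None if pd.isna(mut) else int(mut),
                    population=row.population,
                    subject=row.subject,
                )
            )
        return out


def normalize_gene_call(call: str) -> str:
    """Reduce a raw V/J annotation to its gene label.

    Keeps the first comma-separated call (aligners list the best match first)
    and strips the allele suffix (everything from ``*`` on).  Clustering is
    done at gene level: allele calls are unstable under somatic hypermutation
    and the clonal-assignment rule matches V and J *genes*.

    >>> normalize_gene_call("IGHV3-23*04, IGHV3-23D*01")
    'IGHV3-23'
    """
    if not isinstance(call, str) or not call.strip():
        raise InvalidCallError("empty gene call")
    first = call.split(",")[0]
    gene = first.split("*")[0].strip()
    if not gene:
        raise InvalidCallError(f"cannot normalize gene call {call!r}")
    return gene


def _prepare_frame(df: pd.DataFrame, subject: str, population: str, path) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise AirrFormatError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise EmptyRepertoireError(f"{path}: table contains no rearrangements")

    out = pd.DataFrame()
    out["sequence_id"] = df["sequence_id"].astype(str)
    out["v_call"] = df["v_call"].astype(str)
    out["j_call"] = df["j_call"].astype(str)
    out["junction"] = df["junction"].fillna("").astype(str).str.upper()

    if "junction_length" in df.columns:
        jl = pd.to_numeric(df["junction_length"], errors="coerce")
        jl = jl.fillna(out["junction"].str.len())
    else:
        jl = out["junction"].str.len()
    out["junction_length"] = jl.astype(int)

    if "duplicate_count" in df.columns:
        dc = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1)
    else:
        dc = 1
    out["duplicate_count"] = pd.Series(dc, index=out.index).astype(int)

    if "v_mutation_count" in df.columns:
        out["v_mutation_count"] = pd.to_numeric(df["v_mutation_count"], errors="coerce")
    else:
        out["v_mutation_count"] = float("nan")

    out["population"] = population
    out["subject"] = subject
    return out.reset_index(drop=True)


def read_airr_table(path, subject: str, population: str) -> Repertoire:
    """Read one AIRR rearrangement TSV into a :class:`Repertoire`.

    Missing ``duplicate_count`` defaults to 1; missing ``junction_length`` is
    computed from the junction string.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: empty file") from None
    frame = _prepare_frame(df, subject=subject, population=population, path=path)
    return Repertoire(subject=subject, population=population, frame=frame)


def read_pooled_table(path, subject: str) -> list[Repertoire]:
    """Read a pooled rearrangement TSV carrying a ``population`` column.

    Returns one Repertoire per distinct population, in order of first
    appearance.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyRepertoireError(f"{path}: empty file") from None
    if "population" not in df.columns:
        raise AirrFormatError(f"{path}: missing required column 'population'")
    reps = []
    for pop in df["population"].drop_duplicates():
        sub = df[df["population"] == pop]
        frame = _prepare_frame(sub, subject=subject, population=str(pop), path=path)
        reps.append(Repertoire(subject=subject, population=str(pop), frame=frame))
    return reps


def validate_repertoire(rep: Repertoire) -> tuple[Repertoire, dict[str, int]]:
    """Drop structurally invalid rearrangements; report counts per reason.

    Rejection reasons (keys of the report, present only when nonzero):

    ``empty_junction``
        junction string empty.
    ``non_acgt``
        junction contains characters outside A/C/G/T (including N).
    ``bad_length``
        junction_length <= 0 or inconsistent with the junction string.
    ``bad_gene_call``
        v_call or j_call cannot be normalized.

    Retained row order is preserved; validation is idempotent.
    """
    frame = rep.frame
    report: Counter[str] = Counter()
    keep = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        junction = row.junction
        if not junction:
            report["empty_junction"] += 1
            continue
        if not _ACGT.issuperset(junction):
            report["non_acgt"] += 1
            continue
        if row.junction_length <= 0 or row.junction_length != len(junction):
            report["bad_length"] += 1
            continue
        try:
            normalize_gene_call(row.v_call)
            normalize_gene_call(row.j_call)
        except InvalidCallError:
            report["bad_gene_call"] += 1
            continue
        keep.append(idx)
    if not keep:
        raise EmptyRepertoireError(
            f"repertoire {rep.subject}/{rep.population}: all rearrangements rejected"
        )
    cleaned = frame.iloc[keep].reset_index(drop=True)
    return Repertoire(rep.subject, rep.population, cleaned), dict(report)


def write_table(records: pd.DataFrame, path, float_format: str = "%.10g") -> None:
    """Write a derived table as TSV with deterministic column and row order.

    ``records`` is written as-is (callers establish ordering); integers and
    labels round-trip bit-exactly, floats at full printed precision.
    An empty frame with columns yields a header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(Path(path), sep="\t")
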