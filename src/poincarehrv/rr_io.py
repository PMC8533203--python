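"""Reading, validation and editing of annotated RR-interval series.

An RR series is the beat-to-beat interval stream of a long-term (Holter-style)
ECG recording, one row per beat: the interval in milliseconds that ends at the
beat, plus a beat label (``normal``, ``aberrant`` for ectopic beats, or
``artefact``).  Before any Poincare-plot geometry is computed the series is
edited: isolated ectopic beats are corrected by linear interpolation of the
flanking normal intervals, while runs of consecutive non-normal beats and any
interval adjacent to a non-normal beat are excluded from the plotted pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NORMAL",
    "ABERRANT",
    "ARTEFACT",
    "LABELS",
    "Dialect",
    "BeatRecord",
    "RRSeries",
    "RRPairs",
    "load_rr_series",
    "write_rr_series",
    "correct_isolated_ectopics",
    "build_pairs",
]

NORMAL = "normal"
ABERRANT = "aberrant"
ARTEFACT = "artefact"
LABELS = (NORMAL, ABERRANT, ARTEFACT)


class RRValidationError(ValueError):
    """A row of an RR file violates the series invariants."""


@dataclass(frozen=True)
class Dialect:
    """Column map and token set of a delimited RR file.

    The on-disk format is header-first delimited text with a required
    ``rr_ms`` column, an optional ``label`` column (single-character tokens by
    default: N / A / X) and an optional ``t_ms`` beat-time column.
    """

    delimiter: str = ","
    rr_column: str = "rr_ms"
    label_column: str = "label"
    time_column: str = "t_ms"
    label_tokens: dict = field(
        default_factory=lambda: {"N": NORMAL, "A": ABERRANT, "X": ARTEFACT}
    )

    def token_for(self, label: str) -> str:
        for tok, lab in self.label_tokens.items():
            if lab == label:
                return tok
        raise KeyError(label)


@dataclass(frozen=True)
class BeatRecord:
    """One annotated beat: 0-based index, interval to the previous beat, label."""

    index: int
    rr_ms: float
    label: str

    def __post_init__(self):
        if not np.isfinite(self.rr_ms) or self.rr_ms <= 0:
            raise RRValidationError(
                f"beat {self.index}: rr_ms must be a positive finite number, "
                f"got {self.rr_ms!r}"
            )
        if self.label not in LABELS:
            raise RRValidationError(
                f"beat {self.index}: unknown label {self.label!r}"
            )


class RRSeries:
    """An ordered, annotated RR-interval series.

    Stored internally as parallel numpy arrays (float intervals, string
    labels) for speed on 24-h recordings (~1e5 beats); ``beats`` materialises
    :class:`BeatRecord` objects on demand.
    """

    def __init__(self, rr_ms, labels=None, meta: dict | None = None):
        rr = np.asarray(rr_ms, dtype=float)
        if rr.ndim != 1 or rr.size < 2:
            raise RRValidationError("an RR series needs at least 2 beats")
        if not np.all(np.isfinite(rr)):
            bad = int(np.flatnonzero(~np.isfinite(rr))[0])
            raise RRValidationError(f"beat {bad}: rr_ms is not finite")
        if np.any(rr <= 0):
            bad = int(np.flatnonzero(rr <= 0)[0])
            raise RRValidationError(f"beat {bad}: rr_ms must be > 0, got {rr[bad]}")
        if labels is None:
            lab = np.full(rr.size, NORMAL, dtype=object)
        else:
            lab = np.asarray(labels, dtype=object)
            if lab.shape != rr.shape:
                raise RRValidationError("labels and rr_ms must have equal length")
            unknown = set(lab) - set(LABELS)
            if unknown:
                bad = int(np.flatnonzero(~np.isin(lab, LABELS))[0])
                raise RRValidationError(f"beat {bad}: unknown label {lab[bad]!r}")
        self.rr_ms = rr
        self.labels = lab
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return self.rr_ms.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RRSeries)
            and np.array_equal(self.rr_ms, other.rr_ms)
            and np.array_equal(self.labels, other.labels)
        )

    @property
    def beats(self) -> list[BeatRecord]:
        return [
            BeatRecord(i, float(r), str(l))
            for i, (r, l) in enumerate(zip(self.rr_ms, self.labels))
        ]

    def is_normal(self) -> np.ndarray:
        return self.labels == NORMAL

    def copy(self, meta_update: dict | None = None) -> "RRSeries":
        meta = dict(self.meta)
        meta.update(meta_update or {})
        return RRSeries(self.rr_ms.copy(), self.labels.copy(), meta)


@dataclass(frozen=True)
class RRPairs:
    """Consecutive (RR(n), RR(n+1)) couples surviving label filtering."""

    x: np.ndarray  # RR(n), ms
    y: np.ndarray  # RR(n+1), ms
    n_excluded: int

    def __len__(self) -> int:
        return self.x.size

    def shifted(self, delta_ms: float) -> "RRPairs":
        return replace(self, x=self.x + delta_ms, y=self.y + delta_ms)

    def swapped(self) -> "RRPairs":
        return replace(self, x=self.y.copy(), y=self.x.copy())


def load_rr_series(path, dialect: Dialect | None = None) -> RRSeries:
    """Read an annotated RR series from delimited text.

    Unlabeled rows default to ``normal``.  A parse report (rows read / rows
    rejected) is attached to ``meta``.  Malformed rows raise
    :class:`RRValidationError` naming the offending row.
    """
    dialect = dialect or Dialect()
    try:
        df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    except FileNotFoundError:
        raise
    if dialect.rr_column not in df.columns:
        raise RRValidationError(
            f"{path}: missing required column {dialect.rr_column!r} "
            f"(found {list(df.columns)})"
        )
    rr_raw = pd.to_numeric(df[dialect.rr_column], errors="coerce").to_numpy()
    if np.any(~np.isfinite(rr_raw)):
        bad = int(np.flatnonzero(~np.isfinite(rr_raw))[0])
        raise RRValidationError(
            f"{path}: row {bad}: non-numeric or missing rr_ms "
            f"{df[dialect.rr_column].iloc[bad]!r}"
        )
    if np.any(rr_raw <= 0):
        bad = int(np.flatnonzero(rr_raw <= 0)[0])
        raise RRValidationError(
            f"{path}: row {bad}: rr_ms must be > 0, got {rr_raw[bad]}"
        )

    if dialect.label_column in df.columns:
        tokens = df[dialect.label_column].fillna("N").astype(str).str.strip()
        labels = np.empty(len(df), dtype=object)
        for i, tok in enumerate(tokens):
            if tok not in dialect.label_tokens:
                raise RRValidationError(
                    f"{path}: row {i}: unknown label token {tok!r} "
                    f"(expected one of {sorted(dialect.label_tokens)})"
                )
            labels[i] = dialect.label_tokens[tok]
    else:
        labels = None

    meta = {
        "source": str(path),
        "rows_read": int(len(df)),
        "rows_rejected": 0,
    }
    if dialect.time_column in df.columns:
        meta["t_ms_first"] = float(df[dialect.time_column].iloc[0])
    return RRSeries(rr_raw, labels, meta)


def write_rr_series(series: RRSeries, path, dialect: Dialect | None = None) -> None:
    """Write a series in the same dialect ``load_rr_series`` reads.

    Interval values are written with ``repr`` (shortest round-tripping float
    form) so a write -> read cycle reproduces the series exactly.
    """
    dialect = dialect or Dialect()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{dialect.rr_column}{dialect.delimiter}{dialect.label_column}\n")
        for rr, lab in zip(series.rr_ms, series.labels):
            fh.write(f"{float(rr)!r}{dialect.delimiter}{dialect.token_for(lab)}\n")


def correct_isolated_ectopics(series: RRSeries) -> RRSeries:
    """Replace each isolated non-normal beat's interval by linear interpolation.

    A beat is *isolated* when it is non-normal and both its neighbours are
    normal; its interval becomes the mean of the two flanking normal intervals
    and its label becomes normal.  Runs of >= 2 consecutive non-normal beats
    are left untouched (they are excluded downstream), as are non-normal beats
    at the series boundary, which lack a flank to interpolate from.  The input
    series is not mutated.
    """
    notn = ~series.is_normal()
    n = len(series)
    isolated = np.zeros(n, dtype=bool)
    if n >= 3:
        isolated[1:-1] = notn[1:-1] & ~notn[:-2] & ~notn[2:]
    out = series.copy()
    idx = np.flatnonzero(isolated)
    out.rr_ms[idx] = 0.5 * (series.rr_ms[idx - 1] + series.rr_ms[idx + 1])
    out.labels[idx] = NORMAL
    n_boundary = int(notn[0]) + int(notn[-1] if n > 1 else 0)
    out.meta["n_ectopics_corrected"] = int(idx.size)
    out.meta["n_boundary_uncorrected"] = n_boundary
    return out


def build_pairs(series: RRSeries) -> RRPairs:
    """Emit the time-closed RR couples used by the Poincare plots.

    The interval carried by beat ``i`` spans beat ``i-1`` -> beat ``i``; it is
    usable only when neither endpoint beat is non-normal (an interval
    preceding or following an ectopic/artefact beat never enters a pair).  A
    couple ``(rr[i], rr[i+1])`` is emitted when both intervals are usable,
    which guarantees no pair spans a non-normal beat and pairs stay
    consecutive in time.
    """
    normal = series.is_normal()
    usable = normal.copy()
    usable[1:] &= normal[:-1]
    keep = usable[:-1] & usable[1:]
    x = series.rr_ms[:-1][keep]
    y = series.rr_ms[1:][keep]
    n_excluded = int((len(series) - 1) - x.size)
    if x.size == 0:
        warnings.warn("no usable RR pairs after label filtering", stacklevel=2)
    return RRPairs(x=x, y=y, n_excluded=n_excluded)
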