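"""Reading, validating and writing per-call acoustic measurement tables.

The unit of analysis is a single vocalization ("call") described by four
acoustic parameters measured from its spectrogram:

* ``maxfreq_hz``   — frequency of highest amplitude (Hz), a proxy of pitch;
* ``duration_s``   — call duration (seconds);
* ``freqslope_hz`` — average slope of the peak-frequency contour (Hz, as
  reported by the measurement software; no unit conversion is attempted);
* ``entropy_bits`` — average acoustic (spectral) entropy of the call (bits).

Calls are grouped into ordered sequences, one per recording session of a
subject.  Two table dialects are supported: a plain delimited call table
(CSV/TSV, one row per call) and the tab-delimited selection tables produced
by the Raven sound-analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Required columns of the plain call-table dialect.
CALL_TABLE_COLUMNS = (
    "subject",
    "session",
    "order",
    "maxfreq_hz",
    "duration_s",
    "freqslope_hz",
    "entropy_bits",
)

#: The four acoustic parameters, in canonical order.
PARAMETERS = ("maxfreq_hz", "duration_s", "freqslope_hz", "entropy_bits")


class SchemaError(ValueError):
    """A required column is missing or unmapped."""


class ParseError(ValueError):
    """A cell could not be parsed as a number."""


class IntegrityError(ValueError):
    """Row-level contradiction (duplicate order, negative duration span...)."""


@dataclass(frozen=True)
class CallRecord:
    """One vocalization: its position in the session and its four parameters."""

    subject: str
    session: str
    order: int
    maxfreq: float
    duration: float
    freqslope: float
    acentropy: float


@dataclass
class CallSequence:
    """An ordered sequence of calls from one subject in one session."""

    subject: str
    session: str
    records: list[CallRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def param(self, name: str) -> np.ndarray:
        """Return one acoustic parameter as a float array, in call order."""
        attr = _PARAM_ATTR[name]
        return np.array([getattr(r, attr) for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [r.subject for r in self.records],
                "session": [r.session for r in self.records],
                "order": [r.order for r in self.records],
                "maxfreq_hz": [r.maxfreq for r in self.records],
                "duration_s": [r.duration for r in self.records],
                "freqslope_hz": [r.freqslope for r in self.records],
                "entropy_bits": [r.acentropy for r in self.records],
            }
        )


_PARAM_ATTR = {
    "maxfreq_hz": "maxfreq",
    "duration_s": "duration",
    "freqslope_hz": "freqslope",
    "entropy_bits": "acentropy",
}


def _sequences_from_frame(df: pd.DataFrame) -> list[CallSequence]:
    seqs = []
    for (subject, session), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("order")
        records = [
            CallRecord(
                subject=str(subject),
                session=str(session),
                order=int(row.order),
                maxfreq=float(row.maxfreq_hz),
                duration=float(row.duration_s),
                freqslope=float(row.freqslope_hz),
                acentropy=float(row.entropy_bits),
            )
            for row in grp.itertuples()
        ]
        seqs.append(CallSequence(str(subject), str(session), records))
    return seqs


def read_call_table(source, dialect: str = "csv") -> list[CallSequence]:
    """Read a plain delimited call table into one :class:`CallSequence` per
    (subject, session).

    Parameters
    ----------
    source
        Path or open text stream.
    dialect
        ``"csv"`` (comma) or ``"tsv"`` (tab).

    Rows may appear in any order; each sequence is returned sorted by the
    1-based ``order`` column.  Missing values are rejected rather than
    imputed — the downstream analyses are sequence-positional, and imputing
    a call would fabricate transitions that were never observed.
    """
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    df = pd.read_csv(source, sep=sep, dtype="object")
    missing = [c for c in CALL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    numeric = ("order", "maxfreq_hz", "duration_s", "freqslope_hz", "entropy_bits")
    for col in numeric:
        parsed = []
        # float() is an exact round-trip parser (pd.to_numeric's fast path
        # is not) and lets us report the offending row
        for idx, value in df[col].items():
            try:
                number = float(value)
                if number != number:  # NaN: empty cell
                    raise ValueError
                parsed.append(number)
            except (TypeError, ValueError):
                row = int(idx) + 2  # 1-based, counting the header
                raise ParseError(
                    f"non-numeric or missing value in column {col!r} at row {row}"
                ) from None
        df[col] = parsed
    dup = df.duplicated(subset=["subject", "session", "order"])
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise IntegrityError(
            "duplicate (subject, session, order): "
            f"({first['subject']}, {first['session']}, {int(first['order'])})"
        )
    return _sequences_from_frame(df)


def read_raven_selection_table(
    source,
    column_map: Mapping[str, str],
    subject: str,
    session: str,
) -> CallSequence:
    """Read a Raven-style tab-delimited selection table as one sequence.

    Raven selection tables carry one row per selection box drawn on the
    spectrogram, with standard columns ``Selection``, ``Begin Time (s)``,
    ``End Time (s)`` and ``Peak Freq (Hz)``.  ``column_map`` names the
    columns holding the frequency-contour slope and acoustic entropy
    measurements (keys ``freqslope`` and ``entropy``), since those are
    configured per study.  Duration is ``End Time − Begin Time`` and call
    order is the ``Selection`` number.  Unmapped extra columns are ignored.
    """
    df = pd.read_csv(source, sep="\t")
    required = {
        "Selection": "Selection",
        "Begin Time (s)": "Begin Time (s)",
        "End Time (s)": "End Time (s)",
        "Peak Freq (Hz)": "Peak Freq (Hz)",
    }
    for col in required.values():
        if col not in df.columns:
            raise SchemaError(f"missing Raven column {col!r}")
    for key in ("freqslope", "entropy"):
        if key not in column_map:
            raise SchemaError(f"column_map must map the {key!r} parameter")
        if column_map[key] not in df.columns:
            raise SchemaError(f"mapped column {column_map[key]!r} not present in table")

    if df["Selection"].duplicated().any():
        sel = int(df.loc[df["Selection"].duplicated(), "Selection"].iloc[0])
        raise IntegrityError(f"duplicate Selection number {sel}")
    span = df["End Time (s)"].to_numpy(float) - df["Begin Time (s)"].to_numpy(float)
    if (span < 0).any():
        sel = int(df.loc[span < 0, "Selection"].iloc[0])
        raise IntegrityError(f"End Time < Begin Time for Selection {sel}")

    records = [
        CallRecord(
            subject=subject,
            session=session,
            order=int(row["Selection"]),
            maxfreq=float(row["Peak Freq (Hz)"]),
            duration=float(span[i]),
            freqslope=float(row[column_map["freqslope"]]),
            acentropy=float(row[column_map["entropy"]]),
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
    records.sort(key=lambda r: r.order)
    return CallSequence(subject, session, records)


def validate_sequence(seq: CallSequence) -> list[str]:
    """Check record invariants; return a list of human-readable violations.

    An empty list means the sequence is valid.  This never raises: it is a
    reporting operation used by the pipeline to surface data problems.
    """
    violations: list[str] = []
    if len(seq) < 1:
        violations.append("sequence must contain at least one call")
    orders = [r.order for r in seq.records]
    if len(set(orders)) != len(orders):
        violations.append("order unique within (subject, session) violated")
    if orders != sorted(orders):
        violations.append("records not sorted by order")
    for r in seq.records:
        if r.subject != seq.subject or r.session != seq.session:
            violations.append(
                f"record order={r.order}: subject/session differs from sequence"
            )
        if not r.duration > 0:
            violations.append(f"record order={r.order}: duration > 0 violated")
        if not r.maxfreq > 0:
            violations.append(f"record order={r.order}: maxfreq > 0 violated")
        if not r.acentropy >= 0:
            violations.append(f"record order={r.order}: acentropy >= 0 violated")
        if r.order < 1:
            violations.append(f"record order={r.order}: order must be a positive integer")
    return violations


def write_call_table(seqs: Iterable[CallSequence], target, dialect: str = "csv") -> None:
    """Write sequences back to the plain call-table schema (full precision)."""
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    frames = [s.to_frame() for s in seqs]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(CALL_TABLE_COLUMNS)
    )
    df.to_csv(target, sep=sep, index=False, float_format="%.17g")


def sequences_to_frame(seqs: Sequence[CallSequence]) -> pd.DataFrame:
    """Concatenate sequences into one long table (one row per call)."""
    frames = [s.to_frame() for s in seqs]
    if not frames:
        return pd.DataFrame(columns=list(CALL_TABLE_COLUMNS))
    return pd.concat(frames, ignore_index=True)
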