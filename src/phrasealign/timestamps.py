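"""Word-level timestamps: Praat TextGrid and tabular readers.

The time axis of the pipeline is a sequence of word intervals in seconds.
Because phonemes, syllables and words are not nested within each other,
their intervals follow one another without overlap on the time axis; this
module enforces (or diagnoses) exactly that sequentiality.  Inter-word
pauses are legitimate — annotators may or may not fold them into word
boundaries — so gaps between intervals are allowed, overlap is not.

Word timestamps are an *input* here: they may come from a forced aligner,
speech-to-text, or manual annotation in Praat.  Both Praat TextGrid
dialects (long and short text form, UTF-8 or UTF-16) and plain CSV/TSV
tables with word/onset/offset columns are supported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "WordInterval",
    "WordTier",
    "TierError",
    "SequentialityError",
    "read_textgrid",
    "write_textgrid",
    "read_table",
    "write_table",
    "check_sequentiality",
]

log = logging.getLogger(__name__)

#: Default tolerance for boundary rounding slop, in seconds (1 ms).
DEFAULT_TOLERANCE = 1e-3


class TierError(ValueError):
    """Problems locating or interpreting a tier in an annotation file."""


class SequentialityError(ValueError):
    """A tier violates the no-overlap requirement in strict mode."""


@dataclass(frozen=True)
class WordInterval:
    """One timestamped token: ``[onset, offset)`` in seconds."""

    token: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if not self.token:
            raise ValueError("word interval needs a non-empty token")
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset} for {self.token!r}")
        if not self.onset < self.offset:
            raise ValueError(
                f"interval for {self.token!r} must have onset < offset "
                f"(got {self.onset} >= {self.offset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class WordTier:
    """An ordered, non-overlapping sequence of word intervals.

    ``n_silences`` counts empty-label intervals that a reader dropped
    (Praat marks pauses as unlabeled intervals).
    """

    intervals: tuple[WordInterval, ...]
    source: str = ""
    n_silences: int = field(default=0, compare=False)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[WordInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> WordInterval:
        return self.intervals[i]

    @property
    def tokens(self) -> list[str]:
        return [iv.token for iv in self.intervals]

    @property
    def duration_sum(self) -> float:
        return sum(iv.duration for iv in self.intervals)

    def slice(self, start: int, stop: int) -> "WordTier":
        return replace(self, intervals=self.intervals[start:stop])


def check_sequentiality(
    tier: WordTier, tolerance: float = DEFAULT_TOLERANCE
) -> list[tuple[int, str]]:
    """Diagnose ordering problems; an empty list means the tier is valid.

    Returns ``(index, kind)`` pairs: ``"nonpositive"`` when an interval's
    onset is not before its offset (cannot occur for intervals built
    through :class:`WordInterval`, but raw inputs are checked too) and
    ``"overlap"`` when interval *index* starts more than ``tolerance``
    seconds before the previous one ends.  Touching boundaries and pauses
    are both fine.
    """
    violations: list[tuple[int, str]] = []
    for i, iv in enumerate(tier.intervals):
        if not iv.onset < iv.offset:
            violations.append((i, "nonpositive"))
        if i and iv.onset < tier.intervals[i - 1].offset - tolerance:
            violations.append((i, "overlap"))
    return violations


def _validated(tier: WordTier, strict: bool, tolerance: float) -> WordTier:
    bad = check_sequentiality(tier, tolerance)
    if bad:
        msg = f"{tier.source}: sequentiality violations {bad}"
        if strict:
            raise SequentialityError(msg)
        log.warning(msg)
    return tier


# ---------------------------------------------------------------------------
# Praat TextGrid


def _decode_textgrid(path: Path) -> str:
    raw = path.read_bytes()
    if raw.startswith(b"\xfe\xff") or raw.startswith(b"\xff\xfe"):
        return raw.decode("utf-16")
    return raw.decode("utf-8-sig")


def _value_stream(text: str) -> list[str]:
    """Reduce both TextGrid dialects to one flat value stream.

    The long form writes ``key = value`` lines plus structural headers
    (``item [1]:``); the short form writes bare values.  Stripping keys
    and headers leaves the same ordered stream of numbers and quoted
    strings in either dialect.
    """
    values: list[str] = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped:
            continue
        if "=" in stripped and not stripped.startswith('"'):
            stripped = stripped.split("=", 1)[1].strip()
        if stripped.endswith(":") or "<exists>" in stripped:
            continue
        if not stripped:
            continue
        values.append(stripped)
    return values


def _unquote(value: str) -> str:
    value = value.strip()
    if value.startswith('"') and value.endswith('"') and len(value) >= 2:
        value = value[1:-1]
    return value.replace('""', '"')


def read_textgrid(
    path,
    tier_name: str,
    *,
    strict: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
) -> WordTier:
    """Read one interval tier of a Praat TextGrid as a :class:`WordTier`.

    Handles the long ("ooTextFile") and short text forms, in UTF-8 or
    UTF-16.  Intervals whose label is empty or whitespace-only are Praat
    silences: they are dropped and counted in ``n_silences``.
    """
    path = Path(path)
    try:
        text = _decode_textgrid(path)
    except (OSError, UnicodeDecodeError) as exc:
        raise TierError(f"cannot read TextGrid {path}: {exc}") from exc
    if "ooTextFile" not in text or "TextGrid" not in text:
        raise TierError(f"{path} does not look like a Praat text TextGrid")

    values = _value_stream(text)
    # header: "ooTextFile", "TextGrid", xmin, xmax, size  (the <exists>
    # flag was removed by the value stream)
    try:
        idx = 2  # skip file type + object class
        float(values[idx]); float(values[idx + 1])
        idx += 2
        n_tiers = int(values[idx]); idx += 1
    except (IndexError, ValueError) as exc:
        raise TierError(f"malformed TextGrid header in {path}") from exc

    tiers: dict[str, tuple[str, int, int]] = {}  # name -> (class, start, n)
    for _ in range(n_tiers):
        tier_class = _unquote(values[idx]); idx += 1
        name = _unquote(values[idx]); idx += 1
        idx += 2  # tier xmin, xmax
        n_items = int(values[idx]); idx += 1
        tiers[name] = (tier_class, idx, n_items)
        idx += n_items * (3 if tier_class == "IntervalTier" else 2)

    if tier_name not in tiers:
        raise TierError(
            f"tier {tier_name!r} not found in {path}; available tiers: "
            f"{sorted(tiers)}"
        )
    tier_class, start, n_items = tiers[tier_name]
    if tier_class != "IntervalTier":
        raise TierError(
            f"tier {tier_name!r} in {path} is a {tier_class}, not an "
            "interval tier (point tiers carry no word durations)"
        )

    intervals: list[WordInterval] = []
    n_silences = 0
    for k in range(n_items):
        xmin = float(values[start + 3 * k])
        xmax = float(values[start + 3 * k + 1])
        label = _unquote(values[start + 3 * k + 2])
        if not label.strip():
            n_silences += 1
            continue
        intervals.append(WordInterval(label.strip(), xmin, xmax))
    intervals.sort(key=lambda iv: iv.onset)
    tier = WordTier(tuple(intervals), source=f"{path}:{tier_name}", n_silences=n_silences)
    log.info("%s: %d words, %d silences dropped", tier.source, len(tier), n_silences)
    return _validated(tier, strict, tolerance)


def write_textgrid(tier: WordTier, path, tier_name: str = "words") -> None:
    """Write a minimal long-form TextGrid with one interval tier.

    Gaps between words are filled with empty (silence) intervals so Praat
    accepts the file; the reader drops them again on the way back in.
    """
    xmin = tier.intervals[0].onset if tier.intervals else 0.0
    xmax = tier.intervals[-1].offset if tier.intervals else 1.0
    cells: list[tuple[float, float, str]] = []
    cursor = xmin
    for iv in tier.intervals:
        if iv.onset > cursor:
            cells.append((cursor, iv.onset, ""))
        cells.append((iv.onset, iv.offset, iv.token))
        cursor = iv.offset
    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        f"xmin = {xmin:.6f}",
        f"xmax = {xmax:.6f}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        f"        xmin = {xmin:.6f}",
        f"        xmax = {xmax:.6f}",
        f"        intervals: size = {len(cells)}",
    ]
    for i, (a, b, label) in enumerate(cells, start=1):
        escaped = label.replace('"', '""')
        lines += [
            f"        intervals [{i}]:",
            f"            xmin = {a:.6f}",
            f"            xmax = {b:.6f}",
            f'            text = "{escaped}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# tabular timestamps

DEFAULT_COLUMNS: Mapping[str, str] = {"word": "word", "onset": "onset", "offset": "offset"}


def read_table(
    path,
    columns: Mapping[str, str] | None = None,
    *,
    sep: str | None = None,
    strict: bool = True,
    tolerance: float = DEFAULT_TOLERANCE,
) -> WordTier:
    """Read word timestamps from a delimited text file (CSV or TSV).

    ``columns`` maps the roles ``word``, ``onset``, ``offset`` to the
    file's column names.  Times must be numeric seconds; the error for a
    bad cell names the offending row.
    """
    path = Path(path)
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [name for name in cols.values() if name not in frame.columns]
    if missing:
        raise TierError(
            f"{path}: missing column(s) {missing}; file has {list(frame.columns)}"
        )
    intervals: list[WordInterval] = []
    n_silences = 0
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(frame.columns, row))
        token = str(record[cols["word"]]).strip()
        if not token:
            n_silences += 1
            continue
        try:
            onset = float(record[cols["onset"]])
            offset = float(record[cols["offset"]])
        except ValueError as exc:
            raise TierError(f"{path} line {row_no}: non-numeric time ({exc})") from exc
        try:
            intervals.append(WordInterval(token, onset, offset))
        except ValueError as exc:
            raise TierError(f"{path} line {row_no}: {exc}") from exc
    tier = WordTier(tuple(intervals), source=str(path), n_silences=n_silences)
    return _validated(tier, strict, tolerance)


def write_table(tier: WordTier, path, *, sep: str | None = None, precision: int = 3) -> None:
    """Write a tier back to CSV/TSV with ``word,onset,offset`` columns."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.DataFrame(
        {
            "word": [iv.token for iv in tier.intervals],
            "onset": [round(iv.onset, precision) for iv in tier.intervals],
            "offset": [round(iv.offset, precision) for iv in tier.intervals],
        }
    )
    frame.to_csv(path, sep=sep, index=False, float_format=f"%.{precision}f")


def tier_from_records(records: Sequence[tuple[str, float, float]], source: str = "") -> WordTier:
    """Build a tier from ``(token, onset, offset)`` triples."""
    return WordTier(tuple(WordInterval(t, a, b) for t, a, b in records), source=source)
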