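"""Per-phrase timestamps, durations, and frequency bands.

Once words carry the tags of all their dominating nodes, every syntactic
phrase inherits temporal references from its words.  Two duration
definitions coexist:

``duration_sum``
    the sum of the durations of the words tagged with the phrase's label
    — inter-word pauses are filtered out;

``duration_span``
    the offset of the last word carrying the tag minus the onset of the
    first — pauses inside the phrase are retained.  The (minOnset,
    maxOffset) pair doubles as the phrase's own timestamps.

Durations convert to the frequency domain as F = 1/T, which is how phrase
timescales become narrow-band filter specifications for speech or M/EEG
envelopes.  Frequency bounds are always computed from unrounded durations
and only rounded for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentTable
from .tree import NodeTag

__all__ = [
    "PhraseRecord",
    "phrase_duration_sum",
    "phrase_span",
    "all_phrases",
    "to_frequency",
    "frequency_band",
    "duration_distribution",
    "phrases_to_frame",
]


@dataclass(frozen=True)
class PhraseRecord:
    """One node's temporal profile: tag, timestamps, both durations."""

    tag: NodeTag
    onset: float
    offset: float
    duration_span: float
    duration_sum: float
    n_words: int

    @property
    def label(self) -> str:
        return self.tag.label

    @property
    def depth(self) -> int:
        return self.tag.depth


def phrase_duration_sum(table: AlignmentTable, tag: "NodeTag | str") -> float:
    """Sum of word durations under ``tag`` (pauses filtered out)."""
    rows = table.rows_for(tag)
    return float(sum(table.rows[i].duration for i in rows))


def phrase_span(table: AlignmentTable, tag: "NodeTag | str") -> tuple[float, float, float]:
    """(minOnset, maxOffset, difference) over the words under ``tag``.

    The pair is the phrase's own onset/offset; the difference is its
    pause-retaining duration.  Because constituents cover contiguous word
    spans, min/max reduce to the first and last row carrying the tag.
    """
    rows = table.rows_for(tag)
    onset = min(table.rows[i].onset for i in rows)
    offset = max(table.rows[i].offset for i in rows)
    return onset, offset, offset - onset


def _classify(table: AlignmentTable) -> tuple[set[NodeTag], set[NodeTag]]:
    """Return (leaf tags, preterminal tags) of the table.

    In any row the deepest cell is the word's own tag and the one above it
    the part-of-speech (preterminal) tag; everything shallower is phrasal.
    A depth-1 sentence tag is always phrasal, even when it directly
    dominates the word (single-word sentence).
    """
    leaves = {row.leaf_tag for row in table.rows}
    preterminals = {row.tags[-2] for row in table.rows if len(row.tags) >= 3}
    return leaves, preterminals - leaves


def all_phrases(
    table: AlignmentTable,
    *,
    include_preterminals: bool = False,
    include_leaves: bool = False,
) -> list[PhraseRecord]:
    """One record per distinct tag, phrasal nodes by default.

    Order is deterministic: by depth, then onset, then position.
    """
    leaves, preterminals = _classify(table)
    records = []
    for tag in table.tags():
        if tag in leaves and not include_leaves:
            continue
        if tag in preterminals and not include_preterminals:
            continue
        onset, offset, span = phrase_span(table, tag)
        records.append(
            PhraseRecord(
                tag=tag,
                onset=onset,
                offset=offset,
                duration_span=span,
                duration_sum=phrase_duration_sum(table, tag),
                n_words=len(table.rows_for(tag)),
            )
        )
    records.sort(key=lambda r: (r.depth, r.onset, r.tag.position))
    return records


def to_frequency(duration: float) -> float:
    """Convert a duration to its frequency-domain twin, F = 1/T (Hz)."""
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return 1.0 / duration


def frequency_band(records: Iterable[PhraseRecord], *, use: str = "span") -> tuple[float, float]:
    """(f_lo, f_hi) in Hz from the longest and shortest phrase durations."""
    durations = _durations(list(records), use)
    return to_frequency(max(durations)), to_frequency(min(durations))


def _durations(records: Sequence[PhraseRecord], use: str) -> list[float]:
    if not records:
        raise ValueError("no phrase records given")
    if use == "span":
        return [r.duration_span for r in records]
    if use == "sum":
        return [r.duration_sum for r in records]
    raise ValueError(f"unknown duration definition {use!r} (want 'span' or 'sum')")


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    min: float
    max: float
    mean: float
    quantiles: tuple[tuple[float, float], ...]  # (probability, value)

    @property
    def median(self) -> float:
        return dict(self.quantiles)[0.5]


def duration_distribution(
    records: Sequence[PhraseRecord],
    *,
    label: str | None = None,
    use: str = "span",
    probs: Sequence[float] = (0.25, 0.5, 0.75),
) -> DistributionSummary:
    """Summary of the phrase-duration distribution (span by default).

    ``label`` restricts to one phrase category ("NP", "VP", ...), the way
    per-label timescales are compared across annotation methods.
    """
    if label is not None:
        records = [r for r in records if r.label == label]
        if not records:
            raise ValueError(f"no phrase records with label {label!r}")
    values = np.asarray(_durations(records, use), dtype=float)
    qs = np.quantile(values, probs)
    return DistributionSummary(
        n=len(values),
        min=float(values.min()),
        max=float(values.max()),
        mean=float(values.mean()),
        quantiles=tuple(zip([float(p) for p in probs], map(float, qs))),
    )


def phrases_to_frame(records: Sequence[PhraseRecord], precision: int | None = 3) -> pd.DataFrame:
    """Tabular view: tag, label, position, depth, times, durations."""
    rnd = (lambda x: round(x, precision)) if precision else (lambda x: x)
    return pd.DataFrame(
        {
            "tag": [r.tag.id for r in records],
            "label": [r.label for r in records],
            "position": [r.tag.id.rpartition("/")[2] for r in records],
            "depth": [r.depth for r in records],
            "onset": [rnd(r.onset) for r in records],
            "offset": [rnd(r.offset) for r in records],
            "duration_span": [rnd(r.duration_span) for r in records],
            "duration_sum": [rnd(r.duration_sum) for r in records],
            "n_words": [r.n_words for r in records],
        }
    )
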