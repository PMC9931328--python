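"""Data model and I/O for acoustic landmark event streams.

A landmark (LM) is a timestamped acoustic event marking an abrupt
articulatory change.  Five landmark kinds are used, each with an onset
(``+``) and offset (``-``) sign:

====  =========================================================
kind  articulatory event
====  =========================================================
g     sustained vocal-fold motion (voicing on / off)
b     frication or burst in an unvoiced segment
s     release / closure of a sonorant consonant (voiced segment)
f     frication in an unvoiced segment
v     frication in a voiced segment
====  =========================================================

One utterance is a :class:`LandmarkStream`: a time-ordered sequence of
:class:`LandmarkEvent` records, each carrying a detector strength on a
0-100 percent scale.  Streams are carried on disk as TSV files with
columns ``time_s``, ``landmark``, ``strength_pct``; a cohort is described
by a CSV manifest with columns ``sample_id``, ``path``, ``label``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Landmark kinds, in canonical order.
KINDS = ("g", "b", "s", "f", "v")
SIGNS = ("+", "-")
#: The ten legal landmark label strings.
LEGAL_LABELS = tuple(f"{s}{k}" for k in KINDS for s in SIGNS)

CLASS_LABELS = ("normal", "disordered")

STREAM_COLUMNS = ("time_s", "landmark", "strength_pct")
MANIFEST_COLUMNS = ("sample_id", "path", "label")


class LandmarkParseError(ValueError):
    """A landmark table or manifest could not be parsed."""


class LandmarkValidationError(ValueError):
    """Parsed data violates a stream or manifest invariant."""


@dataclass(frozen=True, order=True)
class LandmarkLabel:
    """A signed landmark label such as ``+g`` (voicing onset)."""

    sign: str
    kind: str

    def __post_init__(self) -> None:
        if self.sign not in SIGNS or self.kind not in KINDS:
            raise LandmarkValidationError(
                f"illegal landmark label {self.sign!r}{self.kind!r}; "
                f"legal labels are {', '.join(LEGAL_LABELS)}"
            )

    @property
    def text(self) -> str:
        """Canonical text form, sign then kind (``'+g'``)."""
        return f"{self.sign}{self.kind}"

    @classmethod
    def parse(cls, text: str) -> "LandmarkLabel":
        text = text.strip()
        if text not in LEGAL_LABELS:
            raise LandmarkParseError(
                f"malformed landmark label {text!r}; legal labels are "
                f"{', '.join(LEGAL_LABELS)}"
            )
        return cls(sign=text[0], kind=text[1])

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class LandmarkEvent:
    """One detected landmark: time (s), label, strength (percent)."""

    time: float
    label: LandmarkLabel
    strength: float

    def __post_init__(self) -> None:
        if not (self.time >= 0.0 and self.time == self.time):  # NaN-safe
            raise LandmarkValidationError(
                f"event time must be finite and >= 0, got {self.time!r}"
            )
        if not (0.0 <= self.strength <= 100.0):
            raise LandmarkValidationError(
                f"event strength must be in [0, 100], got {self.strength!r}"
            )


@dataclass(frozen=True)
class LandmarkStream:
    """A validated, time-sorted landmark sequence for one utterance."""

    sample_id: str
    events: tuple[LandmarkEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise LandmarkValidationError(
                f"stream {self.sample_id!r}: events not sorted by time"
            )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration(self) -> float:
        """Last minus first event time in seconds; 0 for < 2 events."""
        if len(self.events) < 2:
            return 0.0
        return self.events[-1].time - self.events[0].time

    @classmethod
    def from_events(
        cls, sample_id: str, events: Iterable[LandmarkEvent]
    ) -> "LandmarkStream":
        """Build a stream, sorting out-of-order events with a warning.

        Ties in time keep their input order (stable sort), which fixes the
        tokenization order downstream.
        """
        ev = list(events)
        if any(a.time > b.time for a, b in zip(ev, ev[1:])):
            logger.warning(
                "stream %r: out-of-order timestamps; re-sorting", sample_id
            )
            ev.sort(key=lambda e: e.time)
        return cls(sample_id=sample_id, events=tuple(ev))


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    path: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise LandmarkValidationError(
                f"sample {self.sample_id!r}: unknown class label "
                f"{self.label!r} (expected one of {CLASS_LABELS})"
            )


@dataclass(frozen=True)
class CohortManifest:
    """Maps sample ids to stream files and binary class labels."""

    entries: tuple[ManifestEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.sample_id in seen:
                raise LandmarkValidationError(
                    f"duplicate sample_id {e.sample_id!r} in manifest"
                )
            seen.add(e.sample_id)

    def __len__(self) -> int:
        return len(self.entries)

    def class_counts(self) -> dict[str, int]:
        counts = {lbl: 0 for lbl in CLASS_LABELS}
        for e in self.entries:
            counts[e.label] += 1
        return counts

    def labels(self) -> dict[str, str]:
        return {e.sample_id: e.label for e in self.entries}


# ---------------------------------------------------------------------------
# Stream tables
# ---------------------------------------------------------------------------

def read_landmark_table(path: str | Path) -> LandmarkStream:
    """Read one stream from a TSV file (time_s, landmark, strength_pct).

    The sample id is the file stem.  Rows out of time order are sorted
    (with a logged warning); malformed labels or out-of-range values
    raise, naming the offending line.
    """
    path = Path(path)
    events: list[LandmarkEvent] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(STREAM_COLUMNS):
            raise LandmarkParseError(
                f"{path}: expected header {STREAM_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise LandmarkParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                time = float(row[0])
                strength = float(row[2])
            except ValueError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                label = LandmarkLabel.parse(row[1])
                events.append(
                    LandmarkEvent(time=time, label=label, strength=strength)
                )
            except LandmarkParseError as exc:
                raise LandmarkParseError(f"{path}:{lineno}: {exc}") from exc
            except LandmarkValidationError as exc:
                raise LandmarkValidationError(f"{path}:{lineno}: {exc}") from exc
    return LandmarkStream.from_events(path.stem, events)


def write_landmark_table(stream: LandmarkStream, path: str | Path) -> None:
    """Write a stream as TSV; times and strengths at 6 decimals."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(STREAM_COLUMNS)
        for e in stream.events:
            writer.writerow([f"{e.time:.6f}", e.label.text, f"{e.strength:.6f}"])


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> CohortManifest:
    """Read a cohort manifest CSV (sample_id, path, label)."""
    path = Path(path)
    entries: list[ManifestEntry] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != list(MANIFEST_COLUMNS):
            raise LandmarkParseError(
                f"{path}: expected header {MANIFEST_COLUMNS}, got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise LandmarkParseError(f"{path}:{lineno}: expected 3 columns")
            try:
                entries.append(
                    ManifestEntry(
                        sample_id=row[0].strip(),
                        path=row[1].strip(),
                        label=row[2].strip(),
                    )
                )
            except LandmarkValidationError as exc:
                raise LandmarkValidationError(f"{path}:{lineno}: {exc}") from exc
    manifest = CohortManifest(entries=tuple(entries))
    logger.info(
        "manifest %s: %s", path, ", ".join(
            f"{k}={v}" for k, v in manifest.class_counts().items()
        )
    )
    return manifest


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for e in manifest.entries:
            writer.writerow([e.sample_id, e.path, e.label])


def load_cohort(
    manifest: CohortManifest, root: str | Path = "."
) -> list[LandmarkStream]:
    """Load every stream named by a manifest, relative to *root*."""
    root = Path(root)
    streams = []
    for e in manifest.entries:
        p = Path(e.path)
        stream = read_landmark_table(p if p.is_absolute() else root / p)
        # the manifest's id wins over the file stem
        streams.append(LandmarkStream(sample_id=e.sample_id, events=stream.events))
    return streams
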