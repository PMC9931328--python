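"""Landmark-stream feature engineering.

Twenty feature categories are computed per utterance from the
time-ordered landmark sequence:

* **n-gram counts** (n = 1, 2, 3): sliding-window counts of each
  landmark n-gram type over the single time-merged label sequence
  (overlapping windows, stride 1; n-grams may span silent gaps).
* **durations**: mean duration over all bigram / trigram instances, and
  mean matched onset-offset pair duration per landmark kind.
* **rates**: n-gram instances per second, and speech rate = syllabic
  clusters per second.  Utterance duration is last minus first landmark
  time.
* **syllabic clusters**: maximal ``+g``..``-g`` voiced spans of at least
  30 ms, each bundled with the unvoiced burst/frication events since the
  previous cluster.
* **strengths**: per-type mean strength of each n-gram (an n-gram
  instance's strength is the arithmetic mean of its members'), grand
  means over all bigram / trigram instances, and the mean absolute
  strength change between consecutive landmarks.
* **ratios**: count of each n-gram type divided by the count of each
  unigram type (denominators restricted to unigrams) — the BMI-style
  normalisation intended to absorb within-class individual variation.

A value that is undefined for a sample (absent token, zero denominator,
too few events) is marked NaN; :func:`assemble_features` prunes any
feature that is undefined for *any* cohort sample, along with all-zero
columns, so the resulting table is complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landmark_io import KINDS, CohortManifest, LandmarkLabel, LandmarkStream

__all__ = [
    "NgramToken",
    "SyllabicCluster",
    "FeatureTable",
    "MIN_VOICED_S",
    "tokenize",
    "ngram_counts",
    "ngram_mean_duration",
    "lm_pair_durations",
    "ngram_rate",
    "detect_syllabic_clusters",
    "speech_rate",
    "strength_features",
    "ratio_features",
    "assemble_features",
]

#: Minimum voiced-segment duration for a syllabic cluster (seconds).
MIN_VOICED_S = 0.030

#: Feature categories, their units, and whether values are integer counts.
CATEGORIES: dict[str, tuple[str, bool]] = {
    "count1": ("#", True),
    "count2": ("#", True),
    "count3": ("#", True),
    "dur2": ("s", False),
    "dur3": ("s", False),
    "pairdur": ("s", False),
    "rate1": ("#/s", False),
    "rate2": ("#/s", False),
    "rate3": ("#/s", False),
    "sc_count": ("#", True),
    "speech_rate": ("#/s", False),
    "str1": ("%", False),
    "str2": ("%", False),
    "str3": ("%", False),
    "strchange": ("%", False),
    "strmean2": ("%", False),
    "strmean3": ("%", False),
    "ratio11": ("-", False),
    "ratio21": ("-", False),
    "ratio31": ("-", False),
}

_NAN = float("nan")

#: Human-readable definition per category (feature-dictionary sidecar).
CATEGORY_DEFINITIONS: dict[str, str] = {
    "count1": "number of occurrences of the unigram type",
    "count2": "number of occurrences of the bigram type (overlapping windows)",
    "count3": "number of occurrences of the trigram type (overlapping windows)",
    "dur2": "mean duration over all bigram instances",
    "dur3": "mean duration over all trigram instances",
    "pairdur": "mean matched onset-offset pair duration for the landmark kind",
    "rate1": "unigram instances per second (duration = last - first landmark)",
    "rate2": "bigram instances per second (duration = last - first landmark)",
    "rate3": "trigram instances per second (duration = last - first landmark)",
    "sc_count": "number of syllabic clusters (voiced span >= 30 ms)",
    "speech_rate": "syllabic clusters per second",
    "str1": "mean strength of the unigram type",
    "str2": "mean strength of the bigram type (instance = mean of members)",
    "str3": "mean strength of the trigram type (instance = mean of members)",
    "strchange": "mean absolute strength difference of consecutive landmarks",
    "strmean2": "mean strength over all bigram instances",
    "strmean3": "mean strength over all trigram instances",
    "ratio11": "unigram count divided by unigram count",
    "ratio21": "bigram count divided by unigram count",
    "ratio31": "trigram count divided by unigram count",
}


@dataclass(frozen=True)
class NgramToken:
    """An ordered tuple of 1-3 landmark labels, named by concatenation."""

    labels: tuple[LandmarkLabel, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.labels) <= 3:
            raise ValueError("n-gram order must be 1, 2 or 3")

    @property
    def name(self) -> str:
        return "".join(lbl.text for lbl in self.labels)

    @classmethod
    def parse(cls, name: str) -> "NgramToken":
        if len(name) % 2 != 0:
            raise ValueError(f"malformed n-gram name {name!r}")
        labels = tuple(
            LandmarkLabel.parse(name[i : i + 2]) for i in range(0, len(name), 2)
        )
        return cls(labels=labels)


@dataclass(frozen=True)
class SyllabicCluster:
    """A voiced span of >= 30 ms plus its leading unvoiced events."""

    start: float
    end: float
    events: tuple
    voiced_span: float


def tokenize(stream: LandmarkStream) -> list[str]:
    """Time-ordered label texts, ties broken by input row order."""
    return [e.label.text for e in stream.events]


def ngram_counts(stream: LandmarkStream, n: int) -> dict[str, int]:
    """Overlapping sliding-window n-gram counts (stride 1)."""
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    tokens = tokenize(stream)
    counts: dict[str, int] = {}
    for i in range(len(tokens) - n + 1):
        name = "".join(tokens[i : i + n])
        counts[name] = counts.get(name, 0) + 1
    return counts


def _ngram_instances(stream: LandmarkStream, n: int):
    """Yield (events window) for each n-gram instance."""
    ev = stream.events
    for i in range(len(ev) - n + 1):
        yield ev[i : i + n]


def ngram_mean_duration(stream: LandmarkStream, n: int) -> float:
    """Mean (last - first event time) over all n-gram instances; NaN if none."""
    if n not in (2, 3):
        raise ValueError(f"n must be 2 or 3, got {n}")
    durations = [w[-1].time - w[0].time for w in _ngram_instances(stream, n)]
    return float(np.mean(durations)) if durations else _NAN


def lm_pair_durations(stream: LandmarkStream) -> dict[str, float]:
    """Mean matched onset-offset duration per landmark kind.

    An offset closes the nearest preceding unmatched onset of its kind;
    unmatched onsets are ignored.  Kinds with no matched pair map to NaN.
    """
    open_onsets: dict[str, list[float]] = {k: [] for k in KINDS}
    durations: dict[str, list[float]] = {k: [] for k in KINDS}
    for e in stream.events:
        kind = e.label.kind
        if e.label.sign == "+":
            open_onsets[kind].append(e.time)
        elif open_onsets[kind]:
            durations[kind].append(e.time - open_onsets[kind].pop())
    return {
        k: (float(np.mean(d)) if d else _NAN) for k, d in durations.items()
    }


def ngram_rate(stream: LandmarkStream, n: int) -> float:
    """Total n-gram instances per second of utterance; NaN if degenerate."""
    if n not in (1, 2, 3):
        raise ValueError(f"n must be 1, 2 or 3, got {n}")
    if len(stream) < 2 or stream.duration <= 0:
        return _NAN
    total = max(len(stream) - n + 1, 0)
    return total / stream.duration


def detect_syllabic_clusters(
    stream: LandmarkStream, min_voiced_s: float = MIN_VOICED_S
) -> list[SyllabicCluster]:
    """Group landmarks into syllabic clusters.

    Each maximal ``+g``..``-g`` voiced span with duration >= *min_voiced_s*
    yields one cluster holding all events from the ``+g`` through its
    ``-g`` inclusive, plus any unvoiced burst/frication (b, f) events
    accumulated since the previous cluster's end.  Shorter spans yield
    no cluster (their leading b/f events stay buffered for the next one).
    """
    clusters: list[SyllabicCluster] = []
    ev = stream.events
    buffer: list = []  # pending b/f events outside clusters
    i = 0
    while i < len(ev):
        e = ev[i]
        if e.label.kind in ("b", "f"):
            buffer.append(e)
            i += 1
            continue
        if e.label.text == "+g":
            j = i + 1
            while j < len(ev) and ev[j].label.text != "-g":
                j += 1
            if j < len(ev):
                span = ev[j].time - e.time
                if span >= min_voiced_s:
                    members = tuple(buffer) + tuple(ev[i : j + 1])
                    clusters.append(
                        SyllabicCluster(
                            start=members[0].time,
                            end=ev[j].time,
                            events=members,
                            voiced_span=span,
                        )
                    )
                    buffer = []
                i = j + 1
                continue
        i += 1
    return clusters


def speech_rate(
    stream: LandmarkStream, min_voiced_s: float = MIN_VOICED_S
) -> float:
    """Syllabic clusters per second of utterance; NaN for zero duration."""
    if len(stream) < 2 or stream.duration <= 0:
        return _NAN
    return len(detect_syllabic_clusters(stream, min_voiced_s)) / stream.duration


def strength_features(stream: LandmarkStream) -> dict[str, float]:
    """Strength-based features, keyed ``<category>:<token-or-all>``.

    Per-type mean strengths for every unigram/bigram/trigram present in
    the stream (an n-gram instance's strength is the mean of its member
    strengths), grand means over all bigram / trigram instances, and the
    mean absolute strength difference between consecutive landmarks.
    Absent quantities are simply missing from the map (NaN at assembly).
    """
    out: dict[str, float] = {}
    by_type: dict[str, list[float]] = {}
    for e in stream.events:
        by_type.setdefault(f"str1:{e.label.text}", []).append(e.strength)
    for n, cat in ((2, "str2"), (3, "str3")):
        for window in _ngram_instances(stream, n):
            name = "".join(e.label.text for e in window)
            inst = float(np.mean([e.strength for e in window]))
            by_type.setdefault(f"{cat}:{name}", []).append(inst)
    for key, vals in by_type.items():
        out[key] = float(np.mean(vals))
    for n, cat in ((2, "strmean2"), (3, "strmean3")):
        insts = [
            float(np.mean([e.strength for e in w]))
            for w in _ngram_instances(stream, n)
        ]
        if insts:
            out[f"{cat}:all"] = float(np.mean(insts))
    strengths = [e.strength for e in stream.events]
    if len(strengths) >= 2:
        out["strchange:all"] = float(np.mean(np.abs(np.diff(strengths))))
    return out


def ratio_features(
    counts1: Mapping[str, int],
    counts2: Mapping[str, int],
    counts3: Mapping[str, int],
) -> dict[str, float]:
    """n-gram-count / unigram-count ratios, named ``<num>/<den>``.

    Every (numerator token, denominator unigram) pair over the tokens in
    the supplied maps is emitted; a zero denominator yields NaN for all
    its ratios (the undefined-feature marker).
    """
    out: dict[str, float] = {}
    denominators = sorted(counts1)
    for cat, counts in (("ratio11", counts1), ("ratio21", counts2), ("ratio31", counts3)):
        for num in sorted(counts):
            for den in denominators:
                d = counts1[den]
                value = counts[num] / d if d > 0 else _NAN
                out[f"{cat}:{num}/{den}"] = value
    return out


@dataclass
class FeatureTable:
    """A samples x features matrix with per-feature category and unit.

    ``values`` is a DataFrame indexed by sample_id; ``categories`` maps
    each feature name to its category tag (see :data:`CATEGORIES`).
    """

    values: pd.DataFrame
    categories: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def integer_mask(self) -> np.ndarray:
        """Boolean mask over columns: True for integer count features."""
        return np.array(
            [CATEGORIES[self.categories[c]][1] for c in self.values.columns]
        )

    def units(self) -> dict[str, str]:
        return {c: CATEGORIES[self.categories[c]][0] for c in self.values.columns}

    def select(self, names: Sequence[str]) -> "FeatureTable":
        return FeatureTable(
            values=self.values[list(names)].copy(),
            categories={n: self.categories[n] for n in names},
        )

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="sample_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="sample_id")
        cats = {c: c.split(":", 1)[0] for c in df.columns}
        unknown = sorted(set(cats.values()) - set(CATEGORIES))
        if unknown:
            raise ValueError(f"unknown feature categories in CSV: {unknown}")
        return cls(values=df, categories=cats)

    def feature_dictionary(self) -> list[dict[str, str]]:
        """Name/category/unit records, for the featurize CLI's JSON sidecar."""
        return [
            {
                "name": name,
                "category": self.categories[name],
                "unit": CATEGORIES[self.categories[name]][0],
                "definition": CATEGORY_DEFINITIONS[self.categories[name]],
            }
            for name in self.values.columns
        ]

    def write_dictionary(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.feature_dictionary(), indent=1))


def _sample_features(
    stream: LandmarkStream, alphabet: dict[int, list[str]]
) -> dict[str, float]:
    """All per-sample feature values over a fixed cohort alphabet."""
    counts = {n: ngram_counts(stream, n) for n in (1, 2, 3)}
    row: dict[str, float] = {}
    for n in (1, 2, 3):
        for token in alphabet[n]:
            row[f"count{n}:{token}"] = counts[n].get(token, 0)
    row["dur2:all"] = ngram_mean_duration(stream, 2)
    row["dur3:all"] = ngram_mean_duration(stream, 3)
    for kind, value in lm_pair_durations(stream).items():
        row[f"pairdur:{kind}"] = value
    for n in (1, 2, 3):
        row[f"rate{n}:all"] = ngram_rate(stream, n)
    row["sc_count:all"] = len(detect_syllabic_clusters(stream))
    row["speech_rate:all"] = speech_rate(stream)
    strengths = strength_features(stream)
    for n, cat in ((1, "str1"), (2, "str2"), (3, "str3")):
        for token in alphabet[n]:
            row[f"{cat}:{token}"] = strengths.get(f"{cat}:{token}", _NAN)
    for key in ("strchange:all", "strmean2:all", "strmean3:all"):
        row[key] = strengths.get(key, _NAN)
    full_counts = {
        n: {t: counts[n].get(t, 0) for t in alphabet[n]} for n in (1, 2, 3)
    }
    row.update(ratio_features(full_counts[1], full_counts[2], full_counts[3]))
    return row


def cohort_alphabet(streams: Sequence[LandmarkStream]) -> dict[int, list[str]]:
    """Tokens of each order observed in at least one stream, sorted."""
    alphabet: dict[int, set[str]] = {1: set(), 2: set(), 3: set()}
    for s in streams:
        for n in (1, 2, 3):
            alphabet[n].update(ngram_counts(s, n))
    return {n: sorted(v) for n, v in alphabet.items()}


def compute_features(
    stream: LandmarkStream, alphabet: dict[int, list[str]]
) -> dict[str, float]:
    """Public per-sample feature computation over a fixed alphabet."""
    return _sample_features(stream, alphabet)


def assemble_features(
    streams: Sequence[LandmarkStream],
    manifest: CohortManifest | None = None,
) -> FeatureTable:
    """Build the pruned cohort feature table.

    The feature universe is the union of all families over the cohort
    alphabet (tokens observed in >= 1 sample).  Pruning then removes
    (a) features undefined (NaN) in any sample — absent-token strengths,
    zero-denominator ratios, zero-duration rates; (b) all-zero columns;
    (c) duplicate names.  The returned matrix is complete and finite.
    """
    if len(streams) == 0:
        raise ValueError("cannot assemble features for an empty cohort")
    if manifest is not None:
        by_id = {s.sample_id: s for s in streams}
        streams = [by_id[e.sample_id] for e in manifest.entries]
    alphabet = cohort_alphabet(streams)
    rows = [_sample_features(s, alphabet) for s in streams]
    df = pd.DataFrame(rows, index=[s.sample_id for s in streams])
    # (c) duplicate names cannot arise from the dict rows, but guard anyway
    df = df.loc[:, ~df.columns.duplicated()]
    # (a) undefined anywhere -> drop cohort-wide
    df = df.dropna(axis=1, how="any")
    # (b) all-zero columns carry no information
    df = df.loc[:, (df != 0).any(axis=0)]
    categories = {c: c.split(":", 1)[0] for c in df.columns}
    return FeatureTable(values=df, categories=categories)
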