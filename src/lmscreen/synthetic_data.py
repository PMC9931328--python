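"""Synthetic landmark-stream generator for two speaker classes.

The generator emulates the structure that the downstream feature
inventory assumes for short single-word utterances: an utterance is a
sequence of *syllabic units*, each a voiced core bounded by a ``+g``
(voicing onset) and ``-g`` (voicing offset).  Unvoiced consonantal
events — burst (``b``) and unvoiced-frication (``f``) onset/offset pairs
— occur only in the silent gaps between voiced cores; sonorant (``s``)
and voiced-frication (``v``) pairs occur only inside them.  Every onset
is eventually closed by a matching offset of the same kind before the
next onset of that kind, so matched-pair duration features are always
well defined on generated data.

Class differences (normal vs. disordered) are injected through three
channels — event-pattern probabilities, voiced-segment durations, and
landmark strengths — all scaled by a single separation parameter
``delta``.  At ``delta = 0`` the two class-conditional distributions are
identical, which gives a null cohort for calibration tests; large
``delta`` gives a strongly separable cohort.

The defaults model a preschool child producing a one-to-three-syllable
word: voiced cores around 150 ms (normal), consonant pairs present in
roughly half the units, strengths around 70 %.  The disordered offsets
shorten voicing (-40 ms/unit at delta = 1, pushing cores toward the
30 ms syllabic-cluster threshold), thin out consonant pairs (-0.15 on
each probability) and weaken strengths (-8 points) — the direction of
effect the screening method presupposes, with magnitudes chosen so that
delta ~ 2 yields near-separable classes at cohort size 39/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .landmark_io import (
    CLASS_LABELS,
    CohortManifest,
    LandmarkEvent,
    LandmarkLabel,
    LandmarkStream,
    ManifestEntry,
    write_landmark_table,
    write_manifest,
)

__all__ = [
    "ClassParams",
    "GeneratorConfig",
    "generate_stream",
    "generate_dataset",
    "write_dataset",
]

_MIN_VOICED_S = 0.005  # floor keeping -g strictly after +g

#: Separation at which the disordered voiced-duration mean reaches the
#: 30 ms syllabic-cluster threshold (150 ms - 3 * 40 ms/unit): the
#: generator's "strongly separated" study condition.
HIGH_SEPARATION = 3.0


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional generator parameters (times in ms, strengths in %)."""

    voiced_duration_mean_ms: float = 150.0
    voiced_duration_sd_ms: float = 40.0
    p_burst: float = 0.7
    p_frication: float = 0.5
    p_sonorant: float = 0.5
    p_voiced_frication: float = 0.4
    strength_mean: float = 70.0
    strength_sd: float = 12.0

    def validate(self) -> None:
        for name in ("p_burst", "p_frication", "p_sonorant", "p_voiced_frication"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.voiced_duration_mean_ms <= 0:
            raise ValueError("voiced_duration_mean_ms must be > 0")


# Additive offsets applied to the disordered class, per unit of separation.
_DISORDERED_OFFSETS = {
    "voiced_duration_mean_ms": -40.0,
    "p_burst": -0.15,
    "p_frication": -0.15,
    "p_sonorant": -0.15,
    "p_voiced_frication": -0.15,
    "strength_mean": -8.0,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-cohort configuration.

    ``separation`` (delta >= 0) scales every between-class offset; the
    disordered class parameters are ``normal + separation * offset``,
    with probabilities clipped to [0, 1] and the voiced-duration mean
    floored just above zero.  ``separation = 0`` makes both classes
    draw from the identical distribution.
    """

    n_syllables_range: tuple[int, int] = (1, 3)
    gap_ms_range: tuple[float, float] = (50.0, 300.0)
    normal: ClassParams = field(default_factory=ClassParams)
    disordered_offsets: dict[str, float] = field(
        default_factory=lambda: dict(_DISORDERED_OFFSETS)
    )
    separation: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.n_syllables_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid n_syllables_range {self.n_syllables_range}")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        self.normal.validate()
        self.class_params("disordered").validate()

    def class_params(self, class_label: str) -> ClassParams:
        """Effective parameters for one class at this separation."""
        if class_label == "normal" or self.separation == 0.0:
            return self.normal
        if class_label != "disordered":
            raise ValueError(f"unknown class label {class_label!r}")
        values = asdict(self.normal)
        for name, off in self.disordered_offsets.items():
            values[name] = values[name] + self.separation * off
        for name in ("p_burst", "p_frication", "p_sonorant", "p_voiced_frication"):
            values[name] = float(np.clip(values[name], 0.0, 1.0))
        values["voiced_duration_mean_ms"] = max(
            values["voiced_duration_mean_ms"], 1.0
        )
        return ClassParams(**values)

    def with_separation(self, separation: float) -> "GeneratorConfig":
        return replace(self, separation=separation)


def _strength(rng: np.random.Generator, params: ClassParams) -> float:
    return float(
        np.clip(rng.normal(params.strength_mean, params.strength_sd), 0.0, 100.0)
    )


def _pair_times(
    rng: np.random.Generator, start: float, duration: float
) -> tuple[float, float]:
    """Two strictly ordered interior times within (start, start+duration)."""
    f = np.sort(rng.uniform(0.05, 0.95, size=2))
    while f[1] - f[0] < 1e-3:
        f = np.sort(rng.uniform(0.05, 0.95, size=2))
    return start + f[0] * duration, start + f[1] * duration


def generate_stream(
    class_label: str,
    config: GeneratorConfig,
    seed: int | np.random.SeedSequence,
    sample_id: str = "synthetic",
) -> LandmarkStream:
    """Generate one grammar-valid landmark stream for a class.

    Deterministic in (class_label, config, seed).  The stream obeys the
    pairing grammar and the voiced/unvoiced placement rules described in
    the module docstring, with strictly increasing timestamps.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    config.validate()
    rng = np.random.default_rng(seed)
    params = config.class_params(class_label)

    lo, hi = config.n_syllables_range
    n_units = int(rng.integers(lo, hi + 1))
    gap_lo, gap_hi = config.gap_ms_range

    events: list[LandmarkEvent] = []

    def emit(time_s: float, label: str) -> None:
        events.append(
            LandmarkEvent(
                time=time_s,
                label=LandmarkLabel.parse(label),
                strength=_strength(rng, params),
            )
        )

    t = 0.0
    for _ in range(n_units):
        # silent gap before the voiced core; unvoiced b/f pairs live here
        t += rng.uniform(gap_lo, gap_hi) / 1000.0
        if rng.random() < params.p_burst:
            on, off = t, t + rng.uniform(15.0, 80.0) / 1000.0
            emit(on, "+b")
            emit(off, "-b")
            t = off + rng.uniform(10.0, 40.0) / 1000.0
        if rng.random() < params.p_frication:
            on, off = t, t + rng.uniform(20.0, 100.0) / 1000.0
            emit(on, "+f")
            emit(off, "-f")
            t = off + rng.uniform(10.0, 40.0) / 1000.0

        # voiced core bounded by +g ... -g
        voiced = max(
            rng.normal(params.voiced_duration_mean_ms, params.voiced_duration_sd_ms)
            / 1000.0,
            _MIN_VOICED_S,
        )
        emit(t, "+g")
        interior: list[tuple[float, str]] = []
        if rng.random() < params.p_sonorant:
            a, b = _pair_times(rng, t, voiced)
            interior += [(a, "+s"), (b, "-s")]
        if rng.random() < params.p_voiced_frication:
            a, b = _pair_times(rng, t, voiced)
            interior += [(a, "+v"), (b, "-v")]
        for time_s, label in sorted(interior):
            emit(time_s, label)
        t += voiced
        emit(t, "-g")

    # enforce strictly increasing times (interior draws may collide)
    out: list[LandmarkEvent] = []
    last = -1.0
    for e in sorted(events, key=lambda e: e.time):
        time_s = e.time if e.time > last else last + 1e-6
        out.append(LandmarkEvent(time=time_s, label=e.label, strength=e.strength))
        last = time_s
    return LandmarkStream(sample_id=sample_id, events=tuple(out))


def generate_dataset(
    n_normal: int,
    n_disordered: int,
    config: GeneratorConfig,
) -> tuple[list[LandmarkStream], CohortManifest]:
    """Generate a cohort of streams plus its manifest.

    Reproducible: the same (arguments, config.seed) yields bit-identical
    streams.  Per-stream seeds are spawned from the config seed with a
    counter-based derivation so streams are mutually independent.
    """
    if n_normal < 0 or n_disordered < 0:
        raise ValueError("cohort sizes must be >= 0")
    config.validate()
    root = np.random.SeedSequence(config.seed)
    streams: list[LandmarkStream] = []
    entries: list[ManifestEntry] = []
    specs = [("normal", i) for i in range(n_normal)]
    specs += [("disordered", i) for i in range(n_disordered)]
    for counter, (label, i) in enumerate(specs):
        sid = f"{label}_{i:03d}"
        child = np.random.SeedSequence(config.seed, spawn_key=(counter,))
        streams.append(generate_stream(label, config, child, sample_id=sid))
        entries.append(ManifestEntry(sample_id=sid, path=f"{sid}.tsv", label=label))
    return streams, CohortManifest(entries=tuple(entries))


def write_dataset(
    streams: list[LandmarkStream],
    manifest: CohortManifest,
    out_dir: str | Path,
) -> Path:
    """Write stream TSVs and the manifest CSV into *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.sample_id: s for s in streams}
    for e in manifest.entries:
        write_landmark_table(by_id[e.sample_id], out_dir / e.path)
    manifest_path = out_dir / "manifest.csv"
    write_manifest(manifest, manifest_path)
    return manifest_path
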