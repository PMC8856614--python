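"""Synthetic cohorts, volumes and traces with carried ground truth.

Every analysis stage in the package has a matching generator here so the
full pipeline can be exercised without any imaging or behavioral raw data:

- Bernoulli innervation cohorts with a "paper-like" frequency preset
  (6 glomeruli always innervated, 3 near-always at 0.97, 9 variable in
  [0.10, 0.84], remainder never) and optional per-group overrides for
  planting dimorphic frequencies. The preset approximates the published
  frequency structure; it is not a fit to any supplementary table.
- Paired left/right cohorts with a tunable concordance: the right profile
  copies each left entry with probability ``pair_concordance`` and
  otherwise redraws from the marginal, so concordance 1 gives mirror-
  symmetric brains and concordance 0 gives independent hemispheres.
- Ellipsoidal glomerulus phantoms on a voxel grid: intensity = uniform
  lobe background + per-glomerulus true density, plus optional Poisson or
  Gaussian noise; the reference glomerulus (DM5) has true density 0.
- Capacitance traces: baseline + linear drift + rectangular feeding bouts
  (length >= 5 samples, supra-threshold amplitude) + brief sub-run
  artifacts + Gaussian noise. Rectangular bouts suffice because the
  detector is purely threshold/run-length based.

All generators are bit-reproducible under a fixed seed and return a truth
record sufficient to recompute every downstream expectation.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .density import LabeledVolume
from .flic import DEFAULT_MIN_RUN, DEFAULT_THRESHOLD, FlicTrace, \
    SAMPLING_INTERVAL_S
from .glomeruli import GlomerulusMap, default_map
from .profiles import METADATA_COLUMNS, ProfileCollection

ALWAYS_GLOMERULI = ("DA1", "VA1d", "VA1v", "DA4m", "DL3", "DL4")
HIGH_GLOMERULI = ("D", "DM6", "DC3")
VARIABLE_GLOMERULI = ("VL2a", "DL1", "DA3", "DC2", "DL5", "DM1", "VA2",
                      "VC1", "VM2")


def paper_like_frequencies(map: GlomerulusMap | None = None
                           ) -> dict[str, float]:
    """Default per-glomerulus Bernoulli frequencies.

    6 glomeruli at 1.0, 3 at 0.97, 9 spread evenly over [0.10, 0.84]
    (deterministic preset), all others 0.
    """
    map = map or default_map()
    freqs = {name: 0.0 for name in map.names}
    for name in ALWAYS_GLOMERULI:
        freqs[name] = 1.0
    for name in HIGH_GLOMERULI:
        freqs[name] = 0.97
    for name, p in zip(VARIABLE_GLOMERULI,
                       np.linspace(0.10, 0.84, len(VARIABLE_GLOMERULI))):
        freqs[name] = float(p)
    return freqs


@dataclass
class GroupSpec:
    """One cohort stratum with optional frequency overrides."""

    n: int
    sex: str = "female"
    mating_status: str = "unknown"
    condition: str = ""
    overrides: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.sex}/{self.mating_status}"


@dataclass
class CohortSpec:
    """Parameters for innervation-cohort generation."""

    n_profiles: int = 100
    frequencies: Mapping[str, float] | None = None
    groups: list[GroupSpec] = field(default_factory=list)
    pair_concordance: float = 1.0
    n_left_only: int = 0
    seed: int = 0
    map: GlomerulusMap = field(default_factory=default_map)

    def freq_vector(self, overrides: Mapping[str, float] | None = None
                    ) -> np.ndarray:
        freqs = dict(self.frequencies or paper_like_frequencies(self.map))
        freqs.update(overrides or {})
        unknown = set(freqs) - set(self.map.names)
        if unknown:
            raise ValueError(f"frequencies for unknown glomeruli: {unknown}")
        vec = np.array([freqs.get(name, 0.0) for name in self.map.names])
        if ((vec < 0) | (vec > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")
        return vec


@dataclass
class CohortTruth:
    """Generating frequencies per group, aligned to the map."""

    frequencies: pd.DataFrame  # columns: group_label, glomerulus, frequency
    pair_concordance: float | None
    seed: int


def _meta_row(brain_id: str, hemisphere: str, group: GroupSpec) -> dict:
    return {"brain_id": brain_id, "hemisphere": hemisphere,
            "sex": group.sex, "mating_status": group.mating_status,
            "genotype": "synthetic", "condition": group.condition}


def gen_profiles(spec: CohortSpec) -> tuple[ProfileCollection, CohortTruth]:
    """Independent Bernoulli innervation draws, one brain per profile.

    With ``spec.groups`` set, each group draws its own ``n`` profiles at
    the base frequencies updated by the group's overrides; otherwise a
    single unlabeled group of ``n_profiles`` is drawn.
    """
    rng = np.random.default_rng(spec.seed)
    groups = spec.groups or [GroupSpec(n=spec.n_profiles)]
    meta_rows, blocks, truth_rows = [], [], []
    counter = 0
    for g, group in enumerate(groups):
        p = spec.freq_vector(group.overrides)
        blocks.append((rng.random((group.n, p.size)) < p).astype(np.uint8))
        for _ in range(group.n):
            meta_rows.append(_meta_row(f"b{counter:05d}", "R", group))
            counter += 1
        truth_rows.append(pd.DataFrame({
            "group_label": group.label,
            "glomerulus": list(spec.map.names), "frequency": p}))
    coll = ProfileCollection(spec.map, pd.DataFrame(meta_rows),
                             np.concatenate(blocks))
    truth = CohortTruth(frequencies=pd.concat(truth_rows,
                                              ignore_index=True),
                        pair_concordance=None, seed=spec.seed)
    return coll, truth


def gen_paired_cohort(spec: CohortSpec
                      ) -> tuple[ProfileCollection, CohortTruth]:
    """Paired left/right cohort of ``n_profiles`` brains.

    Each brain's left profile is an independent Bernoulli draw; the right
    profile copies each left entry with probability ``pair_concordance``
    and otherwise redraws from the marginal frequency. ``n_left_only``
    additional brains carry only a left profile (so random-pairing cohorts
    have more lefts than rights, as in real collections where one
    hemisphere's label fails).
    """
    c = spec.pair_concordance
    if not 0.0 <= c <= 1.0:
        raise ValueError("pair_concordance must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    group = spec.groups[0] if spec.groups else GroupSpec(n=spec.n_profiles)
    p = spec.freq_vector(group.overrides)
    n, extra = spec.n_profiles, spec.n_left_only
    left = (rng.random((n + extra, p.size)) < p).astype(np.uint8)
    copy = rng.random((n, p.size)) < c
    redraw = (rng.random((n, p.size)) < p).astype(np.uint8)
    right = np.where(copy, left[:n], redraw).astype(np.uint8)
    meta_rows, blocks = [], []
    for i in range(n + extra):
        meta_rows.append(_meta_row(f"b{i:05d}", "L", group))
        blocks.append(left[i])
        if i < n:
            meta_rows.append(_meta_row(f"b{i:05d}", "R", group))
            blocks.append(right[i])
    coll = ProfileCollection(spec.map, pd.DataFrame(meta_rows),
                             np.stack(blocks))
    truth = CohortTruth(
        frequencies=pd.DataFrame({"group_label": group.label,
                                  "glomerulus": list(spec.map.names),
                                  "frequency": p}),
        pair_concordance=c, seed=spec.seed)
    return coll, truth


DEFAULT_LAYOUT: dict[str, tuple[tuple[int, int, int],
                                tuple[int, int, int]]] = {
    # name: (center (z, y, x), radii (z, y, x))
    "DA1": ((10, 14, 14), (6, 9, 9)),
    "VA1d": ((10, 14, 44), (6, 9, 9)),
    "VA1v": ((10, 44, 14), (6, 9, 9)),
    "VL2a": ((10, 44, 44), (5, 7, 7)),
    "DL1": ((10, 30, 62), (4, 6, 6)),
    "DM5": ((10, 62, 30), (4, 6, 6)),
}


@dataclass
class VolumeSpec:
    """Parameters for the glomerular-volume phantom."""

    shape: tuple[int, int, int] = (21, 76, 76)
    layout: Mapping[str, tuple[tuple[int, int, int],
                               tuple[int, int, int]]] = \
        field(default_factory=lambda: dict(DEFAULT_LAYOUT))
    densities: Mapping[str, float] = field(default_factory=lambda: {
        "DA1": 30.0, "VA1d": 30.0, "VA1v": 30.0, "VL2a": 10.0,
        "DL1": 5.0, "DM5": 0.0})
    background: float = 20.0
    noise: str = "none"  # none | gaussian | poisson
    noise_scale: float = 0.0
    seed: int = 0


@dataclass
class VolumeTruth:
    densities: dict[str, float]
    background: float
    seed: int


def _ellipsoid(shape: tuple[int, int, int], center: Sequence[int],
               radii: Sequence[int]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def gen_glomerular_volume(spec: VolumeSpec
                          ) -> tuple[LabeledVolume, VolumeTruth]:
    """Phantom lobe: ellipsoidal glomeruli with known densities on a
    uniform background, exact masks, optional noise. Overlapping
    ellipsoids are rejected (mask disjointness is a load invariant)."""
    masks = {name: _ellipsoid(spec.shape, center, radii)
             for name, (center, radii) in spec.layout.items()}
    intensity = np.full(spec.shape, spec.background, dtype=float)
    densities = dict(spec.densities)
    for name, mask in masks.items():
        intensity[mask] += densities.get(name, 0.0)
    rng = np.random.default_rng(spec.seed)
    if spec.noise == "poisson":
        intensity = rng.poisson(intensity).astype(float)
    elif spec.noise == "gaussian":
        intensity = np.clip(
            intensity + rng.normal(0.0, spec.noise_scale, spec.shape), 0,
            None)
    elif spec.noise != "none":
        raise ValueError(f"unknown noise model {spec.noise!r}")
    volume = LabeledVolume(intensity=intensity, masks=masks)
    return volume, VolumeTruth(densities=densities,
                               background=spec.background, seed=spec.seed)


@dataclass
class TraceSpec:
    """Parameters for capacitance-trace generation.

    Explicit schedules are lists of ``(start_index, length, amplitude)``;
    when ``None``, ``n_events``/``n_artifacts`` items are placed uniformly
    at random with a minimum gap. Event lengths must be >= the detector's
    default minimum run; artifact lengths must be below it.
    """

    duration_s: float = 86400.0
    sampling_interval_s: float = SAMPLING_INTERVAL_S
    baseline: float = 100.0
    drift_per_hour: float = 0.0
    events: list[tuple[int, int, float]] | None = None
    n_events: int = 20
    event_length: int = 10
    event_amplitude: float = 2 * DEFAULT_THRESHOLD
    artifacts: list[tuple[int, int, float]] | None = None
    n_artifacts: int = 10
    artifact_length: int = DEFAULT_MIN_RUN - 1
    artifact_amplitude: float = 4 * DEFAULT_THRESHOLD
    noise_sd: float = 0.0
    min_gap: int = 50
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.sampling_interval_s))


@dataclass
class TraceTruth:
    events: list[tuple[int, int, float]]
    artifacts: list[tuple[int, int, float]]
    baseline: float
    seed: int


def _schedule(rng: np.random.Generator, n_items: int, length: int,
              amplitude: float, n_samples: int, occupied: list[tuple],
              min_gap: int) -> list[tuple[int, int, float]]:
    items: list[tuple[int, int, float]] = []
    margin = min_gap
    for _ in range(10000):
        if len(items) >= n_items:
            break
        start = int(rng.integers(margin, n_samples - length - margin))
        clash = any(start < s + l + min_gap and s < start + length + min_gap
                    for s, l, _ in occupied + items)
        if not clash:
            items.append((start, length, amplitude))
    if len(items) < n_items:
        raise ValueError("could not schedule items without overlap; "
                         "reduce counts or lengths")
    return sorted(items)


def _validate_schedule(items: Sequence[tuple[int, int, float]],
                       n_samples: int) -> None:
    prev_stop = -1
    for start, length, _ in sorted(items):
        if start < 0 or start + length > n_samples or length < 1:
            raise ValueError(f"scheduled item ({start}, {length}) outside "
                             "trace")
        if start <= prev_stop:
            raise ValueError("scheduled items overlap")
        prev_stop = start + length


def gen_flic_trace(spec: TraceSpec, fly_id: str = "fly0",
                   condition: str = "L-D", mating_status: str = "unknown",
                   vl2a_innervated: bool | None = None
                   ) -> tuple[FlicTrace, TraceTruth]:
    """Baseline + drift + rectangular bouts + artifacts + Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    if spec.events is not None:
        events = sorted(tuple(e) for e in spec.events)
    else:
        events = _schedule(rng, spec.n_events, spec.event_length,
                           spec.event_amplitude, n, [], spec.min_gap)
    if spec.artifacts is not None:
        artifacts = sorted(tuple(a) for a in spec.artifacts)
    else:
        artifacts = _schedule(rng, spec.n_artifacts, spec.artifact_length,
                              spec.artifact_amplitude, n, list(events),
                              spec.min_gap)
    _validate_schedule(list(events) + list(artifacts), n)
    t_hours = np.arange(n) * spec.sampling_interval_s / 3600.0
    samples = spec.baseline + spec.drift_per_hour * t_hours
    for start, length, amplitude in list(events) + list(artifacts):
        samples[start:start + length] += amplitude
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0.0, spec.noise_sd, n)
    trace = FlicTrace(fly_id=fly_id, samples=samples,
                      sampling_interval_s=spec.sampling_interval_s,
                      condition=condition, mating_status=mating_status,
                      vl2a_innervated=vl2a_innervated)
    return trace, TraceTruth(events=[tuple(e) for e in events],
                             artifacts=[tuple(a) for a in artifacts],
                             baseline=spec.baseline, seed=spec.seed)
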