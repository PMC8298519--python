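"""Seeded generator of task- and experience-conditioned force segments.

The generator stands in for clinical recordings: each (task, experience)
cell draws segment durations and force ranges from log-normal distributions
moment-matched to the published per-task summary statistics, shapes the
segment with a task-specific motif (so task recognition is learnable), and
injects experience effects through the noise scale and a peak multiplier
(novices show higher within-segment variability and higher peaks, not
different means).

Default per-task conditions (mean (SD)):

=============  ================  ==============  =================
task           duration (s)      range (N)       segments (E/N)
=============  ================  ==============  =================
Coagulation    12.1 (7.2)        0.7 (0.5)       1108 / 977
Pulling        7.6 (5.3)         1.0 (0.6)       192 / 111
Manipulation   5.4 (2.5)         1.2 (0.5)       210 / 86
Dissecting     10.1 (8.6)        0.9 (0.5)       64 / 25
Retracting     7.6 (5.1)         0.7 (0.4)       71 / 51
=============  ================  ==============  =================

Experience effect: the novice force-range (peak) scale is multiplied by
0.39/0.35 and the additive noise SD is raised from 0.05 N to 0.065 N,
targeting the published expert-vs-novice contrast in within-segment SD
(0.23 vs 0.27 N) and peak force (0.35 vs 0.39 N).

Everything is deterministic under a seed: each cell consumes an independent
child of one ``SeedSequence`` in a fixed order, so regeneration is bitwise
identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .catalog import EXPERIENCE_LEVELS, TASKS
from .errors import ParameterError
from .segment_io import ForceSegment, SegmentTable

#: published per-task segment counts (Expert, Novice)
SEGMENT_COUNTS: dict[str, tuple[int, int]] = {
    "Coagulation": (1108, 977),
    "Pulling": (192, 111),
    "Manipulation": (210, 86),
    "Dissecting": (64, 25),
    "Retracting": (71, 51),
}

#: published per-task duration mean/SD in seconds
DURATION_STATS: dict[str, tuple[float, float]] = {
    "Coagulation": (12.1, 7.2),
    "Pulling": (7.6, 5.3),
    "Manipulation": (5.4, 2.5),
    "Dissecting": (10.1, 8.6),
    "Retracting": (7.6, 5.1),
}

#: published per-task force-range mean/SD in Newtons
RANGE_STATS: dict[str, tuple[float, float]] = {
    "Coagulation": (0.7, 0.5),
    "Pulling": (1.0, 0.6),
    "Manipulation": (1.2, 0.5),
    "Dissecting": (0.9, 0.5),
    "Retracting": (0.7, 0.4),
}

#: task -> motif shaping the within-segment force profile
TASK_MOTIFS: dict[str, str] = {
    "Coagulation": "sustained_plateau",
    "Retracting": "grasp_hold",
    "Manipulation": "oscillatory",
    "Pulling": "ramp_pull",
    "Dissecting": "burst_train",
}

#: expert/novice peak multipliers (published peak means 0.35 vs 0.39 N)
PEAK_SCALE: dict[str, float] = {"Expert": 1.0, "Novice": 0.39 / 0.35}
#: expert/novice additive noise SD in Newtons
NOISE_SD: dict[str, float] = {"Expert": 0.05, "Novice": 0.065}

DEFAULT_SAMPLING_RATE = 100.0
MIN_DURATION = 0.5  # seconds; keeps every segment long enough for all features


@dataclass(frozen=True)
class TaskProfileSpec:
    """Generating conditions for one (task, experience) cell."""

    task: str
    experience: str
    duration_mean: float
    duration_sd: float
    range_mean: float
    range_sd: float
    baseline_force: float
    motif: str
    noise_sd: float
    n_segments: int

    def __post_init__(self) -> None:
        if self.duration_mean <= 0 or self.range_mean <= 0:
            raise ParameterError("duration/range means must be positive")
        if self.duration_sd < 0 or self.range_sd < 0 or self.noise_sd < 0:
            raise ParameterError("SDs must be non-negative")
        if self.n_segments < 0:
            raise ParameterError("n_segments must be >= 0")


@dataclass
class SyntheticDataset:
    """A generated segment table plus the spec and seed that produced it."""

    table: SegmentTable
    spec: dict[tuple[str, str], TaskProfileSpec]
    seed: int
    sampling_rate: float


def default_study_spec() -> dict[tuple[str, str], TaskProfileSpec]:
    """The published study conditions, one spec per (task, experience) cell."""
    spec = {}
    for task in TASKS:
        d_mean, d_sd = DURATION_STATS[task]
        r_mean, r_sd = RANGE_STATS[task]
        for i, exp in enumerate(EXPERIENCE_LEVELS):
            scale = PEAK_SCALE[exp]
            spec[(task, exp)] = TaskProfileSpec(
                task=task,
                experience=exp,
                duration_mean=d_mean,
                duration_sd=d_sd,
                range_mean=r_mean * scale,
                range_sd=r_sd * scale,
                baseline_force=0.2,
                motif=TASK_MOTIFS[task],
                noise_sd=NOISE_SD[exp],
                n_segments=SEGMENT_COUNTS[task][i],
            )
    return spec


def with_counts(
    spec: dict[tuple[str, str], TaskProfileSpec], n_per_cell: int
) -> dict[tuple[str, str], TaskProfileSpec]:
    """Same conditions, ``n_per_cell`` segments in every cell."""
    return {k: replace(v, n_segments=n_per_cell) for k, v in spec.items()}


# ---------------------------------------------------------------------------
# Motifs: shape functions on u in [0, 1], scaled to [0, 1]


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def motif_profile(motif: str, u: np.ndarray, duration: float) -> np.ndarray:
    """Evaluate a named motif on normalized time ``u``; output spans [0, 1]."""
    if motif == "sustained_plateau":
        # smooth rise, long hold, smooth release
        return _smoothstep(u / 0.15) * _smoothstep((1.0 - u) / 0.15)
    if motif == "grasp_hold":
        # fast grasp then a slow partial relaxation while holding
        rise = _smoothstep(u / 0.06)
        decay = 0.55 + 0.45 * np.exp(-3.0 * u)
        return rise * decay * _smoothstep((1.0 - u) / 0.08)
    if motif == "oscillatory":
        # rhythmic cotton-manipulation cycles at ~1.2 Hz
        n_cycles = max(2.0, round(1.2 * duration))
        env = _smoothstep(u / 0.1) * _smoothstep((1.0 - u) / 0.1)
        return env * (0.5 + 0.5 * np.sin(2.0 * np.pi * n_cycles * u - np.pi / 2))
    if motif == "ramp_pull":
        # steadily increasing traction released at the end
        ramp = np.clip(u / 0.9, 0.0, 1.0)
        return ramp * _smoothstep((1.0 - u) / 0.1)
    if motif == "burst_train":
        # repeated short dissection bursts at ~0.8 Hz
        n_bursts = max(2, int(round(0.8 * duration)))
        centres = (np.arange(n_bursts) + 0.5) / n_bursts
        width = 0.25 / n_bursts
        prof = np.zeros_like(u)
        for c in centres:
            prof += np.exp(-0.5 * ((u - c) / width) ** 2)
        return prof / prof.max()
    raise ParameterError(f"unknown motif {motif!r}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if sd == 0:
        return float(np.log(mean)), 0.0
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


def _generate_cell(
    cell: TaskProfileSpec, fs: float, rng: np.random.Generator, surgeons: list[str], cases: list[str]
) -> list[ForceSegment]:
    mu_d, sg_d = _lognormal_params(cell.duration_mean, cell.duration_sd)
    mu_r, sg_r = _lognormal_params(cell.range_mean, cell.range_sd)
    durations = np.maximum(rng.lognormal(mu_d, sg_d, size=cell.n_segments), MIN_DURATION)
    ranges = np.maximum(rng.lognormal(mu_r, sg_r, size=cell.n_segments), 0.05)
    segments = []
    tag = f"{cell.task[:4]}-{cell.experience[:3]}".lower()
    for i in range(cell.n_segments):
        n = max(int(round(durations[i] * fs)), 2)
        u = np.arange(n) / max(n - 1, 1)
        shape = motif_profile(cell.motif, u, durations[i])
        base = cell.baseline_force + ranges[i] * shape
        right = base + rng.normal(0.0, cell.noise_sd, size=n)
        left = 0.95 * base + rng.normal(0.0, cell.noise_sd, size=n)
        segments.append(
            ForceSegment(
                segment_id=f"syn-{tag}-{i:04d}",
                case_id=cases[i % len(cases)],
                sampling_rate=fs,
                left_force=left,
                right_force=right,
                task=cell.task,
                surgeon_id=surgeons[i % len(surgeons)],
                experience=cell.experience,
                metadata={
                    "drawn_duration": float(durations[i]),
                    "drawn_range": float(ranges[i]),
                },
            )
        )
    return segments


def generate(
    spec: dict[tuple[str, str], TaskProfileSpec],
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a segment table from per-cell specs; bitwise seed-reproducible."""
    ss = np.random.SeedSequence(seed)
    keys = sorted(spec)  # fixed order so child streams are stable
    children = ss.spawn(len(keys))
    segments = []
    for key, child in zip(keys, children):
        cell = spec[key]
        rng = np.random.Generator(np.random.PCG64(child))
        if cell.experience == "Expert":
            surgeons = ["EXP01"]
        else:
            surgeons = ["NOV01", "NOV02", "NOV03", "NOV04"]
        cases = [f"C{j:02d}" for j in range(1, 11)]
        segments.extend(_generate_cell(cell, sampling_rate, rng, surgeons, cases))
    table = SegmentTable(segments, provenance=f"synthetic(seed={seed}, fs={sampling_rate})")
    return SyntheticDataset(table=table, spec=dict(spec), seed=seed, sampling_rate=sampling_rate)


def make_fixture(profile: str = "tiny", seed: int = 0) -> SyntheticDataset:
    """Standard fixtures: ``tiny`` (10 segments/cell) or ``published_counts``
    (the published per-cell counts, 2895 segments)."""
    if profile == "tiny":
        spec = with_counts(default_study_spec(), 10)
    elif profile == "published_counts":
        spec = default_study_spec()
    else:
        raise ParameterError(f"unknown fixture profile {profile!r}; use tiny or published_counts")
    return generate(spec, seed=seed)
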