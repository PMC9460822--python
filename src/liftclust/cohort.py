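"""Synthetic lifting-cohort generator.

Emulates a cohort of lifting trials whose per-cluster trunk/hip/knee ROM
means/SDs, PSEQ/pain scores, and cluster prevalences follow a configurable set
of four archetypes.  The defaults reproduce the published per-cluster
statistics of the chronic-low-back-pain lifting study this pipeline targets:
473 trials over 115 participants, extreme-cluster prevalences 6.76% and
40.80%, and the printed per-cluster ROM and questionnaire distributions.

Every trial carries five synthetic angular-displacement traces shaped as a
raised-cosine descend-hold-ascend lift, so the kinematics stage can be
exercised end to end; the generating archetype is recorded as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from ._rng import stage_rng
from .kinematics import AngleTrace

__all__ = [
    "ClusterArchetype",
    "CohortConfig",
    "LiftTrial",
    "DEFAULT_ARCHETYPES",
    "apportion_counts",
    "generate_trace",
    "assign_scores",
    "generate_cohort",
    "trials_frame",
    "traces_frame",
]

PSEQ_RANGE = (0.0, 60.0)
PAIN_RANGE = (0.0, 100.0)


@dataclass(frozen=True)
class ClusterArchetype:
    """Generating distribution of one lifting-technique cluster."""

    cluster_id: int
    rom_mean: tuple  # (trunk, hip, knee) degrees
    rom_sd: tuple  # degrees, componentwise > 0
    pseq_mean: float
    pseq_sd: float
    pain_mean: float
    pain_sd: float
    prevalence: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "rom_mean", tuple(float(x) for x in self.rom_mean))
        object.__setattr__(self, "rom_sd", tuple(float(x) for x in self.rom_sd))
        if len(self.rom_mean) != 3 or len(self.rom_sd) != 3:
            raise ValueError("rom_mean and rom_sd must be 3-vectors (trunk, hip, knee)")
        if any(sd <= 0 for sd in self.rom_sd):
            raise ValueError("rom_sd must be positive componentwise")
        if not PSEQ_RANGE[0] <= self.pseq_mean <= PSEQ_RANGE[1]:
            raise ValueError("pseq_mean out of [0, 60]")
        if not PAIN_RANGE[0] <= self.pain_mean <= PAIN_RANGE[1]:
            raise ValueError("pain_mean out of [0, 100]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if self.pseq_sd < 0 or self.pain_sd < 0:
            raise ValueError("score SDs must be non-negative")


#: Default archetypes: per-cluster ROM mean (SD) from the published Ward
#: clustering block, PSEQ/pain from the published questionnaire table, and
#: prevalences 6.76% / 40.80% for the extreme clusters.  The remaining 52.44%
#: is split 28.04% / 24.40% between clusters 3 and 4 (unpublished; configurable).
DEFAULT_ARCHETYPES = (
    ClusterArchetype(1, (34.19, 114.58, 136.24), (6.84, 9.74, 12.35), 35.56, 8.45, 51.03, 10.22, 0.0676),
    ClusterArchetype(2, (41.88, 107.37, 96.39), (7.84, 9.27, 12.66), 43.89, 9.95, 50.33, 20.40, 0.4080),
    ClusterArchetype(3, (54.00, 83.92, 26.70), (9.26, 13.02, 10.36), 46.13, 10.53, 47.73, 21.21, 0.2804),
    ClusterArchetype(4, (48.04, 93.54, 67.29), (9.73, 9.61, 13.72), 45.57, 9.50, 48.17, 19.27, 0.2440),
)


@dataclass
class CohortConfig:
    n_trials: int = 473
    n_participants: int = 115
    archetypes: Sequence[ClusterArchetype] = DEFAULT_ARCHETYPES
    trace_duration: float = 5.0  # seconds
    sample_rate: float = 120.0  # Hz
    side_asymmetry_sd: float = 2.0  # degrees; left/right ROM = nominal +/- draw
    rom_noise_sd: float = 0.5  # degrees of mean-zero amplitude noise per trace
    mixed_participant_fraction: float = 0.0  # fraction of participants spanning 2 archetypes
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials < 2 * len(self.archetypes):
            raise ValueError("n_trials must be at least twice the number of archetypes")
        if self.n_participants < len(self.archetypes):
            raise ValueError("need at least one participant per archetype")
        if self.sample_rate <= 0 or self.trace_duration <= 0:
            raise ValueError("sample_rate and trace_duration must be positive")
        if self.side_asymmetry_sd < 0 or self.rom_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.mixed_participant_fraction <= 1.0:
            raise ValueError("mixed_participant_fraction must be in [0, 1]")
        total = sum(a.prevalence for a in self.archetypes)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"prevalences must sum to 1 (got {total!r})")


@dataclass
class LiftTrial:
    """One lifting repetition: five joint traces plus participant metadata."""

    participant_id: str
    trial_index: int
    traces: dict  # joint name -> AngleTrace
    pseq: float
    pain: float
    true_cluster: Optional[int] = None  # generating archetype; absent in real-data mode
    nominal_rom: Optional[np.ndarray] = None  # (trunk, hip, knee) pre-noise draw

    def __post_init__(self) -> None:
        if not PSEQ_RANGE[0] <= self.pseq <= PSEQ_RANGE[1]:
            raise ValueError("pseq out of [0, 60]")
        if not PAIN_RANGE[0] <= self.pain <= PAIN_RANGE[1]:
            raise ValueError("pain out of [0, 100]")
        lengths = {len(t.samples) for t in self.traces.values()}
        if len(self.traces) and len(lengths) != 1:
            raise ValueError("all traces of a trial must have equal length")


def apportion_counts(prevalences: Sequence[float], n: int) -> np.ndarray:
    """Integer counts per archetype by largest-remainder apportionment.

    Deterministic: quotas ``p_i * n`` are floored and the leftover units go to
    the largest fractional remainders (ties to the larger prevalence, then the
    lower index).  Guarantees the counts sum to ``n`` and that a quota whose
    rounding is unambiguous (e.g. 0.4080 * 473 = 192.98 -> 193) is honored.
    """
    prev = np.asarray(prevalences, dtype=float)
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError("prevalences must sum to 1")
    if n < prev.size:
        raise ValueError("fewer trials than archetypes")
    quotas = prev * n
    counts = np.floor(quotas).astype(int)
    remainder = int(n - counts.sum())
    order = sorted(
        range(prev.size),
        key=lambda i: (-(quotas[i] - counts[i]), -prev[i], i),
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _lift_profile(n_samples: int) -> np.ndarray:
    """Unimodal 0->1->0 flexion profile: stand, raised-cosine descend, hold, ascend, stand."""
    t = np.linspace(0.0, 1.0, n_samples)
    profile = np.zeros(n_samples)
    descend = (t >= 0.15) & (t < 0.45)
    hold = (t >= 0.45) & (t < 0.55)
    ascend = (t >= 0.55) & (t < 0.85)
    profile[descend] = 0.5 * (1 - np.cos(np.pi * (t[descend] - 0.15) / 0.30))
    profile[hold] = 1.0
    profile[ascend] = 0.5 * (1 + np.cos(np.pi * (t[ascend] - 0.55) / 0.30))
    peak = profile.max()
    if peak == 0.0:  # too few samples to land in the flexed phase
        profile[n_samples // 2] = 1.0
    elif peak < 1.0:  # rescale so max - min equals the target exactly
        profile /= peak
    return profile


def generate_trace(
    rom_target: float,
    duration: float,
    rate: float,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    joint: str = "trunk",
    baseline: float = 0.0,
) -> AngleTrace:
    """Smooth descend-hold-ascend angle trace whose noiseless ROM equals ``rom_target``.

    Noise perturbs the realized flexion amplitude (a mean-zero Gaussian draw
    added to the ROM, truncated so the ROM stays non-negative), which keeps
    the curve smooth and unimodal and leaves ROM extraction unbiased; the
    post-noise ROM lies within 3 * noise_sd of the target with probability
    ~99.7%.
    """
    if rom_target < 0:
        raise ValueError("rom_target must be non-negative")
    if rate <= 0 or duration <= 0:
        raise ValueError("rate and duration must be positive")
    n_samples = int(round(duration * rate))
    if n_samples < 2:
        raise ValueError("duration * rate must give at least 2 samples")
    amplitude = rom_target
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        amplitude = max(rom_target + rng.normal(0.0, noise_sd), 0.0)
    samples = baseline + amplitude * _lift_profile(n_samples)
    return AngleTrace(joint=joint, samples=samples, rate=rate)


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, size, rng: np.random.Generator
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def assign_scores(
    archetype: ClusterArchetype, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(pseq, pain) pairs for ``n`` participants, truncated to their valid ranges."""
    if n < 1:
        raise ValueError("n must be >= 1")
    pseq = _truncated_normal(archetype.pseq_mean, archetype.pseq_sd, *PSEQ_RANGE, n, rng)
    pain = _truncated_normal(archetype.pain_mean, archetype.pain_sd, *PAIN_RANGE, n, rng)
    return np.column_stack([pseq, pain])


def _participant_counts(config: CohortConfig, trial_counts: np.ndarray) -> np.ndarray:
    """Participants per archetype, proportional to prevalence, >=1 where trials exist."""
    prev = np.array([a.prevalence for a in config.archetypes])
    counts = apportion_counts(prev, config.n_participants)
    # every archetype with trials needs a participant; never exceed its trial count
    for i in range(counts.size):
        if trial_counts[i] > 0 and counts[i] == 0:
            counts[i] = 1
        counts[i] = min(counts[i], max(trial_counts[i], 1))
    while counts.sum() > config.n_participants:
        i = int(np.argmax(counts))
        counts[i] -= 1
    while counts.sum() < config.n_participants:
        deficit = trial_counts - counts  # room for more participants
        i = int(np.argmax(deficit))
        counts[i] += 1
    return counts


def generate_cohort(config: CohortConfig, seed: Optional[int] = None) -> list:
    """Generate a reproducible synthetic cohort of :class:`LiftTrial` objects.

    Trial counts per archetype follow largest-remainder apportionment of the
    prevalences.  Each participant's trials come from a single archetype by
    default; ``mixed_participant_fraction`` lets a subset of participants span
    two archetypes (their extra trials keep the second archetype's ground-truth
    tag).  Scores are drawn once per participant and repeated across that
    participant's trials.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = stage_rng(seed, "cohort")

    archetypes = list(config.archetypes)
    n_arch = len(archetypes)
    trial_counts = apportion_counts([a.prevalence for a in archetypes], config.n_trials)
    part_counts = _participant_counts(config, trial_counts)

    # participant ids, grouped by archetype
    participants = []  # (participant_id, archetype_index)
    pid = 0
    for ai in range(n_arch):
        for _ in range(part_counts[ai]):
            pid += 1
            participants.append((f"P{pid:03d}", ai))

    # trials per participant: archetype trials split as evenly as possible
    slots = {p: [] for p, _ in participants}  # participant -> list of archetype indices
    for ai in range(n_arch):
        members = [p for p, a in participants if a == ai]
        n_p = len(members)
        if n_p == 0:
            continue
        base, extra = divmod(int(trial_counts[ai]), n_p)
        for j, p in enumerate(members):
            slots[p].extend([ai] * (base + (1 if j < extra else 0)))

    # optionally let some participants span two archetypes: a mixed participant
    # takes over one trial slot from a donor participant of another archetype
    n_mixed = int(round(config.mixed_participant_fraction * len(participants)))
    if n_mixed > 0:
        mixed_idx = rng.choice(len(participants), size=n_mixed, replace=False)
        for mi in np.sort(mixed_idx):
            p, ai = participants[mi]
            others = [o for o in range(n_arch) if o != ai and trial_counts[o] > 0]
            if not others:
                continue
            target = int(rng.choice(others))
            donors = [q for q, a in participants if a == target and len(slots[q]) > 1]
            if not donors:
                continue
            donor = max(donors, key=lambda q: (len(slots[q]), q))
            slots[donor].remove(target)
            slots[p].append(target)

    # per-participant scores from the primary archetype
    scores = {}
    for p, ai in participants:
        scores[p] = assign_scores(archetypes[ai], 1, rng)[0]

    # batch the nominal ROM draws per archetype (3 truncated-normal draws per
    # axis set), consumed in participant order for determinism
    demand = np.zeros(n_arch, dtype=int)
    for p, _ai in participants:
        for arch_idx in slots[p]:
            demand[arch_idx] += 1
    nominal_pool = {}
    for ai in range(n_arch):
        arch = archetypes[ai]
        cols = [
            _truncated_normal(arch.rom_mean[d], arch.rom_sd[d], 0.0, np.inf, max(demand[ai], 1), rng)
            for d in range(3)
        ]
        nominal_pool[ai] = np.column_stack(cols)
    cursor = np.zeros(n_arch, dtype=int)

    trials = []
    for p, _ai in participants:
        pseq, pain = scores[p]
        for ti, arch_idx in enumerate(slots[p], start=1):
            arch = archetypes[arch_idx]
            nominal = nominal_pool[arch_idx][cursor[arch_idx]]
            cursor[arch_idx] += 1
            hip_asym = rng.normal(0.0, config.side_asymmetry_sd) if config.side_asymmetry_sd else 0.0
            knee_asym = rng.normal(0.0, config.side_asymmetry_sd) if config.side_asymmetry_sd else 0.0
            targets = {
                "trunk": nominal[0],
                "hip_left": max(nominal[1] + hip_asym, 0.0),
                "hip_right": max(nominal[1] - hip_asym, 0.0),
                "knee_left": max(nominal[2] + knee_asym, 0.0),
                "knee_right": max(nominal[2] - knee_asym, 0.0),
            }
            traces = {
                joint: generate_trace(
                    rom,
                    config.trace_duration,
                    config.sample_rate,
                    noise_sd=config.rom_noise_sd,
                    rng=rng,
                    joint=joint,
                )
                for joint, rom in targets.items()
            }
            trials.append(
                LiftTrial(
                    participant_id=p,
                    trial_index=ti,
                    traces=traces,
                    pseq=float(pseq),
                    pain=float(pain),
                    true_cluster=arch.cluster_id,
                    nominal_rom=nominal,
                )
            )
    return trials


def trials_frame(trials) -> pd.DataFrame:
    """Per-trial metadata table (participant_id, trial_index, true_cluster, pseq, pain)."""
    return pd.DataFrame(
        {
            "participant_id": [t.participant_id for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "true_cluster": [t.true_cluster for t in trials],
            "pseq": [t.pseq for t in trials],
            "pain": [t.pain for t in trials],
        }
    )


def traces_frame(trials) -> pd.DataFrame:
    """Long-format trace table (participant_id, trial_index, joint, sample_index, angle_deg)."""
    records = []
    for t in trials:
        for joint, trace in t.traces.items():
            n = trace.samples.size
            records.append(
                pd.DataFrame(
                    {
                        "participant_id": t.participant_id,
                        "trial_index": t.trial_index,
                        "joint": joint,
                        "sample_index": np.arange(n),
                        "angle_deg": trace.samples,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)
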