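"""Forward simulation of cohorts with a planted body-part geometry.

The generator plants a three-cluster representational structure over the
8 body-part conditions — action effectors (hand, foot, arm, leg), trunk
noneffectors (chest, waist) and face parts (upper/lower face) — whose
strength is governed by a cohesion parameter kappa in [0, 1]:

    pattern(c) = sqrt(kappa) * prototype(category(c))
               + sqrt(1 - kappa) * unique(c)

with prototypes and uniques i.i.d. standard normal over voxels, so the
expected correlation between two same-category patterns equals kappa.
BOLD runs are generated from these amplitudes through the same
boxcar-x-HRF model the GLM inverts, plus slow drift and AR(1) noise;
head motion is a six-parameter random walk; trait scores are linear in
kappa plus Gaussian noise so rank-correlation recovery is testable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .design import (
    BODY_PART_CONDITIONS,
    CATEGORY_OF,
    CONDITIONS,
    DesignSpec,
    StimulusSchedule,
    build_design,
)
from . import glm as _glm

__all__ = [
    "TRAIT_NAMES",
    "GroundTruthPatterns",
    "generate_patterns",
    "simulate_bold",
    "simulate_motion",
    "GroupConfig",
    "CohortConfig",
    "SimulatedParticipant",
    "SimulatedCohort",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

#: Trait scores carried per participant. The questionnaire instruments
#: themselves are not modeled; only their numeric totals are simulated.
TRAIT_NAMES: tuple[str, ...] = (
    "SRS",
    "AQ",
    "SP_low_registration",
    "SP_sensory_seeking",
    "SP_sensory_sensitivity",
    "SP_sensation_avoiding",
    "DCDQ",
    "MABC2",
    "age",
    "FSIQ",
)


@dataclass
class GroundTruthPatterns:
    """Planted condition x voxel response amplitudes."""

    amplitudes: np.ndarray  # len(CONDITIONS) x n_voxels, CONDITIONS order
    conditions: tuple[str, ...]
    cohesion: float
    contrast_gain: float

    @property
    def n_voxels(self) -> int:
        return self.amplitudes.shape[1]

    def pattern(self, condition: str) -> np.ndarray:
        return self.amplitudes[self.conditions.index(condition)]


def generate_patterns(
    n_voxels: int,
    cohesion: float,
    contrast_gain: float = 1.0,
    seed: int = 0,
) -> GroundTruthPatterns:
    """Draw planted amplitudes with three-cluster structure.

    kappa = 0 gives independent patterns; kappa = 1 makes same-category
    patterns identical. The whole-body pattern exceeds the chair pattern
    in mean amplitude by ``contrast_gain`` (both otherwise independent
    standard normal), so the localizer contrast has a planted effect.
    """
    if not 0.0 <= cohesion <= 1.0:
        raise ValueError(f"cohesion must lie in [0, 1], got {cohesion}")
    if n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    rng = np.random.default_rng(seed)
    protos = {
        cat: rng.standard_normal(n_voxels)
        for cat in ("effector", "noneffector", "face")
    }
    amps = np.empty((len(CONDITIONS), n_voxels))
    for i, cond in enumerate(CONDITIONS):
        cat = CATEGORY_OF[cond]
        if cond == "whole_body":
            amps[i] = rng.standard_normal(n_voxels) + contrast_gain
        elif cond == "chair":
            amps[i] = rng.standard_normal(n_voxels)
        else:
            amps[i] = np.sqrt(cohesion) * protos[cat] + np.sqrt(
                1.0 - cohesion
            ) * rng.standard_normal(n_voxels)
    return GroundTruthPatterns(
        amplitudes=amps,
        conditions=CONDITIONS,
        cohesion=float(cohesion),
        contrast_gain=float(contrast_gain),
    )


def simulate_bold(
    schedule: StimulusSchedule,
    patterns: GroundTruthPatterns,
    noise_sd: float = 1.0,
    ar1_coeff: float = 0.0,
    drift_amplitude: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
) -> np.ndarray:
    """Simulate one run as voxels x volumes.

    Y = baseline + X B + drift + AR(1) noise, where X is the
    boxcar-convolved-HRF design over the full (dummy-inclusive) run and
    B the planted amplitudes. ``noise_sd`` is the stationary noise SD
    (innovations are scaled by sqrt(1 - phi^2)); drift is a half-cycle
    cosine over the run with a random phase per voxel.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not abs(ar1_coeff) < 1:
        raise ValueError("|ar1_coeff| must be < 1")
    sched_conds = sorted({e.condition for e in schedule.events})
    if not set(sched_conds) <= set(patterns.conditions):
        missing = set(sched_conds) - set(patterns.conditions)
        raise ValueError(f"schedule conditions without planted pattern: {missing}")
    rng = np.random.default_rng(seed)
    X, labels = _glm.condition_regressors(schedule)
    B = np.stack([patterns.pattern(lab) for lab in labels])
    Y = (X @ B).T + baseline
    n_vol, n_vox = schedule.n_volumes, patterns.n_voxels
    if drift_amplitude:
        t = np.arange(n_vol) * schedule.tr
        phase = rng.uniform(0, 2 * np.pi, size=n_vox)
        Y += drift_amplitude * np.cos(
            np.pi * t[None, :] / schedule.total_duration + phase[:, None]
        )
    if noise_sd:
        innov = rng.standard_normal((n_vox, n_vol)) * noise_sd
        if ar1_coeff:
            innov *= np.sqrt(1.0 - ar1_coeff**2)
            noise = sp_signal.lfilter([1.0], [1.0, -ar1_coeff], innov, axis=1)
        else:
            noise = innov
        Y += noise
    return Y


def simulate_motion(
    n_volumes: int,
    step_sd_mm: float = 0.025,
    step_sd_rad: float = 0.0003,
    seed: int = 0,
) -> np.ndarray:
    """Six-parameter rigid-body motion as independent random walks.

    Returns n_volumes x 6 (3 translations in mm, 3 rotations in rad);
    the first volume sits at the origin. Default step sizes give a mean
    framewise displacement near 0.10 mm, the adult-group level.
    """
    if step_sd_mm < 0 or step_sd_rad < 0:
        raise ValueError("step SDs must be >= 0")
    rng = np.random.default_rng(seed)
    steps = rng.standard_normal((n_volumes, 6))
    steps[:, :3] *= step_sd_mm
    steps[:, 3:] *= step_sd_rad
    steps[0] = 0.0
    return np.cumsum(steps, axis=0)


@dataclass
class GroupConfig:
    """Generation parameters for one cohort group."""

    n: int
    kappa_mean: float = 0.7
    kappa_sd: float = 0.1
    noise_sd: float = 1.2
    motion_step_mm: float = 0.025
    motion_step_rad: float = 0.0003
    drift_amplitude: float = 0.5
    ar1_coeff: float = 0.3


@dataclass
class CohortConfig:
    """Study-level generation parameters.

    Defaults emulate the study cohort: 26 adults and 22 children/
    adolescents, with the younger group noisier (higher BOLD noise and
    roughly doubled head motion, matching its higher mean FD) and
    slightly weaker category cohesion. Noise SDs are calibrated so the
    run-level beta standard error is about half the unit pattern SD in
    adults (lower in children), the regime where split-half RDMs and
    decoding sit above chance but off ceiling as in real data. Trait
    scores are ``intercept + slope * kappa + N(0, noise_sd)`` per
    trait.
    """

    groups: dict[str, GroupConfig] = field(
        default_factory=lambda: {
            "adult": GroupConfig(n=26, kappa_mean=0.75, kappa_sd=0.10),
            "child_adolescent": GroupConfig(
                n=22,
                kappa_mean=0.65,
                kappa_sd=0.12,
                noise_sd=1.8,
                motion_step_mm=0.05,
                motion_step_rad=0.0006,
            ),
        }
    )
    n_voxels: int = 120
    contrast_gain: float = 1.0
    design: DesignSpec = field(default_factory=DesignSpec)
    # trait model: score = intercept + slope * kappa + noise
    trait_slopes: dict[str, float] = field(
        default_factory=lambda: {
            "SRS": -40.0,
            "AQ": -15.0,
            "SP_low_registration": -10.0,
            "SP_sensory_seeking": -8.0,
            "SP_sensory_sensitivity": -10.0,
            "SP_sensation_avoiding": -12.0,
            "DCDQ": 20.0,
            "MABC2": 6.0,
            "age": 0.0,
            "FSIQ": 0.0,
        }
    )
    trait_intercepts: dict[str, float] = field(
        default_factory=lambda: {
            "SRS": 90.0,
            "AQ": 25.0,
            "SP_low_registration": 30.0,
            "SP_sensory_seeking": 38.0,
            "SP_sensory_sensitivity": 32.0,
            "SP_sensation_avoiding": 34.0,
            "DCDQ": 40.0,
            "MABC2": 8.0,
            "age": 12.0,
            "FSIQ": 105.0,
        }
    )
    trait_noise_sd: float = 5.0

    def validate(self) -> None:
        for name, g in self.groups.items():
            if g.n <= 0:
                raise ValueError(f"group {name!r} has nonpositive size {g.n}")
        self.design.validate()


@dataclass
class SimulatedParticipant:
    id: str
    group: str
    bold_runs: list[np.ndarray]  # voxels x volumes, dummy-inclusive
    motion_runs: list[np.ndarray]  # volumes x 6
    schedules: list[StimulusSchedule]
    patterns: GroundTruthPatterns
    trait_scores: dict[str, float]
    seed: int

    @property
    def n_voxels(self) -> int:
        return self.bold_runs[0].shape[0]


@dataclass
class SimulatedCohort:
    participants: list[SimulatedParticipant]
    config: CohortConfig
    seed: int

    def group(self, name: str) -> list[SimulatedParticipant]:
        return [p for p in self.participants if p.group == name]


def generate_cohort(config: CohortConfig, seed: int) -> SimulatedCohort:
    """Simulate a full cohort; every sub-seed derives from ``seed``."""
    config.validate()
    root = np.random.SeedSequence(seed)
    participants: list[SimulatedParticipant] = []
    for gname in sorted(config.groups):
        g = config.groups[gname]
        for i in range(g.n):
            pseed = int(root.spawn(1)[0].generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(pseed)
            kappa = float(np.clip(rng.normal(g.kappa_mean, g.kappa_sd), 0.0, 1.0))
            patterns = generate_patterns(
                config.n_voxels, kappa, config.contrast_gain, seed=pseed
            )
            schedules = build_design(config.design, seed=pseed + 1)
            bold, motion = [], []
            for r, sched in enumerate(schedules):
                bold.append(
                    simulate_bold(
                        sched,
                        patterns,
                        noise_sd=g.noise_sd,
                        ar1_coeff=g.ar1_coeff,
                        drift_amplitude=g.drift_amplitude,
                        seed=pseed + 10 + r,
                    )
                )
                motion.append(
                    simulate_motion(
                        sched.n_volumes,
                        g.motion_step_mm,
                        g.motion_step_rad,
                        seed=pseed + 100 + r,
                    )
                )
            traits = {
                t: config.trait_intercepts[t]
                + config.trait_slopes[t] * kappa
                + rng.normal(0.0, config.trait_noise_sd)
                for t in TRAIT_NAMES
            }
            participants.append(
                SimulatedParticipant(
                    id=f"{gname}_{i:02d}",
                    group=gname,
                    bold_runs=bold,
                    motion_runs=motion,
                    schedules=schedules,
                    patterns=patterns,
                    trait_scores=traits,
                    seed=pseed,
                )
            )
    return SimulatedCohort(participants=participants, config=config, seed=seed)


# ---------------------------------------------------------------------------
# on-disk cohort layout: one .npy per run per participant, a participants
# table (TSV) and a JSON config capturing all generation parameters/seeds.

def save_cohort(cohort: SimulatedCohort, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in cohort.participants:
        pdir = d / p.id
        pdir.mkdir(exist_ok=True)
        for r, (Y, mo) in enumerate(zip(p.bold_runs, p.motion_runs)):
            np.save(pdir / f"bold_run{r + 1}.npy", Y)
            np.save(pdir / f"motion_run{r + 1}.npy", mo)
        onsets = [
            {"run": s.run_index, "events": [[e.condition, e.onset, e.duration] for e in s.events]}
            for s in p.schedules
        ]
        (pdir / "schedule.json").write_text(json.dumps(onsets))
        rows.append(
            {"id": p.id, "group": p.group, "seed": p.seed,
             "kappa": p.patterns.cohesion, **p.trait_scores}
        )
    pd.DataFrame(rows).to_csv(d / "participants.tsv", sep="\t", index=False)
    cfg = asdict(cohort.config)
    cfg["seed"] = cohort.seed
    (d / "config.json").write_text(json.dumps(cfg, indent=1))
    return d


def load_cohort(directory: str | Path) -> SimulatedCohort:
    """Reload a serialized cohort (planted patterns are regenerated
    from the recorded per-participant seeds)."""
    d = Path(directory)
    cfg_raw = json.loads((d / "config.json").read_text())
    seed = cfg_raw.pop("seed")
    groups = {k: GroupConfig(**v) for k, v in cfg_raw.pop("groups").items()}
    design_raw = cfg_raw.pop("design")
    for key in ("conditions", "baseline_interior_after"):
        design_raw[key] = tuple(design_raw[key])
    config = CohortConfig(
        groups=groups, design=DesignSpec(**design_raw), **cfg_raw
    )
    table = pd.read_csv(d / "participants.tsv", sep="\t")
    participants = []
    for _, row in table.iterrows():
        pdir = d / row["id"]
        sched_raw = json.loads((pdir / "schedule.json").read_text())
        schedules = _schedules_from_json(sched_raw, config.design)
        bold = [np.load(pdir / f"bold_run{s.run_index + 1}.npy") for s in schedules]
        motion = [np.load(pdir / f"motion_run{s.run_index + 1}.npy") for s in schedules]
        pseed = int(row["seed"])
        patterns = generate_patterns(
            config.n_voxels, float(row["kappa"]), config.contrast_gain, seed=pseed
        )
        traits = {t: float(row[t]) for t in TRAIT_NAMES}
        participants.append(
            SimulatedParticipant(
                id=row["id"], group=row["group"], bold_runs=bold,
                motion_runs=motion, schedules=schedules, patterns=patterns,
                trait_scores=traits, seed=pseed,
            )
        )
    return SimulatedCohort(participants=participants, config=config, seed=seed)


def _schedules_from_json(raw: list[dict], spec: DesignSpec) -> list[StimulusSchedule]:
    from .design import BlockEvent

    out = []
    for s in raw:
        events = [BlockEvent(c, o, dur) for c, o, dur in s["events"]]
        out.append(
            StimulusSchedule(
                run_index=s["run"],
                events=events,
                total_duration=spec.total_duration,
                n_volumes=spec.n_volumes,
                tr=spec.tr,
            )
        )
    return out
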