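"""Block design of the body-part viewing task.

A run presents 10 conditions (whole body, chair, and 8 body parts) in
12-s blocks, two blocks per condition, separated by fixation baselines.
The schedule objects produced here drive both the BOLD forward model and
the GLM design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONDITIONS",
    "BODY_PART_CONDITIONS",
    "CATEGORY_OF",
    "DesignError",
    "DesignSpec",
    "BlockEvent",
    "StimulusSchedule",
    "build_design",
    "design_summary",
]

#: Full condition set, in canonical order.
CONDITIONS: tuple[str, ...] = (
    "whole_body",
    "chair",
    "hand",
    "foot",
    "arm",
    "leg",
    "chest",
    "waist",
    "upper_face",
    "lower_face",
)

#: The 8 body-part conditions entering the representational analyses.
BODY_PART_CONDITIONS: tuple[str, ...] = (
    "hand",
    "foot",
    "arm",
    "leg",
    "chest",
    "waist",
    "upper_face",
    "lower_face",
)

#: Hypothesized category of each condition: action effectors, trunk
#: (noneffector) parts, face parts, plus the two localizer conditions.
CATEGORY_OF: dict[str, str] = {
    "hand": "effector",
    "foot": "effector",
    "arm": "effector",
    "leg": "effector",
    "chest": "noneffector",
    "waist": "noneffector",
    "upper_face": "face",
    "lower_face": "face",
    "whole_body": "whole_body",
    "chair": "chair",
}


class DesignError(ValueError):
    """Raised for an internally inconsistent design specification."""


@dataclass(frozen=True)
class DesignSpec:
    """Timing parameters of the block design.

    Defaults reproduce the study design: four 318-s runs of 20 blocks
    (10 conditions x 2 repetitions), 12 s per block, with fixation
    baselines of 27 s before the first block, 12 s after blocks 5, 10
    and 15, and 15 s after the last block; TR = 3 s, 5 dummy volumes
    discarded per run.
    """

    n_runs: int = 4
    conditions: tuple[str, ...] = CONDITIONS
    blocks_per_condition_per_run: int = 2
    block_duration: float = 12.0
    tr: float = 3.0
    baseline_initial: float = 27.0
    baseline_interior: float = 12.0
    baseline_interior_after: tuple[int, ...] = (5, 10, 15)
    baseline_final: float = 15.0
    n_dummy_volumes: int = 5
    pictures_per_block: int = 12
    picture_duration_ms: float = 500.0
    isi_ms: float = 500.0
    pictures_per_condition_in_set: int = 44

    @property
    def n_blocks_per_run(self) -> int:
        return len(self.conditions) * self.blocks_per_condition_per_run

    @property
    def total_duration(self) -> float:
        """Run duration in seconds (blocks plus all baselines)."""
        return (
            self.baseline_initial
            + len(self.baseline_interior_after) * self.baseline_interior
            + self.baseline_final
            + self.n_blocks_per_run * self.block_duration
        )

    @property
    def n_volumes(self) -> int:
        return int(round(self.total_duration / self.tr))

    def validate(self) -> None:
        if self.n_runs < 1:
            raise DesignError("n_runs must be >= 1")
        if len(set(self.conditions)) != len(self.conditions):
            raise DesignError("condition labels must be unique")
        if self.tr <= 0:
            raise DesignError("tr must be positive")
        rem = self.total_duration % self.tr
        if min(rem, self.tr - rem) > 1e-9:
            raise DesignError(
                f"run duration {self.total_duration} s is not divisible by "
                f"tr {self.tr} s"
            )
        block_ms = self.pictures_per_block * (self.picture_duration_ms + self.isi_ms)
        if abs(block_ms / 1000.0 - self.block_duration) > 1e-9:
            raise DesignError(
                f"pictures per block x (duration + ISI) = {block_ms / 1000.0} s "
                f"does not equal block_duration {self.block_duration} s"
            )


@dataclass(frozen=True)
class BlockEvent:
    condition: str
    onset: float  # seconds from run start
    duration: float  # seconds


@dataclass
class StimulusSchedule:
    """Block timing of a single run."""

    run_index: int
    events: list[BlockEvent]
    total_duration: float
    n_volumes: int
    tr: float

    def onsets(self, condition: str) -> np.ndarray:
        return np.array([e.onset for e in self.events if e.condition == condition])

    def shifted(self, seconds: float) -> "StimulusSchedule":
        """Schedule re-expressed on a timeline starting ``seconds`` later.

        Used when dummy volumes are discarded: onsets shift earlier and the
        volume count shrinks accordingly.
        """
        n_vol = int(round((self.total_duration - seconds) / self.tr))
        events = [replace(e, onset=e.onset - seconds) for e in self.events]
        return StimulusSchedule(
            run_index=self.run_index,
            events=events,
            total_duration=self.total_duration - seconds,
            n_volumes=n_vol,
            tr=self.tr,
        )


def build_design(spec: DesignSpec, seed: int) -> list[StimulusSchedule]:
    """Build one pseudo-randomized schedule per run.

    Block order within each run is an independent uniform permutation of
    the multiset holding every condition ``blocks_per_condition_per_run``
    times; fixation baselines are inserted at the positions fixed by the
    spec. Deterministic given ``seed``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    block_labels = [
        c for c in spec.conditions for _ in range(spec.blocks_per_condition_per_run)
    ]
    schedules = []
    for run in range(spec.n_runs):
        order = [block_labels[i] for i in rng.permutation(len(block_labels))]
        t = spec.baseline_initial
        events = []
        for i, cond in enumerate(order, start=1):
            events.append(BlockEvent(cond, t, spec.block_duration))
            t += spec.block_duration
            if i in spec.baseline_interior_after:
                t += spec.baseline_interior
        t += spec.baseline_final
        assert abs(t - spec.total_duration) < 1e-9
        schedules.append(
            StimulusSchedule(
                run_index=run,
                events=events,
                total_duration=spec.total_duration,
                n_volumes=spec.n_volumes,
                tr=spec.tr,
            )
        )
    return schedules


def design_summary(spec: DesignSpec) -> dict:
    """Derived quantities of the design (durations, volume counts)."""
    spec.validate()
    return {
        "run_duration_s": spec.total_duration,
        "volumes_per_run": spec.n_volumes,
        "analyzed_volumes": (spec.n_volumes - spec.n_dummy_volumes) * spec.n_runs,
        "stimulus_set_size": spec.pictures_per_condition_in_set * len(spec.conditions),
        "n_runs": spec.n_runs,
        "blocks_per_run": spec.n_blocks_per_run,
    }
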