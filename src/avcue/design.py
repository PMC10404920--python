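"""Experiment schedule generation for the audio-visual localization task.

The session has three blocks:

* a visual **calibration** block — low- and high-variance dot-cloud cues,
  interleaved, used to measure each observer's single-cue variable error;
* an **audio training** block — white-noise bursts from one of nine locations;
* a **test** block mixing single-cue, congruent double-cue and incongruent
  (cue-conflict) double-cue trials.

All positions are expressed as proportions of screen width in [0, 1]
(0 = left edge, 1 = right edge, 0.5 = centre). Block generation is a pure
function of the configuration, including its seed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "Condition",
    "CueKind",
    "TrialSpec",
    "DesignConfig",
    "default_locations",
    "make_calibration_block",
    "make_audio_training_block",
    "make_test_block",
    "make_design",
    "design_to_frame",
    "frame_to_design",
]


class Block(str, enum.Enum):
    CALIBRATION = "calibration"
    AUDIO_TRAINING = "audio_training"
    TEST = "test"


class Condition(str, enum.Enum):
    SINGLE = "single"
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"


class CueKind(str, enum.Enum):
    """The four cue types.

    VIS_LOW        low-variance dot cloud (sd 0.05), calibration block only
    VIS_INTRINSIC  high-variance dot cloud (sd 0.2), intrinsic noise only
    VIS_INTR_EXTR  low-variance cloud plus an extrinsic Gaussian shift
    AUD            white-noise auditory cue
    """

    VIS_LOW = "VIS_LOW"
    VIS_INTRINSIC = "VIS_INTRINSIC"
    VIS_INTR_EXTR = "VIS_INTR_EXTR"
    AUD = "AUD"


#: Visual cue kinds (complement of AUD).
VISUAL_CUES = (CueKind.VIS_LOW, CueKind.VIS_INTRINSIC, CueKind.VIS_INTR_EXTR)

#: The two audio-visual pairings used in the test block.
TEST_PAIRINGS = (
    (CueKind.VIS_INTRINSIC, CueKind.AUD),
    (CueKind.VIS_INTR_EXTR, CueKind.AUD),
)


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial.

    ``visual_source`` is the location the visual cue nominally signals before
    any extrinsic shift; ``audio_loc`` is the speaker position. Either may be
    absent (None) on single-cue trials. Feedback is withheld exactly on
    incongruent trials, where it would reveal the conflict.
    """

    block: Block
    index: int
    condition: Condition
    cues: frozenset
    hidden: float
    visual_source: float | None = None
    audio_loc: float | None = None
    feedback: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.hidden <= 1.0:
            raise ValueError(f"hidden location {self.hidden} outside [0, 1]")
        if self.condition is Condition.INCONGRUENT:
            if self.visual_source is None or self.audio_loc is None:
                raise ValueError("incongruent trial needs both cue locations")
            if self.visual_source == self.audio_loc:
                raise ValueError("incongruent trial with equal cue locations")
            if self.feedback:
                raise ValueError("feedback must be withheld on incongruent trials")
        elif not self.feedback:
            raise ValueError("feedback is given on all non-incongruent trials")

    @property
    def visual_cue(self) -> CueKind | None:
        vis = [c for c in self.cues if c is not CueKind.AUD]
        return vis[0] if vis else None

    @property
    def has_audio(self) -> bool:
        return CueKind.AUD in self.cues


def default_locations() -> tuple[float, ...]:
    """Nine approximately evenly spaced target locations spanning 0.37–0.63.

    The five 'intermittent' locations (0.37, 0.43, 0.5, 0.57, 0.63) used for
    cue-conflict trials are a subset.
    """
    return (0.37, 0.40, 0.43, 0.47, 0.50, 0.53, 0.57, 0.60, 0.63)


INTERMITTENT_LOCATIONS = (0.37, 0.43, 0.50, 0.57, 0.63)


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters: locations, repeat counts, dot-cloud spreads, seed.

    Defaults reproduce the published design: 10 repeats x 9 locations per
    calibration cue (90 trials each), 90 audio-training trials, and a test
    block of 405 single-cue, 270 congruent and 400 incongruent trials.
    ``left_hemisphere_only`` mirrors the incongruent locations into the left
    half of the screen to replicate a known presentation bug; it is off by
    default.
    """

    locations: tuple[float, ...] = field(default_factory=default_locations)
    intermittent: tuple[float, ...] = INTERMITTENT_LOCATIONS
    calib_repeats: int = 10
    single_repeats: int = 15
    congruent_repeats: int = 15
    incongruent_repeats: int = 10
    sd_low: float = 0.05
    sd_high: float = 0.2
    n_dots: int = 4
    seed: int = 0
    left_hemisphere_only: bool = False

    def __post_init__(self) -> None:
        if not set(self.intermittent) <= set(self.locations):
            raise ValueError("intermittent locations must be a subset of locations")
        for name in ("calib_repeats", "single_repeats", "congruent_repeats", "incongruent_repeats"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(not 0.0 <= x <= 1.0 for x in self.locations):
            raise ValueError("locations must lie in [0, 1]")
        if self.sd_low < 0 or self.sd_high < 0 or self.n_dots < 1:
            raise ValueError("invalid stimulus parameters")

    def with_seed(self, seed: int) -> "DesignConfig":
        return replace(self, seed=seed)


def _shuffled(trials: list[dict], block: Block, rng: np.random.Generator) -> list[TrialSpec]:
    order = rng.permutation(len(trials))
    return [
        TrialSpec(block=block, index=i, **trials[j]) for i, j in enumerate(order)
    ]


def _block_rng(config: DesignConfig, label: str) -> np.random.Generator:
    # independent stream per block, fully determined by the config seed
    salt = {"calibration": 1, "audio_training": 2, "test": 3}[label]
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), salt]))


def make_calibration_block(config: DesignConfig) -> list[TrialSpec]:
    """90 low-variance + 90 high-variance single-cue visual trials, interleaved.

    Each of the nine locations appears exactly ``calib_repeats`` times per
    cue; feedback is always given.
    """
    trials: list[dict] = []
    for cue in (CueKind.VIS_LOW, CueKind.VIS_INTRINSIC):
        for loc in config.locations:
            for _ in range(config.calib_repeats):
                trials.append(
                    dict(
                        condition=Condition.SINGLE,
                        cues=frozenset({cue}),
                        hidden=loc,
                        visual_source=loc,
                        audio_loc=None,
                        feedback=True,
                    )
                )
    return _shuffled(trials, Block.CALIBRATION, _block_rng(config, "calibration"))


def make_audio_training_block(config: DesignConfig) -> list[TrialSpec]:
    """90 auditory single-cue trials (``calib_repeats`` per location), with feedback."""
    trials = [
        dict(
            condition=Condition.SINGLE,
            cues=frozenset({CueKind.AUD}),
            hidden=loc,
            visual_source=None,
            audio_loc=loc,
            feedback=True,
        )
        for loc in config.locations
        for _ in range(config.calib_repeats)
    ]
    return _shuffled(trials, Block.AUDIO_TRAINING, _block_rng(config, "audio_training"))


def make_test_block(config: DesignConfig) -> list[TrialSpec]:
    """The randomly interleaved test block.

    Composition under the default config:

    * 405 single-cue trials — ``single_repeats`` x 9 locations x 3 cues
      (intrinsic-only visual, intrinsic+extrinsic visual, auditory);
    * 270 congruent double-cue trials — ``congruent_repeats`` x 9 locations
      x 2 audio-visual pairings, both cues at the hidden location;
    * 400 incongruent double-cue trials — ``incongruent_repeats`` repeats of
      every ordered pair of distinct intermittent locations (5 x 4 = 20) for
      each pairing. The hidden location of an incongruent trial is defined as
      the audio source (bookkeeping only; no feedback is given).
    """
    trials: list[dict] = []

    for cue in (CueKind.VIS_INTRINSIC, CueKind.VIS_INTR_EXTR, CueKind.AUD):
        for loc in config.locations:
            for _ in range(config.single_repeats):
                trials.append(
                    dict(
                        condition=Condition.SINGLE,
                        cues=frozenset({cue}),
                        hidden=loc,
                        visual_source=loc if cue is not CueKind.AUD else None,
                        audio_loc=loc if cue is CueKind.AUD else None,
                        feedback=True,
                    )
                )

    for vis_cue, _aud in TEST_PAIRINGS:
        for loc in config.locations:
            for _ in range(config.congruent_repeats):
                trials.append(
                    dict(
                        condition=Condition.CONGRUENT,
                        cues=frozenset({vis_cue, CueKind.AUD}),
                        hidden=loc,
                        visual_source=loc,
                        audio_loc=loc,
                        feedback=True,
                    )
                )

    conflict_locs = config.intermittent
    if config.left_hemisphere_only:
        # replication switch for the original presentation bug: conflict
        # stimuli restricted to the left half of the screen
        conflict_locs = tuple(x for x in config.intermittent if x <= 0.5)
    for vis_cue, _aud in TEST_PAIRINGS:
        for v_loc in conflict_locs:
            for a_loc in conflict_locs:
                if v_loc == a_loc:
                    continue
                for _ in range(config.incongruent_repeats):
                    trials.append(
                        dict(
                            condition=Condition.INCONGRUENT,
                            cues=frozenset({vis_cue, CueKind.AUD}),
                            hidden=a_loc,
                            visual_source=v_loc,
                            audio_loc=a_loc,
                            feedback=False,
                        )
                    )

    return _shuffled(trials, Block.TEST, _block_rng(config, "test"))


def make_design(config: DesignConfig) -> dict[Block, list[TrialSpec]]:
    """All three blocks keyed by block identity."""
    return {
        Block.CALIBRATION: make_calibration_block(config),
        Block.AUDIO_TRAINING: make_audio_training_block(config),
        Block.TEST: make_test_block(config),
    }


def design_to_frame(blocks: dict[Block, list[TrialSpec]] | Iterable[TrialSpec]) -> pd.DataFrame:
    """Flatten TrialSpecs into a tidy table (one row per trial)."""
    if isinstance(blocks, dict):
        trials: list[TrialSpec] = [t for b in blocks.values() for t in b]
    else:
        trials = list(blocks)
    rows = [
        dict(
            block=t.block.value,
            index=t.index,
            condition=t.condition.value,
            cues="+".join(sorted(c.value for c in t.cues)),
            hidden=t.hidden,
            visual_source=t.visual_source,
            audio_loc=t.audio_loc,
            feedback=t.feedback,
        )
        for t in trials
    ]
    return pd.DataFrame(rows)


def frame_to_design(frame: pd.DataFrame) -> dict[Block, list[TrialSpec]]:
    """Inverse of :func:`design_to_frame`."""
    out: dict[Block, list[TrialSpec]] = {b: [] for b in Block}
    for row in frame.itertuples(index=False):
        cues = frozenset(CueKind(c) for c in str(row.cues).split("+"))
        out[Block(row.block)].append(
            TrialSpec(
                block=Block(row.block),
                index=int(row.index),
                condition=Condition(row.condition),
                cues=cues,
                hidden=float(row.hidden),
                visual_source=None if pd.isna(row.visual_source) else float(row.visual_source),
                audio_loc=None if pd.isna(row.audio_loc) else float(row.audio_loc),
                feedback=bool(row.feedback),
            )
        )
    return {b: trials for b, trials in out.items() if trials}
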