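"""Block design of the emotional face identification task.

The scanner acquires one whole-brain volume every ``tr_seconds``.  A run is
a sequence of blocks; each block shows a fixation cross for
``fixation_seconds`` and then ``images_per_block`` images of one emotion
condition for ``stim_seconds`` each.  The default layout is
12 blocks of 20 s fixation + 5 x 4 s images at TR 2 s: 480 s, 240 volumes,
with three conditions (negative / neutral / positive) balanced over blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidDesignError


def _volumes(seconds: float, tr: float, what: str) -> int:
    v = seconds / tr
    if abs(v - round(v)) > 1e-9:
        raise InvalidDesignError(
            f"{what} of {seconds} s is not a whole number of volumes at TR {tr} s"
        )
    return int(round(v))


@dataclass(frozen=True)
class TaskDesign:
    """A balanced block design.

    Attributes
    ----------
    tr_seconds : float
        Repetition time (one volume every TR).
    n_blocks : int
        Number of blocks in the run.
    images_per_block : int
        Images shown per block, all of the block's condition.
    stim_seconds : float
        Presentation time per image.
    fixation_seconds : float
        Fixation-cross time preceding each block's images.
    condition_order : tuple of str
        Condition label of each block, length ``n_blocks``.
    """

    tr_seconds: float
    n_blocks: int
    images_per_block: int
    stim_seconds: float
    fixation_seconds: float
    condition_order: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "condition_order", tuple(self.condition_order))
        if self.tr_seconds <= 0 or self.n_blocks <= 0 or self.images_per_block <= 0:
            raise InvalidDesignError("tr, n_blocks and images_per_block must be positive")
        if self.stim_seconds <= 0 or self.fixation_seconds < 0:
            raise InvalidDesignError("stim_seconds must be positive, fixation_seconds >= 0")
        if len(self.condition_order) != self.n_blocks:
            raise InvalidDesignError(
                f"condition_order has {len(self.condition_order)} entries "
                f"for {self.n_blocks} blocks"
            )
        # must tile evenly into volumes
        _volumes(self.fixation_seconds, self.tr_seconds, "fixation period")
        _volumes(self.images_per_block * self.stim_seconds, self.tr_seconds, "stimulus period")

    @property
    def conditions(self) -> tuple[str, ...]:
        """Distinct condition labels in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.condition_order:
            seen.setdefault(c)
        return tuple(seen)

    @property
    def fixation_volumes(self) -> int:
        return _volumes(self.fixation_seconds, self.tr_seconds, "fixation period")

    @property
    def stimulus_volumes(self) -> int:
        """Volumes in one block's stimulus period."""
        return _volumes(
            self.images_per_block * self.stim_seconds, self.tr_seconds, "stimulus period"
        )

    @property
    def block_volumes(self) -> int:
        return self.fixation_volumes + self.stimulus_volumes

    @property
    def n_volumes(self) -> int:
        return self.n_blocks * self.block_volumes

    @property
    def duration_seconds(self) -> float:
        return self.n_blocks * (
            self.fixation_seconds + self.images_per_block * self.stim_seconds
        )


def build_task_design(
    tr: float,
    n_blocks: int,
    images_per_block: int,
    stim_seconds: float,
    fixation_seconds: float,
    condition_labels: list[str],
    seed: int,
) -> TaskDesign:
    """Build a balanced, seed-randomized block design.

    Each condition appears exactly ``n_blocks / len(condition_labels)``
    times; the order is a seeded random permutation (a stand-in for the
    Latin-square counterbalancing typical of such designs).

    Raises
    ------
    InvalidDesignError
        If ``n_blocks`` is not divisible by the number of conditions, or
        the durations do not tile into whole volumes.
    """
    labels = list(condition_labels)
    if not labels:
        raise InvalidDesignError("at least one condition label required")
    if len(set(labels)) != len(labels):
        raise InvalidDesignError("condition labels must be distinct")
    if n_blocks % len(labels) != 0:
        raise InvalidDesignError(
            f"{n_blocks} blocks cannot be balanced over {len(labels)} conditions"
        )
    per = n_blocks // len(labels)
    order = np.array(labels * per, dtype=object)
    rng = np.random.default_rng(seed)
    rng.shuffle(order)
    return TaskDesign(
        tr_seconds=tr,
        n_blocks=n_blocks,
        images_per_block=images_per_block,
        stim_seconds=stim_seconds,
        fixation_seconds=fixation_seconds,
        condition_order=tuple(order),
    )


#: Default acquisition layout: 12 blocks x (20 s fixation + 5 x 4 s
#: images) at TR 2 s over 3 conditions = 480 s, 240 volumes.
def default_design(seed: int = 0) -> TaskDesign:
    return build_task_design(
        tr=2.0,
        n_blocks=12,
        images_per_block=5,
        stim_seconds=4.0,
        fixation_seconds=20.0,
        condition_labels=["negative", "neutral", "positive"],
        seed=seed,
    )
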