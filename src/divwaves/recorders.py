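"""Streaming observers fed by :func:`divwaves.model.simulate`.

Recorders see the saturated state after every step (``on_step``) and,
if they override it, the unsaturated populations at wave boundaries
(``on_pre_saturation`` — the moment right after a dominant collapse but
before the freed capacity is redistributed).  They accumulate summaries
in place so multi-million-step runs never hold full trajectories in
memory unless explicitly asked to (``EventLogRecorder``).
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np
import pandas as pd

from .analysis import SADHistogram

__all__ = [
    "Recorder",
    "SADRecorder",
    "SnapshotSADRecorder",
    "DiversityRecorder",
    "EventLogRecorder",
    "WaveRecorder",
    "JumpRecorder",
    "MeanPopulationRecorder",
]

EVENT_COLUMNS = (
    "step",
    "victim_index",
    "victim_species_id",
    "victim_birth_step",
    "victim_n_substantial_at_birth",
    "pre_collapse_size",
    "is_wave_boundary",
    "rescale_factor",
    "n_substantial",
)


class Recorder:
    """Base observer; all hooks are no-ops."""

    def start(self, state, params) -> None:  # noqa: D102
        pass

    def on_pre_saturation(self, populations: np.ndarray, event) -> None:
        """Called at wave boundaries with the unsaturated populations."""

    def on_step(self, state, event) -> None:  # noqa: D102
        pass

    def finish(self, state) -> None:  # noqa: D102
        pass


def _default_burn_in(burn_in: Optional[int], params) -> int:
    # transient from the uniform initial condition; discarded by default
    return 10 * params.N if burn_in is None else int(burn_in)


class SADRecorder(Recorder):
    """Time-aggregated log-binned species abundance distribution.

    Every population of every post-burn-in saturated state increments
    its log10 bin; the resulting density estimates
    ``pi(P) = dProb(P_i > P) / dlog10 P``.
    """

    def __init__(
        self,
        bins_per_decade: int = 5,
        burn_in: Optional[int] = None,
        low_edge: Optional[float] = None,
    ):
        self.bins_per_decade = bins_per_decade
        self._burn_in_arg = burn_in
        self._low_edge = low_edge
        self.histogram: Optional[SADHistogram] = None

    def start(self, state, params) -> None:
        self.burn_in = _default_burn_in(self._burn_in_arg, params)
        low = self._low_edge if self._low_edge is not None else params.gamma / 10.0
        self.histogram = SADHistogram(
            low=low, high=1.0, bins_per_decade=self.bins_per_decade
        )

    def on_step(self, state, event) -> None:
        if event.step > self.burn_in:
            self.histogram.add(state.populations)


class SnapshotSADRecorder(Recorder):
    """Wave-boundary snapshot distributions.

    ``phase='pre_rescale'`` aggregates populations at the very end of
    each wave (dominant species just collapsed, capacity not yet
    redistributed); ``phase='post_rescale'`` at the very beginning of the
    next wave, right after redistribution.
    """

    PHASES = ("pre_rescale", "post_rescale")

    def __init__(
        self,
        phase: str = "pre_rescale",
        bins_per_decade: int = 5,
        burn_in: Optional[int] = None,
    ):
        if phase not in self.PHASES:
            raise ValueError(f"phase must be one of {self.PHASES}")
        self.phase = phase
        self.bins_per_decade = bins_per_decade
        self._burn_in_arg = burn_in
        self.histogram: Optional[SADHistogram] = None

    def start(self, state, params) -> None:
        self.burn_in = _default_burn_in(self._burn_in_arg, params)
        self.histogram = SADHistogram(
            low=params.gamma / 10.0, high=1.0, bins_per_decade=self.bins_per_decade
        )

    def on_pre_saturation(self, populations, event) -> None:
        if self.phase == "pre_rescale" and event.step > self.burn_in:
            self.histogram.add(populations)

    def on_step(self, state, event) -> None:
        if (
            self.phase == "post_rescale"
            and event.is_wave_boundary
            and event.step > self.burn_in
        ):
            self.histogram.add(state.populations)


class DiversityRecorder(Recorder):
    """Per-step inverse-Simpson diversity ``D = 1/sum(P^2)`` and ``P_max``."""

    def __init__(self):
        self._diversity: List[float] = []
        self._p_max: List[float] = []

    def on_step(self, state, event) -> None:
        p = state.populations
        self._diversity.append(1.0 / float(np.dot(p, p)))
        self._p_max.append(float(p.max()))

    @property
    def diversity(self) -> np.ndarray:
        """D after step t, at index t-1."""
        return np.asarray(self._diversity)

    @property
    def p_max(self) -> np.ndarray:
        return np.asarray(self._p_max)

    def to_frame(self) -> pd.DataFrame:
        d = self.diversity
        return pd.DataFrame(
            {"step": np.arange(1, d.size + 1), "diversity": d, "p_max": self.p_max}
        )


class EventLogRecorder(Recorder):
    """Keeps every :class:`~divwaves.model.CollapseEvent` of the run."""

    def __init__(self):
        self.events: list = []

    def on_step(self, state, event) -> None:
        self.events.append(event)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {col: [getattr(e, col) for e in self.events] for col in EVENT_COLUMNS}
        )


class WaveRecorder(Recorder):
    """Wave-boundary step indices only (cheap enough for any run length)."""

    def __init__(self):
        self.boundaries: List[int] = []

    def on_step(self, state, event) -> None:
        if event.is_wave_boundary:
            self.boundaries.append(event.step)

    @property
    def durations(self) -> np.ndarray:
        return np.diff(np.asarray(self.boundaries))


class JumpRecorder(Recorder):
    """Survivor jumps ``-ln(1 - P_collapsed)`` for substantial collapses.

    Each retained event carries the time elapsed since the current wave
    started and the victim's substantial-population count at birth (the
    cross-wave memory label).  Events before the first wave boundary are
    skipped because their wave offset is undefined.
    """

    def __init__(self, substantial_threshold: Optional[float] = None):
        self._threshold_arg = substantial_threshold
        self._wave_start: Optional[int] = None
        self._t_in_wave: List[int] = []
        self._jump: List[float] = []
        self._n_sub_at_birth: List[int] = []

    def start(self, state, params) -> None:
        self.threshold = (
            params.substantial_threshold
            if self._threshold_arg is None
            else self._threshold_arg
        )

    def on_step(self, state, event) -> None:
        if self._wave_start is not None and event.pre_collapse_size > self.threshold:
            from .analysis import jump_value

            self._t_in_wave.append(event.step - self._wave_start)
            self._jump.append(
                jump_value(event.pre_collapse_size, event.rescale_factor)
            )
            self._n_sub_at_birth.append(event.victim_n_substantial_at_birth)
        if event.is_wave_boundary:
            self._wave_start = event.step

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_in_wave": self._t_in_wave,
                "jump": self._jump,
                "n_substantial_at_birth": self._n_sub_at_birth,
            }
        )


class MeanPopulationRecorder(Recorder):
    """Time-averaged population per slot, ``<P_i>_t``, after burn-in.

    Slot averages equal species averages only when identities are fixed
    (the resilience variant); that is the intended use.
    """

    def __init__(self, burn_in: Optional[int] = None):
        self._burn_in_arg = burn_in
        self._sum: Optional[np.ndarray] = None
        self.n_snapshots = 0

    def start(self, state, params) -> None:
        self.burn_in = _default_burn_in(self._burn_in_arg, params)
        self._sum = np.zeros(state.N)

    def on_step(self, state, event) -> None:
        if event.step > self.burn_in:
            self._sum += state.populations
            self.n_snapshots += 1

    @property
    def mean_populations(self) -> np.ndarray:
        if self.n_snapshots == 0:
            raise ValueError("no snapshots accumulated (run shorter than burn-in?)")
        return self._sum / self.n_snapshots
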