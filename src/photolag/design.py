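"""Time-course design for a brief light-pulse experiment.

A mycelial culture is exposed to a short light pulse and returned to
darkness; samples are harvested at fixed minutes after the pulse, separately
for the transcript and protein layers, alongside a never-exposed dark
control (DD).  Time is measured in minutes after the *end* of the pulse, so
the pulse itself occupies the interval ``[-pulse_minutes, 0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


def condition_label(minutes: float, pulse_minutes: float = 5.0) -> str:
    """Condition name for a harvest ``minutes`` after a pulse, e.g. ``5L 10D``."""
    return f"{pulse_minutes:g}L {minutes:g}D"


@dataclass(frozen=True)
class PulseDesign:
    """Design of one pulse-chase time course with a dark control.

    Parameters
    ----------
    pulse_minutes:
        Duration of the stimulus, minutes (> 0).
    transcript_times, protein_times:
        Strictly increasing, nonnegative minutes-after-pulse at which the
        transcript and protein layers are harvested.
    control_label:
        Name of the never-stimulated condition (default ``DD``).
    n_replicates:
        Independent replicate experiments per layer (>= 2).
    seed:
        Base RNG seed carried with the design for simulation.
    """

    pulse_minutes: float = 5.0
    transcript_times: tuple[float, ...] = (0.0, 10.0, 25.0, 55.0, 115.0)
    protein_times: tuple[float, ...] = (10.0, 25.0, 55.0, 115.0, 235.0)
    control_label: str = "DD"
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.pulse_minutes > 0 and math.isfinite(self.pulse_minutes)):
            raise ValueError("pulse_minutes must be positive and finite")
        for name in ("transcript_times", "protein_times"):
            times = getattr(self, name)
            if len(times) == 0:
                raise ValueError(f"{name} must not be empty")
            if any(t < 0 or not math.isfinite(t) for t in times):
                raise ValueError(f"{name} must be nonnegative and finite")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        for t in set(self.transcript_times) | set(self.protein_times):
            if self.condition_label(t) == self.control_label:
                raise ValueError("control_label collides with a pulse condition")

    # -- labels -------------------------------------------------------------

    def condition_label(self, minutes: float) -> str:
        return condition_label(minutes, self.pulse_minutes)

    def times_for(self, layer: str) -> tuple[float, ...]:
        if layer == "transcript":
            return self.transcript_times
        if layer == "protein":
            return self.protein_times
        raise ValueError(f"unknown layer {layer!r}")

    def conditions_for(self, layer: str, include_control: bool = True) -> list[str]:
        """Ordered condition labels for a layer, control first."""
        labels = [self.condition_label(t) for t in self.times_for(layer)]
        return ([self.control_label] + labels) if include_control else labels

    def condition_minutes(self, layer: str) -> dict[str, float]:
        """Map pulse-condition label -> minutes after pulse (control excluded)."""
        return {self.condition_label(t): t for t in self.times_for(layer)}

    def sample_names(self, layer: str) -> list[str]:
        return [
            f"{cond}_R{r}"
            for cond in self.conditions_for(layer)
            for r in range(1, self.n_replicates + 1)
        ]

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pulse_minutes": self.pulse_minutes,
            "transcript_times": list(self.transcript_times),
            "protein_times": list(self.protein_times),
            "control_label": self.control_label,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PulseDesign":
        d = dict(d)
        for key in ("transcript_times", "protein_times"):
            if key in d:
                d[key] = tuple(float(t) for t in d[key])
        return cls(**d)
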