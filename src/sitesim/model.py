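"""Model-level containers: perturbation events, pattern observables, and the
bundle of signatures/rules/initial state that defines a runnable model."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .core import ComplexPattern, Rule, SignatureSet, SiteGraph

__all__ = [
    "AddCopies",
    "SetCopies",
    "SetRate",
    "Event",
    "EventSchedule",
    "PatternObservable",
    "ModelDefinition",
]


@dataclass(frozen=True)
class AddCopies:
    """Add ``n`` copies of a species (by canonical id or graph expression)."""

    species: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("copies added must be nonnegative")


@dataclass(frozen=True)
class SetCopies:
    """Set the copy number of a species to ``n`` (used by SBML event import)."""

    species: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("copy numbers must be nonnegative")


@dataclass(frozen=True)
class SetRate:
    """Set the rate constant shared by every reaction carrying ``rate_id``."""

    rate_id: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("rate values must be nonnegative")


Action = Union[AddCopies, SetCopies, SetRate]


@dataclass(frozen=True)
class Event:
    time: float  # seconds
    action: Action


class EventSchedule:
    """Time-ordered perturbation events applied during a simulation.

    Models timed stimuli such as a second-messenger pulse (copy-number
    addition) or in-silico mutagenesis (zeroing a rate constant).
    """

    def __init__(self, events: Sequence[Event] = ()):
        evs = list(events)
        for a, b in zip(evs, evs[1:]):
            if b.time < a.time:
                raise ValueError("event times must be nondecreasing")
        self.events: list[Event] = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventSchedule) and self.events == other.events

    def shifted(self, dt: float) -> "EventSchedule":
        return EventSchedule([Event(e.time + dt, e.action) for e in self.events])


@dataclass(frozen=True)
class PatternObservable:
    """A tracked quantity: the tally of matches of a pattern in the mixture.

    ``mode="agent-instances"`` counts pattern embeddings (a species containing
    the motif twice contributes twice per copy); ``mode="species-copies"``
    counts copies of species containing at least one match.
    """

    name: str
    pattern: ComplexPattern
    mode: str = "agent-instances"

    def __post_init__(self) -> None:
        if self.mode not in ("agent-instances", "species-copies"):
            raise ValueError(f"unknown counting mode {self.mode!r}")


@dataclass
class ModelDefinition:
    """Signatures, rules, initial copies, observables and stimuli of one model."""

    signatures: SignatureSet
    rules: list[Rule]
    init: list[tuple[int, SiteGraph]] = field(default_factory=list)
    observables: list[PatternObservable] = field(default_factory=list)
    events: EventSchedule = field(default_factory=EventSchedule)
    snapshot_period: Optional[int] = None
    name: str = "model"
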