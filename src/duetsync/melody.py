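"""The notated stimulus melody and its rhythmic template.

Every behavioral and neural analysis stage is anchored to a fixed 32-tone
melody (a round in 4/4, note range G3-A4) made of 20 quarter notes, 4 half
notes and 8 eighth notes, for a total of 32 quarter-note beats.  The first
8 tones are all quarter notes: in duets the leader performs them alone as a
count-in that signals the beat, and the follower joins on the 9th tone.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = ["MelodyEvent", "MelodySpec", "make_melody_spec", "COUNT_IN_EVENTS"]

#: number of leading tones the leader performs alone in each duet trial
COUNT_IN_EVENTS = 8

# MIDI note numbers for the pitches used (C major, treble clef)
_G3, _C4, _D4, _E4, _F4, _G4, _A4 = 55, 60, 62, 64, 65, 67, 69


@dataclass(frozen=True)
class MelodyEvent:
    """One notated tone: pitch, duration in beats, and metrical position."""

    pitch: int
    beat_value: Fraction  # duration in quarter-note beats: 1/2, 1 or 2
    is_on_beat: bool


@dataclass(frozen=True)
class MelodySpec:
    """Ordered rhythm/pitch template that performances are aligned against."""

    events: tuple[MelodyEvent, ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def total_beats(self) -> Fraction:
        return sum((e.beat_value for e in self.events), Fraction(0))

    @property
    def pitches(self) -> tuple[int, ...]:
        return tuple(e.pitch for e in self.events)

    def beat_positions(self) -> tuple[Fraction, ...]:
        """Cumulative onset position of each event, in quarter-note beats.

        Off-beat eighth notes land on half-integer positions, i.e. at the
        temporal midpoint of their beat under isochronous subdivision.
        """
        pos = []
        acc = Fraction(0)
        for e in self.events:
            pos.append(acc)
            acc += e.beat_value
        return tuple(pos)


def make_melody_spec() -> MelodySpec:
    """Return the fixed 32-event melody template.

    Phrase structure (each phrase stated twice, as in the round):

    1. four quarters x2           -- the all-quarter count-in segment
    2. quarter, quarter, half x2
    3. four eighths + two quarters x2
    4. quarter, quarter, half x2
    """
    q, h, e = Fraction(1), Fraction(2), Fraction(1, 2)

    def phrase(spec):
        return [(p, v) for p, v in spec]

    tones: list[tuple[int, Fraction]] = []
    tones += phrase([(_C4, q), (_D4, q), (_E4, q), (_C4, q)]) * 2
    tones += phrase([(_E4, q), (_F4, q), (_G4, h)]) * 2
    tones += phrase([(_G4, e), (_A4, e), (_G4, e), (_F4, e), (_E4, q), (_C4, q)]) * 2
    tones += phrase([(_C4, q), (_G3, q), (_C4, h)]) * 2

    events = []
    acc = Fraction(0)
    for pitch, bv in tones:
        events.append(MelodyEvent(pitch=pitch, beat_value=bv, is_on_beat=acc.denominator == 1))
        acc += bv
    return MelodySpec(events=tuple(events))
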