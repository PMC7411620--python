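"""Russell-quadrant emotion labeling of SAM valence/arousal ratings.

The Self-Assessment Manikin (SAM) yields integer valence and arousal
scores on a 1-9 scale.  Russell's circumplex model partitions the
valence-arousal plane into four quadrants:

* high valence, high arousal  -> happy
* low  valence, high arousal  -> angry
* low  valence, low  arousal  -> sad
* high valence, low  arousal  -> relaxed

Scores equal to the midpoint (5) are assigned to the "low" side; the
midpoint policy is explicit in :func:`label_emotion` and documented so
downstream counts are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

#: Canonical class order used by every confusion matrix and probability
#: vector in this package.
EMOTIONS: tuple[str, ...] = ("relaxed", "sad", "happy", "angry")


@dataclass(frozen=True)
class SAMRating:
    """One session's SAM self-report: integer valence and arousal in [1, 9]."""

    valence: int
    arousal: int

    def __post_init__(self) -> None:
        for name, v in (("valence", self.valence), ("arousal", self.arousal)):
            if not 1 <= v <= 9:
                raise ValueError(f"{name} must be in [1, 9], got {v}")


def label_emotion(rating: SAMRating, midpoint: float = 5) -> str:
    """Map a SAM rating to one of the four quadrant emotions.

    Scores strictly above ``midpoint`` count as "high"; scores at or
    below it count as "low" (so a rating of exactly 5 falls on the
    low side of both axes and labels as sad).
    """
    high_v = rating.valence > midpoint
    high_a = rating.arousal > midpoint
    if high_v and high_a:
        return "happy"
    if not high_v and high_a:
        return "angry"
    if not high_v and not high_a:
        return "sad"
    return "relaxed"


def label_dataset(
    ratings: list[SAMRating], midpoint: float = 5
) -> tuple[list[str], dict[str, int]]:
    """Label every rating and tally class counts in canonical order.

    Returns ``(labels, counts)`` where ``counts`` maps each emotion in
    :data:`EMOTIONS` order to its number of sessions (0 for empty
    quadrants).
    """
    if not ratings:
        raise ValueError("ratings must be nonempty")
    labels = [label_emotion(r, midpoint) for r in ratings]
    tally = Counter(labels)
    counts = {emotion: tally.get(emotion, 0) for emotion in EMOTIONS}
    return labels, counts
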