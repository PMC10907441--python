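"""The lexical availability index.

A word is "available" to the degree that informants produce it, and produce
it *early*: availability weights each occurrence by an exponential decay in
its list position.  For word j with positional frequencies f_ji (number of
informants producing j at position i), sample-wide maximal position n and
informant count I1, the index is

    D(P_j) = sum_{i=1..n}  exp(-lambda * (i-1)/(n-1)) * f_ji / I1

with the conventional decay constant lambda = 2.3 (Strassburger &
Lopez Chavez).  D lies in (0, 1]: a word produced first by every informant
scores exactly 1, and D is bounded above by the word's relative frequency.
When n = 1 the exponent is taken as 0 (the i = 1 limit), so D reduces to
relative frequency.

The reference corpora leave ambiguous whether n is the longest chain in the
sample or the last position at which the *word itself* appears; the
sample-wide reading is the standard one and the default here, with
``per_word_n`` switching to the alternative.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import Corpus

__all__ = [
    "AvailabilityRecord",
    "AvailabilityParams",
    "PositionalProfiles",
    "positional_frequencies",
    "availability_index",
    "write_availability",
]

DEFAULT_DECAY = 2.3


@dataclass(frozen=True)
class AvailabilityParams:
    """Decay constant, sample-wide maximal position n, informant count I1."""

    n: int
    informant_count: int
    decay: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        if self.n < 1 or self.informant_count < 1 or self.decay <= 0:
            raise ValueError("need n >= 1, informant_count >= 1, decay > 0")


@dataclass(frozen=True)
class AvailabilityRecord:
    word: str
    availability: float
    frequencies: dict = field(compare=False)

    @property
    def total_frequency(self) -> int:
        return sum(self.frequencies.values())

    @property
    def max_position_reached(self) -> int:
        return max(self.frequencies)


@dataclass(frozen=True)
class PositionalProfiles:
    """f_ji for every word j, plus the sample-wide n and informant count."""

    profiles: dict
    n: int
    informant_count: int


def positional_frequencies(corpus: Corpus) -> PositionalProfiles:
    """Tally f_ji = number of chains in which word j occupies position i."""
    profiles: dict[str, Counter] = {}
    n = 0
    for chain in corpus.chains:
        n = max(n, len(chain))
        for i, word in enumerate(chain.words, start=1):
            profiles.setdefault(word, Counter())[i] += 1
    return PositionalProfiles(
        {w: dict(c) for w, c in profiles.items()}, n, corpus.informant_count
    )


def _index_one(freqs: dict, n: int, i1: int, decay: float) -> float:
    if n == 1:
        return sum(freqs.values()) / i1
    return sum(
        math.exp(-decay * (i - 1) / (n - 1)) * f / i1 for i, f in freqs.items()
    )


def availability_index(
    profiles: PositionalProfiles,
    params: AvailabilityParams | None = None,
    per_word_n: bool = False,
) -> list[AvailabilityRecord]:
    """Availability index per word, sorted by D descending (ties lexicographic).

    ``per_word_n`` replaces the sample-wide n by each word's own maximal
    position — the alternative reading of the formula's n; it makes D
    insensitive to how long *other* informants' chains run.
    """
    if params is None:
        params = AvailabilityParams(profiles.n, profiles.informant_count)
    records = []
    for word, freqs in profiles.profiles.items():
        if max(freqs) > params.n:
            raise ValueError(
                f"word {word!r} occurs at position {max(freqs)} > n = {params.n}"
            )
        n = max(freqs) if per_word_n else params.n
        d = _index_one(freqs, n, params.informant_count, params.decay)
        records.append(AvailabilityRecord(word, d, freqs))
    records.sort(key=lambda r: (-r.availability, r.word))
    return records


def write_availability(records: list[AvailabilityRecord], path: str | Path) -> None:
    """CSV ``rank,word,availability,total_frequency``, highest index first."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rank", "word", "availability", "total_frequency"])
        for rank, rec in enumerate(records, start=1):
            w.writerow([rank, rec.word, f"{rec.availability:.6f}", rec.total_frequency])
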