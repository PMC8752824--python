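"""Information entropy of sub-segmentation experiments.

A region of ``L`` consecutive design units can be tiled by all
``L - n + 1`` stride-1 windows of length ``n``. Each unit ``i`` is then
contained in a fraction ``P_i`` of the tested constructs, and the
experiment's information content is scored as

    entropy(L, n) = -sum_{i=1..L} P_i * log2(P_i)   [bits]

Note that the ``P_i`` are inclusion fractions, not a probability
distribution (they sum to ``n``, not 1); the score is applied to them
directly. The inclusion fraction has the closed form

    P_i = min(i, n, L - i + 1, L - n + 1) / (L - n + 1)

which the test suite cross-checks against brute-force window enumeration.
Lengths within a tolerance (default 90%) of the maximal entropy are
"admissible": they buy near-maximal information while letting the caller
prefer larger, better-folding sub-segments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

#: Relative epsilon for the tolerance threshold, guarding against float
#: boundary exclusions of exactly-at-threshold lengths.
_REL_EPS = 1e-9


def inclusion_fractions(L: int, n: int) -> list[Fraction]:
    """Exact fraction of length-``n`` windows containing each unit ``i``.

    Parameters
    ----------
    L:
        Region length in units.
    n:
        Sub-segment length, ``1 <= n <= L``.
    """
    _validate(L, n)
    n_constructs = L - n + 1
    return [
        Fraction(min(i, n, L - i + 1, n_constructs), n_constructs)
        for i in range(1, L + 1)
    ]


def segmentation_entropy(L: int, n: int) -> float:
    """Entropy in bits of the length-``n`` tiling of an ``L``-unit region."""
    total = 0.0
    for p in inclusion_fractions(L, n):
        if p != 1:  # 1*log2(1) = 0 by convention
            pf = float(p)
            total -= pf * math.log2(pf)
    return total


@dataclass(frozen=True)
class EntropyEntry:
    """Design metrics for one candidate sub-segment length."""

    n: int
    n_constructs: int
    inclusion_fractions: tuple[Fraction, ...]
    entropy_bits: float


@dataclass(frozen=True)
class EntropyProfile:
    """Entropy of every sub-segment length ``n = 1..L`` for a region."""

    region_length: int
    entries: tuple[EntropyEntry, ...]

    def entry(self, n: int) -> EntropyEntry:
        return self.entries[n - 1]

    @property
    def max_entropy(self) -> float:
        return max(e.entropy_bits for e in self.entries)

    @property
    def argmax_n(self) -> int:
        """Entropy-maximal length; ties break toward the larger ``n``
        (larger sub-segments fold in a more native-like environment)."""
        best = self.max_entropy
        return max(e.n for e in self.entries if e.entropy_bits == best)

    def admissible(self, tolerance: float) -> list[int]:
        return admissible_lengths(self, tolerance)


def entropy_profile(L: int) -> EntropyProfile:
    """Profile over all sub-segment lengths ``1..L``."""
    if L < 1:
        raise ValueError(f"region length must be >= 1, got {L}")
    entries = []
    for n in range(1, L + 1):
        fracs = tuple(inclusion_fractions(L, n))
        entries.append(
            EntropyEntry(
                n=n,
                n_constructs=L - n + 1,
                inclusion_fractions=fracs,
                entropy_bits=segmentation_entropy(L, n),
            )
        )
    return EntropyProfile(region_length=L, entries=tuple(entries))


def admissible_lengths(profile: EntropyProfile, tolerance: float) -> list[int]:
    """Lengths whose entropy reaches ``tolerance``x the profile maximum.

    ``tolerance`` is a fraction in (0, 1]; the comparison applies a small
    relative epsilon so lengths sitting exactly on the threshold are kept.
    """
    if not 0 < tolerance <= 1:
        raise ValueError(f"tolerance must be in (0, 1], got {tolerance}")
    threshold = tolerance * profile.max_entropy * (1 - _REL_EPS)
    return [e.n for e in profile.entries if e.entropy_bits >= threshold]


def _validate(L: int, n: int) -> None:
    if L < 1:
        raise ValueError(f"region length must be >= 1, got {L}")
    if not 1 <= n <= L:
        raise ValueError(f"sub-segment length n={n} outside [1, L={L}]")
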