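"""Modular repeat-protein model and construct assembly.

A repeat protein (the motivating case is a leucine-rich-repeat receptor
ectodomain) is represented as an ordered chain of design *units*: the
repeats ``1..R``, plus an optional non-repeat "loopout" insertion that
occupies one pseudo-unit slot between two repeats. N- and C-terminal cap
sequences bury the hydrophobic cores of the outermost repeats and are
appended to every construct.

All design and statistics operations work on unit indices alone; amino-acid
sequences are optional and only required for construct assembly and FASTA
export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Label of the loopout pseudo-unit in unit orderings and window bounds.
LOOPOUT = "l/o"

#: A design unit: a 1-based repeat index, or the loopout label.
Unit = Union[int, str]


class SequenceUnavailableError(ValueError):
    """Raised when assembly needs a sequence the protein does not carry."""


def _unit_str(unit: Unit) -> str:
    return LOOPOUT if unit == LOOPOUT else str(unit)


@dataclass(frozen=True)
class Loopout:
    """A non-repeat insertion sitting immediately after ``after_repeat``."""

    after_repeat: int
    seq: str | None = None


@dataclass(frozen=True)
class UnitWindow:
    """A contiguous, inclusive run of units, e.g. repeats 6-10 or l/o-31.

    Contiguity is defined by the protein's unit ordering; use
    :meth:`RepeatProtein.window` to construct validated windows.
    """

    start_unit: Unit
    end_unit: Unit

    @property
    def label(self) -> str:
        return f"{_unit_str(self.start_unit)}-{_unit_str(self.end_unit)}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class RepeatProtein:
    """Ordered modular units of a repeat protein: caps, repeats, loopout.

    Parameters
    ----------
    name:
        Identifier used in FASTA headers and artifact metadata.
    n_repeats:
        Number of repeat units (e.g. 31 for the LeEIX2 demo).
    repeat_seqs:
        Optional per-repeat amino-acid sequences, length ``n_repeats``.
    ncap_seq, ccap_seq:
        Optional terminal cap sequences appended to every construct.
    loopout:
        Optional loopout pseudo-unit; its position must leave at least one
        repeat on each side.
    """

    name: str
    n_repeats: int
    repeat_seqs: tuple[str, ...] | None = None
    ncap_seq: str | None = None
    ccap_seq: str | None = None
    loopout: Loopout | None = None

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        if self.repeat_seqs is not None:
            object.__setattr__(self, "repeat_seqs", tuple(self.repeat_seqs))
            if len(self.repeat_seqs) != self.n_repeats:
                raise ValueError(
                    f"repeat_seqs has {len(self.repeat_seqs)} entries, "
                    f"expected n_repeats={self.n_repeats}"
                )
        if self.loopout is not None:
            pos = self.loopout.after_repeat
            if not 1 <= pos <= self.n_repeats - 1:
                raise ValueError(
                    f"loopout.after_repeat={pos} outside [1, {self.n_repeats - 1}]"
                )

    # -- unit ordering -------------------------------------------------

    def unit_order(self) -> tuple[Unit, ...]:
        """Linearized design units: repeats in index order, loopout interleaved."""
        units: list[Unit] = []
        for i in range(1, self.n_repeats + 1):
            units.append(i)
            if self.loopout is not None and self.loopout.after_repeat == i:
                units.append(LOOPOUT)
        return tuple(units)

    @property
    def n_units(self) -> int:
        return self.n_repeats + (1 if self.loopout is not None else 0)

    def ordinal(self, unit: Unit) -> int:
        """0-based position of a unit in the ordering."""
        try:
            return self.unit_order().index(unit)
        except ValueError:
            raise KeyError(f"unknown unit {unit!r} for protein {self.name}") from None

    def unit_at(self, pos: int) -> Unit:
        order = self.unit_order()
        if not 0 <= pos < len(order):
            raise IndexError(f"ordinal {pos} outside [0, {len(order) - 1}]")
        return order[pos]

    # -- windows -------------------------------------------------------

    def window(self, start_unit: Unit, end_unit: Unit) -> UnitWindow:
        """Validated inclusive window; start must not come after end."""
        a, b = self.ordinal(start_unit), self.ordinal(end_unit)
        if a > b:
            raise ValueError(f"window start {start_unit} after end {end_unit}")
        return UnitWindow(start_unit, end_unit)

    def window_from_ordinals(self, a: int, b: int) -> UnitWindow:
        return self.window(self.unit_at(a), self.unit_at(b))

    def window_ordinals(self, window: UnitWindow) -> range:
        return range(self.ordinal(window.start_unit), self.ordinal(window.end_unit) + 1)

    def window_units(self, window: UnitWindow) -> tuple[Unit, ...]:
        order = self.unit_order()
        return tuple(order[p] for p in self.window_ordinals(window))

    def window_length(self, window: UnitWindow) -> int:
        """Number of design units covered (loopout counts as one unit)."""
        return len(self.window_ordinals(window))

    def full_window(self) -> UnitWindow:
        return self.window(1, self.n_repeats)

    # -- sequences -----------------------------------------------------

    def unit_seq(self, unit: Unit) -> str:
        if unit == LOOPOUT:
            if self.loopout is None or self.loopout.seq is None:
                raise SequenceUnavailableError(
                    f"sequences unavailable: loopout of {self.name}"
                )
            return self.loopout.seq
        if self.repeat_seqs is None:
            raise SequenceUnavailableError(
                f"sequences unavailable: repeat {unit} of {self.name}"
            )
        return self.repeat_seqs[int(unit) - 1]

    def cap_seq(self, which: str) -> str:
        seq = self.ncap_seq if which == "N" else self.ccap_seq
        if seq is None:
            raise SequenceUnavailableError(
                f"sequences unavailable: {which}-cap of {self.name}"
            )
        return seq


@dataclass(frozen=True)
class ConstructDesign:
    """One testable construct: a contiguous unit window with caps appended."""

    construct_id: str
    window: UnitWindow
    protein: RepeatProtein
    include_caps: bool = True


def unit_order(protein: RepeatProtein) -> tuple[Unit, ...]:
    """Ordered unit identifiers of the protein (repeats + loopout)."""
    return protein.unit_order()


def assemble_construct(design: ConstructDesign) -> str:
    """Amino-acid sequence of a construct: N-cap + window units + C-cap.

    Raises
    ------
    SequenceUnavailableError
        If a cap or any unit in the window lacks a sequence; the message
        names the missing unit.
    """
    protein = design.protein
    parts: list[str] = []
    if design.include_caps:
        parts.append(protein.cap_seq("N"))
    for unit in protein.window_units(design.window):
        parts.append(protein.unit_seq(unit))
    if design.include_caps:
        parts.append(protein.cap_seq("C"))
    return "".join(parts)


def write_constructs_fasta(
    designs: Sequence[ConstructDesign], path: str | Path
) -> None:
    """Write constructs as a multi-FASTA (60-column wrapped), in plan order."""
    if not designs:
        logger.warning("writing empty FASTA: no constructs given")
    records = [
        SeqRecord(
            Seq(assemble_construct(d)),
            id=d.construct_id,
            description=f"{d.protein.name} units {d.window.label}",
        )
        for d in designs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")
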