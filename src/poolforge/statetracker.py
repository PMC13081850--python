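"""Integer state algebra for library computation graphs.

Every sequence in a designed pool is indexed by a single non-negative
integer, its *state*.  An operation that combines an internal choice with
choices made by its input pools spans a Cartesian product of state
spaces; an operation that merges pools side by side spans a disjoint
union.  The functions here implement the bijections between a combined
state and its parts, using arbitrary-precision integers so that
combinatorial libraries far beyond 2**63 sequences are indexed exactly.

Digit convention (product layouts): the internal state is the least
significant digit; input pools follow in declaration order with
increasing significance.  Consecutive states therefore enumerate an
operation's own variants before advancing any parent.

Offset convention (union layouts): inputs occupy consecutive state
blocks in declaration order.

The inactive marker for union branches that receive no state is
:data:`INACTIVE` (``None``).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from math import prod

__all__ = [
    "INACTIVE",
    "StateRangeError",
    "ProductLayout",
    "UnionLayout",
    "Decomposition",
    "decompose_product",
    "compose_product",
    "decompose_union",
    "compose_union",
]

#: Marker placed in a decomposition slot whose branch receives no state.
INACTIVE = None


class StateRangeError(ValueError):
    """A state or digit fell outside the cardinality that bounds it."""


@dataclass(frozen=True)
class ProductLayout:
    """Mixed-radix layout: internal choices x one choice per input pool."""

    internal_cardinality: int
    input_cardinalities: tuple[int, ...]

    def __init__(self, internal_cardinality: int, input_cardinalities=()):
        if internal_cardinality < 1:
            raise ValueError("internal_cardinality must be >= 1")
        cards = tuple(int(c) for c in input_cardinalities)
        if any(c < 1 for c in cards):
            raise ValueError("input cardinalities must be >= 1")
        object.__setattr__(self, "internal_cardinality", int(internal_cardinality))
        object.__setattr__(self, "input_cardinalities", cards)

    @property
    def total(self) -> int:
        return self.internal_cardinality * prod(self.input_cardinalities)


@dataclass(frozen=True)
class UnionLayout:
    """Disjoint-union layout: inputs occupy consecutive state blocks."""

    input_cardinalities: tuple[int, ...]
    offsets: tuple[int, ...]

    def __init__(self, input_cardinalities):
        cards = tuple(int(c) for c in input_cardinalities)
        if not cards:
            raise ValueError("union layout needs at least one input")
        if any(c < 0 for c in cards):
            raise ValueError("input cardinalities must be >= 0")
        offs = [0]
        for c in cards:
            offs.append(offs[-1] + c)
        object.__setattr__(self, "input_cardinalities", cards)
        object.__setattr__(self, "offsets", tuple(offs))

    @property
    def total(self) -> int:
        return self.offsets[-1]


@dataclass(frozen=True)
class Decomposition:
    """A state split into an internal digit plus one slot per input.

    For product layouts every slot holds an integer.  For union layouts
    exactly one slot holds an integer and the rest hold :data:`INACTIVE`;
    there is no internal digit.
    """

    internal_state: int | None
    component_states: tuple[int | None, ...]


def decompose_product(s: int, layout: ProductLayout) -> Decomposition:
    """Split ``s`` into (internal digit, one digit per input).

    Inverse of :func:`compose_product` under the documented digit order.
    """
    if not 0 <= s < layout.total:
        raise StateRangeError(
            f"state {s} out of range for product layout of cardinality {layout.total}"
        )
    internal = s % layout.internal_cardinality
    rest = s // layout.internal_cardinality
    comps = []
    for c in layout.input_cardinalities:
        comps.append(rest % c)
        rest //= c
    return Decomposition(internal, tuple(comps))


def compose_product(d: Decomposition, layout: ProductLayout) -> int:
    """Recombine digits into a single state (inverse of decomposition)."""
    if d.internal_state is None or not 0 <= d.internal_state < layout.internal_cardinality:
        raise StateRangeError(
            f"internal digit {d.internal_state} out of range "
            f"for radix {layout.internal_cardinality}"
        )
    if len(d.component_states) != len(layout.input_cardinalities):
        raise StateRangeError("component count does not match layout")
    s = 0
    weight = layout.internal_cardinality
    for digit, card in zip(d.component_states, layout.input_cardinalities):
        if digit is INACTIVE or not 0 <= digit < card:
            raise StateRangeError(f"digit {digit} out of range for radix {card}")
        s += digit * weight
        weight *= card
    return s + d.internal_state


def decompose_union(s: int, layout: UnionLayout) -> Decomposition:
    """Select the unique input block containing ``s``.

    The active slot receives ``s`` minus its block offset; every other
    slot receives :data:`INACTIVE`.  Union operations keep no internal
    digit.
    """
    if not 0 <= s < layout.total:
        raise StateRangeError(
            f"state {s} out of range for union layout of cardinality {layout.total}"
        )
    # offsets[0] == 0, so the block index is the rightmost offset <= s
    i = bisect_right(layout.offsets, s) - 1
    # skip empty blocks that share an offset with their successor
    while layout.input_cardinalities[i] == 0:
        i += 1
    comps: list[int | None] = [INACTIVE] * len(layout.input_cardinalities)
    comps[i] = s - layout.offsets[i]
    return Decomposition(None, tuple(comps))


def compose_union(d: Decomposition, layout: UnionLayout) -> int:
    """Recombine a union decomposition into a single state."""
    active = [
        (i, st) for i, st in enumerate(d.component_states) if st is not INACTIVE
    ]
    if len(active) != 1:
        raise StateRangeError("union decomposition must have exactly one active slot")
    i, st = active[0]
    if not 0 <= st < layout.input_cardinalities[i]:
        raise StateRangeError(
            f"digit {st} out of range for radix {layout.input_cardinalities[i]}"
        )
    return layout.offsets[i] + st
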