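"""Pools, the Operation contract, and lazy per-state sequence generation.

A library design is a directed acyclic graph in which each *Operation*
consumes zero or more *Pools* and produces exactly one Pool.  A Pool is
a virtual collection of sequences indexed by integer states; nothing is
generated until a specific state is requested.

Generating state ``s`` of a root Pool runs two passes:

* **backward** — ``s`` propagates root-to-leaves, each Operation
  decomposing the state it receives into an internal state (kept) plus
  component states handed to its inputs (inactive union branches
  receive no state);
* **forward** — each Operation constructs its output
  :class:`~poolforge.seqmodel.TaggedSequence` from its internal state
  and its inputs' sequences, appending tracked variables to the design
  card and emitting a name token.

``generate`` is a pure function of ``(pool, state, master_seed)``: every
random draw is keyed by a stable hash of the master seed, the node's
topology-derived identifier, and the internal state, so results do not
depend on call order or process identity.
"""

from __future__ import annotations

import hashlib
import random
import warnings
from dataclasses import dataclass

import numpy as np

from .statetracker import (
    INACTIVE,
    Decomposition,
    ProductLayout,
    StateRangeError,
    decompose_product,
)
from .seqmodel import Style, TaggedSequence
from . import metadata

__all__ = [
    "GraphError",
    "GenerationError",
    "Operation",
    "Pool",
    "GenerationResult",
    "pool_size",
    "generate",
    "print_dag",
    "sample_library",
    "construction_count",
    "reset_construction_count",
]


class GraphError(ValueError):
    """The graph of Pools and Operations is invalid (cycle, bad wiring)."""


class GenerationError(RuntimeError):
    """Sequence construction failed; carries (node_id, state) context."""

    def __init__(self, node_id: str, state: int, message: str):
        super().__init__(f"[node {node_id}, state {state}] {message}")
        self.node_id = node_id
        self.state = state


# number of Operation.construct calls since the last reset; used to verify
# that size queries never build sequences
_construction_count = 0


def construction_count() -> int:
    return _construction_count


def reset_construction_count() -> None:
    global _construction_count
    _construction_count = 0


def derive_seed(master_seed: int, node_id: str, internal, salt: str = "") -> int:
    """Stable 63-bit stream seed for one (node, internal state) draw."""
    payload = f"{master_seed}|{node_id}|{internal}|{salt}".encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") >> 1


class OpContext:
    """Per-invocation context handed to ``Operation.construct``.

    Exposes the node identifier, the state the operation received, its
    internal state, the resolved component states, a keyed RNG, and
    ``record`` for design-card variables.
    """

    __slots__ = ("node_id", "state", "internal", "components", "master_seed",
                 "_rng", "_records")

    def __init__(self, node_id, state, internal, master_seed):
        self.node_id = node_id
        self.state = state
        self.internal = internal
        self.components = ()
        self.master_seed = master_seed
        self._rng = None
        self._records: list[tuple[str, object]] = []

    def rng(self) -> np.random.Generator:
        """Numpy generator keyed by (master_seed, node_id, internal)."""
        if self._rng is None:
            self._rng = np.random.default_rng(
                derive_seed(self.master_seed, self.node_id, self.internal)
            )
        return self._rng

    def pyrandom(self, salt: str = "") -> random.Random:
        """Arbitrary-precision RNG for draws over huge integer ranges."""
        return random.Random(
            derive_seed(self.master_seed, self.node_id, self.internal, salt)
        )

    def record(self, name: str, value) -> None:
        self._records.append((name, value))


class Operation:
    """Base class for all graph operations.

    Subclasses declare ``kind`` and ``mode`` (sequential / random /
    fixed), an ``internal_cardinality`` (1 for fixed mode), and implement
    :meth:`construct`.  The default layout is the Cartesian product of
    the internal state space and the input pools' state spaces; override
    :meth:`output_cardinality` / :meth:`decompose` for other topologies.
    """

    kind = "op"
    mode = "fixed"
    internal_cardinality: int = 1
    #: design-card variable names this operation may record (unqualified)
    card_fields: tuple[str, ...] = ()
    #: whether the name token precedes its inputs' tokens (stack branches)
    token_first = False

    def __init__(self, inputs=(), *, prefix: str | None = None,
                 style: Style | None = None, params: dict | None = None):
        self.inputs: tuple[Pool, ...] = tuple(inputs)
        if any(not isinstance(p, Pool) for p in self.inputs):
            raise GraphError(f"{self.kind}: inputs must be Pools")
        self.prefix = prefix
        self.style = style
        self._params = dict(params or {})

    # -- layout ------------------------------------------------------------

    def layout(self) -> ProductLayout:
        return ProductLayout(
            self.internal_cardinality, tuple(p.size for p in self.inputs)
        )

    def output_cardinality(self) -> int:
        return self.layout().total

    def decompose(self, s: int) -> Decomposition:
        return decompose_product(s, self.layout())

    def resolve_components(self, ctx: OpContext, d: Decomposition):
        """Hook: operations whose input choice is seeded rather than
        state-indexed may replace inactive slots with drawn states."""
        return d.component_states

    # -- construction ------------------------------------------------------

    def construct(self, ctx: OpContext, inputs) -> TaggedSequence:
        raise NotImplementedError

    # -- metadata ----------------------------------------------------------

    def own_token(self, ctx: OpContext, d: Decomposition) -> str | None:
        if self.prefix is None:
            return None
        return metadata.render_token(self.prefix, d.internal_state or 0,
                                     self.internal_cardinality)

    def describe_params(self) -> dict:
        """Constructor parameters, for design-file serialization."""
        return dict(self._params)


@dataclass(frozen=True)
class GenerationResult:
    """One generated sequence with its name and design card."""

    sequence: TaggedSequence
    name: str
    card: dict
    state: int


@dataclass(frozen=True)
class _NodeResult:
    seq: TaggedSequence
    card_items: tuple
    tokens: tuple  # (prefix_or_None, token_string) pairs


class Pool:
    """A DAG node: the output of exactly one Operation.

    Exposes lazy ``size`` and per-state generation.  Pools are cheap
    handles; sequences exist only while a state is being generated.
    """

    __slots__ = ("op", "_size", "_cache", "_node_ids", "_schema")

    def __init__(self, op: Operation):
        self.op = op
        self._size = None
        self._cache: dict = {}
        self._node_ids = None
        self._schema = None

    # -- size --------------------------------------------------------------

    @property
    def size(self) -> int:
        if self._size is None:
            _check_acyclic(self)
            self._size = self.op.output_cardinality()
        return self._size

    # -- generation --------------------------------------------------------

    def generate(self, state: int, master_seed: int = 0) -> GenerationResult:
        return generate(self, state, master_seed)

    def peek(self, state: int = 0, master_seed: int = 0) -> TaggedSequence:
        """Sequence only (used for structural probes)."""
        return generate(self, state, master_seed).sequence

    def iter_results(self, master_seed: int = 0, states=None):
        ids = _node_ids(self)
        schema = _card_schema(self)
        size = self.size
        if states is None:
            states = range(size)
        for s in states:
            yield _finalize(self, s, master_seed, ids, schema, size)

    def sample(self, n: int, master_seed: int = 0):
        return sample_library(self, n, master_seed)

    def print_dag(self) -> str:
        return print_dag(self)

    def to_frame(self, master_seed: int = 0, states=None):
        """Compile generated sequences and design cards into a DataFrame."""
        return metadata.compile_cards(
            list(self.iter_results(master_seed, states))
        )

    def __repr__(self):
        return f"<Pool {self.op.kind} size={self.size}>"


# ---------------------------------------------------------------------------
# graph walks


def _topo_order(root: Pool) -> list[Pool]:
    """Leaves-first topological order; inputs in declaration order."""
    order: list[Pool] = []
    seen: set[int] = set()

    def visit(p: Pool, path: tuple[int, ...]):
        if id(p) in path:
            raise GraphError("cycle detected in design graph")
        if id(p) in seen:
            return
        for child in p.op.inputs:
            visit(child, path + (id(p),))
        seen.add(id(p))
        order.append(p)

    visit(root, ())
    return order


def _check_acyclic(root: Pool) -> None:
    _topo_order(root)


def _node_ids(root: Pool) -> dict[int, str]:
    """Stable topology-derived node identifiers (never runtime identity)."""
    if root._node_ids is None:
        ids = {}
        for i, p in enumerate(_topo_order(root)):
            label = p.op.prefix or p.op.kind
            ids[id(p)] = f"n{i}.{label}"
        root._node_ids = ids
    return root._node_ids


def _card_schema(root: Pool) -> list[str]:
    """Qualified card variable names for every node, leaves first."""
    if root._schema is None:
        ids = _node_ids(root)
        schema: list[str] = []
        for p in _topo_order(root):
            qual = p.op.prefix if p.op.prefix is not None else ids[id(p)]
            for f in p.op.card_fields:
                key = f"{qual}.{f}"
                if key not in schema:
                    schema.append(key)
        root._schema = schema
    return root._schema


# ---------------------------------------------------------------------------
# generation engine


def _generate_node(pool: Pool, state: int, master_seed: int, ids) -> _NodeResult:
    nid = ids[id(pool)]
    key = (state, master_seed, nid)
    hit = pool._cache.get(key)
    if hit is not None:
        return hit
    op = pool.op
    if not 0 <= state < pool.size:
        raise StateRangeError(
            f"state {state} out of range for pool {nid} of cardinality {pool.size}"
        )
    d = op.decompose(state)
    ctx = OpContext(nid, state, d.internal_state, master_seed)
    comps = op.resolve_components(ctx, d)
    ctx.components = tuple(comps)
    parts = [
        None if cs is INACTIVE else _generate_node(child, cs, master_seed, ids)
        for child, cs in zip(op.inputs, comps)
    ]
    global _construction_count
    _construction_count += 1
    try:
        seq = op.construct(ctx, [p.seq if p is not None else None for p in parts])
    except (GenerationError, StateRangeError):
        raise
    except Exception as exc:  # attach graph context to construction failures
        raise GenerationError(nid, state, str(exc)) from exc

    items: list[tuple[str, object]] = []
    for p in parts:
        if p is not None:
            items.extend(p.card_items)
    cp = op.prefix if op.prefix is not None else nid
    items.extend((f"{cp}.{name}", value) for name, value in ctx._records)

    tokens: list[tuple[str, str | None, str]] = []
    own = op.own_token(ctx, d)
    if own is not None and op.token_first:
        tokens.append((nid, op.prefix, own))
    for p in parts:
        if p is not None:
            tokens.extend(p.tokens)
    if own is not None and not op.token_first:
        tokens.append((nid, op.prefix, own))

    res = _NodeResult(seq, tuple(items), tuple(tokens))
    if len(pool._cache) >= 128:
        pool._cache.clear()
    pool._cache[key] = res
    return res


def _finalize(pool, state, master_seed, ids, schema, size) -> GenerationResult:
    nr = _generate_node(pool, state, master_seed, ids)
    card = dict.fromkeys(schema)
    # depth-first order; a node reached twice (diamond DAG) writes last
    for k, v in nr.card_items:
        card[k] = v
    owners: dict[str, str] = {}
    for nid, pfx, _ in nr.tokens:
        if pfx is None:
            continue
        if owners.setdefault(pfx, nid) != nid:
            # one node reached twice (diamond) may repeat its token, but
            # two different operations must not share a prefix
            raise metadata.IntegrityError(
                f"prefix {pfx!r} used by two operations on one active path"
            )
    if nr.tokens:
        name = ".".join(t for _, _, t in nr.tokens)
    else:
        name = "s" + str(state).zfill(max(2, len(str(size - 1))))
    return GenerationResult(nr.seq, name, card, state)


def generate(pool: Pool, state: int, master_seed: int = 0) -> GenerationResult:
    """Generate one sequence; pure in (pool, state, master_seed)."""
    ids = _node_ids(pool)
    return _finalize(pool, state, master_seed, ids, _card_schema(pool),
                     pool.size)


def pool_size(pool: Pool) -> int:
    """Total cardinality from the layout algebra alone (O(nodes))."""
    return pool.size


# ---------------------------------------------------------------------------
# inspection and sampling


def print_dag(root: Pool) -> str:
    """Deterministic indented listing of the DAG, leaves first.

    One line per node (kind, mode, cardinality, inputs) plus a final
    root summary line.
    """
    order = _topo_order(root)
    index = {id(p): i for i, p in enumerate(order)}
    depth: dict[int, int] = {}
    for p in order:
        depth[id(p)] = 1 + max((depth[id(c)] for c in p.op.inputs), default=-1)
    maxd = max(depth.values())
    lines = []
    for p in order:
        op = p.op
        indent = "  " * (maxd - depth[id(p)])
        parts = [f"[{index[id(p)]}] {op.kind}", f"mode={op.mode}", f"size={p.size}"]
        if op.inputs:
            parts.append("inputs=[" + ",".join(str(index[id(c)]) for c in op.inputs) + "]")
        if op.prefix:
            parts.append(f"prefix={op.prefix}")
        lines.append(indent + "  ".join(parts))
    lines.append(f"root: [{index[id(root)]}] size={root.size}")
    return "\n".join(lines)


def sample_library(pool: Pool, n: int, master_seed: int = 0):
    """Seeded sample of ``n`` states without replacement, in state order."""
    if n < 1:
        raise ValueError("n must be >= 1")
    size = pool.size
    if n >= size:
        if n > size:
            warnings.warn(
                f"requested {n} sequences from a pool of {size}; returning all",
                stacklevel=2,
            )
        states = range(size)
    else:
        rnd = random.Random(derive_seed(master_seed, "sample_library", n))
        chosen: set[int] = set()
        while len(chosen) < n:
            chosen.add(rnd.randrange(size))
        states = sorted(chosen)
    return list(pool.iter_results(master_seed, states))
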