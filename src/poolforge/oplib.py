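"""The operation catalog: source, transformation, composition, and state
operations for building library computation graphs.

Each operation declares how its output state space is laid out (a
Cartesian product of its internal choices and its inputs' states, or a
disjoint union for :func:`stack`), how a sequence is constructed from an
internal state plus input sequences, which design-card variables it
records, and its name token.

Enumeration orders are fixed and documented so that sequential states
are meaningful: nucleotide substitutions in A<C<G<T order, substitute
residues in alphabetical single-letter order, position pairs
lexicographic, IUPAC expansions with the leftmost position as the least
significant digit.

Operations that need the parent's sequence structure to declare their
cardinality (region coordinates, ORF content, position counts) probe
parent state 0 once at construction time; they therefore assume that
structure is shared by all parent states, which holds for every
catalog operation that preserves regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .statetracker import INACTIVE, Decomposition, UnionLayout, decompose_union
from .seqmodel import (
    Edit,
    Region,
    Style,
    TaggedSequence,
    apply_edit,
    as_style,
    overlay_style,
    parse_tagged,
    reverse_complement as _revcomp,
    translate,
    IUPAC_CODES,
)
from .core import Operation, OpContext, Pool, derive_seed
import random as _pyrandom

__all__ = [
    "PWM",
    "CapacityError",
    "PlacementError",
    "from_seq",
    "from_seqs",
    "from_pwm",
    "from_iupac",
    "random_kmers",
    "get_barcodes",
    "mutagenize",
    "mutagenize_orf",
    "delete_scan",
    "insert",
    "shuffle",
    "recombine",
    "flip",
    "join",
    "stack",
    "insert_multiscan",
    "repeat",
    "select",
    "reorder",
    "filter_pool",
    "stylize",
]

ALPHABET = "ACGT"
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical single-letter order


class CapacityError(ValueError):
    """A barcode space too small for the pool it must label."""


class PlacementError(RuntimeError):
    """Non-overlapping placement could not be found within the attempt budget."""


def _probe(pool: Pool) -> TaggedSequence:
    """Structural probe: parent state 0 under master seed 0."""
    return pool.peek(0, 0)


def _splice_styles(seq: TaggedSequence, at: int, styles) -> TaggedSequence:
    if styles is None:
        return seq
    base = list(seq.styles) if seq.styles is not None else [None] * len(seq.chars)
    base[at:at + len(styles)] = list(styles)
    return TaggedSequence(seq.chars, seq.regions, tuple(base))


# ---------------------------------------------------------------------------
# position weight matrices


@dataclass(frozen=True)
class PWM:
    """Per-position nucleotide probabilities, columns ordered A,C,G,T."""

    columns: tuple[tuple[float, float, float, float], ...]

    def __init__(self, rows):
        arr = np.asarray(rows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 4:
            raise ValueError("PWM must be a positions x 4 table (A,C,G,T)")
        if (arr < 0).any():
            raise ValueError("PWM entries must be >= 0")
        sums = arr.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("each PWM column must sum to 1 within 1e-9")
        object.__setattr__(self, "columns", tuple(map(tuple, arr)))

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.columns, dtype=float)

    def consensus(self) -> str:
        return "".join(ALPHABET[int(np.argmax(row))] for row in self.matrix)

    def log_odds(self, seq: str, background: float = 0.25) -> float:
        """Log2 odds of ``seq`` under the PWM vs a uniform background."""
        if len(seq) != len(self.columns):
            raise ValueError(f"sequence length {len(seq)} != PWM length {len(self)}")
        m = self.matrix
        score = 0.0
        for i, c in enumerate(seq):
            p = max(m[i, ALPHABET.index(c)], 1e-9)
            score += math.log2(p / background)
        return score


# ---------------------------------------------------------------------------
# source operations


class _FromSeqs(Operation):
    kind = "from_seqs"
    mode = "sequential"
    card_fields = ("index",)

    def __init__(self, texts, *, style=None, card_values=None, prefix=None):
        style = as_style(style) if style is not None else None
        seqs = []
        for t in texts:
            s = t if isinstance(t, TaggedSequence) else parse_tagged(t)
            if style is not None and not style.is_plain():
                s = overlay_style(s, 0, len(s.chars), style)
            seqs.append(s)
        if not seqs:
            raise ValueError("from_seqs requires at least one sequence")
        if card_values is not None and len(card_values) != len(seqs):
            raise ValueError("card_values length must match sequence count")
        super().__init__((), prefix=prefix, style=style,
                         params={"texts": [t if isinstance(t, str) else None for t in texts]})
        self._seqs = tuple(seqs)
        self._card_values = card_values
        if card_values:
            extra = []
            for cv in card_values:
                for k in cv:
                    if k not in extra:
                        extra.append(k)
            self.card_fields = ("index", *extra)
        self.internal_cardinality = len(seqs)

    def construct(self, ctx, inputs):
        i = ctx.internal
        ctx.record("index", i)
        if self._card_values is not None:
            for k, v in self._card_values[i].items():
                ctx.record(k, v)
        return self._seqs[i]


def from_seq(text, *, style=None, prefix=None) -> Pool:
    """Single-sequence source pool (cardinality 1); markup is parsed."""
    return Pool(_FromSeqs([text], style=style, prefix=prefix))


def from_seqs(texts, *, style=None, prefix=None, card_values=None) -> Pool:
    """Source pool over a list of sequences; state i yields the i-th one.

    ``style`` (a color name, Style, or attribute dict) is applied to
    every character of every sequence.  ``card_values`` optionally
    attaches extra per-sequence design-card entries.
    """
    return Pool(_FromSeqs(texts, style=style, prefix=prefix, card_values=card_values))


class _FromPWM(Operation):
    kind = "from_pwm"
    mode = "random"
    card_fields = ("seq",)

    def __init__(self, pwm: PWM, n: int, *, prefix=None):
        if n < 1:
            raise ValueError("sample count n must be >= 1")
        super().__init__((), prefix=prefix, params={"n": n, "pwm": [list(r) for r in pwm.columns]})
        self.pwm = pwm
        self.internal_cardinality = n
        self._cum = np.cumsum(pwm.matrix, axis=1)

    def construct(self, ctx, inputs):
        u = ctx.rng().random(len(self.pwm))
        chars = "".join(
            ALPHABET[int(np.searchsorted(self._cum[i], u[i], side="right"))]
            for i in range(len(self.pwm))
        )
        ctx.record("seq", chars)
        return TaggedSequence(chars)


def from_pwm(pwm, n, *, prefix=None) -> Pool:
    """Pool of ``n`` sequences drawn column-wise from a PWM (random mode)."""
    if not isinstance(pwm, PWM):
        pwm = PWM(pwm)
    return Pool(_FromPWM(pwm, n, prefix=prefix))


class _FromIUPAC(Operation):
    kind = "from_iupac"
    mode = "sequential"
    card_fields = ("index",)

    def __init__(self, motif: str, *, prefix=None):
        motif = motif.upper()
        bad = set(motif) - set(IUPAC_CODES)
        if bad or not motif:
            raise ValueError(f"invalid IUPAC motif {motif!r}")
        super().__init__((), prefix=prefix, params={"motif": motif})
        self._choices = tuple(IUPAC_CODES[c] for c in motif)
        card = 1
        for ch in self._choices:
            card *= len(ch)
        self.internal_cardinality = card

    def construct(self, ctx, inputs):
        s = ctx.internal
        ctx.record("index", s)
        chars = []
        for ch in self._choices:  # leftmost position = least significant digit
            chars.append(ch[s % len(ch)])
            s //= len(ch)
        return TaggedSequence("".join(chars))


def from_iupac(motif, *, prefix=None) -> Pool:
    """Sequentially enumerate all expansions of an IUPAC motif."""
    return Pool(_FromIUPAC(motif, prefix=prefix))


class _RandomKmers(Operation):
    kind = "random_kmers"
    mode = "random"

    def __init__(self, k: int, n: int, *, prefix=None):
        if k < 1 or n < 1:
            raise ValueError("k and n must be >= 1")
        super().__init__((), prefix=prefix, params={"k": k, "n": n})
        self.k = k
        self.internal_cardinality = n

    def construct(self, ctx, inputs):
        draws = ctx.rng().integers(0, 4, self.k)
        return TaggedSequence("".join(ALPHABET[int(d)] for d in draws))


def random_kmers(k, n, *, prefix=None) -> Pool:
    """Pool of ``n`` uniform random k-mers (random mode, seeded)."""
    return Pool(_RandomKmers(k, n, prefix=prefix))


# ---------------------------------------------------------------------------
# transformation operations


class _GetBarcodes(Operation):
    """One guaranteed-distinct barcode per incoming state.

    The barcode for overall state ``s`` is the base-4 encoding of a
    seeded affine bijection ``s -> (a*s + b) mod 4**L`` (``a`` odd), so
    barcodes are pairwise distinct across the whole pool without any
    global bookkeeping; generation stays lazy and per-state.
    """

    kind = "get_barcodes"
    mode = "random"
    card_fields = ("barcode",)

    def __init__(self, parent: Pool, region: str, length: int, *, prefix=None,
                 style=Style(bold=True)):
        if length < 1:
            raise ValueError("barcode length must be >= 1")
        space = 4 ** length
        if space < parent.size:
            need = math.ceil(math.log(max(parent.size, 2), 4))
            raise CapacityError(
                f"4^{length} = {space} barcodes cannot label {parent.size} "
                f"sequences; minimal length is {need}"
            )
        super().__init__((parent,), prefix=prefix, style=style,
                         params={"region": region, "length": length})
        self.region = region
        self.length = length
        self._perm_cache: dict = {}
        self.internal_cardinality = parent.size  # token width tracks pool size

    def output_cardinality(self):
        return self.inputs[0].size

    def decompose(self, s):
        return Decomposition(s, (s,))

    def _perm(self, master_seed, node_id):
        key = (master_seed, node_id)
        if key not in self._perm_cache:
            m = 4 ** self.length
            rnd = _pyrandom.Random(derive_seed(master_seed, node_id, "perm"))
            a = 2 * rnd.randrange(m // 2) + 1
            b = rnd.randrange(m)
            self._perm_cache[key] = (a, b, m)
        return self._perm_cache[key]

    def construct(self, ctx, inputs):
        a, b, m = self._perm(ctx.master_seed, ctx.node_id)
        code = (a * ctx.internal + b) % m
        digits = []
        for _ in range(self.length):
            digits.append(ALPHABET[code % 4])
            code //= 4
        bc = "".join(reversed(digits))
        seq = inputs[0]
        r = seq.region(self.region)
        ctx.record("barcode", bc)
        return apply_edit(seq, Edit(r.start, r.end, bc), style=self.style)


def get_barcodes(parent, region, length, *, prefix=None, style=Style(bold=True)) -> Pool:
    """Fill ``region`` with a distinct seeded barcode per pool member."""
    return Pool(_GetBarcodes(parent, region, length, prefix=prefix, style=style))


def _positions_for(parent, region, positions):
    probe = _probe(parent)
    if positions is not None:
        pos = tuple(int(p) for p in positions)
        if not pos:
            raise ValueError("empty position set")
        if any(not 0 <= p < len(probe.chars) for p in pos):
            raise ValueError("positions outside the parent sequence")
        return pos
    if region is not None:
        r = probe.region(region)
        if r.start == r.end:
            raise ValueError(f"region {region!r} is empty")
        return tuple(range(r.start, r.end))
    return tuple(range(len(probe.chars)))


class _Mutagenize(Operation):
    """Nucleotide-level point mutagenesis (sequential or random)."""

    kind = "mutagenize"
    card_fields = ("positions", "ref", "alt")

    def __init__(self, parent, *, scheme="single", region=None, positions=None,
                 rate=0.1, n=None, prefix=None, style=Style(fg="red")):
        pos = _positions_for(parent, region, positions)
        super().__init__((parent,), prefix=prefix, style=style, params={
            "scheme": scheme, "region": region,
            "positions": list(positions) if positions is not None else None,
            "rate": rate, "n": n,
        })
        self.scheme = scheme
        self.positions = pos
        self.rate = float(rate)
        if scheme == "single":
            self.mode = "sequential"
            self.internal_cardinality = len(pos) * 3
        elif scheme == "random":
            if n is None or n < 1:
                raise ValueError("random scheme requires a sample count n >= 1")
            self.mode = "random"
            self.internal_cardinality = n
        else:
            raise ValueError(f"unknown mutagenesis scheme {scheme!r}")

    def _substitute(self, seq, p, alt):
        return apply_edit(seq, Edit(p, p + 1, alt), style=self.style)

    def construct(self, ctx, inputs):
        seq = inputs[0]
        if self.scheme == "single":
            i = ctx.internal
            p = self.positions[i // 3]
            cur = seq.chars[p]
            if cur not in ALPHABET:
                raise ValueError(f"cannot mutate ambiguous base {cur!r} at {p}")
            alt = [c for c in ALPHABET if c != cur][i % 3]
            ctx.record("positions", [p])
            ctx.record("ref", [cur])
            ctx.record("alt", [alt])
            return self._substitute(seq, p, alt)
        # random scheme: per-position Bernoulli(rate), uniform substitute
        rng = ctx.rng()
        hits = np.nonzero(rng.random(len(self.positions)) < self.rate)[0]
        picks = rng.integers(0, 3, len(hits))
        ps, refs, alts = [], [], []
        for j, k in zip(hits, picks):
            p = self.positions[int(j)]
            cur = seq.chars[p]
            alt = [c for c in ALPHABET if c != cur][int(k)]
            seq = self._substitute(seq, p, alt)
            ps.append(p)
            refs.append(cur)
            alts.append(alt)
        ctx.record("positions", ps)
        ctx.record("ref", refs)
        ctx.record("alt", alts)
        return seq


def mutagenize(parent, **kwargs) -> Pool:
    """Point-mutation variants of a parent pool.

    ``scheme="single"`` sequentially enumerates every substitution at
    every target position (internal cardinality ``|positions| * 3``,
    substitutes in A<C<G<T order minus the current base).
    ``scheme="random"`` draws ``n`` variants, mutating each position
    with probability ``rate``.
    """
    return Pool(_Mutagenize(parent, **kwargs))


class _MutagenizeORF(Operation):
    """Codon-aware mutagenesis over an open reading frame.

    Single scheme: every amino-acid substitution at every eligible codon
    (``P x 19``); pairwise: every unordered position pair with every
    residue combination (``C(P,2) x 19**2``); random: ``n`` variants,
    each codon mutated with probability ``rate``.  Substitute codons
    follow the codon policy (``missense_only_first`` picks the most
    frequent codon encoding the substitute residue).  By default all
    codons are eligible except an initial ATG and a terminal stop.
    """

    kind = "mutagenize_orf"
    card_fields = ("scheme", "positions", "wt_aa", "mut_aa")

    def __init__(self, parent, *, scheme="single", region=None, frame_offset=0,
                 positions=None, rate=0.1, n=None,
                 codon_policy="missense_only_first", usage=None,
                 prefix=None, style=Style(fg="red")):
        if codon_policy != "missense_only_first":
            raise ValueError(f"unknown codon policy {codon_policy!r}")
        if usage is None:
            from ._data import usage_table
            usage = usage_table()
        probe = _probe(parent)
        if region is not None:
            r = probe.region(region)
            start = r.start
            span = probe.chars[r.start:r.end]
        else:
            start = frame_offset
            span = probe.chars[frame_offset:]
        if len(span) % 3 != 0:
            raise ValueError(f"framed span length {len(span)} is not a multiple of 3")
        wt_aa = translate(span)
        n_codons = len(span) // 3
        if positions is not None:
            elig = tuple(int(p) - 1 for p in positions)  # 1-based residue indices
            if any(not 0 <= p < n_codons for p in elig):
                raise ValueError("residue positions outside the framed span")
        else:
            elig = tuple(
                i for i in range(n_codons)
                if not (i == 0 and span[:3] == "ATG")
                and not (i == n_codons - 1 and wt_aa[i] == "*")
            )
        if not elig:
            raise ValueError("position exclusions leave no eligible codons")
        super().__init__((parent,), prefix=prefix, style=style, params={
            "scheme": scheme, "region": region, "frame_offset": frame_offset,
            "positions": list(positions) if positions is not None else None,
            "rate": rate, "n": n, "codon_policy": codon_policy,
        })
        self.scheme = scheme
        self._start = start
        self._wt = wt_aa
        self._elig = elig
        self._usage = usage
        self.rate = float(rate)
        P = len(elig)
        if scheme == "single":
            self.mode = "sequential"
            self.internal_cardinality = P * 19
        elif scheme == "pairwise":
            self.mode = "sequential"
            self.internal_cardinality = math.comb(P, 2) * 19 * 19
            self._pairs = [(i, j) for i in range(P) for j in range(i + 1, P)]
        elif scheme == "random":
            if n is None or n < 1:
                raise ValueError("random scheme requires a sample count n >= 1")
            self.mode = "random"
            self.internal_cardinality = n
        else:
            raise ValueError(f"unknown mutagenesis scheme {scheme!r}")

    def _subs_for(self, codon_idx):
        wt = self._wt[codon_idx]
        return [r for r in RESIDUES if r != wt]

    def _apply(self, seq, codon_idx, res):
        codon = self._usage[res][0][0]  # most frequent codon for the residue
        at = self._start + 3 * codon_idx
        return apply_edit(seq, Edit(at, at + 3, codon), style=self.style)

    def _emit(self, ctx, seq, muts):
        ctx.record("scheme", self.scheme)
        ctx.record("positions", [m[0] + 1 for m in muts])  # 1-based residues
        ctx.record("wt_aa", [self._wt[m[0]] for m in muts])
        ctx.record("mut_aa", [m[1] for m in muts])
        for idx, res in muts:
            seq = self._apply(seq, idx, res)
        return seq

    def construct(self, ctx, inputs):
        seq = inputs[0]
        i = ctx.internal
        if self.scheme == "single":
            codon = self._elig[i // 19]
            res = self._subs_for(codon)[i % 19]
            return self._emit(ctx, seq, [(codon, res)])
        if self.scheme == "pairwise":
            pi, rest = divmod(i, 19 * 19)
            r1, r2 = divmod(rest, 19)
            a, b = self._pairs[pi]
            ca, cb = self._elig[a], self._elig[b]
            return self._emit(
                ctx, seq,
                [(ca, self._subs_for(ca)[r1]), (cb, self._subs_for(cb)[r2])],
            )
        # random scheme: Bernoulli(rate) per codon; all-wild-type draws kept
        rng = ctx.rng()
        hits = np.nonzero(rng.random(len(self._elig)) < self.rate)[0]
        picks = rng.integers(0, 19, len(hits))
        muts = []
        for j, k in zip(hits, picks):
            codon = self._elig[int(j)]
            muts.append((codon, self._subs_for(codon)[int(k)]))
        return self._emit(ctx, seq, muts)


def mutagenize_orf(parent, **kwargs) -> Pool:
    """Codon-aware amino-acid mutagenesis of an ORF (see _MutagenizeORF)."""
    return Pool(_MutagenizeORF(parent, **kwargs))


class _DeleteScan(Operation):
    kind = "delete_scan"
    mode = "sequential"
    card_fields = ("start", "window")

    def __init__(self, parent, region, window, *, prefix=None, style=None):
        probe = _probe(parent)
        r = probe.region(region)
        rl = r.end - r.start
        if not 1 <= window <= rl:
            raise ValueError(f"window {window} exceeds region length {rl}")
        super().__init__((parent,), prefix=prefix, style=style,
                         params={"region": region, "window": window})
        self.region = region
        self.window = window
        self.internal_cardinality = rl - window + 1

    def construct(self, ctx, inputs):
        seq = inputs[0]
        r = seq.region(self.region)
        i = ctx.internal
        ctx.record("start", i)
        ctx.record("window", self.window)
        out = apply_edit(seq, Edit(r.start + i, r.start + i + self.window, ""))
        if self.style is not None:
            nr = out.region(self.region)
            out = overlay_style(out, nr.start, nr.end, self.style)
        return out


def delete_scan(parent, region, window, *, prefix=None, style=None) -> Pool:
    """Slide a deletion window across a region (one variant per offset)."""
    return Pool(_DeleteScan(parent, region, window, prefix=prefix, style=style))


class _Insert(Operation):
    kind = "insert"
    mode = "fixed"
    card_fields = ("payload_state",)

    def __init__(self, parent, payload, region, *, prefix=None):
        probe = _probe(parent)
        probe.region(region)  # existence check
        super().__init__((parent, payload), prefix=prefix,
                         params={"region": region})
        self.region = region

    def construct(self, ctx, inputs):
        parent, payload = inputs
        r = parent.region(self.region)
        out = apply_edit(parent, Edit(r.start, r.end, payload.chars))
        out = _splice_styles(out, r.start, payload.styles)
        if payload.regions:
            shifted = tuple(
                Region(pr.name, pr.start + r.start, pr.end + r.start)
                for pr in payload.regions
            )
            out = TaggedSequence(out.chars, out.regions + shifted, out.styles)
        ctx.record("payload_state", ctx.components[1])
        return out


def insert(parent, payload, region, *, prefix=None) -> Pool:
    """Splice each payload-pool sequence into ``region`` of each parent.

    Product layout: sizes multiply.  The target region stretches to
    cover the payload; payload regions and styles are carried along.
    """
    return Pool(_Insert(parent, payload, region, prefix=prefix))


class _Shuffle(Operation):
    kind = "shuffle"
    mode = "random"

    def __init__(self, parent, n, *, region=None, prefix=None):
        if n < 1:
            raise ValueError("n must be >= 1")
        super().__init__((parent,), prefix=prefix,
                         params={"n": n, "region": region})
        self.region = region
        self.internal_cardinality = n

    def construct(self, ctx, inputs):
        seq = inputs[0]
        if self.region is not None:
            r = seq.region(self.region)
            a, b = r.start, r.end
        else:
            a, b = 0, len(seq.chars)
        perm = ctx.rng().permutation(b - a)
        span = seq.chars[a:b]
        chars = seq.chars[:a] + "".join(span[int(i)] for i in perm) + seq.chars[b:]
        styles = seq.styles
        if styles is not None:
            mid = tuple(styles[a + int(i)] for i in perm)
            styles = styles[:a] + mid + styles[b:]
        return TaggedSequence(chars, seq.regions, styles)


def shuffle(parent, n, *, region=None, prefix=None) -> Pool:
    """Uniformly random permutations of a region's characters (seeded)."""
    return Pool(_Shuffle(parent, n, region=region, prefix=prefix))


class _Recombine(Operation):
    kind = "recombine"
    mode = "random"
    card_fields = ("crossovers",)

    def __init__(self, parent_a, parent_b, n_crossovers, n, *, prefix=None):
        la, lb = len(_probe(parent_a).chars), len(_probe(parent_b).chars)
        if la != lb:
            raise ValueError(f"parents must be equal length ({la} vs {lb})")
        if n_crossovers < 0 or n_crossovers > la - 1:
            raise ValueError("invalid crossover count")
        if n < 1:
            raise ValueError("n must be >= 1")
        super().__init__((parent_a, parent_b), prefix=prefix,
                         params={"n_crossovers": n_crossovers, "n": n})
        self.n_crossovers = n_crossovers
        self.internal_cardinality = n

    def construct(self, ctx, inputs):
        a, b = inputs
        L = len(a.chars)
        if self.n_crossovers == 0:
            ctx.record("crossovers", [])
            return a
        points = sorted(
            int(p) for p in ctx.rng().choice(
                np.arange(1, L), size=self.n_crossovers, replace=False
            )
        )
        ctx.record("crossovers", points)
        bounds = [0, *points, L]
        sources = [a, b]
        chars = "".join(
            sources[k % 2].chars[bounds[k]:bounds[k + 1]]
            for k in range(len(bounds) - 1)
        )
        return TaggedSequence(chars, a.regions, None)


def recombine(parent_a, parent_b, n_crossovers, n, *, prefix=None) -> Pool:
    """Alternating-segment recombinants of two equal-length parents."""
    return Pool(_Recombine(parent_a, parent_b, n_crossovers, n, prefix=prefix))


class _Flip(Operation):
    kind = "flip"
    mode = "sequential"
    card_fields = ("orientation",)
    internal_cardinality = 2

    def __init__(self, parent, *, prefix=None):
        super().__init__((parent,), prefix=prefix)

    def construct(self, ctx, inputs):
        if ctx.internal == 0:
            ctx.record("orientation", "fwd")
            return inputs[0]
        ctx.record("orientation", "rev")
        return _revcomp(inputs[0])


def flip(parent, *, prefix=None) -> Pool:
    """Both orientations of each parent sequence (0=forward, 1=revcomp)."""
    return Pool(_Flip(parent, prefix=prefix))


# ---------------------------------------------------------------------------
# composition operations


class _Join(Operation):
    kind = "join"
    mode = "fixed"

    def __init__(self, pools, *, prefix=None):
        if not pools:
            raise ValueError("join requires at least one input")
        super().__init__(tuple(pools), prefix=prefix)

    def construct(self, ctx, inputs):
        chars = "".join(s.chars for s in inputs)
        regions = []
        offset = 0
        any_styles = any(s.styles is not None for s in inputs)
        styles: list = []
        for s in inputs:
            regions.extend(
                Region(r.name, r.start + offset, r.end + offset) for r in s.regions
            )
            if any_styles:
                styles.extend(s.styles if s.styles is not None else (None,) * len(s.chars))
            offset += len(s.chars)
        return TaggedSequence(chars, tuple(regions),
                              tuple(styles) if any_styles else None)


def join(*pools, prefix=None) -> Pool:
    """Concatenate parent sequences end-to-end (product layout)."""
    return Pool(_Join(pools, prefix=prefix))


class _Stack(Operation):
    """Merge pools side by side: the output state space is the disjoint
    union of the input state spaces; exactly one branch is active per
    state, and inactive branches receive no state."""

    kind = "stack"
    mode = "fixed"
    card_fields = ("component",)
    token_first = True

    def __init__(self, pools, *, labels=None, prefix=None):
        if not pools:
            raise ValueError("stack requires at least one input")
        if labels is not None and len(labels) != len(pools):
            raise ValueError("labels must match input count")
        super().__init__(tuple(pools), prefix=prefix,
                         params={"labels": list(labels) if labels else None})
        self.labels = tuple(labels) if labels is not None else None

    def _layout(self):
        return UnionLayout(tuple(p.size for p in self.inputs))

    def output_cardinality(self):
        return self._layout().total

    def decompose(self, s):
        return decompose_union(s, self._layout())

    def _active(self, ctx):
        return next(i for i, c in enumerate(ctx.components) if c is not INACTIVE)

    def own_token(self, ctx, d):
        if self.labels is None:
            return None
        i = next(j for j, c in enumerate(d.component_states) if c is not INACTIVE)
        return self.labels[i]

    def construct(self, ctx, inputs):
        i = self._active(ctx)
        label = self.labels[i] if self.labels is not None else f"b{i}"
        ctx.record("component", label)
        return inputs[i]


def stack(*pools, labels=None, prefix=None) -> Pool:
    """Merge pools into one; ``labels`` name the branches in sequence names."""
    return Pool(_Stack(pools, labels=labels, prefix=prefix))


class _InsertMultiscan(Operation):
    """Place one member of each site pool at seeded random, pairwise
    disjoint offsets inside a region of the template.

    Internal cardinality is the declared sample count ``n``: for each
    internal state the keyed RNG first draws one member state per site
    pool, then draws disjoint placements by rejection sampling.  Site
    placement replaces the region background in place (equal-length
    substitution), so region coordinates are unchanged.
    """

    kind = "insert_multiscan"
    mode = "random"
    card_fields = ("sites", "offsets")

    def __init__(self, template, site_pools, region, n, *, no_overlap=True,
                 max_rejections=1000, prefix=None):
        if n < 1:
            raise ValueError("n must be >= 1")
        probe = _probe(template)
        r = probe.region(region)
        super().__init__((template, *site_pools), prefix=prefix, params={
            "region": region, "n": n, "no_overlap": no_overlap,
            "max_rejections": max_rejections,
        })
        self.region = region
        self.no_overlap = no_overlap
        self.max_rejections = max_rejections
        self.internal_cardinality = n
        self._region_len = r.end - r.start
        self._site_labels = tuple(
            p.op.prefix or p.op.kind for p in site_pools
        )

    def output_cardinality(self):
        return self.internal_cardinality * self.inputs[0].size

    def decompose(self, s):
        if not 0 <= s < self.output_cardinality():
            from .statetracker import StateRangeError
            raise StateRangeError(
                f"state {s} out of range for cardinality {self.output_cardinality()}"
            )
        internal = s % self.internal_cardinality
        t = s // self.internal_cardinality
        return Decomposition(internal, (t,) + (INACTIVE,) * (len(self.inputs) - 1))

    def resolve_components(self, ctx, d):
        rng = ctx.rng()
        drawn = tuple(
            int(rng.integers(int(p.size))) for p in self.inputs[1:]
        )
        return (d.component_states[0], *drawn)

    def construct(self, ctx, inputs):
        template, *sites = inputs
        r = template.region(self.region)
        rlen = r.end - r.start
        lens = [len(s.chars) for s in sites]
        if any(L > rlen for L in lens):
            raise PlacementError("a site is longer than the target region")
        rng = ctx.rng()  # same generator instance that drew the member states
        for _ in range(self.max_rejections + 1):
            offsets = [int(rng.integers(0, rlen - L + 1)) for L in lens]
            if not self.no_overlap:
                break
            iv = sorted((o, o + L) for o, L in zip(offsets, lens))
            if all(iv[k][1] <= iv[k + 1][0] for k in range(len(iv) - 1)):
                break
        else:
            raise PlacementError(
                f"no disjoint placement found in {self.max_rejections} attempts"
            )
        out = template
        for o, site in zip(offsets, sites):
            at = r.start + o
            out = apply_edit(out, Edit(at, at + len(site.chars), site.chars))
            out = _splice_styles(out, at, site.styles)
        ctx.record("sites", list(self._site_labels))
        ctx.record("offsets", offsets)
        return out


def insert_multiscan(template, *site_pools, region, n, no_overlap=True,
                     max_rejections=1000, prefix=None) -> Pool:
    """``n`` seeded arrangements of one member per site pool inside a region."""
    return Pool(_InsertMultiscan(template, site_pools, region, n,
                                 no_overlap=no_overlap,
                                 max_rejections=max_rejections, prefix=prefix))


# ---------------------------------------------------------------------------
# state operations


class _Repeat(Operation):
    kind = "repeat"
    mode = "sequential"
    card_fields = ("replicate",)

    def __init__(self, parent, n, *, prefix=None):
        if n < 1:
            raise ValueError("n must be >= 1")
        super().__init__((parent,), prefix=prefix, params={"n": n})
        self.internal_cardinality = n

    def construct(self, ctx, inputs):
        ctx.record("replicate", ctx.internal)
        return inputs[0]


def repeat(parent, n, *, prefix=None) -> Pool:
    """Replicate every parent sequence ``n`` times (distinct states/names)."""
    return Pool(_Repeat(parent, n, prefix=prefix))


class _Select(Operation):
    kind = "select"
    mode = "sequential"
    card_fields = ("parent_state",)

    def __init__(self, parent, indices, *, prefix=None):
        idx = tuple(int(i) for i in indices)
        if any(not 0 <= i < parent.size for i in idx):
            raise ValueError("selection index out of range")
        super().__init__((parent,), prefix=prefix, params={"indices": list(idx)})
        self._idx = idx
        self.internal_cardinality = len(idx)

    def output_cardinality(self):
        return len(self._idx)

    def decompose(self, s):
        return Decomposition(s, (self._idx[s],))

    def construct(self, ctx, inputs):
        ctx.record("parent_state", ctx.components[0])
        return inputs[0]


def select(parent, indices, *, prefix=None) -> Pool:
    """Keep the given parent states, in the order given."""
    return Pool(_Select(parent, indices, prefix=prefix))


def reorder(parent, permutation, *, prefix=None) -> Pool:
    """Reorder a pool by a bijective permutation of its states."""
    perm = [int(i) for i in permutation]
    if sorted(perm) != list(range(parent.size)):
        raise ValueError("permutation must be a bijection on the parent states")
    return Pool(_Select(parent, perm, prefix=prefix))


class _Filter(Operation):
    """Keep parent states whose generated sequence satisfies a predicate.

    Cardinality is not computable from the layout algebra alone, so the
    kept-state index is materialized by a one-time scan of the parent
    (an eager cost, triggered by the first size query).  The predicate
    is evaluated with the parent as its own generation root under
    ``materialize_seed``; intended for deterministic upstreams.
    """

    kind = "filter"
    mode = "sequential"
    card_fields = ("parent_state",)

    def __init__(self, parent, predicate, *, materialize_seed=0, prefix=None):
        super().__init__((parent,), prefix=prefix)
        self.predicate = predicate
        self.materialize_seed = materialize_seed
        self._idx = None

    def _materialize(self):
        if self._idx is None:
            parent = self.inputs[0]
            self._idx = tuple(
                r.state for r in parent.iter_results(self.materialize_seed)
                if self.predicate(r.sequence)
            )
            self.internal_cardinality = max(len(self._idx), 1)
        return self._idx

    def output_cardinality(self):
        return len(self._materialize())

    def decompose(self, s):
        return Decomposition(s, (self._materialize()[s],))

    def construct(self, ctx, inputs):
        ctx.record("parent_state", ctx.components[0])
        return inputs[0]


def filter_pool(parent, predicate, *, materialize_seed=0, prefix=None) -> Pool:
    """Keep parent sequences satisfying ``predicate`` (eager index scan)."""
    return Pool(_Filter(parent, predicate, materialize_seed=materialize_seed,
                        prefix=prefix))


class _Stylize(Operation):
    kind = "stylize"
    mode = "fixed"

    def __init__(self, parent, region, style, *, prefix=None):
        probe = _probe(parent)
        probe.region(region)
        style = as_style(style)
        super().__init__((parent,), prefix=prefix, style=style,
                         params={"region": region})
        self.region = region

    def construct(self, ctx, inputs):
        seq = inputs[0]
        r = seq.region(self.region)
        return overlay_style(seq, r.start, r.end, self.style)


def stylize(parent, region, style, *, prefix=None) -> Pool:
    """Overlay style attributes on a region; characters are unchanged."""
    return Pool(_Stylize(parent, region, style, prefix=prefix))
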