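"""Packaged example library builders.

Three complete designs exercise the catalog end to end:

* :func:`build_gb1` — a deep-mutational-scanning library for the 56-codon
  GB1 domain: 100 wild-type replicates, all 1,045 single and all 536,085
  pairwise amino-acid substitutions (start codon excluded, 19 substitute
  residues per position), plus 10,000 random higher-order variants
  (per-codon mutation probability 0.1), stacked into one 547,230-member
  pool.
* :func:`build_mpra` — a reporter-assay library: both orientations of
  three liver TF binding sites placed without overlap at seeded random
  offsets inside a 100-bp CRE, 10,000 arrangements, three replicates
  each, and a distinct 10-nt barcode per sequence (30,000 total).
* :func:`build_splice` — a cryptic 5' splice-site library: 9-mers
  sampled from a 5'ss PWM, scored for strength, binned into 100
  equal-count quantile bins, 20 drawn per bin (2,000 sites), each
  substituted at 100 positions flanking a canonical 5'ss and paired with
  a GT-disrupted control (T>A at +2); design cards record strength ``s``,
  position ``p``, and the control flag.

:class:`ScanSubstitute` is written against the public Operation
subclassing contract and shows how a new operation inherits state
tracking, cards, and naming for free.
"""

from __future__ import annotations

import numpy as np

from ._data import SS5_PWM_ROWS, TFBS_MOTIFS, gb1_orf
from .core import Operation, Pool, derive_seed
from .oplib import (
    PWM,
    flip,
    from_pwm,
    from_seq,
    from_seqs,
    get_barcodes,
    insert_multiscan,
    mutagenize_orf,
    repeat,
    stack,
    stylize,
)
from .seqmodel import Edit, Style, apply_edit

__all__ = [
    "build_gb1",
    "build_mpra",
    "build_splice",
    "ScanSubstitute",
    "quantile_bin_draw",
    "mpra_template",
    "splice_template",
]


# ---------------------------------------------------------------------------
# GB1 deep mutational scan


def build_gb1(*, n_random: int = 10_000, rate: float = 0.1) -> Pool:
    """GB1 DMS design: wt replicates + single + pairwise + random variants.

    Branch sizes are 100 / 1,045 / 536,085 / ``n_random``; the stacked
    root has 547,230 members at the defaults.
    """
    orf = from_seq(gb1_orf())
    wt = repeat(orf, 100, prefix="rep")
    single = mutagenize_orf(orf, scheme="single", prefix="mut")
    double = mutagenize_orf(orf, scheme="pairwise", prefix="mut")
    multi = mutagenize_orf(orf, scheme="random", rate=rate, n=n_random,
                           prefix="mut")
    return stack(wt, single, double, multi,
                 labels=["wt", "single", "double", "multi"], prefix="stack")


# ---------------------------------------------------------------------------
# MPRA regulatory-grammar library


def _filler(length: int, seed: int) -> str:
    """Deterministic inert background sequence."""
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[int(i)] for i in rng.integers(0, 4, length))


def mpra_template() -> str:
    """Reporter template: 100-bp CRE region plus a barcode anchor."""
    return (
        _filler(18, 11) + "<cre>" + _filler(100, 12) + "</cre>"
        + _filler(20, 13) + "<bc></bc>" + _filler(12, 14)
    )


_TFBS_COLORS = {"HNF4A": "blue", "PPARA": "purple", "XBP1": "orange"}


def build_mpra(*, n_arrangements: int = 10_000, n_replicates: int = 3,
               barcode_length: int = 10) -> Pool:
    """MPRA design: flipped TFBS pools scattered in the CRE, then barcoded."""
    template = stylize(from_seq(mpra_template()), "cre", "gray")
    sites = [
        flip(from_seqs([TFBS_MOTIFS[name]], style=_TFBS_COLORS[name]),
             prefix=name.lower())
        for name in ("HNF4A", "PPARA", "XBP1")
    ]
    lib = insert_multiscan(template, *sites, region="cre",
                           n=n_arrangements, prefix="var")
    lib = repeat(lib, n_replicates, prefix="rep")
    return get_barcodes(lib, "bc", barcode_length, prefix="bc")


# ---------------------------------------------------------------------------
# cryptic 5' splice-site library


def splice_template() -> str:
    """Synthetic exon/intron junction; <canon> tags the canonical 5'ss 9-mer."""
    return _filler(67, 21) + "<canon>CAGGTAAGT</canon>" + _filler(73, 22)


class ScanSubstitute(Operation):
    """Substitute a payload 9-mer at each of a fixed list of positions,
    optionally disrupting its GT dinucleotide (T>A at +2) as a matched
    control.

    A custom operation written against the public subclassing contract:
    it declares an internal cardinality (``len(slots) * 2``), constructs
    from its internal state plus input sequences, and records card
    variables; state tracking, naming, and card plumbing are inherited.
    """

    kind = "scan_substitute"
    mode = "sequential"
    card_fields = ("p", "control")

    def __init__(self, template: Pool, payload: Pool, slots, *, prefix=None,
                 style=Style(fg="red")):
        super().__init__((template, payload), prefix=prefix, style=style)
        self._slots = tuple(slots)  # (signed position label, window start)
        self.internal_cardinality = len(self._slots) * 2

    def construct(self, ctx, inputs):
        template, payload = inputs
        slot, control = divmod(ctx.internal, 2)
        p, start = self._slots[slot]
        nine = payload.chars
        if control:
            nine = nine[:4] + "A" + nine[5:]  # +2 is index 4 of the 9-mer
        ctx.record("p", p)
        ctx.record("control", bool(control))
        return apply_edit(template, Edit(start, start + len(nine), nine),
                          style=self.style)


def quantile_bin_draw(scores, n_bins: int, per_bin: int, seed: int):
    """Indices of ``per_bin`` draws from each of ``n_bins`` equal-count
    score quantile bins (ties broken by index; draws seeded)."""
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(scores, kind="stable")
    bins = np.array_split(order, n_bins)
    if min(len(b) for b in bins) < per_bin:
        raise ValueError(
            f"cannot draw {per_bin} from bins of {len(scores)}//{n_bins} scores"
        )
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for b in bins:
        chosen.extend(sorted(int(i) for i in rng.choice(b, size=per_bin,
                                                        replace=False)))
    return chosen


def build_splice(scorer=None, *, n_sample: int = 10_000, n_bins: int = 100,
                 per_bin: int = 20, n_flank: int = 50,
                 master_seed: int = 0) -> Pool:
    """Cryptic 5'ss scan: PWM-sampled 9-mers, strength-binned, scanned.

    The strength scorer is pluggable; the default is the PWM log-odds.
    The binning step is eager (it generates the ``n_sample`` candidate
    9-mers once); the resulting pool of ``n_bins * per_bin`` sites times
    ``2 * n_flank`` positions times variant/control stays lazy.
    """
    pwm = PWM(SS5_PWM_ROWS)
    if scorer is None:
        scorer = pwm.log_odds
    candidates = from_pwm(pwm, n_sample)
    ninemers = [r.sequence.chars for r in candidates.iter_results(master_seed)]
    scores = [scorer(s) for s in ninemers]
    idx = quantile_bin_draw(scores, n_bins, per_bin,
                            derive_seed(master_seed, "splice_bins", 0))
    sites = from_seqs(
        [ninemers[i] for i in idx],
        prefix="site",
        card_values=[{"s": round(scores[i], 4), "source_state": i} for i in idx],
    )
    template = from_seq(splice_template())
    # canonical 9-mer occupies [67, 76); windows abut it on either side
    slots = [(-k, 67 - 9 - (k - 1)) for k in range(1, n_flank + 1)]
    slots += [(k, 76 + (k - 1)) for k in range(1, n_flank + 1)]
    slots.sort(key=lambda s: s[0])
    return Pool(ScanSubstitute(template, sites, slots, prefix="scan"))
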