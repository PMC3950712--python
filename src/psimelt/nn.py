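"""Nearest-neighbor free-energy prediction and increment arithmetic.

The free energy of duplex formation at 37 °C is modelled as

    ΔG°37 = ΔG°init + Σ stacks + Σ terminal-pair penalties + Σ dangling ends

with parameters for Watson–Crick pairs, G-U wobbles, pseudouridine–adenosine
(Ψ-A) pairs and single dangling nucleotides.  Internal Ψ-G, Ψ-U and Ψ-C
pairs have no published propagation parameters and raise
:class:`~psimelt.params.UnparameterizedContextError`; the measured
substitution increments of this study can be layered on as an explicitly
provisional correction set (see :func:`predict_dG37_with_corrections`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .duplex import GAP, Duplex, PairClass, classify_pairs, reverse_duplex
from .params import (
    NNParameterSet,
    UnparameterizedContextError,
    stack_key,
    terminal_category,
)

__all__ = [
    "EnergyWithSD",
    "IncrementRecord",
    "Prediction",
    "propagate_sd",
    "predict_dG37",
    "predict_dG37_with_corrections",
    "predicted_terminal_increment",
    "terminal_increment",
    "substitution_increment",
]


@dataclass(frozen=True)
class EnergyWithSD:
    """A free energy (kcal/mol, formation convention) with its standard deviation."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")

    def round(self, ndigits: int = 2) -> "EnergyWithSD":
        return EnergyWithSD(round(self.value, ndigits), round(self.sd, ndigits))

    def __sub__(self, other: "EnergyWithSD") -> "EnergyWithSD":
        return EnergyWithSD(self.value - other.value, propagate_sd(self.sd, other.sd))

    def __str__(self) -> str:
        return f"{self.value:.2f} ± {self.sd:.2f}"


def propagate_sd(sd_a: float, sd_b: float) -> float:
    """Root-sum-square propagation for a sum/difference of two measurements."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    return math.hypot(sd_a, sd_b)


@dataclass(frozen=True)
class Term:
    """One additive contribution of a nearest-neighbor prediction."""

    kind: str  # initiation | stack | terminal | dangle
    label: str
    dG37: float
    provenance: str


@dataclass
class Prediction:
    """Predicted ΔG°37 with its per-term breakdown."""

    energy: EnergyWithSD
    terms: list[Term] = field(default_factory=list)

    @property
    def value(self) -> float:
        return self.energy.value


@dataclass(frozen=True)
class IncrementRecord:
    """A ΔΔG°37 between two duplexes with propagated sd and context label."""

    delta: EnergyWithSD
    context: str
    source: str  # measured | predicted


_ALLOWED_INTERNAL = {
    PairClass.WC_AU,
    PairClass.WC_UA,
    PairClass.WC_GC,
    PairClass.WC_CG,
    PairClass.WOBBLE_GU,
    PairClass.PSI_A,
}


def predict_dG37(d: Duplex, params: NNParameterSet) -> Prediction:
    """Nearest-neighbor ΔG°37 of duplex formation with per-term breakdown.

    Raises :class:`UnparameterizedContextError` (naming the missing key) for
    any pair or stack outside the parameterized WC / G-U / Ψ-A / dangling
    repertoire, e.g. an internal Ψ-G pair.
    """
    classes = classify_pairs(d)
    cols = d.columns()
    for i, cls in enumerate(classes):
        if cls.is_paired and cls not in _ALLOWED_INTERNAL:
            t, b = cols[i]
            raise UnparameterizedContextError(f"{cls.value} pair {t}-{b} (column {i})")

    terms: list[Term] = []
    if params.initiation is None:
        raise UnparameterizedContextError("duplex initiation")
    terms.append(
        Term("initiation", "helix initiation", params.initiation.value,
             params.initiation.provenance)
    )

    paired_idx = [i for i, cls in enumerate(classes) if cls.is_paired]
    if not paired_idx:
        raise UnparameterizedContextError("duplex with no base pairs")

    # stacking terms over consecutive paired columns
    for a, b in zip(paired_idx, paired_idx[1:]):
        key = cols[a][0] + cols[b][0] + "/" + cols[a][1] + cols[b][1]
        entry = params.stack(key)
        terms.append(Term("stack", f"stack {key}", entry.value, entry.provenance))

    # terminal penalties at both ends of the paired region
    for end, idx in (("5'", paired_idx[0]), ("3'", paired_idx[-1])):
        t, b = cols[idx]
        cat = terminal_category(t, b)
        entry = params.terminal_penalty(cat)
        terms.append(
            Term("terminal", f"{end} terminal {t}-{b} ({cat})", entry.value,
                 entry.provenance)
        )

    # dangling ends: rotate bottom-strand overhangs onto the top strand
    for i, cls in enumerate(classes):
        if not cls.is_dangling:
            continue
        t, b = cols[i]
        j = paired_idx[0] if i < paired_idx[0] else paired_idx[-1]
        pt, pb = cols[j]
        if b == GAP:  # overhang on the top strand
            kind = "dangle5" if i < j else "dangle3"
            base, pair = t, pt + pb
        else:  # overhang on the bottom strand; 180° rotation puts it on top
            kind = "dangle3" if i < j else "dangle5"
            base, pair = b, pb + pt
        entry = params.dangle(kind, base, pair)
        terms.append(
            Term("dangle", f"{cls.value.lower()} {base} on {pair}", entry.value,
                 entry.provenance)
        )

    total = sum(t.dG37 for t in terms)
    return Prediction(EnergyWithSD(total, 0.0), terms)


def predicted_terminal_increment(
    stack_context: str, params: NNParameterSet, end: str = "5'"
) -> EnergyWithSD:
    """NN-predicted ΔΔG°37 for adding one terminal base pair.

    ``stack_context`` is the new terminal stack written ``XY/WZ`` with the
    added pair outermost: at the 5' end the added pair is (X, W), at the 3'
    end it is (Y, Z).  The increment is the new stack term plus the penalty
    of the new terminal pair minus the penalty of the pair it displaced
    from the helix end.
    """
    top, bottom = stack_context.replace("Ψ", "P").upper().split("/")
    if end.startswith("5"):
        new_pair, old_pair = (top[0], bottom[0]), (top[1], bottom[1])
    else:
        new_pair, old_pair = (top[1], bottom[1]), (top[0], bottom[0])
    stack = params.stack(stack_context.replace("Ψ", "P").upper())
    new_pen = params.terminal_penalty(terminal_category(*new_pair))
    old_pen = params.terminal_penalty(terminal_category(*old_pair))
    return EnergyWithSD(stack.value + new_pen.value - old_pen.value, 0.0)


def _strip_one_terminal(extended: Duplex) -> list[tuple[Duplex, int]]:
    """All duplexes obtained by deleting one terminal alignment column."""
    out = []
    t, b = extended.top_aligned, extended.bottom_aligned
    if len(t) > 1:
        for idx, (tt, bb) in (((0), (t[1:], b[1:])), ((len(t) - 1), (t[:-1], b[:-1]))):
            try:
                out.append((Duplex(tt, bb), idx))
            except Exception:
                pass
    return out


def terminal_increment(
    core: Duplex,
    extended: Duplex,
    dG_core: EnergyWithSD,
    dG_ext: EnergyWithSD,
) -> IncrementRecord:
    """Measured ΔΔG°37 of a single terminal addition (pair or dangling end).

    ``extended`` must equal ``core`` after removal of exactly one terminal
    nucleotide (dangling) or base pair; the context label is derived from
    the added terminus, e.g. ``5'P`` for a dangling pseudouridine or
    ``3'P/5'G`` for a 3'-terminal Ψ-G pair.
    """
    added = None
    for reduced, col in _strip_one_terminal(extended):
        if reduced == core:
            added = col
            break
    if added is None:
        raise ValueError("extended duplex does not differ from core by one terminal unit")
    t = extended.top_aligned[added]
    b = extended.bottom_aligned[added]
    left = added == 0
    if b == GAP:
        context = f"5'{t}" if left else f"3'{t}"
    elif t == GAP:
        context = f"3'{b}" if left else f"5'{b}"
    else:
        context = f"5'{t}/3'{b}" if left else f"3'{t}/5'{b}"
    return IncrementRecord(dG_ext - dG_core, context, "measured")


def substitution_increment(
    dG_ref: EnergyWithSD, dG_mod: EnergyWithSD, context: str = ""
) -> IncrementRecord:
    """ΔΔG°37 of replacing U by Ψ: modified minus reference duplex energy."""
    return IncrementRecord(dG_mod - dG_ref, context, "measured")


def predict_dG37_with_corrections(
    d: Duplex,
    params: NNParameterSet,
    corrections: dict[str, EnergyWithSD],
) -> Prediction:
    """Provisional prediction for duplexes with one non-Ψ-A pseudouridine pair.

    The duplex is predicted with every Ψ replaced by U and the *measured*
    substitution increment for the central motif (keyed ``XPY@N``: the
    Ψ-containing top triplet and the opposing base) is added.  These
    corrections are experimental increments of this study, not fitted
    nearest-neighbor parameters, and the returned breakdown flags them as
    such.
    """
    classes = classify_pairs(d)
    cols = d.columns()
    psi_cols = [i for i, (t, b) in enumerate(cols) if "P" in (t, b)]
    if len(psi_cols) != 1:
        raise ValueError("correction path requires exactly one pseudouridine")
    i = psi_cols[0]
    if not (0 < i < len(cols) - 1) or not classes[i].is_paired:
        raise ValueError("correction path covers internal pairs only")
    t, b = cols[i]
    if t != "P":
        return predict_dG37_with_corrections(reverse_duplex(d), params, corrections)
    motif = cols[i - 1][0] + "P" + cols[i + 1][0] + "@" + b
    if motif not in corrections:
        raise UnparameterizedContextError(f"measured correction {motif}")
    u_analog = Duplex(
        d.top_aligned.replace("P", "U"), d.bottom_aligned.replace("P", "U")
    )
    base = predict_dG37(u_analog, params)
    corr = corrections[motif]
    terms = base.terms + [
        Term("correction", f"measured U->Ψ increment {motif}", corr.value,
             "this-study-measured")
    ]
    return Prediction(
        EnergyWithSD(base.energy.value + corr.value, corr.sd), terms
    )
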