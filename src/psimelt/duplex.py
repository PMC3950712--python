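"""Representation of short RNA duplexes containing pseudouridine.

A duplex is two antiparallel strands written the way melting studies print
them: the top strand 5'->3', the bottom strand 3'->5', so that column ``i``
of the top pairs with column ``i`` of the bottom.  Pseudouridine is encoded
as ``P`` (the Unicode Psi is accepted on input).  Single-nucleotide
terminal overhangs (dangling ends) are carried as ``-`` gaps in the
opposing strand, e.g. ::

    5' P C A G U C A G U 3'
    3' - G U C A G U C A 5'

is the core duplex with an unpaired 5'-dangling pseudouridine.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

ALPHABET = frozenset("ACGUP")
GAP = "-"
_PSI_ALIASES = {"Ψ": "P", "ψ": "P"}  # Ψ, ψ
_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


class DuplexError(ValueError):
    """Malformed strand or irreconcilable duplex geometry."""


class PairClass(Enum):
    """Category of one alignment column of a duplex."""

    WC_AU = "WC_AU"
    WC_UA = "WC_UA"
    WC_GC = "WC_GC"
    WC_CG = "WC_CG"
    WOBBLE_GU = "WOBBLE_GU"
    PSI_A = "PSI_A"
    PSI_G = "PSI_G"
    PSI_U = "PSI_U"
    PSI_C = "PSI_C"
    MISMATCH = "MISMATCH"
    DANGLING_5 = "DANGLING_5"
    DANGLING_3 = "DANGLING_3"

    @property
    def is_dangling(self) -> bool:
        return self in (PairClass.DANGLING_5, PairClass.DANGLING_3)

    @property
    def is_paired(self) -> bool:
        return not self.is_dangling

    @property
    def identity(self) -> str:
        """Strand-orientation-free label: the physical pair or overhang kind.

        Rotation of a duplex swaps which strand a category is read from
        (WC_AU <-> WC_UA, WC_GC <-> WC_CG, DANGLING positions), but leaves
        this identity unchanged.
        """
        if self is PairClass.WC_AU or self is PairClass.WC_UA:
            return "AU"
        if self is PairClass.WC_GC or self is PairClass.WC_CG:
            return "GC"
        if self.is_dangling:
            return "DANGLING"
        return self.value


@dataclass(frozen=True)
class Strand:
    """A single RNA strand, residues written 5'->3' over {A, C, G, U, P}."""

    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise DuplexError("strand must contain at least one residue")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise DuplexError(f"illegal residue code(s): {sorted(bad)}")

    @classmethod
    def from_text(cls, text: str) -> "Strand":
        """Parse a strand string, tolerating 5'/3' decorations and whitespace."""
        s = text.strip().upper()
        for alias, repl in _PSI_ALIASES.items():
            s = s.replace(alias.upper(), repl)
        for deco in ("5'", "3'", "5′", "3′", "5`", "3`"):
            s = s.replace(deco, "")
        s = "".join(s.split())
        return cls(s)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def reverse(self) -> "Strand":
        return Strand(self.residues[::-1])


def classify_column(top: str, bottom: str) -> PairClass:
    """Classify one alignment column (top 5'->3', bottom 3'->5')."""
    if top == GAP and bottom == GAP:
        raise DuplexError("alignment column with no residue on either strand")
    if bottom == GAP or top == GAP:
        raise DuplexError("use _classify_gap for dangling columns")
    if "P" in (top, bottom):
        other = bottom if top == "P" else top
        if other == "P":
            return PairClass.MISMATCH
        return PairClass[f"PSI_{other}"]
    if (top, bottom) in _WC:
        return PairClass[f"WC_{top}{bottom}"]
    if {top, bottom} == {"G", "U"}:
        return PairClass.WOBBLE_GU
    return PairClass.MISMATCH


class Duplex:
    """Two aligned antiparallel strands with at most one overhang per end.

    Parameters
    ----------
    top, bottom:
        Aligned residue strings of equal length; ``top`` is 5'->3', ``bottom``
        is 3'->5'.  ``-`` marks the absent strand under/over a single-residue
        terminal overhang and may appear only at the ends.
    """

    def __init__(self, top: str, bottom: str):
        if len(top) != len(bottom):
            raise DuplexError("aligned strands must have equal length")
        if len(top) == 0:
            raise DuplexError("empty duplex")
        for aligned in (top, bottom):
            core = aligned.strip(GAP)
            if GAP in core:
                raise DuplexError("gaps are only allowed at duplex ends")
            if len(aligned) - len(core) > 2:
                raise DuplexError("more than one overhang per duplex end")
            if not set(core) <= ALPHABET:
                raise DuplexError(f"illegal residue in {core!r}")
        for i in (0, len(top) - 1):
            if top[i] == GAP and bottom[i] == GAP:
                raise DuplexError("column with gaps on both strands")
        for i, (t, b) in enumerate(zip(top, bottom)):
            if (t == GAP or b == GAP) and i not in (0, len(top) - 1):
                raise DuplexError("internal gaps (bulges) are not supported")
        self.top_aligned = top
        self.bottom_aligned = bottom

    # -- basic views ---------------------------------------------------
    @property
    def top(self) -> Strand:
        """Top strand, 5'->3', gaps removed."""
        return Strand(self.top_aligned.replace(GAP, ""))

    @property
    def bottom(self) -> Strand:
        """Bottom strand read 5'->3' (it is stored 3'->5')."""
        return Strand(self.bottom_aligned.replace(GAP, "")[::-1])

    def __len__(self) -> int:
        return len(self.top_aligned)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Duplex)
            and self.top_aligned == other.top_aligned
            and self.bottom_aligned == other.bottom_aligned
        )

    def __hash__(self) -> int:
        return hash((self.top_aligned, self.bottom_aligned))

    def __repr__(self) -> str:
        return f"Duplex({self.top_aligned!r}, {self.bottom_aligned!r})"

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.top_aligned, self.bottom_aligned))

    @property
    def n_paired(self) -> int:
        return sum(1 for t, b in self.columns() if GAP not in (t, b))


def parse_duplex(text: str) -> Duplex:
    """Parse a two-line duplex string (top 5'->3', bottom 3'->5').

    Lines may carry 5'/3' decorations and whitespace; the Unicode Psi is
    accepted for pseudouridine.  When strand lengths differ by one and no
    explicit ``-`` gap is given, the single-residue overhang is placed at
    whichever end maximises the number of recognisable (WC / G-U / Psi)
    pairs, which is unambiguous for every construct of interest.
    """
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    if len(lines) != 2:
        raise DuplexError(f"expected two strand lines, got {len(lines)}")
    raw_top, raw_bot = (ln.strip() for ln in lines)
    explicit = GAP in raw_top or GAP in raw_bot

    def clean(s: str) -> str:
        for alias, repl in _PSI_ALIASES.items():
            s = s.upper().replace(alias.upper(), repl)
        for deco in ("5'", "3'", "5′", "3′", "5`", "3`"):
            s = s.replace(deco, "")
        return "".join(s.split())

    top, bot = clean(raw_top), clean(raw_bot)
    if explicit:
        return Duplex(top, bot)

    if len(top) == len(bot):
        return Duplex(top, bot)
    if abs(len(top) - len(bot)) > 2:
        raise DuplexError("strand lengths differ by more than one per end")

    def candidates(short: str, diff: int) -> list[str]:
        pads = []
        if diff == 1:
            pads = [GAP + short, short + GAP]
        elif diff == 2:
            pads = [GAP + short + GAP]
        return pads

    if len(top) > len(bot):
        options = [(top, p) for p in candidates(bot, len(top) - len(bot))]
    else:
        options = [(p, bot) for p in candidates(top, len(bot) - len(top))]

    def score(t: str, b: str) -> int:
        good = 0
        for ct, cb in zip(t, b):
            if GAP in (ct, cb):
                continue
            if classify_column(ct, cb) is not PairClass.MISMATCH:
                good += 1
        return good

    scored = [(score(t, b), i, t, b) for i, (t, b) in enumerate(options)]
    scored.sort(key=lambda x: (-x[0], x[1]))
    best = scored[0]
    return Duplex(best[2], best[3])


def serialize_duplex(d: Duplex) -> str:
    """Two-line machine-readable form; ``parse_duplex`` round-trips it."""
    return f"{d.top_aligned}\n{d.bottom_aligned}"


def format_duplex(d: Duplex) -> str:
    """Human-oriented form with 5'/3' markers, for reports and logs."""
    return f"5'-{d.top_aligned}-3'\n3'-{d.bottom_aligned}-5'"


def reverse_duplex(d: Duplex) -> Duplex:
    """The same physical molecule read from the other strand.

    The bottom strand (reversed into 5'->3') becomes the top and vice
    versa; an involution that leaves every physical stack in place.
    """
    return Duplex(d.bottom_aligned[::-1], d.top_aligned[::-1])


def classify_pairs(d: Duplex) -> list[PairClass]:
    """One :class:`PairClass` per alignment column, dangling ends included.

    A dangling residue is labelled by its own strand end: a top-strand
    overhang at the left column is that strand's 5' end (``DANGLING_5``),
    a bottom-strand overhang at the left column is the bottom 3' end
    (``DANGLING_3``), and symmetrically on the right.
    """
    out: list[PairClass] = []
    last = len(d) - 1
    for i, (t, b) in enumerate(d.columns()):
        if b == GAP:  # unpaired top residue
            out.append(PairClass.DANGLING_5 if i == 0 else PairClass.DANGLING_3)
        elif t == GAP:  # unpaired bottom residue
            out.append(PairClass.DANGLING_3 if i == 0 else PairClass.DANGLING_5)
        else:
            out.append(classify_column(t, b))
        if (t == GAP or b == GAP) and i not in (0, last):
            raise DuplexError("internal gap")
    return out
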