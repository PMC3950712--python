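"""Nearest-neighbor single-strand extinction coefficients at 260 nm.

ε(strand) = Σᵢ ε(NᵢNᵢ₊₁) − Σ_interior ε(Nᵢ), the standard dinucleoside-
phosphate approximation for an unstructured strand (dinucleotide values
are per dinucleoside, i.e. twice the per-residue averages of the classic
tabulation).  Pseudouridine has no tabulated values and is assigned
those of U (its true nucleoside ε260 is ~20% lower); ``overrides`` lets
callers quantify that bias: each dinucleotide containing an overridden
residue is shifted by the full mononucleotide difference per occurrence,
so the net effect is one mononucleotide difference per substitution
whether terminal or interior.
"""

from __future__ import annotations

import csv
from importlib import resources

from .duplex import Strand

_TABLE_FILE = "extinction_260.tsv"


def _load_table() -> tuple[dict[str, float], dict[str, float]]:
    text = resources.files("psimelt.data").joinpath(_TABLE_FILE).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    mono: dict[str, float] = {}
    di: dict[str, float] = {}
    for row in csv.DictReader(lines, delimiter="\t"):
        (mono if row["kind"] == "mono" else di)[row["key"]] = float(row["eps_260"])
    return mono, di


_MONO, _DI = _load_table()


def _as_u(base: str) -> str:
    return "U" if base == "P" else base


def _eps_mono(base: str, overrides: dict[str, float] | None) -> float:
    if overrides and base in overrides:
        return overrides[base]
    return _MONO[_as_u(base)]


def extinction_nn(strand: Strand, overrides: dict[str, float] | None = None) -> float:
    """Nearest-neighbor ε260 (M⁻¹ cm⁻¹) of a single strand."""
    seq = strand.residues
    if len(seq) == 1:
        return _eps_mono(seq, overrides)
    total = 0.0
    for a, b in zip(seq, seq[1:]):
        di = _DI[_as_u(a) + _as_u(b)]
        for x in (a, b):
            if overrides and x in overrides:
                di += overrides[x] - _MONO[_as_u(x)]
        total += di
    for x in seq[1:-1]:
        total -= _eps_mono(x, overrides)
    return total
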