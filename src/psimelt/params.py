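"""Nearest-neighbor parameter tables.

Free energies are ΔG°37 of helix propagation/initiation in kcal/mol,
formation convention (negative = stabilizing), at 1 M NaCl.  Tables ship
as plain-text TSV inside the package (``psimelt/data``) and can be
overridden or extended from user files of the same format.

Stack keys are dinucleotide duplex fragments written ``XY/WZ``: top
strand 5'-XY-3' over bottom strand 3'-WZ-5'.  Reading the same physical
stack from the other strand rotates it by 180 degrees, ``XY/WZ`` ->
``ZW/YX``; keys are stored under the lexicographically smaller of the two
spellings, so every physical stack appears exactly once.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .duplex import GAP, Duplex, PairClass, classify_column

_DATA_PACKAGE = "psimelt.data"

#: terminal-pair penalty categories
TERMINAL_CATEGORY = {
    PairClass.WC_AU: "AU",
    PairClass.WC_UA: "AU",
    PairClass.WC_GC: "GC",
    PairClass.WC_CG: "GC",
    PairClass.WOBBLE_GU: "GU",
    PairClass.PSI_A: "PA",
}


class UnparameterizedContextError(KeyError):
    """A duplex context with no tabulated nearest-neighbor parameter."""

    def __init__(self, key: str):
        super().__init__(key)
        self.key = key

    def __str__(self) -> str:  # KeyError quotes its arg; keep it readable
        return f"unparameterized context: {self.key}"


def rotate_stack_key(key: str) -> str:
    """``XY/WZ`` read from the other strand: ``ZW/YX``."""
    top, bottom = key.split("/")
    return bottom[::-1] + "/" + top[::-1]


def canonical_stack_key(key: str) -> str:
    """Canonical spelling of a stack key, invariant under 180° rotation."""
    return min(key, rotate_stack_key(key))


def stack_key(pair_i: tuple[str, str], pair_j: tuple[str, str]) -> str:
    """Key of the stack formed by two adjacent pairs (5'->3' on top)."""
    return canonical_stack_key(pair_i[0] + pair_j[0] + "/" + pair_i[1] + pair_j[1])


@dataclass(frozen=True)
class ParamEntry:
    value: float
    provenance: str


@dataclass
class NNParameterSet:
    """Keyed ΔG°37 tables with per-entry provenance.

    ``stacks`` maps canonical stack keys; ``terminal`` maps the category of
    a helix-terminal pair (AU, GC, GU, PA) to its end penalty; ``dangling``
    maps ``(kind, base, pair)`` where kind is ``dangle5``/``dangle3``, the
    dangling base sits on the top strand and ``pair`` is the adjacent pair
    written top+bottom.
    """

    name: str = "custom"
    stacks: dict[str, ParamEntry] = field(default_factory=dict)
    initiation: ParamEntry | None = None
    terminal: dict[str, ParamEntry] = field(default_factory=dict)
    dangling: dict[tuple[str, str, str], ParamEntry] = field(default_factory=dict)

    # -- lookups -------------------------------------------------------
    def stack(self, key: str) -> ParamEntry:
        canon = canonical_stack_key(key)
        try:
            return self.stacks[canon]
        except KeyError:
            raise UnparameterizedContextError(f"stack {key}") from None

    def terminal_penalty(self, category: str) -> ParamEntry:
        try:
            return self.terminal[category]
        except KeyError:
            raise UnparameterizedContextError(f"terminal {category} pair") from None

    def dangle(self, kind: str, base: str, pair: str) -> ParamEntry:
        try:
            return self.dangling[(kind, base, pair)]
        except KeyError:
            raise UnparameterizedContextError(f"{kind} {base}@{pair}") from None

    # -- construction --------------------------------------------------
    def update_from_rows(self, rows: Iterable[Mapping[str, str]]) -> None:
        for row in rows:
            kind = row["kind"]
            key = row["key"]
            entry = ParamEntry(float(row["dG37_kcal_mol"]), row.get("provenance", ""))
            if kind == "stack":
                self.stacks[canonical_stack_key(key)] = entry
            elif kind == "init":
                self.initiation = entry
            elif kind == "terminal":
                self.terminal[key] = entry
            elif kind in ("dangle5", "dangle3"):
                base, pair = key.split("@")
                self.dangling[(kind, base, pair)] = entry
            else:
                raise ValueError(f"unknown parameter kind {kind!r}")
        self._check()

    def _check(self) -> None:
        for key, entry in self.stacks.items():
            if key != canonical_stack_key(key):
                raise ValueError(f"non-canonical stack key {key}")
            if not entry.provenance:
                raise ValueError(f"missing provenance for {key}")

    def copy(self) -> "NNParameterSet":
        out = NNParameterSet(name=self.name, initiation=self.initiation)
        out.stacks = dict(self.stacks)
        out.terminal = dict(self.terminal)
        out.dangling = dict(self.dangling)
        return out


def _read_tsv(name_or_path: str | Path) -> list[dict[str, str]]:
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text()
    else:
        text = resources.files(_DATA_PACKAGE).joinpath(str(name_or_path)).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    return list(reader)


_TABLE_FILES = {
    "wc": "nn_wc.tsv",
    "gu": "nn_gu.tsv",
    "psi_a": "nn_psi_a.tsv",
    "dangling": "nn_dangling.tsv",
}


def load_parameters(
    tables: Iterable[str] = ("wc", "gu", "psi_a", "dangling"),
    overrides: str | Path | None = None,
    name: str | None = None,
) -> NNParameterSet:
    """Assemble a parameter set from the shipped tables.

    ``tables`` selects among the built-in component tables (``wc``, ``gu``,
    ``psi_a``, ``dangling``); ``overrides`` optionally points to a TSV of
    the same layout whose entries replace or extend the built-ins.
    """
    tables = tuple(tables)
    pset = NNParameterSet(name=name or "+".join(tables))
    for t in tables:
        try:
            fname = _TABLE_FILES[t]
        except KeyError:
            raise ValueError(f"unknown parameter table {t!r}") from None
        pset.update_from_rows(_read_tsv(fname))
    if overrides is not None:
        pset.update_from_rows(_read_tsv(overrides))
    return pset


def default_parameters() -> NNParameterSet:
    """WC + revised G-U + Ψ-A + dangling ends: the full working set."""
    return load_parameters()


def paired_stack_keys(d: Duplex) -> list[str]:
    """Canonical stack keys over consecutive paired columns of a duplex."""
    cols = [(t, b) for t, b in d.columns() if GAP not in (t, b)]
    return [stack_key(cols[i], cols[i + 1]) for i in range(len(cols) - 1)]


def terminal_category(top: str, bottom: str) -> str:
    cls = classify_column(top, bottom)
    try:
        return TERMINAL_CATEGORY[cls]
    except KeyError:
        raise UnparameterizedContextError(
            f"terminal {top}-{bottom} ({cls.value}) pair"
        ) from None
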