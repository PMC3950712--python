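"""Published duplex fixtures: measured thermodynamics and printed increments.

Three packaged TSVs transcribe the study's result tables at printed
precision: the per-duplex thermodynamics for both estimation routes (22
duplex systems: 20 pseudouridine test duplexes and the two unmodified
cores they extend), the terminal-addition increments, and the central
U→Ψ substitution increments.  Values are stored as printed magnitudes
(−ΔH°, −ΔS°, −ΔG°37) and converted to the formation (negative) convention
on load.  Fixture-based tests must use table-precision tolerances.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

from .duplex import Duplex
from .nn import EnergyWithSD


@dataclass(frozen=True)
class ThermoPoint:
    """ΔH°/ΔS°/ΔG°37/Tm from one estimation route, formation convention."""

    dh: EnergyWithSD      # kcal/mol
    ds: EnergyWithSD      # eu
    dg37: EnergyWithSD    # kcal/mol
    tm_c: float           # at 1e-4 M total strand


@dataclass(frozen=True)
class FixtureRecord:
    """One duplex row: measured values for both routes plus printed predictions."""

    system: str
    variant: str          # psi | u | core
    duplex: Duplex
    curve_average: ThermoPoint
    tm_plot: ThermoPoint
    predicted_psi_dg37: float | None   # Ψ-A NN prediction as printed (negative)
    predicted_wc_dg37: float | None    # WC/G-U NN prediction as printed (negative)
    two_state: bool


@dataclass(frozen=True)
class PrintedIncrement:
    """A printed ΔΔG°37 with the duplex pair it derives from."""

    label: str
    core_or_motif: str
    system: str
    variant: str
    ddg: float
    ddg_sd: float
    predicted: float | None


def _rows(fname: str) -> list[dict[str, str]]:
    text = resources.files("psimelt.data").joinpath(fname).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _point(row: dict[str, str], prefix: str) -> ThermoPoint:
    def e(col: str) -> EnergyWithSD:
        return EnergyWithSD(-float(row[f"{prefix}_{col}"]), float(row[f"{prefix}_{col}_sd"]))

    return ThermoPoint(e("mdh"), e("mds"), e("mdg"), float(row[f"{prefix}_tm"]))


def table_fixtures() -> list[FixtureRecord]:
    """All 22 duplex systems of the thermodynamic table."""
    out = []
    for row in _rows("table1_duplexes.tsv"):
        out.append(
            FixtureRecord(
                system=row["system"],
                variant=row["variant"],
                duplex=Duplex(row["top"], row["bottom"]),
                curve_average=_point(row, "avg"),
                tm_plot=_point(row, "plot"),
                predicted_psi_dg37=-float(row["pred_psi"]) if row["pred_psi"] else None,
                predicted_wc_dg37=-float(row["pred_wc"]) if row["pred_wc"] else None,
                two_state=row["two_state"] == "1",
            )
        )
    return out


def fixture_index() -> dict[tuple[str, str], FixtureRecord]:
    return {(f.system, f.variant): f for f in table_fixtures()}


def terminal_increment_records() -> list[PrintedIncrement]:
    """Printed terminal-addition increments (core → extended duplex)."""
    return [
        PrintedIncrement(
            label=row["label"],
            core_or_motif=row["core"],
            system=row["extended_system"],
            variant=row["extended_variant"],
            ddg=float(row["ddG"]),
            ddg_sd=float(row["ddG_sd"]),
            predicted=float(row["predicted"]) if row.get("predicted") else None,
        )
        for row in _rows("table2_terminal_increments.tsv")
    ]


def substitution_increment_records() -> list[PrintedIncrement]:
    """Printed central U→Ψ substitution increments."""
    return [
        PrintedIncrement(
            label=f"{row['motif']} opposite {row['opposite']}",
            core_or_motif=row["motif"],
            system=row["system"],
            variant="psi",
            ddg=float(row["ddG"]),
            ddg_sd=float(row["ddG_sd"]),
            predicted=float(row["predicted"]) if row.get("predicted") else None,
        )
        for row in _rows("table3_substitution_increments.tsv")
    ]


def psi_correction_set() -> dict[str, EnergyWithSD]:
    """Measured U→Ψ substitution increments keyed by central motif.

    Keys are ``XPY@N``: the Ψ-containing top-strand triplet and the base
    opposite Ψ.  These are experimental increments of this study offered
    as a provisional correction layer for otherwise unparameterized
    internal Ψ pairs — measured values, not fitted NN parameters.
    """
    out: dict[str, EnergyWithSD] = {}
    for row in _rows("table3_substitution_increments.tsv"):
        motif = row["motif"].split("/")[0].replace("5'", "")  # e.g. GPC
        key = f"{motif}@{row['opposite']}"
        out[key] = EnergyWithSD(float(row["ddG"]), float(row["ddG_sd"]))
    return out
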