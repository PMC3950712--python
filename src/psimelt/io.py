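"""File formats: melting-data CSV, duplex lists, and report TSVs.

Melting CSV dialect: columns ``curve_id, CT_molar, temperature_C,
absorbance`` (+ optional ``duplex_id``); one file may hold many curves and
many duplexes.  Duplex lists are TSV with ``name, top, bottom`` where the
top strand is written 5'->3' and the bottom 3'->5' (``P`` or ``Ψ`` for
pseudouridine, ``-`` for an absent residue opposite an overhang).
Reports mirror the published table layout: magnitudes with ΔH°/ΔS°/Tm
rounded to 1 decimal and ΔG°37 to 2.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .duplex import Duplex, parse_duplex
from .melt import FitResult, MeltCurve, MeltingDataset

MELT_COLUMNS = ["curve_id", "CT_molar", "temperature_C", "absorbance"]


def write_melting_csv(
    datasets: dict[str, MeltingDataset] | MeltingDataset, path: str | Path
) -> None:
    if isinstance(datasets, MeltingDataset):
        datasets = {datasets.name or "duplex": datasets}
    frames = []
    for did, ds in datasets.items():
        for curve in ds:
            frames.append(
                pd.DataFrame(
                    {
                        "duplex_id": did,
                        "curve_id": curve.curve_id,
                        "CT_molar": np.repeat(curve.ct, len(curve.temperatures_c)),
                        "temperature_C": curve.temperatures_c,
                        "absorbance": curve.absorbances,
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.8g")


def read_melting_csv(path: str | Path) -> dict[str, MeltingDataset]:
    """Parse a melting CSV into one :class:`MeltingDataset` per duplex id."""
    df = pd.read_csv(path)
    missing = [c for c in MELT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"melting CSV lacks column(s) {missing}")
    if "duplex_id" not in df.columns:
        df["duplex_id"] = Path(path).stem
    out: dict[str, MeltingDataset] = {}
    for did, dgrp in df.groupby("duplex_id", sort=True):
        curves = []
        for cid, cgrp in dgrp.groupby("curve_id", sort=True):
            cgrp = cgrp.sort_values("temperature_C")
            ct = float(cgrp["CT_molar"].iloc[0])
            curves.append(
                MeltCurve(
                    cgrp["temperature_C"].to_numpy(),
                    cgrp["absorbance"].to_numpy(),
                    ct,
                    curve_id=str(cid),
                )
            )
        curves.sort(key=lambda c: c.ct)
        out[str(did)] = MeltingDataset(curves, name=str(did))
    return out


def read_duplex_tsv(path: str | Path) -> dict[str, Duplex]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("name", "top", "bottom"):
        if col not in df.columns:
            raise ValueError(f"duplex TSV lacks column {col!r}")
    out: dict[str, Duplex] = {}
    for _, row in df.iterrows():
        out[row["name"]] = parse_duplex(f"{row['top']}\n{row['bottom']}")
    return out


def thermo_frame(results: dict[str, dict[str, FitResult]]) -> pd.DataFrame:
    """Published-layout table: both routes side by side, printed magnitudes."""
    rows = []
    for did in sorted(results):
        row: dict[str, object] = {"duplex_id": did}
        for tag, fit in results[did].items():
            row[f"{tag}_mdH"] = round(-fit.dh.value, 1)
            row[f"{tag}_mdH_sd"] = round(fit.dh.sd, 1)
            row[f"{tag}_mdS"] = round(-fit.ds.value, 1)
            row[f"{tag}_mdS_sd"] = round(fit.ds.sd, 1)
            row[f"{tag}_mdG37"] = round(-fit.dg37.value, 2)
            row[f"{tag}_mdG37_sd"] = round(fit.dg37.sd, 2)
            row[f"{tag}_Tm"] = round(fit.tm_1e4_c, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV serialization (fixed float rendering)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
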