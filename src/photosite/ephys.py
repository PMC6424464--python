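"""Electrophysiology-derived quantities for receptor modulation studies.

Three per-cell quantities from two-electrode voltage-clamp peak currents
(signed, recorded at -60 mV):

* potentiation response ratio — peak response to GABA + modulator over the
  peak response to GABA alone;
* direct activation — peak response to modulator alone, normalized to the
  saturating GABA + propofol response (open-probability units); a flag
  switches the denominator to the saturating-GABA response instead;
* constitutive open probability — P_o,const = I_PTX / (I_PTX − I_GABA+prop),
  anchored between picrotoxin (P_o ~ 0) and saturating GABA + propofol
  (P_o ~ 1).

Summaries are mean +/- SD (n-1 denominator) with n, per construct.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "CellMeasurement",
    "EphysSummary",
    "potentiation_ratio",
    "direct_activation",
    "po_const",
    "summarize",
    "cells_from_dataframe",
]

QUANTITIES = ("potentiation", "activation", "poconst")


@dataclass
class CellMeasurement:
    """Signed peak currents for one cell (same units throughout, e.g. uA)."""

    cell_id: str
    construct: str
    i_gaba: float | None = None
    i_gaba_mod: float | None = None
    i_mod_alone: float | None = None
    i_picrotoxin: float | None = None
    i_gaba_sat_propofol: float | None = None
    i_gaba_sat: float | None = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite for cell {self.cell_id}")


@dataclass
class EphysSummary:
    quantity: str
    per_construct: dict[str, tuple[float, float, int]]  # construct -> (mean, SD, n)
    single_cell_constructs: tuple[str, ...] = ()  # SD reported as 0 with n == 1


def potentiation_ratio(peak_gaba_plus_mod: float, peak_gaba: float) -> float:
    """Peak response with GABA + modulator over peak response with GABA alone."""
    if peak_gaba == 0:
        raise ValueError("peak GABA response is zero; ratio undefined")
    return peak_gaba_plus_mod / peak_gaba


def direct_activation(peak_modulator_alone: float, peak_reference: float) -> float:
    """Modulator-alone response as a fraction of the reference response.

    The reference is the saturating GABA + propofol response (open-
    probability units); multiply by 100 for percent display.
    """
    if peak_reference == 0:
        raise ValueError("reference response is zero; fraction undefined")
    return peak_modulator_alone / peak_reference


def po_const(i_picrotoxin: float, i_gaba_sat_propofol: float) -> float:
    """Constitutive open probability, I_PTX / (I_PTX - I_GABA+propofol).

    Under the recording sign convention (picrotoxin holding-current shift
    >= 0, GABA+propofol current <= 0) the result lies in [0, 1].
    """
    denom = i_picrotoxin - i_gaba_sat_propofol
    if denom == 0:
        raise ValueError("I_PTX equals I_GABA+propofol; P_o,const undefined")
    return i_picrotoxin / denom


def _cell_value(cell: CellMeasurement, quantity: str, activation_reference: str) -> float:
    if quantity == "potentiation":
        return potentiation_ratio(_req(cell, "i_gaba_mod"), _req(cell, "i_gaba"))
    if quantity == "activation":
        ref = (
            "i_gaba_sat" if activation_reference == "gaba_sat" else "i_gaba_sat_propofol"
        )
        return direct_activation(_req(cell, "i_mod_alone"), _req(cell, ref))
    if quantity == "poconst":
        return po_const(_req(cell, "i_picrotoxin"), _req(cell, "i_gaba_sat_propofol"))
    raise ValueError(f"unknown quantity {quantity!r}; expected one of {QUANTITIES}")


class _MissingField(Exception):
    pass


def _req(cell: CellMeasurement, name: str) -> float:
    v = getattr(cell, name)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        raise _MissingField(name)
    return float(v)


def summarize(
    cells: list[CellMeasurement],
    quantity: str,
    activation_reference: str = "gaba_propofol",
) -> EphysSummary:
    """Mean +/- SD (ddof 1) and n per construct; cells missing fields skipped."""
    values: dict[str, list[float]] = {}
    for cell in cells:
        try:
            v = _cell_value(cell, quantity, activation_reference)
        except _MissingField:
            continue
        values.setdefault(cell.construct, []).append(v)
    if not values:
        raise ValueError(f"no cells carry the fields required for {quantity!r}")
    per_construct = {}
    singles = []
    for construct, vals in sorted(values.items()):
        arr = np.asarray(vals)
        if arr.size == 1:
            per_construct[construct] = (float(arr[0]), 0.0, 1)
            singles.append(construct)
        else:
            per_construct[construct] = (
                float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)
            )
    return EphysSummary(quantity, per_construct, tuple(singles))


def cells_from_dataframe(df: pd.DataFrame) -> list[CellMeasurement]:
    """Build cells from a table with one labeled row per cell."""
    known = {f.name for f in fields(CellMeasurement)}
    out = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in known}
        kwargs.setdefault("cell_id", str(len(out)))
        kwargs.setdefault("construct", "all")
        out.append(CellMeasurement(**kwargs))
    return out
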