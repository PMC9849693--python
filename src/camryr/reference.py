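"""Published binding parameters for CaM variants and RyR peptides.

Small reference tables of experimentally determined constants for wild
type, N97I and Q135P calmodulin binding the RyR1/RyR2 CaMBD2 peptides:
apparent K_D values from fluorescence titrations, and the calorimetric
(K_D, ΔH) pairs together with the derived ΔG, −TΔS and ΔΔG they imply.
The derived columns serve as the fixed point for the thermodynamic
conversion layer: running :func:`camryr.equilibria.make_thermo_record`
and :func:`camryr.equilibria.ddg` on the (K_D, ΔH) inputs must
reproduce every derived cell to the printed 0.01 kcal/mol precision
(±0.02 tolerance).
"""

from __future__ import annotations

import io as _stdlib_io

import pandas as pd

from camryr.equilibria import ThermoRecord, ddg, make_thermo_record

# Apparent K_D (nM, mean ± s.d. over triplicate titrations) from
# Trp-fluorescence titrations of 1 µM peptide with CaM.
_FLUORESCENCE_CSV = """\
variant,peptide,kd_nM,kd_sd_nM,n
WT,RyR1,256,27,3
WT,RyR2,110,22,3
N97I,RyR1,198,38,3
N97I,RyR2,199,30,3
Q135P,RyR1,269,39,3
Q135P,RyR2,317,134,3
"""

# Calorimetric one-set-of-sites parameters (25 °C) with the published
# free-energy decomposition.  kd/dh are the fitted inputs; dg,
# minus_tds and ddg are the derived cells the conversion layer must
# reproduce.  ddg is relative to WT for the same peptide.
_ITC_CSV = """\
variant,peptide,n_titrations,kd_nM,kd_sd_nM,dh_kcal,dh_sd_kcal,dg_kcal,minus_tds_kcal,ddg_kcal
WT,RyR1,3,12.31,4.87,-9.94,1.23,-10.78,-0.84,
N97I,RyR1,3,19.93,3.23,-9.58,0.16,-10.50,-0.92,0.28
Q135P,RyR1,4,62.03,21.13,-19.97,4.37,-9.83,10.14,0.95
WT,RyR2,5,8.62,2.20,-11.28,0.62,-11.01,0.27,
N97I,RyR2,3,12.32,3.18,-10.02,0.13,-10.78,-0.76,0.23
Q135P,RyR2,3,83.45,7.99,-16.20,0.14,-9.65,6.55,1.36
"""


def fluorescence_kd_table() -> pd.DataFrame:
    """Published fluorescence-titration K_D values (nM)."""
    return pd.read_csv(_stdlib_io.StringIO(_FLUORESCENCE_CSV))


def itc_table() -> pd.DataFrame:
    """Published ITC parameters and their free-energy decomposition."""
    return pd.read_csv(_stdlib_io.StringIO(_ITC_CSV))


def itc_thermo_records() -> dict[tuple[str, str], ThermoRecord]:
    """ThermoRecords recomputed from the published (K_D, ΔH) inputs.

    Only the measured inputs are used; ΔG and −TΔS are recomputed by
    the package's own conversion layer.
    """
    records = {}
    for row in itc_table().itertuples():
        records[(row.variant, row.peptide)] = make_thermo_record(
            kd=row.kd_nM * 1e-9, dh=row.dh_kcal,
            variant=row.variant, peptide=row.peptide)
    return records


def itc_comparison_table() -> pd.DataFrame:
    """Recomputed vs published ΔG / −TΔS / ΔΔG, side by side.

    Columns ``*_calc`` are computed from the (K_D, ΔH) inputs at run
    time; ``*_ref`` carry the published values.
    """
    records = itc_thermo_records()
    rows = []
    for row in itc_table().itertuples():
        rec = records[(row.variant, row.peptide)]
        wt = records[("WT", row.peptide)]
        rows.append({
            "variant": row.variant,
            "peptide": row.peptide,
            "kd_nM": row.kd_nM,
            "dh_kcal": row.dh_kcal,
            "dg_calc": rec.dg,
            "dg_ref": row.dg_kcal,
            "minus_tds_calc": rec.minus_tds,
            "minus_tds_ref": row.minus_tds_kcal,
            "ddg_calc": None if row.variant == "WT" else ddg(rec, wt),
            "ddg_ref": None if row.variant == "WT" else row.ddg_kcal,
        })
    return pd.DataFrame(rows)
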