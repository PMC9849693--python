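"""One-set-of-sites isothermal titration calorimetry.

Models a perfusion-cell titration in which peptide (syringe) is
injected into CaM (cell): each injection displaces part of the cell
content, so cumulative concentrations carry the standard displacement
correction before the 1:1 mass balance is solved.  Fitting recovers the
stoichiometry N, the dissociation constant K_D and the molar binding
enthalpy ΔH; the entropic term follows through the shared
thermodynamic layer in :mod:`camryr.equilibria`.

Sign convention: exothermic binding (ΔH < 0) produces negative
injection heats.  Heats are expressed in kcal per mole of injectant
unless tagged otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize

from camryr.equilibria import (
    STANDARD_TEMPERATURE,
    FitFailureError,
    ThermoRecord,
    make_thermo_record,
)


@dataclass(frozen=True)
class ITCProtocol:
    """Instrument protocol for one titration.

    Volumes in litres, concentrations molar.  ``cell_conc`` is the
    species pre-loaded in the cell (CaM); ``syringe_conc`` the titrant
    (peptide).
    """

    cell_volume: float
    cell_conc: float
    syringe_conc: float
    injection_volumes: np.ndarray
    temperature: float = STANDARD_TEMPERATURE

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes, dtype=float)
        object.__setattr__(self, "injection_volumes", v)
        if self.cell_volume <= 0 or self.cell_conc <= 0 or self.syringe_conc <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if v.size < 5:
            raise ValueError("at least 5 injections required")
        if np.any(v <= 0):
            raise ValueError("injection volumes must be positive")


@dataclass(frozen=True)
class Thermogram:
    """Integrated per-injection heats, with an optional dilution blank."""

    heats: np.ndarray
    units: str = "kcal/mol_injectant"
    blank_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.heats, dtype=float)
        object.__setattr__(self, "heats", h)
        if self.blank_heats is not None:
            b = np.asarray(self.blank_heats, dtype=float)
            if b.shape != h.shape:
                raise ValueError("blank must match thermogram length")
            object.__setattr__(self, "blank_heats", b)


def _cell_concentrations(protocol: ITCProtocol) -> tuple[np.ndarray, np.ndarray]:
    """Displacement-corrected totals in the cell after each injection.

    Standard perfusion-cell formulas: with cumulative injected volume
    ΔV and cell volume V0,

        [M]_i = M0 · (1 − ΔV/2V0) / (1 + ΔV/2V0)
        [X]_i = Xs · (ΔV/V0) / (1 + ΔV/2V0)

    for macromolecule M (in the cell) and titrant X (syringe).
    """
    v0 = protocol.cell_volume
    dv = np.cumsum(protocol.injection_volumes)
    half = dv / (2.0 * v0)
    m = protocol.cell_conc * (1.0 - half) / (1.0 + half)
    x = protocol.syringe_conc * (dv / v0) / (1.0 + half)
    return m, x


def _bound_concentration(m_total: np.ndarray, x_total: np.ndarray,
                         n_sites: float, kd: float) -> np.ndarray:
    """Complex concentration from the 1:1 mass balance with N·[M] sites."""
    sites = n_sites * m_total
    s = sites + x_total + kd
    disc = s * s - 4.0 * sites * x_total
    return (s - np.sqrt(np.maximum(disc, 0.0))) / 2.0


def itc_forward(protocol: ITCProtocol, n_sites: float, kd: float,
                dh: float) -> Thermogram:
    """Predicted per-injection heats (kcal per mole of injectant).

    The cell heat content after injection i is Q_i = [MX]_i·ΔH·V0; the
    measured injection heat corrects for the enthalpy carried out with
    the displaced volume,

        q_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2,

    then is normalized by the moles of titrant injected.
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    v0 = protocol.cell_volume
    m, x = _cell_concentrations(protocol)
    bound = _bound_concentration(m, x, n_sites, kd)
    q = bound * dh * v0  # kcal in cell
    q_prev = np.concatenate(([0.0], q[:-1]))
    dv = protocol.injection_volumes
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    moles_injected = protocol.syringe_conc * dv
    return Thermogram(heats=dq / moles_injected)


def subtract_dilution(thermogram: Thermogram, blank: Thermogram) -> Thermogram:
    """Element-wise blank (heat-of-dilution) subtraction."""
    if thermogram.heats.shape != blank.heats.shape:
        raise ValueError("thermogram and blank lengths differ")
    return Thermogram(heats=thermogram.heats - blank.heats,
                      units=thermogram.units)


def fit_itc(thermogram: Thermogram, protocol: ITCProtocol,
            variant: str = "", peptide: str = "") -> ThermoRecord:
    """Least-squares fit of the one-set-of-sites model.

    Returns a :class:`~camryr.equilibria.ThermoRecord` carrying N, K_D,
    ΔH and the derived ΔG / −TΔS.  The Wiseman c-parameter
    (N·[M]0/K_D) is checked and a reliability warning issued outside
    the informative 1–1000 range.
    """
    heats = thermogram.heats
    if heats.size < 10:
        raise ValueError("need at least 10 injections to fit")
    if np.allclose(heats, 0.0):
        raise FitFailureError("all-zero heats: nothing to fit")

    dh0 = float(np.mean(heats[:3]))
    params = Parameters()
    params.add("n_sites", value=1.0, min=0.1, max=10.0)
    params.add("log10_kd", value=-7.5, min=-13.0, max=-2.0)
    params.add("dh", value=dh0 if dh0 != 0 else -1.0)

    def residual(p):
        model = itc_forward(protocol, p["n_sites"].value,
                            10.0 ** p["log10_kd"].value, p["dh"].value)
        return model.heats - heats

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitFailureError(f"ITC fit did not converge ({out.message})")
    n_hat = out.params["n_sites"].value
    kd_hat = 10.0 ** out.params["log10_kd"].value
    dh_hat = out.params["dh"].value

    c = n_hat * protocol.cell_conc / kd_hat
    if not 1.0 <= c <= 1000.0:
        warnings.warn(
            f"c-parameter {c:.3g} outside the informative 1-1000 window; "
            "K_D estimate may be unreliable", RuntimeWarning, stacklevel=2)

    return make_thermo_record(kd=kd_hat, dh=dh_hat,
                              temperature=protocol.temperature,
                              n_sites=n_hat, variant=variant, peptide=peptide)
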