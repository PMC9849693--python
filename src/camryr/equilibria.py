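"""Equilibrium binding analysis for fluorescence titrations.

A fixed amount of RyR peptide (the only tryptophan in the system) is
titrated with increasing CaM; the Trp emission-peak wavelength reports
the bound fraction.  This module holds the one-site binding isotherms,
the per-replica nonlinear fit, and the thermodynamic conversion layer
(ΔG = RT ln K_D, −TΔS = ΔG − ΔH, ΔΔG = ΔG_mut − ΔG_WT) shared by the
fluorescence and calorimetric experiments.

Concentrations are molar, energies kcal/mol, temperatures kelvin
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT = 1.9872e-3

#: 25 °C, the temperature of every binding experiment modelled here.
STANDARD_TEMPERATURE = 298.15

MODEL_TAGS = ("hyperbolic", "quadratic_depletion")


class DegenerateSpanError(ValueError):
    """Raised when the titration endpoints coincide (y0 == ymax)."""


class FitFailureError(RuntimeError):
    """Raised when a nonlinear fit does not converge to a usable optimum."""


@dataclass(frozen=True)
class TitrationSeries:
    """One fluorescence-titration replica.

    Parameters
    ----------
    titrant_total
        Total titrant (CaM) concentration per point, molar, strictly
        increasing from 0.
    signal
        Scalar observable per point — here the Trp emission-peak
        wavelength in nm.
    ligand_total
        Fixed total peptide concentration (molar).
    temperature
        Kelvin.
    replicate_id
        Free-form replica label.
    """

    titrant_total: np.ndarray
    signal: np.ndarray
    ligand_total: float
    temperature: float = STANDARD_TEMPERATURE
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        x = np.asarray(self.titrant_total, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "titrant_total", x)
        object.__setattr__(self, "signal", y)
        if x.shape != y.shape:
            raise ValueError("titrant_total and signal must have equal length")
        if x.size < 5:
            raise ValueError("a titration needs at least 5 points")
        if np.any(x < 0):
            raise ValueError("titrant concentrations must be non-negative")
        if np.any(np.diff(x) <= 0):
            raise ValueError("titrant concentrations must be strictly increasing")
        if not self.ligand_total > 0:
            raise ValueError("ligand_total must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Result of a single-replica one-site fit."""

    kd: float
    kd_stderr: float | None
    amplitude: float
    model_tag: str
    residual_norm: float
    y0: float = 0.0
    ymax: float = 1.0
    replicate_id: str = ""
    boundary_warning: bool = False

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be non-negative")


@dataclass(frozen=True)
class ThermoRecord:
    """Equilibrium constant plus its free-energy decomposition.

    ``dg = R·T·ln(kd / 1 M)`` and ``minus_tds = dg − dh`` hold by
    construction; use :func:`make_thermo_record` to build records.
    """

    kd: float
    dh: float
    dg: float
    minus_tds: float
    temperature: float
    n_sites: float = 1.0
    variant: str = ""
    peptide: str = ""

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise ValueError("kd must be positive")
        if abs(self.dg - delta_g_from_kd(self.kd, self.temperature)) > 1e-9:
            raise ValueError("dg inconsistent with RT·ln(kd)")
        if abs(self.minus_tds - (self.dg - self.dh)) > 1e-9:
            raise ValueError("minus_tds inconsistent with dg − dh")


def fraction_bound(signal, y0: float, ymax: float):
    """Fraction of peptide bound from the signal endpoints.

    ``fb = (y − y0) / (ymax − y0)`` where ``y0`` and ``ymax`` are the
    emission-peak wavelengths of the free peptide and the saturated
    complex.  Noise can push values slightly outside [0, 1]; they are
    returned unclamped.
    """
    if ymax == y0:
        raise DegenerateSpanError("signal endpoints coincide; fraction bound undefined")
    return (np.asarray(signal, dtype=float) - y0) / (ymax - y0)


def one_site_model(titrant_total, kd: float, ligand_total: float = 0.0,
                   model_tag: str = "hyperbolic"):
    """Predicted fraction bound for a 1:1 binding equilibrium.

    ``hyperbolic`` evaluates x/(kd + x) on the *total* titrant
    concentration (no depletion).  ``quadratic_depletion`` solves the
    exact 1:1 mass balance for the complex and divides by the fixed
    ligand (peptide) total:

        fb = ((x + L + kd) − sqrt((x + L + kd)² − 4·x·L)) / (2·L)
    """
    x = np.asarray(titrant_total, dtype=float)
    if not kd > 0:
        raise ValueError("kd must be positive")
    if np.any(x < 0):
        raise ValueError("titrant concentrations must be non-negative")
    if model_tag == "hyperbolic":
        return x / (kd + x)
    if model_tag == "quadratic_depletion":
        if not ligand_total > 0:
            raise ValueError("quadratic_depletion needs ligand_total > 0")
        s = x + ligand_total + kd
        disc = s * s - 4.0 * x * ligand_total
        # clip tiny negative round-off before the root
        complex_conc = (s - np.sqrt(np.maximum(disc, 0.0))) / 2.0
        return complex_conc / ligand_total
    raise ValueError(f"unknown model_tag {model_tag!r}")


def fit_fluorescence_titration(series: TitrationSeries,
                               model_tag: str = "hyperbolic",
                               fix_endpoints: bool = False) -> BindingFit:
    """Nonlinear least-squares K_D estimate for one titration replica.

    Each replica is fitted individually (never pooled).  By default the
    signal endpoints ``y0``/``ymax`` are free parameters, which is
    robust to noise on the first/last points; ``fix_endpoints=True``
    pins them to the first and last observed signal, the literal
    endpoint reading of the fraction-bound formula.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model_tag {model_tag!r}")
    x, y = series.titrant_total, series.signal
    span = y[-1] - y[0]
    if span == 0 or np.ptp(y) == 0:
        raise FitFailureError(
            f"replica {series.replicate_id!r}: constant signal, no transition to fit")

    kd_min, kd_max = 1e-13, 1e-2
    params = Parameters()
    # log-spaced kd keeps the optimizer well conditioned over nM–µM
    params.add("log10_kd", value=np.log10(max(x[1], 1e-9)),
               min=np.log10(kd_min), max=np.log10(kd_max))
    params.add("y0", value=float(y[0]), vary=not fix_endpoints)
    params.add("ymax", value=float(y[-1]), vary=not fix_endpoints)

    def residual(p):
        fb = one_site_model(x, 10.0 ** p["log10_kd"].value,
                            series.ligand_total, model_tag)
        return p["y0"].value + (p["ymax"].value - p["y0"].value) * fb - y

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitFailureError(
            f"replica {series.replicate_id!r}: fit did not converge ({out.message})")

    log_kd = out.params["log10_kd"]
    kd = 10.0 ** log_kd.value
    boundary = bool(np.isclose(log_kd.value, log_kd.min) or
                    np.isclose(log_kd.value, log_kd.max))
    if boundary:
        warnings.warn(f"replica {series.replicate_id!r}: kd hit a fit boundary",
                      RuntimeWarning, stacklevel=2)
    kd_stderr = None
    if log_kd.stderr is not None:
        kd_stderr = kd * np.log(10.0) * log_kd.stderr
    y0_hat = out.params["y0"].value
    ymax_hat = out.params["ymax"].value
    resid = np.asarray(out.residual, dtype=float)
    return BindingFit(
        kd=kd,
        kd_stderr=kd_stderr,
        amplitude=abs(ymax_hat - y0_hat) / abs(span) if span else 1.0,
        model_tag=model_tag,
        residual_norm=float(np.linalg.norm(resid) / max(abs(span), 1e-300)),
        y0=float(y0_hat),
        ymax=float(ymax_hat),
        replicate_id=series.replicate_id,
        boundary_warning=boundary,
    )


def delta_g_from_kd(kd: float, temperature: float = STANDARD_TEMPERATURE) -> float:
    """Standard free energy of binding, ΔG = R·T·ln(K_D / 1 M), kcal/mol.

    Negative for sub-molar dissociation constants; the 1 M standard
    state is implicit in expressing ``kd`` in molar units.
    """
    if not kd > 0:
        raise ValueError("kd must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT * temperature * float(np.log(kd))


def make_thermo_record(kd: float, dh: float,
                       temperature: float = STANDARD_TEMPERATURE,
                       n_sites: float = 1.0, variant: str = "",
                       peptide: str = "") -> ThermoRecord:
    """Build a :class:`ThermoRecord` with ΔG and −TΔS derived from K_D and ΔH."""
    dg = delta_g_from_kd(kd, temperature)
    return ThermoRecord(kd=kd, dh=dh, dg=dg, minus_tds=dg - dh,
                        temperature=temperature, n_sites=n_sites,
                        variant=variant, peptide=peptide)


def ddg(mutant: ThermoRecord, wildtype: ThermoRecord) -> float:
    """Mutational free-energy penalty ΔΔG = ΔG_mut − ΔG_WT (kcal/mol).

    Positive values mean the mutation weakens binding.  Both records
    must describe the same peptide at the same temperature.
    """
    if mutant.peptide != wildtype.peptide:
        raise ValueError(
            f"peptide mismatch: {mutant.peptide!r} vs {wildtype.peptide!r}")
    if mutant.temperature != wildtype.temperature:
        raise ValueError("temperature mismatch between records")
    return mutant.dg - wildtype.dg


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean ± s.d. aggregation of per-replica K_D estimates."""

    kd_mean: float
    kd_sd: float
    n: int
    kds: tuple[float, ...] = field(default_factory=tuple)


def aggregate_replicates(fits: list[BindingFit]) -> ReplicateSummary:
    """Mean ± s.d. over per-replica K_D values (ddof=1)."""
    if not fits:
        raise ValueError("no fits to aggregate")
    kds = np.array([f.kd for f in fits], dtype=float)
    sd = float(np.std(kds, ddof=1)) if kds.size > 1 else 0.0
    return ReplicateSummary(kd_mean=float(np.mean(kds)), kd_sd=sd,
                            n=kds.size, kds=tuple(kds))


def compare_kd(fits_a: list[BindingFit], fits_b: list[BindingFit]) -> float:
    """Welch t-test p-value for a difference in mean K_D between two conditions."""
    a = [f.kd for f in fits_a]
    b = [f.kd for f in fits_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicas per condition")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
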