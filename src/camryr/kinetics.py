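"""SPR kinetics under the 1:1 Langmuir model.

CaM is immobilized on the chip and RyR peptide flows over it.  Under
pseudo-first-order conditions the association phase follows
``R(t) = Req·(1 − exp(−kobs·t))`` with ``kobs = kon·C + koff`` and the
dissociation phase is a single exponential ``R(t) = R0·exp(−koff·t)``.
Following standard practice for this kind of data the dissociation
phase is fitted first; the resulting koff is then held fixed while
kon is extracted from each association curve.

Units: time s, response RU (1 RU = 1 pg/mm²), concentration M,
kon M⁻¹s⁻¹, koff s⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Parameters, minimize
from scipy import stats

from camryr.equilibria import FitFailureError


@dataclass(frozen=True)
class Sensorgram:
    """One SPR binding curve: 60 s association, 300 s dissociation by default."""

    time: np.ndarray
    response: np.ndarray
    analyte_conc: float
    assoc_window: tuple[float, float] = (0.0, 60.0)
    dissoc_window: tuple[float, float] = (60.0, 360.0)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.shape != r.shape:
            raise ValueError("time and response must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        a0, a1 = self.assoc_window
        d0, d1 = self.dissoc_window
        if not (a0 < a1 <= d0 < d1):
            raise ValueError("association window must precede dissociation window")

    def phase(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        """Time (rebased to phase start) and response inside one phase window."""
        lo, hi = self.assoc_window if which == "association" else self.dissoc_window
        mask = (self.time >= lo) & (self.time <= hi)
        return self.time[mask] - lo, self.response[mask]


@dataclass(frozen=True)
class KineticFit:
    """Aggregated rate constants: mean ± s.e.m. over independent curves."""

    kon: float
    kon_sem: float
    koff: float
    koff_sem: float
    n_curves: int
    kons: tuple[float, ...] = ()
    koffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (self.kon > 0 and self.koff > 0):
            raise ValueError("rate constants must be positive")

    @property
    def kd_kinetic(self) -> float:
        """Kinetic dissociation constant K_D = koff/kon (M)."""
        return self.koff / self.kon


def fit_dissociation(sensorgram: Sensorgram, drift_offset: bool = False
                     ) -> tuple[float, float]:
    """Single-exponential dissociation fit; returns (koff, R0).

    ``R(t) = R0·exp(−koff·t)`` (plus a constant offset when
    ``drift_offset``), with t rebased to the start of the dissociation
    window.
    """
    t, r = sensorgram.phase("dissociation")
    if t.size < 20:
        raise ValueError("need at least 20 points in the dissociation window")
    if r[0] <= 0:
        raise ValueError("dissociation phase must start from a positive response")
    if np.polyfit(t, r, 1)[0] >= 0:
        raise FitFailureError("dissociation signal does not decay")

    params = Parameters()
    params.add("r0", value=float(r[0]), min=0.0)
    params.add("koff", value=max(1.0 / t[-1], 1e-6), min=1e-8, max=10.0)
    params.add("offset", value=0.0, vary=drift_offset)

    def residual(p):
        return (p["r0"].value * np.exp(-p["koff"].value * t)
                + p["offset"].value - r)

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitFailureError(f"dissociation fit failed ({out.message})")
    return float(out.params["koff"].value), float(out.params["r0"].value)


def fit_association(sensorgram: Sensorgram, koff: float
                    ) -> tuple[float, float, float]:
    """Pseudo-first-order association fit; returns (kobs, kon, Req).

    Fits ``R(t) = Req·(1 − exp(−kobs·t))`` on the association window,
    then converts ``kon = (kobs − koff)/C``.  A kobs at or below koff
    is physically impossible under this scheme and raises.
    """
    if sensorgram.analyte_conc <= 0:
        raise ValueError("analyte concentration must be positive")
    t, r = sensorgram.phase("association")
    if t.size < 5:
        raise ValueError("too few association points")

    # initialize kobs from the observed half-rise time, which keeps the
    # optimizer out of the saturated-exponential local minimum
    r_end = float(r[-1])
    half_idx = int(np.argmax(r >= r_end / 2.0))
    t_half = t[half_idx] if t[half_idx] > 0 else t[1]
    params = Parameters()
    params.add("req", value=float(max(r.max(), 1.0)), min=0.0)
    params.add("kobs", value=float(np.clip(np.log(2.0) / t_half, 1e-6, 50.0)),
               min=1e-8, max=100.0)

    def residual(p):
        return p["req"].value * (1.0 - np.exp(-p["kobs"].value * t)) - r

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitFailureError(f"association fit failed ({out.message})")
    kobs = float(out.params["kobs"].value)
    req = float(out.params["req"].value)
    if kobs <= koff:
        raise FitFailureError(
            f"kobs ({kobs:.3g}/s) ≤ koff ({koff:.3g}/s): negative kon — check "
            "the analyte concentration labelling or the koff estimate")
    kon = (kobs - koff) / sensorgram.analyte_conc
    return kobs, kon, req


def fit_langmuir_series(curves: list[Sensorgram],
                        koff_mode: str = "per_curve") -> KineticFit:
    """Two-stage 1:1 Langmuir analysis over a concentration series.

    Dissociation first: ``per_curve`` fits koff independently on every
    sensorgram; ``global`` fits one shared koff across all dissociation
    phases simultaneously.  Each curve's association phase then yields
    a kon with that koff fixed.  Rates aggregate as mean ± s.e.m. over
    curves.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 concentrations")
    if koff_mode not in ("per_curve", "global"):
        raise ValueError(f"unknown koff_mode {koff_mode!r}")

    if koff_mode == "global":
        koff_global = _fit_global_koff(curves)
        koffs = [koff_global] * len(curves)
    else:
        koffs = [fit_dissociation(c)[0] for c in curves]

    kons = [fit_association(c, k)[1] for c, k in zip(curves, koffs)]

    kons_arr = np.array(kons)
    koffs_arr = np.array(koffs)
    n = len(curves)

    def sem(a):
        vals = np.unique(a)
        if vals.size == 1:
            return 0.0
        return float(np.std(a, ddof=1) / np.sqrt(len(a)))

    return KineticFit(
        kon=float(kons_arr.mean()), kon_sem=sem(kons_arr),
        koff=float(koffs_arr.mean()), koff_sem=sem(koffs_arr),
        n_curves=n, kons=tuple(kons_arr), koffs=tuple(koffs_arr))


def _fit_global_koff(curves: list[Sensorgram]) -> float:
    """Shared-koff simultaneous fit over all dissociation phases."""
    phases = [c.phase("dissociation") for c in curves]
    params = Parameters()
    params.add("koff", value=1e-2, min=1e-8, max=10.0)
    for i, (t, r) in enumerate(phases):
        params.add(f"r0_{i}", value=float(r[0]), min=0.0)

    def residual(p):
        parts = [p[f"r0_{i}"].value * np.exp(-p["koff"].value * t) - r
                 for i, (t, r) in enumerate(phases)]
        return np.concatenate(parts)

    out = minimize(residual, params, method="leastsq")
    if not out.success:
        raise FitFailureError(f"global koff fit failed ({out.message})")
    return float(out.params["koff"].value)


def fold_change(variant: KineticFit, wildtype: KineticFit,
                which: str = "kon") -> tuple[float, float]:
    """Ratio of mean rate constants (variant/WT) with propagated s.e.m.

    Standard first-order error propagation for a ratio r = a/b:
    σ_r = r·sqrt((σ_a/a)² + (σ_b/b)²).
    """
    a, sa = ((variant.kon, variant.kon_sem) if which == "kon"
             else (variant.koff, variant.koff_sem))
    b, sb = ((wildtype.kon, wildtype.kon_sem) if which == "kon"
             else (wildtype.koff, wildtype.koff_sem))
    ratio = a / b
    err = ratio * np.sqrt((sa / a) ** 2 + (sb / b) ** 2)
    return float(ratio), float(err)


def compare_rates(fit_a: KineticFit, fit_b: KineticFit,
                  which: str = "kon") -> float:
    """Welch t-test p-value on per-curve rate constants between conditions."""
    a = fit_a.kons if which == "kon" else fit_a.koffs
    b = fit_b.kons if which == "kon" else fit_b.koffs
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need per-curve rates on both sides")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
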