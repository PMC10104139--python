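"""Binding-assay analysis: thermal-shift Tm extraction and one-site ITC fits.

Two measurements validate motif-based ligand predictions:

* Thermal shift (differential scanning fluorimetry): a dye reports protein
  unfolding while the sample is heated; the melting temperature Tm is the
  extremum of the first derivative of the fluorescence trace, and a
  ligand-induced shift dTm >= 2 degC is treated as evidence of binding.

* Isothermal titration calorimetry: ligand is injected stepwise into the
  protein solution and the heat of each injection is recorded.  The one-site
  (Wiseman) model relates normalized injection heats to the stoichiometry n,
  dissociation constant K_D and binding enthalpy dH.  After each injection
  the bound fraction Theta solves

      Theta^2 - Theta (1 + Xt/(n Mt) + K_D/(n Mt)) + Xt/(n Mt) = 0

  (root in [0, 1]); the cumulative heat is Q = n Theta Mt dH V0 and the
  per-injection heat includes the displaced-volume correction
  dQ_i = Q_i - Q_{i-1} + (dV_i/V0) (Q_i + Q_{i-1})/2.

The ITC fit is exposed statsmodels-style: build a
:class:`OneSiteBindingModel` from an :class:`Isotherm`, call ``fit()``, and
read estimates, standard errors and ``summary()`` off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

KCAL_PER_CAL = 1e-3

# ---------------------------------------------------------------------------
# Thermal shift


@dataclass
class MeltCurve:
    """One well's fluorescence trace over a temperature ramp (degC)."""

    temperatures: np.ndarray
    fluorescence: np.ndarray
    well: str = ""
    protein: str = ""
    ligand: str = ""

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError("temperature and fluorescence lengths differ")
        if self.temperatures.size < 10:
            raise ValueError("melt curve needs >= 10 points")
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TmResult:
    tm: float | None  # degC; None when the curve is flat
    derivative_extremum: float
    quality: Literal["ok", "flat", "edge"]
    well: str = ""
    protein: str = ""
    ligand: str = ""


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.full(pad, y[0]), y, np.full(pad, y[-1])])
    return np.convolve(padded, kernel, mode="valid")


def compute_tm(
    curve: MeltCurve,
    smooth_window: int = 5,
    extremum_mode: Literal["min", "max"] = "min",
    search_window: tuple[float, float] | None = None,
) -> TmResult:
    """Locate Tm at the extremum of the first derivative of the (smoothed)
    fluorescence, with parabolic sub-gridstep interpolation.

    ``extremum_mode='min'`` follows the instrument convention in which the
    transition appears as a minimum of dF/dT; ``'max'`` covers exports with
    the opposite sign.  A curve whose derivative amplitude does not rise
    above the noise floor is flagged ``flat`` (no Tm); an extremum on the
    first or last usable grid point is flagged ``edge``.
    """
    if smooth_window % 2 == 0 or smooth_window >= curve.temperatures.size:
        raise ValueError("smooth_window must be odd and smaller than the curve")
    T = curve.temperatures
    F = _moving_average(curve.fluorescence, smooth_window)
    dFdT = np.gradient(F, T)
    lo, hi = search_window if search_window else (T[0], T[-1])
    mask = (T >= lo) & (T <= hi)
    idx_all = np.nonzero(mask)[0]
    if idx_all.size < 3:
        raise ValueError("search window holds fewer than 3 points")
    d = dFdT[idx_all]
    k = int(np.argmin(d) if extremum_mode == "min" else np.argmax(d))
    extremum = float(d[k])
    meta = dict(well=curve.well, protein=curve.protein, ligand=curve.ligand)

    # flat test: extremum amplitude vs robust noise of the derivative
    amp = abs(extremum - float(np.median(d)))
    mad = float(np.median(np.abs(d - np.median(d))))
    if amp <= max(6.0 * 1.4826 * mad, 1e-12):
        return TmResult(None, extremum, "flat", **meta)

    i = idx_all[k]
    if k == 0 or k == idx_all.size - 1:
        return TmResult(float(T[i]), extremum, "edge", **meta)
    # parabola through (T[i-1..i+1], d) — vertex gives sub-gridstep Tm
    t0, t1, t2 = T[i - 1], T[i], T[i + 1]
    y0, y1, y2 = dFdT[i - 1], dFdT[i], dFdT[i + 1]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (y1 - y0) + t1 * (y0 - y2) + t0 * (y2 - y1)) / denom
    b = (t2**2 * (y0 - y1) + t1**2 * (y2 - y0) + t0**2 * (y1 - y2)) / denom
    tm = float(-b / (2 * a)) if a != 0 else float(t1)
    if not (t0 <= tm <= t2):
        tm = float(t1)
    return TmResult(tm, extremum, "ok", **meta)


@dataclass(frozen=True)
class DeltaTmRecord:
    delta_tm: float | None
    significant: bool | None
    status: Literal["ok", "not_evaluable"]
    sample: TmResult = None
    control: TmResult = None


def delta_tm(
    sample: TmResult, control: TmResult, threshold: float = 2.0
) -> DeltaTmRecord:
    """Ligand-induced Tm shift; shifts >= ``threshold`` (degC) are significant.

    A flat sample or control propagates a ``not_evaluable`` status.
    """
    if sample.quality == "flat" or control.quality == "flat":
        return DeltaTmRecord(None, None, "not_evaluable", sample, control)
    d = sample.tm - control.tm
    return DeltaTmRecord(float(d), bool(d >= threshold), "ok", sample, control)


# ---------------------------------------------------------------------------
# ITC: protocol, isotherm, forward model


@dataclass(frozen=True)
class ItcProtocol:
    """Titration protocol: volumes in litres, concentrations in mol/L."""

    cell_volume: float  # V0, L
    cell_concentration: float  # Mt0, mol/L (macromolecule)
    syringe_concentration: float  # Xt0, mol/L (ligand)
    injection_volumes: tuple[float, ...]  # L, per injection
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if min(self.cell_volume, self.cell_concentration, self.syringe_concentration) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if len(self.injection_volumes) < 5:
            raise ValueError("protocol needs >= 5 injections")
        if any(v <= 0 for v in self.injection_volumes):
            raise ValueError("injection volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Xt/Mt after each injection (x-axis of the binding isotherm)."""
        _, Mt, Xt = _active_concentrations(self)
        return Xt / Mt


def choline_reference_protocol(n_injections: int = 29) -> ItcProtocol:
    """Titration of 16 uM protein with 9.6 uL injections of 0.5 mM ligand
    into a 1.4 mL perfusion cell — the wild-type choline titration setup."""
    return ItcProtocol(
        cell_volume=1.4e-3,
        cell_concentration=16e-6,
        syringe_concentration=0.5e-3,
        injection_volumes=(9.6e-6,) * n_injections,
    )


def scaled_protocol(
    kd_uM: float,
    c_target: float = 15.0,
    ratio_end: float = 1.6,
    n_injections: int = 58,
    injection_volume: float = 4.8e-6,
    cell_volume: float = 1.4e-3,
    min_cell_uM: float = 16.0,
) -> ItcProtocol:
    """Concentration-scaled titration design for a given expected K_D.

    Keeps the c-value at ``c_target`` (never below the reference 16 uM cell
    concentration) and sets the syringe concentration so the titration ends
    near molar ratio ``ratio_end``.  The default schedule halves the
    reference injection volume and doubles the injection count: at high c
    the transition is sharp, and finer injections are needed to sample it.
    """
    mt = max(min_cell_uM * 1e-6, c_target * kd_uM * 1e-6)
    xt = ratio_end * mt * cell_volume / (n_injections * injection_volume)
    return ItcProtocol(
        cell_volume=cell_volume,
        cell_concentration=mt,
        syringe_concentration=xt,
        injection_volumes=(injection_volume,) * n_injections,
    )


def _active_concentrations(protocol: ItcProtocol):
    """Cumulative injected volume and perfusion-corrected cell concentrations.

    The standard overfill correction for a fixed-volume cell:
    Mt = Mt0 (1 - dV/2V0)/(1 + dV/2V0) and Xt = Xt0 (dV/V0)/(1 + dV/2V0).
    """
    dV = np.cumsum(np.asarray(protocol.injection_volumes))
    V0 = protocol.cell_volume
    Mt = protocol.cell_concentration * (1 - dV / (2 * V0)) / (1 + dV / (2 * V0))
    Xt = protocol.syringe_concentration * (dV / V0) / (1 + dV / (2 * V0))
    return dV, Mt, Xt


def one_site_heats(
    n: float,
    kd_uM: float,
    dh_kcal: float,
    protocol: ItcProtocol,
    normalize: bool = True,
    displacement_correction: bool = True,
) -> np.ndarray:
    """Per-injection heats under the one-site model.

    Parameters are the stoichiometry ``n`` (sites per macromolecule), the
    dissociation constant ``kd_uM`` (uM) and molar enthalpy ``dh_kcal``
    (kcal/mol).  Returns heats in kcal per mole of injectant when
    ``normalize`` is true, else kcal per injection.
    """
    if n <= 0 or kd_uM <= 0:
        raise ValueError("n and K_D must be positive")
    kd = kd_uM * 1e-6  # mol/L
    _, Mt, Xt = _active_concentrations(protocol)
    r = Xt / (n * Mt)
    b = 1.0 + r + kd / (n * Mt)
    theta = (b - np.sqrt(b * b - 4.0 * r)) / 2.0
    Q = n * theta * Mt * dh_kcal * protocol.cell_volume  # kcal
    Qprev = np.concatenate([[0.0], Q[:-1]])
    dVi = np.asarray(protocol.injection_volumes)
    if displacement_correction:
        heats = Q - Qprev + (dVi / protocol.cell_volume) * (Q + Qprev) / 2.0
    else:
        heats = Q - Qprev
    if normalize:
        heats = heats / (protocol.syringe_concentration * dVi)
    return heats


@dataclass
class Isotherm:
    """Integrated per-injection heats plus the protocol that produced them.

    ``heats`` are kcal per mole of injectant (the normalized lower-panel
    convention); raw ucal-per-injection data can be ingested with
    :meth:`from_raw_ucal`.  ``blank_heats`` are ligand-into-buffer dilution
    heats in the same units.
    """

    heats: np.ndarray
    protocol: ItcProtocol
    blank_heats: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.heats.size != self.protocol.n_injections:
            raise ValueError(
                f"{self.heats.size} heats for {self.protocol.n_injections} injections"
            )
        if self.blank_heats is not None:
            self.blank_heats = np.asarray(self.blank_heats, dtype=float)

    @classmethod
    def from_raw_ucal(
        cls, raw_ucal: Sequence[float], protocol: ItcProtocol, **kw
    ) -> "Isotherm":
        raw = np.asarray(raw_ucal, dtype=float)  # ucal per injection
        moles = protocol.syringe_concentration * np.asarray(protocol.injection_volumes)
        return cls(raw * 1e-6 * KCAL_PER_CAL / moles, protocol, **kw)

    def corrected(self) -> np.ndarray:
        if self.blank_heats is None:
            return self.heats.copy()
        return subtract_dilution(self.heats, self.blank_heats)


def subtract_dilution(heats: np.ndarray, blank_heats: Sequence[float]) -> np.ndarray:
    """Subtract the mean ligand-into-buffer dilution heat from every injection."""
    blank = np.asarray(blank_heats, dtype=float)
    if blank.size == 0:
        raise ValueError("blank heats must be non-empty")
    return np.asarray(heats, dtype=float) - float(blank.mean())


# ---------------------------------------------------------------------------
# One-site fit (Model / Results)


@dataclass(frozen=True)
class FitResult:
    """Point estimates and uncertainties of the one-site model."""

    n: float
    kd_uM: float
    dh_kcal: float
    se_n: float
    se_kd_uM: float
    se_dh_kcal: float
    c_value: float
    converged: bool
    no_binding: bool = False
    rss: float = float("nan")

    @property
    def low_c(self) -> bool:
        return self.c_value < 1.0


class OneSiteBindingModel:
    """One-site binding model for an ITC isotherm.

    Parameters
    ----------
    isotherm :
        Dilution-corrected (or correctable) injection heats with protocol.
    weights :
        Optional per-injection weights for the least-squares objective.
    no_binding_threshold :
        Heats all below this magnitude (kcal/mol of injectant) yield a
        no-binding verdict instead of a fit.
    """

    param_names = ("n", "K_D (uM)", "dH (kcal/mol)")

    def __init__(
        self,
        isotherm: Isotherm,
        weights: np.ndarray | None = None,
        no_binding_threshold: float = 0.05,
        bounds_n: tuple[float, float] = (0.2, 5.0),
        bounds_kd: tuple[float, float] = (1e-3, 1e5),
    ):
        self.isotherm = isotherm
        self.heats = isotherm.corrected()
        if self.heats.size < 5:
            raise ValueError("fit needs >= 5 injections")
        self.weights = (
            np.ones_like(self.heats) if weights is None else np.asarray(weights, float)
        )
        self.no_binding_threshold = no_binding_threshold
        self.bounds_n = bounds_n
        self.bounds_kd = bounds_kd

    def predict(self, n: float, kd_uM: float, dh_kcal: float) -> np.ndarray:
        return one_site_heats(n, kd_uM, dh_kcal, self.isotherm.protocol)

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        n, log_kd, dh = x
        return self.weights * (self.predict(n, 10.0**log_kd, dh) - self.heats)

    def _start_points(self, start) -> list[np.ndarray]:
        if start is not None:
            n0, kd0, dh0 = start
            return [np.array([n0, math.log10(kd0), dh0])]
        dh0 = float(self.heats[np.argmax(np.abs(self.heats))])
        mt_uM = self.isotherm.protocol.cell_concentration * 1e6
        # multi-start across c-values: the isotherm shape changes regime
        starts = []
        for c in (0.05, 0.5, 5.0, 50.0, 500.0):
            kd0 = max(self.bounds_kd[0] * 1.01, min(self.bounds_kd[1] * 0.99, mt_uM / c))
            starts.append(np.array([1.0, math.log10(kd0), dh0]))
        return starts

    def fit(self, start: tuple[float, float, float] | None = None) -> "OneSiteBindingResults":
        """Weighted least squares against the one-site forward model.

        ``start`` is an optional (n, K_D uM, dH kcal/mol) initial guess; by
        default several c-value regimes are tried and the best kept.
        Non-convergence is flagged on the results, never raised.
        """
        proto = self.isotherm.protocol
        if np.all(np.abs(self.heats) < self.no_binding_threshold):
            fr = FitResult(
                float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), float("nan"),
                c_value=float("nan"), converged=False, no_binding=True,
            )
            return OneSiteBindingResults(self, fr)
        lo = [self.bounds_n[0], math.log10(self.bounds_kd[0]), -1e4]
        hi = [self.bounds_n[1], math.log10(self.bounds_kd[1]), 1e4]
        best = None
        for x0 in self._start_points(start):
            x0 = np.clip(x0, lo, hi)
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=(lo, hi),
                    xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=4000,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            fr = FitResult(
                float("nan"), float("nan"), float("nan"),
                float("nan"), float("nan"), float("nan"),
                c_value=float("nan"), converged=False,
            )
            return OneSiteBindingResults(self, fr)
        n_hat, log_kd_hat, dh_hat = best.x
        kd_hat = 10.0**log_kd_hat
        # standard errors from local curvature at the solution, in the
        # natural (n, K_D, dH) parameterization
        se = self._standard_errors(np.array([n_hat, kd_hat, dh_hat]))
        c_value = n_hat * proto.cell_concentration * 1e6 / kd_hat
        fr = FitResult(
            float(n_hat), float(kd_hat), float(dh_hat),
            se[0], se[1], se[2],
            c_value=float(c_value),
            converged=bool(best.success),
            rss=float(2 * best.cost),
        )
        return OneSiteBindingResults(self, fr)

    def _standard_errors(self, params: np.ndarray) -> np.ndarray:
        def resid_nat(x):
            return self.weights * (self.predict(*x) - self.heats)

        r0 = resid_nat(params)
        m, p = r0.size, 3
        J = np.empty((m, p))
        for j in range(p):
            h = max(1e-7 * abs(params[j]), 1e-12)
            xp = params.copy()
            xp[j] += h
            J[:, j] = (resid_nat(xp) - r0) / h
        dof = max(m - p, 1)
        sigma2 = float(r0 @ r0) / dof
        try:
            cov = sigma2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            se = np.full(p, float("nan"))
        return se


class OneSiteBindingResults:
    """Results of a one-site ITC fit: estimates, uncertainties, diagnostics."""

    def __init__(self, model: OneSiteBindingModel, fit_result: FitResult):
        self.model = model
        self._fr = fit_result

    @property
    def params(self) -> pd.Series:
        fr = self._fr
        return pd.Series(
            [fr.n, fr.kd_uM, fr.dh_kcal], index=list(self.model.param_names)
        )

    @property
    def bse(self) -> pd.Series:
        fr = self._fr
        return pd.Series(
            [fr.se_n, fr.se_kd_uM, fr.se_dh_kcal], index=list(self.model.param_names)
        )

    @property
    def fit_result(self) -> FitResult:
        return self._fr

    @property
    def n(self) -> float:
        return self._fr.n

    @property
    def kd_uM(self) -> float:
        return self._fr.kd_uM

    @property
    def dh_kcal(self) -> float:
        return self._fr.dh_kcal

    @property
    def c_value(self) -> float:
        return self._fr.c_value

    @property
    def converged(self) -> bool:
        return self._fr.converged

    @property
    def no_binding(self) -> bool:
        return self._fr.no_binding

    def predicted(self) -> np.ndarray:
        fr = self._fr
        return self.model.predict(fr.n, fr.kd_uM, fr.dh_kcal)

    def plot(self, ax=None):
        """Measured heats and the fitted isotherm against molar ratio."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ratios = self.model.isotherm.protocol.molar_ratios()
        ax.plot(ratios, self.model.heats, "ks", ms=4, label="measured")
        if not self._fr.no_binding:
            ax.plot(ratios, self.predicted(), "r-", label="one-site fit")
        ax.set_xlabel("molar ratio [ligand]/[protein]")
        ax.set_ylabel("kcal per mole of injectant")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        fr = self._fr
        lines = ["One-site binding model", "=" * 46]
        if fr.no_binding:
            lines.append("verdict: no binding (all heats below threshold)")
            return "\n".join(lines)
        rows = zip(self.model.param_names, self.params, self.bse)
        for name, val, se in rows:
            lines.append(f"{name:>14s}  {val:12.4g}  +/- {se:9.3g}")
        lines.append(f"{'c-value':>14s}  {fr.c_value:12.4g}" + ("  (low c: c < 1)" if fr.low_c else ""))
        lines.append(f"{'converged':>14s}  {fr.converged}")
        lines.append(f"{'RSS':>14s}  {fr.rss:12.4g}")
        return "\n".join(lines)


def fit_one_site(
    isotherm: Isotherm, start: tuple[float, float, float] | None = None, **model_kw
) -> FitResult:
    """Functional wrapper: fit the one-site model and return the FitResult."""
    return OneSiteBindingModel(isotherm, **model_kw).fit(start).fit_result


# ---------------------------------------------------------------------------
# Mutant reporting


def fold_reduction(kd_variant_uM: float, kd_reference_uM: float) -> float:
    """Affinity loss of a variant relative to reference, K_D ratio.

    Rounded to the nearest integer when >= 10, one decimal place otherwise —
    the convention of the mutant-affinity table.
    """
    if kd_variant_uM <= 0 or kd_reference_uM <= 0:
        raise ValueError("dissociation constants must be positive")
    ratio = kd_variant_uM / kd_reference_uM
    if ratio >= 10:
        return float(round(ratio))
    return round(ratio, 1)
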