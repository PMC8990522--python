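"""Van't Hoff solubility modelling and composition conversions.

ln x = -dH_d / (R T) + dS_d / R with T in kelvin, x the mole-fraction
solubility, dH_d / dS_d the enthalpy / entropy of dissolution. Fitting is
ordinary least squares of ln x on 1/T. All temperature handling is in
kelvin internally; degrees Celsius only at the interfaces.

Molar masses and solvent density are external chemistry constants supplied
via configuration; the defaults below are literature values for mefenamic
acid / diglyme / water systems, not outputs of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "R_GAS", "DEFAULT_MOLAR_MASSES", "DEFAULT_SOLVENT_DENSITY",
    "SolubilityModel", "VantHoffModel", "CompositionPoint",
    "fit_vanthoff", "predict_x", "solubility_temperature",
    "convert_composition", "solubility_bias",
]

R_GAS = 8.314  # J / (mol K)
KELVIN = 273.15

#: g/mol — solute (mefenamic acid), diglyme, water
DEFAULT_MOLAR_MASSES = {"solute": 241.29, "dig": 134.17, "water": 18.015}
#: g/mL, temperature-independent default for the mixed solvent
DEFAULT_SOLVENT_DENSITY = 0.95


@dataclass(frozen=True)
class SolubilityModel:
    """Van't Hoff parameters defining the mole-fraction solubility x(T)."""

    dH_d: float                    # J/mol, enthalpy of dissolution
    dS_d: float                    # J/(mol K), entropy of dissolution
    r2_adj: float = float("nan")   # fit diagnostics (NaN when constructed)
    rmse_lnx: float = float("nan")

    def predict_x(self, T_C) -> np.ndarray | float:
        T_K = np.asarray(T_C, dtype=float) + KELVIN
        x = np.exp(-self.dH_d / (R_GAS * T_K) + self.dS_d / R_GAS)
        return float(x) if np.isscalar(T_C) else x

    def solubility_temperature(self, x) -> float:
        """Inverse of x(T): saturation temperature (degC) of mole fraction x."""
        if not 0 < x < 1:
            raise ValueError("mole fraction must lie in (0, 1)")
        if self.dH_d == 0:
            raise ValueError("dH_d must be nonzero to invert")
        denom = self.dS_d - R_GAS * np.log(x)
        T_K = self.dH_d / denom
        if denom <= 0 or T_K <= 0:
            raise ValueError("requested mole fraction outside the model range")
        return float(T_K - KELVIN)


def fit_vanthoff(points) -> SolubilityModel:
    """OLS fit of ln x on 1/T(K) for (T_degC, x_mol) pairs.

    Slope = -dH_d/R, intercept = dS_d/R. Returns the model with adjusted
    R^2 and the RMSE of the ln x residuals (both 0-residual quantities for
    exactly linear data; r2_adj is NaN for a two-point fit).
    """
    pts = [(float(t), float(x)) for t, x in points]
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    T_C = np.array([p[0] for p in pts])
    x = np.array([p[1] for p in pts])
    if np.any(x <= 0) or np.any(x >= 1):
        raise ValueError("mole fractions must lie in (0, 1)")
    if np.unique(T_C).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    inv_T = 1.0 / (T_C + KELVIN)
    lnx = np.log(x)
    slope, intercept = np.polyfit(inv_T, lnx, 1)
    resid = lnx - (slope * inv_T + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((lnx - lnx.mean())**2).sum())
    n = len(pts)
    if ss_tot > 0 and n > 2:
        r2 = 1 - ss_res / ss_tot
        r2_adj = 1 - (1 - r2) * (n - 1) / (n - 2)
    else:
        r2_adj = float("nan")
    rmse = float(np.sqrt(ss_res / n))
    return SolubilityModel(dH_d=-slope * R_GAS, dS_d=intercept * R_GAS,
                           r2_adj=r2_adj, rmse_lnx=rmse)


def predict_x(model: SolubilityModel, T_C):
    return model.predict_x(T_C)


def solubility_temperature(model: SolubilityModel, x: float) -> float:
    return model.solubility_temperature(x)


def solubility_bias(fitted: SolubilityModel,
                    truth: SolubilityModel) -> tuple[float, float]:
    """(fitted - truth) differences of (dH_d [J/mol], dS_d [J/(mol K)])."""
    return fitted.dH_d - truth.dH_d, fitted.dS_d - truth.dS_d


class VantHoffModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper: fit solubility x(T) from clear points.

    fit takes X = temperatures (degC, shape (n, 1) or (n,)) and y = mole
    fractions; predict returns mole fractions at new temperatures.
    """

    def fit(self, X, y):
        T = np.asarray(X, dtype=float).reshape(-1)
        model = fit_vanthoff(zip(T, np.asarray(y, dtype=float)))
        self.model_ = model
        self.dH_d_ = model.dH_d
        self.dS_d_ = model.dS_d
        self.r2_adj_ = model.r2_adj
        self.rmse_lnx_ = model.rmse_lnx
        return self

    def predict(self, X):
        T = np.asarray(X, dtype=float).reshape(-1)
        return self.model_.predict_x(T)


@dataclass(frozen=True)
class CompositionPoint:
    """Mutually consistent composition measures of one sample."""

    T_C: float
    solvent_ratio: tuple[float, float]   # (DIG, WAT) mass fractions, sum 1
    x_mol: float                         # mole fraction solute
    x_gg: float                          # g solute / g solvent
    x_c: float                           # mg solute / mL solvent


def _solvent_mol_per_g(solvent_ratio, molar_masses) -> float:
    dig, wat = solvent_ratio
    if abs(dig + wat - 1.0) > 1e-9:
        raise ValueError("solvent mass fractions must sum to 1")
    return dig / molar_masses["dig"] + wat / molar_masses["water"]


def x_gg_to_mol(x_gg: float, solvent_ratio, molar_masses=None) -> float:
    mm = molar_masses or DEFAULT_MOLAR_MASSES
    n_solute = x_gg / mm["solute"]
    n_solv = _solvent_mol_per_g(solvent_ratio, mm)
    return n_solute / (n_solute + n_solv)


def x_mol_to_gg(x_mol: float, solvent_ratio, molar_masses=None) -> float:
    mm = molar_masses or DEFAULT_MOLAR_MASSES
    n_solv = _solvent_mol_per_g(solvent_ratio, mm)
    return x_mol / (1.0 - x_mol) * n_solv * mm["solute"]


def convert_composition(T_C: float, solvent_ratio, *, x_mol=None, x_gg=None,
                        m_solute_mg=None, m_solvent_g=None,
                        molar_masses=None,
                        solvent_density=DEFAULT_SOLVENT_DENSITY) -> CompositionPoint:
    """Complete a composition point from any one composition measure.

    Accepts a mole fraction, a g-solute-per-g-solvent ratio, or raw masses
    (mg solute, g solvent). ``solvent_density`` (g/mL; a constant or a
    callable of temperature) converts to mg solute per mL solvent.
    """
    mm = molar_masses or DEFAULT_MOLAR_MASSES
    given = sum(v is not None for v in (x_mol, x_gg, m_solute_mg))
    if given != 1:
        raise ValueError("supply exactly one of x_mol, x_gg, m_solute_mg")
    if m_solute_mg is not None:
        if m_solvent_g is None:
            raise ValueError("m_solvent_g required with m_solute_mg")
        x_gg = (m_solute_mg / 1000.0) / m_solvent_g
    if x_gg is not None:
        x_mol = x_gg_to_mol(x_gg, solvent_ratio, mm)
    else:
        x_gg = x_mol_to_gg(x_mol, solvent_ratio, mm)
    rho = solvent_density(T_C) if callable(solvent_density) else solvent_density
    if rho is None:
        raise ValueError("solvent density required for mg/mL conversion")
    x_c = x_gg * rho * 1000.0
    return CompositionPoint(T_C=T_C, solvent_ratio=tuple(solvent_ratio),
                            x_mol=x_mol, x_gg=x_gg, x_c=x_c)
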