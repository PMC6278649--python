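"""Estimate equilibrium constants from titration data.

Four sklearn-style estimators cover the observable regimes:

* :class:`RatioExchangeFit` — Z-form imino exchange rates vs the molar
  ratio chi (half-stoichiometry regime, K_BZ1 = 1): estimates alpha and,
  optionally, the limiting rates.
* :class:`BFormExchangeFit` — B-form imino exchange rates vs the Z
  fraction f_Z: estimates (alpha, K_BZ1) and the B-side limiting rates.
* :class:`ZFormExchangeFit` — Z-form imino exchange rates vs f_Z:
  estimates (alpha, K_BZ1) and the Z-side limiting rates.
* :class:`GlobalShiftFit` — joint fit of per-probe amide chemical-shift
  perturbations and f_Z over ([P]_t, [N]_t) compositions: estimates the
  absolute constants (Kd_BP, Kd_ZP2, K_BZ1) shared across probes plus
  per-probe limiting shifts (ddelta_B, ddelta_Z).

All positive equilibrium constants are fitted in log10 space by default,
with deterministic Latin-hypercube multi-start; weighted least squares
uses per-point standard errors when provided.  The module-level
``fit_*`` functions are thin wrappers taking :class:`TitrationDataset`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.utils.validation import check_is_fitted

from .equilibria import ModelParams, MixtureComposition, solve_species
from .exceptions import DatasetValidationError
from .observables import (
    ExchangeRateParams,
    ShiftPair,
    kex_bform_vs_fz,
    kex_vs_chi,
    kex_zform_vs_fz,
)

__all__ = [
    "OBSERVABLE_KINDS",
    "TitrationDataset",
    "FitResult",
    "RatioExchangeFit",
    "BFormExchangeFit",
    "ZFormExchangeFit",
    "GlobalShiftFit",
    "fit_exchange_vs_ratio",
    "fit_exchange_bform",
    "fit_exchange_zform",
    "fit_global_shifts",
    "fit_dataset",
    "bootstrap_uncertainty",
]

OBSERVABLE_KINDS = ("kex_vs_chi", "kex_bform", "kex_zform", "shift_and_fz")

# fit bounds (natural units); the log10 transform applies to all of them
ALPHA_BOUNDS = (1e-4, 1e3)
K_BZ1_BOUNDS = (1e-3, 1e2)
KD_BOUNDS = (1e-4, 1e4)  # uM

#: a fit is flagged weakly identified when any relative 1-sigma exceeds this
_WEAK_ID_RELATIVE = 10.0


# ---------------------------------------------------------------------------
# containers


@dataclass
class TitrationDataset:
    """A set of titration points of one observable kind.

    ``data`` schemas by kind:

    * exchange kinds (``kex_vs_chi``, ``kex_bform``, ``kex_zform``):
      columns ``chi``, ``f_z`` (exactly one populated), ``kex_s1`` and
      optional ``kex_sigma``;
    * ``shift_and_fz``: columns ``P_total_uM``, ``N_total_uM``,
      ``probe_id``, ``nucleus``, ``ddelta_obs_ppm``, ``sigma_ppm``,
      ``f_z``, ``f_z_sigma``; shift rows carry a probe_id, f_Z rows leave
      it empty.

    ``metadata`` holds condition labels (pH, salt, sequence) and, for
    synthetic data, the generating truth.
    """

    observable_kind: str
    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observable_kind not in OBSERVABLE_KINDS:
            raise DatasetValidationError(
                f"unknown observable_kind {self.observable_kind!r}; "
                f"expected one of {OBSERVABLE_KINDS}"
            )
        if len(self.data) == 0:
            raise DatasetValidationError("dataset has an empty data section")
        if self.observable_kind in ("kex_vs_chi", "kex_bform", "kex_zform"):
            self._validate_exchange()
        else:
            self._validate_shift()

    def _validate_exchange(self) -> None:
        df = self.data
        for col in ("kex_s1",):
            if col not in df.columns:
                raise DatasetValidationError(f"missing required column {col!r}")
        x_col = "chi" if self.observable_kind == "kex_vs_chi" else "f_z"
        if x_col not in df.columns or df[x_col].isna().any():
            raise DatasetValidationError(
                f"{self.observable_kind} datasets need column {x_col!r} populated on every row"
            )
        other = "f_z" if x_col == "chi" else "chi"
        if other in df.columns and df[other].notna().any():
            raise DatasetValidationError(
                f"exactly one of chi/f_z may be populated; found values in {other!r}"
            )
        if "kex_sigma" in df.columns:
            sig = df["kex_sigma"].dropna()
            if (sig <= 0).any():
                raise DatasetValidationError("kex_sigma values must be > 0")

    def _validate_shift(self) -> None:
        df = self.data
        for col in ("P_total_uM", "N_total_uM"):
            if col not in df.columns:
                raise DatasetValidationError(
                    f"missing required column {col!r} (shift model needs absolute concentrations)"
                )
        is_shift = self.shift_mask()
        is_fz = self.fz_mask()
        if not (is_shift | is_fz).all():
            bad = df.index[~(is_shift | is_fz)].tolist()
            raise DatasetValidationError(
                f"rows {bad} are neither shift rows (probe_id + ddelta_obs_ppm) "
                "nor f_Z rows (empty probe_id + f_z)"
            )
        for col, mask in (("sigma_ppm", is_shift), ("f_z_sigma", is_fz)):
            if col in df.columns:
                sig = df.loc[mask, col].dropna()
                if (sig <= 0).any():
                    raise DatasetValidationError(f"{col} values must be > 0")

    def shift_mask(self) -> pd.Series:
        df = self.data
        probe = df.get("probe_id", pd.Series("", index=df.index))
        has_probe = probe.notna() & (probe.astype(str).str.len() > 0)
        return has_probe & df.get("ddelta_obs_ppm", pd.Series(np.nan, index=df.index)).notna()

    def fz_mask(self) -> pd.Series:
        df = self.data
        probe = df.get("probe_id", pd.Series("", index=df.index))
        no_probe = probe.isna() | (probe.astype(str).str.len() == 0)
        return no_probe & df.get("f_z", pd.Series(np.nan, index=df.index)).notna()

    @property
    def n_points(self) -> int:
        return len(self.data)


@dataclass
class FitResult:
    """Outcome of a titration fit.

    ``estimates``/``uncertainties`` are in natural units (uM for Kd, ppm
    for shifts, s^-1 for rates); uncertainties are 1-sigma values from the
    covariance at the optimum (None when unavailable).  ``flags`` records
    diagnostics such as ``'few-points'``, ``'rank-deficient'`` or
    ``'weakly-identified'``; ``converged`` is never silently False.
    """

    estimates: dict[str, float]
    uncertainties: dict[str, float | None]
    objective: float
    n_points: int
    converged: bool
    flags: tuple[str, ...]
    residuals: np.ndarray
    estimator: Any = field(default=None, repr=False)
    bootstrap: pd.DataFrame | None = field(default=None, repr=False)

    def summary(self) -> str:
        lines = [
            f"converged: {self.converged}   objective: {self.objective:.6g}   "
            f"n_points: {self.n_points}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        for name, value in self.estimates.items():
            err = self.uncertainties.get(name)
            err_s = f" +/- {err:.3g}" if err is not None and math.isfinite(err) else ""
            lines.append(f"  {name} = {value:.6g}{err_s}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# optimization engine


@dataclass(frozen=True)
class _ParamSpec:
    name: str
    init: float
    lo: float
    hi: float
    log: bool = False
    vary: bool = True


def _clip(value: float, lo: float, hi: float) -> float:
    return min(max(value, lo), hi)


def _internal(spec: _ParamSpec, value: float) -> float:
    value = _clip(value, spec.lo, spec.hi)
    return math.log10(value) if spec.log else value


def _natural(spec: _ParamSpec, value: float) -> float:
    return 10.0**value if spec.log else value


def _make_params(specs: Sequence[_ParamSpec], start: dict[str, float]) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for spec in specs:
        lo = math.log10(spec.lo) if spec.log else spec.lo
        hi = math.log10(spec.hi) if spec.log else spec.hi
        params.add(
            spec.name,
            value=_clip(start[spec.name], lo, hi),
            min=lo,
            max=hi,
            vary=spec.vary,
        )
    return params


def _values_from(params: lmfit.Parameters, specs: Sequence[_ParamSpec]) -> dict[str, float]:
    return {s.name: _natural(s, params[s.name].value) for s in specs}


def _lhs_starts(
    specs: Sequence[_ParamSpec], n: int, seed: int
) -> list[dict[str, float]]:
    """Deterministic Latin-hypercube starts in internal coordinates."""
    free = [s for s in specs if s.vary]
    starts: list[dict[str, float]] = []
    base = {s.name: _internal(s, s.init) for s in specs}
    starts.append(dict(base))
    if n > 1 and free:
        sampler = qmc.LatinHypercube(d=len(free), seed=seed)
        unit = sampler.random(n - 1)
        for row in unit:
            start = dict(base)
            for s, u in zip(free, row):
                lo = math.log10(s.lo) if s.log else s.lo
                hi = math.log10(s.hi) if s.log else s.hi
                start[s.name] = lo + u * (hi - lo)
            starts.append(start)
    return starts


def _multistart_least_squares(
    residual: Callable[[dict[str, float]], np.ndarray],
    specs: Sequence[_ParamSpec],
    n_starts: int,
    seed: int,
    max_nfev: int | None = None,
) -> tuple[lmfit.minimizer.MinimizerResult, dict[str, float], dict[str, float | None]]:
    """Run lmfit least-squares from multiple starts, keep the best optimum."""

    def wrapped(params: lmfit.Parameters) -> np.ndarray:
        return residual(_values_from(params, specs))

    best: lmfit.minimizer.MinimizerResult | None = None
    for start in _lhs_starts(specs, n_starts, seed):
        params = _make_params(specs, start)
        try:
            result = lmfit.minimize(
                wrapped,
                params,
                method="least_squares",
                nan_policy="raise",
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best is None:
        raise RuntimeError("all optimization starts failed")
    estimates = _values_from(best.params, specs)
    uncertainties: dict[str, float | None] = {}
    for spec in specs:
        stderr = best.params[spec.name].stderr if spec.vary else 0.0
        if stderr is None or not math.isfinite(stderr):
            uncertainties[spec.name] = None
        elif spec.log:
            uncertainties[spec.name] = estimates[spec.name] * math.log(10.0) * stderr
        else:
            uncertainties[spec.name] = stderr
    return best, estimates, uncertainties


def _identifiability_flags(
    result: lmfit.minimizer.MinimizerResult,
    estimates: dict[str, float],
    uncertainties: dict[str, float | None],
    n_points: int,
    n_free: int,
) -> list[str]:
    flags: list[str] = []
    if n_points < 5 * n_free:
        flags.append("few-points")
        warnings.warn(
            f"only {n_points} points for {n_free} free parameters "
            "(fewer than 5 per parameter); estimates may be under-determined",
            stacklevel=3,
        )
    if getattr(result, "covar", None) is None and n_free > 0:
        flags.append("rank-deficient")
        flags.append("non-identifiable")
        return flags
    for name, err in uncertainties.items():
        est = estimates.get(name, 0.0)
        if err is None:
            continue
        if est != 0 and err / abs(est) > _WEAK_ID_RELATIVE:
            flags.append("weakly-identified")
            break
    return flags


# ---------------------------------------------------------------------------
# exchange-rate estimators


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise ValueError(f"expected a 1-d titration coordinate, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("titration coordinate contains non-finite values")
    return x


class _ExchangeFitBase(RegressorMixin, BaseEstimator):
    """Shared machinery of the three exchange-rate curve estimators."""

    #: names of the two limiting rates this curve interpolates between,
    #: ordered (value at x -> low end, value at x -> high end)
    _rate_names: tuple[str, str] = ("", "")
    _fits_k_bz1 = False
    _x_bounds: tuple[float, float] = (0.0, 1.0)

    def __init__(
        self,
        fixed_rates: ExchangeRateParams | None = None,
        n_starts: int = 8,
        log_scale: bool = True,
        random_state: int = 0,
        initial_values: dict | None = None,
        max_nfev: int | None = None,
    ):
        self.fixed_rates = fixed_rates
        self.n_starts = n_starts
        self.log_scale = log_scale
        self.random_state = random_state
        self.initial_values = initial_values
        self.max_nfev = max_nfev

    # subclasses map parameter values to a model curve
    def _curve(self, x: np.ndarray, values: dict[str, float]) -> np.ndarray:
        raise NotImplementedError

    def _param_specs(self, x: np.ndarray, y: np.ndarray) -> list[_ParamSpec]:
        init = dict(self.initial_values or {})
        log = self.log_scale
        specs = [
            _ParamSpec("alpha", init.get("alpha", 0.1), *ALPHA_BOUNDS, log=log)
        ]
        if self._fits_k_bz1:
            specs.append(
                _ParamSpec("k_bz1", init.get("k_bz1", 1.0), *K_BZ1_BOUNDS, log=log)
            )
        lo_name, hi_name = self._rate_names
        order = np.argsort(x)
        rate_hi = max(3.0 * float(np.max(np.abs(y))), 1.0)
        fixed = self.fixed_rates
        for name, default in (
            (lo_name, float(y[order[0]])),
            (hi_name, float(y[order[-1]])),
        ):
            if fixed is not None:
                value = getattr(fixed, {"kex_b": "kex_B", "kex_bp": "kex_BP",
                                        "kex_zp": "kex_ZP", "kex_zp2": "kex_ZP2"}[name])
                specs.append(_ParamSpec(name, value, 0.0, rate_hi + value, vary=False))
            else:
                specs.append(
                    _ParamSpec(name, init.get(name, max(default, 1e-6)), 0.0, rate_hi)
                )
        return specs

    def fit(self, X, y, sample_weight=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if y.shape != x.shape:
            raise ValueError("X and y must have matching lengths")
        lo, hi = self._x_bounds
        if np.any(x < lo) or np.any(x > hi):
            raise ValueError(
                f"titration coordinate must lie in [{lo}, {hi}] for {type(self).__name__}"
            )
        if sample_weight is None:
            sw = np.ones_like(y)
        else:
            sw = np.asarray(sample_weight, dtype=float)
            if sw.shape != y.shape or np.any(sw <= 0):
                raise ValueError("sample_weight must be positive and match y")
        root_w = np.sqrt(sw)
        specs = self._param_specs(x, y)

        def residual(values: dict[str, float]) -> np.ndarray:
            return (self._curve(x, values) - y) * root_w

        result, estimates, uncertainties = _multistart_least_squares(
            residual,
            specs,
            n_starts=self.n_starts if self.initial_values is None else 1,
            seed=self.random_state,
            max_nfev=self.max_nfev,
        )
        n_free = sum(s.vary for s in specs)
        flags = _identifiability_flags(result, estimates, uncertainties, len(y), n_free)
        for name, value in estimates.items():
            setattr(self, f"{name}_", value)
        self.result_ = FitResult(
            estimates=estimates,
            uncertainties=uncertainties,
            objective=float(result.chisqr),
            n_points=len(y),
            converged=bool(result.success),
            flags=tuple(flags),
            residuals=np.asarray(result.residual, dtype=float),
            estimator=self,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        x = _as_1d(X)
        return self._curve(x, self.result_.estimates)

    def objective_profile(self, name: str, values: Sequence[float], X, y,
                          sample_weight=None) -> np.ndarray:
        """Objective along a 1-d slice through the optimum (other parameters
        held at their estimates); used for profile sanity scans."""
        check_is_fitted(self, "result_")
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        sw = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        out = []
        for v in values:
            vals = dict(self.result_.estimates)
            vals[name] = v
            out.append(float(np.sum(sw * (self._curve(x, vals) - y) ** 2)))
        return np.asarray(out)


class RatioExchangeFit(_ExchangeFitBase):
    """Fit Z-form imino exchange rates vs the molar ratio chi.

    Valid in the half-stoichiometry regime (K_BZ1 = 1, tight binding,
    chi <= 2).  Free parameters: ``alpha`` plus ``kex_zp``/``kex_zp2``
    unless ``fixed_rates`` is given.
    """

    _rate_names = ("kex_zp", "kex_zp2")
    _fits_k_bz1 = False
    _x_bounds = (0.0, 2.0)

    def _curve(self, x: np.ndarray, values: dict[str, float]) -> np.ndarray:
        rates = ExchangeRateParams(
            kex_ZP=values["kex_zp"], kex_ZP2=values["kex_zp2"]
        )
        return np.array([kex_vs_chi(rates, values["alpha"], xi) for xi in x])


class BFormExchangeFit(_ExchangeFitBase):
    """Fit B-form imino exchange rates vs the Z fraction f_Z.

    Free parameters: ``alpha``, ``k_bz1`` plus ``kex_b``/``kex_bp`` unless
    ``fixed_rates`` is given.  Requires f_Z < 1 (a B-form probe vanishes at
    full conversion).
    """

    _rate_names = ("kex_b", "kex_bp")
    _fits_k_bz1 = True
    _x_bounds = (0.0, 1.0 - 1e-12)

    def _curve(self, x: np.ndarray, values: dict[str, float]) -> np.ndarray:
        rates = ExchangeRateParams(kex_B=values["kex_b"], kex_BP=values["kex_bp"])
        return np.array(
            [kex_bform_vs_fz(rates, values["alpha"], values["k_bz1"], xi) for xi in x]
        )


class ZFormExchangeFit(_ExchangeFitBase):
    """Fit Z-form imino exchange rates vs the Z fraction f_Z.

    The general-regime counterpart of :class:`RatioExchangeFit`: jointly
    estimates ``alpha`` and ``k_bz1`` plus ``kex_zp``/``kex_zp2`` unless
    ``fixed_rates`` is given.
    """

    _rate_names = ("kex_zp", "kex_zp2")
    _fits_k_bz1 = True
    _x_bounds = (0.0, 1.0)

    def _curve(self, x: np.ndarray, values: dict[str, float]) -> np.ndarray:
        rates = ExchangeRateParams(kex_ZP=values["kex_zp"], kex_ZP2=values["kex_zp2"])
        return np.array(
            [kex_zform_vs_fz(rates, values["alpha"], values["k_bz1"], xi) for xi in x]
        )


# ---------------------------------------------------------------------------
# global shift + f_Z estimator


_SHIFT_X_COLUMNS = ("P_total_uM", "N_total_uM", "observable", "probe_id")


class GlobalShiftFit(RegressorMixin, BaseEstimator):
    """Global fit of chemical-shift perturbations and Z fractions.

    ``X`` is a DataFrame with columns ``P_total_uM``, ``N_total_uM``,
    ``observable`` (``'shift'`` or ``'fz'``) and ``probe_id`` (empty for
    f_Z rows); ``y`` holds the observed values (ppm or fraction).

    The three equilibrium constants (``kd_bp``, ``kd_zp2``, ``k_bz1``) are
    shared across all probes and optimized in log10 space with
    Latin-hypercube multi-start; the per-probe limiting shifts enter the
    model linearly and are profiled out exactly by weighted linear least
    squares at every residual evaluation (variable projection), which
    keeps the nonlinear search three-dimensional.

    Fitted attributes: ``kd_bp_``, ``kd_zp2_``, ``k_bz1_``,
    ``probe_shifts_`` (probe_id -> :class:`ShiftPair`) and ``result_``.
    Shift uncertainties are conditional on the fitted constants; use
    :func:`bootstrap_uncertainty` for joint uncertainty.
    """

    def __init__(
        self,
        fz_denominator: str = "dna",
        fixed: dict | None = None,
        n_starts: int = 8,
        log_scale: bool = True,
        random_state: int = 0,
        initial_values: dict | None = None,
        max_nfev: int | None = None,
    ):
        self.fz_denominator = fz_denominator
        self.fixed = fixed
        self.n_starts = n_starts
        self.log_scale = log_scale
        self.random_state = random_state
        self.initial_values = initial_values
        self.max_nfev = max_nfev

    def _validate_X(self, X: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("GlobalShiftFit expects a DataFrame X")
        missing = [c for c in _SHIFT_X_COLUMNS if c not in X.columns]
        if missing:
            raise DatasetValidationError(f"X is missing columns {missing}")
        if self.fz_denominator not in ("dna", "protein"):
            raise ValueError("fz_denominator must be 'dna' or 'protein'")
        bad = ~X["observable"].isin(["shift", "fz"])
        if bad.any():
            raise DatasetValidationError(
                f"unknown observable labels {sorted(X.loc[bad, 'observable'].unique())}"
            )
        return X.reset_index(drop=True)

    def _weights(self, params: ModelParams, comps: np.ndarray) -> np.ndarray:
        """Per-composition model weights: columns (w_B, w_Z, f_dna, f_prot)."""
        out = np.empty((len(comps), 4))
        for i, (P_t, N_t) in enumerate(comps):
            state = solve_species(params, MixtureComposition(P_t, N_t))
            if P_t > 0:
                out[i, 0] = state.BP / P_t
                out[i, 1] = (state.ZP + 2.0 * state.ZP2) / P_t
            else:
                out[i, 0] = out[i, 1] = 0.0
            out[i, 2] = state.f_Z_dna
            out[i, 3] = state.f_Z_protein
        return out

    def fit(self, X, y, sample_weight=None):
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(X):
            raise ValueError("X and y must have matching lengths")
        if sample_weight is None:
            sw = np.ones_like(y)
        else:
            sw = np.asarray(sample_weight, dtype=float)
            if sw.shape != y.shape or np.any(sw <= 0):
                raise ValueError("sample_weight must be positive and match y")
        root_w = np.sqrt(sw)

        comps, comp_idx = np.unique(
            X[["P_total_uM", "N_total_uM"]].to_numpy(dtype=float),
            axis=0,
            return_inverse=True,
        )
        is_shift = (X["observable"] == "shift").to_numpy()
        is_fz = ~is_shift
        probes = sorted(X.loc[is_shift, "probe_id"].astype(str).unique())
        probe_rows = {
            p: np.flatnonzero(is_shift & (X["probe_id"].astype(str) == p).to_numpy())
            for p in probes
        }
        fz_rows = np.flatnonzero(is_fz)
        fz_col = 2 if self.fz_denominator == "dna" else 3

        init = dict(self.initial_values or {})
        fixed = dict(self.fixed or {})
        specs = []
        for name, bounds, default in (
            ("kd_bp", KD_BOUNDS, 1.0),
            ("kd_zp2", KD_BOUNDS, 1.0),
            ("k_bz1", K_BZ1_BOUNDS, 1.0),
        ):
            value = init.get(name, fixed.get(name, default))
            specs.append(
                _ParamSpec(
                    name, value, *bounds, log=self.log_scale, vary=name not in fixed
                )
            )

        def solve_shifts(values: dict[str, float]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
            params = ModelParams(
                Kd_BP=values["kd_bp"], Kd_ZP2=values["kd_zp2"], K_BZ1=values["k_bz1"]
            )
            w = self._weights(params, comps)
            shift_sol: dict[str, np.ndarray] = {}
            model = np.zeros_like(y)
            for p, rows in probe_rows.items():
                A = w[comp_idx[rows]][:, :2] * root_w[rows, None]
                b = y[rows] * root_w[rows]
                theta, *_ = np.linalg.lstsq(A, b, rcond=None)
                shift_sol[p] = theta
                model[rows] = w[comp_idx[rows]][:, :2] @ theta
            model[fz_rows] = w[comp_idx[fz_rows], fz_col]
            return model, shift_sol

        def residual(values: dict[str, float]) -> np.ndarray:
            model, _ = solve_shifts(values)
            return (model - y) * root_w

        result, estimates, uncertainties = _multistart_least_squares(
            residual,
            specs,
            n_starts=self.n_starts if self.initial_values is None else 1,
            seed=self.random_state,
            max_nfev=self.max_nfev,
        )
        model, shift_sol = solve_shifts(estimates)

        # conditional 1-sigma for the profiled shifts, per probe
        redchi = result.redchi if result.nfree > 0 else 0.0
        params_opt = ModelParams(
            Kd_BP=estimates["kd_bp"],
            Kd_ZP2=estimates["kd_zp2"],
            K_BZ1=estimates["k_bz1"],
        )
        w_opt = self._weights(params_opt, comps)
        self.probe_shifts_ = {}
        for p, rows in probe_rows.items():
            dB, dZ = shift_sol[p]
            self.probe_shifts_[p] = ShiftPair(probe_id=p, delta_B=float(dB), delta_Z=float(dZ))
            A = w_opt[comp_idx[rows]][:, :2] * np.sqrt(sw[rows])[:, None]
            try:
                cov = np.linalg.inv(A.T @ A) * max(redchi, 0.0)
                errs = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            except np.linalg.LinAlgError:
                errs = (None, None)
            estimates[f"ddelta_b:{p}"] = float(dB)
            estimates[f"ddelta_z:{p}"] = float(dZ)
            uncertainties[f"ddelta_b:{p}"] = None if errs[0] is None else float(errs[0])
            uncertainties[f"ddelta_z:{p}"] = None if errs[1] is None else float(errs[1])

        n_free = sum(s.vary for s in specs) + 2 * len(probes)
        flags = _identifiability_flags(result, estimates, uncertainties, len(y), n_free)
        self.kd_bp_ = estimates["kd_bp"]
        self.kd_zp2_ = estimates["kd_zp2"]
        self.k_bz1_ = estimates["k_bz1"]
        self.result_ = FitResult(
            estimates=estimates,
            uncertainties=uncertainties,
            objective=float(result.chisqr),
            n_points=len(y),
            converged=bool(result.success),
            flags=tuple(flags),
            residuals=(model - y) * root_w,
            estimator=self,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = self._validate_X(X)
        params = ModelParams(Kd_BP=self.kd_bp_, Kd_ZP2=self.kd_zp2_, K_BZ1=self.k_bz1_)
        comps, comp_idx = np.unique(
            X[["P_total_uM", "N_total_uM"]].to_numpy(dtype=float),
            axis=0,
            return_inverse=True,
        )
        w = self._weights(params, comps)
        fz_col = 2 if self.fz_denominator == "dna" else 3
        out = np.empty(len(X))
        for i in range(len(X)):
            if X.loc[i, "observable"] == "fz":
                out[i] = w[comp_idx[i], fz_col]
            else:
                pair = self.probe_shifts_.get(str(X.loc[i, "probe_id"]))
                if pair is None:
                    raise ValueError(f"unknown probe {X.loc[i, 'probe_id']!r}")
                out[i] = w[comp_idx[i], 0] * pair.delta_B + w[comp_idx[i], 1] * pair.delta_Z
        return out


# ---------------------------------------------------------------------------
# dataset wrappers


def _exchange_xy(
    data: TitrationDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    x_col = "chi" if data.observable_kind == "kex_vs_chi" else "f_z"
    x = data.data[x_col].to_numpy(dtype=float)
    y = data.data["kex_s1"].to_numpy(dtype=float)
    sigma = None
    if "kex_sigma" in data.data.columns and data.data["kex_sigma"].notna().all():
        sigma = data.data["kex_sigma"].to_numpy(dtype=float)
    return x, y, sigma


def _run_exchange_fit(
    estimator: _ExchangeFitBase, data: TitrationDataset, kind: str
) -> FitResult:
    if data.observable_kind != kind:
        raise DatasetValidationError(
            f"expected a {kind!r} dataset, got {data.observable_kind!r}"
        )
    x, y, sigma = _exchange_xy(data)
    sw = None if sigma is None else 1.0 / sigma**2
    estimator.fit(x, y, sample_weight=sw)
    return estimator.result_


def fit_exchange_vs_ratio(
    data: TitrationDataset, fixed: ExchangeRateParams | None = None, **kwargs
) -> FitResult:
    """Fit the chi-domain Z-form exchange curve (half-stoichiometry regime).

    Estimates ``alpha`` (log-parameterized) and, unless ``fixed`` provides
    them, the limiting rates ``kex_zp``/``kex_zp2``.
    """
    x = data.data["chi"] if "chi" in data.data.columns else None
    if x is not None and ((x <= 0) | (x > 2)).any():
        raise DatasetValidationError(
            "kex_vs_chi fits require chi in (0, 2] at every point"
        )
    return _run_exchange_fit(
        RatioExchangeFit(fixed_rates=fixed, **kwargs), data, "kex_vs_chi"
    )


def fit_exchange_bform(
    data: TitrationDataset, fixed: ExchangeRateParams | None = None, **kwargs
) -> FitResult:
    """Fit the B-form exchange curve vs f_Z: estimates (alpha, K_BZ1) and
    the B-side limiting rates unless fixed."""
    if (data.data.get("f_z", pd.Series(dtype=float)) >= 1).any():
        raise DatasetValidationError("kex_bform fits require f_z < 1 at every point")
    return _run_exchange_fit(
        BFormExchangeFit(fixed_rates=fixed, **kwargs), data, "kex_bform"
    )


def fit_exchange_zform(
    data: TitrationDataset, fixed: ExchangeRateParams | None = None, **kwargs
) -> FitResult:
    """Fit the Z-form exchange curve vs f_Z: estimates (alpha, K_BZ1) and
    the Z-side limiting rates unless fixed."""
    if (data.data.get("f_z", pd.Series(dtype=float)) <= 0).any():
        raise DatasetValidationError("kex_zform fits require f_z in (0, 1]")
    return _run_exchange_fit(
        ZFormExchangeFit(fixed_rates=fixed, **kwargs), data, "kex_zform"
    )


def stack_shift_datasets(
    datasets: Sequence[TitrationDataset],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Stack shift_and_fz datasets into (X, y, sigma) for GlobalShiftFit.

    All datasets must share the same ([P]_t, [N]_t) composition grid;
    deviating grids raise :class:`DatasetValidationError`.
    """
    if not datasets:
        raise DatasetValidationError("need at least one shift_and_fz dataset")
    grids = []
    rows_X, rows_y, rows_sigma = [], [], []
    for ds in datasets:
        if ds.observable_kind != "shift_and_fz":
            raise DatasetValidationError(
                f"global fits take shift_and_fz datasets, got {ds.observable_kind!r}"
            )
        df = ds.data
        grids.append(
            frozenset(
                (round(float(p), 9), round(float(n), 9))
                for p, n in df[["P_total_uM", "N_total_uM"]].itertuples(index=False)
            )
        )
        shift = ds.shift_mask()
        fz = ds.fz_mask()
        for mask, obs, val_col, sig_col, default_sig in (
            (shift, "shift", "ddelta_obs_ppm", "sigma_ppm", 1.0),
            (fz, "fz", "f_z", "f_z_sigma", 1.0),
        ):
            sub = df[mask]
            if len(sub) == 0:
                continue
            rows_X.append(
                pd.DataFrame(
                    {
                        "P_total_uM": sub["P_total_uM"].to_numpy(dtype=float),
                        "N_total_uM": sub["N_total_uM"].to_numpy(dtype=float),
                        "observable": obs,
                        "probe_id": sub.get("probe_id", "").fillna("").astype(str)
                        if obs == "shift"
                        else "",
                    }
                )
            )
            rows_y.append(sub[val_col].to_numpy(dtype=float))
            if sig_col in sub.columns and sub[sig_col].notna().all():
                rows_sigma.append(sub[sig_col].to_numpy(dtype=float))
            else:
                rows_sigma.append(np.full(len(sub), default_sig))
    if len(set(grids)) > 1:
        raise DatasetValidationError(
            "datasets use inconsistent ([P]_t, [N]_t) composition grids"
        )
    X = pd.concat(rows_X, ignore_index=True)
    return X, np.concatenate(rows_y), np.concatenate(rows_sigma)


def fit_global_shifts(
    datasets: Sequence[TitrationDataset] | TitrationDataset,
    config: dict | None = None,
    **kwargs,
) -> FitResult:
    """Globally fit shift titrations and f_Z data for the absolute constants.

    ``config`` keys: ``fz_denominator`` ('dna' default, or 'protein' for
    the protein-normalized convention) and ``fixed`` (dict of constants to
    hold).  Returns shared (Kd_BP, Kd_ZP2, K_BZ1) plus per-probe limiting
    shifts.
    """
    if isinstance(datasets, TitrationDataset):
        datasets = [datasets]
    config = dict(config or {})
    X, y, sigma = stack_shift_datasets(datasets)
    est = GlobalShiftFit(
        fz_denominator=config.get("fz_denominator", "dna"),
        fixed=config.get("fixed"),
        **kwargs,
    )
    est.fit(X, y, sample_weight=1.0 / sigma**2)
    return est.result_


_FITTERS = {
    "kex_vs_chi": fit_exchange_vs_ratio,
    "kex_bform": fit_exchange_bform,
    "kex_zform": fit_exchange_zform,
}


def fit_dataset(
    data: TitrationDataset,
    fixed: ExchangeRateParams | None = None,
    config: dict | None = None,
    **kwargs,
) -> FitResult:
    """Dispatch a dataset to the fit matching its observable kind."""
    if data.observable_kind == "shift_and_fz":
        return fit_global_shifts([data], config=config, **kwargs)
    return _FITTERS[data.observable_kind](data, fixed=fixed, **kwargs)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_uncertainty(
    fit: FitResult,
    data: TitrationDataset | Sequence[TitrationDataset],
    n_boot: int = 200,
    seed: int = 0,
    n_starts: int = 1,
) -> pd.DataFrame:
    """Case-resampling bootstrap percentile intervals for a converged fit.

    Resamples titration points with replacement (stratified by probe and
    observable for global fits), refits each replicate, and reports
    16/50/84 percentile columns per parameter.  With the default
    ``n_starts=1`` each refit is warm-started from the point estimates
    (fast, appropriate for well-identified fits); pass ``n_starts > 1``
    for cold multi-start refits, which explore flat or multi-modal
    objectives and give more honest intervals for weakly identified fits.
    Replicates whose refit fails or does not converge are skipped and
    counted in ``df.attrs['n_skipped']``.  Deterministic for a fixed seed.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if fit.estimator is None:
        raise ValueError("FitResult carries no estimator to refit")
    rng = np.random.default_rng(seed)

    base = fit.estimator
    est_proto = clone(base)
    if n_starts <= 1:
        warm = {k: v for k, v in fit.estimates.items() if ":" not in k}
        est_proto.set_params(initial_values=warm, n_starts=1)
    else:
        est_proto.set_params(initial_values=None, n_starts=n_starts)

    if isinstance(base, GlobalShiftFit):
        datasets = [data] if isinstance(data, TitrationDataset) else list(data)
        X, y, sigma = stack_shift_datasets(datasets)
        strata = (X["observable"] + ":" + X["probe_id"].astype(str)).to_numpy()

        def refit(idx: np.ndarray) -> dict[str, float] | None:
            est = clone(est_proto)
            est.fit(
                X.iloc[idx].reset_index(drop=True),
                y[idx],
                sample_weight=1.0 / sigma[idx] ** 2,
            )
            return est.result_.estimates if est.result_.converged else None

    else:
        if not isinstance(data, TitrationDataset):
            raise TypeError("exchange-fit bootstrap takes a single TitrationDataset")
        x, y, sigma_arr = _exchange_xy(data)
        sigma = np.ones_like(y) if sigma_arr is None else sigma_arr
        strata = np.zeros(len(y), dtype=int)

        def refit(idx: np.ndarray) -> dict[str, float] | None:
            est = clone(est_proto)
            est.fit(x[idx], y[idx], sample_weight=1.0 / sigma[idx] ** 2)
            return est.result_.estimates if est.result_.converged else None

    groups = {g: np.flatnonzero(strata == g) for g in np.unique(strata)}
    draws: list[dict[str, float]] = []
    n_skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(rows, size=len(rows), replace=True) for rows in groups.values()]
            )
            try:
                estimates = refit(np.sort(idx))
            except Exception:
                estimates = None
            if estimates is None:
                n_skipped += 1
                continue
            draws.append(estimates)
    if not draws:
        raise RuntimeError("every bootstrap replicate failed")
    table = pd.DataFrame(draws)
    out = pd.DataFrame(
        {
            "estimate": pd.Series(fit.estimates),
            "p16": table.quantile(0.16),
            "p50": table.quantile(0.50),
            "p84": table.quantile(0.84),
        }
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["n_ok"] = len(draws)
    return out
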