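"""Forward models for the three NMR observables of the B-Z titration.

Three quantities report on the four-state mechanism:

* imino-proton hydrogen-exchange rates ``k_ex`` of the DNA, observed either
  on Z-form resonances (as a function of the molar ratio chi under the
  half-stoichiometry regime, or of the Z fraction f_Z in general) or on
  B-form resonances (as a function of f_Z);
* amide chemical-shift perturbations ``ddelta_obs`` of the protein,
  population-weighted over the bound states.

Each exchange-rate curve is a population-weighted average of limiting
rates over the states carrying the observed proton.  The closed forms
contain removable singularities (chi -> 0, f_Z -> 0, alpha -> 1); they
are evaluated here through an exact conjugate rearrangement that cancels
the singular prefactor algebraically, so no series switch or threshold is
needed (see docs/methods.md).

Convention note.  The curve parameters ``alpha`` and ``K_BZ1`` are the
standard exchange-curve parameterization in which published constants for
these systems are reported; they are the reciprocals of the species-model
ratios of :mod:`bzfit.equilibria`.  Exactly, for every f_Z::

    curve(alpha, K_BZ1, f_Z)
      == population-weighted average of the four-state model with
         Kd_ZP2 / Kd_BP = 1/alpha   and   [ZP]/[BP] = 1/K_BZ1

(machine-precision identity; see docs/methods.md).  In particular
``alpha -> 0`` means the second binding event is much weaker than the
first, giving sequential filling: ZP forms first, ZP2 only past one
equivalent of protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import NumericalDomainError, UndefinedObservableError
from .equilibria import SpeciesState

__all__ = [
    "ExchangeRateParams",
    "ShiftPair",
    "kex_vs_chi",
    "kex_bform_vs_fz",
    "kex_zform_vs_fz",
    "delta_obs",
]

#: negative sqrt arguments within this absolute tolerance are clamped to 0;
#: larger violations raise NumericalDomainError
_SQRT_CLAMP = 1e-12


@dataclass(frozen=True)
class ExchangeRateParams:
    """Limiting imino-proton exchange rate constants per state, s^-1.

    ``kex_B``/``kex_BP`` are the rates of B-form imino protons in free DNA
    and in the BP complex; ``kex_ZP``/``kex_ZP2`` those of Z-form imino
    protons in the singly and doubly bound Z complexes.
    """

    kex_B: float = 0.0
    kex_BP: float = 0.0
    kex_ZP: float = 0.0
    kex_ZP2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("kex_B", "kex_BP", "kex_ZP", "kex_ZP2"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class ShiftPair:
    """Limiting chemical-shift changes of one amide probe, ppm.

    ``delta_B`` and ``delta_Z`` are the shift differences of the
    B-DNA-bound and Z-DNA-bound forms relative to the free protein; either
    sign is allowed.
    """

    probe_id: str
    delta_B: float
    delta_Z: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_B) and math.isfinite(self.delta_Z)):
            raise ValueError("delta_B and delta_Z must be finite")


def _safe_sqrt(arg: float, context: str) -> float:
    if arg < -_SQRT_CLAMP:
        raise NumericalDomainError(f"sqrt argument {arg!r} < -1e-12 in {context}")
    return math.sqrt(max(arg, 0.0))


def kex_vs_chi(rates: ExchangeRateParams, alpha: float, chi: float) -> float:
    """Z-form imino exchange rate vs molar ratio, half-stoichiometry regime.

    Valid for K_BZ1 = 1 and tight binding (Z_t = chi [N]_t / 2), hence only
    exposed for chi in [0, 2].  The curve interpolates from ``kex_ZP`` at
    chi -> 0 to exactly ``kex_ZP2`` at chi = 2 as the second binding event
    saturates; ``alpha`` controls the shape in between.

    Evaluated as ``kex_ZP2 + (kex_ZP - kex_ZP2) (2 - chi) /
    (1 + sqrt(1 - 4 (1-alpha)(chi/2 - chi^2/4)))``, the conjugate form of
    the printed expression, exact including the removable chi -> 0 and
    alpha -> 1 points.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha!r}")
    if not 0.0 <= chi <= 2.0:
        raise ValueError(
            f"chi must lie in [0, 2] (the regime assumes Z_t = chi [N]_t / 2), got {chi!r}"
        )
    q = 4.0 * (1.0 - alpha) * (chi / 2.0 - chi * chi / 4.0)
    root = _safe_sqrt(1.0 - q, "kex_vs_chi")
    weight = (2.0 - chi) / (1.0 + root)
    return rates.kex_ZP2 + (rates.kex_ZP - rates.kex_ZP2) * weight


def _fz_discriminant_root(alpha: float, K_BZ1: float, f_Z: float, context: str) -> tuple[float, float]:
    """Shared pieces of the f_Z-domain exchange curves: m and sqrt(m^2 - q)."""
    m = 1.0 + (K_BZ1 - 1.0) * f_Z
    q = 4.0 * K_BZ1 * (1.0 - alpha) * f_Z * (1.0 - f_Z)
    root = _safe_sqrt(m * m - q, context)
    return m, root


def kex_bform_vs_fz(
    rates: ExchangeRateParams, alpha: float, K_BZ1: float, f_Z: float
) -> float:
    """B-form imino exchange rate as a function of the Z fraction.

    Averages ``kex_B`` and ``kex_BP`` over the B-form states {B, BP}; used
    when the probe resonance belongs to the residual B-form population, so
    f_Z = 1 (no B form left) is outside the domain.

    Conjugate form: ``kex_B + (kex_BP - kex_B) * 2 K_BZ1 f_Z /
    (m + sqrt(m^2 - q))`` with ``m = 1 + (K_BZ1 - 1) f_Z`` and
    ``q = 4 K_BZ1 (1 - alpha) f_Z (1 - f_Z)``.
    """
    if alpha <= 0 or K_BZ1 <= 0:
        raise ValueError("alpha and K_BZ1 must be > 0")
    if not 0.0 <= f_Z < 1.0:
        raise ValueError(
            f"f_Z must lie in [0, 1) for a B-form probe (none left at f_Z=1), got {f_Z!r}"
        )
    m, root = _fz_discriminant_root(alpha, K_BZ1, f_Z, "kex_bform_vs_fz")
    weight = 2.0 * K_BZ1 * f_Z / (m + root)
    return rates.kex_B + (rates.kex_BP - rates.kex_B) * weight


def kex_zform_vs_fz(
    rates: ExchangeRateParams, alpha: float, K_BZ1: float, f_Z: float
) -> float:
    """Z-form imino exchange rate as a function of the Z fraction.

    Averages ``kex_ZP`` and ``kex_ZP2`` over the Z-form states {ZP, ZP2};
    the general-regime counterpart of :func:`kex_vs_chi` (no K_BZ1 = 1
    assumption).  Returns exactly ``kex_ZP2`` at f_Z = 1 and ``kex_ZP`` in
    the removable f_Z -> 0 limit.

    Conjugate form: ``kex_ZP2 + (kex_ZP - kex_ZP2) * 2 (1 - f_Z) /
    (m + sqrt(m^2 - q))``.
    """
    if alpha <= 0 or K_BZ1 <= 0:
        raise ValueError("alpha and K_BZ1 must be > 0")
    if not 0.0 <= f_Z <= 1.0:
        raise ValueError(f"f_Z must lie in [0, 1], got {f_Z!r}")
    m, root = _fz_discriminant_root(alpha, K_BZ1, f_Z, "kex_zform_vs_fz")
    weight = 2.0 * (1.0 - f_Z) / (m + root)
    return rates.kex_ZP2 + (rates.kex_ZP - rates.kex_ZP2) * weight


def delta_obs(state: SpeciesState, shifts: ShiftPair) -> float:
    """Population-weighted amide chemical-shift change, ppm.

    ``ddelta_obs = ([BP]/[P]_t) ddelta_B + (([ZP] + 2[ZP2])/[P]_t)
    ddelta_Z``: the ZP2 state carries two protein molecules, both Z-bound,
    hence the factor 2.  Bounded by the convex hull of {0, ddelta_B,
    ddelta_Z} scaled by the bound-protein fraction.
    """
    if state.P_total <= 0:
        raise UndefinedObservableError(
            "delta_obs is a protein-observed quantity; P_total must be > 0"
        )
    w_B = state.BP / state.P_total
    w_Z = (state.ZP + 2.0 * state.ZP2) / state.P_total
    return w_B * shifts.delta_B + w_Z * shifts.delta_Z
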