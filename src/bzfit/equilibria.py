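"""Coupled binding equilibria of the protein-induced B-Z DNA transition.

A Z-DNA-binding protein (ZBP, ``P``) converts a short DNA duplex (``N``)
from the right-handed B form to the left-handed Z form through a
sequential four-state mechanism::

    B + P <=> BP        dissociation constant Kd_BP   (uM)
    BP    <=> ZP        conformational constant K_BZ1 = [ZP]/[BP]
    ZP + P <=> ZP2      dissociation constant Kd_ZP2  (uM)

``B`` is free B-form DNA, ``BP`` the B-form/protein complex, ``ZP`` the
Z-form complex with one protein, and ``ZP2`` the Z-form complex saturated
by a second protein.  The ratio ``alpha = Kd_ZP2 / Kd_BP`` compares the
second binding event with the first.

Given total concentrations ``[P]_t`` and ``[N]_t``, mass balance reduces
to a monic cubic in the free protein concentration ``[P]``; this module
solves it both in closed (trigonometric) form and by bracketing on the
mass-balance residual, and exposes the resulting species partition,
the total Z-DNA concentration ``Z_t = [ZP] + [ZP2]``, and the Z fractions
``f_Z = Z_t/[N]_t`` (DNA convention) and ``([ZP]+[ZP2])/[P]_t`` (protein
convention).

All concentrations are micromolar throughout; convert nM/mM on input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .exceptions import (
    DegenerateModelError,
    NumericalDomainError,
    RootSelectionError,
)

__all__ = [
    "ModelParams",
    "MixtureComposition",
    "CubicCoefficients",
    "SpeciesState",
    "cubic_coefficients",
    "solve_free_protein_closed_form",
    "solve_free_protein_numeric",
    "free_protein",
    "species_concentrations",
    "solve_species",
    "titration_curve",
    "half_stoichiometry_deviation",
]

#: relative tolerance used for internal consistency checks (mass balances,
#: cubic residuals)
REL_TOL = 1e-9

#: lower bound on K_BZ1 accepted by fitting/simulation paths; 0 is rejected
#: outright because the cubic coefficients divide by K_BZ1
K_BZ1_FLOOR = 1e-6


@dataclass(frozen=True)
class ModelParams:
    """Equilibrium constants of the four-state B-Z transition mechanism.

    Parameters
    ----------
    Kd_BP : float
        Dissociation constant of the BP complex, uM.
    Kd_ZP2 : float
        Dissociation constant of the second binding event
        (ZP + P <=> ZP2), uM.
    K_BZ1 : float
        Dimensionless conformational equilibrium constant [ZP]/[BP].
    """

    Kd_BP: float
    Kd_ZP2: float
    K_BZ1: float

    def __post_init__(self) -> None:
        if self.K_BZ1 == 0:
            raise DegenerateModelError(
                "K_BZ1 == 0 collapses the mechanism (coefficients divide by "
                "K_BZ1); use a small positive value instead"
            )
        for name in ("Kd_BP", "Kd_ZP2", "K_BZ1"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")

    @property
    def alpha(self) -> float:
        """Ratio of dissociation constants, Kd_ZP2 / Kd_BP (dimensionless)."""
        return self.Kd_ZP2 / self.Kd_BP


@dataclass(frozen=True)
class MixtureComposition:
    """Total protein and DNA-duplex concentrations of a titration point.

    ``chi`` is the molar ratio [P]_t/[N]_t; it is only defined when
    N_total > 0.
    """

    P_total: float
    N_total: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.P_total) or self.P_total < 0:
            raise ValueError(f"P_total must be finite and >= 0, got {self.P_total!r}")
        if not math.isfinite(self.N_total) or self.N_total < 0:
            raise ValueError(f"N_total must be finite and >= 0, got {self.N_total!r}")

    @property
    def chi(self) -> float:
        if self.N_total == 0:
            raise ValueError("chi is undefined when N_total == 0")
        return self.P_total / self.N_total

    @classmethod
    def from_chi(cls, chi: float, N_total: float) -> "MixtureComposition":
        """Build a composition from a molar ratio and a DNA concentration."""
        if chi < 0:
            raise ValueError(f"chi must be >= 0, got {chi!r}")
        return cls(P_total=chi * N_total, N_total=N_total)


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the monic cubic ``[P]^3 + a[P]^2 + b[P] + c = 0``.

    ``theta`` is the trigonometric angle of the closed-form solution; it is
    ``None`` when the discriminant-like quantity ``a^2 - 3b`` is too small
    for the trigonometric form (callers then use the numeric solver).
    """

    a: float
    b: float
    c: float
    theta: float | None = None


def cubic_coefficients(
    params: ModelParams, mix: MixtureComposition
) -> CubicCoefficients:
    """Coefficients of the free-protein cubic for a given mixture.

    The monic cubic follows from eliminating the bound species with the
    shared-denominator partition and imposing protein mass balance::

        a = 2[N]_t - [P]_t + (1 + 1/K_BZ1) Kd_ZP2
        b = (1 + 1/K_BZ1) Kd_ZP2 ([N]_t - [P]_t) + Kd_BP Kd_ZP2 / K_BZ1
        c = -Kd_BP Kd_ZP2 [P]_t / K_BZ1
    """
    P_t, N_t = mix.P_total, mix.N_total
    kappa = (1.0 + 1.0 / params.K_BZ1) * params.Kd_ZP2
    a = 2.0 * N_t - P_t + kappa
    b = kappa * (N_t - P_t) + params.Kd_BP * params.Kd_ZP2 / params.K_BZ1
    c = -params.Kd_BP * params.Kd_ZP2 * P_t / params.K_BZ1
    theta = _trig_angle(a, b, c)
    return CubicCoefficients(a=a, b=b, c=c, theta=theta)


def _trig_angle(a: float, b: float, c: float) -> float | None:
    """Angle of the trigonometric root formula, or None when unusable."""
    disc = a * a - 3.0 * b
    scale = max(a * a, abs(3.0 * b), 1e-300)
    if disc <= 1e-12 * scale:
        # at (or numerically near) a triple-root configuration; the
        # trigonometric form is ill-conditioned there
        return None
    arg = (-2.0 * a**3 + 9.0 * a * b - 27.0 * c) / (2.0 * disc**1.5)
    if abs(arg) > 1.0 + 1e-9:
        return None
    return math.acos(min(1.0, max(-1.0, arg)))


def _single_real_root(a: float, b: float, c: float) -> float:
    """Real root of the monic cubic when the discriminant allows only one.

    Depressed-cubic hyperbolic forms (cosh for p < 0, sinh for p > 0,
    cube root at p ~ 0); the complement of the trigonometric branch in the
    analytic solution.
    """
    p = b - a * a / 3.0
    q = 2.0 * a**3 / 27.0 - a * b / 3.0 + c
    scale = max(abs(b), a * a / 3.0, 1e-300)
    if abs(p) <= 1e-12 * scale:
        t = -math.copysign(abs(q) ** (1.0 / 3.0), q)
    elif p < 0:
        u = -3.0 * abs(q) / (2.0 * p) * math.sqrt(-3.0 / p)
        if u < 1.0:  # rounding placed us back in the trigonometric regime
            u = 1.0
        t = -2.0 * math.copysign(math.sqrt(-p / 3.0), q) * math.cosh(
            math.acosh(u) / 3.0
        )
    else:
        u = 3.0 * q / (2.0 * p) * math.sqrt(3.0 / p)
        t = -2.0 * math.sqrt(p / 3.0) * math.sinh(math.asinh(u) / 3.0)
    return t - a / 3.0


def _bound_protein(params: ModelParams, N_total: float, P: float) -> float:
    """Protein sequestered in complexes, [BP] + [ZP] + 2[ZP2], at free [P]."""
    K = params.K_BZ1
    denom = (
        params.Kd_BP * params.Kd_ZP2
        + (1.0 + K) * params.Kd_ZP2 * P
        + K * P * P
    )
    numer = (1.0 + K) * params.Kd_ZP2 * P + 2.0 * K * P * P
    return N_total * numer / denom


def _mass_balance_residual(
    params: ModelParams, mix: MixtureComposition, P: float
) -> float:
    """g([P]) = [P] + [BP] + [ZP] + 2[ZP2] - [P]_t; strictly increasing."""
    return P + _bound_protein(params, mix.N_total, P) - mix.P_total


def _polish_root(params: ModelParams, mix: MixtureComposition, P: float) -> float:
    """Newton-refine a root of the mass-balance residual.

    The trigonometric formula computes the root as a difference of terms of
    order ``|a|``; when the physical root is many orders of magnitude smaller
    (tight binding at high concentrations) that costs relative precision.
    Two Newton steps on the well-conditioned mass-balance residual restore
    it.  Standard polish for analytic cubic solvers.
    """
    K = params.K_BZ1
    kd = params.Kd_BP * params.Kd_ZP2
    c1 = (1.0 + K) * params.Kd_ZP2
    N_t, P_t = mix.N_total, mix.P_total
    for _ in range(2):
        D = kd + c1 * P + K * P * P
        u = c1 * P + 2.0 * K * P * P
        g = P + N_t * u / D - P_t
        du = c1 + 4.0 * K * P
        dD = c1 + 2.0 * K * P
        gp = 1.0 + N_t * (du * D - u * dD) / (D * D)
        if gp <= 0:  # cannot happen for valid params; bail out defensively
            break
        P_new = P - g / gp
        if not (0.0 <= P_new <= P_t):
            P_new = min(max(P_new, 0.0), P_t)
        if P_new == P:
            break
        P = P_new
    return P


def solve_free_protein_closed_form(
    coeffs: CubicCoefficients, mix: MixtureComposition, params: ModelParams | None = None
) -> float:
    """Free-protein concentration from the analytic root formula.

    In the three-real-root regime (``a^2 - 3b > 0`` with the arccos
    argument in range) this evaluates all three trigonometric candidates
    ``-a/3 + (2/3) sqrt(a^2 - 3b) cos((theta + 2 pi k)/3)`` and keeps the
    unique one inside ``[0, [P]_t]`` (with 1e-9-scale slack); otherwise it
    uses the hyperbolic single-real-root branch of the same analytic
    solution.  Physical uniqueness is guaranteed by the strictly
    increasing mass balance, so candidate ambiguity only ever arises from
    rounding; in that case a :class:`RootSelectionError` is raised so
    callers can fall back to :func:`solve_free_protein_numeric`.

    When ``params`` is given the root is Newton-polished on the
    mass-balance residual; it is always verified against the cubic
    (residual below 1e-9 of the largest term, else
    :class:`NumericalDomainError`).
    """
    P_t = mix.P_total
    if P_t == 0.0:
        return 0.0
    if mix.N_total == 0.0:
        return P_t
    a, b, c = coeffs.a, coeffs.b, coeffs.c
    theta = coeffs.theta if coeffs.theta is not None else _trig_angle(a, b, c)
    if theta is not None:
        # three real roots: the printed trigonometric branch
        disc = max(a * a - 3.0 * b, 0.0)
        r = (2.0 / 3.0) * math.sqrt(disc)
        candidates = [
            -a / 3.0 + r * math.cos((theta + 2.0 * math.pi * k) / 3.0)
            for k in range(3)
        ]
    else:
        # one real root: hyperbolic branches of the same analytic solution
        candidates = [_single_real_root(a, b, c)]
    slack = 1e-9 * max(1.0, P_t)
    inside = [p for p in candidates if -slack <= p <= P_t + slack]
    if len(inside) != 1:
        raise RootSelectionError(
            f"expected exactly one root in [0, {P_t}], found {len(inside)}",
            candidates=candidates,
        )
    root = min(max(inside[0], 0.0), P_t)
    if params is not None:
        root = _polish_root(params, mix, root)
    residual = root**3 + a * root**2 + b * root + c
    scale = max(abs(root**3), abs(a * root**2), abs(b * root), abs(c))
    if scale > 0 and abs(residual) > 1e-9 * scale:
        raise NumericalDomainError(
            f"cubic residual {residual!r} exceeds 1e-9 of largest term {scale!r}"
        )
    return root


def solve_free_protein_numeric(
    params: ModelParams, mix: MixtureComposition
) -> float:
    """Free-protein concentration by bracketing the mass-balance residual.

    ``g([P]) = [P] + [BP] + [ZP] + 2[ZP2] - [P]_t`` is strictly increasing
    with ``g(0) = -[P]_t <= 0`` and ``g([P]_t) >= 0``, so Brent's method on
    ``[0, [P]_t]`` converges to the unique physical root.  Serves both as
    the independent oracle for the closed form and as its fallback.
    """
    P_t = mix.P_total
    if P_t == 0.0:
        return 0.0
    if mix.N_total == 0.0:
        return P_t

    def g(P: float) -> float:
        return _mass_balance_residual(params, mix, P)

    g0, g1 = g(0.0), g(P_t)
    if g0 > 0 or g1 < 0:
        raise RootSelectionError(
            f"no sign change of the mass balance on [0, {P_t}] "
            f"(g(0)={g0!r}, g(P_t)={g1!r}); inputs are inconsistent",
            candidates=(),
        )
    root = brentq(g, 0.0, P_t, xtol=1e-12 * max(1.0, P_t), rtol=8.9e-16)
    return _polish_root(params, mix, float(root))


def free_protein(params: ModelParams, mix: MixtureComposition) -> float:
    """Free-protein concentration; closed form with numeric fallback."""
    try:
        return solve_free_protein_closed_form(
            cubic_coefficients(params, mix), mix, params=params
        )
    except (NumericalDomainError, RootSelectionError):
        return solve_free_protein_numeric(params, mix)


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species partition of one titration point (all uM).

    ``Z_total = ZP + ZP2`` is the total Z-DNA concentration.  Two Z-fraction
    conventions are exposed: ``f_Z_dna = Z_total/[N]_t`` (the DNA-population
    convention used for titration curves and the half-stoichiometry
    relation) and ``f_Z_protein = (ZP + ZP2)/[P]_t``.
    """

    P_free: float
    B: float
    BP: float
    ZP: float
    ZP2: float
    Z_total: float
    f_Z_dna: float
    f_Z_protein: float
    P_total: float
    N_total: float


def species_concentrations(
    params: ModelParams, mix: MixtureComposition, P_free: float
) -> SpeciesState:
    """Species partition at a given free-protein concentration.

    All four DNA species share the denominator
    ``D = Kd_BP Kd_ZP2 + (1 + K_BZ1) Kd_ZP2 [P] + K_BZ1 [P]^2``::

        [B]   = [N]_t Kd_BP Kd_ZP2        / D
        [BP]  = [N]_t Kd_ZP2 [P]          / D
        [ZP]  = [N]_t K_BZ1 Kd_ZP2 [P]    / D
        [ZP2] = [N]_t K_BZ1 [P]^2         / D
    """
    if P_free < 0:
        raise ValueError(f"P_free must be >= 0, got {P_free!r}")
    K = params.K_BZ1
    N_t = mix.N_total
    D = params.Kd_BP * params.Kd_ZP2 + (1.0 + K) * params.Kd_ZP2 * P_free + K * P_free**2
    B = N_t * params.Kd_BP * params.Kd_ZP2 / D
    BP = N_t * params.Kd_ZP2 * P_free / D
    ZP = N_t * K * params.Kd_ZP2 * P_free / D
    ZP2 = N_t * K * P_free**2 / D
    Z_total = ZP + ZP2
    f_dna = Z_total / N_t if N_t > 0 else 0.0
    f_prot = Z_total / mix.P_total if mix.P_total > 0 else 0.0
    return SpeciesState(
        P_free=P_free,
        B=B,
        BP=BP,
        ZP=ZP,
        ZP2=ZP2,
        Z_total=Z_total,
        f_Z_dna=f_dna,
        f_Z_protein=f_prot,
        P_total=mix.P_total,
        N_total=mix.N_total,
    )


def solve_species(params: ModelParams, mix: MixtureComposition) -> SpeciesState:
    """Solve the free protein and return the full species partition."""
    return species_concentrations(params, mix, free_protein(params, mix))


def titration_curve(
    params: ModelParams, N_total: float, chi_grid: Sequence[float]
) -> list[SpeciesState]:
    """Species states along a titration, one per molar ratio chi.

    Each point uses ``[P]_t = chi * [N]_t`` at fixed ``[N]_t``; by the
    model's monotone mass balance, ``f_Z_dna`` is non-decreasing in chi.
    """
    states = []
    for chi in chi_grid:
        if chi < 0:
            raise ValueError(f"chi values must be >= 0, got {chi!r}")
        states.append(
            solve_species(params, MixtureComposition.from_chi(chi, N_total))
        )
    return states


def half_stoichiometry_deviation(
    params: ModelParams, chi_grid: Sequence[float], N_total: float = 1.0
) -> float:
    """Sup-norm deviation of ``f_Z_dna`` from the line ``chi/2``.

    Under tight binding with K_BZ1 = 1 the model produces Z-DNA equal to
    half the added protein (``Z_t = [P]_t / 2``) for sub-stoichiometric
    ratios, i.e. ``f_Z_dna = chi/2``.  The sup-norm deviation from that
    line over a chi grid measures how far a given parameter set is from
    the half-stoichiometry regime.
    """
    states = titration_curve(params, N_total, chi_grid)
    return max(
        abs(s.f_Z_dna - 0.5 * chi) for s, chi in zip(states, chi_grid)
    )
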