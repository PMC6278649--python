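"""Synthetic titration generators with the statistical structure the model assumes.

Noise-free curves are always computed through the equilibria/observables
modules, then perturbed with the noise models the observables warrant:
Gaussian additive noise on chemical shifts and f_Z (f_Z clipped to [0, 1]),
mean-preserving log-normal multiplicative noise on exchange rates (rates
are positive by nature).  Every dataset records its generating truth in
``metadata['truth']`` and is byte-reproducible under a fixed seed.

Default designs: exchange-rate titrations use 12 molar-ratio points from
0.17 to 2.0 at [N]_t = 100 uM (a typical NMR titration of a short
duplex); the shift/f_Z design crosses [N]_t in {0.5, 5, 50} uM with chi in
{0.25, 0.75, 1.5, 2.5} (12 compositions) so that absolute dissociation
constants from sub-uM to tens of uM stay identifiable — a fixed single
concentration far above Kd would leave only ratios identifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibria import ModelParams, MixtureComposition, solve_species, titration_curve
from .exceptions import DatasetValidationError
from .fitting import TitrationDataset
from .observables import (
    ExchangeRateParams,
    ShiftPair,
    delta_obs,
    kex_bform_vs_fz,
    kex_vs_chi,
    kex_zform_vs_fz,
)
from .reference import (
    BINDING_SYSTEMS,
    DEFAULT_EXCHANGE_RATES,
    EXCHANGE_SYSTEMS,
    ReferenceSystem,
)

__all__ = [
    "SimulationSpec",
    "DEFAULT_CHI_GRID",
    "DEFAULT_N_TOTAL_UM",
    "DEFAULT_GLOBAL_DESIGN",
    "default_probe_shifts",
    "simulate_dataset",
    "make_fixture_suite",
    "spec_for_reference_system",
]

#: 12-point molar-ratio grid mirroring a typical B-Z titration
DEFAULT_CHI_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.linspace(0.17, 2.0, 12), 6)
)

#: DNA duplex concentration for exchange-rate designs, uM
DEFAULT_N_TOTAL_UM = 100.0

#: shift/f_Z design: ([P]_t, [N]_t) pairs crossing three DNA concentrations
#: with four molar ratios (12 titration points)
DEFAULT_GLOBAL_DESIGN: tuple[tuple[float, float], ...] = tuple(
    (round(chi * n, 9), n) for n in (0.5, 5.0, 50.0) for chi in (0.25, 0.75, 1.5, 2.5)
)

_DEFAULT_FZ_GRID: tuple[float, ...] = tuple(
    float(x) for x in np.round(np.linspace(0.05, 0.92, 12), 6)
)


def default_probe_shifts(n_probes: int = 8) -> tuple[ShiftPair, ...]:
    """Deterministic limiting-shift pairs for synthetic amide probes.

    Half the probes emulate 1H amides (|ddelta| up to ~0.5 ppm), half 15N
    (up to ~3 ppm), with mixed signs — the magnitudes a winged-helix
    domain shows on DNA binding.
    """
    pairs = []
    for i in range(n_probes):
        nucleus = "1H" if i % 2 == 0 else "15N"
        scale = 0.5 if nucleus == "1H" else 3.0
        sign_b = 1.0 if i % 4 < 2 else -1.0
        frac = (i + 1) / n_probes
        pairs.append(
            ShiftPair(
                probe_id=f"{nucleus}_probe{i + 1}",
                delta_B=round(sign_b * scale * (0.2 + 0.6 * frac), 6),
                delta_Z=round(-sign_b * scale * (0.9 - 0.5 * frac), 6),
            )
        )
    return tuple(pairs)


@dataclass
class SimulationSpec:
    """Recipe for one synthetic titration dataset.

    ``truth`` carries whichever parameters the observable needs: ``alpha``
    (and ``k_bz1``) for exchange curves over f_Z grids, a full
    :class:`ModelParams` triple for composition-driven observables.
    Noise levels: ``sigma_shift`` (ppm, Gaussian), ``sigma_fz`` (fraction,
    Gaussian, clipped to [0, 1]), ``cv_kex`` (coefficient of variation of
    the log-normal multiplicative rate noise).
    """

    observable_kind: str
    alpha: float | None = None
    k_bz1: float | None = None
    kd_bp: float | None = None
    kd_zp2: float | None = None
    rates: ExchangeRateParams | None = None
    shifts: tuple[ShiftPair, ...] | None = None
    chi_grid: tuple[float, ...] | None = None
    fz_grid: tuple[float, ...] | None = None
    n_total: float = DEFAULT_N_TOTAL_UM
    compositions: tuple[tuple[float, float], ...] | None = None
    sigma_shift: float = 0.005
    sigma_fz: float = 0.02
    cv_kex: float = 0.05
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("sigma_shift", "sigma_fz", "cv_kex"):
            if getattr(self, name) < 0:
                raise DatasetValidationError(f"{name} must be >= 0")
        if self.observable_kind == "kex_vs_chi":
            if self.alpha is None or self.rates is None:
                raise DatasetValidationError("kex_vs_chi needs alpha and rates")
        elif self.observable_kind in ("kex_bform", "kex_zform"):
            if self.alpha is None or self.k_bz1 is None or self.rates is None:
                raise DatasetValidationError(
                    f"{self.observable_kind} needs alpha, k_bz1 and rates"
                )
            if self.fz_grid is None and (self.kd_bp is None or self.kd_zp2 is None):
                raise DatasetValidationError(
                    "f_Z-domain curves need either an explicit fz_grid or full "
                    "binding constants to derive it from a chi grid"
                )
        elif self.observable_kind == "shift_and_fz":
            if None in (self.k_bz1, self.kd_bp, self.kd_zp2) or self.shifts is None:
                raise DatasetValidationError(
                    "shift_and_fz needs kd_bp, kd_zp2, k_bz1 and probe shifts"
                )
        else:
            raise DatasetValidationError(
                f"unknown observable_kind {self.observable_kind!r}"
            )
        grid = self.chi_grid
        if grid is not None and any(b <= a for a, b in zip(grid, grid[1:])):
            raise DatasetValidationError("chi_grid must be strictly increasing")

    def model_params(self) -> ModelParams:
        return ModelParams(Kd_BP=self.kd_bp, Kd_ZP2=self.kd_zp2, K_BZ1=self.k_bz1)

    def truth_dict(self) -> dict:
        truth: dict = {}
        for name in ("alpha", "k_bz1", "kd_bp", "kd_zp2"):
            if getattr(self, name) is not None:
                truth[name] = getattr(self, name)
        if self.rates is not None:
            truth["rates"] = {
                "kex_B": self.rates.kex_B,
                "kex_BP": self.rates.kex_BP,
                "kex_ZP": self.rates.kex_ZP,
                "kex_ZP2": self.rates.kex_ZP2,
            }
        if self.shifts is not None:
            truth["shifts"] = {
                s.probe_id: [s.delta_B, s.delta_Z] for s in self.shifts
            }
        return truth


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative factors with SD/mean exactly cv."""
    if cv == 0:
        return np.ones(n)
    sigma_ln = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, size=n))


def _exchange_means(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (chi, f_z, kex) noise-free arrays for an exchange-kind spec."""
    if spec.observable_kind == "kex_vs_chi":
        chi = np.asarray(spec.chi_grid if spec.chi_grid is not None else DEFAULT_CHI_GRID)
        chi = chi[chi <= 2.0]
        kex = np.array([kex_vs_chi(spec.rates, spec.alpha, c) for c in chi])
        return chi, np.full_like(chi, np.nan), kex
    if spec.fz_grid is not None:
        fz = np.asarray(spec.fz_grid, dtype=float)
        chi = np.full_like(fz, np.nan)
    else:
        chi = np.asarray(spec.chi_grid if spec.chi_grid is not None else DEFAULT_CHI_GRID)
        states = titration_curve(spec.model_params(), spec.n_total, chi)
        fz = np.array([s.f_Z_dna for s in states])
    fn = kex_bform_vs_fz if spec.observable_kind == "kex_bform" else kex_zform_vs_fz
    kex = np.array([fn(spec.rates, spec.alpha, spec.k_bz1, f) for f in fz])
    return chi, fz, kex


def simulate_dataset(spec: SimulationSpec) -> TitrationDataset:
    """Generate one titration dataset according to ``spec``.

    Noise-free means come from the forward models; with all noise levels
    at zero the dataset values equal forward-model calls exactly.  The
    generating truth is recorded in ``metadata['truth']``.
    """
    rng = np.random.default_rng(spec.seed)
    metadata = {
        "observable_kind": spec.observable_kind,
        "truth": spec.truth_dict(),
        "seed": spec.seed,
        "label": spec.label,
        "noise": {
            "sigma_shift": spec.sigma_shift,
            "sigma_fz": spec.sigma_fz,
            "cv_kex": spec.cv_kex,
        },
    }
    if spec.observable_kind in ("kex_vs_chi", "kex_bform", "kex_zform"):
        chi, fz, kex = _exchange_means(spec)
        noisy = kex * _lognormal_factors(rng, spec.cv_kex, len(kex))
        sigma = spec.cv_kex * kex if spec.cv_kex > 0 else np.full_like(kex, np.nan)
        df = pd.DataFrame(
            {"chi": chi, "f_z": fz, "kex_s1": noisy, "kex_sigma": sigma}
        )
        return TitrationDataset(spec.observable_kind, df, metadata)

    # shift_and_fz
    comps = spec.compositions if spec.compositions is not None else DEFAULT_GLOBAL_DESIGN
    params = spec.model_params()
    states = [solve_species(params, MixtureComposition(p, n)) for p, n in comps]
    rows = []
    for state, (p_t, n_t) in zip(states, comps):
        for pair in spec.shifts:
            mean = delta_obs(state, pair)
            rows.append(
                {
                    "P_total_uM": p_t,
                    "N_total_uM": n_t,
                    "probe_id": pair.probe_id,
                    "nucleus": pair.probe_id.split("_")[0],
                    "ddelta_obs_ppm": mean + rng.normal(0.0, spec.sigma_shift)
                    if spec.sigma_shift > 0
                    else mean,
                    "sigma_ppm": spec.sigma_shift if spec.sigma_shift > 0 else np.nan,
                    "f_z": np.nan,
                    "f_z_sigma": np.nan,
                }
            )
    for state, (p_t, n_t) in zip(states, comps):
        mean = state.f_Z_dna
        value = (
            float(np.clip(mean + rng.normal(0.0, spec.sigma_fz), 0.0, 1.0))
            if spec.sigma_fz > 0
            else mean
        )
        rows.append(
            {
                "P_total_uM": p_t,
                "N_total_uM": n_t,
                "probe_id": "",
                "nucleus": "",
                "ddelta_obs_ppm": np.nan,
                "sigma_ppm": np.nan,
                "f_z": value,
                "f_z_sigma": spec.sigma_fz if spec.sigma_fz > 0 else np.nan,
            }
        )
    return TitrationDataset("shift_and_fz", pd.DataFrame(rows), metadata)


def spec_for_reference_system(
    system: ReferenceSystem,
    noise_scale: float = 1.0,
    seed: int = 0,
    n_probes: int = 8,
) -> SimulationSpec:
    """Simulation spec whose truth is a published reference parameter set."""
    rates = ExchangeRateParams(**DEFAULT_EXCHANGE_RATES)
    common = dict(
        sigma_shift=0.005 * noise_scale,
        sigma_fz=0.02 * noise_scale,
        cv_kex=0.05 * noise_scale,
        seed=seed,
        label=system.key,
    )
    if system.observable_kind == "kex_vs_chi":
        return SimulationSpec(
            observable_kind="kex_vs_chi", alpha=system.alpha, rates=rates, **common
        )
    if system.observable_kind in ("kex_bform", "kex_zform"):
        fz_grid = _DEFAULT_FZ_GRID
        if system.observable_kind == "kex_zform":
            fz_grid = tuple(np.round(np.linspace(0.05, 1.0, 12), 6))
        return SimulationSpec(
            observable_kind=system.observable_kind,
            alpha=system.alpha,
            k_bz1=system.k_bz1,
            rates=rates,
            fz_grid=fz_grid,
            **common,
        )
    return SimulationSpec(
        observable_kind="shift_and_fz",
        k_bz1=system.k_bz1,
        kd_bp=system.kd_bp_uM,
        kd_zp2=system.kd_zp2_uM,
        shifts=default_probe_shifts(n_probes),
        **common,
    )


def make_fixture_suite(output_dir: str | Path, seed: int = 0) -> dict:
    """Write a versioned fixture suite of CSV datasets plus a JSON manifest.

    Covers all four observable kinds, every reference parameter row, and
    three noise levels (0, 0.5x, 1x of the defaults).  The manifest lists
    SHA-256 hashes of each file, the generating truths and the seed; a
    rerun with the same seed reproduces identical hashes.
    """
    from . import __version__
    from .io import write_titration_csv

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    noise_levels = (0.0, 0.5, 1.0)
    systems = EXCHANGE_SYSTEMS + BINDING_SYSTEMS
    for i_sys, system in enumerate(systems):
        for i_noise, level in enumerate(noise_levels):
            spec = spec_for_reference_system(
                system, noise_scale=level, seed=seed + 1000 * i_sys + i_noise
            )
            dataset = simulate_dataset(spec)
            safe_key = system.key.replace(":", "_").replace(".", "p")
            name = f"{system.observable_kind}__{safe_key}__noise{level:g}.csv"
            path = output_dir / name
            write_titration_csv(dataset, path)
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            entries.append(
                {
                    "file": name,
                    "sha256": digest,
                    "observable_kind": system.observable_kind,
                    "system": system.as_dict(),
                    "noise_scale": level,
                    "truth": spec.truth_dict(),
                    "seed": spec.seed,
                }
            )
    manifest = {
        "version": __version__,
        "seed": seed,
        "n_datasets": len(entries),
        "note": (
            "synthetic fixtures; noise defaults (sigma_shift=0.005 ppm, "
            "sigma_fz=0.02, cv_kex=0.05) are generator placeholders, not "
            "measured NMR uncertainties"
        ),
        "datasets": entries,
    }
    manifest_path = output_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
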