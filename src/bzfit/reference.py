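"""Reference equilibrium constants reported for ZBP-induced B-Z transitions.

These literature values serve two purposes: defaults for the synthetic-data
generator and ground truths for parameter-recovery testing.  They are NOT
re-derived by this package; the underlying NMR titration data are not
public.

Two kinds of entries:

* exchange-curve systems — (alpha, K_BZ1) pairs fitted from imino-proton
  hydrogen-exchange titrations of hZa_ADAR1, and yabZa_E3L with 6-bp
  duplexes;
* binding-constant systems — (K_BZ1, Kd_BP, Kd_ZP2) triples from global
  chemical-shift/f_Z fits of caZa_PKZ under varying pH and ionic strength.

Note on ``alpha_matches_inverse_kd_ratio``: the reported convention is
``alpha = Kd_ZP2 / Kd_BP``, but for the two hZa_ADAR1 non-CG-repeat rows
the printed alpha matches the INVERSE ratio Kd_BP/Kd_ZP2 within rounding
(13.9 vs 400/29 = 13.8; 1.42 vs 260/180 = 1.44).  The printed numbers are
recorded uncorrected and the inconsistency is flagged, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

__all__ = [
    "ReferenceSystem",
    "EXCHANGE_SYSTEMS",
    "BINDING_SYSTEMS",
    "DEFAULT_EXCHANGE_RATES",
]


@dataclass(frozen=True)
class ReferenceSystem:
    """One published parameter set for a ZBP/DNA-duplex pair."""

    key: str
    protein: str
    dna: str
    observable_kind: str
    alpha: float | None = None
    k_bz1: float | None = None
    kd_bp_uM: float | None = None
    kd_zp2_uM: float | None = None
    pH: float | None = None
    nacl_mM: float | None = None
    #: printed alpha agrees with Kd_BP/Kd_ZP2 instead of Kd_ZP2/Kd_BP
    alpha_matches_inverse_kd_ratio: bool = False
    notes: str = ""

    def as_dict(self) -> dict:
        return asdict(self)


#: alpha / K_BZ1 values from hydrogen-exchange titration fits.  The
#: d(CGCGCG)2-hZa_ADAR1 system satisfies the half-stoichiometry relation
#: (K_BZ1 ~ 1, Kd values only bounded above by 0.1 uM), so its exchange
#: curve is analysed against the molar ratio chi; the others against f_Z.
EXCHANGE_SYSTEMS: tuple[ReferenceSystem, ...] = (
    ReferenceSystem(
        key="hZa_ADAR1:CGCGCG",
        protein="hZa_ADAR1",
        dna="d(CGCGCG)2",
        observable_kind="kex_vs_chi",
        alpha=1.15e-2,
        k_bz1=1.0,
        notes="K_BZ1 ~ 1 inferred from Z_t = [P]_t/2; Kd_BP, Kd_ZP2 < 0.1 uM (upper bounds)",
    ),
    ReferenceSystem(
        key="hZa_ADAR1:CACGTG",
        protein="hZa_ADAR1",
        dna="d(CACGTG)2",
        observable_kind="kex_bform",
        alpha=1.42,
        k_bz1=0.4,
        kd_bp_uM=260.0,
        kd_zp2_uM=180.0,
        alpha_matches_inverse_kd_ratio=True,
    ),
    ReferenceSystem(
        key="hZa_ADAR1:CGTACG",
        protein="hZa_ADAR1",
        dna="d(CGTACG)2",
        observable_kind="kex_bform",
        alpha=13.9,
        k_bz1=6.3,
        kd_bp_uM=400.0,
        kd_zp2_uM=29.0,
        alpha_matches_inverse_kd_ratio=True,
    ),
    ReferenceSystem(
        key="yabZa_E3L:CGCGCG",
        protein="yabZa_E3L",
        dna="d(CGCGCG)2",
        observable_kind="kex_zform",
        alpha=0.154,
        k_bz1=1.02,
        notes="Kd values not determined",
    ),
)


#: K_BZ1 / Kd_BP / Kd_ZP2 triples from global chemical-shift + f_Z fits of
#: caZa_PKZ titrations under varying pH and NaCl.
BINDING_SYSTEMS: tuple[ReferenceSystem, ...] = (
    ReferenceSystem(
        key="caZa_PKZ:TCGCGCG:pH6.0:10mM",
        protein="caZa_PKZ",
        dna="d(TCGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=0.87,
        kd_bp_uM=0.028,
        kd_zp2_uM=0.345,
        pH=6.0,
        nacl_mM=10.0,
    ),
    ReferenceSystem(
        key="caZa_PKZ:TCGCGCG:pH6.0:100mM",
        protein="caZa_PKZ",
        dna="d(TCGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=0.19,
        kd_bp_uM=16.4,
        kd_zp2_uM=8.76,
        pH=6.0,
        nacl_mM=100.0,
    ),
    ReferenceSystem(
        key="caZa_PKZ:TCGCGCG:pH6.0:250mM",
        protein="caZa_PKZ",
        dna="d(TCGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=0.01,
        kd_bp_uM=64.1,
        kd_zp2_uM=9.57,
        pH=6.0,
        nacl_mM=250.0,
        notes="K_BZ1 reported as ~0.01",
    ),
    ReferenceSystem(
        key="caZa_PKZ:TCGCGCG:pH8.0:10mM",
        protein="caZa_PKZ",
        dna="d(TCGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=1.18,
        kd_bp_uM=0.157,
        kd_zp2_uM=0.129,
        pH=8.0,
        nacl_mM=10.0,
    ),
    ReferenceSystem(
        key="caZa_PKZ:TCGCGCG:pH8.0:100mM",
        protein="caZa_PKZ",
        dna="d(TCGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=0.18,
        kd_bp_uM=5.41,
        kd_zp2_uM=2.41,
        pH=8.0,
        nacl_mM=100.0,
    ),
    ReferenceSystem(
        key="caZa_PKZ:CGCGCG:pH8.0:10mM",
        protein="caZa_PKZ",
        dna="d(CGCGCG)2",
        observable_kind="shift_and_fz",
        k_bz1=0.11,
        kd_bp_uM=5.18,
        kd_zp2_uM=1.79,
        pH=8.0,
        nacl_mM=10.0,
    ),
)


#: Limiting imino exchange rates are never reported for these systems; the
#: generator needs concrete values, so these are generic magnitudes typical
#: of imino-proton exchange in short duplexes (units s^-1).  They are fit
#: parameters, not physical claims.
DEFAULT_EXCHANGE_RATES: dict[str, float] = {
    "kex_B": 50.0,
    "kex_BP": 20.0,
    "kex_ZP": 10.0,
    "kex_ZP2": 1.0,
}
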