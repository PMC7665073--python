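"""Degree of protein hydrolysis (pH-stat titration) and predicted
in-vitro protein digestibility (IPD).

Two-phase pH-stat assay: an acid-titrated stomach phase (pH 2.0, crude
stomach enzyme extract) followed by an alkali-titrated intestinal phase
(pH 8.0, crude intestinal extract).  Titrant consumption is converted to
the fraction of peptide bonds cleaved (DH, %), and DH maps linearly to
predicted digestibility:

    IPD (%) = 3.5093 * DH + 70.248

Stomach phase:   DH = (V*N/E) * (1/P) * F_pH * 100
Intestine phase: DH = B * Nb * (1/a) * (1/MP) * (1/H_tot) * 100

with V/B titrant volumes (mL), N/Nb normalities (meqv/mL), E/MP substrate
protein mass (g), P peptide bonds cleaved (default 8.0 mol/g protein when
the amino-acid composition is unknown), F_pH = 1.08 the pH-2.0/25C
correction, 1/a = 1.50 the alpha-amino dissociation factor at pH 8.0/25C,
and H_tot the total peptide-bond content of the substrate (7.6-9.2 meqv/g
protein depending on the protein source).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import InvalidInputError

__all__ = [
    "IPD_SLOPE",
    "IPD_INTERCEPT",
    "H_TOT_RANGE",
    "StomachTitration",
    "IntestineTitration",
    "DigestibilityResult",
    "dh_stomach",
    "dh_intestine",
    "predict_ipd",
    "titration_to_result",
]

IPD_SLOPE = 3.5093
IPD_INTERCEPT = 70.248
H_TOT_RANGE = (7.6, 9.2)  # meqv peptide bonds per g protein


def _volume(v: float | Iterable[float]) -> float:
    """Accept a single consumed volume or an auto-titrator dosing log."""
    if isinstance(v, (int, float)):
        return float(v)
    return float(sum(v))


@dataclass(frozen=True)
class StomachTitration:
    """Acid-phase pH-stat record (pH 2.0, 25 C).

    ``V`` may be a total consumed volume (mL) or an iterable of
    incremental auto-titrator doses, which are summed.
    """

    V: float | tuple[float, ...]
    N: float  # acid normality, meqv H+ per mL
    E: float  # substrate protein mass, g
    P: float = 8.0  # peptide bonds cleaved, mol per g protein
    F_pH: float = 1.08  # correction factor for pH 2.0 at 25 C

    def __post_init__(self) -> None:
        if _volume(self.V) < 0:
            raise InvalidInputError("acid volume must be >= 0")
        if self.N <= 0 or self.E <= 0 or self.P <= 0 or self.F_pH <= 0:
            raise InvalidInputError("N, E, P and F_pH must be positive")


@dataclass(frozen=True)
class IntestineTitration:
    """Alkali-phase pH-stat record (pH 8.0, 25 C).

    ``H_tot`` must lie in the documented substrate range [7.6, 9.2]
    meqv/g protein unless ``allow_h_tot_out_of_range`` is set.
    """

    B: float | tuple[float, ...]
    Nb: float  # alkali normality, meqv per mL
    MP: float  # substrate protein mass, g
    inv_a: float = 1.50  # 1/a dissociation factor for pH 8.0 at 25 C
    H_tot: float = 8.0  # total peptide bonds, meqv per g protein
    allow_h_tot_out_of_range: bool = False

    def __post_init__(self) -> None:
        if _volume(self.B) < 0:
            raise InvalidInputError("alkali volume must be >= 0")
        if self.Nb <= 0 or self.MP <= 0 or self.inv_a <= 0 or self.H_tot <= 0:
            raise InvalidInputError("Nb, MP, inv_a and H_tot must be positive")
        lo, hi = H_TOT_RANGE
        if not self.allow_h_tot_out_of_range and not (lo <= self.H_tot <= hi):
            raise InvalidInputError(
                f"H_tot={self.H_tot} outside [{lo}, {hi}] meqv/g protein; "
                "set allow_h_tot_out_of_range=True to override"
            )


@dataclass(frozen=True)
class DigestibilityResult:
    """Phase-wise DH plus the DH value fed to the IPD prediction."""

    dh_stomach: float
    dh_intestine: float
    dh_reported: float
    ipd: float


def dh_stomach(t: StomachTitration) -> float:
    """Stomach-phase degree of hydrolysis (%)."""
    return (_volume(t.V) * t.N / t.E) * (1.0 / t.P) * t.F_pH * 100.0


def dh_intestine(t: IntestineTitration) -> float:
    """Intestinal-phase degree of hydrolysis (%)."""
    return _volume(t.B) * t.Nb * t.inv_a * (1.0 / t.MP) * (1.0 / t.H_tot) * 100.0


def predict_ipd(dh: float) -> float:
    """Predicted in-vitro protein digestibility (%) from DH (%)."""
    if dh < 0:
        raise InvalidInputError("DH must be >= 0")
    return IPD_SLOPE * dh + IPD_INTERCEPT


def titration_to_result(
    s: StomachTitration,
    i: IntestineTitration,
    reported: Literal["intestine", "stomach", "sum"] = "intestine",
) -> DigestibilityResult:
    """Evaluate both phases and predict IPD from the selected DH.

    ``reported`` picks which DH enters the IPD equation; the assay
    protocol the prediction was calibrated on uses the intestinal phase,
    hence the default.
    """
    ds = dh_stomach(s)
    di = dh_intestine(i)
    if reported == "intestine":
        dr = di
    elif reported == "stomach":
        dr = ds
    elif reported == "sum":
        dr = ds + di
    else:
        raise InvalidInputError(f"unknown reported selector {reported!r}")
    return DigestibilityResult(
        dh_stomach=ds, dh_intestine=di, dh_reported=dr, ipd=predict_ipd(dr)
    )
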