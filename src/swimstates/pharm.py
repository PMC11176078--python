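"""Bath-application dosage conversions.

Larval zebrafish drugs are dosed by bath concentration; comparing with
mammalian literature requires converting between mass concentration, molar
concentration, and the mg/kg equivalent of a bath concentration (assuming
equilibration with body water at 1 kg/L).
"""

from __future__ import annotations

__all__ = ["MOLECULAR_WEIGHT", "molarity_mM", "bath_dose_mg_per_kg"]

# g/mol
MOLECULAR_WEIGHT = {
    "psilocybin": 284.25,          # C12H17N2O4P
    "psilocin": 204.27,            # C12H16N2O
    "fluoxetine_hcl": 345.79,      # C17H18F3NO . HCl
    "fluvoxamine_maleate": 434.41,
    "ketamine_hcl": 274.19,
    "ketanserin": 395.43,
}


def molarity_mM(mg_per_ml: float, compound: str) -> float:
    """Molar concentration (mM) of a mass-concentration stock.

    mg/mL divided by the molecular weight (g/mol) gives mol/L; x1000 -> mM.
    E.g. a 1.0 mg/mL psilocybin stock is 3.52 mM.
    """
    return mg_per_ml / MOLECULAR_WEIGHT[compound] * 1000.0


def bath_dose_mg_per_kg(concentration_uM: float, compound: str) -> float:
    """mg/kg equivalent of a bath concentration in μM.

    μmol/L times g/mol gives μg/L = μg/kg of water; /1000 -> mg/kg.
    E.g. a 2.5 μM psilocybin bath corresponds to 0.71 mg/kg.
    """
    return concentration_uM * MOLECULAR_WEIGHT[compound] / 1000.0
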