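"""Published per-experiment efflux-ratio and abundance inputs, and literature
anchor constants used for scaling.

The per-experiment table holds the measured efflux ratios of four P-gp
substrate drugs — the corticosteroid epimers dexamethasone (DEX) and
betamethasone (BET) and the HIV protease inhibitors darunavir (DRV) and
lopinavir (LPV) — in hMDR1-MDCK (canine P-gp knockout) monolayers, without
(``er_minus``) and with (``er_plus``) the P-gp inhibitor tariquidar, together
with the P-gp abundance measured by targeted proteomics in the very cells of
each experiment (pmol per mg homogenate protein). These printed values are
the inputs of the ER-REF worked example and of the reproduction tests.
"""

from __future__ import annotations

import pandas as pd

from .refscale import AbundanceMeasurement

__all__ = [
    "published_efflux_table",
    "IN_VIVO_PGP_ABUNDANCE",
    "MDZ_CL_INT_PD_PLACENTA",
    "MDZ_PAPP",
    "PAPP_DRV",
    "PAPP_LPV",
    "Q_PLACENTAL_TERM",
    "Q_PLACENTAL_GW20",
    "GW20_PGP_ABUNDANCE_RATIO",
    "GW20_SURFACE_AREA_RATIO",
]

# (drug, experiment, ER without tariquidar, ER with tariquidar,
#  in vitro P-gp abundance pmol/mg homogenate protein)
_ROWS = [
    ("DEX", 1, 5.42, 0.85, 1.16),
    ("DEX", 2, 5.37, 1.04, 1.34),
    ("DEX", 3, 8.33, 1.35, 1.92),
    ("DEX", 4, 5.65, 0.90, 1.20),
    ("BET", 1, 6.56, 0.95, 1.16),
    ("BET", 2, 5.64, 1.07, 1.34),
    ("BET", 3, 8.64, 1.03, 1.92),
    ("BET", 4, 7.66, 0.92, 1.20),
    ("DRV", 1, 40.43, 0.82, 1.16),
    ("DRV", 2, 41.83, 1.48, 1.34),
    ("DRV", 3, 37.86, 1.12, 1.92),
    ("DRV", 4, 41.73, 1.06, 1.20),
    ("LPV", 1, 95.37, 1.02, 1.30),
    ("LPV", 2, 90.07, 1.29, 1.20),
    ("LPV", 3, 75.63, 1.64, 1.20),
    ("LPV", 4, 76.57, 1.30, 0.99),
]


def published_efflux_table(drug: str | None = None) -> pd.DataFrame:
    """Per-experiment ER and in vitro P-gp abundance table.

    Columns: drug, experiment, er_minus, er_plus, er_pgp
    (= er_minus - er_plus), in_vitro_abundance (pmol/mg homogenate protein).
    ``drug`` filters to one compound (DEX, BET, DRV or LPV).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["drug", "experiment", "er_minus", "er_plus", "in_vitro_abundance"],
    )
    df["er_pgp"] = df["er_minus"] - df["er_plus"]
    df = df[["drug", "experiment", "er_minus", "er_plus", "er_pgp", "in_vitro_abundance"]]
    if drug is not None:
        drug = drug.upper()
        if drug not in set(df["drug"]):
            raise KeyError(f"unknown drug {drug!r}; choose from DEX, BET, DRV, LPV")
        df = df[df["drug"] == drug].reset_index(drop=True)
    return df


#: P-gp abundance in term human placental homogenate (pmol/mg homogenate protein).
IN_VIVO_PGP_ABUNDANCE = AbundanceMeasurement(
    system="placenta_term", mean=0.16, sd=0.07, n=1, experiment_id="pooled"
)

#: Midazolam anchor for passive transplacental clearance scaling.
MDZ_CL_INT_PD_PLACENTA = 500.0  # l/h, in vivo
MDZ_PAPP = 4.9e-5  # cm/s, MDCKII/Caco-2

#: Monolayer apparent permeabilities used for passive-clearance scaling (cm/s).
PAPP_DRV = 1.19e-5
PAPP_LPV = 1.25e-5

#: Placental blood flow caps for perfusion-limited passive clearance (l/h).
Q_PLACENTAL_TERM = 45.0
Q_PLACENTAL_GW20 = 27.5

#: Total placental P-gp abundance at GW20 relative to term (40% lower).
GW20_PGP_ABUNDANCE_RATIO = 0.60

#: GW20/term placental surface-area ratio. Derived (not printed): back-
#: calculated from the published term -> GW20 passive-clearance pair
#: 121 -> 47 l/h; ships as an editable config default.
GW20_SURFACE_AREA_RATIO = 47.0 / 121.0
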