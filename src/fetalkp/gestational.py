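"""Gestational-age translation of placental clearances.

Placental passive diffusion clearance scales with the exchange surface area
of the placenta, while the P-gp efflux clearance scales with the *total*
placental transporter abundance (abundance per gram is higher earlier in
gestation, but the organ is much smaller). Passive clearance remains capped
by the gestational-age placental blood flow. Because the two clearances fall
by different factors, K_p,uu changes with gestational age even though it
depends only on their ratio (plus the flow caps).

The physiology vs gestational week ships as an editable table with two
anchor rows (term and GW20); intermediate ages are linearly interpolated and
ages outside [20, 40] weeks are refused (fetal physiologic parameters are
not reliably available earlier, and before ~GW13 the maternal-placental
circulation is not established).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import datasets
from .pbpk import (
    DoseRegimen,
    PbpkParameterSet,
    SimulationResult,
    effective_pd_clearance,
    kpuu_from_simulation,
    simulate,
)

__all__ = [
    "GestationalScalers",
    "GaProjection",
    "default_ga_table",
    "scalers_from_table",
    "scale_clpd",
    "scale_clpgp",
    "params_at_ga",
    "project_kpuu_at_ga",
]

GA_TABLE_COLUMNS = ["gw", "sa_ratio", "abundance_ratio", "q_mp_lph", "q_uv_lph", "v_fetal_l"]


@dataclass(frozen=True)
class GestationalScalers:
    """Scalers relating a gestational age to term placental physiology."""

    gw: float
    surface_area_ratio: float  # placental surface area / term
    total_pgp_abundance_ratio: float  # total placental P-gp abundance / term
    q_placenta_maternal: float  # l/h at this GA
    q_umbilical: float  # l/h at this GA

    def __post_init__(self) -> None:
        if self.surface_area_ratio <= 0 or self.total_pgp_abundance_ratio <= 0:
            raise ValueError("scaling ratios must be positive")
        if self.q_placenta_maternal < 0 or self.q_umbilical < 0:
            raise ValueError("flows must be nonnegative")


def default_ga_table() -> pd.DataFrame:
    """Anchor physiology rows: term (GW38) and GW20.

    The GW20 surface-area ratio is derived (back-calculated from the
    published 121 -> 47 l/h passive-clearance pair), not printed; the GW20
    abundance ratio (0.60) and flow cap (27.5 l/h) are published anchors.
    Umbilical flows and fetal volume are plumbing defaults (they do not move
    steady-state K_p,uu in this topology).
    """
    return pd.DataFrame(
        [
            [20.0, datasets.GW20_SURFACE_AREA_RATIO, datasets.GW20_PGP_ABUNDANCE_RATIO,
             datasets.Q_PLACENTAL_GW20, 7.0, 0.7],
            [38.0, 1.0, 1.0, datasets.Q_PLACENTAL_TERM, 21.0, 5.0],
        ],
        columns=GA_TABLE_COLUMNS,
    )


def scalers_from_table(gw: float, table: pd.DataFrame | None = None) -> GestationalScalers:
    """Linear interpolation of the GA table at ``gw`` (weeks).

    Raises outside [min GW in table, 40]; predictions there would be
    extrapolation beyond available fetal physiology.
    """
    table = default_ga_table() if table is None else table
    missing = [c for c in GA_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"GA table missing required columns: {missing}")
    table = table.sort_values("gw")
    lo, hi = float(table["gw"].min()), 40.0
    if not lo <= gw <= hi:
        raise ValueError(
            f"gestational week {gw} outside supported range [{lo}, {hi}] "
            "(fetal physiology not reliably available)"
        )
    gws = table["gw"].to_numpy(dtype=float)

    def interp(col: str) -> float:
        return float(np.interp(gw, gws, table[col].to_numpy(dtype=float)))

    return GestationalScalers(
        gw=gw,
        surface_area_ratio=interp("sa_ratio"),
        total_pgp_abundance_ratio=interp("abundance_ratio"),
        q_placenta_maternal=interp("q_mp_lph"),
        q_umbilical=interp("q_uv_lph"),
    )


def scale_clpd(term_cl_int_pd: float, scalers: GestationalScalers) -> tuple[float, float]:
    """(intrinsic, effective) passive clearance at the target GA.

    Intrinsic scales with placental surface area; effective is
    perfusion-limited by the GA maternal-placental flow.
    """
    if term_cl_int_pd <= 0:
        raise ValueError("term passive clearance must be positive")
    intrinsic = term_cl_int_pd * scalers.surface_area_ratio
    return intrinsic, effective_pd_clearance(intrinsic, scalers.q_placenta_maternal)


def scale_clpgp(term_cl_pm: float, scalers: GestationalScalers) -> float:
    """Efflux clearance at the target GA: term value scaled by the total
    placental P-gp abundance ratio."""
    if term_cl_pm < 0:
        raise ValueError("term efflux clearance must be nonnegative")
    return term_cl_pm * scalers.total_pgp_abundance_ratio


def params_at_ga(
    params_term: PbpkParameterSet,
    scalers: GestationalScalers,
    *,
    v_fetal: float | None = None,
) -> PbpkParameterSet:
    """Rebuild a term parameter set at the scalers' gestational age.

    Placental volume is scaled with the surface-area ratio (organ size);
    fetal volume comes from the GA table via ``v_fetal`` when provided.
    Maternal disposition is left untouched — gestational changes there enter
    through the user's own maternal configuration.
    """
    intrinsic, _ = scale_clpd(params_term.cl_int_pd_placenta, scalers)
    kwargs = dict(
        cl_int_pd_placenta=intrinsic,
        cl_pm=scale_clpgp(params_term.cl_pm, scalers),
        q_placenta_maternal=scalers.q_placenta_maternal,
        q_umbilical=scalers.q_umbilical,
        v_placenta=params_term.v_placenta * scalers.surface_area_ratio,
        gw=scalers.gw,
    )
    if v_fetal is not None:
        kwargs["v_fetal"] = v_fetal
    return params_term.replace(**kwargs)


@dataclass(frozen=True)
class GaProjection:
    """Simulation-backed K_p,uu projection at a gestational age."""

    scalers: GestationalScalers
    params: PbpkParameterSet
    sim: SimulationResult
    kpuu: float
    kpuu_term: float
    auc_maternal_ratio_vs_term: float
    auc_fetal_ratio_vs_term: float

    def summary(self) -> str:
        return "\n".join([
            f"K_p,uu projection at GW{self.scalers.gw:g}",
            "=" * 32,
            f"K_p,uu at GW{self.scalers.gw:g}:          {self.kpuu:.3f}",
            f"K_p,uu at term:           {self.kpuu_term:.3f}",
            f"ratio vs term:            {self.kpuu / self.kpuu_term:.2f}",
            f"maternal AUC / term:      {self.auc_maternal_ratio_vs_term:.2f}",
            f"fetal AUC / term:         {self.auc_fetal_ratio_vs_term:.2f}",
        ])


def project_kpuu_at_ga(
    params_term: PbpkParameterSet,
    regimen: DoseRegimen,
    scalers: GestationalScalers,
    *,
    v_fetal: float | None = None,
) -> GaProjection:
    """Scale a term parameter set to the target GA and simulate steady state.

    Returns the GA K_p,uu together with the GA-to-term ratios of maternal and
    fetal steady-state AUCs.
    """
    params_ga = params_at_ga(params_term, scalers, v_fetal=v_fetal)
    sim_term = simulate(params_term, regimen, from_steady_state=True)
    sim_ga = simulate(params_ga, regimen, from_steady_state=True)
    return GaProjection(
        scalers=scalers,
        params=params_ga,
        sim=sim_ga,
        kpuu=kpuu_from_simulation(sim_ga),
        kpuu_term=kpuu_from_simulation(sim_term),
        auc_maternal_ratio_vs_term=sim_ga.auc_maternal_ss / sim_term.auc_maternal_ss,
        auc_fetal_ratio_vs_term=sim_ga.auc_fetal_ss / sim_term.auc_fetal_ss,
    )
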