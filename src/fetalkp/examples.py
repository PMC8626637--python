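"""Example maternal-fetal parameter sets and dose regimens.

These are illustrative, literature-flavoured configurations for a
darunavir-like (DRV), lopinavir-like (LPV) and dexamethasone-like (DEX) drug
at term (GW38) — starting points for simulation and synthetic-data
generation, not fitted to any clinical dataset. Maternal disposition
(volume, clearance, absorption) enters this package purely as configuration;
the placental-fetal unit carries the science.

The passive transplacental clearances come from the midazolam anchor scaling
(500 l/h at P_app 4.9e-5 cm/s) and are perfusion-limited at the term
placental flow of ~45 l/h. The efflux clearance defaults are chosen so the
closed-form steady-state K_p,uu matches the ER-REF point predictions of the
corresponding drug (0.16 DRV-like, 0.08 LPV-like, 0.63 DEX-like); on this
lumped topology K_p,uu = CL_mp/(CL_mp + CL_PM), so CL_PM = CL_mp*(1/K-1).
"""

from __future__ import annotations

from . import datasets
from .pbpk import DoseRegimen, PbpkParameterSet, effective_pd_clearance, scale_passive_from_reference

__all__ = ["example_parameter_set", "example_regimen"]


def _clpm_for_kpuu(kpuu: float, cl_mp_eff: float) -> float:
    return cl_mp_eff * (1.0 / kpuu - 1.0)


def example_parameter_set(drug: str = "DRV", gw: float = 38.0) -> PbpkParameterSet:
    """Example :class:`PbpkParameterSet` for ``drug`` in {DRV, LPV, DEX} at term.

    Gestational ages other than term are produced by
    :func:`fetalkp.gestational.params_at_ga`, not here.
    """
    drug = drug.upper()
    common = dict(
        q_placenta_maternal=datasets.Q_PLACENTAL_TERM,
        q_umbilical=21.0,  # term umbilical blood flow, l/h
        v_placenta=0.6,
        v_fetal=5.0,
        induction_scalar=1.0,  # pregnancy effects folded into cl_maternal
        fetal_cl=0.0,
        gw=gw,
    )
    if drug == "DRV":
        cl_pd = scale_passive_from_reference(
            datasets.MDZ_CL_INT_PD_PLACENTA, datasets.PAPP_DRV, datasets.MDZ_PAPP
        )  # 121 l/h
        cl_mp = effective_pd_clearance(cl_pd, datasets.Q_PLACENTAL_TERM)
        return PbpkParameterSet(
            ka=0.4, tlag=1.3, f_oral=0.8, v_maternal=97.0, cl_maternal=10.0,
            fu_m=0.11, fu_f=0.15, cl_int_pd_placenta=cl_pd,
            cl_pm=_clpm_for_kpuu(0.16, cl_mp), **common,
        )
    if drug == "LPV":
        cl_pd = scale_passive_from_reference(
            datasets.MDZ_CL_INT_PD_PLACENTA, datasets.PAPP_LPV, datasets.MDZ_PAPP
        )  # 127.6 l/h
        cl_mp = effective_pd_clearance(cl_pd, datasets.Q_PLACENTAL_TERM)
        return PbpkParameterSet(
            ka=0.6, tlag=1.5, f_oral=0.7, v_maternal=80.0, cl_maternal=6.0,
            fu_m=0.02, fu_f=0.03, cl_int_pd_placenta=cl_pd,
            cl_pm=_clpm_for_kpuu(0.08, cl_mp), **common,
        )
    if drug == "DEX":
        cl_pd = 100.0  # moderately permeable corticosteroid, perfusion-limited at term
        cl_mp = effective_pd_clearance(cl_pd, datasets.Q_PLACENTAL_TERM)
        return PbpkParameterSet(
            ka=1.0, tlag=0.3, f_oral=0.8, v_maternal=70.0, cl_maternal=15.0,
            fu_m=0.3, fu_f=0.35, cl_int_pd_placenta=cl_pd,
            cl_pm=_clpm_for_kpuu(0.63, cl_mp), **common,
        )
    raise KeyError(f"no example parameter set for {drug!r}; choose DRV, LPV or DEX")


def example_regimen(drug: str = "DRV") -> DoseRegimen:
    """Example multiple-dose oral regimen (steady state by dose 16)."""
    drug = drug.upper()
    if drug == "DRV":
        return DoseRegimen(dose_mg=600.0, interval_h=12.0, n_doses=16)
    if drug == "LPV":
        return DoseRegimen(dose_mg=400.0, interval_h=12.0, n_doses=16)
    if drug == "DEX":
        return DoseRegimen(dose_mg=6.0, interval_h=12.0, n_doses=16)
    raise KeyError(f"no example regimen for {drug!r}; choose DRV, LPV or DEX")
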