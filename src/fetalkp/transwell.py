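"""Reduction of Transwell bidirectional transport assays to apparent
permeabilities and efflux ratios.

A polarized cell monolayer grown on a permeable insert separates an apical
(A) and a basal (B) chamber. A drug dosed on one side (donor) appears on the
other (receiver) over time; the apparent permeability

    P_app = cA_R(T) / (AUC_D(0..T) * area)

uses the cumulative receiver amount, corrected for the aliquots withdrawn at
each sampling time (withdrawals are replaced with blank buffer, so withdrawn
mass must be added back), and the donor concentration AUC rather than the
time-zero donor concentration, which corrects for donor depletion during the
experiment. The efflux ratio ER = P_app(B->A) / P_app(A->B) exceeds 1 for
substrates of apically localized efflux transporters such as P-glycoprotein,
and the transporter-attributable component is the difference of ER measured
without and with a specific inhibitor (tariquidar for P-gp).

Internal units: minutes, uM, ml, cm2. Conversion to cm/s happens only at the
P_app boundary (1 uM*ml / (uM*min*cm2) = 1 ml/(min*cm2) -> /60 cm/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LY_PAPP_THRESHOLD",
    "CONTROL_ER_THRESHOLD",
    "ReceiverSample",
    "DonorSample",
    "TranswellExperiment",
    "EffluxRatioResult",
    "PgpEffluxRatio",
    "QcResult",
    "cumulative_receiver_amount",
    "donor_auc",
    "apparent_permeability",
    "papp_from_experiment",
    "efflux_ratio",
    "pgp_mediated_er",
    "qc_gate",
]

#: Tight-junction integrity gate: Lucifer yellow P_app must stay below this (cm/s).
LY_PAPP_THRESHOLD = 2e-6
#: Transporter-activity gate: positive-control (quinidine/prazosin) ER must exceed this.
CONTROL_ER_THRESHOLD = 7.0

Direction = Literal["A2B", "B2A"]
Inhibitor = Literal["none", "pgp_inhibitor", "bcrp_inhibitor"]


class DataQualityError(ValueError):
    """Raised when raw plate measurements violate basic physical constraints."""


@dataclass(frozen=True)
class ReceiverSample:
    time_min: float
    conc_uM: float
    sampled_volume_ml: float
    replaced_with_blank: bool = True


@dataclass(frozen=True)
class DonorSample:
    time_min: float
    conc_uM: float
    sampled_volume_ml: float = 0.010


@dataclass
class TranswellExperiment:
    """One directional Transwell run (possibly well-averaged triplicate).

    ``donor_volume_ml``/``receiver_volume_ml`` follow the run direction: for
    A2B the donor is the apical chamber (0.5 ml default) and the receiver the
    basal chamber (1 ml), reversed for B2A.
    """

    drug_id: str
    direction: Direction
    receiver_samples: Sequence[ReceiverSample]
    donor_samples: Sequence[DonorSample]
    inhibitor: Inhibitor = "none"
    insert_area_cm2: float = 1.12
    donor_volume_ml: float | None = None
    receiver_volume_ml: float | None = None
    ly_papp: float | None = None
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("A2B", "B2A"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.inhibitor not in ("none", "pgp_inhibitor", "bcrp_inhibitor"):
            raise ValueError(f"unknown inhibitor state {self.inhibitor!r}")
        if self.donor_volume_ml is None:
            self.donor_volume_ml = 0.5 if self.direction == "A2B" else 1.0
        if self.receiver_volume_ml is None:
            self.receiver_volume_ml = 1.0 if self.direction == "A2B" else 0.5
        if self.insert_area_cm2 <= 0:
            raise ValueError("insert area must be positive")
        for name, series in (("receiver", self.receiver_samples), ("donor", self.donor_samples)):
            times = [s.time_min for s in series]
            if any(t < 0 for t in times):
                raise DataQualityError(f"{name} sample times must be nonnegative")
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise DataQualityError(f"{name} sample times must be strictly increasing")
            for s in series:
                if s.conc_uM < 0:
                    raise DataQualityError(
                        f"negative {name} concentration {s.conc_uM} at t={s.time_min} min"
                    )
        if self.donor_samples and self.donor_samples[0].time_min != 0:
            raise DataQualityError("first donor sample must be at time 0")
        for s in self.receiver_samples:
            if s.sampled_volume_ml < 0 or s.sampled_volume_ml >= self.receiver_volume_ml:
                raise DataQualityError("receiver sampled volume must be in [0, receiver volume)")
        for s in self.donor_samples:
            if s.sampled_volume_ml < 0 or s.sampled_volume_ml >= self.donor_volume_ml:
                raise DataQualityError("donor sampled volume must be in [0, donor volume)")


@dataclass(frozen=True)
class EffluxRatioResult:
    drug_id: str
    inhibitor: Inhibitor
    papp_a2b: float  # cm/s
    papp_b2a: float  # cm/s
    er: float
    qc_ly_pass: bool | None
    qc_control_pass: bool | None
    n_timepoints_used: int


@dataclass(frozen=True)
class PgpEffluxRatio:
    er_without_inhibitor: float
    er_with_inhibitor: float
    er_pgp: float
    negative_flagged: bool = False


@dataclass(frozen=True)
class QcResult:
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def cumulative_receiver_amount(
    samples: Sequence[ReceiverSample], receiver_volume_ml: float
) -> np.ndarray:
    """Cumulative receiver amount (uM*ml = nmol) at each sampling time.

    Each withdrawal removes ``sampled_volume * C`` of mass and is replaced
    with blank buffer, so the cumulative amount at sample k adds back all
    previously withdrawn aliquots:

        cA_k = V_R * C_k + sum_{j<k} v_j * C_j
    """
    if receiver_volume_ml <= 0:
        raise ValueError("receiver volume must be positive")
    conc = np.array([s.conc_uM for s in samples], dtype=float)
    vols = np.array([s.sampled_volume_ml for s in samples], dtype=float)
    if (conc < 0).any():
        raise DataQualityError("negative receiver concentration")
    if (vols >= receiver_volume_ml).any():
        raise DataQualityError("sampled volume must be smaller than the receiver volume")
    withdrawn = np.concatenate([[0.0], np.cumsum(vols * conc)[:-1]])
    return receiver_volume_ml * conc + withdrawn


def donor_auc(
    samples: Sequence[DonorSample],
    t_end_min: float,
    *,
    allow_constant_donor: bool = False,
) -> float:
    """Linear-trapezoid AUC (uM*min) of the donor concentration over [0, t_end].

    With the standard protocol there are exactly two donor samples (t = 0 and
    the end of the run); intermediate samples, if present, are used. A single
    donor sample is only accepted when ``allow_constant_donor`` is set, in
    which case the donor is treated as constant (no depletion correction).
    """
    if t_end_min <= 0:
        raise ValueError("t_end must be positive")
    inside = [s for s in samples if s.time_min <= t_end_min + 1e-9]
    if len(inside) < 2:
        if len(inside) == 1 and allow_constant_donor:
            return inside[0].conc_uM * t_end_min
        raise ValueError(
            "need >= 2 donor samples spanning [0, t_end]; for a single sample, "
            "explicitly enable the constant-donor fallback (allow_constant_donor=True)"
        )
    t = np.array([s.time_min for s in inside], dtype=float)
    c = np.array([s.conc_uM for s in inside], dtype=float)
    if (c < 0).any():
        raise DataQualityError("negative donor concentration")
    if t[-1] < t_end_min - 1e-9:
        # extend flat from the last sample to t_end (sample taken slightly early)
        t = np.append(t, t_end_min)
        c = np.append(c, c[-1])
    return float(np.trapezoid(c, t))


def apparent_permeability(
    cum_amount_final: float, donor_auc_value: float, area_cm2: float
) -> float:
    """P_app (cm/s) from final cumulative receiver amount and donor AUC.

    P_app = cA(T) / (AUC_D * area); with cA in uM*ml and AUC in uM*min the
    quotient is ml/(min*cm2) = cm/min, divided by 60 to give cm/s. Equals the
    classic slope-based P_app when the donor is constant.
    """
    if donor_auc_value <= 0:
        raise ValueError("donor AUC must be positive")
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    if cum_amount_final < 0:
        raise ValueError("cumulative amount must be nonnegative")
    return cum_amount_final / (donor_auc_value * 60.0 * area_cm2)


def papp_from_experiment(
    exp: TranswellExperiment,
    *,
    method: Literal["cumulative", "slope"] = "cumulative",
    sampled_volume_correction: bool = True,
) -> float:
    """Reduce one directional run to P_app (cm/s).

    ``method='cumulative'`` (default) divides the final sampled-volume-
    corrected cumulative amount by the full-interval donor AUC. The
    ``'slope'`` alternative regresses cumulative amount on time and divides
    the slope by the time-averaged donor concentration — a linearity
    diagnostic, not the reporting path. Disabling
    ``sampled_volume_correction`` reproduces the naive (biased) estimator for
    comparison purposes.
    """
    if not exp.receiver_samples:
        raise ValueError("experiment has no receiver samples")
    t_end = exp.receiver_samples[-1].time_min
    if sampled_volume_correction:
        cum = cumulative_receiver_amount(exp.receiver_samples, exp.receiver_volume_ml)
    else:
        conc = np.array([s.conc_uM for s in exp.receiver_samples])
        cum = exp.receiver_volume_ml * conc
    auc = donor_auc(exp.donor_samples, t_end)
    if method == "cumulative":
        return apparent_permeability(float(cum[-1]), auc, exp.insert_area_cm2)
    if method == "slope":
        times = np.array([s.time_min for s in exp.receiver_samples], dtype=float)
        slope = float(np.polyfit(times, cum, 1)[0])  # uM*ml/min
        mean_donor = auc / t_end
        return slope / (mean_donor * 60.0 * exp.insert_area_cm2)
    raise ValueError(f"unknown method {method!r}")


def efflux_ratio(
    exp_a2b: TranswellExperiment,
    exp_b2a: TranswellExperiment,
    *,
    control_er: float | None = None,
    method: Literal["cumulative", "slope"] = "cumulative",
) -> EffluxRatioResult:
    """ER = P_app(B->A) / P_app(A->B) for one paired bidirectional experiment.

    Both runs must be the same drug in the same inhibitor state. QC flags are
    populated from the Lucifer yellow permeabilities attached to the runs and
    from ``control_er`` (the positive-control ER measured on the same plate),
    when available; a flag is None when the datum was not recorded.
    """
    if exp_a2b.drug_id != exp_b2a.drug_id:
        raise ValueError(f"drug mismatch: {exp_a2b.drug_id!r} vs {exp_b2a.drug_id!r}")
    if exp_a2b.inhibitor != exp_b2a.inhibitor:
        raise ValueError("inhibitor state mismatch between directions")
    if exp_a2b.direction != "A2B" or exp_b2a.direction != "B2A":
        raise ValueError("efflux_ratio expects one A2B and one B2A experiment, in that order")
    papp_ab = papp_from_experiment(exp_a2b, method=method)
    papp_ba = papp_from_experiment(exp_b2a, method=method)
    if papp_ab <= 0:
        raise ValueError("P_app(A->B) is zero; ER undefined")
    ly_values = [p for p in (exp_a2b.ly_papp, exp_b2a.ly_papp) if p is not None]
    qc_ly = max(ly_values) < LY_PAPP_THRESHOLD if ly_values else None
    qc_control = control_er > CONTROL_ER_THRESHOLD if control_er is not None else None
    return EffluxRatioResult(
        drug_id=exp_a2b.drug_id,
        inhibitor=exp_a2b.inhibitor,
        papp_a2b=papp_ab,
        papp_b2a=papp_ba,
        er=papp_ba / papp_ab,
        qc_ly_pass=qc_ly,
        qc_control_pass=qc_control,
        n_timepoints_used=min(len(exp_a2b.receiver_samples), len(exp_b2a.receiver_samples)),
    )


def pgp_mediated_er(er_no_inhibitor: float, er_inhibitor: float) -> PgpEffluxRatio:
    """Inhibitor-sensitive ER component: ER(-inhibitor) - ER(+inhibitor).

    May be near zero for non-substrates; negative values (sampling noise) are
    allowed but flagged.
    """
    if er_no_inhibitor <= 0 or er_inhibitor <= 0:
        raise ValueError("efflux ratios must be positive")
    diff = er_no_inhibitor - er_inhibitor
    return PgpEffluxRatio(er_no_inhibitor, er_inhibitor, diff, negative_flagged=diff < 0)


def qc_gate(ly_papp: float | None, control_er: float | None) -> QcResult:
    """Experiment-level QC: leaky monolayers and weak transporter activity fail.

    Fails when the Lucifer yellow P_app is at/above 2e-6 cm/s (compromised
    tight junctions) or the positive-control ER is at/below 7 (insufficient
    transporter activity). A missing datum does not fail the gate.
    """
    reasons: list[str] = []
    if ly_papp is not None and ly_papp >= LY_PAPP_THRESHOLD:
        reasons.append(
            f"leaky monolayer: LY P_app {ly_papp:.2e} cm/s >= {LY_PAPP_THRESHOLD:.0e} cm/s"
        )
    if control_er is not None and control_er <= CONTROL_ER_THRESHOLD:
        reasons.append(
            f"weak transporter activity: control ER {control_er:.2f} <= {CONTROL_ER_THRESHOLD:g}"
        )
    return QcResult(passed=not reasons, reasons=tuple(reasons))
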