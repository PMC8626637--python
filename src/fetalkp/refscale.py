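"""ER-REF scaling: from P-gp-mediated efflux ratios and proteomic abundances
to predicted in vivo fetal K_p,uu.

The unbound fetal-to-maternal partition coefficient of a drug whose only
active placental process is apical (fetal-to-maternal) efflux is

    K_p,uu = CL_PD / (CL_PD + CL_efflux) = 1 / (1 + REF * ER_P-gp)

where ER_P-gp is the inhibitor-sensitive component of the in vitro efflux
ratio and REF (relative expression factor) = in vivo transporter abundance /
in vitro cell-line abundance, both per mg total homogenate protein, converts
cell-line transport activity to tissue. A non-substrate has ER_P-gp = 0 and
K_p,uu = 1; the fraction of transplacental flux attributable to the
transporter is f_t = 1 - K_p,uu.

``ErRefModel`` is the statsmodels-style front end: construct from a
per-experiment table plus the in vivo abundance, ``fit()`` returns
``ErRefResults`` with per-experiment predictions, the pooled point estimate,
a seeded Monte-Carlo CI90 and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbundanceMeasurement",
    "RefEstimate",
    "KpuuPrediction",
    "compute_ref",
    "predict_kpuu",
    "er_from_kpuu",
    "kpuu_ci_montecarlo",
    "summarize_prediction",
    "ErRefModel",
    "ErRefResults",
]


@dataclass(frozen=True)
class AbundanceMeasurement:
    """Transporter abundance, pmol per mg total homogenate protein."""

    system: Literal["cell_line", "placenta_term", "placenta_ga"]
    mean: float
    sd: float = 0.0
    n: int = 1
    experiment_id: str | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("abundance mean must be positive")
        if self.sd < 0:
            raise ValueError("abundance sd must be nonnegative")


@dataclass(frozen=True)
class RefEstimate:
    ref: float
    in_vivo_abundance: float
    in_vitro_abundance: float


@dataclass(frozen=True)
class KpuuPrediction:
    kpuu_point: float
    ci90_low: float | None
    ci90_high: float | None
    ft_pgp: float
    per_experiment_kpuu: tuple[float, ...]
    seed: int | None = None


def compute_ref(
    in_vivo: AbundanceMeasurement | float, in_vitro: AbundanceMeasurement | float
) -> RefEstimate:
    """REF = in vivo abundance / in vitro abundance (dimensionless)."""
    vivo = in_vivo.mean if isinstance(in_vivo, AbundanceMeasurement) else float(in_vivo)
    vitro = in_vitro.mean if isinstance(in_vitro, AbundanceMeasurement) else float(in_vitro)
    if vivo <= 0 or vitro <= 0:
        raise ValueError("abundances must be positive")
    return RefEstimate(ref=vivo / vitro, in_vivo_abundance=vivo, in_vitro_abundance=vitro)


def predict_kpuu(
    ref: RefEstimate | float,
    er_pgp: float,
    *,
    negative_er: Literal["clamp", "raise"] = "clamp",
) -> float:
    """K_p,uu = 1 / (1 + REF * ER_P-gp), in (0, 1].

    A negative ER_P-gp (noise around zero for a non-substrate) is clamped to
    0 by default, yielding K_p,uu = 1; strict mode raises instead.
    """
    r = ref.ref if isinstance(ref, RefEstimate) else float(ref)
    if r <= 0:
        raise ValueError("REF must be positive")
    if er_pgp < 0:
        if negative_er == "raise":
            raise ValueError(f"negative ER_P-gp ({er_pgp}); non-substrate?")
        er_pgp = 0.0
    return 1.0 / (1.0 + r * er_pgp)


def er_from_kpuu(kpuu: float, ref: RefEstimate | float) -> float:
    """Inverse of :func:`predict_kpuu`: ER_P-gp = (1/K_p,uu - 1) / REF."""
    r = ref.ref if isinstance(ref, RefEstimate) else float(ref)
    if not 0 < kpuu <= 1:
        raise ValueError("kpuu must be in (0, 1]")
    return (1.0 / kpuu - 1.0) / r


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, mean)
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def kpuu_ci_montecarlo(
    er_mean: float,
    er_sd: float,
    invitro_mean: float,
    invitro_sd: float,
    invivo_mean: float,
    invivo_sd: float,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded Monte-Carlo CI90 (5th/95th percentiles) of the predicted K_p,uu.

    Pooled-variance propagation: ER_P-gp is drawn from a normal truncated at
    0, both abundances from normals truncated at a small positive floor, the
    three sources treated as independent; K_p,uu is evaluated per draw. All
    sds zero degenerates to the point estimate.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 1e4 for stable percentiles")
    if min(er_sd, invitro_sd, invivo_sd) < 0:
        raise ValueError("sds must be nonnegative")
    rng = np.random.default_rng(seed)
    floor = 1e-6
    er = _truncated_normal(rng, er_mean, er_sd, 0.0, n_draws)
    vitro = _truncated_normal(rng, invitro_mean, invitro_sd, floor, n_draws)
    vivo = _truncated_normal(rng, invivo_mean, invivo_sd, floor, n_draws)
    kpuu = 1.0 / (1.0 + (vivo / vitro) * er)
    low, high = np.percentile(kpuu, [5.0, 95.0])
    return float(low), float(high)


def summarize_prediction(
    per_experiment: Sequence[tuple[float, float]],
    in_vivo: AbundanceMeasurement,
    *,
    n_draws: int = 100_000,
    seed: int | None = None,
) -> KpuuPrediction:
    """Pool per-experiment (ER_P-gp, in vitro abundance) pairs into one prediction.

    Each experiment's ER is matched with that experiment's own measured cell
    abundance; the point estimate is the arithmetic mean of the per-experiment
    K_p,uu values. With >= 2 experiments a Monte-Carlo CI90 is attached,
    propagating the experiment-to-experiment spread of ER and in vitro
    abundance together with the in vivo abundance uncertainty.
    """
    if not per_experiment:
        raise ValueError("need at least one experiment")
    ers = np.array([e for e, _ in per_experiment], dtype=float)
    abunds = np.array([a for _, a in per_experiment], dtype=float)
    per_kpuu = tuple(
        predict_kpuu(compute_ref(in_vivo, a), e) for e, a in zip(ers, abunds)
    )
    point = float(np.mean(per_kpuu))
    if len(per_experiment) >= 2:
        low, high = kpuu_ci_montecarlo(
            float(ers.mean()),
            float(ers.std(ddof=1)),
            float(abunds.mean()),
            float(abunds.std(ddof=1)),
            in_vivo.mean,
            in_vivo.sd,
            n_draws=n_draws,
            seed=seed,
        )
    else:
        low = high = None
    return KpuuPrediction(
        kpuu_point=point,
        ci90_low=low,
        ci90_high=high,
        ft_pgp=1.0 - point,
        per_experiment_kpuu=per_kpuu,
        seed=seed,
    )


class ErRefModel:
    """ER-REF prediction of fetal K_p,uu from a per-experiment table.

    Parameters
    ----------
    per_experiment
        DataFrame with one row per independent Transwell experiment and
        columns ``er_pgp`` (or ``er_minus``/``er_plus``, from which it is
        derived) and ``in_vitro_abundance`` (pmol/mg homogenate protein).
    in_vivo
        Placental P-gp abundance measurement to scale against.
    """

    def __init__(self, per_experiment: pd.DataFrame, in_vivo: AbundanceMeasurement):
        df = per_experiment.copy()
        if "er_pgp" not in df.columns:
            if {"er_minus", "er_plus"} <= set(df.columns):
                df["er_pgp"] = df["er_minus"] - df["er_plus"]
            else:
                raise ValueError(
                    "per_experiment needs 'er_pgp' or both 'er_minus' and 'er_plus'"
                )
        if "in_vitro_abundance" not in df.columns:
            raise ValueError("per_experiment needs an 'in_vitro_abundance' column")
        if (df["in_vitro_abundance"] <= 0).any():
            raise ValueError("in vitro abundances must be positive")
        self.data = df
        self.in_vivo = in_vivo

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, in_vivo: AbundanceMeasurement
    ) -> "ErRefModel":
        return cls(df, in_vivo)

    def fit(self, *, n_draws: int = 100_000, seed: int | None = None) -> "ErRefResults":
        df = self.data
        refs = [compute_ref(self.in_vivo, a) for a in df["in_vitro_abundance"]]
        kpuus = [predict_kpuu(r, e) for r, e in zip(refs, df["er_pgp"])]
        table = df.copy()
        table["ref"] = [r.ref for r in refs]
        table["kpuu"] = kpuus
        pred = summarize_prediction(
            list(zip(df["er_pgp"], df["in_vitro_abundance"])),
            self.in_vivo,
            n_draws=n_draws,
            seed=seed,
        )
        # alternative pooled estimator: K_p,uu of (mean ER x REF of mean abundance)
        pooled = predict_kpuu(
            compute_ref(self.in_vivo, float(df["in_vitro_abundance"].mean())),
            float(df["er_pgp"].mean()),
        )
        return ErRefResults(model=self, per_experiment=table, prediction=pred,
                            point_kpuu_pooled=pooled)


@dataclass(frozen=True)
class ErRefResults:
    """Fitted ER-REF prediction: per-experiment detail plus pooled estimates.

    ``point_kpuu`` is the mean of per-experiment K_p,uu values (the reporting
    default); ``point_kpuu_pooled`` applies the scaling once to the mean ER
    and mean abundance — the two differ when ER and abundance co-vary across
    experiments, and both are reported.
    """

    model: ErRefModel
    per_experiment: pd.DataFrame
    prediction: KpuuPrediction
    point_kpuu_pooled: float

    @property
    def point_kpuu(self) -> float:
        return self.prediction.kpuu_point

    @property
    def ft_pgp(self) -> float:
        return self.prediction.ft_pgp

    @property
    def ci90(self) -> tuple[float | None, float | None]:
        return self.prediction.ci90_low, self.prediction.ci90_high

    def summary(self) -> str:
        p = self.prediction
        lines = ["ER-REF fetal K_p,uu prediction", "=" * 34]
        cols = [c for c in ("drug", "experiment", "er_pgp", "in_vitro_abundance", "ref", "kpuu")
                if c in self.per_experiment.columns]
        lines.append(self.per_experiment[cols].to_string(index=False,
                                                         float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(f"in vivo abundance [pmol/mg HP]: "
                     f"{self.model.in_vivo.mean:.3g} +/- {self.model.in_vivo.sd:.3g}")
        lines.append(f"K_p,uu (mean of experiments):   {p.kpuu_point:.3f}")
        lines.append(f"K_p,uu (pooled ER x REF):       {self.point_kpuu_pooled:.3f}")
        if p.ci90_low is not None:
            lines.append(f"CI90 (Monte-Carlo, seed={p.seed}):  "
                         f"({p.ci90_low:.3f}, {p.ci90_high:.3f})")
        lines.append(f"f_t,P-gp = 1 - K_p,uu:          {p.ft_pgp:.3f}")
        return "\n".join(lines)
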