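"""Homeostasis-perturbation model of post-stroke blood pressure.

Systolic BP is a homeostatic baseline ``SBP_H`` perturbed by (a) a spontaneous
post-stroke deviation that decays geometrically, ``P_spon(t) = B_max (1-r_B)^t``,
and (b) a saturating (Hill / E_max) effect per antihypertensive drug,
``P_med(t) = E_max c(t) / (EC50 + c(t))``:

    SBP(t) = SBP_H + P_spon(t) + sum_drugs P_med(t)
    DBP(t) = DBP_H + ratio_SD * (P_spon(t) + sum_drugs P_med(t))

``t`` counts discrete charting steps (15 min by default) starting at 0, so
``r_B`` is a per-step decay rate.  Perturbations may be positive or negative
(post-shock recovery is a negative ``B_max``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .pk import ConcentrationSeries

__all__ = [
    "DrugEffect",
    "PerturbationParams",
    "p_spon",
    "p_med",
    "total_perturbation",
    "track",
    "emax_ratio",
]


@dataclass(frozen=True)
class DrugEffect:
    """Pharmacodynamic (E_max model) parameters of one drug.

    ``e_max`` is the maximal BP effect in mmHg (negative for an
    antihypertensive); ``ec50`` the plasma concentration (ng/mL, > 0) at
    half-maximal effect.
    """

    name: str
    e_max: float
    ec50: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"EC50 must be > 0 ng/mL, got {self.ec50}")


@dataclass(frozen=True)
class PerturbationParams:
    """Clinically interpretable parameter set of the perturbation model."""

    sbp_h: float
    dbp_h: float
    b_max: float
    r_b: float
    ratio_sd: float
    drugs: tuple[DrugEffect, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_b <= 1.0:
            raise ValueError(f"r_B must lie in [0, 1], got {self.r_b}")
        if self.sbp_h <= self.dbp_h:
            raise ValueError(
                f"SBP_H ({self.sbp_h}) must exceed DBP_H ({self.dbp_h})"
            )

    def drug(self, name: str) -> DrugEffect:
        for d in self.drugs:
            if d.name == name:
                return d
        raise KeyError(name)

    # flat-JSON serialization shared by both estimators and the simulator
    def to_dict(self) -> dict:
        out = {
            "sbp_h": self.sbp_h,
            "dbp_h": self.dbp_h,
            "b_max": self.b_max,
            "r_b": self.r_b,
            "ratio_sd": self.ratio_sd,
        }
        for d in self.drugs:
            out[f"{d.name}_emax"] = d.e_max
            out[f"{d.name}_ec50"] = d.ec50
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "PerturbationParams":
        names = sorted({k[:-5] for k in data if k.endswith("_emax")})
        drugs = tuple(
            DrugEffect(n, float(data[f"{n}_emax"]), float(data[f"{n}_ec50"]))
            for n in names
        )
        return cls(
            sbp_h=float(data["sbp_h"]),
            dbp_h=float(data["dbp_h"]),
            b_max=float(data["b_max"]),
            r_b=float(data["r_b"]),
            ratio_sd=float(data["ratio_sd"]),
            drugs=drugs,
        )

    @classmethod
    def from_json(cls, text: str) -> "PerturbationParams":
        return cls.from_dict(json.loads(text))


def p_spon(t, b_max: float, r_b: float):
    """Spontaneous post-stroke perturbation ``B_max (1 - r_B)^t`` at step(s) t."""
    if not 0.0 <= r_b <= 1.0:
        raise ValueError(f"r_B must lie in [0, 1], got {r_b}")
    t_arr = np.asarray(t)
    return b_max * (1.0 - r_b) ** t_arr


def p_med(c, e_max: float, ec50: float):
    """E_max (Hill) drug effect ``E_max c / (EC50 + c)``; bounded by |E_max|."""
    if ec50 <= 0:
        raise ValueError(f"EC50 must be > 0, got {ec50}")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be non-negative")
    return e_max * c_arr / (ec50 + c_arr)


def total_perturbation(
    params: PerturbationParams,
    conc: Mapping[str, ConcentrationSeries],
    n_steps: int,
) -> np.ndarray:
    """Systolic-side perturbation ``P_spon(t) + sum_drugs P_med(t)`` for t=0..n_steps-1."""
    t = np.arange(n_steps)
    s = np.asarray(p_spon(t, params.b_max, params.r_b), dtype=float)
    for d in params.drugs:
        if d.name not in conc:
            raise KeyError(f"no concentration track for declared drug {d.name!r}")
        c = conc[d.name].values
        if c.shape[0] != n_steps:
            raise ValueError(f"concentration track for {d.name!r} has wrong length")
        s = s + p_med(c, d.e_max, d.ec50)
    return s


def track(
    params: PerturbationParams,
    conc: Mapping[str, ConcentrationSeries],
    n_steps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (SBP, DBP) series of the perturbation model over ``n_steps``."""
    s = total_perturbation(params, conc, n_steps)
    sbp = params.sbp_h + s
    dbp = params.dbp_h + params.ratio_sd * s
    return sbp, dbp


def emax_ratio(e_max: float, ec50: float, mean_c: float) -> float:
    """Aggregate drug-effectiveness metric ``E_max / (EC50 + mean_c)``.

    ``mean_c`` is the mean concentration over the drug's active period.  The
    ratio is more stable across fits than E_max and EC50 individually when
    the dosing range under-explores the dose-response curve; a larger
    magnitude (more negative for antihypertensives) means a more effective
    drug.
    """
    denom = ec50 + mean_c
    if denom <= 0:
        raise ValueError(f"EC50 + mean concentration must be > 0, got {denom}")
    return e_max / denom
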