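"""Nonlinear least-squares comparator for the perturbation model.

Fits the systolic equation ``SBP(t) = SBP_H + B_max (1-r_B)^t +
sum_d E_max_d c_d(t) / (EC50_d + c_d(t))`` to an observed SBP series by
Levenberg-Marquardt.  Parameters are unbounded by default, mirroring the
classical maximum-likelihood treatment of E_max dose-response fits (and
permitting the characteristic EC50 instability when dosing under-explores
the response curve); a bounded trust-region mode is available behind a
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import least_squares

from .perturbation import DrugEffect, PerturbationParams
from .pk import ConcentrationSeries

__all__ = ["NLLSConfig", "NLLSResult", "fit_nlls"]

_DEFAULT_EC50_INIT = {"labetalol": 100.0, "nicardipine": 50.0}


@dataclass(frozen=True)
class NLLSConfig:
    """Initialization and solver settings.

    Defaults: ``SBP_H`` starts at the mean of the last 12 h of SBP,
    ``B_max`` at (first SBP - SBP_H), ``r_B`` at 0.05/step, ``E_max`` at
    -20 mmHg and ``EC50`` at a drug-specific plausible median.
    """

    r_b_init: float = 0.05
    emax_init: float = -20.0
    ec50_init: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_EC50_INIT))
    sbp_h_init: float | None = None        # override the data-driven default
    last_hours: float = 12.0               # window for the SBP_H default
    max_nfev: int | None = None
    xtol: float = 1e-10
    multi_start: int = 0                   # extra jittered starts; best kept
    bounded: bool = False                  # trust-region with sign bounds
    # identifiability screen: an EC50 fitted beyond this multiple of the
    # maximum achieved concentration (or an implausibly large |E_max|) marks
    # the fit as diverged along the unidentifiable E_max/EC50 ridge
    ec50_identifiable_factor: float = 2.0
    emax_plausible: float = 500.0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.ec50_init.values()):
            raise ValueError("initial EC50 must be > 0")


@dataclass
class NLLSResult:
    estimates: dict[str, float]
    cost: float                       # 0.5 * sum of squared residuals
    success: bool
    flags: list[str]
    n_eval: int

    @property
    def params(self) -> PerturbationParams:
        """SBP-side estimates packaged as perturbation parameters.

        DBP-side quantities are not fitted; ``dbp_h``/``ratio_sd`` are
        placeholders (SBP_H - 40, 0) so the object remains constructible.
        """
        e = self.estimates
        names = sorted(k[:-5] for k in e if k.endswith("_emax"))
        drugs = tuple(
            DrugEffect(n, e[f"{n}_emax"], max(abs(e[f"{n}_ec50"]), 1e-9))
            for n in names
        )
        return PerturbationParams(
            e["sbp_h"], e["sbp_h"] - 40.0, e["b_max"],
            min(max(e["r_b"], 0.0), 1.0), 0.0, drugs,
        )


def _model(theta: np.ndarray, t: np.ndarray, conc_cols: np.ndarray) -> np.ndarray:
    sbp_h, b_max, r_b = theta[:3]
    base = 1.0 - r_b
    # integer exponents keep negative bases legal for the unbounded search;
    # magnitudes are capped so a wild iterate cannot overflow to inf
    with np.errstate(over="ignore", invalid="ignore"):
        spon = b_max * np.power(base, t)
    spon = np.nan_to_num(spon, nan=0.0, posinf=1e12, neginf=-1e12)
    out = sbp_h + np.clip(spon, -1e12, 1e12)
    for j in range(conc_cols.shape[1]):
        e_max, ec50 = theta[3 + 2 * j], theta[4 + 2 * j]
        c = conc_cols[:, j]
        denom = ec50 + c
        with np.errstate(divide="ignore", invalid="ignore"):
            eff = e_max * c / denom
        out = out + np.clip(np.nan_to_num(eff, nan=0.0, posinf=1e12, neginf=-1e12),
                            -1e12, 1e12)
    return out


def fit_nlls(
    sbp: np.ndarray,
    conc: Mapping[str, ConcentrationSeries],
    config: NLLSConfig | None = None,
    dt: float = 15.0,
    rng: np.random.Generator | int | None = None,
) -> NLLSResult:
    """Levenberg-Marquardt fit of the systolic perturbation model.

    ``sbp`` is the observed systolic series on the uniform grid (NaNs are
    dropped); ``conc`` maps drug name to its concentration track on the
    same grid.  Returns point estimates for ``(SBP_H, B_max, r_B)`` and
    per-drug ``(E_max, EC50)``, the final cost, and quality flags
    (non-convergence, unidentifiable drugs with all-zero exposure).
    """
    config = config or NLLSConfig()
    sbp = np.asarray(sbp, dtype=float)
    t_all = np.arange(sbp.size)
    drug_names = sorted(conc)
    conc_cols = (
        np.column_stack([conc[n].values for n in drug_names])
        if drug_names else np.zeros((sbp.size, 0))
    )
    if any(conc[n].values.shape[0] != sbp.size for n in drug_names):
        raise ValueError("concentration tracks must match the SBP grid")

    ok = np.isfinite(sbp)
    if not ok.any():
        raise ValueError("no finite SBP observations")
    t, y, cols = t_all[ok], sbp[ok], conc_cols[ok]

    flags: list[str] = []
    for n in drug_names:
        if not np.any(conc[n].values > 0):
            flags.append(f"unidentifiable:{n}")

    n_last = max(1, int(round(config.last_hours * 60.0 / dt)))
    sbp_h0 = (config.sbp_h_init if config.sbp_h_init is not None
              else float(np.mean(y[-n_last:])))
    theta0 = [sbp_h0, float(y[0] - sbp_h0), config.r_b_init]
    for n in drug_names:
        theta0 += [config.emax_init,
                   config.ec50_init.get(n, 100.0)]
    theta0 = np.array(theta0)

    def residuals(theta: np.ndarray) -> np.ndarray:
        return _model(theta, t, cols) - y

    def solve(x0: np.ndarray):
        if config.bounded:
            lo = [-np.inf, -np.inf, 0.0] + [-np.inf, 1e-6] * len(drug_names)
            hi = [np.inf, np.inf, 1.0] + [0.0, np.inf] * len(drug_names)
            return least_squares(residuals, x0, bounds=(lo, hi),
                                 method="trf", xtol=config.xtol,
                                 max_nfev=config.max_nfev)
        return least_squares(residuals, x0, method="lm", xtol=config.xtol,
                             max_nfev=config.max_nfev)

    best = solve(theta0)
    if config.multi_start:
        rng = np.random.default_rng(rng)
        for _ in range(config.multi_start):
            jitter = theta0 * (1.0 + 0.2 * rng.standard_normal(theta0.size))
            jitter[2] = abs(jitter[2]) % 1.0
            try:
                cand = solve(jitter)
            except Exception:
                continue
            if cand.cost < best.cost:
                best = cand
    if not best.success:
        flags.append("non-convergence")

    est = {
        "sbp_h": float(best.x[0]),
        "b_max": float(best.x[1]),
        "r_b": float(best.x[2]),
    }
    # non-physical backbone (baseline outside any survivable BP, explosive
    # perturbation, or a decay rate off its unit support) marks the whole
    # fit as diverged
    if not (0.0 < est["sbp_h"] < 400.0 and abs(est["b_max"]) < 400.0
            and 0.0 <= est["r_b"] <= 1.0):
        flags.append("diverged:baseline")
    for j, n in enumerate(drug_names):
        e_max = float(best.x[3 + 2 * j])
        ec50 = float(best.x[4 + 2 * j])
        est[f"{n}_emax"] = e_max
        est[f"{n}_ec50"] = ec50
        c_max = float(conc[n].values.max())
        if c_max > 0 and (
            not 0.0 < ec50 <= config.ec50_identifiable_factor * c_max
            or abs(e_max) > config.emax_plausible
        ):
            # the iterate ran up the E_max/EC50 ridge beyond the exposure
            # the data explored: the pair is unidentifiable for this course
            flags.append(f"diverged:{n}")
    # aggregate effectiveness metric on the same concentration exposure
    from .pk import mean_active_concentration
    for n in drug_names:
        if np.any(conc[n].values > 0):
            mean_c = mean_active_concentration(conc[n])
            denom = est[f"{n}_ec50"] + mean_c
            if denom > 0:
                est[f"{n}_emax_ratio"] = est[f"{n}_emax"] / denom
            else:
                flags.append(f"emax_ratio_undefined:{n}")
    return NLLSResult(
        estimates=est,
        cost=float(best.cost),
        success=bool(best.success),
        flags=flags,
        n_eval=int(best.nfev),
    )
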