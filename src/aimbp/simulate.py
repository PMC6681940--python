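"""Synthetic ICU courses for four clinical scenarios of hypertensive ICH care.

Every scenario starts with a patient admitted at 220/110 mmHg whose BP is
managed toward a systolic goal of 140 mmHg with two 20 mg IV labetalol
pushes and, in scenarios 3-4, a titrated IV nicardipine drip.  The scenarios
differ "under the hood" -- in the homeostasis baseline the patient's BP
would spontaneously trend to and in how effective each drug actually is --
so that superficially similar BP courses hide different drug
pharmacodynamics:

    1. baseline 130/80,  labetalol E_max -40, EC50  70 (medium effect)
    2. baseline 110/70,  labetalol E_max -20, EC50 110 (weak drug, low baseline)
    3. baseline 180/100, labetalol -20/160, nicardipine -60/40 (potent drip)
    4. baseline 160/100, labetalol -20/160, nicardipine -40/70 (moderate drip)

Courses run 200 steps of 15 minutes (~2 days) with inherent BP variability
Q = diag(81, 49) mmHg^2 (SBP, DBP) and measurement noise R = diag(25, 16);
HR is simulated as pure homeostasis noise around 80 bpm.  The nicardipine
drip is closed-loop: the protocol reacts to the *observed* (noisy) SBP, as
a bedside nurse would.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from . import dlm
from .dlm import DEFAULT_CHANNELS, VitalsSeries
from .perturbation import DrugEffect, PerturbationParams, p_med, p_spon
from .pk import ConcentrationSeries, DoseEvent, DrugSpec, unit_bolus_profile

__all__ = [
    "DRUG_LIBRARY",
    "ProtocolConfig",
    "ScenarioConfig",
    "SimulatedCourse",
    "TreatmentProtocol",
    "scenario_config",
    "simulate_course",
    "simulate_perturbation_course",
    "generate_replicates",
]

#: PK constants (minutes, liters). Central (initial-distribution) volumes
#: govern the peak concentration of an IV push; with a 70 kg patient the
#: central volumes are ~1 L/kg.  Under the scenario dosing these constants
#: put mean active concentrations at ~90 ng/mL (labetalol) and ~140 ng/mL
#: (nicardipine), commensurate with the scenario EC50s.  They are
#: configuration, not estimated quantities.
DRUG_LIBRARY = {
    "labetalol": DrugSpec(
        "labetalol", half_life=330.0, volume_of_distribution=70.0,
        time_to_peak=5.0, route="bolus",
    ),
    "nicardipine": DrugSpec(
        "nicardipine", half_life=45.0, volume_of_distribution=80.0,
        time_to_peak=5.0, route="infusion",
    ),
}


@dataclass(frozen=True)
class ProtocolConfig:
    """Codified BP-management protocol (labetalol loading + drip titration)."""

    bolus_mg: float = 20.0
    bolus_steps: tuple[int, ...] = (0, 1)   # two pushes one grid step apart
    drip_start_step: int = 4                # drip begun once boluses judged insufficient
    drip_start_rate: float = 5.0            # mg/hr
    drip_step: float = 2.5                  # mg/hr per decision interval
    drip_cap: float = 15.0                  # mg/hr
    maintenance_rate: float = 3.0           # mg/hr once the goal is first reached
    sbp_goal: float = 140.0                 # mmHg

    def __post_init__(self) -> None:
        if self.bolus_mg <= 0 or self.drip_cap < self.drip_start_rate:
            raise ValueError("invalid protocol parameters")
        if self.maintenance_rate < 0 or self.drip_step <= 0:
            raise ValueError("invalid protocol parameters")


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth + noise + protocol settings for one clinical scenario."""

    scenario: int
    truth: PerturbationParams
    uses_drip: bool
    n_steps: int = 200
    dt: float = 15.0
    admission_sbp: float = 220.0
    admission_dbp: float = 110.0
    hr_h: float = 80.0
    q_diag: tuple[float, float, float] = (81.0, 49.0, 25.0)
    r_diag: tuple[float, float, float] = (25.0, 16.0, 9.0)
    r_h: float = 0.9
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    drug_specs: tuple[DrugSpec, ...] = ()

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.q_diag + self.r_diag):
            raise ValueError("variances must be non-negative")
        declared = {d.name for d in self.truth.drugs}
        if self.uses_drip and "nicardipine" not in declared:
            raise ValueError("drip scenarios must declare nicardipine")
        if not self.uses_drip and "nicardipine" in declared:
            raise ValueError("scenarios 1-2 must not declare nicardipine")

    def spec_for(self, name: str) -> DrugSpec:
        for s in self.drug_specs:
            if s.name == name:
                return s
        raise KeyError(name)


# Table-style ground truth per scenario: (SBP_H, DBP_H, labetalol, nicardipine?)
_SCENARIOS = {
    1: (130.0, 80.0, DrugEffect("labetalol", -40.0, 70.0), None),
    2: (110.0, 70.0, DrugEffect("labetalol", -20.0, 110.0), None),
    3: (180.0, 100.0, DrugEffect("labetalol", -20.0, 160.0),
        DrugEffect("nicardipine", -60.0, 40.0)),
    4: (160.0, 100.0, DrugEffect("labetalol", -20.0, 160.0),
        DrugEffect("nicardipine", -40.0, 70.0)),
}

#: default per-step decay rate of the spontaneous post-stroke perturbation
DEFAULT_R_B = 0.02


def scenario_config(scenario: int, r_b: float = DEFAULT_R_B, **overrides) -> ScenarioConfig:
    """Shipped configuration for clinical scenarios 1-4.

    ``B_max`` is set so admission BP is 220/110 by construction:
    ``B_max = 220 - SBP_H`` and ``ratio_SD = (110 - DBP_H) / B_max``.
    """
    if scenario not in _SCENARIOS:
        raise ValueError(f"scenario must be 1-4, got {scenario}")
    sbp_h, dbp_h, lab, nic = _SCENARIOS[scenario]
    b_max = 220.0 - sbp_h
    ratio_sd = (110.0 - dbp_h) / b_max
    drugs = (lab,) if nic is None else (lab, nic)
    truth = PerturbationParams(sbp_h, dbp_h, b_max, r_b, ratio_sd, drugs)
    specs = tuple(DRUG_LIBRARY[d.name] for d in drugs)
    cfg = ScenarioConfig(
        scenario=scenario, truth=truth, uses_drip=nic is not None,
        drug_specs=specs,
    )
    return replace(cfg, **overrides) if overrides else cfg


class TreatmentProtocol:
    """Closed-loop dosing decisions, one per 15-min step, from observed SBP.

    Labetalol: fixed loading pushes at the scheduled steps.  Nicardipine
    (drip scenarios only): started at ``drip_start_rate`` once the boluses
    are judged insufficient, uptitrated by ``drip_step`` per decision
    interval while SBP exceeds the goal (capped), dropped to the maintenance
    rate at the first at-goal reading; in maintenance the rate is raised one
    step if SBP re-exceeds the goal and stepped back down toward the
    maintenance rate while at goal.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self.rate = 0.0
        self._phase = "pre"   # pre -> titration -> maintenance

    def bolus_at(self, step: int) -> float:
        """Labetalol mg pushed at this step (0 if none scheduled)."""
        proto = self.config.protocol
        return proto.bolus_mg if step in proto.bolus_steps else 0.0

    def decide(self, step: int, observed_sbp: float) -> float:
        """Drip rate (mg/hr) to run from the *next* step, given this step's SBP."""
        proto = self.config.protocol
        if not self.config.uses_drip or step + 1 < proto.drip_start_step:
            return self.rate
        at_goal = observed_sbp <= proto.sbp_goal
        if self._phase == "pre":
            self.rate = proto.drip_start_rate
            self._phase = "titration"
        elif self._phase == "titration":
            if at_goal:
                self.rate = proto.maintenance_rate
                self._phase = "maintenance"
            else:
                self.rate = min(self.rate + proto.drip_step, proto.drip_cap)
        else:  # maintenance: adjust as necessary around the goal
            if not at_goal:
                self.rate = min(self.rate + proto.drip_step, proto.drip_cap)
            elif self.rate > proto.maintenance_rate:
                self.rate = max(self.rate - proto.drip_step, proto.maintenance_rate)
        return self.rate


@dataclass
class SimulatedCourse:
    """One simulated ICU course with its hidden truth retrievable for scoring."""

    vitals: VitalsSeries
    hidden: np.ndarray                    # (T, 7) true state path
    conc: dict[str, ConcentrationSeries]
    doses: list[DoseEvent]
    truth: PerturbationParams
    config: ScenarioConfig
    seed: int | None = None


def simulate_course(
    config: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
) -> SimulatedCourse:
    """Simulate one course: DLM state evolution interleaved with protocol dosing.

    The initial state pins SBP/DBP to the admission presentation (targets at
    the homeostasis baselines, HR at its target); states then propagate via
    ``x_t = Phi x_{t-1} + Upsilon u_t + w_t`` with observations
    ``y_t = A x_t + v_t``.  Dosing is decided each step from the observed
    SBP, so drip titration reacts to measurement noise exactly as a bedside
    protocol would.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    truth, proto = config.truth, config.protocol
    n, dt = config.n_steps, config.dt
    grid = np.arange(n) * dt
    drug_names = [d.name for d in truth.drugs]

    # unit response (per mg) of each drug sampled on grid offsets
    unit = {
        name: unit_bolus_profile(grid, config.spec_for(name))
        for name in drug_names
    }
    conc = {name: np.zeros(n) for name in drug_names}

    phi = dlm.build_phi(config.r_h)
    ups = dlm.build_upsilon(config.r_h, truth.ratio_sd, len(truth.drugs))
    a = dlm.build_emission(DEFAULT_CHANNELS)
    q_sd = np.sqrt(np.array(config.q_diag))
    r_sd = np.sqrt(np.array(config.r_diag))

    protocol = TreatmentProtocol(config)
    doses: list[DoseEvent] = []
    x = np.empty((n, dlm.N_STATE))
    y = np.empty((n, 3))
    effects = {d.name: d for d in truth.drugs}

    def administer(name: str, step: int, mg: float) -> None:
        conc[name][step:] += mg * unit[name][: n - step]

    rate = 0.0
    for t in range(n):
        # doses landing at this step
        lab_mg = protocol.bolus_at(t)
        if lab_mg > 0:
            administer("labetalol", t, lab_mg)
            doses.append(DoseEvent(grid[t], "labetalol", amount=lab_mg))
        if rate > 0:
            # running drip contributes one micro-bolus per grid interval
            administer("nicardipine", t, rate * dt / 60.0)

        u_t = np.empty(1 + len(drug_names))
        u_t[0] = p_spon(t, truth.b_max, truth.r_b)
        for j, name in enumerate(drug_names):
            d = effects[name]
            u_t[1 + j] = p_med(conc[name][t], d.e_max, d.ec50)

        if t == 0:
            x[0] = [
                config.admission_sbp, config.admission_dbp,
                truth.sbp_h, truth.dbp_h,
                config.hr_h, config.hr_h, 1.0,
            ]
        else:
            w = np.zeros(dlm.N_STATE)
            w[[dlm.SBP, dlm.DBP, dlm.HR]] = q_sd * rng.standard_normal(3)
            x[t] = phi @ x[t - 1] + ups @ u_t + w
        y[t] = a @ x[t] + r_sd * rng.standard_normal(3)

        new_rate = protocol.decide(t, y[t, 0])
        if new_rate != rate and t + 1 < n:
            doses.append(DoseEvent(grid[t + 1], "nicardipine", rate=new_rate))
        rate = new_rate

    vitals = VitalsSeries(grid, y, DEFAULT_CHANNELS)
    conc_series = {
        name: ConcentrationSeries(name, grid, conc[name]) for name in drug_names
    }
    return SimulatedCourse(vitals, x, conc_series, doses, truth, config, seed)


def simulate_perturbation_course(
    config: ScenarioConfig,
    rng: np.random.Generator | int | None = None,
) -> SimulatedCourse:
    """Alternative generator: perturbation model plus white noise.

    Observations are the noise-free perturbation-model tracks plus Gaussian
    noise of variance ``Q + R`` per channel -- the mechanism the NLLS
    comparator's own model assumes.  Dosing is replayed open-loop from a
    noiseless closed-loop run of :func:`simulate_course` so both generators
    share the same medication exposure.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    base = simulate_course(
        replace(config, q_diag=(0.0, 0.0, 0.0), r_diag=(0.0, 0.0, 0.0)), rng=0
    )
    n = config.n_steps
    from .perturbation import track

    sbp, dbp = track(config.truth, base.conc, n)
    sd = np.sqrt(np.array(config.q_diag) + np.array(config.r_diag))
    y = np.empty((n, 3))
    y[:, 0] = sbp + sd[0] * rng.standard_normal(n)
    y[:, 1] = dbp + sd[1] * rng.standard_normal(n)
    y[:, 2] = config.hr_h + sd[2] * rng.standard_normal(n)
    vitals = VitalsSeries(base.vitals.time, y, DEFAULT_CHANNELS)
    return SimulatedCourse(
        vitals, base.hidden, base.conc, base.doses, config.truth, config, seed
    )


def generate_replicates(
    config: ScenarioConfig,
    n_reps: int,
    master_seed: int,
    mechanism: str = "dlm",
) -> list[SimulatedCourse]:
    """Independent seeded replicate courses, reproducible from ``master_seed``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if mechanism not in ("dlm", "perturbation"):
        raise ValueError(f"unknown mechanism {mechanism!r}")
    sim = simulate_course if mechanism == "dlm" else simulate_perturbation_course
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    return [sim(config, np.random.default_rng(child)) for child in children]
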