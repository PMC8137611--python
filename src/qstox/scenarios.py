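"""Canonical simulation scenarios and synthetic observations.

Bundles the study conditions exercised throughout the package: the
myelosuppression model under a single 95% progenitor kill and under 95% kills
repeated every 21 days, each at feedback exponents 0.17, 0.3 and 0.5; and the
crypt model under 85% cycle arrest of the lower vs upper half of the
transit-amplifying band.  Bundles serialize to the config/schedule file
formats of the engine modules and round-trip losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .crypt import CryptConfig, InjurySpec
from .hematopoiesis import ModelParams, Trajectory, TreatmentSchedule

__all__ = [
    "ScenarioBundle",
    "canonical_hematology_scenarios",
    "canonical_crypt_scenarios",
    "noisy_observations",
]

GAMMA_VALUES = (0.17, 0.3, 0.5)
KILL_FRACTION = 0.95
DOSE_INTERVAL_H = 21.0 * 24.0  # every 21 days
N_CYCLES = 6
ARREST_FRACTION = 0.85
LOW_BAND = (5, 12)
HIGH_BAND = (13, 20)
CRYPT_SEEDS = tuple(range(1, 11))
CRYPT_HORIZON_H = 240.0


@dataclass(frozen=True)
class ScenarioBundle:
    """A named, self-contained simulation scenario.

    ``model_params`` is a :class:`ModelParams` (ODE scenarios) or a
    :class:`CryptConfig` (crypt scenarios); ``schedule`` correspondingly a
    :class:`TreatmentSchedule` or an :class:`InjurySpec`.
    """

    name: str
    model_params: ModelParams | CryptConfig
    schedule: TreatmentSchedule | InjurySpec
    horizon: float
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        stochastic = isinstance(self.model_params, CryptConfig)
        if stochastic and not self.seeds:
            raise ValueError("stochastic scenarios need at least one seed")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("seeds must be distinct")

    @property
    def kind(self) -> str:
        return "crypt" if isinstance(self.model_params, CryptConfig) else "hematology"

    def write(self, directory) -> dict[str, str]:
        """Materialize the bundle as config + schedule files; returns paths."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg_path = d / f"{self.name}.config.yaml"
        meta = {
            "name": self.name,
            "kind": self.kind,
            "horizon_h": self.horizon,
            "seeds": list(self.seeds),
            "model_params": self.model_params.to_dict(),
        }
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        sched_path = d / (
            f"{self.name}.schedule.json" if self.kind == "hematology" else f"{self.name}.injury.json"
        )
        self.schedule.to_json(sched_path)
        return {"config": str(cfg_path), "schedule": str(sched_path)}

    @classmethod
    def read(cls, config_path, schedule_path) -> "ScenarioBundle":
        with open(config_path) as fh:
            meta = yaml.safe_load(fh)
        if meta["kind"] == "hematology":
            params = ModelParams.from_dict(meta["model_params"])
            schedule = TreatmentSchedule.from_json(schedule_path)
        else:
            params = CryptConfig.from_dict(meta["model_params"])
            schedule = InjurySpec.from_json(schedule_path)
        return cls(
            name=meta["name"],
            model_params=params,
            schedule=schedule,
            horizon=meta["horizon_h"],
            seeds=tuple(meta.get("seeds", ())),
        )


def canonical_hematology_scenarios() -> tuple[ScenarioBundle, ...]:
    """The six myelosuppression scenarios: gamma x {single dose, q21d}.

    Single-dose horizons are 2,160 h (90 days), extended to 4,320 h for
    gamma = 0.5 whose damped oscillations take months to settle; repeated
    dosing runs six 21-day cycles.
    """
    bundles = []
    for gamma in GAMMA_VALUES:
        params = ModelParams(gamma=gamma)
        single_horizon = 4320.0 if gamma == 0.5 else 2160.0
        bundles.append(
            ScenarioBundle(
                name=f"single_dose_gamma_{gamma}",
                model_params=params,
                schedule=TreatmentSchedule.single_dose(KILL_FRACTION, 0.0),
                horizon=single_horizon,
            )
        )
        bundles.append(
            ScenarioBundle(
                name=f"q21d_gamma_{gamma}",
                model_params=params,
                schedule=TreatmentSchedule.repeated(KILL_FRACTION, DOSE_INTERVAL_H, N_CYCLES),
                horizon=N_CYCLES * DOSE_INTERVAL_H,
            )
        )
    return tuple(bundles)


def canonical_crypt_scenarios(
    n_seeds: int = 10, base_config: CryptConfig | None = None
) -> tuple[ScenarioBundle, ...]:
    """The two crypt-injury scenarios: 85% arrest in the low vs high TA band."""
    cfg = base_config if base_config is not None else CryptConfig()
    seeds = tuple(range(1, n_seeds + 1))
    return (
        ScenarioBundle(
            name="arrest_low_band",
            model_params=cfg,
            schedule=InjurySpec(ARREST_FRACTION, LOW_BAND, 0.0),
            horizon=CRYPT_HORIZON_H,
            seeds=seeds,
        ),
        ScenarioBundle(
            name="arrest_high_band",
            model_params=cfg,
            schedule=InjurySpec(ARREST_FRACTION, HIGH_BAND, 0.0),
            horizon=CRYPT_HORIZON_H,
            seeds=seeds,
        ),
    )


def noisy_observations(traj: Trajectory, cv: float, seed: int) -> np.ndarray:
    """Circulating-cell series with multiplicative lognormal observation noise.

    The noise is mean-preserving with coefficient of variation ``cv``
    (sigma^2 = ln(1 + cv^2), mu = -sigma^2/2); cv = 0 returns the series
    unchanged.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    circ = traj.circ.copy()
    if cv == 0:
        return circ
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(cv**2)
    factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=circ.shape)
    return circ * factors
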