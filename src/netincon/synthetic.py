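"""Synthetic contrast-level network meta-analysis data.

Each study's true arm effects versus the reference are the configured basic
effects plus its design's inconsistency offsets plus study-level random
heterogeneity; observed contrasts versus the study baseline add sampling
noise generated at arm level (shared baseline arm), which induces the
recorded within-study covariance of sigma2 on the diagonal and sigma2/2
off-diagonal.  Heterogeneity is likewise exchangeable: contrast variance tau2,
within-study covariance tau2/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .inference import ContrastDataset, StudyRecord
from .partitions import Design

__all__ = ["SimulationConfig", "simulate_network", "scenario", "scenario_suite"]

SCENARIO_NAMES = ("triangle", "full_T_n4", "star_plus_loop")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic network.

    ``delta`` maps each non-reference treatment to its basic effect versus the
    reference; ``omega`` maps design labels to per-treatment inconsistency
    offsets (again versus the reference).  ``sigma2`` is the within-study
    contrast variance; ``seed`` is mandatory for reproducibility.
    """

    treatments: tuple[str, ...]
    designs: tuple[Design, ...]
    studies_per_design: int
    delta: Mapping[str, float]
    tau2: float
    omega: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    sigma2: float = 0.1
    seed: int = 0
    reference: str | None = None

    def __post_init__(self) -> None:
        ts = set(self.treatments)
        ref = self.reference if self.reference is not None else min(ts)
        object.__setattr__(self, "reference", ref)
        if ref not in ts:
            raise ConfigError(f"reference {ref} not among treatments")
        if self.tau2 < 0:
            raise ConfigError("tau2 must be nonnegative")
        if self.sigma2 <= 0:
            raise ConfigError("sigma2 must be positive")
        if self.studies_per_design < 1:
            raise ConfigError("studies_per_design must be at least 1")
        labels = {d.label for d in self.designs}
        for d in self.designs:
            if not d.members <= ts:
                raise ConfigError(f"design {d.label} uses unknown treatments")
        for t in self.delta:
            if t not in ts or t == ref:
                raise ConfigError(f"delta given for invalid treatment {t}")
        for dlabel, offsets in self.omega.items():
            if dlabel not in labels:
                raise ConfigError(f"omega given for unobserved design {dlabel}")
            members = Design.parse(dlabel).members
            for t in offsets:
                if t not in members:
                    raise ConfigError(
                        f"omega for design {dlabel} names treatment {t} "
                        "not in that design"
                    )
                if t == ref:
                    raise ConfigError(
                        f"omega for the reference treatment {t} is not a "
                        "free parameter"
                    )

    def arm_effect(self, design: Design, treatment: str) -> float:
        """True mean effect of an arm versus the reference, delta + omega."""
        base = 0.0 if treatment == self.reference else self.delta.get(treatment, 0.0)
        return base + self.omega.get(design.label, {}).get(treatment, 0.0)

    def to_dict(self) -> dict:
        return {
            "treatments": list(self.treatments),
            "designs": [d.label for d in self.designs],
            "studies_per_design": self.studies_per_design,
            "delta": dict(self.delta),
            "tau2": self.tau2,
            "omega": {k: dict(v) for k, v in self.omega.items()},
            "sigma2": self.sigma2,
            "seed": self.seed,
            "reference": self.reference,
        }


def simulate_network(config: SimulationConfig) -> ContrastDataset:
    """Draw one dataset from the configured generative model.

    Deterministic given the seed: each study gets its own substream spawned
    from the master seed in canonical design order.
    """
    designs = sorted(config.designs)
    n_studies = len(designs) * config.studies_per_design
    streams = np.random.SeedSequence(config.seed).spawn(n_studies)
    records = []
    study_no = 0
    for design in designs:
        arms = sorted(design.members)
        baseline = arms[0]
        others = tuple(a for a in arms if a != baseline)
        k = len(others)
        # known within-study covariance from the shared baseline arm
        cov = config.sigma2 / 2.0 * (np.eye(k) + np.ones((k, k)))
        for _ in range(config.studies_per_design):
            rng = np.random.default_rng(streams[study_no])
            study_no += 1
            # per-arm random effects: heterogeneity then sampling noise
            u = rng.normal(0.0, np.sqrt(config.tau2 / 2.0), size=len(arms))
            e = rng.normal(0.0, np.sqrt(config.sigma2 / 2.0), size=len(arms))
            arm_value = {
                a: config.arm_effect(design, a) + u[i] + e[i]
                for i, a in enumerate(arms)
            }
            y = np.array([arm_value[a] - arm_value[baseline] for a in others])
            records.append(
                StudyRecord(
                    study=f"{design.label}-{study_no}",
                    design=design,
                    baseline=baseline,
                    treatments=others,
                    estimates=y,
                    covariance=cov.copy(),
                )
            )
    return ContrastDataset(records)


def scenario(
    name: str,
    *,
    omega: float = 0.0,
    tau2: float = 0.0,
    studies: int = 1,
    sigma2: float = 0.1,
    seed: int = 0,
) -> SimulationConfig:
    """A ready-made simulation configuration by scenario name.

    - ``triangle``: designs AB, AC, BC; the omega offset acts on design BC.
    - ``full_T_n4``: one design for each of the 11 multi-treatment subsets of
      {A, B, C, D}; the omega offset acts on design AB.
    - ``star_plus_loop``: star AB, AC, AD plus the loop-closing BC; omega acts
      on design BC.
    """
    if name == "triangle":
        treatments = ("A", "B", "C")
        designs = tuple(Design.parse(s) for s in ("AB", "AC", "BC"))
        delta = {"B": 0.2, "C": 0.5}
        omega_map = {"BC": {"C": omega}} if omega else {}
    elif name == "full_T_n4":
        treatments = ("A", "B", "C", "D")
        from .partitions import enumerate_designs

        designs = tuple(sorted(enumerate_designs(treatments).designs))
        delta = {"B": 0.2, "C": 0.5, "D": 0.8}
        omega_map = {"AB": {"B": omega}} if omega else {}
    elif name == "star_plus_loop":
        treatments = ("A", "B", "C", "D")
        designs = tuple(Design.parse(s) for s in ("AB", "AC", "AD", "BC"))
        delta = {"B": 0.2, "C": 0.5, "D": 0.8}
        omega_map = {"BC": {"C": omega}} if omega else {}
    else:
        raise ConfigError(
            f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}"
        )
    return SimulationConfig(
        treatments=treatments,
        designs=designs,
        studies_per_design=studies,
        delta=delta,
        tau2=tau2,
        omega=omega_map,
        sigma2=sigma2,
        seed=seed,
    )


def scenario_suite(name: str) -> list[SimulationConfig]:
    """Default configurations for a named scenario: a consistent network and
    an inconsistent variant with a 0.3 offset."""
    return [scenario(name), scenario(name, omega=0.3, seed=1)]
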