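"""Management scenarios: definition, projection and result tables.

A scenario is a cyclic sequence of management conditions (one
:class:`~weeddyn.markov.CovariateProfile` per year of the cycle), an
initial coverage-level distribution and a projection horizon.  The
canonical set mirrors the comparison the model was built for: continuous
wheat, wheat alternated with each of the five other farmland uses, wheat
with summer irrigation every year, and wheat alternated with irrigated
wheat - each started from a field with no weed (level 0) and from a heavy
infestation (level 3), projected 20 years with the site effect at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .clmm import FittedModel
from .markov import (
    CovariateProfile,
    EquilibriumResult,
    TransitionMatrix,
    Trajectory,
    build_transition_matrix,
    convergence_time,
    project_trajectory,
    stationary_distribution,
)
from .survey import LAND_USES

__all__ = [
    "ScenarioDef",
    "ScenarioResult",
    "delta_state",
    "default_scenarios",
    "cycle_equilibrium",
    "run_scenario",
    "equilibrium_table",
    "trajectory_frame",
]

DEFAULT_HORIZON = 20
STEADY_STATE_TOL = 0.01


def delta_state(level: int) -> np.ndarray:
    """Point mass at one coverage level."""
    if level not in (0, 1, 2, 3):
        raise ValueError("level must be 0..3")
    q = np.zeros(4)
    q[level] = 1.0
    return q


@dataclass(frozen=True)
class ScenarioDef:
    """A cyclic management sequence with an initial state and horizon."""

    id: str
    cycle: tuple[CovariateProfile, ...]
    horizon: int = DEFAULT_HORIZON
    initial: np.ndarray = field(default_factory=lambda: delta_state(0))

    def __post_init__(self):
        if not self.cycle:
            raise ValueError("cycle must be non-empty")
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        object.__setattr__(self, "cycle", tuple(self.cycle))
        object.__setattr__(self, "initial", np.asarray(self.initial, dtype=float))


@dataclass
class ScenarioResult:
    scenario: ScenarioDef
    matrices: list[TransitionMatrix]
    trajectory: Trajectory
    equilibrium: EquilibriumResult
    convergence_years: int | str


def default_scenarios(model: FittedModel | None = None,
                      horizon: int = DEFAULT_HORIZON) -> list[ScenarioDef]:
    """The eight canonical management cycles, each from level 0 and level 3.

    Cycles: continuous wheat; wheat alternated with barley, other crop,
    paddy rice, managed fallow and unmanaged fallow; continuously irrigated
    wheat; and wheat alternated with irrigated wheat.  All profiles have
    the site effect fixed at zero.
    """
    wheat = CovariateProfile(land_use="wheat")
    wheat_irr = CovariateProfile(land_use="wheat", irrigation=1)
    cycles: list[tuple[str, tuple[CovariateProfile, ...]]] = [
        ("wheat", (wheat,)),
    ]
    for use in LAND_USES[1:]:
        cycles.append((f"wheat-{use}", (wheat, CovariateProfile(land_use=use))))
    cycles.append(("wheat_irrigated", (wheat_irr,)))
    cycles.append(("wheat-wheat_irrigated", (wheat, wheat_irr)))

    out = []
    for cid, cycle in cycles:
        for lvl in (0, 3):
            out.append(ScenarioDef(id=f"{cid}@lv{lvl}", cycle=cycle,
                                   horizon=horizon, initial=delta_state(lvl)))
    return out


def cycle_equilibrium(matrices: Sequence[TransitionMatrix]) -> EquilibriumResult:
    """Phase equilibria of a cyclic matrix sequence.

    Phase j (the state observed in years governed by cycle position j) is
    the stationary vector of the cyclically rotated product
    M_j M_{j-1} ... M_{j+1}; for a one-matrix cycle this is the ordinary
    stationary distribution.
    """
    mats = [m.P for m in matrices]
    L = len(mats)
    # phase 0 from its rotated product; later phases by pushing forward,
    # which keeps the phases mutually consistent to machine precision
    prod = mats[0]
    for k in range(1, L):
        prod = prod @ mats[(0 - k) % L]   # M_0 M_{L-1} ... M_1
    r0 = stationary_distribution(prod)
    phases = [r0.phases[0]]
    residual = r0.residual
    for j in range(1, L):
        q = mats[j] @ phases[-1]
        q = np.clip(q, 0.0, None)
        phases.append(q / q.sum())
    # close the cycle: M_0 applied to the last phase must reproduce phase 0
    if L > 1:
        back = mats[0] @ phases[-1]
        residual = max(residual, float(np.max(np.abs(back / back.sum() - phases[0]))))
    return EquilibriumResult(phases=phases,
                             dominant_eigenvalue=r0.dominant_eigenvalue,
                             residual=residual, warnings=list(r0.warnings))


def run_scenario(model: FittedModel, scenario: ScenarioDef,
                 tol: float = STEADY_STATE_TOL) -> ScenarioResult:
    """Project one scenario and locate its equilibrium; fully deterministic."""
    try:
        matrices = [build_transition_matrix(model, p) for p in scenario.cycle]
        trajectory = project_trajectory(matrices, scenario.initial,
                                        scenario.horizon, scenario_id=scenario.id)
        equilibrium = cycle_equilibrium(matrices)
        L = len(matrices)
        if L == 1:
            conv = convergence_time(trajectory, equilibrium.phases[0], tol)
        else:
            dist = np.array([
                np.max(np.abs(trajectory.states[t] - equilibrium.phases[(t - 1) % L]))
                for t in range(1, scenario.horizon + 1)
            ])
            hits = np.nonzero(dist < tol)[0]
            conv = int(hits[0] + 1) if hits.size else "not reached"
    except Exception as exc:
        raise RuntimeError(f"scenario {scenario.id!r}: {exc}") from exc
    return ScenarioResult(scenario=scenario, matrices=matrices,
                          trajectory=trajectory, equilibrium=equilibrium,
                          convergence_years=conv)


def equilibrium_table(model: FittedModel, rotations: Sequence[ScenarioDef],
                      rounded: bool = True) -> pd.DataFrame:
    """One row per rotation phase, in the layout of a rotation-equilibrium table.

    Constant cycles contribute a single row.  Unrounded phase vectors sum
    to 1 exactly; with ``rounded=True`` probabilities print at 2 decimals.
    """
    rows = []
    seen = set()
    for sc in rotations:
        base_id = sc.id.split("@")[0]
        if base_id in seen:
            continue
        seen.add(base_id)
        res = run_scenario(model, sc)
        for profile, q in zip(sc.cycle, res.equilibrium.phases):
            vals = np.round(q, 2) if rounded else q
            rows.append({
                "rotation": base_id,
                "phase": profile.label(),
                "p_level0": vals[0],
                "p_level1": vals[1],
                "p_level2": vals[2],
                "p_level3": vals[3],
            })
    return pd.DataFrame(rows)


def trajectory_frame(result: ScenarioResult) -> pd.DataFrame:
    """Trajectory as a tidy table: year, four state probabilities, ids."""
    tr = result.trajectory
    df = pd.DataFrame(tr.states, columns=[f"p_level{j}" for j in range(4)])
    df.insert(0, "year", np.arange(len(tr.states)))
    df["scenario"] = result.scenario.id
    df["initial_level"] = int(np.argmax(result.scenario.initial))
    return df
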