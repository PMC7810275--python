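"""Transition matrices, projections, stationary and rotation equilibria.

A fitted transition model plus one covariate profile yields a 4x4
column-stochastic matrix P whose entry (j, i) is the probability of moving
from coverage level i last year to level j this year.  Coverage dynamics
under a (possibly cyclic) management sequence are then the linear system
q_t = P_t q_{t-1}; long-run behaviour is read off eigenvectors: the
stationary distribution of a single matrix at its dominant eigenvalue
(lambda = 1 for any column-stochastic matrix), and for a two-use rotation
the pair of phase states given by the stationary vectors of P1 P2 and
P2 P1.

The site random intercept is fixed at zero for projections, so matrices
describe the average field; a nonzero ``epsilon`` in the profile supports
sensitivity analyses.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clmm import FittedModel, conditional_transition_probs, encode_profile_row
from .survey import LAND_USES

logger = logging.getLogger("weeddyn.markov")

__all__ = [
    "CovariateProfile",
    "TransitionMatrix",
    "Trajectory",
    "EquilibriumResult",
    "build_transition_matrix",
    "project_trajectory",
    "stationary_distribution",
    "rotation_equilibrium",
    "convergence_time",
]

_COL_TOL = 1e-12


def _check_distribution(q: np.ndarray, what: str = "state distribution") -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape != (4,):
        raise ValueError(f"{what} must be a 4-vector")
    if (q < -_COL_TOL).any() or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError(f"{what} must be nonnegative and sum to 1")
    return np.clip(q, 0.0, None) / np.clip(q, 0.0, None).sum()


@dataclass(frozen=True)
class CovariateProfile:
    """One management condition: the covariates of a projection year."""

    land_use: str = "wheat"
    irrigation: int = 0
    delayed_sowing: int = 0
    temp_dec_apr: float | None = None
    epsilon: float = 0.0

    def __post_init__(self):
        if self.land_use not in LAND_USES:
            raise ValueError(f"unknown land_use token {self.land_use!r}")
        if self.irrigation not in (0, 1) or self.delayed_sowing not in (0, 1):
            raise ValueError("irrigation and delayed_sowing must be 0/1")

    def as_mapping(self) -> dict:
        return {
            "land_use": self.land_use,
            "irrigation": self.irrigation,
            "delayed_sowing": self.delayed_sowing,
            "temp_dec_apr": self.temp_dec_apr,
        }

    def label(self) -> str:
        tag = self.land_use
        if self.irrigation:
            tag += "(irrigated)"
        if self.delayed_sowing:
            tag += "(delayed)"
        return tag


@dataclass
class TransitionMatrix:
    """Column-stochastic 4x4 matrix P for one covariate profile."""

    P: np.ndarray
    profile: CovariateProfile | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (4, 4):
            raise ValueError("P must be 4x4")
        if (self.P < -_COL_TOL).any() or (self.P > 1 + _COL_TOL).any():
            raise ValueError("entries must lie in [0, 1]")
        if np.max(np.abs(self.P.sum(axis=0) - 1.0)) > _COL_TOL:
            raise ValueError("columns must sum to 1 within 1e-12")

    def __matmul__(self, other):
        if isinstance(other, TransitionMatrix):
            return self.P @ other.P
        return self.P @ np.asarray(other)


@dataclass
class Trajectory:
    """Projected state-probability path q_0, q_1, ..., q_horizon."""

    states: np.ndarray        # (horizon + 1, 4), row 0 is the initial state
    scenario_id: str = ""

    @property
    def horizon(self) -> int:
        return len(self.states) - 1

    def final(self) -> np.ndarray:
        return self.states[-1]


@dataclass
class EquilibriumResult:
    """Stationary phase distribution(s) with eigen diagnostics."""

    phases: list[np.ndarray]
    dominant_eigenvalue: float
    residual: float
    convergence_years: int | str = "not computed"
    warnings: list[str] = field(default_factory=list)


def build_transition_matrix(model: FittedModel, profile: CovariateProfile,
                            force: bool = False) -> TransitionMatrix:
    """Evaluate the fitted model at one profile, one column per source level."""
    if not model.converged and not force:
        raise ValueError(
            "model did not converge; pass force=True to project anyway"
        )
    x = encode_profile_row(profile.as_mapping(), model.spec)
    cols = [
        conditional_transition_probs(model, i, x, epsilon=profile.epsilon)
        for i in range(4)
    ]
    return TransitionMatrix(P=np.column_stack(cols), profile=profile)


def project_trajectory(matrices: Sequence[TransitionMatrix | np.ndarray],
                       q0: np.ndarray, horizon: int,
                       scenario_id: str = "") -> Trajectory:
    """Iterate q_t = P_t q_{t-1}, cycling through ``matrices``.

    ``matrices[0]`` governs the first transition (year 0 -> year 1); the
    sequence repeats cyclically for ``horizon`` years.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    mats = [m.P if isinstance(m, TransitionMatrix) else np.asarray(m, float)
            for m in matrices]
    if not mats:
        raise ValueError("need at least one transition matrix")
    q = _check_distribution(q0, "initial state")
    out = np.empty((horizon + 1, 4))
    out[0] = q
    for t in range(1, horizon + 1):
        q = mats[(t - 1) % len(mats)] @ q
        q = np.clip(q, 0.0, None)
        q = q / q.sum()
        out[t] = q
    return Trajectory(states=out, scenario_id=scenario_id)


def _power_iteration(P: np.ndarray, iters: int = 500) -> np.ndarray:
    q = np.full(4, 0.25)
    for _ in range(iters):
        q = P @ q
        q = q / q.sum()
    return q


def stationary_distribution(P: TransitionMatrix | np.ndarray) -> EquilibriumResult:
    """Right eigenvector of P at the eigenvalue nearest 1, as a distribution.

    Column-stochastic matrices always have dominant eigenvalue 1; the
    eigenvector is normalized to the probability simplex after clipping
    numerically negative entries (< 1e-12 in magnitude).  When the
    eigensolver returns a numerically complex or degenerate vector (e.g.
    reducible or periodic chains), a 500-step power iteration is used
    instead and the result is flagged.
    """
    A = P.P if isinstance(P, TransitionMatrix) else np.asarray(P, dtype=float)
    warnings: list[str] = []
    eigvals, eigvecs = np.linalg.eig(A)
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    lam = eigvals[k]
    v = eigvecs[:, k]
    # non-unique stationary vector: more than one eigenvalue at 1
    n_unit = int(np.sum(np.abs(eigvals - 1.0) < 1e-8))
    use_power = False
    if n_unit > 1:
        warnings.append("stationary distribution not unique; power-iteration limit returned")
        use_power = True
    if np.max(np.abs(v.imag)) > 1e-10 * max(np.max(np.abs(v.real)), 1e-300):
        warnings.append("complex eigenvector; falling back to power iteration")
        use_power = True
    if use_power:
        logger.warning("eigen fallback: %s", "; ".join(warnings))
        q = _power_iteration(A)
    else:
        q = v.real
        if q.sum() < 0:
            q = -q
        q = np.where(np.abs(q) < 1e-12, 0.0, q)
        if (q < 0).any():
            warnings.append("negative eigenvector entries; falling back to power iteration")
            q = _power_iteration(A)
        q = q / q.sum()
    residual = float(np.max(np.abs(A @ q - q)))
    return EquilibriumResult(
        phases=[q],
        dominant_eigenvalue=float(lam.real),
        residual=residual,
        warnings=warnings,
    )


def rotation_equilibrium(P1: TransitionMatrix | np.ndarray,
                         P2: TransitionMatrix | np.ndarray) -> EquilibriumResult:
    """Two-phase equilibrium of the alternation ... P1, P2, P1, P2, ...

    Phase 1 (the state observed in use-1 years, i.e. after the transition
    into a use-1 year) is the stationary vector of P1 P2; phase 2 is the
    stationary vector of P2 P1.  The two satisfy q2* = P2 q1* and
    q1* = P1 q2*.
    """
    A1 = P1.P if isinstance(P1, TransitionMatrix) else np.asarray(P1, float)
    A2 = P2.P if isinstance(P2, TransitionMatrix) else np.asarray(P2, float)
    r1 = stationary_distribution(A1 @ A2)
    q1 = r1.phases[0]
    q2 = A2 @ q1
    q2 = np.clip(q2, 0.0, None)
    q2 = q2 / q2.sum()
    residual = max(
        r1.residual,
        float(np.max(np.abs(A2 @ A1 @ q2 - q2))),
        float(np.max(np.abs(A1 @ q2 - q1))),
    )
    return EquilibriumResult(
        phases=[q1, q2],
        dominant_eigenvalue=r1.dominant_eigenvalue,
        residual=residual,
        warnings=list(r1.warnings),
    )


def convergence_time(trajectory: Trajectory, target: np.ndarray,
                     tol: float = 0.01) -> int | str:
    """Smallest t with max_j |q_t[j] - target[j]| < tol, or "not reached".

    The default tolerance 0.01 matches 2-decimal reporting granularity.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    target = _check_distribution(target, "target")
    dist = np.max(np.abs(trajectory.states - target), axis=1)
    hits = np.nonzero(dist < tol)[0]
    return int(hits[0]) if hits.size else "not reached"
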