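"""Vital-rate models, Leslie-matrix projection, growth rate and elasticities.

The life cycle has three stages — fledglings, sub-adults (one year old) and
adults (two years and older); only adults breed. The annual transition matrix
is

    A_t = [[0,        rho_t*phi2, rho_t*phi2],
           [phi1,     0,          0         ],
           [0,        phi2,       phi2      ]]

where phi1 and phi2 are fledgling and adult/sub-adult annual survival and
rho_t is fecundity (offspring per adult per year). Fecundity is rainfall- and
year-dependent on the logit scale, bounded above by 1.5 offspring per adult
(three per pair). The sub-adult and adult columns are identical, so removing
a sub-adult or an adult perturbs the projected population identically.

Adult survival is informed by telemetry through a constant-hazard
(exponential) survival model: a bird tracked for ``exposure_days`` either
dies (event) or is censored at the end of tracking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .data_model import PopulationVector, TrackingRecord

__all__ = [
    "MAX_FECUNDITY",
    "TransitionMatrix",
    "ElasticityReport",
    "fecundity",
    "build_matrix",
    "project",
    "growth_rate",
    "growth_rate_closed_form",
    "stable_stage_distribution",
    "elasticities",
    "survival_loglik",
    "fit_hazard_mle",
    "annual_survival",
]

#: Upper bound on fecundity: 1.5 offspring per adult, i.e. 3 per pair.
MAX_FECUNDITY = 1.5

TransitionMatrix = np.ndarray  # 3x3, layout documented above


def fecundity(
    beta0: float, beta1: float, rain_covariate: float = 0.0, gamma: float = 0.0
) -> float:
    """Expected offspring per adult per year.

    ``MAX_FECUNDITY * inverse_logit(beta0 + beta1*rain + gamma)``: the logistic
    keeps mean fecundity between 0 and 1.5 birds per adult. ``rain_covariate``
    is the standardized annual rainfall; ``gamma`` the annual random effect.
    """
    return MAX_FECUNDITY * expit(beta0 + beta1 * rain_covariate + gamma)


def build_matrix(rho: float, phi1: float, phi2: float) -> TransitionMatrix:
    """Assemble the 3x3 stage transition matrix for one year."""
    if not 0.0 <= rho <= MAX_FECUNDITY:
        raise ValueError(f"rho must be in [0, {MAX_FECUNDITY}], got {rho}")
    if not (0.0 < phi1 < phi2 < 1.0):
        raise ValueError(
            f"survival constraint 0 < phi1 < phi2 < 1 violated: "
            f"phi1={phi1}, phi2={phi2}"
        )
    a = rho * phi2
    return np.array(
        [
            [0.0, a, a],
            [phi1, 0.0, 0.0],
            [0.0, phi2, phi2],
        ]
    )


def project(population: PopulationVector, matrix: TransitionMatrix) -> PopulationVector:
    """One-year projection ``N_{t+1} = A_t N_t``."""
    out = matrix @ population.as_array()
    return PopulationVector(*out)


def growth_rate(matrix: TransitionMatrix) -> float:
    """Asymptotic annual growth rate: the dominant eigenvalue of ``matrix``."""
    eigenvalues = np.linalg.eigvals(matrix)
    return float(np.max(eigenvalues.real))


def growth_rate_closed_form(matrix: TransitionMatrix) -> float:
    """Dominant eigenvalue from the characteristic polynomial.

    For this life cycle the characteristic polynomial factors as
    ``lambda * (lambda^2 - phi2*lambda - rho*phi2*phi1)``, so

        lambda = (phi2 + sqrt(phi2^2 + 4*rho*phi2*phi1)) / 2.

    Serves as an independent oracle for :func:`growth_rate`.
    """
    phi2 = matrix[2, 2]
    phi1 = matrix[1, 0]
    a = matrix[0, 1]  # rho * phi2
    return float((phi2 + np.sqrt(phi2**2 + 4.0 * a * phi1)) / 2.0)


def stable_stage_distribution(matrix: TransitionMatrix) -> np.ndarray:
    """Long-run stage proportions: the right dominant eigenvector, sum 1."""
    values, vectors = np.linalg.eig(matrix)
    i = int(np.argmax(values.real))
    w = np.abs(vectors[:, i].real)
    return w / w.sum()


@dataclass(frozen=True)
class ElasticityReport:
    """Entrywise and stage-level elasticities of the growth rate.

    ``entrywise[i, j]`` is the proportional sensitivity of lambda to matrix
    entry ``a_ij``; the entries sum to 1. Stage-level elasticities group the
    entries by the life-history transition they represent, so the three
    groups partition the total of 1: reproduction (first row) is attributed
    to fecundity ``rho``, a21 to fledgling survival ``phi1``, and the
    third-row survival entries to adult/sub-adult survival ``phi2``. (The
    reproduction entries also contain phi2 algebraically — a breeder must
    survive the year to produce the brood — so the elasticity to phi2 as a
    raw parameter would be ``phi2 + rho``; ``phi2_total`` reports it.)
    """

    entrywise: np.ndarray
    phi2: float
    phi1: float
    rho: float

    @property
    def phi2_total(self) -> float:
        return self.phi2 + self.rho


def elasticities(matrix: TransitionMatrix) -> ElasticityReport:
    """Eigenvalue elasticities ``e_ij = (a_ij/lambda) v_i w_j / (v.w)``.

    ``w`` and ``v`` are the right and left dominant eigenvectors (stable stage
    distribution and reproductive values).
    """
    values, right = np.linalg.eig(matrix)
    i = int(np.argmax(values.real))
    lam = values[i].real
    if lam <= 0:
        raise ValueError("growth rate must be positive for elasticities")
    w = np.abs(right[:, i].real)
    lvalues, left = np.linalg.eig(matrix.T)
    j = int(np.argmax(lvalues.real))
    v = np.abs(left[:, j].real)
    sensitivity = np.outer(v, w) / (v @ w)
    e = matrix * sensitivity / lam
    return ElasticityReport(
        entrywise=e,
        phi2=float(e[2, 1] + e[2, 2]),
        phi1=float(e[1, 0]),
        rho=float(e[0, 1] + e[0, 2]),
    )


# --- exponential survival ---------------------------------------------------

DAYS_PER_YEAR = 365.0


def survival_loglik(records: list[TrackingRecord], hazard: float) -> float:
    """Log-likelihood of tracking data under a constant annual hazard.

    Deaths contribute events, surviving birds right-censoring; exposure is
    measured in bird-years (days / 365):

        D * log(hazard) - hazard * total_exposure_years
    """
    if hazard <= 0:
        raise ValueError(f"hazard must be > 0, got {hazard}")
    deaths = sum(r.died for r in records)
    exposure = sum(r.exposure_days for r in records) / DAYS_PER_YEAR
    return deaths * np.log(hazard) - hazard * exposure


def fit_hazard_mle(records: list[TrackingRecord]) -> float:
    """Closed-form MLE of the exponential hazard: deaths / exposure-years."""
    deaths = sum(r.died for r in records)
    exposure = sum(r.exposure_days for r in records) / DAYS_PER_YEAR
    if deaths == 0:
        raise ValueError("no deaths observed; hazard MLE is at the boundary 0")
    return deaths / exposure


def annual_survival(hazard: float) -> float:
    """Probability of surviving one year under a constant hazard: exp(-hazard)."""
    if hazard < 0:
        raise ValueError(f"hazard must be >= 0, got {hazard}")
    return float(np.exp(-hazard))
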