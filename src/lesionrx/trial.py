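"""Treatment allocation policies and outcome sampling.

Three allocation regimes: randomized (fair coin), observably confounded
(allocation probability follows the lesion centroid's rank along the axis
best separating the two subnetwork centroids, controlled by b_obs), and
unobservably confounded (allocation follows the hidden optimal arm with
probability b_unobs). Outcomes are Bernoulli draws from the TE/RE model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ground_truth import NoiseConfig, ResponsivenessRecord, expected_outcomes
from .parcellation import SubnetworkPair


@dataclass(frozen=True)
class AllocationPolicy:
    kind: str                   # 'randomized' | 'observable' | 'unobservable'
    b_obs: float = 0.0
    b_unobs: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("randomized", "observable", "unobservable"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 <= self.b_obs <= 1.0:
            raise ValueError("b_obs must be in [0, 1]")
        if not 0.0 <= self.b_unobs <= 1.0:
            raise ValueError("b_unobs must be in [0, 1]")


@dataclass(frozen=True)
class ConfoundingAxis:
    axis: int
    c_A: np.ndarray
    c_B: np.ndarray


@dataclass
class TrialDataset:
    """Observational tuples plus the hidden truth they were generated from."""

    patient_ids: list[str]
    X: np.ndarray               # (n, d) phenotypes
    w: np.ndarray               # (n,) in {'A', 'B'}
    y: np.ndarray               # (n,) in {0, 1}
    hidden: list[ResponsivenessRecord]
    policy: AllocationPolicy
    noise: NoiseConfig
    rho: np.ndarray             # (n,) P(W = B) under the policy

    def __post_init__(self):
        n = len(self.patient_ids)
        if not (len(self.w) == len(self.y) == len(self.hidden) == n):
            raise ValueError("trial dataset fields have inconsistent lengths")


def centroid(mask: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the voxel coordinates of a nonempty mask."""
    coords = np.argwhere(np.asarray(mask, bool))
    if len(coords) == 0:
        raise ValueError("empty mask has no centroid")
    return coords.mean(axis=0)


def confounding_axis(pair: SubnetworkPair) -> ConfoundingAxis:
    """Axis of maximal absolute difference between subnetwork centroids;
    exact ties go to the lowest axis index."""
    c_a, c_b = centroid(pair.mask_A), centroid(pair.mask_B)
    return ConfoundingAxis(int(np.argmax(np.abs(c_a - c_b))), c_a, c_b)


def allocate_observable(
    coords: np.ndarray,
    b_obs: float,
    train_median: float,
    seed: int,
    patient_ids=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-confounded allocation along one coordinate.

    Patients sorted ascending by ``coords`` (ties by patient id, stable)
    receive P(W=B) from an evenly spaced ramp: for b_obs <= 0.5 the ramp
    spans [0.5 - b_obs, 0.5 + b_obs]; beyond 0.5 a per-tail fraction
    f = b_obs - 0.5 of the ranked patients is allocated deterministically
    by their side of the training-set median (below -> A, at or above -> B)
    while the interior ramp spans [0, 1]. Continuous in b_obs at 0.5 and
    fully deterministic at 1.
    """
    if not 0.0 <= b_obs <= 1.0:
        raise ValueError("b_obs must be in [0, 1]")
    coords = np.asarray(coords, dtype=float)
    N = len(coords)
    if N < 2:
        raise ValueError("need at least two patients to allocate")
    if patient_ids is None:
        patient_ids = np.arange(N)
    order = np.lexsort((np.asarray(patient_ids), coords))
    rho_sorted = np.empty(N)
    if b_obs <= 0.5:
        rho_sorted[:] = np.linspace(0.5 - b_obs, 0.5 + b_obs, N)
    else:
        f = b_obs - 0.5
        ranks = np.arange(N)
        det = (ranks < f * N) | (ranks >= N - f * N)
        rho_sorted[det] = (coords[order][det] >= train_median).astype(float)
        n_int = int((~det).sum())
        if n_int:
            rho_sorted[~det] = np.linspace(0.0, 1.0, n_int)
    rho = np.empty(N)
    rho[order] = rho_sorted
    rng = np.random.default_rng(seed)
    w = np.where(rng.random(N) < rho, "B", "A")
    return w, rho


def allocate_unobservable(
    hidden: list[ResponsivenessRecord], b_unobs: float, seed: int
) -> np.ndarray:
    """Hidden-confounded allocation: W = w* with probability b_unobs for
    single responders; dual responders get a fair coin."""
    if not 0.0 <= b_unobs <= 1.0:
        raise ValueError("b_unobs must be in [0, 1]")
    rng = np.random.default_rng(seed)
    u = rng.random(len(hidden))
    w = np.empty(len(hidden), dtype="<U1")
    for i, rec in enumerate(hidden):
        if rec.s == 0:
            w[i] = "B" if u[i] < 0.5 else "A"
        else:
            other = "B" if rec.w_star == "A" else "A"
            w[i] = rec.w_star if u[i] < b_unobs else other
    return w


def sample_outcomes(
    hidden: list[ResponsivenessRecord],
    w: np.ndarray,
    noise: NoiseConfig,
    seed: int,
    semantics: str = "branch",
) -> np.ndarray:
    """Independent Bernoulli outcomes y_i ~ Bern(E[Y | w_i, hidden_i])."""
    if len(hidden) != len(w):
        raise ValueError("hidden records and allocations differ in length")
    rng = np.random.default_rng(seed)
    p = np.array(
        [expected_outcomes(rec, wi, noise, semantics) for rec, wi in zip(hidden, w)]
    )
    return (rng.random(len(p)) < p).astype(np.int8)


def check_fittable(dataset: TrialDataset, learner_kind: str = "T") -> str:
    """'fittable' or 'degenerate' — the latter when an arm is empty or an
    outcome class required by the learner is missing (T: per arm; S:
    overall). Degenerate conditions are skipped, not errors."""
    w, y = np.asarray(dataset.w), np.asarray(dataset.y)
    for arm in ("A", "B"):
        if not (w == arm).any():
            return "degenerate"
    if len(np.unique(y)) < 2:
        return "degenerate"
    if learner_kind == "T":
        for arm in ("A", "B"):
            if len(np.unique(y[w == arm])) < 2:
                return "degenerate"
    return "fittable"
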