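"""Hidden potential-outcome ground truth for virtual trials.

For each patient and functional network, the overlap between the lesion
representation and the two responsiveness subterritories designates which
of the two virtual treatments the patient truly responds to. Outcomes are
Bernoulli with two dials: the treatment effect TE = P(Y=1 | suitably
treated) and the recovery effect RE = P(Y=1 | unsuitably treated), so that
TE=1, RE=0 is the noiseless endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parcellation import SubnetworkPair
from .synth import LesionCohort, TractSet, compute_disconnectome


class EmptyTrialError(ValueError):
    """No patient met the inclusion criterion."""


@dataclass(frozen=True)
class NoiseConfig:
    TE: float
    RE: float

    def __post_init__(self):
        for name, v in (("TE", self.TE), ("RE", self.RE)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class ResponsivenessRecord:
    """Per patient-per network hidden truth the trial is scored against.

    s = r_A - r_B encodes the responsiveness class (+1 A-only, -1 B-only,
    0 dual responder); w_star is the individually optimal arm ('either'
    for dual responders); tau the true individual treatment effect.
    """

    patient_id: str
    network_id: int
    r_A: int
    r_B: int
    s: int
    w_star: str                 # 'A' | 'B' | 'either'
    tau: float
    rep_kind: str               # 'lesion' | 'disconnectome'


def binarize_disconnectome(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strictly-above-threshold binarization of a probabilistic map."""
    m = np.asarray(prob_map, dtype=float)
    if m.min() < 0 or m.max() > 1:
        raise ValueError("disconnectome values must lie in [0, 1]")
    return m > threshold


def subnetwork_overlap(lesion_mask: np.ndarray, subnetwork_mask: np.ndarray) -> float:
    """Fraction of the subnetwork's volume covered by the lesion."""
    les, sub = np.asarray(lesion_mask, bool), np.asarray(subnetwork_mask, bool)
    if les.shape != sub.shape:
        raise ValueError("mask shapes differ")
    n_sub = int(sub.sum())
    if n_sub == 0:
        raise ValueError("empty subnetwork")
    return int((les & sub).sum()) / n_sub


def designate(
    lesion_mask: np.ndarray, pair: SubnetworkPair, threshold: float = 0.05
) -> tuple[int, int]:
    """Responsiveness flags: r_X = 1 iff the lesion covers strictly more
    than ``threshold`` of subnetwork X's volume."""
    r_a = int(subnetwork_overlap(lesion_mask, pair.mask_A) > threshold)
    r_b = int(subnetwork_overlap(lesion_mask, pair.mask_B) > threshold)
    return r_a, r_b


def _w_star(s: int) -> str:
    return {1: "A", -1: "B", 0: "either"}[s]


def make_record(
    patient_id: str,
    network_id: int,
    r_a: int,
    r_b: int,
    noise: NoiseConfig,
    rep_kind: str,
    tau_mode: str = "effect_scaled",
) -> ResponsivenessRecord:
    s = r_a - r_b
    tau = float(s) if tau_mode == "sign" else s * (noise.TE - noise.RE)
    return ResponsivenessRecord(
        patient_id, network_id, r_a, r_b, s, _w_star(s), tau, rep_kind
    )


def build_cohort(
    cohort: LesionCohort,
    pair: SubnetworkPair,
    noise: NoiseConfig,
    rep_kind: str = "lesion",
    tracts: TractSet | None = None,
    overlap_threshold: float = 0.05,
    disconnectome_threshold: float = 0.5,
    tau_mode: str = "effect_scaled",
) -> list[ResponsivenessRecord]:
    """Designate every lesion against a subnetwork pair and keep responders.

    The designating mask is the lesion itself, or its binarized
    disconnectome when rep_kind='disconnectome' (requires tracts). Patients
    responsive to neither arm are excluded from the trial.
    """
    if rep_kind not in ("lesion", "disconnectome"):
        raise ValueError(f"unknown rep_kind {rep_kind!r}")
    if rep_kind == "disconnectome" and tracts is None:
        raise ValueError("disconnectome designation requires a TractSet")
    records = []
    for patient_id, lesion in cohort.patients:
        if rep_kind == "disconnectome":
            mask = binarize_disconnectome(
                compute_disconnectome(lesion, tracts), disconnectome_threshold
            )
        else:
            mask = lesion
        r_a, r_b = designate(mask, pair, overlap_threshold)
        if r_a == 0 and r_b == 0:
            continue
        records.append(
            make_record(
                patient_id, pair.network_id, r_a, r_b, noise, rep_kind, tau_mode
            )
        )
    if not records:
        raise EmptyTrialError(
            f"no patient overlaps network {pair.network_id} subnetworks "
            f"beyond {overlap_threshold:.0%}"
        )
    return records


def expected_outcomes(
    record: ResponsivenessRecord,
    w: str,
    noise: NoiseConfig,
    semantics: str = "branch",
) -> float:
    """E[Y | W=w] for one patient.

    'branch' (default): P(Y=1) = TE when the arm is individually suitable
    (w == w_star, or w_star == 'either'), else RE. 'or' composes an immune
    draw with a responder draw: P = RE + (1-RE)*TE when suitable, else RE.
    """
    suitable = record.w_star == "either" or w == record.w_star
    if semantics == "branch":
        return noise.TE if suitable else noise.RE
    if semantics == "or":
        return noise.RE + (1 - noise.RE) * noise.TE if suitable else noise.RE
    raise ValueError(f"unknown outcome semantics {semantics!r}")
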