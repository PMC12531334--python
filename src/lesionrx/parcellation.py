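"""Functional parcellation and treatment-responsiveness subdivision.

Grey-matter voxels are clustered hierarchically by the similarity of their
functional association profiles, small disconnected islands are cleaned up
with a KNN vote, and each resulting network is split into two candidate
treatment-target subterritories using either receptor preponderance or
clustered transcriptome samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree

from .synth import ReceptorSet, TermMatrix, TranscriptomeSamples

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class DegenerateSubdivisionError(ValueError):
    """A subdivision left one side of the network empty."""


@dataclass
class Parcellation:
    labels: np.ndarray          # integer volume, 0 outside grey matter
    K: int
    linkage_record: np.ndarray  # scipy linkage matrix

    def network_mask(self, network_id: int) -> np.ndarray:
        return self.labels == network_id

    @property
    def network_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SubnetworkPair:
    """A functional network split into two responsiveness territories."""

    network_id: int
    mask_A: np.ndarray
    mask_B: np.ndarray
    provenance: tuple
    criterion: str              # 'receptome' | 'transcriptome'

    def __post_init__(self):
        a, b = np.asarray(self.mask_A, bool), np.asarray(self.mask_B, bool)
        if (a & b).any():
            raise ValueError("subnetwork masks overlap")
        if not a.any() or not b.any():
            raise DegenerateSubdivisionError(
                f"network {self.network_id}: one subnetwork side is empty"
            )
        self.mask_A, self.mask_B = a, b

    @property
    def network_mask(self) -> np.ndarray:
        return self.mask_A | self.mask_B


@dataclass
class TermRanking:
    network_id: int
    ranked_terms: list[tuple[str, float]]


def cluster_voxels(
    term_matrix: TermMatrix,
    K: int,
    metric: str = "correlation",
    method: str = "average",
) -> Parcellation:
    """Agglomerative clustering of voxel columns, cut to exactly K clusters.

    Voxels are observations, their per-term association scores the features;
    correlation distance with average linkage by default.
    """
    data = np.asarray(term_matrix.scores).T    # (V, T)
    V = data.shape[0]
    if not 2 <= K <= V:
        raise ValueError(f"K must be in [2, {V}], got {K}")
    const = np.where(np.ptp(data, axis=1) == 0)[0]
    if len(const):
        coord = tuple(int(c) for c in term_matrix.voxel_index[const[0]])
        raise ValueError(
            f"constant association column at voxel {coord}: "
            "correlation distance undefined"
        )
    Z = linkage(data, method=method, metric=metric)
    flat = fcluster(Z, t=K, criterion="maxclust")
    shape = term_matrix.grid_shape or tuple(
        term_matrix.voxel_index.max(axis=0) + 1
    )
    labels = np.zeros(shape, dtype=np.int32)
    # relabel to 1..K in first-appearance order for stability
    _, relabeled = np.unique(flat, return_inverse=True)
    labels[tuple(term_matrix.voxel_index.T)] = relabeled + 1
    return Parcellation(labels, int(relabeled.max() + 1), Z)


def clean_small_components(
    parc: Parcellation,
    min_volume_vox: int = 64,
    k_neighbours: int = 5,
    connectivity: int = 26,
) -> Parcellation:
    """Reassign voxels of undersized connected components by KNN vote.

    Components (26-connectivity by default) of any label smaller than
    ``min_volume_vox`` are dissolved: each of their voxels takes the
    majority label among its ``k_neighbours`` nearest voxels that do not
    themselves belong to an undersized component. Single pass; voxel count
    is conserved.
    """
    if min_volume_vox < 1:
        raise ValueError("min_volume_vox must be >= 1")
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6
    labels = parc.labels.copy()
    undersized = np.zeros(labels.shape, dtype=bool)
    for lab in parc.network_ids:
        comp, _ = ndimage.label(labels == lab, structure=struct)
        sizes = np.bincount(comp.ravel())[1:]
        for ci, size in enumerate(sizes, start=1):
            if size < min_volume_vox:
                undersized |= comp == ci
    if not undersized.any():
        return Parcellation(labels, parc.K, parc.linkage_record)
    donors = (labels > 0) & ~undersized
    if not donors.any():
        raise ValueError("all voxels belong to undersized components; no donors")
    donor_coords = np.argwhere(donors)
    donor_labels = labels[donors]
    tree = cKDTree(donor_coords)
    targets = np.argwhere(undersized)
    k = min(k_neighbours, len(donor_coords))
    _, idx = tree.query(targets, k=k)
    idx = np.atleast_2d(idx.T).T
    new = labels.copy()
    for t, nbrs in zip(targets, idx):
        votes = donor_labels[nbrs]
        counts = np.bincount(votes)
        new[tuple(t)] = int(np.argmax(counts))   # ties -> smallest label
    remaining = len(np.unique(new[new > 0]))
    return Parcellation(new, remaining, parc.linkage_record)


def rank_terms(
    parc: Parcellation,
    term_matrix: TermMatrix,
    network_id: int,
    similarity: str = "mean",
) -> TermRanking:
    """Rank terms by similarity to a network (mean in-network score by
    default, cosine as an alternative); ties keep term order."""
    in_net = parc.labels[tuple(term_matrix.voxel_index.T)] == network_id
    if not in_net.any():
        raise ValueError(f"unknown or empty network {network_id}")
    if similarity == "mean":
        scores = term_matrix.scores[:, in_net].mean(axis=1)
    elif similarity == "cosine":
        ind = in_net.astype(float)
        norms = np.linalg.norm(term_matrix.scores, axis=1) * np.linalg.norm(ind)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(norms > 0, term_matrix.scores @ ind / norms, 0.0)
    else:
        raise ValueError(f"unknown similarity {similarity!r}")
    order = np.argsort(-scores, kind="stable")
    ranked = [(term_matrix.terms[i], float(scores[i])) for i in order]
    return TermRanking(network_id, ranked)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|)."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice undefined for two empty masks")
    return 2.0 * int((a & b).sum()) / (na + nb)


def subdivide_receptome(
    network_mask: np.ndarray,
    receptors: ReceptorSet,
    network_id: int = 0,
    z_threshold: float = 0.0,
) -> SubnetworkPair:
    """Split a network by its two most preponderant receptors.

    Preponderance of a receptor is the Dice coefficient between the network
    mask and its z-map binarized at ``z_threshold``; each network voxel then
    goes to whichever of the two top receptors has the greater z there.
    """
    mask = np.asarray(network_mask, bool)
    if not mask.any():
        raise ValueError("empty network mask")
    if len(receptors.zmaps) < 2:
        raise ValueError("need at least two receptors")
    prep = np.array(
        [dice(mask, z > z_threshold) for z in receptors.zmaps]
    )
    top = np.argsort(-prep, kind="stable")[:2]
    zA, zB = receptors.zmaps[top[0]], receptors.zmaps[top[1]]
    side_a = mask & (zA >= zB)       # ties go to the top-ranked receptor
    side_b = mask & (zA < zB)
    return SubnetworkPair(
        network_id,
        side_a,
        side_b,
        (receptors.names[top[0]], receptors.names[top[1]]),
        "receptome",
    )


def _n_components(mask: np.ndarray, struct: np.ndarray) -> int:
    return int(ndimage.label(mask, structure=struct)[1])


def subdivide_transcriptome(
    network_mask: np.ndarray,
    samples: TranscriptomeSamples,
    sigma_grid: list[float],
    network_id: int = 0,
    lam: float = 0.05,
    connectivity: int = 26,
) -> SubnetworkPair:
    """Split a network by two-way clustering of in-network transcriptome
    samples, propagated to voxels by Gaussian smoothing.

    The in-network samples are agglomeratively clustered into two groups
    (correlation distance, average linkage). For each candidate kernel sd
    sigma, the two clusters' site indicators are smoothed and every network
    voxel assigned to the cluster with the larger smoothed value. The sigma
    minimizing J = |n_A - n_B|/(n_A + n_B) + lam * (components_A +
    components_B - 2) wins; sigmas leaving a side empty are skipped.
    """
    mask = np.asarray(network_mask, bool)
    if len(sigma_grid) == 0:
        raise ValueError("sigma_grid is empty")
    in_net = mask[tuple(samples.sites.T)]
    sites = samples.sites[in_net]
    profiles = samples.profiles[in_net]
    if len(sites) < 4:
        raise ValueError(
            f"only {len(sites)} transcriptome samples inside the network; need >= 4"
        )
    Z = linkage(profiles, method="average", metric="correlation")
    groups = fcluster(Z, t=2, criterion="maxclust")
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6

    best = None
    for sigma in sigma_grid:
        if sigma <= 0:
            raise ValueError("sigma values must be positive")
        fields = []
        for g in (1, 2):
            vol = np.zeros(mask.shape)
            pts = sites[groups == g]
            vol[tuple(pts.T)] = 1.0
            fields.append(ndimage.gaussian_filter(vol, sigma=sigma))
        side_a = mask & (fields[0] >= fields[1])
        side_b = mask & (fields[0] < fields[1])
        n_a, n_b = int(side_a.sum()), int(side_b.sum())
        if n_a == 0 or n_b == 0:
            continue
        J = abs(n_a - n_b) / (n_a + n_b) + lam * (
            _n_components(side_a, struct) + _n_components(side_b, struct) - 2
        )
        if best is None or J < best[0]:
            best = (J, sigma, side_a, side_b)
    if best is None:
        raise DegenerateSubdivisionError(
            f"network {network_id}: every sigma left one side empty"
        )
    _, sigma, side_a, side_b = best
    return SubnetworkPair(
        network_id, side_a, side_b, ("cluster_1", "cluster_2", sigma),
        "transcriptome",
    )
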