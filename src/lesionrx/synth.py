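"""Synthetic brain worlds with planted, recoverable structure.

Every input the downstream pipeline would normally obtain from empirical
sources — grey-matter grid, term–voxel association maps, receptor z-maps,
transcriptome sample sites, lesion cohorts and tractographies — is generated
here with known ground truth, so that recovery can be verified exactly.

All generators are pure functions of their arguments and a seed: rerunning
with identical inputs yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class SizingError(ValueError):
    """Grid or region too small to host the requested structure."""


@dataclass(frozen=True)
class GridSpec:
    """Shared voxel grid: all volumes in one run live on the same grid."""

    dims: tuple[int, int, int]
    voxel_size_mm: float = 2.0

    def __post_init__(self):
        if len(self.dims) != 3 or any(d < 8 for d in self.dims):
            raise SizingError(f"each grid dimension must be >= 8, got {self.dims}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return a


@dataclass
class BrainWorld:
    """Grey-matter mask, vascular territory atlases, and planted networks.

    ``planted_networks`` assigns every grey voxel to exactly one latent
    functional network; the vascular label volumes partition the mask
    geometrically (coarse: anterior/posterior x hemisphere, 4 labels;
    fine: 6 wedges).
    """

    spec: GridSpec
    gm_mask: np.ndarray
    vascular_labels_coarse: np.ndarray
    vascular_labels_fine: np.ndarray
    planted_networks: np.ndarray
    seed: int

    @property
    def n_networks(self) -> int:
        return int(self.planted_networks.max())

    @property
    def anterior_posterior_labels(self) -> np.ndarray:
        """Two-territory atlas (1 = anterior, 2 = posterior), hemispheres
        collapsed — the conventional coarse baseline of stroke trials."""
        out = np.zeros(self.spec.dims, dtype=np.int32)
        half = self.spec.dims[1] // 2
        out[..., :half, :][self.gm_mask[..., :half, :]] = 1
        out[..., half:, :][self.gm_mask[..., half:, :]] = 2
        return out

    def network_mask(self, network_id: int) -> np.ndarray:
        return self.planted_networks == network_id


@dataclass
class TermMatrix:
    """Term-by-voxel association scores (synthetic meta-analytic maps)."""

    terms: list[str]
    scores: np.ndarray          # (T, V)
    voxel_index: np.ndarray     # (V, 3) voxel coordinate of each column
    term_networks: np.ndarray   # (T,) planted network id of each term
    grid_shape: tuple | None = None


@dataclass
class ReceptorSet:
    names: list[str]
    zmaps: list[np.ndarray]


@dataclass
class TranscriptomeSamples:
    sites: np.ndarray           # (S, 3) voxel coordinates
    profiles: np.ndarray        # (S, G)
    planted_split: np.ndarray   # (S,) labels in {1, 2}


@dataclass
class LesionCohort:
    patients: list[tuple[str, np.ndarray]]
    seed: int

    def __len__(self) -> int:
        return len(self.patients)


@dataclass
class TractSet:
    """Surrogate tractography: per subject, a set of voxel paths."""

    subjects: list[list[np.ndarray]]   # each path (L, 3), step-adjacent

    def __len__(self) -> int:
        return len(self.subjects)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _ellipsoid_mask(dims: tuple[int, int, int]) -> np.ndarray:
    c = (np.asarray(dims) - 1) / 2.0
    r = np.asarray(dims) * 0.42
    grids = np.indices(dims).astype(float)
    d2 = sum(((grids[i] - c[i]) / r[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def generate_world(spec: GridSpec, n_networks: int, seed: int) -> BrainWorld:
    """Build a grey-matter world with contiguous planted networks.

    Networks are grown simultaneously from random seed voxels by repeated
    dilation inside the mask, yielding a contiguous partition of grey matter.
    """
    if n_networks < 2:
        raise ValueError("n_networks must be >= 2")
    gm = _ellipsoid_mask(spec.dims)
    n_gm = int(gm.sum())
    if n_networks > n_gm // 32:
        raise SizingError(
            f"grid {spec.dims} has {n_gm} grey voxels; cannot host "
            f"{n_networks} networks (need >= 32 voxels each)"
        )
    rng = np.random.default_rng(seed)
    coords = np.argwhere(gm)
    seeds = coords[rng.choice(n_gm, size=n_networks, replace=False)]

    labels = np.zeros(spec.dims, dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        labels[tuple(s)] = i
    # simultaneous region growth: each round, every label claims the
    # unassigned mask voxels adjacent to it; claim order shuffled per round
    while True:
        unassigned = gm & (labels == 0)
        if not unassigned.any():
            break
        claimed_any = False
        order = rng.permutation(n_networks) + 1
        new_labels = labels.copy()
        for lab in order:
            grown = ndimage.binary_dilation(labels == lab, structure=_STRUCT6)
            claim = grown & gm & (new_labels == 0)
            if claim.any():
                new_labels[claim] = lab
                claimed_any = True
        labels = new_labels
        if not claimed_any:     # isolated mask component: nearest label wins
            from scipy.spatial import cKDTree

            assigned = np.argwhere(labels > 0)
            tree = cKDTree(assigned)
            rest = np.argwhere(unassigned)
            _, idx = tree.query(rest, k=1)
            labels[tuple(rest.T)] = labels[tuple(assigned[idx].T)]
            break

    coarse = np.zeros(spec.dims, dtype=np.int32)
    fine = np.zeros(spec.dims, dtype=np.int32)
    xs, ys, _ = np.indices(spec.dims)
    hemi = (xs >= spec.dims[0] / 2).astype(np.int32)          # 0=L, 1=R
    antpost = (ys >= spec.dims[1] / 2).astype(np.int32)       # 0=ant, 1=post
    coarse[gm] = (1 + 2 * antpost + hemi)[gm]
    third = (np.minimum(3 * ys // spec.dims[1], 2)).astype(np.int32)
    fine[gm] = (1 + 3 * hemi + third)[gm]
    return BrainWorld(spec, gm, coarse, fine, labels, seed)


def generate_term_matrix(
    world: BrainWorld,
    terms_per_network: int,
    noise_sd: float,
    effect: float,
    seed: int,
) -> TermMatrix:
    """Term scores = effect * [term's network == voxel's network] + noise."""
    if effect <= 0:
        raise ValueError("effect must be > 0 for recoverable structure")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    net_ids = np.arange(1, world.n_networks + 1)
    voxel_index = np.argwhere(world.gm_mask)
    voxel_nets = world.planted_networks[world.gm_mask]
    term_networks = np.repeat(net_ids, terms_per_network)
    terms = [
        f"term_n{n}_{j}" for n in net_ids for j in range(terms_per_network)
    ]
    membership = (term_networks[:, None] == voxel_nets[None, :]).astype(float)
    scores = effect * membership
    if noise_sd > 0:
        scores = scores + rng.normal(0.0, noise_sd, size=scores.shape)
    return TermMatrix(terms, scores, voxel_index, term_networks, world.spec.dims)


def generate_receptors(
    world: BrainWorld, n_receptors: int, smoothness_vox: float, seed: int
) -> ReceptorSet:
    """Smoothed random fields standardized to z-scores on grey matter."""
    if n_receptors < 2:
        raise ValueError("n_receptors must be >= 2")
    if smoothness_vox <= 0:
        raise ValueError("smoothness_vox must be positive")
    rng = np.random.default_rng(seed)
    zmaps, names = [], []
    for r in range(n_receptors):
        f = ndimage.gaussian_filter(
            rng.standard_normal(world.spec.dims), sigma=smoothness_vox
        )
        vals = f[world.gm_mask]
        z = np.zeros(world.spec.dims)
        z[world.gm_mask] = (vals - vals.mean()) / vals.std()
        zmaps.append(z)
        names.append(f"receptor_{r}")
    return ReceptorSet(names, zmaps)


def generate_transcriptome(
    world: BrainWorld,
    sites_per_network: int,
    n_genes: int,
    split_effect: float,
    seed: int,
) -> TranscriptomeSamples:
    """Sample sites per network with a planted spatial two-way split.

    Each network's sites are divided by a half-plane along the network's
    widest axis; the two sides receive opposite-signed copies of a random
    gene pattern scaled by ``split_effect``, on top of unit noise.
    """
    if sites_per_network < 4:
        raise ValueError("sites_per_network must be >= 4")
    rng = np.random.default_rng(seed)
    all_sites, all_profiles, all_split = [], [], []
    for net in range(1, world.n_networks + 1):
        coords = np.argwhere(world.network_mask(net))
        if len(coords) < sites_per_network:
            raise SizingError(
                f"network {net} has {len(coords)} voxels; cannot place "
                f"{sites_per_network} sample sites"
            )
        axis = int(np.argmax(coords.max(axis=0) - coords.min(axis=0)))
        cut = np.median(coords[:, axis])
        side1 = coords[coords[:, axis] < cut]
        side2 = coords[coords[:, axis] >= cut]
        n1 = sites_per_network // 2
        n2 = sites_per_network - n1
        if len(side1) < n1 or len(side2) < n2:
            raise SizingError(f"network {net} too thin for a balanced split")
        s1 = side1[rng.choice(len(side1), n1, replace=False)]
        s2 = side2[rng.choice(len(side2), n2, replace=False)]
        pattern = rng.standard_normal(n_genes)
        for sites, sign, lab in ((s1, +1.0, 1), (s2, -1.0, 2)):
            prof = sign * (split_effect / 2.0) * pattern + rng.standard_normal(
                (len(sites), n_genes)
            )
            all_sites.append(sites)
            all_profiles.append(prof)
            all_split.append(np.full(len(sites), lab, dtype=np.int32))
    return TranscriptomeSamples(
        np.concatenate(all_sites),
        np.concatenate(all_profiles),
        np.concatenate(all_split),
    )


def generate_lesions(
    world: BrainWorld,
    n_patients: int,
    size_range_vox: tuple[int, int] = (20, 400),
    frequency_map: np.ndarray | None = None,
    seed: int = 0,
    max_retries: int = 10,
) -> LesionCohort:
    """Grow one connected lesion per synthetic patient.

    Seed voxels are drawn proportionally to ``frequency_map`` (uniform on
    the grey-matter mask if none); lesions grow by stochastic region
    growing within the mask to a size uniform in ``size_range_vox``.
    """
    lo, hi = size_range_vox
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid size range {size_range_vox}")
    if hi > np.prod(world.spec.dims) / 4:
        raise SizingError("max lesion size exceeds a quarter of the grid")
    rng = np.random.default_rng(seed)
    gm_coords = np.argwhere(world.gm_mask)
    if frequency_map is None:
        probs = np.full(len(gm_coords), 1.0 / len(gm_coords))
    else:
        w = np.asarray(frequency_map, dtype=float)[world.gm_mask]
        if w.min() < 0 or w.sum() <= 0:
            raise ValueError("frequency_map must be nonnegative with mass on the mask")
        probs = w / w.sum()

    gm_set = world.gm_mask
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    dims = world.spec.dims
    patients = []
    for i in range(n_patients):
        target = int(rng.integers(lo, hi + 1))
        lesion = None
        for _ in range(max_retries):
            start = tuple(gm_coords[rng.choice(len(gm_coords), p=probs)])
            grown = {start}
            frontier = set()
            for dx, dy, dz in offsets:
                v = (start[0] + dx, start[1] + dy, start[2] + dz)
                if all(0 <= v[a] < dims[a] for a in range(3)) and gm_set[v]:
                    frontier.add(v)
            while len(grown) < target and frontier:
                pick = list(frontier)[int(rng.integers(len(frontier)))]
                frontier.discard(pick)
                grown.add(pick)
                for dx, dy, dz in offsets:
                    v = (pick[0] + dx, pick[1] + dy, pick[2] + dz)
                    if (
                        all(0 <= v[a] < dims[a] for a in range(3))
                        and gm_set[v]
                        and v not in grown
                    ):
                        frontier.add(v)
            if len(grown) == target:
                lesion = grown
                break
        if lesion is None:
            raise SizingError(
                f"could not grow a lesion of {target} voxels after "
                f"{max_retries} attempts"
            )
        vol = np.zeros(dims, dtype=bool)
        vol[tuple(np.array(sorted(lesion)).T)] = True
        patients.append((f"p{i:04d}", vol))
    return LesionCohort(patients, seed)


def generate_tracts(
    world: BrainWorld, n_subjects: int, bundles_per_subject: int, seed: int
) -> TractSet:
    """Smooth random walks between grey regions, jittered per subject."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    gm_coords = np.argwhere(world.gm_mask)
    dims = np.asarray(world.spec.dims)
    endpoints = [
        (
            gm_coords[rng.integers(len(gm_coords))],
            gm_coords[rng.integers(len(gm_coords))],
        )
        for _ in range(bundles_per_subject)
    ]
    subjects = []
    for s in range(n_subjects):
        bundles = []
        for start, end in endpoints:
            a = np.clip(start + rng.integers(-2, 3, size=3), 0, dims - 1)
            b = np.clip(end + rng.integers(-2, 3, size=3), 0, dims - 1)
            path = [a.copy()]
            cur = a.astype(int)
            budget = int(4 * dims.sum())
            while not np.array_equal(cur, b):
                step = np.sign(b - cur)
                if budget > 0:
                    jitter = rng.integers(-1, 2, size=3)
                    use = rng.random(3) < 0.3
                    step = np.where(use, jitter, step)
                cur = np.clip(cur + step, 0, dims - 1)
                budget -= 1
                if not np.array_equal(cur, path[-1]):
                    path.append(cur.copy())
            bundles.append(np.array(path, dtype=np.int64))
        subjects.append(bundles)
    return TractSet(subjects)


def compute_disconnectome(
    lesion: np.ndarray, tracts: TractSet, include_lesion: bool = True
) -> np.ndarray:
    """Proportion-of-subjects disconnection map for one lesion.

    For each reference subject, every voxel on any of their bundles that
    intersects the lesion is marked disconnected; the output value is the
    fraction of subjects whose disconnection mask covers the voxel. By
    convention the lesion core itself is set to 1 (switchable).
    """
    if len(tracts) == 0:
        raise ValueError("empty TractSet")
    lesion = np.asarray(lesion, dtype=bool)
    counts = np.zeros(lesion.shape, dtype=np.int32)
    for bundles in tracts.subjects:
        mask = np.zeros(lesion.shape, dtype=bool)
        for path in bundles:
            if (path.max(axis=0) >= np.asarray(lesion.shape)).any():
                raise ValueError("tract path exceeds lesion grid")
            if lesion[tuple(path.T)].any():
                mask[tuple(path.T)] = True
        counts += mask
    out = counts / float(len(tracts))
    if include_lesion:
        out[lesion] = 1.0
    return out
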