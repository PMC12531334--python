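"""Phenotype characterizations of controllable expressivity.

Lesion (or disconnectome) volumes are vectorized over the grey-matter mask
and compressed with PCA or NMF to a latent phenotype x in R^d; deep
auto-encoders (AE/VAE) are an optional extra requiring torch. The
low-expressivity baseline codes each patient one-hot by the vascular
territory with the greatest Dice overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF, PCA

from .parcellation import dice

METHODS = ("PCA", "NMF", "AE", "VAE")
DEFAULT_DIMS = (2, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50)


@dataclass
class Embedder:
    method: str
    d: int
    gm_mask: np.ndarray
    fitted_params: object = None
    fit_seed: int = 0

    @property
    def fitted(self) -> bool:
        return self.fitted_params is not None


@dataclass
class BaselineCoding:
    territory: int
    x: np.ndarray               # one-hot over atlas labels


def _vectorize(volumes, gm_mask) -> np.ndarray:
    rows = []
    for v in volumes:
        v = np.asarray(v, dtype=float)
        if v.shape != gm_mask.shape:
            raise ValueError(
                f"volume shape {v.shape} does not match grid {gm_mask.shape}"
            )
        rows.append(v[gm_mask])
    return np.asarray(rows)


def fit_embedder(
    train_volumes,
    method: str,
    d: int,
    gm_mask: np.ndarray,
    seed: int = 0,
) -> Embedder:
    """Fit a latent embedder on training-fold volumes only.

    PCA uses the scikit-learn default (full SVD of the centred matrix);
    NMF requires elementwise-nonnegative inputs and a seeded random
    initialization.
    """
    X = _vectorize(train_volumes, gm_mask)
    if d > X.shape[0]:
        raise ValueError(f"d={d} exceeds the {X.shape[0]} training volumes")
    if method == "PCA":
        model = PCA(n_components=d, random_state=seed).fit(X)
    elif method == "NMF":
        if X.min() < 0:
            raise ValueError("NMF requires nonnegative inputs")
        model = NMF(
            n_components=d, init="random", random_state=seed, max_iter=500
        ).fit(X)
    elif method in ("AE", "VAE"):
        raise ImportError(
            f"{method} embedders are an optional extra requiring torch; "
            "install lesionrx with the deep-learning extra to enable them"
        )
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedder(method, d, gm_mask, model, seed)


def embed(embedder: Embedder, volume: np.ndarray) -> np.ndarray:
    """Deterministic latent phenotype of one volume (or a stack)."""
    if not embedder.fitted:
        raise ValueError("embedder is not fitted")
    single = np.asarray(volume).ndim == 3
    vols = [volume] if single else list(volume)
    X = _vectorize(vols, embedder.gm_mask)
    Z = embedder.fitted_params.transform(X)
    return Z[0] if single else Z


def inverse_embed(embedder: Embedder, x: np.ndarray) -> np.ndarray:
    """Map a latent phenotype back to a volume (PCA/NMF reconstruction)."""
    if not embedder.fitted:
        raise ValueError("embedder is not fitted")
    flat = embedder.fitted_params.inverse_transform(np.atleast_2d(x))[0]
    out = np.zeros(embedder.gm_mask.shape)
    out[embedder.gm_mask] = flat
    return out


def archetype(embedder: Embedder, component_index: int) -> np.ndarray:
    """Volume image of one latent direction (PCA loading / NMF basis)."""
    if not embedder.fitted:
        raise ValueError("embedder is not fitted")
    if not 0 <= component_index < embedder.d:
        raise IndexError(
            f"component {component_index} out of range for d={embedder.d}"
        )
    comp = embedder.fitted_params.components_[component_index]
    out = np.zeros(embedder.gm_mask.shape)
    out[embedder.gm_mask] = comp
    return out


def baseline_phenotype(lesion: np.ndarray, atlas: np.ndarray) -> BaselineCoding:
    """One-hot vascular-territory coding by maximal Dice overlap.

    Ties are broken toward the lowest label id. The coding's length equals
    the number of nonzero atlas labels.
    """
    lesion = np.asarray(lesion, bool)
    if not lesion.any():
        raise ValueError("empty lesion")
    labels = np.unique(atlas)
    labels = labels[labels > 0]
    scores = []
    for lab in labels:
        mask = atlas == lab
        scores.append(dice(lesion, mask) if mask.any() else 0.0)
    scores = np.asarray(scores)
    if scores.max() == 0.0:
        raise ValueError("lesion overlaps no vascular territory")
    best = int(np.argmax(scores))   # argmax takes the first (lowest label) on ties
    x = np.zeros(len(labels))
    x[best] = 1.0
    return BaselineCoding(int(labels[best]), x)
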