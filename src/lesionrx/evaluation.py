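"""Cross-validated virtual-trial execution and evaluation.

Runs (condition x representation x learner) cells of the experiment grid
under patient-grouped k-fold cross-validation, scoring each validation fold
with balanced accuracy (dual responders excluded) and PEHE (dual responders
included), and provides the between-condition statistics: pooled-variance
t-tests, Cohen's d, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ground_truth import NoiseConfig, ResponsivenessRecord
from .learners import (
    BaseLearnerSpec,
    DegenerateDataError,
    estimate_cate,
    fit_s_learner,
    fit_t_learner,
    prescribe,
)
from .parcellation import SubnetworkPair
from .representations import baseline_phenotype, embed, fit_embedder
from .trial import (
    AllocationPolicy,
    TrialDataset,
    allocate_observable,
    allocate_unobservable,
    centroid,
    check_fittable,
    confounding_axis,
    sample_outcomes,
)


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable per-cell seed: CRC-32 of the master seed and cell tokens."""
    key = "|".join([str(master_seed), *map(str, tokens)])
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


@dataclass
class FoldSplit:
    k: int
    assignments: dict               # patient_id -> fold index

    def fold_ids(self, j: int) -> list:
        return [p for p, f in self.assignments.items() if f == j]


def make_folds(patient_ids, k: int = 10, seed: int = 0) -> FoldSplit:
    """Random patient-level partition into k folds, fixed before any
    fitting; duplicate ids share a fold by construction."""
    unique = list(dict.fromkeys(patient_ids))
    if len(unique) < k:
        raise ValueError(f"{len(unique)} patients cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(unique))
    assignments = {}
    for j, chunk in enumerate(np.array_split(perm, k)):
        for idx in chunk:
            assignments[unique[idx]] = j
    return FoldSplit(k, assignments)


def balanced_accuracy(prescriptions, hidden) -> float | None:
    """Mean of per-class correct-prescription proportions over the two
    single-responder classes; dual responders (s=0) are excluded. Returns
    None (with a warning) when either class is absent."""
    w = np.asarray(prescriptions)
    s = np.array([rec.s for rec in hidden])
    if len(w) != len(s):
        raise ValueError("prescriptions and hidden records differ in length")
    pos, neg = s == 1, s == -1
    if not pos.any() or not neg.any():
        warnings.warn("a responder class is absent; balanced accuracy undefined")
        return None
    return 0.5 * float((w[pos] == "A").mean()) + 0.5 * float((w[neg] == "B").mean())


def pehe(tau_hat, tau) -> float:
    """Root-mean-square error between estimated and true individual
    effects, over all validation participants including dual responders."""
    tau_hat, tau = np.asarray(tau_hat, float), np.asarray(tau, float)
    if tau_hat.shape != tau.shape:
        raise ValueError("tau_hat and tau differ in shape")
    if tau_hat.size == 0:
        raise ValueError("PEHE undefined on an empty fold")
    return float(np.sqrt(np.mean((tau_hat - tau) ** 2)))


@dataclass
class Comparison:
    t: float
    p: float
    cohens_d: float
    significant: bool | None = None


def compare_groups(metric_a, metric_b) -> Comparison:
    """Two-sided pooled-variance t-test plus Cohen's d (pooled SD)."""
    a, b = np.asarray(metric_a, float), np.asarray(metric_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return Comparison(0.0, 1.0, 0.0)
        return Comparison(
            np.inf if a.mean() > b.mean() else -np.inf,
            0.0,
            np.inf if a.mean() > b.mean() else -np.inf,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    return Comparison(float(t), float(p), float(d))


def bh_adjust(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level q."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


@dataclass(frozen=True)
class RepresentationSpec:
    kind: str                   # 'embedding' | 'atlas' | 'oracle'
    method: str = "PCA"
    d: int = 10

    @property
    def name(self) -> str:
        if self.kind == "embedding":
            return f"{self.method}-{self.d}"
        return self.kind


@dataclass(frozen=True)
class LearnerConfig:
    meta: str                   # 'S' | 'T'
    base: BaseLearnerSpec

    @property
    def name(self) -> str:
        return f"{self.meta}-{self.base.algorithm}"


@dataclass
class TrialResult:
    condition: dict
    fold_ba: list
    fold_pehe: list
    n_val: list
    degenerate: list

    @property
    def mean_ba(self) -> float:
        vals = [b for b in self.fold_ba if b is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_pehe(self) -> float:
        vals = [p for p in self.fold_pehe if p is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def n_degenerate(self) -> int:
        return int(sum(self.degenerate))


def _phenotypes(rep, ids, volumes, hidden_by_id, gm_mask, atlas, train_ids, seed):
    """Per-fold phenotype matrix for ``ids``; embedders see only training
    volumes (the leakage guard is structural: validation volumes are never
    passed to fit)."""
    if rep.kind == "embedding":
        train_vols = [volumes[p] for p in train_ids]
        emb = fit_embedder(train_vols, rep.method, rep.d, gm_mask, seed)
        return np.asarray(embed(emb, [volumes[p] for p in ids]))
    if rep.kind == "atlas":
        if atlas is None:
            raise ValueError("atlas representation requires an atlas volume")
        rows = []
        for p in ids:
            mask = np.asarray(volumes[p]) > 0.5
            rows.append(baseline_phenotype(mask, atlas).x)
        return np.asarray(rows)
    if rep.kind == "oracle":
        return np.array(
            [[hidden_by_id[p].r_A, hidden_by_id[p].r_B] for p in ids], float
        )
    raise ValueError(f"unknown representation kind {rep.kind!r}")


def _allocate(policy, hidden, coords, train_median, seed):
    if policy.kind == "unobservable":
        w = allocate_unobservable(hidden, policy.b_unobs, seed)
        rho = np.full(len(hidden), np.nan)
        return w, rho
    b = 0.0 if policy.kind == "randomized" else policy.b_obs
    ids = [rec.patient_id for rec in hidden]
    return allocate_observable(coords, b, train_median, seed, ids)


def run_condition(
    volumes: dict,
    hidden: list,
    pair: SubnetworkPair,
    gm_mask: np.ndarray,
    rep: RepresentationSpec,
    learner: LearnerConfig,
    policy: AllocationPolicy,
    noise: NoiseConfig,
    folds: FoldSplit,
    master_seed: int = 0,
    condition_key: str = "",
    atlas: np.ndarray | None = None,
    outcome_semantics: str = "branch",
) -> TrialResult:
    """One (condition x representation x learner) cell over all folds.

    Per fold: fit the phenotype representation on the training patients,
    allocate treatments (training-set median anchors the deterministic
    extremes), sample outcomes, fit the meta-learner if the training data
    are fittable, then prescribe and estimate the CATE on the validation
    patients.
    """
    hidden_by_id = {rec.patient_id: rec for rec in hidden}
    axis = confounding_axis(pair).axis if policy.kind != "unobservable" else 0
    coords_by_id = {}
    for rec in hidden:
        if policy.kind != "unobservable":
            coords_by_id[rec.patient_id] = centroid(
                np.asarray(volumes[rec.patient_id]) > 0.5
            )[axis]
        else:
            coords_by_id[rec.patient_id] = 0.0

    fold_ba, fold_pehe, fold_n, fold_deg = [], [], [], []
    for j in range(folds.k):
        val_ids = [r.patient_id for r in hidden if folds.assignments[r.patient_id] == j]
        train_ids = [r.patient_id for r in hidden if folds.assignments[r.patient_id] != j]
        if len(val_ids) == 0 or len(train_ids) < 2:
            fold_ba.append(None); fold_pehe.append(None)
            fold_n.append(len(val_ids)); fold_deg.append(True)
            continue
        seed_rep = derive_seed(master_seed, condition_key, j, "rep")
        X_train = _phenotypes(
            rep, train_ids, volumes, hidden_by_id, gm_mask, atlas, train_ids, seed_rep
        )
        X_val = _phenotypes(
            rep, val_ids, volumes, hidden_by_id, gm_mask, atlas, train_ids, seed_rep
        )
        h_train = [hidden_by_id[p] for p in train_ids]
        h_val = [hidden_by_id[p] for p in val_ids]
        train_median = float(np.median([coords_by_id[p] for p in train_ids]))
        w_train, rho_train = _allocate(
            policy, h_train, np.array([coords_by_id[p] for p in train_ids]),
            train_median, derive_seed(master_seed, condition_key, j, "alloc-train"),
        )
        w_val, _ = _allocate(
            policy, h_val, np.array([coords_by_id[p] for p in val_ids]),
            train_median, derive_seed(master_seed, condition_key, j, "alloc-val"),
        )
        y_train = sample_outcomes(
            h_train, w_train, noise,
            derive_seed(master_seed, condition_key, j, "y-train"),
            outcome_semantics,
        )
        ds_train = TrialDataset(
            train_ids, X_train, w_train, y_train, h_train, policy, noise, rho_train
        )
        if check_fittable(ds_train, learner.meta) == "degenerate":
            fold_ba.append(None); fold_pehe.append(None)
            fold_n.append(len(val_ids)); fold_deg.append(True)
            continue
        fit = fit_t_learner if learner.meta == "T" else fit_s_learner
        try:
            model = fit(X_train, w_train, y_train, learner.base)
        except DegenerateDataError:
            fold_ba.append(None); fold_pehe.append(None)
            fold_n.append(len(val_ids)); fold_deg.append(True)
            continue
        presc = prescribe(model, X_val)
        tau_hat = estimate_cate(model, X_val).tau_hat
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ba = balanced_accuracy(presc, h_val)
        fold_ba.append(ba)
        fold_pehe.append(pehe(tau_hat, np.array([r.tau for r in h_val])))
        fold_n.append(len(val_ids))
        fold_deg.append(False)
    condition = {
        "network": pair.network_id,
        "criterion": pair.criterion,
        "TE": noise.TE,
        "RE": noise.RE,
        "policy": policy.kind,
        "b_obs": policy.b_obs,
        "b_unobs": policy.b_unobs,
        "representation": rep.name,
        "learner": learner.name,
    }
    return TrialResult(condition, fold_ba, fold_pehe, fold_n, fold_deg)


def results_table(results: list) -> pd.DataFrame:
    """Tidy one-row-per-fold table from a list of TrialResults."""
    rows = []
    for res in results:
        for j, (ba, pe, n, deg) in enumerate(
            zip(res.fold_ba, res.fold_pehe, res.n_val, res.degenerate)
        ):
            rows.append(
                {**res.condition, "fold": j, "balanced_accuracy": ba,
                 "pehe": pe, "n_val": n, "degenerate": deg}
            )
    return pd.DataFrame(rows)


@dataclass
class GridConfig:
    """Enumerable levels of a (possibly reduced) experiment grid."""

    networks: list
    criteria: list
    rep_kinds: list
    te_levels: list
    re_levels: list
    policies: list
    representations: list
    learners: list
    k_folds: int = 10
    master_seed: int = 0


def run_grid(assets, grid: GridConfig, tau_mode: str = "effect_scaled"):
    """Cartesian product of condition levels crossed with representation x
    learner configurations; returns the tidy per-fold results table and
    the cell accounting. Conditions whose cohort is empty are skipped with
    a degenerate row."""
    from .ground_truth import EmptyTrialError, build_cohort

    results = []
    for net, crit, rep_kind, te, re_, policy in product(
        grid.networks, grid.criteria, grid.rep_kinds,
        grid.te_levels, grid.re_levels, grid.policies,
    ):
        noise = NoiseConfig(te, re_)
        pair = assets.pair(net, crit)
        try:
            hidden = build_cohort(
                assets.lesions, pair, noise, rep_kind,
                tracts=assets.tracts, tau_mode=tau_mode,
            )
        except EmptyTrialError:
            continue
        volumes = assets.volumes(rep_kind)
        folds = make_folds(
            [r.patient_id for r in hidden], grid.k_folds,
            derive_seed(grid.master_seed, "folds"),
        )
        for rep, learner in product(grid.representations, grid.learners):
            key = f"{net}|{crit}|{rep_kind}|{te}|{re_}|{policy.kind}|" \
                  f"{policy.b_obs}|{policy.b_unobs}|{rep.name}|{learner.name}"
            res = run_condition(
                volumes, hidden, pair, assets.gm_mask, rep, learner,
                policy, noise, folds, grid.master_seed, key,
                atlas=getattr(assets, "baseline_atlas", None),
            )
            res.condition["rep_kind"] = rep_kind
            results.append(res)
    table = results_table(results)
    accounting = grid_accounting(
        len(grid.networks), len(grid.criteria), len(grid.rep_kinds),
        len(grid.te_levels), len(grid.re_levels), len(grid.policies),
        len(grid.representations), len(grid.learners), grid.k_folds,
    )
    return table, accounting


def grid_accounting(
    n_networks: int,
    n_criteria: int,
    n_rep_kinds: int,
    n_te: int,
    n_re: int,
    n_policies: int,
    n_representations: int,
    n_learners: int,
    k_folds: int,
) -> dict:
    """Experiment-grid cell counts: conditions are the product of the
    trial-defining levels; each is crossed with every representation x
    learner configuration and evaluated per fold."""
    conditions = n_networks * n_criteria * n_rep_kinds * n_te * n_re * n_policies
    configs = n_representations * n_learners
    return {
        "conditions": conditions,
        "configs": configs,
        "folds": k_folds,
        "total_simulations": conditions * configs * k_folds,
    }


def representation_count(n_baselines: int, dims, n_methods: int) -> int:
    """Representations per trial: atlas baselines plus every
    dimensionality of every embedding method."""
    return n_baselines + len(tuple(dims)) * n_methods


# Full-scale accounting preset: 16 functional networks, 2 responsiveness
# criteria, 2 lesion input representations, 4 TE x 4 RE noise levels and 11
# confounding levels under 2 observability regimes; 46 representations
# (2 atlas baselines + 11 dimensionalities x 4 embedding methods) x 10
# learner configurations (5 base algorithms x S/T); 10 folds.
FULL_SCALE_GRID = {
    "n_networks": 16,
    "n_criteria": 2,
    "n_rep_kinds": 2,
    "n_te": 4,
    "n_re": 4,
    "n_policies": 22,
    "n_representations": representation_count(2, range(11), 4),
    "n_learners": 10,
    "k_folds": 10,
}


def full_scale_accounting() -> dict:
    return grid_accounting(**FULL_SCALE_GRID)
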