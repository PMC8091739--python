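"""Gene prioritization: resampled training datasets, from-scratch SMOTE,
leakage-safe grid-searched gradient-boosted classifiers, and ensemble mean
positive-class probability ranking.

Each of the ``n_datasets`` datasets holds every known positive gene plus
``n_negatives`` genes sampled uniformly without replacement from the rest
of the universe. Within each dataset a grid search with stratified 5-fold
cross-validation picks boosting hyperparameters; the class balance is
restored by SMOTE applied *after* the fold split, to the training portion
only, so no synthetic row ever reaches a validation fold. Genes outside
the positive set are ranked by the mean positive-class probability over
all fitted models.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pin2target.embedding import LatentFeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """One resampled training dataset with per-row provenance."""

    index: int
    features: np.ndarray
    labels: np.ndarray  # 1 = positive, 0 = negative
    genes: list[str]  # gene id per row ("<synthetic>" for SMOTE rows)
    synthetic: np.ndarray  # bool per row

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.features) == n == len(self.genes) == len(self.synthetic)):
            raise ValueError("dataset arrays are not aligned")
        overlap = {g for g, y in zip(self.genes, self.labels) if y == 1} & {
            g for g, y in zip(self.genes, self.labels) if y == 0
        }
        if overlap:
            raise ValueError(f"genes labeled both positive and negative: {overlap}")


@dataclass
class GridConfig:
    """Hyperparameter grid for the boosted-tree classifier.

    Field names follow the gradient-boosting convention (gamma = minimum
    split gain, reg_alpha = L1-style complexity penalty). The backing
    implementation is scikit-learn's GradientBoostingClassifier, which maps
    gamma -> min_impurity_decrease and reg_alpha -> ccp_alpha and has no L2
    leaf penalty, so grid points differing only in reg_lambda collapse to
    one effective point (deduplicated, first occurrence kept).
    """

    learning_rate: tuple[float, ...] = (0.01, 0.1, 0.5)
    max_depth: tuple[int, ...] = (1, 2, 3, 5, 10)
    n_estimators: int = 100
    gamma: tuple[float, ...] = (0.0, 0.3)
    reg_lambda: tuple[float, ...] = (0.0, 0.1, 1.0)
    reg_alpha: tuple[float, ...] = (0.0, 0.1, 1.0)
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def iter_points(self):
        """Documented iteration order: learning_rate, max_depth, gamma,
        reg_lambda, reg_alpha; deduplicated after backend mapping."""
        seen = set()
        for lr, depth, gamma, lam, alpha in itertools.product(
            self.learning_rate, self.max_depth, self.gamma,
            self.reg_lambda, self.reg_alpha,
        ):
            params = {
                "learning_rate": lr,
                "max_depth": depth,
                "n_estimators": self.n_estimators,
                "min_impurity_decrease": gamma,
                "ccp_alpha": alpha,
            }
            key = tuple(sorted(params.items()))
            if key in seen:
                continue
            seen.add(key)
            yield params


SMALL_GRID = GridConfig(
    learning_rate=(0.1,),
    max_depth=(2, 3),
    gamma=(0.0,),
    reg_lambda=(0.0,),
    reg_alpha=(0.0,),
)


def build_datasets(
    latent: LatentFeatureMatrix,
    positives: set[str],
    n_datasets: int = 100,
    n_negatives: int = 500,
    seed: int = 0,
) -> list[LabeledDataset]:
    """All positives plus ``n_negatives`` uniformly resampled negatives per
    dataset (without replacement within a dataset, independent across)."""
    gene_index = {g: i for i, g in enumerate(latent.genes)}
    missing = positives - set(gene_index)
    if missing:
        raise ValueError(f"positives not in the gene universe: {sorted(missing)}")
    pos = sorted(positives)
    neg_pool = [g for g in latent.genes if g not in positives]
    if n_negatives > len(neg_pool):
        raise ValueError(
            f"requested {n_negatives} negatives but only {len(neg_pool)} available"
        )
    datasets = []
    for d in range(n_datasets):
        rng = np.random.default_rng(seed + d)
        chosen = rng.choice(len(neg_pool), size=n_negatives, replace=False)
        negs = [neg_pool[i] for i in sorted(chosen)]
        genes = pos + negs
        rows = np.array([gene_index[g] for g in genes])
        labels = np.array([1] * len(pos) + [0] * len(negs))
        datasets.append(
            LabeledDataset(
                index=d,
                features=latent.values[rows],
                labels=labels,
                genes=genes,
                synthetic=np.zeros(len(genes), dtype=bool),
            )
        )
    return datasets


def smote_oversample(
    minority_rows: np.ndarray, k: int = 2, n_synthetic: int = 0, seed: int = 0
) -> np.ndarray:
    """Synthetic minority rows by interpolation toward k-nearest neighbors.

    Each synthetic row is ``x + u * (x_nn - x)`` for a uniformly drawn base
    row x, one of its k Euclidean nearest minority neighbors (uniform among
    the k), and u ~ Uniform(0, 1). k is capped at ``len(minority) - 1``.
    """
    x = np.asarray(minority_rows, dtype=float)
    if len(x) < 2:
        raise ValueError("SMOTE needs at least 2 minority rows")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(x) - 1)
    rng = np.random.default_rng(seed)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    out = np.empty((n_synthetic, x.shape[1]))
    for s in range(n_synthetic):
        i = int(rng.integers(len(x)))
        j = int(nn[i, int(rng.integers(k))])
        u = rng.random()
        out[s] = x[i] + u * (x[j] - x[i])
    return out


def _balance_with_smote(
    features: np.ndarray, labels: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Append synthetic minority rows to exact class parity. Returns
    (features, labels, synthetic_flags)."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    minority_label = 1 if n_pos < n_neg else 0
    n_synth = abs(n_neg - n_pos)
    if n_synth == 0:
        return features, labels, np.zeros(len(labels), dtype=bool)
    minority = features[labels == minority_label]
    synth = smote_oversample(minority, k=k, n_synthetic=n_synth, seed=seed)
    feats = np.vstack([features, synth])
    labs = np.concatenate([labels, np.full(n_synth, minority_label)])
    flags = np.concatenate(
        [np.zeros(len(labels), dtype=bool), np.ones(n_synth, dtype=bool)]
    )
    return feats, labs, flags


@dataclass
class DatasetFit:
    """Grid-search outcome for one resampled dataset."""

    index: int
    model: GradientBoostingClassifier
    best_params: dict
    cv_auc: float
    leakage_audit: list[int]  # synthetic rows seen per validation fold (must be 0)


def fit_one_dataset(
    dataset: LabeledDataset,
    grid: GridConfig | None = None,
    seed: int = 0,
    smote_k: int = 2,
) -> DatasetFit:
    """Grid search with stratified CV; SMOTE applied inside the training
    folds only; best point refitted on the fully balanced dataset."""
    grid = grid or GridConfig()
    y = dataset.labels
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("dataset must contain both classes")
    skf = StratifiedKFold(n_splits=grid.cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(dataset.features, y))
    for f, (_, val_idx) in enumerate(folds):
        if y[val_idx].sum() == 0:
            raise ValueError(
                f"fold {f} has no positives; check stratification / class sizes"
            )

    # balance each training fold once; folds are shared across grid points
    prepared = []
    audit = []
    for f, (tr_idx, val_idx) in enumerate(folds):
        feats, labs, flags = _balance_with_smote(
            dataset.features[tr_idx], y[tr_idx], k=smote_k, seed=seed * 1000 + f
        )
        n_leaked = int(dataset.synthetic[val_idx].sum())
        audit.append(n_leaked)
        prepared.append((feats, labs, dataset.features[val_idx], y[val_idx]))
    if any(audit):
        raise AssertionError(f"synthetic rows leaked into validation: {audit}")

    best_auc, best_params = -np.inf, None
    for params in grid.iter_points():
        fold_aucs = []
        for feats, labs, xv, yv in prepared:
            clf = GradientBoostingClassifier(random_state=seed, **params)
            clf.fit(feats, labs)
            fold_aucs.append(roc_auc_score(yv, clf.predict_proba(xv)[:, 1]))
        mean_auc = float(np.mean(fold_aucs))
        if mean_auc > best_auc:  # strict: ties keep the first grid point
            best_auc, best_params = mean_auc, params

    feats, labs, _ = _balance_with_smote(
        dataset.features, y, k=smote_k, seed=seed * 1000 + 999
    )
    model = GradientBoostingClassifier(random_state=seed, **best_params)
    model.fit(feats, labs)
    return DatasetFit(dataset.index, model, best_params, best_auc, audit)


@dataclass
class EnsembleResult:
    """All per-dataset fits plus the ensemble-level mean CV AUC."""

    fits: list[DatasetFit]
    mean_cv_auc: float

    @property
    def n_models(self) -> int:
        return len(self.fits)

    def cv_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"dataset": f.index, "cv_auc": f.cv_auc, **f.best_params}
                for f in self.fits
            ]
        )


def fit_ensemble(
    datasets: list[LabeledDataset],
    grid: GridConfig | None = None,
    seed: int = 0,
    smote_k: int = 2,
) -> EnsembleResult:
    """One grid-searched classifier per dataset, seeds fanned out from the
    run seed."""
    if not datasets:
        raise ValueError("need at least one dataset")
    fits = [
        fit_one_dataset(ds, grid=grid, seed=seed + ds.index, smote_k=smote_k)
        for ds in datasets
    ]
    mean_auc = float(np.mean([f.cv_auc for f in fits]))
    logger.info("ensemble of %d models, mean CV AUC %.3f", len(fits), mean_auc)
    return EnsembleResult(fits, mean_auc)


def score_genes(
    ensemble: EnsembleResult,
    latent: LatentFeatureMatrix,
    positives: set[str],
) -> pd.Series:
    """Mean positive-class probability per non-positive gene, sorted
    descending (ties broken by gene id for determinism)."""
    mask = np.array([g not in positives for g in latent.genes])
    genes = [g for g in latent.genes if g not in positives]
    x = latent.values[mask]
    probs = np.mean(
        [f.model.predict_proba(x)[:, 1] for f in ensemble.fits], axis=0
    )
    frame = pd.DataFrame({"gene": genes, "p": probs})
    frame = frame.sort_values(["p", "gene"], ascending=[False, True], kind="stable")
    return pd.Series(
        frame["p"].to_numpy(), index=list(frame["gene"]), name="mean_probability"
    ).rename_axis("gene")


@dataclass
class PutativeTargetSet:
    """Genes scoring strictly above the selection threshold."""

    genes: list[str]  # sorted by score descending
    scores: pd.Series
    threshold: float

    def __len__(self) -> int:
        return len(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


def select_putative(scores: pd.Series, threshold: float = 0.75) -> PutativeTargetSet:
    """Strict-inequality cut on the mean positive probability."""
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    selected = scores[scores > threshold]
    if selected.empty:
        logger.warning("no gene exceeds the %.2f threshold", threshold)
    return PutativeTargetSet(list(selected.index), selected, threshold)


def write_scores(scores: pd.Series, path) -> None:
    frame = scores.rename_axis("gene").reset_index()
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")
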