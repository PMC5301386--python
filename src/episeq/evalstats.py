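"""Feature screening, ROC/AUC and leakage-safe grouped cross-validation.

Feature screening uses the two-sample Kolmogorov-Smirnov statistic: the
D-value is the largest vertical distance between the empirical CDFs of a
feature over epitope and non-epitope residues, with an asymptotic p-value.

Prediction performance is the area under the ROC curve, computed so that it
equals the pairwise-ordering (Mann-Whitney) statistic with ties counted 1/2.

Cross-validation splits *by antigen record*: all residues of a protein land
in the same fold, so no window context leaks between training and test.
Within each fold the full training stack -- composition ratios, both
potential models, imputation means, SVM-SMOTE and the voting ensemble -- is
fitted on the training records only, and the oversampling happens strictly
after the split.  SMOTE provenance can be retained per fold to audit that no
synthetic row descends from a test record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from . import ensemble as ens
from .features import FeaturePipeline, FeatureRegistry
from .resample import SmoteConfig, svm_smote
from .seqdata import Corpus


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS D-value and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> dict:
    """ROC curve and AUC; ties contribute 1/2 of a concordant pair.

    Returns ``{"auc", "fpr", "tpr", "thresholds"}``; raises on one-class
    label vectors, where the AUC is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC is undefined for single-class labels")
    fpr, tpr, thr = roc_curve(labels, scores)
    return {
        "auc": float(roc_auc_score(labels, scores)),
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thr,
    }


@dataclass
class FoldResult:
    """One CV fold: which records were held out, test scores, provenance."""

    test_records: list[str]
    train_records: list[str]
    scores: np.ndarray
    labels: np.ndarray
    index: pd.MultiIndex
    auc: float
    smote_provenance: pd.DataFrame | None = None
    #: (record_id, position) of every training matrix row, aligned with the
    #: row indices referenced by ``smote_provenance``.
    train_index: pd.MultiIndex | None = None


@dataclass
class EvaluationReport:
    """Pooled and per-fold CV results plus configuration echo."""

    pooled_auc: float
    fold_aucs: list[float]
    folds: list[FoldResult]
    scores: np.ndarray
    labels: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))


def fold_record_ids(
    record_ids: list[str], k: int, seed: int
) -> list[list[str]]:
    """Deterministic record-level fold assignment from (ids, seed) only."""
    if len(record_ids) < k:
        raise ValueError(f"{len(record_ids)} records cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = list(np.array(record_ids, dtype=object)[rng.permutation(len(record_ids))])
    return [list(chunk) for chunk in np.array_split(order, k)]


def _fit_fold(
    train_corpus: Corpus,
    registry: FeatureRegistry,
    W: int,
    interval: int,
    sigma: float,
    smote: SmoteConfig | None,
    seed: int,
    keep_provenance: bool,
):
    pipeline = FeaturePipeline(
        registry=registry, W=W, interval=interval, sigma=sigma
    ).fit(train_corpus)
    fm = pipeline.transform(train_corpus)
    keep = fm.labeled
    X, y = fm.X[keep], fm.y[keep]
    train_index = fm.index[keep]
    provenance = None
    if smote is not None:
        cfg = SmoteConfig(
            svm_c=smote.svm_c,
            svm_gamma=smote.svm_gamma,
            k_neighbors=smote.k_neighbors,
            target_ratio=smote.target_ratio,
            seed=seed,
        )
        X, y, provenance = svm_smote(X, y, cfg)
        if not keep_provenance:
            provenance = None
    model = ens.train(X, y, seed=seed)
    return pipeline, model, provenance, train_index


def cross_validate(
    corpus: Corpus,
    registry: FeatureRegistry | None = None,
    W: int = 9,
    interval: int = 7,
    sigma: float = 10.0,
    smote: SmoteConfig | None = SmoteConfig(),
    k: int = 10,
    seed: int = 0,
    keep_provenance: bool = False,
) -> EvaluationReport:
    """Grouped k-fold CV of the full pipeline; split before oversampling.

    Fold membership depends only on the record ids and the seed.  Per-fold
    seeds are derived deterministically from ``seed``.
    """
    registry = registry or FeatureRegistry.reduced()
    folds = fold_record_ids([r.id for r in corpus], k, seed)
    all_ids = {r.id for r in corpus}

    results: list[FoldResult] = []
    for fi, test_ids in enumerate(folds):
        train_ids = [r.id for r in corpus if r.id not in set(test_ids)]
        fold_seed = (seed * 1000 + fi) % (2**31 - 1)
        pipeline, model, provenance, train_index = _fit_fold(
            corpus.subset(train_ids),
            registry,
            W,
            interval,
            sigma,
            smote,
            fold_seed,
            keep_provenance,
        )
        fm_test = pipeline.transform(corpus.subset(list(test_ids)))
        keep = fm_test.labeled
        scores = ens.predict_proba(model, fm_test.X[keep])
        labels = fm_test.y[keep]
        fold_auc = (
            roc_auc(scores, labels)["auc"] if np.unique(labels).size == 2 else np.nan
        )
        results.append(
            FoldResult(
                test_records=list(test_ids),
                train_records=train_ids,
                scores=scores,
                labels=labels,
                index=fm_test.index[keep],
                auc=fold_auc,
                smote_provenance=provenance,
                train_index=train_index,
            )
        )
    pooled_scores = np.concatenate([f.scores for f in results])
    pooled_labels = np.concatenate([f.labels for f in results])
    pooled = roc_auc(pooled_scores, pooled_labels)["auc"]
    return EvaluationReport(
        pooled_auc=pooled,
        fold_aucs=[f.auc for f in results],
        folds=results,
        scores=pooled_scores,
        labels=pooled_labels,
        config={
            "registry": registry.names,
            "W": W,
            "interval": interval,
            "sigma": sigma,
            "k": k,
            "seed": seed,
            "smote": None if smote is None else vars(smote).copy(),
            "records": sorted(all_ids),
        },
    )


def audit_smote_leakage(report: EvaluationReport) -> pd.DataFrame:
    """Parents of every synthetic SMOTE row, with the fold they belong to.

    Returns one row per (fold, synthetic row, parent) with the parent's
    record id and whether that record sat in the fold's *test* set -- which
    must never happen when the split precedes the oversampling.
    """
    rows = []
    for fi, fold in enumerate(report.folds):
        if fold.smote_provenance is None:
            continue
        test = set(fold.test_records)
        recs = fold.train_index.get_level_values(0)
        for _, p in fold.smote_provenance.iterrows():
            for which in ("parent_a", "parent_b"):
                rid = recs[int(p[which])]
                rows.append(
                    {
                        "fold": fi,
                        "row": int(p["row"]),
                        "parent": which,
                        "record_id": rid,
                        "in_test_fold": rid in test,
                    }
                )
    return pd.DataFrame(
        rows, columns=["fold", "row", "parent", "record_id", "in_test_fold"]
    )


def ks_screen(
    corpus: Corpus,
    registry: FeatureRegistry | None = None,
    interval: int = 7,
    sigma: float = 10.0,
) -> pd.DataFrame:
    """Per-feature-column KS D and p between epitope and non-epitope rows."""
    registry = registry or FeatureRegistry.reduced()
    pipeline = FeaturePipeline(registry=registry, W=0, interval=interval, sigma=sigma)
    fm = pipeline.fit_transform(corpus)
    keep = fm.labeled
    X, y = fm.X[keep], fm.y[keep]
    out = []
    for ci, cname in enumerate(fm.columns):
        d, p = ks_two_sample(X[y == 1, ci], X[y == 0, ci])
        out.append({"column": cname, "D": d, "p": p})
    return pd.DataFrame(out).set_index("column")


def ablation_single_features(
    corpus: Corpus,
    registry: FeatureRegistry | None = None,
    W_list: list[int] = (0, 3, 5, 7, 9),
    k: int = 10,
    seed: int = 0,
    smote: SmoteConfig | None = SmoteConfig(),
    include_combined: bool = True,
) -> pd.DataFrame:
    """Pooled CV AUC for every single-feature registry at every window size.

    Rows are features (plus ``combined``), columns window sizes.
    """
    registry = registry or FeatureRegistry.reduced()
    rows = {}
    for feat in registry.names:
        sub = registry.subset([feat])
        rows[feat] = {
            W: cross_validate(
                corpus, sub, W=W, k=k, seed=seed, smote=smote
            ).pooled_auc
            for W in W_list
        }
    if include_combined:
        rows["combined"] = {
            W: cross_validate(
                corpus, registry, W=W, k=k, seed=seed, smote=smote
            ).pooled_auc
            for W in W_list
        }
    return pd.DataFrame(rows).T[list(W_list)]


def ablation_sequential(
    corpus: Corpus,
    order: list[str],
    registry: FeatureRegistry | None = None,
    W: int = 9,
    k: int = 10,
    seed: int = 0,
    smote: SmoteConfig | None = SmoteConfig(),
) -> pd.Series:
    """Pooled CV AUC for growing feature prefixes F[0], F[0:2], ...

    AUC is not forced to grow monotonically; plateaus are expected.
    """
    registry = registry or FeatureRegistry.reduced()
    aucs = {}
    for i in range(1, len(order) + 1):
        prefix = order[:i]
        aucs[" + ".join(prefix)] = cross_validate(
            corpus, registry.subset(prefix), W=W, k=k, seed=seed, smote=smote
        ).pooled_auc
    return pd.Series(aucs, name="pooled_auc")
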