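"""Cross-validation protocols and metrics.

10-fold CV partitions the validated pairs into roughly equal folds (balanced
1:1 or imbalanced 1:10 test negatives); LODOCV withholds one disease's entire
column to test cold-start ranking.  AUC is the tie-aware Mann-Whitney
statistic, AUPR the step-integrated precision-recall area; ACC, Precision,
Recall, Specificity and F1 are computed at a fixed 0.5 threshold.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score

from .core_io import AssociationTable, NamedMatrix, ValidationError
from .gae import AdvConfig, EncoderConfig, TrainConfig, score_matrix, train
from .hetgraph import GraphConfig, assemble_hetero_graph, threshold_affinity
from .multiview import AffinityMatrix
from .sampling import SamplerConfig, sample_negatives, sample_negatives_random

METRIC_NAMES = ("auc", "aupr", "acc", "precision", "recall", "specificity", "f1")


@dataclass
class FoldSplit:
    fold_id: int
    train_positives: set[tuple[str, str]]
    test_positives: set[tuple[str, str]]
    train_negatives: set[tuple[str, str]]
    test_negatives: set[tuple[str, str]]

    def __post_init__(self) -> None:
        sets = [
            self.train_positives,
            self.test_positives,
            self.train_negatives,
            self.test_negatives,
        ]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValidationError(f"fold {self.fold_id}: overlapping pair sets")


@dataclass
class EvalReport:
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def mean(self, metric: str) -> float:
        vals = [f[metric] for f in self.per_fold if np.isfinite(f[metric])]
        return float(np.mean(vals)) if vals else float("nan")

    def sd(self, metric: str) -> float:
        vals = [f[metric] for f in self.per_fold if np.isfinite(f[metric])]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in METRIC_NAMES}


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalised Mann-Whitney U statistic (ties score 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def compute_metrics(
    scores, labels, threshold: float = 0.5
) -> dict[str, float]:
    """All evaluation metrics for one scored test set.

    Single-class label vectors leave AUC/AUPR as NaN markers; the thresholded
    confusion metrics are still reported.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be 0/1")
    single_class = labels.min() == labels.max()
    auc = mann_whitney_auc(scores, labels)
    aupr = (
        float("nan")
        if single_class
        else float(average_precision_score(labels, scores))
    )
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    acc = (tp + tn) / len(labels)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "auc": auc,
        "aupr": aupr,
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def kfold_splits(
    assoc: AssociationTable,
    C_ss: AffinityMatrix,
    k: int = 10,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> list[FoldSplit]:
    """Seeded shuffle + contiguous chunking of the positives into k folds.

    Test negatives are drawn per fold at the sampler's configured ratio and
    method; training negatives are drawn uniformly at 1:1 from the remaining
    candidate pool (test pairs excluded — train and test never share a pair).
    The uniform training draw keeps the protocol feasible under the
    guilt-by-association method, whose candidates are confined to the
    positive's disease column: at a 1:10 test ratio a heavily annotated
    disease can exhaust its column with test negatives alone.
    """
    sampler = sampler or SamplerConfig()
    positives = sorted(assoc.positives)
    if len(positives) < k:
        raise ValidationError(f"{len(positives)} positives cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    chunks = np.array_split(order, k)
    universe = [(s, d) for s in assoc.site_index for d in assoc.disease_index]
    folds = []
    for fold_id, chunk in enumerate(chunks):
        test_pos = {positives[i] for i in chunk}
        train_pos = assoc.positives - test_pos
        test_sampler = dataclasses.replace(sampler, seed=sampler.seed + 7919 * fold_id)
        test_neg = sample_negatives(
            test_sampler, test_pos, C_ss, universe, exclude=train_pos, strict=False
        )
        train_neg = sample_negatives_random(
            train_pos,
            universe,
            ratio=1.0,
            seed=test_sampler.seed + 1,
            exclude=test_pos | test_neg,
        )
        folds.append(FoldSplit(fold_id, train_pos, test_pos, train_neg, test_neg))
    return folds


def _train_and_score(
    assoc, C_ss_bin, C_dd_bin, site_feats, disease_feats, graph_config,
    enc, adv, tr, train_pos, train_neg, test_pairs,
):
    train_assoc = AssociationTable(
        positives=set(train_pos),
        negatives=set(train_neg),
        site_index=list(assoc.site_index),
        disease_index=list(assoc.disease_index),
    )
    graph = assemble_hetero_graph(
        C_ss_bin, C_dd_bin, assoc, site_feats, disease_feats, graph_config,
        train_positives=set(train_pos),
    )
    model = train(graph, train_assoc, enc, adv, tr)
    scores = score_matrix(model, graph).values
    idx = assoc.pair_indices(test_pairs)
    return scores[idx[:, 0], idx[:, 1]], model


def run_cv(
    assoc: AssociationTable,
    C_ss: AffinityMatrix,
    C_dd: AffinityMatrix,
    site_feats: NamedMatrix,
    disease_feats: NamedMatrix,
    graph_config: GraphConfig,
    enc: EncoderConfig | None = None,
    adv: AdvConfig | None = None,
    tr: TrainConfig | None = None,
    sampler: SamplerConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """k-fold CV: per fold, rebuild the graph from training positives only,
    train, score the held-out pairs and aggregate the metrics."""
    enc = enc or EncoderConfig()
    adv = adv or AdvConfig()
    tr = tr or TrainConfig()
    C_ss_bin = threshold_affinity(C_ss, graph_config.tau)
    C_dd_bin = threshold_affinity(C_dd, graph_config.tau)
    folds = kfold_splits(assoc, C_ss, k=k, sampler=sampler, seed=seed)
    report = EvalReport()
    for fold in folds:
        test_pairs = sorted(fold.test_positives) + sorted(fold.test_negatives)
        labels = [1] * len(fold.test_positives) + [0] * len(fold.test_negatives)
        fold_enc = dataclasses.replace(enc, seed=enc.seed + fold.fold_id)
        scores, _ = _train_and_score(
            assoc, C_ss_bin, C_dd_bin, site_feats, disease_feats, graph_config,
            fold_enc, adv, tr, fold.train_positives, fold.train_negatives, test_pairs,
        )
        report.per_fold.append(compute_metrics(scores, labels))
    return report


def run_lodocv(
    assoc: AssociationTable,
    C_ss: AffinityMatrix,
    C_dd: AffinityMatrix,
    site_feats: NamedMatrix,
    disease_feats: NamedMatrix,
    graph_config: GraphConfig,
    enc: EncoderConfig | None = None,
    adv: AdvConfig | None = None,
    tr: TrainConfig | None = None,
    sampler: SamplerConfig | None = None,
    diseases: list[str] | None = None,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Leave-one-disease-out CV: per disease, all its pairs are withheld from
    the graph and the loss, every site is scored against it, and the AUC uses
    its validated sites as positives against all remaining sites."""
    enc = enc or EncoderConfig()
    adv = adv or AdvConfig()
    tr = tr or TrainConfig()
    sampler = sampler or SamplerConfig()
    C_ss_bin = threshold_affinity(C_ss, graph_config.tau)
    C_dd_bin = threshold_affinity(C_dd, graph_config.tau)
    universe = [(s, d) for s in assoc.site_index for d in assoc.disease_index]
    targets = diseases if diseases is not None else list(assoc.disease_index)
    results: list[tuple[str, float]] = []
    for di, d in enumerate(targets):
        held = {(s, dd) for (s, dd) in assoc.positives if dd == d}
        if not held:
            warnings.warn(f"disease {d!r} has no validated sites; skipped")
            continue
        train_pos = assoc.positives - held
        if not train_pos:
            warnings.warn(f"all positives belong to disease {d!r}; skipped")
            continue
        column = {(s, d) for s in assoc.site_index}
        neg_sampler = dataclasses.replace(sampler, ratio=1.0, seed=sampler.seed + di)
        train_neg = sample_negatives(
            neg_sampler, train_pos, C_ss, universe, exclude=column
        )
        test_pairs = [(s, d) for s in assoc.site_index]
        labels = np.array([1 if p in held else 0 for p in test_pairs])
        scores, _ = _train_and_score(
            assoc, C_ss_bin, C_dd_bin, site_feats, disease_feats, graph_config,
            enc, adv, tr, train_pos, train_neg, test_pairs,
        )
        results.append((d, mann_whitney_auc(scores, labels)))
    return results


def wilcoxon_compare(metric_vec_a, metric_vec_b) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value (all-zero diffs -> 1.0)."""
    a = np.asarray(metric_vec_a, dtype=float)
    b = np.asarray(metric_vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("paired vectors must have equal length")
    if a.size < 2:
        raise ValidationError("need at least 2 paired observations")
    if np.allclose(a, b):
        return 1.0
    res = stats.wilcoxon(a, b, alternative="two-sided")
    return float(res.pvalue)
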