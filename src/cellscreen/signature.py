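"""Random-forest gene-signature pipeline.

Stages: stratified 66/34 train-test split of the labeled cell lines,
Mann-Whitney feature selection (p < 0.05) on the training set only,
random-forest integration of the significant genes, held-out evaluation
(confusion matrix at probability threshold 0.5, test ROC AUC with
Mann-Whitney p on the predicted probabilities).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .biomarker import mann_whitney, raw_auc, roc_auc
from .datastore import ExpressionMatrix, GeneSet
from .errors import ValidationError
from .response import RESISTANT, SENSITIVE, ResponseLabeling

DEFAULT_TRAIN_FRACTION = 0.66
DEFAULT_N_TREES = 500
DEFAULT_ALPHA = 0.05


@dataclass
class SignatureModel:
    """Fitted classifier plus the feature-gene order it expects."""

    genes: list[str]
    classifier: RandomForestClassifier

    def resistant_probability(self, m: ExpressionMatrix, cell_lines: list[str]) -> np.ndarray:
        X = _feature_matrix(m, self.genes, cell_lines)
        proba = self.classifier.predict_proba(X)
        col = list(self.classifier.classes_).index(RESISTANT)
        return proba[:, col]


@dataclass
class SignatureResult:
    compound: str
    dataset: str
    gene_set_name: str
    selected_genes: list[tuple[str, float, float]]  # (gene, mw_p, auc)
    split_seed: int
    n_train: int
    n_test: int
    confusion: tuple[int, int, int, int]  # TP, FP, TN, FN
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    test_auc: float
    test_auc_p: float
    radar: dict[str, float] = field(default_factory=dict)  # full-cohort per-gene AUCs

    def to_dict(self) -> dict:
        tp, fp, tn, fn = self.confusion
        return {
            "compound": self.compound, "dataset": self.dataset,
            "gene_set_name": self.gene_set_name,
            "selected_genes": [{"gene": g, "mw_p": p, "auc": a}
                               for g, p, a in self.selected_genes],
            "split_seed": self.split_seed, "n_train": self.n_train, "n_test": self.n_test,
            "confusion": {"TP": tp, "FP": fp, "TN": tn, "FN": fn},
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "test_auc": self.test_auc, "test_auc_p": self.test_auc_p,
            "radar": self.radar,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def _feature_matrix(m: ExpressionMatrix, genes: list[str], cell_lines: list[str]) -> np.ndarray:
    gidx = {g: i for i, g in enumerate(m.genes)}
    cidx = {c: i for i, c in enumerate(m.cell_lines)}
    rows = [gidx[g] for g in genes]
    cols = [cidx[c] for c in cell_lines]
    return m.values[np.ix_(rows, cols)].T


def split_train_test(labels: dict[str, str], seed: int,
                     train_fraction: float = DEFAULT_TRAIN_FRACTION
                     ) -> tuple[list[str], list[str]]:
    """Stratified train/test split of labeled cell lines.

    ``n_train = round(train_fraction * n)`` overall; per-class counts are
    apportioned by largest remainder so both classes appear in both
    partitions.  Deterministic given the seed.
    """
    labeled = {cl: lab for cl, lab in labels.items() if lab in (SENSITIVE, RESISTANT)}
    n = len(labeled)
    if n < 12:
        raise ValidationError(f"need >= 12 labeled cell lines, got {n}")
    classes = sorted({lab for lab in labeled.values()})
    if len(classes) < 2:
        raise ValidationError("both classes must be present")
    n_train = int(round(train_fraction * n))

    by_class = {c: sorted(cl for cl, lab in labeled.items() if lab == c) for c in classes}
    ideal = {c: train_fraction * len(by_class[c]) for c in classes}
    counts = {c: int(np.floor(ideal[c])) for c in classes}
    leftover = n_train - sum(counts.values())
    for c in sorted(classes, key=lambda c: (-(ideal[c] - counts[c]), c))[:leftover]:
        counts[c] += 1

    rng = np.random.default_rng(seed)
    train, test = [], []
    for c in classes:
        members = list(by_class[c])
        rng.shuffle(members)
        train.extend(members[: counts[c]])
        test.extend(members[counts[c]:])
    for c in classes:
        n_tr = sum(1 for cl in train if labeled[cl] == c)
        n_te = sum(1 for cl in test if labeled[cl] == c)
        if n_tr < 2 or n_te < 2:
            raise ValidationError(
                f"class {c!r} has < 2 members in a partition "
                f"(train {n_tr}, test {n_te}); use more data or another seed"
            )
    return sorted(train), sorted(test)


def select_genes(m: ExpressionMatrix, labeling: ResponseLabeling, train: list[str],
                 candidate_genes: GeneSet | list[str],
                 alpha: float = DEFAULT_ALPHA) -> list[tuple[str, float, float]]:
    """Genes with training-set Mann-Whitney p < alpha; returns (gene, p, auc).

    Uses the training cell lines only — test labels never influence
    selection.  Candidates absent from the matrix are skipped.
    """
    genes = list(candidate_genes.genes) if isinstance(candidate_genes, GeneSet) \
        else list(candidate_genes)
    in_matrix = set(m.genes)
    present = [g for g in genes if g in in_matrix]
    if not present:
        raise ValidationError(f"no candidate gene is in the matrix: {genes}")
    gidx = {g: i for i, g in enumerate(m.genes)}
    cidx = {c: i for i, c in enumerate(m.cell_lines)}
    train = [cl for cl in train if cl in cidx]
    sens = [cidx[cl] for cl in train if labeling.labels.get(cl) == SENSITIVE]
    res = [cidx[cl] for cl in train if labeling.labels.get(cl) == RESISTANT]
    if len(sens) < 2 or len(res) < 2:
        raise ValidationError("training set needs >= 2 cell lines per class")
    selected = []
    for g in present:
        row = m.values[gidx[g]]
        _, p = mann_whitney(row[res], row[sens])
        if p < alpha:
            a = raw_auc(row[res], row[sens])
            selected.append((g, p, max(a, 1.0 - a)))
    return selected


def fit_signature(m: ExpressionMatrix, labeling: ResponseLabeling, train: list[str],
                  selected: list[str], seed: int,
                  n_trees: int = DEFAULT_N_TREES) -> SignatureModel:
    """Train a random forest on the selected genes over the training lines.

    Defaults: ``n_trees`` trees, sqrt(p) features per split, unlimited depth.
    """
    if not selected:
        raise ValidationError("no significant genes to fit")
    train = [cl for cl in train if labeling.labels.get(cl) in (SENSITIVE, RESISTANT)]
    X = _feature_matrix(m, selected, train)
    y = np.array([labeling.labels[cl] for cl in train])
    clf = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt",
                                 max_depth=None, random_state=seed)
    clf.fit(X, y)
    return SignatureModel(genes=list(selected), classifier=clf)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    """Accuracy, sensitivity, specificity, precision; None on empty denominators."""
    def ratio(num, den):
        return num / den if den else None
    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "precision": ratio(tp, tp + fp),
    }


def evaluate_signature(model: SignatureModel, m: ExpressionMatrix,
                       labeling: ResponseLabeling, test: list[str],
                       threshold: float = 0.5) -> dict:
    """Held-out evaluation: confusion at the probability threshold, derived
    metrics, and the unfolded test ROC AUC of the resistant-class probability
    with its Mann-Whitney p."""
    test = [cl for cl in test if labeling.labels.get(cl) in (SENSITIVE, RESISTANT)]
    if not test:
        raise ValidationError("empty test set")
    y = np.array([labeling.labels[cl] for cl in test])
    if len(set(y)) < 2:
        raise ValidationError("test set contains a single class")
    proba = model.resistant_probability(m, test)
    pred_res = proba >= threshold
    actual_res = y == RESISTANT
    tp = int(np.sum(pred_res & actual_res))
    fp = int(np.sum(pred_res & ~actual_res))
    tn = int(np.sum(~pred_res & ~actual_res))
    fn = int(np.sum(~pred_res & actual_res))
    metrics = confusion_metrics(tp, fp, tn, fn)
    test_auc = raw_auc(proba[actual_res], proba[~actual_res])
    _, test_auc_p = mann_whitney(proba[actual_res], proba[~actual_res])
    return {"confusion": (tp, fp, tn, fn), **metrics,
            "test_auc": float(test_auc), "test_auc_p": float(test_auc_p),
            "n_test": len(test)}


def run_signature_pipeline(m: ExpressionMatrix, labeling: ResponseLabeling,
                           gene_set: GeneSet, seed: int,
                           n_trees: int = DEFAULT_N_TREES,
                           alpha: float = DEFAULT_ALPHA,
                           train_fraction: float = DEFAULT_TRAIN_FRACTION
                           ) -> SignatureResult:
    """Deterministic split -> select -> fit -> evaluate composition.

    The radar data are full-cohort folded AUCs of the selected genes.
    """
    shared = set(m.cell_lines)
    labels = {cl: lab for cl, lab in labeling.labels.items() if cl in shared}
    train, test = split_train_test(labels, seed, train_fraction)
    selected = select_genes(m, labeling, train, gene_set, alpha)
    if not selected:
        raise ValidationError(
            f"no gene in set {gene_set.name!r} is significant at p < {alpha} on the training set"
        )
    model = fit_signature(m, labeling, train, [g for g, _, _ in selected], seed, n_trees)
    ev = evaluate_signature(model, m, labeling, test)
    gidx = {g: i for i, g in enumerate(m.genes)}
    radar = {}
    for g, _, _ in selected:
        expr = dict(zip(m.cell_lines, m.values[gidx[g]]))
        radar[g] = roc_auc(expr, labeling, gene=g).auc
    return SignatureResult(
        compound=labeling.compound, dataset=labeling.dataset,
        gene_set_name=gene_set.name,
        selected_genes=sorted(selected),
        split_seed=seed, n_train=len(train), n_test=ev["n_test"],
        confusion=ev["confusion"], accuracy=ev["accuracy"],
        sensitivity=ev["sensitivity"], specificity=ev["specificity"],
        precision=ev["precision"], test_auc=ev["test_auc"],
        test_auc_p=ev["test_auc_p"], radar=radar,
    )
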