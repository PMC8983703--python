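"""Secondary-structure class and fold assignment, with evaluation metrics.

Class assignment (alpha / beta / alphabeta / small) comes in two flavours:

* expert rule cascades on (length, helix fraction, sheet fraction) — the
  "original" thresholds (length < 50 -> small; helix >= 60% -> alpha;
  sheet >= 35% and helix < 20% -> beta; else alphabeta) and the
  sweep-"optimized" variant (55 aa, 55%, 25% with the same 20% helix cap);
* a bagged ensemble of 20 RBF-kernel SVMs, each trained on a 5% bootstrap
  sample, predicting by majority vote.

Fold assignment compares a query descriptor against up to 10 randomly
sampled exemplars per fold with a trained pair scorer and returns the fold
of highest probability.

Secondary-structure content is estimated from CA geometry alone (i->i+3 /
i->i+4 distance windows for helix, extended i->i+2 spacing plus a paired
neighbour strand for sheet), so no external assigner is needed; callers
with DSSP-style assignments can supply fractions directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .structure_io import Structure
from .zernike import ZernikeDescriptor

__all__ = [
    "SSContent",
    "ClassLabel",
    "FoldLabel",
    "ConfusionCounts",
    "UndefinedMetricError",
    "assign_class_rule",
    "BaggedSVMEnsemble",
    "train_bagged_svm",
    "assign_fold",
    "metrics",
    "ss_content_from_structure",
]

CLASS_LABELS = ("alpha", "alphabeta", "beta", "small")  # lexicographic
ClassLabel = Literal["alpha", "beta", "alphabeta", "small"]


@dataclass(frozen=True)
class SSContent:
    """Protein length and helix/sheet residue fractions."""

    length: int
    helix_frac: float
    sheet_frac: float

    def __post_init__(self) -> None:
        if not (0 <= self.helix_frac <= 1 and 0 <= self.sheet_frac <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.helix_frac + self.sheet_frac > 1 + 1e-9:
            raise ValueError("helix and sheet fractions sum to more than 1")


@dataclass(frozen=True)
class FoldLabel:
    fold_id: str
    class_label: ClassLabel | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")


class UndefinedMetricError(ZeroDivisionError):
    """A requested metric has a zero denominator."""


# cascade thresholds: (small length cutoff, helix cutoff, sheet cutoff, helix cap)
_RULES = {
    "original": (50, 0.60, 0.35, 0.20),
    "optimized": (55, 0.55, 0.25, 0.20),
}


def assign_class_rule(
    c: SSContent, rule: Literal["original", "optimized"] = "original"
) -> ClassLabel:
    """First-match expert cascade on length and secondary-structure content."""
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}")
    len_cut, helix_cut, sheet_cut, helix_cap = _RULES[rule]
    if c.length < len_cut:
        return "small"
    if c.helix_frac >= helix_cut:
        return "alpha"
    if c.sheet_frac >= sheet_cut and c.helix_frac < helix_cap:
        return "beta"
    return "alphabeta"


def _features(data: Sequence[SSContent]) -> np.ndarray:
    return np.array([[c.length, c.helix_frac, c.sheet_frac] for c in data], dtype=float)


class BaggedSVMEnsemble:
    """Majority vote over RBF-kernel SVMs trained on small bootstrap samples.

    Ties are broken by summed decision-function confidence over the
    ensemble, then by lexicographic class order. Features are standardized
    with the training statistics stored on the ensemble.
    """

    def __init__(
        self,
        members: list[SVC],
        feat_mean: np.ndarray,
        feat_std: np.ndarray,
        classes: tuple[str, ...],
    ):
        self.members = members
        self.feat_mean = feat_mean
        self.feat_std = feat_std
        self.classes = classes

    def _transform(self, data: Sequence[SSContent]) -> np.ndarray:
        return (_features(data) - self.feat_mean) / self.feat_std

    def predict(self, data: Sequence[SSContent]) -> list[str]:
        x = self._transform(data)
        votes = np.zeros((len(x), len(self.classes)), dtype=int)
        proba = np.zeros((len(x), len(self.classes)))
        cls_index = {c: i for i, c in enumerate(self.classes)}
        for svm in self.members:
            pred = svm.predict(x)
            for row, lab in enumerate(pred):
                votes[row, cls_index[lab]] += 1
            df = svm.decision_function(x)
            if len(svm.classes_) == 2:  # single signed column for classes_[1]
                proba[:, cls_index[svm.classes_[1]]] += df
                proba[:, cls_index[svm.classes_[0]]] -= df
            else:
                for j, lab in enumerate(svm.classes_):
                    proba[:, cls_index[lab]] += df[:, j]
        out = []
        for row in range(len(x)):
            top = votes[row].max()
            tied = np.where(votes[row] == top)[0]
            if len(tied) > 1:
                tied = tied[np.argsort(-proba[row, tied], kind="stable")]
            out.append(self.classes[tied[0]])
        return out


def train_bagged_svm(
    data: Sequence[tuple[SSContent, str]],
    n_classifiers: int = 20,
    sample_frac: float = 0.05,
    seed: int = 0,
    gamma: float | str = "scale",
    C: float = 1.0,
) -> BaggedSVMEnsemble:
    """Train the bagged SVM class ensemble.

    Each member sees a bootstrap sample (with replacement) of
    ``sample_frac`` of the data; samples that happen to contain fewer than
    two classes are redrawn (up to 100 attempts).
    """
    contents = [d[0] for d in data]
    labels = np.array([d[1] for d in data])
    classes = tuple(sorted(set(labels)))
    if len(classes) < 4:
        raise ValueError(f"need all four classes in training data, got {classes}")
    rng = np.random.default_rng(seed)
    x = _features(contents)
    mean = x.mean(axis=0)
    std = np.maximum(x.std(axis=0), 1e-8)
    xs = (x - mean) / std
    n_sample = max(2, int(round(sample_frac * len(data))))
    members = []
    for k in range(n_classifiers):
        for _attempt in range(100):
            pick = rng.integers(0, len(data), n_sample)
            if len(set(labels[pick])) >= 2:
                break
        else:
            raise ValueError("could not draw a bootstrap sample with two classes")
        svm = SVC(kernel="rbf", gamma=gamma, C=C, random_state=k)
        svm.fit(xs[pick], labels[pick])
        members.append(svm)
    return BaggedSVMEnsemble(members, mean, std, classes)


def assign_fold(
    query: ZernikeDescriptor,
    catalogue: Mapping[str, Sequence[ZernikeDescriptor]],
    scorer: Callable[[ZernikeDescriptor, ZernikeDescriptor], float],
    k: int = 10,
    seed: int = 0,
    aggregate: Literal["max", "mean"] = "max",
) -> tuple[FoldLabel, float]:
    """Assign the query to the fold with the highest pair score.

    For each fold, up to ``k`` exemplars are sampled without replacement
    (seeded); the fold score aggregates the pair scores (``max`` by
    default). Ties break lexicographically by fold id.
    """
    if not catalogue:
        raise ValueError("empty fold catalogue")
    rng = np.random.default_rng(seed)
    best_fold, best_score = None, -np.inf
    for fold_id in sorted(catalogue):
        exemplars = list(catalogue[fold_id])
        if not exemplars:
            raise ValueError(f"fold {fold_id} has no exemplars")
        if len(exemplars) > k:
            idx = rng.choice(len(exemplars), k, replace=False)
            exemplars = [exemplars[i] for i in idx]
        scores = [float(scorer(query, e)) for e in exemplars]
        agg = max(scores) if aggregate == "max" else float(np.mean(scores))
        if agg > best_score:  # strict: first (lexicographic) fold wins ties
            best_fold, best_score = fold_id, agg
    return FoldLabel(fold_id=best_fold), best_score


def metrics(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F-measure) from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F = 2 P R / (P + R). A zero denominator raises
    :class:`UndefinedMetricError` naming the metric.
    """
    total = c.TP + c.TN + c.FP + c.FN
    if total == 0:
        raise UndefinedMetricError("accuracy undefined: no observations")
    accuracy = (c.TP + c.TN) / total
    if c.TP + c.FP == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    precision = c.TP / (c.TP + c.FP)
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    recall = c.TP / (c.TP + c.FN)
    if precision + recall == 0:
        raise UndefinedMetricError("F-measure undefined: precision + recall = 0")
    f_measure = 2 * precision * recall / (precision + recall)
    return accuracy, precision, recall, f_measure


# CA-geometry windows (Angstrom): ideal helix has d(i,i+3) ~ 5.1 and
# d(i,i+4) ~ 6.2; extended strands have d(i,i+2) ~ 6.7 with a partner
# strand CA within pairing distance.
_HELIX_D3 = (4.6, 5.6)
_HELIX_D4 = (5.5, 6.9)
_STRAND_D2 = (5.9, 7.4)
_PAIR_DIST = 5.5


def ss_content_from_structure(s: Structure) -> SSContent:
    """Estimate helix/sheet fractions from CA geometry.

    A residue window i..i+4 is helical when both the i->i+3 and i->i+4 CA
    distances fall in the helical bands; a residue is strand-like when an
    i->i+2 window around it is extended and some sequence-distant
    strand-like CA lies within pairing distance. Helix wins where both
    patterns match. Crude next to a hydrogen-bond assigner, but driven by
    coordinates alone.
    """
    ca = np.array([a.coord for a in s.atoms if a.name == "CA"])
    n = len(ca)
    if n < 5:
        raise ValueError("need at least 5 CA atoms for content estimation")
    d = lambda i, j: float(np.linalg.norm(ca[i] - ca[j]))
    win = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        win[i] = _HELIX_D3[0] <= d(i, i + 3) <= _HELIX_D3[1] and _HELIX_D4[
            0
        ] <= d(i, i + 4) <= _HELIX_D4[1]
    helix = np.zeros(n, dtype=bool)
    # one accidental window is common in coils; demand two in a row
    for i in range(n - 5):
        if win[i] and win[i + 1]:
            helix[i : i + 6] = True
    extended = np.zeros(n, dtype=bool)
    for i in range(n - 2):
        if _STRAND_D2[0] <= d(i, i + 2) <= _STRAND_D2[1]:
            extended[i : i + 3] = True
    strand = np.zeros(n, dtype=bool)
    ext_idx = np.where(extended)[0]
    if len(ext_idx):
        dist = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
        for i in ext_idx:
            partners = ext_idx[np.abs(ext_idx - i) > 2]
            if len(partners) and dist[i, partners].min() < _PAIR_DIST:
                strand[i] = True
    strand &= ~helix
    return SSContent(
        length=n,
        helix_frac=float(helix.mean()),
        sheet_frac=float(strand.mean()),
    )
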