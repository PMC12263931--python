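"""Evaluation protocol: participant-level splits, metrics, ablations, statistics.

Augmentation multiplies each subject into many overlapping windows, so naive
row-level splitting leaks subject identity between train and test. Every split
here is therefore performed on *subjects*; windows inherit their subject's
assignment, and the leakage invariant (empty intersection of subject sets) is
asserted on every plan.

Metrics follow the standard confusion-matrix definitions with AD as the
positive class; AUC uses the Mann-Whitney midrank statistic, which equals the
trapezoidal area under the ROC curve.

The statistical toolkit compares two classifiers: Wilcoxon signed-rank on
paired per-fold F1 scores, the DeLong test on correlated AUCs computed from
the same test instances, Cohen's d as a paired effect size, and
Benjamini-Hochberg adjustment across a comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dataset import SegmentDataset
from .model import ArchitectureConfig, EEGGraphClassifier, TrainConfig
from .montage import region_of

__all__ = [
    "SplitPlan",
    "subject_split",
    "kfold_cv",
    "cross_validate",
    "MetricsReport",
    "compute_metrics",
    "auc_score",
    "train_and_evaluate",
    "band_evaluation",
    "AblationReport",
    "electrode_ablation",
    "delong_test",
    "cohens_d",
    "bh_adjust",
    "stats_suite",
]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Subject-level train/test assignment."""

    train_subjects: tuple
    test_subjects: tuple
    test_fraction: float
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_subjects) & set(self.test_subjects)
        if overlap:
            raise ValueError(f"subjects on both sides of the split: {sorted(overlap)}")
        if not self.train_subjects or not self.test_subjects:
            raise ValueError("both sides of the split must be non-empty")

    def side_of(self, subject_id: str) -> str:
        if subject_id in set(self.train_subjects):
            return "train"
        if subject_id in set(self.test_subjects):
            return "test"
        raise KeyError(subject_id)

    def apply(self, ds: SegmentDataset) -> tuple:
        """(train, test) row subsets of a segment dataset."""
        return (ds.select_subjects(self.train_subjects),
                ds.select_subjects(self.test_subjects))


def _subject_label_map(cohort) -> dict:
    """subject_id -> label from a SegmentDataset or a list of recordings."""
    if isinstance(cohort, SegmentDataset):
        return cohort.subject_labels()
    if isinstance(cohort, dict):
        return dict(cohort)
    return {rec.subject_id: rec.label for rec in cohort}


def subject_split(cohort, test_fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Random participant-level split, stratified by class.

    All of a subject's augmented windows land on one side. Stratification
    keeps both classes present in the test set (required for AUC). Per class,
    round(test_fraction * n) subjects are held out; with the 36 AD + 29 HC
    default cohort and test_fraction 0.2 this gives 52 train and 13 test
    subjects (520 / 130 tenfold windows).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    labels = _subject_label_map(cohort)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in sorted(set(labels.values())):
        subs = sorted(s for s, l in labels.items() if l == cls)
        if len(subs) < 2:
            raise ValueError(f"need >= 2 subjects of class {cls} to split")
        n_test = int(round(test_fraction * len(subs)))
        n_test = min(max(n_test, 1), len(subs) - 1)
        perm = rng.permutation(len(subs))
        test += [subs[i] for i in perm[:n_test]]
        train += [subs[i] for i in perm[n_test:]]
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)),
                     test_fraction, seed)


def kfold_cv(train_subjects, k: int = 5, seed: int = 0, labels: dict | None = None) -> list:
    """Subject-level k-fold partition: list of k disjoint subject tuples.

    Fold sizes differ by at most one (e.g. 52 subjects, k=5 -> sizes 11, 11,
    10, 10, 10). With ``labels`` (subject -> class) the folds are additionally
    stratified so each class is dealt cyclically across folds, keeping both
    classes present in every fold whenever each class has >= k subjects.
    """
    subjects = sorted(train_subjects)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the {len(subjects)} available subjects")
    rng = np.random.default_rng(seed)
    if labels is None:
        perm = rng.permutation(len(subjects))
        folds = np.array_split(perm, k)
        return [tuple(subjects[i] for i in f) for f in folds]
    folds = [[] for _ in range(k)]
    counter = 0
    for cls in sorted(set(labels[s] for s in subjects)):
        members = [s for s in subjects if labels[s] == cls]
        for s in (members[i] for i in rng.permutation(len(members))):
            folds[counter % k].append(s)
            counter += 1
    return [tuple(sorted(f)) for f in folds]


def cross_validate(ds: SegmentDataset, k: int = 5, seed: int = 0,
                   arch: ArchitectureConfig | None = None,
                   train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Subject-level k-fold CV; one MetricsReport row per fold plus mean/sd."""
    folds = kfold_cv(ds.subjects, k, seed, labels=ds.subject_labels())
    rows = []
    for i, held_out in enumerate(folds):
        train_subs = [s for f in folds for s in f if f is not folds[i]]
        tr = ds.select_subjects(train_subs)
        te = ds.select_subjects(held_out)
        rep = train_and_evaluate(tr, te, arch=arch, train_config=train_config)
        rows.append({"fold": i, **rep.as_dict()})
    df = pd.DataFrame(rows).set_index("fold")
    df.loc["mean"] = df.mean()
    df.loc["sd"] = df.iloc[:-1].std()
    return df


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC via the Mann-Whitney midrank statistic (ties -> midranks)."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = sps.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass
class MetricsReport:
    """Accuracy/precision/recall/F1/AUC (all in %) plus confusion counts."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    tp: int
    tn: int
    fp: int
    fn: int
    provenance: str = ""

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "auc": self.auc,
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
        }

    def __str__(self) -> str:
        return (f"Acc {self.accuracy:.2f}%  Pre {self.precision:.2f}%  "
                f"Rec {self.recall:.2f}%  F1 {self.f1:.2f}%  "
                f"AUC {self.auc:.2f}%  [{self.provenance}]")


def compute_metrics(labels, probabilities, threshold: float = 0.5,
                    provenance: str = "") -> MetricsReport:
    """Confusion-matrix metrics at a threshold, AUC from the raw scores.

    ``labels`` are integers with AD = 1; ``probabilities`` are AD-class
    probabilities (or any monotone scores for the AUC).
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / len(y)
    pre = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * pre * rec / (pre + rec) if pre + rec else 0.0
    auc = auc_score(y, p)
    return MetricsReport(
        accuracy=100 * acc, precision=100 * pre, recall=100 * rec,
        f1=100 * f1, auc=100 * auc, tp=tp, tn=tn, fp=fp, fn=fn,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# protocol runs
# ---------------------------------------------------------------------------

def train_and_evaluate(train_ds: SegmentDataset, test_ds: SegmentDataset,
                       arch: ArchitectureConfig | None = None,
                       train_config: TrainConfig | None = None) -> MetricsReport:
    """Fit on the train rows, report the metric suite on the test rows."""
    overlap = set(train_ds.subjects) & set(test_ds.subjects)
    if overlap:
        raise ValueError(f"subject leakage between splits: {sorted(overlap)}")
    arch = arch or ArchitectureConfig.from_dataset(train_ds)
    res = EEGGraphClassifier(train_ds, test_ds, arch).fit(train_config)
    return res.evaluate(test_ds)


def band_evaluation(train_ds: SegmentDataset, test_ds: SegmentDataset,
                    band_subsets, arch: ArchitectureConfig | None = None,
                    train_config: TrainConfig | None = None) -> pd.DataFrame:
    """Retrain per band subset; one metric row per subset.

    Each subset is a sequence of band names (or the string name of a single
    band); the architecture's band count and flatten size shrink accordingly.
    """
    base = arch or ArchitectureConfig.from_dataset(train_ds)
    rows = []
    for subset in band_subsets:
        names = [subset] if isinstance(subset, str) else list(subset)
        if not names:
            raise ValueError("empty band subset")
        tr = train_ds.subset_bands(names)
        te = test_ds.subset_bands(names)
        sub_arch = ArchitectureConfig.from_dataset(
            tr, gcn_hidden=base.gcn_hidden, gcn_out=base.gcn_out,
            fc_hidden=base.fc_hidden, fc_hidden2=base.fc_hidden2,
            n_classes=base.n_classes, weight_sharing=base.weight_sharing,
            gcn_bias=base.gcn_bias,
        )
        rep = train_and_evaluate(tr, te, sub_arch, train_config)
        rows.append({"bands": "+".join(names), **rep.as_dict()})
    return pd.DataFrame(rows).set_index("bands")


@dataclass
class AblationReport:
    """Leave-one-channel-out results, ranked by AUC drop."""

    full_auc: float
    table: pd.DataFrame = field(repr=False)  # channel, region, auc_removed, delta_auc

    @property
    def ranking(self) -> list:
        return list(self.table.index)


def electrode_ablation(train_ds: SegmentDataset, test_ds: SegmentDataset,
                       arch: ArchitectureConfig | None = None,
                       train_config: TrainConfig | None = None,
                       full_auc: float | None = None) -> AblationReport:
    """Leave-one-electrode-out: retrain from scratch with each channel removed.

    For each channel the features and both adjacencies lose that row/column
    (N -> N-1), the model is retrained, and the AUC drop vs the full model is
    recorded. Channels are ranked by delta AUC descending.
    """
    base = arch or ArchitectureConfig.from_dataset(train_ds)
    if full_auc is None:
        full_auc = train_and_evaluate(train_ds, test_ds, base, train_config).auc
    rows = []
    for ch in train_ds.channel_names:
        tr = train_ds.drop_channel(ch)
        te = test_ds.drop_channel(ch)
        sub_arch = ArchitectureConfig.from_dataset(
            tr, gcn_hidden=base.gcn_hidden, gcn_out=base.gcn_out,
            fc_hidden=base.fc_hidden, fc_hidden2=base.fc_hidden2,
            n_classes=base.n_classes, weight_sharing=base.weight_sharing,
            gcn_bias=base.gcn_bias,
        )
        rep = train_and_evaluate(tr, te, sub_arch, train_config)
        rows.append({"channel": ch, "region": region_of(ch),
                     "auc_removed": rep.auc, "delta_auc": full_auc - rep.auc})
    table = (pd.DataFrame(rows).set_index("channel")
             .sort_values("delta_auc", ascending=False))
    return AblationReport(full_auc=full_auc, table=table)


# ---------------------------------------------------------------------------
# statistical comparisons
# ---------------------------------------------------------------------------

def cohens_d(a, b) -> float:
    """Cohen's d for paired vectors: mean difference over pooled sd."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diff = a.mean() - b.mean()
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf * np.sign(diff)
    return float(diff / pooled)


def _delong_components(labels: np.ndarray, scores: np.ndarray):
    """AUC and its structural components V10 (per positive), V01 (per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # pairwise comparison with midrank tie handling
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_test(labels, scores_a, scores_b) -> dict:
    """DeLong test for two correlated AUCs on the same test instances.

    Returns a dict with both AUCs (fractions), the AUC difference, the z
    statistic and the two-sided p value. Variances come from the covariance of
    the structural components of the paired models.
    """
    y = np.asarray(labels).astype(int)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if not (y.shape == sa.shape == sb.shape):
        raise ValueError("labels and both score vectors must share length")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    auc_a, v10a, v01a = _delong_components(y, sa)
    auc_b, v10b, v01b = _delong_components(y, sb)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return {"auc_a": auc_a, "auc_b": auc_b, "auc_difference": diff,
            "z": float(z), "p_value": p}


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone in raw order)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def stats_suite(fold_scores_a, fold_scores_b, test_labels,
                probs_a, probs_b) -> dict:
    """Paired comparison of two classifiers (A vs B).

    * Wilcoxon signed-rank p on paired per-fold scores (e.g. F1 per CV fold);
    * DeLong p on the correlated AUC difference, with the difference in
      percentage points;
    * Cohen's d on the paired fold scores.

    BH adjustment is applied by the caller across the whole comparison family
    (see :func:`bh_adjust`), since the family is not visible from one pair.
    """
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired fold-score vectors must have equal length")
    if np.all(a == b):
        raise ValueError(
            "all paired scores tied: the Wilcoxon signed-rank test is undefined"
        )
    wil = sps.wilcoxon(a, b)
    dl = delong_test(test_labels, probs_a, probs_b)
    return {
        "wilcoxon_p": float(wil.pvalue),
        "cohens_d": cohens_d(a, b),
        "delong_p": dl["p_value"],
        "auc_a_pct": 100 * dl["auc_a"],
        "auc_b_pct": 100 * dl["auc_b"],
        "auc_difference_pct": 100 * dl["auc_difference"],
    }
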