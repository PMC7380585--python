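"""Source-signature training: feature selection, voting ensemble, cutoff.

One signature is a one-vs-rest classifier for a single fecal source, 16S
region and bacterial order.  Training proceeds in four steps:

1. **Gini ranking** — replicate random forests (default 100 x 10,000
   trees, Gini splits, sqrt(p) candidate features) are grown on the full
   relative-abundance table; the mean decrease in Gini of every ASV is
   averaged across replicates.
2. **Breakpoint selection** — the ranked importances form a scree curve;
   a single least-squares change-point separates the signal plateau from
   the noise floor, and only ASVs above the breakpoint enter the
   signature.
3. **Ensemble training** — profiles restricted to the selected ASVs are
   renormalized to sum to 1 and replicate forests (default 100 x 1,000
   trees) are pooled into one voting ensemble; the voting probability of
   a query is the fraction of pooled trees voting the focal source.
4. **Cutoff calibration** — the decision cutoff is chosen on held-out test
   probabilities to maximize the smaller of sensitivity and specificity,
   subject to both being at least 70%; classifiers are typed *global*
   (cutoff > 10%), *draft* (> 5-10%) or *discarded* (<= 5% or no feasible
   cutoff).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "ClassifierType",
    "GiniRanking",
    "PooledForest",
    "SourceSignature",
    "CutoffResult",
    "one_vs_rest_labels",
    "gini_ranking",
    "breakpoint_select",
    "renormalize",
    "train_ensemble",
    "voting_probability",
    "calibrate_cutoff",
    "classify_type",
    "train_signature",
]


class ClassifierType(str, Enum):
    GLOBAL = "global"
    DRAFT = "draft"
    DISCARDED = "discarded"


@dataclass
class GiniRanking:
    """Replicate-averaged mean decrease in Gini per ASV."""

    importances: pd.Series  # index: ASV sequence, values >= 0
    n_replicates: int
    n_trees: int


@dataclass
class CutoffResult:
    cutoff: float | None
    sensitivity: float | None
    specificity: float | None

    @property
    def defined(self) -> bool:
        return self.cutoff is not None


class PooledForest:
    """Replicate random forests pooled into one tree-voting ensemble.

    The vote of the pool on a query is the fraction of all trees across
    all replicates predicting the positive class — the voting tree
    probability.  Replicates are seeded ``seed + i`` so the pool is
    bit-reproducible.
    """

    def __init__(self, forests: list[RandomForestClassifier], positive_label: int = 1):
        self.forests = forests
        self.positive_label = positive_label

    @property
    def n_trees(self) -> int:
        return sum(len(f.estimators_) for f in self.forests)

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        """Per-row fraction of pooled trees voting the positive class."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        votes = np.zeros(len(X))
        total = 0
        for forest in self.forests:
            for tree in forest.estimators_:
                pred = forest.classes_[np.argmax(tree.predict_proba(X), axis=1)]
                votes += pred == self.positive_label
            total += len(forest.estimators_)
        return votes / total


@dataclass
class SourceSignature:
    """Trained signature: selected ASVs, pooled ensemble, cutoff, type."""

    source: str
    region: str
    group: str
    asv_sequences: list[str]
    ensemble: PooledForest
    decision_cutoff: float | None
    sensitivity: float | None
    specificity: float | None
    classifier_type: ClassifierType
    metadata: dict = field(default_factory=dict)

    def save(self, bundle_dir: str | Path) -> Path:
        """Write the bundle: signature.fasta, model.joblib, meta.json."""
        bundle = Path(bundle_dir)
        bundle.mkdir(parents=True, exist_ok=True)
        with open(bundle / "signature.fasta", "w") as fh:
            for i, seq in enumerate(self.asv_sequences, 1):
                fh.write(f">{self.source}_ASV_{i:04d}\n{seq}\n")
        joblib.dump(self.ensemble, bundle / "model.joblib")
        meta = {
            "source": self.source,
            "region": self.region,
            "group": self.group,
            "n_asvs": len(self.asv_sequences),
            "decision_cutoff": self.decision_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "classifier_type": self.classifier_type.value,
            **self.metadata,
        }
        with open(bundle / "meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        return bundle

    @classmethod
    def load(cls, bundle_dir: str | Path) -> "SourceSignature":
        from Bio import SeqIO

        bundle = Path(bundle_dir)
        with open(bundle / "meta.json") as fh:
            meta = json.load(fh)
        seqs = [
            str(rec.seq).upper()
            for rec in SeqIO.parse(str(bundle / "signature.fasta"), "fasta")
        ]
        ensemble = joblib.load(bundle / "model.joblib")
        core = {
            k: meta.pop(k)
            for k in (
                "source",
                "region",
                "group",
                "decision_cutoff",
                "sensitivity",
                "specificity",
                "classifier_type",
            )
        }
        meta.pop("n_asvs", None)
        return cls(
            source=core["source"],
            region=core["region"],
            group=core["group"],
            asv_sequences=seqs,
            ensemble=ensemble,
            decision_cutoff=core["decision_cutoff"],
            sensitivity=core["sensitivity"],
            specificity=core["specificity"],
            classifier_type=ClassifierType(core["classifier_type"]),
            metadata=meta,
        )


def one_vs_rest_labels(
    labels: Mapping[str, str] | pd.Series,
    focal_source: str | Sequence[str],
) -> pd.Series:
    """Binary labels: 1 for the focal source(s), 0 for every other source.

    ``focal_source`` may be a single label or a collection of member
    labels for diet/physiology signatures (e.g. ruminant = cattle + deer).
    """
    lab = pd.Series(labels, dtype=str)
    if lab.nunique() < 2:
        raise ValueError("one-vs-rest requires at least two sources")
    focal = {focal_source} if isinstance(focal_source, str) else set(focal_source)
    missing = focal - set(lab.unique())
    if missing:
        raise ValueError(f"focal source(s) absent from labels: {sorted(missing)}")
    return lab.isin(focal).astype(int)


def renormalize(table: pd.DataFrame) -> pd.DataFrame:
    """Rows scaled to sum to 1; all-zero rows stay zero (and are flagged)."""
    totals = table.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have no reads on the selected ASVs; "
            "profiles left at zero",
            stacklevel=2,
        )
    safe = totals.where(~zero, 1.0)
    return table.div(safe, axis=0)


def _grow_forests(
    X: np.ndarray,
    y: np.ndarray,
    n_replicates: int,
    n_trees: int,
    seed: int,
) -> list[RandomForestClassifier]:
    forests = []
    for i in range(n_replicates):
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=seed + i,
            n_jobs=1,
        )
        rf.fit(X, y)
        forests.append(rf)
    return forests


def gini_ranking(
    train_table: pd.DataFrame,
    labels: pd.Series,
    n_replicates: int = 100,
    n_trees: int = 10_000,
    seed: int = 0,
) -> GiniRanking:
    """Replicate-averaged Gini importance of every ASV.

    ``train_table`` is a samples x ASVs table; it is converted to relative
    abundances so depth differences cannot masquerade as importance.
    Labels must contain both classes.
    """
    y = labels.loc[train_table.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; ranking undefined")
    X = renormalize(train_table).to_numpy(dtype=float)
    forests = _grow_forests(X, y, n_replicates, n_trees, seed)
    imp = np.mean([f.feature_importances_ for f in forests], axis=0)
    return GiniRanking(
        importances=pd.Series(imp, index=train_table.columns),
        n_replicates=n_replicates,
        n_trees=n_trees,
    )


def _two_segment_sse(sorted_vals: np.ndarray, k: int) -> float:
    """SSE of fitting two constant segments split after index k (1-based count)."""
    left, right = sorted_vals[:k], sorted_vals[k:]
    sse = float(((left - left.mean()) ** 2).sum())
    if len(right):
        sse += float(((right - right.mean()) ** 2).sum())
    return sse


def breakpoint_select(
    ranking: GiniRanking,
    max_residual_ratio: float = 0.10,
    fallback_mass: float = 0.90,
) -> tuple[list[str], bool]:
    """Select the ASVs above the scree-curve breakpoint.

    Importances are sorted descending and a single change-point is placed
    by exhaustive two-segment least squares (each segment fitted by its
    mean).  Everything left of the breakpoint is the signature.  The
    breakpoint is considered real when the two-segment fit explains the
    curve — residual SSE below ``max_residual_ratio`` of the one-segment
    SSE; a smooth decay (geometric, or pure noise) leaves a large relative
    residual at every split, in which case the selection falls back to the
    smallest prefix carrying ``fallback_mass`` of total importance, with a
    warning.

    Returns ``(selected_asv_ids, used_fallback)``.
    """
    imp = ranking.importances.sort_values(ascending=False, kind="mergesort")
    vals = imp.to_numpy(dtype=float)
    p = len(vals)
    if p == 1:
        return list(imp.index), False
    sse1 = float(((vals - vals.mean()) ** 2).sum())
    sses = [_two_segment_sse(vals, k) for k in range(1, p)]
    k = int(np.argmin(sses)) + 1
    if sse1 > 0 and sses[k - 1] / sse1 < max_residual_ratio:
        return list(imp.index[:k]), False
    # No elbow: smooth decay. Take the smallest head carrying most of the
    # importance mass rather than silently selecting nothing.
    warnings.warn(
        "no breakpoint detected in the importance scree curve; "
        f"falling back to the top features carrying {fallback_mass:.0%} of mass",
        stacklevel=2,
    )
    total = vals.sum()
    if total <= 0:
        return list(imp.index), True
    csum = np.cumsum(vals) / total
    k = int(np.searchsorted(csum, fallback_mass)) + 1
    return list(imp.index[:k]), True


def train_ensemble(
    train_table: pd.DataFrame,
    labels: pd.Series,
    n_replicates: int = 100,
    n_trees: int = 1_000,
    seed: int = 0,
) -> PooledForest:
    """Train the pooled voting ensemble on renormalized selected-ASV profiles.

    ``train_table`` must already be restricted to the selected ASVs; each
    profile is renormalized to sum to 1 (the signature carries 100% of the
    relative abundance).  ``n_replicates`` forests of ``n_trees`` trees,
    seeded ``seed + i``, are pooled tree-level.
    """
    if train_table.shape[1] == 0:
        raise ValueError("no ASVs selected; cannot train an ensemble")
    y = labels.loc[train_table.index].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    X = renormalize(train_table).to_numpy(dtype=float)
    forests = _grow_forests(X, y, n_replicates, n_trees, seed)
    return PooledForest(forests, positive_label=1)


def voting_probability(ensemble: PooledForest, profile: np.ndarray | pd.Series) -> float:
    """Fraction of pooled trees voting the focal source for one profile."""
    x = np.asarray(profile, dtype=float)
    return float(ensemble.vote_fractions(x[None, :])[0])


def _sens_spec(probs: np.ndarray, y: np.ndarray, cutoff: float) -> tuple[float, float]:
    called = probs > cutoff
    pos, neg = y == 1, y == 0
    sens = called[pos].mean() if pos.any() else np.nan
    spec = (~called[neg]).mean() if neg.any() else np.nan
    return float(sens), float(spec)


def calibrate_cutoff(
    probabilities: Sequence[float],
    labels: Sequence[int],
    min_perf: float = 0.70,
) -> CutoffResult:
    """Choose the decision cutoff from held-out voting probabilities.

    Candidates are all midpoints between adjacent distinct observed
    probabilities plus the percent grid 0.01..1.00.  Feasible cutoffs give
    sensitivity and specificity both at least ``min_perf``; among those
    the cutoff maximizing min(sensitivity, specificity) wins.  Ties are
    broken by higher sensitivity (the platform's purpose is detection),
    then higher specificity, then the largest margin — the cutoff farthest
    from any observed probability, placing the threshold mid-gap between
    the score distributions — and finally the lower cutoff.  If nothing is
    feasible the classifier cannot be validated and the result is
    undefined.
    """
    probs = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if probs.shape != y.shape:
        raise ValueError("probabilities and labels must align")
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("cutoff calibration needs both positive and negative samples")
    uniq = np.unique(probs)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    grid = np.arange(1, 101) / 100.0
    candidates = np.unique(np.concatenate([mids, grid]))
    best_key: tuple | None = None
    best: tuple[float, float, float] | None = None
    for c in candidates:
        sens, spec = _sens_spec(probs, y, c)
        if sens >= min_perf and spec >= min_perf:
            margin = float(np.min(np.abs(uniq - c)))
            key = (min(sens, spec), sens, spec, margin, -c)
            if best_key is None or key > best_key:
                best_key, best = key, (float(c), sens, spec)
    if best is None:
        return CutoffResult(None, None, None)
    cutoff, sens, spec = best
    return CutoffResult(cutoff, sens, spec)


def classify_type(cutoff: float | None) -> ClassifierType:
    """Type a classifier from its decision cutoff.

    > 10% global; > 5% and <= 10% draft; <= 5% or undefined discarded.
    """
    if cutoff is None:
        return ClassifierType.DISCARDED
    if cutoff > 0.10:
        return ClassifierType.GLOBAL
    if cutoff > 0.05:
        return ClassifierType.DRAFT
    return ClassifierType.DISCARDED


def train_signature(
    table: pd.DataFrame,
    labels: pd.Series,
    focal_source: str | Sequence[str],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    region: str = "unknown",
    group: str = "bacteroidales",
    ranking_replicates: int = 100,
    ranking_trees: int = 10_000,
    ensemble_replicates: int = 100,
    ensemble_trees: int = 1_000,
    min_perf: float = 0.70,
    seed: int = 0,
) -> SourceSignature:
    """Full signature pipeline for one focal source.

    ``table`` holds counts for all train+test samples of every source;
    ``labels`` maps sample id -> source label.  Ranking and selection use
    the training samples only; the cutoff is calibrated on the held-out
    test samples.
    """
    name = focal_source if isinstance(focal_source, str) else "+".join(focal_source)
    binary = one_vs_rest_labels(labels, focal_source)
    train_tab = table.loc[list(train_ids)]
    ranking = gini_ranking(
        train_tab, binary, n_replicates=ranking_replicates,
        n_trees=ranking_trees, seed=seed,
    )
    selected, used_fallback = breakpoint_select(ranking)
    ensemble = train_ensemble(
        train_tab[selected], binary,
        n_replicates=ensemble_replicates, n_trees=ensemble_trees,
        seed=seed + ranking_replicates,
    )
    test_tab = renormalize(table.loc[list(test_ids), selected])
    probs = ensemble.vote_fractions(test_tab.to_numpy(dtype=float))
    cut = calibrate_cutoff(probs, binary.loc[list(test_ids)].to_numpy(), min_perf)
    ctype = classify_type(cut.cutoff)
    return SourceSignature(
        source=name,
        region=region,
        group=group,
        asv_sequences=list(selected),
        ensemble=ensemble,
        decision_cutoff=cut.cutoff,
        sensitivity=cut.sensitivity,
        specificity=cut.specificity,
        classifier_type=ctype,
        metadata={
            "seed": seed,
            "ranking_replicates": ranking_replicates,
            "ranking_trees": ranking_trees,
            "ensemble_replicates": ensemble_replicates,
            "ensemble_trees": ensemble_trees,
            "min_perf": min_perf,
            "breakpoint_fallback": used_fallback,
            "train_ids": sorted(train_ids),
            "test_ids": sorted(test_ids),
            "test_probabilities": {
                str(s): float(p) for s, p in zip(test_ids, probs)
            },
            "test_labels": {
                str(s): int(v) for s, v in binary.loc[list(test_ids)].items()
            },
        },
    )
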