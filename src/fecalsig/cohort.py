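"""Cohort quality screening and train/test design for source classifiers.

Each fecal source contributes a cohort of labeled samples.  Before training
a one-vs-rest classifier the cohort is screened:

* low-depth samples (box-plot lower outliers of log10 ASV-assigned reads),
* low-MED-retention samples (more than half the reads discarded), and
* extreme community outliers (box-plot upper outliers of the per-sample
  mean intrasource Bray-Curtis dissimilarity)

are excluded.  The remaining samples split into a training set — the 15 to
20 samples with the most cohesive (lowest mean intrasource dissimilarity)
assemblages — and a test set of the most dissimilar ones (at least six and
at least 30% of the usable cohort), which makes performance assessment
deliberately stringent.

Sources whose gut community bifurcates (e.g. two husbandry regimes) are
detected by Ward hierarchical clustering of the Bray-Curtis matrix; when
the top merge is far above the preceding one the cohort is split into two
subgroups and training draws a balanced number of samples from each.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import braycurtis, pdist, squareform

__all__ = [
    "SourceCohort",
    "InsufficientCohortError",
    "bray_curtis",
    "bray_curtis_matrix",
    "mean_intrasource_bc",
    "flag_low_depth",
    "flag_extreme_outliers",
    "detect_subgroups",
    "split_train_test",
    "build_cohort",
    "cohort_report",
]


class InsufficientCohortError(ValueError):
    """Raised when a source has too few usable samples to train and test."""


@dataclass
class SourceCohort:
    """Screened, split sample cohort of one fecal source."""

    source: str
    sample_ids: list[str]
    mean_intra_bc: pd.Series
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    excluded: dict[str, str] = field(default_factory=dict)  # id -> reason
    subgroups: pd.Series | None = None

    @property
    def usable_ids(self) -> list[str]:
        return [s for s in self.sample_ids if s not in self.excluded]


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity of two samples on relative abundances.

    Counts are normalized per sample before comparison so that sequencing
    depth (which spans orders of magnitude across platforms) does not
    dominate the dissimilarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        raise ValueError("Bray-Curtis undefined for an all-zero sample")
    return float(braycurtis(x / sx, y / sy))


def _relabund(table: pd.DataFrame) -> pd.DataFrame:
    totals = table.sum(axis=1)
    if (totals == 0).any():
        zero = list(table.index[totals == 0])
        raise ValueError(f"all-zero samples in table: {zero[:5]}")
    return table.div(totals, axis=0)


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis matrix of a samples x ASVs count table."""
    rel = _relabund(table)
    dm = squareform(pdist(rel.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dm, index=table.index, columns=table.index)


def mean_intrasource_bc(table: pd.DataFrame) -> pd.Series:
    """Per-sample mean dissimilarity to the other samples of its source."""
    if len(table) < 2:
        return pd.Series(0.0, index=table.index)
    dm = bray_curtis_matrix(table)
    n = len(dm)
    return (dm.sum(axis=1)) / (n - 1)


def _box_outliers(values: pd.Series, side: str) -> list[str]:
    """Box-plot outliers by the 1.5 x IQR rule, type-7 (linear) quantiles."""
    q1, q3 = np.quantile(values.to_numpy(), [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    if side == "lower":
        mask = values < q1 - 1.5 * iqr
    else:
        mask = values > q3 + 1.5 * iqr
    return list(values.index[mask])


def flag_low_depth(asv_totals: Mapping[str, int] | pd.Series) -> list[str]:
    """Samples whose log10 ASV-assigned read total is a box-plot lower outlier.

    With fewer than 4 samples the quartiles are meaningless; nothing is
    excluded and a warning is emitted.
    """
    totals = pd.Series(asv_totals, dtype=float)
    if len(totals) < 4:
        warnings.warn(
            f"only {len(totals)} samples: skipping low-depth outlier screen",
            stacklevel=2,
        )
        return []
    zero = list(totals.index[totals <= 0])
    positive = totals[totals > 0]
    if len(positive) < 4:
        return zero
    return zero + _box_outliers(np.log10(positive), "lower")


def flag_extreme_outliers(mean_bc: Mapping[str, float] | pd.Series) -> list[str]:
    """Samples whose mean intrasource dissimilarity is a box-plot upper outlier.

    These samples (handling or contamination artifacts, sometimes with
    dissimilarities >0.95 to every conspecific) are withheld from both
    training and performance evaluation, but reported rather than deleted.
    """
    mbc = pd.Series(mean_bc, dtype=float)
    if len(mbc) < 4:
        return []
    return _box_outliers(mbc, "upper")


def detect_subgroups(
    table: pd.DataFrame, branch_threshold: float = 5.0
) -> pd.Series:
    """Detect a bifurcated source community by Ward clustering.

    Ward linkage is computed on the Bray-Curtis matrix using the legacy
    agglomeration criterion applied to raw dissimilarities (R ``hclust``
    ``ward.D``), whose heights accumulate: a genuine two-type cohort pushes
    the final merge far above the rest.  When the final merge height minus
    the preceding one exceeds ``branch_threshold`` (default 5), the cohort
    is split into the two top-level subgroups; otherwise everything is one
    subgroup.

    Returns a Series mapping sample id -> subgroup label (1-based).
    """
    if len(table) < 4:
        return pd.Series(1, index=table.index, dtype=int)
    rel = _relabund(table)
    d = pdist(rel.to_numpy(), metric="braycurtis")
    # ward on sqrt(d) runs the Lance-Williams update on d itself; squared
    # heights therefore reproduce ward.D heights on raw dissimilarities.
    Z = linkage(np.sqrt(d), method="ward")
    heights = Z[:, 2] ** 2
    if len(heights) >= 2 and heights[-1] - heights[-2] > branch_threshold:
        Zd = Z.copy()
        Zd[:, 2] = heights
        labels = fcluster(Zd, t=2, criterion="maxclust")
        return pd.Series(labels, index=table.index, dtype=int)
    return pd.Series(1, index=table.index, dtype=int)


def _pick_most_cohesive(
    candidates: list[str], mean_bc: pd.Series, k: int
) -> list[str]:
    """k candidates with smallest mean intrasource BC; ties by sample id."""
    ranked = sorted(candidates, key=lambda s: (mean_bc[s], s))
    return ranked[:k]


def split_train_test(
    cohort: SourceCohort,
    train_size: int = 20,
    min_train: int = 15,
    min_test: int = 6,
    min_test_fraction: float = 0.30,
) -> SourceCohort:
    """Split usable samples into cohesive train and dissimilar test sets.

    Training takes the ``train_size`` samples with the smallest mean
    intrasource Bray-Curtis dissimilarity (balanced across subgroups when a
    bifurcation was detected); everything else tests the classifier and is
    by construction the most dissimilar part of the cohort.  The test set
    must hold at least ``min_test`` samples and at least
    ``min_test_fraction`` of the training-set size (six test samples for
    the full 20-sample training set); if not, ``train_size`` is reduced
    toward ``min_train``, and below that the cohort is rejected.
    """
    usable = cohort.usable_ids
    n = len(usable)
    size = min(train_size, n)
    while size >= min_train:
        n_test = n - size
        if n_test >= max(min_test, int(np.ceil(min_test_fraction * size))):
            break
        size -= 1
    else:
        raise InsufficientCohortError(
            f"source {cohort.source!r}: {n} usable samples cannot satisfy "
            f"train {min_train}-{train_size} with >= {min_test} test samples "
            f"({min_test_fraction:.0%} minimum)"
        )

    mbc = cohort.mean_intra_bc
    if cohort.subgroups is not None and cohort.subgroups.nunique() > 1:
        groups = sorted(cohort.subgroups.unique())
        per = {g: [s for s in usable if cohort.subgroups[s] == g] for g in groups}
        # Balanced draw: distribute the train budget as evenly as the
        # subgroup sizes allow, largest groups absorbing remainders.
        quota = {g: size // len(groups) for g in groups}
        rem = size - sum(quota.values())
        for g in sorted(groups, key=lambda g: -len(per[g]))[:rem]:
            quota[g] += 1
        # If a subgroup is too small, its shortfall spills into the others.
        train: list[str] = []
        spill = 0
        for g in groups:
            take = min(quota[g], len(per[g]))
            spill += quota[g] - take
            train += _pick_most_cohesive(per[g], mbc, take)
        if spill:
            rest = [s for s in usable if s not in set(train)]
            train += _pick_most_cohesive(rest, mbc, spill)
    else:
        train = _pick_most_cohesive(usable, mbc, size)

    train_set = set(train)
    cohort.train_ids = sorted(train)
    cohort.test_ids = sorted(s for s in usable if s not in train_set)
    return cohort


def build_cohort(
    source: str,
    table: pd.DataFrame,
    retention: pd.Series | None = None,
    retention_threshold: float = 0.5,
    train_size: int = 20,
    branch_threshold: float = 5.0,
    detect_bifurcation: bool = True,
) -> SourceCohort:
    """Full cohort pipeline for one source's count table.

    Order of screens: MED retention, sequencing depth, then community
    outliers on the survivors; finally subgroup detection and the
    train/test split.
    """
    excluded: dict[str, str] = {}
    if retention is not None:
        for s in table.index:
            if s in retention.index and retention[s] < (1 - retention_threshold):
                excluded[s] = "low_retention"
    surv = table.drop(index=list(excluded))
    for s in flag_low_depth(surv.sum(axis=1)):
        excluded[s] = "low_depth"
    surv = table.drop(index=list(excluded))
    mbc_all = mean_intrasource_bc(surv)
    for s in flag_extreme_outliers(mbc_all):
        excluded[s] = "extreme_outlier"
    surv = table.drop(index=list(excluded))
    # Recompute cohesion among the final usable set only.
    mbc = mean_intrasource_bc(surv)

    cohort = SourceCohort(
        source=source,
        sample_ids=list(table.index),
        mean_intra_bc=mbc,
        excluded=excluded,
    )
    if detect_bifurcation and len(surv) >= 4:
        sub = detect_subgroups(surv, branch_threshold=branch_threshold)
        if sub.nunique() > 1:
            cohort.subgroups = sub
    return split_train_test(cohort, train_size=train_size)


def cohort_report(cohorts: Iterable[SourceCohort]) -> pd.DataFrame:
    """Tabular report: sample, source, cohesion, role, reason, subgroup."""
    rows = []
    for c in cohorts:
        roles = {s: "train" for s in c.train_ids}
        roles.update({s: "test" for s in c.test_ids})
        for s in c.sample_ids:
            rows.append(
                {
                    "sample_id": s,
                    "source": c.source,
                    "mean_intra_bc": float(c.mean_intra_bc[s]) if s in c.mean_intra_bc.index else np.nan,
                    "role": roles.get(s, "excluded"),
                    "reason": c.excluded.get(s, ""),
                    "subgroup": int(c.subgroups[s]) if c.subgroups is not None and s in c.subgroups.index else 1,
                }
            )
    return pd.DataFrame(rows)
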