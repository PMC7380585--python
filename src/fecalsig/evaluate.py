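"""Classifier performance evaluation and detection-limit analyses.

Sensitivity is TP/(TP+FN) over samples whose true source is the focal one;
specificity is TN/(TN+FP) over samples of every other source (including
any extra hold-out sources supplied to make the negative panel harder).
Undefined quotients are reported as missing, never as zero.

The detection limit is probed two ways, both in silico:

* **subsampling curves** — a positive sample is subsampled without
  replacement at decreasing percentages (90 down to 0.001) and
  reclassified; the limit is the smallest matched-read count at which the
  call is still correct;
* **artificial mixtures** — defined proportions of reads from background
  water and fecal samples are combined at a chosen depth, with repeated
  random draws, and the mixtures classified against the signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import Read
from .classify import FlagThresholds, classify_sample, decide, match_reads
from .signature import SourceSignature

__all__ = [
    "ConfusionSummary",
    "MixtureDesign",
    "confusion",
    "subsample_curve",
    "detection_limit",
    "make_mixture",
    "evaluation_report",
    "DEFAULT_SUBSAMPLE_FRACTIONS",
]

# Percentages used for the incremental subsampling of test samples.
DEFAULT_SUBSAMPLE_FRACTIONS = (
    90, 80, 70, 60, 50, 40, 30, 20, 10, 5, 1, 0.5, 0.1, 0.05, 0.01, 0.005, 0.001,
)


@dataclass(frozen=True)
class ConfusionSummary:
    TP: int
    FN: int
    TN: int
    FP: int

    @property
    def sensitivity(self) -> float | None:
        return self.TP / (self.TP + self.FN) if (self.TP + self.FN) else None

    @property
    def specificity(self) -> float | None:
        return self.TN / (self.TN + self.FP) if (self.TN + self.FP) else None


@dataclass(frozen=True)
class MixtureDesign:
    """Recipe for an artificial community: components, proportions, depth."""

    components: tuple[str, ...]
    proportions: tuple[float, ...]
    depth: int
    repeats: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) != len(self.proportions):
            raise ValueError("components and proportions must align")
        if not math.isclose(sum(self.proportions), 1.0, abs_tol=1e-9):
            raise ValueError("proportions must sum to 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def confusion(
    calls: Mapping[str, bool] | pd.Series,
    truth: Mapping[str, str] | pd.Series,
    focal_source: str | Sequence[str],
) -> ConfusionSummary:
    """Confusion counts of one signature's calls against truth labels.

    ``calls`` maps sample id -> contaminated-by-focal-source decision;
    ``truth`` maps sample id -> true source label.  Samples of the focal
    source(s) are positives; everything else (other sources, background,
    sources without a classifier) is negative.
    """
    calls = pd.Series(calls, dtype=bool)
    truth = pd.Series(truth, dtype=str)
    missing = set(calls.index) - set(truth.index)
    if missing:
        raise ValueError(f"samples without truth labels: {sorted(missing)[:5]}")
    focal = {focal_source} if isinstance(focal_source, str) else set(focal_source)
    tp = fn = tn = fp = 0
    for s, called in calls.items():
        if truth[s] in focal:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionSummary(TP=int(tp), FN=int(fn), TN=int(tn), FP=int(fp))


def subsample_curve(
    reads: Sequence[Read],
    signature: SourceSignature,
    fractions: Sequence[float] = DEFAULT_SUBSAMPLE_FRACTIONS,
    repeats: int = 10,
    seed: int = 0,
    thresholds: FlagThresholds = FlagThresholds(),
) -> pd.DataFrame:
    """Voting probability vs library size for one positive sample.

    For each percentage, reads are drawn without replacement ``repeats``
    times and scored.  Returns a frame with one row per fraction:
    mean_probability, call_rate (fraction of repeats above the cutoff),
    mean_matched_reads, mean_matched_asvs.  A fraction yielding zero reads
    is recorded as an empty draw with probability 0.
    """
    if not reads:
        raise ValueError("subsample_curve requires a non-empty sample")
    bad = [f for f in fractions if not (0 < f <= 100)]
    if bad:
        raise ValueError(f"fractions must lie in (0, 100]: {bad}")
    rng = np.random.default_rng(seed)
    seqs = np.array([r.sequence for r in reads])
    n = len(seqs)
    rows = []
    for frac in fractions:
        k = int(round(n * frac / 100.0))
        probs, calls, mreads, masvs = [], [], [], []
        for _ in range(repeats):
            if k == 0:
                probs.append(0.0)
                calls.append(False)
                mreads.append(0)
                masvs.append(0)
                continue
            draw = seqs[rng.choice(n, size=k, replace=False)]
            counts, m, u = match_reads(list(draw), signature.asv_sequences)
            res = decide(signature, counts)
            probs.append(res.voting_probability if m > 0 else 0.0)
            calls.append(res.contaminated)
            mreads.append(m)
            masvs.append(u)
        rows.append(
            {
                "fraction_pct": frac,
                "n_drawn": k,
                "mean_probability": float(np.mean(probs)),
                "sd_probability": float(np.std(probs)),
                "call_rate": float(np.mean(calls)),
                "mean_matched_reads": float(np.mean(mreads)),
                "sd_matched_reads": float(np.std(mreads)),
                "mean_matched_asvs": float(np.mean(masvs)),
            }
        )
    return pd.DataFrame(rows)


def detection_limit(curve: pd.DataFrame, min_call_rate: float = 0.5) -> float | None:
    """Smallest mean matched-read count at which the call still holds.

    Scans the subsample curve for rows whose call rate is at least
    ``min_call_rate`` and returns the smallest mean matched-read count
    among them; None if the source is never called.
    """
    ok = curve[curve["call_rate"] >= min_call_rate]
    if ok.empty:
        return None
    return float(ok["mean_matched_reads"].min())


def make_mixture(
    design: MixtureDesign,
    component_reads: Mapping[str, Sequence[Read]],
) -> list[list[Read]]:
    """Generate repeated artificial community mixtures.

    Per repeat, ``round(depth * proportion)`` reads are drawn without
    replacement from each component, concatenated and shuffled.  A
    component shallower than its requested draw is an error — mixtures
    must honor their stated proportions exactly.
    """
    rng = np.random.default_rng(design.seed)
    wants = {
        c: int(round(design.depth * p))
        for c, p in zip(design.components, design.proportions)
    }
    for c, k in wants.items():
        if c not in component_reads:
            raise ValueError(f"missing component {c!r}")
        if k > len(component_reads[c]):
            raise ValueError(
                f"component {c!r} has {len(component_reads[c])} reads; "
                f"{k} requested"
            )
    mixtures: list[list[Read]] = []
    for rep in range(design.repeats):
        pool: list[Read] = []
        for c, k in wants.items():
            src = component_reads[c]
            idx = rng.choice(len(src), size=k, replace=False)
            pool.extend(src[i] for i in idx)
        order = rng.permutation(len(pool))
        mixtures.append([pool[i] for i in order])
    return mixtures


def evaluation_report(
    signatures: Sequence[SourceSignature],
    sample_reads: Mapping[str, Sequence[Read]],
    truth: Mapping[str, str],
    focal_members: Mapping[str, Sequence[str]] | None = None,
    thresholds: FlagThresholds = FlagThresholds(),
) -> pd.DataFrame:
    """Confusion summary of every signature over a labeled sample panel."""
    rows = []
    for sig in signatures:
        calls = {}
        for sid, reads in sample_reads.items():
            counts, _, _ = match_reads(reads, sig.asv_sequences)
            calls[sid] = decide(sig, counts, sample_id=sid).contaminated
        members = (
            focal_members.get(sig.source, [sig.source])
            if focal_members
            else [sig.source]
        )
        cm = confusion(calls, truth, list(members))
        rows.append(
            {
                "signature": sig.source,
                "region": sig.region,
                "group": sig.group,
                "TP": cm.TP,
                "FN": cm.FN,
                "TN": cm.TN,
                "FP": cm.FP,
                "sensitivity": cm.sensitivity,
                "specificity": cm.specificity,
                "n": cm.TP + cm.FN + cm.TN + cm.FP,
            }
        )
    return pd.DataFrame(rows)
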