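"""Classify query samples against trained source signatures.

Classification is deliberately simple at query time: a read counts toward a
signature ASV only when its sequence is byte-identical to the stored
representative (which is why trimming query reads to the exact region
coordinates matters).  The matched-count profile is renormalized over the
signature's ASVs and scored by the pooled voting ensemble; a sample is
called contaminated by a source when the voting probability strictly
exceeds the signature's decision cutoff.

Warning flags mirror the depth findings behind the method: about 1,000
signature-matching sequences spread over ~100 unique ASVs are needed for a
reliable call, so shallower samples are flagged rather than silently
trusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import Read, Region, detect_region
from .signature import ClassifierType, SourceSignature

__all__ = [
    "Flag",
    "SpecificityBand",
    "FlagThresholds",
    "VotingResult",
    "match_reads",
    "decide",
    "apply_flags",
    "source_arcs",
    "classify_sample",
]


class Flag(str, Enum):
    LOW_INPUT = "LOW_INPUT"
    LOW_MATCH = "LOW_MATCH"
    NO_MATCH = "NO_MATCH"
    DISCARDED_CLASSIFIER = "DISCARDED_CLASSIFIER"


class SpecificityBand(str, Enum):
    HIGH = "high"  # empirical specificity >= 80% at the observed probability
    LOW = "low"
    NA = "n/a"


@dataclass(frozen=True)
class FlagThresholds:
    """Depth thresholds below which a call carries a warning."""

    min_input_reads: int = 1_000
    min_matched_reads: int = 1_000
    min_matched_asvs: int = 100


@dataclass
class VotingResult:
    """Per-sample, per-signature classification record."""

    sample_id: str
    signature_id: str
    matched_read_count: int
    matched_unique_asv_count: int
    voting_probability: float
    decision_cutoff: float | None
    contaminated: bool
    classifier_type: ClassifierType
    specificity_band: SpecificityBand = SpecificityBand.NA
    flags: set[Flag] = field(default_factory=set)


def match_reads(
    reads: Sequence[Read] | Sequence[str],
    asv_sequences: Sequence[str],
) -> tuple[np.ndarray, int, int]:
    """Exact-match read counts over a signature's ASVs.

    Accepts Read objects or raw sequence strings.  Returns
    ``(counts, matched_read_count, matched_unique_asv_count)`` with
    ``counts`` aligned to ``asv_sequences``.
    """
    index = {seq: i for i, seq in enumerate(asv_sequences)}
    counts = np.zeros(len(asv_sequences), dtype=int)
    for r in reads:
        seq = r.sequence if isinstance(r, Read) else r
        i = index.get(seq)
        if i is not None:
            counts[i] += 1
    return counts, int(counts.sum()), int((counts > 0).sum())


def _check_region(reads: Sequence[Read], signature: SourceSignature) -> None:
    sig_region = signature.region
    if sig_region in (None, "", Region.UNKNOWN.value):
        return
    detected = detect_region(list(reads))
    if detected is Region.UNKNOWN:
        return
    if detected.value != sig_region:
        raise ValueError(
            f"region mismatch: input reads look like {detected.value} but "
            f"signature {signature.source!r} targets {sig_region}"
        )


def _empirical_specificity_band(
    signature: SourceSignature, probability: float
) -> SpecificityBand:
    """Band the call by held-out negative behavior at this probability.

    The empirical specificity at probability p is the fraction of the
    signature's held-out negative test samples scoring at or below p; if
    the calibration distributions were not stored the band is n/a.
    """
    probs = signature.metadata.get("test_probabilities")
    labs = signature.metadata.get("test_labels")
    if not probs or not labs:
        return SpecificityBand.NA
    neg = [probs[s] for s, v in labs.items() if v == 0 and s in probs]
    if not neg:
        return SpecificityBand.NA
    spec = float(np.mean([p <= probability for p in neg]))
    return SpecificityBand.HIGH if spec >= 0.80 else SpecificityBand.LOW


def decide(
    signature: SourceSignature,
    counts: np.ndarray,
    sample_id: str = "",
) -> VotingResult:
    """Score one matched-count profile against one signature.

    The profile is renormalized over the signature ASVs; contamination is
    declared when probability strictly exceeds the cutoff.  Discarded
    classifiers still report their probability but never make a call.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    profile = counts / total if total > 0 else counts
    prob = float(signature.ensemble.vote_fractions(profile[None, :])[0])
    discarded = signature.classifier_type is ClassifierType.DISCARDED
    cutoff = signature.decision_cutoff
    contaminated = (
        not discarded and cutoff is not None and prob > cutoff and total > 0
    )
    flags = {Flag.DISCARDED_CLASSIFIER} if discarded else set()
    return VotingResult(
        sample_id=sample_id,
        signature_id=f"{signature.source}:{signature.region}:{signature.group}",
        matched_read_count=int(total),
        matched_unique_asv_count=int((counts > 0).sum()),
        voting_probability=prob,
        decision_cutoff=cutoff,
        contaminated=contaminated,
        classifier_type=signature.classifier_type,
        specificity_band=_empirical_specificity_band(signature, prob),
        flags=flags,
    )


def apply_flags(
    result: VotingResult,
    sample_total_reads: int,
    thresholds: FlagThresholds = FlagThresholds(),
) -> VotingResult:
    """Attach depth warnings; the decision itself is left untouched."""
    if sample_total_reads < thresholds.min_input_reads:
        result.flags.add(Flag.LOW_INPUT)
    if result.matched_read_count == 0:
        result.flags.add(Flag.NO_MATCH)
    elif (
        result.matched_read_count < thresholds.min_matched_reads
        or result.matched_unique_asv_count < thresholds.min_matched_asvs
    ):
        result.flags.add(Flag.LOW_MATCH)
    return result


def source_arcs(
    reads: Sequence[Read] | Sequence[str],
    signatures: Sequence[SourceSignature],
) -> pd.Series:
    """Per-source share of all fecally-matched reads in a sample.

    Reads matching several signatures' ASVs (shared sequences) are split
    equally among the matching sources so the shares sum to 1.  Returns an
    empty Series when nothing matches.
    """
    if not signatures:
        raise ValueError("source_arcs requires at least one signature")
    membership: dict[str, list[str]] = {}
    for sig in signatures:
        for seq in sig.asv_sequences:
            membership.setdefault(seq, []).append(sig.source)
    shares: dict[str, float] = {sig.source: 0.0 for sig in signatures}
    total = 0.0
    for r in reads:
        seq = r.sequence if isinstance(r, Read) else r
        owners = membership.get(seq)
        if not owners:
            continue
        total += 1.0
        w = 1.0 / len(owners)
        for src in owners:
            shares[src] += w
    if total == 0:
        return pd.Series(dtype=float)
    return pd.Series({s: v / total for s, v in shares.items() if v > 0}).sort_values(
        ascending=False
    )


def classify_sample(
    reads: Sequence[Read],
    signatures: Sequence[SourceSignature],
    sample_id: str = "",
    thresholds: FlagThresholds = FlagThresholds(),
    check_region: bool = True,
) -> tuple[list[VotingResult], pd.Series]:
    """Run one sample against every signature; returns results and arcs."""
    results = []
    for sig in signatures:
        if check_region:
            _check_region(reads, sig)
        counts, _, _ = match_reads(reads, sig.asv_sequences)
        res = decide(sig, counts, sample_id=sample_id)
        results.append(apply_flags(res, len(reads), thresholds))
    arcs = source_arcs(reads, signatures)
    return results, arcs
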