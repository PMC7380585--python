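"""Minimum entropy decomposition (MED) of equal-length amplicon reads.

MED partitions reads into amplicon sequence variants (ASVs) by repeatedly
splitting the read set at the highest-entropy alignment position: true
biological variation concentrates entropy at a few positions, while random
sequencing error spreads low entropy everywhere.  A node whose per-position
Shannon entropy profile is everywhere below the stopping criterion is a
final ASV; children smaller than the minimum substantive abundance ``M``
are dissolved and their reads counted as discarded noise.

``M`` scales with library size: N/30,000 for V4V5, N/40,000 for V4 and
N/60,000 for V6, rounded up and floored at 2 so singletons never form an
ASV.

Reads must be equal length (the upstream length window guarantees this for
one region) and free of ambiguous bases (upstream quality filter), so
entropy is over {A,C,G,T} only and columns are plain read positions — no
alignment step is needed.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import Read, Region

__all__ = [
    "M_DIVISORS",
    "column_entropy",
    "compute_M",
    "med_decompose",
    "retention_check",
    "MEDResult",
    "write_asv_table",
    "read_asv_table",
]

M_DIVISORS: dict[Region, int] = {
    Region.V4V5: 30_000,
    Region.V4: 40_000,
    Region.V6: 60_000,
}

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class MEDResult:
    """Outcome of one MED run over a pooled sample set.

    ``table`` is the samples x ASVs count matrix, columns keyed by the
    ASV representative sequence.  ``discarded`` and ``retention`` are
    per-sample; retention is the fraction of input reads assigned to a
    surviving ASV.
    """

    table: pd.DataFrame
    discarded: pd.Series
    retention: pd.Series
    M: int

    @property
    def representative_sequences(self) -> list[str]:
        return list(self.table.columns)


def column_entropy(counts: Mapping[str, int] | Sequence[int]) -> float:
    """Shannon entropy (bits) of one alignment column's base counts.

    Accepts a mapping over {A,C,G,T} or a length-4 count vector in ACGT
    order.  The total must be positive; ambiguous bases never reach MED so
    only the four concrete bases are counted.
    """
    if isinstance(counts, Mapping):
        vec = np.array([counts.get(b, 0) for b in _BASES], dtype=float)
        extra = set(counts) - set(_BASES)
        if extra:
            raise ValueError(f"unexpected bases in column counts: {sorted(extra)}")
    else:
        vec = np.asarray(counts, dtype=float)
        if vec.shape != (4,):
            raise ValueError("count vector must have length 4 (ACGT order)")
    total = vec.sum()
    if total <= 0:
        raise ValueError("column has zero total count")
    p = vec[vec > 0] / total
    return float(-(p * np.log2(p)).sum())


def compute_M(N: int, region: Region, min_M: int = 2) -> int:
    """Minimum substantive abundance for a library of N reads.

    ``ceil(N / divisor)`` with the region-specific divisor, clamped from
    below at ``min_M`` (default 2) so singleton variants are always noise.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    divisor = M_DIVISORS.get(region)
    if divisor is None:
        raise ValueError(f"no M divisor defined for region {region!r}")
    return max(min_M, math.ceil(N / divisor))


def _entropy_profile(seqs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-position entropy (bits) of weighted sequences.

    ``seqs`` is an (n_unique, L) uint8 array of base indices; ``weights``
    the count of each unique sequence.
    """
    n, L = seqs.shape
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = ((seqs == b) * weights[:, None]).sum(axis=0)
    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=0)


def _minor_counts(seqs: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-position count of reads NOT carrying the majority base."""
    n, L = seqs.shape
    counts = np.zeros((4, L))
    for b in range(4):
        counts[b] = ((seqs == b) * weights[:, None]).sum(axis=0)
    return counts.sum(axis=0) - counts.max(axis=0)


def med_decompose(
    reads: Sequence[Read],
    M: int,
    max_entropy: float = 0.0,
    max_discriminants: int = 4,
    minor_count_floor: int = 1,
) -> MEDResult:
    """Decompose pooled reads into ASVs by iterative entropy splitting.

    At each node the entropy profile is computed; positions with entropy
    strictly above ``max_entropy`` and at least ``minor_count_floor`` reads
    off the majority base are discriminative.  The node splits on the joint
    base pattern at up to ``max_discriminants`` highest-entropy
    discriminative positions; children with fewer than ``M`` reads are
    dissolved and their reads discarded.  Recursion ends when no position
    is discriminative.

    The result is deterministic in the read *multiset*: read order never
    matters.  Representative sequences are the most abundant member
    sequence of each ASV, ties broken lexicographically.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if not reads:
        raise ValueError("med_decompose requires at least one read")
    lengths = {len(r.sequence) for r in reads}
    if len(lengths) > 1:
        raise ValueError(
            f"reads have unequal lengths {sorted(lengths)}; "
            "apply the region length filter before MED"
        )

    # Collapse to unique sequences with per-sample counts; sorted for
    # order-independence.
    per_seq_sample: dict[str, Counter] = defaultdict(Counter)
    for r in reads:
        per_seq_sample[r.sequence][r.sample_id] += 1
    uniq = sorted(per_seq_sample)
    L = lengths.pop()
    mat = np.frombuffer(
        "".join(uniq).encode(), dtype=np.uint8
    ).reshape(len(uniq), L)
    lut = np.zeros(256, dtype=np.uint8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    mat = lut[mat]
    weights = np.array([sum(per_seq_sample[s].values()) for s in uniq])

    samples = sorted({r.sample_id for r in reads})
    sample_totals = Counter(r.sample_id for r in reads)

    final_groups: list[np.ndarray] = []  # index arrays into uniq
    discarded_idx: list[np.ndarray] = []

    stack: list[np.ndarray] = [np.arange(len(uniq))]
    while stack:
        idx = stack.pop()
        sub, w = mat[idx], weights[idx]
        ent = _entropy_profile(sub, w)
        minor = _minor_counts(sub, w)
        discr = np.flatnonzero((ent > max_entropy) & (minor >= minor_count_floor))
        if discr.size == 0:
            final_groups.append(idx)
            continue
        # Up to max_discriminants highest-entropy positions; stable order by
        # (-entropy, position) for determinism.
        order = sorted(discr, key=lambda j: (-ent[j], j))[:max_discriminants]
        patterns = defaultdict(list)
        for local, row in enumerate(sub[:, order]):
            patterns[tuple(row)].append(idx[local])
        for pat in sorted(patterns):
            child = np.array(patterns[pat])
            if weights[child].sum() < M:
                discarded_idx.append(child)
            else:
                stack.append(child)

    # Apply the M criterion to final nodes too (a node may drop below M
    # only at the root when the whole input is sparse).
    kept_groups = []
    for g in final_groups:
        if weights[g].sum() < M:
            discarded_idx.append(g)
        else:
            kept_groups.append(g)

    # Representative = most abundant member sequence, ties lexicographic.
    columns: dict[str, Counter] = {}
    for g in kept_groups:
        members = [(uniq[i], weights[i]) for i in g]
        rep = min(members, key=lambda t: (-t[1], t[0]))[0]
        agg: Counter = Counter()
        for i in g:
            agg.update(per_seq_sample[uniq[i]])
        columns[rep] = agg

    table = pd.DataFrame(
        {rep: [columns[rep].get(s, 0) for s in samples] for rep in sorted(columns)},
        index=pd.Index(samples, name="sample_id"),
        dtype=int,
    )
    discarded = pd.Series(0, index=table.index, dtype=int)
    for g in discarded_idx:
        for i in g:
            for s, c in per_seq_sample[uniq[i]].items():
                discarded[s] += c
    assigned = table.sum(axis=1) if len(table.columns) else pd.Series(0, index=table.index)
    totals = pd.Series({s: sample_totals[s] for s in samples})
    retention = (assigned / totals).astype(float)
    return MEDResult(table=table, discarded=discarded, retention=retention, M=M)


def retention_check(
    result: MEDResult | Mapping[str, float] | pd.Series, threshold: float = 0.5
) -> pd.Series:
    """Per-sample pass/fail on read retention through MED.

    A sample fails when *more than* ``threshold`` of its reads were
    discarded, i.e. retention strictly below ``1 - threshold``; exactly at
    the boundary passes.  When screening multiple bacterial groups, a
    sample failing for any group is dropped — combine the boolean Series
    with ``&`` across runs.
    """
    if isinstance(result, MEDResult):
        retention = result.retention
    else:
        retention = pd.Series(result, dtype=float)
    return retention >= (1 - threshold)


def write_asv_table(result: MEDResult, counts_path: str | Path, fasta_path: str | Path) -> None:
    """Serialize an ASV table as TSV plus a companion representative FASTA.

    Columns are renamed ``ASV_0001``... in the TSV; the FASTA maps each id
    back to its representative sequence.
    """
    ids = [f"ASV_{i+1:04d}" for i in range(len(result.table.columns))]
    out = result.table.copy()
    seqs = list(out.columns)
    out.columns = ids
    out.to_csv(counts_path, sep="\t")
    with open(fasta_path, "w") as fh:
        for asv_id, seq in zip(ids, seqs):
            fh.write(f">{asv_id}\n{seq}\n")


def read_asv_table(counts_path: str | Path, fasta_path: str | Path) -> pd.DataFrame:
    """Load a TSV + FASTA pair back into a sequence-keyed count table."""
    from Bio import SeqIO

    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    id2seq = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    missing = set(df.columns) - set(id2seq)
    if missing:
        raise ValueError(f"ASV ids missing from FASTA: {sorted(missing)[:5]}")
    df.columns = [id2seq[c] for c in df.columns]
    return df
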