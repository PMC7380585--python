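"""Synthetic host-source communities with controlled ASV structure.

Real fecal microbiomes carry host-specific sequence variants: some ASVs
are exclusive to one host species, some are shared among hosts, and water
samples dilute any fecal signal into a large environmental background.
This module fabricates data with exactly that structure so every pipeline
stage — filtering, MED, cohort screening, signature training, and
classification — can be exercised end to end without downloads:

* an ASV pool of random equal-length sequences (region length: 253 bp V4,
  60 bp V6, 372 bp V4V5) at pairwise Hamming distance >= 2, partitioned
  into per-source exclusive sets, shared sets and a background set;
* per-sample community profiles drawn from a source-specific Dirichlet
  (the concentration controls intra-host dispersion);
* reads drawn multinomially at a log-normal depth, optionally with
  per-base substitution noise to exercise MED's abundance filter;
* contaminated "water" samples mixing background with a chosen fraction
  of fecal reads.

Everything is bit-reproducible under (design, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amplicon_io import Read, Region

__all__ = [
    "SourceSpec",
    "SyntheticDesign",
    "ASVPool",
    "default_design",
    "generate_asv_pool",
    "sample_community",
    "generate_cohorts",
    "contaminate",
]

REGION_LENGTHS = {Region.V4: 253, Region.V6: 60, Region.V4V5: 372}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SourceSpec:
    """One host archetype: its ASV complement and variability."""

    label: str
    n_exclusive_asvs: int = 30
    n_shared_asvs: int = 5
    concentration: float = 50.0  # Dirichlet concentration per ASV; lower = more dispersed
    subgroups: int = 1  # >1 plants a community bifurcation


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design: sources, depths, background, and the master seed.

    Defaults mirror a desk-scale version of a multi-host fecal survey:
    five sources, 25 samples each, ~10^4 reads per sample, 30 exclusive
    plus 5 shared ASVs per source — large enough for the 15-20 train /
    >=6 test split rule, small enough for minutes-scale runs.
    """

    sources: tuple[SourceSpec, ...] = (
        SourceSpec("sewage"),
        SourceSpec("dog"),
        SourceSpec("cattle"),
        SourceSpec("pig"),
        SourceSpec("deer"),
    )
    region: Region = Region.V6
    n_samples: int = 25
    depth_log10_mean: float = 4.0
    depth_log10_sd: float = 0.1
    background_asvs: int = 100
    noise_rate: float = 0.0  # per-base substitution probability
    seed: int = 0

    @property
    def read_length(self) -> int:
        return REGION_LENGTHS[self.region]


@dataclass
class ASVPool:
    """Generated ASV sequences with their source assignments."""

    sequences: list[str]
    source_asvs: dict[str, list[int]]  # source label -> indices into sequences
    background: list[int]
    subgroup_asvs: dict[str, list[list[int]]] = field(default_factory=dict)

    def sequences_of(self, source: str) -> list[str]:
        return [self.sequences[i] for i in self.source_asvs[source]]


def default_design(**overrides) -> SyntheticDesign:
    return replace(SyntheticDesign(), **overrides)


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random sequences at pairwise Hamming distance >= 2.

    Rejection sampling; at 60+ bp random 4-letter sequences collide at
    distance < 2 with vanishing probability, so a modest retry budget
    suffices.  Requesting more sequences than the length can support
    collision-free raises.
    """
    if n > 4 ** min(length, 30) // 4:
        raise ValueError(f"cannot place {n} distinct ASVs at length {length}")
    out: list[np.ndarray] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n:
            raise ValueError(
                f"could not generate {n} sequences of length {length} at "
                "pairwise Hamming distance >= 2"
            )
        cand = _BASES[rng.integers(0, 4, size=length)]
        if all(int((cand != prev).sum()) >= 2 for prev in out):
            out.append(cand)
    return [s.tobytes().decode() for s in out]


def generate_asv_pool(design: SyntheticDesign) -> ASVPool:
    """Build the ASV pool: exclusive, shared and background sequences.

    Shared ASVs are assigned to a source and its ring neighbor so every
    shared sequence belongs to exactly two sources; a source with
    ``subgroups > 1`` has its exclusive ASVs split into disjoint per-subgroup
    blocks (a planted community bifurcation).
    """
    rng = np.random.default_rng(design.seed)
    n_excl = sum(s.n_exclusive_asvs for s in design.sources)
    n_shared = sum(s.n_shared_asvs for s in design.sources)
    total = n_excl + n_shared + design.background_asvs
    seqs = _random_sequences(rng, total, design.read_length)

    source_asvs: dict[str, list[int]] = {s.label: [] for s in design.sources}
    subgroup_asvs: dict[str, list[list[int]]] = {}
    cursor = 0
    for spec in design.sources:
        idx = list(range(cursor, cursor + spec.n_exclusive_asvs))
        cursor += spec.n_exclusive_asvs
        source_asvs[spec.label].extend(idx)
        if spec.subgroups > 1:
            blocks = [list(b) for b in np.array_split(idx, spec.subgroups)]
            subgroup_asvs[spec.label] = blocks
    labels = [s.label for s in design.sources]
    for si, spec in enumerate(design.sources):
        idx = list(range(cursor, cursor + spec.n_shared_asvs))
        cursor += spec.n_shared_asvs
        neighbor = labels[(si + 1) % len(labels)]
        source_asvs[spec.label].extend(idx)
        if neighbor != spec.label:
            source_asvs[neighbor].extend(idx)
    background = list(range(cursor, cursor + design.background_asvs))
    return ASVPool(
        sequences=seqs,
        source_asvs=source_asvs,
        background=background,
        subgroup_asvs=subgroup_asvs,
    )


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def sample_community(
    design: SyntheticDesign,
    pool: ASVPool,
    source: str,
    sample_id: str,
    depth: int,
    rng: np.random.Generator,
    subgroup: int | None = None,
) -> list[Read]:
    """Draw one sample's reads from a source community.

    Proportions over the source's ASVs follow a symmetric Dirichlet with
    the source's concentration; reads are multinomial at ``depth``.  For a
    bifurcated source, ``subgroup`` selects which exclusive-ASV block
    dominates (the other block is absent).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    spec = next(s for s in design.sources if s.label == source)
    asv_idx = list(pool.source_asvs[source])
    if subgroup is not None and source in pool.subgroup_asvs:
        blocks = pool.subgroup_asvs[source]
        drop = {i for b, blk in enumerate(blocks) if b != subgroup for i in blk}
        asv_idx = [i for i in asv_idx if i not in drop]
    props = rng.dirichlet(np.full(len(asv_idx), spec.concentration))
    counts = rng.multinomial(depth, props)
    reads = []
    k = 0
    for idx, c in zip(asv_idx, counts):
        seq = pool.sequences[idx]
        for _ in range(c):
            reads.append(
                Read(
                    read_id=f"{sample_id}_r{k:06d}",
                    sample_id=sample_id,
                    sequence=_mutate(seq, rng, design.noise_rate),
                    region=design.region,
                )
            )
            k += 1
    return reads


def sample_background(
    design: SyntheticDesign,
    pool: ASVPool,
    sample_id: str,
    depth: int,
    rng: np.random.Generator,
    concentration: float = 5.0,
) -> list[Read]:
    """One environmental (non-fecal) water sample over the background ASVs."""
    props = rng.dirichlet(np.full(len(pool.background), concentration))
    counts = rng.multinomial(depth, props)
    reads = []
    k = 0
    for idx, c in zip(pool.background, counts):
        seq = pool.sequences[idx]
        for _ in range(c):
            reads.append(
                Read(
                    read_id=f"{sample_id}_b{k:06d}",
                    sample_id=sample_id,
                    sequence=_mutate(seq, rng, design.noise_rate),
                    region=design.region,
                )
            )
            k += 1
    return reads


def generate_cohorts(
    design: SyntheticDesign,
) -> tuple[dict[str, list[Read]], pd.Series, ASVPool]:
    """Generate the full labeled training survey.

    Returns ``(reads_per_sample, truth_labels, pool)``.  Sample ids are
    ``{source}_{k:03d}``; depths are log-normal per sample; bifurcated
    sources alternate subgroups so both community types are represented.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(design.seed + 1)
    pool = generate_asv_pool(design)
    reads: dict[str, list[Read]] = {}
    truth: dict[str, str] = {}
    for spec in design.sources:
        # Depths are stratified quantiles of the log-normal (one draw per
        # probability stratum, shuffled): the depth spread follows the
        # stated distribution, while the survey stays free of accidental
        # box-plot depth outliers — these cohorts emulate runs that passed
        # per-run sequencing QC.
        n = design.n_samples
        z = norm.ppf((np.arange(n) + 0.5) / n)
        depths = np.round(
            10 ** (design.depth_log10_mean + design.depth_log10_sd * z)
        ).astype(int)
        depths = depths[rng.permutation(n)]
        for k in range(design.n_samples):
            sid = f"{spec.label}_{k:03d}"
            depth = int(depths[k])
            sub = k % spec.subgroups if spec.subgroups > 1 else None
            reads[sid] = sample_community(
                design, pool, spec.label, sid, depth, rng, subgroup=sub
            )
            truth[sid] = spec.label
    return reads, pd.Series(truth), pool


def contaminate(
    background_reads: Sequence[Read],
    source_reads: Sequence[Read] | Mapping[str, Sequence[Read]],
    signature_fraction: float | Mapping[str, float],
    depth: int,
    sample_id: str,
    seed: int = 0,
) -> list[Read]:
    """Compose a water-column sample with known fecal contamination.

    ``signature_fraction`` of the ``depth`` reads come from the fecal
    source(s) (a mapping allows several sources at once), the rest from
    the background.  Draws are without replacement; ground truth is the
    argument itself.
    """
    rng = np.random.default_rng(seed)
    if isinstance(source_reads, Mapping):
        fracs = dict(signature_fraction)
        sources = source_reads
    else:
        fracs = {"source": float(signature_fraction)}
        sources = {"source": source_reads}
    if not all(0 < f < 1 for f in fracs.values()) or sum(fracs.values()) >= 1:
        raise ValueError("fractions must lie in (0,1) and sum below 1")
    out: list[Read] = []
    for name, frac in fracs.items():
        k = int(round(depth * frac))
        src = list(sources[name])
        if k > len(src):
            raise ValueError(f"source {name!r} too shallow for fraction {frac}")
        idx = rng.choice(len(src), size=k, replace=False)
        out.extend(src[i] for i in idx)
    k_bg = depth - len(out)
    bg = list(background_reads)
    if k_bg > len(bg):
        raise ValueError("background too shallow for requested depth")
    idx = rng.choice(len(bg), size=k_bg, replace=False)
    out.extend(bg[i] for i in idx)
    order = rng.permutation(len(out))
    shuffled = [out[i] for i in order]
    return [
        replace(r, read_id=f"{sample_id}_m{i:06d}", sample_id=sample_id)
        for i, r in enumerate(shuffled)
    ]
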