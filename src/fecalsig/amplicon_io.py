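"""Amplicon read I/O and pre-classification filtering.

Reads arrive as merged, primer-trimmed 16S fragments in multi-FASTA form.
Before any downstream step they pass two per-read filters mirroring the
standard mothur-style screening of merged libraries:

* a length window around the expected median of the targeted variable
  region (372 bp for V4V5 at 5% tolerance; 253 bp for V4 and 60 bp for V6
  at 10% tolerance), and
* a quality screen discarding reads with ambiguous bases (``N``) or a
  homopolymer run longer than eight bases.

The targeted region is inferred from the median read length against those
windows.  V4V5 reads can additionally be trimmed down to the V4 fragment by
locating the V4 primer sites (IUPAC-degenerate match with a small mismatch
budget), which makes them comparable to de novo V4 libraries.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Region",
    "Read",
    "RegionProfile",
    "REGION_PROFILES",
    "FastaError",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "filter_by_length",
    "filter_by_quality",
    "detect_region",
    "trim_to_v4",
    "length_window",
]

DNA_ALPHABET = frozenset("ACGTN")

# IUPAC nucleotide codes -> the set of concrete bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Earth Microbiome Project V4 primer pair (515F/806R); configurable because
# the exact pair is a protocol choice, not a property of the method.
DEFAULT_V4_FORWARD = "GTGYCAGCMGCCGCAGCGG"
DEFAULT_V4_REVERSE = "GGACTACNVGGGTWTCTAAT"


class Region(str, Enum):
    V4 = "V4"
    V6 = "V6"
    V4V5 = "V4V5"
    UNKNOWN = "unknown"


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input; names the offending record."""


@dataclass(frozen=True)
class Read:
    """One merged amplicon read with its sample of origin."""

    read_id: str
    sample_id: str
    sequence: str
    region: Region = Region.UNKNOWN

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaError(f"read {self.read_id!r}: empty sequence")

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass(frozen=True)
class RegionProfile:
    """Expected merged-read geometry of one 16S variable region."""

    region: Region
    median_length: int
    tolerance_fraction: float
    primer_pair: tuple[str, str] | None = None
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        if self.median_length <= 0:
            raise ValueError("median_length must be positive")
        if self.tolerance_fraction not in (0.05, 0.10):
            raise ValueError("tolerance_fraction must be 0.05 or 0.10")


REGION_PROFILES: dict[Region, RegionProfile] = {
    Region.V4V5: RegionProfile(Region.V4V5, 372, 0.05),
    Region.V4: RegionProfile(
        Region.V4, 253, 0.10, (DEFAULT_V4_FORWARD, DEFAULT_V4_REVERSE)
    ),
    Region.V6: RegionProfile(Region.V6, 60, 0.10),
}


def length_window(profile: RegionProfile) -> tuple[int, int]:
    """Inclusive [low, high] read-length bounds for a region.

    Bounds are ``ceil(median*(1-tol))`` and ``floor(median*(1+tol))`` so the
    window is deterministic in integers and conservative at the edges.
    """
    m, tol = profile.median_length, profile.tolerance_fraction
    return math.ceil(m * (1 - tol)), math.floor(m * (1 + tol))


def read_fasta(path: str | Path, sample_id: str) -> list[Read]:
    """Parse a multi-FASTA file into reads for one sample.

    Sequences are uppercased; anything outside {A,C,G,T,N} is rejected with
    an error naming the record.  An empty file is an explicit error rather
    than a silent empty result.
    """
    path = Path(path)
    reads: list[Read] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FastaError(
                f"{path}: record {rec.id!r} contains non-DNA characters "
                f"{sorted(bad)}; expected bases over A,C,G,T,N"
            )
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate read id {rec.id!r} in sample {sample_id!r}")
        seen.add(rec.id)
        reads.append(Read(read_id=rec.id, sample_id=sample_id, sequence=seq))
    if not reads:
        raise FastaError(f"{path}: no FASTA records found (empty input)")
    return reads


def write_fasta(reads: Iterable[Read], path: str | Path) -> int:
    """Write reads as multi-FASTA; returns the number of records written."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_manifest(path: str | Path):
    """Load a sample manifest TSV.

    Columns: ``sample_id``, ``fasta_path`` and optionally ``source_label``
    and ``region``.  Returns a pandas DataFrame with missing optional
    columns filled with NA.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fasta_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path}: missing columns {sorted(missing)}")
    for col in ("source_label", "region"):
        if col not in df.columns:
            df[col] = pd.NA
    return df


def filter_by_length(
    reads: Sequence[Read], profile: RegionProfile
) -> tuple[list[Read], int]:
    """Keep reads inside the region's length window; count the removed."""
    low, high = length_window(profile)
    kept = [r for r in reads if low <= len(r.sequence) <= high]
    return kept, len(reads) - len(kept)


def filter_by_quality(
    reads: Sequence[Read], max_homopolymer: int = 8
) -> tuple[list[Read], int]:
    """Discard reads with ambiguous bases or a homopolymer run > max_homopolymer.

    A run of exactly ``max_homopolymer`` identical bases is kept; only
    strictly longer runs are discarded (mothur ``maxhomop`` semantics).
    """
    kept = []
    for r in reads:
        if "N" in r.sequence:
            continue
        if _max_run(r.sequence) > max_homopolymer:
            continue
        kept.append(r)
    return kept, len(reads) - len(kept)


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def detect_region(reads: Sequence[Read]) -> Region:
    """Infer the targeted region from the median read length.

    Returns the region whose length window contains the median; ``unknown``
    if no window matches or if the median falls inside two windows (the
    stated windows are disjoint, but custom profiles may overlap).
    """
    if not reads:
        raise ValueError("detect_region requires at least one read")
    med = statistics.median(len(r.sequence) for r in reads)
    hits = [
        prof.region
        for prof in REGION_PROFILES.values()
        if length_window(prof)[0] <= med <= length_window(prof)[1]
    ]
    if len(hits) == 1:
        return hits[0]
    return Region.UNKNOWN


def _iupac_mismatches(primer: str, window: str) -> int:
    """Hamming-style mismatch count of a read window against an IUPAC primer.

    'N' in the *read* never matches a primer base (an ambiguous base carries
    no evidence of the primer site).
    """
    mism = 0
    for p, b in zip(primer, window):
        if b == "N" or b not in IUPAC[p]:
            mism += 1
    return mism


def _find_site(seq: str, primer: str, max_mismatches: int) -> int | None:
    """Leftmost start of a primer site within the mismatch budget, else None."""
    plen = len(primer)
    best_pos, best_mism = None, max_mismatches + 1
    for pos in range(len(seq) - plen + 1):
        m = _iupac_mismatches(primer, seq[pos : pos + plen])
        if m < best_mism:
            best_pos, best_mism = pos, m
            if m == 0:
                break
    return best_pos if best_mism <= max_mismatches else None


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    return seq.translate(comp)[::-1]


def trim_to_v4(
    reads: Sequence[Read],
    primer_pair: tuple[str, str] = (DEFAULT_V4_FORWARD, DEFAULT_V4_REVERSE),
    max_mismatches: int = 2,
) -> tuple[list[Read], int]:
    """Trim V4V5 reads to the V4 fragment ending at the V4 reverse-primer site.

    V4 and V4V5 amplicons share the forward primer, so in primer-trimmed
    V4V5 reads the V4 fragment starts at the 5' end; if a forward-primer
    site is nonetheless present (untrimmed input) it is located and removed
    first.  The internal V4 reverse-primer site (matched as its reverse
    complement on the forward strand) must be found within the mismatch
    budget; reads where it cannot be located are dropped and counted.  The
    returned fragment excludes both primer sites.

    Returns ``(trimmed_reads, dropped_count)``.
    """
    fwd, rev = (p.upper() for p in primer_pair)
    for name, p in (("forward", fwd), ("reverse", rev)):
        bad = set(p) - set(IUPAC)
        if bad:
            raise ValueError(f"{name} primer contains non-IUPAC codes {sorted(bad)}")
    rev_rc = _revcomp(rev)
    out: list[Read] = []
    dropped = 0
    for r in reads:
        f = _find_site(r.sequence, fwd, max_mismatches)
        tail = r.sequence if f is None else r.sequence[f + len(fwd):]
        g = _find_site(tail, rev_rc, max_mismatches)
        if g is None or g == 0:
            dropped += 1
            continue
        out.append(replace(r, sequence=tail[:g], region=Region.V4))
    return out, dropped
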