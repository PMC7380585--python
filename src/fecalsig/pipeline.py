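"""End-to-end workflows: build signature bundles, classify query samples.

``run_build`` wires the stages together: per-sample read filtering, pooled
minimum entropy decomposition (``M`` computed from the pooled library
size), per-source cohort screening and train/test splitting, then
signature training with cutoff calibration for every source (plus any
requested multi-source diet/physiology groups).  ``run_classify`` loads
the bundles and scores query FASTA samples, producing the predictions,
arcs and report tables.

All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import amplicon_io as aio
from .amplicon_io import REGION_PROFILES, Read, Region
from .classify import FlagThresholds, VotingResult, classify_sample
from .cohort import SourceCohort, build_cohort, cohort_report
from .med import MEDResult, compute_M, med_decompose, retention_check
from .signature import SourceSignature, train_signature

logger = logging.getLogger("fecalsig")

__all__ = ["RunConfig", "BuildResult", "run_build", "run_classify", "load_bundles"]


@dataclass
class RunConfig:
    """All tunable parameters of a build or classify run.

    Defaults are the published study values wherever the study states one:
    length tolerances and medians via the region profiles; homopolymer cap
    8; M divisors 30k/40k/60k; 50% retention rule; train 15-20 with >= 6
    test samples; 100x10,000 ranking forests and 100x1,000 training
    forests with a 70% performance floor; warning thresholds 1,000 reads /
    100 unique ASVs.  ``ranking_replicates``/``ensemble_replicates`` and
    tree counts may be lowered for desk-scale runs, but never silently.
    """

    region: str = "V6"
    group: str = "bacteroidales"
    max_homopolymer: int = 8
    retention_threshold: float = 0.5
    train_size: int = 20
    branch_threshold: float = 5.0
    ranking_replicates: int = 100
    ranking_trees: int = 10_000
    ensemble_replicates: int = 100
    ensemble_trees: int = 1_000
    min_perf: float = 0.70
    min_input_reads: int = 1_000
    min_matched_reads: int = 1_000
    min_matched_asvs: int = 100
    max_discriminants: int = 4
    max_entropy: float = 0.0
    seed: int = 0

    def paper_defaults(self) -> "RunConfig":
        """A copy with every published value pinned (already the default)."""
        return RunConfig(region=self.region, group=self.group, seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    @property
    def thresholds(self) -> FlagThresholds:
        return FlagThresholds(
            min_input_reads=self.min_input_reads,
            min_matched_reads=self.min_matched_reads,
            min_matched_asvs=self.min_matched_asvs,
        )


@dataclass
class BuildResult:
    signatures: list[SourceSignature]
    cohorts: list[SourceCohort]
    med: MEDResult
    table: pd.DataFrame
    report: pd.DataFrame
    filter_log: pd.DataFrame


def _filter_sample(
    reads: Sequence[Read], region: Region, config: RunConfig
) -> tuple[list[Read], dict]:
    profile = REGION_PROFILES[region]
    by_len, n_len = aio.filter_by_length(reads, profile)
    by_qual, n_qual = aio.filter_by_quality(by_len, config.max_homopolymer)
    return list(by_qual), {
        "input": len(reads),
        "removed_length": n_len,
        "removed_quality": n_qual,
        "kept": len(by_qual),
    }


def run_build(
    config: RunConfig,
    reads_per_sample: Mapping[str, Sequence[Read]],
    labels: Mapping[str, str] | pd.Series,
    out_dir: str | Path | None = None,
    composite_sources: Mapping[str, Sequence[str]] | None = None,
) -> BuildResult:
    """Build one signature bundle per source from labeled samples.

    ``composite_sources`` adds diet/physiology signatures trained on the
    union of member cohorts (e.g. ``{"ruminant": ["cattle", "deer"]}``).
    """
    labels = pd.Series(labels, dtype=str)
    if labels.nunique() < 2:
        raise ValueError("run_build requires samples from at least two sources")
    region = Region(config.region)

    filtered: dict[str, list[Read]] = {}
    flog = {}
    for sid, reads in reads_per_sample.items():
        filtered[sid], flog[sid] = _filter_sample(reads, region, config)
        logger.info("filter %s: %s", sid, flog[sid])
    filter_log = pd.DataFrame.from_dict(flog, orient="index")

    pooled = [r for reads in filtered.values() for r in reads]
    if not pooled:
        raise ValueError("no reads survived filtering")
    M = compute_M(len(pooled), region)
    logger.info("MED over %d pooled reads, M=%d", len(pooled), M)
    med = med_decompose(
        pooled, M,
        max_entropy=config.max_entropy,
        max_discriminants=config.max_discriminants,
    )
    retained = retention_check(med, config.retention_threshold)
    table = med.table

    cohorts: list[SourceCohort] = []
    for source in sorted(labels.unique()):
        ids = [s for s in table.index if labels.get(s) == source]
        cohorts.append(
            build_cohort(
                source,
                table.loc[ids],
                retention=med.retention,
                retention_threshold=config.retention_threshold,
                train_size=config.train_size,
                branch_threshold=config.branch_threshold,
            )
        )
    by_source = {c.source: c for c in cohorts}

    jobs: list[tuple[str, list[str]]] = [(c.source, [c.source]) for c in cohorts]
    for name, members in (composite_sources or {}).items():
        missing = [m for m in members if m not in by_source]
        if missing:
            raise ValueError(f"composite source {name!r}: unknown members {missing}")
        jobs.append((name, list(members)))

    # One-vs-rest: every signature trains on all sources' train samples
    # (focal = positives, the rest = negatives) and calibrates its cutoff
    # on all sources' held-out test samples.
    all_train = sorted(x for c in cohorts for x in c.train_ids)
    all_test = sorted(x for c in cohorts for x in c.test_ids)
    signatures = []
    for i, (name, members) in enumerate(jobs):
        sig = train_signature(
            table,
            labels,
            members if len(members) > 1 else members[0],
            train_ids=all_train,
            test_ids=all_test,
            region=region.value,
            group=config.group,
            ranking_replicates=config.ranking_replicates,
            ranking_trees=config.ranking_trees,
            ensemble_replicates=config.ensemble_replicates,
            ensemble_trees=config.ensemble_trees,
            min_perf=config.min_perf,
            seed=config.seed + 1000 * i,
        )
        sig.source = name
        logger.info(
            "signature %s: %d ASVs, cutoff=%s, type=%s",
            name, len(sig.asv_sequences), sig.decision_cutoff,
            sig.classifier_type.value,
        )
        signatures.append(sig)

    report = cohort_report(cohorts)
    result = BuildResult(
        signatures=signatures,
        cohorts=cohorts,
        med=med,
        table=table,
        report=report,
        filter_log=filter_log,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sig in signatures:
            sig.save(out / f"{sig.source}_{sig.region}_{sig.group}")
        report.to_csv(out / "cohort_report.tsv", sep="\t", index=False)
        filter_log.to_csv(out / "filter_log.tsv", sep="\t")
        config.to_yaml(out / "config.yaml")
    return result


def load_bundles(bundles_dir: str | Path) -> list[SourceSignature]:
    """Load every signature bundle found under a directory."""
    bundles_dir = Path(bundles_dir)
    sigs = []
    for meta in sorted(bundles_dir.glob("*/meta.json")):
        sigs.append(SourceSignature.load(meta.parent))
    if not sigs:
        raise ValueError(f"no signature bundles found under {bundles_dir}")
    return sigs


def run_classify(
    config: RunConfig,
    signatures: Sequence[SourceSignature],
    reads_per_sample: Mapping[str, Sequence[Read]],
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Score query samples against every signature.

    Returns ``(predictions, arcs, report)``; when ``out_dir`` is given,
    writes predictions.tsv, arcs.tsv and report.json.  A sample matching
    nothing is a result (flagged NO_MATCH), not a failure.
    """
    pred_rows, arc_rows = [], []
    report: dict = {"samples": {}}
    for sid, reads in reads_per_sample.items():
        results, arcs = classify_sample(
            list(reads), list(signatures), sample_id=sid,
            thresholds=config.thresholds,
        )
        for res in results:
            pred_rows.append(
                {
                    "sample_id": sid,
                    "signature": res.signature_id,
                    "matched_reads": res.matched_read_count,
                    "matched_asvs": res.matched_unique_asv_count,
                    "voting_probability": res.voting_probability,
                    "decision_cutoff": res.decision_cutoff,
                    "contaminated": res.contaminated,
                    "classifier_type": res.classifier_type.value,
                    "specificity_band": res.specificity_band.value,
                    "flags": ";".join(sorted(f.value for f in res.flags)),
                }
            )
        for source, share in arcs.items():
            arc_rows.append({"sample_id": sid, "source": source, "share": share})
        report["samples"][sid] = {
            "n_reads": len(reads),
            "calls": [r["signature"] for r in pred_rows
                      if r["sample_id"] == sid and r["contaminated"]],
            "arcs": {k: float(v) for k, v in arcs.items()},
        }
    predictions = pd.DataFrame(pred_rows)
    arcs_df = pd.DataFrame(arc_rows, columns=["sample_id", "source", "share"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        predictions.to_csv(out / "predictions.tsv", sep="\t", index=False)
        arcs_df.to_csv(out / "arcs.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return predictions, arcs_df, report
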