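"""End-to-end orchestration: one config in, all result tables out.

``run_full_analysis`` sweeps every peak experiment against every callset and
event subset (all / interchromosomal / intrachromosomal), applying the
zero-cell filter, and writes per-experiment records plus the aggregated
summary table (n, mean, sd, two-tailed p of log2 ORs per stratum), the
synergy records and summary, and — when a segmentation is supplied — the
breakpoint state histogram, functional-group summary and state-pair
matrices.  Identical inputs produce byte-identical outputs; every filtering
decision (dropped events, experiments excluded by the zero-cell rule) is
logged with counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import io as sio
from .chromstate import default_state_groups, pair_matrix, state_group_summary, state_histogram
from .enrichment import (
    EnrichmentParams,
    aggregate,
    build_vicinity,
    classify_gene_proximity,
    evaluate_peaks,
)
from .stats import InsufficientDataError
from .synergy import aggregate_synergy, build_partition, group_experiments, synergy_odds_ratio

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)

EVENT_SUBSETS = ("all", "inter", "intra")


@dataclass
class RunConfig:
    chrom_sizes: str
    callsets: dict[str, str]  # label -> breakpoint-pair TSV path
    genes: str
    peak_manifest: str
    outdir: str
    segmentation: str | None = None
    vicinity_radius: int = 50_000
    gene_threshold: int = 60_000
    distance_cutoffs: tuple[int, ...] = (10_000, 50_000, 100_000, 200_000, 500_000)
    synergy_k_hi: int = 2
    synergy_k_lo: int = 1
    event_subsets: tuple[str, ...] = EVENT_SUBSETS

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("distance_cutoffs", "event_subsets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        base = Path(path).parent

        def resolve(p):
            return str(p if Path(p).is_absolute() else base / p)

        for key in ("chrom_sizes", "genes", "peak_manifest", "segmentation", "outdir"):
            if raw.get(key):
                raw[key] = resolve(raw[key])
        raw["callsets"] = {k: resolve(v) for k, v in raw["callsets"].items()}
        return cls(**raw)


def _summary_frame(summaries) -> pd.DataFrame:
    rows = [
        {
            "callset": s.callset,
            "assay_class": s.assay_class,
            "stratum": s.stratum,
            "n": s.n,
            "mean_log2_or": s.mean,
            "sd": s.sd,
            "t": s.t,
            "p": s.p,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["callset", "assay_class", "stratum", "n", "mean_log2_or", "sd", "t", "p"],
    ).sort_values(["callset", "assay_class", "stratum"], kind="stable")


def run_full_analysis(config: RunConfig) -> dict[str, Path]:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = sio.read_chrom_sizes(config.chrom_sizes)
    genes = sio.read_genes(config.genes, layout)
    params = EnrichmentParams(
        vicinity_radius=config.vicinity_radius, gene_threshold=config.gene_threshold
    )
    strata = classify_gene_proximity(genes, params.gene_threshold, layout)
    experiments = [
        sio.read_peaks(m.path, layout, m.target, m.cell_line, m.lab, m.assay_class)
        for m in sio.read_manifest(config.peak_manifest)
    ]
    logger.info("loaded %d peak experiments", len(experiments))

    records, summaries, synergy_records, synergy_summaries = [], [], [], []
    for label in sorted(config.callsets):
        callset = sio.read_sm_callset(config.callsets[label], layout, label=label)
        logger.info(
            "callset %s: %d events retained, %d dropped (non-autosomal)",
            label,
            len(callset),
            callset.n_dropped,
        )
        for subset in config.event_subsets:
            sub = callset.subset(subset)
            if len(sub) == 0:
                logger.info("callset %s subset %s empty; skipped", label, subset)
                continue
            vicinity = build_vicinity(sub, params.vicinity_radius, layout)
            sub_records = [
                evaluate_peaks(
                    exp.peaks,
                    vicinity,
                    strata,
                    layout,
                    target=exp.target,
                    cell_line=exp.cell_line,
                    lab=exp.lab,
                    assay_class=exp.assay_class,
                    callset_label=sub.label,
                )
                for exp in experiments
            ]
            n_filtered = sum(not r.passed_filter for r in sub_records)
            if n_filtered:
                logger.info(
                    "callset %s subset %s: %d experiments excluded by the zero-cell filter",
                    label,
                    subset,
                    n_filtered,
                )
            records.extend(sub_records)
            for assay in sorted({r.assay_class for r in sub_records}):
                per_assay = [r for r in sub_records if r.assay_class == assay]
                for stratum in ("near", "far", "delta"):
                    try:
                        summaries.append(
                            aggregate(per_assay, stratum, callset=sub.label, assay_class=assay)
                        )
                    except InsufficientDataError:
                        logger.info(
                            "callset %s subset %s assay %s: < 2 passing experiments",
                            label,
                            subset,
                            assay,
                        )
            if subset == "all":
                chip = [e for e in experiments if e.assay_class == "chipseq"]
                for group in group_experiments(chip, layout):
                    partition = build_partition(group, layout)
                    synergy_records.append(
                        synergy_odds_ratio(
                            partition,
                            vicinity,
                            config.synergy_k_hi,
                            config.synergy_k_lo,
                            cell_line=group.cell_line,
                            lab=group.lab,
                            callset=sub.label,
                        )
                    )
                try:
                    synergy_summaries.append(
                        aggregate_synergy(
                            [r for r in synergy_records if r.callset == sub.label],
                            callset=sub.label,
                        )
                    )
                except InsufficientDataError:
                    logger.info("callset %s: < 2 synergy groups pass; no summary", label)

    paths: dict[str, Path] = {}
    paths["records"] = outdir / "records.tsv"
    sio.write_table(
        records, paths["records"], sort_by=["callset", "assay_class", "target", "cell_line", "lab"]
    )
    paths["summary"] = outdir / "summary.tsv"
    _summary_frame(summaries).to_csv(paths["summary"], sep="\t", index=False, float_format="%.6g")
    paths["synergy"] = outdir / "synergy.tsv"
    sio.write_table(synergy_records, paths["synergy"], sort_by=["callset", "cell_line", "lab"])
    paths["synergy_summary"] = outdir / "synergy_summary.tsv"
    _summary_frame(synergy_summaries).to_csv(
        paths["synergy_summary"], sep="\t", index=False, float_format="%.6g"
    )

    if config.segmentation:
        seg = sio.read_segmentation(config.segmentation, layout)
        hist_rows, group_rows, pair_rows = [], [], []
        for label in sorted(config.callsets):
            callset = sio.read_sm_callset(config.callsets[label], layout, label=label)
            hist = state_histogram(callset, seg)
            for i, state in enumerate(hist.catalog):
                hist_rows.append(
                    {
                        "callset": label,
                        "state": state,
                        "observed_count": int(hist.observed_counts[i]),
                        "observed_freq": hist.observed_freq[i],
                        "expected_freq": hist.expected_freq[i],
                        "se": hist.se[i],
                    }
                )
            for g in state_group_summary(hist, default_state_groups(hist.catalog)):
                group_rows.append(
                    {
                        "callset": label,
                        "group": g.group,
                        "observed_freq": g.observed_freq,
                        "expected_freq": g.expected_freq,
                        "se": g.se,
                    }
                )
            for inter_only in (False, True):
                if inter_only and not any(e.interchromosomal for e in callset.events):
                    continue
                pm = pair_matrix(callset, seg, interchromosomal_only=inter_only)
                obs, exp, diff = pm.observed_freq, pm.expected_freq, pm.difference
                for i, a in enumerate(pm.catalog):
                    for j in range(i, len(pm.catalog)):
                        pair_rows.append(
                            {
                                "callset": label,
                                "events": "inter" if inter_only else "all",
                                "state_a": a,
                                "state_b": pm.catalog[j],
                                "observed_count": int(pm.observed_counts[i, j]),
                                "observed_freq": obs[i, j],
                                "expected_freq": exp[i, j],
                                "difference": diff[i, j],
                            }
                        )
        paths["state_histogram"] = outdir / "state_histogram.tsv"
        pd.DataFrame(hist_rows).to_csv(
            paths["state_histogram"], sep="\t", index=False, float_format="%.6g"
        )
        paths["state_groups"] = outdir / "state_groups.tsv"
        pd.DataFrame(group_rows).to_csv(
            paths["state_groups"], sep="\t", index=False, float_format="%.6g"
        )
        paths["state_pairs"] = outdir / "state_pairs.tsv"
        pd.DataFrame(pair_rows).to_csv(
            paths["state_pairs"], sep="\t", index=False, float_format="%.6g"
        )
    return paths
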