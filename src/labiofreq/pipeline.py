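"""End-to-end analysis orchestration.

``run_full_analysis`` chains ingest -> profile -> metadata join -> group
summaries -> mixed models -> stratified contrasts, mirroring the published
analysis layout: with both subsistence taxonomies supplied it fits the four
headline linear mixed models (LR/WILR x large/AUTOTYP-style taxonomy) and
draws the four matching contrast distributions.  Every stage's row counts
and drop reasons are logged, and a manifest (config, seed, derived
sub-seeds, package version) makes a run reproducible bit for bit.

``run_text_analysis`` covers the pre-tokenized text pathway: per-text
consonant/labiodental counts with lineage and subsistence labels are turned
into LR/WILR values, aggregated to lineage-level presence/absence, and
tested with the uncorrected chi-square.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .segments import SegmentClassTable
from .wordlists import parse_wordlist_file
from .stats import profile_doculects, profiles_frame, summarize_by_group, pearson_chi_square, TestResult
from .metadata import load_metadata, join_metadata, AnalysisTable
from .lmm import fit_lmm, LMMTestResult
from .glmm import fit_binomial_glmm, GLMMTestResult
from .resampling import StratifiedContrast, ContrastDistribution

__all__ = ["RunConfig", "ReportBundle", "StageError", "run_full_analysis", "run_text_analysis"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    wordlists: str | Path
    metadata: str | Path
    taxonomies: tuple[str, ...] = ("large", "autotyp")
    responses: tuple[str, ...] = ("lr", "wilr")
    transform: str = "logit_smoothed"
    models: tuple[str, ...] = ("lmm",)
    contrast_iterations: int = 5000
    dialect: str = "long"
    segment_table: str = "asjp"
    seed: int = 0
    outdir: str | Path | None = None


@dataclass
class ReportBundle:
    """All artifacts of a run, writable as CSV/JSON."""

    group_summaries: dict[str, pd.DataFrame]
    model_results: list
    contrasts: dict[tuple[str, str], ContrastDistribution]
    drop_counts: dict[str, dict[str, int]]
    manifest: dict
    tables: dict[str, AnalysisTable] = field(default_factory=dict)

    def models_frame(self) -> pd.DataFrame:
        """Headline model table (one row per response x taxonomy)."""
        return pd.DataFrame([m.to_dict() for m in self.model_results])

    def contrasts_frame(self) -> pd.DataFrame:
        return pd.DataFrame([d.summary() for d in self.contrasts.values()])

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for tax, summ in self.group_summaries.items():
            p = outdir / f"group_summary_{tax}.csv"
            summ.to_csv(p, index=False)
            paths[f"group_summary_{tax}"] = p
        p = outdir / "model_results.csv"
        self.models_frame().to_csv(p, index=False)
        paths["model_results"] = p
        for (stat, tax), dist in self.contrasts.items():
            p = outdir / f"disparities_{stat}_{tax}.csv"
            dist.to_frame().to_csv(p, index=False)
            paths[f"disparities_{stat}_{tax}"] = p
        p = outdir / "contrast_summaries.json"
        with open(p, "w") as fh:
            json.dump([d.summary() for d in self.contrasts.values()], fh, indent=1)
        paths["contrast_summaries"] = p
        p = outdir / "manifest.json"
        with open(p, "w") as fh:
            json.dump(self.manifest, fh, indent=1, default=str)
        paths["manifest"] = p
        return paths


def _sub_seeds(seed: int, k: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s & 0x7FFFFFFF) for s in state]


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute all configured stages; any failure aborts with the stage name."""
    classes = SegmentClassTable.default(config.segment_table)

    def stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s done", name)
        return out

    doculects, issues = stage(
        "ingest", lambda: parse_wordlist_file(config.wordlists, dialect=config.dialect,
                                              classes=classes))
    logger.info("ingest: %d doculects, %d row issues", len(doculects), len(issues))
    profiles, excluded = stage("profile", lambda: profile_doculects(doculects, classes))
    prof_frame = profiles_frame(profiles)
    metadata = stage("metadata", lambda: load_metadata(config.metadata))

    tables: dict[str, AnalysisTable] = {}
    summaries: dict[str, pd.DataFrame] = {}
    drops: dict[str, dict[str, int]] = {"profile": {"zero_consonants": len(excluded)}}
    for tax in config.taxonomies:
        table = stage(f"join[{tax}]", lambda t=tax: join_metadata(
            prof_frame, metadata, taxonomy=t, transform=config.transform))
        tables[tax] = table
        drops[f"join[{tax}]"] = table.drop_counts
        logger.info("join[%s]: %d rows admitted, drops %s", tax, table.n, table.drop_counts)
        summaries[tax] = summarize_by_group(table.frame, table.group_labels())

    seeds = _sub_seeds(config.seed, len(config.taxonomies) * len(config.responses) + 1)
    model_results: list = []
    contrasts: dict[tuple[str, str], ContrastDistribution] = {}
    i = 0
    for tax in config.taxonomies:
        for resp in config.responses:
            run_seed = seeds[i]
            i += 1
            if "lmm" in config.models:
                model_results.append(stage(
                    f"lmm[{resp},{tax}]",
                    lambda t=tax, r=resp: fit_lmm(tables[t], response=f"{r}_t")))
            contrasts[(resp, tax)] = stage(
                f"contrast[{resp},{tax}]",
                lambda t=tax, r=resp, s=run_seed: StratifiedContrast(
                    tables[t], statistic=r).run(
                        iterations=config.contrast_iterations, seed=s))
        if "glmm" in config.models:
            model_results.append(stage(
                f"glmm[{tax}]", lambda t=tax: fit_binomial_glmm(tables[t])))

    manifest = {
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "seed": config.seed,
        "sub_seeds": seeds[:i],
        "version": __version__,
        "n_doculects_ingested": len(doculects),
        "drop_counts": drops,
    }
    bundle = ReportBundle(group_summaries=summaries, model_results=model_results,
                          contrasts=contrasts, drop_counts=drops, manifest=manifest,
                          tables=tables)
    if config.outdir is not None:
        bundle.write(config.outdir)
    return bundle


def run_text_analysis(segment_counts) -> dict:
    """Analyse a pre-tokenized per-text consonant-count table.

    Expected columns: ``text_id``, ``lineage``, ``subsistence`` (HG/nonHG),
    ``n_consonants``, ``n_labiodental`` and optionally ``n_wi_labiodental``.
    Returns per-text LR/WILR, group summaries, and the lineage-level
    presence/absence chi-square (a lineage counts as having labiodentals
    when any of its texts does).
    """
    counts = segment_counts if isinstance(segment_counts, pd.DataFrame) else pd.read_csv(segment_counts)
    required = {"text_id", "lineage", "subsistence", "n_consonants", "n_labiodental"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"text counts table lacks columns {sorted(missing)}")
    if counts["lineage"].isna().any() or (counts["lineage"].astype(str) == "").any():
        raise ValueError("every text must be assigned to a lineage")
    bad = ~counts["subsistence"].isin(["HG", "nonHG"])
    if bad.any():
        raise ValueError("subsistence labels must be HG or nonHG")
    counts = counts.copy()
    if "n_wi_labiodental" not in counts.columns:
        counts["n_wi_labiodental"] = 0
    counts["lr"] = counts["n_labiodental"] / counts["n_consonants"]
    counts["wilr"] = counts["n_wi_labiodental"] / counts["n_consonants"]

    texts = counts.rename(columns={"text_id": "doculect_id"})
    texts["group"] = texts["subsistence"]
    summary = summarize_by_group(texts[["doculect_id", "lr", "wilr", "group"]])

    lineages = counts.groupby("lineage").agg(
        present=("n_labiodental", lambda s: int((s >= 1).any())),
        subsistence=("subsistence", "first"),
    )
    mixed = counts.groupby("lineage")["subsistence"].nunique()
    if (mixed > 1).any():
        raise ValueError(
            f"lineages with both HG and non-HG texts: {list(mixed[mixed > 1].index)}")
    hg = lineages[lineages["subsistence"] == "HG"]
    nonhg = lineages[lineages["subsistence"] == "nonHG"]
    table = [
        [int(hg["present"].sum()), int((1 - hg["present"]).sum())],
        [int(nonhg["present"].sum()), int((1 - nonhg["present"]).sum())],
    ]
    test: TestResult = pearson_chi_square(table)
    return {
        "texts": texts,
        "group_summary": summary,
        "lineage_table": table,
        "lineage_presence_test": test,
    }
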