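"""End-to-end orchestration: spectra or score tables in, audit report out.

A run produces three artifacts in the output directory: ``scores.csv``
(one row per sample, mirroring the reference table's columns),
``report.json`` (ROC, confusion, Pearson r, Monte Carlo triage
summary), and ``run.log`` (effective config, seed, package version).
Outputs are written atomically — a failed stage leaves no partial
files — and are byte-identical across runs with the same inputs,
config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig, load_config
from .evaluation import (
    CohortEntry,
    LabeledCohort,
    confusion_at_threshold,
    empirical_roc,
    monte_carlo_triage,
    pearson_correlation,
)
from .fixtures import load_cohort_csv, load_table2
from .scoring import SampleScore, score_sample
from .spectra_io import read_spectrum, resample_to_grid

__all__ = ["run_pipeline", "evaluate_cohort", "scores_to_frame"]

log = logging.getLogger("serscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def scores_to_frame(scores: list[SampleScore]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "z_ratio_monomer": s.ratio_monomer,
            "z_ratio_dimer": s.ratio_dimer,
            "sum_score": s.sum_score,
            "fluctuation_significant": s.fluctuation_significant,
            "rule5_high_risk": s.rule5_high_risk,
        }
        for s in scores
    ]
    return pd.DataFrame(rows)


def evaluate_cohort(
    cohort: LabeledCohort, cfg: PipelineConfig, seed: int = 0
) -> dict:
    """All evaluation statistics for a labeled cohort, as a JSON-ready dict."""
    roc = empirical_roc(cohort)
    conf = confusion_at_threshold(
        cohort, cfg.rules.rule5_threshold, inclusive=cfg.rules.rule5_inclusive
    )
    mc = monte_carlo_triage(
        cohort,
        cfg.rules.rule5_threshold,
        n_iter=cfg.mc_iters,
        seed=seed,
        inclusive=cfg.rules.rule5_inclusive,
    )
    flagged = [
        e.sample_id
        for e in cohort.entries
        if cfg.rules.is_high_risk(e.sum_score)
    ]
    return {
        "n_samples": len(cohort),
        "regulatory_limit_ppm": cohort.regulatory_limit,
        "rule5_threshold": cfg.rules.rule5_threshold,
        "pearson_r": pearson_correlation(cohort),
        "auc": roc.auc,
        "optimal_threshold": roc.optimal_threshold,
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
        "roc_points": roc.points,
        "sensitivity": conf.sensitivity,
        "specificity": conf.specificity,
        "confusion": {"tp": conf.tp, "fp": conf.fp, "tn": conf.tn, "fn": conf.fn},
        "n_flagged": len(flagged),
        "flagged_sample_ids": flagged,
        "monte_carlo": {
            "n_iter": mc.n_iter,
            "seed": mc.seed,
            "fn_rate_mean": mc.fn_rate_mean,
            "fp_triage_mean": mc.fp_triage_mean,
            "fn_rate_quantiles": {str(k): v for k, v in mc.fn_rate_quantiles.items()},
            "fp_triage_quantiles": {str(k): v for k, v in mc.fp_triage_quantiles.items()},
        },
    }


def _load_inputs(inputs: str | Path, cfg: PipelineConfig) -> tuple[LabeledCohort, list]:
    """Resolve pipeline inputs to a labeled cohort (+ scores when spectra)."""
    if inputs == "table2":
        return load_table2(regulatory_limit=cfg.regulatory_limit), []

    path = Path(inputs)
    if not path.exists():
        raise PipelineError(f"input stage: path does not exist: {path}")
    if path.is_dir():
        table = path / "cohort.csv"
        if not table.exists():
            raise PipelineError(f"input stage: no cohort.csv in directory {path}")
        path = table

    df = pd.read_csv(path)
    if "spectrum_path" in df.columns:
        root = path.parent
        scores, entries = [], []
        for r in df.itertuples(index=False):
            spec = read_spectrum(root / r.spectrum_path, sample_id=str(r.sample_id))
            spec = resample_to_grid(spec, edge_hold=True)
            sc = score_sample(spec, cfg.airpls, cfg.bands, cfg.rules)
            scores.append(sc)
            entries.append(CohortEntry(sc.sample_id, sc.sum_score, float(r.hplc_ppm)))
        return LabeledCohort(entries, regulatory_limit=cfg.regulatory_limit), scores
    return load_cohort_csv(path, regulatory_limit=cfg.regulatory_limit), []


def run_pipeline(
    config: str | Path | PipelineConfig | None,
    inputs: str | Path,
    outdir: str | Path,
    seed: int = 0,
) -> dict:
    """Run score + evaluate end to end and write the audit artifacts.

    ``inputs`` is a cohort CSV (score-table mode, or spectra mode when
    it has a ``spectrum_path`` column), a directory containing
    ``cohort.csv``, or the literal string ``"table2"`` for the bundled
    reference cohort.
    """
    cfg = config if isinstance(config, PipelineConfig) else load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort, scores = _load_inputs(inputs, cfg)
    report = {
        "serscreen_version": __version__,
        "seed": seed,
        "inputs": str(inputs),
        "config": cfg.to_dict(),
        "evaluation": evaluate_cohort(cohort, cfg, seed=seed),
    }

    if scores:
        frame = scores_to_frame(scores)
    else:
        frame = pd.DataFrame(
            {
                "sample_id": [e.sample_id for e in cohort.entries],
                "sum_score": [e.sum_score for e in cohort.entries],
                "hplc_ppm": [e.hplc_ppm for e in cohort.entries],
                "rule5_high_risk": [
                    cfg.rules.is_high_risk(e.sum_score) for e in cohort.entries
                ],
            }
        )

    # atomic writes: temp file then rename, so failures leave nothing partial
    for name, writer in (
        ("scores.csv", lambda p: frame.to_csv(p, index=False)),
        ("report.json", lambda p: p.write_text(json.dumps(report, indent=2, sort_keys=True))),
    ):
        tmp = outdir / (name + ".tmp")
        writer(tmp)
        tmp.replace(outdir / name)

    log_path = outdir / "run.log"
    log_path.write_text(
        f"serscreen {__version__}\nseed: {seed}\ninputs: {inputs}\n"
        f"config: {json.dumps(cfg.to_dict(), sort_keys=True)}\n"
    )
    log.info("pipeline finished: %d samples, outputs in %s", len(cohort), outdir)
    return report
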