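"""End-to-end orchestration: simulate -> QC -> call -> quantify -> concord.

The pipeline is a thin composition of the library stages. In simulation
mode it draws an independent negative reference cohort for threshold
derivation (mirroring how a laboratory would lock thresholds on control
material before touching study samples), then a study cohort, and produces
a single JSON report bundling per-sample QC, calls, chip quantification,
the diagnostic concordance tables and the technique comparison. The report
embeds the seed and a hash of the full configuration so any report can be
reproduced from itself.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from . import calling, concordance, dpcr
from .io import RunConfig, config_hash, write_calls_tsv, write_cohort, write_quant_tsv
from .panel import ProbePanel, default_panel
from .simulate import CohortSample, CohortSpec, SimulationConfig, simulate_cohort

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and sample."""


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    return obj


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    cohort_spec: CohortSpec | None = None,
    panel: ProbePanel | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run the simulated end-to-end analysis and return the report dict.

    Stages: simulate reference negatives -> derive thresholds -> simulate
    study cohort -> QC -> fusion/MET calls -> chip quantification ->
    per-gene + pooled concordance vs the simulated tissue truth ->
    nCounter-vs-dPCR comparison on the tissue-positive subset.
    """
    out_dir = Path(out_dir)
    panel = panel or default_panel()
    spec = cohort_spec or CohortSpec.reference_cohort()
    sim_config = SimulationConfig(
        seed=config.seed,
        partition_volume_ul=config.partition_volume_ul,
        **config.simulation,
    )
    rng = sim_config.rng()

    def stage(name: str, fn, *args, sample: str = "", **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            where = f"{name}" + (f" (sample {sample})" if sample else "")
            raise PipelineError(f"stage {where} failed: {exc}") from exc

    # 1. thresholds from an independent simulated negative cohort
    ref_spec = CohortSpec(n_controls=config.n_reference_negatives)
    reference = stage("simulate-reference", simulate_cohort, ref_spec, sim_config, panel=panel, rng=rng)
    thresholds = stage(
        "derive-thresholds",
        calling.derive_thresholds,
        [s.profile for s in reference],
        panel,
        sd_multiplier=config.sd_multiplier,
        met_ratio_cutoff=config.met_ratio_cutoff,
    )

    # 2. study cohort
    cohort: Sequence[CohortSample] = stage(
        "simulate-cohort", simulate_cohort, spec, sim_config, panel=panel, rng=rng
    )

    # 3. QC + calls
    qc_results, call_sets = [], []
    for s in cohort:
        qc = stage("qc", calling.geometric_mean_hk, s.profile, panel, sample=s.truth.sample_id)
        qc_results.append(qc)
        if qc.evaluable:
            call_sets.append(
                stage("call", calling.call_fusions, s.profile, thresholds, panel,
                      sample=s.truth.sample_id)
            )
        else:
            call_sets.append(calling.FusionCallSet(sample_id=s.truth.sample_id, evaluable=False))

    # 4. dPCR quantification
    quant_results = [
        stage(
            "quant",
            dpcr.quantify_chip,
            s.chip,
            partition_volume_ul=config.partition_volume_ul,
            min_reference_copies_per_ul=config.min_reference_copies_per_ul,
            sample=s.truth.sample_id,
        )
        for s in cohort
    ]

    # 5. concordance vs tissue truth
    truth_genes = {
        s.truth.sample_id: (panel.gene_of(s.truth.alteration) if s.truth.is_positive else "none")
        for s in cohort
    }
    called_genes = {c.sample_id: (c.overall_gene if c.evaluable else "none") for c in call_sets}
    summaries = stage(
        "concord", concordance.diagnostic_summary, called_genes, truth_genes,
        ci_method=config.ci_method,
    )

    # 6. technique comparison on tissue-positive samples
    positive_ids = [s.truth.sample_id for s in cohort if s.truth.is_positive]
    ncounter_det = {c.sample_id: c.detected for c in call_sets if c.sample_id in positive_ids}
    dpcr_det = {
        q.sample_id: bool(q.evaluable and q.mutant.copies_per_ul > 0)
        for q in quant_results
        if q.sample_id in positive_ids
    }
    comparison = (
        stage("compare", concordance.compare_techniques, ncounter_det, dpcr_det)
        if positive_ids
        else None
    )

    report = {
        "config": dataclasses.asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_samples": len(cohort),
        "thresholds": {
            "per_probe": thresholds.thresholds,
            "sd_multiplier": thresholds.sd_multiplier,
            "met_ratio_cutoff": thresholds.met_ratio_cutoff,
            "negative_cohort_ids": thresholds.negative_cohort_ids,
            "flags": thresholds.flags,
        },
        "qc": [_jsonable(q) for q in qc_results],
        "calls": [_jsonable(c) for c in call_sets],
        "quant": [_jsonable(q) for q in quant_results],
        "concordance": {k: _jsonable(v) for k, v in summaries.items()},
        "technique_comparison": _jsonable(comparison),
    }

    if write_outputs:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_cohort(cohort, sim_config, panel, out_dir)
        write_calls_tsv(call_sets, out_dir / "calls.tsv")
        write_quant_tsv(quant_results, out_dir / "quant.tsv")
        with (out_dir / "report.json").open("w") as fh:
            json.dump(report, fh, indent=2)
            fh.write("\n")
        logger.info("pipeline report written to %s", out_dir / "report.json")
    return report
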