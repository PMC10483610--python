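"""QC, thresholding and positivity calling for multiplexed count profiles.

The calling logic is deliberately simple and auditable, the way clinical
assay rules are written:

* a sample is *evaluable* when the geometric mean of its housekeeping
  counts is strictly above 30 (an RNA-quantity gate);
* a fusion probe is *positive* when its count is strictly above the
  arithmetic mean plus six standard deviations of the counts observed on
  that probe in a reference cohort of tissue-negative samples;
* MET exon-14 skipping is *positive* when the skip/wild-type count ratio
  is strictly above 1.0;
* technical variation across runs is tracked with a Levey-Jennings chart
  (mean, +/-2SD warning and +/-3SD control limits).

The six no-target negative-control probes are used as a background QC
floor by default: a fusion threshold that falls below the negative-control
mean + 2SD is flagged, because calls from such a threshold would sit inside
nonspecific background. Optionally the negative-control mean can instead be
subtracted from all counts before thresholding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .panel import ProbeClass, ProbePanel
from .profiles import CountProfile

__all__ = [
    "QC_HK_GEOMEAN_THRESHOLD",
    "DEFAULT_SD_MULTIPLIER",
    "DEFAULT_MET_RATIO_CUTOFF",
    "QcResult",
    "CallThresholds",
    "FusionCallSet",
    "LeveyJenningsStats",
    "LodResult",
    "NotEvaluableError",
    "geometric_mean_hk",
    "derive_thresholds",
    "call_fusions",
    "levey_jennings",
    "plot_levey_jennings",
    "lod_from_dilution",
]

logger = logging.getLogger(__name__)

QC_HK_GEOMEAN_THRESHOLD = 30.0
DEFAULT_SD_MULTIPLIER = 6.0
DEFAULT_MET_RATIO_CUTOFF = 1.0


class NotEvaluableError(ValueError):
    """Raised when calls are requested on a sample that failed QC."""


@dataclass
class QcResult:
    sample_id: str
    hk_geomean: float
    evaluable: bool
    threshold_used: float = QC_HK_GEOMEAN_THRESHOLD


@dataclass
class CallThresholds:
    """Per-probe positivity thresholds derived from a negative reference cohort."""

    means: dict[str, float]
    sds: dict[str, float]
    thresholds: dict[str, float]
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER
    met_ratio_cutoff: float = DEFAULT_MET_RATIO_CUTOFF
    negative_cohort_ids: list[str] = field(default_factory=list)
    background_floor: float | None = None   # negative-control mean + 2SD
    background_subtract: float = 0.0        # 0 unless subtraction mode
    flags: list[str] = field(default_factory=list)


@dataclass
class FusionCallSet:
    sample_id: str
    evaluable: bool
    probe_calls: dict[str, bool] = field(default_factory=dict)
    met_ratio: float | None = None
    met_call: str = "non_evaluable"   # "positive" | "negative" | "non_evaluable"
    positives: list[str] = field(default_factory=list)
    overall_alteration: str = "none"  # winning target probe id, or "none"
    overall_gene: str = "none"

    @property
    def detected(self) -> bool:
        return self.overall_alteration != "none"


@dataclass
class LeveyJenningsStats:
    values: list[float]
    center: float
    sd: float
    warning_limits: tuple[float, float]   # +/- 2SD
    control_limits: tuple[float, float]   # +/- 3SD
    out_of_control: list[bool]            # 1_3s rule: |value - center| > 3SD


@dataclass
class LodResult:
    """Limit of detection from a dilution bank.

    ``tumor_fraction`` is None when no level reached the required detection
    rate (LOD above the highest fraction tested).
    """

    tumor_fraction: float | None
    detection_rates: dict[float, float]
    n_replicates: dict[float, int]
    min_detection_rate: float
    rna_pg_per_ul: float | None = None

    @property
    def defined(self) -> bool:
        return self.tumor_fraction is not None


def geometric_mean_hk(profile: CountProfile, panel: ProbePanel) -> QcResult:
    """Evaluability gate: geometric mean of housekeeping counts must exceed 30.

    A zero housekeeping count annihilates the product, so the geometric
    mean is 0 and the sample fails QC.
    """
    hk_ids = panel.housekeeping_ids
    if not hk_ids:
        raise ValueError("panel has no housekeeping probes")
    missing = [p for p in hk_ids if p not in profile.counts]
    if missing:
        raise ValueError(f"{profile.sample_id}: missing housekeeping counts for {missing}")
    counts = np.array([profile.counts[p] for p in hk_ids], dtype=float)
    gm = float(np.prod(counts) ** (1.0 / len(counts))) if np.all(counts > 0) else 0.0
    evaluable = gm > QC_HK_GEOMEAN_THRESHOLD
    logger.info("QC %s: HK geomean %.2f -> %s", profile.sample_id, gm,
                "evaluable" if evaluable else "non-evaluable")
    return QcResult(profile.sample_id, hk_geomean=gm, evaluable=evaluable)


def derive_thresholds(
    negative_profiles: Sequence[CountProfile],
    panel: ProbePanel,
    sd_multiplier: float = DEFAULT_SD_MULTIPLIER,
    met_ratio_cutoff: float = DEFAULT_MET_RATIO_CUTOFF,
    ddof: int = 1,
    background_mode: str = "floor",
) -> CallThresholds:
    """Per-fusion-probe thresholds: mean + ``sd_multiplier`` * SD of the
    negative reference cohort (sample SD, n-1 denominator, by default).

    Non-evaluable profiles are excluded with a warning. ``background_mode``:
    ``"floor"`` flags any threshold below the negative-control-probe
    mean + 2SD; ``"subtract"`` instead subtracts the negative-control mean
    from every count before thresholding (and will do so again at call time).
    """
    if background_mode not in ("floor", "subtract"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    usable: list[CountProfile] = []
    for prof in negative_profiles:
        if geometric_mean_hk(prof, panel).evaluable:
            usable.append(prof)
        else:
            logger.warning("threshold derivation: excluding non-evaluable %s", prof.sample_id)
    if len(usable) < 2:
        raise ValueError(
            f"need >= 2 evaluable negative profiles to estimate an SD, got {len(usable)}"
        )
    neg_ctrl = np.array(
        [[p.counts[q] for q in panel.negative_control_ids] for p in usable], dtype=float
    )
    bg_floor = float(neg_ctrl.mean() + 2.0 * neg_ctrl.std(ddof=ddof))
    subtract = float(neg_ctrl.mean()) if background_mode == "subtract" else 0.0

    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    flags: list[str] = []
    for pid in panel.fusion_ids:
        counts = np.array([p.counts[pid] for p in usable], dtype=float) - subtract
        mean = float(counts.mean())
        sd = float(counts.std(ddof=ddof))
        means[pid], sds[pid] = mean, sd
        thresholds[pid] = mean + sd_multiplier * sd
        if background_mode == "floor" and thresholds[pid] < bg_floor:
            flags.append(
                f"threshold for {pid} ({thresholds[pid]:.1f}) below negative-control "
                f"background floor ({bg_floor:.1f})"
            )
    for flag in flags:
        logger.warning("%s", flag)
    return CallThresholds(
        means=means,
        sds=sds,
        thresholds=thresholds,
        sd_multiplier=sd_multiplier,
        met_ratio_cutoff=met_ratio_cutoff,
        negative_cohort_ids=[p.sample_id for p in usable],
        background_floor=bg_floor if background_mode == "floor" else None,
        background_subtract=subtract,
        flags=flags,
    )


def call_fusions(
    profile: CountProfile,
    thresholds: CallThresholds,
    panel: ProbePanel,
) -> FusionCallSet:
    """Call per-probe positivity and resolve the sample's overall alteration.

    Strict inequalities at both cutoffs: a count exactly at its threshold
    and a MET ratio exactly at the cutoff are negative. When probes of more
    than one gene exceed their thresholds (biologically the alterations are
    mutually exclusive, so this indicates noise) the probe with the largest
    count/threshold ratio wins; every positive probe stays listed.
    A zero wild-type MET count leaves the MET ratio undefined and the MET
    call non-evaluable — never positive.
    """
    qc = geometric_mean_hk(profile, panel)
    if not qc.evaluable:
        raise NotEvaluableError(
            f"{profile.sample_id}: HK geometric mean {qc.hk_geomean:.2f} <= "
            f"{qc.threshold_used:g}; sample failed QC, no calls emitted"
        )
    calls: dict[str, bool] = {}
    scores: dict[str, float] = {}
    for pid in panel.fusion_ids:
        count = profile.counts[pid] - thresholds.background_subtract
        thr = thresholds.thresholds[pid]
        calls[pid] = count > thr
        if calls[pid]:
            scores[pid] = count / thr if thr > 0 else math.inf
            logger.info("call %s: %s count %.0f > threshold %.1f -> positive",
                        profile.sample_id, pid, count, thr)
    wt = profile.counts[panel.met_wt_id]
    skip = profile.counts[panel.met_skip_id]
    if wt == 0:
        met_ratio, met_call = None, "non_evaluable"
    else:
        met_ratio = skip / wt
        met_call = "positive" if met_ratio > thresholds.met_ratio_cutoff else "negative"
    positives = sorted(scores, key=scores.get, reverse=True)
    if met_call == "positive":
        # score the MET call by its ratio/cutoff margin, same currency as fusions
        scores[panel.met_skip_id] = met_ratio / thresholds.met_ratio_cutoff
        positives = sorted(scores, key=scores.get, reverse=True)
    overall = positives[0] if positives else "none"
    return FusionCallSet(
        sample_id=profile.sample_id,
        evaluable=True,
        probe_calls=calls,
        met_ratio=met_ratio,
        met_call=met_call,
        positives=positives,
        overall_alteration=overall,
        overall_gene=panel.gene_of(overall) if overall != "none" else "none",
    )


def levey_jennings(
    values: Sequence[float],
    reference_center: float | None = None,
    reference_sd: float | None = None,
) -> LeveyJenningsStats:
    """Levey-Jennings statistics of replicate runs: mean center, +/-2SD
    warning and +/-3SD control limits, and per-value 1_3s violation flags.

    By default the center and SD come from the replicates themselves. Note
    that self-derived limits on a small batch can never flag (with n values
    the largest |z| is (n-1)/sqrt(n) < 3 for n <= 10); pass the
    laboratory's established QC mean and SD as ``reference_center`` /
    ``reference_sd`` to chart new runs against historical limits.
    """
    if len(values) < 2:
        raise ValueError(f"need >= 2 replicate values, got {len(values)}")
    arr = np.asarray(values, dtype=float)
    center = float(arr.mean()) if reference_center is None else float(reference_center)
    sd = float(arr.std(ddof=1)) if reference_sd is None else float(reference_sd)
    if sd < 0:
        raise ValueError("reference_sd must be >= 0")
    return LeveyJenningsStats(
        values=[float(v) for v in arr],
        center=center,
        sd=sd,
        warning_limits=(center - 2 * sd, center + 2 * sd),
        control_limits=(center - 3 * sd, center + 3 * sd),
        out_of_control=[bool(abs(v - center) > 3 * sd) for v in arr],
    )


def plot_levey_jennings(stats: LeveyJenningsStats, ax=None, title: str = ""):
    """Render a Levey-Jennings chart; returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    x = np.arange(1, len(stats.values) + 1)
    ax.plot(x, stats.values, "o-", color="tab:blue")
    ax.axhline(stats.center, color="k", lw=1)
    for lim, style in ((stats.warning_limits, "--"), (stats.control_limits, ":")):
        for y in lim:
            ax.axhline(y, color="tab:red", ls=style, lw=0.8)
    flagged = [i + 1 for i, bad in enumerate(stats.out_of_control) if bad]
    if flagged:
        ax.plot(flagged, [stats.values[i - 1] for i in flagged], "rx", ms=10)
    ax.set_xlabel("run")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    return ax


def lod_from_dilution(
    calls_by_level: Mapping[float, Sequence[FusionCallSet]],
    target_probe: str,
    min_detection_rate: float = 1.0,
    rna_conc_pg_per_ul: float | None = None,
) -> LodResult:
    """Limit of detection from a dilution bank's call sets.

    A replicate counts as detected when ``target_probe`` is among its
    positive calls (for the MET skip probe: a positive MET call). The LOD
    is the smallest tumor fraction whose detection rate reaches
    ``min_detection_rate`` (default 1.0 — every replicate positive); levels
    below the LOD are not required to pass. With ``rna_conc_pg_per_ul``
    (total RNA concentration of the undiluted stock) the LOD is also
    expressed in pg/uL of tumor RNA.
    """
    if len(calls_by_level) < 2:
        raise ValueError("need >= 2 dilution levels")
    if not 0.0 < min_detection_rate <= 1.0:
        raise ValueError("min_detection_rate must be in (0, 1]")
    rates: dict[float, float] = {}
    n_reps: dict[float, int] = {}
    for level in sorted(calls_by_level, reverse=True):
        callsets = calls_by_level[level]
        if len(callsets) == 0:
            raise ValueError(f"level {level} has no replicates")
        detected = [
            cs.met_call == "positive" if target_probe == "MET_delta14"
            else cs.probe_calls.get(target_probe, False)
            for cs in callsets
        ]
        rates[level] = sum(detected) / len(detected)
        n_reps[level] = len(detected)
    passing = [lv for lv, rate in rates.items() if rate >= min_detection_rate]
    lod = min(passing) if passing else None
    return LodResult(
        tumor_fraction=lod,
        detection_rates=rates,
        n_replicates=n_reps,
        min_detection_rate=min_detection_rate,
        rna_pg_per_ul=(lod * rna_conc_pg_per_ul if lod is not None and rna_conc_pg_per_ul else None),
    )
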