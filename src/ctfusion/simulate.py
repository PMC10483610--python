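"""Synthetic cohorts for the liquid-biopsy fusion-transcript pipeline.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without clinical data:

* multiplexed count profiles — overdispersed negative-binomial background on
  non-target and negative-control probes, lognormal housekeeping counts, and
  a lognormal fusion signal whose median scales linearly with the sample's
  tumor-RNA fraction;
* MET exon-14 skipping via the skip/wild-type count ratio (median 1.7 in
  carriers at tumor fraction 1 vs 0.1 in non-carriers);
* serial-dilution banks built from a concentrated cell-line-like stock
  (``dilution_stock_scale`` times brighter than a clinical-scale sample at
  the same nominal fraction — cell-line RNA carries far more fusion
  transcript per nanogram than patient cfRNA);
* 20,000-partition digital-PCR chips with independent Poisson co-loading of
  mutant and reference molecules;
* full cohorts (count profile + chip per sample) with a configurable
  alteration composition.

All draws go through a single :class:`numpy.random.Generator`, so a fixed
seed reproduces a cohort exactly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .dpcr import ChipReadout
from .panel import CANONICAL_TARGET, PanelError, ProbeClass, ProbePanel, default_panel
from .profiles import CountProfile

__all__ = [
    "SimulationConfig",
    "AssayTruth",
    "CohortSpec",
    "CohortSample",
    "simulate_count_profile",
    "simulate_dilution_bank",
    "simulate_chip",
    "simulate_chip_intensities",
    "simulate_cohort",
]

#: alteration label meaning "no fusion or splicing variant"
NO_ALTERATION = "none"

_FLUIDS = ("plasma", "PE", "CSF", "ASC")


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the study conditions of the assay.

    background_mean / background_dispersion
        Negative-binomial background on non-target probes; d is the excess
        Fano factor, variance = (1 + d) * mean. The three clinically
        characterised probes carry their own observed negative-sample
        medians via ``probe_background_means``.
    hk_geomean / hk_cv
        Lognormal housekeeping counts; 500 counts emulates an adequate
        cfRNA input (the QC gate is at 30). Lower values emulate
        EV-RNA-like low-input preparations.
    signal_median / probe_signal_medians / detection_noise_cv
        Median counts on the true-positive probe in a clinical-scale sample
        at tumor fraction 1, with lognormal multiplicative noise; the three
        characterised probes default to their observed positive medians
        (6756 / 4063 / 6911).
    met_ratio_positive / met_ratio_negative
        Target MET skip/wt count ratio in carriers (at tumor fraction 1)
        and non-carriers.
    dilution_stock_scale
        Brightness of the dilution-bank stock relative to a clinical-scale
        sample at the same tumor fraction (cell-line total RNA vs cfRNA).
    partitions_per_chip / partition_volume_ul
        Chip geometry (20K chip, nominal 0.755 nL wells).
    chip_mutant_copies_per_ul / chip_reference_copies_per_ul
        Chip loading concentrations used by :func:`simulate_cohort`
        (mutant scaled by tumor fraction).
    """

    seed: int = 0
    background_mean: float = 6.0
    background_dispersion: float = 0.5
    hk_geomean: float = 500.0
    hk_cv: float = 0.5
    signal_median: float = 6756.0
    detection_noise_cv: float = 0.6
    met_wt_mean: float = 300.0
    met_ratio_positive: float = 1.7
    met_ratio_negative: float = 0.1
    dilution_stock_scale: float = 100.0
    partitions_per_chip: int = 20000
    partition_volume_ul: float = 7.55e-4
    chip_mutant_copies_per_ul: float = 50.0
    chip_reference_copies_per_ul: float = 10.0
    probe_background_means: dict[str, float] = field(
        default_factory=lambda: {
            "ALK_EML4_E13:A20": 8.0,
            "ROS1_CD74_C6:R32": 6.0,
            "RET_KIF5B_K15:R12": 3.0,
        }
    )
    probe_signal_medians: dict[str, float] = field(
        default_factory=lambda: {
            "ALK_EML4_E13:A20": 6756.0,
            "ROS1_CD74_C6:R32": 4063.0,
            "RET_KIF5B_K15:R12": 6911.0,
        }
    )

    def __post_init__(self) -> None:
        positive = {
            "background_mean": self.background_mean,
            "hk_geomean": self.hk_geomean,
            "hk_cv": self.hk_cv,
            "signal_median": self.signal_median,
            "detection_noise_cv": self.detection_noise_cv,
            "met_wt_mean": self.met_wt_mean,
            "met_ratio_positive": self.met_ratio_positive,
            "met_ratio_negative": self.met_ratio_negative,
            "dilution_stock_scale": self.dilution_stock_scale,
            "partition_volume_ul": self.partition_volume_ul,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if self.background_dispersion < 0:
            raise ValueError("background_dispersion must be >= 0")
        if self.partitions_per_chip < 1:
            raise ValueError("partitions_per_chip must be >= 1")
        if self.chip_mutant_copies_per_ul < 0 or self.chip_reference_copies_per_ul < 0:
            raise ValueError("chip concentrations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class AssayTruth:
    """Ground-truth alteration of one simulated sample."""

    sample_id: str
    alteration: str = NO_ALTERATION   # target probe id, or "none"
    tumor_fraction: float = 0.0
    fluid: str = "plasma"

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError(f"tumor_fraction must be in [0, 1], got {self.tumor_fraction}")
        if self.fluid not in _FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}, expected one of {_FLUIDS}")

    @property
    def is_positive(self) -> bool:
        return self.alteration != NO_ALTERATION


@dataclass
class CohortSpec:
    """Composition of a simulated cohort.

    ``alterations`` maps an alteration — a target probe id, or a gene name
    (resolved to the most recurrent junction) — to a number of samples.
    ``fluid_counts``, when given, assigns fluids to samples in order.
    ``dilution_levels`` / ``dilution_replicates`` describe the replicate
    structure of any dilution bank built alongside the cohort.
    """

    alterations: dict[str, int] = field(default_factory=dict)
    n_controls: int = 0
    tumor_fraction: float = 1.0
    fluid_counts: dict[str, int] | None = None
    dilution_levels: tuple[float, ...] = ()
    dilution_replicates: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.alterations.values()) or self.n_controls < 0:
            raise ValueError("class counts must be non-negative")
        levels = self.dilution_levels
        if any(b >= a for a, b in zip(levels, levels[1:])):
            raise ValueError(f"dilution levels must be strictly decreasing, got {levels}")

    @property
    def n_samples(self) -> int:
        return sum(self.alterations.values()) + self.n_controls

    @classmethod
    def reference_cohort(cls) -> "CohortSpec":
        """The default clinical-like composition: 14 ALK, 9 ROS1, 12 RET,
        5 MET exon-14 skipping, and 16 pan-negative controls (32/5/3 plasma/
        PE/CSF among positives; 12/3/1 plasma/PE/ASC among controls)."""
        return cls(
            alterations={"ALK": 14, "ROS1": 9, "RET": 12, "MET": 5},
            n_controls=16,
            fluid_counts={"plasma": 44, "PE": 8, "CSF": 3, "ASC": 1},
        )


@dataclass
class CohortSample:
    truth: AssayTruth
    profile: CountProfile
    chip: ChipReadout


# ---------------------------------------------------------------------------
# elementary draws

def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _draw_background(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """NB(mean, var = (1 + d) * mean); Poisson when d == 0."""
    if dispersion == 0:
        return rng.poisson(mean, size=size)
    r = mean / dispersion
    p = 1.0 / (1.0 + dispersion)
    return rng.negative_binomial(r, p, size=size)


def _draw_signal(rng: np.random.Generator, median: float, cv: float) -> float:
    return float(rng.lognormal(math.log(median), _lognormal_sigma(cv)))


def _resolve_target(alteration: str, panel: ProbePanel) -> str:
    """Map an alteration label (gene or probe id) to its target probe id."""
    if alteration in CANONICAL_TARGET:
        alteration = CANONICAL_TARGET[alteration]
    if alteration not in panel or panel[alteration].probe_class not in (
        ProbeClass.FUSION,
        ProbeClass.MET_SKIP,
    ):
        raise PanelError(f"alteration {alteration!r} is not a target probe of the panel")
    return alteration


# ---------------------------------------------------------------------------
# generators

def simulate_count_profile(
    truth: AssayTruth,
    config: SimulationConfig,
    panel: ProbePanel | None = None,
    rng: np.random.Generator | None = None,
    signal_scale: float = 1.0,
) -> CountProfile:
    """Draw one sample's count profile.

    Non-target fusion probes and negative-control probes carry negative-
    binomial background; housekeeping probes are lognormal around the HK
    geometric mean; the true-positive probe (if any) adds a lognormal
    signal with median ``signal_median * tumor_fraction * signal_scale``
    on top of its background. Wild-type MET is always expressed; the MET
    skip probe is scaled off the wild-type count so the skip/wt ratio
    targets the carrier or non-carrier ratio.
    """
    panel = panel or default_panel()
    rng = rng if rng is not None else config.rng()
    target = (
        _resolve_target(truth.alteration, panel) if truth.alteration != NO_ALTERATION else None
    )
    eff_fraction = min(1.0, truth.tumor_fraction * signal_scale)
    counts: dict[str, int] = {}
    for probe in panel:
        pid = probe.probe_id
        if probe.probe_class in (ProbeClass.FUSION, ProbeClass.NEGATIVE_CONTROL):
            mean = config.probe_background_means.get(pid, config.background_mean)
            c = int(_draw_background(rng, mean, config.background_dispersion))
            if pid == target and truth.tumor_fraction > 0:
                median = (
                    config.probe_signal_medians.get(pid, config.signal_median)
                    * truth.tumor_fraction
                    * signal_scale
                )
                c += int(round(_draw_signal(rng, median, config.detection_noise_cv)))
            counts[pid] = c
        elif probe.probe_class == ProbeClass.HOUSEKEEPING:
            counts[pid] = int(round(_draw_signal(rng, config.hk_geomean, config.hk_cv)))
        elif probe.probe_class == ProbeClass.MET_WT:
            counts[pid] = int(round(_draw_signal(rng, config.met_wt_mean, config.detection_noise_cv)))
        elif probe.probe_class == ProbeClass.MET_SKIP:
            counts[pid] = 0  # filled below, needs the wt draw
    wt = counts[panel.met_wt_id]
    if target == panel.met_skip_id:
        ratio = config.met_ratio_negative + (
            config.met_ratio_positive - config.met_ratio_negative
        ) * eff_fraction
    else:
        ratio = config.met_ratio_negative
    skip_noise = _draw_signal(rng, 1.0, config.detection_noise_cv)
    counts[panel.met_skip_id] = int(round(wt * ratio * skip_noise))
    return CountProfile(
        sample_id=truth.sample_id,
        counts=counts,
        fluid=truth.fluid,
        metadata={"alteration": truth.alteration, "tumor_fraction": truth.tumor_fraction},
    )


def simulate_dilution_bank(
    variant: str,
    levels: Sequence[float],
    replicates: int,
    config: SimulationConfig,
    panel: ProbePanel | None = None,
    rng: np.random.Generator | None = None,
) -> list[CountProfile]:
    """Serial-dilution bank of a cell-line-like stock into pan-negative cfRNA.

    ``levels`` are tumor fractions in (0, 1], strictly decreasing. The stock
    is ``config.dilution_stock_scale`` times brighter than a clinical-scale
    sample, so signal medians are ``signal_median * level * stock_scale``.
    Each profile records its level and replicate index in ``metadata``.
    """
    if len(levels) == 0:
        raise ValueError("dilution bank needs at least one level")
    if any(not 0.0 < lv <= 1.0 for lv in levels):
        raise ValueError(f"levels must lie in (0, 1], got {list(levels)}")
    if any(b >= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"levels must be strictly decreasing, got {list(levels)}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    panel = panel or default_panel()
    rng = rng if rng is not None else config.rng()
    target = _resolve_target(variant, panel)
    out: list[CountProfile] = []
    for level in levels:
        for rep in range(replicates):
            truth = AssayTruth(
                sample_id=f"{target}_f{level:g}_r{rep + 1}",
                alteration=target,
                tumor_fraction=level,
            )
            profile = simulate_count_profile(
                truth, config, panel=panel, rng=rng, signal_scale=config.dilution_stock_scale
            )
            profile.metadata["replicate"] = rep + 1
            out.append(profile)
    return out


def simulate_chip(
    mutant_copies_per_ul: float,
    wt_copies_per_ul: float,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    sample_id: str = "chip",
    assay: str = "assay",
) -> ChipReadout:
    """Draw one chip's partition tallies.

    Per-channel occupancy is lambda = concentration * partition volume;
    a channel is positive in a partition with probability 1 - exp(-lambda),
    and the two channels co-load independently, so the four quadrant
    probabilities are products. Tallies always sum to the partition count.
    """
    if mutant_copies_per_ul < 0 or wt_copies_per_ul < 0:
        raise ValueError("concentrations must be >= 0")
    rng = rng if rng is not None else config.rng()
    lam_m = mutant_copies_per_ul * config.partition_volume_ul
    lam_w = wt_copies_per_ul * config.partition_volume_ul
    p_m = -math.expm1(-lam_m)
    p_w = -math.expm1(-lam_w)
    probs = [
        p_m * (1 - p_w),        # mutant only
        p_w * (1 - p_m),        # reference only
        p_m * p_w,              # double positive
        (1 - p_m) * (1 - p_w),  # negative
    ]
    n_mut, n_ref, n_dbl, n_neg = rng.multinomial(config.partitions_per_chip, probs)
    return ChipReadout(
        sample_id=sample_id,
        assay=assay,
        n_partitions=config.partitions_per_chip,
        n_mut_only=int(n_mut),
        n_ref_only=int(n_ref),
        n_double=int(n_dbl),
        n_neg=int(n_neg),
    )


def simulate_chip_intensities(
    chip: ChipReadout,
    rng: np.random.Generator,
    negative_mean: tuple[float, float] = (1000.0, 1000.0),
    positive_mean: tuple[float, float] = (6000.0, 6000.0),
    sd: float = 400.0,
) -> np.ndarray:
    """Per-partition two-channel Gaussian fluorescence for a chip's tallies.

    Cluster means default to a 5-sigma-plus separation, mimicking a clean
    chip read; useful for exercising threshold classification against known
    quadrant assignments.
    """
    blocks = []
    for n, mut_hot, ref_hot in (
        (chip.n_mut_only, True, False),
        (chip.n_ref_only, False, True),
        (chip.n_double, True, True),
        (chip.n_neg, False, False),
    ):
        mu = np.array(
            [
                positive_mean[0] if mut_hot else negative_mean[0],
                positive_mean[1] if ref_hot else negative_mean[1],
            ]
        )
        blocks.append(rng.normal(mu, sd, size=(n, 2)))
    return np.vstack(blocks)


def simulate_cohort(
    spec: CohortSpec,
    config: SimulationConfig,
    panel: ProbePanel | None = None,
    rng: np.random.Generator | None = None,
) -> list[CohortSample]:
    """Simulate a full cohort: truth manifest, count profile and chip per sample.

    Chip mutant loading is ``chip_mutant_copies_per_ul * tumor_fraction``
    for carriers and 0 for controls; the reference channel is loaded at
    ``chip_reference_copies_per_ul`` throughout. Deterministic under the
    config seed.
    """
    panel = panel or default_panel()
    rng = rng if rng is not None else config.rng()
    classes: list[str] = []
    for alteration, n in spec.alterations.items():
        classes.extend([alteration] * n)
    classes.extend([NO_ALTERATION] * spec.n_controls)
    fluids: list[str] = []
    if spec.fluid_counts:
        for fluid, n in spec.fluid_counts.items():
            fluids.extend([fluid] * n)
        if len(fluids) != len(classes):
            raise ValueError(
                f"fluid_counts sum to {len(fluids)} but cohort has {len(classes)} samples"
            )
    else:
        fluids = ["plasma"] * len(classes)
    out: list[CohortSample] = []
    for i, (alteration, fluid) in enumerate(zip(classes, fluids), start=1):
        positive = alteration != NO_ALTERATION
        target = _resolve_target(alteration, panel) if positive else NO_ALTERATION
        truth = AssayTruth(
            sample_id=f"S{i:03d}",
            alteration=target,
            tumor_fraction=spec.tumor_fraction if positive else 0.0,
            fluid=fluid,
        )
        profile = simulate_count_profile(truth, config, panel=panel, rng=rng)
        mut_conc = config.chip_mutant_copies_per_ul * truth.tumor_fraction if positive else 0.0
        chip = simulate_chip(
            mut_conc,
            config.chip_reference_copies_per_ul,
            config,
            rng=rng,
            sample_id=truth.sample_id,
            assay=target if positive else "panel_reference",
        )
        out.append(CohortSample(truth, profile, chip))
    return out
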