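"""Digital-PCR partition statistics.

A chip partitions a PCR into ~20,000 microreactions. Molecules load into
partitions approximately independently, so the number of target molecules
per partition is Poisson with mean (occupancy) lambda = c * v, where c is
the concentration in copies/uL and v the partition volume in uL. A
partition is read out as positive when it received at least one molecule:

    P(positive) = 1 - exp(-lambda)

Inverting the observed positive fraction f gives the maximum-likelihood
occupancy lambda = -ln(1 - f) and concentration lambda / v. The mutant
allele frequency (MAF) is mutant / (mutant + wild-type) on the estimated
molecule concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_PARTITION_VOLUME_UL",
    "DEFAULT_MIN_REFERENCE_COPIES_PER_UL",
    "ChipReadout",
    "ChannelQuant",
    "QuantResult",
    "MafResult",
    "SaturatedChipError",
    "poisson_concentration",
    "quantify_chip",
    "compute_maf",
    "assess_evaluability",
    "classify_partitions",
    "check_run_controls",
]

#: nominal partition volume of a 20K microwell chip (0.755 nL)
DEFAULT_PARTITION_VOLUME_UL = 7.55e-4

#: reference-channel concentration below which a reaction is not evaluable
DEFAULT_MIN_REFERENCE_COPIES_PER_UL = 0.5


class SaturatedChipError(ValueError):
    """All partitions positive: occupancy is unbounded and cannot be estimated."""


@dataclass
class ChipReadout:
    """Partition classification tallies of one chip, two fluorescence channels.

    The mutant channel carries the variant-specific assay; the reference
    channel carries an endogenous control (e.g. PUM1, or wild-type MET for
    the exon-14-skipping assay).
    """

    sample_id: str
    assay: str
    n_partitions: int
    n_mut_only: int
    n_ref_only: int
    n_double: int
    n_neg: int

    def __post_init__(self) -> None:
        tallies = (self.n_mut_only, self.n_ref_only, self.n_double, self.n_neg)
        if any(t < 0 for t in tallies):
            raise ValueError(f"{self.sample_id}: negative partition tally {tallies}")
        if sum(tallies) != self.n_partitions:
            raise ValueError(
                f"{self.sample_id}: tallies sum to {sum(tallies)}, "
                f"expected {self.n_partitions} partitions"
            )

    @property
    def mut_positive(self) -> int:
        """Partitions positive in the mutant channel (double positives included)."""
        return self.n_mut_only + self.n_double

    @property
    def ref_positive(self) -> int:
        return self.n_ref_only + self.n_double


@dataclass
class ChannelQuant:
    """Poisson quantification of one fluorescence channel."""

    positive: int
    total: int
    positive_fraction: float
    occupancy: float               # lambda, molecules per partition
    copies_per_ul: float
    ci_low: float
    ci_high: float

    @property
    def ci(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)


@dataclass
class QuantResult:
    sample_id: str
    assay: str
    mutant: ChannelQuant
    reference: ChannelQuant
    evaluable: bool
    maf: "MafResult | None" = None


@dataclass
class MafResult:
    mutant_copies_per_ul: float
    wt_copies_per_ul: float
    maf: float | None    # None when both concentrations are 0 (undefined)


def poisson_concentration(
    positive: int,
    total: int,
    partition_volume_ul: float = DEFAULT_PARTITION_VOLUME_UL,
    ci_method: str = "normal",
) -> ChannelQuant:
    """Estimate concentration (copies/uL) from a channel's positive-partition count.

    The 95% CI is a normal approximation on lambda,
    lambda +/- 1.96 * sqrt(f / (total * (1 - f))), scaled by 1/volume and
    floored at 0. ``ci_method="clopper-pearson"`` instead transforms an
    exact binomial CI on f through -ln(1-f)/v.
    """
    if partition_volume_ul <= 0:
        raise ValueError(f"partition volume must be > 0, got {partition_volume_ul}")
    if total < 1:
        raise ValueError(f"need at least one partition, got {total}")
    if not 0 <= positive <= total:
        raise ValueError(f"positive count {positive} outside [0, {total}]")
    if positive == total:
        raise SaturatedChipError(
            f"all {total} partitions positive: occupancy unbounded, dilute and rerun"
        )
    f = positive / total
    lam = -math.log1p(-f)
    conc = lam / partition_volume_ul
    if ci_method == "normal":
        half = 1.96 * math.sqrt(f / (total * (1.0 - f)))
        lo = max(0.0, (lam - half)) / partition_volume_ul
        hi = (lam + half) / partition_volume_ul
    elif ci_method == "clopper-pearson":
        from statsmodels.stats.proportion import proportion_confint

        f_lo, f_hi = proportion_confint(positive, total, alpha=0.05, method="beta")
        f_hi = min(f_hi, 1.0 - 1.0 / (2 * total))  # keep the transform finite
        lo = -math.log1p(-f_lo) / partition_volume_ul
        hi = -math.log1p(-f_hi) / partition_volume_ul
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ChannelQuant(positive, total, f, lam, conc, lo, hi)


def assess_evaluability(
    reference: ChannelQuant,
    min_copies_per_ul: float = DEFAULT_MIN_REFERENCE_COPIES_PER_UL,
) -> bool:
    """A reaction fails QC when the endogenous reference is below the floor.

    Failure is strictly "< min"; a reference at exactly the floor is evaluable.
    """
    return reference.copies_per_ul >= min_copies_per_ul


def compute_maf(mutant: ChannelQuant, wt: ChannelQuant) -> MafResult:
    """Mutant allele frequency: mutant molecules over total (mutant + wt) molecules.

    Undefined (``maf=None``) when neither channel detected anything —
    distinct from a genuine MAF of 0.
    """
    m, w = mutant.copies_per_ul, wt.copies_per_ul
    maf = None if (m + w) == 0 else m / (m + w)
    return MafResult(mutant_copies_per_ul=m, wt_copies_per_ul=w, maf=maf)


def quantify_chip(
    chip: ChipReadout,
    partition_volume_ul: float = DEFAULT_PARTITION_VOLUME_UL,
    min_reference_copies_per_ul: float = DEFAULT_MIN_REFERENCE_COPIES_PER_UL,
    ci_method: str = "normal",
) -> QuantResult:
    """Full per-chip quantification: both channels, evaluability gate, MAF.

    Double-positive partitions count as positive in both channels
    (independent co-loading).
    """
    mut = poisson_concentration(chip.mut_positive, chip.n_partitions, partition_volume_ul, ci_method)
    ref = poisson_concentration(chip.ref_positive, chip.n_partitions, partition_volume_ul, ci_method)
    evaluable = assess_evaluability(ref, min_reference_copies_per_ul)
    maf = compute_maf(mut, ref) if evaluable else None
    return QuantResult(chip.sample_id, chip.assay, mut, ref, evaluable, maf)


def classify_partitions(
    fluorescence: np.ndarray,
    thresholds: tuple[float, float],
    sample_id: str = "",
    assay: str = "",
    overrides: dict[int, str] | None = None,
) -> ChipReadout:
    """Threshold per-partition two-channel intensities into quadrant tallies.

    ``fluorescence`` is an (n, 2) array with the mutant channel in column 0
    and the reference channel in column 1; a partition is positive in a
    channel when its intensity exceeds that channel's threshold. ``overrides``
    maps partition index -> quadrant label (``"mut_only" | "ref_only" |
    "double" | "neg"``), reproducing manual cluster reassignment in an
    auditable way.
    """
    arr = np.asarray(fluorescence, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected (n, 2) intensities, got shape {arr.shape}")
    t_mut, t_ref = thresholds
    if not (np.isfinite(t_mut) and np.isfinite(t_ref)):
        raise ValueError("thresholds must be finite")
    mut_pos = arr[:, 0] > t_mut
    ref_pos = arr[:, 1] > t_ref
    labels = np.where(
        mut_pos & ref_pos, "double",
        np.where(mut_pos, "mut_only", np.where(ref_pos, "ref_only", "neg")),
    )
    if overrides:
        valid = {"mut_only", "ref_only", "double", "neg"}
        for idx, lab in overrides.items():
            if lab not in valid:
                raise ValueError(f"invalid override label {lab!r}")
            labels[idx] = lab
    n = arr.shape[0]
    return ChipReadout(
        sample_id=sample_id,
        assay=assay,
        n_partitions=n,
        n_mut_only=int(np.sum(labels == "mut_only")),
        n_ref_only=int(np.sum(labels == "ref_only")),
        n_double=int(np.sum(labels == "double")),
        n_neg=int(np.sum(labels == "neg")),
    )


@dataclass
class RunControlReport:
    blank_clean: bool
    negative_clean: bool
    positive_detected: bool | None
    flags: list[str] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not self.flags


def check_run_controls(
    blank: ChipReadout | None,
    negative: ChipReadout | None,
    positive: ChipReadout | None = None,
) -> RunControlReport:
    """Cohort-level validity of a dPCR run's controls.

    The blank (no cDNA) and the wild-type negative control must show zero
    mutant-positive partitions; a positive control, when run, must show at
    least one. Violations flag the run rather than silently dropping it.
    """
    flags: list[str] = []
    blank_clean = blank is None or blank.mut_positive == 0
    if not blank_clean:
        flags.append(f"blank shows {blank.mut_positive} mutant-positive partitions")
    negative_clean = negative is None or negative.mut_positive == 0
    if not negative_clean:
        flags.append(f"negative control shows {negative.mut_positive} mutant-positive partitions")
    positive_detected = None if positive is None else positive.mut_positive > 0
    if positive_detected is False:
        flags.append("positive control shows no mutant-positive partitions")
    return RunControlReport(blank_clean, negative_clean, positive_detected, flags)
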