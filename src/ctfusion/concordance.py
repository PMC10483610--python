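"""Diagnostic-agreement statistics for liquid-biopsy vs tissue genotyping.

For each gene g, every sample contributes one binary test: tissue truth
(altered in g or not) against the liquid-biopsy call. Negatives for g
include samples positive for *other* genes — the panel answers "is g
altered?" per sample, so an ALK-positive patient is a true negative for
ROS1. The pooled ("overall") table is the cell-wise sum of the per-gene
tables.

Statistics: sensitivity/specificity/concordance with Wilson score 95% CIs
(Wald and Clopper-Pearson available), Cohen's kappa with an asymptotic
95% CI, between-technique agreement with a two-proportion Z test, and the
algebra for reconstructing a joint 2x2 from printed marginals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

__all__ = [
    "ConfusionTable",
    "ProportionCI",
    "KappaResult",
    "DiagnosticSummary",
    "TechniqueComparison",
    "build_confusion",
    "pool_tables",
    "sensitivity_specificity",
    "proportion_ci",
    "cohen_kappa",
    "concordance_fraction",
    "diagnostic_summary",
    "compare_techniques",
    "reconcile_marginals",
    "mann_whitney_counts",
]

_Z95 = 1.96


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement counts of a binary call against truth."""

    tp: int
    fn: int
    fp: int
    tn: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def concordant(self) -> int:
        return self.tp + self.tn

    @property
    def discordant(self) -> int:
        return self.fn + self.fp


@dataclass(frozen=True)
class ProportionCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str = "wilson"


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    se: float

    def clipped(self) -> tuple[float, float]:
        """CI intersected with [-1, 1]; the raw asymptotic bounds may exceed it."""
        return (max(self.ci_low, -1.0), min(self.ci_high, 1.0))


@dataclass
class DiagnosticSummary:
    label: str
    table: ConfusionTable
    sensitivity: ProportionCI | None
    specificity: ProportionCI | None
    concordance: float
    kappa: KappaResult | None


@dataclass
class TechniqueComparison:
    n: int
    both_pos: int
    a_only: int
    b_only: int
    both_neg: int
    agreement: float
    union_detection: float
    z_statistic: float
    p_value: float

    @property
    def joint(self) -> tuple[int, int, int, int]:
        return (self.both_pos, self.a_only, self.b_only, self.both_neg)


def build_confusion(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
    gene: str,
) -> ConfusionTable:
    """Confusion table for one gene (or the pooled table with gene="overall").

    ``calls`` and ``truth`` map sample id -> detected/true gene (or "none")
    over the same samples. For ``gene="overall"`` the per-gene tables of
    every gene appearing in the truth are pooled cell-wise.
    """
    if set(calls) != set(truth):
        only_c = sorted(set(calls) - set(truth))[:3]
        only_t = sorted(set(truth) - set(calls))[:3]
        raise ValueError(f"sample sets differ (calls-only {only_c}, truth-only {only_t})")
    if gene == "overall":
        genes = sorted({g for g in truth.values() if g != "none"})
        return pool_tables([build_confusion(calls, truth, g) for g in genes], label="overall")
    tp = fn = fp = tn = 0
    for sid, true_gene in truth.items():
        called = calls[sid] == gene
        if true_gene == gene:
            tp += called
            fn += not called
        else:
            fp += called
            tn += not called
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, label=gene)


def pool_tables(tables: Sequence[ConfusionTable], label: str = "overall") -> ConfusionTable:
    return ConfusionTable(
        tp=sum(t.tp for t in tables),
        fn=sum(t.fn for t in tables),
        fp=sum(t.fp for t in tables),
        tn=sum(t.tn for t in tables),
        label=label,
    )


def proportion_ci(successes: int, n: int, method: str = "wilson") -> ProportionCI:
    """Binomial proportion with a 95% CI (wilson | wald | clopper-pearson)."""
    if n < 1:
        raise ValueError("proportion undefined for an empty margin")
    sm_method = {"wilson": "wilson", "wald": "normal", "clopper-pearson": "beta"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = proportion_confint(successes, n, alpha=0.05, method=sm_method)
    p_hat = successes / n
    # guard against float dust at the boundaries (e.g. upper 1 - 1e-16 at p=1)
    lo = min(max(float(lo), 0.0), p_hat)
    hi = max(min(float(hi), 1.0), p_hat)
    return ProportionCI(p_hat, lo, hi, method=method)


def sensitivity_specificity(
    t: ConfusionTable, ci_method: str = "wilson"
) -> tuple[ProportionCI | None, ProportionCI | None]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) with 95% CIs.

    A statistic whose margin is empty is returned as None (undefined), not 0.
    """
    sens = proportion_ci(t.tp, t.tp + t.fn, ci_method) if t.tp + t.fn >= 1 else None
    spec = proportion_ci(t.tn, t.tn + t.fp, ci_method) if t.tn + t.fp >= 1 else None
    return sens, spec


def concordance_fraction(t: ConfusionTable) -> float:
    """Observed agreement (TP+TN)/n."""
    return t.concordant / t.n


def cohen_kappa(t: ConfusionTable) -> KappaResult:
    """Chance-corrected agreement with an asymptotic 95% CI.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the agreement expected from the marginals;
    SE = sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)). The CI is reported as
    computed and may exceed [-1, 1]; ``KappaResult.clipped()`` intersects it.
    """
    if t.n < 2:
        raise ValueError("kappa needs n >= 2")
    n = t.n
    p_o = (t.tp + t.tn) / n
    p_e = ((t.tp + t.fp) * (t.tp + t.fn) + (t.fn + t.tn) * (t.fp + t.tn)) / n**2
    if p_e == 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    se = math.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    return KappaResult(kappa, kappa - _Z95 * se, kappa + _Z95 * se, se)


def diagnostic_summary(
    calls: Mapping[str, str],
    truth: Mapping[str, str],
    genes: Sequence[str] | None = None,
    ci_method: str = "wilson",
) -> dict[str, DiagnosticSummary]:
    """Per-gene and pooled diagnostic statistics (the shape of a concordance
    table: concordant/discordant counts, sensitivity, specificity,
    concordance, kappa)."""
    if genes is None:
        genes = sorted({g for g in truth.values() if g != "none"})
    out: dict[str, DiagnosticSummary] = {}
    for label in list(genes) + ["overall"]:
        table = build_confusion(calls, truth, label)
        sens, spec = sensitivity_specificity(table, ci_method)
        out[label] = DiagnosticSummary(
            label=label,
            table=table,
            sensitivity=sens,
            specificity=spec,
            concordance=concordance_fraction(table),
            kappa=cohen_kappa(table),
        )
    return out


def compare_techniques(
    calls_a: Mapping[str, bool],
    calls_b: Mapping[str, bool],
) -> TechniqueComparison:
    """Agreement of two techniques on the same (tissue-positive) cohort.

    Reports the joint 2x2 (both+, A-only, B-only, both-), the agreement
    fraction, the union detection fraction (detected by at least one
    technique), and a two-proportion two-tailed Z test on the per-technique
    detection rates.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("technique call sets cover different samples")
    n = len(calls_a)
    if n == 0:
        raise ValueError("empty cohort")
    both_pos = sum(calls_a[s] and calls_b[s] for s in calls_a)
    a_only = sum(calls_a[s] and not calls_b[s] for s in calls_a)
    b_only = sum(calls_b[s] and not calls_a[s] for s in calls_a)
    both_neg = n - both_pos - a_only - b_only
    pos_a, pos_b = both_pos + a_only, both_pos + b_only
    if (pos_a, pos_b) in (((0, 0)), (n, n)) and pos_a == pos_b:
        z, p = 0.0, 1.0  # identical degenerate rates: no detectable difference
    else:
        z, p = proportions_ztest([pos_a, pos_b], [n, n], alternative="two-sided")
    return TechniqueComparison(
        n=n,
        both_pos=both_pos,
        a_only=a_only,
        b_only=b_only,
        both_neg=both_neg,
        agreement=(both_pos + both_neg) / n,
        union_detection=1.0 - both_neg / n,
        z_statistic=float(z),
        p_value=float(p),
    )


def reconcile_marginals(n: int, pos_a: int, pos_b: int, n_agree: int) -> tuple[int, int, int, int]:
    """Reconstruct the joint 2x2 (both+, A-only, B-only, both-) from printed
    marginals: cohort size, per-technique positives, and agreement count.

    The linear system has the unique solution
    both+ = (pos_a + pos_b - n + n_agree) / 2; inconsistent inputs (a
    non-integer or negative cell) raise a ValueError.
    """
    both_pos2 = pos_a + pos_b - n + n_agree
    if both_pos2 % 2 != 0:
        raise ValueError(
            f"inconsistent marginals: both-positive cell would be {both_pos2 / 2}"
        )
    both_pos = both_pos2 // 2
    both_neg = n_agree - both_pos
    a_only = pos_a - both_pos
    b_only = pos_b - both_pos
    cells = (both_pos, a_only, b_only, both_neg)
    if any(c < 0 for c in cells) or sum(cells) != n:
        raise ValueError(f"inconsistent marginals: joint cells {cells} for n={n}")
    return cells


def mann_whitney_counts(
    group_pos: Sequence[float], group_neg: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U with a two-tailed p value.

    For combined n <= 20 the p value is an exact enumeration over all
    group assignments of the (midrank-based) rank sum, which handles ties;
    larger samples use the normal approximation with tie correction.
    Returns (U of the first group, two-tailed p).
    """
    x = np.asarray(group_pos, dtype=float)
    y = np.asarray(group_neg, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    m, n_total = len(x), len(x) + len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2)
    if n_total <= 20:
        mu = m * (n_total + 1) / 2.0
        r_obs = float(ranks[:m].sum())
        dev = abs(r_obs - mu)
        hits = total = 0
        for idx in combinations(range(n_total), m):
            total += 1
            if abs(float(ranks[list(idx)].sum()) - mu) >= dev - 1e-9:
                hits += 1
        return u_obs, hits / total
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
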