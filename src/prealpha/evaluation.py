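"""Diagnostic-accuracy statistics for DLB-vs-AD classification.

DLB is the positive class throughout: sensitivity is the fraction of
clinically diagnosed DLB subjects classified DLB, specificity the
fraction of AD subjects classified AD.  Confidence intervals are exact
binomial (Clopper-Pearson); the Fisher exact test uses the conventional
two-sided "sum of no-more-probable tables" definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

from .errors import MetricsError, RowSkippedWarning

POSITIVE_LABEL = "DLB"
NEGATIVE_LABEL = "AD"

#: Maximum approved daily doses (mg) of the acetylcholinesterase
#: inhibitors; the half-max subgroup rule excludes doses above half these.
ACHEI_MAX_DOSE_MG = {"donepezil": 10.0, "rivastigmine": 18.0, "galantamine": 24.0}


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts with DLB positive: tp+fn DLB subjects, tn+fp AD."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity/specificity/accuracy in percent with exact 95% CIs."""

    sensitivity: float
    specificity: float
    accuracy: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def as_dict(self) -> dict:
        return {
            "n_dlb": self.n_pos,
            "n_ad": self.n_neg,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
        }

    def format_row(self, name: str, value: float, ci: tuple[float, float]) -> str:
        return f"{name} (95% CI)\t{_round1(value)} ({_round1(ci[0])}-{_round1(ci[1])})"


def _round1(x: float) -> float:
    """Round half-up to one decimal (display only)."""
    return float(np.floor(x * 10 + 0.5) / 10)


def confusion(predictions, truths) -> ConfusionTable:
    """Cross-tabulate predicted against clinical labels (DLB positive)."""
    pred = list(predictions)
    true = list(truths)
    if len(pred) != len(true):
        raise ValueError("predictions and truths differ in length")
    valid = {POSITIVE_LABEL, NEGATIVE_LABEL}
    bad = (set(pred) | set(true)) - valid
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)}")
    tp = sum(p == POSITIVE_LABEL and t == POSITIVE_LABEL for p, t in zip(pred, true))
    fn = sum(p == NEGATIVE_LABEL and t == POSITIVE_LABEL for p, t in zip(pred, true))
    tn = sum(p == NEGATIVE_LABEL and t == NEGATIVE_LABEL for p, t in zip(pred, true))
    fp = sum(p == POSITIVE_LABEL and t == NEGATIVE_LABEL for p, t in zip(pred, true))
    return ConfusionTable(tp=tp, fn=fn, tn=tn, fp=fp)


def clopper_pearson(
    successes: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial CI as percentages, by inverting the binomial tails.

    The bounds are the beta-quantile form; lower = 0 when successes = 0
    and upper = 100 when successes = n.
    """
    if not (0 <= successes <= n) or n < 1:
        raise ValueError(f"invalid counts {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="beta")
    return 100.0 * lo, 100.0 * hi


def diagnostic_metrics(
    table: ConfusionTable, ci_level: float = 0.95
) -> DiagnosticMetrics:
    """Point estimates (percent) and exact CIs from a confusion table."""
    if table.n_pos == 0 or table.n_neg == 0:
        raise MetricsError("both classes must be represented")
    sens = 100.0 * table.tp / table.n_pos
    spec = 100.0 * table.tn / table.n_neg
    acc = 100.0 * (table.tp + table.tn) / table.n
    return DiagnosticMetrics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        sensitivity_ci=clopper_pearson(table.tp, table.n_pos, ci_level),
        specificity_ci=clopper_pearson(table.tn, table.n_neg, ci_level),
        accuracy_ci=clopper_pearson(table.tp + table.tn, table.n, ci_level),
        n_pos=table.n_pos,
        n_neg=table.n_neg,
    )


def roc_auc(scores, labels) -> float:
    """Probability that a random DLB subject outscores a random AD one.

    Mann-Whitney form: ties count one half.
    """
    y = np.asarray(labels)
    if len(set(y.tolist())) < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(y == POSITIVE_LABEL, np.asarray(scores, dtype=float)))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums the hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed
    table's (to a small relative tolerance).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin")
    return float(_stats.fisher_exact(t, alternative="two-sided")[1])


def binomial_power(
    n: int, p0: float, p1: float, alpha: float = 0.05, one_sided: bool = True
) -> float:
    """Power of the exact one-sided binomial test of H0: p = p0 vs p > p0.

    The critical count k* is the smallest k with P(X >= k | p0) <= alpha;
    power is P(X >= k* | p1).  For a two-sided request alpha is halved
    (upper-tail rejection only, appropriate for p1 > p0).
    """
    if not (0 < p0 < 1 and 0 < p1 < 1) or n < 1:
        raise ValueError("require 0 < p0, p1 < 1 and n >= 1")
    a = alpha if one_sided else alpha / 2
    tail = _stats.binom.sf(np.arange(n + 1) - 1, n, p0)  # P(X >= k)
    ok = np.nonzero(tail <= a)[0]
    k_star = int(ok[0]) if ok.size else n + 1
    if k_star > n:
        return 0.0
    return float(_stats.binom.sf(k_star - 1, n, p1))


def subgroup_filter(manifest: pd.DataFrame, rule: str | None) -> pd.DataFrame:
    """Apply a medication-based exclusion rule to a cohort manifest.

    Rules:
      * ``None`` or ``""`` — identity.
      * ``"donepezil_le5"`` — exclude subjects taking more than 5 mg/day
        donepezil.
      * ``"achei_half_max"`` — exclude subjects taking any AChEI above
        half its maximum approved dose (donepezil 5, rivastigmine 9,
        galantamine 12 mg/day).

    Rows whose drug matches a rule but lack a dose are skipped from the
    subgroup with a :class:`RowSkippedWarning`.
    """
    if not rule:
        return manifest
    if rule not in ("donepezil_le5", "achei_half_max"):
        raise ValueError(f"unknown subgroup rule {rule!r}")
    keep = []
    for idx, row in manifest.iterrows():
        drug = str(row.get("drug", "") or "").strip().lower()
        dose = row.get("dose_mg_per_day", np.nan)
        if drug in ("", "none", "nan"):
            keep.append(idx)
            continue
        if rule == "donepezil_le5" and drug != "donepezil":
            keep.append(idx)
            continue
        if rule == "achei_half_max" and drug not in ACHEI_MAX_DOSE_MG:
            keep.append(idx)
            continue
        if pd.isna(dose):
            warnings.warn(
                f"row {row.get('subject_id', idx)}: drug {drug!r} without dose; "
                "excluded from subgroup",
                RowSkippedWarning,
            )
            continue
        limit = 5.0 if rule == "donepezil_le5" else ACHEI_MAX_DOSE_MG[drug] / 2
        if float(dose) <= limit:
            keep.append(idx)
    return manifest.loc[keep]
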