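"""Occurrence, agreement and diagnostic metrics, plus expression roll-up.

Relative occurrence is a per-million frequency, N_select / N_total x 1e6.
The diagnostic formulas are implemented exactly as published:
sensitivity = N_str/(N_str+N_seq) and specificity = N_seq/(N_seq+N_str),
which makes specificity identically 1 - sensitivity, so the positive and
negative likelihood ratios are both identically 1 whenever both counts
are positive.  That degeneracy is a property of the published formulas,
not of this implementation, and is flagged in the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .model import CoverageRecord, ValidationError


def relative_occurrence(n_select: int, n_total: int) -> float:
    """Per-million relative occurrence of a function: n_select/n_total * 1e6."""
    if n_total <= 0:
        raise ValidationError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_select <= n_total):
        raise ValidationError(
            f"n_select {n_select} outside [0, n_total={n_total}]"
        )
    return n_select / n_total * 1e6


@dataclass(frozen=True)
class DiagnosticMetrics:
    n_str: int
    n_seq: int
    sensitivity: float
    specificity: float
    plr: float      # NaN when 1 - specificity == 0 (undefined, flagged)
    nlr: float      # NaN when specificity == 0 (undefined, flagged)
    degenerate: bool = True  # the published formulas force PLR = NLR = 1

    def to_dict(self) -> dict:
        def v(x: float):
            return None if math.isnan(x) else x
        return {
            "n_str": self.n_str, "n_seq": self.n_seq,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "plr": v(self.plr), "nlr": v(self.nlr),
            "plr_defined": not math.isnan(self.plr),
            "nlr_defined": not math.isnan(self.nlr),
            "degenerate_formulas": self.degenerate,
        }


def diagnostic_metrics(n_str: int, n_seq: int) -> DiagnosticMetrics:
    """Sensitivity/specificity/likelihood ratios over correct-call counts.

    ``n_str`` and ``n_seq`` count correct structure- and sequence-based
    annotations.  Undefined ratios (zero denominators) are returned as
    NaN rather than raised, so degenerate corner counts stay reportable.
    """
    if n_str < 0 or n_seq < 0:
        raise ValidationError("counts must be non-negative")
    total = n_str + n_seq
    if total == 0:
        raise ValidationError("n_str + n_seq must be positive")
    sensitivity = n_str / total
    specificity = n_seq / total
    plr = sensitivity / (1 - specificity) if specificity < 1 else math.nan
    nlr = (1 - sensitivity) / specificity if specificity > 0 else math.nan
    return DiagnosticMetrics(n_str, n_seq, sensitivity, specificity, plr, nlr)


def percent(count: int, total: int, ndigits: int = 0) -> float:
    """100*count/total, rounded half-away-from-zero to ``ndigits``.

    Python's built-in round is banker's rounding; published percentages
    (46%, 31%, ...) follow the half-away convention, so the rounding is
    done in decimal.
    """
    if total <= 0:
        raise ValidationError(f"total must be positive, got {total}")
    q = Decimal(100) * Decimal(count) / Decimal(total)
    exp = Decimal(1).scaleb(-ndigits)
    value = float(q.quantize(exp, rounding=ROUND_HALF_UP))
    return int(value) if ndigits == 0 else value


def agreement_summary(consensus: pd.DataFrame,
                      group_of: Optional[Mapping[str, str]] = None
                      ) -> pd.DataFrame:
    """Count agreement categories per supercluster group.

    ``consensus`` is the annotation table (needs ``subject_id`` and
    ``agreement``; a ``group`` column may be present or supplied via
    ``group_of``).  Output rows are (group, category, count, total,
    percent) with the percent rounded half-away-from-zero to an integer;
    an empty group reports percent as missing.
    """
    df = consensus.copy()
    if "group" not in df.columns:
        if group_of is None:
            raise ValueError("consensus table lacks a 'group' column and no "
                             "group mapping was given")
        df["group"] = df["subject_id"].map(dict(group_of))
    categories = ["consistent", "disparate", "structure_only",
                  "sequence_only", "unannotated"]
    rows = []
    for group in sorted(df["group"].dropna().unique()):
        sub = df[df["group"] == group]
        total = len(sub)
        for cat in categories:
            count = int((sub["agreement"] == cat).sum())
            rows.append({
                "group": group,
                "category": cat,
                "count": count,
                "total": total,
                "percent": percent(count, total) if total else math.nan,
            })
    return pd.DataFrame(rows, columns=["group", "category", "count",
                                       "total", "percent"])


@dataclass
class ClusterExpression:
    """Metatranscriptomic coverage of one cluster's member genes."""

    label: str
    per_sample: dict[str, float]
    overall_mean: Optional[float]   # None when no member gene was covered
    high_expression: bool


def cluster_expression(coverage: Iterable[CoverageRecord],
                       membership: Mapping[str, Iterable[str]],
                       high_expr_percentile: float = 75.0
                       ) -> list[ClusterExpression]:
    """Aggregate per-gene mean coverage to cluster level.

    For each cluster (keyed by its label) and sample, coverage is the
    mean over member genes with data; the overall mean is then taken
    over samples.  A cluster with no covered member genes keeps a
    missing overall mean (never an implicit zero) and is excluded from
    the high-expression percentile pool.  ``high_expression`` flags
    clusters at or above the given percentile of overall means.
    """
    records = list(coverage)
    if records:
        cov = pd.DataFrame(
            [(r.gene_id, r.sample_id, r.mean_coverage) for r in records],
            columns=["gene_id", "sample_id", "mean_coverage"],
        )
    else:
        cov = pd.DataFrame(columns=["gene_id", "sample_id", "mean_coverage"])

    results: list[ClusterExpression] = []
    for label in sorted(membership):
        genes = set(membership[label])
        sub = cov[cov["gene_id"].isin(genes)]
        per_sample = (
            sub.groupby("sample_id")["mean_coverage"].mean().to_dict()
        )
        overall = float(np.mean(list(per_sample.values()))) if per_sample else None
        results.append(ClusterExpression(label, per_sample, overall, False))

    pool = [r.overall_mean for r in results if r.overall_mean is not None]
    if pool:
        threshold = float(np.percentile(pool, high_expr_percentile))
        for r in results:
            r.high_expression = (
                r.overall_mean is not None and r.overall_mean >= threshold
            )
    return results


def expression_table(expressions: Iterable[ClusterExpression]) -> pd.DataFrame:
    rows = [
        {
            "label": e.label,
            "overall_mean": math.nan if e.overall_mean is None else e.overall_mean,
            "n_samples": len(e.per_sample),
            "high_expression": e.high_expression,
        }
        for e in expressions
    ]
    return pd.DataFrame(rows, columns=["label", "overall_mean", "n_samples",
                                       "high_expression"])


def occurrence_table(ko_counts: Mapping[str, int], n_total: int,
                     labels: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Relative-occurrence table over a domain's KO counts."""
    rows = [
        {
            "ko_id": ko,
            "label": (labels or {}).get(ko, ""),
            "n_select": n,
            "n_total": n_total,
            "relative_occurrence": relative_occurrence(n, n_total),
        }
        for ko, n in sorted(ko_counts.items())
    ]
    return pd.DataFrame(rows, columns=["ko_id", "label", "n_select",
                                       "n_total", "relative_occurrence"])
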