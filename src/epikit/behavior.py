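"""Behavioral, expression and cohort-level seizure statistics.

* Discrimination index for object-location / novel-object tests:
  DI = (time with altered object − time with unchanged object) / total
  exploration time, in [−1, 1].
* Relative gene expression by the ΔΔCT method: ΔCT = CT_target −
  CT_reference per sample, ΔΔCT against the mean control ΔCT (or paired
  within-animal references), fold change 2^(−ΔΔCT).
* Two-sided Fisher's exact test for 2×2 contingency tables, by summing
  hypergeometric probabilities of all tables with fixed margins whose
  probability does not exceed the observed one.
* Cohort seizure summaries: per-animal seizure rates before and after a
  treatment boundary, a fewer-vs-more classification (ties count against
  "fewer"), baseline-normalized cumulative seizure curves, and the
  "at least one seizure per week" inclusion flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .synthetic import ExplorationLog

__all__ = [
    "discrimination_index",
    "ddct_relative_expression",
    "fisher_exact_2x2",
    "bonferroni_alpha",
    "cohort_summary",
    "cumulative_normalized",
    "CohortSummary",
]


def discrimination_index(log: ExplorationLog) -> float | None:
    """DI = (t_altered − t_unchanged) / (t_altered + t_unchanged).

    Returns None (with a warning) when there was no exploration at all.
    """
    t_alt = log.total("altered")
    t_unc = log.total("unchanged")
    total = t_alt + t_unc
    if total <= 0:
        warnings.warn("no exploration; discrimination index undefined", stacklevel=2)
        return None
    return (t_alt - t_unc) / total


def ddct_relative_expression(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    control_condition: str = "control",
    paired_by: str | None = None,
) -> pd.DataFrame:
    """Fold change per sample by the ΔΔCT method.

    ``ct`` is tidy: columns ``sample``, ``condition``, ``gene``, ``ct``.
    ΔCT = CT_target − CT_reference per sample; ΔΔCT subtracts the mean
    control ΔCT; fold = 2^(−ΔΔCT).  With ``paired_by`` (a column naming
    e.g. the animal), each sample's reference is the mean control ΔCT within
    its own pairing group — the within-animal design used when expression is
    measured relative to the contralateral hippocampus.
    """
    for col in ("sample", "condition", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"CT table missing column {col!r}")
    wide = ct.pivot_table(index="sample", columns="gene", values="ct")
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValueError(f"every sample needs a CT value for gene {gene!r}")
    meta = ct.drop_duplicates("sample").set_index("sample")
    dct = wide[target_gene] - wide[reference_gene]
    control = meta["condition"] == control_condition
    if not control.any():
        raise ValueError(f"no samples with control condition {control_condition!r}")
    if paired_by is None:
        ref = pd.Series(dct[control.reindex(dct.index)].mean(), index=dct.index)
    else:
        grp = meta[paired_by]
        ctrl_mean = dct[control.reindex(dct.index)].groupby(grp).mean()
        ref = grp.map(ctrl_mean)
        if ref.isna().any():
            missing = list(dct.index[ref.isna()])
            raise ValueError(f"samples {missing} have no paired control reference")
    ddct = dct - ref
    out = pd.DataFrame(
        {
            "sample": dct.index,
            "condition": meta["condition"].reindex(dct.index).to_numpy(),
            "delta_ct": dct.to_numpy(),
            "delta_delta_ct": ddct.to_numpy(),
            "fold_change": np.power(2.0, -ddct.to_numpy()),
        }
    ).reset_index(drop=True)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test p-value for the table [[a, b], [c, d]].

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (with a 1e-7 relative tolerance on the comparison, so ties at the
    observed probability are included despite floating-point noise).
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    rv = hypergeom(n, r1, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(1.0, p)


def bonferroni_alpha(family_alpha: float, n_comparisons: int) -> float:
    """Per-comparison significance level at a given family-wise alpha."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return family_alpha / n_comparisons


# ---------------------------------------------------------------------------
# Cohort seizure summaries


@dataclass
class CohortSummary:
    """Per-animal phase rates and classifications, plus the group 2×2 table."""

    per_animal: pd.DataFrame

    def contingency(
        self, group_a: str, group_b: str
    ) -> tuple[tuple[int, int], tuple[int, int]]:
        """2×2 table of (fewer, more_or_equal) counts for two groups."""
        rows = []
        for g in (group_a, group_b):
            sub = self.per_animal[self.per_animal["group"] == g]
            fewer = int((sub["classification"] == "fewer").sum())
            rows.append((fewer, len(sub) - fewer))
        return rows[0], rows[1]


def cohort_summary(
    events: pd.DataFrame,
    phases: pd.DataFrame,
    weekly_inclusion_rate: float = 1.0 / 7.0,
) -> CohortSummary:
    """Summarize per-animal seizure burden across a treatment boundary.

    ``events``: columns ``animal``, ``time_d`` (seizure times in days from
    recording start).  ``phases``: columns ``animal``, ``group``,
    ``baseline_start_d``, ``treatment_start_d``, ``end_d``.  Rates are
    seizures/day per phase; an animal is classified "fewer" only if its
    treatment-phase daily rate is strictly below baseline (ties land in
    "more_or_equal"); the inclusion flag requires a baseline rate of at
    least one seizure per week.
    """
    for col in ("animal", "time_d"):
        if col not in events.columns:
            raise ValueError(f"events table missing column {col!r}")
    rows = []
    for ph in phases.itertuples():
        b0, b1, e1 = ph.baseline_start_d, ph.treatment_start_d, ph.end_d
        if not (b0 < b1 < e1):
            raise ValueError(
                f"animal {ph.animal}: phases must satisfy "
                f"baseline_start < treatment_start < end"
            )
        t = events.loc[events["animal"] == ph.animal, "time_d"].to_numpy()
        if t.size and (t.min() < b0 or t.max() >= e1):
            raise ValueError(f"animal {ph.animal}: event outside recording span")
        n_base = int(np.sum((t >= b0) & (t < b1)))
        n_treat = int(np.sum((t >= b1) & (t < e1)))
        rate_base = n_base / (b1 - b0)
        rate_treat = n_treat / (e1 - b1)
        rows.append(
            {
                "animal": ph.animal,
                "group": ph.group,
                "n_baseline": n_base,
                "n_treatment": n_treat,
                "rate_baseline_per_day": rate_base,
                "rate_treatment_per_day": rate_treat,
                "classification": "fewer" if rate_treat < rate_base else "more_or_equal",
                "included": rate_base >= weekly_inclusion_rate,
            }
        )
    return CohortSummary(per_animal=pd.DataFrame(rows))


def cumulative_normalized(
    times_d: np.ndarray, treatment_start_d: float, baseline_start_d: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative seizure count over time divided by the baseline total.

    Returns (event times, normalized cumulative counts); an animal with equal
    baseline and treatment counts ends at 2.0.
    """
    t = np.sort(np.asarray(times_d, dtype=float))
    n_base = np.sum((t >= baseline_start_d) & (t < treatment_start_d))
    if n_base == 0:
        raise ValueError("no baseline seizures; normalized curve undefined")
    return t, np.arange(1, t.size + 1) / n_base
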