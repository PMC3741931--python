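"""Univariate descriptive layer: cross-tabulations, chi-square tests,
per-category survival percentages.

Each clinical attribute is cross-tabulated against a dichotomous outcome —
survival beyond 36 months, or the 5-year survivor flag — and compared with
a Pearson chi-square test of homogeneity (no continuity correction), the
standard choice for r x 2 tables of this size.  Categories with zero
patients are dropped before testing; expected cells below 5 raise a warning
in the result rather than switching test (no exact-test fallback).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CATEGORY_ORDER, MISSING

logger = logging.getLogger(__name__)

OUTCOME_LABELS = {
    "survived_gt36": {True: ">36", False: "<=36"},
    "five_year_survivor": {True: "yes", False: "no"},
}


@dataclass
class ContingencyTable:
    """Cross-tabulation of one attribute's categories against an outcome."""

    counts: pd.DataFrame  # rows: attribute categories; columns: outcome levels
    attribute: str
    outcome: str
    n_excluded: int

    @property
    def N(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def column_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class ChiSquareResult:
    statistic: float | None
    dof: int | None
    p_value: float | None
    status: str  # "ok" or an explanation of why no test was run
    warning: str | None = None


def _category_index(attribute: str, values: pd.Series) -> list:
    order = CATEGORY_ORDER.get(attribute)
    present = list(pd.unique(values))
    if order is None:
        return sorted(map(str, present))
    ordered = [c for c in order if c in present]
    return ordered + sorted(str(c) for c in present if c not in order)


def contingency(
    cohort: pd.DataFrame, attribute: str, outcome: str = "survived_gt36"
) -> ContingencyTable:
    """Cross-tabulate ``attribute`` against a dichotomous outcome column.

    Records missing either variable are excluded (and the count logged);
    the remaining counts partition the retained records.
    """
    if attribute not in cohort.columns:
        raise KeyError(f"attribute not in cohort table: {attribute!r}")
    if outcome not in OUTCOME_LABELS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_LABELS)}")
    sub = cohort[[attribute, outcome]]
    keep = (
        sub.notna().all(axis=1)
        & (sub[attribute].astype(object) != MISSING)
        & (sub[outcome].astype(object) != MISSING)
    )
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "contingency(%s, %s): excluded %d records with missing values",
            attribute, outcome, n_excluded,
        )
    sub = sub[keep]
    labels = OUTCOME_LABELS[outcome]
    out_col = sub[outcome].map(labels)
    table = pd.crosstab(sub[attribute].astype(str), out_col)
    table = table.reindex(
        index=_category_index(attribute, sub[attribute].astype(str)),
        columns=[labels[True], labels[False]],
        fill_value=0,
    )
    return ContingencyTable(
        counts=table, attribute=attribute, outcome=outcome, n_excluded=n_excluded
    )


def chi_square(table: ContingencyTable | pd.DataFrame | np.ndarray) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity, without continuity correction.

    All-zero rows and columns are dropped first (they carry no information
    and would make expected counts degenerate).  A table reduced to fewer
    than two rows or columns yields a no-test result with an explanatory
    status instead of an error.
    """
    if isinstance(table, ContingencyTable):
        obs = table.counts.to_numpy(dtype=float)
    elif isinstance(table, pd.DataFrame):
        obs = table.to_numpy(dtype=float)
    else:
        obs = np.asarray(table, dtype=float)
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        return ChiSquareResult(
            statistic=None, dof=None, p_value=None,
            status="degenerate table: fewer than 2 non-empty rows or columns",
        )
    result = sps.chi2_contingency(obs, correction=False)
    warning = None
    if (result.expected_freq < 5).any():
        n_small = int((result.expected_freq < 5).sum())
        warning = f"{n_small} cells have expected count < 5; chi-square approximation may be poor"
    return ChiSquareResult(
        statistic=float(result.statistic),
        dof=int(result.dof),
        p_value=float(result.pvalue),
        status="ok",
        warning=warning,
    )


def survival_rate(cohort: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Five-year survival percentage per category of ``attribute``.

    Only records with a known 5-year survivor flag contribute.  Returns a
    DataFrame with survivor and total counts and the percentage rounded to
    one decimal for display; empty categories report NA.
    """
    table = contingency(cohort, attribute, outcome="five_year_survivor")
    survivors = table.counts["yes"]
    totals = table.row_margins
    pct = 100.0 * survivors / totals.where(totals > 0)
    return pd.DataFrame(
        {
            "survivors": survivors,
            "total": totals,
            "percent": pct.round(1),
        }
    )


#: Attributes reported in the standard cohort summary.
REPORT_ATTRIBUTES = (
    "age_group",
    "primary_site",
    "laterality",
    "grade",
    "nodes_group",
    "clinical_stage_group",
    "pathologic_stage_group",
    "clinical_size_group",
    "pathology_size_group",
    "op_group",
)


def univariate_report(
    cohort: pd.DataFrame, attributes: tuple[str, ...] = REPORT_ATTRIBUTES
) -> pd.DataFrame:
    """Cohort summary: per attribute, the category counts split by the
    36-month dichotomy with its chi-square P, and the 5-year survival
    percentages with theirs.

    The per-attribute P values are repeated on each of the attribute's
    category rows for a flat, machine-readable table.
    """
    blocks = []
    for attr in attributes:
        t36 = contingency(cohort, attr, "survived_gt36")
        p36 = chi_square(t36).p_value
        rates = survival_rate(cohort, attr)
        p5 = chi_square(contingency(cohort, attr, "five_year_survivor")).p_value
        block = pd.DataFrame(
            {
                "attribute": attr,
                "category": t36.counts.index,
                "total": t36.row_margins.to_numpy(),
                "gt36": t36.counts[">36"].to_numpy(),
                "le36": t36.counts["<=36"].to_numpy(),
                "p_gt36": p36,
                "five_year_pct": rates["percent"].reindex(t36.counts.index).to_numpy(),
                "p_five_year": p5,
            }
        )
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
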