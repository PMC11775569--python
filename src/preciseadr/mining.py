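"""Demographic ADR signal mining on adverse-event reports.

The pipeline screens report-level contingency tables for ADRs whose
reporting frequency differs across demographic strata: quality control
(reputable reporters, complete demographics), drug-interference
filtering (keep only reports plausibly describing drug events), then
per-ADR Pearson chi-square tests with Benjamini-Hochberg FDR control.

An ADR is flagged significant only when the adjusted p-value clears the
FDR level, every expected cell count is at least ``min_expected``, and
an effect-size floor is met (|log OR| >= log(min_odds_ratio) for 2x2
tables; for multi-stratum tables, the largest one-vs-rest |log OR|).
This is a screening statistic in the spirit of routine pharmacovigilance
disproportionality practice, not a causal analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import AdverseEventReport
from .simulate import AGE_BINS

__all__ = ["AssociationRecord", "quality_control", "drug_interference_filter",
           "mine_gender_associations", "mine_age_associations",
           "summarize_signals"]

logger = logging.getLogger(__name__)

#: reporter qualifications treated as health professionals
HEALTH_PROFESSIONALS = frozenset({1, 2, 3})
DEFAULT_AGE_BINS = AGE_BINS  # child < 18, adult 18-64, elderly >= 65


@dataclass(frozen=True)
class AssociationRecord:
    """Per-ADR stratified contingency test result."""

    adr_id: str
    attribute: str                 # "gender" or "age"
    contingency: np.ndarray        # (strata, 2): [with ADR, without ADR]
    odds_ratio: float | None       # defined only for 2x2 (two occupied strata)
    chi2: float
    dof: int
    p: float
    q: float
    significant: bool


def quality_control(reports: Sequence[AdverseEventReport],
                    allowed_qualifications: frozenset[int] = HEALTH_PROFESSIONALS
                    ) -> list[AdverseEventReport]:
    """Keep reports from allowed reporter qualifications with complete
    age and sex; order preserved. May return an empty list."""
    return [r for r in reports
            if r.qualification in allowed_qualifications and r.has_demographics]


def drug_interference_filter(reports: Sequence[AdverseEventReport]
                             ) -> list[AdverseEventReport]:
    """Keep reports that plausibly describe drug events: at least one
    drug, at least one ADR, and an ADR set that does not merely restate
    an indication (no overlap between ADR IDs and disease IDs)."""
    return [r for r in reports
            if r.drugs and r.adrs and not (r.adrs & r.diseases)]


def _log_or_floor(table: np.ndarray) -> float:
    """Largest one-stratum-vs-rest |log OR| (Haldane 0.5 correction)."""
    best = 0.0
    total = table.sum(axis=0)
    for row in table:
        rest = total - row
        a, b = row + 0.5
        c, d = rest + 0.5
        best = max(best, abs(np.log((a * d) / (b * c))))
    return best


def _mine(reports: Sequence[AdverseEventReport], attribute: str,
          stratum_of, n_strata: int, alpha: float, min_count: int,
          min_expected: float, min_odds_ratio: float
          ) -> list[AssociationRecord]:
    strata = np.array([stratum_of(r) for r in reports], dtype=np.intp)
    counts = np.bincount(strata, minlength=n_strata)

    adr_universe = sorted({a for r in reports for a in r.adrs})
    tested: list[tuple[str, np.ndarray, float, int, float, float | None]] = []
    n_below_min = 0
    for adr in adr_universe:
        has = np.array([adr in r.adrs for r in reports])
        if has.sum() < min_count:
            n_below_min += 1
            continue
        with_adr = np.bincount(strata[has], minlength=n_strata)
        table = np.stack([with_adr, counts - with_adr], axis=1)
        occupied = table.sum(axis=1) > 0
        if occupied.sum() < 2 or (table.sum(axis=0) == 0).any():
            logger.info("skipping ADR %s (%s): degenerate table", adr, attribute)
            continue
        sub = table[occupied]
        chi2, p, dof, _ = stats.chi2_contingency(sub, correction=False)
        odds = None
        if sub.shape == (2, 2):
            a, b = sub[0] + 0.5
            c, d = sub[1] + 0.5
            odds = float((a * d) / (b * c))
        tested.append((adr, table, float(chi2), int(dof), float(p), odds))
    logger.info("%s mining: %d ADRs in universe, %d below min_count=%d, "
                "%d tested", attribute, len(adr_universe), n_below_min,
                min_count, len(tested))

    if not tested:
        return []
    pvals = np.array([t[4] for t in tested])
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    qvals = np.maximum(qvals, pvals)  # q >= p elementwise

    records = []
    for (adr, table, chi2, dof, p, odds), q in zip(tested, qvals):
        occupied = table.sum(axis=1) > 0
        sub = table[occupied]
        expected = stats.contingency.expected_freq(sub)
        effect_ok = _log_or_floor(sub) >= np.log(min_odds_ratio)
        sig = bool(q <= alpha and expected.min() >= min_expected and effect_ok)
        records.append(AssociationRecord(
            adr_id=adr, attribute=attribute, contingency=table,
            odds_ratio=odds, chi2=chi2, dof=dof, p=p, q=float(q),
            significant=sig))
    records.sort(key=lambda r: (r.q, r.p, r.adr_id))
    return records


def mine_gender_associations(reports: Sequence[AdverseEventReport],
                             alpha: float = 0.05, min_count: int = 100,
                             min_expected: float = 5.0,
                             min_odds_ratio: float = 1.5
                             ) -> list[AssociationRecord]:
    """Flag ADRs whose report frequency differs by sex.

    Per ADR occurring >= ``min_count`` times, a 2x2 (sex x present/absent)
    table is tested with Pearson chi-square (no continuity correction);
    p-values are BH-adjusted across all tested ADRs. Rows of the stored
    table are [male, female].
    """
    return _mine(reports, "gender", lambda r: r.sex - 1, 2,
                 alpha, min_count, min_expected, min_odds_ratio)


def mine_age_associations(reports: Sequence[AdverseEventReport],
                          bins: tuple[int, ...] = DEFAULT_AGE_BINS,
                          alpha: float = 0.05, min_count: int = 100,
                          min_expected: float = 5.0,
                          min_odds_ratio: float = 1.5
                          ) -> list[AssociationRecord]:
    """Flag ADRs whose report frequency differs across age strata
    (default child < 18, adult 18-64, elderly >= 65); chi-square test of
    homogeneity with dof = occupied strata - 1; BH across tested ADRs."""
    n_strata = len(bins) + 1
    return _mine(reports, "age", lambda r: int(np.digitize(r.age, bins)),
                 n_strata, alpha, min_count, min_expected, min_odds_ratio)


def summarize_signals(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Counts of tested and flagged ADRs per attribute, TSV-writable."""
    rows = []
    for attribute in sorted({r.attribute for r in records}):
        sub = [r for r in records if r.attribute == attribute]
        rows.append({"attribute": attribute, "tested": len(sub),
                     "flagged": sum(r.significant for r in sub)})
    if not rows:
        rows = [{"attribute": "none", "tested": 0, "flagged": 0}]
    return pd.DataFrame(rows, columns=["attribute", "tested", "flagged"])


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Flatten association records to a long-format table."""
    rows = []
    for r in records:
        rows.append({
            "adr_id": r.adr_id, "attribute": r.attribute,
            "contingency": ";".join(",".join(map(str, row))
                                    for row in r.contingency),
            "odds_ratio": "" if r.odds_ratio is None else r.odds_ratio,
            "chi2": r.chi2, "dof": r.dof, "p": r.p, "q": r.q,
            "significant": int(r.significant),
        })
    return pd.DataFrame(rows, columns=["adr_id", "attribute", "contingency",
                                       "odds_ratio", "chi2", "dof", "p", "q",
                                       "significant"])
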