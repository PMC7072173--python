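"""Exact 2x2 association testing, written from first principles.

The two-sided Fisher exact p-value is defined by the probability method:
conditioning on both margins, sum the hypergeometric probabilities of
every table whose probability does not exceed that of the observed table
(with a small relative tolerance for the comparison, since equally
probable tables arise from symmetric margins).  Factorials are evaluated
in log space so tables with totals up to ~1e6 are handled without
overflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_cbio import Cohort
from .pairing import AlignedCoupleSet

logger = logging.getLogger(__name__)

#: Relative tolerance for the "probability <= observed" comparison.
PROB_RTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d; rows one binary variable, columns the other."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("table total must be >= 1")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _log_hypergeom_pmf(ks: np.ndarray, r1: int, r2: int, c1: int) -> np.ndarray:
    """log P(A = k | margins) for the table's top-left cell."""
    n = r1 + r2
    return (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )


def fisher_exact(table: ContingencyTable2x2 | tuple[int, int, int, int]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    A table with any zero margin carries no information about association;
    by convention its p-value is 1 (logged).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    r1, r2, c1, _ = table.margins
    if 0 in table.margins:
        logger.debug("fisher_exact: zero margin in %s; p = 1 by convention", table)
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(ks, r1, r2, c1)
    # normalize in log space for numerical stability at extreme margins
    logp -= np.logaddexp.reduce(logp)
    p = np.exp(logp)
    p_obs = p[ks == table.a][0]
    p_value = float(p[p <= p_obs * (1.0 + PROB_RTOL)].sum())
    return min(1.0, max(p_value, np.nextafter(0.0, 1.0)))


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, bool]:
    """Sample odds ratio; 0.5 continuity correction when any cell is zero.

    Returns ``(odds_ratio, corrected?)``.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c), corrected


def couple_association(cohort: Cohort, aligned: AlignedCoupleSet) -> pd.DataFrame:
    """Fisher association between snoRNA and host alteration per couple.

    For every couple, samples are cross-classified by "snoRNA altered"
    (deep event, |code| = 2) and "host altered"; cells with a missing code
    for either member are excluded.  Raw p-values are Benjamini-Hochberg
    adjusted across all couples of the cohort.
    """
    if not aligned.couples:
        raise ValueError("empty couple set")
    samples = cohort.sample_ids
    codes = cohort.cna.codes[samples]
    sno = codes.loc[[c.snorna_id for c in aligned.couples]].to_numpy(dtype=float)
    host = codes.loc[[c.host_id for c in aligned.couples]].to_numpy(dtype=float)
    ok = ~np.isnan(sno) & ~np.isnan(host)
    s_alt = (np.abs(sno) == 2) & ok
    h_alt = (np.abs(host) == 2) & ok

    rows = []
    for i, couple in enumerate(aligned.couples):
        a = int((s_alt[i] & h_alt[i]).sum())
        b = int((s_alt[i] & ~h_alt[i] & ok[i]).sum())
        c = int((~s_alt[i] & h_alt[i] & ok[i]).sum())
        d = int((~s_alt[i] & ~h_alt[i] & ok[i]).sum())
        if a + b + c + d == 0:
            rows.append({
                "cohort": cohort.acronym, "label": couple.label,
                "snorna_id": couple.snorna_id, "host_id": couple.host_id,
                "a": 0, "b": 0, "c": 0, "d": 0,
                "odds_ratio": np.nan, "or_continuity_corrected": False,
                "p_raw": 1.0,
            })
            continue
        tab = ContingencyTable2x2(a, b, c, d)
        oratio, corrected = odds_ratio(tab)
        rows.append({
            "cohort": cohort.acronym, "label": couple.label,
            "snorna_id": couple.snorna_id, "host_id": couple.host_id,
            "a": a, "b": b, "c": c, "d": d,
            "odds_ratio": oratio, "or_continuity_corrected": corrected,
            "p_raw": fisher_exact(tab),
        })
    frame = pd.DataFrame(rows)
    frame["p_bh"] = multipletests(frame["p_raw"].to_numpy(), method="fdr_bh")[1]
    return frame
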