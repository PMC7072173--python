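"""Copy-number co-alteration statistics for snoRNA/host-gene couples.

A *CNA event* is restricted to the deep calls of the GISTIC encoding:
high-level amplification (+2) or homozygous deep deletion (-2).  Shallow
deletions (-1) and single-copy gains (+1) are not events.  Each
(couple, sample) cell is classified by which members carry an event:

* ``none``          — neither member altered
* ``snorna_only``   — only the snoRNA altered
* ``host_only``     — only the host gene altered
* ``co_occurring``  — both members altered (signs may or may not agree;
  concordance is recorded, not required)

The cohort-level *cumulative CNA frequency* is the number of altered
cells divided by couples x samples (missing cells excluded from both
numerator and denominator).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_cbio import Cohort, VALID_CNA_CODES
from .pairing import AlignedCoupleSet, CouplePair

EVENT_CLASSES = ("none", "snorna_only", "host_only", "co_occurring")

#: Couple-level co-occurrence classes within one cohort.
COUPLE_CLASSES = ("co_occurring", "altered_not_co_occurring", "absent")


def is_event(code: float | int | None) -> tuple[bool, str | None]:
    """Classify one GISTIC code as a deep CNA event.

    Returns ``(event?, sign)`` with sign ``"amp"`` for +2, ``"del"`` for -2,
    ``None`` otherwise.  A missing code (None/NaN) is not an event.
    """
    if code is None or (isinstance(code, float) and math.isnan(code)):
        return False, None
    code = int(code)
    if code not in VALID_CNA_CODES:
        raise ValueError(f"invalid GISTIC code {code}; allowed codes are -2..2")
    if code == 2:
        return True, "amp"
    if code == -2:
        return True, "del"
    return False, None


@dataclass(frozen=True)
class EventClass:
    """Classification of one (couple, sample) cell."""

    value: str                     # one of EVENT_CLASSES, or "missing"
    sign_snorna: str | None = None
    sign_host: str | None = None
    concordant: bool | None = None  # defined only for co_occurring cells


def classify_cell(snorna_code, host_code) -> EventClass:
    """Classify a cell from the two members' GISTIC codes.

    If either code is missing the whole cell is ``missing`` and excluded
    from every downstream count.
    """
    def _missing(c):
        return c is None or (isinstance(c, float) and math.isnan(c))

    if _missing(snorna_code) or _missing(host_code):
        # still validate the non-missing side
        for c in (snorna_code, host_code):
            if not _missing(c):
                is_event(c)
        return EventClass(value="missing")
    ev_s, sign_s = is_event(snorna_code)
    ev_h, sign_h = is_event(host_code)
    if ev_s and ev_h:
        return EventClass("co_occurring", sign_s, sign_h, concordant=sign_s == sign_h)
    if ev_s:
        return EventClass("snorna_only", sign_snorna=sign_s)
    if ev_h:
        return EventClass("host_only", sign_host=sign_h)
    return EventClass("none")


@dataclass
class CoalterationSummary:
    """All cell-level and couple-level CNA statistics for one cohort."""

    acronym: str
    n_samples: int
    n_couples: int
    cell_counts: dict[str, int]
    n_missing_cells: int
    #: gene-level event counts keyed by (context, sign); contexts are the
    #: three altered cell classes, signs are the member's own sign.  For
    #: co_occurring cells the snoRNA-side sign is counted here and the
    #: host-side sign in ``host_amp_del_counts``.
    amp_del_counts: dict[tuple[str, str], int]
    host_amp_del_counts: dict[tuple[str, str], int]
    n_concordant_co: int
    cumulative_frequency: float
    event_counting: str = "cell"
    #: per-couple table: n_nonmissing_samples, n_altered_samples,
    #: altered_fraction, couple_class, label
    per_couple: pd.DataFrame | None = None

    @property
    def per_sample_rates(self) -> dict[str, float]:
        return {k: v / self.n_samples for k, v in self.cell_counts.items()}

    @property
    def couple_class_counts(self) -> dict[str, int]:
        if self.per_couple is None:
            return {}
        counts = self.per_couple["couple_class"].value_counts()
        return {c: int(counts.get(c, 0)) for c in COUPLE_CLASSES}


def _code_arrays(cohort: Cohort, couples: list[CouplePair]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    samples = cohort.sample_ids
    codes = cohort.cna.codes[samples]
    sno = codes.loc[[c.snorna_id for c in couples]].to_numpy(dtype=float)
    host = codes.loc[[c.host_id for c in couples]].to_numpy(dtype=float)
    return sno, host, samples


def summarize_cohort(cohort: Cohort, aligned: AlignedCoupleSet,
                     event_counting: str = "cell") -> CoalterationSummary:
    """Count event classes over every (couple, sample) cell of one cohort.

    ``event_counting`` selects the numerator of the cumulative frequency:
    ``"cell"`` counts each altered cell once (the default; bounded by 1
    given the couples x samples denominator); ``"gene"`` counts each
    altered gene, so a co-occurring cell contributes two.
    """
    if event_counting not in ("cell", "gene"):
        raise ValueError(f"unknown event_counting mode {event_counting!r}")
    couples = aligned.couples
    if not couples:
        raise ValueError("empty couple set: no couples aligned to this cohort")
    sno, host, samples = _code_arrays(cohort, couples)
    n_couples, n_samples = sno.shape

    missing = np.isnan(sno) | np.isnan(host)
    ev_s = np.abs(sno) == 2          # NaN compares False
    ev_h = np.abs(host) == 2
    ev_s &= ~missing
    ev_h &= ~missing
    co = ev_s & ev_h
    s_only = ev_s & ~ev_h
    h_only = ev_h & ~ev_s
    none = ~missing & ~ev_s & ~ev_h

    cell_counts = {
        "none": int(none.sum()),
        "snorna_only": int(s_only.sum()),
        "host_only": int(h_only.sum()),
        "co_occurring": int(co.sum()),
    }
    n_missing = int(missing.sum())
    assert sum(cell_counts.values()) + n_missing == n_couples * n_samples

    amp_s, del_s = sno == 2, sno == -2
    amp_h, del_h = host == 2, host == -2
    amp_del = {
        ("snorna_only", "amp"): int((s_only & amp_s).sum()),
        ("snorna_only", "del"): int((s_only & del_s).sum()),
        ("host_only", "amp"): int((h_only & amp_h).sum()),
        ("host_only", "del"): int((h_only & del_h).sum()),
        ("co_occurring", "amp"): int((co & amp_s).sum()),
        ("co_occurring", "del"): int((co & del_s).sum()),
    }
    host_amp_del = {
        ("host_only", "amp"): amp_del[("host_only", "amp")],
        ("host_only", "del"): amp_del[("host_only", "del")],
        ("co_occurring", "amp"): int((co & amp_h).sum()),
        ("co_occurring", "del"): int((co & del_h).sum()),
    }
    n_concordant = int((co & ((amp_s & amp_h) | (del_s & del_h))).sum())

    denom = n_couples * n_samples - n_missing
    altered_cells = cell_counts["snorna_only"] + cell_counts["host_only"] + cell_counts["co_occurring"]
    numerator = altered_cells if event_counting == "cell" else altered_cells + cell_counts["co_occurring"]
    frequency = numerator / denom if denom else 0.0

    altered = co | s_only | h_only
    per_couple = pd.DataFrame({
        "snorna_id": [c.snorna_id for c in couples],
        "host_id": [c.host_id for c in couples],
        "label": [c.label for c in couples],
        "n_nonmissing_samples": (~missing).sum(axis=1).astype(int),
        "n_altered_samples": altered.sum(axis=1).astype(int),
        "n_co_occurring_samples": co.sum(axis=1).astype(int),
    })
    with np.errstate(invalid="ignore"):
        per_couple["altered_fraction"] = np.where(
            per_couple["n_nonmissing_samples"] > 0,
            per_couple["n_altered_samples"] / per_couple["n_nonmissing_samples"],
            0.0,
        )
    per_couple["couple_class"] = np.select(
        [per_couple["n_co_occurring_samples"] > 0, per_couple["n_altered_samples"] > 0],
        ["co_occurring", "altered_not_co_occurring"],
        default="absent",
    )

    return CoalterationSummary(
        acronym=cohort.acronym,
        n_samples=n_samples,
        n_couples=n_couples,
        cell_counts=cell_counts,
        n_missing_cells=n_missing,
        amp_del_counts=amp_del,
        host_amp_del_counts=host_amp_del,
        n_concordant_co=n_concordant,
        cumulative_frequency=frequency,
        event_counting=event_counting,
        per_couple=per_couple,
    )


@dataclass
class CoupleCrossCohort:
    couple: CouplePair
    altered_in: frozenset[str]
    category: str  # never | all | some | not_evaluable


def cross_cohort_categories(
    couples: Iterable[CouplePair],
    altered_flags: Mapping[tuple[str, str], Mapping[str, bool]],
) -> tuple[list[CoupleCrossCohort], dict[str, float]]:
    """Categorize each couple by the cohorts in which it is ever altered.

    ``altered_flags[couple.key][acronym]`` is True when the couple has at
    least one altered cell in that cohort; a cohort key is present only
    where the couple was evaluable (both members in the CNA matrix).
    Returns the per-couple records plus category percentages over the
    evaluable couples (summing to 100 up to rounding); couples evaluable
    in no cohort are categorized ``not_evaluable`` and excluded from the
    percentages.
    """
    records: list[CoupleCrossCohort] = []
    for couple in couples:
        flags = altered_flags.get(couple.key, {})
        evaluable = set(flags)
        altered_in = frozenset(a for a, f in flags.items() if f)
        if not evaluable:
            category = "not_evaluable"
        elif not altered_in:
            category = "never"
        elif altered_in == evaluable:
            category = "all"
        else:
            category = "some"
        records.append(CoupleCrossCohort(couple, altered_in, category))
    n_eval = sum(1 for r in records if r.category != "not_evaluable")
    percentages = {
        cat: (100.0 * sum(1 for r in records if r.category == cat) / n_eval
              if n_eval else float("nan"))
        for cat in ("never", "all", "some")
    }
    return records, percentages


def altered_flags_from_summaries(
    summaries: Iterable[CoalterationSummary],
) -> dict[tuple[str, str], dict[str, bool]]:
    """Collect per-couple per-cohort altered flags from cohort summaries."""
    flags: dict[tuple[str, str], dict[str, bool]] = {}
    for summary in summaries:
        pc = summary.per_couple
        for sno_id, host_id, n_alt in zip(pc["snorna_id"], pc["host_id"],
                                          pc["n_altered_samples"]):
            flags.setdefault((sno_id, host_id), {})[summary.acronym] = bool(n_alt > 0)
    return flags


def top_k_couples(summary: CoalterationSummary, k: int = 10) -> pd.DataFrame:
    """The k couples altered in the largest fraction of samples.

    Ties break deterministically: descending fraction, then ascending
    ``snorna_symbol/host_symbol`` label, then ascending snorna_id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pc = summary.per_couple.copy()
    pc = pc.sort_values(
        by=["altered_fraction", "label", "snorna_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    pc = pc.reset_index(drop=True)
    pc.insert(0, "rank", np.arange(1, len(pc) + 1))
    pc.insert(1, "cohort", summary.acronym)
    return pc
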