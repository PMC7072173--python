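"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over cells and exact
rational arithmetic, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction


def oracle_is_event(code):
    if code is None or (isinstance(code, float) and math.isnan(code)):
        return None  # missing
    return {2: "amp", -2: "del"}.get(int(code))


def oracle_classify(sno_code, host_code):
    """Cell class as (value, sign_sno, sign_host)."""
    s = oracle_is_event(sno_code) if not _miss(sno_code) else None
    h = oracle_is_event(host_code) if not _miss(host_code) else None
    if _miss(sno_code) or _miss(host_code):
        return ("missing", None, None)
    if s and h:
        return ("co_occurring", s, h)
    if s:
        return ("snorna_only", s, None)
    if h:
        return ("host_only", None, h)
    return ("none", None, None)


def _miss(code):
    return code is None or (isinstance(code, float) and math.isnan(code))


def oracle_summarize(sno_rows, host_rows):
    """Count cell classes and gene-level signs over couples x samples.

    ``sno_rows[i][j]`` / ``host_rows[i][j]`` are the codes of couple i in
    sample j (may be None/NaN).  Returns (cell_counts, n_missing,
    amp_del sno-side, amp_del host-side, per-couple altered sample counts,
    per-couple non-missing counts, per-couple co counts).
    """
    counts = {"none": 0, "snorna_only": 0, "host_only": 0, "co_occurring": 0}
    missing = 0
    amp_del = {(c, s): 0 for c in ("snorna_only", "host_only", "co_occurring")
               for s in ("amp", "del")}
    host_side = {(c, s): 0 for c in ("host_only", "co_occurring") for s in ("amp", "del")}
    n_couples = len(sno_rows)
    per_altered = [0] * n_couples
    per_nonmiss = [0] * n_couples
    per_co = [0] * n_couples
    for i in range(n_couples):
        for j in range(len(sno_rows[i])):
            value, s, h = oracle_classify(sno_rows[i][j], host_rows[i][j])
            if value == "missing":
                missing += 1
                continue
            counts[value] += 1
            per_nonmiss[i] += 1
            if value != "none":
                per_altered[i] += 1
            if value == "co_occurring":
                per_co[i] += 1
                amp_del[("co_occurring", s)] += 1
                host_side[("co_occurring", h)] += 1
            elif value == "snorna_only":
                amp_del[("snorna_only", s)] += 1
            elif value == "host_only":
                amp_del[("host_only", h)] += 1
                host_side[("host_only", h)] += 1
    return counts, missing, amp_del, host_side, per_altered, per_nonmiss, per_co


def oracle_cumulative_frequency(sno_rows, host_rows):
    counts, missing, *_ = oracle_summarize(sno_rows, host_rows)
    denom = sum(counts.values())
    altered = counts["snorna_only"] + counts["host_only"] + counts["co_occurring"]
    return altered / denom if denom else 0.0


def oracle_categories(flags_per_couple):
    """flags_per_couple: dict cohort -> bool (evaluable cohorts only)."""
    if not flags_per_couple:
        return "not_evaluable"
    altered = {a for a, f in flags_per_couple.items() if f}
    if not altered:
        return "never"
    if altered == set(flags_per_couple):
        return "all"
    return "some"


def oracle_top_k(fractions_labels_ids, k):
    """Full sort then slice; items are (fraction, label, snorna_id)."""
    ordered = sorted(fractions_labels_ids, key=lambda t: (-t[0], t[1], t[2]))
    return ordered[:k]


def oracle_fisher(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration with exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if 0 in (r1, r2, c1, b + d):
        return Fraction(1)
    denom = math.comb(n, c1)
    probs = {}
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[k] = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs)


def oracle_zscores(expr_rows, cna_rows, min_ref=3):
    """Per-gene diploid-reference standardization with explicit loops.

    Rows are aligned lists over the same samples; returns list of rows of
    z-values (None where undefined).
    """
    out = []
    for xs, codes in zip(expr_rows, cna_rows):
        ref = [x for x, c in zip(xs, codes)
               if not _miss(c) and int(c) == 0 and not _miss(x)]
        if len(ref) < min_ref:
            out.append([None] * len(xs))
            continue
        mu = sum(ref) / len(ref)
        var = sum((x - mu) ** 2 for x in ref) / (len(ref) - 1)
        if var == 0:
            out.append([None] * len(xs))
            continue
        sd = math.sqrt(var)
        out.append([(x - mu) / sd if not _miss(x) else None for x in xs])
    return out


def oracle_expression_rates(sno_calls, host_calls, n_samples):
    """Counts of up/down per member over all cells, divided by n_samples."""
    rates = {}
    for member, rows in (("snorna", sno_calls), ("host", host_calls)):
        for direction in ("up", "down"):
            count = sum(1 for row in rows for call in row if call == direction)
            rates[(member, direction)] = count / n_samples
    return rates
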