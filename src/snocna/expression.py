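"""Diploid-referenced expression Z-scores and expression-alteration calls.

For each gene, the reference population is the set of samples that are
copy-number diploid (GISTIC code 0) for that gene.  A sample's Z-score is
its expression minus the reference mean, over the reference standard
deviation (ddof=1).  A gene whose reference has fewer than ``min_ref``
samples, or zero spread, yields undefined scores.  A call is *up* when
z > 2 and *down* when z < -2 (strict inequalities).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_cbio import CnaMatrix, Cohort, ExprMatrix
from .pairing import AlignedCoupleSet

logger = logging.getLogger(__name__)

DEFAULT_UP_THRESHOLD = 2.0
DEFAULT_DOWN_THRESHOLD = -2.0
DEFAULT_MIN_REF = 3


@dataclass
class ZScoreMatrix:
    """Diploid-referenced Z-scores with per-gene reference bookkeeping."""

    z: pd.DataFrame                 # genes x samples, NaN where undefined
    reference_n: pd.Series          # per-gene diploid reference size
    undefined_genes: pd.Index       # genes with no valid reference

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)


def compute_z(expr: ExprMatrix, cna: CnaMatrix,
              min_ref: int = DEFAULT_MIN_REF) -> ZScoreMatrix:
    """Standardize each gene's expression against its diploid samples.

    Only genes and samples shared by the two matrices are scored.  Samples
    whose CNA code is missing are excluded from the reference even when
    expression exists.  Raises ``ValueError`` when the matrices share no
    samples or no genes.
    """
    genes = [g for g in expr.gene_ids if g in set(cna.gene_ids)]
    samples = [s for s in expr.sample_ids if s in set(cna.sample_ids)]
    if not samples:
        raise ValueError("expression and CNA matrices share no samples")
    if not genes:
        raise ValueError("expression and CNA matrices share no genes")

    x = expr.values.loc[genes, samples].to_numpy(dtype=float)
    codes = cna.codes.loc[genes, samples].to_numpy(dtype=float)
    ref_mask = (codes == 0) & ~np.isnan(x)

    ref_n = ref_mask.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x_ref = np.where(ref_mask, x, np.nan)
        mu = np.nanmean(x_ref, axis=1)
        sd = np.nanstd(x_ref, axis=1, ddof=1)
        z = (x - mu[:, None]) / sd[:, None]
    invalid = (ref_n < min_ref) | ~np.isfinite(sd) | (sd == 0)
    z[invalid, :] = np.nan

    z_frame = pd.DataFrame(z, index=pd.Index(genes, name="gene_id"), columns=samples)
    undefined = z_frame.index[invalid]
    if len(undefined):
        logger.warning("z-scores undefined for %d gene(s) (reference < %d or zero spread)",
                       len(undefined), min_ref)
    return ZScoreMatrix(
        z=z_frame,
        reference_n=pd.Series(ref_n, index=z_frame.index, name="reference_n"),
        undefined_genes=undefined,
    )


def classify_expression(zscores: ZScoreMatrix,
                        up: float = DEFAULT_UP_THRESHOLD,
                        down: float = DEFAULT_DOWN_THRESHOLD) -> pd.DataFrame:
    """Map Z-scores to calls in {up, down, normal, undefined}.

    The thresholds are strict: z exactly at a threshold is ``normal``.
    """
    z = zscores.z.to_numpy()
    calls = np.full(z.shape, "normal", dtype=object)
    calls[z > up] = "up"
    calls[z < down] = "down"
    calls[np.isnan(z)] = "undefined"
    return pd.DataFrame(calls, index=zscores.z.index, columns=zscores.z.columns)


def _member_calls(calls: pd.DataFrame, aligned: AlignedCoupleSet,
                  samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(couples x samples) call arrays for snoRNA and host members.

    Members absent from the call matrix are treated as undefined.
    """
    undef = pd.Series(["undefined"] * len(samples), index=samples)
    gene_set = set(calls.index)

    def row(gid: str) -> np.ndarray:
        if gid in gene_set:
            return calls.loc[gid, samples].to_numpy(dtype=object)
        return undef.to_numpy(dtype=object)

    sno = np.array([row(c.snorna_id) for c in aligned.couples], dtype=object)
    host = np.array([row(c.host_id) for c in aligned.couples], dtype=object)
    return sno, host


def expression_rates(calls: pd.DataFrame, aligned: AlignedCoupleSet,
                     cohort: Cohort) -> pd.DataFrame:
    """Per-sample up/down call rates, split by couple member.

    One row per (member, direction): the count of calls over all
    (couple, sample) cells, the per-sample rate (count / n_samples), and
    the number of undefined cells for that member.
    """
    if not aligned.couples:
        raise ValueError("empty couple set")
    samples = [s for s in cohort.sample_ids if s in set(calls.columns)]
    if not samples:
        raise ValueError("no cohort samples in the call matrix")
    sno, host = _member_calls(calls, aligned, samples)
    if (sno != "undefined").any():
        logger.warning("snoRNA expression rows present: abundances from small-RNA "
                       "enriched libraries can under-represent mid/large snoRNAs; "
                       "rates are reported as-is")
    n_samples = len(samples)
    rows = []
    for member, arr in (("snorna", sno), ("host", host)):
        n_undef = int((arr == "undefined").sum())
        for direction in ("up", "down"):
            count = int((arr == direction).sum())
            rows.append({
                "cohort": cohort.acronym, "member": member, "direction": direction,
                "n_events": count, "n_samples": n_samples,
                "rate_per_sample": count / n_samples, "n_undefined_cells": n_undef,
            })
    return pd.DataFrame(rows)


def top_k_upregulated(calls: pd.DataFrame, aligned: AlignedCoupleSet,
                      cohort: Cohort, k: int = 10) -> pd.DataFrame:
    """The k couples most frequently up-regulated across samples.

    A couple counts as up-regulated in a sample when *either* member is
    called up; which member(s) drove the call is recorded.  The fraction
    denominator is the number of samples where at least one member has a
    defined call.  Tie-break: descending fraction, ascending label,
    ascending snorna_id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not aligned.couples:
        raise ValueError("empty couple set")
    samples = [s for s in cohort.sample_ids if s in set(calls.columns)]
    sno, host = _member_calls(calls, aligned, samples)
    sno_up = sno == "up"
    host_up = host == "up"
    defined = (sno != "undefined") | (host != "undefined")
    up_any = sno_up | host_up

    n_eval = defined.sum(axis=1)
    n_up = up_any.sum(axis=1)
    n_sno = (sno_up & ~host_up).sum(axis=1)
    n_host = (host_up & ~sno_up).sum(axis=1)
    n_both = (sno_up & host_up).sum(axis=1)
    member_flag = np.select(
        [n_both > 0,
         (n_sno > 0) & (n_host > 0),
         n_sno > 0,
         n_host > 0],
        ["both", "mixed", "snorna_only", "host_only"],
        default="none",
    )
    with np.errstate(invalid="ignore"):
        fraction = np.where(n_eval > 0, n_up / np.maximum(n_eval, 1), 0.0)
    frame = pd.DataFrame({
        "cohort": cohort.acronym,
        "snorna_id": [c.snorna_id for c in aligned.couples],
        "host_id": [c.host_id for c in aligned.couples],
        "label": [c.label for c in aligned.couples],
        "n_evaluable_samples": n_eval.astype(int),
        "n_upregulated_samples": n_up.astype(int),
        "upregulated_fraction": fraction,
        "member": member_flag,
    })
    frame = frame.sort_values(
        by=["upregulated_fraction", "label", "snorna_id"],
        ascending=[False, True, True], kind="mergesort",
    ).head(k).reset_index(drop=True)
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    return frame


def cna_expression_concordance(calls: pd.DataFrame, aligned: AlignedCoupleSet,
                               cohort: Cohort, k: int = 10,
                               cna_top: pd.DataFrame | None = None,
                               expr_top: pd.DataFrame | None = None) -> dict:
    """Concordance between copy-number amplification and up-calls.

    Per couple, over both member genes: the fraction of amplified
    (gene, sample) cells that are also called up, and the fraction of
    up-called cells that are also amplified (NaN when the denominator is
    empty).  When the two top-k tables are supplied, their couple-label
    overlap is reported as well.
    """
    if not aligned.couples:
        raise ValueError("empty couple set")
    samples = [s for s in cohort.sample_ids if s in set(calls.columns)]
    codes = cohort.cna.codes[samples]
    sno_calls, host_calls = _member_calls(calls, aligned, samples)
    sno_codes = codes.loc[[c.snorna_id for c in aligned.couples]].to_numpy(dtype=float)
    host_codes = codes.loc[[c.host_id for c in aligned.couples]].to_numpy(dtype=float)

    rows = []
    for i, couple in enumerate(aligned.couples):
        amp = np.concatenate([sno_codes[i] == 2, host_codes[i] == 2])
        up = np.concatenate([sno_calls[i] == "up", host_calls[i] == "up"])
        defined = np.concatenate([sno_calls[i] != "undefined", host_calls[i] != "undefined"])
        amp, up = amp & defined, up & defined
        n_amp, n_up, n_amp_up = int(amp.sum()), int(up.sum()), int((amp & up).sum())
        rows.append({
            "cohort": cohort.acronym, "label": couple.label,
            "snorna_id": couple.snorna_id, "host_id": couple.host_id,
            "n_amplified_cells": n_amp, "n_up_cells": n_up,
            "n_amplified_and_up": n_amp_up,
            "frac_amplified_also_up": n_amp_up / n_amp if n_amp else np.nan,
            "frac_up_also_amplified": n_amp_up / n_up if n_up else np.nan,
        })
    table = pd.DataFrame(rows)
    result = {"per_couple": table}
    if cna_top is not None and expr_top is not None:
        cna_set = set(cna_top["label"])
        expr_set = set(expr_top["label"])
        overlap = cna_set & expr_set
        result["topk_overlap"] = {
            "k": k,
            "n_overlap": len(overlap),
            "overlap_labels": sorted(overlap),
            "jaccard": len(overlap) / len(cna_set | expr_set) if (cna_set | expr_set) else np.nan,
        }
    return result
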