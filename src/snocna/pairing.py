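"""snoRNA / host-gene couple table: construction, validation, alignment.

A *couple* is one intronic snoRNA paired with the gene whose intron hosts
it.  A snoRNA hosted by two genes, or a host containing several snoRNAs,
yields multiple independent couples (e.g. SNORD12, SNORD12B and SNORD12C
each pair separately with ZFAS1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io_cbio import Cohort, write_table

logger = logging.getLogger(__name__)

PAIRING_COLUMNS = ["snorna_id", "snorna_symbol", "host_id", "host_symbol",
                   "box_class", "host_biotype"]

VALID_BIOTYPES = frozenset({"protein_coding", "lncRNA"})
VALID_BOX_CLASSES = frozenset({"CD", "HACA", "other"})


@dataclass(frozen=True)
class CouplePair:
    """One snoRNA and its intronic host gene."""

    snorna_id: str
    host_id: str
    snorna_symbol: str = ""
    host_symbol: str = ""
    box_class: str = "other"     # CD | HACA | other
    host_biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if not self.snorna_id or not self.host_id:
            raise ValueError("couple ids must be non-empty")
        if self.snorna_id == self.host_id:
            raise ValueError(f"snoRNA and host share the id {self.snorna_id!r}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.snorna_id, self.host_id)

    @property
    def label(self) -> str:
        """Human-readable ``SNORNA/HOST`` label used in rankings."""
        sno = self.snorna_symbol or self.snorna_id
        host = self.host_symbol or self.host_id
        return f"{sno}/{host}"


@dataclass
class AlignedCoupleSet:
    """Couples split into those present in a cohort's matrices and those not."""

    couples: list[CouplePair]
    dropped: list[tuple[CouplePair, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.couples)


def _norm(value: object) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    return str(value).strip()


def build_couples(records: Iterable[Mapping] | pd.DataFrame) -> list[CouplePair]:
    """Build the validated couple list from raw pairing rows.

    Rows missing either Ensembl-style id are excluded (the inclusion
    criterion requires both), as are rows whose host biotype is neither
    protein-coding nor lncRNA; exclusions are logged with a reason.
    Couples are de-duplicated on (snorna_id, host_id), keeping the first.
    Raises ``ValueError`` if no valid couple remains.
    """
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    couples: list[CouplePair] = []
    seen: set[tuple[str, str]] = set()
    for row in records:
        sno_id, host_id = _norm(row.get("snorna_id")), _norm(row.get("host_id"))
        if not sno_id or not host_id:
            logger.info("pairing: excluding row %r: missing ensembl id", row)
            continue
        biotype = _norm(row.get("host_biotype")) or "protein_coding"
        if biotype not in VALID_BIOTYPES:
            logger.info("pairing: excluding %s/%s: host_biotype %r not allowed",
                        sno_id, host_id, biotype)
            continue
        box = _norm(row.get("box_class"))
        if box not in VALID_BOX_CLASSES:
            box = "other"
        if (sno_id, host_id) in seen:
            logger.info("pairing: duplicate couple %s/%s dropped", sno_id, host_id)
            continue
        if sno_id == host_id:
            logger.info("pairing: excluding %s: snoRNA id equals host id", sno_id)
            continue
        seen.add((sno_id, host_id))
        couples.append(CouplePair(
            snorna_id=sno_id, host_id=host_id,
            snorna_symbol=_norm(row.get("snorna_symbol")),
            host_symbol=_norm(row.get("host_symbol")),
            box_class=box, host_biotype=biotype,
        ))
    if not couples:
        raise ValueError("no valid couples")
    return couples


def align_couples(couples: Iterable[CouplePair], cohort: Cohort) -> AlignedCoupleSet:
    """Split couples by presence of both members in the cohort's CNA matrix.

    Retained couples keep their input order; each dropped couple carries a
    reason naming the absent member.  Conservation holds:
    ``len(retained) + len(dropped) == len(input)``.
    """
    genes = set(cohort.cna.gene_ids)
    retained: list[CouplePair] = []
    dropped: list[tuple[CouplePair, str]] = []
    for couple in couples:
        if couple.snorna_id not in genes:
            dropped.append((couple, "snorna_id not in CNA matrix"))
        elif couple.host_id not in genes:
            dropped.append((couple, "host_id not in CNA matrix"))
        else:
            retained.append(couple)
    for couple, reason in dropped:
        logger.warning("align[%s]: dropped %s: %s", cohort.acronym, couple.label, reason)
    return AlignedCoupleSet(couples=retained, dropped=dropped)


def couples_to_frame(couples: Iterable[CouplePair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(p, c) for c in PAIRING_COLUMNS} for p in couples],
        columns=PAIRING_COLUMNS,
    )


def read_pairing_table(path: str | Path) -> list[CouplePair]:
    """Read a pairing TSV (columns per :data:`PAIRING_COLUMNS`) into couples."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("snorna_id", "host_id") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: pairing table missing columns {missing}")
    return build_couples(frame)


def write_pairing_table(couples: Iterable[CouplePair], path: str | Path) -> None:
    write_table(couples_to_frame(couples), path, schema=PAIRING_COLUMNS)


def write_dropped_report(aligned: AlignedCoupleSet, path: str | Path) -> None:
    rows = pd.DataFrame(
        [{"snorna_id": c.snorna_id, "host_id": c.host_id, "couple": c.label,
          "reason": reason} for c, reason in aligned.dropped],
        columns=["snorna_id", "host_id", "couple", "reason"],
    )
    write_table(rows, path)
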