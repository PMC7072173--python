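"""Seeded multi-cohort simulator of couple-structured CNA and expression data.

The generator emulates the statistical structure a pan-cancer
snoRNA/host-gene co-alteration study measures, without any download:

* **Couple classes.**  A fraction of couples never acquires deep CNA in
  any cohort (``frac_never``), a fraction can be altered in every cohort
  (``frac_all``), and the remainder is active only in a random proper
  subset of cohorts — reproducing the never / all / some partition a
  cross-cohort analysis recovers.
* **Joint alteration.**  In an active (couple, cohort), each sample
  carries an alteration with probability ``p_alt``; given an alteration,
  both members are hit with probability ``p_co``, otherwise a single
  member chosen by ``p_sno_given_single``.  Event signs are amplification
  with probability ``p_amp`` (else deep deletion); co-occurring events
  share the sign with probability ``p_sign_concord``.
* **Nuisance codes.**  Otherwise-diploid gene cells become shallow
  (+/-1) at rate ``p_shallow``; these are not events and must be ignored
  downstream.  Cells go missing at rate ``p_missing``.
* **Expression.**  Per-gene log-normal baseline, multiplied by ``f_amp``
  under amplification and ``f_del`` under deep deletion, with
  multiplicative log-normal noise — non-negative, right-skewed,
  dosage-coupled abundances.

The same seed always produces bit-identical matrices, and the returned
truth record is re-counted from the emitted matrices before returning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .io_cbio import CnaMatrix, Cohort, ExprMatrix
from .pairing import CouplePair

#: Cohort acronyms and sample counts of a ten-cancer pan-TCGA-like design.
DEFAULT_COHORTS: dict[str, int] = {
    "HNSC": 496, "KIRC": 354, "BRCA": 1070, "COAD": 592, "LUSC": 487,
    "SKCM": 367, "LUAD": 511, "UCEC": 509, "OV": 398, "GBM": 575,
}

#: Per-cohort alteration regimes: OV-like series carry the highest burden,
#: KIRC and GBM the lowest; KIRC is strongly co-occurring, BRCA weakly.
DEFAULT_COHORT_OVERRIDES: dict[str, dict[str, float]] = {
    "OV": {"p_alt": 0.040},
    "LUSC": {"p_alt": 0.030},
    "BRCA": {"p_alt": 0.025, "p_co": 0.30},
    "HNSC": {"p_alt": 0.022},
    "LUAD": {"p_alt": 0.020},
    "KIRC": {"p_alt": 0.006, "p_co": 0.75},
    "GBM": {"p_alt": 0.008},
}

EVENT_KEYS = ("none", "snorna_only", "host_only", "co_occurring")


@dataclass(frozen=True)
class GeneratorParams:
    """Full parameterization of one simulated multi-cohort study."""

    n_couples: int = 295
    cohorts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORTS))
    p_alt: float = 0.02          # per-(couple,sample) alteration probability
    p_co: float = 0.5            # both members hit, given an alteration
    p_sno_given_single: float = 0.5
    p_amp: float = 0.7           # amplification vs deep deletion
    p_sign_concord: float = 0.95
    p_shallow: float = 0.10      # spurious +/-1 on otherwise diploid gene cells
    p_missing: float = 0.0
    frac_never: float = 0.39     # couples never altered anywhere
    frac_all: float = 0.10       # couples active in every cohort
    expr_log_loc: float = 3.0    # per-gene baseline, natural-log scale
    expr_log_scale: float = 1.0
    f_amp: float = 4.0           # dosage multiplier under amplification
    f_del: float = 0.25          # dosage multiplier under deep deletion
    noise_sd: float = 0.5        # multiplicative noise, natural-log scale
    per_cohort: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_alt": self.p_alt, "p_co": self.p_co,
            "p_sno_given_single": self.p_sno_given_single,
            "p_amp": self.p_amp, "p_sign_concord": self.p_sign_concord,
            "p_shallow": self.p_shallow, "p_missing": self.p_missing,
            "frac_never": self.frac_never, "frac_all": self.frac_all,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.frac_never + self.frac_all > 1.0:
            raise ValueError("frac_never + frac_all must not exceed 1")
        # f_amp == 1 is allowed as the no-dosage-effect null
        if not (0.0 <= self.f_del < 1.0 <= self.f_amp):
            raise ValueError("dosage multipliers must satisfy 0 <= f_del < 1 <= f_amp")
        if self.n_couples < 1 or any(n < 1 for n in self.cohorts.values()):
            raise ValueError("n_couples and every cohort size must be >= 1")
        if self.noise_sd < 0 or self.expr_log_scale < 0:
            raise ValueError("scales must be non-negative")
        for acronym in self.per_cohort:
            if acronym not in self.cohorts:
                raise ValueError(f"per_cohort override for unknown cohort {acronym!r}")

    def for_cohort(self, acronym: str) -> "GeneratorParams":
        """Parameters with any per-cohort overrides applied."""
        overrides = dict(self.per_cohort.get(acronym, {}))
        return replace(self, per_cohort={}, **overrides) if overrides else self


@dataclass
class SyntheticTruth:
    """What the generator actually did, for recovery tests."""

    params: GeneratorParams
    couple_class: pd.Series                  # never | all | some, per couple label
    active_cohorts: dict[str, frozenset[str]]
    #: per (cohort, couple) realized counts of each cell event class
    cell_counts: pd.DataFrame
    #: per cohort realized gene-level sign counts keyed (context, sign)
    sign_counts: dict[str, dict[tuple[str, str], int]]
    gene_baseline: pd.Series                 # per-gene log-scale location

    def cohort_totals(self, acronym: str) -> dict[str, int]:
        sub = self.cell_counts[self.cell_counts["cohort"] == acronym]
        return {k: int(sub[k].sum()) for k in EVENT_KEYS + ("missing",)}


@dataclass
class SimulationResult:
    couples: list[CouplePair]
    cohorts: list[Cohort]
    truth: SyntheticTruth

    @property
    def pairing_frame(self) -> pd.DataFrame:
        from .pairing import couples_to_frame
        return couples_to_frame(self.couples)


def _make_couples(n: int) -> list[CouplePair]:
    couples = []
    for i in range(n):
        box = "CD" if i % 2 == 0 else "HACA"
        prefix = "SNORD" if box == "CD" else "SNORA"
        biotype = "lncRNA" if i % 10 == 7 else "protein_coding"
        couples.append(CouplePair(
            snorna_id=f"ENSG{7_0000_0000 + i:011d}",
            host_id=f"ENSG{1_0000_0000 + i:011d}",
            snorna_symbol=f"{prefix}{i + 1}S",
            host_symbol=f"HG{i + 1}",
            box_class=box,
            host_biotype=biotype,
        ))
    return couples


def generate(params: GeneratorParams) -> SimulationResult:
    """Generate pairing, cohorts and truth from one parameter set.

    Deterministic in ``params.rng_seed``; invalid parameters raise before
    any generation.  The truth record is verified against the emitted
    matrices by an internal recount.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    couples = _make_couples(params.n_couples)
    gene_ids = [c.snorna_id for c in couples] + [c.host_id for c in couples]
    gene_symbols = pd.Series(
        [c.snorna_symbol for c in couples] + [c.host_symbol for c in couples],
        index=pd.Index(gene_ids, name="gene_id"),
    )
    n = params.n_couples
    acronyms = list(params.cohorts)

    # couple classes: never / all / some, with "some" couples active in a
    # random non-empty proper subset of cohorts
    n_never = int(round(params.frac_never * n))
    n_all = int(round(params.frac_all * n))
    classes = np.array(["some"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_never]] = "never"
    classes[order[n_never:n_never + n_all]] = "all"
    active: dict[str, set[int]] = {a: set() for a in acronyms}
    active_per_couple: list[frozenset[str]] = []
    for i in range(n):
        if classes[i] == "never":
            chosen: list[str] = []
        elif classes[i] == "all":
            chosen = acronyms
        else:
            k = int(rng.integers(1, max(2, len(acronyms))))
            chosen = list(rng.choice(acronyms, size=min(k, len(acronyms) - 1) or 1,
                                     replace=False))
        active_per_couple.append(frozenset(chosen))
        for a in chosen:
            active[a].add(i)

    baseline = pd.Series(
        rng.normal(params.expr_log_loc, params.expr_log_scale, size=2 * n),
        index=gene_symbols.index, name="log_baseline",
    )

    cohorts: list[Cohort] = []
    count_rows = []
    sign_counts: dict[str, dict[tuple[str, str], int]] = {}
    for acronym in acronyms:
        cp = params.for_cohort(acronym)
        n_samples = int(params.cohorts[acronym])
        samples = [f"{acronym}-{j + 1:04d}" for j in range(n_samples)]

        sno_codes = np.zeros((n, n_samples), dtype=float)
        host_codes = np.zeros((n, n_samples), dtype=float)
        active_mask = np.zeros(n, dtype=bool)
        active_mask[list(active[acronym])] = True

        altered = (rng.random((n, n_samples)) < cp.p_alt) & active_mask[:, None]
        both = altered & (rng.random((n, n_samples)) < cp.p_co)
        single = altered & ~both
        single_sno = single & (rng.random((n, n_samples)) < cp.p_sno_given_single)
        single_host = single & ~single_sno

        sno_sign = np.where(rng.random((n, n_samples)) < cp.p_amp, 2.0, -2.0)
        concord = rng.random((n, n_samples)) < cp.p_sign_concord
        host_sign_co = np.where(concord, sno_sign, -sno_sign)
        host_sign_single = np.where(rng.random((n, n_samples)) < cp.p_amp, 2.0, -2.0)

        sno_codes[both | single_sno] = sno_sign[both | single_sno]
        host_codes[both] = host_sign_co[both]
        host_codes[single_host] = host_sign_single[single_host]

        # shallow +/-1 nuisance on diploid gene cells
        for codes in (sno_codes, host_codes):
            diploid = codes == 0
            shallow = diploid & (rng.random((n, n_samples)) < cp.p_shallow)
            codes[shallow] = np.where(rng.random((n, n_samples)) < 0.5, 1.0, -1.0)[shallow]

        if cp.p_missing > 0:
            for codes in (sno_codes, host_codes):
                codes[rng.random((n, n_samples)) < cp.p_missing] = np.nan

        code_frame = pd.DataFrame(
            np.vstack([sno_codes, host_codes]),
            index=gene_symbols.index, columns=samples,
        )
        cna = CnaMatrix(codes=code_frame, gene_symbols=gene_symbols.copy())

        mult = np.ones_like(code_frame.to_numpy())
        arr = code_frame.to_numpy()
        mult[arr == 2] = params.f_amp
        mult[arr == -2] = params.f_del
        noise = rng.normal(0.0, params.noise_sd, size=arr.shape)
        values = np.exp(baseline.to_numpy()[:, None] + noise) * mult
        expr = ExprMatrix(
            values=pd.DataFrame(values, index=gene_symbols.index, columns=samples),
            gene_symbols=gene_symbols.copy(),
        )
        cohorts.append(Cohort(acronym=acronym, cna=cna, expr=expr))

        # truth: recount event classes and signs from the emitted codes
        missing = np.isnan(sno_codes) | np.isnan(host_codes)
        ev_s = (np.abs(sno_codes) == 2) & ~missing
        ev_h = (np.abs(host_codes) == 2) & ~missing
        co = ev_s & ev_h
        s_only = ev_s & ~ev_h
        h_only = ev_h & ~ev_s
        for i, couple in enumerate(couples):
            count_rows.append({
                "cohort": acronym, "label": couple.label,
                "snorna_id": couple.snorna_id, "host_id": couple.host_id,
                "none": int((~missing[i] & ~ev_s[i] & ~ev_h[i]).sum()),
                "snorna_only": int(s_only[i].sum()),
                "host_only": int(h_only[i].sum()),
                "co_occurring": int(co[i].sum()),
                "missing": int(missing[i].sum()),
            })
        sign_counts[acronym] = {
            ("snorna_only", "amp"): int((s_only & (sno_codes == 2)).sum()),
            ("snorna_only", "del"): int((s_only & (sno_codes == -2)).sum()),
            ("host_only", "amp"): int((h_only & (host_codes == 2)).sum()),
            ("host_only", "del"): int((h_only & (host_codes == -2)).sum()),
            ("co_occurring", "amp"): int((co & (sno_codes == 2)).sum()),
            ("co_occurring", "del"): int((co & (sno_codes == -2)).sum()),
        }

    truth = SyntheticTruth(
        params=params,
        couple_class=pd.Series(classes, index=[c.label for c in couples], name="couple_class"),
        active_cohorts={c.label: a for c, a in zip(couples, active_per_couple)},
        cell_counts=pd.DataFrame(count_rows),
        sign_counts=sign_counts,
        gene_baseline=baseline,
    )
    result = SimulationResult(couples=couples, cohorts=cohorts, truth=truth)
    verify_truth(result)
    return result


def verify_truth(result: SimulationResult) -> None:
    """Recount the emitted matrices and compare with the truth record."""
    for cohort in result.cohorts:
        totals = result.truth.cohort_totals(cohort.acronym)
        n_cells = len(result.couples) * cohort.n_samples
        if sum(totals.values()) != n_cells:
            raise AssertionError(f"truth counts do not sum to cells in {cohort.acronym}")
        codes = cohort.cna.codes
        sno = codes.loc[[c.snorna_id for c in result.couples]].to_numpy()
        host = codes.loc[[c.host_id for c in result.couples]].to_numpy()
        missing = np.isnan(sno) | np.isnan(host)
        ev_s = (np.abs(sno) == 2) & ~missing
        ev_h = (np.abs(host) == 2) & ~missing
        recount = {
            "none": int((~missing & ~ev_s & ~ev_h).sum()),
            "snorna_only": int((ev_s & ~ev_h).sum()),
            "host_only": int((ev_h & ~ev_s).sum()),
            "co_occurring": int((ev_s & ev_h).sum()),
            "missing": int(missing.sum()),
        }
        if recount != totals:
            raise AssertionError(
                f"truth/matrix mismatch in {cohort.acronym}: {totals} vs {recount}")


_PRESETS: dict[str, GeneratorParams] = {
    # one full ten-cohort pan-cancer design
    "default": GeneratorParams(per_cohort=DEFAULT_COHORT_OVERRIDES),
    # strongly co-occurring, low-burden series (co ~= 3x single-gene cells)
    "kirc_like": GeneratorParams(cohorts={"KIRC": 354}, p_alt=0.006, p_co=0.75,
                                 frac_never=0.0, frac_all=1.0),
    # high-burden serous-ovarian-like series
    "ov_like": GeneratorParams(cohorts={"OV": 398}, p_alt=0.040, p_co=0.5,
                               frac_never=0.0, frac_all=1.0),
    # weakly coupled series: most alterations hit one member only
    "brca_like": GeneratorParams(cohorts={"BRCA": 1070}, p_alt=0.025, p_co=0.30,
                                 frac_never=0.0, frac_all=1.0),
}


def scenario_presets() -> dict[str, GeneratorParams]:
    """Documented named parameter sets covering the main cohort regimes."""
    return dict(_PRESETS)


def get_preset(name: str, seed: int | None = None) -> GeneratorParams:
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; valid presets: {sorted(_PRESETS)}")
    params = _PRESETS[name]
    return replace(params, rng_seed=seed) if seed is not None else params
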