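import numpy as np
import pandas as pd
import pytest

from snocna.io_cbio import CnaMatrix, Cohort, ExprMatrix
from snocna.pairing import AlignedCoupleSet, CouplePair


def make_couples(n: int) -> list[CouplePair]:
    return [
        CouplePair(
            snorna_id=f"SNO{i:04d}", host_id=f"HOST{i:04d}",
            snorna_symbol=f"SNORD{i}T", host_symbol=f"HG{i}",
            box_class="CD" if i % 2 == 0 else "HACA",
        )
        for i in range(n)
    ]


def make_cohort(sno_codes, host_codes, acronym="TST", couples=None,
                expr=None) -> tuple[Cohort, AlignedCoupleSet]:
    """Build a cohort + aligned couple set from (couples x samples) code arrays."""
    sno_codes = np.asarray(sno_codes, dtype=float)
    host_codes = np.asarray(host_codes, dtype=float)
    n, m = sno_codes.shape
    couples = couples or make_couples(n)
    samples = [f"{acronym}-{j}" for j in range(m)]
    gene_ids = [c.snorna_id for c in couples] + [c.host_id for c in couples]
    codes = pd.DataFrame(np.vstack([sno_codes, host_codes]),
                         index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    expr_matrix = None
    if expr is not None:
        expr_matrix = ExprMatrix(values=pd.DataFrame(
            np.asarray(expr, dtype=float), index=codes.index, columns=samples))
    cohort = Cohort(acronym=acronym, cna=CnaMatrix(codes=codes), expr=expr_matrix)
    return cohort, AlignedCoupleSet(couples=list(couples))


def random_codes(rng, n, m, p_missing=0.0):
    """Random valid GISTIC codes skewed toward diploid, optional missing cells."""
    codes = rng.choice([-2, -1, 0, 0, 0, 1, 2], size=(n, m)).astype(float)
    if p_missing:
        codes[rng.random((n, m)) < p_missing] = np.nan
    return codes


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def toy_cohort():
    """2 couples x 3 samples: one co-occurring, one host-only cell."""
    sno = [[2, 0, 0], [0, 0, 0]]
    host = [[2, 0, -2], [0, 1, 0]]
    return make_cohort(sno, host)
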