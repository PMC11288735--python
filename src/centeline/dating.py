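"""Insertion-age estimation from sequence divergence.

Because every new insertion is a copy of an existing element, the sequence
identity between a copy and its closest relative measures the time since the
copy was made: both lineages accumulate substitutions at rate ``mu``, so

    age = (1 - identity) / (2 * mu)            [years]

with the default mu = 1.3e-8 substitutions/bp/year.  No multiple-hit
correction is applied — identity maps linearly to time, which is accurate in
the recent-divergence regime these elements occupy (identity > ~0.84).  For
LTR retrotransposons the same formula applies to the identity of the two
LTRs, which are identical at insertion time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import edit_identity

DEFAULT_MU = 1.3e-8

#: Identity below which an estimated age is considered beyond the method's
#: reliable range (multiple hits and alignment noise dominate).
DETECTION_LIMIT_IDENTITY = 0.80


@dataclass
class AgeEstimate:
    element_id: str
    best_partner_id: str
    identity: float
    age_years: float


def age_from_identity(identity: float, mu: float = DEFAULT_MU) -> float:
    """Years since insertion given identity to the closest relative."""
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity {identity} outside [0,1]")
    if mu <= 0:
        raise ValueError("mu must be positive")
    return (1.0 - identity) / (2.0 * mu)


def identity_matrix(
    sequences: dict[str, str], mode: str = "exclude_terminal_gaps"
) -> pd.DataFrame:
    """Symmetric all-vs-all global-alignment identity matrix."""
    ids = list(sequences)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 elements")
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = edit_identity(sequences[ids[i]], sequences[ids[j]], mode=mode)
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


def highest_pairwise_identity(
    sequences: dict[str, str], mode: str = "exclude_terminal_gaps"
) -> pd.DataFrame:
    """Best-partner identity per element (columns element_id, best_partner_id, identity)."""
    mat = identity_matrix(sequences, mode=mode)
    ids = list(mat.index)
    rows = []
    for i, eid in enumerate(ids):
        col = mat.iloc[i].drop(labels=[eid])
        best = col.idxmax()
        rows.append(
            {"element_id": eid, "best_partner_id": best, "identity": float(col[best])}
        )
    return pd.DataFrame(rows)


def estimate_ages(
    sequences: dict[str, str],
    mu: float = DEFAULT_MU,
    mode: str = "exclude_terminal_gaps",
) -> list[AgeEstimate]:
    """Highest-pairwise-identity dating of every element in the set."""
    best = highest_pairwise_identity(sequences, mode=mode)
    return [
        AgeEstimate(
            element_id=r.element_id,
            best_partner_id=r.best_partner_id,
            identity=r.identity,
            age_years=age_from_identity(r.identity, mu),
        )
        for r in best.itertuples()
    ]


@dataclass
class LtrAge:
    identity: float
    age_years: float
    beyond_detection_limit: bool


def ltr_insertion_age(
    ltr5: str,
    ltr3: str,
    mu: float = DEFAULT_MU,
    detection_limit_identity: float = DETECTION_LIMIT_IDENTITY,
) -> LtrAge:
    """Insertion age of an LTR element from the divergence of its two LTRs.

    Identical LTRs date the insertion to (essentially) the present.  When
    the LTR identity falls below ``detection_limit_identity`` the estimate is
    flagged: at that divergence the pair may not even be homologous.
    """
    if not ltr5 or not ltr3:
        raise ValueError("empty LTR sequence")
    ident = edit_identity(ltr5, ltr3, mode="exclude_terminal_gaps")
    return LtrAge(
        identity=ident,
        age_years=age_from_identity(ident, mu),
        beyond_detection_limit=ident < detection_limit_identity,
    )


def age_spectrum(ages: list[float], bin_years: float = 1.0e5) -> pd.DataFrame:
    """Histogram of ages (columns bin_start, bin_end, count)."""
    if not ages:
        raise ValueError("no ages")
    if bin_years <= 0:
        raise ValueError("bin width must be positive")
    arr = np.asarray(ages, dtype=float)
    n_bins = int(np.floor(arr.max() / bin_years)) + 1
    counts, edges = np.histogram(arr, bins=n_bins, range=(0, n_bins * bin_years))
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )


def percent_below(ages: list[float], cutoff: float) -> int:
    """Percentage of ages strictly below a cutoff, rounded to the nearest integer."""
    if not ages:
        raise ValueError("no ages")
    frac = sum(1 for a in ages if a < cutoff) / len(ages)
    return int(round(100.0 * frac))
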