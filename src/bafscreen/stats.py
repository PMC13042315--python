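"""Exact r x 2 Fisher test and contamination-rate summaries across studies.

Given per-study counts of uncontaminated and contaminated genomes, the exact
test enumerates every table with the observed margins (compositions of the
contaminated-column total across studies, subject to row-total caps), computes
each table's multivariate hypergeometric probability in log space, and sums
the probabilities of tables no more probable than the observed one — the
probability-ordering two-sided criterion, matching R's ``fisher.test`` for
r x c tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["StudyTable", "fisher_exact_rx2", "rate_summary", "table_probabilities"]


@dataclass
class StudyTable:
    """Rows of (study id, uncontaminated count, contaminated count)."""

    rows: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("need at least 2 studies")
        for sid, u, c in self.rows:
            if u < 0 or c < 0 or u != int(u) or c != int(c):
                raise ValueError(f"counts must be non-negative integers ({sid})")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyTable":
        return cls(
            [
                (str(r.study), int(r.uncontaminated), int(r.contaminated))
                for r in df.itertuples()
            ]
        )

    def exclude(self, study: str) -> "StudyTable":
        rows = [r for r in self.rows if r[0] != study]
        if len(rows) == len(self.rows):
            raise KeyError(f"study {study!r} not in table")
        return StudyTable(rows)

    @property
    def totals(self) -> tuple[int, int]:
        return sum(r[1] for r in self.rows), sum(r[2] for r in self.rows)


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _compositions(total: int, caps: list[int]):
    """All ways to split `total` contaminated genomes across rows (capped)."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    for first in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - first, caps[1:]):
            yield (first,) + rest


def table_probabilities(table: StudyTable):
    """Log-probability of every margin-respecting table, plus the observed one.

    Returns (log_probs array, observed log_prob, number of tables).
    """
    obs = [c for _, _, c in table.rows]
    row_totals = [u + c for _, u, c in table.rows]
    K = sum(obs)
    N = sum(row_totals)
    log_denom = _log_binom(N, K)

    def logp(ks) -> float:
        return float(sum(_log_binom(n, k) for n, k in zip(row_totals, ks)) - log_denom)

    lps = np.array([logp(ks) for ks in _compositions(K, row_totals)])
    return lps, logp(obs), lps.size


def fisher_exact_rx2(table: StudyTable) -> float:
    """Two-sided exact p-value for homogeneity of rates across r studies.

    p = sum of probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (with a small relative
    tolerance so ties land in the rejection set). A zero contaminated-column
    total means the observed table is the only attainable one: p = 1.
    """
    _, K = table.totals
    if K == 0:
        return 1.0
    lps, lp_obs, _ = table_probabilities(table)
    keep = lps <= lp_obs + 1e-7  # relative tolerance on the log scale
    m = lps[keep].max()
    return float(np.exp(m) * np.exp(lps[keep] - m).sum())


def rate_summary(table: StudyTable) -> pd.DataFrame:
    """Per-study and pooled contamination percentages.

    The pooled row is labelled ``(all)``. Percentages are returned unrounded;
    round to the precision you report.
    """
    rows = []
    for sid, u, c in table.rows:
        n = u + c
        rows.append((sid, u, c, n, 100.0 * c / n if n else 0.0))
    U, C = table.totals
    n = U + C
    rows.append(("(all)", U, C, n, 100.0 * C / n if n else 0.0))
    return pd.DataFrame(
        rows, columns=["study", "uncontaminated", "contaminated", "n", "percent"]
    )
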