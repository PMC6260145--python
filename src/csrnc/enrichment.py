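"""Tissue-by-cluster enrichment with Fisher's exact test and BH correction.

For every tissue x cluster pair a 2x2 contingency table is built (samples in
the tissue and in the cluster, in the tissue but not the cluster, and so on)
and a two-sided Fisher's exact test is applied. Two-sided p-values follow the
point-probability rule: the sum of hypergeometric probabilities of all tables
with the observed margins whose probability does not exceed that of the
observed table (within relative tolerance 1e-7, the convention of standard
exact-test implementations). p-values are adjusted jointly across all tested
pairs with the Benjamini-Hochberg step-up procedure; pairs with q below the
FDR threshold (default 0.01) are called significantly enriched or depleted
according to the sample odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Relative slack when comparing point probabilities (ties under float error).
_REL_ERR = 1e-7


class EnrichmentError(ValueError):
    """Invalid enrichment input."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a = tissue & cluster, b = tissue only, c = cluster only,
    d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EnrichmentError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return np.inf if self.a * self.d > 0 else np.nan
        return (self.a * self.d) / (self.b * self.c)


@dataclass(frozen=True)
class EnrichmentConfig:
    fdr_threshold: float = 0.01
    alternative: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise EnrichmentError("fdr_threshold must be in (0, 1)")
        if self.alternative != "two-sided":
            raise EnrichmentError("only the two-sided alternative is supported")


@dataclass(frozen=True)
class EnrichmentRow:
    tissue: str
    cluster: str
    table: ContingencyTable
    odds_ratio: float
    p: float
    q: float
    significant: bool
    direction: str  # enriched | depleted


def fisher_two_sided(t: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher's exact p and the sample odds ratio ad/bc.

    Degenerate margins (an empty row or column) give p = 1.
    """
    r1, c1, n = t.a + t.b, t.a + t.c, t.n
    if n == 0 or r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0, t.odds_ratio
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    logpmf = hypergeom.logpmf(support, n, r1, c1)
    log_obs = hypergeom.logpmf(t.a, n, r1, c1)
    include = logpmf <= log_obs + np.log1p(_REL_ERR)
    p = float(np.exp(logpmf[include]).sum())
    return min(p, 1.0), t.odds_ratio


def build_tables(assignments: pd.Series, metadata: pd.DataFrame) -> pd.DataFrame:
    """One contingency table per tissue x cluster pair.

    ``assignments`` maps sample_id -> cluster label; ``metadata`` must carry a
    ``tissue`` column indexed (or keyed by a ``sample_id`` column) by sample.
    Samples missing a tissue label are listed in a warning and excluded.
    """
    meta = metadata
    if "sample_id" in meta.columns:
        meta = meta.set_index("sample_id")
    if "tissue" not in meta.columns:
        raise EnrichmentError("metadata must have a 'tissue' column")
    tissue = meta["tissue"].reindex(assignments.index)
    missing = list(assignments.index[tissue.isna()])
    if missing:
        logger.warning(
            "%d sample(s) missing a tissue label excluded: %s",
            len(missing), missing[:5],
        )
    keep = ~tissue.isna()
    df = pd.DataFrame({"tissue": tissue[keep], "cluster": assignments[keep]})
    n = len(df)
    counts = df.groupby(["tissue", "cluster"], observed=True).size()
    tissue_tot = df.groupby("tissue", observed=True).size()
    cluster_tot = df.groupby("cluster", observed=True).size()
    rows = []
    for t in sorted(tissue_tot.index):
        for z in sorted(cluster_tot.index):
            a = int(counts.get((t, z), 0))
            b = int(tissue_tot[t] - a)
            c = int(cluster_tot[z] - a)
            d = int(n - a - b - c)
            rows.append({"tissue": t, "cluster": z, "a": a, "b": b, "c": c, "d": d})
    return pd.DataFrame(rows)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    assignments: pd.Series,
    metadata: pd.DataFrame,
    config: EnrichmentConfig = EnrichmentConfig(),
) -> pd.DataFrame:
    """Full enrichment scan: tables, Fisher tests, joint BH adjustment.

    The BH family is all tested tissue x cluster pairs. ``direction`` is
    "enriched" when the sample odds ratio exceeds 1, else "depleted".
    """
    tables = build_tables(assignments, metadata)
    results = []
    for row in tables.itertuples(index=False):
        t = ContingencyTable(row.a, row.b, row.c, row.d)
        p, orat = fisher_two_sided(t)
        results.append((p, orat))
    tables = tables.copy()
    tables["odds_ratio"] = [orat for _, orat in results]
    tables["p"] = [p for p, _ in results]
    tables["q"] = bh_adjust(tables["p"].to_numpy())
    tables["significant"] = tables["q"] < config.fdr_threshold
    tables["direction"] = np.where(
        tables["odds_ratio"] > 1, "enriched", "depleted"
    )
    return tables
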