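"""Fine-mapping statistics on individually genotyped segregants.

After a linked region is called from pooled counts, selected markers can be
re-scored in individual segregants: at each marker, k of m scored
segregants carry the superior-parent variant.  Under no linkage k ~
Binomial(m, 1/2); each marker gets a two-sided exact binomial p-value
(double the smaller tail, capped at 1) and the marker set is corrected for
multiple testing with the Benjamini–Yekutieli procedure, which controls the
FDR under arbitrary dependence — appropriate here because neighbouring
markers are strongly correlated through linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SegregantGenotypes",
    "exact_binomial_pvalue",
    "benjamini_yekutieli",
    "score_individual_segregants",
    "read_genotype_table",
]


@dataclass
class SegregantGenotypes:
    """Per-marker individual-segregant scores: k of m segregants superior."""

    markers: list[str]
    positions: np.ndarray
    k_superior: np.ndarray
    m_scored: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.k_superior = np.asarray(self.k_superior, dtype=np.int64)
        self.m_scored = np.asarray(self.m_scored, dtype=np.int64)
        if not (
            len(self.markers)
            == len(self.positions)
            == len(self.k_superior)
            == len(self.m_scored)
        ):
            raise ValueError("genotype table columns must align")
        if np.any(self.k_superior < 0) or np.any(self.k_superior > self.m_scored):
            raise ValueError("need 0 <= k_superior <= m_scored at every marker")

    def __len__(self) -> int:
        return len(self.markers)


def exact_binomial_pvalue(k: int, m: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial test of proportion ``p0``.

    Doubles the smaller of P(X <= k) and P(X >= k), capped at 1; at
    p0 = 0.5 this coincides with the minimum-likelihood two-sided test by
    symmetry.
    """
    if m < 1 or not (0 <= k <= m):
        raise ValueError(f"need 0 <= k <= m with m >= 1, got k={k}, m={m}")
    if not (0.0 < p0 < 1.0):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    lower = binom.cdf(k, m, p0)
    upper = binom.sf(k - 1, m, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def benjamini_yekutieli(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def score_individual_segregants(
    genos: SegregantGenotypes, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-marker exact test + BY correction; linked iff adjusted p < alpha."""
    if len(genos) == 0:
        return pd.DataFrame(
            columns=["MARKER", "POS", "K_SUPERIOR", "M_SCORED", "P", "P_ADJ", "LINKED"]
        )
    p = np.array(
        [
            exact_binomial_pvalue(int(k), int(m))
            for k, m in zip(genos.k_superior, genos.m_scored)
        ]
    )
    p_adj = benjamini_yekutieli(p)
    return pd.DataFrame(
        {
            "MARKER": genos.markers,
            "POS": genos.positions,
            "K_SUPERIOR": genos.k_superior,
            "M_SCORED": genos.m_scored,
            "P": p,
            "P_ADJ": p_adj,
            "LINKED": p_adj < alpha,
        }
    )


def read_genotype_table(source) -> SegregantGenotypes:
    """Read a genotype TSV with columns MARKER, POS, K_SUPERIOR, M_SCORED."""
    df = pd.read_csv(source, sep="\t", comment="#")
    required = ["MARKER", "POS", "K_SUPERIOR", "M_SCORED"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"genotype table missing column(s) {missing}")
    return SegregantGenotypes(
        markers=df["MARKER"].astype(str).tolist(),
        positions=df["POS"].to_numpy(),
        k_superior=df["K_SUPERIOR"].to_numpy(),
        m_scored=df["M_SCORED"].to_numpy(),
    )
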