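"""Rank-based single-sample gene-set scoring and the HER2 expression/FISH
correlation.

Counts are normalized as log2(cpm + 1) — a simple monotone normalization;
the downstream uses (ranking, correlation) only depend on monotonicity.
The signature score is a singscore-style up-set statistic: the mean rank of
the set genes in a sample, rescaled so that the lowest attainable mean rank
maps to -0.5 and the highest to +0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["normalize", "score_signature", "expression_fish_correlation", "SignatureScore"]


@dataclass(frozen=True)
class SignatureScore:
    sample_id: str
    gene_set: str
    score: float
    m: int  # set genes scored
    n_total: int  # genes ranked


def normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(counts-per-million + 1) per sample."""
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"zero library size in samples: {list(totals.index[totals <= 0])}")
    return np.log2(counts / totals * 1e6 + 1.0)


def score_signature(
    normalized: pd.DataFrame,
    gene_set: Sequence[str],
    set_id: str = "signature",
) -> pd.DataFrame:
    """Up-set rank score of a gene set per sample, bounded in [-0.5, 0.5].

    Within each sample all N genes are ranked ascending (ties get average
    ranks) and the mean rank of the m set genes is rescaled:
    score = (meanrank - mu_min) / (mu_max - mu_min) - 0.5 with
    mu_min = (m+1)/2 and mu_max = (2N-m+1)/2, so the bounds are attained
    exactly when the set occupies the bottom or top m ranks.  Set genes
    missing from the matrix are dropped with a warning.
    """
    present = [g for g in gene_set if g in normalized.index]
    missing = set(gene_set) - set(present)
    if missing:
        warnings.warn(f"{len(missing)} gene-set genes absent from the matrix; dropped")
    m, n_total = len(present), len(normalized)
    rows = []
    for sample in normalized.columns:
        if m == 0:
            rows.append((sample, set_id, np.nan, 0, n_total))
            continue
        ranks = stats.rankdata(normalized[sample].to_numpy())
        meanrank = ranks[normalized.index.get_indexer(present)].mean()
        mu_min = (m + 1) / 2
        mu_max = (2 * n_total - m + 1) / 2
        score = (meanrank - mu_min) / (mu_max - mu_min) - 0.5
        rows.append((sample, set_id, float(score), m, n_total))
    return pd.DataFrame(rows, columns=["sample_id", "gene_set", "score", "m", "n_total"])


def expression_fish_correlation(
    expression: pd.Series,
    fish_mean_signals: pd.Series,
) -> dict:
    """Pearson correlation between a gene's normalized expression and the
    mean FISH signals/cell per duct.

    Both series are indexed by duct (sample) id; only shared ids are used.
    Returns {"r", "p", "n"}; fewer than 3 shared ducts or zero variance in
    either vector yields r = p = NaN.
    """
    both = pd.concat([expression, fish_mean_signals], axis=1, join="inner").dropna()
    n = len(both)
    if n < 3:
        return {"r": float("nan"), "p": float("nan"), "n": n}
    x, y = both.iloc[:, 0].to_numpy(), both.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": n}
    r, p = stats.pearsonr(x, y)
    return {"r": float(r), "p": float(p), "n": n}
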