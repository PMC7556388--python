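"""Differential Activation Analysis: permutation t-tests on activity scores.

The pathway-level analogue of differential expression: for each atom
(latent feature) a two-sided Welch t-statistic compares the activity
scores of two sample classes, and significance is assessed by permuting
the class labels.  One permutation matrix is shared across atoms per
replicate, preserving the inter-atom score correlations under the null.
The p-value uses the add-one estimator

    p = (1 + #{ |t*| ≥ |t_obs| }) / (B + 1),

so p ≥ 1/(B+1) and p = 0 is impossible.  Benjamini–Hochberg q-values
are reported alongside the raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = ["DaaResult", "activation_ttest", "rank_report"]


@dataclass
class DaaResult:
    """Per-atom differential-activation table plus test metadata.

    ``table`` columns: atom, t, p, q, mean/sd per class, constant flag.
    Ranking: ascending p, ties broken by descending |t|.
    """

    table: pd.DataFrame
    classes: tuple[str, str]
    n_permutations: int
    seed: int | None

    def ranked(self) -> pd.DataFrame:
        order = self.table.assign(_abs_t=self.table["t"].abs().fillna(0.0)).sort_values(
            ["p", "_abs_t"], ascending=[True, False], kind="stable"
        )
        return order.drop(columns="_abs_t").reset_index(drop=True)


def _welch_t(sum1, sumsq1, n1, sum2, sumsq2, n2):
    """Welch t from per-group sums and sums of squares (vectorized)."""
    m1, m2 = sum1 / n1, sum2 / n2
    v1 = np.maximum(sumsq1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(sumsq2 - n2 * m2**2, 0.0) / (n2 - 1)
    denom = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (m1 - m2) / denom


def activation_ttest(
    L: pd.DataFrame,
    labels: pd.Series | np.ndarray | list,
    B: int = 10000,
    seed: int | None = None,
) -> DaaResult:
    """Two-class permutation Welch t-test per atom.

    ``L`` is samples × atoms; ``labels`` assigns each row to one of
    exactly two classes, each with at least two samples.  ``B`` label
    permutations are drawn (shared across atoms) with the given seed.
    A constant score column has no defined t; its p is set to 1 and
    flagged in the output.
    """
    L = L if isinstance(L, pd.DataFrame) else pd.DataFrame(np.asarray(L))
    y = pd.Series(list(labels), index=L.index) if not isinstance(labels, pd.Series) else labels
    if len(y) != len(L):
        raise ValueError("labels length does not match score rows")
    classes = sorted(map(str, pd.unique(y.astype(str))))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask = (y.astype(str) == classes[0]).to_numpy()
    n1, n2 = int(mask.sum()), int((~mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each class needs at least 2 samples")
    if B < 1:
        raise ValueError("B must be >= 1")

    V = L.to_numpy(dtype=np.float64)
    V2 = V * V
    tot, tot2 = V.sum(axis=0), V2.sum(axis=0)

    b = mask.astype(np.float64)
    s1, sq1 = b @ V, b @ V2
    t_obs = _welch_t(s1, sq1, n1, tot - s1, tot2 - sq1, n2)
    constant = ~np.isfinite(t_obs)
    abs_obs = np.abs(np.where(constant, 0.0, t_obs))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(V.shape[1], dtype=np.int64)
    chunk = max(1, min(B, int(2e7) // max(V.size, 1)))
    done = 0
    while done < B:
        k = min(chunk, B - done)
        P = np.empty((k, len(y)), dtype=np.float64)
        base = mask.astype(np.float64)
        for r in range(k):
            P[r] = rng.permutation(base)
        S1, SQ1 = P @ V, P @ V2
        T = _welch_t(S1, SQ1, n1, tot - S1, tot2 - SQ1, n2)
        T = np.abs(np.nan_to_num(T, nan=np.inf))  # constant-under-perm: count as extreme
        exceed += (T >= abs_obs[None, :] - 1e-12).sum(axis=0)
        done += k

    p = (1.0 + exceed) / (B + 1.0)
    p = np.where(constant, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]

    g1, g2 = V[mask], V[~mask]
    table = pd.DataFrame(
        {
            "atom": list(L.columns),
            "t": np.where(constant, np.nan, t_obs),
            "p": p,
            "q": q,
            f"mean_{classes[0]}": g1.mean(axis=0),
            f"mean_{classes[1]}": g2.mean(axis=0),
            f"sd_{classes[0]}": g1.std(axis=0, ddof=1),
            f"sd_{classes[1]}": g2.std(axis=0, ddof=1),
            "constant": constant,
        }
    )
    return DaaResult(table=table, classes=(classes[0], classes[1]), n_permutations=B, seed=seed)


def rank_report(result: DaaResult, top_k: int) -> pd.DataFrame:
    """Top-k differentially activated atoms, labelled 1DA, 2DA, ...

    Returns at most ``min(top_k, n_atoms)`` rows (with a warning when
    truncated), ordered by ascending p then descending |t|, with the
    per-class score summaries needed for box-plot export.
    """
    if top_k < 0:
        raise ValueError("top_k must be >= 0")
    ranked = result.ranked()
    if top_k > len(ranked):
        import warnings

        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked)} available atoms; truncating",
            stacklevel=2,
        )
    out = ranked.head(top_k).copy()
    out.insert(0, "rank", [f"{i}DA" for i in range(1, len(out) + 1)])
    return out
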