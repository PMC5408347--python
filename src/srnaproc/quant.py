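"""Count normalization and a simplified differential-abundance test.

Size factors use the median-of-ratios estimator: for sample j,
``s_j = median_i( k_ij / geometric_mean_j'(k_ij') )`` over features with
nonzero counts in every sample, rescaled so the factors have geometric mean
one. RPM is reads per million mapped reads.

The differential test is deliberately simple and is labeled as such in every
output: with one sample per group it is an exact two-sided binomial test on
the pooled count (conditioning on the feature total, the control-sample count
is binomial with probability s_ctrl/(s_ctrl+s_stress) under the null); with
replicates it is a Wald test on the log ratio of group means under a
negative-binomial variance with a method-of-moments common dispersion. No
dispersion shrinkage, outlier filtering or fold-change moderation is
performed. P-values are Benjamini-Hochberg adjusted across features.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5


class CountMatrix:
    """Features x samples non-negative integer counts."""

    def __init__(self, counts: pd.DataFrame,
                 library_totals: Mapping[str, int] | None = None):
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)
        if library_totals is None:
            self.library_totals = self.counts.sum(axis=0)
        else:
            self.library_totals = pd.Series(library_totals).reindex(counts.columns)
        self._size_factors: pd.Series | None = None

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def size_factors(self) -> pd.Series:
        """Median-of-ratios size factors, geometric mean 1."""
        if self._size_factors is not None:
            return self._size_factors
        k = self.counts.to_numpy(dtype=float)
        valid = (k > 0).all(axis=1)
        if not valid.any():
            raise ValueError(
                "no feature has nonzero counts in all samples; "
                "consider a pseudocount before computing size factors")
        logk = np.log(k[valid])
        log_ratios = logk - logk.mean(axis=1, keepdims=True)
        log_s = np.median(log_ratios, axis=0)
        log_s -= log_s.mean()  # geometric mean 1
        self._size_factors = pd.Series(np.exp(log_s), index=self.samples,
                                       name="size_factor")
        return self._size_factors

    def normalized(self) -> pd.DataFrame:
        return self.counts / self.size_factors()

    def rpm(self) -> pd.DataFrame:
        """Reads per million mapped reads."""
        totals = self.library_totals
        if (totals <= 0).any():
            raise ValueError("library totals must be positive for RPM")
        return self.counts / totals * 1e6


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    mask = ~np.isnan(pvalues)
    out = np.full_like(pvalues, np.nan, dtype=float)
    if mask.any():
        out[mask] = multipletests(pvalues[mask], method="fdr_bh")[1]
    return out


def _nb_common_dispersion(norm: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments common NB dispersion from within-group moments."""
    alphas = []
    for g in np.unique(groups):
        sub = norm[:, groups == g]
        if sub.shape[1] < 2:
            continue
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        ok = mean > 0
        alphas.append((var[ok] - mean[ok]) / mean[ok] ** 2)
    if not alphas:
        return 0.0
    pooled = np.concatenate(alphas)
    if pooled.size == 0:
        return 0.0
    return float(max(0.0, np.median(pooled)))


def simple_de(matrix: CountMatrix,
              groups: Mapping[str, str],
              baseline: str | None = None,
              alpha_dispersion: float | None = None) -> pd.DataFrame:
    """Per-feature logFC, p-value and BH-adjusted q-value between two groups.

    ``groups`` maps sample id -> group label (exactly two labels);
    ``baseline`` names the reference group (default: the label of the first
    sample). logFC is log2(mean_other / mean_baseline) on size-factor-
    normalized counts with a 0.5 pseudocount.
    """
    labels = pd.Series({s: groups[s] for s in matrix.samples})
    uniq = list(dict.fromkeys(labels))
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {uniq}")
    baseline = baseline or uniq[0]
    other = next(l for l in uniq if l != baseline)
    sf = matrix.size_factors()
    k = matrix.counts.to_numpy(dtype=float)
    g_base = (labels == baseline).to_numpy()
    g_other = (labels == other).to_numpy()
    n_base, n_other = int(g_base.sum()), int(g_other.sum())

    norm = k / sf.to_numpy()
    mean_base = norm[:, g_base].mean(axis=1)
    mean_other = norm[:, g_other].mean(axis=1)
    logfc = np.log2((mean_other + PSEUDOCOUNT) / (mean_base + PSEUDOCOUNT))
    base_mean = norm.mean(axis=1)

    if n_base == 1 and n_other == 1:
        # exact binomial on pooled counts
        s_b = float(sf[labels.index[g_base][0]])
        s_o = float(sf[labels.index[g_other][0]])
        p_null = s_o / (s_b + s_o)
        kb = k[:, g_base].ravel().astype(int)
        ko = k[:, g_other].ravel().astype(int)
        pvals = np.array([
            stats.binomtest(int(o), int(b + o), p_null).pvalue if b + o > 0 else 1.0
            for b, o in zip(kb, ko)])
    elif n_base < 2 or n_other < 2:
        raise ValueError("need >= 2 samples per group, or exactly 1 vs 1 "
                         "for the pooled binomial test")
    else:
        alpha = (_nb_common_dispersion(norm, labels.to_numpy())
                 if alpha_dispersion is None else alpha_dispersion)
        sf_arr = sf.to_numpy()
        pvals = np.full(k.shape[0], 1.0)
        # delta-method Wald on log2 ratio of group means, NB variance
        mu_b = np.maximum(mean_base, PSEUDOCOUNT)
        mu_o = np.maximum(mean_other, PSEUDOCOUNT)
        var_b = (mu_b[:, None] / sf_arr[g_base] + alpha * mu_b[:, None] ** 2).sum(axis=1) / n_base ** 2
        var_o = (mu_o[:, None] / sf_arr[g_other] + alpha * mu_o[:, None] ** 2).sum(axis=1) / n_other ** 2
        ln2sq = np.log(2.0) ** 2
        se = np.sqrt(var_b / (mu_b ** 2 * ln2sq) + var_o / (mu_o ** 2 * ln2sq))
        wald = np.log2(mu_o / mu_b) / se
        pvals = 2 * stats.norm.sf(np.abs(wald))

    qvals = bh_adjust(pvals)
    return pd.DataFrame({
        "baseMean": base_mean,
        "log2FC": logfc,
        "pvalue": pvals,
        "qvalue": qvals,
    }, index=matrix.features)
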