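"""Expression normalization, low-expression filtering, and a simplified
negative-binomial two-group Wald test for differential expression.

Library-size normalization is median-of-ratios: each sample's size factor is
the median over genes (nonzero in every sample) of the ratio of its count to
the gene's geometric mean across samples. Genes whose normalized count is
below 4 in every sample are treated as unexpressed and removed; retained
values are log2(x + 1) transformed.

The differential-expression stage is a deliberately simple NB Wald test:
per-gene method-of-moments dispersion shrunk 50/50 toward a fitted
mean-dispersion trend (alpha(mu) = a0 + a1/mu), a delta-method standard error
on log2 fold change, and Benjamini-Hochberg control. A gene is called when
FDR <= 0.05 and |log2FC| >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXPRESSION_FLOOR = 4.0
DE_FDR = 0.05
DE_LOG2FC = 2.0
_MIN_ALPHA = 1e-8
_FC_PSEUDOCOUNT = 0.5


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts with optional size factors."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    def normalized(self) -> pd.DataFrame:
        if self.size_factors is None:
            raise ValueError("compute size_factors first")
        return self.counts / self.size_factors

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id index; log2fc, se, p_value, fdr, passed

    def passed_genes(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])


def size_factors(
    m: ExpressionMatrix, pseudo_reference: bool = False
) -> ExpressionMatrix:
    """Median-of-ratios size factors.

    factor(s) = median over reference genes of count(g, s) / geometric mean of
    gene g across samples. Reference genes are those nonzero in all samples;
    with ``pseudo_reference`` the geometric mean is taken over nonzero entries
    only, rescuing datasets with no all-nonzero gene.
    """
    counts = m.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    all_nonzero = np.all(counts > 0, axis=1)
    if pseudo_reference:
        any_nonzero = np.any(counts > 0, axis=1)
        log_gm = np.full(counts.shape[0], -np.inf)
        for i in np.flatnonzero(any_nonzero):
            vals = logc[i, counts[i] > 0]
            log_gm[i] = vals.mean()
        usable = any_nonzero
    else:
        if not all_nonzero.any():
            raise ValueError(
                "no gene has nonzero counts in every sample; "
                "retry with pseudo_reference=True"
            )
        log_gm = np.where(all_nonzero, logc.mean(axis=1), -np.inf)
        usable = all_nonzero
    ratios = logc[usable] - log_gm[usable, np.newaxis]
    if pseudo_reference:
        # per sample, median over genes observed in that sample
        factors = np.empty(counts.shape[1])
        counts_u = counts[usable]
        for j in range(counts.shape[1]):
            ok = counts_u[:, j] > 0
            if not ok.any():
                raise ValueError(f"sample {m.counts.columns[j]} has no counts")
            factors[j] = np.exp(np.median(ratios[ok, j]))
    else:
        factors = np.exp(np.median(ratios, axis=0))
    m.size_factors = pd.Series(factors, index=m.counts.columns, name="size_factor")
    return m


def filter_and_log(
    m: ExpressionMatrix,
    floor: float = EXPRESSION_FLOOR,
    any_sample: bool = False,
) -> pd.DataFrame:
    """Drop unexpressed genes and log-transform the normalized counts.

    Default rule: a gene is removed iff its normalized count is below ``floor``
    in every sample (it is never expressed). The stricter alternative
    (``any_sample``) removes a gene when any sample falls below the floor.
    Retained values are log2(x + 1).
    """
    norm = m.normalized()
    if any_sample:
        keep = (norm >= floor).all(axis=1)
    else:
        keep = (norm >= floor).any(axis=1)
    return np.log2(norm.loc[keep] + 1.0)


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha ~ a0 + a1/mu over informative genes."""
    ok = (mu > 0) & (alpha > _MIN_ALPHA)
    if ok.sum() < 3:
        med = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return med, 0.0
    x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(x, alpha[ok], rcond=None)
    a0 = max(float(coef[0]), _MIN_ALPHA)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def differential_expression(
    m: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    fdr_cutoff: float = DE_FDR,
    lfc_cutoff: float = DE_LOG2FC,
) -> DEResult:
    """Two-group NB Wald test on normalized counts (log2FC of b over a).

    Per gene: group means of normalized counts; log2FC with a 0.5 pseudocount;
    method-of-moments dispersion from within-group variances, shrunk 50/50
    toward the fitted mean-dispersion trend; Wald z from the delta-method SE;
    BH across genes. Genes with zero counts in both groups are excluded.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >=2 samples per group")
    missing = (set(group_a) | set(group_b)) - set(m.samples)
    if missing:
        raise ValueError(f"unknown samples: {sorted(missing)}")
    norm = m.normalized()
    xa = norm[group_a].to_numpy(dtype=float)
    xb = norm[group_b].to_numpy(dtype=float)
    tested = (xa.sum(axis=1) + xb.sum(axis=1)) > 0
    xa, xb = xa[tested], xb[tested]
    genes = norm.index[tested]
    n_a, n_b = len(group_a), len(group_b)
    sf_a = m.size_factors[group_a].to_numpy()
    sf_b = m.size_factors[group_b].to_numpy()

    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    log2fc = np.log2((mu_b + _FC_PSEUDOCOUNT) / (mu_a + _FC_PSEUDOCOUNT))

    # method-of-moments dispersion from pooled within-group variance
    var_pooled = (
        xa.var(axis=1, ddof=1) * (n_a - 1) + xb.var(axis=1, ddof=1) * (n_b - 1)
    ) / (n_a + n_b - 2)
    mu_bar = (mu_a + mu_b) / 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = np.where(
            mu_bar > 0, (var_pooled - mu_bar) / np.square(mu_bar), _MIN_ALPHA
        )
    alpha_g = np.clip(alpha_g, _MIN_ALPHA, 10.0)
    a0, a1 = _fit_dispersion_trend(mu_bar, alpha_g)
    alpha_tr = a0 + a1 / np.maximum(mu_bar, 1e-8)
    alpha = 0.5 * alpha_g + 0.5 * alpha_tr

    # delta-method variance of log2 of (group mean + pseudocount):
    # Var(K_s/sf_s) = mu/sf_s + alpha*mu^2 for K_s ~ NB(sf_s*mu, alpha)
    def group_var(mu: np.ndarray, sf: np.ndarray, n: int) -> np.ndarray:
        per_sample = mu[:, None] / sf[None, :] + alpha[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / n**2

    ln2sq = np.log(2.0) ** 2
    var_log2 = (
        group_var(mu_a, sf_a, n_a) / np.square(mu_a + _FC_PSEUDOCOUNT)
        + group_var(mu_b, sf_b, n_b) / np.square(mu_b + _FC_PSEUDOCOUNT)
    ) / ln2sq
    se = np.sqrt(np.maximum(var_log2, 1e-12))
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]
    passed = (fdr <= fdr_cutoff) & (np.abs(log2fc) >= lfc_cutoff)
    table = pd.DataFrame(
        {
            "base_mean_a": mu_a,
            "base_mean_b": mu_b,
            "log2fc": log2fc,
            "se": se,
            "wald_z": z,
            "p_value": p,
            "fdr": fdr,
            "passed": passed,
        },
        index=genes,
    )
    return DEResult(table=table)
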