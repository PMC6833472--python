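"""Normalization and per-contrast differential expression calls.

Depth normalization uses the median-of-ratios estimator: each sample's
size factor is the median, over genes positive in every sample, of that
sample's count divided by the gene's geometric mean across samples;
factors are then rescaled to geometric mean 1 so they are identifiable.

Differential expression is deliberately simple: for each non-reference
condition, log2 fold change of (pseudocounted) mean normalized counts
against the reference, a two-sample t test on log2(normalized count + c)
across replicates, Benjamini-Hochberg adjustment within each contrast,
and a trinary call: "up" if log2fc >= +lfc_threshold and q <= q_threshold,
"down" symmetrically, otherwise "unchanged". The calls — not the raw
p-values — are what feed the downstream path classification.

With the few biological replicates typical of such designs, per-gene
variance estimates are too noisy for an ordinary t test: at n = 4 the
Welch degrees of freedom fall to ~3 and genuinely shifted genes are
missed whenever their variance estimate comes out unluckily large. The
default test therefore moderates the per-gene pooled variance toward
the panel-wide mean with a fixed prior (``prior_df`` pseudo-replicates
of the common variance), gaining degrees of freedom exactly as
empirical-Bayes moderation does in the standard small-replicate
RNA-seq toolkits. Per-gene Welch remains available via
``variance_mode="welch"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountDataset, ExperimentDesign
from .errors import DesignError, NormalizationError

DE_COLUMNS = ("gene", "contrast", "log2fc", "p", "q", "call")


def estimate_size_factors(ds: CountDataset) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Raises
    ------
    NormalizationError
        If no gene has a positive count in every sample. Total-count
        normalization with a pseudocount is the usual fallback then.
    """
    counts = ds.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has positive counts in every sample; consider "
            "total-count normalization with a pseudocount instead"
        )
    ref = counts[all_positive]
    log_ref = np.log(ref)
    pseudo_reference = log_ref.mean(axis=1, keepdims=True)  # log geometric mean
    factors = np.exp(np.median(log_ref - pseudo_reference, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=ds.counts.columns, name="size_factor")


def normalized_counts(
    ds: CountDataset, size_factors: pd.Series | None = None
) -> pd.DataFrame:
    """Counts divided by per-sample size factors."""
    if size_factors is None:
        size_factors = estimate_size_factors(ds)
    return ds.counts / size_factors


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the sorted p-values, capped
    at 1. All inputs must lie in (0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return np.array([])
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _moderated_t_pvalues(
    cond_log: np.ndarray, ref_log: np.ndarray, prior_df: float
) -> np.ndarray:
    """Two-sided p-values from a variance-moderated pooled t test.

    Per-gene pooled variances are squeezed toward their panel-wide mean:
    s2_mod = (d0 * s0^2 + d * s2) / (d0 + d) with d0 = prior_df and
    d = n1 + n2 - 2; the t statistic is referred to d + d0 degrees of
    freedom. Genes with no signal and no variance get p = 1.
    """
    n1, n2 = cond_log.shape[1], ref_log.shape[1]
    d = n1 + n2 - 2
    s2 = (
        cond_log.var(axis=1, ddof=1) * (n1 - 1) + ref_log.var(axis=1, ddof=1) * (n2 - 1)
    ) / d
    s0_sq = float(s2.mean())
    s2_mod = (prior_df * s0_sq + d * s2) / (prior_df + d)
    diff = cond_log.mean(axis=1) - ref_log.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), d + prior_df)
    return np.where(np.isfinite(t), p, np.where(diff == 0, 1.0, 0.0))


def _trinary_call(
    log2fc: np.ndarray, q: np.ndarray, lfc_threshold: float, q_threshold: float
) -> np.ndarray:
    call = np.full(log2fc.shape, "unchanged", dtype=object)
    call[(log2fc >= lfc_threshold) & (q <= q_threshold)] = "up"
    call[(log2fc <= -lfc_threshold) & (q <= q_threshold)] = "down"
    return call


def differential_expression(
    ds: CountDataset,
    design: ExperimentDesign,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
    pseudocount: float = 1.0,
    min_mean_count: float = 5.0,
    fold_change_only: bool = False,
    variance_mode: str = "moderated",
    prior_df: float = 4.0,
) -> pd.DataFrame:
    """Per-gene, per-contrast DE table with trinary calls.

    Parameters
    ----------
    ds, design
        Counts plus the reference / contrast condition layout.
    lfc_threshold, q_threshold
        Call thresholds: |log2fc| >= lfc_threshold and q <= q_threshold.
    pseudocount
        Added on the normalized scale before all log-ratios; bounds the
        fold change of genes with zero counts.
    min_mean_count
        Genes whose mean normalized count over all samples falls below
        this are dropped before testing; the remaining genes define the
        analyzed universe used downstream.
    fold_change_only
        With single-replicate conditions no test is possible; this mode
        calls by |log2fc| alone and reports p = q = 1. Requesting the
        test branch with < 2 replicates raises a :class:`DesignError`
        pointing here.
    variance_mode
        "moderated" (default) squeezes per-gene variances toward the
        panel mean before the t test; "welch" runs a per-gene Welch t.
    prior_df
        Weight of the common variance in moderated mode, in
        pseudo-replicate units.

    Returns
    -------
    DataFrame with columns gene, contrast, log2fc, p, q, call; one row
    per analyzed gene per path condition, contrasts in design order.
    """
    if variance_mode not in ("moderated", "welch"):
        raise ValueError(
            f"variance_mode must be 'moderated' or 'welch', got {variance_mode!r}"
        )
    present = set(ds.sample_meta["condition"])
    for cond in design.conditions:
        if cond not in present:
            raise DesignError(f"condition {cond!r} not found in dataset")

    norm = normalized_counts(ds)
    keep = norm.mean(axis=1) >= min_mean_count
    norm = norm.loc[keep]
    genes = list(norm.index)
    if not genes:
        raise DesignError(
            f"no gene passes the min_mean_count={min_mean_count} filter"
        )

    log_norm = np.log2(norm + pseudocount)
    ref_samples = ds.condition_samples(design.reference_condition)
    ref_log = log_norm[ref_samples].to_numpy()
    ref_mean = norm[ref_samples].mean(axis=1).to_numpy()

    frames = []
    for cond in design.path_conditions:
        cond_samples = ds.condition_samples(cond)
        cond_mean = norm[cond_samples].mean(axis=1).to_numpy()
        log2fc = np.log2(cond_mean + pseudocount) - np.log2(ref_mean + pseudocount)

        if fold_change_only:
            p = np.ones(len(genes))
            q = np.ones(len(genes))
            call = np.full(len(genes), "unchanged", dtype=object)
            call[log2fc >= lfc_threshold] = "up"
            call[log2fc <= -lfc_threshold] = "down"
        else:
            if len(ref_samples) < 2 or len(cond_samples) < 2:
                raise DesignError(
                    f"contrast {cond!r} vs {design.reference_condition!r} "
                    "has a condition with < 2 replicates; rerun with "
                    "fold_change_only=True for pilot data"
                )
            cond_log = log_norm[cond_samples].to_numpy()
            if variance_mode == "moderated":
                p = _moderated_t_pvalues(cond_log, ref_log, prior_df)
            else:
                res = stats.ttest_ind(cond_log, ref_log, axis=1, equal_var=False)
                p = np.asarray(res.pvalue)
                # Zero within-group variance in both groups gives NaN: no
                # evidence either way, report p = 1.
                p = np.where(np.isfinite(p), p, 1.0)
            p = np.clip(p, 1e-300, 1.0)
            q = bh_adjust(p)
            call = _trinary_call(log2fc, q, lfc_threshold, q_threshold)

        frames.append(
            pd.DataFrame(
                {
                    "gene": genes,
                    "contrast": cond,
                    "log2fc": log2fc,
                    "p": p,
                    "q": q,
                    "call": call,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
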