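"""Per-path gene-set over-representation with a confidence transform.

Each non-flat path is tested against each term with the one-sided
hypergeometric upper tail: the probability of drawing at least the
observed overlap k when n path genes are sampled without replacement
from a universe of N genes of which K carry the term. The universe is
the set of genes analyzed for differential expression (not all annotated
genes), the standard guard against detection bias; term annotations are
intersected with it before testing.

P-values are BH-adjusted across the whole path x term matrix by default
(the heatmap is read as a single screen) and displayed as a confidence
score, -10 * log10(p), with p floored at 1e-300 so the score stays
finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneSetCollection
from .de import bh_adjust
from .paths import CoexpressionPath

ENRICHMENT_COLUMNS = ("path", "term", "k", "K", "n", "N", "p", "q", "confidence")

P_FLOOR = 1e-300


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the annotated genes in it, n the draw
    (path) size and k the observed overlap. P[X >= 0] = 1 by convention.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def confidence_score(p) -> np.ndarray:
    """The display statistic -10 * log10(p), with p floored at 1e-300."""
    return -10.0 * np.log10(np.maximum(np.asarray(p, dtype=float), P_FLOOR))


def enrich_paths(
    paths: list[CoexpressionPath],
    sets: GeneSetCollection,
    universe: set[str],
    bh_scope: str = "global",
) -> pd.DataFrame:
    """Hypergeometric enrichment of every term in every non-flat path.

    Parameters
    ----------
    paths
        Output of :func:`copath.paths.classify_paths`; the all-unchanged
        path is excluded from the foreground but its genes stay in the
        universe.
    sets
        Term annotations; each term is intersected with the universe.
    universe
        Background gene set; must contain every path's genes.
    bh_scope
        "global" adjusts across all (path, term) rows jointly; "per-path"
        adjusts within each path separately.

    Returns
    -------
    One row per (non-flat path, term) with the overlap k, term size K,
    path size n, universe size N, hypergeometric p, BH q, and the
    confidence score. Terms with empty intersection yield k = 0, p = 1.
    """
    if bh_scope not in ("global", "per-path"):
        raise ValueError(f"bh_scope must be 'global' or 'per-path', got {bh_scope!r}")
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    for path in paths:
        stray = path.genes - universe
        if stray:
            raise ValueError(
                f"path {path.label_str!r} has genes outside the universe, "
                f"e.g. {sorted(stray)[0]!r}"
            )
    N = len(universe)
    term_members = {t: sets.genes_of(t) & universe for t in sets}

    rows = []
    for path in paths:
        if path.is_flat:
            continue
        n = len(path.genes)
        for term_id in sets:
            members = term_members[term_id]
            K = len(members)
            k = len(path.genes & members)
            p = hypergeom_upper_tail(k, K, n, N)
            rows.append(
                {
                    "path": path.label_str,
                    "term": term_id,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "q" and c != "confidence"])
    if table.empty:
        table["q"] = pd.Series(dtype=float)
        table["confidence"] = pd.Series(dtype=float)
        return table
    p_clipped = table["p"].clip(lower=P_FLOOR)
    if bh_scope == "global":
        table["q"] = bh_adjust(p_clipped)
    else:
        table["q"] = (
            p_clipped.groupby(table["path"], group_keys=False)
            .apply(lambda s: pd.Series(bh_adjust(s), index=s.index))
        )
    table["confidence"] = confidence_score(table["p"])
    return table[list(ENRICHMENT_COLUMNS)]


def heatmap_matrix(table: pd.DataFrame, top_terms: int) -> pd.DataFrame:
    """Path x term matrix of confidence values for the top terms.

    Terms are ranked by their maximum confidence across paths
    (descending, ties by term ID); untested (path, term) cells are 0.
    """
    if top_terms < 1:
        raise ValueError("top_terms must be >= 1")
    if table.empty:
        raise ValueError("enrichment table is empty")
    best = (
        table.groupby("term")["confidence"]
        .max()
        .sort_values(ascending=False, kind="stable")
    )
    ranked = best.reset_index().sort_values(
        ["confidence", "term"], ascending=[False, True], kind="stable"
    )
    chosen = list(ranked["term"].head(top_terms))
    matrix = (
        table.pivot_table(index="path", columns="term", values="confidence")
        .reindex(columns=chosen)
        .fillna(0.0)
    )
    return matrix


def render_heatmap(
    table: pd.DataFrame, top_terms: int, matrix_path, image_path
) -> pd.DataFrame:
    """Write the confidence matrix as TSV and as a heatmap image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = heatmap_matrix(table, top_terms)
    out = matrix.copy()
    out.insert(0, "path", out.index)
    out.to_csv(matrix_path, sep="\t", index=False, float_format="%.6g")

    fig_w = max(4.0, 0.35 * matrix.shape[1] + 2.5)
    fig_h = max(3.0, 0.45 * matrix.shape[0] + 2.0)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels(matrix.index, fontsize=8)
    fig.colorbar(im, ax=ax, label="confidence, $-10\\,\\log_{10}(p)$")
    ax.set_xlabel("term")
    ax.set_ylabel("co-expression path")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    return matrix
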