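"""Expression transforms, tissue-specificity tau, co-expression statistics
and gene-family enrichment.

TPM matrices are log2-transformed with a 0.01 pseudocount before
correlation analyses. Tissue specificity uses the tau index,

    tau = sum_i (1 - x_i / max(x)) / (n - 1),

ranging 0 (ubiquitous) to 1 (single-tissue). Per-pair co-expression is the
Pearson correlation across samples of the two genes' log expression;
category distributions are compared with two-sided Wilcoxon rank-sum tests
under Benjamini-Hochberg correction.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.01


def log_transform(matrix: pd.DataFrame, epsilon: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(TPM + epsilon); negative inputs are rejected."""
    vals = matrix.to_numpy(float)
    if (vals < 0).any():
        raise ValueError("expression matrix contains negative values")
    return pd.DataFrame(np.log2(vals + epsilon), index=matrix.index, columns=matrix.columns)


def tau(values, floor_negative: bool = False) -> float:
    """Tissue-specificity index on a per-tissue expression vector.

    By default expects linear-scale (non-negative) values. With
    ``floor_negative=True``, negative entries (log-scale input) are floored
    at 0 first so the index stays in [0, 1]. All-zero vectors return NaN;
    fewer than 2 tissues is an error.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("tau requires at least 2 tissues")
    if floor_negative:
        x = np.clip(x, 0.0, None)
    elif (x < 0).any():
        raise ValueError("negative values; pass floor_negative=True for log-scale input")
    mx = x.max()
    if mx == 0:
        return math.nan
    t = float(np.sum(1.0 - x / mx) / (x.size - 1))
    return min(max(t, 0.0), 1.0)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pair_pearson(
    records, log_matrix: pd.DataFrame, gene_resolver=None
) -> pd.DataFrame:
    """Per-pair Pearson r on log-transformed expression.

    ``gene_resolver`` optionally maps a pair's gene id to a row of the
    matrix (e.g. through orthologs). Pairs with a missing gene or with zero
    variance in either gene get NaN (excluded from tests); exclusion counts
    are logged.
    """
    resolve = gene_resolver or (lambda g: g)
    rows = []
    n_missing = n_flat = 0
    for rec in records:
        ga, gb = resolve(rec.gene_a), resolve(rec.gene_b)
        if ga not in log_matrix.index or gb not in log_matrix.index:
            n_missing += 1
            r = math.nan
        else:
            xa = log_matrix.loc[ga].to_numpy(float)
            xb = log_matrix.loc[gb].to_numpy(float)
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                n_flat += 1
                r = math.nan
            else:
                r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append(
            {"gene_a": rec.gene_a, "gene_b": rec.gene_b,
             "category": getattr(rec.category, "value", rec.category), "r": r}
        )
    if n_missing or n_flat:
        logger.info(
            "co-expression: %d pairs missing from matrix, %d with a zero-variance gene",
            n_missing, n_flat,
        )
    return pd.DataFrame(rows)


def category_rank_tests(per_pair: pd.DataFrame, value_col: str = "r") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests between all category pairs of a
    per-observation table, BH-adjusted across comparisons."""
    clean = per_pair.dropna(subset=[value_col])
    cats = sorted(clean["category"].unique())
    rows = []
    for ca, cb in itertools.combinations(cats, 2):
        xa = clean.loc[clean["category"] == ca, value_col]
        xb = clean.loc[clean["category"] == cb, value_col]
        if len(xa) == 0 or len(xb) == 0:
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {"category_a": ca, "category_b": cb, "n_a": len(xa), "n_b": len(xb),
             "median_a": float(xa.median()), "median_b": float(xb.median()),
             "p": float(res.pvalue)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def coexpression(
    records, matrix: pd.DataFrame, epsilon: float = DEFAULT_PSEUDOCOUNT, gene_resolver=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-pair Pearson r (log scale) and per-category rank-test summary."""
    logm = log_transform(matrix, epsilon)
    per_pair = pair_pearson(records, logm, gene_resolver)
    return per_pair, category_rank_tests(per_pair)


def tau_by_category(
    gene_sets: dict, matrix: pd.DataFrame, on_log: bool = False,
    epsilon: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene tau labelled by category gene set.

    ``on_log=True`` computes tau on log2(TPM + eps) with negative flooring
    (the 0-1 range is preserved by clipping); the default linear mode keeps
    the index's scale-invariance.
    """
    data = log_transform(matrix, epsilon) if on_log else matrix
    rows = []
    for cat, genes in gene_sets.items():
        cat_label = getattr(cat, "value", cat)
        for g in sorted(genes):
            if g not in data.index:
                continue
            t = tau(data.loc[g].to_numpy(float), floor_negative=on_log)
            rows.append({"category": cat_label, "gene_id": g, "tau": t})
    return pd.DataFrame(rows)


def gene_family_enrichment(
    category_sets: dict, family: set[str], universe: set[str]
) -> pd.DataFrame:
    """Two-sided Fisher's exact test of family membership per category.

    The 2x2 table per category is (in-category & family, in-category &
    not-family; out-of-category & family, out-of-category & not-family)
    over the gene universe. BH correction is applied within this series.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not family <= universe:
        raise ValueError("family must be a subset of the universe")
    rows = []
    for cat, genes in category_sets.items():
        genes = set(genes) & universe
        a = len(genes & family)
        b = len(genes - family)
        c = len(family - genes)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"category": getattr(cat, "value", cat), "n_in_family": a,
             "n_category": len(genes), "odds_ratio": float(odds), "p": float(p)}
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_adjust(df["p"].to_numpy())
    return df
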