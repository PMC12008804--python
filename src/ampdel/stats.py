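"""Statistical layer: small-sample exact tests, copy-number-adjusted
expression, the gene-dosage linear model, a per-gene differential
expression stage, and ORF-screen log-fold-change utilities.

The rank-sum and Fisher tests are computed exactly (full enumeration of
group assignments / the hypergeometric support) at small sample sizes and
by normal approximation with tie correction otherwise; scipy supplies
only distribution functions, not the exact enumeration.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, isfinite
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .caller import locus_cn
from .io import CopyNumberSegment, ExpressionTable, GeneLocus

logger = logging.getLogger(__name__)

EXACT_RANKSUM_MAX_N = 12  # combined size at/below which enumeration is used


@dataclass(frozen=True)
class GroupComparison:
    test_name: str
    statistic: float
    p_value: float
    sidedness: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float] | None = None
    medians: tuple[float, float] | None = None
    method: str = "exact"
    flags: tuple[str, ...] = ()
    odds_ratio: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0,1]")


# ---------------------------------------------------------------------------
# rank-sum


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    labels: tuple[str, str] = ("group1", "group2"),
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration of all C(n, n1) group assignments for combined
    n <= 12; normal approximation with tie correction above that.
    The two-sided exact p is P(|W - E[W]| >= |w - E[W]|) under random
    assignment of the pooled (mid-)ranks.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    pooled = np.concatenate([x, y])
    n1, n2 = len(x), len(y)
    n = n1 + n2
    ranks = sps.rankdata(pooled)
    w_obs = float(ranks[:n1].sum())
    mu = n1 * (n + 1) / 2.0
    flags: list[str] = []
    if np.ptp(pooled) == 0:
        return GroupComparison(
            "wilcoxon_rank_sum", w_obs, 1.0, "two-sided", labels, (n1, n2),
            (float(x.mean()), float(y.mean())),
            (float(np.median(x)), float(np.median(y))),
            method="degenerate", flags=("zero_variance",),
        )
    if n <= EXACT_RANKSUM_MAX_N:
        dev = abs(w_obs - mu)
        hits = total = 0
        for idx in combinations(range(n), n1):
            total += 1
            w = ranks[list(idx)].sum()
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
        method = "exact"
    else:
        # normal approximation with tie and continuity corrections
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts**3 - counts)).sum())
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
            flags.append("zero_variance")
        else:
            z = max(abs(w_obs - mu) - 0.5, 0.0) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(z))
        method = "normal_tie_corrected"
    return GroupComparison(
        "wilcoxon_rank_sum", w_obs, min(p, 1.0), "two-sided", labels, (n1, n2),
        (float(x.mean()), float(y.mean())),
        (float(np.median(x)), float(np.median(y))),
        method=method, flags=tuple(flags),
    )


def compare_locus_cn(
    cn_carriers: Sequence[float], cn_noncarriers: Sequence[float]
) -> GroupComparison:
    """Compare locus copy number between focal-deletion carriers and
    non-carriers (two-sided rank-sum)."""
    return rank_sum_test(cn_carriers, cn_noncarriers, ("carriers", "non-carriers"))


# ---------------------------------------------------------------------------
# Fisher's exact test


def cooccurrence_fisher(
    n_amp_del: int, n_amp_nodel: int, n_noamp_del: int, n_noamp_nodel: int
) -> GroupComparison:
    """Two-sided Fisher exact test on the 2x2 amplification x deletion
    table, by enumeration of the hypergeometric support: sum of all
    table probabilities not exceeding the observed table's.
    """
    cells = (n_amp_del, n_amp_nodel, n_noamp_del, n_noamp_nodel)
    if any((not float(c).is_integer()) or c < 0 for c in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    total = a + b + c + d
    if total < 1:
        raise ValueError("table total must be >= 1")
    row1, col1 = a + b, a + c
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    # hypergeometric pmf over the support, computed with exact binomials
    denom = comb(total, col1)
    pmf = {k: comb(row1, k) * comb(total - row1, col1 - k) / denom for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    p = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))
    flags: list[str] = []
    if min(row1, col1, total - row1, total - col1) == 0:
        # a zero margin: odds ratio via Haldane 0.5 continuity, flagged
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        flags.append("haldane_continuity")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)
    return GroupComparison(
        "fisher_exact", float(a), min(p, 1.0), "two-sided",
        ("amplified", "not_amplified"), (row1, total - row1),
        method="exact", flags=tuple(flags), odds_ratio=float(odds),
    )


# ---------------------------------------------------------------------------
# copy-number-adjusted expression


def cn_adjusted_expression(
    expr: ExpressionTable,
    segments_by_sample: dict[str, list[CopyNumberSegment]],
    neighbor: GeneLocus,
) -> ExpressionTable:
    """Normalize expression to diploid using the neighbor gene's copy
    number: adjusted FPKM = FPKM * 2 / CN(neighbor). The neighbor is used
    because copy number within the target gene is variable by definition
    in deletion carriers. Samples with missing or non-positive neighbor
    CN are dropped (logged)."""
    keep, scale, dropped = [], [], []
    for sample in expr.samples:
        segs = segments_by_sample.get(sample, [])
        cn = locus_cn(segs, neighbor)
        if not isfinite(cn) or cn <= 0:
            dropped.append(sample)
            continue
        keep.append(sample)
        scale.append(2.0 / cn)
    if dropped:
        logger.warning("cn_adjusted_expression: dropped samples %s", dropped)
    values = expr.values[keep].mul(pd.Series(scale, index=keep), axis=1)
    return ExpressionTable(values)


# ---------------------------------------------------------------------------
# gene-dosage linear model


@dataclass(frozen=True)
class DosageModelFit:
    """OLS fit of expression ~ copy number + focal deletion + tumor type."""

    coefficients: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    residual_sd: float
    n: int
    reference_type: str

    def __post_init__(self):
        for name, est in self.coefficients.items():
            lo, hi = self.conf_int[name]
            if not lo <= est <= hi:
                raise ValueError(f"coefficient {name}: CI ({lo},{hi}) excludes estimate {est}")


class RankDeficientDesignError(ValueError):
    pass


def fit_dosage_model(
    expression: pd.Series,
    copy_number: pd.Series,
    deletion_status: pd.Series,
    tumor_type: pd.Series,
    patient: pd.Series | None = None,
    reference_type: str = "Other",
) -> DosageModelFit:
    """Fit FPKM ~ copy_number + focal_deletion + C(tumor_type) by OLS,
    with 95% confidence intervals from the t distribution.

    Multi-sample patients are collapsed to per-patient means (expression
    and copy number averaged, deletion status any, tumor type first)
    BEFORE fitting.
    """
    df = pd.DataFrame(
        {
            "expr": expression.astype(float),
            "cn": copy_number.astype(float),
            "deleted": deletion_status.astype(float),
            "tumor_type": tumor_type.astype(str),
        }
    ).dropna()
    if patient is not None:
        df["patient"] = patient.reindex(df.index)
        df = (
            df.groupby("patient")
            .agg(
                expr=("expr", "mean"),
                cn=("cn", "mean"),
                deleted=("deleted", "max"),
                tumor_type=("tumor_type", "first"),
            )
            .reset_index(drop=True)
        )
    levels = sorted(df["tumor_type"].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 tumor-type levels")
    if reference_type not in levels:
        raise ValueError(f"reference type {reference_type!r} absent from data")
    others = [t for t in levels if t != reference_type]
    X = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    for t in others:
        X[f"tumor_type[{t}]"] = (df["tumor_type"] == t).astype(float)
    X["copy_number"] = df["cn"].to_numpy()
    X["focal_deletion"] = df["deleted"].to_numpy()
    if len(df) <= X.shape[1]:
        raise ValueError(f"n={len(df)} too small for {X.shape[1]} coefficients")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the collinear columns: those whose removal restores full rank
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == rank
        ]
        raise RankDeficientDesignError(
            f"rank-deficient design matrix; collinear columns: {collinear}"
        )
    fit = sm.OLS(df["expr"].to_numpy(), X).fit()
    ci = fit.conf_int(alpha=0.05)
    return DosageModelFit(
        coefficients={k: float(v) for k, v in fit.params.items()},
        conf_int={k: (float(ci.loc[k, 0]), float(ci.loc[k, 1])) for k in X.columns},
        residual_sd=float(np.sqrt(fit.mse_resid)),
        n=len(df),
        reference_type=reference_type,
    )


# ---------------------------------------------------------------------------
# differential expression


def differential_expression(
    expr: ExpressionTable,
    carrier: pd.Series,
    tumor_type: pd.Series,
    genes: Sequence[str] | None = None,
    q_threshold: float = 0.1,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene linear model on log2(FPKM + 1): carrier status plus
    tumor-type covariates; Bonferroni-corrected q; pass iff q below the
    threshold AND |log2 fold change| at or above ``lfc_threshold``.

    ``genes`` restricts the tested universe (e.g. autosomal protein-coding
    genes). This is a plain per-gene OLS stage: empirical-Bayes moderation
    and precision weights are deliberately not applied. Returns a
    DataFrame (gene, log2fc, p, q, passed, zero_variance) sorted by p.
    """
    samples = expr.samples
    carrier = carrier.reindex(samples)
    tumor_type = tumor_type.reindex(samples)
    if carrier.isna().any() or tumor_type.isna().any():
        raise ValueError("carrier/tumor_type must cover every expression sample")
    n_car = int(carrier.sum())
    if n_car < 2 or len(samples) - n_car < 2:
        raise ValueError("need >= 2 carriers and >= 2 non-carriers")
    values = expr.values
    if genes is not None:
        missing = [g for g in genes if g not in values.index]
        if missing:
            raise ValueError(f"genes absent from expression table: {missing[:5]}")
        values = values.loc[list(genes)]
    Y = np.log2(values.to_numpy(dtype=float) + 1.0)  # genes x samples

    levels = sorted(tumor_type.unique())
    cols = [np.ones(len(samples)), carrier.to_numpy(dtype=float)]
    for t in levels[1:]:
        cols.append((tumor_type == t).to_numpy(dtype=float))
    X = np.column_stack(cols)  # samples x p
    p_dim = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    XtX_inv = np.linalg.pinv(X.T @ X)
    B = XtX_inv @ X.T @ Y.T  # p x genes
    resid = Y.T - X @ B
    dof = len(samples) - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[1, 1], 0.0))
    lfc = B[1]
    zero_var = Y.var(axis=1) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p_raw = 2.0 * sps.t.sf(np.abs(t_stat), dof)
    p_raw = np.where((se == 0) | zero_var, 1.0, p_raw)
    n_genes = Y.shape[0]
    q = np.minimum(1.0, p_raw * n_genes)
    passed = (q < q_threshold) & (np.abs(lfc) >= lfc_threshold) & ~zero_var
    out = pd.DataFrame(
        {
            "gene": values.index,
            "log2fc": lfc,
            "p": p_raw,
            "q": q,
            "passed": passed,
            "zero_variance": zero_var,
        }
    )
    return out.sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ORF screen utilities


def orf_lfc(abundance_early, abundance_late, pseudocount: float = 0.0):
    """log2((late + pc) / (early + pc)); negative values indicate a growth
    deficit (toxicity) of the overexpressed construct."""
    early = np.asarray(abundance_early, dtype=float)
    late = np.asarray(abundance_late, dtype=float)
    if np.any(early < 0) or np.any(late < 0):
        raise ValueError("abundances must be >= 0")
    if np.any(early + pseudocount <= 0) or np.any(late + pseudocount <= 0):
        raise ValueError("undefined log fold change: zero abundance with zero pseudocount")
    out = np.log2((late + pseudocount) / (early + pseudocount))
    return float(out) if out.ndim == 0 else out


def orf_isoform_compare(
    lfc_long: Sequence[float], lfc_short: Sequence[float]
) -> GroupComparison:
    """Paired two-tailed t test of per-cell-line growth log fold changes
    between the long and short isoform constructs."""
    a = np.asarray(list(lfc_long), dtype=float)
    b = np.asarray(list(lfc_short), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    res = sps.ttest_rel(a, b)
    return GroupComparison(
        "paired_t", float(res.statistic), float(res.pvalue), "two-sided",
        ("long", "short"), (len(a), len(b)),
        (float(a.mean()), float(b.mean())),
        (float(np.median(a)), float(np.median(b))),
        method="t",
    )
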