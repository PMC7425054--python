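"""Negative-binomial Wald differential expression for two-group contrasts.

The model is the classic count-GLM used for bulk RNA-seq: for gene ``g`` and
sample ``j`` with size factor ``s_j``,

    y_gj ~ NB(mu_gj, alpha_g),   Var = mu + alpha * mu^2,
    log mu_gj = log s_j + beta0_g + beta1_g * x_j,

with ``x_j`` an indicator for the treatment group.  ``beta1_g`` (converted to
log2) is the log fold change, and the Wald statistic ``z = beta1 / se`` is
referred to the standard normal.  This is a deliberately simple estimator:
gene-wise method-of-moments dispersions with an optional trend shrinkage, no
Cox-Reid adjustment, no MAP shrinkage, no independent filtering and no
outlier replacement.  Size factors follow the median-of-ratios convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

#: floor applied to dispersion estimates
DISPERSION_FLOOR = 1e-8

REQUIRED_META = ("cell_line", "condition", "replicate")


class CountMatrixError(ValueError):
    """Raised when a count matrix or its metadata violates the contract."""


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus per-sample metadata.

    ``counts`` is indexed by gene id with one column per sample;
    ``sample_meta`` is indexed by sample id and carries at least
    ``cell_line``, ``condition`` and ``replicate`` columns.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene ids: {dups[:5]}")
        if self.counts.columns.duplicated().any():
            raise CountMatrixError("duplicate sample ids in count matrix")
        for col in REQUIRED_META:
            if col not in self.sample_meta.columns:
                raise CountMatrixError(f"sample sheet misses column {col!r}")
        missing = [s for s in self.counts.columns if s not in self.sample_meta.index]
        if missing:
            raise CountMatrixError(f"sample sheet misses sample {missing[0]!r}")
        extra = [s for s in self.sample_meta.index if s not in self.counts.columns]
        if extra:
            raise CountMatrixError(f"count matrix misses sample {extra[0]!r}")
        # align metadata to column order
        self.sample_meta = self.sample_meta.loc[list(self.counts.columns)]
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise CountMatrixError("counts must be integers")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise CountMatrixError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset(
        self, cell_line: str | None = None, conditions: tuple[str, ...] | None = None
    ) -> "CountMatrix":
        meta = self.sample_meta
        keep = pd.Series(True, index=meta.index)
        if cell_line is not None:
            keep &= meta["cell_line"] == cell_line
        if conditions is not None:
            keep &= meta["condition"].isin(conditions)
        samples = list(meta.index[keep])
        if not samples:
            raise CountMatrixError(
                f"no samples match cell_line={cell_line!r}, conditions={conditions!r}"
            )
        return CountMatrix(self.counts[samples].copy(), meta.loc[samples].copy())


def size_factors(
    counts: CountMatrix | pd.DataFrame, fallback: bool = True
) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with no zero count; each sample's factor is the
    median over reference genes of its count divided by the gene's geometric
    mean.  With a single sample the factor is defined as 1.  If every gene
    contains a zero, a fallback using only the positive entries of each gene
    is applied (or an error raised when ``fallback`` is disabled).
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    if df.shape[1] == 1:
        return pd.Series(1.0, index=df.columns, name="size_factor")
    vals = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(vals)
    allpos = (vals > 0).all(axis=1)
    if allpos.any():
        loggeo = logc[allpos].mean(axis=1)
        ratios = logc[allpos] - loggeo[:, None]
        fac = np.exp(np.median(ratios, axis=0))
    else:
        if not fallback:
            raise CountMatrixError(
                "every gene contains a zero count; cannot compute "
                "median-of-ratios size factors (fallback disabled)"
            )
        pos = vals > 0
        anyuse = pos.any(axis=1)
        if not anyuse.any() or (vals.sum(axis=0) == 0).any():
            raise CountMatrixError("a sample has no positive counts")
        loggeo = np.where(
            anyuse, np.nansum(np.where(pos, logc, 0.0), axis=1) / pos.sum(axis=1), np.nan
        )
        fac = np.empty(vals.shape[1])
        for j in range(vals.shape[1]):
            use = pos[:, j] & anyuse
            fac[j] = np.exp(np.median(logc[use, j] - loggeo[use]))
    return pd.Series(fac, index=df.columns, name="size_factor")


def normalized_counts(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series
) -> pd.DataFrame:
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    return df / factors.reindex(df.columns)


def estimate_dispersion(
    counts: CountMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    groups: pd.Series | None = None,
    shrink: bool = True,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Gene-wise method-of-moments NB dispersion with optional trend shrinkage.

    Within each group with >= 2 replicates the moment identity
    ``alpha = (s^2 - mean) / mean^2`` is evaluated on size-factor-normalised
    counts and pooled across groups by degrees of freedom.  With
    ``shrink=True`` a mean-dispersion trend ``a0 + a1/mu`` is fitted to
    binned gene-wise values and the final estimate is the midpoint of the
    (unclipped) gene-wise value and the trend, floored at ``floor``.
    """
    if isinstance(counts, CountMatrix):
        if groups is None:
            groups = counts.sample_meta["condition"]
        df = counts.counts
    else:
        df = counts
        if groups is None:
            raise ValueError("groups required when counts is a plain DataFrame")
    if factors is None:
        factors = size_factors(counts)
    groups = groups.reindex(df.columns)
    y = (df / factors.reindex(df.columns)).to_numpy(dtype=float)

    ss = np.zeros(df.shape[0])
    dfree = 0
    raw_num = np.zeros(df.shape[0])
    raw_den = np.zeros(df.shape[0])
    any_group = False
    for _, idx in groups.groupby(groups).groups.items():
        cols = [df.columns.get_loc(s) for s in idx]
        n = len(cols)
        if n < 2:
            continue
        any_group = True
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        a = np.where(ok, (v - m) / np.where(ok, m, 1.0) ** 2, np.nan)
        w = n - 1
        raw_num += np.where(np.isnan(a), 0.0, a * w)
        raw_den += np.where(np.isnan(a), 0.0, w)
        ss += v * (n - 1)
        dfree += n - 1
    if not any_group:
        raise ValueError(
            "no group has >= 2 replicates; provide dispersions explicitly "
            "or use dispersion 0 (Poisson mode)"
        )
    with np.errstate(invalid="ignore"):
        raw = np.where(raw_den > 0, raw_num / np.maximum(raw_den, 1e-300), np.nan)
    mu = y.mean(axis=1)

    if not shrink:
        out = np.where(np.isnan(raw), floor, np.clip(raw, floor, None))
        return pd.Series(out, index=df.index, name="dispersion")

    trend = _dispersion_trend(mu, raw, floor)
    mid = 0.5 * np.where(np.isnan(raw), trend, raw) + 0.5 * trend
    out = np.clip(mid, floor, None)
    return pd.Series(out, index=df.index, name="dispersion")


def _dispersion_trend(mu: np.ndarray, raw: np.ndarray, floor: float) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on decile-binned means of gene-wise values."""
    ok = ~np.isnan(raw) & (mu > 0)
    fallback = max(float(np.nanmean(raw[ok])) if ok.any() else floor, floor)
    if ok.sum() < 20:
        return np.full_like(mu, fallback)
    q = np.quantile(mu[ok], np.linspace(0, 1, 11))
    q[0] -= 1e-9
    which = np.searchsorted(q, mu[ok], side="right") - 1
    which = np.clip(which, 0, 9)
    bm, ba = [], []
    for b in range(10):
        sel = which == b
        if sel.sum() >= 3:
            bm.append(mu[ok][sel].mean())
            ba.append(raw[ok][sel].mean())
    if len(bm) < 2:
        return np.full_like(mu, fallback)
    X = np.column_stack([np.ones(len(bm)), 1.0 / np.asarray(bm)])
    coef, *_ = np.linalg.lstsq(X, np.asarray(ba), rcond=None)
    a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    if a0 == 0.0 and a1 == 0.0:
        return np.full_like(mu, fallback)
    with np.errstate(divide="ignore"):
        tr = a0 + a1 / np.where(mu > 0, mu, np.inf)
    return np.clip(tr, floor, None)


@dataclass
class DEResult:
    """Per-gene differential-expression table for one treatment-vs-control
    contrast within a single cell line.

    Columns: ``base_mean``, ``log2fc``, ``se``, ``stat``, ``p_value``,
    ``padj``, ``status`` ("tested" / "filtered_all_zero"), ``separated``
    (one group all zero; point estimate used a 0.5 pseudocount on group
    totals), ``converged``.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame
    cell_line: str | None = None

    @property
    def label(self) -> str:
        return f"{self.contrast[0]}_vs_{self.contrast[1]}"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing values are excluded from the number of tests and returned as
    missing.  Raises if any p lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def _nb_irls_two_group(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    dev_tol: float = 1e-8,
    beta_tol: float = 1e-10,
):
    """Vectorised IRLS for the two-group NB GLM with log link and offsets.

    Parameters are per gene (rows of ``y``); ``x`` is the 0/1 treatment
    indicator over samples.  Returns natural-log ``beta0``, ``beta1``, the
    standard error of ``beta1`` and a per-gene convergence flag.  Requires
    positive group sums in both groups for every row.
    """
    G = y.shape[0]
    s = np.exp(offset)
    sum0, sum1 = s[x == 0].sum(), s[x == 1].sum()
    m0 = y[:, x == 0].sum(axis=1) / sum0
    m1 = y[:, x == 1].sum(axis=1) / sum1
    b0 = np.log(m0)
    b1 = np.log(m1) - np.log(m0)
    a = alpha[:, None]
    dev_old = np.full(G, np.inf)
    conv = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = b0[:, None] + np.outer(b1, x) + offset[None, :]
        mu = np.exp(eta)
        mu = np.clip(mu, 1e-300, None)
        w = mu / (1.0 + a * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        w0 = w * (1.0 - x)[None, :]
        w1 = w * x[None, :]
        sw0 = w0.sum(axis=1)
        sw1 = w1.sum(axis=1)
        nb0 = (w0 * z).sum(axis=1) / sw0
        nb1 = (w1 * z).sum(axis=1) / sw1 - nb0
        step = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1))
        b0, b1 = nb0, nb1
        dev = _nb_deviance(y, np.exp(b0[:, None] + np.outer(b1, x) + offset[None, :]), alpha)
        rel = np.abs(dev - dev_old) / (np.abs(dev) + 0.1)
        conv = (rel <= dev_tol) | (step <= beta_tol)
        dev_old = dev
        if conv.all():
            break
    eta = b0[:, None] + np.outer(b1, x) + offset[None, :]
    mu = np.clip(np.exp(eta), 1e-300, None)
    w = mu / (1.0 + a * mu)
    sw0 = (w * (1.0 - x)[None, :]).sum(axis=1)
    sw1 = (w * x[None, :]).sum(axis=1)
    se1 = np.sqrt(1.0 / sw0 + 1.0 / sw1)
    return b0, b1, se1, conv


def _nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
        pois = t1 - (y - mu)
        nb = t1 - (y + 1.0 / np.where(a > 0, a, 1.0)) * np.log(
            (1.0 + a * y) / (1.0 + a * mu)
        )
    per = np.where(a > 0, nb, pois)
    return 2.0 * per.sum(axis=1)


def wald_test(
    counts: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    cell_line: str | None = None,
    max_iter: int = 100,
    dev_tol: float = 1e-8,
) -> DEResult:
    """Two-group NB Wald test of ``treatment`` vs ``control``.

    Size factors enter as offsets; dispersions are taken as given (estimated
    from the contrast's samples when omitted).  Genes with zero counts in
    every sample of both groups are marked ``filtered_all_zero`` and excluded
    from the BH denominator.  Genes that are all-zero in exactly one group
    get a finite fold change via a 0.5 pseudocount on group totals and are
    flagged ``separated``.
    """
    treatment, control = contrast
    meta = counts.sample_meta
    lines = meta["cell_line"].unique()
    if cell_line is None:
        if len(lines) > 1:
            raise ValueError(
                "count matrix contains several cell lines; pass cell_line"
            )
        cell_line = lines[0]
    sub = counts.subset(cell_line=cell_line, conditions=(treatment, control))
    cond = sub.sample_meta["condition"]
    for c in (treatment, control):
        if (cond == c).sum() < 1:
            raise ValueError(f"condition {c!r} has no samples in cell line {cell_line!r}")
    if factors is None:
        factors = size_factors(sub)
    factors = factors.reindex(sub.sample_ids)
    if dispersions is None:
        dispersions = estimate_dispersion(sub, factors=factors)
    dispersions = dispersions.reindex(sub.gene_ids)
    if (dispersions < 0).any():
        raise ValueError("dispersions must be non-negative")

    Y = sub.counts.to_numpy(dtype=float)
    x = (cond == treatment).to_numpy(dtype=float)
    s = factors.to_numpy(dtype=float)
    offset = np.log(s)
    alpha = dispersions.to_numpy(dtype=float)

    tot0 = Y[:, x == 0].sum(axis=1)
    tot1 = Y[:, x == 1].sum(axis=1)
    filtered = (tot0 == 0) & (tot1 == 0)
    separated = ((tot0 == 0) | (tot1 == 0)) & ~filtered
    fit = ~filtered & ~separated

    G = Y.shape[0]
    lfc = np.full(G, np.nan)
    se = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    conv = np.zeros(G, dtype=bool)

    if fit.any():
        b0, b1, se1, cv = _nb_irls_two_group(
            Y[fit], x, offset, alpha[fit], max_iter=max_iter, dev_tol=dev_tol
        )
        lfc[fit] = b1 / LN2
        se[fit] = se1 / LN2
        stat[fit] = b1 / se1
        conv[fit] = cv
        p = 2.0 * stats.norm.sf(np.abs(b1 / se1))
        p = np.where(cv, np.clip(p, 0.0, 1.0), np.nan)
        pval[fit] = p
        if not cv.all():
            logger.warning("%d genes did not converge in %d IRLS iterations",
                           int((~cv).sum()), max_iter)

    if separated.any():
        sum0, sum1 = s[x == 0].sum(), s[x == 1].sum()
        m0 = (tot0[separated] + 0.5) / sum0
        m1 = (tot1[separated] + 0.5) / sum1
        b1 = np.log(m1) - np.log(m0)
        asep = alpha[separated]
        mu0 = np.outer(m0, s[x == 0])
        mu1 = np.outer(m1, s[x == 1])
        sw0 = (mu0 / (1.0 + asep[:, None] * mu0)).sum(axis=1)
        sw1 = (mu1 / (1.0 + asep[:, None] * mu1)).sum(axis=1)
        se1 = np.sqrt(1.0 / sw0 + 1.0 / sw1)
        lfc[separated] = b1 / LN2
        se[separated] = se1 / LN2
        stat[separated] = b1 / se1
        pval[separated] = np.clip(2.0 * stats.norm.sf(np.abs(b1 / se1)), 0.0, 1.0)
        conv[separated] = True

    base_mean = (Y / s[None, :]).mean(axis=1)
    padj = np.full(G, np.nan)
    tested = ~filtered & ~np.isnan(pval)
    padj[tested] = bh_adjust(pval[tested])

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": lfc,
            "se": se,
            "stat": stat,
            "p_value": pval,
            "padj": padj,
            "status": np.where(filtered, "filtered_all_zero", "tested"),
            "separated": separated,
            "converged": conv,
        },
        index=sub.counts.index,
    )
    return DEResult(contrast=(treatment, control), table=table, cell_line=cell_line)


@dataclass(frozen=True)
class DEGSet:
    """Directional set of significant genes for one contrast."""

    contrast: str
    direction: str  # up | down | both
    genes: frozenset
    alpha: float = 0.05
    min_abs_lfc: float = 1.0
    p_column: str = "adjusted"

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, g) -> bool:
        return g in self.genes


_P_COLUMNS = {"adjusted": "padj", "padj": "padj", "raw": "p_value", "p_value": "p_value"}


def call_degs(
    result: DEResult,
    alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
    p_column: str = "adjusted",
    direction: str = "both",
) -> DEGSet:
    """Significant genes at inclusive thresholds ``p <= alpha`` and
    ``|log2fc| >= min_abs_lfc``; direction by the sign of the fold change."""
    if p_column not in _P_COLUMNS:
        raise ValueError(f"unknown p_column {p_column!r}")
    if direction not in ("up", "down", "both"):
        raise ValueError(f"unknown direction {direction!r}")
    t = result.table
    col = _P_COLUMNS[p_column]
    sel = (t["status"] == "tested") & t[col].notna() & (t[col] <= alpha)
    if direction == "up":
        sel &= t["log2fc"] >= min_abs_lfc
    elif direction == "down":
        sel &= t["log2fc"] <= -min_abs_lfc
    else:
        sel &= t["log2fc"].abs() >= min_abs_lfc
    return DEGSet(
        contrast=result.label,
        direction=direction,
        genes=frozenset(t.index[sel]),
        alpha=alpha,
        min_abs_lfc=min_abs_lfc,
        p_column=p_column,
    )
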