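"""Zonal composition statistics, differential expression and gene-set scores.

Composition across the six margin bands is summarized as per-band
cell-type proportions and compared with the two-sided Wilcoxon rank-sum
(Mann-Whitney U) test; p-values are Benjamini-Hochberg adjusted within a
comparison family.  Differential expression uses a per-gene Welch t-test
on log1p library-size-normalized expression with the |log2FC| >= 1.5 and
BH-adjusted p < 0.05 flagging rule.  Gene-set scores are the mean
expression of the set minus the mean of an expression-matched control set
drawn from mean-expression bins (a plain-mean mode is available).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, ParameterError
from .qc import UNASSIGNED
from .simulate import BAND_LABELS

__all__ = [
    "band_composition",
    "rank_sum_test",
    "bh_adjust",
    "differential_expression",
    "gene_set_score",
    "GeneSetScorer",
    "normalize_log1p",
    "compare_compositions",
]

#: pool size at or below which the exact permutation null is enumerated
EXACT_ENUM_MAX = 12


def band_composition(band_labels, type_labels=None, abundance=None,
                     band_order=BAND_LABELS) -> pd.DataFrame:
    """Per-band cell-type proportions.

    Two composition units are supported, mirroring the two ways zonal
    make-up is read off a section:

    * assigned-spot counts (``type_labels``):
      proportion(band, type) = n(band, type) / n(band, assigned); spots
      with no band or an ``UNASSIGNED`` type are excluded.
    * relative abundance mass (``abundance``: spot × cell-type frame
      aligned with ``band_labels``): proportion(band, type) = summed
      abundance of the type / summed abundance in the band.  This is the
      natural unit when the per-spot composition itself is fractional
      (a deconvolved multi-cell spot), where a dominant-type count can
      hide a real but never-dominant gradient.

    Bands listed in ``band_order`` but holding zero spots are reported
    with ``n_spots = 0`` and null proportions rather than dropped.
    """
    if (type_labels is None) == (abundance is None):
        raise InputError("provide exactly one of type_labels or abundance")
    bands = pd.Series(np.asarray(band_labels, dtype=object), name="band")

    if abundance is not None:
        ab = abundance if isinstance(abundance, pd.DataFrame) else pd.DataFrame(abundance)
        if len(ab) != len(bands):
            raise InputError("band labels and abundance must be aligned")
        keep = bands.notna()
        if not keep.any():
            warnings.warn("no spot in any band", stacklevel=2)
        rows = []
        for band in band_order:
            sel = (keep & (bands == band)).to_numpy()
            n_band = int(sel.sum())
            mass = ab.loc[sel].sum(axis=0)
            total = float(mass.sum())
            for t in ab.columns:
                rows.append((
                    band, t, n_band,
                    float(mass[t]) / total if total > 0 else np.nan,
                ))
        out = pd.DataFrame(rows, columns=["band", "cell_type", "n_spots", "proportion"])
        out.attrs["empty"] = not bool(keep.any())
        return out

    types = pd.Series(np.asarray(type_labels, dtype=object), name="cell_type")
    if len(bands) != len(types):
        raise InputError("band and type labels must be aligned")
    keep = bands.notna() & (types != UNASSIGNED) & types.notna()
    observed_types = sorted(types[keep].unique()) if keep.any() else []
    if not keep.any():
        warnings.warn("no assigned spot in any band", stacklevel=2)

    rows = []
    for band in band_order:
        sel = keep & (bands == band)
        n_band = int(sel.sum())
        for t in observed_types or [None]:
            if t is None:
                rows.append((band, None, 0, np.nan))
                continue
            n = int((types[sel] == t).sum())
            rows.append((band, t, n, n / n_band if n_band else np.nan))
    out = pd.DataFrame(rows, columns=["band", "cell_type", "n_spots", "proportion"])
    out.attrs["empty"] = not bool(keep.any())
    return out


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x, midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    return float(ranks[:n].sum() - n * (n + 1) / 2.0)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    For pooled sample sizes n+m <= 12 the exact two-sided p-value is
    obtained by enumerating all C(n+m, n) assignments of the pooled values
    (ties handled by midranks); larger samples use the normal
    approximation with continuity and tie corrections.

    Returns (U, p) with U the statistic of the first sample.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise InputError("both samples must be nonempty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n * m / 2.0

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return u_obs, 1.0

    if n + m <= EXACT_ENUM_MAX:
        ranks = stats.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        const = n * (n + 1) / 2.0
        hits = total = 0
        for idx in combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - const
            total += 1
            # tolerance guards float midrank sums in the comparison
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        return u_obs, hits / total

    _, counts = np.unique(pooled, return_counts=True)
    nn = n + m
    tie_term = (counts**3 - counts).sum() / (nn * (nn - 1))
    var = n * m / 12.0 * ((nn + 1) - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(max(z, 0.0)))
    return u_obs, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def normalize_log1p(counts, target_sum: float = 1e4) -> pd.DataFrame:
    """log1p of library-size-scaled counts (rows are observations)."""
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    arr = df.to_numpy(dtype=float)
    totals = arr.sum(axis=1, keepdims=True)
    scaled = np.divide(arr, np.where(totals > 0, totals, 1.0)) * target_sum
    return pd.DataFrame(np.log1p(scaled), index=df.index, columns=df.columns)


def differential_expression(
    counts_a,
    counts_b,
    normalized: bool = False,
    lfc_min: float = 1.5,
    alpha: float = 0.05,
    target_sum: float = 1e4,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two spot groups with BH correction.

    A gene is flagged iff |log2FC| >= ``lfc_min`` and BH-adjusted
    p < ``alpha``.  log2FC is the difference of group means of log1p
    normalized expression, rescaled to base 2.  Genes with zero variance
    in both groups get p = 1 (the fold change is still reported).
    """
    a = counts_a if isinstance(counts_a, pd.DataFrame) else pd.DataFrame(counts_a)
    b = counts_b if isinstance(counts_b, pd.DataFrame) else pd.DataFrame(counts_b)
    if list(a.columns) != list(b.columns):
        raise InputError("groups must share an identical gene set")
    if len(a) < 2 or len(b) < 2:
        raise InputError("each group needs >= 2 observations")
    if not normalized:
        a, b = normalize_log1p(a, target_sum), normalize_log1p(b, target_sum)
    xa, xb = a.to_numpy(dtype=float), b.to_numpy(dtype=float)

    mean_a, mean_b = xa.mean(axis=0), xb.mean(axis=0)
    log2fc = (mean_a - mean_b) / math.log(2.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(xa, xb, axis=0, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, 1.0, p)
    t = np.where(np.isfinite(t), t, 0.0)
    p_adj = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "flagged": (np.abs(log2fc) >= lfc_min) & (p_adj < alpha),
        },
        index=a.columns,
    )


class GeneSetScorer(BaseEstimator):
    """Per-spot gene-set score with expression-matched control subtraction.

    Genes are binned into ``n_bins`` by their mean expression across
    spots; for every set gene, ``ctrl_size`` control genes are drawn from
    its bin (set genes excluded), and the score is the mean expression of
    the set minus the mean of the pooled control genes.  ``method="mean"``
    skips the control and returns the raw set mean (raw means are depth-
    confounded, which is why matched control is the default).

    Parameters
    ----------
    gene_set : list of gene ids (missing genes dropped with a warning).
    n_bins : int, default 25.
    ctrl_size : int, default 50.
    seed : int, RNG seed for control sampling.
    method : {"matched", "mean"}.

    Attributes
    ----------
    genes_used_ : genes of the set present in the expression matrix.
    control_genes_ : pooled control genes (matched mode).
    """

    def __init__(self, gene_set, n_bins: int = 25, ctrl_size: int = 50,
                 seed: int = 0, method: str = "matched"):
        self.gene_set = gene_set
        self.n_bins = n_bins
        self.ctrl_size = ctrl_size
        self.seed = seed
        self.method = method

    def fit(self, X, y=None):
        if self.method not in ("matched", "mean"):
            raise ParameterError(f"unknown method {self.method!r}")
        expr = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        genes = [g for g in self.gene_set if g in expr.columns]
        missing = [g for g in self.gene_set if g not in expr.columns]
        if missing:
            warnings.warn(
                f"{len(missing)} gene-set genes absent from the matrix: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}",
                stacklevel=2,
            )
        if not genes:
            raise ParameterError("gene set empty after dropping missing genes")
        self.genes_used_ = genes
        self.control_genes_ = []
        if self.method == "matched":
            means = expr.mean(axis=0)
            ranks = means.rank(method="first")
            bins = pd.cut(ranks, bins=min(self.n_bins, len(ranks)), labels=False)
            rng = np.random.default_rng(self.seed)
            in_set = set(genes)
            ctrl: set[str] = set()
            for g in genes:
                pool = bins.index[(bins == bins[g]) & ~bins.index.isin(in_set)]
                if len(pool) == 0:
                    continue
                take = min(self.ctrl_size, len(pool))
                ctrl.update(rng.choice(pool, size=take, replace=False))
            self.control_genes_ = sorted(ctrl)
        return self

    def transform(self, X) -> pd.Series:
        expr = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        score = expr[self.genes_used_].mean(axis=1)
        if self.method == "matched" and self.control_genes_:
            score = score - expr[self.control_genes_].mean(axis=1)
        score.name = "gene_set_score"
        return score

    def fit_transform(self, X, y=None) -> pd.Series:
        return self.fit(X).transform(X)


def gene_set_score(expr, gene_set, n_bins: int = 25, ctrl_size: int = 50,
                   seed: int = 0, method: str = "matched") -> pd.Series:
    """Functional wrapper around :class:`GeneSetScorer`."""
    return GeneSetScorer(gene_set, n_bins=n_bins, ctrl_size=ctrl_size,
                         seed=seed, method=method).fit_transform(expr)


def compare_compositions(samples: dict, pairs=None) -> pd.DataFrame:
    """Rank-sum comparisons between labelled samples, BH over the family.

    ``samples`` maps a label (band, group ...) to a 1-D sample of values
    (e.g. per-section proportions of one cell type, or per-spot scores).
    ``pairs`` restricts the comparisons; default: all label pairs.
    """
    labels = list(samples)
    if pairs is None:
        pairs = list(combinations(labels, 2))
    rows = []
    for a, b in pairs:
        u, p = rank_sum_test(samples[a], samples[b])
        rows.append((a, b, len(np.atleast_1d(samples[a])),
                     len(np.atleast_1d(samples[b])), u, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "n_a", "n_b", "U", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else out["p"]
    return out
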