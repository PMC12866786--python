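"""Sliding-window copy-number burden scoring.

A simplified inferCNV-style procedure: genes are ordered along the genome
(chromosome, then ordinal position), per-spot log1p-normalized expression
is expressed relative to the mean profile of a normal reference population
(AT2 cells by default), and a centered 250-gene moving average — truncated
at chromosome boundaries so a window never spans two chromosomes —
smooths the relative profile.  Each spot is then summarized by a scalar
burden: the signed mean of the smoothed profile (higher = net gain) or
its mean square (total aberration), and groups of spots are compared with
the two-sided Mann-Whitney test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InputError, ParameterError
from .zonal import bh_adjust, normalize_log1p, rank_sum_test

__all__ = [
    "CNVConfig",
    "CNVProfile",
    "order_genes",
    "smooth_cnv",
    "cnv_burden",
    "compare_burden",
    "CNVScorer",
]


@dataclass(frozen=True)
class CNVConfig:
    """Parameters of the sliding-window CNV score.

    ``window_genes`` is the moving-average width (250 genes by default;
    even widths center on the gene with ``w//2`` genes to the left and
    ``w - 1 - w//2`` to the right).  Windows truncate at chromosome
    boundaries.  ``burden_stat`` picks the per-spot scalar.
    """

    window_genes: int = 250
    reference_label: str = "AT2"
    burden_stat: str = "signed_mean"

    def __post_init__(self) -> None:
        if self.window_genes < 3:
            raise ParameterError("window_genes must be >= 3")
        if self.burden_stat not in ("signed_mean", "mean_square"):
            raise ParameterError("burden_stat must be signed_mean|mean_square")


@dataclass
class CNVProfile:
    """Smoothed reference-relative profiles plus per-spot burden."""

    profile: pd.DataFrame  # spot × genome-ordered genes
    burden: pd.Series
    gene_order: pd.DataFrame  # gene, chromosome, ordinal (genome order)


def _chrom_sort_key(c: str):
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < chrX."""
    s = str(c)
    for pre in ("chr", "Chr", "CHR"):
        if s.startswith(pre):
            s = s[len(pre):]
            break
    return (0, int(s)) if s.isdigit() else (1, s)


def order_genes(annotation: pd.DataFrame,
                genes=None) -> tuple[pd.DataFrame, list[str]]:
    """Stable genome ordering by (chromosome, ordinal).

    ``annotation`` needs columns gene/chromosome/ordinal.  When ``genes``
    is given, only those genes are ordered and unannotated ones are
    dropped (returned separately, logged via a warning).  Duplicate
    (chromosome, ordinal) pairs are tie-broken by gene id with a warning.

    Returns (ordered annotation frame, dropped gene ids).
    """
    required = {"gene", "chromosome", "ordinal"}
    if not required.issubset(annotation.columns):
        raise InputError(f"annotation must have columns {sorted(required)}")
    ann = annotation.copy()
    dropped: list[str] = []
    if genes is not None:
        genes = list(genes)
        known = set(ann["gene"])
        dropped = [g for g in genes if g not in known]
        if dropped:
            warnings.warn(
                f"{len(dropped)} genes lack annotation and are excluded",
                stacklevel=2,
            )
        ann = ann[ann["gene"].isin(set(genes) - set(dropped))]
    if ann.duplicated(subset=["chromosome", "ordinal"]).any():
        warnings.warn(
            "duplicate (chromosome, ordinal) pairs: ties broken by gene id",
            stacklevel=2,
        )
    ann = ann.assign(_ck=ann["chromosome"].map(_chrom_sort_key))
    ann = ann.sort_values(["_ck", "ordinal", "gene"], kind="stable").drop(columns="_ck")
    return ann.reset_index(drop=True), dropped


def _moving_average_truncated(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over axis 1 with truncation at both ends.

    Window covers [i - w//2, i + (w - 1 - w//2)] clipped to the array; the
    divisor is the realized window length.
    """
    n = values.shape[1]
    left, right = window // 2, window - 1 - window // 2
    csum = np.cumsum(values, axis=1)
    csum = np.concatenate([np.zeros((values.shape[0], 1)), csum], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right, n - 1)
    return (csum[:, hi + 1] - csum[:, lo]) / (hi - lo + 1)


def smooth_cnv(expr: pd.DataFrame, reference: pd.Series,
               chromosomes, cfg: CNVConfig | None = None) -> pd.DataFrame:
    """Reference-relative smoothed profile.

    ``expr`` is spot × genome-ordered log-expression, ``reference`` the
    mean log-expression profile of the reference population on the same
    gene order, ``chromosomes`` the per-gene chromosome labels.  The
    moving average never crosses a chromosome boundary; chromosomes with
    fewer than 3 genes pass through unsmoothed (with a warning).
    """
    cfg = cfg or CNVConfig()
    if list(expr.columns) != list(reference.index):
        raise InputError("expr and reference must share the same gene order")
    chroms = np.asarray(chromosomes)
    if len(chroms) != expr.shape[1]:
        raise InputError("chromosomes must align with expr columns")
    rel = expr.to_numpy(dtype=float) - reference.to_numpy(dtype=float)[None, :]

    out = np.empty_like(rel)
    # preserve the input's chromosome block order
    _, first_idx = np.unique(chroms, return_index=True)
    for c in chroms[np.sort(first_idx)]:
        sel = chroms == c
        block = rel[:, sel]
        if block.shape[1] < 3:
            warnings.warn(
                f"chromosome {c} has {block.shape[1]} genes: left unsmoothed",
                stacklevel=2,
            )
            out[:, sel] = block
        else:
            out[:, sel] = _moving_average_truncated(block, cfg.window_genes)
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def cnv_burden(profile: pd.DataFrame, cfg: CNVConfig | None = None) -> pd.Series:
    """Per-spot scalar burden of a smoothed profile."""
    cfg = cfg or CNVConfig()
    arr = profile.to_numpy(dtype=float)
    if cfg.burden_stat == "signed_mean":
        vals = arr.mean(axis=1)
    else:
        vals = (arr**2).mean(axis=1)
    return pd.Series(vals, index=profile.index, name="cnv_burden")


def compare_burden(groups: dict) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of burden samples, BH-adjusted.

    ``groups`` maps a label to a 1-D sample of burden values.  A single
    group yields an empty table.
    """
    labels = [k for k in groups if len(np.atleast_1d(groups[k]))]
    if len(labels) < len(groups):
        raise InputError("every group must be nonempty")
    rows = []
    for a, b in combinations(labels, 2):
        u, p = rank_sum_test(groups[a], groups[b])
        rows.append((a, b, u, p))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "U", "p"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else out.get("p")
    return out


class CNVScorer(BaseEstimator):
    """Sliding-window CNV scorer with a normal-reference baseline.

    :meth:`fit` learns the genome gene order and the reference mean
    profile from spots labelled ``reference_label``; :meth:`transform`
    returns the smoothed reference-relative profile of any count matrix
    on the same genes; :meth:`score_burden` collapses profiles to the
    per-spot scalar burden.

    Parameters
    ----------
    window_genes : int, default 250
    reference_label : str, default "AT2"
    burden_stat : {"signed_mean", "mean_square"}
    target_sum : library-size scaling target for log1p normalization.

    Attributes
    ----------
    gene_order_ : ordered annotation frame (gene, chromosome, ordinal)
    reference_profile_ : mean log-expression of reference spots
    dropped_genes_ : genes excluded for missing annotation
    """

    def __init__(self, window_genes: int = 250, reference_label: str = "AT2",
                 burden_stat: str = "signed_mean", target_sum: float = 1e4):
        self.window_genes = window_genes
        self.reference_label = reference_label
        self.burden_stat = burden_stat
        self.target_sum = target_sum

    @property
    def _cfg(self) -> CNVConfig:
        return CNVConfig(window_genes=self.window_genes,
                         reference_label=self.reference_label,
                         burden_stat=self.burden_stat)

    def fit(self, X, annotation: pd.DataFrame, labels=None):
        """Learn gene order and reference profile.

        ``X`` is a spot × gene count matrix; reference spots are those
        whose entry in ``labels`` equals ``reference_label`` (``labels``
        may be omitted when every row of X is reference).
        """
        _ = self._cfg  # validates parameters
        counts = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        order, dropped = order_genes(annotation, genes=list(counts.columns))
        self.gene_order_ = order
        self.dropped_genes_ = dropped
        ordered_genes = order["gene"].tolist()
        expr = normalize_log1p(counts, self.target_sum)[ordered_genes]
        if labels is None:
            ref = expr
        else:
            mask = np.asarray(labels) == self.reference_label
            if not mask.any():
                raise ParameterError(
                    f"no spot labelled {self.reference_label!r} for reference"
                )
            ref = expr.loc[mask]
        self.reference_profile_ = ref.mean(axis=0)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Smoothed reference-relative profile for a count matrix."""
        if not hasattr(self, "reference_profile_"):
            raise RuntimeError("fit the scorer first")
        counts = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        genes = self.gene_order_["gene"].tolist()
        expr = normalize_log1p(counts, self.target_sum)[genes]
        return smooth_cnv(expr, self.reference_profile_,
                          self.gene_order_["chromosome"].to_numpy(), self._cfg)

    def score_burden(self, X) -> pd.Series:
        """Per-spot burden of a count matrix (transform then summarize)."""
        return cnv_burden(self.transform(X), self._cfg)

    def profile(self, X, labels=None) -> CNVProfile:
        """Convenience: full :class:`CNVProfile` for a count matrix."""
        prof = self.transform(X)
        return CNVProfile(profile=prof, burden=cnv_burden(prof, self._cfg),
                          gene_order=self.gene_order_.copy())
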