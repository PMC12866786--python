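"""Quality control and ratio-threshold spot-to-cell-type assignment.

Single-cell QC removes cells with fewer than 200 or more than 2500
expressed genes or more than 5% mitochondrial transcripts, then genes
expressed in fewer than 3 retained cells.  Spatial QC removes spots whose
detected-gene count falls strictly below the section's 5th percentile,
then genes detected in fewer than 10 retained spots.

Assignment takes a deconvolved spot × cell-type abundance matrix,
normalizes each spot to a 0-1 scale (division by the row maximum), and
assigns each spot to its dominant cell type provided the ratio of the
dominant to the second-highest abundance strictly exceeds the q-th
percentile (default q = 10) of the finite-ratio distribution across all
spots in the section; otherwise the spot is left UNASSIGNED.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import InputError, ParameterError

__all__ = [
    "QCConfig",
    "QCResult",
    "AssignmentResult",
    "UNASSIGNED",
    "qc_filter_cells",
    "qc_filter_spots",
    "normalize_abundance",
    "assign_spots",
    "SpotTypeAssigner",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class QCConfig:
    """QC thresholds.

    ``min_genes_per_cell``/``max_genes_per_cell``/``max_mito_fraction``/
    ``min_cells_per_gene`` drive single-cell filtering;
    ``spot_gene_count_percentile``/``min_spots_per_gene`` drive spatial
    filtering.  A gene counts as "expressed" when its count is > 0.
    """

    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 2500
    max_mito_fraction: float = 0.05
    min_cells_per_gene: int = 3
    spot_gene_count_percentile: float = 5.0
    min_spots_per_gene: int = 10

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ParameterError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0.0 <= self.spot_gene_count_percentile <= 100.0:
            raise ParameterError("percentile must lie in [0, 100]")


@dataclass
class QCResult:
    """Filtered counts plus a per-removal log.

    ``empty`` is True when no observation survived; this is reported as a
    flag rather than raised, so pipelines can skip downstream stages.
    """

    counts: pd.DataFrame
    removed: pd.DataFrame  # columns: id, kind ("cell"/"spot"/"gene"), reason
    empty: bool = False


def _as_frame(counts, axis_name: str) -> pd.DataFrame:
    df = counts if isinstance(counts, pd.DataFrame) else pd.DataFrame(counts)
    arr = df.to_numpy()
    if np.any(arr < 0):
        raise InputError(f"{axis_name} counts must be nonnegative")
    return df


def qc_filter_cells(counts, mito_flags, cfg: QCConfig | None = None) -> QCResult:
    """Single-cell QC: cell filters first, then the gene-prevalence filter.

    Parameters
    ----------
    counts : (cells × genes) DataFrame or array of nonnegative integers.
    mito_flags : boolean per gene, aligned with the columns of ``counts``.
    """
    cfg = cfg or QCConfig()
    df = _as_frame(counts, "cell")
    mito = np.asarray(mito_flags, dtype=bool)
    if mito.shape[0] != df.shape[1]:
        raise InputError("mito_flags length must equal the number of genes")

    expressed = (df.to_numpy() > 0).sum(axis=1)
    totals = df.to_numpy().sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, df.to_numpy()[:, mito].sum(axis=1) / np.maximum(totals, 1), 0.0)

    log = []
    keep_cell = np.ones(df.shape[0], dtype=bool)
    for i, cell in enumerate(df.index):
        if expressed[i] < cfg.min_genes_per_cell:
            keep_cell[i] = False
            log.append((cell, "cell", f"expressed genes {expressed[i]} < {cfg.min_genes_per_cell}"))
        elif expressed[i] > cfg.max_genes_per_cell:
            keep_cell[i] = False
            log.append((cell, "cell", f"expressed genes {expressed[i]} > {cfg.max_genes_per_cell}"))
        elif mito_frac[i] > cfg.max_mito_fraction:
            keep_cell[i] = False
            log.append((cell, "cell", f"mito fraction {mito_frac[i]:.4f} > {cfg.max_mito_fraction}"))

    kept = df.loc[keep_cell]
    cells_per_gene = (kept.to_numpy() > 0).sum(axis=0)
    keep_gene = cells_per_gene >= cfg.min_cells_per_gene
    for j, gene in enumerate(df.columns):
        if not keep_gene[j]:
            log.append((gene, "gene", f"expressed in {cells_per_gene[j]} < {cfg.min_cells_per_gene} cells"))
    out = kept.loc[:, keep_gene]
    return QCResult(
        counts=out,
        removed=pd.DataFrame(log, columns=["id", "kind", "reason"]),
        empty=out.shape[0] == 0 or out.shape[1] == 0,
    )


def qc_filter_spots(counts, cfg: QCConfig | None = None) -> QCResult:
    """Spatial QC for one tissue section.

    Spots whose detected-gene count is strictly below the section's
    ``spot_gene_count_percentile`` (linear-interpolation percentile) are
    removed; genes detected in fewer than ``min_spots_per_gene`` retained
    spots are then removed.
    """
    cfg = cfg or QCConfig()
    df = _as_frame(counts, "spot")
    if df.shape[0] < 20:
        warnings.warn(
            f"section has only {df.shape[0]} spots; percentile threshold "
            "is poorly determined",
            stacklevel=2,
        )
    detected = (df.to_numpy() > 0).sum(axis=1)
    thresh = float(np.percentile(detected, cfg.spot_gene_count_percentile))
    keep_spot = detected >= thresh  # strictly-below spots removed

    log = [
        (spot, "spot", f"detected genes {detected[i]} < p{cfg.spot_gene_count_percentile:g} = {thresh:g}")
        for i, spot in enumerate(df.index)
        if not keep_spot[i]
    ]
    kept = df.loc[keep_spot]
    spots_per_gene = (kept.to_numpy() > 0).sum(axis=0)
    keep_gene = spots_per_gene >= cfg.min_spots_per_gene
    for j, gene in enumerate(df.columns):
        if not keep_gene[j]:
            log.append((gene, "gene", f"detected in {spots_per_gene[j]} < {cfg.min_spots_per_gene} spots"))
    out = kept.loc[:, keep_gene]
    return QCResult(
        counts=out,
        removed=pd.DataFrame(log, columns=["id", "kind", "reason"]),
        empty=out.shape[0] == 0 or out.shape[1] == 0,
    )


def normalize_abundance(abundance) -> tuple[pd.DataFrame, np.ndarray]:
    """Scale each spot's abundances to [0, 1] by its row maximum.

    Returns the normalized frame and a boolean mask of all-zero rows
    (left as zeros, flagged for exclusion from assignment).
    """
    df = abundance if isinstance(abundance, pd.DataFrame) else pd.DataFrame(abundance)
    arr = df.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise InputError("abundances must be nonnegative")
    rowmax = arr.max(axis=1)
    zero = rowmax == 0
    scaled = np.divide(arr, np.where(zero, 1.0, rowmax)[:, None])
    return pd.DataFrame(scaled, index=df.index, columns=df.columns), zero


@dataclass
class AssignmentResult:
    """Per-spot assignment under the dominant/second ratio rule."""

    table: pd.DataFrame  # spot_id index; assigned_type, dominant_abundance,
    #                      second_abundance, ratio, assigned
    ratio_threshold: float | None
    threshold_percentile: float
    warnings: list[str] = field(default_factory=list)

    @property
    def assigned_fraction(self) -> float:
        return float(self.table["assigned"].mean())


class SpotTypeAssigner(BaseEstimator):
    """Assign spots to cell types by the dominant/second abundance ratio.

    The section-level ratio threshold (the ``q``-th percentile of the
    finite-ratio distribution) is learned in :meth:`fit`; :meth:`predict`
    returns the per-spot cell-type call, with ``UNASSIGNED`` for spots
    whose ratio does not strictly exceed the threshold.

    Parameters
    ----------
    q : float in [0, 100)
        Percentile of the finite-ratio distribution used as threshold.
    pre_normalized : bool
        If False (default), abundances are 0-1 normalized per spot first.
        The ratio is scale-free, so this does not change the calls.

    Attributes
    ----------
    ratio_threshold_ : float or None
        Learned threshold; None when no finite ratio exists (every spot is
        then assigned).
    result_ : AssignmentResult
        Full per-spot table for the fitted section.
    """

    def __init__(self, q: float = 10.0, pre_normalized: bool = False):
        self.q = q
        self.pre_normalized = pre_normalized

    def fit(self, X, y=None):
        if not 0.0 <= self.q < 100.0:
            raise ParameterError("q must lie in [0, 100)")
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        if self.pre_normalized:
            norm, zero = df.copy(), df.to_numpy().max(axis=1) == 0
            if np.any(norm.to_numpy() < 0):
                raise InputError("abundances must be nonnegative")
        else:
            norm, zero = normalize_abundance(df)
        arr = norm.to_numpy(dtype=float)
        n, k = arr.shape
        msgs: list[str] = []

        order = np.argsort(arr, axis=1)
        dom_idx = order[:, -1]
        dominant = arr[np.arange(n), dom_idx]
        second = arr[np.arange(n), order[:, -2]] if k >= 2 else np.zeros(n)
        if k < 2:
            msgs.append("single cell type: all ratios infinite, all spots assigned")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(second > 0, dominant / np.maximum(second, 1e-300), np.inf)
        ratio = np.where(dominant > 0, ratio, np.nan)  # all-zero spots: undefined

        finite = np.isfinite(ratio)
        if finite.any():
            threshold = float(np.percentile(ratio[finite], self.q))
            assigned = ratio > threshold  # strict; NaN compares False
            if not assigned[finite].any():
                msgs.append("all finite-ratio spots at or below threshold: none assigned")
        else:
            threshold = None
            assigned = ~np.isnan(ratio)
            msgs.append("no finite ratio in section: threshold undefined, all spots assigned")
        if np.isinf(ratio).any():
            assigned = assigned | np.isinf(ratio)
        assigned = assigned & ~zero

        types = np.array(norm.columns, dtype=object)
        labels = types[dom_idx].copy()
        labels[~assigned] = UNASSIGNED
        for m in msgs:
            warnings.warn(m, stacklevel=2)

        self.ratio_threshold_ = threshold
        self.cell_types_ = list(norm.columns)
        self.result_ = AssignmentResult(
            table=pd.DataFrame(
                {
                    "assigned_type": labels,
                    "dominant_abundance": dominant,
                    "second_abundance": second,
                    "ratio": ratio,
                    "assigned": assigned,
                },
                index=norm.index,
            ),
            ratio_threshold=threshold,
            threshold_percentile=self.q,
            warnings=msgs,
        )
        return self

    def predict(self, X=None) -> np.ndarray:
        """Cell-type call per spot of the fitted section."""
        if not hasattr(self, "result_"):
            raise RuntimeError("fit the assigner first")
        if X is not None:
            return SpotTypeAssigner(q=self.q, pre_normalized=self.pre_normalized).fit(X).predict()
        return self.result_.table["assigned_type"].to_numpy(dtype=object)


def assign_spots(abundance, q: float = 10.0,
                 pre_normalized: bool = True) -> AssignmentResult:
    """Functional wrapper around :class:`SpotTypeAssigner`.

    Expects abundances already normalized to a 0-1 scale per spot (set
    ``pre_normalized=False`` to normalize here).
    """
    return SpotTypeAssigner(q=q, pre_normalized=pre_normalized).fit(abundance).result_
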