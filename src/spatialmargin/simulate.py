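"""Synthetic spatial-transcriptomics sections with planted ground truth.

The generator emulates a Stereo-seq-style section binned into 50-µm spots:
a rectangular spot grid, per-spot mixed cell-type abundances with a planted
tumor region where a malignant "AT2-like" population dominates, exponential
stromal gradients at the tumor border, negative-binomial counts drawn from
cell-type signature profiles, and contiguous CNV gain/loss gene blocks in
tumor spots.  Every downstream stage (assignment, border detection, zonal
statistics, CNV scoring) therefore has an analytic ground truth to recover.

Coordinates are µm, origin at the bottom-left corner, y increasing upward.
Spot centers sit at ((i + 1/2)·pitch, (j + 1/2)·pitch).  All randomness
flows from a single scene seed; each stage draws from a deterministically
derived substream, and counts are drawn per spot so that re-drawing one
spot (e.g. after planting a CNV) leaves every other spot bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from .exceptions import ParameterError, SceneError

__all__ = [
    "SignaturePanel",
    "GradientSpec",
    "CNVBlock",
    "Scene",
    "SpatialSection",
    "disk",
    "make_signature_panel",
    "simulate_section",
    "plant_cnv",
    "signed_band_label",
    "BAND_LABELS",
    "TUMOR_BANDS",
    "NORMAL_BANDS",
]

#: Zonal band labels, normal side outward to tumor side inward.
NORMAL_BANDS = ("NR1", "NR2", "NR3")
TUMOR_BANDS = ("TR1", "TR2", "TR3")
BAND_LABELS = ("NR3", "NR2", "NR1", "TR1", "TR2", "TR3")

_DEFAULT_TYPE_NAMES = (
    "AT2",
    "AT2-like",
    "Fibroblast",
    "Macrophage",
    "Tcell",
    "Bcell",
    "Endothelial",
    "NK",
)

# RNG substream tags (SeedSequence entropy suffixes)
_SS_LIBRARY = 1
_SS_NOISE = 2
_SS_COUNTS = 3


@dataclass(frozen=True)
class SignaturePanel:
    """Cell-type expression signatures over an artificial genome.

    Plays the role of the scRNA-seq reference a deconvolution method would
    use: each cell type owns a disjoint block of elevated marker genes.

    Attributes
    ----------
    genes : list of str
        Unique gene identifiers, genome order.
    chrom : ndarray of str
        Chromosome label per gene.
    ord_pos : ndarray of int
        Ordinal genomic position, strictly increasing within a chromosome.
    mito_flag : ndarray of bool
        True for mitochondrial genes (used by QC).
    mu : ndarray, shape (n_genes, n_types)
        Non-negative mean expression per gene and cell type.
    dispersion : ndarray, shape (n_genes,)
        Negative-binomial size parameter per gene (larger = closer to
        Poisson); ``np.inf`` selects exact Poisson sampling.
    cell_types : list of str
        Cell-type names, columns of ``mu``.
    """

    genes: list[str]
    chrom: np.ndarray
    ord_pos: np.ndarray
    mito_flag: np.ndarray
    mu: np.ndarray
    dispersion: np.ndarray
    cell_types: list[str]

    def __post_init__(self) -> None:
        n = len(self.genes)
        if len(set(self.genes)) != n:
            raise ParameterError("gene ids must be unique")
        if self.mu.shape != (n, len(self.cell_types)):
            raise ParameterError("mu shape must be (n_genes, n_types)")
        if np.any(self.mu < 0):
            raise ParameterError("mu must be nonnegative")
        if np.any(self.dispersion <= 0):
            raise ParameterError("dispersion must be positive")
        for c in np.unique(self.chrom):
            pos = self.ord_pos[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ParameterError(
                    f"ord_pos must be strictly increasing within {c}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_types(self) -> int:
        return len(self.cell_types)

    def annotation_frame(self):
        """Gene annotation table (gene, chromosome, ordinal, mito)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "gene": self.genes,
                "chromosome": self.chrom,
                "ordinal": self.ord_pos,
                "mito": self.mito_flag,
            }
        )


@dataclass(frozen=True)
class GradientSpec:
    """Peri-tumoral abundance gradient for one cell type.

    The type's mixing weight is boosted by ``peak_fraction * exp(-d/decay)``
    where d is the distance (µm) from the tumor borderline, applied on the
    requested side only.
    """

    cell_type: str
    side: str  # "tumor" | "normal"
    decay_um: float
    peak_fraction: float

    def __post_init__(self) -> None:
        if self.side not in ("tumor", "normal"):
            raise ParameterError(f"side must be tumor|normal, got {self.side!r}")
        if not 0.0 < self.peak_fraction < 1.0:
            raise SceneError("peak_fraction must lie in (0, 1)")
        if self.decay_um <= 0:
            raise ParameterError("decay_um must be positive")


@dataclass(frozen=True)
class CNVBlock:
    """Contiguous copy-number block: genes on ``chrom`` with ordinal in
    [start_ord, end_ord] get their expected counts multiplied by ``factor``
    in tumor spots (factor > 1 = gain, < 1 = loss)."""

    chrom: str
    start_ord: int
    end_ord: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise SceneError("CNV factor must be > 0")
        if self.end_ord < self.start_ord:
            raise ParameterError("end_ord must be >= start_ord")


def disk(center_x_um: float, center_y_um: float, radius_um: float,
         quad_segs: int = 128) -> Polygon:
    """Circular tumor region as a finely discretized polygon."""
    if radius_um <= 0:
        raise ParameterError("radius must be positive")
    return Point(center_x_um, center_y_um).buffer(radius_um, quad_segs=quad_segs)


@dataclass(frozen=True)
class Scene:
    """Description of a synthetic tissue section.

    The tumor region must keep >= 1500 µm clearance to every section edge
    so that all six 500-µm zonal bands fit inside the tissue.
    """

    width_um: float
    height_um: float
    tumor_region: Polygon
    pitch_um: float = 50.0
    gradient_specs: tuple[GradientSpec, ...] = ()
    cnv_blocks: tuple[CNVBlock, ...] = ()
    seed: int = 0
    tumor_type: str = "AT2-like"
    normal_type: str = "AT2"
    tumor_purity: float = 0.7
    normal_dominance: float = 0.55
    library_size_median: float = 3000.0
    library_size_sigma: float = 0.35
    abundance_noise_sigma: float = 0.0
    band_offsets: tuple[float, ...] = (500.0, 1000.0, 1500.0)

    def __post_init__(self) -> None:
        if self.pitch_um <= 0 or self.width_um <= 0 or self.height_um <= 0:
            raise SceneError("section extent and pitch must be positive")
        object.__setattr__(self, "gradient_specs", tuple(self.gradient_specs))
        object.__setattr__(self, "cnv_blocks", tuple(self.cnv_blocks))

    def validate(self) -> None:
        """Raise :class:`SceneError` on invariant violations."""
        clear = max(self.band_offsets) if self.band_offsets else 1500.0
        minx, miny, maxx, maxy = self.tumor_region.bounds
        if (minx < clear or miny < clear
                or maxx > self.width_um - clear or maxy > self.height_um - clear):
            raise SceneError(
                f"tumor region must keep >= {clear:g} um clearance to every "
                f"section edge (bounds {self.tumor_region.bounds})"
            )
        if not self.tumor_region.is_valid or self.tumor_region.area <= 0:
            raise SceneError("tumor region must be a valid nonempty polygon")

    @property
    def n_spots_x(self) -> int:
        return int(math.floor(self.width_um / self.pitch_um))

    @property
    def n_spots_y(self) -> int:
        return int(math.floor(self.height_um / self.pitch_um))


@dataclass
class SpatialSection:
    """A simulated (or loaded) spatial section.

    Attributes
    ----------
    spot_ids : list of str
    x_um, y_um : ndarray
        Spot-center coordinates, µm.
    counts : ndarray, shape (n_spots, n_genes)
        Non-negative integer counts.
    abundance : ndarray, shape (n_spots, n_types)
        Per-spot cell-type abundances (as an external deconvolution would
        estimate them; may carry estimation noise).
    genes, cell_types : list of str
    truth_type : ndarray of str or None
        Dominant ground-truth cell type per spot (simulated sections only).
    truth_band : ndarray of object or None
        Ground-truth zonal band (NR3..TR3) or None, from the exact signed
        distance to the planted tumor boundary.
    true_abundance : ndarray or None
        Noise-free mixing weights the counts were drawn from.
    library_size : ndarray or None
        Expected transcript total per spot.
    seed : int or None
        Scene seed the section was drawn with.
    """

    spot_ids: list[str]
    x_um: np.ndarray
    y_um: np.ndarray
    counts: np.ndarray
    abundance: np.ndarray
    genes: list[str]
    cell_types: list[str]
    truth_type: np.ndarray | None = None
    truth_band: np.ndarray | None = None
    true_abundance: np.ndarray | None = None
    library_size: np.ndarray | None = None
    seed: int | None = None
    pitch_um: float | None = None

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def counts_frame(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=self.spot_ids, columns=self.genes)

    def abundance_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.abundance, index=self.spot_ids, columns=self.cell_types
        )


def make_signature_panel(
    n_genes: int,
    n_types: int,
    n_chroms: int,
    mito_fraction: float = 0.02,
    seed: int = 0,
    cell_types: list[str] | None = None,
    marker_block_size: int = 10,
    marker_fold: float = 8.0,
) -> SignaturePanel:
    """Generate cell-type signatures over an artificial genome.

    Each cell type receives a disjoint block of ``marker_block_size``
    consecutive genes whose mean expression is ``marker_fold`` times the
    baseline, guaranteeing distinguishable signatures.  Genes are split
    into ``n_chroms`` contiguous chromosomes of near-equal size.

    Raises
    ------
    ParameterError
        If ``n_genes < n_types * 10`` or ``mito_fraction`` is outside
        [0, 0.5).
    """
    if n_genes < n_types * 10:
        raise ParameterError("n_genes must be >= 10 * n_types")
    if not (0.0 <= mito_fraction < 0.5):
        raise ParameterError("mito_fraction must lie in [0, 0.5)")
    if min(n_genes, n_types, n_chroms) < 1:
        raise ParameterError("counts must be positive")
    if cell_types is None:
        cell_types = [
            _DEFAULT_TYPE_NAMES[i] if i < len(_DEFAULT_TYPE_NAMES) else f"Type{i + 1}"
            for i in range(n_types)
        ]
    if len(cell_types) != n_types:
        raise ParameterError("cell_types length must equal n_types")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"G{i + 1:0{width}d}" for i in range(n_genes)]

    # contiguous chromosomes of near-equal size, ordinal restarting at 1
    sizes = np.full(n_chroms, n_genes // n_chroms)
    sizes[: n_genes % n_chroms] += 1
    chrom = np.repeat([f"chr{c + 1}" for c in range(n_chroms)], sizes)
    ord_pos = np.concatenate([np.arange(1, s + 1) for s in sizes])

    mu = rng.lognormal(mean=0.0, sigma=0.5, size=(n_genes, n_types))
    # disjoint marker blocks, spread across the genome
    stride = n_genes // n_types
    marker_of = np.full(n_genes, -1)
    for t in range(n_types):
        start = t * stride
        block = slice(start, start + marker_block_size)
        mu[block, t] *= marker_fold
        marker_of[block] = t

    n_mito = int(math.floor(mito_fraction * n_genes))
    mito_flag = np.zeros(n_genes, dtype=bool)
    if n_mito:
        non_marker = np.flatnonzero(marker_of < 0)
        pool = non_marker if len(non_marker) >= n_mito else np.arange(n_genes)
        mito_flag[rng.choice(pool, size=n_mito, replace=False)] = True

    dispersion = rng.lognormal(mean=np.log(2.0), sigma=0.4, size=n_genes)
    return SignaturePanel(
        genes=genes,
        chrom=chrom,
        ord_pos=ord_pos,
        mito_flag=mito_flag,
        mu=mu,
        dispersion=dispersion,
        cell_types=list(cell_types),
    )


def signed_band_label(
    inside: np.ndarray,
    dist_um: np.ndarray,
    offsets: tuple[float, ...] = (500.0, 1000.0, 1500.0),
) -> np.ndarray:
    """Zonal band label from exact signed distance to the borderline.

    Tumor-side intervals are half-open ``[off_{k-1}, off_k)`` (a point on
    the borderline itself is TR1); normal-side intervals are
    ``(off_{k-1}, off_k]``.  Points farther than the outermost offset on
    either side get ``None``.
    """
    inside = np.asarray(inside, dtype=bool)
    dist_um = np.asarray(dist_um, dtype=float)
    labels = np.full(inside.shape, None, dtype=object)
    edges = (0.0, *offsets)
    for k in range(len(offsets)):
        tr = inside & (dist_um >= edges[k]) & (dist_um < edges[k + 1])
        nr = ~inside & (dist_um > edges[k]) & (dist_um <= edges[k + 1])
        labels[tr] = f"TR{k + 1}"
        labels[nr] = f"NR{k + 1}"
    return labels


def _grid_points(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = scene.n_spots_x, scene.n_spots_y
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = (ix.ravel() + 0.5) * scene.pitch_um
    y = (iy.ravel() + 0.5) * scene.pitch_um
    return x, y


def _composition(scene: Scene, panel: SignaturePanel,
                 x: np.ndarray, y: np.ndarray):
    """Noise-free mixing weights, tumor mask and signed distances."""
    types = panel.cell_types
    if scene.tumor_type not in types or scene.normal_type not in types:
        raise SceneError(
            "panel cell types must include the scene's tumor and normal types"
        )
    t_idx = {t: i for i, t in enumerate(types)}
    pts = shapely.points(x, y)
    inside = shapely.covers(scene.tumor_region, pts)
    dist = shapely.distance(pts, scene.tumor_region.exterior)

    n = len(x)
    k = len(types)
    w = np.empty((n, k))
    # background mixture: dominant type plus a uniform remainder
    others = max(k - 1, 1)
    w[~inside] = (1.0 - scene.normal_dominance) / others
    w[~inside, t_idx[scene.normal_type]] = scene.normal_dominance
    w[inside] = (1.0 - scene.tumor_purity) / others
    w[inside, t_idx[scene.tumor_type]] = scene.tumor_purity

    for g in scene.gradient_specs:
        if g.cell_type not in t_idx:
            raise SceneError(f"gradient cell type {g.cell_type!r} not in panel")
        mask = inside if g.side == "tumor" else ~inside
        w[mask, t_idx[g.cell_type]] += g.peak_fraction * np.exp(
            -dist[mask] / g.decay_um
        )
    w /= w.sum(axis=1, keepdims=True)
    return w, inside, dist


def _cnv_gene_mask(panel: SignaturePanel, blocks) -> np.ndarray:
    """Per-gene multiplicative CNV factor; validates block coordinates."""
    factors = np.ones(panel.n_genes)
    chroms = set(np.unique(panel.chrom))
    for b in blocks:
        if b.chrom not in chroms:
            raise ParameterError(f"CNV block chromosome {b.chrom!r} unknown")
        on_chrom = panel.chrom == b.chrom
        lo, hi = panel.ord_pos[on_chrom].min(), panel.ord_pos[on_chrom].max()
        if b.start_ord < lo or b.end_ord > hi:
            raise ParameterError(
                f"CNV block [{b.start_ord}, {b.end_ord}] outside {b.chrom} "
                f"ordinal range [{lo}, {hi}]"
            )
        sel = on_chrom & (panel.ord_pos >= b.start_ord) & (panel.ord_pos <= b.end_ord)
        factors[sel] *= b.factor
    return factors


def _spot_rng(seed: int, spot_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, _SS_COUNTS, spot_index)))


def _draw_counts(mean: np.ndarray, dispersion: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """NB(mean, size=dispersion) via gamma-Poisson; inf dispersion = Poisson."""
    finite = np.isfinite(dispersion)
    lam = np.array(mean, dtype=float)
    if finite.any():
        r = dispersion[finite]
        lam[finite] = rng.gamma(shape=r, scale=np.maximum(mean[finite], 0.0) / r)
    return rng.poisson(lam)


def simulate_section(scene: Scene, panel: SignaturePanel) -> SpatialSection:
    """Simulate a section on the scene's spot grid.

    The expected count of gene g in spot s is
    ``L_s * sum_t A_{s,t} * mu_norm_{g,t}`` where ``L_s`` is a log-normal
    library size, ``A`` the noise-free mixing weights (rows sum to 1) and
    ``mu_norm`` the panel signatures normalized to sum to 1 per cell type;
    counts are negative-binomial with the panel's per-gene dispersion.
    CNV blocks declared in the scene are NOT applied here — use
    :func:`plant_cnv` on the result.
    """
    scene.validate()
    x, y = _grid_points(scene)
    n_spots = len(x)
    w, inside, dist = _composition(scene, panel, x, y)
    truth_type = np.array(panel.cell_types, dtype=object)[np.argmax(w, axis=1)]
    truth_band = signed_band_label(inside, dist, scene.band_offsets)

    rng_lib = np.random.default_rng(np.random.SeedSequence((scene.seed, _SS_LIBRARY)))
    library = rng_lib.lognormal(
        mean=np.log(scene.library_size_median),
        sigma=scene.library_size_sigma,
        size=n_spots,
    )

    mu_norm = panel.mu / panel.mu.sum(axis=0, keepdims=True)
    mean_expr = (w @ mu_norm.T) * library[:, None]

    counts = np.empty((n_spots, panel.n_genes), dtype=np.int64)
    for s in range(n_spots):
        counts[s] = _draw_counts(mean_expr[s], panel.dispersion, _spot_rng(scene.seed, s))

    abundance = w
    if scene.abundance_noise_sigma > 0:
        rng_noise = np.random.default_rng(
            np.random.SeedSequence((scene.seed, _SS_NOISE))
        )
        abundance = np.clip(
            w + rng_noise.normal(0.0, scene.abundance_noise_sigma, size=w.shape),
            0.0,
            None,
        )

    width = len(str(n_spots))
    spot_ids = [f"s{i + 1:0{width}d}" for i in range(n_spots)]
    return SpatialSection(
        spot_ids=spot_ids,
        x_um=x,
        y_um=y,
        counts=counts,
        abundance=abundance,
        genes=list(panel.genes),
        cell_types=list(panel.cell_types),
        truth_type=truth_type,
        truth_band=truth_band,
        true_abundance=w,
        library_size=library,
        seed=scene.seed,
        pitch_um=scene.pitch_um,
    )


def plant_cnv(section: SpatialSection, panel: SignaturePanel,
              scene: Scene) -> SpatialSection:
    """Apply the scene's CNV blocks to tumor-truth spots.

    Counts of tumor spots (truth type == scene.tumor_type) are re-drawn
    from the same per-spot RNG substreams with the expected counts of
    block genes multiplied by the block factor; all other spots keep their
    counts bit-identically, and a factor of 1.0 reproduces the input
    section exactly.
    """
    if section.truth_type is None or section.library_size is None:
        raise ParameterError("plant_cnv requires a simulated section")
    factors = _cnv_gene_mask(panel, scene.cnv_blocks)
    x, y = section.x_um, section.y_um
    w, _, _ = _composition(scene, panel, x, y)
    mu_norm = panel.mu / panel.mu.sum(axis=0, keepdims=True)
    base_mean = (w @ mu_norm.T) * section.library_size[:, None]

    tumor = section.truth_type == scene.tumor_type
    counts = section.counts.copy()
    for s in np.flatnonzero(tumor):
        counts[s] = _draw_counts(
            base_mean[s] * factors, panel.dispersion, _spot_rng(scene.seed, s)
        )
    return replace(section, counts=counts)
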