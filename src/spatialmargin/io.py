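"""Readers and writers for the pipeline's on-disk formats.

Sections travel as a spot table TSV (spot_id, x_um, y_um, truth columns
when simulated), a MatrixMarket counts matrix with sidecar barcodes /
features text files, an abundance TSV and a panel/annotation TSV.  Band
geometry is written as GeoJSON (µm coordinates, borderline as LineString,
bands as labelled polygons).  Scenes round-trip through a small YAML
document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse
from shapely.geometry import mapping, shape

from .exceptions import InputError
from .geometry import BandSet
from .simulate import CNVBlock, GradientSpec, Scene, SpatialSection, disk

__all__ = [
    "write_section",
    "read_section",
    "write_bands_geojson",
    "read_bands_geojson",
    "scene_from_yaml",
    "scene_to_yaml",
    "read_gene_list",
    "validate_inputs",
]


def write_section(section: SpatialSection, out_dir, panel=None) -> dict:
    """Write a section to ``out_dir``; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spots = pd.DataFrame(
        {
            "spot_id": section.spot_ids,
            "x_um": section.x_um,
            "y_um": section.y_um,
        }
    )
    if section.truth_type is not None:
        spots["truth_type"] = section.truth_type
    if section.truth_band is not None:
        spots["truth_band"] = [b if b is not None else "" for b in section.truth_band]
    paths = {
        "spots": out / "spots.tsv",
        "counts": out / "counts.mtx",
        "barcodes": out / "barcodes.tsv",
        "features": out / "features.tsv",
        "abundance": out / "abundance.tsv",
    }
    spots.to_csv(paths["spots"], sep="\t", index=False)
    spio.mmwrite(paths["counts"], sparse.csr_matrix(section.counts))
    Path(paths["barcodes"]).write_text("\n".join(section.spot_ids) + "\n")
    Path(paths["features"]).write_text("\n".join(section.genes) + "\n")
    section.abundance_frame().rename_axis("spot_id").to_csv(
        paths["abundance"], sep="\t"
    )
    if panel is not None:
        paths["panel"] = out / "panel.tsv"
        panel.annotation_frame().to_csv(paths["panel"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def read_section(in_dir) -> SpatialSection:
    """Read a section previously written by :func:`write_section`."""
    d = Path(in_dir)
    spots = pd.read_csv(d / "spots.tsv", sep="\t")
    barcodes = (d / "barcodes.tsv").read_text().split()
    features = (d / "features.tsv").read_text().split()
    counts = np.asarray(spio.mmread(d / "counts.mtx").todense())
    ab = pd.read_csv(d / "abundance.tsv", sep="\t", index_col=0)
    if list(ab.index) != barcodes or list(spots["spot_id"]) != barcodes:
        raise InputError("spot ids disagree between spots/abundance/barcodes")
    truth_type = spots["truth_type"].to_numpy(dtype=object) if "truth_type" in spots else None
    truth_band = None
    if "truth_band" in spots:
        tb = spots["truth_band"].fillna("").astype(str).to_numpy(dtype=object)
        truth_band = np.where(tb == "", None, tb)
    xs = spots["x_um"].to_numpy(dtype=float)
    pitch = float(np.min(np.diff(np.unique(xs)))) if len(np.unique(xs)) > 1 else None
    return SpatialSection(
        spot_ids=barcodes,
        x_um=xs,
        y_um=spots["y_um"].to_numpy(dtype=float),
        counts=counts.astype(np.int64),
        abundance=ab.to_numpy(dtype=float),
        genes=features,
        cell_types=list(ab.columns),
        truth_type=truth_type,
        truth_band=truth_band,
        pitch_um=pitch,
    )


def write_bands_geojson(bands: BandSet, path) -> None:
    feats = [
        {
            "type": "Feature",
            "properties": {"role": "borderline"},
            "geometry": mapping(bands.borderline),
        }
    ]
    for label, geom in bands.bands.items():
        feats.append(
            {
                "type": "Feature",
                "properties": {"role": "band", "label": label},
                "geometry": mapping(geom),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"units": "um", "offsets": list(bands.offsets)},
        "features": feats,
    }
    Path(path).write_text(json.dumps(doc))


def read_bands_geojson(path) -> BandSet:
    from shapely.geometry import LineString, Polygon

    doc = json.loads(Path(path).read_text())
    borderline = None
    bands = {}
    for f in doc["features"]:
        geom = shape(f["geometry"])
        if f["properties"]["role"] == "borderline":
            borderline = LineString(geom.coords)
        else:
            bands[f["properties"]["label"]] = geom
    if borderline is None:
        raise InputError("GeoJSON lacks a borderline feature")
    coords = list(borderline.coords)
    if coords[0] != coords[-1]:
        coords.append(coords[0])
    return BandSet(
        borderline=LineString(coords),
        offsets=tuple(doc.get("properties", {}).get("offsets", (500.0, 1000.0, 1500.0))),
        bands=bands,
        tumor_polygon=Polygon(coords),
    )


def scene_from_yaml(path_or_text) -> Scene:
    """Build a Scene from a YAML document (path or raw text).

    Schema::

        width_um: 4000
        height_um: 4000
        pitch_um: 50
        seed: 1
        tumor: {shape: disk, center: [2000, 2000], radius: 400}
        gradients:
          - {cell_type: Fibroblast, side: tumor, decay_um: 400, peak_fraction: 0.4}
        cnv_blocks:
          - {chrom: chr1, start_ord: 10, end_ord: 60, factor: 2.0}
    """
    text = str(path_or_text)
    if "\n" not in text and len(text) < 4000 and Path(text).exists():
        text = Path(text).read_text()
    doc = yaml.safe_load(text)
    tumor = doc.get("tumor", {})
    if tumor.get("shape", "disk") != "disk":
        raise InputError("only disk tumors are supported in scene YAML")
    region = disk(*tumor["center"], tumor["radius"])
    grads = tuple(GradientSpec(**g) for g in doc.get("gradients", []))
    blocks = tuple(CNVBlock(**b) for b in doc.get("cnv_blocks", []))
    keys = (
        "pitch_um", "seed", "tumor_type", "normal_type", "tumor_purity",
        "normal_dominance", "library_size_median", "library_size_sigma",
        "abundance_noise_sigma",
    )
    extra = {k: doc[k] for k in keys if k in doc}
    return Scene(
        width_um=doc["width_um"],
        height_um=doc["height_um"],
        tumor_region=region,
        gradient_specs=grads,
        cnv_blocks=blocks,
        **extra,
    )


def scene_to_yaml(scene: Scene, path=None) -> str:
    c = scene.tumor_region.centroid
    radius = float(np.sqrt(scene.tumor_region.area / np.pi))
    doc = {
        "width_um": scene.width_um,
        "height_um": scene.height_um,
        "pitch_um": scene.pitch_um,
        "seed": scene.seed,
        "tumor": {"shape": "disk", "center": [float(c.x), float(c.y)], "radius": radius},
        "gradients": [vars(g).copy() for g in scene.gradient_specs],
        "cnv_blocks": [vars(b).copy() for b in scene.cnv_blocks],
        "tumor_purity": scene.tumor_purity,
        "normal_dominance": scene.normal_dominance,
        "library_size_median": scene.library_size_median,
        "library_size_sigma": scene.library_size_sigma,
        "abundance_noise_sigma": scene.abundance_noise_sigma,
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one gene per line, '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def validate_inputs(spots_path=None, mtx_path=None, barcodes_path=None,
                    features_path=None, abundance_path=None,
                    annotation_path=None) -> dict:
    """Schema and cross-file consistency checks.

    Returns ``{"ok": bool, "errors": [...], "warnings": [...]}``; never
    raises on malformed data, so callers can report every problem at once.
    """
    errors: list[str] = []
    warnings_: list[str] = []
    spot_ids = None

    if spots_path is not None:
        try:
            spots = pd.read_csv(spots_path, sep="\t")
            missing = {"spot_id", "x_um", "y_um"} - set(spots.columns)
            if missing:
                errors.append(f"spots: missing columns {sorted(missing)}")
            else:
                if spots["spot_id"].duplicated().any():
                    dup = spots["spot_id"][spots["spot_id"].duplicated()].tolist()[:5]
                    errors.append(f"spots: duplicate spot ids {dup}")
                for c in ("x_um", "y_um"):
                    if not np.issubdtype(spots[c].dtype, np.number):
                        errors.append(f"spots: non-numeric column {c}")
                spot_ids = spots["spot_id"].astype(str).tolist()
        except Exception as e:  # noqa: BLE001
            errors.append(f"spots: unreadable ({e})")

    n_rows = n_cols = None
    if mtx_path is not None:
        try:
            with open(mtx_path) as fh:
                header = fh.readline()
                if not header.startswith("%%MatrixMarket"):
                    errors.append("mtx: missing MatrixMarket header")
                line = fh.readline()
                while line.startswith("%"):
                    line = fh.readline()
                dims = line.split()
                if len(dims) < 2:
                    errors.append("mtx: malformed dimension line")
                else:
                    n_rows, n_cols = int(dims[0]), int(dims[1])
        except Exception as e:  # noqa: BLE001
            errors.append(f"mtx: unreadable ({e})")

    barcodes = None
    if barcodes_path is not None:
        barcodes = Path(barcodes_path).read_text().split()
        if n_rows is not None and len(barcodes) != n_rows:
            errors.append(
                f"mtx rows ({n_rows}) inconsistent with barcodes ({len(barcodes)})"
            )
    if features_path is not None:
        features = Path(features_path).read_text().split()
        if n_cols is not None and len(features) != n_cols:
            errors.append(
                f"mtx cols ({n_cols}) inconsistent with features ({len(features)})"
            )

    if abundance_path is not None:
        try:
            ab = pd.read_csv(abundance_path, sep="\t", index_col=0)
            ref = spot_ids if spot_ids is not None else barcodes
            if ref is not None:
                missing_ids = sorted(set(ref) - set(ab.index.astype(str)))
                if missing_ids:
                    errors.append(
                        f"abundance: {len(missing_ids)} spot ids missing "
                        f"(first: {missing_ids[:5]})"
                    )
            if (ab.to_numpy(dtype=float) < 0).any():
                errors.append("abundance: negative entries")
        except Exception as e:  # noqa: BLE001
            errors.append(f"abundance: unreadable ({e})")

    if annotation_path is not None:
        try:
            ann = pd.read_csv(annotation_path, sep="\t")
            missing = {"gene", "chromosome", "ordinal"} - set(ann.columns)
            if missing:
                errors.append(f"annotation: missing columns {sorted(missing)}")
        except Exception as e:  # noqa: BLE001
            errors.append(f"annotation: unreadable ({e})")

    return {"ok": not errors, "errors": errors, "warnings": warnings_}
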