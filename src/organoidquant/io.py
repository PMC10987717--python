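"""File formats, run configuration, and the pipeline driver.

Formats handled here:

* OME-TIFF read/write for calibrated image channels and 3D stacks (pixel
  size from OME metadata, overridable from config);
* rosette boundaries as CSV (``rosette_id,role,vertex_index,x_um,y_um``) or
  ImageJ ``.roi``/``.zip`` polygon files (a minimal codec for the stable
  polygon subset of the format);
* count matrices as MatrixMarket + ``genes.tsv``/``barcodes.tsv`` (with an
  optional ``clusters.csv``) or dense CSV;
* GMT gene-set collections;
* YAML run configuration that round-trips losslessly and records every
  physical parameter in µm.

Outputs of every pipeline stage include a ``parameters.json`` snapshot so a
run can be reproduced byte-for-byte from its own records.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import struct
import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csc_matrix

from . import __version__
from .roi import (
    BoundaryPolyline,
    PixelGrid,
    RosetteMeasurement,
    build_rosette_roi,
    rosette_morphometrics,
)
from .intensity import ImageChannel, mean_roi_intensity, quantify_marker
from .coloc import VolumeStack, coloc_report
from .screen import (
    CountMatrix,
    QCThresholds,
    cluster_aggregate_log2ratio,
    compute_cell_qc,
    downsample_cells,
    qc_filter,
    select_cells,
    select_de_genes,
)
from .stats import stats_report
from .synthetic import (
    RosetteSceneParams,
    make_coloc_stack,
    make_count_experiment,
    make_marker_field,
    make_rosette_scene,
)

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_boundaries",
    "write_boundaries",
    "read_imagej_roi",
    "write_imagej_roi",
    "read_counts",
    "write_counts",
    "read_gmt",
    "run_pipeline",
]

logger = logging.getLogger("organoidquant")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the study's stated parameters."""

    stage: str = "run-all"
    input_paths: dict[str, str] = field(default_factory=dict)
    channel_roles: dict[str, str] = field(default_factory=dict)
    output_dir: str = "."
    pixel_size_um: float | None = None  # override when TIFF lacks calibration
    erosion_um: float = 1.8
    dilation_um: float = 1.8
    refine: bool = False
    tophat_radius_um: float = 54.0
    qc_max_nFeature: int = 8000
    qc_min_nFeature: int = 200
    qc_max_nCount: int = 50_000
    qc_max_pct_mito: float = 20.0
    downsample_n: int = 6400
    pseudocount: float = 0.01
    de_threshold: float = 1.0
    nes_cutoff: float = 7.5
    seed: int = 0
    simulate: dict = field(default_factory=dict)  # generator-specific overrides

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            max_nFeature=self.qc_max_nFeature,
            min_nFeature=self.qc_min_nFeature,
            max_nCount=self.qc_max_nCount,
            max_pct_mito=self.qc_max_pct_mito,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# images

def write_image(
    path: str | Path,
    channels: Mapping[str, np.ndarray],
    pixel_size_um: float,
    dtype=np.float32,
) -> None:
    """Write named channels (2D, or 3D for stacks) as OME-TIFF with physical
    pixel size recorded in the OME metadata."""
    arrays = [np.asarray(a) for a in channels.values()]
    data = np.stack(arrays).astype(dtype)
    axes = "CYX" if arrays[0].ndim == 2 else "CZYX"
    tifffile.imwrite(
        path,
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": axes,
            "PhysicalSizeX": pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": list(channels.keys())},
        },
    )


def _ome_pixel_size(tif: tifffile.TiffFile) -> float | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    try:
        d = tifffile.xml2dict(meta)
        pixels = d["OME"]["Image"]
        if isinstance(pixels, list):
            pixels = pixels[0]
        return float(pixels["Pixels"]["PhysicalSizeX"])
    except (KeyError, TypeError, ValueError):
        return None


def _ome_channel_names(tif: tifffile.TiffFile, n: int) -> list[str]:
    meta = tif.ome_metadata
    if meta:
        try:
            d = tifffile.xml2dict(meta)
            image = d["OME"]["Image"]
            if isinstance(image, list):
                image = image[0]
            ch = image["Pixels"]["Channel"]
            if isinstance(ch, dict):
                ch = [ch]
            names = [c.get("Name", f"channel_{i}") for i, c in enumerate(ch)]
            if len(names) == n:
                return [str(x) for x in names]
        except (KeyError, TypeError):
            pass
    return [f"channel_{i}" for i in range(n)]


def read_image(
    path: str | Path, pixel_size_um: float | None = None
) -> dict[str, ImageChannel]:
    """Read a 2D multi-channel OME-TIFF into named :class:`ImageChannel`\\ s.

    Pixel size comes from the OME metadata; a ``pixel_size_um`` override wins,
    and its absence from both is an error — uncalibrated quantification in
    physical units is meaningless.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        size = pixel_size_um if pixel_size_um is not None else _ome_pixel_size(tif)
        if size is None:
            raise ValueError(f"{path}: no pixel calibration in metadata and no override given")
        if data.ndim == 2:
            data = data[np.newaxis]
        names = _ome_channel_names(tif, data.shape[0])
    grid = PixelGrid(width=data.shape[-1], height=data.shape[-2], pixel_size_um=float(size))
    return {
        name: ImageChannel(plane.astype(float), grid, name=name)
        for name, plane in zip(names, data)
    }


def _ome_size(tif: tifffile.TiffFile, key: str) -> int | None:
    meta = tif.ome_metadata
    if not meta:
        return None
    try:
        d = tifffile.xml2dict(meta)
        image = d["OME"]["Image"]
        if isinstance(image, list):
            image = image[0]
        return int(image["Pixels"][key])
    except (KeyError, TypeError, ValueError):
        return None


def read_stack(path: str | Path, pixel_size_um: float | None = None) -> VolumeStack:
    """Read a CZYX OME-TIFF as a named-channel volume stack."""
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        size = pixel_size_um if pixel_size_um is not None else _ome_pixel_size(tif)
        if size is None:
            raise ValueError(f"{path}: no pixel calibration in metadata and no override given")
        n_c = _ome_size(tif, "SizeC") or (data.shape[0] if data.ndim == 4 else 1)
        n_z = _ome_size(tif, "SizeZ") or (data.size // (n_c * data.shape[-2] * data.shape[-1]))
        data = data.reshape(n_c, n_z, data.shape[-2], data.shape[-1])
        names = _ome_channel_names(tif, data.shape[0])
    return VolumeStack(
        channels={n: p.astype(float) for n, p in zip(names, data)},
        voxel_size_um=(float(size),) * 3,
    )


# ---------------------------------------------------------------------------
# boundaries (CSV and minimal ImageJ .roi polygon codec)

BOUNDARY_COLUMNS = ["rosette_id", "role", "vertex_index", "x_um", "y_um"]


def write_boundaries(path: str | Path, boundaries: Mapping[str, dict[str, BoundaryPolyline]]) -> None:
    """CSV writer for {rosette_id: {'outer': ..., 'inner': ...}} in µm."""
    rows = []
    for rid, pair in boundaries.items():
        for role, poly in pair.items():
            for i, (x, y) in enumerate(poly.vertices_um):
                rows.append({"rosette_id": rid, "role": role, "vertex_index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=BOUNDARY_COLUMNS).to_csv(path, index=False)


def read_boundaries(path: str | Path, pixel_size_um: float | None = None) -> dict[str, dict[str, BoundaryPolyline]]:
    """Read paired outer/inner boundaries from CSV or an ImageJ .roi zip.

    Every rosette id must carry both roles; an unpaired boundary is an error.
    ImageJ coordinates are in pixels, so ``pixel_size_um`` is required for
    .roi/.zip input.
    """
    path = Path(path)
    if path.suffix.lower() in {".zip", ".roi"}:
        if pixel_size_um is None:
            raise ValueError("ImageJ ROI input needs pixel_size_um to convert to µm")
        return _read_imagej_boundaries(path, pixel_size_um)
    df = pd.read_csv(path)
    if list(df.columns) != BOUNDARY_COLUMNS:
        raise ValueError(f"boundary CSV must have columns {BOUNDARY_COLUMNS}")
    out: dict[str, dict[str, BoundaryPolyline]] = {}
    for (rid, role), sub in df.groupby(["rosette_id", "role"]):
        sub = sub.sort_values("vertex_index")
        out.setdefault(str(rid), {})[str(role)] = BoundaryPolyline(
            sub[["x_um", "y_um"]].to_numpy(float), closed=True
        )
    for rid, pair in out.items():
        if set(pair) != {"outer", "inner"}:
            raise ValueError(f"rosette {rid!r} must have exactly an outer and an inner boundary")
    return out


_ROI_HEADER_SIZE = 64
_ROI_POLYGON = 0
_ROI_FREEHAND = 7


def write_imagej_roi(vertices_px: np.ndarray, roi_type: int = _ROI_POLYGON) -> bytes:
    """Encode integer pixel vertices as an ImageJ .roi polygon blob."""
    v = np.asarray(vertices_px)
    left, top = int(np.floor(v[:, 0].min())), int(np.floor(v[:, 1].min()))
    right, bottom = int(np.ceil(v[:, 0].max())), int(np.ceil(v[:, 1].max()))
    n = len(v)
    header = bytearray(_ROI_HEADER_SIZE)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = roi_type
    struct.pack_into(">4h", header, 8, top, left, bottom, right)
    struct.pack_into(">h", header, 16, n)
    coords = bytearray()
    for x in v[:, 0]:
        coords += struct.pack(">h", int(round(x)) - left)
    for y in v[:, 1]:
        coords += struct.pack(">h", int(round(y)) - top)
    return bytes(header) + bytes(coords)


def read_imagej_roi(blob: bytes) -> np.ndarray:
    """Decode an ImageJ .roi polygon/freehand blob to (n, 2) pixel vertices."""
    if blob[0:4] != b"Iout":
        raise ValueError("not an ImageJ ROI file")
    roi_type = blob[6]
    if roi_type not in (_ROI_POLYGON, _ROI_FREEHAND):
        raise ValueError(f"unsupported ROI type {roi_type}; only polygon/freehand handled")
    top, left, _bottom, _right = struct.unpack_from(">4h", blob, 8)
    (n,) = struct.unpack_from(">h", blob, 16)
    xs = np.frombuffer(blob, dtype=">i2", count=n, offset=_ROI_HEADER_SIZE) + left
    ys = np.frombuffer(blob, dtype=">i2", count=n, offset=_ROI_HEADER_SIZE + 2 * n) + top
    return np.column_stack([xs, ys]).astype(float)


def _read_imagej_boundaries(path: Path, pixel_size_um: float) -> dict[str, dict[str, BoundaryPolyline]]:
    blobs: dict[str, bytes] = {}
    if path.suffix.lower() == ".zip":
        with zipfile.ZipFile(path) as zf:
            for name in zf.namelist():
                blobs[Path(name).stem] = zf.read(name)
    else:
        blobs[path.stem] = path.read_bytes()
    out: dict[str, dict[str, BoundaryPolyline]] = {}
    for name, blob in blobs.items():
        if name.endswith("_outer"):
            rid, role = name[: -len("_outer")], "outer"
        elif name.endswith("_inner"):
            rid, role = name[: -len("_inner")], "inner"
        else:
            raise ValueError(f"ROI name {name!r} must end in _outer or _inner")
        vertices_um = (read_imagej_roi(blob) + 0.5) * pixel_size_um
        out.setdefault(rid, {})[role] = BoundaryPolyline(vertices_um, closed=True)
    for rid, pair in out.items():
        if set(pair) != {"outer", "inner"}:
            raise ValueError(f"rosette {rid!r} must have exactly an outer and an inner boundary")
    return out


# ---------------------------------------------------------------------------
# count matrices and gene sets

def write_counts(outdir: str | Path, m: CountMatrix) -> None:
    """MatrixMarket + genes.tsv + barcodes.tsv (+ clusters.csv) writer."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(outdir / "matrix.mtx", csc_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = {"sample": m.sample, "mito_genes": sorted(m.mito_genes)}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=1))
    if m.clusters is not None:
        pd.DataFrame({"cell_id": m.cell_ids, "cluster": m.clusters}).to_csv(
            outdir / "clusters.csv", index=False
        )


def read_counts(path: str | Path) -> CountMatrix:
    """Read a count matrix from a MatrixMarket directory or dense CSV.

    The CSV dialect is genes as rows (first column gene id), cells as columns.
    """
    path = Path(path)
    if path.is_dir():
        counts = np.asarray(mmread(path / "matrix.mtx").todense())
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
        if counts.shape != (len(genes), len(cells)):
            raise ValueError("matrix shape does not match genes/barcodes files")
        sample, mito = path.name, frozenset()
        meta_path = path / "meta.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            sample = meta.get("sample", sample)
            mito = frozenset(meta.get("mito_genes", []))
        clusters = None
        cl_path = path / "clusters.csv"
        if cl_path.exists():
            cl = pd.read_csv(cl_path, dtype=str).set_index("cell_id")["cluster"]
            clusters = cl.reindex(cells).to_numpy()
        return CountMatrix(counts.astype(np.int64), genes, cells, sample, clusters, mito)
    df = pd.read_csv(path, index_col=0)
    return CountMatrix(
        df.to_numpy(np.int64),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        sample=path.stem,
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set reader: name <TAB> description <TAB> gene1 <TAB> ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# ---------------------------------------------------------------------------
# truth serialization

def _truth_to_json(truth) -> dict:
    out: dict = {"seed": truth.seed}
    if truth.outer_polyline_um is not None:
        out["outer_polyline_um"] = np.asarray(truth.outer_polyline_um).tolist()
        out["inner_polyline_um"] = np.asarray(truth.inner_polyline_um).tolist()
    if truth.region_means:
        out["region_means"] = truth.region_means
    if truth.foreground_mean is not None:
        out["foreground_mean"] = truth.foreground_mean
    if truth.tvc_fractions:
        out["tvc_fractions"] = {f"{a}_in_{b}": f for (a, b), f in truth.tvc_fractions.items()}
    if truth.de_table is not None and len(truth.de_table):
        out["de_table"] = truth.de_table.to_dict(orient="records")
    if truth.qc_violators:
        out["qc_violators"] = truth.qc_violators
    return out


# ---------------------------------------------------------------------------
# pipeline driver

def _write_parameters(outdir: Path, config: RunConfig, stage: str) -> None:
    payload = dataclasses.asdict(config)
    payload["package_version"] = __version__
    payload["stage_executed"] = stage
    payload["doubletfinder_multiplet_rate"] = 0.008  # provenance from upstream doublet calling
    (outdir / "parameters.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    sim = config.simulate
    seed = config.seed
    n_rosettes = int(sim.get("n_rosettes", 3))
    boundaries = {}
    rosette_dir = outdir / "rosettes"
    rosette_dir.mkdir(parents=True, exist_ok=True)
    truths = {}
    for i in range(n_rosettes):
        params = RosetteSceneParams(
            size_px=tuple(sim.get("rosette_size_px", (256, 256))),
            seed=seed + i,
            noise_sigma=float(sim.get("noise_sigma", 10.0)),
        )
        channel, truth = make_rosette_scene(params)
        rid = f"rosette_{i:02d}"
        write_image(rosette_dir / f"{rid}.ome.tif", {"rosette": channel.data}, params.pixel_size_um)
        boundaries[rid] = {
            "outer": BoundaryPolyline(truth.outer_polyline_um),
            "inner": BoundaryPolyline(truth.inner_polyline_um),
        }
        truths[rid] = _truth_to_json(truth)
    write_boundaries(rosette_dir / "boundaries.csv", boundaries)

    marker_dir = outdir / "markers"
    marker_dir.mkdir(exist_ok=True)
    for i in range(int(sim.get("n_markers", 3))):
        channel, truth = make_marker_field(
            size_px=tuple(sim.get("marker_size_px", (256, 256))),
            noise_sigma=float(sim.get("marker_noise_sigma", 5.0)),
            background_plane_coeffs=tuple(sim.get("plane_coeffs", (50.0, 0.2, 0.1))),
            seed=seed + 100 + i,
        )
        write_image(marker_dir / f"marker_{i:02d}.ome.tif", {"marker": channel.data}, channel.grid.pixel_size_um)
        truths[f"marker_{i:02d}"] = _truth_to_json(truth)

    coloc_dir = outdir / "coloc"
    coloc_dir.mkdir(exist_ok=True)
    fractions = sim.get("coloc_fractions", {"regionA": 0.8, "regionB": 0.4})
    n_stacks = int(sim.get("n_stacks_per_region", 2))
    for region, f in fractions.items():
        for i in range(n_stacks):
            stack, truth = make_coloc_stack(
                shape=tuple(sim.get("stack_shape", (32, 32, 32))),
                overlap_nuclear=float(f),
                overlap_neuronal=float(f),
                seed=seed + 200 + i + 97 * (zlib.crc32(region.encode()) % 1000),
            )
            write_image(
                coloc_dir / f"{region}_{i:02d}.ome.tif",
                stack.channels,
                stack.voxel_size_um[0],
            )
            truths[f"{region}_{i:02d}"] = _truth_to_json(truth)

    counts_dir = outdir / "counts"
    planted = {("gene_0100", "0"): 2.0, ("gene_0101", "1"): -2.0}
    violators = {"A_cell_0000": "low_nFeature", "B_cell_0001": "high_pct_mito"}
    (pair_a, pair_b), truth = make_count_experiment(
        n_genes=int(sim.get("n_genes", 500)),
        n_cells_per_sample=int(sim.get("n_cells", 300)),
        planted_log2fc=sim.get("planted_log2fc", planted),
        qc_violations=sim.get("qc_violations", violators),
        seed=seed + 300,
    )
    write_counts(counts_dir / "sample_A", pair_a)
    write_counts(counts_dir / "sample_B", pair_b)
    truths["counts"] = _truth_to_json(truth)

    (outdir / "truth.json").write_text(json.dumps(truths, indent=1, sort_keys=True))


def _stage_rosette_quant(config: RunConfig, outdir: Path) -> None:
    image_dir = Path(config.input_paths["images"])
    boundaries = read_boundaries(config.input_paths["boundaries"], config.pixel_size_um)
    rows = []
    for rid in sorted(boundaries):
        channels = read_image(image_dir / f"{rid}.ome.tif", config.pixel_size_um)
        channel = next(iter(channels.values()))
        roi = build_rosette_roi(
            boundaries[rid]["outer"],
            boundaries[rid]["inner"],
            channel.grid,
            channel,
            erosion_um=config.erosion_um,
            dilation_um=config.dilation_um,
            refine=config.refine,
        )
        area, aspect = rosette_morphometrics(roi)
        rows.append(
            RosetteMeasurement(
                rosette_id=rid,
                group="",
                mean_body=mean_roi_intensity(channel, roi.body_mask),
                mean_ribbon=mean_roi_intensity(channel, roi.ribbon_mask),
                area_um2=area,
                aspect_ratio=aspect,
            )
        )
    columns = ["rosette_id", "mean_body", "mean_ribbon", "area_um2", "aspect_ratio"]
    pd.DataFrame([dataclasses.asdict(r) for r in rows])[columns].to_csv(
        outdir / "rosette_measurements.csv", index=False
    )


def _stage_marker_quant(config: RunConfig, outdir: Path) -> None:
    image_dir = Path(config.input_paths["images"])
    rows = []
    for path in sorted(image_dir.glob("*.tif")) + sorted(image_dir.glob("*.ome.tif")):
        for name, channel in read_image(path, config.pixel_size_um).items():
            rec = quantify_marker(channel, radius_um=config.tophat_radius_um)
            rows.append(
                {
                    "image": path.name,
                    "channel": name,
                    "otsu_threshold": rec.otsu_threshold,
                    "mean_foreground": rec.mean_foreground,
                    "foreground_fraction": rec.foreground_fraction,
                    "tophat_radius_um": rec.tophat_radius_um,
                }
            )
    pd.DataFrame(rows).drop_duplicates(subset=["image", "channel"]).to_csv(
        outdir / "marker_quant.csv", index=False
    )


def _stage_coloc(config: RunConfig, outdir: Path) -> None:
    stack_dir = Path(config.input_paths["stacks"])
    by_region: dict[str, list[VolumeStack]] = {}
    for path in sorted(stack_dir.glob("*.ome.tif")):
        region = path.stem.split(".")[0].rsplit("_", 1)[0]
        by_region.setdefault(region, []).append(read_stack(path, config.pixel_size_um))
    report = coloc_report(by_region)
    pd.DataFrame(report["table"]).to_csv(outdir / "coloc.csv", index=False)
    (outdir / "coloc_stats.json").write_text(json.dumps(report["statistics"], indent=1))


def _stage_screen(config: RunConfig, outdir: Path) -> None:
    a = read_counts(config.input_paths["sample_a"])
    b = read_counts(config.input_paths["sample_b"])
    thresholds = config.qc_thresholds()
    screened = []
    for m in (a, b):
        qc = compute_cell_qc(m)
        qc.to_csv(outdir / f"qc_{m.sample}.csv")
        survivors = qc_filter(qc, thresholds)
        m = select_cells(m, survivors)
        m = downsample_cells(m, n=config.downsample_n, seed=config.seed, allow_smaller=True)
        screened.append(m)
    a, b = screened
    table = cluster_aggregate_log2ratio(a, b, pseudocount=config.pseudocount)
    table.to_csv(outdir / "cluster_ratios.csv", index=False)
    de = select_de_genes(table, threshold=config.de_threshold)
    (outdir / "de_genes.json").write_text(json.dumps(de, indent=1, sort_keys=True))


def _stage_stats(config: RunConfig, outdir: Path) -> None:
    df = pd.read_csv(config.input_paths["measurements"])
    if not {"group", "value"} <= set(df.columns):
        raise ValueError("stats input CSV must have 'group' and 'value' columns")
    groups = {g: sub["value"].to_numpy(float) for g, sub in df.groupby("group", sort=True)}
    report = stats_report(groups)
    (outdir / "stats_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    tukey_rows = [
        {
            "group_a": t["pair"][0],
            "group_b": t["pair"][1],
            "mean_difference": t["mean_difference"],
            "q": t["q"],
            "p_adjusted": t["p_adjusted"],
        }
        for t in report["tukey"]
    ]
    pd.DataFrame(
        tukey_rows, columns=["group_a", "group_b", "mean_difference", "q", "p_adjusted"]
    ).to_csv(outdir / "tukey.csv", index=False)


_STAGES = {
    "simulate": _stage_simulate,
    "rosette-quant": _stage_rosette_quant,
    "marker-quant": _stage_marker_quant,
    "coloc": _stage_coloc,
    "screen": _stage_screen,
    "stats": _stage_stats,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute one stage (or ``run-all`` over simulated data) deterministically.

    Every stage writes its outputs plus a ``parameters.json`` snapshot into
    ``config.output_dir``; identical config + seed reproduce identical bytes.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    logger.addHandler(handler)
    try:
        for key, p in config.input_paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"stage {config.stage!r}: missing input {key!r} at {p}")
        if config.stage == "run-all":
            sim = dataclasses.replace(config, stage="simulate", output_dir=str(outdir / "simulated"))
            run_pipeline(sim)
            sim_dir = outdir / "simulated"
            specs = {
                "rosette-quant": {"images": str(sim_dir / "rosettes"), "boundaries": str(sim_dir / "rosettes" / "boundaries.csv")},
                "marker-quant": {"images": str(sim_dir / "markers")},
                "coloc": {"stacks": str(sim_dir / "coloc")},
                "screen": {"sample_a": str(sim_dir / "counts" / "sample_A"), "sample_b": str(sim_dir / "counts" / "sample_B")},
            }
            for stage, inputs in specs.items():
                sub = dataclasses.replace(
                    config, stage=stage, input_paths=inputs, output_dir=str(outdir / stage)
                )
                run_pipeline(sub)
        elif config.stage in _STAGES:
            logger.info("running stage %s", config.stage)
            _STAGES[config.stage](config, outdir)
        else:
            raise ValueError(f"unknown stage {config.stage!r}")
        _write_parameters(outdir, config, config.stage)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
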