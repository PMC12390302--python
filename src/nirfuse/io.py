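"""Stack readers/writers, filename conventions, and the pipeline driver.

Frames live on disk either as a directory of single-page TIFFs named

    band{cwl}nm_exp{ms}ms.tiff

as a multi-page TIFF whose description holds the label table as JSON, or
as an explicit JSON manifest (``{"entries": [{"path", "center_wavelength_nm",
"exposure_time_ms"}, ...]}``) for foreign data that does not follow the
naming convention.

Integer frames are normalised to [0, 1] by the dtype maximum (not by the
per-image range) so that exposure relationships across frames survive
loading — the exposedness weight is meaningless otherwise.  Float input
is passed through unchanged.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml
from imageio.v3 import imread, imwrite

from . import __version__
from .calibration import FlatField, apply_flat_field, build_flat_field
from .fusion import FrameLabel, FusionResult, ImageStack, fuse_stack
from .phantom import PhantomScene, default_scene, generate_stack, white_light_proxy
from .profiles import ProfileReport, cnr, cross_section

__all__ = [
    "StackManifest",
    "read_stack",
    "write_stack",
    "write_result",
    "read_image",
    "run_pipeline",
]

_FRAME_RE = re.compile(r"^band(?P<cwl>[0-9.]+)nm_exp(?P<ms>[0-9.]+)ms\.(tif|tiff)$")


@dataclass
class StackManifest:
    """Provenance of where a stack's frames came from."""

    entries: list[tuple[str, float, float]]  # (path-or-page, cwl_nm, exposure_ms)
    source: str  # directory_scan | multipage_tiff | explicit_manifest


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Map integer data to [0, 1] by dtype max; pass float through."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    return arr.astype(np.float64)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel image, normalised to [0, 1] by dtype."""
    arr = imread(Path(path))
    if arr.ndim == 3:  # collapse an incidental colour axis
        arr = arr.mean(axis=2)
    return _normalize(arr)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def frame_filename(label: FrameLabel) -> str:
    return f"band{_fmt_num(label.center_wavelength_nm)}nm_exp{_fmt_num(label.exposure_time_ms)}ms.tiff"


def parse_frame_filename(name: str) -> FrameLabel:
    m = _FRAME_RE.match(name)
    if m is None:
        raise ValueError(
            f"cannot parse frame label from {name!r}; expected band<cwl>nm_exp<ms>ms.tiff"
        )
    return FrameLabel(float(m.group("cwl")), float(m.group("ms")))


def _assemble(frames: list[np.ndarray], labels: list[FrameLabel], entries, source) -> ImageStack:
    if len(frames) == 0:
        raise ValueError("empty image stack")
    shape = frames[0].shape
    mixed = [str(labels[i]) for i, f in enumerate(frames) if f.shape != shape]
    if mixed:
        raise ValueError(f"frames have mixed dimensions: {', '.join(mixed)}")
    order = sorted(range(len(frames)), key=lambda i: tuple(labels[i]))
    stack = ImageStack(
        np.stack([frames[i] for i in order]), [labels[i] for i in order]
    )
    stack.manifest = StackManifest(entries=[entries[i] for i in order], source=source)
    return stack


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack from a directory, multi-page TIFF, or JSON manifest.

    Frames are sorted by (wavelength, exposure); the resulting
    :class:`~nirfuse.fusion.ImageStack` carries a ``manifest`` attribute.
    """
    p = Path(path)
    if p.is_dir():
        aux = {"white_light_proxy.tiff", "white_light_proxy.tif"}
        files = sorted(q for q in p.iterdir() if _FRAME_RE.match(q.name))
        stray = [
            q.name
            for q in p.iterdir()
            if q.suffix.lower() in (".tif", ".tiff")
            and not _FRAME_RE.match(q.name)
            and q.name not in aux
        ]
        if stray:
            raise ValueError(f"unparseable frame filenames in {p}: {', '.join(sorted(stray))}")
        frames = [read_image(q) for q in files]
        labels = [parse_frame_filename(q.name) for q in files]
        entries = [(str(q), l.center_wavelength_nm, l.exposure_time_ms) for q, l in zip(files, labels)]
        return _assemble(frames, labels, entries, "directory_scan")
    if p.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(p) as tf:
            desc = tf.pages[0].description
            meta = json.loads(desc) if desc else {}
            arr = tf.asarray()
        if arr.ndim == 2:
            arr = arr[None]
        labels = [FrameLabel(*lbl) for lbl in meta.get("labels", [])]
        if len(labels) != arr.shape[0]:
            raise ValueError(
                f"multi-page TIFF {p} lacks a label table for its {arr.shape[0]} pages"
            )
        frames = [_normalize(a) for a in arr]
        entries = [(f"{p}#page{i}", l.center_wavelength_nm, l.exposure_time_ms) for i, l in enumerate(labels)]
        return _assemble(frames, labels, entries, "multipage_tiff")
    if p.suffix.lower() == ".json":
        spec = json.loads(p.read_text())
        frames, labels, entries = [], [], []
        for e in spec["entries"]:
            fp = (p.parent / e["path"]).resolve()
            frames.append(read_image(fp))
            labels.append(FrameLabel(float(e["center_wavelength_nm"]), float(e["exposure_time_ms"])))
            entries.append((str(fp), labels[-1].center_wavelength_nm, labels[-1].exposure_time_ms))
        return _assemble(frames, labels, entries, "explicit_manifest")
    raise ValueError(f"cannot read a stack from {p}: not a directory, TIFF, or manifest")


def write_stack(stack: ImageStack, out_dir: str | Path) -> list[Path]:
    """Write each frame as a float32 single-page TIFF under the naming convention."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for frame, label in zip(stack.frames, stack.labels):
        fp = out / frame_filename(label)
        tifffile.imwrite(fp, frame.astype(np.float32))
        paths.append(fp)
    return paths


def write_multipage(stack: ImageStack, path: str | Path) -> Path:
    """Write the whole stack as one multi-page float32 TIFF with a JSON label table."""
    p = Path(path)
    meta = {"labels": [list(lbl) for lbl in stack.labels]}
    tifffile.imwrite(p, stack.frames.astype(np.float32), description=json.dumps(meta))
    return p


def _to_preview(img: np.ndarray) -> np.ndarray:
    """8-bit preview with min/max mapped to 0/255 (constant images map to 0)."""
    lo, hi = float(img.min()), float(img.max())
    if hi > lo:
        scaled = (img - lo) / (hi - lo)
    else:
        scaled = np.zeros_like(img)
    return np.round(scaled * 255.0).astype(np.uint8)


def write_result(result: FusionResult, path: str | Path) -> dict[str, Path]:
    """Write a fusion result as float32 TIFF + 8-bit PNG preview + JSON sidecar."""
    p = Path(path)
    if p.suffix.lower() not in (".tif", ".tiff"):
        p = p.with_suffix(".tiff")
    p.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(p, result.fused.astype(np.float32))
    preview = p.with_suffix(".png")
    imwrite(preview, _to_preview(result.fused))
    sidecar = p.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {
                "software": f"nirfuse {__version__}",
                "mode": result.mode,
                "strategy": result.strategy,
                "depth": result.depth,
                "sigma": result.provenance.get("sigma"),
                "provenance": _jsonable(result.provenance),
            },
            indent=2,
        )
    )
    return {"tiff": p, "preview": preview, "sidecar": sidecar}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_phantom(scene: PhantomScene, out_dir: str | Path) -> dict:
    """Materialise a phantom acquisition on disk in the layout ``read_stack`` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, truth = generate_stack(scene)
    paths = write_stack(stack, out)
    mask_path = out / "truth_mask.png"
    imwrite(mask_path, (truth.mask.astype(np.uint8) * 255))
    scene_path = out / "scene.yaml"
    scene_path.write_text(yaml.safe_dump(scene.to_dict(), sort_keys=False))
    proxy_path = out / "white_light_proxy.tiff"
    tifffile.imwrite(proxy_path, white_light_proxy(scene).astype(np.float32))
    return {
        "frames": paths,
        "mask": mask_path,
        "scene": scene_path,
        "white_light_proxy": proxy_path,
        "stack": stack,
        "truth": truth,
    }


def _log(log_path: Path | None, stage: str, **params) -> None:
    if log_path is None:
        return
    with log_path.open("a") as fh:
        fh.write(json.dumps({"stage": stage, **_jsonable(params)}) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> tuple[FusionResult, ProfileReport]:
    """phantom/load -> optional flat-field -> weights -> fuse -> profile.

    ``config`` keys (all optional unless noted):

    * ``input`` — stack path, or ``phantom_seed`` to synthesise one
    * ``scene`` — phantom scene overrides (dict)
    * ``flat`` — path to a gray-patch reference image
    * ``sigma``, ``depth``, ``mode``, ``strategy`` — fusion parameters
    * ``profile_row``, ``profile_col`` — cross-section location
      (defaults to the image centre)
    * ``mask`` — path to a binary mask for CNR (phantom runs use the
      ground truth automatically)

    Deterministic given config + seed; every stage appends a JSON line
    to ``run_log.jsonl`` in ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"

    mask = None
    if "input" in config:
        stack = read_stack(config["input"])
        _log(log_path, "load", input=str(config["input"]), n_frames=len(stack))
        if "mask" in config:
            mask = read_image(config["mask"]) > 0.5
    elif "phantom_seed" in config:
        scene_kwargs = dict(config.get("scene", {}))
        scene_kwargs["seed"] = int(config["phantom_seed"])
        scene = PhantomScene.from_dict({**default_scene().to_dict(), **scene_kwargs})
        stack, truth = generate_stack(scene)
        mask = truth.mask
        _log(log_path, "phantom", seed=scene.seed, n_frames=len(stack))
    else:
        raise ValueError("pipeline config must provide 'input' or 'phantom_seed'")

    if config.get("flat"):
        ff = build_flat_field(read_image(config["flat"]))
        stack = ImageStack(
            np.stack([apply_flat_field(f, ff) for f in stack.frames]), stack.labels
        )
        _log(log_path, "calibrate", flat=str(config["flat"]), floor=ff.floor)

    sigma = float(config.get("sigma", 2.0))
    depth = config.get("depth")
    depth = None if depth in (None, "auto") else int(depth)
    mode = config.get("mode", "pyramid")
    strategy = config.get("strategy", "flat")
    try:
        result = fuse_stack(stack, sigma=sigma, depth=depth, mode=mode, strategy=strategy)
    except ValueError as exc:
        raise ValueError(f"fuse stage failed: {exc}") from exc
    _log(log_path, "fuse", sigma=sigma, depth=result.depth, mode=mode, strategy=strategy)
    artifacts = write_result(result, out / "fused.tiff")

    h, w = result.fused.shape
    row = int(config.get("profile_row", h // 2))
    col = int(config.get("profile_col", w // 2))
    report = cross_section(result.fused, row, col)
    if mask is not None:
        report.cnr = cnr(result.fused, mask)
    (out / "profile.json").write_text(json.dumps(report.to_dict(), indent=2))
    _log(log_path, "profile", row=row, col=col, cnr=report.cnr)
    _log(log_path, "done", artifacts={k: str(v) for k, v in artifacts.items()})
    return result, report
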