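"""File formats and run configuration.

TIFF/OME-TIFF for images and stacks (via tifffile), CSV for tables, JSON for
fit reports, YAML for configuration.  Configurations round-trip exactly
(load -> save -> load identity) and every stochastic stage carries an
explicit seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .binding import DEFAULT_BIN_EDGES
from .segment import SegParams
from .simulate import SceneGeometry, SceneImages

__all__ = [
    "FitOptions",
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "read_image_stack",
    "write_image",
    "write_scene",
    "read_scene",
    "write_fit_json",
]


@dataclass(frozen=True)
class FitOptions:
    """Binding-curve fitting options."""

    bin_edges: tuple = DEFAULT_BIN_EDGES
    donor_window: tuple = (1.0, 3.0)
    acceptor_max: float = 50.0
    n_boot: int = 200
    hill_n_free: bool = False


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one reproducible synthetic-pipeline run."""

    seed: int = 0
    kd_true: float = 6.0
    n_cells: int = 900
    cells_per_scene: int = 20
    n_donor_only_cells: int = 80
    landmark_kind: str = "er"
    instrument_phase: float = 0.2  # synthetic instrument offset, rad
    instrument_mod: float = 0.9
    fluorescein_lifetime: float = 4.0  # ns, calibration standard
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    seg: SegParams = field(
        default_factory=lambda: SegParams(
            background_threshold=30.0,
            log_kernel_size=25,
            log_sigma=4.0,
            structuring_element_size=21,
            min_roi_size=40,
            erode_factor=0,
        )
    )
    fit: FitOptions = field(default_factory=FitOptions)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (list, dict)):
        it = obj.items() if isinstance(obj, dict) else enumerate(obj)
        out = {k: _to_plain(v) for k, v in it}
        return out if isinstance(obj, dict) else list(out.values())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def config_to_dict(config: RunConfig) -> dict:
    return _to_plain(config)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    geometry = SceneGeometry(
        **_tupled(d.pop("geometry", {}), ("shape", "cell_radius", "axial_ratio"))
    )
    seg = SegParams(**d.pop("seg", {}))
    fit = FitOptions(**_tupled(d.pop("fit", {}), ("bin_edges", "donor_window")))
    return RunConfig(geometry=geometry, seg=seg, fit=fit, **d)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def load_config(path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    """Stable short hash identifying a configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def read_image_stack(path) -> np.ndarray:
    """Read a TIFF/OME-TIFF image or stack; axes normalized to (t?, y, x)."""
    path = Path(path)
    try:
        arr = tifffile.imread(path)
    except Exception as err:
        raise ValueError(f"cannot read image file {path}: {err}") from err
    arr = np.asarray(arr)
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image dimensionality {arr.ndim} in {path}")
    return arr


def write_image(array: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(array))


def write_scene(scene: SceneImages, directory) -> Path:
    """Write a rendered scene: multi-page channel TIFF, 3-D TCSPC TIFF,
    label TIFF and a YAML sidecar with acquisition metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    channels = np.stack(
        [
            scene.donor_intensity,
            scene.acceptor_intensity,
            scene.landmark,
            scene.nuclear,
        ]
    ).astype(np.float32)
    tifffile.imwrite(directory / "channels.tif", channels, photometric="minisblack")
    tifffile.imwrite(directory / "tcspc.tif", scene.tcspc.astype(np.uint16))
    tifffile.imwrite(directory / "truth_labels.tif", scene.truth_labels.astype(np.uint16))
    meta = {
        "rep_period_ns": float(scene.rep_period),
        "n_bins": int(scene.tcspc.shape[0]),
        "bin_width_ns": float(scene.rep_period / scene.tcspc.shape[0]),
        "harmonic": 1,
        "channel_order": ["donor", "acceptor", "landmark", "nuclear"],
        "landmark_kind": scene.landmark_kind,
    }
    (directory / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


def read_scene(directory) -> SceneImages:
    directory = Path(directory)
    meta = yaml.safe_load((directory / "meta.yaml").read_text())
    channels = read_image_stack(directory / "channels.tif")
    return SceneImages(
        donor_intensity=channels[0],
        acceptor_intensity=channels[1],
        landmark=channels[2],
        nuclear=channels[3],
        tcspc=read_image_stack(directory / "tcspc.tif"),
        truth_labels=read_image_stack(directory / "truth_labels.tif").astype(np.int32),
        rep_period=meta["rep_period_ns"],
        landmark_kind=meta.get("landmark_kind", "er"),
    )


def write_fit_json(fit, path) -> None:
    """Serialize a HillFit to JSON."""
    payload = {
        "kd_apparent_uM": fit.kd_apparent,
        "bmax": fit.bmax,
        "hill_n": fit.hill_n,
        "rss": fit.rss,
        "sratio": fit.sratio,
        "ci90_kd_uM": list(fit.ci90_kd),
        "n_roi": fit.n_roi,
        "classification": fit.classification,
        "converged": fit.converged,
        "condition": fit.condition,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
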