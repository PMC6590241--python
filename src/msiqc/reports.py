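"""Report rendering: JSON run reports and label-raster PNGs."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .resolution import PixelLabel

__all__ = ["write_report", "labels_to_png", "file_checksum"]

_LABEL_COLORS = {
    PixelLabel.EXCLUDED: (0, 0, 0),
    PixelLabel.RED: (255, 0, 0),
    PixelLabel.GREEN: (0, 255, 0),
    PixelLabel.YELLOW: (255, 255, 0),
}


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(path, command: str, metrics: dict, config: RunConfig, inputs: list) -> dict:
    """Write the machine-readable JSON run report: command, effective config,
    input checksums, library version, and all metrics."""
    report = {
        "command": command,
        "msiqc_version": __version__,
        "config": config.to_dict(),
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
        "metrics": _jsonify(metrics),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


def labels_to_png(labels: np.ndarray, path) -> None:
    """Render a mixed-pixel (or cluster) label raster as an RGB PNG."""
    from PIL import Image

    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    if labels.max() <= max(int(l) for l in PixelLabel):
        for lab, color in _LABEL_COLORS.items():
            rgb[labels == lab] = color
    else:  # generic cluster labels: spread over a fixed palette
        palette = np.array(
            [(0, 0, 0), (228, 26, 28), (55, 126, 184), (77, 175, 74), (152, 78, 163),
             (255, 127, 0), (255, 255, 51), (166, 86, 40), (247, 129, 191)],
            dtype=np.uint8,
        )
        rgb = palette[labels % len(palette)]
    Image.fromarray(rgb).save(path)
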