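"""Width-gradient visualization: contact pixels painted over the source patch.

Each contacting mitochondria boundary pixel is painted with the color of
its width bin (bin 0 = overlap through bin T), organelle regions receive a
translucent tint, and everything else shows the grayscale patch. The
painted pixel set is exactly the contacting set from the contact profile —
no anti-aliasing is applied to the label layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from matplotlib import colormaps

from ._errors import ConfigError, ShapeMismatchError
from .contact import DistanceGrid

__all__ = ["OverlayConfig", "default_colors", "overlay_profile", "render_colorbar"]

_DEFAULT_TINTS = {
    "er": (0.15, 0.45, 0.15),
    "mito": (0.15, 0.15, 0.5),
    "ld": (0.5, 0.4, 0.1),
}


def default_colors(threshold: int, cmap: str = "turbo") -> tuple:
    """T+1 perceptually ordered colors for bins 0..T."""
    cm = colormaps[cmap]
    return tuple(tuple(cm(i / max(1, threshold))[:3]) for i in range(threshold + 1))


@dataclass
class OverlayConfig:
    """Colors for the width bins plus organelle tints.

    colors: exactly threshold+1 distinct RGB triples (floats in [0, 1]),
    one per bin 0..threshold. tint_strength blends organelle tints into the
    background image; scale integer-upsamples the output raster.
    """

    colors: Sequence[Tuple[float, float, float]]
    tints: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_TINTS))
    tint_strength: float = 0.35
    scale: int = 1

    def validate(self, threshold: int) -> None:
        if len(self.colors) != threshold + 1:
            raise ConfigError(
                f"colormap has {len(self.colors)} colors, needs threshold+1 = {threshold + 1}")
        if len({tuple(c) for c in self.colors}) != len(self.colors):
            raise ConfigError("bin colors must be distinct")
        if self.scale < 1:
            raise ConfigError("scale must be >= 1")


def overlay_profile(image: Optional[np.ndarray], distance_map: DistanceGrid,
                    masks: Dict[str, np.ndarray], config: OverlayConfig) -> np.ndarray:
    """Render the contact overlay as an RGB uint8 raster.

    ``image`` is an optional grayscale background (any range; normalized
    for display); ``masks`` maps organelle names ('er', 'mito', 'ld') to
    region masks for tinting. Contact pixels (distance <= threshold on the
    distance map) are painted with their bin color; non-contact pixels keep
    the tinted background. Deterministic.
    """
    T = distance_map.threshold
    config.validate(T)
    shape = distance_map.values.shape
    for name, m in masks.items():
        if np.asarray(m).shape != shape:
            raise ShapeMismatchError(f"mask {name!r} shape {np.asarray(m).shape} != {shape}")
    if image is None:
        base = np.full(shape, 0.5)
    else:
        img = np.asarray(image, dtype=float)
        if img.shape != shape:
            raise ShapeMismatchError(f"image shape {img.shape} != {shape}")
        span = img.max() - img.min()
        base = (img - img.min()) / span if span > 0 else np.zeros(shape)
    rgb = np.repeat(base[..., None], 3, axis=-1)
    s = config.tint_strength
    for name, m in masks.items():
        tint = np.asarray(config.tints.get(name, (0.3, 0.3, 0.3)))
        sel = np.asarray(m).astype(bool)
        rgb[sel] = (1 - s) * rgb[sel] + s * tint
    d = distance_map.values
    contact = d <= T
    if contact.any():
        bins = np.ceil(d[contact]).astype(int)
        palette = np.asarray([config.colors[b] for b in range(T + 1)])
        rgb[contact] = palette[bins]
    out = np.clip(rgb * 255.0 + 0.5, 0, 255).astype(np.uint8)
    if config.scale > 1:
        out = np.repeat(np.repeat(out, config.scale, axis=0), config.scale, axis=1)
    return out


def render_colorbar(config: OverlayConfig, threshold: int,
                    pixel_nm: float = 10.0) -> np.ndarray:
    """An RGB raster of T+1 labeled swatches: bin index and nm range each.

    Bin 0 is the overlap bin; bin b covers contact widths in
    ((b-1)*pixel_nm, b*pixel_nm].
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    config.validate(threshold)
    fig = Figure(figsize=(1.8, 0.45 * (threshold + 1)), dpi=100)
    FigureCanvasAgg(fig)
    ax = fig.add_subplot(111)
    for b in range(threshold + 1):
        ax.add_patch(matplotlib.patches.Rectangle((0, b), 1, 1,
                                                  facecolor=config.colors[b]))
        label = ("overlap" if b == 0
                 else f"{b} px / {(b - 1) * pixel_nm:g}-{b * pixel_nm:g} nm")
        ax.text(1.1, b + 0.5, label, va="center", fontsize=8)
    ax.set_xlim(0, 3.2)
    ax.set_ylim(0, threshold + 1)
    ax.axis("off")
    fig.canvas.draw()
    buf = np.asarray(fig.canvas.buffer_rgba())[..., :3]
    return buf.copy()
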