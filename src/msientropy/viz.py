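"""Deterministic raster rendering of entropy heat maps and ion images.

Maps are rendered one image pixel per grid pixel (integer upscaling
allowed) through a matplotlib colormap lookup, with a vertical color bar
annotated with the scale's min/max.  The default palette runs yellow
(low entropy) to red (high entropy).  Rendering is a pure function of the
map and the scale, so images for the same inputs are byte-identical
across runs; samples being compared should share one fixed scale.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps
from PIL import Image, ImageDraw

from .entropy import EntropyMap

#: Default palette: yellow (low) -> red (high).
DEFAULT_PALETTE = "autumn_r"

_BAR_WIDTH = 16
_MARGIN = 6
_TEXT_WIDTH = 52


def colorize(
    grid: np.ndarray,
    vmin: float | None = None,
    vmax: float | None = None,
    palette: str = DEFAULT_PALETTE,
    background: tuple[int, int, int] = (245, 245, 245),
) -> np.ndarray:
    """Map a (rows, cols) value grid to uint8 RGB via a palette lookup.

    NaN cells (undefined pixels) get the background color.
    """
    grid = np.asarray(grid, dtype=np.float64)
    valid = np.isfinite(grid)
    if not valid.any():
        raise ValueError("map has no valid pixels")
    if vmin is None:
        vmin = float(grid[valid].min())
    if vmax is None:
        vmax = float(grid[valid].max())
    if vmax > vmin:
        norm = np.clip((grid - vmin) / (vmax - vmin), 0.0, 1.0)
    else:
        norm = np.full_like(grid, 0.5)
    cmap = colormaps[palette]
    rgb = (cmap(np.nan_to_num(norm))[:, :, :3] * 255).astype(np.uint8)
    rgb[~valid] = background
    return rgb


def render_map(
    emap: EntropyMap | np.ndarray,
    output: str,
    vmin: float | None = None,
    vmax: float | None = None,
    palette: str = DEFAULT_PALETTE,
    scale: int = 4,
) -> None:
    """Render a map (EntropyMap or value grid) to a PNG file.

    The tissue area is drawn at ``scale`` image pixels per grid pixel;
    a color bar on the right is annotated with the scale minimum and
    maximum.
    """
    grid = emap.values if isinstance(emap, EntropyMap) else np.asarray(emap, float)
    if int(scale) != scale or scale < 1:
        raise ValueError("scale must be a positive integer")
    valid = np.isfinite(grid)
    if not valid.any():
        raise ValueError("map has no valid pixels")
    lo = float(grid[valid].min()) if vmin is None else vmin
    hi = float(grid[valid].max()) if vmax is None else vmax

    rgb = colorize(grid, vmin=lo, vmax=hi, palette=palette)
    h, w = rgb.shape[:2]
    s = int(scale)
    tissue = Image.fromarray(rgb, "RGB").resize((w * s, h * s), Image.NEAREST)

    height = h * s
    bar_vals = np.linspace(hi, lo, max(height, 2)).reshape(-1, 1)
    bar = colorize(bar_vals, vmin=lo, vmax=hi, palette=palette)
    bar_img = Image.fromarray(np.repeat(bar, _BAR_WIDTH, axis=1), "RGB")

    canvas = Image.new(
        "RGB", (w * s + 2 * _MARGIN + _BAR_WIDTH + _TEXT_WIDTH, height),
        (255, 255, 255))
    canvas.paste(tissue, (0, 0))
    canvas.paste(bar_img, (w * s + _MARGIN, 0))
    draw = ImageDraw.Draw(canvas)
    tx = w * s + _MARGIN + _BAR_WIDTH + 4
    draw.text((tx, 1), f"{hi:.2f}", fill=(0, 0, 0))
    draw.text((tx, max(height - 12, 0)), f"{lo:.2f}", fill=(0, 0, 0))
    canvas.save(output, format="PNG")
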