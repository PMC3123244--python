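"""Frame rendering and animation assembly.

Each pairwise comparison becomes one raster frame: compartment bands,
edges (PPI solid, coexpression dashed), and nodes coloured on a continuous
red-to-green gradient — red for up-regulation, green for down-regulation,
a configurable neutral colour (black by default, the microarray
convention) at log2fc = 0, saturating at ``color_saturation``.  Frames are
stacked into an animated GIF plus a self-contained HTML flipbook for
stepping through comparisons by eye, which is the discovery mode this
kind of analysis is built for.

Rendering is pure Pillow drawing with no global state, so identical
inputs produce byte-identical images.
"""

from __future__ import annotations

import base64
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .layout import LayoutCoordinates

__all__ = ["FrameStyle", "fc_to_color", "render_frame", "assemble_animation"]

RGB = tuple[int, int, int]


@dataclass(frozen=True)
class FrameStyle:
    """Visual parameters for a frame."""

    node_radius: int = 6
    neutral_color: RGB = (0, 0, 0)
    saturation: float = 2.0  # |log2fc| at full red/green
    background: RGB = (255, 255, 255)
    band_colors: tuple[RGB, RGB] = ((245, 245, 245), (235, 235, 235))
    ppi_color: RGB = (40, 40, 40)
    coexpr_color: RGB = (150, 150, 150)
    label_color: RGB = (90, 90, 90)
    scale: float = 28.0  # canvas units -> pixels
    margin: int = 60
    dash: tuple[int, int] = (6, 4)


def fc_to_color(log2fc: float, style: FrameStyle | None = None) -> RGB:
    """Map a log2 fold change to an RGB colour.

    Linear interpolation from the neutral colour to pure red (positive) or
    pure green (negative), clamped at ±saturation.  With a neutral colour
    whose red and green channels are equal, the map is odd under hue
    exchange: ``fc_to_color(-x)`` equals ``fc_to_color(x)`` with red and
    green swapped.
    """
    style = style or FrameStyle()
    if not np.isfinite(log2fc):
        raise ValueError(f"log2fc must be finite, got {log2fc}")
    t = min(abs(float(log2fc)) / style.saturation, 1.0)
    full = (255, 0, 0) if log2fc > 0 else (0, 255, 0)
    if log2fc == 0:
        return tuple(style.neutral_color)
    return tuple(
        int(round(n + t * (f - n))) for n, f in zip(style.neutral_color, full)
    )


def _to_pixels(coords: LayoutCoordinates, style: FrameStyle) -> tuple[dict[str, tuple[int, int]], dict[str, tuple[int, int]], tuple[int, int]]:
    xs = [p[0] for p in coords.positions.values()] or [0.0]
    x_min, x_max = min(xs), max(xs)
    y_max_band = max(b[1] for b in coords.bands.values())
    width = int((x_max - x_min) * style.scale) + 2 * style.margin
    height = int(y_max_band * style.scale) + 2 * style.margin

    def px(x: float, y: float) -> tuple[int, int]:
        return (
            int(round((x - x_min) * style.scale)) + style.margin,
            int(round(y * style.scale)) + style.margin,
        )

    node_px = {n: px(x, y) for n, (x, y) in coords.positions.items()}
    band_px = {
        layer: (px(0, top)[1], px(0, bottom)[1]) for layer, (top, bottom) in coords.bands.items()
    }
    return node_px, band_px, (width, height)


def _dashed_line(draw: ImageDraw.ImageDraw, a: tuple[int, int], b: tuple[int, int], color: RGB, dash: tuple[int, int]) -> None:
    ax, ay, bx, by = float(a[0]), float(a[1]), float(b[0]), float(b[1])
    length = ((bx - ax) ** 2 + (by - ay) ** 2) ** 0.5
    if length == 0:
        return
    ux, uy = (bx - ax) / length, (by - ay) / length
    on, off = dash
    pos = 0.0
    while pos < length:
        end = min(pos + on, length)
        draw.line(
            [(ax + ux * pos, ay + uy * pos), (ax + ux * end, ay + uy * end)],
            fill=color,
            width=1,
        )
        pos = end + off


def render_frame(
    network,
    coords: LayoutCoordinates,
    log2fc: dict[str, float],
    label: str,
    style: FrameStyle | None = None,
) -> Image.Image:
    """Render one comparison as an RGB image.

    Bands are painted first, then edges (under nodes), then nodes coloured
    by :func:`fc_to_color`, then the comparison label.  Nodes missing from
    ``log2fc`` are drawn in the neutral colour.
    """
    style = style or FrameStyle()
    missing = [n for n in network.nodes if n not in coords.positions]
    if missing:
        raise ValueError(f"layout is missing coordinates for node(s): {missing[:5]}")
    node_px, band_px, size = _to_pixels(coords, style)
    img = Image.new("RGB", size, style.background)
    draw = ImageDraw.Draw(img)

    for i, (layer, (top, bottom)) in enumerate(sorted(band_px.items(), key=lambda kv: kv[1][0])):
        draw.rectangle([0, top, size[0], bottom], fill=style.band_colors[i % 2])
        draw.text((4, top + 2), layer, fill=style.label_color)

    for a, b, key in sorted(network.edges(keys=True)):
        pa, pb = node_px[a], node_px[b]
        if key == "coexpr":
            _dashed_line(draw, pa, pb, style.coexpr_color, style.dash)
        else:
            draw.line([pa, pb], fill=style.ppi_color, width=1)

    r = style.node_radius
    for n in sorted(network.nodes):
        cx, cy = node_px[n]
        color = fc_to_color(log2fc.get(n, 0.0), style)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=color, outline=(60, 60, 60))

    draw.text((style.margin, 8), label, fill=(0, 0, 0))
    return img


def assemble_animation(
    frames: list[Image.Image],
    out_dir: str | Path,
    frame_duration_ms: int = 1000,
    loop: bool = True,
    labels: list[str] | None = None,
) -> dict[str, Path]:
    """Write per-frame PNGs, an animated GIF, and an HTML flipbook.

    Frames must share dimensions and are written in the given order (the
    animation order of the comparisons).  The flipbook embeds the PNGs as
    base64 and steps with the arrow keys, for repeated manual inspection.
    Returns the paths written.
    """
    if not frames:
        raise ValueError("need at least one frame")
    sizes = {f.size for f in frames}
    if len(sizes) > 1:
        raise ValueError(f"frames have mixed dimensions: {sorted(sizes)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    labels = labels or [f"frame_{i + 1}" for i in range(len(frames))]

    png_paths = []
    encoded = []
    for i, frame in enumerate(frames):
        p = out_dir / f"frame_{i + 1:02d}.png"
        frame.save(p, format="PNG")
        png_paths.append(p)
        buf = _stdio.BytesIO()
        frame.save(buf, format="PNG")
        encoded.append(base64.b64encode(buf.getvalue()).decode("ascii"))

    gif_path = out_dir / "animation.gif"
    frames[0].save(
        gif_path,
        format="GIF",
        save_all=True,
        append_images=frames[1:],
        duration=frame_duration_ms,
        loop=0 if loop else 1,
    )

    imgs_js = ",".join(f'"data:image/png;base64,{e}"' for e in encoded)
    labels_js = ",".join(f'"{l}"' for l in labels)
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>comparison flipbook</title></head>
<body style="font-family:sans-serif">
<p id="label"></p><img id="frame" alt="network frame">
<p>left/right arrows step through comparisons; space plays.</p>
<script>
const imgs=[{imgs_js}];const labels=[{labels_js}];let i=0;let timer=null;
function show(){{document.getElementById('frame').src=imgs[i];
document.getElementById('label').textContent=(i+1)+'/'+imgs.length+': '+labels[i];}}
document.addEventListener('keydown',e=>{{
if(e.key==='ArrowRight')i=(i+1)%imgs.length;
if(e.key==='ArrowLeft')i=(i-1+imgs.length)%imgs.length;
if(e.key===' ')timer?(clearInterval(timer),timer=null):timer=setInterval(()=>{{i=(i+1)%imgs.length;show();}},{frame_duration_ms});
show();}});
show();
</script></body></html>
"""
    html_path = out_dir / "flipbook.html"
    html_path.write_text(html, encoding="utf-8")
    return {"gif": gif_path, "html": html_path, "frames": png_paths}
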