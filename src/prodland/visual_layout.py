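"""Deterministic layout geometry and static rendering of the landscape views.

Five encodings are produced: ensemble spaghetti plots (one polyline per time
step over a protein's copy-number axis, colour intensity encoding time),
stacked 1D heatmaps, 2D heatmaps optionally enhanced with per-cell time
curves, peak glyphs (a stack of horizontal bars, one per protein, bar length
encoding the peak's copy numbers and fill intensity its probability; suspect
peaks are greyed), and 3D probability surfaces with an animation across
time.

Layout geometry is computed by pure functions of (data, options) and is
serialisable to JSON sidecars, so rendering determinism is testable without
comparing raster images.  Colour and height scales are strictly per panel —
never normalised across panels — because peak values span orders of
magnitude and cross-panel normalisation hides small peaks.
"""

from __future__ import annotations

import base64
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landscape_io import SpeciesDescriptor
from .peak_analysis import SystemPeak
from .projection import MarginalSeries1D, MarginalSeries2D

#: fixed qualitative palette for species hues (colour-blind-safe classes).
SPECIES_PALETTE = [
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02",
]
#: number of classes in the qualitative probability colormap.
QUALITATIVE_CLASSES = 7
#: above this many cells, time-curve overlays are restricted to the
#: top-variance cells to avoid sub-pixel clutter.
OVERLAY_CELL_FLOOR = 2000


def _species_hue(index: int) -> str:
    return SPECIES_PALETTE[index % len(SPECIES_PALETTE)]


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj))
    return obj


def write_geometry_sidecar(layout, path: str | Path) -> Path:
    """Serialize a layout's geometry deterministically (sorted keys,
    12-significant-digit floats)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(_round_floats(layout.to_dict()), fh, sort_keys=True, indent=1)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# spaghetti plots
# ---------------------------------------------------------------------------

@dataclass
class SpaghettiLayout:
    """One polyline per time step over a species' copy-number axis; the
    polyline intensity ramps linearly from light (early) to dark (late)."""

    species: str
    hue: str
    axis: np.ndarray
    polylines: np.ndarray      # (T, C) probability vertices over axis
    intensities: np.ndarray    # (T,) in (0, 1], non-decreasing
    time_indices: np.ndarray

    def to_dict(self) -> dict:
        return {
            "view": "spaghetti",
            "species": self.species,
            "hue": self.hue,
            "axis": self.axis,
            "polylines": self.polylines,
            "intensities": self.intensities,
            "time_indices": self.time_indices,
        }


def spaghetti_layout(
    marginal: MarginalSeries1D,
    selected_time: int | None = None,
    species_index: int = 0,
) -> SpaghettiLayout:
    """Spaghetti geometry for one protein; ``selected_time`` restricts the
    view to a single time step's polyline at full intensity."""
    t = marginal.n_times
    if t < 1:
        raise ValueError("marginal has no time steps")
    intensities = np.linspace(1.0 / t, 1.0, t)
    indices = np.arange(t)
    lines = marginal.probs.T
    if selected_time is not None:
        if not 0 <= selected_time < t:
            raise IndexError(f"selected_time {selected_time} outside 0..{t - 1}")
        lines = lines[[selected_time]]
        intensities = np.array([1.0])
        indices = np.array([selected_time])
    return SpaghettiLayout(
        species=marginal.species.name,
        hue=_species_hue(species_index),
        axis=marginal.axis.copy(),
        polylines=lines.copy(),
        intensities=intensities,
        time_indices=indices,
    )


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

@dataclass
class HeatmapLayout:
    """Cell grid with per-cell colour values and optional per-cell time
    curves rescaled into the unit cell box.

    ``color_values`` are normalised to this panel's own maximum only; with
    the qualitative colormap, ``classes`` holds the per-cell class index
    under logarithmically spaced probability boundaries.
    """

    axis_labels: tuple[str, ...]
    values: np.ndarray
    color_values: np.ndarray
    colormap: str
    time_index: int
    classes: np.ndarray | None = None
    class_boundaries: np.ndarray | None = None
    overlays: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "view": "heatmap",
            "axis_labels": list(self.axis_labels),
            "values": self.values,
            "color_values": self.color_values,
            "colormap": self.colormap,
            "time_index": self.time_index,
        }
        if self.classes is not None:
            d["classes"] = self.classes
            d["class_boundaries"] = self.class_boundaries
        if self.overlays:
            d["overlays"] = {
                ",".join(map(str, k)): v for k, v in sorted(self.overlays.items())
            }
        return d


def _qualitative_classes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vmax = values.max()
    if vmax <= 0:
        return np.zeros_like(values, dtype=int), np.zeros(0)
    # class boundaries at log-spaced fractions of the panel maximum
    boundaries = vmax * 10.0 ** np.arange(-(QUALITATIVE_CLASSES - 1), 0)
    classes = np.digitize(values, boundaries)
    return classes, boundaries


def heatmap_layout(
    marginal: MarginalSeries1D | MarginalSeries2D,
    time_index: int,
    overlay_curves: bool = False,
    colormap: str = "sequential",
    overlay_cell_floor: int = OVERLAY_CELL_FLOOR,
) -> HeatmapLayout:
    """Heatmap geometry at one time step.

    1D marginals become a single-row grid.  Colour is scaled by this
    panel's maximum only (no cross-panel normalisation).  Overlay curves
    are each cell's full time curve rescaled into the unit cell box by the
    cell's own maximum, so the overlay conveys shape; when the grid
    exceeds ``overlay_cell_floor`` cells only the top cells by temporal
    variance keep their overlay.
    """
    if colormap not in ("sequential", "qualitative"):
        raise ValueError(f"unknown colormap {colormap!r}")
    if isinstance(marginal, MarginalSeries1D):
        if not 0 <= time_index < marginal.n_times:
            raise IndexError(f"time_index {time_index} outside grid")
        values = marginal.column(time_index)[np.newaxis, :]
        series = marginal.probs[np.newaxis, :, :]
        labels = ("", marginal.species.name)
    elif isinstance(marginal, MarginalSeries2D):
        if not 0 <= time_index < marginal.n_times:
            raise IndexError(f"time_index {time_index} outside grid")
        values = marginal.frame(time_index)
        series = marginal.grid
        labels = (marginal.species_pair[0].name, marginal.species_pair[1].name)
    else:
        raise TypeError(f"unsupported marginal type {type(marginal).__name__}")

    vmax = values.max()
    color_values = values / vmax if vmax > 0 else np.zeros_like(values)
    classes = boundaries = None
    if colormap == "qualitative":
        classes, boundaries = _qualitative_classes(values)

    overlays: dict = {}
    if overlay_curves:
        cells = [
            (i, j) for i in range(values.shape[0]) for j in range(values.shape[1])
        ]
        if len(cells) > overlay_cell_floor:
            variance = series.var(axis=2)
            order = np.argsort(variance.ravel(), kind="stable")[::-1]
            keep = set(map(tuple, np.array(np.unravel_index(
                order[:overlay_cell_floor], values.shape)).T.tolist()))
            cells = [c for c in cells if c in keep]
        t_norm = (
            np.linspace(0.0, 1.0, series.shape[2])
            if series.shape[2] > 1
            else np.array([0.5])
        )
        for i, j in cells:
            curve = series[i, j, :]
            cmax = curve.max()
            v_norm = curve / cmax if cmax > 0 else np.zeros_like(curve)
            overlays[(i, j)] = np.column_stack([t_norm, v_norm])
    return HeatmapLayout(
        axis_labels=labels,
        values=values.copy(),
        color_values=color_values,
        colormap=colormap,
        time_index=time_index,
        classes=classes,
        class_boundaries=boundaries,
        overlays=overlays,
    )


# ---------------------------------------------------------------------------
# peak glyphs
# ---------------------------------------------------------------------------

@dataclass
class GlyphSpec:
    """One peak state as a stack of horizontal bars (one per protein).

    Bar length is the peak's copy number as a fraction of that protein's
    maximum; fill intensity encodes the peak's probability relative to
    ``value_scale``; suspect peaks are drawn grey.
    """

    species: tuple[str, ...]
    bar_lengths: tuple[float, ...]
    location: tuple[int, ...]
    intensity: float
    gray: bool
    value: float

    def to_dict(self) -> dict:
        return {
            "view": "glyph",
            "species": list(self.species),
            "bar_lengths": list(self.bar_lengths),
            "location": list(self.location),
            "intensity": self.intensity,
            "gray": self.gray,
            "value": self.value,
        }


def glyph_spec(
    peak: SystemPeak,
    species: Sequence[SpeciesDescriptor],
    value_scale: float = 1.0,
) -> GlyphSpec:
    """Glyph geometry for one evaluated, classified system peak."""
    proteins = [s for s in species if s.is_protein]
    if len(proteins) != len(peak.location):
        raise ValueError(
            f"peak location has {len(peak.location)} components for "
            f"{len(proteins)} protein species"
        )
    if peak.value is None:
        raise ValueError("peak must be evaluated before building its glyph")
    lengths = tuple(
        c / s.max_copies if s.max_copies > 0 else 0.0
        for c, s in zip(peak.location, proteins)
    )
    if any(not 0 <= ln <= 1 for ln in lengths):
        raise ValueError("peak location outside its species axis")
    intensity = float(np.clip(peak.value / value_scale, 0.0, 1.0)) if value_scale > 0 else 0.0
    return GlyphSpec(
        species=tuple(s.name for s in proteins),
        bar_lengths=lengths,
        location=tuple(peak.location),
        intensity=intensity,
        gray=bool(peak.suspect),
        value=float(peak.value),
    )


# ---------------------------------------------------------------------------
# 3D surface
# ---------------------------------------------------------------------------

@dataclass
class SurfaceFrames:
    """Per-time height fields of a 2D marginal (frame t = grid[:, :, t])."""

    species_pair: tuple[str, str]
    frames: np.ndarray       # (T, A, B)
    times: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_dict(self) -> dict:
        return {
            "view": "surface",
            "species_pair": list(self.species_pair),
            "frames": self.frames,
            "times": self.times,
        }


def surface_frames(marginal: MarginalSeries2D) -> SurfaceFrames:
    """Height fields for the 3D surface view: frame t equals the 2D grid at
    time t, exactly (no normalisation)."""
    return SurfaceFrames(
        species_pair=(
            marginal.species_pair[0].name,
            marginal.species_pair[1].name,
        ),
        frames=np.moveaxis(marginal.grid, 2, 0).copy(),
        times=marginal.times.copy(),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spaghetti(layout: SpaghettiLayout, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 3))
    base = matplotlib.colors.to_rgb(layout.hue)
    for line, inten in zip(layout.polylines, layout.intensities):
        color = tuple(1 - inten * (1 - c) for c in base)
        ax.plot(layout.axis, line, color=color, linewidth=0.9)
    ax.set_xlabel(f"{layout.species} copy number")
    ax.set_ylabel("probability")
    ax.set_title(f"{layout.species} (light = early, dark = late)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def _heatmap_colors(layout: HeatmapLayout):
    if layout.colormap == "qualitative":
        cmap = plt.get_cmap("Set1", QUALITATIVE_CLASSES)
        return cmap(layout.classes)
    cmap = plt.get_cmap("Blues")
    return cmap(layout.color_values)


def render_heatmap(layout: HeatmapLayout, path: str | Path) -> Path:
    rows, cols = layout.values.shape
    fig, ax = plt.subplots(figsize=(max(4, cols * 0.08), max(1.2, rows * 0.08)))
    ax.imshow(
        _heatmap_colors(layout), origin="lower", aspect="auto",
        extent=(-0.5, cols - 0.5, -0.5, rows - 0.5), interpolation="nearest",
    )
    for (i, j), curve in layout.overlays.items():
        ax.plot(
            j - 0.45 + 0.9 * curve[:, 0],
            i - 0.45 + 0.9 * curve[:, 1],
            color="#555555", linewidth=0.5,
        )
    ax.set_xlabel(f"{layout.axis_labels[1]} copy number")
    if layout.axis_labels[0]:
        ax.set_ylabel(f"{layout.axis_labels[0]} copy number")
    else:
        ax.set_yticks([])
    ax.set_title(
        f"time index {layout.time_index} "
        f"(panel max {layout.values.max():.3g})"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def render_glyphs(
    glyphs: Sequence[GlyphSpec], path: str | Path, columns: int = 4
) -> Path:
    """Small-multiple panel of peak glyphs; an empty peak list renders an
    explanatory placeholder."""
    if not glyphs:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no peaks detected", ha="center", va="center")
        ax.axis("off")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        return Path(path)
    n = len(glyphs)
    ncols = min(columns, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(2.2 * ncols, 1.4 * nrows), squeeze=False
    )
    cmap = plt.get_cmap("Blues")
    for k, g in enumerate(glyphs):
        ax = axes[k // ncols][k % ncols]
        color = "#9e9e9e" if g.gray else cmap(0.25 + 0.75 * g.intensity)
        y = np.arange(len(g.bar_lengths))
        ax.barh(y, g.bar_lengths, color=color, height=0.7)
        ax.set_xlim(0, 1)
        ax.set_yticks(y, g.species, fontsize=7)
        ax.invert_yaxis()
        ax.set_xticks([])
        ax.set_title(
            f"{g.location}  p={g.value:.3g}" + ("  [suspect]" if g.gray else ""),
            fontsize=7,
        )
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path)


def _surface_figure(frame: np.ndarray, pair: tuple[str, str], title: str):
    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    a = np.arange(frame.shape[0])
    b = np.arange(frame.shape[1])
    bb, aa = np.meshgrid(b, a)
    ax.plot_surface(aa, bb, frame, cmap="viridis", linewidth=0)
    ax.set_xlabel(pair[0])
    ax.set_ylabel(pair[1])
    ax.set_zlabel("probability")
    ax.set_title(title, fontsize=9)
    return fig


def render_surface_animation(frames: SurfaceFrames, path: str | Path) -> Path:
    """GIF animation of the probability surface across all time steps."""
    import matplotlib.animation as manim

    fig = plt.figure(figsize=(5, 4))
    ax = fig.add_subplot(projection="3d")
    a = np.arange(frames.frames.shape[1])
    b = np.arange(frames.frames.shape[2])
    bb, aa = np.meshgrid(b, a)

    def draw(t):
        ax.clear()
        ax.plot_surface(aa, bb, frames.frames[t], cmap="viridis", linewidth=0)
        ax.set_xlabel(frames.species_pair[0])
        ax.set_ylabel(frames.species_pair[1])
        ax.set_title(f"t = {frames.times[t]:g}", fontsize=9)

    anim = manim.FuncAnimation(fig, draw, frames=frames.n_frames)
    anim.save(str(path), writer=manim.PillowWriter(fps=4))
    plt.close(fig)
    return Path(path)


def render_surface_html(frames: SurfaceFrames, path: str | Path) -> Path:
    """Self-contained HTML page with a frame slider over pre-rendered
    surface snapshots (no external libraries)."""
    images = []
    for t in range(frames.n_frames):
        fig = _surface_figure(
            frames.frames[t],
            frames.species_pair,
            f"{frames.species_pair[0]} x {frames.species_pair[1]}  "
            f"t = {frames.times[t]:g}",
        )
        buf = io.BytesIO()
        fig.savefig(buf, format="png", dpi=90)
        plt.close(fig)
        images.append(base64.b64encode(buf.getvalue()).decode("ascii"))
    payload = json.dumps(images)
    html = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>probability surface</title></head>
<body>
<h3>Probability surface: {frames.species_pair[0]} x {frames.species_pair[1]}</h3>
<input type="range" id="slider" min="0" max="{frames.n_frames - 1}" value="0">
<span id="label"></span><br>
<img id="frame" alt="surface frame">
<script>
const frames = {payload};
const img = document.getElementById("frame");
const slider = document.getElementById("slider");
const label = document.getElementById("label");
function show(t) {{
  img.src = "data:image/png;base64," + frames[t];
  label.textContent = "frame " + t;
}}
slider.addEventListener("input", () => show(slider.value));
show(0);
</script>
</body></html>
"""
    path = Path(path)
    path.write_text(html)
    return path


def render_report(
    landscape,
    out_dir: str | Path,
    time_index: int = -1,
    threshold: float = 1e-12,
    suspect_threshold: float = 1e-6,
    colormap: str = "sequential",
    views: Sequence[str] = ("spaghetti", "heat1d", "heat2d", "glyphs", "surface"),
    overlay_curves: bool = True,
    animate: bool = False,
) -> list[Path]:
    """Render the full small-multiple report of a landscape.

    One file per view per projection, with a JSON geometry sidecar next to
    every raster so re-runs can be compared byte-for-byte.  Scales are per
    panel; nothing is normalised across panels.
    """
    from .peak_analysis import find_system_peaks
    from .projection import all_marginals_1d, all_marginals_2d

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if time_index < 0:
        time_index = landscape.n_times + time_index
    written: list[Path] = []

    m1 = all_marginals_1d(landscape)
    if "spaghetti" in views:
        for k, (name, marg) in enumerate(m1.items()):
            lay = spaghetti_layout(marg, species_index=k)
            written.append(render_spaghetti(lay, out / f"spaghetti_{name}.png"))
            written.append(
                write_geometry_sidecar(lay, out / f"spaghetti_{name}.json")
            )
    if "heat1d" in views:
        for name, marg in m1.items():
            lay = heatmap_layout(marg, time_index, colormap=colormap)
            written.append(render_heatmap(lay, out / f"heat1d_{name}.png"))
            written.append(
                write_geometry_sidecar(lay, out / f"heat1d_{name}.json")
            )
    need_2d = {"heat2d", "surface"} & set(views)
    if need_2d and len(landscape.state_space.proteins) >= 2:
        for (a, b), marg in all_marginals_2d(landscape).items():
            if "heat2d" in views:
                lay = heatmap_layout(
                    marg, time_index, overlay_curves=overlay_curves,
                    colormap=colormap,
                )
                written.append(
                    render_heatmap(lay, out / f"heat2d_{a}_{b}.png")
                )
                written.append(
                    write_geometry_sidecar(lay, out / f"heat2d_{a}_{b}.json")
                )
            if "surface" in views:
                frames = surface_frames(marg)
                written.append(
                    render_surface_html(frames, out / f"surface_{a}_{b}.html")
                )
                written.append(
                    write_geometry_sidecar(frames, out / f"surface_{a}_{b}.json")
                )
                if animate:
                    written.append(
                        render_surface_animation(
                            frames, out / f"surface_{a}_{b}.gif"
                        )
                    )
    if "glyphs" in views:
        peaks = find_system_peaks(
            landscape, time_index, threshold, suspect_threshold
        )
        authentic = [pk.value for pk in peaks if not pk.suspect]
        scale = max(authentic) if authentic else 1.0
        glyphs = [
            glyph_spec(pk, landscape.state_space.species, value_scale=scale)
            for pk in peaks
        ]
        written.append(render_glyphs(glyphs, out / "glyphs.png"))
        with open(out / "glyphs.json", "w") as fh:
            json.dump(
                [_round_floats(g.to_dict()) for g in glyphs],
                fh, sort_keys=True, indent=1,
            )
            fh.write("\n")
        written.append(out / "glyphs.json")
    return written
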