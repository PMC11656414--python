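"""Pseudospectrum rendering.

The display convention: the x axis is the 1H chemical shift in ppm,
decreasing left to right as in any NMR spectrum; the curve height is the
covariance with activity (left y axis, positive peaks = positive
covariance); the line color encodes the Pearson correlation coefficient
(right y axis / colorbar), running from blue at low correlation to deep red
at high correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")  # file output only; no display needed

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection

from .correlation import Pseudospectrum
from .spectral import ValidationError

__all__ = ["PlotSpec", "render_pseudospectrum"]


@dataclass(frozen=True)
class PlotSpec:
    """Rendering options for a pseudospectrum.

    window      : (lo, hi) ppm range to draw; None = full range.
    color_mode  : "signed" colors r in [-1, 1] with a diverging map;
                  "magnitude" colors |r| in [0, 1] blue -> red.
    cmap        : matplotlib colormap name (defaults per mode).
    """

    window: tuple[float, float] | None = None
    color_mode: str = "magnitude"
    cmap: str | None = None
    title: str | None = None

    def __post_init__(self) -> None:
        if self.color_mode not in ("signed", "magnitude"):
            raise ValidationError("color_mode must be 'signed' or 'magnitude'")


def render_pseudospectrum(ps: Pseudospectrum, spec: PlotSpec = PlotSpec(),
                          out: str | None = None):
    """Draw a covariance-height / correlation-color pseudospectrum.

    Returns the matplotlib figure; writes it to ``out`` (PNG/SVG by
    extension) when a path is given.  Inputs are never modified.
    """
    ppm = ps.ppm_centers
    cov = ps.covariance
    r = ps.correlation
    if spec.window is not None:
        lo, hi = sorted(spec.window)
        keep = (ppm >= lo) & (ppm <= hi)
        if not keep.any():
            raise ValidationError(f"no variables inside window {lo}..{hi} ppm")
        ppm, cov, r = ppm[keep], cov[keep], r[keep]
    order = np.argsort(ppm)[::-1]  # descending ppm, left to right
    ppm, cov, r = ppm[order], cov[order], r[order]

    if spec.color_mode == "signed":
        cmap = plt.get_cmap(spec.cmap or "RdBu_r")
        norm = plt.Normalize(-1.0, 1.0)
        color_values = r
        bar_label = "Pearson r"
    else:
        cmap = plt.get_cmap(spec.cmap or "jet")
        norm = plt.Normalize(0.0, 1.0)
        color_values = np.abs(r)
        bar_label = "|Pearson r|"

    points = np.column_stack([ppm, cov]).reshape(-1, 1, 2)
    segments = np.concatenate([points[:-1], points[1:]], axis=1)
    seg_colors = 0.5 * (color_values[:-1] + color_values[1:])

    fig, ax = plt.subplots(figsize=(10, 4))
    lc = LineCollection(segments, cmap=cmap, norm=norm, linewidths=1.0)
    lc.set_array(seg_colors)
    ax.add_collection(lc)
    ax.set_xlim(ppm.max(), ppm.min())  # NMR convention: ppm decreasing
    pad = 0.05 * (np.ptp(cov) or 1.0)
    ax.set_ylim(cov.min() - pad, cov.max() + pad)
    ax.axhline(0.0, color="0.7", lw=0.5, zorder=0)
    ax.set_xlabel(r"$^1$H chemical shift (ppm)")
    ax.set_ylabel("covariance with activity")
    ax.set_title(spec.title or ps.source)
    cbar = fig.colorbar(lc, ax=ax)
    cbar.set_label(bar_label)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
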