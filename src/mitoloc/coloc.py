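"""Membrane-potential readout by dual-marker co-localisation.

Mitochondrial membrane potential (MMP) drives the import of the red marker
(preCOX4-mCherry) while the green marker (preSU9-GFP) imports independently
of MMP.  With an intact potential both markers occupy the same voxels and
their per-cell Pearson correlation is high; when the potential collapses the
red marker spreads through the cytosol and the correlation drops toward a
floor set by the jointly dark background.  The statistic is computed in 3D
over the voxels of a smoothed-Otsu cell mask of the cropped cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .masking import ConstantVolumeError, cell_mask
from .stacks import BinaryVolume, CellROI, ImageStack, crop_cell

__all__ = [
    "ColocResult",
    "pearson_cc",
    "r_squared",
    "batch_coloc",
    "min_cells_power",
    "group_summary",
]

#: fraction of mask voxels at the channel maximum above which a cell is
#: flagged as saturated
SATURATION_FLAG_FRACTION = 0.01


@dataclass
class ColocResult:
    cell_label: str
    pcc: float | None
    r2: float | None
    n_voxels: int
    mask_provenance: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.pcc is not None


def _masked_pair(green, red, mask: BinaryVolume):
    g = np.asarray(green, dtype=np.float64)[mask.mask]
    r = np.asarray(red, dtype=np.float64)[mask.mask]
    if g.size < 2:
        raise ValueError("need at least 2 masked voxels")
    if g.std() == 0 or r.std() == 0:
        raise ValueError("zero variance in a channel within the mask")
    return g, r


def pearson_cc(green: np.ndarray, red: np.ndarray, mask: BinaryVolume) -> float:
    """Pearson correlation of the two channels over the masked voxels."""
    g, r = _masked_pair(green, red, mask)
    return float(stats.pearsonr(g, r).statistic)


def r_squared(green: np.ndarray, red: np.ndarray, mask: BinaryVolume) -> float:
    """Coefficient of determination of the least-squares fit red ~ green.

    With a single predictor this equals the squared Pearson correlation.
    """
    return pearson_cc(green, red, mask) ** 2


def batch_coloc(
    stack: ImageStack,
    rois: list[CellROI],
    sigma: float = 5.0,
    green: str | int = "gfp",
    red: str | int = "mcherry",
    subtract_background: bool = False,
) -> list[ColocResult]:
    """Per-cell co-localisation over a list of ROIs.

    Each ROI is cropped, a cell mask is built (Gaussian blur sigma then Otsu
    on the channel sum) and PCC/R² are computed over the masked voxels.
    Cells violating preconditions (flat intensities, degenerate masks) are
    returned with an error flag rather than silently dropped.  Background is
    not subtracted by default — the jointly dark background contributes a
    correlation floor that is part of the measurement's behaviour —
    ``subtract_background`` removes the per-channel mode-of-histogram
    estimate first.
    """
    out: list[ColocResult] = []
    for roi in rois:
        try:
            cell = crop_cell(stack, roi)
            mask = cell_mask(cell, sigma=sigma)
            g = cell.channel(green).astype(np.float64)
            r = cell.channel(red).astype(np.float64)
            if subtract_background:
                g = np.clip(g - _background_level(g), 0, None)
                r = np.clip(r - _background_level(r), 0, None)
            flags = []
            for name, chan in (("green", g), ("red", r)):
                sat = (chan[mask.mask] >= chan.max()).mean() if chan.max() > 0 else 0.0
                if chan.max() > 0 and sat > SATURATION_FLAG_FRACTION:
                    flags.append(f"saturated_{name}")
            pcc = pearson_cc(g, r, mask)
            out.append(
                ColocResult(roi.label, pcc, pcc**2, mask.n_foreground, mask.provenance, flags)
            )
        except (ValueError, ConstantVolumeError, KeyError) as exc:
            out.append(ColocResult(roi.label, None, None, 0, {}, [f"error: {exc}"]))
    return out


def _background_level(volume: np.ndarray) -> float:
    """Most common intensity (histogram mode over 256 bins) as background."""
    hist, edges = np.histogram(volume, bins=256)
    i = int(hist.argmax())
    return float((edges[i] + edges[i + 1]) / 2)


def group_summary(results: list[ColocResult]) -> dict:
    """Mean ± SEM of PCC over the successfully measured cells of one group."""
    vals = [r.pcc for r in results if r.ok]
    n = len(vals)
    summary = {
        "n": n,
        "n_failed": len(results) - n,
        "mean_pcc": float(np.mean(vals)) if n else None,
        "sem_pcc": float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else None,
    }
    return summary


def min_cells_power(
    pcc_a: list[float],
    pcc_b: list[float],
    alpha: float = 0.05,
    power: float = 0.8,
    n_max: int = 10_000,
) -> float:
    """Smallest per-group cell count for a two-sample comparison of PCC means.

    The effect size is the pooled-SD Cohen's d of the two observed groups;
    the required n solves the normal-approximation power equation for a
    two-sided two-sample z-test,
    ``power = Phi(d*sqrt(n/2) - z_{1-alpha/2})``, searched over integer n.
    Returns ``inf`` when the observed effect is zero.
    """
    a = np.asarray(pcc_a, dtype=np.float64)
    b = np.asarray(pcc_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (len(a) + len(b) - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    d = abs(a.mean() - b.mean()) / math.sqrt(sp2)
    if d == 0:
        return float("inf")
    z_alpha = stats.norm.ppf(1 - alpha / 2)
    for n in range(2, n_max + 1):
        achieved = stats.norm.cdf(d * math.sqrt(n / 2.0) - z_alpha)
        if achieved >= power:
            return float(n)
    return float("inf")
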