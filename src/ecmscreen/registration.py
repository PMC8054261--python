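"""Co-registration of cell centroids with the segmented disc mask.

Detection tables use 0-based continuous pixel coordinates with x = column
and y = row (the dialect of the synthetic generator's CSV export). A
centroid is on-disc iff the mask pixel at its round-half-up coordinates is
foreground — a single deterministic rule for boundary cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .segmentation import DiscMask
from .types import GrowthCurve

__all__ = ["register_cells", "on_disc_growth_curve", "registration_summary"]

REQUIRED_COLUMNS = ("well", "time_h", "x_px", "y_px", "viability")


def _round_half_up(v: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(v, float) + 0.5).astype(int)


def register_cells(cells: pd.DataFrame, mask: DiscMask | np.ndarray) -> pd.DataFrame:
    """Label every detection on-disc / off-disc against the mask.

    Returns a copy of ``cells`` with an ``on_disc`` boolean column; the
    on/off split is exhaustive and exclusive. Out-of-bounds centroids are
    rejected with the offending row index.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"detection table missing columns {missing}")
    grid = np.asarray(getattr(mask, "mask", mask), bool)
    rows = _round_half_up(cells["y_px"].to_numpy())
    cols = _round_half_up(cells["x_px"].to_numpy())
    oob = (rows < 0) | (cols < 0) | (rows >= grid.shape[0]) | (cols >= grid.shape[1])
    if oob.any():
        i = int(np.flatnonzero(oob)[0])
        raise ValueError(f"centroid out of mask bounds at row index {i}")
    out = cells.copy()
    out["on_disc"] = grid[rows, cols]
    return out


def on_disc_growth_curve(registered: pd.DataFrame, condition: dict | None = None) -> GrowthCurve:
    """Per-timepoint live on-disc cell counts, sorted by time.

    Dead cells are excluded; timepoints where no on-disc live cell was
    detected contribute a zero count. A curve with no on-disc cells at all
    is returned with the ``all_off_disc`` flag set in its condition.
    """
    if "on_disc" not in registered.columns:
        raise ValueError("run register_cells first: on_disc column missing")
    times = np.sort(registered["time_h"].unique()).astype(float)
    if len(times) < 2:
        raise ValueError(f"need >= 2 distinct timepoints, got {len(times)}")
    sel = registered[(registered["on_disc"]) & (registered["viability"] == "live")]
    tally = sel.groupby("time_h").size()
    counts = np.array([float(tally.get(t, 0)) for t in times])
    cond = dict(condition or {})
    if counts.sum() == 0:
        cond["all_off_disc"] = True
    return GrowthCurve(times=times, counts=counts, condition=cond)


def registration_summary(registered: pd.DataFrame) -> pd.DataFrame:
    """Per-timepoint tallies of on/off-disc and live/dead detections."""
    g = registered.groupby("time_h")
    return pd.DataFrame(
        {
            "n_total": g.size(),
            "n_on": g["on_disc"].sum().astype(int),
            "n_off": (~registered["on_disc"]).groupby(registered["time_h"]).sum().astype(int),
            "n_live": (registered["viability"] == "live").groupby(registered["time_h"]).sum().astype(int),
            "n_dead": (registered["viability"] == "dead").groupby(registered["time_h"]).sum().astype(int),
        }
    ).reset_index()
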