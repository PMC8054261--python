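"""Seeded synthetic data emulating a high-content CRC screening study.

Four generators, each returning ground truth alongside the data so that
every downstream stage of the analysis can be tested against a known
answer:

* :func:`gen_growth_counts` — exponential live-cell count time series
  N(t) = N0 * exp(r t) with multiplicative lognormal counting noise.
* :func:`gen_dose_response` — a family of such series across an oxaliplatin
  dilution ladder, with growth rates suppressed by a Hill function of dose
  so the true IC50 of the relative-rate curve is known by construction.
* :func:`gen_well_scene` — a 96-well scan containing a circular liver-ECM
  disc: smooth vignetting illumination, higher intensity texture on the
  disc than off it (the premise of the texture segmentation), Gaussian
  nuclear spots on and off the disc with true on/off labels, camera noise.
* :func:`gen_effects_table` — multi-experiment growth-rate tables with
  fixed cell-line and plate-type effects, a shared random experiment-date
  effect and plate-type-specific residual noise, i.e. exactly the
  structure the hierarchical model assumes.

All randomness derives from the top-level ``seed`` of each parameter
object via named substreams (see :mod:`ecmscreen._rng`), so a fixed seed
is bit-reproducible end to end.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .types import FieldImage, GrowthCurve, LightProfile

__all__ = [
    "GrowthParams",
    "DiscSceneParams",
    "EffectsTableSpec",
    "WellScene",
    "gen_growth_counts",
    "gen_dose_response",
    "gen_well_scene",
    "gen_effects_table",
    "write_scene",
    "DEFAULT_DOSES_UM",
]

#: Oxaliplatin 3-fold dilution ladder used throughout the study (uM).
DEFAULT_DOSES_UM: tuple[float, ...] = (0.0, 0.062, 0.185, 0.555, 1.667, 5.0)

#: Default sampling grid: 0-72 h every 12 h.
DEFAULT_TIMES_H: tuple[float, ...] = tuple(float(t) for t in range(0, 73, 12))


# ---------------------------------------------------------------------------
# growth counts
# ---------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """Parameters of the exponential growth-count generator.

    n0
        initial live-cell count, > 0 (cells).
    rate
        specific growth rate r in 1/h; negative values model cytotoxic
        doses that shrink the population.
    times
        sampling times in hours, strictly increasing, >= 0.
    noise_cv
        coefficient of variation of the multiplicative lognormal counting
        noise (0 disables noise). Counting error in confluent imaging
        scales with the count, hence multiplicative rather than additive.
    """

    n0: float = 1500.0
    rate: float = 0.03
    times: Sequence[float] = DEFAULT_TIMES_H
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("times must be a 1-D, non-empty sequence")
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise ValueError(
                f"times must be strictly increasing: offending index {int(bad[0]) + 1}"
            )
        if t[0] < 0:
            raise ValueError("times must be >= 0")
        if not self.n0 > 0:
            raise ValueError("n0 must be > 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        self.times = t


def gen_growth_counts(
    params: GrowthParams, *, poisson: bool = False, condition: dict | None = None
) -> GrowthCurve:
    """Simulate live-cell counts N(t) = round(N0 * exp(r t) * m(t)).

    m(t) is i.i.d. lognormal with mean 1 and coefficient of variation
    ``noise_cv`` (identically 1 when ``noise_cv == 0``). With
    ``poisson=True`` an additional Poisson resampling of the noisy mean is
    applied. Counts are clipped at zero.
    """
    t = np.asarray(params.times, dtype=float)
    expected = params.n0 * np.exp(params.rate * t)
    if params.noise_cv > 0:
        rng = substream(params.seed, "growth-counts")
        sigma2 = math.log1p(params.noise_cv**2)
        m = rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=t.shape)
        expected = expected * m
    if poisson:
        rng_p = substream(params.seed, "growth-counts-poisson")
        counts = rng_p.poisson(np.clip(expected, 0, None)).astype(float)
    else:
        counts = np.round(expected)
    counts = np.clip(counts, 0, None)
    return GrowthCurve(times=t, counts=counts, condition=dict(condition or {}))


def gen_dose_response(
    growth: GrowthParams,
    doses: Sequence[float] = DEFAULT_DOSES_UM,
    hill_ic50: float = 0.32,
    hill_slope: float = 1.0,
    seed: int | None = None,
) -> dict[float, GrowthCurve]:
    """Generate one growth curve per dose of a dilution ladder.

    The growth rate at dose d is r * (1 - d^h / (d^h + IC50^h)), so the
    dose at which the rate halves — the ground-truth IC50 of the
    relative-rate curve — equals ``hill_ic50`` by construction.
    """
    doses = [float(d) for d in doses]
    if any(d < 0 for d in doses):
        raise ValueError("doses must be >= 0")
    if 0.0 not in doses:
        raise ValueError("dose 0 (untreated reference) must be present")
    if not hill_ic50 > 0:
        raise ValueError("hill_ic50 must be > 0")
    base_seed = growth.seed if seed is None else seed
    curves: dict[float, GrowthCurve] = {}
    for d in sorted(doses):
        inhibition = 0.0 if d == 0 else d**hill_slope / (d**hill_slope + hill_ic50**hill_slope)
        p = GrowthParams(
            n0=growth.n0,
            rate=growth.rate * (1.0 - inhibition),
            times=np.asarray(growth.times, dtype=float).copy(),
            noise_cv=growth.noise_cv,
            seed=int(substream(base_seed, "dose", f"{d:.6g}").integers(2**31)),
        )
        curves[d] = gen_growth_counts(p, condition={"dose_uM": d})
    return curves


# ---------------------------------------------------------------------------
# well scene
# ---------------------------------------------------------------------------


@dataclass
class DiscSceneParams:
    """Parameters of the synthetic well-scan generator.

    The physical disc is 6 mm in diameter; at the default 20 um/px that is
    a 150 px radius in a 512 px well image. ``texture_sd_on`` must be >=
    ``texture_sd_off`` — higher local intensity variance on the scaffold
    than on bare plastic is the premise of the texture segmentation;
    equality produces a degenerate scene flagged ``no_texture_contrast``.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 20.0
    disc_center: tuple[float, float] = (256.0, 256.0)
    disc_radius: float = 150.0
    background: float = 2000.0
    disc_offset: float = 250.0
    texture_sd_on: float = 120.0
    texture_sd_off: float = 15.0
    illum_amplitude: float = 300.0
    camera_sd: float = 10.0
    n_cells_on: int = 150
    n_cells_off: int = 60
    spot_amplitude: float = 3000.0
    spot_sigma: float = 2.0
    boundary_margin: float = 3.0
    allow_clipped: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        r0, c0 = self.disc_center
        nr, nc = self.image_shape
        inside = (
            r0 - self.disc_radius >= 0
            and c0 - self.disc_radius >= 0
            and r0 + self.disc_radius < nr
            and c0 + self.disc_radius < nc
        )
        if not inside and not self.allow_clipped:
            raise ValueError("disc extends outside the image; set allow_clipped=True to permit")
        if self.texture_sd_on < self.texture_sd_off:
            raise ValueError("texture_sd_on must be >= texture_sd_off")
        if self.disc_radius <= 0 or self.spot_sigma <= 0:
            raise ValueError("disc_radius and spot_sigma must be > 0")


@dataclass
class WellScene:
    """A generated scene: image, illumination reference and ground truth."""

    image: FieldImage
    profile: LightProfile
    mask: np.ndarray  # exact rasterized disc, bool
    cells: pd.DataFrame  # columns well,time_h,x_px,y_px,viability,on_disc
    meta: dict = field(default_factory=dict)


def _radial_profile(shape: tuple[int, int], background: float, amplitude: float) -> np.ndarray:
    """Radially symmetric quadratic vignette, brightest at the image centre."""
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    rho2 = (rr - r0) ** 2 + (cc - c0) ** 2
    rho2_max = r0**2 + c0**2
    return background + amplitude * (1.0 - rho2 / rho2_max)


def _stamp_spots(image: np.ndarray, ys: np.ndarray, xs: np.ndarray, amp: float, sigma: float) -> None:
    half = int(math.ceil(4 * sigma))
    ax = np.arange(-half, half + 1, dtype=float)
    kernel = amp * np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma**2))
    nr, nc = image.shape
    for y, x in zip(ys, xs):
        r, c = int(round(y)), int(round(x))
        r0, r1 = max(r - half, 0), min(r + half + 1, nr)
        c0, c1 = max(c - half, 0), min(c + half + 1, nc)
        image[r0:r1, c0:c1] += kernel[
            r0 - (r - half) : kernel.shape[0] - ((r + half + 1) - r1),
            c0 - (c - half) : kernel.shape[1] - ((c + half + 1) - c1),
        ]


def _sample_in_disc(rng: np.random.Generator, n: int, center, radius: float):
    theta = rng.uniform(0, 2 * math.pi, n)
    rho = radius * np.sqrt(rng.uniform(0, 1, n))
    return center[0] + rho * np.sin(theta), center[1] + rho * np.cos(theta)


def _sample_off_disc(rng: np.random.Generator, n: int, shape, center, radius: float):
    ys = np.empty(n)
    xs = np.empty(n)
    got = 0
    # rejection sampling; off-disc area dominates, so this terminates fast
    while got < n:
        m = max(2 * (n - got), 16)
        y = rng.uniform(1.0, shape[0] - 2.0, m)
        x = rng.uniform(1.0, shape[1] - 2.0, m)
        keep = (y - center[0]) ** 2 + (x - center[1]) ** 2 > radius**2
        k = min(int(keep.sum()), n - got)
        ys[got : got + k] = y[keep][:k]
        xs[got : got + k] = x[keep][:k]
        got += k
    return ys, xs


def gen_well_scene(params: DiscSceneParams, *, time_h: float = 0.0, well: str = "A1") -> WellScene:
    """Generate a synthetic well scan with a textured liver-ECM disc.

    The image is built as smooth illumination + uniform disc offset +
    per-region Gaussian texture + Gaussian nuclear spots + camera noise.
    The returned mask is the exact rasterized disc, and every centroid in
    ``cells`` carries its true on/off label; on-disc centroids are placed
    at least ``boundary_margin`` px inside the true boundary and off-disc
    centroids at least that far outside it.
    """
    p = params
    nr, nc = p.image_shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(float)
    dist2 = (rr - p.disc_center[0]) ** 2 + (cc - p.disc_center[1]) ** 2
    mask = dist2 <= p.disc_radius**2

    disc_area = math.pi * (max(p.disc_radius - p.boundary_margin, 1.0)) ** 2
    off_area = nr * nc - math.pi * p.disc_radius**2
    cap_on = int(disc_area / (9.0 * p.spot_sigma**2))
    cap_off = int(off_area / (9.0 * p.spot_sigma**2))
    if p.n_cells_on > cap_on or p.n_cells_off > cap_off:
        raise ValueError(
            f"spot counts exceed area capacity (on<= {cap_on}, off<= {cap_off})"
        )

    profile = _radial_profile((nr, nc), p.background, p.illum_amplitude)
    rng_tex = substream(p.seed, "scene-texture")
    image = profile.copy()
    image[mask] += p.disc_offset
    texture = np.where(
        mask,
        rng_tex.normal(0.0, p.texture_sd_on, (nr, nc)),
        rng_tex.normal(0.0, p.texture_sd_off, (nr, nc)),
    )
    image += texture

    rng_cells = substream(p.seed, "scene-cells")
    y_on, x_on = _sample_in_disc(
        rng_cells, p.n_cells_on, p.disc_center, max(p.disc_radius - p.boundary_margin, 1.0)
    )
    y_off, x_off = _sample_off_disc(
        rng_cells, p.n_cells_off, (nr, nc), p.disc_center, p.disc_radius + p.boundary_margin
    )
    _stamp_spots(image, np.r_[y_on, y_off], np.r_[x_on, x_off], p.spot_amplitude, p.spot_sigma)

    rng_cam = substream(p.seed, "scene-camera")
    image += rng_cam.normal(0.0, p.camera_sd, (nr, nc))

    viability = np.array(["live"] * (p.n_cells_on + p.n_cells_off))
    cells = pd.DataFrame(
        {
            "well": well,
            "time_h": float(time_h),
            "x_px": np.r_[x_on, x_off],
            "y_px": np.r_[y_on, y_off],
            "viability": viability,
            "on_disc": np.r_[np.ones(p.n_cells_on, bool), np.zeros(p.n_cells_off, bool)],
        }
    )

    meta = {
        "seed": p.seed,
        "disc_center": list(p.disc_center),
        "disc_radius": p.disc_radius,
        "pixel_size_um": p.pixel_size_um,
        "no_texture_contrast": bool(p.texture_sd_on == p.texture_sd_off),
    }
    return WellScene(
        image=FieldImage(image, p.pixel_size_um),
        profile=LightProfile(profile, p.pixel_size_um),
        mask=mask,
        cells=cells,
        meta=meta,
    )


def write_scene(scene: WellScene, outdir: str | Path, stem: str = "scene") -> dict[str, Path]:
    """Write a scene to disk: 16-bit TIFFs, detections CSV, truth JSON sidecar."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": outdir / f"{stem}_image.tif",
        "profile": outdir / f"{stem}_profile.tif",
        "cells": outdir / f"{stem}_cells.csv",
        "truth": outdir / f"{stem}_truth.json",
    }
    for key, img in (("image", scene.image), ("profile", scene.profile)):
        tifffile.imwrite(
            paths[key], np.clip(np.round(img.data), 0, 65535).astype(np.uint16)
        )
    scene.cells.to_csv(paths["cells"], index=False)
    truth = dict(scene.meta)
    truth["mask_area_px"] = int(scene.mask.sum())
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths


# ---------------------------------------------------------------------------
# effects table
# ---------------------------------------------------------------------------


@dataclass
class EffectsTableSpec:
    """Ground-truth structure for multi-experiment growth-rate tables.

    Rows follow y = mu + beta_cell + beta_plate + u_e + eps, with the
    experiment-date effect u_e ~ N(0, exp_sd^2) shared by all rows of an
    experiment and eps ~ N(0, residual_sd_by_plate^2) grouped by plate
    type. Default magnitudes mirror the study scale: rates of a few
    percent per hour, a 0.006/h stiffness contrast, experiment-to-
    experiment spread and residual noise of a few thousandths per hour.
    """

    cell_levels: tuple[str, ...] = ("HCT116", "HT29")
    plate_levels: tuple[str, ...] = ("Plastic", "Softwell 0.2 kPa", "Softwell 2 kPa")
    grand_mean: float = 0.025
    cell_effects: Mapping[str, float] = field(
        default_factory=lambda: {"HCT116": 0.0, "HT29": -0.008}
    )
    plate_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "Plastic": 0.0,
            "Softwell 0.2 kPa": -0.010,
            "Softwell 2 kPa": -0.004,
        }
    )
    exp_sd: float = 0.002
    residual_sd_by_plate: Mapping[str, float] = field(
        default_factory=lambda: {
            "Plastic": 0.002,
            "Softwell 0.2 kPa": 0.004,
            "Softwell 2 kPa": 0.003,
        }
    )
    n_experiments: int = 4
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for lev in self.cell_levels:
            if lev not in self.cell_effects:
                raise ValueError(f"cell level {lev!r} has no effect entry")
        for lev in self.plate_levels:
            if lev not in self.plate_effects:
                raise ValueError(f"plate level {lev!r} has no effect entry")
            if lev not in self.residual_sd_by_plate:
                raise ValueError(f"plate level {lev!r} has no residual SD entry")
        if self.exp_sd < 0 or any(s < 0 for s in self.residual_sd_by_plate.values()):
            raise ValueError("all SDs must be >= 0")
        if self.n_experiments < 1 or self.n_replicates < 1:
            raise ValueError("n_experiments and n_replicates must be >= 1")


def gen_effects_table(spec: EffectsTableSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a growth-rate table with known fixed and random effects.

    Returns the table (columns rate, cell, plate, experiment) and a truth
    dict holding the grand mean, the per-level effects and the realized
    experiment-date effects u_e.
    """
    rng = substream(spec.seed, "effects-table")
    u = rng.normal(0.0, spec.exp_sd, spec.n_experiments)
    rows = []
    for e in range(spec.n_experiments):
        for cell in spec.cell_levels:
            for plate in spec.plate_levels:
                mean = (
                    spec.grand_mean
                    + spec.cell_effects[cell]
                    + spec.plate_effects[plate]
                    + u[e]
                )
                eps = rng.normal(0.0, spec.residual_sd_by_plate[plate], spec.n_replicates)
                for r in range(spec.n_replicates):
                    rows.append(
                        {
                            "rate": mean + eps[r],
                            "cell": cell,
                            "plate": plate,
                            "experiment": f"exp{e:02d}",
                        }
                    )
    truth = {
        "grand_mean": spec.grand_mean,
        "cell_effects": dict(spec.cell_effects),
        "plate_effects": dict(spec.plate_effects),
        "u_experiment": {f"exp{e:02d}": float(u[e]) for e in range(spec.n_experiments)},
        "exp_sd": spec.exp_sd,
        "residual_sd_by_plate": dict(spec.residual_sd_by_plate),
    }
    return pd.DataFrame(rows), truth
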