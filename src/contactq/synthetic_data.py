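"""Synthetic EM-like segmentation scenes with exact ground truth.

The generator emulates manually traced transmission-EM cross-sections of the
kind the contact metrics were designed for: one closed mitochondrial outer
membrane (MOM) contour per mitochondrion — a perturbed circle
``r(φ) = r₀ + Σ_{k=2..4} a_k cos(kφ + ψ_k)`` — with open ER membrane arcs
running locally parallel to the MOM at prescribed distances, mostly inside
the 0–30 nm contact range.  Because each ER arc is constructed as a normal
offset of the MOM at a known distance ``d`` and known perimeter coverage,
the ground-truth contact length L, band-edge average distance D, perimeter
P and ERMICC are exact by construction (computed before tracing jitter is
applied).

Tracing error is modeled as a smooth, correlated displacement of the
polyline vertices (hand tremor), not white per-vertex noise: white noise on
a densely sampled polyline would inflate its arc length by several percent,
which manual tracing does not do.

All randomness flows from one integer seed through per-mitochondrion
``numpy.random.SeedSequence`` substreams, so adding mitochondria to a spec
does not perturb the ones already generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contact_geometry import BandConfig
from .traces import MembraneTrace, SegmentedScene, ROLE_ER, ROLE_MOM


class SpecError(ValueError):
    """A scene specification is outside its supported parameter ranges."""


@dataclass(frozen=True)
class Dist:
    """A tiny distribution spec: ``constant``, ``uniform`` or ``uniform_int``.

    Parsed from a scalar (constant), a ``("uniform", lo, hi)`` /
    ``("uniform_int", lo, hi)`` tuple, or another ``Dist``.
    """

    kind: str
    args: tuple

    @staticmethod
    def parse(value) -> "Dist":
        if isinstance(value, Dist):
            return value
        if isinstance(value, (int, float)):
            return Dist("constant", (float(value),))
        if isinstance(value, (tuple, list)) and len(value) == 3:
            kind, lo, hi = value
            if kind in {"uniform", "uniform_int"}:
                if not lo <= hi:
                    raise SpecError(f"bad distribution bounds {value!r}")
                return Dist(kind, (float(lo), float(hi)))
        raise SpecError(f"cannot parse distribution spec {value!r}")

    def sample(self, rng: np.random.Generator):
        if self.kind == "constant":
            return self.args[0]
        lo, hi = self.args
        if self.kind == "uniform":
            return float(rng.uniform(lo, hi))
        return int(rng.integers(int(lo), int(hi) + 1))

    @property
    def upper(self) -> float:
        return self.args[-1]

    @property
    def lower(self) -> float:
        return self.args[0]


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of one synthetic scene.

    Defaults describe an ER-rich cultured-cell EM field: a handful of
    mitochondria of 300–800 nm radius with mild shape irregularity, each with
    2–3 nearby ER profiles at cleft distances in the canonical 10–25 nm
    contact range, each profile apposed to 10–30% of the perimeter, a small
    fraction of profiles lying beyond the 30 nm cutoff, traced at 1 nm pixel
    size with sub-pixel hand jitter.
    """

    seed: int = 0
    n_mitochondria: int = 6
    shape_noise_amp_nm: float = 20.0
    trace_jitter_nm: float = 0.5
    raster_pixel_nm: float = 1.0
    out_of_range_fraction: float = 0.05
    mito_radius_nm_spec: object = ("uniform", 300.0, 800.0)
    er_arcs_per_mito_spec: object = ("uniform_int", 2, 3)
    arc_distance_nm_spec: object = ("uniform", 10.0, 25.0)
    far_distance_nm_spec: object = ("uniform", 35.0, 80.0)
    arc_coverage_frac_spec: object = ("uniform", 0.10, 0.30)

    def __post_init__(self) -> None:
        if self.n_mitochondria < 0:
            raise SpecError("n_mitochondria must be >= 0")
        if self.raster_pixel_nm <= 0:
            raise SpecError("raster_pixel_nm must be > 0")
        if not 0 <= self.out_of_range_fraction <= 1:
            raise SpecError("out_of_range_fraction must be in [0, 1]")
        if self.shape_noise_amp_nm < 0 or self.trace_jitter_nm < 0:
            raise SpecError("noise amplitudes must be >= 0")
        d = self.dists
        if d["arc_distance_nm"].lower <= 0 or d["arc_distance_nm"].upper > 30:
            raise SpecError("arc_distance_nm support must lie in (0, 30]")
        if not (0 < d["arc_coverage_frac"].lower
                and d["arc_coverage_frac"].upper < 1):
            raise SpecError("arc_coverage_frac support must lie in (0, 1)")
        if d["mito_radius_nm"].lower <= 0:
            raise SpecError("mito_radius_nm must be positive")

    @property
    def dists(self) -> dict[str, Dist]:
        return {
            "mito_radius_nm": Dist.parse(self.mito_radius_nm_spec),
            "er_arcs_per_mito": Dist.parse(self.er_arcs_per_mito_spec),
            "arc_distance_nm": Dist.parse(self.arc_distance_nm_spec),
            "far_distance_nm": Dist.parse(self.far_distance_nm_spec),
            "arc_coverage_frac": Dist.parse(self.arc_coverage_frac_spec),
        }


def _smooth_noise(rng: np.random.Generator, n: int, amp_rms: float,
                  window: int = 15) -> np.ndarray:
    """Correlated 2D vertex displacement with the requested RMS amplitude."""
    if amp_rms == 0 or n < 2:
        return np.zeros((n, 2))
    raw = rng.standard_normal((n + 2 * window, 2))
    kernel = np.ones(window) / window
    sm = np.column_stack([np.convolve(raw[:, i], kernel, mode="same")
                          for i in (0, 1)])[window:window + n]
    rms = np.sqrt(np.mean(sm ** 2))
    return sm * (amp_rms / rms) if rms > 0 else sm


def _mom_polyline(rng: np.random.Generator, r0: float, amp: float,
                  center: np.ndarray, arc_step_nm: float = 2.0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Perturbed-circle MOM sampled at ~arc_step_nm; returns (xy, phi, radius(phi))."""
    n = max(96, int(math.ceil(2 * math.pi * r0 / arc_step_nm)))
    phi = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    r = np.full(n, r0)
    if amp > 0:
        for k in (2, 3, 4):
            a_k = rng.uniform(0, amp / 3.0)
            psi = rng.uniform(0, 2 * math.pi)
            r = r + a_k * np.cos(k * phi + psi)
    xy = center + np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    return xy, phi, r


def _polyline_length(xy: np.ndarray, closed: bool) -> float:
    v = np.vstack([xy, xy[:1]]) if closed else xy
    return float(np.hypot(*np.diff(v, axis=0).T).sum())


def _offset_arc(mom_xy: np.ndarray, start_idx: int, n_pts: int, d: float
                ) -> np.ndarray:
    """ER arc as the outward normal offset of a stretch of the (closed) MOM."""
    n = len(mom_xy)
    idx = (start_idx + np.arange(n_pts)) % n
    pts = mom_xy[idx]
    tang = mom_xy[(idx + 1) % n] - mom_xy[(idx - 1) % n]
    tang /= np.hypot(tang[:, 0], tang[:, 1])[:, None]
    # MOM is counter-clockwise in (x, y): outward normal = tangent rotated -90°
    normal = np.column_stack([tang[:, 1], -tang[:, 0]])
    # orientation check against the centroid: outward means away from it
    c = mom_xy.mean(axis=0)
    if np.mean(np.sum((pts - c) * normal, axis=1)) < 0:
        normal = -normal
    return pts + d * normal


def generate_scene(spec: SceneSpec, *, scene_id: str = "synthetic",
                   cell_id: str = "", group: str = "",
                   band_config: BandConfig | None = None
                   ) -> tuple[SegmentedScene, pd.DataFrame]:
    """Generate one scene plus its exact per-mitochondrion ground truth.

    Ground truth (computed from the pre-jitter geometry): perimeter P, total
    in-range ER length L, band-edge weighted average distance D for the given
    band configuration (default 30 × 1 nm), and ERMICC = L/(P·D).
    """
    config = band_config or BandConfig()
    dists = spec.dists
    # lay mitochondria on a grid with clearance for radius + shape noise + far ER
    clearance = (dists["mito_radius_nm"].upper + spec.shape_noise_amp_nm
                 + dists["far_distance_nm"].upper + 60.0)
    pitch = 2.0 * clearance
    n_cols = max(1, int(math.ceil(math.sqrt(max(spec.n_mitochondria, 1)))))
    substreams = np.random.SeedSequence(spec.seed).spawn(spec.n_mitochondria)
    traces: list[MembraneTrace] = []
    truth_rows = []
    for m, ss in enumerate(substreams):
        rng = np.random.Generator(np.random.PCG64(ss))
        center = np.array([
            clearance + (m % n_cols) * pitch,
            clearance + (m // n_cols) * pitch,
        ])
        r0 = dists["mito_radius_nm"].sample(rng)
        mom_xy, _, _ = _mom_polyline(rng, r0, spec.shape_noise_amp_nm, center)
        P_true = _polyline_length(mom_xy, closed=True)
        mito_id = f"mito_{m}"
        n_arcs = int(dists["er_arcs_per_mito"].sample(rng))
        arc_lengths, arc_bands = [], []
        er_polylines = []
        n_mom = len(mom_xy)
        for a in range(n_arcs):
            far = rng.uniform() < spec.out_of_range_fraction
            d = (dists["far_distance_nm"].sample(rng) if far
                 else dists["arc_distance_nm"].sample(rng))
            coverage = dists["arc_coverage_frac"].sample(rng)
            n_pts = max(2, int(round(coverage * n_mom)))
            start = int(rng.integers(0, n_mom))
            er_xy = _offset_arc(mom_xy, start, n_pts, d)
            er_polylines.append((f"{mito_id}_er_{a}", er_xy))
            if not far:
                arc_lengths.append(_polyline_length(er_xy, closed=False))
                arc_bands.append(int(math.ceil(d / config.step_nm)))
        L_true = float(np.sum(arc_lengths)) if arc_lengths else 0.0
        if L_true > 0:
            D_true = (config.step_nm
                      * float(np.dot(arc_bands, arc_lengths)) / L_true)
            ermicc_true = L_true / (P_true * D_true)
        else:
            D_true, ermicc_true = math.nan, 0.0
        truth_rows.append({
            "mito_id": mito_id, "P_nm": P_true, "L_nm": L_true,
            "D_nm": D_true, "ermicc_per_nm": ermicc_true,
            "n_er_traces": len(er_polylines),
        })
        # apply tracing jitter after the truth is recorded
        mom_j = mom_xy + _smooth_noise(rng, n_mom, spec.trace_jitter_nm)
        traces.append(MembraneTrace(mito_id, ROLE_MOM, mom_j, closed=True))
        for er_id, er_xy in er_polylines:
            er_j = er_xy + _smooth_noise(rng, len(er_xy), spec.trace_jitter_nm)
            traces.append(MembraneTrace(er_id, ROLE_ER, er_j, closed=False))
    scene = SegmentedScene(scene_id=scene_id, pixel_size_nm=spec.raster_pixel_nm,
                           traces=traces, cell_id=cell_id, group=group)
    return scene, pd.DataFrame(truth_rows)


def rasterize_scene(scene: SegmentedScene, pixel_nm: float, *,
                    margin_nm: float = 50.0
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize a scene into paired integer label masks.

    MOM traces become filled instance labels; ER traces become 1-px-wide
    membrane rasters.  Returns ``(mom_mask, er_mask, origin_nm)`` where
    ``origin_nm`` is the scene coordinate of pixel (0, 0)'s center.
    """
    from skimage.draw import line as _draw_line
    from skimage.draw import polygon as _draw_polygon

    if pixel_nm <= 0:
        raise ValueError("pixel_nm must be > 0")
    allv = np.vstack([t.vertices for t in scene.traces])
    lo = allv.min(axis=0) - margin_nm
    hi = allv.max(axis=0) + margin_nm
    origin = lo
    shape = tuple(np.ceil((hi - lo)[::-1] / pixel_nm).astype(int) + 1)  # (rows, cols)
    mom_mask = np.zeros(shape, dtype=np.int32)
    er_mask = np.zeros(shape, dtype=np.int32)
    for label, t in enumerate([t for t in scene.traces if t.role == ROLE_MOM], 1):
        px = (t.vertices - origin) / pixel_nm
        rr, cc = _draw_polygon(px[:, 1], px[:, 0], shape)
        mom_mask[rr, cc] = label
    for label, t in enumerate([t for t in scene.traces if t.role == ROLE_ER], 1):
        px = np.round((t.vertices - origin) / pixel_nm).astype(int)
        v = np.vstack([px, px[:1]]) if t.closed else px
        for (x0, y0), (x1, y1) in zip(v[:-1], v[1:]):
            rr, cc = _draw_line(y0, x0, y1, x1)
            ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
            er_mask[rr[ok], cc[ok]] = label
    return mom_mask, er_mask, origin


def generate_line_profile(peak_positions: dict[str, float], *,
                          widths: dict[str, float] | float = 25.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          positions: np.ndarray | None = None):
    """Synthetic multi-channel cross-sectional profile: one Gaussian per channel.

    Peak amplitude 1 before noise; seeded additive Gaussian noise of standard
    deviation ``noise_sd`` (in normalized-intensity units).
    """
    from .profile_analysis import LineProfile

    if positions is None:
        lo = min(peak_positions.values()) - 60.0
        hi = max(peak_positions.values()) + 60.0
        positions = np.arange(lo, hi + 1.0, 1.0)
    positions = np.asarray(positions, float)
    rng = np.random.default_rng(seed)
    channels = {}
    for name, mu in peak_positions.items():
        w = widths[name] if isinstance(widths, dict) else float(widths)
        signal = np.exp(-0.5 * ((positions - mu) / w) ** 2)
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=len(positions))
        channels[name] = signal
    return LineProfile(positions, channels)


def save_scene(scene: SegmentedScene, truth: pd.DataFrame, outdir, *,
               pixel_nm: float | None = None) -> None:
    """Write a scene as polyline CSV + TIFF masks + ground_truth.csv."""
    import tifffile

    from .segmentation_io import write_polyline_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_polyline_table(scene, outdir / f"{scene.scene_id}_traces.csv")
    truth.to_csv(outdir / f"{scene.scene_id}_ground_truth.csv", index=False)
    mom, er, origin = rasterize_scene(scene, pixel_nm or scene.pixel_size_nm)
    tifffile.imwrite(outdir / f"{scene.scene_id}_mom.tif", mom)
    tifffile.imwrite(outdir / f"{scene.scene_id}_er.tif", er)


def measure_synthetic_cohort(spec: SceneSpec, n_mitochondria: int, *,
                             group: str = "", seed: int | None = None,
                             band_config: BandConfig | None = None) -> pd.DataFrame:
    """Generate scenes until ``n_mitochondria`` are collected and measure them.

    Convenience for cohort-level simulations: returns the per-mitochondrion
    metrics table (one row per mitochondrion, annotated with ``group``),
    measured through the full polyline pipeline.
    """
    from .contact_geometry import measure_scene

    if seed is not None:
        spec = replace(spec, seed=seed)
    tables = []
    collected = 0
    scene_idx = 0
    base = np.random.SeedSequence(spec.seed)
    while collected < n_mitochondria:
        n_left = n_mitochondria - collected
        n_here = min(spec.n_mitochondria, n_left) or n_left
        sub_seed = int(base.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        sub = replace(spec, seed=sub_seed, n_mitochondria=n_here)
        scene, _ = generate_scene(sub, scene_id=f"scene_{scene_idx}",
                                  cell_id=f"cell_{scene_idx}", group=group)
        metrics, _ = measure_scene(scene, band_config)
        tables.append(metrics)
        collected += len(metrics)
        scene_idx += 1
    return pd.concat(tables, ignore_index=True)
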