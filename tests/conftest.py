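"""Shared fixtures: hand-built geometric scenes with closed-form metrics."""

from __future__ import annotations

import numpy as np
import pytest

from contactq import MembraneTrace, SceneSpec


def circle_trace(r_nm: float, n: int = 2000, center=(0.0, 0.0),
                 object_id: str = "mom", role: str = "MOM") -> MembraneTrace:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    xy = np.column_stack([center[0] + r_nm * np.cos(th),
                          center[1] + r_nm * np.sin(th)])
    return MembraneTrace(object_id, role, xy, closed=True)


def square_trace(side_nm: float = 100.0, object_id: str = "sq") -> MembraneTrace:
    s = side_nm
    xy = np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])
    return MembraneTrace(object_id, "MOM", xy, closed=True)


@pytest.fixture
def concentric_arc_scene():
    """Circular MOM (r = 500 nm) with a concentric ER arc at radius 515 nm
    spanning a quarter turn, angularly aligned with the MOM vertices so the
    radial separation of 15 nm is realized as an exact normal offset.

    Closed forms: P = 2π·500, L = (π/2)·515 ≈ 808.98 nm, all length in band
    15, D = 15 nm, ERMICC = L/(P·D) ≈ 0.01717 nm⁻¹.
    """
    n = 3600
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    mom = MembraneTrace("mom", "MOM",
                        np.column_stack([500 * np.cos(th), 500 * np.sin(th)]),
                        closed=True)
    th_arc = th[: n // 4 + 1]
    er = MembraneTrace("er", "ER",
                       np.column_stack([515 * np.cos(th_arc), 515 * np.sin(th_arc)]),
                       closed=False)
    return mom, er


@pytest.fixture
def canonical_spec():
    """The closed-form generator scene: one unperturbed circular mitochondrion
    of radius 500 nm with a single concentric ER arc at d = 12 nm covering a
    quarter of the perimeter; ground-truth ERMICC = 0.25·2π·512/(2π·500·12)
    = 0.021333 nm⁻¹."""
    return SceneSpec(seed=1, n_mitochondria=1, shape_noise_amp_nm=0.0,
                     trace_jitter_nm=0.0, out_of_range_fraction=0.0,
                     mito_radius_nm_spec=500.0, er_arcs_per_mito_spec=1.0,
                     arc_distance_nm_spec=("uniform", 12.0, 12.0),
                     arc_coverage_frac_spec=("uniform", 0.25, 0.25))
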