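"""Membrane traces and segmented scenes.

All geometry downstream of I/O lives in nanometres, in image coordinates
(x to the right, y down, origin at the centre of pixel ``(0, 0)``).  A
:class:`MembraneTrace` is an ordered 2D polyline: closed for a mitochondrial
outer membrane (MOM) cross-section, open or closed for an ER membrane
profile.  A :class:`SegmentedScene` bundles the traces of one EM field of
view together with its pixel calibration and experimental-group metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from shapely.geometry import LinearRing

ROLE_MOM = "MOM"
ROLE_ER = "ER"
_VALID_ROLES = frozenset({ROLE_MOM, ROLE_ER})

#: Two consecutive vertices closer than this (nm) are considered duplicates.
MIN_VERTEX_SEPARATION_NM = 1e-9


class TraceValidationError(ValueError):
    """A membrane trace violates its geometric invariants."""


@dataclass(frozen=True)
class MembraneTrace:
    """An ordered 2D membrane polyline in nanometres.

    Parameters
    ----------
    object_id:
        Identifier of the traced organelle instance.
    role:
        ``"MOM"`` (mitochondrial outer membrane, must be closed) or ``"ER"``.
    vertices:
        ``(n, 2)`` array of ``(x_nm, y_nm)`` vertex coordinates.  For closed
        traces the closing edge from the last back to the first vertex is
        implicit; the first vertex is not repeated.
    closed:
        Whether the polyline is a closed curve.
    """

    object_id: str
    role: str
    vertices: np.ndarray
    closed: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise TraceValidationError(
                f"{self.object_id}: vertices must be an (n, 2) array, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)
        if self.role not in _VALID_ROLES:
            raise TraceValidationError(
                f"{self.object_id}: unknown role {self.role!r} (expected MOM or ER)"
            )
        min_n = 3 if self.closed else 2
        if len(v) < min_n:
            raise TraceValidationError(
                f"{self.object_id}: needs at least {min_n} vertices "
                f"({'closed' if self.closed else 'open'}), got {len(v)}"
            )
        if not np.all(np.isfinite(v)):
            raise TraceValidationError(f"{self.object_id}: non-finite coordinates")
        seg = np.diff(v, axis=0)
        if self.closed:
            seg = np.vstack([seg, v[0] - v[-1]])
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) <= MIN_VERTEX_SEPARATION_NM):
            raise TraceValidationError(
                f"{self.object_id}: consecutive vertices closer than "
                f"{MIN_VERTEX_SEPARATION_NM} nm"
            )
        if self.closed and not LinearRing(v).is_simple:
            raise TraceValidationError(
                f"{self.object_id}: closed trace is self-intersecting"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edge_array(self) -> np.ndarray:
        """Edges as an ``(m, 2, 2)`` array of segment endpoints, closing edge included."""
        v = self.vertices
        if self.closed:
            v = np.vstack([v, v[:1]])
        return np.stack([v[:-1], v[1:]], axis=1)

    def arc_length(self) -> float:
        """Total polyline length in nm (perimeter for a closed trace)."""
        e = self.edge_array()
        d = e[:, 1] - e[:, 0]
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def transformed(self, *, rotation_rad: float = 0.0,
                    translation_nm: Sequence[float] = (0.0, 0.0),
                    scale: float = 1.0) -> "MembraneTrace":
        """Return a rigidly moved (and optionally scaled) copy."""
        c, s = np.cos(rotation_rad), np.sin(rotation_rad)
        rot = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ rot.T) + np.asarray(translation_nm, float)
        return replace(self, vertices=v)


@dataclass
class SegmentedScene:
    """Traces of one segmented EM field of view.

    Invariant: at least one closed MOM trace; ``pixel_size_nm > 0``.
    """

    scene_id: str
    pixel_size_nm: float
    traces: list[MembraneTrace] = field(default_factory=list)
    cell_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if not self.pixel_size_nm > 0:
            raise TraceValidationError(
                f"scene {self.scene_id}: pixel_size_nm must be > 0, got {self.pixel_size_nm}"
            )
        for t in self.mom_traces:
            if not t.closed:
                raise TraceValidationError(
                    f"scene {self.scene_id}: MOM trace {t.object_id} is not closed"
                )

    @property
    def mom_traces(self) -> list[MembraneTrace]:
        return [t for t in self.traces if t.role == ROLE_MOM]

    @property
    def er_traces(self) -> list[MembraneTrace]:
        return [t for t in self.traces if t.role == ROLE_ER]


def resample_polyline(vertices: np.ndarray, closed: bool, step_nm: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Subdivide a polyline into sub-segments no longer than ``step_nm``.

    Each original edge is split into ``ceil(len/step)`` equal pieces, so the
    pieces lie exactly on the polyline and their lengths sum exactly to the
    polyline's arc length.

    Returns
    -------
    midpoints : (m, 2) array of sub-segment midpoints (nm)
    lengths : (m,) array of sub-segment lengths (nm)
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be > 0")
    v = np.asarray(vertices, float)
    if closed:
        v = np.vstack([v, v[:1]])
    a, b = v[:-1], v[1:]
    d = b - a
    edge_len = np.hypot(d[:, 0], d[:, 1])
    n_sub = np.maximum(1, np.ceil(edge_len / step_nm)).astype(int)
    mids = []
    lens = []
    for ai, di, li, ni in zip(a, d, edge_len, n_sub):
        # fractional midpoints (k + 0.5)/n along the edge
        frac = (np.arange(ni) + 0.5) / ni
        mids.append(ai + frac[:, None] * di)
        lens.append(np.full(ni, li / ni))
    return np.concatenate(mids), np.concatenate(lens)


def smooth_polyline(vertices: np.ndarray, closed: bool, window: int) -> np.ndarray:
    """Centered moving-average smoothing of polyline vertices.

    Used to remove the staircase digitization of pixel-derived traces, whose
    raw chain length overestimates the underlying smooth curve by several
    percent.  ``window`` must be odd; ``window == 1`` is the identity.  Open
    polylines are edge-padded and their endpoints pinned, so smoothing does
    not shorten the trace.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return np.asarray(vertices, float).copy()
    v = np.asarray(vertices, float)
    h = window // 2
    if closed:
        padded = np.vstack([v[-h:], v, v[:h]])
    else:
        padded = np.vstack([np.repeat(v[:1], h, axis=0), v,
                            np.repeat(v[-1:], h, axis=0)])
    kernel = np.ones(window) / window
    out = np.column_stack([
        np.convolve(padded[:, i], kernel, mode="valid") for i in (0, 1)
    ])
    if not closed:
        out[0], out[-1] = v[0], v[-1]
    return out


def dedupe_vertices(vertices: np.ndarray, closed: bool,
                    tol_nm: float = MIN_VERTEX_SEPARATION_NM) -> np.ndarray:
    """Drop consecutive vertices closer than ``tol_nm`` (incl. the wrap pair)."""
    v = np.asarray(vertices, float)
    keep = np.ones(len(v), bool)
    d = np.hypot(*np.diff(v, axis=0).T)
    keep[1:] = d > tol_nm
    v = v[keep]
    if closed and len(v) > 1 and np.hypot(*(v[0] - v[-1])) <= tol_nm:
        v = v[:-1]
    return v
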