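"""Box-synapse geometry.

The model world is three nested axis-aligned boxes: a presynaptic element
and a postsynaptic element, each La x La x element_height, facing each
other across a 20 nm synaptic cleft, all enclosed by a perisynaptic box
(glial/neuronal membranes) that stands off the elements by a gap solved so
that the extracellular space (ECS) is a target fraction of the total
enclosed volume.

Coordinates are right-handed, in nm.  The cleft axis is z: the
postsynaptic top face lies at z = 0, the presynaptic bottom face at
z = Hc = 20.  The release point is the center of the active zone (AZ),
(0, 0, Hc).  The PSD is the central Ls x Ls square of the postsynaptic
face; the AZ is its congruent, directly apposed partner on the
presynaptic face.

Surface tags
------------
``psd``                  receptor-bearing central square at z = 0
``az``                   reflective central square at z = Hc
``extrasynaptic_post``   transporter-bearing annulus of the post face
``extrasynaptic_pre``    transporter-bearing annulus of the pre face
``peri_*``               six transporter-bearing inner faces of the peri box
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .population import SynapseConfig

__all__ = [
    "HC_NM",
    "PERI_GAP_RANGE_NM",
    "ECS_TARGET_DEFAULT",
    "Face",
    "SynapseGeometry",
    "EcsBalanceWarning",
    "ecs_fraction_for_gap",
    "build_geometry",
    "point_in_ecs",
]

#: synaptic cleft height, nm.
HC_NM = 20.0

#: allowed distance between the perisynaptic box and the synaptic elements, nm.
PERI_GAP_RANGE_NM = (38.0, 65.0)

#: extracellular space as a fraction of the total enclosed volume.
ECS_TARGET_DEFAULT = 0.20


class EcsBalanceWarning(UserWarning):
    """The ECS volume balance could not be met inside the peri-gap bounds."""


@dataclass(frozen=True)
class Face:
    """An axis-aligned rectangular surface patch.

    ``axis`` is the fixed coordinate axis (0=x, 1=y, 2=z), ``coord`` its
    value, and ``normal_sign`` the direction of the outward-into-ECS
    normal.  ``u_axis``/``v_axis`` span the face; ``exclude`` optionally
    cuts a centered rectangle out of the patch (used for the annuli).
    """

    tag: str
    axis: int
    coord: float
    normal_sign: float
    u_axis: int
    v_axis: int
    u_range: tuple[float, float]
    v_range: tuple[float, float]
    exclude: tuple[float, float] | None = None  # half-widths (u, v) of cutout

    @property
    def area(self) -> float:
        a = (self.u_range[1] - self.u_range[0]) * (self.v_range[1] - self.v_range[0])
        if self.exclude is not None:
            a -= 4.0 * self.exclude[0] * self.exclude[1]
        return a


def _box_volume(lo: np.ndarray, hi: np.ndarray) -> float:
    d = np.maximum(hi - lo, 0.0)
    return float(d[0] * d[1] * d[2])


def _box_intersection_volume(
    alo: np.ndarray, ahi: np.ndarray, blo: np.ndarray, bhi: np.ndarray
) -> float:
    return _box_volume(np.maximum(alo, blo), np.minimum(ahi, bhi))


@dataclass
class SynapseGeometry:
    """Fully resolved box-synapse world (all lengths in nm)."""

    Ls: float
    La: float
    Hc: float
    element_height: float
    peri_gap: float
    ecs_target: float
    ecs_fraction: float
    clipped: bool = False
    faces: list[Face] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.faces:
            self.faces = self._build_faces()

    # --- extents -----------------------------------------------------------
    @property
    def half_La(self) -> float:
        return self.La / 2.0

    @property
    def half_Ls(self) -> float:
        return self.Ls / 2.0

    @property
    def peri_lo(self) -> np.ndarray:
        g, h = self.peri_gap, self.element_height
        return np.array([-self.half_La - g, -self.half_La - g, -h - g])

    @property
    def peri_hi(self) -> np.ndarray:
        g, h = self.peri_gap, self.element_height
        return np.array([self.half_La + g, self.half_La + g, self.Hc + h + g])

    @property
    def post_lo(self) -> np.ndarray:
        return np.array([-self.half_La, -self.half_La, -self.element_height])

    @property
    def post_hi(self) -> np.ndarray:
        return np.array([self.half_La, self.half_La, 0.0])

    @property
    def pre_lo(self) -> np.ndarray:
        return np.array([-self.half_La, -self.half_La, self.Hc])

    @property
    def pre_hi(self) -> np.ndarray:
        return np.array([self.half_La, self.half_La, self.Hc + self.element_height])

    @property
    def release_point(self) -> np.ndarray:
        """Center of the AZ, on the presynaptic membrane."""
        return np.array([0.0, 0.0, self.Hc])

    @property
    def psd_rect(self) -> tuple[float, float]:
        """Half-widths (x, y) of the PSD square at z = 0."""
        return (self.half_Ls, self.half_Ls)

    @property
    def az_rect(self) -> tuple[float, float]:
        return (self.half_Ls, self.half_Ls)

    @property
    def As(self) -> float:
        return self.Ls * self.Ls

    # --- volumes -----------------------------------------------------------
    @property
    def volume_total(self) -> float:
        return _box_volume(self.peri_lo, self.peri_hi)

    @property
    def volume_solid(self) -> float:
        return _box_volume(self.post_lo, self.post_hi) + _box_volume(
            self.pre_lo, self.pre_hi
        )

    @property
    def volume_ecs(self) -> float:
        return self.volume_total - self.volume_solid

    def ecs_volume_in_box(self, lo, hi) -> float:
        """Analytic ECS volume inside an arbitrary axis-aligned box."""
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        v = _box_intersection_volume(lo, hi, self.peri_lo, self.peri_hi)
        v -= _box_intersection_volume(lo, hi, self.post_lo, self.post_hi)
        v -= _box_intersection_volume(lo, hi, self.pre_lo, self.pre_hi)
        return v

    # --- predicates --------------------------------------------------------
    def point_in_ecs(self, p) -> bool:
        """True iff p lies strictly inside the ECS (membranes are solid)."""
        p = np.asarray(p, dtype=float)
        if np.any(p <= self.peri_lo) or np.any(p >= self.peri_hi):
            return False
        for lo, hi in ((self.post_lo, self.post_hi), (self.pre_lo, self.pre_hi)):
            if np.all(p >= lo) and np.all(p <= hi):
                return False
        return True

    def points_in_ecs(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`point_in_ecs` over an (n, 3) array."""
        pts = np.asarray(pts, dtype=float)
        inside_peri = np.all(pts > self.peri_lo, axis=1) & np.all(
            pts < self.peri_hi, axis=1
        )
        in_post = np.all(pts >= self.post_lo, axis=1) & np.all(
            pts <= self.post_hi, axis=1
        )
        in_pre = np.all(pts >= self.pre_lo, axis=1) & np.all(pts <= self.pre_hi, axis=1)
        return inside_peri & ~in_post & ~in_pre

    # --- faces -------------------------------------------------------------
    def _build_faces(self) -> list[Face]:
        hl, hs = self.half_La, self.half_Ls
        plo, phi = self.peri_lo, self.peri_hi
        faces = [
            Face("psd", 2, 0.0, +1.0, 0, 1, (-hs, hs), (-hs, hs)),
            Face("az", 2, self.Hc, -1.0, 0, 1, (-hs, hs), (-hs, hs)),
            Face(
                "extrasynaptic_post", 2, 0.0, +1.0, 0, 1, (-hl, hl), (-hl, hl),
                exclude=(hs, hs),
            ),
            Face(
                "extrasynaptic_pre", 2, self.Hc, -1.0, 0, 1, (-hl, hl), (-hl, hl),
                exclude=(hs, hs),
            ),
        ]
        # six inner faces of the perisynaptic box
        for axis, tag_lo, tag_hi in ((0, "peri_xlo", "peri_xhi"),
                                     (1, "peri_ylo", "peri_yhi"),
                                     (2, "peri_zlo", "peri_zhi")):
            u_axis, v_axis = [a for a in (0, 1, 2) if a != axis]
            ur = (plo[u_axis], phi[u_axis])
            vr = (plo[v_axis], phi[v_axis])
            faces.append(Face(tag_lo, axis, float(plo[axis]), +1.0, u_axis, v_axis, ur, vr))
            faces.append(Face(tag_hi, axis, float(phi[axis]), -1.0, u_axis, v_axis, ur, vr))
        return faces

    @property
    def transporter_faces(self) -> list[Face]:
        return [f for f in self.faces if f.tag.startswith(("extrasynaptic", "peri"))]

    @property
    def transporter_area(self) -> float:
        """Total transporter-bearing membrane area, nm^2."""
        return sum(f.area for f in self.transporter_faces)

    # --- serialization -----------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "units": "nm",
            "Ls": self.Ls,
            "La": self.La,
            "Hc": self.Hc,
            "element_height": self.element_height,
            "peri_gap": self.peri_gap,
            "ecs_target": self.ecs_target,
            "ecs_fraction": self.ecs_fraction,
            "clipped": self.clipped,
            "volume_total": self.volume_total,
            "volume_ecs": self.volume_ecs,
            "release_point": self.release_point.tolist(),
            "faces": [
                {
                    "tag": f.tag,
                    "axis": f.axis,
                    "coord": f.coord,
                    "normal_sign": f.normal_sign,
                    "u_range": list(f.u_range),
                    "v_range": list(f.v_range),
                    "exclude": list(f.exclude) if f.exclude else None,
                    "area": f.area,
                }
                for f in self.faces
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def ecs_fraction_for_gap(La: float, element_height: float, gap: float, Hc: float = HC_NM) -> float:
    """ECS fraction of the total volume for a given peri gap."""
    total = (La + 2 * gap) ** 2 * (2 * element_height + Hc + 2 * gap)
    solid = 2 * La * La * element_height
    return 1.0 - solid / total


def build_geometry(
    cfg: SynapseConfig,
    ecs_target: float = ECS_TARGET_DEFAULT,
    element_height: float | None = None,
) -> SynapseGeometry:
    """Build the world for one configuration, solving the ECS balance.

    The peri gap is solved so that ECS volume / total volume equals
    ``ecs_target``; when no solution exists inside the allowed gap range
    the nearest bound is used, a :class:`EcsBalanceWarning` is emitted and
    the achieved fraction is recorded.
    """
    if not (0.0 < ecs_target < 1.0):
        raise ValueError("ecs_target must lie in (0, 1)")
    h = float(cfg.La) if element_height is None else float(element_height)
    if h <= 0:
        raise ValueError("element_height must be positive")
    lo, hi = PERI_GAP_RANGE_NM

    def f(g: float) -> float:
        return ecs_fraction_for_gap(cfg.La, h, g, HC_NM) - ecs_target

    clipped = False
    # the fraction is strictly increasing in the gap
    if f(lo) > 0:
        gap, clipped = lo, True
    elif f(hi) < 0:
        gap, clipped = hi, True
    else:
        gap = float(brentq(f, lo, hi, xtol=1e-9))
    achieved = ecs_fraction_for_gap(cfg.La, h, gap, HC_NM)
    if clipped:
        warnings.warn(
            f"ECS balance unsolvable within peri-gap bounds {PERI_GAP_RANGE_NM} nm "
            f"for La={cfg.La:.0f}, h={h:.0f}: gap clipped to {gap:.0f} nm, "
            f"achieved ECS fraction {achieved:.3f} (target {ecs_target})",
            EcsBalanceWarning,
            stacklevel=2,
        )
    return SynapseGeometry(
        Ls=float(cfg.Ls),
        La=float(cfg.La),
        Hc=HC_NM,
        element_height=h,
        peri_gap=gap,
        ecs_target=ecs_target,
        ecs_fraction=achieved,
        clipped=clipped,
    )


def point_in_ecs(geom: SynapseGeometry, p) -> bool:
    """Functional alias of :meth:`SynapseGeometry.point_in_ecs`."""
    return geom.point_in_ecs(p)
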