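"""VH/VL packing-angle geometry.

The packing angle is the signed torsion between two best-fit lines: one
through the C-alpha atoms of eight structurally conserved light-chain
positions (L35-L38, L85-L88), the other through the equivalent heavy-chain
positions (H36-H39, H89-H92).  The torsion is taken about the axis joining
the projections of the two residue-set centroids onto their fitted lines
(for a total-least-squares line that projection is the centroid itself).

Conventions fixed here and used consistently by the synthetic-structure
generator:

* line fitting is the principal axis of the centred coordinates (SVD);
* each fitted direction points from the centroid of the first four
  residues (L35-L38 / H36-H39) towards the centroid of the last four
  (L85-L88 / H89-H92), a deterministic numbering-based orientation rule;
* the torsion is the standard right-handed (IUPAC) dihedral computed on
  the four points (light_pivot + light_vector, light_pivot, heavy_pivot,
  heavy_pivot + heavy_vector), in degrees in (-180, 180].

Under these conventions natural antibody structures score near -46 deg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structure_io import FvStructure, ResidueKey, read_fv

logger = logging.getLogger(__name__)

#: Conserved framework positions defining the light-chain vector, in order.
CONSERVED_LIGHT = tuple(
    ResidueKey("L", n) for n in (35, 36, 37, 38, 85, 86, 87, 88)
)
#: Conserved framework positions defining the heavy-chain vector, in order.
CONSERVED_HEAVY = tuple(
    ResidueKey("H", n) for n in (36, 37, 38, 39, 89, 90, 91, 92)
)


class MissingResiduesError(ValueError):
    """Raised when conserved positions (or their C-alpha) are absent."""

    def __init__(self, missing: Sequence[ResidueKey]):
        self.missing = list(missing)
        super().__init__(
            "missing C-alpha for conserved positions: "
            + ", ".join(str(k) for k in self.missing)
        )


class DegenerateGeometryError(ValueError):
    """Raised when a line cannot be fitted (all points coincident)."""


@dataclass
class PackingAngle:
    """Signed VH/VL packing torsion plus the geometry that produced it."""

    degrees: float
    light_vector: np.ndarray
    heavy_vector: np.ndarray
    light_pivot: np.ndarray
    heavy_pivot: np.ndarray


def conserved_ca_sets(fv: FvStructure) -> tuple[np.ndarray, np.ndarray]:
    """Collect the 8+8 conserved C-alpha coordinates, in canonical order.

    Raises :class:`MissingResiduesError` naming *every* absent position,
    so callers can report (and exclude) incomplete structures in one pass.
    """
    missing: list[ResidueKey] = []
    coords: dict[ResidueKey, np.ndarray] = {}
    for key in CONSERVED_LIGHT + CONSERVED_HEAVY:
        res = fv.get(key)
        if res is None or res.ca is None:
            missing.append(key)
        else:
            coords[key] = res.ca
    if missing:
        raise MissingResiduesError(missing)
    light = np.array([coords[k] for k in CONSERVED_LIGHT])
    heavy = np.array([coords[k] for k in CONSERVED_HEAVY])
    return light, heavy


def best_fit_vector(
    points: Iterable[Sequence[float]],
    orient: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares line through a point cloud.

    Returns ``(direction, centroid)`` where ``direction`` is the unit
    principal axis of the centred points (dominant right singular vector)
    and ``centroid`` the arithmetic mean.  The principal axis minimises
    the sum of squared perpendicular distances over all lines.

    ``orient``, when given, resolves the +/- ambiguity of the axis by
    flipping it to have a positive dot product with that vector.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need at least two 3-D points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    if np.allclose(centred, 0.0):
        raise DegenerateGeometryError("all points coincide; no line defined")
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    direction = vt[0] / np.linalg.norm(vt[0])
    if orient is not None and float(np.dot(direction, orient)) < 0.0:
        direction = -direction
    return direction, centroid


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral of four points, degrees, right-handed convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    return float(np.degrees(np.arctan2(y, x)))


def _fitted_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient from the centroid of the first four residues to the last four
    toward = coords[4:].mean(axis=0) - coords[:4].mean(axis=0)
    return best_fit_vector(coords, orient=toward)


def packing_angle(fv: FvStructure) -> PackingAngle:
    """Compute the signed VH/VL packing angle of one Fv structure."""
    light_coords, heavy_coords = conserved_ca_sets(fv)
    light_vec, light_pivot = _fitted_axis(light_coords)
    heavy_vec, heavy_pivot = _fitted_axis(heavy_coords)
    degrees = dihedral(
        light_pivot + light_vec,
        light_pivot,
        heavy_pivot,
        heavy_pivot + heavy_vec,
    )
    return PackingAngle(
        degrees=degrees,
        light_vector=light_vec,
        heavy_vector=heavy_vec,
        light_pivot=light_pivot,
        heavy_pivot=heavy_pivot,
    )


def batch_angles(
    paths: Iterable[str | Path],
    light_chain: str = "L",
    heavy_chain: str = "H",
) -> pd.DataFrame:
    """Packing angle for each readable structure in ``paths``.

    Returns a DataFrame with columns ``id`` and ``angle_deg``, one row per
    structure that could be read and computed.  Failures are logged with
    their reason, recorded in ``df.attrs['failures']`` as (path, reason)
    pairs, and excluded from the table.
    """
    rows: list[tuple[str, float]] = []
    failures: list[tuple[str, str]] = []
    for path in paths:
        try:
            fv = read_fv(path, light_chain=light_chain, heavy_chain=heavy_chain)
            rows.append((fv.id, packing_angle(fv).degrees))
        except (OSError, ValueError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            failures.append((str(path), str(exc)))
    df = pd.DataFrame(rows, columns=["id", "angle_deg"])
    df.attrs["failures"] = failures
    return df
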