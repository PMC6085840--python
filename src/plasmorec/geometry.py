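"""Discretised permittivity cross-sections of the three fiber sensor designs.

Designs
-------
``full_clad_removed``
    The cladding is stripped over the sensing region and the bare 5 um
    silica core carries an annular 50 nm gold shell, immersed in buffer.
``half_clad_removed``
    The fiber is polished flat down to the top of the core (the polish
    normal is +y, the flat sits at ``y = +core_radius``); a gold slab of the
    stated thickness is deposited on the flat, the remaining cladding stays
    intact below, buffer above the gold.
``half_core_removed``
    The polish goes through the fiber axis (half the core and half the
    cladding are gone, flat at ``y = 0``), with the gold slab on the cut.

The cross-section is discretised on a rectilinear tensor grid, geometrically
graded so the gold film is resolved by at least ``min_cells_in_film`` cells
along its normal.  Material assignment is by cell centre, with optional
sub-cell volume averaging of the permittivity at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .materials import Medium

__all__ = [
    "DESIGNS",
    "FiberGeometry",
    "PermittivityMap",
    "MeshingError",
    "build_cross_section",
    "graded_axis",
    "symmetric_axis",
]

DESIGNS = ("full_clad_removed", "half_clad_removed", "half_core_removed")


class MeshingError(RuntimeError):
    """The resolution policy could not resolve the gold film."""


@dataclass(frozen=True)
class FiberGeometry:
    """Geometry of one sensor design plus the media filling its regions."""

    design: str
    media: Dict[str, Medium]
    core_radius: float = 5e-6
    gold_thickness: float = 50e-9
    cladding_thickness: float = 2.5e-6

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        if self.core_radius <= 0.0:
            raise ValueError("core_radius must be positive")
        if not 0.0 <= self.gold_thickness < self.core_radius:
            raise ValueError("gold_thickness must satisfy 0 <= t < core_radius")
        for label in self.region_labels():
            if label not in self.media:
                raise ValueError(f"design {self.design} needs a medium for region {label!r}")

    def region_labels(self) -> Tuple[str, ...]:
        labels = ["core", "buffer"]
        if self.gold_thickness > 0.0:
            labels.insert(1, "gold")
        if self.design != "full_clad_removed":
            labels.append("cladding")
        return tuple(labels)

    def region_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Region label (as index into :meth:`region_labels`) at points."""
        labels = self.region_labels()
        idx = {lab: i for i, lab in enumerate(labels)}
        r = self.core_radius
        t = self.gold_thickness
        rad = np.hypot(x, y)
        out = np.full(np.broadcast(x, y).shape, idx["buffer"], dtype=np.int8)

        if self.design == "full_clad_removed":
            out[rad < r] = idx["core"]
            if t > 0.0:
                out[(rad >= r) & (rad < r + t)] = idx["gold"]
            return out

        flat = r if self.design == "half_clad_removed" else 0.0
        below = y < flat
        r_clad = r + self.cladding_thickness
        out[below & (rad < r_clad)] = idx["cladding"]
        out[below & (rad < r)] = idx["core"]
        if t > 0.0:
            out[(y >= flat) & (y < flat + t)] = idx["gold"]
        return out


@dataclass
class PermittivityMap:
    """Complex relative permittivity sampled on a rectilinear grid.

    ``xn``/``yn`` are the strictly increasing cell-vertex coordinates;
    ``eps`` and ``cell_region`` live on the ``(len(xn)-1, len(yn)-1)`` cell
    centres, x index first.
    """

    xn: np.ndarray
    yn: np.ndarray
    eps: np.ndarray
    cell_region: np.ndarray
    region_labels: Tuple[str, ...]
    lambda0: float
    provenance: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.xn) <= 0) or np.any(np.diff(self.yn) <= 0):
            raise ValueError("grid coordinates must be strictly increasing")
        if not np.all(np.isfinite(self.eps)):
            raise ValueError("permittivity map contains non-finite entries")

    @property
    def xc(self) -> np.ndarray:
        return 0.5 * (self.xn[:-1] + self.xn[1:])

    @property
    def yc(self) -> np.ndarray:
        return 0.5 * (self.yn[:-1] + self.yn[1:])

    @property
    def cell_areas(self) -> np.ndarray:
        return np.outer(np.diff(self.xn), np.diff(self.yn))

    def region_area(self, label: str) -> float:
        i = self.region_labels.index(label)
        return float(np.sum(self.cell_areas[self.cell_region == i]))

    def max_real_index(self) -> float:
        return float(np.sqrt(np.max(self.eps.real)))

    def mirror_x_asymmetry(self) -> float:
        """Max |eps - eps_mirrored| under x -> -x (0 on symmetric grids)."""
        return float(np.max(np.abs(self.eps - self.eps[::-1, :])))

    def to_csv(self, path: str) -> None:
        """Plain-text dump (one cell per row) for inspection/regression."""
        xc, yc = self.xc, self.yc
        with open(path, "w") as fh:
            fh.write(f"# lambda0_m={self.lambda0!r}\n")
            for k, v in self.provenance.items():
                fh.write(f"# {k}={v!r}\n")
            fh.write("# labels=" + ",".join(self.region_labels) + "\n")
            fh.write("x_m,y_m,region,eps_re,eps_im\n")
            for i in range(len(xc)):
                for j in range(len(yc)):
                    fh.write(
                        f"{xc[i]:.9e},{yc[j]:.9e},{int(self.cell_region[i, j])},"
                        f"{self.eps[i, j].real:.9e},{self.eps[i, j].imag:.9e}\n"
                    )


# ---------------------------------------------------------------------------
# Graded 1-D meshes


def graded_axis(
    start: float,
    stop: float,
    bands: Sequence[Tuple[float, float, float]],
    h_coarse: float,
    growth: float = 1.4,
) -> np.ndarray:
    """Strictly increasing node positions refined inside ``bands``.

    Each band ``(a, b, h)`` requests spacing ``h`` inside ``[a, b]``; the
    spacing grows geometrically (factor ``growth``) away from band edges up
    to ``h_coarse``.  Band edges inside the domain become exact nodes.
    """
    if stop <= start:
        raise ValueError("stop must exceed start")
    bands = [(max(a, start), min(b, stop), h) for a, b, h in bands if b > start and a < stop]

    def target_h(x: float) -> float:
        h = h_coarse
        for a, b, hb in bands:
            if a <= x <= b:
                h = min(h, hb)
            else:
                dist = a - x if x < a else x - b
                # geometric growth from the band edge
                h = min(h, hb * growth ** (dist / hb) if dist / hb < 60 else h_coarse)
        return min(h, h_coarse)

    anchors = sorted({start, stop, *(a for a, _, _ in bands), *(b for _, b, _ in bands)})
    nodes = [anchors[0]]
    for p, q in zip(anchors[:-1], anchors[1:]):
        seg = [p]
        x = p
        while x < q:
            x = x + target_h(x)
            seg.append(min(x, q))
        if len(seg) > 2 and (seg[-1] - seg[-2]) < 0.25 * (seg[-2] - seg[-3]):
            seg.pop(-2)  # avoid a sliver cell at the segment end
        # rescale interior steps so the segment lands exactly on q
        seg = np.asarray(seg)
        seg = p + (seg - p) * (q - p) / (seg[-1] - p)
        nodes.extend(seg[1:].tolist())
    return np.asarray(nodes)


def symmetric_axis(
    half_width: float,
    bands: Sequence[Tuple[float, float, float]],
    h_coarse: float,
    growth: float = 1.4,
) -> np.ndarray:
    """Axis over [-W, W], mirror-symmetric about 0.

    ``bands`` are specified on the positive half (they are mirrored).
    """
    pos = graded_axis(0.0, half_width, bands, h_coarse, growth)
    return np.concatenate([-pos[::-1], pos[1:]])


# ---------------------------------------------------------------------------
# Cross-section builder


def _film_bands(geom: FiberGeometry, h_film: float):
    """(x_bands, y_bands) resolving the gold film of each design."""
    r, t = geom.core_radius, geom.gold_thickness
    pad = 4 * t
    if geom.design == "full_clad_removed":
        b = [(0.0, r + t + pad, h_film)]        # ring occupies all radii <= r+t
        return b, [( -(r + t + pad), r + t + pad, h_film)]
    if geom.design == "half_clad_removed":
        return [], [(r - pad, r + t + pad, h_film)]
    return [], [(-pad, t + pad, h_film)]


def build_cross_section(
    geom: FiberGeometry,
    lambda0: float,
    min_cells_in_film: int = 5,
    window_factor: float = 4.0,
    points_per_wavelength: float = 4.0,
    volume_averaging: bool = True,
) -> PermittivityMap:
    """Build the discretised permittivity map of one design.

    Parameters
    ----------
    geom : FiberGeometry
    lambda0 : float
        Vacuum wavelength (m) at which every medium is evaluated.
    min_cells_in_film : int
        Minimum number of cells across the gold thickness along its normal.
    window_factor : float
        Square computational window of side ``window_factor * core_radius``.
    points_per_wavelength : float
        Coarse-grid sampling of the local wavelength in the densest medium.
    volume_averaging : bool
        If true, each cell's permittivity is the 4x4-subsample average of
        the material permittivity over the cell (first-order smoothing of
        staircased interfaces); cell_region stays centre-assigned.
    """
    r, t = geom.core_radius, geom.gold_thickness
    half = 0.5 * window_factor * r
    labels = geom.region_labels()
    eps_by_region = np.array(
        [complex(geom.media[lab].permittivity(lambda0)) for lab in labels]
    )
    n_max = float(np.max(np.sqrt(eps_by_region.real.clip(min=0.0) + 0j)).real) or 1.5
    h_coarse = lambda0 / (points_per_wavelength * max(n_max, 1.0))

    if t > 0.0:
        h_film = t / float(min_cells_in_film)
        if h_film <= 0.0:
            raise MeshingError("cannot resolve a non-positive film thickness")
    else:
        h_film = h_coarse
    x_bands, y_bands = _film_bands(geom, h_film) if t > 0 else ([], [])
    # resolve the curved core-cladding interface moderately in y
    y_bands = list(y_bands) + [(-r - h_coarse, -r + h_coarse, h_coarse / 2), (r - h_coarse, r + h_coarse, h_coarse / 2)]

    xn = symmetric_axis(half, x_bands, h_coarse)
    yn = graded_axis(-half, half, y_bands, h_coarse)

    xc = 0.5 * (xn[:-1] + xn[1:])
    yc = 0.5 * (yn[:-1] + yn[1:])
    Xc, Yc = np.meshgrid(xc, yc, indexing="ij")
    region = geom.region_at(Xc, Yc)

    if volume_averaging and t > 0.0:
        nss = 4
        offs = (np.arange(nss) + 0.5) / nss
        dx = np.diff(xn)
        dy = np.diff(yn)
        eps_acc = np.zeros(region.shape, dtype=complex)
        for ox in offs:
            xs = xn[:-1] + ox * dx
            for oy in offs:
                ys = yn[:-1] + oy * dy
                Xs, Ys = np.meshgrid(xs, ys, indexing="ij")
                eps_acc += eps_by_region[geom.region_at(Xs, Ys)]
        eps = eps_acc / (nss * nss)
    else:
        eps = eps_by_region[region].astype(complex)

    pmap = PermittivityMap(
        xn=xn,
        yn=yn,
        eps=eps,
        cell_region=region,
        region_labels=labels,
        lambda0=lambda0,
        provenance={
            "design": geom.design,
            "core_radius_m": r,
            "gold_thickness_m": t,
        },
    )
    if t > 0.0:
        _check_film_resolution(pmap, geom, min_cells_in_film)
    return pmap


def _check_film_resolution(pmap: PermittivityMap, geom: FiberGeometry, n_min: int) -> None:
    r, t = geom.core_radius, geom.gold_thickness
    yc = pmap.yc
    xc = pmap.xc
    if geom.design == "half_clad_removed":
        n = int(np.sum((yc > r) & (yc < r + t)))
    elif geom.design == "half_core_removed":
        n = int(np.sum((yc > 0.0) & (yc < t)))
    else:
        n = min(
            int(np.sum((yc > r) & (yc < r + t))),
            int(np.sum((xc > r) & (xc < r + t))),
        )
    if n < n_min:
        raise MeshingError(
            f"only {n} cells across the {t*1e9:.0f} nm gold film (need >= {n_min})"
        )
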