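"""Ground-truthed synthetic inputs for every stage of the analysis chain.

The centrepiece is :func:`generate_monolayer`, which builds a
membrane-labelled columnar epithelial monolayer (MDCK-like packing from a
Voronoi tessellation of a jittered lattice) and optionally applies an
optogenetic constriction program: cells under the stimulation rectangle
shrink their apical surface with saturating exponential kinetics, the
surrounding apical tessellation is pulled inward by a smooth radial
displacement field, and — with volume conservation and a fixed basal
surface — cells elongate following the linear-taper relation
``h = 2V / (A_apical + A_basal)``.

Every cell is constructed with a cross-sectional area that varies
*linearly* from apical to basal, so the ground-truth table satisfies that
relation exactly, to machine precision; voxelisation is the only
discrepancy downstream measurements have to contend with.

Also provided: analytic radial displacement fields for the PIV stage,
arc-band "colony cross-section" images for curvature, junction-grid
images for the translocation ratio, flattened organoid contours, and
exponential on/off translocation time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram
from skimage.draw import polygon as draw_polygon

from .stack import ImageStack, LabelVolume
from .tracking import StimulationROI

_N_ANGLES = 96  # polar resampling resolution for cross-sections


@dataclass
class SyntheticTissueSpec:
    """Study conditions for the synthetic monolayer.

    Defaults reproduce the imaging conditions of the experiments this
    package analyses: 0.207 µm/px in x-y, 0.7 µm/px in z, ~100 µm²
    apical footprints and ~10 µm columnar cells.
    """

    grid_shape: tuple[int, int] = (5, 5)
    cell_footprint: float = 10.0  # µm, lattice spacing (≈ sqrt(apical area))
    tissue_height: float = 10.0  # µm
    taper: float = 1.0  # apical/basal area ratio at t0
    voxel_size_xy: float = 0.207  # µm
    voxel_size_z: float = 0.7  # µm
    membrane_width: float = 0.4  # µm
    psf_sigma: float = 0.25  # µm, lateral PSF width
    psf_sigma_z: float = 0.45  # µm, axial PSF width (confocal z-resolution is worse)
    gaussian_sd: float = 0.03  # read-noise sd (fraction of membrane signal)
    poisson_scale: float = 200.0  # photons at unit intensity; 0 disables shot noise
    cytoplasm_level: float = 0.10  # interior signal relative to membrane
    frame_interval: float = 2.0  # minutes between frames
    n_frames: int = 1
    margin: float = 2.0  # µm of empty field around the tissue
    jitter: float = 0.25  # centre jitter as a fraction of cell_footprint
    seed: int = 0
    noise_seed: int | None = None  # separate stream; derived from seed when None

    def __post_init__(self) -> None:
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape must be at least (1, 1)")
        for name in ("cell_footprint", "tissue_height", "voxel_size_xy", "voxel_size_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.taper <= 0:
            raise ValueError("taper must be positive")

    @property
    def field_size(self) -> tuple[float, float]:
        """(width, height) of the image field in µm."""
        nx, ny = self.grid_shape
        return (
            nx * self.cell_footprint + 2 * self.margin,
            ny * self.cell_footprint + 2 * self.margin,
        )


@dataclass
class ConstrictionProgram:
    """Apical-constriction schedule applied to cells under the ROI.

    During stimulation the apical area of a programmed cell follows
    ``A0 * (1 - r * (1 - exp(-(t - t_on)/tau_on)))``; after stimulation
    the remaining deficit relaxes back with ``tau_off``.  With
    ``conserve_volume`` and ``fix_basal`` the cell height follows
    ``h = 2V/(A_apical + A_basal)`` by construction.
    """

    roi: StimulationROI
    plateau_reduction: float = 0.254  # fraction of initial apical area removed
    tau_on: float = 10.0  # minutes
    tau_off: float = 5.0  # minutes
    conserve_volume: bool = True
    fix_basal: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.plateau_reduction < 1.0):
            raise ValueError("plateau_reduction must be in [0, 1)")
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("time constants must be positive")

    def area_factor(self, t: float) -> float:
        """Fraction of the initial apical area remaining at time t."""
        r = self.plateau_reduction
        t0, t1 = self.roi.t_start, self.roi.t_end
        if t <= t0:
            return 1.0
        if t <= t1:
            return 1.0 - r * (1.0 - math.exp(-(t - t0) / self.tau_on))
        deficit_end = r * (1.0 - math.exp(-(t1 - t0) / self.tau_on))
        return 1.0 - deficit_end * math.exp(-(t - t1) / self.tau_off)


@dataclass
class _CellGeometry:
    """One cell's analytic geometry at one frame (µm coordinates)."""

    label: int
    apical_poly: np.ndarray  # (N, 2) closed-ring vertices, x-y µm
    basal_poly: np.ndarray
    apical_area: float
    basal_area: float
    height: float
    volume: float
    cls: str


@dataclass
class SyntheticMonolayer:
    """Generator output: image series, ground-truth labels and table."""

    spec: SyntheticTissueSpec
    program: ConstrictionProgram | None
    stacks: list[ImageStack]
    labels: list[LabelVolume]
    truth: pd.DataFrame
    geometry: list[list[_CellGeometry]] = field(repr=False, default_factory=list)
    times: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def rasterize_labels(self, voxel_size_z: float, voxel_size_xy: float) -> list[LabelVolume]:
        """Re-rasterise the analytic ground truth at another voxel size.

        All frames share one stack depth (that of the tallest cell over
        the whole timelapse), as in an acquired timelapse.
        """
        max_h = max(c.height for geo in self.geometry for c in geo)
        nz = _stack_depth(max_h, self.spec, voxel_size_z)
        return [
            _rasterize_frame(geo, self.spec, voxel_size_z, voxel_size_xy, nz=nz)
            for geo in self.geometry
        ]


# ---------------------------------------------------------------------------
# tessellation helpers


def _polygon_to_ring(poly: Polygon) -> np.ndarray:
    pts = np.asarray(poly.exterior.coords)[:-1]
    # enforce counter-clockwise order in (x, y)
    if _ring_area(pts) < 0:
        pts = pts[::-1]
    return pts


def _ring_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ring_centroid(pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    a = 0.5 * cross.sum()
    cx = float(((x + np.roll(x, -1)) * cross).sum() / (6 * a))
    cy = float(((y + np.roll(y, -1)) * cross).sum() / (6 * a))
    return np.array([cx, cy])


def _radial_profile(pts: np.ndarray, center: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Boundary distance from ``center`` at each query angle.

    Valid for polygons that are star-shaped about ``center`` (Voronoi
    cells are convex; the smooth constriction warp preserves
    star-shapedness for the moderate deformations generated here).
    """
    rel = pts - center
    phi = np.arctan2(rel[:, 1], rel[:, 0])
    order = np.argsort(phi)
    phi = phi[order]
    rel = rel[order]
    nxt = np.roll(np.arange(len(phi)), -1)
    # pad for wrap-around lookup
    phi_ext = np.concatenate([phi, [phi[0] + 2 * np.pi]])
    q = np.mod(angles - phi[0], 2 * np.pi) + phi[0]
    idx = np.searchsorted(phi_ext, q, side="right") - 1
    idx = np.clip(idx, 0, len(phi) - 1)
    p1 = rel[idx]
    p2 = rel[nxt[idx]]
    d = np.column_stack([np.cos(q), np.sin(q)])
    e = p2 - p1
    denom = d[:, 0] * e[:, 1] - d[:, 1] * e[:, 0]
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    r = (p1[:, 0] * e[:, 1] - p1[:, 1] * e[:, 0]) / denom
    return np.maximum(r, 1e-6)


def _base_tessellation(spec: SyntheticTissueSpec, rng: np.random.Generator):
    """Voronoi tessellation of a jittered lattice, clipped to the tissue box."""
    nx_, ny_ = spec.grid_shape
    f = spec.cell_footprint
    m = spec.margin
    gx, gy = np.meshgrid(np.arange(nx_), np.arange(ny_))
    cx = m + (gx.ravel() + 0.5) * f
    cy = m + (gy.ravel() + 0.5) * f
    # offset alternate rows for hexagonal-like packing
    cx = cx + (gy.ravel() % 2) * 0.25 * f - 0.125 * f
    jit = rng.uniform(-0.5, 0.5, size=(cx.size, 2)) * spec.jitter * f
    centers = np.column_stack([cx, cy]) + jit
    tissue_box = box(m, m, m + nx_ * f, m + ny_ * f)
    if centers.shape[0] == 1:
        return centers, [_polygon_to_ring(tissue_box)]
    cells = voronoi_diagram(MultiPoint([tuple(c) for c in centers]), envelope=tissue_box)
    polys: list[np.ndarray | None] = [None] * len(centers)
    for geom in cells.geoms:
        clipped = geom.intersection(tissue_box)
        if clipped.is_empty:
            continue
        for i, c in enumerate(centers):
            if polys[i] is None and geom.contains(Point(c)):
                polys[i] = _polygon_to_ring(clipped)
                break
    if any(p is None for p in polys):
        raise RuntimeError("Voronoi tessellation failed to cover every seed")
    return centers, polys


def _scale_ring(pts: np.ndarray, factor: float, about: np.ndarray | None = None) -> np.ndarray:
    c = _ring_centroid(pts) if about is None else about
    return c + factor * (pts - c)


def _warp(
    points: np.ndarray, center: np.ndarray, strain: float, radius: float, decay: float
) -> np.ndarray:
    """Radial pull of ``points`` toward ``center``: the constriction field.

    Inside the stimulated radius the displacement grows linearly with
    distance (``u = strain * r``), compressing the region uniformly;
    outside it decays as ``strain * radius²/r`` with an extra
    exponential cut-off of length ``decay`` — adjacent tissue is pulled
    inward with displacement fading over a few cell diameters.
    """
    rel = points - center
    d = np.linalg.norm(rel, axis=-1)
    inside = d <= radius
    with np.errstate(invalid="ignore", divide="ignore"):
        tail = np.where(
            d > 1e-9,
            (radius**2 / np.maximum(d, 1e-9)) * np.exp(-np.maximum(d - radius, 0.0) / decay),
            0.0,
        )
    mag = strain * np.where(inside, d, tail)
    mag = np.minimum(mag, 0.9 * d)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(d[:, None] > 1e-9, rel / np.maximum(d, 1e-9)[:, None], 0.0)
    return points - mag[:, None] * unit


def _solve_warp_amplitude(
    apical_polys: list[np.ndarray],
    stim_idx: list[int],
    center: np.ndarray,
    radius: float,
    decay: float,
    target_area: float,
) -> float:
    """Bisection on the strain so the stimulated apical area hits target."""

    def stim_area(s: float) -> float:
        return sum(
            abs(_ring_area(_warp(apical_polys[i], center, s, radius, decay)))
            for i in stim_idx
        )

    a0 = stim_area(0.0)
    if target_area >= a0 - 1e-12:
        return 0.0
    lo, hi = 0.0, 0.8
    if stim_area(hi) > target_area:
        raise ValueError(
            "programmed constriction too strong for the warp model; "
            "reduce plateau_reduction or enlarge the field"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if stim_area(mid) > target_area:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# rasterisation


def _stack_depth(max_h: float, spec: SyntheticTissueSpec, voxel_size_z: float) -> int:
    # image past the basal side: leave room for the blurred basal face and
    # dark medium below it, as an acquired stack would
    pad_um = 2.0 * spec.psf_sigma_z + voxel_size_z
    return int(np.floor(max_h / voxel_size_z + 0.5)) + 1 + int(np.ceil(pad_um / voxel_size_z))


def _rasterize_frame(
    geo: list[_CellGeometry],
    spec: SyntheticTissueSpec,
    voxel_size_z: float,
    voxel_size_xy: float,
    nz: int | None = None,
) -> LabelVolume:
    w, h = spec.field_size
    nx_pix = int(round(w / voxel_size_xy))
    ny_pix = int(round(h / voxel_size_xy))
    if nz is None:
        nz = _stack_depth(max(c.height for c in geo), spec, voxel_size_z)
    vol = np.zeros((nz, ny_pix, nx_pix), dtype=np.int32)
    angles = np.linspace(0, 2 * np.pi, _N_ANGLES, endpoint=False)
    unit = np.column_stack([np.cos(angles), np.sin(angles)])

    for cell in geo:
        ca = _ring_centroid(cell.apical_poly)
        cb = _ring_centroid(cell.basal_poly)
        ra = _radial_profile(cell.apical_poly, ca, angles)
        rb = _radial_profile(cell.basal_poly, cb, angles)
        for k in range(nz):
            zc = (k + 0.5) * voxel_size_z
            if zc >= cell.height:
                break
            f = zc / cell.height
            c_f = (1 - f) * ca + f * cb
            r_f = (1 - f) * ra + f * rb
            pts = c_f + r_f[:, None] * unit
            # rescale so the cross-sectional area is exactly linear in z
            a_target = cell.apical_area + f * (cell.basal_area - cell.apical_area)
            a_poly = abs(_ring_area(pts))
            pts = _scale_ring(pts, math.sqrt(a_target / a_poly), about=c_f)
            rows = pts[:, 1] / voxel_size_xy - 0.5
            cols = pts[:, 0] / voxel_size_xy - 0.5
            rr, cc = draw_polygon(rows, cols, shape=(ny_pix, nx_pix))
            sel = vol[k, rr, cc] == 0
            vol[k, rr[sel], cc[sel]] = cell.label
    return LabelVolume(vol, (voxel_size_z, voxel_size_xy, voxel_size_xy))


def _lateral_membrane_mask(labels: np.ndarray, extra_iters: int = 0) -> np.ndarray:
    """Lateral membrane voxels: cell voxels whose x/y neighbour differs.

    Each cell contributes one boundary-voxel layer, so walls shared by
    two cells are two voxels thick and centred on the interface.
    ``extra_iters`` dilates in-plane (within the cells) for wider
    membranes.
    """
    fg = labels > 0
    mem = np.zeros(labels.shape, dtype=bool)
    for axis in (1, 2):
        for shift in (1, -1):
            nb = np.full_like(labels, 0)
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if shift == 1:
                src[axis] = slice(1, None)
                dst[axis] = slice(None, -1)
            else:
                src[axis] = slice(None, -1)
                dst[axis] = slice(1, None)
            nb[tuple(dst)] = labels[tuple(src)]
            mem |= fg & (nb != labels)
            # rim walls: the monolayer notionally continues beyond the
            # field, so virtual outside neighbours contribute the second
            # membrane layer there, like any interior wall
            mem |= (~fg) & (nb > 0)
    if extra_iters > 0:
        st = np.zeros((1, 3, 3), dtype=bool)
        st[0] = True
        mem = ndimage.binary_dilation(mem, structure=st, iterations=extra_iters) & fg
    return mem


def _render_membrane(
    labels_iso: LabelVolume,
    geo: list[_CellGeometry],
    spec: SyntheticTissueSpec,
    noise_rng: np.random.Generator,
    nz_out: int,
) -> ImageStack:
    """Image formation: fine-grid membrane object → PSF → z-sampling → noise.

    Lateral walls are painted on the cells' boundary voxels (centred on
    the shared interface).  Apical and basal face membranes are thin
    sheets lying exactly *at* the cell's top/bottom plane, so their
    intensity is deposited with sub-voxel linear weights at that plane —
    the face peak of the blurred image then localises the true surface.
    The object is blurred by an anisotropic PSF, box-averaged down to
    the confocal z-spacing (detector partial-volume), and shot/read
    noise applied at the recorded resolution.
    """
    v = labels_iso.voxel_size[2]
    vz = spec.voxel_size_z
    extra = max(0, int(round((spec.membrane_width - 2 * v) / (2 * v))))
    mem = _lateral_membrane_mask(labels_iso.labels, extra_iters=extra)
    img = np.where(labels_iso.labels > 0, spec.cytoplasm_level, 0.0)
    img[mem] = 1.0
    # face sheets at z = 0 (apical) and z = h_cell (basal), sub-voxel weighted
    ny_pix, nx_pix = img.shape[1], img.shape[2]
    for cell in geo:
        for poly, plane_z in ((cell.apical_poly, 0.0), (cell.basal_poly, cell.height)):
            rows = poly[:, 1] / v - 0.5
            cols = poly[:, 0] / v - 0.5
            rr, cc = draw_polygon(rows, cols, shape=(ny_pix, nx_pix))
            pos = plane_z / v - 0.5
            k0 = int(np.floor(pos))
            w = pos - k0
            if 0 <= k0 < img.shape[0]:
                img[k0, rr, cc] += (1.0 - w)
            if 0 <= k0 + 1 < img.shape[0]:
                img[k0 + 1, rr, cc] += w
    img = ndimage.gaussian_filter(
        img, sigma=(spec.psf_sigma_z / v, spec.psf_sigma / v, spec.psf_sigma / v)
    )
    zc = (np.arange(img.shape[0]) + 0.5) * v
    out = np.zeros((nz_out, img.shape[1], img.shape[2]), dtype=np.float64)
    for k in range(nz_out):
        sel = (zc >= k * vz) & (zc < (k + 1) * vz)
        if np.any(sel):
            out[k] = img[sel].mean(axis=0)
    if spec.poisson_scale > 0:
        out = noise_rng.poisson(np.clip(out, 0, None) * spec.poisson_scale) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        out = out + noise_rng.normal(0.0, spec.gaussian_sd, size=out.shape)
    return ImageStack(
        out.astype(np.float32), (vz, spec.voxel_size_xy, spec.voxel_size_xy), channel="membrane"
    )


# ---------------------------------------------------------------------------
# main generator


def generate_monolayer(
    spec: SyntheticTissueSpec,
    program: ConstrictionProgram | None = None,
) -> SyntheticMonolayer:
    """Generate a membrane-labelled monolayer timelapse with ground truth.

    Returns a :class:`SyntheticMonolayer` holding, per frame, the noisy
    membrane-channel :class:`~optomorph.stack.ImageStack`, the
    ground-truth :class:`~optomorph.stack.LabelVolume` (both at the
    spec's anisotropic voxel size), and a tidy ground-truth table with
    one row per cell per frame (volume µm³, apical/basal area µm²,
    height µm, centroid µm, class).

    Raises
    ------
    ValueError
        If the ROI extends outside the field, or a programmed cell's
        apical area would collapse below the rasterisable minimum.
    """
    geom_rng = np.random.default_rng(spec.seed)
    noise_seed = spec.noise_seed if spec.noise_seed is not None else spec.seed + 10_000
    noise_rng = np.random.default_rng(noise_seed)

    w, h = spec.field_size
    if program is not None:
        roi = program.roi
        if roi.x_min < 0 or roi.y_min < 0 or roi.x_max > w or roi.y_max > h:
            raise ValueError("stimulation ROI extends outside the image field")

    centers, basal_polys = _base_tessellation(spec, geom_rng)
    n_cells = len(basal_polys)
    basal_areas = np.array([abs(_ring_area(p)) for p in basal_polys])

    # apical tessellation at t0: basal polygons scaled to the taper ratio
    s0 = math.sqrt(spec.taper)
    apical0 = [_scale_ring(p, s0) for p in basal_polys]
    apical0_areas = basal_areas * spec.taper
    v0 = spec.tissue_height * (apical0_areas + basal_areas) / 2.0

    # stimulated set: majority of the t0 apical area inside the ROI
    stim_idx: list[int] = []
    if program is not None:
        roi_poly = box(program.roi.x_min, program.roi.y_min, program.roi.x_max, program.roi.y_max)
        for i, ring in enumerate(apical0):
            p = Polygon(ring)
            if p.intersection(roi_poly).area > 0.5 * p.area:
                stim_idx.append(i)

    classes = _classify_truth(basal_polys, stim_idx, n_cells)

    times = np.arange(spec.n_frames) * spec.frame_interval
    if program is not None:
        # effective radius of the illuminated rectangle; displacement decays
        # over a couple of cell diameters beyond it
        radius = math.sqrt(program.roi.width * program.roi.height / math.pi)
        decay = 2.0 * spec.cell_footprint
        stim_area0 = sum(apical0_areas[i] for i in stim_idx)
    min_area = (3 * spec.voxel_size_xy) ** 2

    geometry: list[list[_CellGeometry]] = []
    rows = []
    for fidx, t in enumerate(times):
        if program is not None and stim_idx:
            g = program.area_factor(float(t))
            amp = _solve_warp_amplitude(
                apical0, stim_idx, program.roi.center, radius, decay, g * stim_area0
            )
            apical_t = [_warp(p, program.roi.center, amp, radius, decay) for p in apical0]
            if program.fix_basal:
                basal_t = basal_polys
            else:
                basal_t = [_warp(p, program.roi.center, amp, radius, decay) for p in basal_polys]
        else:
            apical_t = apical0
            basal_t = basal_polys

        frame_geo: list[_CellGeometry] = []
        for i in range(n_cells):
            aa = abs(_ring_area(apical_t[i]))
            ab = abs(_ring_area(basal_t[i]))
            if aa < min_area or ab < min_area:
                raise ValueError(
                    f"cell {i + 1} degenerates at frame {fidx}: apical area {aa:.3g} µm²"
                )
            if program is not None and program.conserve_volume:
                vol = float(v0[i])
                hgt = 2.0 * vol / (aa + ab)
            else:
                hgt = spec.tissue_height
                vol = hgt * (aa + ab) / 2.0
            cen = _ring_centroid(basal_t[i])
            frame_geo.append(
                _CellGeometry(
                    label=i + 1,
                    apical_poly=apical_t[i],
                    basal_poly=basal_t[i],
                    apical_area=aa,
                    basal_area=ab,
                    height=hgt,
                    volume=vol,
                    cls=classes[i],
                )
            )
            rows.append(
                {
                    "label": i + 1,
                    "frame": fidx,
                    "time": float(t),
                    "volume_um3": vol,
                    "apical_area_um2": aa,
                    "basal_area_um2": ab,
                    "height_um": hgt,
                    "centroid_x_um": cen[0],
                    "centroid_y_um": cen[1],
                    "centroid_z_um": hgt / 2.0,
                    "class": classes[i],
                }
            )
        geometry.append(frame_geo)

    truth = pd.DataFrame(rows)
    max_h_all = max(c.height for geo in geometry for c in geo)
    nz_anis = _stack_depth(max_h_all, spec, spec.voxel_size_z)
    nz_iso = _stack_depth(max_h_all, spec, spec.voxel_size_xy)
    labels = [
        _rasterize_frame(geo, spec, spec.voxel_size_z, spec.voxel_size_xy, nz=nz_anis)
        for geo in geometry
    ]
    stacks = []
    for fidx, (geo, lab) in enumerate(zip(geometry, labels)):
        lab_iso = _rasterize_frame(geo, spec, spec.voxel_size_xy, spec.voxel_size_xy, nz=nz_iso)
        st = _render_membrane(lab_iso, geo, spec, noise_rng, nz_out=lab.shape[0])
        st.timepoint = fidx
        stacks.append(st)
    return SyntheticMonolayer(
        spec=spec,
        program=program,
        stacks=stacks,
        labels=labels,
        truth=truth,
        geometry=geometry,
        times=times,
    )


def _classify_truth(basal_polys, stim_idx, n_cells) -> list[str]:
    """Layer classes from shared-edge adjacency of the basal tessellation."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(n_cells))
    shp = [Polygon(p) for p in basal_polys]
    for i in range(n_cells):
        for j in range(i + 1, n_cells):
            inter = shp[i].buffer(1e-6).intersection(shp[j].buffer(1e-6))
            if inter.area > 1e-9 or shp[i].exterior.intersection(shp[j].exterior).length > 1e-6:
                g.add_edge(i, j)
    classes = ["unclassified"] * n_cells
    if stim_idx:
        dist = nx.multi_source_dijkstra_path_length(g, set(stim_idx), weight=None)
        for i in range(n_cells):
            if i in stim_idx:
                classes[i] = "stimulated"
            elif i in dist:
                classes[i] = f"layer{dist[i]}"
    else:
        classes = ["layer0"] * n_cells
    return classes


# ---------------------------------------------------------------------------
# flow-field generator


def generate_flow_field(
    center: np.ndarray,
    magnitude_profile,
    grid_spacing: float,
    extent: tuple[float, float],
    n_frames: int = 1,
    time_profile: np.ndarray | None = None,
    frame_interval: float = 1.0,
):
    """Analytic radially converging displacement fields.

    Each vector points from its grid position toward ``center`` with
    magnitude ``magnitude_profile(distance)`` (µm per frame interval),
    scaled per frame by ``time_profile`` (default: all ones; negative
    values reverse the field outward).

    Returns a list of :class:`~optomorph.flow.VectorField`, one per frame
    interval.
    """
    from .flow import VectorField

    center = np.asarray(center, dtype=float)
    if time_profile is None:
        time_profile = np.ones(n_frames)
    else:
        time_profile = np.asarray(time_profile, dtype=float)
        if time_profile.size != n_frames:
            raise ValueError("time_profile length must equal n_frames")
    x = np.arange(grid_spacing / 2.0, extent[0], grid_spacing)
    y = np.arange(grid_spacing / 2.0, extent[1], grid_spacing)
    xx, yy = np.meshgrid(x, y)
    dx = center[0] - xx
    dy = center[1] - yy
    d = np.hypot(dx, dy)
    mag = np.vectorize(magnitude_profile)(d).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(d > 1e-12, mag * dx / np.maximum(d, 1e-12), 0.0)
        uy = np.where(d > 1e-12, mag * dy / np.maximum(d, 1e-12), 0.0)
    fields = []
    for s in time_profile:
        fields.append(
            VectorField(x=x, y=y, u=s * ux, v=s * uy, frame_interval=frame_interval)
        )
    return fields


# ---------------------------------------------------------------------------
# curvature generators


def generate_colony_profile(
    arc_radius: float,
    arc_span: float,
    thickness: float,
    shape: tuple[int, int],
    pixel_size: float,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """2D cross-section of a curved colony: a bright band along a circular arc.

    The band midline is an arc of radius ``arc_radius`` µm spanning
    ``arc_span`` degrees, opening upward (centre of curvature above the
    band, i.e. concave toward low y).  ``arc_radius=np.inf`` produces a
    straight horizontal band.

    Returns ``(image, true_curvature)`` with curvature ``1/arc_radius``
    in µm⁻¹ (0 for the straight band).
    """
    if not np.isinf(arc_radius) and arc_radius <= thickness:
        raise ValueError("arc_radius must exceed the band thickness")
    ny, nx = shape
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * pixel_size, (np.arange(nx) + 0.5) * pixel_size, indexing="ij"
    )
    cx = nx * pixel_size / 2.0
    cy_mid = ny * pixel_size / 2.0
    if np.isinf(arc_radius):
        dist_mid = np.abs(yy - cy_mid)
        in_span = np.ones_like(dist_mid, dtype=bool)
        kappa = 0.0
    else:
        # circle centre directly above the band midline
        ccy = cy_mid - arc_radius
        d = np.hypot(xx - cx, yy - ccy)
        dist_mid = np.abs(d - arc_radius)
        ang = np.degrees(np.arctan2(xx - cx, yy - ccy))  # 0° straight down
        in_span = np.abs(ang) <= arc_span / 2.0
        kappa = 1.0 / arc_radius
    img = np.where((dist_mid <= thickness / 2.0) & in_span, 1.0, 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float32), kappa


def flattened_disc_contour(
    radius: float,
    flatten_span_deg: float,
    center_angle_deg: float = 0.0,
    n_points: int = 2000,
) -> np.ndarray:
    """Closed contour of a disc with one arc replaced by its chord.

    Models an organoid perimeter locally flattened by stimulation: the
    arc of ``flatten_span_deg`` degrees centred on ``center_angle_deg``
    is replaced by a straight chord.  Points are ordered
    counter-clockwise, in µm, centred on the origin, and approximately
    uniform in arc length.
    """
    span = math.radians(flatten_span_deg)
    a0 = math.radians(center_angle_deg)
    th_start = a0 + span / 2.0
    th_end = a0 + 2 * math.pi - span / 2.0
    arc_len = radius * (th_end - th_start)
    chord_p1 = radius * np.array([math.cos(th_end), math.sin(th_end)])
    chord_p2 = radius * np.array([math.cos(th_start), math.sin(th_start)])
    chord_len = float(np.linalg.norm(chord_p2 - chord_p1))
    total = arc_len + chord_len
    n_arc = max(3, int(round(n_points * arc_len / total)))
    n_chord = max(2, n_points - n_arc)
    th = np.linspace(th_start, th_end, n_arc, endpoint=True)
    arc_pts = radius * np.column_stack([np.cos(th), np.sin(th)])
    s = np.linspace(0, 1, n_chord + 2)[1:-1]
    chord_pts = chord_p1 + s[:, None] * (chord_p2 - chord_p1)
    return np.vstack([arc_pts, chord_pts])


def contour_to_mask(contour: np.ndarray, shape: tuple[int, int], pixel_size: float, center=None):
    """Rasterise a closed µm contour into a binary mask (contour centred)."""
    ny, nx = shape
    if center is None:
        center = np.array([nx * pixel_size / 2.0, ny * pixel_size / 2.0])
    pts = contour + np.asarray(center)
    rows = pts[:, 1] / pixel_size - 0.5
    cols = pts[:, 0] / pixel_size - 0.5
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(rows, cols, shape=shape)
    mask[rr, cc] = True
    return mask


# ---------------------------------------------------------------------------
# junction / translocation generators


def generate_junction_image(
    ratio: float,
    shape: tuple[int, int] = (256, 256),
    cell_pitch: int = 40,
    junction_width: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """2D image whose junction-grid pixels are ``ratio`` × the cytoplasm level.

    Before noise, the mean intensity on the junction mask is exactly
    ``ratio`` times the mean off the mask (cytoplasm level 1).

    Returns ``(image, junction_mask)``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    ny, nx = shape
    mask = np.zeros(shape, dtype=bool)
    half = junction_width // 2
    for r in range(cell_pitch // 2, ny, cell_pitch):
        mask[max(0, r - half) : r + half + 1, :] = True
    for c in range(cell_pitch // 2, nx, cell_pitch):
        mask[:, max(0, c - half) : c + half + 1] = True
    img = np.where(mask, float(ratio), 1.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img.astype(np.float64), mask


def generate_translocation_series(
    t: np.ndarray,
    stim_window: tuple[float, float],
    baseline: float = 1.0,
    amplitude: float = 0.75,
    tau_on: float = 10.0,
    tau_off: float = 43.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Junction/cytoplasm ratio time series with exponential on/off kinetics.

    During the stimulation window the ratio rises as
    ``baseline + amplitude*(1 - exp(-(t-t_on)/tau_on))``; afterwards it
    decays back with ``tau_off`` (half-life ``tau_off * ln 2``).
    """
    t = np.asarray(t, dtype=float)
    t_on, t_off = stim_window
    y = np.full_like(t, baseline)
    during = (t >= t_on) & (t <= t_off)
    y[during] = baseline + amplitude * (1 - np.exp(-(t[during] - t_on) / tau_on))
    amp_end = amplitude * (1 - np.exp(-(t_off - t_on) / tau_on))
    after = t > t_off
    y[after] = baseline + amp_end * np.exp(-(t[after] - t_off) / tau_off)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return y


__all__ = [
    "SyntheticTissueSpec",
    "ConstrictionProgram",
    "SyntheticMonolayer",
    "generate_monolayer",
    "generate_flow_field",
    "generate_colony_profile",
    "generate_junction_image",
    "generate_translocation_series",
    "flattened_disc_contour",
    "contour_to_mask",
]
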