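"""Synthetic liver-lobule generator with full ground truth.

Emulates the six-marker panel of a lobule imaged between a central vein
(CV) and a portal vein (PV): two interdigitated tubular networks (fine bile
canaliculi, coarser sinusoids), two large vein cylinders at opposite ends of
the field, space-filling polyhedral hepatocytes carrying 1-2 nuclei whose
DAPI integral scales with ploidy class, and sparse elongated stellate (HSC)
and Kupffer (KC) cells whose densities follow opposing gradients along the
CV-PV axis.  Rendering applies a Gaussian PSF and additive noise.

Everything is driven by a single seeded RNG, so identical parameters give
bit-identical images, and the generating skeletons/labels serve as oracles
for the reconstruction code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import networkx as nx
import pandas as pd
import yaml
from scipy import ndimage as ndi
from scipy.interpolate import splev, splprep
from scipy.spatial.transform import Rotation

from .core import (
    LabelMap,
    Lobule3DError,
    MultiChannelImage,
    VoxelGrid,
    binary_map,
    logger,
)

PLOIDY_MULTIPLIER = {"2n": 1.0, "4n": 2.0, "8n": 4.0, "16n": 8.0}


class InfeasibleGeometryError(Lobule3DError):
    """Requested object counts do not fit in the available space."""


class RadiusTooSmallError(Lobule3DError):
    """Tube radius below one voxel cannot be rasterized."""


# ---------------------------------------------------------------------------
# Parameters and ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class TubeNetworkParams:
    """Schema for one tubular network (random smoothed CV->PV paths)."""

    n_paths: int = 10
    n_branches: int = 4
    mean_radius_um: float = 1.35
    radius_jitter: float = 0.15  # relative sd of per-path radius
    wiggle: float = 0.18  # lateral jitter as a fraction of the field span


@dataclass
class LobuleParams:
    """Generator knobs.  Defaults describe the standard desk-scale lobule:

    a 128^3 field at 0.3 um voxels (38.4 um cube) holding ~90 hepatocytes,
    ~30 % of them binucleate, ploidy classes 2n/4n/8n at 60/30/10 %, a
    sinusoid network of ~1.35 um mean radius, a bile-canalicular network of
    ~0.6 um mean radius, and 16 HSCs / 16 KCs with U-shaped (peri-venous)
    and interior-hump (mid-zonal) density profiles respectively.
    """

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size_um: float = 0.3
    # large veins: cylinders along z at opposite x ends of the field
    cv_radius_um: float = 4.2
    pv_radius_um: float = 3.6
    cv_x_frac: float = 0.06
    pv_x_frac: float = 0.94
    sinusoids: TubeNetworkParams = field(
        default_factory=lambda: TubeNetworkParams(
            n_paths=18, n_branches=8, mean_radius_um=1.35, radius_jitter=0.15
        )
    )
    bc: TubeNetworkParams = field(
        default_factory=lambda: TubeNetworkParams(
            n_paths=26, n_branches=12, mean_radius_um=0.62, radius_jitter=0.12
        )
    )
    hepatocyte_count: int = 90
    mean_cell_volume_um3: float = 400.0
    binucleation_fraction: float = 0.30
    ploidy_fractions: dict[str, float] = field(
        default_factory=lambda: {"2n": 0.6, "4n": 0.3, "8n": 0.1}
    )
    nucleus_radius_um: float = 1.6
    dna_base: float = 1.0
    dna_jitter: float = 0.10  # lognormal sd of DNA content around class value
    hsc_count: int = 16
    hsc_length_um: float = 11.0
    hsc_radius_um: float = 0.9
    kc_count: int = 16
    kc_length_um: float = 9.0
    kc_radius_um: float = 1.05
    # density ~ c^a (1-c)^b along the CV->PV coordinate c in (0,1)
    hsc_gradient: tuple[float, float] = (-0.5, -0.5)
    kc_gradient: tuple[float, float] = (2.0, 2.0)
    npc_nucleus_radius_um: float = 1.1
    noise_sd: float = 0.04
    psf_sigma_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        fr = self.ploidy_fractions
        if abs(sum(fr.values()) - 1.0) > 1e-6:
            raise ValueError("ploidy fractions must sum to 1")
        if not (0.0 <= self.binucleation_fraction <= 1.0):
            raise ValueError("binucleation fraction must be in [0, 1]")
        for r in (
            self.cv_radius_um,
            self.pv_radius_um,
            self.nucleus_radius_um,
            self.hsc_radius_um,
            self.kc_radius_um,
        ):
            if not r > 0:
                raise ValueError("all radii must be positive")
        if min(self.hepatocyte_count, self.hsc_count, self.kc_count) < 0:
            raise ValueError("counts must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["hsc_gradient"] = list(self.hsc_gradient)
        d["kc_gradient"] = list(self.kc_gradient)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LobuleParams":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("shape", "hsc_gradient", "kc_gradient"):
            if k in d:
                d[k] = tuple(d[k])
        for k in ("sinusoids", "bc"):
            if k in d and isinstance(d[k], dict):
                d[k] = TubeNetworkParams(**d[k])
        return cls(**d)


@dataclass
class LobuleGroundTruth:
    """True labels, graphs and per-object tables backing a rendered lobule."""

    bc: LabelMap
    sinusoids: LabelMap
    cv: LabelMap
    pv: LabelMap
    nuclei: LabelMap
    hepatocytes: LabelMap
    hsc: LabelMap
    kc: LabelMap
    bc_graph: nx.Graph
    sinusoid_graph: nx.Graph
    nucleus_table: pd.DataFrame  # nucleus_id, cell_id, cell_type, ploidy_class, dna_content
    cell_table: pd.DataFrame  # cell_id, cell_type, n_nuclei
    params: LobuleParams

    def volume_fractions(self) -> dict[str, float]:
        """Fraction of the whole field occupied by each structure class.

        The classes partition the field, so the fractions sum to 1.
        """
        n = self.bc.labels.size
        out = {
            "cv": self.cv.mask.sum() / n,
            "pv": self.pv.mask.sum() / n,
            "sinusoids": self.sinusoids.mask.sum() / n,
            "bc": self.bc.mask.sum() / n,
            "hsc": self.hsc.mask.sum() / n,
            "kc": self.kc.mask.sum() / n,
            "hepatocytes": self.hepatocytes.mask.sum() / n,
        }
        out["unassigned"] = 1.0 - sum(out.values())
        return {k: float(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------


def _stamp_balls(
    mask: np.ndarray, centers: np.ndarray, radii: np.ndarray
) -> None:
    """Set ``mask`` voxels within ``radii[i]`` of ``centers[i]`` (in place).

    Inclusion is tested against the exact fractional center, so a dense
    chain of stamps rasterizes a capsule without lattice-rounding dilation.
    """
    shape = np.array(mask.shape)
    centers = np.asarray(centers, float)
    radii = np.asarray(radii, float)
    order = np.argsort(radii)
    centers, radii = centers[order], radii[order]
    i = 0
    while i < len(radii):
        j = i
        while j < len(radii) and abs(radii[j] - radii[i]) < 0.05:
            j += 1
        r = radii[i:j].max()
        n = int(np.ceil(r)) + 1
        ax = np.arange(-n, n + 1)
        dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
        offs = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1)
        for k0 in range(i, j, 256):  # chunk to bound memory
            cs = centers[k0 : min(k0 + 256, j)]
            base = np.floor(cs).astype(int)
            frac = cs - base
            d2 = np.sum(
                (offs[None, :, :] - frac[:, None, :]) ** 2, axis=2
            )
            keep = d2 <= radii[k0 : min(k0 + 256, j), None] ** 2
            pts = (base[:, None, :] + offs[None, :, :])[keep]
            ok = np.all((pts >= 0) & (pts < shape), axis=1)
            pts = pts[ok]
            mask[pts[:, 0], pts[:, 1], pts[:, 2]] = True
        i = j


def _smooth_path(
    points: np.ndarray, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Cubic-spline interpolate control points to a dense smooth path."""
    points = np.asarray(points, float)
    k = min(3, len(points) - 1)
    # splprep needs strictly increasing parameter; tiny jitter avoids
    # coincident control points
    tck, _ = splprep(points.T, s=0.0, k=k)
    u = np.linspace(0, 1, n_samples)
    return np.stack(splev(u, tck), axis=1)


def _vein_masks(params: LobuleParams) -> tuple[np.ndarray, np.ndarray]:
    nz, ny, nx = params.shape
    vs = params.voxel_size_um
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    cv_c = (ny / 2.0, params.cv_x_frac * nx)
    pv_c = (ny / 2.0, params.pv_x_frac * nx)
    cv2d = (yy - cv_c[0]) ** 2 + (xx - cv_c[1]) ** 2 <= (params.cv_radius_um / vs) ** 2
    pv2d = (yy - pv_c[0]) ** 2 + (xx - pv_c[1]) ** 2 <= (params.pv_radius_um / vs) ** 2
    cv = np.broadcast_to(cv2d, (nz, ny, nx)).copy()
    pv = np.broadcast_to(pv2d, (nz, ny, nx)).copy()
    return cv, pv


# ---------------------------------------------------------------------------
# Tube networks
# ---------------------------------------------------------------------------


def generate_tube_network(
    shape: tuple[int, int, int],
    voxel_size_um: float,
    net: TubeNetworkParams,
    rng: np.random.Generator,
    connected: bool = True,
) -> tuple[LabelMap, nx.Graph]:
    """Generate a random smoothed tube network crossing the field in x.

    Returns the rasterized binary mask (union of capsules around the graph
    edges) and the exact generating centerline graph.  Graph nodes carry
    ``pos_um`` (z, y, x) and ``radius_um``; edges carry ``length_um``.

    The first path spans the field; subsequent paths and branches start on
    the existing network, so with ``connected=True`` the result is a single
    connected component.
    """
    mean_r_vox = net.mean_radius_um / voxel_size_um
    if net.n_paths > 0 and mean_r_vox < 1.0:
        raise RadiusTooSmallError(
            f"mean radius {net.mean_radius_um} um is below one voxel"
        )
    nz, ny, nx_ = shape
    mask = np.zeros(shape, bool)
    graph = nx.Graph()
    if net.n_paths == 0:
        return binary_map(mask, voxel_size_um), graph

    span = np.array(shape, float)
    all_samples: list[np.ndarray] = []  # per-path dense samples (voxel coords)
    all_radii: list[np.ndarray] = []

    def _random_endpoint(x_frac: float) -> np.ndarray:
        return np.array(
            [
                rng.uniform(0.1, 0.9) * nz,
                rng.uniform(0.1, 0.9) * ny,
                x_frac * nx_,
            ]
        )

    def _add_path(start: np.ndarray, end: np.ndarray, radius_um: float) -> None:
        length = np.linalg.norm(end - start)
        n_ctrl = max(3, int(length / (0.25 * span.mean())) + 2)
        ts = np.linspace(0, 1, n_ctrl)[1:-1]
        ctrl = [start]
        for t in ts:
            p = start + t * (end - start)
            p = p + rng.normal(0, net.wiggle * span.mean(), 3)
            ctrl.append(np.clip(p, 1, span - 2))
        ctrl.append(end)
        n_samp = max(8, int(2.0 * length))
        path = _smooth_path(np.array(ctrl), n_samp, rng)
        path = np.clip(path, 0, span - 1)
        radii = np.full(len(path), radius_um / voxel_size_um)
        all_samples.append(path)
        all_radii.append(radii)
        # graph: chain of nodes at sample points
        base = graph.number_of_nodes()
        for i, p in enumerate(path):
            graph.add_node(
                base + i,
                pos_um=tuple(np.asarray(p) * voxel_size_um),
                radius_um=radius_um,
            )
            if i:
                graph.add_edge(
                    base + i - 1,
                    base + i,
                    length_um=float(
                        np.linalg.norm(path[i] - path[i - 1]) * voxel_size_um
                    ),
                )

    def _path_radius() -> float:
        r = net.mean_radius_um * float(
            np.clip(1.0 + net.radius_jitter * rng.standard_normal(), 0.4, 2.5)
        )
        return max(r, voxel_size_um)  # >= 1 voxel

    # main spanning path
    _add_path(_random_endpoint(0.03), _random_endpoint(0.97), _path_radius())
    for _ in range(net.n_paths - 1):
        if connected:
            src_path = all_samples[rng.integers(len(all_samples))]
            start = src_path[rng.integers(len(src_path))].copy()
        else:
            start = _random_endpoint(rng.uniform(0.05, 0.95))
        end = _random_endpoint(rng.choice([0.03, 0.97]))
        _add_path(start, end, _path_radius())
    for _ in range(net.n_branches):
        src_path = all_samples[rng.integers(len(all_samples))]
        start = src_path[rng.integers(len(src_path))].copy()
        end = np.clip(
            start + rng.normal(0, 0.35, 3) * span, 1, span - 2
        )
        _add_path(start, end, _path_radius())

    # connect chained paths in the graph: weld each path start onto the
    # nearest node of previously added paths (they share coordinates)
    if connected and len(all_samples) > 1:
        offsets = np.cumsum([0] + [len(s) for s in all_samples[:-1]])
        coords = np.concatenate(all_samples)
        for pi in range(1, len(all_samples)):
            start_idx = offsets[pi]
            prev = coords[: offsets[pi]]
            d = np.linalg.norm(prev - coords[start_idx], axis=1)
            j = int(np.argmin(d))
            if d[j] < 1.5:  # welded start point
                graph.add_edge(
                    j, start_idx, length_um=float(d[j] * voxel_size_um)
                )

    centers = np.concatenate(all_samples)
    radii = np.concatenate(all_radii)
    _stamp_balls(mask, centers, radii)
    return binary_map(mask, voxel_size_um), graph


# ---------------------------------------------------------------------------
# Cells, nuclei, non-parenchymal cells
# ---------------------------------------------------------------------------


def _cvpv_coordinate_voxels(cv: np.ndarray, pv: np.ndarray) -> np.ndarray:
    d_cv = ndi.distance_transform_edt(~cv)
    d_pv = ndi.distance_transform_edt(~pv)
    s = d_cv + d_pv
    s[s == 0] = 1.0
    return np.clip(d_cv / s, 0.0, 1.0)


def _rasterize_capsule_cell(
    shape: tuple[int, int, int],
    center: np.ndarray,
    length_vox: float,
    radius_vox: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Dense sample points of a thin curved capsule (elongated cell body)."""
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction)
    half = length_vox / 2.0
    ctrl = np.stack(
        [
            center - half * direction,
            center + rng.normal(0, 0.25 * half, 3),
            center + half * direction,
        ]
    )
    ctrl = np.clip(ctrl, 1, np.array(shape, float) - 2)
    n = max(8, int(2 * length_vox))
    # the cubic spline can overshoot its control points; keep samples in-field
    return np.clip(_smooth_path(ctrl, n, rng), 0, np.array(shape, float) - 1)


def _place_npc(
    params: LobuleParams,
    kind: str,
    count: int,
    length_um: float,
    radius_um: float,
    gradient: tuple[float, float],
    free: np.ndarray,
    coord: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Place elongated cells with density ~ c^a (1-c)^b along the CV-PV axis.

    Returns the instance label volume and per-cell nucleus center (voxel).
    """
    vs = params.voxel_size_um
    labels = np.zeros(params.shape, np.int32)
    nucleus_centers: list[np.ndarray] = []
    if count == 0:
        return labels, nucleus_centers
    a, b = gradient
    free_idx = np.flatnonzero(free)
    if len(free_idx) < count * 50:
        raise InfeasibleGeometryError(f"not enough free space for {count} {kind}s")
    c = np.clip(coord.ravel()[free_idx], 0.02, 0.98)
    w = c**a * (1 - c) ** b
    w = w / w.sum()
    # keep cells separated so neighbours stay resolvable after PSF blur
    gap_vox = 4.0
    blocker = np.zeros(params.shape, bool)
    placed = 0
    attempts = 0
    while placed < count:
        attempts += 1
        if attempts > 40 * count:
            raise InfeasibleGeometryError(
                f"could not place {count} {kind}s after {attempts} attempts"
            )
        center = np.array(
            np.unravel_index(rng.choice(free_idx, p=w), params.shape), float
        )
        path = _rasterize_capsule_cell(
            params.shape, center, length_um / vs, radius_um / vs, rng
        )
        body = np.zeros(params.shape, bool)
        _stamp_balls(body, path, np.full(len(path), radius_um / vs))
        # nucleus bulge at a random point along the body
        ncen = path[rng.integers(len(path) // 4, 3 * len(path) // 4)]
        nucleus = np.zeros(params.shape, bool)
        _stamp_balls(
            nucleus,
            ncen[None],
            np.array([params.npc_nucleus_radius_um / vs]),
        )
        body |= nucleus
        body &= free & (labels == 0)
        # keep only the component containing the nucleus center
        lab, _ = ndi.label(body)
        seed_lab = lab[tuple(np.rint(ncen).astype(int))]
        if seed_lab == 0:
            continue
        body = lab == seed_lab
        if body.sum() < 0.4 * (length_um / vs) * np.pi * (radius_um / vs) ** 2:
            continue  # mostly swallowed by occupied space; retry
        if (body & blocker).any():
            continue  # too close to an already placed cell
        placed += 1
        labels[body] = placed
        nucleus_centers.append(ncen)
        _stamp_balls(
            blocker, path, np.full(len(path), radius_um / vs + gap_vox)
        )
        _stamp_balls(
            blocker, ncen[None],
            np.array([params.npc_nucleus_radius_um / vs + gap_vox]),
        )
    return labels, nucleus_centers


def _ellipsoid_mask_local(
    semi_axes_vox: np.ndarray, rot: np.ndarray
) -> np.ndarray:
    """Offsets inside a rotated ellipsoid centred at the origin."""
    r = int(np.ceil(semi_axes_vox.max()))
    ax = np.arange(-r, r + 1)
    dz, dy, dx = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([dz.ravel(), dy.ravel(), dx.ravel()], axis=1).astype(float)
    local = pts @ rot  # rotate into ellipsoid frame
    inside = np.sum((local / semi_axes_vox) ** 2, axis=1) <= 1.0
    return pts[inside].astype(int)


def generate_cells_and_nuclei(
    params: LobuleParams,
    occupied: LabelMap,
    cv: LabelMap,
    pv: LabelMap,
    rng: np.random.Generator,
) -> dict:
    """Fill unoccupied space with hepatocytes, nuclei and HSC/KC cells.

    ``occupied`` is the union of veins and both tube networks.  Hepatocytes
    are grown simultaneously from Poisson-disc-like seeds (nearest-seed
    geodesic flooding), each receives 1 or 2 ellipsoidal nuclei according to
    the binucleation fraction, and every nucleus gets a ploidy class and a
    DNA content (class multiplier x base, lognormal jitter).
    """
    from skimage.segmentation import watershed

    vs = params.voxel_size_um
    shape = params.shape
    occ = occupied.mask
    free = ~occ
    if free.mean() < 0.5:
        raise InfeasibleGeometryError(
            f"occupied mask leaves only {free.mean():.0%} of the field free"
        )
    coord = _cvpv_coordinate_voxels(cv.mask, pv.mask)

    # --- non-parenchymal cells first (they exclude hepatocyte space)
    hsc_labels, hsc_ncen = _place_npc(
        params, "hsc", params.hsc_count, params.hsc_length_um,
        params.hsc_radius_um, params.hsc_gradient, free, coord, rng,
    )
    free &= hsc_labels == 0
    kc_labels, kc_ncen = _place_npc(
        params, "kc", params.kc_count, params.kc_length_um,
        params.kc_radius_um, params.kc_gradient, free, coord, rng,
    )
    free &= kc_labels == 0

    # --- hepatocyte seeds: dart throwing with a minimum-distance constraint
    n_cells = params.hepatocyte_count
    hep_labels = np.zeros(shape, np.int32)
    seeds: list[np.ndarray] = []
    if n_cells > 0:
        free_idx = np.flatnonzero(free)
        if len(free_idx) < n_cells * 20:
            raise InfeasibleGeometryError(
                f"not enough free space for {n_cells} hepatocytes"
            )
        target_spacing = 0.9 * (free.sum() / n_cells) ** (1 / 3)
        spacing = target_spacing
        while True:
            seeds = []
            order = rng.permutation(len(free_idx))
            for idx in order:
                p = np.array(np.unravel_index(free_idx[idx], shape), float)
                if all(np.linalg.norm(p - q) >= spacing for q in seeds):
                    seeds.append(p)
                    if len(seeds) == n_cells:
                        break
            if len(seeds) == n_cells:
                break
            spacing *= 0.85
            if spacing < 2.0:
                raise InfeasibleGeometryError(
                    f"cannot seed {n_cells} hepatocytes in the free space"
                )
        markers = np.zeros(shape, np.int32)
        for i, p in enumerate(seeds, start=1):
            markers[tuple(np.rint(p).astype(int))] = i
        dist_to_seed = ndi.distance_transform_edt(markers == 0)
        hep_labels = watershed(dist_to_seed, markers, mask=free).astype(np.int32)

    # --- nuclei inside hepatocytes
    nuclei = np.zeros(shape, np.int32)
    nuc_rows = []
    cell_rows = []
    classes = list(params.ploidy_fractions)
    probs = np.array([params.ploidy_fractions[c] for c in classes])
    r_n = params.nucleus_radius_um / vs
    objects = ndi.find_objects(hep_labels)
    nid = 0
    for cid in range(1, n_cells + 1):
        sl = objects[cid - 1]
        if sl is None:
            cell_rows.append((cid, "hepatocyte", 0))
            continue
        cell = hep_labels[sl] == cid
        interior = ndi.distance_transform_edt(cell)
        binuc = rng.random() < params.binucleation_fraction
        wanted = 2 if binuc else 1
        cls = classes[int(rng.choice(len(classes), p=probs))]
        centers = _nucleus_centers(cell, interior, r_n, wanted, rng)
        for ncen_local in centers:
            nid += 1
            ncen = ncen_local + np.array([s.start for s in sl])
            _carve_nucleus(
                nuclei, nid, ncen, r_n, rng,
                within=(hep_labels == cid),
            )
            content = (
                PLOIDY_MULTIPLIER[cls]
                * params.dna_base
                * float(rng.lognormal(0.0, params.dna_jitter))
            )
            nuc_rows.append((nid, cid, "hepatocyte", cls, content))
        cell_rows.append((cid, "hepatocyte", len(centers)))

    # --- HSC/KC nuclei (small, 2n)
    for kind, labs, ncens in (
        ("hsc", hsc_labels, hsc_ncen),
        ("kc", kc_labels, kc_ncen),
    ):
        for i, ncen in enumerate(ncens, start=1):
            nid += 1
            _carve_nucleus(
                nuclei, nid, ncen, params.npc_nucleus_radius_um / vs, rng,
                within=(labs == i),
            )
            content = params.dna_base * float(
                rng.lognormal(0.0, params.dna_jitter)
            )
            nuc_rows.append((nid, i, kind, "2n", content))
            cell_rows.append((i, kind, 1))

    nucleus_table = pd.DataFrame(
        nuc_rows,
        columns=["nucleus_id", "cell_id", "cell_type", "ploidy_class", "dna_content"],
    )
    cell_table = pd.DataFrame(cell_rows, columns=["cell_id", "cell_type", "n_nuclei"])
    return {
        "hepatocytes": LabelMap(hep_labels, vs, "instance"),
        "hsc": LabelMap(hsc_labels, vs, "instance"),
        "kc": LabelMap(kc_labels, vs, "instance"),
        "nuclei": LabelMap(nuclei, vs, "instance"),
        "nucleus_table": nucleus_table,
        "cell_table": cell_table,
    }


def _nucleus_centers(
    cell: np.ndarray,
    interior: np.ndarray,
    r_n: float,
    wanted: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Pick 1 or 2 well-separated nucleus centers deep inside a cell."""
    deep = np.argwhere(interior >= max(r_n * 0.9, 1.5))
    if len(deep) == 0:
        deep = np.argwhere(interior == interior.max())
    if wanted == 1:
        return [deep[rng.integers(len(deep))].astype(float)]
    # binucleate: retry first positions and relax the separation before
    # falling back to a single nucleus
    for sep in (2.4, 2.2, 2.0):
        for _ in range(8):
            first = deep[rng.integers(len(deep))].astype(float)
            d = np.linalg.norm(deep - first, axis=1)
            ok = d >= sep * r_n
            if ok.any():
                cand = deep[ok]
                second = cand[rng.integers(len(cand))].astype(float)
                return [first, second]
    return [deep[rng.integers(len(deep))].astype(float)]


def _carve_nucleus(
    nuclei: np.ndarray,
    nid: int,
    center_vox: np.ndarray,
    r_n: float,
    rng: np.random.Generator,
    within: np.ndarray,
) -> None:
    """Rasterize a randomly oriented ellipsoidal nucleus clipped to its cell."""
    semi = r_n * np.array([1.15, 1.0, 0.87])
    rot = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    offs = _ellipsoid_mask_local(semi, rot)
    pts = np.rint(center_vox).astype(int)[None] + offs
    shape = np.array(nuclei.shape)
    ok = np.all((pts >= 0) & (pts < shape), axis=1)
    pts = pts[ok]
    inside = within[pts[:, 0], pts[:, 1], pts[:, 2]] & (
        nuclei[pts[:, 0], pts[:, 1], pts[:, 2]] == 0
    )
    pts = pts[inside]
    nuclei[pts[:, 0], pts[:, 1], pts[:, 2]] = nid


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# rendered intensity levels; BC is the brightest phalloidin structure so the
# virtual-staining task is well-posed from intensity plus shape context
_I_CELL_BORDER = 0.55
_I_SIN_WALL = 0.78
_I_BC = 1.0
_I_MASK = 1.0


def render_channels(gt: LobuleGroundTruth, params: LobuleParams) -> MultiChannelImage:
    """Render the six-marker panel from ground truth.

    dapi: per-nucleus uniform intensity whose integral equals the true DNA
    content; phalloidin: hepatocyte boundary shells + sinusoid walls + the
    BC mask; cd13/flk1/desmin/f480: the respective structure masks.  All
    stained channels are blurred with the PSF sigma and corrupted with
    additive Gaussian noise; the vein masks pass through clean.
    """
    from skimage.segmentation import find_boundaries

    vs = params.voxel_size_um
    rng = np.random.default_rng(params.seed + 101)

    dapi = np.zeros(params.shape, np.float32)
    labs = gt.nuclei.labels
    if len(gt.nucleus_table):
        counts = np.bincount(labs.ravel(), minlength=int(labs.max()) + 1)
        # scale so a typical diploid nucleus renders near unit intensity;
        # the per-nucleus integral stays proportional to true DNA content
        v_ref = (4.0 / 3.0) * np.pi * (params.nucleus_radius_um / vs) ** 3
        scale = v_ref / params.dna_base
        lut = np.zeros(int(labs.max()) + 1, np.float32)
        for _, row in gt.nucleus_table.iterrows():
            n = counts[int(row.nucleus_id)]
            if n:
                lut[int(row.nucleus_id)] = scale * row.dna_content / n
        dapi = lut[labs]

    phalloidin = np.zeros(params.shape, np.float32)
    cell_borders = find_boundaries(gt.hepatocytes.labels, mode="thick")
    phalloidin = np.maximum(phalloidin, _I_CELL_BORDER * cell_borders)
    sin_wall = find_boundaries(gt.sinusoids.labels, mode="outer")
    phalloidin = np.maximum(phalloidin, _I_SIN_WALL * sin_wall)
    phalloidin = np.maximum(phalloidin, _I_BC * gt.bc.mask)

    channels = {
        "dapi": dapi,
        "phalloidin": phalloidin,
        "cd13": _I_MASK * gt.bc.mask.astype(np.float32),
        "flk1": _I_MASK * gt.sinusoids.mask.astype(np.float32),
        "desmin": _I_MASK * (gt.hsc.labels > 0).astype(np.float32),
        "f480": _I_MASK * (gt.kc.labels > 0).astype(np.float32),
    }
    sigma_vox = params.psf_sigma_um / vs
    out = {}
    for name, data in channels.items():
        if sigma_vox > 0:
            data = ndi.gaussian_filter(data, sigma_vox)
        if params.noise_sd > 0:
            data = data + rng.normal(0, params.noise_sd, data.shape).astype(
                np.float32
            )
        out[name] = VoxelGrid(data.astype(np.float32), vs)
    out["cv_mask"] = VoxelGrid(gt.cv.labels.astype(np.float32), vs)
    out["pv_mask"] = VoxelGrid(gt.pv.labels.astype(np.float32), vs)
    return MultiChannelImage(out)


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------


def generate_lobule(
    params: LobuleParams | None = None,
) -> tuple[MultiChannelImage, LobuleGroundTruth]:
    """Generate a complete synthetic lobule image plus ground truth."""
    params = params or LobuleParams()
    rng = np.random.default_rng(params.seed)
    vs = params.voxel_size_um

    cv_m, pv_m = _vein_masks(params)
    veins = cv_m | pv_m

    sin_mask, sin_graph = generate_tube_network(
        params.shape, vs, params.sinusoids, rng
    )
    sin = sin_mask.mask & ~veins
    bc_mask, bc_graph = generate_tube_network(params.shape, vs, params.bc, rng)
    bc = bc_mask.mask & ~veins & ~sin

    occupied = binary_map(veins | sin | bc, vs)
    cv_lm = binary_map(cv_m, vs)
    pv_lm = binary_map(pv_m, vs)
    cells = generate_cells_and_nuclei(params, occupied, cv_lm, pv_lm, rng)

    gt = LobuleGroundTruth(
        bc=binary_map(bc, vs),
        sinusoids=binary_map(sin, vs),
        cv=cv_lm,
        pv=pv_lm,
        nuclei=cells["nuclei"],
        hepatocytes=cells["hepatocytes"],
        hsc=cells["hsc"],
        kc=cells["kc"],
        bc_graph=bc_graph,
        sinusoid_graph=sin_graph,
        nucleus_table=cells["nucleus_table"],
        cell_table=cells["cell_table"],
        params=params,
    )
    image = render_channels(gt, params)
    logger.info(
        "generated lobule %s: %d hepatocytes, %d nuclei, %d HSC, %d KC",
        params.shape,
        gt.hepatocytes.n_labels,
        gt.nuclei.n_labels,
        gt.hsc.n_labels,
        gt.kc.n_labels,
    )
    return image, gt
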