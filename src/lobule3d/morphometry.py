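"""Per-object and cross-object quantification.

Volumes, principal-axis elongation, DNA content and ploidy from DAPI,
nuclearity classes (e.g. ``2x2n``), structure volume fractions (excluding
the large veins), hepatocyte contact-surface percentages, KC-HSC contact
site counts, and inter-nuclear surface distances.  Results assemble into an
atlas table of per-cell and per-nucleus records with mean +/- s.e.m.
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .core import LabelMap, Lobule3DError, VoxelGrid, logger

PLOIDY_CLASSES = ("2n", "4n", "8n", "16n")
PLOIDY_MULTIPLIER = {"2n": 1.0, "4n": 2.0, "8n": 4.0, "16n": 8.0}


class EmptyTissueError(Lobule3DError):
    """Volume fraction undefined over an empty tissue mask."""


class OrphanNucleusError(Lobule3DError):
    """A nucleus overlaps no cell label."""


class NonPositiveContentError(Lobule3DError):
    """DNA contents must be positive for ploidy classification."""


# ---------------------------------------------------------------------------
# Shape descriptors
# ---------------------------------------------------------------------------


def shape_descriptors(
    labels: LabelMap, elongation_formula: str = "one_minus_min_over_max"
) -> pd.DataFrame:
    """Volume, centroid and principal-axis lengths per labelled object.

    Axis lengths are derived from the eigenvalues of the voxel covariance
    matrix, scaled to full ellipsoid axes (a solid ellipsoid with semi-axis
    ``a`` has second moment ``a^2/5``).  Elongation is ``1 - A3/A1`` with
    ``A1 >= A2 >= A3`` (sphere -> 0, filament -> 1); the variant
    ``as_printed`` emits ``1 - A1/A3`` for auditability.  Single-voxel
    objects get elongation 0 by convention.
    """
    arr = labels.labels
    vs = labels.voxel_size_um
    rows = []
    for sl, lab in zip(ndi.find_objects(arr), range(1, int(arr.max()) + 1)):
        if sl is None:
            continue
        coords = np.argwhere(arr[sl] == lab).astype(float)
        coords += np.array([s.start for s in sl], float)
        n = len(coords)
        centroid = coords.mean(axis=0)
        if n < 2:
            a1 = a2 = a3 = vs
            elong = 0.0
            logger.debug("label %d is a single voxel; elongation set to 0", lab)
        else:
            cov = np.cov(coords.T, bias=True) + np.eye(3) / 12.0
            evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
            evals = np.clip(evals, 1e-12, None)
            a1, a2, a3 = (2.0 * np.sqrt(5.0 * evals)) * vs
            if elongation_formula == "as_printed":
                elong = 1.0 - a1 / a3
            else:
                elong = 1.0 - a3 / a1
        rows.append(
            {
                "label": lab,
                "volume_um3": n * vs**3,
                "centroid_z_um": centroid[0] * vs,
                "centroid_y_um": centroid[1] * vs,
                "centroid_x_um": centroid[2] * vs,
                "A1_um": a1,
                "A2_um": a2,
                "A3_um": a3,
                "elongation": elong,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "volume_um3", "centroid_z_um", "centroid_y_um",
            "centroid_x_um", "A1_um", "A2_um", "A3_um", "elongation",
        ],
    )


# ---------------------------------------------------------------------------
# DNA content and ploidy
# ---------------------------------------------------------------------------


def dna_content(
    nuclei: LabelMap, dapi: VoxelGrid, background_correction: bool = True
) -> pd.DataFrame:
    """Integral DAPI intensity per nucleus (raw and background-corrected).

    The corrected value subtracts the median outside-nuclei intensity times
    the nucleus voxel count (floored at 0); both values are reported.
    """
    if nuclei.shape != dapi.shape:
        raise ValueError("nuclei and DAPI image must share shape")
    arr = nuclei.labels
    data = np.asarray(dapi.data, np.float64)
    labs = np.arange(1, int(arr.max()) + 1)
    if len(labs) == 0:
        return pd.DataFrame(columns=["label", "dna_raw", "dna_corrected"])
    raw = ndi.sum_labels(data, arr, labs)
    counts = ndi.sum_labels(np.ones_like(data), arr, labs)
    if background_correction:
        outside = data[arr == 0]
        bg = float(np.median(outside)) if outside.size else 0.0
    else:
        bg = 0.0
    corrected = np.maximum(raw - bg * counts, 0.0)
    return pd.DataFrame({"label": labs, "dna_raw": raw, "dna_corrected": corrected})


def classify_ploidy(
    contents: np.ndarray, reference_2n: float | str = "auto"
) -> tuple[np.ndarray, dict[str, float], float]:
    """Assign 2n/4n/8n/16n classes from DNA contents.

    With a numeric reference, ``class = 2n * 2^round(log2(c / ref))``
    clamped to the four classes.  With ``"auto"``, the diploid reference is
    fitted by a 1D k-means whose centers are constrained to the geometric
    ratios 1:2:4:8, initialised from the first quartile of the contents.

    Returns (classes, class fractions, fitted reference).
    """
    contents = np.asarray(contents, float)
    if contents.size == 0:
        raise NonPositiveContentError("no nuclei to classify")
    if np.any(contents <= 0):
        raise NonPositiveContentError("DNA contents must be positive")
    if reference_2n == "auto":
        ref = _fit_reference(contents)
    else:
        ref = float(reference_2n)
    k = np.clip(np.round(np.log2(contents / ref)), 0, 3).astype(int)
    classes = np.array(PLOIDY_CLASSES)[k]
    fractions = {
        c: float(np.mean(classes == c)) for c in PLOIDY_CLASSES
    }
    return classes, fractions, ref


def _fit_reference(contents: np.ndarray, n_iter: int = 100) -> float:
    """Constrained 1D k-means: centers fixed at (m, 2m, 4m, 8m), fit m.

    The alternating fit has local optima when the diploid class is not
    dominant, so several quantile-anchored starts (including halved and
    quartered guesses) are fitted and the lowest within-cluster cost wins.
    The geometric grid is degenerate under halving (centers at m/2 fit the
    same data with an empty bottom class), so fits whose diploid class
    holds fewer than 2 % of the nuclei are rejected: the reference is by
    definition the lowest *occupied* major peak.
    """
    mult = np.array([1.0, 2.0, 4.0, 8.0])
    q5, q25, q50 = np.percentile(contents, [5, 25, 50])
    starts = {q5, q25, q25 / 2, q50 / 2, q50 / 4, float(contents.min())}

    def _iterate(m: float) -> tuple[float, float, float]:
        assign = None
        for _ in range(n_iter):
            assign = np.argmin(
                np.abs(contents[:, None] - m * mult[None, :]), axis=1
            )
            k = mult[assign]
            m_new = float(np.sum(contents * k) / np.sum(k * k))
            if abs(m_new - m) < 1e-12 * max(m, 1.0):
                m = m_new
                break
            m = m_new
        cost = float(
            np.sum(np.min((contents[:, None] - m * mult[None, :]) ** 2, axis=1))
        )
        bottom = float(np.mean(assign == 0))
        return m, cost, bottom

    fits = [_iterate(m0) for m0 in starts if m0 > 0]
    occupied = [f for f in fits if f[2] >= 0.02]
    pool = occupied or fits
    return min(pool, key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# Nuclearity
# ---------------------------------------------------------------------------


def assign_nuclei_to_cells(cells: LabelMap, nuclei: LabelMap) -> dict[int, int]:
    """Nucleus -> cell by maximal voxel overlap (ties to the lower cell id)."""
    narr, carr = nuclei.labels, cells.labels
    sel = narr > 0
    pairs = np.stack([narr[sel].astype(np.int64), carr[sel].astype(np.int64)])
    key = pairs[0] * (carr.max() + 1) + pairs[1]
    uniq, counts = np.unique(key, return_counts=True)
    nuc_ids = uniq // (carr.max() + 1)
    cell_ids = uniq % (carr.max() + 1)
    owner: dict[int, int] = {}
    best: dict[int, tuple[int, int]] = {}
    for nid, cid, cnt in zip(nuc_ids, cell_ids, counts):
        if cid == 0:
            continue
        cur = best.get(int(nid))
        # more overlap wins; ties to lower cell id
        if cur is None or cnt > cur[0] or (cnt == cur[0] and cid < cur[1]):
            best[int(nid)] = (int(cnt), int(cid))
    for nid in np.unique(narr[narr > 0]):
        if int(nid) not in best:
            raise OrphanNucleusError(f"nucleus {nid} overlaps no cell")
        owner[int(nid)] = best[int(nid)][1]
    return owner


def assign_nuclearity(
    cells: LabelMap, nuclei: LabelMap, ploidy: dict[int, str]
) -> pd.DataFrame:
    """Per-cell nuclearity class string ``k x pn`` (e.g. ``2x2n``).

    Mixed-ploidy multinucleate cells are labelled by their maximal nucleus
    class with ``mixed=True``.
    """
    owner = assign_nuclei_to_cells(cells, nuclei)
    per_cell: dict[int, list[str]] = {}
    for nid, cid in owner.items():
        per_cell.setdefault(cid, []).append(ploidy[nid])
    rows = []
    for cid in range(1, int(cells.labels.max()) + 1):
        classes = per_cell.get(cid, [])
        if not classes:
            rows.append({"cell_id": cid, "n_nuclei": 0, "nuclearity": "0x-",
                         "mixed": False})
            continue
        top = max(classes, key=lambda c: PLOIDY_MULTIPLIER[c])
        mixed = len(set(classes)) > 1
        rows.append(
            {
                "cell_id": cid,
                "n_nuclei": len(classes),
                "nuclearity": f"{len(classes)}x{top}",
                "mixed": mixed,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Volume fractions
# ---------------------------------------------------------------------------


def volume_fraction(structure: LabelMap, tissue: LabelMap) -> float:
    """|structure intersect tissue| / |tissue|.

    ``tissue`` is the field minus the large veins (CV, PV).
    """
    t = tissue.mask
    if not t.any():
        raise EmptyTissueError("tissue mask is empty")
    return float(np.logical_and(structure.mask, t).sum() / t.sum())


# ---------------------------------------------------------------------------
# Contact analysis
# ---------------------------------------------------------------------------


def _surface_voxels(cells: np.ndarray) -> np.ndarray:
    """Boolean mask of 6-connected boundary voxels of every labelled object."""
    surf = np.zeros(cells.shape, bool)
    for axis in range(3):
        lo = np.take(cells, np.arange(cells.shape[axis] - 1), axis=axis)
        hi = np.take(cells, np.arange(1, cells.shape[axis]), axis=axis)
        diff = lo != hi
        idx_lo = [slice(None)] * 3
        idx_lo[axis] = slice(0, cells.shape[axis] - 1)
        idx_hi = [slice(None)] * 3
        idx_hi[axis] = slice(1, cells.shape[axis])
        surf[tuple(idx_lo)] |= diff & (lo > 0)
        surf[tuple(idx_hi)] |= diff & (hi > 0)
    # border of the field counts as surface too
    for axis in range(3):
        for edge in (0, -1):
            idx = [slice(None)] * 3
            idx[axis] = edge
            surf[tuple(idx)] |= np.take(cells, edge, axis=axis) > 0
    return surf


def contact_surface_fractions(
    cells: LabelMap,
    structures: dict[str, LabelMap],
    contact_radius_um: float = 0.3,
    include_other_cells: bool = True,
) -> pd.DataFrame:
    """Percent of each cell's surface in contact with each structure.

    A cell's surface voxels are its 6-connected boundary shell; a surface
    voxel is in contact with a structure if any structure voxel lies within
    ``contact_radius_um``.  Percentages for different structures are
    independent (a voxel may touch several structures).  When
    ``include_other_cells`` is set, contact with any *different* cell label
    is reported under ``"other_cells"``.
    """
    arr = cells.labels
    vs = cells.voxel_size_um
    surf = _surface_voxels(arr)
    surf_idx = np.argwhere(surf)
    surf_labels = arr[surf]
    n_max = int(arr.max())
    totals = np.bincount(surf_labels, minlength=n_max + 1).astype(float)

    result: dict[str, np.ndarray] = {}
    for name, st in structures.items():
        if not st.mask.any():
            result[name] = np.zeros(n_max + 1)
            continue
        dist = ndi.distance_transform_edt(~st.mask) * vs
        hit = dist[tuple(surf_idx.T)] <= contact_radius_um + 1e-9
        result[name] = np.bincount(
            surf_labels[hit], minlength=n_max + 1
        ).astype(float)

    if include_other_cells:
        r_vox = max(1, int(round(contact_radius_um / vs)))
        other = np.zeros(len(surf_idx), bool)
        shape = np.array(arr.shape)
        offs = [
            (dz, dy, dx)
            for dz in range(-r_vox, r_vox + 1)
            for dy in range(-r_vox, r_vox + 1)
            for dx in range(-r_vox, r_vox + 1)
            if (dz, dy, dx) != (0, 0, 0)
            and np.sqrt(dz**2 + dy**2 + dx**2) <= r_vox + 1e-9
        ]
        for off in offs:
            nb = surf_idx + np.array(off)
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            vals = np.zeros(len(surf_idx), arr.dtype)
            vals[ok] = arr[tuple(nb[ok].T)]
            other |= (vals > 0) & (vals != surf_labels)
        result["other_cells"] = np.bincount(
            surf_labels[other], minlength=n_max + 1
        ).astype(float)

    rows = []
    for lab in range(1, n_max + 1):
        if totals[lab] == 0:
            continue
        row = {"cell_id": lab, "surface_voxels": int(totals[lab])}
        for name, cnt in result.items():
            row[f"contact_pct_{name}"] = 100.0 * cnt[lab] / totals[lab]
        rows.append(row)
    return pd.DataFrame(rows)


def count_contact_sites(
    a: LabelMap, b: LabelMap, contact_radius_um: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Contact sites between objects of ``a`` and objects of ``b``.

    The contact region of pair ``(a_i, b_j)`` is the set of ``a_i`` voxels
    within ``contact_radius_um`` of ``b_j``; its 26-connected components are
    the sites.  Returns (per-pair counts, per-a-object totals, mean sites
    per a-object).
    """
    vs = a.voxel_size_um
    arr_a, arr_b = a.labels, b.labels
    r_vox = contact_radius_um / vs
    pad = int(np.ceil(r_vox)) + 1
    slices_a = ndi.find_objects(arr_a)
    slices_b = ndi.find_objects(arr_b)
    struct = np.ones((3, 3, 3), int)
    pair_rows = []
    per_a: dict[int, int] = {i + 1: 0 for i, sl in enumerate(slices_a) if sl is not None}
    for ia, sa in enumerate(slices_a):
        if sa is None:
            continue
        for ib, sb in enumerate(slices_b):
            if sb is None:
                continue
            if not _bboxes_close(sa, sb, pad):
                continue
            sl = tuple(
                slice(
                    max(0, min(x.start, y.start) - pad),
                    min(n, max(x.stop, y.stop) + pad),
                )
                for x, y, n in zip(sa, sb, arr_a.shape)
            )
            mask_a = arr_a[sl] == ia + 1
            mask_b = arr_b[sl] == ib + 1
            if not mask_b.any():
                continue
            dist = ndi.distance_transform_edt(~mask_b) * vs
            region = mask_a & (dist <= contact_radius_um + 1e-9)
            if not region.any():
                continue
            _, n_sites = ndi.label(region, structure=struct)
            if n_sites:
                pair_rows.append(
                    {"a_id": ia + 1, "b_id": ib + 1, "n_sites": int(n_sites)}
                )
                per_a[ia + 1] += int(n_sites)
    pairs = pd.DataFrame(pair_rows, columns=["a_id", "b_id", "n_sites"])
    totals = pd.DataFrame(
        [{"a_id": k, "total_sites": v} for k, v in sorted(per_a.items())]
    )
    mean_sites = float(totals["total_sites"].mean()) if len(totals) else 0.0
    return pairs, totals, mean_sites


def _bboxes_close(sa: tuple, sb: tuple, pad: int) -> bool:
    return all(
        x.start - pad < y.stop and y.start - pad < x.stop for x, y in zip(sa, sb)
    )


# ---------------------------------------------------------------------------
# Inter-nuclear distances
# ---------------------------------------------------------------------------


def internuclear_distances(
    nuclei: LabelMap,
    types: dict[int, str],
    proximity_threshold_um: float = 2.0,
    n_candidates: int = 4,
) -> pd.DataFrame:
    """Nearest-neighbor surface-to-surface distances between nucleus types.

    For each nucleus of type X the distance to the nearest nucleus of type
    Y is the minimal voxel-to-voxel gap (touching nuclei -> 0).  Candidate
    neighbors are pre-selected by centroid distance, then measured exactly
    on their surface voxels.  Returns one row per (X nucleus, Y type) with
    the distance; the proximity fraction below ``proximity_threshold_um``
    can be aggregated from it (see :func:`proximity_fraction`).
    """
    arr = nuclei.labels
    vs = nuclei.voxel_size_um
    ids = [int(i) for i in np.unique(arr[arr > 0])]
    if len(ids) < 2:
        raise Lobule3DError("need at least two nuclei")
    centroids = ndi.center_of_mass(arr > 0, arr, ids)
    centroids = {i: np.array(c) for i, c in zip(ids, centroids)}
    surf = _surface_voxels(arr)
    coords_by_id = {}
    surf_idx = np.argwhere(surf)
    surf_lab = arr[surf]
    for i in ids:
        coords_by_id[i] = surf_idx[surf_lab == i]
    type_sets: dict[str, list[int]] = {}
    for i in ids:
        t = types.get(i)
        if t is not None:
            type_sets.setdefault(t, []).append(i)
    rows = []
    for tx, xs in type_sets.items():
        for ty, ys in type_sets.items():
            for i in xs:
                cand = [j for j in ys if j != i]
                if not cand:
                    logger.warning("type pair (%s,%s): no partner for %d", tx, ty, i)
                    continue
                cd = sorted(
                    cand, key=lambda j: np.linalg.norm(centroids[i] - centroids[j])
                )[:n_candidates]
                best = np.inf
                for j in cd:
                    tree = cKDTree(coords_by_id[j])
                    d, _ = tree.query(coords_by_id[i], k=1)
                    best = min(best, float(d.min()))
                gap = max(best - 1.0, 0.0) * vs  # adjacent voxels touch
                rows.append(
                    {
                        "nucleus_id": i,
                        "type": tx,
                        "partner_type": ty,
                        "distance_um": gap,
                        "below_threshold": gap < proximity_threshold_um,
                    }
                )
    return pd.DataFrame(rows)


def proximity_fraction(
    distances: pd.DataFrame, type_x: str, type_y: str
) -> float:
    """Share of X nuclei whose nearest Y nucleus is below the threshold."""
    sel = distances[
        (distances["type"] == type_x) & (distances["partner_type"] == type_y)
    ]
    if len(sel) == 0:
        return float("nan")
    return float(sel["below_threshold"].mean())


def distance_distribution(
    distances: pd.DataFrame, type_x: str, type_y: str, bin_width_um: float = 0.5
) -> pd.DataFrame:
    """Unit-area histogram of nearest-neighbor distances for one type pair."""
    sel = distances[
        (distances["type"] == type_x) & (distances["partner_type"] == type_y)
    ]["distance_um"].to_numpy()
    if len(sel) == 0:
        return pd.DataFrame(columns=["bin_left_um", "bin_right_um", "density"])
    hi = max(sel.max(), bin_width_um)
    edges = np.arange(0.0, hi + bin_width_um, bin_width_um)
    dens, edges = np.histogram(sel, bins=edges, density=True)
    return pd.DataFrame(
        {"bin_left_um": edges[:-1], "bin_right_um": edges[1:], "density": dens}
    )


# ---------------------------------------------------------------------------
# Cell typing from marker masks
# ---------------------------------------------------------------------------


def classify_nucleus_types(
    nuclei: LabelMap,
    desmin_mask: LabelMap,
    f480_mask: LabelMap,
    overlap_fraction: float = 0.5,
) -> dict[int, str]:
    """Type each nucleus: HSC / KC if enough of its boundary shell lies in
    the respective marker mask, hepatocyte otherwise (identity by
    exclusion)."""
    arr = nuclei.labels
    surf = _surface_voxels(arr)
    surf_idx = np.argwhere(surf)
    surf_lab = arr[surf]
    # dilate shell by one voxel outward: sample marker at shell positions and
    # their 6-neighbors so thin marker rims are caught
    shape = np.array(arr.shape)
    hits_d = np.zeros(len(surf_idx), bool)
    hits_f = np.zeros(len(surf_idx), bool)
    for off in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]:
        nb = surf_idx + np.array(off)
        ok = np.all((nb >= 0) & (nb < shape), axis=1)
        idx = tuple(nb[ok].T)
        hits_d[ok] |= desmin_mask.mask[idx]
        hits_f[ok] |= f480_mask.mask[idx]
    out = {}
    for i in np.unique(surf_lab):
        sel = surf_lab == i
        fd = hits_d[sel].mean()
        ff = hits_f[sel].mean()
        if fd >= overlap_fraction and fd >= ff:
            out[int(i)] = "hsc"
        elif ff >= overlap_fraction:
            out[int(i)] = "kc"
        else:
            out[int(i)] = "hepatocyte"
    return out


# ---------------------------------------------------------------------------
# Atlas assembly
# ---------------------------------------------------------------------------


@dataclass
class AtlasTable:
    """Joined per-cell and per-nucleus records with provenance."""

    cells: pd.DataFrame
    nuclei: pd.DataFrame
    summary: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def to_csv(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(d / "cells.csv", index=False)
        self.nuclei.to_csv(d / "nuclei.csv", index=False)
        self.summary.to_csv(d / "summary.csv", index=False)


def sem(values: np.ndarray) -> float:
    """Standard error of the mean; 0 for a single sample (flagged by n=1)."""
    values = np.asarray(values, float)
    if len(values) < 2:
        return 0.0
    return float(values.std(ddof=1) / np.sqrt(len(values)))


def build_atlas(
    cell_records: pd.DataFrame,
    nucleus_records: pd.DataFrame,
    provenance: dict | None = None,
    exclude_edge: bool = True,
) -> AtlasTable:
    """Assemble the atlas and a mean +/- s.e.m. summary per (type, parameter).

    ``cell_records`` must have unique ``cell_id`` per ``cell_type``;
    border-touching cells (``edge_object``) are excluded from the summary by
    default.
    """
    for df, key in ((cell_records, "cell_id"), (nucleus_records, "nucleus_id")):
        if len(df) and df.duplicated(subset=[key] + (
            ["cell_type"] if "cell_type" in df else []
        )).any():
            raise Lobule3DError(f"duplicate {key}s in atlas input")
    cells = cell_records.copy()
    use = cells
    if exclude_edge and "edge_object" in cells:
        use = cells[~cells["edge_object"]]
    rows = []
    numeric = use.select_dtypes(include=[np.number]).columns
    group_key = "cell_type" if "cell_type" in use else None
    groups = use.groupby(group_key) if group_key else [("all", use)]
    for gname, g in groups:
        for col in numeric:
            if col in ("cell_id",):
                continue
            vals = g[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "cell_type": gname,
                    "parameter": col,
                    "mean": float(np.mean(vals)),
                    "sem": sem(vals),
                    "n": int(len(vals)),
                }
            )
    summary = pd.DataFrame(rows, columns=["cell_type", "parameter", "mean", "sem", "n"])
    return AtlasTable(
        cells=cells,
        nuclei=nucleus_records,
        summary=summary,
        provenance=provenance or {},
    )
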