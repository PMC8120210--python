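"""Confocal cell-morphometry pipeline for engineered heart tissue.

Reimplements the image-analysis chain used on DAPI / WGA / alpha-actinin
scans: nuclei are segmented from DAPI by a histogram-based threshold plus
morphological closing, cells by a nucleus-seeded watershed flooding the
WGA intensity, and the actinin signal by a mode + 1 SD threshold.
Segments are filtered to myocytes (actinin area fraction >= 0.07 and
nucleus >= 5 um^2, both inclusive), then characterized by principal-
component geometry (area, length, width, axial orientation), a
first/second-degree-neighbor orientation dispersion, and the sarcomere
length from the striation period along the cell axis.

Orientations are axial (mod 180 deg); all axial statistics use the
doubled-angle circular method, since a plain SD is wrong near the 0/180
wrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import find_peaks
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk
from skimage.segmentation import expand_labels, watershed

__all__ = [
    "ChannelImage",
    "TissueSection",
    "segment_nuclei",
    "watershed_cells",
    "segment_actinin",
    "filter_myocytes",
    "cell_morphology",
    "neighbor_graph",
    "second_degree_neighbors",
    "axial_dispersion",
    "local_dispersion",
    "sarcomere_length",
    "cross_section_stats",
    "analyze_tissue",
]

DEFAULT_PIXEL_SIZE = 0.1  # um


@dataclass
class ChannelImage:
    """One 2D fluorescence channel with its pixel size."""

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE
    channel: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.size == 0:
            raise ValueError("channel image must be a non-empty 2D array")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class TissueSection:
    """Section-level actinin cross-section statistics."""

    section_area_um2: float
    actinin_area_um2: float
    actinin_fraction: float
    n_cells_total: int = 0
    n_cells_retained: int = 0
    meta: dict = field(default_factory=dict)


def _as_array(img):
    if isinstance(img, ChannelImage):
        return img.data, img.pixel_size
    return np.asarray(img, dtype=float), DEFAULT_PIXEL_SIZE


def segment_nuclei(
    dapi,
    pixel_size: float | None = None,
    *,
    closing_radius_um: float = 0.3,
    min_area_um2: float = 5.0,
):
    """Label nuclei in a DAPI channel.

    Automatic histogram (Otsu) threshold, morphological closing with a
    disk of ``closing_radius_um``, connected-component labelling, and
    removal of components smaller than ``min_area_um2`` (the bound is
    inclusive: a nucleus of exactly that area is retained).
    """
    img, px = _as_array(dapi)
    if pixel_size is not None:
        px = pixel_size
    if img.max() == img.min():
        warnings.warn("uniform DAPI image: no nuclei found", stacklevel=2)
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img)
    mask = img > thr
    r = max(int(round(closing_radius_um / px)), 1)
    mask = closing(mask, disk(r))
    labels, n = ndi.label(mask)
    if n == 0:
        warnings.warn("no nuclei found after thresholding", stacklevel=2)
        return labels.astype(np.int32)
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas * px * px >= min_area_um2) + 1
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    return out


def watershed_cells(
    wga,
    nuclei: np.ndarray,
    *,
    pixel_size: float | None = None,
    mask: np.ndarray | None = None,
    use_gradient: bool = False,
    mask_closing_um: float = 0.3,
):
    """Nucleus-seeded watershed of the WGA (membrane) channel.

    The watershed floods the WGA intensity directly — membranes are
    bright ridges, so cell interiors are basins — from the nucleus seeds
    (``use_gradient=True`` floods the Sobel gradient magnitude instead).
    Unless a foreground ``mask`` is given, one is built from the WGA+DAPI
    support: thresholded WGA rings are hole-filled and closed so that
    empty background is excluded.  Every output segment contains exactly
    one seed.
    """
    img, px = _as_array(wga)
    if pixel_size is not None:
        px = pixel_size
    if nuclei.max() == 0:
        raise ValueError("no nucleus seeds")
    if mask is None:
        thr = threshold_otsu(img)
        support = ndi.binary_fill_holes(img > thr)
        r = max(int(round(mask_closing_um / px)), 1)
        support = closing(support, disk(r))
        support = ndi.binary_fill_holes(support)
        mask = support | (nuclei > 0)
    flood = img
    if use_gradient:
        from skimage.filters import sobel

        flood = sobel(img)
    return watershed(flood, markers=nuclei.astype(np.int32), mask=mask)


def segment_actinin(
    actinin,
    *,
    bin_width: float = 1.0,
    sd_scope: str = "image",
    background_mask: np.ndarray | None = None,
):
    """Threshold the alpha-actinin channel at histogram mode + 1 SD.

    The mode is the center of the fullest histogram bin (``bin_width``
    intensity units); the SD is taken over the whole image by default, or
    over ``background_mask`` when ``sd_scope="background"``.  Returns
    ``(mask, threshold)``.
    """
    img, _ = _as_array(actinin)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant actinin image: empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool), hi
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    counts, edges = np.histogram(img, bins=n_bins, range=(lo, lo + n_bins * bin_width))
    i = int(np.argmax(counts))
    mode = float((edges[i] + edges[i + 1]) / 2.0)
    if sd_scope == "background":
        if background_mask is None:
            raise ValueError("background scope needs a background_mask")
        sd = float(img[background_mask].std())
    else:
        sd = float(img.std())
    thr = mode + sd
    return img > thr, thr


def filter_myocytes(
    cells: pd.DataFrame,
    *,
    min_actinin_fraction: float = 0.07,
    min_nucleus_area: float = 5.0,
) -> tuple[pd.DataFrame, dict]:
    """Retain cells with actinin area fraction and nucleus area at or
    above the thresholds (both bounds inclusive).

    Returns the retained table and a count summary.  Raising either
    threshold can only shrink the retained set.
    """
    keep = (cells["actinin_area_fraction"] >= min_actinin_fraction) & (
        cells["nucleus_area_um2"] >= min_nucleus_area
    )
    counts = dict(n_total=int(len(cells)), n_retained=int(keep.sum()))
    return cells[keep].copy(), counts


def cell_morphology(pixels, pixel_size: float = DEFAULT_PIXEL_SIZE, *, isotropy_tol: float = 1.1) -> dict:
    """Principal-component geometry of one cell's pixel set.

    ``pixels`` is either a boolean mask or an (N, 2) array of (row, col)
    coordinates.  Area is the pixel count times the pixel area; the
    orientation is the angle of the first principal axis mapped to the
    axial range [0, 180) degrees; length and width are the extents of the
    pixel projections on the first and second axes.  Nearly isotropic
    cells (principal-axis ratio below ``isotropy_tol``) are flagged,
    since their orientation is not meaningful.
    """
    pts = np.asarray(pixels)
    if pts.ndim == 2 and pts.dtype == bool:
        pts = np.argwhere(pts)
    pts = pts.astype(float)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 pixels")
    area = pts.shape[0] * pixel_size**2
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    major, minor = evecs[:, 1], evecs[:, 0]
    # (row, col) components; axial angle measured from the col (x) axis
    orientation = float(np.rad2deg(np.arctan2(major[0], major[1])) % 180.0)
    proj1 = centered @ major
    proj2 = centered @ minor
    length = (proj1.max() - proj1.min() + 1.0) * pixel_size
    width = (proj2.max() - proj2.min() + 1.0) * pixel_size if evals[0] > 0 else 0.0
    if width > length:
        length, width = width, length
    isotropic = bool(evals[0] > 0 and np.sqrt(evals[1] / evals[0]) < isotropy_tol)
    return dict(
        area_um2=float(area),
        length_um=float(length),
        width_um=float(width),
        orientation_deg=orientation,
        isotropic=isotropic,
    )


def neighbor_graph(labels: np.ndarray, *, max_gap: int = 0) -> nx.Graph:
    """First-degree adjacency of a cell label map.

    Two cells are adjacent iff their labels touch across a 4-connected
    boundary.  ``max_gap`` > 0 first expands labels by that many pixels
    into the background, bridging thin membrane gaps.
    """
    lab = labels
    if max_gap > 0:
        lab = expand_labels(labels, distance=max_gap)
    g = nx.Graph()
    g.add_nodes_from(np.unique(lab[lab > 0]).tolist())
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = (a != b) & (a > 0) & (b > 0)
        pairs = np.unique(np.stack([a[m], b[m]], axis=1), axis=0) if m.any() else []
        for u, v in pairs:
            g.add_edge(int(u), int(v))
    return g


def second_degree_neighbors(graph: nx.Graph, node) -> set:
    """Neighbors-of-neighbors, excluding the node and its 1st-degree set."""
    first = set(graph.neighbors(node))
    second = set()
    for nb in first:
        second |= set(graph.neighbors(nb))
    return second - first - {node}


def axial_dispersion(orientations_deg, *, ddof: int = 1) -> float:
    """Axial circular SD (degrees) of a set of cell-axis orientations.

    All angles are doubled, the circular mean of the doubled angles is
    taken, deviations are wrapped to (-180, 180] and halved back to the
    axial scale (giving deviations in (-90, 90]), and the sample SD of
    those deviations is returned.
    """
    ang = np.asarray(orientations_deg, dtype=float)
    doubled = np.deg2rad(2.0 * ang)
    mean2 = np.arctan2(np.sin(doubled).mean(), np.cos(doubled).mean())
    dev = np.rad2deg(np.angle(np.exp(1j * (doubled - mean2)))) / 2.0
    return float(np.std(dev, ddof=ddof))


def local_dispersion(
    cells: pd.DataFrame,
    graph: nx.Graph,
    *,
    min_set_size: int = 3,
    ddof: int = 1,
) -> pd.Series:
    """Per-cell orientation dispersion over {self} + 1st + 2nd neighbors.

    The dispersion is the axial circular SD of the main-axis orientations
    of each cell together with its first- and second-degree neighbors; a
    low value means good local alignment.  Cells whose neighbor set is
    smaller than ``min_set_size`` get NaN.
    """
    ori = cells.set_index("cell_id")["orientation_deg"]
    out = {}
    for cid in ori.index:
        if cid not in graph:
            out[cid] = np.nan
            continue
        members = {cid} | set(graph.neighbors(cid)) | second_degree_neighbors(graph, cid)
        members &= set(ori.index)
        if len(members) < min_set_size:
            out[cid] = np.nan
            continue
        out[cid] = axial_dispersion(ori.loc[sorted(members)].to_numpy(), ddof=ddof)
    return pd.Series(out, name="dispersion_deg")


def sarcomere_length(
    actinin,
    cell: dict | pd.Series,
    cell_mask: np.ndarray,
    *,
    pixel_size: float | None = None,
    n_lines: int = 5,
    period_range: tuple[float, float] = (1.2, 3.0),
    min_periods: int = 3,
    prominence: float = 0.1,
) -> dict:
    """Striation period (um) along a cell's principal axis.

    The actinin intensity is sampled along ``n_lines`` parallel lines
    through the cell (offset perpendicular to its axis); each line's
    dominant period is the highest autocorrelation peak within
    ``period_range``, refined by parabolic interpolation, and the cell
    value is the mean over lines.  The "clear striations" gate requires
    the autocorrelation peak prominence to exceed ``prominence``; cells
    failing it, or shorter than ``min_periods`` maximal periods, return
    NaN with a reason.
    """
    img, px = _as_array(actinin)
    if pixel_size is not None:
        px = pixel_size
    theta = np.deg2rad(float(cell["orientation_deg"]))
    length_px = float(cell["length_um"]) / px
    width_px = float(cell["width_um"]) / px
    if length_px * px < min_periods * period_range[1]:
        return dict(sarcomere_length_um=np.nan, reason="cell shorter than "
                    f"{min_periods} maximal periods", n_lines=0)
    rows, cols = np.argwhere(cell_mask).mean(axis=0)
    u = np.array([np.sin(theta), np.cos(theta)])  # (row, col) step along the axis
    v = np.array([np.cos(theta), -np.sin(theta)])
    s = np.arange(-length_px / 2.0, length_px / 2.0, 1.0)
    offsets = (np.arange(n_lines) - (n_lines - 1) / 2.0) * (width_px / (n_lines + 1))
    lo_lag = max(int(np.floor(period_range[0] / px)), 2)
    hi_lag = int(np.ceil(period_range[1] / px))
    periods = []
    for off in offsets:
        pts = np.array([[rows], [cols]]) + np.outer(u, s) + off * v[:, None]
        inside = (
            (pts[0] >= 0)
            & (pts[0] <= img.shape[0] - 1)
            & (pts[1] >= 0)
            & (pts[1] <= img.shape[1] - 1)
        )
        # restrict to samples within the cell
        ri = np.clip(np.round(pts[0]).astype(int), 0, img.shape[0] - 1)
        ci = np.clip(np.round(pts[1]).astype(int), 0, img.shape[1] - 1)
        inside &= cell_mask[ri, ci]
        if inside.sum() < min_periods * lo_lag:
            continue
        prof = ndi.map_coordinates(img, pts[:, inside], order=1)
        prof = prof - prof.mean()
        if not prof.any():
            continue
        ac = np.correlate(prof, prof, mode="full")[prof.size - 1 :]
        if ac[0] <= 0:
            continue
        # unbiased estimate: normalize by the overlap count at each lag,
        # else the taper drags the peak toward smaller lags
        ac = ac / (prof.size - np.arange(ac.size))
        ac = ac / ac[0]
        hi = min(hi_lag + 2, ac.size - 2)
        if hi <= lo_lag:
            continue
        peaks, props = find_peaks(ac[: hi + 1], prominence=prominence)
        peaks = peaks[(peaks >= lo_lag) & (peaks <= hi_lag)]
        if peaks.size == 0:
            continue
        pk = int(peaks[np.argmax(ac[peaks])])
        # parabolic sub-pixel refinement
        y0, y1, y2 = ac[pk - 1], ac[pk], ac[pk + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        periods.append((pk + shift) * px)
    if len(periods) < n_lines:
        return dict(sarcomere_length_um=np.nan, reason="no striation", n_lines=len(periods))
    return dict(
        sarcomere_length_um=float(np.mean(periods)),
        reason="",
        n_lines=len(periods),
        line_periods_um=periods,
    )


def cross_section_stats(
    actinin_mask: np.ndarray,
    section_area_um2: float | None = None,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> TissueSection:
    """Actinin-positive area and its fraction of the section area."""
    if section_area_um2 is None:
        section_area_um2 = actinin_mask.size * pixel_size**2
    if not section_area_um2 > 0:
        raise ValueError("section area must be positive")
    pos = float(actinin_mask.sum()) * pixel_size**2
    return TissueSection(
        section_area_um2=float(section_area_um2),
        actinin_area_um2=pos,
        actinin_fraction=pos / float(section_area_um2),
    )


def analyze_tissue(
    channels,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    min_actinin_fraction: float = 0.07,
    min_nucleus_area: float = 5.0,
    neighbor_max_gap_um: float = 2.5,
    dispersion_min_set: int = 3,
    sarcomere_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, TissueSection, np.ndarray]:
    """Run the full morphometry pipeline on a (dapi, wga, actinin) stack.

    Returns the per-cell table (geometry, actinin fraction, myocyte
    filter flag, neighbor counts, dispersion, sarcomere length), the
    section-level actinin statistics, and the watershed cell label map.
    """
    dapi, wga, actinin = (np.asarray(c, dtype=float) for c in channels)
    nuclei = segment_nuclei(dapi, pixel_size)
    labels = watershed_cells(wga, nuclei, pixel_size=pixel_size)
    act_mask, act_thr = segment_actinin(actinin)
    rows = []
    for cid in np.unique(labels[labels > 0]):
        m = labels == cid
        if m.sum() < 3:
            continue
        morph = cell_morphology(m, pixel_size)
        nuc_px = int(((nuclei > 0) & m).sum())
        rows.append(
            dict(
                cell_id=int(cid),
                **morph,
                nucleus_area_um2=nuc_px * pixel_size**2,
                actinin_area_fraction=float(act_mask[m].mean()),
            )
        )
    cells = pd.DataFrame(rows)
    retained, counts = filter_myocytes(
        cells,
        min_actinin_fraction=min_actinin_fraction,
        min_nucleus_area=min_nucleus_area,
    )
    cells["is_myocyte"] = cells["cell_id"].isin(retained["cell_id"])
    graph = neighbor_graph(labels, max_gap=int(round(neighbor_max_gap_um / pixel_size)))
    disp = local_dispersion(cells, graph, min_set_size=dispersion_min_set)
    cells["dispersion_deg"] = cells["cell_id"].map(disp)
    sk = sarcomere_kwargs or {}
    sl = {}
    for _, rec in cells[cells["is_myocyte"]].iterrows():
        res = sarcomere_length(
            actinin, rec, labels == rec["cell_id"], pixel_size=pixel_size, **sk
        )
        sl[rec["cell_id"]] = res["sarcomere_length_um"]
    cells["sarcomere_length_um"] = cells["cell_id"].map(sl)
    section = cross_section_stats(act_mask, pixel_size=pixel_size)
    section.n_cells_total = counts["n_total"]
    section.n_cells_retained = counts["n_retained"]
    section.meta["actinin_threshold"] = act_thr
    return cells, section, labels
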