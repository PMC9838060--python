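"""High-content image analysis for arrayed protoplast reporter assays.

Turns raw multi-channel Z-stacks of a well's fields into per-cell records and
per-well counts.  The workflow mirrors an automated high-content screening
analysis of plant protoplasts: maximum-intensity projection over Z, pseudo
flat-field correction, chlorophyll-based cell segmentation with a roundness
filter (wheat), nucleus segmentation from the union of the nuclear mCherry and
GFP reporter channels, and intensity gating of nuclear reporter signal against
negative-control wells.

Two species modes are supported:

``wheat_chlorophyll``
    Cells are segmented from the chlorophyll autofluorescence channel and kept
    as protoplasts when round enough; each protoplast is then assigned at most
    one nucleus.

``maize_etiolated``
    Etiolated protoplasts carry no chlorophyll, so the reporter nuclei
    themselves are the analysis units.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import ConfigurationError, FormatError

CHANNELS = ("brightfield", "chlorophyll", "GFP", "mCherry")

WHEAT = "wheat_chlorophyll"
MAIZE = "maize_etiolated"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ChannelStack:
    """One field's raw acquisition: named channels x Z planes of intensities.

    Parameters
    ----------
    well : str
        Well identifier, e.g. ``"B7"``.
    field : int
        Zero-based field-of-view index within the well.
    channels : dict of str to ndarray
        Mapping channel name -> ``(Z, Y, X)`` array of 16-bit intensities.
        The chlorophyll channel may be absent (etiolated material).
    pixel_size_um : float, optional
        Physical pixel size in micrometres.
    """

    well: str
    field: int
    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise FormatError("stack has no channels")
        shapes = {c: a.shape for c, a in self.channels.items()}
        dims = {s[-2:] for s in shapes.values()}
        if len(dims) != 1:
            raise FormatError(f"channel plane dimensions differ: {shapes}")
        for name, arr in self.channels.items():
            if arr.ndim == 2:
                self.channels[name] = arr[None, :, :]
            elif arr.ndim != 3:
                raise FormatError(f"channel {name!r} must be 2-D or 3-D")

    @property
    def plane_shape(self) -> tuple[int, int]:
        arr = next(iter(self.channels.values()))
        return arr.shape[-2:]


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation and gating workflow.

    Roundness is 4*pi*Area/Perimeter**2 (1 for a perfect disc); regions below
    ``roundness_cutoff`` are flagged as non-protoplast debris.  Gate thresholds
    default to the 99.9th percentile of reporter-channel intensity in
    negative-control wells of the same plate.
    """

    mode: str = WHEAT
    smoothing_sigma: float = 2.0
    cell_threshold_method: str = "otsu"  # or "fixed"
    cell_threshold_value: float = 0.0
    roundness_cutoff: float = 0.8
    min_cell_area: float = 200.0
    max_cell_area: float = 1e5
    nucleus_threshold_method: str = "otsu"  # or "fixed"
    nucleus_threshold_value: float = 0.0
    min_nucleus_area: float = 20.0
    max_nucleus_area: float = 2000.0
    # an Otsu nucleus threshold must clear background by this factor, else the
    # field is treated as nucleus-free (guards against featureless images)
    nucleus_min_contrast: float = 1.5
    gate_method: str = "negative_control_quantile"  # or "otsu", "fixed"
    gate_quantile: float = 0.999
    gate_margin: float = 1.2
    fixed_mcherry_threshold: float = 0.0
    fixed_gfp_threshold: float = 0.0
    watershed_min_distance: int = 15
    exclude_border: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.roundness_cutoff <= 1.0:
            raise ConfigurationError("roundness cutoff must be in (0, 1]")
        if self.min_cell_area <= 0 or self.min_cell_area >= self.max_cell_area:
            raise ConfigurationError("cell area bounds must satisfy 0 < min < max")
        if self.min_nucleus_area <= 0 or self.min_nucleus_area >= self.max_nucleus_area:
            raise ConfigurationError("nucleus area bounds must satisfy 0 < min < max")
        if self.mode not in (WHEAT, MAIZE):
            raise ConfigurationError(f"unknown mode {self.mode!r}")


@dataclass
class CellRecord:
    """One segmented object with its shape metrics and gate flags."""

    well: str
    field: int
    label: int
    centroid: tuple[float, float]
    area: float
    roundness: float
    has_nucleus: bool
    mean_nuclear_mcherry: float
    mean_nuclear_gfp: float
    is_protoplast: bool
    is_transfected: bool
    is_gfp_positive: bool
    # independent (non-nested) GFP gate, used for co-transfection efficiency
    gfp_above_threshold: bool = False

    def __post_init__(self) -> None:
        if self.is_gfp_positive and not self.is_transfected:
            raise ValueError("is_gfp_positive requires is_transfected")


@dataclass
class WellSummary:
    """Per-well counts from which all plate statistics derive."""

    well: str
    n_cells: int
    n_transfected: int
    n_gfp_positive: int
    mean_gfp_transfected: float = float("nan")
    n_gfp_independent: int = 0
    condition: str = ""
    control: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.n_gfp_positive <= self.n_transfected <= self.n_cells:
            raise ValueError(
                "count nesting violated: need "
                f"0 <= {self.n_gfp_positive} <= {self.n_transfected} <= {self.n_cells}"
            )


@dataclass
class GateThresholds:
    """Resolved nuclear-intensity gate thresholds for one plate."""

    mcherry: float
    gfp: float
    method: str = "negative_control_quantile"
    n_control_wells: int = 0


# ---------------------------------------------------------------------------
# projection and correction
# ---------------------------------------------------------------------------


def project_stack(stack: ChannelStack) -> dict[str, np.ndarray]:
    """Maximum-intensity projection of every channel over Z."""
    return {name: arr.max(axis=0) for name, arr in stack.channels.items()}


def flatfield_correct(
    image: np.ndarray, background_sigma: float = 32.0, iterations: int = 2
) -> np.ndarray:
    """Remove smooth illumination gradients (vignetting) from a field image.

    The image is divided by a heavily Gaussian-smoothed copy of itself (a
    pseudo flat-field); repeating the division once more removes most of the
    curvature bias the smoothing itself introduces.  The result is rescaled
    to preserve the original mean and is non-negative float.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise FormatError("empty image")
    corrected = img
    for _ in range(max(1, iterations)):
        # nearest-edge padding keeps the estimate sane where falloff is steepest
        background = ndi.gaussian_filter(corrected, background_sigma, mode="nearest")
        eps = max(1e-6, 1e-6 * float(background.max()))
        corrected = corrected / np.maximum(background, eps)
    mean = corrected.mean()
    if mean > 0:
        corrected = corrected * (img.mean() / mean)
    return np.maximum(corrected, 0.0)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _roundness(region) -> float:
    perim = region.perimeter_crofton
    if perim <= 0:
        return 0.0
    return min(1.0, 4.0 * math.pi * region.area / perim**2)


def _threshold(image: np.ndarray, method: str, fixed: float) -> float | None:
    """Return a foreground threshold, or None when the image is featureless."""
    if method == "fixed":
        return fixed
    if float(image.max()) == float(image.min()):
        return None
    return float(threshold_otsu(image))


def segment_protoplasts(
    chlorophyll: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, list[dict]]:
    """Segment protoplast bodies from the chlorophyll channel (wheat mode).

    The channel is smoothed and thresholded, holes are filled, and touching
    cells are split by a distance-transform watershed.  Every region is kept
    and measured; regions failing the roundness cutoff, the area bounds, or
    touching the field border are flagged ``is_protoplast=False`` rather than
    deleted.

    Returns
    -------
    labels : ndarray of int
        Labelled segmentation image.
    regions : list of dict
        One dict per region with keys ``label``, ``centroid``, ``area``,
        ``roundness``, ``touches_border``, ``is_protoplast``.
    """
    if params.mode != WHEAT:
        raise ConfigurationError("segment_protoplasts requires wheat_chlorophyll mode")
    img = ndi.gaussian_filter(np.asarray(chlorophyll, dtype=float), params.smoothing_sigma)
    thr = _threshold(img, params.cell_threshold_method, params.cell_threshold_value)
    if thr is None:
        return np.zeros(img.shape, dtype=np.int32), []
    mask = ndi.binary_fill_holes(img > thr)
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), []

    distance = ndi.distance_transform_edt(mask)
    # thin objects (debris streaks) must not be split into round-ish chunks:
    # a credible cell seed needs at least half the minimum cell radius of depth
    min_depth = 0.5 * math.sqrt(params.min_cell_area / math.pi)
    peaks = peak_local_max(
        distance, min_distance=params.watershed_min_distance, labels=mask,
        threshold_abs=min_depth, exclude_border=False,
    )
    if len(peaks) == 0:
        labels = sk_label(mask)
    else:
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = watershed(-distance, markers, mask=mask)

    regions = []
    h, w = mask.shape
    for region in regionprops(labels):
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        roundness = _roundness(region)
        ok = (
            roundness >= params.roundness_cutoff
            and params.min_cell_area <= region.area <= params.max_cell_area
            and not (touches and params.exclude_border)
        )
        regions.append(
            {
                "label": region.label,
                "centroid": tuple(region.centroid),
                "area": float(region.area),
                "roundness": roundness,
                "touches_border": touches,
                "is_protoplast": ok,
            }
        )
    return labels, regions


def segment_nuclei(
    mcherry: np.ndarray | None,
    gfp: np.ndarray | None,
    params: SegmentationParams,
) -> tuple[np.ndarray, list[dict]]:
    """Segment reporter nuclei from the union of the mCherry and GFP channels.

    Nuclei are connected regions of the thresholded pixelwise maximum of the
    two nuclear reporter channels, filtered by the nucleus area bounds.  Either
    channel may be None.  In maize (etiolated) mode these regions are the
    analysis units themselves.
    """
    imgs = [np.asarray(a, dtype=float) for a in (mcherry, gfp) if a is not None]
    if not imgs:
        raise ConfigurationError("segment_nuclei needs at least one reporter channel")
    combined = imgs[0] if len(imgs) == 1 else np.maximum(imgs[0], imgs[1])
    thr = _threshold(combined, params.nucleus_threshold_method, params.nucleus_threshold_value)
    if thr is None:
        return np.zeros(combined.shape, dtype=np.int32), []
    mask = combined > thr
    labels = sk_label(mask)
    nuclei = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    # genuine nuclear reporter signal stands far above the image median;
    # halos and spurious Otsu splits of a featureless background do not
    floor = params.nucleus_min_contrast * float(np.median(combined))
    for region in regionprops(labels, intensity_image=combined):
        if not params.min_nucleus_area <= region.area <= params.max_nucleus_area:
            continue
        if params.nucleus_threshold_method == "otsu" and region.intensity_mean <= floor:
            continue
        keep[region.label] = True
        nuclei.append(
            {
                "label": region.label,
                "centroid": tuple(region.centroid),
                "area": float(region.area),
                "roundness": _roundness(region),
            }
        )
    labels = np.where(keep[labels], labels, 0)
    return labels, nuclei


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


def control_thresholds(
    control_images: list[dict[str, np.ndarray]],
    quantile: float = 0.999,
    margin: float = 1.2,
) -> GateThresholds:
    """Derive gate thresholds from negative-control wells.

    ``control_images`` holds projected channel images (one dict per control
    field).  The base level for each reporter is the ``quantile`` percentile
    of that channel's pixel intensities pooled over all control fields:
    control wells received no DNA, so nothing above background appears there.
    The threshold is this level times ``margin`` — the headroom keeps
    background-level nuclear means (which straddle the raw quantile) on the
    negative side while true nuclear reporter signal sits far above it.
    """
    if not control_images:
        raise ConfigurationError(
            "negative_control_quantile gating requested but no control wells in layout"
        )
    mch = np.concatenate([d["mCherry"].ravel() for d in control_images if "mCherry" in d])
    gfp = np.concatenate([d["GFP"].ravel() for d in control_images if "GFP" in d])
    return GateThresholds(
        mcherry=margin * float(np.quantile(mch, quantile)),
        gfp=margin * float(np.quantile(gfp, quantile)),
        method="negative_control_quantile",
        n_control_wells=len(control_images),
    )


def _otsu_thresholds(projected: dict[str, np.ndarray]) -> GateThresholds:
    out = {}
    for ch in ("mCherry", "GFP"):
        img = projected[ch]
        thr = _threshold(img, "otsu", 0.0)
        out[ch] = float(img.max()) if thr is None else thr
    return GateThresholds(mcherry=out["mCherry"], gfp=out["GFP"], method="otsu")


def gate_cells(
    cell_labels: np.ndarray,
    cells: list[dict],
    nucleus_labels: np.ndarray,
    nuclei: list[dict],
    projected: dict[str, np.ndarray],
    params: SegmentationParams,
    thresholds: GateThresholds | None = None,
    well: str = "",
    fld: int = 0,
) -> list[CellRecord]:
    """Assign nuclei to cells and apply the nested reporter gates.

    Each protoplast receives at most one nucleus by centroid containment (the
    nucleus with the brightest mean mCherry wins ties).  A cell is transfected
    iff its mean nuclear mCherry reaches the mCherry threshold, and GFP
    positive iff additionally its mean nuclear GFP reaches the GFP threshold.
    In maize mode the nuclei themselves become the records.
    """
    if thresholds is None:
        if params.gate_method == "fixed":
            thresholds = GateThresholds(
                params.fixed_mcherry_threshold, params.fixed_gfp_threshold, "fixed"
            )
        elif params.gate_method == "otsu":
            thresholds = _otsu_thresholds(projected)
        else:
            raise ConfigurationError(
                "negative_control_quantile gating requires precomputed thresholds "
                "(no control wells resolved)"
            )

    mch_img = projected["mCherry"]
    gfp_img = projected["GFP"]

    def nuclear_means(nucleus_label: int) -> tuple[float, float]:
        m = nucleus_labels == nucleus_label
        return float(mch_img[m].mean()), float(gfp_img[m].mean())

    records: list[CellRecord] = []

    if params.mode == MAIZE:
        for nuc in nuclei:
            mch, gfp = nuclear_means(nuc["label"])
            transfected = mch >= thresholds.mcherry
            gfp_pos = gfp >= thresholds.gfp
            records.append(
                CellRecord(
                    well=well,
                    field=fld,
                    label=nuc["label"],
                    centroid=nuc["centroid"],
                    area=nuc["area"],
                    roundness=nuc["roundness"],
                    has_nucleus=True,
                    mean_nuclear_mcherry=mch,
                    mean_nuclear_gfp=gfp,
                    is_protoplast=True,
                    is_transfected=transfected,
                    is_gfp_positive=transfected and gfp_pos,
                    gfp_above_threshold=gfp_pos,
                )
            )
        return records

    # wheat: map each nucleus to the cell containing its centroid
    by_cell: dict[int, list[tuple[float, float, float]]] = {}
    for nuc in nuclei:
        r, c = (int(round(v)) for v in nuc["centroid"])
        if not (0 <= r < cell_labels.shape[0] and 0 <= c < cell_labels.shape[1]):
            continue
        owner = int(cell_labels[r, c])
        if owner == 0:
            continue
        mch, gfp = nuclear_means(nuc["label"])
        by_cell.setdefault(owner, []).append((mch, gfp, nuc["label"]))

    for cell in cells:
        assigned = by_cell.get(cell["label"], [])
        if assigned:
            mch, gfp, _ = max(assigned)  # brightest mean mCherry wins ties
            has_nucleus = True
        else:
            mch = gfp = 0.0
            has_nucleus = False
        transfected = has_nucleus and mch >= thresholds.mcherry
        gfp_pos = has_nucleus and gfp >= thresholds.gfp
        records.append(
            CellRecord(
                well=well,
                field=fld,
                label=cell["label"],
                centroid=cell["centroid"],
                area=cell["area"],
                roundness=cell["roundness"],
                has_nucleus=has_nucleus,
                mean_nuclear_mcherry=mch,
                mean_nuclear_gfp=gfp,
                is_protoplast=cell["is_protoplast"],
                is_transfected=transfected,
                is_gfp_positive=transfected and gfp_pos,
                gfp_above_threshold=gfp_pos,
            )
        )
    return records


def summarize_well(
    records: list[CellRecord],
    well: str,
    condition: str = "",
    control: bool = False,
) -> WellSummary:
    """Collapse a well's cell records into counts.

    Only records flagged as protoplasts contribute.  The mean nuclear GFP is
    computed over transfected cells only.  An empty well yields zero counts and
    a warning.
    """
    kept = [r for r in records if r.is_protoplast]
    for r in kept:
        if r.well and r.well != well:
            raise ValueError(f"record from well {r.well!r} passed to summary of {well!r}")
    n_transfected = sum(r.is_transfected for r in kept)
    n_gfp = sum(r.is_gfp_positive for r in kept)
    n_gfp_ind = sum(r.gfp_above_threshold for r in kept)
    gfp_means = [r.mean_nuclear_gfp for r in kept if r.is_transfected]
    if not kept:
        warnings.warn(f"well {well}: no cells after segmentation", stacklevel=2)
    return WellSummary(
        well=well,
        n_cells=len(kept),
        n_transfected=n_transfected,
        n_gfp_positive=n_gfp,
        mean_gfp_transfected=float(np.mean(gfp_means)) if gfp_means else float("nan"),
        n_gfp_independent=n_gfp_ind,
        condition=condition,
        control=control,
    )


# ---------------------------------------------------------------------------
# field- and plate-level orchestration
# ---------------------------------------------------------------------------


def analyze_field(
    stack: ChannelStack,
    params: SegmentationParams,
    thresholds: GateThresholds | None = None,
    flatfield: bool = True,
) -> list[CellRecord]:
    """Run the full single-field workflow: project, correct, segment, gate."""
    projected = project_stack(stack)
    if flatfield:
        projected = {c: flatfield_correct(img) for c, img in projected.items()}
    nuc_labels, nuclei = segment_nuclei(
        projected.get("mCherry"), projected.get("GFP"), params
    )
    if params.mode == WHEAT:
        if "chlorophyll" not in projected:
            raise ConfigurationError("wheat mode requires a chlorophyll channel")
        cell_labels, cells = segment_protoplasts(projected["chlorophyll"], params)
    else:
        cell_labels, cells = np.zeros_like(nuc_labels), []
    return gate_cells(
        cell_labels, cells, nuc_labels, nuclei, projected, params, thresholds,
        well=stack.well, fld=stack.field,
    )


def process_plate(
    stacks: list[ChannelStack],
    layout: "pd.DataFrame",  # noqa: F821 - imported lazily to avoid heavy import
    params: SegmentationParams,
    flatfield: bool = True,
) -> tuple[list[CellRecord], list[WellSummary]]:
    """Process every field of a plate and summarise per well.

    When gating uses the negative-control quantile, thresholds are first
    resolved from all fields of wells whose ``control_role`` is not ``none``.
    """
    layout_idx = {row.well: row for row in layout.itertuples()}
    thresholds: GateThresholds | None = None
    if params.gate_method == "negative_control_quantile":
        control_imgs = []
        for stack in stacks:
            row = layout_idx.get(stack.well)
            if row is not None and getattr(row, "control_role", "none") != "none":
                projected = project_stack(stack)
                if flatfield:
                    projected = {c: flatfield_correct(i) for c, i in projected.items()}
                control_imgs.append(projected)
        thresholds = control_thresholds(control_imgs, params.gate_quantile, params.gate_margin)

    records: list[CellRecord] = []
    by_well: dict[str, list[CellRecord]] = {}
    for stack in stacks:
        recs = analyze_field(stack, params, thresholds, flatfield=flatfield)
        records.extend(recs)
        by_well.setdefault(stack.well, []).extend(recs)

    summaries = []
    for well in sorted(by_well):
        row = layout_idx.get(well)
        condition = getattr(row, "condition", "") if row is not None else ""
        control = (
            getattr(row, "control_role", "none") != "none" if row is not None else False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries.append(summarize_well(by_well[well], well, condition, control))
    return records, summaries
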