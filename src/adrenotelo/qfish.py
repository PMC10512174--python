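"""Per-nucleus telomere quantification: TCR, cell-block NTCR, and RTL.

The measurement chain mirrors tissue Q-FISH practice: segment nuclei on
the DAPI plane, integrate background-corrected telomere (Cy3) and
centromere (FITC) signal inside each nucleus mask, form the
telomere/centromere ratio (TCR) per nucleus, divide by the mean TCR of a
cultured-fibroblast cell block mounted on the same slide to get the
normalized TCR (NTCR) — cancelling slide-wide gain differences from
hybridization and acquisition — and average 110–120 cells of one cell
type in one patient into a relative telomere length (RTL).

The cell-block line carries a Southern-blot-calibrated telomere length
of 8.64 kbp, so NTCR can optionally be expressed in kilobase pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import clear_border, watershed

__all__ = [
    "TIG1_TELOMERE_KBP",
    "QFISHImage",
    "NucleusMeasurement",
    "CellBlockReference",
    "PatientRTL",
    "segment_nuclei",
    "estimate_background",
    "measure_nuclei",
    "compute_tcr",
    "cellblock_reference",
    "normalize_ntcr",
    "compute_rtl",
    "estimate_absolute_length_kbp",
]

#: Southern-blot telomere length of the TIG-1 cell-block reference (kbp).
TIG1_TELOMERE_KBP = 8.64


@dataclass
class QFISHImage:
    """Co-registered DAPI / Cy3 (telomere) / FITC (centromere) planes."""

    dapi: np.ndarray
    cy3: np.ndarray
    fitc: np.ndarray
    slide_id: str = "slide"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        for name in ("dapi", "cy3", "fitc"):
            plane = np.asarray(getattr(self, name), dtype=float)
            if plane.ndim != 2:
                raise ValueError(f"{name} plane must be 2-D")
            if not np.all(np.isfinite(plane)) or np.any(plane < 0):
                raise ValueError(f"{name} plane must be finite and non-negative")
            setattr(self, name, plane)
        if not (self.dapi.shape == self.cy3.shape == self.fitc.shape):
            raise ValueError("DAPI, Cy3 and FITC planes must share one shape")


@dataclass(frozen=True)
class NucleusMeasurement:
    """Background-corrected integrated signals and TCR for one nucleus."""

    nucleus_id: int
    centroid: tuple[float, float]  # (row, col), 0-based pixel centers
    area_px: int
    tel_signal: float
    cen_signal: float
    tcr: float
    lipofuscin_score: float | None = None
    cell_type: str = "unknown"


@dataclass(frozen=True)
class CellBlockReference:
    """Mean TCR of the same-slide cell block; the NTCR denominator."""

    slide_id: str
    mean_tcr: float
    n_nuclei: int


@dataclass
class PatientRTL:
    """RTL of one cell type in one patient: mean of 110-120 NTCRs."""

    patient_id: str
    cell_type: str
    ntcr_values: list[float]
    rtl: float = field(init=False)

    def __post_init__(self) -> None:
        self.rtl = float(np.mean(self.ntcr_values))


def segment_nuclei(
    dapi: np.ndarray,
    min_area_px: int = 30,
    max_area_px: int = 2000,
    smooth_sigma: float = 1.0,
    min_peak_distance: int = 5,
    remove_border: bool = True,
) -> np.ndarray:
    """Label nuclei on a DAPI plane.

    Gaussian smoothing, Otsu threshold, distance-transform watershed to
    split touching nuclei, then an area filter and (optionally) removal
    of border-touching nuclei.  A constant plane yields zero labels.
    """
    plane = np.asarray(dapi, dtype=float)
    if plane.ndim != 2:
        raise ValueError("dapi must be a 2-D plane")
    if np.ptp(plane) == 0:
        return np.zeros(plane.shape, dtype=np.int32)
    smoothed = gaussian(plane, sigma=smooth_sigma, preserve_range=True)
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        return np.zeros(plane.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_peak_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(plane.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=mask)
    if remove_border:
        labels = clear_border(labels)
    # area filter + sequential relabel, deterministic order
    out = np.zeros(plane.shape, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        if min_area_px <= prop.area <= max_area_px:
            out[labels == prop.label] = next_id
            next_id += 1
    return out


def estimate_background(
    plane: np.ndarray,
    labels: np.ndarray,
    lipofuscin_mask: np.ndarray | None = None,
) -> float:
    """Median intensity outside all nuclei and outside lipofuscin pixels."""
    plane = np.asarray(plane, dtype=float)
    bg = labels == 0
    if lipofuscin_mask is not None:
        bg &= ~np.asarray(lipofuscin_mask, dtype=bool)
    if not bg.any():
        raise ValueError("no background pixels available to estimate from")
    return float(np.median(plane[bg]))


def measure_nuclei(
    labels: np.ndarray,
    cy3: np.ndarray,
    fitc: np.ndarray,
    bg_cy3: float,
    bg_fitc: float,
    lipofuscin_mask: np.ndarray | None = None,
) -> tuple[list[NucleusMeasurement], dict[str, int]]:
    """Integrate background-corrected Cy3/FITC signal per nucleus.

    Pixels flagged as lipofuscin are excluded from integration (the
    pigment autofluoresces in both probe channels).  Nuclei whose
    centromere signal is non-positive, or that are fully covered by the
    lipofuscin mask, are dropped and counted in the returned QC dict.
    """
    labels = np.asarray(labels)
    cy3 = np.asarray(cy3, dtype=float)
    fitc = np.asarray(fitc, dtype=float)
    if not (labels.shape == cy3.shape == fitc.shape):
        raise ValueError("labels, cy3 and fitc must share one shape")
    lip = (
        np.asarray(lipofuscin_mask, dtype=bool)
        if lipofuscin_mask is not None
        else np.zeros(labels.shape, dtype=bool)
    )
    if lip.shape != labels.shape:
        raise ValueError("lipofuscin_mask shape mismatch")

    tel_excess = np.clip(cy3 - bg_cy3, 0.0, None)
    cen_excess = np.clip(fitc - bg_fitc, 0.0, None)
    qc = {"measured": 0, "dropped_fully_masked": 0, "dropped_nonpositive_centromere": 0}
    out: list[NucleusMeasurement] = []
    for prop in regionprops(labels):
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        keep = ~lip[rr, cc]
        if not keep.any():
            qc["dropped_fully_masked"] += 1
            continue
        tel = float(tel_excess[rr[keep], cc[keep]].sum())
        cen = float(cen_excess[rr[keep], cc[keep]].sum())
        if cen <= 0:
            qc["dropped_nonpositive_centromere"] += 1
            continue
        qc["measured"] += 1
        out.append(
            NucleusMeasurement(
                nucleus_id=int(prop.label),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                area_px=int(prop.area),
                tel_signal=tel,
                cen_signal=cen,
                tcr=tel / cen,
            )
        )
    return out, qc


def compute_tcr(tel_signal: float, cen_signal: float) -> float:
    """Telomere/centromere ratio; the caller drops nuclei with cen <= 0."""
    if cen_signal <= 0:
        raise ValueError(f"centromere signal must be > 0, got {cen_signal}")
    return tel_signal / cen_signal


def cellblock_reference(
    measurements: list[NucleusMeasurement],
    slide_id: str,
    min_nuclei: int = 50,
) -> CellBlockReference:
    """Mean TCR over the same-slide cell-block nuclei."""
    if len(measurements) < min_nuclei:
        raise ValueError(
            f"slide {slide_id!r}: cell block has {len(measurements)} nuclei, "
            f"need >= {min_nuclei}"
        )
    mean_tcr = float(np.mean([m.tcr for m in measurements]))
    if mean_tcr <= 0:
        raise ValueError(f"slide {slide_id!r}: cell-block mean TCR must be > 0")
    return CellBlockReference(slide_id=slide_id, mean_tcr=mean_tcr, n_nuclei=len(measurements))


def normalize_ntcr(
    tcr: float,
    reference: CellBlockReference,
    slide_id: str | None = None,
) -> float:
    """NTCR = TCR / same-slide cell-block mean TCR.

    Passing ``slide_id`` enforces that the nucleus and the reference come
    from the same slide — the normalization is only meaningful then.
    """
    if slide_id is not None and slide_id != reference.slide_id:
        raise ValueError(
            f"slide mismatch: nucleus from {slide_id!r}, reference from {reference.slide_id!r}"
        )
    if reference.mean_tcr <= 0:
        raise ValueError("cell-block reference mean TCR must be > 0")
    return tcr / reference.mean_tcr


def compute_rtl(
    patient_id: str,
    cell_type: str,
    ntcr_values,
    n_min: int = 110,
    n_max: int = 120,
    seed: int | None = None,
) -> PatientRTL:
    """Aggregate per-nucleus NTCRs into an RTL (mean of 110-120 cells).

    With more than ``n_max`` values available, a seeded uniform random
    subsample of ``n_max`` is retained (the sampling protocol of the
    source study is unstated, so the choice is explicit and reproducible).
    """
    values = [float(v) for v in ntcr_values]
    if len(values) < n_min:
        raise ValueError(
            f"{patient_id}/{cell_type}: {len(values)} NTCR values available, "
            f"need >= {n_min} (short by {n_min - len(values)})"
        )
    if len(values) > n_max:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(values), size=n_max, replace=False))
        values = [values[i] for i in idx]
    return PatientRTL(patient_id=patient_id, cell_type=cell_type, ntcr_values=values)


def estimate_absolute_length_kbp(ntcr: float) -> float:
    """Calibration-anchored absolute estimate: NTCR x 8.64 kbp.

    This leans on the cell block's Southern-blot length; it is an
    estimate tied to that anchor, not a measured quantity.
    """
    if ntcr <= 0:
        raise ValueError("ntcr must be > 0")
    return ntcr * TIG1_TELOMERE_KBP
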