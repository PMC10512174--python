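"""Cell-type assignment for segmented adrenal nuclei.

The adrenal gland is layered: capsule, then the cortical zona
glomerulosa (ZG), zona fasciculata (ZF) and zona reticularis (ZR), then
the chromaffin-cell medulla.  In Q-FISH images the cues used to tell
cell types apart are (a) the brilliant yellow lipofuscin
autofluorescence of ZR cytoplasm — bright in *both* the Cy3 and FITC
channels, (b) position relative to the capsule/medulla, (c) the small,
densely packed ZG nuclei, and (d) the regular, near-circular chromaffin
nuclei.  The original identification was visual; here it is a
transparent deterministic rule cascade with configurable thresholds,
validated on ground-truthed phantoms only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import regionprops

from .qfish import estimate_background

__all__ = [
    "ZoneLayout",
    "ClassifierThresholds",
    "CellFeatures",
    "lipofuscin_thresholds",
    "detect_lipofuscin",
    "lipofuscin_score",
    "extract_features",
    "classify_cell",
    "classify_nuclei",
]

CELL_TYPE_LABELS = ("ZG", "ZF", "ZR", "chromaffin", "cellblock", "unknown")


@dataclass(frozen=True)
class ZoneLayout:
    """Row boundaries of the tissue bands (capsule at the top).

    ``cortex_start`` is the capsule/ZG boundary and ``cortex_end`` the
    ZR/medulla boundary; normalized depth 0..1 spans the cortex, with
    values > 1 inside the medulla.
    """

    cortex_start: float
    zg_end: float
    zf_end: float
    cortex_end: float
    height: int

    @classmethod
    def from_fractions(
        cls, height: int, capsule: float, zg: float, zf: float, zr: float
    ) -> "ZoneLayout":
        if capsule + zg + zf + zr > 1.0 + 1e-9:
            raise ValueError("band fractions sum above 1")
        c0 = capsule * height
        return cls(
            cortex_start=c0,
            zg_end=c0 + zg * height,
            zf_end=c0 + (zg + zf) * height,
            cortex_end=c0 + (zg + zf + zr) * height,
            height=height,
        )

    def depth(self, row: float) -> float:
        """Normalized cortical depth of an image row."""
        thickness = self.cortex_end - self.cortex_start
        if thickness <= 0:
            raise ValueError("degenerate layout: zero cortex thickness")
        return (row - self.cortex_start) / thickness

    @property
    def zg_depth_max(self) -> float:
        return (self.zg_end - self.cortex_start) / (self.cortex_end - self.cortex_start)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Tunable thresholds of the rule cascade (defaults set on phantoms)."""

    tau_zr: float = 0.15  # min lipofuscin score for a ZR call
    mad_k: float = 6.0  # lipofuscin pixel threshold: background + k*MAD
    ring_width_px: int = 3
    chromaffin_ecc_max: float = 0.7  # nucleus regularity for a chromaffin call
    zg_density_min: float = 4e-4  # nuclei per px^2 in the neighborhood
    density_radius_px: float = 40.0


@dataclass(frozen=True)
class CellFeatures:
    nucleus_id: int
    area_px: int
    eccentricity: float
    ring_mean_cy3: float
    ring_mean_fitc: float
    lipofuscin_score: float | None
    depth: float
    local_density: float


def lipofuscin_thresholds(
    cy3: np.ndarray,
    fitc: np.ndarray,
    labels: np.ndarray,
    k: float = 6.0,
) -> tuple[float, float]:
    """Per-channel brightness thresholds: background median + k * MAD."""
    thr = []
    for plane in (cy3, fitc):
        bgpix = np.asarray(plane, dtype=float)[labels == 0]
        if bgpix.size == 0:
            raise ValueError("no background pixels to derive lipofuscin thresholds")
        med = np.median(bgpix)
        mad = np.median(np.abs(bgpix - med))
        thr.append(float(med + k * mad))
    return thr[0], thr[1]


def detect_lipofuscin(
    cy3: np.ndarray,
    fitc: np.ndarray,
    labels: np.ndarray,
    k: float = 6.0,
) -> np.ndarray:
    """Extranuclear pixels bright in both probe channels (yellow pigment)."""
    t_cy3, t_fitc = lipofuscin_thresholds(cy3, fitc, labels, k=k)
    return (np.asarray(cy3) > t_cy3) & (np.asarray(fitc) > t_fitc) & (labels == 0)


def _ring_mask(
    nucleus_mask: np.ndarray, all_nuclei: np.ndarray, ring_width: int
) -> np.ndarray:
    if ring_width < 1:
        raise ValueError("ring width must be >= 1")
    dilated = ndi.binary_dilation(nucleus_mask, iterations=ring_width)
    return dilated & ~all_nuclei


def lipofuscin_score(
    nucleus_mask: np.ndarray,
    cy3: np.ndarray,
    fitc: np.ndarray,
    thresholds: tuple[float, float],
    all_nuclei: np.ndarray | None = None,
    ring_width: int = 3,
) -> float | None:
    """Fraction of perinuclear-ring pixels jointly above both thresholds.

    Returns ``None`` when the ring is empty (e.g. a border nucleus), in
    which case the cell type cannot be assigned from autofluorescence.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    occupied = nucleus_mask if all_nuclei is None else np.asarray(all_nuclei, dtype=bool)
    ring = _ring_mask(nucleus_mask, occupied, ring_width)
    # clip the ring at the image border: pixels outside simply don't exist
    if not ring.any():
        return None
    t_cy3, t_fitc = thresholds
    joint = (np.asarray(cy3)[ring] > t_cy3) & (np.asarray(fitc)[ring] > t_fitc)
    return float(np.mean(joint))


def extract_features(
    labels: np.ndarray,
    cy3: np.ndarray,
    fitc: np.ndarray,
    layout: ZoneLayout | None = None,
    thresholds: ClassifierThresholds | None = None,
    lipofuscin_mask: np.ndarray | None = None,
) -> list[CellFeatures]:
    """Per-nucleus features feeding the classification cascade."""
    cfg = thresholds or ClassifierThresholds()
    labels = np.asarray(labels)
    all_nuclei = labels > 0
    try:
        bg_cy3 = estimate_background(cy3, labels, lipofuscin_mask)
        bg_fitc = estimate_background(fitc, labels, lipofuscin_mask)
        del bg_cy3, bg_fitc
        lip_thr = lipofuscin_thresholds(cy3, fitc, labels, k=cfg.mad_k)
    except ValueError:
        lip_thr = (np.inf, np.inf)

    props = regionprops(labels)
    centroids = np.array([p.centroid for p in props]) if props else np.empty((0, 2))
    out: list[CellFeatures] = []
    for i, prop in enumerate(props):
        score = lipofuscin_score(
            labels == prop.label,
            cy3,
            fitc,
            lip_thr,
            all_nuclei=all_nuclei,
            ring_width=cfg.ring_width_px,
        )
        ring = _ring_mask(labels == prop.label, all_nuclei, cfg.ring_width_px)
        ring_cy3 = float(np.mean(np.asarray(cy3)[ring])) if ring.any() else float("nan")
        ring_fitc = float(np.mean(np.asarray(fitc)[ring])) if ring.any() else float("nan")
        if centroids.shape[0] > 1:
            d = np.hypot(*(centroids - centroids[i]).T)
            n_near = int(np.sum(d <= cfg.density_radius_px))  # includes self
            density = n_near / (np.pi * cfg.density_radius_px**2)
        else:
            density = 0.0
        depth = layout.depth(prop.centroid[0]) if layout is not None else float("nan")
        out.append(
            CellFeatures(
                nucleus_id=int(prop.label),
                area_px=int(prop.area),
                eccentricity=float(prop.eccentricity),
                ring_mean_cy3=ring_cy3,
                ring_mean_fitc=ring_fitc,
                lipofuscin_score=score,
                depth=depth,
                local_density=float(density),
            )
        )
    return out


def classify_cell(
    features: CellFeatures,
    layout: ZoneLayout | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> tuple[str, str]:
    """Deterministic rule cascade; returns ``(cell_type, rule_fired)``.

    Precedence: (1) lipofuscin autofluorescence -> ZR; (2) position past
    the cortex with a regular nucleus -> chromaffin; (3) outer cortex
    with dense packing -> ZG; (4) otherwise ZF.  Undefined score or
    missing layout falls back to ``unknown``.
    """
    cfg = thresholds or ClassifierThresholds()
    score = features.lipofuscin_score
    if score is not None and score >= cfg.tau_zr:
        return "ZR", "lipofuscin"
    if score is None or layout is None or not np.isfinite(features.depth):
        return "unknown", "no_signal_or_priors"
    if features.depth > 1.0:
        if features.eccentricity <= cfg.chromaffin_ecc_max:
            return "chromaffin", "medullary_regular_nucleus"
        return "unknown", "medullary_irregular_nucleus"
    if features.depth <= layout.zg_depth_max and features.local_density >= cfg.zg_density_min:
        return "ZG", "outer_cortex_dense"
    return "ZF", "default_cortex"


def classify_nuclei(
    features: list[CellFeatures],
    layout: ZoneLayout | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> list[tuple[str, str]]:
    return [classify_cell(f, layout, thresholds) for f in features]
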