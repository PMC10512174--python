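"""Ground-truthed synthetic slides: Q-FISH fields, cell blocks, IHC images.

No image accessions exist for the source cohort, so every imaging stage
of the pipeline is exercised on seeded phantoms that reproduce the
*statistical structure* the analysis relies on:

* layered adrenal architecture (capsule, ZG, ZF, ZR, medulla) as
  horizontal bands, nuclei as non-overlapping ellipses per band;
* per-nucleus telomere content drawn lognormally with zone-specific
  medians (defaults proportional to the control-group zone means, via
  the 8.64 kbp cell-block anchor) and distributed over discrete Cy3
  spots inside the nucleus mask;
* centromere content (FITC) with shared parameters across zones;
* lipofuscin pigment as perinuclear granules bright in BOTH probe
  channels, confined to ZR — the identification cue and a controllable
  contamination stressor;
* a same-slide cell-block field of constant telomere content sharing
  the tissue field's multiplicative channel gains, so cell-block
  normalization can be tested for gain invariance;
* Poisson photon noise followed by additive Gaussian read noise;
* brightfield double-IHC images composed via Beer-Lambert from stain
  OD vectors, with controllable per-zone positive fractions.

Everything is deterministic given (config, seed): noise-free renders
conserve integrated signal exactly (truth x gain inside each mask).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import disk, ellipse

from .ihc import MarkerRun, StainModel
from .qfish import TIG1_TELOMERE_KBP, QFISHImage

__all__ = [
    "ZoneBands",
    "SlidePhantomConfig",
    "GroundTruth",
    "SlideSimulation",
    "IHCPhantomConfig",
    "IHCSimulation",
    "simulate_qfish_slide",
    "simulate_cellblock",
    "simulate_slide_pair",
    "simulate_ihc_image",
    "lognormal_group",
    "simulate_cohort",
]

QFISH_ZONES = ("ZG", "ZF", "ZR", "chromaffin")


@dataclass(frozen=True)
class ZoneBands:
    """Band heights as fractions of image height (top to bottom)."""

    capsule: float = 0.05
    zg: float = 0.16
    zf: float = 0.32
    zr: float = 0.27
    medulla: float = 0.20

    def __post_init__(self) -> None:
        fr = (self.capsule, self.zg, self.zf, self.zr, self.medulla)
        if any(f < 0 for f in fr) or sum(fr) > 1.0 + 1e-9:
            raise ValueError("band fractions must be >= 0 and sum to <= 1")

    def rows(self, height: int) -> dict[str, tuple[int, int]]:
        """Half-open row intervals per nucleus-bearing zone."""
        edges = np.cumsum(
            [0.0, self.capsule, self.zg, self.zf, self.zr, self.medulla]
        ) * height
        e = [int(round(v)) for v in edges]
        return {
            "ZG": (e[1], e[2]),
            "ZF": (e[2], e[3]),
            "ZR": (e[3], e[4]),
            "chromaffin": (e[4], e[5]),
        }


@dataclass(frozen=True)
class SlidePhantomConfig:
    """Everything the Q-FISH phantom renderer needs; all units documented."""

    shape: tuple[int, int] = (420, 360)
    bands: ZoneBands = field(default_factory=ZoneBands)
    nuclei_per_zone: dict[str, int] = field(
        default_factory=lambda: {"ZG": 45, "ZF": 45, "ZR": 45, "chromaffin": 40}
    )
    nucleus_radius_px: tuple[float, float] = (4.5, 7.0)
    zg_radius_scale: float = 0.72  # ZG nuclei are smaller and denser
    cortex_axis_ratio: tuple[float, float] = (0.55, 0.95)
    chromaffin_axis_ratio: tuple[float, float] = (0.85, 1.0)  # regular nuclei
    # telomere content: lognormal median per zone, in kbp (cell-block
    # anchor: 8.64 kbp == content 1.0 in normalized units)
    tel_median_kbp: dict[str, float] = field(
        default_factory=lambda: {"ZG": 7.17, "ZF": 5.88, "ZR": 9.50, "chromaffin": 6.22}
    )
    tel_gsd: float = 1.18  # geometric SD (1.0 = constant)
    kbp_to_au: float = 1000.0  # integrated Cy3 a.u. per kbp at gain 1
    spots_per_nucleus: tuple[int, int] = (8, 20)
    cen_median_au: float = 8000.0  # integrated FITC a.u. per nucleus
    cen_gsd: float = 1.10
    # lipofuscin granules (ZR only), perinuclear, bright in both channels
    lipofuscin_granules: int = 14
    lipofuscin_ring_px: int = 3
    lipofuscin_radius_px: int = 2
    lipofuscin_intensity: float = 400.0
    # slide-wide multiplicative gains (sample prep / acquisition)
    gain_cy3: float = 1.0
    gain_fitc: float = 1.0
    # backgrounds and noise
    bg_dapi: float = 5.0
    bg_cy3: float = 20.0
    bg_fitc: float = 20.0
    dapi_intensity: float = 150.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    # placement
    min_separation_px: int = 2
    max_attempts_per_nucleus: int = 400
    touching_pairs: int = 0  # extra ZF nucleus pairs that touch (watershed stress)
    # cell block
    cellblock_shape: tuple[int, int] = (160, 360)
    cellblock_nuclei: int = 60
    cellblock_tel_kbp: float = TIG1_TELOMERE_KBP
    cellblock_tel_gsd: float = 1.0

    def noise_free(self) -> "SlidePhantomConfig":
        return replace(self, poisson_noise=False, read_noise_sd=0.0)


@dataclass
class GroundTruth:
    """Per-nucleus truth plus the exact label map used for rendering.

    ``nuclei`` columns: nucleus_id, zone, row, col, tel_kbp, tel_au,
    cen_au, tcr_true (content ratio, before gain and noise).
    """

    nuclei: pd.DataFrame
    labels: np.ndarray
    lipofuscin_mask: np.ndarray


@dataclass
class SlideSimulation:
    """A tissue field and its same-slide cell block (shared gains)."""

    tissue: QFISHImage
    tissue_truth: GroundTruth
    cellblock: QFISHImage
    cellblock_truth: GroundTruth
    slide_id: str


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("a seed is required for reproducible simulation")
    return np.random.default_rng(seed)


def _place_ellipse(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    row_band: tuple[int, int],
    radius_range: tuple[float, float],
    axis_ratio: tuple[float, float],
    separation: int,
    max_attempts: int,
) -> tuple[np.ndarray, np.ndarray, float, float, float, float] | None:
    """Rejection-sample one non-overlapping ellipse inside a row band."""
    h, w = occupancy.shape
    r0, r1 = row_band
    for _ in range(max_attempts):
        a = rng.uniform(*radius_range)  # major semi-axis
        b = a * rng.uniform(*axis_ratio)
        rot = rng.uniform(0.0, math.pi)
        margin = a + 1.0
        if r1 - r0 <= 2 * margin:
            return None
        cr = rng.uniform(r0 + margin, r1 - margin)
        cc = rng.uniform(margin, w - margin)
        grown = ellipse(cr, cc, a + separation, b + separation, shape=(h, w), rotation=rot)
        if occupancy[grown].any():
            continue
        rr, cc_ = ellipse(cr, cc, a, b, shape=(h, w), rotation=rot)
        if rr.size == 0:
            continue
        return rr, cc_, cr, cc, a, b
    return None


def _place_touching_pair(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    row_band: tuple[int, int],
    radius_range: tuple[float, float],
    separation: int,
    max_attempts: int,
) -> tuple[tuple[np.ndarray, np.ndarray, float, float], ...] | None:
    """Two circular nuclei whose masks touch (~1 px overlap)."""
    h, w = occupancy.shape
    r0, r1 = row_band
    for _ in range(max_attempts):
        ra = rng.uniform(*radius_range)
        rb = rng.uniform(*radius_range)
        ang = rng.uniform(0.0, 2 * math.pi)
        dist = ra + rb - 1.0
        margin = max(ra, rb) + 1.0
        if r1 - r0 <= 2 * margin + dist:
            return None
        cr1 = rng.uniform(r0 + margin + dist, r1 - margin - dist)
        cc1 = rng.uniform(margin + dist, w - margin - dist)
        cr2 = cr1 + dist * math.sin(ang)
        cc2 = cc1 + dist * math.cos(ang)
        if not (r0 + margin < cr2 < r1 - margin and margin < cc2 < w - margin):
            continue
        grown1 = ellipse(cr1, cc1, ra + separation, ra + separation, shape=(h, w))
        grown2 = ellipse(cr2, cc2, rb + separation, rb + separation, shape=(h, w))
        if occupancy[grown1].any() or occupancy[grown2].any():
            continue
        m1 = ellipse(cr1, cc1, ra, ra, shape=(h, w))
        m2 = ellipse(cr2, cc2, rb, rb, shape=(h, w))
        return (m1[0], m1[1], cr1, cc1), (m2[0], m2[1], cr2, cc2)
    return None


def _render_field(
    config: SlidePhantomConfig,
    rng: np.random.Generator,
    shape: tuple[int, int],
    zone_plan: list[tuple[str, tuple[int, int], int]],
    tel_median_kbp: dict[str, float],
    tel_gsd_by_zone: dict[str, float],
    slide_id: str,
) -> tuple[QFISHImage, GroundTruth]:
    h, w = shape
    labels = np.zeros((h, w), dtype=np.int32)
    occupancy = np.zeros((h, w), dtype=bool)
    meta: list[dict] = []
    nid = 0

    for zone, band, n in zone_plan:
        radius = config.nucleus_radius_px
        if zone == "ZG":
            radius = (radius[0] * config.zg_radius_scale, radius[1] * config.zg_radius_scale)
        ratio = (
            config.chromaffin_axis_ratio
            if zone in ("chromaffin", "cellblock")
            else config.cortex_axis_ratio
        )
        for _ in range(n):
            placed = _place_ellipse(
                rng,
                occupancy,
                band,
                radius,
                ratio,
                config.min_separation_px,
                config.max_attempts_per_nucleus,
            )
            if placed is None:
                raise ValueError(
                    f"zone {zone!r} (rows {band}) too small for the requested nuclei"
                )
            rr, cc, cr, ccen, a, b = placed
            nid += 1
            labels[rr, cc] = nid
            occupancy[rr, cc] = True
            meta.append({"nucleus_id": nid, "zone": zone, "row": cr, "col": ccen})

    # optional touching pairs (ZF band) to stress watershed splitting
    zf_band = next((band for zone, band, _ in zone_plan if zone == "ZF"), None)
    if config.touching_pairs and zf_band is not None:
        for _ in range(config.touching_pairs):
            pair = _place_touching_pair(
                rng,
                occupancy,
                zf_band,
                config.nucleus_radius_px,
                config.min_separation_px,
                config.max_attempts_per_nucleus,
            )
            if pair is None:
                raise ValueError("ZF band too crowded to place touching pairs")
            for rr, cc, cr, ccen in pair:
                nid += 1
                labels[rr, cc] = nid
                occupancy[rr, cc] = True
                meta.append({"nucleus_id": nid, "zone": "ZF", "row": cr, "col": ccen})

    # --- content rendering (signal above background, gain-free) ---
    dapi_sig = np.zeros((h, w))
    cy3_sig = np.zeros((h, w))
    fitc_sig = np.zeros((h, w))
    slices = ndi.find_objects(labels)
    spot_lo, spot_hi = config.spots_per_nucleus
    for rec in meta:
        i = rec["nucleus_id"]
        sl = slices[i - 1]
        local = labels[sl] == i
        rows, cols = np.nonzero(local)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        npix = rows.size

        dapi_sig[rows, cols] = config.dapi_intensity * rng.uniform(0.85, 1.15)

        gsd = tel_gsd_by_zone[rec["zone"]]
        tel_kbp = tel_median_kbp[rec["zone"]] * math.exp(
            rng.normal(0.0, math.log(gsd)) if gsd > 1.0 else 0.0
        )
        tel_au = tel_kbp * config.kbp_to_au
        k = min(int(rng.integers(spot_lo, spot_hi + 1)), npix)
        pick = rng.choice(npix, size=k, replace=False)
        weights = rng.dirichlet(np.ones(k))
        np.add.at(cy3_sig, (rows[pick], cols[pick]), tel_au * weights)

        cen_au = config.cen_median_au * math.exp(
            rng.normal(0.0, math.log(config.cen_gsd)) if config.cen_gsd > 1.0 else 0.0
        )
        fitc_sig[rows, cols] += cen_au / npix

        rec.update(
            tel_kbp=tel_kbp,
            tel_au=tel_au,
            cen_au=cen_au,
            tcr_true=tel_au / cen_au,
            area_px=npix,
        )

    # --- lipofuscin granules around ZR nuclei, strictly extranuclear ---
    lip_mask = np.zeros((h, w), dtype=bool)
    any_nucleus = labels > 0
    for rec in meta:
        if rec["zone"] != "ZR":
            continue
        i = rec["nucleus_id"]
        ring = (
            ndi.binary_dilation(labels == i, iterations=config.lipofuscin_ring_px)
            & ~any_nucleus
        )
        ring_rows, ring_cols = np.nonzero(ring)
        if ring_rows.size == 0:
            continue
        # spread granule centers around the ring: order by angle about the
        # nucleus centroid, take evenly spaced pixels at a random rotation
        angles = np.arctan2(ring_rows - rec["row"], ring_cols - rec["col"])
        order = np.argsort(angles, kind="stable")
        k = min(config.lipofuscin_granules, ring_rows.size)
        offset = rng.integers(ring_rows.size)
        centers = order[(offset + np.arange(k) * ring_rows.size // k) % ring_rows.size]
        for ci in centers:
            rad = int(rng.integers(1, config.lipofuscin_radius_px + 1))
            gr, gc = disk((ring_rows[ci], ring_cols[ci]), rad, shape=(h, w))
            keep = ~any_nucleus[gr, gc]
            gr, gc = gr[keep], gc[keep]
            amp = config.lipofuscin_intensity * rng.uniform(0.8, 1.2)
            cy3_sig[gr, gc] += amp
            fitc_sig[gr, gc] += amp
            lip_mask[gr, gc] = True

    dapi = config.bg_dapi + dapi_sig
    cy3 = config.gain_cy3 * (config.bg_cy3 + cy3_sig)
    fitc = config.gain_fitc * (config.bg_fitc + fitc_sig)

    planes = []
    for plane in (dapi, cy3, fitc):
        if config.poisson_noise:
            plane = rng.poisson(plane).astype(float)
        if config.read_noise_sd > 0:
            plane = plane + rng.normal(0.0, config.read_noise_sd, size=plane.shape)
        planes.append(np.clip(plane, 0.0, None))

    image = QFISHImage(dapi=planes[0], cy3=planes[1], fitc=planes[2], slide_id=slide_id)
    nuclei = pd.DataFrame(
        meta,
        columns=[
            "nucleus_id",
            "zone",
            "row",
            "col",
            "area_px",
            "tel_kbp",
            "tel_au",
            "cen_au",
            "tcr_true",
        ],
    )
    nuclei["tel_norm"] = nuclei["tel_kbp"] / TIG1_TELOMERE_KBP
    return image, GroundTruth(nuclei=nuclei, labels=labels, lipofuscin_mask=lip_mask)


def simulate_qfish_slide(
    config: SlidePhantomConfig, seed, slide_id: str = "phantom"
) -> tuple[QFISHImage, GroundTruth]:
    """Render one adrenal tissue field (capsule to medulla)."""
    rng = _as_rng(seed)
    bands = config.bands.rows(config.shape[0])
    plan = [
        (zone, bands[zone], int(config.nuclei_per_zone.get(zone, 0)))
        for zone in QFISH_ZONES
    ]
    gsd = {zone: config.tel_gsd for zone in QFISH_ZONES}
    return _render_field(
        config, rng, config.shape, plan, dict(config.tel_median_kbp), gsd, slide_id
    )


def simulate_cellblock(
    config: SlidePhantomConfig, seed, slide_id: str = "phantom"
) -> tuple[QFISHImage, GroundTruth]:
    """Render the same-slide cell-block field: constant telomere content.

    Shares the tissue field's channel gains, noise model and centromere
    parameters; telomere content is the 8.64 kbp anchor for every
    nucleus (geometric SD 1.0 by default).
    """
    rng = _as_rng(seed)
    h = config.cellblock_shape[0]
    plan = [("cellblock", (0, h), int(config.cellblock_nuclei))]
    return _render_field(
        config,
        rng,
        config.cellblock_shape,
        plan,
        {"cellblock": config.cellblock_tel_kbp},
        {"cellblock": config.cellblock_tel_gsd},
        slide_id,
    )


def simulate_slide_pair(
    config: SlidePhantomConfig, seed, slide_id: str = "phantom"
) -> SlideSimulation:
    """Tissue field plus same-slide cell block from one seeded stream."""
    rng = _as_rng(seed)
    tissue, tissue_truth = simulate_qfish_slide(config, rng, slide_id)
    block, block_truth = simulate_cellblock(config, rng, slide_id)
    return SlideSimulation(
        tissue=tissue,
        tissue_truth=tissue_truth,
        cellblock=block,
        cellblock_truth=block_truth,
        slide_id=slide_id,
    )


# --------------------------------------------------------------------------
# brightfield IHC phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IHCPhantomConfig:
    """Brightfield double-IHC phantom: Beer-Lambert composition."""

    shape: tuple[int, int] = (300, 380)
    bands: ZoneBands = field(default_factory=ZoneBands)
    cells_per_zone: dict[str, int] = field(
        default_factory=lambda: {"ZG": 22, "ZF": 22, "ZR": 22, "chromaffin": 18}
    )
    nucleus_radius_px: tuple[float, float] = (3.5, 5.5)
    ring_width_px: int = 3
    stain_model: StainModel = field(default_factory=StainModel)
    hema_nuclear_od: float = 0.7
    hema_cytoplasm_od: float = 0.05
    positive_od: dict[str, float] = field(
        default_factory=lambda: {"dab": 0.45, "vector_red": 0.6}
    )
    negative_od: float = 0.01
    # fraction of cells positive for each marker, per zone
    positive_fractions: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "cytb5": {"ZR": 1.0},
            "ki67": {"ZR": 0.05},
            "cyp17a1": {"ZF": 1.0, "ZR": 1.0},
            "cga": {"chromaffin": 1.0},
        }
    )
    noise_od_sd: float = 0.0
    max_attempts_per_cell: int = 400

    def __post_init__(self) -> None:
        for marker, zones in self.positive_fractions.items():
            for zone, frac in zones.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"{marker}/{zone}: fraction {frac} outside [0, 1]")
        self.stain_model.inverse  # raises on a degenerate matrix


@dataclass
class IHCSimulation:
    rgb: np.ndarray  # uint8 (H, W, 3)
    cells: pd.DataFrame  # cell_id, zone, row, col, <marker>_pos flags
    nuclei_labels: np.ndarray
    cytoplasm_labels: np.ndarray


def simulate_ihc_image(
    config: IHCPhantomConfig, run: MarkerRun, seed
) -> IHCSimulation:
    """Render one double-IHC field for a marker run, with truth labels.

    Per zone, ``round(fraction x n)`` cells are positive for each marker
    (a deterministic count, so configured proportions are recovered
    exactly on noise-free renders); which cells are positive is seeded.
    Only the run's markers are rendered as chromogen; all marker labels
    are recorded in the truth table regardless.
    """
    rng = _as_rng(seed)
    h, w = config.shape
    from .ihc import STAINS  # stain ordering

    bands = config.bands.rows(h)
    nuclei = np.zeros((h, w), dtype=np.int32)
    occupancy = np.zeros((h, w), dtype=bool)
    meta: list[dict] = []
    separation = 2 * config.ring_width_px + 2
    nid = 0
    for zone in QFISH_ZONES:
        n = int(config.cells_per_zone.get(zone, 0))
        for _ in range(n):
            placed = _place_ellipse(
                rng,
                occupancy,
                bands[zone],
                config.nucleus_radius_px,
                (0.75, 1.0),
                separation,
                config.max_attempts_per_cell,
            )
            if placed is None:
                raise ValueError(f"zone {zone!r} too small for the requested cells")
            rr, cc, cr, ccen, _, _ = placed
            nid += 1
            nuclei[rr, cc] = nid
            occupancy[rr, cc] = True
            meta.append({"cell_id": nid, "zone": zone, "row": cr, "col": ccen})

    cells = pd.DataFrame(meta)
    for marker, zone_fracs in config.positive_fractions.items():
        flags = np.zeros(len(cells), dtype=bool)
        for zone, frac in zone_fracs.items():
            idx = np.flatnonzero(cells["zone"].to_numpy() == zone)
            n_pos = int(round(frac * idx.size))
            if n_pos > 0:
                chosen = rng.choice(idx, size=n_pos, replace=False)
                flags[chosen] = True
        cells[f"{marker}_pos"] = flags

    from skimage.segmentation import expand_labels

    cytoplasm = np.where(
        nuclei == 0, expand_labels(nuclei, distance=config.ring_width_px), 0
    ).astype(np.int32)

    conc = np.zeros((h, w, 3))  # stain concentration maps, STAINS order
    stain_index = {name: i for i, name in enumerate(STAINS)}
    conc[..., stain_index["hematoxylin"]] += np.where(
        nuclei > 0, config.hema_nuclear_od, 0.0
    )
    conc[..., stain_index["hematoxylin"]] += np.where(
        cytoplasm > 0, config.hema_cytoplasm_od, 0.0
    )
    for marker, spec in run.markers.items():
        col = f"{marker}_pos"
        if col not in cells.columns:
            continue
        comp = nuclei if spec.compartment == "nucleus" else cytoplasm
        si = stain_index[spec.stain]
        for cell_id, positive in zip(cells["cell_id"], cells[col]):
            od = config.positive_od[spec.stain] if positive else config.negative_od
            conc[..., si] += np.where(comp == cell_id, od, 0.0)

    if config.noise_od_sd > 0:
        conc = conc + rng.normal(0.0, config.noise_od_sd, size=conc.shape)
        conc = np.clip(conc, 0.0, None)

    od_rgb = conc @ config.stain_model.matrix
    rgb = np.clip(np.round(255.0 * np.power(10.0, -od_rgb)), 0, 255).astype(np.uint8)
    return IHCSimulation(
        rgb=rgb, cells=cells, nuclei_labels=nuclei, cytoplasm_labels=cytoplasm
    )


def match_to_truth(
    truth: GroundTruth,
    centroids: np.ndarray,
    max_distance_px: float = 4.0,
) -> np.ndarray:
    """Match measured centroids to ground-truth nuclei (nearest centroid).

    Returns an array of truth ``nucleus_id`` per input centroid, with -1
    for unmatched ones.  Greedy nearest-neighbour, adequate for
    non-overlapping phantom nuclei.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    truth_xy = truth.nuclei[["row", "col"]].to_numpy(dtype=float)
    truth_ids = truth.nuclei["nucleus_id"].to_numpy()
    out = np.full(pts.shape[0], -1, dtype=int)
    if truth_xy.size == 0 or pts.size == 0:
        return out
    d = np.hypot(
        pts[:, 0:1] - truth_xy[None, :, 0], pts[:, 1:2] - truth_xy[None, :, 1]
    )
    nearest = np.argmin(d, axis=1)
    ok = d[np.arange(pts.shape[0]), nearest] <= max_distance_px
    out[ok] = truth_ids[nearest[ok]]
    return out


# --------------------------------------------------------------------------
# synthetic cohorts for statistical calibration
# --------------------------------------------------------------------------

def lognormal_group(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n lognormal values with the requested arithmetic mean and SD."""
    if n < 1:
        raise ValueError("group size must be >= 1")
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), n)


# control/PCI men zone means and SDs of the published RTL table, used as
# the default effect structure for synthetic cohorts
DEFAULT_COHORT_MEANS = {
    ("control", "zg"): (0.83, 0.05),
    ("control", "zf"): (0.68, 0.10),
    ("control", "zr"): (1.10, 0.14),
    ("control", "chromaffin"): (0.72, 0.23),
    ("PCI", "zg"): (0.90, 0.12),
    ("PCI", "zf"): (0.72, 0.11),
    ("PCI", "zr"): (0.61, 0.10),
    ("PCI", "chromaffin"): (0.62, 0.24),
}


def simulate_cohort(
    n_per_group: dict[str, int] | None = None,
    effects: dict[tuple[str, str], tuple[float, float]] | None = None,
    seed=None,
    out_dir=None,
) -> dict[str, pd.DataFrame]:
    """Draw a synthetic patient cohort in the fixture CSV schema.

    ``effects`` maps (group, cell_type) to (mean, sd) of a lognormal RTL
    distribution.  Returns ``{"patients": ..., "rtl": ..., "serum": ...}``
    data frames; with ``out_dir`` they are also written as
    ``patients.csv`` / ``rtl.csv`` / ``serum.csv`` readable by
    :func:`adrenotelo.cohort.load_cohort_tables`.
    """
    rng = _as_rng(seed)
    n_per_group = n_per_group or {"control": 7, "PCI": 10}
    effects = effects or DEFAULT_COHORT_MEANS
    cell_types = sorted({ct for (_, ct) in effects})
    patients, rtl_rows, serum_rows = [], [], []
    for group, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"group {group!r}: n must be >= 1")
        draws = {
            ct: lognormal_group(*effects[(group, ct)], n, rng) for ct in cell_types
        }
        for i in range(n):
            pid = f"S-{group}-{i + 1}"
            age = int(rng.integers(70, 96))
            duration = (
                f"{int(rng.integers(1, 24))} h"
                if group == "control"
                else f"{int(rng.integers(25, 300))} days"
            )
            patients.append(
                {
                    "patient_id": pid,
                    "group": group,
                    "sex": "M",
                    "age": age,
                    "disease_duration": duration,
                    "cause_of_death": "synthetic",
                }
            )
            rtl_rows.append(
                {"patient_id": pid}
                | {f"rtl_{ct}": round(float(draws[ct][i]), 4) for ct in cell_types}
            )
            serum_rows.append(
                {
                    "patient_id": pid,
                    "dheas_ug_dl": "NA",
                    "dheas_collection": "NA",
                    "albumin_g_dl": "NA",
                    "albumin_collection": "NA",
                }
            )
    frames = {
        "patients": pd.DataFrame(patients),
        "rtl": pd.DataFrame(rtl_rows),
        "serum": pd.DataFrame(serum_rows),
    }
    if out_dir is not None:
        from pathlib import Path

        base = Path(out_dir)
        base.mkdir(parents=True, exist_ok=True)
        for name, df in frames.items():
            df.to_csv(base / f"{name}.csv", index=False)
    return frames
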