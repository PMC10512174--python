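"""End-to-end orchestration: simulate -> quantify -> classify -> compare.

``compare_cohort`` reproduces the published comparison battery on a
cohort table set (packaged fixtures by default): Mann–Whitney for each
cell type and sex between the sudden-death control group and the
prolonged-critical-illness (PCI) group, Kruskal–Wallis with Dunn's test
across cell types within each group, serum DHEA-S and albumin
comparisons, and Spearman correlations of disease duration with ZR RTL.

RTL comparisons force the exact Mann–Whitney branch: the printed
per-patient RTLs are 2-decimal roundings of continuous NTCR means, and
that rounding manufactures ties the underlying data did not have (the
tied inputs go through full midrank enumeration, which coincides with
the tie-free recurrence when no ties exist).  Serum values are compared
in auto mode (exact when tie-free, otherwise the corrected Gaussian
branch), matching the printed analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as npstats
from .cohort import (
    CELL_TYPES,
    CohortTables,
    load_cohort_tables,
    summarize_group,
)
from .io import dump_config_yaml
from .phantom import (
    DEFAULT_COHORT_MEANS,
    SlidePhantomConfig,
    simulate_slide_pair,
)
from .qfish import (
    CellBlockReference,
    QFISHImage,
    cellblock_reference,
    compute_rtl,
    estimate_background,
    measure_nuclei,
    normalize_ntcr,
    segment_nuclei,
)
from .zones import (
    ClassifierThresholds,
    ZoneLayout,
    classify_nuclei,
    detect_lipofuscin,
    extract_features,
)

__all__ = [
    "RunConfig",
    "quantify_pair",
    "compare_cohort",
    "run_compare",
    "run_full",
    "write_manifest",
]

SEXES = ("M", "F")


# --------------------------------------------------------------------------
# slide-level quantification
# --------------------------------------------------------------------------

def quantify_pair(
    tissue: QFISHImage,
    cellblock: QFISHImage,
    layout: ZoneLayout | None = None,
    thresholds: ClassifierThresholds | None = None,
    min_block_nuclei: int = 50,
    segment_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, CellBlockReference, dict]:
    """Quantify a tissue field against its same-slide cell block.

    Returns a per-nucleus table (tel/cen signals, TCR, NTCR, lipofuscin
    score, cell type, rule fired), the cell-block reference, and a QC
    dict with drop counts.
    """
    if tissue.slide_id != cellblock.slide_id:
        raise ValueError(
            f"tissue ({tissue.slide_id!r}) and cell block ({cellblock.slide_id!r}) "
            "must come from the same slide"
        )
    seg = segment_kwargs or {}
    cfg = thresholds or ClassifierThresholds()

    block_labels = segment_nuclei(cellblock.dapi, **seg)
    block_bg_cy3 = estimate_background(cellblock.cy3, block_labels)
    block_bg_fitc = estimate_background(cellblock.fitc, block_labels)
    block_meas, block_qc = measure_nuclei(
        block_labels, cellblock.cy3, cellblock.fitc, block_bg_cy3, block_bg_fitc
    )
    reference = cellblock_reference(block_meas, cellblock.slide_id, min_block_nuclei)

    labels = segment_nuclei(tissue.dapi, **seg)
    lip = detect_lipofuscin(tissue.cy3, tissue.fitc, labels, k=cfg.mad_k)
    bg_cy3 = estimate_background(tissue.cy3, labels, lip)
    bg_fitc = estimate_background(tissue.fitc, labels, lip)
    measurements, qc = measure_nuclei(
        labels, tissue.cy3, tissue.fitc, bg_cy3, bg_fitc, lipofuscin_mask=lip
    )
    features = extract_features(
        labels, tissue.cy3, tissue.fitc, layout, cfg, lipofuscin_mask=lip
    )
    feat_by_id = {f.nucleus_id: f for f in features}
    calls = dict(
        zip(
            feat_by_id.keys(),
            classify_nuclei(list(feat_by_id.values()), layout, cfg),
        )
    )

    rows = []
    for m in measurements:
        f = feat_by_id.get(m.nucleus_id)
        cell_type, rule = calls.get(m.nucleus_id, ("unknown", "missing_features"))
        rows.append(
            {
                "nucleus_id": m.nucleus_id,
                "row": m.centroid[0],
                "col": m.centroid[1],
                "area_px": m.area_px,
                "tel_signal": m.tel_signal,
                "cen_signal": m.cen_signal,
                "tcr": m.tcr,
                "ntcr": normalize_ntcr(m.tcr, reference, slide_id=tissue.slide_id),
                "lipofuscin_score": (f.lipofuscin_score if f is not None else None),
                "cell_type": cell_type,
                "rule": rule,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "nucleus_id",
            "row",
            "col",
            "area_px",
            "tel_signal",
            "cen_signal",
            "tcr",
            "ntcr",
            "lipofuscin_score",
            "cell_type",
            "rule",
        ],
    )
    qc = {"tissue": qc, "cellblock": block_qc, "reference_mean_tcr": reference.mean_tcr}
    return df, reference, qc


# --------------------------------------------------------------------------
# the comparison battery
# --------------------------------------------------------------------------

def _test_entry(name: str, res: npstats.TestResult, alpha: float, **extra) -> dict:
    return {
        "name": name,
        "n1": res.n1,
        "n2": res.n2,
        "u_raw": res.u_raw,
        "method": res.method,
        "p": res.p_two_sided,
        "tie_present": res.tie_present,
        "significant": bool(res.p_two_sided < alpha),
        **extra,
    }


def compare_cohort(tables: CohortTables, alpha: float = 0.05) -> dict:
    """Run the full printed-comparison battery on a cohort table set."""
    report: dict = {"alpha": alpha}

    summaries = {}
    for group in ("control", "PCI"):
        for sex in SEXES:
            ages = tables.ages(group, sex)
            entry = {"n": len(ages)}
            if ages:
                s = summarize_group(ages)
                entry["age_mean"] = s.mean
            for ct in CELL_TYPES:
                vals = tables.rtl_values(group, sex, ct)
                if vals:
                    s = summarize_group(vals)
                    entry[f"rtl_{ct}_mean"] = s.mean
                    entry[f"rtl_{ct}_sd"] = s.sd
            summaries[f"{group}_{sex}"] = entry
    report["summaries"] = summaries

    rtl_comparisons = []
    for ct in CELL_TYPES:
        for sex in SEXES:
            x = tables.rtl_values("control", sex, ct)
            y = tables.rtl_values("PCI", sex, ct)
            res = npstats.mann_whitney(x, y, method="exact")
            rtl_comparisons.append(
                _test_entry(f"rtl_{ct}_{sex}", res, alpha, cell_type=ct, sex=sex)
            )
    report["rtl_comparisons"] = rtl_comparisons

    kruskal = []
    for group in ("control", "PCI"):
        for sex in SEXES:
            groups = [tables.rtl_values(group, sex, ct) for ct in CELL_TYPES]
            if any(len(g) == 0 for g in groups):
                continue
            res = npstats.kruskal_wallis_dunn(groups)
            kruskal.append(
                {
                    "group": group,
                    "sex": sex,
                    "h": res.h,
                    "df": res.df,
                    "p": res.p_two_sided,
                    "dunn_p_adjusted": {
                        f"{CELL_TYPES[i]}|{CELL_TYPES[j]}": p
                        for (i, j), p in res.dunn_p_adjusted.items()
                    },
                }
            )
    report["celltype_kruskal"] = kruskal

    serum_comparisons = []
    for analyte in ("dheas", "albumin"):
        for sex in SEXES:
            x = tables.serum_values("control", sex, analyte)
            y = tables.serum_values("PCI", sex, analyte)
            if not x or not y:
                serum_comparisons.append(
                    {"name": f"{analyte}_{sex}", "skipped": "no non-missing values"}
                )
                continue
            res = npstats.mann_whitney(x, y, method="auto")
            serum_comparisons.append(
                _test_entry(f"{analyte}_{sex}", res, alpha, analyte=analyte, sex=sex)
            )
    report["serum_comparisons"] = serum_comparisons

    correlations = []
    for sex in SEXES:
        ids = tables.patient_ids("PCI", sex)
        durations, rtls = [], []
        rtl_by_id = {r.patient_id: r for r in tables.rtl}
        for p in tables.patients:
            if p.patient_id in ids and p.patient_id in rtl_by_id:
                durations.append(p.duration_hours())
                rtls.append(rtl_by_id[p.patient_id].rtl_zr)
        if len(durations) >= 3:
            corr = npstats.spearman(durations, rtls)
            correlations.append(
                {
                    "name": f"duration_vs_rtl_zr_PCI_{sex}",
                    "sex": sex,
                    "rho": corr.rho,
                    "p": corr.p_two_sided,
                    "n": corr.n,
                }
            )
    report["duration_correlations"] = correlations
    return report


# --------------------------------------------------------------------------
# run configuration and top-level entry points
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a pipeline run; serialized into every output dir."""

    out_dir: Path | str = "adrenotelo_out"
    mode: str = "full"  # simulate | quantify | ihc | compare | full
    seed: int | None = None
    fixtures: bool = True  # compare the packaged printed tables
    fixtures_dir: Path | str | None = None
    alpha: float = 0.05
    # synthetic end-to-end mode (fixtures=False)
    n_patients_per_group: int = 3
    rtl_n_min: int = 110
    rtl_n_max: int = 120
    phantom: SlidePhantomConfig = field(default_factory=SlidePhantomConfig)


def _group_phantom_config(base: SlidePhantomConfig, group: str) -> SlidePhantomConfig:
    """Zone telomere medians for a group, via the 8.64 kbp anchor."""
    medians = {
        zone: DEFAULT_COHORT_MEANS[(group, ct)][0] * 8.64
        for zone, ct in (("ZG", "zg"), ("ZF", "zf"), ("ZR", "zr"), ("chromaffin", "chromaffin"))
    }
    return replace(base, tel_median_kbp=medians)


def _computed_rtl_tables(config: RunConfig) -> pd.DataFrame:
    """Simulate slides per synthetic patient and compute per-zone RTLs."""
    if config.seed is None:
        raise ValueError("a seed is required for the synthetic end-to-end mode")
    rng_seq = np.random.SeedSequence(config.seed)
    rows = []
    zone_to_ct = {"ZG": "zg", "ZF": "zf", "ZR": "zr", "chromaffin": "chromaffin"}
    for group in ("control", "PCI"):
        gcfg = _group_phantom_config(config.phantom, group)
        layout = ZoneLayout.from_fractions(
            gcfg.shape[0], gcfg.bands.capsule, gcfg.bands.zg, gcfg.bands.zf, gcfg.bands.zr
        )
        for i in range(config.n_patients_per_group):
            child = rng_seq.spawn(1)[0]
            seed_int = int(child.generate_state(1)[0] % (2**31))
            sim = simulate_slide_pair(gcfg, seed_int, slide_id=f"{group}-{i + 1}")
            df, _, _ = quantify_pair(sim.tissue, sim.cellblock, layout=layout)
            row = {"patient_id": f"S-{group}-{i + 1}", "group": group}
            for zone, ct in zone_to_ct.items():
                vals = df.loc[df["cell_type"] == zone, "ntcr"].to_numpy()
                rtl = compute_rtl(
                    row["patient_id"],
                    ct,
                    vals,
                    n_min=config.rtl_n_min,
                    n_max=config.rtl_n_max,
                    seed=seed_int,
                )
                row[f"rtl_{ct}"] = rtl.rtl
            rows.append(row)
    return pd.DataFrame(rows)


def _compare_computed(rtl_table: pd.DataFrame, alpha: float) -> dict:
    report: dict = {"alpha": alpha, "mode": "computed_rtl"}
    comparisons = []
    for ct in CELL_TYPES:
        col = f"rtl_{ct}"
        x = rtl_table.loc[rtl_table["group"] == "control", col].to_numpy()
        y = rtl_table.loc[rtl_table["group"] == "PCI", col].to_numpy()
        res = npstats.mann_whitney(x, y, method="exact")
        comparisons.append(_test_entry(f"rtl_{ct}", res, alpha, cell_type=ct))
    report["rtl_comparisons"] = comparisons
    report["summaries"] = {
        group: {
            f"rtl_{ct}_mean": float(
                rtl_table.loc[rtl_table["group"] == group, f"rtl_{ct}"].mean()
            )
            for ct in CELL_TYPES
        }
        for group in ("control", "PCI")
    }
    return report


def write_manifest(out_dir: Path) -> Path:
    """List every artifact in the output directory with a content hash."""
    out_dir = Path(out_dir)
    entries = []
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "MANIFEST.json":
            entries.append(
                {
                    "path": str(path.relative_to(out_dir)),
                    "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
                    "bytes": path.stat().st_size,
                }
            )
    manifest = out_dir / "MANIFEST.json"
    manifest.write_text(json.dumps({"artifacts": entries}, indent=2))
    return manifest


def _summary_text(report: dict) -> str:
    lines = ["Cohort comparison report", "=" * 24]
    for section in ("rtl_comparisons", "serum_comparisons"):
        for entry in report.get(section, []):
            if entry.get("skipped"):
                lines.append(f"{entry['name']:<24} skipped ({entry['skipped']})")
                continue
            star = "*" if entry["significant"] else " "
            lines.append(
                f"{entry['name']:<24} U={entry['u_raw']:<7g} "
                f"method={entry['method']:<9} p={entry['p']:.4f} {star}"
            )
    for entry in report.get("duration_correlations", []):
        lines.append(
            f"{entry['name']:<30} rho={entry['rho']:+.3f} p={entry['p']:.4f} n={entry['n']}"
        )
    return "\n".join(lines) + "\n"


def run_compare(config: RunConfig) -> dict:
    """Comparison battery on fixture tables; writes report + MANIFEST."""
    tables = load_cohort_tables(config.fixtures_dir)
    report = compare_cohort(tables, alpha=config.alpha)
    _write_outputs(config, report)
    return report


def run_full(config: RunConfig) -> dict:
    """Full pipeline: fixture comparison and/or synthetic end-to-end."""
    if config.fixtures:
        tables = load_cohort_tables(config.fixtures_dir)
        report = compare_cohort(tables, alpha=config.alpha)
    else:
        rtl_table = _computed_rtl_tables(config)
        report = _compare_computed(rtl_table, config.alpha)
    _write_outputs(config, report)
    return report


def _write_outputs(config: RunConfig, report: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "summary.txt").write_text(_summary_text(report))
    dump_config_yaml(config, out / "config.yaml")
    write_manifest(out)
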