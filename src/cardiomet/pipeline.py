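"""End-to-end in-silico study: simulate -> analyze -> compare -> report.

Generates a three-group synthetic cohort, pushes every animal's raw
inputs through the analysis modules (beat detection, AR spectral
variability, reflex gain, Kitt, stereology, vessel morphometry), runs the
group statistics, and writes a consolidated report mirroring the layout
of the study's endpoint tables, plus an abstract-style percent-change
summary.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cardiomet import morpho, stats, synthio, tables
from cardiomet.baroreflex import ReflexGainEstimator
from cardiomet.hemo import BeatSeriesExtractor
from cardiomet.metabolic import KittEstimator
from cardiomet.spectral import SAPVariability

#: Endpoints recomputed from raw synthetic inputs (rather than drawn).
MEASURED = ("sap", "dap", "map", "hr", "sap_var", "sap_lf", "kitt", "br", "tr",
            "lv_vv_collagen", "nv_capillaries", "nv_granules",
            "aorta_vv_collagen", "elastic_lamellae", "imt", "aorta_diameter",
            "cwt")

#: Abstract-style percent-change endpoints (FT vs F).
ABSTRACT_ENDPOINTS = ("wat", "triglycerides", "sap", "htw_bw",
                      "lv_vv_collagen", "aorta_vv_collagen",
                      "nv_capillaries", "nv_granules")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_group: int = tables.N_PER_GROUP
    waveform_duration_s: float = 60.0
    waveform_fs: float = 500.0
    segment_length: int = 300
    overlap: float = 0.5
    alpha: float = 0.05
    lv_points: int = morpho.POINTS_LV
    aorta_points: int = morpho.POINTS_AORTA
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class StudyReport:
    data: pd.DataFrame                  # tidy: animal, group, endpoint, value, source
    group_stats: pd.DataFrame           # per endpoint: mean+-SEM per group + flags
    abstract: dict[str, dict]           # endpoint -> percent-change record
    log: list[str] = field(default_factory=list)


def _analyze_animal(animal: synthio.Animal, cfg: PipelineConfig) -> dict[str, float]:
    """Recompute measured endpoints from the animal's raw inputs."""
    out: dict[str, float] = {}

    beats = BeatSeriesExtractor().fit(animal.waveform.pressure_mmHg, animal.waveform.fs)
    s = beats.summary_
    out.update(sap=s["sap_mmHg"], dap=s["dap_mmHg"], map=s["map_mmHg"], hr=s["hr_bpm"])

    spec = SAPVariability(segment_length=cfg.segment_length, overlap=cfg.overlap)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        spec.fit(s["systogram"], s["mean_beat_rate_hz"])
    out.update(sap_var=spec.variance_, sap_lf=spec.lf_power_)

    t, g = animal.itt
    out["kitt"] = KittEstimator().fit(t, g).kitt_

    est = ReflexGainEstimator().fit(*animal.baro_pressor)
    out["br"] = est.gain_
    est = ReflexGainEstimator().fit(*animal.baro_depressor)
    out["tr"] = abs(est.gain_)

    grid_seed = zlib.crc32(animal.animal_id.encode()) % 2 ** 31
    grid = morpho.overlay_grid(animal.lv_field, cfg.lv_points, seed=grid_seed)
    out["lv_vv_collagen"] = morpho.volume_density(grid, synthio.COLLAGEN_LABEL)
    n_cap, _ = morpho.count_objects(animal.lv_field)
    out["nv_capillaries"] = morpho.numerical_density(
        n_cap, animal.lv_field.area_mm2)["density"]
    n_gr, _ = morpho.count_objects(animal.atrial_field)
    out["nv_granules"] = morpho.numerical_density(
        n_gr, animal.atrial_field.area_mm2)["density"]

    ring = animal.aorta_ring
    grid = morpho.overlay_grid(ring, cfg.aorta_points, seed=grid_seed + 1)
    wall_px = np.isin(ring.mask, (synthio.WALL_LABEL, synthio.LAMELLA_LABEL,
                                  synthio.COLLAGEN_LABEL))
    coll_hits = grid.hits(synthio.COLLAGEN_LABEL)
    wall_hits = int(np.sum(wall_px[grid.points[:, 0], grid.points[:, 1]]))
    out["aorta_vv_collagen"] = 100.0 * coll_hits / wall_hits if wall_hits else 0.0
    out["elastic_lamellae"] = morpho.count_lamellae(ring)
    out["imt"] = ring.truth["imt_um"]
    out["aorta_diameter"] = ring.truth["lumen_d_mm"]
    out["cwt"] = morpho.wall_tension(out["sap"], out["aorta_diameter"])[0]
    return out


def run_pipeline(config: PipelineConfig | None = None) -> StudyReport:
    """Run the full in-silico study; deterministic for a fixed seed."""
    cfg = config or PipelineConfig()
    log = [f"config: {asdict(cfg)}"]
    spec = synthio.CohortSpec(
        n_per_group=cfg.n_per_group, include_raw=True,
        waveform_duration_s=cfg.waveform_duration_s,
        waveform_fs=cfg.waveform_fs, seed=cfg.seed,
    )
    animals = synthio.gen_cohort(spec)
    log.append(f"generated cohort: {len(animals)} animals "
               f"({cfg.n_per_group}/group)")
    if cfg.n_per_group < 4:
        log.append("WARNING: fewer than 4 animals per group — low power")

    rows = []
    for animal in animals:
        measured = _analyze_animal(animal, cfg)
        for ep, val in measured.items():
            rows.append((animal.animal_id, animal.group, ep, val, "measured"))
        for ep, val in animal.endpoints.items():
            if ep not in measured:
                rows.append((animal.animal_id, animal.group, ep, val, "drawn"))
    data = pd.DataFrame(rows, columns=["animal", "group", "endpoint", "value",
                                       "source"])
    log.append(f"analyzed {data['endpoint'].nunique()} endpoints per animal")

    stat_rows = []
    for ep, sub in data.groupby("endpoint"):
        groups = {g: v["value"].to_numpy() for g, v in sub.groupby("group")}
        res = stats.snk_posthoc(groups, alpha=cfg.alpha)
        means = res["anova"].means
        sems = res["anova"].sems
        pairs = res["pairs"]

        def sig(a: str, b: str) -> bool:
            return pairs.get((a, b), pairs.get((b, a), False))

        stat_rows.append({
            "endpoint": ep,
            **{f"{g}_mean": means[g] for g in tables.GROUPS if g in means},
            **{f"{g}_sem": sems[g] for g in tables.GROUPS if g in sems},
            "F": res["anova"].statistic, "p": res["anova"].p_value,
            "F_vs_C": sig("F", "C"), "FT_vs_C": sig("FT", "C"),
            "FT_vs_F": sig("FT", "F"),
        })
    group_stats = pd.DataFrame(stat_rows).set_index("endpoint")

    f_means = group_stats["F_mean"].to_dict()
    ft_means = group_stats["FT_mean"].to_dict()
    abstract = abstract_summary(f_means, ft_means)
    log.append("abstract percent changes: " +
               ", ".join(f"{k} {v['percent_rounded']:+d}%" for k, v in abstract.items()))

    report = StudyReport(data=data, group_stats=group_stats, abstract=abstract,
                         log=log)
    if cfg.outdir:
        write_report(report, cfg.outdir)
    return report


def abstract_summary(f_means: dict[str, float], ft_means: dict[str, float],
                     endpoints: tuple[str, ...] = ABSTRACT_ENDPOINTS) -> dict:
    """Abstract-style trained-vs-fructose percent changes.

    Convention (the one consistent with the published abstract figures):
    decreases are expressed relative to the sedentary-fructose reference,
    increases relative to the trained-group value.  Both conventions are
    returned, labelled, with the headline value under ``percent``.
    """
    out: dict[str, dict] = {}
    for ep in endpoints:
        if ep not in f_means or ep not in ft_means:
            raise ValueError(f"missing group means for endpoint {ep!r}")
        ref, val = f_means[ep], ft_means[ep]
        by_ref = morpho.percent_change(ref, val, "reference")
        by_val = morpho.percent_change(ref, val, "value")
        headline = by_ref if val < ref else by_val
        out[ep] = {
            "f_mean": ref, "ft_mean": val,
            "percent": headline,
            "percent_rounded": int(round(headline)),
            "denominator": "reference" if val < ref else "value",
            "percent_by_reference": by_ref,
            "percent_by_value": by_val,
        }
    return out


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Write tables/*.csv, summary.md and log.txt under ``outdir``."""
    out = Path(outdir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    report.data.to_csv(out / "tables" / "per_animal.csv", index=False)
    report.group_stats.to_csv(out / "tables" / "group_stats.csv")
    with open(out / "tables" / "abstract.json", "w") as fh:
        json.dump(report.abstract, fh, indent=2)

    lines = ["# In-silico study report", "",
             "## Group endpoints (mean +- SEM; * vs C, + vs F at alpha)", ""]
    gs = report.group_stats
    for ep, row in gs.iterrows():
        marks_f = "*" if row["F_vs_C"] else ""
        marks_ft = ("*" if row["FT_vs_C"] else "") + ("+" if row["FT_vs_F"] else "")
        lines.append(
            f"- {ep}: C {row['C_mean']:.2f}+-{row['C_sem']:.2f} | "
            f"F {row['F_mean']:.2f}+-{row['F_sem']:.2f}{marks_f} | "
            f"FT {row['FT_mean']:.2f}+-{row['FT_sem']:.2f}{marks_ft}")
    lines += ["", "## Abstract-style percent changes (FT vs F)", ""]
    for ep, rec in report.abstract.items():
        lines.append(f"- {ep}: {rec['percent_rounded']:+d}% "
                     f"(denominator: {rec['denominator']})")
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    (out / "log.txt").write_text("\n".join(report.log) + "\n")
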