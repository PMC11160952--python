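"""End-to-end orchestration: images + annotations -> metrics -> statistics.

The pipeline is manifest-driven: a CSV manifest lists one row per eye and
plexus (patient id, side, DR stage, plexus, image path, FAZ trace path for
the SCP, age, sex, HbA1c).  ``run_pipeline`` binarizes each image, builds
the ETDRS grid from the FAZ-trace centroid, measures vessel density per
sector, fractal dimension, and FAZ metrics, pairs the eyes, and fits the
cohort statistics, writing ``metrics.csv``, ``intereye.csv``,
``stats.json`` and ``run.log`` to the output directory.

``simulate_image_cohort`` produces a fully synthetic input set (images, FAZ
traces, manifest) so the whole chain can run without clinical data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .segmentation import (EnFaceImage, BinarizationParams, BinaryVesselMap,
                           analysis_mask, big_vessel_mask, binarize,
                           STD_COEFF_ALL_VESSELS, STD_COEFF_BIG_VESSELS)
from .etdrs import build_grid
from .density import vessel_density
from .fractal import fractal_dimension
from .faz import FazTrace, faz_metrics, read_faz_trace, write_faz_trace
from .intereye import pair_eyes
from .cohort_stats import (MixedModelSpec, branch_and_contrast,
                           fit_intereye_model, kruskal_wallis, stage_summary,
                           wilcoxon_signed_rank)
from .synthetic import STAGES, ImageGenParams, generate_angiogram_pair

logger = logging.getLogger(__name__)

MIXED_MODEL_METRICS = ("vd_scp_total", "vd_scp_ir", "vd_scp_or",
                       "vd_dcp_total", "vd_dcp_ir", "vd_dcp_or",
                       "fd_scp", "fd_dcp", "faza", "fazp", "fazc")


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str = ""
    output_dir: str = "octa_out"
    pixel_pitch: float = 0.012
    std_coeff_all: float = STD_COEFF_ALL_VESSELS
    std_coeff_big: float = STD_COEFF_BIG_VESSELS
    big_dilation: int = 0
    fd_box_sizes: tuple[int, ...] | None = None
    fd_restrict_to_disc: bool = False
    dcp_exclude_projection: bool = True
    alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (self.std_coeff_all > 0 and self.std_coeff_big > 0):
            raise ValueError("threshold coefficients must be positive")
        if self.big_dilation < 0:
            raise ValueError("big_dilation must be >= 0")


def load_image(path: str | Path, pixel_pitch: float, **meta) -> EnFaceImage:
    """Read an 8-bit grayscale PNG/TIFF en-face image."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    arr = np.asarray(Image.open(path).convert("L"))
    return EnFaceImage(pixels=arr, pixel_pitch=pixel_pitch, **meta)


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8)).save(path)


def quantify_eye(scp: EnFaceImage, dcp: EnFaceImage | None, faz_trace: FazTrace,
                 config: PipelineConfig) -> dict[str, float]:
    """All per-eye metrics from the SCP (and optionally DCP) image pair.

    SCP: vessels at std_coeff_all, big vessels at std_coeff_big (dilated),
    big vessels excluded from density and fractal dimension; DCP: projection
    artifacts approximated by the SCP big-vessel footprint when enabled.
    The ETDRS grid is centered on the FAZ-trace centroid.
    """
    from shapely.geometry import Polygon

    centroid = Polygon(faz_trace.polygon).centroid
    grid = build_grid((centroid.x, centroid.y), scp.pixel_pitch, scp.size)

    all_scp = binarize(scp, BinarizationParams(config.std_coeff_all))
    big_scp = big_vessel_mask(scp, dilation_radius=config.big_dilation)
    cap_scp, excl_scp = analysis_mask(all_scp, big_scp, plexus="SCP")

    restrict = grid.total if config.fd_restrict_to_disc else None
    fd_scp = fractal_dimension(cap_scp, restrict=restrict,
                               box_sizes=config.fd_box_sizes)
    vd_scp = vessel_density(cap_scp, excl_scp, grid)
    fazm = faz_metrics(faz_trace)

    out = {
        "vd_scp_total": vd_scp.vd_total, "vd_scp_ir": vd_scp.vd_ir,
        "vd_scp_or": vd_scp.vd_or, "fd_scp": fd_scp.fd,
        "faza": fazm.faza, "fazp": fazm.fazp, "fazc": fazm.fazc,
    }
    if dcp is not None:
        all_dcp = binarize(dcp, BinarizationParams(config.std_coeff_all))
        cap_dcp, excl_dcp = analysis_mask(
            all_dcp, big_scp, plexus="DCP",
            exclude_projection=config.dcp_exclude_projection)
        vd_dcp = vessel_density(cap_dcp, excl_dcp, grid)
        fd_dcp = fractal_dimension(cap_dcp, restrict=restrict,
                                   box_sizes=config.fd_box_sizes)
        out.update({"vd_dcp_total": vd_dcp.vd_total, "vd_dcp_ir": vd_dcp.vd_ir,
                    "vd_dcp_or": vd_dcp.vd_or, "fd_dcp": fd_dcp.fd})
    if grid.clipped:
        out["qc_grid_clipped"] = 1.0
    return out


def _read_manifest(path: str | Path) -> pd.DataFrame:
    mf = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "side", "stage", "plexus", "image",
                "age", "sex", "hba1c"}
    missing = required - set(mf.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    dup = mf.duplicated(subset=["patient_id", "side", "plexus"])
    if dup.any():
        row = mf.loc[dup.idxmax()]
        raise ValueError(f"duplicate eye in manifest: {row['patient_id']} "
                         f"{row['side']} {row['plexus']}")
    return mf


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis on a manifest; returns the stats report dict.

    Writes ``metrics.csv`` (tidy per-eye metrics), ``intereye.csv``
    (per-patient paired differences), ``stats.json`` and ``run.log`` to
    ``config.output_dir``.  Every input eye ends up either in the metrics
    table or in the exclusion log with a reason.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"octa-intereye {__version__}", f"config: {asdict(config)}"]

    mf = _read_manifest(config.manifest)
    base = Path(config.manifest).parent

    metric_rows, exclusions = [], []
    for (pid, side), grp in mf.groupby(["patient_id", "side"], sort=True):
        by_plexus = {row["plexus"].upper(): row for _, row in grp.iterrows()}
        if "SCP" not in by_plexus:
            exclusions.append(f"{pid}/{side}: no SCP image in manifest")
            continue
        scp_row = by_plexus["SCP"]
        try:
            scp = load_image(base / scp_row["image"], config.pixel_pitch,
                             eye_side=side, plexus="SCP", patient_id=pid)
            faz_path = scp_row.get("faz", "")
            if not isinstance(faz_path, str) or not faz_path:
                raise FileNotFoundError(f"no FAZ trace for {pid}/{side}")
            trace = read_faz_trace(base / faz_path, config.pixel_pitch)
            dcp = None
            if "DCP" in by_plexus:
                dcp = load_image(base / by_plexus["DCP"]["image"], config.pixel_pitch,
                                 eye_side=side, plexus="DCP", patient_id=pid)
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"manifest row {pid}/{side}: {exc}") from exc
        try:
            values = quantify_eye(scp, dcp, trace, config)
        except ValueError as exc:
            exclusions.append(f"{pid}/{side}: {exc}")
            continue
        for metric, value in values.items():
            metric_rows.append((pid, side, scp_row["stage"], float(scp_row["age"]),
                                scp_row["sex"], float(scp_row["hba1c"]),
                                metric, round(float(value), 6)))

    metrics = pd.DataFrame(metric_rows, columns=["patient_id", "side", "stage",
                                                 "age", "sex", "hba1c",
                                                 "metric", "value"])
    metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.6f")

    pairs, unpaired = pair_eyes(metrics[~metrics["metric"].str.startswith("qc_")]
                                if not metrics.empty else metrics)
    exclusions.extend(f"unpaired: {u}" for u in unpaired)
    pairs_out = pairs.copy()
    for col in ("right", "left", "delta_abs", "asymmetry_index"):
        pairs_out[col] = pairs_out[col].astype(float).round(6)
    pairs_out.to_csv(outdir / "intereye.csv", index=False, float_format="%.6f")

    report = cohort_statistics(metrics, pairs, alpha=config.alpha)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)

    log_lines += [f"eyes quantified: {metrics[['patient_id', 'side']].drop_duplicates().shape[0]}",
                  f"pairs: {pairs['patient_id'].nunique() if not pairs.empty else 0}"]
    log_lines += [f"excluded {e}" for e in exclusions]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def cohort_statistics(metrics: pd.DataFrame, pairs: pd.DataFrame,
                      alpha: float = 0.05) -> dict:
    """Stage-wise rank tests plus per-metric mixed models on a tidy table.

    Mirrors the cohort workflow: Kruskal-Wallis of asymmetry measures across
    stages, Wilcoxon signed-rank of inner- vs outer-ring asymmetry, and one
    mixed model per response metric with the branch-and-contrast logic.
    """
    report: dict = {"alpha": alpha, "rank_tests": {}, "mixed_models": {}}

    if not pairs.empty:
        for metric, grp in pairs.groupby("metric"):
            kw: dict = {}
            for measure in ("asymmetry_index", "delta_abs"):
                groups = [g[measure].to_numpy() for _, g in grp.groupby("stage")]
                if len(groups) >= 2 and all(len(g) for g in groups):
                    res = kruskal_wallis(groups)
                    kw[measure] = {"statistic": res.statistic, "p_value": res.p_value}
            if kw:
                report["rank_tests"][metric] = kw
        # inner vs outer ring asymmetry, per plexus
        for plexus in ("scp", "dcp"):
            ir = pairs[pairs["metric"] == f"vd_{plexus}_ir"].set_index("patient_id")
            orr = pairs[pairs["metric"] == f"vd_{plexus}_or"].set_index("patient_id")
            common = ir.index.intersection(orr.index)
            if len(common) >= 5:
                for measure in ("asymmetry_index", "delta_abs"):
                    d = (ir.loc[common, measure] - orr.loc[common, measure]).to_numpy()
                    if np.any(d != 0):
                        res = wilcoxon_signed_rank(d)
                        report["rank_tests"][f"vd_{plexus}_ir_vs_or_{measure}"] = {
                            "statistic": res.statistic, "p_value": res.p_value,
                            "n": len(common)}

    for metric in MIXED_MODEL_METRICS:
        sub = metrics[metrics["metric"] == metric]
        if sub.empty:
            continue
        cohort = sub.rename(columns={"value": "response"})
        try:
            fit = fit_intereye_model(cohort, MixedModelSpec(response="response",
                                                            alpha=alpha))
            rep = branch_and_contrast(fit)
            rep["response"] = metric
            report["mixed_models"][metric] = rep
        except (ValueError, np.linalg.LinAlgError) as exc:
            report["mixed_models"][metric] = {"error": str(exc)}
    return report


def summarize(metrics: pd.DataFrame, pairs: pd.DataFrame | None = None
              ) -> dict[str, pd.DataFrame]:
    """Descriptive summaries: mean +/- SD per stage x side x metric, and
    median (Q1; Q3) of the intereye asymmetry measures per stage."""
    per_cell = (metrics.groupby(["metric", "stage", "side"])["value"]
                .agg(mean="mean", sd="std", n="count").reset_index())
    per_cell["sd"] = per_cell["sd"].fillna(0.0)
    out = {"by_stage_side": per_cell}
    if pairs is not None and not pairs.empty:
        out["intereye_by_stage"] = stage_summary(pairs)
    return out


# ---------------------------------------------------------------------------
# synthetic input set
# ---------------------------------------------------------------------------

def simulate_image_cohort(outdir: str | Path, n_patients: int = 10,
                          seed: int = 0,
                          image_params: ImageGenParams | None = None,
                          left_capillary_delta: float = -0.009,
                          stages: tuple[str, ...] = STAGES) -> Path:
    """Write a synthetic image cohort (PNGs, FAZ traces, manifest.csv).

    Patients cycle through the DR stages; each eye gets an SCP and a DCP
    image (the DCP drawn with slightly denser coverage, as in real scans)
    and the SCP ground-truth FAZ polygon is written as the manual trace.
    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = image_params if image_params is not None else ImageGenParams()
    rng = np.random.default_rng([seed, 99])
    rows = []
    for i in range(n_patients):
        stage = stages[i % len(stages)]
        pid = f"S{i:03d}"
        age = float(np.round(rng.normal(57.2, 13.1), 1))
        sex = "male" if rng.uniform() < 111 / 168 else "female"
        hba1c = float(np.round(rng.normal(7.34, 1.32), 2))
        for plexus, frac_shift in (("SCP", 0.0), ("DCP", 0.015)):
            params = replace(base,
                             capillary_fraction=base.capillary_fraction + frac_shift,
                             left_capillary_delta=(left_capillary_delta
                                                   if plexus == "SCP" else 0.0),
                             seed=int(np.random.default_rng(
                                 [seed, i, 0 if plexus == "SCP" else 1]
                             ).integers(0, 2**31)))
            right, left, truth_r, truth_l = generate_angiogram_pair(params)
            for side, img, truth in (("right", right, truth_r), ("left", left, truth_l)):
                name = f"{pid}_{side}_{plexus.lower()}"
                Image.fromarray(img.pixels).save(outdir / f"{name}.png")
                faz_name = ""
                if plexus == "SCP":
                    faz_name = f"{name}_faz.csv"
                    write_faz_trace(FazTrace(truth.faz_polygon, params.pixel_pitch),
                                    outdir / faz_name)
                rows.append((pid, side, stage, plexus, f"{name}.png", faz_name,
                             age, sex, hba1c))
    manifest = pd.DataFrame(rows, columns=["patient_id", "side", "stage", "plexus",
                                           "image", "faz", "age", "sex", "hba1c"])
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path
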