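"""Per-condition summaries and the end-to-end synthetic pipeline driver.

Results are reported as mean ± sample SD (n−1 denominator) per condition
and metric. ``run_pipeline`` executes the full analysis on seeded synthetic
fields described by a JSON config; re-running the same config reproduces
every output byte-for-byte. Hypothesis testing (ANOVA, t-tests, mixed
models) is out of scope here — exported tables are shaped
(condition, replicate, metric, value) for standard statistical software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clusters as clusters_mod
from . import elongation as elong_mod
from . import markers as markers_mod
from . import myotubes as myotubes_mod
from . import nuclei as nuclei_mod
from . import synthetic
from .errors import ConfigError
from .io_core import ResultsTable, write_table

logger = logging.getLogger("nmjquant")


@dataclass
class ConditionSummary:
    condition: str
    metric: str
    n: int
    mean: float
    sd: float
    per_replicate_values: list[float] = field(default_factory=list)
    sd_degenerate: bool = False  # True when n == 1 and sd is reported as 0


def summarize(
    table: ResultsTable,
    group_keys: list[str] | None = None,
    metrics: list[str] | None = None,
) -> list[ConditionSummary]:
    """Grouped mean and sample SD, deterministic lexicographic group order."""
    if group_keys is None:
        group_keys = ["condition", "metric"]
    if metrics is not None:
        available = {row["metric"] for row in table.rows}
        missing = set(metrics) - available
        if missing:
            raise KeyError(f"metric(s) not present in table: {sorted(missing)}")
    groups: dict[tuple, list[float]] = {}
    meta: dict[tuple, dict] = {}
    for row in table.rows:
        if metrics is not None and row["metric"] not in metrics:
            continue
        key = tuple(row[k] for k in group_keys)
        groups.setdefault(key, []).append(row["value"])
        meta.setdefault(key, row)
    out = []
    for key in sorted(groups):
        values = groups[key]
        n = len(values)
        out.append(
            ConditionSummary(
                condition=str(meta[key].get("condition", key[0])),
                metric=str(meta[key]["metric"]),
                n=n,
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)) if n > 1 else 0.0,
                per_replicate_values=list(values),
                sd_degenerate=(n == 1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# pipeline


_SYNTH_KINDS = {"nuclei", "cell_body", "coculture"}


def _build_spec(sim: dict, seed: int, pixel_size_um: float) -> synthetic.SynthSpec:
    params = {k: v for k, v in sim.items() if k != "kind"}
    params.setdefault("pixel_size_um", pixel_size_um)
    if "image_shape" in params:
        params["image_shape"] = tuple(params["image_shape"])
    return synthetic.SynthSpec(seed=seed, **params)


def run_pipeline(config: str | Path) -> ResultsTable:
    """Run the configured stages over every condition/replicate and write CSVs.

    The config is JSON with keys ``out_dir``, ``pixel_size_um``,
    ``conditions`` (each with ``name``, ``seeds`` and a ``simulate`` block
    whose ``kind`` is one of nuclei / cell_body / coculture) and ``stages``
    (any of ``nuclei``, ``markers``, ``elongation``, ``clusters``,
    ``myotubes`` with their parameters). Every threshold used is logged
    with its provenance, since user-defined thresholds are the analysis'
    chief reproducibility gap.
    """
    config = Path(config)
    cfg = json.loads(config.read_text())
    out_dir = Path(cfg.get("out_dir", "nmjquant_out"))
    if not out_dir.is_absolute():
        out_dir = config.parent / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    pixel_size_um = float(cfg.get("pixel_size_um", 0.5))
    stages: dict = cfg.get("stages", {})
    conditions: list = cfg.get("conditions", [])

    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)
        logger.info(msg)

    table = ResultsTable()
    if not conditions:
        log("warning: config lists no conditions; writing empty results")

    for cond in conditions:
        name = cond["name"]
        sim = cond.get("simulate")
        if sim is None:
            raise ConfigError(
                f"condition {name!r} has no 'simulate' block; per-stage CLI "
                "subcommands handle real image files"
            )
        kind = sim.get("kind", "nuclei")
        if kind not in _SYNTH_KINDS:
            raise ConfigError(f"unknown simulate kind {kind!r}")
        for seed in cond.get("seeds", [0]):
            rep = str(seed)
            spec = _build_spec(sim, int(seed), pixel_size_um)
            log(f"condition={name} replicate={rep} kind={kind} spec={spec}")
            if kind == "nuclei":
                _run_nuclei_field(table, name, rep, spec, stages, log)
            elif kind == "cell_body":
                _run_cell_body_field(table, name, rep, spec, stages, log)
            else:
                _run_coculture_field(table, name, rep, spec, stages, log)

    write_table(table, out_dir / "results.csv")
    summary_table = ResultsTable()
    for s in summarize(table):
        summary_table.add(s.condition, "summary", f"{s.metric}__mean", s.mean, "au")
        summary_table.add(s.condition, "summary", f"{s.metric}__sd", s.sd, "au")
    write_table(summary_table, out_dir / "summary.csv")
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return table


def _threshold_of(params: dict, key: str, stage: str, log) -> float:
    if key not in params:
        raise ConfigError(f"stage {stage!r} requires parameter {key!r}")
    log(f"stage={stage} {key}={params[key]} (user-defined)")
    return float(params[key])


def _run_nuclei_field(table, name, rep, spec, stages, log) -> None:
    dapi, marker, truth = synthetic.generate_nuclei_image(spec)
    if "nuclei" not in stages:
        raise ConfigError("nuclei-kind condition requires the 'nuclei' stage")
    npar = stages["nuclei"]
    points = nuclei_mod.detect_nuclei(
        dapi,
        min_sigma_px=npar.get("min_sigma_px", 2.0),
        max_sigma_px=npar.get("max_sigma_px", 6.0),
        detect_threshold=_threshold_of(npar, "detect_threshold", "nuclei", log),
    )
    table.add(name, rep, "n_nuclei_detected", len(points), "count")
    if "markers" in stages:
        mpar = stages["markers"]
        rule = mpar.get("rule", "point_max")
        threshold = _threshold_of(mpar, "threshold", "markers", log)
        if rule == "point_max":
            result = markers_mod.classify_point_max(marker, points, threshold)
        elif rule == "nuclear_mean":
            seg = nuclei_mod.segment_nuclei(
                dapi, points, fg_threshold=mpar.get("fg_threshold")
            )
            result = markers_mod.classify_nuclear_mean(marker, seg, threshold)
        else:
            raise ConfigError(f"unknown marker rule {rule!r}")
        table.add(name, rep, "fraction_positive", 100.0 * result.fraction_positive, "percent")
        table.add(name, rep, "n_positive", result.n_positive, "count")


def _run_cell_body_field(table, name, rep, spec, stages, log) -> None:
    stain, truth = synthetic.generate_cell_body_image(spec)
    if "elongation" not in stages:
        raise ConfigError("cell_body-kind condition requires the 'elongation' stage")
    epar = dict(stages["elongation"])
    seg_threshold = _threshold_of(epar, "seg_threshold", "elongation", log)
    params = elong_mod.ElongationParams(
        smooth_sigma_px=epar.get("smooth_sigma_px", 8.0),
        seg_threshold=seg_threshold,
        n_erosions=epar.get("n_erosions", 8),
        n_dilations=epar.get("n_dilations", 8),
        min_area_px2=epar.get("min_area_px2", 960.0),
        min_eccentricity=epar.get("min_eccentricity", 0.75),
        min_major_axis_px=epar.get("min_major_axis_px", 120.0),
    )
    if "markers" in stages:
        mpar = stages["markers"]
        centers = nuclei_mod.PointSet(truth.nucleus_centers, stain.shape)
        result = markers_mod.classify_point_max(
            stain, centers, _threshold_of(mpar, "threshold", "markers", log)
        )
        n_positive = result.n_positive
    else:
        n_positive = int(truth.nucleus_positive_flags.sum())
        log("elongation denominator from ground truth (no markers stage)")
    res = elong_mod.elongation_index(stain, n_positive, params)
    table.add(name, rep, "elongation_index", res.index, "index")
    table.add(name, rep, "n_positive", n_positive, "count")
    table.add(name, rep, "n_residual_objects", res.residual_objects.n_labels, "count")


def _run_coculture_field(table, name, rep, spec, stages, log) -> None:
    channels, truth = synthetic.generate_coculture_image(spec)
    myo_ch, btx_ch, rapsyn_ch = channels
    if "clusters" in stages:
        cpar = stages["clusters"]
        mask = clusters_mod.segment_clusters(
            btx_ch,
            threshold=_threshold_of(cpar, "threshold", "clusters", log),
            min_area_px2=cpar.get("min_area_px2", 4.0),
        )
        myo_mask, area_mm2 = clusters_mod.segment_myotubes_for_normalization(
            myo_ch,
            contrast_percentiles=tuple(cpar.get("percentiles", (1.0, 99.0))),
            threshold=cpar.get("myotube_threshold", 0.5),
        )
        tab = clusters_mod.cluster_table(mask, spec.pixel_size_um, area_mm2)
        table.add(name, rep, "n_clusters", tab.n_clusters, "count")
        table.add(name, rep, "mean_cluster_area", tab.mean_area_um2, "um2")
        table.add(name, rep, "mean_cluster_intensity", tab.mean_intensity_au, "au")
        table.add(name, rep, "myotube_area", area_mm2, "mm2")
        table.add(name, rep, "clusters_per_mm2", tab.clusters_per_mm2, "count_per_mm2")
        if "secondary_rule" in cpar:
            calls, frac = clusters_mod.score_secondary_channel(
                mask,
                rapsyn_ch,
                rule=cpar["secondary_rule"],
                threshold=cpar.get("secondary_threshold", 0.25),
            )
            table.add(name, rep, "fraction_rapsyn_positive", 100.0 * frac, "percent")
    if "myotubes" in stages:
        mpar = stages["myotubes"]
        myo_mask, _ = clusters_mod.segment_myotubes_for_normalization(
            myo_ch,
            contrast_percentiles=tuple(mpar.get("percentiles", (1.0, 99.0))),
            threshold=mpar.get("threshold", 0.5),
        )
        records = myotubes_mod.measure_myotubes(
            myo_mask, spec.pixel_size_um, float(np.prod(myo_ch.shape))
        )
        cov = myotubes_mod.coverage_by_class(records)
        table.add(name, rep, "coverage_large", cov["large"], "percent")
        table.add(name, rep, "coverage_small", cov["small"], "percent")
        table.add(name, rep, "n_myotubes", len(records), "count")
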