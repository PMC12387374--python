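"""End-to-end orchestration: parse -> climatology -> fits -> model comparison
-> multiplicity corrections -> latitude gradient -> figure-ready tables.

`run_pipeline` takes a :class:`PipelineConfig` pointing either at on-disk
Trends exports plus a metadata CSV, or at a synthetic scenario, and returns
a :class:`PipelineResult` bundle of tidy DataFrames.  When an output
directory is configured the bundle is also written as deterministic CSV/JSON
files together with a run manifest (seed, config hash, row counts), so two
runs with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic as synth
from .cosinor import CosinorFit, fit_cosinor
from .exceptions import DomainError, PerfectFitError, PipelineStageError
from .harmonics import Evidence
from .geo import GeoGradientResult, fit_latitude_gradient
from .harmonics import BimodalFit, ModelComparison, compare_models, fit_bimodal
from .multiplicity import (
    GroupSummary,
    MultiplicityRecord,
    multiplicity_frame,
    run_multiplicity,
    summary_frame,
)
from .trends import (
    Climatology,
    Group,
    LocationMeta,
    MonthlySeries,
    climatology_frame,
    monthly_climatology,
    parse_trends_csv,
    read_location_meta,
)

logger = logging.getLogger("infoseason")

_FLOAT_FMT = "%.10g"  # fixed float formatting keeps reruns byte-identical


@dataclass
class PipelineConfig:
    """Declarative configuration of one analysis run.

    Exactly one of ``series_paths`` (mapping location_id -> export path, with
    ``metadata_path``) or ``synthetic`` (scenario mapping, see
    ``_panel_from_scenario``) must be set.
    """

    series_paths: dict | None = None
    metadata_path: str | None = None
    synthetic: dict | None = None
    fit_on: str = "climatology"  # or "full"
    significance: str = "f_test"  # or "amplitude_t"
    alpha: float = 0.05
    criterion_formula: str = "log_sse"  # or "gaussian"
    bonferroni_scope: str = "pooled"  # or "per_group"
    geo_only_significant: bool = True
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.series_paths is None) == (self.synthetic is None):
            raise DomainError(
                "exactly one of series_paths or synthetic scenario must be set"
            )
        if not 0.0 < self.alpha < 1.0:
            raise DomainError("alpha must lie in (0, 1)")
        if self.fit_on not in ("climatology", "full"):
            raise DomainError(f"unknown fit_on {self.fit_on!r}")
        if self.significance not in ("f_test", "amplitude_t"):
            raise DomainError(f"unknown significance mode {self.significance!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class LocationResult:
    location_id: str
    group: Group
    uni: CosinorFit
    bi: BimodalFit
    comparison: ModelComparison


@dataclass
class PipelineResult:
    fits: pd.DataFrame
    comparisons: pd.DataFrame
    multiplicity: pd.DataFrame
    group_summary: pd.DataFrame
    geo: GeoGradientResult | None
    geo_scatter: pd.DataFrame
    heatmap: pd.DataFrame
    polar: pd.DataFrame
    climatologies: pd.DataFrame
    manifest: dict
    location_results: list[LocationResult] = field(repr=False, default_factory=list)
    records: list[MultiplicityRecord] = field(repr=False, default_factory=list)
    summaries: list[GroupSummary] = field(repr=False, default_factory=list)


def _panel_from_scenario(scenario: dict, seed: int):
    """Build (series, metas) from a synthetic scenario mapping.

    The scenario holds ``n_locations``, optional ``latitude_range``,
    ``frac_null``, ``group``, ``id_prefix`` and a ``template`` mapping of
    :class:`~infoseason.synthetic.SyntheticSpec` fields.  Multiple panels can
    be given under a ``panels`` list (one scenario mapping each); their
    locations are concatenated.
    """
    if "panels" in scenario:
        all_series, all_metas = [], []
        for i, sub in enumerate(scenario["panels"]):
            s, m = _panel_from_scenario(sub, seed + 1000 * (i + 1))
            all_series.extend(s)
            all_metas.extend(m)
        return all_series, all_metas
    template = synth.SyntheticSpec(**scenario.get("template", {}))
    return synth.generate_panel(
        n_locations=int(scenario["n_locations"]),
        template=template,
        latitude_range=tuple(scenario.get("latitude_range", (25.0, 49.0))),
        frac_null=float(scenario.get("frac_null", 0.0)),
        seed=scenario.get("seed", seed),
        group=scenario.get("group", Group.na_cities),
        id_prefix=scenario.get("id_prefix", "loc"),
    )


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        return _panel_from_scenario(config.synthetic, config.seed)
    series_list = []
    for loc_id, entry in config.series_paths.items():
        if isinstance(entry, dict):
            path, group = entry["path"], entry.get("group", "symptoms")
        else:
            path, group = entry, "symptoms"
        text = Path(path).read_text()
        series_list.append(parse_trends_csv(text, loc_id, group))
    metas = []
    if config.metadata_path:
        metas = read_location_meta(Path(config.metadata_path).read_text())
    return series_list, metas


def heatmap_matrix(
    climatologies: list[Climatology],
) -> tuple[pd.DataFrame, dict[str, bool]]:
    """12 x L matrix of per-location min-max scaled climatologies.

    Each location's column is scaled to [0, 1] relative to its own range —
    values are not comparable across separately normalized series, so only
    within-location contrast is meaningful.  A constant climatology maps to
    all 0.5 and is flagged flat.
    """
    cols = {}
    flat_flags: dict[str, bool] = {}
    for clim in climatologies:
        m = clim.monthly_mean
        rng = np.ptp(m)
        if rng == 0:
            cols[clim.location_id] = np.full(12, 0.5)
            flat_flags[clim.location_id] = True
        else:
            cols[clim.location_id] = (m - m.min()) / rng
            flat_flags[clim.location_id] = False
    df = pd.DataFrame(cols, index=pd.Index(np.arange(1, 13), name="month"))
    return df, flat_flags


def polar_table(climatologies: list[Climatology]) -> pd.DataFrame:
    """Per-location 12-point polar plot data: month, angle (rad), mean, scaled."""
    rows = []
    for clim in climatologies:
        m = clim.monthly_mean
        rng = np.ptp(m)
        scaled = np.full(12, 0.5) if rng == 0 else (m - m.min()) / rng
        for month in range(12):
            rows.append(
                {
                    "location_id": clim.location_id,
                    "month": month + 1,
                    "angle_rad": 2.0 * np.pi * month / 12.0,
                    "mean": m[month],
                    "scaled": scaled[month],
                }
            )
    return pd.DataFrame(rows)


def _fits_frame(results: list[LocationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "location_id": r.location_id,
                "group": r.group.value,
                "mesor": r.uni.mesor,
                "amplitude": r.uni.amplitude,
                "acrophase_rad": r.uni.acrophase,
                "peak_time": r.uni.peak_time,
                "peak_month": r.uni.peak_month,
                "sse": r.uni.sse,
                "n": r.uni.n,
                "t_stat": r.uni.t_stat,
                "p_amplitude": r.uni.p_amplitude,
                "p_F": r.uni.p_seasonality_F,
            }
        )
    return pd.DataFrame(rows)


def _comparisons_frame(results: list[LocationResult], q_bh: np.ndarray) -> pd.DataFrame:
    rows = []
    for r, q in zip(results, q_bh):
        c = r.comparison
        rows.append(
            {
                "location_id": r.location_id,
                "sse_uni": c.sse_uni,
                "sse_bi": c.sse_bi,
                "n": c.n,
                "delta_bic": c.delta_bic,
                "delta_aic": c.delta_aic,
                "p_second_harmonic": c.p_second_harmonic,
                "p_second_harmonic_bh": q,
                "evidence_bic": c.evidence_bic.value,
                "evidence_aic": c.evidence_aic.value,
                "gated": c.gated,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full seasonality analysis described by ``config``.

    Stage failures are wrapped in :class:`PipelineStageError` carrying the
    stage name and location id.  With ``out_dir`` set, all result tables are
    written as CSV (plus the gradient and manifest as JSON).
    """
    series_list, metas = _load_inputs(config)
    meta_by_id = {m.location_id: m for m in metas}

    climatologies: list[Climatology] = []
    results: list[LocationResult] = []
    for s in series_list:
        try:
            clim = monthly_climatology(s)
            climatologies.append(clim)
            if config.fit_on == "climatology":
                y, t = clim.monthly_mean, clim.t
            else:
                y, t = s.values, s.t
            uni = fit_cosinor(y, t)
            bi = fit_bimodal(y, t)
            try:
                comparison = compare_models(
                    uni, bi, alpha=config.alpha, criterion_formula=config.criterion_formula
                )
            except PerfectFitError:
                # zero-residual fit: ln(SSE) undefined, no criterion comparison
                comparison = ModelComparison(
                    delta_bic=float("nan"),
                    delta_aic=float("nan"),
                    evidence_bic=Evidence.excluded,
                    evidence_aic=Evidence.excluded,
                    gated=bool(bi.p_second_harmonic < config.alpha),
                    excluded=True,
                    sse_uni=uni.sse,
                    sse_bi=bi.sse,
                    n=uni.n,
                    p_second_harmonic=bi.p_second_harmonic,
                )
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise PipelineStageError("fit", s.location_id, exc) from exc
        results.append(
            LocationResult(
                location_id=s.location_id, group=s.group, uni=uni, bi=bi, comparison=comparison
            )
        )

    from .harmonics import adjust_bimodal_terms

    p2 = [r.comparison.p_second_harmonic for r in results]
    q2 = adjust_bimodal_terms(p2) if p2 else np.array([])

    records_in = [
        (r.location_id, r.group, r.uni.significance_p(config.significance))
        for r in results
    ]
    records, summaries = run_multiplicity(
        records_in, alpha=config.alpha, bonferroni_scope=config.bonferroni_scope
    )

    sig_by_id = {rec.unit_id: rec.sig_raw for rec in records}
    scatter_rows = []
    for r in results:
        meta = meta_by_id.get(r.location_id)
        if meta is None:
            continue
        if config.geo_only_significant and not sig_by_id[r.location_id]:
            continue
        scatter_rows.append(
            {
                "location_id": r.location_id,
                "latitude": meta.latitude,
                "amplitude": r.uni.amplitude,
            }
        )
    geo_scatter = pd.DataFrame(scatter_rows, columns=["location_id", "latitude", "amplitude"])
    geo_result = None
    if (
        len(geo_scatter) >= 4
        and geo_scatter["latitude"].nunique() > 1
        and geo_scatter["amplitude"].nunique() > 1
    ):
        geo_result = fit_latitude_gradient(
            geo_scatter["latitude"].to_numpy(), geo_scatter["amplitude"].to_numpy()
        )
    else:
        logger.info("geo gradient skipped: fewer than 4 usable points")

    heatmap, flat_flags = heatmap_matrix(climatologies)
    polar = polar_table(climatologies)

    fits = _fits_frame(results).sort_values("location_id", ignore_index=True)
    comparisons = _comparisons_frame(results, q2).sort_values(
        "location_id", ignore_index=True
    )
    mult = multiplicity_frame(records).sort_values("unit_id", ignore_index=True)
    summary = summary_frame(summaries).sort_values("group", ignore_index=True)
    clim_df = climatology_frame(climatologies)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_locations": len(series_list),
        "n_tests": len(records),
        "n_flat_climatologies": int(sum(flat_flags.values())),
        "geo_n_points": int(len(geo_scatter)),
    }

    result = PipelineResult(
        fits=fits,
        comparisons=comparisons,
        multiplicity=mult,
        group_summary=summary,
        geo=geo_result,
        geo_scatter=geo_scatter,
        heatmap=heatmap,
        polar=polar,
        climatologies=clim_df,
        manifest=manifest,
        location_results=results,
        records=records,
        summaries=summaries,
    )
    if config.out_dir:
        _write_outputs(result, Path(config.out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {
        "fits.csv": result.fits,
        "model_comparison.csv": result.comparisons,
        "multiplicity.csv": result.multiplicity,
        "group_summary.csv": result.group_summary,
        "geo_scatter.csv": result.geo_scatter,
        "climatologies.csv": result.climatologies,
        "polar.csv": result.polar,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / name, index=False, float_format=_FLOAT_FMT)
    result.heatmap.to_csv(out_dir / "heatmap.csv", float_format=_FLOAT_FMT)
    if result.geo is not None:
        (out_dir / "geo_gradient.json").write_text(
            json.dumps(result.geo.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    (out_dir / "run_manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
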