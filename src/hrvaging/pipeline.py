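"""End-to-end study pipeline: preprocess -> metrics/spectra -> blockade QC ->
longitudinal modelling.

`run_pipeline` consumes a cohort (a manifest of RR files, or an in-memory
synthetic cohort) and produces tidy tables at every stage:

* per-(mouse, age, state) HRV metric rows (time/fragmentation/nonlinear
  metrics on the most stationary 512-beat segment; spectral metrics
  averaged over non-overlapping 3-min windows),
* blockade QC decisions and the per-age pass-rate table,
* mixed-model fits, mouse-specific rates, autonomic signatures,
  baseline-normalised trajectories, rate correlation triangles, the rate
  dendrogram, and paired early/late rate-variability tests.

With an output directory set, every table is written as CSV, loess
trajectory plots are rendered per metric, and a markdown report is
generated purely from the tables (nothing is recomputed for the report).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from hrvaging import blockade_qc, hrv_metrics, io_preprocess, longitudinal, spectral
from hrvaging.io_preprocess import AnalysisWindow, CohortManifest, RRSeries
from hrvaging.synth import SimulatedCohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "RunConfig", "run_pipeline"]

#: metrics modelled longitudinally (HRV record fields + spectral summaries)
SPECTRAL_METRICS = ("total_power", "vlf", "lf", "hf", "vlf_pct", "lf_pct", "hf_pct",
                    "lf_hf", "beta")


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the study-standard values."""

    manifest_path: str | None = None
    data_dir: str | None = None
    output_dir: str | None = None

    range_lo_ms: float = io_preprocess.RANGE_LO_MS
    range_hi_ms: float = io_preprocess.RANGE_HI_MS
    k_sd: float = 2.0
    window_s: float = 180.0
    abk_discard_s: float = 120.0
    target_n: int = 512

    ar_order: int = spectral.DEFAULT_AR_ORDER
    resample_hz: float = spectral.DEFAULT_RESAMPLE_HZ
    band_vlf: tuple[float, float] = (0.0056, 0.152)
    band_lf: tuple[float, float] = (0.152, 1.24)
    band_hf: tuple[float, float] = (1.24, 5.0)

    qc_peak_threshold: float = blockade_qc.PEAK_RATIO_THRESHOLD
    qc_power_threshold: float = blockade_qc.POWER_RATIO_THRESHOLD

    period_split_age: float = 21.0
    rate_eval_age_early: float = 6.0
    rate_eval_age_late: float = 24.0
    cluster_height_cut: float = 0.6
    loess_span: float = 0.75

    seed: int = 0
    make_plots: bool = True

    def bands(self) -> spectral.BandDefinition:
        return spectral.BandDefinition(self.band_vlf, self.band_lf, self.band_hf)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    """All stage outputs as in-memory tables."""

    metrics: pd.DataFrame                 # tidy long table
    qc_decisions: pd.DataFrame
    qc_by_age: pd.DataFrame
    fits: pd.DataFrame
    rates: pd.DataFrame
    signature: pd.DataFrame
    baseline_normalized: pd.DataFrame
    corr_r: pd.DataFrame
    corr_p: pd.DataFrame
    cluster: longitudinal.ClusterResult | None
    rate_sd_tests: pd.DataFrame
    fit_objects: dict[tuple[str, str, str], longitudinal.LMEFit] = field(default_factory=dict)


def _load_series(manifest: CohortManifest, data_dir: Path,
                 store: dict | None) -> dict[tuple[str, float, str], RRSeries]:
    out = {}
    for row in manifest.iter_records():
        key = (row["mouse_id"], float(row["age_months"]), row["state"])
        if store is not None and key in store:
            out[key] = store[key]
            continue
        path = data_dir / row["file"]
        try:
            out[key] = io_preprocess.read_rr_file(
                path, mouse_id=row["mouse_id"],
                age_months=float(row["age_months"]), state=row["state"])
        except Exception as exc:
            logger.warning("skipping %s: %s", path, exc)
    return out


def _recording_metrics(series: RRSeries, cfg: RunConfig) -> tuple[dict, list[spectral.WindowSpectrum]]:
    """Metric dict + window spectra for one cleaned recording."""
    windows = io_preprocess.make_windows(series, window_s=cfg.window_s,
                                         abk_discard_s=cfg.abk_discard_s)
    spectra = []
    for w in windows:
        try:
            spectra.append(spectral.estimate_psd(
                w, method="ar", ar_order=cfg.ar_order,
                resample_hz=cfg.resample_hz, bands=cfg.bands()))
        except spectral.TooShortError:
            continue
    seg = io_preprocess.select_stationary_segment(series, target_n=cfg.target_n)
    rec = hrv_metrics.compute_hrv_record(seg.intervals)
    metrics = rec.as_dict()
    metrics.pop("n_intervals", None)
    if spectra:
        for name in SPECTRAL_METRICS:
            vals = [getattr(s, name) for s in spectra]
            metrics[name] = float(np.nanmean(vals)) if len(vals) else math.nan
    return metrics, spectra


def run_pipeline(
    config: RunConfig,
    cohort: SimulatedCohort | None = None,
) -> PipelineResult:
    """Run every stage on a cohort of RR recordings.

    ``cohort`` supplies an in-memory synthetic cohort; otherwise the
    manifest and data files referenced by the config are read.  Per-file
    failures are logged and skipped; the run fails only if no usable
    recording remains.
    """
    if cohort is not None:
        manifest = cohort.manifest
        store = cohort.series
        data_dir = Path(".")
    else:
        if config.manifest_path is None:
            raise ValueError("need either a cohort or config.manifest_path")
        manifest = CohortManifest.read_csv(config.manifest_path)
        store = None
        data_dir = Path(config.data_dir or Path(config.manifest_path).parent)

    series_map = _load_series(manifest, data_dir, store)
    if not series_map:
        raise RuntimeError("no usable recordings in cohort")

    # --- preprocessing + per-recording metrics/spectra ---------------------
    metric_rows = []
    spectra_store: dict[tuple[str, float, str], list[spectral.WindowSpectrum]] = {}
    for key, series in sorted(series_map.items()):
        try:
            cleaned, n_rep, n_ect = io_preprocess.preprocess_series(
                series, lo=config.range_lo_ms, hi=config.range_hi_ms, k_sd=config.k_sd)
        except io_preprocess.EmptySegmentError as exc:
            logger.warning("skipping %s: %s", key, exc)
            continue
        metrics, spectra = _recording_metrics(cleaned, config)
        spectra_store[key] = spectra
        for name, value in metrics.items():
            metric_rows.append({
                "mouse_id": key[0], "age_months": key[1], "state": key[2],
                "metric": name, "value": value,
            })
    metrics_table = pd.DataFrame(
        metric_rows, columns=["mouse_id", "age_months", "state", "metric", "value"])

    # --- blockade QC -------------------------------------------------------
    qc = blockade_qc.qc_cohort(spectra_store,
                               peak_threshold=config.qc_peak_threshold,
                               power_threshold=config.qc_power_threshold)
    qc_by_age = blockade_qc.qc_summary_by_age(qc)

    # exclude QC-failed (mouse, age) pairs in both states
    passed = qc[qc["passed"]][["mouse_id", "age_months"]]
    usable = metrics_table.merge(passed, on=["mouse_id", "age_months"], how="inner")

    # --- longitudinal modelling -------------------------------------------
    early_tab, late_tab = longitudinal.split_periods(usable)
    fit_objects: dict[tuple[str, str, str], longitudinal.LMEFit] = {}
    fit_rows, rate_rows = [], []
    metric_names = sorted(usable["metric"].unique())
    for metric in metric_names:
        for state in ("basal", "abk"):
            for period, tab in (("early", early_tab), ("late", late_tab)):
                try:
                    fit = longitudinal.fit_lme(tab, metric, state, period=period)
                except longitudinal.FitFailureError as exc:
                    logger.info("fit skipped: %s", exc)
                    continue
                fit_objects[(metric, state, period)] = fit
                fit_rows.append({
                    "metric": metric, "state": state, "period": period,
                    "model_form": fit.model_form, "beta0": fit.beta0,
                    "beta1": fit.beta1, "beta2": fit.beta2,
                    "resid_var": fit.resid_var, "n_mice": fit.n_mice, "n_obs": fit.n_obs,
                })
                eval_age = (config.rate_eval_age_early if period == "early"
                            else config.rate_eval_age_late)
                for r in longitudinal.mouse_rates(fit, age_at_eval=eval_age):
                    rate_rows.append(r.__dict__.copy())
    fits = pd.DataFrame(fit_rows)
    rates = pd.DataFrame(rate_rows)

    signature = longitudinal.autonomic_signature(metrics_table, qc=qc)
    baseline_norm = longitudinal.baseline_normalize(usable)

    # --- rate structure: correlations, clustering, paired SD tests ---------
    corr_r = corr_p = pd.DataFrame()
    cluster = None
    sd_rows = []
    if not rates.empty:
        def _matrix(state: str, period: str) -> pd.DataFrame:
            sub = rates[(rates["state"] == state) & (rates["period"] == period)]
            if sub.empty:
                return pd.DataFrame()
            return sub.pivot_table(index="mouse_id", columns="metric", values="rate")

        early_m = _matrix("abk", "early")
        late_m = _matrix("abk", "late")
        if not early_m.empty and not late_m.empty:
            corr_r, corr_p = longitudinal.correlation_triangle_table(early_m, late_m)
        if late_m.shape[1] >= 2 and late_m.shape[0] >= 4:
            cluster = longitudinal.cluster_rates(late_m, height_cut=config.cluster_height_cut)
        for state in ("basal", "abk"):
            em, lm = _matrix(state, "early"), _matrix(state, "late")
            if em.empty or lm.empty:
                continue
            common_mice = em.index.intersection(lm.index)
            for metric in em.columns.intersection(lm.columns):
                x = em.loc[common_mice, metric].dropna()
                y = lm.loc[common_mice, metric].dropna()
                mice = x.index.intersection(y.index)
                if len(mice) < 4:
                    continue
                t, dof, p = longitudinal.pitman_morgan(x.loc[mice], y.loc[mice])
                sd_rows.append({
                    "metric": metric, "state": state,
                    "sd_rate_early": float(np.std(x.loc[mice], ddof=1)),
                    "sd_rate_late": float(np.std(y.loc[mice], ddof=1)),
                    "t": t, "df": dof, "p": p, "n": len(mice),
                })
    rate_sd_tests = pd.DataFrame(sd_rows)

    result = PipelineResult(
        metrics=metrics_table, qc_decisions=qc, qc_by_age=qc_by_age,
        fits=fits, rates=rates, signature=signature,
        baseline_normalized=baseline_norm, corr_r=corr_r, corr_p=corr_p,
        cluster=cluster, rate_sd_tests=rate_sd_tests, fit_objects=fit_objects,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    tables = {
        "metrics.csv": result.metrics,
        "qc_decisions.csv": result.qc_decisions,
        "qc_by_age.csv": result.qc_by_age,
        "fits.csv": result.fits,
        "rates.csv": result.rates,
        "signature.csv": result.signature,
        "baseline_normalized.csv": result.baseline_normalized,
        "rate_sd_tests.csv": result.rate_sd_tests,
    }
    for name, df in tables.items():
        df.to_csv(out / name, index=False)
    if not result.corr_r.empty:
        result.corr_r.to_csv(out / "rate_correlations_r.csv")
        result.corr_p.to_csv(out / "rate_correlations_p.csv")
    if result.cluster is not None:
        (out / "rate_cluster.nwk").write_text(result.cluster.newick + "\n")
    if config.make_plots:
        _plot_trajectories(result, config, out / "plots")
    _write_report(result, config, out)


def _plot_trajectories(result: PipelineResult, config: RunConfig, plotdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    for metric in sorted(result.metrics["metric"].unique()):
        fig, ax = plt.subplots(figsize=(5, 3.5))
        plotted = False
        for state, color in (("basal", "tab:blue"), ("abk", "tab:red")):
            try:
                traj = longitudinal.loess_trajectory(
                    result.metrics, metric, state, span=config.loess_span)
            except Exception:
                continue
            if traj.empty:
                continue
            label = "intrinsic (abk)" if state == "abk" else "basal"
            ax.plot(traj["age"], traj["fit"], color=color, label=label)
            if traj["se"].notna().any():
                ax.fill_between(traj["age"], traj["lo95"], traj["hi95"],
                                color=color, alpha=0.2)
            plotted = True
        if not plotted:
            plt.close(fig)
            continue
        ax.set_xlabel("age [months]")
        ax.set_ylabel(metric)
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(plotdir / f"{metric}.png", dpi=110)
        plt.close(fig)


def _write_report(result: PipelineResult, config: RunConfig, out: Path) -> None:
    lines = ["# HRV life-course pipeline report", ""]
    n_rec = result.metrics[["mouse_id", "age_months", "state"]].drop_duplicates()
    lines += [f"Recordings analysed: {len(n_rec)} "
              f"({n_rec['mouse_id'].nunique()} mice).", ""]
    lines += ["## Blockade QC pass rates by age", "",
              result.qc_by_age.to_markdown(index=False), ""]
    if not result.fits.empty:
        lines += ["## Mixed-model fits", "", result.fits.to_markdown(index=False), ""]
    if result.cluster is not None:
        lines += ["## Late-period rate clusters (intrinsic)", ""]
        for metric, cl in sorted(result.cluster.assignments.items()):
            lines.append(f"- {metric}: cluster {cl}")
        lines.append("")
    if not result.rate_sd_tests.empty:
        lines += ["## Early vs late rate variability (Pitman-Morgan)", "",
                  result.rate_sd_tests.to_markdown(index=False), ""]
    if config.make_plots:
        lines += ["## Trajectories", ""]
        lines += [f"![{m}](plots/{m}.png)" for m in sorted(result.metrics['metric'].unique())]
    (out / "report.md").write_text("\n".join(lines) + "\n")
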