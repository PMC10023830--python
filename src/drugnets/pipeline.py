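"""Per-version analysis pipeline and cross-version evolution tables.

For each release (real or synthetic fixture): parse → filter approved human
drugs → build DDI and DTI networks → summary metrics → power-law degree fits
→ Benford first-digit reports → (optionally) the edge-injection robustness
simulation.  Failures in one version are isolated and reported; the pipeline
continues with the remaining versions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import benford, netstats, powerlaw
from .build import InteractionNetwork, build_ddi, build_dti, write_edgelist_tsv
from .ingest import filter_approved, parse_release
from .netstats import MetricsSummary
from .robustness import RobustnessConfig, RobustnessCurve, run_robustness

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    filter_policy: str = "permissive"
    centralities: tuple[str, ...] = ("degree", "betweenness")
    run_robustness: bool = False
    robustness_network: str = "dti"  # dense DDI robustness is computationally heavy
    robustness: RobustnessConfig = field(default_factory=RobustnessConfig)
    seed: int = 0
    out_dir: str | None = None


@dataclass
class VersionReport:
    version_label: str
    ddi_summary: MetricsSummary | None = None
    dti_summary: MetricsSummary | None = None
    powerlaw_fits: dict[str, powerlaw.PowerLawFit] = field(default_factory=dict)
    benford_reports: dict[str, benford.BenfordReport] = field(default_factory=dict)
    robustness_curve: RobustnessCurve | None = None
    n_records: int = 0
    n_kept: int = 0
    error: str | None = None


def _fmt(x: float | None) -> float | None:
    return None if x is None else float(f"{x:.6g}")


def analyze_release(
    version_label: str, xml_path: str | Path, config: PipelineConfig
) -> VersionReport:
    report = VersionReport(version_label=version_label)
    records = parse_release(xml_path)
    report.n_records = len(records)
    kept = filter_approved(records, policy=config.filter_policy)
    report.n_kept = len(kept)
    logger.info(
        "%s: %d records parsed, %d kept by the approved-human filter",
        version_label, len(records), len(kept),
    )

    ddi = build_ddi(kept, version_label=version_label)
    dti = build_dti(kept, version_label=version_label)
    if ddi.n_nodes:
        report.ddi_summary = netstats.summarize(ddi)
    if dti.n_nodes:
        report.dti_summary = netstats.summarize(dti)

    for kind, net in (("ddi", ddi), ("dti", dti)):
        if net.n_nodes == 0:
            continue
        for cname in config.centralities:
            table = netstats.compute_centrality(net, cname)
            key = f"{kind}_{cname}"
            try:
                report.benford_reports[key] = benford.benford_test(table)
            except benford.EmptySampleError:
                logger.warning("%s %s: no positive values for Benford test", version_label, key)
            vals = table.positive_values()
            try:
                report.powerlaw_fits[key] = powerlaw.fit_power_law(vals)
            except (ValueError, powerlaw.DegenerateSampleError) as exc:
                logger.warning("%s %s: power-law fit skipped (%s)", version_label, key, exc)

    if config.run_robustness:
        net = dti if config.robustness_network == "dti" else ddi
        if net.n_nodes:
            report.robustness_curve = run_robustness(net, config.robustness)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for kind, net in (("ddi", ddi), ("dti", dti)):
            if net.n_nodes:
                write_edgelist_tsv(net, out / f"{version_label}_{kind}.tsv")
        (out / f"{version_label}_report.json").write_text(
            json.dumps(report_to_dict(report), indent=2, default=str) + "\n"
        )
    return report


def run_pipeline(
    inputs: list[tuple[str, str | Path]], config: PipelineConfig | None = None
) -> tuple[list[VersionReport], pd.DataFrame]:
    """Analyse each (version_label, xml_path) release and tabulate evolution.

    Returns the per-version reports and a cross-version table of node/link
    counts, density, average degree, clustering, path length, diameter and
    fitted degree exponents for both network kinds.
    """
    if not inputs:
        raise ValueError("at least one release is required")
    config = config or PipelineConfig()
    reports: list[VersionReport] = []
    for label, path in inputs:
        try:
            reports.append(analyze_release(label, path, config))
        except Exception as exc:  # isolate per-version failures
            logger.error("version %s failed: %s", label, exc)
            reports.append(VersionReport(version_label=label, error=str(exc)))
    table = evolution_table(reports)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "evolution.csv", index=False)
    return reports, table


def evolution_table(reports: list[VersionReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row: dict = {"version": rep.version_label, "error": rep.error}
        for kind, summary in (("ddi", rep.ddi_summary), ("dti", rep.dti_summary)):
            if summary is None:
                continue
            row[f"{kind}_nodes"] = summary.n_nodes
            row[f"{kind}_links"] = summary.n_edges
            row[f"{kind}_density"] = _fmt(summary.density)
            row[f"{kind}_avg_degree"] = _fmt(summary.avg_degree)
            row[f"{kind}_avg_clustering"] = _fmt(summary.avg_clustering)
            row[f"{kind}_avg_path_length"] = _fmt(summary.avg_path_length)
            row[f"{kind}_diameter"] = summary.diameter
            fit = rep.powerlaw_fits.get(f"{kind}_degree")
            if fit is not None:
                row[f"{kind}_degree_alpha"] = _fmt(fit.alpha)
            ben = rep.benford_reports.get(f"{kind}_degree")
            if ben is not None:
                row[f"{kind}_degree_benford_wasserstein"] = _fmt(ben.wasserstein)
        rows.append(row)
    return pd.DataFrame(rows)


def report_to_dict(rep: VersionReport) -> dict:
    out: dict = {
        "version_label": rep.version_label,
        "n_records": rep.n_records,
        "n_kept": rep.n_kept,
        "error": rep.error,
    }
    if rep.ddi_summary:
        out["ddi_summary"] = rep.ddi_summary.as_dict()
    if rep.dti_summary:
        out["dti_summary"] = rep.dti_summary.as_dict()
    out["powerlaw_fits"] = {
        k: dataclasses.asdict(v) for k, v in rep.powerlaw_fits.items()
    }
    out["benford_reports"] = {k: v.as_dict() for k, v in rep.benford_reports.items()}
    if rep.robustness_curve:
        out["robustness"] = {
            "centrality": rep.robustness_curve.centrality_name,
            "reference_alpha": rep.robustness_curve.reference_alpha,
            "points": [
                {
                    "q": p.q,
                    "n_injected_edges": p.n_injected_edges,
                    "tau_mean": p.tau_mean,
                    "tau_var": p.tau_var,
                    "alpha_mean": p.alpha_mean,
                    "alpha_var": p.alpha_var,
                    "n_tau_degenerate": p.n_tau_degenerate,
                }
                for p in rep.robustness_curve.points
            ],
        }
    return out
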