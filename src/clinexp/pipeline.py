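"""End-to-end orchestration: normalize -> screen -> shapes -> enrich -> tau -> mtdna.

A :class:`PipelineConfig` (usually loaded from YAML) names the input
tables and stage settings; :func:`run_pipeline` writes every stage's TSV
plus a JSON summary and a plain-text run log into the output directory.
Re-running with identical config and inputs is bit-identical.
:func:`recovery_report` compares pipeline calls against a simulation
truth table.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrich, io, mtdna, norm, screen, shapes


@dataclass
class PipelineConfig:
    counts: str = ""
    metadata: str = ""
    gene_sets: str | None = None
    tissue_profiles: str | None = None
    allele_counts: str | None = None
    outdir: str = "results"
    fdr: float = 0.01
    method: str = "pearson"
    cpm_min: float = 2.0
    min_samples: int = 3
    grid_c: int = 25
    grid_k: int = 25
    sigma_floor: float = 1e-6
    restrict_to_ce: bool = True
    yates: bool = True
    testis_fold_cutoff: float = 50.0
    mtdna_min_depth: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr < 1.0:
            raise ValueError(f"fdr must be in (0, 1), got {self.fdr}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _require(config: PipelineConfig, name: str) -> str:
    path = getattr(config, name)
    if not path:
        raise ValueError(f"config is missing required input {name!r}")
    if not Path(path).exists():
        raise FileNotFoundError(f"config input {name!r} not found: {path}")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON).

    Stage failures abort with the failing stage named; outputs written so
    far are retained next to a ``FAILED.<stage>`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"clinexp {__version__}",
        f"seed: {config.seed}",
        "parameters: " + json.dumps(asdict(config), sort_keys=True),
    ]
    summary: dict = {"stages": []}
    stage = "setup"
    try:
        stage = "load"
        cm = io.read_counts(_require(config, "counts"))
        meta = io.read_metadata(_require(config, "metadata"), sample_ids=cm.sample_ids)
        meta = meta.set_index("sample_id").loc[cm.sample_ids].reset_index()
        lat = meta["latitude"].to_numpy(float)
        log_lines.append(f"loaded {len(cm)} transcripts x {len(cm.sample_ids)} samples")
        summary["n_transcripts_input"] = len(cm)
        summary["n_samples"] = len(cm.sample_ids)

        stage = "normalize"
        filtered = norm.filter_low_expression(cm, config.cpm_min, config.min_samples)
        nm = norm.normalize(filtered)
        io.write_table(nm.values, outdir / "normalized_cpm.tsv", index=True)
        io.write_table(
            nm.factors.rename_axis("sample_id").reset_index(), outdir / "tmm_factors.tsv"
        )
        summary["n_transcripts_filtered"] = len(filtered)
        log_lines.append(
            f"filter: CPM >= {config.cpm_min} in >= {config.min_samples} samples; "
            f"{len(filtered)} transcripts retained"
        )
        summary["stages"].append("normalize")

        stage = "screen"
        ce = screen.screen_latitude(nm.values, lat, fdr=config.fdr, method=config.method)
        io.write_table(ce, outdir / "ce_results.tsv")
        counts_by_dir = ce["direction"].value_counts().to_dict()
        summary["ce_counts"] = {k: int(v) for k, v in counts_by_dir.items()}
        summary["method_concordance"] = screen.method_concordance(
            ce["r_pearson"].to_numpy(), ce["rho_spearman"].to_numpy()
        )
        normality = screen.normality_screen(nm.values, fdr=config.fdr)
        io.write_table(normality, outdir / "normality.tsv")
        testable = normality["testable"]
        summary["normality_departure_fraction"] = (
            float(normality.loc[testable, "departs"].mean()) if testable.any() else np.nan
        )
        log_lines.append(f"screen ({config.method}, FDR {config.fdr}): {summary['ce_counts']}")
        summary["stages"].append("screen")

        stage = "shapes"
        if config.restrict_to_ce:
            fit_ids = ce.loc[ce["direction"].isin(["+CE", "-CE"]), "transcript_id"].tolist()
        else:
            fit_ids = ce.loc[ce["direction"] != "untestable", "transcript_id"].tolist()
        shape_res = shapes.fit_all(
            nm.values, lat, transcript_ids=fit_ids,
            sigma_floor=config.sigma_floor, grid_c=config.grid_c, grid_k=config.grid_k,
        )
        io.write_table(shape_res, outdir / "shape_results.tsv")
        if len(shape_res):
            freq = shape_res["selected_model"].value_counts(normalize=True)
            summary["shape_selection_frequencies"] = {k: float(v) for k, v in freq.items()}
        else:
            summary["shape_selection_frequencies"] = {}
        log_lines.append(
            f"shapes: fitted {len(shape_res)} transcripts; "
            f"frequencies {summary['shape_selection_frequencies']}"
        )
        summary["stages"].append("shapes")

        if config.gene_sets:
            stage = "enrich"
            gene_sets = io.read_gene_sets(_require(config, "gene_sets"))
            rows = []
            for gs in gene_sets:
                for direction in ("+CE", "-CE"):
                    try:
                        res = enrich.set_representation(
                            ce, direction, gs, yates=config.yates
                        )
                    except ValueError as exc:
                        log_lines.append(f"enrich {gs.name}/{direction}: skipped ({exc})")
                        continue
                    rows.append(
                        {
                            "set": gs.name,
                            "direction": direction,
                            "chi2": res.chi2,
                            "p": res.p,
                            "chi2_uncorrected": res.chi2_uncorrected,
                            "residual_focal": res.residuals[0, 0],
                            "representation": res.direction,
                        }
                    )
            enr = pd.DataFrame(rows)
            io.write_table(enr, outdir / "enrichment.tsv")
            summary["enrichment"] = rows
            summary["stages"].append("enrich")

        if config.tissue_profiles:
            stage = "tau"
            profiles = io.read_tissue_profiles(_require(config, "tissue_profiles"))
            taus = enrich.tau_table(profiles)
            testis = profiles.apply(
                lambda row: enrich.classify_testis_biased(row, config.testis_fold_cutoff),
                axis=1,
            )
            tau_df = pd.DataFrame(
                {"transcript_id": profiles.index, "tau": taus.values, "testis_biased": testis.values}
            )
            io.write_table(tau_df, outdir / "tau.tsv")
            pos_ids = set(ce.loc[ce["direction"] == "+CE", "transcript_id"])
            neg_ids = set(ce.loc[ce["direction"] == "-CE", "transcript_id"])
            tau_pos = taus.loc[taus.index.intersection(pos_ids)].dropna().to_numpy()
            tau_neg = taus.loc[taus.index.intersection(neg_ids)].dropna().to_numpy()
            if tau_pos.size and tau_neg.size:
                w, p = enrich.compare_tau(tau_pos, tau_neg)
                summary["tau_comparison"] = {
                    "W": w, "p": p,
                    "median_tau_pos": float(np.median(tau_pos)),
                    "median_tau_neg": float(np.median(tau_neg)),
                    "n_pos": int(tau_pos.size), "n_neg": int(tau_neg.size),
                }
                log_lines.append(f"tau: W = {w:.1f}, p = {p:.3g}")
            summary["stages"].append("tau")

        if config.allele_counts:
            stage = "mtdna"
            ac = io.read_allele_counts(_require(config, "allele_counts"))
            freq = mtdna.haplotype_frequency(ac, min_depth=config.mtdna_min_depth)
            io.write_table(freq, outdir / "mtdna_frequencies.tsv")
            retained = freq[freq["retained"]].merge(
                meta[["sample_id", "latitude"]], on="sample_id"
            )
            check = mtdna.frequency_cline_check(
                retained["frequency"].to_numpy(), retained["latitude"].to_numpy()
            )
            summary["mtdna"] = check
            log_lines.append(f"mtdna: {check['verdict']} (r = {check['r']:.3f}, p = {check['p']:.3g})")
            summary["stages"].append("mtdna")

    except Exception as exc:
        (outdir / f"FAILED.{stage}").write_text(str(exc) + "\n")
        raise StageError(stage, exc) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def recovery_report(
    shape_results: pd.DataFrame, ce_results: pd.DataFrame, truth: pd.DataFrame
) -> dict:
    """Compare pipeline calls against a simulation truth table.

    Returns the per-true-shape confusion matrix of selected models, the
    sensitivity and realized false-discovery proportion of CE calls
    against true non-null transcripts, and direction accuracy.
    """
    truth_ids = set(truth["transcript_id"])
    ce_ids = set(ce_results["transcript_id"])
    if not ce_ids <= truth_ids:
        missing = sorted(ce_ids - truth_ids)[:5]
        raise ValueError(f"result transcripts absent from truth table: {missing}")

    merged = ce_results.merge(
        truth[["transcript_id", "true_shape", "direction"]].rename(
            columns={"direction": "true_direction"}
        ),
        on="transcript_id",
    )
    testable = merged[merged["direction"] != "untestable"]
    is_ce = testable["direction"].isin(["+CE", "-CE"])
    true_clinal = testable["true_shape"] != "null"
    sensitivity = float(is_ce[true_clinal].mean()) if true_clinal.any() else np.nan
    fdp = float((~true_clinal[is_ce]).mean()) if is_ce.any() else np.nan
    called = testable[is_ce & true_clinal]
    dir_ok = (
        ((called["direction"] == "+CE") & (called["true_direction"] == "+"))
        | ((called["direction"] == "-CE") & (called["true_direction"] == "-"))
    )
    direction_accuracy = float(dir_ok.mean()) if len(called) else np.nan

    confusion = pd.DataFrame()
    if len(shape_results):
        sm = shape_results.merge(truth[["transcript_id", "true_shape"]], on="transcript_id")
        if len(sm) != len(shape_results):
            raise ValueError("shape results contain transcripts absent from truth table")
        confusion = pd.crosstab(sm["true_shape"], sm["selected_model"])

    return {
        "ce_sensitivity": sensitivity,
        "ce_false_discovery_proportion": fdp,
        "direction_accuracy": direction_accuracy,
        "confusion": confusion,
    }
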