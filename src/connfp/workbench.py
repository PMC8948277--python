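"""End-to-end orchestration of the fingerprinting-vs-prediction analysis.

``run_pipeline`` composes the stages in order: cohort (synthetic draw or
file ingest) → fingerprinting (identification, permutation test,
differential power, percentile masks) → prediction per behaviour (CPM,
fixed-discriminatory-edge control, optional SVR) → overlap (single-edge,
network-cell, topographical/spin) → variability (edge SDs, SD-overlap,
Welch ANOVA + Games–Howell), then FDR-corrects the prediction p values as
one family across behaviours.  A single top-level seed is fanned out to
each stochastic stage through fixed stage keys, so adding a stage never
shifts another stage's random stream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortParams, read_cohort, simulate_cohort
from .cpm import CPMConfig, PredictionResult, predict_with_fixed_edges, run_cpm, run_svr
from .fingerprint import (
    DPVector,
    EdgeMask,
    IdentificationResult,
    differential_power,
    format_p,
    identification_permutation_test,
    threshold_percentile,
)
from .overlap import (
    NetworkMatrix,
    OverlapResult,
    SpinTestResult,
    edge_overlap_test,
    network_cell_proportions,
    network_matrix_correlation,
    node_degree,
    predictive_mask,
    spin_test,
)
from .variability import EdgeStats, GroupComparison, edge_sd, games_howell, sd_overlap, welch_anova

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "fdr_correct", "run_pipeline", "stage_seed"]

# fixed stage keys for seed fan-out; never renumber, only append
_STAGE_KEYS = {
    "cohort": 1,
    "identification": 2,
    "cpm": 3,
    "fixed_edges": 4,
    "svr": 5,
    "edge_overlap": 6,
    "spin": 7,
    "sd_overlap": 8,
}


def stage_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed derived from the single top-level seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_KEYS[stage], int(extra)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    mode: str = "synthetic"
    cohort: CohortParams = field(default_factory=CohortParams)
    input_dir: str | None = None  # files mode
    cpm: CPMConfig = field(default_factory=CPMConfig)
    thresholds: tuple[float, ...] = (99, 98, 95)
    predict_session: str = "mean"  # or "1" / "2": which session feeds prediction
    min_fold_frac: float = 0.8
    n_perm_identification: int = 1000
    n_perm_overlap: int = 1000
    n_perm_spin: int = 1000
    with_svr: bool = True
    with_fixed_edges: bool = True
    output_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortParams(**raw.pop("cohort", {}))
        cpm = CPMConfig(**raw.pop("cpm", {}))
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(cohort=cohort, cpm=cpm, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohort: Cohort
    identification: IdentificationResult
    dp: DPVector
    dp_masks: dict[float, EdgeMask]
    predictions: dict[str, PredictionResult]
    predictions_fdr: dict[str, float]
    fixed_edge_predictions: dict[str, PredictionResult]
    svr_predictions: dict[str, PredictionResult]
    predictive_masks: dict[str, EdgeMask]
    edge_overlaps: dict[str, OverlapResult]
    network_matrices: dict[str, NetworkMatrix]
    network_correlations: dict[str, tuple[float, float, int]]
    node_degrees: dict[str, np.ndarray]
    spin_results: dict[str, SpinTestResult]
    edge_stats: EdgeStats
    sd_overlaps: dict[float, OverlapResult]
    group_comparison: GroupComparison | None
    provenance: dict

    def summary(self) -> dict:
        """Flat machine-readable summary of the headline numbers."""
        out = {
            "package_version": self.provenance["version"],
            "seed": self.config.seed,
            "n_subjects": self.cohort.connectomes.n_subjects,
            "n_edges": self.cohort.connectomes.n_edges,
            "identification": {
                "accuracy_1to2": self.identification.accuracy_1to2,
                "accuracy_2to1": self.identification.accuracy_2to1,
                "p": self.identification.p_value,
                "p_report": format_p(
                    self.identification.p_value, self.config.n_perm_identification
                ),
            },
            "dp_mask_sizes": {str(t): m.n_selected for t, m in self.dp_masks.items()},
            "predictions": {
                name: {
                    "rho": r.rho,
                    "pearson_r": r.pearson_r,
                    "p": r.p_value,
                    "p_fdr": self.predictions_fdr[name],
                    "n": r.n_complete,
                }
                for name, r in self.predictions.items()
            },
            "fixed_edge_predictions": {
                name: {"rho": r.rho, "p": r.p_value}
                for name, r in self.fixed_edge_predictions.items()
            },
            "svr_predictions": {
                name: {"rho": r.rho, "p": r.p_value}
                for name, r in self.svr_predictions.items()
            },
            "edge_overlaps": {
                name: {
                    "n_predictive": int(self.predictive_masks[name].n_selected),
                    "observed": r.observed,
                    "null_mean": r.null_mean,
                    "null_sd": r.null_sd,
                    "p": r.p_value,
                }
                for name, r in self.edge_overlaps.items()
            },
            "network_correlations": {
                name: {"r": r, "p": p, "df": df}
                for name, (r, p, df) in self.network_correlations.items()
            },
            "spin": {
                name: {"rho": s.rho, "p": s.p_value}
                for name, s in self.spin_results.items()
            },
            "sd_overlaps": {
                str(t): {"observed": r.observed, "p": r.p_value}
                for t, r in self.sd_overlaps.items()
            },
        }
        if self.group_comparison is not None:
            g = self.group_comparison
            out["variability_anova"] = {
                "welch_F": g.welch_F,
                "df1": g.df1,
                "df2": g.df2,
                "p": g.p,
                "omega_sq": g.omega_sq,
            }
        return out


def fdr_correct(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (monotone in raw rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def run_pipeline(config: PipelineConfig | None = None, **kwargs) -> ReportBundle:
    """Run the complete analysis and (optionally) write all artifacts."""
    config = config or PipelineConfig(**kwargs)
    logging.basicConfig(level=config.log_level)

    if config.mode == "synthetic":
        cohort = simulate_cohort(config.cohort, seed=stage_seed(config.seed, "cohort"))
    elif config.mode == "files":
        if not config.input_dir or not Path(config.input_dir).exists():
            raise FileNotFoundError(f"input_dir {config.input_dir!r} does not exist")
        cohort = read_cohort(config.input_dir)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    cset = cohort.connectomes
    s1, s2 = cset.session(0), cset.session(1)

    logger.info("identification (%d subjects, %d edges)", cset.n_subjects, cset.n_edges)
    ident = identification_permutation_test(
        s1, s2, n_perm=config.n_perm_identification,
        seed=stage_seed(config.seed, "identification"),
    )
    dp = differential_power(s1, s2)
    dp_masks = {t: threshold_percentile(dp.values, pct=t) for t in config.thresholds}
    dp_mask = dp_masks[config.thresholds[0]]

    if config.predict_session == "mean":
        X = cset.session_mean()
    else:
        X = cset.session(int(config.predict_session) - 1)
    predictions: dict[str, PredictionResult] = {}
    fixed_preds: dict[str, PredictionResult] = {}
    svr_preds: dict[str, PredictionResult] = {}
    pred_masks: dict[str, EdgeMask] = {}
    for bi, name in enumerate(cohort.behaviours.columns):
        y = cohort.behaviours[name].to_numpy(float)
        logger.info("CPM for behaviour %s", name)
        cfg = dataclasses.replace(config.cpm, seed=stage_seed(config.seed, "cpm", bi))
        predictions[name] = run_cpm(X, y, cfg, subjects=cset.subjects)
        side = config.cpm.model_side if config.cpm.model_side != "both" else "positive"
        pred_masks[name] = predictive_mask(
            predictions[name].selection_frequency[side], min_frac=config.min_fold_frac
        )
        if config.with_fixed_edges:
            fcfg = dataclasses.replace(
                config.cpm, seed=stage_seed(config.seed, "fixed_edges", bi)
            )
            fixed_preds[name] = predict_with_fixed_edges(
                X, y, dp_mask, fcfg, subjects=cset.subjects
            )
        if config.with_svr:
            scfg = dataclasses.replace(config.cpm, seed=stage_seed(config.seed, "svr", bi))
            svr_preds[name] = run_svr(X, y, scfg, subjects=cset.subjects)

    raw_p = [predictions[n].p_value for n in predictions]
    adj = fdr_correct(raw_p) if raw_p else np.array([])
    predictions_fdr = dict(zip(predictions, adj.tolist()))

    edge_overlaps: dict[str, OverlapResult] = {}
    network_matrices: dict[str, NetworkMatrix] = {
        "discriminatory": network_cell_proportions(dp_mask, cohort.parcellation)
    }
    network_corrs: dict[str, tuple[float, float, int]] = {}
    degrees: dict[str, np.ndarray] = {
        "discriminatory": node_degree(dp_mask, cohort.parcellation)
    }
    spins: dict[str, SpinTestResult] = {}
    for bi, name in enumerate(predictions):
        pm = pred_masks[name]
        edge_overlaps[name] = edge_overlap_test(
            dp_mask, pm, n_perm=config.n_perm_overlap,
            seed=stage_seed(config.seed, "edge_overlap", bi),
        )
        network_matrices[name] = network_cell_proportions(pm, cohort.parcellation)
        try:
            network_corrs[name] = network_matrix_correlation(
                network_matrices["discriminatory"], network_matrices[name]
            )
        except ValueError:
            logger.warning("network correlation undefined for %s", name)
        degrees[name] = node_degree(pm, cohort.parcellation)
        spins[name] = spin_test(
            degrees["discriminatory"], degrees[name], cohort.parcellation,
            n_perm=config.n_perm_spin, seed=stage_seed(config.seed, "spin", bi),
        )

    stats = edge_sd(cset, basis="session_mean")
    sd_overlaps = {
        t: sd_overlap(
            dp, stats, pct=t, n_perm=config.n_perm_overlap,
            seed=stage_seed(config.seed, "sd_overlap", int(t)),
        )
        for t in config.thresholds
    }
    groups = {"all edges": stats.sd, "discriminatory": stats.sd[dp_mask.bits]}
    for name, pm in pred_masks.items():
        if pm.n_selected >= 2:
            groups[f"predictive ({name})"] = stats.sd[pm.bits]
        else:
            logger.warning("predictive mask for %s too small for group stats", name)
    comparison: GroupComparison | None = None
    try:
        F, df1, df2, p, omega = welch_anova(groups)
        comparison = GroupComparison(
            groups=groups, welch_F=F, df1=df1, df2=df2, p=p, omega_sq=omega,
            posthoc=games_howell(groups, fdr=True),
        )
    except ValueError as exc:
        logger.warning("variability group comparison skipped: %s", exc)

    bundle = ReportBundle(
        config=config,
        cohort=cohort,
        identification=ident,
        dp=dp,
        dp_masks=dp_masks,
        predictions=predictions,
        predictions_fdr=predictions_fdr,
        fixed_edge_predictions=fixed_preds,
        svr_predictions=svr_preds,
        predictive_masks=pred_masks,
        edge_overlaps=edge_overlaps,
        network_matrices=network_matrices,
        network_correlations=network_corrs,
        node_degrees=degrees,
        spin_results=spins,
        edge_stats=stats,
        sd_overlaps=sd_overlaps,
        group_comparison=comparison,
        provenance={"version": __version__, "config": config.to_dict()},
    )
    if config.output_dir:
        write_report(bundle, config.output_dir)
    return bundle


def write_report(bundle: ReportBundle, outdir) -> None:
    """Write every stage's artifacts as TSV plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = bundle.config
    (outdir / "config.yaml").write_text(yaml.safe_dump(cfg.to_dict()))

    ident = bundle.identification
    pd.DataFrame(
        {
            "direction": ["1to2", "2to1"],
            "hits": [ident.hits_1to2, ident.hits_2to1],
            "n_subjects": [ident.n_subjects] * 2,
            "accuracy": [ident.accuracy_1to2, ident.accuracy_2to1],
            "p": [ident.p_value] * 2,
        }
    ).to_csv(outdir / "identification.tsv", sep="\t", index=False)

    pd.DataFrame({"edge": np.arange(bundle.dp.values.size), "dp": bundle.dp.values}).to_csv(
        outdir / "differential_power.tsv", sep="\t", index=False
    )
    for t, m in bundle.dp_masks.items():
        m.to_tsv(outdir / f"dp_mask_p{t:g}.tsv")
    for name, m in bundle.predictive_masks.items():
        m.to_tsv(outdir / f"predictive_mask_{name}.tsv")

    rows = []
    for name, r in bundle.predictions.items():
        rows.append(
            (name, "cpm", cfg.cpm.model_side, r.rho, r.p_value,
             bundle.predictions_fdr[name], r.n_complete, cfg.cpm.threshold_p)
        )
    for name, r in bundle.fixed_edge_predictions.items():
        rows.append((name, "fixed_dp_edges", cfg.cpm.model_side, r.rho, r.p_value,
                     np.nan, r.n_complete, np.nan))
    for name, r in bundle.svr_predictions.items():
        rows.append((name, "svr", "all", r.rho, r.p_value, np.nan, r.n_complete, np.nan))
    pd.DataFrame(
        rows,
        columns=["behaviour", "model", "side", "rho", "p", "p_fdr", "n", "threshold_p"],
    ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    pd.DataFrame(
        [
            ("dp_mask", name, r.observed, r.null_mean, r.null_sd, r.p_value, r.n_perm)
            for name, r in bundle.edge_overlaps.items()
        ]
        + [
            ("dp_mask", f"sd_pct{t:g}", r.observed, r.null_mean, r.null_sd, r.p_value, r.n_perm)
            for t, r in bundle.sd_overlaps.items()
        ],
        columns=["maskA", "maskB", "observed", "null_mean", "null_sd", "p", "n_perm"],
    ).to_csv(outdir / "overlaps.tsv", sep="\t", index=False)

    for name, nm in bundle.network_matrices.items():
        pd.DataFrame(nm.cells, index=nm.labels, columns=nm.labels).to_csv(
            outdir / f"network_matrix_{name}.tsv", sep="\t"
        )
    deg = pd.DataFrame(bundle.node_degrees)
    deg.insert(0, "node_id", bundle.cohort.parcellation.node_ids)
    deg.to_csv(outdir / "node_degrees.tsv", sep="\t", index=False)

    pd.DataFrame(
        [(n, s.rho, s.p_value, s.n_perm) for n, s in bundle.spin_results.items()],
        columns=["behaviour", "rho", "p", "n_perm"],
    ).to_csv(outdir / "spin_tests.tsv", sep="\t", index=False)

    pd.DataFrame(
        {"edge": np.arange(bundle.edge_stats.sd.size), "sd": bundle.edge_stats.sd}
    ).to_csv(outdir / "edge_sd.tsv", sep="\t", index=False)
    if bundle.group_comparison is not None:
        bundle.group_comparison.posthoc.to_csv(
            outdir / "variability_posthoc.tsv", sep="\t", index=False
        )

    (outdir / "summary.json").write_text(json.dumps(bundle.summary(), indent=1))
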