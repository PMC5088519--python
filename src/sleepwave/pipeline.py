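"""End-to-end orchestration of the analysis and a machine-readable report.

The stage order follows the analysis: quantile normalization, removal of
unwanted variation (with a k-scan when k is not fixed), moderated
differential expression against time-matched controls, circadian flags
from the undisturbed controls, trajectory clustering with responder
classification, per-cluster decay time constants, and (when an annotation
collection is supplied) functional enrichment of the responder gene lists.
Runs are deterministic given the seed; a single global seed fans out to
per-stage seeds so one stage can be re-run reproducibly.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .de import PAPER_CONTRASTS, circadian_contrasts, evaluate, fit_contrasts
from .enrich import enrich
from .io import ControlGeneSets, ExpressionDataset, load_controls, load_design, load_expression, load_gmt, write_expression
from .kinetics import (
    build_trajectories,
    classify_clusters,
    cluster_trajectories,
    fit_decay,
    summarize_kinetics,
)
from .normalize import quantile_normalize, ruv_fit, scan_k
from .simulate import SimulationConfig, generate

logger = logging.getLogger("sleepwave")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "make_figures"]


@dataclass
class PipelineConfig:
    """Parameters of a full run.

    When no input paths are given a synthetic dataset is generated with
    ``synthetic`` (defaulting to the emulated study design, seeded from
    ``seed``). ``k=None`` triggers a k-scan; ``use_w_covariates`` switches
    from subtracting W alpha-hat to carrying W as design covariates.
    ``quantile=None`` applies quantile normalization to file inputs only:
    the generator emulates data already summarized on a common quantile
    scale, so renormalizing it is redundant.
    """

    seed: int = 0
    synthetic: SimulationConfig = None
    expression_path: str = None
    design_path: str = None
    negative_controls_path: str = None
    positive_controls_path: str = None
    gmt_path: str = None
    quantile: bool = None
    variant: str = "replicate_samples"
    k: int = None
    k_max: int = 6
    fdr: float = 0.01
    n_clusters: int = 7
    recovery_fraction: float = 0.25
    #: estimate treatment effects with W in the design rather than on the
    #: subtracted matrix: subtraction also removes the part of the real
    #: treatment profile that falls in span(W), biasing late-time logFC
    use_w_covariates: bool = True
    #: keep time-of-day-flagged genes out of trajectory clustering; their
    #: logFC against imperfectly time-matched controls (RS3 vs the ZT8
    #: control, RS6 vs the ZT11 control) mixes circadian change into the
    #: recovery kinetics, so they are reported separately
    exclude_time_of_day: bool = True
    #: clusters smaller than this are left out of the class-average tau;
    #: complete linkage always produces a few tiny heterogeneous leftovers
    min_cluster_size: int = 25
    ease_cutoff: float = 0.05
    similarity_threshold: float = 0.2
    group_membership: int = 2
    score_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr <= 1.0:
            raise ValueError("fdr must lie in (0, 1]")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        for path_attr in (
            "expression_path",
            "design_path",
            "negative_controls_path",
            "positive_controls_path",
            "gmt_path",
        ):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{path_attr}: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SimulationConfig.from_dict(raw["synthetic"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


@dataclass
class RunReport:
    """Per-stage summaries of one pipeline run (JSON-serializable)."""

    version: str
    seed: int
    config: dict
    stages: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "stages": self.stages,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_jsonable)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        d = json.loads(text)
        return cls(version=d["version"], seed=d["seed"], config=d["config"], stages=d["stages"])

    @classmethod
    def read(cls, path) -> "RunReport":
        return cls.from_json(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, tuple)):
        return sorted(x) if isinstance(x, set) else list(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def _load_inputs(config: PipelineConfig):
    if config.expression_path is not None:
        matrix = load_expression(config.expression_path)
        design = load_design(config.design_path)
        dataset = ExpressionDataset(matrix=matrix, design=design)
        controls = ControlGeneSets()
        if config.negative_controls_path and config.positive_controls_path:
            controls = load_controls(
                config.negative_controls_path, config.positive_controls_path
            )
        return dataset, None, controls
    sim = config.synthetic
    if sim is None:
        # fan the global seed out to the generation stage
        stage_seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % (2**31))
        sim = SimulationConfig(seed=stage_seed)
    dataset, truth, controls = generate(sim)
    return dataset, truth, controls


def run_pipeline(config: PipelineConfig, outdir=None) -> RunReport:
    """Execute all stages in order; returns the run report.

    Intermediate tables are written as TSV under ``outdir`` when given.
    In-memory objects (DE results, trajectories, fits...) are kept on
    ``report.artifacts`` for figure generation.
    """
    t_start = time.time()
    report = RunReport(version=__version__, seed=config.seed, config=config.to_dict())
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def _finish_stage(name, summary):
        report.stages[name] = summary
        logger.info("stage %s done: %s", name, {k: v for k, v in summary.items() if not isinstance(v, dict)})

    try:
        dataset, truth, controls = _load_inputs(config)
        _finish_stage(
            "input",
            {"n_genes": dataset.n_features, "n_samples": dataset.n_samples,
             "n_groups": int(dataset.design["group"].nunique()),
             "synthetic": truth is not None},
        )

        apply_quantile = (
            config.quantile
            if config.quantile is not None
            else config.expression_path is not None
        )
        if apply_quantile:
            dataset = quantile_normalize(dataset)
        controls = controls.restrict_to(dataset.feature_ids)

        contrasts = [
            c for c in PAPER_CONTRASTS
            if {c.treatment, c.control} <= set(dataset.design["group"])
        ]
        if len(contrasts) < len(PAPER_CONTRASTS):
            warnings.warn("not all canonical contrasts are available in the design")

        # recall-based k selection uses the early contrasts, where positive
        # controls are expected to still be differentially expressed
        scan_contrasts = [
            c for c in contrasts if c.name in ("SD_vs_CC6", "RS1_vs_CC7")
        ] or contrasts
        # negative controls anchor the factor estimation in both variants:
        # carrying treatment-responsive genes into the per-sample factor
        # regression would leak real signal into W
        control_ids = sorted(controls.negative) if controls.negative else None
        if config.k is None and controls.positive and controls.negative:
            scan = scan_k(
                dataset, controls, scan_contrasts, k_max=config.k_max,
                variant=config.variant, control_ids=control_ids, fdr=config.fdr,
                use_w_covariates=config.use_w_covariates,
            )
            k_used = scan.recommended_k
            report.artifacts["kscan"] = scan
            _finish_stage(
                "k_scan",
                {"recommended_k": k_used,
                 "table": scan.table.round(6).to_dict(orient="index")},
            )
        else:
            k_used = config.k if config.k is not None else 0
        fit = ruv_fit(dataset, k=k_used, variant=config.variant, control_ids=control_ids)
        adjusted = fit.adjusted
        _finish_stage("normalization", {"k": k_used, "variant": config.variant,
                                        "quantile": apply_quantile})
        if out is not None:
            write_expression(adjusted, out / "adjusted.tsv")

        w_cov = fit.W.to_numpy() if (config.use_w_covariates and k_used > 0) else None
        if w_cov is not None:
            de_results = fit_contrasts(dataset, contrasts, covariates=w_cov)
        else:
            de_results = fit_contrasts(adjusted, contrasts)
        de_by_group = {c.treatment: de for c, de in zip(contrasts, de_results)}
        de_summary = {}
        for c, de in zip(contrasts, de_results):
            diag = evaluate(de, controls, fdr=config.fdr)
            de_summary[c.name] = {
                "n_up": diag.n_up,
                "n_down": diag.n_down,
                "recall": None if np.isnan(diag.recall) else diag.recall,
                "ks_statistic": diag.ks_statistic,
            }
            if out is not None:
                de.table.round(6).to_csv(out / f"de_{c.name}.tsv", sep="\t")
        report.artifacts["de"] = de_by_group
        report.artifacts["adjusted"] = adjusted
        _finish_stage("differential_expression", de_summary)

        if w_cov is not None:
            circ = circadian_contrasts(dataset, fdr=config.fdr, covariates=w_cov)
        else:
            circ = circadian_contrasts(adjusted, fdr=config.fdr)
        _finish_stage("circadian", {"n_flagged": int(circ.sum())})

        kinetics_summary = {"n_trajectory_genes": 0}
        if all(g in de_by_group for g in ("SD", "RS1", "RS2", "RS3", "RS6")):
            tm = build_trajectories(de_by_group, circadian_flags=circ, fdr=config.fdr)
            kinetics_summary["n_trajectory_genes"] = int(len(tm.logfc))
            if config.exclude_time_of_day and tm.circadian.any():
                keep = tm.circadian.index[~tm.circadian]
                from .kinetics import TrajectoryMatrix

                tm = TrajectoryMatrix(
                    logfc=tm.logfc.loc[keep],
                    significant=tm.significant.loc[keep],
                    times=tm.times,
                    circadian=tm.circadian.loc[keep],
                    fdr=tm.fdr,
                )
                kinetics_summary["n_time_of_day_excluded"] = int(
                    kinetics_summary["n_trajectory_genes"] - len(keep)
                )
            if len(tm.logfc) >= config.n_clusters:
                ca = cluster_trajectories(tm, n_clusters=config.n_clusters)
                classes = classify_clusters(ca, tm, recovery_fraction=config.recovery_fraction)
                fits = {cid: fit_decay(ca.means.loc[cid], tm.times) for cid in ca.cluster_ids}
                sizes = {cid: int((ca.labels == cid).sum()) for cid in ca.cluster_ids}
                class_tau = summarize_kinetics(
                    fits, classes, sizes=sizes, min_size=config.min_cluster_size
                )
                cluster_rows = {}
                for cid in ca.cluster_ids:
                    f = fits[cid]
                    cluster_rows[str(cid)] = {
                        "class": classes[cid],
                        "n_genes": int((ca.labels == cid).sum()),
                        "logfc0": f.logfc0,
                        "la": f.la,
                        "tau": None if np.isnan(f.tau) else f.tau,
                        "converged": bool(f.converged),
                    }
                kinetics_summary["clusters"] = cluster_rows
                kinetics_summary["class_tau"] = class_tau
                report.artifacts["trajectories"] = tm
                report.artifacts["clusters"] = ca
                report.artifacts["fits"] = fits
                if out is not None:
                    ca.labels.to_frame().assign(
                        cls=[classes[c] for c in ca.labels]
                    ).to_csv(out / "clusters.tsv", sep="\t")
                    pd.DataFrame(
                        {
                            "cluster": list(fits),
                            "class": [classes[c] for c in fits],
                            "logFC0": [fits[c].logfc0 for c in fits],
                            "LA": [fits[c].la for c in fits],
                            "tau_d": [fits[c].tau for c in fits],
                            "rss": [fits[c].rss for c in fits],
                            "converged": [fits[c].converged for c in fits],
                        }
                    ).to_csv(out / "fits.tsv", sep="\t", index=False)
        _finish_stage("kinetics", kinetics_summary)

        if config.gmt_path is not None and "clusters" in report.artifacts:
            collection = load_gmt(config.gmt_path)
            ca = report.artifacts["clusters"]
            tm = report.artifacts["trajectories"]
            background = dataset.feature_ids
            enr_summary = {}
            enr_artifacts = {}
            for cls in ("fast", "slow", "late_induced"):
                members = [
                    g for g in ca.labels.index if ca.classes.get(ca.labels[g]) == cls
                ]
                if not members:
                    continue
                res = enrich(
                    members,
                    background,
                    collection,
                    ease_cutoff=config.ease_cutoff,
                    similarity_threshold=config.similarity_threshold,
                    group_membership=config.group_membership,
                    score_cutoff=config.score_cutoff,
                )
                enr_summary[cls] = {
                    "n_genes": len(members),
                    "n_enriched_terms": int((res.term_table["p"] < config.ease_cutoff).sum())
                    if len(res.term_table)
                    else 0,
                    "clusters": [
                        {"members": list(c.members), "score": c.score} for c in res.clusters
                    ],
                }
                enr_artifacts[cls] = res
            report.artifacts["enrichment"] = enr_artifacts
            _finish_stage("enrichment", enr_summary)
    except Exception as exc:  # annotate the failing stage, keep partial artifacts
        done = list(report.stages)
        raise RuntimeError(
            f"pipeline failed after stages {done}: {exc}"
        ) from exc

    report.stages["runtime_seconds"] = round(time.time() - t_start, 3)
    if out is not None:
        report.write(out / "report.json")
    return report


def make_figures(report: RunReport, outdir) -> list:
    """Write diagnostic figures for the artifacts present on the report.

    Missing artifacts skip their figure with a warning. Returns the list
    of files written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    adjusted = report.artifacts.get("adjusted")
    if adjusted is not None:
        from .integrate import pca_report

        pca = pca_report(adjusted, n_components=2)
        fig, ax = plt.subplots(figsize=(5, 4))
        for grp, rows in pca.scores.groupby(adjusted.design["group"], observed=True):
            ax.scatter(rows["PC1"], rows["PC2"], label=str(grp), s=14)
        ax.set_xlabel(f"PC1 ({pca.variance_fraction['PC1']:.0%})")
        ax.set_ylabel(f"PC2 ({pca.variance_fraction['PC2']:.0%})")
        ax.legend(fontsize=6, ncol=2)
        fig.savefig(out / "pca.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "pca.png")
    else:
        warnings.warn("no adjusted matrix on report; skipping PCA figure")

    de = report.artifacts.get("de")
    if de:
        fig, axes = plt.subplots(1, len(de), figsize=(3 * len(de), 2.6), squeeze=False)
        for ax, (name, res) in zip(axes[0], de.items()):
            ax.hist(res.table["p"], bins=20, range=(0, 1), color="grey")
            ax.set_title(name, fontsize=8)
            ax.set_xlabel("p")
        fig.savefig(out / "pvalue_histograms.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "pvalue_histograms.png")

        first = next(iter(de.values()))
        if len(first.table) == 0:
            warnings.warn("empty DE result; volcano plot skipped")
        else:
            fig, ax = plt.subplots(figsize=(4, 4))
            sig = first.table["fdr"] < 0.01
            ax.scatter(
                first.table["logFC"],
                -np.log10(np.clip(first.table["p"], 1e-300, None)),
                c=np.where(sig, "tab:blue", "lightgrey"),
                s=4,
            )
            ax.set_xlabel("logFC")
            ax.set_ylabel("-log10 p")
            ax.set_title(first.contrast.name, fontsize=9)
            fig.savefig(out / "volcano.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(out / "volcano.png")

        fig, ax = plt.subplots(figsize=(5, 3))
        names = list(de)
        ups = [report.stages["differential_expression"][d.contrast.name]["n_up"] for d in de.values()]
        downs = [report.stages["differential_expression"][d.contrast.name]["n_down"] for d in de.values()]
        x = np.arange(len(names))
        ax.bar(x - 0.2, ups, width=0.4, label="up")
        ax.bar(x + 0.2, downs, width=0.4, label="down")
        ax.set_xticks(x, names, rotation=30, fontsize=7)
        ax.set_ylabel("significant genes")
        ax.legend()
        fig.savefig(out / "de_counts.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "de_counts.png")
    else:
        warnings.warn("no DE results on report; skipping DE figures")

    ca = report.artifacts.get("clusters")
    tm = report.artifacts.get("trajectories")
    if ca is not None and tm is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        for cid in ca.cluster_ids:
            m = ca.means.loc[cid]
            s = ca.sds.loc[cid]
            ax.plot(tm.times, m, label=f"cluster {cid} ({ca.classes.get(cid, '?')})")
            ax.fill_between(tm.times, m - s, m + s, alpha=0.15)
        ax.set_xlabel("hours of recovery sleep")
        ax.set_ylabel("mean logFC")
        ax.legend(fontsize=6)
        fig.savefig(out / "trajectories.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(out / "trajectories.png")
    else:
        warnings.warn("no trajectory clustering on report; skipping trajectory figure")

    enr = report.artifacts.get("enrichment")
    if enr:
        fig, ax = plt.subplots(figsize=(5, 3))
        labels, scores = [], []
        for cls, res in enr.items():
            for i, c in enumerate(res.clusters):
                labels.append(f"{cls}:{i+1}")
                scores.append(c.score)
        if scores:
            ax.barh(labels, scores)
            ax.set_xlabel("enrichment score")
            fig.savefig(out / "enrichment.png", dpi=120, bbox_inches="tight")
            written.append(out / "enrichment.png")
        plt.close(fig)
    return [str(p) for p in written]
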