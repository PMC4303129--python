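"""End-to-end orchestration: simulate → QC → cluster → test → survive → enrich.

One :class:`PipelineConfig` holds every threshold of the analysis (all at
their standard defaults: detection p 1e-5, 25% sample-fail fraction, probe
SD floor 0.06, variant SD cut 0.2, 80% subsampling over 100 iterations for
k = 2..10 with a 0.9 cluster-consensus rule, FDR 0.05) plus the master
seed.  ``run_all`` executes the stages, writes the per-stage tables, and
records counts, config and seed in a JSON run manifest so a run is
reproducible and auditable.
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

from . import io as mio
from .cluster import ConsensusKMeans, summarize_clusters
from .containers import BetaMatrix, FilterRecord, ProbeManifest, RawIntensitySet
from .differential import (
    bh_fdr,
    direction_summary,
    methylation_expression_correlation,
    overlap_sets,
    run_comparison,
    wilcoxon_rank_sum,
)
from .enrichment import dedupe_genes, enrich
from .preprocess import (
    average_replicates,
    compute_beta,
    detect_failed_probes,
    drop_tumors,
    filter_probes,
    filter_samples,
    replicate_concordance,
    select_variant_probes,
)
from .simulate import SimConfig, generate_dataset
from .survival import cox_fit, kaplan_meier, log_rank, ph_check

__all__ = ["PipelineConfig", "run_qc", "run_all", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline thresholds, file locations and the master seed."""

    detection_p_thresh: float = 1e-5
    sample_max_fail_frac: float = 0.25
    probe_sd_min: float = 0.06
    variant_sd_cut: float = 0.2
    subsample_frac: float = 0.8
    n_iter: int = 100
    k_min: int = 2
    k_max: int = 10
    consensus_threshold: float = 0.9
    fdr_alpha: float = 0.05
    logit_eps: float = 1e-3
    ties: str = "efron"
    seed: int = 0
    sim: dict = field(default_factory=dict)  # SimConfig overrides for the simulate stage

    def __post_init__(self):
        if not 0 < self.sample_max_fail_frac < 1:
            raise ValueError("sample_max_fail_frac must be in (0, 1)")
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid k range")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not 0 < self.logit_eps < 0.5:
            raise ValueError("logit_eps must be in (0, 0.5)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_qc(
    raw: RawIntensitySet,
    manifest: ProbeManifest,
    config: PipelineConfig | None = None,
    ineligible_tumors=(),
) -> BetaMatrix:
    """Sample filter → probe filters → ineligible-tumor drop → replicate averaging.

    Returns the tumor-level β matrix with the full provenance log.
    """
    if config is None:
        config = PipelineConfig()
    retained_samples, removed_samples = filter_samples(
        raw, p_thresh=config.detection_p_thresh, max_fail_frac=config.sample_max_fail_frac
    )
    beta = BetaMatrix(compute_beta(raw.cy5.loc[:, retained_samples], raw.cy3.loc[:, retained_samples]))
    beta.provenance.append(
        FilterRecord(
            "sample_qc", len(raw.samples), len(removed_samples),
            len(retained_samples), tuple(removed_samples),
        )
    )
    det_fail = detect_failed_probes(raw, retained_samples, p_thresh=config.detection_p_thresh)
    beta = filter_probes(beta, manifest, det_fail, sd_min=config.probe_sd_min)
    ineligible_samples = [
        s for t in ineligible_tumors for s in raw.replicate_map.get(t, [])
    ]
    if ineligible_samples:
        beta = drop_tumors(beta, ineligible_samples, stage="ineligible")
    return average_replicates(beta, raw.replicate_map)


#: Differential comparisons run by the diff stage:
#: name -> (factor column, contrast or "ordinal")
DEFAULT_COMPARISONS: dict[str, tuple] = {
    "hr_status": ("hr_status", ("HR+", "HR-")),
    "subtype": ("subtype", ("LuminalA", "Basal-like")),
    "p53": ("p53", ("Wild-type", "Mutant")),
    "grade": ("grade", "ordinal"),
    "stage": ("stage", "ordinal"),
    "tumor_size": ("tumor_size", ("<=2cm", ">2-5cm")),
    "node_status": ("node_status", ("Negative", "Positive")),
}

#: Multivariate Cox adjustment terms for the cluster model.
COX_ADJUSTMENT = ["age", "menopause", "race", "stage_ord", "hr_status", "grade_2or3", "node_status", "size_cat"]


def _survival_frame(annotation: pd.DataFrame, clusters: pd.Series, endpoint: str) -> pd.DataFrame:
    time_col, event_col = f"time_{endpoint}", f"event_{endpoint}"
    df = pd.DataFrame(
        {
            "time": annotation[time_col],
            "event": annotation[event_col],
            "cluster": pd.Categorical(clusters.reindex(annotation.index)),
        },
        index=annotation.index,
    )
    for col in ("age", "menopause", "race", "hr_status", "node_status"):
        if col in annotation:
            df[col] = annotation[col]
    if "stage" in annotation:
        df["stage_ord"] = pd.to_numeric(annotation["stage"], errors="coerce")
    if "grade" in annotation:
        grade = pd.to_numeric(annotation["grade"], errors="coerce")
        df["grade_2or3"] = (grade >= 2).astype(float).where(grade.notna())
    if "tumor_size" in annotation:
        df["size_cat"] = annotation["tumor_size"]
    return df


def _cluster_indicators(clusters: pd.Series, reference: int) -> pd.DataFrame:
    out = {}
    for c in sorted(clusters.dropna().unique()):
        if c == reference:
            continue
        out[f"cluster{c}"] = (clusters == c).astype(float)
    return pd.DataFrame(out, index=clusters.index)


def run_all(
    config: PipelineConfig | None = None,
    outdir=None,
    dataset=None,
) -> dict:
    """Run the full pipeline; returns the run manifest (also written to disk).

    If ``dataset`` is None the simulate stage generates one from
    ``config.sim`` overrides with the master seed.
    """
    if config is None:
        config = PipelineConfig()
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    manifest_log: dict = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
    }
    manifest_log["config_hash"] = hashlib.sha256(
        json.dumps(manifest_log["config"], sort_keys=True).encode()
    ).hexdigest()[:16]

    # ---- simulate -------------------------------------------------------
    if dataset is None:
        sim_cfg = SimConfig(**{**config.sim, "seed": config.seed})
        dataset = generate_dataset(sim_cfg)
        manifest_log["stages"]["simulate"] = {
            "n_tumors": sim_cfg.n_tumors,
            "n_probes": sim_cfg.n_probes,
            "n_samples": len(dataset.intensities.samples),
        }

    # ---- qc -------------------------------------------------------------
    beta = run_qc(
        dataset.intensities, dataset.manifest, config,
        ineligible_tumors=dataset.ineligible_tumors,
    )
    concord = replicate_concordance(
        BetaMatrix(compute_beta(dataset.intensities.cy5, dataset.intensities.cy3)),
        dataset.intensities.replicate_map,
    )
    manifest_log["stages"]["qc"] = {
        "provenance": [dataclasses.asdict(r) | {"removed": None} for r in beta.provenance],
        "n_probes_retained": int(len(beta.probes)),
        "n_tumors_retained": int(len(beta.samples)),
        "replicate_concordance_median": float(np.nanmedian(concord)) if len(concord) else None,
    }

    # ---- cluster --------------------------------------------------------
    variant = select_variant_probes(beta, sd_cut=config.variant_sd_cut)
    X = beta.beta.loc[variant].T  # tumors x probes
    model = ConsensusKMeans(
        k_range=range(config.k_min, config.k_max + 1),
        n_iter=config.n_iter,
        subsample_frac=config.subsample_frac,
        consensus_threshold=config.consensus_threshold,
        random_state=config.seed,
    ).fit(X)
    assignment = model.assignment_series()
    ann = dataset.annotation.loc[assignment.index]
    summary = summarize_clusters(
        beta.beta.loc[variant], assignment, ann,
        categorical=[c for c in ("hr_status", "subtype", "p53", "race", "menopause",
                                 "node_status", "tumor_size", "grade", "stage", "age_band")
                     if c in ann.columns],
        continuous=[c for c in ("age",) if c in ann.columns],
    )
    manifest_log["stages"]["cluster"] = {
        "n_variant_probes": int(len(variant)),
        "chosen_k": int(model.best_k_),
        "cluster_sizes": {int(k): int(v) for k, v in assignment.value_counts().items()},
        "cluster_consensus": {
            int(k): {int(c): float(v) for c, v in cc.items()}
            for k, cc in model.cluster_consensus_.items()
        },
        "mean_beta_per_cluster": summary["mean_beta"],
    }

    # ---- differential ---------------------------------------------------
    diff_results: dict[str, pd.DataFrame] = {}
    diff_counts = {}
    for name, (col, contrast) in DEFAULT_COMPARISONS.items():
        if col not in ann.columns:
            continue
        kwargs = {"ordinal": True} if contrast == "ordinal" else {"contrast": contrast}
        res = run_comparison(
            beta.beta, ann, name, col, eps=config.logit_eps,
            alpha=config.fdr_alpha, **kwargs,
        )
        diff_results[name] = res
        n_hyper, n_hypo = direction_summary(res, alpha=config.fdr_alpha)
        diff_counts[name] = {
            "n_significant": int((res["q"] < config.fdr_alpha).sum()),
            "n_hyper": n_hyper,
            "n_hypo": n_hypo,
            "n_used": res.attrs["n_used"],
            "n_dropped": res.attrs["n_dropped"],
        }
    sig_sets = {
        name: set(res.index[res["q"] < config.fdr_alpha])
        for name, res in diff_results.items()
        if name in ("hr_status", "subtype", "p53")
    }
    venn = overlap_sets(sig_sets) if len(sig_sets) == 3 else {}

    # hypermethylated-cluster signature: rank test per variant probe,
    # chosen cluster (highest mean beta) vs all other tumors
    hyper_cluster = max(summary["mean_beta"], key=summary["mean_beta"].get)
    in_c = assignment.index[assignment == hyper_cluster]
    out_c = assignment.index[assignment != hyper_cluster]
    sig_rows = []
    for probe in variant:
        stat, p = wilcoxon_rank_sum(
            beta.beta.loc[probe, in_c].dropna(), beta.beta.loc[probe, out_c].dropna()
        )
        sig_rows.append((probe, stat, p))
    signature = pd.DataFrame(sig_rows, columns=["probe_id", "statistic", "raw_p"]).set_index("probe_id")
    signature["q"] = bh_fdr(signature["raw_p"].to_numpy())
    signature["direction"] = np.where(
        beta.beta.loc[signature.index, in_c].mean(axis=1)
        > beta.beta.loc[signature.index, out_c].mean(axis=1),
        "hyper", "hypo",
    )
    signature_probes = signature.index[signature["q"] < config.fdr_alpha]
    manifest_log["stages"]["differential"] = {
        "comparisons": diff_counts,
        "venn_regions": {"+".join(sorted(k)): v for k, v in venn.items()},
        "hyper_cluster": int(hyper_cluster),
        "n_signature_probes": int(len(signature_probes)),
    }

    # methylation-expression correlation on the designated genes
    probe_gene = dataset.manifest.table.loc[variant, "gene_symbol"]
    probe_gene = probe_gene[probe_gene.isin(dataset.expression.index)]
    corr = methylation_expression_correlation(
        beta.beta, dataset.expression, probe_gene,
        strata=ann["subtype"] if "subtype" in ann.columns else None,
    )
    if len(corr):
        overall = corr[corr["stratum"] == "all"]
        manifest_log["stages"]["expression"] = {
            "n_pairs": int(len(overall)),
            "mean_r": float(overall["r"].mean()),
            "frac_significant_negative": float(
                ((overall["p"] < 0.05) & (overall["r"] < 0)).mean()
            ),
        }

    # ---- survival -------------------------------------------------------
    surv_stage = {}
    for endpoint in ("dss", "os"):
        frame = _survival_frame(ann, assignment, endpoint)
        km = kaplan_meier(frame, group_col="cluster")
        chi2, dfree, p = log_rank(frame, group_col="cluster")
        reference = int(assignment.value_counts().idxmax())
        ind = _cluster_indicators(assignment, reference)
        uni = cox_fit(
            frame.join(ind), list(ind.columns), ties=config.ties, endpoint=endpoint
        )
        multi_terms = list(ind.columns) + [c for c in COX_ADJUSTMENT if c in frame.columns]
        multi = cox_fit(
            frame.join(ind), multi_terms, ties=config.ties, endpoint=endpoint
        )
        ph = ph_check(multi) if multi.converged else None
        surv_stage[endpoint] = {
            "log_rank": {"chi2": chi2, "df": dfree, "p": p},
            "reference_cluster": reference,
            "univariate_hr": {t: float(uni.table.loc[t, "hr"]) for t in ind.columns},
            "multivariate_hr": {
                t: float(multi.table.loc[t, "hr"]) for t in ind.columns
            } if multi.converged else None,
            "ph_global_p": (float(ph.loc["global", "p"]) if ph is not None else None),
        }
        if outdir is not None:
            for g, tab in km.items():
                tab.to_csv(outdir / f"km_{endpoint}_cluster{g}.tsv", sep="\t", index=False)
            uni.table.to_csv(outdir / f"cox_{endpoint}_univariate.tsv", sep="\t")
            if multi.converged:
                multi.table.to_csv(outdir / f"cox_{endpoint}_multivariate.tsv", sep="\t")
    manifest_log["stages"]["survival"] = surv_stage

    # ---- enrichment -----------------------------------------------------
    background = dedupe_genes(list(beta.probes), dataset.manifest)
    gene_list = dedupe_genes(list(signature_probes), dataset.manifest)
    enr = enrich(gene_list, dataset.gene_sets, background, alpha=config.fdr_alpha)
    manifest_log["stages"]["enrichment"] = {
        "background_size": len(background),
        "list_size": len(gene_list),
        "n_terms_tested": int(len(enr)),
        "n_significant_terms": int(enr["significant"].sum()) if len(enr) else 0,
    }

    # ---- outputs --------------------------------------------------------
    if outdir is not None:
        mio.write_beta_matrix(beta, outdir / "beta_filtered.tsv")
        beta.provenance_frame().to_csv(outdir / "qc_provenance.tsv", sep="\t", index=False)
        assignment.to_csv(outdir / "cluster_assignment.tsv", sep="\t")
        for k, cm in model.consensus_matrices_.items():
            pd.DataFrame(cm, index=assignment.index, columns=assignment.index).to_csv(
                outdir / f"consensus_k{k}.tsv", sep="\t"
            )
        for name, res in diff_results.items():
            res.to_csv(outdir / f"diff_{name}.tsv", sep="\t", index_label="probe_id")
            volcano = pd.DataFrame(
                {"estimate": res["estimate"], "neg_log10_p": -np.log10(res["raw_p"])}
            )
            volcano.to_csv(outdir / f"volcano_{name}.tsv", sep="\t", index_label="probe_id")
        signature.to_csv(outdir / "hyper_cluster_signature.tsv", sep="\t", index_label="probe_id")
        if len(corr):
            corr.to_csv(outdir / "methylation_expression_corr.tsv", sep="\t", index=False)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest_log, fh, indent=2, default=str)
    return manifest_log


def validate_inputs(paths: dict) -> list[dict]:
    """Schema checks on pipeline input files; returns row-level diagnostics.

    ``paths`` may contain keys beta / intensities / samples / manifest /
    annotation.  An empty report means the inputs look clean.
    """
    report: list[dict] = []

    def _missing(kind, path):
        report.append({"file": str(path), "problem": f"{kind} file not found"})

    if "manifest" in paths:
        path = Path(paths["manifest"])
        if not path.exists():
            _missing("manifest", path)
        else:
            tab = pd.read_csv(path, sep="\t")
            if "probe_id" not in tab.columns:
                report.append({"file": str(path), "problem": "missing probe_id column"})
            else:
                dupes = tab["probe_id"][tab["probe_id"].duplicated()]
                for _, d in dupes.items():
                    report.append({"file": str(path), "problem": f"duplicate probe_id {d}"})
    if "beta" in paths:
        path = Path(paths["beta"])
        if not path.exists():
            _missing("beta", path)
        else:
            frame = pd.read_csv(path, sep="\t", index_col=0)
            bad = frame.stack()[(frame.stack() < 0) | (frame.stack() > 1)]
            for (probe, sample), val in bad.items():
                report.append(
                    {
                        "file": str(path),
                        "problem": f"beta value {val} outside [0,1]",
                        "probe_id": probe,
                        "sample_id": sample,
                    }
                )
            if frame.index.duplicated().any():
                for d in frame.index[frame.index.duplicated()]:
                    report.append({"file": str(path), "problem": f"duplicate probe_id {d}"})
    if "annotation" in paths:
        path = Path(paths["annotation"])
        if not path.exists():
            _missing("annotation", path)
        else:
            ann = pd.read_csv(path, sep="\t")
            if "tumor_id" not in ann.columns:
                report.append({"file": str(path), "problem": "missing tumor_id column"})
    if "intensities" in paths:
        path = Path(paths["intensities"])
        if not path.exists():
            _missing("intensities", path)
        else:
            head = pd.read_csv(path, sep="\t", nrows=5)
            need = {"sample_id", "probe_id", "cy5", "cy3", "detection_p"}
            lack = need - set(head.columns)
            if lack:
                report.append({"file": str(path), "problem": f"missing columns {sorted(lack)}"})
    return report
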