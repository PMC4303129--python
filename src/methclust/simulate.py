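"""Synthetic methylation-cohort generator.

Emulates the statistical structure of a population-based breast-tumor
promoter-methylation array study so that every downstream stage (QC,
consensus clustering, differential testing, survival, enrichment) can be
exercised and validated without any external data:

* four latent tumor clusters with distinct β profiles over blocks of
  variant CpG probes, one cluster globally hypermethylated;
* β noise drawn from beta distributions parameterised by (mean, precision),
  with a tumor-level biological layer and a measurement layer so replicate
  samples of one tumor are concordant (Pearson r > 0.9) while probes still
  vary across tumors;
* two-channel intensities that invert the β formula exactly, with detection
  p-values arranged so controlled numbers of samples and probes fail each
  QC rule;
* clinical covariates drawn conditionally on the latent cluster from
  cluster-wise composition counts of the emulated cohort;
* exponential survival with cluster-specific hazards and independent
  censoring; a separate other-cause hazard yields the overall-survival
  endpoint;
* log-scale expression values inversely correlated with methylation for a
  designated gene subset.

Everything flows from one seeded :class:`numpy.random.Generator`, so a
given config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ProbeManifest, RawIntensitySet
from .enrichment import GeneSetAnnotation

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_dataset",
    "generate_intensities",
    "generate_survival",
    "DEFAULT_CLUSTER_SIZES",
    "DEFAULT_COVARIATE_COUNTS",
    "DEFAULT_BLOCK_MEANS",
]

#: Observed sizes of the four methylation clusters in the emulated cohort.
DEFAULT_CLUSTER_SIZES = (123, 108, 99, 187)

#: Per-cluster composition counts for each clinical covariate (one row of
#: counts per cluster, clusters ordered 1..4).  Drawing covariates from
#: these counts reproduces the cluster <-> phenotype associations of the
#: emulated cohort: cluster 2 basal-enriched / HR-negative / p53-mutant /
#: high grade; clusters 3-4 luminal-enriched; cluster 3 with the highest
#: node positivity.
DEFAULT_COVARIATE_COUNTS: dict[str, dict] = {
    "age_band": {
        "levels": ["<50", "50+"],
        "counts": [[73, 50], [82, 26], [54, 45], [109, 78]],
    },
    "race": {
        "levels": ["White/Other", "African-American"],
        "counts": [[66, 57], [53, 55], [58, 41], [124, 63]],
    },
    "menopause": {
        "levels": ["Postmenopausal", "Premenopausal"],
        "counts": [[61, 62], [39, 69], [51, 48], [91, 96]],
    },
    "stage": {
        "levels": [1, 2, 3, 4],
        "counts": [[58, 48, 12, 1], [26, 58, 9, 4], [24, 56, 11, 3], [70, 83, 13, 5]],
    },
    "tumor_size": {
        "levels": ["<=2cm", ">2-5cm", ">5cm"],
        "counts": [[72, 39, 9], [35, 53, 11], [36, 49, 11], [107, 64, 11]],
    },
    "node_status": {
        "levels": ["Positive", "Negative"],
        "counts": [[44, 76], [40, 62], [48, 48], [75, 105]],
    },
    "grade": {
        "levels": [1, 2, 3],
        "counts": [[29, 34, 58], [3, 16, 87], [17, 40, 42], [77, 66, 41]],
    },
    "hr_status": {
        "levels": ["HR+", "HR-"],
        "counts": [[69, 51], [20, 81], [83, 13], [166, 18]],
    },
    "subtype": {
        "levels": ["LuminalA", "LuminalB", "Basal-like", "HER2+/HR-", "Unclassified"],
        "counts": [[48, 12, 25, 6, 8], [12, 5, 54, 7, 10], [52, 17, 3, 8, 1], [100, 31, 4, 5, 5]],
    },
    "p53": {
        "levels": ["Mutant", "Wild-type"],
        "counts": [[59, 64], [90, 18], [25, 74], [44, 141]],
    },
}

#: Per-cluster mean β for each block of variant probes (rows: blocks,
#: columns: clusters 1..4).  Cluster 3 (index 2) is the globally
#: hypermethylated one; every block keeps an across-cluster SD comfortably
#: above the 0.2 variant-probe cut.
DEFAULT_BLOCK_MEANS = (
    (0.15, 0.70, 0.80, 0.30),
    (0.30, 0.15, 0.80, 0.65),
    (0.15, 0.40, 0.80, 0.20),
    (0.60, 0.15, 0.85, 0.70),
)

#: Univariate cluster hazard ratios of the emulated cohort (vs cluster 4).
DEFAULT_CLUSTER_HR = (1.11, 1.91, 1.71, 1.00)


def _default_survival_model() -> dict:
    return {
        "baseline_hazard": 0.01,  # disease-specific events per month, reference cluster
        "log_hr": tuple(float(np.log(h)) for h in DEFAULT_CLUSTER_HR),
        "censoring_rate": 0.30,
        "other_cause_hazard": 0.002,  # drives the overall-survival endpoint
    }


def _default_covariate_model() -> dict:
    model = {}
    for name, spec in DEFAULT_COVARIATE_COUNTS.items():
        counts = np.asarray(spec["counts"], dtype=float)
        model[name] = {
            "levels": list(spec["levels"]),
            "probs": (counts / counts.sum(axis=1, keepdims=True)).tolist(),
        }
    return model


@dataclass
class SimConfig:
    """Generative parameters for one synthetic cohort.

    The defaults are the study conditions of the emulated cohort:
    ~500 tumors x 1000 probes, four clusters sized proportionally to
    123/108/99/187, 167 variant probes in four blocks, 90 replicated tumors
    (89 duplicates + 1 triplicate), QC-fail probe counts 273/13/93 (scaled
    from 411/19/140 on a 1505-probe panel), 13 QC-failing samples and 3
    ineligible tumors, cluster hazard ratios (1.11, 1.91, 1.71, 1.00) and a
    planted methylation-expression correlation of -0.6.
    """

    n_tumors: int = 500
    n_probes: int = 1000
    n_clusters: int = 4
    cluster_proportions: tuple = tuple(
        s / sum(DEFAULT_CLUSTER_SIZES) for s in DEFAULT_CLUSTER_SIZES
    )
    block_means: tuple = DEFAULT_BLOCK_MEANS
    n_variant_probes: int = 167
    precision: float = 100.0  # measurement-layer beta concentration
    bio_precision: float = 30.0  # tumor-level layer for background probes
    variant_bio_precision: float = 150.0  # tumor-level layer for variant probes
    low_sd_precision: float = 2000.0  # designated low-SD probes
    hyper_cluster_index: int = 2
    n_replicated_tumors: int = 90
    qc_fail_counts: tuple = (273, 13, 93)  # (snp_flagged, detect_fail, low_sd)
    n_failed_samples: int = 13
    n_ineligible: int = 3
    covariate_model: dict = field(default_factory=_default_covariate_model)
    missing_rate: float = 0.02
    survival_model: dict = field(default_factory=_default_survival_model)
    expression_r: float = -0.6
    n_expression_genes: int = 50
    n_control_genes: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("invalid config field n_tumors: must be >= 1")
        if self.n_clusters < 1:
            raise ValueError("invalid config field n_clusters: must be >= 1")
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.shape != (self.n_clusters,):
            raise ValueError("invalid config field cluster_proportions: wrong length")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("invalid config field cluster_proportions: must sum to 1")
        bm = np.asarray(self.block_means, dtype=float)
        if bm.ndim != 2 or bm.shape[1] != self.n_clusters:
            raise ValueError("invalid config field block_means: shape mismatch")
        if bm.min() < 0 or bm.max() > 1:
            raise ValueError("invalid config field block_means: values outside [0, 1]")
        if self.precision <= 0:
            raise ValueError("invalid config field precision: must be > 0")
        if not 0 <= self.hyper_cluster_index < self.n_clusters:
            raise ValueError("invalid config field hyper_cluster_index: out of range")
        qc = tuple(int(c) for c in self.qc_fail_counts)
        if len(qc) != 3 or any(c < 0 for c in qc):
            raise ValueError("invalid config field qc_fail_counts: need 3 counts >= 0")
        if sum(qc) + self.n_variant_probes >= self.n_probes:
            raise ValueError(
                "invalid config field qc_fail_counts: fail sets plus variant probes "
                "must leave background probes"
            )
        reserved = self.n_replicated_tumors + self.n_failed_samples + self.n_ineligible
        if reserved > self.n_tumors:
            raise ValueError(
                "invalid config field n_replicated_tumors: replicated + failed + "
                "ineligible tumors exceed n_tumors"
            )
        sm = self.survival_model
        if not 0 <= sm["censoring_rate"] < 1:
            raise ValueError("invalid config field survival_model: censoring_rate in [0,1)")
        if not np.all(np.isfinite(sm["log_hr"])):
            raise ValueError("invalid config field survival_model: log_hr must be finite")
        if len(sm["log_hr"]) != self.n_clusters:
            raise ValueError("invalid config field survival_model: one log_hr per cluster")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def scaled(cls, n_tumors: int | None = None, n_probes: int | None = None, **kwargs) -> "SimConfig":
        """Default config rescaled to a different cohort size.

        Probe-class counts (variant, QC-fail) scale with n_probes and the
        replicated/failed/ineligible tumor counts with n_tumors, keeping
        the default composition.
        """
        base = cls()
        if n_probes is not None:
            f = n_probes / base.n_probes
            kwargs.setdefault("n_probes", n_probes)
            kwargs.setdefault("n_variant_probes", max(8, int(round(base.n_variant_probes * f))))
            kwargs.setdefault(
                "qc_fail_counts", tuple(int(round(c * f)) for c in base.qc_fail_counts)
            )
        if n_tumors is not None:
            f = n_tumors / base.n_tumors
            kwargs.setdefault("n_tumors", n_tumors)
            kwargs.setdefault("n_replicated_tumors", int(round(base.n_replicated_tumors * f)))
            kwargs.setdefault("n_failed_samples", int(round(base.n_failed_samples * f)))
            kwargs.setdefault("n_ineligible", int(round(base.n_ineligible * f)))
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class SyntheticDataset:
    """Bundle of everything the pipeline consumes, plus ground truth."""

    intensities: RawIntensitySet
    manifest: ProbeManifest
    annotation: pd.DataFrame  # index: tumor_id
    expression: pd.DataFrame  # genes x tumors
    truth_clusters: pd.Series  # tumor_id -> latent cluster label (1-based)
    probe_roles: pd.Series  # probe_id -> variant_block{i}|background|snp_flagged|detect_fail|low_sd
    tumor_beta: pd.DataFrame  # latent tumor-level beta (probes x tumors), pre-measurement
    gene_sets: list  # GeneSetAnnotation terms (one planted, rest random)
    expression_probes: pd.Series  # designated gene -> representative CpG probe
    ineligible_tumors: tuple
    failed_sample_tumors: tuple
    config: SimConfig

    def variant_probes(self) -> pd.Index:
        return self.probe_roles.index[self.probe_roles.str.startswith("variant")]


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, conc: float) -> np.ndarray:
    """Beta draw parameterised by (mean, concentration); degenerate means pass through."""
    mean = np.asarray(mean, dtype=float)
    out = np.empty_like(mean)
    interior = (mean > 0) & (mean < 1)
    a = mean[interior] * conc
    b = (1.0 - mean[interior]) * conc
    out[interior] = rng.beta(a, b)
    out[~interior] = mean[~interior]
    return out


def generate_intensities(
    beta_target: pd.DataFrame,
    cfg: SimConfig | None = None,
    *,
    fail_samples=(),
    fail_probes=(),
    rng: np.random.Generator | None = None,
    fail_frac: float = 0.30,
    unmeth_scale: float = 5000.0,
) -> RawIntensitySet:
    """Emit Cy5/Cy3 intensities whose β round-trips to ``beta_target`` exactly.

    For target b < 1 we set Cy3 = (1-b)*scale and solve
    Cy5 = b*(Cy3+100)/(1-b), which makes max(Cy5,0)/(|Cy5|+|Cy3|+100) equal
    b to machine precision.  b = 1 is rejected: with the +100 offset the
    ratio cannot attain 1.

    ``fail_samples`` get detection p > 1e-5 on a ``fail_frac`` fraction of
    probes (deterministically the first ones); ``fail_probes`` get failing
    detection p in every sample, so the per-probe median rule trips.
    """
    if rng is None:
        rng = np.random.default_rng(0 if cfg is None else cfg.seed)
    b = beta_target.to_numpy(dtype=float)
    if np.any(~np.isfinite(b)) or b.min() < 0 or b.max() > 1:
        raise ValueError("beta targets must be finite and in [0, 1)")
    if np.any(b >= 1.0):
        raise ValueError("beta target of exactly 1 cannot be produced (offset +100)")
    cy3 = (1.0 - b) * unmeth_scale
    cy5 = b * (cy3 + 100.0) / (1.0 - b)

    n_probes, n_samples = b.shape
    # reliable baseline detection p: log-uniform in [1e-9, 1e-6]
    detp = 10.0 ** rng.uniform(-9, -6, size=b.shape)
    probe_pos = {p: i for i, p in enumerate(beta_target.index)}
    sample_pos = {s: j for j, s in enumerate(beta_target.columns)}
    n_fail = int(round(fail_frac * n_probes))
    for s in fail_samples:
        detp[:n_fail, sample_pos[s]] = 10.0 ** rng.uniform(-4, -2, size=n_fail)
    for p in fail_probes:
        detp[probe_pos[p], :] = 10.0 ** rng.uniform(-4, -2, size=n_samples)

    idx, cols = beta_target.index, beta_target.columns
    replicate_map = {str(s): [str(s)] for s in cols}
    return RawIntensitySet(
        cy5=pd.DataFrame(cy5, index=idx, columns=cols),
        cy3=pd.DataFrame(cy3, index=idx, columns=cols),
        detection_p=pd.DataFrame(detp, index=idx, columns=cols),
        replicate_map=replicate_map,
    )


def generate_survival(
    truth_labels,
    survival_model: dict,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential event times with cluster-specific rates and independent censoring.

    Event time T ~ Exp(h0 * exp(log_hr[cluster])); censoring time
    C ~ Exp(h0 * c/(1-c)) so that a reference-cluster subject is censored
    with probability ~c.  Returns columns ``time`` (months) and ``event``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = pd.Series(truth_labels)
    log_hr = np.asarray(survival_model["log_hr"], dtype=float)
    if not np.all(np.isfinite(log_hr)):
        raise ValueError("log hazard ratios must be finite")
    c = float(survival_model["censoring_rate"])
    if not 0 <= c < 1:
        raise ValueError("censoring_rate must be in [0, 1)")
    h0 = float(survival_model["baseline_hazard"])
    rate = h0 * np.exp(log_hr[labels.to_numpy(dtype=int) - 1])
    t_event = rng.exponential(1.0 / rate)
    if c > 0:
        t_cens = rng.exponential(1.0 / (h0 * c / (1.0 - c)), size=len(labels))
    else:
        t_cens = np.full(len(labels), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event}, index=labels.index)


def _make_manifest(rng, probe_ids, flagged: set) -> ProbeManifest:
    """Assign probes to genes with realistic multiplicity (~1.75 probes/gene)."""
    genes = []
    gene_no = 0
    i = 0
    while i < len(probe_ids):
        gene_no += 1
        mult = rng.choice([1, 2, 3], p=[0.45, 0.35, 0.20])
        name = f"GENE{gene_no:04d}"
        take = min(int(mult), len(probe_ids) - i)
        genes.extend([name] * take)
        i += take
    table = pd.DataFrame(
        {
            "gene_symbol": genes,
            "snp_repeat_flag": [p in flagged for p in probe_ids],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(table)


def generate_dataset(cfg: SimConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic cohort under ``cfg`` (deterministic given seed)."""
    if cfg is None:
        cfg = SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_snp, n_det, n_lowsd = (int(c) for c in cfg.qc_fail_counts)
    probe_ids = [f"cg{i:05d}" for i in range(cfg.n_probes)]
    block_means = np.asarray(cfg.block_means, dtype=float)
    n_blocks = block_means.shape[0]

    # contiguous probe layout: variant blocks, then each QC-fail class, then background
    roles = np.empty(cfg.n_probes, dtype=object)
    block_sizes = np.full(n_blocks, cfg.n_variant_probes // n_blocks)
    block_sizes[: cfg.n_variant_probes % n_blocks] += 1
    pos = 0
    block_of_probe = np.full(cfg.n_probes, -1)
    for b, size in enumerate(block_sizes):
        roles[pos : pos + size] = f"variant_block{b}"
        block_of_probe[pos : pos + size] = b
        pos += size
    roles[pos : pos + n_snp] = "snp_flagged"
    pos += n_snp
    roles[pos : pos + n_det] = "detect_fail"
    pos += n_det
    roles[pos : pos + n_lowsd] = "low_sd"
    pos += n_lowsd
    roles[pos:] = "background"
    probe_roles = pd.Series(roles, index=pd.Index(probe_ids, name="probe_id"))

    # latent cluster per tumor (1-based labels)
    tumor_ids = [f"T{i:04d}" for i in range(cfg.n_tumors)]
    clusters = rng.choice(
        np.arange(1, cfg.n_clusters + 1), size=cfg.n_tumors, p=cfg.cluster_proportions
    )
    truth = pd.Series(clusters, index=pd.Index(tumor_ids, name="tumor_id"), name="cluster")

    # tumor-level beta (biological layer), probes x tumors
    tumor_beta = np.empty((cfg.n_probes, cfg.n_tumors))
    is_variant = block_of_probe >= 0
    variant_rows = np.where(is_variant)[0]
    for k in range(1, cfg.n_clusters + 1):
        cols = np.where(clusters == k)[0]
        if cols.size == 0:
            continue
        means = block_means[block_of_probe[variant_rows], k - 1]
        grid = np.repeat(means[:, None], cols.size, axis=1)
        tumor_beta[np.ix_(variant_rows, cols)] = _beta_draw(
            rng, grid, cfg.variant_bio_precision
        )
    nonvariant_rows = np.where(~is_variant)[0]
    base_mean = rng.uniform(0.25, 0.75, size=nonvariant_rows.size)
    lowsd_mask = roles[nonvariant_rows] == "low_sd"
    grid = np.repeat(base_mean[:, None], cfg.n_tumors, axis=1)
    bio = _beta_draw(rng, grid, cfg.bio_precision)
    # low-SD probes: no biological layer, near-constant across tumors
    bio[lowsd_mask, :] = grid[lowsd_mask, :]
    tumor_beta[nonvariant_rows, :] = bio
    tumor_beta_df = pd.DataFrame(tumor_beta, index=probe_ids, columns=tumor_ids)

    # tumor role assignment: replicated / QC-failing / ineligible, all disjoint
    order = rng.permutation(cfg.n_tumors)
    rep_idx = order[: cfg.n_replicated_tumors]
    fail_idx = order[cfg.n_replicated_tumors : cfg.n_replicated_tumors + cfg.n_failed_samples]
    inel_idx = order[
        cfg.n_replicated_tumors
        + cfg.n_failed_samples : cfg.n_replicated_tumors
        + cfg.n_failed_samples
        + cfg.n_ineligible
    ]
    replicated = [tumor_ids[i] for i in sorted(rep_idx)]
    failed_tumors = tuple(tumor_ids[i] for i in sorted(fail_idx))
    ineligible = tuple(tumor_ids[i] for i in sorted(inel_idx))

    # samples: replicated tumors get 2 (first one: 3) hybridisations
    replicate_map: dict[str, list[str]] = {}
    sample_cols: list[str] = []
    sample_tumor: list[str] = []
    for t in tumor_ids:
        if t in set(replicated):
            n_rep = 3 if replicated and t == replicated[0] else 2
            ids = [f"{t}_r{j+1}" for j in range(n_rep)]
        else:
            ids = [f"{t}_r1"]
        replicate_map[t] = ids
        sample_cols.extend(ids)
        sample_tumor.extend([t] * len(ids))

    # measurement layer: beta per sample around the tumor-level mean
    col_idx = tumor_beta_df.columns.get_indexer(sample_tumor)
    sample_mean = tumor_beta[:, col_idx]
    lowsd_rows = np.where(roles == "low_sd")[0]
    sample_beta = _beta_draw(rng, sample_mean, cfg.precision)
    sample_beta[lowsd_rows, :] = _beta_draw(
        rng, sample_mean[lowsd_rows, :], cfg.low_sd_precision
    )
    sample_beta_df = pd.DataFrame(sample_beta, index=probe_ids, columns=sample_cols)

    detect_fail_probes = [probe_ids[i] for i in np.where(roles == "detect_fail")[0]]
    fail_sample_ids = [replicate_map[t][0] for t in failed_tumors]
    intensities = generate_intensities(
        sample_beta_df,
        cfg,
        fail_samples=fail_sample_ids,
        fail_probes=detect_fail_probes,
        rng=rng,
    )
    intensities.replicate_map.clear()
    intensities.replicate_map.update(replicate_map)

    manifest = _make_manifest(
        rng, probe_ids, {probe_ids[i] for i in np.where(roles == "snp_flagged")[0]}
    )

    # clinical covariates conditional on latent cluster
    ann = pd.DataFrame(index=truth.index)
    ann["cluster_truth"] = truth
    for name, spec in cfg.covariate_model.items():
        levels = np.asarray(spec["levels"], dtype=object)
        probs = np.asarray(spec["probs"], dtype=float)
        vals = np.empty(cfg.n_tumors, dtype=object)
        for k in range(1, cfg.n_clusters + 1):
            rows = np.where(clusters == k)[0]
            if rows.size:
                vals[rows] = rng.choice(levels, size=rows.size, p=probs[k - 1])
        ann[name] = vals
    if "age_band" in ann:
        young = ann["age_band"].to_numpy() == "<50"
        age = np.where(
            young, rng.uniform(25, 50, cfg.n_tumors), rng.uniform(50, 75, cfg.n_tumors)
        )
        ann["age"] = np.round(age, 1)
    if cfg.missing_rate > 0:
        for col in ("subtype", "p53", "stage", "tumor_size", "node_status", "grade"):
            if col in ann:
                mask = rng.random(cfg.n_tumors) < cfg.missing_rate
                ann.loc[mask, col] = np.nan

    # survival: disease-specific endpoint from the cluster model, plus an
    # independent other-cause hazard for the overall-survival endpoint
    dss = generate_survival(truth, cfg.survival_model, rng=rng)
    t_other = rng.exponential(
        1.0 / cfg.survival_model["other_cause_hazard"], size=cfg.n_tumors
    )
    ann["time_dss"] = dss["time"]
    ann["event_dss"] = dss["event"]
    ann["time_os"] = np.minimum(dss["time"], t_other)
    ann["event_os"] = ((dss["event"] == 1) | (t_other <= dss["time"])).astype(int)
    ann.loc[ann["time_os"] < ann["time_dss"], "event_dss"] = 0
    ann.loc[ann["time_os"] < ann["time_dss"], "time_dss"] = ann["time_os"]
    ann["eligible"] = [t not in set(ineligible) for t in ann.index]

    # expression inversely correlated with methylation for designated genes
    variant_probe_ids = probe_roles.index[probe_roles.str.startswith("variant")]
    gene_of = manifest.table.loc[variant_probe_ids, "gene_symbol"]
    designated = gene_of.drop_duplicates()[: cfg.n_expression_genes]
    rho = float(cfg.expression_r)
    expr_rows = {}
    expression_probes = {}
    for gene in designated:
        probe = gene_of.index[gene_of == gene][0]
        expression_probes[gene] = probe
        b = tumor_beta_df.loc[probe].to_numpy()
        z = (b - b.mean()) / b.std(ddof=0)
        e = rho * z + np.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(cfg.n_tumors)
        expr_rows[gene] = 8.0 + 2.0 * e
    # control genes: uncorrelated expression, drawn away from variant probes
    variant_gene_set = set(gene_of)
    background_genes = [
        g for g in manifest.table["gene_symbol"].unique() if g not in variant_gene_set
    ]
    for gene in background_genes[: cfg.n_control_genes]:
        expr_rows[gene] = 8.0 + 2.0 * rng.standard_normal(cfg.n_tumors)
    expression = pd.DataFrame(expr_rows, index=truth.index).T

    # annotation terms: one planted among the variant-probe genes (emulating
    # the developmental-gene enrichment of the hypermethylated cluster's
    # signature) plus random terms from the whole gene universe
    all_genes = list(dict.fromkeys(manifest.table["gene_symbol"]))
    variant_genes = list(dict.fromkeys(gene_of))
    planted = list(rng.choice(variant_genes, size=min(25, len(variant_genes)), replace=False))
    planted += list(rng.choice(all_genes, size=5, replace=False))
    gene_sets = [GeneSetAnnotation("TERM_DEV", "development (planted)", frozenset(planted))]
    for i in range(15):
        members = rng.choice(all_genes, size=20, replace=False)
        gene_sets.append(
            GeneSetAnnotation(f"TERM_R{i:02d}", f"random term {i}", frozenset(members))
        )

    return SyntheticDataset(
        intensities=intensities,
        manifest=manifest,
        annotation=ann,
        expression=expression,
        truth_clusters=truth,
        probe_roles=probe_roles,
        tumor_beta=tumor_beta_df,
        gene_sets=gene_sets,
        expression_probes=pd.Series(expression_probes, name="probe_id"),
        ineligible_tumors=ineligible,
        failed_sample_tumors=failed_tumors,
        config=cfg,
    )
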