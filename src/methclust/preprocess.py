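"""β-value computation and array quality control.

Implements the GoldenGate-style preprocessing chain: the β ratio from the
two channel intensities, removal of samples with too many unreliable
detection p-values, the ordered probe filters (SNP/repeat overlap →
detection failure → low standard deviation), replicate averaging and
concordance, variant-probe selection, and the clamped logit transform used
by the regression models.

β is defined as ``max(Cy5, 0) / (|Cy5| + |Cy3| + 100)`` where Cy5 is the
methylated-allele and Cy3 the unmethylated-allele signal; the +100 offset
stabilises the ratio at low intensities and keeps β strictly below 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import BetaMatrix, FilterRecord, ProbeManifest, RawIntensitySet

__all__ = [
    "compute_beta",
    "beta_from_intensities",
    "filter_samples",
    "detect_failed_probes",
    "filter_probes",
    "drop_tumors",
    "average_replicates",
    "replicate_concordance",
    "select_variant_probes",
    "logit_transform",
    "inverse_logit",
]

logger = logging.getLogger(__name__)

#: Offset added to total signal in the β denominator.
BETA_OFFSET = 100.0


def compute_beta(cy5, cy3):
    """β = max(Cy5, 0) / (|Cy5| + |Cy3| + 100), elementwise.

    Accepts scalars, arrays or DataFrames (shapes must match).  Result is
    always in [0, 1): a non-positive methylated signal gives exactly 0,
    and the +100 offset keeps the ratio strictly below 1.
    """
    cy5_arr = np.asarray(cy5, dtype=float)
    cy3_arr = np.asarray(cy3, dtype=float)
    if not (np.all(np.isfinite(cy5_arr)) and np.all(np.isfinite(cy3_arr))):
        raise ValueError("non-finite intensity values")
    beta = np.maximum(cy5_arr, 0.0) / (np.abs(cy5_arr) + np.abs(cy3_arr) + BETA_OFFSET)
    if isinstance(cy5, pd.DataFrame):
        return pd.DataFrame(beta, index=cy5.index, columns=cy5.columns)
    if np.isscalar(cy5) and np.isscalar(cy3):
        return float(beta)
    return beta


def beta_from_intensities(raw: RawIntensitySet) -> BetaMatrix:
    """Compute the β matrix for a whole intensity set (no filtering)."""
    return BetaMatrix(compute_beta(raw.cy5, raw.cy3))


def filter_samples(
    raw: RawIntensitySet,
    p_thresh: float = 1e-5,
    max_fail_frac: float = 0.25,
) -> tuple[pd.Index, pd.Index]:
    """Remove samples with too many unreliable detection p-values.

    A sample is removed iff the fraction of its probes with
    ``detection_p > p_thresh`` is *strictly greater* than ``max_fail_frac``
    (both comparisons strict: a sample at exactly 25% failing is retained).

    Returns ``(retained, removed)`` sample indexes.
    """
    if raw.detection_p.size == 0:
        raise ValueError("empty intensity set")
    fail_frac = (raw.detection_p > p_thresh).mean(axis=0)
    removed = fail_frac.index[fail_frac > max_fail_frac]
    retained = fail_frac.index[fail_frac <= max_fail_frac]
    logger.info(
        "sample filter: %d input, %d removed (>%.0f%% probes with p>%g), %d retained",
        len(fail_frac), len(removed), 100 * max_fail_frac, p_thresh, len(retained),
    )
    return retained, removed


def detect_failed_probes(
    raw: RawIntensitySet,
    samples: pd.Index | None = None,
    p_thresh: float = 1e-5,
) -> pd.Index:
    """Probes whose *median* detection p across retained samples exceeds p_thresh.

    The per-probe aggregation of cellwise detection p-values is a package
    choice (median over retained samples); the threshold itself matches the
    sample-level rule.
    """
    detp = raw.detection_p if samples is None else raw.detection_p.loc[:, samples]
    med = detp.median(axis=1)
    return med.index[med > p_thresh]


def filter_probes(
    beta: BetaMatrix,
    manifest: ProbeManifest,
    detection_fail,
    sd_min: float = 0.06,
) -> BetaMatrix:
    """Ordered probe filters: SNP/repeat flag → detection failure → low SD.

    The stages run strictly in that order and each stage's removal count is
    recorded in the provenance log.  SD is the sample standard deviation
    (n−1 denominator) across the retained samples, computed after the first
    two stages so the counts are stage-order dependent, and a probe is
    removed only if its SD is *strictly less* than ``sd_min``.
    """
    missing = beta.probes.difference(manifest.probe_ids)
    if len(missing):
        raise KeyError(f"manifest missing probes: {list(missing[:5])}")

    frame = beta.beta
    out = BetaMatrix(frame, provenance=list(beta.provenance))

    flagged = frame.index.intersection(manifest.flagged_probes)
    out.log("probe_snp_repeat_flag", len(frame.index), flagged)
    frame = frame.drop(index=flagged)

    det_fail = frame.index.intersection(pd.Index(detection_fail))
    out.log("probe_detection_fail", len(frame.index), det_fail)
    frame = frame.drop(index=det_fail)

    sd = frame.std(axis=1, ddof=1)
    low_sd = frame.index[sd < sd_min]
    out.log("probe_low_sd", len(frame.index), low_sd)
    frame = frame.drop(index=low_sd)

    out.beta = frame
    logger.info(
        "probe filter: flagged=%d detection=%d low_sd=%d retained=%d",
        len(flagged), len(det_fail), len(low_sd), len(frame.index),
    )
    return out


def drop_tumors(beta: BetaMatrix, samples_to_drop, stage: str = "ineligible") -> BetaMatrix:
    """Drop whole sample columns (e.g. tumors that became study-ineligible)."""
    drop = beta.samples.intersection(pd.Index(samples_to_drop))
    out = BetaMatrix(beta.beta.drop(columns=drop), provenance=list(beta.provenance))
    out.provenance.append(
        FilterRecord(stage, len(beta.samples), len(drop), len(beta.samples) - len(drop), tuple(drop))
    )
    return out


def average_replicates(beta: BetaMatrix, replicate_map: dict[str, list[str]]) -> BetaMatrix:
    """Collapse replicate sample columns to one tumor column by per-probe mean.

    Only samples present in the matrix (survivors of sample QC) are
    averaged; tumors whose samples were all removed are dropped with a log
    entry; singleton tumors pass through unchanged.
    """
    present = set(beta.samples)
    columns: dict[str, pd.Series] = {}
    dropped: list[str] = []
    for tumor, sample_ids in replicate_map.items():
        alive = [s for s in sample_ids if s in present]
        if not alive:
            dropped.append(tumor)
            continue
        if len(alive) == 1:
            columns[tumor] = beta.beta[alive[0]]
        else:
            columns[tumor] = beta.beta[alive].mean(axis=1)
    if dropped:
        logger.info("replicate averaging: %d tumors dropped (no surviving samples)", len(dropped))
    out = BetaMatrix(pd.DataFrame(columns), provenance=list(beta.provenance))
    out.provenance.append(
        FilterRecord(
            "replicate_averaging",
            len(beta.samples),
            len(beta.samples) - len(columns),
            len(columns),
            tuple(dropped),
        )
    )
    return out


def replicate_concordance(
    beta: BetaMatrix, replicate_map: dict[str, list[str]]
) -> pd.Series:
    """Pearson r between replicate sample pairs over shared non-missing probes.

    Pairs with fewer than 3 shared probes are reported as NaN.  For a
    triplicate, all three pairwise correlations are returned.
    """
    present = set(beta.samples)
    rows: dict[str, float] = {}
    for tumor, sample_ids in replicate_map.items():
        alive = [s for s in sample_ids if s in present]
        if len(alive) < 2:
            continue
        for i in range(len(alive)):
            for j in range(i + 1, len(alive)):
                a = beta.beta[alive[i]]
                b = beta.beta[alive[j]]
                ok = a.notna() & b.notna()
                key = f"{tumor}:{alive[i]}|{alive[j]}"
                if ok.sum() < 3:
                    rows[key] = np.nan
                    continue
                rows[key] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    return pd.Series(rows, dtype=float)


def select_variant_probes(beta: BetaMatrix, sd_cut: float = 0.2) -> pd.Index:
    """Probes whose across-tumor SD is >= sd_cut (SD < cut excluded)."""
    sd = beta.beta.std(axis=1, ddof=1)
    return sd.index[sd >= sd_cut]


def logit_transform(beta, eps: float = 1e-3):
    """log(β'/(1−β')) with β clamped into [eps, 1−eps].

    The clamp keeps boundary values (fully unmethylated/methylated loci)
    finite; eps must lie in (0, 0.5).
    """
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta outside [0, 1]")
    clamped = np.clip(arr, eps, 1 - eps)
    out = np.log(clamped / (1 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(out, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(out, index=beta.index)
    if np.isscalar(beta):
        return float(out)
    return out


def inverse_logit(x):
    """Logistic function; inverse of :func:`logit_transform` on (eps, 1−eps)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))
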