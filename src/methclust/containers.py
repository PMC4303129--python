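"""Core in-memory containers shared across the pipeline.

Conventions
-----------
All matrices are :class:`pandas.DataFrame` with **probes as rows** and
**samples (or tumors) as columns**.  A *sample* is one array hybridisation;
replicate samples of the same tumor are collapsed to a single tumor column
by :func:`methclust.preprocess.average_replicates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawIntensitySet",
    "ProbeManifest",
    "FilterRecord",
    "BetaMatrix",
]


@dataclass
class RawIntensitySet:
    """Two-channel bead-array intensities with per-cell detection p-values.

    Parameters
    ----------
    cy5 : DataFrame, probes x samples
        Methylated-allele channel signal (arbitrary fluorescence units,
        may be negative after background subtraction).
    cy3 : DataFrame, probes x samples
        Unmethylated-allele channel signal.
    detection_p : DataFrame, probes x samples
        Per-cell detection p-value in [0, 1].
    replicate_map : dict
        tumor_id -> list of sample_ids hybridised for that tumor.  Every
        sample column must appear in exactly one entry.
    """

    cy5: pd.DataFrame
    cy3: pd.DataFrame
    detection_p: pd.DataFrame
    replicate_map: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, frame in (("cy3", self.cy3), ("detection_p", self.detection_p)):
            if not frame.index.equals(self.cy5.index) or not frame.columns.equals(
                self.cy5.columns
            ):
                raise ValueError(f"{name} index/columns do not match cy5")
        mapped = [s for ids in self.replicate_map.values() for s in ids]
        if len(mapped) != len(set(mapped)):
            raise ValueError("a sample_id appears in more than one replicate_map entry")
        missing = set(self.cy5.columns) - set(mapped)
        if missing:
            raise ValueError(f"samples missing from replicate_map: {sorted(missing)}")

    @property
    def samples(self) -> pd.Index:
        return self.cy5.columns

    @property
    def probes(self) -> pd.Index:
        return self.cy5.index


@dataclass
class ProbeManifest:
    """Probe annotation: gene symbol and SNP/repeat overlap flag."""

    table: pd.DataFrame  # index: probe_id; columns: gene_symbol, snp_repeat_flag

    def __post_init__(self) -> None:
        if not self.table.index.is_unique:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe_id in manifest: {dupes[:5]}")
        for col in ("gene_symbol", "snp_repeat_flag"):
            if col not in self.table.columns:
                raise ValueError(f"manifest missing column {col!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def genes_for(self, probes) -> pd.Series:
        missing = [p for p in probes if p not in self.table.index]
        if missing:
            raise KeyError(f"probes absent from manifest: {missing[:5]}")
        return self.table.loc[list(probes), "gene_symbol"]

    @property
    def flagged_probes(self) -> pd.Index:
        return self.table.index[self.table["snp_repeat_flag"].astype(bool)]


@dataclass(frozen=True)
class FilterRecord:
    """One QC filtering stage: what ran, what it removed, what survived."""

    stage: str
    n_input: int
    n_removed: int
    n_retained: int
    removed: tuple = ()

    def __post_init__(self) -> None:
        if self.n_input - self.n_removed != self.n_retained:
            raise ValueError(
                f"provenance mismatch at {self.stage}: "
                f"{self.n_input} - {self.n_removed} != {self.n_retained}"
            )


@dataclass
class BetaMatrix:
    """Methylation fractions (β) with an ordered QC provenance log."""

    beta: pd.DataFrame  # probes x samples, values in [0, 1]
    provenance: list[FilterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values outside [0, 1]")

    @property
    def probes(self) -> pd.Index:
        return self.beta.index

    @property
    def samples(self) -> pd.Index:
        return self.beta.columns

    def log(self, stage: str, n_input: int, removed) -> None:
        removed = tuple(removed)
        self.provenance.append(
            FilterRecord(stage, n_input, len(removed), n_input - len(removed), removed)
        )

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": r.stage,
                    "n_input": r.n_input,
                    "n_removed": r.n_removed,
                    "n_retained": r.n_retained,
                }
                for r in self.provenance
            ]
        )
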