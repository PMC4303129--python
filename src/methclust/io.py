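"""Tabular I/O for the pipeline's standard file formats.

All tables are TSV with header rows.  β matrices are written with probes
as rows and samples/tumors as columns; intensities are written long
(sample_id, probe_id, cy5, cy3, detection_p) with a companion sample table
carrying the sample → tumor (replicate) mapping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import BetaMatrix, ProbeManifest, RawIntensitySet

__all__ = [
    "write_dataset",
    "read_intensities",
    "read_manifest",
    "read_annotation",
    "read_beta_matrix",
    "write_beta_matrix",
]


def write_beta_matrix(beta: BetaMatrix | pd.DataFrame, path) -> None:
    frame = beta.beta if isinstance(beta, BetaMatrix) else beta
    frame.to_csv(path, sep="\t", index_label="probe_id")


def read_beta_matrix(path) -> BetaMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="probe_id")
    return BetaMatrix(frame)


def write_dataset(dataset, outdir) -> dict[str, str]:
    """Write a synthetic dataset's pipeline inputs to a directory."""
    from .enrichment import write_gmt  # local import to keep io dependency-light
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    raw = dataset.intensities

    long = (
        raw.cy5.stack()
        .rename("cy5")
        .to_frame()
        .join(raw.cy3.stack().rename("cy3"))
        .join(raw.detection_p.stack().rename("detection_p"))
        .reset_index()
    )
    long.columns = ["probe_id", "sample_id", "cy5", "cy3", "detection_p"]
    long = long[["sample_id", "probe_id", "cy5", "cy3", "detection_p"]]
    long.to_csv(outdir / "intensities.tsv", sep="\t", index=False)

    samples = pd.DataFrame(
        [(s, t) for t, ids in raw.replicate_map.items() for s in ids],
        columns=["sample_id", "tumor_id"],
    )
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    dataset.manifest.table.to_csv(outdir / "manifest.tsv", sep="\t", index_label="probe_id")
    dataset.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index_label="tumor_id")
    dataset.expression.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene_symbol")
    truth = pd.DataFrame({"cluster": dataset.truth_clusters, "": ""}).drop(columns="")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="tumor_id")
    dataset.probe_roles.rename("role").to_csv(outdir / "probe_roles.tsv", sep="\t")
    dataset.expression_probes.rename_axis("gene_symbol").to_csv(
        outdir / "expression_probes.tsv", sep="\t"
    )
    write_gmt(dataset.gene_sets, outdir / "gene_sets.gmt")
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=False)
    return {p.name: str(p) for p in sorted(outdir.iterdir())}


def read_intensities(intensity_path, samples_path) -> RawIntensitySet:
    long = pd.read_csv(intensity_path, sep="\t")
    samples = pd.read_csv(samples_path, sep="\t")
    replicate_map = {
        t: sorted(sub["sample_id"]) for t, sub in samples.groupby("tumor_id")
    }
    mats = {}
    for col in ("cy5", "cy3", "detection_p"):
        mats[col] = long.pivot(index="probe_id", columns="sample_id", values=col)
    return RawIntensitySet(
        cy5=mats["cy5"], cy3=mats["cy3"], detection_p=mats["detection_p"],
        replicate_map=replicate_map,
    )


def read_manifest(path) -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, sep="\t", index_col="probe_id"))


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="tumor_id")
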