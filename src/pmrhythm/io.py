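"""Readers/writers for the package's text formats, feature filtering, QC.

Formats (all UTF-8, tab-separated, with headers unless noted):

- sample metadata TSV: the schema in :data:`pmrhythm.timeref.METADATA_COLUMNS`;
- measurement matrix TSV: first column ``feature_id``, one column per sample;
- TSS TSV: feature_id, chrom, tss_pos, strand [, active];
- BED6 (no header): chrom, start, end, name, score, strand, 0-based
  half-open coordinates.

Feature filtering keeps features detected (value > 0 for FPKM-derived
data, non-missing for methylation) in at least 90% of samples.  Sample QC
keeps samples whose scores on the first three principal components lie
within 3 standard deviations of each component's mean (a single pass).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .timeref import METADATA_COLUMNS, add_time_columns

FLOAT_FORMAT = "%.10g"


def read_metadata(path, with_angles: bool = True) -> pd.DataFrame:
    """Read and validate a sample metadata TSV; optionally append angles."""
    meta = pd.read_csv(path, sep="\t", dtype={"batch": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in {path}: {dups[:5]}")
    return add_time_columns(meta) if with_angles else meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_matrix(path) -> pd.DataFrame:
    """Read a features x samples matrix TSV (index = feature_id)."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].tolist()
        raise ValueError(f"duplicate feature IDs in {path}: {dups[:5]}")
    return mat


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="feature_id", float_format=FLOAT_FORMAT)


def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into chrom/start/end/name/score/strand columns."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    bad = bed.index[bed["start"] >= bed["end"]]
    if len(bad):
        raise ValueError(f"BED {path}: start >= end at line {int(bad[0]) + 1}")
    if (bed["start"] < 0).any():
        line = int(bed.index[bed["start"] < 0][0]) + 1
        raise ValueError(f"BED {path}: negative start at line {line}")
    return bed


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss(path) -> pd.DataFrame:
    tss = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    needed = {"feature_id", "chrom", "tss_pos", "strand"}
    missing = needed - set(tss.columns)
    if missing:
        raise ValueError(f"TSS table {path} is missing columns: {sorted(missing)}")
    if "active" not in tss.columns:
        tss["active"] = True
    return tss


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    """One feature ID per line, blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def filter_features(
    matrix: pd.DataFrame, min_expressed_frac: float = 0.9, mode: str = "rna"
) -> pd.DataFrame:
    """Drop features detected in fewer than the threshold fraction of samples.

    "Detected" means value > 0 for FPKM-derived modes (rna, h3k9ac) and
    simply non-missing for methylation beta values.
    """
    if mode == "meth":
        frac = matrix.notna().mean(axis=1)
    else:
        frac = ((matrix > 0) & matrix.notna()).mean(axis=1)
    return matrix.loc[frac >= min_expressed_frac]


def qc_pca_filter(matrix: pd.DataFrame, n_components: int = 3, sd_limit: float = 3.0) -> list[str]:
    """Sample QC: keep samples within sd_limit on each top principal component.

    PCA is computed on feature-standardized data (features with zero
    variance are ignored); a sample is kept when its score on each of the
    first ``n_components`` components lies within ``sd_limit`` standard
    deviations of that component's mean.  Single pass, no iteration.
    Returns the kept sample IDs in input order.
    """
    if matrix.shape[1] < 10:
        raise ValueError(f"need >= 10 samples for PCA QC, got {matrix.shape[1]}")
    X = matrix.to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=0)
    keep_feat = sd > 0
    if not keep_feat.any():
        raise ValueError("constant matrix: PCA undefined")
    Xs = (X[:, keep_feat] - X[:, keep_feat].mean(axis=0)) / sd[keep_feat]
    n_comp = min(n_components, min(Xs.shape) - 1)
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(Xs)
    z = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    ok = np.all(np.abs(z) <= sd_limit, axis=1)
    return [s for s, k in zip(matrix.columns, ok) if k]
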