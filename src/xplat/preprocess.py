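"""Platform normalization and vehicle-matched log2-ratio construction.

Three normalization paths feed a common log2-ratio representation:

* targeted counts (TempO-Seq-like): drop genes whose total read count across
  all samples is at or below a threshold (default 214), normalize to counts
  per million, log2-transform with an offset of 1;
* whole-transcriptome counts (RNA-Seq-like): per-transcript "Index"
  transform, ``Index = log2(Z + sqrt(4 + Z^2)) - 1`` with ``Z`` a scaled
  reads-per-base-per-depth quantity, imputing 5.0 for transcripts with fewer
  than 3 reads;
* microarray intensities arrive already log2-normalized and pass through.

Log2 ratios subtract, per gene, the mean of the matched control samples
(matched by the vehicle's nutritional class) from each treated sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, IdMap, StudyDesign

__all__ = [
    "MagicIndexInput",
    "filter_low_count_genes",
    "cpm_log2",
    "magic_index",
    "magic_index_matrix",
    "log2_ratio",
    "merge_platforms_by_cluster_id",
]

#: Scale constant in Z = MAGIC_Z_CONSTANT * n / (N * L). With the default,
#: Z is 0.5e12 times reads per base per unit depth.
MAGIC_Z_CONSTANT = 1e12 / 2.0

#: Below this read count the Index is imputed rather than computed.
MAGIC_MIN_READS = 3

#: Index value assigned to transcripts that are not highly expressed.
MAGIC_IMPUTED_INDEX = 5.0


@dataclass(frozen=True)
class MagicIndexInput:
    """One transcript observation for the Index transform.

    n: read count of the transcript; N: read depth for the sample;
    L: transcript length in bases.
    """

    n: int
    N: float
    L: float

    def __post_init__(self) -> None:
        if self.n < 0 or int(self.n) != self.n:
            raise ValueError(f"read count must be a non-negative integer, got {self.n}")
        if self.N <= 0:
            raise ValueError(f"read depth must be positive, got {self.N}")
        if self.L <= 0:
            raise ValueError(f"transcript length must be positive, got {self.L}")


def filter_low_count_genes(counts: ExpressionMatrix, threshold: int = 214) -> ExpressionMatrix:
    """Remove genes whose total count across all samples is <= ``threshold``.

    Survivor order is preserved. An empty result is returned with a warning
    rather than an error.
    """
    if counts.scale != "counts":
        raise ValueError(f"expected counts matrix, got scale {counts.scale!r}")
    totals = counts.values.sum(axis=1)
    keep = totals > threshold
    if not keep.any():
        warnings.warn(f"no genes survive the total-count filter (threshold {threshold})")
    genes = [g for g, k in zip(counts.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(counts.sample_ids), counts.values[keep, :],
                            "counts", counts.platform_label)


def cpm_log2(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million normalization followed by log2 with offset 1.

    value = log2(count / sample_total * 1e6 + 1). Requires every sample total
    to be positive.
    """
    if counts.scale != "counts":
        raise ValueError(f"expected counts matrix, got scale {counts.scale!r}")
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero total count")
    cpm = counts.values / totals[None, :] * 1e6
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            np.log2(cpm + 1.0), "log2norm", counts.platform_label)


def magic_index(
    inp: MagicIndexInput,
    z_constant: float = MAGIC_Z_CONSTANT,
    impute: bool = True,
) -> float:
    """Index transform for one transcript observation.

    For lowly expressed transcripts (n < 3) the Index is imputed with 5.0
    (disable with ``impute=False``); otherwise
    ``Z = z_constant * n / (N * L)`` and
    ``Index = log2(Z + sqrt(4 + Z^2)) - 1`` — an asinh-like transform that is
    ~log2(Z) for large Z and 0 at Z = 0.
    """
    if impute and inp.n < MAGIC_MIN_READS:
        return MAGIC_IMPUTED_INDEX
    z = z_constant * inp.n / (inp.N * inp.L)
    return float(np.log2(z + np.sqrt(4.0 + z * z)) - 1.0)


def magic_index_matrix(
    counts: ExpressionMatrix,
    lengths: pd.Series,
    z_constant: float = MAGIC_Z_CONSTANT,
) -> ExpressionMatrix:
    """Vectorized Index transform of a per-transcript count matrix.

    ``lengths`` maps every transcript ID to its length in bases; sample read
    depth is the per-sample total count. Entries with fewer than 3 reads are
    imputed with 5.0.
    """
    if counts.scale != "counts":
        raise ValueError(f"expected counts matrix, got scale {counts.scale!r}")
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"transcripts without length: {missing[:5]}")
    length = lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    if np.any(length <= 0):
        raise ValueError("transcript lengths must be positive")
    depth = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(depth == 0)
    if zero.size:
        raise ValueError(f"sample {counts.sample_ids[zero[0]]!r} has zero read depth")
    z = z_constant * counts.values / (depth[None, :] * length[:, None])
    index = np.log2(z + np.sqrt(4.0 + z * z)) - 1.0
    index[counts.values < MAGIC_MIN_READS] = MAGIC_IMPUTED_INDEX
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids), index,
                            "log2norm", counts.platform_label)


def log2_ratio(log2norm: ExpressionMatrix, design: StudyDesign) -> ExpressionMatrix:
    """Subtract the matched-control mean from each treated sample, per gene.

    Controls are matched through ``control_match_group`` (the vehicle's
    nutritional class in the canonical design). Control samples are dropped
    from the output, so the canonical design yields 45 treated columns.
    """
    if log2norm.scale != "log2norm":
        raise ValueError(f"expected log2norm matrix, got scale {log2norm.scale!r}")
    col = {s: i for i, s in enumerate(log2norm.sample_ids)}
    missing = [s for s in design.sample_ids if s not in col]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing[:5]}")

    control_means: dict[str, np.ndarray] = {}
    for group in sorted(set(design.table["control_match_group"])):
        ctrl = design.controls_for_group(group)
        if ctrl:
            control_means[group] = log2norm.values[:, [col[s] for s in ctrl]].mean(axis=1)

    treated = design.treated
    out_ids, out_cols = [], []
    for _, row in treated.iterrows():
        group = row["control_match_group"]
        if group not in control_means:
            raise ValueError(
                f"treated sample {row['sample_id']!r}: no control samples in "
                f"match group {group!r}"
            )
        out_ids.append(row["sample_id"])
        out_cols.append(log2norm.values[:, col[row["sample_id"]]] - control_means[group])
    return ExpressionMatrix(list(log2norm.gene_ids), out_ids,
                            np.column_stack(out_cols), "log2ratio",
                            log2norm.platform_label)


def merge_platforms_by_cluster_id(
    matrices: list[ExpressionMatrix],
    idmap: IdMap,
    platforms: list[str] | None = None,
) -> ExpressionMatrix:
    """Average rows sharing a cluster ID per platform, then join platforms on
    the cluster IDs common to all of them.

    Sample columns are concatenated with ``|platform`` suffixes. Platform
    names default to each matrix's ``platform_label`` and must exist in the
    ID map. Raises on an empty cluster-ID intersection.
    """
    if platforms is None:
        platforms = [m.platform_label for m in matrices]
    if len(platforms) != len(matrices):
        raise ValueError("one platform name required per matrix")

    averaged: list[pd.DataFrame] = []
    for matrix, platform in zip(matrices, platforms):
        mapping = idmap.for_platform(platform)
        frame = matrix.to_frame()
        cluster = frame.index.to_series().map(mapping)
        dropped = int(cluster.isna().sum())
        if dropped:
            warnings.warn(f"{platform}: {dropped} rows without a cluster ID dropped")
        frame = frame[cluster.notna()].groupby(cluster.dropna()).mean()
        frame.columns = [f"{s}|{platform}" for s in frame.columns]
        averaged.append(frame)

    shared = set(averaged[0].index)
    for frame in averaged[1:]:
        shared &= set(frame.index)
    if not shared:
        raise ValueError("empty intersection of cluster IDs across platforms")
    shared_ids = sorted(shared)
    merged = pd.concat([frame.loc[shared_ids] for frame in averaged], axis=1)
    return ExpressionMatrix(shared_ids, list(merged.columns), merged.to_numpy(),
                            matrices[0].scale, "merged")
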