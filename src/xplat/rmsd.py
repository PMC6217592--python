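"""Replicate cohesion via root mean squared distance (RMSD).

``RMSD(x, y) = sqrt(sum_i (I_ix - I_iy)^2 / N)`` over the N genes of a
platform, where I is the log2 expression ratio. Smaller values mean the two
samples agree more closely. The summary aggregates the canonical design:
chemical-RMSD averages a chemical's 3 replicate pairs, the average
chemical-RMSD averages chemicals unweighted, MOA-RMSD averages all 36
treated-sample pairs within a MOA (3 chemicals x 3 replicates gives
C(9,2) = 36 pairs, cross-chemical pairs included), and the platform-RMSD
averages the five MOA-RMSD values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, StudyDesign

__all__ = ["RmsdSummary", "rmsd_pair", "summarize_rmsd"]


def rmsd_pair(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared difference of two equal-length log2-ratio profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"profile shapes differ: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty profiles")
    keep = np.isfinite(x) & np.isfinite(y)
    dropped = x.size - int(keep.sum())
    if dropped:
        warnings.warn(f"{dropped} genes with missing values excluded pairwise")
    if not keep.any():
        raise ValueError("no complete gene pairs")
    d = x[keep] - y[keep]
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class RmsdSummary:
    pairwise: pd.DataFrame                 # sample_x, sample_y, chemical_x, chemical_y, moa, rmsd
    chemical_rmsd: dict[str, float]        # mean over each chemical's replicate pairs
    avg_chemical_rmsd: float               # unweighted mean over chemicals
    moa_rmsd: dict[str, float]             # mean over all within-MOA treated pairs
    platform_rmsd: float                   # mean over MOAs


def summarize_rmsd(log2ratio: ExpressionMatrix, design: StudyDesign) -> RmsdSummary:
    """All within-MOA pairwise RMSDs plus the chemical/MOA/platform averages.

    Chemicals with fewer than 2 replicates present in the matrix are excluded
    from the chemical-level average with a warning; MOA-RMSD uses every
    within-MOA treated pair that can be formed.
    """
    if log2ratio.scale != "log2ratio":
        raise ValueError(f"expected log2ratio matrix, got scale {log2ratio.scale!r}")
    col = {s: i for i, s in enumerate(log2ratio.sample_ids)}
    treated = design.treated[design.treated["sample_id"].isin(col)]

    rows = []
    for moa, group in treated.groupby("moa"):
        samples = list(group["sample_id"])
        chem = dict(zip(group["sample_id"], group["chemical"]))
        for sx, sy in combinations(samples, 2):
            rows.append({
                "sample_x": sx, "sample_y": sy,
                "chemical_x": chem[sx], "chemical_y": chem[sy], "moa": moa,
                "rmsd": rmsd_pair(log2ratio.values[:, col[sx]],
                                  log2ratio.values[:, col[sy]]),
            })
    pairwise = pd.DataFrame(rows, columns=["sample_x", "sample_y", "chemical_x",
                                           "chemical_y", "moa", "rmsd"])

    chemical_rmsd: dict[str, float] = {}
    for chemical, group in treated.groupby("chemical"):
        if len(group) < 2:
            warnings.warn(f"chemical {chemical!r} has <2 replicates; excluded")
            continue
        mask = (pairwise["chemical_x"] == chemical) & (pairwise["chemical_y"] == chemical)
        chemical_rmsd[str(chemical)] = float(pairwise.loc[mask, "rmsd"].mean())
    avg_chemical = float(np.mean(list(chemical_rmsd.values()))) if chemical_rmsd else np.nan

    moa_rmsd = {str(m): float(g["rmsd"].mean()) for m, g in pairwise.groupby("moa")}
    platform = float(np.mean(list(moa_rmsd.values()))) if moa_rmsd else np.nan
    return RmsdSummary(pairwise, chemical_rmsd, avg_chemical, moa_rmsd, platform)
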