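"""Shared data model: expression matrices, study designs and cross-platform ID maps.

The toolkit compares transcriptomic platforms on a rat-liver mode-of-action
(MOA) design: five MOAs, three chemicals per MOA, three biological replicates
per chemical, with vehicle-matched controls. Everything downstream consumes
the two containers defined here — :class:`ExpressionMatrix` (genes x samples
with an explicit scale tag) and :class:`StudyDesign` (per-sample treatment
metadata) — plus a many-to-one :class:`IdMap` linking platform-specific gene
identifiers to shared cluster IDs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SCALES",
    "CHEMICAL_TO_MOA",
    "MOA_LEVELS",
    "ExpressionMatrix",
    "StudyDesign",
    "IdMap",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_design",
    "read_id_map",
]

SCALES = ("counts", "log2norm", "log2ratio")

#: Canonical chemical -> mode-of-action assignment for the rat liver benchmark
#: (five MOAs, three chemicals each).
CHEMICAL_TO_MOA: Mapping[str, str] = {
    "3ME": "AhR", "LEF": "AhR", "NAP": "AhR",
    "PHE": "CAR/PXR", "MET": "CAR/PXR", "ECO": "CAR/PXR",
    "CHO": "Cytotox", "THI": "Cytotox", "CAR": "Cytotox",
    "AFL": "DNA_Damage", "IFO": "DNA_Damage", "NIT": "DNA_Damage",
    "PIR": "PPARA", "BEZ": "PPARA", "NAF": "PPARA",
}

MOA_LEVELS = ("AhR", "CAR/PXR", "Cytotox", "DNA_Damage", "PPARA")

_DESIGN_COLUMNS = (
    "sample_id", "chemical", "moa", "route_class",
    "replicate", "is_control", "control_match_group",
)


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class ExpressionMatrix:
    """Dense genes x samples expression matrix with an explicit value scale.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, unique, case-sensitive identifiers for rows and columns.
    values
        Dense real matrix of shape ``(len(gene_ids), len(sample_ids))``.
        Non-negative integers when ``scale == "counts"``; finite floats for
        the log2 scales.
    scale
        One of ``counts`` (raw reads), ``log2norm`` (log2 normalized
        abundance) or ``log2ratio`` (log2 treated-over-control ratio).
    platform_label
        Free-text platform tag (e.g. ``microarray``), carried through the
        pipeline for reporting.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str
    platform_label: str = ""

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if self.scale == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts matrix contains negative values")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts matrix contains non-integer values")
            self.values = np.round(self.values).astype(np.int64)
        else:
            self.values = self.values.astype(float)
            if not np.all(np.isfinite(self.values)):
                raise ValueError(f"non-finite values in {self.scale} matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale: str, platform_label: str = "") -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(), scale, platform_label)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[rows, :],
                                self.scale, self.platform_label)

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, cols],
                                self.scale, self.platform_label)


def read_expression_tsv(path: str | Path, scale: str, platform_label: str = "") -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample IDs, first column = gene IDs)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row ({len(fields) - 1} values, "
                    f"expected {len(sample_ids)})"
                )
            gene_ids.append(fields[0])
            row = []
            for col, cell in enumerate(fields[1:], start=1):
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric cell at column {col} "
                        f"(sample {sample_ids[col - 1]!r}): {cell!r}"
                    ) from exc
            rows.append(row)
    if not gene_ids:
        raise ValueError(f"{path}: no gene rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows), scale, platform_label)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, preserving values to full float precision."""
    frame = matrix.to_frame()
    if matrix.scale == "counts":
        frame.to_csv(path, sep="\t", index_label="gene_id")
    else:
        frame.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


@dataclass
class StudyDesign:
    """Per-sample treatment metadata for the MOA design.

    Wraps a DataFrame with columns ``sample_id``, ``chemical``, ``moa``,
    ``route_class``, ``replicate``, ``is_control``, ``control_match_group``.
    Treated samples resolve to >=1 control through their match group;
    controls carry the MOA label ``Control``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in _DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if len(self.table) == 0:
            raise ValueError("no samples in sample sheet")
        self.table = self.table.reset_index(drop=True).copy()
        self.table["sample_id"] = self.table["sample_id"].astype(str)
        self.table["is_control"] = self.table["is_control"].astype(bool)
        self.table["replicate"] = self.table["replicate"].astype(int)
        _check_unique(self.table["sample_id"], "sample")
        if (self.table["replicate"] < 1).any():
            raise ValueError("replicate indices must be >= 1")
        self._validate_moa_assignments()
        self._validate_control_matching()

    def _validate_moa_assignments(self) -> None:
        treated = self.table[~self.table["is_control"]]
        for chem, moas in treated.groupby("chemical")["moa"]:
            levels = set(moas)
            if len(levels) > 1:
                raise ValueError(f"chemical {chem!r} assigned to multiple MOAs: {sorted(levels)}")
            moa = next(iter(levels))
            if chem in CHEMICAL_TO_MOA and moa != CHEMICAL_TO_MOA[chem]:
                raise ValueError(
                    f"chemical {chem!r} labeled MOA {moa!r} but the canonical "
                    f"assignment is {CHEMICAL_TO_MOA[chem]!r}"
                )

    def _validate_control_matching(self) -> None:
        control_groups = set(self.table.loc[self.table["is_control"], "control_match_group"])
        for _, row in self.table[~self.table["is_control"]].iterrows():
            if row["control_match_group"] not in control_groups:
                raise ValueError(
                    f"treated sample {row['sample_id']!r} has control_match_group "
                    f"{row['control_match_group']!r} with no matching control samples"
                )

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def treated(self) -> pd.DataFrame:
        return self.table[~self.table["is_control"]]

    @property
    def controls(self) -> pd.DataFrame:
        return self.table[self.table["is_control"]]

    @property
    def moas(self) -> list[str]:
        return sorted(set(self.treated["moa"]))

    @property
    def chemicals(self) -> list[str]:
        return sorted(set(self.treated["chemical"]))

    def controls_for_group(self, group: str) -> list[str]:
        mask = self.table["is_control"] & (self.table["control_match_group"] == group)
        return list(self.table.loc[mask, "sample_id"])

    def subset(self, sample_ids: Iterable[str]) -> "StudyDesign":
        keep = set(sample_ids)
        return StudyDesign(self.table[self.table["sample_id"].isin(keep)])

    def factor(self, name: str, sample_ids: Iterable[str] | None = None) -> pd.Series:
        """Per-sample factor levels (indexed by sample_id), optionally reordered."""
        ser = self.table.set_index("sample_id")[name]
        if sample_ids is not None:
            ser = ser.loc[list(sample_ids)]
        return ser


def derive_control_match_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``control_match_group`` from ``route_class`` when absent.

    Vehicle-matched controls are paired with treated samples by the
    nutritional class of the vehicle (e.g. corn-oil vs non-nutritive), which
    the sample sheet expresses as ``route_class``.
    """
    table = table.copy()
    if "control_match_group" not in table.columns or table["control_match_group"].isna().any():
        table["control_match_group"] = table["route_class"].astype(str)
    return table


def read_design(path: str | Path) -> StudyDesign:
    """Read and validate a sample sheet (CSV or TSV by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    table = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if len(table) == 0:
        raise ValueError(f"{path}: no samples")
    table = derive_control_match_groups(table)
    return StudyDesign(table)


@dataclass
class IdMap:
    """Many-to-one map from platform gene/probe/transcript IDs to shared cluster IDs."""

    mapping: dict[str, dict[str, str]]  # platform -> {platform_id -> cluster_id}

    def cluster_ids(self, platform: str) -> set[str]:
        return set(self.mapping[platform].values())

    def for_platform(self, platform: str) -> dict[str, str]:
        return self.mapping[platform]

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("platform\tplatform_id\tcluster_id\n")
            for platform, table in self.mapping.items():
                for pid, cid in table.items():
                    fh.write(f"{platform}\t{pid}\t{cid}\n")


def read_id_map(path: str | Path) -> IdMap:
    """Read a 3-column TSV (platform, platform_id, cluster_id) into an IdMap."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"platform", "platform_id", "cluster_id"}
    if not required.issubset(table.columns):
        raise ValueError(f"ID map must have columns {sorted(required)}")
    mapping: dict[str, dict[str, str]] = {}
    for platform, sub in table.groupby("platform"):
        dup = sub["platform_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"platform {platform!r}: duplicate platform_id "
                f"{sub.loc[dup, 'platform_id'].iloc[0]!r}"
            )
        mapping[str(platform)] = dict(zip(sub["platform_id"], sub["cluster_id"]))
    return IdMap(mapping)
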