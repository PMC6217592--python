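"""Synthetic three-platform expression data with a known variance decomposition.

The generator emulates the rat-liver MOA benchmark design: 5 modes of action
x 3 chemicals x 3 biological replicates (45 treated samples) plus vehicle
controls matched by route class (63 samples total). Per-gene log2 expression
is a sum of Gaussian random effects for MOA, chemical-within-MOA and route,
plus iid residual noise, with variances proportional to requested fractions —
the same additive structure the downstream mixed-model analyses assume. A
designated subset of genes additionally carries fixed MOA offsets so that
differential-expression and enrichment stages have ground truth.

The same underlying biology is rendered three ways: as log2 intensities
(microarray-like), as per-transcript read counts with transcript lengths
(whole-transcriptome RNA-Seq-like), and as targeted counts on a ~2,300-gene
panel (TempO-Seq-like), linked by a many-to-one ID map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CHEMICAL_TO_MOA, MOA_LEVELS, ExpressionMatrix, IdMap, StudyDesign

__all__ = [
    "SyntheticTruth",
    "PlatformBundle",
    "default_truth",
    "make_canonical_design",
    "simulate_log2_dataset",
    "simulate_counts",
    "make_three_platform_bundle",
    "de_assignments",
    "make_synthetic_godag",
]

_FACTORS = ("moa", "chemical", "route", "residual")

#: Route class per chemical: two vehicle classes per MOA so route is not
#: confounded with MOA (corn-oil vehicle for two chemicals per MOA, a
#: non-nutritive vehicle for the third).
_ROUTE_BY_CHEMICAL = {
    chem: ("corn_oil" if i % 3 < 2 else "aqueous")
    for i, chem in enumerate(CHEMICAL_TO_MOA)
}


@dataclass
class SyntheticTruth:
    """Ground-truth generating parameters for one synthetic dataset.

    ``variance_fractions`` gives the share of per-gene log2 variance carried
    by each random effect (must sum to 1); ``de_gene_ids`` lists genes given
    a fixed MOA offset of ``effect_size`` log2 units on top of the random
    structure.
    """

    variance_fractions: dict[str, float]
    de_gene_ids: list[str] = field(default_factory=list)
    effect_size: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.variance_fractions) - set(_FACTORS)
        if unknown:
            raise ValueError(f"unknown variance factors: {sorted(unknown)}")
        fracs = {f: float(self.variance_fractions.get(f, 0.0)) for f in _FACTORS}
        if any(v < 0 for v in fracs.values()):
            raise ValueError("variance fractions must be non-negative")
        total = sum(fracs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"variance fractions sum to {total}, expected 1")
        self.variance_fractions = fracs


def default_truth(
    n_genes: int,
    seed: int = 0,
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    variance_fractions: dict[str, float] | None = None,
) -> SyntheticTruth:
    """Truth object with the default study conditions.

    Defaults: variance split {moa 0.4, chemical 0.3, route 0.05, residual
    0.25}, 10% of genes differentially expressed with a 2 log2-unit MOA
    offset. DE genes are the first ``floor(de_fraction * n_genes)`` gene IDs;
    gene IDs are ``g000001`` upward.
    """
    if variance_fractions is None:
        variance_fractions = {"moa": 0.4, "chemical": 0.3, "route": 0.05, "residual": 0.25}
    n_de = int(np.floor(de_fraction * n_genes))
    de_ids = [f"g{i + 1:06d}" for i in range(n_de)]
    return SyntheticTruth(variance_fractions, de_ids, effect_size, seed)


def make_canonical_design(n_replicates: int = 3, n_controls_per_group: int = 9) -> StudyDesign:
    """The benchmark design: 5 MOAs x 3 chemicals x ``n_replicates``, plus
    ``n_controls_per_group`` vehicle controls per route class (63 samples at
    the defaults)."""
    rows = []
    for chem, moa in CHEMICAL_TO_MOA.items():
        route = _ROUTE_BY_CHEMICAL[chem]
        for rep in range(1, n_replicates + 1):
            rows.append({
                "sample_id": f"{chem}_{rep}", "chemical": chem, "moa": moa,
                "route_class": route, "replicate": rep, "is_control": False,
                "control_match_group": route,
            })
    for route in ("corn_oil", "aqueous"):
        for rep in range(1, n_controls_per_group + 1):
            rows.append({
                "sample_id": f"CTRL_{route}_{rep}", "chemical": f"VEH_{route}",
                "moa": "Control", "route_class": route, "replicate": rep,
                "is_control": True, "control_match_group": route,
            })
    return StudyDesign(pd.DataFrame(rows))


def de_assignments(truth: SyntheticTruth) -> pd.DataFrame:
    """Deterministic DE gene -> (target MOA, sign) assignment.

    Genes cycle through the five MOAs; the offset sign flips every full
    cycle, so each MOA receives both up- and down-regulated genes.
    """
    rows = []
    for i, gene in enumerate(truth.de_gene_ids):
        moa = MOA_LEVELS[i % len(MOA_LEVELS)]
        sign = 1.0 if (i // len(MOA_LEVELS)) % 2 == 0 else -1.0
        rows.append({"gene_id": gene, "moa": moa, "offset": sign * truth.effect_size})
    return pd.DataFrame(rows, columns=["gene_id", "moa", "offset"])


def simulate_log2_dataset(
    n_genes: int,
    design: StudyDesign,
    truth: SyntheticTruth,
    total_sd: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Simulate a log2-normalized genes x samples matrix under the design.

    Treated samples receive per-gene Gaussian random effects for their MOA,
    chemical and route levels plus residual noise; variances are
    ``fraction * total_sd**2``. Controls receive baseline plus residual only
    (treatment-linked effects are, by construction, responses to treatment),
    so vehicle-matched log2 ratios retain the full treatment variance
    structure. Genes in ``truth.de_gene_ids`` get their fixed MOA offset.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    gene_ids = [f"g{i + 1:06d}" for i in range(n_genes)]
    missing_de = set(truth.de_gene_ids) - set(gene_ids)
    if missing_de:
        raise ValueError(f"de_gene_ids outside generated gene set: {sorted(missing_de)[:5]}")

    table = design.table
    sample_ids = list(table["sample_id"])
    treated = (~table["is_control"]).to_numpy()
    var = {f: truth.variance_fractions[f] * total_sd**2 for f in _FACTORS}

    moa_levels = sorted(set(table.loc[~table["is_control"], "moa"]))
    chem_levels = sorted(set(table.loc[~table["is_control"], "chemical"]))
    route_levels = sorted(set(table["route_class"]))
    moa_idx = {m: i for i, m in enumerate(moa_levels)}
    chem_idx = {c: i for i, c in enumerate(chem_levels)}
    route_idx = {r: i for i, r in enumerate(route_levels)}

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    moa_eff = rng.normal(0.0, np.sqrt(var["moa"]), size=(n_genes, len(moa_levels)))
    chem_eff = rng.normal(0.0, np.sqrt(var["chemical"]), size=(n_genes, len(chem_levels)))
    route_eff = rng.normal(0.0, np.sqrt(var["route"]), size=(n_genes, len(route_levels)))
    resid = rng.normal(0.0, np.sqrt(var["residual"]), size=(n_genes, len(sample_ids)))

    values = baseline[:, None] + resid
    for j, (_, row) in enumerate(table.iterrows()):
        if not treated[j]:
            continue
        values[:, j] += (
            moa_eff[:, moa_idx[row["moa"]]]
            + chem_eff[:, chem_idx[row["chemical"]]]
            + route_eff[:, route_idx[row["route_class"]]]
        )

    if truth.de_gene_ids:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        moa_per_sample = table["moa"].to_numpy()
        for _, de in de_assignments(truth).iterrows():
            cols = np.flatnonzero(treated & (moa_per_sample == de["moa"]))
            values[gene_pos[de["gene_id"]], cols] += de["offset"]

    return ExpressionMatrix(gene_ids, sample_ids, values, "log2norm", "synthetic")


def simulate_counts(
    log2_matrix: ExpressionMatrix,
    depth_per_sample: float,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    near_zero_fraction: float = 0.0,
    near_zero_log2: float = -15.0,
) -> ExpressionMatrix:
    """Render log2 abundances as sequencing counts.

    Per sample, the library size is Poisson around ``depth_per_sample`` and
    counts are multinomial over genes with proportions ``2**log2value``
    (renormalized per sample). A ``near_zero_fraction`` of genes (taken from
    the end of the gene list) has its abundance replaced by ``2**near_zero_log2``
    relative to the per-sample maximum, producing genes whose expected totals
    sit far below typical low-count filters.
    """
    if depth_per_sample <= 0:
        raise ValueError("depth_per_sample must be positive")
    if log2_matrix.scale != "log2norm":
        raise ValueError(f"expected log2norm input, got {log2_matrix.scale}")
    if rng is None:
        rng = np.random.default_rng(seed)
    log2 = log2_matrix.values.astype(float).copy()
    n_genes, n_samples = log2.shape
    n_rare = int(np.floor(near_zero_fraction * n_genes))
    if n_rare:
        log2[n_genes - n_rare:, :] = log2.max(axis=0, keepdims=True) + near_zero_log2
    abundance = np.exp2(log2 - log2.max(axis=0, keepdims=True))
    props = abundance / abundance.sum(axis=0, keepdims=True)
    counts = np.empty((n_genes, n_samples), dtype=np.int64)
    for j in range(n_samples):
        lib = rng.poisson(depth_per_sample)
        counts[:, j] = rng.multinomial(lib, props[:, j])
    return ExpressionMatrix(list(log2_matrix.gene_ids), list(log2_matrix.sample_ids),
                            counts, "counts", log2_matrix.platform_label)


@dataclass
class PlatformBundle:
    """One synthetic biology rendered on three platforms, with linkage metadata."""

    microarray: ExpressionMatrix        # log2norm probe intensities
    rnaseq_counts: ExpressionMatrix     # per-transcript raw counts
    rnaseq_lengths: pd.Series           # transcript -> length (bases)
    temposeq_counts: ExpressionMatrix   # targeted panel raw counts
    id_map: IdMap
    design: StudyDesign
    truth: SyntheticTruth
    base_log2: ExpressionMatrix         # the shared underlying log2 biology


def _duplicate_rows(
    base: np.ndarray, gene_ids: list[str], dup_fraction: float,
    prefix: str, rng: np.random.Generator, noise_sd: float,
) -> tuple[list[str], np.ndarray, dict[str, str]]:
    """Render genes as platform features, a fraction with two features each."""
    n = len(gene_ids)
    n_dup = int(np.floor(dup_fraction * n))
    dup_set = set(rng.choice(n, size=n_dup, replace=False).tolist())
    feat_ids, rows, mapping = [], [], {}
    for i, gene in enumerate(gene_ids):
        copies = 2 if i in dup_set else 1
        for c in range(1, copies + 1):
            fid = f"{prefix}_{gene}_{c}"
            feat_ids.append(fid)
            rows.append(base[i] + rng.normal(0.0, noise_sd, size=base.shape[1]))
            mapping[fid] = gene
    return feat_ids, np.array(rows), mapping


def make_three_platform_bundle(
    truth: SyntheticTruth,
    n_genes: int = 4000,
    design: StudyDesign | None = None,
    temposeq_panel_size: int | None = None,
    temposeq_near_zero: int | None = None,
    rnaseq_depth: float = 1e7,
    temposeq_depth: float = 1e6,
    probe_noise_sd: float = 0.15,
) -> PlatformBundle:
    """Generate the default three-platform bundle from one ground truth.

    The shared biology is ``n_genes`` cluster genes. The microarray measures
    every gene (10% via two probes, with probe-level noise); RNA-Seq measures
    every gene as transcripts (20% via two transcripts) with lengths drawn
    uniformly on [500, 3000] bases; TempO-Seq measures a targeted panel of
    ``temposeq_panel_size`` genes of which ``temposeq_near_zero`` are
    near-zero background probes, exercising the low-total-count filter. The
    panel defaults to 2,284 genes with 229 near-zero probes (the assay's
    nominal content), shrunk proportionally when ``n_genes`` is smaller.
    All randomness derives from ``truth.seed`` via spawned substreams.
    """
    if temposeq_panel_size is None:
        temposeq_panel_size = min(2284, n_genes)
    if temposeq_near_zero is None:
        temposeq_near_zero = int(round(temposeq_panel_size * 229 / 2284))
    if temposeq_panel_size > n_genes:
        raise ValueError("temposeq_panel_size cannot exceed n_genes")
    if design is None:
        design = make_canonical_design()
    ss = np.random.SeedSequence(truth.seed)
    rng_base, rng_ma, rng_rs, rng_ts = (np.random.default_rng(s) for s in ss.spawn(4))

    base = simulate_log2_dataset(n_genes, design, truth, rng=rng_base)
    gene_ids = list(base.gene_ids)

    # microarray: probe intensities, log2norm
    ma_ids, ma_vals, ma_map = _duplicate_rows(base.values, gene_ids, 0.10, "pr",
                                              rng_ma, probe_noise_sd)
    microarray = ExpressionMatrix(ma_ids, list(base.sample_ids), ma_vals,
                                  "log2norm", "microarray")

    # RNA-Seq: transcript counts + lengths
    tx_ids, tx_log2, rs_map = _duplicate_rows(base.values, gene_ids, 0.20, "tx",
                                              rng_rs, probe_noise_sd)
    tx_matrix = ExpressionMatrix(tx_ids, list(base.sample_ids), tx_log2,
                                 "log2norm", "rnaseq")
    rnaseq_counts = simulate_counts(tx_matrix, rnaseq_depth, rng=rng_rs)
    lengths = pd.Series(rng_rs.integers(500, 3001, size=len(tx_ids)), index=tx_ids,
                        name="length")

    # TempO-Seq: targeted panel counts; near-zero probes appended at the end
    # of the panel so simulate_counts' tail convention flattens exactly them.
    n_expressed = temposeq_panel_size - temposeq_near_zero
    expressed = [gene_ids[i] for i in sorted(
        rng_ts.choice(n_genes, size=n_expressed, replace=False).tolist())]
    remaining = [g for g in gene_ids if g not in set(expressed)]
    rare = [remaining[i] for i in sorted(
        rng_ts.choice(len(remaining), size=temposeq_near_zero, replace=False).tolist())]
    panel = expressed + rare
    panel_matrix = base.subset_genes(panel)
    panel_matrix = ExpressionMatrix(
        [f"ts_{g}" for g in panel], list(panel_matrix.sample_ids),
        panel_matrix.values, "log2norm", "temposeq")
    temposeq_counts = simulate_counts(
        panel_matrix, temposeq_depth, rng=rng_ts,
        near_zero_fraction=temposeq_near_zero / temposeq_panel_size)
    ts_map = {f"ts_{g}": g for g in panel}

    id_map = IdMap({"microarray": ma_map, "rnaseq": rs_map, "temposeq": ts_map})
    return PlatformBundle(microarray, rnaseq_counts, lengths, temposeq_counts,
                          id_map, design, truth, base)


def make_synthetic_godag(
    gene_ids: list[str],
    truth: SyntheticTruth,
    n_modules: int = 10,
    annotations_per_gene: int = 1,
    seed: int | None = None,
):
    """Small synthetic GO-BP-like DAG with MOA-linked enriched terms.

    Builds a three-level is_a hierarchy (root <- ``n_modules`` module terms
    <- two leaf terms each). Background genes are annotated to random
    leaves; DE genes are preferentially annotated to the leaves of the
    module matching their target MOA (module index = MOA index), so the DE
    gene list genuinely over-represents those terms. Term IDs are
    ``SYN:NNNNNNN`` — this ontology is synthetic, not a GO release.
    """
    from .ontology import GoDag  # local import to avoid a cycle at module load

    if seed is None:
        seed = truth.seed + 1
    rng = np.random.default_rng(seed)
    terms = {"SYN:0000001": "biological process (root)"}
    edges = []
    leaves_by_module: list[list[str]] = []
    tid = 1
    for m in range(n_modules):
        tid += 1
        module = f"SYN:{tid:07d}"
        terms[module] = f"module {m + 1} process"
        edges.append((module, "SYN:0000001"))
        leaves = []
        for c in range(2):
            tid += 1
            leaf = f"SYN:{tid:07d}"
            terms[leaf] = f"module {m + 1} subprocess {c + 1}"
            edges.append((leaf, module))
            leaves.append(leaf)
        leaves_by_module.append(leaves)

    all_leaves = [l for leaves in leaves_by_module for l in leaves]
    term_to_genes: dict[str, set[str]] = {t: set() for t in all_leaves}
    de_module = {row["gene_id"]: MOA_LEVELS.index(row["moa"]) % n_modules
                 for _, row in de_assignments(truth).iterrows()}
    for gene in gene_ids:
        if gene in de_module:
            home = leaves_by_module[de_module[gene]]
            picks = [home[int(rng.integers(0, len(home)))]]
            extra = annotations_per_gene - 1
        else:
            picks, extra = [], annotations_per_gene
        for _ in range(extra):
            picks.append(all_leaves[int(rng.integers(0, len(all_leaves)))])
        for leaf in picks:
            term_to_genes[leaf].add(gene)
    return GoDag(terms, edges, term_to_genes)
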