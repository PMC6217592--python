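"""Per-gene nested ANOVA for mode-of-action effects.

Model: ``Y_ijkl = mu + M_i + R_j + C(MxR)_ijk + eps_ijkl`` — MOA (M) and
route (R) main effects with chemical (C) nested in MOA x route, fitted to
each gene's log2-ratio profile over the treated samples. Chemical is a
random effect, so the MOA F-test uses the chemical-within stratum as its
error term: ``F = MS_MOA / MS_chemical-within`` with the matching degrees of
freedom — the classical expected-mean-squares test, exact and deterministic
for (near-)balanced designs. Sums of squares are Type II (each effect
adjusted for the other main effect), which coincides with the sequential
partition in the balanced case. Benjamini-Hochberg adjusted q-values control
the false discovery rate across genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, StudyDesign

__all__ = ["AnovaResult", "fit_moa_anova", "bh_fdr", "select_moa_varying"]


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone). NaNs propagate."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if (~ok).any():
        warnings.warn(f"{int((~ok).sum())} NaN p-values propagated unadjusted")
    if ok.any():
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _projection(columns: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projection onto the column space, plus its rank."""
    u, s, _ = np.linalg.svd(columns, full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    basis = u[:, :rank]
    return basis @ basis.T, rank


def _dummies(levels: pd.Series) -> np.ndarray:
    return pd.get_dummies(levels).to_numpy(dtype=float)


@dataclass
class AnovaResult:
    """Per-gene MOA test results plus the shared degrees of freedom."""

    table: pd.DataFrame       # index gene_id: ss_moa, ss_route, ss_chem, ss_resid, F, p, q, degenerate
    df_moa: int
    df_route: int
    df_chem: int
    df_resid: int


def fit_moa_anova(log2ratio: ExpressionMatrix, design: StudyDesign) -> AnovaResult:
    """Nested MOA ANOVA for every gene of a log2-ratio matrix.

    Sums of squares via projection differences: SS_MOA = y'(P_MR - P_R)y
    (Type II, adjusted for route), SS_route = y'(P_MR - P_M)y, SS_chem =
    y'(P_C - P_MR)y, residual = y'(I - P_C)y, where P_C projects onto the
    chemical factor (which, by nesting, spans MOA and route). Genes with zero
    total variance are flagged with p = 1.
    """
    if log2ratio.scale != "log2ratio":
        raise ValueError(f"expected log2ratio matrix, got scale {log2ratio.scale!r}")
    col = {s: i for i, s in enumerate(log2ratio.sample_ids)}
    treated = design.treated[design.treated["sample_id"].isin(col)]
    if len(treated) < len(design.treated):
        warnings.warn("some treated samples in the design are absent from the matrix")
    sample_ids = list(treated["sample_id"])
    n = len(sample_ids)

    moa = treated["moa"].reset_index(drop=True)
    route = treated["route_class"].reset_index(drop=True)
    chem = treated["chemical"].reset_index(drop=True)
    if moa.nunique() < 2 or chem.nunique() < 2:
        raise ValueError("need >=2 MOAs and >=2 chemicals")
    drop_route = route.nunique() < 2
    if drop_route:
        warnings.warn("route has a single level; dropped from the model")

    cells = treated.groupby(["chemical"]).size()
    if cells.nunique() > 1:
        warnings.warn("unbalanced design: using Type-II sums of squares")

    ones = np.ones((n, 1))
    p_m, _ = _projection(np.hstack([ones, _dummies(moa)]))
    if drop_route:
        p_r, rank_r = _projection(ones)
        p_mr, rank_mr = p_m, _projection(np.hstack([ones, _dummies(moa)]))[1]
    else:
        p_r, rank_r = _projection(np.hstack([ones, _dummies(route)]))
        p_mr, rank_mr = _projection(np.hstack([ones, _dummies(moa), _dummies(route)]))
    rank_m = _projection(np.hstack([ones, _dummies(moa)]))[1]
    p_c, rank_c = _projection(np.hstack([ones, _dummies(chem)]))

    df_moa = rank_mr - rank_r
    df_route = 0 if drop_route else rank_mr - rank_m
    df_chem = rank_c - rank_mr
    df_resid = n - rank_c
    if df_chem < 1:
        raise ValueError("no degrees of freedom for chemical-within-(MOA x route)")

    y = log2ratio.values[:, [col[s] for s in sample_ids]].astype(float)

    def ss(proj_hi: np.ndarray, proj_lo: np.ndarray) -> np.ndarray:
        diff = proj_hi - proj_lo
        return np.clip(np.einsum("gi,ij,gj->g", y, diff, y), 0.0, None)

    ss_moa = ss(p_mr, p_r)
    ss_route = np.zeros(y.shape[0]) if drop_route else ss(p_mr, p_m)
    ss_chem = ss(p_c, p_mr)
    ss_resid = ss(np.eye(n), p_c)
    total_var = y.var(axis=1)

    ms_moa = ss_moa / df_moa
    ms_chem = ss_chem / df_chem
    degenerate = total_var <= 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_moa / ms_chem
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 1.0),
                                            df_moa, df_chem), 0.0)
    # MS_chem == 0 with no MOA signal, or a flat gene, carries no evidence
    p = np.where((ms_chem == 0) & (ms_moa == 0), 1.0, p)
    p = np.where(degenerate, 1.0, p)
    f = np.where(degenerate, np.nan, f)

    table = pd.DataFrame({
        "ss_moa": ss_moa, "ss_route": ss_route, "ss_chem": ss_chem,
        "ss_resid": ss_resid, "F": f, "p": p, "q": bh_fdr(p),
        "degenerate": degenerate,
    }, index=pd.Index(log2ratio.gene_ids, name="gene_id"))
    return AnovaResult(table, df_moa, df_route, df_chem, df_resid)


def select_moa_varying(result: AnovaResult, q_cut: float = 0.01) -> list[str]:
    """Genes with q < ``q_cut``, ordered by ascending q then gene ID."""
    table = result.table
    hits = table[table["q"] < q_cut]
    hits = hits.sort_values(["q"], kind="mergesort")
    order = sorted(hits.index, key=lambda g: (hits.loc[g, "q"], g))
    return list(order)
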