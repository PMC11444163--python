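"""Mutation-burden / expression association and survival interaction.

The genome-wide screen regresses a target gene's expression on each gene's
functional protein-coding mutation burden, adjusting for tumor purity;
grouping for survival analysis uses a median split of the target's
expression, and the treatment-benefit question is asked through a Cox model
with a group x treatment product term.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .mutscan import PROTEIN_ALTERING_CLASSES, MutationCall
from .stats import bh_adjust, rank_sum_test
from .survival import CoxResult, cox_ph, km_curve, logrank_test

__all__ = [
    "burden_matrix",
    "burden_screen",
    "group_compare",
    "interaction_lm",
    "median_split",
    "cox_interaction",
]


def burden_matrix(
    calls: list[MutationCall],
    sample_ids: list[str],
    functional_classes: frozenset[str] = PROTEIN_ALTERING_CLASSES,
) -> pd.DataFrame:
    """Genes x samples count of functional protein-coding mutations."""
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for c in calls:
        if c.impact in functional_classes and c.gene is not None:
            counts[c.gene][c.sample_id] += 1
    mat = pd.DataFrame(0, index=sorted(counts), columns=sample_ids, dtype=int)
    for gene, per_sample in counts.items():
        for sid, k in per_sample.items():
            if sid in mat.columns:
                mat.loc[gene, sid] = k
    return mat


def burden_screen(
    target_expr: pd.Series,
    burden: pd.DataFrame,
    purity: pd.Series,
) -> pd.DataFrame:
    """Per-gene OLS of target expression on mutation burden + purity.

    A gene is evaluable iff at least one sample carries a functional
    mutation. Returns per gene: beta, se, t, p (two-sided), q (BH), and the
    expected -log10 p under uniformity for QQ plotting (``qq_expected`` is
    aligned to the rank of the observed p).
    """
    samples = list(target_expr.index)
    y = target_expr.to_numpy(dtype=float)
    pur = purity.loc[samples].to_numpy(dtype=float)
    n = y.size
    base = np.column_stack([np.ones(n), pur])
    rows = []
    for gene in burden.index:
        b = burden.loc[gene, samples].to_numpy(dtype=float)
        if (b > 0).sum() == 0:
            continue
        X = np.column_stack([base, b])
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            rows.append((gene, np.nan, np.nan, np.nan, np.nan, True))
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - X.shape[1]
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[2, 2])
        t = beta[2] / se
        p = 2.0 * sps.t.sf(abs(t), dof)
        rows.append((gene, beta[2], se, t, p, False))
    out = pd.DataFrame(
        rows, columns=["gene", "beta", "se", "t", "p_value", "collinear"]
    ).set_index("gene")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    m = out["p_value"].notna().sum()
    ranks = out["p_value"].rank(method="first")
    out["qq_expected"] = -np.log10(ranks / (m + 1))
    out["qq_observed"] = -np.log10(out["p_value"])
    return out.sort_values("p_value")


def group_compare(expr, grouping) -> tuple[float, float]:
    """Two-sided rank-sum comparison of expression between two groups.

    Returns (statistic, p). ``grouping`` is a boolean/2-level vector.
    """
    expr = np.asarray(expr, dtype=float)
    grouping = np.asarray(grouping)
    levels = np.unique(grouping)
    if levels.size != 2:
        raise ValueError("grouping must have exactly 2 levels")
    res = rank_sum_test(expr[grouping == levels[1]], expr[grouping == levels[0]])
    return res.statistic, res.p_value


def interaction_lm(
    expr: pd.Series,
    exposure: pd.Series,
    mut_status: pd.Series,
    purity: pd.Series,
) -> pd.DataFrame:
    """OLS of expression on exposure + mutation status + their interaction + purity.

    Returns the coefficient table (coef, se, t, p). With a single exposure
    level the model degenerates to a one-group fit (no interaction) with a
    warning in the table's attrs; an empty exposed-and-mutated cell leaves
    the interaction inestimable (flagged via attrs).
    """
    df = pd.DataFrame(
        {
            "expr": np.asarray(expr, dtype=float),
            "exposure": np.asarray(exposure, dtype=float),
            "mut": np.asarray(mut_status, dtype=float),
            "purity": np.asarray(purity, dtype=float),
        }
    )
    notes = []
    if df["exposure"].nunique() < 2:
        notes.append("single-level exposure: reduced to one-group model")
        X = sm.add_constant(df[["mut", "purity"]])
    else:
        df["interaction"] = df["exposure"] * df["mut"]
        X = sm.add_constant(df[["exposure", "mut", "interaction", "purity"]])
        if df["interaction"].nunique() < 2 or np.linalg.matrix_rank(X) < X.shape[1]:
            notes.append("interaction inestimable (empty exposed-mutated cell)")
            X = sm.add_constant(df[["exposure", "mut", "purity"]])
    fit = sm.OLS(df["expr"], X).fit()
    out = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p_value": fit.pvalues}
    )
    out.attrs["notes"] = notes
    return out


def median_split(expr: pd.Series) -> pd.Series:
    """High/low grouping at the median: high = strictly above the median,
    ties at the median assigned low. Constant input yields all-low."""
    expr = pd.Series(expr).astype(float)
    if len(expr) < 2:
        raise ValueError("need >= 2 samples for a median split")
    med = float(expr.median())
    return pd.Series(
        np.where(expr > med, "high", "low"), index=expr.index, name="group"
    )


@dataclass
class SurvivalInteractionResult:
    cox: CoxResult
    km_curves: dict[str, pd.DataFrame]
    logrank_by_treatment: dict[str, tuple[float, float]]

    @property
    def interaction_p(self) -> float:
        return float(self.cox.p[self.cox.names.index("group_low:treated")])

    @property
    def interaction_log_hr(self) -> float:
        return float(self.cox.coef[self.cox.names.index("group_low:treated")])


def cox_interaction(
    surv: pd.DataFrame,
    group: pd.Series,
    treatment_col: str = "treatment_after_biopsy",
    treated_level: str = "ARSI",
) -> SurvivalInteractionResult:
    """Cox model with a group x treatment product term, plus KM curves.

    ``surv`` needs sample_id, time_months, event and the treatment column;
    ``group`` maps sample_id -> {high, low} (typically from
    :func:`median_split`). The product term measures whether the treated
    stratum's benefit differs between expression groups; per-treatment
    two-group log-rank tests and the four KM curves accompany the fit.
    """
    df = surv.set_index("sample_id") if "sample_id" in surv.columns else surv.copy()
    n_before = len(df)
    df = df.join(group.rename("group"), how="inner")
    if df["group"].isna().any() or len(df) < n_before or len(df) == 0:
        raise ValueError("group labels missing for some survival records")
    low = (df["group"] == "low").astype(float)
    treated = (df[treatment_col] == treated_level).astype(float)
    X = pd.DataFrame(
        {
            "group_low": low,
            "treated": treated,
            "group_low:treated": low * treated,
        },
        index=df.index,
    )
    cox = cox_ph(df["time_months"], df["event"], X)
    curves = {}
    for glab in ("high", "low"):
        for tlab, tmask in (("treated", treated == 1), ("other", treated == 0)):
            m = (df["group"] == glab) & tmask
            if m.sum() > 0:
                curves[f"{glab}_{tlab}"] = km_curve(df.loc[m, "time_months"],
                                                   df.loc[m, "event"])
    logranks = {}
    for tlab, tmask in (("treated", treated == 1), ("other", treated == 0)):
        sub = df[tmask.to_numpy(dtype=bool)]
        if sub["group"].nunique() == 2 and sub["event"].sum() > 0:
            logranks[tlab] = logrank_test(
                sub["time_months"], sub["event"], sub["group"]
            )
    return SurvivalInteractionResult(cox, curves, logranks)
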