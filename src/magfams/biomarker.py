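"""Stratified differential-abundance biomarker discovery.

Case/control cohorts assembled from several studies carry strong
study-level (block) effects; an unstratified rank test would confound them
with the condition. Family abundances are therefore compared with a
blocked (van Elteren-style) Wilcoxon rank-sum test: ranks are computed
within each block, block statistics are combined with locally-best weights
``1/(n_b + 1)``, and a two-sided p-value is taken from the normal
approximation with tie-corrected variance. p-values across families are
adjusted with the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import AbundanceMatrix


def family_abundance(
    hit_table: pd.DataFrame,
    sample_meta: pd.DataFrame,
    evalue_max: float = 1e-3,
    min_coverage: float = 0.5,
) -> AbundanceMatrix:
    """Aggregate per-hit abundances into a family x sample matrix.

    ``hit_table`` columns: family_id, sample_id, evalue, coverage,
    abundance. Hits qualify with E-value strictly below ``evalue_max`` and
    coverage strictly above ``min_coverage``; qualifying hit abundances are
    summed per (family, sample); everything else is 0. ``sample_meta``
    columns: sample_id, condition, block (optionally habitat, colonoscopy);
    when a colonoscopy column exists it is collapsed into the block key.
    """
    meta = sample_meta.set_index("sample_id")
    samples = list(meta.index)
    ok = (hit_table["evalue"] < evalue_max) & (hit_table["coverage"] > min_coverage)
    sig = hit_table.loc[ok]
    families = sorted(hit_table["family_id"].unique())
    mat = pd.DataFrame(0.0, index=families, columns=samples)
    if len(sig):
        sums = sig.groupby(["family_id", "sample_id"])["abundance"].sum()
        for (fam, smp), v in sums.items():
            if smp in mat.columns:
                mat.loc[fam, smp] = v
    block = meta["block"].astype(str)
    if "colonoscopy" in meta.columns:
        block = block + "|" + meta["colonoscopy"].astype(str)
    return AbundanceMatrix(
        values=mat,
        condition=meta["condition"].to_dict(),
        block=block.to_dict(),
        habitat=meta["habitat"].to_dict() if "habitat" in meta.columns else {},
    )


def _block_stats(
    values: np.ndarray, is_case: np.ndarray
) -> tuple[float, float, float]:
    """Within-block rank-sum statistic, its null mean and null variance.

    Midranks for ties; variance uses the tie-corrected finite-population
    form ``Var[T] = m*k/(n*(n-1)) * (sum r^2 - n*rbar^2)``.
    """
    n = len(values)
    m = int(is_case.sum())
    k = n - m
    ranks = stats.rankdata(values)
    t = float(ranks[is_case].sum())
    mean = m * (n + 1) / 2.0
    rbar = (n + 1) / 2.0
    var = m * k / (n * (n - 1)) * float((ranks**2).sum() - n * rbar**2)
    return t, mean, var


def blocked_wilcoxon(
    values: Sequence[float],
    condition: Sequence[str],
    block: Sequence[str],
    weighting: str = "van_elteren",
) -> tuple[float, float]:
    """Stratified two-sample Wilcoxon rank-sum (van Elteren) test.

    Returns ``(Z, p)`` with a two-sided normal-approximation p-value.
    Blocks containing only one condition contribute nothing; with a single
    informative block and no ties the result coincides with the ordinary
    normal-approximation rank-sum test. ``weighting`` is ``"van_elteren"``
    (block weight ``1/(n_b+1)``, locally best) or ``"unweighted"``.
    """
    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition)
    block = np.asarray(block)
    if weighting not in ("van_elteren", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    num = 0.0
    var = 0.0
    informative = 0
    for b in np.unique(block):
        sel = block == b
        is_case = condition[sel] == "case"
        if is_case.all() or (~is_case).all() or sel.sum() < 2:
            continue
        t, mean, v = _block_stats(values[sel], is_case)
        w = 1.0 / (sel.sum() + 1) if weighting == "van_elteren" else 1.0
        num += w * (t - mean)
        var += w**2 * v
        informative += 1
    if informative == 0:
        raise ValueError("no block contains both conditions")
    if var == 0.0:
        return 0.0, 1.0  # all values tied within every block
    z = num / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fdr_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # per-family statistics
    over: pd.DataFrame  # q < alpha and case-enriched
    under: pd.DataFrame  # q < alpha and control-enriched


def differential_families(
    matrix: AbundanceMatrix,
    alpha: float = 0.01,
    weighting: str = "van_elteren",
) -> DifferentialResult:
    """Blocked-Wilcoxon differential abundance across all families.

    Families absent everywhere are excluded from testing. The effect is the
    per-block difference of mean case vs control abundance, averaged across
    informative blocks; prevalence is the fraction of samples with non-zero
    abundance. Families with ``q < alpha`` are split into over-/
    under-abundant by the sign of the mean effect.
    """
    samples = matrix.sample_ids
    cond = np.array([matrix.condition[s] for s in samples])
    block = np.array([matrix.block[s] for s in samples])
    rows = []
    for fam in matrix.family_ids:
        vals = matrix.values.loc[fam].to_numpy(dtype=float)
        prevalence = float((vals > 0).mean())
        if prevalence == 0.0:
            continue
        z, p = blocked_wilcoxon(vals, cond, block, weighting=weighting)
        effects = []
        for b in np.unique(block):
            sel = block == b
            case_sel = sel & (cond == "case")
            ctrl_sel = sel & (cond == "control")
            if case_sel.any() and ctrl_sel.any():
                effects.append(vals[case_sel].mean() - vals[ctrl_sel].mean())
        rows.append(
            {
                "family_id": fam,
                "Z": z,
                "p": p,
                "mean_effect": float(np.mean(effects)),
                "prevalence": prevalence,
            }
        )
    table = pd.DataFrame(
        rows, columns=["family_id", "Z", "p", "mean_effect", "prevalence"]
    )
    if len(table):
        table["q"] = fdr_bh(table["p"].to_numpy())
    else:
        table["q"] = []
    table["direction"] = np.where(table["mean_effect"] > 0, "over", "under")
    sig = table[table["q"] < alpha]
    return DifferentialResult(
        table=table,
        over=sig[sig["mean_effect"] > 0].reset_index(drop=True),
        under=sig[sig["mean_effect"] < 0].reset_index(drop=True),
    )
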