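"""Differential-expression statistics: moderated two-group contrasts,
one-way time-course ANOVA, BH-FDR, predominance and cold-response calls.

The moderated t follows the standard empirical-Bayes construction for
microarray linear models: gene-wise residual variances s_g^2 (d_g df) are
assumed to follow a scaled inverse-chi-square prior with hyperparameters
(d0, s0^2); marginally s_g^2 ~ s0^2 * F(d_g, d0), so moment matching on
log s_g^2 via digamma/trigamma identities yields (d0, s0^2).  The posterior
variance shrinks s_g^2 toward s0^2 and the resulting t statistic gains
d0 extra degrees of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SampleDesign, ValidationError

log = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds for the analysis stages.

    predominant_q / predominant_fold: FDR-adjusted p and linear fold change
    for tissue predominance; timecourse_p: raw ANOVA p; cold_p / cold_fold:
    per-pair cold response; k_neighborhood: co-expression neighborhood size;
    promoter_length: upstream window (nt); motif_fdr: cis-element q cutoff.
    """

    predominant_q: float = 0.0005
    predominant_fold: float = 2.0
    timecourse_p: float = 0.001
    cold_p: float = 0.05
    cold_fold: float = 2.0
    k_neighborhood: int = 500
    promoter_length: int = 3000
    motif_fdr: float = 0.05

    def __post_init__(self):
        for name in ("predominant_q", "timecourse_p", "cold_p", "motif_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name}={v} outside (0,1]")
        for name in ("predominant_fold", "cold_fold"):
            if getattr(self, name) <= 1:
                raise ValidationError(f"{name} must exceed 1")
        if self.k_neighborhood <= 0 or self.promoter_length <= 0:
            raise ValidationError("k_neighborhood and promoter_length must be positive")


# ---------------------------------------------------------------------------
# Two-group contrast + empirical-Bayes moderation
# ---------------------------------------------------------------------------

def fit_contrast(
    m: ExpressionMatrix,
    design: SampleDesign | None,
    group_a,
    group_b,
) -> pd.DataFrame:
    """Ordinary two-group fit per gene.

    estimate = mean(A) - mean(B); s2 = pooled within-group variance with
    df = nA + nB - 2; v = 1/nA + 1/nB is the squared standard-error factor.
    ``design`` is accepted for interface symmetry; groups are explicit
    sample-id lists.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("contrast groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each contrast group needs >=2 samples")
    a = m.data[group_a].to_numpy()
    b = m.data[group_b].to_numpy()
    na, nb = a.shape[1], b.shape[1]
    est = a.mean(axis=1) - b.mean(axis=1)
    ssa = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    return pd.DataFrame(
        {
            "estimate": est,
            "s2": s2,
            "df": float(df),
            "v": 1.0 / na + 1.0 / nb,
        },
        index=m.data.index,
    )


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float]:
    """Moment-matching estimate of the scaled inverse-chi-square variance
    prior (d0, s0^2) from gene-wise sample variances.

    Uses e_g = log s_g^2 - psi(d_g/2) + log(d_g/2); then
    mean(e) = log s0^2 - psi(d0/2) + log(d0/2) and
    var(e) ~= psi'(d_g/2) + psi'(d0/2).  Returns (inf, exp(...)) when the
    observed spread is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = s2 > VARIANCE_FLOOR
    if ok.sum() < 2:
        raise ValidationError("too few positive variances to pool")
    s2, df = s2[ok], df[ok]
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    n = e.size
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(np.mean(special.polygamma(1, df / 2.0)))
    if excess <= 0:
        # no spread beyond sampling noise: degenerate prior at the common
        # variance (arithmetic mean, exact for constant s2)
        d0 = np.inf
        s0sq = float(s2.mean())
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0sq = float(
            np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    return d0, s0sq


def moderate(fit: pd.DataFrame, d0: float | None = None, s0sq: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderation of a two-group fit.

    Returns a ContrastResult frame: estimate (log2FC), s2, s2_post,
    moderated t, two-sided p, and BH q; hyperparameters are attached as
    ``result.attrs['d0']`` / ``['s0sq']``.
    """
    if len(fit) < 50 and d0 is None:
        warnings.warn("moderate: <50 genes, hyperparameter estimates unstable")
    s2 = fit["s2"].to_numpy().copy()
    df = fit["df"].to_numpy(dtype=float)
    v = fit["v"].to_numpy(dtype=float)
    est = fit["estimate"].to_numpy(dtype=float)

    if not (s2 > VARIANCE_FLOOR).any():
        warnings.warn("moderate: all residual variances ~0; using floor, ordinary t")
        s2 = np.maximum(s2, VARIANCE_FLOOR)
        d0, s0sq = 0.0, float(np.median(s2))
    if d0 is None or s0sq is None:
        d0, s0sq = estimate_variance_prior(s2, df)
        log.info("moderate: estimated d0=%.3g s0sq=%.4g", d0, s0sq)
    s2 = np.maximum(s2, VARIANCE_FLOOR)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = df + d0
    with np.errstate(divide="ignore"):
        t = est / np.sqrt(s2_post * v)
    finite_df = np.where(np.isinf(df_total), 1e9, df_total)
    p = 2.0 * stats.t.sf(np.abs(t), finite_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    out = pd.DataFrame(
        {
            "estimate": est,
            "s2": fit["s2"].to_numpy(),
            "s2_post": s2_post,
            "df_total": df_total,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
        },
        index=fit.index,
    )
    out.attrs["d0"] = float(d0)
    out.attrs["s0sq"] = float(s0sq)
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Calls
# ---------------------------------------------------------------------------

def call_predominant(
    embryo: pd.DataFrame,
    endosperm: pd.DataFrame,
    th: Thresholds = Thresholds(),
) -> pd.Series:
    """Classify each gene as embryo / endosperm / both / none.

    A tissue passes when q < predominant_q and the linear fold change exceeds
    predominant_fold in the tissue's favor (log2FC > log2(fold))."""
    if not embryo.index.equals(endosperm.index):
        raise ValidationError("contrast results cover different gene universes")
    lfc_cut = np.log2(th.predominant_fold)
    pass_em = (embryo["q"] < th.predominant_q) & (embryo["estimate"] > lfc_cut)
    pass_en = (endosperm["q"] < th.predominant_q) & (endosperm["estimate"] > lfc_cut)
    cls = np.where(
        pass_em & pass_en, "both",
        np.where(pass_em, "embryo", np.where(pass_en, "endosperm", "none")),
    )
    return pd.Series(cls, index=embryo.index, name="class")


def anova_timecourse(
    m: ExpressionMatrix,
    design: SampleDesign,
    tissue: str,
    treatment: str = "control",
) -> pd.DataFrame:
    """One-way fixed-effects F test over developmental stages of a tissue.

    Returns per gene: F, p, direction ('up'/'down': sign of last-stage mean
    minus first-stage mean).  Zero between- and within-group variation gives
    F = 0, p = 1 by convention.
    """
    table = design.table
    mask = (table["tissue"] == tissue) & (table["treatment"] == treatment)
    stages = sorted(int(s) for s in table.loc[mask, "stage"].dropna().unique())
    if len(stages) < 3:
        raise ValidationError(f"tissue {tissue!r}: need >=3 stages, got {len(stages)}")
    groups = []
    for s in stages:
        ids = design.samples_for(tissue=tissue, stage=s, treatment=treatment)
        if len(ids) < 2:
            raise ValidationError(f"stage {s} of {tissue} has <2 replicates")
        groups.append(m.data[ids].to_numpy())
    k = len(groups)
    ns = np.array([g.shape[1] for g in groups], dtype=float)
    n_tot = ns.sum()
    means = np.column_stack([g.mean(axis=1) for g in groups])
    grand = (means * ns).sum(axis=1) / n_tot
    ssb = ((means - grand[:, None]) ** 2 * ns).sum(axis=1)
    ssw = np.zeros_like(ssb)
    for g, mu in zip(groups, means.T):
        ssw += ((g - mu[:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, int(n_tot) - k
    msb = ssb / df_b
    msw = ssw / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    p = stats.f.sf(f, df_b, df_w)
    # both mean squares zero: no evidence of change
    degen = (msw == 0) & (msb == 0)
    f = np.where(degen, 0.0, f)
    p = np.where(degen, 1.0, p)
    p = np.where((msw == 0) & (msb > 0), np.finfo(float).tiny, p)
    f = np.where(np.isinf(f), np.finfo(float).max, f)
    direction = np.where(means[:, -1] >= means[:, 0], "up", "down")
    return pd.DataFrame(
        {"F": f, "p": np.clip(p, np.finfo(float).tiny, 1.0), "direction": direction},
        index=m.data.index,
    )


def timecourse_regulated(result: pd.DataFrame, th: Thresholds = Thresholds()) -> pd.Series:
    """Direction map (gene -> 'up'/'down') of genes passing the raw
    time-course p threshold."""
    hits = result[result["p"] < th.timecourse_p]
    return hits["direction"].copy()


def call_cold_regulated(
    m: ExpressionMatrix,
    design: SampleDesign,
    pairs: list[tuple[list, list]],
    th: Thresholds = Thresholds(),
) -> list[dict]:
    """Per (treated, control) pair: moderated contrast treated-vs-control and
    up/down gene sets at cold_p and cold_fold.

    'up' = higher in the treated (later) group.  Returns one dict per pair
    with keys 'up', 'down' (gene-id sets), 'result' (ContrastResult frame).
    """
    lfc_cut = np.log2(th.cold_fold)
    out = []
    for treated, control in pairs:
        fit = fit_contrast(m, design, treated, control)
        res = moderate(fit)
        up = set(res.index[(res["p"] < th.cold_p) & (res["estimate"] > lfc_cut)])
        down = set(res.index[(res["p"] < th.cold_p) & (res["estimate"] < -lfc_cut)])
        out.append({"up": up, "down": down, "result": res})
    return out


def trend_concordance(dir_a: pd.Series | dict, dir_b: pd.Series | dict):
    """Compare two gene->direction maps on their common genes.

    Returns (common gene list, n_common, fraction with equal direction);
    fraction is None when there are no common genes.
    """
    da = dict(dir_a)
    db = dict(dir_b)
    bad = {v for v in list(da.values()) + list(db.values())} - {"up", "down"}
    if bad:
        raise ValidationError(f"directions must be 'up'/'down', got {sorted(bad)}")
    common = sorted(set(da) & set(db))
    if not common:
        return [], 0, None
    same = sum(1 for g in common if da[g] == db[g])
    return common, len(common), same / len(common)
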