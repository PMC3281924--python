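"""Detection calls, expressed-gene logic, normalization, Z-scores and QC.

Input arrays are gene-level log2 intensities.  Detection mimics the semantics
of Present/Absent calling: a gene is "expressed" in a sample group only when
Present in every replicate of that group, and expressed in a scope (e.g. the
whole seed) when expressed in at least one group of the scope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, SampleDesign, ValidationError

log = logging.getLogger(__name__)


def detection_call(
    m: ExpressionMatrix,
    mode: str = "quantile",
    threshold: float = 6.0,
    q: float = 0.30,
) -> pd.DataFrame:
    """Present/Absent calls per gene and array.

    mode="absolute": Present where value > ``threshold`` (log2 units).
    mode="quantile": Present where value > that array's ``q`` quantile
    (strictly greater, so a constant array is all-Absent).

    Returns a boolean DataFrame (True = Present) with the matrix's shape.
    """
    if mode == "absolute":
        return m.data > threshold
    if mode == "quantile":
        if not (0.0 < q < 1.0):
            raise ValueError(f"quantile must be in (0,1), got {q}")
        cut = m.data.quantile(q, axis=0)
        return m.data.gt(cut, axis=1)
    raise ValueError(f"unknown detection mode {mode!r}")


def expressed_genes(
    calls: pd.DataFrame,
    design: SampleDesign,
    scope,
) -> set[str]:
    """Genes expressed anywhere in ``scope``.

    ``scope`` is a group key (tissue, stage, treatment) or an iterable of
    group keys.  A gene is expressed in a group iff called Present in ALL
    replicates of that group; expressed in the scope iff expressed in >=1
    group.
    """
    groups = design.groups()
    if isinstance(scope, tuple) and len(scope) == 3 and isinstance(scope[0], str):
        scope = [scope]
    out: set[str] = set()
    for key in scope:
        if key not in groups:
            raise KeyError(f"unknown sample group {key!r}")
        samples = groups[key]
        if len(samples) < 2:
            raise ValidationError(f"group {key!r} has <2 replicates")
        present_all = calls[samples].all(axis=1)
        out |= set(calls.index[present_all])
    return out


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every array onto the common (row-mean of sorted columns)
    distribution; within-array ranks preserved, ties averaged."""
    if m.shape[1] < 2:
        warnings.warn("quantile_normalize: single-column matrix, no-op")
        return ExpressionMatrix(m.data.copy())
    x = m.values
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(method="average").to_numpy()  # 1..n, ties averaged
    out = np.interp(ranks, np.arange(1, n + 1), ref)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    )


def zscore_by_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene (x - mean)/sd with sample sd (n-1); constant genes -> zeros."""
    x = m.values
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z = np.nan_to_num(z)
    return ExpressionMatrix(pd.DataFrame(z, index=m.data.index, columns=m.data.columns))


def replicate_qc(m: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Pearson correlation between the two replicate arrays of each
    (tissue, stage, treatment) group; groups without exactly 2 replicates
    are skipped with a warning."""
    rows = []
    for key, samples in design.groups().items():
        if len(samples) != 2:
            warnings.warn(f"replicate_qc: group {key!r} has {len(samples)} arrays, skipped")
            continue
        a = m.data[samples[0]].to_numpy()
        b = m.data[samples[1]].to_numpy()
        pcc = float(np.corrcoef(a, b)[0, 1])
        tissue, stage, treatment = key
        rows.append(
            {
                "tissue": tissue,
                "stage": "" if stage is None else stage,
                "treatment": treatment,
                "sample_1": samples[0],
                "sample_2": samples[1],
                "pcc": pcc,
            }
        )
    return pd.DataFrame(rows)


def filter_low_expression(
    m: ExpressionMatrix,
    calls: pd.DataFrame | None = None,
    mode: str = "all-absent",
) -> ExpressionMatrix:
    """Drop uninformative genes.

    mode="all-absent": drop genes called Absent in every array (requires
    ``calls``); mode="negative": drop genes whose maximum log2 value is < 0.
    """
    if mode == "all-absent":
        if calls is None:
            raise ValueError("mode 'all-absent' requires detection calls")
        if calls.shape != m.shape:
            raise ValidationError("calls shape does not match matrix")
        keep = calls.any(axis=1)
    elif mode == "negative":
        keep = m.data.max(axis=1) >= 0
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_low_expression(%s): dropped %d genes", mode, dropped)
    return ExpressionMatrix(m.data.loc[keep])


def percent_expressed(n_subset: int, n_total: int) -> int:
    """Report a subset as a whole-number percentage of a total, the rounding
    convention used for headline expressed-gene summaries."""
    if n_total <= 0:
        raise ValueError("total must be positive")
    return int(round(100.0 * n_subset / n_total))
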