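"""Chi-square over-representation of categories in gene sets.

Each term yields a 2x2 table {in-set, out-of-set} x {in-term, out-of-term}
over a fixed background; the statistic is the Pearson chi-square without
continuity correction (df = 1).  Only over-representation (set fraction
above background fraction) counts as enrichment; depleted terms carry a
"not enriched" marker in matrix output.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CategoryMap, ValidationError
from .diffexpr import bh_fdr


def chi2_2x2(a, b, c, d):
    """Closed-form Pearson chi-square for the 2x2 table [[a, b], [c, d]]
    (vectorized).  Degenerate margins give 0."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom == 0, 0.0, stat)


def chisq_enrichment(
    geneset,
    cats: CategoryMap,
    expected_floor: float = 5.0,
) -> pd.DataFrame:
    """Per-term chi-square over-representation of ``geneset`` against the
    category background.

    Returns a frame with term, label, a (set & term), n (set), K (background
    & term), N (background), chi2, p, neglog10p, q (BH over tested terms),
    enriched flag (a/n > K/N) and low_expected flag (any expected cell < 5).
    Terms with no background genes are skipped with a warning.
    """
    geneset = set(geneset)
    if not geneset:
        raise ValidationError("empty gene set")
    bg = cats.background
    extra = geneset - bg
    if extra:
        raise ValidationError(f"gene set outside background: {sorted(extra)[:5]}")
    n, N = len(geneset), len(bg)
    if N < 2:
        raise ValidationError("background must contain >=2 genes")
    rows = []
    for term in cats.terms:
        genes = cats.term_genes[term]
        K = len(genes)
        if K == 0:
            warnings.warn(f"term {term}: no background genes, skipped")
            continue
        a = len(geneset & genes)
        rows.append((term, a, K))
    if not rows:
        return pd.DataFrame(
            columns=["term", "label", "a", "n", "K", "N", "chi2", "p",
                     "neglog10p", "q", "enriched", "low_expected"]
        )
    terms = [r[0] for r in rows]
    a = np.array([r[1] for r in rows], dtype=float)
    K = np.array([r[2] for r in rows], dtype=float)
    b = n - a            # in set, not in term
    c = K - a            # in term, not in set
    d = N - n - K + a    # neither
    chi2 = chi2_2x2(a, b, c, d)
    p = np.clip(stats.chi2.sf(chi2, df=1), np.finfo(float).tiny, 1.0)
    expected = np.stack(
        [n * K / N, n * (N - K) / N, (N - n) * K / N, (N - n) * (N - K) / N]
    )
    low = (expected < expected_floor).any(axis=0)
    enriched = a / n > K / N
    out = pd.DataFrame(
        {
            "term": terms,
            "label": [cats.term_labels.get(t, t) for t in terms],
            "a": a.astype(int),
            "n": n,
            "K": K.astype(int),
            "N": N,
            "chi2": chi2,
            "p": p,
            "neglog10p": -np.log10(p),
            "q": bh_fdr(p),
            "enriched": enriched,
            "low_expected": low,
        }
    ).set_index("term")
    return out.sort_values("p")


def enrichment_matrix(results: dict[str, pd.DataFrame], terms=None) -> pd.DataFrame:
    """Terms x gene-set-names matrix of -log10 p for visualization.

    Cells hold neglog10p only where the term was tested and enriched
    (over-represented); otherwise NaN, written as '-' in TSV output.  Terms
    tested in no result set are dropped with a warning.
    """
    if terms is None:
        seen: list[str] = []
        for res in results.values():
            for t in res.index:
                if t not in seen:
                    seen.append(t)
        terms = seen
    mat = pd.DataFrame(np.nan, index=list(terms), columns=list(results))
    for name, res in results.items():
        for term in mat.index:
            if term in res.index and bool(res.loc[term, "enriched"]):
                mat.loc[term, name] = res.loc[term, "neglog10p"]
    untested = [
        t for t in mat.index if all(t not in res.index for res in results.values())
    ]
    if untested:
        warnings.warn(f"terms absent from all result lists dropped: {untested[:5]}")
        mat = mat.drop(index=untested)
    return mat


def write_enrichment_matrix(mat: pd.DataFrame, path) -> None:
    mat.to_csv(path, sep="\t", index_label="term", na_rep="-", float_format="%.4f")


def read_enrichment_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="term", na_values=["-"])


def family_enrichment(
    tf_sets: dict[str, set],
    family_map: CategoryMap,
) -> dict[str, pd.DataFrame]:
    """TF-family over-representation in named TF gene sets, with the
    background restricted to TF genes (the family map's universe)."""
    out = {}
    for name, genes in tf_sets.items():
        out[name] = chisq_enrichment(set(genes) & family_map.background, family_map)
    return out
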