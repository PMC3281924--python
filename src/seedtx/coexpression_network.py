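"""TF-centered guilt-by-association over an expression compendium.

For each transcription factor, Pearson correlation against every other gene
across the arrays defines a top-k neighborhood (k = 500 by default); GO
enrichment of the neighborhood annotates the TF, and the (TF, term) pairs
form a bipartite network for export.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io_formats import CategoryMap, ExpressionMatrix, TFNetwork, ValidationError
from .enrichment import chisq_enrichment


def pcc_profiles(compendium: ExpressionMatrix, tfs) -> pd.DataFrame:
    """TF x gene Pearson correlations across arrays.

    Zero-variance genes are excluded with a warning; each TF's
    self-correlation is NaN so it never enters a neighborhood.
    """
    tfs = list(tfs)
    missing = [t for t in tfs if t not in compendium.data.index]
    if missing:
        raise ValidationError(f"TFs absent from compendium: {missing[:5]}")
    if compendium.shape[1] < 3:
        raise ValidationError("compendium needs >=3 arrays")
    x = compendium.values
    sd = x.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = [g for g, k in zip(compendium.gene_ids, keep) if not k]
    if dropped:
        warnings.warn(f"pcc_profiles: {len(dropped)} zero-variance genes excluded")
    genes = [g for g, k in zip(compendium.gene_ids, keep) if k]
    xk = x[keep]
    zero_var_tfs = [t for t in tfs if t in dropped]
    if zero_var_tfs:
        raise ValidationError(f"TFs with zero variance: {zero_var_tfs[:5]}")
    xs = (xk - xk.mean(axis=1, keepdims=True)) / xk.std(axis=1, ddof=1, keepdims=True)
    idx = {g: i for i, g in enumerate(genes)}
    tf_rows = xs[[idx[t] for t in tfs]]
    n = xk.shape[1]
    pcc = tf_rows @ xs.T / (n - 1)
    pcc = np.clip(pcc, -1.0, 1.0)
    out = pd.DataFrame(pcc, index=tfs, columns=genes)
    for t in tfs:
        out.loc[t, t] = np.nan
    return out


def top_k(profiles: pd.DataFrame, k: int = 500) -> dict[str, list[tuple[str, float]]]:
    """Per TF: the k most-correlated genes, descending PCC, ties broken by
    ascending gene id (deterministic).  Fewer than k candidates yields the
    whole candidate list with a warning."""
    out: dict[str, list[tuple[str, float]]] = {}
    for tf in profiles.index:
        row = profiles.loc[tf].dropna()
        if len(row) < k:
            warnings.warn(f"top_k: TF {tf} has only {len(row)} candidates (< {k})")
        order = sorted(row.items(), key=lambda gv: (-gv[1], gv[0]))
        out[tf] = [(g, float(v)) for g, v in order[:k]]
    return out


def annotate_tf(
    neighborhoods: dict[str, list[tuple[str, float]]],
    cats: CategoryMap,
    q_threshold: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """GO enrichment of each TF's neighborhood against the compendium
    background; returns per-TF result frames filtered to enriched terms at
    q < ``q_threshold``.  Empty neighborhoods are skipped with a warning."""
    out = {}
    for tf, nbhd in neighborhoods.items():
        genes = {g for g, _ in nbhd} & cats.background
        if not genes:
            warnings.warn(f"annotate_tf: TF {tf} neighborhood empty, skipped")
            continue
        res = chisq_enrichment(genes, cats)
        out[tf] = res[res["enriched"] & (res["q"] < q_threshold)]
    return out


def build_network(
    annotations: dict[str, pd.DataFrame],
    tf_classes: pd.Series | dict | None = None,
) -> TFNetwork:
    """Bipartite TF-term network from per-TF enrichment tables.

    TF nodes carry their predominance class (embryo/endosperm/both, or
    'unclassified'); edges carry the enrichment q-value.  TFs with no
    surviving terms remain as isolated nodes.
    """
    classes = dict(tf_classes) if tf_classes is not None else {}
    net = TFNetwork()
    for tf, res in annotations.items():
        cls = classes.get(tf, "unclassified")
        if cls in (None, "none"):
            cls = "unclassified"
        net.add_tf(tf, expr_class=str(cls))
        for term, row in res.iterrows():
            net.add_term(str(term), label=str(row.get("label", term)))
            net.add_edge(tf, str(term), q=float(row["q"]))
    return net
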