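"""Promoter extraction and degenerate cis-element enrichment.

Upstream regions ("up to" a fixed length, default 3000 nt, measured from the
translation start) are pulled from a genome FASTA guided by GFF3 gene models
and reported 5'->3' on the gene's sense strand.  IUPAC patterns are scanned
on both strands; enrichment compares the fraction of genes carrying >=1
occurrence in a group against the genome-wide fraction with the same 2x2
chi-square used for category enrichment.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import gffutils
import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .io_formats import IUPAC_CODES, CategoryMap, MotifLibrary, ValidationError
from .enrichment import chisq_enrichment

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Promoter:
    """Upstream sequence of one gene, 5'->3' on the gene's sense strand."""

    gene_id: str
    seq: str
    contig: str
    start: int  # 1-based inclusive genomic coordinates of the extracted window
    end: int
    strand: str


def _translation_starts(db: gffutils.FeatureDB) -> dict[str, tuple[str, int, int, str]]:
    """Per gene: (contig, start, end, strand) of the coding span used to
    anchor the promoter (CDS extent if annotated, else the gene span)."""
    out = {}
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if cds:
            start = min(c.start for c in cds)
            end = max(c.end for c in cds)
        else:
            start, end = gene.start, gene.end
        out[gene.id] = (gene.seqid, start, end, gene.strand)
    return out


def extract_upstream(genome_fasta, gff3, length: int = 3000) -> dict[str, Promoter]:
    """Extract up-to-``length`` nt upstream of each gene's translation start.

    Plus-strand gene starting at s: genomic bases [max(1, s-length), s-1].
    Minus-strand gene ending at e: reverse complement of
    [e+1, min(contig_end, e+length)].  Truncated only at contig boundaries;
    genes with a zero-length window are skipped with a warning.
    """
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        str(gff3), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: dict[str, Promoter] = {}
    for gene_id, (contig, gstart, gend, strand) in _translation_starts(db).items():
        if contig not in fasta:
            raise ValidationError(f"gene {gene_id}: unknown contig {contig!r}")
        contig_len = len(fasta[contig])
        if strand == "-":
            lo = gend + 1
            hi = min(contig_len, gend + length)
            if hi < lo:
                warnings.warn(f"gene {gene_id}: zero-length promoter, skipped")
                continue
            seq = reverse_complement(fasta[contig][lo - 1 : hi])
        else:
            lo = max(1, gstart - length)
            hi = gstart - 1
            if hi < lo:
                warnings.warn(f"gene {gene_id}: zero-length promoter, skipped")
                continue
            seq = str(fasta[contig][lo - 1 : hi])
        out[gene_id] = Promoter(gene_id, seq, contig, lo, hi, strand)
    return out


def iupac_to_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern to an overlapping-occurrence regex.

    Sequence letter N matches only pattern letter N (a genomic N carries no
    information about the three specific bases of, say, pattern B)."""
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_CODES:
            raise ValidationError(f"illegal IUPAC character {ch!r} in {pattern!r}")
        bases = IUPAC_CODES[ch]
        if ch == "N":
            parts.append("[ACGTN]")
        elif len(bases) == 1:
            parts.append(bases)
        else:
            parts.append(f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def count_occurrences(seq: str, pattern: str) -> int:
    """Occurrences of an IUPAC pattern in ``seq`` and its reverse complement
    (overlaps counted)."""
    rx = iupac_to_regex(pattern)
    seq = seq.upper()
    return len(rx.findall(seq)) + len(rx.findall(reverse_complement(seq)))


def scan_motifs(
    promoters: dict[str, Promoter] | dict[str, str],
    lib: MotifLibrary,
) -> pd.DataFrame:
    """Gene x motif occurrence counts over both strands.

    Accepts either Promoter records or plain gene->sequence strings.
    Presence is count >= 1; use ``hits > 0`` for the indicator.
    """
    seqs = {
        g: (p.seq if isinstance(p, Promoter) else p) for g, p in promoters.items()
    }
    regexes = {mid: iupac_to_regex(pat) for mid, pat in lib}
    rows = []
    for gene, seq in seqs.items():
        seq = seq.upper()
        rc = reverse_complement(seq)
        rows.append([len(rx.findall(seq)) + len(rx.findall(rc)) for rx in regexes.values()])
    return pd.DataFrame(rows, index=list(seqs), columns=list(regexes), dtype=int)


def motif_enrichment(
    hits: pd.DataFrame,
    group,
    universe=None,
    mode: str = "presence",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-motif chi-square enrichment of a gene group against the universe.

    mode="presence" (default): a gene counts once if it has >=1 occurrence —
    the gene-level 2x2 table the genome-background comparison requires.
    mode="occurrences": total occurrence counts form the table instead.
    Motifs with zero carriers in the universe are skipped with a warning.
    Adds an ``enriched_call`` column: enriched and q < ``fdr``.
    """
    universe = set(hits.index) if universe is None else set(universe)
    group = set(group)
    if not group <= universe:
        raise ValidationError("group must be a subset of the universe")
    missing = universe - set(hits.index)
    if missing:
        raise ValidationError(f"hits missing universe genes: {sorted(missing)[:5]}")
    sub = hits.loc[sorted(universe)]
    if mode == "presence":
        carriers = {
            mid: frozenset(sub.index[sub[mid] > 0]) for mid in sub.columns
        }
        keep = {}
        for mid, genes in carriers.items():
            if not genes:
                warnings.warn(f"motif {mid}: absent from entire universe, skipped")
                continue
            keep[mid] = genes
        cats = CategoryMap(
            term_labels={m: m for m in keep},
            term_genes=keep,
            background=frozenset(universe),
        )
        res = chisq_enrichment(group, cats)
    elif mode == "occurrences":
        from scipy import stats as _st
        from .enrichment import chi2_2x2
        from .diffexpr import bh_fdr
        rows = []
        total_group = int(sub.loc[sorted(group)].to_numpy().sum())
        total_all = int(sub.to_numpy().sum())
        for mid in sub.columns:
            a = int(sub.loc[sorted(group), mid].sum())
            K = int(sub[mid].sum())
            if K == 0:
                warnings.warn(f"motif {mid}: absent from entire universe, skipped")
                continue
            b = total_group - a
            c = K - a
            d = total_all - total_group - c
            chi2 = float(chi2_2x2(a, b, c, d))
            p = float(np.clip(_st.chi2.sf(chi2, 1), np.finfo(float).tiny, 1.0))
            rows.append((mid, a, total_group, K, total_all, chi2, p,
                         a / max(total_group, 1) > K / total_all))
        res = pd.DataFrame(
            rows, columns=["term", "a", "n", "K", "N", "chi2", "p", "enriched"]
        ).set_index("term")
        res["neglog10p"] = -np.log10(res["p"])
        res["q"] = bh_fdr(res["p"].to_numpy()) if len(res) else []
        res = res.sort_values("p")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = res.copy()
    res["enriched_call"] = res["enriched"] & (res["q"] < fdr)
    return res
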