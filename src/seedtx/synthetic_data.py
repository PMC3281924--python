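"""Synthetic compendia, cold experiments, co-expression collections and
promoters with planted, fully-known ground truth.

The development compendium mirrors the study layout: embryo sampled at 3, 6,
9 and 12 days after fertilization (DAF), endosperm at 3, 6, 9 and 16 DAF,
plus root, leaf, seedling and ovary reference tissues, two biological
replicates each (24 arrays).  Values are log2 intensities: a per-gene
baseline plus planted class offsets plus Normal noise whose gene-wise
variance is drawn from a scaled inverse-chi-square prior (d0, s0^2) — the
same family the moderated-t machinery assumes, so hyperparameter recovery is
a meaningful end-to-end check.  All randomness flows from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    IUPAC_CODES,
    MotifLibrary,
    SampleDesign,
    CategoryMap,
)
from .promoter_motifs import reverse_complement


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-condition parameters of the development compendium.

    Fractions partition the gene universe into planted classes; effect sizes
    are log2 units.  Defaults plant 4-fold predominance effects and
    mean-centered monotone time-course trajectories with a 2.0 log2 step per
    stage, on a detection geometry where expressed baselines span 7-13 log2
    units and absent genes sit well below the 6.0 detection floor.
    """

    n_genes: int = 5000
    n_replicates: int = 2
    embryo_stages: tuple = (3, 6, 9, 12)
    endosperm_stages: tuple = (3, 6, 9, 16)
    reference_tissues: tuple = ("root", "leaf", "seedling", "ovary")
    frac_embryo: float = 0.05
    frac_endosperm: float = 0.04
    frac_both: float = 0.015
    frac_timecourse: float = 0.02     # per seed tissue, half up / half down
    frac_absent: float = 0.10
    effect_size: float = 2.0          # log2 predominance offset (4-fold)
    timecourse_step: float = 2.0      # log2 per stage, mean-centered
    baseline_range: tuple = (7.0, 13.0)
    absent_mean: float = 4.5
    absent_sd: float = 0.5
    detection_floor: float = 6.0
    d0: float = 4.0                   # variance-prior degrees of freedom
    s0sq: float = 0.05                # variance-prior scale (log2^2)
    heavy_tail_fraction: float = 0.0  # fraction of noise drawn from t(3)
    # cold experiment
    cold_stages: tuple = (4, 10)
    n_cold_down: int = 150
    n_cold_up: int = 50
    cold_effect: float = 2.0

    def __post_init__(self):
        total = (
            self.frac_embryo + self.frac_endosperm + self.frac_both
            + 2 * self.frac_timecourse + self.frac_absent
        )
        if total > 1:
            raise ConfigError(f"planted fractions sum to {total:.3f} > 1")
        if self.effect_size <= 0 or self.timecourse_step <= 0 or self.cold_effect <= 0:
            raise ConfigError("effect sizes must be positive")
        if self.d0 <= 0 or self.s0sq <= 0:
            raise ConfigError("variance prior requires d0 > 0 and s0sq > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated data set."""

    predominant: dict = field(default_factory=dict)   # gene -> (class, log2 effect)
    timecourse: dict = field(default_factory=dict)    # gene -> (tissue, dir, offsets)
    cold: dict = field(default_factory=dict)          # gene -> (stage, dir, effect)
    absent: set = field(default_factory=set)
    variance_prior: tuple = (4.0, 0.05)
    modules: dict = field(default_factory=dict)       # id -> (tf, members, go term)
    motif_targets: dict = field(default_factory=dict) # motif -> gene set
    promoter_group: set = field(default_factory=set)
    baseline: pd.Series | None = None
    sigma2: pd.Series | None = None
    seed: int | None = None

    @property
    def expressed(self) -> set:
        return set(self.baseline.index) - self.absent if self.baseline is not None else set()


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _draw_variances(rng, n, d0, s0sq):
    # scaled inverse-chi-square: d0*s0sq / chi2(d0)
    return d0 * s0sq / rng.chisquare(d0, size=n)


def _assign_truth(cfg: SimulationConfig, rng, genes) -> SyntheticTruth:
    truth = SyntheticTruth(variance_prior=(cfg.d0, cfg.s0sq))
    order = list(rng.permutation(genes))
    n = len(order)

    def take(k):
        nonlocal order
        got, order = order[:k], order[k:]
        return got

    for g in take(int(round(cfg.frac_embryo * n))):
        truth.predominant[g] = ("embryo", cfg.effect_size)
    for g in take(int(round(cfg.frac_endosperm * n))):
        truth.predominant[g] = ("endosperm", cfg.effect_size)
    for g in take(int(round(cfg.frac_both * n))):
        truth.predominant[g] = ("both", cfg.effect_size)
    for tissue, stages in (("embryo", cfg.embryo_stages),
                           ("endosperm", cfg.endosperm_stages)):
        k = len(stages)
        centered = np.arange(k) - (k - 1) / 2.0
        n_tc = int(round(cfg.frac_timecourse * n))
        for i, g in enumerate(take(n_tc)):
            direction = "up" if i < (n_tc + 1) // 2 else "down"
            sgn = 1.0 if direction == "up" else -1.0
            offsets = tuple(sgn * cfg.timecourse_step * centered)
            truth.timecourse[g] = (tissue, direction, offsets)
    truth.absent = set(take(int(round(cfg.frac_absent * n))))
    return truth


def _sample_layout(cfg: SimulationConfig):
    """Ordered (sample_id, tissue, stage, treatment) rows of the
    development compendium."""
    rows = []
    for t in cfg.reference_tissues:
        stage = 0 if t == "ovary" else None
        for r in range(1, cfg.n_replicates + 1):
            rows.append((f"{t}_r{r}", t, stage, "control", r))
    for t, stages in (("embryo", cfg.embryo_stages), ("endosperm", cfg.endosperm_stages)):
        for s in stages:
            for r in range(1, cfg.n_replicates + 1):
                rows.append((f"{t}_{s}daf_r{r}", t, s, "control", r))
    return rows


def _noise(rng, cfg: SimulationConfig, sigma, shape):
    z = rng.standard_normal(size=shape)
    if cfg.heavy_tail_fraction > 0:
        mask = rng.random(size=shape) < cfg.heavy_tail_fraction
        z = np.where(mask, rng.standard_t(3, size=shape), z)
    return z * np.asarray(sigma)[:, None]


def simulate_compendium(
    cfg: SimulationConfig,
    seed: int,
    truth: SyntheticTruth | None = None,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Simulate the 12-group x 2-replicate development compendium.

    Passing an existing ``truth`` replants the same classes, baselines and
    gene variances with fresh noise — two calls with different seeds then
    emulate an independent replication of the same biology (the
    cross-cultivar comparison setting).
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(cfg.n_genes)
    if truth is None:
        truth = _assign_truth(cfg, rng, genes)
        truth.seed = seed
        lo, hi = cfg.baseline_range
        baseline = rng.uniform(lo, hi, size=cfg.n_genes)
        absent_idx = np.array([g in truth.absent for g in genes])
        baseline[absent_idx] = np.minimum(
            rng.normal(cfg.absent_mean, cfg.absent_sd, size=int(absent_idx.sum())),
            cfg.detection_floor - 1.0,
        )
        truth.baseline = pd.Series(baseline, index=genes)
        truth.sigma2 = pd.Series(
            _draw_variances(rng, cfg.n_genes, cfg.d0, cfg.s0sq), index=genes
        )
    layout = _sample_layout(cfg)
    sample_ids = [r[0] for r in layout]
    mean = np.tile(truth.baseline.to_numpy()[:, None], (1, len(layout)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    stage_index = {
        "embryo": {s: i for i, s in enumerate(cfg.embryo_stages)},
        "endosperm": {s: i for i, s in enumerate(cfg.endosperm_stages)},
    }
    for j, (_sid, tissue, stage, _trt, _rep) in enumerate(layout):
        for g, (cls, eff) in truth.predominant.items():
            if cls == tissue or (cls == "both" and tissue in ("embryo", "endosperm")):
                mean[gene_pos[g], j] += eff
        if tissue in stage_index:
            for g, (t, _d, offsets) in truth.timecourse.items():
                if t == tissue:
                    mean[gene_pos[g], j] += offsets[stage_index[tissue][stage]]
    sigma = np.sqrt(truth.sigma2.to_numpy())
    values = mean + _noise(rng, cfg, sigma, mean.shape)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    design = SampleDesign(
        pd.DataFrame(
            {
                "tissue": [r[1] for r in layout],
                "stage": [r[2] for r in layout],
                "replicate": [r[4] for r in layout],
                "treatment": [r[3] for r in layout],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, design, truth


def simulate_cold_experiment(
    cfg: SimulationConfig,
    seed: int,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth, list]:
    """Simulate the paired cold-treatment experiment on whole seeds.

    Two stages (default 4 and 10 DAF), cold-treated vs control, two
    replicates each (8 arrays).  Cold effects are additive log2 offsets on
    the treated arrays of the planted stage only; the down-regulated class
    outnumbers the up-regulated one (the early-stage asymmetry).  Returns
    (matrix, design, truth, pairs) where pairs is the
    [(treated ids, control ids), ...] list for ``call_cold_regulated``.
    """
    rng = np.random.default_rng(seed)
    genes = _gene_ids(cfg.n_genes)
    truth = SyntheticTruth(variance_prior=(cfg.d0, cfg.s0sq), seed=seed)
    n_planted = (cfg.n_cold_down + cfg.n_cold_up) * len(cfg.cold_stages)
    if n_planted > cfg.n_genes:
        raise ConfigError("more planted cold genes than genes")
    order = list(rng.permutation(genes))
    for stage in cfg.cold_stages:
        for g in order[:cfg.n_cold_down]:
            truth.cold[g] = (stage, "down", cfg.cold_effect)
        order = order[cfg.n_cold_down:]
        for g in order[:cfg.n_cold_up]:
            truth.cold[g] = (stage, "up", cfg.cold_effect)
        order = order[cfg.n_cold_up:]
    lo, hi = cfg.baseline_range
    truth.baseline = pd.Series(rng.uniform(lo, hi, size=cfg.n_genes), index=genes)
    truth.sigma2 = pd.Series(
        _draw_variances(rng, cfg.n_genes, cfg.d0, cfg.s0sq), index=genes
    )
    layout = []
    for s in cfg.cold_stages:
        for trt in ("cold", "control"):
            for r in range(1, cfg.n_replicates + 1):
                layout.append((f"seed_{s}daf_{trt}_r{r}", "seed", s, trt, r))
    sample_ids = [r[0] for r in layout]
    mean = np.tile(truth.baseline.to_numpy()[:, None], (1, len(layout)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, (_sid, _t, stage, trt, _rep) in enumerate(layout):
        if trt != "cold":
            continue
        for g, (s, direction, eff) in truth.cold.items():
            if s == stage:
                mean[gene_pos[g], j] += eff if direction == "up" else -eff
    sigma = np.sqrt(truth.sigma2.to_numpy())
    values = mean + _noise(rng, cfg, sigma, mean.shape)
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    design = SampleDesign(
        pd.DataFrame(
            {
                "tissue": [r[1] for r in layout],
                "stage": [r[2] for r in layout],
                "replicate": [r[4] for r in layout],
                "treatment": [r[3] for r in layout],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    pairs = []
    for s in cfg.cold_stages:
        treated = [sid for sid, _, st, trt, _ in layout if st == s and trt == "cold"]
        control = [sid for sid, _, st, trt, _ in layout if st == s and trt == "control"]
        pairs.append((treated, control))
    return matrix, design, truth, pairs


# ---------------------------------------------------------------------------
# Co-expression collection
# ---------------------------------------------------------------------------

def simulate_coexpression_collection(
    n_arrays: int,
    modules: list[dict],
    seed: int,
    n_genes: int = 2000,
    expected_pcc: float = 0.8,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Many-array compendium with TF-centered co-expression modules.

    Each module dict names ``tf`` (gene id), ``n_members`` and ``go_term``.
    The TF profile is Normal(mu, 1) across arrays; each member is
    baseline + r*(TF - mu) + Normal(0, 1 - r^2) so its expected Pearson
    correlation with the TF is ``expected_pcc``; all other genes are
    independent unit-variance noise.
    """
    if not (0.0 <= expected_pcc < 1.0):
        raise ConfigError("expected_pcc must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    pool = [g for g in genes]
    used: set = set()
    truth = SyntheticTruth(seed=seed)
    for mod in modules:
        if mod["n_members"] >= n_genes:
            raise ConfigError("module member count must be < n_genes")
        if mod["tf"] not in genes:
            raise ConfigError(f"module TF {mod['tf']} not in gene universe")
        used.add(mod["tf"])
    free = [g for g in pool if g not in used]
    rng.shuffle(free)
    values = np.empty((n_genes, n_arrays))
    baseline = rng.uniform(7.0, 11.0, size=n_genes)
    pos = {g: i for i, g in enumerate(genes)}
    # start everything as independent noise
    values[:] = baseline[:, None] + rng.standard_normal((n_genes, n_arrays))
    r = expected_pcc
    resid_sd = np.sqrt(1.0 - r * r)
    for mid, mod in enumerate(modules):
        tf = mod["tf"]
        members = free[: mod["n_members"]]
        free = free[mod["n_members"]:]
        tf_centered = values[pos[tf]] - baseline[pos[tf]]
        for g in members:
            values[pos[g]] = (
                baseline[pos[g]]
                + r * tf_centered
                + resid_sd * rng.standard_normal(n_arrays)
            )
        truth.modules[f"module_{mid + 1}"] = (tf, frozenset(members), mod["go_term"])
    sample_ids = [f"array_{i:03d}" for i in range(1, n_arrays + 1)]
    matrix = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    return matrix, truth


def category_map_from_modules(
    truth: SyntheticTruth,
    background,
    n_decoy_terms: int = 10,
    decoy_size: int = 50,
    seed: int = 0,
) -> CategoryMap:
    """GO-style category map: one term per planted module plus random decoy
    terms drawn uniformly from the background."""
    rng = np.random.default_rng(seed)
    background = sorted(set(background))
    labels, sets = {}, {}
    for mid, (tf, members, term) in truth.modules.items():
        labels[term] = f"{term} ({mid})"
        sets[term] = frozenset(members) & set(background)
    for i in range(n_decoy_terms):
        term = f"GO:9{i:06d}"
        labels[term] = f"decoy term {i}"
        sets[term] = frozenset(rng.choice(background, size=decoy_size, replace=False))
    return CategoryMap(term_labels=labels, term_genes=sets, background=frozenset(background))


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.array(list("ACGT")), size=length, p=p)


def _realize_iupac(rng, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC_CODES[ch])) for ch in pattern)


def simulate_promoter_sequences(
    n_genes: int,
    length: int,
    motifs: MotifLibrary,
    target_fraction_in_group: float,
    background_fraction: float,
    seed: int,
    group_size: int | None = None,
    planted_motif: str | None = None,
    gc: float = 0.5,
) -> tuple[dict[str, str], SyntheticTruth]:
    """In-memory promoter set with a planted motif at known frequencies.

    i.i.d. background nucleotides at the stated GC; each designated target
    promoter receives exactly one planted exact instance of the motif (a
    concrete realization of its IUPAC pattern) at a uniform random position
    and strand.  Group genes are targets with probability
    ``target_fraction_in_group``; the rest with ``background_fraction``.
    Returns (gene -> 5'->3' promoter sequence, truth).
    """
    if not (0.0 <= background_fraction <= target_fraction_in_group <= 1.0):
        raise ConfigError("need 0 <= background_fraction <= target_fraction <= 1")
    planted_motif = planted_motif or next(iter(motifs.patterns))
    pattern = motifs.patterns[planted_motif]
    if len(pattern) > length:
        raise ConfigError("motif longer than promoter")
    group_size = n_genes // 10 if group_size is None else group_size
    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)
    group = set(genes[:group_size])
    truth = SyntheticTruth(seed=seed)
    truth.promoter_group = group
    targets: set = set()
    seqs: dict[str, str] = {}
    for g in genes:
        prom = _random_seq(rng, length, gc)
        frac = target_fraction_in_group if g in group else background_fraction
        if rng.random() < frac:
            inst = _realize_iupac(rng, pattern)
            if rng.random() < 0.5:
                inst = reverse_complement(inst)
            posn = int(rng.integers(0, length - len(inst) + 1))
            prom[posn : posn + len(inst)] = list(inst)
            targets.add(g)
        seqs[g] = "".join(prom)
    truth.motif_targets[planted_motif] = targets
    return seqs, truth


def simulate_promoters(
    n_genes: int,
    length: int,
    motifs: MotifLibrary,
    target_fraction_in_group: float,
    background_fraction: float,
    seed: int,
    fasta_path,
    gff3_path,
    group_size: int | None = None,
    planted_motif: str | None = None,
    gc: float = 0.5,
    gene_length: int = 300,
) -> SyntheticTruth:
    """Emit a synthetic genome FASTA + GFF3 whose promoters carry a planted
    motif at known frequencies.

    One contig per gene, random strand; promoter content as in
    ``simulate_promoter_sequences``.  Gene bodies start with ATG so the
    promoter window is anchored at the translation start.
    """
    seqs, truth = simulate_promoter_sequences(
        n_genes, length, motifs, target_fraction_in_group, background_fraction,
        seed, group_size=group_size, planted_motif=planted_motif, gc=gc,
    )
    rng = np.random.default_rng(seed + 1)
    fa_lines, gff_lines = [], ["##gff-version 3"]
    for g, prom in seqs.items():
        body = "ATG" + "".join(_random_seq(rng, gene_length - 3, gc))
        strand = "+" if rng.random() < 0.5 else "-"
        contig = f"ctg_{g}"
        if strand == "+":
            seq = prom + body
            gstart, gend = length + 1, length + gene_length
        else:
            seq = reverse_complement(body) + reverse_complement(prom)
            gstart, gend = 1, gene_length
        fa_lines.append(f">{contig}")
        for i in range(0, len(seq), 70):
            fa_lines.append(seq[i : i + 70])
        gff_lines.append(
            f"{contig}\tseedtx\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={g}"
        )
        gff_lines.append(
            f"{contig}\tseedtx\tCDS\t{gstart}\t{gend}\t.\t{strand}\t0\t"
            f"ID={g}.cds;Parent={g}"
        )
    with open(fasta_path, "w") as fh:
        fh.write("\n".join(fa_lines) + "\n")
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    return truth


def default_motif_library() -> MotifLibrary:
    """A small PLACE-style library: GCN4/prolamin-box/ACGT-core style
    elements plus degenerate decoys (synthetic stand-ins, not the curated
    database entries).

    Decoy patterns deliberately share no sequence core with the GCN4-like
    element (on either strand): a decoy overlapping the planted element gets
    genuinely co-planted at insertion junctions, which would conflate library
    redundancy with a specificity failure of the statistics.
    """
    return MotifLibrary(
        patterns={
            "GCN4_like": "TGAGTCA",
            "PROLAMIN_BOX": "TGTAAAG",
            "ACGT_CORE": "TACGTA",
            "RY_REPEAT": "CATGCA",
            "AACA_CORE": "AACAAAC",
            "MYB_PBOX": "CCWACC",
            "EBOX_like": "CANNTG",
            "GATA_deg": "WGATAR",
        },
        descriptions={
            "GCN4_like": "bZIP target core (synthetic)",
            "PROLAMIN_BOX": "endosperm box P-site (synthetic)",
        },
    )
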