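"""Configuration-driven orchestration of the full seed-transcriptome analysis.

A run is reproducible from (config, seed) alone: every output TSV is written
with a fixed float format, and the JSON manifest records the config hash,
seed, per-class gene counts and estimated variance-prior hyperparameters.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, enrichment, preprocess
from .diffexpr import Thresholds
from .io_formats import (
    ExpressionMatrix,
    SampleDesign,
    read_expression_matrix,
    read_gene_sets,
    read_sample_design,
    write_expression_matrix,
)

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    """Declarative description of one analysis run."""

    matrix: str
    design: str
    out_dir: str
    gene_sets: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    detection_mode: str = "absolute"
    detection_threshold: float = 6.0
    detection_q: float = 0.30
    normalize: bool = True
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate_paths(self) -> None:
        for name in ("matrix", "design"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {name}: {p} does not exist")
        if self.gene_sets and not Path(self.gene_sets).exists():
            raise FileNotFoundError(f"config gene_sets: {self.gene_sets} does not exist")


def _write_tsv(df: pd.DataFrame, path, index_label="gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label, float_format=FLOAT_FMT)


def _detection(cfg: PipelineConfig, m: ExpressionMatrix) -> pd.DataFrame:
    return preprocess.detection_call(
        m, mode=cfg.detection_mode, threshold=cfg.detection_threshold, q=cfg.detection_q
    )


class StageError(RuntimeError):
    """An analysis stage failed; partial outputs have been removed."""


def _staged(out_dir: Path, created_dir: bool):
    """Context: on error, remove partial outputs (the whole out_dir if this
    run created it, else the files this run wrote)."""
    class _Ctx:
        def __init__(self):
            self.stage = "setup"

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                if created_dir:
                    shutil.rmtree(out_dir, ignore_errors=True)
                raise StageError(f"stage {self.stage!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_development_analysis(cfg: PipelineConfig) -> dict:
    """Preprocess -> predominance + time-course -> enrichment; returns the
    manifest dict (also written to ``out_dir/manifest.json``)."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.digest(), "seed": cfg.seed}
    with _staged(out, created) as ctx:
        ctx.stage = "read"
        m = read_expression_matrix(cfg.matrix)
        design = read_sample_design(cfg.design)
        design.validate_against(m)

        ctx.stage = "qc"
        qc = preprocess.replicate_qc(m, design)
        _write_tsv(qc.set_index("sample_1"), out / "replicate_qc.tsv", "sample_1")

        ctx.stage = "normalize"
        if cfg.normalize:
            m = preprocess.quantile_normalize(m)
        write_expression_matrix(m, out / "normalized_matrix.tsv", FLOAT_FMT)

        ctx.stage = "detection"
        calls = _detection(cfg, m)
        calls.replace({True: "P", False: "A"}).to_csv(
            out / "detection_calls.tsv", sep="\t", index_label="gene_id"
        )
        groups = design.groups()
        seed_groups = [k for k in groups if k[0] in ("embryo", "endosperm")]
        detected = preprocess.expressed_genes(calls, design, list(groups))
        in_seed = preprocess.expressed_genes(calls, design, seed_groups)
        em_groups = [k for k in groups if k[0] == "embryo"]
        en_groups = [k for k in groups if k[0] == "endosperm"]
        counts = {
            "detected": len(detected),
            "expressed_in_seed": len(in_seed),
            "expressed_in_embryo": len(preprocess.expressed_genes(calls, design, em_groups)),
            "expressed_in_endosperm": len(preprocess.expressed_genes(calls, design, en_groups)),
        }
        counts["seed_expressed_percent"] = preprocess.percent_expressed(
            counts["expressed_in_seed"], counts["detected"]
        ) if counts["detected"] else 0
        manifest["expressed_counts"] = counts

        ctx.stage = "filter"
        m = preprocess.filter_low_expression(m, calls, mode="all-absent")

        ctx.stage = "predominance"
        ref = design.samples_for(tissue=("root", "leaf", "seedling", "ovary"))
        em = design.samples_for(tissue="embryo")
        en = design.samples_for(tissue="endosperm")
        res_em = diffexpr.moderate(diffexpr.fit_contrast(m, design, em, ref))
        res_en = diffexpr.moderate(diffexpr.fit_contrast(m, design, en, ref))
        _write_tsv(res_em, out / "contrast_embryo.tsv")
        _write_tsv(res_en, out / "contrast_endosperm.tsv")
        classes = diffexpr.call_predominant(res_em, res_en, cfg.thresholds)
        classes.to_frame().to_csv(out / "predominance.tsv", sep="\t", index_label="gene_id")
        cls_counts = classes.value_counts().to_dict()
        manifest["predominance_counts"] = {
            k: int(cls_counts.get(k, 0)) for k in ("embryo", "endosperm", "both", "none")
        }
        manifest["hyperparameters"] = {
            "embryo": {"d0": res_em.attrs["d0"], "s0sq": res_em.attrs["s0sq"]},
            "endosperm": {"d0": res_en.attrs["d0"], "s0sq": res_en.attrs["s0sq"]},
        }

        ctx.stage = "timecourse"
        tc_dirs = {}
        tc_counts = {}
        for tissue in ("embryo", "endosperm"):
            res = diffexpr.anova_timecourse(m, design, tissue)
            _write_tsv(res, out / f"timecourse_{tissue}.tsv")
            dirs = diffexpr.timecourse_regulated(res, cfg.thresholds)
            tc_dirs[tissue] = dirs
            tc_counts[tissue] = {
                "regulated": int(len(dirs)),
                "up": int((dirs == "up").sum()),
                "down": int((dirs == "down").sum()),
            }
        manifest["timecourse_counts"] = tc_counts

        ctx.stage = "enrichment"
        if cfg.gene_sets:
            cats = read_gene_sets(cfg.gene_sets, background=m.gene_ids)
            named_sets = {
                "Em": set(classes.index[classes == "embryo"]),
                "En": set(classes.index[classes == "endosperm"]),
                "Both": set(classes.index[classes == "both"]),
                "Em_T": set(tc_dirs["embryo"].index),
                "En_T": set(tc_dirs["endosperm"].index),
            }
            results = {}
            for name, genes in named_sets.items():
                if not genes:
                    continue
                res = enrichment.chisq_enrichment(genes, cats)
                _write_tsv(res, out / f"enrichment_{name}.tsv", "term")
                results[name] = res
            if results:
                mat = enrichment.enrichment_matrix(results)
                enrichment.write_enrichment_matrix(mat, out / "enrichment_matrix.tsv")

        ctx.stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_cold_analysis(cfg: PipelineConfig) -> dict:
    """Per-pair cold-vs-control differential expression with up/down counts
    and a cross-pair trend-concordance report."""
    cfg.validate_paths()
    out = Path(cfg.out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.digest(), "seed": cfg.seed}
    with _staged(out, created) as ctx:
        ctx.stage = "read"
        m = read_expression_matrix(cfg.matrix)
        design = read_sample_design(cfg.design)
        design.validate_against(m)

        ctx.stage = "pairs"
        groups = design.groups()
        stages = sorted({k[1] for k in groups if k[2] == "cold"})
        pairs, pair_names = [], []
        for s in stages:
            treated = design.samples_for(stage=s, treatment="cold")
            control = design.samples_for(stage=s, treatment="control")
            pairs.append((treated, control))
            pair_names.append(f"{s}daf")

        ctx.stage = "contrasts"
        results = diffexpr.call_cold_regulated(m, design, pairs, cfg.thresholds)
        dir_maps = []
        count_rows = []
        for name, res in zip(pair_names, results):
            _write_tsv(res["result"], out / f"cold_contrast_{name}.tsv")
            dirs = pd.Series(
                {**{g: "up" for g in res["up"]}, **{g: "down" for g in res["down"]}}
            )
            dirs.sort_index().to_frame("direction").to_csv(
                out / f"cold_regulated_{name}.tsv", sep="\t", index_label="gene_id"
            )
            dir_maps.append(dirs)
            count_rows.append(
                {"pair": name, "up": len(res["up"]), "down": len(res["down"])}
            )
        counts = pd.DataFrame(count_rows).set_index("pair")
        counts.to_csv(out / "cold_counts.tsv", sep="\t")
        manifest["cold_counts"] = {
            r["pair"]: {"up": r["up"], "down": r["down"]} for r in count_rows
        }

        ctx.stage = "concordance"
        if len(dir_maps) >= 2:
            common, n_common, frac = diffexpr.trend_concordance(dir_maps[0], dir_maps[1])
            manifest["concordance"] = {
                "pairs": f"{pair_names[0]} vs {pair_names[1]}",
                "n_common": n_common,
                "fraction_same_trend": frac,
            }
            pd.DataFrame(
                {
                    "gene_id": common,
                    pair_names[0]: [dir_maps[0][g] for g in common],
                    pair_names[1]: [dir_maps[1][g] for g in common],
                }
            ).to_csv(out / "cold_concordance.tsv", sep="\t", index=False)

        ctx.stage = "manifest"
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
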