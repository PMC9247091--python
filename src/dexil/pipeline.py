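"""End-to-end pipeline: simulate/load -> DE -> reversal -> signature -> enrich -> phenotype.

Every number written by the pipeline is produced by the corresponding module
function; this layer only sequences stages, writes TSVs, and records a run
manifest with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import decore, enrich, io, phenoassoc, scoring, simdata

log = logging.getLogger("dexil")

STAGES = ("simulate", "de", "reversal", "signature", "enrich", "pheno")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; CLI flags override file values override defaults."""

    counts: str | None = None
    samples: str | None = None
    gmt: str | None = None
    outdir: str = "dexil_out"
    padj: float = 0.05
    fc_threshold: float = 1.5
    reversal_cutoff: float = 50.0
    fdr_q: float = 0.05
    pairing: bool = True
    interaction: bool = True
    rank_metric: str = "wald_stat"
    eligibility_padj_filter: bool = False
    signature_size: int = 10
    n_perm: int = 1000
    seed: int = 0
    skip: list = field(default_factory=list)
    sim: dict = field(default_factory=dict)  # SimConfig overrides when simulating

    def validate(self) -> None:
        if not (0 < self.padj < 1) or not (0 < self.fdr_q < 1):
            raise ValueError("padj and fdr_q thresholds must lie in (0, 1)")
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must be > 1")
        if not (0 <= self.reversal_cutoff <= 100):
            raise ValueError("reversal cutoff must lie in [0, 100]")
        unknown = set(self.skip) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages in skip: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all non-skipped stages; returns the manifest (also written last)."""
    from . import __version__

    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": {},
        "warnings": [],
    }
    out = lambda name: os.path.join(config.outdir, name)

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    def emit(name: str, df: pd.DataFrame, index: bool = False) -> None:
        path = out(name)
        io.write_tsv(df, path, index=index)
        manifest["outputs"][name] = _sha256(path)

    try:
        # --- inputs ----------------------------------------------------
        truth = None
        if "simulate" not in config.skip and config.counts is None:
            cfg = simdata.SimConfig(**{**config.sim, "seed": config.seed})
            matrix, truth = simdata.generate_counts(cfg)
            simdata.write_fixture(matrix, truth, config.outdir)
            for name in (simdata.COUNTS_FILE, simdata.SAMPLES_FILE, simdata.TRUTH_FILE):
                manifest["outputs"][name] = _sha256(out(name))
            record("simulate", n_genes=cfg.n_genes, n_samples=len(matrix.sample_ids))
        else:
            matrix = io.read_count_matrix(config.counts, config.samples)
            manifest["inputs"] = {
                config.counts: _sha256(config.counts),
                config.samples: _sha256(config.samples),
            }
            record("load", n_genes=len(matrix.gene_ids), n_samples=len(matrix.sample_ids))

        size_factors = decore.estimate_size_factors(matrix)

        # --- differential expression -----------------------------------
        de = None
        if "de" not in config.skip:
            design = decore.DesignSpec(
                pairing=config.pairing, interaction=config.interaction
            )
            de = decore.run_de(matrix, design, size_factors=size_factors)
            emit("de_results.tsv", de)
            n_sig = {
                c: int((g["padj"] < config.padj).sum())
                for c, g in de.groupby("contrast")
            }
            record("de", n_genes=de["gene_id"].nunique(), significant=n_sig)

        # --- reversal scoring -------------------------------------------
        if "reversal" not in config.skip and de is not None:
            rev = scoring.compute_reversal_scores(
                de[de["contrast"] == "il17_vs_ctrl"],
                de[de["contrast"] == "combo_vs_ctrl"],
                fc_threshold=config.fc_threshold,
                cutoff=config.reversal_cutoff,
                padj_filter=config.padj if config.eligibility_padj_filter else None,
            )
            emit("reversal_scores.tsv", rev)
            summ = scoring.summarize_classification(rev)
            record("reversal", **dataclasses.asdict(summ))

        # --- signature z-scores -----------------------------------------
        if "signature" not in config.skip and de is not None:
            z, _params = scoring.zscore_matrix(matrix, size_factors)
            rows = []
            for contrast, signame in (
                ("il17_vs_ctrl", "il17_top"),
                ("dex_vs_ctrl", "dex_top"),
            ):
                sub = de[de["contrast"] == contrast]
                genes = scoring.top_genes(sub, config.signature_size)
                res = scoring.signature_score(z, genes, matrix.samples)
                for sid, row in res["per_sample"].iterrows():
                    rows.append(
                        {
                            "sample_id": sid,
                            "group": row["group"],
                            "signature_name": signame,
                            "score": row["score"],
                        }
                    )
            emit("signature_scores.tsv", pd.DataFrame(rows))
            record("signature", n_signatures=2)

        # --- enrichment --------------------------------------------------
        if "enrich" not in config.skip and de is not None:
            if config.gmt is not None:
                coll = enrich.read_gmt(config.gmt)
                manifest["inputs"][config.gmt] = _sha256(config.gmt)
            elif truth is not None:
                coll = truth_gene_sets(truth)
            else:
                coll = None
                manifest["warnings"].append("enrich: no GMT supplied, stage skipped")
            if coll is not None and len(coll):
                ranked = enrich.rank_genes(
                    de[de["contrast"] == "il17_vs_ctrl"], config.rank_metric
                )
                res = enrich.permutation_test(
                    ranked, coll, n_perm=config.n_perm, seed=config.seed
                )
                emit("enrichment.tsv", res)
                record(
                    "enrich",
                    n_sets=len(res),
                    significant=int((res["fdr_q"] < config.fdr_q).sum()),
                )

        # --- phenotype association ---------------------------------------
        if "pheno" not in config.skip:
            if matrix.samples["permeability"].notna().all():
                assoc = phenoassoc.associate_phenotype(
                    matrix,
                    pairing=config.pairing,
                    de_il17=de[de["contrast"] == "il17_vs_ctrl"] if de is not None else None,
                    padj_threshold=config.padj,
                )
                emit("assoc_results.tsv", assoc)
                record(
                    "pheno",
                    n_significant=int(assoc["significant"].sum()),
                    n_up=int((assoc["significant"] & (assoc["direction"] == "up")).sum()),
                    n_down=int((assoc["significant"] & (assoc["direction"] == "down")).sum()),
                )
            else:
                manifest["warnings"].append("pheno: permeability missing, stage skipped")
    finally:
        for stage in config.skip:
            manifest["stages"].setdefault(stage, {"skipped": True})
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def truth_gene_sets(truth: simdata.SimTruth, min_size: int = 10) -> enrich.GeneSetCollection:
    """Gene sets from planted classes (plus the cilia set) for self-contained runs."""
    coll = enrich.GeneSetCollection()
    for cls in simdata.GENE_CLASSES:
        if cls == "null":
            continue
        genes = truth.genes_in_class(cls).tolist()
        if len(genes) >= min_size:
            coll.add(f"planted_{cls}", f"planted {cls} genes", genes)
    cilia = truth.table.loc[truth.table["cilia_member"], "gene_id"].tolist()
    if len(cilia) >= min_size:
        coll.add("planted_cilia", "phenotype-coupled genes", cilia)
    return coll
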