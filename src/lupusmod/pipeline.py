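"""End-to-end orchestration: simulate/ingest -> score -> call -> frequencies
-> DE + overlap -> stepwise ORs + edges -> classify -> sex QC.

A run is driven by a :class:`RunConfig`; every stage writes plain TSV/CSV/
JSON artifacts into the output directory, and a run manifest records the
configuration, fanned-out per-stage seeds, and a SHA-256 checksum of every
output file, so a rerun with the same config is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import build_predictor_matrix, or_to_edge, spearman_screen, \
    stepwise_select
from .calling import fit_normal_range, frequency_tests, group_frequencies, \
    pairwise_group_tests, trichotomize
from .classify import cross_validate, stratified_kfold, top_predictors
from .de import moderated_t_test, overlap_test, randomization_control
from .gsva import score_modules
from .io import check_sample_concordance, read_expression, read_metadata, \
    write_expression, write_metadata
from .modules import ModuleCollection, read_gmt, write_gmt
from .qc import sex_discordance_report, sex_module_score
from .simulate import CohortConfig, default_effect_table, default_modules, \
    generate_expression, generate_metadata

log = logging.getLogger("lupusmod")

#: documented seed fan-out: child seed = base seed + offset, per stage
SEED_OFFSETS = {
    "metadata": 1,
    "expression": 2,
    "randomization": 3,
    "folds": 4,
}


@dataclass
class RunConfig:
    """Paths, stage parameters, and the global seed for one pipeline run."""

    out_dir: str
    seed: int = 0
    # either provide all three paths or the cohort is simulated
    expression: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    # simulation sizes (None -> generator defaults)
    n_aa: int | None = None
    n_ea: int | None = None
    n_naa: int | None = None
    n_hc: int | None = None
    n_genes: int = 2000
    # stage parameters
    fdr: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.05
    hl_alpha: float = 0.05
    outcomes: list = field(default_factory=list)  # empty -> all modules, +1 calls
    classify_pos: str = "AA"
    classify_neg: str = "EA"
    k_folds: int = 10
    l1_weight: float = 0.01
    l2_weight: float = 0.01

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2 ** 31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest (also written to
    ``manifest.json``). A stage failure halts the run with the manifest
    recording the stages completed so far."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "lupusmod", "version": __version__,
        "seed": config.seed,
        "stage_seeds": {k: config.stage_seed(k) for k in SEED_OFFSETS},
        "config": {k: v for k, v in vars(config).items()},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [], "checksums": {},
    }

    def record(stage: str, *paths: Path):
        manifest["stages"].append(stage)
        for p in paths:
            manifest["checksums"][p.name] = _sha256(p)
        _write_manifest(out, manifest)
        log.info("stage %s complete (%d artifact(s))", stage, len(paths))

    try:
        # -- stage 1: ingest or simulate -----------------------------------
        if config.expression and config.metadata and config.gmt:
            expr = read_expression(config.expression)
            metadata = read_metadata(config.metadata)
            modules = read_gmt(config.gmt)
            check_sample_concordance(expr, metadata)
            record("ingest")
        else:
            cc_kwargs = {k: getattr(config, k) for k in
                         ("n_aa", "n_ea", "n_naa", "n_hc")
                         if getattr(config, k) is not None}
            cohort = CohortConfig(seed=config.stage_seed("metadata"), **cc_kwargs)
            metadata = generate_metadata(cohort)
            modules = default_modules()
            expr = generate_expression(
                metadata, modules, default_effect_table(),
                n_genes=config.n_genes, seed=config.stage_seed("expression"),
            )
            ep, mp, gp = out / "expression.tsv", out / "metadata.csv", \
                out / "modules.gmt"
            write_expression(expr, ep)
            write_metadata(metadata, mp)
            write_gmt(modules, gp)
            log.info("simulated cohort with seed %d", cohort.seed)
            record("simulate", ep, mp, gp)

        patients = metadata.index[metadata["is_control"] == 0]
        controls = metadata.index[metadata["is_control"] == 1]

        # -- stage 2: enrichment scores ------------------------------------
        scores = score_modules(expr, modules)
        sp = out / "scores.tsv"
        scores.to_csv(sp, sep="\t", index_label="module")
        record("score", sp)

        # -- stage 3: HC-referenced calls and frequencies ------------------
        nr = fit_normal_range(scores, list(controls))
        calls = trichotomize(scores, nr)
        cp = out / "calls.tsv"
        calls[patients].to_csv(cp, sep="\t", index_label="module")
        nrp = out / "normal_range.csv"
        pd.DataFrame({"mean": nr.mean, "sd": nr.sd}).to_csv(
            nrp, index_label="module")
        grouping = metadata.loc[patients, "ancestry"]
        freq = group_frequencies(calls[patients], grouping)
        fp = out / "call_frequencies.csv"
        freq.to_csv(fp, index=False)
        ft = pd.concat([frequency_tests(freq, "up"),
                        frequency_tests(freq, "down")])
        ftp = out / "frequency_fisher.csv"
        ft.to_csv(ftp, index=False)
        wt = pairwise_group_tests(scores[patients], grouping, adjust="sidak")
        wtp = out / "score_welch.csv"
        wt.to_csv(wtp, index=False)
        record("call", cp, nrp, fp, ftp, wtp)

        # -- stage 4: DE, randomization null, overlap ----------------------
        a = [s for s in patients if metadata.loc[s, "ancestry"] ==
             config.classify_pos]
        b = [s for s in patients if metadata.loc[s, "ancestry"] ==
             config.classify_neg]
        de = moderated_t_test(expr, a, b)
        dep = out / f"de_{config.classify_pos}_vs_{config.classify_neg}.csv"
        de.to_csv(dep, index_label="gene")
        null_count = randomization_control(
            expr, b, config.stage_seed("randomization"), fdr=config.fdr)
        deg_up = list(de[(de["q"] < config.fdr) & (de["log2fc"] > 0)].index)
        planted = sorted(
            set(modules["plasma_cell"].genes) | set(modules["ig_chains"].genes)
            | set(modules["b_cell"].genes)
        ) if "plasma_cell" in modules else []
        ov = overlap_test(deg_up, [g for g in planted if g in de.index],
                          list(de.index)) if planted else None
        op = out / "de_overlap.json"
        with open(op, "w") as fh:
            json.dump({
                "randomized_split_deg_count": null_count,
                "deg_up_count": len(deg_up),
                "overlap_with_b_cell_axis": vars(ov) if ov else None,
            }, fh, indent=2, default=str)
        record("de", dep, op)

        # -- stage 5: stepwise ORs + edges ---------------------------------
        X = build_predictor_matrix(metadata.loc[patients])
        _, drops = spearman_screen(X)
        X = X.drop(columns=drops)
        outcomes = config.outcomes or list(calls.index)
        results, edges = [], []
        for module in outcomes:
            y = (calls.loc[module, patients] == 1).astype(int)
            if y.nunique() < 2:
                log.warning("outcome %s is constant; skipped", module)
                continue
            res = stepwise_select(y, X, config.p_enter, config.p_remove,
                                  hl_alpha=config.hl_alpha, outcome=module)
            results.append(res.to_dict())
            if not res.discarded:
                for pred, row in res.table.iterrows():
                    edges.append(vars(or_to_edge(pred, module, row["or"])))
        swp = out / "stepwise.json"
        with open(swp, "w") as fh:
            json.dump({"dropped_collinear": drops, "models": results}, fh,
                      indent=2, default=float)
        edp = out / "circos_edges.csv"
        pd.DataFrame(edges).to_csv(edp, index=False)
        record("assoc", swp, edp)

        # -- stage 6: ancestry classification ------------------------------
        feat = [g for g in modules.gene_union() if g in expr.index]
        Xc = expr.loc[feat, a + b].T
        yc = pd.Series([1] * len(a) + [0] * len(b), index=a + b)
        k = min(config.k_folds, min(len(a), len(b)))
        folds = stratified_kfold(yc, k=k, seed=config.stage_seed("folds"))
        report = cross_validate(Xc, yc, folds, l1_weight=config.l1_weight,
                                l2_weight=config.l2_weight)
        clp = out / "classifier_report.json"
        with open(clp, "w") as fh:
            doc = report.to_dict()
            doc["top_predictors"] = top_predictors(report.final_model, 25) \
                .to_dict(orient="records")
            json.dump(doc, fh, indent=2)
        rocp = out / "roc.csv"
        pd.DataFrame({"fpr": report.roc_fpr, "tpr": report.roc_tpr}).to_csv(
            rocp, index=False)
        record("classify", clp, rocp)

        # -- stage 7: sex QC ----------------------------------------------
        sex = sex_discordance_report(sex_module_score(expr), metadata)
        sxp = out / "sex_report.csv"
        sex.to_csv(sxp, index_label="sample_id")
        record("sexcheck", sxp)
    finally:
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
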