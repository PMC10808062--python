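"""End-to-end orchestration: simulate/ingest -> neutral fit -> scoring ->
depth classification -> segmentation -> UCE scan, with a checksummed output
manifest and a frozen copy of the resolved configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from typing import Any

import numpy as np
import pandas as pd

from . import alignment_io, constraint_scan, depth_classify, phylo_core, synthetic_data, uce_scan
from .constraint_scan import HmmParams

log = logging.getLogger("constraintdepth")

__all__ = ["RunConfig", "run_pipeline", "load_config", "save_config"]

_CONFIG_FIELDS: dict[str, type] = {
    "scenario": str, "seed": int, "out_dir": str,
    "alpha": float, "lam": float,
    "expected_length": float, "target_coverage": float, "conserved_scale": float,
    "n_elements": int, "n_planted": int, "element_length": int,
    "planted_rho": float, "missing_rate": float,
    "uce_min_length": int, "uce_missing_tolerance": float,
    "fit_neutral": int,
}


@dataclasses.dataclass
class RunConfig:
    """Flat, typed run configuration; defaults mirror the published settings
    (expected length 45, target coverage 0.3, conserved scale 0.31, 5% FDR)."""

    scenario: str = "planted"
    seed: int = 0
    out_dir: str = "run_out"
    alpha: float = 0.05
    lam: float = 0.5
    expected_length: float = 45.0
    target_coverage: float = 0.3
    conserved_scale: float = 0.31
    n_elements: int = 500
    n_planted: int = 50
    element_length: int = 40
    planted_rho: float = 0.2
    missing_rate: float = 0.0
    uce_min_length: int = 20
    uce_missing_tolerance: float = 0.01
    fit_neutral: int = 1   # 1: refit the neutral model from non-planted columns

    def hmm_params(self) -> HmmParams:
        return HmmParams(self.expected_length, self.target_coverage,
                         self.conserved_scale)


def save_config(config: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(config):
            fh.write(f"{f.name}\t{getattr(config, f.name)}\n")


def load_config(path: str, overrides: dict[str, Any] | None = None) -> RunConfig:
    kv: dict[str, Any] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                key, value = line.rstrip("\n").split("\t")
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: expected 'key<TAB>value'") from exc
            if key not in _CONFIG_FIELDS:
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            kv[key] = _CONFIG_FIELDS[key](value)
    if overrides:
        kv.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**kv)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the planted desk-scale scenario end to end; returns the manifest."""
    if config.scenario != "planted":
        raise ValueError(f"unknown scenario {config.scenario!r}")
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "outputs": [], "stages": {}}

    def emit(stage: str, name: str) -> str:
        path = os.path.join(config.out_dir, name)
        manifest["outputs"].append({"stage": stage, "file": name,
                                    "sha256": _sha256(path)})
        return path

    save_config(config, os.path.join(config.out_dir, "config.resolved.tsv"))
    emit("config", "config.resolved.tsv")

    # ---- simulate ---------------------------------------------------- #
    sim_config, elements, truth_mask = synthetic_data.planted_scenario(
        seed=config.seed, n_elements=config.n_elements,
        n_planted=config.n_planted, element_length=config.element_length,
        rho=config.planted_rho, missing_rate=config.missing_rate)
    cols, truth = synthetic_data.simulate_alignment(sim_config)
    tree = sim_config.tree
    alignment_io.write_maf(cols, os.path.join(config.out_dir, "alignment.maf"))
    emit("simulate", "alignment.maf")
    with open(os.path.join(config.out_dir, "tree.nwk"), "w") as fh:
        fh.write(tree.to_newick() + "\n")
    emit("simulate", "tree.nwk")
    truth.to_csv(os.path.join(config.out_dir, "truth.tsv"), sep="\t", index=False)
    emit("simulate", "truth.tsv")
    log.info("simulate: %d columns, %d elements (%d planted)",
             cols.n_columns, len(elements), int(truth_mask.sum()))

    # ---- neutral model ----------------------------------------------- #
    if config.fit_neutral:
        planted_cols = np.zeros(cols.n_columns, dtype=bool)
        for el in sim_config.planted:
            planted_cols[el.start:el.end] = True
        neutral_codes = cols.codes[:, ~planted_cols]
        fit = phylo_core.fit_neutral_model(neutral_codes, tree,
                                           species=cols.species,
                                           min_columns=min(1000, neutral_codes.shape[1]))
        neutral = fit.model
        log.info("fit-neutral: loglik=%.2f scale=%.4f converged=%s",
                 fit.log_likelihood, fit.branch_scale, fit.converged)
    else:
        fit = None
        neutral = sim_config.model
    phylo_core.write_model(fit if fit is not None else neutral,
                           os.path.join(config.out_dir, "neutral_model.tsv"))
    emit("fit-neutral", "neutral_model.tsv")

    # ---- element-wise scoring per clade ------------------------------ #
    clade_views = {
        "primates": alignment_io.extract_clade_columns(cols, tree, "primates"),
        "mammals": alignment_io.extract_clade_columns(cols, tree, "mammals",
                                                      exclude="primates"),
        "vertebrates": alignment_io.extract_clade_columns(cols, tree, "vertebrates",
                                                          exclude="primates"),
    }
    subtree = {name: tree.subtree(name) for name in clade_views}
    rows = []
    for e in elements:
        row = {"element_id": e.element_id, "start": e.start, "end": e.end}
        for name, view in clade_views.items():
            sub = subtree[name]
            view_sub = view.subset_species([s for s in view.species
                                            if s in sub.tip_index])
            res = constraint_scan.phylop_element(view_sub, sub, neutral, None, e)
            row[f"{name}_p"] = res.p_value
            row[f"{name}_score"] = res.score
            row[f"{name}_scale"] = res.scale
        rows.append(row)
    scores = pd.DataFrame(rows)
    scores.to_csv(os.path.join(config.out_dir, "element_scores.tsv"),
                  sep="\t", index=False)
    emit("phylop", "element_scores.tsv")

    # ---- segmentation (primate clade) -------------------------------- #
    prim_cols = clade_views["primates"]
    segments, posteriors = constraint_scan.phastcons_segment(
        prim_cols, subtree["primates"], neutral, config.hmm_params())
    with open(os.path.join(config.out_dir, "conserved_segments.bed"), "w") as fh:
        for i, s in enumerate(segments):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\tcons{i:04d}\t{s.score}\n")
    emit("phastcons", "conserved_segments.bed")
    log.info("phastcons: %d segments", len(segments))

    # ---- depth classification ---------------------------------------- #
    qsets = {name: depth_classify.storey_qvalues(scores[f"{name}_p"].to_numpy(),
                                                 lam=config.lam)
             for name in clade_views}
    _, overlap_flags = uce_scan.uce_overlap(segments, elements, min_bp=1)
    calls = []
    for i, e in enumerate(elements):
        call = depth_classify.classify_depth(
            qsets["primates"].q_values[i], qsets["mammals"].q_values[i],
            qsets["vertebrates"].q_values[i],
            phastcons_overlap=bool(overlap_flags[i]),
            alpha=config.alpha, element_id=e.element_id)
        calls.append({"element_id": e.element_id, "start": e.start, "end": e.end,
                      "category": call.category.value,
                      "primate_q": qsets["primates"].q_values[i],
                      "mammal_q": qsets["mammals"].q_values[i],
                      "vertebrate_q": qsets["vertebrates"].q_values[i],
                      "phastcons_overlap": bool(overlap_flags[i]),
                      "planted": bool(truth_mask[i])})
    calls_df = pd.DataFrame(calls)
    calls_df.to_csv(os.path.join(config.out_dir, "depth_calls.tsv"),
                    sep="\t", index=False)
    emit("classify", "depth_calls.tsv")

    planted_cat = depth_classify.DepthCategory.PRIMATE.value
    called = calls_df["category"] == planted_cat
    tp = int((called & calls_df["planted"]).sum())
    fp = int((called & ~calls_df["planted"]).sum())
    sens = tp / max(1, int(calls_df["planted"].sum()))
    fdr = fp / max(1, tp + fp)
    manifest["stages"]["classify"] = {"n_called_primate": int(called.sum()),
                                      "sensitivity": sens, "empirical_fdr": fdr}
    log.info("classify: %d primate calls, sensitivity=%.3f FDR=%.3f",
             int(called.sum()), sens, fdr)

    # ---- UCEs --------------------------------------------------------- #
    max_missing = uce_scan.resolve_max_missing(prim_cols.n_species,
                                               config.uce_missing_tolerance)
    strict = uce_scan.scan_uces(uce_scan.perfect_columns(prim_cols, max_missing=0),
                                prim_cols.coords, prim_cols.chrom,
                                config.uce_min_length, "strict")
    relaxed = uce_scan.scan_uces(
        uce_scan.perfect_columns(prim_cols, max_missing=max_missing),
        prim_cols.coords, prim_cols.chrom, config.uce_min_length, "relaxed")
    with open(os.path.join(config.out_dir, "uces.bed"), "w") as fh:
        for recs in (strict, relaxed):
            for i, u in enumerate(recs):
                fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.mode}{i:04d}\n")
    emit("uce", "uces.bed")
    manifest["stages"]["uce"] = {"n_strict": len(strict), "n_relaxed": len(relaxed)}

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
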