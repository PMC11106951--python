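"""End-to-end orchestration: simulate -> normalize -> binarize -> learn ->
decode -> label -> annotate -> TSS regions/broad -> specificity -> enrich ->
overlap, with a deterministic run manifest.

Every stage output is a pure function of (inputs, config, seed); rerunning
with the same config reproduces byte-identical non-log outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genome_io import GenomicInterval, write_bed, write_track
from .signal_norm import (
    binarize,
    normalize_track,
    spikein_scale_factor,
    write_binarized,
)
from .hmm_segmentation import decode, learn_model, write_model
from .state_annotation import (
    annotate_intervals,
    intersect,
    label_states,
    state_feature_enrichment,
)
from .broad_specificity import (
    broad_gene_set,
    broad_specific_overlap,
    call_expressed,
    cpm,
    extract_tss_regions,
    genes_for_regions,
    specificity_t,
    tmm_factors,
)
from .enrichment_stats import enrich
from .synthetic_data import SimulationConfig, simulate_study, write_study

log = logging.getLogger("chromstate")

DEFAULTS = {
    # every analysis default in one block for auditability
    "bin_size": 200,
    "p_binarize": 1e-4,
    "n_states": 10,
    "seed": 0,
    "broad_min": 4000,
    "top_fraction": 0.10,
    "alpha_p": 0.05,
    "alpha_q": 0.05,
    "smooth_bins": 3,
    "constant_C": 10_000.0,
    "learn_mode": "concatenated",  # or "separate"
    "decode_mode": "posterior",
    "n_restarts": 3,
    "max_iter": 200,
    "rel_tol": 1e-4,
}


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = dict(DEFAULTS)
    sim = user.pop("simulate", {})
    cfg.update(user)
    cfg["simulate"] = sim
    return cfg


def _config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage '{name}' failed: {e}") from e
        return inner
    return wrap


def _mark_call_runs(binary, mark: str) -> list[GenomicInterval]:
    """Maximal runs of 1-calls for one mark, as intervals (peak stand-ins)."""
    m_idx = binary.marks.index(mark)
    runs: list[GenomicInterval] = []
    bs = binary.grid.bin_size
    for chrom in binary.grid.chroms:
        col = binary.calls[chrom][:, m_idx].astype(np.int8)
        if col.sum() == 0:
            continue
        edges = np.flatnonzero(np.diff(col))
        starts = edges[col[edges + 1] == 1] + 1
        ends = edges[col[edges] == 1] + 1
        if col[0] == 1:
            starts = np.concatenate(([0], starts))
        if col[-1] == 1:
            ends = np.concatenate((ends, [len(col)]))
        chrom_len = binary.grid.chrom_lengths[chrom]
        for s, e in zip(starts, ends):
            runs.append(
                GenomicInterval(chrom, int(s) * bs, min(int(e) * bs, chrom_len))
            )
    return runs


def run(config: dict, outdir: str | Path) -> Path:
    """Execute the full pipeline on a synthetic study; returns the run dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.setLevel(logging.INFO)
    try:
        return _run_stages(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: dict, outdir: Path) -> Path:
    cfg = dict(DEFAULTS)
    cfg.update(config)
    sim_kwargs = dict(cfg.get("simulate") or {})
    sim_kwargs.setdefault("seed", cfg["seed"])
    sim_kwargs.setdefault("bin_size", cfg["bin_size"])
    sim_cfg = SimulationConfig(**sim_kwargs)

    # --- simulate -----------------------------------------------------------
    bundle = _stage("simulate")(simulate_study)(sim_cfg)
    write_study(bundle, outdir / "sim")
    grid, genes, truth = bundle.grid, bundle.genes, bundle.truth
    analysis_marks = [m for m in sim_cfg.marks if m != "IgG"]

    # --- normalize ----------------------------------------------------------
    @_stage("normalize")
    def _normalize():
        norm_dir = outdir / "normalized"
        norm_dir.mkdir(exist_ok=True)
        for ct, marks in bundle.tracks.items():
            for mark, reps in marks.items():
                for t in reps:
                    sf = spikein_scale_factor(
                        bundle.spikein[t.sample_id], cfg["constant_C"],
                        sample_id=t.sample_id,
                    )
                    nt = normalize_track(t, sf, smooth_bins=cfg["smooth_bins"])
                    write_track(nt, norm_dir / f"{t.sample_id}.bedGraph")
    _normalize()

    # --- binarize -----------------------------------------------------------
    @_stage("binarize")
    def _binarize():
        binaries = {}
        for ct in sim_cfg.cell_types:
            binaries[ct] = binarize(
                {m: bundle.tracks[ct][m] for m in analysis_marks},
                control=bundle.tracks[ct].get("IgG"),
                p=cfg["p_binarize"],
                cell_type=ct,
                marks=analysis_marks,
            )
            write_binarized(binaries[ct], outdir / "binarized")
        return binaries
    binaries = _binarize()

    # --- learn --------------------------------------------------------------
    @_stage("learn")
    def _learn():
        models = {}
        if cfg["learn_mode"] == "concatenated":
            shared = learn_model(
                list(binaries.values()), K=cfg["n_states"], seed=cfg["seed"],
                max_iter=cfg["max_iter"], rel_tol=cfg["rel_tol"],
                n_restarts=cfg["n_restarts"],
            )
            for ct in binaries:
                models[ct] = shared
            write_model(shared, outdir / "model.tsv")
        else:
            for i, ct in enumerate(binaries):
                models[ct] = learn_model(
                    binaries[ct], K=cfg["n_states"], seed=cfg["seed"] + i,
                    max_iter=cfg["max_iter"], rel_tol=cfg["rel_tol"],
                    n_restarts=cfg["n_restarts"],
                )
                write_model(models[ct], outdir / f"model_{ct}.tsv")
        return models
    models = _learn()

    # --- decode -------------------------------------------------------------
    @_stage("decode")
    def _decode():
        return {
            ct: decode(models[ct], binaries[ct], mode=cfg["decode_mode"])
            for ct in binaries
        }
    segs = _decode()

    # --- label + state/feature enrichment ------------------------------------
    tss_feature = [
        GenomicInterval(g.interval.chrom, max(0, g.tss - 1000), g.tss + 1000)
        for g in genes
    ]
    gene_feature = [g.interval for g in genes]

    @_stage("label")
    def _label():
        labels = {}
        for ct, seg in segs.items():
            folds = state_feature_enrichment(
                seg, {"TSS": tss_feature, "gene_body": gene_feature}
            )
            fold_col = folds["TSS"].reindex(
                range(1, models[ct].n_states + 1), fill_value=0.0
            )
            labels[ct] = label_states(models[ct], fold_col.to_numpy())
            folds.rename_axis("state").to_csv(
                outdir / f"state_enrichment_{ct}.tsv", sep="\t"
            )
            pd.DataFrame(
                {
                    "state": [l.state for l in labels[ct]],
                    "label": [l.label for l in labels[ct]],
                    "tss_fold": [l.tss_fold for l in labels[ct]],
                }
            ).to_csv(outdir / f"state_labels_{ct}.tsv", sep="\t", index=False)
            name_of = {l.state: f"{l.state}_{l.label.replace(' ', '_')}"
                       for l in labels[ct]}
            write_bed(
                [(iv, name_of[s]) for iv, s in seg.segments],
                outdir / f"segments_{ct}.bed",
            )
        return labels
    labels = _label()

    # predicted TSS states: any state labeled TSS-like, plus any state whose
    # H3K4me3 emission is promoter-grade (the fold-based label can miss a
    # genuine TSS state whose bins sit mostly in broad domains beyond the
    # TSS +-1 kb window)
    tss_like = ("TSS Active", "TSS Flanking", "Bivalent/poised TSS")
    tss_states_of = {}
    for ct in segs:
        k4_col = models[ct].marks.index("H3K4me3")
        by_label = {l.state for l in labels[ct] if l.label in tss_like}
        by_emission = {
            k + 1
            for k in range(models[ct].n_states)
            if models[ct].emissionprob[k, k4_col] >= 0.5
        }
        tss_states_of[ct] = (by_label | by_emission) or {1, 2}

    # --- annotate (binarized-call runs stand in for peaks) -------------------
    @_stage("annotate")
    def _annotate():
        rows = []
        for ct, binary in binaries.items():
            for mark in analysis_marks:
                runs = _mark_call_runs(binary, mark)
                if not runs:
                    continue
                _, pct = annotate_intervals(runs, genes)
                for cat, val in pct.items():
                    rows.append({"cell_type": ct, "mark": mark,
                                 "category": cat, "percent": val})
        pd.DataFrame(rows).to_csv(outdir / "annotation.tsv", sep="\t",
                                  index=False)
    _annotate()

    # --- TSS regions / broad domains -----------------------------------------
    @_stage("tss-regions")
    def _tss_regions():
        broad = {}
        for ct, seg in segs.items():
            regions, hist, summary = extract_tss_regions(
                seg, tss_states=tss_states_of[ct], broad_min=cfg["broad_min"]
            )
            genes_for_regions(regions, genes)
            broad[ct] = broad_gene_set(regions)
            pd.DataFrame(
                {
                    "chrom": [r.interval.chrom for r in regions],
                    "start": [r.interval.start for r in regions],
                    "end": [r.interval.end for r in regions],
                    "length": [r.length for r in regions],
                    "is_broad": [r.is_broad for r in regions],
                    "genes": [",".join(r.genes) for r in regions],
                }
            ).to_csv(outdir / f"tss_regions_{ct}.tsv", sep="\t", index=False)
            hist.rename_axis("length_kb").rename("count").to_csv(
                outdir / f"tss_length_hist_{ct}.tsv", sep="\t"
            )
        return broad
    broad = _tss_regions()

    # --- expression / specificity --------------------------------------------
    @_stage("specificity")
    def _specificity():
        factors = tmm_factors(bundle.expression)
        cpm_mat = cpm(bundle.expression, factors)
        call_expressed(cpm_mat, bundle.samples).rename_axis("gene_id").to_csv(
            outdir / "expressed.tsv", sep="\t"
        )
        specific = {}
        for ct in sim_cfg.cell_types:
            res = specificity_t(
                bundle.expression, bundle.samples, ct,
                top_fraction=cfg["top_fraction"], factors=factors,
            )
            specific[ct] = {r.gene_id for r in res if r.is_specific}
            pd.DataFrame(
                {
                    "gene_id": [r.gene_id for r in res],
                    "t_stat": [r.t_stat for r in res],
                    "rank": [r.rank for r in res],
                    "is_specific": [r.is_specific for r in res],
                }
            ).to_csv(outdir / f"specificity_{ct}.tsv", sep="\t", index=False)
        return specific
    specific = _specificity()

    # --- enrichment -----------------------------------------------------------
    @_stage("enrich")
    def _enrich():
        universe = {g.gene_id for g in genes}
        for ct, genes_b in broad.items():
            results = enrich(genes_b & universe, bundle.term_map, universe,
                             p_max=cfg["alpha_p"], q_max=cfg["alpha_q"])
            pd.DataFrame(
                [
                    {"term": r.term, "k": r.k, "K": r.K, "n": r.n,
                     "N": r.N, "p": r.p, "q": r.q}
                    for r in results
                ]
            ).to_csv(outdir / f"enrichment_{ct}.tsv", sep="\t", index=False)
    _enrich()

    # --- overlap report --------------------------------------------------------
    @_stage("overlap")
    def _overlap():
        rows = []
        for ct in sim_cfg.cell_types:
            if broad[ct]:
                k, total, pct = broad_specific_overlap(broad[ct], specific[ct])
            else:
                k, total, pct = 0, 0, 0.0
            k4_runs = _mark_call_runs(binaries[ct], "H3K4me3")
            k27_runs = _mark_call_runs(binaries[ct], "H3K27ac")
            _, n_hit = intersect(k4_runs, k27_runs)
            rows.append(
                {
                    "cell_type": ct,
                    "broad_and_specific": k,
                    "broad_total": total,
                    "pct_broad_specific": pct,
                    "k4me3_sites": len(k4_runs),
                    "k4me3_overlapping_k27ac": n_hit,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "overlap_report.tsv", sep="\t",
                                  index=False)
    _overlap()

    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "n_genes": len(genes),
        "chroms": grid.chroms,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1, default=str)
    return outdir
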