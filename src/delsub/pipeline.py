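"""End-to-end scenario orchestration: simulate -> decode -> enrich -> report.

A scenario is a YAML/dict config naming the library design, the
abundance and activity models, selection parameters, dope-ins, and
analysis settings.  One top-level seed fans out deterministically to
per-stage sub-seeds (documented derivation: the first words of
``numpy.random.SeedSequence(seed).generate_state``, masked to 31 bits),
so re-running a manifest reproduces every stochastic output
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decode import CountTable, DecodeSettings, count_genes
from .design import LibraryDesign, build_design, enumerate_genes
from .enrich import (
    Molecule,
    collapse_to_molecules,
    detect_families,
    dope_in_metrics,
    fold_enrichment,
    frequency_fold_enrichment,
    redundancy_concordance,
    select_hits,
    synthon_summary,
)
from .simulate import (
    AbundanceCalibration,
    ActivityModel,
    SelectionParams,
    capture_probability,
    emit_reads,
    generate_gene_abundances,
    phospho_probability,
    pool_from_design,
    assign_activities,
    simulate_selection,
    spike_dope_in,
    write_fastq,
    SelectionPool,
)

STAGES = ("abundance", "activity", "selection", "reference", "reads")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage sub-seeds from one top-level seed."""
    words = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(w) & 0x7FFFFFFF for name, w in zip(STAGES, words)}


def _require(config: dict, dotted: str):
    node = config
    walked = []
    for key in dotted.split("."):
        walked.append(key)
        if not isinstance(node, dict) or key not in node:
            raise KeyError(f"scenario config missing key '{'.'.join(walked)}'")
        node = node[key]
    return node


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(canon).hexdigest()


def _gene_capture_probabilities(design: LibraryDesign, config: dict,
                                seeds: dict[str, int]) -> tuple[np.ndarray, SelectionParams]:
    sel_cfg = dict(_require(config, "selection"))
    depth = int(_require(config, "selection.depth"))
    if "pharmacophore" in config:
        # affinity-style validation selection: capture set by pharmacophore
        # membership, not by the kinase activity model
        ph = config["pharmacophore"]
        cycle, bid = int(ph["cycle"]), int(ph["block_id"])
        p_hit, p_bg = float(ph["p_cap"]), float(ph["background"])
        mols = design.molecule_array()
        hit = mols[:, cycle - 1] == bid
        p_cap_mol = np.where(hit, p_hit, p_bg)
        p_cap = np.tile(p_cap_mol, len(design.lineages))
        params = SelectionParams(p_ab=p_hit, beta=p_bg, depth=depth,
                                 seed=seeds["selection"])
        return p_cap, params
    act = ActivityModel(**config.get("activity", {}))
    x_mol = assign_activities(design, act, seeds["activity"])
    params = SelectionParams(
        dose=float(sel_cfg.get("dose", SelectionParams().dose)),
        p_ab=float(sel_cfg.get("p_ab", SelectionParams().p_ab)),
        beta=float(sel_cfg.get("beta", SelectionParams().beta)),
        depth=depth,
        seed=seeds["selection"],
    )
    x = np.tile(x_mol, len(design.lineages))
    p_cap = capture_probability(phospho_probability(x, params.dose), params)
    return p_cap, params


def run_scenario(config, outdir) -> dict:
    """Execute a scenario config end to end; returns the run manifest.

    Stages: build design; draw gene abundances; assign activities (or
    apply a pharmacophore capture override); sequence the unselected
    reference; run the selection (count level, or FASTQ emission plus
    decoding in reads mode); compute enrichments, molecule summaries,
    concordance, hits, and dope-in metrics.  All tables land in outdir
    with stable names, listed in manifest.json.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seed = int(_require(config, "seed"))
    seeds = stage_seeds(seed)
    design = build_design(_require(config, "design"))
    genes = list(enumerate_genes(design))
    G = len(genes)

    # --- pre-selection pool ------------------------------------------------
    copies_per_member = float(config.get("library_copies_per_member", 10_000))
    total_copies = copies_per_member * G
    ab_cfg = config.get("abundance")
    if ab_cfg is not None:
        cal = AbundanceCalibration(G=G, seed=seeds["abundance"], **ab_cfg)
        abundances = generate_gene_abundances(cal)
        pool = pool_from_design(design, abundances=abundances, total_copies=total_copies)
    else:
        pool = pool_from_design(design, copies_per_member=copies_per_member)

    p_cap, params = _gene_capture_probabilities(design, config, seeds)
    for dope in config.get("dope_ins", []):
        pool = spike_dope_in(pool, dope["id"], float(dope["copies"]),
                             x=float(dope.get("x", 1.0)))
        if "pharmacophore" in config:
            p_dope = params.beta
        else:
            p_dope = capture_probability(
                phospho_probability(float(dope.get("x", 1.0)), params.dose), params
            )
        p_cap = np.append(p_cap, p_dope)

    # --- sequence the unselected reference ---------------------------------
    ref_depth = int(config.get("reference_depth", params.depth))
    rng_ref = np.random.default_rng(seeds["reference"])
    ref_reads = rng_ref.multinomial(ref_depth, pool.pre_counts / pool.total_copies)

    # --- selection ----------------------------------------------------------
    post = simulate_selection(pool.pre_counts, p_cap, params.depth, params.seed)

    outputs: dict[str, str] = {}
    mode = config.get("mode", "counts")
    lib_post = post[:G]
    lib_ref = ref_reads[:G]
    if mode == "reads":
        error_rate = float(config.get("read_error_rate", 0.0))
        settings = DecodeSettings(**config.get("decode", {}))
        fq_sel = outdir / "reads_selected.fastq"
        fq_ref = outdir / "reads_unselected.fastq"
        write_fastq(emit_reads(lib_post, design, error_rate, seeds["reads"], genes), fq_sel)
        write_fastq(emit_reads(lib_ref, design, error_rate, seeds["reads"] + 1, genes), fq_ref)
        outputs["reads_selected"] = str(fq_sel)
        outputs["reads_unselected"] = str(fq_ref)
        sel_table = count_genes(fq_sel, design, settings, sample_id="selected")
        ref_table = count_genes(fq_ref, design, settings, sample_id="unselected")
    elif mode == "counts":
        sel_table = CountTable.from_vector(genes, lib_post, "selected")
        ref_table = CountTable.from_vector(genes, lib_ref, "unselected")
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'counts' or 'reads')")

    sel_path, ref_path = outdir / "counts_selected.tsv", outdir / "counts_unselected.tsv"
    sel_table.to_tsv(sel_path)
    ref_table.to_tsv(ref_path)
    outputs["counts_selected"] = str(sel_path)
    outputs["counts_unselected"] = str(ref_path)

    # --- enrichment ----------------------------------------------------------
    an = config.get("analysis", {})
    alpha = float(an.get("alpha", 1.0))
    records = fold_enrichment(sel_table, ref_table, design, alpha=alpha,
                              mode=an.get("ref_mode", "observed_ref"))
    records.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    outputs["enrichment"] = str(outdir / "enrichment.tsv")

    summaries = collapse_to_molecules(records, design,
                                      merge_rule=an.get("merge_rule", "mean_log"))
    summaries.to_csv(outdir / "molecules.tsv", sep="\t", index=False)
    outputs["molecules"] = str(outdir / "molecules.tsv")

    report: dict = {"seed": seed, "stage_seeds": seeds, "n_genes": G,
                    "mode": mode, "depth": params.depth}
    if len(design.lineages) == 2:
        k = min(int(an.get("top_k", 200)), len(summaries))
        report["concordance"] = redundancy_concordance(summaries, k)

    top_k = min(int(an.get("top_k", 200)), len(summaries))
    top_mols = [
        Molecule(int(r.c1), int(r.c2), int(r.c3), int(r.c4))
        for r in summaries.sort_values("E_combined", ascending=False, kind="mergesort")
        .head(top_k).itertuples()
    ]
    syn = synthon_summary(top_mols, design)
    report["top_k"] = top_k
    report["phenol_cap_fraction_topk"] = syn["phenol_cap_fraction"]

    families = detect_families(top_mols, min_size=int(an.get("family_min_size", 3)))
    report["n_families"] = len(families)
    hits = select_hits(summaries, min_enrichment=float(an.get("min_enrichment", 10.0)))
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)
    outputs["hits"] = str(outdir / "hits.tsv")
    report["n_hits"] = len(hits)

    # --- dope-in metrics ------------------------------------------------------
    dope_report = {}
    total_post = post.sum()
    for dope in config.get("dope_ins", []):
        idx = pool.dope_ins[dope["id"]]
        pre_frac = pool.pre_counts[idx] / pool.total_copies
        post_frac = post[idx] / total_post
        enr = frequency_fold_enrichment(post_frac, pre_frac)
        recovered = pool.pre_counts[idx] * p_cap[idx]  # expected captured copies
        m = dope_in_metrics(enr, pool.pre_counts[idx], recovered)
        dope_report[dope["id"]] = {
            "enrichment": m.enrichment,
            "recovery": m.recovery,
            "implied_background": m.implied_background,
        }
    if dope_report:
        report["dope_ins"] = dope_report

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    outputs["report"] = str(outdir / "report.json")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "stage_seeds": seeds,
        "version": __version__,
        "outputs": outputs,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_scenario(name: str) -> dict:
    """Load a packaged scenario config ('paper_like' or 'caii_validation')."""
    ref = resources.files("delsub") / "scenarios" / f"{name}.yaml"
    with ref.open() as fh:
        return yaml.safe_load(fh)
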