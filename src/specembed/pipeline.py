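"""End-to-end workflow: embed -> build libraries -> decoys -> search ->
FDR -> report, driven by a single config mapping (YAML/JSON-friendly).

Three search modes share one code path:

* ``library``  — search against embedded experimental spectra only;
* ``database`` — search against embedded predicted spectra of digested /
  supplied peptides only;
* ``hybrid``   — the merged library, experimental vectors winning on
  peptides covered by both.

Every run writes results.tsv, fdr.tsv, summary.json and a run.log carrying
the seeds and the config needed to reproduce it; with a fixed seed the
result files are bit-identical across runs."""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from . import library_search as ls
from . import synthetic
from .digest import DigestConfig, digest_proteins
from .evaluate import score_against_truth
from .model import (
    EncoderConfig,
    LossConfig,
    SpecEmbedModel,
    TrainingConfig,
    train,
)
from .spectra_io import read_fasta, read_mgf, read_msp
from .vectorize import VectorizationConfig

log = logging.getLogger(__name__)

DEFAULTS = {
    "mode": "library",
    "charge": 2,
    "ppm_tol": 10.0,
    "fdr": 0.01,
    "level": "peptide",
    "seed": 1,
    "scale": "reduced",
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _configs(scale: str) -> tuple[EncoderConfig, VectorizationConfig]:
    if scale == "reduced":
        return EncoderConfig.reduced(), VectorizationConfig.reduced()
    return EncoderConfig(), VectorizationConfig()


def _get_model(cfg: dict, charge: int, scale: str, seed: int):
    enc_cfg, vec_cfg = _configs(scale)
    model_cfg = cfg.get("model", {})
    if "weights" in model_cfg:
        return SpecEmbedModel.load(model_cfg["weights"]), None
    tr = cfg.get("train", {})
    n_pep = int(tr.get("n_peptides", 100))
    n_rep = int(tr.get("n_replicates", 6))
    epochs = int(tr.get("epochs", 30))
    peptides, spectra = synthetic.make_training_set(
        n_peptides=n_pep, n_replicates=n_rep, charge=charge, seed=seed
    )
    result = train(
        spectra,
        enc_cfg,
        vec_cfg,
        LossConfig(),
        TrainingConfig(charge=charge, epochs=epochs, seed=seed),
    )
    return result.model, result


def run_pipeline(config: dict, output_dir: str | Path | None = None) -> dict:
    """Execute the full search workflow; returns the summary dict."""
    cfg = {**DEFAULTS, **config}
    mode = cfg["mode"]
    if mode not in ("library", "database", "hybrid"):
        raise ValueError(f"unknown mode {mode!r}")
    charge = int(cfg["charge"])
    seed = int(cfg["seed"])
    out = Path(output_dir or cfg.get("output_dir", "specembed_run"))
    out.mkdir(parents=True, exist_ok=True)
    run_log = out / "run.log"

    def note(msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat()
        with open(run_log, "a") as fh:
            fh.write(f"{stamp} {msg}\n")
        log.info("%s", msg)

    note(f"config: {json.dumps(cfg, sort_keys=True, default=str)}")
    model, train_result = _get_model(cfg, charge, cfg["scale"], seed)
    note(f"model ready (config hash {model.config_hash()})")

    truth: dict[str, str] | None = None
    library_spectra = queries = None
    peptides_for_db: list[str] = []

    if "simulate" in cfg:
        sim = cfg["simulate"] or {}
        bench = synthetic.make_benchmark(
            n_lib_peptides=int(sim.get("n_lib_peptides", 100)),
            n_queries=int(sim.get("n_queries", 200)),
            foreign_fraction=float(sim.get("foreign_fraction", 0.0)),
            charge=charge,
            seed=seed,
            library_peptides=sim.get("library_peptides"),
        )
        library_spectra, queries, truth = (
            bench.library_spectra,
            bench.query_spectra,
            bench.truth,
        )
        peptides_for_db = list(bench.library_peptides)
        note(f"simulated benchmark: {len(library_spectra)} library spectra, "
             f"{len(queries)} queries")
    else:
        inputs = cfg.get("inputs", {})
        if "queries_mgf" not in inputs:
            raise ValueError("config needs a 'simulate' block or inputs.queries_mgf")
        queries = [s for s in read_mgf(inputs["queries_mgf"]) if s.charge_known]
        if "library_msp" in inputs:
            library_spectra = read_msp(inputs["library_msp"])
        if "fasta" in inputs:
            proteins = list(read_fasta(inputs["fasta"]))
            digest_cfg = DigestConfig()
            peptides_for_db = [
                p.sequence
                for p in digest_proteins(proteins, digest_cfg)
                if set(p.sequence) <= set("ACDEFGHIKLMNPQRSTVWY")
            ]
            note(f"digested {len(proteins)} proteins into {len(peptides_for_db)} peptides")

    queries = [q for q in queries if q.charge == charge]
    if not queries:
        raise ValueError(f"no charge-{charge} queries")

    # build target library per mode
    libs = []
    if mode in ("library", "hybrid"):
        if not library_spectra:
            raise ValueError(f"mode {mode!r} needs library spectra")
        libs.append(("experimental", ls.build_library_from_spectra(library_spectra, model)))
    if mode in ("database", "hybrid"):
        if not peptides_for_db:
            raise ValueError(f"mode {mode!r} needs peptides (fasta or simulate block)")
        libs.append(("predicted", ls.build_library_from_peptides(peptides_for_db, charge, model)))
    if mode == "hybrid":
        target = ls.merge_hybrid(libs[0][1], libs[1][1])
    else:
        target = libs[0][1]
    note(f"target library: {len(target)} entries (mode={mode})")

    decoys = ls.make_decoys(target, model, rng_seed=cfg.get("decoy_seed", seed))
    combined = ls.combine(target, decoys)
    note(f"combined target+decoy library: {len(combined)} entries")

    qvecs = model.embed_spectra(queries)
    results = ls.search(queries, qvecs, combined, ppm_tol=float(cfg["ppm_tol"]))
    note(f"search: {len(results)} of {len(queries)} queries matched a candidate")

    fdr_table = ls.estimate_fdr(results, level=cfg["level"])
    accepted = ls.apply_cutoff(results, fdr_table, alpha=float(cfg["fdr"]))
    note(f"accepted at q<={cfg['fdr']}: {accepted.n_psm} PSMs, "
         f"{accepted.n_unique_peptides} unique peptides")

    df = ls.results_frame(results)
    df.to_csv(out / "results.tsv", sep="\t", index=False)
    fdr_table.table.to_csv(out / "fdr.tsv", sep="\t", index=False)

    summary = {
        "mode": mode,
        "charge": charge,
        "seed": seed,
        "n_queries": len(queries),
        "n_matched": len(results),
        "library_size": len(target),
        "fdr_alpha": cfg["fdr"],
        "score_threshold": accepted.threshold,
        "n_accepted_psm": accepted.n_psm,
        "n_accepted_unique_peptides": accepted.n_unique_peptides,
        "config_hash": model.config_hash(),
    }
    if train_result is not None:
        summary["best_val_accuracy"] = train_result.best_val_accuracy
        summary["best_epoch"] = int(train_result.best_epoch)
    if truth is not None:
        score = score_against_truth(accepted.results, truth)
        summary["truth"] = {
            "n_correct": score.n_correct,
            "n_wrong": score.n_wrong,
            "false_discovery_proportion": score.false_discovery_proportion,
            "n_correct_unique_peptides": score.n_correct_unique_peptides,
        }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    note("done")
    return summary
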