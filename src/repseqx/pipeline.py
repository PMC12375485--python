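"""End-to-end orchestration: simulate-or-read, preprocess, then every
analysis stage, with versioned TSV/JSON outputs and a run log.

Reruns with the same config and seed are byte-identical on all numeric
outputs: every random step (simulation, downsampling, train/test split)
derives from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import RepertoireSet, read_repertoire_set, write_repertoire_set
from .diversity import age_correlation, diversity_table
from .homeostasis import homeostasis_group_test, homeostasis_profiles
from .overlap import (
    differential_clonotypes,
    motif_matrix,
    overlap_group_comparison,
    shared_cdr3_matrix,
)
from .preprocess import PreprocessConfig, preprocess_set
from .screening import project_pca, split_and_cv, train_evaluate
from .simulate import SimulationConfig, simulate_repertoire_set
from .usage import differential_usage, usage_correlation, usage_matrix

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("repseqx")


@dataclass
class PipelineConfig:
    out_dir: str = "repseqx_out"
    seed: int = 0
    receptor: str = "TCR"
    # either read an existing cohort ...
    input_dir: str | None = None
    metadata: str | None = None
    # ... or simulate one
    simulate: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    screening: dict = field(default_factory=dict)
    motif_window: tuple[int, int] = (6, 9)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**raw)


def load_config(path: str | Path) -> PipelineConfig:
    return PipelineConfig.from_yaml(path)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                log.info("stage %s ...", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def _acquire(config: PipelineConfig, out: Path) -> tuple[RepertoireSet, dict | None]:
    if config.input_dir is not None:
        if config.metadata is None:
            raise FileNotFoundError("metadata path required with input_dir")
        if not Path(config.metadata).exists():
            raise FileNotFoundError(f"metadata file not found: {config.metadata}")
        return (
            read_repertoire_set(config.input_dir, config.metadata, config.receptor),
            None,
        )
    sim = SimulationConfig(
        seed=config.seed, receptor=config.receptor, **config.simulate
    )
    rep_set, ledger = simulate_repertoire_set(sim)
    write_repertoire_set(rep_set, out / "simulated")
    with open(out / "simulated" / "ground_truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1)
    return rep_set, ledger


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run every stage; returns a mapping of stage name to output path."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    run_log: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    rep_set, _ = _stage("acquire")(_acquire)(config, out)
    run_log["stages"]["acquire"] = {
        "n_samples": len(rep_set),
        "group_sizes": rep_set.group_sizes(),
    }

    pp_conf = PreprocessConfig(seed=config.seed, **config.preprocess)
    rep_set, logs = _stage("preprocess")(preprocess_set)(rep_set, pp_conf)
    write_repertoire_set(rep_set, out / "preprocessed")
    run_log["stages"]["preprocess"] = {
        "merged": sum(len(v) for v in logs.merges.values()),
        "contaminants_removed": len(logs.contaminants),
        "nonfunctional_removed": sum(len(v) for v in logs.nonfunctional.values()),
        "depth": logs.depth,
    }
    outputs["preprocessed"] = str(out / "preprocessed")

    div_table, div_p = _stage("diversity")(diversity_table)(rep_set)
    div_table.to_csv(out / "diversity.tsv", sep="\t", index=False)
    age_corr = _stage("diversity")(age_correlation)(rep_set, "unique_clonotypes")
    payload = {"group_p_values": div_p, "age_correlation": age_corr.to_dict("index")}
    (out / "diversity_tests.json").write_text(json.dumps(payload, indent=1))
    outputs["diversity"] = str(out / "diversity.tsv")
    run_log["stages"]["diversity"] = {"n_rows": len(div_table)}

    matrix = _stage("overlap")(shared_cdr3_matrix)(rep_set)
    matrix.to_csv(out / "overlap_matrix.tsv", sep="\t")
    parts, overlap_p = overlap_group_comparison(matrix, rep_set.groups)
    (out / "overlap_tests.json").write_text(
        json.dumps(
            {
                "p_values": overlap_p,
                "medians": {k: float(np.median(v)) if v.size else None for k, v in parts.items()},
            },
            indent=1,
        )
    )
    outputs["overlap"] = str(out / "overlap_matrix.tsv")
    run_log["stages"]["overlap"] = {"n_pairs": int(len(matrix) * (len(matrix) - 1) / 2)}

    hits, full = _stage("differential")(differential_clonotypes)(
        rep_set, **config.differential
    )
    full.to_csv(out / "differential_clonotypes.tsv", sep="\t", index=False)
    outputs["differential"] = str(out / "differential_clonotypes.tsv")
    run_log["stages"]["differential"] = {
        "tested": len(full),
        "hits": len(hits),
        "malignant_associated": int((hits["direction"] == "malignant").sum()),
        "benign_associated": int((hits["direction"] == "benign").sum()),
    }

    motif_payload = {}
    for direction in ("malignant", "benign"):
        seqs = hits.loc[hits["direction"] == direction, "clone"].tolist()
        seqs = [s for s in seqs if isinstance(s, str)]
        if seqs:
            pfm, kmer, freq = motif_matrix(seqs, tuple(config.motif_window))
            pfm.to_csv(out / f"motif_{direction}.tsv", sep="\t")
            motif_payload[direction] = {
                "top_kmer": kmer,
                "frequency": freq,
                "window": list(config.motif_window),
                "n_sequences": len(seqs),
            }
    (out / "motifs.json").write_text(json.dumps(motif_payload, indent=1))
    run_log["stages"]["motif"] = {k: v["top_kmer"] for k, v in motif_payload.items()}

    vj = _stage("usage")(usage_matrix)(rep_set, "VJ", "reads")
    vj.to_csv(out / "usage_vj.tsv", sep="\t")
    du = differential_usage(vj, rep_set.groups)
    du.to_csv(out / "usage_tests.tsv", sep="\t", index=False)
    corr = usage_correlation(vj, rep_set.groups)
    (out / "usage_correlation.json").write_text(
        json.dumps({k: list(map(float, v)) for k, v in corr.items()}, indent=1)
    )
    outputs["usage"] = str(out / "usage_vj.tsv")
    run_log["stages"]["usage"] = {
        "segments": vj.shape[1],
        "significant": int(du["significant"].sum()),
    }

    profiles = _stage("homeostasis")(homeostasis_profiles)(rep_set)
    profiles.to_csv(out / "homeostasis.tsv", sep="\t")
    p_hyper, direction = homeostasis_group_test(
        profiles, rep_set.groups, "Hyperexpanded"
    )
    (out / "homeostasis_tests.json").write_text(
        json.dumps(
            {"bin": "Hyperexpanded", "p": p_hyper, "direction": direction,
             "bin_convention": "[lower, upper); last bin closed at 1"},
            indent=1,
        )
    )
    outputs["homeostasis"] = str(out / "homeostasis.tsv")
    run_log["stages"]["homeostasis"] = {"hyperexpanded_p": p_hyper}

    def _screen():
        y = (rep_set.groups == "malignant").astype(int).to_numpy()
        plan = split_and_cv(y, seed=config.seed)
        reports, fs = train_evaluate(
            vj, rep_set.groups, plan, seed=config.seed, **config.screening
        )
        coords, loadings, evr = project_pca(vj[fs.features] - vj[fs.features].mean())
        return plan, reports, fs, coords, evr

    plan, reports, fs, coords, evr = _stage("screening")(_screen)()
    screening_payload = {
        "seed": config.seed,
        "features": fs.features,
        "selection_p_values": {k: float(v) for k, v in fs.p_values.items()},
        "train_samples": [rep_set.sample_ids[i] for i in plan.train_idx],
        "test_samples": [rep_set.sample_ids[i] for i in plan.test_idx],
        "models": {
            r.model: {
                "cv_aucs": r.cv_aucs,
                "test_auc": r.test_auc,
                "roc_fpr": r.roc[0].tolist(),
                "roc_tpr": r.roc[1].tolist(),
            }
            for r in reports
        },
        "mean_test_auc": float(np.mean([r.test_auc for r in reports])),
        "pca_explained_variance_ratio": evr.tolist(),
    }
    (out / "screening.json").write_text(json.dumps(screening_payload, indent=1))
    coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
    outputs["screening"] = str(out / "screening.json")
    run_log["stages"]["screening"] = {
        "mean_test_auc": screening_payload["mean_test_auc"],
        "n_features": len(fs.features),
    }

    (out / "run_log.json").write_text(json.dumps(run_log, indent=1))
    outputs["run_log"] = str(out / "run_log.json")
    return outputs
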