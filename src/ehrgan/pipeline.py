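"""End-to-end orchestration.

Two entry points:

* :func:`run_ssl_experiment` — in-memory convenience chain used by the
  evaluation scripts and tests: scale → split → mask → graph → embed →
  adversarial training → test-set metrics (transductive: the graph and
  embedding cover all records, test labels are hidden from the learner).
* :func:`run_pipeline` — config-driven, file-based staged run with a
  manifest (config hash, per-stage seeds, timings, artifact checksums) and
  cache-hit skipping, backing the command-line interface.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate as ev
from . import gan as gan_mod
from .data import (FeatureSchema, ProcessedDataset, SplitSpec, mask_labels,
                   preprocess, read_processed, read_tabular_dataset,
                   split_train_test, write_processed, SchemaError)
from .embedding import (EmbeddingMatrix, LineConfig, assemble_gan_inputs,
                        read_embedding, train_line, write_embedding)
from .gan import GanConfig, TrainedGanModel, predict_proba, train
from .graph import build_patient_graph, read_edge_list, write_edge_list
from .synthetic import default_ehr_spec, generate_mixed_ehr

__all__ = ["run_ssl_experiment", "run_pipeline", "RunConfig", "unit_scale"]

# stage seeds fan out from the global seed by fixed offsets so each stage
# can be rerun in isolation
_STAGE_SEED_OFFSETS = {
    "simulate": 11, "split": 23, "mask": 37, "graph": 0, "embed": 53,
    "train": 71, "generate": 89, "privacy": 97,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1009 + _STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def unit_scale(X: np.ndarray) -> np.ndarray:
    """Min-max scale each column into [0, 1] (constant columns -> 0)."""
    X = np.asarray(X, dtype=np.float64)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return np.where(hi > lo, (X - lo) / span, 0.0)


def run_ssl_experiment(
    X, y, *, label_rate: float = 0.1, seed: int = 0,
    k: int = 10, lower_bound: float = 0.0,
    input_mode: str = "concat_features",
    line: LineConfig | None = None,
    gan: GanConfig | None = None,
    test_fraction: float = 0.2,
    binary_cols=None,
) -> dict:
    """Full semisupervised run on a numeric data matrix; returns a dict with
    the trained model, graph, embedding, test indices and test metrics.

    Records pruned from the graph as noise are scored with uniform class
    probabilities at evaluation time (they never reach the discriminator).
    """
    Xs = unit_scale(X)
    y = np.asarray(y, dtype=np.int64)
    M = int(y.max()) + 1
    ds = ProcessedDataset(X=Xs, y=y, mask=np.ones(len(y), dtype=bool), M=M,
                          binary_cols=list(binary_cols) if binary_cols is not None else [])
    split = SplitSpec(test_fraction=test_fraction, label_rate=label_rate,
                      seed=_stage_seed(seed, "split"))
    train_idx, test_idx = split_train_test(ds, split)

    masked = mask_labels(ds, label_rate, seed=_stage_seed(seed, "mask"))
    train_mask = masked.mask.copy()
    train_mask[test_idx] = False  # test labels are never visible to the learner

    g = build_patient_graph(Xs, k=k, lower_bound=lower_bound)
    d = ds.d
    line_cfg = line or LineConfig(dim=max(2, -(-d // 2)), seed=_stage_seed(seed, "embed"))
    emb = train_line(g, line_cfg)
    inputs = assemble_gan_inputs(replace(ds, mask=train_mask), emb, mode=input_mode)

    gan_cfg = gan or GanConfig(seed=_stage_seed(seed, "train"))
    if gan_cfg.seed == 0 and gan is not None:
        gan_cfg = replace(gan_cfg, seed=_stage_seed(seed, "train"))
    model = train(inputs.samples, inputs.y, inputs.mask, gan_cfg,
                  feature_dim=inputs.feature_dim, input_mode=input_mode)

    # score test records: rows present in the graph get discriminator
    # probabilities, pruned ones a uniform fallback
    row_of = {int(r): i for i, r in enumerate(inputs.index_map)}
    probs = np.full((len(test_idx), M), 1.0 / M)
    present = [t for t, rec in enumerate(test_idx) if int(rec) in row_of]
    if present:
        rows = [row_of[int(test_idx[t])] for t in present]
        probs[present] = predict_proba(model, inputs.samples[rows])
    metrics = ev.classification_metrics(y[test_idx], probs)
    metrics.label_rate = label_rate

    return {
        "dataset": ds, "graph": g, "embedding": emb, "inputs": inputs,
        "model": model, "train_idx": train_idx, "test_idx": test_idx,
        "train_mask": train_mask, "test_probs": probs, "metrics": metrics,
    }


# ---------------------------------------------------------------------
# config-driven staged pipeline
# ---------------------------------------------------------------------

_KNOWN_SECTIONS = {"simulate", "data", "split", "graph", "embedding", "gan",
                   "evaluation", "seed", "out_dir"}


class RunConfig(dict):
    """Validated nested run configuration (rejects unknown top-level keys)."""

    def __init__(self, mapping):
        unknown = set(mapping) - _KNOWN_SECTIONS
        if unknown:
            raise SchemaError(f"unknown config sections: {sorted(unknown)}")
        if "seed" not in mapping:
            raise SchemaError("config must declare a global seed")
        split = mapping.get("split", {})
        lr = split.get("label_rate", 0.1)
        if not 0 < lr <= 1:
            raise SchemaError(f"label_rate {lr} outside (0, 1]")
        super().__init__(mapping)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, force: bool = False) -> Path:
    """Execute simulate → preprocess → graph → embed → train → evaluate,
    writing every artifact plus ``manifest.json`` into the run directory.
    Stages whose outputs already exist are skipped unless ``force``.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig(config)
    out = Path(config.get("out_dir", "ehrgan_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {"config_hash": hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seed": seed, "stages": {}}

    def stage(name: str, outputs: list[Path], fn):
        t0 = time.perf_counter()
        if all(p.exists() for p in outputs) and not force:
            manifest["stages"][name] = {"cached": True,
                                        "artifacts": {p.name: _sha256(p) for p in outputs}}
            return
        fn()
        manifest["stages"][name] = {
            "cached": False, "seconds": round(time.perf_counter() - t0, 3),
            "artifacts": {p.name: _sha256(p) for p in outputs},
        }

    # ---- simulate / load ---------------------------------------------
    data_csv = out / "data.csv"
    schema_yaml = out / "schema.yaml"

    def do_simulate():
        sim = dict(config.get("simulate", {}))
        spec = default_ehr_spec(n=int(sim.get("n", 1000)),
                                seed=_stage_seed(seed, "simulate"))
        table, schema, _ = generate_mixed_ehr(spec)
        table.to_csv(data_csv, index=False)
        schema.to_yaml(schema_yaml)

    if "data" in config:
        data_csv = Path(config["data"]["csv"])
        schema_yaml = Path(config["data"]["schema"])
    else:
        stage("simulate", [data_csv, schema_yaml], do_simulate)

    # ---- preprocess ---------------------------------------------------
    proc_prefix = out / "processed"

    def do_preprocess():
        schema = FeatureSchema.from_yaml(schema_yaml)
        raw = read_tabular_dataset(data_csv, schema)
        ds = preprocess(raw, schema, dedupe=bool(config.get("data", {}).get("dedupe", False)))
        ds = mask_labels(ds, config.get("split", {}).get("label_rate", 0.1),
                         seed=_stage_seed(seed, "mask"))
        write_processed(ds, proc_prefix)

    stage("preprocess", [proc_prefix.with_suffix(".tsv"), proc_prefix.with_suffix(".json")],
          do_preprocess)

    # ---- graph --------------------------------------------------------
    edges_tsv, noise_txt = out / "edges.tsv", out / "noise_nodes.txt"

    def do_graph():
        ds = read_processed(proc_prefix)
        gcfg = config.get("graph", {})
        g = build_patient_graph(ds.X, k=int(gcfg.get("k", 10)),
                                lower_bound=float(gcfg.get("lower_bound", 0.0)))
        write_edge_list(g, edges_tsv)
        noise_txt.write_text("\n".join(map(str, g.noise_nodes)) + "\n")

    stage("graph", [edges_tsv, noise_txt], do_graph)

    # ---- embed --------------------------------------------------------
    emb_tsv = out / "embedding.tsv"

    def do_embed():
        ds = read_processed(proc_prefix)
        g = read_edge_list(edges_tsv)
        ecfg = dict(config.get("embedding", {}))
        ecfg.setdefault("dim", max(2, -(-ds.d // 2)))
        ecfg.setdefault("seed", _stage_seed(seed, "embed"))
        emb = train_line(g, LineConfig(**ecfg))
        write_embedding(emb, emb_tsv)

    stage("embed", [emb_tsv], do_embed)

    # ---- train --------------------------------------------------------
    model_npz, loss_tsv = out / "model.npz", out / "losses.tsv"

    def do_train():
        ds = read_processed(proc_prefix)
        emb = read_embedding(emb_tsv)
        gcfg = dict(config.get("gan", {}))
        mode = gcfg.pop("input_mode", "concat_features")
        gcfg.setdefault("seed", _stage_seed(seed, "train"))
        if "gen_layers" in gcfg:
            gcfg["gen_layers"] = tuple(gcfg["gen_layers"])
        if "disc_layers" in gcfg:
            gcfg["disc_layers"] = tuple(gcfg["disc_layers"])
        inputs = assemble_gan_inputs(ds, emb, mode=mode)
        model = train(inputs.samples, inputs.y, inputs.mask, GanConfig(**gcfg),
                      feature_dim=inputs.feature_dim, input_mode=mode)
        gan_mod.save_model(model, model_npz)
        rows = [vars(h) for h in model.history]
        pd.DataFrame(rows).to_csv(loss_tsv, sep="\t", index_label="epoch",
                                  float_format="%.10g")

    stage("train", [model_npz, loss_tsv], do_train)

    # ---- evaluate -----------------------------------------------------
    metrics_json = out / "metrics.json"

    def do_evaluate():
        ds = read_processed(proc_prefix)
        emb = read_embedding(emb_tsv)
        model = gan_mod.load_model(model_npz)
        inputs = assemble_gan_inputs(ds, emb, mode=model.input_mode)
        probs = predict_proba(model, inputs.samples)
        m = ev.classification_metrics(inputs.y, probs)
        metrics_json.write_text(json.dumps(
            {"auc": m.auc, "accuracy": m.accuracy, "recall": m.recall,
             "flags": m.flags}, indent=1))

    stage("evaluate", [metrics_json], do_evaluate)

    # ---- fidelity + privacy ------------------------------------------
    fidelity_json = out / "fidelity.json"
    privacy_json = out / "privacy.json"

    def do_fidelity():
        ds = read_processed(proc_prefix)
        model = gan_mod.load_model(model_npz)
        syn = gan_mod.generate_samples(model, ds.n, seed=_stage_seed(seed, "generate"))
        syn_feats = gan_mod.synthetic_feature_view(model, syn)
        rep = ev.dimensionwise_probability(ds.X, syn_feats, ds.binary_cols)
        fidelity_json.write_text(json.dumps(
            {"pairs": rep.probabilities, "mean_abs_dev": rep.mean_abs_dev,
             "correlation": rep.correlation}, indent=1))

    def do_privacy():
        ds = read_processed(proc_prefix)
        model = gan_mod.load_model(model_npz)
        syn = gan_mod.generate_samples(model, ds.n, seed=_stage_seed(seed, "generate"))
        syn_feats = gan_mod.synthetic_feature_view(model, syn)
        pcfg = config.get("evaluation", {})
        r_values = pcfg.get("r_values", [2, 5, 8])
        rep = ev.disclosure_curve(
            ds.X, syn_feats, r_values, binary_cols=ds.binary_cols,
            compromised_fraction=float(pcfg.get("compromised_fraction", 0.01)),
            k_attack=int(pcfg.get("k_attack", 1)),
            repeats=int(pcfg.get("repeats", 100)),
            seed=_stage_seed(seed, "privacy"))
        privacy_json.write_text(json.dumps(
            {"per_r": rep.per_r, "k_attack": rep.k_attack,
             "repeats": rep.n_repeats, "flags": rep.flags}, indent=1))

    stage("fidelity", [fidelity_json], do_fidelity)
    stage("privacy", [privacy_json], do_privacy)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
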