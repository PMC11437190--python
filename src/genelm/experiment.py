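"""Config-driven orchestration of the full study.

One call runs: corpus preparation (real gene table or synthetic Markov
corpus) -> length filter -> train/validation/test split -> n-gram family
fits -> optional neural training -> perplexity table -> mutation benchmark
-> comparison plots and a manifest of every seed used.  Re-running the same
config reproduces every table byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_io import (
    Corpus,
    FilterSpec,
    SplitSpec,
    corpus_stats,
    filter_by_length,
    load_gene_table,
    split_corpus,
    write_split_manifest,
)
from .mutation import MutationConfig, build_mutation_dataset, evaluate_accuracy
from .ngram import corpus_perplexity, fit_ngram
from .neural import (
    NeuralLMConfig,
    SelectionRule,
    build_model,
    count_parameters,
    neural_perplexity,
    restore_checkpoint,
    select_checkpoint,
    train,
)
from .synthetic import LengthLaw, default_length_law, generate_corpus, random_sim_spec

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Everything a run needs; every random draw traces to a seed listed here."""

    output_dir: str = "runs/experiment"
    data: dict[str, Any] = field(default_factory=lambda: {"synthetic": {"order": 2, "n_records": 500, "seed": 7}})
    filter: dict[str, Any] = field(default_factory=dict)
    split: dict[str, Any] = field(default_factory=dict)
    ngram: list[dict[str, Any]] = field(default_factory=lambda: [{"order": 2, "smoothing": "laplace"}])
    neural: list[dict[str, Any]] = field(default_factory=list)
    mutation: list[dict[str, Any]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _load_data(data_cfg: dict[str, Any]) -> Corpus:
    if "synthetic" in data_cfg:
        syn = dict(data_cfg["synthetic"])
        law_cfg = syn.pop("length_law", "lognormal")
        if law_cfg == "lognormal":
            law: LengthLaw | None = default_length_law()
        elif law_cfg in (None, "markov"):
            law = None
        elif isinstance(law_cfg, dict):
            law = LengthLaw(**law_cfg)
        else:
            raise ValueError(f"unknown length_law: {law_cfg!r}")
        spec = random_sim_spec(length_law=law, **syn)
        return generate_corpus(spec)
    if "path" in data_cfg:
        return load_gene_table(data_cfg["path"], format=data_cfg.get("format"))
    raise ValueError("data config needs either 'synthetic' or 'path'")


def run_experiment(config: ExperimentConfig, skip_neural: bool = False) -> dict[str, Any]:
    """Execute every configured stage; return paths and in-memory tables."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict[str, Any] = {"genelm_version": __version__, "config": asdict(config), "stages": {}}

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)
        manifest["stages"][name] = round(time.time() - t0, 2)

    # -- data ---------------------------------------------------------------
    stage("data")
    corpus = _load_data(config.data)
    if "path" in config.data:
        digest = hashlib.sha256(Path(config.data["path"]).read_bytes()).hexdigest()
        manifest["input_sha256"] = digest
    corpus = filter_by_length(corpus, FilterSpec(**config.filter))
    split_spec = SplitSpec(**config.split)
    train_c, val_c, test_c = split_corpus(corpus, split_spec)
    manifest["corpus"] = {
        "stats": corpus_stats(corpus),
        "n_train": len(train_c),
        "n_validation": len(val_c),
        "n_test": len(test_c),
        "split_seed": split_spec.seed,
    }
    write_split_manifest({"train": train_c, "validation": val_c, "test": test_c}, out / "split_manifest.csv")

    # -- models -------------------------------------------------------------
    stage("ngram")
    ppl_rows = []
    scorers: dict[str, Any] = {}
    for setting in config.ngram:
        model = fit_ngram(train_c, N=setting["order"], smoothing=setting.get("smoothing", "mle"))
        name = f"ngram{model.order}-{model.smoothing}"
        ppl_rows.append(
            {
                "model": name,
                "validation_perplexity": corpus_perplexity(model, val_c),
                "test_perplexity": corpus_perplexity(model, test_c),
            }
        )
        scorers[name] = model.score

    if config.neural and not skip_neural:
        stage("neural")
        for setting in config.neural:
            ncfg = NeuralLMConfig(**setting)
            model = build_model(ncfg)
            history = train(model, train_c, val_c, ncfg)
            best = select_checkpoint(history, SelectionRule())
            restore_checkpoint(model, history, best)
            name = f"{ncfg.architecture}-s{ncfg.seed}"
            ppl_rows.append(
                {
                    "model": name,
                    "validation_perplexity": history.epochs[best][1],
                    "test_perplexity": neural_perplexity(model, test_c),
                }
            )
            scorers[name] = model.score
            (out / f"{name}_history.json").write_text(
                json.dumps({"epochs": history.epochs, "selected_epoch": best + 1, "parameters": count_parameters(ncfg)})
                + "\n"
            )

    ppl_table = pd.DataFrame(ppl_rows)
    ppl_table.to_csv(out / "perplexity_table.csv", index=False, float_format="%.6f")

    # -- mutation benchmark ---------------------------------------------------
    acc_table = pd.DataFrame(columns=["model", "max_changes", "seed", "accuracy"])
    if config.mutation:
        stage("mutation")
        acc_rows = []
        for setting in config.mutation:
            seeds = setting.get("seeds", [setting.get("seed", 0)])
            for seed in seeds:
                mcfg = MutationConfig(
                    n_pairs=setting.get("n_pairs", 1000), max_changes=setting["max_changes"], seed=seed
                )
                pairs = build_mutation_dataset(test_c, mcfg)
                for name, scorer in scorers.items():
                    acc_rows.append(
                        {
                            "model": name,
                            "max_changes": mcfg.max_changes,
                            "seed": seed,
                            "accuracy": evaluate_accuracy(scorer, pairs),
                        }
                    )
        acc_table = pd.DataFrame(acc_rows)
        acc_table.to_csv(out / "accuracy_table.csv", index=False, float_format="%.6f")

    stage("plots")
    _plot_perplexity(ppl_table, out / "perplexity_comparison.png")
    if len(acc_table):
        _plot_accuracy(acc_table, out / "accuracy_comparison.png")

    stage("done")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"output_dir": str(out), "perplexity_table": ppl_table, "accuracy_table": acc_table, "manifest": manifest}


def _plot_perplexity(table: pd.DataFrame, path: Path) -> None:
    """Bar chart of test-set perplexity by model (finite values only)."""
    finite = table[np.isfinite(table["test_perplexity"])]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(finite["model"], finite["test_perplexity"], color="tab:blue")
    ax.set_ylabel("test set perplexity")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_accuracy(table: pd.DataFrame, path: Path) -> None:
    """Seed-averaged discrimination accuracy, grouped by max_changes."""
    mean = table.groupby(["model", "max_changes"])["accuracy"].mean().unstack()
    fig, ax = plt.subplots(figsize=(6, 4))
    mean.plot.bar(ax=ax)
    ax.set_ylabel("accuracy (mean over seeds)")
    ax.legend(title="max changes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
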