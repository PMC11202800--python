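"""End-to-end orchestration: simulate/load -> features -> split ->
balance -> select -> train -> evaluate.

One master seed fans out to per-stage seeds through a stable hash, so a
stage can be re-run in isolation and reproduce exactly what the full
pipeline did. Every artifact written to disk embeds the configuration
hash and the stage seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .balancing import balance
from .datamodel import (
    FeatureTable,
    read_residue_table,
    split_by_complex,
    write_feature_table,
)
from .emd import EMDConfig
from .errors import EcpdhError
from .features import build_feature_table
from .model_eval import (
    CVSummary,
    EvalReport,
    ModelConfig,
    evaluate,
    make_cv_evaluator,
    repeated_cv,
    train,
)
from .selection import mrmr_rank, mrmr_sfs
from .synthgen import SynthSpec, generate
from .wavelet import WaveletConfig


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    input_path: str | None = None  # residue table CSV; None -> simulate
    out_dir: str = "ecpdh_out"
    seed: int = 0
    n_test_complexes: int = 25
    balance_strategy: str = "smote-tomek"
    balance_seed: int = 74
    selection: str = "mrmr-sfs"  # mrmr-sfs | mrmr | none
    select_top_k: int = 20
    sfs_patience: int = 5
    cv_folds: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    emd: EMDConfig = field(default_factory=EMDConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    synth: SynthSpec = field(default_factory=SynthSpec)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (paths excluded, so the
        same analysis in a different directory hashes identically)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        payload.pop("input_path", None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _select_features(table: FeatureTable, config: PipelineConfig, seed: int) -> list[str]:
    if config.selection == "none":
        return table.feature_names
    if config.selection == "mrmr":
        return mrmr_rank(table, k=config.select_top_k)
    if config.selection == "mrmr-sfs":
        # a light linear evaluator keeps the wrapper search tractable;
        # the final model is still the boosted classifier
        evaluator = make_cv_evaluator(
            ModelConfig(backend="logistic", seed=config.model.seed),
            cv_folds=min(config.cv_folds, 5),
            seed=seed,
        )
        ranked_table = table.subset_columns(
            mrmr_rank(table, k=min(config.select_top_k * 2, len(table.feature_names)))
        )
        result = mrmr_sfs(ranked_table, evaluator, cv_folds=config.cv_folds,
                          patience=config.sfs_patience)
        return result.selected_subset
    raise EcpdhError(f"unknown selection strategy {config.selection!r}")


def run_pipeline(config: PipelineConfig) -> EvalReport:
    """Execute all stages and write artifacts under ``config.out_dir``.

    Returns the held-out evaluation report. Raises with a stage-tagged
    message on failure, removing partial outputs first.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = {
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "version": __version__,
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("simulate", "split", "balance", "select")
        },
    }
    stage = "simulate"
    try:
        if config.input_path is None:
            spec = dataclasses.replace(config.synth, seed=stage_seed(config.seed, "simulate"))
            records = generate(spec)
        else:
            records = read_residue_table(config.input_path)

        stage = "features"
        table = build_feature_table(records, emd_config=config.emd,
                                    wavelet_config=config.wavelet)
        fpath = out / "features.csv"
        write_feature_table(table, fpath)
        written.append(fpath)

        stage = "split"
        split = split_by_complex(table, config.n_test_complexes,
                                 seed=stage_seed(config.seed, "split"))
        train_table = table.subset_rows(split.train_indices)
        test_table = table.subset_rows(split.test_indices)

        stage = "balance"
        bal = balance(train_table.rows, train_table.labels,
                      config.balance_strategy, seed=config.balance_seed)
        bal_table = FeatureTable(
            table.schema, bal.rows, bal.labels,
            np.array(["_balanced_"] * len(bal.labels), dtype=object),
        )

        stage = "select"
        selected = _select_features(bal_table, config, stage_seed(config.seed, "select"))
        spath = out / "selection.json"
        spath.write_text(json.dumps({**meta, "selected_features": selected}, indent=1))
        written.append(spath)

        stage = "train"
        cols = [table.schema.index(n) for n in selected]
        model = train(bal.rows[:, cols], bal.labels, config.model)
        mpath = out / "model.pkl"
        with open(mpath, "wb") as fh:
            pickle.dump(model, fh)
        written.append(mpath)
        (out / "model.json").write_text(
            json.dumps({**meta, "model": dataclasses.asdict(config.model),
                        "selected_features": selected}, indent=1)
        )
        written.append(out / "model.json")

        stage = "evaluate"
        report = evaluate(model, test_table.rows[:, cols], test_table.labels)
        rpath = out / "report.json"
        rpath.write_text(json.dumps({**meta, "metrics": report.as_dict()}, indent=1))
        written.append(rpath)
        return report
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise EcpdhError(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_training_cv(
    config: PipelineConfig, table: FeatureTable, repeats: int = 5
) -> CVSummary:
    """Repeated stratified CV on a feature table with the pipeline's
    balancing and a per-fold mRMR selector, the leakage-safe way."""
    selector = None
    if config.selection != "none":
        selector = lambda t: mrmr_rank(t, k=min(config.select_top_k,
                                                len(t.feature_names)))
    return repeated_cv(
        table,
        config.model,
        folds=config.cv_folds,
        repeats=repeats,
        seed=stage_seed(config.seed, "cv"),
        balance_strategy=config.balance_strategy,
        balance_seed=config.balance_seed,
        selector=selector,
    )
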