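"""End-to-end run configuration and pipeline driver.

One ``RunConfig`` carries the settings of every stage (synthesis, I/O,
preprocessing, balancing, model, training); every stage seed derives
deterministically from the single master seed via named substreams, so a
run is reproducible regardless of how many random draws each stage makes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import dataio, preprocess, synth
from .balance import BalanceConfig
from .model.config import MsResConfig
from .train import TrainConfig, cross_validate, evaluate_model, train_model
from .model.network import build_model

__all__ = ["RunConfig", "parse_config", "run_pipeline", "derive_seed"]

logger = logging.getLogger("msres")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved settings of one pipeline run."""

    # data source: synthetic generation or an on-disk dataset directory
    data_dir: str | None = None
    synth: bool = True
    n_records: int = 200
    af_fraction: float = 771 / 8528  # emulated AF prevalence

    # preprocessing
    window_s: float = 9.0
    step_s: float = 9.0
    clip_s: float = 0.0
    normalize: bool = True

    # balancing
    balance: str = "smote"  # smote | borderline_smote | adasyn | none
    k_neighbors: int = 5
    sampling_strategy: float = 1.0
    balance_first: bool = False  # balance the whole population before splitting

    # model
    kernels: tuple[int, ...] = (5, 7, 9)
    blocks: int = 7
    filters: int = 32
    dense_units: tuple[int, ...] = (64, 32, 16)
    dropout: float = 0.25

    # training / evaluation
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 50
    optimizer: str = "adam"
    folds: int = 5  # 0 or 1 = single 8:2 hold-out split
    test_fraction: float = 0.2
    threshold: float = 0.5

    seed: int = 0
    out_dir: str = "runs/run"

    def model_config(self, input_len: int) -> MsResConfig:
        return MsResConfig(
            kernel_sizes=tuple(self.kernels), n_blocks=self.blocks, filters=self.filters,
            dense_units=tuple(self.dense_units), dropout=self.dropout, input_len=input_len,
        )

    def balance_config(self, seed: int) -> BalanceConfig | None:
        if self.balance == "none":
            return None
        return BalanceConfig(self.balance, self.k_neighbors, self.sampling_strategy, None, seed)

    def train_config(self, seed: int) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            epochs=self.epochs, optimizer=self.optimizer, seed=seed,
            threshold=self.threshold,
        )


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def derive_seed(master: int, stage: str) -> int:
    """Deterministic per-stage substream seed below 2**31."""
    ss = np.random.SeedSequence([master, sum(ord(c) for c in stage) + len(stage) * 1009])
    return int(ss.generate_state(1)[0] % (2**31))


def parse_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file plus flag overrides.

    Flag values win over file values; unknown keys, wrong types and invalid
    values raise ``ValueError`` naming the key.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        values.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            values[k] = v
    for key in values:
        if key not in _FIELDS:
            raise ValueError(f"unknown config key {key!r}")
    # normalize sequence fields
    for key in ("kernels", "dense_units"):
        if key in values:
            v = values[key]
            if isinstance(v, str):
                v = [int(x) for x in v.replace(",", " ").split()]
            values[key] = tuple(int(x) for x in v)
    cfg = RunConfig(**values)
    _validate(cfg)
    return cfg


def _validate(cfg: RunConfig) -> None:
    checks = [
        (cfg.n_records >= 0, "n_records must be >= 0"),
        (0 <= cfg.af_fraction <= 1, "af_fraction must lie in [0, 1]"),
        (cfg.window_s > 0 and cfg.step_s > 0, "window_s and step_s must be > 0"),
        (cfg.clip_s >= 0, "clip_s must be >= 0"),
        (cfg.balance in ("smote", "borderline_smote", "adasyn", "none"),
         f"unknown balance method {cfg.balance!r}"),
        (cfg.learning_rate > 0, "learning_rate must be > 0"),
        (cfg.batch_size >= 1, "batch_size must be >= 1"),
        (cfg.epochs >= 1, "epochs must be >= 1"),
        (cfg.optimizer in ("adam", "adadelta", "adagrad"),
         f"unknown optimizer {cfg.optimizer!r}"),
        (cfg.folds >= 0, "folds must be >= 0"),
        (0 < cfg.test_fraction < 1, "test_fraction must lie in (0, 1)"),
        (0 < cfg.threshold < 1, "threshold must lie in (0, 1)"),
    ]
    for ok, msg in checks:
        if not ok:
            raise ValueError(msg)
    MsResConfig(kernel_sizes=cfg.kernels, n_blocks=cfg.blocks, filters=cfg.filters,
                dense_units=cfg.dense_units, dropout=cfg.dropout)


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["kernels"] = list(d["kernels"])
    d["dense_units"] = list(d["dense_units"])
    return d


def run_pipeline(cfg: RunConfig) -> dict:
    """Run synth/load -> clip -> segment -> balance -> train -> evaluate.

    Writes the resolved config, a log, and the evaluation report into
    ``cfg.out_dir`` and returns the report dictionary.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=True)
    handler = logging.FileHandler(out / "log.txt")
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        # --- data ---------------------------------------------------------
        if cfg.data_dir is not None:
            records, table = dataio.load_dataset(cfg.data_dir)
            labels = table.binary()
        elif cfg.synth:
            n_af = int(round(cfg.n_records * cfg.af_fraction))
            recs = synth.generate_dataset(n_af, cfg.n_records - n_af,
                                          seed=derive_seed(cfg.seed, "synth"))
            records = [dataio.record_from_synthetic(r) for r in recs]
            labels = {r.name: r.label for r in recs}
        else:
            raise FileNotFoundError("no data_dir given and synthesis disabled")
        logger.info("stage=data n_records=%d", len(records))

        # --- preprocessing -------------------------------------------------
        segset = preprocess.segment_records(
            records, labels, cfg.window_s, cfg.step_s, cfg.clip_s, cfg.normalize
        )
        logger.info("stage=segment n_segments=%d counts=%s", len(segset), segset.class_counts())
        input_len = segset.window_samples
        model_cfg = cfg.model_config(input_len)

        # --- train / evaluate ----------------------------------------------
        if cfg.folds >= 2:
            result = cross_validate(
                segset, k=cfg.folds, model_config=model_cfg,
                train_config=cfg.train_config(derive_seed(cfg.seed, "train")),
                balance_config=cfg.balance_config(derive_seed(cfg.seed, "balance")),
                seed=derive_seed(cfg.seed, "folds"),
                balance_before_split=cfg.balance_first,
            )
            report = {
                "mode": f"{cfg.folds}-fold-cv",
                "mean": result.mean,
                "folds": [r.to_dict() for r in result.fold_reports],
                "excluded_folds": list(result.excluded_folds),
            }
        else:
            from .balance import balance_training_set

            bal_cfg = cfg.balance_config(derive_seed(cfg.seed, "balance"))
            if cfg.balance_first and bal_cfg is not None:
                X, y = balance_training_set(segset.matrix, segset.labels, bal_cfg)
                extra = len(X) - len(segset)
                segset = preprocess.SegmentSet(
                    X, y,
                    np.concatenate([segset.sources,
                                    np.array(["synthetic"] * extra, dtype=object)]),
                    np.concatenate([segset.starts, np.zeros(extra, dtype=np.int64)]),
                )
            train_set, test_set = preprocess.stratified_split(
                segset, cfg.test_fraction, seed=derive_seed(cfg.seed, "split")
            )
            X_tr, y_tr = train_set.matrix, train_set.labels
            if bal_cfg is not None and not cfg.balance_first:
                X_tr, y_tr = balance_training_set(X_tr, y_tr, bal_cfg)
            model = build_model(model_cfg, seed=derive_seed(cfg.seed, "init"))
            history = train_model(model, X_tr, y_tr,
                                  cfg.train_config(derive_seed(cfg.seed, "train")))
            ev = evaluate_model(model, test_set.matrix, test_set.labels, cfg.threshold)
            np.savez(out / "model.npz",
                     **{f"p{i}": p.data for i, p in enumerate(model.parameters())})
            report = {"mode": "holdout", "mean": {k: getattr(ev, k) for k in
                                                  ("precision", "recall", "accuracy", "f1")},
                      "holdout": ev.to_dict(), "history": history}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("stage=done mean=%s", report["mean"])
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
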