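"""End-to-end orchestration: generate/read -> extract -> split -> tune -> evaluate.

``RunConfig`` resolves every setting explicitly (no hidden defaults at run
time) and hashes its canonical JSON; every artifact written to disk embeds
that hash so mismatched artifacts are refused by downstream subcommands.
A fixed master seed yields byte-identical feature CSVs and reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import synth
from .classify import (
    EvaluationReport,
    GridSpec,
    SplitSpec,
    evaluate,
    grid_search,
    split_dataset,
    train_final,
)
from .errors import ArtifactMismatchError, ConfigError
from .features import (
    ExtractionConfig,
    anova_screen,
    anova_table,
    build_feature_matrix,
)
from .entropy import EntropyParams
from .signal_io import read_record

logger = logging.getLogger("ecgsubband")

_CONFIG_KEYS = {
    "source", "input_dir", "n_per_class", "duration_s", "fs",
    "wavelet_name", "levels", "mode",
    "entropy", "feature_family", "test_counts", "classifier", "standardize",
    "seed", "out_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Fully explicit run configuration."""

    source: str = "synth"  # "synth" or "dir"
    input_dir: str | None = None
    n_per_class: int = 50
    duration_s: float = 2.0
    fs: float = 250.0
    wavelet_name: str = "db4"
    levels: int = 5
    mode: str = "symmetric"
    entropy: EntropyParams = field(default_factory=EntropyParams)
    feature_family: str = "all"
    test_counts: dict = field(default_factory=lambda: {"AF": 12, "CHF": 14, "NSR": 12})
    classifier: str = "knn"
    standardize: bool = False
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if self.source not in ("synth", "dir"):
            raise ConfigError(f"source must be 'synth' or 'dir', got {self.source!r}")
        if self.source == "dir" and not self.input_dir:
            raise ConfigError("source 'dir' requires input_dir")
        if self.feature_family not in ("hjorth", "entropy", "all"):
            raise ConfigError(f"unknown feature family {self.feature_family!r}")
        if self.classifier not in ("knn", "svm", "rf", "ann", "rbfn"):
            raise ConfigError(f"unknown classifier {self.classifier!r}")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _CONFIG_KEYS if k != "entropy"}
        d["entropy"] = self.entropy.to_dict()
        return d

    def config_hash(self) -> str:
        # out_dir is provenance-neutral: the same experiment written to two
        # places must produce interchangeable artifacts
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def extraction_config(self) -> ExtractionConfig:
        return ExtractionConfig(
            wavelet_name=self.wavelet_name, levels=self.levels, mode=self.mode,
            entropy=self.entropy,
        )

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Flat key/value YAML document; unknown keys are errors."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "entropy" in raw:
            raw["entropy"] = EntropyParams(**raw["entropy"])
        raw.update(overrides)
        return cls(**raw)


def load_records(cfg: RunConfig) -> list:
    if cfg.source == "synth":
        return synth.generate_dataset(
            n_per_class=cfg.n_per_class, duration_s=cfg.duration_s, fs=cfg.fs,
            seed=cfg.seed,
        )
    manifest = Path(cfg.input_dir) / "manifest.csv"
    if not manifest.exists():
        raise ConfigError(f"no manifest.csv in {cfg.input_dir}")
    records = []
    for line in manifest.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        rec_id, label, fname = line.split(",")[:3]
        records.append(
            read_record(Path(cfg.input_dir) / fname, format="csv", fs=cfg.fs,
                        label=label, record_id=rec_id)
        )
    return records


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage (and record if known)."""


def run_experiment(cfg: RunConfig) -> EvaluationReport:
    """Execute the full pipeline; write artifacts if ``cfg.out_dir`` is set."""
    cfg.validate()
    chash = cfg.config_hash()
    out = Path(cfg.out_dir) if cfg.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(
            f"# config_hash: {chash}\n" + yaml.safe_dump(cfg.to_dict(), sort_keys=True)
        )

    stage = "load"
    try:
        logger.info("stage: load")
        records = load_records(cfg)
        logger.info("loaded %d records", len(records))

        stage = "extract"
        logger.info("stage: extract")
        fm = build_feature_matrix(records, cfg.extraction_config())
        fm.meta["config_hash"] = chash

        stage = "anova"
        screen = anova_screen(fm)
        if out:
            with open(out / "anova.csv", "w") as fh:
                fh.write(f"# config_hash: {chash}\n")
                anova_table(screen).to_csv(fh)

        fam = fm.subset(cfg.feature_family)
        if out:
            fam.to_csv(out / "features.csv")

        stage = "split"
        train, test = split_dataset(fam, SplitSpec(cfg.test_counts, seed=cfg.seed))
        logger.info("split: %d train / %d test", train.n_rows, test.n_rows)

        stage = "grid_search"
        gs = grid_search(train, GridSpec(cfg.classifier, cv_folds=5, seed=cfg.seed,
                                         standardize=cfg.standardize))
        if out:
            with open(out / "cv_table.csv", "w") as fh:
                fh.write(f"# config_hash: {chash}\n")
                gs.cv_table.to_csv(fh, index=False)

        stage = "train_final"
        model = train_final(train, cfg.classifier, gs.best_params, seed=cfg.seed,
                            standardize=cfg.standardize,
                            cv_accuracies=gs.cv_table.loc[
                                gs.cv_table["mean_accuracy"].idxmax(),
                                [c for c in gs.cv_table.columns if c.startswith("fold")],
                            ].tolist(),
                            config_hash=chash)

        stage = "evaluate"
        report = evaluate(model, test, feature_family=cfg.feature_family)
        report.config_hash = chash
        if out:
            (out / "report.txt").write_text(report.to_text())
            with open(out / "confusion.csv", "w") as fh:
                fh.write(f"# config_hash: {chash}\n")
                report.confusion.to_csv(fh)
        return report
    except (ConfigError, ArtifactMismatchError):
        raise
    except Exception as exc:
        raise PipelineStageError(f"stage {stage!r} failed: {exc}") from exc


def check_artifact_hash(path: str | Path, expected: str) -> None:
    """Refuse an artifact whose embedded config hash differs from ``expected``."""
    first = Path(path).read_text().splitlines()[0] if Path(path).exists() else ""
    found = None
    if "config_hash:" in first:
        found = first.split("config_hash:")[1].strip()
    if found != expected:
        raise ArtifactMismatchError(
            f"{path}: config hash {found!r} does not match expected {expected!r}"
        )
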