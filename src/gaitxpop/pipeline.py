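"""Reproducible end-to-end pipeline and report generation.

Stages: simulate -> preprocess -> window -> train/evaluate (within,
cross) -> compare -> report.  Every stage writes its outputs plus a
SHA-256 entry in ``manifest.json``; downstream stages verify their
inputs' hashes before use and refuse tampered intermediates.  A single
top-level seed (plus the fold seed) fully determines every artifact on
a fixed platform.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import evaluation, stats, synthetic, training, windowing
from .preprocessing import preprocess_recording
from .windowing import WindowConfig, WindowDataset

log = logging.getLogger("gaitxpop")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    seed: int = 0
    fold_seed: int = 0
    profiles: dict | None = None  # name -> PopulationProfile kwargs; None = study defaults
    gap_rate: float = 0.05  # gap starts per second
    tap_amplitude: float = 60.0
    max_gap: int = 5
    window_len: int = 200
    stride: int = 10
    scaled: bool = False  # desk-scale training profile
    epochs: int | None = None  # override; None = profile default
    width_multiplier: float | None = None  # override; None = profile default
    strategies: tuple[str, ...] = ("within", "cross")
    groups: tuple[str, ...] | None = None  # within-strategy groups; None = all
    outer_folds: tuple[int, ...] | None = None  # None = all five
    bootstrap_b: int = 10_000

    def resolve_profiles(self) -> dict[str, synthetic.PopulationProfile]:
        if self.profiles is None:
            return synthetic.default_profiles()
        out = {}
        for name, kwargs in self.profiles.items():
            kwargs = dict(kwargs)
            kwargs.setdefault("name", name)
            if "bout_duration_dist" in kwargs:
                kwargs["bout_duration_dist"] = tuple(kwargs["bout_duration_dist"])
            if "rom_mean" in kwargs:
                kwargs["rom_mean"] = dict(kwargs["rom_mean"])
            out[name] = synthetic.PopulationProfile(**kwargs)
        return out

    def train_config(self) -> training.TrainConfig:
        cfg = (training.scaled_config(seed=self.seed) if self.scaled
               else training.TrainConfig(seed=self.seed))
        if self.epochs is not None:
            cfg = dataclasses.replace(cfg, epochs=self.epochs)
        if self.width_multiplier is not None:
            cfg = dataclasses.replace(cfg, width_multiplier=self.width_multiplier)
        return cfg

    def window_config(self) -> WindowConfig:
        return WindowConfig(self.window_len, self.stride)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh)

    @staticmethod
    def load(path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("strategies", "groups", "outer_folds"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return ExperimentConfig(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class StageIntegrityError(RuntimeError):
    """An upstream artifact's hash does not match the manifest."""


class RunManifest:
    """Stage completion records with artifact hashes."""

    def __init__(self, out_dir: Path, config_hash: str):
        self.path = out_dir / "manifest.json"
        self.config_hash = config_hash
        if self.path.exists():
            with open(self.path) as fh:
                data = json.load(fh)
            if data.get("config_hash") == config_hash:
                self.stages = data["stages"]
            else:
                self.stages = {}
        else:
            self.stages = {}

    def record(self, stage: str, files: list[Path]) -> None:
        self.stages[stage] = {str(f.name): _sha256(f) for f in files}
        with open(self.path, "w") as fh:
            json.dump({"config_hash": self.config_hash,
                       "stages": self.stages}, fh, indent=1, sort_keys=True)

    def verify(self, stage: str, directory: Path) -> None:
        if stage not in self.stages:
            raise StageIntegrityError(f"stage '{stage}' has not run")
        for name, digest in self.stages[stage].items():
            f = directory / name
            if not f.exists() or _sha256(f) != digest:
                raise StageIntegrityError(
                    f"artifact '{name}' of stage '{stage}' is missing or "
                    "was modified after it was produced")

    def completed(self, stage: str, directory: Path) -> bool:
        try:
            self.verify(stage, directory)
            return True
        except StageIntegrityError:
            return False


def run_pipeline(config: ExperimentConfig, out_dir: str | Path,
                 resume: bool = True) -> Path:
    """Execute all stages; stages with intact outputs are skipped when
    resuming.  Returns the results directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    manifest = RunManifest(out, config.config_hash())
    data_dir = out / "data"
    win_dir = out / "windows"
    res_dir = out / "results"
    for d in (data_dir, win_dir, res_dir):
        d.mkdir(exist_ok=True)

    # -- simulate ------------------------------------------------------------
    if not (resume and manifest.completed("simulate", data_dir)):
        log.info("stage=simulate seed=%d", config.seed)
        recordings = synthetic.generate_dataset(
            config.resolve_profiles(), seed=config.seed,
            gap_rate=config.gap_rate, tap_amplitude=config.tap_amplitude)
        synthetic.write_dataset(recordings, data_dir)
        manifest.record("simulate", sorted(data_dir.glob("*.csv")))

    # -- preprocess + window -------------------------------------------------
    if not (resume and manifest.completed("window", win_dir)):
        manifest.verify("simulate", data_dir)
        log.info("stage=preprocess max_gap=%d", config.max_gap)
        recordings = synthetic.read_dataset(data_dir)
        cleaned, sidecars = [], []
        for rec in recordings:
            c, side = preprocess_recording(rec, max_gap=config.max_gap)
            cleaned.append(c)
            sidecars.append(side)
        with open(win_dir / "preprocess_sidecars.json", "w") as fh:
            json.dump(sidecars, fh, indent=1)
        log.info("stage=window len=%d stride=%d",
                 config.window_len, config.stride)
        tcfg = config.train_config()
        ds = windowing.windows_from_recordings(
            cleaned, config.window_config(),
            max_windows_per_participant=tcfg.max_windows_per_participant)
        ds.save(win_dir / "windows.h5")
        manifest.record("window", [win_dir / "windows.h5",
                                   win_dir / "preprocess_sidecars.json"])

    # -- train + evaluate ----------------------------------------------------
    metrics_path = res_dir / "metrics.csv"
    if not (resume and manifest.completed("evaluate", res_dir)):
        manifest.verify("window", win_dir)
        ds = WindowDataset.load(win_dir / "windows.h5")
        data_manifest = pd.read_csv(data_dir / "manifest.csv")
        assignment = training.assign_folds(data_manifest,
                                           seed=config.fold_seed)
        assignment.save(out / "folds.json")
        tcfg = config.train_config()
        outer = list(config.outer_folds or range(1, assignment.k + 1))
        records: list[evaluation.MetricRecord] = []
        histories = []
        for strategy in config.strategies:
            scopes = ([None] if strategy == "cross"
                      else list(config.groups or assignment.group_names()))
            for group in scopes:
                for test_fold in outer:
                    log.info("stage=train strategy=%s group=%s fold=%d",
                             strategy, group, test_fold)
                    run = training.run_strategy_outer_fold(
                        ds, assignment, tcfg, strategy, test_fold, group)
                    records += evaluation.compute_metrics(
                        run["predictions"], run["truths"],
                        run["provenance"], strategy)
                    for res in run["results"]:
                        h = res.history.assign(
                            strategy=strategy, group=str(group),
                            test_fold=test_fold, val_fold=res.plan.val_fold,
                            seed=res.seed)
                        histories.append(h)
        evaluation.metrics_frame(records).to_csv(metrics_path, index=False)
        pd.concat(histories, ignore_index=True).to_csv(
            res_dir / "loss_curves.csv", index=False)
        evaluation.aggregate_group(records).to_csv(
            res_dir / "group_tables.csv", index=False)
        manifest.record("evaluate", [metrics_path,
                                     res_dir / "loss_curves.csv",
                                     res_dir / "group_tables.csv"])

    # -- compare -------------------------------------------------------------
    if not (resume and manifest.completed("compare", res_dir)):
        manifest.verify("evaluate", res_dir)
        mdf = pd.read_csv(metrics_path)
        comparison_files = [res_dir / "deltas.csv"]
        if {"within", "cross"} <= set(mdf["strategy"].unique()):
            deltas = _deltas_from_frame(mdf)
            deltas.to_csv(res_dir / "deltas.csv", index=False)
            # groups need >= 2 paired participants for a CI; skip the rest
            sizes = deltas.groupby("group").size()
            testable = deltas[deltas["group"].isin(sizes[sizes >= 2].index)]
            if len(testable):
                comps = stats.compare_strategies(
                    testable, b=config.bootstrap_b, seed=config.seed)
                stats.comparisons_frame(comps).to_csv(
                    res_dir / "comparisons.csv", index=False)
                comparison_files.append(res_dir / "comparisons.csv")
            else:
                log.warning("stage=compare: too few paired participants, "
                            "comparison table omitted")
        else:
            pd.DataFrame(columns=["participant_id", "group", "delta_mae",
                                  "delta_r"]).to_csv(res_dir / "deltas.csv",
                                                     index=False)
        boxes = _boxplot_summary(mdf)
        with open(res_dir / "boxplots.json", "w") as fh:
            json.dump(boxes, fh, indent=1)
        comparison_files.append(res_dir / "boxplots.json")
        manifest.record("compare", comparison_files)

    # -- report --------------------------------------------------------------
    report = make_report(res_dir)
    (out / "report.md").write_text(report)
    manifest.record("report", [out / "report.md"])
    return res_dir


def _deltas_from_frame(mdf: pd.DataFrame) -> pd.DataFrame:
    pivot = mdf.pivot_table(index=["participant_id", "group"],
                            columns="strategy",
                            values=["mae_avg", "r_avg"])
    out = pd.DataFrame({
        "participant_id": pivot.index.get_level_values(0),
        "group": pivot.index.get_level_values(1),
        "delta_mae": (pivot[("mae_avg", "cross")]
                      - pivot[("mae_avg", "within")]).to_numpy(),
        "delta_r": (pivot[("r_avg", "cross")]
                    - pivot[("r_avg", "within")]).to_numpy(),
    }).dropna().sort_values("participant_id").reset_index(drop=True)
    return out


def _boxplot_summary(mdf: pd.DataFrame) -> dict:
    out: dict = {}
    for (group, strategy), gdf in mdf.groupby(["group", "strategy"]):
        for metric, col in (("MAE", "mae_avg"), ("R", "r_avg")):
            vals = gdf[col].dropna().to_numpy()
            if len(vals) == 0:
                continue
            bs = evaluation.boxplot_stats(vals)
            out.setdefault(group, {}).setdefault(strategy, {})[metric] = {
                "median": bs.median, "q1": bs.q1, "q3": bs.q3,
                "iqr": bs.iqr, "whisker_low": bs.whisker_low,
                "whisker_high": bs.whisker_high,
                "outliers": list(bs.outliers), "n": int(len(vals))}
    return out


def make_report(res_dir: str | Path) -> str:
    """Render the results directory into a markdown report; missing
    pieces are reported as explicit gaps."""
    res_dir = Path(res_dir)
    lines = ["# Within- vs cross-population joint-angle estimation", ""]

    def table(df: pd.DataFrame) -> list[str]:
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "---|" * len(df.columns)
        rows = ["| " + " | ".join(
            f"{v:.3f}" if isinstance(v, float) else str(v) for v in row)
            + " |" for row in df.itertuples(index=False)]
        return [header, sep, *rows, ""]

    gt = res_dir / "group_tables.csv"
    if gt.exists():
        lines += ["## Group-level joint metrics", ""]
        lines += table(pd.read_csv(gt).round(3))
    else:
        lines += ["## Group-level joint metrics", "", "_not available_", ""]

    dl = res_dir / "deltas.csv"
    if dl.exists() and len(df_d := pd.read_csv(dl)):
        lines += ["## Per-participant Δ (cross − within)", ""]
        lines += table(df_d.round(3))
    else:
        lines += ["## Per-participant Δ (cross − within)", "",
                  "_not available (needs both strategies)_", ""]

    cp = res_dir / "comparisons.csv"
    if cp.exists():
        lines += ["## Paired statistical comparison", ""]
        lines += table(pd.read_csv(cp).round(4))
    else:
        lines += ["## Paired statistical comparison", "", "_not available_", ""]

    bx = res_dir / "boxplots.json"
    if bx.exists():
        lines += ["## Distribution summaries (Tukey boxplot statistics)", "",
                  "```json", (res_dir / "boxplots.json").read_text(), "```", ""]
    return "\n".join(lines)
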