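"""Experiment orchestration: generation -> preprocessing -> splits ->
training -> evaluation -> method comparison.

An experiment is described by a YAML/JSON config (see
:func:`load_experiment`); every command reads and writes documented file
formats under the experiment's output directory so partial runs can resume
from on-disk state.  All randomness flows from the global seed; method- and
fold-level seeds are derived with ``numpy.random.SeedSequence`` and stay
below 2**31.
"""

from __future__ import annotations

import json
import resource
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .evaluation import (aggregate, evaluate_pair, export_report, lesion_size_analysis,
                         overlay_png, weighted_mean)
from .models import Model, ModelConfig, build_model, count_macs, count_parameters
from .phantom import PhantomSpec, generate_dataset, load_record, save_mask_png
from .preprocess import ClaheParams, augment_rotation, preprocess_scan
from .splits import FoldSplit, stratified_patient_kfold
from .training import TrainConfig, run_hpt, train


@dataclass
class ExperimentConfig:
    seed: int = 0
    output_dir: str = "runs/experiment"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    methods: list = field(default_factory=list)  # [ModelConfig]
    train: dict = field(default_factory=dict)  # method name -> TrainConfig
    preprocess: dict = field(default_factory=dict)
    k_folds: int = 5
    val_fraction: float = 0.2
    augment: bool = True

    def __post_init__(self):
        names = [m.name for m in self.methods]
        if len(names) != len(set(names)):
            raise ValueError(f"method names must be unique, got {names}")

    @property
    def out(self) -> Path:
        return Path(self.output_dir)

    def train_config(self, method: str) -> TrainConfig:
        return self.train.get(method, self.train.get("default", TrainConfig()))

    def dump(self, path):
        doc = {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "phantom": asdict(self.phantom),
            "methods": [asdict(m) for m in self.methods],
            "train": {k: asdict(v) for k, v in self.train.items()},
            "preprocess": self.preprocess,
            "k_folds": self.k_folds,
            "val_fraction": self.val_fraction,
            "augment": self.augment,
        }
        Path(path).write_text(yaml.safe_dump(doc, default_flow_style=False))


def load_experiment(path) -> ExperimentConfig:
    doc = yaml.safe_load(Path(path).read_text())
    return experiment_from_dict(doc)


def experiment_from_dict(doc: dict) -> ExperimentConfig:
    phantom = PhantomSpec(**{k: tuple(v) if k == "class_probs" else v
                             for k, v in doc.get("phantom", {}).items()})
    methods = [ModelConfig.from_dict(m) for m in doc.get("methods", [])]
    train_cfgs = {k: TrainConfig(**v) for k, v in doc.get("train", {}).items()}
    return ExperimentConfig(
        seed=int(doc.get("seed", 0)),
        output_dir=doc.get("output_dir", "runs/experiment"),
        phantom=phantom,
        methods=methods,
        train=train_cfgs,
        preprocess=doc.get("preprocess", {}),
        k_folds=int(doc.get("k_folds", 5)),
        val_fraction=float(doc.get("val_fraction", 0.2)),
        augment=bool(doc.get("augment", True)),
    )


def derived_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# pipeline stages


def cmd_generate(cfg: ExperimentConfig) -> pd.DataFrame:
    ds_dir = cfg.out / "dataset"
    manifest_path = ds_dir / "manifest.csv"
    if manifest_path.exists():
        return pd.read_csv(manifest_path)
    spec = PhantomSpec(**{**asdict(cfg.phantom), "seed": derived_seed(cfg.seed, 1)})
    return generate_dataset(spec, ds_dir)


def cmd_preprocess(cfg: ExperimentConfig) -> pd.DataFrame:
    """Run the preprocessing chain over the generated dataset."""
    ds_dir = cfg.out / "dataset"
    proc_dir = cfg.out / "processed"
    out_manifest = proc_dir / "manifest.csv"
    if out_manifest.exists():
        return pd.read_csv(out_manifest)
    manifest = pd.read_csv(ds_dir / "manifest.csv")
    pp = cfg.preprocess
    clahe_params = ClaheParams(**pp.get("clahe", {}))
    target = int(pp.get("target_size", 224))
    for sub in ("images", "masks", "sidecars"):
        (proc_dir / sub).mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        image, mask, layers = load_record(ds_dir, row)
        img, msk, sidecar = preprocess_scan(
            image, mask, layers.ilm, layers.bm.astype(float), rpe_line=layers.rpe,
            axial_resolution=cfg.phantom.axial_resolution,
            offset_um=float(pp.get("offset_um", 390.0)),
            bm_degree=int(pp.get("bm_degree", 2)),
            clahe_params=clahe_params,
            anchor_fraction=float(pp.get("anchor_fraction", 0.65)),
            target_size=target,
        )
        stem = Path(row["image_path"]).stem
        Image.fromarray(img, mode="L").save(proc_dir / "images" / f"{stem}.png")
        save_mask_png(msk, proc_dir / "masks" / f"{stem}.png")
        (proc_dir / "sidecars" / f"{stem}.json").write_text(json.dumps(sidecar))
        new = dict(row)
        new["image_path"] = f"images/{stem}.png"
        new["mask_path"] = f"masks/{stem}.png"
        rows.append(new)
    out = pd.DataFrame(rows)
    out.to_csv(out_manifest, index=False)
    return out


def cmd_split(cfg: ExperimentConfig) -> FoldSplit:
    path = cfg.out / "splits.csv"
    manifest = pd.read_csv(cfg.out / "dataset" / "manifest.csv")
    if path.exists():
        return FoldSplit.load(path)
    split = stratified_patient_kfold(manifest, k=cfg.k_folds,
                                     seed=derived_seed(cfg.seed, 2),
                                     val_fraction=cfg.val_fraction)
    split.save(path)
    return split


def load_arrays(cfg: ExperimentConfig):
    """(images, targets, patient_ids) of the preprocessed dataset."""
    proc_dir = cfg.out / "processed"
    manifest = pd.read_csv(proc_dir / "manifest.csv")
    imgs, msks, pids = [], [], []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(proc_dir / row["image_path"]), dtype=np.float32) / 255.0
        msk = np.asarray(Image.open(proc_dir / row["mask_path"]), dtype=np.int64)
        imgs.append(img)
        msks.append(msk)
        pids.append(row["patient_id"])
    return np.stack(imgs)[:, None], np.stack(msks), np.array(pids)


def _rotation_augment(max_degrees=20.0, probability=0.5):
    def fn(xb, yb, rng):
        xs, ys = [], []
        for i in range(xb.shape[0]):
            img, msk = augment_rotation(xb[i, 0], yb[i], rng,
                                        max_degrees=max_degrees, probability=probability)
            xs.append(img)
            ys.append(msk)
        return np.stack(xs)[:, None].astype(np.float32), np.stack(ys)
    return fn


def _fold_data(cfg, fold_idx):
    split = cmd_split(cfg)
    x, y, pids = load_arrays(cfg)
    roles = split.folds[fold_idx]
    sel = lambda ps: np.isin(pids, list(ps))
    return {role: (x[sel(roles[role])], y[sel(roles[role])]) for role in ("train", "val", "test")}


def cmd_train(cfg: ExperimentConfig, method: str, fold: int):
    """Train one method on one outer fold; resumable via the checkpoint."""
    mdir = cfg.out / "models" / method
    mdir.mkdir(parents=True, exist_ok=True)
    ckpt = mdir / f"fold{fold}.npz"
    if ckpt.exists():
        return Model.load(ckpt), pd.read_csv(mdir / f"fold{fold}_history.csv")
    mconf = next(m for m in cfg.methods if m.name == method)
    data = _fold_data(cfg, fold)
    tc = cfg.train_config(method)
    tc = TrainConfig(**{**asdict(tc), "seed": derived_seed(cfg.seed, 3, fold)})
    model = build_model(mconf, seed=derived_seed(cfg.seed, 4, fold))
    aug = _rotation_augment() if cfg.augment else None
    t0 = time.perf_counter()
    hist = train(model, data["train"], data["val"], tc, augment_fn=aug)
    wall = time.perf_counter() - t0
    model.save(ckpt)
    df = hist.to_frame()
    df.to_csv(mdir / f"fold{fold}_history.csv", index=False)
    meta = {"best_epoch": hist.best_epoch, "best_val_loss": hist.best_val_loss,
            "wall_time_s": wall, "stopped_early": hist.stopped_early,
            "max_rss_kb": resource.getrusage(resource.RUSAGE_SELF).ru_maxrss,
            "train_config": asdict(tc)}
    (mdir / f"fold{fold}_meta.json").write_text(json.dumps(meta, indent=2))
    return model, df


def cmd_evaluate(cfg: ExperimentConfig, method: str, fold: int) -> pd.DataFrame:
    """Evaluate a trained method on its outer-fold test patients."""
    mdir = cfg.out / "models" / method
    model = Model.load(mdir / f"fold{fold}.npz")
    data = _fold_data(cfg, fold)
    x_te, y_te = data["test"]
    records = []
    for i in range(x_te.shape[0]):
        pred = model.predict(x_te[i : i + 1])[0]
        records.extend(evaluate_pair(y_te[i], pred, image_id=f"fold{fold}_img{i}"))
    agg = aggregate(records)
    rdir = cfg.out / "reports" / method / f"fold{fold}"
    try:
        size_df = lesion_size_analysis(records)
    except ValueError:
        size_df = None
    export_report(rdir, records, agg, size_df)
    out = agg.to_frame()
    out.insert(0, "fold", fold)
    out.insert(0, "method", method)
    return out


def cmd_hpt(cfg: ExperimentConfig, method: str, stage: int, fold: int = 0) -> pd.DataFrame:
    """One stage of the 3-stage manual search on the fold's inner split."""
    mconf = next(m for m in cfg.methods if m.name == method)
    data = _fold_data(cfg, fold)
    base = cfg.train_config(method)
    prev_path = cfg.out / "hpt" / method / f"stage{stage - 1}_winner.json"
    if stage > 1 and prev_path.exists():
        base = TrainConfig(**json.loads(prev_path.read_text()))
    table, winner = run_hpt(lambda seed: build_model(mconf, seed=seed),
                            data["train"], data["val"], base, stage)
    hdir = cfg.out / "hpt" / method
    hdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(hdir / f"stage{stage}.csv", index=False)
    (hdir / f"stage{stage}_winner.json").write_text(json.dumps(asdict(winner), indent=2))
    return table


def cmd_compare(cfg: ExperimentConfig) -> pd.DataFrame:
    """All methods over all outer folds: Table-style per-class Dice report
    plus architecture efficiency metrics."""
    cmd_generate(cfg)
    cmd_preprocess(cfg)
    cfg.out.mkdir(parents=True, exist_ok=True)
    cfg.dump(cfg.out / "experiment.yaml")  # provenance
    per_fold = []
    efficiency = []
    for mconf in cfg.methods:
        t0 = time.perf_counter()
        for fold in range(cfg.k_folds):
            cmd_train(cfg, mconf.name, fold)
            per_fold.append(cmd_evaluate(cfg, mconf.name, fold))
        model = build_model(mconf, seed=0)
        efficiency.append({
            "method": mconf.name,
            "n_params": count_parameters(model),
            "macs": count_macs(model),
            "wall_time_s_non_normative": time.perf_counter() - t0,
            "max_rss_kb_non_normative": resource.getrusage(resource.RUSAGE_SELF).ru_maxrss,
        })
    fold_df = pd.concat(per_fold, ignore_index=True)
    fold_df.to_csv(cfg.out / "compare_folds.csv", index=False)
    eff_df = pd.DataFrame(efficiency)
    eff_df.to_csv(cfg.out / "efficiency.csv", index=False)

    rows = []
    for method in fold_df["method"].unique():
        sub = fold_df[fold_df["method"] == method]
        for cls in sub["class"].unique():
            cc = sub[sub["class"] == cls]
            rows.append({"method": method, "class": cls,
                         "dice_mean": cc["dice_mean"].mean(),
                         "dice_std": cc["dice_mean"].std(ddof=0),
                         "sensitivity_mean": cc["sensitivity_mean"].mean(),
                         "specificity_mean": cc["specificity_mean"].mean()})
    summary = pd.DataFrame(rows)
    summary.to_csv(cfg.out / "compare_summary.csv", index=False)
    return summary


def cmd_report(cfg: ExperimentConfig, n_overlays: int = 4):
    """Qualitative overlays (reference vs prediction) for a few test scans."""
    odir = cfg.out / "overlays"
    odir.mkdir(parents=True, exist_ok=True)
    x, y, pids = load_arrays(cfg)
    for mconf in cfg.methods:
        ckpt = cfg.out / "models" / mconf.name / "fold0.npz"
        if not ckpt.exists():
            continue
        model = Model.load(ckpt)
        data = _fold_data(cfg, 0)
        x_te, y_te = data["test"]
        for i in range(min(n_overlays, x_te.shape[0])):
            img8 = np.round(x_te[i, 0] * 255).astype(np.uint8)
            pred = model.predict(x_te[i : i + 1])[0]
            overlay_png(img8, y_te[i], odir / f"{mconf.name}_img{i}_ref.png")
            overlay_png(img8, pred, odir / f"{mconf.name}_img{i}_pred.png")
    return odir
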