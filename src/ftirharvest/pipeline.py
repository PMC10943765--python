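"""End-to-end orchestration: simulate -> preprocess -> split -> models ->
phenotype report.

A :class:`RunConfig` fixes every stage's parameters and one global seed;
per-stage seeds are derived deterministically from it (SeedSequence spawn
keyed by stage order), so two runs with the same config produce identical
reports.  Each completed stage leaves a marker with a config checksum;
re-running with the same output directory skips stages whose marker and
checksum are intact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cos, phenotype
from .gasvm import GASVMClassifier, SvmConfig
from .pls import PLSDA, PLSR, select_factors
from .preprocess import PreprocessSpec, apply_preprocess, kennard_stone_split
from .resnet import ResNetClassifier, ResNetConfig
from .simulate import SimConfig, generate_linked_dataset
from .spectra import average_replicates, write_spectra

log = logging.getLogger("ftirharvest.pipeline")

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "preprocess", "plsda", "svm", "cos_images", "resnet",
          "plsr", "phenotype")


@dataclass
class RunConfig:
    """Pipeline settings; any stage can be dropped from ``stages``."""

    out_dir: str = "runs/default"
    seed: int = 0
    stages: tuple = STAGES

    sim: SimConfig | None = None
    part: str = "stem"

    plsda_method: str = "sd"
    plsda_n_lv: int = 12
    plsda_permutations: int = 200
    train_fraction: float = 0.7
    cv_folds: int = 7

    svm: SvmConfig | None = None

    resnet: ResNetConfig | None = None
    image_size: int = 64
    cos_which: str = "phi"
    cos_augment: int = 0

    plsr_method: dict = field(default_factory=lambda: {"stem": "msc", "leaf": "sg"})
    plsr_max_factors: int = 15

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
            if isinstance(o, pd.DataFrame):
                return o.to_csv()
            if isinstance(o, (np.ndarray, tuple, list)):
                return [enc(v) for v in o]
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            return o
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(cfg: RunConfig, stage: str) -> int:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2 ** 31))


class _Runner:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.hash = cfg.config_hash()

    def done(self, stage: str) -> bool:
        marker = self.out / f".{stage}.done"
        if marker.exists() and marker.read_text().strip() == self.hash:
            log.info("stage %s: up to date, skipping", stage)
            return True
        return False

    def mark(self, stage: str) -> None:
        (self.out / f".{stage}.done").write_text(self.hash)
        log.info("stage %s: complete", stage)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    r = _Runner(cfg)
    cfg.sim = cfg.sim or SimConfig(seed=_stage_seed(cfg, "simulate"))
    log.info("run directory %s (config %s, seed %d)", r.out, r.hash, cfg.seed)

    spectra, traits, env = generate_linked_dataset(cfg.sim)
    if "simulate" in cfg.stages and not r.done("simulate"):
        write_spectra(spectra, r.out / "spectra.csv", r.out / "spectra_meta.csv")
        traits.to_csv(r.out / "traits.csv", index=False)
        env.to_csv(r.out / "environment.csv", index=False)
        r.mark("simulate")

    averaged = average_replicates(spectra)
    part_mask = (averaged.meta["part"] == cfg.part).to_numpy()
    part_set = averaged.select(part_mask)

    if "preprocess" in cfg.stages and not r.done("preprocess"):
        pre = apply_preprocess(part_set, PreprocessSpec(method=cfg.plsda_method))
        split = kennard_stone_split(pre.absorbance, cfg.train_fraction)
        subset = np.full(pre.n_spectra, "test", dtype=object)
        subset[split.train_indices] = "train"
        pd.DataFrame({"row_id": np.arange(pre.n_spectra), "subset": subset}).to_csv(
            r.out / "split.csv", index=False)
        r.mark("preprocess")

    pre = apply_preprocess(part_set, PreprocessSpec(method=cfg.plsda_method))
    labels = pre.meta["month"].to_numpy()
    split = kennard_stone_split(pre.absorbance, cfg.train_fraction)
    tr, te = split.train_indices, split.test_indices

    if "plsda" in cfg.stages and not r.done("plsda"):
        res = PLSDA(pre.absorbance[tr], labels[tr]).fit(cfg.plsda_n_lv)
        rep = res.evaluate(pre.absorbance[te], labels[te], cv_folds=cfg.cv_folds)
        perm = res.permutation_test(cfg.plsda_permutations,
                                    seed=_stage_seed(cfg, "plsda"),
                                    cv_folds=cfg.cv_folds)
        pd.DataFrame([{
            "Style": f"{cfg.plsda_method.upper()}-{cfg.part[0].upper()}",
            "LVs": rep.n_lv, "R2": rep.r2, "Q2": rep.q2, "RMSEE": rep.rmsee,
            "RMSECV": rep.rmsecv, "RMSEP": rep.rmsep,
            "Accuracy of training test (%)": rep.accuracy_train,
            "Accuracy of testing test (%)": rep.accuracy_test,
            "Q2 permuted 95th pct": perm.q2_quantile(0.95),
        }]).to_csv(r.out / "plsda_report.csv", index=False)
        r.mark("plsda")

    if "svm" in cfg.stages and not r.done("svm"):
        svm_cfg = cfg.svm or SvmConfig(seed=_stage_seed(cfg, "svm"))
        res = GASVMClassifier(pre.absorbance[tr], labels[tr],
                              pre.absorbance[te], labels[te], svm_cfg).fit()
        pd.DataFrame([{
            "c": res.c, "g": res.g,
            "Accuracy of training test (%)": res.accuracy_train,
            "Accuracy of testing test (%)": res.accuracy_test,
        }]).to_csv(r.out / "svm_report.csv", index=False)
        r.mark("svm")

    if "cos_images" in cfg.stages and not r.done("cos_images"):
        img_dir = r.out / "cos_images"
        img_dir.mkdir(exist_ok=True)
        seed0 = _stage_seed(cfg, "cos_images")
        for i, (_, row) in enumerate(part_set.meta.drop_duplicates(
                ["month", "part", "sample_id"]).iterrows()):
            key = (row["month"], row["part"], row["sample_id"])
            maps = cos.cos_for_sample(spectra, key, augmentation=cfg.cos_augment,
                                      seed=seed0 + i)
            cls_dir = img_dir / f"month_{row['month']:02d}"
            cls_dir.mkdir(exist_ok=True)
            cos.render_cos_image(maps, which=cfg.cos_which, size_px=cfg.image_size,
                                 path=cls_dir / f"{row['sample_id']}.png")
        r.mark("cos_images")

    if "resnet" in cfg.stages and not r.done("resnet"):
        rs_cfg = cfg.resnet or ResNetConfig(seed=_stage_seed(cfg, "resnet"))
        keys = part_set.meta.drop_duplicates(["month", "part", "sample_id"])
        seed0 = _stage_seed(cfg, "cos_images")
        images, lab = [], []
        for i, (_, row) in enumerate(keys.iterrows()):
            key = (row["month"], row["part"], row["sample_id"])
            maps = cos.cos_for_sample(spectra, key, augmentation=cfg.cos_augment,
                                      seed=seed0 + i)
            images.append(cos.render_cos_image(maps, which=cfg.cos_which,
                                               size_px=cfg.image_size))
            lab.append(row["month"])
        res = ResNetClassifier(np.stack(images), np.array(lab), rs_cfg).fit()
        res.curve.to_csv(r.out / "resnet_curve.csv", index=False)
        pd.DataFrame([{
            "best_epoch": res.best_epoch,
            "Accuracy of training test (%)": res.accuracy_train,
            "Accuracy of testing test (%)": res.accuracy_test,
            "Accuracy of external validation (%)": res.accuracy_external,
        }]).to_csv(r.out / "resnet_report.csv", index=False)
        r.mark("resnet")

    if "plsr" in cfg.stages and not r.done("plsr"):
        rows = []
        for part in ("stem", "leaf"):
            mask = (averaged.meta["part"] == part).to_numpy()
            sub = averaged.select(mask)
            method = cfg.plsr_method.get(part, "raw")
            x = apply_preprocess(sub, PreprocessSpec(method=method)).absorbance
            col = "X6" if part == "stem" else "X7"
            y = traits.set_index("sample_id").loc[sub.meta["sample_id"], col].to_numpy()
            sp = kennard_stone_split(x, cfg.train_fraction)
            k = select_factors(x[sp.train_indices], y[sp.train_indices],
                               max_factors=cfg.plsr_max_factors, cv_folds=cfg.cv_folds)
            res = PLSR(x[sp.train_indices], y[sp.train_indices]).fit(k)
            rep = res.evaluate(x[sp.test_indices], y[sp.test_indices])
            rows.append({"Parts": part, "Pretreatment methods": method.upper(),
                         "Factors": rep.factors, "Slope": rep.slope,
                         "RMSE": rep.rmse, "R2": rep.r2, "RPD": rep.rpd,
                         "RPD class": rep.rpd_class})
        pd.DataFrame(rows).to_csv(r.out / "plsr_report.csv", index=False)
        r.mark("plsr")

    if "phenotype" in cfg.stages and not r.done("phenotype"):
        fr = phenotype.factor_analysis(traits)
        report = phenotype.rank_harvest_months(fr, traits)
        report.to_csv(r.out / "harvest_ranking.csv", index=False)
        phenotype.monthly_cv_table(traits).to_csv(r.out / "cv_table.csv")
        harvest_months = [11, 12, 1, 2, 3, 4]
        sp = phenotype.spearman_env(
            traits[traits["month"].isin(harvest_months)], env)
        sp.to_csv(r.out / "spearman_env.csv", index=False)
        (r.out / "phenotype_summary.txt").write_text(
            fr.summary() + "\n" + report.attrs.get("note", "") + "\n")
        r.mark("phenotype")

    return r.out
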