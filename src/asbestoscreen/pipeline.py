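"""End-to-end orchestration: simulate, preprocess, detect, classify, fuse.

Two entry points:

* :func:`run_desk_experiment` — the in-memory desk-scale experiment used by
  the test-suite and the acceptance script: a phantom cohort is generated,
  preprocessed, a VAE is fitted on the healthy training slices, anomaly
  heatmaps are computed, soft- and hard-label classifiers are trained, and
  the evaluation quantities (AUCs, dispersions, contrast fractions,
  agreement statistics) are measured on the held-out test split.

* :func:`run_pipeline` — the file-based pipeline behind the ``run`` CLI
  command: same stages, with every artifact written next to a manifest
  recording the configuration hash, master seed, stage timings and case
  counts.

All randomness flows from one master seed; each stage derives its own seed
deterministically from it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .anomaly import ConvVAE, VAEConfig, compute_heatmap, save_vae, train_vae
from .classifier import (
    ClassifierConfig,
    contradictory_mask,
    predict,
    save_classifier,
    split_cohort,
    train_classifier,
)
from .evaluation import agreement_stratified_report, mcnemar_test, roc_auc, saliency_map, threshold_metrics
from .lung_function import ama_class, lf_eligible, simple_combine
from .panel import VoteTable, agreement_summary, krippendorff_alpha
from .phantoms import generate_cohort
from .preprocess import preprocess_case
from .volumes import write_mask, write_volume

logger = logging.getLogger("asbestoscreen")

__all__ = ["RunConfig", "run_pipeline", "run_desk_experiment", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (one plain YAML file)."""

    out_dir: str = "run_output"
    cohort_dir: str | None = None  # None -> simulate a phantom cohort
    n_cases: int = 60
    prevalence_target: float = 0.46
    grid_shape: tuple[int, int, int] = (48, 48, 24)
    target_shape: tuple[int, int, int] = (48, 48, 24)
    lung_threshold_hu: float = -320.0
    dilation_kernel: tuple[int, int, int] = (13, 13, 5)
    label_kind: str = "soft"  # soft | hard
    use_heatmap: bool = True
    fusion: str = "simple"  # none | simple | advanced
    triage_low: float = 0.35
    triage_high: float = 0.60
    vae_epochs: int = 40
    classifier_epochs: int = 15
    exclude_contradictory: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _prep_cohort(cases, target_shape):
    """Preprocess every case; returns aligned stacks plus resampled truth masks."""
    vols, masks, lesions = [], [], []
    for case in cases:
        prep, mask, (lesion,) = preprocess_case(
            case.volume, target_shape=target_shape, extra_masks=(case.lesion_mask,)
        )
        vols.append(prep.values)
        masks.append(mask)
        lesions.append(lesion)
    return np.stack(vols), np.stack(masks), np.stack(lesions)


def _healthy_slices(vols, masks, cases, indices, min_lung_fraction=0.05):
    """Axial slices of severity-zero phantoms among ``indices`` with enough lung."""
    slices = []
    for i in indices:
        if cases[i].severity_img == 0.0:
            vol, mask = vols[i], masks[i]
            for k in range(vol.shape[2]):
                if mask[:, :, k].mean() >= min_lung_fraction:
                    slices.append(vol[:, :, k])
    return np.stack(slices) if slices else np.empty((0,) + vols.shape[1:3])


def _predict_batch(model, x, dlco=None, batch_size=16):
    out = []
    for start in range(0, x.shape[0], batch_size):
        sl = slice(start, start + batch_size)
        out.append(model.predict_proba(x[sl], None if dlco is None else dlco[sl]))
    return np.concatenate(out) if out else np.empty(0)


def run_desk_experiment(
    n: int = 200,
    grid_shape: tuple[int, int, int] = (48, 48, 24),
    seed: int = 7,
    vae_epochs: int = 40,
    classifier_epochs: int = 25,
    n_detector_cases: int = 20,
    n_saliency_cases: int = 10,
    exclude_contradictory: bool = True,
) -> dict:
    """Run the full synthetic study at desk scale and measure everything.

    Returns a dictionary with the trained models, the per-split indices, the
    held-out predictions of the soft- and hard-label classifiers, and the
    headline quantities: imaging AUC, simple-combination AUC, prediction
    dispersions, detector and saliency lesion-contrast fractions, and the
    cohort agreement statistics.
    """
    t0 = time.perf_counter()
    cases = generate_cohort(n, seed=derive_seed(seed, "cohort"), grid_shape=grid_shape)
    vols, masks, lesions = _prep_cohort(cases, target_shape=grid_shape)

    contradictory = contradictory_mask(cases) if exclude_contradictory else np.zeros(len(cases), bool)
    usable = [i for i in range(len(cases)) if not contradictory[i]]
    idx_cases = [(i, cases[i].verdict) for i in usable]
    train_ix, val_ix, test_ix = (
        [i for i, _ in part] for part in split_cohort(idx_cases, seed=derive_seed(seed, "split"))
    )

    healthy = _healthy_slices(vols, masks, cases, train_ix)
    vae = train_vae(
        healthy,
        VAEConfig(slice_shape=grid_shape[:2], epochs=vae_epochs, seed=derive_seed(seed, "vae")),
    )
    from .volumes import Volume

    heatmaps = np.stack([compute_heatmap(Volume(v), vae) for v in vols])

    x = np.stack([vols, heatmaps], axis=1).astype(np.float32)
    y_soft = np.array([c.votes.soft_label for c in cases])
    y_hard = np.array([float(c.verdict) for c in cases])
    verdicts = y_hard.astype(int)

    models, preds = {}, {}
    for kind, y in (("soft", y_soft), ("hard", y_hard)):
        cfg = ClassifierConfig(
            input_channels=2, epochs=classifier_epochs, seed=derive_seed(seed, f"clf-{kind}")
        )
        models[kind] = train_classifier(x[train_ix], y[train_ix], x[val_ix], y[val_ix], cfg)
        preds[kind] = _predict_batch(models[kind], x[test_ix])

    dlco_test = np.array([cases[i].lung_function.dlco_pct for i in test_ix])
    combined = np.array(
        [simple_combine(p, d).combined for p, d in zip(preds["soft"], dlco_test)]
    )
    labels_test = verdicts[test_ix]

    auc_imaging = roc_auc(preds["soft"], labels_test, seed=derive_seed(seed, "boot-img"))
    auc_combined = roc_auc(combined, labels_test, seed=derive_seed(seed, "boot-comb"))
    auc_dlco = roc_auc(1.0 - np.clip(dlco_test / 100.0, 0, 1), labels_test, seed=derive_seed(seed, "boot-dlco"))

    sev_test = np.array([cases[i].severity_img for i in test_ix])
    spearman_severity = float(spearmanr(preds["soft"], sev_test).statistic)

    k_test = np.array([cases[i].votes.n_positive for i in test_ix])
    strata = agreement_stratified_report(preds["soft"], k_test)

    mcnemar_p = mcnemar_test(
        (preds["soft"] >= 0.5) == labels_test.astype(bool),
        (preds["hard"] >= 0.5) == labels_test.astype(bool),
    )

    # detector property: heatmap contrast against the generative lesion masks
    lesioned = [i for i in range(len(cases)) if lesions[i].sum() >= 20]
    det_ix = lesioned[:n_detector_cases]
    det_hits = []
    for i in det_ix:
        inside = heatmaps[i][lesions[i]].mean()
        outside = heatmaps[i][~lesions[i]].mean()
        det_hits.append(inside > outside)
    detector_fraction = float(np.mean(det_hits)) if det_hits else float("nan")

    sal_ix = [i for i in lesioned if i in set(test_ix)][:n_saliency_cases]
    if len(sal_ix) < n_saliency_cases:
        sal_ix = lesioned[:n_saliency_cases]
    sal_hits = []
    for i in sal_ix:
        sal = saliency_map(models["soft"], vols[i], heatmap=heatmaps[i])
        sal_hits.append(sal[lesions[i]].mean() > sal[~lesions[i]].mean())
    saliency_fraction = float(np.mean(sal_hits)) if sal_hits else float("nan")

    table = VoteTable.from_votes([c.votes.votes for c in cases])
    summary = agreement_summary(table)

    dlco_all = np.array([c.lung_function.dlco_pct for c in cases])
    sev_all = np.array([c.severity_img for c in cases])
    r2_dlco_img = float(np.corrcoef(dlco_all, sev_all)[0, 1] ** 2)

    logger.info("desk experiment finished in %.1f s", time.perf_counter() - t0)
    return {
        "cases": cases,
        "volumes": vols,
        "masks": masks,
        "lesions": lesions,
        "heatmaps": heatmaps,
        "vae": vae,
        "models": models,
        "splits": {"train": train_ix, "val": val_ix, "test": test_ix},
        "contradictory": contradictory,
        "predictions": preds,
        "combined": combined,
        "labels_test": labels_test,
        "dlco_test": dlco_test,
        "auc_imaging": auc_imaging,
        "auc_combined": auc_combined,
        "auc_dlco": auc_dlco,
        "pred_std_soft": float(np.std(preds["soft"], ddof=1)),
        "pred_std_hard": float(np.std(preds["hard"], ddof=1)),
        "spearman_severity": spearman_severity,
        "strata": strata,
        "mcnemar_soft_vs_hard_p": mcnemar_p,
        "detector_fraction": detector_fraction,
        "detector_n": len(det_hits),
        "saliency_fraction": saliency_fraction,
        "agreement": summary,
        "alpha": krippendorff_alpha(table),
        "r2_dlco_imaging": r2_dlco_img,
        "runtime_s": time.perf_counter() - t0,
    }


def run_pipeline(config: RunConfig) -> dict:
    """File-based pipeline: simulate -> preprocess -> detect -> classify ->
    predict -> fuse -> evaluate, with a manifest tying artifacts to the
    configuration hash and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    from .volumes import Volume

    def stage(name):
        logger.info("stage: %s", name)
        manifest["current_stage"] = name
        return time.perf_counter()

    try:
        t = stage("simulate")
        if config.cohort_dir is not None:
            raise NotImplementedError("external cohorts are read by the individual CLI commands; `run` simulates")
        cases = generate_cohort(
            config.n_cases,
            prevalence_target=config.prevalence_target,
            seed=derive_seed(config.seed, "cohort"),
            grid_shape=tuple(config.grid_shape),
            out_dir=out / "cohort",
        )
        manifest["stages"]["simulate"] = {"seconds": time.perf_counter() - t, "cases": len(cases)}

        t = stage("preprocess")
        vols, masks, lesions = _prep_cohort(cases, target_shape=tuple(config.target_shape))
        prep_dir = out / "prep"
        prep_dir.mkdir(exist_ok=True)
        for case, v in zip(cases, vols):
            write_volume(Volume(v), prep_dir / f"{case.case_id}.nii.gz")
        manifest["stages"]["preprocess"] = {"seconds": time.perf_counter() - t, "cases": len(cases)}

        contradictory = (
            contradictory_mask(cases) if config.exclude_contradictory else np.zeros(len(cases), bool)
        )
        usable = [i for i in range(len(cases)) if not contradictory[i]]
        idx_cases = [(i, cases[i].verdict) for i in usable]
        train_ix, val_ix, test_ix = (
            [i for i, _ in part]
            for part in split_cohort(idx_cases, seed=derive_seed(config.seed, "split"))
        )

        t = stage("train-vae")
        healthy = _healthy_slices(vols, masks, cases, train_ix)
        vae = train_vae(
            healthy,
            VAEConfig(
                slice_shape=tuple(config.target_shape[:2]),
                epochs=config.vae_epochs,
                seed=derive_seed(config.seed, "vae"),
            ),
        )
        save_vae(vae, out / "vae.npz")
        manifest["stages"]["train-vae"] = {"seconds": time.perf_counter() - t, "slices": len(healthy)}

        t = stage("heatmap")
        heatmaps = np.stack([compute_heatmap(Volume(v), vae) for v in vols])
        heat_dir = out / "heatmaps"
        heat_dir.mkdir(exist_ok=True)
        for case, h in zip(cases, heatmaps):
            write_volume(Volume(h), heat_dir / f"{case.case_id}_heat.nii.gz")
        manifest["stages"]["heatmap"] = {"seconds": time.perf_counter() - t}

        t = stage("train-classifier")
        channels = 2 if config.use_heatmap else 1
        x = (
            np.stack([vols, heatmaps], axis=1) if config.use_heatmap else vols[:, None]
        ).astype(np.float32)
        if config.label_kind == "soft":
            y = np.array([c.votes.soft_label for c in cases])
        else:
            y = np.array([float(c.verdict) for c in cases])
        dlco_frac = np.array(
            [np.clip((c.lung_function.dlco_pct or 100.0) / 100.0, 0, 1) for c in cases]
        )
        use_dlco = config.fusion == "advanced"
        cfg = ClassifierConfig(
            input_channels=channels,
            use_dlco_input=use_dlco,
            epochs=config.classifier_epochs,
            max_epochs=config.classifier_epochs,  # fixed budget: predictable stage runtime
            seed=derive_seed(config.seed, "clf"),
        )
        model = train_classifier(
            x[train_ix],
            y[train_ix],
            x[val_ix],
            y[val_ix],
            cfg,
            dlco_train=dlco_frac[train_ix] if use_dlco else None,
            dlco_val=dlco_frac[val_ix] if use_dlco else None,
        )
        save_classifier(model, out / "classifier.npz")
        manifest["stages"]["train-classifier"] = {
            "seconds": time.perf_counter() - t,
            "train": len(train_ix),
            "val": len(val_ix),
            "test": len(test_ix),
            "contradictory_held_out": int(contradictory.sum()),
        }

        t = stage("predict")
        probs = _predict_batch(model, x, dlco_frac if use_dlco else None)
        preds = pd.DataFrame(
            {"case_id": [c.case_id for c in cases], "probability": probs}
        )
        preds.to_csv(out / "predictions.csv", index=False)
        manifest["stages"]["predict"] = {"seconds": time.perf_counter() - t}

        t = stage("fuse")
        rows = []
        for case, p in zip(cases, probs):
            lf = case.lung_function
            ama = ama_class(lf.fvc_pct, lf.dlco_pct)
            if config.fusion == "simple":
                fused = simple_combine(float(p), lf.dlco_pct, config.triage_low, config.triage_high)
                combined, tri = fused.combined, fused.triage
            else:
                from .lung_function import triage as triage_rule

                combined, tri = float(p), triage_rule(float(p), config.triage_low, config.triage_high)
            rows.append(
                {
                    "case_id": case.case_id,
                    "probability": float(p),
                    "ama_class": ama,
                    "lf_eligible": lf_eligible(ama),
                    "combined": combined,
                    "triage": tri,
                }
            )
        fused_df = pd.DataFrame(rows)
        fused_df.to_csv(out / "fused.csv", index=False)
        manifest["stages"]["fuse"] = {"seconds": time.perf_counter() - t}

        t = stage("evaluate")
        labels = np.array([int(c.verdict) for c in cases])
        scores_eval = fused_df["combined"].to_numpy() if config.fusion == "simple" else probs
        test_scores = np.asarray(scores_eval)[test_ix]
        test_labels = labels[test_ix]
        report = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_cases": len(cases),
            "splits": {"train": len(train_ix), "val": len(val_ix), "test": len(test_ix)},
            "auc": roc_auc(test_scores, test_labels, seed=derive_seed(config.seed, "boot")),
            "threshold_metrics": threshold_metrics(
                test_scores, test_labels, seed=derive_seed(config.seed, "boot-thr")
            ),
            "agreement": agreement_summary(VoteTable.from_votes([c.votes.votes for c in cases])),
            "krippendorff_alpha": krippendorff_alpha(
                VoteTable.from_votes([c.votes.votes for c in cases])
            ),
            "contradictory_cases": [cases[i].case_id for i in np.flatnonzero(contradictory)],
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        manifest["stages"]["evaluate"] = {"seconds": time.perf_counter() - t}
    except Exception as exc:
        failed = manifest.pop("current_stage", "unknown")
        manifest["failed_stage"] = failed
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc
    manifest.pop("current_stage", None)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return report
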