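"""End-to-end experiment orchestration.

For each cross-validation fold: fit the normalizer on the training
segments, augment the training set with white Gaussian noise, train the
angle predictor end-to-end, transfer the frozen feature extractor to the
movement classifier, predict on the held-out fold, smooth the concatenated
per-trial angle predictions with the iterative spline algorithm, and score
everything.  Fold reports, models and the aggregate report are written
under the output directory; the whole run is reproducible from the master
seed (single-threaded).
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np

from . import dataio
from .dataio import Recording
from .eia import EiaConfig, eia_smooth
from .evaluate import MetricsReport, aggregate_folds, fold_report
from .lrcn import LrcnConfig, LrcnNetwork
from .preprocess import (AugmentConfig, Segment, augment_wgn, fit_normalizer,
                         apply_normalizer, kfold_split, segment_windows,
                         segments_to_arrays)
from .synthetic import SimConfig, gen_dataset


@dataclasses.dataclass
class RunConfig:
    """Everything one experiment needs, with one master seed.

    If ``recordings`` is None, a synthetic dataset is generated from
    ``sim`` and ``n_trials_per_class``.  Sub-config seeds are derived from
    ``seed`` so one integer pins the whole run.
    """

    out_dir: str | Path | None = None
    recordings: list[Recording] | None = None
    n_trials_per_class: int = 2
    sim: SimConfig | None = None
    window_ms: float = 256.0
    overlap_ms: float = 64.0
    augment: AugmentConfig | None = None
    augment_test: bool = False
    k: int = 3
    lrcn: LrcnConfig | None = None
    eia: EiaConfig | None = None
    mae_normalization: str = "range"
    seed: int = 0


def _derive(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0]
               % (2 ** 31))


def _concat_trial_traces(test_segments: list[Segment], pred: np.ndarray,
                         eia_cfg: EiaConfig):
    """Group held-out segments by trial, concatenate in time order, smooth.

    Returns concatenated (actual, smoothed-predicted, raw-predicted) traces
    over all trials; smoothing is applied per trial, matching how a
    continuous goniometer trace would be reconstructed.
    """
    order: dict[str, list[int]] = {}
    for i, seg in enumerate(test_segments):
        order.setdefault(seg.origin[0], []).append(i)
    actual, smoothed, raw = [], [], []
    for trial_id, idxs in order.items():
        idxs = sorted(idxs, key=lambda i: test_segments[i].origin[1])
        aj = np.concatenate([test_segments[i].y_angle for i in idxs])
        pj = np.concatenate([pred[i] for i in idxs])
        actual.append(aj)
        raw.append(pj)
        smoothed.append(eia_smooth(pj, eia_cfg).smoothed)
    return (np.concatenate(actual), np.concatenate(smoothed),
            np.concatenate(raw))


def run_fold(fold: int, segments: list[Segment], split, cfg: RunConfig,
             log: list[str]) -> tuple[MetricsReport, LrcnNetwork]:
    """Train and evaluate one fold; returns its report and trained model."""
    aug_cfg = cfg.augment or AugmentConfig()
    lrcn_cfg = cfg.lrcn or LrcnConfig()
    eia_cfg = cfg.eia or EiaConfig()

    train_idx = split.train_indices(fold)
    test_idx = split.test_indices(fold)
    train = [segments[i] for i in train_idx]
    test = [segments[i] for i in test_idx]

    norm = fit_normalizer(train)
    train = apply_normalizer(norm, train)
    test = apply_normalizer(norm, test)
    aug = dataclasses.replace(aug_cfg, seed=_derive(cfg.seed, 100 + fold))
    train = augment_wgn(train, aug)
    if cfg.augment_test:
        test = augment_wgn(test, aug)
    log.append(f"[fold {fold}] train={len(train)} "
               f"(augmented x{aug.factor}) test={len(test)}")

    net = LrcnNetwork(dataclasses.replace(
        lrcn_cfg, seed=_derive(cfg.seed, 200 + fold)))
    Xtr, Ytr, ytr = segments_to_arrays(train)
    net.fit_angle(Xtr, Ytr)
    log.append(f"[fold {fold}] angle training done")
    net.fit_classifier(Xtr, ytr)
    log.append(f"[fold {fold}] transfer/classifier training done")

    Xte, _, yte = segments_to_arrays(test)
    pred_angle = net.predict_angle(Xte)
    y_pred = net.predict_proba(Xte).argmax(axis=1)
    aj, pj_eia, pj_raw = _concat_trial_traces(test, pred_angle, eia_cfg)
    report = fold_report(yte, y_pred, aj, pj_eia, pj_raw,
                         cfg.mae_normalization)
    return report, net


def run_experiment(cfg: RunConfig) -> MetricsReport:
    """Run the full cross-validated experiment described by ``cfg``."""
    t0 = time.time()
    log: list[str] = []
    out_dir = Path(cfg.out_dir) if cfg.out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    recs = cfg.recordings
    if recs is None:
        sim = cfg.sim or SimConfig(seed=_derive(cfg.seed, 1))
        recs = gen_dataset(cfg.n_trials_per_class, sim)
        log.append(f"generated {len(recs)} synthetic recordings")

    segments: list[Segment] = []
    for rec in recs:
        segments.extend(segment_windows(rec, cfg.window_ms, cfg.overlap_ms))
    if not segments:
        raise ValueError("no segments: recordings shorter than one window")
    log.append(f"segmented into {len(segments)} windows")

    split = kfold_split(len(segments), k=cfg.k, seed=_derive(cfg.seed, 2))
    if out_dir is not None:
        manifest = {
            "n_segments": len(segments),
            "k": cfg.k,
            "assignments": split.assignments.tolist(),
            "window_ms": cfg.window_ms,
            "overlap_ms": cfg.overlap_ms,
            "seed": cfg.seed,
        }
        (out_dir / "fold_manifest.json").write_text(
            json.dumps(manifest, indent=2))

    reports = []
    for fold in range(cfg.k):
        report, net = run_fold(fold, segments, split, cfg, log)
        reports.append(report)
        log.append(f"[fold {fold}] accuracy {report.accuracy:.2f}% "
                   f"mae {report.mae_percent:.2f}% r {report.pearson_r:.4f}")
        if out_dir is not None:
            dataio.write_metrics_report(report,
                                        out_dir / f"fold{fold}_report.json")
            dataio.save_model(net, out_dir / f"fold{fold}_model.npz")

    aggregate = aggregate_folds(reports)
    log.append(f"aggregate accuracy {aggregate.accuracy:.2f}% "
               f"mae {aggregate.mae_percent:.2f}% "
               f"r {aggregate.pearson_r:.4f} "
               f"({time.time() - t0:.1f}s)")
    if out_dir is not None:
        dataio.write_metrics_report(aggregate, out_dir / "aggregate_report.json")
        (out_dir / "run.log").write_text(
            "\n".join(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {line}"
                      for line in log) + "\n")
    return aggregate
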