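"""End-to-end orchestration: windows -> TFMs -> CNN -> SDA -> classifiers.

For every sliding-window location, an independent stack is fitted on the
training trials only: the C3/C4 Stockwell magnitude maps of each window
are cropped to the mu/beta band, stacked into one image, a CNN is
trained on the *labeled* two-thirds of the training trials, its deep
features are reduced to 2-D by SDA (the unlabeled third shapes the
neighbor graph only), and the five optimized classifiers plus their
majority-vote fusion are evaluated on the held-out trials.  The split is
at trial level, so overlapping windows never leak across it.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np

from . import classify, cnn, metrics, sda, segmentation, stockwell
from .errors import DataError, ParameterError
from .synthetic import LABELS, TrialParams, EEGTrial, generate_dataset

__all__ = ["ExperimentConfig", "WindowResult", "EvaluationReport", "run_experiment", "summarize_windows"]

_LABEL_CODE = {"left": 0, "right": 1}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    trial_params: TrialParams = field(default_factory=TrialParams)
    n_trials: int = 80
    win_s: float = 3.0
    stride_s: float = 0.25
    mi_start: float = 3.0
    mi_end: float | None = None  # trial end when None
    band: tuple[float, float] = (7.0, 30.0)
    prefilter: bool = True  # zero-phase 7-30 Hz Butterworth on raw trials
    image_size: int = 220
    cnn_layers: int = 2
    cnn_epochs: int = 30
    cnn_batch_size: int = 16
    cnn_learning_rate: float = 1e-3
    sda_beta: float | None = 0.1  # None searches beta_grid by CV
    beta_grid: tuple[float, ...] = (0.0, 1e-2, 1e-1, 1.0, 10.0)
    sda_p: int = 5
    labeled_fraction: float = 2.0 / 3.0
    classifier_names: tuple[str, ...] = classify.CLASSIFIER_NAMES
    search_iters: int = 30
    train_fraction: float = 0.5
    seed: int = 0


@dataclass
class WindowResult:
    t_start: float
    t_end: float
    reports: dict  # classifier name (incl. 'fusion') -> MetricReport
    timings: dict = field(default_factory=dict)

    @property
    def duration_label(self) -> str:
        return f"{self.t_start:g}-{self.t_end:g}"


@dataclass
class EvaluationReport:
    config: ExperimentConfig
    windows: list

    def accuracies(self, name: str) -> np.ndarray:
        return np.array([w.reports[name].accuracy for w in self.windows])

    def to_dict(self) -> dict:
        return {
            "win_s": self.config.win_s,
            "stride_s": self.config.stride_s,
            "seed": self.config.seed,
            "windows": [
                {
                    "t_start": w.t_start,
                    "t_end": w.t_end,
                    "reports": {k: r.to_dict() for k, r in w.reports.items()},
                    "timings": {k: round(v, 3) for k, v in w.timings.items()},
                }
                for w in self.windows
            ],
        }


def _split_trials(trials: list[EEGTrial], fraction: float, rng: np.random.Generator) -> set[int]:
    """Stratified trial-id subset of the requested fraction."""
    chosen: set[int] = set()
    for label in LABELS:
        ids = np.array(sorted(t.trial_id for t in trials if t.label == label))
        rng.shuffle(ids)
        chosen.update(ids[: round(fraction * len(ids))].tolist())
    return chosen


def stacked_image(
    seg: segmentation.Segment, band: tuple[float, float], image_size: int
) -> stockwell.StackedTFM:
    """C3/C4 Stockwell magnitude maps of one window, cropped and stacked."""
    maps = []
    for row in (0, 2):  # C3, C4
        ctfm = stockwell.discrete_stockwell(seg.data[row], seg.fs)
        tfm = stockwell.band_crop(stockwell.tfm_magnitude(ctfm), *band)
        maps.append(tfm)
    img = stockwell.stack_and_resize(maps[0], maps[1], out=image_size)
    img.source_window = (seg.t_start, seg.t_end)
    return img


def _select_beta(
    z_fn, grid: tuple[float, ...], y: np.ndarray, seed: int
) -> tuple[float, sda.SDAModel]:
    """Pick the graph weight by CV accuracy of a linear discriminant on the
    labeled projections; z_fn(beta) fits SDA and returns (model, z_labeled)."""
    best = (-1.0, grid[0], None)
    for beta in grid:
        model, z = z_fn(beta)
        obj = classify.cv_accuracy_objective("discriminant", z, y, seed=seed)
        v = obj({"kind": "linear"})
        if v > best[0]:
            best = (v, beta, model)
    return best[1], best[2]


def run_experiment(config: ExperimentConfig, stage_hook=None) -> EvaluationReport:
    """Run the full pipeline; deterministic given the config seed.

    ``stage_hook(stage, role)``, if given, is called whenever a fitting
    stage consumes data (role 'train'/'test'); it exists so tests can
    assert that no fitting stage ever touches the held-out split.
    """
    hook = stage_hook or (lambda stage, role: None)
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    trials = generate_dataset(config.trial_params, config.n_trials, seed=seeds[0])
    if config.prefilter:
        for t in trials:
            t.data = stockwell.bandpass(t.data, t.fs, *config.band)

    rng_split = np.random.default_rng(seeds[1])
    train_ids = _split_trials(trials, config.train_fraction, rng_split)
    train_trials = [t for t in trials if t.trial_id in train_ids]
    labeled_ids = _split_trials(train_trials, config.labeled_fraction, rng_split)

    t_end = config.mi_end
    per_trial_windows = {
        t.trial_id: segmentation.sliding_windows(
            t, config.win_s, config.stride_s, t_start=config.mi_start, t_end=t_end
        )
        for t in trials
    }
    n_loc = len(next(iter(per_trial_windows.values())))
    if any(len(w) != n_loc for w in per_trial_windows.values()):
        raise DataError("trials produced differing window counts")

    results = []
    for j in range(n_loc):
        timings: dict[str, float] = {}
        t0 = time.perf_counter()
        segs = {tid: ws[j] for tid, ws in per_trial_windows.items()}
        images = {
            tid: stacked_image(seg, config.band, config.image_size).image
            for tid, seg in segs.items()
        }
        timings["tfm"] = time.perf_counter() - t0

        lab_ids = sorted(labeled_ids)
        unlab_ids = sorted(train_ids - labeled_ids)
        test_ids = sorted(set(segs) - train_ids)
        y = {tid: _LABEL_CODE[segs[tid].label] for tid in segs}
        y_lab = np.array([y[tid] for tid in lab_ids])
        y_test = np.array([y[tid] for tid in test_ids])

        t0 = time.perf_counter()
        cfg = cnn.CNNConfig(
            n_conv_layers=config.cnn_layers,
            input_size=config.image_size,
            epochs=config.cnn_epochs,
            batch_size=config.cnn_batch_size,
            learning_rate=config.cnn_learning_rate,
            seed=seeds[2] + j,
        )
        model = cnn.build_cnn(cfg)
        hook("cnn_train", "train")
        cnn.train_cnn(model, np.stack([images[i] for i in lab_ids]), y_lab, cfg)
        timings["cnn"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        feat = {}
        for ids in (lab_ids, unlab_ids, test_ids):
            for lo in range(0, len(ids), 16):
                chunk = ids[lo : lo + 16]
                F = model.features(np.stack([images[i] for i in chunk]))
                feat.update(dict(zip(chunk, F)))
        X_lab = np.array([feat[i] for i in lab_ids])
        X_unlab = np.array([feat[i] for i in unlab_ids]) if unlab_ids else None
        X_test = np.array([feat[i] for i in test_ids])
        timings["features"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        hook("sda_fit", "train")

        def fit_at(beta):
            m = sda.fit_sda(X_lab, y_lab, X_unlab, beta=beta, p=config.sda_p)
            return m, sda.transform(m, X_lab)

        if config.sda_beta is None:
            _, sda_model = _select_beta(fit_at, config.beta_grid, y_lab, seeds[3])
        else:
            sda_model, _ = fit_at(config.sda_beta)
        z_lab = sda.transform(sda_model, X_lab)
        z_test = sda.transform(sda_model, X_test)
        timings["sda"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        predictions = {}
        reports = {}
        for name in config.classifier_names:
            hook(f"optimize_{name}", "train")
            clf, _ = classify.optimize_classifier(
                name, z_lab, y_lab, n_iter=config.search_iters, seed=seeds[3] + j
            )
            predictions[name] = np.asarray(clf.predict(z_test))
            reports[name] = metrics.report(y_test, predictions[name])
        if len(config.classifier_names) == 5:
            fused = np.array(
                [
                    classify.majority_vote([predictions[n][i] for n in config.classifier_names])
                    for i in range(len(y_test))
                ]
            )
            reports["fusion"] = metrics.report(y_test, fused)
        timings["classify"] = time.perf_counter() - t0

        seg0 = next(iter(segs.values()))
        results.append(
            WindowResult(t_start=seg0.t_start, t_end=seg0.t_end, reports=reports, timings=timings)
        )

    return EvaluationReport(config=config, windows=results)


def summarize_windows(report: EvaluationReport | list) -> dict:
    """Best/worst/mean accuracy and kappa per classifier across windows."""
    windows = report.windows if isinstance(report, EvaluationReport) else report
    if not windows:
        raise ParameterError("need at least one window to summarize")
    names = windows[0].reports.keys()
    summary = {}
    for name in names:
        accs = np.array([w.reports[name].accuracy for w in windows])
        kappas = np.array([w.reports[name].kappa for w in windows])
        durations = [w.duration_label for w in windows]
        i_best, i_worst = int(np.argmax(accs)), int(np.argmin(accs))
        summary[name] = {
            "best": {
                "accuracy": round(float(accs[i_best]), 2),
                "kappa": round(float(kappas[i_best]), 3),
                "duration": durations[i_best],
            },
            "worst": {
                "accuracy": round(float(accs[i_worst]), 2),
                "kappa": round(float(kappas[i_worst]), 3),
                "duration": durations[i_worst],
            },
            "mean": {
                "accuracy": round(float(accs.mean()), 2),
                "kappa": round(float(kappas.mean()), 3),
            },
        }
    return summary
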