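"""End-to-end pipeline drivers for the multi-trial and single-trial branches.

The multi-trial branch: simulate (or load) a cohort, preprocess each
subject x stimulus epoch set to a clean grand-average ERP, build the
candidate feature vector, select features by cross-validated lasso, fit
the four regressors on identical folds, and attach residual diagnostics.

The single-trial branch: simulate, filter and truncate individual trials,
convert them to time-frequency images, tune the CNN's hyperparameters by
GP/EI Bayesian optimization, and report the best configuration's
subject-grouped CV error (optionally against a shuffled-label null).

All randomness derives from the single top-level seed via fixed offsets;
reports are plain JSON-serializable dictionaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import bayesopt, diagnostics, features, regression, selection
from .cohort import CohortSpec, SyntheticCohort, generate_cohort
from .nn import CnnSpec
from .preprocess import (
    ErpWaveform,
    bandpass_erp,
    baseline_correct,
    filter_single_trials,
    grand_average,
    reject_amplitude,
)
from .singletrial import epochs_to_tf_images, make_objective, train_eval_cnn


@dataclass
class MultiTrialSettings:
    reject_threshold_uv: float = 50.0
    band: tuple[float, float] = (0.0, 30.0)
    include_td: bool = True
    td_n_keep: int | None = 510
    win_ms: float = 25.0
    overlap: float = 0.5
    cv_folds: int = 5
    methods: tuple[str, ...] = regression.METHODS


@dataclass
class SingleTrialSettings:
    rt_min: float = 0.2
    rt_max: float = 1.5
    range_max_uv: float = 100.0
    f_max: float = 100.0
    image_shape: tuple[int, int] = (32, 32)
    n_presample: int = 5
    n_bo_iter: int = 15
    cv_folds: int = 5
    space: bayesopt.SearchSpace = field(default_factory=bayesopt.SearchSpace)
    shuffled_null: bool = False


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    multitrial: MultiTrialSettings = field(default_factory=MultiTrialSettings)
    singletrial: SingleTrialSettings = field(default_factory=SingleTrialSettings)
    seed: int = 0
    out_dir: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        cfg = cls()
        if "cohort" in d:
            cfg.cohort = CohortSpec.from_dict(d["cohort"])
        if "multitrial" in d:
            m = dict(d["multitrial"])
            if "band" in m:
                m["band"] = tuple(m["band"])
            if "methods" in m:
                m["methods"] = tuple(m["methods"])
            cfg.multitrial = MultiTrialSettings(**m)
        if "singletrial" in d:
            s = dict(d["singletrial"])
            if "image_shape" in s:
                s["image_shape"] = tuple(s["image_shape"])
            if "space" in s:
                s["space"] = bayesopt.SearchSpace(
                    **{k: tuple(v) for k, v in s["space"].items()}
                )
            cfg.singletrial = SingleTrialSettings(**s)
        cfg.seed = d.get("seed", 0)
        cfg.out_dir = d.get("out_dir")
        return cfg


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def preprocess_cohort(
    cohort: SyntheticCohort, settings: MultiTrialSettings
) -> tuple[dict[tuple[str, str], ErpWaveform], dict]:
    """Raw epochs -> baseline-corrected, artifact-free, filtered ERPs."""
    erps: dict[tuple[str, str], ErpWaveform] = {}
    reports = {}
    for key, epochs in sorted(cohort.epochs.items()):
        corrected = baseline_correct(epochs)
        kept, rep = reject_amplitude(corrected, settings.reject_threshold_uv)
        if rep.all_rejected:
            reports["|".join(key)] = rep.to_dict()
            continue
        erp = grand_average(kept)
        erps[key] = bandpass_erp(erp, *settings.band)
        reports["|".join(key)] = rep.to_dict()
    return erps, reports


def run_multitrial(config: RunConfig) -> dict:
    """Simulate -> preprocess -> features -> select -> regress -> diagnose."""
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(spec)
    mt = config.multitrial

    erps, rejection_reports = preprocess_cohort(cohort, mt)

    table = features.build_feature_table(
        erps,
        include_td=mt.include_td,
        win_ms=mt.win_ms,
        overlap=mt.overlap,
    )
    n_prominent = sum(1 for c in table.columns if "|td|" not in c)
    groups = cohort.subjects.set_index("id")["group"]
    if mt.include_td:
        screening = features.screen_td_features(table, groups, n_keep=mt.td_n_keep)
        cfv = table[screening.retained]
    else:
        screening = None
        cfv = table

    # drop features that are missing or constant across the cohort: the
    # flagged-missing CV dynamics (NaN) cannot enter the lasso
    cfv = cfv.dropna(axis=1)
    cfv = cfv.loc[:, cfv.std(ddof=0) > 0]

    y = cohort.subjects.set_index("id").loc[cfv.index, "moca"].to_numpy(float)
    path = selection.cv_deviance_curve(
        cfv, y, k=min(mt.cv_folds, len(y)), seed=config.seed
    )
    selected = path.selected_features
    if not selected:  # null model won CV; fall back to sparsest non-empty fit
        nz = np.flatnonzero(path.n_nonzero > 0)
        if len(nz):
            idx = nz[int(np.argmin(path.cv_deviance[nz]))]
            support = np.flatnonzero(path.coefs[:, idx] != 0)
            selected = [path.feature_names[j] for j in support]
    X = cfv[selected].to_numpy(float)

    results = regression.compare_methods(
        X, y, methods=mt.methods, k=min(mt.cv_folds, len(y)), seed=config.seed
    )
    diag = {}
    for m, res in results.items():
        try:
            diag[m] = diagnostics.check_residuals(res.y_pred, res.residuals).to_dict()
        except ValueError:
            diag[m] = {"error": "too few residuals"}

    report = {
        "branch": "multitrial",
        "seed": config.seed,
        "n_subjects": len(cohort.subjects),
        "n_stimuli": spec.n_stimuli,
        "rejection": rejection_reports,
        "feature_counts": {
            "prominent_block": n_prominent,
            "td_candidates": int(len(table.columns) - n_prominent),
            "cfv_total": int(cfv.shape[1]),
            "selected": len(selected),
        },
        "lasso": path.to_dict(),
        "selected_features": selected,
        "regression": {m: r.to_dict() for m, r in results.items()},
        "diagnostics": diag,
        "null_sd": float(np.std(y, ddof=0)),
        "provenance": {"moca_digest": _digest(y)},
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "multitrial_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


def run_singletrial(config: RunConfig) -> dict:
    """Simulate -> filter trials -> TF images -> BO -> final grouped CV."""
    spec = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(spec)
    st = config.singletrial

    images, labels, subj_ids = [], [], []
    filter_reports = {}
    for key, epochs in sorted(cohort.epochs.items()):
        corrected = baseline_correct(epochs)
        kept, rep = filter_single_trials(
            corrected,
            cohort.rts[key],
            rt_min=st.rt_min,
            rt_max=st.rt_max,
            range_max_uv=st.range_max_uv,
        )
        filter_reports["|".join(key)] = rep.to_dict()
        if kept.n_trials == 0:
            continue
        moca = cohort.moca_of(key[0])
        for img in epochs_to_tf_images(
            kept, label=moca, f_max=st.f_max, out_shape=st.image_shape
        ):
            images.append(img.power)
            labels.append(img.label)
            subj_ids.append(img.subject)
    images = np.array(images)
    labels = np.array(labels)
    subj_ids = np.array(subj_ids)

    k = min(st.cv_folds, len(np.unique(subj_ids)))
    objective = make_objective(images, labels, subj_ids, k=k, seed=config.seed)
    state = bayesopt.optimize(
        st.space,
        objective,
        n_presample=st.n_presample,
        n_iter=st.n_bo_iter,
        seed=config.seed,
    )

    best = state.best_config
    final_spec = CnnSpec(
        filter_size=int(best[0]), dropout_rate=float(best[1]), epochs=int(best[2])
    )
    rmse, mae = train_eval_cnn(
        images, labels, subj_ids, final_spec, k=k, seed=config.seed
    )

    report = {
        "branch": "singletrial",
        "seed": config.seed,
        "n_images": int(len(images)),
        "n_subjects": int(len(np.unique(subj_ids))),
        "filtering": filter_reports,
        "bo": state.to_dict(),
        "final": {
            "filter_size": int(best[0]),
            "dropout_rate": float(best[1]),
            "epochs": int(best[2]),
            "rmse": rmse,
            "mae": mae,
        },
        "label_sd": float(np.std(labels)),
        "provenance": {"image_digest": _digest(images)},
    }
    if st.shuffled_null:
        rng = np.random.default_rng(config.seed + 1)
        shuffled = labels.copy()
        # permute labels between subjects, keeping within-subject constancy
        uniq = np.unique(subj_ids)
        perm = rng.permutation(uniq)
        moca_by_subj = {s: labels[subj_ids == s][0] for s in uniq}
        for s, ps in zip(uniq, perm):
            shuffled[subj_ids == s] = moca_by_subj[ps]
        null_rmse, null_mae = train_eval_cnn(
            images, shuffled, subj_ids, final_spec, k=k, seed=config.seed
        )
        report["shuffled_null"] = {"rmse": null_rmse, "mae": null_mae}
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "singletrial_report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report


# ---------------------------------------------------------------------------
# ERP container round-trip used by the CLI stages
# ---------------------------------------------------------------------------

def save_erps(erps: dict[tuple[str, str], ErpWaveform], path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        for (sid, stim), erp in erps.items():
            g = f.require_group(sid).require_group(stim)
            d = g.create_dataset("data", data=erp.data)
            g.create_dataset("times", data=erp.times)
            d.attrs["fs"] = erp.fs
            d.attrs["n_trials_averaged"] = erp.n_trials_averaged
            if erp.filter_band is not None:
                d.attrs["filter_band"] = list(erp.filter_band)


def load_erps(path: str | Path) -> dict[tuple[str, str], ErpWaveform]:
    out = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            for stim in f[sid]:
                d = f[sid][stim]["data"]
                band = d.attrs.get("filter_band")
                out[(sid, stim)] = ErpWaveform(
                    data=d[...],
                    fs=float(d.attrs["fs"]),
                    times=f[sid][stim]["times"][...],
                    n_trials_averaged=int(d.attrs["n_trials_averaged"]),
                    filter_band=tuple(band) if band is not None else None,
                )
    return out
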