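"""End-to-end analyses: moisture-content modeling and whiteness grading.

``run_moisture`` mirrors the full model-comparison study: preprocess
(default MSC, reference frozen on the training split), reduce wavelengths by
SPA and PCA, then fit every configured model — full-spectrum PLSR and BP,
SPA-BP, PCA-BP with 3/4/5 components, SPA-PLSR, PCA-PLSR and SPA-SSA-BP —
reporting RC2/RMSEC on the training split and Rp2/RMSEP on the held-out
split for each.

``run_whiteness`` computes per-sample Ganz whiteness and grades, per-grade
summary statistics, a Kruskal-Wallis rank test across grades, and
(optionally) a BP regression of whiteness on SPA-selected bands.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .features import pca_fit, pca_select, pca_transform, spa_select
from .neural import BpConfig, bp_predict, bp_scan_hidden, bp_train
from .plsr import plsr_fit, plsr_predict, plsr_select_k
from .preprocess import MscModel, PreprocessConfig, apply_preprocess
from .spectra import ModelMetrics, SpectrumSet, r2_score, rmse, split_train_test
from .ssa import SsaConfig
from .ssa_bp import ssa_bp_train
from .synthetic import GeneratorConfig, generate_spectra, generate_whiteness_batches
from .whiteness import whiteness_pipeline

__all__ = ["MoistureRunConfig", "WhitenessRunConfig", "run_moisture",
           "run_whiteness", "average_replicates"]

DEFAULT_MOISTURE_MODELS = (
    "full-plsr", "full-bp", "spa-bp", "pca-bp-5", "pca-bp-4", "pca-bp-3",
    "spa-plsr", "pca-plsr", "spa-ssa-bp",
)


@dataclass(frozen=True)
class MoistureRunConfig:
    seed: int = 0
    generator: GeneratorConfig | None = None   # used when no spectra are passed
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    spa_max_size: int = 10
    models: tuple[str, ...] = DEFAULT_MOISTURE_MODELS
    bp: BpConfig = field(default_factory=BpConfig)
    ssa: SsaConfig = field(default_factory=SsaConfig)
    scan_hidden: bool = False       # scan 5-10 hidden units per BP model


@dataclass(frozen=True)
class WhitenessRunConfig:
    seed: int = 0
    n_per_grade: int = 40
    generator: GeneratorConfig | None = None
    regression: bool = False        # BP model spectra -> whiteness
    spa_max_size: int = 32
    bp: BpConfig = field(default_factory=BpConfig)


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Collapse replicate scans (rows sharing a sample_id) to their mean."""
    ids = pd.Index(sset.sample_ids)
    order = ids.drop_duplicates()
    values = np.vstack([sset.values[ids == sid].mean(axis=0) for sid in order])
    labels = None
    if sset.labels is not None:
        labels = pd.DataFrame([
            sset.labels[(ids == sid).tolist()].iloc[0] for sid in order
        ]).reset_index(drop=True)
    return SpectrumSet(sset.grid, values, list(order), labels)


def _metrics(y_tr, p_tr, y_te, p_te) -> ModelMetrics:
    return ModelMetrics(r2_score(y_tr, p_tr), rmse(y_tr, p_tr),
                        r2_score(y_te, p_te), rmse(y_te, p_te))


def _manifest(config, seed: int) -> dict:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return {
        "config": json.loads(blob),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }


def _fit_bp(X_tr, y_tr, X_te, cfg: MoistureRunConfig, stage: str):
    bp_cfg = replace(cfg.bp, seed=cfg.bp.seed + zlib.crc32(stage.encode()) % 1000)
    if cfg.scan_hidden:
        model, _ = bp_scan_hidden(X_tr, y_tr, config=bp_cfg)
    else:
        model = bp_train(X_tr, y_tr, bp_cfg)
    return model, bp_predict(model, X_tr), bp_predict(model, X_te)


def run_moisture(sset: SpectrumSet | None = None,
                 config: MoistureRunConfig | None = None) -> dict:
    """Train and compare all configured moisture models; returns a results dict
    with the comparison table, fitted models, selection artifacts and manifest."""
    config = config or MoistureRunConfig()
    if sset is None:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        sset, _ = generate_spectra(gen)
    if sset.labels is None or "moisture_pct" not in sset.labels.columns:
        raise ValueError("moisture analysis needs 'moisture_pct' labels")

    train, test = split_train_test(sset, config.seed)
    y_tr = train.label("moisture_pct")
    y_te = test.label("moisture_pct")

    msc_model = None
    if config.preprocess.method == "msc":
        msc_model = MscModel.fit(train)
    train_p, _ = apply_preprocess(train, config.preprocess, msc_model)
    test_p, _ = apply_preprocess(test, config.preprocess, msc_model)
    X_tr, X_te = train_p.values, test_p.values

    artifacts: dict = {}
    needs_spa = any(m.startswith("spa") for m in config.models)
    needs_pca = any(m.startswith("pca") for m in config.models)
    if needs_spa:
        spa = spa_select(X_tr, y_tr, config.spa_max_size, grid=sset.grid,
                         seed=config.seed)
        artifacts["spa"] = spa
        S_tr, S_te = X_tr[:, spa.selected_indices], X_te[:, spa.selected_indices]
    if needs_pca:
        pca = pca_select(pca_fit(X_tr))
        artifacts["pca"] = pca

    rows, models = [], {}
    for name in config.models:
        if name == "full-plsr":
            k, _ = plsr_select_k(X_tr, y_tr, k_max=15, seed=config.seed)
            m = plsr_fit(X_tr, y_tr, k)
            p_tr, p_te = plsr_predict(m, X_tr), plsr_predict(m, X_te)
        elif name == "spa-plsr":
            k, _ = plsr_select_k(S_tr, y_tr, seed=config.seed)
            m = plsr_fit(S_tr, y_tr, k)
            p_tr, p_te = plsr_predict(m, S_tr), plsr_predict(m, S_te)
        elif name == "pca-plsr":
            k_feats = pca.n_selected
            P_tr = pca_transform(pca, X_tr, k_feats)
            P_te = pca_transform(pca, X_te, k_feats)
            k, _ = plsr_select_k(P_tr, y_tr, seed=config.seed)
            m = plsr_fit(P_tr, y_tr, k)
            p_tr, p_te = plsr_predict(m, P_tr), plsr_predict(m, P_te)
        elif name == "full-bp":
            m, p_tr, p_te = _fit_bp(X_tr, y_tr, X_te, config, name)
        elif name == "spa-bp":
            m, p_tr, p_te = _fit_bp(S_tr, y_tr, S_te, config, name)
        elif name.startswith("pca-bp-"):
            k_feats = int(name.rsplit("-", 1)[1])
            P_tr = pca_transform(pca, X_tr, k_feats)
            P_te = pca_transform(pca, X_te, k_feats)
            m, p_tr, p_te = _fit_bp(P_tr, y_tr, P_te, config, name)
        elif name == "spa-ssa-bp":
            m = ssa_bp_train(S_tr, y_tr, config.bp, config.ssa)
            p_tr, p_te = bp_predict(m, S_tr), bp_predict(m, S_te)
        else:
            raise ValueError(f"unknown model {name!r}")
        met = _metrics(y_tr, p_tr, y_te, p_te)
        models[name] = m
        rows.append({"model": name, **met.as_dict()})

    return {
        "table": pd.DataFrame(rows).set_index("model"),
        "models": models,
        "train": train,
        "test": test,
        **artifacts,
        "manifest": _manifest(config, config.seed),
    }


def run_whiteness(sset: SpectrumSet | None = None,
                  config: WhitenessRunConfig | None = None) -> dict:
    """Whiteness colorimetry, grade statistics, across-grade test, optional
    spectra->whiteness regression."""
    config = config or WhitenessRunConfig()
    if sset is None:
        gen = config.generator or GeneratorConfig(seed=config.seed)
        sset, _ = generate_whiteness_batches(config.n_per_grade, gen)

    results = whiteness_pipeline(sset)
    per_sample = pd.DataFrame([{
        "sample_id": r.sample_id, "X10": r.X10, "Y10": r.Y10, "Z10": r.Z10,
        "x10": r.x10, "y10": r.y10, "W10": r.W10, "grade": r.grade,
        "flag": r.flag,
    } for r in results])

    out: dict = {"per_sample": per_sample,
                 "manifest": _manifest(config, config.seed)}

    if sset.labels is not None and "grade" in sset.labels.columns:
        true_grade = sset.label("grade").astype(int)
        w = per_sample["W10"].to_numpy()
        stats_rows = []
        groups = []
        for level in sorted(set(true_grade)):
            wl = w[true_grade == level]
            groups.append(wl)
            stats_rows.append({
                "grade": level, "n": wl.size, "min": wl.min(),
                "median": float(np.median(wl)), "max": wl.max(),
            })
        out["grade_stats"] = pd.DataFrame(stats_rows).set_index("grade")
        if len(groups) >= 2:
            out["kruskal_p"] = float(stats.kruskal(*groups).pvalue)
        else:
            out["kruskal_p"] = None
            out["notice"] = "only one grade present: across-grade test skipped"

    if config.regression:
        if sset.labels is None or "whiteness" not in sset.labels.columns:
            raise ValueError("whiteness regression needs 'whiteness' labels")
        train, test = split_train_test(sset, config.seed)
        y_tr, y_te = train.label("whiteness"), test.label("whiteness")
        spa = spa_select(train.values, y_tr, config.spa_max_size,
                         grid=sset.grid, seed=config.seed)
        S_tr = train.values[:, spa.selected_indices]
        S_te = test.values[:, spa.selected_indices]
        model = bp_train(S_tr, y_tr, config.bp)
        met = _metrics(y_tr, bp_predict(model, S_tr), y_te, bp_predict(model, S_te))
        out["regression_metrics"] = met
        out["regression_spa"] = spa
        out["regression_model"] = model
    return out
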