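"""End-to-end five-model comparison harness.

Reproduces the experimental design of the multiblock soil-spectra
workflow on synthetic or user-supplied data: preprocess both sensor
blocks with per-attribute recipes, carve one shared Kennard-Stone
training/test split, then fit and evaluate five model families per
attribute:

* MIR-TPLS, XRF-TPLS - single-sensor PLS;
* SF-PLS           - PLS on the concatenated (fused) spectra;
* SF-SOPLS         - sequential orthogonalized two-block fit;
* SF-VIP-SOPLS     - sequential fit on VIP-selected channels.

The split is computed once, on a stateless reference preprocessing
(moving average + max-normalize of each block, concatenated), so all
models and attributes share the same test set; stateful recipe
statistics (the MSC reference) are learned on the training partition
only and frozen for the test partition.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blocks import SpectraBlock, AttributeTable, concatenate, read_spectra, read_attributes
from .datasets import SynthConfig, generate
from .metrics import evaluate
from .pls import fit_pls, select_lv, make_folds
from .preprocess import mir_preset, xrf_preset, fit_recipe, moving_average, max_normalize
from .sampling import kennard_stone, SplitIndex
from .sopls import fit_sopls, select_lv_grid
from .vip import fit_sf_vip_sopls

__all__ = ["RunConfig", "ComparisonResult", "run_comparison", "MODEL_NAMES"]

logger = logging.getLogger("soilfusion")

MODEL_NAMES = ("MIR-TPLS", "XRF-TPLS", "SF-PLS", "SF-SOPLS", "SF-VIP-SOPLS")


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved configuration of one comparison run."""

    synth: SynthConfig | None = None
    mir_path: str | None = None
    xrf_path: str | None = None
    attributes_path: str | None = None
    fraction: float = 0.8
    folds: int = 10          # k-fold CV for single-block LV selection
    grid_folds: int = 5      # k-fold CV for the (a1, a2) grid search
    max_lv: int = 15
    max_a1: int = 10
    max_a2: int = 10
    vip_threshold: float = 1.0
    seed: int = 0
    out_dir: str | None = None
    attributes: tuple[str, ...] = ()  # empty = all in the table

    def __post_init__(self) -> None:
        if self.synth is None and not (
            self.mir_path and self.xrf_path and self.attributes_path
        ):
            raise ValueError(
                "RunConfig needs either a SynthConfig or all three input paths"
            )
        if not 0.0 < self.fraction < 1.0:
            raise ValueError(f"fraction must be in (0, 1), got {self.fraction!r}")
        for name in ("folds", "grid_folds", "max_lv", "max_a1", "max_a2"):
            if getattr(self, name) < 1 and name not in ("max_a1", "max_a2"):
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synth is not None:
            d["synth"] = self.synth.to_dict()
        return d


@dataclass(frozen=True)
class ComparisonResult:
    """Evaluation grid plus per-model metadata from one run."""

    report: pd.DataFrame
    split: SplitIndex
    config: RunConfig
    details: dict = field(default_factory=dict)  # per (attribute, model) metadata


def _load_blocks(config: RunConfig):
    if config.synth is not None:
        ds = generate(config.synth)
        return ds.mir, ds.xrf, ds.attributes
    mir = read_spectra(config.mir_path, label="MIR")
    xrf = read_spectra(config.xrf_path, label="XRF")
    attrs = read_attributes(config.attributes_path)
    return mir, xrf, attrs


def _reference_split(mir: SpectraBlock, xrf: SpectraBlock, fraction: float) -> SplitIndex:
    """Shared split on a stateless reference preprocessing of both blocks."""
    ref = concatenate(
        max_normalize(moving_average(mir)), max_normalize(moving_average(xrf))
    )
    return kennard_stone(ref, fraction=fraction)


def _cv_pls_predictions(X, y, n_lv, folds, seed):
    """Cross-validated training predictions at a fixed LV count."""
    labels = make_folds(len(y), folds, seed)
    preds = np.zeros(len(y))
    import warnings as _w
    for f in range(int(labels.max()) + 1):
        test = labels == f
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            m = fit_pls(X[~test], y[~test], min(n_lv, int((~test).sum()) - 1))
        preds[test] = m.predict(X[test]).ravel()
    return preds


def _cv_sopls_predictions(X1, X2, y, a1, a2, folds, seed):
    labels = make_folds(len(y), folds, seed)
    preds = np.zeros(len(y))
    import warnings as _w
    for f in range(int(labels.max()) + 1):
        test = labels == f
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            m = fit_sopls(X1[~test], X2[~test], y[~test], a1, a2)
        preds[test] = m.predict(X1[test], X2[test]).ravel()
    return preds


def run_comparison(config: RunConfig) -> ComparisonResult:
    """Run the full five-model comparison; deterministic given the seed."""
    t0 = time.time()
    mir, xrf, attrs = _load_blocks(config)
    logger.info(
        "data: %d samples, MIR %d channels, XRF %d channels",
        mir.n_samples, mir.n_channels, xrf.n_channels,
    )
    split = _reference_split(mir, xrf, config.fraction)
    logger.info("Kennard-Stone split: %d train / %d test", split.n_train, split.n_test)

    names = config.attributes or attrs.names
    unknown = [a for a in names if a not in attrs.names]
    if unknown:
        raise ValueError(f"unknown attribute(s) {unknown}; table has {list(attrs.names)}")

    entries = []
    details: dict = {}
    for i, attr in enumerate(names):
        seed_i = config.seed + 31 * i
        y_tr = attrs.subset(split.train_ids).column(attr)
        y_te = attrs.subset(split.test_ids).column(attr)

        # per-attribute preprocessing, statistics learned on train only
        blocks_tt = {}
        for sensor, block, preset in (
            ("MIR", mir, mir_preset(attr)),
            ("XRF", xrf, xrf_preset(attr)),
        ):
            recipe = fit_recipe(block.subset(split.train_ids), preset)
            blocks_tt[sensor] = (
                recipe.transform(block.subset(split.train_ids)).values,
                recipe.transform(block.subset(split.test_ids)).values,
            )
        X1_tr, X1_te = blocks_tt["MIR"]
        X2_tr, X2_te = blocks_tt["XRF"]
        Xf_tr = np.hstack([X1_tr, X2_tr])
        Xf_te = np.hstack([X1_te, X2_te])

        stage = time.time()
        # --- single-sensor and fused PLS ---------------------------------
        for model_name, (Xtr, Xte) in (
            ("MIR-TPLS", (X1_tr, X1_te)),
            ("XRF-TPLS", (X2_tr, X2_te)),
            ("SF-PLS", (Xf_tr, Xf_te)),
        ):
            cv = select_lv(Xtr, y_tr, max_lv=config.max_lv, folds=config.folds, seed=seed_i)
            model = fit_pls(Xtr, y_tr, cv.n_lv)
            entries.append(
                {
                    "attribute": attr, "model": model_name,
                    "y_train": y_tr,
                    "y_cv": _cv_pls_predictions(Xtr, y_tr, cv.n_lv, config.folds, seed_i),
                    "y_test": y_te, "y_pred": model.predict(Xte).ravel(),
                    "variables": Xtr.shape[1],
                }
            )
            details[(attr, model_name)] = {"n_lv": cv.n_lv, "rmsecv": cv.best_rmsecv}

        # --- sequential fusion -------------------------------------------
        grid = select_lv_grid(
            X1_tr, X2_tr, y_tr, max_a1=config.max_a1, max_a2=config.max_a2,
            folds=config.grid_folds, seed=seed_i,
        )
        so = fit_sopls(X1_tr, X2_tr, y_tr, grid.a1, grid.a2)
        entries.append(
            {
                "attribute": attr, "model": "SF-SOPLS",
                "y_train": y_tr,
                "y_cv": _cv_sopls_predictions(
                    X1_tr, X2_tr, y_tr, grid.a1, grid.a2, config.grid_folds, seed_i
                ),
                "y_test": y_te, "y_pred": so.predict(X1_te, X2_te).ravel(),
                "variables": X1_tr.shape[1] + X2_tr.shape[1],
            }
        )
        details[(attr, "SF-SOPLS")] = {"a1": grid.a1, "a2": grid.a2}

        # --- VIP-selected sequential fusion ------------------------------
        vm = fit_sf_vip_sopls(
            X1_tr, X2_tr, y_tr, folds=config.grid_folds, seed=seed_i,
            threshold=config.vip_threshold, max_lv=config.max_lv,
            max_a1=config.max_a1, max_a2=config.max_a2,
        )
        entries.append(
            {
                "attribute": attr, "model": "SF-VIP-SOPLS",
                "y_train": y_tr,
                "y_cv": _cv_sopls_predictions(
                    X1_tr[:, vm.mask1], X2_tr[:, vm.mask2], y_tr,
                    vm.grid.a1, vm.grid.a2, config.grid_folds, seed_i,
                ),
                "y_test": y_te, "y_pred": vm.predict(X1_te, X2_te).ravel(),
                "variables": vm.n_variables,
            }
        )
        details[(attr, "SF-VIP-SOPLS")] = {
            "a1": vm.grid.a1, "a2": vm.grid.a2,
            "selected_block1": int(vm.mask1.sum()),
            "selected_block2": int(vm.mask2.sum()),
            "vip_mask1": vm.mask1, "vip_mask2": vm.mask2,
        }
        logger.info("attribute %s done in %.1f s", attr, time.time() - stage)

    report = evaluate(entries)
    result = ComparisonResult(report=report, split=split, config=config, details=details)
    if config.out_dir is not None:
        _write_artifacts(result)
    logger.info("comparison finished in %.1f s", time.time() - t0)
    return result


def _write_artifacts(result: ComparisonResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.csv", index=False)
    result.split.save(out / "split.csv")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(result.config.to_dict(), fh, sort_keys=False)
    meta = {
        "package_version": __version__,
        "seed": result.config.seed,
        "model_choices": {
            f"{attr}/{model}": {
                k: (int(v.sum()) if isinstance(v, np.ndarray) else v)
                for k, v in d.items()
            }
            for (attr, model), d in result.details.items()
        },
    }
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    for (attr, model), d in result.details.items():
        if "vip_mask1" in d:
            pd.DataFrame(
                {
                    "block": ["MIR"] * d["vip_mask1"].size + ["XRF"] * d["vip_mask2"].size,
                    "selected": np.concatenate([d["vip_mask1"], d["vip_mask2"]]).astype(int),
                }
            ).to_csv(out / f"vip_mask_{attr}.csv", index=False)
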