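"""End-to-end orchestration: cohort synthesis, training, planning,
evaluation and paired comparison.

Every stage materializes its products to disk (doses as NRRD, plans and
provenance as JSON, reports as CSV) so each step of the
predict -> postprocess -> mimic chain can be audited afterwards.  All
randomness flows from explicit seeds recorded next to the outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dose_engine as de
from . import dose_model as dm
from . import evaluate as ev
from . import mimic
from . import phantoms
from .grid_core import (
    DoseGrid,
    RoiMask,
    StructureSet,
    build_input_channels,
    crop_pad,
    read_grid,
    read_structure_set,
    write_grid,
)
from .postprocess import apply_dvh_rules
from .settings import ModelSettings

log = logging.getLogger(__name__)

__all__ = ["run_synth_cohort", "run_train", "run_plan", "run_compare", "run_evaluate"]


def _write_run_record(out_dir: Path, settings: ModelSettings, seed: int, extra: dict) -> None:
    record = {"settings_hash": settings.content_hash(), "seed": seed, **extra}
    (out_dir / "run.json").write_text(json.dumps(record, indent=2, sort_keys=True))


def run_synth_cohort(
    out_dir: str | Path,
    settings: ModelSettings,
    n: int,
    seed: int = 0,
    split: tuple[int, int, int] | None = None,
) -> Path:
    """Generate a cohort of phantoms with reference doses and write it with
    a train/validation/test split manifest."""
    out_dir = Path(out_dir)
    cases = phantoms.generate_cohort(n, seed=seed, rx=settings.rx_gy)
    if split is None:
        n_train, n_val = settings.train.split
        n_train = min(n_train, max(n - 2, 1))
        n_val = min(n_val, max(n - n_train - 1, 1)) if n - n_train > 1 else max(n - n_train, 0)
        split = (n_train, n_val, n - n_train - n_val)
    groups = phantoms.split_cohort(n, split, seed=seed)
    split_dict = {
        "train": [int(i) for i in groups[0]],
        "validation": [int(i) for i in groups[1]],
        "test": [int(i) for i in groups[2]] if len(groups) > 2 else [],
    }
    phantoms.write_cohort(cases, out_dir, split=split_dict)
    _write_run_record(out_dir, settings, seed, {"n_cases": n, "split": split_dict})
    return out_dir


def _padded_dims(shape: tuple[int, int, int], depth: int) -> tuple[int, int, int]:
    f = 2**depth
    return tuple(int(-(-s // f) * f) for s in shape)


def _case_pairs(cases, settings: ModelSettings, depth: int):
    pairs = []
    for case in cases:
        ch = build_input_channels(case.structures, settings.roi_channel_map)
        target = case.dose.values / settings.rx_gy
        dims = _padded_dims(target.shape, depth)
        if dims != target.shape:
            ch = np.stack(
                [crop_pad(RoiMask("c", c.astype(bool)), dims).values.astype(np.float32) for c in ch]
            )
            target = crop_pad(DoseGrid(target, case.dose.spacing), dims).values
        pairs.append((ch.astype(np.float32), target[None].astype(np.float32)))
    return pairs


def run_train(
    cohort_dir: str | Path,
    settings: ModelSettings,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Train the dose-prediction U-Net on a cohort directory's manifest
    split; writes the checkpoint, the loss curves and the selected epoch."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases, split = phantoms.read_cohort(cohort_dir)
    if not split or not split.get("train"):
        raise ValueError("cohort manifest has no training split")
    if not split.get("validation"):
        raise ValueError("cohort manifest has no validation split: best-epoch selection undefined")

    config = dm.UNetConfig(level_channels=tuple(settings.train.level_channels), seed=seed)
    model = dm.build_unet(config)
    train_pairs = _case_pairs([cases[i] for i in split["train"]], settings, config.depth)
    val_pairs = _case_pairs([cases[i] for i in split["validation"]], settings, config.depth)
    tcfg = dm.TrainConfig(
        epochs=settings.train.epochs, learning_rate=settings.train.learning_rate, seed=seed
    )
    t0 = time.perf_counter()
    result = dm.train(model, train_pairs, val_pairs, tcfg)
    elapsed = time.perf_counter() - t0
    log.info("training finished in %.1f s, best epoch %d", elapsed, result.best_epoch)

    dm.save_checkpoint(out_dir / "checkpoint.npz", result.model, tcfg, result.best_epoch)
    losses = pd.DataFrame(
        {
            "epoch": np.arange(len(result.train_losses)),
            "train_l1": result.train_losses,
            "validation_l1": result.val_losses,
        }
    )
    losses.to_csv(out_dir / "losses.csv", index=False, float_format="%.8f")
    _write_run_record(
        out_dir, settings, seed,
        {"best_epoch": int(result.best_epoch), "n_train": len(train_pairs), "n_validation": len(val_pairs)},
    )
    return out_dir


@dataclass
class PlanProducts:
    predicted: DoseGrid
    postprocessed: DoseGrid
    mimicked: DoseGrid
    plan: de.SpotPlan
    goals: pd.DataFrame
    robustness: pd.DataFrame
    gamma_result: ev.GammaResult
    objective_trace: np.ndarray


def plan_case(
    structures: StructureSet,
    density: DoseGrid,
    model: dm.UNet3d,
    settings: ModelSettings,
) -> PlanProducts:
    """The machine part of planning one case:
    predict -> DVH postprocess -> spot placement -> robust mimic -> evaluate."""
    rx = settings.rx_gy
    depth = model.config.depth
    ch = build_input_channels(structures, settings.roi_channel_map)
    dims = _padded_dims(structures.shape, depth)
    ch_in = ch
    if dims != structures.shape:
        ch_in = np.stack(
            [crop_pad(RoiMask("c", c.astype(bool)), dims).values.astype(np.float32) for c in ch]
        )
    predicted = dm.predict_dose(model, ch_in, rx, density.spacing, density.origin)
    if dims != structures.shape:
        predicted = crop_pad(predicted, structures.shape)
        predicted = DoseGrid(predicted.values, density.spacing, density.origin)
    predicted = predicted.new_like(np.where(structures.external.values, predicted.values, 0.0))

    postprocessed = apply_dvh_rules(predicted, structures, settings.dvh_rules(), rx)

    target_union = np.zeros(structures.shape, dtype=bool)
    for m in structures.by_role("target"):
        target_union |= m.values
    e = settings.engine
    plan0 = de.place_spots(
        RoiMask("targets", target_union, role="target"),
        density,
        margin_mm=e.margin_mm,
        lateral_spacing_mm=e.lateral_spacing_mm,
        layer_spacing_mm=e.layer_spacing_mm,
    )
    engine_cfg = settings.engine_config()
    scen = settings.scenarios
    opt_scenarios = de.make_scenarios(scen.setup_mm, scen.range_pct, "optimization")
    influences = [
        de.influence_matrix(plan0, density, engine_cfg, s) / rx for s in opt_scenarios
    ]
    nominal_index = next(i for i, s in enumerate(opt_scenarios) if s.is_nominal)

    mcfg = settings.mimic_config()
    w = mimic.assign_voxel_weights(structures, mcfg)
    robust_mask = np.zeros(structures.shape, dtype=bool)
    for name in mcfg.robust_rois:
        if name in structures:
            robust_mask |= structures[name].values
    result = mimic.optimize(
        plan0, influences, postprocessed.values / rx, w, mcfg,
        robust_mask=robust_mask, nominal_index=nominal_index,
    )
    mimicked = DoseGrid(
        (influences[nominal_index] @ result.weights).reshape(structures.shape) * rx,
        density.spacing, density.origin,
    )

    goals = ev.evaluate_goals(mimicked, structures, settings.clinical_goals(), rx)
    eval_scenarios = de.make_scenarios(scen.setup_mm, scen.range_pct, "evaluation")
    scenario_doses = [
        DoseGrid(
            (de.influence_matrix(result.plan, density, engine_cfg, s) @ result.weights
             ).reshape(structures.shape),
            density.spacing, density.origin,
        )
        for s in eval_scenarios
    ]
    robustness = ev.robustness_pass_rate(scenario_doses, structures, settings.clinical_goals(), rx)
    g = ev.gamma(postprocessed, mimicked)
    return PlanProducts(predicted, postprocessed, mimicked, result.plan, goals,
                        robustness, g, result.trace)


def run_plan(
    case_dir: str | Path,
    checkpoint: str | Path,
    settings: ModelSettings,
    out_dir: str | Path,
    seed: int = 0,
) -> Path:
    """Plan one phantom case from disk and write all stage products."""
    case_dir, out_dir = Path(case_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    structures = read_structure_set(case_dir / "structures")
    density = read_grid(case_dir / "density.nrrd")
    model, _sidecar = dm.load_checkpoint(checkpoint)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    try:
        products = plan_case(structures, density, model, settings)
    except Exception as exc:  # pragma: no cover - error surface
        raise RuntimeError(f"planning failed during the optimization chain: {exc}") from exc
    timings["plan"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    write_grid(products.predicted, out_dir / "predicted.nrrd")
    write_grid(products.postprocessed, out_dir / "postprocessed.nrrd")
    write_grid(products.mimicked, out_dir / "mimicked.nrrd")
    products.plan.to_json(out_dir / "plan.json")
    products.goals.to_csv(out_dir / "goals.csv", index=False, float_format="%.6f")
    products.robustness.to_csv(out_dir / "robustness.csv", index=False, float_format="%.6f")
    (out_dir / "gamma.json").write_text(
        json.dumps({"pass_rate_pct": products.gamma_result.pass_rate_pct,
                    "n_evaluated": products.gamma_result.n_evaluated,
                    "criteria": "3%(local)/3mm, 10% threshold"}, indent=2)
    )
    edges, counts = products.gamma_result.histogram()
    pd.DataFrame({"gamma_bin_low": edges[:-1], "gamma_bin_high": edges[1:],
                  "count": counts}).to_csv(out_dir / "gamma_histogram.csv",
                                           index=False, float_format="%.4f")
    pd.DataFrame({"iteration": np.arange(len(products.objective_trace)),
                  "objective": products.objective_trace}).to_csv(
        out_dir / "objective_trace.csv", index=False, float_format="%.8e")
    timings["write"] = time.perf_counter() - t0
    for stage, dt in timings.items():
        log.info("stage %-6s %.2f s", stage, dt)
    _write_run_record(out_dir, settings, seed, {"timings_s": {k: round(v, 3) for k, v in timings.items()}})
    return out_dir


def run_evaluate(
    dose_path: str | Path,
    structures_dir: str | Path,
    settings: ModelSettings,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Score an existing dose volume against the configured clinical goals."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dose = read_grid(dose_path)
    structures = read_structure_set(structures_dir)
    goals = ev.evaluate_goals(dose, structures, settings.clinical_goals(), settings.rx_gy)
    goals.to_csv(out_dir / "goals.csv", index=False, float_format="%.6f")
    return goals


def run_compare(
    a_dir: str | Path,
    b_dir: str | Path,
    settings: ModelSettings,
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Paired per-goal comparison of two arms of planned cases.

    Both directories must contain matching case subdirectories, each with a
    ``goals.csv`` produced by :func:`run_plan`.  Reports per-goal means of
    both arms, the percent difference of means, and the two-sided Wilcoxon
    signed-rank p-value across cases.
    """
    a_dir, b_dir = Path(a_dir), Path(b_dir)
    a_cases = sorted(p.name for p in a_dir.iterdir() if (p / "goals.csv").exists())
    b_cases = sorted(p.name for p in b_dir.iterdir() if (p / "goals.csv").exists())
    if a_cases != b_cases:
        raise ValueError(
            f"case mismatch between arms: only in a: {sorted(set(a_cases) - set(b_cases))}, "
            f"only in b: {sorted(set(b_cases) - set(a_cases))}"
        )
    if not a_cases:
        raise ValueError("no planned cases found to compare")

    frames_a = [pd.read_csv(a_dir / c / "goals.csv") for c in a_cases]
    frames_b = [pd.read_csv(b_dir / c / "goals.csv") for c in b_cases]
    keys = frames_a[0][["roi", "goal"]]
    rows = []
    for i in range(len(keys)):
        va = np.array([f.loc[i, "value"] for f in frames_a], dtype=float)
        vb = np.array([f.loc[i, "value"] for f in frames_b], dtype=float)
        res = ev.paired_compare(va, vb)
        mean_a, mean_b = float(np.mean(va)), float(np.mean(vb))
        rows.append(
            {
                "roi": keys.loc[i, "roi"],
                "goal": keys.loc[i, "goal"],
                "mean_a": mean_a,
                "mean_b": mean_b,
                "pct_diff": 100.0 * (mean_b - mean_a) / mean_a if mean_a else np.nan,
                "wilcoxon_p": res.p_value,
                "degenerate": res.degenerate,
                "n_cases": len(va),
            }
        )
    table = pd.DataFrame(rows)
    if out_path is not None:
        table.to_csv(out_path, index=False, float_format="%.6f")
    return table
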