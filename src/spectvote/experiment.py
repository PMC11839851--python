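"""End-to-end experiment: simulate -> split -> train x methods x K -> intervals -> evaluate.

One :func:`run_experiment` call reproduces the whole study design at a
configurable scale: an in-distribution development cohort with 12
augmentation instances per scan and a three-reader panel, K scan-level
60/20/20 splits shared by all three training methods, one network per
(method, split), inconclusive-interval grids from each network's
validation subset, and the comparative evaluation on the in-distribution
test subsets and two out-of-distribution cohorts.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, OODProfile, generate_cohort, generate_ood_cohort
from .conclusiveness import (
    GRID_TARGETS,
    IntervalGrid,
    build_grid,
    determine_interval,
    grid_table,
    interval_range_coverage,
    observed_proportion,
)
from .evaluation import (
    CertaintyCurve,
    ConfusionCounts,
    balanced_accuracy,
    build_certainty_curve,
    certainty_auc,
    distance_by_consistency,
    nadeau_bengio_ttest,
    regression_through_origin,
)
from .labels import Method
from .network import DESK_SPEC, ArchitectureSpec
from .training import Subset, TrainingConfig, make_splits, predict, train


@dataclass(frozen=True)
class ExperimentConfig:
    n_scans: int = 200
    n_ood_scans: int = 200
    k_realizations: int = 3
    epochs: int = 12
    batch_size: int = 64
    learning_rate: float = 1e-4
    arch: ArchitectureSpec = DESK_SPEC
    methods: tuple[Method, ...] = (Method.MVT, Method.RVT, Method.AVT)
    seed: int = 0


@dataclass
class MethodRealization:
    """All artifacts for one trained network."""

    method: Method
    realization: int
    epoch_losses: list[float]
    val_pred: pd.DataFrame
    test_pred: pd.DataFrame
    ood_pred: dict[str, pd.DataFrame]
    grid: IntervalGrid
    curve: CertaintyCurve
    auc: float
    test_ba: float
    ood_slopes: dict[str, float]
    test_slope: float


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    runs: list[MethodRealization]
    summary: dict = field(default_factory=dict)
    elapsed_s: float = 0.0

    def runs_for(self, method: Method) -> list[MethodRealization]:
        return [r for r in self.runs if r.method is method]

    def interval_tables(self) -> pd.DataFrame:
        return pd.concat(
            [grid_table(r.grid, r.method.value, r.realization) for r in self.runs],
            ignore_index=True,
        )


def _derived_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _distance_gap(pred: pd.DataFrame) -> float:
    """Mean |s - 0.5| of reader-consistent minus reader-discrepant cases."""
    table = distance_by_consistency(pred.sigmoid.values, pred.unanimous.values)
    by = table.set_index("group").mean_distance
    if "discrepant" not in by.index or "consistent" not in by.index:
        return float("nan")
    return float(by["consistent"] - by["discrepant"])


def run_experiment(config: ExperimentConfig = ExperimentConfig(), verbose: bool = False) -> ExperimentResult:
    t_start = time.time()
    (cohort_seed, ppmi_seed, mph_seed, split_seed, *model_seeds) = _derived_seeds(
        config.seed, 4 + 3 * config.k_realizations
    )
    records = generate_cohort(CohortConfig(n_scans=config.n_scans, seed=cohort_seed))
    ood_cohorts = {
        "PPMI_LIKE": generate_ood_cohort(
            CohortConfig(n_scans=config.n_ood_scans, seed=ppmi_seed, ood_profile=OODProfile.PPMI_LIKE)
        ),
        "MPH_LIKE": generate_ood_cohort(
            CohortConfig(n_scans=config.n_ood_scans, seed=mph_seed, ood_profile=OODProfile.MPH_LIKE)
        ),
    }
    scan_ids = [r.scan_id for r in records]
    splits = make_splits(scan_ids, k=config.k_realizations, seed=split_seed)

    runs: list[MethodRealization] = []
    for i, split in enumerate(splits):
        init_seed, shuffle_seed, rvt_seed = model_seeds[3 * i : 3 * i + 3]
        for method in config.methods:
            tc = TrainingConfig(
                method=method,
                epochs=config.epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                init_seed=init_seed,  # identical initial weights across methods
                shuffle_seed=shuffle_seed,
                rvt_seed=rvt_seed,
            )
            trained = train(records, split, tc, config.arch)
            val_ids = set(split.scan_ids(Subset.VAL))
            test_ids = set(split.scan_ids(Subset.TEST))
            val_pred = predict(trained, records, val_ids)
            test_pred = predict(trained, records, test_ids)
            ood_pred = {
                name: predict(trained, cohort) for name, cohort in ood_cohorts.items()
            }
            grid = build_grid(val_pred.sigmoid.values)
            curve = build_certainty_curve(
                test_pred.sigmoid.values,
                test_pred.majority_label.values,
                grid,
                method.value,
                split.realization,
            )
            auc = certainty_auc(curve)
            test_ba = balanced_accuracy(
                ConfusionCounts.from_predictions(
                    test_pred.majority_label.values, test_pred.prediction.values
                )
            )
            targets = np.array(GRID_TARGETS)
            test_slope = regression_through_origin(
                targets,
                [observed_proportion(test_pred.sigmoid.values, iv) for iv in grid],
            )
            ood_slopes = {
                name: regression_through_origin(
                    targets,
                    [observed_proportion(p.sigmoid.values, iv) for iv in grid],
                )
                for name, p in ood_pred.items()
            }
            runs.append(
                MethodRealization(
                    method,
                    split.realization,
                    trained.epoch_losses,
                    val_pred,
                    test_pred,
                    ood_pred,
                    grid,
                    curve,
                    auc,
                    test_ba,
                    ood_slopes,
                    test_slope,
                )
            )
            if verbose:
                print(
                    f"[{method.value} r{split.realization}] "
                    f"loss {trained.epoch_losses[0]:.3f}->{trained.epoch_losses[-1]:.3f} "
                    f"BA {test_ba:.1f} AUC {auc:.1f}",
                    flush=True,
                )

    result = ExperimentResult(config, runs)
    result.summary = summarize(result)
    result.elapsed_s = time.time() - t_start
    return result


def summarize(result: ExperimentResult) -> dict:
    """Per-method aggregates and pairwise corrected t-tests."""
    out: dict = {}
    per_method: dict[str, dict] = {}
    for method in result.config.methods:
        rs = result.runs_for(method)
        val_sig = [r.val_pred for r in rs]
        coverage5 = [
            interval_range_coverage(determine_interval(p.sigmoid.values, 0.05))
            for p in val_sig
        ]
        per_method[method.value] = {
            "test_balanced_accuracy": float(np.mean([r.test_ba for r in rs])),
            "certainty_auc": float(np.mean([r.auc for r in rs])),
            "coverage5_percent": float(np.mean(coverage5)),
            # realizations whose validation subset happens to contain no
            # discrepant scan cannot contribute a gap
            "val_distance_gap": float(
                np.nanmean([_distance_gap(r.val_pred) for r in rs])
            ),
            "test_slope": float(np.mean([r.test_slope for r in rs])),
            "ood_slopes": {
                name: float(np.mean([r.ood_slopes[name] for r in rs]))
                for name in rs[0].ood_slopes
            },
        }
    out["per_method"] = per_method
    tests = {}
    if result.config.k_realizations < 2:
        out["auc_paired_tests"] = tests
        return out
    methods = list(result.config.methods)
    for a in methods:
        for b in methods:
            if methods.index(a) >= methods.index(b):
                continue
            da = np.array([r.auc for r in result.runs_for(a)])
            db = np.array([r.auc for r in result.runs_for(b)])
            cmp = nadeau_bengio_ttest(da - db, metric="certainty_auc")
            tests[f"{a.value}_vs_{b.value}"] = {
                "t": cmp.t_corrected,
                "p": cmp.p_two_sided,
                "mean_difference": cmp.mean_difference,
            }
    out["auc_paired_tests"] = tests
    return out
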