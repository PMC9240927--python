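"""Cross-validation, donor-subgroup training strategies and scenario
prediction.

``cross_validate`` reproduces the k-fold protocol: the cohort is split
into k random partitions; in each round one partition is held out, the
model is trained and the risk-bin calibration fitted on the remaining
folds only, and both raw and calibrated predictions are scored on the
held-out fold.

``strategy_experiment`` compares three ways of obtaining predictions for
a minority donor subgroup (e.g. DCD grafts): training on the subgroup
only, training on the combined cohort, and transfer learning (pretrain
on the majority subgroup, fine-tune on the minority), all evaluated on
held-out minority data.

``scenario_predict`` implements the decision-support view: for a fixed
recipient, calibrated survival curves under the offered donor and under
predefined average DCD / average NDD donor profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import RiskBinModel
from .core import SurvivalDataset, SurvivalMatrix, TimeGrid, hazards_to_survival
from .metrics import MetricReport, antolini_cindex, evaluate_model
from .model import LossConfig, ModelConfig, RecurrentHazard, RecurrentHazardResults

__all__ = [
    "ExperimentConfig",
    "AverageDonorProfile",
    "kfold_split",
    "cross_validate",
    "strategy_experiment",
    "scenario_predict",
]

STRATEGIES = ("subgroup_only", "combined", "transfer")


@dataclass
class ExperimentConfig:
    """Settings of a cross-validation or strategy experiment."""

    k_folds: int = 5
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    n_bins: int = 10
    strategy: str = "combined"
    subgroup_column: str = "group"
    subgroup_labels: tuple[str, str] = ("NDD", "DCD")  # (majority, minority)
    horizons: tuple[float, ...] = (1.0, 5.0, 15.0)

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """k disjoint random index sets covering range(n), sizes differing by <= 1."""
    if k > n:
        raise ValueError("k must not exceed n")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return [np.sort(part) for part in np.array_split(rng.permutation(n), k)]


def _fit_with_seed(data, grid, cfg: ExperimentConfig, seed: int) -> RecurrentHazardResults:
    mcfg = ModelConfig(**{**cfg.model.__dict__, "seed": seed})
    return RecurrentHazard(data, grid, mcfg, cfg.loss).fit()


def cross_validate(
    config: ExperimentConfig,
    data: SurvivalDataset,
    grid: TimeGrid | None = None,
) -> dict:
    """k-fold cross-validation of the calibrated recurrent hazard model.

    Returns per-fold :class:`MetricReport` pairs (raw and calibrated
    predictions) plus a mean +/- sd summary across completed folds.
    """
    grid = grid or TimeGrid()
    folds = kfold_split(data.n, config.k_folds, config.seed)
    all_idx = np.arange(data.n)
    fold_reports: list[dict] = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train, test = data.subset(train_idx), data.subset(test_idx)
        try:
            result = _fit_with_seed(train, grid, config, config.seed + f)
            train_scores = result.predict_risk_scores(train)
            bin_model = RiskBinModel.fit(train, train_scores, grid, config.n_bins)
            raw_S = result.predict_survival(test)
            cal_h = bin_model.calibrate(result.predict_risk_scores(test))
            cal_S = hazards_to_survival(cal_h)
            provenance = {
                "fold": f,
                "strategy": config.strategy,
                "n_train": int(train.n),
                "n_test": int(test.n),
                "calibration_fit_on": "training_fold",
                "n_bins": config.n_bins,
            }
            fold_reports.append(
                {
                    "fold": f,
                    "raw": evaluate_model(raw_S, test, grid, config.horizons,
                                          settings=provenance),
                    "calibrated": evaluate_model(cal_S, test, grid, config.horizons,
                                                 settings=provenance),
                }
            )
        except Exception as err:
            warnings.warn(f"fold {f} failed and was skipped: {err}", RuntimeWarning)
    if not fold_reports:
        raise RuntimeError("all cross-validation folds failed")
    return {
        "folds": fold_reports,
        "mean": {
            kind: _mean_report([fr[kind] for fr in fold_reports])
            for kind in ("raw", "calibrated")
        },
    }


def _mean_report(reports: list[MetricReport]) -> dict:
    out: dict = {}
    for name in ("harrell_c", "antolini_c", "ibs"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        out[name] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    for name in ("brier", "ici"):
        keys = getattr(reports[0], name).keys()
        out[name] = {
            k: {
                "mean": float(np.mean([getattr(r, name)[k] for r in reports])),
                "sd": float(np.std([getattr(r, name)[k] for r in reports])),
            }
            for k in keys
        }
    return out


# ----------------------------------------------------------------------
# Donor-subgroup training strategies
# ----------------------------------------------------------------------
def strategy_experiment(
    data: SurvivalDataset,
    grid: TimeGrid | None = None,
    config: ExperimentConfig | None = None,
    strategies: tuple[str, ...] = STRATEGIES,
) -> pd.DataFrame:
    """Compare training strategies on a held-out minority-subgroup set.

    A fraction 1/k_folds of the minority subgroup is held out for
    evaluation; the remaining data feed each strategy's training set.
    Returns a tidy frame (strategy, c_index, n_train, n_eval).
    """
    grid = grid or TimeGrid()
    config = config or ExperimentConfig()
    if data.group_label is None:
        raise ValueError("strategy_experiment needs a dataset with group labels")
    majority, minority = config.subgroup_labels
    labels = np.asarray(data.group_label, dtype=object)
    for lab in (majority, minority):
        if not np.any(labels == lab):
            raise ValueError(f"subgroup label {lab!r} not present in the data")

    minority_idx = np.flatnonzero(labels == minority)
    folds = kfold_split(minority_idx.size, config.k_folds, config.seed)
    test_idx = minority_idx[folds[0]]
    train_mask = np.ones(data.n, dtype=bool)
    train_mask[test_idx] = False
    train_all = data.subset(np.flatnonzero(train_mask))
    test = data.subset(test_idx)
    test_intervals, test_events = test.discretize(grid)

    train_labels = labels[train_mask]
    sub_train = train_all.subset(np.flatnonzero(train_labels == minority))
    maj_train = train_all.subset(np.flatnonzero(train_labels == majority))

    rows = []
    for strategy in strategies:
        if strategy == "subgroup_only":
            result = _fit_with_seed(sub_train, grid, config, config.seed)
            n_train = sub_train.n
        elif strategy == "combined":
            result = _fit_with_seed(train_all, grid, config, config.seed)
            n_train = train_all.n
        elif strategy == "transfer":
            mcfg = ModelConfig(**{**config.model.__dict__, "seed": config.seed})
            result = RecurrentHazard.transfer_fit(
                maj_train, sub_train, grid, mcfg, config.loss
            )
            n_train = maj_train.n + sub_train.n
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        S = result.predict_survival(test)
        c = antolini_cindex(S, test_intervals, test_events)
        rows.append(
            {"strategy": strategy, "c_index": c, "n_train": n_train, "n_eval": test.n}
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Scenario prediction (decision support)
# ----------------------------------------------------------------------
@dataclass
class AverageDonorProfile:
    """Reference donor: means of continuous donor covariates, modes of
    categorical ones, computed from a training subgroup."""

    values: dict[str, float]

    @classmethod
    def from_training(
        cls,
        data: SurvivalDataset,
        donor_columns: list[str],
        subgroup_label: str | None = None,
    ) -> "AverageDonorProfile":
        mask = np.ones(data.n, dtype=bool)
        if subgroup_label is not None:
            if data.group_label is None:
                raise ValueError("dataset has no group labels")
            mask = np.asarray(data.group_label, dtype=object) == subgroup_label
            if not mask.any():
                raise ValueError(f"no rows with group label {subgroup_label!r}")
        X = data.covariates[mask]
        name_to_idx = {n: i for i, n in enumerate(data.column_names)}
        # group expanded one-hot columns ("var=level") back into blocks
        blocks: dict[str, list[str]] = {}
        for col in donor_columns:
            if col not in name_to_idx:
                raise KeyError(f"unknown covariate column {col!r}")
            base = col.split("=", 1)[0] if "=" in col else col
            blocks.setdefault(base, []).append(col)
        values: dict[str, float] = {}
        for base, cols in blocks.items():
            if len(cols) == 1 and "=" not in cols[0]:
                values[cols[0]] = float(X[:, name_to_idx[cols[0]]].mean())
            else:  # one-hot block: mode level gets 1, the rest 0
                means = [X[:, name_to_idx[c]].mean() for c in cols]
                top = int(np.argmax(means))
                for j, c in enumerate(cols):
                    values[c] = 1.0 if j == top else 0.0
        return cls(values)


def scenario_predict(
    result: RecurrentHazardResults,
    bin_model: RiskBinModel,
    recipient_covariates: dict[str, float],
    offered_donor_covariates: dict[str, float],
    training_data: SurvivalDataset,
    donor_columns: list[str],
    subgroup_labels: tuple[str, str] = ("NDD", "DCD"),
) -> dict[str, SurvivalMatrix]:
    """Calibrated survival curves under three scenarios.

    The offered-donor scenario combines the recipient with the entered
    donor; the two reference scenarios replace the donor covariates by the
    average DCD and average NDD donor profiles computed from the training
    data.  Returns label -> single-row :class:`SurvivalMatrix`.
    """
    columns = result.column_names
    donor_set = set(donor_columns)
    expected_recipient = [c for c in columns if c not in donor_set]
    missing = [c for c in expected_recipient if c not in recipient_covariates]
    if missing:
        raise KeyError(f"missing recipient covariates: {missing}")
    missing = [c for c in donor_columns if c not in offered_donor_covariates]
    if missing:
        raise KeyError(f"missing donor covariates: {missing}")
    unknown = [c for c in donor_columns if c not in columns]
    if unknown:
        raise KeyError(f"unknown donor columns: {unknown}")

    majority, minority = subgroup_labels
    profiles = {
        f"average_{minority}": AverageDonorProfile.from_training(
            training_data, donor_columns, minority
        ),
        f"average_{majority}": AverageDonorProfile.from_training(
            training_data, donor_columns, majority
        ),
    }

    def build_row(donor_values: dict[str, float]) -> np.ndarray:
        row = np.empty(len(columns))
        for j, col in enumerate(columns):
            row[j] = donor_values[col] if col in donor_set else recipient_covariates[col]
        return row

    rows = {"offered_donor": build_row(offered_donor_covariates)}
    for label, profile in profiles.items():
        rows[label] = build_row(profile.values)

    out: dict[str, SurvivalMatrix] = {}
    for label, row in rows.items():
        scores = result.predict_risk_scores(row[None, :])
        out[label] = hazards_to_survival(bin_model.calibrate(scores))
    return out
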