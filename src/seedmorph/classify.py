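"""Stepwise linear discriminant analysis for cultivar attribution.

Feature selection is the classic Wilks'-lambda stepwise procedure: at each
step every excluded descriptor's partial F-to-enter and every included
descriptor's partial F-to-remove are computed from determinant ratios of
within-group (W) and total (T) sums-of-squares-and-cross-products
submatrices,

    Lambda(S) = det(W_S) / det(T_S),
    F_enter(x | S)  = (n - g - p) / (g - 1) * (Lambda_S / Lambda_{S+x} - 1),
    F_remove(x in S) = (n - g - p + 1) / (g - 1) * (Lambda_{S-x} / Lambda_S - 1),

with ``p = |S|`` variables currently in the model, ``n`` specimens and
``g`` classes.  A candidate may enter only if its within-group tolerance
(1 - R^2 against the included set) clears the collinearity guard.  Default
thresholds (F-to-enter 3.84, F-to-remove 2.71, tolerance 0.001) follow the
conventions of the classic statistics packages that popularised the
procedure.

Classification uses Gaussian linear discriminant scores with the pooled
within-class covariance; unknown specimens (e.g. an archaeological cohort)
are allocated to the argmax-posterior class and summarised as a
row-percentage allocation table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import (
    CollinearityError,
    EmptyModelError,
    InputError,
    ValidationError,
)
from .morphometry import FEATURE_NAMES, FeatureTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepwiseConfig:
    """Controls of the stepwise selection: the entry/removal partial-F
    thresholds, the collinearity tolerance, a step cap and the prior rule."""

    tolerance: float = 0.001
    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    max_steps: int = 200
    priors: str = "equal"

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 1.0:
            raise ValidationError(f"tolerance must be in (0, 1), got {self.tolerance}")
        if self.f_to_enter < 0 or self.f_to_remove < 0:
            raise ValidationError("F thresholds must be non-negative")
        if self.f_to_remove >= self.f_to_enter:
            raise ValidationError(
                f"f_to_remove ({self.f_to_remove}) must be < f_to_enter ({self.f_to_enter})"
            )
        if self.max_steps < 1:
            raise ValidationError("max_steps must be >= 1")
        if self.priors not in ("equal", "proportional"):
            raise ValidationError(f"priors must be 'equal' or 'proportional', got {self.priors!r}")


def _group_sscp(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) SSCP matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for label in np.unique(y):
        G = X[y == label]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def _logdet(M: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(M)
    return ld if sign > 0 else -np.inf


def _wilks(W: np.ndarray, T: np.ndarray, idx: list[int]) -> float:
    """Wilks' lambda of the feature subset ``idx`` (1.0 for the empty set)."""
    if not idx:
        return 1.0
    sub = np.ix_(idx, idx)
    lw, lt = _logdet(W[sub]), _logdet(T[sub])
    if not np.isfinite(lw) or not np.isfinite(lt):
        return np.nan
    return float(np.exp(lw - lt))


def _tolerance(W: np.ndarray, included: list[int], cand: int) -> float:
    """Within-group tolerance (1 - R^2) of a candidate given the model."""
    if W[cand, cand] <= 0:
        return 0.0
    if not included:
        return 1.0
    sub = np.ix_(included, included)
    ld_s = _logdet(W[sub])
    full = included + [cand]
    ld_f = _logdet(W[np.ix_(full, full)])
    if not np.isfinite(ld_s):
        return 0.0
    if not np.isfinite(ld_f):
        return 0.0
    return float(np.exp(ld_f - ld_s) / W[cand, cand])


def _check_training_table(table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    labelled = table.labelled()
    y = labelled.labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError(f"need >= 2 classes, got {list(classes)}")
    small = classes[counts < 2]
    if len(small):
        raise ValidationError(f"classes with fewer than 2 specimens: {list(small)}")
    X = labelled.features.to_numpy(dtype=float)
    return X, y


def stepwise_select(
    table: FeatureTable, config: StepwiseConfig | None = None
) -> tuple[list[str], list[dict]]:
    """Wilks'-lambda stepwise feature selection on the labelled rows.

    Returns the ordered list of selected descriptor names and a step log
    (one entry per enter/remove action with its partial F and the Wilks'
    lambda of the model after the action).  UNKNOWN rows never participate.
    """
    config = config or StepwiseConfig()
    X, y = _check_training_table(table)
    n, n_feat = X.shape
    g = len(np.unique(y))
    W, T = _group_sscp(X, y)

    included: list[int] = []
    log: list[dict] = []
    seen_states: set[frozenset] = set()
    for step in range(1, config.max_steps + 1):
        changed = False
        p = len(included)
        lam_cur = _wilks(W, T, included)

        # --- entry phase: best admissible excluded candidate
        best_f, best_j = -np.inf, None
        if n - g - p > 0:
            for j in range(n_feat):
                if j in included:
                    continue
                if _tolerance(W, included, j) < config.tolerance:
                    continue
                lam_new = _wilks(W, T, included + [j])
                if not np.isfinite(lam_new) or lam_new <= 0:
                    continue
                f = (n - g - p) / (g - 1) * (lam_cur / lam_new - 1.0)
                if f > best_f:
                    best_f, best_j = f, j
        if best_j is not None and best_f >= config.f_to_enter:
            included.append(best_j)
            changed = True
            log.append(
                {
                    "step": step,
                    "action": "enter",
                    "feature": FEATURE_NAMES[best_j],
                    "F": float(best_f),
                    "wilks": _wilks(W, T, included),
                }
            )

        # --- removal phase: drop anything below the removal threshold
        while len(included) > 1:
            p = len(included)
            lam_cur = _wilks(W, T, included)
            worst_f, worst_j = np.inf, None
            for j in included:
                rest = [i for i in included if i != j]
                lam_rest = _wilks(W, T, rest)
                f = (n - g - p + 1) / (g - 1) * (lam_rest / lam_cur - 1.0)
                if f < worst_f:
                    worst_f, worst_j = f, j
            if worst_j is None or worst_f >= config.f_to_remove:
                break
            included.remove(worst_j)
            changed = True
            log.append(
                {
                    "step": step,
                    "action": "remove",
                    "feature": FEATURE_NAMES[worst_j],
                    "F": float(worst_f),
                    "wilks": _wilks(W, T, included),
                }
            )

        state = frozenset(included)
        if not changed or state in seen_states:
            break
        seen_states.add(state)

    if not included:
        raise EmptyModelError(
            f"no descriptor reached F-to-enter = {config.f_to_enter}; "
            "lower the threshold or inspect the data"
        )
    return [FEATURE_NAMES[j] for j in included], log


@dataclass
class DiscriminantModel:
    """A fitted linear discriminant: selected descriptors, per-class means,
    pooled within-class covariance and class priors."""

    selected_features: list[str]
    class_labels: list[str]
    class_means: np.ndarray  # (g, p)
    pooled_within_covariance: np.ndarray  # (p, p)
    priors: np.ndarray  # (g,)
    training_units: str = "px"
    _cov_inv: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.selected_features:
            raise ValidationError("model needs at least one selected feature")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValidationError("priors must sum to 1")
        try:
            np.linalg.cholesky(self.pooled_within_covariance)
        except np.linalg.LinAlgError as exc:
            raise CollinearityError(
                "pooled within-class covariance is not positive definite "
                f"on features {self.selected_features}"
            ) from exc
        self._cov_inv = np.linalg.inv(self.pooled_within_covariance)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Gaussian linear discriminant scores (up to a shared constant)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Sm = self._cov_inv @ self.class_means.T  # (p, g)
        const = -0.5 * np.einsum("gp,pg->g", self.class_means, Sm) + np.log(self.priors)
        return X @ Sm + const

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        s = self.decision_scores(X)
        return np.exp(s - logsumexp(s, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax-posterior class; ties broken lexicographically (labels
        are stored sorted, and argmax returns the first maximum)."""
        s = self.decision_scores(X)
        return np.asarray(self.class_labels)[np.argmax(s, axis=1)]

    def to_json(self, path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "class_labels": self.class_labels,
            "class_means": self.class_means.tolist(),
            "pooled_within_covariance": self.pooled_within_covariance.tolist(),
            "priors": self.priors.tolist(),
            "training_units": self.training_units,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiscriminantModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            selected_features=payload["selected_features"],
            class_labels=payload["class_labels"],
            class_means=np.asarray(payload["class_means"], dtype=float),
            pooled_within_covariance=np.asarray(
                payload["pooled_within_covariance"], dtype=float
            ),
            priors=np.asarray(payload["priors"], dtype=float),
            training_units=payload["training_units"],
        )


def _fit_arrays(
    X: np.ndarray, y: np.ndarray, priors_rule: str
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    classes = sorted(np.unique(y).tolist())
    g = len(classes)
    n, p = X.shape
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    W = np.zeros((p, p))
    for c in classes:
        G = X[y == c]
        Gc = G - G.mean(axis=0)
        W += Gc.T @ Gc
    if n - g <= 0:
        raise ValidationError("not enough specimens to estimate the covariance")
    cov = W / (n - g)
    if priors_rule == "proportional":
        priors = np.array([(y == c).sum() / n for c in classes])
    else:
        priors = np.full(g, 1.0 / g)
    return classes, means, cov, priors


def fit_lda(
    table: FeatureTable, selected: list[str], priors: str = "equal"
) -> DiscriminantModel:
    """Fit the linear discriminant on the labelled rows, restricted to the
    selected descriptors."""
    if not selected:
        raise ValidationError("selected feature list is empty")
    unknown = [f for f in selected if f not in FEATURE_NAMES]
    if unknown:
        raise ValidationError(f"unknown feature names: {unknown}")
    labelled = table.labelled()
    X = labelled.data[selected].to_numpy(dtype=float)
    y = labelled.labels.to_numpy()
    classes, means, cov, pri = _fit_arrays(X, y, priors)
    return DiscriminantModel(
        selected_features=list(selected),
        class_labels=classes,
        class_means=means,
        pooled_within_covariance=cov,
        priors=pri,
        training_units=table.units,
    )


@dataclass
class AllocationTable:
    """Row-percentage classification table (the shape of the published
    cultivar-attribution tables).

    ``counts[i, j]`` is the number of row-``i`` specimens assigned to
    predicted class ``j``.  Percentages are row-stochastic; the rounded
    view uses largest-remainder rounding so every printed row totals
    exactly 100.0.  ``overall_correct`` is the count-weighted diagonal
    percentage, defined only when row labels are true classes.
    """

    row_labels: list[str]
    column_labels: list[str]
    counts: np.ndarray
    overall_correct: float | None = None

    @property
    def n_per_row(self) -> np.ndarray:
        return self.counts.sum(axis=1).astype(int)

    @property
    def percentages(self) -> np.ndarray:
        n = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, 100.0 * self.counts / n, 0.0)

    def rounded_percentages(self, decimals: int = 1) -> np.ndarray:
        """Largest-remainder rounding: each row sums to exactly 100.0."""
        pct = self.percentages
        out = np.zeros_like(pct)
        quantum = 10**decimals
        for i, row in enumerate(pct):
            if row.sum() == 0:  # empty row (no specimens)
                continue
            scaled = row * quantum  # row in units of 10^-decimals
            floor = np.floor(scaled)
            deficit = int(round(100.0 * quantum - floor.sum()))
            order = np.argsort(-(scaled - floor), kind="stable")
            floor[order[:deficit]] += 1
            out[i] = floor / quantum
        return out

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        pct = self.rounded_percentages(decimals)
        df = pd.DataFrame(pct, index=self.row_labels, columns=self.column_labels)
        df.insert(0, "n", self.n_per_row)
        df["Total"] = pct.sum(axis=1).round(decimals)
        return df

    def to_csv(self, path, decimals: int = 1) -> None:
        df = self.to_frame(decimals)
        df.index.name = "row"
        with open(path, "w") as fh:
            df.to_csv(fh, float_format=f"%.{decimals}f")
            if self.overall_correct is not None:
                fh.write(f"overall,,{self.overall_correct:.1f}\n")


def cross_validate(
    table: FeatureTable,
    config: StepwiseConfig | None = None,
    scheme: str = "loo",
    k: int = 5,
    seed: int | None = None,
    features: list[str] | None = None,
    reselect_per_fold: bool = False,
) -> AllocationTable:
    """Cross-validated allocation table for the labelled rows.

    By default descriptors are selected once on the full labelled table
    and each held-out specimen is classified by a discriminant refit
    without it (the optimistic, source-faithful variant; pass
    ``reselect_per_fold=True`` for honest per-fold reselection, or
    ``features`` to skip selection entirely).  ``scheme`` is ``'loo'`` or
    ``'kfold'`` (stratified, shuffled with ``seed``).
    """
    config = config or StepwiseConfig()
    labelled = table.labelled()
    y_all = labelled.labels.to_numpy()
    classes, counts = np.unique(y_all, return_counts=True)
    singletons = set(classes[counts < 2])
    if singletons:
        logger.warning(
            "classes with a single specimen are skipped under cross-validation: %s",
            sorted(singletons),
        )
        keep = ~np.isin(y_all, list(singletons))
        labelled = FeatureTable(
            data=labelled.data[keep].reset_index(drop=True), units=labelled.units
        )
        y_all = labelled.labels.to_numpy()
        classes = np.unique(y_all)

    if features is None and not reselect_per_fold:
        features, _ = stepwise_select(labelled, config)

    n = len(labelled)
    if scheme == "loo":
        folds = [np.array([i]) for i in range(n)]
    elif scheme == "kfold":
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [test for _, test in skf.split(np.zeros(n), y_all)]
    else:
        raise ValidationError(f"unknown cross-validation scheme {scheme!r}")

    class_list = sorted(classes.tolist())
    c_index = {c: i for i, c in enumerate(class_list)}
    conf = np.zeros((len(class_list), len(class_list)))
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        train = FeatureTable(
            data=labelled.data[train_mask].reset_index(drop=True), units=labelled.units
        )
        fold_features = features
        if reselect_per_fold:
            fold_features, _ = stepwise_select(train, config)
        Xtr = train.data[fold_features].to_numpy(dtype=float)
        ytr = train.labels.to_numpy()
        cls, means, cov, pri = _fit_arrays(Xtr, ytr, config.priors)
        model = DiscriminantModel(
            selected_features=fold_features,
            class_labels=cls,
            class_means=means,
            pooled_within_covariance=cov,
            priors=pri,
            training_units=labelled.units,
        )
        Xte = labelled.data.iloc[test_idx][fold_features].to_numpy(dtype=float)
        pred = model.predict(Xte)
        for true, hat in zip(y_all[test_idx], pred):
            conf[c_index[true], c_index[hat]] += 1

    overall = 100.0 * np.trace(conf) / conf.sum()
    return AllocationTable(
        row_labels=class_list,
        column_labels=class_list,
        counts=conf,
        overall_correct=float(overall),
    )


def allocate_unknowns(
    model: DiscriminantModel,
    unknowns: FeatureTable,
    row_label: str = "Archaeological samples",
) -> tuple[AllocationTable, pd.DataFrame]:
    """Allocate an UNKNOWN cohort across the model's classes.

    Returns a one-row percentage table plus the per-specimen posterior
    table (one column per class, rows summing to 1).
    """
    rows = unknowns.unknowns()
    if len(rows) == 0:
        raise ValidationError("no UNKNOWN rows to allocate")
    if rows.units != model.training_units:
        raise ValidationError(
            f"unit mismatch: model trained in {model.training_units!r}, "
            f"unknowns measured in {rows.units!r}"
        )
    X = rows.data[model.selected_features].to_numpy(dtype=float)
    pred = model.predict(X)
    post = model.posteriors(X)
    counts = np.array(
        [[(pred == c).sum() for c in model.class_labels]], dtype=float
    )
    table = AllocationTable(
        row_labels=[row_label],
        column_labels=list(model.class_labels),
        counts=counts,
        overall_correct=None,
    )
    posterior_df = pd.DataFrame(post, columns=model.class_labels)
    posterior_df.insert(0, "specimen_id", rows.data["specimen_id"].to_numpy())
    posterior_df["assigned"] = pred
    return table, posterior_df


def write_report(
    tables: dict[str, AllocationTable],
    path,
    step_log: list[dict] | None = None,
) -> list:
    """Write one CSV per allocation table (plus the stepwise trace as
    JSON) under ``path``; returns the files written."""
    from pathlib import Path

    out_dir = Path(path)
    if not tables:
        logger.warning("write_report: no tables to write")
        return []
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, tab in tables.items():
            f = out_dir / f"{name}.csv"
            tab.to_csv(f)
            written.append(f)
        if step_log is not None:
            f = out_dir / "stepwise_log.json"
            with open(f, "w") as fh:
                json.dump(step_log, fh, indent=2)
            written.append(f)
    except OSError as exc:
        raise InputError(f"cannot write report under {out_dir}: {exc}") from exc
    return written
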