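"""Occupancy features and the bagged multinomial LASSO enhancer classifier.

Raw DNA-binding scores are normalised per factor in two steps. First an
SES-style cutoff separates non-specific from specific binding: the score
at which the gap between the control and observed cumulative
distributions is maximal. Then scores are squashed through a sigmoid
centred at the median of above-cutoff scores, scaled so that the cutoff
itself maps to occupancy 0.1. The region-level feature is the maximum
occupancy over a 750-bp window.

The classifier bags many small L1-regularised multinomial logistic
fits — each on at most 50 class-stratified training rows and 5 factors —
and averages, per factor and class, the weights over the base estimators
that sampled the factor. Binding energy ranks factors per class as
aggregated weight times the class-mean occupancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from arena.simulate import allocate_counts

LN9 = np.log(9.0)
CLASS_ORDER = ("inducible", "constitutive", "inactive")


class SESCutoff(NamedTuple):
    cutoff: float
    gap: float


def ses_cutoff(observed, control) -> SESCutoff:
    """Score maximising F_control(x) - F_observed(x) over pooled scores.

    Ties take the smallest score. A non-positive maximal gap (observed
    not stochastically larger than control anywhere) degenerates to the
    minimum pooled score with a warning.
    """
    obs = np.asarray(observed, dtype=float)
    ctl = np.asarray(control, dtype=float)
    obs = obs[~np.isnan(obs)]
    ctl = ctl[~np.isnan(ctl)]
    if obs.size == 0 or ctl.size == 0:
        raise ValueError("observed and control must be nonempty")
    candidates = np.unique(np.concatenate([obs, ctl]))
    if candidates.size == 1:
        warnings.warn("all scores constant; cutoff set to that constant")
        return SESCutoff(float(candidates[0]), 0.0)
    f_obs = np.searchsorted(np.sort(obs), candidates, side="right") / obs.size
    f_ctl = np.searchsorted(np.sort(ctl), candidates, side="right") / ctl.size
    gaps = f_ctl - f_obs
    best = int(np.argmax(gaps))  # argmax returns first maximum -> smallest x
    if gaps[best] <= 0:
        warnings.warn("no specific binding detected (max CDF gap <= 0)")
        return SESCutoff(float(candidates[0]), float(gaps[best]))
    return SESCutoff(float(candidates[best]), float(gaps[best]))


class SigmoidParams(NamedTuple):
    midpoint: float
    scale: float
    uninformative: bool


def sigmoid_params(scores, cutoff: float) -> SigmoidParams:
    """Midpoint (median of above-cutoff scores) and scale of the transform.

    The scale (m - cutoff)/ln 9 pins occupancy(cutoff) = 0.1 and
    occupancy(m) = 0.5. No scores above the cutoff flags the factor
    uninformative (its occupancies will all be 0); m = cutoff collapses
    to a step function via a tiny floor on the scale.
    """
    x = np.asarray(scores, dtype=float)
    above = x[~np.isnan(x) & (x > cutoff)]
    if above.size == 0:
        return SigmoidParams(float(cutoff), np.finfo(float).tiny, True)
    m = float(np.median(above))
    s = (m - cutoff) / LN9
    if s <= 0:
        s = np.finfo(float).tiny
    return SigmoidParams(m, s, False)


def occupancy_transform(scores, cutoff: float,
                        params: SigmoidParams | None = None) -> np.ndarray:
    """Map raw scores to [0, 1] occupancy; NaN (missing) maps to 0."""
    if params is None:
        params = sigmoid_params(scores, cutoff)
    x = np.asarray(scores, dtype=float)
    if params.uninformative:
        return np.zeros_like(x)
    with np.errstate(over="ignore"):
        occ = expit((x - params.midpoint) / params.scale)
    return np.where(np.isnan(x), 0.0, occ)


@dataclass
class OccupancyTable:
    """Per-factor normalised occupancy with the transform's bookkeeping."""

    occupancy: pd.DataFrame
    cutoffs: pd.Series
    midpoints: pd.Series
    missing_mask: pd.DataFrame
    uninformative: pd.Series


def build_occupancy_table(raw: pd.DataFrame, control: pd.DataFrame) -> OccupancyTable:
    """SES + sigmoid normalisation of a raw region x factor score table.

    ``control`` holds matched null scores per factor (same columns).
    Missing raw entries become occupancy 0 and are flagged in the mask —
    missingness therefore biases toward under-calling, which is the
    transparent failure mode.
    """
    occ = {}
    cutoffs, midpoints, uninf = {}, {}, {}
    for factor in raw.columns:
        ses = ses_cutoff(raw[factor], control[factor])
        params = sigmoid_params(raw[factor], ses.cutoff)
        occ[factor] = occupancy_transform(raw[factor].to_numpy(), ses.cutoff, params)
        cutoffs[factor] = ses.cutoff
        midpoints[factor] = params.midpoint
        uninf[factor] = params.uninformative
    return OccupancyTable(
        occupancy=pd.DataFrame(occ, index=raw.index),
        cutoffs=pd.Series(cutoffs, name="cutoff"),
        midpoints=pd.Series(midpoints, name="midpoint"),
        missing_mask=raw.isna(),
        uninformative=pd.Series(uninf, name="uninformative"),
    )


def region_feature(profile, resolution: int = 50) -> float:
    """Scalar feature for one region: max occupancy over its binned profile.

    ``profile`` holds per-bin occupancies covering the 750-bp window
    centred on the region midpoint (15 bins at 50-bp resolution). All-NaN
    coverage returns NaN (missing; caller sets the mask).
    """
    x = np.asarray(profile, dtype=float)
    if x.size == 0 or np.isnan(x).all():
        return float("nan")
    return float(np.nanmax(x))


@dataclass(frozen=True)
class TrainTestSplit:
    x_train: pd.DataFrame
    y_train: pd.Series
    x_test: pd.DataFrame
    y_test: pd.Series


def make_training_set(
    occupancy: pd.DataFrame,
    calls: pd.Series,
    n_noninducible: int = 500,
    train_frac: float = 0.8,
    seed: int = 0,
) -> TrainTestSplit:
    """Class-balanced dataset and stratified train/test split.

    The dataset is ``n_noninducible`` randomly chosen inactive regions
    plus all constitutive and all inducible regions. The split assigns
    floor(train_frac * n) regions per class to training and the rest to
    test. Fewer inactive regions than requested uses them all with a
    warning.
    """
    rng = np.random.default_rng(seed)
    calls = calls.reindex(occupancy.index).dropna()
    for cls in CLASS_ORDER:
        if (calls == cls).sum() == 0:
            raise ValueError(f"no regions called {cls!r}")
    inactive = calls.index[calls == "inactive"].to_numpy()
    if len(inactive) < n_noninducible:
        warnings.warn(f"only {len(inactive)} inactive regions available; using all")
        sampled_inactive = inactive
    else:
        sampled_inactive = rng.choice(inactive, size=n_noninducible, replace=False)
    keep = np.concatenate([
        calls.index[calls == "inducible"].to_numpy(),
        calls.index[calls == "constitutive"].to_numpy(),
        sampled_inactive,
    ])
    y = calls.loc[keep]
    train_idx, test_idx = [], []
    for cls in CLASS_ORDER:
        members = y.index[y == cls].to_numpy()
        members = members[rng.permutation(len(members))]
        n_train = int(np.floor(train_frac * len(members)))
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    return TrainTestSplit(
        x_train=occupancy.loc[train_idx],
        y_train=y.loc[train_idx],
        x_test=occupancy.loc[test_idx],
        y_test=y.loc[test_idx],
    )


@dataclass
class EnsembleModel:
    """Aggregated weights of a bag of small multinomial LASSO fits."""

    classes: tuple[str, ...]
    factors: tuple[str, ...]
    weights: pd.DataFrame          # class x factor, mean over sampling estimators
    intercept: pd.Series           # per class, mean over all estimators
    feature_mean: pd.Series
    feature_sd: pd.Series
    n_estimators: int
    max_samples: int
    max_features: int
    l1_penalty: float
    seed: int
    never_sampled: tuple[str, ...] = ()
    estimator_factors: list = field(default_factory=list, repr=False)
    estimator_rows: list = field(default_factory=list, repr=False)


def _stratified_rows(y: np.ndarray, classes, max_samples: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Class-stratified row subsample without replacement, >=1 per class."""
    sizes = np.array([(y == c).sum() for c in classes])
    quota = allocate_counts(max_samples, tuple(sizes / sizes.sum()))
    quota = [max(1, min(q, s)) for q, s in zip(quota, sizes)]
    picks = []
    for c, q in zip(classes, quota):
        members = np.flatnonzero(y == c)
        picks.append(rng.choice(members, size=q, replace=False))
    return np.concatenate(picks)


def fit_bagged_multinomial_lasso(
    x_train: pd.DataFrame,
    y_train: pd.Series,
    n_estimators: int = 100_000,
    max_samples: int = 50,
    max_features: int = 5,
    l1_penalty: float = 0.1,
    seed: int = 0,
    record_metadata: bool = True,
) -> EnsembleModel:
    """Bag ``n_estimators`` small L1 multinomial logistic fits.

    Each base estimator draws at most ``max_samples`` class-stratified
    rows (without replacement) and ``max_features`` factors, fits an
    L1-penalised multinomial logistic regression on standardised
    features, and contributes its weights. The aggregated weight of a
    factor for a class is the mean over the estimators that sampled that
    factor (0, and flagged, if never sampled); the intercept is the mean
    over all estimators.
    """
    classes = tuple(c for c in CLASS_ORDER if c in set(y_train))
    if len(classes) < 2:
        raise ValueError("training labels must span >= 2 classes")
    factors = tuple(x_train.columns)
    if len(factors) < 1:
        raise ValueError("no factors to train on")
    n_feat = min(max_features, len(factors))
    x = x_train.to_numpy(dtype=float)
    y = y_train.to_numpy()
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    xs = (x - mean) / sd_safe

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    weight_sum = np.zeros((len(classes), len(factors)))
    weight_n = np.zeros(len(factors), dtype=np.int64)
    intercept_sum = np.zeros(len(classes))
    n_fitted = 0
    est_factors, est_rows = [], []
    class_index = {c: i for i, c in enumerate(classes)}
    clf = LogisticRegression(solver="saga", l1_ratio=1.0, C=1.0 / l1_penalty,
                             max_iter=3000, tol=1e-6)

    for _ in range(n_estimators):
        cols = rng.choice(len(factors), size=n_feat, replace=False)
        rows = None
        for _attempt in range(5):
            cand = _stratified_rows(y, classes, max_samples, rng)
            if len(np.unique(y[cand])) == len(classes):
                rows = cand
                break
        if rows is None:  # pragma: no cover - stratification guarantees classes
            warnings.warn("skipping estimator: subsample missing a class")
            continue
        with warnings.catch_warnings():
            # near-separable 50-row subsamples can hit the iteration cap
            # a hair above tol; the aggregated weights are insensitive
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            clf.fit(xs[np.ix_(rows, cols)], y[rows])
        coef = clf.coef_
        inter = clf.intercept_
        if len(classes) == 2 and coef.shape[0] == 1:
            # sklearn collapses binary fits; expand to the symmetric form
            coef = np.vstack([-coef[0] / 2, coef[0] / 2])
            inter = np.array([-inter[0] / 2, inter[0] / 2])
        order = [list(clf.classes_).index(c) for c in classes]
        weight_sum[np.ix_(range(len(classes)), cols)] += coef[order]
        weight_n[cols] += 1
        intercept_sum += inter[order]
        n_fitted += 1
        if record_metadata:
            est_factors.append(cols.copy())
            est_rows.append(rows.copy())
    if n_fitted == 0:
        raise RuntimeError("no base estimator could be fitted")

    with np.errstate(invalid="ignore"):
        weights = np.where(weight_n > 0, weight_sum / np.maximum(weight_n, 1), 0.0)
    never = tuple(f for f, n in zip(factors, weight_n) if n == 0)
    if never:
        warnings.warn(f"{len(never)} factors never sampled by any estimator")
    return EnsembleModel(
        classes=classes,
        factors=factors,
        weights=pd.DataFrame(weights, index=list(classes), columns=list(factors)),
        intercept=pd.Series(intercept_sum / n_fitted, index=list(classes)),
        feature_mean=pd.Series(mean, index=list(factors)),
        feature_sd=pd.Series(sd_safe, index=list(factors)),
        n_estimators=n_fitted,
        max_samples=max_samples,
        max_features=n_feat,
        l1_penalty=l1_penalty,
        seed=seed,
        never_sampled=never,
        estimator_factors=est_factors,
        estimator_rows=est_rows,
    )


def predict(model: EnsembleModel, occupancy: pd.DataFrame) -> pd.DataFrame:
    """Per-class probabilities (softmax of aggregated scores) + argmax call."""
    missing = [f for f in model.factors if f not in occupancy.columns]
    if missing:
        raise ValueError(f"missing features: {missing[:5]}")
    x = occupancy[list(model.factors)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("NaN features passed to predict; impute occupancy first")
    xs = (x - model.feature_mean.to_numpy()) / model.feature_sd.to_numpy()
    scores = xs @ model.weights.to_numpy().T + model.intercept.to_numpy()
    probs = softmax(scores, axis=1)
    out = pd.DataFrame(probs, index=occupancy.index, columns=list(model.classes))
    out["predicted_class"] = out[list(model.classes)].idxmax(axis=1)
    return out


def evaluate(model: EnsembleModel, x_test: pd.DataFrame, y_test: pd.Series) -> dict:
    """Confusion-matrix metrics and per-class one-vs-rest ROC AUC."""
    pred = predict(model, x_test)
    y = y_test.reindex(x_test.index)
    metrics: dict = {"n_test": int(len(y))}
    correct = (pred["predicted_class"] == y).sum()
    metrics["accuracy"] = float(correct / len(y))
    per_class = {}
    for cls in model.classes:
        tp = int(((pred["predicted_class"] == cls) & (y == cls)).sum())
        fp = int(((pred["predicted_class"] == cls) & (y != cls)).sum())
        fn = int(((pred["predicted_class"] != cls) & (y == cls)).sum())
        precision = tp / (tp + fp) if (tp + fp) else float("nan")
        recall = tp / (tp + fn) if (tp + fn) else float("nan")
        pos = (y == cls).to_numpy()
        if pos.any() and (~pos).any():
            auc = float(roc_auc_score(pos, pred[cls].to_numpy()))
        else:
            auc = float("nan")
        per_class[cls] = {"precision": precision, "recall": recall,
                          "auc": auc, "n": int(pos.sum())}
    metrics["per_class"] = per_class
    return metrics


def binding_energy(
    model: EnsembleModel,
    occupancy: pd.DataFrame,
    calls: pd.Series,
) -> pd.DataFrame:
    """Energy(factor, class) = aggregated weight x class-mean occupancy.

    Occupancy enters on its natural [0, 1] scale. The returned table also
    carries the pairwise differential energies used to rank factors by
    class-predictive power; the differential is antisymmetric under class
    swap by construction.
    """
    calls = calls.reindex(occupancy.index)
    energies = {}
    for cls in model.classes:
        members = occupancy.loc[calls == cls, list(model.factors)]
        if len(members) == 0:
            raise ValueError(f"no regions labelled {cls!r}")
        energies[cls] = (model.weights.loc[cls].to_numpy()
                         * members.mean(axis=0).to_numpy())
    out = pd.DataFrame(energies, index=list(model.factors))
    for i, a in enumerate(model.classes):
        for b in model.classes[i + 1:]:
            out[f"diff_{a}_vs_{b}"] = out[a] - out[b]
    return out


def feature_downsample_eval(
    occupancy: pd.DataFrame,
    calls: pd.Series,
    factor_subsets: dict[str, list[str]],
    n_estimators: int = 2000,
    n_noninducible: int = 500,
    l1_penalty: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the ensemble on factor subsets; AUC inducible-vs-inactive.

    Every subset reuses the same seeded train/test split so AUCs are
    comparable; ``max_features`` caps at the subset size.
    """
    if not factor_subsets:
        raise ValueError("no factor subsets supplied")
    unknown = {f for subset in factor_subsets.values() for f in subset
               if f not in occupancy.columns}
    if unknown:
        raise ValueError(f"unknown factors in subsets: {sorted(unknown)[:5]}")
    split = make_training_set(occupancy, calls, n_noninducible=n_noninducible,
                              seed=seed)
    rows = []
    for name, subset in factor_subsets.items():
        model = fit_bagged_multinomial_lasso(
            split.x_train[list(subset)], split.y_train,
            n_estimators=n_estimators, max_features=min(5, len(subset)),
            l1_penalty=l1_penalty, seed=seed, record_metadata=False)
        pred = predict(model, split.x_test[list(subset)])
        keep = split.y_test.isin(["inducible", "inactive"])
        pos = (split.y_test[keep] == "inducible").to_numpy()
        auc = float(roc_auc_score(pos, pred.loc[keep, "inducible"].to_numpy()))
        rows.append({"subset": name, "n_factors": len(subset), "auc": auc})
    return pd.DataFrame(rows)
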