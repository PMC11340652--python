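"""Per-organ base classifiers and the stacking meta-classifier.

The discrimination pipeline trains one probabilistic classifier per
organ (fruit, leaf, endocarp) on its descriptor table, then a
meta-classifier on the *concatenated class-probability vectors* of the
three organ classifiers — never on the raw descriptors.  The training
protocol:

1. stratified split: 9/10 training, 1/10 holdout;
2. within the training part, stratified 5-fold generation of
   out-of-fold probability matrices — for each fold the three base
   classifiers train on the other 4/5 and predict the held fold, so no
   base model ever scores a row it was trained on;
3. the meta-classifier trains on the stacked out-of-fold probabilities
   (input width 3 × n_classes);
4. cross-validation on that meta training set yields the cv metrics;
   the untouched 1/10 holdout is scored separately.

Gradient-boosted trees are the default base and meta algorithm;
k-nearest neighbors, random forests and probability-calibrated support
vector machines are available alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureTable

ALGORITHMS = (
    "gradient_boosted_trees",
    "random_forest",
    "k_nearest_neighbors",
    "support_vector",
)


@dataclass
class BaseClassifierSpec:
    """Algorithm choice plus hyperparameter overrides for one classifier."""

    algorithm: str = "gradient_boosted_trees"
    hyperparameters: dict = field(default_factory=dict)
    organ: str = ""

    def build(self, seed: int) -> Pipeline:
        """Instantiate a scaler+classifier pipeline (z-scoring is fit on
        training folds only, by construction of the pipeline)."""
        hp = dict(self.hyperparameters)
        if self.algorithm == "gradient_boosted_trees":
            clf = XGBClassifier(random_state=seed, n_jobs=1, verbosity=0, **hp)
        elif self.algorithm == "random_forest":
            clf = RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
        elif self.algorithm == "k_nearest_neighbors":
            clf = KNeighborsClassifier(**hp)
        elif self.algorithm == "support_vector":
            hp.setdefault("probability", True)
            clf = SVC(random_state=seed, **hp)
        else:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; one of {ALGORITHMS}")
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])


@dataclass
class JointInstances:
    """Organ-wise aligned feature matrices for jointly sampled organs.

    Row i of each matrix belongs to the same joint instance; all three
    carry the label ``y[i]``.
    """

    fruit: np.ndarray
    leaf: np.ndarray
    endocarp: np.ndarray
    y: np.ndarray
    sample_ids: list[str]
    feature_names: dict[str, list[str]] = field(default_factory=dict)
    pairing_seed: int = 0

    def __len__(self) -> int:
        return len(self.y)

    @property
    def organs(self) -> dict[str, np.ndarray]:
        return {"fruit": self.fruit, "leaf": self.leaf, "endocarp": self.endocarp}

    def subset(self, idx: np.ndarray) -> "JointInstances":
        return JointInstances(
            fruit=self.fruit[idx],
            leaf=self.leaf[idx],
            endocarp=self.endocarp[idx],
            y=self.y[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            feature_names=self.feature_names,
            pairing_seed=self.pairing_seed,
        )


def pair_organs(
    fruit: FeatureTable, leaf: FeatureTable, endocarp: FeatureTable, seed: int = 0
) -> JointInstances:
    """Match organ samples into joint instances, cultivar by cultivar.

    Endocarps come from the sampled fruits, so fruit and endocarp rows
    with the same sample_id are paired directly; leaves are paired by a
    seeded random permutation within the cultivar.  The number of joint
    instances per cultivar is the minimum of the three organ counts.
    Cultivars missing from any table are excluded with a warning.
    """
    import warnings

    rng = np.random.default_rng(seed)
    sets = {t.organ: set(t.df["cultivar"]) for t in (fruit, leaf, endocarp)}
    common = sorted(set.intersection(*sets.values()))
    dropped = sorted(set.union(*sets.values()) - set(common))
    if dropped:
        warnings.warn(f"cultivars missing an organ table, excluded: {dropped}", stacklevel=2)
    if len(common) < 2:
        raise ValueError("need at least two cultivars present in all three tables")

    blocks = {o: [] for o in ("fruit", "leaf", "endocarp")}
    labels: list[str] = []
    ids: list[str] = []
    for cv in common:
        f = fruit.df[fruit.df["cultivar"] == cv].sort_values("sample_id")
        e = endocarp.df[endocarp.df["cultivar"] == cv].sort_values("sample_id")
        l = leaf.df[leaf.df["cultivar"] == cv].sort_values("sample_id")
        shared = sorted(set(f["sample_id"]) & set(e["sample_id"]))
        n = min(len(shared), len(l))
        shared = shared[:n]
        f = f.set_index("sample_id").loc[shared]
        e = e.set_index("sample_id").loc[shared]
        perm = rng.permutation(len(l))[:n]
        l = l.iloc[perm]
        blocks["fruit"].append(f[fruit.feature_names].to_numpy(float))
        blocks["endocarp"].append(e[endocarp.feature_names].to_numpy(float))
        blocks["leaf"].append(l[leaf.feature_names].to_numpy(float))
        labels.extend([cv] * n)
        ids.extend(shared)
    return JointInstances(
        fruit=np.vstack(blocks["fruit"]),
        leaf=np.vstack(blocks["leaf"]),
        endocarp=np.vstack(blocks["endocarp"]),
        y=np.asarray(labels),
        sample_ids=ids,
        feature_names={
            "fruit": fruit.feature_names,
            "leaf": leaf.feature_names,
            "endocarp": endocarp.feature_names,
        },
        pairing_seed=seed,
    )


def _encode(y: np.ndarray, class_order: list[str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(class_order)}
    return np.array([index[c] for c in y])


def train_base(
    table: FeatureTable,
    spec: BaseClassifierSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[Pipeline, float, float]:
    """Fit one organ classifier; report stratified CV accuracy mean ± sd.

    The returned model is refit on all rows after cross-validation.
    """
    spec = spec or BaseClassifierSpec(organ=table.organ)
    X, y = table.matrix(), table.labels()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two cultivars to train a classifier")
    if counts.min() < cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} rows < {cv_folds} folds"
        )
    y_enc = _encode(y, sorted(classes))
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(spec.build(seed), X, y_enc, cv=cv, scoring="accuracy")
    model = spec.build(seed).fit(X, y_enc)
    model.class_order_ = sorted(classes)
    return model, float(scores.mean()), float(scores.std())


def check_probability_matrix(proba: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    if np.any(proba < -atol) or np.any(proba > 1 + atol):
        raise ValueError("probabilities outside [0, 1]")
    if not np.allclose(proba.sum(axis=1), 1.0, atol=atol):
        raise ValueError("probability rows must sum to 1")
    return proba


@dataclass
class StackingModel:
    """Fitted organ classifiers plus the probability-space meta-classifier."""

    base_models: dict[str, Pipeline]
    meta_model: Pipeline
    class_order: list[str]
    #: cross-validated metrics on the meta training set (protocol step 4)
    cv_report: pd.DataFrame
    #: metrics on the untouched 1/10 holdout
    holdout_report: pd.DataFrame
    holdout_accuracy: float
    meta_cv_accuracy: float
    meta_cv_accuracy_sd: float
    #: out-of-fold bookkeeping: fold id that produced each meta training row
    oof_fold_of_row: np.ndarray

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def meta_inputs(self, joint: JointInstances) -> np.ndarray:
        """Concatenated organ probability vectors (width 3 × n_classes)."""
        cols = []
        for organ, X in joint.organs.items():
            cols.append(check_probability_matrix(self.base_models[organ].predict_proba(X)))
        return np.hstack(cols)

    def predict(self, joint: JointInstances) -> np.ndarray:
        pred = self.meta_model.predict(self.meta_inputs(joint))
        return np.asarray(self.class_order)[pred]

    def meta_feature_names(self) -> list[str]:
        return [
            f"p_{organ}_{cv}"
            for organ in ("fruit", "leaf", "endocarp")
            for cv in self.class_order
        ]


def _per_class_report(
    y_true: np.ndarray, y_pred: np.ndarray, class_order: list[str]
) -> pd.DataFrame:
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=class_order, zero_division=np.nan
    )
    df = pd.DataFrame(
        {"cultivar": class_order, "precision": prec, "recall": rec,
         "f1": f1, "support": support}
    )
    # an absent holdout class has undefined metrics: NA, not 0
    df.loc[df["support"] == 0, ["precision", "recall", "f1"]] = np.nan
    return df


def train_stacking(
    instances: JointInstances,
    base_specs: dict[str, BaseClassifierSpec] | None = None,
    meta_spec: BaseClassifierSpec | None = None,
    seed: int = 0,
    holdout_fraction: float = 0.1,
    n_folds: int = 5,
) -> tuple[StackingModel, JointInstances]:
    """Train the stacking classifier by the out-of-fold protocol.

    Returns the fitted model and the holdout instances it was never
    shown (also summarized in ``model.holdout_report``).
    """
    base_specs = base_specs or {
        o: BaseClassifierSpec(organ=o) for o in ("fruit", "leaf", "endocarp")
    }
    meta_spec = meta_spec or BaseClassifierSpec(organ="meta")
    class_order = sorted(np.unique(instances.y).tolist())
    y_enc = _encode(instances.y, class_order)

    idx_train, idx_hold = train_test_split(
        np.arange(len(instances)),
        test_size=holdout_fraction,
        stratify=y_enc,
        random_state=seed,
    )
    train, hold = instances.subset(idx_train), instances.subset(idx_hold)
    y_train = y_enc[idx_train]

    # step 2: out-of-fold probability matrices from the base classifiers
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    n_train, k = len(train), len(class_order)
    oof = {o: np.full((n_train, k), np.nan) for o in train.organs}
    fold_of_row = np.full(n_train, -1)
    for fold, (fit_idx, oof_idx) in enumerate(skf.split(np.zeros(n_train), y_train)):
        assert not np.intersect1d(fit_idx, oof_idx).size, "fold leakage"
        for organ, X in train.organs.items():
            model = base_specs[organ].build(seed + fold).fit(X[fit_idx], y_train[fit_idx])
            proba = np.zeros((len(oof_idx), k))
            proba[:, model.named_steps["clf"].classes_] = model.predict_proba(X[oof_idx])
            oof[organ][oof_idx] = proba
        fold_of_row[oof_idx] = fold
    assert (fold_of_row >= 0).all()
    meta_X = np.hstack([check_probability_matrix(oof[o]) for o in ("fruit", "leaf", "endocarp")])

    # step 4: cross-validated metric of the meta-classifier on its training set
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(meta_spec.build(seed), meta_X, y_train, cv=cv)
    cv_pred = np.empty(n_train, dtype=int)
    for fit_idx, test_idx in cv.split(meta_X, y_train):
        m = meta_spec.build(seed).fit(meta_X[fit_idx], y_train[fit_idx])
        cv_pred[test_idx] = m.predict(meta_X[test_idx])
    cv_report = _per_class_report(
        np.asarray(class_order)[y_train], np.asarray(class_order)[cv_pred], class_order
    )

    # step 3: final meta model on all out-of-fold rows; base models refit
    meta_model = meta_spec.build(seed).fit(meta_X, y_train)
    base_models = {
        o: base_specs[o].build(seed).fit(X, y_train) for o, X in train.organs.items()
    }
    model = StackingModel(
        base_models=base_models,
        meta_model=meta_model,
        class_order=class_order,
        cv_report=cv_report,
        holdout_report=pd.DataFrame(),
        holdout_accuracy=np.nan,
        meta_cv_accuracy=float(cv_scores.mean()),
        meta_cv_accuracy_sd=float(cv_scores.std()),
        oof_fold_of_row=fold_of_row,
    )
    y_hold_pred = model.predict(hold)
    model.holdout_report = _per_class_report(hold.y, y_hold_pred, class_order)
    model.holdout_accuracy = float(accuracy_score(hold.y, y_hold_pred))
    return model, hold


def evaluate(model: StackingModel, holdout: JointInstances) -> pd.DataFrame:
    """Per-class precision/recall/F1 of the stacked model on a holdout."""
    return _per_class_report(holdout.y, model.predict(holdout), model.class_order)


def repeated_evaluation(
    instances: JointInstances,
    base_specs: dict[str, BaseClassifierSpec] | None = None,
    meta_spec: BaseClassifierSpec | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean ± sd per-class holdout metrics over seeded re-splits.

    Each repeat redraws the 9/10–1/10 split (and refits everything), so
    the spread reflects split-to-split variability.
    """
    reports = []
    accs = []
    for r in range(n_repeats):
        model, hold = train_stacking(
            instances, base_specs, meta_spec, seed=seed + r
        )
        rep = evaluate(model, hold)
        rep["repeat"] = r
        reports.append(rep)
        accs.append(model.holdout_accuracy)
    allrep = pd.concat(reports, ignore_index=True)
    out = (
        allrep.groupby("cultivar", sort=True)[["precision", "recall", "f1"]]
        .agg(["mean", "std"])
    )
    out.columns = [f"{m}_{s}" for m, s in out.columns]
    out = out.reset_index()
    total = {
        "cultivar": "Total",
        **{
            f"{m}_{s}": getattr(allrep.groupby("repeat")[m].mean(), s)()
            for m in ("precision", "recall", "f1")
            for s in ("mean", "std")
        },
    }
    out = pd.concat([out, pd.DataFrame([total])], ignore_index=True)
    out.attrs["holdout_accuracy_mean"] = float(np.mean(accs))
    out.attrs["holdout_accuracy_sd"] = float(np.std(accs))
    return out


def _single_organ_accuracy(
    X: np.ndarray, y_enc: np.ndarray, spec: BaseClassifierSpec, seed: int,
    holdout_fraction: float = 0.1,
) -> float:
    idx_tr, idx_ho = train_test_split(
        np.arange(len(y_enc)), test_size=holdout_fraction, stratify=y_enc,
        random_state=seed,
    )
    model = spec.build(seed).fit(X[idx_tr], y_enc[idx_tr])
    return float(accuracy_score(y_enc[idx_ho], model.predict(X[idx_ho])))


def accuracy_vs_k(
    instances: JointInstances,
    k_range: range | list[int],
    subsets_per_k: int = 20,
    seed: int = 0,
    base_specs: dict[str, BaseClassifierSpec] | None = None,
    meta_spec: BaseClassifierSpec | None = None,
) -> pd.DataFrame:
    """Mean holdout accuracy per organ and stacked, vs number of cultivars.

    For each k, ``subsets_per_k`` seeded random cultivar subsets are
    drawn (just one when k equals the number of cultivars); per subset
    each organ classifier and the stacked model are trained and scored
    on a stratified holdout.  Long-format output: organ, k, mean, sd.
    """
    base_specs = base_specs or {
        o: BaseClassifierSpec(organ=o) for o in ("fruit", "leaf", "endocarp")
    }
    meta_spec = meta_spec or BaseClassifierSpec(organ="meta")
    cultivars = sorted(np.unique(instances.y).tolist())
    if min(k_range) < 2 or max(k_range) > len(cultivars):
        raise ValueError(f"k_range must lie within [2, {len(cultivars)}]")
    rng = np.random.default_rng(seed)
    rows = []
    for k in k_range:
        n_subsets = 1 if k == len(cultivars) else subsets_per_k
        acc: dict[str, list[float]] = {o: [] for o in ("fruit", "leaf", "endocarp", "stacked")}
        for s in range(n_subsets):
            chosen = rng.choice(cultivars, size=k, replace=False)
            idx = np.flatnonzero(np.isin(instances.y, chosen))
            sub = instances.subset(idx)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            y_enc = _encode(sub.y, sorted(chosen.tolist()))
            for organ, X in sub.organs.items():
                acc[organ].append(
                    _single_organ_accuracy(X, y_enc, base_specs[organ], sub_seed)
                )
            model, _ = train_stacking(sub, base_specs, meta_spec, seed=sub_seed)
            acc["stacked"].append(model.holdout_accuracy)
        for organ, vals in acc.items():
            rows.append(
                {"organ": organ, "k": k, "mean": float(np.mean(vals)),
                 "sd": float(np.std(vals)), "n_subsets": n_subsets}
            )
    return pd.DataFrame(rows)
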