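"""Shapley-value attribution of descriptors and organs.

The Shapley value of a descriptor is its average marginal contribution
to the model output over all orderings of the descriptors — the unique
attribution satisfying efficiency (values sum to the difference between
the model output and its background expectation), symmetry and the
null-player property.  Absent features are imputed *interventionally*:
a coalition's value is the model output averaged over background rows
substituted for the missing features.

Two estimators are provided: exact enumeration over all 2^m coalitions
(m ≤ 14) and a seeded Monte-Carlo permutation estimator with standard
errors.  Organ-level attribution runs the same machinery on the
meta-classifier's probability inputs and sums mean |value| over each
organ's probability columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from .classify import JointInstances, StackingModel
from .features import FeatureTable

MAX_EXACT_FEATURES = 14
DEFAULT_BACKGROUND_SIZE = 100


def _as_model_fn(model):
    """Accept a callable scorer or a fitted probabilistic classifier."""
    if callable(model) and not hasattr(model, "predict_proba"):
        return lambda X: np.atleast_1d(np.asarray(model(X)))
    return lambda X: model.predict_proba(X)


def _eval(model_fn, X: np.ndarray) -> np.ndarray:
    """Model output as an (n, n_outputs) array."""
    out = np.asarray(model_fn(X), dtype=float)
    if out.ndim == 1:
        out = out[:, None]
    return out


def shapley_exact(
    model, instance: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values by enumeration over all feature coalitions.

    Returns ``(values, baseline)`` with ``values`` of shape
    (n_features, n_outputs) and ``baseline`` the expected model output
    over the background.  Efficiency holds exactly:
    ``baseline + values.sum(0) == f(instance)``.
    """
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    m = x.size
    if m > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{m} features exceed the exact-enumeration limit of "
            f"{MAX_EXACT_FEATURES}; use shapley_sampled instead"
        )
    model_fn = _as_model_fn(model)
    n_masks = 1 << m
    bits = (np.arange(n_masks)[:, None] >> np.arange(m)) & 1  # (2^m, m)

    # v(S): model output with S taken from the instance, rest from the
    # background, averaged over background rows; evaluated in chunks
    v = None
    chunk = max(1, 2**18 // max(len(bg), 1))
    for lo in range(0, n_masks, chunk):
        b = bits[lo : lo + chunk]  # (c, m)
        X = np.where(b[:, None, :].astype(bool), x[None, None, :], bg[None, :, :])
        out = _eval(model_fn, X.reshape(-1, m)).reshape(len(b), len(bg), -1).mean(axis=1)
        v = out if v is None else np.vstack([v, out])

    sizes = bits.sum(axis=1)
    weights = np.array(
        [factorial(s) * factorial(m - s - 1) / factorial(m) for s in range(m)]
    )
    values = np.zeros((m, v.shape[1]))
    for j in range(m):
        without = np.flatnonzero(bits[:, j] == 0)
        with_j = without | (1 << j)
        w = weights[sizes[without]]
        values[j] = w @ (v[with_j] - v[without])
    return values, v[0]


def shapley_sampled(
    model,
    instance: np.ndarray,
    background: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo permutation estimator of the Shapley values.

    Each draw samples a feature ordering and a background row, walks the
    ordering replacing background values with the instance's, and
    credits each feature its output increment.  Returns ``(values,
    standard_errors, baseline)``; values and errors have shape
    (n_features, n_outputs).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    x = np.asarray(instance, dtype=float).ravel()
    bg = np.atleast_2d(np.asarray(background, dtype=float))
    m = x.size
    rng = np.random.default_rng(seed)
    model_fn = _as_model_fn(model)

    perms = np.array([rng.permutation(m) for _ in range(n_permutations)])
    z_idx = rng.integers(0, len(bg), size=n_permutations)
    # walk matrix: row t*(m+1)+s = background row with the first s features
    # of permutation t replaced by the instance's values
    X = np.repeat(bg[z_idx], m + 1, axis=0).reshape(n_permutations, m + 1, m)
    for s in range(1, m + 1):
        step = perms[:, s - 1]
        X[np.arange(n_permutations), s:, step] = x[step][:, None]
    out = _eval(model_fn, X.reshape(-1, m)).reshape(n_permutations, m + 1, -1)
    incr = np.diff(out, axis=1)  # (n_perm, m, n_out) in permutation order
    contrib = np.empty_like(incr)
    rows = np.arange(n_permutations)[:, None]
    contrib[rows, perms] = incr
    values = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations) if n_permutations > 1 else np.zeros_like(values)
    baseline = _eval(model_fn, bg).mean(axis=0)
    return values, se, baseline


@dataclass
class ShapleySummary:
    """Per-instance, per-class Shapley values and their global ranking."""

    feature_names: list[str]
    class_order: list[str]
    #: (n_instances, n_features, n_classes)
    values: np.ndarray
    baseline: np.ndarray
    sample_ids: list[str]

    @property
    def spread(self) -> np.ndarray:
        """Mean |Shapley value| per feature over instances and classes —
        a wider spread means the feature moves the model output more."""
        return np.abs(self.values).mean(axis=(0, 2))

    @property
    def ranking(self) -> list[str]:
        order = np.argsort(self.spread)[::-1]
        return [self.feature_names[i] for i in order]

    def to_long(self) -> pd.DataFrame:
        """Beeswarm-ready long format: instance, class, feature, value."""
        n, m, k = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.sample_ids, self.feature_names, self.class_order],
            names=["sample_id", "feature", "class"],
        )
        return (
            pd.Series(self.values.reshape(-1), index=idx, name="shapley_value")
            .reset_index()
        )


def feature_importance_report(
    model,
    table: FeatureTable,
    mode: str = "sampled",
    n_permutations: int = 500,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    max_instances: int | None = None,
    seed: int = 0,
) -> ShapleySummary:
    """Per-class Shapley values of every descriptor for every instance.

    ``model`` is a fitted organ classifier (pipeline with
    ``predict_proba``) trained on ``table``'s descriptor matrix.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError("mode must be 'exact' or 'sampled'")
    X = table.matrix()
    names = table.feature_names
    n_classes = len(model.classes_)
    class_order = getattr(model, "class_order_", None) or [str(c) for c in model.classes_]
    rng = np.random.default_rng(seed)
    bg_idx = (
        rng.choice(len(X), size=background_size, replace=False)
        if len(X) > background_size
        else np.arange(len(X))
    )
    background = X[bg_idx]
    idx = np.arange(len(X))
    if max_instances is not None and len(idx) > max_instances:
        idx = rng.choice(idx, size=max_instances, replace=False)
    values = np.empty((len(idx), len(names), n_classes))
    baseline = None
    for row, i in enumerate(idx):
        if mode == "exact":
            vals, baseline = shapley_exact(model, X[i], background)
        else:
            vals, _, baseline = shapley_sampled(
                model, X[i], background, n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        values[row] = vals
    return ShapleySummary(
        feature_names=names,
        class_order=list(class_order),
        values=values,
        baseline=baseline,
        sample_ids=[table.df["sample_id"].iloc[i] for i in idx],
    )


def organ_contribution(
    model: StackingModel,
    instances: JointInstances,
    n_permutations: int = 300,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    max_instances_per_cultivar: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fractional contribution of each organ to each cultivar's identification.

    Shapley values are computed on the meta-classifier over its
    3 × n_classes probability inputs; for each cultivar the weight of an
    organ is the summed mean |value| over that organ's probability
    columns, normalized to sum to 1 across the three organs.
    """
    Z = model.meta_inputs(instances)
    k = model.n_classes
    organ_cols = {
        organ: np.arange(i * k, (i + 1) * k)
        for i, organ in enumerate(("fruit", "leaf", "endocarp"))
    }
    rng = np.random.default_rng(seed)
    bg_idx = (
        rng.choice(len(Z), size=background_size, replace=False)
        if len(Z) > background_size
        else np.arange(len(Z))
    )
    background = Z[bg_idx]
    rows = []
    for cultivar in model.class_order:
        idx = np.flatnonzero(instances.y == cultivar)
        if max_instances_per_cultivar is not None and len(idx) > max_instances_per_cultivar:
            idx = rng.choice(idx, size=max_instances_per_cultivar, replace=False)
        col_importance = np.zeros(3 * k)
        for i in idx:
            vals, _, _ = shapley_sampled(
                model.meta_model, Z[i], background, n_permutations=n_permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            col_importance += np.abs(vals).mean(axis=1)
        col_importance /= max(len(idx), 1)
        weights = np.array([col_importance[cols].sum() for cols in organ_cols.values()])
        total = weights.sum()
        weights = weights / total if total > 0 else np.full(3, 1 / 3)
        rows.append({"cultivar": cultivar, **dict(zip(organ_cols, weights))})
    return pd.DataFrame(rows)
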