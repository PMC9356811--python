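"""Adaptive neuro-fuzzy inference system (ANFIS) for 3-class labeling.

Model
-----
A zero-order Takagi-Sugeno fuzzy system evaluated as a layered network:

1. *Fuzzification* — each (z-scored) input feature is mapped through
   Gaussian membership functions ``exp(-(x - c)^2 / (2 sigma^2))``.
2. *Rule firing* — each rule selects one membership function per feature;
   its firing strength is the product t-norm of the selected degrees.
3. *Normalization* — strengths are normalized to sum to 1.
4. *Defuzzification* — the per-class score is the strength-weighted average
   of the rules' consequent weight vectors, so scores are convex
   combinations of consequents.

Training minimizes the (optionally weighted) sum of squared errors between
scores and the one-hot target by full-batch gradient descent with momentum:
``v <- rho * v - eta * grad;  theta <- theta + v``
applied to membership centers, widths (clamped to a floor) and consequent
weights.  All gradients are analytic; a finite-difference check lives in
the test-suite.

Feature vectors are standardized (z-score) with statistics stored in the
model, so membership widths are in standardized feature units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import DataError, DegenerateInputError, ModelSchemaError, TrainingError
from .image_io import FEATURE_NAMES

__all__ = [
    "CLASS_LABELS",
    "MembershipFunction",
    "FuzzyRule",
    "AnfisModel",
    "TrainingTrace",
    "membership",
    "fuzzify",
    "rule_strengths",
    "predict_scores",
    "predict",
    "predict_batch",
    "loss",
    "dataset_loss",
    "train",
    "initialize_from_data",
    "save_model",
    "load_model",
]

#: Class order; argmax ties break toward the earlier label.
CLASS_LABELS: tuple[str, ...] = ("normal", "benign", "malignant")

#: Minimum membership width, in standardized feature units.
WIDTH_FLOOR = 1e-3

_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MembershipFunction:
    """Gaussian fuzzy set: value 1 at ``center``, scale ``width`` (> 0)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise DataError(f"membership width must be > 0, got {self.width}")


@dataclass(frozen=True)
class FuzzyRule:
    """One membership-function index per feature, plus per-class weights."""

    antecedent: tuple[int, ...]
    consequent: tuple[float, ...]


@dataclass(frozen=True)
class AnfisModel:
    """Complete parameterization of the neuro-fuzzy classifier."""

    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    mfs_per_feature: tuple[tuple[MembershipFunction, ...], ...]
    rules: tuple[FuzzyRule, ...]
    feature_means: tuple[float, ...]
    feature_stds: tuple[float, ...]
    momentum: float = 0.9
    learning_rate: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        F = len(self.feature_names)
        if len(self.mfs_per_feature) != F or len(self.feature_means) != F or len(self.feature_stds) != F:
            raise DataError("per-feature parameter lists must match feature_names length")
        if not 0 <= self.momentum < 1:
            raise DataError(f"momentum must lie in [0, 1), got {self.momentum}")
        if not self.learning_rate > 0:
            raise DataError(f"learning_rate must be > 0, got {self.learning_rate}")
        for rule in self.rules:
            if len(rule.antecedent) != F:
                raise DataError("rule antecedent length must equal the feature count")
            if len(rule.consequent) != len(self.classes):
                raise DataError("rule consequent length must equal the class count")
            for f, m in enumerate(rule.antecedent):
                if not 0 <= m < len(self.mfs_per_feature[f]):
                    raise DataError(f"antecedent index {m} invalid for feature {f}")

    # -- array views used by the vectorized evaluation/training kernels ----

    def _arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(centers[F, M], widths[F, M], antecedents[R, F], consequents[R, C])."""
        M = max(len(mfs) for mfs in self.mfs_per_feature)
        F = len(self.feature_names)
        C_ = np.zeros((F, M))
        S = np.full((F, M), 1.0)
        for f, mfs in enumerate(self.mfs_per_feature):
            for m, mf in enumerate(mfs):
                C_[f, m] = mf.center
                S[f, m] = mf.width
        A = np.array([r.antecedent for r in self.rules], dtype=np.int64)
        Y = np.array([r.consequent for r in self.rules], dtype=np.float64)
        return C_, S, A, Y

    def _with_arrays(self, C: np.ndarray, S: np.ndarray, Y: np.ndarray) -> "AnfisModel":
        mfs = tuple(
            tuple(
                MembershipFunction(float(C[f, m]), float(S[f, m]))
                for m in range(len(self.mfs_per_feature[f]))
            )
            for f in range(len(self.feature_names))
        )
        rules = tuple(
            FuzzyRule(r.antecedent, tuple(float(y) for y in Y[i]))
            for i, r in enumerate(self.rules)
        )
        return replace(self, mfs_per_feature=mfs, rules=rules)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        mu = np.asarray(self.feature_means)
        sd = np.asarray(self.feature_stds)
        return (np.asarray(X, dtype=np.float64) - mu) / sd


@dataclass(frozen=True)
class TrainingTrace:
    """Per-epoch mean training loss and the last epoch index run."""

    errors: tuple[float, ...]
    final_epoch: int


def membership(x: float, mf: MembershipFunction) -> float:
    """Gaussian membership degree ``exp(-(x - c)^2 / (2 w^2))`` in (0, 1]."""
    if not np.isfinite(x):
        raise DataError(f"membership input must be finite, got {x}")
    return float(np.exp(-((x - mf.center) ** 2) / (2.0 * mf.width**2)))


def fuzzify(features, model: AnfisModel) -> list[np.ndarray]:
    """Per-feature vectors of membership degrees for one (raw) feature vector."""
    x = np.asarray(list(features), dtype=np.float64)
    if x.shape != (len(model.feature_names),):
        raise DataError(
            f"expected {len(model.feature_names)} features, got shape {x.shape}"
        )
    z = model.standardize(x)
    return [
        np.array([membership(float(z[f]), mf) for mf in mfs])
        for f, mfs in enumerate(model.mfs_per_feature)
    ]


def rule_strengths(degrees: list[np.ndarray], model: AnfisModel) -> tuple[np.ndarray, np.ndarray]:
    """Product-t-norm firing strengths and their normalized form."""
    w = np.array(
        [np.prod([degrees[f][m] for f, m in enumerate(r.antecedent)]) for r in model.rules]
    )
    total = w.sum()
    if total <= 0:
        raise DegenerateInputError("all rule firing strengths are zero")
    return w, w / total


def predict_scores(features, model: AnfisModel) -> np.ndarray:
    """Per-class scores: normalized-strength-weighted average of consequents."""
    _, wbar = rule_strengths(fuzzify(features, model), model)
    Y = np.array([r.consequent for r in model.rules])
    return wbar @ Y


def predict(features, model: AnfisModel) -> str:
    """Class label with the highest score; ties break toward the earlier class."""
    scores = predict_scores(features, model)
    return model.classes[int(np.argmax(scores))]


def loss(scores, target, q=None) -> float:
    """(Weighted) sum of squared errors between scores and a one-hot target."""
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(target, dtype=np.float64)
    w = np.ones_like(s) if q is None else np.asarray(q, dtype=np.float64)
    return float((w * (s - t) ** 2).sum())


# ---------------------------------------------------------------------------
# Vectorized evaluation and analytic gradients
# ---------------------------------------------------------------------------


def _forward(Z, C, S, A, Y):
    """Batch forward pass on standardized inputs Z[n, F].

    Returns (scores[n, C], w[n, R], wbar[n, R]).
    """
    logU = -((Z[:, :, None] - C[None]) ** 2) / (2.0 * S[None] ** 2)  # (n, F, M)
    F = Z.shape[1]
    LW = logU[:, np.arange(F)[None, :], A].sum(axis=2)  # (n, R)
    # log-sum-exp shift: w is returned on a per-sample scale (max entry 1);
    # everything downstream uses only the scale-invariant ratios w / sum(w)
    w = np.exp(LW - LW.max(axis=1, keepdims=True))
    W = w.sum(axis=1, keepdims=True)
    wbar = w / W
    return wbar @ Y, w, wbar


def _loss_and_grads(Z, T, C, S, A, Y, q):
    """Mean per-sample SSE loss and its gradients w.r.t. C, S, Y."""
    n, F = Z.shape
    scores, w, wbar = _forward(Z, C, S, A, Y)
    resid = scores - T  # (n, C)
    total = float((q[None, :] * resid**2).sum() / n)

    D = 2.0 * q[None, :] * resid / n  # dE/dscores
    gY = wbar.T @ D  # (R, C)
    W = w.sum(axis=1, keepdims=True)
    dE_dw = (D @ Y.T - (D * scores).sum(axis=1, keepdims=True)) / W  # (n, R)

    gC = np.zeros_like(C)
    gS = np.zeros_like(S)
    Zw = dE_dw * w  # (n, R)
    for f in range(F):
        idx = A[:, f]  # (R,)
        c_f = C[f, idx][None, :]  # (1, R)
        s_f = S[f, idx][None, :]
        diff = Z[:, f, None] - c_f  # (n, R)
        # d log w_r / d c = (z - c) / s^2 ; d log w_r / d s = (z - c)^2 / s^3
        contrib_c = (Zw * diff / s_f**2).sum(axis=0)  # (R,)
        contrib_s = (Zw * diff**2 / s_f**3).sum(axis=0)
        np.add.at(gC[f], idx, contrib_c)
        np.add.at(gS[f], idx, contrib_s)
    return total, gC, gS, gY


def dataset_loss(model: AnfisModel, X, labels, q=None) -> float:
    """Mean per-sample loss of a model on a labeled dataset."""
    Z = model.standardize(np.atleast_2d(np.asarray(X, dtype=np.float64)))
    T = _one_hot(labels, model.classes)
    C, S, A, Y = model._arrays()
    qv = np.ones(len(model.classes)) if q is None else np.asarray(q, dtype=np.float64)
    scores, _, _ = _forward(Z, C, S, A, Y)
    return float((qv[None, :] * (scores - T) ** 2).sum() / Z.shape[0])


def _one_hot(labels, classes) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        rows = [index[lab] for lab in labels]
    except KeyError as exc:
        raise DataError(f"label {exc.args[0]!r} not in classes {classes}") from exc
    T = np.zeros((len(rows), len(classes)))
    T[np.arange(len(rows)), rows] = 1.0
    return T


def _split_dataset(dataset):
    X = np.array([np.asarray(list(fv), dtype=np.float64) for fv, _ in dataset])
    labels = [lab for _, lab in dataset]
    return X, labels


def train(
    model: AnfisModel,
    dataset,
    epochs: int = 200,
    learning_rate: float | None = None,
    momentum: float | None = None,
    seed: int | None = None,
    q=None,
) -> tuple[AnfisModel, TrainingTrace]:
    """Full-batch gradient descent with momentum on all model parameters.

    ``dataset`` is a sequence of ``(feature_vector, label)`` pairs.  The run
    is deterministic for a fixed model, dataset and configuration; ``seed``
    overrides the model's stored ``rng_seed`` (full-batch training itself
    draws no random numbers, but the seed is recorded in the result for
    provenance).  Widths are clamped to the floor after every step.
    """
    if len(dataset) == 0:
        raise DataError("training dataset must be non-empty")
    if epochs < 1:
        raise DataError(f"epochs must be >= 1, got {epochs}")
    eta = model.learning_rate if learning_rate is None else float(learning_rate)
    rho = model.momentum if momentum is None else float(momentum)
    if not 0 <= rho < 1:
        raise DataError(f"momentum must lie in [0, 1), got {rho}")
    if eta <= 0:
        raise DataError(f"learning_rate must be > 0, got {eta}")

    X, labels = _split_dataset(dataset)
    Z = model.standardize(X)
    T = _one_hot(labels, model.classes)
    qv = np.ones(len(model.classes)) if q is None else np.asarray(q, dtype=np.float64)

    C, S, A, Y = model._arrays()
    vC, vS, vY = np.zeros_like(C), np.zeros_like(S), np.zeros_like(Y)
    errors: list[float] = []
    for epoch in range(epochs):
        total, gC, gS, gY = _loss_and_grads(Z, T, C, S, A, Y, qv)
        if not np.isfinite(total):
            raise TrainingError(f"training diverged (non-finite loss) at epoch {epoch}")
        errors.append(total)
        vC = rho * vC - eta * gC
        vS = rho * vS - eta * gS
        vY = rho * vY - eta * gY
        C = C + vC
        S = np.maximum(S + vS, WIDTH_FLOOR)
        Y = Y + vY

    out = model._with_arrays(C, S, Y)
    out = replace(
        out,
        learning_rate=eta,
        momentum=rho,
        rng_seed=model.rng_seed if seed is None else int(seed),
    )
    return out, TrainingTrace(errors=tuple(errors), final_epoch=epochs - 1)


# ---------------------------------------------------------------------------
# Initialization and serialization
# ---------------------------------------------------------------------------

#: Grid rule bases larger than this fall back to one rule per class.
MAX_GRID_RULES = 256


def initialize_from_data(
    dataset,
    mfs_per_feature: int = 2,
    seed: int = 0,
    classes: tuple[str, ...] = CLASS_LABELS,
    feature_names: tuple[str, ...] | None = None,
) -> AnfisModel:
    """Data-driven initial model.

    Features are z-scored with dataset statistics.  When the full grid of
    membership combinations has at most :data:`MAX_GRID_RULES` rules, centers
    sit at equally spaced quantiles of each standardized feature and the rule
    base is the full grid (each rule's consequent starts as the mean one-hot
    of the training points firing it most strongly).  Otherwise one rule per
    class is created, anchored at the class medians, with one membership
    function per class on every feature and indicator consequents.
    """
    if mfs_per_feature < 1:
        raise DataError(f"mfs_per_feature must be >= 1, got {mfs_per_feature}")
    if len(dataset) == 0:
        raise DataError("cannot initialize from an empty dataset")
    X, labels = _split_dataset(dataset)
    n, F = X.shape
    if feature_names is None:
        feature_names = FEATURE_NAMES if F == len(FEATURE_NAMES) else tuple(
            f"f{i}" for i in range(F)
        )
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mu) / sd

    M = mfs_per_feature
    use_grid = M**F <= MAX_GRID_RULES
    if use_grid:
        qs = (np.arange(1, M + 1)) / (M + 1)
        centers = np.quantile(Z, qs, axis=0).T  # (F, M)
        if M > 1:
            spacing = np.diff(centers, axis=1).mean(axis=1)
        else:
            spacing = np.full(F, 1.0)
        widths = np.maximum(np.abs(spacing) / 2.0, 0.25)
        mfs = tuple(
            tuple(MembershipFunction(float(centers[f, m]), float(widths[f])) for m in range(M))
            for f in range(F)
        )
        grid = np.stack(
            np.meshgrid(*[np.arange(M)] * F, indexing="ij"), axis=-1
        ).reshape(-1, F)
        # seed consequents from the samples each rule wins
        T = _one_hot(labels, classes)
        stub = AnfisModel(
            feature_names=tuple(feature_names),
            classes=tuple(classes),
            mfs_per_feature=mfs,
            rules=tuple(FuzzyRule(tuple(int(i) for i in row), (0.0,) * len(classes)) for row in grid),
            feature_means=tuple(float(v) for v in mu),
            feature_stds=tuple(float(v) for v in sd),
            rng_seed=int(seed),
        )
        C_, S_, A_, Y_ = stub._arrays()
        _, _, wbar = _forward(Z, C_, S_, A_, Y_)
        winner = wbar.argmax(axis=1)
        Y0 = np.full((len(grid), len(classes)), 1.0 / len(classes))
        for r in range(len(grid)):
            sel = winner == r
            if sel.any():
                Y0[r] = T[sel].mean(axis=0)
        return stub._with_arrays(C_, S_, Y0)

    # one rule per class, membership functions at class medians
    med = np.zeros((F, len(classes)))
    lab_arr = np.array(labels)
    for c, cls in enumerate(classes):
        sel = lab_arr == cls
        med[:, c] = np.median(Z[sel], axis=0) if sel.any() else 0.0
    span = med.max(axis=1) - med.min(axis=1)
    widths = np.maximum(span / max(2 * (len(classes) - 1), 1), 0.25)
    mfs = tuple(
        tuple(MembershipFunction(float(med[f, c]), float(widths[f])) for c in range(len(classes)))
        for f in range(F)
    )
    rules = tuple(
        FuzzyRule(
            (c,) * F,
            tuple(1.0 if k == c else 0.0 for k in range(len(classes))),
        )
        for c in range(len(classes))
    )
    return AnfisModel(
        feature_names=tuple(feature_names),
        classes=tuple(classes),
        mfs_per_feature=mfs,
        rules=rules,
        feature_means=tuple(float(v) for v in mu),
        feature_stds=tuple(float(v) for v in sd),
        rng_seed=int(seed),
    )


def predict_batch(X, model: AnfisModel) -> list[str]:
    """Predicted labels for a 2-D array of raw feature vectors."""
    Z = model.standardize(np.atleast_2d(np.asarray(X, dtype=np.float64)))
    C, S, A, Y = model._arrays()
    scores, _, _ = _forward(Z, C, S, A, Y)
    return [model.classes[int(i)] for i in scores.argmax(axis=1)]


def save_model(model: AnfisModel, path: str | Path) -> None:
    """Serialize to the versioned JSON schema (floats round-trip exactly)."""
    doc = {
        "schema_version": _SCHEMA_VERSION,
        "feature_names": list(model.feature_names),
        "classes": list(model.classes),
        "feature_means": list(model.feature_means),
        "feature_stds": list(model.feature_stds),
        "momentum": model.momentum,
        "learning_rate": model.learning_rate,
        "rng_seed": model.rng_seed,
        "mfs_per_feature": [
            [{"center": mf.center, "width": mf.width} for mf in mfs]
            for mfs in model.mfs_per_feature
        ],
        "rules": [
            {"antecedent": list(r.antecedent), "consequent": list(r.consequent)}
            for r in model.rules
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> AnfisModel:
    """Load a model saved by :func:`save_model`; validates the schema."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"not valid JSON: {exc}") from exc
    try:
        if doc["schema_version"] != _SCHEMA_VERSION:
            raise ModelSchemaError(f"unsupported schema version {doc['schema_version']}")
        return AnfisModel(
            feature_names=tuple(doc["feature_names"]),
            classes=tuple(doc["classes"]),
            mfs_per_feature=tuple(
                tuple(MembershipFunction(mf["center"], mf["width"]) for mf in mfs)
                for mfs in doc["mfs_per_feature"]
            ),
            rules=tuple(
                FuzzyRule(tuple(r["antecedent"]), tuple(r["consequent"]))
                for r in doc["rules"]
            ),
            feature_means=tuple(doc["feature_means"]),
            feature_stds=tuple(doc["feature_stds"]),
            momentum=doc["momentum"],
            learning_rate=doc["learning_rate"],
            rng_seed=doc["rng_seed"],
        )
    except KeyError as exc:
        raise ModelSchemaError(f"missing field {exc.args[0]!r} in model file") from exc
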