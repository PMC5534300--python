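"""Per-element cascade of two MLP regressors.

The first network estimates the serum concentration from the
drinking-water concentration and anthropometrics; the second estimates
the urine concentration from the water concentration, the serum
estimate, body surface area and daily diuresis.  A magnitude-pruning
reduction step selects a smaller network on the accuracy-vs-size Pareto
front.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.neural_network import MLPRegressor

from traceret.core import SubjectRecord, TraceElement, body_surface_area

__all__ = [
    "MLPSpec",
    "TrainedCascade",
    "TrainedNetwork",
    "make_features_serum",
    "make_features_urine",
    "predict_cascade",
    "reduce_network",
    "train_cascade",
    "train_network",
]

SERUM_FEATURES = ("water_conc", "body_surface_area", "height", "weight")
URINE_FEATURES = ("water_conc", "serum_estimate", "body_surface_area", "daily_diuresis")


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training settings of one regressor.

    Training is deterministic: full-batch L-BFGS with a fixed seed.
    """

    hidden_layout: tuple[int, ...] = (8,)
    activation: str = "logistic"
    max_epochs: int = 2000
    alpha: float = 1e-4
    tol: float = 1e-8
    finetune_epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.hidden_layout) < 1:
            raise ValueError("at least one hidden layer is required")
        if any(w <= 0 for w in self.hidden_layout):
            raise ValueError(f"hidden widths must be positive, got {self.hidden_layout}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_layout"] = list(self.hidden_layout)
        return d

    @classmethod
    def from_dict(cls, payload: dict) -> "MLPSpec":
        payload = dict(payload)
        payload["hidden_layout"] = tuple(payload.get("hidden_layout", (8,)))
        return cls(**payload)


def make_features_serum(subject: SubjectRecord, element: TraceElement) -> np.ndarray:
    """Feature vector for the serum net: water concentration, body
    surface area, height, weight."""
    element = TraceElement.from_code(element)
    water = subject.water_conc.get(element)
    if water is None:
        raise ValueError(f"subject has no water concentration for {element.value}")
    return np.array(
        [water, body_surface_area(subject.height, subject.weight), subject.height, subject.weight],
        dtype=float,
    )


def make_features_urine(
    subject: SubjectRecord, element: TraceElement, serum_estimate: float
) -> np.ndarray:
    """Feature vector for the urine net: water concentration, serum
    estimate, body surface area, daily diuresis (ml)."""
    element = TraceElement.from_code(element)
    water = subject.water_conc.get(element)
    if water is None:
        raise ValueError(f"subject has no water concentration for {element.value}")
    if serum_estimate < 0:
        raise ValueError(f"serum estimate must be non-negative, got {serum_estimate}")
    if subject.daily_diuresis is None:
        raise ValueError("daily diuresis is required for the urine net")
    return np.array(
        [
            water,
            serum_estimate,
            body_surface_area(subject.height, subject.weight),
            subject.daily_diuresis,
        ],
        dtype=float,
    )


_ACTIVATIONS = {
    "identity": lambda z: z,
    "logistic": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class TrainedNetwork:
    """A trained regressor with its input scaling, so prediction is
    self-contained; weights are stored explicitly and the forward pass
    is evaluated from them."""

    spec: MLPSpec
    feature_names: tuple[str, ...]
    coefs: list[np.ndarray]
    intercepts: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    validation_rmse: float
    reduction: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.validation_rmse):
            raise ValueError("validation RMSE must be finite")

    @property
    def n_parameters(self) -> int:
        """Count of non-zero weights plus biases."""
        nz = sum(int(np.count_nonzero(c)) for c in self.coefs)
        return nz + sum(b.size for b in self.intercepts)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        act = _ACTIVATIONS[self.spec.activation]
        h = (X - self.scaler_mean) / self.scaler_scale
        for W, b in zip(self.coefs[:-1], self.intercepts[:-1]):
            h = act(h @ W + b)
        out = h @ self.coefs[-1] + self.intercepts[-1]
        return out.ravel()

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "feature_names": list(self.feature_names),
            "coefs": [c.tolist() for c in self.coefs],
            "intercepts": [b.tolist() for b in self.intercepts],
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "validation_rmse": self.validation_rmse,
            "reduction": self.reduction,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TrainedNetwork":
        return cls(
            spec=MLPSpec.from_dict(payload["spec"]),
            feature_names=tuple(payload["feature_names"]),
            coefs=[np.asarray(c, dtype=float) for c in payload["coefs"]],
            intercepts=[np.asarray(b, dtype=float) for b in payload["intercepts"]],
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
            validation_rmse=float(payload["validation_rmse"]),
            reduction=dict(payload.get("reduction", {})),
        )


def _split(n: int, seed: int, val_frac: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * val_frac)))
    return perm[n_val:], perm[:n_val]


def _rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def _fit_mlp(Xz: np.ndarray, y: np.ndarray, spec: MLPSpec, max_iter: int) -> MLPRegressor:
    model = MLPRegressor(
        hidden_layer_sizes=tuple(spec.hidden_layout),
        activation=spec.activation,
        solver="lbfgs",
        alpha=spec.alpha,
        tol=spec.tol,
        max_iter=max_iter,
        random_state=spec.seed,
    )
    model.fit(Xz, y)
    if not np.isfinite(model.loss_):
        raise RuntimeError("training diverged: non-finite loss")
    return model


def train_network(
    dataset: tuple[np.ndarray, np.ndarray],
    spec: MLPSpec = MLPSpec(),
    feature_names: Sequence[str] = SERUM_FEATURES,
) -> TrainedNetwork:
    """Train one regressor on (features, targets).

    Inputs are standardized on the training split; validation RMSE is
    measured on a held-out seeded 20% split.  Requires at least 50 rows.
    """
    X, y = dataset
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features and targets must align row-wise")
    if X.shape[0] < 50:
        raise ValueError(f"need at least 50 rows to train, got {X.shape[0]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.any(y < 0):
        raise ValueError("targets must be non-negative concentrations")

    train_idx, val_idx = _split(X.shape[0], spec.seed)
    mean = X[train_idx].mean(axis=0)
    scale = X[train_idx].std(axis=0)
    scale[scale == 0] = 1.0
    Xz = (X - mean) / scale

    model = _fit_mlp(Xz[train_idx], y[train_idx], spec, spec.max_epochs)
    net = TrainedNetwork(
        spec=spec,
        feature_names=tuple(feature_names),
        coefs=[np.array(c) for c in model.coefs_],
        intercepts=[np.array(b) for b in model.intercepts_],
        scaler_mean=mean,
        scaler_scale=scale,
        validation_rmse=0.0,
    )
    net.validation_rmse = _rmse(y[val_idx], net.predict(X[val_idx]))
    return net


_ACT_DERIVS = {
    "identity": lambda a: np.ones_like(a),
    "logistic": lambda a: a * (1.0 - a),
    "tanh": lambda a: 1.0 - a**2,
    "relu": lambda a: (a > 0).astype(float),
}


def _masked_finetune(
    coefs: list[np.ndarray],
    intercepts: list[np.ndarray],
    masks: list[np.ndarray],
    Xz: np.ndarray,
    y: np.ndarray,
    spec: MLPSpec,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """L-BFGS-B fine-tune of the surviving weights and all biases;
    pruned weights stay exactly zero (their gradient is masked)."""
    from scipy.optimize import minimize

    act = _ACTIVATIONS[spec.activation]
    dact = _ACT_DERIVS[spec.activation]
    n = Xz.shape[0]
    shapes_w = [c.shape for c in coefs]
    shapes_b = [b.shape for b in intercepts]

    def pack(cs, bs):
        return np.concatenate([c.ravel() for c in cs] + [b.ravel() for b in bs])

    def unpack(theta):
        cs, bs, off = [], [], 0
        for shp in shapes_w:
            size = int(np.prod(shp))
            cs.append(theta[off : off + size].reshape(shp))
            off += size
        for shp in shapes_b:
            size = int(np.prod(shp))
            bs.append(theta[off : off + size].reshape(shp))
            off += size
        return cs, bs

    def objective(theta):
        cs, bs = unpack(theta)
        cs = [c * m for c, m in zip(cs, masks)]
        activations = [Xz]
        h = Xz
        for W, b in zip(cs[:-1], bs[:-1]):
            h = act(h @ W + b)
            activations.append(h)
        out = (h @ cs[-1] + bs[-1]).ravel()
        resid = out - y
        loss = 0.5 * float(resid @ resid) / n
        grads_w = [np.zeros_like(c) for c in cs]
        grads_b = [np.zeros_like(b) for b in bs]
        delta = (resid / n)[:, None]
        for layer in range(len(cs) - 1, -1, -1):
            grads_w[layer] = activations[layer].T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = (delta @ cs[layer].T) * dact(activations[layer])
        # L2 penalty on surviving weights, matching the training objective.
        reg = 0.5 * spec.alpha / n
        for i, c in enumerate(cs):
            loss += reg * float(np.sum(c**2))
            grads_w[i] = (grads_w[i] + 2 * reg * c) * masks[i]
        return loss, pack(grads_w, grads_b)

    res = minimize(
        objective,
        pack(coefs, intercepts),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": spec.finetune_epochs},
    )
    cs, bs = unpack(res.x)
    return [c * m for c, m in zip(cs, masks)], bs


def _prune_and_finetune(
    net: TrainedNetwork,
    keep_fraction: float,
    X_train: np.ndarray,
    y_train: np.ndarray,
) -> TrainedNetwork:
    """Zero the smallest-magnitude weights globally, then fine-tune the
    surviving weights for a fixed small budget."""
    coefs = [np.array(c) for c in net.coefs]
    all_w = np.concatenate([np.abs(c).ravel() for c in coefs])
    n_keep = int(round(keep_fraction * all_w.size))
    if n_keep >= all_w.size:
        masks = [np.ones_like(c, dtype=bool) for c in coefs]
    else:
        if n_keep == 0:
            n_keep = 1
        threshold = np.sort(all_w)[::-1][n_keep - 1]
        masks = [np.abs(c) >= threshold for c in coefs]
        coefs = [c * m for c, m in zip(coefs, masks)]

    spec = net.spec
    intercepts = [np.array(b) for b in net.intercepts]
    if spec.finetune_epochs > 0 and n_keep < all_w.size:
        Xz = (X_train - net.scaler_mean) / net.scaler_scale
        coefs, intercepts = _masked_finetune(coefs, intercepts, masks, Xz, y_train, spec)

    return TrainedNetwork(
        spec=spec,
        feature_names=net.feature_names,
        coefs=coefs,
        intercepts=intercepts,
        scaler_mean=net.scaler_mean,
        scaler_scale=net.scaler_scale,
        validation_rmse=0.0,
        reduction={"keep_fraction": keep_fraction},
    )


def _pareto_front(points: list[tuple[float, int]]) -> list[int]:
    """Indices of the non-dominated (rmse, n_params) points."""
    idx = sorted(range(len(points)), key=lambda i: (points[i][1], points[i][0]))
    front, best_rmse = [], np.inf
    for i in idx:
        if points[i][0] < best_rmse:
            front.append(i)
            best_rmse = points[i][0]
    return front


def _knee_point(points: list[tuple[float, int]], front: list[int]) -> int:
    """Pareto knee: max perpendicular distance from the chord through
    the front's endpoints, axes min-max normalized."""
    if len(front) == 1:
        return front[0]
    pts = np.array([[points[i][1], points[i][0]] for i in front], dtype=float)
    span = pts.max(axis=0) - pts.min(axis=0)
    span[span == 0] = 1.0
    norm = (pts - pts.min(axis=0)) / span
    a, b = norm[0], norm[-1]
    chord = b - a
    chord_len = np.linalg.norm(chord)
    if chord_len == 0:
        return front[0]
    rel = norm - a
    dists = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / chord_len
    return front[int(np.argmax(dists))]


def reduce_network(
    net: TrainedNetwork,
    validation_set: tuple[np.ndarray, np.ndarray],
    tradeoff_grid: Sequence[float] = (1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
    train_set: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> TrainedNetwork:
    """Network reduction: magnitude pruning swept over kept-weight
    fractions, Pareto front over (validation RMSE, parameter count),
    knee-point selection.

    Candidates whose validation RMSE exceeds twice the unpruned net's
    are discarded before the Pareto step, so the returned model never
    violates that guard rail.
    """
    grid = list(tradeoff_grid)
    if not grid:
        raise ValueError("tradeoff grid must be non-empty")
    X_val, y_val = validation_set
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float).ravel()
    if X_val.shape[0] == 0:
        raise ValueError("validation set must be non-empty")
    if train_set is None:
        train_set = validation_set
    X_tr = np.asarray(train_set[0], dtype=float)
    y_tr = np.asarray(train_set[1], dtype=float).ravel()

    base_rmse = _rmse(y_val, net.predict(X_val))
    candidates: list[TrainedNetwork] = []
    for keep in grid:
        if keep >= 1.0:
            cand = TrainedNetwork(
                spec=net.spec,
                feature_names=net.feature_names,
                coefs=[np.array(c) for c in net.coefs],
                intercepts=[np.array(b) for b in net.intercepts],
                scaler_mean=net.scaler_mean,
                scaler_scale=net.scaler_scale,
                validation_rmse=base_rmse,
                reduction={"keep_fraction": 1.0},
            )
        else:
            cand = _prune_and_finetune(net, keep, X_tr, y_tr)
            cand.validation_rmse = _rmse(y_val, cand.predict(X_val))
        candidates.append(cand)

    if len(grid) == 1 and grid[0] >= 1.0:
        chosen = candidates[0]
        chosen.reduction.update({"pareto_front_size": 1, "unpruned_rmse": base_rmse})
        return chosen

    admissible = [c for c in candidates if c.validation_rmse <= 2.0 * base_rmse] or [candidates[0]]
    points = [(c.validation_rmse, c.n_parameters) for c in admissible]
    front = _pareto_front(points)
    chosen = admissible[_knee_point(points, front)]
    assert chosen.validation_rmse <= 2.0 * base_rmse, "reduction guard rail violated"
    chosen.reduction.update(
        {
            "pareto_front_size": len(front),
            "unpruned_rmse": base_rmse,
            "grid": grid,
        }
    )
    return chosen


@dataclass
class TrainedCascade:
    """The serum + urine regressor pair for one element."""

    element: TraceElement
    serum_net: TrainedNetwork
    urine_net: TrainedNetwork

    def __post_init__(self) -> None:
        self.element = TraceElement.from_code(self.element)
        if "serum_estimate" not in self.urine_net.feature_names:
            raise ValueError("urine net must take the serum estimate as a feature")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "element": self.element.value,
            "serum_net": self.serum_net.to_dict(),
            "urine_net": self.urine_net.to_dict(),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "TrainedCascade":
        return cls(
            element=TraceElement.from_code(payload["element"]),
            serum_net=TrainedNetwork.from_dict(payload["serum_net"]),
            urine_net=TrainedNetwork.from_dict(payload["urine_net"]),
        )

    @classmethod
    def load(cls, path) -> "TrainedCascade":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def train_cascade(
    subjects: Sequence[SubjectRecord],
    element: TraceElement,
    spec: MLPSpec = MLPSpec(),
    reduce: bool = False,
    tradeoff_grid: Sequence[float] = (1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1),
) -> TrainedCascade:
    """Train the serum and urine nets of one element from subjects with
    all three compartments measured.

    The urine net is trained with the measured serum concentration in
    the serum-estimate slot (teacher forcing); at prediction time the
    serum net's output feeds it.
    """
    element = TraceElement.from_code(element)
    rows = [
        s
        for s in subjects
        if s.serum_conc is not None
        and s.urine_conc is not None
        and element in s.serum_conc
        and element in s.urine_conc
        and element in s.water_conc
    ]
    if len(rows) < 50:
        raise ValueError(f"need at least 50 complete subjects for {element.value}, got {len(rows)}")

    X_serum = np.array([make_features_serum(s, element) for s in rows])
    y_serum = np.array([s.serum_conc[element] for s in rows])
    X_urine = np.array(
        [make_features_urine(s, element, s.serum_conc[element]) for s in rows]
    )
    y_urine = np.array([s.urine_conc[element] for s in rows])

    serum_net = train_network((X_serum, y_serum), spec, SERUM_FEATURES)
    urine_net = train_network((X_urine, y_urine), spec, URINE_FEATURES)

    if reduce:
        _, val_idx = _split(len(rows), spec.seed)
        tr_idx, _ = _split(len(rows), spec.seed)
        serum_net = reduce_network(
            serum_net,
            (X_serum[val_idx], y_serum[val_idx]),
            tradeoff_grid,
            train_set=(X_serum[tr_idx], y_serum[tr_idx]),
        )
        urine_net = reduce_network(
            urine_net,
            (X_urine[val_idx], y_urine[val_idx]),
            tradeoff_grid,
            train_set=(X_urine[tr_idx], y_urine[tr_idx]),
        )

    return TrainedCascade(element=element, serum_net=serum_net, urine_net=urine_net)


def predict_cascade(cascade: TrainedCascade, subject: SubjectRecord) -> tuple[float, float]:
    """Predict (serum, urine) concentrations (mg/l) for one subject;
    both clamped at zero from below."""
    serum = float(cascade.serum_net.predict(make_features_serum(subject, cascade.element))[0])
    serum = max(0.0, serum)
    urine = float(
        cascade.urine_net.predict(make_features_urine(subject, cascade.element, serum))[0]
    )
    return serum, max(0.0, urine)
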