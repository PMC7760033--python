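"""Bespoke PCA and OPLS-DA for binned NMR fingerprints.

OPLS-DA (orthogonal projections to latent structures, discriminant flavour)
separates the predictive variation — the part of X correlated with the class
variable y in {-1, +1} — from structured variation orthogonal to it. Each
orthogonal component is extracted from the current (centred/scaled) X as

    w   = X' y / ||X' y||          class-correlated weight
    t   = X w,  p = X' t / (t' t)  scores and loadings
    w_o = p - (w' p) w,  normalized  orthogonal weight
    t_o = X w_o,  p_o = X' t_o / (t_o' t_o)
    X  <- X - t_o p_o'             deflation

and the predictive part is a single-component PLS regression on the filtered
matrix, so that with zero orthogonal components the model IS one-component
PLS. Class prediction is the sign of the continuous score on the +/-1 coded
scale (threshold 0); the predictive direction is sign-fixed so the positive
(responder) class has positive mean training score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np

__all__ = ["PCAModel", "OPLSModel", "fit_pca", "fit_oplsda", "predict",
           "save_model", "load_model", "SCALINGS"]

SCALINGS = ("center", "uv", "pareto")

POSITIVE_CLASS = +1  # responder coding


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray          # components x variables, rows orthonormal
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    scores: np.ndarray            # training scores, subjects x components

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.loadings.T


def fit_pca(X: np.ndarray, n_components: int | None = None) -> PCAModel:
    """Mean-centred SVD principal components (exploratory overview).

    Scores are reproducible up to the usual per-component sign ambiguity;
    signs are fixed so each loading's largest-magnitude element is positive.
    """
    X = np.asarray(X, float)
    n, m = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 subjects")
    k_max = min(n - 1, m)
    k = k_max if n_components is None else int(n_components)
    if not (1 <= k <= k_max):
        raise ValueError(f"n_components must be in [1, {k_max}]")
    mean = X.mean(axis=0)
    Xc = X - mean
    if not np.any(Xc):
        raise ValueError("matrix has no variance (all rows identical)")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| element positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    var = s ** 2 / (n - 1)
    return PCAModel(mean=mean, loadings=Vt[:k], explained_variance=var[:k],
                    explained_variance_ratio=(var / var.sum())[:k],
                    scores=(U * s)[:, :k])


@dataclass
class OPLSModel:
    """Fitted OPLS-DA model; everything needed to filter and score new data."""

    mean: np.ndarray
    scale: np.ndarray
    w: np.ndarray                  # predictive weights, unit norm
    p: np.ndarray                  # predictive loadings
    q: float                       # regression scalar (y on t)
    t: np.ndarray                  # training predictive scores
    W_orth: np.ndarray             # n_orth x variables
    P_orth: np.ndarray
    T_orth: np.ndarray             # training orthogonal scores, n x n_orth
    scaling: str = "center"
    threshold: float = 0.0
    class_names: dict[int, str] = field(
        default_factory=lambda: {+1: "responder", -1: "non-responder"})
    bin_left_edges: np.ndarray | None = None
    bin_right_edges: np.ndarray | None = None

    @property
    def n_orthogonal(self) -> int:
        return self.W_orth.shape[0]


def _scale_vector(Xc: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "center":
        return np.ones(Xc.shape[1])
    sd = Xc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    if scaling == "uv":
        return sd
    if scaling == "pareto":
        return np.sqrt(sd)
    raise ValueError(f"unknown scaling {scaling!r}; expected one of {SCALINGS}")


def fit_oplsda(X: np.ndarray, y: np.ndarray, n_predictive: int = 1,
               n_orthogonal: int = 1, scaling: str = "uv",
               bin_left_edges: np.ndarray | None = None,
               bin_right_edges: np.ndarray | None = None) -> OPLSModel:
    """Fit OPLS-DA on a subjects x bins matrix with +/-1 class labels."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if n_predictive != 1:
        raise ValueError("only a single predictive component is supported")
    if n_orthogonal < 0:
        raise ValueError("n_orthogonal must be >= 0")
    classes = np.unique(y)
    if not np.array_equal(classes, [-1, 1]):
        raise ValueError("y must contain both classes coded -1/+1")
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_orthogonal >= rank:
        raise ValueError(f"n_orthogonal={n_orthogonal} >= rank(X)={rank}")

    mean = X.mean(axis=0)
    Xc = X - mean
    scale = _scale_vector(Xc, scaling)
    Xw = Xc / scale

    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xw.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise ValueError("no class-correlated variance left; reduce n_orthogonal")
        w /= nw
        t = Xw @ w
        p = Xw.T @ t / (t @ t)
        w_orth = p - (w @ p) * w
        n_wo = np.linalg.norm(w_orth)
        if n_wo < 1e-12:
            raise ValueError("orthogonal weight degenerate; reduce n_orthogonal")
        w_orth /= n_wo
        t_orth = Xw @ w_orth
        p_orth = Xw.T @ t_orth / (t_orth @ t_orth)
        Xw = Xw - np.outer(t_orth, p_orth)
        W_o.append(w_orth)
        P_o.append(p_orth)
        T_o.append(t_orth)

    # predictive component: one-component PLS on the filtered matrix
    w = Xw.T @ y
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("orthogonal filtering removed all class-correlated "
                         "variance; use fewer orthogonal components")
    w /= nw
    t = Xw @ w
    p = Xw.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    if q < 0:  # sign convention: positive class scores positive
        w, t, p, q = -w, -t, -p, -q

    return OPLSModel(
        mean=mean, scale=scale, w=w, p=p, q=q, t=t,
        W_orth=np.array(W_o).reshape(len(W_o), X.shape[1]),
        P_orth=np.array(P_o).reshape(len(P_o), X.shape[1]),
        T_orth=(np.column_stack(T_o) if T_o else np.empty((X.shape[0], 0))),
        scaling=scaling,
        bin_left_edges=None if bin_left_edges is None else np.asarray(bin_left_edges, float),
        bin_right_edges=None if bin_right_edges is None else np.asarray(bin_right_edges, float),
    )


def _filter_new(model: OPLSModel, X_new: np.ndarray) -> np.ndarray:
    Xw = (np.asarray(X_new, float) - model.mean) / model.scale
    for w_o, p_o in zip(model.W_orth, model.P_orth):
        t_o = Xw @ w_o
        Xw = Xw - np.outer(t_o, p_o)
    return Xw


def predict(model: OPLSModel, X_new: np.ndarray,
            bin_left_edges: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Continuous scores on the +/-1 coded scale and hard +/-1 labels.

    New data are centred/scaled with the training vectors and filtered with
    the stored orthogonal components before projection. When both the model
    and the caller carry bin edges they must match exactly.
    """
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.mean.size:
        raise ValueError(f"expected {model.mean.size} bins, got {X_new.shape[1]}")
    if bin_left_edges is not None and model.bin_left_edges is not None:
        if not np.allclose(bin_left_edges, model.bin_left_edges, atol=1e-9):
            diff = np.flatnonzero(~np.isclose(bin_left_edges, model.bin_left_edges, atol=1e-9))
            raise ValueError(f"bin-edge mismatch at bin indices {diff[:10].tolist()}")
    Xf = _filter_new(model, X_new)
    scores = (Xf @ model.w) * model.q
    labels = np.where(scores >= model.threshold, 1, -1)
    return scores, labels


def save_model(model: OPLSModel, path: str | Path) -> None:
    """Serialize the model to a single JSON file (round-trips to 1e-16)."""
    payload = {
        "scaling": model.scaling,
        "threshold": model.threshold,
        "q": model.q,
        "class_names": {str(k): v for k, v in model.class_names.items()},
        "mean": model.mean.tolist(),
        "scale": model.scale.tolist(),
        "w": model.w.tolist(),
        "p": model.p.tolist(),
        "t": model.t.tolist(),
        "W_orth": model.W_orth.tolist(),
        "P_orth": model.P_orth.tolist(),
        "T_orth": model.T_orth.tolist(),
        "bin_left_edges": None if model.bin_left_edges is None else model.bin_left_edges.tolist(),
        "bin_right_edges": None if model.bin_right_edges is None else model.bin_right_edges.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> OPLSModel:
    d = json.loads(Path(path).read_text())
    arr = lambda k: np.asarray(d[k], float)
    return OPLSModel(
        mean=arr("mean"), scale=arr("scale"), w=arr("w"), p=arr("p"),
        q=float(d["q"]), t=arr("t"),
        W_orth=arr("W_orth"), P_orth=arr("P_orth"), T_orth=arr("T_orth"),
        scaling=d["scaling"], threshold=float(d["threshold"]),
        class_names={int(k): v for k, v in d["class_names"].items()},
        bin_left_edges=None if d["bin_left_edges"] is None else arr("bin_left_edges"),
        bin_right_edges=None if d["bin_right_edges"] is None else arr("bin_right_edges"),
    )
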