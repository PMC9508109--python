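"""Per-landmark linear epsilon-SV regression from sparse multi-view annotations.

From M annotated frame pairs (default M = 10, sampled equidistantly over
the sequence) one scalar linear epsilon-SV regressor is trained per
landmark and output coordinate — four per landmark (u, v in each of the
two views), grouped under a single handle per landmark pair — and used to
locate all landmarks in the remaining frames of the sequence.

The model is the standard linear epsilon-SVR primal

    min 1/2 ||w||^2 + C sum_i (xi_i + xi_i*)
    s.t. |y_i - <w, x_i> - b| <= eps + slack,  slack >= 0,

solved by libsvm's SMO through scikit-learn (kernel="linear"); no kernel
is used anywhere. Features are standardized with statistics of the
training frames; targets are raw pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .cameras import Observations2D
from .features import FeatureSet

COORDS = ("u", "v")

#: library-level defaults; the end-to-end synthetic pipeline overrides these
#: via its configuration (see PipelineConfig)
DEFAULT_C = 1.0
DEFAULT_EPSILON = 0.1


def select_training_frames(L: int, M: int) -> list:
    """M frame indices sampled equidistantly over [1, L] (1-based).

    First and last frames are always included; real-valued equidistant
    positions are rounded to integers and deduplicated by falling back to
    the nearest unused frame.
    """
    if not 1 <= M <= L:
        raise ValueError(f"need 1 <= M <= L (got M={M}, L={L})")
    if M == 1:
        return [1]
    raw = np.linspace(1, L, M)
    chosen: list = []
    used = set()
    for r in raw:
        idx = int(round(r))
        if idx in used:
            for off in range(1, L):
                for cand in (idx - off, idx + off):
                    if 1 <= cand <= L and cand not in used:
                        idx = cand
                        break
                else:
                    continue
                break
        used.add(idx)
        chosen.append(idx)
    return sorted(chosen)


@dataclass
class AnnotationSet:
    """2D landmark annotations of both views at the M training frames."""

    sequence_length: int
    frames: tuple                      # 1-based frame indices, |frames| = M
    table: pd.DataFrame                # columns frame, landmark, view, u, v

    def __post_init__(self) -> None:
        self.frames = tuple(int(f) for f in self.frames)
        if len(set(self.frames)) != len(self.frames):
            raise ValueError("training frame indices must be unique")
        if any(not 1 <= f <= self.sequence_length for f in self.frames):
            raise ValueError("training frames outside [1, L]")
        need = {"frame", "landmark", "view", "u", "v"}
        if not need <= set(self.table.columns):
            raise ValueError(f"annotation table needs columns {sorted(need)}")

    @property
    def M(self) -> int:
        return len(self.frames)

    @property
    def landmarks(self) -> tuple:
        return tuple(sorted(self.table.landmark.unique()))

    @property
    def views(self) -> tuple:
        return tuple(sorted(self.table.view.unique()))

    def positions(self, landmark: str, view: str) -> np.ndarray:
        """(M, 2) pixel positions at the training frames, in frame order."""
        sel = self.table[(self.table.landmark == landmark)
                         & (self.table.view == view)]
        sel = sel.set_index("frame")
        try:
            return sel.loc[list(self.frames), ["u", "v"]].to_numpy(float)
        except KeyError as e:
            raise ValueError(
                f"missing annotation for {landmark!r}/{view!r}: {e}") from None


def annotate_from_observations(obs_d: Observations2D, obs_l: Observations2D,
                               frames) -> AnnotationSet:
    """Build an annotation table by reading observations at given frames."""
    rows = []
    for obs in (obs_d, obs_l):
        for f in frames:
            for j, name in enumerate(obs.landmark_names):
                u, v = obs.uv[f - 1, j]
                rows.append({"frame": f, "landmark": name, "view": obs.view,
                             "u": u, "v": v})
    return AnnotationSet(sequence_length=obs_d.n_frames, frames=tuple(frames),
                         table=pd.DataFrame(rows))


def train_epsilon_svr(X: np.ndarray, y: np.ndarray, C: float = DEFAULT_C,
                      epsilon: float = DEFAULT_EPSILON,
                      tol: float = 1e-8) -> tuple:
    """Solve the linear epsilon-SVR primal; returns ``(w, b)``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(X) < 2:
        raise ValueError("need at least 2 training samples")
    if C <= 0 or epsilon < 0:
        raise ValueError("require C > 0 and epsilon >= 0")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite training data")
    if np.ptp(y) == 0.0:
        # degenerate program: w = 0, b = y is feasible with zero loss
        return np.zeros(X.shape[1]), float(y[0])
    model = SVR(kernel="linear", C=C, epsilon=epsilon, tol=tol,
                max_iter=2_000_000, cache_size=64)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")   # convergence handled below
        model.fit(X, y)
    if model.n_iter_ >= 2_000_000:
        # SMO ran out of its iteration budget; the KKT polish below still
        # recovers the active-set optimum in the common near-feasible case
        resid = np.abs(y - X @ model.coef_.ravel() - model.intercept_[0])
        _warnings.warn(
            "epsilon-SVR solver hit its iteration cap before reaching the "
            f"dual tolerance (max residual {resid.max():.3g})",
            RuntimeWarning, stacklevel=2)
    w = model.coef_.ravel().astype(float)
    b = float(model.intercept_[0])
    w, b = _kkt_polish(X, y, C, epsilon, model, w, b)
    return w, b


def _kkt_polish(X, y, C, epsilon, model, w0, b0):
    """Refine the SMO solution by solving the KKT system on its active set.

    At the optimum every margin support vector sits exactly on the tube
    boundary; with the active set identified from the dual coefficients
    the remaining unknowns satisfy a small linear system. The polished
    solution is kept only when it is feasible and lowers the primal
    objective (libsvm's stopping rule otherwise leaves a ~1e-5 gap).
    """
    obj0 = svr_objective(X, y, w0, b0, C, epsilon)
    sv = model.support_
    alpha = np.zeros(len(y))
    alpha[sv] = model.dual_coef_.ravel()
    at_bound = np.abs(np.abs(alpha[sv]) - C) <= 1e-6 * C
    margin = sv[~at_bound]
    if len(margin) == 0:
        return w0, b0
    bounded = sv[at_bound]
    K = X @ X.T
    m = len(margin)
    A = np.zeros((m + 1, m + 1))
    A[:m, :m] = K[np.ix_(margin, margin)]
    A[:m, m] = 1.0
    A[m, :m] = 1.0
    s = np.sign(alpha[margin])
    rhs = np.empty(m + 1)
    rhs[:m] = y[margin] - s * epsilon
    if len(bounded):
        rhs[:m] -= K[np.ix_(margin, bounded)] @ alpha[bounded]
    rhs[m] = -alpha[bounded].sum() if len(bounded) else 0.0
    try:
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    except np.linalg.LinAlgError:
        return w0, b0
    new_alpha = alpha.copy()
    new_alpha[margin] = sol[:m]
    if np.any(np.abs(new_alpha[margin]) > C * (1 + 1e-9)):
        return w0, b0
    w = X.T @ new_alpha
    b = float(sol[m])
    if svr_objective(X, y, w, b, C, epsilon) < obj0:
        return w, b
    return w0, b0


def svr_objective(X: np.ndarray, y: np.ndarray, w: np.ndarray, b: float,
                  C: float, epsilon: float) -> float:
    """Primal objective value 1/2 ||w||^2 + C sum(slack) at (w, b)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    resid = np.abs(np.asarray(y, float) - X @ np.asarray(w, float) - b)
    slack = np.maximum(resid - epsilon, 0.0)
    return 0.5 * float(np.dot(w, w)) + C * float(slack.sum())


@dataclass
class LandmarkRegressor:
    """Trained scalar models for every landmark pair: 4 per landmark."""

    landmark_names: tuple
    views: tuple
    C: float
    epsilon: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    weights: dict = field(default_factory=dict)     # (lm, view, coord) -> w
    intercepts: dict = field(default_factory=dict)  # (lm, view, coord) -> b

    @property
    def D(self) -> int:
        return len(self.feature_mean)

    @property
    def n_models(self) -> int:
        return len(self.weights)

    def predict(self, features: FeatureSet | np.ndarray) -> dict:
        """Predict all landmarks for every frame; returns view -> Observations2D."""
        X = features.X if isinstance(features, FeatureSet) else np.asarray(features)
        if X.shape[1] != self.D:
            raise ValueError(
                f"feature dimension mismatch (got {X.shape[1]}, trained {self.D})")
        Xs = (X - self.feature_mean) / self.feature_scale
        out = {}
        for view in self.views:
            uv = np.empty((len(X), len(self.landmark_names), 2))
            for j, lm in enumerate(self.landmark_names):
                for k, coord in enumerate(COORDS):
                    w = self.weights[(lm, view, coord)]
                    b = self.intercepts[(lm, view, coord)]
                    uv[:, j, k] = Xs @ w + b
            out[view] = Observations2D(view, self.landmark_names, uv)
        return out

    def to_json(self) -> str:
        return json.dumps({
            "landmark_names": list(self.landmark_names),
            "views": list(self.views),
            "C": self.C, "epsilon": self.epsilon,
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "weights": {"|".join(k): v.tolist() for k, v in self.weights.items()},
            "intercepts": {"|".join(k): v for k, v in self.intercepts.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "LandmarkRegressor":
        d = json.loads(text)
        reg = cls(tuple(d["landmark_names"]), tuple(d["views"]),
                  d["C"], d["epsilon"],
                  np.array(d["feature_mean"]), np.array(d["feature_scale"]))
        for key, w in d["weights"].items():
            reg.weights[tuple(key.split("|"))] = np.array(w)
        for key, b in d["intercepts"].items():
            reg.intercepts[tuple(key.split("|"))] = float(b)
        return reg


def train_landmark_regressors(annotations: AnnotationSet,
                              features: FeatureSet | np.ndarray,
                              C: float = DEFAULT_C,
                              epsilon: float = DEFAULT_EPSILON) -> LandmarkRegressor:
    """Train the 4-per-landmark scalar models on the annotated frames."""
    X = features.X if isinstance(features, FeatureSet) else np.asarray(features)
    if X.shape[0] < annotations.sequence_length:
        raise ValueError("features missing for part of the sequence")
    idx = np.array(annotations.frames) - 1
    Xtr = X[idx]
    mu = Xtr.mean(axis=0)
    sd = np.maximum(Xtr.std(axis=0), 1e-9)
    reg = LandmarkRegressor(annotations.landmarks, annotations.views,
                            C, epsilon, mu, sd)
    Xs = (Xtr - mu) / sd
    for lm in annotations.landmarks:
        for view in annotations.views:
            Y = annotations.positions(lm, view)
            for k, coord in enumerate(COORDS):
                w, b = train_epsilon_svr(Xs, Y[:, k], C=C, epsilon=epsilon)
                reg.weights[(lm, view, coord)] = w
                reg.intercepts[(lm, view, coord)] = b
    return reg


def predict_landmarks(regressor: LandmarkRegressor,
                      features: FeatureSet | np.ndarray) -> dict:
    """Locate all landmarks of the entire sequence in each view."""
    return regressor.predict(features)


def evaluate_localization(predicted: Observations2D,
                          truth: Observations2D) -> pd.DataFrame:
    """Per-landmark pixel RMSE of predictions against reference positions."""
    if set(predicted.landmark_names) != set(truth.landmark_names):
        raise ValueError("landmark catalogs differ")
    idx = [predicted.landmark_names.index(n) for n in truth.landmark_names]
    common = min(predicted.n_frames, truth.n_frames)
    if common == 0:
        raise ValueError("no overlapping frames to evaluate")
    d2 = np.sum((predicted.uv[:common, idx] - truth.uv[:common]) ** 2, axis=-1)
    rows = [{"view": truth.view, "landmark": n,
             "rmse_px": float(np.sqrt(np.nanmean(d2[:, j])))}
            for j, n in enumerate(truth.landmark_names)]
    rows.append({"view": truth.view, "landmark": "__pooled__",
                 "rmse_px": float(np.sqrt(np.nanmean(d2)))})
    return pd.DataFrame(rows)
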