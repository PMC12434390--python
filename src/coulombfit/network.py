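"""Feedforward networks trained by Bayesian-regularized Levenberg-Marquardt.

The regressor minimises the regularised objective

    F(w) = beta * E_D + alpha * E_W,
    E_D  = 1/2 * sum_i e_i^2,     E_W = 1/2 * ||w||^2,

with full-batch Levenberg-Marquardt steps

    dw = -(beta J^T J + (alpha + mu) I)^{-1} (beta J^T e + alpha w),

where J is the analytic Jacobian of the residuals obtained by
backpropagation.  After every accepted step the evidence (MacKay) updates
are applied:

    gamma = N_w - alpha * tr[(beta J^T J + alpha I)^{-1}]
    alpha = gamma / (2 E_W),      beta = (n - gamma) / (2 E_D),

where ``gamma`` is the effective number of well-determined parameters.
Training stops when the mean-squared error of the *denormalised* outputs
reaches ``target_mse`` (so a target quoted in cm^-2 is meaningful when y is
supplied in cm^-1), when ``max_epochs`` is hit, or when the damping ``mu``
exceeds ``mu_max``.  One epoch is one accepted-or-rejected LM trial over
the full training set.

Inputs and outputs are affinely normalised to [-1, 1] over the training
data.  Hidden layers use an odd, saturating sigmoid (``tansig``,
algebraically tanh); the output layer is linear.  An empty
``hidden_layer_sizes`` gives a plain affine model, useful as a
least-squares oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = ["BRNNRegressor", "TrainHistory", "activation", "mse", "rmsd",
           "count_parameters"]


# -- activations -------------------------------------------------------------

def _tansig(x):
    # 2/(1+exp(-2x)) - 1, the odd saturating sigmoid; numerically tanh
    return np.tanh(x)


def _tansig_deriv_from_output(a):
    return 1.0 - a * a


def _logsig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logsig_deriv_from_output(a):
    return a * (1.0 - a)


#: activation registry: id -> (f, f' expressed through the output value)
ACTIVATIONS = {
    "tansig": (_tansig, _tansig_deriv_from_output),
    "logsig": (_logsig, _logsig_deriv_from_output),
}


def activation(x, activation_id: str = "tansig"):
    """Evaluate a registered hidden-layer activation function."""
    return ACTIVATIONS[activation_id][0](np.asarray(x, dtype=float))


def mse(pred, ref) -> float:
    """Mean squared error, in squared units of the inputs."""
    pred, ref = np.asarray(pred, float), np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError("length mismatch between prediction and reference")
    return float(np.mean((pred - ref) ** 2))


def rmsd(pred, ref) -> float:
    """Root-mean-squared deviation; ``rmsd**2 == mse`` exactly."""
    return float(np.sqrt(mse(pred, ref)))


# -- parameter bookkeeping ---------------------------------------------------

def _layer_shapes(n_inputs: int, hidden: tuple[int, ...], n_outputs: int = 1):
    sizes = [n_inputs, *hidden, n_outputs]
    return [(sizes[k], sizes[k + 1]) for k in range(len(sizes) - 1)]


def count_parameters(n_inputs: int, hidden: tuple[int, ...], n_outputs: int = 1) -> int:
    """Total weight + bias count: sum over layers of (n_in + 1) * n_out."""
    return sum((i + 1) * o for i, o in _layer_shapes(n_inputs, hidden, n_outputs))


def _unpack(w: np.ndarray, shapes):
    """Views (W, b) per layer into the flat parameter vector."""
    out, k = [], 0
    for i, o in shapes:
        W = w[k:k + i * o].reshape(i, o)
        k += i * o
        b = w[k:k + o]
        k += o
        out.append((W, b))
    return out


def _init_weights(shapes, rng: np.random.Generator) -> np.ndarray:
    """Layer-scaled uniform initialisation, deterministic for a fixed seed.

    Hidden layers follow the Nguyen-Widrow prescription: random directions
    scaled to magnitude 0.7 * width^(1/fan_in), with biases spread evenly
    so the sigmoid transitions tile the normalised [-1, 1] input range.
    """
    parts = []
    for layer, (i, o) in enumerate(shapes):
        last = layer == len(shapes) - 1
        if last:
            s = np.sqrt(3.0 / max(i, 1))
            parts.append(rng.uniform(-s, s, size=i * o))
            parts.append(rng.uniform(-0.5, 0.5, size=o))
            continue
        mag = 0.7 * o ** (1.0 / max(i, 1))
        W = rng.uniform(-1.0, 1.0, size=(i, o))
        W *= mag / np.maximum(np.linalg.norm(W, axis=0, keepdims=True), 1e-12)
        b = mag * np.linspace(-1.0, 1.0, o) * np.sign(W[0] + (W[0] == 0))
        parts.append(W.ravel())
        parts.append(b)
    return np.concatenate(parts)


def _forward(w, shapes, act, X):
    """Network output (n,) for normalised inputs X (n, d)."""
    layers = _unpack(w, shapes)
    a = X
    for W, b in layers[:-1]:
        a = act(a @ W + b)
    W, b = layers[-1]
    return (a @ W + b)[:, 0]


def _forward_jacobian(w, shapes, act, act_deriv, X):
    """Output f (n,) and Jacobian df/dw (n, N_w) by backpropagation."""
    layers = _unpack(w, shapes)
    acts = [X]
    for W, b in layers[:-1]:
        acts.append(act(acts[-1] @ W + b))
    W, b = layers[-1]
    f = (acts[-1] @ W + b)[:, 0]

    n = X.shape[0]
    # delta[l]: df/dz_l for the pre-activation of layer l (n, width_l)
    deltas = [None] * len(layers)
    deltas[-1] = np.ones((n, 1))
    for l in range(len(layers) - 2, -1, -1):
        W_next = layers[l + 1][0]
        deltas[l] = (deltas[l + 1] @ W_next.T) * act_deriv(acts[l + 1])

    cols = []
    for l, (W, b) in enumerate(layers):
        a_prev, delta = acts[l], deltas[l]
        # d f / d W[i, o] = a_prev[:, i] * delta[:, o]
        cols.append((a_prev[:, :, None] * delta[:, None, :]).reshape(n, -1))
        cols.append(delta)
    return f, np.concatenate(cols, axis=1)


# -- history -----------------------------------------------------------------

@dataclass
class TrainHistory:
    """Per-epoch training record.

    ``mse`` is the denormalised mean-squared error (physical units of y);
    ``gamma`` is the effective number of parameters, in [0, N_w].
    """

    mse: list = field(default_factory=list)
    E_D: list = field(default_factory=list)
    E_W: list = field(default_factory=list)
    alpha: list = field(default_factory=list)
    beta: list = field(default_factory=list)
    gamma: list = field(default_factory=list)
    mu: list = field(default_factory=list)
    accepted: list = field(default_factory=list)
    objective: list = field(default_factory=list)
    stop_reason: str = ""

    @property
    def n_epochs(self) -> int:
        return len(self.mse)


# -- the estimator -----------------------------------------------------------

class BRNNRegressor:
    """Bayesian-regularized Levenberg-Marquardt network, sklearn-style.

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden-layer widths, e.g. ``(15,)`` or ``(10, 10)``.  Empty tuple
        gives a plain affine model.
    activation : str
        Hidden activation id (``"tansig"`` default).
    target_mse : float
        Stopping threshold on the denormalised training MSE (squared units
        of y; cm^-2 when y is supplied in cm^-1).
    max_epochs : int
        Epoch cap; one epoch is one accepted-or-rejected LM trial.
    random_state : int or None
        Seed for the weight initialisation; fixed seed gives bit-identical
        training.
    bayes : bool
        If False, alpha stays frozen at ``alpha_init`` (plain LM when 0).
    """

    def __init__(self, hidden_layer_sizes=(15,), activation="tansig",
                 target_mse=0.04, max_epochs=5000, random_state=None,
                 mu_init=1e-3, mu_increase=10.0, mu_decrease=10.0, mu_max=1e10,
                 alpha_init=0.0, beta_init=1.0, bayes=True, bayes_warmup=25):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.target_mse = target_mse
        self.max_epochs = max_epochs
        self.random_state = random_state
        self.mu_init = mu_init
        self.mu_increase = mu_increase
        self.mu_decrease = mu_decrease
        self.mu_max = mu_max
        self.alpha_init = alpha_init
        self.beta_init = beta_init
        self.bayes = bayes
        self.bayes_warmup = bayes_warmup

    # sklearn plumbing ----------------------------------------------------
    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "hidden_layer_sizes", "activation", "target_mse", "max_epochs",
            "random_state", "mu_init", "mu_increase", "mu_decrease", "mu_max",
            "alpha_init", "beta_init", "bayes", "bayes_warmup")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # ---------------------------------------------------------------------
    def _validate_X(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D array")
        return X

    def fit(self, X, y):
        """Train on (X, y); y in physical units (typically cm^-1)."""
        X = self._validate_X(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite training data")
        if self.max_epochs < 1 or self.target_mse <= 0:
            raise ValueError("max_epochs >= 1 and target_mse > 0 required")

        hidden = tuple(int(h) for h in self.hidden_layer_sizes)
        if any(h < 1 for h in hidden):
            raise ValueError("all hidden widths must be >= 1")
        act, act_deriv = ACTIVATIONS[self.activation]
        n, d = X.shape

        # affine normalisation to [-1, 1] over the training data
        xmin, xmax = X.min(axis=0), X.max(axis=0)
        xhalf = np.where(xmax > xmin, (xmax - xmin) / 2.0, 1.0)
        xmid = (xmax + xmin) / 2.0
        ymin, ymax = y.min(), y.max()
        yhalf = (ymax - ymin) / 2.0 if ymax > ymin else 1.0
        ymid = (ymax + ymin) / 2.0
        Xn = (X - xmid) / xhalf
        yn = (y - ymid) / yhalf

        shapes = _layer_shapes(d, hidden, 1)
        n_params = count_parameters(d, hidden, 1)
        rng = np.random.default_rng(self.random_state)
        w = _init_weights(shapes, rng)
        identity = np.eye(n_params)

        alpha, beta, mu = float(self.alpha_init), float(self.beta_init), float(self.mu_init)
        gamma = float(n_params)
        hist = TrainHistory()

        f, J = _forward_jacobian(w, shapes, act, act_deriv, Xn)
        e = f - yn
        E_D = 0.5 * float(e @ e)
        E_W = 0.5 * float(w @ w)
        F = beta * E_D + alpha * E_W
        need_hyper_update = False
        n_accepted = 0
        stop = None

        for _epoch in range(self.max_epochs):
            JtJ = J.T @ J
            if need_hyper_update and self.bayes and n_accepted >= self.bayes_warmup:
                # MacKay evidence updates at the current (accepted) point
                if alpha == 0.0:
                    gamma = float(n_params)
                else:
                    evals = np.clip(np.linalg.eigvalsh(JtJ), 0.0, None)
                    tr_inv = float(np.sum(1.0 / (beta * evals + alpha)))
                    gamma = float(np.clip(n_params - alpha * tr_inv,
                                          0.0, n_params))
                alpha = min(gamma / max(2.0 * E_W, 1e-300), 1e30)
                beta = min(max(n - gamma, 1e-2) / max(2.0 * E_D, 1e-300), 1e30)
                F = beta * E_D + alpha * E_W
                need_hyper_update = False

            A = beta * JtJ + (alpha + mu) * identity
            rhs = -(beta * (J.T @ e) + alpha * w)
            solved = bool(np.all(np.isfinite(A)))
            if solved:
                try:
                    dw = scipy.linalg.cho_solve(
                        scipy.linalg.cho_factor(A, lower=True), rhs)
                    solved = bool(np.all(np.isfinite(dw)))
                except (scipy.linalg.LinAlgError, ValueError):
                    solved = False

            accepted = False
            if solved:
                w_new = w + dw
                f_new = _forward(w_new, shapes, act, Xn)
                e_new = f_new - yn
                E_D_new = 0.5 * float(e_new @ e_new)
                E_W_new = 0.5 * float(w_new @ w_new)
                F_new = beta * E_D_new + alpha * E_W_new
                if np.isfinite(F_new) and F_new < F:
                    accepted = True
                    w, e, E_D, E_W, F = w_new, e_new, E_D_new, E_W_new, F_new
                    f, J = _forward_jacobian(w, shapes, act, act_deriv, Xn)
                    mu = max(mu / self.mu_decrease, 1e-20)
                    n_accepted += 1
                    need_hyper_update = True

            if not accepted:
                mu *= self.mu_increase

            mse_phys = (2.0 * E_D / n) * yhalf ** 2
            hist.mse.append(mse_phys)
            hist.E_D.append(E_D)
            hist.E_W.append(E_W)
            hist.alpha.append(alpha)
            hist.beta.append(beta)
            hist.gamma.append(gamma)
            hist.mu.append(mu)
            hist.accepted.append(accepted)
            hist.objective.append(F)

            if mse_phys <= self.target_mse:
                stop = "target_mse"
                break
            if mu > self.mu_max:
                stop = "mu_max"
                break
        hist.stop_reason = stop or "max_epochs"

        self.n_features_in_ = d
        self.n_params_ = n_params
        self.shapes_ = shapes
        self.weights_ = w
        self.input_scaler_ = (xmid, xhalf)
        self.output_scaler_ = (float(ymid), float(yhalf))
        self.alpha_ = alpha
        self.beta_ = beta
        self.gamma_ = gamma
        self.mu_ = mu
        self.history_ = hist
        self.stop_reason_ = hist.stop_reason
        self.n_epochs_ = hist.n_epochs
        self.final_mse_ = hist.mse[-1] if hist.mse else None
        return self

    def predict(self, X) -> np.ndarray:
        """Denormalised network output in the units y was supplied in."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("this BRNNRegressor instance is not fitted yet")
        X = self._validate_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}")
        xmid, xhalf = self.input_scaler_
        ymid, yhalf = self.output_scaler_
        act = ACTIVATIONS[self.activation][0]
        fn = _forward(self.weights_, self.shapes_, act, (X - xmid) / xhalf)
        return fn * yhalf + ymid

    def score(self, X, y) -> float:
        """Coefficient of determination R^2 (sklearn convention)."""
        y = np.asarray(y, float).ravel()
        resid = y - self.predict(X)
        denom = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(resid ** 2)) / denom if denom else 0.0

    # serialisation -------------------------------------------------------
    def to_json(self) -> str:
        """Bit-exact JSON serialisation of the fitted state."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("cannot serialise an unfitted model")
        doc = {
            "format": "coulombfit-brnn-1",
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "n_features_in": self.n_features_in_,
            "weights": self.weights_.tolist(),
            "input_scaler": [list(self.input_scaler_[0]), list(self.input_scaler_[1])],
            "output_scaler": list(self.output_scaler_),
            "hyper": {"alpha": self.alpha_, "beta": self.beta_,
                      "gamma": self.gamma_, "mu": self.mu_},
            "stop_reason": self.stop_reason_,
            "n_epochs": self.n_epochs_,
            "final_mse": self.final_mse_,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, doc: str) -> "BRNNRegressor":
        data = json.loads(doc)
        if data.get("format") != "coulombfit-brnn-1":
            raise ValueError("not a coulombfit network document")
        params = dict(data["params"])
        params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
        model = cls(**params)
        d = int(data["n_features_in"])
        hidden = params["hidden_layer_sizes"]
        model.n_features_in_ = d
        model.shapes_ = _layer_shapes(d, hidden, 1)
        model.n_params_ = count_parameters(d, hidden, 1)
        model.weights_ = np.asarray(data["weights"], dtype=float)
        xm, xh = data["input_scaler"]
        model.input_scaler_ = (np.asarray(xm, float), np.asarray(xh, float))
        model.output_scaler_ = tuple(data["output_scaler"])
        hyper = data["hyper"]
        model.alpha_, model.beta_ = hyper["alpha"], hyper["beta"]
        model.gamma_, model.mu_ = hyper["gamma"], hyper["mu"]
        model.stop_reason_ = data["stop_reason"]
        model.n_epochs_ = data["n_epochs"]
        model.final_mse_ = data["final_mse"]
        model.history_ = TrainHistory(stop_reason=data["stop_reason"])
        return model
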