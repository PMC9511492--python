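"""Neural-network inverse solver for sheet orientation.

A 200-100-50 multilayer perceptron with hyperbolic-tangent activations and
a linear 11-wide output maps normalized signed two-sheet susceptibilities
to the target encoding of :mod:`vsfgorient.synth` (grouped
hyperpolarizability, folded angles, coverage ratio, interval indicators).
Because homodyne detection loses the susceptibility signs, inversion of a
measured observation enumerates all 2^16 sign assignments, predicts a
candidate solution for each, pushes it back through the forward model and
keeps the assignment whose normalized prediction has the smallest mean
squared error against the signed input.

The estimator follows the scikit-learn fit/predict protocol and is built
on :class:`sklearn.neural_network.MLPRegressor`, driven one epoch at a
time so that training and held-out validation losses are recorded per
epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .synth import (
    N_INPUTS,
    N_OUTPUTS,
    TrainingSet,
    decode_targets,
    two_sheet_susceptibilities,
)

__all__ = [
    "OrientationRegressor",
    "TwoSheetObservation",
    "OrientationSolution",
    "enumerate_signs",
    "train_solver",
    "solve",
]

#: Fixed affine scaling applied to targets during training: grouped
#: amplitudes are already unit-norm components, angles are mapped to [0, 1]
#: by their interval lengths, the coverage ratio by its upper default bound.
_TARGET_SCALE = np.array([1.0] * 6 + [1.0 / np.pi, 2.0 / np.pi, 0.2, 1.0, 1.0])


class OrientationRegressor(RegressorMixin, BaseEstimator):
    """MLP regressor from normalized susceptibilities to the 11-value targets.

    Parameters
    ----------
    hidden_layer_sizes : tuple, default (200, 100, 50)
        Widths of the three hidden layers.
    epochs : int, default 1000
        Number of passes over the training split.
    batch_size : int, default 100
        Minibatch size for the Adam updates.
    validation_fraction : float, default 0.1
        Fraction held out (the last rows of the seeded shuffle) to monitor
        generalization; its loss is recorded per epoch, never trained on.
    learning_rate_init : float, default 1e-3
        Adam step size at the first epoch.
    learning_rate_final : float, default 5e-5
        Adam step size at the last epoch; the step decays geometrically
        between the two so late epochs refine rather than overwrite.
        Set equal to ``learning_rate_init`` for a constant step.
    random_state : int or None
        Seed controlling the shuffle, weight initialization and batch order.

    Attributes
    ----------
    mlp_ : fitted :class:`MLPRegressor`
    loss_curve_ : list of per-epoch training losses (half mean squared
        error on scaled targets, scikit-learn's convention)
    validation_curve_ : list of per-epoch validation losses (same scale)
    """

    def __init__(
        self,
        hidden_layer_sizes=(200, 100, 50),
        epochs=1000,
        batch_size=100,
        validation_fraction=0.1,
        learning_rate_init=1e-3,
        learning_rate_final=5e-5,
        random_state=None,
        verbose=False,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.learning_rate_init = learning_rate_init
        self.learning_rate_final = learning_rate_final
        self.random_state = random_state
        self.verbose = verbose

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_INPUTS:
            raise ValueError(f"X must be (n, {N_INPUTS})")
        if y.shape != (X.shape[0], N_OUTPUTS):
            raise ValueError(f"y must be (n, {N_OUTPUTS})")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        rng = np.random.default_rng(
            np.random.SeedSequence([0 if self.random_state is None else int(self.random_state), 10])
        )
        n = X.shape[0]
        perm = rng.permutation(n)
        n_val = int(round(self.validation_fraction * n))
        n_val = min(max(n_val, 0), n - 1)
        train_idx, val_idx = perm[: n - n_val], perm[n - n_val:]
        ys = y * _TARGET_SCALE
        Xtr, ytr = X[train_idx], ys[train_idx]
        Xval, yval = X[val_idx], ys[val_idx]

        self.mlp_ = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation="tanh",
            solver="adam",
            batch_size=min(int(self.batch_size), len(Xtr)),
            alpha=0.0,  # pure mean-squared-error loss, no weight penalty
            learning_rate_init=self.learning_rate_init,
            shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
            tol=0.0,
            n_iter_no_change=10**9,
            max_iter=1,
        )
        self.loss_curve_ = []
        self.validation_curve_ = []
        epochs = int(self.epochs)
        decay = (
            (self.learning_rate_final / self.learning_rate_init) ** (1.0 / max(epochs - 1, 1))
            if self.learning_rate_final != self.learning_rate_init
            else 1.0
        )
        for epoch in range(epochs):
            self.mlp_.partial_fit(Xtr, ytr)
            if decay != 1.0:
                # geometric step-size schedule on top of Adam
                self.mlp_._optimizer.learning_rate_init = self.learning_rate_init * decay ** (
                    epoch + 1
                )
            loss = float(self.mlp_.loss_)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch + 1}: loss={loss!r}"
                )
            self.loss_curve_.append(loss)
            if len(Xval):
                resid = self.mlp_.predict(Xval) - yval
                self.validation_curve_.append(float(0.5 * np.mean(resid**2)))
            if self.verbose and (epoch + 1) % 50 == 0:
                vloss = self.validation_curve_[-1] if self.validation_curve_ else float("nan")
                print(f"epoch {epoch + 1}: train {loss:.3e}  val {vloss:.3e}")
        self.n_features_in_ = N_INPUTS
        return self

    def predict(self, X):
        check_is_fitted(self, "mlp_")
        X = np.asarray(X, dtype=float)
        return self.mlp_.predict(X) / _TARGET_SCALE

    def save(self, path) -> None:
        """Checkpoint: weights as npz plus a JSON architecture manifest."""
        check_is_fitted(self, "mlp_")
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        arrays = {}
        for i, (w, b) in enumerate(zip(self.mlp_.coefs_, self.mlp_.intercepts_)):
            arrays[f"w{i}"] = w
            arrays[f"b{i}"] = b
        np.savez_compressed(path, **arrays)
        manifest = {
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "activation": "tanh",
            "n_inputs": N_INPUTS,
            "n_outputs": N_OUTPUTS,
            "epochs": int(self.epochs),
            "batch_size": int(self.batch_size),
            "validation_fraction": self.validation_fraction,
            "learning_rate_init": self.learning_rate_init,
            "learning_rate_final": self.learning_rate_final,
            "random_state": self.random_state,
            "loss_curve": self.loss_curve_,
            "validation_curve": self.validation_curve_,
        }
        with open(path + ".json", "w") as fh:
            json.dump(manifest, fh)

    @classmethod
    def load(cls, path) -> "OrientationRegressor":
        path = str(path)
        if not path.endswith(".npz"):
            path += ".npz"
        with open(path + ".json") as fh:
            manifest = json.load(fh)
        est = cls(
            hidden_layer_sizes=tuple(manifest["hidden_layer_sizes"]),
            epochs=manifest["epochs"],
            batch_size=manifest["batch_size"],
            validation_fraction=manifest["validation_fraction"],
            learning_rate_init=manifest["learning_rate_init"],
            learning_rate_final=manifest.get("learning_rate_final", manifest["learning_rate_init"]),
            random_state=manifest["random_state"],
        )
        arrs = np.load(path)
        layers = [N_INPUTS, *manifest["hidden_layer_sizes"], N_OUTPUTS]
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(manifest["hidden_layer_sizes"]),
            activation="tanh",
            max_iter=1,
        )
        # minimal fitted-state reconstruction
        mlp.n_features_in_ = N_INPUTS
        mlp.n_outputs_ = N_OUTPUTS
        mlp.n_layers_ = len(layers)
        mlp.out_activation_ = "identity"
        mlp.coefs_ = [arrs[f"w{i}"] for i in range(len(layers) - 1)]
        mlp.intercepts_ = [arrs[f"b{i}"] for i in range(len(layers) - 1)]
        est.mlp_ = mlp
        est.loss_curve_ = manifest.get("loss_curve", [])
        est.validation_curve_ = manifest.get("validation_curve", [])
        est.n_features_in_ = N_INPUTS
        return est


def train_solver(training_set: TrainingSet, **params) -> OrientationRegressor:
    """Fit an :class:`OrientationRegressor` on a generated training set."""
    est = OrientationRegressor(**params)
    return est.fit(training_set.inputs, training_set.outputs)


@dataclass
class TwoSheetObservation:
    """Measured susceptibility magnitudes of a sheet pair.

    ``magnitudes`` holds 16 nonnegative values (2 sheets x 8 polarization
    combinations, sheet 1 first); ``delta_phi_deg`` is the known in-plane
    rotation offset between the sheets.
    """

    magnitudes: np.ndarray
    delta_phi_deg: float = 60.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitudes, dtype=float).reshape(-1)
        if m.size != N_INPUTS:
            raise ValueError(f"need {N_INPUTS} magnitudes, got {m.size}")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValueError("magnitudes must be finite and nonnegative")
        self.magnitudes = m


@dataclass
class OrientationSolution:
    """One candidate inversion: orientation, response, sign pattern, misfit.

    ``susceptibility_mse`` is the final (locally refined) misfit;
    ``nn_mse`` the misfit of the raw network decode that seeded it.
    """

    theta_deg: float
    phi1_deg: float
    grouped_beta: np.ndarray
    n_ratio: float
    sign_pattern: str
    susceptibility_mse: float
    nn_mse: float = float("nan")
    ind_phi: float = 0.0
    ind_theta: float = 0.0
    equivalent_patterns: list = field(default_factory=list)
    runner_ups: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "theta_deg": self.theta_deg,
            "phi1_deg": self.phi1_deg,
            "grouped_beta": np.asarray(self.grouped_beta).tolist(),
            "n_ratio": self.n_ratio,
            "sign_pattern": self.sign_pattern,
            "susceptibility_mse": self.susceptibility_mse,
            "nn_mse": self.nn_mse,
            "ind_phi": self.ind_phi,
            "ind_theta": self.ind_theta,
            "equivalent_patterns": list(self.equivalent_patterns),
        }
        if self.runner_ups:
            d["runner_ups"] = [r.to_dict() for r in self.runner_ups]
        return d

    def to_json(self, path=None):
        if path is None:
            return json.dumps(self.to_dict(), indent=2)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def enumerate_signs(magnitudes):
    """Yield all 2^16 signed versions of 16 nonnegative magnitudes.

    Pattern ``p`` assigns component ``i`` the sign ``-1`` if bit ``i`` of
    ``p`` is set, ``+1`` otherwise; patterns are yielded in increasing
    ``p``.  The sequence is lazy: nothing is materialized up front.
    """
    m = np.asarray(magnitudes, dtype=float).reshape(-1)
    if m.size != N_INPUTS:
        raise ValueError(f"need {N_INPUTS} magnitudes, got {m.size}")
    if np.any(m < 0):
        raise ValueError("magnitudes must be nonnegative")
    bits = np.arange(N_INPUTS)
    for p in range(2**N_INPUTS):
        signs = 1.0 - 2.0 * ((p >> bits) & 1)
        yield m * signs


_SIGNS_CACHE = None


def _sign_matrix() -> np.ndarray:
    """All 2^16 sign rows (+1/-1), pattern index = bit pattern."""
    global _SIGNS_CACHE
    if _SIGNS_CACHE is None:
        p = np.arange(2**N_INPUTS, dtype=np.uint32)[:, None]
        bits = (p >> np.arange(N_INPUTS, dtype=np.uint32)[None, :]) & 1
        _SIGNS_CACHE = (1.0 - 2.0 * bits).astype(np.float64)
    return _SIGNS_CACHE


def _pattern_string(signs_row) -> str:
    return "".join("+" if s > 0 else "-" for s in signs_row)


def _refine(x_signed, g0, phi0, theta0, n0, delta_phi_deg):
    """Local least-squares polish of a decoded candidate.

    Minimizes the misfit between the normalized forward prediction and the
    signed, normalized input over (phi, theta, grouped beta, N), starting
    from the network's decode.  Deterministic; cheap (16 residuals, 9
    parameters).
    """
    from scipy.optimize import least_squares

    def pack(phi, theta, g, n):
        return np.concatenate([[phi, theta, np.log(n)], g])

    def residual(p):
        phi, theta, logn = p[0], p[1], p[2]
        g = p[3:]
        pred = two_sheet_susceptibilities(
            g, phi, theta, np.exp(logn), delta_phi_deg=delta_phi_deg
        )
        return pred - x_signed

    lo = [-np.pi, 1e-4, np.log(1e-4)] + [-10.0] * 6
    hi = [2 * np.pi, np.pi / 2 - 1e-4, np.log(1e4)] + [10.0] * 6
    x0 = np.clip(pack(phi0, theta0, g0, n0), lo, hi)
    res = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    phi, theta, n = res.x[0] % np.pi, res.x[1], float(np.exp(res.x[2]))
    g = res.x[3:]
    gn = np.linalg.norm(g)
    if gn > 0:
        g = g / gn
    mse = float(np.mean(residual(res.x) ** 2))
    return phi, theta, g, n, mse


def solve(
    obs: TwoSheetObservation,
    model: OrientationRegressor,
    top_k: int = 5,
    refine: bool = True,
) -> OrientationSolution:
    """Invert a magnitude-only observation by exhaustive sign enumeration.

    For every sign assignment the signed vector is normalized, the network
    predicts a candidate (grouped beta, angles, coverage ratio), the
    candidate is pushed through the two-sheet forward model, and the mean
    squared error between the normalized prediction and the signed input
    is recorded.  With ``refine`` (default), the best candidates are then
    polished by local least squares against their signed inputs and
    re-ranked by the refined misfit — the network proposes, Gauss-Newton
    disposes.  Ties go to the lowest pattern index and are reported.
    Flipping all 16 signs leaves the misfit unchanged by construction
    (homodyne symmetry), so each reported pattern lists its global flip as
    equivalent.
    """
    check_is_fitted(model, "mlp_")
    m = obs.magnitudes
    if np.all(m == 0):
        raise ValueError(
            "all-zero observation: orientation unidentifiable (zero-tilt family)"
        )
    S = _sign_matrix()
    j0 = int(np.argmax(m > 0))  # first nonzero magnitude fixes the global sign
    canonical = S[:, j0] > 0
    idx = np.nonzero(canonical)[0]
    Sc = S[idx]
    X = Sc * m
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    Y = model.predict(X)
    g, phi, theta, n_ratio, ind_p, ind_t = decode_targets(Y)
    gnorm = np.linalg.norm(g, axis=1, keepdims=True)
    ok = gnorm[:, 0] > 0
    g = np.divide(g, gnorm, out=np.zeros_like(g), where=gnorm > 0)
    phi = np.clip(phi, 0.0, np.pi)
    theta = np.clip(theta, 0.0, np.pi / 2)
    n_ratio = np.clip(n_ratio, 1e-9, None)
    pred = two_sheet_susceptibilities(
        g, phi, theta, n_ratio, delta_phi_deg=obs.delta_phi_deg
    )
    nn_mse = np.mean((pred - X) ** 2, axis=1)
    nn_mse[~ok] = np.inf

    order = np.argsort(nn_mse, kind="stable")
    # Refine the network's best-scored candidates, escalating in batches:
    # if none of them fits essentially exactly, the true sign pattern may
    # sit deeper in the ranking, so widen the search up to max_refine.
    max_refine = min(64 if refine else max(top_k, 8), len(order))
    batch = max(top_k, 8)
    candidates = []
    k = 0
    while k < max_refine:
        stop = min(k + batch, max_refine)
        for kk in range(k, stop):
            i = order[kk]
            entry = {
                "i": int(i),
                "nn_mse": float(nn_mse[i]),
                "phi": float(phi[i]),
                "theta": float(theta[i]),
                "g": g[i].copy(),
                "n": float(n_ratio[i]),
                "mse": float(nn_mse[i]),
            }
            if refine and np.isfinite(nn_mse[i]):
                rphi, rtheta, rg, rn, rmse = _refine(
                    X[i], g[i], phi[i], theta[i], n_ratio[i], obs.delta_phi_deg
                )
                entry.update(phi=rphi, theta=rtheta, g=rg, n=rn, mse=rmse)
            candidates.append(entry)
        k = stop
        if not refine or min(e["mse"] for e in candidates) < 1e-10:
            break
    candidates.sort(key=lambda e: (e["mse"], idx[e["i"]]))

    def build(entry, with_ties=False):
        i = entry["i"]
        ties = []
        if with_ties:
            ties = [
                _pattern_string(Sc[e["i"]])
                for e in candidates
                if e["mse"] == entry["mse"] and e["i"] != i
            ]
        return OrientationSolution(
            theta_deg=float(np.rad2deg(entry["theta"])),
            phi1_deg=float(np.rad2deg(entry["phi"])),
            grouped_beta=np.asarray(entry["g"]),
            n_ratio=entry["n"],
            sign_pattern=_pattern_string(Sc[i]),
            susceptibility_mse=entry["mse"],
            nn_mse=entry["nn_mse"],
            ind_phi=float(ind_p[i]),
            ind_theta=float(ind_t[i]),
            equivalent_patterns=[_pattern_string(-Sc[i])] + ties,
        )

    best = build(candidates[0], with_ties=True)
    best.runner_ups = [build(e) for e in candidates[1:top_k]]
    return best
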