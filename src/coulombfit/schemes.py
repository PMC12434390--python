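"""Scheme A and Scheme B surface fitting.

Scheme A trains a network directly on the potential energy V(R).  Scheme B
trains on the smooth electronic energy E_el = V - V_nu and adds the exact
Coulomb repulsion V_nu back at prediction time, so the network never has to
represent the 1/R singularity.  By construction a scheme-B surface obeys
the decomposition identity V_pred - E_el_pred = V_nu(exact) at every
geometry.

:class:`PESRegressor` is the sklearn-style estimator; :func:`fit_scheme_a`
/ :func:`fit_scheme_b` are table-level drivers returning a
:class:`FittedPES`, and :func:`compare_networks` reproduces the
network-comparison report layout (network notation, train/test RMSD,
epochs, stop reason).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import hartree_to_cm
from .dataset import EnergyTable, SplitSpec, split_train_test, subtract_nuclear
from .geometry import CoordinateSpec
from .network import BRNNRegressor, rmsd

__all__ = ["TrainConfig", "PESRegressor", "FittedPES", "FitStats",
           "fit_scheme_a", "fit_scheme_b", "fit_best_of",
           "predict_potential", "predict_electronic",
           "compare_networks", "parse_network"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters shared by both schemes.

    ``target_mse`` is in cm^-2 on denormalised outputs; ``seed`` fixes the
    weight initialisation.
    """

    target_mse: float = 0.04
    max_epochs: int = 5000
    seed: int | None = None
    mu_init: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 10.0
    mu_max: float = 1e10

    def estimator_kwargs(self) -> dict:
        return dict(target_mse=self.target_mse, max_epochs=self.max_epochs,
                    random_state=self.seed, mu_init=self.mu_init,
                    mu_increase=self.mu_increase, mu_decrease=self.mu_decrease,
                    mu_max=self.mu_max)


class PESRegressor:
    """Potential-energy-surface regressor with pluggable Coulomb handling.

    fit(X, y) takes coordinates in the spec's internal units (bohr /
    degrees) and potential energies y in cm^-1.  With ``scheme="B"`` the
    exact nuclear repulsion (from ``coordinate_spec``) is subtracted before
    training and re-added in :meth:`predict`; with ``scheme="A"`` the
    network fits V directly.
    """

    def __init__(self, coordinate_spec: CoordinateSpec = None, scheme: str = "B",
                 hidden_layer_sizes=(15,), target_mse=0.04, max_epochs=5000,
                 random_state=None, mu_init=1e-3, mu_increase=10.0,
                 mu_decrease=10.0, mu_max=1e10, activation="tansig"):
        self.coordinate_spec = coordinate_spec
        self.scheme = scheme
        self.hidden_layer_sizes = hidden_layer_sizes
        self.target_mse = target_mse
        self.max_epochs = max_epochs
        self.random_state = random_state
        self.mu_init = mu_init
        self.mu_increase = mu_increase
        self.mu_decrease = mu_decrease
        self.mu_max = mu_max
        self.activation = activation

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in (
            "coordinate_spec", "scheme", "hidden_layer_sizes", "target_mse",
            "max_epochs", "random_state", "mu_init", "mu_increase",
            "mu_decrease", "mu_max", "activation")}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _vnu_cm(self, X) -> np.ndarray:
        return hartree_to_cm(self.coordinate_spec.vnu(X))

    def fit(self, X, y, electronic: np.ndarray | None = None):
        """Fit to potential energies ``y`` (cm^-1).

        For scheme B, ``electronic`` may supply E_el (cm^-1) directly
        (e.g. to include a united-atom record for which V is undefined);
        otherwise E_el is derived as ``y - V_nu``.
        """
        if self.scheme not in ("A", "B"):
            raise ValueError(f"scheme must be 'A' or 'B', got {self.scheme!r}")
        if self.coordinate_spec is None:
            raise ValueError("coordinate_spec is required")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, self.coordinate_spec.n_dims)
        if self.scheme == "B":
            target = (np.asarray(electronic, float) if electronic is not None
                      else np.asarray(y, float) - self._vnu_cm(X))
        else:
            target = np.asarray(y, float)
        net = BRNNRegressor(hidden_layer_sizes=self.hidden_layer_sizes,
                            activation=self.activation,
                            target_mse=self.target_mse,
                            max_epochs=self.max_epochs,
                            random_state=self.random_state,
                            mu_init=self.mu_init, mu_increase=self.mu_increase,
                            mu_decrease=self.mu_decrease, mu_max=self.mu_max)
        net.fit(X, target)
        self.network_ = net
        self.stop_reason_ = net.stop_reason_
        self.n_epochs_ = net.n_epochs_
        return self

    def predict(self, X) -> np.ndarray:
        """Potential energy V in cm^-1 (scheme B adds exact V_nu)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, self.coordinate_spec.n_dims)
        out = self.network_.predict(X)
        if self.scheme == "B":
            out = out + self._vnu_cm(X)
        return out

    def predict_electronic(self, X) -> np.ndarray:
        """Fitted electronic energy E_el in cm^-1 (scheme B only)."""
        if self.scheme != "B":
            raise ValueError("predict_electronic is defined for scheme B only")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, self.coordinate_spec.n_dims)
        return self.network_.predict(X)


@dataclass
class FitStats:
    train_rmsd: float
    test_rmsd: float
    epochs: int
    stop_reason: str
    seed: int | None


@dataclass
class FittedPES:
    """A trained scheme-A or scheme-B surface with its realised split."""

    scheme: str
    model: PESRegressor
    coordinate_spec: CoordinateSpec
    split: SplitSpec
    train_indices: np.ndarray
    test_indices: np.ndarray
    stats: FitStats
    network_spec: tuple = field(default_factory=tuple)

    def predict_potential(self, X) -> np.ndarray:
        return self.model.predict(X)

    def predict_electronic(self, X) -> np.ndarray:
        return self.model.predict_electronic(X)

    def potential_curve(self):
        """1-D callable R (bohr) -> V (cm^-1), for spectra and extension."""
        if self.coordinate_spec.n_dims != 1:
            raise ValueError("potential_curve applies to 1-D surfaces only")
        return lambda R: self.predict_potential(np.atleast_1d(R).reshape(-1, 1))


def _prepare_tables(table: EnergyTable, scheme: str) -> EnergyTable:
    if scheme == "B" and np.any(~table.is_united_atom & np.isnan(table.Eel)):
        table = subtract_nuclear(table)
    return table


def _fit(table: EnergyTable, network, split: SplitSpec, config: TrainConfig,
         scheme: str) -> FittedPES:
    network = tuple(network) if not np.isscalar(network) else (int(network),)
    table = _prepare_tables(table, scheme)
    if scheme == "A":
        n_ua = int(table.is_united_atom.sum())
        if n_ua:
            log.info("scheme A: excluding %d united-atom record(s)", n_ua)
            keep = np.flatnonzero(~table.is_united_atom)
            table = EnergyTable(table.coordinate_spec, table.coords[keep],
                                V=table.V[keep], Eel=table.Eel[keep],
                                state_label=table.state_label,
                                provenance=table.provenance)
        if np.any(np.isnan(table.V)):
            raise ValueError("scheme A requires V on every record")
    train, test = split_train_test(table, split)
    X = table.coords
    model = PESRegressor(coordinate_spec=table.coordinate_spec, scheme=scheme,
                         hidden_layer_sizes=network, **config.estimator_kwargs())
    if scheme == "B":
        eel_cm = table.Eel_cm()
        model.fit(X[train], None, electronic=eel_cm[train])
        stats = FitStats(
            train_rmsd=rmsd(model.predict_electronic(X[train]), eel_cm[train]),
            test_rmsd=rmsd(model.predict_electronic(X[test]), eel_cm[test]),
            epochs=model.n_epochs_, stop_reason=model.stop_reason_,
            seed=config.seed)
    else:
        v_cm = table.V_cm()
        model.fit(X[train], v_cm[train])
        stats = FitStats(
            train_rmsd=rmsd(model.predict(X[train]), v_cm[train]),
            test_rmsd=rmsd(model.predict(X[test]), v_cm[test]),
            epochs=model.n_epochs_, stop_reason=model.stop_reason_,
            seed=config.seed)
    return FittedPES(scheme=scheme, model=model,
                     coordinate_spec=table.coordinate_spec, split=split,
                     train_indices=train, test_indices=test, stats=stats,
                     network_spec=network)


def fit_scheme_a(table: EnergyTable, network, split: SplitSpec,
                 config: TrainConfig) -> FittedPES:
    """Direct network fit of the potential energy (united-atom rows dropped)."""
    return _fit(table, network, split, config, "A")


def fit_scheme_b(table: EnergyTable, network, split: SplitSpec,
                 config: TrainConfig) -> FittedPES:
    """Network fit of E_el; exact V_nu re-added at prediction.

    United-atom records (if present) are forced into the training set by
    the splitter and enter the E_el fit like any other record.
    """
    return _fit(table, network, split, config, "B")


def fit_best_of(table: EnergyTable, network, split: SplitSpec,
                config: TrainConfig, scheme: str, seeds) -> FittedPES:
    """Refit with several initialisation seeds, keep the best test RMSD.

    Training from random initial weights is stochastic; reports in the
    comparison tables are conventionally the best of a few runs.
    """
    best = None
    for s in seeds:
        cfg = TrainConfig(**{**config.__dict__, "seed": int(s)})
        pes = _fit(table, network, split, cfg, scheme)
        if best is None or pes.stats.test_rmsd < best.stats.test_rmsd:
            best = pes
    return best


def predict_potential(pes: FittedPES, X) -> np.ndarray:
    """Potential energy (cm^-1) of a fitted surface at given coordinates."""
    return pes.predict_potential(X)


def predict_electronic(pes: FittedPES, X) -> np.ndarray:
    """Electronic energy (cm^-1) of a fitted scheme-B surface."""
    return pes.predict_electronic(X)


def compare_networks(table: EnergyTable, networks, split: SplitSpec,
                     config: TrainConfig, scheme: str = "B",
                     seeds=None) -> pd.DataFrame:
    """One report row per network, all sharing the same realised split.

    Columns: network, train_rmsd, test_rmsd, epochs, stop_reason, seed.
    Per-row failures are flagged in ``stop_reason`` instead of aborting.
    """
    if not networks:
        raise ValueError("at least one network spec is required")
    rows = []
    for net in networks:
        try:
            if seeds is not None:
                pes = fit_best_of(table, net, split, config, scheme, seeds)
            else:
                pes = _fit(table, net, split, config, scheme)
            st = pes.stats
            rows.append(dict(network=format_network(pes.network_spec),
                             train_rmsd=st.train_rmsd, test_rmsd=st.test_rmsd,
                             epochs=st.epochs, stop_reason=st.stop_reason,
                             seed=st.seed))
        except Exception as exc:  # noqa: BLE001 - flagged, not fatal
            rows.append(dict(network=format_network(net), train_rmsd=np.nan,
                             test_rmsd=np.nan, epochs=0,
                             stop_reason=f"error: {exc}", seed=config.seed))
    return pd.DataFrame(rows)


def parse_network(text: str) -> tuple[int, ...]:
    """Parse a network notation like ``"15"`` or ``"(10,10)"``."""
    body = text.strip().strip("()")
    return tuple(int(p) for p in body.split(",") if p.strip())


def format_network(net) -> str:
    net = (int(net),) if np.isscalar(net) else tuple(net)
    return str(net[0]) if len(net) == 1 else "(" + ", ".join(map(str, net)) + ")"
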