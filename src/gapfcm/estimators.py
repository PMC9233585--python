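"""Scikit-learn style estimators wrapping the clustering routines.

`FuzzyCMeans` clusters an ``(n_samples, n_features)`` matrix like
`sklearn.cluster.KMeans` does, but returns graded memberships.
`SpatialFuzzyCMeans` segments a 2-D grayscale image — its ``fit``
input is the ``(H, W)`` pixel grid, because the spatial membership
penalty needs the pixel lattice.  Both support ``init="ga"`` to pick
the starting centers with the genetic algorithm.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from . import fcm as _fcm
from . import spatial as _spatial
from .ga import GaConfig, run_ga

__all__ = ["FuzzyCMeans", "SpatialFuzzyCMeans"]


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """Fuzzy C-means clustering.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of clusters x.
    fuzzifier : float, default=2.0
        Membership softness exponent w > 1; w -> 1 approaches hard
        k-means-like assignments.
    tol : float, default=1e-5
        Convergence threshold on the maximum center shift.
    max_iter : int, default=300
        Iteration cap for the alternating updates.
    init : {"random", "ga"} or array of shape (n_clusters, n_features)
        Center initialization: distinct random data points, a
        genetic-algorithm search, or explicit centers.
    ga_config : GaConfig or None
        Settings for ``init="ga"``; defaults are used when None.
    random_state : int or None
        Seed for initialization randomness.

    Attributes
    ----------
    cluster_centers_ : (n_clusters, n_features) array
    membership_ : (n_samples, n_clusters) array, rows sum to 1
    labels_ : (n_samples,) argmax-membership labels
    objective_trace_ : list of per-iteration objective values
    n_iter_ : iterations run

    Examples
    --------
    >>> import numpy as np
    >>> X = np.concatenate([np.random.normal(0, .05, 50),
    ...                     np.random.normal(1, .05, 50)]).reshape(-1, 1)
    >>> fcm = FuzzyCMeans(n_clusters=2, random_state=0).fit(X)
    >>> sorted(np.round(fcm.cluster_centers_.ravel(), 1))
    [0.0, 1.0]
    """

    def __init__(
        self,
        n_clusters: int = 2,
        *,
        fuzzifier: float = 2.0,
        tol: float = 1e-5,
        max_iter: int = 300,
        init="random",
        ga_config: GaConfig | None = None,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.fuzzifier = fuzzifier
        self.tol = tol
        self.max_iter = max_iter
        self.init = init
        self.ga_config = ga_config
        self.random_state = random_state

    # image geometry hook used by the spatial subclass
    _image_input = False

    def _validate(self, X) -> tuple[np.ndarray, tuple[int, int] | None]:
        X = np.asarray(X, dtype=float)
        if self._image_input:
            if X.ndim != 2:
                raise ValueError("expected a 2-D (H, W) grayscale image")
            return X.reshape(-1, 1), X.shape
        if X.ndim != 2:
            raise ValueError("expected a 2-D (n_samples, n_features) array")
        return X, None

    def _ga_seed_config(self) -> GaConfig:
        cfg = self.ga_config
        if cfg is None:
            return GaConfig(seed=self.random_state)
        if cfg.seed is None and self.random_state is not None:
            return GaConfig(**{**cfg.__dict__, "seed": self.random_state})
        return cfg

    def _initial_centers(
        self, data: np.ndarray, image_shape: tuple[int, int] | None
    ) -> np.ndarray | None:
        if isinstance(self.init, str):
            if self.init == "random":
                return None  # drawn inside run_fcm/run_pfcm from random_state
            if self.init == "ga":
                return run_ga(
                    data,
                    self.n_clusters,
                    image_shape,
                    self._ga_seed_config(),
                    fuzzifier=self.fuzzifier,
                    sigma=getattr(self, "sigma", 0.0),
                    connectivity=getattr(self, "connectivity", 8),
                    penalty_exponent=getattr(self, "penalty_exponent", None),
                )
            raise ValueError(f"unknown init {self.init!r}")
        centers = np.asarray(self.init, dtype=float)
        if centers.shape != (self.n_clusters, data.shape[1]):
            raise ValueError("explicit init centers have the wrong shape")
        return centers

    def fit(self, X, y=None):
        data, _ = self._validate(X)
        init_centers = self._initial_centers(data, None)
        res = _fcm.run_fcm(
            data,
            self.n_clusters,
            fuzzifier=self.fuzzifier,
            tol=self.tol,
            max_iter=self.max_iter,
            init_centers=init_centers,
            seed=self.random_state,
        )
        self._store(res, data.shape[1])
        return self

    def _store(self, res, n_features: int) -> None:
        self.cluster_centers_ = res.centers
        self.membership_ = res.memberships.T
        self.labels_ = np.argmax(res.memberships, axis=0)
        self.objective_trace_ = res.objective_trace
        self.n_iter_ = res.n_iter
        self.n_features_in_ = n_features

    def predict_proba(self, X) -> np.ndarray:
        """Memberships of new points w.r.t. the fitted centers."""
        check_is_fitted(self, "cluster_centers_")
        data, _ = self._validate(X)
        d2 = _fcm.squared_distances(data, self.cluster_centers_)
        return _fcm.update_memberships_fcm(d2, self.fuzzifier).T

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


class SpatialFuzzyCMeans(FuzzyCMeans):
    """Spatially penalized fuzzy C-means image segmentation.

    ``fit`` takes a 2-D ``(H, W)`` grayscale image; intensities should
    be on a [0, 1]-like scale for the default penalty weight to be
    meaningful.  The objective adds
    ``sigma * sum u**w (1 - P)**w`` to plain FCM, where P averages each
    pixel's neighborhood memberships, so noisy isolated pixels are
    pulled toward their local majority.  ``sigma=0`` reduces exactly to
    `FuzzyCMeans` on the flattened pixels.

    Extra parameters
    ----------------
    sigma : float, default=1.0
        Spatial penalty weight (>= 0).
    connectivity : {4, 8}, default=8
        Pixel neighborhood used for the prior.
    penalty_exponent : float or None
        Exponent on (1 - P); None means the fuzzifier w.

    Extra attributes
    ----------------
    labels_image_ : (H, W) label map
    """

    _image_input = True

    def __init__(
        self,
        n_clusters: int = 2,
        *,
        fuzzifier: float = 2.0,
        sigma: float = 1.0,
        connectivity: int = 8,
        penalty_exponent: float | None = None,
        tol: float = 1e-5,
        max_iter: int = 300,
        init="random",
        ga_config: GaConfig | None = None,
        random_state: int | None = None,
    ):
        super().__init__(
            n_clusters,
            fuzzifier=fuzzifier,
            tol=tol,
            max_iter=max_iter,
            init=init,
            ga_config=ga_config,
            random_state=random_state,
        )
        self.sigma = sigma
        self.connectivity = connectivity
        self.penalty_exponent = penalty_exponent

    def fit(self, X, y=None):
        data, shape = self._validate(X)
        init_centers = self._initial_centers(data, shape)
        res = _spatial.run_pfcm(
            np.asarray(X, dtype=float),
            self.n_clusters,
            fuzzifier=self.fuzzifier,
            sigma=self.sigma,
            connectivity=self.connectivity,
            penalty_exponent=self.penalty_exponent,
            tol=self.tol,
            max_iter=self.max_iter,
            init_centers=init_centers,
            seed=self.random_state,
        )
        self._store(
            _fcm.FcmResult(res.memberships, res.centers, res.objective_trace, res.n_iter),
            1,
        )
        self.labels_image_ = res.labels
        return self
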