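"""Population histograms and Gaussian-mixture decomposition.

Per-molecule population histograms are built either from the mean FRET
efficiency of the first 10 frames of each trace (one value per molecule) or
by pooling all frames of the first 30 s of every trace (cumulative mode,
used when state FRET levels are too close for per-molecule averaging).
The histogram is decomposed into U/I/F/F* populations with a maximum-
likelihood Gaussian mixture; population percentages are the mixture
weights.  Conditions are compared with Welch's unpaired two-sided t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

from .traces import FretTrace

__all__ = [
    "HistogramSpec",
    "MixtureFit",
    "FretPopulationMixture",
    "histogram_values",
    "binned_histogram",
    "fit_mixture",
    "compare_means",
]

SD_FLOOR = 1e-3


@dataclass
class HistogramSpec:
    """How to reduce FRET traces to histogram values.

    mode="initial_frames": one value per trace, the mean of its first
    ``n_frames`` valid frames (traces with fewer valid frames are dropped
    and counted).  mode="cumulative": all valid frames within the first
    ``window_s`` seconds of every trace, pooled.
    """

    mode: str = "initial_frames"
    n_frames: int = 10
    window_s: float = 30.0
    bin_width: float = 0.02
    range: Tuple[float, float] = (-0.2, 1.2)

    def __post_init__(self) -> None:
        if self.mode not in ("initial_frames", "cumulative"):
            raise ValueError(f"unknown histogram mode {self.mode!r}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def histogram_values(
    fret_traces: Sequence[FretTrace], spec: Optional[HistogramSpec] = None
) -> Tuple[np.ndarray, int]:
    """FRET values entering the population histogram.

    Returns (values, n_dropped) where n_dropped counts traces discarded in
    initial_frames mode for having fewer than ``n_frames`` valid frames.
    """
    spec = spec or HistogramSpec()
    if len(fret_traces) == 0:
        raise ValueError("no traces supplied")
    values: List[float] = []
    dropped = 0
    if spec.mode == "initial_frames":
        for ft in fret_traces:
            vals = ft.valid_values()
            if len(vals) < spec.n_frames:
                dropped += 1
                continue
            values.append(float(vals[: spec.n_frames].mean()))
    else:  # cumulative
        for ft in fret_traces:
            in_window = ft.valid_mask & (ft.time_s < spec.window_s)
            values.extend(ft.efret[in_window].tolist())
    return np.asarray(values, dtype=float), dropped


def binned_histogram(
    values: np.ndarray, spec: Optional[HistogramSpec] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Counts and bin edges on the spec's grid (for CSV export / bin fits)."""
    spec = spec or HistogramSpec()
    lo, hi = spec.range
    edges = np.arange(lo, hi + spec.bin_width / 2, spec.bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return counts, edges


@dataclass
class MixtureFit:
    """Gaussian mixture components sorted by ascending mean."""

    components: List[Tuple[float, float, float]]  # (mean, sd, weight)
    k: int
    log_likelihood: float
    bic: float
    n_values: int
    converged: bool = True

    @property
    def means(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[2] for c in self.components])

    @property
    def percentages(self) -> np.ndarray:
        """Population proportions as percentages (mixture weights x 100)."""
        return self.weights * 100.0


class FretPopulationMixture(BaseEstimator):
    """Maximum-likelihood Gaussian mixture over FRET histogram values.

    EM on the raw values (10 restarts, log-likelihood tolerance 1e-8), with
    a variance floor giving an sd floor of 1e-3.  ``n_components="auto"``
    selects k in {1..4} by BIC; the fitted components are sorted by
    ascending mean so population labels are stable.

    By default all components share one emission width ("tied"): on a FRET
    population histogram the width of every state's peak is set by the same
    channel noise at constant total intensity, and tying it removes the
    classic pathology where a wide component swallows a small neighbouring
    population.  Pass ``covariance="free"`` for per-component widths.

    Attributes (after fit): means_, sds_, weights_, bic_, log_likelihood_,
    n_components_.
    """

    def __init__(
        self,
        n_components: Union[int, str] = "auto",
        max_auto_components: int = 4,
        n_init: int = 10,
        tol: float = 1e-8,
        max_iter: int = 2000,
        covariance: str = "tied",
        random_state: Optional[int] = None,
    ):
        self.n_components = n_components
        self.max_auto_components = max_auto_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.covariance = covariance
        self.random_state = random_state

    def _fit_k(self, x: np.ndarray, k: int) -> GaussianMixture:
        if self.covariance not in ("tied", "free"):
            raise ValueError(f"unknown covariance mode {self.covariance!r}")
        gm = GaussianMixture(
            n_components=k,
            covariance_type="tied" if self.covariance == "tied" else "diag",
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            reg_covar=SD_FLOOR**2,
            random_state=self.random_state,
        )
        gm.fit(x)
        return gm

    def _sds_of(self, gm: GaussianMixture) -> np.ndarray:
        if gm.covariance_type == "tied":
            return np.full(gm.n_components, float(np.sqrt(gm.covariances_[0, 0])))
        return np.sqrt(gm.covariances_.ravel())

    def fit(self, X, y=None) -> "FretPopulationMixture":
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        if np.any(~np.isfinite(x)):
            raise ValueError("values must be finite")
        if np.ptp(x) == 0:
            raise ValueError(
                "degenerate input: all values identical, mixture undefined"
            )
        if self.n_components == "auto":
            ks = range(1, self.max_auto_components + 1)
        else:
            ks = [int(self.n_components)]
        best = None
        for k in ks:
            if len(x) < 20 * k:
                if best is None and k == min(ks):
                    raise ValueError(
                        f"need at least {20 * k} values for k={k}, got {len(x)}"
                    )
                continue
            gm = self._fit_k(x, k)
            if best is None or gm.bic(x) < best.bic(x):
                best = gm
        if not best.converged_:
            raise RuntimeError(
                "EM did not converge within max_iter across restarts"
            )
        order = np.argsort(best.means_.ravel())
        self.means_ = best.means_.ravel()[order]
        self.sds_ = self._sds_of(best)[order]
        self.weights_ = best.weights_[order]
        self.n_components_ = best.n_components
        self.log_likelihood_ = float(best.score(x) * len(x))
        self.bic_ = float(best.bic(x))
        self.n_values_ = len(x)
        return self

    def predict(self, X) -> np.ndarray:
        """Hard component assignment (by posterior) for new values."""
        check_is_fitted(self, "means_")
        x = np.asarray(X, dtype=float).reshape(-1, 1)
        logp = np.stack(
            [
                np.log(w) + stats.norm.logpdf(x.ravel(), m, s)
                for m, s, w in zip(self.means_, self.sds_, self.weights_)
            ]
        )
        return logp.argmax(axis=0)

    def to_fit(self) -> MixtureFit:
        check_is_fitted(self, "means_")
        return MixtureFit(
            components=[
                (float(m), float(s), float(w))
                for m, s, w in zip(self.means_, self.sds_, self.weights_)
            ],
            k=self.n_components_,
            log_likelihood=self.log_likelihood_,
            bic=self.bic_,
            n_values=self.n_values_,
        )


def fit_mixture(
    values: Sequence[float],
    k: Union[int, str] = "auto",
    seed: Optional[int] = None,
    covariance: str = "tied",
) -> MixtureFit:
    """Fit a Gaussian mixture to FRET values; see FretPopulationMixture."""
    est = FretPopulationMixture(
        n_components=k, random_state=seed, covariance=covariance
    )
    est.fit(values)
    return est.to_fit()


def compare_means(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Tuple[float, float, float]:
    """Welch unpaired two-sided t-test; returns (t, dof, p)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("zero variance in both groups; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
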