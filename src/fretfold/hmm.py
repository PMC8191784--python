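"""Hidden Markov model idealization of FRET trajectories.

A Gaussian-emission HMM is fitted to each trajectory (or to a pooled set of
trajectories sharing one condition) by Baum-Welch, and the maximum a
posteriori state sequence is decoded with Viterbi.  The fitted transition
matrix is in units of transitions per frame; multiplying by the frame rate
converts per-frame transition probabilities into rates in 1/s, a conversion
that is only trustworthy while the per-frame probabilities stay well below
one (a warning is emitted above 0.2/frame).

Masked frames are treated as missing observations: each trace is split into
contiguous valid segments which enter the fit as independent sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .traces import FretTrace

__all__ = [
    "HmmModel",
    "StatePath",
    "FretHMM",
    "fit_hmm",
    "viterbi_path",
    "transitions_to_rates",
]

SD_FLOOR = 1e-3
DISCRETIZATION_WARN = 0.2  # per-frame probability above which rates are biased


class _FlooredGaussianHMM(GaussianHMM):
    """Plain-ML Gaussian HMM with a hard emission-variance floor.

    hmmlearn's min_covar only regularizes initialization; on noiseless data
    the ML M-step can collapse a component's variance to zero.  Flooring the
    variance at SD_FLOOR**2 after every M-step keeps the estimate ML
    wherever the data support it and merely prevents degeneracy.
    """

    def _do_mstep(self, stats):
        super()._do_mstep(stats)
        self._covars_ = np.maximum(self._covars_, SD_FLOOR**2)


class _HistoryMonitor(ConvergenceMonitor):
    """ConvergenceMonitor that keeps the full log-likelihood history."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: List[float] = []

    def report(self, log_prob):
        self.full_history.append(float(log_prob))
        super().report(log_prob)


@dataclass
class HmmModel:
    """Fitted Gaussian-emission HMM with states sorted by ascending mean."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    trans: np.ndarray  # row-stochastic, per-frame probabilities
    initial: np.ndarray
    log_likelihood: float
    n_iterations: int
    converged: bool
    log_likelihoods: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "trans": self.trans.tolist(),
            "initial": self.initial.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


@dataclass
class StatePath:
    """Idealized (Viterbi) state sequence over a trace's valid frames."""

    trace_id: str
    states: np.ndarray  # int labels into model states, one per valid frame
    frame_index: np.ndarray  # original frame index of each entry
    frame_interval: float
    model: HmmModel
    posteriors: Optional[np.ndarray] = None

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def state_names(self, names: Sequence[str]) -> List[str]:
        return [names[s] for s in self.states]


TraceLike = Union[FretTrace, np.ndarray]


def _segments(fret: TraceLike) -> Tuple[List[np.ndarray], np.ndarray]:
    """Contiguous valid segments and the valid frame indices of a trace."""
    if isinstance(fret, FretTrace):
        idx = fret.valid_indices()
        vals = fret.efret[idx]
    else:
        vals = np.asarray(fret, dtype=float)
        idx = np.arange(len(vals))
    if len(vals) == 0:
        return [], idx
    breaks = np.flatnonzero(np.diff(idx) > 1)
    return np.split(vals, breaks + 1), idx


class FretHMM(BaseEstimator):
    """Gaussian-emission HMM estimator for FRET trajectories.

    fit(X) accepts one FretTrace/array or a list of them (pooled mode:
    emission and transition parameters are shared across traces of a
    condition).  Baum-Welch runs to |delta logL| < tol or max_iter, with
    ``n_init`` k-means-seeded restarts; the best restart by final
    log-likelihood is kept, ties broken by lowest restart index.

    Fitted attributes: means_, sds_, transmat_, startprob_,
    log_likelihood_, n_iter_, converged_, log_likelihoods_.
    """

    def __init__(
        self,
        n_components: int = 2,
        n_init: int = 10,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: Optional[int] = None,
        means_init: Optional[Sequence[float]] = None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.means_init = means_init

    def _collect(self, X) -> Tuple[np.ndarray, List[int]]:
        traces = X if isinstance(X, (list, tuple)) else [X]
        seqs: List[np.ndarray] = []
        for t in traces:
            segs, _ = _segments(t)
            seqs.extend(s for s in segs if len(s) >= 2)
        if not seqs:
            raise ValueError("no valid segments of length >= 2 to fit")
        concat = np.concatenate(seqs).reshape(-1, 1)
        lengths = [len(s) for s in seqs]
        return concat, lengths

    def fit(self, X, y=None) -> "FretHMM":
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        concat, lengths = self._collect(X)
        if concat.shape[0] < 50:
            raise ValueError(
                f"need >= 50 valid frames to fit an HMM, got {concat.shape[0]}"
            )
        seeds = np.random.SeedSequence(self.random_state).generate_state(
            max(1, self.n_init)
        )
        best = None
        best_ll = -np.inf
        best_hist: List[float] = []
        fixed = self.means_init is not None
        for seed in seeds:
            hmm = _FlooredGaussianHMM(
                n_components=self.n_components,
                covariance_type="diag",
                min_covar=SD_FLOOR**2,
                covars_prior=0.0,  # plain ML; the floor handles collapse
                covars_weight=0.0,
                tol=self.tol,
                n_iter=self.max_iter,
                random_state=int(seed) % (2**32 - 1),
                init_params="stc" if fixed else "stmc",
            )
            if fixed:
                hmm.means_ = np.asarray(self.means_init, dtype=float).reshape(
                    -1, 1
                )
            hmm.monitor_ = _HistoryMonitor(self.tol, self.max_iter)
            hmm_log = logging.getLogger("hmmlearn.base")
            old_level = hmm_log.level
            hmm_log.setLevel(logging.ERROR)  # float-noise deltas spam warnings
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hmm.fit(concat, lengths)
            finally:
                hmm_log.setLevel(old_level)
            ll = hmm.monitor_.full_history[-1]
            if ll > best_ll:
                best, best_ll, best_hist = hmm, ll, hmm.monitor_.full_history
            if fixed:
                break  # deterministic start: restarts are identical
        order = np.argsort(best.means_.ravel())
        self.means_ = best.means_.ravel()[order]
        self.sds_ = np.sqrt(
            np.maximum(best.covars_.reshape(-1)[order], SD_FLOOR**2)
        )
        self.transmat_ = best.transmat_[np.ix_(order, order)]
        self.startprob_ = best.startprob_[order]
        self.log_likelihood_ = float(best_ll)
        self.log_likelihoods_ = list(best_hist)
        self.n_iter_ = len(best_hist)
        self.converged_ = bool(best.monitor_.converged)
        if not self.converged_:
            warnings.warn(
                "Baum-Welch did not converge within max_iter; "
                "result flagged via converged_=False",
                RuntimeWarning,
            )
        self._order = order
        self._hmm = best
        return self

    def _decode_model(self) -> GaussianHMM:
        """The underlying hmmlearn model with states re-sorted by mean."""
        check_is_fitted(self, "means_")
        hmm = GaussianHMM(
            n_components=self.n_components, covariance_type="diag"
        )
        hmm.means_ = self.means_.reshape(-1, 1)
        hmm.covars_ = (self.sds_**2).reshape(-1, 1)
        hmm.transmat_ = self.transmat_
        hmm.startprob_ = self.startprob_
        return hmm

    def predict(self, X, return_posteriors: bool = False) -> StatePath:
        """Viterbi maximum a posteriori state path for one trace."""
        check_is_fitted(self, "means_")
        segs, idx = _segments(X)
        hmm = self._decode_model()
        states = []
        posts = []
        for seg in segs:
            obs = seg.reshape(-1, 1)
            states.append(hmm.predict(obs))
            if return_posteriors:
                posts.append(hmm.predict_proba(obs))
        trace_id = X.trace_id if isinstance(X, FretTrace) else ""
        dt = X.frame_interval if isinstance(X, FretTrace) else 1.0
        return StatePath(
            trace_id=trace_id,
            states=np.concatenate(states) if states else np.array([], int),
            frame_index=idx,
            frame_interval=dt,
            model=self.to_model(),
            posteriors=np.concatenate(posts) if posts else None,
        )

    def to_model(self) -> HmmModel:
        check_is_fitted(self, "means_")
        return HmmModel(
            k=self.n_components,
            means=self.means_.copy(),
            sds=self.sds_.copy(),
            trans=self.transmat_.copy(),
            initial=self.startprob_.copy(),
            log_likelihood=self.log_likelihood_,
            n_iterations=self.n_iter_,
            converged=self.converged_,
            log_likelihoods=list(self.log_likelihoods_),
        )


def fit_hmm(
    fret: Union[TraceLike, Sequence[TraceLike]],
    k: int,
    init: str = "kmeans",
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: Optional[int] = None,
    means_init: Optional[Sequence[float]] = None,
    n_init: int = 10,
) -> HmmModel:
    """Fit a k-state Gaussian HMM; see :class:`FretHMM`.

    init="kmeans" uses seeded k-means restarts; init="fixed" starts the
    emission means at ``means_init``.
    """
    if init == "fixed":
        if means_init is None:
            raise ValueError("init='fixed' requires means_init")
    elif init == "kmeans":
        means_init = None
    else:
        raise ValueError(f"unknown init {init!r}")
    est = FretHMM(
        n_components=k,
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        random_state=seed,
        means_init=means_init,
    )
    est.fit(fret)
    return est.to_model()


def viterbi_path(model: HmmModel, fret: TraceLike) -> StatePath:
    """Decode the MAP state sequence of a trace under a fitted model."""
    est = FretHMM(n_components=model.k)
    est.means_ = model.means
    est.sds_ = model.sds
    est.transmat_ = model.trans
    est.startprob_ = model.initial
    est.log_likelihood_ = model.log_likelihood
    est.log_likelihoods_ = model.log_likelihoods
    est.n_iter_ = model.n_iterations
    est.converged_ = model.converged
    return est.predict(fret)


def transitions_to_rates(
    model: HmmModel, frame_rate: float
) -> np.ndarray:
    """Convert per-frame transition probabilities to rates: k_ij = p_ij * f.

    Off-diagonal only; the diagonal of the result is zero.  Probabilities
    above 0.2/frame trigger a discretization-bias warning.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    p = model.trans.copy()
    np.fill_diagonal(p, 0.0)
    if np.any(p > DISCRETIZATION_WARN):
        warnings.warn(
            "per-frame transition probability exceeds 0.2; "
            "p*frame_rate underestimates the true rate (discretization bias)",
            UserWarning,
        )
    return p * frame_rate
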