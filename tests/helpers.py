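"""Shared independent oracles for the test suite."""

import itertools

import numpy as np
from scipy import stats

from fretfold.hmm import HmmModel


def brute_force_viterbi(model: HmmModel, obs: np.ndarray) -> np.ndarray:
    """Exhaustive MAP path over all k^n state sequences (tiny n only)."""
    k, n = model.k, len(obs)
    log_trans = np.log(model.trans)
    log_init = np.log(model.initial)
    best_lp, best_seq = -np.inf, None
    for seq in itertools.product(range(k), repeat=n):
        lp = log_init[seq[0]] + stats.norm.logpdf(
            obs[0], model.means[seq[0]], model.sds[seq[0]]
        )
        for a, b, x in zip(seq, seq[1:], obs[1:]):
            lp += log_trans[a, b] + stats.norm.logpdf(
                x, model.means[b], model.sds[b]
            )
        if lp > best_lp:
            best_lp, best_seq = lp, seq
    return np.array(best_seq)


def random_model(rng: np.random.Generator, k: int) -> HmmModel:
    """A random valid Gaussian-emission HMM for property tests."""
    return HmmModel(
        k=k,
        means=np.sort(rng.uniform(0.1, 0.9, k)),
        sds=rng.uniform(0.03, 0.1, k),
        trans=rng.dirichlet(np.ones(k) * 2, size=k),
        initial=rng.dirichlet(np.ones(k)),
        log_likelihood=0.0,
        n_iterations=0,
        converged=True,
    )
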