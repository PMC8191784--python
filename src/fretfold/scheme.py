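"""Kinetic schemes and acquisition models for smFRET simulation.

A :class:`KineticScheme` is a continuous-time Markov chain over a small set of
RNA conformers (e.g. U, I, F, F* for a riboswitch aptamer), each with a
characteristic mean FRET efficiency and emission width.  The default
four-state scheme mirrors a folding pathway in which the unfolded (U) and
intermediate (I) states sit at low/mid FRET, while the ligand-free folded (F)
and ligand-bound folded (F*) states share a high FRET level and are
distinguishable only kinetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "KineticScheme",
    "AcquisitionModel",
    "Condition",
    "StateEvent",
    "default_four_state_scheme",
    "two_state_scheme",
]


@dataclass(frozen=True)
class Condition:
    """Buffer / ligand condition attached to a trace or dataset.

    Concentrations are in the units conventional for each axis:
    NaCl and MgCl2 in mM, urea in M, ligand in uM.
    """

    nacl_mM: float = 0.0
    mgcl2_mM: float = 0.0
    urea_M: float = 0.0
    ligand_name: str = "none"
    ligand_uM: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nacl_mM", "mgcl2_mM", "urea_M", "ligand_uM"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.ligand_name not in ("none", "DAP", "adenine"):
            raise ValueError(f"unknown ligand_name {self.ligand_name!r}")

    def to_dict(self) -> dict:
        return {
            "nacl_mM": self.nacl_mM,
            "mgcl2_mM": self.mgcl2_mM,
            "urea_M": self.urea_M,
            "ligand_name": self.ligand_name,
            "ligand_uM": self.ligand_uM,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Condition":
        return cls(**d)


@dataclass
class KineticScheme:
    """Continuous-time Markov chain over conformational states.

    Parameters
    ----------
    state_names : ordered state labels, e.g. ``("U", "I", "F", "Fstar")``.
    fret_mean : per-state FRET efficiency in [0, 1].
    fret_sd : per-state emission width (dimensionless FRET units).
    rates : square matrix of transition rates k_ij in 1/s; off-diagonal
        entries must be >= 0, the diagonal is ignored.
    initial_probs : distribution over states at t=0; defaults to the
        stationary distribution of ``rates``.
    """

    state_names: tuple
    fret_mean: np.ndarray
    fret_sd: np.ndarray
    rates: np.ndarray
    initial_probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.state_names = tuple(self.state_names)
        self.fret_mean = np.asarray(self.fret_mean, dtype=float)
        self.fret_sd = np.asarray(self.fret_sd, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        n = len(self.state_names)
        if n < 1:
            raise ValueError("need at least one state")
        if self.fret_mean.shape != (n,) or self.fret_sd.shape != (n,):
            raise ValueError("fret_mean/fret_sd must have one entry per state")
        if np.any(self.fret_mean < 0) or np.any(self.fret_mean > 1):
            raise ValueError("fret_mean values must lie in [0, 1]")
        if np.any(self.fret_sd < 0):
            raise ValueError("fret_sd values must be >= 0")
        if self.rates.shape != (n, n):
            raise ValueError(f"rates must be {n}x{n}")
        off = self.rates[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if self.initial_probs is None:
            self.initial_probs = self.stationary_distribution()
        else:
            self.initial_probs = np.asarray(self.initial_probs, dtype=float)
            if self.initial_probs.shape != (n,):
                raise ValueError("initial_probs must have one entry per state")
            if np.any(self.initial_probs < 0):
                raise ValueError("initial_probs must be >= 0")
            if abs(self.initial_probs.sum() - 1.0) > 1e-9:
                raise ValueError("initial_probs must sum to 1 within 1e-9")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def state_index(self, name: str) -> int:
        return self.state_names.index(name)

    def exit_rates(self) -> np.ndarray:
        """Total exit rate per state (sum of off-diagonal row entries)."""
        k = self.rates.copy()
        np.fill_diagonal(k, 0.0)
        return k.sum(axis=1)

    def generator_matrix(self) -> np.ndarray:
        """Infinitesimal generator Q (rows sum to zero)."""
        q = self.rates.copy()
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary distribution of the CTMC, by solving pi Q = 0.

        For reducible chains this returns one valid stationary vector
        (the null-space solution with minimal norm, renormalized).
        """
        n = self.n_states
        if n == 1:
            return np.ones(1)
        q = self.generator_matrix()
        # solve pi Q = 0, sum(pi) = 1 as a least-squares system
        a = np.vstack([q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()

    def to_dict(self) -> dict:
        return {
            "state_names": list(self.state_names),
            "fret_mean": self.fret_mean.tolist(),
            "fret_sd": self.fret_sd.tolist(),
            "rates": self.rates.tolist(),
            "initial_probs": self.initial_probs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticScheme":
        return cls(
            state_names=tuple(d["state_names"]),
            fret_mean=np.asarray(d["fret_mean"], dtype=float),
            fret_sd=np.asarray(d["fret_sd"], dtype=float),
            rates=np.asarray(d["rates"], dtype=float),
            initial_probs=(
                np.asarray(d["initial_probs"], dtype=float)
                if d.get("initial_probs") is not None
                else None
            ),
        )


@dataclass
class AcquisitionModel:
    """Camera/acquisition forward model for rendering intensity traces.

    frame_interval is the integration time per frame in seconds (50 ms by
    default, with 100 ms as the common slower variant); total_intensity is
    the summed donor+acceptor signal per frame in camera units.
    """

    frame_interval: float = 0.050
    total_intensity: float = 1000.0
    channel_noise_sd: float = 0.0
    donor_background: float = 0.0
    acceptor_background: float = 0.0
    bleach_lifetime: Optional[float] = None
    n_frames: int = 600

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.channel_noise_sd < 0:
            raise ValueError("channel_noise_sd must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.bleach_lifetime is not None and self.bleach_lifetime <= 0:
            raise ValueError("bleach_lifetime must be > 0 or None")

    @property
    def frame_rate(self) -> float:
        """Frames per second (Hz)."""
        return 1.0 / self.frame_interval

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def to_dict(self) -> dict:
        return {
            "frame_interval": self.frame_interval,
            "total_intensity": self.total_intensity,
            "channel_noise_sd": self.channel_noise_sd,
            "donor_background": self.donor_background,
            "acceptor_background": self.acceptor_background,
            "bleach_lifetime": self.bleach_lifetime,
            "n_frames": self.n_frames,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionModel":
        return cls(**d)


@dataclass(frozen=True)
class StateEvent:
    """Entry into a state at a given time of the continuous realization."""

    state: str
    entry_time: float


def default_four_state_scheme(
    k_ui: float = 1.0,
    k_iu: float = 1.0,
    k_if: float = 0.5,
    k_fi: float = 0.5,
    k_ffstar: float = 0.0,
    k_fstarf: float = 0.0,
) -> KineticScheme:
    """Linear U <-> I <-> F <-> F* pathway with demo FRET levels.

    F and F* share the same FRET mean (0.92) and are separable only through
    their kinetics; the F<->F* exchange is off unless ligand-binding rates
    are supplied.
    """
    names = ("U", "I", "F", "Fstar")
    rates = np.zeros((4, 4))
    rates[0, 1] = k_ui
    rates[1, 0] = k_iu
    rates[1, 2] = k_if
    rates[2, 1] = k_fi
    rates[2, 3] = k_ffstar
    rates[3, 2] = k_fstarf
    return KineticScheme(
        state_names=names,
        fret_mean=np.array([0.35, 0.48, 0.92, 0.92]),
        fret_sd=np.array([0.05, 0.05, 0.05, 0.05]),
        rates=rates,
    )


def two_state_scheme(
    k_fold: float,
    k_unfold: float,
    fret_unfolded: float = 0.35,
    fret_folded: float = 0.89,
    fret_sd: float = 0.05,
) -> KineticScheme:
    """Two-state folding scheme: unfolded (U/I lump) <-> folded (F).

    k_fold is the U->F rate and k_unfold the F->U rate, both in 1/s.
    """
    rates = np.array([[0.0, k_fold], [k_unfold, 0.0]])
    return KineticScheme(
        state_names=("U", "F"),
        fret_mean=np.array([fret_unfolded, fret_folded]),
        fret_sd=np.array([fret_sd, fret_sd]),
        rates=rates,
    )
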