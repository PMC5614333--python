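"""Mutual information, channel capacity and the redundancy/synergy decomposition.

The environment-to-expression system is modelled as a discrete memoryless
channel: the input is one of F environmental states (food levels) and the
output is the index of the grid bin into which the response vector g falls.
The channel is fully described by the F x M conditional probability matrix
P[f, m] = p(g in bin m | f).

All information quantities are reported in bits (log base 2).  Zero
probabilities follow the 0*log(0) = 0 convention; no flooring or
pseudo-counts are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from wormcode.density import ConditionalDensity, GridSpec

_ROW_TOL = 1e-9


@dataclass(frozen=True)
class DiscreteChannel:
    """Discrete memoryless channel from environmental states to binned responses.

    Parameters
    ----------
    states
        Ordered labels of the F input states (e.g. food concentrations).
    P
        F x M row-stochastic matrix; row f is the conditional distribution
        p(g|f) over the M response bins.
    shape
        The multidimensional bin layout of the response grid, as a tuple of
        bins per readout dimension (row-major linearization).  ``(M,)`` for a
        one-dimensional response.
    grid
        Optional :class:`GridSpec` the bins refer to, kept for provenance.
    """

    states: tuple
    P: np.ndarray
    shape: tuple = None
    grid: GridSpec | None = None

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        if P.ndim != 2:
            raise ValueError("P must be a 2-D (F x M) matrix")
        if np.any(P < -_ROW_TOL) or not np.all(np.isfinite(P)):
            raise ValueError("conditional probabilities must be finite and >= 0")
        rowsums = P.sum(axis=1)
        if np.any(rowsums <= 0):
            bad = [self.states[i] for i in np.nonzero(rowsums <= 0)[0]]
            raise ValueError(f"all-zero conditional distribution for state(s) {bad}")
        if np.any(np.abs(rowsums - 1.0) > 1e-6):
            raise ValueError("channel rows must each sum to 1")
        # exact renormalization within tolerance keeps downstream sums stable
        object.__setattr__(self, "P", np.clip(P, 0.0, None) / rowsums[:, None])
        object.__setattr__(self, "states", tuple(self.states))
        shape = self.shape if self.shape is not None else (P.shape[1],)
        shape = tuple(int(s) for s in shape)
        if int(np.prod(shape)) != P.shape[1]:
            raise ValueError(f"shape {shape} incompatible with M={P.shape[1]} bins")
        object.__setattr__(self, "shape", shape)
        if len(self.states) != P.shape[0]:
            raise ValueError("number of states must match number of rows")

    @property
    def n_states(self) -> int:
        return self.P.shape[0]

    @property
    def n_bins(self) -> int:
        return self.P.shape[1]

    @property
    def ndim(self) -> int:
        """Number of readout dimensions of the response grid."""
        return len(self.shape)


@dataclass(frozen=True)
class CapacityResult:
    """Outcome of the Blahut-Arimoto capacity computation.

    capacity is in bits; ``p_star`` is the capacity-achieving input
    distribution over the channel states; ``gap`` is the final difference
    between the upper and lower capacity bounds (the a-posteriori accuracy
    guarantee of the alternating optimization).
    """

    capacity: float
    p_star: np.ndarray
    iterations: int
    gap: float
    converged: bool = True


@dataclass(frozen=True)
class InfoDecomposition:
    """Breakdown of joint information into marginal, redundancy and correlation terms.

    ``I_joint`` is the channel capacity of the joint response; ``I_marginal``
    holds the per-readout informations I_N evaluated at the joint channel's
    optimal input; ``I_shuffle`` is the information of the surrogate channel
    in which within-condition correlations between readouts are removed.

    The identities hold by construction::

        redundancy  = sum(I_marginal) - I_joint
        noise_corr  = I_joint - I_shuffle
        signal_corr = I_shuffle - sum(I_marginal)
        signal_corr + noise_corr = -redundancy

    A positive redundancy means the parts jointly repeat each other
    (redundant code); a negative one means the whole carries more than the
    sum of its parts (synergistic code).
    """

    I_joint: float
    I_marginal: tuple
    redundancy: float
    I_shuffle: float
    signal_corr: float
    noise_corr: float
    p_star: np.ndarray = field(default=None, repr=False)

    @property
    def label(self) -> str:
        return "redundant" if self.redundancy >= 0 else "synergistic"

    def to_dict(self) -> dict:
        return {
            "I_joint": self.I_joint,
            "I_marginal": list(self.I_marginal),
            "redundancy": self.redundancy,
            "I_shuffle": self.I_shuffle,
            "signal_corr": self.signal_corr,
            "noise_corr": self.noise_corr,
            "label": self.label,
        }


def channel_from_densities(densities: Sequence[ConditionalDensity]) -> DiscreteChannel:
    """Stack per-condition grid densities (sharing one grid) into a channel."""
    if len(densities) < 2:
        raise ValueError("need at least two conditions to form a channel")
    grid = densities[0].grid
    for d in densities[1:]:
        if d.grid != grid:
            raise ValueError("all densities must share the same grid")
    P = np.vstack([d.p for d in densities])
    states = tuple(d.condition for d in densities)
    return DiscreteChannel(states=states, P=P, shape=(grid.gs,) * grid.dims, grid=grid)


def _check_input_distribution(ch: DiscreteChannel, p_in) -> np.ndarray:
    p = np.asarray(p_in, dtype=float)
    if p.shape != (ch.n_states,):
        raise ValueError(f"input distribution must have length {ch.n_states}")
    if np.any(p < -_ROW_TOL) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("input distribution must be non-negative and sum to 1")
    return np.clip(p, 0.0, None) / p.sum()


def mutual_information(ch: DiscreteChannel, p_in) -> float:
    """I(F;G) in bits for input distribution ``p_in`` over the channel states.

    I = sum_f p(f) sum_g p(g|f) log2[ p(g|f) / p(g) ] with
    p(g) = sum_f p(f) p(g|f).
    """
    p = _check_input_distribution(ch, p_in)
    q = p @ ch.P  # marginal response distribution p(g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ch.P > 0, ch.P / np.where(q > 0, q, 1.0), 1.0)
        terms = np.where(ch.P > 0, ch.P * np.log2(ratio), 0.0)
    mi = float(p @ terms.sum(axis=1))
    return max(mi, 0.0)


def channel_capacity(ch: DiscreteChannel, tol: float = 1e-8,
                     max_iter: int = 100_000) -> CapacityResult:
    """Channel capacity by the Blahut-Arimoto alternating optimization.

    Starts from the uniform input distribution and iterates

        D_f   = KL( p(g|f) || p(g) )        (bits)
        p(f) <- p(f) 2^{D_f} / Z

    After each step the mutual information at the current input is a lower
    bound on capacity and max_f D_f is an upper bound; iteration stops when
    the two differ by less than ``tol`` bits.  The lower bound is
    non-decreasing, so the returned ``capacity`` (the last lower bound) is
    within ``gap`` of the true maximum.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    P = ch.P
    F = ch.n_states
    logP = np.where(P > 0, np.log2(np.where(P > 0, P, 1.0)), 0.0)
    p = np.full(F, 1.0 / F)
    lower = 0.0
    upper = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        q = p @ P
        with np.errstate(divide="ignore"):
            logq = np.where(q > 0, np.log2(np.where(q > 0, q, 1.0)), 0.0)
        # D_f = sum_g p(g|f) log2 p(g|f)/p(g); bins where p(g|f)=0 contribute 0
        D = (np.where(P > 0, P * (logP - logq[None, :]), 0.0)).sum(axis=1)
        lower = float(p @ D)
        upper = float(D.max())
        if upper - lower < tol:
            return CapacityResult(capacity=max(lower, 0.0), p_star=p, iterations=it,
                                  gap=upper - lower, converged=True)
        w = p * np.exp2(D - D.max())
        p = w / w.sum()
    return CapacityResult(capacity=max(lower, 0.0), p_star=p, iterations=it,
                          gap=upper - lower, converged=False)


def marginalize_channel(ch: DiscreteChannel, index: int) -> DiscreteChannel:
    """Channel of a single readout: sum each p(g|f) over all other dimensions."""
    if not 0 <= index < ch.ndim:
        raise ValueError(f"readout index {index} out of range for {ch.ndim} dimensions")
    if ch.ndim == 1:
        return ch
    axes = tuple(1 + ax for ax in range(ch.ndim) if ax != index)
    rows = ch.P.reshape((ch.n_states,) + ch.shape).sum(axis=axes)
    return DiscreteChannel(states=ch.states, P=rows,
                           shape=(ch.shape[index],), grid=None)


def shuffle_channel(ch: DiscreteChannel) -> DiscreteChannel:
    """Surrogate channel with within-condition correlations removed.

    Per condition f the joint p(g|f) is replaced by the product of its own
    per-readout marginals.  This preserves every marginal response
    distribution but destroys "noise" correlations, i.e. trial-to-trial
    co-variation of the readouts at fixed environmental state.
    """
    if ch.ndim < 2:
        raise ValueError("shuffle requires at least two readout dimensions")
    F = ch.n_states
    joint = ch.P.reshape((F,) + ch.shape)
    out = np.empty_like(ch.P)
    for f in range(F):
        prod = np.ones(())
        for ax in range(ch.ndim):
            other = tuple(a for a in range(ch.ndim) if a != ax)
            marg = joint[f].sum(axis=other)
            # outer product accumulated axis by axis
            prod = np.multiply.outer(prod, marg)
        out[f] = prod.reshape(-1)
    return DiscreteChannel(states=ch.states, P=out, shape=ch.shape, grid=ch.grid)


def decompose(ch: DiscreteChannel, tol: float = 1e-8,
              max_iter: int = 100_000) -> InfoDecomposition:
    """Full information breakdown of a multi-readout channel.

    The joint information is the channel capacity; its optimal input p* is
    then reused to evaluate each readout's marginal information and the
    shuffle information, so all terms refer to the same input statistics.
    """
    if ch.ndim < 2:
        raise ValueError("decomposition requires at least two readout dimensions")
    cap = channel_capacity(ch, tol=tol, max_iter=max_iter)
    p_star = cap.p_star
    I_joint = cap.capacity
    I_marginal = tuple(
        mutual_information(marginalize_channel(ch, i), p_star)
        for i in range(ch.ndim)
    )
    I_shuffle = mutual_information(shuffle_channel(ch), p_star)
    redundancy = sum(I_marginal) - I_joint
    noise_corr = I_joint - I_shuffle
    signal_corr = I_shuffle - sum(I_marginal)
    return InfoDecomposition(I_joint=I_joint, I_marginal=I_marginal,
                             redundancy=redundancy, I_shuffle=I_shuffle,
                             signal_corr=signal_corr, noise_corr=noise_corr,
                             p_star=p_star)
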