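"""Synthetic worm populations and image fixtures with known coding structure.

Every downstream stage of the pipeline (density estimation, capacity,
decomposition, bias correction) is validated against data whose true
information content is computable.  A :class:`CodingConfig` specifies, per
environmental state, the location and covariance of the (log-)expression
distribution of each readout neuron; :func:`simulate_expression` draws worm
populations from it and :func:`oracle_mi` computes the true mutual
information by Monte-Carlo integration of the exact densities.

The default configuration mirrors a broad-range dietary-restriction design:
six bacterial food levels spanning ad libitum to complete deprivation, and
three neuronal readouts (a *daf-7* reporter in ASI, non-monotonic in food;
*tph-1* reporters in ADF and NSM, graded in food) with log-normal
expression noise and weak positive inter-neuron correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from wormcode.fed import WormRecord
from wormcode.quantify import ImageStack

__all__ = [
    "CodingConfig", "simulate_expression", "oracle_mi", "make_image_fixture",
    "default_coding_config", "redundant_config", "synergistic_config",
    "uninformative_config", "FOOD_LEVELS",
]

#: Bacterial food concentrations (cells/mL) of the broad-range DR design.
FOOD_LEVELS = ("1.12e10", "2.0e9", "6.3e8", "6.3e7", "2.0e7", "0")


@dataclass(frozen=True)
class CodingConfig:
    """Ground-truth population model: per-state response location/scale/correlation.

    For the ``"lognormal"`` family (default) ``means`` and ``covs`` are the
    mean vectors and covariances of log-expression; for ``"normal"`` they
    parameterize linear-scale expression directly (negative draws are
    resampled, so means should sit several SDs above zero for the analytic
    oracle to apply).
    """

    states: tuple
    means: np.ndarray            # F x D
    covs: np.ndarray             # F x D x D
    n_per_state: int = 500
    family: str = "lognormal"
    readouts: tuple = ("ASI", "ADF", "NSM")
    genotype: str = "N2"
    seed: int = 0

    def __post_init__(self):
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        F, D = means.shape
        covs = np.asarray(self.covs, dtype=float)
        if covs.ndim == 2:
            covs = np.broadcast_to(covs, (F, D, D)).copy()
        if covs.shape != (F, D, D):
            raise ValueError(f"covs must be ({F},{D},{D}) or ({D},{D})")
        for f in range(F):
            if not np.allclose(covs[f], covs[f].T):
                raise ValueError(f"covariance for state {self.states[f]!r} not symmetric")
            if np.linalg.eigvalsh(covs[f]).min() <= 0:
                raise ValueError(f"covariance for state {self.states[f]!r} not "
                                 "positive-definite")
        if len(self.states) != F:
            raise ValueError("one mean vector per state required")
        if len(self.readouts) != D:
            raise ValueError("one readout name per dimension required")
        if self.n_per_state < 1:
            raise ValueError("n_per_state must be >= 1")
        if F < 2:
            raise ValueError("need at least 2 environmental states")
        if self.family not in ("lognormal", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        object.__setattr__(self, "readouts", tuple(self.readouts))
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covs", covs)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def dims(self) -> int:
        return self.means.shape[1]


def simulate_expression(cfg: CodingConfig, seed: int | None = None) -> list[WormRecord]:
    """Draw ``n_per_state`` worms per condition from the configured model.

    Deterministic for a given seed (``cfg.seed`` unless overridden).  For the
    normal family, draws with any non-positive component are resampled, since
    fluorescence readouts entering joint-density estimation must be positive.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    records: list[WormRecord] = []
    for f, state in enumerate(cfg.states):
        n = cfg.n_per_state
        if cfg.family == "lognormal":
            draws = np.exp(rng.multivariate_normal(cfg.means[f], cfg.covs[f], size=n))
        else:
            draws = rng.multivariate_normal(cfg.means[f], cfg.covs[f], size=n)
            for _ in range(1000):
                bad = np.any(draws <= 0, axis=1)
                if not bad.any():
                    break
                draws[bad] = rng.multivariate_normal(cfg.means[f], cfg.covs[f],
                                                     size=int(bad.sum()))
            else:
                raise ValueError("could not draw positive samples; means too close to 0")
        for i in range(n):
            records.append(WormRecord(batch="sim", worm=f"{state}_{i:04d}",
                                      genotype=cfg.genotype, condition=state,
                                      g=tuple(draws[i])))
    return records


def oracle_mi(cfg: CodingConfig, p_in=None, n_mc: int = 50_000,
              seed: int = 0) -> tuple[float, float]:
    """Ground-truth mutual information I(g; f) in bits, by Monte-Carlo integration.

    I = E[ log2 p(g|f) - log2 sum_f' p_in(f') p(g|f') ] over (f, g) ~ p_in x
    p(g|f).  For the log-normal family the computation runs in log-expression
    space, where the Jacobian of the transform cancels between numerator and
    denominator, so the estimate is exact up to Monte-Carlo error.  Returns
    ``(mi_bits, standard_error_bits)``.
    """
    import warnings
    if n_mc < 1000:
        warnings.warn("n_mc < 1000: Monte-Carlo error will be large", stacklevel=2)
    F = cfg.n_states
    p = np.full(F, 1.0 / F) if p_in is None else np.asarray(p_in, dtype=float)
    if p.shape != (F,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p_in must be a distribution over the config's states")
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    # sampling and density evaluation both happen in (log-)response space
    states = rng.choice(F, size=n_mc, p=p)
    z = np.empty((n_mc, cfg.dims))
    for f in range(F):
        mask = states == f
        if mask.any():
            z[mask] = rng.multivariate_normal(cfg.means[f], cfg.covs[f],
                                              size=int(mask.sum()))
    logpdf = np.empty((F, n_mc))
    for f in range(F):
        logpdf[f] = multivariate_normal(cfg.means[f], cfg.covs[f]).logpdf(z)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    mix = logsumexp(logpdf + logp[:, None], axis=0)
    info = (logpdf[states, np.arange(n_mc)] - mix) / np.log(2.0)
    return float(info.mean()), float(info.std(ddof=1) / np.sqrt(n_mc))


def make_image_fixture(amplitude: float, sigma: float, center: tuple,
                       background: float, shape: tuple = (20, 40, 40),
                       seed: int = 0, poisson: bool = True
                       ) -> tuple[ImageStack, float]:
    """Gaussian spot on constant background with optional Poisson noise.

    Returns the stack and the ground-truth integrated spot intensity (the sum
    of the noise-free spot voxels, background excluded).
    """
    if sigma <= 0:
        raise ValueError("spot sigma must be positive")
    if not all(0 <= c < s for c, s in zip(center, shape)):
        raise ValueError(f"spot center {center} outside stack shape {shape}")
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2)
    spot = amplitude * np.exp(-0.5 * r2 / sigma ** 2)
    true_sum = float(spot.sum())
    clean = spot + background
    if poisson:
        rng = np.random.default_rng(seed)
        voxels = rng.poisson(clean).astype(float)
    else:
        voxels = clean
    return ImageStack(voxels=voxels), true_sum


def _cov(sds, rho: float) -> np.ndarray:
    sds = np.asarray(sds, dtype=float)
    D = len(sds)
    C = np.full((D, D), rho) + (1 - rho) * np.eye(D)
    return C * np.outer(sds, sds)


def default_coding_config(n_per_state: int = 500, seed: int = 0) -> CodingConfig:
    """Six food levels, three readouts, log-normal noise.

    Log-mean profiles (natural log of arbitrary fluorescence units): the ASI
    readout peaks at intermediate food (non-monotonic, as transcriptional
    *daf-7* reporters do), ADF decreases monotonically from ad libitum to
    starvation, NSM responds weakly.  Log-SDs 0.30-0.35 give the ~30-40%
    coefficient of variation typical of single-copy reporter lines, with
    inter-neuron correlation 0.25 from shared worm-level factors.
    """
    means = np.array([
        # ASI    ADF    NSM        (food level, high -> zero)
        [7.2, 7.8, 7.20],
        [7.6, 7.6, 7.15],
        [7.8, 7.3, 7.05],
        [7.5, 7.0, 6.95],
        [7.0, 6.8, 6.90],
        [6.5, 6.6, 6.85],
    ])
    cov = _cov([0.35, 0.35, 0.30], 0.25)
    return CodingConfig(states=FOOD_LEVELS, means=means, covs=cov,
                        n_per_state=n_per_state, family="lognormal", seed=seed)


def redundant_config(n_per_state: int = 300, seed: int = 0) -> CodingConfig:
    """Two readouts tracking the same food gradient: a redundant code.

    Both neurons' log-means rise together across four states, so each
    readout alone carries most of the joint information and the marginal
    informations double-count it (redundancy > 0).
    """
    m = np.array([6.5, 7.0, 7.5, 8.0])
    means = np.stack([m, m], axis=1)
    cov = _cov([0.35, 0.35], 0.3)
    return CodingConfig(states=("f1", "f2", "f3", "f4"), means=means, covs=cov,
                        n_per_state=n_per_state, family="lognormal",
                        readouts=("ASI", "ADF"), seed=seed)


def synergistic_config(n_per_state: int = 300, seed: int = 0) -> CodingConfig:
    """Two states coded purely in the correlation between readouts: a synergistic code.

    Both states share identical marginal distributions for each neuron, but
    the inter-neuron correlation is +0.85 in one state and -0.85 in the
    other.  Neither readout alone is informative (I_N ~ 0) while the joint
    response is, so redundancy is negative.
    """
    means = np.array([[7.0, 7.0], [7.0, 7.0]])
    covs = np.stack([_cov([0.4, 0.4], 0.85), _cov([0.4, 0.4], -0.85)])
    return CodingConfig(states=("corr+", "corr-"), means=means, covs=covs,
                        n_per_state=n_per_state, family="lognormal",
                        readouts=("ASI", "ADF"), seed=seed)


def uninformative_config(n_per_state: int = 200, n_states: int = 4,
                         seed: int = 0) -> CodingConfig:
    """Identical response distribution in every state: true information is 0 bits."""
    means = np.tile([7.0, 7.0], (n_states, 1))
    cov = _cov([0.35, 0.35], 0.25)
    return CodingConfig(states=tuple(f"s{i}" for i in range(n_states)),
                        means=means, covs=cov, n_per_state=n_per_state,
                        family="lognormal", readouts=("ASI", "ADF"), seed=seed)
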