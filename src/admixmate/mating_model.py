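"""Ancestry-related mating model.

Mating probabilities between males and females of a three-way admixed
population are controlled by per-ancestry assortative-mating (AM) and
sex-bias (SB) parameters. The difference in ancestry proportions within a
couple is scored under a multivariate normal kernel whose mean encodes SB
and whose (co)variances encode AM.

Sign convention
---------------
The difference vector is ``d = a_male - a_female`` throughout, so a
*positive* SB for ancestry ``s`` means couples in which the male carries
more of ancestry ``s`` than the female are favoured.

Because ancestry proportions sum to one, the three differences sum to zero
and the kernel lives in two dimensions: ``mu = (SB1, SB2)`` and a 2x2
covariance whose off-diagonal term is fixed by the third ancestry's
variance, ``Cov12 = (sigma3^2 - sigma1^2 - sigma2^2) / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "N_ANCESTRIES",
    "AncestryVector",
    "MatingParams",
    "GaussianMatingKernel",
    "PriorConfig",
    "KernelInfeasibleError",
    "am_to_variance",
    "variance_to_am",
    "build_kernel",
    "couple_density",
    "conditional_mate_probs",
    "couple_probability",
    "sample_mating_params",
]

#: Number of source ancestries (1 = sub-Saharan African, 2 = Native
#: American, 3 = European). Only the three-ancestry model is implemented.
N_ANCESTRIES = 3

#: Variance bounds implied by AM in [0, 1]: sigma^2 = 3**(3 - 7*am).
_VAR_MAX = 27.0
_VAR_MIN = 3.0 ** -4

#: Margin below which the 2x2 kernel covariance is treated as singular.
_PSD_MARGIN = 1e-10


class KernelInfeasibleError(ValueError):
    """The AM triple implies a non-positive-definite mating covariance."""

    def __init__(self, am: Sequence[float], message: str | None = None):
        self.am = tuple(float(a) for a in am)
        super().__init__(
            message
            or f"AM triple {self.am} implies a non-positive-definite covariance"
        )


@dataclass(frozen=True)
class AncestryVector:
    """Genome-wide ancestry proportions of one individual.

    Components are non-negative fractions over the three ancestries and
    must sum to one.
    """

    proportions: tuple[float, float, float]

    def __post_init__(self):
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (N_ANCESTRIES,):
            raise ValueError(f"expected {N_ANCESTRIES} proportions, got {p.shape}")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError(f"proportions must lie in [0, 1]: {p}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "proportions", tuple(float(x) for x in p))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.proportions, dtype=float)


@dataclass(frozen=True)
class MatingParams:
    """The AM/SB (and optional GFR) parameter vector of one scenario.

    ``sb`` holds all three sex-bias values; they must sum to zero
    (``SB3 = -SB1 - SB2``). ``gfr`` is only meaningful under the
    two-pulses migration model.
    """

    am: tuple[float, float, float]
    sb: tuple[float, float, float]
    gfr: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        am = np.asarray(self.am, dtype=float)
        sb = np.asarray(self.sb, dtype=float)
        if am.shape != (3,) or sb.shape != (3,):
            raise ValueError("am and sb must each have 3 components")
        if np.any(am < 0) or np.any(am > 1):
            raise ValueError(f"AM values must lie in [0, 1]: {am}")
        if abs(sb.sum()) > 1e-9:
            raise ValueError(f"SB values must sum to 0, got {sb.sum()!r}")
        object.__setattr__(self, "am", tuple(float(x) for x in am))
        object.__setattr__(self, "sb", tuple(float(x) for x in sb))
        if self.gfr is not None:
            g = np.asarray(self.gfr, dtype=float)
            if g.shape != (3,):
                raise ValueError("gfr must have 3 components")
            if np.any(g < 0) or np.any(g > 1):
                raise ValueError(f"GFR values must lie in [0, 1]: {g}")
            object.__setattr__(self, "gfr", tuple(float(x) for x in g))

    @classmethod
    def from_sb12(cls, am, sb1, sb2, gfr=None) -> "MatingParams":
        """Build from the five (or eight) free parameters, deriving SB3."""
        return cls(tuple(am), (sb1, sb2, -sb1 - sb2), None if gfr is None else tuple(gfr))

    def to_dict(self) -> dict:
        d = {f"am{i + 1}": self.am[i] for i in range(3)}
        d.update({f"sb{i + 1}": self.sb[i] for i in range(3)})
        if self.gfr is not None:
            d.update({f"gfr{i + 1}": self.gfr[i] for i in range(3)})
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "MatingParams":
        am = tuple(float(d[f"am{i}"]) for i in (1, 2, 3))
        sb = tuple(float(d[f"sb{i}"]) for i in (1, 2, 3))
        gfr = None
        if "gfr1" in d:
            gfr = tuple(float(d[f"gfr{i}"]) for i in (1, 2, 3))
        return cls(am, sb, gfr)


@dataclass(frozen=True)
class GaussianMatingKernel:
    """Two-dimensional normal kernel on the couple ancestry differences."""

    mu: np.ndarray
    sigma: np.ndarray
    # Cached quantities for fast vectorised density evaluation.
    _sigma_inv: np.ndarray = field(repr=False, default=None)
    _log_norm: float = field(repr=False, default=0.0)

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        if not np.allclose(sigma, sigma.T, atol=1e-12):
            raise ValueError("sigma must be symmetric")
        det = float(np.linalg.det(sigma))
        if det <= _PSD_MARGIN or sigma[0, 0] <= 0 or sigma[1, 1] <= 0:
            raise ValueError("sigma must be strictly positive definite")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "_sigma_inv", np.linalg.inv(sigma))
        object.__setattr__(self, "_log_norm", -math.log(2.0 * math.pi) - 0.5 * math.log(det))

    @property
    def implied_var3(self) -> float:
        """Variance of the third difference ``d3 = -d1 - d2`` under the kernel."""
        s = self.sigma
        return float(s[0, 0] + s[1, 1] + 2.0 * s[0, 1])

    def log_density(self, d: np.ndarray) -> np.ndarray:
        """Log density at difference vectors ``d`` (shape (..., 2))."""
        d = np.asarray(d, dtype=float)
        z = d - self.mu
        q = np.einsum("...i,ij,...j->...", z, self._sigma_inv, z)
        return self._log_norm - 0.5 * q

    def density(self, d: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(d))


@dataclass(frozen=True)
class PriorConfig:
    """Uniform prior ranges for the mating parameters.

    SB bounds default to ``(-1, 1)``: the natural range given that both
    ancestry proportions lie in [0, 1], and wide enough to cover every
    reported estimate.
    """

    am_range: tuple[float, float] = (0.0, 1.0)
    sb_range: tuple[float, float] = (-1.0, 1.0)
    gfr_range: tuple[float, float] = (0.0, 1.0)
    reject_non_psd: bool = True

    def __post_init__(self):
        for name, (lo, hi) in (
            ("am_range", self.am_range),
            ("sb_range", self.sb_range),
            ("gfr_range", self.gfr_range),
        ):
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if not (0.0 <= self.am_range[0] and self.am_range[1] <= 1.0):
            raise ValueError("am_range must be contained in [0, 1]")
        if not (0.0 <= self.gfr_range[0] and self.gfr_range[1] <= 1.0):
            raise ValueError("gfr_range must be contained in [0, 1]")


def am_to_variance(am: float) -> float:
    """Map an AM value in [0, 1] to a difference variance.

    ``sigma^2 = 3**(3 - 7*am)``: AM=0 (random mating) gives 27, AM=1
    (very strong assortment) gives 1/81; strictly decreasing.
    """
    am = float(am)
    if not 0.0 <= am <= 1.0:
        raise ValueError(f"AM must lie in [0, 1], got {am}")
    return 3.0 ** (3.0 - 7.0 * am)


def variance_to_am(variance: float) -> float:
    """Exact inverse of :func:`am_to_variance` on [3**-4, 27]."""
    v = float(variance)
    if not _VAR_MIN - 1e-15 <= v <= _VAR_MAX + 1e-12:
        raise ValueError(f"variance must lie in [{_VAR_MIN}, {_VAR_MAX}], got {v}")
    return (3.0 - math.log(v) / math.log(3.0)) / 7.0


def build_kernel(params: MatingParams) -> GaussianMatingKernel:
    """Construct the 2-D mating kernel from AM and SB parameters.

    Raises :class:`KernelInfeasibleError` when the implied covariance is
    not positive definite (e.g. AM = (1, 1, 0)).
    """
    v1, v2, v3 = (am_to_variance(a) for a in params.am)
    cov12 = (v3 - v1 - v2) / 2.0
    det = v1 * v2 - cov12 * cov12
    if det <= _PSD_MARGIN:
        raise KernelInfeasibleError(params.am)
    sigma = np.array([[v1, cov12], [cov12, v2]])
    mu = np.array([params.sb[0], params.sb[1]])
    return GaussianMatingKernel(mu=mu, sigma=sigma)


def _diff(a_f: AncestryVector, a_m: AncestryVector) -> np.ndarray:
    """Couple difference d = a_male - a_female, first two components."""
    return a_m.as_array()[:2] - a_f.as_array()[:2]


def couple_density(kernel: GaussianMatingKernel, a_f: AncestryVector, a_m: AncestryVector) -> float:
    """Unnormalised mating affinity of one couple under the kernel."""
    return float(kernel.density(_diff(a_f, a_m)))


def conditional_mate_probs(
    kernel: GaussianMatingKernel,
    initiator: AncestryVector,
    candidates: Sequence[AncestryVector],
    initiator_sex: str,
) -> np.ndarray:
    """Probability of each candidate being chosen by the initiator.

    ``initiator_sex`` is ``"F"`` (candidates are males) or ``"M"``
    (candidates are females); densities are renormalised over the
    candidate list.
    """
    if len(candidates) == 0:
        raise ValueError("candidate list must not be empty")
    if initiator_sex not in ("F", "M"):
        raise ValueError("initiator_sex must be 'F' or 'M'")
    cand = np.stack([c.as_array()[:2] for c in candidates])
    init = initiator.as_array()[:2]
    if initiator_sex == "F":
        d = cand - init  # males - female
    else:
        d = init - cand  # male - females
    logw = kernel.log_density(d)
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def couple_probability(
    kernel: GaussianMatingKernel,
    f_index: int,
    m_index: int,
    females: Sequence[AncestryVector],
    males: Sequence[AncestryVector],
) -> float:
    """Marginal probability that couple (f, m) produces the next mating event.

    Either sex initiates with probability 1/2; the initiator is uniform
    within its sex and the partner is drawn from the kernel-weighted
    conditional over the opposite sex. Summed over all F x M couples this
    is a probability distribution.
    """
    if len(females) == 0 or len(males) == 0:
        raise ValueError("both sex classes must be non-empty")
    p_f = conditional_mate_probs(kernel, females[f_index], males, "F")[m_index]
    p_m = conditional_mate_probs(kernel, males[m_index], females, "M")[f_index]
    return 0.5 * p_f / len(females) + 0.5 * p_m / len(males)


def sample_mating_params(
    prior: PriorConfig,
    rng: np.random.Generator,
    with_gfr: bool = False,
    max_rejections: int = 10_000,
) -> MatingParams:
    """Draw one parameter set from independent uniform priors.

    With ``reject_non_psd`` (the default), AM triples whose kernel
    covariance is not positive definite are resampled; the model is left
    exactly as stated for all accepted draws.
    """
    for _ in range(max_rejections):
        am = rng.uniform(*prior.am_range, size=3)
        sb1, sb2 = rng.uniform(*prior.sb_range, size=2)
        gfr = tuple(rng.uniform(*prior.gfr_range, size=3)) if with_gfr else None
        params = MatingParams.from_sb12(am, sb1, sb2, gfr)
        if not prior.reject_non_psd:
            return params
        try:
            build_kernel(params)
        except KernelInfeasibleError:
            continue
        return params
    raise RuntimeError(
        f"prior rejected {max_rejections} consecutive draws; widen am_range"
    )
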