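"""Model builders and randomized parameter samplers.

Covers every randomization scheme used in the standard analyses: uniform
growth-rate draws, growth effects drawn from U(-alpha, alpha), heterogeneous
competition matrices, random niche structures and strong-selection
communities, plus the printed worked-example parameterizations packaged as
``demo_*`` fixture functions (the single source of truth for those
constants — tests import them rather than re-typing values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import CommunityModel

__all__ = [
    "SamplerSpec",
    "sample_model",
    "two_species",
    "multispecies_from_mu",
    "demo_two_species_P",
    "demo_two_species_Q",
    "demo_five_species",
    "demo_selection",
    "FIXTURES",
]

SAMPLER_SCHEMA = "mgecomm/sampler-v1"


def _lam_from_mu(mu: np.ndarray, mu0: np.ndarray) -> np.ndarray:
    """Host-independent growth-effect matrix from full rates.

    lam_jj = mu_j/mu0_j - 1 and lam_ij = lam_jj (the element carries the
    same effect into any host).
    """
    lam_diag = np.asarray(mu, float) / np.asarray(mu0, float) - 1.0
    m = len(lam_diag)
    return np.tile(lam_diag, (m, 1))


def two_species(
    mu1: float,
    mu2: float,
    *,
    eta: float = 0.0,
    gamma=1.1,
    kappa: float = 0.005,
    D: float = 0.2,
    mu0: float = 0.5,
    variant: str = "two_species_hgt",
    delta=None,
    xi: Optional[tuple] = None,
) -> CommunityModel:
    """Two competing species exchanging plasmids.

    ``mu1, mu2`` are the full growth rates; growth effects are derived as
    lam_ii = mu_i/mu0 - 1.  ``xi = (xi1, xi2)`` switches to the epistasis
    variant with lam_21 = xi1*lam_11 and lam_12 = xi2*lam_22; ``delta``
    switches to the interaction-modification variant.
    """
    mu = np.array([mu1, mu2], float)
    mu0v = np.full(2, mu0)
    lam = _lam_from_mu(mu, mu0v)
    if xi is not None:
        xi1, xi2 = xi
        lam[1, 0] = xi1 * lam[0, 0]
        lam[0, 1] = xi2 * lam[1, 1]
        variant = "epistasis"
    if delta is not None:
        variant = "interaction_mod"
    return CommunityModel(
        variant=variant, m=2, mu0=mu0v, lam=lam, gamma=gamma, eta=eta, kappa=kappa, D=D, delta=delta
    )


def multispecies_from_mu(
    mu,
    *,
    eta: float = 0.0,
    gamma=1.05,
    kappa: float = 0.005,
    D: float = 0.2,
    mu0: float = 0.5,
    variant: str = "multispecies",
    **extra,
) -> CommunityModel:
    """m-species community with host-independent growth effects."""
    mu = np.asarray(mu, float)
    m = len(mu)
    mu0v = np.full(m, mu0)
    return CommunityModel(
        variant=variant,
        m=m,
        mu0=mu0v,
        lam=_lam_from_mu(mu, mu0v),
        gamma=gamma,
        eta=eta,
        kappa=kappa,
        D=D,
        **extra,
    )


# ----------------------------------------------------------------------
# Worked-example parameterizations
# ----------------------------------------------------------------------


def demo_two_species_P(eta: float = 0.0) -> CommunityModel:
    """Two species with a large growth-rate gap (mu = 0.3, 0.8 hr^-1).

    gamma = 1.1, kappa = 0.005, D = 0.2, mu0 = 0.5.  Monostable at any
    moderate transfer rate: the fast grower always wins.
    """
    return two_species(0.3, 0.8, eta=eta)


def demo_two_species_Q(eta: float = 0.0) -> CommunityModel:
    """Two species with a small growth-rate gap (mu = 0.4, 0.6 hr^-1).

    gamma = 1.1, kappa = 0.005, D = 0.2, mu0 = 0.5.  Monostable without
    HGT; bistable once the transfer rate is high enough (e.g. 0.2 hr^-1).
    """
    return two_species(0.4, 0.6, eta=eta)


def demo_five_species(eta: float = 0.0) -> CommunityModel:
    """Five-species community with near-neutral growth differences.

    mu = (0.52, 0.48, 0.44, 0.60, 0.31) hr^-1, mu0 = 0.5, gamma = 1.05,
    kappa = 0.005, D = 0.2.  Monostable without HGT; four attractors at
    eta = 0.4 hr^-1.
    """
    return multispecies_from_mu([0.52, 0.48, 0.44, 0.60, 0.31], eta=eta, gamma=1.05)


def demo_selection(m: int = 5, eta: float = 0.0, mu=None) -> CommunityModel:
    """Community under strong selection: only MGE carriers grow.

    Species 0 is the donor.  For m = 2 the competition strength is 1.1
    (phase-diagram setting); for larger communities 1.5, with growth rates
    spread over [0.3, 0.7] hr^-1 unless given.
    """
    if mu is None:
        mu = np.linspace(0.3, 0.7, m) if m > 1 else np.array([0.5])
    gamma = 1.1 if m == 2 else 1.5
    mu = np.asarray(mu, float)
    return CommunityModel(
        variant="selection",
        m=m,
        mu0=mu,
        lam=np.zeros((m, m)),
        gamma=gamma,
        eta=eta,
        kappa=0.005,
        D=0.2,
        donor_index=0,
    )


FIXTURES = {
    "two_species_P": demo_two_species_P,
    "two_species_Q": demo_two_species_Q,
    "five_species": demo_five_species,
    "selection": demo_selection,
}


# ----------------------------------------------------------------------
# Randomized samplers
# ----------------------------------------------------------------------


@dataclass
class SamplerSpec:
    """Declarative description of one model-randomization scheme.

    growth scheme (one of):
      - ``{"kind": "fixed", "mu": [...]}``
      - ``{"kind": "uniform", "low": a, "high": b}`` — full rates mu_i
      - ``{"kind": "lambda_width", "alpha": a}`` — lam_ii ~ U(-a, a),
        mu_i = mu0 (1 + lam_ii)

    gamma scheme:
      - ``{"kind": "scalar", "value": g}``
      - ``{"kind": "uniform", "mean": g, "half_width": w}`` — iid entries

    Optional extensions: ``delta`` (interaction modification), ``xi``
    (epistasis ratios, m = 2), ``niche=True`` (random niche structure with
    l ~ U{2..m/2} niches and U(0,1] capacities), ``selection=True``
    (strong-selection variant, mu_i ~ U(0.3, 0.7), donor species 0).
    """

    m: int
    mu0: float = 0.5
    growth: dict = field(default_factory=lambda: {"kind": "uniform", "low": 0.0, "high": 1.0})
    gamma: dict = field(default_factory=lambda: {"kind": "scalar", "value": 1.1})
    eta: float = 0.0
    kappa: float = 0.005
    D: float = 0.2
    delta: Optional[float] = None
    xi: Optional[tuple] = None
    niche: bool = False
    selection: bool = False

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        kind = self.growth.get("kind")
        if kind not in ("fixed", "uniform", "lambda_width"):
            raise ValueError(f"unknown growth scheme {kind!r}")
        if kind == "lambda_width" and not (0 <= self.growth["alpha"] < 1):
            raise ValueError("lambda width alpha must lie in [0, 1) so that 1 + lam > 0")
        gkind = self.gamma.get("kind")
        if gkind not in ("scalar", "uniform"):
            raise ValueError(f"unknown gamma scheme {gkind!r}")
        if self.niche and self.m < 4:
            raise ValueError("niche randomization requires m >= 4 (at least 2 niches)")
        if self.xi is not None and self.m != 2:
            raise ValueError("epistasis ratios are defined for m = 2")

    def to_dict(self) -> dict:
        d = {
            "schema": SAMPLER_SCHEMA,
            "m": self.m,
            "mu0": self.mu0,
            "growth": dict(self.growth),
            "gamma": dict(self.gamma),
            "eta": self.eta,
            "kappa": self.kappa,
            "D": self.D,
            "niche": self.niche,
            "selection": self.selection,
        }
        if self.delta is not None:
            d["delta"] = self.delta
        if self.xi is not None:
            d["xi"] = list(self.xi)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SamplerSpec":
        d = dict(d)
        schema = d.pop("schema", None)
        if schema != SAMPLER_SCHEMA:
            raise ValueError(f"unsupported or missing sampler schema: {schema!r}")
        if "xi" in d and d["xi"] is not None:
            d["xi"] = tuple(d["xi"])
        return cls(**d)


def _sample_mu(spec: SamplerSpec, rng) -> np.ndarray:
    g = spec.growth
    if g["kind"] == "fixed":
        mu = np.asarray(g["mu"], float)
        if len(mu) != spec.m:
            raise ValueError("fixed growth scheme length must equal m")
        return mu
    if g["kind"] == "uniform":
        return rng.uniform(g["low"], g["high"], size=spec.m)
    lam = rng.uniform(-g["alpha"], g["alpha"], size=spec.m)
    return spec.mu0 * (1.0 + lam)


def _sample_gamma(spec: SamplerSpec, rng):
    g = spec.gamma
    if g["kind"] == "scalar":
        return g["value"]
    low = g["mean"] - g["half_width"]
    high = g["mean"] + g["half_width"]
    if low < 0:
        raise ValueError("gamma uniform scheme would produce negative strengths")
    return rng.uniform(low, high, size=(spec.m, spec.m))


def sample_model(spec: SamplerSpec, rng) -> CommunityModel:
    """Draw one CommunityModel from a :class:`SamplerSpec`.

    Growth effects are host-independent (lam_ij = lam_jj) unless the spec
    carries epistasis ratios ``xi``.
    """
    spec.validate()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = spec.m
    gamma = _sample_gamma(spec, rng)
    if spec.selection:
        mu = rng.uniform(0.3, 0.7, size=m)
        return CommunityModel(
            variant="selection",
            m=m,
            mu0=mu,
            lam=np.zeros((m, m)),
            gamma=gamma,
            eta=spec.eta,
            kappa=spec.kappa,
            D=spec.D,
            donor_index=0,
        )
    mu = _sample_mu(spec, rng)
    mu0 = np.full(m, spec.mu0)
    lam = _lam_from_mu(mu, mu0)
    variant = "multispecies" if m != 2 else "two_species_hgt"
    extra = {}
    if spec.xi is not None:
        xi1, xi2 = spec.xi
        lam[1, 0] = xi1 * lam[0, 0]
        lam[0, 1] = xi2 * lam[1, 1]
        variant = "epistasis"
    if spec.delta is not None:
        variant = "interaction_mod"
        extra["delta"] = spec.delta
    if spec.niche:
        n_niches = int(rng.integers(2, max(m // 2, 2) + 1))
        cap = rng.uniform(0.0, 1.0, size=n_niches)
        cap[cap == 0.0] = 0.5  # capacities must be positive
        niche_map = rng.integers(0, n_niches, size=m)
        variant = "niche"
        extra["niche_map"] = niche_map
        extra["niche_capacity"] = cap
    return CommunityModel(
        variant=variant,
        m=m,
        mu0=mu0,
        lam=lam,
        gamma=gamma,
        eta=spec.eta,
        kappa=spec.kappa,
        D=spec.D,
        **extra,
    )
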