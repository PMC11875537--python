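"""Community models of competing microbes exchanging mobile genetic elements.

The core object is :class:`CommunityModel`, a full parameterization of one
model variant.  All variants extend a Lotka-Volterra (LV) competition model
with dilution: species ``i`` grows logistically at an effective rate
``mu_i^e``, is inhibited by competitors through a matrix ``gamma`` and is
removed at a dilution/death rate ``D``.  Horizontal gene transfer (HGT)
creates carrier subpopulations ``p_ij`` (cells of species ``i`` carrying the
mobile genetic element, MGE, that originates in species ``j``); carriers are
gained by conjugative transfer at rate ``eta`` (mass-action) and lost by
segregation at rate ``kappa``.  Carriage multiplies the host growth rate by
``1 + lam_ij``, so

    mu_i^e = mu_i * prod_{j != i} (1 + lam_ij * p_ij / s_i)

with ``mu_i = mu0_i * (1 + lam_ii)`` the full-carriage rate of the native
element.  Abundances are dimensionless (scaled by carrying capacity).

Variants
--------
``classic_lv``
    No MGEs; plain LV competition with dilution.
``two_species_hgt``
    The two-species plasmid-exchange model (``m = 2``).
``multispecies``
    m species, every pair exchanging MGEs; ``lam_ij = lam_jj`` by default
    (the element's growth effect is host-independent).
``epistasis``
    Same equations with a host-dependent ``lam`` matrix (``lam_ij`` differs
    from ``lam_jj``); quantified by ratios ``xi_j = lam_ij / lam_jj``.
``interaction_mod``
    MGE carriage also modifies competition: the effective strength of
    species ``j`` on ``i`` is ``gamma_ji + delta_j * p_ji / s_j``.
``selection``
    Strong environmental selection: only carriers of a single MGE
    (initially held by ``donor_index``) can grow; ``p`` is a vector.
``niche``
    Species compete only within shared niches, each niche with its own
    carrying capacity.

All indices are 0-based.  ``gamma[i, j]`` is the competitive effect of
species ``i`` ON species ``j``; the competition term in species ``i``'s
equation is ``sum_j gamma[j, i] * s_j``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

__all__ = [
    "VARIANTS",
    "CommunityModel",
    "CommunityState",
    "LVFixedPoints",
    "effective_growth_rates",
    "rhs",
    "lv_fixed_points",
    "lv_bistable",
    "eta_from_empirical",
    "eta_to_empirical",
]

VARIANTS = (
    "classic_lv",
    "two_species_hgt",
    "multispecies",
    "interaction_mod",
    "epistasis",
    "selection",
    "niche",
)

#: variants whose carrier state is the full m-by-m matrix p_ij
GROWTH_VARIANTS = (
    "two_species_hgt",
    "multispecies",
    "interaction_mod",
    "epistasis",
    "niche",
)

MODEL_SCHEMA = "mgecomm/model-v1"


def _as_matrix(x, m: int) -> np.ndarray:
    """Broadcast a scalar to an (m, m) matrix, or validate a given matrix."""
    a = np.asarray(x, dtype=float)
    if a.ndim == 0:
        return np.full((m, m), float(a))
    if a.shape != (m, m):
        raise ValueError(f"expected scalar or ({m}, {m}) matrix, got shape {a.shape}")
    return a.copy()


@dataclass
class CommunityModel:
    """Parameters of one community model variant.

    Parameters
    ----------
    variant : str
        One of :data:`VARIANTS`.
    m : int
        Number of species.
    mu0 : array (m,)
        Basal (chromosomal) growth rates, hr^-1.
    lam : array (m, m)
        ``lam[i, j]`` is the growth-rate effect of the species-j-originated
        MGE in species i (dimensionless, > -1).
    gamma : scalar or array (m, m)
        ``gamma[i, j]`` = competition strength of species i on species j
        (diagonal unused).
    eta : scalar or array (m, m, m)
        Transfer rate, hr^-1.  ``eta[j, k, i]`` is the rate of the
        species-j-originated MGE from donor k to recipient i; a scalar means
        one uniform rate (equal intra-/inter-species transfer).
    kappa : scalar or array (m, m)
        Segregation-loss rate of MGE j in species i, hr^-1.
    D : float
        Dilution/death rate, hr^-1.
    delta : scalar or array (m,), optional
        Competition modification per unit carrier fraction
        (``interaction_mod`` only).
    niche_map : array (m,) of int, optional
        Niche index of each species, 0..l-1 (``niche`` only).
    niche_capacity : array (l,), optional
        Carrying capacity of each niche, in (0, 1] (``niche`` only).
    donor_index : int, optional
        Initial MGE carrier species (``selection`` only).
    rho : float
        Carrying-capacity ratio Nm2/Nm1 of the two-species model; 1 by
        default (equal capacities).
    """

    variant: str
    m: int
    mu0: np.ndarray
    lam: Union[float, np.ndarray] = 0.0
    gamma: Union[float, np.ndarray] = 1.0
    eta: Union[float, np.ndarray] = 0.0
    kappa: Union[float, np.ndarray] = 0.0
    D: float = 0.0
    delta: Optional[Union[float, np.ndarray]] = None
    niche_map: Optional[np.ndarray] = None
    niche_capacity: Optional[np.ndarray] = None
    donor_index: Optional[int] = None
    rho: float = 1.0

    def __post_init__(self):
        self.m = int(self.m)
        m = self.m
        self.mu0 = np.broadcast_to(np.asarray(self.mu0, float), (m,)).copy()
        self.lam = _as_matrix(self.lam, m)
        self.gamma = _as_matrix(self.gamma, m)
        self.kappa = _as_matrix(self.kappa, m)
        eta = np.asarray(self.eta, dtype=float)
        if eta.ndim == 0:
            self.eta = float(eta)
        elif eta.shape == (m, m, m):
            self.eta = eta.copy()
        elif self.variant == "selection" and eta.shape == (m, m):
            self.eta = eta.copy()
        else:
            raise ValueError(f"eta must be scalar or ({m},{m},{m}) tensor")
        self.D = float(self.D)
        if self.delta is not None:
            self.delta = np.broadcast_to(np.asarray(self.delta, float), (m,)).copy()
        if self.niche_map is not None:
            self.niche_map = np.asarray(self.niche_map, dtype=int).copy()
        if self.niche_capacity is not None:
            self.niche_capacity = np.asarray(self.niche_capacity, float).copy()
        self.validate()

    # ------------------------------------------------------------------
    @property
    def mu(self) -> np.ndarray:
        """Full per-capita growth rates mu_i = mu0_i * (1 + lam_ii), hr^-1."""
        return self.mu0 * (1.0 + np.diag(self.lam))

    def validate(self) -> None:
        m = self.m
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if m < 1:
            raise ValueError("m must be >= 1")
        if self.variant in ("classic_lv", "two_species_hgt") and m != 2:
            raise ValueError(f"variant {self.variant!r} requires m=2")
        if np.any(self.mu0 < 0):
            raise ValueError("basal growth rates must be >= 0")
        if np.any(1.0 + self.lam <= 0):
            raise ValueError("growth effects must satisfy 1 + lam > 0")
        if np.any(self.mu < 0):
            raise ValueError("mu = mu0*(1+lam_ii) must be >= 0")
        if np.any(self.gamma < 0):
            raise ValueError("competition strengths must be >= 0")
        if np.any(np.asarray(self.eta) < 0):
            raise ValueError("transfer rates must be >= 0")
        if np.any(self.kappa < 0):
            raise ValueError("loss rates must be >= 0")
        if self.D < 0 or self.rho <= 0:
            raise ValueError("D must be >= 0 and rho > 0")
        if self.variant == "interaction_mod" and self.delta is None:
            raise ValueError("interaction_mod requires delta")
        if self.variant == "selection":
            if self.donor_index is None or not (0 <= self.donor_index < m):
                raise ValueError("selection requires donor_index in 0..m-1")
        if self.variant == "niche":
            if self.niche_map is None or self.niche_capacity is None:
                raise ValueError("niche requires niche_map and niche_capacity")
            if self.niche_map.shape != (m,):
                raise ValueError("niche_map must have length m")
            n_niches = len(self.niche_capacity)
            if np.any(self.niche_map < 0) or np.any(self.niche_map >= n_niches):
                raise ValueError("niche_map values must be in 0..l-1")
            if np.any(self.niche_capacity <= 0) or np.any(self.niche_capacity > 1):
                raise ValueError("niche capacities must lie in (0, 1]")

    def with_eta(self, eta) -> "CommunityModel":
        """Copy of this model with a different transfer rate."""
        return replace(self, eta=eta)

    # -------------------------- serialization -------------------------
    def to_dict(self) -> dict:
        d = {
            "schema": MODEL_SCHEMA,
            "variant": self.variant,
            "m": self.m,
            "mu0": self.mu0.tolist(),
            "lam": self.lam.tolist(),
            "gamma": self.gamma.tolist(),
            "eta": self.eta if np.isscalar(self.eta) else np.asarray(self.eta).tolist(),
            "kappa": self.kappa.tolist(),
            "D": self.D,
            "rho": self.rho,
        }
        if self.delta is not None:
            d["delta"] = self.delta.tolist()
        if self.niche_map is not None:
            d["niche_map"] = self.niche_map.tolist()
        if self.niche_capacity is not None:
            d["niche_capacity"] = self.niche_capacity.tolist()
        if self.donor_index is not None:
            d["donor_index"] = self.donor_index
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityModel":
        d = dict(d)
        schema = d.pop("schema", None)
        if schema != MODEL_SCHEMA:
            raise ValueError(f"unsupported or missing model schema: {schema!r}")
        return cls(**d)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CommunityModel":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


@dataclass
class CommunityState:
    """Abundances at one instant: species ``s`` and carriers ``p``.

    ``p[i, j]`` is the abundance of cells of species i carrying the
    species-j-originated MGE; ``0 <= p[i, j] <= s[i]`` and the diagonal is
    defined as ``p[i, i] == s[i]`` (every cell carries its native element).
    For the ``selection`` variant only the column ``p[:, donor_index]`` is
    dynamic (a single MGE circulates).
    """

    s: np.ndarray
    p: np.ndarray = None

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float).copy()
        m = self.s.shape[0]
        if self.p is None:
            self.p = np.zeros((m, m))
            np.fill_diagonal(self.p, self.s)
        else:
            self.p = np.asarray(self.p, dtype=float).copy()
            if self.p.shape != (m, m):
                raise ValueError(f"p must be ({m}, {m})")

    @property
    def m(self) -> int:
        return self.s.shape[0]

    def copy(self) -> "CommunityState":
        return CommunityState(self.s.copy(), self.p.copy())

    def validate(self, atol: float = 1e-9) -> None:
        if np.any(self.s < -atol):
            raise ValueError("species abundances must be >= 0")
        if np.any(self.p < -atol) or np.any(self.p > self.s[:, None] + atol):
            raise ValueError("carriers must satisfy 0 <= p_ij <= s_i")


# ======================================================================
# Vectorized right-hand-side kernels
# ======================================================================


def _carrier_fraction(S: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Carrier fraction p_ij / s_i with the extinct-species convention 0/0 -> 0.

    S is (B, m), P is (B, m, m).  The fraction is clipped to [0, 1]: inside
    the physical domain (0 <= p <= s) the clip is inactive, and it extends
    the vector field smoothly over the small excursions an adaptive solver
    makes outside it (s < 0, or p transiently above s between clamps).
    """
    denom = S[:, :, None]
    out = np.zeros_like(P)
    np.divide(P, denom, out=out, where=denom > 0.0)
    np.clip(out, 0.0, 1.0, out=out)
    return out


class Kernel:
    """Precompiled, batch-vectorized RHS of one model.

    The ODE state of a batch of B independent communities is a (B, dim)
    array; :meth:`rhs` maps it to its time derivative.  Layouts:

    - ``classic_lv``: ``y = s`` (dim = m)
    - growth variants: ``y = [s, p_offdiag]`` (dim = m + m(m-1)); the
      diagonal p_ii == s_i is implicit.
    - ``selection``: ``y = [s, p]`` (dim = 2m), p the carrier vector.
    """

    def __init__(self, model: CommunityModel):
        self.model = model
        m = model.m
        self.m = m
        v = model.variant
        self.mu = model.mu.copy()
        self.D = model.D
        # competition matrix with zeroed diagonal (self-inhibition is the
        # explicit s_i term); niche variant masks cross-niche pairs and
        # rescales by per-niche capacity
        G = model.gamma.copy()
        np.fill_diagonal(G, 0.0)
        self.cap = np.ones(m)
        if v == "niche":
            same = model.niche_map[:, None] == model.niche_map[None, :]
            G = np.where(same, G, 0.0)
            self.cap = model.niche_capacity[model.niche_map].astype(float)
        self.Gmat = G
        self.lam_off = model.lam.copy()
        np.fill_diagonal(self.lam_off, 0.0)
        self.kappa = model.kappa
        self.eta = model.eta
        self.scalar_eta = np.isscalar(model.eta)
        self.delta = model.delta if v == "interaction_mod" else None
        # two-species dimensionless form with unequal carrying capacities:
        # the donor pool of the competitor plasmid is scaled by rho (or 1/rho)
        self.rho_scale = None
        if v == "two_species_hgt" and model.rho != 1.0:
            self.rho_scale = np.array([model.rho, 1.0 / model.rho])
        if v == "classic_lv":
            self.kind = "lv"
            self.dim = m
        elif v == "selection":
            self.kind = "selection"
            self.dim = 2 * m
            self.kappa_vec = np.diag(model.kappa).copy()
        else:
            self.kind = "growth"
            self.offdiag = np.where(~np.eye(m, dtype=bool))
            self.dim = m + m * (m - 1)

    # ------------------------------ layout -----------------------------
    def pack(self, states) -> np.ndarray:
        """Stack CommunityStates into a (B, dim) ODE state array."""
        states = list(states)
        B = len(states)
        Y = np.empty((B, self.dim))
        for b, st in enumerate(states):
            Y[b, : self.m] = st.s
            if self.kind == "growth":
                Y[b, self.m :] = st.p[self.offdiag]
            elif self.kind == "selection":
                Y[b, self.m :] = st.p[:, self.model.donor_index]
        return Y

    def unpack(self, Y: np.ndarray) -> list:
        """Inverse of :meth:`pack`."""
        Y = np.atleast_2d(Y)
        out = []
        for b in range(Y.shape[0]):
            s = Y[b, : self.m].copy()
            p = np.zeros((self.m, self.m))
            np.fill_diagonal(p, s)
            if self.kind == "growth":
                p[self.offdiag] = Y[b, self.m :]
            elif self.kind == "selection":
                p[:, self.model.donor_index] = Y[b, self.m :]
                np.fill_diagonal(p, s)
                j = self.model.donor_index
                p[j, j] = Y[b, self.m + j]
            out.append(CommunityState(s, p))
        return out

    def split(self, Y: np.ndarray):
        """View the batch array as (S, P) components."""
        m = self.m
        S = Y[:, :m]
        if self.kind == "lv":
            return S, None
        if self.kind == "selection":
            return S, Y[:, m:]
        B = Y.shape[0]
        P = np.empty((B, m, m))
        P[:, self.offdiag[0], self.offdiag[1]] = Y[:, m:]
        P[:, np.arange(m), np.arange(m)] = S
        return S, P

    def clamp(self, Y: np.ndarray) -> np.ndarray:
        """Project solver output onto the physical domain (in place).

        Abundances are floored at 0 and carriers at p_ij <= s_i; applied to
        solver output only, never inside the RHS, to keep the integrated
        vector field smooth.
        """
        m = self.m
        np.maximum(Y, 0.0, out=Y)
        if self.kind == "growth":
            S, _ = Y[:, :m], None
            Pflat = Y[:, m:]
            cap = S[:, self.offdiag[0]]
            np.minimum(Pflat, cap, out=Pflat)
        elif self.kind == "selection":
            np.minimum(Y[:, m:], Y[:, :m], out=Y[:, m:])
        return Y

    # ------------------------------- RHS -------------------------------
    def rhs(self, Y: np.ndarray) -> np.ndarray:
        Y = np.atleast_2d(Y)
        m = self.m
        S, P = self.split(Y)
        dY = np.empty_like(Y)
        if self.kind == "lv":
            growth = 1.0 - (S + S @ self.Gmat) / self.cap
            dY[:] = (self.mu * growth - self.D) * S
            return dY
        if self.kind == "selection":
            growth = 1.0 - (S + S @ self.Gmat) / self.cap
            g = self.mu * P * growth
            if self.scalar_eta:
                trans = self.eta * P.sum(axis=1, keepdims=True)
            else:
                eta2 = self.eta if self.eta.ndim == 2 else self.eta[self.model.donor_index]
                trans = P @ eta2
            dY[:, :m] = g - self.D * S
            dY[:, m:] = g + (S - P) * trans - (self.kappa_vec + self.D) * P
            return dY
        # growth variants
        r = _carrier_fraction(S, P)
        F = 1.0 + self.lam_off * r  # F[b,i,j]; diagonal == 1
        prod = F.prod(axis=2)  # prod_{j!=i} (1 + lam_ij p_ij/s_i)
        mue = self.mu * prod
        if self.delta is not None:
            # effective competition of j on i: gamma_ji + delta_j * p_ji/s_j
            r_off = r.copy()
            r_off[:, np.arange(m), np.arange(m)] = 0.0
            comp = S @ self.Gmat + np.einsum("bj,bji->bi", self.delta * S, r_off)
        else:
            comp = S @ self.Gmat
        growth = 1.0 - (S + comp) / self.cap
        dS = (mue * growth - self.D) * S
        # carrier growth coefficient: mu_i (1+lam_ij) prod_{k!=i,j}(1+lam_ik r_ik)
        coef = (self.mu[None, :, None] * prod[:, :, None] / F) * (1.0 + self.lam_off)
        dP = coef * P * growth[:, :, None]
        if self.scalar_eta:
            colsum = P.sum(axis=1)  # includes the donor pool p_jj = s_j
            trans = self.eta * colsum[:, None, :]
            if self.rho_scale is not None:
                # unequal carrying capacities rescale the competitor's own
                # pool seen by each recipient: (rho s2 + p1), (s1/rho + p2)
                trans = trans + self.eta * (self.rho_scale[None, :, None] - 1.0) * S[:, None, :]
        else:
            trans = np.einsum("jki,bkj->bij", self.eta, P)
        dP += (S[:, :, None] - P) * trans
        dP -= (self.D + self.kappa) * P
        dY[:, :m] = dS
        dY[:, m:] = dP[:, self.offdiag[0], self.offdiag[1]]
        return dY

    def rhs_flat(self, t: float, y: np.ndarray, B: int) -> np.ndarray:
        """solve_ivp-compatible RHS over a flattened batch."""
        return self.rhs(y.reshape(B, self.dim)).ravel()

    def residual(self, Y: np.ndarray) -> np.ndarray:
        """Per-member max-norm of the time derivative (hr^-1)."""
        return np.abs(self.rhs(np.atleast_2d(Y))).max(axis=1)


# ======================================================================
# Module-level operations
# ======================================================================


def effective_growth_rates(model: CommunityModel, state: CommunityState) -> np.ndarray:
    """Effective per-capita growth rates mu_i^e, hr^-1.

    For MGE growth-effect variants this is
    ``mu_i * prod_{j != i} (1 + lam_ij p_ij / s_i)`` with the convention
    that the carrier fraction of an extinct species (s_i = 0) is 0.  For
    ``classic_lv`` it is ``mu_i``; for ``selection`` it is the realized
    rate ``mu_i * p_i / s_i`` (only carriers grow).
    """
    S = state.s[None, :]
    if model.variant == "classic_lv":
        return model.mu.copy()
    if model.variant == "selection":
        p = state.p[:, model.donor_index][None, :]
        return (model.mu * _carrier_fraction(S, p[:, :, None])[0, :, 0]).copy()
    kern = Kernel(model)
    P = state.p[None, :, :].copy()
    P[:, np.arange(model.m), np.arange(model.m)] = S
    r = _carrier_fraction(S, P)
    F = 1.0 + kern.lam_off * r
    return (model.mu * F.prod(axis=2))[0]


def rhs(model: CommunityModel, state: CommunityState) -> CommunityState:
    """Time derivative of a single state, as a CommunityState-shaped object.

    The returned object's ``s`` and ``p`` hold ds/dt and dp/dt (its diagonal
    carries ds/dt, consistent with p_ii == s_i).
    """
    kern = Kernel(model)
    Y = kern.pack([state])
    dY = kern.rhs(Y)
    m = model.m
    ds = dY[0, :m]
    dp = np.zeros((m, m))
    np.fill_diagonal(dp, ds)
    if kern.kind == "growth":
        dp[kern.offdiag] = dY[0, m:]
    elif kern.kind == "selection":
        dp[:, model.donor_index] = dY[0, m:]
        j = model.donor_index
        dp[j, j] = dY[0, m + j]
    out = CommunityState.__new__(CommunityState)
    out.s = ds
    out.p = dp
    return out


@dataclass
class LVFixedPoints:
    """The four closed-form fixed points of the two-species LV model.

    ``points[k]`` is (s1*, s2*) for, in order: total extinction, species-2
    dominance, species-1 dominance, and coexistence; ``stability[k]`` is
    True iff all Jacobian eigenvalues at the point have negative real part.
    The coexistence point is None when gamma1*gamma2 == 1 (degenerate).
    """

    points: list
    stability: list
    eigenvalues: list = field(default_factory=list)


def _lv_jacobian(mu1, mu2, g1, g2, D, s1, s2) -> np.ndarray:
    # gamma1 = effect of species 1 on 2; gamma2 = effect of 2 on 1
    return np.array(
        [
            [mu1 * (1 - 2 * s1 - g2 * s2) - D, -mu1 * g2 * s1],
            [-mu2 * g1 * s2, mu2 * (1 - 2 * s2 - g1 * s1) - D],
        ]
    )


def lv_fixed_points(model: CommunityModel) -> LVFixedPoints:
    """Closed-form fixed points and Jacobian stability of the classic LV model.

    Requires ``variant='classic_lv'``.  ``gamma1`` is the strength of
    species 1 on species 2 (``gamma[0, 1]``) and vice versa.
    """
    if model.variant != "classic_lv":
        raise ValueError("lv_fixed_points requires the classic_lv variant")
    mu1, mu2 = model.mu
    g1 = model.gamma[0, 1]  # effect of species 1 on species 2
    g2 = model.gamma[1, 0]  # effect of species 2 on species 1
    D = model.D
    pts = [
        (0.0, 0.0),
        (0.0, 1.0 - D / mu2 if mu2 > 0 else 0.0),
        (1.0 - D / mu1 if mu1 > 0 else 0.0, 0.0),
    ]
    if g1 * g2 != 1.0 and mu1 > 0 and mu2 > 0:
        den = mu1 * mu2 * (g1 * g2 - 1.0)
        s1 = (g2 * mu1 * mu2 - D * g2 * mu1 - mu1 * mu2 + D * mu2) / den
        s2 = (g1 * mu1 * mu2 - D * g1 * mu2 - mu1 * mu2 + D * mu1) / den
        pts.append((s1, s2))
    else:
        pts.append(None)
    stability, eigs = [], []
    for pt in pts:
        if pt is None:
            stability.append(False)
            eigs.append(None)
            continue
        w = np.linalg.eigvals(_lv_jacobian(mu1, mu2, g1, g2, D, *pt))
        eigs.append(w)
        stability.append(bool(np.max(w.real) < 0.0))
    return LVFixedPoints(points=pts, stability=stability, eigenvalues=eigs)


def lv_bistable(model: CommunityModel) -> bool:
    """Analytic bistability condition of the two-species classic LV model.

    The two single-species states coexist as attractors iff
    ``gamma1 > phi2/phi1`` and ``gamma2 > phi1/phi2`` with
    ``phi_i = (mu_i - D)/mu_i``.  Returns False when either species is not
    viable (``mu_i <= D``).
    """
    if model.variant != "classic_lv":
        raise ValueError("lv_bistable requires the classic_lv variant")
    mu1, mu2 = model.mu
    D = model.D
    if mu1 <= D or mu2 <= D:
        return False
    phi1 = (mu1 - D) / mu1
    phi2 = (mu2 - D) / mu2
    g1 = model.gamma[0, 1]
    g2 = model.gamma[1, 0]
    return bool(g1 > phi2 / phi1 and g2 > phi1 / phi2)


def eta_from_empirical(eta_c: float, Nm: float) -> float:
    """Model transfer rate (hr^-1) from a per-cell conjugation efficiency.

    ``eta = Nm * eta_c`` where ``eta_c`` has units cells^-1 mL hr^-1 and
    ``Nm`` (cells/mL) is the maximum carrying capacity.
    """
    if eta_c < 0 or Nm < 0:
        raise ValueError("rates and capacities must be >= 0")
    return Nm * eta_c


def eta_to_empirical(eta: float, Nm: float) -> float:
    """Inverse of :func:`eta_from_empirical`: ``eta_c = eta / Nm``."""
    if eta < 0 or Nm <= 0:
        raise ValueError("eta must be >= 0 and Nm > 0")
    return eta / Nm
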