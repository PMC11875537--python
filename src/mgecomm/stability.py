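"""Stability-landscape analysis by random-initialization ensembles.

The number of alternative stable states of a community is estimated by
relaxing many uniformly random initial compositions to equilibrium and
grouping the resulting steady states into attractors: two steady states
belong to the same attractor when the Euclidean distance between their
species-abundance vectors is below a threshold, closed transitively
(single linkage).  Basin sizes are estimated as the fraction of converged
initializations reaching each attractor, and summarized by the
multistability coefficient

    chi = exp( -sum_i x_i log x_i ),

the exponential Shannon entropy of the basin fractions x_i: chi = 1 for a
monostable system and chi = phi when phi attractors have equal basins.

Default protocol sizes follow the two standard analyses: 200
initializations with clustering threshold 0.01 for two-species systems,
500 initializations with threshold 0.05 for larger communities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .models import CommunityModel, CommunityState
from .simulate import CONVERGENCE_TOL, EXTINCTION_FLOOR, SteadyState, solve_steady_batch

__all__ = [
    "Ensemble",
    "AttractorSet",
    "PhaseDiagram",
    "EtaScanResult",
    "sample_initial_conditions",
    "run_ensemble",
    "cluster_attractors",
    "multistability_coefficient",
    "count_stable_states",
    "phase_diagram",
    "bistability_fraction",
    "eta_scan",
]


# ----------------------------------------------------------------------
# Initial conditions
# ----------------------------------------------------------------------


def _spawn_rngs(seed, n):
    """n independent RNG substreams from one master seed.

    Stream k depends only on (seed, k), so enlarging n extends the draw
    sequence without reshuffling earlier initializations.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n)
    return [np.random.default_rng(c) for c in children], [c.spawn_key for c in children]


def sample_initial_conditions(
    m: int,
    n_init: int,
    seed=0,
    carrier_mode: str = "native",
    donor_index: Optional[int] = None,
):
    """Uniform random initial communities.

    Species abundances are iid U(0, 1).  Carrier modes:

    - ``"native"``: each species carries only its own element
      (p_ii = s_i, p_ij = 0 for i != j) — the standard protocol.
    - ``"nonzero"``: off-diagonal carriers start at p_ij ~ U(0, s_i).
    - ``"donor"``: a single MGE held entirely by ``donor_index``
      (selection variant).

    Returns ``(states, seed_keys)`` where ``seed_keys`` records the spawn
    key of each initialization's RNG substream.
    """
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if carrier_mode == "donor" and donor_index is None:
        raise ValueError("carrier_mode='donor' requires donor_index")
    rngs, keys = _spawn_rngs(seed, n_init)
    states = []
    for rng in rngs:
        s = rng.uniform(0.0, 1.0, size=m)
        p = np.zeros((m, m))
        if carrier_mode == "native":
            np.fill_diagonal(p, s)
        elif carrier_mode == "nonzero":
            p = rng.uniform(0.0, 1.0, size=(m, m)) * s[:, None]
            np.fill_diagonal(p, s)
        elif carrier_mode == "donor":
            p[donor_index, donor_index] = s[donor_index]
        else:
            raise ValueError(f"unknown carrier_mode {carrier_mode!r}")
        states.append(CommunityState(s, p))
    return states, keys


def default_carrier_mode(model: CommunityModel) -> str:
    return "donor" if model.variant == "selection" else "native"


# ----------------------------------------------------------------------
# Ensembles and attractors
# ----------------------------------------------------------------------


@dataclass
class Ensemble:
    """Steady states of ``n_init`` random initializations of one model."""

    model: CommunityModel
    steady_states: list
    seeds: list
    n_init: int

    @property
    def s_matrix(self) -> np.ndarray:
        """(n_init, m) array of steady-state species abundances."""
        return np.array([st.state.s for st in self.steady_states])

    @property
    def converged(self) -> np.ndarray:
        return np.array([st.converged for st in self.steady_states])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, st in enumerate(self.steady_states):
            row = {"init": k, "converged": st.converged, "residual": st.residual, "t_final": st.t_final}
            row.update({f"s_{i}": v for i, v in enumerate(st.state.s)})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AttractorSet:
    """Clustered attractors of an ensemble.

    ``representatives[k]`` is the mean species-abundance vector of cluster
    k, ``basin_counts[k]`` the number of converged initializations in its
    basin, and ``chi`` the multistability coefficient.
    """

    representatives: np.ndarray  # (n_attractors, m)
    basin_counts: np.ndarray  # (n_attractors,)
    chi: float
    threshold: float
    n_converged: int
    n_total: int
    labels: np.ndarray = field(default=None, repr=False)  # per converged member

    @property
    def n_attractors(self) -> int:
        return len(self.basin_counts)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.representatives, columns=[f"s_{i}" for i in range(self.representatives.shape[1])]
        )
        df.insert(0, "attractor", np.arange(self.n_attractors))
        df.insert(1, "basin_count", self.basin_counts)
        return df


def run_ensemble(
    model: CommunityModel,
    n_init: int = 500,
    seed=0,
    *,
    carrier_mode: Optional[str] = None,
    horizon: float = 2000.0,
    tol: float = CONVERGENCE_TOL,
    hard_cap: float = 10000.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    fixed_horizon: bool = False,
) -> Ensemble:
    """Relax ``n_init`` uniform random initializations of ``model``.

    With ``fixed_horizon=True`` every member is integrated for exactly
    ``horizon`` hours — the fixed-window observation protocol — instead of
    extending non-converged members; the ``converged`` flags still report
    the residual check.
    """
    mode = carrier_mode or default_carrier_mode(model)
    inits, keys = sample_initial_conditions(
        model.m, n_init, seed, carrier_mode=mode, donor_index=model.donor_index
    )
    from .models import Kernel

    kern = Kernel(model)
    if fixed_horizon:
        hard_cap = horizon
    Y, conv, res, tf = solve_steady_batch(
        model,
        kern.pack(inits),
        horizon=horizon,
        tol=tol,
        hard_cap=hard_cap,
        rtol=rtol,
        atol=atol,
        early_stop=not fixed_horizon,
    )
    states = kern.unpack(Y)
    sts = [
        SteadyState(state=st, converged=bool(c), residual=float(r), t_final=float(t))
        for st, c, r, t in zip(states, conv, res, tf)
    ]
    return Ensemble(model=model, steady_states=sts, seeds=keys, n_init=n_init)


def multistability_coefficient(basin_counts) -> float:
    """chi = exp(Shannon entropy) of the basin-size distribution.

    Equals 1 for a single basin and the attractor count when basins are
    equal-sized; invariant under permutation of basin labels.
    """
    counts = np.asarray(basin_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("basin_counts must be nonempty")
    if np.any(counts <= 0):
        raise ValueError("basin counts must be positive")
    x = counts / counts.sum()
    return float(np.exp(-np.sum(x * np.log(x))))


def cluster_attractors(ensemble, threshold: float = 0.05, include_nonconverged: bool = False) -> AttractorSet:
    """Group steady states into attractors by single-linkage at ``threshold``.

    Steady states whose species-abundance vectors are closer (Euclidean)
    than ``threshold`` belong to the same attractor; the relation is closed
    transitively, i.e. clusters are the connected components of the
    sub-threshold distance graph.  Non-converged members are excluded (and
    counted in ``n_total`` only).  Abundances below the extinction floor
    are zeroed first so near-extinct tails do not split clusters.

    ``ensemble`` may be an :class:`Ensemble` or an (n, m) array of
    steady-state abundance vectors (all treated as converged).
    """
    if isinstance(ensemble, Ensemble):
        S = ensemble.s_matrix
        conv = ensemble.converged
        if include_nonconverged:
            conv = np.ones(S.shape[0], dtype=bool)
    else:
        S = np.asarray(ensemble, dtype=float)
        conv = np.ones(S.shape[0], dtype=bool)
    n_total = S.shape[0]
    S = S[conv]
    if S.shape[0] == 0:
        raise ValueError("no converged steady states to cluster")
    S = np.where(S < EXTINCTION_FLOOR, 0.0, S)
    n = S.shape[0]
    adj = squareform(pdist(S) < threshold).astype(np.int8)
    np.fill_diagonal(adj, 1)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # relabel by first occurrence so the labelling is deterministic
    order = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in labels])
    k = labels.max() + 1
    reps = np.array([S[labels == c].mean(axis=0) for c in range(k)])
    counts = np.bincount(labels, minlength=k)
    return AttractorSet(
        representatives=reps,
        basin_counts=counts,
        chi=multistability_coefficient(counts),
        threshold=threshold,
        n_converged=n,
        n_total=n_total,
        labels=labels,
    )


def count_stable_states(
    model: CommunityModel,
    n_init: int = 500,
    threshold: float = 0.05,
    seed=0,
    include_nonconverged: bool = False,
    **kwargs,
) -> AttractorSet:
    """Sample -> relax -> cluster: the standard stable-state count."""
    ens = run_ensemble(model, n_init=n_init, seed=seed, **kwargs)
    return cluster_attractors(ens, threshold=threshold, include_nonconverged=include_nonconverged)


# ----------------------------------------------------------------------
# Phase diagrams and parameter sweeps
# ----------------------------------------------------------------------


@dataclass
class PhaseDiagram:
    """Stable-state counts over a (mu1, mu2) grid of a two-species model."""

    mu1_values: np.ndarray
    mu2_values: np.ndarray
    n_states: np.ndarray  # (len(mu1), len(mu2))
    bistable: np.ndarray  # boolean mask
    bistable_area_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.mu1_values):
            for j, b in enumerate(self.mu2_values):
                rows.append(
                    {"mu1": a, "mu2": b, "n_states": int(self.n_states[i, j]), "bistable": bool(self.bistable[i, j])}
                )
        return pd.DataFrame(rows)


def _with_growth_rates(model: CommunityModel, mu: np.ndarray) -> CommunityModel:
    """Copy of ``model`` with full growth rates mu (lam_ii = mu/mu0 - 1).

    Off-diagonal lam entries tied to the native element (columns) follow:
    lam_ij = lam_jj whenever the template had lam_ij == lam_jj (no
    epistasis); epistatic templates keep their xi ratios.
    """
    from dataclasses import replace

    mu = np.asarray(mu, float)
    old_diag = np.diag(model.lam)
    new_diag = mu / model.mu0 - 1.0
    lam = model.lam.copy()
    for j in range(model.m):
        col = lam[:, j]
        ratio = np.ones(model.m)
        nz = old_diag[j] != 0
        if nz:
            ratio = col / old_diag[j]
            lam[:, j] = ratio * new_diag[j]
        else:
            lam[:, j] = np.where(col == old_diag[j], new_diag[j], col)
    lam[np.arange(model.m), np.arange(model.m)] = new_diag
    if model.variant == "selection":
        # carriage switches growth from 0 to mu directly
        return replace(model, mu0=mu, lam=np.zeros_like(lam))
    return replace(model, lam=lam)


def phase_diagram(
    model: CommunityModel,
    mu1_values: Sequence[float],
    mu2_values: Sequence[float],
    n_init: int = 200,
    threshold: float = 0.01,
    seed=0,
    **kwargs,
) -> PhaseDiagram:
    """Bistability phase diagram of a two-species template over (mu1, mu2).

    For each growth-rate combination the stable states are counted from
    ``n_init`` random initializations; a cell is bistable iff more than one
    attractor is found.  The same initialization seed is reused across
    cells (common random numbers).
    """
    if model.m != 2:
        raise ValueError("phase_diagram requires a two-species template")
    mu1_values = np.asarray(mu1_values, float)
    mu2_values = np.asarray(mu2_values, float)
    counts = np.zeros((len(mu1_values), len(mu2_values)), dtype=int)
    for i, a in enumerate(mu1_values):
        for j, b in enumerate(mu2_values):
            cell = _with_growth_rates(model, np.array([a, b]))
            aset = count_stable_states(cell, n_init=n_init, threshold=threshold, seed=seed, **kwargs)
            counts[i, j] = aset.n_attractors
    bist = counts > 1
    return PhaseDiagram(
        mu1_values=mu1_values,
        mu2_values=mu2_values,
        n_states=counts,
        bistable=bist,
        bistable_area_fraction=float(bist.mean()),
    )


def bistability_fraction(
    sampler: Callable,
    n_draws: int = 500,
    n_init: int = 200,
    threshold: float = 0.01,
    seed=0,
    **kwargs,
) -> float:
    """Fraction of sampled parameterizations that are multistable.

    ``sampler(rng)`` must return a CommunityModel; each draw uses its own
    RNG substream (draw k depends only on the master seed and k, so the
    same seed yields the same parameter draws for samplers that consume
    the stream identically — e.g. across different eta values).  Each
    sampled model is scored bistable iff its ensemble has >= 2 attractors.
    """
    rngs, _ = _spawn_rngs(seed, n_draws)
    init_seed = np.random.SeedSequence(entropy=(seed if np.isscalar(seed) else 0), spawn_key=(0xB15,))
    hits = 0
    for rng in rngs:
        model = sampler(rng)
        aset = count_stable_states(model, n_init=n_init, threshold=threshold, seed=init_seed, **kwargs)
        if aset.n_attractors >= 2:
            hits += 1
    return hits / n_draws


@dataclass
class EtaScanResult:
    """Stable-state counts and chi along a transfer-rate grid."""

    table: pd.DataFrame  # columns: eta, replicate, n_states, chi
    summary: pd.DataFrame  # columns: eta, mean_n, sd_n, mean_chi, sd_chi
    onset_eta: Optional[float]  # smallest eta whose mean count exceeds the eta=0 mean
    promotion_threshold: Optional[float] = None  # see multistability_promotion_threshold


def multistability_promotion_threshold(table: pd.DataFrame, alpha: float = 0.01) -> Optional[float]:
    """Largest scanned eta at which HGT does not yet promote multistability.

    The raw "first eta whose mean attractor count exceeds the eta=0 mean"
    rule is noise-limited: attractor counts are small integers, and basins
    near the clustering threshold flip by +-1 between replicates, so the
    zero-margin comparison trips on the plateau of near-zero transfer
    rates.  Instead, each eta's counts are compared with the eta=0 counts
    of the *same* replicates (paired, common initializations) by a
    one-sided paired t-test at level ``alpha``.  The promotion threshold is
    the largest grid value below the smallest eta from which the excess is
    significant at every larger eta — i.e. HGT promotes multistability for
    rates *above* the returned value.  None when no sustained significant
    excess exists.
    """
    from scipy import stats

    piv = table.pivot(index="replicate", columns="eta", values="n_states")
    if 0.0 not in piv.columns:
        raise ValueError("the scan must include eta = 0 as the baseline")
    base = piv[0.0]
    etas = sorted(e for e in piv.columns if e > 0.0)
    sig = {}
    for eta in etas:
        d = piv[eta] - base
        sd = d.std(ddof=1)
        if sd == 0:
            sig[eta] = bool(d.mean() > 0)
        else:
            t = d.mean() / (sd / np.sqrt(len(d)))
            sig[eta] = bool(t > stats.t.ppf(1.0 - alpha, len(d) - 1))
    star = None
    for i, eta in enumerate(etas):
        if all(sig[e] for e in etas[i:]):
            star = i
            break
    if star is None:
        return None
    return float(etas[star - 1]) if star > 0 else 0.0


def eta_scan(
    sampler: Callable,
    eta_values: Sequence[float],
    n_replicates: int = 10,
    n_init: int = 500,
    threshold: float = 0.05,
    seed=0,
    **kwargs,
) -> EtaScanResult:
    """Scan attractor counts and chi over HGT rates.

    ``sampler(rng)`` returns a CommunityModel; one model is drawn per
    replicate (replicates differ by their growth-rate draws) and re-run at
    every ``eta`` with the same initialization seed, so the eta effect is
    measured against common random numbers.  ``onset_eta`` is the smallest
    scanned eta whose replicate-mean attractor count exceeds the mean at
    the smallest eta (use a grid containing 0 to anchor the baseline).
    """
    eta_values = list(eta_values)
    rngs, _ = _spawn_rngs(seed, n_replicates)
    rows = []
    for r, rng in enumerate(rngs):
        model = sampler(rng)
        init_seed = np.random.SeedSequence(entropy=(seed if np.isscalar(seed) else 0), spawn_key=(0xE7A, r))
        for eta in eta_values:
            aset = count_stable_states(
                model.with_eta(eta), n_init=n_init, threshold=threshold, seed=init_seed, **kwargs
            )
            rows.append({"eta": eta, "replicate": r, "n_states": aset.n_attractors, "chi": aset.chi})
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("eta")
        .agg(mean_n=("n_states", "mean"), sd_n=("n_states", "std"), mean_chi=("chi", "mean"), sd_chi=("chi", "std"))
        .reset_index()
        .sort_values("eta")
        .reset_index(drop=True)
    )
    base = summary["mean_n"].iloc[0]
    above = summary[summary["mean_n"] > base]
    onset = float(above["eta"].iloc[0]) if len(above) else None
    thr = None
    if 0.0 in set(table["eta"]):
        thr = multistability_promotion_threshold(table)
    return EtaScanResult(table=table, summary=summary, onset_eta=onset, promotion_threshold=thr)
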