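"""Variational-Bayes hidden Markov model for diffusive states.

Single-particle trajectories are reduced to sequences of 2-D displacements
between successive frames.  A hidden Markov model with K in {1, 2, 3}
diffusive states is fitted by conjugate variational inference: state k
emits displacements whose components are zero-mean Gaussian with variance
``2 * D_k * dt``, transition rows carry Dirichlet priors whose
self-transition pseudocounts encode a prior mean dwell time (default 50
frames = 1000 ms at 20 ms/frame), and the per-state emission precision
carries a Gamma prior centered on a prior diffusion coefficient (default
0.1 um^2/s).  The number of states is chosen by the maximal evidence
(variational lower bound) criterion.

The evidence bound is guaranteed non-decreasing across iterations; states
are canonically ordered by increasing D so output is invariant to restart
permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln

from .datatypes import TrajectorySet

__all__ = [
    "HMMPriors",
    "DisplacementSequences",
    "DiffusionHMM",
    "StateMetrics",
    "displacements",
    "fit_hmm",
    "select_model",
    "state_metrics",
]

_D_FLOOR = 1e-12  # um^2/s floor reported for degenerate (all-zero) data


@dataclass
class HMMPriors:
    """Weakly informative priors for the diffusive-state HMM.

    ``prior_D_um2_s`` centers the Gamma prior on each state's emission
    precision (strength ``gamma_strength`` pseudo-displacements);
    ``prior_dwell_frames`` sets the Dirichlet self-transition pseudocount to
    ``prior_dwell_frames - 1`` with a total off-diagonal pseudocount of
    ``dirichlet_offdiag_total`` split evenly.
    """

    prior_D_um2_s: float = 0.1
    prior_dwell_frames: float = 50.0
    dirichlet_offdiag_total: float = 1.0
    gamma_strength: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.prior_D_um2_s,
            self.prior_dwell_frames,
            self.dirichlet_offdiag_total,
            self.gamma_strength,
        ) <= 0:
            raise ValueError("all prior parameters must be positive")


@dataclass
class DisplacementSequences:
    """Per-trajectory ordered 2-D displacement vectors (um) at interval dt."""

    sequences: list  # list of (L_i, 2) float arrays, L_i >= 1
    dt_s: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.sequences = [np.asarray(s, dtype=np.float64).reshape(-1, 2) for s in self.sequences]
        for s in self.sequences:
            if len(s) < 1:
                raise ValueError("each displacement sequence needs >= 1 step")
            if not np.all(np.isfinite(s)):
                raise ValueError("displacements must be finite")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def total_steps(self) -> int:
        return sum(len(s) for s in self.sequences)

    def squared_norms(self) -> list:
        return [np.sum(s**2, axis=1) for s in self.sequences]


@dataclass
class DiffusionHMM:
    """Fitted diffusive-state HMM (posterior summaries, canonical D order)."""

    K: int
    D_um2_s: np.ndarray
    A: np.ndarray                 # posterior-mean transition matrix
    pi: np.ndarray                # posterior-mean initial distribution
    evidence_bound: float
    converged: bool
    n_iterations: int
    occupancy: np.ndarray         # mean posterior state mass over all steps
    dt_s: float
    bound_history: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False
    # posterior hyperparameters (canonical order)
    dirichlet_A: np.ndarray = field(repr=False, default=None)
    gamma_shape: np.ndarray = field(repr=False, default=None)
    gamma_rate: np.ndarray = field(repr=False, default=None)


@dataclass
class StateMetrics:
    """Per-state diffusion coefficient, dwell time, and occupancy."""

    D_um2_s: np.ndarray
    dwell_time_ms: np.ndarray
    occupancy: np.ndarray
    stationary_occupancy: np.ndarray
    dwell_infinite: np.ndarray


def displacements(traj: TrajectorySet) -> DisplacementSequences:
    """Displacement vectors between successive observations per trajectory.

    Trajectories are split at frame gaps (non-unit frame steps); resulting
    fragments shorter than two positions are dropped and counted in
    ``n_dropped``.
    """
    seqs: list[np.ndarray] = []
    n_dropped = 0
    for tid in np.unique(traj.trajectory_id):
        idx = np.flatnonzero(traj.trajectory_id == tid)
        idx = idx[np.argsort(traj.frame[idx], kind="stable")]
        frames = traj.frame[idx]
        xy = np.column_stack([traj.x_um[idx], traj.y_um[idx]])
        if len(idx) < 2:
            n_dropped += 1
            continue
        # split at frame gaps
        breaks = np.flatnonzero(np.diff(frames) != 1)
        start = 0
        for b in np.append(breaks, len(frames) - 1):
            seg = xy[start : b + 1]
            if len(seg) >= 2:
                seqs.append(np.diff(seg, axis=0))
            else:
                n_dropped += 1
            start = b + 1
    return DisplacementSequences(sequences=seqs, dt_s=traj.dt_s, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# variational inference internals
# ---------------------------------------------------------------------------

def _kl_dirichlet(w: np.ndarray, w0: np.ndarray) -> float:
    sw, sw0 = w.sum(), w0.sum()
    return float(
        gammaln(sw)
        - gammaln(w).sum()
        - gammaln(sw0)
        + gammaln(w0).sum()
        + np.sum((w - w0) * (digamma(w) - digamma(sw)))
    )


def _kl_gamma(a: np.ndarray, b: np.ndarray, a0: float, b0: float) -> np.ndarray:
    return (
        (a - a0) * digamma(a)
        - gammaln(a)
        + gammaln(a0)
        + a0 * (np.log(b) - np.log(b0))
        + a * (b0 - b) / b
    )


def _group_by_length(r2_list: list) -> list:
    """Group squared-norm sequences by length -> [(r2_matrix (n, L))]."""
    by_len: dict[int, list[np.ndarray]] = {}
    for r2 in r2_list:
        by_len.setdefault(len(r2), []).append(r2)
    return [np.vstack(group) for _, group in sorted(by_len.items())]


def _forward_backward(
    batches: list, ln_pi: np.ndarray, ln_A: np.ndarray, e_lam: np.ndarray, e_lnlam: np.ndarray
):
    """Scaled forward-backward over length-grouped batches.

    Returns (total log normalizer, Npi, Nij, Nk, Sk) where Nk/Sk aggregate
    responsibilities and responsibility-weighted r^2/2 per state.
    """
    K = len(e_lam)
    tilde_pi = np.exp(ln_pi)
    tilde_A = np.exp(ln_A)
    lnZ = 0.0
    Npi = np.zeros(K)
    Nij = np.zeros((K, K))
    Nk = np.zeros(K)
    Sk = np.zeros(K)
    for r2 in batches:
        n, L = r2.shape
        lnB = e_lnlam[None, None, :] - np.log(2 * np.pi) - 0.5 * e_lam[None, None, :] * r2[:, :, None]
        m = lnB.max(axis=2, keepdims=True)
        B = np.exp(lnB - m)
        lnZ += float(m.sum())

        alpha = np.empty((n, L, K))
        c = np.empty((n, L))
        a0 = tilde_pi[None, :] * B[:, 0, :]
        c[:, 0] = a0.sum(axis=1)
        alpha[:, 0, :] = a0 / c[:, 0, None]
        for t in range(1, L):
            at = (alpha[:, t - 1, :] @ tilde_A) * B[:, t, :]
            c[:, t] = at.sum(axis=1)
            alpha[:, t, :] = at / c[:, t, None]
        lnZ += float(np.log(c).sum())

        beta = np.empty((n, L, K))
        beta[:, L - 1, :] = 1.0
        for t in range(L - 2, -1, -1):
            bt = (B[:, t + 1, :] * beta[:, t + 1, :]) @ tilde_A.T
            beta[:, t, :] = bt / c[:, t + 1, None]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=2, keepdims=True)

        Npi += gamma[:, 0, :].sum(axis=0)
        Nk += gamma.sum(axis=(0, 1))
        Sk += 0.5 * np.einsum("ntk,nt->k", gamma, r2)
        if L > 1:
            # xi_t(i,j) proportional to alpha_t(i) A(i,j) B_{t+1}(j) beta_{t+1}(j)
            for t in range(L - 1):
                xi = (
                    alpha[:, t, :, None]
                    * tilde_A[None, :, :]
                    * (B[:, t + 1, None, :] * beta[:, t + 1, None, :])
                ) / c[:, t + 1, None, None]
                Nij += xi.sum(axis=0)
    return lnZ, Npi, Nij, Nk, Sk


def _kmeans_responsibilities(
    r2_all: np.ndarray, K: int, rng: np.random.Generator, soft: float = 0.85
) -> np.ndarray:
    """Randomized 1-D k-means on squared step lengths -> soft labels."""
    centers = rng.choice(r2_all, size=K, replace=False).astype(np.float64)
    centers += 1e-12 * rng.uniform(size=K)
    for _ in range(10):
        d = np.abs(r2_all[:, None] - centers[None, :])
        lab = np.argmin(d, axis=1)
        for k in range(K):
            sel = lab == k
            if sel.any():
                centers[k] = r2_all[sel].mean()
    gamma = np.full((len(r2_all), K), (1.0 - soft) / K)
    gamma[np.arange(len(r2_all)), lab] += soft - (1.0 - soft) * 0  # peak on own label
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma


def fit_hmm(
    ds: DisplacementSequences,
    K: int,
    priors: HMMPriors | None = None,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> DiffusionHMM:
    """Fit a K-state diffusive HMM by conjugate variational inference.

    ``tol`` is the convergence threshold on the evidence-bound improvement
    per displacement step (nats).  The best of ``n_restarts`` randomized
    initializations (k-means on squared step lengths) by final bound is
    returned, with states sorted by increasing D.
    """
    if priors is None:
        priors = HMMPriors()
    if K < 1:
        raise ValueError("K must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if ds.n_sequences == 0:
        raise ValueError("no displacement sequences to fit")

    dt = ds.dt_s
    r2_list = ds.squared_norms()
    batches = _group_by_length(r2_list)
    r2_all = np.concatenate(r2_list)
    N_total = len(r2_all)
    degenerate = bool(np.all(r2_all < 1e-30))

    # priors
    a0 = priors.gamma_strength
    b0 = a0 * 2.0 * priors.prior_D_um2_s * dt
    w_pi0 = np.ones(K)
    if K > 1:
        w_A0 = np.full((K, K), priors.dirichlet_offdiag_total / (K - 1))
        np.fill_diagonal(w_A0, priors.prior_dwell_frames - 1.0)
    else:
        w_A0 = np.ones((1, 1))

    def _iterate(state, n_iter):
        """Run up to ``n_iter`` VB iterations in place; bound is monotone."""
        w_pi, w_A, a, b = state["w_pi"], state["w_A"], state["a"], state["b"]
        prev = state["bounds"][-1] if state["bounds"] else -np.inf
        for _ in range(n_iter):
            ln_pi = digamma(w_pi) - digamma(w_pi.sum())
            ln_A = digamma(w_A) - digamma(w_A.sum(axis=1, keepdims=True))
            e_lam = a / b
            e_lnlam = digamma(a) - np.log(b)

            lnZ, Npi, Nij, Nk, Sk = _forward_backward(batches, ln_pi, ln_A, e_lam, e_lnlam)
            bound = (
                lnZ
                - _kl_dirichlet(w_pi, w_pi0)
                - sum(_kl_dirichlet(w_A[k], w_A0[k]) for k in range(K))
                - float(_kl_gamma(a, b, a0, b0).sum())
            )
            state["bounds"].append(bound)
            state["occupancy"] = Nk / Nk.sum()
            if len(state["bounds"]) > 1 and bound - prev < tol * N_total:
                state["converged"] = True
                break
            prev = bound
            w_pi = w_pi0 + Npi
            w_A = w_A0 + Nij
            a = a0 + Nk
            b = b0 + Sk
            state.update(w_pi=w_pi, w_A=w_A, a=a, b=b)
        return state

    master = np.random.default_rng(seed)
    n_restarts = max(1, n_restarts if K > 1 else 1)  # K=1 has a unique optimum
    pilot_iters = min(max_iter, 50)
    states = []
    for _ in range(n_restarts):
        rng = np.random.default_rng(master.integers(0, 2**31))
        if K == 1:
            gamma0 = np.ones((N_total, 1))
        else:
            gamma0 = _kmeans_responsibilities(r2_all, K, rng)
        # initial M-step from flat responsibilities (transitions ~ independence)
        Nk = gamma0.sum(axis=0)
        Sk = 0.5 * (gamma0 * r2_all[:, None]).sum(axis=0)
        occ = Nk / N_total
        state = {
            "w_pi": w_pi0 + occ * ds.n_sequences,
            "w_A": w_A0 + (N_total - ds.n_sequences) * np.outer(occ, occ),
            "a": a0 + Nk,
            "b": b0 + Sk,
            "bounds": [],
            "occupancy": occ,
            "converged": False,
        }
        # short pilot run per restart; only the best continues to convergence
        states.append(_iterate(state, pilot_iters))
    best = max(states, key=lambda s: s["bounds"][-1])
    if not best["converged"]:
        _iterate(best, max_iter - len(best["bounds"]))
    best["bound"] = best["bounds"][-1]
    best["bounds"] = np.array(best["bounds"])
    best["n_iter"] = len(best["bounds"])

    D = (best["b"] / best["a"]) / (2.0 * dt)
    if degenerate:
        D = np.maximum(D, _D_FLOOR)
    order = np.argsort(D, kind="stable")
    A_mean = best["w_A"] / best["w_A"].sum(axis=1, keepdims=True)
    pi_mean = best["w_pi"] / best["w_pi"].sum()
    return DiffusionHMM(
        K=K,
        D_um2_s=D[order],
        A=A_mean[np.ix_(order, order)],
        pi=pi_mean[order],
        evidence_bound=float(best["bound"]),
        converged=bool(best["converged"]),
        n_iterations=int(best["n_iter"]),
        occupancy=best["occupancy"][order],
        dt_s=dt,
        bound_history=best["bounds"],
        degenerate=degenerate,
        dirichlet_A=best["w_A"][np.ix_(order, order)],
        gamma_shape=best["a"][order],
        gamma_rate=best["b"][order],
    )


def select_model(
    ds: DisplacementSequences,
    priors: HMMPriors | None = None,
    candidate_K=(1, 2, 3),
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
    tie_nats: float = 0.1,
) -> tuple[DiffusionHMM, dict]:
    """Choose the number of diffusive states by maximal evidence.

    Fits every candidate K and returns the model with the largest evidence
    bound together with the per-K bound table.  Bound differences below
    ``tie_nats`` are broken toward the smaller K (parsimony).
    """
    candidates = sorted(set(int(k) for k in candidate_K))
    if not candidates:
        raise ValueError("candidate_K must be non-empty")
    if any(k < 1 for k in candidates):
        raise ValueError("candidate K values must be >= 1")
    master = np.random.default_rng(seed)
    models: dict[int, DiffusionHMM] = {}
    bounds: dict[int, float] = {}
    errors: dict[int, Exception] = {}
    for K in candidates:
        sub_seed = int(master.integers(0, 2**31))
        try:
            models[K] = fit_hmm(
                ds, K, priors=priors, n_restarts=n_restarts, max_iter=max_iter, tol=tol, seed=sub_seed
            )
            bounds[K] = models[K].evidence_bound
        except Exception as exc:  # propagate only if every K fails
            errors[K] = exc
    if not models:
        raise RuntimeError(f"all candidate models failed: {errors}")
    best_k = max(bounds, key=lambda k: bounds[k])
    for k in sorted(bounds):  # parsimony tie-break toward smaller K
        if k < best_k and bounds[best_k] - bounds[k] < tie_nats:
            best_k = k
            break
    return models[best_k], bounds


def state_metrics(m: DiffusionHMM, ds: DisplacementSequences | None = None) -> StateMetrics:
    """Dwell times and occupancies of a fitted model.

    ``dwell_time_ms(k) = 1000 * dt / (1 - A_kk)``; occupancy is the mean
    posterior state mass over all displacement steps (the stationary
    distribution of A is reported alongside).
    """
    diag = np.diag(m.A)
    infinite = diag >= 1.0 - 1e-12
    dwell = np.full(m.K, np.inf)
    dwell[~infinite] = 1000.0 * m.dt_s / (1.0 - diag[~infinite])
    if m.K == 1:
        stationary = np.ones(1)
    else:
        from .synthetic import stationary_distribution

        stationary = stationary_distribution(m.A)
    return StateMetrics(
        D_um2_s=m.D_um2_s,
        dwell_time_ms=dwell,
        occupancy=m.occupancy,
        stationary_occupancy=stationary,
        dwell_infinite=infinite,
    )
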