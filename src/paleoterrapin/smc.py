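"""Pairwise sequentially-Markovian-coalescent HMM for Ne inference.

The two alleles of one diploid genome are modelled as a hidden Markov chain
over discretized TMRCA intervals.  Per 100-bp bin, the emission probability
of a heterozygous bin in state k is 1 - exp(-theta * t_k) with t_k the
conditional mean coalescent time of interval k, and transitions follow the
SMC' kernel: with probability exp(-rho * t) no recombination occurs and the
state persists; otherwise the recombination point is uniform on (0, t) and
the detached lineage re-coalesces against the piecewise-constant rates
lambda_k, with back-coalescence restoring the previous TMRCA.

Fitting is EM: exact E-step by scaled forward-backward, generalized M-step
(bounded quasi-Newton ascent of the expected complete-data log-likelihood
in log-parameters, accepted only when it improves), which guarantees a
non-decreasing observed-data log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.optimize import minimize

from ._kernels import forward_backward_counts, posterior_marginals
from .demography import DemographicTrajectory
from .discretize import TimeDiscretization
from .hetstats import BIN_HET, BIN_MISSING, HetBinTrack

_EPS = 1e-300


@dataclass
class SMCModel:
    """Scaled parameters of the coalescent HMM (per-bin theta and rho)."""

    theta: float
    rho: float
    lam_free: np.ndarray  # relative coalescence rate per free interval (1/Ne relative)

    def __post_init__(self) -> None:
        self.lam_free = np.asarray(self.lam_free, dtype=float)
        if self.theta <= 0 or self.rho <= 0 or np.any(self.lam_free <= 0):
            raise ValueError("theta, rho and lambda must be positive")


def _cumulative_rate(disc: TimeDiscretization, lam_atomic: np.ndarray) -> np.ndarray:
    """Integral of the coalescence rate from 0 to each atomic boundary."""
    e = disc.boundaries
    widths = np.diff(e[:-1])  # finite widths; last interval unbounded
    L = np.zeros(disc.n_atomic + 1)
    L[1:-1] = np.cumsum(lam_atomic[:-1] * widths)
    L[-1] = np.inf
    return L


def representative_times(disc: TimeDiscretization, lam_free: np.ndarray) -> np.ndarray:
    """Conditional mean TMRCA within each atomic interval under lambda."""
    lam = disc.lam_atomic(lam_free)
    e = disc.boundaries
    t = np.empty(disc.n_atomic)
    for k in range(disc.n_atomic):
        a, b = e[k], e[k + 1]
        if np.isinf(b):
            t[k] = a + 1.0 / lam[k]
        else:
            d = b - a
            x = lam[k] * d
            # E[t | a <= t < b] for rate lam[k]; stable for small x
            if x < 1e-8:
                t[k] = a + d / 2
            else:
                t[k] = a + 1.0 / lam[k] - d * np.exp(-x) / (1.0 - np.exp(-x))
    return t


def prior_distribution(disc: TimeDiscretization, lam_free: np.ndarray) -> np.ndarray:
    """Stationary (prior) probability of TMRCA falling in each interval."""
    L = _cumulative_rate(disc, disc.lam_atomic(lam_free))
    s = np.exp(-L)
    return s[:-1] - s[1:]


def _rate_integral_at(v: np.ndarray, disc: TimeDiscretization, lam: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Lambda(v) = cumulative coalescence rate at arbitrary times v."""
    e = disc.boundaries
    idx = np.clip(np.searchsorted(e, v, side="right") - 1, 0, disc.n_atomic - 1)
    return L[idx] + lam[idx] * (v - e[idx])


def transition_matrix(
    disc: TimeDiscretization, lam_free: np.ndarray, rho: float, n_u_nodes: int = 16
) -> np.ndarray:
    """SMC' transition matrix between atomic TMRCA intervals.

    For source state i with representative height t: no recombination with
    probability exp(-rho*t).  Given recombination at u ~ U(0,t), the new
    height s has density lam(s)*exp(-2*(Lam(s)-Lam(u))) on (u,t) (coalescing
    with the other branch; total rate below t is 2*lam since the floating
    lineage sees two branches), an atom at t of mass (1-exp(-2*(Lam(t)-Lam(u))))/2
    (back-coalescence onto its own branch), and density
    exp(-2*(Lam(t)-Lam(u))) * lam(s) * exp(-(Lam(s)-Lam(t))) above t.
    The u-average uses Gauss-Legendre quadrature.
    """
    K = disc.n_atomic
    lam = disc.lam_atomic(lam_free)
    e = disc.boundaries
    L = _cumulative_rate(disc, lam)
    trep = representative_times(disc, lam_free)
    gl_x, gl_w = leggauss(n_u_nodes)

    P = np.zeros((K, K))
    lo_edges = e[:-1]
    hi_edges = e[1:]
    expL = np.exp(-L)  # exp(-Lam) at boundaries; last entry 0
    for i in range(K):
        t = trep[i]
        u = 0.5 * t * (gl_x + 1.0)  # nodes on (0, t)
        w = gl_w / 2.0  # weights of the uniform average
        Lu = _rate_integral_at(u, disc, lam, L)
        Lt = _rate_integral_at(np.array([t]), disc, lam, L)[0]
        E2 = np.exp(-2.0 * (Lt - Lu))  # survival of the floating lineage to t

        M = np.zeros((n_u_nodes, K))
        # destinations below t: intersect [e_j, e_{j+1}) with (u, t)
        lo = np.maximum(lo_edges[None, :], u[:, None])
        hi = np.broadcast_to(np.minimum(hi_edges, t), lo.shape)
        has = hi > lo
        if np.any(has):
            Llo = _rate_integral_at(lo[has], disc, lam, L)
            Lhi = _rate_integral_at(hi[has], disc, lam, L)
            contrib = 0.5 * (np.exp(-2.0 * (Llo - np.broadcast_to(Lu[:, None], lo.shape)[has]))
                             - np.exp(-2.0 * (Lhi - np.broadcast_to(Lu[:, None], lo.shape)[has])))
            M[has] += contrib
        # back-coalescence atom at the old height
        M[:, i] += 0.5 * (1.0 - E2)
        # destinations above t (Lam at the unbounded upper edge is inf, exp(-inf)=0)
        lo2 = np.maximum(lo_edges, t)
        has2 = hi_edges > lo2
        Llo2 = _rate_integral_at(lo2[has2], disc, lam, L)
        Lhi2 = _rate_integral_at(hi_edges[has2], disc, lam, L)
        surv = np.exp(-(Llo2 - Lt)) - np.exp(-(Lhi2 - Lt))
        M[:, has2] += E2[:, None] * surv[None, :]

        row = w @ M
        row /= row.sum()  # guard quadrature error; mass is analytically 1
        p_r = 1.0 - np.exp(-rho * t)
        P[i] = p_r * row
        P[i, i] += 1.0 - p_r
    return P


def emission_matrix(disc: TimeDiscretization, lam_free: np.ndarray, theta: float) -> np.ndarray:
    """Columns: P(obs | state) for obs in (HOM, HET, MISSING)."""
    trep = representative_times(disc, lam_free)
    p_het = 1.0 - np.exp(-theta * trep)
    E = np.empty((disc.n_atomic, 3))
    E[:, 0] = 1.0 - p_het
    E[:, 1] = p_het
    E[:, 2] = 1.0
    return E


@dataclass
class SMCFit:
    model: SMCModel
    disc: TimeDiscretization
    trajectory: DemographicTrajectory
    loglik_history: list[float] = field(default_factory=list)
    degenerate: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_history[-1] if self.loglik_history else float("nan")


def _default_init(track: HetBinTrack, disc: TimeDiscretization) -> SMCModel:
    h = track.het_fraction()
    h = min(max(h, 1e-6), 0.5)
    theta0 = -np.log1p(-h)  # E[t]=1 under lambda=1, so E[het] ~ 1-exp(-theta)
    return SMCModel(theta=theta0, rho=theta0 / 5.0, lam_free=np.ones(disc.n_free))


def _trajectory_from(model: SMCModel, disc: TimeDiscretization, track: HetBinTrack) -> DemographicTrajectory:
    return DemographicTrajectory(
        times=disc.free_left_edges(),
        ne=1.0 / model.lam_free,
        units="coalescent",
        theta_per_bin=model.theta,
        bin_size=track.bin_size,
    )


def fit_smc(
    track: HetBinTrack,
    disc: TimeDiscretization | None = None,
    init: SMCModel | None = None,
    n_em_iters: int = 25,
    tol: float = 1e-6,
    estimate_rho: bool = True,
    max_mstep_evals: int = 400,
    verbose: bool = False,
) -> SMCFit:
    """EM fit of theta, rho and the per-interval coalescence rates.

    Returns the fitted model and the implied stepwise Ne trajectory in
    coalescent units (Ne relative to N0; times in 2*N0 generations).
    """
    disc = disc or TimeDiscretization()
    obs_list = [np.ascontiguousarray(v, dtype=np.int8) for v in track.bins.values()]
    if not obs_list or all(np.all(o == BIN_MISSING) for o in obs_list):
        raise ValueError("track is empty or entirely missing")
    model = init or _default_init(track, disc)
    if not any(np.any(o == BIN_HET) for o in obs_list):
        warnings.warn("no heterozygous bins: degenerate fit, returning initial model")
        fit = SMCFit(model, disc, _trajectory_from(model, disc, track), [], degenerate=True)
        return fit

    n_free = disc.n_free
    loglik_history: list[float] = []

    def _obs_loglik(m: SMCModel) -> float:
        P = transition_matrix(disc, m.lam_free, m.rho)
        E = emission_matrix(disc, m.lam_free, m.theta)
        pi = prior_distribution(disc, m.lam_free)
        return sum(forward_backward_counts(o, P, E, pi)[0] for o in obs_list)

    def _rho_line_search(m: SMCModel, n_grid: int = 9) -> SMCModel:
        """Direct ascent of the observed likelihood in rho.

        EM updates rho very slowly (posterior paths under a sticky chain
        show few recombination jumps), so a coarse golden-style search on
        log-rho, accepted only on improvement, keeps the fit monotone while
        escaping the crawl.
        """
        base = _obs_loglik(m)
        grid = m.rho * np.logspace(-0.7, 1.3, n_grid)
        best_rho, best_ll = m.rho, base
        for r in grid:
            if r >= 1.0:
                continue
            cand = SMCModel(theta=m.theta, rho=float(r), lam_free=m.lam_free.copy())
            ll = _obs_loglik(cand)
            if ll > best_ll:
                best_rho, best_ll = float(r), ll
        return SMCModel(theta=m.theta, rho=best_rho, lam_free=m.lam_free.copy())

    def _e_step(m: SMCModel):
        P = transition_matrix(disc, m.lam_free, m.rho)
        E = emission_matrix(disc, m.lam_free, m.theta)
        pi = prior_distribution(disc, m.lam_free)
        ll = 0.0
        counts_emit = np.zeros((disc.n_atomic, 3))
        A = np.zeros((disc.n_atomic, disc.n_atomic))
        g0 = np.zeros(disc.n_atomic)
        for obs in obs_list:
            l, ce, a, gg = forward_backward_counts(obs, P, E, pi)
            ll += l
            counts_emit += ce
            A += a
            g0 += gg
        return ll, counts_emit, A, g0

    def _q(x, counts_emit, A, g0) -> float:
        lam = np.exp(x[:n_free])
        theta = np.exp(x[n_free])
        rho = np.exp(x[n_free + 1])
        P = transition_matrix(disc, lam, rho)
        E = emission_matrix(disc, lam, theta)
        pi = prior_distribution(disc, lam)
        q = float(g0 @ np.log(np.maximum(pi, _EPS)))
        q += float(np.sum(A * np.log(np.maximum(P, _EPS))))
        q += float(np.sum(counts_emit[:, :2] * np.log(np.maximum(E[:, :2], _EPS))))
        return q

    if estimate_rho:
        model = _rho_line_search(model)

    for it in range(n_em_iters):
        if estimate_rho and it > 0 and it % 5 == 0:
            model = _rho_line_search(model, n_grid=5)
        ll, counts_emit, A, g0 = _e_step(model)
        loglik_history.append(ll)
        if verbose:
            print(f"EM iter {it}: loglik = {ll:.4f}")
        if it >= 1 and abs(ll - loglik_history[-2]) <= tol * abs(loglik_history[-2]):
            break
        # alternated generalized M-step: the low-dimensional (theta, rho)
        # block converges fast when optimized on its own, which the joint
        # finite-difference quasi-Newton step starves (rho would crawl)
        x0 = np.concatenate([np.log(model.lam_free), [np.log(model.theta), np.log(model.rho)]])
        q0 = _q(x0, counts_emit, A, g0)
        x_cur = x0.copy()

        def _sub(idx, maxfun):
            def f(z):
                x = x_cur.copy()
                x[idx] = z
                return -_q(x, counts_emit, A, g0)

            b = [(np.log(1e-8), 0.0) if i >= n_free else (-7.0, 7.0) for i in idx]
            return minimize(f, x_cur[idx], method="L-BFGS-B", bounds=b, options={"maxfun": maxfun})

        scalar_idx = [n_free, n_free + 1] if estimate_rho else [n_free]
        r1 = _sub(scalar_idx, 150)
        if -r1.fun > _q(x_cur, counts_emit, A, g0):
            x_cur[scalar_idx] = r1.x
        r2 = _sub(list(range(n_free)), max_mstep_evals)
        if -r2.fun > _q(x_cur, counts_emit, A, g0):
            x_cur[: n_free] = r2.x
        if _q(x_cur, counts_emit, A, g0) > q0:  # generalized EM: accept improvements only
            model = SMCModel(
                theta=float(np.exp(x_cur[n_free])),
                rho=float(np.exp(x_cur[n_free + 1])),
                lam_free=np.exp(x_cur[:n_free]),
            )
        else:
            break
    if not np.isfinite(loglik_history[-1]):
        raise FloatingPointError("non-finite likelihood")
    return SMCFit(model, disc, _trajectory_from(model, disc, track), loglik_history)


def sequence_loglik(track: HetBinTrack, disc: TimeDiscretization, model: SMCModel) -> float:
    """Observed-data log-likelihood of a track under a fixed model."""
    P = transition_matrix(disc, model.lam_free, model.rho)
    E = emission_matrix(disc, model.lam_free, model.theta)
    pi = prior_distribution(disc, model.lam_free)
    return sum(
        forward_backward_counts(np.asarray(o, dtype=np.int8), P, E, pi)[0] for o in track.bins.values()
    )


def posterior_decode(track: HetBinTrack, disc: TimeDiscretization, model: SMCModel):
    """Per-bin posterior TMRCA-interval probabilities per scaffold."""
    P = transition_matrix(disc, model.lam_free, model.rho)
    E = emission_matrix(disc, model.lam_free, model.theta)
    pi = prior_distribution(disc, model.lam_free)
    return {name: posterior_marginals(obs, P, E, pi)[1] for name, obs in track.bins.items()}


def write_fit_report(fit: SMCFit, path) -> None:
    """Plain-text fit report in the familiar psmc-output layout:
    iteration log-likelihoods (LK), theta/rho (TR), and one RS line per
    atomic interval with its left edge and fitted relative coalescence rate."""
    disc = fit.disc
    lam = disc.lam_atomic(fit.model.lam_free)
    with open(path, "w") as fh:
        for i, ll in enumerate(fit.loglik_history):
            fh.write(f"LK\t{i}\t{ll:.6f}\n")
        fh.write(f"TR\t{fit.model.theta:.6g}\t{fit.model.rho:.6g}\n")
        for k in range(disc.n_atomic):
            fh.write(f"RS\t{k}\t{disc.boundaries[k]:.6g}\t{lam[k]:.6g}\n")
        fh.write(f"//\tdegenerate={int(fit.degenerate)}\n")


def bootstrap(
    track: HetBinTrack,
    disc: TimeDiscretization | None = None,
    init: SMCModel | None = None,
    n_reps: int = 30,
    segment_size_bp: float = 5e6,
    seed: int = 0,
    **fit_kwargs,
) -> list[DemographicTrajectory]:
    """Block bootstrap: resample fixed-size segments and refit each replicate."""
    disc = disc or TimeDiscretization()
    seg_bins = max(1, int(segment_size_bp // track.bin_size))
    segments: list[np.ndarray] = []
    for arr in track.bins.values():
        for s in range(0, len(arr), seg_bins):
            segments.append(arr[s : s + seg_bins])
    if not segments:
        raise ValueError("track shorter than one segment")
    total = sum(len(s) for s in segments)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        picked, size = [], 0
        while size < total:
            seg = segments[int(rng.integers(len(segments)))]
            picked.append(seg)
            size += len(seg)
        rep = HetBinTrack(
            bins={f"seg{j}": s for j, s in enumerate(picked)},
            bin_size=track.bin_size,
            genome_size_bp=size * track.bin_size,
        )
        out.append(fit_smc(rep, disc, init, **fit_kwargs).trajectory)
    return out
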