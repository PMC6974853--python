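"""Cox partial-likelihood engine.

A single Newton-Raphson core that covers everything the landmark machinery
needs: Breslow handling of tied event times, delayed entry (left truncation)
through ``(entry, exit]`` at-risk logic, stratification, model-based and
cluster-robust (sandwich) covariances, Breslow baseline-hazard increments and
Schoenfeld residuals.

The at-risk set at an event time ``t`` within a stratum is
``{j : entry_j < t <= exit_j}``.  Risk-set sums are computed per stratum via
suffix cumulative sums over exit- and entry-sorted rows:

    sum_{j at risk at t} w_j = sum_{exit_j >= t} w_j - sum_{entry_j >= t} w_j,

which is valid because ``entry_j >= t`` implies ``exit_j > t``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = [
    "CoxError",
    "ConvergenceError",
    "NoEventsError",
    "RankDeficientError",
    "EmptyStratumError",
    "PartialLikelihoodFit",
    "fit_partial_likelihood",
]


class CoxError(RuntimeError):
    pass


class ConvergenceError(CoxError):
    def __init__(self, message: str, trace: list | None = None):
        super().__init__(message)
        self.trace = trace or []


class NoEventsError(CoxError):
    pass


class RankDeficientError(CoxError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, self.columns))
        )


class EmptyStratumError(CoxError):
    def __init__(self, strata):
        self.strata = list(strata)
        super().__init__(
            "stratum without events: " + ", ".join(map(str, self.strata))
        )


def check_full_rank(X: np.ndarray, names) -> None:
    """Raise :class:`RankDeficientError` naming the dependent columns."""
    n, p = X.shape
    if p == 0:
        return
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        offenders = [names[j] for j in sorted(piv[rank:])]
        raise RankDeficientError(offenders)


class _Stratum:
    """Pre-sorted per-stratum arrays; everything beta-independent."""

    def __init__(self, entry, exit_, status, X):
        self.entry = entry
        self.exit = exit_
        self.status = status.astype(bool)
        self.X = X
        self.n, self.p = X.shape
        ev = self.status
        self.n_events = int(ev.sum())
        # unique event times (ascending) with multiplicities
        te, inv = np.unique(exit_[ev], return_inverse=True)
        self.te = te
        self.event_time_idx_of_event = inv  # per event row, index into te
        self.dk = np.bincount(inv, minlength=te.size).astype(float)
        self.sum_x_events = np.zeros((te.size, self.p))
        if self.p:
            np.add.at(self.sum_x_events, inv, X[ev])
        self.order_exit = np.argsort(exit_, kind="stable")
        self.order_entry = np.argsort(entry, kind="stable")
        exit_sorted = exit_[self.order_exit]
        entry_sorted = entry[self.order_entry]
        # suffix-sum positions: rows with exit >= te_k / entry >= te_k
        self.pos_exit = np.searchsorted(exit_sorted, te, side="left")
        self.pos_entry = np.searchsorted(entry_sorted, te, side="left")
        self.XX = None
        if self.p:
            self.XX = (X[:, :, None] * X[:, None, :]).reshape(self.n, self.p * self.p)

    def _suffix(self, w: np.ndarray) -> np.ndarray:
        """suffix[i] = sum(w[i:]); shape (n+1, ...)."""
        out = np.zeros((w.shape[0] + 1,) + w.shape[1:])
        np.cumsum(w[::-1], axis=0, out=out[1:])
        return out[::-1]

    def risk_sums(self, r: np.ndarray, need_s2: bool = True):
        """S0, S1, S2 at each unique event time, given per-row hazards r."""
        s0_t = self._suffix(r[self.order_exit])
        s0_e = self._suffix(r[self.order_entry])
        S0 = s0_t[self.pos_exit] - s0_e[self.pos_entry]
        S1 = S2 = None
        if self.p:
            xw = self.X * r[:, None]
            s1_t = self._suffix(xw[self.order_exit])
            s1_e = self._suffix(xw[self.order_entry])
            S1 = s1_t[self.pos_exit] - s1_e[self.pos_entry]
            if need_s2:
                xxw = self.XX * r[:, None]
                s2_t = self._suffix(xxw[self.order_exit])
                s2_e = self._suffix(xxw[self.order_entry])
                S2 = (s2_t[self.pos_exit] - s2_e[self.pos_entry]).reshape(
                    -1, self.p, self.p
                )
        return S0, S1, S2

    def hazards(self, beta: np.ndarray) -> np.ndarray:
        lp = self.X @ beta if self.p else np.zeros(self.n)
        lp = lp - lp.mean()  # per-stratum shift; cancels in the loglik
        return np.exp(lp)


def _loglik_grad_info(strata: list[_Stratum], beta, need_info=True):
    p = strata[0].p
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    for st in strata:
        r = st.hazards(beta)
        S0, S1, S2 = st.risk_sums(r, need_s2=need_info)
        lp_shift = (st.X @ beta - (st.X @ beta).mean()) if p else np.zeros(st.n)
        ll += lp_shift[st.status].sum() - float(st.dk @ np.log(S0))
        if p:
            M1 = S1 / S0[:, None]
            grad += st.sum_x_events.sum(axis=0) - st.dk @ M1
            if need_info:
                outer = M1[:, :, None] * M1[:, None, :]
                info += np.einsum("k,kij->ij", st.dk, S2 / S0[:, None, None] - outer)
    return ll, grad, info


@dataclass
class PartialLikelihoodFit:
    beta: np.ndarray
    cov: np.ndarray               # inverse observed information
    cov_robust: np.ndarray | None  # sandwich, clustered (None if no cluster)
    loglik: float
    score: np.ndarray
    info: np.ndarray
    n: int
    n_events: int
    iterations: int
    strata_labels: list
    _strata: list

    def baseline(self, stratum_index: int = 0):
        """Breslow increments ``(event_times, dH)`` for one stratum."""
        st = self._strata[stratum_index]
        r = st.hazards(self.beta)
        S0, _, _ = st.risk_sums(r, need_s2=False)
        return st.te, st.dk / S0

    def schoenfeld(self):
        """Per-event Schoenfeld residuals.

        Returns (times, residuals) with one row per individual event,
        ordered by event time within stratum blocks; risk-set means use the
        Breslow convention (same mean for tied events).
        """
        times, resid = [], []
        for st in self._strata:
            if st.n_events == 0:
                continue
            r = st.hazards(self.beta)
            S0, S1, _ = st.risk_sums(r, need_s2=False)
            M1 = S1 / S0[:, None]
            x_ev = st.X[st.status]
            t_ev = st.exit[st.status]
            order = np.argsort(t_ev, kind="stable")
            times.append(t_ev[order])
            resid.append(x_ev[order] - M1[st.event_time_idx_of_event[order]])
        return np.concatenate(times), np.vstack(resid)

    def score_residuals(self):
        """Per-row score residuals (Lin-Wei), stacked in input row order."""
        p = self._strata[0].p
        rows = []
        idx = []
        for st in self._strata:
            r = st.hazards(self.beta)
            S0, S1, _ = st.risk_sums(r, need_s2=False)
            M1 = S1 / S0[:, None]
            dH = st.dk / S0
            cumA = np.concatenate(([0.0], np.cumsum(dH)))
            cumB = np.vstack((np.zeros(p), np.cumsum(M1 * dH[:, None], axis=0)))
            it = np.searchsorted(st.te, st.exit, side="right")
            ie = np.searchsorted(st.te, st.entry, side="right")
            a = cumA[it] - cumA[ie]
            B = cumB[it] - cumB[ie]
            U = -r[:, None] * (st.X * a[:, None] - B)
            if st.n_events:
                k_ev = np.searchsorted(st.te, st.exit, side="left")
                ev = st.status
                U[ev] += st.X[ev] - M1[k_ev[ev]]
            rows.append(U)
            idx.append(st.row_index)
        order = np.argsort(np.concatenate(idx), kind="stable")
        return np.vstack(rows)[order]


def fit_partial_likelihood(
    entry,
    exit_,
    status,
    X,
    strata=None,
    cluster=None,
    names=None,
    init=None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> PartialLikelihoodFit:
    """Maximise the (stratified) Breslow partial likelihood.

    Parameters
    ----------
    entry, exit_, status
        Counting-process triples; a row is at risk on ``(entry, exit]``.
    X
        Design matrix, shape ``(n, p)``; ``p == 0`` fits the null model.
    strata
        Optional stratum labels; risk sets never cross strata.
    cluster
        Optional cluster labels (e.g. subject ids) for the sandwich
        covariance; required when rows are not independent.
    """
    entry = np.asarray(entry, dtype=float)
    exit_ = np.asarray(exit_, dtype=float)
    status = np.asarray(status)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    if np.any(exit_ <= entry):
        raise ValueError("every row needs exit > entry")
    if not np.isin(status, (0, 1)).all():
        raise ValueError("status must be 0/1")
    if int(np.sum(status)) == 0:
        raise NoEventsError("no events in the data")
    check_full_rank(X, names)

    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    labels, sidx = np.unique(strata, return_inverse=True)
    groups = []
    empty = []
    for g, lab in enumerate(labels):
        m = sidx == g
        st = _Stratum(entry[m], exit_[m], status[m], X[m])
        st.row_index = np.nonzero(m)[0]
        if st.n_events == 0:
            empty.append(lab)
        groups.append(st)
    if empty:
        raise EmptyStratumError(empty)

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    ll, grad, info = _loglik_grad_info(groups, beta)
    trace = [(0, ll, float(np.max(np.abs(grad))) if p else 0.0)]
    iterations = 0
    if p:
        for it in range(1, max_iter + 1):
            iterations = it
            try:
                delta = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ConvergenceError(f"singular information at iter {it}", trace) from exc
            step = 1.0
            while True:
                cand = beta + step * delta
                ll_new, grad_new, info_new = _loglik_grad_info(groups, cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                step /= 2.0
                if step < 1e-12:
                    raise ConvergenceError(
                        f"step-halving failed at iter {it}", trace
                    )
            converged = abs(ll_new - ll) < tol * (abs(ll_new) + 1.0)
            beta, ll, grad, info = cand, ll_new, grad_new, info_new
            trace.append((it, ll, float(np.max(np.abs(grad)))))
            if converged:
                break
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations", trace
            )

    cov = np.linalg.inv(info) if p else np.zeros((0, 0))
    fit = PartialLikelihoodFit(
        beta=beta,
        cov=cov,
        cov_robust=None,
        loglik=ll,
        score=grad,
        info=info,
        n=n,
        n_events=int(np.sum(status)),
        iterations=iterations,
        strata_labels=list(labels),
        _strata=groups,
    )
    if cluster is not None and p:
        U = fit.score_residuals()
        cl = np.asarray(cluster)
        _, cidx = np.unique(cl, return_inverse=True)
        G = np.zeros((cidx.max() + 1, p))
        np.add.at(G, cidx, U)
        fit.cov_robust = cov @ (G.T @ G) @ cov
    return fit
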