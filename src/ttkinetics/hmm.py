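"""Two-state Poisson hidden Markov model for transcription-unit segmentation.

Binned labeled-RNA counts are modeled as a binary HMM with states
``inactive`` (state 0, low Poisson rate) and ``active`` (state 1, high rate).
Fitting is plain Baum-Welch on scaled forward-backward recursions; after
fitting, states are relabeled so that state 1 always carries the larger
emission mean.

An optional log-normal random effect on the Poisson rate (a common way to
absorb overdispersion in genomic count data) is approximated by a 5-point
Gauss-Hermite mixture; with ``sigma=0`` the model is exactly Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp


def _hermite_nodes(sigma: float, n: int = 5):
    """Nodes/weights so that rate multipliers have mean 1 under the mixture."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    mult = np.exp(sigma * x - 0.5 * sigma**2)
    return mult, w / w.sum()


@dataclass
class PoissonHMM:
    """Binary Poisson(-log-normal) HMM with Baum-Welch fitting.

    Parameters
    ----------
    rates : per-state Poisson means, state 0 = inactive, state 1 = active.
    transmat : 2x2 row-stochastic transition matrix.
    startprob : initial state distribution.
    sigma : log-normal SD of the per-bin rate multiplier (0 = pure Poisson).
    """

    rates: np.ndarray = field(default_factory=lambda: np.array([0.1, 2.0]))
    transmat: np.ndarray = field(
        default_factory=lambda: np.array([[0.99, 0.01], [0.01, 0.99]])
    )
    startprob: np.ndarray = field(default_factory=lambda: np.array([0.9, 0.1]))
    sigma: float = 0.0
    converged_: bool = False
    loglik_path_: list = field(default_factory=list)

    def _log_emission(self, counts: np.ndarray) -> np.ndarray:
        """(n_bins, 2) log emission probabilities."""
        counts = np.asarray(counts)
        rates = np.maximum(self.rates, 1e-12)
        base = -gammaln(counts + 1.0)[:, None]
        if self.sigma <= 0:
            return base + counts[:, None] * np.log(rates)[None, :] - rates[None, :]
        mult, w = _hermite_nodes(self.sigma)
        lam = rates[None, :, None] * mult[None, None, :]  # (1, 2, 5)
        lp = (
            counts[:, None, None] * np.log(lam)
            - lam
            - gammaln(counts + 1.0)[:, None, None]
            + np.log(w)[None, None, :]
        )
        return logsumexp(lp, axis=2)

    def _forward_backward(self, counts: np.ndarray):
        """Scaled forward-backward. Returns (loglik, gamma, xi_sum)."""
        logb = self._log_emission(counts)
        b = np.exp(logb - logb.max(axis=1, keepdims=True))
        n = len(counts)
        A = self.transmat
        alpha = np.empty((n, 2))
        scale = np.empty(n)
        alpha[0] = self.startprob * b[0]
        scale[0] = alpha[0].sum()
        alpha[0] /= scale[0]
        for t in range(1, n):
            alpha[t] = (alpha[t - 1] @ A) * b[t]
            scale[t] = alpha[t].sum()
            alpha[t] /= scale[t]
        beta = np.empty((n, 2))
        beta[-1] = 1.0
        for t in range(n - 2, -1, -1):
            beta[t] = (A @ (b[t + 1] * beta[t + 1])) / scale[t + 1]
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi_sum = np.zeros((2, 2))
        for t in range(n - 1):
            xi = A * np.outer(alpha[t], b[t + 1] * beta[t + 1]) / scale[t + 1]
            xi_sum += xi
        loglik = float(np.log(scale).sum() + logb.max(axis=1).sum())
        return loglik, gamma, xi_sum

    def loglik(self, counts) -> float:
        return self._forward_backward(np.asarray(counts))[0]

    def posterior(self, counts) -> np.ndarray:
        """Per-bin posterior probability of the active state."""
        return self._forward_backward(np.asarray(counts))[1][:, 1]

    def _init_from_data(self, sequences: list[np.ndarray]) -> None:
        allc = np.concatenate(sequences)
        nonzero = allc[allc > 0]
        if len(nonzero) == 0:
            self.rates = np.array([1e-6, 1e-6])
            return
        lo = max(np.percentile(nonzero, 25) * 0.1, 1e-3)
        hi = max(np.percentile(nonzero, 90), lo * 2)
        self.rates = np.array([lo, hi])

    def fit(self, counts, max_iter: int = 100, tol: float = 1e-6) -> "PoissonHMM":
        """Baum-Welch EM over one count sequence or a list of sequences.

        The log-likelihood is non-decreasing over iterations; convergence is
        declared when the improvement drops below ``tol``. An all-zero input
        collapses to a single inactive state (no error).
        """
        sequences = (
            [np.asarray(s, dtype=float) for s in counts]
            if isinstance(counts, (list, tuple))
            else [np.asarray(counts, dtype=float)]
        )
        total_bins = sum(len(s) for s in sequences)
        if total_bins == 0:
            raise ValueError("no bins to fit")
        if all((s == 0).all() for s in sequences):
            self.rates = np.array([0.0, 0.0])
            self.converged_ = True
            return self
        self._init_from_data(sequences)
        self.loglik_path_ = []
        prev = -np.inf
        for _ in range(max_iter):
            ll = 0.0
            g_sum = np.zeros(2)
            gc_sum = np.zeros(2)
            xi_tot = np.zeros((2, 2))
            start = np.zeros(2)
            for seq in sequences:
                l, gamma, xi = self._forward_backward(seq)
                ll += l
                g_sum += gamma.sum(axis=0)
                gc_sum += gamma.T @ seq
                xi_tot += xi
                start += gamma[0]
            self.loglik_path_.append(ll)
            if ll - prev < tol and np.isfinite(prev):
                self.converged_ = True
                break
            prev = ll
            self.rates = gc_sum / np.maximum(g_sum, 1e-300)
            self.transmat = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), 1e-300)
            self.startprob = start / start.sum()
        if self.rates[1] < self.rates[0]:  # relabel: state 1 = larger mean
            self.rates = self.rates[::-1].copy()
            self.transmat = self.transmat[::-1, ::-1].copy()
            self.startprob = self.startprob[::-1].copy()
        return self
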