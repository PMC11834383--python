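"""Compiled kernel for the yearly multivariate-normal log-likelihood.

The estimator maximises  sum_t log MVN(y_t; 0, Sigma_t)  where Sigma_t has
unit diagonal and off-diagonal entries rho(d_ij). Panels are packed into flat
arrays grouped by observation pattern (years observing the same population
set share Sigma_t, so one Cholesky factor serves all of them); the kernel is
numba-compiled because the parametric bootstrap needs on the order of 1e5
likelihood evaluations per fit-and-bootstrap cycle.

A plain numpy reference implementation (`loglik_reference`) of the same
quantity, computed year by year with explicit matrix inverses, is kept for
cross-checking.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))
_JITTER = 1e-8


class PackedPanel:
    """Flat-array view of a PanelData/SiteGeometry pair for the kernel."""

    def __init__(self, panel, geometry):
        from .panel import check_alignment

        geo_idx = check_alignment(panel, geometry)
        sizes, kcounts = [], []
        d2_parts, y_parts = [], []
        self._placements = []  # (pop_idx, year_cols) to refill y after simulation
        for pat in panel.patterns:
            n = len(pat.pop_idx)
            k = len(pat.year_cols)
            gi = geo_idx[pat.pop_idx]
            d = geometry.distance_km[np.ix_(gi, gi)]
            d2_parts.append((d * d).ravel())
            block = panel.normalised[np.ix_(pat.pop_idx, pat.year_cols)]
            y_parts.append(block.ravel())
            sizes.append(n)
            kcounts.append(k)
            self._placements.append((pat.pop_idx, pat.year_cols))
        self.sizes = np.asarray(sizes, dtype=np.int64)
        self.kcounts = np.asarray(kcounts, dtype=np.int64)
        self.d2_flat = np.concatenate(d2_parts) if d2_parts else np.empty(0)
        self.y_flat = np.concatenate(y_parts) if y_parts else np.empty(0)
        self.d2_off = np.concatenate([[0], np.cumsum(self.sizes ** 2)]).astype(np.int64)
        self.y_off = np.concatenate([[0], np.cumsum(self.sizes * self.kcounts)]).astype(np.int64)
        self.n_patterns = len(sizes)
        self.shape = panel.values.shape

    def refill(self, normalised: np.ndarray) -> np.ndarray:
        """New y_flat from a (re-normalised) panel matrix, same patterns."""
        parts = [normalised[np.ix_(pi, yc)].ravel() for pi, yc in self._placements]
        return np.concatenate(parts) if parts else np.empty(0)


@njit(cache=True)
def _nll_packed(rho0, rho_inf, l, sizes, kcounts, d2_flat, d2_off, y_flat, y_off):
    """Negative total log-likelihood; large finite value if Cholesky fails."""
    total = 0.0
    inv_2l2 = 1.0 / (2.0 * l * l)
    for p in range(sizes.shape[0]):
        n = sizes[p]
        k = kcounts[p]
        C = np.empty((n, n))
        base = d2_off[p]
        for i in range(n):
            for j in range(n):
                d2 = d2_flat[base + i * n + j]
                if i == j:
                    C[i, j] = 1.0
                else:
                    C[i, j] = rho_inf + (rho0 - rho_inf) * np.exp(-d2 * inv_2l2)
        # in-place Cholesky, one jitter retry on failure
        ok = _chol(C, n)
        if not ok:
            for i in range(n):
                for j in range(n):
                    d2 = d2_flat[base + i * n + j]
                    if i == j:
                        C[i, j] = 1.0 + _JITTER
                    else:
                        C[i, j] = rho_inf + (rho0 - rho_inf) * np.exp(-d2 * inv_2l2)
            ok = _chol(C, n)
            if not ok:
                return 1e12
        logdet = 0.0
        for i in range(n):
            logdet += 2.0 * np.log(C[i, i])
        quad = 0.0
        ybase = y_off[p]
        z = np.empty(n)
        for t in range(k):
            for i in range(n):
                s = y_flat[ybase + i * k + t]
                for j in range(i):
                    s -= C[i, j] * z[j]
                z[i] = s / C[i, i]
            for i in range(n):
                quad += z[i] * z[i]
        total += -0.5 * (k * (n * LOG_2PI + logdet) + quad)
    return -total


@njit(cache=True)
def _chol(C, n):
    """Lower-triangular Cholesky of C in place; False if not PD."""
    for j in range(n):
        s = C[j, j]
        for kk in range(j):
            s -= C[j, kk] * C[j, kk]
        if s <= 0.0:
            return False
        C[j, j] = np.sqrt(s)
        for i in range(j + 1, n):
            s = C[i, j]
            for kk in range(j):
                s -= C[i, kk] * C[j, kk]
            C[i, j] = s / C[j, j]
    return True


def nll_packed(rho0: float, rho_inf: float, l: float, packed: PackedPanel,
               y_flat: np.ndarray | None = None) -> float:
    y = packed.y_flat if y_flat is None else y_flat
    return float(
        _nll_packed(rho0, rho_inf, l, packed.sizes, packed.kcounts,
                    packed.d2_flat, packed.d2_off, y, packed.y_off)
    )


def loglik_reference(rho0, rho_inf, l, panel, geometry) -> float:
    """Year-by-year reference: explicit Sigma_t inverse and determinant."""
    from .panel import check_alignment

    geo_idx = check_alignment(panel, geometry)
    total = 0.0
    obs = ~np.isnan(panel.normalised)
    for t in range(panel.values.shape[1]):
        idx = np.flatnonzero(obs[:, t])
        if len(idx) < 2:
            continue
        gi = geo_idx[idx]
        d = geometry.distance_km[np.ix_(gi, gi)]
        sigma = rho_inf + (rho0 - rho_inf) * np.exp(-(d ** 2) / (2.0 * l ** 2))
        np.fill_diagonal(sigma, 1.0)
        y = panel.normalised[idx, t]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return -np.inf
        quad = y @ np.linalg.inv(sigma) @ y
        total += -0.5 * (len(idx) * LOG_2PI + logdet + quad)
    return float(total)
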