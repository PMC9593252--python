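"""Time-resolved cluster-state dynamics.

A live two-color acquisition, sliced into fixed-duration windows and
cropped to one cluster ROI (1.5 x 1.5 um), yields per-window features for
each species: molecular density (per um^2), the short-range
self-clustering summary g(0-100), and the short-range extent of mixing.
On the pooled 2D density-clustering feature cloud a 3-component Gaussian
mixture defines discrete states (1 = dispersed: low density, low g;
2 = dense but unclustered; 3 = dense and clustered), and a row-stochastic
3x3 Markov transition matrix is estimated from the state sequences at the
window lag (5 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ParameterError,
)
from .paircorr import (
    RadialBins,
    bpcf,
    eom,
    mean_eom_short,
    mean_g_short,
    pcf,
    rl_envelope,
)
from .patterns import PointPattern, Window, crop_roi

N_STATES = 3


@dataclass
class ClusterTrajectory:
    """Per-window (density, g(0-100), EOM) features for one cluster ROI."""

    roi: Window
    times: np.ndarray  # s, strictly increasing
    density_a: np.ndarray  # molecules / um^2
    density_b: np.ndarray
    g_a: np.ndarray  # g(0-100); NaN where undefined (< 2 points)
    g_b: np.ndarray
    eom_short: np.ndarray  # mean EOM over r < 100 nm; NaN where undefined

    def __post_init__(self) -> None:
        lengths = {
            len(self.times),
            len(self.density_a),
            len(self.density_b),
            len(self.g_a),
            len(self.g_b),
            len(self.eom_short),
        }
        if len(lengths) != 1:
            raise ParameterError("all trajectory series must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.times)

    def features(self, species: str = "both") -> np.ndarray:
        """(density, g) observations with defined g, for state-model fitting."""
        cols = []
        if species in ("a", "both"):
            cols.append(np.column_stack([self.density_a, self.g_a]))
        if species in ("b", "both"):
            cols.append(np.column_stack([self.density_b, self.g_b]))
        if not cols:
            raise ParameterError("species must be 'a', 'b' or 'both'")
        obs = np.vstack(cols)
        return obs[np.isfinite(obs).all(axis=1)]


def extract_trajectory(
    windows_a: Sequence[PointPattern],
    windows_b: Sequence[PointPattern],
    roi: Window,
    bins: Optional[RadialBins] = None,
    n_sims: int = 19,
    seed=None,
    edge_correction: str = "translation",
    compute_eom: bool = True,
) -> ClusterTrajectory:
    """Crop each time window to the ROI and extract per-window features.

    Windows with fewer than 2 points give NaN for g; windows where either
    species is empty give NaN for the EOM summary (missing, not imputed).
    """
    if len(windows_a) != len(windows_b):
        raise ParameterError("species windows must have equal counts")
    if not len(windows_a):
        raise ParameterError("need at least one window")
    bins = bins or RadialBins.linear(r_max=200.0, width=10.0)
    rng = np.random.default_rng(seed)
    n = len(windows_a)
    times = np.empty(n)
    dens_a, dens_b = np.empty(n), np.empty(n)
    g_a, g_b, eoms = np.full(n, np.nan), np.full(n, np.nan), np.full(n, np.nan)
    for k, (wa, wb) in enumerate(zip(windows_a, windows_b)):
        ca, cb = crop_roi(wa, roi), crop_roi(wb, roi)
        times[k] = wa.t_start if wa.t_start is not None else float(k)
        dens_a[k], dens_b[k] = ca.density, cb.density
        if ca.n >= 2:
            g_a[k] = mean_g_short(pcf(ca, bins, edge_correction))
        if cb.n >= 2:
            g_b[k] = mean_g_short(pcf(cb, bins, edge_correction))
        if compute_eom and ca.n >= 1 and cb.n >= 1 and ca.n + cb.n >= 2:
            env = rl_envelope(ca, cb, bins, n_sims=n_sims, seed=rng, edge_correction=edge_correction)
            curve = eom(bpcf(ca, cb, bins, edge_correction), env)
            eoms[k] = mean_eom_short(curve)
    return ClusterTrajectory(roi, times, dens_a, dens_b, g_a, g_b, eoms)


def synchrony(traj: ClusterTrajectory, feature: str = "density") -> float:
    """Pearson correlation between the two species' per-window series of the
    chosen feature ('density' or 'g'), over pairwise-complete windows."""
    if feature == "density":
        xa, xb = traj.density_a, traj.density_b
    elif feature == "g":
        xa, xb = traj.g_a, traj.g_b
    else:
        raise ParameterError("feature must be 'density' or 'g'")
    mask = np.isfinite(xa) & np.isfinite(xb)
    if mask.sum() < 3:
        raise InsufficientDataError("synchrony needs >= 3 paired defined values")
    xa, xb = xa[mask], xb[mask]
    if np.var(xa) == 0 or np.var(xb) == 0:
        raise DegenerateDataError("synchrony undefined for a constant series")
    return float(stats.pearsonr(xa, xb).statistic)


# ---------------------------------------------------------------------------
# 3-state Gaussian mixture on the density-clustering map


@dataclass
class StateModel:
    """3-component GMM over (density, g(0-100)) with a fixed label convention.

    State 1 = lowest density; of the two denser components, state 2 has the
    lower and state 3 the higher mean g.  Component parameters are stored in
    the original (unstandardized) feature units, ordered by state.
    """

    means: np.ndarray  # (3, 2), state-ordered, original units
    covariances: np.ndarray  # (3, 2, 2)
    weights: np.ndarray  # (3,)
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    _gmm: GaussianMixture
    _state_of_component: np.ndarray  # component index -> state label (1..3)

    @property
    def n_states(self) -> int:
        return N_STATES

    def predict(self, observations: np.ndarray) -> np.ndarray:
        """State labels in {1, 2, 3} for (density, g) observations."""
        obs = np.asarray(observations, dtype=float)
        z = (obs - self.scaler_mean) / self.scaler_std
        comp = self._gmm.predict(z)
        return self._state_of_component[comp]


def fit_state_model(observations: np.ndarray, seed: Optional[int] = None) -> StateModel:
    """Fit the 3-state Gaussian mixture on standardized (density, g) features.

    Density and g differ by orders of magnitude, so features are z-scored
    before the fit; full covariances, 10 restarts, deterministic under a
    fixed seed.  Components are relabeled to the state convention so labels
    do not depend on the fit's internal component order.
    """
    obs = np.asarray(observations, dtype=float)
    obs = obs[np.isfinite(obs).all(axis=1)]
    if obs.shape[0] < 30:
        raise InsufficientDataError("state model needs >= 30 defined observations")
    mean = obs.mean(axis=0)
    std = obs.std(axis=0)
    if np.any(std == 0):
        raise DegenerateDataError("degenerate features: zero variance")
    z = (obs - mean) / std
    gmm = GaussianMixture(
        n_components=N_STATES,
        covariance_type="full",
        n_init=10,
        random_state=None if seed is None else int(seed),
    ).fit(z)
    means_orig = gmm.means_ * std + mean
    covs_orig = gmm.covariances_ * np.outer(std, std)
    # label convention: lowest density -> 1; remaining by ascending g -> 2, 3
    order = np.argsort(means_orig[:, 0])
    low = order[0]
    rest = sorted(order[1:], key=lambda c: means_orig[c, 1])
    comp_order = [low, rest[0], rest[1]]
    state_of_component = np.empty(N_STATES, dtype=int)
    for state_idx, comp in enumerate(comp_order, start=1):
        state_of_component[comp] = state_idx
    return StateModel(
        means=means_orig[comp_order],
        covariances=covs_orig[comp_order],
        weights=gmm.weights_[comp_order],
        scaler_mean=mean,
        scaler_std=std,
        _gmm=gmm,
        _state_of_component=state_of_component,
    )


# ---------------------------------------------------------------------------
# Markov transition estimation


@dataclass
class MarkovEstimate:
    matrix: np.ndarray  # 3x3 row-stochastic
    counts: np.ndarray  # raw transition counts
    uniform_rows: np.ndarray  # states whose row had zero counts (uniform fill)

    @property
    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector of the matrix)."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        return pi / pi.sum()


def transition_matrix(state_sequences: Sequence[Sequence[int]]) -> MarkovEstimate:
    """Maximum-likelihood transition matrix pooled over state sequences.

    Transitions between consecutive windows are counted across all
    sequences and each row normalized; a state never left in the data gets
    a uniform row and is flagged.
    """
    counts = np.zeros((N_STATES, N_STATES))
    any_seq = False
    for seq in state_sequences:
        s = np.asarray(seq, dtype=int)
        if s.size < 2:
            raise ParameterError("each state sequence needs length >= 2")
        if np.any((s < 1) | (s > N_STATES)):
            raise ParameterError("state labels must be in {1, 2, 3}")
        np.add.at(counts, (s[:-1] - 1, s[1:] - 1), 1)
        any_seq = True
    if not any_seq:
        raise ParameterError("need at least one sequence")
    row_sums = counts.sum(axis=1)
    uniform_rows = np.flatnonzero(row_sums == 0) + 1
    matrix = np.where(
        row_sums[:, None] > 0,
        counts / np.maximum(row_sums[:, None], 1),
        1.0 / N_STATES,
    )
    return MarkovEstimate(matrix=matrix, counts=counts, uniform_rows=uniform_rows)


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class TTestSummary:
    t: float
    p: float
    mean_x: float
    mean_y: float
    sem_x: float
    sem_y: float
    n_x: int
    n_y: int


def compare_groups(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TTestSummary:
    """Two-tailed two-sample Student's t test (Welch correction optional),
    with per-group mean and SEM."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise DegenerateDataError("t test undefined with zero combined variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestSummary(
        t=float(res.statistic),
        p=float(res.pvalue),
        mean_x=float(x.mean()),
        mean_y=float(y.mean()),
        sem_x=float(stats.sem(x)),
        sem_y=float(stats.sem(y)),
        n_x=int(x.size),
        n_y=int(y.size),
    )
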