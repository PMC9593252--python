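"""Synthetic localization data with known ground truth.

Every analysis stage in this package assumes a particular statistical
structure in its input; the generators here produce exactly those
structures so recovery can be tested against programmed truth:

- homogeneous Poisson backgrounds (the complete-spatial-randomness null),
- Thomas-process nanoclusters (Poisson parents, Gaussian offspring; the
  analytic pair correlation of this process serves as an oracle),
- bivariate patterns spanning perfect mixing (random labeling) to
  independence, with a tunable mixing fraction,
- peripheral (annular) enrichment of one species around the clusters of
  another,
- two-species patterns with a programmed fold enrichment inside domains,
- photoblinking emitter movies over many camera frames, and
- time-evolving cluster assembly/disassembly driven by a latent 3-state
  Markov chain.

All generators take a ``seed`` (int or numpy Generator) and are
bit-reproducible under a fixed seed.  Densities are molecules per square
micrometre; coordinates nanometres.  Cluster offspring are wrapped
periodically into the window, which keeps the marginal intensity uniform
and matches the periodic edge mode of the pair-correlation estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely

from .domains import DomainParams, DomainSet, domain_polygons, find_domains
from .errors import ParameterError
from .io_preprocess import LocalizationTable
from .patterns import NM2_PER_UM2, PointPattern, Window


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_in(window: Window, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(window.origin, window.origin + window.sizes, size=(n, 2))


def _wrap(points: np.ndarray, window: Window) -> np.ndarray:
    return (points - window.origin) % window.sizes + window.origin


# ---------------------------------------------------------------------------
# homogeneous Poisson


def gen_poisson(
    density: float = 100.0,
    window: Window = None,
    seed=None,
    label: str = "",
) -> PointPattern:
    """Homogeneous Poisson pattern: count ~ Poisson(density * area), uniform
    positions.  ``density`` in molecules per um^2."""
    window = window or Window.square(10_000.0)
    if density <= 0:
        raise ParameterError("density must be > 0")
    if window.area_nm2 <= 0:
        raise ParameterError("window must have positive area")
    rng = _rng(seed)
    n = rng.poisson(density * window.area_um2)
    return PointPattern(_uniform_in(window, n, rng), window, label=label)


# ---------------------------------------------------------------------------
# Thomas clusters


def _thomas_clusters(
    window: Window,
    parent_density: float,
    mean_offspring: float,
    sigma: float,
    rng: np.random.Generator,
) -> Tuple[List[np.ndarray], np.ndarray]:
    """Per-parent offspring position arrays (wrapped into the window)."""
    if parent_density <= 0 or mean_offspring <= 0 or sigma <= 0:
        raise ParameterError("parent_density, mean_offspring and sigma must be > 0")
    n_parents = rng.poisson(parent_density * window.area_um2)
    parents = _uniform_in(window, n_parents, rng)
    clusters = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        offspring = p + rng.normal(0.0, sigma, size=(k, 2))
        clusters.append(_wrap(offspring, window))
    return clusters, parents


def gen_thomas(
    parent_density: float = 2.0,
    mean_offspring: float = 20.0,
    sigma: float = 30.0,
    window: Window = None,
    seed=None,
    label: str = "",
) -> PointPattern:
    """Thomas process: Poisson parents (per um^2), Poisson(mean_offspring)
    children displaced by an isotropic Gaussian of scale ``sigma`` nm;
    parents are discarded."""
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    clusters, _ = _thomas_clusters(window, parent_density, mean_offspring, sigma, rng)
    pts = np.vstack(clusters) if clusters else np.empty((0, 2))
    return PointPattern(pts, window, label=label)


def thomas_pcf_theory(r: np.ndarray, parent_density: float, sigma: float) -> np.ndarray:
    """Closed-form pair correlation of the Thomas process:
    g(r) = 1 + exp(-r^2 / (4 sigma^2)) / (4 pi sigma^2 kappa),
    with kappa the parent intensity (converted here from per-um^2 to per-nm^2).
    """
    kappa_nm2 = parent_density / NM2_PER_UM2
    r = np.asarray(r, dtype=float)
    return 1.0 + np.exp(-(r**2) / (4 * sigma**2)) / (4 * np.pi * sigma**2 * kappa_nm2)


# ---------------------------------------------------------------------------
# bivariate mixing


def gen_random_label_mix(
    mixing_fraction: float = 1.0,
    parent_density: float = 2.0,
    mean_offspring: float = 20.0,
    sigma: float = 30.0,
    window: Window = None,
    seed=None,
) -> Tuple[PointPattern, PointPattern]:
    """Two-species clustered pattern with a tunable degree of mixing.

    A fraction ``mixing_fraction`` of the Thomas clusters is mixed (each
    point labeled species A or B independently with probability 1/2); the
    remaining clusters are single-label (whole cluster A or B with
    probability 1/2).  mixing_fraction = 1 is exact per-point random
    labeling of the parent pattern (EOM -> 1); 0 gives independent
    single-species cluster sets (EOM -> 0).
    """
    if not (0.0 <= mixing_fraction <= 1.0):
        raise ParameterError("mixing_fraction must be in [0, 1]")
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    clusters, _ = _thomas_clusters(window, parent_density, mean_offspring, sigma, rng)
    pts_a, pts_b = [], []
    for cluster in clusters:
        if cluster.shape[0] == 0:
            continue
        if rng.uniform() < mixing_fraction:
            lab = rng.integers(0, 2, size=cluster.shape[0])
            pts_a.append(cluster[lab == 0])
            pts_b.append(cluster[lab == 1])
        elif rng.uniform() < 0.5:
            pts_a.append(cluster)
        else:
            pts_b.append(cluster)
    a = np.vstack(pts_a) if pts_a else np.empty((0, 2))
    b = np.vstack(pts_b) if pts_b else np.empty((0, 2))
    return PointPattern(a, window, label="A"), PointPattern(b, window, label="B")


def gen_independent_pair(
    parent_density: float = 2.0,
    mean_offspring: float = 20.0,
    sigma: float = 30.0,
    window: Window = None,
    seed=None,
) -> Tuple[PointPattern, PointPattern]:
    """Two independently generated Thomas patterns sharing one window."""
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    a = gen_thomas(parent_density, mean_offspring, sigma, window, rng, label="A")
    b = gen_thomas(parent_density, mean_offspring, sigma, window, rng, label="B")
    return a, b


# ---------------------------------------------------------------------------
# peripheral enrichment


def gen_periphery(
    parent_density: float = 1.0,
    mean_offspring: float = 20.0,
    sigma: float = 30.0,
    annulus_inner: float = 60.0,
    annulus_outer: float = 100.0,
    n_target: int = 500,
    background_fraction: float = 0.0,
    window: Window = None,
    seed=None,
) -> Tuple[PointPattern, PointPattern]:
    """Species A = Thomas clusters; species B placed uniformly on annuli
    around the cluster centres (peripheral enrichment) plus a uniform
    background fraction.  background_fraction = 1 reduces to an
    independent uniform target."""
    if annulus_inner >= annulus_outer:
        raise ParameterError("annulus_inner must be < annulus_outer")
    if not (0.0 <= background_fraction <= 1.0):
        raise ParameterError("background_fraction must be in [0, 1]")
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    clusters, parents = _thomas_clusters(window, parent_density, mean_offspring, sigma, rng)
    a_pts = np.vstack([c for c in clusters if c.shape[0]]) if clusters else np.empty((0, 2))
    b_pts = np.empty((n_target, 2))
    on_bg = rng.uniform(size=n_target) < background_fraction
    n_bg = int(on_bg.sum())
    b_pts[on_bg] = _uniform_in(window, n_bg, rng)
    n_ring = n_target - n_bg
    if n_ring and parents.shape[0] == 0:
        raise ParameterError("no clusters generated; cannot place annular target points")
    if n_ring:
        centers = parents[rng.integers(0, parents.shape[0], size=n_ring)]
        radii = np.sqrt(rng.uniform(annulus_inner**2, annulus_outer**2, size=n_ring))
        theta = rng.uniform(0, 2 * np.pi, size=n_ring)
        ring = centers + radii[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        b_pts[~on_bg] = _wrap(ring, window)
    return (
        PointPattern(a_pts, window, label="A"),
        PointPattern(b_pts, window, label="B"),
    )


# ---------------------------------------------------------------------------
# domain enrichment


@dataclass
class DomainEnrichmentTruth:
    domains: DomainSet
    programmed_fold: float
    realized_fold: float
    n_in: int
    n_out: int


def gen_domain_enrichment(
    fold: float = 10.0,
    probe_density_out: float = 20.0,
    parent_density: float = 1.0,
    mean_offspring: float = 15.0,
    sigma: float = 30.0,
    domain_params: Optional[DomainParams] = None,
    window: Window = None,
    seed=None,
) -> Tuple[PointPattern, PointPattern, DomainEnrichmentTruth]:
    """Species A forms Thomas domains; species B is Poisson with intensity
    ``probe_density_out`` outside the domain polygons and ``fold`` times
    that inside.  The realized fold is recorded as ground truth."""
    if fold < 0:
        raise ParameterError("fold must be >= 0")
    if probe_density_out <= 0:
        raise ParameterError("probe_density_out must be > 0")
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    a = gen_thomas(parent_density, mean_offspring, sigma, window, rng, label="A")
    ds = domain_polygons(find_domains(a, domain_params or DomainParams()))
    if ds.domain_union is None:
        raise ParameterError("no polygonal domains formed; increase cluster parameters")
    shapely.prepare(ds.domain_union)
    area_in = ds.total_domain_area_um2
    area_out = window.area_um2 - area_in
    n_in = rng.poisson(fold * probe_density_out * area_in)
    n_out = rng.poisson(probe_density_out * area_out)
    b_in = _rejection_sample(window, ds.domain_union, n_in, rng, inside=True)
    b_out = _rejection_sample(window, ds.domain_union, n_out, rng, inside=False)
    b = PointPattern(np.vstack([b_in, b_out]), window, label="B")
    realized = (n_in / area_in) / (n_out / area_out) if n_out else float("inf")
    truth = DomainEnrichmentTruth(ds, fold, realized, n_in, n_out)
    return a, b, truth


def _rejection_sample(window, union, n: int, rng: np.random.Generator, inside: bool) -> np.ndarray:
    """Uniform points in (or outside) a prepared geometry, by rejection."""
    out = np.empty((0, 2))
    if n == 0:
        return out
    # guard against pathological acceptance rates
    for _ in range(10_000):
        batch = max(4 * n, 1024)
        cand = _uniform_in(window, batch, rng)
        keep = shapely.covers(union, shapely.points(cand))
        if not inside:
            keep = ~keep
        out = np.vstack([out, cand[keep]])
        if out.shape[0] >= n:
            return out[:n]
    raise ParameterError("rejection sampling failed to reach the requested count")


# ---------------------------------------------------------------------------
# blinking movies


def gen_blinking_movie(
    n_emitters: int = 200,
    n_frames: int = 12_000,
    fps: float = 50.0,
    mean_bursts: float = 3.0,
    mean_burst_len: float = 2.0,
    max_off_gap: int = 3,
    jitter_sigma: float = 20.0,
    window: Window = None,
    seed=None,
) -> LocalizationTable:
    """Photoblinking emitters over a camera acquisition.

    Each ground-truth molecule sits at a fixed position and emits in
    on-bursts (lengths 1 + Poisson(mean_burst_len - 1) frames) separated by
    off-gaps of 1..max_off_gap frames (contiguous if max_off_gap = 0); each
    per-frame appearance is localized with isotropic Gaussian jitter.  The
    ground-truth emitter id is kept in an ``emitter`` column so grouping
    recovery can be validated.
    """
    window = window or Window.square(10_000.0)
    rng = _rng(seed)
    positions = _uniform_in(window, n_emitters, rng)
    rows = []
    for eid in range(n_emitters):
        n_bursts = 1 + rng.poisson(max(mean_bursts - 1.0, 0.0))
        frame = int(rng.integers(1, max(n_frames // 2, 2)))
        for b in range(n_bursts):
            length = 1 + rng.poisson(max(mean_burst_len - 1.0, 0.0))
            for _ in range(length):
                if frame > n_frames:
                    break
                jitter = rng.normal(0.0, jitter_sigma, size=2) if jitter_sigma > 0 else np.zeros(2)
                xy = np.clip(
                    positions[eid] + jitter,
                    window.origin,
                    window.origin + window.sizes,
                )
                rows.append((frame, xy[0], xy[1], eid))
                frame += 1
            gap = int(rng.integers(1, max_off_gap + 1)) if max_off_gap >= 1 else 0
            frame += gap
    df = pd.DataFrame(rows, columns=["frame", "x", "y", "emitter"])
    return LocalizationTable(data=df, window=window, acquisition_fps=fps, n_frames=n_frames)


# ---------------------------------------------------------------------------
# dynamic assembly (3-state Markov)


DEFAULT_TRANSITION = np.array(
    [
        [0.90, 0.05, 0.05],
        [0.15, 0.70, 0.15],
        [0.10, 0.10, 0.80],
    ]
)

#: per-state (background density per um^2, mean cluster size, cluster sigma nm)
DEFAULT_STATE_PARAMS = {
    1: (10.0, 0.0, 50.0),  # dispersed, low density, no cluster
    2: (55.0, 0.0, 50.0),  # dense but unclustered
    3: (10.0, 100.0, 50.0),  # dense and clustered
}


def _check_stochastic(P: np.ndarray) -> np.ndarray:
    P = np.asarray(P, dtype=float)
    if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0):
        raise ParameterError("transition matrix must be 3x3 row-stochastic")
    return P


def simulate_markov_chain(
    P: np.ndarray,
    n_steps: int,
    seed=None,
    init: Optional[Sequence[float]] = None,
) -> np.ndarray:
    """Sample a chain of labels in {1, 2, 3} from a row-stochastic matrix."""
    P = _check_stochastic(P)
    rng = _rng(seed)
    pi0 = np.asarray(init, dtype=float) if init is not None else np.full(3, 1 / 3)
    states = np.empty(n_steps, dtype=int)
    states[0] = rng.choice(3, p=pi0 / pi0.sum()) + 1
    for t in range(1, n_steps):
        states[t] = rng.choice(3, p=P[states[t - 1] - 1]) + 1
    return states


@dataclass
class DynamicAssembly:
    """Ground truth for a simulated live acquisition of co-assembling clusters."""

    chains: List[List[Tuple[PointPattern, PointPattern]]]  # per chain, per window (a, b)
    states: List[np.ndarray]  # latent labels in {1,2,3}
    transition: np.ndarray
    roi: Window


def gen_dynamic_assembly(
    transition: np.ndarray = None,
    n_windows: int = 48,
    n_chains: int = 1,
    state_params=None,
    roi: Window = None,
    dt: float = 5.0,
    seed=None,
) -> DynamicAssembly:
    """Two-species cluster ROIs evolving under a latent 3-state Markov chain.

    Each 5-s window draws both species from the current state's parameters:
    a uniform background plus (in the clustered state) a Gaussian cluster at
    the ROI centre.  Both species share the latent state, which couples
    their density and self-clustering series the way co-assembling clusters
    do.  Returns ground-truth labels for recovery tests.
    """
    P = _check_stochastic(DEFAULT_TRANSITION if transition is None else transition)
    roi = roi or Window.square(1500.0)
    params = state_params or DEFAULT_STATE_PARAMS
    rng = _rng(seed)
    chains, all_states = [], []
    for _ in range(n_chains):
        states = simulate_markov_chain(P, n_windows, rng)
        windows = []
        for t, s in enumerate(states):
            pair = []
            for label in ("A", "B"):
                bg_density, cluster_size, sigma = params[int(s)]
                n_bg = rng.poisson(bg_density * roi.area_um2)
                pts = [_uniform_in(roi, n_bg, rng)]
                if cluster_size > 0:
                    k = rng.poisson(cluster_size)
                    center = roi.origin + roi.sizes / 2
                    pts.append(_wrap(center + rng.normal(0, sigma, size=(k, 2)), roi))
                pat = PointPattern(
                    np.vstack(pts), roi, label=label, t_start=t * dt, t_end=(t + 1) * dt
                )
                pair.append(pat)
            windows.append(tuple(pair))
        chains.append(windows)
        all_states.append(states)
    return DynamicAssembly(chains=chains, states=all_states, transition=P, roi=roi)


def gen_correlated_series(
    rho: float = 0.8,
    n: int = 48,
    mean: float = 50.0,
    sd: float = 10.0,
    seed=None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two series with programmed Pearson correlation ``rho`` (bivariate
    normal), emulating a shared recruitment driver with independent noise.
    Used to calibrate the synchrony estimator."""
    if not (-1.0 <= rho <= 1.0):
        raise ParameterError("rho must be in [-1, 1]")
    rng = _rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]]) * sd**2
    xy = rng.multivariate_normal([mean, mean], cov, size=n)
    return xy[:, 0], xy[:, 1]
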