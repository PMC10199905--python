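"""Mass-univariate statistics with cluster-based max-statistic permutation.

Samples live on a channel x frequency x time lattice; clusters are connected
components over spectral (adjacent frequency bins), temporal (adjacent time
bins) and spatial (sensor-neighborhood) adjacency among samples whose F or T
exceeds a parametric threshold at p < 0.05. Cluster mass is the sum of the
statistic over members; inference compares observed masses to the
permutation distribution of the maximum cluster mass (Monte-Carlo p with the
(1 + x) / (1 + N) estimator; ties counted as exceedances).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .montage import Montage

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyGraph:
    """Undirected sensor-neighbor relation from spherical distances."""

    labels: tuple[str, ...]
    neighbors: np.ndarray  # boolean, symmetric, zero diagonal
    threshold: float

    def __post_init__(self) -> None:
        nb = np.asarray(self.neighbors, dtype=bool)
        if nb.shape != (len(self.labels), len(self.labels)):
            raise ValueError("neighbor matrix shape mismatch")
        if not np.array_equal(nb, nb.T) or nb.diagonal().any():
            raise ValueError("neighbor matrix must be symmetric with no self-edges")
        self.neighbors = nb

    @property
    def degrees(self) -> np.ndarray:
        return self.neighbors.sum(axis=1)


def build_adjacency(montage: Montage, threshold: float = 0.85) -> AdjacencyGraph:
    """Sensors are neighbors iff their great-circle distance <= threshold (rad).

    The 0.85 rad default makes laterally adjacent 10-20 sites (e.g. Cz-C3)
    neighbors and yields a median degree of 4-8 on the 32-channel preset.
    Isolated sensors raise a warning, not an error.
    """
    if len(montage) < 2:
        raise ValueError("adjacency needs at least 2 sensors")
    cosang = np.clip(montage.positions @ montage.positions.T, -1.0, 1.0)
    dist = np.arccos(cosang)
    nb = (dist <= threshold) & ~np.eye(len(montage), dtype=bool)
    isolated = [montage.labels[i] for i in np.flatnonzero(nb.sum(axis=1) == 0)]
    if isolated:
        warnings.warn(f"isolated sensors under threshold {threshold}: {isolated}")
    return AdjacencyGraph(montage.labels, nb, threshold)


@dataclass
class StatMap:
    """Sample-wise F or T values with the cluster-forming threshold."""

    values: np.ndarray
    stat: str                    # "F" or "T"
    df: tuple
    threshold: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("statistic map must be finite")
        if self.stat == "F" and np.any(self.values < -1e-12):
            raise ValueError("F values must be non-negative")


@dataclass
class ClusterResult:
    """A connected set of supra-threshold (channel, freq, time) samples."""

    members: np.ndarray          # flat indices into the sample lattice
    mass: float
    sign: int                    # +1 / -1 for T, +1 for F
    shape: tuple                 # (n_channels, n_freqs, n_times)
    monte_carlo_p: float | None = None
    channels: tuple = ()
    freq_window: tuple = ()
    time_window: tuple = ()

    def member_mask(self) -> np.ndarray:
        m = np.zeros(int(np.prod(self.shape)), dtype=bool)
        m[self.members] = True
        return m.reshape(self.shape)

    def summarize(self, labels=None, freqs=None, times=None) -> "ClusterResult":
        ch, fr, ti = np.unravel_index(self.members, self.shape)
        if labels is not None:
            self.channels = tuple(sorted({labels[c] for c in ch},
                                         key=list(labels).index))
        if freqs is not None:
            self.freq_window = (float(freqs[fr.min()]), float(freqs[fr.max()]))
        if times is not None:
            self.time_window = (float(times[ti.min()]), float(times[ti.max()]))
        return self


# ---------------------------------------------------------------------------
# sample-wise statistics (vectorized over the trailing sample axes)

def samplewise_t(a: np.ndarray, b: np.ndarray, paired: bool = True) -> StatMap:
    """T map per sample; paired (dependent) or pooled independent samples.

    Zero-variance samples get T = 0 with a warning rather than +-inf.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired samples require identical shapes")
        d = a - b
        n = d.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        df = n - 1
        denom = sd / np.sqrt(n)
    else:
        n1, n2 = a.shape[0], b.shape[0]
        if n1 < 2 or n2 < 2:
            raise ValueError("need at least 2 observations per group")
        mean = a.mean(axis=0) - b.mean(axis=0)
        sp2 = ((n1 - 1) * a.var(axis=0, ddof=1)
               + (n2 - 1) * b.var(axis=0, ddof=1)) / (n1 + n2 - 2)
        df = n1 + n2 - 2
        denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    zero = denom <= 0
    if np.any(zero):
        logger.warning("%d samples with zero variance; T set to 0", zero.sum())
    t = np.where(zero, 0.0, mean / np.where(zero, 1.0, denom))
    thr = float(stats.t.ppf(0.975, df))
    return StatMap(t, "T", (df,), thr)


def _f_ratio(ss_eff, df1, ss_err, df2, scale):
    """F with a relative degeneracy floor: both SS ~ 0 (identical data up to
    rounding) gives F = 0 instead of a 0/0 artifact."""
    eps = 1e-12 * (np.asarray(scale) + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_eff / df1) / np.where(ss_err > eps, ss_err / df2, np.inf)
    f = np.where(ss_eff <= eps, 0.0, f)
    return np.nan_to_num(f, nan=0.0, posinf=0.0)


def _rm_oneway_f(data: np.ndarray):
    """Within-subject one-way ANOVA F per sample; data (S, C, ...)."""
    s, c = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)
    cond = data.mean(axis=0)
    ss_cond = s * ((cond - grand) ** 2).sum(axis=0)
    resid = data - subj[:, None] - cond[None] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df1, df2 = c - 1, (s - 1) * (c - 1)
    return _f_ratio(ss_cond, df1, ss_err, df2,
                    (data ** 2).sum(axis=(0, 1))), (df1, df2)


def _rm_twoway_f(data: np.ndarray):
    """Fully within-subject two-way ANOVA; data (S, A, B, ...samples).

    Returns {"A": (F, df), "B": ..., "AxB": ...} with each effect tested
    against its own subject-by-effect interaction error term.
    """
    s, a, b = data.shape[:3]
    grand = data.mean(axis=(0, 1, 2))
    m_s = data.mean(axis=(1, 2))
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)
    m_ab = data.mean(axis=0)

    ss_a = s * b * ((m_a - grand) ** 2).sum(axis=0)
    ss_b = s * a * ((m_b - grand) ** 2).sum(axis=0)
    ss_ab = s * ((m_ab - m_a[:, None] - m_b[None] + grand) ** 2).sum(axis=(0, 1))
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None] + grand) ** 2).sum(axis=(0, 1))
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None] + grand) ** 2).sum(axis=(0, 1))
    resid = (data - m_sa[:, :, None] - m_sb[:, None] - m_ab[None]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None]
             - grand)
    ss_sab = (resid ** 2).sum(axis=(0, 1, 2))

    scale = (data ** 2).sum(axis=(0, 1, 2))
    out = {}
    for name, ss_eff, df1, ss_err, df2 in [
            ("A", ss_a, a - 1, ss_sa, (s - 1) * (a - 1)),
            ("B", ss_b, b - 1, ss_sb, (s - 1) * (b - 1)),
            ("AxB", ss_ab, (a - 1) * (b - 1), ss_sab, (s - 1) * (a - 1) * (b - 1))]:
        out[name] = (_f_ratio(ss_eff, df1, ss_err, df2, scale), (df1, df2))
    return out


def samplewise_rm_anova(data: np.ndarray, design: str = "oneway"):
    """Repeated-measures ANOVA F per sample.

    ``design="oneway"``: data (subjects, conditions, ...samples) -> StatMap.
    ``design="twoway"``: data (subjects, A, B, ...samples) -> dict of
    StatMaps for "A", "B" and "AxB". Requires >= 3 subjects and balanced
    cells (enforced by the rectangular array shape).
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if design == "oneway":
        f, df = _rm_oneway_f(data)
        thr = float(stats.f.ppf(0.95, *df))
        return StatMap(f, "F", df, thr)
    if design == "twoway":
        return {name: StatMap(f, "F", df, float(stats.f.ppf(0.95, *df)))
                for name, (f, df) in _rm_twoway_f(data).items()}
    raise ValueError(f"unknown design {design!r}")


# ---------------------------------------------------------------------------
# clustering

def _lattice_adjacency(shape, neighbors: np.ndarray) -> sparse.csr_matrix:
    """Sparse adjacency of the (channel, freq, time) lattice."""
    n_ch, nf, nt = shape
    n = n_ch * nf * nt
    idx = np.arange(n).reshape(shape)
    rows, cols = [], []
    # temporal neighbors
    rows.append(idx[:, :, :-1].ravel()); cols.append(idx[:, :, 1:].ravel())
    # spectral neighbors
    rows.append(idx[:, :-1, :].ravel()); cols.append(idx[:, 1:, :].ravel())
    # spatial neighbors
    ci, cj = np.nonzero(np.triu(neighbors, 1))
    if len(ci):
        rows.append(idx[ci].ravel()); cols.append(idx[cj].ravel())
    r = np.concatenate(rows); c = np.concatenate(cols)
    m = sparse.coo_matrix((np.ones(len(r), dtype=np.int8), (r, c)), shape=(n, n))
    return (m + m.T).tocsr()


class ClusterGeometry:
    """Precomputed lattice adjacency for repeated clustering calls."""

    def __init__(self, shape, adjacency: AdjacencyGraph):
        if adjacency.neighbors.shape[0] != shape[0]:
            raise ValueError("adjacency size does not match channel axis")
        self.shape = tuple(shape)
        self.nf_nt = shape[1] * shape[2]
        self.adj = _lattice_adjacency(shape, adjacency.neighbors)

    def components(self, supra_flat: np.ndarray):
        """Connected components over supra-threshold flat indices."""
        nodes = np.flatnonzero(supra_flat)
        if len(nodes) == 0:
            return []
        sub = self.adj[nodes][:, nodes]
        n_comp, lab = connected_components(sub, directed=False)
        return [nodes[lab == k] for k in range(n_comp)]


def form_clusters(stat_map: StatMap, geometry: ClusterGeometry,
                  min_sensors: int = 2, tail: str | None = None) -> list:
    """Connected supra-threshold components, small-sensor clusters discarded.

    For signed T maps positive and negative clusters are formed separately.
    ``min_sensors`` is the minimum number of distinct (mutually reachable
    through the neighbor relation) sensors a cluster must span; the
    resting-control variant uses ``min_sensors=0``.
    """
    vals = stat_map.values
    if vals.shape != geometry.shape:
        raise ValueError("stat map shape does not match geometry")
    flat = vals.ravel()
    out = []
    if stat_map.stat == "T" and tail is None:
        tails = [(1, flat > stat_map.threshold), (-1, flat < -stat_map.threshold)]
    elif stat_map.stat == "T" and tail == "pos":
        tails = [(1, flat > stat_map.threshold)]
    elif stat_map.stat == "T" and tail == "neg":
        tails = [(-1, flat < -stat_map.threshold)]
    else:
        tails = [(1, flat > stat_map.threshold)]
    for sign, supra in tails:
        for members in geometry.components(supra):
            n_sens = len(np.unique(members // geometry.nf_nt))
            if n_sens < min_sensors:
                continue
            out.append(ClusterResult(members=members,
                                     mass=float(flat[members].sum()),
                                     sign=sign, shape=geometry.shape))
    out.sort(key=lambda c: -abs(c.mass))
    return out


def _max_cluster_mass(stat_map: StatMap, geometry, min_sensors) -> float:
    cl = form_clusters(stat_map, geometry, min_sensors)
    return max((abs(c.mass) for c in cl), default=0.0)


def _permute_within_subject(data: np.ndarray, rng) -> np.ndarray:
    """Independently permute the condition axis (axis 1 flattened) per subject."""
    s = data.shape[0]
    flatc = data.reshape(s, -1, *data.shape[-3:]) if data.ndim > 4 else data
    out = np.empty_like(flatc)
    n_cells = flatc.shape[1]
    for i in range(s):
        out[i] = flatc[i, rng.permutation(n_cells)]
    return out.reshape(data.shape)


def permutation_test(data, design: str, adjacency: AdjacencyGraph,
                     n_perm: int = 1000, seed: int = 0, min_sensors: int = 2,
                     alpha: float = 0.05, exact: bool = False,
                     groups=None):
    """Cluster-based permutation inference.

    Parameters
    ----------
    data : ndarray
        ``paired``: (subjects, 2, ch, f, t). ``oneway``: (subjects,
        conditions, ch, f, t). ``twoway``: (subjects, A, B, ch, f, t).
        ``independent``: (observations, ch, f, t) with ``groups`` giving a
        binary label per observation.
    design : {"paired", "oneway", "twoway", "independent"}
    exact : bool
        For the paired design, enumerate all 2^S sign assignments instead of
        Monte-Carlo sampling; p is then the exact permutation p
        (#assignments with max mass >= observed) / 2^S.

    Returns a list of ClusterResult (dict of lists keyed by effect for the
    two-way design), sorted by |mass|, each with its Monte-Carlo p.
    """
    data = np.asarray(data, dtype=float)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse Monte-Carlo p")
    rng = np.random.default_rng(seed)
    shape = data.shape[-3:]
    geometry = ClusterGeometry(shape, adjacency)

    if design == "paired":
        return _paired_test(data, geometry, n_perm, rng, min_sensors, exact)
    if design == "independent":
        if groups is None:
            raise ValueError("independent design requires group labels")
        return _independent_test(data, np.asarray(groups), geometry, n_perm,
                                 rng, min_sensors)
    if design == "oneway":
        obs = samplewise_rm_anova(data, "oneway")
        clusters = [c.summarize() for c in form_clusters(obs, geometry, min_sensors)]
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = _permute_within_subject(data, rng)
            null[p] = _max_cluster_mass(samplewise_rm_anova(perm, "oneway"),
                                        geometry, min_sensors)
        _assign_p(clusters, null)
        return clusters
    if design == "twoway":
        obs = samplewise_rm_anova(data, "twoway")
        results = {k: form_clusters(v, geometry, min_sensors)
                   for k, v in obs.items()}
        null = {k: np.empty(n_perm) for k in obs}
        for p in range(n_perm):
            perm = _permute_within_subject(data, rng)
            maps = samplewise_rm_anova(perm, "twoway")
            for k in maps:
                null[k][p] = _max_cluster_mass(maps[k], geometry, min_sensors)
        for k in results:
            _assign_p(results[k], null[k])
        return results
    raise ValueError(f"unknown design {design!r}")


def _assign_p(clusters, null_max: np.ndarray) -> None:
    n = len(null_max)
    for c in clusters:
        c.monte_carlo_p = float((1 + np.sum(null_max >= abs(c.mass))) / (1 + n))


def _paired_test(data, geometry, n_perm, rng, min_sensors, exact):
    s = data.shape[0]
    diffs = (data[:, 0] - data[:, 1]).reshape(s, -1)
    obs_map = samplewise_t(data[:, 0], data[:, 1], paired=True)
    clusters = [c.summarize() for c in form_clusters(obs_map, geometry, min_sensors)]

    # sign-flip t maps in closed form: the sum of squares is flip-invariant
    sum_sq = (diffs ** 2).sum(axis=0)
    if exact:
        signs = np.array(list(product((1.0, -1.0), repeat=s)))
    else:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, s))
    means = signs @ diffs / s
    var = (sum_sq[None] - s * means ** 2) / (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmaps = means / np.sqrt(var / s)
    tmaps = np.nan_to_num(tmaps, nan=0.0, posinf=0.0, neginf=0.0)

    null = np.empty(len(signs))
    for p in range(len(signs)):
        null[p] = _max_cluster_mass(
            StatMap(tmaps[p].reshape(geometry.shape), "T", obs_map.df,
                    obs_map.threshold), geometry, min_sensors)
    if exact:
        for c in clusters:
            c.monte_carlo_p = float(np.sum(null >= abs(c.mass)) / len(null))
    else:
        _assign_p(clusters, null)
    return clusters


def _independent_test(data, groups, geometry, n_perm, rng, min_sensors):
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError("independent design requires exactly two groups")
    ga, gb = (groups == labels[0]), (groups == labels[1])
    obs_map = samplewise_t(data[ga], data[gb], paired=False)
    clusters = [c.summarize() for c in form_clusters(obs_map, geometry, min_sensors)]
    null = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(len(groups))
        pa, pb = perm[:ga.sum()], perm[ga.sum():]
        null[p] = _max_cluster_mass(
            samplewise_t(data[pa], data[pb], paired=False), geometry,
            min_sensors)
    _assign_p(clusters, null)
    return clusters


def posthoc_pairwise(data: np.ndarray, condition_names, adjacency,
                     pairs=None, n_perm: int = 1000, seed: int = 0,
                     alpha: float = 0.025, min_sensors: int = 2,
                     correction: str = "bonferroni") -> dict:
    """Dependent-samples cluster T-tests for condition pairs.

    ``data`` is (subjects, conditions, ch, f, t). Per-pair Monte-Carlo p's
    are Bonferroni-multiplied by the number of pairs (capped at 1); the
    significance decision is two-sided at ``alpha`` (0.025) per tail.
    Returns ``{(name_a, name_b): [ClusterResult, ...]}`` with
    ``bonferroni_p`` set on every cluster.
    """
    names = list(condition_names)
    if pairs is None:
        pairs = list(combinations(names, 2))
    for a, b in pairs:
        if a not in names or b not in names:
            raise ValueError(f"unknown condition in pair ({a}, {b})")
    n_pairs = len(pairs)
    out = {}
    for k, (a, b) in enumerate(pairs):
        sub = data[:, [names.index(a), names.index(b)]]
        clusters = permutation_test(sub, "paired", adjacency, n_perm=n_perm,
                                    seed=seed + k, min_sensors=min_sensors)
        for c in clusters:
            factor = n_pairs if correction == "bonferroni" else 1
            c.bonferroni_p = min(1.0, c.monte_carlo_p * factor)
            c.significant = c.bonferroni_p < alpha
        out[(a, b)] = clusters
    return out
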