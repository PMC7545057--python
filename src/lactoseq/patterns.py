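"""Short time-series model-profile analysis (STEM-style).

Temporal expression patterns over a handful of ordered stages are captured
by integer "model profiles": vectors of length t starting at 0 whose
successive steps change by at most ``c`` units.  A bounded set of mutually
dissimilar representatives is chosen greedily, each gene's log2-ratio
trajectory (anchored to the first stage) is assigned to its most-correlated
profile, and per-profile gene counts are tested against an exact
stage-permutation null with Bonferroni correction.  Significant profiles
with correlated shapes are grouped into clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ModelProfile",
    "enumerate_candidate_profiles",
    "select_model_profiles",
    "assign_genes",
    "profile_significance",
    "summarize_pattern_direction",
    "cluster_significant_profiles",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class ModelProfile:
    """Integer temporal template: levels[0] == 0, |step| <= c.  Ids follow
    the lexicographic order of the step vector and are stable."""

    id: int
    levels: tuple[int, ...]

    @property
    def is_flat(self) -> bool:
        return all(v == 0 for v in self.levels)


def enumerate_candidate_profiles(t: int, c: int) -> list[ModelProfile]:
    """All (2c+1)^(t-1) profiles for t timepoints with max unit change c,
    ordered lexicographically by step vector."""
    if t < 2:
        raise ValueError("need at least 2 timepoints")
    if c < 1:
        raise ValueError("max unit change must be >= 1")
    profiles = []
    for i, steps in enumerate(product(range(-c, c + 1), repeat=t - 1)):
        levels = (0, *np.cumsum(steps).tolist())
        profiles.append(ModelProfile(id=i, levels=levels))
    return profiles


def _profile_distance(p: tuple[int, ...], q: tuple[int, ...]) -> float:
    """1 - Pearson correlation of level vectors.  The flat profile has zero
    variance, so by convention its distance to any non-flat profile is 1
    and to itself 0."""
    pa, qa = np.asarray(p, float), np.asarray(q, float)
    p_flat = np.ptp(pa) == 0
    q_flat = np.ptp(qa) == 0
    if p_flat and q_flat:
        return 0.0
    if p_flat or q_flat:
        return 1.0
    r = np.corrcoef(pa, qa)[0, 1]
    return float(1.0 - r)


def select_model_profiles(candidates: list[ModelProfile], m: int) -> list[ModelProfile]:
    """Greedy max-min selection of up to m representatives.

    Seeded with the flat profile; each round adds the candidate whose
    minimum distance (1 - correlation) to the chosen set is largest, ties
    broken by lowest candidate id.  Deterministic.  Result is sorted by id.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if m >= len(candidates):
        return sorted(candidates, key=lambda p: p.id)
    flat = next(p for p in candidates if p.is_flat)
    chosen = [flat]
    chosen_ids = {flat.id}
    # min distance of every candidate to the chosen set, updated incrementally
    min_dist = {p.id: _profile_distance(p.levels, flat.levels) for p in candidates}
    while len(chosen) < m:
        best = None
        for p in candidates:
            if p.id in chosen_ids:
                continue
            d = min_dist[p.id]
            if best is None or d > best[0] + _TIE_TOL:
                best = (d, p)
        chosen.append(best[1])
        chosen_ids.add(best[1].id)
        for p in candidates:
            if p.id not in chosen_ids:
                d = _profile_distance(p.levels, best[1].levels)
                if d < min_dist[p.id]:
                    min_dist[p.id] = d
    return sorted(chosen, key=lambda p: p.id)


def _transform(stage_means: pd.DataFrame, pseudocount: float) -> np.ndarray:
    """log2 ratio to the first stage, so every trajectory starts at 0."""
    x = np.log2(stage_means.to_numpy(dtype=float) + pseudocount)
    if not np.isfinite(x).all():
        bad = stage_means.index[~np.isfinite(x).all(axis=1)][:5].tolist()
        raise ValueError(f"undefined log transform (zero mean, zero pseudocount?) for genes {bad}")
    return x - x[:, [0]]


def _correlation_matrix(x: np.ndarray, profiles: list[ModelProfile]) -> np.ndarray:
    """Pearson correlation of each gene trajectory with each profile.
    Zero-variance rows/profiles follow the flat conventions: flat gene vs
    flat profile -> 1, flat vs non-flat -> 0."""
    n, t = x.shape
    p_levels = np.array([p.levels for p in profiles], dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    pc = p_levels - p_levels.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(xc, axis=1)
    pn = np.linalg.norm(pc, axis=1)
    gene_flat = xn < _TIE_TOL
    prof_flat = pn < _TIE_TOL
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (xc @ pc.T) / np.outer(np.where(gene_flat, 1.0, xn), np.where(prof_flat, 1.0, pn))
    corr[gene_flat, :] = 0.0
    corr[:, prof_flat] = 0.0
    corr[np.ix_(gene_flat, prof_flat)] = 1.0
    return np.clip(corr, -1.0, 1.0)


def _assign(x: np.ndarray, profiles: list[ModelProfile]) -> tuple[np.ndarray, np.ndarray]:
    order = sorted(range(len(profiles)), key=lambda k: profiles[k].id)
    profs = [profiles[k] for k in order]
    corr = _correlation_matrix(x, profs)
    best = corr.max(axis=1, keepdims=True)
    # ties (within tolerance) go to the lowest profile id
    pick = np.argmax(corr >= best - _TIE_TOL, axis=1)
    ids = np.array([p.id for p in profs])
    return ids[pick], corr[np.arange(len(x)), pick]


def assign_genes(
    stage_means: pd.DataFrame,
    profiles: list[ModelProfile],
    pseudocount: float = 0.125,
) -> pd.DataFrame:
    """Assign each gene to its most-correlated model profile.

    Returns a DataFrame indexed by gene with columns profile_id and
    correlation.  Flat (constant) trajectories go to the flat profile.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    x = _transform(stage_means, pseudocount)
    pid, corr = _assign(x, profiles)
    return pd.DataFrame({"profile_id": pid, "correlation": corr}, index=stage_means.index)


def profile_significance(
    stage_means: pd.DataFrame,
    profiles: list[ModelProfile],
    pseudocount: float = 0.125,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Exact permutation test of per-profile gene counts.

    All t! orderings of the stage columns are enumerated; under each, every
    gene trajectory is re-anchored and re-assigned, and the per-profile
    counts are averaged to give expected counts.  Each profile's p-value is
    the binomial tail P(X >= observed) with success probability
    expected / total, Bonferroni-corrected across profiles.
    """
    t = stage_means.shape[1]
    if math.factorial(t) > 720:
        raise ValueError("exact permutation null supports at most 6 stages (t! <= 720)")
    n = len(stage_means)
    ids = [p.id for p in profiles]
    observed = assign_genes(stage_means, profiles, pseudocount)["profile_id"]
    obs_counts = observed.value_counts().reindex(ids, fill_value=0)

    x_full = np.log2(stage_means.to_numpy(dtype=float) + pseudocount)
    perm_counts = np.zeros(len(ids))
    id_pos = {pid: k for k, pid in enumerate(ids)}
    n_perm = 0
    for perm in permutations(range(t)):
        xp = x_full[:, perm]
        xp = xp - xp[:, [0]]
        pid, _ = _assign(xp, profiles)
        for v, c in zip(*np.unique(pid, return_counts=True)):
            perm_counts[id_pos[v]] += c
        n_perm += 1
    expected = perm_counts / n_perm

    pvals = np.array([
        stats.binom.sf(obs_counts.iloc[k] - 1, n, min(expected[k] / n, 1.0)) if n else 1.0
        for k in range(len(ids))
    ])
    bonf = np.minimum(pvals * len(ids), 1.0)
    return pd.DataFrame({
        "profile_id": ids,
        "levels": [",".join(map(str, p.levels)) for p in profiles],
        "observed": obs_counts.to_numpy(),
        "expected": expected,
        "p": pvals,
        "p_bonferroni": bonf,
        "significant": bonf < alpha,
    })


def cluster_significant_profiles(
    significance: pd.DataFrame,
    profiles: list[ModelProfile],
    corr_threshold: float = 0.7,
) -> pd.Series:
    """Group significant profiles whose level vectors correlate at or above
    the threshold (single linkage = connected components).  Returns a
    cluster id per profile id; non-significant profiles get -1."""
    by_id = {p.id: p for p in profiles}
    sig_ids = significance.loc[significance["significant"], "profile_id"].tolist()
    g = nx.Graph()
    g.add_nodes_from(sig_ids)
    for i, a in enumerate(sig_ids):
        for b in sig_ids[i + 1:]:
            if 1.0 - _profile_distance(by_id[a].levels, by_id[b].levels) >= corr_threshold:
                g.add_edge(a, b)
    cluster = pd.Series(-1, index=significance["profile_id"], name="cluster_id")
    for k, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for pid in comp:
            cluster.loc[pid] = k
    return cluster


def summarize_pattern_direction(profile: ModelProfile, i: int, j: int) -> str:
    """Direction of a profile between two stage indices: 'up' if the later
    level is higher, 'down' if lower, 'flat' if equal."""
    if not (0 <= i < len(profile.levels)) or not (0 <= j < len(profile.levels)):
        raise IndexError("stage index out of range for profile")
    diff = profile.levels[j] - profile.levels[i]
    return "up" if diff > 0 else ("down" if diff < 0 else "flat")
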