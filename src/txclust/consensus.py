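"""Resampling-based consensus clustering with stability diagnostics.

The wrapper repeatedly subsamples the cohort (default 80% of subjects,
100 iterations), partitions each subsample with a base clusterer at every
candidate cluster number k (default 2..10), and records for every subject
pair how often the two were sampled together and how often they were then
clustered together.  The consensus value of a pair is the ratio of the two
counts; a stable clustering concentrates consensus values near 0 and 1.

Stability diagnostics per k:

* the empirical CDF of off-diagonal consensus values and the area under it;
* the delta area — the relative change of that area as k grows by one
  (at the smallest k, the area itself);
* PAC, the proportion of ambiguously clustered pairs, i.e. pairs whose
  consensus falls strictly inside (0.1, 0.9) by default — lower is stabler;
* the within-cluster consensus score — the mean consensus over all pairs
  inside one cluster — and its unweighted mean over clusters.

The final k-cluster assignment is obtained by average-linkage hierarchical
clustering of (1 - consensus) cut at k, and clusters are renumbered by
descending size for stable reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .cohort import CohortError, DistanceMatrix

logger = logging.getLogger(__name__)

CDF_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConsensusConfig:
    k_min: int = 2
    k_max: int = 10
    n_iterations: int = 100
    subsample_fraction: float = 0.8
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    base_clusterer: str = "pam"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise CohortError("need 2 <= k_min <= k_max")
        if not 0 < self.subsample_fraction <= 1:
            raise CohortError("subsample_fraction must lie in (0, 1]")
        if not 0 <= self.pac_lower < self.pac_upper <= 1:
            raise CohortError("need 0 <= pac_lower < pac_upper <= 1")
        if self.base_clusterer not in ("pam", "hierarchical_average"):
            raise CohortError("base_clusterer must be pam or hierarchical_average")
        if self.n_iterations < 1:
            raise CohortError("n_iterations must be >= 1")


@dataclass
class ConsensusMatrix:
    """Consensus proportions with the resampling bookkeeping they derive
    from."""

    values: np.ndarray  # symmetric, diagonal 1, entries in [0,1]
    cosample_counts: np.ndarray  # joint-inclusion counts per pair
    k: int

    def __post_init__(self) -> None:
        v = self.values
        if not np.allclose(v, v.T):
            raise CohortError("consensus matrix must be symmetric")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise CohortError("consensus entries must lie in [0,1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def offdiag(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # 1..k per subject
    k: int
    sizes: dict[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.sizes is None:
            uniq, counts = np.unique(self.labels, return_counts=True)
            self.sizes = dict(zip(uniq.tolist(), counts.tolist()))
        if sum(self.sizes.values()) != len(self.labels):
            raise CohortError("cluster sizes must sum to n")


@dataclass
class KSelectionDiagnostics:
    """Per-k stability diagnostics; all fields are dicts keyed by k."""

    ks: list[int]
    cdf: dict[int, np.ndarray]  # CDF values on CDF_GRID
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    cluster_consensus: dict[int, dict[int, float]]
    mean_cluster_consensus: dict[int, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.ks:
            rows.append(
                {
                    "k": k,
                    "pac": self.pac[k],
                    "area": self.area[k],
                    "delta_area": self.delta_area[k],
                    "mean_cluster_consensus": self.mean_cluster_consensus[k],
                    **{
                        f"consensus_cluster_{c}": s
                        for c, s in self.cluster_consensus[k].items()
                    },
                }
            )
        return pd.DataFrame(rows)

    def cdf_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"consensus_value": CDF_GRID})
        for k in self.ks:
            df[f"cdf_k{k}"] = self.cdf[k]
        return df


# ---------------------------------------------------------------------------
# Base clusterers


def _pam(D: np.ndarray, k: int, max_swap: int = 60) -> np.ndarray:
    """Partitioning around medoids on a dissimilarity matrix.

    Greedy BUILD initialization followed by best-swap passes until no swap
    lowers the total within-assignment dissimilarity.  Deterministic (ties
    broken by lowest index).  Returns labels 1..k.
    """
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        reduction = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        reduction[medoids] = -np.inf
        c = int(np.argmax(reduction))
        medoids.append(c)
        d_near = np.minimum(d_near, D[c])

    med = np.array(medoids)
    for _ in range(max_swap):
        dm = D[med]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        nearest = order[0]
        d1 = dm[nearest, np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        current = d1.sum()
        best = (0.0, None, None)
        for j in range(k):
            dn = np.where(nearest == j, d2, d1)
            costs = np.minimum(dn[:, None], D).sum(axis=0)  # cost per candidate h
            costs[med] = np.inf
            h = int(np.argmin(costs))
            gain = current - costs[h]
            if gain > best[0] + 1e-12:
                best = (gain, j, h)
        if best[1] is None:
            break
        med[best[1]] = best[2]
    labels = np.argmin(D[med], axis=0)
    # guarantee each medoid anchors its own cluster even under ties
    labels[med] = np.arange(k)
    return labels + 1


def _hierarchical_average(D: np.ndarray, k: int) -> np.ndarray:
    Z = linkage(squareform(D, checks=False), method="average")
    return fcluster(Z, t=k, criterion="maxclust")


def base_cluster(
    sub_distance: DistanceMatrix | np.ndarray,
    k: int,
    method: str = "pam",
    seed: int = 0,
) -> np.ndarray:
    """Partition a dissimilarity matrix into k clusters; labels 1..k, all
    non-empty.  Both methods are deterministic; the seed is accepted for
    interface stability."""
    D = sub_distance.values if isinstance(sub_distance, DistanceMatrix) else sub_distance
    n = D.shape[0]
    if k > n:
        raise CohortError(f"k={k} exceeds n={n}")
    if k == n:
        return np.arange(1, n + 1)
    if method == "pam":
        return _pam(D, k)
    if method == "hierarchical_average":
        return _hierarchical_average(D, k)
    raise CohortError(f"unknown base clusterer {method!r}")


# ---------------------------------------------------------------------------
# Consensus wrapper


def _assign_from_consensus(values: np.ndarray, k: int) -> np.ndarray:
    """Final assignment: average linkage on (1 - consensus) cut at k,
    clusters renumbered by descending size (ties by first appearance)."""
    diss = 1.0 - values
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[r] for r in raw])


def run_consensus(
    distance: DistanceMatrix, config: ConsensusConfig
) -> dict[int, tuple[ConsensusMatrix, ClusterAssignment]]:
    """Run the consensus-clustering loop over the k grid.

    One subsample is drawn per iteration (without replacement, size
    floor(subsample_fraction * n)) and clustered at every k, so the
    co-sampling counts are shared across the grid.  Per-iteration seeds are
    derived from the master seed and the iteration counter, making runs
    reproducible and parallelizable.  Pairs never co-sampled get consensus
    0 (with a logged count).
    """
    D = distance.values
    n = D.shape[0]
    if n < config.k_max + 1:
        raise CohortError("need n >= k_max + 1 subjects")
    m = int(np.floor(config.subsample_fraction * n))
    if m < config.k_max:
        raise CohortError(
            f"subsample size {m} smaller than k_max={config.k_max}"
        )
    ks = list(range(config.k_min, config.k_max + 1))
    cocluster = {k: np.zeros((n, n)) for k in ks}
    cosample = np.zeros((n, n))
    for it in range(config.n_iterations):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 10, it]))
        idx = np.sort(rng.choice(n, size=m, replace=False))
        block = np.ix_(idx, idx)
        cosample[block] += 1
        subD = D[block]
        for k in ks:
            labels = base_cluster(subD, k, method=config.base_clusterer)
            for c in range(1, k + 1):
                members = idx[labels == c]
                cocluster[k][np.ix_(members, members)] += 1

    never = int(np.triu(cosample == 0, k=1).sum())
    if never:
        logger.warning("%d subject pairs never co-sampled; consensus set to 0", never)

    results: dict[int, tuple[ConsensusMatrix, ClusterAssignment]] = {}
    counts = cosample.astype(int)
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(cosample > 0, cocluster[k] / np.maximum(cosample, 1), 0.0)
        np.fill_diagonal(values, 1.0)
        values = (values + values.T) / 2
        matrix = ConsensusMatrix(values=values, cosample_counts=counts, k=k)
        labels = _assign_from_consensus(values, k)
        results[k] = (matrix, ClusterAssignment(labels=labels, k=k))
    return results


# ---------------------------------------------------------------------------
# Diagnostics and k-selection


def compute_diagnostics(
    runs: dict[int, ConsensusMatrix], config: ConsensusConfig
) -> KSelectionDiagnostics:
    """Stability diagnostics per k, recomputed from the stored consensus
    matrices alone (assignments are re-derived from each matrix)."""
    ks = sorted(runs)
    if not ks:
        raise CohortError("no consensus runs supplied")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise CohortError("k grid must be contiguous")
    cdf: dict[int, np.ndarray] = {}
    area: dict[int, float] = {}
    pac: dict[int, float] = {}
    cluster_cons: dict[int, dict[int, float]] = {}
    mean_cons: dict[int, float] = {}
    for k in ks:
        matrix = runs[k]
        off = matrix.offdiag()
        cdf[k] = np.array([(off <= g).mean() for g in CDF_GRID])
        area[k] = float(np.trapezoid(cdf[k], CDF_GRID))
        pac[k] = float(
            ((off > config.pac_lower) & (off < config.pac_upper)).mean()
        )
        labels = _assign_from_consensus(matrix.values, k)
        scores: dict[int, float] = {}
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            if len(members) < 2:
                logger.info("k=%d cluster %d is a singleton; score 1 by convention", k, c)
                scores[int(c)] = 1.0
                continue
            sub = matrix.values[np.ix_(members, members)]
            iu = np.triu_indices(len(members), k=1)
            scores[int(c)] = float(sub[iu].mean())
        cluster_cons[k] = scores
        mean_cons[k] = float(np.mean(list(scores.values())))
    delta: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area[k]
        else:
            prev = area[ks[i - 1]]
            delta[k] = (area[k] - prev) / prev if prev > 0 else 0.0
    return KSelectionDiagnostics(
        ks=ks,
        cdf=cdf,
        area=area,
        delta_area=delta,
        pac=pac,
        cluster_consensus=cluster_cons,
        mean_cluster_consensus=mean_cons,
    )


def select_k(
    diag: KSelectionDiagnostics, rule: str = "mean_consensus"
) -> int:
    """Choose the cluster number from the diagnostics.

    ``mean_consensus`` (default): argmax of the mean within-cluster
    consensus score.  ``pac``: argmin PAC.  ``composite``: rank-sum over
    (high mean consensus, low PAC, small delta-area gain) — an explicit
    codification of the qualitative multi-plot adjudication.  Ties go to
    the smallest k.
    """
    ks = diag.ks
    if len(ks) < 2:
        raise CohortError("diagnostics must cover at least 2 values of k")
    if rule == "mean_consensus":
        scores = np.array([diag.mean_cluster_consensus[k] for k in ks])
        return ks[int(np.argmax(scores))]
    if rule == "pac":
        scores = np.array([diag.pac[k] for k in ks])
        return ks[int(np.argmin(scores))]
    if rule == "composite":
        from scipy.stats import rankdata

        mean_c = np.array([diag.mean_cluster_consensus[k] for k in ks])
        pac = np.array([diag.pac[k] for k in ks])
        delta = np.array([abs(diag.delta_area[k]) for k in ks])
        rank_sum = rankdata(-mean_c) + rankdata(pac) + rankdata(delta)
        return ks[int(np.argmin(rank_sum))]
    raise CohortError(f"unknown selection rule {rule!r}")


def selection_table(diag: KSelectionDiagnostics) -> pd.DataFrame:
    """Per-criterion table backing ``select_k``, for human adjudication."""
    return diag.to_frame()[["k", "mean_cluster_consensus", "pac", "delta_area"]]


# ---------------------------------------------------------------------------
# I/O helpers


def write_run(
    out_dir: str | Path,
    runs: dict[int, tuple[ConsensusMatrix, ClusterAssignment]],
    diag: KSelectionDiagnostics,
    subject_ids,
    chosen_k: int,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (matrix, _) in runs.items():
        pd.DataFrame(matrix.values, index=subject_ids, columns=subject_ids).to_csv(
            out / f"consensus_k{k}.csv"
        )
    diag.to_frame().to_csv(out / "diagnostics.csv", index=False)
    diag.cdf_frame().to_csv(out / "cdf_curves.csv", index=False)
    assignment = runs[chosen_k][1]
    pd.DataFrame(
        {"subject_id": subject_ids, "cluster": assignment.labels}
    ).to_csv(out / "assignment.csv", index=False)
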