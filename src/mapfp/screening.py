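"""Ligand-based virtual-screening protocol and early-recognition metrics.

The evaluation protocol: from a labelled (actives, decoys) library, a few
randomly selected actives serve as queries; each query ranks the remaining
compounds by fingerprint similarity (Jaccard for MinHashed fingerprints,
Dice for folded bit vectors), and AUC, EF1, EF5, BEDROC20/100 and RIE20/100
are averaged over the queries.  Fingerprints are then compared by their
mean rank per metric across many sets.

Metric definitions (n library compounds, n_a actives at 1-based ranks r_i,
alpha the early-recognition exponent):

    AUC     = P(random active outranks random decoy), ties counted 1/2
    EF_x%   = (actives in top ceil(x/100 * n) / n_a) / (x/100)
    RIE     = sum_i exp(-alpha r_i / n)  /  < same sum under uniform ranks >
    BEDROC  = (RIE - RIE_min) / (RIE_max - RIE_min)  in [0, 1]

RIE_max/RIE_min are evaluated by placing all actives at the top/bottom of
the list, which keeps the rescaling exact for any (n, n_a, alpha).  Ties in
the ranking are broken deterministically by molecule id; AUC uses mid-rank
tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigMismatchError, MissingSetError, TooFewActivesError
from .fingerprint import MinHashedAtomPairFingerprint
from .minhash import MinHashFP
from .shingling import FPConfig

METRICS = ("AUC", "EF1", "EF5", "BEDROC20", "BEDROC100", "RIE20", "RIE100")


@dataclass(frozen=True)
class RankedScreen:
    """A similarity-ranked, labelled library (descending score order)."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    actives: tuple[bool, ...]

    def __post_init__(self) -> None:
        n, n_actives = len(self.ids), sum(self.actives)
        if not (1 <= n_actives < n):
            raise TooFewActivesError(
                f"need 1 <= n_actives < n, got {n_actives} of {n}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_actives(self) -> int:
        return sum(self.actives)

    @property
    def active_ranks(self) -> np.ndarray:
        """1-based ranks of the actives in the deterministic list order."""
        return np.flatnonzero(self.actives) + 1


def rank_by_similarity(query: MinHashFP, library_fps: np.ndarray,
                       labels, ids=None) -> RankedScreen:
    """Rank a fingerprint library by Jaccard similarity to the query.

    ``library_fps`` is (n, k) with the same configuration as the query;
    ties are broken by molecule id.
    """
    if library_fps.shape[1] != len(query.values):
        raise ConfigMismatchError("query and library fingerprint lengths differ")
    ids = list(ids) if ids is not None else [str(i) for i in range(len(labels))]
    scores = np.mean(library_fps == query.values[None, :], axis=1)
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedScreen(
        ids=tuple(ids[i] for i in order),
        scores=tuple(float(scores[i]) for i in order),
        actives=tuple(bool(labels[i]) for i in order),
    )


def auc(screen: RankedScreen) -> float:
    """Probability that a random active outranks a random decoy (ties 1/2)."""
    scores = np.asarray(screen.scores)
    actives = np.asarray(screen.actives)
    n_a = actives.sum()
    n_d = len(actives) - n_a
    # rankdata is ascending; larger score = better, so rank on score directly
    ranks = rankdata(scores, method="average")
    rank_sum = ranks[actives].sum()
    return float((rank_sum - n_a * (n_a + 1) / 2) / (n_a * n_d))


def enrichment_factor(screen: RankedScreen, pct: float) -> float:
    """EF at the top ``pct`` percent of the deterministic ranking."""
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    top = int(np.ceil(pct / 100 * screen.n))
    hits = sum(screen.actives[:top])
    return (hits / screen.n_actives) / (pct / 100)


def _rie_from_ranks(ranks: np.ndarray, n: int, n_actives: int, alpha: float) -> float:
    observed = np.exp(-alpha * ranks / n).sum()
    random_expectation = (n_actives / n) * (1 - np.exp(-alpha)) / (np.exp(alpha / n) - 1)
    return float(observed / random_expectation)


def rie(screen: RankedScreen, alpha: float) -> float:
    """Robust Initial Enhancement at exponent ``alpha``."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return _rie_from_ranks(screen.active_ranks, screen.n, screen.n_actives, alpha)


def bedroc(screen: RankedScreen, alpha: float) -> float:
    """RIE rescaled to [0, 1] by its exact best/worst-case values."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    n, n_a = screen.n, screen.n_actives
    value = rie(screen, alpha)
    best = _rie_from_ranks(np.arange(1, n_a + 1), n, n_a, alpha)
    worst = _rie_from_ranks(np.arange(n - n_a + 1, n + 1), n, n_a, alpha)
    return float((value - worst) / (best - worst))


def compute_metrics(screen: RankedScreen) -> dict[str, float]:
    return {
        "AUC": auc(screen),
        "EF1": enrichment_factor(screen, 1.0),
        "EF5": enrichment_factor(screen, 5.0),
        "BEDROC20": bedroc(screen, 20.0),
        "BEDROC100": bedroc(screen, 100.0),
        "RIE20": rie(screen, 20.0),
        "RIE100": rie(screen, 100.0),
    }


@dataclass(frozen=True)
class MetricTable:
    """Query-averaged metric values for one (set, fingerprint) combination."""

    set_name: str
    fingerprint: str
    values: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"set": self.set_name, "fingerprint": self.fingerprint,
             "metric": metric, "value": value}
            for metric, value in self.values.items()
        ])


def run_benchmark_set(
    actives, decoys, config: FPConfig | None = None,
    n_queries: int = 5, seed: int = 0, set_name: str = "set",
) -> MetricTable:
    """Run the query-averaged screening protocol on one (actives, decoys) set.

    ``n_queries`` actives are drawn with a seeded RNG, each ranks the
    remaining library (its fellow actives and all decoys); the metric
    values are averaged over queries.
    """
    config = config or FPConfig()
    actives, decoys = list(actives), list(decoys)
    if len(actives) < n_queries + 1:
        raise TooFewActivesError(
            f"need more than n_queries={n_queries} actives, got {len(actives)}"
        )
    transformer = MinHashedAtomPairFingerprint(
        config.variant, n_permutations=config.n_permutations, seed=config.seed
    ).fit()
    active_fps = transformer.transform(actives)
    decoy_fps = transformer.transform(decoys)

    rng = np.random.default_rng(seed)
    query_indices = rng.choice(len(actives), size=n_queries, replace=False)
    accumulated = {metric: 0.0 for metric in METRICS}
    for query_index in query_indices:
        keep = [i for i in range(len(actives)) if i != query_index]
        library = np.vstack([active_fps[keep], decoy_fps]) if decoys else active_fps[keep]
        labels = [True] * len(keep) + [False] * len(decoys)
        ids = [f"a{i}" for i in keep] + [f"d{i}" for i in range(len(decoys))]
        query_fp = MinHashFP(values=active_fps[query_index], config=config)
        screen = rank_by_similarity(query_fp, library, labels, ids)
        for metric, value in compute_metrics(screen).items():
            accumulated[metric] += value
    return MetricTable(
        set_name=set_name, fingerprint=config.variant,
        values={metric: value / n_queries for metric, value in accumulated.items()},
    )


def aggregate_ranks(tables) -> pd.DataFrame:
    """Mean rank (1 = best) of each fingerprint per metric across sets.

    Every fingerprint must cover the same sets; ties get average ranks.
    Returns a DataFrame indexed by fingerprint with one column per metric.
    """
    frame = pd.concat([table.to_frame() for table in tables], ignore_index=True)
    coverage = frame.groupby("fingerprint")["set"].agg(lambda s: frozenset(s))
    if coverage.nunique() != 1:
        raise MissingSetError("all fingerprints must cover the same sets")
    frame["rank"] = frame.groupby(["set", "metric"])["value"].rank(
        ascending=False, method="average"
    )
    return frame.pivot_table(index="fingerprint", columns="metric",
                             values="rank", aggfunc="mean")
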