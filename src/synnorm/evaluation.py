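"""Embedding-coherence evaluation: intra-set distances and significance.

The quality signal is intra-cluster coherence: for a curated set of
related concepts, the mean pairwise cosine distance

    d(u, v) = 1 - cos(u, v)

over all n(n-1)/2 unordered member pairs. Smaller means the embedding
packs related concepts closer together. Two spaces trained on the same
documents (e.g. before and after synonym normalization) are compared
per set with a t-test on the matched pairwise-distance lists — paired by
default, since the identical concept pairs exist in both spaces; Welch's
unpaired test is available as an option. A whole-space distribution
diagnostic (ECDF / Q-Q / Kolmogorov-Smirnov on sampled pairs) checks that
normalization did not distort the overall geometry.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conceptsets import ConceptSet
from .embedding import EmbeddingSpace


def _pairwise_cosine_distances(vectors: np.ndarray) -> np.ndarray:
    """Condensed vector of 1 - cosine over all unordered row pairs."""
    v = np.asarray(vectors, dtype=np.float64)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero vector has undefined cosine distance")
    unit = v / norms[:, None]
    sims = unit @ unit.T
    iu = np.triu_indices(len(v), k=1)
    return 1.0 - sims[iu]


def mean_pairwise_distance(space: EmbeddingSpace, members: Iterable[str]) -> float:
    """Mean cosine distance over all unordered pairs of present members.

    Requires >= 2 members present in the space. Values lie in [0, 2] and
    are invariant to positive rescaling of any vector.
    """
    tokens = sorted(m for m in members if m in space)
    if len(tokens) < 2:
        raise ValueError("mean pairwise distance needs >= 2 members in the space")
    return float(_pairwise_cosine_distances(space.submatrix(tokens)).mean())


@dataclass(frozen=True)
class SetComparison:
    """Per-set coherence comparison between two embedding spaces.

    ``winner`` is the space with the smaller mean intra-set distance
    ("A", "B", or "tie"); ``significant`` means p < alpha. A degenerate
    test (zero variance of the paired differences) reports p = 1.
    """

    set_name: str
    category: str
    n_present: int
    mean_dist_a: float
    mean_dist_b: float
    t_stat: float
    p_value: float
    winner: str
    significant: bool
    degenerate: bool = False


def _paired_t(da: np.ndarray, db: np.ndarray) -> tuple[float, float, bool]:
    diff = da - db
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return 0.0, 1.0, True
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def _welch_t(da: np.ndarray, db: np.ndarray) -> tuple[float, float, bool]:
    na, nb = da.size, db.size
    va, vb = da.var(ddof=1), db.var(ddof=1)
    denom = va / na + vb / nb
    if denom == 0.0:
        return 0.0, 1.0, True
    t = (da.mean() - db.mean()) / np.sqrt(denom)
    df = denom**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return float(t), float(p), False


def compare_set(
    space_a: EmbeddingSpace,
    space_b: EmbeddingSpace,
    concept_set: ConceptSet,
    alpha: float = 0.05,
    paired: bool = True,
) -> SetComparison:
    """Compare intra-set coherence of one concept set across two spaces.

    Pairwise-distance lists are computed over the same member pairs in
    both spaces (members must be present in both). Swapping the spaces
    flips the winner and negates the t statistic.
    """
    tokens = sorted(m for m in concept_set.members if m in space_a and m in space_b)
    if len(tokens) < 2:
        raise ValueError(
            f"set {concept_set.name!r} has {len(tokens)} members present in both spaces"
        )
    da = _pairwise_cosine_distances(space_a.submatrix(tokens))
    db = _pairwise_cosine_distances(space_b.submatrix(tokens))
    t, p, degenerate = _paired_t(da, db) if paired else _welch_t(da, db)
    mean_a, mean_b = float(da.mean()), float(db.mean())
    if mean_a < mean_b:
        winner = "A"
    elif mean_b < mean_a:
        winner = "B"
    else:
        winner = "tie"
    return SetComparison(
        set_name=concept_set.name,
        category=concept_set.category,
        n_present=len(tokens),
        mean_dist_a=mean_a,
        mean_dist_b=mean_b,
        t_stat=t,
        p_value=p,
        winner=winner,
        significant=bool(p < alpha) and winner != "tie",
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CategorySummary:
    """Win counts per concept-set category, significant-only and overall.

    Space B is the normalized (synonym-replaced) corpus in the standard
    pipeline, space A the baseline; ``b_better_all + a_better_all + ties``
    always equals ``n_sets``.
    """

    category: str
    n_sets: int
    n_concepts: int
    a_better_sig: int
    b_better_sig: int
    a_better_all: int
    b_better_all: int
    ties: int

    def pct(self, count: int) -> float:
        return 100.0 * count / self.n_sets if self.n_sets else 0.0


def summarize(
    results: Sequence[SetComparison],
    category_map: Mapping[str, str] | None = None,
) -> list[CategorySummary]:
    """Tally per-category winners, Table-style (significant vs all)."""
    by_cat: dict[str, list[SetComparison]] = defaultdict(list)
    for r in results:
        cat = category_map.get(r.set_name, r.category) if category_map else r.category
        by_cat[cat].append(r)
    out: list[CategorySummary] = []
    for cat in sorted(by_cat):
        rs = by_cat[cat]
        out.append(
            CategorySummary(
                category=cat,
                n_sets=len(rs),
                n_concepts=sum(r.n_present for r in rs),
                a_better_sig=sum(r.winner == "A" and r.significant for r in rs),
                b_better_sig=sum(r.winner == "B" and r.significant for r in rs),
                a_better_all=sum(r.winner == "A" for r in rs),
                b_better_all=sum(r.winner == "B" for r in rs),
                ties=sum(r.winner == "tie" for r in rs),
            )
        )
    return out


def results_frame(results: Sequence[SetComparison]) -> pd.DataFrame:
    """One row per set: name, category, n, means, t, p, winner, significant."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "category": [r.category for r in results],
            "n_present": [r.n_present for r in results],
            "mean_dist_a": [r.mean_dist_a for r in results],
            "mean_dist_b": [r.mean_dist_b for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "winner": [r.winner for r in results],
            "significant": [r.significant for r in results],
        }
    )


def summary_frame(summaries: Sequence[CategorySummary]) -> pd.DataFrame:
    """Category summary table with counts and percentages."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "category": s.category,
                "n_sets": s.n_sets,
                "n_concepts": s.n_concepts,
                "b_better_sig": s.b_better_sig,
                "b_better_sig_pct": s.pct(s.b_better_sig),
                "a_better_sig": s.a_better_sig,
                "a_better_sig_pct": s.pct(s.a_better_sig),
                "b_better_all": s.b_better_all,
                "b_better_all_pct": s.pct(s.b_better_all),
                "a_better_all": s.a_better_all,
                "a_better_all_pct": s.pct(s.a_better_all),
                "ties": s.ties,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class DistributionCheck:
    """Whole-space distance-distribution diagnostic on sampled pairs."""

    grid: np.ndarray        # shared support (sorted union of samples)
    ecdf_a: np.ndarray      # ECDF of space A distances on the grid
    ecdf_b: np.ndarray
    qq_points: np.ndarray   # (n_pairs, 2) matched quantiles
    ks_stat: float


def _sample_distances(space: EmbeddingSpace, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    n = space.vocab_size
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n, size=n_pairs)
    clash = i == j
    while clash.any():  # resample until all pairs are distinct tokens
        j[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = i == j
    v = space.matrix.astype(np.float64)
    norms = np.linalg.norm(v, axis=1)
    norms[norms == 0] = 1.0
    unit = v / norms[:, None]
    return 1.0 - np.einsum("ij,ij->i", unit[i], unit[j])


def distribution_check(
    space_a: EmbeddingSpace,
    space_b: EmbeddingSpace,
    n_pairs: int = 10_000,
    seed: int = 0,
) -> DistributionCheck:
    """Sample distinct-token pairs from each space independently and
    compare the cosine-distance distributions.

    Returns ECDFs on the shared grid, the Q-Q quantile pairs and the
    two-sample Kolmogorov-Smirnov statistic. The default 10,000 pairs is a
    desk-scale stand-in for a full-corpus check of millions of pairs.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    for sp in (space_a, space_b):
        if sp.vocab_size < 2:
            raise ValueError("each space needs >= 2 tokens to form pairs")
    # Each space is sampled by its own generator started from the same
    # seed, so identical spaces yield identical samples (KS = 0).
    da = np.sort(_sample_distances(space_a, n_pairs, np.random.default_rng(seed)))
    db = np.sort(_sample_distances(space_b, n_pairs, np.random.default_rng(seed)))
    grid = np.sort(np.concatenate([da, db]))
    ecdf_a = np.searchsorted(da, grid, side="right") / da.size
    ecdf_b = np.searchsorted(db, grid, side="right") / db.size
    ks = float(np.abs(ecdf_a - ecdf_b).max())
    qq = np.column_stack([da, db])
    return DistributionCheck(grid=grid, ecdf_a=ecdf_a, ecdf_b=ecdf_b, qq_points=qq, ks_stat=ks)
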