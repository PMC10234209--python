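"""Distance matrices and site selections for split-network analysis, plus a
permutation test for karyotype- vs geography-driven clustering.

The Neighbor-Net agglomeration itself is delegated to external split-network
software; this module produces the Jukes-Cantor distance matrix, exports
NEXUS for that software, and quantifies the clustering claim directly: the
statistic is the mean between-class minus mean within-class distance, with
significance from seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import MISSING, HaplotypeMatrix


@dataclass
class DistanceMatrix:
    taxa: list[str]
    p_dist: np.ndarray        # mismatch fractions, complete-case per pair
    jc_dist: np.ndarray       # -(3/4) ln(1 - 4p/3); NaN where p >= 0.75
    undefined_pairs: list[tuple[str, str]]


def jc_distance_matrix(matrix: HaplotypeMatrix) -> DistanceMatrix:
    """Pairwise p-distances over complete-case sites with the Jukes-Cantor
    correction d = -(3/4) ln(1 - (4/3) p).

    Pairs with p >= 0.75 (outside the model's domain) get NaN and are
    reported in ``undefined_pairs``; pairs with no jointly called site
    raise, as no distance is estimable.
    """
    a = matrix.alleles
    n = matrix.n_samples
    p = np.zeros((n, n))
    valid = a != MISSING
    for i in range(n):
        shared = valid[i] & valid
        n_shared = shared.sum(axis=1)
        if (n_shared == 0).any():
            j = int(np.flatnonzero(n_shared == 0)[0])
            if j != i:
                raise ValueError(
                    f"no jointly called sites for pair "
                    f"({matrix.sample_ids[i]}, {matrix.sample_ids[j]})")
        mism = ((a[i] != a) & shared).sum(axis=1)
        with np.errstate(invalid="ignore"):
            p[i] = np.where(n_shared > 0, mism / n_shared, np.nan)
    np.fill_diagonal(p, 0.0)
    undefined = []
    with np.errstate(invalid="ignore", divide="ignore"):
        jc = np.where(p < 0.75, -0.75 * np.log(1 - (4.0 / 3.0) * p), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            if p[i, j] >= 0.75:
                undefined.append((matrix.sample_ids[i], matrix.sample_ids[j]))
    return DistanceMatrix(taxa=list(matrix.sample_ids), p_dist=p,
                          jc_dist=jc, undefined_pairs=undefined)


def karyotype_clustering_test(dist: np.ndarray, labels: np.ndarray,
                              n_perm: int = 1000, seed: int = 0) -> dict:
    """Permutation test for class-driven clustering on a distance matrix.

    statistic = mean between-class distance - mean within-class distance;
    p = fraction of label permutations with a statistic at least as large
    (+1 corrected). Larger positive values mean the classes cluster apart.
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix / labels size mismatch")
    iu = np.triu_indices(n, 1)

    def statistic(lbl: np.ndarray) -> float:
        same = lbl[iu[0]] == lbl[iu[1]]
        d = D[iu]
        ok = ~np.isnan(d)
        between = d[ok & ~same]
        within = d[ok & same]
        if len(between) == 0 or len(within) == 0:
            raise ValueError("need both within- and between-class pairs")
        return float(between.mean() - within.mean())

    obs = statistic(labels)
    rng = np.random.default_rng(seed)
    lbl = labels.copy()
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(lbl)
        if statistic(lbl) >= obs:
            hits += 1
    return {"statistic": obs, "p": (1 + hits) / (1 + n_perm),
            "n_perm": n_perm}


def select_network_sites(matrix: HaplotypeMatrix, mode: str,
                         spans: list[tuple[int, int]],
                         distance: int = 200_000,
                         n: int | None = None, seed: int = 0) -> np.ndarray:
    """Site indices for network construction.

    mode='inside-breakpoints': sites within the first span (the focal
    inversion). mode='random-away': seeded uniform draw of n sites farther
    than ``distance`` bp from every span (the spans being the major
    inversions to stay clear of).
    """
    pos = matrix.positions
    if mode == "inside-breakpoints":
        lo, hi = spans[0]
        return np.flatnonzero((pos >= lo) & (pos <= hi))
    if mode == "random-away":
        away = np.ones(len(pos), dtype=bool)
        for lo, hi in spans:
            away &= (pos < lo - distance) | (pos > hi + distance)
        idx = np.flatnonzero(away)
        if n is None or n >= len(idx):
            return idx
        rng = np.random.default_rng(seed)
        return np.sort(rng.choice(idx, size=n, replace=False))
    raise ValueError(f"unknown mode {mode!r}")
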