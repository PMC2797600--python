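"""Two-stage step-wise regression eQTL scan (the "SR" comparator).

Stage 1 regresses every expression trait on every marker, takes the best
marker per gene, and assesses it against a permutation null of the
per-gene maximum statistic; permutation p-values are converted to
q-values by the rank-based FDR estimate (pi0 = 1, conservative).  Stage 2
repeats the scan on the residuals of the stage-1 discoveries.  Detected
gene-marker pairs are scored 1 - q for ROC benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data import ExpressionMatrix, GenotypeMatrix


def _standardize_rows(a: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return a / sd


def single_marker_scan(expr: ExpressionMatrix, geno: GenotypeMatrix) -> np.ndarray:
    """t statistics of each gene-marker simple regression (G x M).

    Computed from the correlation: t = r sqrt(N-2) / sqrt(1-r^2).
    Monomorphic markers get statistic 0.
    """
    Y = _standardize_rows(expr.values)
    X = _standardize_rows(geno.codes.astype(np.float64))
    n = expr.n_individuals
    r = Y @ X.T / n
    r = np.clip(r, -0.999999, 0.999999)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    mono = geno.codes.std(axis=1) == 0
    t[:, mono] = 0.0
    return t


def lod_from_r2(r2: np.ndarray, n: int) -> np.ndarray:
    """LOD score of a simple regression: -(n/2) log10(1 - r^2)."""
    return -(n / 2.0) * np.log10(1.0 - r2)


@dataclass
class ScanResult:
    """Discoveries of the two-stage scan."""

    primary_marker: np.ndarray  # per gene, best stage-1 marker
    primary_p: np.ndarray
    primary_q: np.ndarray
    secondary_marker: np.ndarray  # -1 where stage 1 not significant
    secondary_p: np.ndarray  # nan where absent
    secondary_q: np.ndarray
    fdr_threshold: float
    pair_scores: dict = field(default_factory=dict)  # (gene, marker) -> 1 - q

    @property
    def discoveries(self) -> list[tuple[int, int]]:
        return sorted(self.pair_scores)


def _pointwise_q(p: np.ndarray) -> np.ndarray:
    """Rank-based FDR estimate with pi0 = 1 (Benjamini-Hochberg style,
    monotone)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    q[order] = p[order] * m / (np.arange(m) + 1)
    # enforce monotonicity from the largest p down
    q_sorted = np.minimum.accumulate(q[order][::-1])[::-1]
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _max_stat_permutation_p(
    Y: np.ndarray, X: np.ndarray, observed_max: np.ndarray, n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation p-value of each gene's maximum |t| over markers, using
    shared permutations of the individuals."""
    n = Y.shape[1]
    exceed = np.ones(Y.shape[0])  # +1 smoothing: p = (1 + #exceed) / (B + 1)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r = Y @ X[:, perm].T / n
        exceed += (np.abs(r).max(axis=1) >= observed_max - 1e-12).astype(float)
    return exceed / (n_permutations + 1)


def two_stage_scan(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    fdr_threshold: float = 0.05,
    n_permutations: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> ScanResult:
    """Two-stage step-wise regression with permutation-based q-values.

    Stage 1: per gene, the marker with the largest |t|; gene-wise
    significance from the permutation null of the max statistic, converted
    to q-values across genes.  Stage 2: for stage-1 discoveries only, the
    best second marker on the stage-1 residuals, assessed the same way.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng(0)
    G = expr.n_genes
    n = expr.n_individuals
    Y = _standardize_rows(expr.values)
    X = _standardize_rows(geno.codes.astype(np.float64))
    r1 = np.abs(Y @ X.T / n)
    best1 = r1.argmax(axis=1)
    obs1 = r1[np.arange(G), best1]
    p1 = _max_stat_permutation_p(Y, X, obs1, n_permutations, rng)
    q1 = _pointwise_q(p1)
    sig1 = q1 <= fdr_threshold

    best2 = np.full(G, -1, dtype=np.int64)
    p2 = np.full(G, np.nan)
    q2 = np.full(G, np.nan)
    if sig1.any():
        idx = np.where(sig1)[0]
        resid = Y[idx].copy()
        for row, g in enumerate(idx):
            x = X[best1[g]]
            resid[row] -= (resid[row] @ x / n) * x
        resid = _standardize_rows(resid)
        r2 = np.abs(resid @ X.T / n)
        r2[np.arange(len(idx)), best1[idx]] = 0.0
        b2 = r2.argmax(axis=1)
        obs2 = r2[np.arange(len(idx)), b2]
        p2_sub = _max_stat_permutation_p(resid, X, obs2, n_permutations, rng)
        q2_sub = _pointwise_q(p2_sub)
        best2[idx] = b2
        p2[idx] = p2_sub
        q2[idx] = q2_sub

    scores: dict[tuple[int, int], float] = {}
    for g in range(G):
        if sig1[g]:
            scores[(g, int(best1[g]))] = 1.0 - float(q1[g])
            if best2[g] >= 0 and q2[g] <= fdr_threshold:
                scores[(g, int(best2[g]))] = 1.0 - float(q2[g])
    return ScanResult(best1, p1, q1, best2, p2, q2, fdr_threshold, scores)


def sr_pair_scores(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    n_permutations: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """G x M matrix of SR scores (1 - q) for ROC construction: the scan is
    run at the loosest threshold so every candidate pair is scored."""
    res = two_stage_scan(expr, geno, fdr_threshold=1.0,
                         n_permutations=n_permutations, rng=rng)
    scores = np.zeros((expr.n_genes, geno.n_markers))
    for (g, m), s in res.pair_scores.items():
        scores[g, m] = s
    return scores
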