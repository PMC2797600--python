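"""Truth-based scoring of gene-marker pair detection (ROC construction)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import GenotypeMatrix
from .simulate import TruthManifest


@dataclass
class RocPoint:
    threshold: float
    tp: float
    fp: float


def _window_members(geno: GenotypeMatrix, m: int, window_r2: float) -> list[int]:
    """Contiguous run of markers around m whose r^2 with m exceeds the
    window threshold."""
    codes = geno.codes.astype(np.float64)
    out = [m]
    for direction in (-1, 1):
        j = m + direction
        while 0 <= j < geno.n_markers:
            a, b = codes[m], codes[j]
            if a.std() == 0 or b.std() == 0:
                break
            r = np.corrcoef(a, b)[0, 1]
            if r * r <= window_r2:
                break
            out.append(j)
            j += direction
    return sorted(out)


def score_pairs(
    scores: np.ndarray,
    truth: TruthManifest,
    thresholds: Sequence[float],
    geno: Optional[GenotypeMatrix] = None,
    credit: str = "exact",
    window_r2: float = 0.8,
) -> list[RocPoint]:
    """TP/FP counts of gene-marker pair detection at each threshold.

    ``credit="exact"`` counts a true pair only at the exact marker;
    ``credit="window"`` credits any marker inside the true marker's LD
    window (and does not count such surrogate hits as false positives).
    """
    scores = np.asarray(scores)
    G, M = scores.shape
    true_set = truth.pairs
    if credit == "window":
        if geno is None:
            raise ValueError("window crediting needs the genotype matrix")
        win: dict[int, list[int]] = {}
        for _, mk in true_set:
            if mk not in win:
                win[mk] = _window_members(geno, mk, window_r2)
        credited = {(g, j) for (g, mk) in true_set for j in win[mk]}
    elif credit == "exact":
        credited = set(true_set)
    else:
        raise ValueError(f"unknown credit mode {credit!r}")
    out = []
    for thr in thresholds:
        hits = np.argwhere(scores >= thr)
        tp_pairs = set()
        fp = 0
        for g, m in hits:
            key = (int(g), int(m))
            if key in credited:
                if credit == "window":
                    for gm in true_set:
                        if gm[0] == key[0] and key[1] in win[gm[1]]:
                            tp_pairs.add(gm)
                else:
                    tp_pairs.add(key)
            else:
                fp += 1
        out.append(RocPoint(float(thr), float(len(tp_pairs)), float(fp)))
    return out


def average_roc(per_replicate: list[list[RocPoint]]) -> list[RocPoint]:
    """Coordinate-wise mean of TP and FP counts across replicates (all
    replicates must share one threshold grid)."""
    grids = [[p.threshold for p in rep] for rep in per_replicate]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("mismatched threshold grids")
    out = []
    for i, thr in enumerate(grids[0]):
        out.append(RocPoint(
            thr,
            float(np.mean([rep[i].tp for rep in per_replicate])),
            float(np.mean([rep[i].fp for rep in per_replicate])),
        ))
    return out


def tp_at_fp(roc: list[RocPoint], fp_budget: float) -> float:
    """Largest TP among ROC points with FP <= budget (step interpolation)."""
    eligible = [p.tp for p in roc if p.fp <= fp_budget]
    return max(eligible) if eligible else 0.0


@dataclass
class ModuleBreakdown:
    tp_pairs: dict  # module -> TP pair count
    genes_one_locus: dict  # module -> genes detected with >= 1 true locus
    genes_both_loci: dict  # module -> genes detected with all true loci


def module_breakdown(
    scores: np.ndarray, truth: TruthManifest, threshold: float
) -> ModuleBreakdown:
    """Per-module detection counts at one threshold."""
    scores = np.asarray(scores)
    tp: dict[int, int] = {}
    one: dict[int, int] = {}
    both: dict[int, int] = {}
    for d, markers in truth.module_markers.items():
        genes = np.where(truth.gene_module == d)[0]
        tp[d] = 0
        one[d] = 0
        both[d] = 0
        for g in genes:
            hits = sum(1 for mk in markers if scores[g, mk] >= threshold)
            tp[d] += hits
            if hits >= 1:
                one[d] += 1
            if hits == len(markers):
                both[d] += 1
    return ModuleBreakdown(tp, one, both)
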