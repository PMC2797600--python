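"""Posterior summaries: module calls from MCMC samples.

The primary detection score is the label-invariant pair posterior: the
fraction of snapshots in which a gene and a marker co-occupy one non-null
module.  Per-gene module labels (for posterior-probability plots) are
obtained by aligning modules across snapshots to the final snapshot via
maximum marker-set overlap.  Marker posteriors diluted by linkage
disequilibrium are repaired by window smoothing: the posterior mass of a
marker's LD window is summed onto its central marker and the rest of the
window masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import f as f_dist

from .data import ExpressionMatrix, GenotypeMatrix
from .sampler import SampleTrace


def pair_posterior(trace: SampleTrace) -> np.ndarray:
    """G x M matrix: fraction of snapshots where gene g and marker m share
    a non-null module.  Invariant to module relabeling by construction."""
    if trace.n_snapshots == 0:
        raise ValueError("empty trace")
    S = trace.n_snapshots
    G = trace.gene_snapshots.shape[1]
    M = trace.marker_snapshots.shape[1]
    out = np.zeros((G, M))
    D = int(max(trace.gene_snapshots.max(initial=0), trace.marker_snapshots.max(initial=0)))
    for s in range(S):
        gs = trace.gene_snapshots[s]
        ms = trace.marker_snapshots[s]
        for d in range(1, D + 1):
            genes = np.where(gs == d)[0]
            markers = np.where(ms == d)[0]
            if len(genes) and len(markers):
                out[np.ix_(genes, markers)] += 1.0
    return out / S


def _align_modules(trace: SampleTrace) -> np.ndarray:
    """Map each snapshot's module indices onto the final snapshot's by
    greedy maximum overlap of marker sets (ties to the lower index);
    returns an S x (D+1) label map (0 stays 0)."""
    S = trace.n_snapshots
    D = trace.type_snapshots.shape[1]
    ref_markers = [set(np.where(trace.marker_snapshots[-1] == d)[0]) for d in range(D + 1)]
    ref_genes = [set(np.where(trace.gene_snapshots[-1] == d)[0]) for d in range(D + 1)]
    maps = np.zeros((S, D + 1), dtype=np.int64)
    for s in range(S):
        used = set()
        order = []
        overlaps = []
        for d in range(1, D + 1):
            mk = set(np.where(trace.marker_snapshots[s] == d)[0])
            gn = set(np.where(trace.gene_snapshots[s] == d)[0])
            for ref in range(1, D + 1):
                ov = len(mk & ref_markers[ref]) + len(gn & ref_genes[ref]) / 1e3
                overlaps.append((-ov, d, ref))
        for negov, d, ref in sorted(overlaps):
            if maps[s, d] == 0 and ref not in used and -negov > 0:
                maps[s, d] = ref
                used.add(ref)
        # leftovers keep their own index if free, else any free slot
        for d in range(1, D + 1):
            if maps[s, d] == 0:
                if d not in used:
                    maps[s, d] = d
                    used.add(d)
                else:
                    free = next(r for r in range(1, D + 1) if r not in used)
                    maps[s, d] = free
                    used.add(free)
    return maps


def gene_module_posterior(trace: SampleTrace):
    """Per-gene modal aligned module label and its posterior frequency.

    Returns ``(labels, probabilities)``: label 0 means the null module.
    """
    if trace.n_snapshots == 0:
        raise ValueError("empty trace")
    maps = _align_modules(trace)
    S, G = trace.gene_snapshots.shape
    D = trace.type_snapshots.shape[1]
    counts = np.zeros((G, D + 1), dtype=np.int64)
    for s in range(S):
        aligned = maps[s][trace.gene_snapshots[s]]
        for g in range(G):
            counts[g, aligned[g]] += 1
    labels = counts.argmax(axis=1)
    probs = counts[np.arange(G), labels] / S
    return labels, probs


def marker_module_posterior(trace: SampleTrace):
    """Per-marker aligned-module occupancy frequencies (M x (D+1))."""
    maps = _align_modules(trace)
    S, M = trace.marker_snapshots.shape
    D = trace.type_snapshots.shape[1]
    counts = np.zeros((M, D + 1), dtype=np.int64)
    for s in range(S):
        aligned = maps[s][trace.marker_snapshots[s]]
        for m in range(M):
            counts[m, aligned[m]] += 1
    return counts / S


def smooth_marker_posterior(
    marker_post: np.ndarray,
    geno: GenotypeMatrix,
    window_r2: float = 0.8,
):
    """LD-window smoothing of a per-marker posterior track.

    The window of marker m is the contiguous run of markers whose r^2
    with m exceeds ``window_r2``.  The smoothed value of m is the summed
    raw posterior over its window, capped at 1.  Peaks are selected
    greedily by descending smoothed value; all other markers inside a
    selected peak's window are masked.

    Returns ``(peaks, smoothed, mask)`` where ``mask`` is True for
    markers masked by a selected peak.
    """
    marker_post = np.asarray(marker_post, dtype=np.float64)
    M = len(marker_post)
    codes = geno.codes.astype(np.float64)
    sd = codes.std(axis=1)
    windows = []
    for m in range(M):
        members = [m]
        for direction in (-1, 1):
            j = m + direction
            while 0 <= j < M and sd[m] > 0 and sd[j] > 0:
                r = np.corrcoef(codes[m], codes[j])[0, 1]
                if r * r <= window_r2:
                    break
                members.append(j)
                j += direction
        windows.append(sorted(members))
    smoothed = np.array([min(1.0, marker_post[w].sum()) for w in windows])
    mask = np.zeros(M, dtype=bool)
    taken = np.zeros(M, dtype=bool)
    peaks = []
    for m in np.lexsort((np.arange(M), -smoothed)):
        if taken[m] or smoothed[m] <= 0:
            continue
        peaks.append(int(m))
        for j in windows[m]:
            taken[j] = True
            if j != m:
                mask[j] = True
    return peaks, smoothed, mask


@dataclass
class ModuleCall:
    """One extracted module: genes, peak markers, posteriors, K estimate."""

    module: int
    genes: list[int]
    gene_posteriors: list[float]
    markers: list[int]
    marker_posteriors: list[float]
    k_estimate: float
    interaction_p: Optional[float] = None
    gene_ids: list[str] = field(default_factory=list)
    marker_ids: list[str] = field(default_factory=list)


def extract_modules(
    trace: SampleTrace,
    geno: GenotypeMatrix,
    threshold: float = 0.8,
    window_r2: float = 0.8,
) -> list[ModuleCall]:
    """Threshold the aligned posteriors into module calls.

    Genes enter the call of their modal module when its posterior reaches
    ``threshold``; module marker lists are the window-smoothed posterior
    peaks at the same threshold.  Modules with no genes or no peak
    markers are dropped.
    """
    labels, probs = gene_module_posterior(trace)
    mk_post = marker_module_posterior(trace)
    D = trace.type_snapshots.shape[1]
    k_mean = trace.K_snapshots.mean(axis=0)
    calls = []
    for d in range(1, D + 1):
        genes = [int(g) for g in np.where((labels == d) & (probs >= threshold))[0]]
        if not genes:
            continue
        peaks, smoothed, _ = smooth_marker_posterior(mk_post[:, d], geno, window_r2)
        markers = [m for m in peaks if smoothed[m] >= threshold]
        if not markers:
            continue
        calls.append(ModuleCall(
            module=d,
            genes=genes,
            gene_posteriors=[float(probs[g]) for g in genes],
            markers=markers,
            marker_posteriors=[float(smoothed[m]) for m in markers],
            k_estimate=float(k_mean[d - 1]),
            gene_ids=[trace.gene_ids[g] for g in genes] if trace.gene_ids else [],
            marker_ids=[trace.marker_ids[m] for m in markers] if trace.marker_ids else [],
        ))
    return calls


def interaction_test(
    expr: ExpressionMatrix,
    gene_set: Sequence[int],
    geno: GenotypeMatrix,
    locus1: int,
    locus2: int,
) -> float:
    """F-test p-value for the two-locus interaction on the module-average
    trait.

    The member genes' standardized expression is averaged per individual
    and fitted to the two-locus cell-means model.  The interaction sum of
    squares is the residual-sum-of-squares drop from the additive model
    (grand mean + locus main effects) to the full four-cell-means model;
    F = (SSE_additive - SSE_full) / (SSE_full / (N - 4)).
    """
    if len(gene_set) == 0:
        raise ValueError("empty gene set")
    x1 = geno.codes[locus1]
    x2 = geno.codes[locus2]
    if np.unique(x1).size != 2 or np.unique(x2).size != 2:
        raise ValueError("both loci must be biallelic in the sample")
    for a in (0, 1):
        for b in (0, 1):
            if not np.any((x1 == a) & (x2 == b)):
                raise ValueError(f"empty genotype cell ({a}, {b})")
    Y = expr.values[list(gene_set)]
    Y = (Y - Y.mean(axis=1, keepdims=True)) / Y.std(axis=1, keepdims=True)
    y = Y.mean(axis=0)
    n = len(y)
    # additive model: design [1, x1, x2]
    Xa = np.column_stack([np.ones(n), x1, x2])
    beta_a, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    sse_a = float(((y - Xa @ beta_a) ** 2).sum())
    # full model: one mean per cell
    cell = x1 * 2 + x2
    fitted = np.zeros(n)
    for c in range(4):
        sel = cell == c
        fitted[sel] = y[sel].mean()
    sse_f = float(((y - fitted) ** 2).sum())
    df2 = n - 4
    fstat = (sse_a - sse_f) / (sse_f / df2)
    return float(f_dist.sf(fstat, 1, df2))


def consensus_modules(
    calls_per_run: list[list[ModuleCall]], jaccard: float = 0.5
) -> list[ModuleCall]:
    """Multi-run consensus: a gene is retained when its co-membership set
    is stable (Jaccard >= threshold) across all runs; surviving modules
    come from the first run, filtered to consensus genes."""
    if not calls_per_run:
        return []
    member_sets = []
    for calls in calls_per_run:
        by_gene: dict[int, frozenset] = {}
        for call in calls:
            fs = frozenset(call.genes)
            for g in call.genes:
                by_gene[g] = fs
        member_sets.append(by_gene)
    stable = set()
    for g, base in member_sets[0].items():
        ok = True
        for other in member_sets[1:]:
            s = other.get(g)
            if s is None:
                ok = False
                break
            jac = len(base & s) / len(base | s)
            if jac < jaccard:
                ok = False
                break
        if ok:
            stable.add(g)
    out = []
    for call in calls_per_run[0]:
        genes = [g for g in call.genes if g in stable]
        if genes:
            keep = [i for i, g in enumerate(call.genes) if g in stable]
            out.append(ModuleCall(
                module=call.module,
                genes=genes,
                gene_posteriors=[call.gene_posteriors[i] for i in keep],
                markers=call.markers,
                marker_posteriors=call.marker_posteriors,
                k_estimate=call.k_estimate,
                gene_ids=[call.gene_ids[i] for i in keep] if call.gene_ids else [],
                marker_ids=call.marker_ids,
            ))
    return out
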