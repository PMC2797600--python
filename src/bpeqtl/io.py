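"""TSV/JSON round-tripping of matrices, configs, traces and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .data import ExpressionMatrix, GenotypeMatrix, Hyperparameters
from .sampler import SampleTrace, SamplerConfig
from .summary import ModuleCall


def write_expression(expr: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# bpeqtl {__version__}\n")
        fh.write("gene\t" + "\t".join(expr.individual_ids) + "\n")
        for g, gid in enumerate(expr.gene_ids):
            row = "\t".join(f"{v:.12g}" for v in expr.values[g])
            fh.write(f"{gid}\t{row}\n")


def read_expression(path) -> ExpressionMatrix:
    """Read a gene x individual TSV (header row of individual ids)."""
    with open(path) as fh:
        header = fh.readline()
        first_data = 2
        while header.startswith("# "):
            header = fh.readline()
            first_data += 1
        header = header.rstrip("\n").split("\t")
        individual_ids = header[1:]
        gene_ids, rows = [], []
        seen = set()
        for lineno, line in enumerate(fh, start=first_data):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(individual_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(individual_ids) + 1} "
                    f"columns, found {len(parts)}"
                )
            if parts[0] in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {parts[0]!r}")
            seen.add(parts[0])
            gene_ids.append(parts[0])
            try:
                rows.append([float(x) for x in parts[1:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric cell ({err})")
    return ExpressionMatrix(np.array(rows), gene_ids, individual_ids)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    has_pos = geno.positions is not None
    with open(path, "w") as fh:
        fh.write(f"# bpeqtl {__version__}\n")
        cols = ["marker"]
        if has_pos:
            cols += ["chrom", "pos"]
        fh.write("\t".join(cols) + "\t#T=" + ",".join(str(int(t)) for t in geno.T) + "\n")
        for m, mid in enumerate(geno.marker_ids):
            row = [mid]
            if has_pos:
                chrom, pos = geno.positions[m]
                row += [chrom, str(pos)]
            row += [str(int(v)) for v in geno.codes[m]]
            fh.write("\t".join(row) + "\n")


def read_genotypes(path, T: Optional[int] = None) -> GenotypeMatrix:
    """Read a marker x individual genotype TSV (integer codes; optional
    chrom/pos columns)."""
    with open(path) as fh:
        header = fh.readline()
        first_data = 2
        while header.startswith("# "):
            header = fh.readline()
            first_data += 1
        header = header.rstrip("\n").split("\t")
        has_pos = len(header) >= 3 and header[1] == "chrom"
        t_spec = None
        if header[-1].startswith("#T="):
            t_spec = [int(x) for x in header[-1][3:].split(",")]
        marker_ids, rows, positions = [], [], []
        seen = set()
        for lineno, line in enumerate(fh, start=first_data):
            parts = line.rstrip("\n").split("\t")
            mid = parts[0]
            if mid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate marker id {mid!r}")
            seen.add(mid)
            marker_ids.append(mid)
            off = 1
            if has_pos:
                positions.append((parts[1], int(parts[2])))
                off = 3
            try:
                rows.append([int(x) for x in parts[off:]])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer genotype ({err})")
            if rows and len(rows[-1]) != len(rows[0]):
                raise ValueError(f"{path}:{lineno}: ragged row")
    codes = np.array(rows, dtype=np.int64)
    t_final = t_spec if t_spec is not None else (T if T is not None else int(codes.max()) + 1)
    return GenotypeMatrix(codes, marker_ids, np.asarray(t_final),
                          positions if has_pos else None)


_CONFIG_HP_KEYS = {f.name for f in Hyperparameters.__dataclass_fields__.values()}
_CONFIG_CFG_KEYS = {f.name for f in SamplerConfig.__dataclass_fields__.values()}


def run_config(path) -> tuple[Hyperparameters, SamplerConfig]:
    """Parse a flat JSON run configuration.

    Keys are the union of :class:`Hyperparameters` and
    :class:`SamplerConfig` fields; unknown keys are rejected, missing
    keys take the documented defaults.  ``D`` is required.
    """
    with open(path) as fh:
        raw = json.load(fh)
    unknown = set(raw) - _CONFIG_HP_KEYS - _CONFIG_CFG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "D" not in raw:
        raise ValueError("config must set D (number of non-null modules)")
    hp = Hyperparameters(**{k: v for k, v in raw.items() if k in _CONFIG_HP_KEYS})
    cfg = SamplerConfig(**{k: v for k, v in raw.items() if k in _CONFIG_CFG_KEYS})
    return hp, cfg


def write_trace(trace: SampleTrace, outdir) -> None:
    """Serialize a trace: columnar text snapshots, log-posterior TSV and a
    JSON manifest (config, seed, versions)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / "gene_snapshots.tsv", trace.gene_snapshots, fmt="%d", delimiter="\t")
    np.savetxt(outdir / "marker_snapshots.tsv", trace.marker_snapshots, fmt="%d", delimiter="\t")
    S, D, N = trace.type_snapshots.shape
    np.savetxt(outdir / "type_snapshots.tsv",
               trace.type_snapshots.reshape(S, D * N), fmt="%d", delimiter="\t")
    np.savetxt(outdir / "K_snapshots.tsv", trace.K_snapshots, fmt="%d", delimiter="\t")
    with open(outdir / "log_posterior.tsv", "w") as fh:
        fh.write("iteration\tlog_posterior\n")
        for i, v in enumerate(trace.log_posterior):
            fh.write(f"{i}\t{v:.12g}\n")
    cfg = trace.config
    manifest = {
        "tool": "bpeqtl",
        "version": __version__,
        "shape": {"S": S, "D": D, "N": N,
                  "G": trace.gene_snapshots.shape[1],
                  "M": trace.marker_snapshots.shape[1]},
        "config": {k: getattr(cfg, k) for k in _CONFIG_CFG_KEYS} if cfg else {},
        "swap_attempts": trace.swap_attempts.tolist(),
        "swap_accepts": trace.swap_accepts.tolist(),
        "gene_ids": trace.gene_ids,
        "marker_ids": trace.marker_ids,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def read_trace(outdir) -> SampleTrace:
    outdir = Path(outdir)
    with open(outdir / "manifest.json") as fh:
        manifest = json.load(fh)
    shape = manifest["shape"]
    gene = np.loadtxt(outdir / "gene_snapshots.tsv", dtype=np.int16, delimiter="\t",
                      ndmin=2)
    marker = np.loadtxt(outdir / "marker_snapshots.tsv", dtype=np.int16, delimiter="\t",
                        ndmin=2)
    types = np.loadtxt(outdir / "type_snapshots.tsv", dtype=np.int8, delimiter="\t",
                       ndmin=2).reshape(shape["S"], shape["D"], shape["N"])
    K = np.loadtxt(outdir / "K_snapshots.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
    lp = np.loadtxt(outdir / "log_posterior.tsv", delimiter="\t", skiprows=1, ndmin=2)[:, 1]
    cfg = SamplerConfig(**manifest["config"]) if manifest.get("config") else None
    return SampleTrace(
        gene, marker, types, K, lp,
        np.array(manifest["swap_attempts"], dtype=np.int64),
        np.array(manifest["swap_accepts"], dtype=np.int64),
        cfg, manifest.get("gene_ids", []), manifest.get("marker_ids", []),
    )


def write_module_report(calls: list[ModuleCall], tsv_path, json_path=None) -> None:
    """Write module calls as a member-per-row TSV and optionally nested
    JSON."""
    with open(tsv_path, "w") as fh:
        fh.write(f"# bpeqtl {__version__}\n")
        fh.write("module\tmember_type\tid\tposterior\n")
        for call in calls:
            gids = call.gene_ids or [str(g) for g in call.genes]
            mids = call.marker_ids or [str(m) for m in call.markers]
            for gid, p in zip(gids, call.gene_posteriors):
                fh.write(f"{call.module}\tgene\t{gid}\t{p:.4f}\n")
            for mid, p in zip(mids, call.marker_posteriors):
                fh.write(f"{call.module}\tmarker\t{mid}\t{p:.4f}\n")
    if json_path is not None:
        payload = []
        for call in calls:
            payload.append({
                "module": call.module,
                "genes": call.gene_ids or [str(g) for g in call.genes],
                "gene_posteriors": call.gene_posteriors,
                "markers": call.marker_ids or [str(m) for m in call.markers],
                "marker_posteriors": call.marker_posteriors,
                "k_estimate": call.k_estimate,
                "interaction_p": call.interaction_p,
            })
        with open(json_path, "w") as fh:
            json.dump({"version": __version__, "modules": payload}, fh, indent=1)


def write_marker_track(
    smoothed: np.ndarray, geno: GenotypeMatrix, path
) -> None:
    """BED-like marker posterior track (0-based half-open) when positions
    are available."""
    if geno.positions is None:
        raise ValueError("genotype matrix has no positions")
    with open(path, "w") as fh:
        for m, (chrom, pos) in enumerate(geno.positions):
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{smoothed[m]:.4f}\n")
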