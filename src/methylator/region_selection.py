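"""Target-region discovery from tumor/normal probe differences.

A probe is "most varied" when the mean tumor beta exceeds the mean normal
beta by at least a delta-beta threshold (0.3 by default, inclusive).
Neighbouring CpG probes tend to share methylation status (a "methylation
block"), so passing probes that sit close together on the chromosome are
assembled into one candidate region per run, optionally pulling in
non-passing probes that lie strictly between two passing ones. Region
endpoints always pass the filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

DEFAULT_DELTA_THRESHOLD = 0.3
DEFAULT_MAX_GAP = 1000  # bp between consecutive probes of one block


@dataclass
class TargetRegion:
    """A contiguous block of promoter probes treated as one methylation unit."""

    gene: str
    probe_ids: list[str]
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_pass: int
    n_fill: int = 0

    def __post_init__(self) -> None:
        if self.n_pass < 1:
            raise InputError("a target region needs at least one passing probe")
        if self.n_pass + self.n_fill != len(self.probe_ids):
            raise InputError("n_pass + n_fill must equal the probe count")


def compute_probe_deltas(matrix, manifest, threshold: float = DEFAULT_DELTA_THRESHOLD,
                         absolute: bool = False) -> pd.DataFrame:
    """Mean tumor/normal beta and their difference for every manifest probe.

    Returns one row per manifest probe present in the matrix with columns
    probe_id, gene, beta_tumor, beta_normal, delta_beta and passes. Group
    means ignore missing values. ``passes`` is delta_beta >= threshold
    (inclusive); with ``absolute`` the magnitude is compared instead.
    Manifest probes absent from the matrix are skipped with a log entry.
    """
    tumor_mask = (matrix.phenotype == "tumor").to_numpy()
    normal_mask = (matrix.phenotype == "normal").to_numpy()
    if not tumor_mask.any() or not normal_mask.any():
        raise ConfigurationError("need at least one tumor and one normal sample")

    present = manifest.table["probe_id"].isin(matrix.values.columns)
    skipped = manifest.table.loc[~present, "probe_id"]
    if len(skipped):
        logger.info("skipping %d manifest probes absent from matrix: %s...",
                    len(skipped), ", ".join(skipped.head(5)))
    probes = manifest.table.loc[present]
    sub = matrix.values[probes["probe_id"]]
    beta_tumor = sub.iloc[tumor_mask].mean(axis=0, skipna=True)
    beta_normal = sub.iloc[normal_mask].mean(axis=0, skipna=True)
    delta = beta_tumor - beta_normal
    crit = delta.abs() if absolute else delta
    return pd.DataFrame({
        "probe_id": probes["probe_id"].to_numpy(),
        "gene": probes["gene"].to_numpy(),
        "beta_tumor": beta_tumor.to_numpy(),
        "beta_normal": beta_normal.to_numpy(),
        "delta_beta": delta.to_numpy(),
        "passes": (crit >= threshold).to_numpy(),
    })


def _blocks_for_gene(probes: pd.DataFrame, max_gap: int, fill_interior: bool) -> list[TargetRegion]:
    """Assemble maximal blocks for one gene's coordinate-sorted probes."""
    passing = probes[probes["passes"]]
    if passing.empty:
        return []
    regions: list[TargetRegion] = []
    # chain passing probes whose consecutive genomic distance is <= max_gap
    run: list[int] = []
    for idx in passing.index:
        if run and (probes.loc[idx, "pos"] - probes.loc[run[-1], "pos"]) > max_gap:
            regions.append(_finalize_run(probes, run, fill_interior, max_gap))
            run = []
        run.append(idx)
    regions.append(_finalize_run(probes, run, fill_interior, max_gap))
    regions.sort(key=lambda r: (-r.n_pass, r.start))
    return regions


def _finalize_run(probes: pd.DataFrame, run: list[int], fill_interior: bool,
                  max_gap: int) -> TargetRegion:
    """Turn a run of passing-probe indices into a region, gap-filling inside."""
    first, last = run[0], run[-1]
    if fill_interior:
        members = probes.loc[first:last]
        # interior non-passing probes are kept only when both flanking
        # distances to the nearest passing neighbours stay within max_gap;
        # endpoints of the run always pass by construction
        keep = []
        pass_pos = probes.loc[run, "pos"].to_numpy()
        for idx in members.index:
            if members.loc[idx, "passes"]:
                keep.append(idx)
                continue
            pos = members.loc[idx, "pos"]
            left = pass_pos[pass_pos < pos]
            right = pass_pos[pass_pos > pos]
            if len(left) and len(right) and (pos - left.max()) <= max_gap \
                    and (right.min() - pos) <= max_gap:
                keep.append(idx)
        members = probes.loc[keep]
    else:
        members = probes.loc[run]
    n_pass = int(members["passes"].sum())
    return TargetRegion(
        gene=str(probes["gene"].iloc[0]),
        probe_ids=list(members["probe_id"]),
        chrom=str(probes["chrom"].iloc[0]),
        start=int(members["pos"].min()),
        end=int(members["pos"].max()),
        n_pass=n_pass,
        n_fill=len(members) - n_pass,
    )


def assemble_regions(deltas: pd.DataFrame, manifest, max_gap: int = DEFAULT_MAX_GAP,
                     fill_interior: bool = True) -> list[TargetRegion]:
    """Assemble candidate methylation-block regions for every gene.

    ``deltas`` must come from :func:`compute_probe_deltas` on the same
    manifest. Per gene, probes are ordered by genomic position; maximal runs
    of passing probes with consecutive inter-probe distance <= ``max_gap``
    form blocks, and with ``fill_interior`` non-passing probes strictly
    inside a block join it (counted in ``n_fill``). Genes without passing
    probes yield no region (logged, not an error). Within a gene, blocks are
    returned largest-first by ``n_pass``.
    """
    merged = manifest.table.merge(
        deltas[["probe_id", "passes"]], on="probe_id", how="inner"
    ).sort_values(["gene", "chrom", "pos"], kind="mergesort")
    regions: list[TargetRegion] = []
    for gene, probes in merged.groupby("gene", sort=True):
        per_chrom = []
        for _, chrom_probes in probes.groupby("chrom", sort=True):
            per_chrom.extend(_blocks_for_gene(
                chrom_probes.reset_index(drop=True), max_gap, fill_interior))
        if not per_chrom:
            logger.info("gene %s has no probe passing the delta-beta filter", gene)
        per_chrom.sort(key=lambda r: (-r.n_pass, r.start))
        regions.extend(per_chrom)
    return regions


def select_primary_region(regions: list[TargetRegion], gene: str) -> TargetRegion:
    """Pick the gene's target region: most passing probes wins.

    Ties break to the larger total probe count, then the leftmost start.
    """
    candidates = [r for r in regions if r.gene == gene]
    if not candidates:
        raise ConfigurationError(f"no candidate region for gene {gene!r}")
    return min(candidates, key=lambda r: (-r.n_pass, -len(r.probe_ids), r.start))


def regions_to_bed(regions: list[TargetRegion]) -> pd.DataFrame:
    """BED-style table (0-based half-open) for export; internals stay 1-based."""
    return pd.DataFrame({
        "chrom": [r.chrom for r in regions],
        "start": [r.start - 1 for r in regions],
        "end": [r.end for r in regions],
        "gene": [r.gene for r in regions],
        "n_pass": [r.n_pass for r in regions],
        "probe_ids": [",".join(r.probe_ids) for r in regions],
    })
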