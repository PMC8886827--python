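"""End-to-end convenience wrappers chaining the analysis stages."""

from __future__ import annotations

import pandas as pd

from .io_formats import BetaMatrix, ProbeManifest
from .meth_transforms import beta_to_m, region_beta
from .phenotype_classification import DEFAULT_BETA_THRESHOLD, call_from_beta
from .region_selection import (assemble_regions, compute_probe_deltas,
                               select_primary_region)
from .threshold_mixture import fit_m_mixture


def score_target_genes(matrix: BetaMatrix, manifest: ProbeManifest,
                       genes=("SDC2", "TFPI2"), delta_threshold: float = 0.3,
                       max_gap: int = 1000) -> pd.DataFrame:
    """Select each gene's primary region and score every sample on it."""
    deltas = compute_probe_deltas(matrix, manifest, threshold=delta_threshold)
    regions = assemble_regions(deltas, manifest, max_gap=max_gap)
    scores = [region_beta(matrix, select_primary_region(regions, g)) for g in genes]
    return pd.concat(scores, ignore_index=True)


def classify_cohort(matrix: BetaMatrix, manifest: ProbeManifest,
                    genes=("SDC2", "TFPI2"),
                    beta_threshold: float = DEFAULT_BETA_THRESHOLD) -> pd.DataFrame:
    """Region selection + scoring + HH/HL/LL calling in one step."""
    scores = score_target_genes(matrix, manifest, genes=genes)
    return call_from_beta(scores, beta_threshold=beta_threshold, genes=genes)


def fit_threshold(matrix: BetaMatrix, seed: int = 0, tumor_only: bool = False,
                  subsample: int | None = None):
    """Fit the M-value mixture on all pooled probe x sample values."""
    values = matrix.values
    if tumor_only:
        values = values.loc[matrix.phenotype == "tumor"]
    m = beta_to_m(values.to_numpy().ravel())
    return fit_m_mixture(m[~pd.isna(m)], seed=seed, subsample=subsample)
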