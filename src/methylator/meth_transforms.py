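"""Methylation-scale transforms and region/qPCR derived quantities.

The two standard scales for Infinium methylation arrays are the beta value
(fraction methylated, in [0, 1], directly interpretable) and the M-value
(log2 odds of beta, unbounded, statistically better behaved). The promoter
methylation level of a gene is summarized as the mean beta over the probes
of its target region. Methylation-specific qPCR is summarized through
delta-Ct against the ACTB internal control and the relative level 2^(-dCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError

#: Clip bound applied to beta before the log-odds transform. Array betas are
#: compressed near 0 and 1 while the logit is unbounded, so exact 0/1 are
#: pulled inside the open interval instead of mapping to +-inf.
BETA_EPS = 1e-6


def beta_to_m(beta):
    """Convert beta (fraction methylated) to the M-value log2(beta/(1-beta)).

    Accepts scalars or arrays. Values of exactly 0 or 1 are clipped to
    [BETA_EPS, 1-BETA_EPS]; values outside [0, 1] raise ``DomainError``.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (arr < 0) | (arr > 1)
    if np.any(bad):
        raise DomainError(f"beta value outside [0, 1]: {arr[bad].flat[0]}")
    clipped = np.clip(arr, BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(clipped / (1.0 - clipped))
    return m.item() if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse transform: beta = 2^m / (1 + 2^m), in the open interval (0, 1)."""
    arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DomainError("non-finite M-value")
    # logistic in base 2, written to avoid overflow for large |m|
    beta = np.where(arr >= 0, 1.0 / (1.0 + 2.0 ** (-arr)),
                    2.0 ** np.minimum(arr, 0) / (1.0 + 2.0 ** np.minimum(arr, 0)))
    return beta.item() if np.isscalar(m) else beta


def region_beta(matrix, region) -> pd.DataFrame:
    """Per-sample mean beta over a target region's probes.

    Returns a DataFrame with columns sample_id, gene, beta_mean and
    n_probes_used. The mean is over the non-missing region probes present in
    the matrix; a sample with no usable probe gets beta_mean NaN and
    n_probes_used 0. Raises ``ConfigurationError`` when none of the region's
    probes exist in the matrix at all.
    """
    probes = [p for p in region.probe_ids if p in matrix.values.columns]
    if not probes:
        raise ConfigurationError(
            f"none of the {len(region.probe_ids)} probes of region "
            f"{region.gene!r} are present in the beta matrix"
        )
    sub = matrix.values[probes]
    return pd.DataFrame({
        "sample_id": sub.index,
        "gene": region.gene,
        "beta_mean": sub.mean(axis=1, skipna=True).to_numpy(),
        "n_probes_used": sub.notna().sum(axis=1).to_numpy(),
    }).reset_index(drop=True)


@dataclass
class RelativeMethylation:
    """qPCR-derived relative methylation of one target in one sample."""

    sample_id: str
    gene: str
    delta_ct: float   # cycles, target minus ACTB control
    rel_level: float  # 2^(-delta_ct); higher = more methylated template


def relative_methylation(ct_target: float, ct_control: float,
                         sample_id: str = "", gene: str = "") -> RelativeMethylation:
    """Compute delta-Ct (target - control) and the relative level 2^(-dCt).

    The target-minus-control direction makes 2^(-dCt) increase with the
    amount of methylated template, so it can be correlated directly with
    covariates such as patient age.
    """
    if not (np.isfinite(ct_target) and np.isfinite(ct_control)):
        raise DomainError("Ct values must be finite")
    delta = float(ct_target) - float(ct_control)
    return RelativeMethylation(sample_id=sample_id, gene=gene,
                               delta_ct=delta, rel_level=2.0 ** (-delta))
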