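"""Expression stage: filtering, normalization, DE and gene-set enrichment.

Counts are filtered of genes that are zero in more than 90% of samples,
normalized by median-of-ratios size factors, and compared pairwise between
the three methylator groups with a rank-based two-sample test per gene,
Benjamini-Hochberg adjusted within each pair. A differentially expressed
gene (DEG) is then assigned to the group in which its mean normalized
expression is strictly highest ("group-specific DEG"); exact ties stay
unassigned. Enrichment of a query gene set against user-supplied collections
(GMT format) uses the one-sided (upper-tail) hypergeometric test with BH
adjustment across sets.

The rank-based DE test is a deliberately simple built-in; it does not aim
to reproduce the gene lists of any particular negative-binomial DE engine.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, InputError
from .io_formats import CountMatrix
from .phenotype_classification import GROUPS

DEFAULT_ZERO_FRACTION = 0.9
DEFAULT_FDR_LEVEL = 0.05

PAIRS = (("HH", "HL"), ("HH", "LL"), ("HL", "LL"))


def filter_low_expression(counts: CountMatrix,
                          zero_fraction: float = DEFAULT_ZERO_FRACTION) -> CountMatrix:
    """Drop genes whose zero fraction strictly exceeds ``zero_fraction``.

    A gene zero in exactly 90% of samples is kept (the rule is "more than").
    """
    zeros = (counts.counts == 0).mean(axis=1)
    return CountMatrix(counts=counts.counts.loc[zeros <= zero_fraction].copy())


def size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Using only genes nonzero in every sample, each sample's factor is the
    median over those genes of its count divided by the gene's geometric
    mean across samples. Raises when no gene is nonzero everywhere.
    """
    mat = counts.counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise AnalysisError(
            "no gene is nonzero in every sample; cannot form the reference "
            "(consider filtering samples or a pseudo-reference)")
    ref = mat[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    return pd.Series(np.median(ratios, axis=0), index=counts.counts.columns,
                     name="size_factor")


def normalized_counts(counts: CountMatrix) -> pd.DataFrame:
    return counts.counts / size_factors(counts)


def differential_expression(counts: CountMatrix, groups: dict | pd.Series,
                            fdr_level: float = DEFAULT_FDR_LEVEL) -> pd.DataFrame:
    """Pairwise rank-based DE between the three methylator groups.

    ``groups`` maps sample id to HH/HL/LL; every group needs at least 3
    samples. Returns one row per gene with the raw and BH-adjusted p-value
    of each pair (adjustment within pair, across genes), per-group mean
    normalized expression, and ``is_deg`` (any adjusted p <= ``fdr_level``).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    samples = [s for s in counts.sample_ids if s in groups.index]
    groups = groups.loc[samples]
    sizes = groups.value_counts()
    for g in GROUPS:
        if sizes.get(g, 0) < 3:
            raise InputError(f"group {g} has fewer than 3 samples")
    sub = CountMatrix(counts=counts.counts[samples].copy())
    norm = normalized_counts(sub)

    out = pd.DataFrame(index=norm.index)
    for g in GROUPS:
        out[f"mean_{g}"] = norm.loc[:, groups == g].mean(axis=1)
    any_sig = np.zeros(len(norm), dtype=bool)
    for a, b in PAIRS:
        xa = norm.loc[:, groups == a].to_numpy()
        xb = norm.loc[:, groups == b].to_numpy()
        # vectorized Mann-Whitney per gene; constant genes get p = 1
        res = stats.mannwhitneyu(xa, xb, axis=1, method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        flat = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0) & \
               (xa[:, 0] == xb[:, 0])
        p[flat | ~np.isfinite(p)] = 1.0
        padj = multipletests(p, method="fdr_bh")[1]
        out[f"p_{a}_vs_{b}"] = p
        out[f"padj_{a}_vs_{b}"] = padj
        any_sig |= padj <= fdr_level
    out["is_deg"] = any_sig
    out.index.name = "gene"
    return out.reset_index()


def assign_group_specific(results: pd.DataFrame) -> pd.DataFrame:
    """Assign each DEG to the group with strictly highest mean expression.

    Exact ties in the argmax leave the gene ``unassigned``. Non-DEGs are
    excluded from the output.
    """
    degs = results[results["is_deg"]].copy()
    means = degs[[f"mean_{g}" for g in GROUPS]].to_numpy()
    assigned = []
    for row in means:
        top = row.max()
        winners = [g for g, v in zip(GROUPS, row) if v == top]
        assigned.append(winners[0] if len(winners) == 1 else "unassigned")
    degs["assigned_group"] = assigned
    return degs[["gene", "assigned_group"] + [f"mean_{g}" for g in GROUPS]]


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def gene_set_enrichment(genes, sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``genes`` in each named set.

    ``genes`` must be a subset of ``universe``; each set is intersected with
    the universe first. Returns per set the overlap, set size within the
    universe, raw p = P(X >= overlap) and BH-adjusted p across sets.
    """
    universe = set(universe)
    query = set(genes)
    if not universe or not query:
        raise InputError("universe and query must be non-empty")
    if not query <= universe:
        raise InputError("query genes must all belong to the universe")
    rows = []
    for name, members in sets.items():
        in_uni = set(members) & universe
        overlap = len(query & in_uni)
        # P(X >= overlap) with X ~ Hypergeom(|U|, |set|, |query|)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(in_uni),
                                     len(query)))
        rows.append({"set": name, "set_size": len(in_uni), "overlap": overlap,
                     "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
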