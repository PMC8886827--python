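"""Group-association statistics: exact contingency tests and comparisons.

The methylator groups are compared against clinical variables with the
tests a clinical-epigenetics study would use: Fisher's exact test for
categorical variables (tumor location, MSI status, per-gene mutation
status), Kruskal-Wallis for continuous ones (age, mutation load), and
Pearson correlation for paired continuous quantities (age versus promoter
methylation level).

The exact test is implemented here from first principles for general r x c
tables: the p-value is the total conditional (multivariate hypergeometric)
probability of all tables with the observed margins whose probability does
not exceed that of the observed table (probability-ordering rule, with a
1e-7 relative tolerance on the comparison). Enumeration proceeds by
recursive cell assignment with margin pruning; when the table is too large
to enumerate, a margin-preserving Monte Carlo permutation estimate is used
instead and flagged in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigurationError, DomainError, InputError

logger = logging.getLogger(__name__)

#: Relative tolerance of the "probability <= observed" comparison.
P_ORDER_RTOL = 1e-7
#: Tables with total count above this use Monte Carlo instead of enumeration.
DEFAULT_MC_THRESHOLD = 5000
DEFAULT_MC_REPS = 100_000
#: Upper bound on enumeration-tree nodes before falling back to Monte Carlo.
ENUM_NODE_CAP = 500_000

MANTIS_MSI_CUTOFF = 0.4


@dataclass
class ContingencyTable:
    """An r x c table of nonnegative integer counts with labelled margins."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        r, c = self.counts.shape
        if r < 2 or c < 2:
            raise InputError("contingency table needs at least 2 rows and 2 columns")
        if (self.counts < 0).any():
            raise InputError("negative count in contingency table")
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise InputError("label lengths do not match table shape")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_crosstab(cls, tab: pd.DataFrame) -> "ContingencyTable":
        return cls(counts=tab.to_numpy(), row_labels=[str(x) for x in tab.index],
                   col_labels=[str(x) for x in tab.columns])


@dataclass
class TestResult:
    """Outcome of one statistical test."""

    p_value: float
    method: str
    statistic: float | None = None
    df: int | None = None
    n: int | None = None
    mc_reps: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise AnalysisError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Fisher's exact test, r x c
# ---------------------------------------------------------------------------

def _log_table_prob(counts: np.ndarray, lgam: np.ndarray,
                    const: float) -> float:
    """log multivariate hypergeometric probability of one table."""
    return const - lgam[counts].sum()


def _enum_bound(row_sums: np.ndarray, col_sums: np.ndarray) -> float:
    """Upper bound on enumeration-tree leaves: free rows' compositions.

    Each of the first r-1 rows branches into at most C(row_i + c - 1, c - 1)
    compositions (column margins only prune further); the last row is forced.
    """
    c = len(col_sums)
    log_bound = 0.0
    for rs in row_sums[:-1]:
        log_bound += (gammaln(rs + c) - gammaln(rs + 1) - gammaln(c))
        if log_bound > 60:  # ~1e26, hopeless either way
            return np.inf
    return float(np.exp(log_bound))


def _enumerate_p(counts: np.ndarray, lgam: np.ndarray) -> float:
    """Exact probability-ordering p by recursive enumeration with pruning."""
    r, c = counts.shape
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = counts.sum()
    const = lgam[row_sums].sum() + lgam[col_sums].sum() - lgam[n]
    log_obs = _log_table_prob(counts, lgam, const)
    cutoff = log_obs + np.log1p(P_ORDER_RTOL)

    total_p = 0.0
    cell = np.zeros((r, c), dtype=np.int64)

    def fill(i: int, j: int, col_left: np.ndarray, row_left: int,
             neg_lgam_acc: float) -> None:
        nonlocal total_p
        if i == r - 1:
            # last row forced by column margins
            lp = const + neg_lgam_acc - lgam[col_left].sum()
            if lp <= cutoff:
                total_p += np.exp(lp)
            return
        if j == c - 1:
            if row_left > col_left[j]:
                return
            col_left[j] -= row_left
            fill(i + 1, 0, col_left, row_sums[i + 1],
                 neg_lgam_acc - lgam[row_left])
            col_left[j] += row_left
            return
        # prune: the rest of this row must fit in the remaining columns
        rest_capacity = col_left[j + 1:].sum()
        lo = max(0, row_left - rest_capacity)
        hi = min(row_left, col_left[j])
        for v in range(lo, hi + 1):
            col_left[j] -= v
            fill(i, j + 1, col_left, row_left - v, neg_lgam_acc - lgam[v])
            col_left[j] += v

    fill(0, 0, col_sums.copy(), int(row_sums[0]), 0.0)
    return min(total_p, 1.0)


def _monte_carlo_p(counts: np.ndarray, lgam: np.ndarray, reps: int,
                   seed: int) -> float:
    """Margin-preserving permutation estimate of the probability-ordering p.

    Row and column labels of the underlying observations are held fixed and
    the column labels permuted, which samples tables from the conditional
    distribution given the margins.
    """
    r, c = counts.shape
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n = int(counts.sum())
    const = lgam[row_sums].sum() + lgam[col_sums].sum() - lgam[n]
    log_obs = _log_table_prob(counts, lgam, const)
    cutoff = log_obs + np.log1p(P_ORDER_RTOL)

    row_lab = np.repeat(np.arange(r), row_sums)
    col_lab = np.repeat(np.arange(c), col_sums)
    rng = np.random.default_rng(seed)
    hits = 0
    batch = max(1, min(reps, 20_000_000 // max(n, 1)))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        # permute column labels independently per replicate
        keys = rng.random((b, n))
        order = np.argsort(keys, axis=1)
        perm_cols = col_lab[order]
        idx = row_lab[None, :] * c + perm_cols
        offset = (np.arange(b) * (r * c))[:, None]
        flat = np.bincount((idx + offset).ravel(), minlength=b * r * c)
        sim_counts = flat.reshape(b, r * c)
        lp = const - lgam[sim_counts].sum(axis=1)
        hits += int((lp <= cutoff).sum())
        done += b
    return (hits + 1) / (reps + 1)


def fisher_exact(table: ContingencyTable, mc_threshold: int = DEFAULT_MC_THRESHOLD,
                 mc_reps: int = DEFAULT_MC_REPS, seed: int = 0,
                 enum_cap: float = ENUM_NODE_CAP) -> TestResult:
    """Two-sided Fisher exact test on an r x c table.

    Uses full enumeration when the table total is at most ``mc_threshold``
    and a bound on the enumeration tree stays below ``enum_cap``; otherwise
    a seeded margin-preserving Monte Carlo estimate (method ``fisher_mc``).
    A zero row or column margin raises ``AnalysisError``.
    """
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise AnalysisError("degenerate contingency table: zero margin")
    # lgam[k] = log(k!) for every count that can appear in a cell or margin
    lgam = gammaln(np.arange(int(counts.sum()) + 2, dtype=float) + 1.0)
    if counts.sum() <= mc_threshold and \
            _enum_bound(row_sums, col_sums) <= enum_cap:
        p = _enumerate_p(counts, lgam)
        return TestResult(p_value=p, method="fisher_exact", n=table.total)
    p = _monte_carlo_p(counts, lgam, reps=mc_reps, seed=seed)
    return TestResult(p_value=p, method="fisher_mc", n=table.total,
                      mc_reps=mc_reps, seed=seed)


# ---------------------------------------------------------------------------
# rank / correlation tests
# ---------------------------------------------------------------------------

def kruskal_wallis(values, groups) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups with midrank ties correction.

    All-identical values yield H = 0 and p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if values.shape != labels.shape:
        raise InputError("values and groups must have equal length")
    uniq = pd.unique(labels)
    samples = [values[labels == g] for g in uniq]
    samples = [s for s in samples if len(s)]
    if len(samples) < 2:
        raise InputError("Kruskal-Wallis needs at least 2 non-empty groups")
    if np.ptp(values) == 0:
        return TestResult(p_value=1.0, method="kruskal_wallis", statistic=0.0,
                          df=len(samples) - 1, n=len(values))
    h, p = stats.kruskal(*samples)
    return TestResult(p_value=float(p), method="kruskal_wallis",
                      statistic=float(h), df=len(samples) - 1, n=len(values))


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with the two-sided t-transform p-value (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("need equal-length vectors of at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return TestResult(p_value=float(p), method="pearson", statistic=float(r),
                      n=x.size)


def msi_group(mantis: float) -> str:
    """MSI call from the MANTIS score: > 0.4 is MSI-H, <= 0.4 is MSS."""
    if mantis < 0:
        raise DomainError(f"MANTIS score must be nonnegative, got {mantis}")
    return "MSI-H" if mantis > MANTIS_MSI_CUTOFF else "MSS"


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

REPORT_VARIABLES = ("location", "age", "msi", "mutation_load", "gene_mutations")


def _crosstab(groups: pd.Series, cats: pd.Series) -> ContingencyTable:
    keep = groups.notna() & cats.notna()
    tab = pd.crosstab(groups[keep], cats[keep])
    return ContingencyTable.from_crosstab(tab)


def group_association_report(calls: pd.DataFrame, clinical,
                             variables=REPORT_VARIABLES,
                             mc_reps: int = DEFAULT_MC_REPS,
                             seed: int = 0) -> dict:
    """Run every requested group-versus-variable comparison.

    ``calls`` is a methylator-call table (only valid HH/HL/LL samples are
    used); ``clinical`` a ClinicalTable. Categorical variables get a group x
    category table plus Fisher's exact test; continuous ones a
    Kruskal-Wallis test; per-gene mutation status a mutated/wildtype x group
    table each, with Benjamini-Hochberg adjusted p-values reported alongside
    the raw ones (raw stays primary).
    """
    valid = calls[calls["group"].isin(("HH", "HL", "LL"))]
    clin = clinical.table
    joined = valid.merge(clin, left_on="sample_id", right_index=True, how="inner")
    if joined.empty:
        raise InputError("no overlap between calls and clinical sample ids")
    groups = joined["group"]
    report: dict[str, dict] = {}
    for var in variables:
        if var == "location":
            if "location" not in joined.columns:
                raise ConfigurationError("clinical table lacks location")
            tab = _crosstab(groups, joined["location"])
            report[var] = {"table": tab,
                           "test": fisher_exact(tab, mc_reps=mc_reps, seed=seed)}
        elif var == "age":
            if "age" not in joined.columns:
                raise ConfigurationError("clinical table lacks age")
            keep = joined["age"].notna()
            report[var] = {"table": None,
                           "test": kruskal_wallis(joined.loc[keep, "age"],
                                                  groups[keep])}
        elif var == "msi":
            if "msi" in joined.columns and joined["msi"].notna().any():
                msi = joined["msi"]
            elif "mantis" in joined.columns:
                msi = joined["mantis"].map(
                    lambda v: msi_group(v) if pd.notna(v) else None)
            else:
                raise ConfigurationError("clinical table lacks msi and mantis")
            tab = _crosstab(groups, pd.Series(msi, index=joined.index))
            report[var] = {"table": tab,
                           "test": fisher_exact(tab, mc_reps=mc_reps, seed=seed)}
        elif var == "mutation_load":
            if "nonsyn_mutations" not in joined.columns:
                raise ConfigurationError("clinical table lacks nonsyn_mutations")
            keep = joined["nonsyn_mutations"].notna()
            report[var] = {"table": None,
                           "test": kruskal_wallis(
                               joined.loc[keep, "nonsyn_mutations"], groups[keep])}
        elif var == "gene_mutations":
            mut_cols = [c for c in joined.columns if c.startswith("mut_")]
            if not mut_cols:
                raise ConfigurationError("clinical table lacks mut_<gene> columns")
            per_gene = {}
            for col in mut_cols:
                tab = _crosstab(pd.Series(joined[col], index=joined.index), groups)
                per_gene[col[4:]] = {
                    "table": tab,
                    "test": fisher_exact(tab, mc_reps=mc_reps, seed=seed)}
            raw = [per_gene[g]["test"].p_value for g in per_gene]
            adj = multipletests(raw, method="fdr_bh")[1]
            for g, a in zip(per_gene, adj):
                per_gene[g]["adjusted_p"] = float(a)
            report[var] = per_gene
        else:
            raise ConfigurationError(f"unknown report variable {var!r}")
    return report


def cross_dataset_average(percentages) -> float:
    """Unweighted mean of per-dataset percentages, to 2 decimals."""
    vals = list(percentages)
    if not vals:
        raise InputError("need at least one dataset percentage")
    return round(float(np.mean(vals)), 2)


def pct(count: int, total: int) -> float:
    """A printed-style percentage, rounded to 2 decimals."""
    if total <= 0:
        raise InputError("total must be positive")
    return round(100.0 * count / total, 2)
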