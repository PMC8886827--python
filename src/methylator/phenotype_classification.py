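"""High/low methylation calls and the combined HH/HL/LL methylator group.

A sample's methylator group combines the per-gene promoter methylation
status of SDC2 and TFPI2: HH when both are high, LL when both are low, HL
when exactly one is high. Status comes either from array region-mean beta
values (high iff beta > threshold, strictly; default 0.2) or from
methylation-specific PCR Ct values (high iff mean Ct < 38, strictly), with
the ACTB internal control deciding sample validity (mean ACTB Ct > 36.00 is
invalid; 36.00 itself is still valid). Replicates with no amplification
curve within 45 cycles are assigned Ct 45.00 before averaging, and a Ct of
exactly 45.00 counts as not detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, FormatError, InputError

DEFAULT_BETA_THRESHOLD = 0.2
DEFAULT_CT_THRESHOLD = 38.0
DEFAULT_CT_CEILING = 45.0
DEFAULT_CONTROL_LIMIT = 36.0

GROUPS = ("HH", "HL", "LL")
FOUR_STATES = ("HH_both", "high_sdc2_low_tfpi2", "low_sdc2_high_tfpi2", "LL_both")

_STATE_OF = {
    ("high", "high"): "HH_both",
    ("high", "low"): "high_sdc2_low_tfpi2",
    ("low", "high"): "low_sdc2_high_tfpi2",
    ("low", "low"): "LL_both",
}
_GROUP_OF = {
    "HH_both": "HH",
    "high_sdc2_low_tfpi2": "HL",
    "low_sdc2_high_tfpi2": "HL",
    "LL_both": "LL",
}


def aggregate_ct(replicates, ceiling: float = DEFAULT_CT_CEILING) -> float:
    """Mean Ct over 1-3 replicates; no-amplification replicates count as ceiling.

    A replicate is "no amplification" when given as None/NaN, or when it
    reached the ceiling cycle (values >= ceiling are truncated to it).
    """
    reps = list(replicates)
    if not 1 <= len(reps) <= 3:
        raise InputError(f"expected 1-3 Ct replicates, got {len(reps)}")
    vals = []
    for r in reps:
        if r is None or (isinstance(r, float) and np.isnan(r)):
            vals.append(ceiling)
        elif r <= 0:
            raise InputError(f"Ct value {r} must be positive")
        else:
            vals.append(min(float(r), ceiling))
    return float(np.mean(vals))


@dataclass
class CtRecord:
    """Averaged MSP triplicate for one target gene in one sample.

    ``replicate_cts``/``actb_cts`` hold the raw replicates with
    no-amplification entries already encoded as the ceiling (use None/NaN on
    construction to mark them). ``valid`` reflects the ACTB internal control:
    mean control Ct above the limit invalidates the measurement.
    """

    sample_id: str
    gene: str
    replicate_cts: list[float]
    actb_cts: list[float]
    ceiling: float = DEFAULT_CT_CEILING
    control_limit: float = DEFAULT_CONTROL_LIMIT
    mean_ct: float = field(init=False)
    mean_actb: float = field(init=False)
    valid: bool = field(init=False)

    def __post_init__(self) -> None:
        self.mean_ct = aggregate_ct(self.replicate_cts, self.ceiling)
        self.mean_actb = aggregate_ct(self.actb_cts, self.ceiling)
        self.replicate_cts = [self.ceiling if (r is None or (isinstance(r, float) and np.isnan(r)))
                              else min(float(r), self.ceiling) for r in self.replicate_cts]
        self.valid = self.mean_actb <= self.control_limit


def _finish_calls(frame: pd.DataFrame, source: str) -> pd.DataFrame:
    four, group = [], []
    for s1, s2 in zip(frame["status_sdc2"], frame["status_tfpi2"]):
        if s1 in ("missing", "invalid") or s2 in ("missing", "invalid"):
            four.append("invalid")
            group.append("invalid")
        else:
            st = _STATE_OF[(s1, s2)]
            four.append(st)
            group.append(_GROUP_OF[st])
    frame["four_state"] = four
    frame["group"] = group
    frame["source"] = source
    return frame


def call_from_beta(scores: pd.DataFrame, beta_threshold: float = DEFAULT_BETA_THRESHOLD,
                   genes: tuple[str, str] = ("SDC2", "TFPI2")) -> pd.DataFrame:
    """Methylator calls from array region scores.

    ``scores`` needs columns sample_id, gene, beta_mean (the output of
    region scoring) covering the two target genes; the first name in
    ``genes`` fills the SDC2 slot, the second the TFPI2 slot. Status is high
    iff beta_mean > threshold (strict), low otherwise, missing when the
    score is absent or NaN — which makes the whole sample invalid.
    """
    needed = {"sample_id", "gene", "beta_mean"}
    if not needed.issubset(scores.columns):
        raise FormatError(f"scores table needs columns {sorted(needed)}")
    dup = scores.duplicated(subset=["sample_id", "gene"])
    if dup.any():
        pair = scores.loc[dup, ["sample_id", "gene"]].iloc[0]
        raise InputError(f"duplicated score for sample {pair['sample_id']!r}, "
                         f"gene {pair['gene']!r}")
    wide = scores.pivot(index="sample_id", columns="gene", values="beta_mean")

    def status(series: pd.Series) -> list[str]:
        return ["missing" if pd.isna(v) else ("high" if v > beta_threshold else "low")
                for v in series]

    frame = pd.DataFrame({"sample_id": wide.index})
    for slot, gene in zip(("status_sdc2", "status_tfpi2"), genes):
        col = wide[gene] if gene in wide.columns else pd.Series(np.nan, index=wide.index)
        frame[slot] = status(col)
    return _finish_calls(frame, source="array")


def call_from_ct(records: list[CtRecord], ct_threshold: float = DEFAULT_CT_THRESHOLD,
                 control_limit: float = DEFAULT_CONTROL_LIMIT,
                 genes: tuple[str, str] = ("SDC2", "TFPI2")) -> pd.DataFrame:
    """Methylator calls from MSP Ct records.

    Per sample there must be a record for each target gene, each carrying
    its ACTB control replicates. The sample is invalid when the mean control
    Ct exceeds ``control_limit``; otherwise status is high iff mean target
    Ct < ``ct_threshold`` (strict).
    """
    by_sample: dict[str, dict[str, CtRecord]] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {})[rec.gene] = rec
    rows = []
    for sample_id, recs in by_sample.items():
        missing = [g for g in genes if g not in recs]
        if missing:
            raise InputError(f"sample {sample_id!r} lacks a Ct record for {missing[0]!r}")
        control_ok = all(recs[g].mean_actb <= control_limit for g in genes)
        statuses = {}
        for slot, gene in zip(("status_sdc2", "status_tfpi2"), genes):
            if not control_ok:
                statuses[slot] = "invalid"
            else:
                statuses[slot] = "high" if recs[gene].mean_ct < ct_threshold else "low"
        rows.append({"sample_id": sample_id, **statuses})
    return _finish_calls(pd.DataFrame(rows), source="msp")


def read_ct_export(path, ceiling: float = DEFAULT_CT_CEILING,
                   control_limit: float = DEFAULT_CONTROL_LIMIT) -> list[CtRecord]:
    """Parse a qPCR Ct export (CSV/TSV) into CtRecords.

    Expected columns: sample_id, gene, ct1..ct3, actb1..actb3. Empty cells
    mark replicates with no amplification curve.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    needed = {"sample_id", "gene"}
    if not needed.issubset(raw.columns):
        raise FormatError("Ct export needs sample_id and gene columns")
    rep_cols = [c for c in ("ct1", "ct2", "ct3") if c in raw.columns]
    ctl_cols = [c for c in ("actb1", "actb2", "actb3") if c in raw.columns]
    if not rep_cols or not ctl_cols:
        raise FormatError("Ct export needs ct1..ct3 and actb1..actb3 columns")
    records = []
    for _, row in raw.iterrows():
        records.append(CtRecord(
            sample_id=str(row["sample_id"]), gene=str(row["gene"]),
            replicate_cts=[row[c] for c in rep_cols],
            actb_cts=[row[c] for c in ctl_cols],
            ceiling=ceiling, control_limit=control_limit,
        ))
    return records


def summarize_groups(calls: pd.DataFrame, tumor_only: bool = True,
                     phenotype: pd.Series | None = None) -> dict:
    """Four-state counts and percentages among valid samples.

    Invalid samples are reported separately and excluded from percentage
    denominators. When ``tumor_only`` and a phenotype series is supplied,
    normal samples are dropped first. Percentages are rounded to 2 decimals
    and sum to 100 before rounding.
    """
    sub = calls
    if tumor_only and phenotype is not None:
        keep = phenotype.reindex(sub["sample_id"]).to_numpy() == "tumor"
        sub = sub.loc[keep]
    valid = sub[sub["group"] != "invalid"]
    n_invalid = int((sub["group"] == "invalid").sum())
    if valid.empty:
        raise AnalysisError("no valid methylator calls to summarize")
    counts = {state: int((valid["four_state"] == state).sum()) for state in FOUR_STATES}
    total = sum(counts.values())
    percentages = {state: round(100.0 * c / total, 2) for state, c in counts.items()}
    group_counts = {g: int((valid["group"] == g).sum()) for g in GROUPS}
    return {
        "n_valid": total,
        "n_invalid": n_invalid,
        "counts": counts,
        "percentages": percentages,
        "group_counts": group_counts,
        "group_percentages": {g: round(100.0 * c / total, 2)
                              for g, c in group_counts.items()},
    }
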