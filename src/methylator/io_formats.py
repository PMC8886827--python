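"""Readers and writers for every table the pipeline touches.

All tables are delimited text (TSV or CSV, delimiter sniffed), UTF-8, one
header row. Genomic coordinates are 1-based and inclusive throughout the
package; they are never rescaled on input or output. Missing values may be
encoded as an empty cell or ``NA`` and are always written back as ``NA``.

No science happens here: this module only parses, validates and serializes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

NA_VALUES = ["", "NA"]

#: Anatomical sites grouped as in clinical practice: distal (left-sided)
#: versus proximal (right-sided) colon, with the rectum kept separate.
DEFAULT_LOCATION_MAP = {
    "rectosigmoid": "left",
    "descending colon": "left",
    "splenic flexure": "left",
    "hepatic flexure": "right",
    "ascending colon": "right",
    "rectum": "rectum",
}

LOCATION_VOCABULARY = ("left", "right", "rectum", "other")

PHENOTYPE_COLUMN = "phenotype"
PHENOTYPES = ("tumor", "normal")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Methylation fractions, canonically oriented samples x probes.

    ``values`` is a float DataFrame indexed by sample id with probe ids as
    columns; NaN marks a missing measurement. ``phenotype`` labels every
    sample as ``tumor`` or ``normal``.
    """

    values: pd.DataFrame
    phenotype: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids in beta matrix")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate probe ids in beta matrix")
        arr = self.values.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value {arr[i, j]!r} outside [0, 1] at sample "
                f"{self.values.index[i]!r}, probe {self.values.columns[j]!r}"
            )
        self.phenotype = self.phenotype.reindex(self.values.index)
        if self.phenotype.isna().any():
            missing = self.phenotype.index[self.phenotype.isna()][0]
            raise FormatError(f"phenotype missing for sample {missing!r}")
        unknown = set(self.phenotype.unique()) - set(PHENOTYPES)
        if unknown:
            raise FormatError(f"unknown phenotype labels: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeManifest:
    """Probe genomic metadata, sorted by (chrom, pos), unique probe ids."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "pos", "gene", "tss_distance")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"manifest missing column {col!r}")
        t = self.table.copy()
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe_id {dup!r} in manifest")
        t["pos"] = t["pos"].astype(int)
        t["tss_distance"] = t["tss_distance"].astype(int)
        if (t["pos"] < 1).any():
            raise FormatError("manifest pos must be >= 1 (1-based coordinates)")
        self.table = t.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.table[self.table["gene"] == gene]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation indexed by sample_id.

    Known columns: age, sex, location_raw, location, mantis, msi,
    nonsyn_mutations, silent_mutations, plus one ``mut_<GENE>`` column per
    assayed gene with values mutated/wildtype.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.name != "sample_id":
            if "sample_id" not in self.table.columns:
                raise FormatError("clinical table missing sample_id")
            self.table = self.table.set_index("sample_id")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate sample_id in clinical table")
        if "location" in self.table.columns:
            bad = set(self.table["location"].dropna()) - set(LOCATION_VOCABULARY)
            if bad:
                raise FormatError(f"unknown location labels: {sorted(bad)}")
        if "mantis" in self.table.columns:
            m = pd.to_numeric(self.table["mantis"], errors="coerce")
            if (m.dropna() < 0).any():
                raise FormatError("negative MANTIS score in clinical table")

    @property
    def mutation_genes(self) -> list[str]:
        return [c[4:] for c in self.table.columns if c.startswith("mut_")]


@dataclass
class CountMatrix:
    """RNA read counts, genes x samples, nonnegative integers."""

    counts: pd.DataFrame = field()

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise FormatError("duplicate gene ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise FormatError("duplicate sample ids in count matrix")
        arr = self.counts.to_numpy()
        if np.isnan(arr.astype(float)).any():
            raise FormatError("missing values not allowed in count matrix")
        if (arr.astype(float) < 0).any():
            raise FormatError("negative count in count matrix")
        if not np.array_equal(arr.astype(float), np.round(arr.astype(float))):
            raise FormatError("non-integral count in count matrix")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read a delimited text table with a sniffed delimiter."""
    return pd.read_csv(
        path, sep=None, engine="python", dtype=str,
        keep_default_na=False, na_values=NA_VALUES,
    )


def _to_numeric(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad][0]
            raise FormatError(
                f"non-numeric {what} cell {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_beta_matrix(
    path,
    orientation: str = "samples_by_probes",
    phenotype: dict | pd.Series | None = None,
    missing_policy: str = "drop_probe",
) -> BetaMatrix:
    """Read a beta matrix and canonicalize to samples x probes.

    The file may carry a ``phenotype`` column (samples_by_probes) or row
    (probes_by_samples); otherwise a sample->label mapping must be supplied.
    ``missing_policy`` handles NaN cells: ``keep`` leaves them, ``drop_probe``
    (default) drops probes with any missing value, ``drop_sample`` drops
    samples, ``mean_impute`` replaces by the probe mean. Affected entry counts
    are logged.
    """
    if orientation not in ("samples_by_probes", "probes_by_samples"):
        raise FormatError(f"unknown orientation {orientation!r}")
    raw = _read_table(path)
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        dup = raw.loc[raw[id_col].duplicated(), id_col].iloc[0]
        raise FormatError(f"duplicate id {dup!r} in beta matrix")
    raw = raw.set_index(id_col)
    if orientation == "probes_by_samples":
        raw = raw.T
    # now rows are samples
    pheno = None
    if PHENOTYPE_COLUMN in raw.columns:
        pheno = raw[PHENOTYPE_COLUMN]
        raw = raw.drop(columns=[PHENOTYPE_COLUMN])
    values = _to_numeric(raw, "beta")
    if pheno is None:
        if phenotype is None:
            raise FormatError(
                "no phenotype column in file and no phenotype mapping given"
            )
        pheno = pd.Series(dict(phenotype))
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing and missing_policy != "keep":
        if missing_policy == "drop_probe":
            values = values.dropna(axis=1)
        elif missing_policy == "drop_sample":
            values = values.dropna(axis=0)
            pheno = pheno.reindex(values.index)
        elif missing_policy == "mean_impute":
            values = values.fillna(values.mean(axis=0))
        else:
            raise FormatError(f"unknown missing_policy {missing_policy!r}")
        logger.info("missing_policy=%s applied to %d missing entries", missing_policy, n_missing)
    return BetaMatrix(values=values, phenotype=pheno)


def read_probe_manifest(path) -> ProbeManifest:
    raw = _read_table(path)
    for col in ProbeManifest.REQUIRED:
        if col not in raw.columns:
            raise FormatError(f"manifest missing column {col!r}")
    for col in ("pos", "tss_distance"):
        conv = pd.to_numeric(raw[col], errors="coerce")
        if (conv.isna() & raw[col].notna()).any():
            raise FormatError(f"non-numeric value in manifest column {col!r}")
        raw[col] = conv
    return ProbeManifest(table=raw)


def read_clinical(path, location_map: dict | None = None) -> ClinicalTable:
    """Read clinical annotation, deriving ``location`` from ``location_raw``.

    ``location_map`` maps lower-cased site text to left/right/rectum/other;
    unmapped sites fall back to ``other``. The default map follows surgical
    convention for sidedness (rectosigmoid, descending colon and splenic
    flexure are left-sided; hepatic flexure and ascending colon right-sided).
    """
    if location_map is None:
        location_map = DEFAULT_LOCATION_MAP
    raw = _read_table(path)
    if "sample_id" not in raw.columns:
        raise FormatError("clinical table missing sample_id column")
    if "location" not in raw.columns and "location_raw" in raw.columns:
        raw["location"] = [
            location_map.get(str(site).strip().lower(), "other") if pd.notna(site) else None
            for site in raw["location_raw"]
        ]
    for col in ("age", "mantis", "nonsyn_mutations", "silent_mutations"):
        if col in raw.columns:
            conv = pd.to_numeric(raw[col], errors="coerce")
            if (conv.isna() & raw[col].notna()).any():
                raise FormatError(f"non-numeric value in clinical column {col!r}")
            raw[col] = conv
    return ClinicalTable(table=raw)


def read_count_matrix(path) -> CountMatrix:
    raw = _read_table(path)
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        raise FormatError("duplicate gene ids in count matrix")
    raw = raw.set_index(id_col)
    values = _to_numeric(raw, "count")
    if values.isna().any().any():
        raise FormatError("missing values not allowed in count matrix")
    return CountMatrix(counts=values)


# ---------------------------------------------------------------------------
# writers (exact round-trip: full stored precision, NA for missing)
# ---------------------------------------------------------------------------

def write_beta_matrix(matrix: BetaMatrix, path) -> None:
    out = matrix.values.copy()
    out.insert(0, PHENOTYPE_COLUMN, matrix.phenotype)
    out.index.name = "sample_id"
    # .17g preserves every double exactly across the write/read round trip
    out.to_csv(path, sep="\t", na_rep="NA",
               float_format=lambda v: format(v, ".17g"))


def write_probe_manifest(manifest: ProbeManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.table.to_csv(path, sep="\t", na_rep="NA")


def write_count_matrix(counts: CountMatrix, path) -> None:
    out = counts.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
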