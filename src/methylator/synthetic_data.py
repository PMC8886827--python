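"""Synthetic cohort generator with the structure the analysis assumes.

One call produces everything the pipeline consumes — a beta matrix with
tumor and normal samples, a probe manifest, a clinical table, an RNA count
matrix and an MSP Ct export — together with the ground-truth methylator
group of every sample, so each stage can be tested end to end without any
external download.

The generative model, component by component:

* Every tumor draws a methylator group from (HH, HL, LL) proportions
  (default 0.88/0.09/0.03). HL tumors split between the two single-positive
  configurations, predominantly low-SDC2/high-TFPI2.
* Target-region probe betas are Beta-distributed per gene and status;
  normal tissue uses the low-status parameters, with TFPI2's low component
  centred higher than SDC2's (higher background methylation in normals).
* Background probes carry no disease signal: each probe is latently
  methylated or unmethylated and its M-values are Gaussian around the
  corresponding peak, giving the pooled M histogram a genuine two-component
  structure with a known analytic high/low crossing.
* Tumor location is multinomial over left/right/rectum/other; HL tumors
  have their left-sided odds multiplied by ``location_effect``.
* Age is Gaussian around a baseline with per-group offsets (HH older, LL
  younger) plus a positive coupling to the sample's mean promoter beta.
* Nonsynonymous mutation counts are negative binomial with per-group means
  (defaults 10.55/3.91/7.02); silent counts scale those means by half.
* MANTIS scores mix an MSS and an MSI-H component, with the MSI-H rate
  highest in HH; BRAF mutations concentrate in HH.
* RNA counts are negative binomial around lognormal baseline means, with a
  block of signature genes per group upregulated ``de_fold``-fold there.
* MSP Ct values decrease linearly in the region beta (so low methylation
  means late amplification), truncated at the 45-cycle ceiling, in
  triplicate, with ACTB control Cts near 25; a small fraction of samples
  fail the control on purpose.

A single global seed fans out through named ``SeedSequence`` substreams, so
generating a subset of components never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .io_formats import (BetaMatrix, ClinicalTable, CountMatrix, ProbeManifest,
                         write_beta_matrix, write_clinical, write_count_matrix,
                         write_probe_manifest)
from .meth_transforms import m_to_beta
from .threshold_mixture import MixtureFit, decision_boundary

#: The four-probe and seven-probe promoter blocks of the two target genes.
SDC2_PROBES = ["cg16935295", "cg04261408", "cg14625631", "cg10292139"]
TFPI2_PROBES = ["cg12973591", "cg22799321", "cg24531255", "cg17338208",
                "cg26739865", "cg22441533", "cg14377593"]

_SUBSTREAMS = ("groups", "beta_regions", "beta_background", "location", "age",
               "mutations", "mantis", "gene_mutations", "counts", "ct")

ALL_COMPONENTS = ("beta", "clinical", "counts", "ct")


@dataclass
class CohortSpec:
    """All knobs of the generator, with study-like defaults."""

    n_tumor: int = 257
    n_normal: int = 54
    group_props: tuple = (0.88, 0.09, 0.03)
    #: fraction of HL tumors that are low-SDC2 / high-TFPI2
    hl_split: float = 0.75
    #: Beta(a, b) parameters of region-probe beta per gene and status
    beta_params: dict = field(default_factory=lambda: {
        "SDC2": {"high": (12.0, 8.0), "low": (1.5, 28.5)},
        "TFPI2": {"high": (12.0, 8.0), "low": (4.5, 25.5)},
    })
    n_background_probes: int = 300
    #: Gaussian peaks of background M-values (unmethylated, methylated)
    bg_m_means: tuple = (-4.0, 2.0)
    bg_m_sds: tuple = (1.0, 1.0)
    bg_meth_fraction: float = 0.5
    location_base: dict = field(default_factory=lambda: {
        "left": 0.32, "right": 0.19, "rectum": 0.35, "other": 0.14})
    location_effect: float = 4.0
    age_baseline: float = 60.0
    age_offsets: dict = field(default_factory=lambda: {"HH": 8.0, "HL": 0.0, "LL": -6.0})
    age_sd: float = 10.0
    age_beta_slope: float = 15.0
    mutation_means: dict = field(default_factory=lambda: {
        "HH": 10.55, "HL": 3.91, "LL": 7.02})
    mutation_size: float = 2.0       # negative-binomial shape
    silent_fraction: float = 0.5
    msih_rates: dict = field(default_factory=lambda: {"HH": 0.18, "HL": 0.01, "LL": 0.08})
    braf_rates: dict = field(default_factory=lambda: {"HH": 0.13, "HL": 0.0, "LL": 0.03})
    flat_mutation_rates: dict = field(default_factory=lambda: {
        "KRAS": 0.40, "TP53": 0.55, "APC": 0.70, "PIK3CA": 0.20})
    n_genes_expr: int = 500
    n_signature: int = 20            # signature genes per group
    de_fold: float = 4.0
    nb_dispersion: float = 0.2       # 1/size of the expression NB
    ct_intercept: float = 43.0       # Ct at beta = 0
    ct_slope: float = 25.0           # cycles lost per unit beta
    ct_noise: float = 0.8
    ct_ceiling: float = 45.0
    actb_mean: float = 25.0
    actb_sd: float = 1.0
    invalid_rate: float = 0.02       # samples with a failed ACTB control
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise InputError("group_props must sum to 1")
        if min(self.group_props) <= 0 or self.de_fold <= 0:
            raise InputError("proportions and fold changes must be positive")

    def analytic_boundary_m(self) -> float:
        """High/low crossing of the generating background mixture (M scale)."""
        w = (1 - self.bg_meth_fraction, self.bg_meth_fraction)
        fit = MixtureFit(means=tuple(self.bg_m_means), sds=tuple(self.bg_m_sds),
                         weights=w, boundary_m=np.nan, boundary_beta=np.nan,
                         loglik=np.nan, n_iter=0, converged=True)
        return decision_boundary(fit)[0]

    def analytic_boundary_beta(self) -> float:
        return float(m_to_beta(self.analytic_boundary_m()))


@dataclass
class CohortBundle:
    """Everything one synthetic cohort provides."""

    spec: CohortSpec
    beta: BetaMatrix | None
    manifest: ProbeManifest | None
    clinical: ClinicalTable | None
    counts: CountMatrix | None
    ct_export: pd.DataFrame | None
    truth: pd.DataFrame


def _make_manifest(spec: CohortSpec, rng: np.random.Generator) -> ProbeManifest:
    rows = []
    for i, probe in enumerate(SDC2_PROBES):
        rows.append((probe, "chr8", 97506030 + 110 * i, "SDC2", -1500 + 110 * i))
    for i, probe in enumerate(TFPI2_PROBES):
        rows.append((probe, "chr7", 93519980 + 80 * i, "TFPI2", -1200 + 80 * i))
    chroms = rng.integers(1, 23, size=300_000)  # stable layout stream
    for j in range(spec.n_background_probes):
        rows.append((f"cgSIM{j:06d}", f"chr{chroms[j]}",
                     1_000_000 + 1500 * j, f"BG{j:05d}", -500))
    return ProbeManifest(table=pd.DataFrame(
        rows, columns=["probe_id", "chrom", "pos", "gene", "tss_distance"]))


def generate_cohort(spec: CohortSpec, components=ALL_COMPONENTS) -> CohortBundle:
    """Generate a full cohort bundle; deterministic given ``spec.seed``.

    ``components`` selects which data products to build ("beta", "clinical",
    "counts", "ct"); the truth table and manifest always exist. Omitting a
    component never changes the draws of the others.
    """
    streams = {name: np.random.default_rng(child) for name, child in
               zip(_SUBSTREAMS, np.random.SeedSequence(spec.seed).spawn(len(_SUBSTREAMS)))}

    tumor_ids = [f"T{i:04d}" for i in range(spec.n_tumor)]
    normal_ids = [f"N{i:04d}" for i in range(spec.n_normal)]
    sample_ids = tumor_ids + normal_ids
    phenotype = pd.Series(["tumor"] * spec.n_tumor + ["normal"] * spec.n_normal,
                          index=sample_ids, name="phenotype")

    # --- ground-truth groups and per-gene statuses -------------------------
    rng = streams["groups"]
    groups = rng.choice(["HH", "HL", "LL"], size=spec.n_tumor, p=list(spec.group_props))
    hl_low_sdc2 = rng.random(spec.n_tumor) < spec.hl_split
    status = {"SDC2": [], "TFPI2": []}
    for i, g in enumerate(groups):
        if g == "HH":
            s1 = s2 = "high"
        elif g == "LL":
            s1 = s2 = "low"
        elif hl_low_sdc2[i]:
            s1, s2 = "low", "high"
        else:
            s1, s2 = "high", "low"
        status["SDC2"].append(s1)
        status["TFPI2"].append(s2)
    truth = pd.DataFrame({
        "sample_id": sample_ids,
        "phenotype": phenotype.to_numpy(),
        "group": list(groups) + ["normal"] * spec.n_normal,
        "status_sdc2": status["SDC2"] + ["low"] * spec.n_normal,
        "status_tfpi2": status["TFPI2"] + ["low"] * spec.n_normal,
    })

    manifest = _make_manifest(spec, np.random.default_rng(12345))

    # --- region-probe betas (needed for beta, clinical coupling and ct) ---
    rng = streams["beta_regions"]
    region_beta_values = {}
    region_mean = {}
    for gene, probes in (("SDC2", SDC2_PROBES), ("TFPI2", TFPI2_PROBES)):
        a_hi, b_hi = spec.beta_params[gene]["high"]
        a_lo, b_lo = spec.beta_params[gene]["low"]
        high = np.array([s == "high" for s in truth[f"status_{gene.lower()}"]])
        a = np.where(high, a_hi, a_lo)[:, None]
        b = np.where(high, b_hi, b_lo)[:, None]
        vals = rng.beta(a, b, size=(len(sample_ids), len(probes)))
        region_beta_values[gene] = vals
        region_mean[gene] = vals.mean(axis=1)
    truth["beta_sdc2"] = region_mean["SDC2"]
    truth["beta_tfpi2"] = region_mean["TFPI2"]

    # --- beta matrix -------------------------------------------------------
    beta = None
    if "beta" in components:
        rng = streams["beta_background"]
        meth_state = rng.random(spec.n_background_probes) < spec.bg_meth_fraction
        mu = np.where(meth_state, spec.bg_m_means[1], spec.bg_m_means[0])
        sd = np.where(meth_state, spec.bg_m_sds[1], spec.bg_m_sds[0])
        bg_m = rng.normal(mu[None, :], sd[None, :],
                          size=(len(sample_ids), spec.n_background_probes))
        bg_beta = m_to_beta(bg_m)
        cols = SDC2_PROBES + TFPI2_PROBES + [f"cgSIM{j:06d}" for j in
                                             range(spec.n_background_probes)]
        values = np.hstack([region_beta_values["SDC2"],
                            region_beta_values["TFPI2"], bg_beta])
        beta = BetaMatrix(values=pd.DataFrame(values, index=sample_ids, columns=cols),
                          phenotype=phenotype)

    # --- clinical ----------------------------------------------------------
    clinical = None
    if "clinical" in components:
        loc_rng = streams["location"]
        sites = {"left": ["descending colon", "splenic flexure", "rectosigmoid"],
                 "right": ["ascending colon", "hepatic flexure"],
                 "rectum": ["rectum"], "other": ["transverse colon"]}
        cats = list(spec.location_base)
        base = np.array([spec.location_base[c] for c in cats], dtype=float)
        locations, location_raw = [], []
        for g in groups:
            w = base.copy()
            if g == "HL":
                w[cats.index("left")] *= spec.location_effect
            w /= w.sum()
            loc = loc_rng.choice(cats, p=w)
            locations.append(loc)
            location_raw.append(loc_rng.choice(sites[loc]))

        age_rng = streams["age"]
        mean_beta = (region_mean["SDC2"] + region_mean["TFPI2"]) / 2.0
        offsets = np.array([spec.age_offsets[g] for g in groups])
        age_t = (spec.age_baseline + offsets
                 + spec.age_beta_slope * (mean_beta[:spec.n_tumor] - 0.5)
                 + age_rng.normal(0, spec.age_sd, spec.n_tumor))
        age_n = spec.age_baseline + age_rng.normal(0, spec.age_sd, spec.n_normal)
        age = np.clip(np.concatenate([age_t, age_n]), 25, 95).round(0)

        mut_rng = streams["mutations"]
        means = np.array([spec.mutation_means[g] for g in groups])
        r = spec.mutation_size
        nonsyn = mut_rng.negative_binomial(r, r / (r + means))
        silent = mut_rng.negative_binomial(
            r, r / (r + means * spec.silent_fraction))

        mantis_rng = streams["mantis"]
        msih = mantis_rng.random(spec.n_tumor) < np.array(
            [spec.msih_rates[g] for g in groups])
        mantis = np.where(
            msih,
            np.clip(mantis_rng.normal(0.65, 0.12, spec.n_tumor), 0.41, 1.5),
            np.clip(mantis_rng.normal(0.25, 0.06, spec.n_tumor), 0.0, 0.40))

        gm_rng = streams["gene_mutations"]
        mut_cols = {}
        braf = gm_rng.random(spec.n_tumor) < np.array(
            [spec.braf_rates[g] for g in groups])
        mut_cols["mut_BRAF"] = np.where(braf, "mutated", "wildtype")
        for gene, rate in spec.flat_mutation_rates.items():
            mut_cols[f"mut_{gene}"] = np.where(
                gm_rng.random(spec.n_tumor) < rate, "mutated", "wildtype")

        sex = gm_rng.choice(["male", "female"], size=spec.n_tumor, p=[0.59, 0.41])

        tumor_frame = pd.DataFrame({
            "sample_id": tumor_ids,
            "age": age[:spec.n_tumor],
            "sex": sex,
            "location_raw": location_raw,
            "location": locations,
            "mantis": np.round(mantis, 4),
            "msi": np.where(msih, "MSI-H", "MSS"),
            "nonsyn_mutations": nonsyn,
            "silent_mutations": silent,
            **mut_cols,
        })
        normal_frame = pd.DataFrame({"sample_id": normal_ids,
                                     "age": age[spec.n_tumor:]})
        clinical = ClinicalTable(table=pd.concat(
            [tumor_frame, normal_frame], ignore_index=True))
        truth["location"] = locations + [None] * spec.n_normal
        truth["msi"] = list(np.where(msih, "MSI-H", "MSS")) + [None] * spec.n_normal

    # --- expression counts (tumors only) -----------------------------------
    counts = None
    if "counts" in components:
        rng = streams["counts"]
        g = spec.n_genes_expr
        base_mean = rng.lognormal(mean=4.0, sigma=1.0, size=g)
        gene_ids = [f"G{j:05d}" for j in range(g)]
        sig_of = {}
        for k, grp in enumerate(("HH", "HL", "LL")):
            for j in range(k * spec.n_signature, (k + 1) * spec.n_signature):
                if j < g:
                    sig_of[j] = grp
        mean_mat = np.tile(base_mean[:, None], (1, spec.n_tumor))
        grp_arr = np.array(groups)
        for j, grp in sig_of.items():
            mean_mat[j, grp_arr == grp] *= spec.de_fold
        size = 1.0 / spec.nb_dispersion
        draws = rng.negative_binomial(size, size / (size + mean_mat))
        counts = CountMatrix(counts=pd.DataFrame(draws, index=gene_ids,
                                                 columns=tumor_ids))
        truth.attrs["signature_genes"] = {
            grp: [gene_ids[j] for j, gg in sig_of.items() if gg == grp]
            for grp in ("HH", "HL", "LL")}

    # --- MSP Ct export ------------------------------------------------------
    ct_export = None
    if "ct" in components:
        rng = streams["ct"]
        invalid = rng.random(len(sample_ids)) < spec.invalid_rate
        rows = []
        for i, sid in enumerate(sample_ids):
            actb_loc = 36.8 if invalid[i] else spec.actb_mean
            actb_sd = 0.4 if invalid[i] else spec.actb_sd
            for gene in ("SDC2", "TFPI2"):
                true_ct = spec.ct_intercept - spec.ct_slope * region_mean[gene][i]
                reps = true_ct + rng.normal(0, spec.ct_noise, 3)
                reps = [np.nan if v >= spec.ct_ceiling else round(float(v), 2)
                        for v in reps]
                actb = np.round(actb_loc + rng.normal(0, actb_sd, 3), 2)
                rows.append({"sample_id": sid, "gene": gene,
                             "ct1": reps[0], "ct2": reps[1], "ct3": reps[2],
                             "actb1": actb[0], "actb2": actb[1], "actb3": actb[2]})
        ct_export = pd.DataFrame(rows)
        truth["control_failed"] = invalid

    return CohortBundle(spec=spec, beta=beta, manifest=manifest,
                        clinical=clinical, counts=counts, ct_export=ct_export,
                        truth=truth)


def ground_truth_report(bundle: CohortBundle) -> pd.DataFrame:
    """One row per sample with the generating labels, for confusion matrices."""
    return bundle.truth.drop(columns=["signature_genes"], errors="ignore").copy()


def write_bundle(bundle: CohortBundle, out_dir) -> dict[str, str]:
    """Serialize every generated component under ``out_dir``; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if bundle.beta is not None:
        write_beta_matrix(bundle.beta, out / "beta.tsv")
        paths["beta"] = str(out / "beta.tsv")
    write_probe_manifest(bundle.manifest, out / "manifest.tsv")
    paths["manifest"] = str(out / "manifest.tsv")
    if bundle.clinical is not None:
        write_clinical(bundle.clinical, out / "clinical.tsv")
        paths["clinical"] = str(out / "clinical.tsv")
    if bundle.counts is not None:
        write_count_matrix(bundle.counts, out / "counts.tsv")
        paths["counts"] = str(out / "counts.tsv")
    if bundle.ct_export is not None:
        bundle.ct_export.to_csv(out / "ct_export.csv", index=False)
        paths["ct"] = str(out / "ct_export.csv")
    ground_truth_report(bundle).to_csv(out / "truth.tsv", sep="\t", index=False)
    paths["truth"] = str(out / "truth.tsv")
    return paths


def spec_from_yaml(path) -> CohortSpec:
    """Load a CohortSpec from a YAML mapping of field overrides."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = set(asdict(CohortSpec()).keys())
    unknown = set(data) - known
    if unknown:
        raise InputError(f"unknown CohortSpec fields: {sorted(unknown)}")
    for key in ("group_props", "bg_m_means", "bg_m_sds"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortSpec(**data)
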