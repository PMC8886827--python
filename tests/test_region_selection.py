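import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylator import (BetaMatrix, ConfigurationError, ProbeManifest,
                        assemble_regions, compute_probe_deltas,
                        select_primary_region)


def _manifest(positions, gene="G", chrom="chr1"):
    return ProbeManifest(table=pd.DataFrame({
        "probe_id": [f"cg{i:05d}" for i in range(len(positions))],
        "chrom": [chrom] * len(positions),
        "pos": positions,
        "gene": [gene] * len(positions),
        "tss_distance": [0] * len(positions)}))


def _deltas(manifest, passes):
    return pd.DataFrame({
        "probe_id": manifest.table["probe_id"],
        "gene": manifest.table["gene"],
        "beta_tumor": [0.6 if p else 0.3 for p in passes],
        "beta_normal": [0.1] * len(passes),
        "delta_beta": [0.5 if p else 0.2 for p in passes],
        "passes": list(passes)})


class TestProbeDeltas:
    def test_tumor_normal_difference(self, small_beta, sdc2_manifest):
        deltas = compute_probe_deltas(small_beta, sdc2_manifest)
        d = deltas.set_index("probe_id")
        # first probe: tumor mean 0.65, normal mean 0.15
        assert d.loc["cg16935295", "beta_tumor"] == pytest.approx(0.65)
        assert d.loc["cg16935295", "beta_normal"] == pytest.approx(0.15)
        assert d.loc["cg16935295", "delta_beta"] == pytest.approx(0.5)
        assert bool(d.loc["cg16935295", "passes"])
        # interior probe misses the cutoff: 0.25 - 0.10 = 0.15
        assert not bool(d.loc["cg14625631", "passes"])

    def test_threshold_is_inclusive(self):
        manifest = _manifest([100, 200])
        values = pd.DataFrame([[0.5, 0.45], [0.2, 0.2]],
                              index=["t", "n"],
                              columns=manifest.table["probe_id"])
        matrix = BetaMatrix(values=values,
                            phenotype=pd.Series(["tumor", "normal"],
                                                index=["t", "n"]))
        d = compute_probe_deltas(matrix, manifest).set_index("probe_id")
        assert bool(d.loc["cg00000", "passes"])       # delta exactly 0.3
        assert not bool(d.loc["cg00001", "passes"])   # delta 0.25

    def test_requires_both_phenotypes(self, sdc2_manifest):
        values = pd.DataFrame([[0.5] * 5], index=["t"],
                              columns=sdc2_manifest.table["probe_id"])
        matrix = BetaMatrix(values=values,
                            phenotype=pd.Series(["tumor"], index=["t"]))
        with pytest.raises(ConfigurationError):
            compute_probe_deltas(matrix, sdc2_manifest)


class TestAssembleRegions:
    def test_interior_gap_fill(self):
        # pass, pass, fail, pass at close spacing -> one region of 4,
        # with the failing interior probe filled in
        manifest = _manifest([100, 200, 300, 400])
        regions = assemble_regions(
            _deltas(manifest, [True, True, False, True]), manifest)
        assert len(regions) == 1
        r = regions[0]
        assert (r.n_pass, r.n_fill, len(r.probe_ids)) == (3, 1, 4)
        assert (r.start, r.end) == (100, 400)

    def test_trailing_fail_excluded(self):
        manifest = _manifest([100, 200])
        regions = assemble_regions(_deltas(manifest, [True, False]), manifest)
        assert len(regions) == 1
        assert regions[0].probe_ids == ["cg00000"]

    def test_gap_splits_blocks(self):
        manifest = _manifest([100, 50_100])
        regions = assemble_regions(_deltas(manifest, [True, True]), manifest,
                                   max_gap=1000)
        assert len(regions) == 2
        assert all(len(r.probe_ids) == 1 for r in regions)

    def test_no_passing_probe_yields_no_region(self):
        manifest = _manifest([100, 200])
        assert assemble_regions(_deltas(manifest, [False, False]),
                                manifest) == []

    def test_fill_can_be_disabled(self):
        manifest = _manifest([100, 200, 300, 400])
        regions = assemble_regions(
            _deltas(manifest, [True, True, False, True]), manifest,
            fill_interior=False)
        assert regions[0].n_fill == 0
        assert len(regions[0].probe_ids) == 3


def _brute_force_blocks(positions, passes, max_gap):
    """Independent oracle: enumerate maximal runs of passing probes.

    A run is a maximal sequence of passing-probe indices whose consecutive
    genomic gaps stay within max_gap; interior failing probes between two
    run members at most max_gap from each neighbour join the block.
    """
    pass_idx = [i for i, p in enumerate(passes) if p]
    if not pass_idx:
        return []
    runs, current = [], [pass_idx[0]]
    for i in pass_idx[1:]:
        if positions[i] - positions[current[-1]] <= max_gap:
            current.append(i)
        else:
            runs.append(current)
            current = [i]
    runs.append(current)
    blocks = []
    for run in runs:
        members = []
        for i in range(run[0], run[-1] + 1):
            if passes[i]:
                members.append(i)
            else:
                left = max(j for j in run if positions[j] < positions[i])
                right = min(j for j in run if positions[j] > positions[i])
                if (positions[i] - positions[left] <= max_gap and
                        positions[right] - positions[i] <= max_gap):
                    members.append(i)
        blocks.append(members)
    return blocks


class TestRegionProperties:
    @given(st.lists(st.tuples(st.integers(min_value=1, max_value=400),
                              st.booleans()),
                    min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_invariants(self, spec):
        gaps = [g for g, _ in spec]
        positions = list(np.cumsum(gaps))
        passes = [p for _, p in spec]
        max_gap = 250
        manifest = _manifest(positions)
        regions = assemble_regions(_deltas(manifest, passes), manifest,
                                   max_gap=max_gap)
        probe_ids = list(manifest.table["probe_id"])
        expected = _brute_force_blocks(positions, passes, max_gap)
        got = sorted([r.probe_ids for r in regions])
        want = sorted([[probe_ids[i] for i in block] for block in expected])
        assert got == want
        pass_of = dict(zip(probe_ids, passes))
        pos_of = dict(zip(probe_ids, positions))
        for r in regions:
            # endpoints pass; probes sorted by coordinate; counts consistent
            assert pass_of[r.probe_ids[0]] and pass_of[r.probe_ids[-1]]
            ps = [pos_of[p] for p in r.probe_ids]
            assert ps == sorted(ps)
            assert r.n_pass == sum(pass_of[p] for p in r.probe_ids)
            assert r.n_pass + r.n_fill == len(r.probe_ids)

    def test_threshold_monotonicity(self, default_cohort):
        """Raising the delta cutoff never grows the primary region."""
        matrix, manifest = default_cohort.beta, default_cohort.manifest
        last = None
        for threshold in (0.2, 0.3, 0.4, 0.5):
            deltas = compute_probe_deltas(matrix, manifest, threshold=threshold)
            regions = assemble_regions(deltas, manifest)
            try:
                n_pass = select_primary_region(regions, "SDC2").n_pass
            except ConfigurationError:
                n_pass = 0
            if last is not None:
                assert n_pass <= last
            last = n_pass


class TestSelectPrimaryRegion:
    def test_most_passing_probes_wins(self):
        manifest = _manifest([100, 200, 300, 10_000])
        regions = assemble_regions(
            _deltas(manifest, [True, True, True, True]), manifest,
            max_gap=1000)
        assert select_primary_region(regions, "G").n_pass == 3

    def test_single_candidate_identity(self):
        manifest = _manifest([100])
        regions = assemble_regions(_deltas(manifest, [True]), manifest)
        assert select_primary_region(regions, "G") is regions[0]

    def test_missing_gene_errors(self):
        with pytest.raises(ConfigurationError):
            select_primary_region([], "NOPE")

    def test_recovers_tfpi2_block(self, default_cohort):
        """The seven-probe TFPI2 promoter block is selected end to end."""
        deltas = compute_probe_deltas(default_cohort.beta,
                                      default_cohort.manifest)
        regions = assemble_regions(deltas, default_cohort.manifest)
        r = select_primary_region(regions, "TFPI2")
        assert r.probe_ids == ["cg12973591", "cg22799321", "cg24531255",
                               "cg17338208", "cg26739865", "cg22441533",
                               "cg14377593"]
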