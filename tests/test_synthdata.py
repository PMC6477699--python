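"""Closed-loop checks of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest

from gagabind import binding, chipprofile as cp, genesets as gs, probes, seqmotif as sm
from gagabind import synthdata as sd
from gagabind.errors import ContractError, InfeasibleDesignError


class TestProbePanel:
    def test_rescanned_counts_equal_ground_truth(self):
        panel, truth = sd.gen_probe_panel(counts=(0, 1, 2, 3), length=39, seed=11)
        for probe in panel:
            assert sm.count_joint_gaga_tctc(probe.sense_seq.seq) == truth[probe.name]

    def test_zero_count_probe_is_motif_free_on_both_strands(self):
        panel, _ = sd.gen_probe_panel(counts=(0,), length=39, seed=3)
        seq = panel.get("probe_c0").sense_seq.seq
        assert sm.count_joint_gaga_tctc(seq) == 0
        assert sm.count_joint_gaga_tctc(sm.reverse_complement(seq)) == 0
        assert sm.count_rgaragrra(seq) == 0

    def test_repeat_probe_carries_degenerate_consensus(self):
        panel, truth = sd.gen_probe_panel(seed=0)
        ann = probes.annotate_panel(panel, classes=["rgaragrra"])
        counts = probes.panel_counts(ann, "rgaragrra")
        assert counts["probe_c4"] >= 1  # (GA)_8 repeat contains RGARAGRRA
        assert all(counts[f"probe_c{c}"] == 0 for c in (0, 1, 2, 3))

    def test_same_seed_same_panel(self):
        a, _ = sd.gen_probe_panel(seed=5)
        b, _ = sd.gen_probe_panel(seed=5)
        assert [p.sense_seq.seq for p in a] == [p.sense_seq.seq for p in b]

    def test_infeasible_packing_raises(self):
        with pytest.raises(InfeasibleDesignError):
            sd.gen_probe_panel(counts=(8,), length=20, seed=0)


class TestBindingMeasurements:
    def test_noiseless_signals_are_exact(self):
        meas = sd.gen_binding_measurements(
            {"p": 3}, sd.SignalModel(baseline=50, gain=100, noise_sd=0), seed=0
        )
        assert (meas["signal"] == 350).all()
        assert len(meas) == 3 * 2  # replicates x technical wells

    def test_noiseless_closed_loop_perfect_statistics(self):
        _, truth = sd.gen_probe_panel(seed=1)
        meas = sd.gen_binding_measurements(
            truth, sd.SignalModel(baseline=0, gain=100, noise_sd=0), seed=1
        )
        summaries, pearson, reports, _ = binding.analyze_panel(
            meas, {"gaga-tctc": truth}, "probe_c0", "probe_c1"
        )
        assert pearson["gaga-tctc"] == pytest.approx(1.0, abs=1e-12)
        assert reports["gaga-tctc"].p_value == pytest.approx(1.0)

    def test_different_seeds_differ_with_noise(self):
        truth = {"a": 1, "b": 2}
        m1 = sd.gen_binding_measurements(truth, sd.SignalModel(noise_sd=5), seed=1)
        m2 = sd.gen_binding_measurements(truth, sd.SignalModel(noise_sd=5), seed=2)
        assert not np.allclose(m1["signal"], m2["signal"])


@pytest.fixture(scope="module")
def small():
    spec = sd.SyntheticGenomeSpec(
        n_genes=5, gene_length=300, intergenic_length=500, repeat_units=8, seed=7
    )
    genome, genes, truth = sd.gen_synthetic_genome(spec)
    return spec, genome, genes, truth


class TestGenomeAndTracks:
    def test_repeat_planted_at_recorded_interval(self, small):
        spec, genome, _, truth = small
        for row in truth.itertuples():
            segment = genome[spec.chrom][row.repeat_start : row.repeat_end]
            assert segment == "GA" * row.units

    def test_background_carries_no_stray_motifs(self, small):
        spec, genome, _, truth = small
        chrom = genome[spec.chrom]
        hits = sm.iupac_match(sm.GAGA, sm.NucleotideSequence("g", chrom), strands=("+",))
        planted = set()
        for row in truth.itertuples():
            planted.update(range(row.repeat_start, row.repeat_end))
        assert all(h.start in planted for h in hits)

    def test_two_unit_repeat_counts_one(self):
        spec = sd.SyntheticGenomeSpec(
            n_genes=1, gene_length=100, intergenic_length=100, repeat_units=2, seed=2
        )
        genome, _, truth = sd.gen_synthetic_genome(spec)
        row = truth.iloc[0]
        segment = genome[spec.chrom][row.repeat_start : row.repeat_end]
        assert sm.count_joint_gaga_tctc(segment) == 1

    def test_same_seed_identical_genome(self):
        spec = sd.SyntheticGenomeSpec(n_genes=2, gene_length=100, intergenic_length=200, seed=9)
        g1, _, _ = sd.gen_synthetic_genome(spec)
        g2, _, _ = sd.gen_synthetic_genome(spec)
        assert g1 == g2

    def test_noiseless_tracks_recover_truth_exactly(self, small):
        spec, genome, _, truth = small
        treats, ctrls, cov = sd.gen_coverage_tracks(spec, truth, jitter_sd=0.0, seed=0)
        med = cp.median_fold_track(treats, ctrls)
        regions = cp.call_enriched_regions(med, threshold=5.0)
        assert [(r.start, r.end) for r in regions] == cov.enriched_regions
        for gene, center in cov.centers.items():
            row = truth[truth.gene == gene].iloc[0]
            peak = cp.locate_peak_center(
                med, region=(int(row.repeat_start) - 200, int(row.repeat_end) + 200)
            )
            assert peak.position == center

    def test_zero_height_yields_no_regions(self, small):
        spec, _, _, truth = small
        treats, ctrls, cov = sd.gen_coverage_tracks(spec, truth, peak_height=0.0, seed=0)
        med = cp.median_fold_track(treats, ctrls)
        assert cp.call_enriched_regions(med, threshold=5.0) == []
        assert cov.enriched_regions == []

    def test_density_map_maximum_inside_repeat_footprint(self, small):
        spec, genome, _, truth = small
        treats, ctrls, cov = sd.gen_coverage_tracks(spec, truth, seed=0)
        centers = {g: (spec.chrom, c) for g, c in cov.centers.items()}
        prof = cp.motif_density_map(genome, centers, halfwidth=100)
        agg = prof.aggregate["GAGA"] + prof.aggregate["TCTC"]
        best_offset = int(prof.offsets[int(np.argmax(agg))])
        row = truth.iloc[0]
        lo = int(row.repeat_start - row.center)
        hi = int(row.repeat_end - row.center)
        assert lo <= best_offset < hi


class TestGeneSets:
    @pytest.mark.parametrize("N,n1,n2,k", [(4, 2, 2, 2), (20, 5, 7, 0), (30, 10, 12, 6)])
    def test_requested_overlap_reproduced(self, N, n1, n2, k):
        _, (a, b) = sd.gen_gene_sets(N, n1, n2, k, seed=4)
        assert len(a) == n1 and len(b) == n2
        part = gs.venn_partition([a, b])
        assert part["A∩B"] == k

    def test_identical_and_disjoint_edges(self):
        _, (a, b) = sd.gen_gene_sets(4, 2, 2, 2, seed=0)
        assert a.members == b.members
        _, (c, d) = sd.gen_gene_sets(10, 3, 3, 0, seed=0)
        assert not (c.members & d.members)

    def test_infeasible_parameters_raise(self):
        with pytest.raises(ContractError):
            sd.gen_gene_sets(5, 4, 4, 0, seed=0)
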