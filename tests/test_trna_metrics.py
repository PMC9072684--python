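"""Abundance, charging, change, and fragment-bin metrics."""

import numpy as np
import pandas as pd
import pytest

from msrtk import pileup_engine as pe
from msrtk import synthetic_data as sd
from msrtk import trna_metrics as tm


@pytest.fixture(scope="module")
def abundance_table(small_library, ref):
    return tm.compute_abundance({"S1": small_library["pileup"]}, ref)


class TestAbundance:
    def test_rpm_arithmetic(self, abundance_table, small_library):
        iso = abundance_table[abundance_table.level == "isodecoder"]
        total = small_library["pileup"].total_reads
        row = iso.iloc[0]
        assert row.normalized_abundance == pytest.approx(
            1e6 * row.raw_reads / total
        )

    def test_isodecoder_rpm_sums_to_million(self, abundance_table):
        iso = abundance_table[abundance_table.level == "isodecoder"]
        assert iso.normalized_abundance.sum() == pytest.approx(1e6)

    def test_isoacceptor_is_sum_of_members(self, abundance_table):
        iso = abundance_table[abundance_table.level == "isodecoder"]
        ser = iso[iso.entity_id.str.startswith("tRNA-Ser-GCT")]
        fam = abundance_table[
            (abundance_table.level == "isoacceptor")
            & (abundance_table.entity_id == "Ser-GCT")
        ]
        assert fam.normalized_abundance.iloc[0] == pytest.approx(
            ser.normalized_abundance.sum()
        )

    def test_zero_read_sample_errors(self, ref):
        empty = pe.PileupMatrix()
        for g in ref:
            empty.genes[g.gene_id] = pe.GenePileup.empty(g.gene_id, g.sequence)
        with pytest.raises(tm.MetricsError, match="S0"):
            tm.compute_abundance({"S0": empty}, ref)

    def test_planted_abundance_recovered(self, small_library, ref):
        truth = small_library["truth"].abundance
        est = tm.compute_abundance({"S1": small_library["pileup"]}, ref)
        iso = est[est.level == "isodecoder"].set_index("entity_id")
        merged = truth.drop(columns="sample_id").set_index("gene_id").join(iso)
        r = np.corrcoef(merged.abundance, merged.normalized_abundance)[0, 1]
        assert r > 0.99


class TestCharging:
    def test_ratio_and_fraction_arithmetic(self):
        row = tm._charging_row("s", "isodecoder", "g", 80, 20, 10)
        assert row["charging_ratio"] == pytest.approx(4.0)
        assert row["charging_fraction"] == pytest.approx(0.8)

    def test_zero_cc_masks_ratio_keeps_fraction(self):
        row = tm._charging_row("s", "isodecoder", "g", 50, 0, 10)
        assert np.isnan(row["charging_ratio"])
        assert row["charging_fraction"] == 1.0

    def test_below_min_reads_masked(self):
        row = tm._charging_row("s", "isodecoder", "g", 4, 3, 10)
        assert row["masked"]
        assert np.isnan(row["charging_fraction"])

    def test_planted_fraction_recovered(self, small_library, ref):
        table = tm.compute_charging({"S1": small_library["pileup"]}, ref)
        iso = table[table.level == "isodecoder"]
        p = small_library["cfg"].charging_fraction
        for _, row in iso.iterrows():
            n = row.n_CCA + row.n_CC
            sd3 = 3 * np.sqrt(p * (1 - p) / n)
            assert abs(row.charging_fraction - p) < sd3, row.entity_id


DESIGN = [
    tm.SampleDesign("c1", "control", "total", 1),
    tm.SampleDesign("c2", "control", "total", 2),
    tm.SampleDesign("c3", "control", "total", 3),
    tm.SampleDesign("h1", "heat", "total", 1),
    tm.SampleDesign("h2", "heat", "total", 2),
    tm.SampleDesign("h3", "heat", "total", 3),
]


def metric_table(values_by_sample, col="normalized_abundance"):
    rows = []
    for sid, v in values_by_sample.items():
        rows.append({"sample_id": sid, "entity_id": "E", col: v})
    return pd.DataFrame(rows)


class TestComputeChange:
    def test_fold_and_log2(self):
        t = metric_table({"c1": 10, "c2": 10, "c3": 10, "h1": 12, "h2": 12, "h3": 12})
        out = tm.compute_change(t, DESIGN, "abundance")
        assert out.change.iloc[0] == pytest.approx(1.2)
        assert out.log2_change.iloc[0] == pytest.approx(np.log2(1.2), abs=1e-6)

    def test_identity_when_equal(self):
        t = metric_table({s: 5.0 for s in ["c1", "c2", "c3", "h1", "h2", "h3"]})
        out = tm.compute_change(t, DESIGN, "abundance")
        assert out.change.iloc[0] == pytest.approx(1.0)

    def test_mutation_fraction_uses_difference(self):
        t = metric_table(
            {"c1": 0.10, "c2": 0.12, "c3": 0.14, "h1": 0.30, "h2": 0.30, "h3": 0.30},
            col="mutation_fraction",
        )
        out = tm.compute_change(t, DESIGN, "mutation_fraction")
        assert out.change.iloc[0] == pytest.approx(0.30 - 0.12)

    def test_zero_control_mean_masks_ratio(self):
        t = metric_table({"c1": 0, "c2": 0, "c3": 0, "h1": 3, "h2": 3, "h3": 3})
        out = tm.compute_change(t, DESIGN, "abundance")
        assert out.masked.iloc[0]
        assert "zero" in out.reason.iloc[0]

    def test_control_vs_control_centered_on_unity(self, ref, tmp_path):
        """Permutation sanity: identically distributed groups give fold ~ 1."""
        rng = np.random.default_rng(3)
        cfg = sd.SimConfig(depth_per_gene=500)
        pileups = {}
        for sid in ["c1", "c2", "c3", "h1", "h2", "h3"]:
            recs, _ = sd.simulate_trna_sample(
                ref, cfg, rng, sid, abundance={g.gene_id: 1.0 for g in ref}
            )
            sd.write_sam(recs, ref, tmp_path / f"{sid}.sam")
            pileups[sid] = pe.build_pileup(tmp_path / f"{sid}.sam", ref)
        ab = tm.compute_abundance(pileups, ref)
        out = tm.compute_change(
            ab[ab.level == "isodecoder"], DESIGN, "abundance"
        )
        assert out.change.mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_three_fold_increase_recovered(self, ref, tmp_path):
        rng = np.random.default_rng(4)
        cfg = sd.SimConfig(depth_per_gene=2000)
        base = {g.gene_id: 1.0 for g in ref}
        boosted = dict(base)
        boosted["tRNA-Lys-TTT-1"] = 3.0
        pileups = {}
        for sid in ["c1", "c2", "c3"]:
            recs, _ = sd.simulate_trna_sample(ref, cfg, rng, sid, abundance=base)
            sd.write_sam(recs, ref, tmp_path / f"{sid}.sam")
            pileups[sid] = pe.build_pileup(tmp_path / f"{sid}.sam", ref)
        for sid in ["h1", "h2", "h3"]:
            recs, _ = sd.simulate_trna_sample(ref, cfg, rng, sid, abundance=boosted)
            sd.write_sam(recs, ref, tmp_path / f"{sid}.sam")
            pileups[sid] = pe.build_pileup(tmp_path / f"{sid}.sam", ref)
        ab = tm.compute_abundance(pileups, ref)
        out = tm.compute_change(ab[ab.level == "isodecoder"], DESIGN, "abundance")
        fold = out.set_index("entity_id").loc["tRNA-Lys-TTT-1", "change"]
        # planted 3x relative copy number; normalization compresses it
        # because the boosted gene inflates the per-sample total
        expected = 3.0 / (sum(boosted.values()) / sum(base.values()))
        assert expected * 0.85 < fold < expected * 1.15


class TestFragments:
    @pytest.mark.parametrize(
        "end1,bin", [(20, "<30"), (30, "30-39"), (45, "40-49"), (59, "50-59"), (60, "60+"), (79, "60+")]
    )
    def test_bin_assignment(self, end1, bin):
        assert tm.assign_bin(end1) == bin

    def test_bins_partition_reads(self, small_library, ref):
        profiles = tm.end_profiles_from_pileups({"S1": small_library["pileup"]})
        bins = tm.bin_fragments(profiles, ref)
        for gid, sub in bins.groupby("gene_id"):
            gp = small_library["pileup"][gid]
            assert sub.read_count.sum() == gp.read_end_clean.sum()

    def test_trf_ratio_recovers_planted_rate(self, small_library, ref):
        profiles = tm.end_profiles_from_pileups({"S1": small_library["pileup"]})
        bins = tm.bin_fragments(profiles, ref)
        ratio = tm.trf_ratio(bins).tRF_ratio.iloc[0]
        p = small_library["cfg"].fragment_rate
        expected = p / (1 - p)
        n = bins.read_count.sum()
        sd3 = 3 * np.sqrt(p * (1 - p) / n) / (1 - p) ** 2
        assert abs(ratio - expected) < sd3

    def test_fragment_mod_compare_planted_gap(self, ref, tmp_path):
        """Hypomodified fragments vs modified full length at one site."""
        rng = np.random.default_rng(9)
        gid = "tRNA-Ser-GCT-1"
        site = 49
        cfg = sd.SimConfig(depth_per_gene=5000, fragment_rate=0.5,
                           fragment_bin_probs=(0.0, 0.0, 0.0, 1.0))
        # fragments end in 50-59 (cover position 49); full-length reads too
        mods = {gid: {site: sd.ModSite(p_mis=0.6)}}
        recs, _ = sd.simulate_trna_sample(
            ref, cfg, rng, "s",
            abundance={g.gene_id: float(g.gene_id == gid) for g in ref},
            modifications=mods,
        )
        # drop the planted modification from fragment reads to create the gap
        for r in recs:
            if r["fragment"] and r["start"] <= site <= r["end"]:
                s = list(r["seq"])
                s[site - r["start"]] = ref[gid].sequence[site]
                r["seq"] = "".join(s)
                r["cigar"] = f"{len(s)}M"
        sam = tmp_path / "frag.sam"
        sd.write_sam(recs, ref, sam)
        bp = tm.binned_pileups(sam, ref)
        out = tm.fragment_mod_compare(bp, gid, site).set_index("bin")
        full = out.loc["60+", "mutation_fraction"]
        frag = out.loc["50-59", "mutation_fraction"]
        assert full == pytest.approx(0.6, abs=0.05)
        assert frag == pytest.approx(0.0, abs=0.02)

    def test_identical_modification_yields_no_gap(self, ref, tmp_path):
        rng = np.random.default_rng(10)
        gid = "tRNA-Ser-GCT-1"
        cfg = sd.SimConfig(depth_per_gene=4000, fragment_rate=0.5,
                           fragment_bin_probs=(0.0, 0.0, 0.0, 1.0))
        mods = {gid: {49: sd.ModSite(p_mis=0.4)}}
        recs, _ = sd.simulate_trna_sample(
            ref, cfg, rng, "s",
            abundance={g.gene_id: float(g.gene_id == gid) for g in ref},
            modifications=mods,
        )
        sam = tmp_path / "frag.sam"
        sd.write_sam(recs, ref, sam)
        out = tm.fragment_mod_compare(
            tm.binned_pileups(sam, ref), gid, 49
        ).set_index("bin")
        gap = out.loc["50-59", "mutation_fraction"] - out.loc["60+", "mutation_fraction"]
        assert abs(gap) < 3 * np.sqrt(0.4 * 0.6 / 1000)
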