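"""TE computation, codon profiles, association tests, wobble analysis."""

import numpy as np
import pandas as pd
import pytest

from msrtk import synthetic_data as sd
from msrtk import translation_codon as tc
from msrtk.trna_metrics import SampleDesign

from _oracles import exact_ranksum_p


class TestAggregateAndNormalize:
    COUNTS = pd.DataFrame(
        {
            "transcript_id": ["g1.t1", "g1.t2", "g2.t1", "nc1.t1"],
            "s1": [30, 70, 900, 500],
        }
    )
    T2G = pd.DataFrame(
        {
            "transcript_id": ["g1.t1", "g1.t2", "g2.t1", "nc1.t1"],
            "gene_id": ["g1", "g1", "g2", "nc1"],
            "biotype": ["protein_coding", "protein_coding", "protein_coding", "lncRNA"],
        }
    )

    def test_transcripts_summed_per_gene(self):
        out = tc.aggregate_and_normalize(self.COUNTS, self.T2G)
        assert out.set_index("gene_id").loc["g1", "raw"] == 100

    def test_rpm_over_coding_only(self):
        out = tc.aggregate_and_normalize(self.COUNTS, self.T2G).set_index("gene_id")
        assert out.loc["g1", "rpm"] == pytest.approx(100000)
        assert out.loc["g2", "rpm"] == pytest.approx(900000)

    def test_noncoding_does_not_change_coding_rpm(self):
        without_nc = tc.aggregate_and_normalize(
            self.COUNTS.iloc[:3], self.T2G.iloc[:3]
        ).set_index("gene_id")
        with_nc = tc.aggregate_and_normalize(self.COUNTS, self.T2G).set_index("gene_id")
        assert with_nc.loc["g1", "rpm"] == without_nc.loc["g1", "rpm"]

    def test_zero_coding_sample_errors(self):
        counts = pd.DataFrame({"transcript_id": ["g1.t1"], "s1": [0]})
        t2g = self.T2G.iloc[:1]
        with pytest.raises(tc.TranslationError):
            tc.aggregate_and_normalize(counts, t2g)


def simple_te_setup(n=200, seed=0):
    cfg = sd.SimConfig(n_mrna_genes=n, n_noncoding=5)
    counts, t2g, cds, truth = sd.simulate_mrna_te(cfg, seed=seed)
    gc = tc.aggregate_and_normalize(counts, t2g)
    return cfg, gc, cds, truth


class TestComputeTE:
    def test_te_arithmetic(self):
        rows = []
        for gid, inp, pol in [("a", 1000, 2000), ("b", 4000, 1000), ("c", 2000, 2000)]:
            rows.append({"gene_id": gid, "biotype": "protein_coding",
                         "sample_id": "i1", "raw": inp, "rpm": inp})
            rows.append({"gene_id": gid, "biotype": "protein_coding",
                         "sample_id": "p1", "raw": pol, "rpm": pol})
        gc = pd.DataFrame(rows)
        design = [SampleDesign("i1", "control", "total", 1),
                  SampleDesign("p1", "control", "polysome", 1)]
        table, well = tc.compute_te(gc, design)
        assert table.set_index("gene_id").loc["a", "TE"] == pytest.approx(2.0)
        assert table.set_index("gene_id").loc["a", "log10_TE"] == pytest.approx(
            np.log10(2), abs=1e-9
        )

    def test_z_scores_standardized_within_sample(self):
        cfg, gc, _, _ = simple_te_setup()
        table, _ = tc.compute_te(gc, sd.mrna_design(cfg))
        for (c, r), sub in table.groupby(["condition", "replicate"]):
            assert sub.Z.mean() == pytest.approx(0, abs=1e-9)
            assert sub.Z.std(ddof=1) == pytest.approx(1, abs=1e-9)

    def test_strict_threshold_excludes_exact_100(self):
        rows = []
        for gid, inp, pol in [("a", 100.0, 5000.0), ("b", 4000, 1000),
                              ("c", 2000, 2000), ("d", 3000, 1500)]:
            rows.append({"gene_id": gid, "biotype": "protein_coding",
                         "sample_id": "i1", "raw": inp, "rpm": inp})
            rows.append({"gene_id": gid, "biotype": "protein_coding",
                         "sample_id": "p1", "raw": pol, "rpm": pol})
        gc = pd.DataFrame(rows)
        design = [SampleDesign("i1", "control", "total", 1),
                  SampleDesign("p1", "control", "polysome", 1)]
        table, _ = tc.compute_te(gc, design)
        assert "a" not in set(table.gene_id)  # rpm == 100 is not > 100

    def test_missing_fraction_errors(self):
        cfg, gc, _, _ = simple_te_setup()
        design = [d for d in sd.mrna_design(cfg) if d.fraction == "total"]
        with pytest.raises(tc.TranslationError, match="missing matched fraction"):
            tc.compute_te(gc, design)

    def test_scale_invariance_of_z_and_deltaz(self):
        """Multiplying all polysome libraries by a constant leaves Z/deltaZ."""
        cfg, gc, _, _ = simple_te_setup()
        design = sd.mrna_design(cfg)
        base, _ = tc.compute_te(gc, design)
        scaled = gc.copy()
        pol_samples = {d.sample_id for d in design if d.fraction == "polysome"}
        mask = scaled.sample_id.isin(pol_samples)
        scaled.loc[mask, "raw"] *= 7
        scaled.loc[mask, "rpm"] = scaled.loc[mask, "rpm"]  # rpm unchanged by design
        table2, _ = tc.compute_te(
            tc.aggregate_and_normalize(
                _to_counts(scaled), _to_t2g(scaled)
            ),
            design,
        )
        key = ["gene_id", "condition", "replicate"]
        a = base.set_index(key).sort_index()
        b = table2.set_index(key).sort_index()
        np.testing.assert_allclose(a.Z, b.Z, rtol=0, atol=1e-12)
        np.testing.assert_allclose(a.deltaZ, b.deltaZ, rtol=0, atol=1e-12)


def _to_counts(gc_long):
    wide = gc_long.pivot_table(index="gene_id", columns="sample_id", values="raw")
    wide.index = [f"{g}.t1" for g in wide.index]
    wide.index.name = "transcript_id"
    return wide.reset_index()


def _to_t2g(gc_long):
    sub = gc_long[["gene_id", "biotype"]].drop_duplicates()
    return pd.DataFrame(
        {
            "transcript_id": [f"{g}.t1" for g in sub.gene_id],
            "gene_id": sub.gene_id.to_numpy(),
            "biotype": sub.biotype.to_numpy(),
        }
    )


class TestCodonFrequency:
    def test_manual_codon_count(self):
        prof = tc.codon_frequency({"g": ["ATGAAAAAATAA"]})
        assert prof.loc["g", "AAA"] == pytest.approx(2 / 3)
        assert prof.loc["g", "ATG"] == pytest.approx(1 / 3)
        assert prof.loc["g", "protein_length"] == 3

    def test_median_across_transcripts(self):
        # AAA frequencies 0.5, 0.25 -> median 0.375
        prof = tc.codon_frequency({"g": ["ATGAAATAA", "ATGAAACCCGGGTAA"]})
        assert prof.loc["g", "AAA"] == pytest.approx(np.median([1 / 2, 1 / 4]))

    def test_sense_frequencies_sum_to_one(self):
        rng = np.random.default_rng(2)
        codons = [c for c in tc.SENSE_CODONS]
        seq = "".join(rng.choice(codons, size=100)) + "TGA"
        prof = tc.codon_frequency({"g": [seq]})
        assert prof.loc["g", list(tc.SENSE_CODONS)].sum() == pytest.approx(1.0)

    def test_internal_stop_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="internal stop"):
            with pytest.raises(tc.TranslationError):
                tc.codon_frequency({"g": ["ATGTAAAAATAA"]})

    def test_non_triplet_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="divisible"):
            prof = tc.codon_frequency({"g": ["ATGAA"], "h": ["ATGAAATAA"]})
        assert list(prof.index) == ["h"]


class TestRankSum:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exact_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 9)), int(rng.integers(3, 9))
        x = rng.normal(size=n)
        y = rng.normal(size=m) + rng.normal() * 0.5
        p_impl = tc.rank_sum_test(x, y)
        p_oracle = exact_ranksum_p(x, y)
        assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(tc.TranslationError):
            tc.rank_sum_test([], [1.0])


@pytest.fixture(scope="module")
def planted():
    cfg = sd.SimConfig()
    counts, t2g, cds, truth = sd.simulate_mrna_te(cfg, seed=17)
    gc = tc.aggregate_and_normalize(counts, t2g)
    te, well = tc.compute_te(gc, sd.mrna_design(cfg))
    profile = tc.codon_frequency(cds)
    return cfg, te, well, profile


class TestAssociation:
    def test_null_grouping_mostly_ns(self, planted):
        _, te, well, profile = planted
        rng = np.random.default_rng(3)
        vals = pd.Series(rng.normal(size=len(profile)), index=profile.index)
        mat = tc.codon_te_association(vals, profile)
        assert (mat.direction == "ns").mean() > 0.8

    def test_planted_negative_aaa_coupling_detected(self, planted):
        cfg, te, well, profile = planted
        mat = tc.association_by_condition(te, profile, grouping="deltaZ", genes=well)
        row = mat[(mat.codon == "AAA") & (mat.condition == "stress")].iloc[0]
        assert row.direction == "down"
        assert row.p < 0.05

    def test_direction_flips_with_negated_grouping(self, planted):
        _, te, well, profile = planted
        vals = te[te.condition == "stress"].groupby("gene_id")["deltaZ"].mean()
        fwd = tc.codon_te_association(vals, profile)
        rev = tc.codon_te_association(-vals, profile)
        np.testing.assert_allclose(fwd.p, rev.p, rtol=1e-9)
        flip = {"up": "down", "down": "up", "ns": "ns"}
        assert list(rev.direction) == [flip[d] for d in fwd.direction]

    def test_too_few_genes_errors(self, planted):
        *_, profile = planted
        few = pd.Series([1.0] * 10, index=profile.index[:10])
        with pytest.raises(tc.TranslationError):
            tc.codon_te_association(few, profile)


class TestWobble:
    def change_table(self, ref, shift_t34=0.0, seed=0, fraction="polysome"):
        rng = np.random.default_rng(seed)
        rows = []
        for g in ref:
            base = rng.normal(0, 0.1)
            if g.wobble == "T":
                base += shift_t34
            rows.append(
                {
                    "fraction": fraction,
                    "entity_id": g.gene_id,
                    "condition": "heat",
                    "statistic": "abundance",
                    "change": 2.0 ** base,
                    "log2_change": base,
                }
            )
        return pd.DataFrame(rows)

    def test_null_changes_not_significant(self, ref):
        res = tc.wobble_analysis(self.change_table(ref, 0.0, seed=1), ref)
        assert (res["pairwise"].p > 0.05).all()

    def test_planted_t34_shift_detected(self, ref):
        res = tc.wobble_analysis(self.change_table(ref, 1.5, seed=2), ref)
        pair = res["pairwise"]
        tc_row = pair[(pair.group1 == "C") & (pair.group2 == "T")]
        assert (tc_row.p < 0.05).all()

    def test_t34_c34_ratio_arithmetic(self, ref):
        table = self.change_table(ref, 0.0, seed=3)
        table.loc[table.entity_id.str.contains("Lys"), "change"] = 1.0
        t34 = table.entity_id.str.contains("Lys-TTT")
        table.loc[t34, "change"] = 1.5
        res = tc.wobble_analysis(table, ref)
        lys = res["t34_vs_c34"].set_index("amino_acid").loc["Lys"]
        assert lys.ratio_change == pytest.approx(1.5)

    def test_amino_acid_missing_wobble_class_excluded(self, ref):
        res = tc.wobble_analysis(self.change_table(ref, 0.0, seed=4), ref)
        # Gly has only a G34 isoacceptor in the synthetic reference
        assert "Gly" not in set(res["t34_vs_c34"].amino_acid)
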