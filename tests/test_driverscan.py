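"""Cohort parsing, per-event tests, co-occurrence screen, combination and
driver calling."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from netdriver import (
    CpwConfig,
    Mgs,
    MutationRecord,
    NullEnsemble,
    build_mgs,
    call_cna,
    combine_cna,
    combine_point,
    cooccurrence_scan,
    fisher_combine,
    gen_network,
    plant_modules,
    rank_and_adjust,
    read_cna_matrix,
    read_maf,
    test_cna_vs_mgs as cna_vs_mgs,
    test_point_vs_mgs as point_vs_mgs,
    test_vs_cpw as vs_cpw,
)
from netdriver.driverscan import (
    CombinedScore,
    PathwayCollection,
    load_pathways,
    read_category_manifest,
    read_gmt,
)


@pytest.fixture(scope="module")
def module_net():
    """ER(400) background with one planted near-clique of 10 genes."""
    base = gen_network(400, 6.0, "ER", seed=61)
    net, coll = plant_modules(base, 2, 10, 0.9, seed=61)
    ens = NullEnsemble.for_network(net, seed=62)
    return net, coll, ens


class TestMafParsing:
    def test_duplicates_collapse_per_sample(self):
        records = [
            MutationRecord("S1", "TP53"),
            MutationRecord("S1", "TP53"),
            MutationRecord("S1", "PTEN"),
        ]
        mgs = build_mgs(records)
        assert mgs["S1"].genes == {"TP53", "PTEN"}

    def test_one_mgs_per_sample(self):
        mgs = build_mgs([MutationRecord("S1", "A"), MutationRecord("S2", "B")])
        assert set(mgs) == {"S1", "S2"}

    def test_read_maf_requires_columns(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Gene\tSample\nTP53\tS1\n")
        with pytest.raises(ValueError, match="Hugo_Symbol"):
            read_maf(path)

    def test_read_maf_round_trip(self, tmp_path):
        path = tmp_path / "ok.maf"
        path.write_text(
            "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
            "tp53\tS1\tMissense_Mutation\n"
            "TP53\tS1\tNonsense_Mutation\n"
            "PTEN\tS2\tSilent\n"
        )
        records = read_maf(path)
        assert len(records) == 3  # classification never filters records
        mgs = build_mgs(records)
        assert mgs["S1"].genes == {"TP53"}
        assert mgs["S2"].genes == {"PTEN"}


class TestCnaCalls:
    def _profile(self, rows):
        return pd.DataFrame(rows).T.rename(columns=lambda c: f"S{c + 1}")

    def test_eligible_gene(self):
        profile = pd.DataFrame(
            {"S1": [-0.4], "S2": [-0.36], "S3": [-0.5]}, index=["GENE1"]
        )
        calls, eligible = call_cna(profile)
        assert len(calls) == 3
        assert all(c.direction == "loss" for c in calls)
        assert eligible == ["GENE1"]

    def test_too_few_genomes_not_eligible(self):
        profile = pd.DataFrame(
            {"S1": [-0.4], "S2": [-0.2], "S3": [0.0]}, index=["GENE1"]
        )
        calls, eligible = call_cna(profile)
        assert len(calls) == 1
        assert eligible == []

    def test_boundary_is_strict(self):
        profile = pd.DataFrame({"S1": [0.35, 0.35001]}, index=["A", "B"]).T
        profile = pd.DataFrame({"A": [0.35], "B": [0.36]}).T
        profile.columns = ["S1"]
        calls, _ = call_cna(profile)
        assert [c.gene for c in calls] == ["B"]

    def test_gain_direction(self):
        profile = pd.DataFrame({"S1": [0.5]}, index=["G"])
        calls, _ = call_cna(profile, min_genomes=1)
        assert calls[0].direction == "gain"

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "cna.tsv"
        path.write_text("gene\tS1\tS2\nA\t0.1\toops\n")
        with pytest.raises(ValueError, match="S2"):
            read_cna_matrix(path)


class TestPathwayInput:
    def test_gmt_and_manifest(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("PATH_A\tdesc\tTP53\tPTEN\nPATH_B\tdesc\tEGFR\tKRAS\tTP53\n")
        manifest = tmp_path / "cats.tsv"
        manifest.write_text("PATH_A\tCAN\tsuperpathway\nPATH_B\tOTH\n")
        coll = load_pathways(gmt, manifest)
        assert coll.sets["PATH_A"] == {"TP53", "PTEN"}
        assert coll.can_sets() == {"PATH_A": frozenset({"TP53", "PTEN"})}
        assert coll.superpathway == "PATH_A"

    def test_yaml_manifest(self, tmp_path):
        manifest = tmp_path / "cats.yaml"
        manifest.write_text("categories:\n  P1: CAN\nsuperpathway: P1\n")
        categories, superpathway = read_category_manifest(manifest)
        assert categories == {"P1": "CAN"}
        assert superpathway == "P1"

    def test_empty_set_rejected(self, tmp_path):
        gmt = tmp_path / "bad.gmt"
        gmt.write_text("P1\tdesc\n")
        with pytest.raises(ValueError):
            read_gmt(gmt)

    def test_duplicate_name_rejected(self, tmp_path):
        gmt = tmp_path / "bad.gmt"
        gmt.write_text("P1\td\tA\nP1\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(gmt)


class TestPointVsMgs:
    def test_small_mgs_skipped(self, module_net):
        net, _, ens = module_net
        nodes = sorted(net.nodes)
        mgs = Mgs("S1", frozenset(nodes[:3]))  # 2 others after removing query
        assert point_vs_mgs(net, mgs, nodes[0], ens) is None

    def test_gene_not_in_sample_errors(self, module_net):
        net, _, ens = module_net
        nodes = sorted(net.nodes)
        mgs = Mgs("S1", frozenset(nodes[:4]))
        with pytest.raises(ValueError, match="not mutated"):
            point_vs_mgs(net, mgs, nodes[10], ens)

    def test_module_comutation_scores_positive(self, module_net):
        """A sample whose MGS is five members of one dense module: each
        member is enriched against the others."""
        net, coll, ens = module_net
        members = sorted(coll.sets["MODULE_01"])[:5]
        mgs = Mgs("S1", frozenset(members))
        zs = [point_vs_mgs(net, mgs, g, ens).z for g in members]
        assert all(z > 0 for z in zs)


class TestCnaVsMgs:
    def test_single_genome_identity(self, module_net):
        net, coll, ens = module_net
        members = sorted(coll.sets["MODULE_01"])
        mgs_map = {"S1": Mgs("S1", frozenset(members[1:6]))}
        from netdriver import CnaCall

        calls = [CnaCall(members[0], "S1", 0.6, "gain")]
        per_genome, combined = cna_vs_mgs(net, members[0], mgs_map, calls, ens)
        assert set(per_genome) == {"S1"}
        assert combined.p == pytest.approx(per_genome["S1"].p, rel=1e-9)
        assert combined.df == 2

    def test_no_usable_genome_returns_none(self, module_net):
        net, coll, ens = module_net
        members = sorted(coll.sets["MODULE_01"])
        mgs_map = {"S1": Mgs("S1", frozenset(members[1:3]))}  # too small
        from netdriver import CnaCall

        calls = [CnaCall(members[0], "S1", 0.6, "gain")]
        _, combined = cna_vs_mgs(net, members[0], mgs_map, calls, ens)
        assert combined is None


class TestCpw:
    def test_single_set_factor_one_reduces_to_gene_vs_set(self, module_net):
        net, coll, ens = module_net
        one = PathwayCollection(
            sets={"M": coll.sets["MODULE_01"]}, categories={"M": "CAN"}
        )
        from netdriver import nea_gene_vs_set

        gene = sorted(coll.sets["MODULE_01"])[0]
        z, p, _ = vs_cpw(
            net, gene, one, CpwConfig(normalization_factor=1.0), ens
        )
        ref = nea_gene_vs_set(
            net, gene, coll.sets["MODULE_01"] - {gene}, ensemble=ens
        )
        assert z == pytest.approx(ref.z, rel=1e-9)
        assert p == pytest.approx(ref.p, rel=1e-9)

    def test_superpathway_mode(self, module_net):
        net, coll, ens = module_net
        gene = sorted(coll.sets["MODULE_01"])[0]
        z, p, sig = vs_cpw(
            net, gene, coll, CpwConfig(mode="superpathway_only"), ens
        )
        assert z > 2.97 and sig

    def test_normalization_bridge(self):
        cfg = CpwConfig()
        assert cfg.normalization_factor == 10.16
        assert round(cfg.normalize(30.17), 2) == 2.97
        assert cfg.z_cutoff == 2.97

    def test_empty_can_category_errors(self, module_net):
        net, coll, ens = module_net
        bare = PathwayCollection(
            sets=dict(coll.sets), categories={n: "OTH" for n in coll.sets}
        )
        gene = sorted(net.nodes)[0]
        with pytest.raises(ValueError, match="CAN"):
            vs_cpw(net, gene, bare, CpwConfig(), ens)


class TestCooccurrence:
    def test_table_reproduced(self):
        samples = [f"S{i}" for i in range(148)]
        both = set(samples[:4])
        cand_only = {samples[4]}
        res = cooccurrence_scan(
            {"FN1": both | cand_only},
            {"MSH6": both},
            samples,
        )["FN1"]
        assert res.min_p == pytest.approx(2.605e-7, rel=1e-3)
        assert res.passes

    def test_ubiquitous_candidate_fails_screen(self):
        samples = [f"S{i}" for i in range(20)]
        res = cooccurrence_scan(
            {"AMP": set(samples)}, {"PM": set(samples[:5])}, samples
        )["AMP"]
        assert res.min_p == pytest.approx(1.0)
        assert not res.passes

    def test_self_pair_skipped(self):
        samples = ["S1", "S2", "S3"]
        res = cooccurrence_scan(
            {"G1": {"S1"}}, {"G1": {"S1"}}, samples
        )["G1"]
        assert res.n_partners_tested == 0
        assert not res.passes

    def test_independent_mutations_calibrated(self):
        """Under independent Bernoulli mutations the screen's raw p-values
        are conservative-uniform: the pass rate at alpha stays within
        binomial bounds of the nominal level."""
        rng = np.random.default_rng(71)
        samples = [f"S{i}" for i in range(200)]
        cands = {
            f"C{j}": {s for s in samples if rng.random() < 0.2} for j in range(25)
        }
        partners = {
            f"P{j}": {s for s in samples if rng.random() < 0.2} for j in range(25)
        }
        raw = []
        from netdriver import fisher_exact_2x2

        for cs in cands.values():
            for ps in partners.values():
                a = len(cs & ps)
                b = len(ps) - a
                c = len(cs) - a
                d = len(samples) - a - b - c
                raw.append(fisher_exact_2x2(a, b, c, d, "one"))
        rate = np.mean(np.asarray(raw) < 0.01)
        n = len(raw)
        assert rate <= 0.01 + 3 * math.sqrt(0.01 * 0.99 / n)


class TestCombination:
    def test_point_two_components(self):
        assert combine_point(0.5, 0.5).p == pytest.approx(0.59657, abs=1e-4)

    def test_point_single_component_identity(self):
        assert combine_point(None, 0.07).p == pytest.approx(0.07, rel=1e-9)

    def test_point_all_ones(self):
        assert combine_point(1.0, 1.0).p == pytest.approx(1.0)

    def test_cna_all_ones(self):
        assert combine_cna(1.0, 1.0, 1.0).p == pytest.approx(1.0)

    def test_cna_single_component(self):
        assert combine_cna(0.03, None, None).p == pytest.approx(0.03, rel=1e-9)

    def test_cna_three_components(self):
        res = combine_cna(0.01, 0.01, 0.01)
        assert res.chi2 == pytest.approx(27.63, abs=0.01)
        assert res.df == 6
        assert res.p == pytest.approx(1.1e-4, rel=0.02)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            combine_point(None, None)


class TestRankAndAdjust:
    @staticmethod
    def _scores(ps):
        return [
            CombinedScore(
                event_id=f"E{i}", gene=f"G{i}", sample=None,
                p_mgs=None, p_cpw=None, p_co=None,
                chi2=0.0, df=2, combined_p=p,
            )
            for i, p in enumerate(ps)
        ]

    def test_bh_boundary_not_called(self):
        # adjusted p of the smallest value is 0.001 * 10 / 1 = 0.01, and the
        # driver threshold is a strict '<'
        out = rank_and_adjust(self._scores([0.001] + [1.0] * 9))
        assert out[0].adjusted_p == pytest.approx(0.01)
        assert not out[0].driver_call

    def test_all_ones_no_drivers(self):
        out = rank_and_adjust(self._scores([1.0] * 5))
        assert not any(s.driver_call for s in out)

    def test_single_strong_event_called(self):
        out = rank_and_adjust(self._scores([0.001]))
        assert out[0].adjusted_p == pytest.approx(0.001)
        assert out[0].driver_call

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_and_adjust([])

    def test_sorted_by_combined_p(self):
        out = rank_and_adjust(self._scores([0.5, 0.01, 0.2]))
        assert [s.combined_p for s in out] == sorted([0.5, 0.01, 0.2])


class TestPipelineOutputs:
    def test_combined_p_round_trip(self, default_pipeline_result):
        """Every reported combined p is reproducible from its stored
        component p-values."""
        for df in (default_pipeline_result.point_events, default_pipeline_result.cna_genes):
            scored = df.dropna(subset=["combined_p"])
            for _, row in scored.iterrows():
                comps = [
                    row[c]
                    for c in ("p_co", "p_mgs", "p_cpw")
                    if c in row and pd.notna(row[c])
                ]
                if not comps:
                    continue
                assert fisher_combine(comps).p == pytest.approx(
                    row["combined_p"], rel=1e-6, abs=1e-12
                )

    def test_gene_track_matches_best_event(self, default_pipeline_result):
        res = default_pipeline_result
        track = res.gene_track.set_index("gene")["neg_log10_combined_p"]
        pe = res.point_events.dropna(subset=["combined_p"])
        best = pe.groupby("gene")["combined_p"].min()
        g = best.index[0]
        if g in track.index and g not in set(res.cna_genes.get("gene", [])):
            assert track[g] == pytest.approx(-math.log10(best[g]), rel=1e-6)

    def test_coherence_reported_for_all_usable_samples(
        self, default_scenario, default_pipeline_result
    ):
        n_samples = default_scenario.point_labels["sample"].nunique()
        assert len(default_pipeline_result.coherence) == n_samples
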