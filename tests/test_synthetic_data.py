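"""Determinism and planted ground truth of the synthetic generators."""

import numpy as np
import pytest

from herbnet.adme_screen import screen_compounds
from herbnet.network_build import build_ppi_network, compute_centralities
from herbnet.synthetic_data import (
    SyntheticConfig,
    SyntheticConfigError,
    generate_animal_study,
    generate_compound_bundle,
    generate_docking_matrix,
    generate_network_bundle,
)
from herbnet.target_assembly import filter_database_records, intersect_targets


class TestDeterminism:
    def test_compound_bundle_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_compound_bundle(cfg).save(d1)
        generate_compound_bundle(cfg).save(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_network_bundle_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_network_bundle(cfg).save(d1)
        generate_network_bundle(cfg).save(d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_animal_study_identical(self):
        cfg = SyntheticConfig(seed=4)
        t1 = generate_animal_study(cfg).table
        t2 = generate_animal_study(cfg).table
        assert t1.equals(t2)

    def test_different_seeds_differ(self):
        a = generate_docking_matrix(SyntheticConfig(seed=1))
        b = generate_docking_matrix(SyntheticConfig(seed=2))
        assert not a.equals(b)


class TestCompoundBundle:
    def test_screen_matches_ground_truth(self):
        cb = generate_compound_bundle(SyntheticConfig(seed=9))
        verdicts = screen_compounds(cb.compounds, cb.keep_list, cb.drop_no_target_list)
        retained = {v.compound_id for v in verdicts if v.retained}
        assert retained == set(cb.ground_truth_retained)
        assert len(retained) == 46  # 34 passers - 1 no-target + 13 literature-kept

    def test_zero_ob_pass_fraction_leaves_only_keep_list(self):
        cfg = SyntheticConfig(seed=2, frac_ob_pass=0.0, n_drop_no_targets=0)
        cb = generate_compound_bundle(cfg)
        verdicts = screen_compounds(cb.compounds, cb.keep_list, cb.drop_no_target_list)
        retained = {v.compound_id for v in verdicts if v.retained}
        assert retained == set(cb.keep_list)

    def test_infeasible_fraction_rejected(self):
        with pytest.raises(SyntheticConfigError):
            generate_compound_bundle(SyntheticConfig(frac_ob_pass=1.5))
        with pytest.raises(SyntheticConfigError):
            generate_compound_bundle(
                SyntheticConfig(frac_ob_pass=0.9, n_literature_keep=30)
            )


class TestNetworkBundle:
    def test_planted_overlap_exact(self):
        nb = generate_network_bundle(SyntheticConfig(seed=7, planted_overlap=50))
        venn = intersect_targets(nb.herb_targets, nb.disease_targets)
        assert venn.n_common == 50
        assert venn.common.symbols == nb.planted_common.symbols

    def test_database_filter_recovers_herb_set(self):
        nb = generate_network_bundle(SyntheticConfig(seed=3))
        # herb-side records carry compound provenance; disease-side do not
        herb_records = [r for r in nb.database_records if r.compound_id is not None]
        kept = filter_database_records(herb_records)
        assert {r.symbol for r in kept} == nb.herb_targets.symbols

    def test_isolated_halo_when_no_attachment(self):
        nb = generate_network_bundle(SyntheticConfig(seed=3, halo_shell_links=0))
        ppi = build_ppi_network(nb.ppi_edges, candidates=nb.planted_common.symbols)
        table = compute_centralities(ppi)
        halo = sorted(nb.planted_halo.symbols)
        assert (table.loc[halo, "degree"] == 0).all()
        assert (table.loc[halo, "closeness"] == 0.0).all()

    def test_core_wired_to_at_least_seven_compounds(self):
        nb = generate_network_bundle(SyntheticConfig(seed=6))
        deg = {}
        for c, t in nb.ct_links:
            deg[t] = deg.get(t, 0) + 1
        assert all(deg[t] >= 7 for t in nb.planted_core.symbols)
        for t in nb.planted_shell.symbols | nb.planted_halo.symbols:
            assert deg.get(t, 0) < 7

    def test_pathways_cover_core_at_configured_fractions(self):
        cfg = SyntheticConfig(seed=8)
        nb = generate_network_bundle(cfg)
        for gs, frac in zip(nb.pathways, cfg.pathway_core_coverage):
            expected = max(1, round(frac * cfg.n_core))
            assert len(gs.members & nb.planted_core.symbols) == expected

    def test_infeasible_tier_sizes_rejected(self):
        with pytest.raises(SyntheticConfigError):
            generate_network_bundle(SyntheticConfig(n_core=10, n_shell=4))
        with pytest.raises(SyntheticConfigError):
            generate_network_bundle(SyntheticConfig(planted_overlap=10))


class TestAnimalStudy:
    def test_zero_variance_recovers_planted_means_exactly(self):
        cfg = SyntheticConfig(
            seed=5,
            group_sds={"fasting_glucose": 0.0, "fasting_insulin": 0.0, "triglycerides": 0.0},
            ct_noise_sd=0.0,
        )
        study = generate_animal_study(cfg)
        for group, means in cfg.group_means.items():
            sub = study.table[study.table["group"] == group]
            assert np.allclose(sub["fasting_glucose"], means["fasting_glucose"])
            assert np.allclose(sub["triglycerides"], means["triglycerides"])

    def test_planted_fold_recoverable(self):
        from herbnet.bioassay_indices import fold_change_table

        cfg = SyntheticConfig(seed=13, gene_folds={"GENE": {"NC": 1.0, "DC": 2.0}})
        study = generate_animal_study(cfg)
        fc = fold_change_table(study.table, "NC", ct_target_col="ct_GENE", ct_ref_col="ct_18s")
        dc_fold = fc[fc["group"] == "DC"]["fold_change"]
        est = float(np.exp(np.mean(np.log(dc_fold))))
        assert 1.5 <= est <= 2.7

    def test_nonpositive_mean_rejected(self):
        cfg = SyntheticConfig(
            group_means={"NC": {"fasting_glucose": -5, "fasting_insulin": 10, "triglycerides": 60}}
        )
        with pytest.raises(SyntheticConfigError):
            generate_animal_study(cfg)


def test_docking_matrix_shape_and_range():
    cfg = SyntheticConfig(seed=1)
    m = generate_docking_matrix(cfg)
    assert m.shape == (cfg.n_docking_compounds, cfg.n_docking_proteins)
    lo, hi = cfg.docking_score_range
    assert float(m.min().min()) >= lo and float(m.max().max()) <= hi
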