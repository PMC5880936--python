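"""Ground-truth consistency of the synthetic endpoint and community
generators."""

import numpy as np
import pandas as pd
import pytest

from soilredox.budget import compute_ledgers, ledgers_to_frame
from soilredox.community import generalized_unifrac, permanova
from soilredox.io import endpoints_from_frame
from soilredox.simulate import (
    CommunityConfig,
    ProcessAllocation,
    SimulationConfig,
    paper_community_preset,
    paper_preset,
    simulate_community,
    simulate_incubation,
)

PROCESS_COLS = ["e_fe_umol", "e_so4_umol", "e_dechlor_umol", "e_ch4_umol"]


def recovered_vs_truth(seed, noise_cv=None, n_replicates=3):
    kw = {"n_replicates": n_replicates}
    if noise_cv is not None:
        kw["noise_cv"] = noise_cv
    endpoints, truth = simulate_incubation(paper_preset(seed=seed, **kw))
    ledgers = ledgers_to_frame(compute_ledgers(endpoints_from_frame(endpoints)))
    return ledgers.merge(
        truth, on=["group", "amendment", "replicate"], suffixes=("_rec", "_true")
    )


class TestIncubation:
    def test_noiseless_round_trip_is_exact(self):
        m = recovered_vs_truth(seed=5, noise_cv=0.0)
        for col in PROCESS_COLS + ["e_total_umol"]:
            assert np.allclose(m[f"{col}_rec"], m[f"{col}_true"], atol=1e-9)

    def test_molybdate_halves_the_total_budget(self):
        _, truth = simulate_incubation(paper_preset(seed=0, noise_cv=0.0))
        by_group = truth.groupby("group")["e_total_umol"].mean()
        ratio = by_group["biotic_molybdate"] / by_group["biotic"]
        assert ratio == pytest.approx(0.493, abs=0.002)

    def test_sterile_bottles_release_no_methane(self):
        endpoints, _ = simulate_incubation(paper_preset(seed=7))
        sterile = endpoints[endpoints.group == "sterile_abiotic"]
        assert (sterile.ch4_permil == 0).all()
        assert (sterile[["tecp_ug_g", "tcp_ug_g", "dcp_ug_g"]] == 0).all().all()

    def test_truth_ledger_conserves_electrons(self):
        _, truth = simulate_incubation(paper_preset(seed=2))
        assert np.allclose(
            truth["e_total_umol"], truth[PROCESS_COLS].sum(axis=1), rtol=1e-12
        )

    def test_same_seed_is_bit_reproducible(self):
        a = simulate_incubation(paper_preset(seed=11))
        b = simulate_incubation(paper_preset(seed=11))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_recovery_error_shrinks_with_replication(self):
        # RMSE of group-mean totals should drop roughly like 1/sqrt(n)
        def rmse(n_reps, seeds):
            errs = []
            for s in seeds:
                m = recovered_vs_truth(seed=s, n_replicates=n_reps)
                g = m.groupby(["group", "amendment"])
                rel = (
                    g["e_total_umol_rec"].mean() - g["e_total_umol_true"].mean()
                ) / g["e_total_umol_true"].mean()
                errs.extend(rel.tolist())
            return float(np.sqrt(np.mean(np.square(errs))))

        seeds = range(12)
        assert rmse(12, seeds) < rmse(3, seeds)

    def test_allocation_pool_bound_enforced(self):
        cfg = paper_preset(electron_pool=1000.0)
        with pytest.raises(ValueError, match="pool"):
            cfg.validate()

    def test_negative_allocation_rejected(self):
        cfg = paper_preset()
        cfg.allocations[("biotic", "control")] = ProcessAllocation(-1.0, 0, 0)
        with pytest.raises(ValueError, match="negative"):
            cfg.validate()


class TestCommunity:
    def test_shape_and_depth(self):
        table, tree, meta = simulate_community(paper_community_preset(seed=0))
        assert table.counts.shape == (120, 18)
        assert (table.counts.sum(axis=0) == 20000).all()
        assert {t.name for t in tree.tips()} == set(table.otu_ids)
        assert len(meta) == 18

    def test_branch_lengths_non_negative(self):
        _, tree, _ = simulate_community(paper_community_preset(seed=1))
        assert all(
            n.length >= 0 for n in tree.traverse(include_self=False)
            if n.length is not None
        )

    def test_expected_proportions_match_configuration(self):
        # no effects, deep sequencing, weak overdispersion: the named
        # taxon's mean relative abundance approaches its configured base
        cfg = CommunityConfig(seed=3, effect_map={}, depth=50000, theta=5000)
        table, _, _ = simulate_community(cfg)
        prop = table.relative_abundance
        i = table.otu_ids.index("OTU0001")  # Desulforudaceae, base 0.293
        assert prop[i].mean() == pytest.approx(0.293, abs=0.02)

    def test_null_communities_show_no_group_contrast(self):
        cfg = CommunityConfig(seed=4, effect_map={}, depth=30000)
        table, tree, meta = simulate_community(cfg)
        dm = generalized_unifrac(table, tree, 0.5)
        groups = meta.loc[list(dm.ids), "group"].to_numpy()
        within, between = [], []
        for a in range(len(dm.ids)):
            for b in range(a + 1, len(dm.ids)):
                (within if groups[a] == groups[b] else between).append(
                    dm.data[a, b]
                )
        assert np.mean(between) == pytest.approx(np.mean(within), rel=0.15)

    def test_effect_on_unknown_taxon_rejected(self):
        cfg = CommunityConfig(effect_map={("biotic", "biochar"): {"Nope": 2.0}})
        with pytest.raises(ValueError, match="unknown taxon"):
            cfg.validate()

    def test_shallow_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            CommunityConfig(depth=10).validate()

    def test_biochar_effect_detected_by_permanova(self):
        # power check: a 5-fold enrichment of SB-1 under biochar makes the
        # amendment factor significant in nearly every draw
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            effect = {
                (g, "biochar"): {"SB-1": 5.0}
                for g in ("biotic", "biotic_molybdate")
            }
            cfg = CommunityConfig(seed=seed, effect_map=effect, n_otus=60)
            table, tree, meta = simulate_community(cfg)
            dm = generalized_unifrac(table, tree, 0.5)
            res = permanova(
                dm, meta.loc[list(dm.ids), "amendment"],
                permutations=99, seed=seed,
            )
            hits += res.p_value <= 0.05
        assert hits >= int(0.9 * n_seeds)

    def test_covariate_link_induces_negative_association(self):
        # a taxon tied to PCP residuals with a strong negative slope is
        # recovered as a significant negative correlation in most draws
        from soilredox.community import aggregate_taxa, associate

        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            endpoints, _ = simulate_incubation(paper_preset(seed=seed))
            biotic = endpoints[endpoints.group != "sterile_abiotic"]
            pcp = biotic["pcp_ug_g"].to_numpy()
            cfg = paper_community_preset(
                seed=seed,
                covariate_links={"Dehalobacteriaceae": (list(pcp), -1.5)},
                n_otus=60,
            )
            table, _, meta = simulate_community(cfg)
            taxa = aggregate_taxa(table, "family", 0.01).drop(
                index="other", errors="ignore"
            )
            env = pd.DataFrame({"pcp_ug_g": pcp}, index=table.sample_ids)
            res = associate(taxa, env)
            hit = res[(res.taxon == "Dehalobacteriaceae")
                      & (res.variable == "pcp_ug_g")]
            if not hit.empty and hit.significant.item() and \
                    hit.spearman_rho.item() < 0:
                hits += 1
        assert hits >= int(0.8 * n_seeds)
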