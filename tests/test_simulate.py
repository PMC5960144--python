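import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest

from fastkit.beta import bray_curtis, jaccard
from fastkit.community import aggregate_by_rank, relative_abundance
from fastkit.inference import linear_regression
from fastkit.recovery import taxa_recovery
from fastkit.simulate import (
    SyntheticConfig,
    generate_donor_community,
    generate_study,
    generate_tree,
    sample_aliquot,
    simulate_engraftment,
    simulate_phenotypes,
    _retention_probs,
)


class TestGenerateTree:
    def test_smallest_tree_is_a_cherry(self):
        tree = generate_tree(2, seed=0)
        assert sorted(t.name for t in tree.tips()) == ["OTU0001", "OTU0002"]
        assert len(list(tree.traverse(include_self=True))) == 3

    def test_fully_bifurcating_node_count(self):
        tree = generate_tree(50, seed=1)
        assert len(list(tree.tips())) == 50
        assert len(list(tree.non_tips(include_self=True))) == 49

    def test_same_seed_gives_identical_newick(self):
        assert str(generate_tree(20, seed=9)) == str(generate_tree(20, seed=9))

    def test_too_few_leaves_rejected(self):
        with pytest.raises(ValueError):
            generate_tree(1, seed=0)


class TestDonorCommunity:
    def test_proportions_sum_to_one(self):
        cfg = SyntheticConfig(n_otus=200)
        donor, tax = generate_donor_community(cfg, 0, seed=3)
        assert donor.sum() == pytest.approx(1.0)
        assert len(tax) == 200

    def test_heavy_tail_top_decile_holds_majority(self):
        # log-normal sigma=2: the top 10% of OTUs carry most of the mass
        cfg = SyntheticConfig(n_otus=300)
        shares = []
        for seed in range(100):
            donor, _ = generate_donor_community(cfg, 0, seed=seed)
            top = donor.sort_values(ascending=False).iloc[:30]
            shares.append(top.sum())
        assert np.mean(shares) > 0.5

    def test_subjects_have_different_presence_masks(self):
        cfg = SyntheticConfig(n_otus=300)
        a, _ = generate_donor_community(cfg, 0, seed=[0, 10, 0])
        b, _ = generate_donor_community(cfg, 1, seed=[0, 11, 0])
        assert ((a > 0) != (b > 0)).any()
        assert jaccard(a, b) > 0


class TestAliquot:
    def test_total_equals_reads(self):
        donor, _ = generate_donor_community(SyntheticConfig(n_otus=100), 0, seed=1)
        counts = sample_aliquot(donor, 5000, seed=2)
        assert counts.sum() == 5000

    def test_binomial_moments_for_abundant_taxon(self):
        donor = pd.Series([0.5, 0.3, 0.2], index=["a", "b", "c"])
        reads = 10_000
        counts = sample_aliquot(donor, reads, seed=0)
        assert abs(counts["a"] - reads / 2) < 4 * np.sqrt(reads * 0.25)

    def test_aliquot_reproducibility_regime(self):
        # two deep resamples of one donor recover >99% of each other's taxa
        # under the 0.1% rule: dropout is confined to rare taxa
        cfg = SyntheticConfig()
        donor, _ = generate_donor_community(cfg, 0, seed=[5, 10, 0])
        s1 = sample_aliquot(donor, cfg.reads_per_sample, seed=[5, 10, 1])
        s2 = sample_aliquot(donor, cfg.reads_per_sample, seed=[5, 10, 2])
        p1, p2 = s1 / s1.sum(), s2 / s2.sum()
        *_, pct = taxa_recovery(p1, [p2], tau=0.001)
        assert pct > 99.0

    def test_aliquots_of_same_donor_closer_than_other_subjects(self):
        cfg = SyntheticConfig(n_otus=300, reads_per_sample=20_000)
        d0, _ = generate_donor_community(cfg, 0, seed=[7, 10, 0])
        d1, _ = generate_donor_community(cfg, 1, seed=[7, 11, 0])
        s1 = sample_aliquot(d0, cfg.reads_per_sample, seed=1)
        s2 = sample_aliquot(d0, cfg.reads_per_sample, seed=2)
        other = sample_aliquot(d1, cfg.reads_per_sample, seed=3)
        assert jaccard(s1, s2) < jaccard(s1, other)
        assert bray_curtis(s1, s2) < bray_curtis(s1, other)


class TestEngraftment:
    def test_identity_limit(self):
        cfg = SyntheticConfig(
            n_otus=100, retention_p=1.0, phylum_fold_changes={},
            engraftment_noise_sigma=0.0, mouse_noise_sigma=0.0,
        )
        donor, tax = generate_donor_community(cfg, 0, seed=1)
        props = simulate_engraftment(donor, tax, cfg, seed=2)
        for m in props.columns:
            np.testing.assert_allclose(props[m], donor, atol=1e-12)

    def test_zero_retention_gives_empty_community(self):
        cfg = SyntheticConfig(n_otus=100, retention_p=0.0)
        donor, tax = generate_donor_community(cfg, 0, seed=1)
        props = simulate_engraftment(donor, tax, cfg, seed=2)
        assert (props.to_numpy() == 0).all()

    def test_retention_curve_calibrated_on_included_taxa(self):
        cfg = SyntheticConfig()
        donor, _ = generate_donor_community(cfg, 0, seed=[3, 10, 0])
        probs = _retention_probs(donor.to_numpy(), cfg)
        included = donor.to_numpy() >= cfg.inclusion_tau
        assert probs[included].mean() == pytest.approx(cfg.retention_p, abs=1e-6)
        # monotone in abundance: rare taxa are the ones lost
        order = np.argsort(donor.to_numpy())
        present = donor.to_numpy()[order] > 0
        assert (np.diff(probs[order][present]) >= -1e-12).all()

    def test_phylum_fold_changes_shift_composition(self, default_bundle):
        # Bacteroidetes blooms and Firmicutes contracts in every subject
        # (sign test over the 8 subjects rejects symmetry at p < 0.01)
        table = default_bundle.table
        phy = aggregate_by_rank(table, default_bundle.taxonomy, "phylum")
        props = relative_abundance(phy)
        up = down = 0
        n = default_bundle.config.n_subjects
        for j in range(n):
            subj = f"sub{j + 1}"
            s2 = props[f"{subj}_S2"]
            mice = props[[f"{subj}_M{m}" for m in (1, 2, 3)]].mean(axis=1)
            up += mice["Bacteroidetes"] > s2["Bacteroidetes"]
            down += mice["Firmicutes"] < s2["Firmicutes"]
        assert binomtest(up, n, 0.5, alternative="greater").pvalue < 0.01
        assert binomtest(down, n, 0.5, alternative="greater").pvalue < 0.01


class TestPhenotypes:
    @staticmethod
    def _mouse_props(cfg, seeds=(0, 1, 2, 3)):
        out = {}
        for j in seeds:
            donor, tax = generate_donor_community(cfg, j, seed=[9, 10 + j, 0])
            out[f"sub{j + 1}"] = simulate_engraftment(donor, tax, cfg, seed=[9, 10 + j, 3])
        return out

    def test_no_producers_means_baseline_phenotype(self):
        cfg = SyntheticConfig(n_otus=100, tmao_noise_sd=0.0, choline_noise_sd=0.0)
        props = self._mouse_props(cfg, seeds=(0,))
        met = simulate_phenotypes(props, producer_otus=[], config=cfg, seed=0)
        assert (met["tmao"] == 0).all()
        assert (met["choline"] == cfg.choline_baseline).all()

    def test_inverse_relation_and_deterministic_limit(self):
        cfg = SyntheticConfig(n_otus=200, tmao_noise_sd=0.0, choline_noise_sd=0.0)
        props = self._mouse_props(cfg)
        producers = [f"OTU{i + 1:04d}" for i in range(0, 200, 7)]
        met = simulate_phenotypes(props, producers, cfg, seed=1)
        res = linear_regression(met["tmao"], met["choline"])
        assert res.slope == pytest.approx(-cfg.choline_per_tmao)
        assert res.r_squared == pytest.approx(1.0)

    def test_noise_degrades_r_squared(self):
        cfg_noisy = SyntheticConfig(n_otus=200, tmao_noise_sd=3.0, choline_noise_sd=4.0)
        props = self._mouse_props(cfg_noisy)
        producers = [f"OTU{i + 1:04d}" for i in range(0, 200, 7)]
        met = simulate_phenotypes(props, producers, cfg_noisy, seed=1)
        res = linear_regression(met["tmao"], met["choline"])
        assert res.slope < 0
        assert res.r_squared < 1.0


class TestGenerateStudy:
    def test_default_design_shape(self, default_bundle):
        cfg = default_bundle.config
        assert default_bundle.table.shape == (800, 40)
        assert len(default_bundle.manifest) == 40
        assert len(default_bundle.manifest.subjects()) == 8
        assert len(default_bundle.metabolites) == 24
        assert len(list(default_bundle.tree.tips())) == cfg.n_otus

    def test_same_config_and_seed_reproduce_the_bundle(self, small_bundle):
        again = generate_study(small_bundle.config)
        assert again.table == small_bundle.table
        assert str(again.tree) == str(small_bundle.tree)
        pd.testing.assert_frame_equal(again.metabolites, small_bundle.metabolites)
        assert again.producer_otus == small_bundle.producer_otus

    def test_each_mouse_nearest_to_its_own_donor(self, default_bundle):
        # Bray-Curtis nearest human sample is the mouse's own donor >= 90%
        props = relative_abundance(default_bundle.table)
        manifest = default_bundle.manifest
        humans = [s for s in manifest.sample_ids
                  if manifest.row(s).role in ("S1", "S2")]
        hits = total = 0
        for sample in manifest.sample_ids:
            if manifest.row(sample).role != "mouse":
                continue
            dists = {h: bray_curtis(props[sample], props[h]) for h in humans}
            nearest = min(dists, key=dists.get)
            hits += manifest.row(nearest).subject_id == manifest.row(sample).subject_id
            total += 1
        assert total == 24
        assert hits / total >= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(retention_p=1.5)
        with pytest.raises(ValueError):
            SyntheticConfig(n_otus=1)
        with pytest.raises(ValueError):
            SyntheticConfig(phylum_fold_changes={"Firmicutes": -1.0})

    def test_bundle_round_trips_through_files(self, tmp_path, small_bundle):
        from fastkit.io import read_count_table, read_manifest, read_taxonomy, read_tree

        paths = small_bundle.write(tmp_path / "bundle")
        assert read_count_table(paths["table"]) == small_bundle.table
        assert read_taxonomy(paths["taxonomy"]) == small_bundle.taxonomy
        assert read_manifest(paths["manifest"]) == small_bundle.manifest
        assert sorted(t.name for t in read_tree(paths["tree"]).tips()) == sorted(
            t.name for t in small_bundle.tree.tips()
        )
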