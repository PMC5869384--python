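"""The synthetic benchmark generator: determinism, calibration, ground truth."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from toxannot.expression import expression_table
from toxannot.simulate import (AMINO_ACIDS, BACKGROUND_FREQS, CONDITIONAL,
                               ConfigurationError, SimulationConfig, evolve,
                               fragment_and_emit, population_b_mature,
                               random_protein, simulate_dataset,
                               simulate_expression, simulate_family,
                               simulate_proteome, write_dataset)


def _pairwise_path_lengths(tree):
    """Leaf-to-leaf path lengths on a generator tree (brute force)."""
    paths = {}

    def rec(node, acc):
        acc = acc + [(node, node.length)]
        if node.is_leaf():
            paths[node.name] = acc
        for c in node.children:
            rec(c, acc)

    for c in tree.children:
        rec(c, [])
    out = {}
    names = sorted(paths)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa = {id(n): l for n, l in paths[a]}
            shared = sum(l for n, l in paths[b] if id(n) in pa)
            da = sum(l for _, l in paths[a])
            db = sum(l for _, l in paths[b])
            out[(a, b)] = da + db - 2 * shared
    return out


class TestConfig:
    def test_invalid_values_rejected_together(self):
        with pytest.raises(ConfigurationError) as exc:
            SimulationConfig(n_families=0, frag_prob=1.5, subst_rate=-1)
        msg = str(exc.value)
        assert "n_families" in msg and "frag_prob" in msg and "subst_rate" in msg

    def test_family_index_out_of_range(self):
        with pytest.raises(ConfigurationError):
            simulate_family(SimulationConfig(n_families=2), 2)


class TestFamilySimulation:
    def test_zero_rate_limit_leaves_equal_root(self):
        cfg = SimulationConfig(seed=3, subst_rate=0.0, toxin_clade_fraction=0.0)
        fam = simulate_family(cfg, 0)
        assert all(seq == fam.root_seq for seq in fam.mature.values())

    def test_determinism(self):
        cfg = SimulationConfig(seed=9)
        f1, f2 = simulate_family(cfg, 1), simulate_family(cfg, 1)
        assert f1.mature == f2.mature
        assert f1.tree.to_newick() == f2.tree.to_newick()
        assert f1.toxin_leaves == f2.toxin_leaves

    def test_branch_lengths_positive(self):
        fam = simulate_family(SimulationConfig(seed=2), 0)
        for node in fam.tree.walk():
            if node is not fam.tree:
                assert node.length > 0

    def test_pairwise_divergence_matches_site_history_oracle(self, rng):
        # Monte-Carlo oracle: per leaf pair, expected proportion of differing
        # sites from 500 replicate single-site histories at that path length.
        cfg = SimulationConfig(seed=17, subst_rate=0.5, toxin_clade_fraction=0.0,
                               leaves_per_family=(8, 8), root_length_aa=90)
        fam = simulate_family(cfg, 0)
        paths = _pairwise_path_lengths(fam.tree)
        L = cfg.root_length_aa
        diffs, expected, var = [], [], []
        for (a, b), t in paths.items():
            obs = sum(x != y for x, y in zip(fam.mature[a], fam.mature[b]))
            # 500-replicate site-history oracle
            same = 0
            for _ in range(500):
                aa = int(rng.choice(len(AMINO_ACIDS), p=BACKGROUND_FREQS))
                x = y = aa
                for _ in range(rng.poisson(t / 2)):
                    x = int(rng.choice(len(AMINO_ACIDS), p=CONDITIONAL[x]))
                for _ in range(rng.poisson(t / 2)):
                    y = int(rng.choice(len(AMINO_ACIDS), p=CONDITIONAL[y]))
                same += x == y
            p_diff = 1 - same / 500
            diffs.append(obs)
            expected.append(L * p_diff)
            var.append(L * p_diff * (1 - p_diff))
        total_obs, total_exp = sum(diffs), sum(expected)
        sd = math.sqrt(sum(var))
        # correlated across pairs, so allow a generous multiple of the SD
        assert abs(total_obs - total_exp) < 6 * sd + 0.05 * total_exp


class TestExpression:
    def test_counts_conserve_library(self):
        cfg = SimulationConfig(seed=4)
        ds = simulate_dataset(cfg)
        assert ds.counts["count_vg"].sum() == cfg.library_size_vg
        assert ds.counts["count_muscle"].sum() == cfg.library_size_muscle

    def test_symmetric_model_gives_equal_expression(self):
        cfg = SimulationConfig(seed=8, vg_logFPKM_toxin=(1.5, 0.0),
                               vg_logFPKM_nontoxin=(1.5, 0.0),
                               muscle_logFPKM=(1.5, 0.0),
                               library_size_vg=10_000_000,
                               library_size_muscle=10_000_000)
        ds = simulate_dataset(cfg)
        expr = expression_table(ds.counts)
        ratio = (expr["fpkm_vg"].mean() / expr["fpkm_muscle"].mean())
        assert ratio == pytest.approx(1.0, rel=0.05)

    def test_toxins_more_expressed_in_vg(self):
        cfg = SimulationConfig(seed=21, n_families=10, toxin_clade_fraction=1.0,
                               vg_logFPKM_toxin=(2.5, 0.7),
                               vg_logFPKM_nontoxin=(0.5, 0.7))
        ds = simulate_dataset(cfg)
        expr = expression_table(ds.counts).set_index("id")
        tox = ds.truth[ds.truth["is_toxin"]]["id"]
        non = ds.truth[~ds.truth["is_toxin"]]["id"]
        assert len(tox) >= 50
        assert expr.loc[tox, "fpkm_vg"].median() > expr.loc[non, "fpkm_vg"].median()

    def test_empty_library(self):
        cfg = SimulationConfig(seed=5, library_size_vg=0)
        ds = simulate_dataset(cfg)
        assert (ds.counts["count_vg"] == 0).all()
        expr = expression_table(ds.counts)
        assert (expr["fpkm_vg"] == 0).all()


class TestProteome:
    def _ds(self, **kw):
        return simulate_dataset(SimulationConfig(seed=6, **kw))

    def test_saturating_intercept_detects_all(self):
        ds = self._ds(detection_slope=0.0, detection_intercept=30.0)
        eligible = set(ds.truth[ds.truth["is_toxin"] & ds.truth["is_secreted"]]["id"])
        assert ds.proteome_ids == eligible

    def test_negative_intercept_detects_none(self):
        ds = self._ds(detection_slope=0.0, detection_intercept=-30.0)
        assert ds.proteome_ids == set()

    def test_nontoxins_never_detected(self):
        ds = self._ds()
        nontox = set(ds.truth[~ds.truth["is_toxin"]]["id"])
        assert not (ds.proteome_ids & nontox)

    def test_detection_rate_matches_logistic_oracle(self):
        cfg = SimulationConfig(seed=23, n_families=12, toxin_clade_fraction=1.0,
                               detection_slope=1.5, detection_intercept=-3.0)
        ds = simulate_dataset(cfg)
        expr = expression_table(ds.counts).set_index("id")
        eligible = ds.truth[ds.truth["is_toxin"] & ds.truth["is_secreted"]]["id"]
        probs = []
        for cid in eligible:
            z = -3.0 + 1.5 * math.log10(expr.loc[cid, "fpkm_vg"] + 1)
            probs.append(1 / (1 + math.exp(-z)))
        mean, sd = sum(probs), math.sqrt(sum(p * (1 - p) for p in probs))
        assert abs(len(ds.proteome_ids) - mean) <= 3 * sd


class TestFragmentation:
    def test_no_fragmentation_emits_complete(self):
        cfg = SimulationConfig(seed=7, frag_prob=0.0)
        ds = simulate_dataset(cfg)
        assert ds.truth["complete"].all()
        for fam in ds.families:
            for leaf, mat in fam.mature.items():
                sp = fam.secreted[leaf] or ""
                row = ds.truth.set_index("id").loc[leaf]
                assert row["protein"] == sp + mat

    def test_full_fragmentation_no_complete(self):
        ds = simulate_dataset(SimulationConfig(seed=7, frag_prob=1.0))
        assert not ds.truth["complete"].any()

    def test_fragmentation_rate_binomial(self):
        cfg = SimulationConfig(seed=13, n_families=25, frag_prob=0.35)
        ds = simulate_dataset(cfg)
        n = len(ds.truth)
        assert n >= 300
        frac = 1 - ds.truth["complete"].mean()
        sd = math.sqrt(0.35 * 0.65 / n)
        assert abs(frac - 0.35) <= 3 * sd


class TestDatabaseTiers:
    def test_zero_divergence_distant_equals_root(self):
        cfg = SimulationConfig(seed=10, db_divergence=0.0, distant_coverage=1.0)
        ds = simulate_dataset(cfg)
        roots = {f.label: f.root_seq for f in ds.families}
        for e in ds.databases["distant"]:
            if not e.family.startswith("DECOY"):
                assert e.seq == roots[e.family]

    def test_species_tier_subset_of_detected_proteins(self):
        ds = simulate_dataset(SimulationConfig(seed=10))
        protein_of = dict(zip(ds.truth["id"], ds.truth["protein"]))
        detected_proteins = {protein_of[c] for c in ds.proteome_ids}
        assert {e.seq for e in ds.databases["species"]} <= detected_proteins

    def test_decoys_disjoint_from_truth_families(self):
        ds = simulate_dataset(SimulationConfig(seed=10))
        decoy_fams = {e.family for e in ds.databases["distant"]
                      if e.family.startswith("DECOY")}
        assert decoy_fams and not (decoy_fams & set(ds.truth["family"]))


class TestDatasetContracts:
    def test_truth_ids_unique_and_consistent(self):
        ds = simulate_dataset(SimulationConfig(seed=12))
        assert ds.truth["id"].is_unique
        assert set(ds.contigs) == set(ds.truth["id"])
        det = ds.truth[ds.truth["detected"]]
        assert (det["is_toxin"] & det["is_secreted"]).all()

    def test_population_b_only_toxins(self):
        ds = simulate_dataset(SimulationConfig(seed=12))
        assert ds.popB_mature
        toxins = ds.toxin_ids
        for bid in ds.popB_mature:
            assert bid.endswith("B") and bid[:-1] in toxins

    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(seed=14, n_families=2, leaves_per_family=(5, 7))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_dataset(simulate_dataset(cfg), d1)
        write_dataset(simulate_dataset(cfg), d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_detection_expression_calibration_across_seeds(self):
        # under default conditions, detection should correlate positively
        # with venom-gland expression in nearly every seed
        from scipy.stats import spearmanr
        positive = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed)
            ds = simulate_dataset(cfg)
            expr = expression_table(ds.counts)
            ind = expr["id"].isin(ds.proteome_ids).astype(float)
            r = spearmanr(ind, expr["fpkm_vg"]).statistic
            positive += r > 0
        assert positive >= 0.95 * n_seeds
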