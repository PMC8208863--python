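"""Generator contracts: planted structure, determinism, calibration."""

import numpy as np
import pytest

from cernet.diffexpr import fold_change, screen
from cernet.enrichment import hypergeom_upper
from cernet.synthetic import (GroundTruth, SimulationConfig, simulate_expression,
                              simulate_genesets, simulate_interaction_table,
                              simulate_sequences, write_fasta)

_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _corr(x, y):
    return float(np.corrcoef(x, y)[0, 1])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_case=0), dict(noise_sd=0.0), dict(coupling=1.5),
        dict(fc_planted=0.5), dict(n_lnc=5, n_triplets=10),
        dict(n_terms=3, n_enriched=5), dict(lnc_length=150),
        dict(site_length=7),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestExpression:
    def test_transcript_conservation_and_reproducibility(self):
        cfg = SimulationConfig(seed=5)
        m1, t1 = simulate_expression(cfg)
        m2, t2 = simulate_expression(SimulationConfig(seed=5))
        assert len(m1.transcript_ids) == cfg.n_lnc + cfg.n_mi + cfg.n_m
        assert m1.values.equals(m2.values)
        assert t1.planted_triplets == t2.planted_triplets
        assert t1.planted_sites == t2.planted_sites

    def test_sign_pattern_holds_for_most_planted_triplets(self):
        """(+,-,-) correlation signs across >= 200 replicate triplets."""
        cfg = SimulationConfig(n_case=30, n_control=30, n_lnc=200, n_m=200,
                               n_mi=50, n_triplets=200, coupling=0.95,
                               noise_sd=0.1, seed=1, lnc_length=200)
        matrix, truth = simulate_expression(cfg)
        ok = 0
        for lnc, mi, m in truth.planted_triplets:
            r_lm = _corr(matrix.row(lnc), matrix.row(m))
            r_ml = _corr(matrix.row(mi), matrix.row(lnc))
            r_mm = _corr(matrix.row(mi), matrix.row(m))
            ok += (r_lm > 0) and (r_ml < 0) and (r_mm < 0)
        assert ok / len(truth.planted_triplets) >= 0.90

    def test_zero_coupling_leaves_triplets_uncorrelated(self):
        cfg = SimulationConfig(coupling=0.0, fc_planted=1.0, n_triplets=50,
                               n_lnc=50, n_m=50, n_mi=50, seed=3)
        matrix, truth = simulate_expression(cfg)
        rs = [_corr(matrix.row(l), matrix.row(m))
              for l, _, m in truth.planted_triplets]
        assert abs(float(np.mean(rs))) < 0.1

    def test_planted_fold_change_near_target(self):
        """fc_planted=4, n=20+20: mean empirical |FC| within [3, 5]."""
        cfg = SimulationConfig(fc_planted=4.0, n_case=20, n_control=20, seed=2)
        matrix, truth = simulate_expression(cfg)
        case = matrix.values[matrix.samples_in("case")]
        ctrl = matrix.values[matrix.samples_in("control")]
        fcs = [abs(fold_change(case.loc[t], ctrl.loc[t], log2=True))
               for t in truth.planted_de]
        assert 3.0 <= float(np.mean(fcs)) <= 5.0

    def test_null_regime_passes_alpha_fraction_before_fc_gate(self):
        """coupling=0, fc=1: the p < 0.05 gate fires at about 5%."""
        cfg = SimulationConfig(coupling=0.0, fc_planted=1.0, seed=4,
                               n_lnc=200, n_mi=50, n_m=400, n_triplets=20)
        matrix, _ = simulate_expression(cfg)
        out = screen(matrix)
        frac = float((out["p"] < 0.05).mean())
        assert 0.02 <= frac <= 0.09

    def test_triplet_members_pairwise_distinct_and_present(self):
        cfg = SimulationConfig(seed=6)
        matrix, truth = simulate_expression(cfg)
        ids = set(matrix.transcript_ids)
        for trip in truth.planted_triplets:
            assert len(set(trip)) == 3
            assert set(trip) <= ids
        assert set(truth.planted_de) <= ids


class TestSequences:
    def test_planted_site_carries_seed_reverse_complement(self):
        cfg = SimulationConfig(seed=8)
        _, truth = simulate_expression(cfg)
        mirnas, lncs = simulate_sequences(cfg, truth)
        for mi, lnc, start in truth.planted_sites:
            seed = mirnas[mi][1:8]
            window = lncs[lnc][start - 1:start + 6]
            # independent complementarity check: antiparallel base pairing
            assert all(_COMP[seed[6 - t]] == window[t] for t in range(7))

    def test_lengths_match_class_definitions(self):
        cfg = SimulationConfig(seed=8)
        _, truth = simulate_expression(cfg)
        mirnas, lncs = simulate_sequences(cfg, truth)
        assert all(19 <= len(s) <= 24 for s in mirnas.values())
        assert all(len(s) >= 200 for s in lncs.values())
        assert all(set(s) <= set("ACGU") for s in list(mirnas.values()) + list(lncs.values()))

    def test_fasta_output_byte_identical_across_reruns(self, tmp_path):
        cfg = SimulationConfig(seed=9)
        _, truth = simulate_expression(cfg)
        for tag in ("a", "b"):
            mirnas, lncs = simulate_sequences(SimulationConfig(seed=9), truth)
            write_fasta(mirnas, tmp_path / f"mi_{tag}.fa")
            write_fasta(lncs, tmp_path / f"lnc_{tag}.fa")
        assert (tmp_path / "mi_a.fa").read_bytes() == (tmp_path / "mi_b.fa").read_bytes()
        assert (tmp_path / "lnc_a.fa").read_bytes() == (tmp_path / "lnc_b.fa").read_bytes()

    def test_overrunning_planted_site_rejected(self):
        cfg = SimulationConfig(seed=8)
        _, truth = simulate_expression(cfg)
        truth.planted_sites.append(("MIR001", "LNC0001", cfg.lnc_length + 100))
        with pytest.raises(ValueError, match="overruns"):
            simulate_sequences(cfg, truth)


class TestInteractionTable:
    def test_planted_pairs_all_present(self):
        cfg = SimulationConfig(seed=10)
        _, truth = simulate_expression(cfg)
        table = simulate_interaction_table(cfg, truth)
        rows = set(zip(table["miRNA"], table["mRNA"]))
        assert {(mi, m) for _, mi, m in truth.planted_triplets} <= rows


class TestGenesets:
    def test_gmt_structure_and_universe(self):
        cfg = SimulationConfig(seed=12)
        _, truth = simulate_expression(cfg)
        coll = simulate_genesets(cfg, truth)
        assert len(coll.terms) == cfg.n_terms
        assert all(t.members <= coll.universe for t in coll.terms)
        assert set(truth.enriched_terms) <= {t.term_id for t in coll.terms}

    def test_empty_truth_yields_unstructured_gmt(self):
        cfg = SimulationConfig(seed=12)
        coll = simulate_genesets(cfg, GroundTruth(enriched_terms=[]))
        assert len(coll.terms) == cfg.n_terms

    def test_boost_one_is_null_calibrated(self):
        """boost=1: planted-term overlap p-values carry no signal."""
        ps = []
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, boost=1.0)
            _, truth = simulate_expression(cfg)
            coll = simulate_genesets(cfg, truth)
            query = {m for _, _, m in truth.planted_triplets}
            N = len(coll.universe)
            for t in coll.terms:
                if t.term_id in set(truth.enriched_terms):
                    k = len(query & t.members)
                    ps.append(hypergeom_upper(k, len(query), len(t.members), N))
        mean_p = float(np.mean(ps))
        assert 0.30 <= mean_p <= 0.75          # centered, slightly conservative
        assert float(np.mean(np.array(ps) < 0.05)) <= 0.12

    def test_boosted_terms_rank_in_top_decile(self):
        """boost=10, 20 triplet mRNAs, universe 1000: the planted terms
        (median rank) land in the top decile by p-value in >= 90% of
        replicates."""
        top = 0
        reps = 25
        for seed in range(reps):
            cfg = SimulationConfig(seed=seed, boost=10.0, n_m=1000)
            _, truth = simulate_expression(cfg)
            coll = simulate_genesets(cfg, truth)
            query = {m for _, _, m in truth.planted_triplets}
            N = len(coll.universe)
            ps = {}
            for t in coll.terms:
                k = len(query & t.members)
                ps[t.term_id] = hypergeom_upper(k, len(query), len(t.members), N)
            order = sorted(ps, key=lambda tid: ps[tid])
            rank = {tid: i for i, tid in enumerate(order)}
            med = np.median([rank[t] for t in truth.enriched_terms])
            top += med < len(order) // 10
        assert top / reps >= 0.90
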