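import itertools

import numpy as np
import pytest

from splicepotts.energetics import (
    EnergyProfile,
    minimum_energy_sequence,
    rank_sum_compare,
    sample_decoys,
    sample_random_sequences,
    score_ensemble,
)
from splicepotts.io import DonorEnsemble, GenomeRecord
from splicepotts.model import (
    PottsModel,
    energies,
    probability_grid,
    sample_sequences,
    _logit_grid,
)


class TestScoreEnsemble:
    def test_zero_model_all_zero(self, zero_model, tiny_ensemble):
        prof = score_ensemble(zero_model, tiny_ensemble)
        assert np.all(prof.energies == 0.0) and prof.sd == 0.0

    def test_constant_ensemble_constant_energy(self):
        rng = np.random.default_rng(0)
        h = rng.normal(0, 1, (9, 4))
        model = PottsModel(h, np.zeros((36, 16)))
        seq = "CAGGTAAGT"
        prof = score_ensemble(model, DonorEnsemble([seq] * 50))
        expected = -sum(h[i, "ACGT".index(c)] for i, c in enumerate(seq))
        assert np.allclose(prof.energies, expected)
        assert prof.sd == 0.0

    def test_mean_energy_matches_enumerated_expectation(self, random_model):
        n = 100000
        ens = sample_sequences(random_model, n, seed=21)
        prof = score_ensemble(random_model, ens)
        p = probability_grid(random_model)
        e_all = -_logit_grid(random_model.h, random_model.J)
        mean_exact = float((p * e_all).sum())
        sd_exact = float(np.sqrt((p * (e_all - mean_exact) ** 2).sum()))
        assert abs(prof.mean - mean_exact) <= 4 * sd_exact / np.sqrt(n)

    def test_quantiles_bracket_90_percent(self, random_model):
        ens = sample_sequences(random_model, 20000, seed=5)
        prof = score_ensemble(random_model, ens)
        lo, hi = prof.quantiles[0.05], prof.quantiles[0.95]
        frac = np.mean((prof.energies >= lo) & (prof.energies <= hi))
        assert frac >= 0.9 - 1e-9


class TestRandomSequences:
    def test_uniform_frequencies(self):
        n = 10000
        ens = sample_random_sequences(n, seed=1)
        codes = np.array([["ACGT".index(c) for c in s] for s in ens.sequences])
        sigma = np.sqrt(0.25 * 0.75 / n)
        for i in range(9):
            freqs = np.bincount(codes[:, i], minlength=4) / n
            assert np.all(np.abs(freqs - 0.25) <= 4 * sigma)

    def test_deterministic_and_min_n(self):
        assert sample_random_sequences(5, 9).sequences == sample_random_sequences(
            5, 9
        ).sequences
        assert len(sample_random_sequences(1, 0).sequences[0]) == 9
        with pytest.raises(ValueError):
            sample_random_sequences(0, 0)


class TestDecoys:
    def test_single_gt_locus_read_off(self):
        #            0123456789012345
        contig = GenomeRecord("c", "AAACCGTTTTCAAAC")
        # forward GT at offset 5: window = offsets 2..10 -> ACCGTTTTC
        decoys = sample_decoys([contig], DonorEnsemble(["CAGGTAAGT"]), 200, seed=0)
        seqs = set(decoys.decoy_a.sequences) | set(decoys.decoy_b.sequences)
        assert "ACCGTTTTC" in seqs
        for s in seqs:
            assert s[3:5] == "GT"

    def test_annotated_sequence_lands_in_decoy_b(self):
        contig = GenomeRecord("c", "AAACCGTTTTCAAAC")
        annotated = DonorEnsemble(["ACCGTTTTC"])
        decoys = sample_decoys([contig], annotated, 200, seed=0)
        assert "ACCGTTTTC" in decoys.decoy_b.sequences
        assert "ACCGTTTTC" not in decoys.decoy_a.sequences
        assert set(decoys.decoy_a.sequences).isdisjoint(decoys.decoy_b.sequences)

    def test_no_gt_errors(self):
        with pytest.raises(ValueError, match="GT"):
            sample_decoys([GenomeRecord("c", "AAAAAAAAAA")], DonorEnsemble([]), 10, 0)

    def test_planted_annotated_fraction_recovered(self):
        # independent oracle: enumerate every GT window on both strands, then
        # annotate a planted 30% of the unique windows
        from splicepotts.alphabet import revcomp

        rng = np.random.default_rng(11)
        fwd = "".join("ACGT"[c] for c in rng.integers(0, 4, 20000))
        oracle = set()
        for s in (fwd, revcomp(fwd)):
            for k in range(3, len(s) - 5):
                if s[k : k + 2] == "GT":
                    oracle.add(s[k - 3 : k + 6])
        oracle = sorted(oracle)
        planted = [w for w in oracle if rng.random() < 0.3]
        decoys = sample_decoys(
            [GenomeRecord("c", fwd)], DonorEnsemble(planted), 200000, seed=3
        )
        na, nb = len(decoys.decoy_a), len(decoys.decoy_b)
        frac_b = nb / (na + nb)
        true_frac = len(planted) / len(oracle)
        sigma = np.sqrt(true_frac * (1 - true_frac) / len(oracle))
        assert abs(frac_b - true_frac) <= 4 * sigma + 0.01


class TestRankSum:
    def test_identical_samples_p_near_one(self):
        a = EnergyProfile.from_energies(np.arange(50, dtype=float))
        res = rank_sum_compare(a, a)
        assert res["p_value"] > 0.9

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        a = EnergyProfile.from_energies(x)
        b = EnergyProfile.from_energies(x + 10)
        assert rank_sum_compare(a, b)["p_value"] < 1e-10

    def test_matches_exact_enumeration_small_samples(self):
        x = np.array([1.0, 3.0, 5.0, 7.0, 9.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        res = rank_sum_compare(
            EnergyProfile.from_energies(x), EnergyProfile.from_energies(y)
        )
        # exact two-sided p by enumerating all C(10,5) rank splits
        ranks = np.arange(1, 11)
        obs = sum(
            np.searchsorted(np.sort(np.concatenate([x, y])), xi) + 1 for xi in x
        )
        u_obs = obs - 5 * 6 / 2
        us = []
        for comb in itertools.combinations(range(10), 5):
            u = sum(ranks[list(comb)]) - 5 * 6 / 2
        # two-sided: distance from mean
            us.append(u)
        us = np.array(us)
        mean = 5 * 5 / 2
        p_exact = np.mean(np.abs(us - mean) >= abs(u_obs - mean) - 1e-12)
        assert res["p_value"] == pytest.approx(p_exact, abs=1e-9)

    def test_statistic_antisymmetric(self):
        rng = np.random.default_rng(2)
        a = EnergyProfile.from_energies(rng.normal(0, 1, 40))
        b = EnergyProfile.from_energies(rng.normal(0.5, 1, 30))
        r1 = rank_sum_compare(a, b)
        r2 = rank_sum_compare(b, a)
        assert r1["statistic"] == pytest.approx(-r2["statistic"], abs=1e-9)
        assert r1["p_value"] == pytest.approx(r2["p_value"], abs=1e-12)

    def test_empty_errors(self):
        a = EnergyProfile.from_energies(np.array([1.0]))
        with pytest.raises(ValueError):
            rank_sum_compare(a, EnergyProfile.from_energies(np.array([])))


class TestMinimumEnergy:
    def test_zero_model_lexicographic_tie(self, zero_model):
        seq, e = minimum_energy_sequence(zero_model, "all_states")
        assert seq == "AAAAAAAAA" and e == 0.0

    def test_fields_only_consensus_dominated(self):
        ens = DonorEnsemble(["CAGGTAAGT"] * 90 + ["AAAGTAAAA"] * 10)
        from splicepotts.marginals import estimate_marginals

        f = estimate_marginals(ens, pseudocount=1.0).f1
        model = PottsModel(np.log(f), np.zeros((36, 16)))
        seq, _ = minimum_energy_sequence(model, "all_states")
        assert seq == "CAGGTAAGT"

    def test_matches_shuffled_exhaustive_scan(self, random_model):
        seq, e = minimum_energy_sequence(random_model, "all_states")
        # independent re-scan in shuffled order
        flat = -_logit_grid(random_model.h, random_model.J)
        rng = np.random.default_rng(1)
        order = rng.permutation(flat.size)
        best = order[np.argmin(flat[order])]
        assert e == pytest.approx(flat[best], abs=1e-12)
        assert e == flat.min()

    def test_ensemble_scope(self, random_model):
        ens = sample_sequences(random_model, 1000, seed=4)
        seq, e = minimum_energy_sequence(random_model, "ensemble", ensemble=ens)
        assert seq in set(ens.sequences)
        assert e == pytest.approx(energies(random_model, ens).min(), abs=1e-12)


def test_energy_ordering_on_donor_like_panel():
    """Model's own samples < decoy-like perturbed sequences < uniform random."""
    from splicepotts.synth import PanelDesign, make_species_panel
    from splicepotts.marginals import estimate_marginals
    from splicepotts.model import fit_maxent

    design = PanelDesign(
        n_groups=1,
        species_per_group=1,
        group_couplings=((("-1G:+6T", -0.7),),),
        n_sequences_per_species=30000,
        seed=13,
    )
    panel = make_species_panel(design)
    ens = panel.ensembles["g1_s1"]
    model = fit_maxent(estimate_marginals(ens, 1.0), 0.01, max_iter=500)
    own = score_ensemble(model, sample_sequences(model, 5000, seed=1)).mean
    rng = np.random.default_rng(3)
    perturbed = []
    for s in ens.sequences[:5000]:
        k = int(rng.integers(0, 9))
        perturbed.append(s[:k] + "ACGT"[int(rng.integers(0, 4))] + s[k + 1 :])
    mid = score_ensemble(model, DonorEnsemble(perturbed)).mean
    rand = score_ensemble(model, sample_random_sequences(5000, seed=2)).mean
    assert own < mid < rand
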