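import numpy as np
import pytest
from scipy import stats

from mitocomp import codon_bias as cb
from mitocomp import genetic_code as gc
from mitocomp.simulate import sim_coding_sequence


def table_from_counts(counts: dict, code: int = 1) -> cb.CodonCountTable:
    """Build a count table with positional composition consistent with counts."""
    pos = np.zeros((3, 4))
    for codon, n in counts.items():
        for p, b in enumerate(codon):
            pos[p, cb._NT_INDEX[b]] += n
    return cb.CodonCountTable(counts=dict(counts), code=code, positional=pos)


class TestCountCodons:
    def test_terminal_stop_excluded(self):
        t = cb.count_codons("ATGTAA")
        assert t.counts == {"ATG": 1}
        assert t.total == 1

    def test_hand_count(self):
        t = cb.count_codons("TTATTGTAA")
        assert t.counts == {"TTA": 1, "TTG": 1}

    def test_pooling_equals_concatenation(self):
        a, b = "ATGGCTTAA", "GCTGCCTAA"
        pooled = cb.count_codons(a) + cb.count_codons(b)
        concat = cb.count_codons(a[:-3] + b)
        assert pooled.counts == concat.counts
        assert np.allclose(pooled.positional, concat.positional)

    def test_internal_stop_flagged_but_counted(self):
        t = cb.count_codons("ATGTAAGCTTAA")
        assert t.n_internal_stops == 1
        assert t.counts["TAA"] == 1

    def test_ambiguous_codons_skipped(self):
        t = cb.count_codons("ATGNNNGCT")
        assert t.n_skipped == 1
        assert t.total == 2

    def test_length_error(self):
        with pytest.raises(ValueError):
            cb.count_codons("ATGA")


class TestEncObserved:
    def test_maximal_bias_is_twenty(self):
        counts = {fam[0]: 50 for fam in gc.families(1).values()}
        assert cb.enc_observed(table_from_counts(counts)) == 20.0

    def test_uniform_usage_capped_at_61(self):
        counts = {c: 100 for c in gc.sense_codons(1)}
        assert cb.enc_observed(table_from_counts(counts)) == 61.0

    def test_two_fold_family_homozygosity_hand_value(self):
        # every family uses one codon (F=1) except Phe with counts (3,1):
        # F_Phe = (4*(9/16+1/16)-1)/3 = 0.5; mean over the nine 2-fold
        # families = (8*1 + 0.5)/9; Nc = 2 + 9/F2 + 1/1 + 5/1 + 3/1
        counts = {fam[0]: 4 for aa, fam in gc.families(1).items() if aa != "F"}
        counts["TTT"], counts["TTC"] = 3, 1
        f2 = (8 * 1.0 + 0.5) / 9
        expected = 2 + 9 / f2 + 1 + 5 + 3
        assert cb.enc_observed(table_from_counts(counts)) == pytest.approx(expected)

    def test_relabeling_within_family_invariant(self):
        rng = np.random.default_rng(0)
        counts = {c: int(rng.integers(0, 50)) for c in gc.sense_codons(1)}
        t1 = table_from_counts(counts)
        swapped = dict(counts)
        for aa, fam in gc.families(1).items():
            vals = [counts[c] for c in fam]
            for c, v in zip(fam, vals[::-1]):
                swapped[c] = v
        t2 = table_from_counts(swapped)
        assert cb.enc_observed(t2) == pytest.approx(cb.enc_observed(t1))

    def test_count_scaling_near_invariant(self):
        rng = np.random.default_rng(1)
        counts = {c: int(rng.integers(50, 500)) for c in gc.sense_codons(1)}
        n1 = cb.enc_observed(table_from_counts(counts))
        n10 = cb.enc_observed(table_from_counts({c: 10 * v for c, v in counts.items()}))
        assert abs(n1 - n10) < 0.1

    def test_missing_class_imputation_and_undefined(self):
        # no Ile codons at all: class 3 imputed from classes 2 and 4
        counts = {fam[0]: 4 for aa, fam in gc.families(1).items()
                  if aa not in ("I",)}
        assert cb.enc_observed(table_from_counts(counts)) is not None
        # a 2-codon-only table cannot support classes 4 and 6
        assert cb.enc_observed(table_from_counts({"TTT": 3, "TTC": 1})) is None


class TestEncExpected:
    def test_printed_formula_on_grid(self):
        for s in np.arange(0, 1.0001, 0.01):
            direct = 2 + s + 29 / (s ** 2 + (1 - s) ** 2)
            assert cb.enc_expected(float(s)) == direct

    @pytest.mark.parametrize("s,val", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_reference_points(self, s, val):
        assert cb.enc_expected(s) == pytest.approx(val)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            cb.enc_expected(1.5)


class TestEncPrime:
    def test_uniform_background_equals_enc_observed(self):
        rng = np.random.default_rng(2)
        counts = {c: int(rng.integers(1, 400)) for c in gc.sense_codons(1)}
        t = table_from_counts(counts)
        uniform = np.full((3, 4), 0.25)
        assert cb.enc_prime(t, background=uniform) == \
               pytest.approx(cb.enc_observed(t), abs=1e-6)

    def test_null_model_limit_reaches_code_maximum(self):
        # counts exactly proportional to the background-product expectation
        bg = np.array([[0.3, 0.2, 0.1, 0.4],
                       [0.25, 0.25, 0.25, 0.25],
                       [0.45, 0.05, 0.05, 0.45]])
        counts = {}
        for aa, fam in gc.families(1).items():
            e = []
            for codon in fam:
                x = 1.0
                for p, b in enumerate(codon):
                    x *= bg[p, cb._NT_INDEX[b]]
                e.append(x)
            e = np.array(e) / sum(e)
            for codon, ei in zip(fam, e):
                counts[codon] = 1e6 * ei
        t = table_from_counts(counts)
        assert cb.enc_prime(t, background=bg) == pytest.approx(61.0)

    def test_hand_chi_square_family(self):
        # 2-fold family (4,0) under a uniform background: chi2 = 4,
        # F' = (4+4-2)/(2*3) = 1, so the family is maximally biased and
        # contributes like a single-codon family.
        counts = {fam[0]: 4 for aa, fam in gc.families(1).items() if aa != "F"}
        counts["TTT"] = 4
        t = table_from_counts(counts)
        uniform = np.full((3, 4), 0.25)
        assert cb.enc_prime(t, background=uniform) == pytest.approx(20.0)

    def test_self_background_on_simulated_null_gene(self):
        cds = sim_coding_sequence(20_000, at_target=0.75, gc3s_target=0.3,
                                  seed=5)
        t = cb.count_codons(cds)
        prime = cb.enc_prime(t)
        assert prime > 58.0  # near the cap under its own null


class TestCDC:
    def test_zero_under_proportionality(self):
        pos = np.full((3, 4), 25.0)
        tmpl = cb.CodonCountTable(counts={}, code=1, positional=pos.copy())
        e = cb._cdc_expected(tmpl)
        counts = {c: 1000 * ei for c, ei in zip(gc.sense_codons(1), e)}
        t = cb.CodonCountTable(counts=counts, code=1, positional=pos.copy())
        value, p = cb.cdc(t, reps=50, seed=0)
        assert value == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_concentrated_usage_has_high_cdc(self):
        counts = {fam[0]: 100 for fam in gc.families(1).values()}
        t = table_from_counts(counts)
        value, p = cb.cdc(t, reps=200, seed=0)
        assert value > 0.1
        assert p <= 0.01

    def test_bootstrap_p_uniform_under_null(self):
        # sequences simulated from their own expected model: p ~ U(0,1)
        rng = np.random.default_rng(42)
        pos = np.full((3, 4), 25.0) * 40
        tmpl = cb.CodonCountTable(counts={}, code=1, positional=pos.copy())
        e = cb._cdc_expected(tmpl)
        sense = gc.sense_codons(1)
        pvals = []
        for _ in range(500):
            cnt = rng.multinomial(300, e)
            counts = {c: int(k) for c, k in zip(sense, cnt) if k}
            t = cb.CodonCountTable(counts=counts, code=1, positional=pos.copy())
            _, p = cb.cdc(t, reps=200, seed=int(rng.integers(2 ** 31)))
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_seeded_reproducibility(self):
        counts = {c: 10 for c in gc.sense_codons(1)}
        t = table_from_counts(counts)
        assert cb.cdc(t, reps=500, seed=7) == cb.cdc(t, reps=500, seed=7)


class TestCompareBias:
    def test_exact_small_sample(self):
        assert cb.compare_bias([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_self_comparison(self):
        assert cb.compare_bias([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == \
               pytest.approx(1.0)

    def test_identical_constants(self):
        assert cb.compare_bias([2, 2, 2], [2, 2]) == 1.0

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 40)
        b = rng.normal(1.2, 1, 40)
        p = cb.compare_bias(a, b)
        assert 0 < p < 1e-3

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            cb.compare_bias([], [1.0])


class TestBiasReport:
    def test_report_fields_consistent(self):
        cds = sim_coding_sequence(2000, seed=8)
        r = cb.bias_report(cds, reps=200, seed=0)
        assert r.n_codons == len(cds) // 3 - 1  # stop excluded
        assert 20 <= r.nc_observed <= 61
        assert 0 <= r.cdc <= 1 and 0 <= r.cdc_p <= 1
        assert r.nc_expected == pytest.approx(cb.enc_expected(r.S))
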