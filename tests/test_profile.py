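"""Stacked profiles, rescaled frequencies, permutation test, stratification."""

import numpy as np
import pandas as pd
import pytest

import exindnm as ed
from exindnm.annotation import CENTRAL_EXON
from exindnm.context import ContextScheme
from exindnm.profile import bin_profile, site_frequencies

from conftest import make_coding_gene


def dnm_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "condition", "dataset"])


@pytest.fixture(scope="module")
def fitted(small_world):
    model = ed.estimate_direct(small_world["dnms"], small_world["genome"], 3)
    windows = small_world["windows"]
    freqs = ed.window_frequencies(windows, small_world["genome"], model)
    observed = ed.window_observed_counts(windows, small_world["dnms"])
    return model, windows, freqs, observed


class TestSiteFrequencies:
    def test_uniform_model_gives_flat_rescaled(self, small_world):
        model = ed.uniform_model(ContextScheme(1, 1, "mono"), 1e-8)
        w = small_world["windows"][0]
        f, resc = site_frequencies(w, small_world["genome"], model)
        np.testing.assert_allclose(resc, 1.0 / w.width)

    def test_rescaled_sums_to_one(self, small_world, fitted):
        model, windows, freqs, _ = fitted
        for w in windows[:10]:
            _, resc = site_frequencies(w, small_world["genome"], model)
            assert resc.sum() == pytest.approx(1.0)

    def test_hand_built_window(self):
        """9-bp window under a hand-built 3-mer model matches manual sums."""
        genome = ed.GenomeSequence({"c": "ACGTACGTA"})
        scheme = ContextScheme(3, 3, "direct")
        probs = np.zeros((64, 3))
        # give context CGT (code 1*16+2*4+3 = 27) total rate 0.3, GTA (code 2*16+3*4+0=44) 0.06
        probs[27] = [0.1, 0.1, 0.1]
        probs[44] = [0.01, 0.02, 0.03]
        model = ed.ContextModel(scheme, probs)
        w = ed.Window("c", 0, 4, 9, np.zeros(9, dtype=np.uint8), "g")
        f, resc = site_frequencies(w, genome, model)
        # positions 2 and 6 have context CGT; 3 and 7 GTA; others zero-rate
        expect = np.array([0, 0, .3, .06, 0, 0, .3, .06, 0])
        np.testing.assert_allclose(f, expect)
        np.testing.assert_allclose(resc, expect / expect.sum())

    def test_all_zero_window_raises(self):
        genome = ed.GenomeSequence({"c": "A" * 9})
        model = ed.ContextModel(ContextScheme(3, 3, "direct"), np.zeros((64, 3)))
        w = ed.Window("c", 0, 4, 9, np.zeros(9, dtype=np.uint8), "g")
        with pytest.raises(ValueError, match="zero total"):
            site_frequencies(w, genome, model)


class TestBuildProfile:
    def test_uniform_single_window_expectation(self):
        genome = ed.GenomeSequence({"c": "ACGT" * 20})
        model = ed.uniform_model(ContextScheme(1, 1, "mono"), 1e-3)
        labels = np.zeros(21, dtype=np.uint8)
        w = ed.Window("c", 10, 20, 21, labels, "g")
        muts = dnm_frame([("c", 12, genome.fetch("c", 12, 13), "T", "h", "d")] * 4)
        freqs = ed.window_frequencies([w], genome, model)
        obs = ed.window_observed_counts([w], muts)
        prof = ed.build_profile([w], freqs, obs)
        np.testing.assert_allclose(prof.expected, 4 / 21)

    def test_conservation_identity(self, fitted):
        """Per run: total observed equals total expected exactly; per window
        the expected vector sums to that window's observed count."""
        _, windows, freqs, observed = fitted
        prof = ed.build_profile(windows, freqs, observed)
        assert prof.observed.sum() == pytest.approx(prof.expected.sum(), rel=1e-12)
        for w, f, obs in zip(windows, freqs, observed):
            n_s = obs.sum()
            expected_s = f / f.sum() * n_s
            assert expected_s.sum() == pytest.approx(n_s, rel=1e-9)

    def test_matches_naive_double_loop(self, small_world, fitted):
        """Cumulative expected profile equals a brute-force loop over windows
        and positions on a 50-window subset."""
        model, windows, freqs, observed = fitted
        sub = windows[:50]
        prof = ed.build_profile(sub, freqs[:50], observed[:50])
        L = sub[0].width
        naive_exp = np.zeros(L)
        naive_obs = np.zeros(L)
        for w, f, obs in zip(sub, freqs[:50], observed[:50]):
            n_s = obs.sum()
            resc = f / f.sum()
            for l in range(L):
                naive_exp[l] += resc[l] * n_s
                naive_obs[l] += obs[l]
        np.testing.assert_allclose(prof.expected, naive_exp, rtol=1e-10)
        np.testing.assert_array_equal(prof.observed, naive_obs)

    def test_mutation_in_overlapping_windows_counted_twice(self, small_world):
        g = small_world["genome"]
        chrom = g.chrom_names[0]
        labels = np.zeros(21, dtype=np.uint8)
        w1 = ed.Window(chrom, 3000, 3010, 21, labels, "g1")
        w2 = ed.Window(chrom, 3010, 3020, 21, labels.copy(), "g2")
        mut = dnm_frame([(chrom, 3012, g.fetch(chrom, 3012, 3013),
                          "A" if g.fetch(chrom, 3012, 3013) != "A" else "C", "h", "d")])
        obs = ed.window_observed_counts([w1, w2], mut)
        assert obs[0].sum() == 1 and obs[1].sum() == 1


class TestBinProfile:
    def test_identity_and_constant(self, rng):
        x = rng.random(100)
        np.testing.assert_array_equal(bin_profile(x, 1), x)
        np.testing.assert_allclose(bin_profile(np.full(100, 3.5), 25), 3.5)

    def test_matches_chunked_mean(self, rng):
        x = rng.random(2001)
        got = bin_profile(x, 25)
        expect = [x[i:i + 25].mean() for i in range(0, 2001, 25)]
        np.testing.assert_allclose(got, expect)
        assert len(got) == 81  # 80 full bins + 1 final bin of one position


class TestExonicExcessTest:
    def test_null_self_consistency(self, small_world, fitted):
        """Observed counts equal to each window's expected allocation give
        excess near 0 and an unremarkable p-value."""
        model, windows, freqs, _ = fitted
        rng = np.random.default_rng(42)
        synthetic_obs = []
        for f in freqs:
            resc = f / f.sum()
            synthetic_obs.append(rng.multinomial(20, resc).astype(float))
        res = ed.exonic_excess_test(windows, freqs, synthetic_obs,
                                    n_permutations=500, seed=9)
        assert abs(res.excess_pct) < 2 * res.sd_pct
        assert res.p_value > 0.05

    def test_p_value_floor(self, small_world, fitted):
        """A gross excess cannot yield p below 1/n_permutations."""
        model, windows, freqs, _ = fitted
        obs = []
        for w, f in zip(windows, freqs):
            o = np.zeros(w.width)
            o[w.label_mask(CENTRAL_EXON)] = 5.0  # everything exonic
            obs.append(o)
        res = ed.exonic_excess_test(windows, freqs, obs, n_permutations=200, seed=1)
        assert res.p_value == 1 / 200
        assert res.excess_pct > 0

    def test_injected_multipliers_recovered_in_order(self, small_world):
        """Exonic multipliers 0.9 / 1.0 / 1.1 produce monotonically ordered
        excess estimates."""
        genome, ann, cfg = (small_world["genome"], small_world["annotation"],
                            small_world["config"])
        truth = ed.ContextModel(small_world["true_model"].scheme,
                                small_world["true_model"].probs * 30)
        windows = small_world["windows"]
        excesses = []
        for i, m in enumerate((0.9, 1.0, 1.1)):
            import dataclasses
            c = dataclasses.replace(cfg, exonic_multiplier=m)
            dnms = ed.simulate_dnms(genome, ann, c, truth,
                                    rng=np.random.default_rng(100 + i),
                                    genes=small_world["genes"])
            freqs = ed.window_frequencies(windows, genome, truth)
            obs = ed.window_observed_counts(windows, dnms)
            res = ed.exonic_excess_test(windows, freqs, obs,
                                        n_permutations=300, seed=5)
            excesses.append(res.excess_pct)
        assert excesses[0] < excesses[1] < excesses[2]

    def test_order_and_naming_invariance(self, small_world, fitted):
        model, windows, freqs, observed = fitted
        res = ed.exonic_excess_test(windows, freqs, observed, 200, seed=3)
        order = np.random.default_rng(0).permutation(len(windows))
        res2 = ed.exonic_excess_test([windows[i] for i in order],
                                     [freqs[i] for i in order],
                                     [observed[i] for i in order], 200, seed=3)
        assert res.observed_exonic == res2.observed_exonic
        assert abs(res.excess_pct - res2.excess_pct) < 2 * res.sd_pct

    def test_zero_permutations_rejected(self, fitted):
        _, windows, freqs, observed = fitted
        with pytest.raises(ValueError):
            ed.exonic_excess_test(windows, freqs, observed, 0, seed=1)


class TestStratification:
    @pytest.fixture()
    def coding_window_setup(self):
        """One gene whose middle exon is fully coding, with a uniform model."""
        rngl = np.random.default_rng(77)
        exons = ["".join(rngl.choice(list("ACGT"), size=60)) for _ in range(3)]
        total = sum(map(len, exons))
        exons[-1] += "A" * ((-total) % 3)
        introns = ["".join(rngl.choice(list("ACGT"), size=400)) for _ in range(2)]
        genome, gene = make_coding_gene(exons, introns, offset=600)
        windows = ed.extract_windows([gene], {"chr1": genome.length("chr1")}, width=801)
        model = ed.uniform_model(ContextScheme(1, 1, "mono"), 1e-4)
        return genome, gene, windows, model

    def test_partition_identity(self, coding_window_setup):
        """Synonymous- plus nonsynonymous-stratified frequencies equal the
        full frequency at every central coding site."""
        genome, gene, windows, model = coding_window_setup
        genes = {gene.gene_id: gene}
        full = ed.window_frequencies(windows, genome, model)
        fs = ed.profile.stratified_window_frequencies(windows, genes, genome,
                                                      model, "synonymous")
        fn = ed.profile.stratified_window_frequencies(windows, genes, genome,
                                                      model, "nonsynonymous")
        for w, f, s, n in zip(windows, full, fs, fn):
            central = w.label_mask(CENTRAL_EXON)
            np.testing.assert_allclose(s[central] + n[central], f[central])
            np.testing.assert_allclose(s[~central], f[~central])

    def test_stratified_matches_exhaustive_alternate_oracle(self, coding_window_setup):
        """Stratified central-site frequencies equal brute-force enumeration of
        all three alternates with codon translation."""
        genome, gene, windows, model = coding_window_setup
        (w,) = windows
        fs = ed.profile.stratified_window_frequencies(
            [w], {gene.gene_id: gene}, genome, model, "synonymous")[0]
        central_offsets = np.flatnonzero(w.label_mask(CENTRAL_EXON))
        p = 1e-4
        for off in central_offsets:
            pos = w.start + int(off)
            ref = genome.fetch("chr1", pos, pos + 1)
            expect = 0.0
            for alt in "ACGT":
                if alt == ref:
                    continue
                if ed.classify_consequence("chr1", pos, ref, alt, gene, genome) == "synonymous":
                    expect += p
            assert fs[off] == pytest.approx(expect)

    def test_unlabeled_exonic_mutation_raises(self, coding_window_setup):
        genome, gene, windows, model = coding_window_setup
        (w,) = windows
        pos = w.center
        ref = genome.fetch("chr1", pos, pos + 1)
        muts = dnm_frame([("chr1", pos, ref, "A" if ref != "A" else "C", "h", "d")])
        muts["consequence"] = [None]
        with pytest.raises(ValueError, match="unlabeled"):
            ed.stratify_by_consequence(muts, windows, {gene.gene_id: gene},
                                       genome, model, "synonymous")
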