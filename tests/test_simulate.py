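"""Synthetic-data generator: haplotypes, fragments, chemistry, reads, cohort."""

import math

import numpy as np
import pytest
from scipy import stats

import methylamp as m
from methylamp.errors import DataError, ValidationError
from methylamp.simulate import (
    DEFAULT_COHORT_FRACTIONS,
    _draw_fragment_lengths,
)


def binom_3sd(p, n):
    return 3 * math.sqrt(p * (1 - p) / n)


class TestTissueProfile:
    def test_from_u_frequencies(self):
        p = m.TissueProfile.from_u("t", 0.78)
        assert p.haplotype_freqs == {"UUUUUU": 0.78, "MMMMMM": pytest.approx(0.22)}
        assert p.fully_unmethylated_fraction == 0.78

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            m.TissueProfile("t", {"UU": 0.5, "MM": 0.4})

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValidationError):
            m.TissueProfile("t", {"UU": 1.2, "MM": -0.2})


class TestDrawHaplotype:
    def test_pure_unmethylated_always_all_u(self, rng):
        p = m.TissueProfile.from_u("t", 1.0)
        assert all(m.draw_haplotype(p, rng) == "UUUUUU" for _ in range(50))

    def test_pure_methylated_never_all_u(self, rng):
        p = m.TissueProfile.from_u("t", 0.0)
        assert all(m.draw_haplotype(p, rng) == "MMMMMM" for _ in range(50))

    def test_mixture_converges_to_frequency(self, rng):
        u, n = 0.78, 50_000
        p = m.TissueProfile.from_u("t", u)
        draws = sum(m.draw_haplotype(p, rng) == "UUUUUU" for _ in range(n))
        assert abs(draws / n - u) < binom_3sd(u, n)


class TestFragments:
    def test_short_max_never_amplifiable(self, assay, rng):
        frag = m.FragmentModel(mode_length=50, max_length=assay.insert_length - 1)
        frs = [m.simulate_fragment(assay, frag, rng) for _ in range(200)]
        assert not any(f.amplifiable for f in frs)

    def test_exact_insert_fragment_is_amplifiable(self, assay):
        frag = m.FragmentModel(mode_length=assay.insert_length,
                               max_length=assay.insert_length, dispersion=0.01)
        rng = np.random.default_rng(0)
        # draw until a fragment of exactly insert length lands exactly on it
        for _ in range(20_000):
            f = m.simulate_fragment(assay, frag, rng)
            if f.start == frag.max_length and f.end - f.start == assay.insert_length:
                assert f.amplifiable
                break
        else:
            pytest.fail("never drew the exact insert interval")

    def test_amplifiable_fraction_matches_direct_integration(self, assay):
        """Monte-Carlo amplifiable fraction vs direct integration of the
        truncated discretised log-normal length distribution."""
        frag = m.FragmentModel(150, 200, 0.2)
        rng = np.random.default_rng(7)
        n = 10_000
        frs = [m.simulate_fragment(assay, frag, rng) for _ in range(n)]
        mc = sum(f.amplifiable for f in frs) / n
        # oracle: integrate P(length) * P(start covers insert | length)
        mu, sigma = frag.log_mu, frag.dispersion
        insert, mx = assay.insert_length, frag.max_length
        ext = insert + 2 * mx
        lengths = np.arange(1, mx + 1)
        cdf = stats.lognorm.cdf
        pmf = cdf(lengths + 0.5, sigma, scale=np.exp(mu)) - cdf(
            lengths - 0.5, sigma, scale=np.exp(mu)
        )
        pmf /= pmf.sum()
        n_starts = ext - lengths + 1
        n_cover = np.clip(lengths - insert + 1, 0, None)
        expected = float((pmf * n_cover / n_starts).sum())
        assert 0.0 < mc < 1.0
        assert abs(mc - expected) < binom_3sd(expected, n)

    def test_length_mode_near_mode_length(self):
        frag = m.FragmentModel(150, 200, 0.2)
        lengths = _draw_fragment_lengths(frag, 100_000, np.random.default_rng(0))
        counts = np.bincount(lengths)
        assert abs(int(np.argmax(counts)) - frag.mode_length) <= 5

    def test_invalid_models_rejected(self):
        with pytest.raises(ValidationError):
            m.FragmentModel(mode_length=300, max_length=200)
        with pytest.raises(ValidationError):
            m.ChemistryModel(conversion_efficiency=1.5)


class TestBisulfiteConvertMolecule:
    def test_full_conversion_all_unmethylated(self, rng):
        chem = m.ChemistryModel(1.0, 0.0, 0.0)
        states = {1: False, 3: False}
        assert m.bisulfite_convert_molecule("ACGCA", states, chem, rng) == "ATGTA"

    def test_zero_efficiency_leaves_sequence(self, rng):
        chem = m.ChemistryModel(0.0, 0.0, 0.0)
        states = {1: False, 3: False}
        assert m.bisulfite_convert_molecule("ACGCA", states, chem, rng) == "ACGCA"

    def test_methylated_c_protected(self, rng):
        chem = m.ChemistryModel(1.0, 0.0, 0.0)
        assert m.bisulfite_convert_molecule("ACGA", {1: True}, chem, rng) == "ACGA"

    def test_missing_position_names_it(self, rng):
        with pytest.raises(DataError, match="position 3"):
            m.bisulfite_convert_molecule("ACGCA", {1: False}, m.ChemistryModel(), rng)

    def test_conversion_rate_matches_binomial(self, rng):
        """At e=0.99, the converted fraction of 10,000 unmethylated Cs stays
        within 3 exact-binomial SDs of 0.99."""
        chem = m.ChemistryModel(0.99, 0.0, 0.0)
        n = 10_000
        seq = "CA" * n
        states = {i: False for i in range(0, 2 * n, 2)}
        out = m.bisulfite_convert_molecule(seq, states, chem, rng)
        converted = sum(1 for i in range(0, 2 * n, 2) if out[i] == "T")
        assert abs(converted / n - 0.99) < binom_3sd(0.99, n)


class TestSimulateReads:
    def test_counts_and_determinism(self, assay, tmp_path):
        mix = m.MixtureSpec(((m.TISSUE_PROFILES["cardiomyocyte"], 1.0),), 10, seed=5)
        out = {}
        for run in ("a", "b"):
            r1 = tmp_path / f"{run}_R1.fastq.gz"
            r2 = tmp_path / f"{run}_R2.fastq.gz"
            m.simulate_reads(mix, assay, out_r1=r1, out_r2=r2)
            import gzip

            out[run] = (gzip.open(r1, "rb").read(), gzip.open(r2, "rb").read())
        assert out["a"] == out["b"]
        n_records = out["a"][0].count(b"@mol")
        assert n_records == 10
        assert out["a"][1].count(b"@mol") == 10

    def test_noiseless_unmethylated_reads_all_t_at_cpgs(self, assay, conv_ref,
                                                        noiseless_chem):
        mix = m.MixtureSpec(((m.TissueProfile.from_u("u1", 1.0), 1.0),), 200, seed=3)
        s = m.simulate_reads(mix, assay, noiseless_chem)
        for r1 in s.r1:
            assert all(r1[off] == "T" for off in conv_ref.cpg_offsets)

    def test_r2_is_reverse_complement_of_template_end(self, assay, noiseless_chem):
        mix = m.MixtureSpec(((m.TissueProfile.from_u("m1", 0.0), 1.0),), 5, seed=3)
        s = m.simulate_reads(mix, assay, noiseless_chem)
        from methylamp.assay import reverse_complement

        for r1, r2 in zip(s.r1, s.r2):
            assert reverse_complement(r2) == r1  # full-overlap amplicon

    def test_truth_table_conservation(self, assay):
        mix = m.MixtureSpec(((m.TISSUE_PROFILES["ventricle"], 1.0),), 500, seed=11)
        s = m.simulate_reads(mix, assay)
        assert len(s.truth) == 500
        assert s.truth.molecule_id.is_unique
        assert set(s.truth.molecule_id) == set(s.ids)

    def test_mixture_truth_proportion(self, assay):
        """50/50 mix of pure-U and pure-M tissues: truth-table fully-unmeth
        proportion within 3 binomial SDs of 0.5 over 20,000 pairs."""
        mix = m.MixtureSpec(
            (
                (m.TissueProfile.from_u("u1", 1.0), 0.5),
                (m.TissueProfile.from_u("m1", 0.0), 0.5),
            ),
            20_000,
            seed=21,
        )
        s = m.simulate_reads(mix, assay)
        prop = s.truth.fully_unmethylated.mean()
        assert abs(prop - 0.5) < binom_3sd(0.5, 20_000)

    def test_unamplifiable_assay_raises(self, assay):
        mix = m.MixtureSpec(((m.TISSUE_PROFILES["cardiomyocyte"], 1.0),), 10, seed=0)
        frag = m.FragmentModel(mode_length=40, max_length=60)
        with pytest.raises(DataError, match="amplify"):
            m.simulate_reads(mix, assay, frag=frag)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            m.MixtureSpec(((m.TISSUE_PROFILES["lung"], 0.7),), 10, seed=0)


class TestCohort:
    def test_default_cohort_shape_and_medians(self):
        spec = m.CohortSpec(seed=9)
        assert len(spec.fractions) == 10
        per_tp = {
            ti: np.median([spec.fractions[p][ti] for p in spec.fractions])
            for ti in range(3)
        }
        for med in per_tp.values():
            assert 0.018 <= med <= 0.020

    def test_generate_cohort_samples_and_manifest(self, assay, tmp_path):
        spec = m.CohortSpec(n_patients=2, depth_range=(30, 50), seed=4)
        manifest = m.generate_cohort(spec, assay, out_dir=tmp_path)
        assert len(manifest) == 6  # 2 patients x 3 timepoints
        assert (tmp_path / "manifest.tsv").exists()
        for row in manifest.itertuples():
            assert (tmp_path / f"{row.sample_id}_R1.fastq.gz").exists()
            assert spec.depth_range[0] <= row.n_read_pairs <= spec.depth_range[1]

    def test_zero_shedding_truth(self, assay):
        spec = m.CohortSpec(
            n_patients=2,
            fractions={"A": (0.0, 0.0, 0.0), "B": (0.0, 0.0, 0.0)},
            depth_range=(20, 30),
            seed=1,
        )
        manifest = m.generate_cohort(spec, assay)
        assert (manifest.true_fraction == 0).all()

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValidationError):
            m.CohortSpec(n_patients=1, fractions={"A": (1.5, 0, 0)}, seed=0)
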