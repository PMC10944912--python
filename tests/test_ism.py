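import numpy as np
import pytest

from seqexpress.annotation import SequenceWindow
from seqexpress.encoding import one_hot
from seqexpress.ism import (
    AlleleMismatchError,
    ISMProfile,
    OutOfWindowError,
    VariantRecord,
    hvg_mean_max_profile,
    max_effect_profile,
    profile_to_frame,
    read_variants,
    saturation_mutagenesis,
    sign_consistent_difference,
    variant_effect,
    window_offset,
)
from seqexpress.model import predict


@pytest.fixture(scope="module")
def gene_context(small_sim, small_ensemble):
    _, res = small_sim
    ens, hln = small_ensemble
    gid = res.gene_ids[0]
    window = res.windows[gid]
    hl = hln.loc[gid].to_numpy()
    return ens, window, hl


@pytest.fixture(scope="module")
def profile(gene_context):
    ens, window, hl = gene_context
    return saturation_mutagenesis(ens, window, hl)


class TestSaturationMutagenesis:
    def test_three_alternatives_per_unambiguous_position(self, profile):
        length = profile.length
        assert profile.effects.shape == (length, 3, 3)
        assert all(len(a) == 3 for a in profile.alts)
        for i, ref in enumerate(profile.ref_seq):
            assert ref not in profile.alts[i]
        assert not np.isnan(profile.effects).any()

    def test_zeroed_convolutions_give_zero_effects(self, gene_context):
        """If the sequence pathway is severed (all conv weights zero), no
        substitution can change the prediction."""
        import copy

        ens, window, hl = gene_context
        dead = copy.deepcopy(ens)
        for net in dead.networks:
            for layer in net.conv_layers:
                for p in layer.params:
                    p[...] = 0.0
        prof = saturation_mutagenesis(dead, window, hl)
        np.testing.assert_allclose(prof.effects, 0.0, atol=1e-5)

    def test_ambiguous_reference_position_flagged_missing(self, gene_context):
        ens, window, hl = gene_context
        seq = list(window.seq)
        seq[5] = "N"
        win_n = SequenceWindow(
            gene_id=window.gene_id, chrom=window.chrom, strand=window.strand,
            tss=window.tss, up_len=window.up_len, down_len=window.down_len,
            seq="".join(seq),
        )
        prof = saturation_mutagenesis(ens, win_n, hl)
        assert prof.alts[5] == ()
        assert np.isnan(prof.effects[5]).all()
        assert not np.isnan(prof.effects[6]).any()

    def test_effects_are_on_unstandardized_scale(self, gene_context, profile):
        """Recompute one mutant by hand through the ensemble."""
        ens, window, hl = gene_context
        wt = one_hot(window.seq).values[None]
        wt_pred = predict(ens, wt, hl[None], unstandardized=True)[0]
        i, j = 17, 1
        alt = profile.alts[i][j]
        x = wt.copy()
        x[0, :, i] = 0.0
        x[0, "ACGT".index(alt), i] = 1.0
        mut_pred = predict(ens, x, hl[None], unstandardized=True)[0]
        np.testing.assert_allclose(
            profile.effects[i, j], mut_pred - wt_pred, atol=1e-5
        )

    def test_mutating_back_restores_wildtype(self, gene_context):
        """Applying a substitution and then substituting back to the
        reference base gives the wild-type prediction exactly."""
        ens, window, hl = gene_context
        wt = one_hot(window.seq).values[None]
        wt_pred = predict(ens, wt, hl[None])
        x = wt.copy()
        ref_channel = "ACGT".index(window.seq[10])
        x[0, :, 10] = 0.0
        x[0, (ref_channel + 1) % 4, 10] = 1.0  # mutate
        x[0, :, 10] = 0.0
        x[0, ref_channel, 10] = 1.0  # revert
        np.testing.assert_array_equal(predict(ens, x, hl[None]), wt_pred)


class TestMaxEffectProfile:
    def _profile_from_effects(self, effects):
        length = effects.shape[0]
        return ISMProfile(
            gene_id="g", ref_seq="A" * length, effects=effects,
            alts=[("C", "G", "T")] * length, task_names=["t0"],
            wildtype_prediction=np.zeros(1),
        )

    def test_signed_max_absolute_effect(self):
        eff = np.zeros((2, 3, 1))
        eff[0, :, 0] = [-0.3, 0.1, 0.2]
        prof = self._profile_from_effects(eff)
        out = max_effect_profile(prof, "t0")
        assert out[0] == pytest.approx(-0.3)
        assert out[1] == 0.0

    def test_tie_broken_by_alternative_order(self):
        eff = np.zeros((1, 3, 1))
        eff[0, :, 0] = [0.5, -0.5, 0.5]
        prof = self._profile_from_effects(eff)
        assert max_effect_profile(prof, "t0")[0] == pytest.approx(0.5)  # first alt

    def test_matches_brute_force_scan(self, profile):
        for task in profile.task_names:
            out = max_effect_profile(profile, task)
            t = profile.task_index(task)
            for i in range(0, profile.length, 37):
                row = profile.effects[i, :, t]
                assert out[i] == row[np.argmax(np.abs(row))]


class TestHvgMeanMax:
    def test_single_gene_equals_absolute_max_profile(self, profile):
        task = profile.task_names[0]
        np.testing.assert_allclose(
            hvg_mean_max_profile([profile], task),
            np.abs(max_effect_profile(profile, task)),
            atol=1e-12,
        )

    def test_sign_flipped_profiles_average_to_magnitude(self, profile):
        import copy

        flipped = copy.deepcopy(profile)
        flipped.effects = -flipped.effects
        task = profile.task_names[0]
        np.testing.assert_allclose(
            hvg_mean_max_profile([profile, flipped], task),
            np.abs(max_effect_profile(profile, task)),
            atol=1e-12,
        )

    def test_matches_direct_formula_on_random_toy(self):
        rng = np.random.default_rng(0)
        profiles = []
        for g in range(3):
            eff = rng.normal(size=(10, 3, 2))
            profiles.append(
                ISMProfile(
                    gene_id=f"g{g}", ref_seq="A" * 10, effects=eff,
                    alts=[("C", "G", "T")] * 10, task_names=["a", "b"],
                    wildtype_prediction=np.zeros(2),
                )
            )
        out = hvg_mean_max_profile(profiles, "b")
        expect = np.mean(
            [np.abs(p.effects[:, :, 1]).max(axis=1) for p in profiles], axis=0
        )
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_mixed_lengths_rejected(self, profile):
        short = ISMProfile(
            gene_id="s", ref_seq="AC", effects=np.zeros((2, 3, 3)),
            alts=[("C", "G", "T")] * 2, task_names=profile.task_names,
            wildtype_prediction=np.zeros(3),
        )
        with pytest.raises(ValueError, match="lengths"):
            hvg_mean_max_profile([profile, short], profile.task_names[0])


def test_sign_consistent_difference_masks_disagreements():
    eff = np.zeros((3, 3, 2))
    eff[0, 0] = [0.4, 0.2]     # agree, positive
    eff[1, 0] = [0.3, -0.2]    # disagree -> masked
    eff[2, 0] = [-0.1, -0.3]   # agree, negative
    prof = ISMProfile(
        gene_id="g", ref_seq="AAA", effects=eff,
        alts=[("C", "G", "T")] * 3, task_names=["x", "y"],
        wildtype_prediction=np.zeros(2),
    )
    d = sign_consistent_difference(prof, "x", "y")
    assert d[0] == pytest.approx(0.2)
    assert np.isnan(d[1])
    assert d[2] == pytest.approx(0.2)


class TestVariantEffect:
    def _genomic_pos(self, window, offset):
        if window.strand == "+":
            return window.tss - window.up_len + offset + 1  # back to 1-based
        return window.tss + window.up_len - offset + 1

    def test_matches_saturation_entry_for_random_variants(
        self, small_sim, gene_context, profile
    ):
        """The single-variant path and the full-profile path agree."""
        _, res = small_sim
        ens, window, hl = gene_context
        rng = np.random.default_rng(2)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(50):
            off = int(rng.integers(0, profile.length))
            j = int(rng.integers(0, 3))
            ref_w = window.seq[off]
            alt_w = profile.alts[off][j]
            ref_g = ref_w if window.strand == "+" else comp[ref_w]
            alt_g = alt_w if window.strand == "+" else comp[alt_w]
            var = VariantRecord(
                chrom=window.chrom, pos=self._genomic_pos(window, off),
                ref=ref_g, alt=alt_g, gene_id=window.gene_id, variant_id=f"v{off}",
            )
            (ve,) = variant_effect(ens, window, hl, var, profile=profile)
            assert ve.offset == off
            np.testing.assert_allclose(ve.effects, profile.effects[off, j], atol=1e-6)
            assert ve.percentile is not None
            assert np.all((ve.percentile >= 0) & (ve.percentile <= 100))

    def test_direct_path_agrees_with_profile_path(self, gene_context, profile):
        ens, window, hl = gene_context
        off = 33
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref_w = window.seq[off]
        ref_g = ref_w if window.strand == "+" else comp[ref_w]
        var = VariantRecord(
            chrom=window.chrom, pos=self._genomic_pos(window, off),
            ref=ref_g, alt=None, gene_id=window.gene_id,
        )
        direct = variant_effect(ens, window, hl, var)  # recomputes mutants
        assert len(direct) == 3
        for ve in direct:
            j = profile.alts[off].index(ve.alt)
            np.testing.assert_allclose(ve.effects, profile.effects[off, j], atol=1e-5)

    def test_out_of_window_raises(self, gene_context):
        ens, window, hl = gene_context
        far = window.tss + 10 * (window.up_len + window.down_len)
        var = VariantRecord(chrom=window.chrom, pos=far, ref="A", alt="C",
                            gene_id=window.gene_id)
        with pytest.raises(OutOfWindowError, match="outside the window"):
            variant_effect(ens, window, hl, var)

    def test_reference_mismatch_names_both_alleles(self, gene_context):
        ens, window, hl = gene_context
        off = 10
        wrong = {"A": "C", "C": "G", "G": "T", "T": "A"}[window.seq[off]]
        wrong_g = wrong if window.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[wrong]
        var = VariantRecord(
            chrom=window.chrom, pos=self._genomic_pos(window, off),
            ref=wrong_g, alt=None, gene_id=window.gene_id,
        )
        with pytest.raises(AlleleMismatchError):
            variant_effect(ens, window, hl, var)

    def test_window_offset_arithmetic(self):
        w = SequenceWindow(gene_id="g", chrom="c", strand="+", tss=10000,
                          up_len=7000, down_len=3500, seq="A" * 10500)
        assert window_offset(w, 10001) == 7000  # the TSS base itself
        assert window_offset(w, 3001) == 0
        with pytest.raises(OutOfWindowError):
            window_offset(w, 2000)  # 8 kb upstream of the TSS


def test_read_variants_tsv_and_vcf(tmp_path):
    tsv = tmp_path / "v.tsv"
    tsv.write_text("chrom\tpos\tid\tref\talt\tgene\nchr1\t100\trs1\tA\tC\tg1\nchr1\t200\trs2\tG\t.\tg2\n")
    recs = read_variants(tsv)
    assert recs[0].pos == 100 and recs[0].alt == "C"
    assert recs[1].alt is None
    vcf = tmp_path / "v.vcf"
    vcf.write_text(
        "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t150\trs9\tT\tG\t.\t.\tgene=g3\n"
    )
    (rec,) = read_variants(vcf)
    assert (rec.pos, rec.ref, rec.alt, rec.gene_id) == (150, "T", "G", "g3")


def test_profile_frame_export(profile):
    df = profile_to_frame(profile)
    assert len(df) == profile.length * 3
    assert {"position", "ref", "alt"} <= set(df.columns)
    assert df["ref"].iloc[0] == profile.ref_seq[0]
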