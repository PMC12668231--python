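"""Synthetic-data generator: determinism, truth construction, NB counts."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal
from scipy.special import logit

from sedq import synth


class TestGenerateTranscriptome:
    def test_deterministic_given_seed(self):
        a = synth.generate_transcriptome(50, seed=7)
        b = synth.generate_transcriptome(50, seed=7)
        assert_frame_equal(a, b)
        c = synth.generate_transcriptome(50, seed=8)
        assert not a.equals(c)

    def test_induced_count_is_floor(self):
        ann = synth.generate_transcriptome(1000, frac_induced=0.05, seed=0)
        assert ann["induced"].sum() == 50

    def test_median_length_matches_lognormal(self):
        ann = synth.generate_transcriptome(
            5000, length_logmean=float(np.log(1500)), length_logsd=0.5, seed=1
        )
        assert abs(ann["length_total"].median() - 1500) / 1500 < 0.10

    def test_length_bounds_and_utr_invariant(self):
        ann = synth.generate_transcriptome(3000, length_logsd=1.5, seed=2)
        assert ann["length_total"].between(100, 20000).all()
        assert (ann["length_total"] >= ann["utr5_len"] + ann["utr3_len"] + 3).all()
        assert ann["gene_id"].is_unique

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            synth.generate_transcriptome(0)
        with pytest.raises(ValueError):
            synth.generate_transcriptome(10, frac_induced=1.5)


def one_gene_annotation(length):
    return pd.DataFrame(
        {"gene_id": ["g0"], "length_total": [length], "utr5_len": [10],
         "utr3_len": [10], "regulon": ["none"], "induced": [False]}
    )


class TestSimulateTruePsup:
    def test_halfway_point(self):
        # beta*L^x = 1e-3 * 500 = 0.5 sedimented
        truth = synth.simulate_true_psup(
            one_gene_annotation(500), beta=1e-3, x=1.0, sigma_g=0.0, seed=0
        )
        assert truth.table["true_psup"].iloc[0] == pytest.approx(0.5)

    def test_stress_multiplier(self):
        truth = synth.simulate_true_psup(
            one_gene_annotation(500), beta=1e-3, x=1.0, mu=float(np.log(1.5)),
            nu=0.0, sigma_g=0.0, seed=0,
        )
        assert truth.table["true_psup"].iloc[0] == pytest.approx(0.25)

    def test_logit_jitter_sd(self, annotation_2k):
        ann = synth.generate_transcriptome(5000, seed=3)
        truth = synth.simulate_true_psup(ann, sigma_g=0.3, seed=4)
        clean = synth.simulate_true_psup(ann, sigma_g=0.0, seed=4)
        resid = logit(truth.table["true_psup"]) - logit(clean.table["true_psup"])
        assert np.std(resid) == pytest.approx(0.3, abs=0.02)

    def test_psup_clipped_and_monotone(self):
        ann = synth.generate_transcriptome(2000, length_logsd=1.0, seed=5)
        truth = synth.simulate_true_psup(ann, beta=5e-4, x=1.2, sigma_g=0.0, seed=6)
        p = truth.table["true_psup"]
        assert p.between(0.001, 0.999).all()
        ordered = truth.table.assign(L=ann["length_total"]).sort_values("L")
        assert (np.diff(ordered["true_psup"]) <= 1e-12).all()

    def test_escape_offset_applies_to_induced_only(self):
        ann = synth.generate_transcriptome(500, frac_induced=0.1, seed=7)
        base = synth.simulate_true_psup(ann, sigma_g=0.0, seed=8)
        esc = synth.simulate_true_psup(ann, sigma_g=0.0, delta_e=1.0, seed=8)
        dlop = logit(esc.table["true_psup"]) - logit(base.table["true_psup"])
        assert np.allclose(dlop[ann["induced"].to_numpy()], 1.0, atol=1e-9)
        assert np.allclose(dlop[~ann["induced"].to_numpy()], 0.0, atol=1e-9)

    def test_overcondensed_warns(self):
        ann = synth.generate_transcriptome(200, seed=9)
        with pytest.warns(UserWarning, match="exceeds 1"):
            synth.simulate_true_psup(ann, beta=1e-2, x=1.5, sigma_g=0.0, seed=0)


class TestSimulateSedseqCounts:
    def test_conservation_in_expectation(self, annotation_2k, study_2k):
        counts = study_2k["counts"]
        one = counts[(counts["condition"] == "control") & (counts["replicate"] == 1)]
        wide = one.pivot_table(index="gene_id", columns="fraction", values="counts")
        a_s, a_p = counts.attrs.get("a_S", 1.5), counts.attrs.get("a_P", 3.0)
        resid = wide["Total"] - a_s * wide["Sup"] - a_p * wide["Pellet"]
        assert abs(resid.mean()) / wide["Total"].mean() < 0.02

    def test_symmetric_split(self):
        ann = synth.generate_transcriptome(5000, seed=10)
        truth = synth.simulate_true_psup(ann, sigma_g=0.0, seed=11)
        truth.table["true_psup"] = 0.5
        truth.phi = 5000.0
        counts = synth.simulate_sedseq_counts(truth, ann, mean_total_count=800, seed=12)
        wide = counts.pivot_table(index="gene_id", columns="fraction", values="counts")
        assert wide["Sup"].mean() == pytest.approx(wide["Total"].mean() / 2, rel=0.02)
        assert wide["Pellet"].mean() == pytest.approx(wide["Total"].mean() / 2, rel=0.02)

    def test_bitwise_determinism(self, annotation_2k):
        truth = synth.simulate_true_psup(annotation_2k, seed=13)
        a = synth.simulate_sedseq_counts(truth, annotation_2k, seed=14)
        b = synth.simulate_sedseq_counts(truth, annotation_2k, seed=14)
        assert_frame_equal(a, b)
        c = synth.simulate_sedseq_counts(truth, annotation_2k, seed=15)
        assert not a.equals(c)

    def test_phi_must_be_positive(self, annotation_2k):
        truth = synth.simulate_true_psup(annotation_2k, seed=16)
        truth.phi = 0.0
        with pytest.raises(ValueError, match="phi"):
            synth.simulate_sedseq_counts(truth, annotation_2k, seed=0)


class TestSimulatePolysomeTpm:
    def test_full_occupancy_empties_free_fraction(self):
        ann = synth.generate_transcriptome(300, seed=17)
        tpm = synth.simulate_polysome_tpm(ann, np.ones(300), seed=18)
        free = tpm[(tpm["fraction"] == "Free") & ~tpm["is_spike"]]
        assert (free["est_counts"] == 0).all()

    def test_determinism_and_spike_rows(self):
        ann = synth.generate_transcriptome(200, seed=19)
        occ = np.full(200, 0.6)
        a = synth.simulate_polysome_tpm(ann, occ, n_spikes=10, seed=20)
        b = synth.simulate_polysome_tpm(ann, occ, n_spikes=10, seed=20)
        assert_frame_equal(a, b)
        assert a[a["is_spike"]].groupby("fraction").size().eq(10).all()

    def test_zero_spikes_rejected(self):
        ann = synth.generate_transcriptome(10, seed=21)
        with pytest.raises(ValueError, match="n_spikes"):
            synth.simulate_polysome_tpm(ann, np.full(10, 0.5), n_spikes=0)


class TestSimulateStudy:
    def test_gene_offsets_shared_between_conditions(self, annotation_2k):
        study = synth.simulate_study(
            annotation_2k, mu=0.0, nu=0.0, delta_e=0.0, seed=22
        )
        lc = logit(study["truth_control"].table["true_psup"])
        ls = logit(study["truth_stress"].table["true_psup"])
        assert np.allclose(lc, ls, atol=1e-9)

    def test_counts_cover_both_conditions(self, study_2k):
        counts = study_2k["counts"]
        assert set(counts["condition"]) == {"control", "stress"}
        assert counts.groupby(["condition", "replicate"]).size().nunique() == 1
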