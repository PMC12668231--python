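"""Length-controlled condensation scores: dSed, eSed, rSed."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from sedq import scores, synth


def psup_table(ann, lop, condition="c", replicate=None):
    tab = pd.DataFrame(
        {"gene_id": ann["gene_id"].to_numpy(), "psup": expit(lop), "lopsup": lop,
         "condition": condition}
    )
    if replicate is not None:
        tab["replicate"] = replicate
    return tab


def spaced_annotation(n, lo=6.0, hi=8.0, seed=None):
    if seed is None:
        ll = np.linspace(lo, hi, n)
    else:
        ll = np.random.default_rng(seed).uniform(lo, hi, n)
    return pd.DataFrame(
        {"gene_id": [f"g{i:04d}" for i in range(n)],
         "length_total": np.exp(ll).round().astype(int),
         "utr5_len": 10, "utr3_len": 10}
    )


class TestLogOdds:
    def test_values_and_roundtrip(self):
        assert scores.log_odds(0.5) == 0.0
        assert scores.log_odds(0.9756) == pytest.approx(np.log(0.9756 / 0.0244))
        p = np.linspace(0.01, 0.99, 23)
        assert np.allclose(scores.inverse_log_odds(scores.log_odds(p)), p, atol=1e-12)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            scores.log_odds(1.2)


class TestWindowedLengthStats:
    def test_constant_field(self):
        ann = spaced_annotation(20)
        prof = scores.windowed_length_stats(psup_table(ann, np.full(20, 1.3)), ann)
        assert np.allclose(prof.table["mu"], 1.3)
        assert prof.sigma_global == pytest.approx(0.0, abs=1e-12)

    def test_three_point_moving_average(self):
        # 5 equally log-spaced genes; window spans exactly the +-1 neighbors
        ann = spaced_annotation(5, 6.0, 7.0)
        lop = np.array([0.1, 0.5, -0.2, 0.8, 0.3])
        prof = scores.windowed_length_stats(
            psup_table(ann, lop), ann, window_fraction=0.55
        )
        ll = np.log(ann["length_total"].to_numpy(float))
        w = 0.55 * (ll.max() - ll.min())
        expected = [
            lop[(ll >= ll[i] - w / 2) & (ll <= ll[i] + w / 2)].mean() for i in range(5)
        ]
        assert np.allclose(prof.table["mu"], expected)

    def test_brute_force_window_oracle(self):
        ann = spaced_annotation(200, seed=5)
        rng = np.random.default_rng(6)
        lop = rng.normal(1.0, 0.5, 200)
        prof = scores.windowed_length_stats(psup_table(ann, lop), ann)
        tab = prof.table.set_index("gene_id")
        ll = np.log(ann["length_total"].to_numpy(float))
        w = 0.02 * (ll.max() - ll.min())
        for i in rng.choice(200, 25, replace=False):
            sel = (ll >= ll[i] - w / 2) & (ll <= ll[i] + w / 2)
            gid = ann["gene_id"].iloc[i]
            assert tab.loc[gid, "mu"] == pytest.approx(lop[sel].mean())
            if sel.sum() > 1:
                assert tab.loc[gid, "sigma"] == pytest.approx(lop[sel].std(ddof=1))

    def test_wider_window_never_more_undefined(self):
        ann = spaced_annotation(60, seed=7)
        lop = np.zeros(60)
        with pytest.warns(UserWarning):
            narrow = scores.windowed_length_stats(
                psup_table(ann, lop), ann, window_fraction=0.001
            )
        wide = scores.windowed_length_stats(
            psup_table(ann, lop), ann, window_fraction=0.5
        )
        assert wide.n_undefined_sigma <= narrow.n_undefined_sigma


class TestDeltaSed:
    def test_control_vs_itself_is_exactly_zero(self):
        ann = spaced_annotation(100, seed=8)
        lop = np.random.default_rng(9).normal(1, 0.5, 100)
        tab = psup_table(ann, lop)
        prof = scores.windowed_length_stats(tab, ann)
        ds = scores.delta_sed(tab, tab, prof)
        assert (ds["delta_sed"] == 0.0).all()

    def test_arithmetic(self):
        ann = spaced_annotation(10)
        c = psup_table(ann, np.full(10, 1.0))
        t = psup_table(ann, np.full(10, -1.0))
        prof = scores.LengthProfile(
            table=pd.DataFrame(), sigma_global=0.5, window_fraction=0.02
        )
        ds = scores.delta_sed(c, t, prof)
        assert np.allclose(ds["delta_sed"], 4.0)

    def test_degenerate_control_rejected(self):
        ann = spaced_annotation(10)
        tab = psup_table(ann, np.zeros(10))
        prof = scores.windowed_length_stats(tab, ann)
        with pytest.raises(ValueError, match="degenerate"):
            scores.delta_sed(tab, tab, prof)

    def test_stress_simulation_gives_positive_median(self, annotation_2k, study_2k):
        from sedq import quant

        counts = study_2k["counts"]
        frames = []
        for _, grp in counts.groupby(["condition", "replicate"]):
            fit = quant.estimate_mixing_ratios(grp)
            frames.append(quant.compute_psup(grp, fit))
        psup = pd.concat(frames)
        pc = psup[psup["condition"] == "control"]
        pt = psup[psup["condition"] == "stress"]
        prof = scores.windowed_length_stats(pc, annotation_2k)
        ds = scores.delta_sed(pc, pt, prof)
        assert ds["delta_sed"].median() > 0


class TestEscapeSed:
    def test_cohort_shift_cancels(self):
        ann = spaced_annotation(50, seed=10)
        rng = np.random.default_rng(11)
        lop_c = rng.normal(1, 0.4, 50)
        # every gene shifts by the same amount: residual change is zero
        c = psup_table(ann, lop_c)
        t = psup_table(ann, lop_c - 1.7)
        prof_c = scores.windowed_length_stats(c, ann)
        prof_t = scores.windowed_length_stats(t, ann)
        es = scores.escape_sed(c, t, prof_c, prof_t)
        assert np.allclose(es["e_sed"], 0.0, atol=1e-12)

    def test_constant_treatment_shift_leaves_esed_changes_dsed(self):
        ann = spaced_annotation(80, seed=12)
        rng = np.random.default_rng(13)
        lop_c = rng.normal(0.8, 0.5, 80)
        lop_t = rng.normal(0.1, 0.5, 80)
        c = psup_table(ann, lop_c)
        t = psup_table(ann, lop_t)
        prof_c = scores.windowed_length_stats(c, ann)
        prof_t = scores.windowed_length_stats(t, ann)
        es0 = scores.escape_sed(c, t, prof_c, prof_t)
        ds0 = scores.delta_sed(c, t, prof_c)
        const = 0.9
        t2 = psup_table(ann, lop_t + const)
        prof_t2 = scores.windowed_length_stats(t2, ann)
        es1 = scores.escape_sed(c, t2, prof_c, prof_t2)
        ds1 = scores.delta_sed(c, t2, prof_c)
        assert np.allclose(es1["e_sed"], es0["e_sed"], atol=1e-9)
        assert np.allclose(
            ds1["delta_sed"], ds0["delta_sed"] - const / prof_c.sigma_global, atol=1e-9
        )

    def test_antisymmetry_of_delta_sed(self):
        ann = spaced_annotation(40, seed=14)
        rng = np.random.default_rng(15)
        c = psup_table(ann, rng.normal(1, 0.3, 40))
        t = psup_table(ann, rng.normal(0, 0.3, 40))
        prof_c = scores.windowed_length_stats(c, ann)
        fwd = scores.delta_sed(c, t, prof_c)
        rev = scores.delta_sed(t, c, prof_c)
        assert np.allclose(fwd["delta_sed"], -rev["delta_sed"], atol=1e-12)

    def test_mismatched_windows_rejected(self):
        ann = spaced_annotation(30, seed=16)
        tab = psup_table(ann, np.random.default_rng(17).normal(size=30))
        p1 = scores.windowed_length_stats(tab, ann, 0.02)
        p2 = scores.windowed_length_stats(tab, ann, 0.05)
        with pytest.raises(ValueError, match="window"):
            scores.escape_sed(tab, tab, p1, p2)


class TestSedScore:
    def test_matches_brute_force_oracle(self):
        ann = spaced_annotation(250, seed=18)
        rng = np.random.default_rng(19)
        lop = rng.normal(0.5, 0.7, 250)
        out = scores.sed_score(psup_table(ann, lop), ann, bin_size=100).set_index("gene_id")

        order = ann.assign(lop=lop).sort_values(
            ["length_total", "gene_id"], kind="stable"
        )
        # bins: 100, 100, 50 -> last merged into second (100, 150)
        bins = [order.iloc[:100], order.iloc[100:]]
        for chunk in bins:
            z = -(chunk["lop"] - chunk["lop"].mean()) / chunk["lop"].std(ddof=1)
            for gid, zi in zip(chunk["gene_id"], z):
                assert out.loc[gid, "r_sed"] == pytest.approx(zi)

    def test_bin_mean_zero_sd_one(self):
        ann = spaced_annotation(300, seed=20)
        lop = np.random.default_rng(21).normal(0, 1, 300)
        out = scores.sed_score(psup_table(ann, lop), ann, bin_size=100)
        merged = out.merge(ann, on="gene_id").sort_values(
            ["length_total", "gene_id"], kind="stable"
        )
        for b in range(3):
            chunk = merged["r_sed"].iloc[b * 100 : (b + 1) * 100]
            assert chunk.mean() == pytest.approx(0.0, abs=1e-9)
            assert chunk.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_replicates_averaged(self):
        ann = spaced_annotation(120, seed=22)
        rng = np.random.default_rng(23)
        r1 = psup_table(ann, rng.normal(0, 1, 120), replicate=1)
        r2 = psup_table(ann, rng.normal(0, 1, 120), replicate=2)
        both = scores.sed_score(pd.concat([r1, r2]), ann, bin_size=60)
        z1 = scores.sed_score(r1, ann, bin_size=60).set_index("gene_id")["r_sed"]
        z2 = scores.sed_score(r2, ann, bin_size=60).set_index("gene_id")["r_sed"]
        expected = (z1 + z2) / 2
        got = both.set_index("gene_id")["r_sed"]
        assert np.allclose(got[expected.index], expected, atol=1e-12)

    def test_too_few_genes(self):
        ann = spaced_annotation(30, seed=24)
        with pytest.raises(ValueError, match="bin_size"):
            scores.sed_score(psup_table(ann, np.zeros(30)), ann, bin_size=100)


class TestLengthControlProperty:
    def test_length_only_signal_gives_zero_scores(self):
        """lopSup that is a (bin-wise constant, monotone) function of length
        alone produces eSed = 0 and rSed = 0: the scores isolate deviations
        from the length trend."""
        ann = spaced_annotation(500, seed=25)
        order = np.argsort(ann["length_total"].to_numpy(), kind="stable")
        lop = np.empty(500)
        # monotone decreasing, constant within each 100-gene length bin
        for b in range(5):
            lop[order[b * 100 : (b + 1) * 100]] = 2.0 - 0.5 * b
        tab = psup_table(ann, lop)
        with pytest.warns(UserWarning, match="zero"):
            rs = scores.sed_score(tab, ann, bin_size=100)
        assert np.abs(rs["r_sed"]).max() < 1e-9
        prof = scores.windowed_length_stats(tab, ann)
        es = scores.escape_sed(tab, tab, prof, prof)
        assert np.abs(es["e_sed"]).max() < 1e-9
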