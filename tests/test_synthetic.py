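"""Generator contracts: determinism, planted truth, and emulated effects."""

import numpy as np
import pandas as pd
import pytest

from voctrace import gcms, synthetic
from voctrace.synthetic import SyntheticConfig, default_grid

COARSE = default_grid(16.0)


def small_cfg(**kw):
    kw.setdefault("n_per_class", 6)
    kw.setdefault("wavenumber_grid", COARSE)
    return SyntheticConfig(**kw)


class TestVocTable:
    def test_zero_cv_gives_exact_class_means(self):
        cfg = small_cfg(conc_cv=0.0)
        voc = synthetic.make_voc_table(cfg)
        lib = synthetic.compound_library(cfg).set_index("compound_id")
        for origin, grp in voc.data.groupby("origin"):
            means = grp.groupby("compound_id")["true_conc"].mean()
            expected = lib[f"mean_{origin}"]
            assert np.allclose(means, expected.loc[means.index])

    def test_same_seed_is_byte_identical(self):
        a = synthetic.make_voc_table(small_cfg(seed=7)).data
        b = synthetic.make_voc_table(small_cfg(seed=7)).data
        pd.testing.assert_frame_equal(a, b)
        c = synthetic.make_voc_table(small_cfg(seed=8)).data
        assert not np.allclose(a["true_conc"], c["true_conc"])

    def test_marker_group_means_match_planted_values(self):
        """At n=50/class the generated group means sit within 3 SE of the
        planted per-class means (0.47 / 0.22 / 0.37 ug/g for marker M01)."""
        cfg = small_cfg(n_per_class=50, seed=3)
        voc = synthetic.make_voc_table(cfg)
        sub = voc.data[voc.data["compound_id"] == "M01"]
        for origin, planted in zip(synthetic.CLASS_LABELS, (0.47, 0.22, 0.37)):
            vals = sub.loc[sub["origin"] == origin, "true_conc"]
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - planted) < 3 * se

    def test_marker_class_ordering(self):
        voc = synthetic.make_voc_table(small_cfg(conc_cv=0.0))
        m = voc.data[voc.data["compound_id"] == "M01"].groupby("origin")["true_conc"].mean()
        assert m["origin_A"] > m["origin_C"] > m["origin_B"]

    def test_nonpositive_means_rejected(self):
        ids = [f"M{i + 1:02d}" for i in range(8)]
        bad = pd.DataFrame(-1.0, index=ids, columns=list(synthetic.CLASS_LABELS))
        with pytest.raises(ValueError, match="> 0"):
            synthetic.make_voc_table(small_cfg(conc_means=bad))

    def test_quantification_roundtrip_recovers_truth(self):
        cfg = small_cfg(seed=5)
        voc = synthetic.make_voc_table(cfg)
        istd = gcms.InternalStandard(
            v_s=cfg.istd_volume_ul,
            c_s=cfg.istd_conc_ug_ml,
            mass_g=cfg.sample_mass_g,
            i_s=cfg.istd_area,
        )
        out = gcms.quantify(voc, istd)
        assert np.allclose(out.data["conc"], out.data["true_conc"], rtol=1e-12)

    def test_planted_markers_are_anova_detectable(self):
        """Welch ANOVA flags every planted marker at p <= 0.05 in >= 95 % of
        seed x marker draws (cv = 0.1, n = 30/class)."""
        hits = total = 0
        for seed in range(20):
            cfg = small_cfg(n_per_class=30, conc_cv=0.1, seed=seed)
            voc = synthetic.make_voc_table(cfg)
            for cid in [f"M{i + 1:02d}" for i in range(8)]:
                grp = voc.data[voc.data["compound_id"] == cid]
                groups = [
                    grp.loc[grp["origin"] == c, "true_conc"].to_numpy()
                    for c in synthetic.CLASS_LABELS
                ]
                hits += gcms.welch_anova_p(groups) <= 0.05
                total += 1
        assert hits / total >= 0.95


class TestSpectra:
    def test_noiseless_spectra_are_linear_in_concentrations(self):
        cfg = small_cfg(noise_sd=0.0, scatter_sd=0.0, baseline_sd=0.0, baseline_degree=0)
        voc = synthetic.make_voc_table(cfg)
        sp = synthetic.make_spectra(cfg, voc)
        conc = voc.pivot("true_conc").to_numpy()
        scans = sp.absorbance[:: cfg.n_replicates]  # one per sample
        coef, res, *_ = np.linalg.lstsq(conc, scans, rcond=None)
        assert np.abs(conc @ coef - scans).max() < 1e-10

    def test_doubling_concentrations_doubles_spectrum(self):
        cfg = small_cfg(noise_sd=0.0, scatter_sd=0.0, baseline_sd=0.0)
        voc = synthetic.make_voc_table(cfg)
        voc2 = voc.data.copy()
        sid = voc.samples[0]
        voc2.loc[voc2["sample_id"] == sid, "true_conc"] *= 2
        from voctrace.containers import VocTable

        sp1 = synthetic.make_spectra(cfg, voc)
        sp2 = synthetic.make_spectra(cfg, VocTable(voc2))
        s1 = sp1.scans_of(sid)[0] - synthetic_baseline(cfg, voc, sid)
        s2 = sp2.scans_of(sid)[0] - synthetic_baseline(cfg, voc, sid)
        assert np.allclose(s2, 2 * s1, atol=1e-12)

    def test_class_mean_difference_peaks_at_marker_bands(self):
        """With explicit single-band profiles, the two most different class
        mean spectra differ most at the marker band centers."""
        wn = COARSE
        rows = []
        for i in range(8):
            rows.append({"compound_id": f"M{i + 1:02d}", "center": 600 + 400 * i, "width": 30.0, "amplitude": 0.2})
        for i in range(8, 12):
            rows.append({"compound_id": f"C{i + 1:02d}", "center": 800 + 400 * (i - 8), "width": 30.0, "amplitude": 0.2})
        bands = pd.DataFrame(rows)
        cfg = small_cfg(
            n_compounds=12,
            conc_cv=0.0,
            noise_sd=0.0,
            scatter_sd=0.0,
            baseline_sd=0.0,
            band_library=bands,
        )
        voc = synthetic.make_voc_table(cfg)
        sp = synthetic.make_spectra(cfg, voc)
        labels = sp.labels()
        mean_a = sp.absorbance[labels == "origin_A"].mean(axis=0)
        mean_b = sp.absorbance[labels == "origin_B"].mean(axis=0)
        diff = np.abs(mean_a - mean_b)
        marker_centers = bands[bands["compound_id"].str.startswith("M")]["center"]
        marker_idx = {int(np.argmin(np.abs(wn - c))) for c in marker_centers}
        top = set(np.argsort(-diff)[: len(marker_idx)].tolist())
        # every top-difference channel sits within one grid step of a marker band
        assert all(any(abs(t - m) <= 1 for m in marker_idx) for t in top)

    def test_replicates_differ_only_in_noise(self):
        cfg = small_cfg(noise_sd=0.0)
        voc = synthetic.make_voc_table(cfg)
        sp = synthetic.make_spectra(cfg, voc)
        for sid in sp.samples:
            scans = sp.scans_of(sid)
            assert np.allclose(scans, scans[0])

    def test_grid_mismatch_rejected(self):
        cfg = small_cfg()
        voc = synthetic.make_voc_table(cfg)
        other = small_cfg(n_compounds=10)
        with pytest.raises(ValueError, match="compound set|true_conc"):
            synthetic.make_spectra(other, voc)

    def test_seed_determinism(self):
        cfg = small_cfg(seed=11)
        voc = synthetic.make_voc_table(cfg)
        a = synthetic.make_spectra(cfg, voc).absorbance
        b = synthetic.make_spectra(cfg, voc).absorbance
        assert np.array_equal(a, b)


def synthetic_baseline(cfg, voc, sid):
    """Reconstruct a sample's baseline via a zero-concentration probe table."""
    from voctrace.containers import VocTable

    zero = voc.data.copy()
    zero["true_conc"] = 1e-300  # numerically zero mixture, same RNG stream
    sp0 = synthetic.make_spectra(cfg, VocTable(zero))
    return sp0.scans_of(sid)[0]
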