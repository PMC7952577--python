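import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import erf

from sortbind import (ReadCountTensor, basal_expression_filter, demux_fastq,
                      filter_read_support, fit_bin_gaussian, normalize_reads,
                      rescale_dose_response)
from sortbind.quantify import cumulate, renormalize_level

EDGES = np.geomspace(100, 10000, 8)


def _tensor(counts, cells=None, edges=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    cells = np.full((6, 8), 0.1) if cells is None else cells
    edges = np.tile(EDGES, (6, 1)) if edges is None else edges
    return ReadCountTensor([f"v{i}" for i in range(n)], counts, cells, edges)


class TestNormalizeReads:
    def test_direct_product(self):
        counts = np.zeros((1, 6, 8), dtype=int)
        counts[0, 0, 0] = 10
        cells = np.zeros((6, 8))
        cells[0, 0] = 0.5
        assert normalize_reads(_tensor(counts, cells))[0, 0, 0] == 5.0

    def test_zero_cell_fraction_kills_reads(self):
        counts = np.full((1, 6, 8), 99)
        cells = np.zeros((6, 8))
        assert (normalize_reads(_tensor(counts, cells)) == 0).all()

    def test_matches_naive_elementwise_loop(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=(4, 6, 8))
        cells = rng.random((6, 8))
        t = _tensor(counts, cells)
        fast = normalize_reads(t)
        for i in range(4):
            for j in range(6):
                for k in range(8):
                    assert fast[i, j, k] == counts[i, j, k] * cells[j, k]

    def test_missing_cell_fraction_rejected(self):
        cells = np.full((6, 8), np.nan)
        with pytest.raises(ValueError):
            normalize_reads(_tensor(np.ones((1, 6, 8), dtype=int), cells))


class TestReadSupportFilter:
    def test_bin_at_exactly_30_reads_drops_the_level(self):
        counts = np.full((1, 6, 8), 1000)
        counts[0, 2, 5] = 30            # "above 30" is strict
        _, level_keep = filter_read_support(_tensor(counts))
        assert not level_keep[0, 2]
        assert level_keep[0, 0]

    def test_total_301_reads_retains_the_variant(self):
        counts = np.zeros((2, 6, 8), dtype=int)
        counts[0, 0, 0] = 301
        counts[1, 0, 0] = 300           # "more than 300" is strict
        variant_keep, _ = filter_read_support(_tensor(counts))
        assert variant_keep[0] and not variant_keep[1]

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 60, size=(5, 6, 8))
        vk, lk = filter_read_support(_tensor(counts))
        for i in range(5):
            assert vk[i] == (counts[i].sum() > 300)
            for j in range(6):
                assert lk[i, j] == all(counts[i, j, k] > 30 for k in range(8))


class TestCumulativeGaussianFit:
    def test_recovers_exact_gaussian_parameters(self):
        mu, sigma = 1000.0, 200.0
        cdf = 0.5 + 0.5 * erf((EDGES - mu) / (sigma * np.sqrt(2)))
        masses = np.diff(np.concatenate([[0.0], cdf]))
        fit_mu, fit_sigma, r2 = fit_bin_gaussian(masses, EDGES)
        assert fit_mu == pytest.approx(mu, rel=0.01)
        assert r2 > 0.99

    def test_single_occupied_bin_localises_mu_to_that_bin(self):
        masses = np.zeros(8)
        masses[3] = 1.0
        mu, _, _ = fit_bin_gaussian(masses, EDGES)
        assert EDGES[2] <= mu <= EDGES[3]

    def test_invariant_under_uniform_count_scaling(self):
        rng = np.random.default_rng(2)
        masses = rng.random(8)
        a = fit_bin_gaussian(masses, EDGES)
        b = fit_bin_gaussian(masses * 7.3, EDGES)
        assert a == pytest.approx(b)

    def test_all_zero_level_rejected(self):
        with pytest.raises(ValueError):
            fit_bin_gaussian(np.zeros(8), EDGES)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=8, max_size=8)
           .filter(lambda v: sum(v) > 0))
    def test_renormalisation_and_cumulation_properties(self, values):
        probs = renormalize_level(np.array(values))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (probs >= 0).all()
        cum = cumulate(probs)
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] == pytest.approx(1.0, abs=1e-9)


class TestRescaling:
    @staticmethod
    def _fits(rows):
        return pd.DataFrame(rows, columns=["variant_id", "level", "mu",
                                           "sigma", "r2", "usable"])

    def test_constant_vector_normalises_to_one(self):
        rows = ([("v", j, 500.0, 50.0, 0.9, True) for j in range(1, 7)]
                + [("neg", j, 400.0, 50.0, 0.9, True) for j in range(1, 7)])
        out = rescale_dose_response(self._fits(rows), {"neg"})
        assert np.allclose(out.loc[out.variant_id == "v", "mu_norm"], 1.0)

    def test_day_effect_correction_flattens_negative_controls(self):
        # two negative controls distorted by the same per-level multipliers
        day = np.array([0.3, 1.0, 1.0, 0.3, 1.0, 0.3])
        rows = []
        for vid, basal in (("negA", 4000.0), ("negB", 6000.0), ("x", 5000.0)):
            for j in range(1, 7):
                rows.append((vid, j, basal * day[j - 1], 100.0, 0.95, True))
        out = rescale_dose_response(self._fits(rows), {"negA", "negB"})
        for vid in ("negA", "negB", "x"):
            tilde = out.loc[out.variant_id == vid, "mu_tilde"]
            assert np.allclose(tilde, 1.0)

    def test_single_negative_control_rescales_itself_to_one(self):
        rows = [("neg", j, v, 10.0, 0.9, True)
                for j, v in zip(range(1, 7), (5, 4, 3, 6, 2, 1))]
        out = rescale_dose_response(self._fits(rows), {"neg"})
        assert np.allclose(out["mu_tilde"], 1.0)

    def test_unusable_levels_and_missing_controls_are_errors(self):
        rows = ([("v", j, 1.0, 1.0, 0.9, True) for j in range(1, 7)]
                + [("neg", j, 1.0, 1.0, 0.9, j < 6) for j in range(1, 7)])
        with pytest.raises(ValueError, match="negative control"):
            rescale_dose_response(self._fits(rows), {"neg"})

    def test_variants_below_min_levels_dropped(self):
        rows = ([("v", j, 1.0, 1.0, 0.9, True) for j in (1, 2)]
                + [("neg", j, 1.0, 1.0, 0.9, True) for j in range(1, 7)])
        out = rescale_dose_response(self._fits(rows), {"neg"}, min_levels=3)
        assert "v" not in set(out.variant_id)


class TestBasalFilter:
    @staticmethod
    def _dose(levels):
        rows = []
        for vid, vals in levels.items():
            for j, v in enumerate(vals, start=1):
                rows.append({"variant_id": vid, "level": j, "mu_tilde": v})
        return pd.DataFrame(rows)

    def test_exactly_15_percent_is_retained(self):
        dose = self._dose({"pos": [1.0] * 6, "edge": [0.15] * 6, "low": [0.1] * 6})
        keep = basal_expression_filter(dose, {"pos"})
        assert "edge" in keep and "low" not in keep

    def test_zero_fluorescence_dropped(self):
        dose = self._dose({"pos": [1.0] * 6, "dark": [0.0] * 6})
        assert "dark" not in basal_expression_filter(dose, {"pos"})

    def test_matches_naive_recomputation(self):
        rng = np.random.default_rng(3)
        table = {f"v{i}": list(rng.random(6)) for i in range(20)}
        table["pos"] = [1.0] * 6
        dose = self._dose(table)
        keep = basal_expression_filter(dose, {"pos"})
        cutoff = 0.15 * np.mean(table["pos"][:3])
        for vid, vals in table.items():
            assert (vid in keep) == (np.mean(vals[:3]) >= cutoff)


class TestDemultiplexing:
    def test_known_barcodes_counted_exactly(self):
        fastq = "".join(f"@r{i}\nAAAATTTT{'ACGT' * 3}\n+\n{'I' * 20}\n"
                        for i in range(10))
        t = demux_fastq(io.StringIO(fastq), {"AAAATTTT": (2, 3)},
                        {"ACGT" * 3: "v7"})
        assert t.counts[t.variant_ids.index("v7"), 1, 2] == 10

    def test_unknown_barcode_increments_unassigned_only(self):
        fastq = "@r\nGGGGGGGGACGTACGTACGT\n+\n" + "I" * 20 + "\n"
        t = demux_fastq(io.StringIO(fastq), {"AAAATTTT": (1, 1)},
                        {"ACGT" * 3: "v"})
        assert t.unassigned == 1
        assert t.counts.sum() == 0

    def test_duplicate_barcode_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            demux_fastq(io.StringIO(""), {"AAAATTTT": (1, 1)},
                        [("ACGTACGTACGT", "a"), ("ACGTACGTACGT", "b")])


class TestEndToEndRecovery:
    def test_fitted_mu_tracks_generating_means(self, recovery_sim):
        from sortbind import quantify, simulate_dose_response
        from scipy.stats import spearmanr
        sim = recovery_sim
        dose = quantify(sim["tensor"], sim["negative_ids"], sim["positive_ids"])
        day = np.array(sim["cfg"].day_effect)
        truth = {r.variant_id: simulate_dose_response(r, sim["cfg"])
                 for r in sim["records"]}
        gen = np.array([truth[r.variant_id][r.level - 1] * day[r.level - 1]
                        for r in dose.itertuples()])
        rho = spearmanr(dose["mu"].to_numpy(), gen).statistic
        assert rho > 0.95
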