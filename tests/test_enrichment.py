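"""Enrichment statistic: per-barcode log ratios, normalization, sweep."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import rubiscan as rb
from rubiscan.enrichment import EmptyConditionError, NoSelectionSignalError


def eq1_oracle(n_pre, n_post, pre_tot, post_tot, c_min, alpha_p):
    """Brute-force per-barcode median enrichment, independent of the library."""
    vals = []
    for n0, nf in zip(n_pre, n_post):
        if max(n0, nf) >= c_min:
            vals.append(
                math.log10((nf + post_tot * alpha_p) / (n0 + pre_tot * alpha_p))
                - math.log10(post_tot / pre_tot)
            )
    return statistics.median(vals) if vals else float("nan")


def make_counts(barcode_counts, variant_id="v1"):
    rows = [
        {"barcode": f"bc{i}", "variant_id": variant_id, "n_pre": n0, "n_post": nf}
        for i, (n0, nf) in enumerate(barcode_counts)
    ]
    return pd.DataFrame(rows)


class TestComputeEnrichment:
    def test_equal_ratios_cancel_to_zero(self):
        counts = make_counts([(100, 100)])
        raw = rb.compute_enrichment(
            counts,
            rb.EnrichmentConfig(c_min=0, alpha_p=1e-7),
            pre_unassigned=10**6 - 100,
            post_unassigned=10**6 - 100,
        )
        assert raw.loc["v1", "e_raw"] == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_pseudocount_value(self):
        # one barcode, N0=0, Nf=10, totals 1e6: e = log10(10.365/0.365)
        counts = make_counts([(0, 10)])
        raw = rb.compute_enrichment(
            counts,
            rb.EnrichmentConfig(c_min=0, alpha_p=3.65e-7),
            pre_unassigned=10**6,
            post_unassigned=10**6 - 10,
        )
        assert raw.loc["v1", "e_raw"] == pytest.approx(
            math.log10(10.365 / 0.365), abs=1e-9
        )

    def test_count_threshold_excludes_and_marks_missing(self):
        counts = make_counts([(2, 3)])
        raw = rb.compute_enrichment(counts, rb.EnrichmentConfig(c_min=5, alpha_p=1e-7))
        assert np.isnan(raw.loc["v1", "e_raw"])
        assert raw.loc["v1", "n_barcodes"] == 0

    def test_threshold_is_inclusive_or(self):
        # observed either pre- OR post-selection
        counts = make_counts([(0, 5), (5, 0)])
        raw = rb.compute_enrichment(counts, rb.EnrichmentConfig(c_min=5, alpha_p=1e-7))
        assert raw.loc["v1", "n_barcodes"] == 2

    def test_zero_totals_rejected(self):
        counts = make_counts([(0, 0)])
        with pytest.raises(EmptyConditionError):
            rb.compute_enrichment(counts, rb.EnrichmentConfig(c_min=0, alpha_p=1e-7))

    def test_matches_bruteforce_oracle_on_random_tables(self):
        """Median-over-barcodes statistic agrees with the per-barcode oracle."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n_bc = int(rng.integers(1, 21))
            n_var = int(rng.integers(1, 4))
            vids = [f"v{rng.integers(0, n_var)}" for _ in range(n_bc)]
            n0 = rng.integers(0, 500, size=n_bc)
            nf = rng.integers(0, 500, size=n_bc)
            c_min = int(rng.integers(0, 12))
            alpha = float(10 ** rng.uniform(-9, -5))
            counts = pd.DataFrame(
                {
                    "barcode": [f"b{i}" for i in range(n_bc)],
                    "variant_id": vids,
                    "n_pre": n0,
                    "n_post": nf,
                }
            )
            pre_extra = int(rng.integers(1, 1000))
            post_extra = int(rng.integers(1, 1000))
            raw = rb.compute_enrichment(
                counts,
                rb.EnrichmentConfig(c_min=c_min, alpha_p=alpha),
                pre_unassigned=pre_extra,
                post_unassigned=post_extra,
            )
            pre_tot = n0.sum() + pre_extra
            post_tot = nf.sum() + post_extra
            for vid in set(vids):
                sel = [i for i, v in enumerate(vids) if v == vid]
                expect = eq1_oracle(
                    n0[sel], nf[sel], pre_tot, post_tot, c_min, alpha
                )
                got = raw.loc[vid, "e_raw"]
                if math.isnan(expect):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect, abs=1e-12)

    @given(
        scale=st.integers(min_value=2, max_value=50),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_scaling_post_counts_cancels(self, scale, seed):
        """Total-normalization removes any common factor on post counts."""
        rng = np.random.default_rng(seed)
        n0 = rng.integers(1, 200, size=8)
        nf = rng.integers(1, 200, size=8)
        counts = make_counts(list(zip(n0, nf)))
        cfg = rb.EnrichmentConfig(c_min=0, alpha_p=1e-7)
        base = rb.compute_enrichment(counts, cfg).loc["v1", "e_raw"]
        scaled = make_counts(list(zip(n0, nf * scale)))
        up = rb.compute_enrichment(scaled, cfg).loc["v1", "e_raw"]
        assert up == pytest.approx(base, abs=1e-10)


class TestNormalization:
    @pytest.fixture()
    def raw(self):
        return pd.DataFrame(
            {"e_raw": [2.0, 0.5, -1.0, -1.2, -0.8], "n_barcodes": 3},
            index=pd.Index(["WT", "mid", "d1", "d2", "d3"], name="variant_id"),
        )

    def test_wild_type_maps_to_one_dead_to_zero(self, raw):
        norm = rb.normalize_enrichment(raw, ["d1", "d2", "d3"])
        assert norm.loc["WT", "e_norm"] == 1.0
        assert np.median(norm.loc[["d1", "d2", "d3"], "e_norm"]) == 0.0

    def test_midpoint_maps_to_half(self, raw):
        norm = rb.normalize_enrichment(raw, ["d1", "d2", "d3"])
        assert norm.loc["mid", "e_norm"] == pytest.approx(0.5)

    def test_idempotent_on_normalized_table(self, raw):
        once = rb.normalize_enrichment(raw, ["d1", "d2", "d3"])
        again = rb.normalize_enrichment(
            once.rename(columns={"e_norm": "x"}).assign(e_raw=lambda d: d["x"]),
            ["d1", "d2", "d3"],
        )
        np.testing.assert_allclose(again["e_norm"], once["e_norm"], atol=1e-14)

    def test_degenerate_denominator_rejected(self):
        raw = pd.DataFrame(
            {"e_raw": [0.5, 0.5], "n_barcodes": 1},
            index=pd.Index(["WT", "d1"], name="variant_id"),
        )
        with pytest.raises(NoSelectionSignalError):
            rb.normalize_enrichment(raw, ["d1"])


class TestReplicateCorrelation:
    def test_identical_replicates_give_one(self):
        s = pd.Series([0.1, 0.5, 0.9, 0.3], index=list("abcd"))
        assert rb.pairwise_replicate_correlation([s, s.copy()]) == pytest.approx(1.0)

    def test_anticorrelated_toy_gives_minus_one(self):
        a = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        b = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        assert rb.pairwise_replicate_correlation([a, b]) == pytest.approx(-1.0)

    def test_three_replicates_average_all_pairs(self):
        rng = np.random.default_rng(0)
        reps = [
            pd.Series(rng.normal(size=20), index=range(20)) for _ in range(3)
        ]
        expect = np.mean(
            [
                np.corrcoef(reps[i], reps[j])[0, 1]
                for i, j in [(0, 1), (0, 2), (1, 2)]
            ]
        )
        assert rb.pairwise_replicate_correlation(reps) == pytest.approx(expect)

    def test_missing_variants_excluded_pairwise(self):
        a = pd.Series([1.0, 2.0, 3.0, np.nan], index=list("abcd"))
        b = pd.Series([1.1, 2.2, 2.9, 5.0], index=list("abcd"))
        # NaN row dropped; remaining three points drive the coefficient
        expect = np.corrcoef([1, 2, 3], [1.1, 2.2, 2.9])[0, 1]
        assert rb.pairwise_replicate_correlation([a, b]) == pytest.approx(expect)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            rb.pairwise_replicate_correlation([pd.Series([1.0, 2.0])])


class TestSweep:
    def test_grid_size_is_product_of_grids(self, small_sim):
        sub = small_sim["counts"][small_sim["counts"]["co2_percent"] == 5.0]
        _, surface = rb.sweep_processing_params(
            sub, small_sim["dead"], c_min_grid=(0, 25, 50), alpha_grid=(1e-9, 1e-7)
        )
        assert len(surface) == 6

    def test_identical_replicates_tie_break_smallest_params(self, small_sim):
        counts = small_sim["counts"]
        rep1 = counts[(counts["co2_percent"] == 5.0) & (counts["replicate"] == 1)]
        rep2 = rep1.assign(replicate=2)
        dup = pd.concat([rep1, rep2], ignore_index=True)
        best, surface = rb.sweep_processing_params(
            dup, small_sim["dead"], c_min_grid=(0, 10, 20), alpha_grid=(1e-9, 1e-8)
        )
        assert surface["mean_pearson"].round(10).eq(1.0).all()
        assert (best.c_min, best.alpha_p) == (0, 1e-9)

    def test_low_count_noise_pushes_threshold_up(self):
        """Noise barcodes uncorrelated between replicates favor c_min > 0."""
        rng = np.random.default_rng(42)
        n_var = 40
        rows = []
        for rep in (1, 2):
            for v in range(n_var):
                signal = 100 + 40 * (v % 7)
                for b in range(3):  # consistent, well-covered barcodes
                    rows.append(
                        {
                            "co2_percent": 5.0,
                            "co2_um": 1223.0,
                            "replicate": rep,
                            "barcode": f"v{v}b{b}",
                            "variant_id": f"v{v}" if v else "WT",
                            "n_pre": 200,
                            "n_post": signal + int(rng.integers(-5, 6)),
                        }
                    )
                for b in range(3, 9):  # sparse noise barcodes, replicate-specific
                    rows.append(
                        {
                            "co2_percent": 5.0,
                            "co2_um": 1223.0,
                            "replicate": rep,
                            "barcode": f"v{v}b{b}",
                            "variant_id": f"v{v}" if v else "WT",
                            "n_pre": int(rng.integers(0, 3)),
                            "n_post": int(rng.integers(0, 3)),
                        }
                    )
        # dead panel: three variants with collapsed post counts
        for rep in (1, 2):
            for v in ("dead1", "dead2", "dead3"):
                for b in range(3):
                    rows.append(
                        {
                            "co2_percent": 5.0,
                            "co2_um": 1223.0,
                            "replicate": rep,
                            "barcode": f"{v}b{b}",
                            "variant_id": v,
                            "n_pre": 200,
                            "n_post": int(rng.integers(0, 4)),
                        }
                    )
        counts = pd.DataFrame(rows)
        best, _ = rb.sweep_processing_params(
            counts,
            ["dead1", "dead2", "dead3"],
            c_min_grid=(0, 5, 10),
            alpha_grid=(1e-8, 1e-7),
        )
        assert best.c_min > 0

    def test_empty_grids_rejected(self, small_sim):
        with pytest.raises(ValueError):
            rb.sweep_processing_params(small_sim["counts"], small_sim["dead"], (), (1e-7,))
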