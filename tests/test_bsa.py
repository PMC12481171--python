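"""Δ-index machinery: index formulas, window smoothing vs brute force,
loess behaviour, null-band properties and region calling/intersection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from bulkmap import bsa


def random_sites(rng, n, chrom="A09", span=5_000_000):
    pos = np.sort(rng.choice(span, size=n, replace=False)) + 1
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "vclass": rng.choice(["SNP", "Indel"], size=n),
        }
    )
    for col in ("P_ref", "P_alt", "M_ref", "M_alt", "aa_ref", "aa_alt", "ab_ref", "ab_alt"):
        df[col] = rng.integers(0, 40, size=n)
    return df


class TestFilterInformative:
    def test_opposite_homozygous_parents_retained(self):
        df = pd.DataFrame(
            [
                dict(P_ref=20, P_alt=0, M_ref=0, M_alt=20, aa_ref=10, aa_alt=10, ab_ref=10, ab_alt=10),
            ]
        )
        out = bsa.filter_informative_sites(df, min_parent_depth=10)
        assert len(out) == 1

    def test_heterozygous_parent_removed(self):
        df = pd.DataFrame(
            [
                dict(P_ref=10, P_alt=10, M_ref=0, M_alt=20, aa_ref=10, aa_alt=10, ab_ref=10, ab_alt=10),
            ]
        )
        assert len(bsa.filter_informative_sites(df)) == 0

    def test_empty_input_passes_through(self):
        df = random_sites(np.random.default_rng(0), 5).iloc[:0]
        assert len(bsa.filter_informative_sites(df)) == 0

    def test_matches_bruteforce_predicate(self, rng):
        df = random_sites(rng, 1000)
        out = bsa.filter_informative_sites(
            df, min_parent_depth=4, max_minor_fraction=0.1, min_pool_depth=4
        )

        def keep(r):
            pt, mt = r.P_ref + r.P_alt, r.M_ref + r.M_alt
            if pt < 4 or mt < 4:
                return False
            if min(r.P_ref, r.P_alt) / pt > 0.1 or min(r.M_ref, r.M_alt) / mt > 0.1:
                return False
            if (r.P_alt > r.P_ref) == (r.M_alt > r.M_ref):
                return False
            return (r.aa_ref + r.aa_alt) >= 4 and (r.ab_ref + r.ab_alt) >= 4

        expected = [i for i, r in enumerate(df.itertuples(index=False)) if keep(r)]
        assert list(out.index) == expected


class TestComputeIndex:
    def _site(self, **kw):
        base = dict(
            chrom="A09", pos=100, P_ref=30, P_alt=0, M_ref=0, M_alt=30,
            aa_ref=0, aa_alt=0, ab_ref=0, ab_alt=0,
        )
        base.update(kw)
        return pd.DataFrame([base])

    def test_symmetric_depths_give_half(self):
        # Maa = 15 (alt, M is alt-homozygous), Paa = 15 -> index_aa = 0.5
        pts = bsa.compute_index(self._site(aa_ref=15, aa_alt=15, ab_ref=10, ab_alt=10))
        assert pts.loc[0, "index_aa"] == pytest.approx(0.5)
        assert pts.loc[0, "index_ab"] == pytest.approx(0.5)
        assert pts.loc[0, "delta"] == pytest.approx(0.0)

    def test_fully_fixed_pools_give_delta_one(self):
        pts = bsa.compute_index(self._site(aa_ref=0, aa_alt=30, ab_ref=30, ab_alt=0))
        assert pts.loc[0, "delta"] == pytest.approx(1.0)

    def test_identical_pools_give_zero_delta(self, rng):
        df = random_sites(rng, 200)
        for suffix in ("ref", "alt"):
            df[f"ab_{suffix}"] = df[f"aa_{suffix}"]
        pts = bsa.compute_index(df)
        ok = pts["delta"].notna()
        assert np.allclose(pts.loc[ok, "delta"], 0.0)

    def test_zero_depth_flagged_missing(self):
        pts = bsa.compute_index(self._site(aa_ref=0, aa_alt=0, ab_ref=10, ab_alt=10))
        assert np.isnan(pts.loc[0, "index_aa"])
        assert np.isnan(pts.loc[0, "delta"])

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            bsa.compute_index(self._site(aa_ref=-1))

    def test_indices_bounded_and_pool_swap_negates(self, rng):
        df = random_sites(rng, 10_000)
        pts = bsa.compute_index(df)
        ok = pts["delta"].notna()
        assert ((pts.loc[ok, "index_aa"] >= 0) & (pts.loc[ok, "index_aa"] <= 1)).all()
        assert ((pts.loc[ok, "delta"] >= -1) & (pts.loc[ok, "delta"] <= 1)).all()
        swapped = df.rename(
            columns={
                "aa_ref": "ab_ref", "ab_ref": "aa_ref",
                "aa_alt": "ab_alt", "ab_alt": "aa_alt",
            }
        )
        pts2 = bsa.compute_index(swapped)
        np.testing.assert_allclose(
            pts2.loc[ok, "delta"], -pts.loc[ok, "delta"], atol=1e-12
        )


class TestSlidingWindows:
    def test_single_window_mean(self):
        pts = pd.DataFrame(
            {
                "chrom": "A09",
                "pos": [100, 200, 300],
                "delta": [0.1, 0.2, 0.3],
                "depth_aa": [30, 30, 30],
                "depth_ab": [30, 30, 30],
            }
        )
        win = bsa.sliding_windows(pts, window_bp=1000, step_bp=1000, min_sites=1)
        assert len(win) == 1
        assert win.loc[0, "mean_delta"] == pytest.approx(0.2)
        assert win.loc[0, "n_sites"] == 3

    def test_matches_bruteforce_recomputation(self, rng):
        n = 2000
        pts = pd.DataFrame(
            {
                "chrom": "A09",
                "pos": np.sort(rng.choice(5_000_000, size=n, replace=False)) + 1,
                "delta": rng.uniform(-1, 1, size=n),
                "depth_aa": rng.integers(1, 60, size=n),
                "depth_ab": rng.integers(1, 60, size=n),
            }
        )
        window_bp, step_bp = 1_000_000, 100_000
        win = bsa.sliding_windows(
            pts, window_bp=window_bp, step_bp=step_bp, min_sites=1,
            chrom_lengths={"A09": 5_000_000},
        )
        pos0 = pts["pos"].to_numpy() - 1
        for r in win.itertuples(index=False):
            mask = (pos0 >= r.start) & (pos0 < r.end)
            assert r.n_sites == mask.sum()
            if mask.sum():
                assert r.mean_delta == pytest.approx(pts.loc[mask, "delta"].mean())
            else:
                assert np.isnan(r.mean_delta)

    def test_empty_chromosome_emits_no_windows(self):
        pts = pd.DataFrame(columns=["chrom", "pos", "delta", "depth_aa", "depth_ab"])
        win = bsa.sliding_windows(pts)
        assert len(win) == 0

    def test_window_smaller_than_step_rejected(self, rng):
        with pytest.raises(ValueError):
            bsa.sliding_windows(random_sites(rng, 5), window_bp=10, step_bp=100)


class TestLoess:
    def _track(self, y):
        return pd.DataFrame(
            {"chrom": "A09", "start": np.arange(len(y)) * 100_000, "mean_delta": y}
        )

    def test_reproduces_constant(self):
        track = self._track(np.full(50, 0.37))
        fit = bsa.loess_fit(track, span=0.3)
        np.testing.assert_allclose(fit["fitted"], 0.37, atol=1e-9)

    def test_reproduces_line(self):
        x = np.arange(60) * 100_000
        track = self._track(0.1 + 2e-8 * x)
        fit = bsa.loess_fit(track, span=0.2)
        np.testing.assert_allclose(fit["fitted"], track["mean_delta"], atol=1e-9)

    def test_step_function_recovered_away_from_break(self, rng):
        n = 200
        y = np.where(np.arange(n) < n // 2, 0.0, 0.5) + rng.normal(0, 0.05, n)
        fit = bsa.loess_fit(self._track(y), span=0.1)
        left = fit["fitted"][: n // 2 - 20]
        right = fit["fitted"][n // 2 + 20 :]
        assert np.all(np.abs(left - 0.0) < 0.05)
        assert np.all(np.abs(right - 0.5) < 0.05)

    def test_short_chromosome_passes_through_with_warning(self):
        track = self._track([0.1, 0.4, 0.2])
        with pytest.warns(UserWarning, match="loess skipped"):
            fit = bsa.loess_fit(track)
        np.testing.assert_allclose(fit["fitted"], track["mean_delta"])


class TestNullBand:
    def test_band_symmetric_about_zero(self):
        ci = bsa.null_ci([30], 30, n_sims=100_000, conf=0.99, seed=3)
        lo, hi = ci.loc[0, "ci_low"], ci.loc[0, "ci_high"]
        assert lo < 0 < hi
        assert abs(lo + hi) < 0.03  # Monte-Carlo wobble of the 0.5% tails

    def test_band_shrinks_with_depth_and_bulk(self):
        wide = bsa.null_ci([30], 30, n_sims=20_000, seed=4)
        narrow = bsa.null_ci([20_000], 20_000, n_sims=20_000, seed=4)
        assert narrow.loc[0, "ci_high"] < 0.03 < wide.loc[0, "ci_high"]
        assert narrow.loc[0, "ci_low"] > -0.03 > wide.loc[0, "ci_low"]

    def test_low_sim_count_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            bsa.null_ci([30], 30, n_sims=500, seed=5)

    def test_invalid_conf_rejected(self):
        with pytest.raises(ValueError):
            bsa.null_ci([30], 30, conf=0.4)


def _windows(chrom, sig_mask, step=100_000, fitted_val=0.6):
    n = len(sig_mask)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * step,
            "end": np.arange(n) * step + step,
            "n_sites": 20,
            "mean_delta": 0.0,
            "mean_depth": 30.0,
            "fitted": np.where(sig_mask, fitted_val, 0.0),
            "ci_low": -0.4,
            "ci_high": 0.4,
        }
    )


class TestRegions:
    def test_simple_intersection(self):
        a = pd.DataFrame([("A09", 10, 20, "SNP", 0.5)], columns=["chrom", "start", "end", "source", "peak_delta"])
        b = pd.DataFrame([("A09", 15, 30, "Indel", 0.4)], columns=["chrom", "start", "end", "source", "peak_delta"])
        out = bsa.intersect_regions(a, b)
        assert out[["start", "end"]].values.tolist() == [[15, 20]]

    def test_missing_indel_track_means_no_candidate(self):
        snp = _windows("A09", [False] * 3 + [True] * 4 + [False] * 3)
        indel = _windows("A09", [False] * 10)
        called = bsa.call_regions(snp, indel)
        assert len(called["snp"]) == 1
        assert len(called["indel"]) == 0
        assert len(called["candidates"]) == 0

    def test_disjoint_chromosomes_warn_and_empty(self):
        snp = _windows("A09", [True] * 5)
        indel = _windows("C03", [True] * 5)
        with pytest.warns(UserWarning, match="no chromosomes"):
            called = bsa.call_regions(snp, indel)
        assert len(called["candidates"]) == 0

    def test_gap_of_exactly_one_step_stays_split(self):
        mask = [True] * 3 + [False] + [True] * 3
        snp = _windows("A09", mask)
        snp.loc[3, "fitted"] = np.nan
        indel = _windows("A09", [True] * 7)
        called = bsa.call_regions(snp, indel)
        # windows here are step-sized, so the hole separates the runs by
        # exactly step_bp and the < step_bp merge rule keeps them apart
        assert len(called["snp"]) == 2

    def test_overlapping_runs_merge(self):
        # realistic geometry: windows much wider than the step, so runs
        # separated by a one-window hole still overlap and merge
        mask = [True] * 3 + [False] + [True] * 3
        snp = _windows("A09", mask)
        snp["end"] = snp["start"] + 500_000
        snp.loc[3, "fitted"] = np.nan
        indel = _windows("A09", [True] * 7)
        indel["end"] = indel["start"] + 500_000
        called = bsa.call_regions(snp, indel)
        assert len(called["snp"]) == 1

    def test_intersection_matches_bruteforce(self, rng):
        def random_regions(k):
            rows = []
            for _ in range(k):
                chrom = rng.choice(["A06", "A09", "C07"])
                start = int(rng.integers(0, 900))
                end = start + int(rng.integers(1, 120))
                rows.append((chrom, start, end, "x", float(rng.normal())))
            return pd.DataFrame(rows, columns=["chrom", "start", "end", "source", "peak_delta"])

        for _ in range(20):
            a, b = random_regions(15), random_regions(12)
            got = bsa.intersect_regions(a, b)
            expected = []
            for ra in a.itertuples(index=False):
                for rb in b.itertuples(index=False):
                    if ra.chrom != rb.chrom:
                        continue
                    s, e = max(ra.start, rb.start), min(ra.end, rb.end)
                    if s < e:
                        expected.append((ra.chrom, s, e))
            exp = sorted(expected)
            assert sorted(map(tuple, got[["chrom", "start", "end"]].values.tolist())) == exp

    def test_pool_swap_mirrors_called_regions(self, rng):
        mask = [False] * 4 + [True] * 5 + [False] * 4
        snp = _windows("A09", mask, fitted_val=0.6)
        indel = _windows("A09", mask, fitted_val=0.55)
        pos = bsa.call_regions(snp, indel)["candidates"]
        for w in (snp, indel):
            w["fitted"] = -w["fitted"]
            w["mean_delta"] = -w["mean_delta"]
        neg = bsa.call_regions(snp, indel)["candidates"]
        assert pos[["chrom", "start", "end"]].equals(neg[["chrom", "start", "end"]])
        np.testing.assert_allclose(neg["peak_delta"], -pos["peak_delta"])
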