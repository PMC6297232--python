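"""QC metrics: dedup, complexity estimation, FRiP, profiles, saturation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pscatac import qc, synth
from pscatac.config import RunConfig
from pscatac.intervals import IntervalSet


def frame(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_id"])
    df["is_mt"] = df["chrom"] == "chrM"
    return df


def grid_search_library_size(t, u, rounds=6, width=2000):
    """Independent oracle: iteratively refined grid search on L(1-e^{-t/L})=u."""
    lo, hi = float(u), max(2.0 * u, float(t))
    f = lambda L: -L * np.expm1(-t / L) - u
    while f(hi) < 0:
        hi *= 4.0
    for _ in range(rounds):
        grid = np.linspace(lo, hi, width)
        vals = -grid * np.expm1(-t / grid) - u
        j = int(np.searchsorted(vals >= 0, True))
        lo, hi = grid[max(j - 1, 0)], grid[min(j, width - 1)]
    return 0.5 * (lo + hi)


class TestDedup:
    def test_same_cell_duplicates_collapse(self):
        fr = frame([("chr1", 0, 100, "a"), ("chr1", 0, 100, "a")])
        assert len(qc.dedup(fr)) == 1

    def test_different_cells_kept(self):
        fr = frame([("chr1", 0, 100, "a"), ("chr1", 0, 100, "b")])
        assert len(qc.dedup(fr)) == 2  # wells are independent libraries

    def test_idempotent(self):
        fr = frame([("chr1", 0, 100, "a"), ("chr1", 5, 50, "a"), ("chr1", 0, 100, "a")])
        once = qc.dedup(fr)
        pd.testing.assert_frame_equal(qc.dedup(once), once)


class TestLibrarySize:
    def test_known_root(self):
        # u/t = 0.5 -> t/L is the root x of (1-e^-x)/x = 1/2, x ~ 1.59362
        assert qc.estimate_library_size(200, 100) == pytest.approx(125.5, abs=0.01)

    def test_saturated_undefined(self):
        assert math.isnan(qc.estimate_library_size(100, 100))

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            qc.estimate_library_size(100, 0)
        with pytest.raises(ValueError):
            qc.estimate_library_size(100, 101)

    def test_matches_grid_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            t = int(rng.integers(100, 1_000_000))
            u = int(rng.integers(1, t))
            est = qc.estimate_library_size(t, u)
            oracle = grid_search_library_size(t, u)
            assert abs(est - oracle) / oracle < 1e-6

    @given(
        L=st.integers(100, 10_000_000),
        ratio=st.floats(0.05, 8.0),
    )
    def test_round_trip_inversion(self, L, ratio):
        """u computed from (L, t) inverts back to L."""
        t = max(int(L * ratio), 1)
        u = -L * math.expm1(-t / L)
        if u >= t - 1e-6 or u < 1:
            return
        est = qc.estimate_library_size(t, u)
        assert est == pytest.approx(L, rel=1e-5)

    def test_recovery_from_resampling(self, small_genome):
        """t = 10 L simulation recovers L within 2%."""
        L, t = 10_000, 100_000
        d = [synth.CellDesign("c0", 0, library_size=L, depth=t, mt_rate=0.0)]
        fr, _ = synth.simulate_cells(small_genome, d, seed=21)
        u = len(qc.dedup(fr))
        assert qc.estimate_library_size(t, u) == pytest.approx(L, rel=0.02)


class TestCellQc:
    PEAKS = IntervalSet.from_arrays(["chr1"], [0], [1_000])

    def test_frip_ratio(self):
        rows = [("chr1", i * 10, i * 10 + 5, "a") for i in range(50)]  # inside peak
        rows += [("chr1", 5_000 + i * 10, 5_000 + i * 10 + 5, "a") for i in range(50)]
        tab = qc.cell_qc(frame(rows), self.PEAKS)
        assert tab.iloc[0]["frip"] == pytest.approx(0.5)

    def test_all_mitochondrial_cell(self):
        fr = frame([("chrM", 0, 50, "a"), ("chrM", 60, 90, "a")])
        tab = qc.cell_qc(fr, self.PEAKS)
        assert tab.iloc[0]["mt_fraction"] == 1.0
        assert math.isnan(tab.iloc[0]["frip"])  # 0/0 reported as missing

    def test_duplication_and_library_size(self):
        fr = frame([("chr1", 0, 100, "a")] * 3 + [("chr1", 200, 300, "a")])
        tab = qc.cell_qc(fr, self.PEAKS)
        row = tab.iloc[0]
        assert row["total_reads"] == 4 and row["unique_fragments"] == 2
        assert row["duplication_rate"] == pytest.approx(0.5)
        assert row["est_library_size"] == pytest.approx(
            qc.estimate_library_size(4, 2)
        )

    def test_metrics_invariant_to_row_order(self):
        rows = [("chr1", i, i + 50, "a") for i in range(0, 400, 7)] + [
            ("chr2", i, i + 30, "b") for i in range(0, 200, 11)
        ]
        fr = frame(rows)
        shuffled = fr.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = qc.cell_qc(fr, self.PEAKS)
        b = qc.cell_qc(shuffled, self.PEAKS)
        pd.testing.assert_frame_equal(a, b)

    def test_fractions_in_unit_interval(self, default_dataset):
        tab = qc.cell_qc(default_dataset["fragments"], default_dataset["genome"].peaks)
        for col in ["duplication_rate", "mt_fraction", "frip"]:
            vals = tab[col].dropna()
            assert ((vals >= 0) & (vals <= 1)).all()
        ok = tab.dropna(subset=["est_library_size"])
        assert (ok["est_library_size"] >= ok["unique_fragments"]).all()

    def test_planted_frip_recovered(self, small_genome):
        d = [synth.CellDesign("c0", 0, library_size=12_500, depth=50_000, mt_rate=0.0, frip=0.6)]
        fr, _ = synth.simulate_cells(small_genome, d, seed=22)
        tab = qc.cell_qc(qc.dedup(fr), small_genome.peaks)
        # dedup'd input: t == u, FRiP still defined
        assert tab.iloc[0]["frip"] == pytest.approx(0.6, abs=0.02)


class TestFilterCells:
    def _qc(self, reads, mapped):
        return pd.DataFrame(
            {"cell_id": ["c"], "total_reads": [reads], "mapped_fraction": [mapped]}
        )

    @pytest.mark.parametrize(
        "reads,mapped,expected",
        [
            (10_000, 0.95, False),  # boundary read count fails (strict >)
            (15_000, 0.95, True),
            (15_000, 0.90, False),  # boundary mapping rate fails (strict >)
            (9_000, 0.99, False),
        ],
    )
    def test_strict_thresholds(self, reads, mapped, expected):
        assert qc.filter_cells(self._qc(reads, mapped)).iloc[0] == expected

    def test_missing_map_rate_skips_clause(self):
        tab = self._qc(15_000, float("nan"))
        assert qc.filter_cells(tab).iloc[0]


class TestInsertSizes:
    def test_single_fragment(self):
        h = qc.insert_size_hist(frame([("chr1", 0, 200, "a")]))
        assert h[200] == 1 and h.sum() == 1

    def test_overflow_pooled(self):
        h = qc.insert_size_hist(frame([("chr1", 0, 5_000, "a")]), max_size=1000)
        assert h[-1] == 1

    def test_empty_table(self):
        assert qc.insert_size_hist(frame([])).sum() == 0

    def test_nucleosomal_banding(self, small_genome):
        """Local maxima near the 75/200/400 bp mixture centres."""
        d = [synth.CellDesign("c0", 0, library_size=100_000, depth=100_000)]
        fr, _ = synth.simulate_cells(small_genome, d, seed=23)
        h = qc.insert_size_hist(fr).astype(float)
        # smooth lightly to find modes
        kernel = np.ones(7) / 7
        smooth = np.convolve(h, kernel, mode="same")
        for centre in (75, 200, 400):
            window = smooth[centre - 10 : centre + 11]
            assert window.max() >= smooth[max(centre - 60, 1) : centre - 40].max()


class TestTssEnrichment:
    TSS = IntervalSet.from_arrays(["chr1"], [5_000], [5_001], name=["g1"])

    def test_uniform_coverage_score_one(self):
        rows = [("chr1", s, s + 100, "a") for s in range(0, 10_000, 100)]
        prof = qc.tss_enrichment(frame(rows), self.TSS, window=2_000)
        assert prof.enrichment_score == pytest.approx(1.0, abs=0.05)

    def test_tss_centred_fragments_score_large(self):
        rows = [("chr1", 4_900 + i, 5_100 - i, "a") for i in range(0, 90, 3)]
        rows += [("chr1", s, s + 50, "a") for s in range(3_000, 7_000, 400)]
        prof = qc.tss_enrichment(frame(rows), self.TSS, window=2_000)
        assert prof.enrichment_score > 5

    def test_no_fragments_flagged(self):
        prof = qc.tss_enrichment(frame([]), self.TSS)
        assert math.isnan(prof.enrichment_score) and prof.flagged

    def test_minus_strand_flip(self):
        tss = IntervalSet.from_arrays(
            ["chr1", "chr1"], [5_000, 20_000], [5_001, 20_001],
            name=["plus", "minus"], strand=["+", "-"],
        )
        # asymmetric signal downstream of the plus TSS, upstream of the minus TSS
        rows = [("chr1", 5_100, 5_200, "a"), ("chr1", 19_800, 19_900, "a")]
        prof = qc.tss_enrichment(frame(rows), tss, window=500)
        left = prof.profile[: 500].sum()
        right = prof.profile[501:].sum()
        assert right > 0 and left == 0  # both contributions map downstream

    def test_monotone_in_planted_enrichment(self, small_genome):
        scores = []
        for frip in (0.2, 0.6):
            d = [synth.CellDesign("c0", 0, library_size=20_000, depth=20_000, frip=frip, mt_rate=0.0)]
            fr, _ = synth.simulate_cells(small_genome, d, seed=24)
            scores.append(qc.tss_enrichment(fr, small_genome.tss).enrichment_score)
        assert scores[1] > scores[0]
        assert scores[1] > 2  # clear enrichment at the study-like FRiP


class TestSaturation:
    def test_full_fraction_identity(self, small_genome):
        d = [synth.CellDesign("c0", 0, library_size=1_000, depth=5_000)]
        fr, _ = synth.simulate_cells(small_genome, d, seed=25)
        curve = qc.saturation_curve(fr, [0.5, 1.0], seed=0)
        assert curve.iloc[-1]["n_unique"] == len(qc.dedup(fr))

    def test_monotone_concave(self, small_genome):
        d = [synth.CellDesign("c0", 0, library_size=2_000, depth=20_000)]
        fr, _ = synth.simulate_cells(small_genome, d, seed=26)
        curve = qc.saturation_curve(fr, [0.2, 0.4, 0.6, 0.8, 1.0], seed=0)
        uniq = curve["n_unique"].to_numpy(dtype=float)
        assert (np.diff(uniq) >= 0).all()
        slopes = np.diff(uniq) / np.diff(curve["fraction"].to_numpy())
        assert (np.diff(slopes) <= 0.01 * 2_000).all()  # concave within noise

    def test_invalid_fraction(self, small_genome):
        with pytest.raises(ValueError):
            qc.saturation_curve(frame([]), [0.0, 1.0], seed=0)
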