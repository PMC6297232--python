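"""Marker extraction, z-score matrices, motif scanning and binomial enrichment."""

from decimal import Decimal, getcontext
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from pscatac import markers, synth
from pscatac.matrix import AccessibilityMatrix

from conftest import majority_cluster_map


def exact_binomial_tail(k, n, p):
    """High-precision summation oracle for P(X >= k)."""
    getcontext().prec = 60
    pd_ = Decimal(p)
    q = Decimal(1) - pd_
    return float(sum(comb(n, i) * pd_**i * q ** (n - i) for i in range(k, n + 1)))


def toy_matrix():
    # 3 peaks x 6 cells; peak 0 open only in cells of cluster 0, peak 2 constant-zero
    dense = np.array(
        [
            [1, 1, 1, 0, 0, 0],
            [1, 0, 1, 1, 1, 0],
            [0, 0, 0, 0, 0, 0],
        ]
    )
    return AccessibilityMatrix(
        sp.csr_matrix(dense), ["pA", "pB", "pC"], [f"c{i}" for i in range(6)]
    )


class TestClassifier:
    LABELS = np.array([0, 0, 0, 1, 1, 1])

    def test_separating_peak_gets_largest_coefficient(self):
        coef = markers.fit_marker_classifier(toy_matrix(), self.LABELS, seed=0)
        assert coef.loc[0].idxmax() == "pA"

    def test_constant_peak_zero_coefficient(self):
        coef = markers.fit_marker_classifier(toy_matrix(), self.LABELS, seed=0)
        assert coef.loc[0, "pC"] == pytest.approx(0.0, abs=1e-6)
        assert coef.loc[1, "pC"] == pytest.approx(0.0, abs=1e-6)

    def test_cell_permutation_invariance(self):
        m = toy_matrix()
        perm = [3, 1, 5, 0, 4, 2]
        m_perm = AccessibilityMatrix(
            m.counts[:, perm], m.peak_ids, [m.cell_ids[i] for i in perm]
        )
        a = markers.fit_marker_classifier(m, self.LABELS, seed=0)
        b = markers.fit_marker_classifier(m_perm, self.LABELS[perm], seed=0)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-6)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            markers.fit_marker_classifier(toy_matrix(), np.zeros(6, dtype=int))


class TestTopMarkers:
    def test_ranking_and_tie_break(self):
        coef = pd.DataFrame(
            [[0.5, 0.5, -1.0, 2.0]], index=[0], columns=["pB", "pA", "pD", "pC"]
        )
        tops = markers.top_marker_peaks(coef, top_n=3)
        assert tops[0] == ["pC", "pA", "pB"]  # tie 0.5 resolves to smaller id

    def test_clamped_when_fewer_peaks(self):
        coef = pd.DataFrame([[1.0, 0.2]], index=[0], columns=["a", "b"])
        assert markers.top_marker_peaks(coef, top_n=500)[0] == ["a", "b"]

    def test_nonfinite_rejected(self):
        coef = pd.DataFrame([[np.inf]], index=[0], columns=["a"])
        with pytest.raises(ValueError):
            markers.top_marker_peaks(coef)

    def test_marker_lists_stable_across_seeds(self, default_dataset, default_labels):
        m = default_dataset["matrix"]
        tops = []
        for seed in (0, 99):
            coef = markers.fit_marker_classifier(m, default_labels, seed=seed)
            tops.append(markers.top_marker_peaks(coef, top_n=500))
        for c in tops[0]:
            a, b = set(tops[0][c]), set(tops[1][c])
            assert len(a & b) / len(a | b) >= 0.8


class TestZscore:
    def test_rows_standardised(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 6, size=(5, 30))
        m = AccessibilityMatrix(
            sp.csr_matrix(dense), [f"p{i}" for i in range(5)], [f"c{i}" for i in range(30)]
        )
        labels = np.repeat([0, 1, 2], 10)
        z = markers.zscore_matrix(m, labels, {0: ["p0", "p1"], 1: ["p2"], 2: ["p3"]})
        vals = z.values.to_numpy()
        assert np.allclose(vals.mean(axis=1), 0, atol=1e-10)
        assert np.allclose(vals.std(axis=1), 1, atol=1e-10)

    def test_constant_row_zeroed_and_flagged(self):
        dense = np.array([[0, 0, 0, 0], [1, 2, 3, 4], [5, 1, 0, 2]])
        m = AccessibilityMatrix(sp.csr_matrix(dense), ["pz", "pv", "pw"], list("abcd"))
        z = markers.zscore_matrix(m, [0, 0, 1, 1], {0: ["pz", "pv"]})
        assert z.flagged_rows == ["0:pz"]
        assert (z.values.loc["0:pz"] == 0).all()

    def test_cells_ordered_by_cluster(self, default_dataset, default_labels):
        m = default_dataset["matrix"]
        tops = {0: [m.peak_ids[0]]}
        z = markers.zscore_matrix(m, default_labels, tops)
        assert (np.diff(z.cell_labels) >= 0).all()

    def test_planted_markers_elevated_in_own_cluster(self, default_dataset, default_labels):
        """Markers are higher inside their cluster for >= 95% of planted rows."""
        g = default_dataset["genome"]
        m = default_dataset["matrix"]
        mapping = majority_cluster_map(default_labels, m.cell_ids, default_dataset["truth"])
        lists = {lab: g.cluster_specific[mapping[lab]] for lab in mapping}
        z = markers.zscore_matrix(m, default_labels, lists)
        ok = 0
        total = 0
        labels_sorted = z.cell_labels
        for rid in z.values.index:
            lab = z.row_cluster[rid]
            inside = z.values.loc[rid].to_numpy()[labels_sorted == lab]
            outside = z.values.loc[rid].to_numpy()[labels_sorted != lab]
            total += 1
            if inside.mean() > 0 > outside.mean():
                ok += 1
        assert ok / total >= 0.95


class TestScanMotifs:
    def motif(self):
        pfm = np.full((4, 6), 0.02)
        for j, b in enumerate("ACGTAC"):
            pfm["ACGT".index(b), j] = 0.94
        return markers.MotifModel("m", pfm)

    def test_consensus_hits_at_consensus_threshold(self):
        m = self.motif()
        m.threshold = m.consensus_score
        hits = markers.scan_motifs({"s": "TTTT" + m.consensus + "TTTT"}, m)
        assert hits["s"] >= 1

    def test_reverse_complement_symmetry(self):
        m = self.motif()
        seq = "GGGG" + m.consensus + "CCCCTTT"
        rc = seq[::-1].translate(str.maketrans("ACGT", "TGCA"))
        a = markers.scan_motifs({"s": seq}, m)
        b = markers.scan_motifs({"s": rc}, m)
        assert a["s"] == b["s"] >= 1

    def test_all_n_sequence_no_hits(self):
        m = self.motif()
        assert markers.scan_motifs({"s": "N" * 50}, m)["s"] == 0

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            markers.scan_motifs({"s": "ACG"}, self.motif())

    def test_planted_peaks_score_hits(self, small_genome):
        seqs = synth.emit_peak_sequences(small_genome, seed=1)
        for name, motif in small_genome.motifs.items():
            hits = markers.scan_motifs(
                {p: seqs[p] for p in small_genome.motif_plan[name]}, motif
            )
            assert (hits >= 1).all()


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,p0,expected",
        [
            (0, 10, 0.3, 1.0),
            (10, 10, 0.5, 2.0**-10),
            (1, 2, 0.5, 0.75),
        ],
    )
    def test_exact_values(self, k, n, p0, expected):
        assert markers.binomial_pvalue(k, n, p0) == pytest.approx(expected, abs=1e-12)

    @given(
        n=st.integers(1, 1000),
        p0=st.floats(0.001, 0.999),
        kf=st.floats(0.0, 1.0),
    )
    def test_matches_summation_oracle(self, n, p0, kf):
        k = int(round(kf * n))
        assert markers.binomial_pvalue(k, n, p0) == pytest.approx(
            exact_binomial_tail(k, n, p0), abs=1e-12
        )

    def test_monotone_in_k(self):
        ps = [markers.binomial_pvalue(k, 50, 0.2) for k in range(51)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            markers.binomial_pvalue(5, 4, 0.1)
        with pytest.raises(ValueError):
            markers.binomial_pvalue(1, 4, 1.5)


class TestEnrichment:
    def hit_table(self):
        # 8 peaks x 2 motifs; motif A hits peaks 0-3, motif B hits peak 7 only
        return pd.DataFrame(
            {"A": [1, 2, 1, 1, 0, 0, 0, 0], "B": [0, 0, 0, 0, 0, 0, 0, 3]},
            index=[f"p{i}" for i in range(8)],
        )

    def test_enriched_motif_low_p(self):
        res = markers.motif_enrichment(
            self.hit_table(), {0: ["p0", "p1", "p2", "p3"]}, background=0.1
        )
        res = res.set_index("motif")
        assert res.loc["A", "p"] == pytest.approx(0.1**4, rel=1e-9)
        assert res.loc["B", "p"] == 1.0

    def test_complement_background(self):
        res = markers.motif_enrichment(self.hit_table(), {0: ["p0", "p1", "p2", "p3"]})
        res = res.set_index("motif")
        assert res.loc["A", "p0"] == 0.0  # no A hits among p4..p7
        assert res.loc["A", "degenerate_background"]
        assert res.loc["B", "p0"] == pytest.approx(0.25)

    def test_bh_adjustment_present(self):
        res = markers.motif_enrichment(
            self.hit_table(), {0: ["p0", "p1"]}, background=0.5
        )
        assert "q" in res.columns and (res["q"] >= res["p"] - 1e-12).all()
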