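"""Chromosome-level statistics: tau, contact enrichment, ChIP, amplicons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from karyoevo.errors import KaryoevoError, TableFormatError
from karyoevo.features import (ContactMatrix, amplicon_expression,
                               contact_enrichment, relative_chip_level, tau)


# -- tau --------------------------------------------------------------------

def _expr(rows, tissues=None):
    genes = [f"g{i}" for i in range(len(rows))]
    tissues = tissues or [f"t{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, index=genes, columns=tissues)


def test_tau_worked_examples():
    # constant profile -> 0; single-tissue -> 1; (8,2,2) -> 0.75
    values = tau(_expr([[5, 5, 5], [7, 0, 0], [8, 2, 2]]))
    assert values["g0"] == pytest.approx(0.0)
    assert values["g1"] == pytest.approx(1.0)
    assert values["g2"] == pytest.approx(0.75)  # (0 + .75 + .75) / 2


def test_tau_excludes_all_zero_genes():
    with pytest.warns(UserWarning, match="all-zero"):
        values = tau(_expr([[0, 0, 0], [1, 2, 3]]))
    assert list(values.index) == ["g1"]


def test_tau_requires_two_tissues():
    with pytest.raises(KaryoevoError, match="two tissues"):
        tau(_expr([[1.0]], tissues=["t0"]))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
       st.floats(0.01, 100.0))
def test_tau_scale_invariance_and_range(xs, k):
    """tau lies in [0,1] and is invariant under positive rescaling."""
    base = tau(_expr([xs]))["g0"]
    scaled = tau(_expr([[k * x for x in xs]]))["g0"]
    assert 0.0 <= base <= 1.0 + 1e-12
    assert scaled == pytest.approx(base, abs=1e-9)


# -- Hi-C contact enrichment -------------------------------------------------

def _matrix(chrom_bins, contact_triples, **kw):
    bins = pd.DataFrame(
        [(chrom, i, i * 40_000) for chrom, n in chrom_bins
         for i in range(n)], columns=["chrom", "index", "start"])
    contacts = pd.DataFrame(contact_triples,
                            columns=["bin_i", "bin_j", "count"])
    return ContactMatrix(bins, contacts, **kw)


def test_enrichment_null_case():
    """When observed contacts already match the marginal product, every
    log2 ratio is zero (uniform complete graph over three chromosomes)."""
    m = _matrix([("a", 1), ("b", 1), ("c", 1)],
                [(0, 1, 7.0), (0, 2, 7.0), (1, 2, 7.0)])
    result = contact_enrichment(m, exclude_pch=False)
    assert np.allclose(result["log2_ratio"], 0.0)


def test_enrichment_hand_computed():
    """Three chromosomes with trans totals computed by independent
    arithmetic written out in full."""
    m = _matrix([("a", 1), ("b", 1), ("c", 1)],
                [(0, 1, 10.0), (0, 2, 30.0), (1, 2, 60.0)])
    result = contact_enrichment(m, exclude_pch=False).set_index(
        ["chrom_a", "chrom_b"])
    # totals: T_a=40, T_b=70, T_c=90, S=200; raw E: ab=14, ac=18, bc=31.5
    # raw sum 63.5, observed sum 100 -> scale 100/63.5
    scale = 100.0 / 63.5
    for pair, obs, raw in ((("a", "b"), 10.0, 14.0),
                           (("a", "c"), 30.0, 18.0),
                           (("b", "c"), 60.0, 31.5)):
        assert result.loc[pair, "expected"] == pytest.approx(raw * scale)
        assert result.loc[pair, "log2_ratio"] == pytest.approx(
            np.log2(obs / (raw * scale)))
    assert result["expected"].sum() == pytest.approx(
        result["observed"].sum(), rel=1e-9)


def test_enrichment_conservation_and_symmetry():
    """Sum E equals sum O to 1e-6 relative, and mirrored input triples give
    identical output (symmetry)."""
    rng = np.random.default_rng(0)
    chroms = [(f"c{i}", 3) for i in range(6)]
    n_bins = 18
    triples = [(i, j, float(rng.integers(1, 50)))
               for i in range(n_bins) for j in range(i + 1, n_bins)]
    m = _matrix(chroms, triples)
    res = contact_enrichment(m, exclude_pch=False)
    assert abs(res["expected"].sum() - res["observed"].sum()) \
        <= 1e-6 * res["observed"].sum()
    mirrored = _matrix(chroms, [(j, i, c) for i, j, c in triples])
    res2 = contact_enrichment(mirrored, exclude_pch=False)
    pd.testing.assert_frame_equal(res, res2)


def test_enrichment_uniform_null_is_flat():
    """A seeded uniform random symmetric matrix over 20 chromosomes has mean
    |log2 ratio| below 0.05 (law of large numbers)."""
    rng = np.random.default_rng(42)
    chroms = [(f"c{i:02d}", 8) for i in range(20)]
    n_bins = 160
    triples = [(i, j, float(rng.uniform(50, 60)))
               for i in range(n_bins) for j in range(i + 1, n_bins)]
    res = contact_enrichment(_matrix(chroms, triples), exclude_pch=False)
    assert np.abs(res["log2_ratio"]).mean() < 0.05


def test_enrichment_pch_masking(tmp_path):
    """Masked pericentromeric bins drop out of the observed counts."""
    m = _matrix([("a", 2), ("b", 1), ("c", 1)],
                [(0, 2, 5.0), (1, 2, 5.0), (0, 3, 5.0), (1, 3, 5.0),
                 (2, 3, 5.0)])
    bed = tmp_path / "pch.bed"
    bed.write_text("a\t40000\t80000\n")  # masks bin index 1 of chromosome a
    m.mask_from_bed(bed)
    assert list(m.bins["masked"]) == [False, True, False, False]
    res = contact_enrichment(m, exclude_pch=True).set_index(
        ["chrom_a", "chrom_b"])
    assert res.loc[("a", "b"), "observed"] == 5.0  # bin 1 contribution gone
    full = contact_enrichment(m, exclude_pch=False).set_index(
        ["chrom_a", "chrom_b"])
    assert full.loc[("a", "b"), "observed"] == 10.0


def test_enrichment_zero_trans_chromosome_undefined():
    m = _matrix([("a", 1), ("b", 1), ("c", 1), ("d", 1)],
                [(0, 1, 4.0), (0, 2, 4.0), (1, 2, 4.0)])
    res = contact_enrichment(m, exclude_pch=False).set_index(
        ["chrom_a", "chrom_b"])
    assert np.isnan(res.loc[("a", "d"), "expected"])
    assert np.isnan(res.loc[("a", "d"), "log2_ratio"])


def test_enrichment_requires_two_chromosomes():
    with pytest.raises(KaryoevoError, match="at least 2"):
        contact_enrichment(_matrix([("a", 4)], [(0, 1, 3.0)]))


# -- ChIP windows -----------------------------------------------------------

def _track(ratios_by_class):
    rows = []
    pos = 0
    for annotation, ratios in ratios_by_class.items():
        for r in ratios:
            rows.append(("chr1", pos, pos + 10_000, r, annotation))
            pos += 10_000
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio",
                                       "annotation"])


def test_relative_chip_level_examples():
    same = _track({"satellite": [0.5, 1.5], "unique": [0.5, 1.5]})
    assert relative_chip_level(same, "satellite") == pytest.approx(1.0)
    strong = _track({"satellite": [2.0, 2.0], "unique": [0.5, 0.5]})
    assert relative_chip_level(strong, "satellite") == pytest.approx(4.0)


def test_relative_chip_level_order_invariance():
    track = _track({"satellite": [1.0, 3.0], "unique": [0.5, 1.5]})
    shuffled = track.iloc[::-1].reset_index(drop=True)
    assert relative_chip_level(track, "satellite") == \
        relative_chip_level(shuffled, "satellite")


def test_relative_chip_level_errors():
    with pytest.raises(KaryoevoError, match="no windows annotated"):
        relative_chip_level(_track({"unique": [1.0]}), "satellite")
    with pytest.raises(KaryoevoError, match="unique"):
        relative_chip_level(_track({"satellite": [1.0]}), "satellite")
    with pytest.raises(KaryoevoError, match="zero"):
        relative_chip_level(_track({"satellite": [1.0],
                                    "unique": [0.0, 0.0]}), "satellite")
    overlapping = pd.DataFrame(
        [("chr1", 0, 10_000, 1.0, "unique"),
         ("chr1", 5_000, 15_000, 1.0, "satellite")],
        columns=["chrom", "start", "end", "ratio", "annotation"])
    with pytest.raises(TableFormatError, match="overlapping"):
        relative_chip_level(overlapping, "satellite")


# -- amplicon expression -----------------------------------------------------

def test_amplicon_expression_examples():
    assert amplicon_expression([10, 20, 30], [1000, 1000, 1000]) == \
        pytest.approx(20 / 3000)
    assert amplicon_expression([7], [350]) == pytest.approx(7 / 350)
    assert amplicon_expression([0, 0], [100, 100]) == 0.0


def test_amplicon_expression_errors():
    with pytest.raises(KaryoevoError, match="at least one copy"):
        amplicon_expression([], [])
    with pytest.raises(KaryoevoError, match="positive"):
        amplicon_expression([1], [0])
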