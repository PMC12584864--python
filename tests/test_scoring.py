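"""Normalisation, CRISPR scores, significance tests and spacer counting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from slscreen import (
    ComparisonSpec,
    adjust_pvalues,
    build_custom_library,
    count_spacers,
    gene_crispr_score,
    normalize_counts,
    sgrna_zscores,
    significance_test,
)
from slscreen.scoring import P_FLOOR, CrisprScores


@pytest.fixture
def lib4():
    return build_custom_library(["GA", "GB"], [], 2, 2, seed=1)


def _matrix(lib, data):
    return pd.DataFrame(data, index=pd.Index(lib.sgrna_ids, name="sgrna_id"))


def test_fraction_normalization_definition(lib4):
    m = _matrix(lib4, {"s1": [10, 30, 60, 0, 0, 0]})
    out = normalize_counts(m, "fraction")
    assert list(out["s1"][:3]) == [0.1, 0.3, 0.6]


def test_median_ratio_identical_columns_scale_equally(lib4):
    m = _matrix(lib4, {"s1": [5, 9, 2, 7, 1, 3], "s2": [5, 9, 2, 7, 1, 3]})
    out = normalize_counts(m, "median_ratio")
    pd.testing.assert_series_equal(out["s1"], out["s2"], check_names=False)


def brute_force_median_ratio_factors(values):
    """Independent oracle: per-column median of count/row-geomean."""
    factors = []
    keep = [row for row in values if all(v > 0 for v in row)]
    for j in range(len(values[0])):
        ratios = []
        for row in keep:
            geomean = np.prod(row) ** (1.0 / len(row))
            ratios.append(row[j] / geomean)
        factors.append(float(np.median(ratios)))
    return factors


def test_median_ratio_matches_brute_force_oracle():
    rng = np.random.default_rng(0)
    lib = build_custom_library([f"G{i}" for i in range(15)], [], 2, 0, seed=2)
    values = rng.integers(1, 1000, size=(30, 4))
    m = _matrix(lib, {f"s{j}": values[:, j] for j in range(4)})
    out = normalize_counts(m, "median_ratio")
    factors = brute_force_median_ratio_factors(values.tolist())
    expected = values / np.array(factors)
    assert np.allclose(out.to_numpy(), expected, rtol=1e-12, atol=1e-12)


@pytest.mark.parametrize("method", ["fraction", "rpm", "median_ratio", "control_scaled"])
def test_scaling_one_sample_leaves_abundances_unchanged(lib4, method):
    """Sequencing one sample deeper must not move relative abundances.

    For fraction/rpm/control_scaled the table is exactly unchanged; the
    median-ratio geometric-mean reference absorbs a depth change as one
    global factor, so there every cross-sample ratio is preserved instead.
    """
    rng = np.random.default_rng(3)
    m = _matrix(lib4, {f"s{j}": rng.integers(1, 500, 6) for j in range(3)})
    scaled = m.copy()
    scaled["s1"] = scaled["s1"] * 7
    a = normalize_counts(m, method, lib4).to_numpy()
    b = normalize_counts(scaled, method, lib4).to_numpy()
    if method == "median_ratio":
        ratio = b / a
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-12)
    else:
        assert np.allclose(a, b, rtol=1e-12)


def test_normalization_rejects_degenerate_input(lib4):
    with pytest.raises(ValueError, match="empty"):
        normalize_counts(pd.DataFrame())
    m = _matrix(lib4, {"s1": [1, 2, 3, 4, 5, 6], "dead": [0] * 6})
    with pytest.raises(ValueError, match="dead"):
        normalize_counts(m, "fraction")


def test_zscores_identities(lib4):
    rng = np.random.default_rng(4)
    m = _matrix(lib4, {f"s{j}": rng.random(6) for j in range(5)})
    m.iloc[0] = 0.25  # constant row
    z, flags = sgrna_zscores(m)
    assert (z.iloc[0] == 0).all() and flags.iloc[0]
    nondegenerate = z.iloc[1:]
    assert np.allclose(nondegenerate.mean(axis=1), 0, atol=1e-12)
    assert np.allclose(nondegenerate.std(axis=1, ddof=1), 1, atol=1e-12)


def test_zscores_two_samples():
    m = pd.DataFrame({"a": [1.0], "b": [2.0]}, index=["sg"])
    z, _ = sgrna_zscores(m)
    assert np.allclose(z.to_numpy(), [[-np.sqrt(0.5), np.sqrt(0.5)]])
    with pytest.raises(ValueError, match="two samples"):
        sgrna_zscores(m[["a"]])


def _cs_fixture(lib4, cond1, cond2, pseudocount=0.5):
    """Two sgRNAs of gene GA with chosen post-pseudocount abundances.

    A filler column value pins the global rescaling factor to exactly 1.
    """
    pre1 = [v - pseudocount for v in cond1]
    pre2 = [v - pseudocount for v in cond2]
    n_rows = 3
    filler = (2 * (1e6 / n_rows) * n_rows - sum(pre1) - sum(pre2)) / 2
    m = pd.DataFrame(
        {"c1": pre1 + [filler], "c2": pre2 + [filler]},
        index=pd.Index(["GA_sg1", "GA_sg2", "NT_sg1"], name="sgrna_id"),
    )
    comp = ComparisonSpec("WT", ("c1",), ("c2",))
    return gene_crispr_score(m, comp, lib4, pseudocount=pseudocount)


def test_crispr_score_cancellation(lib4):
    scores = _cs_fixture(lib4, [2.0, 8.0], [4.0, 4.0])
    row = scores.gene_scores.set_index("gene").loc["GA"]
    assert row["cs"] == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(
        sorted(scores.sgrna_logratios[:2]), [-1.0, 1.0], atol=1e-9
    )


def test_crispr_score_uniform_fourfold(lib4):
    scores = _cs_fixture(lib4, [4.0, 4.0], [1.0, 1.0])
    assert scores.gene_scores.set_index("gene").loc["GA", "cs"] == pytest.approx(2.0, abs=1e-9)


def test_crispr_score_antisymmetric_under_swap(lib4):
    rng = np.random.default_rng(5)
    m = _matrix(lib4, {f"s{j}": rng.integers(10, 1000, 6).astype(float) for j in range(4)})
    comp = ComparisonSpec("MUT", ("s0", "s1"), ("s2", "s3"))
    fwd = gene_crispr_score(m, comp, lib4).gene_scores.set_index("gene")["cs"]
    rev = gene_crispr_score(m, comp.swapped(), lib4).gene_scores.set_index("gene")["cs"]
    assert np.allclose(fwd, -rev, atol=1e-12)


def _fake_scores(lib, logratios):
    lr = pd.Series(logratios)
    gene_of = pd.Series(
        {r.sgrna_id: r.target_gene for r in lib.records}
    ).reindex(lr.index, fill_value="")
    targeted = gene_of != ""
    gs = (
        lr[targeted]
        .groupby(gene_of[targeted])
        .agg(cs="mean", n_sgrnas="size")
        .reset_index(names="gene")
    )
    return CrisprScores(gs, lr, gene_of)


def test_ttest_on_symmetric_logratios_is_null(lib4):
    scores = _fake_scores(
        lib4, {"GA_sg1": -1.0, "GA_sg2": 1.0, "GB_sg1": 0.3, "GB_sg2": 0.4}
    )
    p = significance_test(scores, "A", lib4)
    assert p["GA"] == pytest.approx(1.0)


def test_ttest_zero_variance_hits_floor(lib4):
    scores = _fake_scores(lib4, {"GA_sg1": 0.7, "GA_sg2": 0.7})
    assert significance_test(scores, "A", lib4)["GA"] == P_FLOOR


def test_permutation_addone_formula():
    lib = build_custom_library([f"G{i}" for i in range(100)], [], 4, 0, seed=6)
    rng = np.random.default_rng(7)
    lr = {sid: rng.normal(0, 0.1) for sid in lib.sgrna_ids}
    for sid in lib.gene_map()["G0"]:
        lr[sid] = -50.0  # beyond any permuted CS
    scores = _fake_scores(lib, lr)
    p = significance_test(scores, "C", lib, n_perm=999, seed=8)
    assert p["G0"] == pytest.approx(1 / 1000)
    assert (p >= 1 / 1000).all() and (p <= 1.0).all()


def test_ranksum_is_calibrated_under_the_null(lib4):
    """Gene guides drawn from the control distribution give ~uniform p."""
    rng = np.random.default_rng(9)
    lib = build_custom_library(["GX"], [], 4, 100, seed=10)
    pvals = []
    for _ in range(500):
        lr = pd.Series(rng.normal(0, 1, len(lib)), index=lib.sgrna_ids)
        scores = _fake_scores(lib, lr.to_dict())
        pvals.append(significance_test(scores, "B", lib)["GX"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def brute_force_bh(p):
    """Textbook step-up: p_(i) * m / i with right-to-left monotonicity."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_adjustment_matches_brute_force():
    rng = np.random.default_rng(11)
    for _ in range(20):
        p = rng.random(rng.integers(1, 50))
        assert np.allclose(adjust_pvalues(p), brute_force_bh(p), atol=1e-12)


@pytest.mark.parametrize(
    "p_in, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([0.123], [0.123]),
    ],
)
def test_bh_known_values(p_in, expected):
    assert np.allclose(adjust_pvalues(p_in), expected, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        adjust_pvalues([0.5, 1.5])


def test_count_spacers(tmp_path, small_library):
    from Bio.Seq import reverse_complement

    lib = small_library
    reads = []
    # 100 unambiguous reads cycling through the library, forward strand
    for i in range(100):
        rec = lib.records[i % len(lib)]
        reads.append(f"@r{i}\nTTT{rec.spacer}GGG\n+\n{'I' * 26}")
    # reverse-complement-only read and a two-spacer ambiguous read
    reads.append(
        f"@rc\nAA{reverse_complement(lib.records[0].spacer)}CC\n+\n{'I' * 24}"
    )
    two = lib.records[1].spacer + lib.records[2].spacer
    reads.append(f"@amb\n{two}\n+\n{'I' * 40}")
    fq = tmp_path / "reads.fastq"
    fq.write_text("\n".join(reads) + "\n")

    counts, qc = count_spacers(str(fq), lib)
    assert qc["ambiguous"] == 1
    assert counts.sum() == 101  # 100 cycling + 1 reverse-complement
    assert counts[lib.records[0].sgrna_id] == 100 // len(lib) + 1  # extra revcomp hit
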