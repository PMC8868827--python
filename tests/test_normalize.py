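import numpy as np
import pandas as pd
import pytest

from hrcoreg import normalize, synthetic
from hrcoreg.matrix import (
    ENDOGENOUS, HOUSEKEEPING, NEGATIVE, POSITIVE, CountMatrix,
)
from hrcoreg.normalize import (
    NormalizationError, apply_exclusions, average_replicates,
    background_adjust, housekeeping_normalize, normalize_pipeline,
    positive_control_normalize,
)


def build_matrix(rows, samples=("S1", "S2")):
    """rows: list of (gene, probe_class, counts...)"""
    values = pd.DataFrame(
        {g: list(counts) for g, _, counts in rows},
    ).T
    values.columns = list(samples)
    values.index.name = "gene"
    ann = pd.DataFrame(
        {"probe_class": [cls for _, cls, _ in rows]},
        index=values.index,
    )
    return CountMatrix(values=values, annotation=ann)


def test_background_subtracts_negative_mean_and_clamps():
    """Sample negatives {8, 12} (mean 10): endogenous 15 -> 5, 8 -> 0."""
    m = build_matrix([
        ("G1", ENDOGENOUS, (15, 15)),
        ("G2", ENDOGENOUS, (8, 8)),
        ("NEG_A", NEGATIVE, (8, 0)),
        ("NEG_B", NEGATIVE, (12, 0)),
    ])
    out, bg = background_adjust(m)
    assert bg["S1"] == 10 and bg["S2"] == 0
    assert out.values.loc["G1", "S1"] == 5
    assert out.values.loc["G2", "S1"] == 0  # clamped
    # zero background leaves the other sample unchanged
    assert out.values.loc["G1", "S2"] == 15
    # control rows retained unmodified for audit
    assert out.values.loc["NEG_A", "S1"] == 8


def test_background_requires_negative_controls():
    m = build_matrix([("G1", ENDOGENOUS, (1, 2))])
    with pytest.raises(NormalizationError, match="negative-control"):
        background_adjust(m)


def test_background_output_is_nonnegative(default_study):
    out, _ = background_adjust(default_study.counts)
    assert float(out.values.to_numpy().min()) >= 0.0


def test_positive_control_factors_hand_example():
    """Geometric means 100 and 400: grand mean 250, factors 2.5 / 0.625."""
    m = build_matrix([
        ("G1", ENDOGENOUS, (10, 10)),
        ("POS_A", POSITIVE, (50, 200)),
        ("POS_B", POSITIVE, (200, 800)),
    ])
    out, nf = positive_control_normalize(m)
    assert nf.positive_scale["S1"] == pytest.approx(2.5)
    assert nf.positive_scale["S2"] == pytest.approx(0.625)
    assert out.values.loc["G1", "S1"] == pytest.approx(25.0)
    # identical profiles -> factors 1
    m2 = build_matrix([
        ("G1", ENDOGENOUS, (10, 10)),
        ("POS_A", POSITIVE, (100, 100)),
        ("POS_B", POSITIVE, (400, 400)),
    ])
    out2, nf2 = positive_control_normalize(m2)
    assert (nf2.positive_scale == 1.0).all()
    pd.testing.assert_frame_equal(out2.values, m2.values.astype(float))


def test_positive_control_out_of_range_flags_sample():
    m = build_matrix([
        ("G1", ENDOGENOUS, (10, 10)),
        ("POS_A", POSITIVE, (10, 640)),
        ("POS_B", POSITIVE, (10, 640)),
    ])
    _, nf = positive_control_normalize(m)
    # grand mean 325: factor 32.5 for S1, ~0.5 for S2
    assert "positive_scale_out_of_range" in nf.flags["S1"]
    assert "S2" not in nf.flags


def test_positive_control_zero_count_is_error():
    m = build_matrix([
        ("G1", ENDOGENOUS, (10, 10)),
        ("POS_A", POSITIVE, (0, 100)),
        ("POS_B", POSITIVE, (100, 100)),
    ])
    with pytest.raises(NormalizationError, match="geometric mean"):
        positive_control_normalize(m)


def test_housekeeping_factors_hand_example():
    """Housekeeping means 200 and 100: grand mean 150, factors 0.75 / 1.5."""
    m = build_matrix([
        ("G1", ENDOGENOUS, (40, 40)),
        ("HK1", HOUSEKEEPING, (200, 100)),
    ])
    out, factors = housekeeping_normalize(m)
    assert factors["S1"] == pytest.approx(0.75)
    assert factors["S2"] == pytest.approx(1.5)
    assert out.values.loc["G1", "S1"] == pytest.approx(30.0)
    # housekeeping means now exactly equal across samples
    hk = out.class_values(HOUSEKEEPING)
    assert hk.mean(axis=0).nunique() == 1


def test_housekeeping_scale_invariance():
    """Scaling one sample's counts by k leaves its normalized endogenous
    values unchanged."""
    m = build_matrix([
        ("G1", ENDOGENOUS, (40, 60)),
        ("HK1", HOUSEKEEPING, (200, 100)),
    ])
    k = 3.7
    scaled = m.with_values(m.values.assign(S1=m.values["S1"] * k))
    out1, _ = housekeeping_normalize(m)
    out2, _ = housekeeping_normalize(scaled)
    # ratio endogenous/housekeeping is scale-free; grand mean differs, so
    # compare S1 relative to its own housekeeping level
    r1 = out1.values.loc["G1", "S1"] / out1.class_values(HOUSEKEEPING)["S1"].mean()
    r2 = out2.values.loc["G1", "S1"] / out2.class_values(HOUSEKEEPING)["S1"].mean()
    assert r1 == pytest.approx(r2)


def test_housekeeping_zero_mean_names_sample():
    m = build_matrix([
        ("G1", ENDOGENOUS, (40, 60)),
        ("HK1", HOUSEKEEPING, (0, 100)),
    ])
    with pytest.raises(NormalizationError, match="S1"):
        housekeeping_normalize(m)


def test_exclusions_identity_warning_and_degenerate():
    m = build_matrix([
        ("G1", ENDOGENOUS, (1, 2)),
        ("G2", ENDOGENOUS, (3, 4)),
    ])
    same = apply_exclusions(m, [])
    assert list(same.genes) == ["G1", "G2"]
    with pytest.warns(UserWarning, match="not in matrix"):
        out = apply_exclusions(m, ["G2", "NOPE"])
    assert list(out.genes) == ["G1"]
    empty = apply_exclusions(m, ["G1", "G2"])
    assert empty.values.shape == (0, 2)


def test_panel_exclusion_leaves_168_endogenous(default_study):
    out = apply_exclusions(
        default_study.counts, normalize.TAGSET_EXCLUDED_GENES
    )
    assert len(out.genes_of_class(ENDOGENOUS)) == 168


def test_average_replicates_means_and_groups():
    m = build_matrix(
        [("G1", ENDOGENOUS, (100, 200, 90, 100, 110))],
        samples=("A", "A_r2", "B", "B_r2", "B_r3"),
    )
    sheet = pd.DataFrame(
        {"group": ["tumor"] * 5,
         "replicate_of": ["", "A", "", "B", "B"]},
        index=pd.Index(["A", "A_r2", "B", "B_r2", "B_r3"], name="sample"),
    )
    out, collapsed = average_replicates(m, sheet)
    assert list(out.samples) == ["A", "B"]
    assert out.values.loc["G1", "A"] == 150.0        # mean of pair
    assert out.values.loc["G1", "B"] == 100.0        # three-way mean
    assert (collapsed["replicate_of"] == "").all()


def test_average_replicates_missing_base_is_error():
    m = build_matrix([("G1", ENDOGENOUS, (1, 2))], samples=("A", "A_r2"))
    sheet = pd.DataFrame(
        {"group": ["tumor", "tumor"], "replicate_of": ["", "GONE"]},
        index=pd.Index(["A", "A_r2"], name="sample"),
    )
    with pytest.raises(NormalizationError, match="GONE"):
        average_replicates(m, sheet)


def test_identical_replicates_collapse_to_either_run():
    m = build_matrix([("G1", ENDOGENOUS, (7, 7))], samples=("A", "A_r2"))
    sheet = pd.DataFrame(
        {"group": ["tumor", "tumor"], "replicate_of": ["", "A"]},
        index=pd.Index(["A", "A_r2"], name="sample"),
    )
    out, _ = average_replicates(m, sheet)
    assert out.values.loc["G1", "A"] == 7.0


def test_factor_idempotence(default_study):
    """Re-computing factors on each operation's own output gives exactly 1
    (replicate averaging afterwards perturbs this only at rounding level)."""
    m, _ = background_adjust(default_study.counts)
    m, _ = positive_control_normalize(m)
    _, nf = positive_control_normalize(m)
    assert np.allclose(nf.positive_scale, 1.0)
    m, _ = housekeeping_normalize(m)
    _, hk = housekeeping_normalize(m)
    assert np.allclose(hk, 1.0)


def test_pipeline_recovers_lane_free_means(default_study, normalized):
    """Composing the chain on synthetic data with known lane factors
    recovers the lane-factor-free expression (log-scale correlation of
    normalized values vs true means > 0.95)."""
    truth = default_study.truth["true_mean"]
    norm = normalized.matrix.values
    common_genes = truth.index.intersection(norm.index)
    common_samples = truth.columns.intersection(norm.columns)
    a = np.log1p(truth.loc[common_genes, common_samples].to_numpy().ravel())
    b = np.log1p(norm.loc[common_genes, common_samples].to_numpy().ravel())
    assert np.corrcoef(a, b)[0, 1] > 0.95
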