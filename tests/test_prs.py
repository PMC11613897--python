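"""PRS engine: dosage fallbacks, scoring, group percentiles, thresholds, AUC."""

import numpy as np
import pandas as pd
import pytest

from brcascreen.prs import (PrsModel, assign_percentiles, auc, dosage,
                            read_scoring_file, score_participants,
                            standardize_within_group, top_fraction_flags)


# ---------------------------------------------------------------------------
# dosage fallback chain
# ---------------------------------------------------------------------------

def test_dosage_from_gp_triple():
    assert dosage(gp=(0.1, 0.8, 0.1)) == pytest.approx(1.0)
    assert dosage(gp=(0.8, 0.2, 0.0)) == pytest.approx(0.2)
    assert dosage(gp=(0.0, 0.0, 1.0)) == pytest.approx(2.0)


def test_dosage_gp_must_be_probability_triple():
    with pytest.raises(ValueError):
        dosage(gp=(0.5, 0.5))
    with pytest.raises(ValueError):
        dosage(gp=(0.9, 0.9, 0.9))
    with pytest.raises(ValueError):
        dosage(gp=(-0.1, 1.0, 0.1))


def test_dosage_from_gt_call():
    assert dosage(gt="0/1") == 1.0
    assert dosage(gt="1|1") == 2.0
    assert dosage(gt="0/0") == 0.0
    # index-coded call resolved through the allele pair
    assert dosage(gt="1/1", effect_allele="G", alleles=("A", "G")) == 2.0
    assert dosage(gt="0/1", effect_allele="A", alleles=("A", "G")) == 1.0


def test_dosage_af_fallback_and_errors():
    assert dosage(af_reference=0.25) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        dosage(af_reference=1.5)
    with pytest.raises(ValueError):
        dosage()


def test_dosage_gp_takes_priority_over_gt():
    assert dosage(gp=(0.0, 1.0, 0.0), gt="1/1") == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _model():
    return PrsModel(entries=pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "T"],
            "other_allele": ["G", "T", "C"],
            "effect_weight": [0.5, -0.2, 1.0],
        }
    ))


def test_score_is_weighted_dosage_sum():
    obs = pd.DataFrame(
        [
            # participant P1: GP 1.0 at rs1, GT 2 at rs2, AF fallback at rs3
            {"participant_id": "P1", "variant_id": "rs1",
             "gp0": 0.1, "gp1": 0.8, "gp2": 0.1, "GT": None, "af_reference": 0.5},
            {"participant_id": "P1", "variant_id": "rs2",
             "gp0": None, "gp1": None, "gp2": None, "GT": "1/1",
             "af_reference": 0.5},
            {"participant_id": "P1", "variant_id": "rs3",
             "gp0": None, "gp1": None, "gp2": None, "GT": None,
             "af_reference": 0.25},
            {"participant_id": "P2", "variant_id": "rs1",
             "gp0": 1.0, "gp1": 0.0, "gp2": 0.0, "GT": None, "af_reference": 0.5},
        ]
    )
    s = score_participants(_model(), obs, callability_max_missing=None)
    # P1: 0.5*1.0 + (-0.2)*2 + 1.0*0.5 = 0.6; P2: 0
    assert s["P1"] == pytest.approx(0.5 * 1.0 - 0.2 * 2.0 + 1.0 * 0.5)
    assert s["P2"] == pytest.approx(0.0)


def test_score_linearity_in_weights():
    rng = np.random.default_rng(3)
    obs = pd.DataFrame(
        {
            "participant_id": np.repeat([f"P{i}" for i in range(5)], 3),
            "variant_id": ["rs1", "rs2", "rs3"] * 5,
            "gp0": 0.0, "gp1": 0.0, "gp2": 0.0,
        }
    )
    d = rng.integers(0, 3, size=15).astype(float)
    obs["gp1"] = (d == 1).astype(float)
    obs["gp2"] = (d == 2).astype(float)
    obs["gp0"] = 1.0 - obs["gp1"] - obs["gp2"]
    m1 = _model()
    m2 = PrsModel(entries=m1.entries.assign(
        effect_weight=2.0 * m1.entries["effect_weight"]))
    s1 = score_participants(m1, obs, callability_max_missing=None)
    s2 = score_participants(m2, obs, callability_max_missing=None)
    assert np.allclose(s2.to_numpy(), 2.0 * s1.to_numpy())


def test_low_callability_variant_dropped():
    # rs3 lacks both GP and GT for all participants -> dropped under the
    # default 10% threshold, so af_reference never gets used
    rows = []
    for i in range(20):
        rows.append({"participant_id": f"P{i}", "variant_id": "rs1",
                     "gp0": 0.0, "gp1": 1.0, "gp2": 0.0})
        rows.append({"participant_id": f"P{i}", "variant_id": "rs3",
                     "gp0": None, "gp1": None, "gp2": None,
                     "af_reference": 0.5})
    obs = pd.DataFrame(rows)
    s = score_participants(_model(), obs)
    assert np.allclose(s.to_numpy(), 0.5)  # only rs1 contributes
    s_nofilter = score_participants(_model(), obs, callability_max_missing=None)
    assert np.allclose(s_nofilter.to_numpy(), 0.5 + 1.0 * 1.0)


def test_unknown_variant_ignored_with_warning(caplog):
    obs = pd.DataFrame(
        [{"participant_id": "P1", "variant_id": "rs999",
          "gp0": 0.0, "gp1": 1.0, "gp2": 0.0},
         {"participant_id": "P1", "variant_id": "rs1",
          "gp0": 0.0, "gp1": 1.0, "gp2": 0.0}]
    )
    with caplog.at_level("WARNING"):
        s = score_participants(_model(), obs, callability_max_missing=None)
    assert s["P1"] == pytest.approx(0.5)
    assert any("absent from the scoring model" in r.message for r in caplog.records)


def test_model_validation():
    with pytest.raises(ValueError):
        PrsModel(entries=pd.DataFrame({"variant_id": ["a"]}))
    bad = _model().entries.copy()
    bad.loc[1, "variant_id"] = "rs1"
    with pytest.raises(ValueError, match="duplicate"):
        PrsModel(entries=bad)


def test_read_scoring_file(tmp_path):
    path = tmp_path / "score.txt"
    path.write_text(
        "# PGS Catalog scoring file\n"
        "# genome_build = GRCh37\n"
        "rsID\teffect_allele\tother_allele\teffect_weight\n"
        "rs1\tA\tG\t0.5\n"
        "rs2\tC\tT\t-0.25\n"
    )
    model = read_scoring_file(path)
    assert model.build == "GRCh37"
    assert len(model) == 2
    assert list(model.entries["variant_id"]) == ["rs1", "rs2"]
    assert model.entries["effect_weight"].tolist() == [0.5, -0.25]


# ---------------------------------------------------------------------------
# percentiles and thresholds
# ---------------------------------------------------------------------------

def test_percentiles_four_distinct_scores():
    scores = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c", "d"],
            "genetic_group": ["Europe"] * 4,
            "raw_score": [0.1, 0.4, 0.2, 0.9],
        }
    )
    out = assign_percentiles(scores)
    assert out["percentile"].tolist() == [25.0, 75.0, 50.0, 100.0]


def test_percentiles_ties_get_average_rank():
    scores = pd.DataFrame(
        {
            "participant_id": ["a", "b", "c", "d"],
            "genetic_group": ["Europe"] * 4,
            "raw_score": [0.1, 0.5, 0.5, 0.9],
        }
    )
    out = assign_percentiles(scores)
    # tied ranks (2,3) average to 2.5 -> 62.5
    assert out["percentile"].tolist() == [25.0, 62.5, 62.5, 100.0]


def test_percentiles_singleton_group_is_100():
    scores = pd.DataFrame(
        {"participant_id": ["a"], "genetic_group": ["Oceania"],
         "raw_score": [0.0]}
    )
    assert assign_percentiles(scores)["percentile"].tolist() == [100.0]


def test_percentiles_independent_across_groups():
    """Concatenating a second group never changes the first group's ranks."""
    g1 = pd.DataFrame(
        {"participant_id": [f"e{i}" for i in range(6)],
         "genetic_group": "Europe",
         "raw_score": [0.3, -1.0, 2.0, 0.1, 0.2, 5.0]}
    )
    g2 = pd.DataFrame(
        {"participant_id": [f"a{i}" for i in range(4)],
         "genetic_group": "Africa",
         "raw_score": [100.0, 200.0, 300.0, 400.0]}
    )
    alone = assign_percentiles(g1)
    combined = assign_percentiles(pd.concat([g1, g2], ignore_index=True))
    merged = combined[combined["genetic_group"] == "Europe"]
    assert merged["percentile"].tolist() == alone["percentile"].tolist()


def test_top_fraction_strict_boundary():
    pct = np.array([80.0, 90.0, 90.0001, 95.0, 100.0])
    flags = top_fraction_flags(pct, 0.10)
    assert flags.tolist() == [False, False, True, True, True]
    with pytest.raises(ValueError):
        top_fraction_flags(pct, 0.0)
    with pytest.raises(ValueError):
        top_fraction_flags(pct, 1.0)


def test_top_half_splits_even_group_evenly():
    n = 1000
    scores = pd.DataFrame(
        {"participant_id": [str(i) for i in range(n)],
         "genetic_group": "Europe",
         "raw_score": np.random.default_rng(0).normal(size=n)}
    )
    pct = assign_percentiles(scores)["percentile"]
    flags = top_fraction_flags(pct, 0.5)
    assert flags.sum() == n // 2


def test_standardize_within_group_reference_mask():
    scores = pd.DataFrame(
        {"participant_id": list("abcd"),
         "genetic_group": "Europe",
         "raw_score": [0.0, 1.0, 2.0, 10.0]}
    )
    ref = pd.Series([True, True, True, False], index=scores.index)
    z = standardize_within_group(scores, reference_mask=ref)
    # reference moments: mean 1, sd 1
    assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0, 9.0])
    with pytest.raises(ValueError, match="degenerate"):
        standardize_within_group(scores.assign(raw_score=1.0))


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def test_auc_brute_force_small():
    scores = [0.1, 0.4, 0.35, 0.8, 0.8, 0.2]
    labels = [False, True, False, True, False, True]
    # brute-force pairwise comparison oracle
    cases = [s for s, y in zip(scores, labels) if y]
    controls = [s for s, y in zip(scores, labels) if not y]
    num = sum(1.0 if c > d else 0.5 if c == d else 0.0
              for c in cases for d in controls)
    assert auc(scores, labels) == pytest.approx(num / (len(cases) * len(controls)))


def test_auc_extremes_and_errors():
    assert auc([1, 2, 3, 4], [False, False, True, True]) == 1.0
    assert auc([4, 3, 2, 1], [False, False, True, True]) == 0.0
    assert auc([1, 1, 1, 1], [False, True, False, True]) == 0.5
    with pytest.raises(ValueError):
        auc([1.0, 2.0], [True, True])


def test_auc_matches_sklearn_oracle():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(5)
    y = rng.random(400) < 0.3
    s = rng.normal(size=400) + y.astype(float)
    assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
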