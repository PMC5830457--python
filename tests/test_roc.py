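import numpy as np
import pytest

from hccscreen import (
    ScoredCohort,
    auc,
    auc_scores,
    cutoff_at_sensitivity,
    cutoff_at_specificity,
    roc_curve,
    sens_spec_at_cutoff,
)

from conftest import brute_force_auc


def test_sens_spec_extremes():
    sc = ScoredCohort([0.1, 0.4, 0.6, 0.9], [0, 0, 1, 1])
    assert sens_spec_at_cutoff(sc, -1.0) == (1.0, 0.0)
    assert sens_spec_at_cutoff(sc, 2.0) == (0.0, 1.0)


def test_single_class_rejected():
    with pytest.raises(ValueError):
        sens_spec_at_cutoff(ScoredCohort([0.1, 0.2], [1, 1]), 0.5)


def test_curve_endpoints_and_monotonicity(rng):
    for _ in range(20):
        n = int(rng.integers(4, 60))
        scores = rng.choice(rng.normal(size=5), size=n)  # force ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        curve = roc_curve(ScoredCohort(scores, labels))
        assert curve.sensitivity[0] == 0 and curve.specificity[0] == 1
        assert curve.sensitivity[-1] == 1 and curve.specificity[-1] == 0
        assert (np.diff(curve.sensitivity) >= 0).all()
        assert (np.diff(curve.specificity) <= 0).all()


def test_perfect_separation_curve_and_auc():
    sc = ScoredCohort([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0])
    curve = roc_curve(sc)
    assert any(
        s == 1 and p == 1 for s, p in zip(curve.sensitivity, curve.specificity)
    )
    assert auc(curve) == 1.0


def test_constant_scores_two_corners_auc_half():
    sc = ScoredCohort([0.5] * 6, [1, 0, 1, 0, 0, 1])
    curve = roc_curve(sc)
    assert len(curve.thresholds) == 2
    assert auc(curve) == 0.5


def test_concordant_pair_example():
    sc = ScoredCohort([0.9, 0.3, 0.8, 0.4], [1, 0, 0, 1])
    assert auc_scores(sc) == pytest.approx(0.75)


def test_auc_equals_pairwise_oracle_with_ties(rng):
    """Trapezoid-on-step-curve AUC is exactly the tie-corrected
    Mann-Whitney statistic."""
    for _ in range(200):
        n = int(rng.integers(4, 200))
        scores = rng.choice(np.round(rng.normal(size=8), 2), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        sc = ScoredCohort(scores, labels)
        assert auc_scores(sc) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


def _enumerate_best_specificity(sc, target):
    """Exhaustive oracle: scan every candidate threshold."""
    best = None
    for t in np.concatenate(([np.inf], np.unique(sc.scores))):
        sens, spec = sens_spec_at_cutoff(sc, t)
        if spec >= target and (best is None or sens > best[1] or
                               (sens == best[1] and t < best[0])):
            best = (t, sens, spec)
    return best


def _enumerate_best_sensitivity(sc, target):
    best = None
    for t in np.concatenate(([np.inf], np.unique(sc.scores))):
        sens, spec = sens_spec_at_cutoff(sc, t)
        if sens >= target and (best is None or spec > best[2] or
                               (spec == best[2] and t > best[0])):
            best = (t, sens, spec)
    return best


def test_operating_points_match_exhaustive_enumeration(rng):
    for _ in range(100):
        n = int(rng.integers(4, 50))
        scores = rng.choice(np.round(rng.normal(size=6), 1), size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        sc = ScoredCohort(scores, labels)
        for target in (0.0, 0.5, 0.75, 0.9, 1.0):
            op = cutoff_at_specificity(sc, target)
            t, sens, spec = _enumerate_best_specificity(sc, target)
            assert (op.cutoff, op.sensitivity, op.specificity) == (t, sens, spec)
            op = cutoff_at_sensitivity(sc, target)
            t, sens, spec = _enumerate_best_sensitivity(sc, target)
            assert (op.cutoff, op.sensitivity, op.specificity) == (t, sens, spec)


def test_specificity_floor_examples():
    sc = ScoredCohort([0.1, 0.2, 0.3, 0.4, 0.9], [0, 0, 0, 0, 1])
    op = cutoff_at_specificity(sc, 0.75)
    assert op.cutoff == pytest.approx(0.4) and op.specificity == pytest.approx(0.75)
    op0 = cutoff_at_specificity(sc, 0.0)
    assert op0.sensitivity == 1.0


def test_point_mass_forces_sentinel_and_zero_sensitivity():
    """All negatives scored 1.0: only the +inf sentinel meets a 90%
    specificity floor, so the achieved sensitivity collapses to 0."""
    sc = ScoredCohort([1.0, 1.0, 1.0, 1.0, 1.0, 1.0], [0, 0, 0, 0, 1, 1])
    op = cutoff_at_specificity(sc, 0.9)
    assert op.cutoff == np.inf
    assert op.sensitivity == 0.0 and op.specificity == 1.0


def test_sensitivity_floor_examples():
    sc = ScoredCohort([0.9, 0.8, 0.7, 0.6, 0.1], [1, 1, 1, 1, 0])
    op = cutoff_at_sensitivity(sc, 0.75)
    assert op.cutoff == pytest.approx(0.7) and op.sensitivity == pytest.approx(0.75)
    op1 = cutoff_at_sensitivity(sc, 1.0)
    assert op1.cutoff == pytest.approx(0.6)  # minimum positive score


def test_two_valued_scorer_collapses_specificity():
    """A scorer with two distinct values whose lower value covers 40% of
    negatives cannot reach a 95% sensitivity floor without calling nearly
    everyone positive."""
    scores = np.array([0.8] * 10 + [0.2] * 10)
    labels = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
    op = cutoff_at_sensitivity(ScoredCohort(scores, labels), 0.95)
    assert op.specificity == 0.0


def test_raising_specificity_target_never_raises_sensitivity(rng):
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, size=80)
    labels[0], labels[1] = 0, 1
    sc = ScoredCohort(scores, labels)
    sens = [
        cutoff_at_specificity(sc, t).sensitivity for t in np.linspace(0, 1, 21)
    ]
    assert (np.diff(sens) <= 1e-12).all()


def test_monotone_transform_invariance(rng):
    scores = rng.normal(size=60)
    labels = rng.integers(0, 2, size=60)
    labels[:2] = [0, 1]
    sc1 = ScoredCohort(scores, labels)
    sc2 = ScoredCohort(np.exp(scores / 2), labels)
    assert auc_scores(sc1) == pytest.approx(auc_scores(sc2), abs=1e-12)
    for t in (0.8, 0.9):
        a = cutoff_at_specificity(sc1, t)
        b = cutoff_at_specificity(sc2, t)
        assert (a.sensitivity, a.specificity) == (b.sensitivity, b.specificity)


def test_curve_csv_export(tmp_path):
    sc = ScoredCohort([0.9, 0.3, 0.8, 0.4], [1, 0, 0, 1])
    path = tmp_path / "roc.csv"
    roc_curve(sc).to_csv(path)
    import pandas as pd

    df = pd.read_csv(path)
    assert list(df.columns) == ["threshold", "sensitivity", "specificity"]
    assert len(df) == 5
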