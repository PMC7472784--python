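"""Z-score population assignment: genotype probabilities, moments, LOO, labels."""

import numpy as np
import pytest

from admixprec.assign import (
    ZScoreAssigner,
    _loglik_moments,
    assignment_z,
    classify_outcome,
    locus_genotype_probs,
    loo_assign,
)
from admixprec.datatypes import GenotypeMatrix, PopulationFit


# ---------------------------------------------------------------------------
# Genotype-class probabilities
# ---------------------------------------------------------------------------

def test_plugin_probs_at_half():
    probs = locus_genotype_probs(5, 10, mode="plugin")
    assert np.allclose(probs, [0.25, 0.5, 0.25])


def test_posterior_probs_closed_form():
    # x=0, n=10: Beta(0.5, 10.5); E[p] = 1/22, E[p^2] = 0.75/132
    probs = locus_genotype_probs(0, 10, mode="posterior")
    ep, ep2 = 1 / 22, 0.75 / 132
    assert probs[2] == pytest.approx(ep2)
    assert probs[1] == pytest.approx(2 * (ep - ep2))
    assert probs.sum() == pytest.approx(1.0)


def test_probs_sum_to_one_everywhere(rng):
    n = rng.integers(2, 400, 50)
    x = (rng.random(50) * n).astype(int)
    for mode in ("plugin", "posterior"):
        probs = locus_genotype_probs(x, n, mode)
        assert np.allclose(probs.sum(axis=-1), 1.0)
        assert (probs >= 0).all()


def test_posterior_converges_to_plugin():
    n = 10**6
    x = int(0.37 * n)
    post = locus_genotype_probs(x, n, "posterior")
    plug = locus_genotype_probs(x, n, "plugin")
    assert np.abs(post - plug).max() < 1e-3


def test_invalid_counts_rejected():
    with pytest.raises(ValueError):
        locus_genotype_probs(1, 0)
    with pytest.raises(ValueError):
        locus_genotype_probs(11, 10)


# ---------------------------------------------------------------------------
# Z statistic
# ---------------------------------------------------------------------------

def test_single_locus_z_closed_form():
    # plugin p=0.5: heterozygote -> z = -1; either homozygote -> z = +1
    het = assignment_z([1.0], [5.0], [10.0], mode="plugin")
    assert het.z == pytest.approx(-1.0)
    assert het.accepted
    for hom in (0.0, 2.0):
        fit = assignment_z([hom], [5.0], [10.0], mode="plugin")
        assert fit.z == pytest.approx(1.0)


def test_moments_match_monte_carlo(rng):
    probs = locus_genotype_probs(
        np.array([30.0, 80.0, 10.0]), np.array([100.0, 200.0, 50.0]), "posterior"
    )
    e, v = _loglik_moments(probs)
    draws = 100_000
    classes = np.stack(
        [rng.choice(3, size=draws, p=probs[j]) for j in range(3)], axis=1
    )
    ll = np.log(probs[np.arange(3)[None, :], classes]).sum(axis=1)
    mc_se = ll.std() / np.sqrt(draws)
    assert ll.mean() == pytest.approx(e.sum(), abs=3 * mc_se)
    var_se = ll.var() * np.sqrt(2 / draws)  # approximate SE of a variance
    assert ll.var() == pytest.approx(v.sum(), abs=3 * var_se + 1e-3)


def test_missing_loci_dropped_jointly():
    d = np.array([1.0, np.nan, 0.0])
    x = np.array([5.0, 5.0, 2.0])
    n = np.array([10.0, 10.0, 10.0])
    full = assignment_z(d, x, n, mode="plugin")
    trimmed = assignment_z(d[[0, 2]], x[[0, 2]], n[[0, 2]], mode="plugin")
    assert full.z == pytest.approx(trimmed.z)


def test_zero_variance_is_an_error():
    with pytest.raises(ValueError, match="variance"):
        assignment_z([2.0], [10.0], [10.0], mode="plugin")


# ---------------------------------------------------------------------------
# Leave-one-out
# ---------------------------------------------------------------------------

def _world(rng, n_a=12, n_b=12, L=40):
    pa = rng.uniform(0.1, 0.9, L)
    pb = rng.uniform(0.1, 0.9, L)
    da = rng.binomial(2, pa, (n_a, L)).astype(float)
    db = rng.binomial(2, pb, (n_b, L)).astype(float)
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    g = GenotypeMatrix(ids, [f"m{j}" for j in range(L)], np.vstack([da, db]))
    labels = {f"a{i}": "A" for i in range(n_a)}
    labels.update({f"b{i}": "B" for i in range(n_b)})
    return g, labels


def _full_counts(g, labels, pop):
    rows = [i for i, s in enumerate(g.sample_ids) if labels.get(s) == pop]
    sub = g.dosages[rows]
    return np.nansum(sub, axis=0), 2.0 * (~np.isnan(sub)).sum(axis=0)


def test_external_query_sees_full_reference(rng):
    g, labels = _world(rng)
    labels_without_a0 = {k: v for k, v in labels.items() if k != "a0"}
    out = loo_assign(g, labels_without_a0, query_ids=["a0"])[0]
    # a0 is now external, so its fit against A uses the full (a1..) counts
    x, n = _full_counts(g, labels_without_a0, "A")
    manual = assignment_z(g.dosages[0], x, n, population="A")
    assert out.fit_for("A").z == pytest.approx(manual.z)


def test_member_loo_differs_from_full_reference(rng):
    g, labels = _world(rng)
    loo = loo_assign(g, labels, query_ids=["a0"])[0]
    x, n = _full_counts(g, labels, "A")
    non_loo = assignment_z(g.dosages[0], x, n, population="A")
    assert loo.fit_for("A").z != pytest.approx(non_loo.z)
    # against the other population the query is external: identical fits
    xb, nb = _full_counts(g, labels, "B")
    assert loo.fit_for("B").z == pytest.approx(
        assignment_z(g.dosages[0], xb, nb, population="B").z
    )


def test_two_member_population_leaves_one(rng):
    g, labels = _world(rng, n_a=2)
    out = loo_assign(g, labels, query_ids=["a0"])[0]
    # reference for A is the single remaining individual: counts from a1 only
    d1 = g.dosages[1]
    manual = assignment_z(
        g.dosages[0], d1, np.full(len(d1), 2.0), population="A"
    )
    assert out.fit_for("A").z == pytest.approx(manual.z)


def test_loo_effect_shrinks_with_reference_size(rng):
    deltas = []
    for n_a in (5, 30, 200):
        g, labels = _world(rng, n_a=n_a)
        loo = loo_assign(g, labels, query_ids=["a0"])[0].fit_for("A").z
        x, n = _full_counts(g, labels, "A")
        non_loo = assignment_z(g.dosages[0], x, n, population="A").z
        deltas.append(abs(loo - non_loo))
    assert deltas[0] > deltas[-1]
    assert deltas[-1] < 0.2


def test_emptying_a_population_is_an_error(rng):
    g, labels = _world(rng, n_a=1)
    with pytest.raises(ValueError, match="empties"):
        loo_assign(g, labels, query_ids=["a0"])


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def _fit(pop, z, loglik):
    return PopulationFit(
        population=pop,
        loglik=loglik,
        expected_loglik=loglik,
        var_loglik=1.0,
        z=z,
        p_value=0.5,
        accepted=z <= 1.64,
    )


def test_all_rejected_label():
    fits = [_fit("A", 2.0, -50), _fit("B", 3.0, -60)]
    assert classify_outcome(fits, "A").label == "rejected"


def test_unique_true_acceptance_is_concordant():
    fits = [_fit("A", 0.5, -50), _fit("B", 3.0, -60)]
    assert classify_outcome(fits, "A").label == "concordant"


def test_close_likelihoods_are_ambiguous():
    # delta log10 LR = 0.2 < 1 -> ambiguous
    fits = [_fit("A", 0.5, -50.0), _fit("B", 0.7, -50.0 - 0.2 * np.log(10))]
    assert classify_outcome(fits, "A").label == "ambiguous"


def test_true_population_rejected_while_other_accepted_is_discordant():
    fits = [_fit("A", 2.5, -50), _fit("B", 0.5, -45)]
    assert classify_outcome(fits, "A").label == "discordant"


def test_true_population_beaten_significantly_is_discordant():
    fits = [_fit("A", 0.5, -60.0), _fit("B", 0.6, -60.0 + 2 * np.log(10))]
    assert classify_outcome(fits, "A").label == "discordant"


def test_true_population_wins_significantly_is_concordant():
    fits = [_fit("A", 0.5, -50.0), _fit("B", 0.6, -50.0 - 2 * np.log(10))]
    assert classify_outcome(fits, "A").label == "concordant"


def test_unknown_true_population_rejected():
    with pytest.raises(ValueError, match="not among"):
        classify_outcome([_fit("A", 0.5, -50)], "Z")


# ---------------------------------------------------------------------------
# scikit-learn classifier surface
# ---------------------------------------------------------------------------

def test_sklearn_assigner_predicts_origin(rng):
    L = 120
    pa = rng.uniform(0.05, 0.3, L)
    pb = rng.uniform(0.7, 0.95, L)
    Xa = rng.binomial(2, pa, (60, L)).astype(float)
    Xb = rng.binomial(2, pb, (60, L)).astype(float)
    X = np.vstack([Xa, Xb])
    y = np.array(["A"] * 60 + ["B"] * 60)
    clf = ZScoreAssigner().fit(X, y)
    fresh_a = rng.binomial(2, pa, (10, L)).astype(float)
    pred = clf.predict(fresh_a)
    assert (pred == "A").mean() >= 0.9
    scores = clf.decision_function(fresh_a)
    assert scores.shape == (10, 2)
    assert (scores[:, 0] > scores[:, 1]).all()  # A fits better than B
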