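import numpy as np
import pytest

from mmclonal.contexts import context_index
from mmclonal.errors import DomainError
from mmclonal.signatures import (
    TREATMENT_SIGNATURE,
    default_catalog,
    fit_exposures,
    fit_exposures_batch,
    flag_single_cell_expansion,
    presence_test,
    presence_test_many,
)
from mmclonal.types import SignatureCatalog, Subclone


def grid_oracle_two_signatures(counts, catalog, step=0.001):
    """Independent oracle: 1-simplex grid search of the multinomial loglik."""
    assert len(catalog) == 2
    P = np.clip(catalog.profiles, 1e-300, None)
    best_e, best_ll = None, -np.inf
    for e in np.arange(0.0, 1.0 + step / 2, step):
        mix = e * P[:, 0] + (1 - e) * P[:, 1]
        ll = float(counts @ np.log(np.clip(mix, 1e-300, None)))
        if ll > best_ll:
            best_e, best_ll = e, ll
    return best_e


@pytest.fixture(scope="module")
def catalog():
    return default_catalog()


@pytest.fixture(scope="module")
def two_sig_catalog(catalog):
    return catalog.subset(["BG1", "BG2"])


class TestFitExposures:
    def test_pure_signature_counts_recover_exposure_one(self, catalog):
        counts = catalog.profiles[:, 2] * 960  # exactly proportional
        e, _ = fit_exposures(counts, catalog)
        assert e[2] == pytest.approx(1.0, abs=1e-6)

    def test_expected_mixture_counts_match_grid_oracle(self, two_sig_catalog):
        mix = 0.7 * two_sig_catalog.profiles[:, 0] + 0.3 * two_sig_catalog.profiles[:, 1]
        counts = mix * 10_000
        e, _ = fit_exposures(counts, two_sig_catalog)
        oracle = grid_oracle_two_signatures(counts, two_sig_catalog)
        assert e[0] == pytest.approx(0.7, abs=0.01)
        assert e[0] == pytest.approx(oracle, abs=0.002)

    def test_sampled_mixture_counts_recover_within_sampling_error(self, two_sig_catalog):
        rng = np.random.default_rng(11)
        mix = 0.7 * two_sig_catalog.profiles[:, 0] + 0.3 * two_sig_catalog.profiles[:, 1]
        counts = rng.multinomial(500, mix / mix.sum())
        e, _ = fit_exposures(counts, two_sig_catalog)
        oracle = grid_oracle_two_signatures(counts, two_sig_catalog)
        assert e[0] == pytest.approx(0.7, abs=0.05)
        assert e[0] == pytest.approx(oracle, abs=0.002)

    def test_scaling_counts_leaves_exposures_unchanged(self, catalog):
        rng = np.random.default_rng(4)
        counts = rng.multinomial(300, np.full(96, 1 / 96)).astype(float)
        e1, _ = fit_exposures(counts, catalog)
        e3, _ = fit_exposures(counts * 3, catalog)
        np.testing.assert_allclose(e1, e3, atol=1e-6)

    def test_single_signature_catalog_trivially_one(self, catalog):
        single = catalog.subset(["BG1"])
        counts = np.ones(96)
        e, _ = fit_exposures(counts, single)
        assert e.tolist() == [1.0]

    def test_empty_counts_rejected(self, catalog):
        with pytest.raises(DomainError):
            fit_exposures(np.zeros(96), catalog)

    def test_batch_agrees_with_single_fits(self, catalog):
        rng = np.random.default_rng(8)
        W = rng.dirichlet(np.ones(len(catalog)), size=5)
        spectra = W @ catalog.profiles.T
        counts = np.stack([rng.multinomial(400, s / s.sum()) for s in spectra])
        E, ll = fit_exposures_batch(counts.astype(float), catalog)
        for i in range(5):
            e_i, ll_i = fit_exposures(counts[i].astype(float), catalog)
            assert ll[i] == pytest.approx(ll_i, abs=1e-6)
            np.testing.assert_allclose(E[i], e_i, atol=1e-4)


def _null_counts(rng, catalog, n):
    bg = catalog.drop(TREATMENT_SIGNATURE)
    w = rng.dirichlet(np.ones(len(bg)))
    spec = bg.profiles @ w
    return rng.multinomial(n, spec / spec.sum())


def _target_counts(rng, catalog, n, exposure):
    bg = catalog.drop(TREATMENT_SIGNATURE)
    w = rng.dirichlet(np.ones(len(bg)))
    spec = (1 - exposure) * (bg.profiles @ w)
    spec = spec + exposure * catalog.profiles[:, catalog.index_of(TREATMENT_SIGNATURE)]
    return rng.multinomial(n, spec / spec.sum())


class TestPresenceTest:
    def test_planted_target_rejected_at_005(self, catalog):
        rng = np.random.default_rng(5)
        counts = _target_counts(rng, catalog, 100, 0.3)
        p = presence_test(counts, catalog, TREATMENT_SIGNATURE, n_bootstrap=200, rng=5)
        assert p < 0.05

    def test_null_counts_rarely_rejected(self, catalog):
        rng = np.random.default_rng(3)
        counts = np.stack([_null_counts(rng, catalog, 200) for _ in range(50)])
        ps = presence_test_many(counts, catalog, TREATMENT_SIGNATURE,
                                n_bootstrap=100, rng=3)
        assert np.mean(ps > 0.05) >= 0.9

    def test_degenerate_zero_lr_gives_p_near_one(self, catalog):
        # counts exactly from one background signature: the target adds nothing
        counts = np.round(catalog.profiles[:, 0] * 2000)
        p, lr, _ = presence_test(
            counts, catalog, TREATMENT_SIGNATURE, n_bootstrap=100, rng=1,
            return_details=True,
        )
        assert lr == pytest.approx(0.0, abs=1e-6)
        assert p > 0.5

    def test_power_increases_with_planted_exposure(self, catalog):
        rng = np.random.default_rng(21)
        mean_p = []
        for exposure in (0.0, 0.1, 0.2, 0.4):
            counts = np.stack(
                [_target_counts(rng, catalog, 200, exposure) for _ in range(25)]
            )
            ps = presence_test_many(
                counts, catalog, TREATMENT_SIGNATURE, n_bootstrap=100, rng=21
            )
            mean_p.append(float(np.mean(ps)))
        # stochastically decreasing; the high-exposure end saturates at the
        # bootstrap floor 1/(B+1)
        assert mean_p[0] > mean_p[1] >= mean_p[3]
        assert mean_p[3] < 0.05

    def test_missing_target_rejected(self, catalog):
        with pytest.raises(DomainError):
            presence_test(np.ones(96), catalog, "NOPE", n_bootstrap=10, rng=0)


class TestExpansionFlag:
    def _subclone(self, n):
        return Subclone(id="C1", members=[f"m{i}" for i in range(n)])

    def test_below_25_mutations_not_evaluable(self, catalog):
        rng = np.random.default_rng(2)
        ctxs = list(rng.integers(0, 96, size=24))
        fit = flag_single_cell_expansion(self._subclone(24), ctxs, catalog,
                                         n_bootstrap=50, rng=2)
        assert fit.flagged is None and fit.presence_p is None
        assert fit.n_mutations == 24

    def test_planted_expansion_flagged(self, catalog):
        rng = np.random.default_rng(9)
        counts = _target_counts(rng, catalog, 120, 0.33)
        ctxs = np.repeat(np.arange(96), counts)
        fit = flag_single_cell_expansion(self._subclone(120), ctxs, catalog,
                                         n_bootstrap=200, rng=9)
        assert fit.flagged is True
        assert fit.exposures[TREATMENT_SIGNATURE] > 0.1

    def test_no_planted_target_not_flagged(self, catalog):
        rng = np.random.default_rng(13)
        counts = _null_counts(rng, catalog, 120)
        ctxs = np.repeat(np.arange(96), counts)
        fit = flag_single_cell_expansion(self._subclone(120), ctxs, catalog,
                                         n_bootstrap=200, rng=13)
        assert fit.flagged is False


def test_default_catalog_columns_are_probability_vectors():
    cat = default_catalog()
    assert cat.names[-1] == TREATMENT_SIGNATURE
    np.testing.assert_allclose(cat.profiles.sum(axis=0), 1.0, atol=1e-12)
    assert (cat.profiles >= 0).all()
    # the treatment profile is sparse by construction
    tx = cat.profiles[:, cat.index_of(TREATMENT_SIGNATURE)]
    assert (tx > 0).sum() == 8
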