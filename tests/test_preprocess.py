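import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathdose import (
    FilterConfig,
    GeneSet,
    estimate_dispersion,
    filter_antagonistic,
    filter_invariant,
    filter_pc1,
    transform_counts,
    transform_doses,
)
from pathdose.preprocess import TransformedDataset, apply_filters


class TestTransformDoses:
    def test_log10_of_positive_doses(self):
        d, scale = transform_doses([0.1, 1, 10], use_log10=True)
        assert np.allclose(d, [-1, 0, 1])
        assert scale.pseudo_dose is None

    def test_zero_dose_maps_to_pseudo_dose(self):
        d, scale = transform_doses([0, 0.01, 0.1], use_log10=True)
        assert np.allclose(d, [-3, -2, -1])
        assert scale.pseudo_dose == pytest.approx(0.001)

    def test_natural_scale_is_identity(self):
        d, scale = transform_doses([0, 1, 2], use_log10=False)
        assert np.allclose(d, [0, 1, 2])
        assert scale.kind == "natural"

    def test_all_zero_doses_rejected(self):
        with pytest.raises(ValueError, match="all doses are zero"):
            transform_doses([0, 0], use_log10=True)

    def test_round_trip_back_to_natural(self):
        doses = np.array([0.0, 0.5, 5.0])
        d, scale = transform_doses(doses, use_log10=True)
        back = scale.to_natural(d)
        assert np.allclose(back[1:], doses[1:])
        assert back[0] == pytest.approx(scale.pseudo_dose)

    @given(
        st.lists(st.floats(0.001, 1000), min_size=3, max_size=10, unique=True)
    )
    @settings(max_examples=25, deadline=None)
    def test_log10_preserves_dose_ordering(self, doses):
        d, _ = transform_doses(sorted(doses), use_log10=True)
        assert np.all(np.diff(d) > 0)


class TestDispersion:
    def test_poisson_counts_near_zero_dispersion(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(50, size=(200, 200)).astype(float)
        phi = estimate_dispersion(counts)
        assert np.median(phi) < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(8)
        mu, true_phi = 50.0, 0.2
        r = 1.0 / true_phi
        counts = rng.negative_binomial(r, r / (r + mu), size=(200, 200)).astype(float)
        phi = estimate_dispersion(counts)
        assert 0.1 < np.median(phi) < 0.3

    def test_constant_counts_zero_dispersion(self):
        counts = np.full((5, 10), 7.0)
        phi = estimate_dispersion(counts, shrink=False)
        assert np.all(phi == 0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            estimate_dispersion(np.ones((5, 1)))


class TestTransformCounts:
    def test_closed_form_equal_libraries(self):
        counts = pd.DataFrame(
            np.full((2, 3), 100.0),
            index=["g1", "g2"],
            columns=["a", "b", "c"],
        )
        # pad library to 1e6 with a third gene
        counts.loc["filler"] = 1e6 - 200
        values, weights = transform_counts(counts, np.zeros(3))
        assert np.allclose(values.loc["g1"], np.log2(100.5))
        assert (weights.to_numpy() > 0).all()

    def test_weight_decreases_with_dispersion(self):
        counts = pd.DataFrame(
            np.full((2, 4), 50.0), index=["g1", "g2"], columns=list("abcd")
        )
        _, w0 = transform_counts(counts, np.array([0.0, 0.0]))
        _, w1 = transform_counts(counts, np.array([1.0, 1.0]))
        assert (w0.to_numpy() > w1.to_numpy()).all()

    def test_zero_library_rejected(self):
        counts = pd.DataFrame([[0.0, 5.0]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="zero library"):
            transform_counts(counts, np.zeros(1))


def _make_transformed(values: np.ndarray, genes, doses=None) -> TransformedDataset:
    n = values.shape[1]
    doses = np.arange(n, dtype=float) if doses is None else np.asarray(doses, float)
    samples = [f"S{i}" for i in range(n)]
    from pathdose.preprocess import DoseScale

    return TransformedDataset(
        values=pd.DataFrame(values, index=genes, columns=samples),
        doses=pd.Series(doses, index=samples),
        model_doses=doses,
        dose_scale=DoseScale("natural"),
        omics_type="log_intensity",
    )


class TestFilters:
    cfg = FilterConfig(enable_pc1=True)

    def _background(self, rng, n_genes=40, n=12):
        return rng.normal(0, 1, size=(n_genes, n))

    def test_all_invariant_set_dropped(self):
        rng = np.random.default_rng(0)
        bg = self._background(rng)
        flat = np.tile(np.zeros(12), (5, 1))
        values = np.vstack([bg, flat])
        genes = [f"bg{i}" for i in range(40)] + [f"c{i}" for i in range(5)]
        ds = _make_transformed(values, genes)
        dec = filter_invariant(ds, GeneSet("c", frozenset(genes[40:])), self.cfg)
        assert not dec.keep
        assert dec.statistic == pytest.approx(1.0)

    def test_most_variable_set_kept(self):
        rng = np.random.default_rng(1)
        bg = self._background(rng)
        hot = rng.normal(0, 10, size=(5, 12))
        values = np.vstack([bg, hot])
        genes = [f"bg{i}" for i in range(40)] + [f"h{i}" for i in range(5)]
        ds = _make_transformed(values, genes)
        dec = filter_invariant(ds, GeneSet("h", frozenset(genes[40:])), self.cfg)
        assert dec.keep
        assert dec.statistic == pytest.approx(0.0)

    def test_invariant_boundary_is_strict(self):
        # 10-gene set with exactly half its genes in the low-variance pool:
        # fraction == threshold, strict ">" keeps the set.
        rng = np.random.default_rng(2)
        n = 20
        lowvar = rng.normal(0, 1e-3, size=(5, n))
        highvar = rng.normal(0, 5, size=(5, n))
        bg_low = rng.normal(0, 1e-3, size=(5, n))   # fills the low quantile
        bg_high = rng.normal(0, 5, size=(35, n))
        values = np.vstack([lowvar, highvar, bg_low, bg_high])
        genes = (
            [f"lo{i}" for i in range(5)]
            + [f"hi{i}" for i in range(5)]
            + [f"bg{i}" for i in range(40)]
        )
        ds = _make_transformed(values, genes)
        cfg = dataclasses.replace(self.cfg, low_variance_quantile=0.2)
        dec = filter_invariant(ds, GeneSet("s", frozenset(genes[:10])), cfg)
        assert dec.statistic == pytest.approx(0.5)
        assert dec.keep

    def test_perfectly_anticorrelated_pair_dropped(self):
        x = np.linspace(-1, 1, 12)
        values = np.vstack([x, -x])
        ds = _make_transformed(values, ["up", "dn"])
        dec = filter_antagonistic(ds, GeneSet("s", frozenset(["up", "dn"])), self.cfg)
        assert not dec.keep
        assert dec.statistic == pytest.approx(1.0)

    def test_identical_profiles_kept(self):
        x = np.linspace(-1, 1, 12)
        values = np.vstack([x, x + 0.5, 2 * x])
        ds = _make_transformed(values, ["a", "b", "c"])
        dec = filter_antagonistic(
            ds, GeneSet("s", frozenset(["a", "b", "c"])), self.cfg
        )
        assert dec.keep
        assert dec.statistic == pytest.approx(0.0)

    def test_two_thirds_negative_pairs_dropped(self):
        x = np.linspace(-1, 1, 12)
        rng = np.random.default_rng(3)
        a = x + rng.normal(0, 0.01, 12)
        b = x + rng.normal(0, 0.01, 12)
        c = -x
        ds = _make_transformed(np.vstack([a, b, c]), ["a", "b", "c"])
        dec = filter_antagonistic(
            ds, GeneSet("s", frozenset(["a", "b", "c"])), self.cfg
        )
        assert dec.statistic == pytest.approx(2 / 3)
        assert not dec.keep

    def test_zero_variance_gene_pairs_excluded(self):
        x = np.linspace(-1, 1, 12)
        ds = _make_transformed(np.vstack([x, -x, np.zeros(12)]), ["a", "b", "z"])
        dec = filter_antagonistic(
            ds, GeneSet("s", frozenset(["a", "b", "z"])), self.cfg
        )
        # only the (a, b) pair counts
        assert dec.statistic == pytest.approx(1.0)

    def test_rank_one_set_dropped_by_pc1(self):
        x = np.linspace(-1, 1, 12)
        values = np.vstack([x, 2 * x, -0.5 * x])
        ds = _make_transformed(values, ["a", "b", "c"])
        dec = filter_pc1(ds, GeneSet("s", frozenset(["a", "b", "c"])), self.cfg)
        assert dec.statistic == pytest.approx(1.0)
        assert not dec.keep

    def test_two_orthogonal_genes_kept(self):
        n = 8
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        ds = _make_transformed(np.vstack([a, b]), ["a", "b"])
        dec = filter_pc1(ds, GeneSet("s", frozenset(["a", "b"])), self.cfg)
        assert dec.statistic == pytest.approx(0.5)
        assert dec.keep

    def test_isotropic_noise_kept(self):
        rng = np.random.default_rng(4)
        values = rng.normal(0, 1, size=(4, 200))
        genes = ["a", "b", "c", "d"]
        ds = _make_transformed(values, genes)
        dec = filter_pc1(ds, GeneSet("s", frozenset(genes)), self.cfg)
        assert dec.statistic < 0.5
        assert dec.keep

    def test_small_set_skipped_with_reason(self):
        rng = np.random.default_rng(5)
        ds = _make_transformed(rng.normal(0, 1, (10, 8)), [f"g{i}" for i in range(10)])
        cfg = dataclasses.replace(self.cfg, min_set_size=5)
        decisions = apply_filters(ds, GeneSet("s", frozenset(["g1", "g2"])), cfg)
        assert len(decisions) == 1
        assert decisions[0].reason == "too_small"

    def test_filters_are_pure(self):
        rng = np.random.default_rng(6)
        ds = _make_transformed(rng.normal(0, 1, (20, 10)), [f"g{i}" for i in range(20)])
        gs = GeneSet("s", frozenset(f"g{i}" for i in range(8)))
        d1 = apply_filters(ds, gs, self.cfg)
        d2 = apply_filters(ds, gs, self.cfg)
        assert d1 == d2

    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    @settings(max_examples=20, deadline=None)
    def test_threshold_monotonicity(self, low_thr, high_thr):
        """Raising a filter threshold can only move a set from drop to keep."""
        low_thr, high_thr = sorted([low_thr, high_thr])
        rng = np.random.default_rng(9)
        ds = _make_transformed(
            rng.normal(0, 1, (30, 10)), [f"g{i}" for i in range(30)]
        )
        gs = GeneSet("s", frozenset(f"g{i}" for i in range(10)))
        for fn, field in [
            (filter_invariant, "invariant_gene_fraction"),
            (filter_antagonistic, "negative_correlation_fraction"),
            (filter_pc1, "pc1_variance_fraction"),
        ]:
            lo = fn(ds, gs, dataclasses.replace(self.cfg, **{field: low_thr}))
            hi = fn(ds, gs, dataclasses.replace(self.cfg, **{field: high_thr}))
            if lo.keep:
                assert hi.keep
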