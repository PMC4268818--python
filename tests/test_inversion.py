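"""The two-part inversion: collapse, logarithm, and linear rate recovery."""

import numpy as np
import pytest

from conftest import max_rate_error

from groupphylo import (
    DomainError,
    EdgeSpectrum,
    ModelViolationError,
    PhyloTensor,
    RateSpec,
    SaturationError,
    SpectralVector,
    TreeEdges,
    build_FG,
    collapse,
    edges_from_newick,
    expand,
    forward_spectrum,
    forward_transform,
    invert_tensor,
    log_step,
    make_fixture,
    make_group,
    phylo_tensor,
    recover,
    star_tensor,
    subsets_in_order,
    tensor_from_spectrum,
)


def spectral(P):
    return forward_transform(P)


class TestCollapseExpand:
    def test_star_collapses_to_ones(self, group):
        for n in (2, 3, 4):
            p = collapse(spectral(star_tensor(n, group)))
            assert np.allclose(p.values, 1.0, atol=1e-12)

    def test_two_taxa_binary_closed_form(self):
        G = make_group([2])
        t = 0.42
        P = phylo_tensor(
            G, TreeEdges(2, [frozenset({1})]), RateSpec(G, {frozenset({1}): {(1,): t}})
        )
        p = collapse(spectral(P))
        # u = "0" -> total probability 1; u = "1" -> e^{-2t}
        assert p.values[0] == pytest.approx(1.0, abs=1e-12)
        assert p.values[1] == pytest.approx(np.exp(-2 * t), abs=1e-12)

    def test_trivial_partition_is_total_probability(self, group, rng):
        nwk, rates = make_fixture(4, group, rng)
        P = phylo_tensor(group, edges_from_newick(nwk, 4), rates)
        p = collapse(spectral(P))
        assert p.values[(0,) * 3] == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_with_expand(self, group, rng):
        d = group.order
        vals = rng.normal(size=(d,) * 3) + 1j * rng.normal(size=(d,) * 3)
        p = SpectralVector(group, vals, kind="probability")
        assert np.array_equal(collapse(expand(p)).values, p.values)

    def test_expand_of_ones_is_spectral_star(self, group):
        ones = SpectralVector(group, np.ones((group.order,) * 2), kind="probability")
        from groupphylo.model import spectral_star_values

        assert np.allclose(expand(ones).values, spectral_star_values(3, group))

    def test_off_support_mass_raises(self, group):
        # a non-stationary / non-group-based tensor puts mass on vanishing
        # components
        d = group.order
        vals = np.zeros((d,) * 3)
        vals[(0,) * 3] = 1.0  # point mass, not permutation-invariant
        with pytest.raises(ModelViolationError):
            collapse(spectral(PhyloTensor(group, vals, basis="standard")))


class TestLogStep:
    def test_ones_to_zeros_and_inverse(self, group, rng):
        ones = SpectralVector(group, np.ones((group.order,) * 2), kind="probability")
        assert np.allclose(log_step(ones).values, 0.0)
        x = SpectralVector(
            group, rng.uniform(0.2, 1.0, size=(group.order,) * 2), kind="probability"
        )
        assert np.allclose(np.exp(log_step(x).values), x.values, atol=1e-12)

    def test_saturation_error(self, group):
        vals = np.ones((group.order,) * 2, complex)
        vals[(1,) * 2] = 0.0
        with pytest.raises(SaturationError):
            log_step(SpectralVector(group, vals, kind="probability"))

    def test_branch_cut_warning(self):
        G = make_group([3])
        vals = np.ones((3, 3), complex)
        vals[1, 1] = -0.5 + 1e-12j
        with pytest.warns(UserWarning, match="negative real axis"):
            log_step(SpectralVector(G, vals, kind="probability"))


class TestInversionMatrices:
    def test_binary_two_taxa_self_inverse(self):
        mats = build_FG(make_group([2]), 2)
        F = mats.F[(1,)]
        assert np.allclose(F.real, [[1, 1], [1, -1]], atol=1e-12)
        assert np.allclose(F @ F / 2, np.eye(2), atol=1e-12)

    def test_k3st_channel_formula(self, rng):
        # [F_01]_{(u,v)}^e = (-1)^{|e cap v_1|}: the (0,1) channel only
        # sees the second-factor string
        G = make_group([2, 2])
        n = 4
        mats = build_FG(G, n)
        F01 = mats.F[(0, 1)]
        for row in rng.integers(0, 4 ** (n - 1), size=20):
            idx = np.unravel_index(int(row), (4,) * (n - 1))
            v1 = {j + 1 for j, i in enumerate(idx) if G.element(i)[1] == 1}
            for col, e in enumerate(mats.subsets):
                assert F01[row, col] == pytest.approx((-1) ** len(e & v1), abs=1e-12)

    def test_empty_subset_column_all_ones(self, group):
        mats = build_FG(group, 3)
        for sigma in mats.channels:
            assert np.allclose(mats.F[sigma][:, 0], 1.0, atol=1e-12)

    def test_orthogonality_relations(self, group):
        # G_s F_{s'} = delta_{ss'} 1 on the nonempty-subset block, and the
        # empty row of every G_s annihilates all nonempty columns
        for n in (2, 3, 4):
            mats = build_FG(group, n)
            m = 2 ** (n - 1)
            for s in mats.channels:
                for sp in mats.channels:
                    prod = mats.G[s] @ mats.F[sp]
                    if s == sp:
                        assert np.abs(prod - np.eye(m)).max() < 1e-10
                    else:
                        assert np.abs(prod[1:, 1:]).max() < 1e-10
                        assert np.abs(prod[0, 1:]).max() < 1e-10
                        assert np.abs(prod[1:, 0]).max() < 1e-10
                        assert prod[0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_z3_cross_channel_annihilation(self):
        mats = build_FG(make_group([3]), 3)
        prod = mats.G[(1,)] @ mats.F[(2,)]
        assert np.abs(prod[:, 1:][1:, :]).max() < 1e-10


class TestRecover:
    def test_zero_log_vector(self, group):
        theta = SpectralVector(
            group, np.zeros((group.order,) * 3), kind="log"
        )
        spec = recover(theta)
        assert spec.lambda_total == pytest.approx(0.0, abs=1e-12)
        assert all(a == pytest.approx(0.0, abs=1e-12) for a in spec.rates.values())

    def test_two_taxa_hand_inversion(self):
        G = make_group([2])
        t = 0.3
        theta = SpectralVector(G, np.array([0.0, -2 * t]), kind="log")
        spec = recover(theta)
        assert spec.get(frozenset({1}), (1,)) == pytest.approx(t, abs=1e-12)
        assert spec.lambda_total == pytest.approx(t, abs=1e-12)

    def test_dense_and_matrix_free_agree(self, group, rng):
        nwk, rates = make_fixture(4, group, rng)
        P = phylo_tensor(group, edges_from_newick(nwk, 4), rates)
        theta = log_step(collapse(spectral(P)))
        a = recover(theta, dense=False)
        b = recover(theta, dense=True)
        assert a.lambda_total == pytest.approx(b.lambda_total, abs=1e-10)
        for key in a.rates:
            assert a.rates[key] == pytest.approx(b.rates[key], abs=1e-10)

    def test_full_round_trip(self, group, rng):
        for n in (3, 4, 5):
            nwk, rates = make_fixture(n, group, rng)
            P = phylo_tensor(group, edges_from_newick(nwk, n), rates)
            spec = invert_tensor(P)
            assert max_rate_error(spec, rates) < 1e-9
            assert abs(spec.rate_residual) < 1e-8

    def test_network_round_trip(self, group, rng):
        # the conjugation is one-one for arbitrary split systems too
        edges = TreeEdges(
            4, [frozenset({1, 2}), frozenset({2, 3}), frozenset({3})], network=True
        )
        rates = RateSpec(
            group,
            {
                e: {s: float(rng.uniform(0.05, 0.3)) for s in group.non_identity()}
                for e in edges.edge_subsets
            },
        )
        P = phylo_tensor(group, edges, rates)
        spec = invert_tensor(P)
        assert max_rate_error(spec, rates) < 1e-9

    def test_noisy_input_flagged_not_rejected(self, rng):
        # multinomial noise produces (small) negative recovered rates on
        # zero-rate edges; they are reported, not silently clipped
        from groupphylo import simulate_patterns

        G = make_group([2])
        nwk, rates = make_fixture(5, G, rng)
        P = phylo_tensor(G, edges_from_newick(nwk, 5), rates)
        counts = simulate_patterns(P, 20000, rng)
        with pytest.raises(ModelViolationError):
            invert_tensor(counts.to_tensor())  # strict check sees the noise
        spec = invert_tensor(counts.to_tensor(), vanish_tol=None)
        assert isinstance(spec.has_negative_rates, bool)
        # estimates remain close to truth at this depth
        assert max_rate_error(spec, rates) < 0.2


class TestForwardSpectrum:
    def test_zero_spectrum_all_ones(self, group):
        spec = EdgeSpectrum(group, 3, {}, lambda_total=0.0)
        assert np.allclose(forward_spectrum(spec).values, 1.0)

    def test_two_path_equality(self, group, rng):
        # forward_spectrum(spec) == collapse(transform(phylo_tensor(spec)))
        nwk, rates = make_fixture(4, group, rng)
        P = phylo_tensor(group, edges_from_newick(nwk, 4), rates)
        via_tensor = collapse(spectral(P)).values
        via_spectrum = forward_spectrum(EdgeSpectrum.from_rate_spec(rates, 4)).values
        assert np.abs(via_tensor - via_spectrum).max() < 1e-10

    def test_composition_identity_on_spectra(self, group, rng):
        nwk, rates = make_fixture(4, group, rng)
        spec = EdgeSpectrum.from_rate_spec(rates, 4)
        again = recover(log_step(forward_spectrum(spec)))
        assert again.lambda_total == pytest.approx(spec.lambda_total, abs=1e-10)
        for key, a in spec.rates.items():
            assert again.rates[key] == pytest.approx(a, abs=1e-10)

    def test_tensor_from_spectrum_matches_model(self, group, rng):
        nwk, rates = make_fixture(4, group, rng)
        P = phylo_tensor(group, edges_from_newick(nwk, 4), rates)
        Q = tensor_from_spectrum(EdgeSpectrum.from_rate_spec(rates, 4))
        assert np.abs(P.values - Q.values).max() < 1e-10


class TestEdgeSpectrumSerialization:
    def test_tsv_round_trip(self, group, rng):
        nwk, rates = make_fixture(4, group, rng)
        spec = EdgeSpectrum.from_rate_spec(rates, 4)
        again = EdgeSpectrum.from_tsv(spec.to_tsv(), group, 4)
        assert again.lambda_total == pytest.approx(spec.lambda_total, abs=0)
        assert again.rates == spec.rates

    def test_subset_order_convention(self):
        subs = subsets_in_order(3)
        assert subs[0] == frozenset()
        assert subs[1] == frozenset({1})
        assert subs[2] == frozenset({2})
        assert subs[3] == frozenset({1, 2})
        assert len(subs) == 8


class TestKindGuards:
    def test_wrong_kinds_rejected(self, group):
        prob = SpectralVector(group, np.ones((group.order,) * 2), kind="probability")
        with pytest.raises(DomainError):
            recover(prob)
        logv = log_step(prob)
        with pytest.raises(DomainError):
            log_step(logv)
        with pytest.raises(DomainError):
            expand(logv)
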