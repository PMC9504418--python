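"""GGE biplot: decomposition, polygon geometry, AEA views, ranking."""

import numpy as np
import pytest
from scipy import stats

from metstab import (
    SyntheticConfig,
    TraitMeans,
    cell_means,
    discriminativeness_representativeness,
    fit_gge,
    generate,
    mean_vs_stability,
    rank_by_ideal,
    which_won_where,
    which_won_where_markers,
)
from metstab.exceptions import DegenerateDataError
from conftest import random_means


def _random_model(seed, g=10, e=4):
    data, _ = generate(
        SyntheticConfig(
            g=g, e=e, r=2, interaction_mode="low_rank",
            interaction_rank=min(g, e) - 1,
            interaction_singular_values=tuple(2.0 / (k + 1) for k in range(min(g, e) - 1)),
            error_sd=0.3, seed=seed,
        )
    )
    return fit_gge(cell_means(data, "yield"))


class TestFit:
    def test_rank_one_matrix_fully_explained(self):
        matrix = 5.0 + np.outer([1.0, 2.0, 3.0, 4.0], [0.5, -0.5, 1.0])
        means = TraitMeans("t", list("abcd"), list("xyz"), matrix)
        model = fit_gge(means)
        assert model.explained_2d == pytest.approx(1.0, rel=1e-12)

    def test_published_explained_share(self, yield_means):
        model = fit_gge(yield_means)
        assert 100 * model.explained_2d == pytest.approx(96.23, abs=0.1)

    def test_centering_removes_environment_means(self, rng):
        means = random_means(rng, 6, 4)
        model = fit_gge(means)
        assert model.centered.sum(axis=0) == pytest.approx(np.zeros(4), abs=1e-9)

    def test_markers_match_gram_eigendecomposition(self, rng):
        means = random_means(rng, 8, 4)
        model = fit_gge(means)
        C = model.centered
        evals, evecs = np.linalg.eigh(C.T @ C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert model.singular_values**2 == pytest.approx(evals[: len(model.singular_values)], rel=1e-9)
        G, E = model.markers(1.0)
        recon = G @ E.T
        rank2 = C @ evecs[:, :2] @ evecs[:, :2].T
        assert recon == pytest.approx(rank2, abs=1e-9)

    def test_partition_invariance_of_reconstruction(self, rng):
        means = random_means(rng, 7, 4)
        model = fit_gge(means)
        G0, E0 = model.markers(0.0)
        G1, E1 = model.markers(1.0)
        assert G0 @ E0.T == pytest.approx(G1 @ E1.T, abs=1e-10)

    def test_three_environments_give_three_singular_values(self, yield_means):
        model = fit_gge(yield_means)
        assert len(model.singular_values) == 3
        shares = model.singular_values**2 / (model.singular_values @ model.singular_values)
        assert shares.sum() == pytest.approx(1.0, rel=1e-12)

    def test_zero_matrix_degenerate(self):
        means = TraitMeans("t", list("abc"), list("xy"), np.ones((3, 2)))
        with pytest.raises(DegenerateDataError):
            fit_gge(means)


class TestWhichWonWhere:
    def test_axis_symmetric_square(self):
        G = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
        E = np.array([[1.0, 0.1]])
        part = which_won_where_markers(G, E, ["east", "north", "west", "south"], ["e1"])
        sector = part.environment_sector["e1"]
        assert part.sector_winner[sector] == "east"

    @pytest.mark.parametrize("seed", range(20))
    def test_winner_equals_argmax_inner_product(self, seed):
        model = _random_model(seed)
        part = which_won_where(model)
        G, E = model.genotype_markers, model.environment_markers
        for j, env in enumerate(model.environments):
            best = model.genotypes[int(np.argmax(G @ E[j]))]
            assert part.sector_winner[part.environment_sector[env]] == best

    def test_published_mega_environment(self, yield_means):
        part = which_won_where(fit_gge(yield_means))
        assert (
            part.environment_sector["Gazipur"] == part.environment_sector["Ishwardi"]
        )
        assert part.environment_sector["Barisal"] != part.environment_sector["Gazipur"]
        assert [e for e in ("Gazipur", "Ishwardi")] in [
            sorted(group) for group in part.mega_environments
        ]

    def test_rotation_invariance_of_sectors(self, rng):
        model = _random_model(99)
        G, E = model.genotype_markers, model.environment_markers
        base = which_won_where_markers(G, E, model.genotypes, model.environments)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rot = which_won_where_markers(G @ R.T, E @ R.T, model.genotypes, model.environments)
        for env in model.environments:
            assert (
                base.sector_winner[base.environment_sector[env]]
                == rot.sector_winner[rot.environment_sector[env]]
            )

    def test_collinear_markers_degenerate(self):
        G = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(DegenerateDataError):
            which_won_where_markers(G, G[:1], list("abc"), ["e"])


class TestAEAViews:
    def test_marker_parallel_to_aea_has_zero_deviation(self, yield_means):
        model = fit_gge(yield_means)
        ranking = mean_vs_stability(model)
        # synthetic check: project any marker onto the AEA, deviation of the
        # projected point is zero
        G, E = model.markers(1.0)
        aea = E.mean(axis=0) / np.linalg.norm(E.mean(axis=0))
        parallel = np.outer(G @ aea, aea)
        dev = np.linalg.norm(parallel - np.outer(parallel @ aea, aea), axis=1)
        assert dev == pytest.approx(np.zeros(len(dev)), abs=1e-10)
        assert ranking.stability_deviation.min() >= 0

    def test_most_unstable_hybrid(self, yield_means):
        ranking = mean_vs_stability(fit_gge(yield_means))
        worst = ranking.genotypes[int(np.argmax(ranking.stability_deviation))]
        assert worst == "BRRI35A x BRRI37R"

    def test_projection_tracks_genotype_means(self):
        hits = 0
        for seed in range(30):
            data, _ = generate(
                SyntheticConfig(g=12, e=3, r=2, interaction_mode="low_rank",
                                interaction_rank=2, interaction_singular_values=(1.0, 0.4),
                                error_sd=0.2, seed=seed)
            )
            means = cell_means(data, "yield")
            ranking = mean_vs_stability(fit_gge(means))
            rho = stats.spearmanr(ranking.aea_projection, means.genotype_means).statistic
            hits += rho > 0.9
        assert hits >= 27

    def test_ideal_genotype_ranking(self, yield_means):
        ranking = rank_by_ideal(fit_gge(yield_means))
        assert sorted(ranking.rank) == list(range(1, 27))
        best = ranking.genotypes[int(np.argmin(ranking.distance_to_ideal))]
        assert best == "BRRI hybrid dhan5"
        assert ranking.rank[ranking.genotypes.index("BRRI hybrid dhan5")] == 1

    def test_distances_match_geometry_oracle(self, rng):
        model = _random_model(7)
        ranking = rank_by_ideal(model)
        G, E = model.markers(1.0)
        aea = E.mean(axis=0) / np.linalg.norm(E.mean(axis=0))
        ideal = (G @ aea).max() * aea
        expected = np.sqrt(((G - ideal) ** 2).sum(axis=1))
        assert ranking.distance_to_ideal == pytest.approx(expected, abs=1e-12)


class TestEnvironmentDiagnostics:
    def test_most_discriminating_location(self, yield_means):
        diag = discriminativeness_representativeness(fit_gge(yield_means))
        longest = diag.environments[int(np.argmax(diag.vector_length))]
        assert longest == "Barisal"

    def test_vector_lengths_match_marker_norms(self, rng):
        model = _random_model(3)
        diag = discriminativeness_representativeness(model)
        _, E = model.markers(0.0)
        assert diag.vector_length == pytest.approx(np.linalg.norm(E, axis=1), abs=1e-12)

    def test_representativeness_is_cosine(self, rng):
        model = _random_model(4)
        diag = discriminativeness_representativeness(model)
        assert diag.representativeness == pytest.approx(np.cos(diag.angle_to_aea), abs=1e-12)
        assert np.all(np.abs(diag.representativeness) <= 1.0)
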