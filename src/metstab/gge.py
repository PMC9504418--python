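"""GGE biplot computation and geometry.

GGE removes only the environment main effect: the column-centered matrix
``Y_ij - env_mean_j`` carries genotype main effect plus genotype-by-
environment interaction (G + GE), the two components relevant to cultivar
evaluation.  Its rank-2 SVD gives genotype markers ``U Lambda^f`` and
environment markers ``V Lambda^(1-f)``; the singular-value partition ``f``
only redistributes scale between the two marker sets, leaving the
reconstruction G @ E' invariant.

Views implemented:

* which-won-where — convex hull of genotype markers, rays through the
  origin perpendicular to hull edges partition the plane into sectors
  (the normal cones of the hull vertices); each environment falls in one
  sector and that sector's vertex genotype wins there, so the construction
  is exactly argmax of the marker inner product.
* mean vs stability — projection of genotype markers on the average-
  environment axis (AEA, direction of the mean environment marker) and the
  perpendicular deviation from it.
* discriminativeness vs representativeness — environment vector length and
  cosine of the angle to the AEA.
* ideal-genotype ranking — distance to the point on the AEA at the maximal
  observed projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import TraitMeans
from .exceptions import DegenerateDataError, InsufficientDataError


@dataclass
class GGEModel:
    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray            # g x e, columns sum to zero
    partition_f: float
    singular_values: np.ndarray     # all, descending
    u: np.ndarray                   # g x K left singular vectors
    vt: np.ndarray                  # K x e right singular vectors
    genotype_markers: np.ndarray    # g x 2 at partition_f
    environment_markers: np.ndarray # e x 2 at partition_f
    explained_2d: float

    def markers(self, f: float) -> tuple[np.ndarray, np.ndarray]:
        """Genotype/environment markers for any singular-value partition."""
        s2 = self.singular_values[:2]
        G = self.u[:, :2] * s2**f
        E = self.vt[:2].T * s2 ** (1.0 - f)
        return G, E


@dataclass
class SectorPartition:
    hull_vertices: list[str]            # CCW order
    ray_angles: np.ndarray              # ascending in [0, 2pi)
    sector_winner: dict[int, str]
    environment_sector: dict[str, int]
    mega_environments: list[list[str]]


@dataclass
class GenotypeRanking:
    genotypes: list[str]
    aea_projection: np.ndarray
    stability_deviation: np.ndarray
    distance_to_ideal: np.ndarray | None = None
    rank: np.ndarray | None = None


@dataclass
class EnvironmentDiagnostics:
    environments: list[str]
    vector_length: np.ndarray
    angle_to_aea: np.ndarray        # radians in [0, pi]
    representativeness: np.ndarray  # cos(angle)


def _sign_fix(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def fit_gge(
    means: TraitMeans,
    partition_f: float = 0.5,
    scale_by_env_sd: bool = False,
) -> GGEModel:
    """Environment-centered (optionally column-standardized) rank-2 SVD.

    ``partition_f = 0.5`` (symmetric) suits the polygon view; use
    ``model.markers(1.0)`` for genotype-focused views and ``markers(0.0)``
    for environment-focused ones.
    """
    if means.n_genotypes < 3 or means.n_environments < 2:
        raise InsufficientDataError("GGE needs g >= 3 genotypes, e >= 2 environments")
    centered = means.matrix - means.environment_means[None, :]
    if scale_by_env_sd:
        sd = centered.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateDataError("zero-variance environment column")
        centered = centered / sd
    if not np.any(centered):
        raise DegenerateDataError("centered matrix is identically zero")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, vt = _sign_fix(u, vt)
    total = float(s @ s)
    explained_2d = float((s[:2] @ s[:2]) / total)
    G = u[:, :2] * s[:2] ** partition_f
    E = vt[:2].T * s[:2] ** (1.0 - partition_f)
    return GGEModel(
        genotypes=list(means.genotypes),
        environments=list(means.environments),
        centered=centered,
        partition_f=partition_f,
        singular_values=s,
        u=u,
        vt=vt,
        genotype_markers=G,
        environment_markers=E,
        explained_2d=explained_2d,
    )


# ---------------------------------------------------------------------------
# which-won-where geometry


def _convex_hull_ccw(points: np.ndarray) -> list[int]:
    """Monotone-chain convex hull; returns vertex indices in CCW order.

    Collinear points on the hull boundary are dropped; among coincident
    extremes the farther point is kept by the strict cross-product test.
    """
    order = np.lexsort((points[:, 1], points[:, 0]))

    def cross(o, a, b):
        return (points[a, 0] - points[o, 0]) * (points[b, 1] - points[o, 1]) - (
            points[a, 1] - points[o, 1]
        ) * (points[b, 0] - points[o, 0])

    lower: list[int] = []
    for idx in order:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], idx) <= 0:
            lower.pop()
        lower.append(int(idx))
    upper: list[int] = []
    for idx in order[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], idx) <= 0:
            upper.pop()
        upper.append(int(idx))
    return lower[:-1] + upper[:-1]


def which_won_where_markers(
    G: np.ndarray,
    E: np.ndarray,
    genotypes: list[str],
    environments: list[str],
) -> SectorPartition:
    """Polygon/sector partition from explicit 2-D marker matrices."""
    hull = _convex_hull_ccw(G)
    if len(hull) < 3:
        raise DegenerateDataError("genotype markers are collinear: no polygon")
    m = len(hull)
    # outward normal of CCW edge (a -> b) is the edge vector rotated -90 deg
    entries = []  # (ray angle of edge k, winning vertex = head of edge k)
    for k in range(m):
        a, b = hull[k], hull[(k + 1) % m]
        ex, ey = G[b] - G[a]
        angle = float(np.arctan2(-ex, ey) % (2 * np.pi))
        entries.append((angle, b))
    entries.sort()
    ray_angles = np.array([a for a, _ in entries])
    sector_winner = {
        idx: genotypes[entries[idx][1]] for idx in range(m)
    }
    environment_sector: dict[str, int] = {}
    for j, ename in enumerate(environments):
        theta = float(np.arctan2(E[j, 1], E[j, 0]) % (2 * np.pi))
        # sector idx spans CCW from ray_angles[idx] to the next ray
        idx = int(np.searchsorted(ray_angles, theta, side="right") - 1)
        if idx < 0:
            idx = m - 1
        environment_sector[ename] = idx
    groups: dict[int, list[str]] = {}
    for ename, idx in environment_sector.items():
        groups.setdefault(idx, []).append(ename)
    mega = [groups[k] for k in sorted(groups)]
    return SectorPartition(
        hull_vertices=[genotypes[i] for i in hull],
        ray_angles=ray_angles,
        sector_winner=sector_winner,
        environment_sector=environment_sector,
        mega_environments=mega,
    )


def which_won_where(model: GGEModel) -> SectorPartition:
    """Which-won-where partition at the model's own marker partition."""
    return which_won_where_markers(
        model.genotype_markers,
        model.environment_markers,
        model.genotypes,
        model.environments,
    )


# ---------------------------------------------------------------------------
# AEA-based views


def _aea_direction(E: np.ndarray) -> np.ndarray:
    mean_env = E.mean(axis=0)
    norm = np.linalg.norm(mean_env)
    if norm == 0:
        raise DegenerateDataError("environment markers sum to zero: AEA undefined")
    return mean_env / norm


def mean_vs_stability(model: GGEModel) -> GenotypeRanking:
    """Projection on the AEA (mean performance) and deviation from it
    (instability), computed in the genotype-focused scaling (f = 1)."""
    G, E = model.markers(1.0)
    aea = _aea_direction(E)
    proj = G @ aea
    dev = np.linalg.norm(G - np.outer(proj, aea), axis=1)
    return GenotypeRanking(
        genotypes=list(model.genotypes),
        aea_projection=proj,
        stability_deviation=dev,
    )


def rank_by_ideal(model: GGEModel) -> GenotypeRanking:
    """Distance of every genotype to the ideal point — maximal AEA
    projection with zero deviation — and the resulting ranking (1 = best)."""
    G, E = model.markers(1.0)
    aea = _aea_direction(E)
    proj = G @ aea
    dev = np.linalg.norm(G - np.outer(proj, aea), axis=1)
    ideal = proj.max() * aea
    dist = np.linalg.norm(G - ideal[None, :], axis=1)
    order = np.argsort(dist, kind="stable")
    rank = np.empty(len(dist), dtype=int)
    rank[order] = np.arange(1, len(dist) + 1)
    return GenotypeRanking(
        genotypes=list(model.genotypes),
        aea_projection=proj,
        stability_deviation=dev,
        distance_to_ideal=dist,
        rank=rank,
    )


def discriminativeness_representativeness(model: GGEModel) -> EnvironmentDiagnostics:
    """Environment vector length (discriminating power) and cosine of the
    angle to the AEA (representativeness), environment-focused (f = 0)."""
    _, E = model.markers(0.0)
    aea = _aea_direction(E)
    lengths = np.linalg.norm(E, axis=1)
    with np.errstate(invalid="ignore"):
        cosines = np.where(lengths > 0, (E @ aea) / np.where(lengths > 0, lengths, 1.0), 1.0)
    cosines = np.clip(cosines, -1.0, 1.0)
    return EnvironmentDiagnostics(
        environments=list(model.environments),
        vector_length=lengths,
        angle_to_aea=np.arccos(cosines),
        representativeness=cosines,
    )
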