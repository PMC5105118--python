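"""Landmark superimposition, partitioning, and PCA with a bootstrap stopping rule.

The workflow mirrors standard 3D geometric morphometrics: configurations of
p >= 4 homologous landmarks are superimposed by generalized Procrustes
analysis (GPA, removing translation, scale, and rotation), the aligned
dataset is optionally partitioned into anatomical subsets *after* GPA (so
each subset retains its position relative to the rest of the cranium), and
principal components of the aligned coordinates summarize shape variation.

Component retention follows a three-step stopping rule: bootstrap the
specimens, re-order and sign-flip the bootstrap axes to match the empirical
axes, and keep the leading components whose bootstrapped 95% eigenvalue
confidence interval stays above a broken-stick null spectrum. Seven degrees
of freedom are lost to superimposition in 3D, so at most 3p - 7 components
are ever candidates, and components under 1% of variance are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cranolex.errors import (
    DegenerateInputError,
    FormatError,
    InvalidParameterError,
    UnrecoverableSpecimenError,
)

logger = logging.getLogger(__name__)


@dataclass
class LandmarkConfiguration:
    """One specimen's p x 3 landmark coordinates with a missingness mask."""

    specimen_id: str
    population_id: str
    coords: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise InvalidParameterError("coords must be a p x 3 matrix")
        if self.coords.shape[0] < 4:
            raise InvalidParameterError("need at least 4 landmarks")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.coords.shape[0], dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        present = ~self.missing_mask
        if not np.all(np.isfinite(self.coords[present])):
            raise InvalidParameterError("non-finite coordinates at present landmarks")

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class LandmarkPartition:
    """A named landmark subset with bilateral pairing and midline metadata."""

    name: str
    indices: tuple
    bilateral_pairs: tuple = ()
    midline: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", tuple(int(i) for i in self.indices))
        object.__setattr__(
            self, "bilateral_pairs", tuple((int(a), int(b)) for a, b in self.bilateral_pairs)
        )
        object.__setattr__(self, "midline", tuple(int(i) for i in self.midline))


@dataclass
class AlignedShapeSet:
    """GPA output: n x p x 3 aligned shapes, the consensus, and centroid sizes."""

    shapes: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list = field(default_factory=list)
    population_ids: list = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flattened(self) -> np.ndarray:
        """n x 3p matrix of shape variables (landmark-major: x1 y1 z1 x2 ...)."""
        return self.shapes.reshape(self.n_specimens, -1)


@dataclass
class PCASolution:
    eigenvalues: np.ndarray
    scores: np.ndarray
    axes: np.ndarray
    cumulative_pct: np.ndarray
    retained: int | None = None
    broken_stick: np.ndarray | None = None
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None


# ---------------------------------------------------------------------------
# helpers


def _centroid_size(x: np.ndarray) -> float:
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def _optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||source @ R - target||_F (Kabsch)."""
    h = source.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    return u @ correction @ vt


def _check_nondegenerate(x: np.ndarray, who: str) -> None:
    c = x - x.mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-10) < 2:
        raise DegenerateInputError(f"{who}: landmarks are collinear (rank-deficient)")


# ---------------------------------------------------------------------------
# imputation by reflected relabelling


def impute_bilateral(
    config: LandmarkConfiguration, partition: LandmarkPartition
) -> LandmarkConfiguration:
    """Fill missing bilateral landmarks by reflected relabelling.

    The configuration is reflected across the least-squares plane of its
    midline landmarks, left/right labels are swapped, the reflected copy is
    superimposed onto the original by ordinary Procrustes (rotation and
    translation over landmarks present on both sides), and missing
    coordinates are read off the superimposed reflection. Non-missing
    coordinates are returned unchanged.

    Specimens missing a midline landmark cannot be recovered this way and
    raise :class:`UnrecoverableSpecimenError`.
    """
    missing = np.flatnonzero(config.missing_mask)
    if missing.size == 0:
        return config
    midline = set(partition.midline)
    pair_of = {}
    for a, b in partition.bilateral_pairs:
        pair_of[a] = b
        pair_of[b] = a
    for j in missing:
        if j in midline:
            raise UnrecoverableSpecimenError(
                f"specimen {config.specimen_id}: midline landmark {j} missing"
            )
        if j not in pair_of:
            raise UnrecoverableSpecimenError(
                f"specimen {config.specimen_id}: landmark {j} has no bilateral homologue"
            )
        if config.missing_mask[pair_of[j]]:
            raise UnrecoverableSpecimenError(
                f"specimen {config.specimen_id}: both sides of pair "
                f"({j}, {pair_of[j]}) missing"
            )

    coords = config.coords.copy()
    mid_idx = sorted(midline)
    if len(mid_idx) < 3:
        raise InvalidParameterError("need >= 3 midline landmarks to define a plane")
    mid = coords[mid_idx]
    centroid = mid.mean(axis=0)
    # plane normal = direction of least variance of the midline points
    _, _, vt = np.linalg.svd(mid - centroid)
    normal = vt[-1]
    # reflect every present landmark across the plane
    reflected = coords - 2.0 * ((coords - centroid) @ normal)[:, None] * normal
    # relabel: swap bilateral homologues (midline maps to itself)
    relabelled = reflected.copy()
    for a, b in partition.bilateral_pairs:
        relabelled[[a, b]] = reflected[[b, a]]
    # landmark j of the relabelled copy is defined iff its source (the
    # homologue, or j itself on the midline) was present
    source_index = np.arange(config.n_landmarks)
    for a, b in partition.bilateral_pairs:
        source_index[a], source_index[b] = b, a
    relabelled_present = ~config.missing_mask[source_index]
    common = relabelled_present & ~config.missing_mask

    # ordinary Procrustes (rotation + translation, no scaling) of the
    # relabelled reflection onto the original over the shared landmarks
    src = relabelled[common]
    dst = coords[common]
    src_c = src.mean(axis=0)
    dst_c = dst.mean(axis=0)
    rot = _optimal_rotation(src - src_c, dst - dst_c)
    fitted = (relabelled - src_c) @ rot + dst_c

    coords[missing] = fitted[missing]
    return replace(
        config,
        coords=coords,
        missing_mask=np.zeros(config.n_landmarks, dtype=bool),
    )


# ---------------------------------------------------------------------------
# generalized Procrustes analysis


def gpa(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> AlignedShapeSet:
    """Generalized Procrustes superimposition of complete configurations.

    Each shape is centered and scaled to unit centroid size, then
    iteratively rotated (proper rotations only) to the running consensus
    until the consensus changes by less than ``tol``.
    """
    if not configs:
        raise InvalidParameterError("no configurations given")
    p = configs[0].n_landmarks
    shapes = []
    sizes = []
    for cfg in configs:
        if cfg.missing_mask.any():
            raise InvalidParameterError(
                f"specimen {cfg.specimen_id} has missing landmarks; impute first"
            )
        if cfg.n_landmarks != p:
            raise InvalidParameterError("landmark counts differ across specimens")
        _check_nondegenerate(cfg.coords, f"specimen {cfg.specimen_id}")
        centered = cfg.coords - cfg.coords.mean(axis=0)
        size = _centroid_size(cfg.coords)
        shapes.append(centered / size)
        sizes.append(size)
    x = np.array(shapes)

    consensus = x[0].copy()
    consensus /= _centroid_size(consensus)
    for _ in range(max_iter):
        for i in range(x.shape[0]):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        new_consensus /= _centroid_size(new_consensus)
        if np.abs(new_consensus - consensus).max() < tol:
            consensus = new_consensus
            break
        consensus = new_consensus
    # final pass against the converged consensus
    for i in range(x.shape[0]):
        x[i] = x[i] @ _optimal_rotation(x[i], consensus)

    return AlignedShapeSet(
        shapes=x,
        consensus=x.mean(axis=0),
        centroid_sizes=np.array(sizes),
        specimen_ids=[c.specimen_id for c in configs],
        population_ids=[c.population_id for c in configs],
    )


def subset_partition(aligned: AlignedShapeSet, partition: LandmarkPartition) -> AlignedShapeSet:
    """Select a landmark subset of an aligned set WITHOUT re-superimposition.

    Taking rows of the whole-configuration alignment keeps each subset's
    position relative to the rest of the configuration, which is the point
    of partitioning after (not before) GPA.
    """
    idx = list(partition.indices)
    p = aligned.n_landmarks
    if any(i < 0 or i >= p for i in idx):
        raise InvalidParameterError(f"partition {partition.name}: index out of range")
    return AlignedShapeSet(
        shapes=aligned.shapes[:, idx, :],
        consensus=aligned.consensus[idx, :],
        centroid_sizes=aligned.centroid_sizes.copy(),
        specimen_ids=list(aligned.specimen_ids),
        population_ids=list(aligned.population_ids),
    )


# ---------------------------------------------------------------------------
# PCA and the stopping rule


def pca(aligned: AlignedShapeSet) -> PCASolution:
    """Covariance PCA of the flattened, mean-centered aligned coordinates.

    No variable scaling is applied: after GPA all coordinates share units,
    so the covariance (not correlation) matrix is the appropriate basis.
    """
    flat = aligned.flattened()
    n = flat.shape[0]
    if n < 3:
        raise InvalidParameterError("need at least 3 specimens for PCA")
    centered = flat - flat.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    scores = u * s
    total = eigenvalues.sum()
    cumulative = 100.0 * np.cumsum(eigenvalues) / total if total > 0 else np.zeros_like(eigenvalues)
    return PCASolution(
        eigenvalues=eigenvalues,
        scores=scores,
        axes=vt,
        cumulative_pct=cumulative,
    )


def broken_stick_spectrum(total_variance: float, m: int) -> np.ndarray:
    """Expected eigenvalues when total variance is broken at random into m parts."""
    return np.array(
        [total_variance / m * sum(1.0 / i for i in range(k, m + 1)) for k in range(1, m + 1)]
    )


def _match_axes(ref_axes: np.ndarray, boot_axes: np.ndarray, boot_eigs: np.ndarray) -> np.ndarray:
    """Reorder bootstrap eigenvalues so each empirical axis gets its best match.

    Greedy in descending empirical-eigenvalue order: empirical axis k takes
    the unmatched bootstrap axis with maximal absolute loading correlation
    (ties broken by lower index). Sign flips are irrelevant to eigenvalues.
    """
    k_ref = ref_axes.shape[0]
    k_boot = boot_axes.shape[0]
    corr = np.abs(ref_axes @ boot_axes.T)  # axes are unit vectors
    taken = np.zeros(k_boot, dtype=bool)
    out = np.zeros(k_ref)
    for k in range(k_ref):
        avail = np.flatnonzero(~taken)
        if avail.size == 0:
            break
        best = avail[int(np.argmax(corr[k, avail]))]
        taken[best] = True
        out[k] = boot_eigs[best]
    return out


def select_components(
    aligned: AlignedShapeSet,
    n_boot: int = 10000,
    ci: float = 0.95,
    seed: int | None = None,
    min_pct: float = 1.0,
) -> PCASolution:
    """Bootstrap broken-stick stopping rule for PCA component retention.

    Specimens are resampled with replacement ``n_boot`` times and the PCA
    recomputed; bootstrap axes are re-ordered (and implicitly sign-flipped)
    to correspond to the empirical axes before eigenvalue CIs are formed.
    Components are retained up to (exclusive) the first rank whose CI upper
    bound falls below the broken-stick expectation; components explaining
    less than ``min_pct`` percent of variance are dropped, and the last 7
    components (the superimposition degrees of freedom) are never candidates.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is very small; eigenvalue CIs will be unstable", n_boot)
    sol = pca(aligned)
    n = aligned.n_specimens
    p = aligned.n_landmarks
    max_components = 3 * p - 7
    m = int(min(max_components, len(sol.eigenvalues), n - 1))
    m = max(m, 1)
    total = float(sol.eigenvalues.sum())
    bs = broken_stick_spectrum(total, m)

    rng = np.random.default_rng(seed)
    ref_axes = sol.axes[:m]
    boot_eigs = np.zeros((n_boot, m))
    flat = aligned.flattened()
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = flat[idx]
        centered = sample - sample.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eig = s**2 / (n - 1)
        kk = min(m, len(eig))
        boot_eigs[b] = _match_axes(ref_axes, vt[:kk], eig[:kk])

    # basic (reflected) bootstrap intervals: percentile intervals of top
    # eigenvalues are biased upward at these sample sizes (resampling
    # duplicates concentrate variance), which would keep noise components
    alpha = (1.0 - ci) / 2.0
    emp = sol.eigenvalues[:m]
    lower = 2.0 * emp - np.quantile(boot_eigs, 1.0 - alpha, axis=0)
    upper = 2.0 * emp - np.quantile(boot_eigs, alpha, axis=0)

    retained = m
    for k in range(m):
        if upper[k] < bs[k]:
            retained = k
            break
    pct = 100.0 * sol.eigenvalues / total if total > 0 else np.zeros_like(sol.eigenvalues)
    while retained > 0 and pct[retained - 1] < min_pct:
        retained -= 1

    sol.retained = retained
    sol.broken_stick = bs
    sol.ci_lower = lower
    sol.ci_upper = upper
    return sol


def retained_scores(aligned: AlignedShapeSet, solution: PCASolution) -> pd.DataFrame:
    """Long table (specimen, population, PC1..PCT) of the retained scores."""
    t = solution.retained if solution.retained else 0
    if t < 1:
        raise DegenerateInputError("no components retained")
    cols = {f"PC{k + 1}": solution.scores[:, k] for k in range(t)}
    return pd.DataFrame(
        {"specimen": aligned.specimen_ids, "population": aligned.population_ids, **cols}
    )


# ---------------------------------------------------------------------------
# file I/O


def read_landmarks_csv(path) -> list[LandmarkConfiguration]:
    """Read long-format landmark CSV: specimen, population, landmark, x, y, z.

    Empty x/y/z cells mark a missing landmark.
    """
    df = pd.read_csv(path)
    required = {"specimen", "population", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"landmark CSV needs columns {sorted(required)}")
    configs = []
    for (spec, pop), grp in df.groupby(["specimen", "population"], sort=False):
        grp = grp.sort_values("landmark")
        p = int(grp["landmark"].max()) + 1
        coords = np.full((p, 3), np.nan)
        coords[grp["landmark"].to_numpy(int)] = grp[["x", "y", "z"]].to_numpy(float)
        missing = ~np.isfinite(coords).all(axis=1)
        coords[missing] = 0.0
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(spec),
                population_id=str(pop),
                coords=coords,
                missing_mask=missing,
            )
        )
    return configs


def write_landmarks_csv(configs: list[LandmarkConfiguration], path) -> None:
    rows = []
    for cfg in configs:
        for j in range(cfg.n_landmarks):
            if cfg.missing_mask[j]:
                x = y = z = ""
            else:
                x, y, z = cfg.coords[j]
            rows.append(
                {
                    "specimen": cfg.specimen_id,
                    "population": cfg.population_id,
                    "landmark": j,
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tps(path) -> list[LandmarkConfiguration]:
    """Read a 3D TPS file (LM3= blocks with ID=population:specimen lines)."""
    configs = []
    coords: list | None = None
    expect = 0
    specimen = population = None

    def flush():
        nonlocal coords, specimen, population
        if coords is not None:
            configs.append(
                LandmarkConfiguration(
                    specimen_id=specimen or f"spec{len(configs)}",
                    population_id=population or "",
                    coords=np.array(coords, dtype=float),
                )
            )
        coords = None
        specimen = population = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush()
                expect = int(line.split("=", 1)[1])
                coords = []
            elif upper.startswith("ID="):
                label = line.split("=", 1)[1]
                if ":" in label:
                    population, specimen = label.split(":", 1)
                else:
                    specimen = label
            elif upper.startswith(("IMAGE=", "SCALE=")):
                continue
            else:
                if coords is None:
                    raise FormatError(f"{path}:{lineno}: coordinates before LM3=")
                parts = line.split()
                if len(parts) != 3:
                    raise FormatError(f"{path}:{lineno}: expected 3 coordinates")
                coords.append([float(v) for v in parts])
        flush()
    for cfg in configs:
        if expect and cfg.n_landmarks != expect:
            pass  # TPS files may mix counts; validated downstream by gpa
    return configs


def write_tps(configs: list[LandmarkConfiguration], path) -> None:
    with open(path, "w") as fh:
        for cfg in configs:
            if cfg.missing_mask.any():
                raise InvalidParameterError("TPS export requires complete configurations")
            fh.write(f"LM3={cfg.n_landmarks}\n")
            for row in cfg.coords:
                fh.write(f"{row[0]:.10g} {row[1]:.10g} {row[2]:.10g}\n")
            fh.write(f"ID={cfg.population_id}:{cfg.specimen_id}\n")
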